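"""ASV-side community structure statistics.

Rarefaction to even depth, Good/Chao-style sample-coverage estimation,
core-taxon filtering, centered log-ratio transform, Bray-Curtis
dissimilarity, non-metric multidimensional scaling (Kruskal stress-1 via
iterative majorization with isotonic regression), sequential multi-term
PERMANOVA, and alpha diversity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from skbio import DistanceMatrix

from .containers import AsvTable


# ---------------------------------------------------------------------------
# Rarefaction and coverage
# ---------------------------------------------------------------------------

def rarefy_even_depth(table: AsvTable, depth: int | str = "min",
                      seed: int = 0) -> AsvTable:
    """Subsample every sample without replacement to a common depth.

    ``depth='min'`` uses the lowest sample sum. Samples below the requested
    depth are dropped with a warning; all-zero taxon columns are retained.
    """
    sums = table.counts.sum(axis=1)
    if depth == "min":
        depth = int(sums.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    keep = sums[sums >= depth].index
    if len(keep) < len(sums):
        warnings.warn(
            f"dropping {len(sums) - len(keep)} samples below depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty((len(keep), table.counts.shape[1]), dtype=np.int64)
    for i, s in enumerate(keep):
        row = table.counts.loc[s].to_numpy(dtype=np.int64)
        out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=keep, columns=table.counts.columns)
    return AsvTable(counts=counts, taxonomy=table.taxonomy,
                    metadata=table.metadata.loc[keep])


def estimate_coverage(table: AsvTable) -> pd.Series:
    """Per-sample coverage estimate from singleton/doubleton counts.

    C = 1 - (f1/n) * (n-1) f1 / ((n-1) f1 + 2 f2); C = 1 when f1 = 0,
    NaN for empty samples.
    """
    cov = {}
    for s, row in table.counts.iterrows():
        x = row.to_numpy()
        n = int(x.sum())
        if n == 0:
            cov[s] = np.nan
            continue
        f1 = int((x == 1).sum())
        f2 = int((x == 2).sum())
        if f1 == 0:
            cov[s] = 1.0
        else:
            cov[s] = 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))
    return pd.Series(cov, name="coverage")


# ---------------------------------------------------------------------------
# Core-taxon filter and transforms
# ---------------------------------------------------------------------------

def filter_core_taxa(table: AsvTable, mean_thresh: float = 0.005,
                     prevalence: float = 0.8,
                     group_by: str = "plant") -> AsvTable:
    """Two-step core filter.

    Step 1 drops taxa whose grand-mean relative abundance is below
    ``mean_thresh``; step 2 keeps a taxon only if it is present (count > 0)
    in at least ``prevalence`` of replicates within at least one
    ``group_by`` group.
    """
    rel = table.relative_abundance()
    keep1 = rel.mean(axis=0) >= mean_thresh
    taxa = [t for t in table.taxon_ids if keep1[t]]

    groups = table.metadata[group_by]
    present = table.counts[taxa] > 0
    keep2 = pd.Series(False, index=taxa)
    for g, idx in groups.groupby(groups).groups.items():
        if len(idx) < 2:
            warnings.warn(f"group {g!r} has fewer than 2 replicates; skipped")
            continue
        frac = present.loc[idx].mean(axis=0)
        keep2 |= frac >= prevalence
    survivors = [t for t in taxa if keep2[t]]
    return table.subset_taxa(survivors)


def clr_transform(counts: pd.DataFrame | AsvTable,
                  pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform of (pseudocounted) counts; rows sum to 0."""
    if isinstance(counts, AsvTable):
        counts = counts.counts
    x = counts.to_numpy(dtype=float) + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def bray_curtis_matrix(relabund: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on row-proportions: BC = 1 - sum(min)."""
    X = relabund.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("relative abundances must be non-negative")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids=list(relabund.index))


def aitchison_matrix(counts: pd.DataFrame | AsvTable,
                     pseudocount: float = 0.5) -> DistanceMatrix:
    """Euclidean distance between CLR rows (Aitchison distance)."""
    clr = clr_transform(counts, pseudocount)
    d = squareform(pdist(clr.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, ids=list(clr.index))


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    site_scores: pd.DataFrame
    stress: float | None = None
    eigenvalues: np.ndarray | None = None
    method: str = ""
    converged: bool = True


def _kruskal_stress(d_config: np.ndarray, d_hat: np.ndarray) -> float:
    denom = float((d_config ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_config - d_hat) ** 2).sum() / denom))


def nmds_ordinate(d: DistanceMatrix, k: int = 2, n_starts: int = 20,
                  seed: int = 0, max_iter: int = 300,
                  tol: float = 1e-7) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Alternates isotonic regression of configuration distances on the input
    dissimilarity ranks (primary tie-breaking: ties ordered by current
    configuration distance) with a Guttman majorization update, from
    ``n_starts`` random starts; best configuration is centered and rotated
    to its principal axes.
    """
    D = np.asarray(d.data, dtype=float)
    n = D.shape[0]
    if n < k + 2:
        raise ValueError("need at least k + 2 samples for NMDS")
    iu = np.triu_indices(n, 1)
    delta = D[iu]
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    best_X, best_stress, converged = None, np.inf, False
    for _ in range(n_starts):
        X = rng.normal(size=(n, k))
        prev = np.inf
        for _ in range(max_iter):
            diff = X[:, None, :] - X[None, :, :]
            dist = np.sqrt((diff ** 2).sum(axis=-1))
            dvec = dist[iu]
            # primary approach to ties: within equal delta, order by dvec;
            # exact-zero dissimilarities demand coincident points
            order = np.lexsort((dvec, delta))
            fitted = np.empty_like(dvec)
            fitted[order] = iso.fit_transform(np.arange(len(order)), dvec[order])
            fitted[delta == 0] = 0.0
            stress = _kruskal_stress(dvec, fitted)
            if stress > prev:       # keep recorded sequence non-increasing
                break
            if prev - stress < tol:
                prev = stress
                converged = True
                break
            prev = stress
            # Guttman transform toward the isotonic targets
            dhat = np.zeros((n, n))
            dhat[iu] = fitted
            dhat = dhat + dhat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, dhat / dist, 0.0)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = B @ X / n
        if prev < best_stress:
            best_stress, best_X = prev, X
    if not converged:
        warnings.warn("NMDS did not fully converge in any start")
    best_X = best_X - best_X.mean(axis=0)
    _, _, vt = np.linalg.svd(best_X, full_matrices=False)
    best_X = best_X @ vt.T
    scores = pd.DataFrame(best_X, index=list(d.ids),
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(site_scores=scores, stress=best_stress,
                            method="NMDS", converged=converged)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    table: pd.DataFrame          # index: terms + 'Residual' + 'Total'
    n_permutations: int = 0

    @property
    def r2(self) -> pd.Series:
        return self.table["R2"]


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _term_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for a term: treatment-coded dummies for categoricals
    (and their products for interactions), raw values for numerics."""
    parts = term.split(":")
    blocks = []
    for p in parts:
        col = metadata[p]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float).reshape(-1, 1))
        else:
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            blocks.append(dummies)
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(len(out), -1)
    return out


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > 1e-10 * max(s.max(), 1.0)).sum())
    u = u[:, :rank]
    return u @ u.T, rank


def permanova(d: DistanceMatrix, metadata: pd.DataFrame,
              terms: list[str] | None = None, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Sequential (Type I) multi-term PERMANOVA on a distance matrix.

    Terms are added in the given order (e.g. ``["production", "plant",
    "production:plant", "latitude", "longitude"]``); pseudo-F p-values come
    from free permutation of sample rows.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if terms is None:
        terms = ["production", "plant", "production:plant",
                 "latitude", "longitude"]
    ids = list(d.ids)
    meta = metadata.loc[ids]
    D = np.asarray(d.data, dtype=float)
    n = D.shape[0]
    G = _gower_center(D)
    ss_total = float(np.trace(G))

    # nested projector sequence
    X = np.ones((n, 1))
    H_prev, rank_prev = _hat(X)
    projs, dfs = [], []
    for t in terms:
        X = np.hstack([X, _term_columns(meta, t)])
        H, rank = _hat(X)
        df = rank - rank_prev
        if df <= 0:
            warnings.warn(f"term {t!r} adds no rank (aliased); df = 0")
        projs.append(H - H_prev)
        dfs.append(df)
        H_prev, rank_prev = H, rank
    H_full, rank_full = H_prev, rank_prev
    R = np.eye(n) - H_full
    df_res = n - rank_full

    def _ss(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float((P * Gm.T).sum()) for P in projs])
        ss_res = float((R * Gm.T).sum())
        return ss_terms, ss_res

    ss_terms, ss_res = _ss(G)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_terms / np.maximum(dfs, 1)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_t, ss_r = _ss(Gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = (ss_t / np.maximum(dfs, 1)) / (ss_r / df_res)
        # tolerance so permutations label-equivalent to the identity count
        # as ties rather than falling below from roundoff
        exceed += f_p >= f_obs - 1e-9 * np.maximum(np.abs(f_obs), 1.0)
    pvals = (exceed + 1) / (n_perm + 1)

    rows = []
    for t, df, ss, f, p in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows.append({"term": t, "df": df, "SumOfSqs": ss,
                     "R2": ss / ss_total if ss_total else 0.0,
                     "F": f, "p": p})
    rows.append({"term": "Residual", "df": df_res, "SumOfSqs": ss_res,
                 "R2": ss_res / ss_total if ss_total else 0.0,
                 "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SumOfSqs": ss_total,
                 "R2": 1.0, "F": np.nan, "p": np.nan})
    tab = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=tab, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def diversity_from_proportions(P: pd.DataFrame) -> pd.DataFrame:
    """Richness, Shannon H (natural log), and Pielou evenness per row.

    Evenness is defined as 0 when richness <= 1.
    """
    X = P.to_numpy(dtype=float)
    rich = (X > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logx = np.where(X > 0, np.log(np.where(X > 0, X, 1.0)), 0.0)
    H = -(X * logx).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        even = np.where(rich > 1, H / np.log(np.maximum(rich, 2)), 0.0)
    return pd.DataFrame(
        {"richness": rich, "shannon": H, "evenness": even}, index=P.index
    )


def alpha_diversity(table: AsvTable) -> pd.DataFrame:
    """Alpha diversity of the (ideally rarefied) ASV table."""
    rel = table.relative_abundance()
    # renormalize in case of all-zero rows
    return diversity_from_proportions(rel)
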