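"""Single-cell Raman phenotyping: signature-peak QC, spectral preprocessing,
OPU clustering with AIC-based cutoff selection, OPU tables, Fisher rank
scores, and OPU diversity.

The QC gate requires a local maximum in both the phenylalanine (1003 cm^-1)
and amide I (1657 cm^-1) windows, with prominence measured against a robust
(MAD) noise estimate from an assumed signal-free high-wavenumber region.
Clustering uses 1 - Pearson correlation with average linkage; singleton
clusters are pooled as "unclassified".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import solveh_banded
from scipy.signal import find_peaks, savgol_filter
from scipy.spatial.distance import squareform

from .containers import OPUAssignment, OPUTable, SpectrumSet
from .community import diversity_from_proportions

SIGNATURE_WINDOWS = (1003.0, 1657.0)
NOISE_REGION = (1750.0, 1800.0)
DEFAULT_CUTOFF = 0.44

# Static lookup of diagnostic band assignments (biomolecular annotations).
BAND_ANNOTATIONS = {
    687.0: "carbon-related (Si-CH rocking; nucleotides, cytochrome c region)",
    1003.0: "phenylalanine (signature)",
    1250.0: "lipid CH2",
    1358.0: "protein (amino acids, peptide bonds)",
    1450.0: "lipid CH2",
    1574.0: "protein (amino acids, peptide bonds)",
    1657.0: "amide I (signature)",
}


# ---------------------------------------------------------------------------
# Baseline and preprocessing
# ---------------------------------------------------------------------------

def als_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01,
                 n_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline (Whittaker smoother with asymmetric
    weights), solved as a pentadiagonal system. Exactly equivariant to
    constant offsets."""
    m = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m))
    DtD = (lam * (D.T @ D)).todia()
    # upper banded form for solveh_banded: rows are diagonals 2, 1, 0
    base = np.zeros((3, m))
    offsets = {off: i for i, off in enumerate(DtD.offsets)}
    for off in (2, 1, 0):
        row = DtD.data[offsets[off]]
        base[2 - off] = row
    w = np.ones(m)
    z = y
    for _ in range(n_iter):
        ab = base.copy()
        ab[2] = ab[2] + w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def _mad_noise(y: np.ndarray, wavenumbers: np.ndarray,
               region: tuple[float, float] = NOISE_REGION) -> float:
    mask = (wavenumbers >= region[0]) & (wavenumbers <= region[1])
    seg = y[mask] if mask.any() else y
    mad = np.median(np.abs(seg - np.median(seg)))
    return float(1.4826 * mad) or 1e-12


def qc_signature_filter(spectra: SpectrumSet, window_halfwidth: float = 5.0,
                        snr_min: float = 3.0,
                        noise_region: tuple[float, float] = NOISE_REGION,
                        ) -> tuple[SpectrumSet, list[str]]:
    """Keep spectra with a sufficiently prominent local maximum in BOTH
    signature windows (1003 +- w and 1657 +- w) after baseline subtraction.

    Returns the passing subset (input order preserved) and the rejected ids.
    """
    wn = spectra.wavenumbers
    for c in SIGNATURE_WINDOWS:
        if c - window_halfwidth < wn[0] or c + window_halfwidth > wn[-1]:
            raise ValueError("wavenumber grid does not cover a signature window")
    if spectra.n_spectra == 0:
        return spectra, []

    passed, rejected = [], []
    X = spectra.intensities.to_numpy(dtype=float)
    sg_win = min(11, (X.shape[1] // 2) * 2 - 1)
    for cid, y in zip(spectra.cell_ids, X):
        sig = y - als_baseline(y)
        thresh = snr_min * _mad_noise(sig, wn, noise_region)
        # light smoothing so detection is not driven by single-point noise;
        # prominence is evaluated locally (wlen) rather than spectrum-wide
        smooth = savgol_filter(sig, sg_win, 3) if sg_win >= 5 else sig
        peaks, _ = find_peaks(smooth, height=thresh, prominence=thresh,
                              wlen=int(20 * window_halfwidth))
        ok = True
        for c in SIGNATURE_WINDOWS:
            in_win = np.abs(wn[peaks] - c) <= window_halfwidth
            if not in_win.any():
                ok = False
                break
        (passed if ok else rejected).append(cid)
    return spectra.subset(passed), rejected


def preprocess_spectrum(wavenumbers: np.ndarray, intensities: np.ndarray,
                        grid: np.ndarray, sg_window: int = 11,
                        sg_order: int = 3,
                        als_lam: float = 1e5) -> np.ndarray | None:
    """Interpolate -> ALS baseline subtraction -> Savitzky-Golay smoothing ->
    unit-vector (L2) normalization. Returns None for degenerate (all-zero
    after baseline removal) spectra."""
    y = np.interp(grid, wavenumbers, intensities)
    y = y - als_baseline(y, lam=als_lam)
    y = savgol_filter(y, sg_window, sg_order)
    norm = np.linalg.norm(y)
    if norm < 1e-12:
        return None
    return y / norm


def preprocess_set(spectra: SpectrumSet, grid: np.ndarray | None = None,
                   **kwargs) -> SpectrumSet:
    """Apply :func:`preprocess_spectrum` to every cell; degenerate spectra
    are excluded with a warning."""
    wn = spectra.wavenumbers
    grid = wn if grid is None else np.asarray(grid, dtype=float)
    rows, keep = [], []
    X = spectra.intensities.to_numpy(dtype=float)
    for cid, y in zip(spectra.cell_ids, X):
        out = preprocess_spectrum(wn, y, grid, **kwargs)
        if out is None:
            warnings.warn(f"degenerate spectrum {cid!r} excluded")
            continue
        rows.append(out)
        keep.append(cid)
    intens = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, grid.size)),
                          index=keep, columns=grid)
    return SpectrumSet(intensities=intens, cells=spectra.cells.loc[keep].copy())


# ---------------------------------------------------------------------------
# OPU clustering
# ---------------------------------------------------------------------------

def correlation_dissimilarity(spectra: SpectrumSet) -> np.ndarray:
    """Pairwise d = 1 - Pearson correlation between spectra, clipped to
    [0, 2] with an exact-zero diagonal."""
    X = spectra.intensities.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    d = np.clip(1.0 - corr, 0.0, 2.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _labels_from_flat(flat: np.ndarray, cell_ids: list[str]) -> pd.Series:
    """Relabel flat cluster numbers: singletons -> 'unclassified', other
    clusters -> OPU-0, OPU-1, ... in decreasing size order (ties broken by
    smallest member cell id)."""
    ser = pd.Series(flat, index=cell_ids)
    sizes = ser.value_counts()
    multi = [c for c in sizes.index if sizes[c] > 1]
    multi.sort(key=lambda c: (-sizes[c], min(ser.index[ser == c])))
    mapping = {c: f"OPU-{i}" for i, c in enumerate(multi)}
    return ser.map(lambda c: mapping.get(c, "unclassified"))


def cluster_opus(spectra: SpectrumSet, cutoff: float = DEFAULT_CUTOFF,
                 ) -> OPUAssignment:
    """Average-linkage hierarchical clustering of preprocessed spectra at the
    given correlation-distance cutoff; singletons become 'unclassified'."""
    if not 0.0 < cutoff < 2.0:
        raise ValueError("cutoff must be in (0, 2)")
    ids = spectra.cell_ids
    if len(ids) < 2:
        labels = pd.Series("unclassified", index=ids, dtype=object)
        return OPUAssignment(labels=labels, cutoff=cutoff, linkage_tree=None)
    d = correlation_dissimilarity(spectra)
    Z = linkage(squareform(d, checks=False), method="average")
    flat = fcluster(Z, t=cutoff, criterion="distance")
    return OPUAssignment(labels=_labels_from_flat(flat, ids), cutoff=cutoff,
                         linkage_tree=Z)


def _pca_project(X: np.ndarray, var_explained: float = 0.95) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    if s.sum() == 0:
        return Xc[:, :1]
    frac = np.cumsum(s ** 2) / (s ** 2).sum()
    q = int(np.searchsorted(frac, var_explained) + 1)
    return u[:, :q] * s[:q]


def select_cutoff_by_aic(spectra: SpectrumSet,
                         candidates: list[float],
                         var_explained: float = 0.95,
                         ) -> tuple[float, pd.DataFrame]:
    """Choose the clustering cutoff minimizing a Gaussian (spherical
    within-cluster noise) AIC in the principal-component space explaining
    ``var_explained`` of the variance.

    AIC(h) = n q ln(RSS(h) / (n q)) + 2 k(h) q, with k = number of flat
    clusters (singletons each count). Ties go to the smallest cutoff; a
    fully degenerate scan (every candidate gives all-singleton clusterings)
    returns the largest candidate.
    """
    cands = sorted(set(float(c) for c in candidates))
    if len(cands) < 2:
        raise ValueError("need at least 2 candidate cutoffs")
    ids = spectra.cell_ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 spectra")
    d = correlation_dissimilarity(spectra)
    Z = linkage(squareform(d, checks=False), method="average")
    Y = _pca_project(spectra.intensities.to_numpy(dtype=float), var_explained)
    q = Y.shape[1]

    rows = []
    for h in cands:
        flat = fcluster(Z, t=h, criterion="distance")
        k = len(np.unique(flat))
        rss = 0.0
        for c in np.unique(flat):
            mem = Y[flat == c]
            if len(mem) > 1:
                rss += float(((mem - mem.mean(axis=0)) ** 2).sum())
        rss = max(rss, np.finfo(float).tiny * n * q)
        aic = n * q * np.log(rss / (n * q)) + 2.0 * k * q
        n_multi = int((np.bincount(flat)[1:] > 1).sum())
        rows.append({"cutoff": h, "aic": aic, "k": k,
                     "n_non_singleton": n_multi, "rss": rss})
    curve = pd.DataFrame(rows)
    if (curve["k"] == n).all():
        warnings.warn("degenerate AIC curve: all candidates give singletons")
        return cands[-1], curve
    best = curve.loc[curve["aic"].idxmin(), "cutoff"]  # idxmin -> smallest h on ties
    return float(best), curve


# ---------------------------------------------------------------------------
# OPU tables, Fisher scores, diversity
# ---------------------------------------------------------------------------

def build_opu_table(assignment: OPUAssignment,
                    cell_meta: pd.DataFrame) -> OPUTable:
    """Per-sample OPU shares (including the 'unclassified' pool).

    Samples with zero QC-passing cells are dropped with a warning; OPU
    columns are ordered OPU-0, OPU-1, ... with 'unclassified' last.
    """
    lab = assignment.labels
    samples = cell_meta.loc[lab.index, "sample_id"]
    tab = pd.crosstab(samples, lab)
    all_samples = cell_meta["sample_id"].unique()
    missing = set(all_samples) - set(tab.index)
    if missing:
        warnings.warn(f"samples with no QC-passing cells dropped: {sorted(missing)}")
    cols = assignment.opu_ids
    if "unclassified" in tab.columns:
        cols = cols + ["unclassified"]
    else:
        tab["unclassified"] = 0
        cols = cols + ["unclassified"]
    tab = tab.reindex(columns=cols, fill_value=0)
    shares = tab.div(tab.sum(axis=1), axis=0)
    shares.index.name = "sample_id"
    return OPUTable(shares=shares)


@dataclass
class FisherScoreProfile:
    scores: pd.Series      # index = wavenumber, Fisher discriminant score
    ranks: pd.Series       # descending rank order (1 = most discriminative)

    def top(self, n: int = 10) -> pd.Series:
        return self.scores.sort_values(ascending=False).head(n)


def fisher_rank_scores(spectra: SpectrumSet,
                       assignment: OPUAssignment) -> FisherScoreProfile:
    """Per-wavenumber Fisher discriminant score across OPU classes.

    F(j) = sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c sigma_cj^2 over OPU
    classes (unclassified excluded); zero within-class variances are guarded
    with machine epsilon. Requires >= 2 classes with >= 2 members.
    """
    lab = assignment.labels
    keep = lab[lab != "unclassified"]
    classes = [c for c, k in keep.value_counts().items() if k >= 2]
    if len(classes) < 2:
        raise ValueError("need >= 2 OPU classes with >= 2 members each")
    X = spectra.intensities.loc[keep.index[keep.isin(classes)]]
    y = keep[keep.isin(classes)]
    grand = X.mean(axis=0).to_numpy()
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        mem = X.loc[y.index[y == c]].to_numpy()
        nc = len(mem)
        mu = mem.mean(axis=0)
        var = mem.var(axis=0, ddof=1)
        num += nc * (mu - grand) ** 2
        den += nc * np.maximum(var, np.finfo(float).eps)
    F = num / den
    scores = pd.Series(F, index=spectra.wavenumbers, name="fisher_score")
    ranks = scores.rank(ascending=False, method="first").astype(int)
    return FisherScoreProfile(scores=scores, ranks=ranks)


def opu_diversity(table: OPUTable) -> pd.DataFrame:
    """Richness / Shannon / Pielou evenness over identified OPUs (the
    unclassified pool is excluded and shares renormalized)."""
    return diversity_from_proportions(table.classified_shares(renormalize=True))
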