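"""Linking phenotypic (OPU) and taxonomic (ASV) profiles.

Diversity-coupling OLS regressions (linear and log1p), distance-based
redundancy analysis with OPU abundances as constraints, envfit-style
permutation fitting of OPUs onto ordination axes, and Spearman OPU-taxon
correlation maps with BH control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .containers import OPUTable
from .community import _gower_center


def _stars(p: float, levels=(0.05, 0.01, 0.001)) -> str:
    s = ""
    for lv in levels:
        if p < lv:
            s += "*"
    return s


# ---------------------------------------------------------------------------
# Diversity coupling regressions
# ---------------------------------------------------------------------------

def diversity_coupling_regression(asv_div: pd.DataFrame, opu_div: pd.DataFrame,
                                  treatment: pd.Series | None = None,
                                  models: tuple[str, ...] = ("linear", "log1p"),
                                  ) -> pd.DataFrame:
    """OLS of each OPU diversity metric on the paired ASV metric, per
    treatment and model.

    ``log1p`` maps both variables through ln(1 + x) before fitting. Cells
    with n < 3 are omitted. Returns a tidy frame with columns
    (treatment, metric, model, slope, intercept, r2, p, n, stars)."""
    common = asv_div.index.intersection(opu_div.index)
    asv_div = asv_div.loc[common]
    opu_div = opu_div.loc[common]
    if treatment is None:
        treatment = pd.Series("all", index=common)
    else:
        treatment = treatment.loc[common]
    rows = []
    for grp, idx in treatment.groupby(treatment).groups.items():
        for metric in ("richness", "shannon", "evenness"):
            x0 = asv_div.loc[idx, metric].to_numpy(dtype=float)
            y0 = opu_div.loc[idx, metric].to_numpy(dtype=float)
            for model in models:
                if model == "log1p":
                    x, y = np.log1p(x0), np.log1p(y0)
                else:
                    x, y = x0, y0
                if len(x) < 3 or np.ptp(x) == 0:
                    continue
                res = stats.linregress(x, y)
                rows.append({
                    "treatment": grp, "metric": metric, "model": model,
                    "slope": res.slope, "intercept": res.intercept,
                    "r2": res.rvalue ** 2, "p": res.pvalue, "n": len(x),
                    "stars": _stars(res.pvalue),
                })
    return pd.DataFrame(rows)


def regression_heatmap_frame(result: pd.DataFrame, model: str) -> pd.DataFrame:
    """R-squared matrix (treatment x metric) for one model, heat-map ready."""
    sub = result[result["model"] == model]
    return sub.pivot(index="treatment", columns="metric", values="r2")


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------

@dataclass
class ConstrainedOrdination:
    site_scores: pd.DataFrame
    biplot_arrows: pd.DataFrame
    constrained_fraction: float
    eigenvalues: np.ndarray
    permutation_p: float | None = None
    pseudo_f: float | None = None


def dbrda(d: DistanceMatrix, constraints: pd.DataFrame, n_perm: int = 999,
          seed: int = 0) -> ConstrainedOrdination:
    """Distance-based redundancy analysis.

    The Gower-centered matrix is eigen-decomposed to principal coordinates
    (negative-eigenvalue axes dropped); coordinates are regressed on the
    centered constraints; constrained axes come from the eigen-structure of
    the fitted values. Overall significance is a permutation pseudo-F on
    constrained vs residual inertia, permuting constraint rows."""
    ids = list(d.ids)
    Xc = constraints.loc[ids].to_numpy(dtype=float)
    n = len(ids)
    if Xc.shape[1] > n - 1:
        raise ValueError("need at most samples - 1 constraint columns")
    G = _gower_center(np.asarray(d.data, dtype=float))
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-10
    evals, evecs = evals[pos], evecs[:, pos]
    coords = evecs * np.sqrt(evals)          # principal coordinates
    total_inertia = float(evals.sum())

    Xm = Xc - Xc.mean(axis=0)
    u, s, _ = np.linalg.svd(Xm, full_matrices=False)
    rank = int((s > 1e-10 * max(s.max(), 1.0)).sum()) if s.size else 0
    if rank < Xm.shape[1]:
        warnings.warn("collinear constraints reduced to a full-rank basis")
    U = u[:, :rank]

    fitted = U @ (U.T @ coords)
    # constrained axes: eigen-structure of the fitted coordinates
    uf, sf, vtf = np.linalg.svd(fitted, full_matrices=False)
    ax_evals = sf ** 2
    keep = ax_evals > max(ax_evals.max(), 1e-300) * 1e-12 if ax_evals.size else []
    uf, sf, vtf = uf[:, keep], sf[keep], vtf[keep]
    site = uf * sf
    ss_constr = float((fitted ** 2).sum())
    frac = ss_constr / total_inertia if total_inertia > 0 else 0.0

    # biplot arrows: correlations of constraints with constrained axes
    arrows = np.zeros((Xc.shape[1], site.shape[1]))
    for j in range(Xc.shape[1]):
        xj = Xm[:, j]
        for a in range(site.shape[1]):
            sa = site[:, a]
            denom = xj.std() * sa.std()
            arrows[j, a] = np.corrcoef(xj, sa)[0, 1] if denom > 0 else 0.0

    ss_res = total_inertia - ss_constr
    df_res = n - rank - 1
    f_obs = np.inf
    if df_res > 0 and ss_res > 1e-12 * total_inertia:
        f_obs = (ss_constr / max(rank, 1)) / (ss_res / df_res)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Up = U[perm]
        fit_p = Up @ (Up.T @ coords)
        ss_c = float((fit_p ** 2).sum())
        ss_r = total_inertia - ss_c
        f_p = np.inf if ss_r <= 1e-12 * total_inertia else (
            (ss_c / max(rank, 1)) / (ss_r / df_res) if df_res > 0 else np.inf
        )
        exceed += f_p >= f_obs
    p = (exceed + 1) / (n_perm + 1)

    axes = [f"dbRDA{i + 1}" for i in range(site.shape[1])]
    return ConstrainedOrdination(
        site_scores=pd.DataFrame(site, index=ids, columns=axes),
        biplot_arrows=pd.DataFrame(arrows, index=constraints.columns, columns=axes),
        constrained_fraction=frac,
        eigenvalues=ax_evals[keep] if len(axes) else np.array([]),
        permutation_p=float(p), pseudo_f=float(f_obs),
    )


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------

def envfit(scores: pd.DataFrame, variables: pd.DataFrame, n_perm: int = 999,
           seed: int = 0, alpha: float = 0.1) -> pd.DataFrame:
    """Fit each variable onto the first two ordination axes.

    Per variable: r2 of the multiple regression of the centered variable on
    the centered axis scores; direction = unit coefficient vector;
    permutation p permutes the variable's rows; BH adjustment across
    variables; significance flag at BH p < ``alpha``."""
    ids = scores.index
    S = scores.to_numpy(dtype=float)[:, :2]
    S = S - S.mean(axis=0)
    V = variables.loc[ids].to_numpy(dtype=float)
    n, k = S.shape
    pinv = np.linalg.pinv(S)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    rows = []
    for j, name in enumerate(variables.columns):
        v = V[:, j] - V[:, j].mean()
        tss = float(v @ v)
        if tss <= 0:
            rows.append({"variable": name, "r2": 0.0, "dir1": 0.0, "dir2": 0.0,
                         "p": 1.0})
            continue
        b = pinv @ v
        fit = S @ b
        r2 = float(fit @ fit) / tss
        vp = v[perms.T]                     # n x n_perm permuted copies
        fitp = S @ (pinv @ vp)
        r2p = (fitp ** 2).sum(axis=0) / tss
        p = (int((r2p >= r2).sum()) + 1) / (n_perm + 1)
        norm = np.linalg.norm(b)
        direction = b / norm if norm > 0 else np.zeros(k)
        rows.append({"variable": name, "r2": r2, "dir1": direction[0],
                     "dir2": direction[1], "p": p})
    out = pd.DataFrame(rows).set_index("variable")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out


# ---------------------------------------------------------------------------
# Spearman OPU-taxon map
# ---------------------------------------------------------------------------

def spearman_opu_taxa(taxa_profiles: pd.DataFrame, opu_table: OPUTable | pd.DataFrame,
                      alpha_star: float = 0.1, alpha_double: float = 0.05,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman rho between every (taxon, OPU) pair with BH control over the
    full family.

    Returns (rho, BH-adjusted p, star flags); stars follow the heat-map
    legend convention '*' for BH p < 0.1 and '**' for BH p < 0.05. Constant
    columns give missing (NaN) entries excluded from the BH family."""
    opus = opu_table.shares if isinstance(opu_table, OPUTable) else opu_table
    common = taxa_profiles.index.intersection(opus.index)
    if len(common) < 4:
        raise ValueError("need at least 4 paired samples")
    Xt = taxa_profiles.loc[common]
    Xo = opus.loc[common]
    rho = pd.DataFrame(np.nan, index=Xt.columns, columns=Xo.columns)
    praw = pd.DataFrame(np.nan, index=Xt.columns, columns=Xo.columns)
    for t in Xt.columns:
        xt = Xt[t].to_numpy(dtype=float)
        if np.ptp(xt) == 0:
            continue
        for o in Xo.columns:
            xo = Xo[o].to_numpy(dtype=float)
            if np.ptp(xo) == 0:
                continue
            r, p = stats.spearmanr(xt, xo)
            rho.loc[t, o] = r
            praw.loc[t, o] = p
    flat = praw.to_numpy().ravel()
    mask = ~np.isnan(flat)
    qflat = np.full_like(flat, np.nan)
    if mask.any():
        qflat[mask] = multipletests(flat[mask], method="fdr_bh")[1]
    q = pd.DataFrame(qflat.reshape(praw.shape), index=praw.index,
                     columns=praw.columns)
    stars = q.map(
        lambda v: "" if pd.isna(v) else ("**" if v < alpha_double
                                         else "*" if v < alpha_star else "")
    )
    return rho, q, stars
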