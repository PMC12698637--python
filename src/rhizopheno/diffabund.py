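"""Compositional differential abundance in the ALDEx style.

Counts are converted to Monte-Carlo Dirichlet instances of CLR values; each
instance is tested per taxon with a sequential (Type I) linear model
``CLR ~ production + plant + production:plant``; per-term p-values are
BH-adjusted across taxa within each instance and then averaged over
instances (expected BH p). A taxon is called for a term when its expected
BH p falls below the significance level (0.05 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AsvTable
from .community import _hat, _term_columns

DEFAULT_TERMS = ["production", "plant", "production:plant"]


def dirichlet_clr_instances(table: AsvTable, n_mc: int = 128, seed: int = 0,
                            prior: float = 0.5) -> np.ndarray:
    """Monte-Carlo CLR instances: per sample and instance draw proportions
    from Dirichlet(counts + prior) and CLR-transform them.

    Returns an array of shape (n_mc, n_samples, n_taxa). Uses non-rarefied
    counts by design.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    counts = table.counts.to_numpy(dtype=float) + prior
    rng = np.random.default_rng(seed)
    # gamma draws normalize to Dirichlet; CLR ignores the normalization
    g = rng.standard_gamma(counts[None, :, :].repeat(n_mc, axis=0))
    g = np.maximum(g, 1e-300)
    logg = np.log(g)
    clr = logg - logg.mean(axis=2, keepdims=True)
    return clr


@dataclass
class DaResult:
    """Per-taxon expected effects and expected BH-adjusted p per model term."""

    table: pd.DataFrame
    terms: list[str]
    n_mc: int
    alpha: float = 0.05

    def significant(self, term: str) -> list[str]:
        return list(self.table.index[self.table[f"q_{term}"] < self.alpha])


def aldex_glm_test(instances: np.ndarray, metadata: pd.DataFrame,
                   taxon_ids: list[str], terms: list[str] | None = None,
                   alpha: float = 0.05) -> DaResult:
    """Sequential F-tests per term on every Dirichlet instance.

    Effects are reported as the expected partial eta-squared of each term
    (plus the expected CLR difference between production levels when a
    'production' term is present).
    """
    terms = list(DEFAULT_TERMS if terms is None else terms)
    n_mc, n, D = instances.shape
    if len(metadata) != n:
        raise ValueError("metadata rows must match instance samples")

    # drop unestimable interaction terms (empty design cells)
    usable = []
    for t in terms:
        if ":" in t:
            parts = t.split(":")
            cells = metadata.groupby(parts, observed=True).size()
            full = np.prod([metadata[p].nunique() for p in parts])
            if len(cells) < full:
                warnings.warn(f"interaction {t!r} unestimable (empty cell); dropped")
                continue
        usable.append(t)
    terms = usable

    X = np.ones((n, 1))
    H_prev, rank_prev = _hat(X)
    projs, dfs = [], []
    for t in terms:
        X = np.hstack([X, _term_columns(metadata, t)])
        H, rank = _hat(X)
        projs.append(H - H_prev)
        dfs.append(max(rank - rank_prev, 0))
        H_prev, rank_prev = H, rank
    R = np.eye(n) - H_prev
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    p_sum = {t: np.zeros(D) for t in terms}
    q_sum = {t: np.zeros(D) for t in terms}
    eta_sum = {t: np.zeros(D) for t in terms}
    delta_sum = np.zeros(D)
    prod_mask = None
    if "production" in metadata.columns:
        lv = sorted(metadata["production"].unique())
        if len(lv) == 2:
            prod_mask = (metadata["production"] == lv[1]).to_numpy()

    for m in range(n_mc):
        Y = instances[m]                       # n x D
        ss_res = (Y * (R @ Y)).sum(axis=0)
        for t, P, df in zip(terms, projs, dfs):
            ss_t = (Y * (P @ Y)).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (ss_t / max(df, 1)) / (ss_res / df_res)
            p = stats.f.sf(f, max(df, 1), df_res)
            p = np.nan_to_num(p, nan=1.0)
            q = multipletests(p, method="fdr_bh")[1]
            p_sum[t] += p
            q_sum[t] += q
            eta_sum[t] += np.where(ss_t + ss_res > 0, ss_t / (ss_t + ss_res), 0.0)
        if prod_mask is not None:
            delta_sum += Y[prod_mask].mean(axis=0) - Y[~prod_mask].mean(axis=0)

    out = pd.DataFrame(index=pd.Index(taxon_ids, name="taxon"))
    for t in terms:
        out[f"effect_{t}"] = eta_sum[t] / n_mc
        out[f"p_{t}"] = p_sum[t] / n_mc
        out[f"q_{t}"] = q_sum[t] / n_mc
        out[f"sig_{t}"] = out[f"q_{t}"] < alpha
    if prod_mask is not None:
        out["delta_clr_production"] = delta_sum / n_mc
    return DaResult(table=out, terms=terms, n_mc=n_mc, alpha=alpha)


def aldex_welch_test(instances: np.ndarray, labels: pd.Series,
                     taxon_ids: list[str], alpha: float = 0.05) -> DaResult:
    """Welch-style two-group shortcut for a 2-level single factor."""
    lv = sorted(labels.unique())
    if len(lv) != 2:
        raise ValueError("Welch shortcut needs exactly 2 groups")
    a = (labels == lv[0]).to_numpy()
    b = (labels == lv[1]).to_numpy()
    n_mc, _, D = instances.shape
    p_sum = np.zeros(D)
    q_sum = np.zeros(D)
    d_sum = np.zeros(D)
    for m in range(n_mc):
        Y = instances[m]
        t, p = stats.ttest_ind(Y[a], Y[b], equal_var=False)
        p = np.nan_to_num(p, nan=1.0)
        q = multipletests(p, method="fdr_bh")[1]
        p_sum += p
        q_sum += q
        d_sum += Y[b].mean(axis=0) - Y[a].mean(axis=0)
    out = pd.DataFrame(index=pd.Index(taxon_ids, name="taxon"))
    out["effect_group"] = d_sum / n_mc
    out["p_group"] = p_sum / n_mc
    out["q_group"] = q_sum / n_mc
    out["sig_group"] = out["q_group"] < alpha
    return DaResult(table=out, terms=["group"], n_mc=n_mc, alpha=alpha)


def aggregate_by_rank(table: AsvTable, rank: str = "phylum") -> AsvTable:
    """Sum counts within a taxonomic rank (e.g. phylum-level testing)."""
    groups = table.taxonomy[rank]
    agg = table.counts.T.groupby(groups.loc[table.counts.columns]).sum().T
    tax = pd.DataFrame(index=agg.columns)
    tax[rank] = agg.columns
    for r in table.taxonomy.columns:
        if r not in tax.columns:
            tax[r] = ""
    return AsvTable(counts=agg, taxonomy=tax[table.taxonomy.columns],
                    metadata=table.metadata)
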