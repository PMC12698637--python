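"""Core in-memory containers shared across the pipeline stages.

All tabular data are held as pandas objects keyed by sample / cell / taxon
identifiers; the containers only add light invariant checking and convenient
derived views (relative abundances, aligned metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]


@dataclass
class AsvTable:
    """Sample x taxon integer count matrix with taxonomy and sample metadata.

    counts   : DataFrame, index = sample ids, columns = taxon ids, ints >= 0
    taxonomy : DataFrame, index = taxon ids, columns = the seven ranks
    metadata : DataFrame, index = sample ids, columns include
               'production', 'plant', 'latitude', 'longitude'
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts are not allowed")
        missing_meta = set(self.counts.index) - set(self.metadata.index)
        if missing_meta:
            raise ValueError(f"metadata missing for samples: {sorted(missing_meta)[:5]}")
        missing_tax = set(self.counts.columns) - set(self.taxonomy.index)
        if missing_tax:
            raise ValueError(f"taxonomy missing for taxa: {sorted(missing_tax)[:5]}")
        self.metadata = self.metadata.loc[self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized proportions (rows with zero total stay zero)."""
        totals = self.counts.sum(axis=1).replace(0, np.nan)
        rel = self.counts.div(totals, axis=0).fillna(0.0)
        return rel

    def subset_samples(self, sample_ids) -> "AsvTable":
        return AsvTable(
            counts=self.counts.loc[list(sample_ids)].copy(),
            taxonomy=self.taxonomy,
            metadata=self.metadata.loc[list(sample_ids)].copy(),
        )

    def subset_taxa(self, taxon_ids) -> "AsvTable":
        return AsvTable(
            counts=self.counts[list(taxon_ids)].copy(),
            taxonomy=self.taxonomy.loc[list(taxon_ids)].copy(),
            metadata=self.metadata,
        )


@dataclass
class SpectrumSet:
    """Per-cell Raman spectra on a shared, strictly increasing wavenumber grid.

    intensities : DataFrame, index = cell ids, columns = wavenumbers (float)
    cells       : DataFrame, index = cell ids, columns include 'sample_id'
    """

    intensities: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        wn = self.wavenumbers
        if len(wn) > 1 and not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.isfinite(self.intensities.values).all():
            raise ValueError("intensities must be finite")
        missing = set(self.intensities.index) - set(self.cells.index)
        if missing:
            raise ValueError(f"cell metadata missing for: {sorted(missing)[:5]}")
        self.cells = self.cells.loc[self.intensities.index]

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.asarray(self.intensities.columns, dtype=float)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def subset(self, cell_ids) -> "SpectrumSet":
        ids = list(cell_ids)
        return SpectrumSet(self.intensities.loc[ids].copy(), self.cells.loc[ids].copy())


@dataclass
class OPUAssignment:
    """Flat OPU labels for clustered cells.

    labels : Series, index = cell ids, values 'OPU-k' or 'unclassified'
    """

    labels: pd.Series
    cutoff: float
    linkage_tree: np.ndarray | None = None

    @property
    def opu_ids(self) -> list[str]:
        return sorted(
            (l for l in self.labels.unique() if l != "unclassified"),
            key=lambda s: int(s.split("-")[1]),
        )


@dataclass
class OPUTable:
    """Per-sample relative abundances of OPUs plus the unclassified pool.

    shares : DataFrame, index = sample ids, columns = OPU labels plus
             'unclassified'; each row sums to 1.
    """

    shares: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.shares.sum(axis=1).values
        if len(sums) and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("OPU share rows must sum to 1")
        if (self.shares.values < -1e-12).any():
            raise ValueError("OPU shares must be non-negative")

    @property
    def unclassified_fraction(self) -> pd.Series:
        if "unclassified" in self.shares.columns:
            return self.shares["unclassified"]
        return pd.Series(0.0, index=self.shares.index)

    def classified_shares(self, renormalize: bool = True) -> pd.DataFrame:
        """OPU shares with the unclassified pool dropped from the denominator."""
        cols = [c for c in self.shares.columns if c != "unclassified"]
        sub = self.shares[cols]
        if not renormalize:
            return sub.copy()
        totals = sub.sum(axis=1).replace(0, np.nan)
        return sub.div(totals, axis=0).fillna(0.0)

    def lumped_view(self, minor_thresh: float = 0.005) -> pd.DataFrame:
        """Reporting view: OPUs below ``minor_thresh`` overall mean share are
        lumped into 'Other minor OPUs (<0.5%)'; 'unclassified' is kept as is."""
        overall = self.shares.mean(axis=0)
        minor = [
            c for c in self.shares.columns
            if c != "unclassified" and overall[c] < minor_thresh
        ]
        keep = [c for c in self.shares.columns if c not in minor]
        out = self.shares[keep].copy()
        if minor:
            out["Other minor OPUs (<0.5%)"] = self.shares[minor].sum(axis=1)
        return out


@dataclass
class GroundTruth:
    """Planted structure emitted by the simulator for recovery testing."""

    true_opu_label: pd.Series | None = None          # cell id -> template id / junk / outlier
    true_basis_corr: dict[tuple[str, str], float] = field(default_factory=dict)
    true_da_taxa: dict[str, tuple[str, float]] = field(default_factory=dict)
    true_hubs: set[str] = field(default_factory=set)
    true_couplings: list[tuple[str, str, int]] = field(default_factory=list)
    latent_log_basis: pd.DataFrame | None = None     # sample x taxon latent draws

    def to_jsonable(self) -> dict[str, Any]:
        return {
            "true_opu_label": (
                None if self.true_opu_label is None else self.true_opu_label.to_dict()
            ),
            "true_basis_corr": {f"{a}|{b}": r for (a, b), r in self.true_basis_corr.items()},
            "true_da_taxa": {t: list(v) for t, v in self.true_da_taxa.items()},
            "true_hubs": sorted(self.true_hubs),
            "true_couplings": [list(c) for c in self.true_couplings],
        }
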