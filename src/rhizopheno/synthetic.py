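"""Joint synthetic scenes: ASV counts, single-cell Raman spectra, metadata,
and the planted ground truth the recovery tests check against.

The abundance model is the compositional model SparCC assumes: latent
log-normal basis abundances with a planted correlation structure, closed to
proportions and multinomially sampled at log-normally distributed sequencing
depths. Spectra are Gaussian band mixtures over phenotype templates; every
valid template carries the phenylalanine (1003 cm^-1) and amide I
(1657 cm^-1) signature bands, junk spectra lack them, and outlier spectra
carry unique random band sets so they end up as singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import RANKS, AsvTable, GroundTruth, SpectrumSet

# Default wavenumber grid: 600-1800 cm^-1 at 1 cm^-1 steps, covering the
# phenylalanine/amide I signature bands and all diagnostic bands used below.
DEFAULT_GRID = np.arange(600.0, 1801.0, 1.0)

SIGNATURE_BANDS = (1003.0, 1657.0)

# Diagnostic band pool for templates (lipid CH2, protein amino-acid/peptide,
# carbon-related, nucleic-acid and carbohydrate regions).
DIAGNOSTIC_BAND_POOL = (
    687.0, 725.0, 780.0, 850.0, 900.0, 1090.0, 1130.0, 1250.0, 1320.0,
    1358.0, 1450.0, 1520.0, 1574.0, 1605.0, 1735.0,
)

PHYLA = (
    "Acidobacteriota", "Actinobacteriota", "Bacteroidota", "Chloroflexota",
    "Gemmatimonadota", "Proteobacteria", "Verrucomicrobiota", "Firmicutes",
    "Myxococcota", "Planctomycetota",
)


@dataclass
class SceneDesign:
    """Parameters of a synthetic genotype-phenotype scene.

    The defaults mirror the study design the pipeline targets: two
    production systems (conventional/organic), five replicate plants per
    species, at least 100 spectra per sample, and sequencing depths around
    1.5e4 reads with a lognormal spread and a floor of 1,000.
    """

    n_production: int = 2
    plant_species: Sequence[str] = ("carrot", "lettuce", "potato", "tomato")
    replicates_per_plant: int = 5
    n_taxa: int = 120
    depth_log_mean: float = float(np.log(15000.0))
    depth_log_sd: float = 0.3
    n_da_taxa: int = 6
    da_log2_effects: Sequence[float] = ()
    da_terms: Sequence[str] = ()
    basis_correlation_blocks: Sequence[tuple[Sequence[int], float]] = ()
    planted_hubs: Sequence[int] = ()
    hub_partner_count: int = 12
    hub_rho: float = 0.4
    n_opu_templates: int = 6
    spectra_per_sample: int = 100
    junk_fraction: float = 0.1
    outlier_fraction: float = 0.05
    noise_sd: float = 0.01
    baseline_order: int = 2
    coupling_strength: float = 1.5
    couplings: Sequence[tuple[int, int, int]] = (
        (0, 5, 1), (0, 8, 1), (1, 12, -1), (1, 20, -1),
    )  # (template idx, taxon idx, sign)
    abundance_log_sd: float = 1.0
    taxon_mean_log_sd: float = 1.5
    depth_floor: int = 1000
    wavenumbers: np.ndarray = dc_field(default_factory=lambda: DEFAULT_GRID.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("junk_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.junk_fraction + self.outlier_fraction > 1.0:
            raise ValueError("junk_fraction + outlier_fraction must not exceed 1")
        if self.replicates_per_plant < 2:
            raise ValueError("replicates_per_plant must be >= 2")
        if self.spectra_per_sample < 10:
            raise ValueError("spectra_per_sample must be >= 10")
        planted = [i for idx, _ in self.basis_correlation_blocks for i in idx]
        planted += list(self.planted_hubs)
        planted += [t for _, t, _ in self.couplings]
        if planted and max(planted) >= self.n_taxa:
            raise ValueError("planted taxon index out of range")
        for tmpl, _, _ in self.couplings:
            if tmpl >= self.n_opu_templates:
                raise ValueError(f"coupled OPU template index {tmpl} out of range")
        wn = np.asarray(self.wavenumbers, dtype=float)
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        self.wavenumbers = wn
        if self.n_da_taxa and not self.da_log2_effects:
            self.da_log2_effects = tuple([2.0] * self.n_da_taxa)
        if self.n_da_taxa and not self.da_terms:
            self.da_terms = tuple(["production"] * self.n_da_taxa)
        if len(self.da_log2_effects) != self.n_da_taxa or len(self.da_terms) != self.n_da_taxa:
            raise ValueError("da_log2_effects/da_terms must have length n_da_taxa")

    @property
    def n_samples(self) -> int:
        return self.n_production * len(self.plant_species) * self.replicates_per_plant

    @property
    def production_levels(self) -> list[str]:
        return ["conventional", "organic"][: self.n_production]


def _taxon_id(i: int) -> str:
    return f"ASV{i:04d}"


def _coupling_factors(design: SceneDesign) -> dict[int, int]:
    """One shared latent factor per distinct coupled OPU template, so taxa
    coupled to the same phenotype co-vary while distinct phenotype couplings
    stay independent."""
    factor_of: dict[int, int] = {}
    for tmpl_idx, _, _ in design.couplings:
        factor_of.setdefault(tmpl_idx, len(factor_of))
    return factor_of


def _sample_frame(design: SceneDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Sample metadata: one farm site (lat/lon) per production x plant cell."""
    rows = []
    for prod in design.production_levels:
        for plant in design.plant_species:
            lat = 42.0 + rng.uniform(0, 0.2)
            lon = -76.0 + rng.uniform(0, 0.2)
            for rep in range(design.replicates_per_plant):
                # replicate plants sit at spatially distributed field spots
                rows.append(
                    {
                        "sample_id": f"{prod[:3]}_{plant}_r{rep + 1}",
                        "production": prod,
                        "plant": plant,
                        "latitude": round(lat + rng.normal(0, 0.002), 5),
                        "longitude": round(lon + rng.normal(0, 0.002), 5),
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _build_correlation_matrix(design: SceneDesign) -> tuple[np.ndarray, dict]:
    """Embed the requested equicorrelated blocks and hub star structures into
    a taxon correlation matrix; reject non-positive-definite requests."""
    D = design.n_taxa
    C = np.eye(D)
    truth: dict[tuple[str, str], float] = {}
    for idx, rho in design.basis_correlation_blocks:
        idx = list(idx)
        for a in idx:
            for b in idx:
                if a != b:
                    C[a, b] = rho
        for i, a in enumerate(idx):
            for b in idx[i + 1:]:
                truth[(_taxon_id(min(a, b)), _taxon_id(max(a, b)))] = rho
    # Each hub bridges three otherwise-uncorrelated partner groups: members
    # within a group share a factor (corr 0.6), the hub loads on all three
    # group factors (hub-member corr = hub_rho, requires hub_rho <= sqrt(0.2)),
    # and cross-group member correlations stay zero. The implied matrix is a
    # factor model, hence positive definite.
    within = 0.6
    if design.planted_hubs and design.hub_rho > np.sqrt(within / 3) + 1e-9:
        raise ValueError(
            f"hub_rho must be <= sqrt({within}/3) ~ {np.sqrt(within / 3):.3f} "
            "for the bridging-hub factor construction"
        )
    used = set(i for idx, _ in design.basis_correlation_blocks for i in idx)
    used |= set(design.planted_hubs)
    free = [i for i in range(D) if i not in used]
    pos = 0
    for h in design.planted_hubs:
        partners = free[pos: pos + design.hub_partner_count]
        pos += design.hub_partner_count
        groups = [partners[g::3] for g in range(3)]
        for grp in groups:
            for i, p in enumerate(grp):
                for q in grp[i + 1:]:
                    C[p, q] = C[q, p] = within
        for p in partners:
            C[h, p] = C[p, h] = design.hub_rho
            truth[(_taxon_id(min(h, p)), _taxon_id(max(h, p)))] = design.hub_rho
    try:
        np.linalg.cholesky(C + 1e-10 * np.eye(D))
    except np.linalg.LinAlgError:
        for idx, rho in design.basis_correlation_blocks:
            sub = C[np.ix_(list(idx), list(idx))]
            if np.linalg.eigvalsh(sub).min() <= 0:
                raise ValueError(
                    f"correlation block {tuple(idx)} with rho={rho} is not "
                    "positive definite"
                ) from None
        raise ValueError("requested correlation structure is not positive definite") from None
    return C, truth


def _taxonomy_frame(design: SceneDesign, rng: np.random.Generator) -> pd.DataFrame:
    taxa = [_taxon_id(i) for i in range(design.n_taxa)]
    phyla = rng.choice(PHYLA, size=design.n_taxa)
    rows = []
    for t, ph in zip(taxa, phyla):
        rows.append(
            {
                "taxon_id": t,
                "domain": "Bacteria",
                "phylum": ph,
                "class": f"{ph}_c1",
                "order": f"{ph}_o1",
                "family": f"{ph}_f{int(t[3:]) % 5 + 1}",
                "genus": f"g_{t}",
                "species": f"s_{t}",
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")[RANKS]


def _design_effects(design: SceneDesign, metadata: pd.DataFrame,
                    rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Per-sample log-abundance offsets implementing the planted differential
    taxa under production, plant, or production:plant interaction terms."""
    n = len(metadata)
    offsets = np.zeros((n, design.n_taxa))
    truth: dict[str, tuple[str, float]] = {}
    if design.n_da_taxa == 0:
        return offsets, truth
    da_idx = rng.choice(design.n_taxa, size=design.n_da_taxa, replace=False)
    prod = metadata["production"].values
    plant = metadata["plant"].values
    plants = list(design.plant_species)
    for j, (idx, l2, term) in enumerate(
        zip(da_idx, design.da_log2_effects, design.da_terms)
    ):
        eff = float(l2) * np.log(2.0)
        if term == "production":
            sign = np.where(prod == design.production_levels[-1], 0.5, -0.5)
        elif term == "plant":
            target = plants[j % len(plants)]
            sign = np.where(plant == target, 0.5, -0.5)
        elif term == "interaction":
            target = plants[j % len(plants)]
            sign = np.where(
                (plant == target) & (prod == design.production_levels[-1]), 1.0, 0.0
            )
            sign = sign - sign.mean()
        else:
            raise ValueError(f"unknown DA term {term!r}")
        offsets[:, idx] += eff * sign
        truth[_taxon_id(int(idx))] = (str(term), float(l2))
    return offsets, truth


def _latent_factor(design: SceneDesign, rng: np.random.Generator,
                   metadata: pd.DataFrame) -> np.ndarray:
    """Shared per-sample latent factor behind OPU-taxon couplings."""
    return rng.normal(size=len(metadata))


def generate_asv_counts(
    design: SceneDesign, seed: int | None = None,
    _latent_u: np.ndarray | None = None,
) -> tuple[AsvTable, GroundTruth]:
    """Simulate an ASV count table with planted basis correlations, planted
    differential taxa, and lognormal sequencing depths.

    Counts are drawn multinomially per sample, so each row sums exactly to
    its drawn depth.
    """
    seed = design.seed if seed is None else seed
    ss = np.random.SeedSequence([int(seed), 101])
    rng = np.random.default_rng(ss)
    metadata = _sample_frame(design, rng)
    taxonomy = _taxonomy_frame(design, rng)
    C, corr_truth = _build_correlation_matrix(design)
    n, D = len(metadata), design.n_taxa

    mu = rng.normal(0.0, design.taxon_mean_log_sd, size=D)
    # planted taxa (coupled, correlated blocks, hubs) sit at moderate
    # abundance so the planted structure is identifiable over multinomial
    # counting noise; applied independently of effect/coupling strength so
    # null scenes stay comparable
    for _, taxon_idx, _ in design.couplings:
        mu[taxon_idx] = max(mu[taxon_idx], 1.0)
    for idx, _ in design.basis_correlation_blocks:
        for i in idx:
            mu[i] = max(mu[i], 0.0)
    for h in design.planted_hubs:
        mu[h] = max(mu[h], 0.0)
    sig = np.full(D, design.abundance_log_sd)
    cov = (sig[:, None] * sig[None, :]) * C
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(D))
    z = mu[None, :] + rng.standard_normal((n, D)) @ L.T

    offsets, da_truth = _design_effects(design, metadata, rng)
    z = z + offsets

    if _latent_u is not None and design.coupling_strength > 0:
        factor_of = _coupling_factors(design)
        for tmpl_idx, taxon_idx, sign in design.couplings:
            z[:, taxon_idx] += (design.coupling_strength * sign
                                * _latent_u[:, factor_of[tmpl_idx]])

    props = np.exp(z - z.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)

    depths = np.maximum(
        np.round(rng.lognormal(design.depth_log_mean, design.depth_log_sd, size=n)),
        design.depth_floor,
    ).astype(np.int64)
    counts = np.vstack(
        [rng.multinomial(depths[i], props[i]) for i in range(n)]
    )

    taxa = [_taxon_id(i) for i in range(D)]
    table = AsvTable(
        counts=pd.DataFrame(counts, index=metadata.index, columns=taxa),
        taxonomy=taxonomy,
        metadata=metadata,
    )
    truth = GroundTruth(
        true_basis_corr=corr_truth,
        true_da_taxa=da_truth,
        true_hubs={_taxon_id(h) for h in design.planted_hubs},
        latent_log_basis=pd.DataFrame(z, index=metadata.index, columns=taxa),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Raman spectra
# ---------------------------------------------------------------------------

def _gaussian_bands(grid: np.ndarray, centers: np.ndarray, amps: np.ndarray,
                    widths: np.ndarray) -> np.ndarray:
    diff = grid[None, :] - centers[:, None]
    return (amps[:, None] * np.exp(-0.5 * (diff / widths[:, None]) ** 2)).sum(axis=0)


def _make_templates(design: SceneDesign, rng: np.random.Generator) -> list[dict]:
    """Phenotype templates: shared signature bands plus distinct diagnostic
    bands so templates are separable but realistic mixtures."""
    pool = list(DIAGNOSTIC_BAND_POOL)
    rng.shuffle(pool)
    templates = []
    per = max(2, len(pool) // max(design.n_opu_templates, 1))
    for k in range(design.n_opu_templates):
        diag = pool[(k * per) % len(pool): (k * per) % len(pool) + per]
        if len(diag) < 2:
            diag = (pool * 2)[k * per: k * per + 2]
        centers = np.array(list(SIGNATURE_BANDS) + list(diag))
        amps = np.concatenate(
            [rng.uniform(0.8, 1.2, size=2), rng.uniform(0.5, 1.5, size=len(diag))]
        )
        widths = rng.uniform(6.0, 10.0, size=len(centers))
        templates.append({"centers": centers, "amps": amps, "widths": widths})
    return templates


def _render_cell(grid: np.ndarray, centers: np.ndarray, amps: np.ndarray,
                 widths: np.ndarray, design: SceneDesign,
                 rng: np.random.Generator) -> np.ndarray:
    spec = _gaussian_bands(grid, centers, amps, widths)
    scale = (grid - grid.mean()) / (grid.max() - grid.min())
    coef = rng.normal(0.0, 0.05, size=design.baseline_order + 1)
    baseline = np.polyval(coef, scale)
    jitter = float(np.exp(rng.normal(0.0, 0.1)))
    noise = rng.normal(0.0, design.noise_sd, size=grid.size)
    return jitter * spec + baseline + noise


def generate_spectra(
    design: SceneDesign, seed: int | None = None,
    _latent_u: np.ndarray | None = None,
    metadata: pd.DataFrame | None = None,
) -> tuple[SpectrumSet, GroundTruth]:
    """Simulate per-cell Raman spectra as template band mixtures.

    Each sample draws its cells from a sample-specific mixture over the
    phenotype templates; a ``junk_fraction`` of cells lack the 1003/1657
    signature bands and an ``outlier_fraction`` carry unique random band
    sets (future singletons)."""
    seed = design.seed if seed is None else seed
    ss = np.random.SeedSequence([int(seed), 202])
    rng = np.random.default_rng(ss)
    if metadata is None:
        metadata = _sample_frame(design, np.random.default_rng(
            np.random.SeedSequence([int(seed), 101])))
    grid = design.wavenumbers
    templates = _make_templates(design, rng)
    K = design.n_opu_templates

    # Sample-level template mixtures: shared base weights (geometric decay so
    # a couple of OPUs dominate, as observed in real communities) perturbed
    # per sample on the logit scale.
    base_logits = -0.5 * np.arange(K, dtype=float)
    records, rows, labels = [], [], {}
    for si, sample_id in enumerate(metadata.index):
        logits = base_logits + rng.normal(0.0, 0.4, size=K)
        if _latent_u is not None and design.coupling_strength > 0:
            factor_of = _coupling_factors(design)
            for tmpl_idx in factor_of:
                logits[tmpl_idx] += (design.coupling_strength
                                     * _latent_u[si, factor_of[tmpl_idx]])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        for ci in range(design.spectra_per_sample):
            cell_id = f"{sample_id}_c{ci:03d}"
            u = rng.uniform()
            if u < design.junk_fraction:
                # junk: bands anywhere except the signature windows
                k_bands = rng.integers(1, 4)
                centers = rng.uniform(620.0, 1780.0, size=k_bands)
                for b in SIGNATURE_BANDS:
                    centers = np.where(np.abs(centers - b) < 25.0,
                                       centers + 50.0, centers)
                amps = rng.uniform(0.3, 1.0, size=k_bands)
                widths = rng.uniform(6.0, 12.0, size=k_bands)
                label = "junk"
            elif u < design.junk_fraction + design.outlier_fraction:
                k_bands = rng.integers(3, 6)
                centers = np.concatenate(
                    [np.array(SIGNATURE_BANDS), rng.uniform(620.0, 1780.0, size=k_bands)]
                )
                amps = np.concatenate(
                    [rng.uniform(0.8, 1.2, size=2), rng.uniform(0.5, 1.5, size=k_bands)]
                )
                widths = rng.uniform(5.0, 12.0, size=len(centers))
                label = "outlier"
            else:
                k = int(rng.choice(K, p=w))
                t = templates[k]
                amps = t["amps"] * np.exp(rng.normal(0.0, 0.05, size=len(t["amps"])))
                centers, widths = t["centers"], t["widths"]
                label = f"template-{k}"
            rows.append(_render_cell(grid, np.asarray(centers, float),
                                     np.asarray(amps, float),
                                     np.asarray(widths, float), design, rng))
            records.append({"cell_id": cell_id, "sample_id": sample_id})
            labels[cell_id] = label

    cells = pd.DataFrame(records).set_index("cell_id")
    intensities = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, grid.size)),
                               index=cells.index, columns=grid)
    spectra = SpectrumSet(intensities=intensities, cells=cells)
    truth = GroundTruth(true_opu_label=pd.Series(labels, name="true_opu_label"))
    return spectra, truth


def plant_genopheno_coupling(
    design: SceneDesign, seed: int | None = None
) -> tuple[AsvTable, SpectrumSet, GroundTruth]:
    """Generate a joint scene in which a shared per-sample latent factor
    shifts both selected taxon log-abundances and selected OPU template
    mixture proportions, creating monotone OPU-taxon associations of the
    recorded sign. With ``coupling_strength == 0`` the two tables are
    independent."""
    if design.coupling_strength < 0:
        raise ValueError("coupling_strength must be >= 0")
    seed = design.seed if seed is None else seed
    rng_u = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    meta_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    metadata = _sample_frame(design, meta_rng)
    u = rng_u.normal(size=(len(metadata), max(len(_coupling_factors(design)), 1)))

    table, truth_a = generate_asv_counts(design, seed, _latent_u=u)
    spectra, truth_s = generate_spectra(design, seed, _latent_u=u,
                                        metadata=table.metadata)
    truth = GroundTruth(
        true_opu_label=truth_s.true_opu_label,
        true_basis_corr=truth_a.true_basis_corr,
        true_da_taxa=truth_a.true_da_taxa,
        true_hubs=truth_a.true_hubs,
        true_couplings=[
            (f"template-{tmpl}", _taxon_id(tax), int(sign))
            for tmpl, tax, sign in design.couplings
        ],
        latent_log_basis=truth_a.latent_log_basis,
    )
    return table, spectra, truth
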