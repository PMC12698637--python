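"""Raman phenotyping: QC gate, preprocessing contracts, OPU clustering,
AIC cutoff selection, OPU tables, Fisher scores, diversity."""

import numpy as np
import pandas as pd
import pytest

from rhizopheno import raman
from rhizopheno.containers import OPUAssignment, OPUTable, SpectrumSet
from rhizopheno.synthetic import SceneDesign, generate_spectra

GRID = np.arange(600.0, 1801.0, 1.0)


def gauss(center, amp=1.0, width=8.0, grid=GRID):
    return amp * np.exp(-0.5 * ((grid - center) / width) ** 2)


def make_set(rows, ids=None, grid=GRID, sample="s1"):
    ids = [f"c{i}" for i in range(len(rows))] if ids is None else ids
    data = np.vstack(rows) if len(rows) else np.empty((0, grid.size))
    intens = pd.DataFrame(data, index=ids, columns=grid)
    cells = pd.DataFrame({"sample_id": [sample] * len(ids)}, index=ids)
    return SpectrumSet(intensities=intens, cells=cells)


# ---------------------------------------------------------------------------
# QC gate
# ---------------------------------------------------------------------------

def test_qc_passes_signature_and_rejects_junk():
    rng = np.random.default_rng(0)
    noise = lambda: rng.normal(0, 0.005, GRID.size)
    good = gauss(1003) + gauss(1657) + noise()
    junk = gauss(800) + gauss(1200) + noise()
    one_peak = gauss(1003) + noise()
    s = make_set([good, junk, one_peak], ids=["good", "junk", "one"])
    passed, rejected = raman.qc_signature_filter(s)
    assert passed.cell_ids == ["good"]
    assert set(rejected) == {"junk", "one"}


def test_qc_empty_input_is_empty_output():
    s = make_set([], ids=[])
    passed, rejected = raman.qc_signature_filter(s)
    assert passed.n_spectra == 0 and rejected == []


def test_qc_grid_must_cover_windows():
    grid = np.arange(1100.0, 1500.0, 1.0)
    s = make_set([np.ones(grid.size)], grid=grid)
    with pytest.raises(ValueError, match="window"):
        raman.qc_signature_filter(s)


def test_qc_gate_recall_and_precision_across_seeds():
    """On simulated scenes the gate keeps >= 95% of valid spectra and
    rejects >= 95% of junk, across seeds."""
    recalls, retains = [], []
    for seed in range(10):
        design = SceneDesign(
            n_taxa=10, plant_species=("a",), replicates_per_plant=2,
            spectra_per_sample=40, n_opu_templates=3, junk_fraction=0.25,
            outlier_fraction=0.0, couplings=(),
        )
        spectra, truth = generate_spectra(design, seed=seed)
        passed, rejected = raman.qc_signature_filter(spectra)
        lab = truth.true_opu_label
        junk = set(lab[lab == "junk"].index)
        valid = set(lab[lab != "junk"].index)
        recalls.append(len(junk & set(rejected)) / len(junk))
        retains.append(len(valid & set(passed.cell_ids)) / len(valid))
    assert np.mean(recalls) >= 0.95
    assert np.mean(retains) >= 0.95


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_unit_norm_and_offset_invariance():
    rng = np.random.default_rng(1)
    y = gauss(1003) + gauss(1450, 0.7) + rng.normal(0, 0.01, GRID.size)
    out = raman.preprocess_spectrum(GRID, y, GRID)
    assert abs(np.linalg.norm(out) - 1.0) < 1e-9
    out_shift = raman.preprocess_spectrum(GRID, y + 5.0, GRID)
    assert np.allclose(out, out_shift, atol=1e-6)


def test_preprocess_recovers_band_center_under_linear_baseline():
    y = gauss(1250) + 0.001 * (GRID - 600.0)
    out = raman.preprocess_spectrum(GRID, y, GRID)
    assert abs(GRID[np.argmax(out)] - 1250.0) <= 1.0


def test_preprocess_degenerate_spectrum_flagged():
    assert raman.preprocess_spectrum(GRID, np.zeros(GRID.size), GRID) is None


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_identical_spectra_form_one_opu():
    y = gauss(1003) + gauss(1657)
    s = make_set([y, y.copy()])
    a = raman.cluster_opus(s, cutoff=0.44)
    assert list(a.labels) == ["OPU-0", "OPU-0"]


def test_uncorrelated_spectra_are_unclassified_at_default_cutoff():
    # disjoint narrow bands -> near-zero correlation -> d ~ 1 > 0.44
    s = make_set([gauss(700, width=4.0), gauss(1600, width=4.0)])
    a = raman.cluster_opus(s, cutoff=0.44)
    assert set(a.labels) == {"unclassified"}


def test_fewer_than_two_spectra_all_unclassified():
    s = make_set([gauss(1003)])
    a = raman.cluster_opus(s, cutoff=0.44)
    assert list(a.labels) == ["unclassified"]


def test_cluster_labels_invariant_to_input_order():
    design = SceneDesign(
        n_taxa=10, plant_species=("a",), replicates_per_plant=2,
        spectra_per_sample=25, n_opu_templates=3, junk_fraction=0.0,
        outlier_fraction=0.0, couplings=(),
    )
    spectra, _ = generate_spectra(design, seed=11)
    prep = raman.preprocess_set(spectra)
    a1 = raman.cluster_opus(prep, 0.44)
    order = list(prep.cell_ids)[::-1]
    a2 = raman.cluster_opus(prep.subset(order), 0.44)
    assert a1.labels.sort_index().equals(a2.labels.sort_index())


def test_cluster_count_monotone_in_cutoff():
    design = SceneDesign(
        n_taxa=10, plant_species=("a",), replicates_per_plant=2,
        spectra_per_sample=20, n_opu_templates=4, junk_fraction=0.1,
        outlier_fraction=0.05, couplings=(),
    )
    spectra, _ = generate_spectra(design, seed=12)
    prep = raman.preprocess_set(spectra)
    counts = []
    for h in (0.1, 0.3, 0.5, 0.7, 0.9):
        a = raman.cluster_opus(prep, h)
        n_clusters = a.labels.nunique() - (1 if "unclassified" in set(a.labels) else 0)
        n_clusters += (a.labels == "unclassified").sum()  # singletons as clusters
        counts.append(n_clusters)
    assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# AIC cutoff selection
# ---------------------------------------------------------------------------

def test_aic_scan_recovers_three_separated_templates():
    design = SceneDesign(
        n_taxa=10, plant_species=("a", "b"), replicates_per_plant=3,
        spectra_per_sample=25, n_opu_templates=3, junk_fraction=0.0,
        outlier_fraction=0.0, noise_sd=0.01, couplings=(),
    )
    spectra, _ = generate_spectra(design, seed=13)
    prep = raman.preprocess_set(spectra)
    cands = list(np.round(np.arange(0.1, 0.95, 0.1), 2))
    cutoff, curve = raman.select_cutoff_by_aic(prep, cands)
    chosen = curve[curve["cutoff"] == cutoff]
    assert int(chosen["n_non_singleton"].iloc[0]) == 3


def test_aic_duplicate_candidates_idempotent():
    design = SceneDesign(
        n_taxa=10, plant_species=("a",), replicates_per_plant=2,
        spectra_per_sample=15, n_opu_templates=2, junk_fraction=0.0,
        outlier_fraction=0.0, couplings=(),
    )
    spectra, _ = generate_spectra(design, seed=14)
    prep = raman.preprocess_set(spectra)
    c1, _ = raman.select_cutoff_by_aic(prep, [0.2, 0.4, 0.6])
    c2, _ = raman.select_cutoff_by_aic(prep, [0.2, 0.2, 0.4, 0.4, 0.6])
    assert c1 == c2


def test_aic_single_template_selects_one_cluster():
    design = SceneDesign(
        n_taxa=10, plant_species=("a",), replicates_per_plant=2,
        spectra_per_sample=20, n_opu_templates=1, junk_fraction=0.0,
        outlier_fraction=0.0, noise_sd=0.005, couplings=(),
    )
    spectra, _ = generate_spectra(design, seed=15)
    prep = raman.preprocess_set(spectra)
    cutoff, curve = raman.select_cutoff_by_aic(
        prep, list(np.round(np.arange(0.1, 0.95, 0.1), 2)))
    chosen = curve[curve["cutoff"] == cutoff]
    assert int(chosen["k"].iloc[0]) == 1


# ---------------------------------------------------------------------------
# OPU table and diversity
# ---------------------------------------------------------------------------

def test_opu_table_share_arithmetic():
    labels = pd.Series(["OPU-0", "OPU-0", "OPU-1", "unclassified"],
                       index=["c0", "c1", "c2", "c3"])
    cells = pd.DataFrame({"sample_id": ["s1"] * 4},
                         index=["c0", "c1", "c2", "c3"])
    tab = raman.build_opu_table(
        OPUAssignment(labels=labels, cutoff=0.44), cells)
    row = tab.shares.loc["s1"]
    assert row["OPU-0"] == 0.5
    assert row["OPU-1"] == 0.25
    assert row["unclassified"] == 0.25


def test_opu_table_all_unclassified():
    labels = pd.Series(["unclassified"] * 3, index=["c0", "c1", "c2"])
    cells = pd.DataFrame({"sample_id": ["s1"] * 3}, index=labels.index)
    tab = raman.build_opu_table(OPUAssignment(labels=labels, cutoff=0.44), cells)
    assert tab.unclassified_fraction.loc["s1"] == 1.0


def test_opu_share_recovery_and_minor_lumping():
    design = SceneDesign(
        n_taxa=10, plant_species=("a",), replicates_per_plant=2,
        spectra_per_sample=200, n_opu_templates=3, junk_fraction=0.0,
        outlier_fraction=0.0, couplings=(),
    )
    spectra, truth = generate_spectra(design, seed=16)
    lab = truth.true_opu_label
    prep = raman.preprocess_set(spectra)
    a = raman.cluster_opus(prep, 0.44)
    tab = raman.build_opu_table(a, prep.cells)
    # recovered per-sample shares track true template shares to binomial error
    for sample in tab.shares.index:
        cells = spectra.cells.index[spectra.cells["sample_id"] == sample]
        true_shares = lab.loc[cells].value_counts(normalize=True)
        top_true = true_shares.max()
        top_rec = tab.shares.loc[sample].drop("unclassified").max()
        assert abs(top_rec - top_true) < 0.07
    lumped = tab.lumped_view()
    assert set(tab.shares.columns) >= set(
        c for c in lumped.columns if c.startswith("OPU-"))


def test_fisher_scores_zero_between_class_variance_and_top_band():
    rng = np.random.default_rng(3)
    base = gauss(1003) + gauss(1657)
    a_rows = [base + rng.normal(0, 0.01, GRID.size) for _ in range(6)]
    b_rows = [base + gauss(1450, 0.8) + rng.normal(0, 0.01, GRID.size)
              for _ in range(6)]
    s = make_set(a_rows + b_rows)
    labels = pd.Series(["OPU-0"] * 6 + ["OPU-1"] * 6, index=s.cell_ids)
    prof = raman.fisher_rank_scores(s, OPUAssignment(labels=labels, cutoff=0.44))
    top_wn = prof.scores.idxmax()
    assert abs(top_wn - 1450.0) <= 5
    # scale invariance of the score ratio
    s2 = make_set([2 * r for r in a_rows + b_rows])
    prof2 = raman.fisher_rank_scores(
        s2, OPUAssignment(labels=pd.Series(labels.values, index=s2.cell_ids),
                          cutoff=0.44))
    assert prof.ranks.tolist() == prof2.ranks.tolist()


def test_fisher_scores_require_two_classes():
    s = make_set([gauss(1003)] * 4)
    labels = pd.Series(["OPU-0"] * 4, index=s.cell_ids)
    with pytest.raises(ValueError, match="classes"):
        raman.fisher_rank_scores(s, OPUAssignment(labels=labels, cutoff=0.44))


@pytest.mark.parametrize(
    "shares,expected",
    [
        ([0.25, 0.25, 0.25, 0.25], (4, np.log(4), 1.0)),
        ([1.0, 0.0, 0.0, 0.0], (1, 0.0, 0.0)),
        ([0.5, 0.5, 0.0, 0.0], (2, np.log(2), 1.0)),
    ],
)
def test_opu_diversity_closed_forms(shares, expected):
    tab = OPUTable(shares=pd.DataFrame(
        [shares + [0.0]], index=["s1"],
        columns=["OPU-0", "OPU-1", "OPU-2", "OPU-3", "unclassified"]))
    div = raman.opu_diversity(tab)
    rich, h, even = expected
    assert div.loc["s1", "richness"] == rich
    assert np.isclose(div.loc["s1", "shannon"], h, atol=1e-12)
    assert np.isclose(div.loc["s1", "evenness"], even, atol=1e-12)
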