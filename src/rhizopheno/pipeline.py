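"""End-to-end pipeline orchestration with a single config and deterministic
per-stage seed derivation.

Stage order: simulate (optional) -> phenotype -> community -> diffabund ->
network (per production system) -> integrate. Every stage writes its
artifacts under ``outdir`` and the run manifest records parameters, derived
seeds, and SHA-256 checksums of every output; stage seeds are derived from
the master seed through a fixed counter per stage, so disabling one stage
never shifts another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, diffabund, integration, io, network, raman
from .containers import AsvTable, SpectrumSet
from .synthetic import SceneDesign, plant_genopheno_coupling

STAGE_SEED_COUNTER = {
    "simulate": 0, "phenotype": 1, "community": 2,
    "diffabund": 3, "network": 4, "integrate": 5,
}


def stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master_seed), STAGE_SEED_COUNTER[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31 - 1))


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    # input paths (ignored when simulate is enabled)
    counts: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    spectra: str | None = None
    spectra_meta: str | None = None
    # stage toggles
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "phenotype": True, "community": True,
        "diffabund": True, "network": True, "integrate": True,
    })
    # stage parameters
    scene: dict = field(default_factory=dict)
    cutoff: float | None = raman.DEFAULT_CUTOFF
    select_cutoff: bool = False
    cutoff_candidates: list = field(default_factory=lambda: list(
        np.round(np.arange(0.1, 0.92, 0.02), 2)))
    snr_min: float = 3.0
    qc_halfwidth: float = 5.0
    mean_thresh: float = 0.005
    prevalence: float = 0.8
    pseudocount: float = 0.5
    distance: str = "bray-curtis"          # or "aitchison"
    n_perm: int = 999
    nmds_starts: int = 20
    n_mc: int = 128
    da_level: str = "phylum"
    n_boot: int = 100
    network_alpha: float = 0.1
    hub_quantile: float = 0.10
    mcl_inflation: float = 2.0
    envfit_alpha: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _checksums(paths: dict[str, str]) -> dict[str, str]:
    return {k: io.sha256_of(v) for k, v in paths.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {},
                      "parameters": {
                          k: v for k, v in dataclasses.asdict(config).items()
                          if k not in ("stages", "scene")
                      }}

    table: AsvTable | None = None
    spectra: SpectrumSet | None = None
    opu_table = None
    core = None
    dmat = None

    def _record(stage: str, status: str, outputs: dict[str, str] | None = None,
                extra: dict | None = None, seed: int | None = None) -> None:
        entry = {"status": status, "outputs": outputs or {},
                 "checksums": _checksums(outputs or {})}
        if seed is not None:
            entry["seed"] = seed
        if extra:
            entry["summary"] = extra
        manifest["stages"][stage] = entry

    # ---- simulate ---------------------------------------------------------
    if config.stages.get("simulate", False):
        seed = stage_seed(config.seed, "simulate")
        design = SceneDesign(**config.scene)
        table, spectra, truth = plant_genopheno_coupling(design, seed)
        paths = io.write_asv_table(table, outdir, prefix="asv")
        paths["spectra"] = io.write_spectra_wide(
            spectra, outdir / "spectra_wide.csv", outdir / "spectra_cells.tsv")
        paths["spectra_meta"] = str(outdir / "spectra_cells.tsv")
        paths["ground_truth"] = io.write_ground_truth(
            truth, outdir / "ground_truth.json")
        _record("simulate", "completed", paths, seed=seed)
    else:
        manifest["stages"]["simulate"] = {"status": "skipped"}
        if config.counts:
            table = io.read_asv_table(config.counts, config.taxonomy,
                                      config.metadata)
        if config.spectra:
            spectra = io.read_spectra_wide(config.spectra, config.spectra_meta)

    try:
        # ---- phenotype ----------------------------------------------------
        if config.stages.get("phenotype", True) and spectra is not None:
            passed, rejected = raman.qc_signature_filter(
                spectra, window_halfwidth=config.qc_halfwidth,
                snr_min=config.snr_min)
            prep = raman.preprocess_set(passed)
            if config.select_cutoff:
                cutoff, curve = raman.select_cutoff_by_aic(
                    prep, list(config.cutoff_candidates))
            else:
                cutoff, curve = float(config.cutoff), None
            assignment = raman.cluster_opus(prep, cutoff)
            opu_table = raman.build_opu_table(assignment, prep.cells)
            opu_div = raman.opu_diversity(opu_table)
            paths = {
                "opu_table": io.write_opu_table(opu_table, outdir / "opu_table.tsv"),
                "opu_diversity": str(outdir / "opu_diversity.tsv"),
                "assignment": str(outdir / "opu_assignment.tsv"),
            }
            opu_div.to_csv(paths["opu_diversity"], sep="\t",
                           index_label="sample_id")
            assignment.labels.rename("opu").to_csv(
                paths["assignment"], sep="\t", index_label="cell_id")
            try:
                fisher = raman.fisher_rank_scores(prep, assignment)
                fisher.scores.to_frame().assign(rank=fisher.ranks).to_csv(
                    outdir / "fisher_scores.tsv", sep="\t",
                    index_label="wavenumber")
                paths["fisher_scores"] = str(outdir / "fisher_scores.tsv")
            except ValueError as e:
                warnings.warn(f"fisher scores unavailable: {e}")
            if curve is not None:
                curve.to_csv(outdir / "aic_curve.tsv", sep="\t", index=False)
                paths["aic_curve"] = str(outdir / "aic_curve.tsv")
            _record("phenotype", "completed", paths,
                    extra={"cutoff": cutoff, "n_rejected": len(rejected),
                           "n_opus": len(assignment.opu_ids)})
        else:
            manifest["stages"]["phenotype"] = {"status": "skipped"}

        # ---- community ----------------------------------------------------
        if config.stages.get("community", True) and table is not None:
            seed = stage_seed(config.seed, "community")
            rare = community.rarefy_even_depth(table, "min", seed)
            coverage = community.estimate_coverage(rare)
            core = community.filter_core_taxa(rare, config.mean_thresh,
                                              config.prevalence)
            rel = core.relative_abundance()
            if config.distance == "aitchison":
                dmat = community.aitchison_matrix(core, config.pseudocount)
            else:
                dmat = community.bray_curtis_matrix(rel)
            nmds = community.nmds_ordinate(dmat, n_starts=config.nmds_starts,
                                           seed=seed)
            perm = community.permanova(dmat, core.metadata,
                                       n_perm=config.n_perm, seed=seed)
            adiv = community.alpha_diversity(rare)
            paths = {
                "coverage": str(outdir / "coverage.tsv"),
                "distance": io.write_distance_matrix(dmat, outdir / "distance.tsv"),
                "nmds": str(outdir / "nmds_scores.tsv"),
                "permanova": str(outdir / "permanova.tsv"),
                "alpha_diversity": str(outdir / "asv_diversity.tsv"),
                "core_counts": str(outdir / "core_counts.tsv"),
            }
            coverage.to_csv(paths["coverage"], sep="\t", index_label="sample_id")
            nmds.site_scores.to_csv(paths["nmds"], sep="\t",
                                    index_label="sample_id")
            perm.table.to_csv(paths["permanova"], sep="\t")
            adiv.to_csv(paths["alpha_diversity"], sep="\t",
                        index_label="sample_id")
            core.counts.to_csv(paths["core_counts"], sep="\t",
                               index_label="sample_id")
            _record("community", "completed", paths, seed=seed,
                    extra={"nmds_stress": nmds.stress,
                           "n_core_taxa": len(core.taxon_ids)})
            manifest["asv_diversity"] = paths["alpha_diversity"]
        else:
            manifest["stages"]["community"] = {"status": "skipped"}

        # ---- diffabund ----------------------------------------------------
        if config.stages.get("diffabund", True) and table is not None:
            seed = stage_seed(config.seed, "diffabund")
            tested = (diffabund.aggregate_by_rank(table, config.da_level)
                      if config.da_level != "taxon" else table)
            inst = diffabund.dirichlet_clr_instances(tested, config.n_mc, seed)
            res = diffabund.aldex_glm_test(inst, tested.metadata,
                                           tested.taxon_ids)
            paths = {"diffabund": str(outdir / "diffabund.tsv")}
            res.table.to_csv(paths["diffabund"], sep="\t")
            _record("diffabund", "completed", paths, seed=seed,
                    extra={"n_significant_production":
                           len(res.significant("production"))})
        else:
            manifest["stages"]["diffabund"] = {"status": "skipped"}

        # ---- network ------------------------------------------------------
        if config.stages.get("network", True) and table is not None:
            seed = stage_seed(config.seed, "network")
            paths, summary = {}, {}
            for gi, (prod, idx) in enumerate(
                table.metadata.groupby("production").groups.items()
            ):
                sub = table.subset_samples(idx)
                res = network.sparcc_correlations(sub, seed=seed + gi)
                res = network.sparcc_pseudo_p(sub, res, n_boot=config.n_boot,
                                              seed=seed + 100 + gi)
                net = network.build_network(res, alpha=config.network_alpha,
                                            taxonomy=table.taxonomy)
                summary[prod] = {"n_nodes": net.number_of_nodes(),
                                 "n_edges": net.number_of_edges()}
                if net.number_of_nodes() > 0:
                    cents = network.node_centralities(net)
                    hubs = network.detect_hubs(net, config.hub_quantile, cents)
                    clusters = network.mcl_clusters(net, config.mcl_inflation)
                    for nd in net.nodes:
                        net.nodes[nd]["mcl_cluster"] = int(clusters[nd])
                        net.nodes[nd]["hub"] = nd in set(hubs.hubs)
                    paths[f"{prod}_edges"] = io.write_edge_list(
                        net, outdir / f"network_{prod}_edges.tsv")
                    paths[f"{prod}_graphml"] = io.write_graphml(
                        net, outdir / f"network_{prod}.graphml")
                    cents.assign(mcl_cluster=clusters,
                                 hub=[n in set(hubs.hubs) for n in cents.index]
                                 ).to_csv(outdir / f"network_{prod}_nodes.tsv",
                                          sep="\t")
                    paths[f"{prod}_nodes"] = str(
                        outdir / f"network_{prod}_nodes.tsv")
                    summary[prod].update(
                        {"hubs": hubs.hubs,
                         "hub_subnetwork_nodes": hubs.n_nodes,
                         "hub_subnetwork_edges": hubs.n_edges})
            _record("network", "completed", paths, seed=seed, extra=summary)
        else:
            manifest["stages"]["network"] = {"status": "skipped"}

        # ---- integrate ----------------------------------------------------
        if (config.stages.get("integrate", True) and opu_table is not None
                and table is not None and core is not None and dmat is not None):
            seed = stage_seed(config.seed, "integrate")
            adiv = pd.read_csv(outdir / "asv_diversity.tsv", sep="\t",
                               index_col="sample_id")
            odiv = raman.opu_diversity(opu_table)
            reg = integration.diversity_coupling_regression(
                adiv, odiv, table.metadata["production"])
            common = [s for s in dmat.ids if s in opu_table.shares.index]
            dsub = dmat.filter(common)
            constraints = opu_table.shares.loc[common].drop(
                columns="unclassified", errors="ignore")
            constraints = constraints.loc[:, constraints.std() > 0]
            max_c = len(common) - 2
            if constraints.shape[1] > max_c:
                keep = constraints.mean().sort_values(ascending=False).index[:max_c]
                constraints = constraints[list(keep)]
            ord_res = integration.dbrda(dsub, constraints,
                                        n_perm=config.n_perm, seed=seed)
            env = integration.envfit(ord_res.site_scores, constraints,
                                     n_perm=config.n_perm, seed=seed,
                                     alpha=config.envfit_alpha)
            rel_core = core.relative_abundance().loc[common]
            rho, q, stars = integration.spearman_opu_taxa(
                rel_core, opu_table.shares.loc[common])
            paths = {
                "regressions": str(outdir / "diversity_regressions.tsv"),
                "dbrda_scores": str(outdir / "dbrda_scores.tsv"),
                "dbrda_arrows": str(outdir / "dbrda_arrows.tsv"),
                "envfit": str(outdir / "envfit.tsv"),
                "spearman_rho": str(outdir / "spearman_rho.tsv"),
                "spearman_q": str(outdir / "spearman_q.tsv"),
            }
            reg.to_csv(paths["regressions"], sep="\t", index=False)
            ord_res.site_scores.to_csv(paths["dbrda_scores"], sep="\t",
                                       index_label="sample_id")
            ord_res.biplot_arrows.to_csv(paths["dbrda_arrows"], sep="\t",
                                         index_label="opu")
            env.to_csv(paths["envfit"], sep="\t")
            rho.to_csv(paths["spearman_rho"], sep="\t", index_label="taxon")
            q.to_csv(paths["spearman_q"], sep="\t", index_label="taxon")
            _record("integrate", "completed", paths, seed=seed,
                    extra={"dbrda_constrained_fraction":
                           ord_res.constrained_fraction,
                           "dbrda_p": ord_res.permutation_p,
                           "n_envfit_significant": int(env["significant"].sum())})
        else:
            manifest["stages"]["integrate"] = {"status": "skipped"}
    except Exception as e:  # record partial completion; downstream skipped
        manifest["error"] = f"{type(e).__name__}: {e}"
        for st in STAGE_SEED_COUNTER:
            manifest["stages"].setdefault(st, {"status": "not_run"})
        io.write_manifest(manifest, outdir / "manifest.json")
        raise

    manifest.pop("asv_diversity", None)
    io.write_manifest(manifest, outdir / "manifest.json")
    return manifest
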