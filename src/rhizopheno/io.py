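"""Readers and writers for the pipeline's on-disk dialects.

Counts / taxonomy / metadata as TSV, spectra as wide or long CSV, a minimal
BIOM-style JSON dialect for count tables, distance matrices as square TSV,
networks as edge-list TSV and GraphML, and JSON manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .containers import RANKS, AsvTable, GroundTruth, OPUTable, SpectrumSet


# ---------------------------------------------------------------------------
# ASV tables
# ---------------------------------------------------------------------------

def write_asv_table(table: AsvTable, outdir: str | Path,
                    prefix: str = "asv") -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}_counts.tsv",
        "taxonomy": outdir / f"{prefix}_taxonomy.tsv",
        "metadata": outdir / f"{prefix}_metadata.tsv",
    }
    table.counts.to_csv(paths["counts"], sep="\t", index_label="sample_id")
    table.taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="taxon_id")
    table.metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    return {k: str(v) for k, v in paths.items()}


def read_asv_table(counts_path: str | Path, taxonomy_path: str | Path,
                   metadata_path: str | Path) -> AsvTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="taxon_id",
                           keep_default_na=False)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    return AsvTable(counts=counts.astype(np.int64), taxonomy=taxonomy,
                    metadata=metadata)


def write_biom_json(table: AsvTable, path: str | Path) -> str:
    """Minimal BIOM-style JSON (dense matrix, observation = taxon)."""
    obj = {
        "format": "biom-style-json-1.0",
        "type": "OTU table",
        "matrix_type": "dense",
        "shape": [len(table.taxon_ids), len(table.sample_ids)],
        "rows": [
            {"id": t, "metadata": {"taxonomy": list(table.taxonomy.loc[t, RANKS])}}
            for t in table.taxon_ids
        ],
        "columns": [
            {"id": s, "metadata": table.metadata.loc[s].to_dict()}
            for s in table.sample_ids
        ],
        "data": table.counts.T.to_numpy().tolist(),
    }
    path = Path(path)
    path.write_text(json.dumps(obj, default=_jsonable))
    return str(path)


def read_biom_json(path: str | Path) -> AsvTable:
    obj = json.loads(Path(path).read_text())
    taxa = [r["id"] for r in obj["rows"]]
    samples = [c["id"] for c in obj["columns"]]
    counts = pd.DataFrame(
        np.asarray(obj["data"], dtype=np.int64).T, index=samples, columns=taxa
    )
    taxonomy = pd.DataFrame(
        [r["metadata"].get("taxonomy", [""] * len(RANKS)) for r in obj["rows"]],
        index=taxa, columns=RANKS,
    )
    metadata = pd.DataFrame([c["metadata"] for c in obj["columns"]], index=samples)
    counts.index.name = "sample_id"
    return AsvTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def write_spectra_wide(spectra: SpectrumSet, path: str | Path,
                       meta_path: str | Path | None = None) -> str:
    """Wide CSV: first column 'wavenumber', one column per cell id."""
    wide = spectra.intensities.T
    wide.index.name = "wavenumber"
    wide.to_csv(path)
    if meta_path is not None:
        spectra.cells.to_csv(meta_path, sep="\t", index_label="cell_id")
    return str(path)


def read_spectra_wide(path: str | Path,
                      meta_path: str | Path | None = None) -> SpectrumSet:
    wide = pd.read_csv(path, index_col="wavenumber")
    intens = wide.T
    intens.columns = intens.columns.astype(float)
    if meta_path is not None:
        cells = pd.read_csv(meta_path, sep="\t", index_col="cell_id")
    else:
        cells = pd.DataFrame(
            {"sample_id": [cid.rsplit("_c", 1)[0] for cid in intens.index]},
            index=intens.index,
        )
    return SpectrumSet(intensities=intens, cells=cells)


def read_spectra_long(path: str | Path,
                      meta_path: str | Path | None = None) -> SpectrumSet:
    """Long CSV with columns cell_id, wavenumber, intensity."""
    long = pd.read_csv(path)
    wide = long.pivot(index="cell_id", columns="wavenumber", values="intensity")
    wide.columns = wide.columns.astype(float)
    wide = wide[sorted(wide.columns)]
    if meta_path is not None:
        cells = pd.read_csv(meta_path, sep="\t", index_col="cell_id")
    else:
        cells = pd.DataFrame(
            {"sample_id": [cid.rsplit("_c", 1)[0] for cid in wide.index]},
            index=wide.index,
        )
    return SpectrumSet(intensities=wide, cells=cells)


# ---------------------------------------------------------------------------
# OPU tables, distances, networks, manifests
# ---------------------------------------------------------------------------

def write_opu_table(table: OPUTable, path: str | Path) -> str:
    table.shares.to_csv(path, sep="\t", index_label="sample_id")
    return str(path)


def read_opu_table(path: str | Path) -> OPUTable:
    shares = pd.read_csv(path, sep="\t", index_col="sample_id")
    return OPUTable(shares=shares)


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> str:
    pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )
    return str(path)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))


def write_edge_list(net: nx.Graph, path: str | Path) -> str:
    rows = [
        {"source": u, "target": v, **net.edges[u, v]}
        for u, v in sorted(net.edges)
    ]
    pd.DataFrame(rows, columns=["source", "target", "r", "pseudo_p", "sign"]
                 ).to_csv(path, sep="\t", index=False)
    return str(path)


def write_graphml(net: nx.Graph, path: str | Path) -> str:
    nx.write_graphml(net, path)
    return str(path)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> str:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=1,
                                     default=_jsonable))
    return str(path)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> str:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                     default=_jsonable))
    return str(path)
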