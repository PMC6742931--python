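"""Readers and writers for volumes, tag maps, graphs, tables and reports.

Label volumes are read from NIfTI (.nii/.nii.gz, via nibabel) or NRRD
(.nrrd/.nhdr, via SimpleITK); data must be integer-valued (exactly integral
floats are accepted and cast). Tag maps are JSON objects ({"1": "ectoderm"})
or two-column TSV. Tagged graphs travel as a vertices TSV (vertex_id, tag)
plus an edges TSV (vertex_u, vertex_v); the writer mirrors the reader
bit-exactly. Tables, models and entropy reports serialize to TSV and JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from sementropy.geometry import LabeledVolume, LiminalVolumeTable, TransitionModel
from sementropy.graphs import TaggedGraph
from sementropy.markov import EntropyReport

PathLike = Union[str, Path]


def _as_int_labels(data: np.ndarray) -> np.ndarray:
    if np.issubdtype(data.dtype, np.integer):
        return data
    if np.issubdtype(data.dtype, np.floating) and np.all(data == np.round(data)):
        return data.astype(np.int64)
    raise ValueError("labels must be integers")


def read_tag_map(path: PathLike) -> Dict[int, str]:
    """Tag map from JSON ({"1": "name", ...}) or two-column TSV (label, tag)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        return {int(k): str(v) for k, v in raw.items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("tag map TSV needs two columns: label, tag")
    # tolerate an optional header row
    if not df.iloc[0, 0].lstrip("-").isdigit():
        df = df.iloc[1:]
    return {int(r[0]): str(r[1]) for r in df.itertuples(index=False)}


def write_tag_map(tag_map: Dict[int, str], path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump({str(k): v for k, v in sorted(tag_map.items())}, fh, indent=1)
    else:
        pd.DataFrame(sorted(tag_map.items())).to_csv(
            path, sep="\t", header=False, index=False
        )


def read_volume(
    path: PathLike, tag_map: Union[PathLike, Dict[int, str], None] = None
) -> LabeledVolume:
    """Read a labeled volume; the array is taken as stored, no reorientation.

    ``tag_map`` may be a mapping or a path to a JSON/TSV tag map; if omitted,
    labels are named 'label_<id>'.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    elif name.endswith((".nrrd", ".nhdr")):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        spacing = tuple(float(z) for z in reversed(img.GetSpacing()))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    labels = _as_int_labels(np.asarray(data))
    if labels.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {labels.ndim}D")
    if isinstance(tag_map, (str, Path)):
        tag_map = read_tag_map(tag_map)
    if tag_map is None:
        tag_map = {int(l): f"label_{int(l)}" for l in np.unique(labels) if l != 0}
    missing = set(np.unique(labels).tolist()) - {0} - set(tag_map)
    if missing:
        raise ValueError(f"tag map is missing label ids: {sorted(missing)}")
    return LabeledVolume(labels, spacing, tag_map)


def write_volume(vol: LabeledVolume, path: PathLike) -> None:
    """Write a labeled volume as NIfTI or NRRD (spacing preserved)."""
    path = Path(path)
    name = path.name.lower()
    labels = vol.labels.astype(np.int32)
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(vol.spacing) + [1.0])
        nib.save(nib.Nifti1Image(labels, affine), str(path))
    elif name.endswith((".nrrd", ".nhdr")):
        img = sitk.GetImageFromArray(labels)
        img.SetSpacing(tuple(reversed(vol.spacing)))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_graph(vertices_path: PathLike, edges_path: PathLike) -> TaggedGraph:
    """Tagged graph from a vertices TSV (vertex_id, tag) + edges TSV (u, v)."""
    vdf = pd.read_csv(vertices_path, sep="\t", dtype=str, comment="#")
    if list(vdf.columns[:2]) != ["vertex_id", "tag"]:
        raise ValueError("vertices TSV must have columns vertex_id, tag")
    edf = pd.read_csv(edges_path, sep="\t", dtype=str, comment="#")
    if list(edf.columns[:2]) != ["vertex_u", "vertex_v"]:
        raise ValueError("edges TSV must have columns vertex_u, vertex_v")
    tag_of = dict(zip(vdf["vertex_id"], vdf["tag"]))
    edges = list(zip(edf["vertex_u"], edf["vertex_v"]))
    return TaggedGraph(vertices=tag_of.keys(), edges=edges, tag_of=tag_of)


def write_graph(graph: TaggedGraph, vertices_path: PathLike, edges_path: PathLike) -> None:
    verts = sorted(graph.vertices, key=str)
    pd.DataFrame(
        {"vertex_id": verts, "tag": [graph.tag_of[v] for v in verts]}
    ).to_csv(vertices_path, sep="\t", index=False)
    rows = sorted(tuple(sorted(map(str, e))) for e in graph.edges)
    pd.DataFrame(rows, columns=["vertex_u", "vertex_v"]).to_csv(
        edges_path, sep="\t", index=False
    )


def _matrix_to_tsv(tags, mat: np.ndarray, path: PathLike) -> None:
    pd.DataFrame(mat, index=tags, columns=tags).to_csv(
        path, sep="\t", index_label="tag"
    )


def write_liminal_table(table: LiminalVolumeTable, path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(
                {"tags": table.tags, "v": table.v.tolist(), "clamped": sorted(table.clamped)},
                fh, indent=1,
            )
    else:
        _matrix_to_tsv(table.tags, table.v, path)


def write_transition_model(model: TransitionModel, path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(
                {"tags": model.tags, "Q": model.Q.tolist(), "p0": model.p0.tolist()},
                fh, indent=1,
            )
    else:
        _matrix_to_tsv(model.tags, model.Q, path)


def read_transition_model(path: PathLike) -> TransitionModel:
    with open(path) as fh:
        raw = json.load(fh)
    return TransitionModel(tags=raw["tags"], Q=np.array(raw["Q"]), p0=np.array(raw["p0"]))


def report_to_json(report: EntropyReport, path: PathLike, provenance: Optional[dict] = None) -> None:
    payload = report.to_dict()
    if provenance:
        payload["_provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def report_tsv_row(report: EntropyReport, model_id: str, k: int, connectivity: str) -> Dict:
    """Flat row for concatenation across a developmental series."""
    row: Dict = {
        "model_id": model_id,
        "m": report.m,
        "k": k,
        "connectivity": connectivity,
        "log_base": report.log_base,
    }
    for n in sorted(report.orders):
        row[f"E{n}"] = report.orders[n]
    row["Epi"] = report.stationary
    row["Emax"] = report.e_max
    for key in sorted(report.normalized):
        row[f"{key}_norm"] = report.normalized[key]
    row["non_ergodic_reason"] = report.non_ergodic_reason or ""
    return row


def read_manifest(path: PathLike) -> pd.DataFrame:
    """Staging manifest TSV: model_id, theiler_stage, days, volume_path
    (+ optional tag_map_path)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"model_id", "theiler_stage", "days", "volume_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("manifest is empty")
    return df


def sha256_of(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance(config: dict, inputs: Tuple[PathLike, ...] = (), version: str = "") -> dict:
    if not version:
        from sementropy import __version__ as version  # noqa: PLC0415
    return {
        "tool": "sementropy",
        "version": version,
        "config": config,
        "input_checksums": {str(p): sha256_of(p) for p in inputs},
    }
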