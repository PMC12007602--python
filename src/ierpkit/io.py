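"""Readers and writers for every on-disk artifact.

Formats are deliberately desk-scale and text-first: tab-separated tables
(UTF-8, '.' decimal, mandatory header), CSV connectivity matrices, OFF or
GIFTI surface meshes, and an HDF5 dataset plus human-inspectable JSON
sidecar for epoched recordings. Reader/writer pairs round-trip bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (
    ConnectivityMatrix,
    CorticalMesh,
    EpochedRecording,
    Lead,
    LeadSet,
    Parcellation,
    StimulationRecord,
    SurfaceMap,
)


class FormatError(ValueError):
    """A file does not conform to its expected format."""


class ConsistencyError(ValueError):
    """Two parts of a multi-file artifact disagree."""


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(value, path: Path, line: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise FormatError(
        f"{path}:{line}: column {column!r}: cannot parse boolean {value!r}"
    )


# ---------------------------------------------------------------------------
# lead tables
# ---------------------------------------------------------------------------

LEAD_COLUMNS = ("lead_id", "x", "y", "z", "hemisphere", "grey_matter")


def read_leads_table(path: str | Path) -> LeadSet:
    """Read a lead table TSV with columns lead_id, x, y, z, hemisphere,
    grey_matter and optional region."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in LEAD_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    leads = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after header
        coords = []
        for col in ("x", "y", "z"):
            try:
                coords.append(float(row[col]))
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}:{line}: non-numeric coordinate "
                    f"{row[col]!r} in column {col!r}"
                ) from None
        region = row.get("region")
        if region is not None and (pd.isna(region) or region == ""):
            region = None
        try:
            leads.append(
                Lead(
                    lead_id=str(row["lead_id"]),
                    position=np.array(coords),
                    hemisphere=str(row["hemisphere"]).strip(),
                    in_grey_matter=_parse_bool(
                        row["grey_matter"], path, line, "grey_matter"
                    ),
                    region_label=region,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{line}: {exc}") from None
    return LeadSet(leads)


def write_leads_table(leads: LeadSet, path: str | Path) -> None:
    df = leads.to_frame()
    df["grey_matter"] = df["grey_matter"].map({True: "true", False: "false"})
    df["region"] = df["region"].fillna("")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# epoched recordings: HDF5 dataset + JSON sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_epochs(recording: EpochedRecording, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
    meta = {
        "lead_ids": list(recording.lead_ids),
        "conditions": [str(c) for c in recording.conditions],
        "sampling_rate": recording.sampling_rate,
        "epoch_window": list(recording.epoch_window),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_epochs(path: str | Path) -> EpochedRecording:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError(f"{path}: no 'data' dataset")
        data = f["data"][()]
    if data.ndim != 3 or data.shape[0] != len(meta["lead_ids"]):
        raise ConsistencyError(
            f"{path}: array has {data.shape[0] if data.ndim == 3 else '?'} "
            f"leads but sidecar lists {len(meta['lead_ids'])}"
        )
    if data.shape[1] != len(meta["conditions"]):
        raise ConsistencyError(
            f"{path}: array has {data.shape[1]} trials but sidecar lists "
            f"{len(meta['conditions'])} condition labels"
        )
    return EpochedRecording(
        lead_ids=list(meta["lead_ids"]),
        conditions=np.array(meta["conditions"], dtype=object),
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        epoch_window=tuple(meta["epoch_window"]),
    )


# ---------------------------------------------------------------------------
# surface meshes: OFF and GIFTI
# ---------------------------------------------------------------------------


def read_mesh(path: str | Path) -> CorticalMesh:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".off":
        import trimesh

        mesh = trimesh.load(str(path), file_type="off", process=False)
        return CorticalMesh(
            np.asarray(mesh.vertices, float), np.asarray(mesh.faces, int)
        )
    if suffix == ".gii" or path.name.lower().endswith(".surf.gii"):
        import nibabel as nib

        gii = nib.load(str(path))
        points = tris = None
        for da in gii.darrays:
            intent = da.intent
            if intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                points = np.asarray(da.data, float)
            elif intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                tris = np.asarray(da.data, int)
        if points is None or tris is None:
            raise FormatError(f"{path}: GIFTI lacks pointset/triangle arrays")
        return CorticalMesh(points, tris)
    raise FormatError(
        f"{path}: unsupported mesh extension {suffix!r} (use .off or .gii)"
    )


def write_mesh_off(mesh: CorticalMesh, path: str | Path) -> None:
    lines = ["OFF", f"{mesh.n_nodes} {len(mesh.triangles)} 0"]
    for p in mesh.node_positions:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mesh_gifti(mesh: CorticalMesh, path: str | Path) -> None:
    import nibabel as nib

    points = nib.gifti.GiftiDataArray(
        mesh.node_positions.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[points, tris]), str(path))


# ---------------------------------------------------------------------------
# parcellations
# ---------------------------------------------------------------------------


def read_parcellation(
    node_path: str | Path,
    n_nodes: int,
    region_path: str | Path | None = None,
) -> Parcellation:
    """Read a node-label TSV (node_index, region) and optional region
    table TSV (region, hemisphere, display)."""
    node_path = Path(node_path)
    df = pd.read_csv(node_path, sep="\t", dtype=str)
    for col in ("node_index", "region"):
        if col not in df.columns:
            raise FormatError(
                f"{node_path}: missing mandatory column {col!r}"
            )
    labels = np.full(n_nodes, "", dtype=object)
    for i, row in df.iterrows():
        try:
            idx = int(row["node_index"])
        except ValueError:
            raise FormatError(
                f"{node_path}:{i + 2}: non-integer node index "
                f"{row['node_index']!r}"
            ) from None
        if not 0 <= idx < n_nodes:
            raise FormatError(
                f"{node_path}:{i + 2}: node index {idx} out of range "
                f"for {n_nodes}-node mesh"
            )
        region = row["region"]
        labels[idx] = "" if pd.isna(region) else str(region)
    if region_path is not None:
        table = pd.read_csv(Path(region_path), sep="\t", dtype=str)
        if "region" not in table.columns:
            raise FormatError(f"{region_path}: missing column 'region'")
        table = table.set_index("region")
        if "hemisphere" not in table.columns:
            table["hemisphere"] = "L"
        if "display" not in table.columns:
            table["display"] = table.index
    else:
        names = sorted({str(r) for r in labels if r})
        table = pd.DataFrame(
            {"hemisphere": "L", "display": names},
            index=pd.Index(names, name="region"),
        )
    return Parcellation(labels, table)


def write_parcellation(parc: Parcellation, node_path: str | Path) -> None:
    rows = [
        {"node_index": i, "region": r}
        for i, r in enumerate(parc.node_labels)
        if r
    ]
    pd.DataFrame(rows, columns=["node_index", "region"]).to_csv(
        node_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# connectivity matrices
# ---------------------------------------------------------------------------


def read_connectivity(path: str | Path, direction: str) -> ConnectivityMatrix:
    """Read a square CSV with region names as header row and first column.

    Out-of-range values are an error, never clipped.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(
            f"{path}: matrix must be square, got {df.shape[0]} x {df.shape[1]}"
        )
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError(f"{path}: row and column region order differ")
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise FormatError(f"{path}: non-numeric or missing entries")
    if values.min() < 0 or values.max() > 1:
        bad = values[(values < 0) | (values > 1)][0]
        raise FormatError(
            f"{path}: probability {bad} outside [0, 1]"
        )
    return ConnectivityMatrix(
        regions=list(df.columns.astype(str)), prob=values, direction=direction
    )


def write_connectivity(matrix: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(
        matrix.prob, index=matrix.regions, columns=matrix.regions
    ).to_csv(path)


# ---------------------------------------------------------------------------
# stimulation tables
# ---------------------------------------------------------------------------

STIMULATION_COLUMNS = ("site_id", "hemisphere", "current_ma", "category")


def read_stimulation_table(path: str | Path) -> list[StimulationRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in STIMULATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    from .stimulation import categorize

    rows = df.to_dict("records")
    try:
        return categorize(rows)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_stimulation_table(
    records: list[StimulationRecord], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "hemisphere": [r.hemisphere for r in records],
            "current_ma": [r.current_ma for r in records],
            "category": [r.category for r in records],
            "body_district": [r.body_district or "" for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# surface maps
# ---------------------------------------------------------------------------


def write_surface_map(surface_map: SurfaceMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "node_index": np.arange(len(surface_map.values)),
            "value": surface_map.values,
            "masked": np.where(surface_map.mask, "false", "true"),
        }
    ).to_csv(path, sep="\t", index=False)


def read_surface_map(path: str | Path, map_kind: str) -> SurfaceMap:
    df = pd.read_csv(path, sep="\t")
    order = np.argsort(df["node_index"].to_numpy())
    values = df["value"].to_numpy(float)[order]
    masked = df["masked"].astype(str).str.lower().isin(_TRUE).to_numpy()[order]
    return SurfaceMap(map_kind, values, ~masked)


def write_surface_map_gifti(
    surface_map: SurfaceMap, path: str | Path
) -> None:
    """Export as a GIFTI functional file; masked nodes become NaN."""
    import nibabel as nib

    values = surface_map.values.astype(np.float32).copy()
    values[~surface_map.mask] = np.nan
    da = nib.gifti.GiftiDataArray(values, intent="NIFTI_INTENT_NONE")
    nib.save(nib.gifti.GiftiImage(darrays=[da]), str(path))
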