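"""Channel-sorted electrode tables.

Results are persisted as diff-able text: an ``electrodes.tsv`` whose
core columns (name, x, y, z, size) follow the BIDS-iEEG electrodes
table, with extension columns prefixed ``eloc_``; an ``electrodes.json``
sidecar carrying the probabilistic atlas labels and provenance; and a
``channel_map.tsv`` sorted by channel number so row index == channel.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

import numpy as np
import pandas as pd

from .electrodes import Electrode, ElectrodeSet

SCHEMA_VERSION = 1
_CORE_COLUMNS = [
    "name",
    "x",
    "y",
    "z",
    "size",
    "eloc_channel",
    "eloc_mni_x",
    "eloc_mni_y",
    "eloc_mni_z",
    "eloc_tissue",
]


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "n/a"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def electrodes_to_frame(es: ElectrodeSet) -> pd.DataFrame:
    rows = []
    atlas_names = sorted({a for e in es for a in e.atlas_labels})
    for e in es:
        row = {
            "name": e.label if e.label is not None else f"E{e.id}",
            "x": float(e.centroid_mm[0]),
            "y": float(e.centroid_mm[1]),
            "z": float(e.centroid_mm[2]),
            "size": float(e.radius_mm),
            "eloc_channel": e.channel,
            "eloc_mni_x": None if e.centroid_mni_mm is None else float(e.centroid_mni_mm[0]),
            "eloc_mni_y": None if e.centroid_mni_mm is None else float(e.centroid_mni_mm[1]),
            "eloc_mni_z": None if e.centroid_mni_mm is None else float(e.centroid_mni_mm[2]),
            "eloc_tissue": e.tissue_class,
            "eloc_mean_intensity": None
            if np.isnan(e.mean_intensity)
            else float(e.mean_intensity),
        }
        for a in atlas_names:
            row[f"eloc_atlas_{a}"] = e.atlas_labels.get(a)
        rows.append(row)
    return pd.DataFrame(rows)


def export_channel_map(
    es: ElectrodeSet, outdir, allow_unassigned: bool = False, config_hash: str | None = None
) -> pathlib.Path:
    """Write electrodes.tsv + electrodes.json sidecar + channel_map.tsv.

    Channel numbers must be unique; electrodes lacking one are an error
    unless ``allow_unassigned`` (they are then dropped from the channel
    map but kept in electrodes.tsv).
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chans = [e.channel for e in es if e.channel is not None]
    dupes = sorted({c for c in chans if chans.count(c) > 1})
    if dupes:
        names = [e.label or f"E{e.id}" for e in es if e.channel in dupes]
        raise ValueError(f"duplicate channels {dupes} on electrodes {names}")
    unassigned = [e.label or f"E{e.id}" for e in es if e.channel is None]
    if unassigned and not allow_unassigned:
        raise ValueError(f"electrodes without channel assignment: {unassigned}")

    df = electrodes_to_frame(es)
    _write_tsv(df, outdir / "electrodes.tsv")
    assigned = ElectrodeSet([e for e in es if e.channel is not None]).sorted_by_channel()
    _write_tsv(electrodes_to_frame(assigned), outdir / "channel_map.tsv")

    from . import __version__

    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "software": {"name": "electrolocate", "version": __version__},
        "config_hash": config_hash,
        "prob_labels": {
            (e.label if e.label is not None else f"E{e.id}"): {
                atlas: [[name, frac] for name, frac in pl]
                for atlas, pl in e.prob_labels.items()
            }
            for e in es
        },
    }
    (outdir / "electrodes.json").write_text(json.dumps(sidecar, indent=2))
    (outdir / "manifest.json").write_text(
        json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "files": ["electrodes.tsv", "electrodes.json", "channel_map.tsv"],
            },
            indent=2,
        )
    )
    return outdir


def _write_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def config_digest(obj) -> str:
    """Stable short hash of a configuration dataclass/dict for provenance."""
    try:
        import dataclasses

        if dataclasses.is_dataclass(obj):
            obj = dataclasses.asdict(obj)
    except TypeError:
        pass
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_session(directory) -> ElectrodeSet:
    """Reload a previously exported electrode set.

    Unknown extra columns are preserved verbatim in each electrode's
    ``atlas_labels`` under their original column names prefixed '_extra:'.
    """
    directory = pathlib.Path(directory)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("schema_version", 0) > SCHEMA_VERSION:
            raise ValueError(
                "schema-version mismatch: export was written by a newer "
                f"version (schema {manifest['schema_version']} > {SCHEMA_VERSION}); "
                "migrate before loading"
            )
    tsv = directory / "electrodes.tsv"
    try:
        df = pd.read_csv(tsv, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"corrupted TSV in {tsv}: {exc}") from exc
    _validate_rows(tsv)

    sidecar = {}
    sc_path = directory / "electrodes.json"
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())

    import warnings

    missing_core = [c for c in ("name", "x", "y", "z") if c not in df.columns]
    if missing_core:
        raise ValueError(f"electrodes.tsv missing required columns: {missing_core}")
    if "eloc_tissue" not in df.columns:
        warnings.warn("tissue_class column missing; loading with class unset")

    electrodes = []
    known = set(_CORE_COLUMNS) | {"eloc_mean_intensity"}
    for i, row in df.iterrows():
        def get(col):
            v = row.get(col)
            return None if v is None or v == "n/a" or (isinstance(v, float) and pd.isna(v)) else v

        mni = None
        if get("eloc_mni_x") is not None:
            mni = np.array(
                [float(get("eloc_mni_x")), float(get("eloc_mni_y")), float(get("eloc_mni_z"))]
            )
        atlas_labels = {}
        for col in df.columns:
            if col.startswith("eloc_atlas_") and get(col) is not None:
                atlas_labels[col[len("eloc_atlas_") :]] = get(col)
            elif col not in known and not col.startswith("eloc_atlas_"):
                if get(col) is not None:
                    atlas_labels[f"_extra:{col}"] = get(col)
        name = str(get("name"))
        prob_labels = {
            atlas: [(n, float(f)) for n, f in pl]
            for atlas, pl in sidecar.get("prob_labels", {}).get(name, {}).items()
        }
        mean_int = get("eloc_mean_intensity")
        electrodes.append(
            Electrode(
                id=int(i),
                centroid_mm=np.array([float(get("x")), float(get("y")), float(get("z"))]),
                centroid_mni_mm=mni,
                radius_mm=float(get("size")) if get("size") is not None else 1.3,
                mean_intensity=float(mean_int) if mean_int is not None else float("nan"),
                label=name,
                channel=int(float(get("eloc_channel"))) if get("eloc_channel") is not None else None,
                tissue_class=get("eloc_tissue"),
                atlas_labels=atlas_labels,
                prob_labels=prob_labels,
            )
        )
    return ElectrodeSet(electrodes)


def _validate_rows(tsv_path) -> None:
    lines = pathlib.Path(tsv_path).read_text().rstrip("\n").split("\n")
    ncol = len(lines[0].split("\t"))
    for lineno, line in enumerate(lines[1:], start=2):
        if len(line.split("\t")) != ncol:
            raise ValueError(f"corrupted TSV row at line {lineno} of {tsv_path}")
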