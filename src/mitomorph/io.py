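"""On-disk dataset layout: multi-page TIFF fields with JSON sidecars.

Each field ``<field_id>.tif`` holds three float32 pages in the order
calcium / mito / er (the order is also recorded in the sidecar
``<field_id>.json`` together with condition labels, pixel size and the
scalar ground truth).  Negative controls live in ``<field_id>_ctrl.tif``
(same page order) and boolean truth masks (mito / er / cell) in
``<field_id>_truth.tif``.  ``design.csv`` indexes the dataset;
``manifest.json`` carries sha256 hashes of every file for reproducibility
checks.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .field import FluorescenceField

__all__ = ["write_dataset", "read_dataset", "write_manifest", "CHANNEL_ORDER"]

CHANNEL_ORDER = ("calcium", "mito", "er")


def _field_stack(field: FluorescenceField) -> np.ndarray:
    return np.stack(
        [
            np.asarray(field.calcium_channel, dtype=np.float32),
            np.asarray(field.mito_channel, dtype=np.float32),
            np.asarray(field.er_channel, dtype=np.float32),
        ]
    )


def write_field(field: FluorescenceField, out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    base = out_dir / field.field_id
    tif = base.with_suffix(".tif")
    tifffile.imwrite(tif, _field_stack(field), photometric="minisblack")
    paths.append(tif)

    sidecar = {
        "channel_order": list(CHANNEL_ORDER),
        "pixel_size_um": field.pixel_size,
        **field.labels,
    }
    if field.truth is not None:
        sidecar["truth"] = {
            k: v
            for k, v in field.truth.items()
            if not isinstance(v, np.ndarray)
        }
        masks = np.stack(
            [
                field.truth["mito_mask"],
                field.truth["er_mask"],
                field.truth["cell_mask"],
            ]
        ).astype(np.uint8)
        tpath = Path(str(base) + "_truth.tif")
        tifffile.imwrite(tpath, masks, photometric="minisblack")
        paths.append(tpath)
    if field.controls:
        ctrl = np.stack(
            [np.asarray(field.controls[c], dtype=np.float32) for c in CHANNEL_ORDER]
        )
        cpath = Path(str(base) + "_ctrl.tif")
        tifffile.imwrite(cpath, ctrl, photometric="minisblack")
        paths.append(cpath)
    jpath = base.with_suffix(".json")
    jpath.write_text(json.dumps(sidecar, indent=1, default=float))
    paths.append(jpath)
    return paths


def read_field(tif_path: Path) -> FluorescenceField:
    tif_path = Path(tif_path)
    base = tif_path.with_suffix("")
    sidecar = json.loads(base.with_suffix(".json").read_text())
    stack = tifffile.imread(tif_path).astype(float)
    chans = dict(zip(sidecar["channel_order"], stack))
    controls = None
    cpath = Path(str(base) + "_ctrl.tif")
    if cpath.exists():
        controls = dict(zip(sidecar["channel_order"], tifffile.imread(cpath).astype(float)))
    truth = sidecar.get("truth")
    tpath = Path(str(base) + "_truth.tif")
    if truth is not None and tpath.exists():
        masks = tifffile.imread(tpath).astype(bool)
        truth = dict(truth)
        truth["mito_mask"], truth["er_mask"], truth["cell_mask"] = masks
    return FluorescenceField(
        calcium_channel=chans["calcium"],
        mito_channel=chans["mito"],
        er_channel=chans["er"],
        pixel_size=float(sidecar["pixel_size_um"]),
        katp_level=sidecar["katp_level"],
        rotenone=sidecar["rotenone"],
        replicate_id=sidecar["replicate"],
        field_id=sidecar["field_id"],
        controls=controls,
        truth=truth,
    )


def write_dataset(experiment, out_dir) -> Path:
    """Write a simulated experiment (fields + tables + manifest) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    design_rows = []
    if experiment.fields:
        fdir = out / "fields"
        for fld in experiment.fields:
            written.extend(write_field(fld, fdir))
            design_rows.append(dict(fld.labels))
    else:
        design_rows = experiment.field_table[
            ["field_id", "replicate", "katp_level", "rotenone"]
        ].to_dict("records")
    design = pd.DataFrame(design_rows)[["field_id", "replicate", "katp_level", "rotenone"]]
    for name, df in (
        ("design.csv", design),
        ("latent_fields.csv", experiment.field_table),
        ("mtt_wells.csv", experiment.mtt_wells),
        ("cell_counts.csv", experiment.cell_counts),
        ("truth_means.csv", experiment.truth_means),
    ):
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)
    return write_manifest(out, written)


def write_manifest(out_dir: Path, paths: list[Path]) -> Path:
    out_dir = Path(out_dir)
    entries = {}
    for p in sorted(paths):
        entries[str(p.relative_to(out_dir))] = hashlib.sha256(
            p.read_bytes()
        ).hexdigest()
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(entries, indent=1))
    return mpath


def read_dataset(in_dir) -> tuple[list[FluorescenceField], dict[str, pd.DataFrame]]:
    """Read back a dataset directory written by :func:`write_dataset`.

    Returns (fields, tables); a field whose TIFF cannot be read is skipped
    with a warning entry in ``tables["errors"]`` rather than aborting the
    run.
    """
    in_dir = Path(in_dir)
    tables = {}
    for name in ("design", "latent_fields", "mtt_wells", "cell_counts", "truth_means"):
        p = in_dir / f"{name}.csv"
        if p.exists():
            tables[name] = pd.read_csv(p)
    fields = []
    errors = []
    fdir = in_dir / "fields"
    if fdir.exists():
        for tif in sorted(fdir.glob("*.tif")):
            if tif.stem.endswith(("_ctrl", "_truth")):
                continue
            try:
                fields.append(read_field(tif))
            except Exception as exc:  # noqa: BLE001 - surfaced, not dropped
                errors.append({"path": str(tif), "error": str(exc)})
    if errors:
        tables["errors"] = pd.DataFrame(errors)
    return fields, tables
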