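"""Plain-text / TIFF input-output for every pipeline stage.

All tabular outputs are TSV and all summaries JSON so that results are
diffable; images are single-channel TIFF, one file per channel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .coloc import ColocResult, DistanceRecord
from .geometry import CellMesh, load_masks, rasterize_meshes
from .localize import BrightestPixel, FocusLocalization


def write_image(path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_label_image(path, meshes: list[CellMesh], shape) -> None:
    tifffile.imwrite(str(path), rasterize_meshes(meshes, shape))


def read_label_image(path) -> list[CellMesh]:
    return load_masks(tifffile.imread(str(path)))


def mesh_table(meshes: list[CellMesh]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [m.cell_id for m in meshes],
            "centroid_row": [m.centroid[0] for m in meshes],
            "centroid_col": [m.centroid[1] for m in meshes],
            "length_px": [m.length_px for m in meshes],
            "width_px": [m.width_px for m in meshes],
            "axis_angle_rad": [float(np.arctan2(m.long_axis[0], m.long_axis[1])) for m in meshes],
            "area_px": [m.area_px for m in meshes],
        }
    )


def focus_table(foci: list[FocusLocalization]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [f.cell_id for f in foci],
            "channel": [f.channel for f in foci],
            "row_px": [f.centroid[0] for f in foci],
            "col_px": [f.centroid[1] for f in foci],
            "amplitude": [f.amplitude for f in foci],
            "sigma_major_px": [f.sigma_major_px for f in foci],
            "sigma_minor_px": [f.sigma_minor_px for f in foci],
            "orientation_rad": [f.orientation_rad for f in foci],
            "offset": [f.offset for f in foci],
            "fit_rss": [f.fit_rss for f in foci],
            "accepted": [f.accepted for f in foci],
        }
    )


def brightest_table(bps: list[BrightestPixel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [b.cell_id for b in bps],
            "channel": [b.channel for b in bps],
            "row": [b.pixel[0] for b in bps],
            "col": [b.pixel[1] for b in bps],
            "intensity": [b.intensity for b in bps],
        }
    )


def distance_table(records: list[DistanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "kind": [r.kind for r in records],
            "distance_px": [np.nan if r.absent else r.distance_px for r in records],
            "distance_nm": [np.nan if r.absent else r.distance_nm for r in records],
        }
    )


def curve_table(curve: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"distance_px": curve[:, 0], "cum_fraction": curve[:, 1]})


def coloc_summary(result: ColocResult) -> dict:
    return {
        "kind": result.kind,
        "threshold_px": result.threshold_px,
        "threshold_nm": result.threshold_nm,
        "comparator": result.comparator,
        "n_cells": result.n_cells,
        "n_cells_with_ref_focus": result.n_cells_with_ref_focus,
        "coloc_fraction": result.coloc_fraction,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "asymptote": result.asymptote,
        "n_draws": result.n_draws,
    }


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def truth_table(truth) -> pd.DataFrame:
    """Ground-truth TSV: one row per true point (reference foci + target)."""
    rows = []
    for cell, foci, tgt, teth in zip(truth.cells, truth.ref_foci, truth.target, truth.tethered):
        for f in foci:
            rows.append((cell.cell_id, "ref", f[0], f[1], ""))
        rows.append((cell.cell_id, "target", tgt[0], tgt[1], int(teth)))
    return pd.DataFrame(rows, columns=["cell_id", "channel", "row_px", "col_px", "tethered"])


def write_scene(outdir, truth, images: dict[str, np.ndarray], config) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, img in images.items():
        write_image(outdir / f"{name}.tif", img)
    write_label_image(outdir / "labels.tif", [c.mesh for c in truth.cells], truth.image_shape)
    write_tsv(outdir / "ground_truth.tsv", truth_table(truth))
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()}
    cfg["foci_per_cell_ref"] = {str(k): v for k, v in config.foci_per_cell_ref.items()}
    write_json(outdir / "scene_config.json", cfg)
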