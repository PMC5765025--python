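"""Readers, writers, run configuration and logging."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError

__all__ = [
    "RunConfig",
    "read_feature_table",
    "read_image",
    "read_volume",
    "write_cluster_outputs",
    "write_mask_png",
    "write_label_tiff",
    "logger",
]

logger = logging.getLogger("dfclust")


@dataclass
class RunConfig:
    """Knobs shared by the CLI subcommands; round-trips through YAML."""

    seed: int = 0
    trials: int = 85
    m_max: int = 8
    rel_tol: float = 0.05
    window: int = 2
    grid_resolution: int = 128
    fwhm_n: int = 1
    overlap_thresh: float = 0.3
    min_area: int = 20
    min_voxels: int = 10
    output_dir: str = "."

    def __post_init__(self):
        if self.trials < 1 or self.m_max < 1 or self.window < 1:
            raise FormatError("trials, m_max and window must be positive")
        if not (0 < self.rel_tol < 1) or not (0 <= self.overlap_thresh <= 1):
            raise FormatError("rel_tol must be in (0,1), overlap_thresh in [0,1]")
        if self.grid_resolution < 2 or self.fwhm_n < 1:
            raise FormatError("grid_resolution >= 2 and fwhm_n >= 1 required")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_feature_table(path, delimiter: str | None = None):
    """Numeric matrix from a CSV/TSV file; non-numeric columns are dropped
    with a warning, row order is preserved."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path} is empty")
    first = text.splitlines()[0]
    sep = delimiter
    if sep is None:
        sep = "\t" if "\t" in first else ","
    tokens = [t.strip() for t in first.split(sep)]
    header = 0 if any(t and not _looks_numeric(t) for t in tokens) else None
    try:
        df = pd.read_csv(path, sep=sep, header=header)
    except pd.errors.ParserError as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    numeric = df.select_dtypes(include=[np.number])
    dropped = [str(c) for c in df.columns if c not in numeric.columns]
    if dropped:
        logger.warning("dropping non-numeric columns: %s", dropped)
    if numeric.shape[1] == 0:
        raise FormatError(f"{path} has no numeric columns")
    if numeric.isna().any().any():
        bad = int(numeric.isna().any(axis=1).idxmax()) + 1
        raise FormatError(f"{path}: ragged or missing values near line {bad}")
    names = [str(c) for c in numeric.columns]
    return numeric.to_numpy(dtype=float), names


def read_image(path) -> np.ndarray:
    """2-D grayscale image as float intensities in [0, 1]."""
    arr = np.asarray(iio.imread(path)).astype(float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise FormatError(f"{path} is not a 2-D image")
    peak = arr.max()
    return arr / peak if peak > 0 else arr


def read_volume(path) -> np.ndarray:
    """(Z, H, W, 3) float volume in [0, 1] from a multi-page RGB TIFF."""
    arr = np.asarray(tifffile.imread(path)).astype(float)
    if arr.ndim == 3:
        raise FormatError(f"{path}: expected 3 channels per page")
    if arr.ndim != 4:
        raise FormatError(f"{path} is not a multi-page volume")
    if arr.shape[-1] != 3 and arr.shape[1] == 3:
        arr = np.moveaxis(arr, 1, -1)
    if arr.shape[-1] != 3:
        raise FormatError(f"{path}: could not locate the 3 color channels")
    peak = arr.max()
    return arr / peak if peak > 0 else arr


def write_mask_png(mask: np.ndarray, path):
    """Binary mask as an 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def write_label_tiff(labels: np.ndarray, path):
    """3-D integer labels as a multi-page 16-bit TIFF."""
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.uint16))


def _write_manifest(outdir: Path, config: RunConfig, extra: dict):
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "coordinates": "0-based (row, col) / (z, row, col)",
    }
    manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def write_cluster_outputs(result, config: RunConfig, outdir):
    """Labels, HF curve and boundary polylines as CSV plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"row_index": np.arange(result.labels.size), "label": result.labels}
    ).to_csv(outdir / "labels.csv", index=False)
    curve = result.curve
    pd.DataFrame(
        {
            "m": curve.m_values,
            "hf_mean": curve.hf_mean,
            "n_trials": [len(t) for t in curve.hf_trials],
        }
    ).to_csv(outdir / "hf_curve.csv", index=False)
    if result.solution is not None:
        rows = []
        for k, polys in enumerate(result.solution.boundaries):
            v = 0
            for poly in polys:
                for x, y in np.asarray(poly):
                    rows.append((k, v, x, y))
                    v += 1
        pd.DataFrame(rows, columns=["cluster", "vertex_index", "x", "y"]).to_csv(
            outdir / "boundaries.csv", index=False
        )
    split = result.split
    return _write_manifest(
        outdir,
        config,
        {
            "m_star": result.m_star,
            "split_detected": bool(split.split_detected) if split else False,
            "split_at": split.split_at if split else None,
            "branch_means": list(split.branch_means)
            if split and split.branch_means
            else None,
            "truncated_at": curve.truncated_at,
        },
    )


def write_segmentation_manifest(config: RunConfig, outdir, **extra):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return _write_manifest(outdir, config, extra)
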