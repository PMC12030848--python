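"""Raster, region-of-interest and sample handling.

Scenes are band-major reflectance cubes. Two on-disk containers are
supported: multiband TIFF (via :mod:`tifffile`, with pixel size, band names
and the date tag stored as JSON in the ImageDescription tag, and any
pre-existing geo tags passed through untouched) and a plain ``.npz`` dialect
with keys ``values`` / ``pixel_size`` / ``band_names`` / ``date_tag``.

Labelled samples come from ROI text files in a minimal dialect: one record
per line, ``class_id row col``, whitespace- or comma-delimited, ``#``
comments allowed, 0-based coordinates with row counted from the top image
line.
"""

from __future__ import annotations

import json
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Scene", "ROISet", "SampleSet", "SceneFormatError",
           "read_scene", "write_scene", "read_roi_text", "write_roi_text",
           "extract_samples", "split_samples"]


class SceneFormatError(ValueError):
    """Raised when a raster or ROI file cannot be parsed."""


@dataclass
class Scene:
    """A multiband reflectance raster, indexed (band, row, col)."""

    values: np.ndarray
    pixel_size: float
    band_names: list[str]
    date_tag: str = ""
    geo_meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be (band, row, col)")
        if any(d < 1 for d in self.values.shape):
            raise ValueError("all scene dimensions must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scene values must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if len(self.band_names) != self.values.shape[0]:
            raise ValueError("band_names must match band count")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]


@dataclass
class ROISet:
    """Labelled pixel coordinates: records of (class_id, row, col)."""

    records: list[tuple[int, int, int]]
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.records = [(int(c), int(r), int(k)) for c, r, k in self.records]
        for c, _, _ in self.records:
            if c < 1:
                raise ValueError(f"class ids must be >= 1, got {c}")

    @property
    def class_ids(self) -> list[int]:
        return sorted({c for c, _, _ in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def validate_contiguous(self) -> None:
        """Require class ids to form 1..M with no gaps."""
        ids = self.class_ids
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"class ids are not contiguous 1..M: {ids}")


@dataclass
class SampleSet:
    """Per-pixel (or patch) spectra with integer labels 1..M."""

    spectra: np.ndarray
    labels: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)
    split_tag: str = "unsplit"

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.spectra.shape[0] != self.labels.shape[0]:
            raise ValueError("spectra and labels must have equal sample counts")
        if self.spectra.size and not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.labels.shape[0])

    @property
    def n_bands(self) -> int:
        return int(self.spectra.shape[1])

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) if self.n_samples else 0

    def subset(self, idx: np.ndarray, split_tag: str | None = None) -> "SampleSet":
        return SampleSet(self.spectra[idx], self.labels[idx], dict(self.class_names),
                         split_tag if split_tag is not None else self.split_tag)

    def as_batch(self) -> np.ndarray:
        """Spectra as (n, bands, H, W) ready for the network."""
        if self.spectra.ndim == 2:
            return self.spectra[:, :, None, None]
        return self.spectra


# ------------------------------------------------------------------ raster IO

def write_scene(scene: Scene, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or ("npz" if path.suffix == ".npz" else "geotiff")
    if fmt == "npz":
        np.savez(path, values=scene.values, pixel_size=scene.pixel_size,
                 band_names=np.array(scene.band_names),
                 date_tag=np.array(scene.date_tag))
    elif fmt == "geotiff":
        meta = {"pixel_size": scene.pixel_size, "band_names": scene.band_names,
                "date_tag": scene.date_tag, "geo_meta": scene.geo_meta}
        tifffile.imwrite(path, scene.values.astype(np.float32),
                         photometric="minisblack",
                         description=json.dumps(meta))
    else:
        raise ValueError(f"unknown scene format: {fmt}")
    return path


def read_scene(path: str | Path, format: str | None = None) -> Scene:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("npz" if path.suffix == ".npz" else "geotiff")
    try:
        if fmt == "npz":
            with open(path, "rb") as fh, np.load(fh, allow_pickle=False) as z:
                values = np.asarray(z["values"])
                pixel_size = float(z["pixel_size"])
                band_names = [str(b) for b in z["band_names"]]
                date_tag = str(z["date_tag"]) if "date_tag" in z else ""
            return Scene(values, pixel_size, band_names, date_tag)
        if fmt == "geotiff":
            with tifffile.TiffFile(path) as tf:
                values = tf.asarray()
                desc = tf.pages[0].description or "{}"
            meta = json.loads(desc) if desc.strip().startswith("{") else {}
            if values.ndim == 2:
                values = values[None]
            n_bands = values.shape[0]
            band_names = meta.get("band_names") or [f"B{i+1}" for i in range(n_bands)]
            return Scene(values, float(meta.get("pixel_size", 1.0)), band_names,
                         str(meta.get("date_tag", "")), dict(meta.get("geo_meta", {})))
        raise ValueError(f"unknown scene format: {fmt}")
    except (OSError, KeyError, ValueError, json.JSONDecodeError,
            zipfile.BadZipFile) as exc:
        if isinstance(exc, ValueError) and "unknown scene format" in str(exc):
            raise
        raise SceneFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc


# --------------------------------------------------------------- ROI text IO

_SPLIT_RE = re.compile(r"[,\s]+")


def read_roi_text(path: str | Path,
                  class_names: dict[int, str] | None = None) -> ROISet:
    """Parse a ``class_id row col`` text file into an :class:`ROISet`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[tuple[int, int, int]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p for p in _SPLIT_RE.split(line) if p]
        if len(parts) != 3:
            raise SceneFormatError(
                f"{path}:{lineno}: expected 'class_id row col', got {raw!r}")
        try:
            c, r, k = (int(p) for p in parts)
        except ValueError as exc:
            raise SceneFormatError(
                f"{path}:{lineno}: non-integer field in {raw!r}") from exc
        records.append((c, r, k))
    if not records:
        raise SceneFormatError(f"{path}: no ROI records found")
    return ROISet(records, class_names or {})


def write_roi_text(roi: ROISet, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# class_id row col"]
    for c, r, k in roi.records:
        lines.append(f"{c} {r} {k}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ------------------------------------------------------------------ sampling

def extract_samples(scene: Scene, roi: ROISet, patch: int = 1,
                    pad_edges: bool = False) -> SampleSet:
    """One sample per ROI record.

    ``patch = 1`` gives pure pixel spectra (n, bands); odd ``patch > 1``
    gives (n, bands, patch, patch) neighbourhoods. Without ``pad_edges``
    every coordinate must sit at least ``patch // 2`` pixels from the border.
    """
    if patch < 1 or patch % 2 == 0:
        raise ValueError("patch must be an odd integer >= 1")
    h, w = scene.shape
    half = patch // 2
    offenders = [(c, r, k) for c, r, k in roi.records
                 if not (half <= r < h - half and half <= k < w - half)]
    inbounds = [(c, r, k) for c, r, k in roi.records
                if 0 <= r < h and 0 <= k < w]
    if len(inbounds) != len(roi.records):
        bad = [t for t in roi.records if t not in inbounds]
        raise IndexError(f"ROI coordinates outside scene bounds: {bad[:10]}")
    if offenders and not pad_edges:
        raise IndexError(
            f"ROI coordinates too close to the border for patch={patch} "
            f"(enable edge padding or drop them): {offenders[:10]}")
    values = scene.values
    if half and pad_edges:
        values = np.pad(values, ((0, 0), (half, half), (half, half)), mode="edge")
    spectra = []
    labels = []
    for c, r, k in roi.records:
        rr, kk = r + (half if pad_edges else 0), k + (half if pad_edges else 0)
        if patch == 1:
            spectra.append(values[:, r, k])
        else:
            spectra.append(values[:, rr - half:rr + half + 1,
                                  kk - half:kk + half + 1])
        labels.append(c)
    return SampleSet(np.stack(spectra), np.array(labels),
                     dict(roi.class_names), "unsplit")


def split_samples(samples: SampleSet, train_frac: float, seed: int,
                  stratified: bool = True) -> tuple[SampleSet, SampleSet]:
    """Disjoint, exhaustive train/test split; same seed → same split."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = samples.n_samples
    if stratified:
        train_idx: list[int] = []
        test_idx: list[int] = []
        for cls in np.unique(samples.labels):
            members = np.flatnonzero(samples.labels == cls)
            if members.size < 2:
                raise ValueError(
                    f"class {cls} has fewer than 2 samples; cannot stratify")
            perm = rng.permutation(members)
            k = int(round(train_frac * members.size))
            k = min(max(k, 1), members.size - 1)
            train_idx.extend(perm[:k])
            test_idx.extend(perm[k:])
        train_idx = np.sort(np.array(train_idx))
        test_idx = np.sort(np.array(test_idx))
    else:
        perm = rng.permutation(n)
        k = int(round(train_frac * n))
        train_idx = np.sort(perm[:k])
        test_idx = np.sort(perm[k:])
    return (samples.subset(train_idx, "train"), samples.subset(test_idx, "test"))
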