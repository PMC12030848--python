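"""Land-cover change analysis over classified maps.

Per-class areas in km² (pixel count × pixel_size² / 10⁶), percentage change
rates between two dates ((A₂ − A₁)/A₁ × 100, reported to two decimals with
the raw value retained), and class-transition matrices whose entry (c₁, c₂)
counts pixels labelled c₁ at the first date and c₂ at the second. Areas are
planar; no geodesic correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AreaTable", "ChangeReport", "TransitionMatrix", "class_areas",
           "change_rate", "change_report", "transition_matrix"]


@dataclass
class AreaTable:
    """Per-class area in km² for one classified map."""

    areas_km2: dict[int, float]
    pixel_size: float
    date_tag: str = ""
    class_names: dict[int, str] = field(default_factory=dict)

    @property
    def total_km2(self) -> float:
        return float(sum(self.areas_km2.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"class_id": c,
              "class": self.class_names.get(c, f"class_{c}"),
              "area_km2": a}
             for c, a in sorted(self.areas_km2.items())])


def class_areas(class_map: np.ndarray, pixel_size: float,
                n_classes: int | None = None, date_tag: str = "",
                class_names: dict[int, str] | None = None) -> AreaTable:
    """Tabulate per-class area; declared classes absent from the map get 0."""
    class_map = np.asarray(class_map)
    if class_map.size == 0:
        raise ValueError("empty class map")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    m = int(n_classes if n_classes is not None else class_map.max())
    km2_per_pixel = pixel_size ** 2 / 1e6
    counts = np.bincount(class_map.ravel(), minlength=m + 1)[1:m + 1]
    areas = {c + 1: float(counts[c] * km2_per_pixel) for c in range(m)}
    return AreaTable(areas, pixel_size, date_tag, class_names or {})


def change_rate(a1: float, a2: float) -> float | None:
    """(a2 − a1)/a1 × 100; ``None`` (flagged, not raised) when a1 = 0."""
    if a1 < 0 or a2 < 0:
        raise ValueError("areas must be non-negative")
    if a1 == 0:
        return None
    return (a2 - a1) / a1 * 100.0


@dataclass
class ChangeReport:
    """Per-class area pair and change rate between two dates."""

    table: pd.DataFrame      # class, area_1, area_2, change_rate_pct
    date_tags: tuple[str, str]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.table.copy()
        out["change_rate_pct"] = out["change_rate_pct"].round(2)
        out.to_csv(path, index=False)
        return path


def change_report(t1: AreaTable, t2: AreaTable) -> ChangeReport:
    if set(t1.areas_km2) != set(t2.areas_km2):
        raise ValueError("area tables declare different class sets")
    rows = []
    for c in sorted(t1.areas_km2):
        a1, a2 = t1.areas_km2[c], t2.areas_km2[c]
        rows.append({
            "class_id": c,
            "class": t1.class_names.get(c, f"class_{c}"),
            "area_1_km2": a1,
            "area_2_km2": a2,
            "change_rate_pct": change_rate(a1, a2),
        })
    return ChangeReport(pd.DataFrame(rows), (t1.date_tag, t2.date_tag))


@dataclass
class TransitionMatrix:
    """Pixel counts, rows = class at date 1, columns = class at date 2."""

    counts: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        m = self.counts.shape[0]
        names = [self.class_names.get(i + 1, f"class_{i + 1}") for i in range(m)]
        return pd.DataFrame(self.counts, index=names, columns=names)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path)
        return path


def transition_matrix(map1: np.ndarray, map2: np.ndarray, m: int,
                      class_names: dict[int, str] | None = None
                      ) -> tuple[TransitionMatrix, np.ndarray]:
    """Class transitions plus a change mask (1 where the label changed)."""
    map1 = np.asarray(map1)
    map2 = np.asarray(map2)
    if map1.shape != map2.shape:
        raise ValueError(f"map shapes differ: {map1.shape} vs {map2.shape}")
    for name, arr in (("map1", map1), ("map2", map2)):
        if arr.min() < 1 or arr.max() > m:
            raise ValueError(f"{name} labels must be in 1..{m}")
    counts = np.zeros((m, m), dtype=np.int64)
    np.add.at(counts, (map1.ravel() - 1, map2.ravel() - 1), 1)
    change_mask = (map1 != map2).astype(np.uint8)
    return TransitionMatrix(counts, class_names or {}), change_mask
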