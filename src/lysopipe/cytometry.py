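"""Image-cytometry cell-cycle gating.

Cells are plotted in (mean Hoechst, total p-H3) space and gated into
four populations with axis-aligned rectangles:

* **interphase** — p-H3-low, mean-Hoechst-low (decondensed chromatin);
* **ph3_interphase_prophase** — p-H3-high but chromatin not yet
  condensed (late G2 / prophase);
* **mitotic** — p-H3-high with condensed chromatin (high mean Hoechst);
* **ph3neg_mitotic_apoptotic** — condensed chromatin without the p-H3
  signal (mitotic-exit or apoptotic cells).

Rectangles use half-open containment ``[min, max)`` on both axes so
gates that share an edge are disjoint.  Percentages always use all
imaged cells of a condition as the denominator.  ``auto_gates`` builds
the rectangles from two 1-D valley thresholds (two-class variance split
on the log-scaled axis), for synthetic or well-separated data; manual
gate configs always take precedence in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.filters import threshold_otsu

from .synthetic import POPULATIONS

UNASSIGNED = "unassigned"


class GateConfigError(ValueError):
    """Overlapping, empty or non-finite gate rectangles."""


class GatingImpossibleError(ValueError):
    """A gating axis is degenerate (constant feature)."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in (mean_hoechst, total_ph3) space;
    containment is half-open: min <= v < max on both axes."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x_min) & (x < self.x_max)
            & (y >= self.y_min) & (y < self.y_max)
        )

    def is_valid(self) -> bool:
        return (
            np.isfinite([self.x_min, self.x_max, self.y_min, self.y_max]).all()
            and self.x_min < self.x_max
            and self.y_min < self.y_max
        )

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.x_min < other.x_max
            and other.x_min < self.x_max
            and self.y_min < other.y_max
            and other.y_min < self.y_max
        )


@dataclass
class GateConfig:
    """One rectangle per population, pairwise disjoint."""

    gates: dict[str, Rect]

    def __post_init__(self) -> None:
        unknown = set(self.gates) - set(POPULATIONS)
        if unknown:
            raise GateConfigError(f"unknown population labels: {sorted(unknown)}")
        for label, rect in self.gates.items():
            if not rect.is_valid():
                raise GateConfigError(f"gate {label!r} is empty or non-finite")
        labels = list(self.gates)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if self.gates[a].overlaps(self.gates[b]):
                    raise GateConfigError(f"gates {a!r} and {b!r} overlap")

    def to_yaml(self, path: str | Path) -> None:
        data = {
            label: {k: float(v) for k, v in asdict(rect).items()}
            for label, rect in self.gates.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GateConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls({label: Rect(**rect) for label, rect in data.items()})


def gate_cells(
    cells: pd.DataFrame, gates: GateConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label cells by their containing gate and tally percentages.

    Returns (labelled cells, percentage table).  Every cell receives
    exactly one label (``unassigned`` if outside all gates); per
    condition, percentages over the four populations plus unassigned sum
    to 100 because the denominator is all imaged cells.
    """
    x = cells["mean_hoechst"].to_numpy(float)
    y = cells["total_ph3"].to_numpy(float)
    labels = np.full(len(cells), UNASSIGNED, dtype=object)
    for name, rect in gates.gates.items():
        inside = rect.contains(x, y)
        labels[inside] = name
    out = cells.copy()
    out["label"] = labels
    pct_rows = []
    for cond, sub in out.groupby("condition", sort=False):
        total = len(sub)
        for name in list(POPULATIONS) + [UNASSIGNED]:
            pct_rows.append(
                {
                    "condition": cond,
                    "label": name,
                    "count": int((sub["label"] == name).sum()),
                    "percent": 100.0 * (sub["label"] == name).sum() / total,
                }
            )
    return out, pd.DataFrame(pct_rows)


def _valley_threshold(values: np.ndarray) -> float:
    """Two-class split of a positive-valued feature on the log scale."""
    v = np.asarray(values, float)
    v = v[v > 0]
    if v.size == 0 or np.isclose(v.min(), v.max()):
        raise GatingImpossibleError("feature is constant; cannot split")
    log_v = np.log10(v)
    return float(10 ** threshold_otsu(log_v))


def auto_gates(cells: pd.DataFrame, pad: float = 10.0) -> GateConfig:
    """Propose rectangular gates from 1-D thresholds on both axes.

    The p-H3 and mean-Hoechst axes are each split at the valley between
    their two log-scale modes; the four threshold half-planes are
    intersected into rectangles bounded by the (padded) data range so
    all coordinates stay finite.
    """
    if len(cells) < 100:
        raise ValueError("auto_gates needs at least 100 cells")
    x = cells["mean_hoechst"].to_numpy(float)
    y = cells["total_ph3"].to_numpy(float)
    tx = _valley_threshold(x)
    ty = _valley_threshold(y)
    x_lo, x_hi = x.min() / pad, x.max() * pad
    y_lo, y_hi = y.min() / pad, y.max() * pad
    return GateConfig(
        {
            "interphase": Rect(x_lo, tx, y_lo, ty),
            "ph3_interphase_prophase": Rect(x_lo, tx, ty, y_hi),
            "mitotic": Rect(tx, x_hi, ty, y_hi),
            "ph3neg_mitotic_apoptotic": Rect(tx, x_hi, y_lo, ty),
        }
    )


def dna_histogram(
    cells: pd.DataFrame,
    bins: int = 50,
    edges: np.ndarray | None = None,
    mitotic_label: str = "mitotic",
) -> pd.DataFrame:
    """Binned total-Hoechst (DNA content) counts split into mitotic vs
    non-mitotic cells, per condition.

    Bin edges are equal-width over the observed range unless given.
    """
    if edges is None:
        if bins < 2:
            raise ValueError("need at least 2 bins")
        th = cells["total_hoechst"].to_numpy(float)
        edges = np.linspace(th.min(), th.max(), bins + 1)
    rows = []
    for cond, sub in cells.groupby("condition", sort=False):
        mitotic = sub["label"] == mitotic_label
        counts_m, _ = np.histogram(sub.loc[mitotic, "total_hoechst"], bins=edges)
        counts_n, _ = np.histogram(sub.loc[~mitotic, "total_hoechst"], bins=edges)
        for i in range(len(edges) - 1):
            rows.append(
                {
                    "condition": cond,
                    "bin_left": edges[i],
                    "bin_right": edges[i + 1],
                    "mitotic": int(counts_m[i]),
                    "non_mitotic": int(counts_n[i]),
                }
            )
    return pd.DataFrame(rows)


def mitotic_percentages(percentages: pd.DataFrame) -> pd.Series:
    """Convenience: percent of cells in the mitotic gate per condition."""
    sub = percentages[percentages["label"] == "mitotic"]
    return sub.set_index("condition")["percent"]
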