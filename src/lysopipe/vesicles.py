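"""Vesicle morphometry and ratiometric luminal-pH proxy.

Segmentation uses the maximum-entropy (Kapur) threshold: the gray level
that maximises the sum of Shannon entropies of the background and
foreground partitions of the intensity histogram.  Segmented particles
are 8-connected components; areas below a cutoff (default 0.1 µm²,
inclusive) are discarded as sub-resolution noise.

The luminal-pH proxy is the per-vesicle FITC/TMR mean-intensity ratio
(pH-sensitive over pH-insensitive dextran); a higher ratio means a more
alkaline lumen.  Only ratios are reported — absolute pH would need a
calibration curve.  All group statistics are computed on biological
replicate means, never on pooled vesicles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

DEFAULT_MIN_AREA_UM2 = 0.1

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)
FOUR_CONNECTED = ndimage.generate_binary_structure(2, 1)


class ThresholdUndefinedError(ValueError):
    """The image has a single gray level; no threshold separates it."""


def max_entropy_threshold(histogram: np.ndarray) -> int:
    """Kapur maximum-entropy threshold of an intensity histogram.

    For each candidate t, the histogram is split into background
    (levels <= t) and foreground (levels > t); t* maximises the sum of
    the two partitions' Shannon entropies (natural log, 0·ln 0 := 0).
    Ties break to the lowest t.
    """
    counts = np.asarray(histogram, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("histogram must be 1-D with at least 2 bins")
    if (counts > 0).sum() < 2:
        raise ThresholdUndefinedError(
            "histogram has fewer than 2 nonzero bins; threshold undefined"
        )
    p = counts / counts.sum()
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    cum_p = np.cumsum(p)
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]

    # candidate thresholds t = 0 .. G-2 (both partitions must be nonempty
    # in probability mass for the entropies to be defined)
    t = np.arange(p.size - 1)
    pb = cum_p[t]
    pf = 1.0 - pb
    valid = (pb > 0) & (pf > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hb = -(cum_plogp[t] / pb) + np.log(pb)
        hf = -((total_plogp - cum_plogp[t]) / pf) + np.log(pf)
    crit = np.where(valid, hb + hf, -np.inf)
    return int(np.argmax(crit))  # argmax returns the first (lowest) maximiser


def image_histogram(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Integer gray-level histogram of a uint8/uint16 image (uint16 is
    rebinned to ``levels`` levels)."""
    img = np.asarray(image)
    if img.dtype == np.uint8:
        return np.bincount(img.ravel(), minlength=256)
    scaled = (img.astype(float) - img.min()) / max(int(img.max()) - int(img.min()), 1)
    return np.bincount(
        np.minimum((scaled * levels).astype(int), levels - 1), minlength=levels
    )


@dataclass
class SegmentationResult:
    threshold: int
    mask: np.ndarray
    labels: np.ndarray
    pixel_size_um: float

    @property
    def n_particles(self) -> int:
        return int(self.labels.max())


def segment(
    image: np.ndarray,
    pixel_size_um: float,
    connectivity: np.ndarray = EIGHT_CONNECTED,
) -> SegmentationResult:
    """Max-entropy threshold + connected-component labelling."""
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be > 0")
    hist = image_histogram(image)
    thr = max_entropy_threshold(hist)
    mask = np.asarray(image) > thr
    labels, _ = ndimage.label(mask, structure=connectivity)
    return SegmentationResult(thr, mask, labels, pixel_size_um)


def extract_particles(
    mask: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    connectivity: np.ndarray = EIGHT_CONNECTED,
) -> pd.DataFrame:
    """Label a binary mask and measure particle areas.

    Area = pixel count × pixel size²; particles with area strictly below
    ``min_area_um2`` are dropped (the cutoff is inclusive: a particle at
    exactly the cutoff is retained).  An empty mask yields an empty
    table.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be > 0")
    labels, n = ndimage.label(np.asarray(mask, bool), structure=connectivity)
    if n == 0:
        return pd.DataFrame(columns=["particle_id", "pixels", "area_um2"]).set_index(
            "particle_id"
        )
    pixels = ndimage.sum_labels(
        np.ones_like(labels), labels, index=np.arange(1, n + 1)
    ).astype(int)
    areas = pixels * pixel_size_um**2
    out = pd.DataFrame(
        {"particle_id": np.arange(1, n + 1), "pixels": pixels, "area_um2": areas}
    ).set_index("particle_id")
    return out[out["area_um2"] >= min_area_um2]


def measure_vesicles(
    seg: SegmentationResult,
    fitc: np.ndarray | None = None,
    tmr: np.ndarray | None = None,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> pd.DataFrame:
    """Per-vesicle areas and (optionally) background-subtracted channel
    means and the FITC/TMR ratio.

    Channel background is estimated as the modal intensity of each
    image (the most frequent gray level, i.e. the flat background).
    Vesicles whose background-subtracted TMR signal is not positive are
    excluded (counted in ``attrs['n_excluded_tmr']``).
    """
    particles = extract_particles(
        seg.mask, seg.pixel_size_um, min_area_um2=min_area_um2
    )
    # re-derive labels consistent with extract_particles' numbering
    labels, _ = ndimage.label(seg.mask, structure=EIGHT_CONNECTED)
    out = particles.copy()
    excluded = 0
    if fitc is not None and tmr is not None:
        for name, img in (("fitc", fitc), ("tmr", tmr)):
            background = int(np.bincount(np.asarray(img).ravel()).argmax())
            means = ndimage.mean(
                np.asarray(img, float) - background,
                labels,
                index=out.index.to_numpy(),
            )
            out[name] = means
        ok = out["tmr"] > 0
        excluded = int((~ok).sum())
        out = out[ok].copy()
        out["ratio"] = out["fitc"] / out["tmr"]
    out.attrs["n_excluded_tmr"] = excluded
    out.attrs["threshold"] = seg.threshold
    return out


# ---------------------------------------------------------------------------
# replicate-level statistics


def _replicate_means(
    records: pd.DataFrame, value: str, group: str = "phase", rep: str = "replicate"
) -> pd.DataFrame:
    return (
        records.groupby([group, rep])[value].mean().rename("mean").reset_index()
    )


def area_comparison(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Mean vesicle area per (phase, replicate) and an unpaired
    two-tailed t-test comparing the replicate means of the two phases.

    With a single replicate per phase the means are still reported but
    the test statistics are NaN.
    """
    means = _replicate_means(records, "area_um2")
    groups = [
        g["mean"].to_numpy() for _, g in means.groupby("phase", sort=True)
    ]
    if len(groups) == 2 and all(len(g) >= 2 for g in groups):
        t, p = stats.ttest_ind(groups[0], groups[1])
        test = {"t": float(t), "p": float(p)}
    else:
        test = {"t": math.nan, "p": math.nan}
    return means, test


def ratio_ph(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-(phase, replicate) mean FITC/TMR ratio and the unpaired
    t-test on replicate means; higher ratio = more alkaline lumen."""
    means = _replicate_means(records, "ratio")
    groups = [
        g["mean"].to_numpy() for _, g in means.groupby("phase", sort=True)
    ]
    if len(groups) == 2 and all(len(g) >= 2 for g in groups):
        t, p = stats.ttest_ind(groups[0], groups[1])
        test = {"t": float(t), "p": float(p)}
    else:
        test = {"t": math.nan, "p": math.nan}
    return means, test
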