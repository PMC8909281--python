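"""Kapur thresholding, particle measurement, replicate-level statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from lysopipe import synthetic, vesicles
from lysopipe.vesicles import (
    ThresholdUndefinedError,
    area_comparison,
    extract_particles,
    max_entropy_threshold,
    measure_vesicles,
    ratio_ph,
    segment,
)


def kapur_brute_force(counts):
    """Exhaustive maximisation of the two-partition entropy criterion."""
    p = np.asarray(counts, float)
    p = p / p.sum()
    best_t, best = None, -math.inf

    def entropy(q):
        q = q[q > 0]
        q = q / q.sum()
        return float(-(q * np.log(q)).sum())

    for t in range(len(p) - 1):
        pb, pf = p[: t + 1].sum(), p[t + 1:].sum()
        if pb <= 0 or pf <= 0:
            continue
        crit = entropy(p[: t + 1]) + entropy(p[t + 1:])
        if crit > best + 1e-12:
            best, best_t = crit, t
    return best_t


def test_two_level_histogram_ties_break_low():
    counts = np.zeros(256)
    counts[0] = 100
    counts[255] = 100
    # every split separates the two levels equally well; lowest t wins
    assert max_entropy_threshold(counts) == 0


def test_symmetric_histogram_threshold_at_midpoint():
    x = np.arange(16)
    counts = np.exp(-0.5 * ((x - 3.0) / 1.0) ** 2) + np.exp(
        -0.5 * ((x - 12.0) / 1.0) ** 2
    )
    t = max_entropy_threshold(counts)
    assert 6 <= t <= 9


def test_matches_exhaustive_search_on_random_histograms():
    rng = np.random.default_rng(7)
    for _ in range(200):
        counts = rng.integers(0, 50, size=256)
        counts[rng.integers(0, 256)] += rng.integers(100, 1000)
        if (counts > 0).sum() < 2:
            continue
        assert max_entropy_threshold(counts) == kapur_brute_force(counts)


def test_single_level_image_is_undefined():
    counts = np.zeros(256)
    counts[40] = 1000
    with pytest.raises(ThresholdUndefinedError):
        max_entropy_threshold(counts)


# ---------------------------------------------------------------------------
# particles


def flood_fill_label(mask):
    """Independent BFS 8-connected labelling."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and labels[i, j] == 0:
                nxt += 1
                stack = [(i, j)]
                labels[i, j] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < mask.shape[0]
                                and 0 <= xx < mask.shape[1]
                                and mask[yy, xx]
                                and labels[yy, xx] == 0
                            ):
                                labels[yy, xx] = nxt
                                stack.append((yy, xx))
    return labels, nxt


def test_area_cutoff_boundary():
    mask = np.zeros((20, 20), bool)
    mask[1:4, 1:4] = True  # 9 px = 0.09 um^2 at 0.1 um/px -> dropped
    mask[10:12, 10:15] = True  # 10 px = 0.10 um^2 -> retained (inclusive)
    out = extract_particles(mask, pixel_size_um=0.1, min_area_um2=0.1)
    assert len(out) == 1
    assert out.iloc[0]["pixels"] == 10
    assert out.iloc[0]["area_um2"] == pytest.approx(0.10)


def test_labeling_matches_flood_fill_oracle():
    rng = np.random.default_rng(12)
    for _ in range(10):
        mask = rng.random((40, 40)) > 0.7
        got = extract_particles(mask, pixel_size_um=1.0, min_area_um2=0.0)
        _, n = flood_fill_label(mask)
        assert len(got) == n
        oracle_labels, _ = flood_fill_label(mask)
        oracle_sizes = sorted(
            np.bincount(oracle_labels.ravel())[1:].tolist()
        )
        assert sorted(got["pixels"].tolist()) == oracle_sizes


def test_area_invariant_under_translation_and_rotation():
    mask = np.zeros((30, 30), bool)
    mask[3:8, 4:11] = True
    base = extract_particles(mask, 0.1, 0.0)["area_um2"].iloc[0]
    assert (
        extract_particles(np.roll(mask, (5, 7), (0, 1)), 0.1, 0.0)["area_um2"].iloc[0]
        == base
    )
    assert extract_particles(np.rot90(mask), 0.1, 0.0)["area_um2"].iloc[0] == base


def test_empty_mask_yields_empty_table():
    out = extract_particles(np.zeros((10, 10), bool), 0.1)
    assert len(out) == 0


def test_segmentation_recovers_true_areas_and_ratios():
    spec = synthetic.VesicleImageSpec(n_vesicles=15)
    fitc, tmr, mask, truth = synthetic.simulate_vesicle_images(spec, seed=2)
    seg = segment(tmr, spec.pixel_size_um)
    meas = measure_vesicles(seg, fitc=fitc, tmr=tmr)
    assert len(meas) == len(truth)
    assert meas["area_um2"].mean() == pytest.approx(
        truth["true_area_um2"].mean(), rel=0.15
    )
    assert meas["ratio"].mean() == pytest.approx(truth["true_ratio"].mean(), rel=0.1)


# ---------------------------------------------------------------------------
# replicate statistics


def _records(area_by_phase, ratios_by_phase=None, reps=3):
    rows = []
    for phase, areas in area_by_phase.items():
        for rep in range(1, reps + 1):
            for i, a in enumerate(areas):
                rows.append(
                    {
                        "phase": phase,
                        "replicate": rep,
                        "area_um2": a,
                        "ratio": (ratios_by_phase or {}).get(phase, [1.0])[
                            i % len((ratios_by_phase or {}).get(phase, [1.0]))
                        ],
                    }
                )
    return pd.DataFrame(rows)


def test_identical_areas_give_t_zero():
    rec = _records({"interphase": [0.3, 0.4], "mitotic": [0.3, 0.4]})
    means, test = area_comparison(rec)
    assert test["t"] == pytest.approx(0.0, abs=1e-12)


def test_doubled_areas_detected():
    rng = np.random.default_rng(0)
    rows = []
    for phase, scale in (("interphase", 1.0), ("mitotic", 2.0)):
        for rep in range(1, 4):
            for a in rng.normal(0.35, 0.01, 30):
                rows.append(
                    {"phase": phase, "replicate": rep, "area_um2": a * scale}
                )
    rec = pd.DataFrame(rows)
    means, test = area_comparison(rec)
    by_phase = means.groupby("phase")["mean"].mean()
    assert by_phase["mitotic"] / by_phase["interphase"] == pytest.approx(2.0, rel=0.05)
    assert test["p"] < 0.01


def test_statistics_use_replicate_means_not_pooled_vesicles():
    # replicate means identical across phases even though vesicle counts
    # differ wildly -> t must be ~0
    rows = []
    for phase in ("interphase", "mitotic"):
        for rep, n in zip((1, 2, 3), (5, 50, 500)):
            rows += [
                {"phase": phase, "replicate": rep, "area_um2": 0.2 + 0.1 * rep}
            ] * n
    means, test = area_comparison(pd.DataFrame(rows))
    assert test["t"] == pytest.approx(0.0, abs=1e-12)


def test_single_replicate_reports_means_without_statistics():
    rec = _records({"interphase": [0.3], "mitotic": [0.5]}, reps=1)
    means, test = area_comparison(rec)
    assert len(means) == 2
    assert math.isnan(test["p"])


def test_ratio_trivial_values_and_gain_invariance():
    rec = _records(
        {"interphase": [0.3, 0.3], "mitotic": [0.3, 0.3]},
        ratios_by_phase={"interphase": [0.5, 1.5], "mitotic": [1.0]},
    )
    means, _ = ratio_ph(rec)
    by_phase = means.groupby("phase")["mean"].mean()
    assert by_phase["interphase"] == pytest.approx(1.0)
    # common gain on both channels leaves the ratio unchanged
    fitc, tmr = 120.0, 60.0
    assert (3.0 * fitc) / (3.0 * tmr) == fitc / tmr


def test_planted_alkalinisation_detected_end_to_end():
    specs = synthetic.default_vesicle_specs()
    rows = []
    for phase, vspec in specs.items():
        for rep in range(1, 4):
            fitc, tmr, _, _ = synthetic.simulate_vesicle_images(
                vspec, seed=500 + rep + (0 if phase == "interphase" else 50)
            )
            seg = segment(tmr, vspec.pixel_size_um)
            meas = measure_vesicles(seg, fitc=fitc, tmr=tmr)
            rows.append(meas.assign(phase=phase, replicate=rep))
    rec = pd.concat(rows)
    means, test = ratio_ph(rec)
    by_phase = means.groupby("phase")["mean"].mean()
    assert by_phase["mitotic"] > by_phase["interphase"]
    assert test["p"] < 0.05
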