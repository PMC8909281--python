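"""Moderated two-group fits, class/category roll-ups, heatmap clustering."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from lysopipe import differential, quantify
from lysopipe.differential import (
    Contrast,
    cluster_heatmap_order,
    estimate_prior,
    fit_differential,
    summarize_categories,
    summarize_classes,
    trigamma_inverse,
)

from conftest import make_molar_table, toy_samples


def _table_from_lys_values(taxonomy, values: dict[str, list[float]]):
    """6 LYS samples (3 released + 3 untreated) with given molar rows."""
    samples = toy_samples(replicates=3)
    samples = samples[samples["fraction"] == "LYS"]
    samples = samples[samples["treatment"].isin(["released", "untreated"])]
    # released replicates first: value lists read (released x3, untreated x3)
    order = sorted(samples.index, key=lambda s: ("released" not in s, s))
    samples = samples.loc[order]
    molar = pd.DataFrame(values, index=samples.index).T
    return make_molar_table(molar, samples, taxonomy)


CONTRAST = Contrast.within("LYS", "released", "untreated")


def test_identical_groups_give_zero_fc_and_p_one(taxonomy):
    tbl = _table_from_lys_values(
        taxonomy,
        {"PC 34:1": [5.0] * 6, "SM 42:1": [2.0, 2.2, 1.9, 2.0, 2.2, 1.9]},
    )
    res = fit_differential(tbl, CONTRAST)
    pc = res.loc["PC 34:1"]
    assert pc["log2fc"] == pytest.approx(0.0)
    assert pc["p"] == pytest.approx(1.0)
    assert not pc["significant"]


def test_log2fc_is_log_ratio_of_group_means(taxonomy):
    # constant filler keeps the mol% normalisation identical across samples
    tbl = _table_from_lys_values(
        taxonomy,
        {"PC 34:1": [8.0, 8.0, 8.0, 4.0, 4.0, 4.0], "SM 42:1": [92.0, 92.0, 92.0, 96.0, 96.0, 96.0]},
    )
    res = fit_differential(tbl, CONTRAST)
    # mol% PC: 8% vs 4% exactly
    assert res.loc["PC 34:1", "log2fc"] == pytest.approx(1.0)


def test_sign_flips_and_p_unchanged_under_contrast_reversal(filtered_table):
    a = fit_differential(filtered_table, CONTRAST)
    b = fit_differential(filtered_table, CONTRAST.reversed())
    np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-12)
    np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)


def test_unmoderated_mode_matches_scipy_t_test(filtered_table):
    from scipy import stats

    res = fit_differential(filtered_table, CONTRAST, moderated=False)
    log2 = differential._log2_matrix(filtered_table)
    num = filtered_table.columns_for("LYS", "released")
    den = filtered_table.columns_for("LYS", "untreated")
    sp = res.index[5]
    t, p = stats.ttest_ind(log2.loc[sp, num], log2.loc[sp, den])
    assert res.loc[sp, "t"] == pytest.approx(float(t), rel=1e-9)
    assert res.loc[sp, "p"] == pytest.approx(float(p), rel=1e-9)


def test_moderation_interpolates_between_per_gene_and_pooled(filtered_table):
    """Moderated variances lie between the per-species and pooled
    estimates, and tend to the pooled value as the prior dominates."""
    log2 = differential._log2_matrix(filtered_table)
    num = filtered_table.columns_for("LYS", "released")
    den = filtered_table.columns_for("LYS", "untreated")
    y1, y2 = log2[num].to_numpy(), log2[den].to_numpy()
    rss = ((y1 - y1.mean(1, keepdims=True)) ** 2).sum(1) + (
        (y2 - y2.mean(1, keepdims=True)) ** 2
    ).sum(1)
    s2 = rss / 4.0
    d0, s0 = estimate_prior(s2, np.full_like(s2, 4.0))
    assert d0 > 0 and s0 > 0
    s2_post = (d0 * s0 + 4.0 * s2) / (d0 + 4.0)
    lo, hi = np.minimum(s2, s0), np.maximum(s2, s0)
    assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()
    # prior-dominated limit: posterior collapses to s0
    big = (1e9 * s0 + 4.0 * s2) / (1e9 + 4.0)
    np.testing.assert_allclose(big, s0, rtol=1e-6)


def test_trigamma_inverse_round_trip():
    from scipy import special

    for x in (0.1, 0.5, 2.0, 10.0, 100.0):
        y = float(special.polygamma(1, x))
        assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


def test_moderated_fit_matches_limma_oracle(tmp_path, filtered_table):
    """Independent cross-check of the empirical-Bayes fit against the
    reference R implementation on the identical log2 matrix."""
    num = filtered_table.columns_for("LYS", "released")
    den = filtered_table.columns_for("LYS", "untreated")
    # sub-table of species testable in this contrast, so both routes see
    # the identical matrix and estimate the prior on the same species
    testable = (
        filtered_table.molpct[num].notna().any(axis=1)
        & filtered_table.molpct[den].notna().any(axis=1)
    )
    keep = filtered_table.molpct.index[testable][:80]
    sub_tbl = quantify.to_molpct(
        quantify.MolarTable(
            molar=filtered_table.molar.loc[keep],
            molpct=filtered_table.molpct.loc[keep],
            samples=filtered_table.samples,
            taxonomy=filtered_table.taxonomy,
        )
    )
    mat = differential._log2_matrix(sub_tbl)[num + den]
    mat_path = tmp_path / "log2.tsv"
    mat.to_csv(mat_path, sep="\t", float_format="%.17g")
    out_path = tmp_path / "limma.tsv"
    script = textwrap.dedent(
        f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("{mat_path}", row.names = 1, check.names = FALSE))
        group <- factor(c(rep("num", {len(num)}), rep("den", {len(den)})), levels = c("den", "num"))
        design <- model.matrix(~group)
        fit <- eBayes(lmFit(m, design))
        out <- data.frame(species = rownames(m), t = fit$t[, 2], p = fit$p.value[, 2])
        write.table(out, "{out_path}", sep = "\\t", row.names = FALSE, quote = FALSE)
        """
    )
    r_file = tmp_path / "oracle.R"
    r_file.write_text(script)
    subprocess.run(
        ["Rscript", "--vanilla", str(r_file)], check=True, capture_output=True,
        timeout=300,
    )
    oracle = pd.read_csv(out_path, sep="\t").set_index("species")
    ours = fit_differential(sub_tbl, CONTRAST)
    assert list(ours.index) == list(mat.index)
    np.testing.assert_allclose(
        ours["t"], oracle.loc[mat.index, "t"], rtol=1e-5, atol=1e-8
    )
    np.testing.assert_allclose(
        ours["p"], oracle.loc[mat.index, "p"], rtol=1e-5, atol=1e-10
    )


# ---------------------------------------------------------------------------
# summaries


def test_single_species_class_has_flat_chain_stats(taxonomy):
    tbl = _table_from_lys_values(
        taxonomy, {"PC 34:1": [5.0] * 6, "SM 42:1": [5.0] * 6}
    )
    s = summarize_classes(tbl, CONTRAST)
    assert s.loc["PC", "fc_mean_carbons"] == pytest.approx(1.0)
    assert s.loc["PC", "fc_mean_double_bonds"] == pytest.approx(1.0)


def test_equal_molpct_weighted_chain_means(taxonomy):
    tbl = _table_from_lys_values(
        taxonomy,
        {"PC 34:1": [5.0] * 6, "PC 36:2": [5.0] * 6, "SM 42:1": [90.0] * 6},
    )
    s = summarize_classes(tbl, CONTRAST)
    # equal mol% -> mean carbons 35, mean double bonds 1.5 on either side
    res = fit_differential(tbl, CONTRAST)
    assert s.loc["PC", "molpct_num_mean"] == pytest.approx(10.0)
    assert s.loc["PC", "fc_mean_carbons"] == pytest.approx(1.0)
    num = differential._weighted_chain_stats(tbl, tbl.columns_for("LYS", "released"))
    assert num.loc["PC", "mean_carbons"] == pytest.approx(35.0)
    assert num.loc["PC", "mean_double_bonds"] == pytest.approx(1.5)


def test_planted_double_bond_shift_is_recovered(taxonomy):
    """Shifting PC composition toward the saturated species lowers the
    class's mean double-bond count by the constructed amount."""
    # released: 3:1 toward 34:1 (1 double bond); untreated: 1:3
    tbl = _table_from_lys_values(
        taxonomy,
        {
            "PC 34:1": [30.0, 30.0, 30.0, 10.0, 10.0, 10.0],
            "PC 36:4": [10.0, 10.0, 10.0, 30.0, 30.0, 30.0],
            "SM 42:1": [60.0] * 6,
        },
    )
    s = summarize_classes(tbl, CONTRAST)
    want = (0.75 * 1 + 0.25 * 4) / (0.25 * 1 + 0.75 * 4)
    assert s.loc["PC", "fc_mean_double_bonds"] == pytest.approx(want, rel=1e-9)
    assert s.loc["PC", "fc_mean_double_bonds"] < 1


def test_category_molpct_partitions_each_sample(filtered_table):
    summary, _ = summarize_categories(filtered_table)
    per_cond = summary.groupby("condition")["molpct_mean"].sum()
    np.testing.assert_allclose(per_cond.to_numpy(), 100.0, atol=1e-9)


def test_category_tests_detect_planted_shift(filtered_table):
    summary, tests = summarize_categories(
        filtered_table,
        condition_pairs=[(("LYS", "released"), ("LYS", "untreated"))],
    )
    sl = tests[tests["category"] == "SL"]
    assert len(sl) == 1
    # sphingolipids are planted up in released lysosomes
    assert sl.iloc[0]["t"] > 0


def test_pct_significant_bounded(filtered_table):
    res = fit_differential(filtered_table, CONTRAST)
    s = summarize_classes(filtered_table, CONTRAST, res)
    ok = s["pct_significant"].dropna()
    assert ((ok >= 0) & (ok <= 100)).all()


# ---------------------------------------------------------------------------
# clustering


def naive_complete_linkage(x: np.ndarray) -> np.ndarray:
    """O(n^3) agglomerative complete-linkage with Euclidean distance."""
    n = x.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    merges = []
    next_id = n
    ids = list(range(n))
    dist = {
        (a, b): d[a, b] for i, a in enumerate(ids) for b in ids[i + 1:]
    }
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((a, b, h, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c in clusters:
            if c == next_id:
                continue
            h_new = max(
                d[i, j] for i in clusters[next_id] for j in clusters[c]
            )
            dist[(min(c, next_id), max(c, next_id))] = h_new
        next_id += 1
    return np.array([m[2] for m in merges])


def test_identical_rows_merge_first_at_zero():
    m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
    order = cluster_heatmap_order(m)
    assert order.row_linkage[0, 2] == pytest.approx(0.0)
    assert set(order.row_linkage[0, :2].astype(int)) == {0, 1}


def test_one_dimensional_points_cluster_by_distance():
    m = pd.DataFrame({"v": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
    order = cluster_heatmap_order(m)
    z = order.row_linkage
    assert set(z[0, :2].astype(int)) == {0, 1}  # {0,1} merge before 10 joins
    assert z[0, 2] == pytest.approx(1.0)
    assert z[1, 2] == pytest.approx(10.0)


def test_merge_heights_match_naive_oracle():
    rng = np.random.default_rng(3)
    for _ in range(8):
        x = rng.normal(size=(10, 6))
        z = hierarchy.linkage(x, method="complete", metric="euclidean")
        got = cluster_heatmap_order(pd.DataFrame(x)).row_linkage[:, 2]
        want = np.sort(naive_complete_linkage(x))
        np.testing.assert_allclose(np.sort(got), want, rtol=1e-9)


def test_leaf_order_deterministic():
    rng = np.random.default_rng(4)
    x = pd.DataFrame(rng.normal(size=(12, 5)))
    a = cluster_heatmap_order(x)
    b = cluster_heatmap_order(x)
    assert a.row_order == b.row_order
    assert a.col_order == b.col_order


def test_single_row_matrix_trivial_order():
    m = pd.DataFrame([[1.0, 2.0]], index=["only"])
    order = cluster_heatmap_order(m)
    assert order.row_order == ["only"]
    assert order.row_linkage is None
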