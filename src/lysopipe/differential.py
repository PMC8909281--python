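"""Moderated differential lipid abundance and composition summaries.

Per species, abundance is modelled on the log2 mol% scale with a
two-group linear model.  Residual variances are moderated with the
standard empirical-Bayes scheme for small-n omics designs: the
per-feature variances s²_g (d_g residual df each) are treated as scaled
chi-square draws around an inverse-chi-square prior (d0, s0²), the prior
is estimated by method of moments on log s²_g, and the posterior
variance

    s²_post = (d0 · s0² + d_g · s²_g) / (d0 + d_g)

yields a moderated t-statistic with d0 + d_g degrees of freedom.  When
the observed log-variances are no more dispersed than chi-square
sampling alone explains, d0 is infinite and every variance shrinks to
the pooled s0².

Species are called significantly different at raw p < 0.05 (no
multiple-testing correction, matching the workflow this reimplements);
a Benjamini–Hochberg FDR column is emitted for convenience but never
drives the significance flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy

from .quantify import MolarTable

ALPHA = 0.05


@dataclass(frozen=True)
class Contrast:
    """A two-condition comparison, each side a (fraction, treatment) pair.

    The usual within-fraction form is ``Contrast.within("LYS",
    "released", "untreated")``; a cross-fraction comparison (lysosomal
    vs whole-cell of the same treatment) is built with
    ``Contrast.between_fractions``.
    """

    name: str
    numerator: tuple[str, str]  # (fraction, treatment)
    denominator: tuple[str, str]

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("contrast numerator and denominator are identical")

    @classmethod
    def within(cls, fraction: str, numerator: str, denominator: str) -> "Contrast":
        return cls(
            name=f"{fraction}:{numerator}_vs_{denominator}",
            numerator=(fraction, numerator),
            denominator=(fraction, denominator),
        )

    @classmethod
    def between_fractions(cls, treatment: str) -> "Contrast":
        return cls(
            name=f"LYS_vs_WCL:{treatment}",
            numerator=("LYS", treatment),
            denominator=("WCL", treatment),
        )

    def reversed(self) -> "Contrast":
        return Contrast(
            name=f"{self.name}__reversed",
            numerator=self.denominator,
            denominator=self.numerator,
        )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the (d0, s0²) variance prior.

    Works on z = log s² whose sampling moments around log s0² are known
    digamma/trigamma expressions; returns (d0, s0²) with d0 = inf when
    the excess dispersion of z is non-positive.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return math.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(np.mean(special.polygamma(1, d / 2.0)))
    if excess <= 0:
        # no excess dispersion: the pooled variance is the MLE of the scale
        return math.inf, float(np.mean(s2[ok]))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_sq


def _log2_matrix(tbl: MolarTable) -> pd.DataFrame:
    """log2 mol% with absent/zero values floored at half the smallest
    positive mol% in the table (floor applied only to zeros)."""
    pct = tbl.molpct.fillna(0.0)
    positive = pct.to_numpy()[pct.to_numpy() > 0]
    floor = positive.min() / 2.0 if positive.size else 1.0
    return np.log2(pct.where(pct > 0, floor))


def fit_differential(
    tbl: MolarTable,
    contrast: Contrast,
    moderated: bool = True,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-species two-group fit for one contrast.

    Returns a DataFrame indexed by species with columns lipid_class,
    category, log2fc, t, p, significant, df_total, fdr.  Species absent
    from every sample on one side of the contrast are untestable and are
    excluded.  With ``moderated=False`` an ordinary pooled-variance
    two-sample t-test is used instead of the empirical-Bayes fit.
    """
    num_cols = tbl.columns_for(*contrast.numerator)
    den_cols = tbl.columns_for(*contrast.denominator)
    if len(num_cols) < 2 or len(den_cols) < 2:
        raise ValueError(
            f"contrast {contrast.name!r} needs >=2 replicates per side"
        )
    testable = (
        tbl.molpct[num_cols].notna().any(axis=1)
        & tbl.molpct[den_cols].notna().any(axis=1)
    )
    log2 = _log2_matrix(tbl).loc[testable]
    y1 = log2[num_cols].to_numpy()
    y2 = log2[den_cols].to_numpy()
    n1, n2 = y1.shape[1], y2.shape[1]
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    log2fc = m1 - m2
    rss = ((y1 - m1[:, None]) ** 2).sum(axis=1) + ((y2 - m2[:, None]) ** 2).sum(axis=1)
    df_resid = float(n1 + n2 - 2)
    s2 = rss / df_resid
    design_factor = math.sqrt(1.0 / n1 + 1.0 / n2)

    if moderated:
        d0, s0_sq = estimate_prior(s2, np.full_like(s2, df_resid))
        # the information in the moderated variance cannot exceed the
        # total residual df actually observed across species
        df_cap = df_resid * len(s2)
        if math.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.full_like(s2, df_cap)
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = np.full_like(s2, min(d0 + df_resid, df_cap))
    else:
        s2_post = s2
        df_total = np.full_like(s2, df_resid)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s2_post > 0, log2fc / (np.sqrt(s2_post) * design_factor), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    tax = tbl.taxonomy
    parsed = [tax.parse_species(sp) for sp in log2.index]
    out = pd.DataFrame(
        {
            "lipid_class": [s.lipid_class for s in parsed],
            "category": [s.category for s in parsed],
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "significant": p < alpha,
            "df_total": df_total,
        },
        index=log2.index.rename("species"),
    )
    out["fdr"] = stats.false_discovery_control(out["p"], method="bh")
    out.attrs["contrast"] = contrast.name
    return out


# ---------------------------------------------------------------------------
# class / category roll-ups


def _weighted_chain_stats(tbl: MolarTable, cols: list[str], weighted: bool = True) -> pd.DataFrame:
    """Per class: mol% (summed) and mol%-weighted mean carbons / double
    bonds per sample, averaged over the given samples."""
    tax = tbl.taxonomy
    parsed = {sp: tax.parse_species(sp) for sp in tbl.species}
    info = pd.DataFrame(
        {
            "lipid_class": {sp: s.lipid_class for sp, s in parsed.items()},
            "carbons": {sp: s.carbons for sp, s in parsed.items()},
            "double_bonds": {sp: s.double_bonds for sp, s in parsed.items()},
        }
    )
    pct = tbl.molpct[cols].fillna(0.0)
    rows = []
    for cls, members in info.groupby("lipid_class").groups.items():
        sub = pct.loc[list(members)]
        class_pct = sub.sum(axis=0)
        w = sub if weighted else (sub > 0).astype(float)
        wsum = w.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mc = (w.mul(info.loc[list(members), "carbons"], axis=0).sum(axis=0) / wsum)
            md = (w.mul(info.loc[list(members), "double_bonds"], axis=0).sum(axis=0) / wsum)
        rows.append(
            {
                "lipid_class": cls,
                "molpct_mean": float(class_pct.mean()),
                "molpct_sd": float(class_pct.std(ddof=1)),
                "mean_carbons": float(mc.mean()),
                "mean_double_bonds": float(md.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("lipid_class")


def summarize_classes(
    tbl: MolarTable,
    contrast: Contrast,
    results: pd.DataFrame | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """Class-level summary for one contrast.

    Columns: mol% mean ± sd per side, class log2 fold change of mol%,
    fold changes of the mol%-weighted mean carbon and double-bond
    counts, and the percentage of testable member species flagged
    significant (when ``results`` from :func:`fit_differential` is
    given).  Classes empty on both sides are omitted.
    """
    num_cols = tbl.columns_for(*contrast.numerator)
    den_cols = tbl.columns_for(*contrast.denominator)
    num = _weighted_chain_stats(tbl, num_cols, weighted)
    den = _weighted_chain_stats(tbl, den_cols, weighted)
    classes = num.index.union(den.index)
    rows = []
    for cls in classes:
        a = num.loc[cls] if cls in num.index else None
        b = den.loc[cls] if cls in den.index else None
        if (a is None or a["molpct_mean"] == 0) and (b is None or b["molpct_mean"] == 0):
            continue
        row = {
            "lipid_class": cls,
            "molpct_num_mean": a["molpct_mean"] if a is not None else 0.0,
            "molpct_num_sd": a["molpct_sd"] if a is not None else math.nan,
            "molpct_den_mean": b["molpct_mean"] if b is not None else 0.0,
            "molpct_den_sd": b["molpct_sd"] if b is not None else math.nan,
        }
        if row["molpct_den_mean"] > 0 and row["molpct_num_mean"] > 0:
            row["log2fc_molpct"] = math.log2(
                row["molpct_num_mean"] / row["molpct_den_mean"]
            )
        else:
            row["log2fc_molpct"] = math.nan
        for col in ("mean_carbons", "mean_double_bonds"):
            va = a[col] if a is not None else math.nan
            vb = b[col] if b is not None else math.nan
            row[f"fc_{col}"] = va / vb if vb and not math.isnan(vb) else math.nan
        if results is not None:
            members = results[results["lipid_class"] == cls]
            row["n_testable"] = len(members)
            row["pct_significant"] = (
                100.0 * members["significant"].sum() / len(members)
                if len(members)
                else math.nan
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("lipid_class")
    out.attrs["contrast"] = contrast.name
    return out


def summarize_categories(
    tbl: MolarTable,
    condition_pairs: list[tuple[tuple[str, str], tuple[str, str]]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category mol% per condition (mean ± sd over replicates) and
    unpaired two-tailed t-tests between requested condition pairs.

    Conditions are (fraction, treatment) pairs.  Per sample, category
    mol% is the sum of member-species mol%, so categories partition each
    sample's 100 mol%.
    """
    tax = tbl.taxonomy
    cats = pd.Series(
        {sp: tax.parse_species(sp).category for sp in tbl.species}
    )
    pct = tbl.molpct.fillna(0.0)
    per_sample = pct.groupby(cats).sum()  # category x sample
    types = tbl.sample_types()
    rows = []
    for cond, cols in types.groupby(types).groups.items():
        sub = per_sample[list(cols)]
        for cat in per_sample.index:
            rows.append(
                {
                    "condition": cond,
                    "category": cat,
                    "molpct_mean": float(sub.loc[cat].mean()),
                    "molpct_sd": float(sub.loc[cat].std(ddof=1)),
                    "n": sub.shape[1],
                }
            )
    summary = pd.DataFrame(rows)

    test_rows = []
    if condition_pairs:
        for (fa, ta), (fb, tbt) in condition_pairs:
            cols_a = tbl.columns_for(fa, ta)
            cols_b = tbl.columns_for(fb, tbt)
            for cat in per_sample.index:
                t, p = stats.ttest_ind(
                    per_sample.loc[cat, cols_a], per_sample.loc[cat, cols_b]
                )
                test_rows.append(
                    {
                        "category": cat,
                        "condition_a": f"{fa}:{ta}",
                        "condition_b": f"{fb}:{tbt}",
                        "t": float(t),
                        "p": float(p),
                    }
                )
    tests = pd.DataFrame(
        test_rows, columns=["category", "condition_a", "condition_b", "t", "p"]
    )
    return summary, tests


# ---------------------------------------------------------------------------
# heatmap ordering


@dataclass
class ClusterOrder:
    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def cluster_heatmap_order(matrix: pd.DataFrame) -> ClusterOrder:
    """Agglomerative clustering (Euclidean distance, complete linkage)
    of rows and columns for heatmap display.

    Non-finite entries are imputed with 0 (an absent class has no fold
    change) before distances are computed.  Leaf order is deterministic;
    fewer than 2 rows/columns yields the trivial ordering.
    """
    filled = matrix.replace([np.inf, -np.inf], np.nan).fillna(0.0)

    def order_axis(data: np.ndarray, labels) -> tuple[list, np.ndarray | None]:
        if data.shape[0] < 2:
            return list(labels), None
        z = hierarchy.linkage(data, method="complete", metric="euclidean")
        leaves = hierarchy.leaves_list(z)
        return [labels[i] for i in leaves], z

    row_order, row_z = order_axis(filled.to_numpy(), list(filled.index))
    col_order, col_z = order_axis(filled.to_numpy().T, list(filled.columns))
    return ClusterOrder(row_order, col_order, row_z, col_z)
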