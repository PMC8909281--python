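"""Purification quality metrics and identification bookkeeping.

Organelle-fractionation lipidomics needs three quantitative purity
diagnostics, all computed from paired whole-cell (WCL) and lysosomal
(LYS) fractions of the same culture:

* **lipid yield** — the percentage of total molar lipid retained in the
  organelle fraction;
* **marker enrichment** — the fold change in mol% of an
  organelle-specific marker class (BMP/PG for lysosomes; cardiolipin is
  tracked the same way as a mitochondrial *depletion* marker);
* **marker recovery** — the percentage of the marker's molar amount
  retained, interpreted as the percentage of organelles recovered when
  the marker is confined to that organelle.

Also here: the Venn identification rule (a species is "identified" in a
sample type if it is present in at least one replicate) and the
Spearman replicate-correlation diagnostic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import MolarTable


class PairingError(ValueError):
    """WCL/LYS columns could not be paired by (treatment, replicate)."""


@dataclass
class MarkerStats:
    """Per-replicate values and their mean ± sd summary."""

    values: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else float("nan")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.mean:.4g} (±{self.sd:.2g})"


def _pairs(tbl: MolarTable, treatment: str | None = None) -> list[tuple[str, str]]:
    """Paired (WCL, LYS) sample ids sharing treatment and replicate."""
    s = tbl.samples
    if treatment is not None:
        s = s[s["treatment"] == treatment]
    wcl = s[s["fraction"] == "WCL"]
    lys = s[s["fraction"] == "LYS"]
    pairs = []
    for sid, row in wcl.iterrows():
        match = lys[
            (lys["treatment"] == row["treatment"])
            & (lys["replicate"] == row["replicate"])
        ]
        if len(match) == 1:
            pairs.append((sid, match.index[0]))
    if not pairs:
        raise PairingError(
            "no (treatment, replicate)-paired WCL/LYS samples found"
        )
    return pairs


def lipid_yield(
    tbl: MolarTable,
    treatment: str | None = None,
    aliquot_factors: tuple[float, float] = (1.0, 1.0),
) -> MarkerStats:
    """Per-pair total-lipid yield: 100 x (LYS total / WCL total).

    ``aliquot_factors`` scale the analysed WCL and LYS aliquots to full
    samples; a common rescaling of both leaves the yield unchanged.
    """
    f_wcl, f_lys = aliquot_factors
    if f_wcl <= 0 or f_lys <= 0:
        raise ValueError("aliquot factors must be positive")
    vals = []
    for wcl_col, lys_col in _pairs(tbl, treatment):
        wcl_total = tbl.molar[wcl_col].sum(skipna=True) * f_wcl
        lys_total = tbl.molar[lys_col].sum(skipna=True) * f_lys
        if wcl_total <= 0:
            raise ZeroDivisionError(f"WCL sample {wcl_col!r} has zero total lipid")
        vals.append(100.0 * lys_total / wcl_total)
    return MarkerStats(vals)


def _class_mask(tbl: MolarTable, marker_class: str) -> pd.Index:
    tax = tbl.taxonomy
    cls = tax.resolve(marker_class)
    members = [
        sp for sp in tbl.species if tax.parse_species(sp).lipid_class == cls
    ]
    return pd.Index(members)


def class_molpct(tbl: MolarTable, marker_class: str) -> pd.Series:
    """Summed mol% of one class per sample (absent species count 0)."""
    members = _class_mask(tbl, marker_class)
    return tbl.molpct.loc[members].fillna(0.0).sum(axis=0)


def marker_enrichment(
    tbl: MolarTable, marker_class: str, treatment: str | None = None
) -> MarkerStats:
    """Per-pair fold change of marker mol%: LYS / WCL.

    A marker absent from the WCL of a pair yields ``inf`` for that pair
    (flagged, not an error); absent from LYS yields 0 (depletion limit).
    """
    pct = class_molpct(tbl, marker_class)
    vals = []
    for wcl_col, lys_col in _pairs(tbl, treatment):
        w, l = pct[wcl_col], pct[lys_col]
        vals.append(float("inf") if w == 0 and l > 0 else (l / w if w > 0 else 0.0))
    return MarkerStats(vals)


def marker_recovery(
    tbl: MolarTable,
    marker_class: str,
    treatment: str | None = None,
    aliquot_factors: tuple[float, float] = (1.0, 1.0),
) -> MarkerStats:
    """Per-pair marker molar recovery: 100 x (LYS marker pmol / WCL marker pmol).

    With a marker confined to the purified organelle this estimates the
    percentage of organelles recovered by the purification.
    """
    f_wcl, f_lys = aliquot_factors
    if f_wcl <= 0 or f_lys <= 0:
        raise ValueError("aliquot factors must be positive")
    members = _class_mask(tbl, marker_class)
    molar = tbl.molar.loc[members].fillna(0.0).sum(axis=0)
    vals = []
    for wcl_col, lys_col in _pairs(tbl, treatment):
        w = molar[wcl_col] * f_wcl
        l = molar[lys_col] * f_lys
        if w <= 0:
            raise ZeroDivisionError(
                f"marker {marker_class!r} absent from WCL sample {wcl_col!r}"
            )
        vals.append(100.0 * l / w)
    return MarkerStats(vals)


# ---------------------------------------------------------------------------
# identification bookkeeping


def identification_status(tbl: MolarTable) -> pd.DataFrame:
    """Species x sample-type boolean table.

    A species counts as identified in a sample type (fraction x
    treatment) if it is present in at least one replicate of that type.
    """
    types = tbl.sample_types()
    out = {}
    for t, cols in types.groupby(types).groups.items():
        out[t] = tbl.molar[list(cols)].notna().any(axis=1)
    return pd.DataFrame(out)


def venn_sets(status: pd.DataFrame, set_names: list[str]) -> dict[tuple[str, ...], set[str]]:
    """Exclusive Venn regions over 2 or 3 identification sets.

    Keys are tuples of the member set names for the region (e.g.
    ``("A",)`` = only in A; ``("A", "B")`` = in A and B but not others).
    Region counts sum to the size of the union.
    """
    if not 2 <= len(set_names) <= 3:
        raise ValueError("venn_sets supports 2 or 3 sets")
    missing = [s for s in set_names if s not in status.columns]
    if missing:
        raise KeyError(f"unknown sample types: {missing}")
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(set_names) + 1):
        for combo in itertools.combinations(set_names, r):
            inside = status[list(combo)].all(axis=1)
            outside = ~status[[s for s in set_names if s not in combo]].any(axis=1) \
                if len(combo) < len(set_names) else pd.Series(True, index=status.index)
            regions[combo] = set(status.index[inside & outside])
    return regions


def venn_counts(status: pd.DataFrame, set_names: list[str]) -> dict[tuple[str, ...], int]:
    return {k: len(v) for k, v in venn_sets(status, set_names).items()}


# ---------------------------------------------------------------------------
# replicate correlation


@dataclass
class CorrelationReport:
    within: pd.DataFrame  # columns: sample_a, sample_b, rho
    mixed: pd.DataFrame
    t_stat: float
    p_value: float

    @property
    def mean_within(self) -> float:
        return float(self.within["rho"].mean())

    @property
    def mean_mixed(self) -> float:
        return float(self.mixed["rho"].mean())


def replicate_correlation(tbl: MolarTable) -> CorrelationReport:
    """Spearman correlations for all sample pairs, split into
    within-condition ("replica") and between-condition ("mixed") pairs,
    with an unpaired two-tailed t-test comparing the two groups' means.

    Each pair's coefficient is computed over the species present in
    both samples; pairs sharing fewer than 3 species are an error.
    """
    types = tbl.sample_types()
    cols = list(tbl.molpct.columns)
    within_rows, mixed_rows = [], []
    for a, b in itertools.combinations(cols, 2):
        shared = tbl.molpct[[a, b]].dropna()
        if len(shared) < 3:
            raise ValueError(
                f"samples {a!r} and {b!r} share fewer than 3 species; "
                "Spearman correlation undefined"
            )
        rho = stats.spearmanr(shared[a], shared[b]).statistic
        row = {"sample_a": a, "sample_b": b, "rho": float(rho)}
        (within_rows if types[a] == types[b] else mixed_rows).append(row)
    within = pd.DataFrame(within_rows)
    mixed = pd.DataFrame(mixed_rows)
    if len(within) >= 2 and len(mixed) >= 2:
        t, p = stats.ttest_ind(within["rho"], mixed["rho"])
        t, p = float(t), float(p)
    else:
        t, p = math.nan, math.nan
    return CorrelationReport(within=within, mixed=mixed, t_stat=t, p_value=p)


def purity_report(
    tbl: MolarTable,
    marker_classes: list[str] = ("BMP/PG",),
    depletion_classes: list[str] = ("CL",),
    aliquot_factors: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """One-row-per-metric purity summary across all paired replicates."""
    rows = []
    y = lipid_yield(tbl, aliquot_factors=aliquot_factors)
    rows.append({"metric": "lipid_yield_pct", "class": "total",
                 "mean": y.mean, "sd": y.sd, "n": len(y.values)})
    for role, classes in (("marker", marker_classes), ("depletion", depletion_classes)):
        for cls in classes:
            pct = class_molpct(tbl, cls)
            s = tbl.samples
            for fraction in ("WCL", "LYS"):
                v = pct[s.index[s["fraction"] == fraction]]
                rows.append({"metric": f"{role}_molpct_{fraction}", "class": cls,
                             "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                             "n": len(v)})
            e = marker_enrichment(tbl, cls)
            rows.append({"metric": f"{role}_enrichment_fold", "class": cls,
                         "mean": e.mean, "sd": e.sd, "n": len(e.values)})
            r = marker_recovery(tbl, cls, aliquot_factors=aliquot_factors)
            rows.append({"metric": f"{role}_recovery_pct", "class": cls,
                         "mean": r.mean, "sd": r.sd, "n": len(r.values)})
    return pd.DataFrame(rows)
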