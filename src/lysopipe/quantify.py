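"""Internal-standard absolute quantification and mol% normalisation.

The quantification model is the single-standard ratio used throughout
direct-infusion shotgun lipidomics: each lipid class belongs to an
internal-standard group whose standard is spiked at a known amount
(pmol) into every sample, and

    molar(species, sample) = intensity(species, sample)
                             / standard_intensity(group, sample)
                             * standard_amount(group)          [pmol]

Molar quantities are then expressed as mol% of the summed molar quantity
of all identified species in the sample, and species are retained only
if their median mol% across the replicates of at least one sample type
(fraction x treatment) is strictly above a detection-relevance threshold
(default 0.0001 mol%).

Absent measurements ("not identified") are distinguished from measured
zeros and propagate as NaN; identification bookkeeping downstream
depends on this distinction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import Taxonomy

FRACTIONS = ("WCL", "LYS")
TREATMENTS = ("untreated", "synchronized", "released")

DEFAULT_FILTER_THRESHOLD = 1e-4  # mol%


class QuantificationError(ValueError):
    """Missing or non-positive internal-standard intensity."""


class NormalizationError(ValueError):
    """A sample has no quantifiable species."""


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample sheet: index sample_id, columns fraction/treatment/replicate."""
    required = {"fraction", "treatment", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if samples.index.has_duplicates:
        raise ValueError("duplicate sample_id in sample sheet")
    key = samples[["fraction", "treatment", "replicate"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValueError(
            "duplicate (fraction, treatment, replicate): "
            f"{tuple(dup)}"
        )
    return samples


@dataclass
class IntensityTable:
    """Identified-species ion intensities plus internal-standard data.

    intensities : DataFrame, species x samples, NaN = not identified.
    standard_intensities : DataFrame, standard group x samples.
    standard_amounts : Series, standard group -> spiked pmol.
    samples : DataFrame indexed by sample_id with fraction/treatment/replicate.
    """

    intensities: pd.DataFrame
    standard_intensities: pd.DataFrame
    standard_amounts: pd.Series
    samples: pd.DataFrame
    taxonomy: Taxonomy

    def __post_init__(self) -> None:
        validate_samples(self.samples)
        if list(self.intensities.columns) != list(self.samples.index):
            self.intensities = self.intensities[list(self.samples.index)]
        for sp in self.intensities.index:
            cls = sp.rsplit(" ", 1)[0] if " " in sp else sp
            group = self.taxonomy.standard_group_of(
                self.taxonomy.parse_species(sp).lipid_class
            )
            if group not in self.standard_intensities.index:
                raise QuantificationError(
                    f"species {sp!r} (class {cls!r}): no standard intensities "
                    f"for group {group!r}"
                )
            if group not in self.standard_amounts.index:
                raise QuantificationError(
                    f"standard group {group!r}: no spiked amount"
                )

    @property
    def species(self) -> list[str]:
        return list(self.intensities.index)


@dataclass
class MolarTable:
    """Absolute molar quantities (pmol) and mol%-of-total views.

    ``molar`` and ``molpct`` share one absence (NaN) pattern; every
    present mol% column sums to 100.
    """

    molar: pd.DataFrame
    molpct: pd.DataFrame
    samples: pd.DataFrame
    taxonomy: Taxonomy

    @property
    def species(self) -> list[str]:
        return list(self.molar.index)

    def sample_types(self) -> pd.Series:
        """(fraction, treatment) label per sample."""
        return self.samples["fraction"] + ":" + self.samples["treatment"]

    def columns_for(self, fraction: str, treatment: str) -> list[str]:
        m = (self.samples["fraction"] == fraction) & (
            self.samples["treatment"] == treatment
        )
        return list(self.samples.index[m])


def to_molar(tbl: IntensityTable) -> MolarTable:
    """Absolute quantification via the internal-standard intensity ratio."""
    std = tbl.standard_intensities
    bad = ~(std > 0) | std.isna()
    if bad.to_numpy().any():
        group = bad.any(axis=1).idxmax()
        sample = bad.loc[group][bad.loc[group]].index[0]
        raise QuantificationError(
            f"standard intensity for group {group!r} in sample {sample!r} "
            "is missing or non-positive"
        )
    groups = pd.Index(
        [
            tbl.taxonomy.standard_group_of(
                tbl.taxonomy.parse_species(sp).lipid_class
            )
            for sp in tbl.intensities.index
        ]
    )
    per_species_std = std.loc[groups].set_axis(tbl.intensities.index)
    amounts = tbl.standard_amounts.loc[groups].set_axis(tbl.intensities.index)
    molar = tbl.intensities.div(per_species_std).mul(amounts, axis=0)
    out = MolarTable(
        molar=molar,
        molpct=pd.DataFrame(
            np.nan, index=molar.index, columns=molar.columns
        ),
        samples=tbl.samples,
        taxonomy=tbl.taxonomy,
    )
    return to_molpct(out)


def to_molpct(tbl: MolarTable) -> MolarTable:
    """Fill the mol%-of-total view from the molar view."""
    totals = tbl.molar.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        sample = totals.index[(totals <= 0).argmax()]
        raise NormalizationError(
            f"sample {sample!r}: total molar quantity is not positive"
        )
    molpct = 100.0 * tbl.molar.div(totals, axis=1)
    return replace(tbl, molpct=molpct)


def filter_species(
    tbl: MolarTable,
    threshold: float = DEFAULT_FILTER_THRESHOLD,
) -> tuple[list[str], MolarTable]:
    """Apply the per-sample-type median inclusion filter.

    A species is retained iff, for at least one sample type
    (fraction x treatment group), the median of its mol% across that
    type's replicates is strictly greater than ``threshold``.  Absent
    values count as 0 in the median, so a species seen in a minority of
    replicates does not pass on one detection.  Medians are computed on
    the pre-filter mol% values; re-normalisation over the retained
    species happens once at the end, which makes the rule idempotent.
    """
    if threshold < 0:
        raise ValueError("filter threshold must be nonnegative")
    molpct0 = tbl.molpct.fillna(0.0)
    types = tbl.sample_types()
    retained_mask = pd.Series(False, index=tbl.molpct.index)
    for _, cols in types.groupby(types).groups.items():
        medians = molpct0[list(cols)].median(axis=1)
        retained_mask |= medians > threshold
    retained = list(tbl.molpct.index[retained_mask])
    filtered = MolarTable(
        molar=tbl.molar.loc[retained],
        molpct=tbl.molpct.loc[retained],
        samples=tbl.samples,
        taxonomy=tbl.taxonomy,
    )
    return retained, to_molpct(filtered)


# ---------------------------------------------------------------------------
# long-format TSV I/O

def read_intensity_tables(
    intensities_path: str | Path,
    standards_path: str | Path,
    samples_path: str | Path,
    taxonomy: Taxonomy | None = None,
) -> IntensityTable:
    """Assemble an IntensityTable from the three long-format TSV inputs.

    intensities: species, sample_id, intensity
    standards:   group, sample_id, intensity, amount_pmol
    samples:     sample_id, fraction, treatment, replicate
    """
    taxonomy = taxonomy or Taxonomy.default()
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    samples = samples.set_index("sample_id")
    long = pd.read_csv(intensities_path, sep="\t", dtype={"sample_id": str})
    wide = long.pivot(index="species", columns="sample_id", values="intensity")
    wide = wide.reindex(columns=samples.index)
    stds = pd.read_csv(standards_path, sep="\t", dtype={"sample_id": str})
    std_wide = stds.pivot(index="group", columns="sample_id", values="intensity")
    std_wide = std_wide.reindex(columns=samples.index)
    amounts = stds.groupby("group")["amount_pmol"].first()
    return IntensityTable(
        intensities=wide,
        standard_intensities=std_wide,
        standard_amounts=amounts,
        samples=samples,
        taxonomy=taxonomy,
    )


def write_molar_table(tbl: MolarTable, path: str | Path) -> None:
    """Write molar + mol% values as one long-format TSV."""
    long = (
        tbl.molar.rename_axis("species")
        .reset_index()
        .melt(id_vars="species", var_name="sample_id", value_name="molar_pmol")
    )
    pct = (
        tbl.molpct.rename_axis("species")
        .reset_index()
        .melt(id_vars="species", var_name="sample_id", value_name="molpct")
    )
    long["molpct"] = pct["molpct"]
    long = long.dropna(subset=["molar_pmol"])
    long.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_molar_table(
    path: str | Path,
    samples_path: str | Path,
    taxonomy: Taxonomy | None = None,
) -> MolarTable:
    taxonomy = taxonomy or Taxonomy.default()
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    samples = samples.set_index("sample_id")
    long = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    molar = long.pivot(index="species", columns="sample_id", values="molar_pmol")
    molar = molar.reindex(columns=samples.index)
    tbl = MolarTable(
        molar=molar,
        molpct=pd.DataFrame(np.nan, index=molar.index, columns=molar.columns),
        samples=samples,
        taxonomy=taxonomy,
    )
    return to_molpct(tbl)
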