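"""Synthetic data with known ground truth for every pipeline stage.

Three generators are provided:

* :func:`simulate_lipidomics` — identified-species intensity tables for
  whole-cell (WCL) and lysosomal (LYS) fractions across three treatments
  (untreated, synchronized, released) with replicates, internal-standard
  intensities, multiplicative log-normal measurement noise and a
  detection limit.  Ground-truth molar quantities and planted per-species
  log2 effects are returned alongside.
* :func:`simulate_cells` — per-cell image-cytometry features (mean
  Hoechst, total Hoechst, total phospho-histone-H3) for four cell-cycle
  populations with known labels.
* :func:`simulate_vesicle_images` — two-channel vesicle images (soft
  discs on a noisy background) with ground-truth masks, areas, and
  pH-dependent FITC/TMR channel ratios through a monotone calibration.

The default parameter sets are the package's fixed study conditions
(documented in docs/methods.md): marker-class abundances anchored on
reported lysosome-purification values, treatment effects on sphingolipid
and lyso-glycerophospholipid classes in released-cell lysosomes, CV 0.2
log-normal noise, and three replicates per condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .quantify import FRACTIONS, TREATMENTS, IntensityTable, MolarTable, to_molpct
from .taxonomy import Taxonomy


class SpecValidationError(ValueError):
    """A simulation spec violates its invariants."""


class PlacementError(RuntimeError):
    """Vesicles could not be placed without overlap at the requested density."""


# ---------------------------------------------------------------------------
# lipidomics


@dataclass
class LipidomeSpec:
    """Ground-truth description of a two-fraction, three-treatment lipidome.

    class_profiles : per fraction, baseline class mol% (normalised to 100).
    templates : per class (optionally per (fraction, class)), list of
        (carbons, double_bonds, weight) species templates; weights are
        relative within the class.
    effects : (fraction, treatment) -> {class or species name: true log2
        fold change} applied multiplicatively to source weights before
        renormalisation, so mol% remains compositional.
    total_molar : analysed molar amount per fraction (pmol).
    cv : coefficient of variation of the multiplicative log-normal
        measurement noise (mean-1 parameterisation).
    detection_limit : intensity floor; noisy intensities below it are
        reported absent.
    spike_amounts / response_factors : per internal-standard group.
    """

    class_profiles: dict[str, dict[str, float]]
    templates: dict[object, list[tuple[int, int, float]]]
    effects: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    treatments: tuple[str, ...] = TREATMENTS
    replicates: int = 3
    cv: float = 0.2
    total_molar: dict[str, float] = field(
        default_factory=lambda: {"WCL": 1000.0, "LYS": 13.3}
    )
    detection_limit: float = 5.0
    spike_amounts: dict[str, float] = field(default_factory=dict)
    response_factors: dict[str, float] = field(default_factory=dict)
    taxonomy: Taxonomy = field(default_factory=Taxonomy.default)

    def validate(self) -> None:
        problems: list[str] = []
        if self.cv < 0:
            problems.append("cv must be >= 0")
        if self.replicates < 1:
            problems.append("replicates must be >= 1")
        if self.detection_limit < 0:
            problems.append("detection_limit must be >= 0")
        for fraction, profile in self.class_profiles.items():
            total = sum(profile.values())
            if abs(total - 100.0) > 1e-9:
                problems.append(
                    f"{fraction} class profile sums to {total!r}, not 100"
                )
            for cls in profile:
                self.taxonomy.resolve(cls)
        for group, amt in self.spike_amounts.items():
            if not amt > 0:
                problems.append(f"spike amount for {group!r} must be > 0")
        for group, rf in self.response_factors.items():
            if not rf > 0:
                problems.append(f"response factor for {group!r} must be > 0")
        if problems:
            raise SpecValidationError("; ".join(problems))

    def template_for(self, fraction: str, cls: str) -> list[tuple[int, int, float]]:
        return self.templates.get((fraction, cls), self.templates[cls])


def _species_table(spec: LipidomeSpec) -> pd.DataFrame:
    """Union of species over fractions with per-fraction within-class weights."""
    rows = []
    for cls in spec.class_profiles["WCL"]:
        per_fraction = {}
        for fraction in FRACTIONS:
            tmpl = spec.template_for(fraction, cls)
            total_w = sum(w for _, _, w in tmpl)
            per_fraction[fraction] = {
                (c, d): w / total_w for c, d, w in tmpl
            }
        keys = sorted(set(per_fraction["WCL"]) | set(per_fraction["LYS"]))
        for c, d in keys:
            name = spec.taxonomy.format_name(cls, c, d)
            rows.append(
                {
                    "species": name,
                    "lipid_class": cls,
                    "carbons": c,
                    "double_bonds": d,
                    "w_WCL": per_fraction["WCL"].get((c, d), 0.0),
                    "w_LYS": per_fraction["LYS"].get((c, d), 0.0),
                }
            )
    return pd.DataFrame(rows).set_index("species")


def _expand_effects(
    spec: LipidomeSpec, species: pd.DataFrame
) -> pd.DataFrame:
    """Per-species true log2 fold changes, long format."""
    rows = []
    for (fraction, treatment), eff in spec.effects.items():
        for key, lfc in eff.items():
            if key in species.index:
                members = [key]
            else:
                cls = spec.taxonomy.resolve(key)
                members = list(species.index[species["lipid_class"] == cls])
            for name in members:
                rows.append(
                    {
                        "species": name,
                        "fraction": fraction,
                        "treatment": treatment,
                        "log2fc": lfc,
                    }
                )
    return pd.DataFrame(rows, columns=["species", "fraction", "treatment", "log2fc"])


def simulate_lipidomics(
    spec: LipidomeSpec, seed: int
) -> tuple[IntensityTable, MolarTable, pd.DataFrame]:
    """Draw one complete lipidomics experiment from the spec.

    Returns the noisy :class:`IntensityTable` (with internal-standard
    intensities), the noise-free ground-truth :class:`MolarTable`, and
    the expanded per-species true-effect table.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    tax = spec.taxonomy
    species = _species_table(spec)
    effects = _expand_effects(spec, species)

    sample_rows = []
    for fraction in FRACTIONS:
        for treatment in spec.treatments:
            for rep in range(1, spec.replicates + 1):
                sample_rows.append(
                    {
                        "sample_id": f"{fraction}_{treatment}_r{rep}",
                        "fraction": fraction,
                        "treatment": treatment,
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    # true molar quantity per species per sample (condition-level truth,
    # identical across replicates)
    classes = species["lipid_class"]
    true_molar = pd.DataFrame(
        0.0, index=species.index, columns=samples.index
    )
    for fraction in FRACTIONS:
        profile = spec.class_profiles[fraction]
        base_w = species[f"w_{fraction}"] * classes.map(profile)
        for treatment in spec.treatments:
            w = base_w.copy()
            eff = spec.effects.get((fraction, treatment), {})
            if eff:
                sub = effects[
                    (effects["fraction"] == fraction)
                    & (effects["treatment"] == treatment)
                ]
                mult = pd.Series(1.0, index=species.index)
                mult.loc[sub["species"].to_numpy()] = np.exp2(
                    sub["log2fc"].to_numpy()
                )
                w = w * mult
            frac_of_total = w / w.sum()
            molar = spec.total_molar[fraction] * frac_of_total
            for rep in range(1, spec.replicates + 1):
                true_molar[f"{fraction}_{treatment}_r{rep}"] = molar

    groups = classes.map(lambda c: tax.standard_group_of(c))
    all_groups = sorted(set(groups))
    spikes = pd.Series(
        {g: spec.spike_amounts.get(g, 25.0) for g in all_groups}
    )
    rfs = pd.Series(
        {g: spec.response_factors.get(g, 1000.0) for g in all_groups}
    )

    # multiplicative log-normal noise with mean 1 and CV = spec.cv
    sigma2 = math.log1p(spec.cv**2)
    sigma = math.sqrt(sigma2)

    def noise(shape):
        if spec.cv == 0:
            return np.ones(shape)
        return np.exp(rng.normal(-sigma2 / 2.0, sigma, size=shape))

    species_rf = rfs.loc[groups].set_axis(species.index)
    intensities = (
        true_molar.mul(species_rf, axis=0)
        * noise(true_molar.shape)
    )
    intensities = intensities.where(intensities >= spec.detection_limit)

    std_true = np.outer(spikes.to_numpy() * rfs.to_numpy(), np.ones(len(samples)))
    standard_intensities = pd.DataFrame(
        std_true * noise(std_true.shape),
        index=pd.Index(all_groups, name="group"),
        columns=samples.index,
    )

    tbl = IntensityTable(
        intensities=intensities,
        standard_intensities=standard_intensities,
        standard_amounts=spikes,
        samples=samples,
        taxonomy=tax,
    )
    truth = to_molpct(
        MolarTable(
            molar=true_molar,
            molpct=pd.DataFrame(
                np.nan, index=true_molar.index, columns=true_molar.columns
            ),
            samples=samples,
            taxonomy=tax,
        )
    )
    return tbl, truth, effects


# -- default study conditions ------------------------------------------------

def _gauss_template(
    c_values, d_values, c_mode, d_mode, c_sigma, d_sigma, keep
):
    combos = [
        (c, d, math.exp(
            -0.5 * ((c - c_mode) / c_sigma) ** 2
            - 0.5 * ((d - d_mode) / d_sigma) ** 2
        ))
        for c in c_values
        for d in d_values
        if d <= c  # species invariant
    ]
    combos.sort(key=lambda t: (-t[2], t[0], t[1]))
    kept = sorted(combos[:keep])
    return [(c, d, w) for c, d, w in kept]


# Baseline class mol% profiles.  Marker classes are anchored on reported
# lysosome-purification values: BMP/PG 0.156 mol% (WCL) vs 2.27 mol%
# (LYS); cardiolipin 3.5 mol% (WCL) vs nearly absent (LYS); LYS/WCL
# total-molar ratio 1.33%.  Remaining classes follow typical cultured
# mammalian-cell and lysosome compositions (profiles renormalised to 100).
_WCL_PROFILE = {
    "PC": 35.0, "PE": 12.0, "PC O-": 3.0, "PE O-": 4.0, "PS": 5.0,
    "PI": 7.0, "PA": 1.0, "BMP/PG": 0.156, "CL": 3.5,
    "SM": 6.0, "Cer": 0.8, "HexCer": 0.5, "Hex2Cer": 0.2, "GM3": 0.3,
    "SHexCer": 0.1, "DAG": 1.5, "TAG": 4.0, "Chol": 12.0, "CE": 1.5,
    "FA": 0.5, "LPC": 0.6, "LPC O-": 0.1, "LPE": 0.3, "LPE O-": 0.05,
    "LPS": 0.05, "LPG": 0.02, "LPI": 0.08, "LPA": 0.03,
}
_LYS_PROFILE = {
    "PC": 25.0, "PE": 9.0, "PC O-": 3.5, "PE O-": 4.5, "PS": 7.0,
    "PI": 5.0, "PA": 0.8, "BMP/PG": 2.27, "CL": 0.02,
    "SM": 12.0, "Cer": 1.5, "HexCer": 1.5, "Hex2Cer": 0.5, "GM3": 0.8,
    "SHexCer": 0.3, "DAG": 1.2, "TAG": 2.5, "Chol": 17.0, "CE": 1.0,
    "FA": 0.6, "LPC": 1.8, "LPC O-": 0.3, "LPE": 1.0, "LPE O-": 0.15,
    "LPS": 0.2, "LPG": 0.1, "LPI": 0.3, "LPA": 0.1,
}


def _normalise(profile: dict[str, float]) -> dict[str, float]:
    total = sum(profile.values())
    return {k: 100.0 * v / total for k, v in profile.items()}


def _default_templates() -> dict[object, list[tuple[int, int, float]]]:
    even = lambda lo, hi: list(range(lo, hi + 1, 2))
    t: dict[object, list[tuple[int, int, float]]] = {}
    for cls in ("PC", "PE", "PA"):
        t[cls] = _gauss_template(even(30, 40), range(7), 34, 1.5, 2.5, 1.5, 20)
    for cls in ("PS", "PI"):
        t[cls] = _gauss_template(even(32, 42), range(7), 36, 3, 2.5, 1.5, 20)
    for cls in ("PC O-", "PE O-"):
        t[cls] = _gauss_template(even(30, 40), range(7), 34, 2, 2.5, 1.5, 14)
    for cls in ("LPC", "LPC O-", "LPE", "LPE O-", "LPS", "LPG", "LPI", "LPA"):
        t[cls] = _gauss_template(even(16, 22), range(7), 18, 1, 1.5, 1.2, 10)
    t["SM"] = _gauss_template(even(32, 44), (1, 2, 3), 40, 1.2, 3.0, 0.8, 10)
    for cls in ("Cer", "HexCer"):
        t[cls] = _gauss_template(even(32, 44), (1, 2, 3), 40, 1.2, 3.0, 0.8, 8)
    for cls in ("Hex2Cer", "SHexCer", "GM3"):
        t[cls] = _gauss_template(even(34, 42), (1, 2), 40, 1.2, 3.0, 0.8, 6)
    t["CL"] = _gauss_template(even(66, 74), range(2, 10), 70, 5, 2.0, 1.5, 8)
    t["DAG"] = _gauss_template(even(30, 38), range(5), 34, 1.5, 2.0, 1.2, 8)
    t["TAG"] = _gauss_template(even(46, 58), range(8), 52, 3, 3.0, 1.8, 10)
    t["FA"] = _gauss_template(even(14, 24), range(7), 18, 1.2, 2.0, 1.2, 8)
    t["CE"] = _gauss_template(even(14, 24), range(7), 18, 1.2, 2.0, 1.2, 8)
    t["Chol"] = [(27, 1, 1.0)]
    # BMP/PG: whole-cell signal is dominated by monounsaturated (PG-like)
    # species; the lysosomal pool is dominated by polyunsaturated (BMP-like)
    # species, a subset of which sit below the detection limit in WCL.
    t["BMP/PG"] = [
        (34, 1, 0.35), (34, 2, 0.20), (36, 1, 0.15), (36, 2, 0.20),
        (36, 4, 0.02), (38, 5, 0.015), (40, 7, 0.004), (42, 9, 0.003),
        (44, 8, 0.003), (44, 10, 0.002), (44, 12, 0.001), (42, 10, 0.002),
    ]
    t[("LYS", "BMP/PG")] = [
        (34, 1, 0.05), (34, 2, 0.03), (36, 1, 0.02), (36, 2, 0.02),
        (36, 4, 0.07), (38, 5, 0.08), (40, 7, 0.10), (42, 9, 0.10),
        (44, 8, 0.20), (44, 10, 0.25), (44, 12, 0.10), (42, 10, 0.08),
    ]
    return t


def default_lipidome_spec(
    cv: float = 0.2, replicates: int = 3, taxonomy: Taxonomy | None = None
) -> LipidomeSpec:
    """The package's fixed lipidomics study conditions.

    Released-cell lysosomes carry the planted treatment effects:
    sphingomyelin +1, hexosylceramide +0.7 and phosphatidylcholine −0.5
    log2 units, and +0.4 on every lyso-glycerophospholipid class; the
    untreated and synchronized conditions are effect-free.
    """
    taxonomy = taxonomy or Taxonomy.default()
    lyso_classes = [
        c for c, i in taxonomy.entries.items() if i.category == "lysoGPL"
    ]
    effects = {
        ("LYS", "released"): {
            "SM": 1.0,
            "HexCer": 0.7,
            "PC": -0.5,
            **{c: 0.4 for c in lyso_classes},
        },
        ("WCL", "released"): {"SM": 0.3, "HexCer": 0.2},
    }
    return LipidomeSpec(
        class_profiles={
            "WCL": _normalise(_WCL_PROFILE),
            "LYS": _normalise(_LYS_PROFILE),
        },
        templates=_default_templates(),
        effects=effects,
        replicates=replicates,
        cv=cv,
        taxonomy=taxonomy,
    )


def null_lipidome_spec(cv: float = 0.2, replicates: int = 3) -> LipidomeSpec:
    """Same conditions but with no treatment effects anywhere (null model)."""
    spec = default_lipidome_spec(cv=cv, replicates=replicates)
    return replace(spec, effects={})


def capture_spec(capture_fraction: float) -> LipidomeSpec:
    """Study conditions for the recovery estimator: the lysosomal marker
    is conserved between fractions and the LYS fraction captures exactly
    ``capture_fraction`` of the cell's lysosome pool, so the
    marker-recovery estimate should equal 100 x capture_fraction.

    The detection limit is disabled in this scenario: recovery is
    unbiased only when every marker species is measured, and left-
    censoring of faint species at small capture fractions would test the
    censoring, not the estimator.
    """
    if not 0 < capture_fraction <= 1:
        raise SpecValidationError("capture fraction must be in (0, 1]")
    spec = replace(default_lipidome_spec(), detection_limit=0.0)
    wcl_marker = spec.class_profiles["WCL"]["BMP/PG"] / 100.0
    lys_marker = spec.class_profiles["LYS"]["BMP/PG"] / 100.0
    lysosome_pool = spec.total_molar["WCL"] * wcl_marker / lys_marker
    total = dict(spec.total_molar)
    total["LYS"] = capture_fraction * lysosome_pool
    return replace(spec, total_molar=total)


# ---------------------------------------------------------------------------
# image cytometry

POPULATIONS = (
    "interphase",
    "ph3_interphase_prophase",
    "mitotic",
    "ph3neg_mitotic_apoptotic",
)


@dataclass
class CellPopulationSpec:
    """Per-condition cell counts and population mixture for gating data.

    Feature distributions are log10-normal per population; the
    interphase total-Hoechst distribution is a G1/S/G2 cell-cycle
    mixture with the G2 mode at twice the G1 DNA content.
    """

    n_cells: dict[str, int]
    mitotic_fraction: dict[str, float]
    ph3_interphase_fraction: dict[str, float]
    ph3neg_mitotic_fraction: dict[str, float]
    # (log10 mean, log10 sd) per population for the two gating axes
    mean_hoechst: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "interphase": (2.0, 0.10),
            "ph3_interphase_prophase": (2.0, 0.10),
            "mitotic": (2.6, 0.08),
            "ph3neg_mitotic_apoptotic": (2.6, 0.08),
        }
    )
    total_ph3: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "interphase": (1.0, 0.15),
            "ph3_interphase_prophase": (2.5, 0.15),
            "mitotic": (2.5, 0.15),
            "ph3neg_mitotic_apoptotic": (1.0, 0.15),
        }
    )
    total_hoechst_g1: tuple[float, float] = (3.0, 0.05)
    # per-condition (G1, S, G2) shares of the interphase population
    cycle_shares: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )

    def validate(self) -> None:
        problems = []
        for cond, n in self.n_cells.items():
            if n < 1:
                problems.append(f"{cond}: n_cells must be >= 1")
            fsum = (
                self.mitotic_fraction.get(cond, 0.0)
                + self.ph3_interphase_fraction.get(cond, 0.0)
                + self.ph3neg_mitotic_fraction.get(cond, 0.0)
            )
            for name, frac in (
                ("mitotic", self.mitotic_fraction.get(cond, 0.0)),
                ("ph3_interphase", self.ph3_interphase_fraction.get(cond, 0.0)),
                ("ph3neg_mitotic", self.ph3neg_mitotic_fraction.get(cond, 0.0)),
            ):
                if not 0 <= frac <= 1:
                    problems.append(f"{cond}: {name} fraction outside [0,1]")
            if fsum > 1:
                problems.append(f"{cond}: population fractions sum above 1")
        for dist in (self.mean_hoechst, self.total_ph3):
            for pop, (_, sd) in dist.items():
                if not math.isfinite(sd) or sd < 0:
                    problems.append(f"{pop}: scale parameter must be finite >= 0")
        if problems:
            raise SpecValidationError("; ".join(problems))


def default_cell_spec(n_cells: int = 2000) -> CellPopulationSpec:
    """Fixed cytometry study conditions: untreated / synchronized /
    released adherent populations plus a shake-off-enriched released
    population, with mitotic shares 1.3%, 2.6%, 15.4% and 69%."""
    conditions = ["untreated", "synchronized", "released", "released_shakeoff"]
    return CellPopulationSpec(
        n_cells={c: n_cells for c in conditions},
        mitotic_fraction={
            "untreated": 0.013,
            "synchronized": 0.026,
            "released": 0.154,
            "released_shakeoff": 0.69,
        },
        ph3_interphase_fraction={
            "untreated": 0.02,
            "synchronized": 0.03,
            "released": 0.04,
            "released_shakeoff": 0.05,
        },
        ph3neg_mitotic_fraction={
            "untreated": 0.01,
            "synchronized": 0.01,
            "released": 0.015,
            "released_shakeoff": 0.03,
        },
        cycle_shares={
            "untreated": (0.60, 0.20, 0.20),
            "synchronized": (0.10, 0.10, 0.80),
            "released": (0.10, 0.10, 0.80),
            "released_shakeoff": (0.10, 0.10, 0.80),
        },
    )


def simulate_cells(
    spec: CellPopulationSpec, seed: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw per-cell features; returns (cells, true_labels).

    ``cells`` has columns cell_id, condition, mean_hoechst,
    total_hoechst, total_ph3; ``true_labels`` is indexed by cell_id.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    labels = {}
    g1_mu, g1_sd = spec.total_hoechst_g1
    g2_mu = g1_mu + math.log10(2.0)  # G2 cells hold twice the DNA content
    cell_counter = 0
    for cond in spec.n_cells:
        n = spec.n_cells[cond]
        p_mit = spec.mitotic_fraction.get(cond, 0.0)
        p_gip = spec.ph3_interphase_fraction.get(cond, 0.0)
        p_pneg = spec.ph3neg_mitotic_fraction.get(cond, 0.0)
        probs = [1.0 - p_mit - p_gip - p_pneg, p_gip, p_mit, p_pneg]
        pops = rng.choice(len(POPULATIONS), size=n, p=probs)
        g1, s, g2 = spec.cycle_shares.get(cond, (0.6, 0.2, 0.2))
        for pop_idx in pops:
            pop = POPULATIONS[pop_idx]
            cell_counter += 1
            cid = f"cell{cell_counter:06d}"
            mh_mu, mh_sd = spec.mean_hoechst[pop]
            ph_mu, ph_sd = spec.total_ph3[pop]
            mean_h = 10 ** rng.normal(mh_mu, mh_sd)
            ph3 = 10 ** rng.normal(ph_mu, ph_sd)
            if pop == "interphase":
                u = rng.random()
                if u < g1:
                    th = 10 ** rng.normal(g1_mu, g1_sd)
                elif u < g1 + s:
                    # S phase: DNA content uniform between 1x and 2x
                    th = 10 ** g1_mu * (1.0 + rng.random())
                else:
                    th = 10 ** rng.normal(g2_mu, g1_sd)
            elif pop == "ph3neg_mitotic_apoptotic":
                th = 10 ** rng.normal(g1_mu, 0.12)
            else:  # mitotic and prophase cells carry G2 DNA content
                th = 10 ** rng.normal(g2_mu, g1_sd)
            rows.append(
                {
                    "cell_id": cid,
                    "condition": cond,
                    "mean_hoechst": mean_h,
                    "total_hoechst": th,
                    "total_ph3": ph3,
                }
            )
            labels[cid] = pop
    cells = pd.DataFrame(rows)
    truth = pd.Series(labels, name="true_label")
    truth.index.name = "cell_id"
    return cells, truth


# ---------------------------------------------------------------------------
# vesicle images


def fitc_tmr_calibration(
    ph: np.ndarray | float,
    r_min: float = 0.2,
    r_max: float = 2.0,
    pka: float = 6.4,
) -> np.ndarray | float:
    """Monotone pH -> FITC/TMR ratio calibration (fluorescein-like
    titration curve); strictly increasing in pH."""
    return r_min + (r_max - r_min) / (1.0 + 10 ** (pka - np.asarray(ph, float)))


@dataclass
class VesicleImageSpec:
    """One synthetic two-channel (FITC, TMR) vesicle field of view."""

    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.065
    n_vesicles: int = 25
    radius_um: tuple[float, float] = (0.35, 0.07)  # log-normal-ish (mean, sd)
    ph: tuple[float, float] = (4.7, 0.15)  # per-vesicle true pH (mean, sd)
    amplitude: float = 140.0
    background: float = 12.0
    noise_sd: float = 5.0
    edge_width_px: float = 0.15
    calibration: tuple[float, float, float] = (0.2, 2.0, 6.4)
    min_separation_px: float = 3.0

    def validate(self) -> None:
        problems = []
        if self.pixel_size_um <= 0:
            problems.append("pixel size must be > 0")
        if self.radius_um[0] <= 0:
            problems.append("mean radius must be > 0")
        if self.noise_sd < 0:
            problems.append("noise sd must be >= 0")
        r_min, r_max, _ = self.calibration
        if not r_max > r_min > 0:
            problems.append("calibration must be strictly increasing (r_max > r_min > 0)")
        if problems:
            raise SpecValidationError("; ".join(problems))


def simulate_vesicle_images(
    spec: VesicleImageSpec, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one field of view.

    Returns (fitc, tmr) uint8 images, the ground-truth label mask
    (0 = background, k = vesicle k), and the truth table with one row
    per vesicle: centre, radius, true area (µm²), true pH and the
    calibrated true FITC/TMR ratio.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    r_mu, r_sd = spec.radius_um
    radii_um = np.exp(
        rng.normal(math.log(r_mu), r_sd / r_mu, size=spec.n_vesicles)
    )
    radii_px = radii_um / spec.pixel_size_um
    phs = rng.normal(spec.ph[0], spec.ph[1], size=spec.n_vesicles)
    r_min, r_max, pka = spec.calibration
    ratios = np.asarray(fitc_tmr_calibration(phs, r_min, r_max, pka))

    # non-overlapping placement by rejection sampling
    centres: list[tuple[float, float]] = []
    for i in range(spec.n_vesicles):
        placed = False
        for _ in range(10_000):
            margin = radii_px[i] + 3.0
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ok = all(
                math.hypot(cy - oy, cx - ox)
                >= radii_px[i] + radii_px[j] + spec.min_separation_px
                for j, (oy, ox) in enumerate(centres)
            )
            if ok:
                centres.append((cy, cx))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place vesicle {i + 1}/{spec.n_vesicles} "
                f"without overlap in a {h}x{w} image"
            )

    yy, xx = np.mgrid[0:h, 0:w]
    tmr = np.full((h, w), spec.background, dtype=float)
    fitc = np.full((h, w), spec.background, dtype=float)
    mask = np.zeros((h, w), dtype=np.int32)
    rows = []
    for i, (cy, cx) in enumerate(centres):
        dist = np.hypot(yy - cy, xx - cx)
        # soft disc: near-flat interior with a logistic edge
        profile = special.expit(-(dist - radii_px[i]) / spec.edge_width_px)
        tmr += spec.amplitude * profile
        fitc += spec.amplitude * ratios[i] * profile
        vesicle_mask = dist <= radii_px[i]
        mask[vesicle_mask] = i + 1
        rows.append(
            {
                "vesicle_id": i + 1,
                "cy": cy,
                "cx": cx,
                "radius_um": radii_um[i],
                "true_area_um2": int(vesicle_mask.sum()) * spec.pixel_size_um**2,
                "true_ph": phs[i],
                "true_ratio": ratios[i],
            }
        )
    if spec.noise_sd > 0:
        tmr += rng.normal(0.0, spec.noise_sd, size=(h, w))
        fitc += rng.normal(0.0, spec.noise_sd, size=(h, w))
    fitc8 = np.clip(np.rint(fitc), 0, 255).astype(np.uint8)
    tmr8 = np.clip(np.rint(tmr), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(rows).set_index("vesicle_id")
    return fitc8, tmr8, mask, truth


def default_vesicle_specs() -> dict[str, VesicleImageSpec]:
    """Fixed morphometry conditions: mitotic vesicles are enlarged
    (1.5x area => sqrt(1.5)x radius) and alkalinised (pH 4.7 -> 5.6)."""
    interphase = VesicleImageSpec()
    mitotic = replace(
        interphase,
        radius_um=(0.35 * math.sqrt(1.5), 0.07),
        ph=(5.6, 0.15),
    )
    return {"interphase": interphase, "mitotic": mitotic}
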