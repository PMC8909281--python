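#!/usr/bin/env python
"""Generate every synthetic input the analyses consume.

Draws the default study conditions: a 28-class lipidome for paired
whole-cell (WCL) and lysosomal (LYS) fractions across three treatments
x 3 replicates with internal standards and log-normal noise, plus
per-cell cytometry features for four conditions.  Ground truth is
written alongside with a `_truth` suffix.  Outputs under
results/synthetic/.
"""

from pathlib import Path

from lysopipe import synthetic

SEED = 1
OUT = Path("results/synthetic")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = synthetic.default_lipidome_spec()
    tbl, truth, effects = synthetic.simulate_lipidomics(spec, seed=SEED)

    long = (
        tbl.intensities.rename_axis("species")
        .reset_index()
        .melt(id_vars="species", var_name="sample_id", value_name="intensity")
        .dropna(subset=["intensity"])
    )
    long.to_csv(OUT / "intensities.tsv", sep="\t", index=False, float_format="%.10g")
    stds = (
        tbl.standard_intensities.rename_axis("group")
        .reset_index()
        .melt(id_vars="group", var_name="sample_id", value_name="intensity")
    )
    stds["amount_pmol"] = stds["group"].map(tbl.standard_amounts)
    stds.to_csv(OUT / "standards.tsv", sep="\t", index=False, float_format="%.10g")
    tbl.samples.rename_axis("sample_id").to_csv(OUT / "samples.tsv", sep="\t")
    truth.molpct.rename_axis("species").to_csv(
        OUT / "molpct_truth.tsv", sep="\t", float_format="%.10g"
    )
    effects.to_csv(OUT / "effects_truth.tsv", sep="\t", index=False)

    cells, labels = synthetic.simulate_cells(
        synthetic.default_cell_spec(n_cells=2000), seed=SEED + 1
    )
    cells.to_csv(OUT / "cells.tsv", sep="\t", index=False, float_format="%.10g")
    labels.to_frame().to_csv(OUT / "cells_truth.tsv", sep="\t")

    print(
        f"simulated {len(tbl.species)} lipid species x {len(tbl.samples)} samples "
        f"and {len(cells)} cells across {cells['condition'].nunique()} conditions"
    )
    print(f"inputs and ground truth written to {OUT}/")


if __name__ == "__main__":
    main()
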