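#!/usr/bin/env python
"""Moderated differential lipid abundance and composition summaries.

Fits the empirical-Bayes two-group model per species for the
lysosome-vs-whole-cell comparison and the released-vs-control lysosome
contrasts, rolls results up to lipid classes (mol% fold changes, mean
carbon/double-bond fold changes, % species significant) and categories,
and orders the class fold-change matrix by Euclidean complete-linkage
clustering for heatmap display.  Outputs under results/differential/.
"""

from pathlib import Path

import pandas as pd

from lysopipe import differential, quantify

IN = Path("results")
OUT = Path("results/differential")

CONTRASTS = [
    differential.Contrast.between_fractions("untreated"),
    differential.Contrast.between_fractions("synchronized"),
    differential.Contrast.between_fractions("released"),
    differential.Contrast.within("LYS", "released", "untreated"),
    differential.Contrast.within("LYS", "released", "synchronized"),
    differential.Contrast.within("WCL", "released", "untreated"),
]


def main() -> None:
    filt = quantify.read_molar_table(
        IN / "quantified" / "molar.tsv", IN / "synthetic" / "samples.tsv"
    )
    OUT.mkdir(parents=True, exist_ok=True)
    fc_cols = {}
    for contrast in CONTRASTS:
        res = differential.fit_differential(filt, contrast)
        stem = contrast.name.replace(":", "_")
        res.to_csv(OUT / f"{stem}.tsv", sep="\t", float_format="%.10g")
        cls = differential.summarize_classes(filt, contrast, res)
        cls.to_csv(OUT / f"classes_{stem}.tsv", sep="\t", float_format="%.10g")
        fc_cols[contrast.name] = cls["log2fc_molpct"]
        print(
            f"{contrast.name}: {int(res['significant'].sum())}/{len(res)} species "
            f"significant ({100 * res['significant'].mean():.1f}%)"
        )

    summary, tests = differential.summarize_categories(
        filt,
        condition_pairs=[
            (("LYS", "released"), ("LYS", "untreated")),
            (("LYS", "released"), ("LYS", "synchronized")),
        ],
    )
    summary.to_csv(OUT / "categories.tsv", sep="\t", index=False, float_format="%.10g")
    tests.to_csv(OUT / "category_tests.tsv", sep="\t", index=False, float_format="%.10g")

    matrix = pd.DataFrame(fc_cols)
    order = differential.cluster_heatmap_order(matrix)
    matrix.loc[order.row_order, order.col_order].rename_axis("lipid_class").to_csv(
        OUT / "class_fc_heatmap.tsv", sep="\t", float_format="%.10g"
    )
    print(f"class fold-change heatmap ordering written for {len(matrix)} classes")


if __name__ == "__main__":
    main()
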