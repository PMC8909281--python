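"""End-to-end workflow: simulate -> quantify -> enrich -> differential
-> cytometry -> vesicles, with every stage's tables written as TSV and
a machine-readable run summary.

All tabular output is written with a fixed float format, so a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cytometry, differential, enrich, quantify, synthetic, vesicles
from .taxonomy import Taxonomy

log = logging.getLogger("lysopipe")

FLOAT_FMT = "%.10g"

DEFAULT_CONTRASTS = (
    "LYS:released:untreated",
    "LYS:released:synchronized",
    "WCL:released:untreated",
    "LYS_vs_WCL:untreated",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for :func:`run_all`.

    With ``simulate=True`` (the default demo mode) all inputs are drawn
    from the packaged synthetic study conditions; otherwise the three
    lipidomics TSVs and the per-cell table must be supplied.
    """

    out_dir: str | Path = "results/run"
    seed: int = 0
    simulate: bool = True
    # quantification
    filter_threshold: float = quantify.DEFAULT_FILTER_THRESHOLD
    aliquot_factors: tuple[float, float] = (1.0, 1.0)
    # differential
    alpha: float = differential.ALPHA
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    # synthetic scale
    cv: float = 0.2
    replicates: int = 3
    n_cells: int = 1000
    vesicle_replicates: int = 3
    # external inputs (simulate=False)
    intensities: str | None = None
    standards: str | None = None
    samples: str | None = None
    cells: str | None = None
    gates: str | None = None  # None -> auto_gates
    taxonomy_path: str | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("significance level must be in (0, 1)")
        if self.filter_threshold < 0:
            raise ValueError("filter threshold must be >= 0")
        if not self.simulate:
            for name in ("intensities", "standards", "samples", "cells"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(
                        f"config requires existing {name} file, got {path!r}"
                    )
        if self.gates is not None and not Path(self.gates).exists():
            raise FileNotFoundError(f"gates file {self.gates!r} not found")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.aliquot_factors, list):
            cfg.aliquot_factors = tuple(cfg.aliquot_factors)
        if isinstance(cfg.contrasts, list):
            cfg.contrasts = tuple(cfg.contrasts)
        return cfg


def parse_contrast(text: str) -> differential.Contrast:
    """``FRACTION:num:den`` (within fraction) or ``LYS_vs_WCL:treatment``."""
    parts = text.split(":")
    if parts[0] == "LYS_vs_WCL" and len(parts) == 2:
        return differential.Contrast.between_fractions(parts[1])
    if len(parts) == 3:
        return differential.Contrast.within(*parts)
    raise ValueError(f"cannot parse contrast {text!r}")


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_all(config: RunConfig) -> dict:
    """Execute the full workflow; returns the machine-readable summary
    (also written to ``<out_dir>/summary.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed, "parameters": {
        "filter_threshold": config.filter_threshold,
        "alpha": config.alpha,
        "cv": config.cv,
        "replicates": config.replicates,
        "n_cells": config.n_cells,
    }}
    taxonomy = (
        Taxonomy.from_yaml(config.taxonomy_path)
        if config.taxonomy_path
        else Taxonomy.default()
    )
    t0 = time.time()

    try:
        # -- inputs -----------------------------------------------------
        if config.simulate:
            log.info("simulate: lipidome seed=%d cv=%g", config.seed, config.cv)
            spec = synthetic.default_lipidome_spec(
                cv=config.cv, replicates=config.replicates, taxonomy=taxonomy
            )
            intensity_tbl, truth, effects = synthetic.simulate_lipidomics(
                spec, seed=config.seed
            )
            sim_dir = out / "synthetic"
            _write(
                intensity_tbl.intensities.rename_axis("species"),
                sim_dir / "intensities.tsv",
            )
            _write(truth.molpct.rename_axis("species"), sim_dir / "molpct_truth.tsv")
            _write(effects, sim_dir / "effects_truth.tsv", index=False)
            cell_spec = synthetic.default_cell_spec(n_cells=config.n_cells)
            cells, cell_truth = synthetic.simulate_cells(
                cell_spec, seed=config.seed + 1
            )
            _write(cells, sim_dir / "cells.tsv", index=False)
            _write(cell_truth.to_frame(), sim_dir / "cells_truth.tsv")
        else:
            intensity_tbl = quantify.read_intensity_tables(
                config.intensities, config.standards, config.samples, taxonomy
            )
            cells = pd.read_csv(config.cells, sep="\t")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    # -- quantify -------------------------------------------------------
    try:
        log.info("quantify: %d species, threshold=%g mol%%",
                 len(intensity_tbl.species), config.filter_threshold)
        molar = quantify.to_molar(intensity_tbl)
        retained, filtered = quantify.filter_species(
            molar, threshold=config.filter_threshold
        )
        (out / "quantified").mkdir(parents=True, exist_ok=True)
        quantify.write_molar_table(filtered, out / "quantified" / "molar.tsv")
        status = enrich.identification_status(molar)
        identified_counts = status.sum(axis=0)
        summary["quantify"] = {
            "n_species_input": len(molar.species),
            "n_species_retained": len(retained),
            "identified_per_sample_type": {
                k: int(v) for k, v in identified_counts.items()
            },
        }
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc

    # -- enrich -----------------------------------------------------------
    try:
        report = enrich.purity_report(
            filtered, aliquot_factors=config.aliquot_factors
        )
        _write(report, out / "enrich" / "purity.tsv", index=False)
        lys_types = [c for c in status.columns if c.startswith("LYS")]
        venn = enrich.venn_counts(status, lys_types)
        venn_df = pd.DataFrame(
            [{"region": "&".join(k), "count": v} for k, v in sorted(venn.items())]
        )
        _write(venn_df, out / "enrich" / "venn_lys.tsv", index=False)
        corr = enrich.replicate_correlation(filtered)
        _write(
            pd.concat(
                [corr.within.assign(group="within"), corr.mixed.assign(group="mixed")]
            ),
            out / "enrich" / "spearman.tsv",
            index=False,
        )
        yield_stats = enrich.lipid_yield(filtered, aliquot_factors=config.aliquot_factors)
        enr = enrich.marker_enrichment(filtered, "BMP/PG")
        rec = enrich.marker_recovery(
            filtered, "BMP/PG", aliquot_factors=config.aliquot_factors
        )
        summary["enrich"] = {
            "lipid_yield_pct": {"mean": yield_stats.mean, "sd": yield_stats.sd},
            "bmp_pg_enrichment_fold": {"mean": enr.mean, "sd": enr.sd},
            "lysosome_recovery_pct": {"mean": rec.mean, "sd": rec.sd},
            "spearman_within_mean": corr.mean_within,
            "spearman_mixed_mean": corr.mean_mixed,
            "spearman_t_p": corr.p_value,
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("enrich", str(exc)) from exc

    # -- differential -----------------------------------------------------
    try:
        diff_summary = {}
        class_fc_cols = {}
        for text in config.contrasts:
            contrast = parse_contrast(text)
            res = differential.fit_differential(
                filtered, contrast, alpha=config.alpha
            )
            _write(res, out / "differential" / f"{contrast.name.replace(':', '_')}.tsv")
            cls_sum = differential.summarize_classes(filtered, contrast, res)
            _write(
                cls_sum,
                out / "differential" / f"classes_{contrast.name.replace(':', '_')}.tsv",
            )
            class_fc_cols[contrast.name] = cls_sum["log2fc_molpct"]
            diff_summary[contrast.name] = {
                "n_testable": int(len(res)),
                "n_significant": int(res["significant"].sum()),
                "pct_significant": 100.0 * float(res["significant"].mean()),
            }
        cat_sum, cat_tests = differential.summarize_categories(
            filtered,
            condition_pairs=[
                (("LYS", "released"), ("LYS", "untreated")),
                (("LYS", "released"), ("LYS", "synchronized")),
            ],
        )
        _write(cat_sum, out / "differential" / "categories.tsv", index=False)
        _write(cat_tests, out / "differential" / "category_tests.tsv", index=False)
        fc_matrix = pd.DataFrame(class_fc_cols)
        order = differential.cluster_heatmap_order(fc_matrix)
        _write(
            fc_matrix.loc[order.row_order, order.col_order].rename_axis("lipid_class"),
            out / "differential" / "class_fc_heatmap.tsv",
        )
        summary["differential"] = diff_summary
    except StageError:
        raise
    except Exception as exc:
        raise StageError("differential", str(exc)) from exc

    # -- cytometry --------------------------------------------------------
    try:
        if config.gates is not None:
            gates = cytometry.GateConfig.from_yaml(config.gates)
        else:
            gates = cytometry.auto_gates(cells)
        (out / "cytometry").mkdir(parents=True, exist_ok=True)
        gates.to_yaml(out / "cytometry" / "gates.yaml")
        labeled, percentages = cytometry.gate_cells(cells, gates)
        _write(labeled, out / "cytometry" / "cells_labeled.tsv", index=False)
        _write(percentages, out / "cytometry" / "percentages.tsv", index=False)
        hist = cytometry.dna_histogram(labeled)
        _write(hist, out / "cytometry" / "dna_histogram.tsv", index=False)
        summary["cytometry"] = {
            "mitotic_pct": {
                k: float(v)
                for k, v in cytometry.mitotic_percentages(percentages).items()
            }
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("cytometry", str(exc)) from exc

    # -- vesicles ---------------------------------------------------------
    try:
        specs = synthetic.default_vesicle_specs()
        records = []
        for p_idx, (phase, vspec) in enumerate(sorted(specs.items())):
            for rep in range(1, config.vesicle_replicates + 1):
                fitc, tmr, _, _ = synthetic.simulate_vesicle_images(
                    vspec, seed=config.seed + 100 + 10 * p_idx + rep
                )
                seg = vesicles.segment(tmr, vspec.pixel_size_um)
                meas = vesicles.measure_vesicles(seg, fitc=fitc, tmr=tmr)
                meas = meas.assign(phase=phase, replicate=rep)
                records.append(meas)
        records = pd.concat(records).reset_index()
        _write(records, out / "vesicles" / "vesicles.tsv", index=False)
        area_means, area_test = vesicles.area_comparison(records)
        ratio_means, ratio_test = vesicles.ratio_ph(records)
        _write(area_means, out / "vesicles" / "area_means.tsv", index=False)
        _write(ratio_means, out / "vesicles" / "ratio_means.tsv", index=False)
        by_phase_area = area_means.groupby("phase")["mean"].mean()
        by_phase_ratio = ratio_means.groupby("phase")["mean"].mean()
        summary["vesicles"] = {
            "mean_area_um2": {k: float(v) for k, v in by_phase_area.items()},
            "area_t_p": area_test["p"],
            "mean_fitc_tmr_ratio": {k: float(v) for k, v in by_phase_ratio.items()},
            "ratio_t_p": ratio_test["p"],
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("vesicles", str(exc)) from exc

    log.info("run complete in %.1f s", time.time() - t0)
    log.removeHandler(handler)
    handler.close()
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )
    return summary
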