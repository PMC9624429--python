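"""End-to-end orchestration: counts -> RPKM -> filter -> RTE -> correlations
-> differential screen -> variability -> codon features -> classifier, with
every intermediate table persisted and a consolidated JSON summary.

Runs are pure functions of the config and its seeds; a run is either
table-driven (paths to mRNA/footprint tables and a CDS FASTA) or synthetic
(a simulation block handed to the generators).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import codons as _codons
from . import iofmt, rte as _rte, synthetic

__all__ = ["RunConfig", "StageError", "run"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str = "ribote_run"
    seed: int = 0
    inputs: dict[str, str] | None = None  # mrna, footprint, cds paths
    simulation: dict[str, Any] | None = None
    filter_log10_threshold: float = 1.5
    filter_convention: str = "mean"
    lfc_cut: float = 4.0
    p_cut: float = 0.05
    n_scrambles: int = 50
    differential_pairs: list[tuple[str, str]] = field(default_factory=list)
    variability_index: str = "variance"
    group_contrast_n_top: int = 200
    classifier: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError("exactly one of inputs/simulation must be present")
        if self.classifier.get("enabled", True) and self.inputs is not None:
            if "cds" not in self.inputs:
                raise ValueError(
                    "classifier requested but no CDS FASTA configured; "
                    "set classifier.enabled: false or provide inputs.cds"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pairs = [tuple(p) for p in raw.pop("differential_pairs", [])]
        return cls(differential_pairs=pairs, **raw)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also on disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seeds": {"root": config.seed},
        "headline": {},
    }
    head = summary["headline"]
    stage = "setup"
    try:
        stage = "inputs"
        if config.simulation is not None:
            sim = dict(config.simulation)
            design = synthetic.ConditionDesign.default()
            truth = synthetic.simulate_genes(
                n_genes=sim.get("n_genes", 2000),
                class_proportions=sim.get("class_proportions"),
                effect_size_log2=sim.get("effect_size_log2", 2.0),
                design=design,
                seed=config.seed,
            )
            mrna_tab, fp_tab = synthetic.simulate_counts(
                truth,
                design,
                sequencing_depth=sim.get("sequencing_depth", 5e6),
                dispersion=sim.get("dispersion", 0.05),
                seed=config.seed + 1,
            )
            models = synthetic.simulate_cds(
                truth,
                bias_strength=sim.get("bias_strength", 0.5),
                seed=config.seed + 2,
            )
            synthetic.truth_table(truth).to_csv(out / "truth.tsv", sep="\t")
            iofmt.write_cds_fasta(models, out / "cds.fasta")
        else:
            inp = config.inputs
            mrna_tab = iofmt.read_expression_table(
                inp["mrna"], value_kind=inp.get("value_kind", "rpkm")
            )
            fp_tab = iofmt.read_expression_table(
                inp["footprint"], value_kind=inp.get("value_kind", "rpkm")
            )
            models = (
                iofmt.read_cds_fasta(inp["cds"]) if "cds" in inp else None
            )

        stage = "rpkm"
        if mrna_tab.value_kind == "raw_counts":
            mrna_rpkm = _rte.compute_rpkm(mrna_tab)
            fp_rpkm = _rte.compute_rpkm(fp_tab)
        else:
            mrna_rpkm, fp_rpkm = mrna_tab, fp_tab
        iofmt.write_table(mrna_rpkm, out / "mrna_rpkm.tsv")
        iofmt.write_table(fp_rpkm, out / "footprint_rpkm.tsv")

        stage = "filter"
        mrna_avg = _rte.average_replicates(mrna_rpkm)
        kept = _rte.filter_genes(
            mrna_avg, config.filter_log10_threshold, config.filter_convention
        )
        head["n_genes_total"] = len(mrna_avg)
        head["n_genes_filtered"] = len(kept)

        stage = "rte"
        mrna_rpkm_f = iofmt.ExpressionTable(
            mrna_rpkm.values.loc[kept], mrna_rpkm.gene_lengths.loc[kept], "rpkm"
        )
        fp_rpkm_f = iofmt.ExpressionTable(
            fp_rpkm.values.loc[kept], fp_rpkm.gene_lengths.loc[kept], "rpkm"
        )
        rte_mat = _rte.compute_rte(fp_rpkm_f, mrna_rpkm_f)
        rte_mat.values.to_csv(out / "rte.tsv", sep="\t", float_format="%.10g")
        mrna_avg_f = mrna_avg.loc[kept]

        stage = "correlations"
        cg = _rte.cross_gene_correlation(
            mrna_avg_f.mean(axis=1), rte_mat.values.mean(axis=1)
        )
        report = _rte.correlation_report(
            mrna_avg_f, rte_mat.values,
            n_scrambles=config.n_scrambles, seed=config.seed + 3,
        )
        report.per_gene_rho.to_csv(out / "cross_condition_rho.tsv", sep="\t")
        head["cross_gene"] = cg
        head["rho_summary"] = report.summary
        head["null_summary"] = report.null_summary
        head["ks"] = {"statistic": report.ks_statistic, "p_value": report.ks_pvalue}

        stage = "differential"
        pairs = config.differential_pairs or [
            (mrna_rpkm.condition_ids[0], mrna_rpkm.condition_ids[2])
            if len(mrna_rpkm.condition_ids) > 2
            else (mrna_rpkm.condition_ids[0], mrna_rpkm.condition_ids[1])
        ]
        head["differential"] = {}
        for cond_a, cond_b in pairs:
            res = _rte.differential(
                mrna_rpkm_f, fp_rpkm_f, cond_a, cond_b,
                lfc_cut=config.lfc_cut, p_cut=config.p_cut,
            )
            res.table.to_csv(out / f"differential_{cond_a}_vs_{cond_b}.tsv", sep="\t",
                             float_format="%.10g")
            head["differential"][f"{cond_a}_vs_{cond_b}"] = {
                "n_up": len(res.selected_up),
                "n_down": len(res.selected_down),
                "fraction_up_rte_concordant": res.fraction_up_rte_concordant,
                "fraction_down_rte_concordant": res.fraction_down_rte_concordant,
            }

        stage = "variability"
        vtab = _rte.variability(rte_mat, index=config.variability_index)
        vtab.to_csv(out / "variability.tsv", sep="\t", float_format="%.10g")

        if models is not None:
            stage = "codon_features"
            model_map = {m.gene_id: m for m in models if m.gene_id in set(kept)}
            background = _codons.background_frequencies(list(model_map.values()))
            centered = {
                g: _codons.center_profile(_codons.codon_frequencies(m), background)
                for g, m in model_map.items()
            }
            vtab_codon = vtab.loc[[g for g in vtab.index if g in centered]]
            n_top = min(config.group_contrast_n_top, len(vtab_codon) // 2)
            contrast = _codons.group_contrast(
                vtab_codon, centered, n_top=n_top,
                ranking_key=config.variability_index,
            )
            head["group_contrast_rho"] = contrast["rho"]

            stage = "classifier"
            if config.classifier.get("enabled", True):
                spec = _classify.FeatureSpec.from_names(
                    config.classifier.get("features", ["codon", "mrna", "rte"])
                )
                labels = _classify.label_by_median(vtab_codon)
                features = _classify.build_features(
                    spec,
                    codon_profiles={g: centered[g] for g in vtab_codon.index},
                    mrna_means=mrna_avg_f.mean(axis=1).loc[vtab_codon.index],
                    rte_means=rte_mat.values.mean(axis=1).loc[vtab_codon.index],
                )
                rf = _classify.train_eval(
                    features,
                    labels,
                    n_trees=config.classifier.get("n_trees", 200),
                    min_leaf=config.classifier.get("min_leaf", 5),
                    n_repeats=config.classifier.get("n_repeats", 50),
                    seed=config.seed + 4,
                )
                rf.per_repeat.to_csv(out / "rf_per_repeat.tsv", sep="\t",
                                     float_format="%.10g")
                pd.DataFrame(
                    {"fpr": rf.fpr_grid, "mean_tpr": rf.mean_tpr, "sd_tpr": rf.sd_tpr}
                ).to_csv(out / "rf_roc.tsv", sep="\t", index=False,
                         float_format="%.10g")
                head["rf"] = {
                    "features": sorted(
                        n for n in spec.__dataclass_fields__ if getattr(spec, n)
                    ),
                    "metrics_mean": rf.metrics_mean,
                    "metrics_sd": rf.metrics_sd,
                    "top_importances": rf.importances.head(10).to_dict(),
                }
    except Exception as err:  # noqa: BLE001 - stage name is the point
        if isinstance(err, StageError):
            raise
        raise StageError(stage, err) from err

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary
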