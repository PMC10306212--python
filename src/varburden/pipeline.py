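"""End-to-end orchestration: qualify -> gene burden -> pathway burden ->
inflation and multiplicity correction -> tabular reports.

One configuration file declares the inputs and any number of analysis arms
(control set x allele-frequency threshold).  Arms are independent: removing
one never changes another's outputs, and re-running on identical inputs is
byte-identical.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as vio
from .burden import BurdenResult, gene_burden, gene_counts
from .coverage import joint_coverage_gate
from .inflation import apply_corrections, estimate_lambda, qq_points
from .pathways import GeneSetCollection, aggregate_pathway, pathway_burden, restrict_sets
from .qualify import QualifyConfig, build_snp_map

logger = logging.getLogger("varburden")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class AnalysisArm:
    """One control set x allele-frequency threshold analysis."""

    name: str
    control: str
    af_max: float
    model: str = "dominant"


@dataclass
class PipelineConfig:
    case_vcf: str
    annotations: str
    case_coverage: str
    controls: dict[str, dict]  # label -> {summary, coverage, n_controls}
    gene_sets: list[str]
    arms: list[AnalysisArm]
    out_dir: str
    qualify: QualifyConfig = field(default_factory=QualifyConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        inputs = raw["inputs"]
        arms = [
            AnalysisArm(
                name=a["name"],
                control=a["control"],
                af_max=float(a["af_max"]),
                model=a.get("model", "dominant"),
            )
            for a in raw.get("arms", [])
        ]
        if not arms:
            raise ValueError("configuration declares zero analysis arms")
        qraw = dict(raw.get("qualify", {}))
        if "impact_terms" in qraw:
            qraw["impact_terms"] = frozenset(qraw["impact_terms"])
        if "af_source_order" in qraw:
            qraw["af_source_order"] = tuple(qraw["af_source_order"])
        return cls(
            case_vcf=inputs["case_vcf"],
            annotations=inputs["annotations"],
            case_coverage=inputs["case_coverage"],
            controls=inputs["controls"],
            gene_sets=list(inputs.get("gene_sets", [])),
            arms=arms,
            out_dir=raw["out_dir"],
            qualify=QualifyConfig(**qraw),
        )


def _qq_frame(results: list[BurdenResult]) -> pd.DataFrame | None:
    if not results:
        return None
    return qq_points([r.p_raw for r in results]).to_frame()


@dataclass
class _ArmOutput:
    arm: AnalysisArm
    snp_map: dict
    counts: dict
    gene_results: dict[int, list[BurdenResult]]  # min_case_count -> results
    pathway_results: list[BurdenResult]
    lambdas: list[dict]


def _run_arm(arm, cohort, annotations, case_cov, control, control_cov, sets, base_cfg):
    stage = "coverage-gate"
    try:
        retained = joint_coverage_gate(case_cov, control_cov, base_cfg.coverage_frac_min)
        stage = "qualify"
        cfg = base_cfg.with_af_max(arm.af_max)
        snp_map = build_snp_map(cohort, annotations, cfg, retained)
        stage = "gene-burden"
        counts = gene_counts(snp_map, cohort, control)
        gene_results = {}
        lambdas = []
        for min_case in (1, 2):
            results = gene_burden(
                snp_map, cohort, control, min_case_count=min_case, model=arm.model
            )
            if results:
                lam = estimate_lambda([r.p_raw for r in results])
                apply_corrections(results, lam.lambda_)
                lambdas.append(
                    {
                        "arm": arm.name,
                        "unit_class": f"genes_min{min_case}",
                        "lambda": lam.lambda_,
                        "n_points_used": lam.n_points_used,
                        "n_pvalues": lam.n_pvalues,
                        "stable": lam.stable,
                    }
                )
            gene_results[min_case] = results
        stage = "pathway-burden"
        restricted = restrict_sets(sets, snp_map)
        pathway_counts = [
            aggregate_pathway(counts, restricted.sets[name])
            for name in sorted(restricted.sets)
        ]
        pathway_results = pathway_burden(pathway_counts)
        if pathway_results:
            lam = estimate_lambda([r.p_raw for r in pathway_results])
            apply_corrections(pathway_results, lam.lambda_)
            lambdas.append(
                {
                    "arm": arm.name,
                    "unit_class": "pathways",
                    "lambda": lam.lambda_,
                    "n_points_used": lam.n_points_used,
                    "n_pvalues": lam.n_pvalues,
                    "stable": lam.stable,
                }
            )
        logger.info(
            "arm %s: %d genes with qualifying case variants, %d pathways tested",
            arm.name,
            len(snp_map),
            len(pathway_results),
        )
        return _ArmOutput(arm, snp_map, counts, gene_results, pathway_results, lambdas)
    except Exception as exc:
        raise PipelineError(f"arm {arm.name}, stage {stage}: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every analysis arm and write all outputs under ``config.out_dir``."""
    logger.info("qualifying thresholds: %s", config.qualify)
    try:
        cohort, _ = vio.read_case_vcf(config.case_vcf)
        annotations = vio.read_annotations(config.annotations)
        case_cov = vio.read_coverage(config.case_coverage)
        controls = {
            label: (
                vio.read_control_summary(spec["summary"], int(spec["n_controls"])),
                vio.read_coverage(spec["coverage"]),
            )
            for label, spec in config.controls.items()
        }
        merged = GeneSetCollection()
        for path in config.gene_sets:
            collection = vio.read_gmt(path)
            overlap = set(merged.sets) & set(collection.sets)
            if overlap:
                raise ValueError(f"duplicate pathway names across GMT files: {sorted(overlap)[:3]}")
            merged.sets.update(collection.sets)
            merged.parents.update(collection.parents)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage input-loading: {exc}") from exc

    base = config.qualify
    outputs = []
    for arm in config.arms:
        if arm.control not in controls:
            raise PipelineError(f"arm {arm.name}: unknown control set {arm.control!r}")
        control, control_cov = controls[arm.control]
        cfg = QualifyConfig(
            cadd_min=base.cadd_min,
            impact_terms=base.impact_terms,
            af_max=arm.af_max,
            af_source_order=tuple(
                dict.fromkeys((f"af_{arm.control}_nfe",) + tuple(base.af_source_order))
            ),
            combine_rule=base.combine_rule,
            depth_min=base.depth_min,
            coverage_frac_min=base.coverage_frac_min,
        )
        outputs.append(
            _run_arm(arm, cohort, annotations, case_cov, control, control_cov, merged, cfg)
        )

    out_root = Path(config.out_dir)
    created = not out_root.exists()
    try:
        out_root.mkdir(parents=True, exist_ok=True)
        lambda_rows = []
        for arm_out in outputs:
            arm_dir = out_root / arm_out.arm.name
            for min_case, results in arm_out.gene_results.items():
                vio.write_outputs(
                    arm_out.snp_map,
                    arm_out.counts.values(),
                    results,
                    arm_dir / f"genes_min{min_case}",
                    qq=_qq_frame(results),
                )
            vio.write_outputs(
                arm_out.snp_map,
                arm_out.counts.values(),
                arm_out.pathway_results,
                arm_dir / "pathways",
                qq=_qq_frame(arm_out.pathway_results),
            )
            lambda_rows.extend(arm_out.lambdas)
        pd.DataFrame(
            lambda_rows,
            columns=["arm", "unit_class", "lambda", "n_points_used", "n_pvalues", "stable"],
        ).to_csv(out_root / "lambda_summary.tsv", sep="\t", index=False)
        (out_root / "run.log").write_text(
            _run_log(config, outputs), encoding="utf-8"
        )
    except Exception as exc:
        if created:
            shutil.rmtree(out_root, ignore_errors=True)
        raise PipelineError(f"stage write-outputs: {exc}") from exc
    return out_root


def _run_log(config: PipelineConfig, outputs: list[_ArmOutput]) -> str:
    from . import __version__

    lines = [
        f"varburden {__version__}",
        f"qualify: {config.qualify}",
        f"arms: {[a.name for a in config.arms]}",
    ]
    for arm_out in outputs:
        lines.append(
            f"{arm_out.arm.name}: genes={len(arm_out.snp_map)} "
            f"pathways={len(arm_out.pathway_results)} "
            f"lambdas={[(l['unit_class'], round(l['lambda'], 4)) for l in arm_out.lambdas]}"
        )
    return "\n".join(lines) + "\n"


def report_summary(out_dir: str | Path, alpha: float = 0.05) -> str:
    """Human-readable per-arm summary of a finished run.

    Lists, per arm and unit class, the number of tested units, the inflation
    factor applied, and every unit significant after both corrections.
    """
    out = Path(out_dir)
    lam = pd.read_csv(out / "lambda_summary.tsv", sep="\t")
    lines = []
    for arm_dir in sorted(p for p in out.iterdir() if p.is_dir()):
        lines.append(f"== arm {arm_dir.name} ==")
        for unit_dir in sorted(p for p in arm_dir.iterdir() if p.is_dir()):
            burden_path = unit_dir / vio.BURDEN_FILE
            if not burden_path.exists():
                continue
            table = pd.read_csv(burden_path, sep="\t")
            sel = lam[(lam["arm"] == arm_dir.name) & (lam["unit_class"] == unit_dir.name)]
            lam_text = f"{sel['lambda'].iloc[0]:.3f}" if len(sel) else "n/a"
            hits = table[table["p_final"] <= alpha].sort_values("unit")
            lines.append(
                f"  {unit_dir.name}: {len(table)} units tested, lambda={lam_text}"
            )
            if hits.empty:
                lines.append(f"    no unit significant at corrected p <= {alpha}")
            else:
                for row in hits.itertuples(index=False):
                    lines.append(
                        f"    {row.unit}: p_raw={row.p_raw:.3g} "
                        f"p_final={row.p_final:.3g}"
                    )
    return "\n".join(lines) + "\n"
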