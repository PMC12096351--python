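"""End-to-end evaluation: curate -> pair -> score -> summarize -> report.

:func:`run_evaluation` takes a :class:`RunConfig` pointing either at MSP
files on disk (observed + predicted + a molecule table) or at a synthetic
generation block, runs the curation gates, scores every pair with the four
metrics, and aggregates summaries, chemical-space correlations,
derivatized-vs-free comparisons and threshold classifications.  Every run
writes a manifest sufficient to reproduce it (resolved config + seed +
package version) and a structured attrition log, one record per curation
stage, whose removed counts sum to input minus output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .curation import MoleculeRecord, dedup_against, filter_instrument
from .metrics import MetricParams, SimilarityResult, evaluate_pair
from .spectra import Spectrum, read_msp
from .stats import (
    LibrarySummary,
    ThresholdConfig,
    classify_similarity,
    correlation_table,
    group_comparison_table,
    summarize_library,
)
from .synthetic import (
    DistortionModel,
    SyntheticLibraryConfig,
    generate_paired_library,
    molecules_from_csv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "EvaluationReport", "run_evaluation"]


@dataclass
class RunConfig:
    """Resolved configuration of one evaluation run.

    Exactly one of {file inputs, synthetic block} must be set.  The resolved
    config is serialized verbatim into the output manifest.
    """

    observed_path: str | None = None
    predicted_path: str | None = None
    molecules_path: str | None = None
    synthetic_config: SyntheticLibraryConfig | None = None
    distortion: DistortionModel | None = None
    library_name: str = "synthetic"
    reference_library_path: str | None = None
    instrument_pattern: str | None = None
    apply_type1a_filter: bool = True
    metric_params: MetricParams = field(default_factory=MetricParams)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        file_mode = self.observed_path is not None
        synth_mode = self.synthetic_config is not None
        if file_mode == synth_mode:
            raise ValueError("exactly one of file inputs or a synthetic block must be set")
        if file_mode and (self.predicted_path is None or self.molecules_path is None):
            raise ValueError("file inputs require observed, predicted and molecules paths")

    def as_dict(self) -> dict:
        return {
            "observed_path": self.observed_path,
            "predicted_path": self.predicted_path,
            "molecules_path": self.molecules_path,
            "synthetic_config": self.synthetic_config.as_dict() if self.synthetic_config else None,
            "distortion": self.distortion.as_dict() if self.distortion else None,
            "library_name": self.library_name,
            "reference_library_path": self.reference_library_path,
            "instrument_pattern": self.instrument_pattern,
            "apply_type1a_filter": self.apply_type1a_filter,
            "metric_params": self.metric_params.as_dict(),
            "thresholds": self.thresholds.as_dict(),
            "out_dir": self.out_dir,
            "seed": self.seed,
        }


@dataclass
class EvaluationReport:
    """All tables of one run plus the parameters that produced them."""

    summary: LibrarySummary
    results: list[SimilarityResult]
    pairs_table: pd.DataFrame
    correlations: pd.DataFrame
    comparisons: pd.DataFrame
    classification_rates: dict[str, float]
    attrition: list[dict]
    n_tests: int
    config: RunConfig


def _load_inputs(
    config: RunConfig,
) -> tuple[list[Spectrum], list[Spectrum], list[MoleculeRecord]]:
    if config.synthetic_config is not None:
        model = config.distortion or DistortionModel()
        pairs, molecules = generate_paired_library(config.synthetic_config, model)
        return [p.observed for p in pairs], [p.predicted for p in pairs], molecules
    observed = read_msp(config.observed_path)
    predicted = read_msp(config.predicted_path)
    molecules = molecules_from_csv(config.molecules_path)
    return observed, predicted, molecules


def run_evaluation(config: RunConfig) -> EvaluationReport:
    """Execute the full evaluation and (optionally) write the report tables."""
    observed, predicted, molecules = _load_inputs(config)
    by_id = {m.compound_id: m for m in molecules}
    attrition: list[dict] = []

    def log_stage(stage: str, n_in: int, n_out: int) -> None:
        attrition.append({"stage": stage, "n_in": n_in, "n_out": n_out,
                          "removed": n_in - n_out})
        logger.info("stage %s: %d -> %d", stage, n_in, n_out)

    # --- curation gates on the molecule table -----------------------------
    kept = molecules
    if config.apply_type1a_filter:
        n_in = len(kept)
        kept = [m for m in kept if m.is_type1a_alpha_aa]
        log_stage("type1a_filter", n_in, len(kept))
    if config.reference_library_path:
        reference = molecules_from_csv(config.reference_library_path)
        n_in = len(kept)
        kept = dedup_against(kept, reference)
        log_stage("dedup_against_reference", n_in, len(kept))
    kept_ids = {m.compound_id for m in kept}

    obs_kept = [s for s in observed if s.compound_id in kept_ids]
    if config.instrument_pattern:
        n_in = len(obs_kept)
        obs_kept = filter_instrument(obs_kept, config.instrument_pattern)
        log_stage("instrument_filter", n_in, len(obs_kept))
    obs_ids = {s.compound_id for s in obs_kept}

    if not obs_kept:
        raise ValueError(
            "no spectra survive curation; attrition by stage: "
            + "; ".join(f"{a['stage']}: -{a['removed']}" for a in attrition)
        )

    pred_by_id = {s.compound_id: s for s in predicted}
    orphans = sorted(obs_ids - set(pred_by_id))
    if orphans:
        raise ValueError(f"observed spectra without predicted counterpart: {orphans}")

    # --- scoring ----------------------------------------------------------
    results = [
        evaluate_pair(s, pred_by_id[s.compound_id], config.metric_params)
        for s in obs_kept
    ]
    summary = summarize_library(results, config.library_name)

    rows = []
    for res in results:
        mol = by_id[res.compound_id]
        labels = classify_similarity(res, config.thresholds)
        rows.append(
            {
                "compound_id": res.compound_id,
                "rmse": res.rmse,
                "sca_deg": res.sca_deg,
                "wcs": res.wcs,
                "sen": res.sen,
                "molecular_weight": mol.molecular_weight,
                "logp": mol.logp,
                "derivatized": mol.derivatized,
                "sca_label": labels["sca"],
                "wcs_label": labels["wcs"],
                "sen_label": labels["sen"],
            }
        )
    pairs_table = pd.DataFrame(rows)

    correlations = correlation_table(pairs_table, config.library_name)
    comparisons = group_comparison_table(pairs_table, config.library_name)
    n_tests = int(correlations["r_squared"].notna().sum()
                  + comparisons["p_value"].notna().sum())

    n = len(pairs_table)
    classification_rates = {
        "sca_adequate": float((pairs_table["sca_label"] == "adequate").sum() / n),
        "wcs_similar": float((pairs_table["wcs_label"] == "similar").sum() / n),
        "sen_similar": float((pairs_table["sen_label"] == "similar").sum() / n),
    }

    report = EvaluationReport(
        summary=summary,
        results=results,
        pairs_table=pairs_table,
        correlations=correlations,
        comparisons=comparisons,
        classification_rates=classification_rates,
        attrition=attrition,
        n_tests=n_tests,
        config=config,
    )
    if config.out_dir:
        _write_report(report, Path(config.out_dir))
    return report


def _write_report(report: EvaluationReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    s = report.summary
    pd.DataFrame(
        [{
            "library": s.library_name,
            "n_pairs": s.n_pairs,
            "mean_rmse": s.mean_rmse,
            "mean_sca_deg": s.mean_sca_deg,
            "mean_wcs": s.mean_wcs,
            "mean_sen": s.mean_sen,
        }]
    ).to_csv(out / "summary.csv", index=False)
    report.pairs_table.to_csv(out / "pairs.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False)
    report.comparisons.to_csv(out / "comparisons.csv", index=False)
    manifest = {
        "package_version": __version__,
        "config": report.config.as_dict(),
        "attrition": report.attrition,
        "classification_rates": report.classification_rates,
        "n_statistical_tests": report.n_tests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
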