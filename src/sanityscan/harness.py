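"""The three sanity tests for spurious-correlation detection.

A classifier that truly uses the target should (1) collapse to chance when
the target is removed from the test images, (2) collapse to chance when
trained and tested on anatomy-free noise images, and (3) keep its
performance when the amount of surrounding context changes.  Each check is
a pure function of the cross-format AUC matrix:

1. *Target ablation*: the model trained on target-present volumes, tested
   on target-removed volumes, must have an AUC whose 95% CI contains 0.5.
2. *Noise images*: the noise-format self-test AUC's CI must contain 0.5.
3. *ROI sensitivity*: the target-only model's self-test and its evaluation
   on the full volumes must not differ significantly (paired DeLong test,
   alpha = 0.05).

An AUC significantly *below* 0.5 also fails tests 1-2: anti-learning is
confounding too.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .formats import InputFormat
from .head import TrainingConfig
from .noise import PatchSelectionCriteria
from .stats import (
    CrossFormatMatrix,
    FoldSplit,
    cross_format_evaluation,
    delong_between_cells,
    stratified_kfold,
)

__all__ = [
    "SanityCriteria",
    "SanityEntry",
    "SanityReport",
    "evaluate_target_ablation",
    "evaluate_noise_images",
    "evaluate_roi_sensitivity",
    "run_sanity_suite",
]

PASS = "PASS"
FAIL = "FAIL"


@dataclass(frozen=True)
class SanityCriteria:
    """Decision rules for the three tests.

    ``chance_band`` operationalizes "AUC of around 0.5" as "the 95% CI
    contains 0.5"; ``roi_alpha`` is the significance level of the DeLong
    comparison in the ROI test.  The ROI comparison cells are exposed
    because other pairings are defensible.
    """

    chance_value: float = 0.5
    roi_alpha: float = 0.05
    roi_self_cell: tuple = (InputFormat.TARGET_ONLY, InputFormat.TARGET_ONLY)
    roi_context_cell: tuple = (InputFormat.TARGET_ONLY, InputFormat.ORIGINAL_WP)

    def __post_init__(self):
        if not 0 < self.roi_alpha < 1:
            raise ConfigurationError("roi_alpha must be in (0, 1)")


@dataclass(frozen=True)
class SanityEntry:
    """Outcome of one sanity test."""

    name: str
    decision: str  # PASS or FAIL
    metrics: dict
    evidence: str


@dataclass(frozen=True)
class SanityReport:
    """Three-entry report with provenance."""

    entries: tuple
    provenance: dict

    def __post_init__(self):
        if len(self.entries) != 3:
            raise ConfigurationError("a sanity report has exactly 3 entries")

    @property
    def decisions(self) -> dict:
        return {e.name: e.decision for e in self.entries}

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "entries": [
                {
                    "name": e.name,
                    "decision": e.decision,
                    "metrics": e.metrics,
                    "evidence": e.evidence,
                }
                for e in self.entries
            ],
            "provenance": self.provenance,
        }


def _chance_entry(name, est, crit: SanityCriteria) -> SanityEntry:
    ok = est.ci_lo <= crit.chance_value <= est.ci_hi
    metrics = {
        "auc": est.auc,
        "ci_lo": est.ci_lo,
        "ci_hi": est.ci_hi,
        "level": est.level,
    }
    if ok:
        evidence = (
            f"AUC {est.auc:.3f} (95% CI {est.ci_lo:.3f}-{est.ci_hi:.3f}) "
            f"is compatible with chance"
        )
    else:
        side = "above" if est.ci_lo > crit.chance_value else "below"
        evidence = (
            f"AUC {est.auc:.3f} (95% CI {est.ci_lo:.3f}-{est.ci_hi:.3f}) "
            f"is significantly {side} chance: the classes are separable "
            f"without the causal target"
        )
    return SanityEntry(name=name, decision=PASS if ok else FAIL, metrics=metrics, evidence=evidence)


def evaluate_target_ablation(
    matrix: CrossFormatMatrix, crit: SanityCriteria = SanityCriteria()
) -> SanityEntry:
    """Test 1: train with the target present, test with it removed."""
    cell = matrix.cell(InputFormat.ORIGINAL_WP, InputFormat.WOP)
    return _chance_entry("target_ablation", cell.estimate, crit)


def evaluate_noise_images(
    matrix: CrossFormatMatrix, crit: SanityCriteria = SanityCriteria()
) -> SanityEntry:
    """Test 2: train and test on noise images only."""
    cell = matrix.cell(InputFormat.NOISE, InputFormat.NOISE)
    return _chance_entry("noise_images", cell.estimate, crit)


def evaluate_roi_sensitivity(
    matrix: CrossFormatMatrix, crit: SanityCriteria = SanityCriteria()
) -> SanityEntry:
    """Test 3: added context must not significantly alter performance."""
    auc_self, auc_ctx, z, p = delong_between_cells(
        matrix, crit.roi_self_cell, crit.roi_context_cell
    )
    ok = p > crit.roi_alpha
    metrics = {
        "auc_self": auc_self,
        "auc_context": auc_ctx,
        "delong_z": z,
        "delong_p": p,
        "alpha": crit.roi_alpha,
    }
    if ok:
        evidence = (
            f"self-test AUC {auc_self:.3f} vs full-context AUC {auc_ctx:.3f} "
            f"(DeLong p = {p:.3f}): no significant change"
        )
    else:
        evidence = (
            f"self-test AUC {auc_self:.3f} vs full-context AUC {auc_ctx:.3f} "
            f"(DeLong p = {p:.3g}): context significantly alters performance"
        )
    return SanityEntry(
        name="roi_sensitivity", decision=PASS if ok else FAIL, metrics=metrics, evidence=evidence
    )


def run_sanity_suite(
    cohort: Sequence,
    cfg: TrainingConfig = TrainingConfig(),
    crit: SanityCriteria = SanityCriteria(),
    k: int = 5,
    split: Optional[FoldSplit] = None,
    noise_criteria: PatchSelectionCriteria = PatchSelectionCriteria(),
    extractor=None,
    slice_size: int = 299,
) -> tuple[SanityReport, CrossFormatMatrix]:
    """Build all formats, train the four systems, and render the report.

    Returns the three-entry report together with the full cross-format
    matrix it was derived from.  Decisions are pure functions of the
    matrix and criteria, so recomputing the report from a stored matrix is
    bit-identical.
    """
    labels = [int(lab) for _, _, lab in cohort]
    pids = [vol.patient_id for vol, _, _ in cohort]
    if split is None:
        split = stratified_kfold(labels, k=k, seed=cfg.seed, patient_ids=pids)
    matrix = cross_format_evaluation(
        cohort,
        cfg,
        split,
        noise_criteria=noise_criteria,
        extractor=extractor,
        slice_size=slice_size,
    )
    entries = (
        evaluate_target_ablation(matrix, crit),
        evaluate_noise_images(matrix, crit),
        evaluate_roi_sensitivity(matrix, crit),
    )
    config_blob = json.dumps(
        {
            "cfg": vars(cfg) if not hasattr(cfg, "__dict__") else cfg.__dict__,
            "crit": {
                "chance_value": crit.chance_value,
                "roi_alpha": crit.roi_alpha,
            },
            "k": split.k,
        },
        sort_keys=True,
        default=str,
    )
    provenance = {
        "seed": cfg.seed,
        "k": split.k,
        "n_patients": len(cohort),
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest()[:16],
    }
    return SanityReport(entries=entries, provenance=provenance), matrix
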