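"""Cross-validated AUC inference and the cross-format evaluation matrix.

This module implements the statistical machinery of the sanity harness:

* stratified k-fold splitting at the patient level (via scikit-learn);
* ROC AUC as the Mann-Whitney statistic with midrank tie handling;
* a 95% confidence interval for the cross-validated AUC using
  per-observation influence functions pooled across folds (the
  influence-curve estimator popularized by the cvAUC method);
* the DeLong test for two correlated ROC curves on the same patients,
  via structural components;
* the train-format x test-format AUC matrix: one classifier per training
  format, each evaluated on held-out patients rendered in every format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import (
    ConfigurationError,
    ContractError,
    ParameterError,
    StratificationError,
    UndefinedAUCError,
)
from .formats import InputFormat, MASK_REQUIRING_FORMATS, render_format
from .head import (
    AggregationHead,
    RadiomicSliceExtractor,
    SliceEmbeddingSequence,
    TrainingConfig,
    predict_probability,
    train_head,
)
from .noise import PatchSelectionCriteria
from .volume import NormalizationStats

__all__ = [
    "FoldSplit",
    "AUCEstimate",
    "MatrixCell",
    "CrossFormatMatrix",
    "stratified_kfold",
    "roc_auc",
    "cv_auc_ci",
    "delong_test",
    "delong_between_cells",
    "cross_format_evaluation",
]


@dataclass(frozen=True)
class FoldSplit:
    """Patient-level stratified fold assignment."""

    k: int
    assignments: dict  # patient_id -> fold index
    seed: int

    def folds(self, patient_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignments[p] for p in patient_ids], dtype=int)


@dataclass(frozen=True)
class AUCEstimate:
    """Cross-validated AUC with its Wald confidence interval."""

    auc: float
    ci_lo: float
    ci_hi: float
    level: float = 0.95
    n_folds: int = 0

    def __post_init__(self):
        if not (self.ci_lo <= self.auc + 1e-12 and self.auc <= self.ci_hi + 1e-12):
            raise ContractError("CI must bracket the point estimate")

    def contains_chance(self) -> bool:
        return self.ci_lo <= 0.5 <= self.ci_hi


@dataclass
class MatrixCell:
    """One train-format x test-format evaluation."""

    estimate: AUCEstimate
    fold_results: list          # of (scores, labels) per fold
    scores: np.ndarray          # pooled out-of-fold scores, cohort order
    labels: np.ndarray
    patient_ids: list


@dataclass
class CrossFormatMatrix:
    """Grid of AUC estimates: rows = training format, cols = test format."""

    train_formats: list
    test_formats: list
    cells: dict                 # (InputFormat, InputFormat) -> MatrixCell
    split: FoldSplit
    pairwise_p: dict = field(default_factory=dict)

    def cell(self, train_fmt: InputFormat, test_fmt: InputFormat) -> MatrixCell:
        key = (train_fmt, test_fmt)
        if key not in self.cells:
            raise ConfigurationError(
                f"matrix has no cell for train={train_fmt.value}, test={test_fmt.value}"
            )
        return self.cells[key]


# ---------------------------------------------------------------------------
# Splitting and AUC
# ---------------------------------------------------------------------------

def stratified_kfold(
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
    patient_ids: Optional[Sequence[str]] = None,
) -> FoldSplit:
    """Stratified k-fold assignment; per-fold class counts differ by <= 1."""
    labels = np.asarray(labels, dtype=int)
    if patient_ids is None:
        patient_ids = [str(i) for i in range(len(labels))]
    if len(patient_ids) != len(labels):
        raise ParameterError("labels and patient_ids must align")
    for cls in np.unique(labels):
        if np.sum(labels == cls) < k:
            raise StratificationError(f"class {cls} has fewer than {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32 - 1))
    assignments = {}
    for j, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        for i in test_idx:
            assignments[patient_ids[i]] = j
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise UndefinedAUCError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - m * (m + 1) / 2) / (m * n))


def _influence(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC and per-observation influence-function values."""
    pos = labels == 1
    x, y = scores[pos], scores[~pos]
    m, n = len(x), len(y)
    ranks_all = rankdata(scores)
    auc = float((ranks_all[pos].sum() - m * (m + 1) / 2) / (m * n))
    # midrank placement of each pos among negs and vice versa
    f0 = (ranks_all[pos] - rankdata(x)) / n        # P(Y < x) + 0.5 P(Y = x)
    s1 = 1.0 - (ranks_all[~pos] - rankdata(y)) / m  # P(X > y) + 0.5 P(X = y)
    p1, p0 = m / (m + n), n / (m + n)
    ic = np.empty(m + n)
    ic[pos.nonzero()[0]] = (f0 - auc) / p1
    ic[(~pos).nonzero()[0]] = (s1 - auc) / p0
    return auc, ic


def cv_auc_ci(
    fold_results: Sequence[tuple[Sequence[float], Sequence[int]]],
    level: float = 0.95,
) -> AUCEstimate:
    """Influence-curve CI for the cross-validated AUC.

    The point estimate is the fold-size-weighted mean of fold AUCs.  Each
    fold's variance comes from its structural components — equivalent to
    the per-observation influence-function variance, but with the ddof=1
    sample-variance convention of the DeLong estimator, which matters at
    the small per-fold class counts the harness produces.  Fold variances
    combine with squared fold weights, and the Wald interval is truncated
    to [0, 1].
    """
    if len(fold_results) < 1:
        raise ParameterError("need at least one fold")
    aucs, variances, sizes = [], [], []
    for scores, labels in fold_results:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if len(np.unique(labels)) < 2:
            raise UndefinedAUCError("a fold contains a single class")
        auc_k, v10, v01 = _structural_components(scores, labels)
        m, n = len(v10), len(v01)
        var_k = 0.0
        if m > 1:
            var_k += float(np.var(v10, ddof=1)) / m
        if n > 1:
            var_k += float(np.var(v01, ddof=1)) / n
        aucs.append(auc_k)
        variances.append(var_k)
        sizes.append(len(labels))
    sizes = np.asarray(sizes, dtype=float)
    weights = sizes / sizes.sum()
    point = float(np.average(aucs, weights=sizes))
    var = float(np.sum(weights**2 * np.asarray(variances)))
    zq = norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(max(var, 0.0))
    return AUCEstimate(
        auc=point,
        ci_lo=float(np.clip(point - half, 0.0, 1.0)),
        ci_hi=float(np.clip(point + half, 0.0, 1.0)),
        level=level,
        n_folds=len(fold_results),
    )


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong V10 (per positive) and V01 (per negative) components."""
    pos = labels == 1
    x, y = scores[pos], scores[~pos]
    m, n = len(x), len(y)
    ranks_all = rankdata(scores)
    v10 = (ranks_all[pos] - rankdata(x)) / n
    v01 = 1.0 - (ranks_all[~pos] - rankdata(y)) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
) -> tuple[float, float, float, float]:
    """Paired DeLong test for two correlated AUCs on the same patients.

    Returns (auc_a, auc_b, z, p) with a two-sided p from the normal
    approximation.  Identical score vectors (zero variance of the
    difference) return z = 0, p = 1 by contract.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ParameterError("both score vectors must cover the same patients")
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise UndefinedAUCError("DeLong needs both classes present")
    auc_a, v10_a, v01_a = _structural_components(a, labels)
    auc_b, v10_b, v01_b = _structural_components(b, labels)
    if m < 2 or n < 2:
        raise ParameterError("DeLong variance needs >= 2 patients per class")
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 1e-16:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return auc_a, auc_b, float(z), p


def delong_between_cells(matrix: CrossFormatMatrix, key_a, key_b):
    """DeLong comparison of two matrix cells' pooled out-of-fold scores."""
    cell_a = matrix.cell(*key_a)
    cell_b = matrix.cell(*key_b)
    if cell_a.patient_ids != cell_b.patient_ids:
        raise ConfigurationError("cells score different patients; cannot pair")
    return delong_test(cell_a.scores, cell_b.scores, cell_a.labels)


# ---------------------------------------------------------------------------
# Cross-format evaluation
# ---------------------------------------------------------------------------

def _combine_moments(moments, pids):
    n = sum(moments[p][0] for p in pids)
    tot = sum(moments[p][1] for p in pids)
    tot_sq = sum(moments[p][2] for p in pids)
    mean = tot / n
    var = tot_sq / n - mean * mean
    return NormalizationStats(mean=mean, std=float(np.sqrt(max(var, 1e-12))))


def _stratified_tune_split(pids, labels, frac, rng):
    """Carve a stratified tuning subset out of the training patients."""
    pids = np.asarray(pids)
    labels = np.asarray(labels)
    tune_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        n_tune = max(1, int(round(frac * len(idx))))
        tune_idx.extend(rng.permutation(idx)[:n_tune])
    tune_mask = np.zeros(len(pids), dtype=bool)
    tune_mask[tune_idx] = True
    return pids[~tune_mask].tolist(), pids[tune_mask].tolist()


def cross_format_evaluation(
    cohort: Sequence,
    cfg: TrainingConfig,
    split: FoldSplit,
    train_formats: Optional[Sequence[InputFormat]] = None,
    test_formats: Optional[Sequence[InputFormat]] = None,
    extractor=None,
    noise_criteria: PatchSelectionCriteria = PatchSelectionCriteria(),
    tune_fraction: float = 0.2,
    slice_size: int = 299,
) -> CrossFormatMatrix:
    """Train one classifier per training format; test on every test format.

    ``cohort`` is a sequence of (CTVolume, SegmentationMask | None, label).
    For each fold of ``split``, each training-format classifier is fit on
    the in-fold patients (with a stratified tuning subset for the plateau
    scheduler) and scored on the held-out patients rendered in every test
    format.  Per-format normalization statistics are pooled over the
    training patients of the fold only; held-out data is rendered with the
    statistics of its own format's training patients, so no test
    information leaks into any preprocessing or training step.
    """
    all_formats = list(InputFormat)
    train_formats = list(train_formats) if train_formats else all_formats
    test_formats = list(test_formats) if test_formats else all_formats
    needed = set(train_formats) | set(test_formats)
    if extractor is None:
        extractor = RadiomicSliceExtractor()

    pids = [vol.patient_id for vol, _, _ in cohort]
    if len(set(pids)) != len(pids):
        raise ConfigurationError("patient ids must be unique")
    labels = {vol.patient_id: int(lab) for vol, _, lab in cohort}
    for fmt in needed & set(MASK_REQUIRING_FORMATS):
        if any(mask is None for _, mask, _ in cohort):
            raise ConfigurationError(f"format {fmt.value} requires masks for all patients")

    # Render each patient once per needed format; keep only voxel moments
    # (for per-fold normalization stats) and unnormalized base embeddings.
    # The extractor's closed-form shift_scale then yields the embeddings of
    # the z-scored rendering without re-extraction.
    base_emb: dict = {fmt: {} for fmt in needed}
    moments: dict = {fmt: {} for fmt in needed}
    fast = all(
        hasattr(extractor, meth) for meth in ("extract_base", "shift_scale", "expand")
    )
    rendered_cache: dict = {}
    from .volume import prepare as _prepare

    share_prepared = {InputFormat.ORIGINAL_WP, InputFormat.NOISE} <= needed
    for vol, mask, _ in cohort:
        prepared = _prepare(vol, size=slice_size) if share_prepared else None
        for fmt in needed:
            arr = render_format(
                vol, mask, fmt, noise_criteria, size=slice_size, prepared=prepared
            )
            moments[fmt][vol.patient_id] = (
                arr.size,
                float(arr.sum()),
                float(np.square(arr).sum()),
            )
            if fast:
                base_emb[fmt][vol.patient_id] = extractor.extract_base(arr)
            else:
                rendered_cache[(fmt, vol.patient_id)] = arr

    def embeddings_for(fmt, pid, stats):
        """Pre-standardization embeddings: base descriptors on the fast
        path (expansion is applied after feature standardization so that
        small-scale descriptors are not drowned inside mixed coordinates),
        or the extractor's own output otherwise."""
        if fast:
            emb = extractor.shift_scale(base_emb[fmt][pid], stats.mean, stats.std)
        else:
            emb = extractor.extract(
                (rendered_cache[(fmt, pid)] - stats.mean) / stats.std
            )
        return emb

    fold_ids = split.folds(pids)
    cells = {
        (tf, gf): [] for tf in train_formats for gf in test_formats
    }
    for j in range(split.k):
        test_pids = [p for p, f in zip(pids, fold_ids) if f == j]
        train_pids = [p for p, f in zip(pids, fold_ids) if f != j]
        assert not set(test_pids) & set(train_pids), "fold leakage"
        fold_stats = {
            fmt: _combine_moments(moments[fmt], train_pids) for fmt in needed
        }
        for tf in train_formats:
            rng = np.random.default_rng(
                np.random.SeedSequence((cfg.seed, j, all_formats.index(tf)))
            )
            fit_pids, tune_pids = _stratified_tune_split(
                train_pids, [labels[p] for p in train_pids], tune_fraction, rng
            )
            stats = fold_stats[tf]
            fit_raw = [embeddings_for(tf, p, stats) for p in fit_pids]
            tune_raw = [embeddings_for(tf, p, stats) for p in tune_pids]
            # per-feature standardization, fit on the training patients of
            # this fold only; it is part of the trained model's input
            # pipeline and is applied to whatever test data the model is
            # later fed, regardless of test format.  On the fast path it
            # acts on base descriptors *before* the random expansion, so
            # every descriptor enters the mixture at comparable scale.
            train_stack = np.concatenate(fit_raw + tune_raw)
            fm = train_stack.mean(axis=0)
            fs = np.maximum(train_stack.std(axis=0), 1e-8)

            def _finalize(emb, pid):
                emb = (emb - fm) / fs
                if fast:
                    emb = extractor.expand(emb)
                return SliceEmbeddingSequence(
                    embeddings=emb, patient_id=pid, label=labels[pid]
                )

            fit = [_finalize(e, p) for e, p in zip(fit_raw, fit_pids)]
            tune = [_finalize(e, p) for e, p in zip(tune_raw, tune_pids)]
            fold_seed = int(rng.integers(2**31 - 1))
            fold_cfg = TrainingConfig(
                lr=cfg.lr,
                weight_decay=cfg.weight_decay,
                beta1=cfg.beta1,
                beta2=cfg.beta2,
                epochs=cfg.epochs,
                plateau_factor=cfg.plateau_factor,
                plateau_patience=cfg.plateau_patience,
                plateau_min_delta=cfg.plateau_min_delta,
                lr_floor=cfg.lr_floor,
                hidden_units=cfg.hidden_units,
                seed=fold_seed,
            )
            model = train_head(fit, tune, fold_cfg)
            for gf in test_formats:
                gstats = fold_stats[gf]
                scores = np.array(
                    [
                        predict_probability(
                            _finalize(embeddings_for(gf, p, gstats), p), model
                        )
                        for p in test_pids
                    ]
                )
                labs = np.array([labels[p] for p in test_pids], dtype=int)
                cells[(tf, gf)].append((test_pids, scores, labs))

    out_cells = {}
    for key, folds in cells.items():
        fold_results = [(scores, labs) for _, scores, labs in folds]
        est = cv_auc_ci(fold_results)
        pid_order, score_pool, label_pool = [], [], []
        for fold_pids, scores, labs in folds:
            pid_order.extend(fold_pids)
            score_pool.extend(scores)
            label_pool.extend(labs)
        order = np.argsort([pids.index(p) for p in pid_order])
        out_cells[key] = MatrixCell(
            estimate=est,
            fold_results=fold_results,
            scores=np.asarray(score_pool)[order],
            labels=np.asarray(label_pool, dtype=int)[order],
            patient_ids=[pid_order[i] for i in order],
        )
    return CrossFormatMatrix(
        train_formats=train_formats,
        test_formats=test_formats,
        cells=out_cells,
        split=split,
    )
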