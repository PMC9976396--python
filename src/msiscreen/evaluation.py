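"""ROC/AUC analysis, diagnostic thresholds, and sample-size robustness.

AUC is the probability that a random unstable sample outranks a random
stable one (ties count one half); its confidence interval uses the
DeLong structural-components estimator. Diagnostic metrics follow the
strict ``score > cutoff => positive`` rule throughout, with exact
(Clopper-Pearson) binomial intervals for sensitivity and specificity and
likelihood ratios +LR = sens/(1-spec), -LR = (1-sens)/spec.

The robustness driver repeats training on nested subsets drawn without
replacement at stated per-class train/validation sizes and scores the
untouched remainder, emulating how diagnostic labs probe the sample-size
dependence of a learned panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import binomtest, norm

from .regions import MsLocus, PipelineConfig
from .scoring import predict_from_features
from .training import (
    STABLE_LABEL,
    UNSTABLE_LABEL,
    CohortError,
    LabeledSample,
    ModelBundle,
    fit_models,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EvalMetrics",
    "BootstrapDesign",
    "roc_auc",
    "dual_thresholds",
    "diagnostic_metrics",
    "make_default_scorer",
    "bootstrap_robustness",
    "summarize_robustness",
]


@dataclass
class EvalMetrics:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    lr_pos: float  # math.inf when specificity == 1
    lr_neg: float


@dataclass
class BootstrapDesign:
    """Per-class (train_stable, train_unstable, val_stable, val_unstable) sizes."""

    sizes: list[tuple[int, int, int, int]]
    n_sim: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        for size in self.sizes:
            if len(size) != 4 or any(int(v) < 1 for v in size):
                raise ValueError(f"invalid design size {size!r}")

    @staticmethod
    def label(size: tuple[int, int, int, int]) -> str:
        ts, tu, vs, vu = size
        return f"{ts}-{tu}:{vs}-{vu}"


def _check_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("both classes required")


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged) - the DeLong building block."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def roc_auc(
    scores: Sequence[float], labels: Sequence[int], alpha: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong confidence interval.

    ``labels`` are 1 for the positive (unstable) class. The point
    estimate is the tie-aware pairwise probability, identical to the
    trapezoidal ROC area.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_classes(y)
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(scores)
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[y].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[y] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[~y] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = math.sqrt(max(var, 0.0))
    z = norm.ppf(0.5 + alpha / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


def dual_thresholds(
    scores: Sequence[float],
    labels: Sequence[int],
    target_spec: float = 0.95,
) -> tuple[float, float]:
    """Rule-out / rule-in cutoffs at the target specificity.

    ``high`` is the smallest observed cutoff above which a positive call
    has specificity >= target (few stable samples exceed it); ``low`` is
    the largest observed cutoff below which ruling out misses at most
    (1-target) of unstable samples (sensitivity above it >= target).
    Scores between the two form the gray zone. ``low <= high`` is
    enforced by clamping with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_classes(y)
    if not 0 < target_spec <= 1:
        raise ValueError("target_spec must be in (0, 1]")
    pos, neg = scores[y], scores[~y]
    cands = np.unique(scores)
    spec = np.array([(neg <= c).mean() for c in cands])
    sens = np.array([(pos > c).mean() for c in cands])
    high_ok = np.flatnonzero(spec >= target_spec)
    low_ok = np.flatnonzero(sens >= target_spec)
    if not len(high_ok):
        raise ValueError(
            f"rule-in specificity {target_spec} unattainable; maximum achievable "
            f"is {spec.max():.3f}"
        )
    if not len(low_ok):
        raise ValueError(
            f"rule-out target {target_spec} unattainable; maximum achievable "
            f"sensitivity below any cutoff is {sens.max():.3f}"
        )
    high = float(cands[high_ok[0]])
    low = float(cands[low_ok[-1]])
    if low > high:
        logger.warning("rule-out cutoff %.4f above rule-in cutoff %.4f; clamping",
                       low, high)
        low = high
    return low, high


def diagnostic_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    cutoff: float,
    alpha: float = 0.95,
) -> EvalMetrics:
    """Sensitivity/specificity/LRs at a cutoff (positive iff score > cutoff)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_classes(y)
    pos, neg = scores[y], scores[~y]
    tp = int((pos > cutoff).sum())
    tn = int((neg <= cutoff).sum())
    sens = tp / len(pos)
    spec = tn / len(neg)
    sens_ci = binomtest(tp, len(pos)).proportion_ci(confidence_level=alpha, method="exact")
    spec_ci = binomtest(tn, len(neg)).proportion_ci(confidence_level=alpha, method="exact")
    lr_pos = math.inf if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = math.inf if spec == 0.0 else (1.0 - sens) / spec
    auc, (ci_lo, ci_hi) = roc_auc(scores, labels, alpha=alpha)
    return EvalMetrics(
        auc=auc,
        auc_ci_low=ci_lo,
        auc_ci_high=ci_hi,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        sens_ci=(sens_ci.low, sens_ci.high),
        spec_ci=(spec_ci.low, spec_ci.high),
        lr_pos=lr_pos,
        lr_neg=lr_neg,
    )


Scorer = Callable[
    [Sequence[LabeledSample], Sequence[LabeledSample], Sequence[LabeledSample], int],
    float,
]


def make_default_scorer(panel: list[MsLocus], config: PipelineConfig) -> Scorer:
    """Scorer closure: retrain the combined-voting pair on (train, validation),
    score the evaluation samples, return the combined-score AUC."""

    def scorer(train, validation, evaluation, seed: int) -> float:
        pairs, baselines = fit_models(train, validation, panel, config, seed)
        if not any(p.retained for p in pairs.values()):
            raise CohortError("no locus retained in bootstrap replicate")
        b = ModelBundle(panel=panel, config=config, pairs=pairs,
                        split={}, baselines=baselines, seed=seed)
        scores, labels = [], []
        for s in evaluation:
            result = predict_from_features(s.sample_id, s.features, b)
            scores.append(result.score.score_combined)
            labels.append(1 if s.is_unstable else 0)
        auc, _ = roc_auc(scores, labels)
        return auc

    return scorer


def bootstrap_robustness(
    cohort: Sequence[LabeledSample],
    design: BootstrapDesign,
    scorer: Scorer,
) -> dict[str, np.ndarray]:
    """Per-size AUC distributions over repeated subset draws.

    Each simulation draws the stated per-class train and validation
    counts without replacement, retrains via ``scorer``, and evaluates on
    the untouched remainder. Deterministic for a fixed design seed.
    """
    stable = [s for s in cohort if s.label == STABLE_LABEL]
    unstable = [s for s in cohort if s.label == UNSTABLE_LABEL]
    rng = np.random.default_rng(design.seed)
    results: dict[str, np.ndarray] = {}
    for size in design.sizes:
        ts, tu, vs, vu = size
        label = BootstrapDesign.label(size)
        if ts + vs >= len(stable) or tu + vu >= len(unstable):
            logger.warning(
                "design %s infeasible for cohort of %d stable / %d unstable; skipped",
                label, len(stable), len(unstable),
            )
            continue
        aucs = []
        for _ in range(design.n_sim):
            sim_seed = int(rng.integers(2**31))
            r = np.random.default_rng(sim_seed)
            s_perm = [stable[i] for i in r.permutation(len(stable))]
            u_perm = [unstable[i] for i in r.permutation(len(unstable))]
            train = s_perm[:ts] + u_perm[:tu]
            validation = s_perm[ts:ts + vs] + u_perm[tu:tu + vu]
            remainder = s_perm[ts + vs:] + u_perm[tu + vu:]
            aucs.append(scorer(train, validation, remainder, sim_seed))
        results[label] = np.asarray(aucs)
    return results


def summarize_robustness(results: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    """Mean/median/quartiles per design size."""
    return {
        label: {
            "n_sim": int(len(aucs)),
            "mean": float(np.mean(aucs)),
            "median": float(np.median(aucs)),
            "q25": float(np.percentile(aucs, 25)),
            "q75": float(np.percentile(aucs, 75)),
        }
        for label, aucs in results.items()
    }
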