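"""Sample-level prediction: per-locus voting, sample score, classification.

Each evaluable retained locus gets two binary calls (logistic regression
and SVC); the combined call is unstable only when *both* models agree on
instability. The sample score is, per model, the fraction of evaluable
loci called unstable; classification uses the combined score with either
a single binary cutoff (MSI iff score > cutoff, strict) or dual
rule-out/rule-in cutoffs separated by a gray zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .features import FeatureVector, extract_sample
from .regions import ThresholdConfig
from .training import LocusModelPair, ModelBundle, instability_call

logger = logging.getLogger(__name__)

__all__ = [
    "LocusCall",
    "SampleScore",
    "SampleResult",
    "ScoringError",
    "call_locus",
    "sample_score",
    "classify",
    "predict_from_features",
    "predict_sample",
    "write_sample_result",
    "plot_locus",
    "plot_sample",
]


class ScoringError(RuntimeError):
    """Sample cannot be scored (e.g. no evaluable locus)."""


@dataclass
class LocusCall:
    locus_name: str
    evaluable: bool
    call_logreg: Optional[bool] = None  # True = unstable
    call_svc: Optional[bool] = None
    call_combined: Optional[bool] = None


@dataclass
class SampleScore:
    score_logreg: float
    score_svc: float
    score_combined: float
    n_evaluable: int
    n_unstable_logreg: int
    n_unstable_svc: int
    n_unstable_combined: int


@dataclass
class SampleResult:
    sample_id: str
    calls: list[LocusCall]
    score: SampleScore
    classification: str  # MSS | GRAY | MSI
    low_confidence: bool
    bundle_version: str


def call_locus(pair: LocusModelPair, fv: FeatureVector) -> LocusCall:
    """Dual-model vote at one locus; combined = AND on 'unstable'."""
    if not fv.evaluable or fv.values is None:
        return LocusCall(pair.locus_name, evaluable=False)
    X = np.asarray(fv.values, dtype=float).reshape(1, -1)
    lr = bool(instability_call(pair.model_logreg, X)[0])
    svc = bool(instability_call(pair.model_svc, X)[0])
    return LocusCall(
        pair.locus_name,
        evaluable=True,
        call_logreg=lr,
        call_svc=svc,
        call_combined=lr and svc,
    )


def sample_score(calls: Sequence[LocusCall]) -> SampleScore:
    """Fraction of evaluable loci called unstable, per model and combined."""
    evaluable = [c for c in calls if c.evaluable]
    if not evaluable:
        raise ScoringError("sample not scoreable: zero evaluable loci")
    n = len(evaluable)
    n_lr = sum(c.call_logreg for c in evaluable)
    n_svc = sum(c.call_svc for c in evaluable)
    n_comb = sum(c.call_combined for c in evaluable)
    return SampleScore(
        score_logreg=n_lr / n,
        score_svc=n_svc / n,
        score_combined=n_comb / n,
        n_evaluable=n,
        n_unstable_logreg=n_lr,
        n_unstable_svc=n_svc,
        n_unstable_combined=n_comb,
    )


def classify(score: SampleScore, thresholds: ThresholdConfig) -> str:
    """MSS/GRAY/MSI from the combined score; cutoffs are strict '>' / '<'."""
    s = score.score_combined
    if thresholds.mode == "binary":
        return "MSI" if s > thresholds.binary_cutoff else "MSS"
    if s < thresholds.low:
        return "MSS"
    if s > thresholds.high:
        return "MSI"
    return "GRAY"


def _default_min_evaluable(bundle: ModelBundle) -> int:
    n = len(bundle.retained_loci)
    return max(1, n // 2)


def predict_from_features(
    sample_id: str, features: dict[str, FeatureVector], bundle: ModelBundle
) -> SampleResult:
    """Score one sample from already-extracted feature vectors."""
    calls: list[LocusCall] = []
    for name in bundle.retained_loci:
        pair = bundle.pairs[name]
        fv = features.get(name)
        if fv is None:
            calls.append(LocusCall(name, evaluable=False))
            continue
        try:
            calls.append(call_locus(pair, fv))
        except Exception:
            logger.warning("%s: locus %s failed scoring; marked non-evaluable",
                           sample_id, name, exc_info=True)
            calls.append(LocusCall(name, evaluable=False))
    score = sample_score(calls)
    min_eval = bundle.config.min_evaluable_loci or _default_min_evaluable(bundle)
    return SampleResult(
        sample_id=sample_id,
        calls=calls,
        score=score,
        classification=classify(score, bundle.config.thresholds),
        low_confidence=score.n_evaluable < min_eval,
        bundle_version=bundle.version,
    )


def predict_sample(bam_path: str | Path, bundle: ModelBundle) -> SampleResult:
    """Full pipeline on a BAM using the bundle's own config snapshot."""
    bam_path = Path(bam_path)
    features = extract_sample(bam_path, bundle.panel, bundle.config)
    return predict_from_features(bam_path.stem, features, bundle)


def write_sample_result(result: SampleResult, out_dir: str | Path) -> None:
    """One-row summary TSV plus a per-locus call table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    s = result.score
    with open(out_dir / f"{result.sample_id}.summary.tsv", "w") as fh:
        fh.write(
            "sample_id\tn_evaluable\tscore_logreg\tscore_svc\tscore_combined\t"
            "classification\tlow_confidence\n"
        )
        fh.write(
            f"{result.sample_id}\t{s.n_evaluable}\t{s.score_logreg:.4f}\t"
            f"{s.score_svc:.4f}\t{s.score_combined:.4f}\t{result.classification}\t"
            f"{int(result.low_confidence)}\n"
        )
    with open(out_dir / f"{result.sample_id}.loci.tsv", "w") as fh:
        fh.write("locus\tevaluable\tcall_logreg\tcall_svc\tcall_combined\n")
        for c in result.calls:
            if c.evaluable:
                fh.write(
                    f"{c.locus_name}\t1\t{int(c.call_logreg)}\t{int(c.call_svc)}\t"
                    f"{int(c.call_combined)}\n"
                )
            else:
                fh.write(f"{c.locus_name}\t0\tNA\tNA\tNA\n")


def plot_locus(
    fv: FeatureVector,
    baseline: Optional[np.ndarray],
    out_path: str | Path,
    window: int,
) -> Path:
    """Render one locus: stable-baseline envelope with the sample profile on top.

    The baseline rows are the max-normalized profiles of every stable
    training sample at this locus; the x-axis is the length offset from
    the reference tract length.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    offsets = np.arange(-window, window + 1)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    if not fv.evaluable or fv.values is None:
        ax.text(0.5, 0.5, f"{fv.locus_name}\ninsufficient depth ({fv.depth} reads)",
                ha="center", va="center", transform=ax.transAxes)
        ax.set_axis_off()
    else:
        if baseline is not None and len(baseline):
            lo = baseline.min(axis=0)
            hi = baseline.max(axis=0)
            ax.fill_between(offsets, lo, hi, color="0.8", label="stable baseline")
        else:
            logger.warning("%s: empty baseline; plotting sample alone", fv.locus_name)
        ax.plot(offsets, fv.values, color="C0", marker="o", ms=3, label="sample")
        ax.set_xlabel("length offset (bases)")
        ax.set_ylabel("normalized depth")
        ax.set_title(fv.locus_name)
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


def plot_sample(
    result: SampleResult,
    features: dict[str, FeatureVector],
    bundle: ModelBundle,
    out_dir: str | Path,
    fmt: str = "png",
) -> Path:
    """One image per retained locus plus an index page; returns the index path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    window = bundle.config.window
    lines = [f"# {result.sample_id} - locus plots", ""]
    for name in bundle.retained_loci:
        fv = features.get(name) or FeatureVector(name, None, False, 0)
        img = out_dir / f"{result.sample_id}.{name}.{fmt}"
        plot_locus(fv, bundle.baselines.get(name), img, window)
        lines.append(f"- [{name}]({img.name})")
    index = out_dir / f"{result.sample_id}.index.md"
    index.write_text("\n".join(lines) + "\n")
    return index
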