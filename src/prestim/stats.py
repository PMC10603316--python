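"""Benchmark-comparison statistics for static and time-resolved decoding.

Each classifier's repeated-CV accuracies are compared against the random
benchmark's with a right-tailed two-sample Student t-test (pooled variance,
df = n1 + n2 - 2; with 10 + 10 CV repeats this is the familiar t(18)). For
time-resolved decoding the per-segment p-value sequence of each classifier
is Bonferroni-Holm corrected, and the *best accuracy point* is the left
extreme of the sliding window achieving the highest corrected-significant
accuracy.

The CV repeats are treated as independent samples, as is conventional in
this comparison design; the optimism of that assumption (repeats share
data) is a known caveat, not something this module corrects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .classification import CVResult, DynamicResult

__all__ = [
    "TestResult",
    "BestPoint",
    "t_test_right",
    "holm_correct",
    "best_accuracy_point",
    "benchmark_static",
    "benchmark_dynamic",
    "accuracy_time_correlation",
]

ALPHA = 0.05


@dataclass
class TestResult:
    t_stat: float
    df: int
    p_raw: float
    p_corrected: float
    significant: bool


@dataclass
class BestPoint:
    segment_index: int
    time_s: float
    accuracy: float


def t_test_right(sample_a: np.ndarray, sample_b: np.ndarray,
                 alpha: float = ALPHA) -> TestResult:
    """Right-tailed pooled-variance two-sample t-test (H1: mean_a > mean_b).

    Degenerate zero-variance inputs follow a sign convention rather than
    producing NaN: equal means give p = 0.5, unequal means give p = 0 or 1
    according to the direction of the difference.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        diff = a.mean() - b.mean()
        if diff == 0:
            t, p = 0.0, 0.5
        else:
            t = np.inf if diff > 0 else -np.inf
            p = 0.0 if diff > 0 else 1.0
    else:
        t, p = scipy.stats.ttest_ind(a, b, equal_var=True, alternative="greater")
        t, p = float(t), float(p)
    return TestResult(t_stat=t, df=df, p_raw=p, p_corrected=p, significant=p < alpha)


def holm_correct(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, order-preserving.

    The i-th smallest p-value is multiplied by (m - i + 1), the running
    maximum enforced, values capped at 1, and the result returned in the
    original order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def best_accuracy_point(mean_acc: np.ndarray, p_corrected: np.ndarray,
                        times: np.ndarray, alpha: float = ALPHA) -> BestPoint | None:
    """Highest corrected-significant accuracy; ties go to the earliest window.

    Returns ``None`` when no segment survives correction.
    """
    mean_acc = np.asarray(mean_acc, dtype=float)
    p_corrected = np.asarray(p_corrected, dtype=float)
    times = np.asarray(times, dtype=float)
    if not mean_acc.shape == p_corrected.shape == times.shape:
        raise ValueError("mean_acc, p_corrected and times must have equal length")
    sig = p_corrected < alpha
    if not sig.any():
        return None
    idx = np.flatnonzero(sig)
    best = idx[np.argmax(mean_acc[idx])]  # argmax takes the first max: earliest time
    return BestPoint(segment_index=int(best), time_s=float(times[best]),
                     accuracy=float(mean_acc[best]))


def benchmark_static(cv: CVResult, benchmark_kind: str = "RANDOM",
                     alpha: float = ALPHA) -> dict[str, TestResult]:
    """Compare each classifier's repeat accuracies against the benchmark's."""
    if benchmark_kind not in cv.classifier_kinds:
        raise ValueError(f"benchmark {benchmark_kind!r} not present in CVResult")
    bench = cv.mean_accuracy[:, cv.classifier_kinds.index(benchmark_kind)]
    out = {}
    for c, kind in enumerate(cv.classifier_kinds):
        if kind == benchmark_kind:
            continue
        out[kind] = t_test_right(cv.mean_accuracy[:, c], bench, alpha=alpha)
    return out


def benchmark_dynamic(dyn: DynamicResult, benchmark_kind: str = "RANDOM",
                      alpha: float = ALPHA) -> DynamicResult:
    """Segment-by-segment benchmark comparison with Holm correction.

    For every non-benchmark classifier, each segment's 10 repeat accuracies
    are tested against the benchmark's for the same segment; the raw
    p-value sequence is Holm-corrected *within that classifier's sequence*
    (no cross-classifier correction), and the best accuracy point detected.
    Fills ``p_corrected`` (classifiers x segments; the benchmark row is NaN)
    and ``best_points`` on a copy of the input.
    """
    kinds = dyn.classifier_kinds
    if benchmark_kind not in kinds:
        raise ValueError(f"benchmark {benchmark_kind!r} not present")
    b = kinds.index(benchmark_kind)
    n_class, _, n_seg = dyn.acc_sequences.shape
    p_corr = np.full((n_class, n_seg), np.nan)
    best: dict[str, BestPoint | None] = {}
    for c, kind in enumerate(kinds):
        if c == b:
            continue
        p_raw = np.array([
            t_test_right(dyn.acc_sequences[c, :, i], dyn.acc_sequences[b, :, i]).p_raw
            for i in range(n_seg)
        ])
        p_corr[c] = holm_correct(p_raw)
        mean_seq = dyn.acc_sequences[c].mean(axis=0)
        best[kind] = best_accuracy_point(mean_seq, p_corr[c], dyn.segment_times,
                                         alpha=alpha)
    return DynamicResult(acc_sequences=dyn.acc_sequences,
                         segment_times=dyn.segment_times,
                         classifier_kinds=kinds, seed=dyn.seed,
                         p_corrected=p_corr, best_points=best)


def accuracy_time_correlation(accuracies: np.ndarray, times: np.ndarray):
    """Spearman correlation between best accuracies and their window times.

    Convenience summary over a table of significant time-resolved results;
    returns ``(rho, p_value)``.
    """
    rho, p = scipy.stats.spearmanr(np.asarray(accuracies, dtype=float),
                                   np.asarray(times, dtype=float))
    return float(rho), float(p)
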