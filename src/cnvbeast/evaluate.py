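"""Partial-overlap sensitivity/FDR metrics, FDR-by-score curves, and
Monte-Carlo max-score significance testing.

Definitions (closed bp intervals; any shared base pair counts as overlap):

* sensitivity — the number of true intervals that overlap at least
  partially with any call, divided by the number of true intervals;
  computed over ALL calls regardless of length.
* FDR — among calls whose bp length exceeds ``min_len_bp`` (default
  6,000), the fraction that overlap no true interval.  Short calls are
  excluded because a fair false-discovery comparison across callers needs
  a common minimum reportable length.  An empty filtered call set yields
  an undefined (None) FDR, never a spurious 0.

Because the score is univariate, genome-scan significance can be assessed
by Monte Carlo: run the full caller on replicate datasets known to carry
no signal, record the largest score per replicate (0 when nothing is
called), and use that null max-score distribution to assign p-values to
observed calls with the add-one convention p = (1 + #{max >= s}) / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .calls import CNVCall

__all__ = [
    "EvalResult",
    "overlap_stats",
    "fdr_by_score",
    "mc_max_score_test",
    "validation_tally",
]

Interval = tuple[str, int, int]


def _as_intervals(items) -> list[Interval]:
    out = []
    for it in items:
        if isinstance(it, CNVCall):
            out.append((it.chrom, it.start_bp, it.end_bp))
        else:
            chrom, start, end = it[0], int(it[1]), int(it[2])
            out.append((str(chrom), start, end))
    return out


class _OverlapIndex:
    """Sorted-sweep overlap queries against a fixed interval set."""

    def __init__(self, intervals: Sequence[Interval]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        chroms: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            chroms.setdefault(chrom, []).append((s, e))
        for chrom, ivs in chroms.items():
            ivs.sort()
            starts = np.array([s for s, _ in ivs], dtype=np.int64)
            ends = np.maximum.accumulate(np.array([e for _, e in ivs], dtype=np.int64))
            self.by_chrom[chrom] = (starts, ends)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.by_chrom:
            return False
        starts, cummax_ends = self.by_chrom[chrom]
        i = int(np.searchsorted(starts, end, side="right"))
        return i > 0 and cummax_ends[i - 1] >= start


@dataclass
class EvalResult:
    n_calls: int
    n_truth: int
    n_calls_over_len: int
    n_false_over_len: int
    n_truth_found: int
    sensitivity: float
    fdr: float | None
    curve: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_calls": self.n_calls,
            "n_truth": self.n_truth,
            "n_calls_over_len": self.n_calls_over_len,
            "n_false_over_len": self.n_false_over_len,
            "n_truth_found": self.n_truth_found,
            "sensitivity": self.sensitivity,
            "fdr": self.fdr,
            "curve": self.curve,
        }


def overlap_stats(calls, truth, min_len_bp: int = 6000) -> EvalResult:
    """Sensitivity over all calls; FDR over calls longer than min_len_bp."""
    call_iv = _as_intervals(calls)
    truth_iv = _as_intervals(truth)
    call_idx = _OverlapIndex(call_iv)
    truth_idx = _OverlapIndex(truth_iv)

    n_found = sum(1 for c, s, e in truth_iv if call_idx.overlaps(c, s, e))
    sens = n_found / len(truth_iv) if truth_iv else float("nan")

    long_calls = [(c, s, e) for c, s, e in call_iv if e - s + 1 > min_len_bp]
    n_false = sum(1 for c, s, e in long_calls if not truth_idx.overlaps(c, s, e))
    fdr = n_false / len(long_calls) if long_calls else None
    return EvalResult(
        n_calls=len(call_iv),
        n_truth=len(truth_iv),
        n_calls_over_len=len(long_calls),
        n_false_over_len=n_false,
        n_truth_found=n_found,
        sensitivity=sens,
        fdr=fdr,
    )


def fdr_by_score(
    calls: Sequence[CNVCall],
    truth,
    thresholds: Iterable[float],
    min_len_bp: int = 6000,
) -> list[dict]:
    """Empirical FDR curve: for each threshold t, FDR among calls with
    score > t (and length > min_len_bp) plus the count of true intervals
    found by the score-filtered calls."""
    out = []
    for t in thresholds:
        sub = [c for c in calls if c.score > t]
        res = overlap_stats(sub, truth, min_len_bp)
        out.append(
            {
                "threshold": float(t),
                "n_calls": res.n_calls,
                "n_calls_over_len": res.n_calls_over_len,
                "fdr": res.fdr,
                "n_truth_found": res.n_truth_found,
            }
        )
    return out


def mc_max_score_test(
    null_scores: Callable[[int], Iterable[float]],
    B: int,
    observed_scores: Sequence[float],
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo p-values for observed max-type scores.

    ``null_scores(seed_b)`` must run the caller on one signal-free
    replicate and return the scores of its calls (possibly empty).  The
    null statistic per replicate is the largest score (0 if none); the
    p-value of an observed score s is (1 + #{max_b >= s}) / (B + 1).
    """
    if B < 19:
        raise ValueError("need at least 19 null replicates")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=B)
    maxima = np.empty(B)
    for b, sb in enumerate(child_seeds):
        scores = list(null_scores(int(sb)))
        maxima[b] = max(scores) if scores else 0.0
    obs = np.asarray(observed_scores, dtype=float)
    counts = np.array([(maxima >= s).sum() for s in obs])
    return (1.0 + counts) / (B + 1.0)


def validation_tally(
    detected_true: int, missed_true: int, detected_false: int, missed_false: int
) -> dict:
    """Summary statistics for a 2x2 detection-by-validation contingency
    table of calls with known experimental validation status.

    Rows: validated true/false; columns: detected/missed by the caller.
    """
    for v in (detected_true, missed_true, detected_false, missed_false):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    n_total = detected_true + missed_true + detected_false + missed_false
    n_detected = detected_true + detected_false
    n_missed = missed_true + missed_false
    n_true = detected_true + missed_true
    return {
        "n_total": n_total,
        "n_true": n_true,
        "n_detected": n_detected,
        "n_missed": n_missed,
        "pct_detected": 100.0 * n_detected / n_total if n_total else float("nan"),
        "pct_missed_invalid": 100.0 * missed_false / n_missed if n_missed else float("nan"),
        "pct_detected_valid": 100.0 * detected_true / n_detected if n_detected else float("nan"),
    }
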