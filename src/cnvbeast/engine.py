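"""Backward-elimination step-function regression for CNV calling.

The model: normalized LIR values y_1..y_N on one chromosome are fit by a
step function written as a sum of jump terms,

    y_i ~ sum_j beta(k_j) * I(i > k_j),

where a jump at k (k in 0..N-1) sits between probe k and probe k+1 and
beta(k) is the change in fitted level across it.  The jump at k = 0 plays
the role of an intercept: with it removed, the leading segment is pinned at
the outside baseline 0, which is what "no CNV before the first retained
jump" means for centered/normalized data.  Under the L1 objective
sum_i |y_i - yhat_i| each free segment's fitted level is the median of its
y values, and the fitted height of a jump is the difference of the two
flanking segment medians — so removing one jump only changes the two
neighboring coefficients, which is what makes backward elimination from the
saturated model (a jump at every probe) cheap.

Elimination order: each active jump k has a gap g_k = distance in probes to
its nearest active neighbor (track edges 0 and N act as sentinels), and a
priority delta(k) = |beta(k)| * g_k^alpha - C(g_k), negative exactly when
the jump fails the retention criterion.  The most negative delta is removed
first, subject to an override for adjacent same-direction jumps (see
:func:`JumpModel.select_removal`) that protects the outer boundary of a CNV
whose edge is split across two steps.  Elimination stops when every active
jump has delta >= 0.

The cleanup pass re-runs elimination with fitted levels truncated to 0
whenever their magnitude is below mu_min, forcing the final fit to return
to baseline between calls; consolidation then turns maximal same-sign
nonzero runs of segments into CNV calls.
"""

from __future__ import annotations

import heapq
from typing import Literal, Sequence

import numpy as np

from .calls import CNVCall, ProbeTrack
from .score import CutoffParams, cutoff

__all__ = [
    "JumpModel",
    "init_saturated",
    "segment_level",
    "backward_eliminate",
    "cleanup",
    "consolidate",
    "call_track",
]

#: fitted levels smaller than this in magnitude are treated as exactly zero
ZERO_TOL = 1e-12


def _median(y: np.ndarray, lo: int, hi: int) -> float:
    """Median of y[lo:hi] (0-based, half-open); even counts use the
    mid-mean of the two central order statistics."""
    n = hi - lo
    if n <= 0:
        raise ValueError("empty segment")
    if n == 1:
        return float(y[lo])
    if n == 2:
        return float(0.5 * (y[lo] + y[lo + 1]))
    return float(np.median(y[lo:hi]))


def _mean(y: np.ndarray, lo: int, hi: int) -> float:
    if hi - lo <= 0:
        raise ValueError("empty segment")
    return float(np.mean(y[lo:hi]))


def segment_level(track: ProbeTrack, lo: int, hi: int) -> float:
    """L1-fitted level (median) of probes lo..hi, 1-based inclusive."""
    if not (1 <= lo <= hi <= track.N):
        raise ValueError(f"invalid probe range {lo}..{hi} for N={track.N}")
    return _median(track.lir, lo - 1, hi)


class JumpModel:
    """Active set of step-function jumps over one track, with incremental
    removal updates.

    State per active jump k: the fitted level of the segment to its right
    (``level_r``), its height ``beta`` (right level minus left level, where
    the level left of the leftmost jump is the baseline 0), its gap ``g``
    and its priority ``delta``.  A removal merges the two flanking segments
    and refreshes only the two neighboring jumps; a heap with lazy
    invalidation keeps the next removal candidate at hand.

    ``truncate=True`` switches on the cleanup estimator: heights and
    priorities are computed from truncated levels T(x) = x if |x| >= mu_min
    else 0, so plateaus below the intensity floor are treated as baseline.
    """

    def __init__(
        self,
        y: np.ndarray,
        params: CutoffParams,
        jumps: Sequence[int] | None = None,
        truncate: bool = False,
        objective: Literal["l1", "l2"] = "l1",
    ) -> None:
        y = np.ascontiguousarray(y, dtype=float)
        N = y.size
        if N < 2:
            raise ValueError("need at least 2 probes")
        self.y = y
        self.N = N
        self.params = params
        self.truncate = truncate
        self._level_fn = _median if objective == "l1" else _mean
        self.objective = objective

        if jumps is None:
            ks = list(range(N))
        else:
            ks = sorted(set(int(k) for k in jumps))
            if ks and (ks[0] < 0 or ks[-1] >= N):
                raise ValueError("jump positions must lie in 0..N-1")

        self.active = [False] * N
        self.prv = [-1] * N
        self.nxt = [-1] * N
        self.level_r = [0.0] * N
        self.beta = [0.0] * N
        self.gap = [0] * N
        self.delta = [0.0] * N
        self._ver = [0] * N
        self._heap: list[tuple[int, float, int, int]] = []
        self.n_active = len(ks)
        self.n_removed = 0

        prev = -1
        for k in ks:
            self.active[k] = True
            self.prv[k] = prev
            if prev >= 0:
                self.nxt[prev] = k
            prev = k
        for k in ks:
            end = self.nxt[k] if self.nxt[k] >= 0 else N
            self.level_r[k] = self._level_fn(y, k, end)
        for k in ks:
            self._refresh(k)

    # -- level helpers -------------------------------------------------

    def _trunc(self, x: float) -> float:
        if self.truncate and abs(x) < self.params.mu_min:
            return 0.0
        return x

    def _left_level(self, k: int) -> float:
        p = self.prv[k]
        return self.level_r[p] if p >= 0 else 0.0

    def _eff_beta(self, k: int) -> float:
        return self._trunc(self.level_r[k]) - self._trunc(self._left_level(k))

    def _gap(self, k: int) -> int:
        p, n = self.prv[k], self.nxt[k]
        right = (n if n >= 0 else self.N) - k
        if k == 0:
            return right  # left of jump 0 is the unbounded outside baseline
        left = k - (p if p >= 0 else 0)
        return min(left, right)

    def _refresh(self, k: int) -> None:
        """Recompute beta/gap/delta of active jump k and (re)queue it."""
        b = self._eff_beta(k)
        g = self._gap(k)
        self.beta[k] = self.level_r[k] - self._left_level(k)
        self.gap[k] = g
        sc = abs(b) * g**self.params.alpha
        c = cutoff(g, self.params)
        self.delta[k] = sc - c
        self._ver[k] += 1
        if g < self.params.m_min:
            # wall branch: delta = sc - big_M; ordering by sc keeps the
            # score term from being rounded away against big_M in float64
            entry = (0, sc, k, self._ver[k])
        else:
            entry = (1, sc - c, k, self._ver[k])
        heapq.heappush(self._heap, entry)

    # -- queries -------------------------------------------------------

    def active_jumps(self) -> list[int]:
        ks = []
        k = next((i for i in range(self.N) if self.active[i]), -1)
        # find leftmost by walking from any active via prv? cheaper: scan
        if k < 0:
            return ks
        while self.prv[k] >= 0:
            k = self.prv[k]
        while k >= 0:
            ks.append(k)
            k = self.nxt[k]
        return ks

    def segments(self, apply_truncation: bool | None = None):
        """Yield (start_probe, end_probe, level) with 1-based inclusive
        probe ranges covering the whole track; the segment left of the
        leftmost jump (if any) is the baseline-0 segment."""
        if apply_truncation is None:
            apply_truncation = self.truncate
        T = (lambda x: x if abs(x) >= self.params.mu_min else 0.0) if apply_truncation else (lambda x: x)
        ks = self.active_jumps()
        if not ks:
            yield (1, self.N, 0.0)
            return
        if ks[0] > 0:
            yield (1, ks[0], 0.0)
        for i, k in enumerate(ks):
            end = ks[i + 1] if i + 1 < len(ks) else self.N
            yield (k + 1, end, T(self.level_r[k]))

    def fitted_values(self, apply_truncation: bool | None = None) -> np.ndarray:
        out = np.empty(self.N)
        for lo, hi, lev in self.segments(apply_truncation):
            out[lo - 1 : hi] = lev
        return out

    # -- elimination ---------------------------------------------------

    def _peek(self):
        while self._heap:
            wall, val, k, ver = self._heap[0]
            if self.active[k] and ver == self._ver[k]:
                return wall, val, k
            heapq.heappop(self._heap)
        return None

    def select_removal(self) -> int | None:
        """Next jump to remove, or None when every jump satisfies the
        retention criterion.

        The base candidate k* is the active jump with the most negative
        delta (leftmost on ties).  Adjacent same-direction override: with L
        and R the fitted levels flanking a jump, a jump moves away from
        zero if |R| > |L| and toward zero if |R| < |L|.  If k* and its
        right neighbor carry same-sign heights and both move away from
        zero, the neighbor is removed instead (keep the outer left edge of
        a rising flank); symmetrically, if k* and its left neighbor carry
        same-sign heights and both move toward zero, the left neighbor is
        removed instead (keep the outer right edge of a falling flank).
        Either clause additionally requires the level of the segment
        between the paired jumps to reach mu_min in magnitude, so the
        override engages on split CNV flanks but not on baseline noise.
        """
        top = self._peek()
        if top is None:
            return None
        wall, val, k = top
        if wall == 1 and val >= 0.0:
            return None
        return self._override(k)

    def _override(self, k: int) -> int:
        # The middle-level gate: the segment between the paired jumps must
        # itself be of CNV-grade intensity (|level| >= mu_min).  Without it
        # the override fires on ordinary noise jumps flanking a true
        # boundary and ratchets the boundary outward, absorbing baseline
        # probes into the call until it dissolves; with it the override
        # still protects genuine split flanks, whose intervening shoulder
        # sits at CNV-like level.
        bk = self._eff_beta(k)
        n = self.nxt[k]
        if n >= 0 and abs(self.level_r[k]) >= self.params.mu_min:
            bn = self._eff_beta(n)
            if bk * bn > 0 and self._moves_away(k) and self._moves_away(n):
                return n
        p = self.prv[k]
        if p >= 0 and abs(self.level_r[p]) >= self.params.mu_min:
            bp = self._eff_beta(p)
            if bk * bp > 0 and self._moves_toward(k) and self._moves_toward(p):
                return p
        return k

    def _moves_away(self, k: int) -> bool:
        return abs(self._trunc(self.level_r[k])) > abs(self._trunc(self._left_level(k)))

    def _moves_toward(self, k: int) -> bool:
        return abs(self._trunc(self.level_r[k])) < abs(self._trunc(self._left_level(k)))

    def remove_jump(self, k: int) -> None:
        """Remove active jump k, merge its flanking segments, and refresh
        the two neighboring jumps; all other state is untouched."""
        if not (0 <= k < self.N) or not self.active[k]:
            raise ValueError(f"jump {k} is not active")
        p, n = self.prv[k], self.nxt[k]
        self.active[k] = False
        self._ver[k] += 1
        self.n_active -= 1
        self.n_removed += 1
        if p >= 0:
            self.nxt[p] = n
        if n >= 0:
            self.prv[n] = p
        if p >= 0:
            end = n if n >= 0 else self.N
            self.level_r[p] = self._level_fn(self.y, p, end)
            self._refresh(p)
        # if p < 0 the merged region joins the baseline-0 leading segment
        if n >= 0:
            self._refresh(n)

    def eliminate(self) -> "JumpModel":
        """Run removals until every active jump satisfies delta >= 0."""
        while True:
            k = self.select_removal()
            if k is None:
                return self
            self.remove_jump(k)


def init_saturated(
    track: ProbeTrack, params: CutoffParams, objective: Literal["l1", "l2"] = "l1"
) -> JumpModel:
    """Saturated model: one jump before every probe; the fit reproduces
    the data exactly (beta(0) = y_1, beta(k) = y_{k+1} - y_k)."""
    return JumpModel(track.lir, params, jumps=None, objective=objective)


def backward_eliminate(
    track: ProbeTrack,
    params: CutoffParams,
    init_jumps: Sequence[int] | None = None,
    objective: Literal["l1", "l2"] = "l1",
) -> JumpModel:
    """Backward elimination from the saturated model (or from a supplied
    candidate jump set) to termination."""
    model = JumpModel(track.lir, params, jumps=init_jumps, objective=objective)
    return model.eliminate()


def cleanup(
    track: ProbeTrack, model: JumpModel, params: CutoffParams
) -> JumpModel:
    """Re-run elimination over the surviving jumps with the truncated
    level estimator, so every final fitted level is 0 or at least mu_min
    in magnitude."""
    m2 = JumpModel(
        track.lir,
        params,
        jumps=model.active_jumps(),
        truncate=True,
        objective=model.objective,
    )
    return m2.eliminate()


def consolidate(
    track: ProbeTrack, model: JumpModel, params: CutoffParams
) -> list[CNVCall]:
    """Turn the cleaned-up fit into CNV calls.

    Maximal runs of consecutive segments with nonzero (truncated) level and
    constant sign become one call each; a sign change is a boundary between
    two adjacent calls.  The call's intensity is the probe-count-weighted
    mean of its segment levels, its m the total probe count, and its score
    |intensity| * m^alpha; the median normalized LIR over the call's probes
    is recorded alongside as the robust intensity measure.  A final safety
    filter drops calls failing m >= m_min, score >= score_min, or the
    long-call intensity floor.
    """
    segs = [
        (lo, hi, lev)
        for lo, hi, lev in model.segments(apply_truncation=True)
        if abs(lev) >= ZERO_TOL
    ]
    calls: list[CNVCall] = []
    i = 0
    while i < len(segs):
        j = i
        run = [segs[i]]
        while j + 1 < len(segs):
            lo, hi, lev = segs[j + 1]
            plo, phi, plev = run[-1]
            if lo == phi + 1 and np.sign(lev) == np.sign(plev):
                run.append(segs[j + 1])
                j += 1
            else:
                break
        lo = run[0][0]
        hi = run[-1][1]
        m = hi - lo + 1
        weights = np.array([s[1] - s[0] + 1 for s in run], dtype=float)
        levels = np.array([s[2] for s in run])
        intensity = float(np.sum(weights * levels) / np.sum(weights))
        med = _median(track.lir, lo - 1, hi)
        sc = abs(intensity) * m**params.alpha
        ok = (
            m >= params.m_min
            and sc >= params.score_min
            and (m <= params.m_max or abs(intensity) >= params.mu_min)
        )
        if ok:
            calls.append(
                CNVCall(
                    chrom=track.chrom,
                    start_bp=int(track.positions[lo - 1]),
                    end_bp=int(track.positions[hi - 1]),
                    start_idx=lo,
                    end_idx=hi,
                    m=m,
                    intensity=intensity,
                    median_lir=med,
                    score=sc,
                    sign=1 if intensity > 0 else -1,
                )
            )
        i = j + 1
    return calls


def call_track(
    track: ProbeTrack,
    params: CutoffParams,
    init_jumps: Sequence[int] | None = None,
    objective: Literal["l1", "l2"] = "l1",
) -> list[CNVCall]:
    """Single-block pipeline: eliminate, clean up, consolidate."""
    model = backward_eliminate(track, params, init_jumps, objective)
    cleaned = cleanup(track, model, params)
    return consolidate(track, cleaned, params)
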