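"""Synthetic probe tracks with heavy-tailed noise and planted CNVs.

The generator emulates the data model the caller assumes: a dense, evenly
spaced probe grid (default 50 bp spacing, i.e. 20 probes/kb, typical of
high-density aCGH designs) whose LIR values are baseline noise plus
additive mean shifts over planted CNV intervals.  Noise is marginally a
Student t with 5 df scaled so the population MAD is 0.2 — exactly the
normalization target, so normalized real data and simulated data share the
same scale — and can be given serial correlation through a Gaussian AR(1)
copula: a stationary unit-variance Gaussian AR(1) series is mapped through
its CDF and then through the scaled-t quantile function, preserving the
marginal while introducing lag-1 dependence rho in the driver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .calls import ProbeTrack

__all__ = ["PlantedCNV", "TruthInterval", "simulate_track", "write_truth_bed", "read_truth_bed"]


@dataclass(frozen=True)
class PlantedCNV:
    """Additive mean shift mu over m probes starting at probe start_idx
    (1-based)."""

    start_idx: int
    m: int
    mu: float

    def __post_init__(self) -> None:
        if self.start_idx < 1 or self.m < 1:
            raise ValueError("start_idx and m must be positive")
        if self.mu == 0:
            raise ValueError("mu must be nonzero")

    @property
    def end_idx(self) -> int:
        return self.start_idx + self.m - 1


@dataclass(frozen=True)
class TruthInterval:
    """A planted CNV in both probe and bp coordinates (closed intervals)."""

    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    mu: float


def simulate_track(
    n_probes: int,
    spacing_bp: int = 50,
    noise_df: int = 5,
    noise_mad: float = 0.2,
    ar_rho: float = 0.0,
    cnvs: Sequence[PlantedCNV] = (),
    seed: int | None = None,
    chrom: str = "chr1",
) -> tuple[ProbeTrack, list[TruthInterval]]:
    """Generate one track plus the truth intervals of its planted CNVs.

    Fully reproducible from ``seed``.  Planted CNVs must fit inside the
    track and must not overlap.
    """
    if n_probes < 2:
        raise ValueError("n_probes must be >= 2")
    if not (0.0 <= ar_rho < 1.0):
        raise ValueError("ar_rho must lie in [0, 1)")
    ordered = sorted(cnvs, key=lambda c: c.start_idx)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_idx <= a.end_idx:
            raise ValueError(
                f"planted CNVs overlap: probes {a.start_idx}..{a.end_idx} and "
                f"{b.start_idx}..{b.end_idx}"
            )
    if ordered and ordered[-1].end_idx > n_probes:
        raise ValueError("planted CNV extends past the end of the track")

    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n_probes)
    if ar_rho > 0.0:
        # exact stationary unit-variance AR(1): x_t = rho x_{t-1} + sqrt(1-rho^2) e_t
        w = e * np.sqrt(1.0 - ar_rho**2)
        w[0] = e[0]
        x = signal.lfilter([1.0], [1.0, -ar_rho], w)
    else:
        x = e
    scale = noise_mad / stats.t.ppf(0.75, noise_df)
    y = scale * stats.t.ppf(stats.norm.cdf(x), noise_df)

    for c in ordered:
        y[c.start_idx - 1 : c.end_idx] += c.mu

    positions = spacing_bp * np.arange(1, n_probes + 1, dtype=np.int64)
    track = ProbeTrack(chrom, positions, y)
    truth = [
        TruthInterval(
            chrom=chrom,
            start_idx=c.start_idx,
            end_idx=c.end_idx,
            start_bp=int(positions[c.start_idx - 1]),
            end_bp=int(positions[c.end_idx - 1]),
            mu=c.mu,
        )
        for c in ordered
    ]
    return track, truth


def write_truth_bed(truth: Sequence[TruthInterval], path) -> None:
    """Truth intervals as BED (0-based half-open; name field = planted mu)."""
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.chrom}\t{t.start_bp - 1}\t{t.end_bp}\t{t.mu:+g}\n")


def read_truth_bed(path) -> list[tuple[str, int, int]]:
    """Read BED intervals back as closed (chrom, start_bp, end_bp) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out
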