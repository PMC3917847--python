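"""Probe-track and CNV-call data model, text I/O, and call post-filters.

Input tracks are tab-delimited text with a header and columns
``chrom``, ``position`` (bp, 1-based, strictly increasing within a
chromosome) and ``lir`` (log intensity ratio).  Calls are written as a TSV
with full precision, or as BED (0-based half-open) for genome-browser use.

The post-filters mirror standard practice for segment-level CNV lists:
merging same-sign calls whose endpoints are within a small gap (default
3 kb) with probe-count-weighted intensity averaging, dropping calls whose
probe density is at or below a floor (default 9 probes/kb), and — for
segmentations produced elsewhere — selecting segments whose mean LIR
magnitude beats the sub-array background mean plus one SD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeTrack",
    "CNVCall",
    "read_track",
    "write_calls",
    "read_calls",
    "merge_nearby_calls",
    "filter_by_probe_density",
    "select_segments",
]

TSV_COLUMNS = [
    "chrom",
    "start_bp",
    "end_bp",
    "start_idx",
    "end_idx",
    "m",
    "intensity",
    "median_lir",
    "score",
    "sign",
]


@dataclass(frozen=True)
class ProbeTrack:
    """Ordered probe positions and (normalized) LIR values for one
    sample/chromosome."""

    chrom: str
    positions: np.ndarray
    lir: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        lir = np.asarray(self.lir, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "lir", lir)
        if pos.shape != lir.shape or pos.ndim != 1:
            raise ValueError("positions and lir must be 1-D vectors of equal length")
        if pos.size < 2:
            raise ValueError("a track needs at least 2 probes")
        if np.any(np.diff(pos) <= 0):
            i = int(np.flatnonzero(np.diff(pos) <= 0)[0])
            raise ValueError(
                f"positions must be strictly increasing (violated at probe {i + 2})"
            )
        if not np.all(np.isfinite(lir)):
            i = int(np.flatnonzero(~np.isfinite(lir))[0])
            raise ValueError(f"non-finite LIR at probe {i + 1}")

    @property
    def N(self) -> int:
        return int(self.positions.size)

    def subtrack(self, lo: int, hi: int) -> "ProbeTrack":
        """Probes lo..hi, 1-based inclusive."""
        if not (1 <= lo <= hi <= self.N):
            raise ValueError(f"invalid range {lo}..{hi}")
        return ProbeTrack(self.chrom, self.positions[lo - 1 : hi], self.lir[lo - 1 : hi])


@dataclass(frozen=True)
class CNVCall:
    """One called CNV.

    intensity is the probe-weighted mean fitted level (signed); median_lir
    the median normalized LIR over the call's probes (the robust intensity
    measure recommended for downstream scoring); score = |intensity| * m^alpha.
    """

    chrom: str
    start_bp: int
    end_bp: int
    start_idx: int
    end_idx: int
    m: int
    intensity: float
    median_lir: float
    score: float
    sign: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.m != self.end_idx - self.start_idx + 1:
            raise ValueError("m must equal end_idx - start_idx + 1")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def read_track(path) -> list[ProbeTrack]:
    """Read a probe TSV into one ProbeTrack per chromosome present.

    Line numbers in error messages count the header as line 1.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    required = {"chrom", "position", "lir"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    lir = pd.to_numeric(df["lir"], errors="coerce")
    bad = lir.index[~np.isfinite(lir.to_numpy(dtype=float))]
    if len(bad):
        raise ValueError(f"{path}: non-numeric LIR at line {bad[0] + 2}")
    pos = pd.to_numeric(df["position"], errors="coerce")
    badp = pos.index[pos.isna()]
    if len(badp):
        raise ValueError(f"{path}: non-numeric position at line {badp[0] + 2}")
    tracks = []
    for chrom, sub in df.groupby("chrom", sort=False):
        p = pos[sub.index].to_numpy(dtype=np.int64)
        step = np.diff(p)
        if np.any(step <= 0):
            i = int(sub.index[int(np.flatnonzero(step <= 0)[0]) + 1])
            kind = "duplicate" if p[np.flatnonzero(step <= 0)[0] + 1] == p[np.flatnonzero(step <= 0)[0]] else "unsorted"
            raise ValueError(f"{path}: {kind} position on {chrom} at line {i + 2}")
        tracks.append(ProbeTrack(str(chrom), p, lir[sub.index].to_numpy(dtype=float)))
    return tracks


def write_calls(
    calls: Sequence[CNVCall],
    path,
    format: str = "tsv",
    header_comments: Iterable[str] = (),
) -> None:
    """Write calls as a full-precision TSV or as 5-column BED.

    BED uses the 0-based half-open convention (start = start_bp - 1,
    end = end_bp); its name field is the sign and its score field the CNV
    score scaled by 100, rounded, and capped at BED's 0-1000 range.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(
            [[getattr(c, col) for col in TSV_COLUMNS] for c in calls],
            columns=TSV_COLUMNS,
        )
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)
    elif format == "bed":
        with open(path, "w") as fh:
            for c in calls:
                bed_score = min(1000, int(round(c.score * 100)))
                fh.write(
                    f"{c.chrom}\t{c.start_bp - 1}\t{c.end_bp}\t{c.sign:+d}\t{bed_score}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_calls(path) -> list[CNVCall]:
    """Read back a calls TSV written by :func:`write_calls`."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"chrom": str}, float_precision="round_trip"
    )
    return [
        CNVCall(
            chrom=str(r.chrom),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            start_idx=int(r.start_idx),
            end_idx=int(r.end_idx),
            m=int(r.m),
            intensity=float(r.intensity),
            median_lir=float(r.median_lir),
            score=float(r.score),
            sign=int(r.sign),
        )
        for r in df.itertuples()
    ]


def merge_nearby_calls(
    calls: Sequence[CNVCall], max_gap_bp: int = 3000, alpha: float = 0.5
) -> list[CNVCall]:
    """Merge adjacent same-chromosome, same-sign calls whose endpoints are
    within ``max_gap_bp``, transitively left-to-right.

    The merged intensity (and median_lir) is the probe-count-weighted
    average of the parts; m is the summed probe count and the score is
    recomputed as |intensity| * m^alpha.
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start_bp))
    out: list[CNVCall] = []
    for c in ordered:
        if (
            out
            and out[-1].chrom == c.chrom
            and out[-1].sign == c.sign
            and c.start_bp - out[-1].end_bp <= max_gap_bp
        ):
            a = out[-1]
            m = a.m + c.m
            intensity = (a.intensity * a.m + c.intensity * c.m) / m
            med = (a.median_lir * a.m + c.median_lir * c.m) / m
            out[-1] = replace(
                a,
                end_bp=c.end_bp,
                end_idx=a.start_idx + m - 1,
                m=m,
                intensity=intensity,
                median_lir=med,
                score=abs(intensity) * m**alpha,
                sign=1 if intensity > 0 else -1,
            )
        else:
            out.append(c)
    return out


def filter_by_probe_density(
    calls: Sequence[CNVCall], min_density: float = 9.0
) -> list[CNVCall]:
    """Keep calls with probe density strictly greater than ``min_density``
    probes/kb; density is m / ((end_bp - start_bp + 1)/1000)."""
    kept = []
    for c in calls:
        span_kb = (c.end_bp - c.start_bp + 1) / 1000.0
        if span_kb <= 0 or c.m / span_kb > min_density:
            kept.append(c)
    return kept


def select_segments(
    segment_means: Sequence[tuple[float, int]],
    subarray_mean: float,
    subarray_sd: float,
) -> list[bool]:
    """Flag segments whose |mean LIR| exceeds |sub-array mean + 1 SD|.

    Used to promote raw segmentation output (mean, probe count) to CNV
    candidates against the array-wide background level.
    """
    if subarray_sd < 0:
        raise ValueError("subarray_sd must be nonnegative")
    thr = abs(subarray_mean + subarray_sd)
    return [abs(mean) > thr for mean, _m in segment_means]
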