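"""Overlapping-block driver for large probe tracks.

Backward elimination itself is cheap, but refitting medians over the very
long between-CNV segments that appear late in the elimination grows with
track length.  For large N the track is therefore cut into overlapping
blocks; elimination runs to termination inside each block, the retained
jumps are pooled (in global coordinates), and elimination is re-run once on
the full track with the candidate set restricted to that pool.  With
blocks of 50,000 probes the block-mode and single-block outputs agree in
practice; the overlap exists so that a CNV straddling a block edge has both
of its boundary jumps inside at least one block.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calls import CNVCall, ProbeTrack
from .engine import JumpModel, backward_eliminate, call_track, cleanup, consolidate
from .score import CutoffParams

__all__ = ["BlockConfig", "make_blocks", "blockwise_call"]


@dataclass(frozen=True)
class BlockConfig:
    """Block length M (probes) and the overlap shared by consecutive
    blocks.  block_size must comfortably exceed the longest call of
    interest (>= 2 * m_max)."""

    block_size: int = 50_000
    overlap: int = 5_000

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if not (0 < self.overlap < self.block_size):
            raise ValueError("require 0 < overlap < block_size")


def make_blocks(N: int, cfg: BlockConfig) -> list[tuple[int, int]]:
    """1-based inclusive probe ranges covering 1..N.

    Regular blocks start every (block_size - overlap) probes and are
    truncated at N; if the last regular block is shorter than block_size,
    a final block spanning the last block_size probes is appended.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if N <= cfg.block_size:
        return [(1, N)]
    step = cfg.block_size - cfg.overlap
    blocks = []
    start = 1
    while True:
        end = min(start + cfg.block_size - 1, N)
        blocks.append((start, end))
        if end >= N:
            break
        start += step
    last_start, last_end = blocks[-1]
    if last_end - last_start + 1 < cfg.block_size:
        blocks.append((N - cfg.block_size + 1, N))
    return blocks


def blockwise_call(
    track: ProbeTrack,
    params: CutoffParams,
    cfg: BlockConfig = BlockConfig(),
    objective: str = "l1",
) -> list[CNVCall]:
    """Full calling pipeline in block mode.

    Per-block elimination from the saturated model, pooling of the
    retained jump positions, restricted elimination on the whole track,
    then cleanup and consolidation.  For a track no longer than one block
    this is exactly the single-block pipeline.
    """
    if track.N <= cfg.block_size:
        return call_track(track, params, objective=objective)
    pooled: set[int] = set()
    for start, end in make_blocks(track.N, cfg):
        sub = track.subtrack(start, end)
        model = backward_eliminate(sub, params, objective=objective)
        for k in model.active_jumps():
            pooled.add(start - 1 + k)  # local jump k -> global coordinates
    if not pooled:
        return []
    full = JumpModel(track.lir, params, jumps=sorted(pooled), objective=objective)
    full.eliminate()
    cleaned = cleanup(track, full, params)
    return consolidate(track, cleaned, params)
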