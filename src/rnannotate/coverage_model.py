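"""Shared coverage primitives: normalization, strand-oriented slicing and
drop-point detection.

These are the substrate of the transcript, terminator and sRNA detectors.
A :class:`RegionSlice` always presents its values 5'->3' with respect to the
strand it was cut from, so downstream scans never need to branch on strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import CoverageTrack, STRANDS

__all__ = [
    "RegionSlice",
    "normalize_tracks",
    "slice_track",
    "min_max_ratio",
    "find_drop_point",
]


@dataclass
class RegionSlice:
    """Coverage over [start, end], oriented 5'->3' for ``strand``.

    On the minus strand ``values[0]`` corresponds to genome position ``end``.
    """

    replicon_id: str
    strand: str
    start: int
    end: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.end - self.start + 1:
            raise ValueError("values length must equal end - start + 1")

    def coordinate_of(self, oriented_index: int) -> int:
        """Genome coordinate of ``values[oriented_index]``."""
        if self.strand == "+":
            return self.start + oriented_index
        return self.end - oriented_index


def normalize_tracks(tracks: list[CoverageTrack]) -> list[CoverageTrack]:
    """Library-size normalization: scale each track so its total equals the
    mean total over the input tracks.

    All-zero tracks are returned unchanged, and the mean is taken over the
    nonzero totals only, so an unexpressed library cannot drag the reference
    down.  Within-track value ratios are preserved exactly.
    """
    if not tracks:
        raise ValueError("normalize_tracks requires at least one track")
    totals = np.array([float(t.values.sum()) for t in tracks])
    nonzero = totals[totals > 0]
    if nonzero.size == 0:
        return list(tracks)
    mean_total = float(nonzero.mean())
    out = []
    for t, total in zip(tracks, totals):
        if total == 0:
            out.append(t)
        else:
            out.append(
                CoverageTrack(t.replicon_id, t.strand, t.library, t.values * (mean_total / total))
            )
    return out


def slice_track(track: CoverageTrack, start: int, end: int) -> RegionSlice:
    """Cut [start, end] out of a track, oriented 5'->3' for its strand."""
    if start < 1 or end > track.length or start > end:
        raise IndexError(
            f"slice {start}..{end} out of range for replicon of length {track.length}"
        )
    vals = track.values[start - 1 : end]
    if track.strand == "-":
        vals = vals[::-1]
    return RegionSlice(track.replicon_id, track.strand, start, end, vals.copy())


def min_max_ratio(region: RegionSlice) -> float:
    """min/max of the region's values; 1.0 for an all-zero region.

    The zero-max convention means a flat unexpressed region can never look
    like a coverage drop.
    """
    if region.values.size == 0:
        raise ValueError("empty region")
    hi = float(region.values.max())
    if hi == 0:
        return 1.0
    return float(region.values.min()) / hi


def find_drop_point(region: RegionSlice, decrease_ratio: float) -> int | None:
    """First position (5'->3') whose coverage falls below ``decrease_ratio``
    times the running maximum seen so far; None if coverage never drops.

    The running-maximum reference (rather than the global maximum) keeps a
    late secondary peak from masking an earlier genuine drop.  Returns a
    genome coordinate.
    """
    if not 0 < decrease_ratio < 1:
        raise ValueError("decrease_ratio must be in (0, 1)")
    vals = region.values
    if vals.size == 0:
        return None
    running = np.maximum.accumulate(vals)
    below = vals < decrease_ratio * running
    idx = np.nonzero(below)[0]
    if idx.size == 0:
        return None
    return region.coordinate_of(int(idx[0]))
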