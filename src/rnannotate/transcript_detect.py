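"""Coverage-based transcript calling.

A transcript is a maximal run of positions whose (multi-library combined)
coverage exceeds a cutoff, where short sub-cutoff gaps up to a tolerance are
bridged.  Gene annotations can then merge fragmented calls that overlap the
same gene and extend calls to cover genes completely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import CoverageTrack, Feature

__all__ = [
    "TranscriptCall",
    "call_transcripts",
    "merge_with_genes",
    "expression_summary",
]

GENE_TYPES = ("gene", "CDS")


@dataclass
class TranscriptCall:
    replicon_id: str
    strand: str
    start: int
    end: int
    max_coverage: float = 0.0
    supporting_libraries: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end

    def to_feature(self, source: str = "rnannotate") -> Feature:
        return Feature(
            self.replicon_id,
            source,
            "transcript",
            self.start,
            self.end,
            self.strand,
            attributes={
                "max_coverage": [format(self.max_coverage, "g")],
                "libs": [",".join(self.supporting_libraries)] if self.supporting_libraries else ["."],
            },
        )


def _bridge_runs(mask: np.ndarray, tolerance: int) -> list[tuple[int, int]]:
    """0-based [start, end] runs of True, with gaps <= tolerance bridged."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    run_start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 <= tolerance:
            prev = i
        else:
            runs.append((run_start, prev))
            run_start = prev = i
    runs.append((run_start, prev))
    return runs


def call_transcripts(
    tracks: list[CoverageTrack],
    cutoff: float = 5.0,
    tolerance: int = 5,
    min_length: int = 20,
    include_tex_treated: bool = False,
    combine: str = "max",
) -> list[TranscriptCall]:
    """Call transcripts from coverage runs strictly above ``cutoff``.

    Libraries of the same replicon/strand are combined per position with
    ``max`` by default (a transcript expressed in any condition is called) or
    ``min`` for a conservative replicate-minimum mode.  TEX-treated (TEX+)
    tracks are excluded by default: the exonuclease depletes processed RNA
    and biases 3' coverage.
    """
    if not tracks:
        raise ValueError("call_transcripts requires at least one track")
    if cutoff <= 0 or tolerance < 0:
        raise ValueError("cutoff must be > 0 and tolerance >= 0")
    if combine not in ("max", "min"):
        raise ValueError("combine must be 'max' or 'min'")

    used = [
        t
        for t in tracks
        if include_tex_treated or t.library.treatment != "TEX_plus"
    ]
    if not used:
        raise ValueError("no usable tracks after excluding TEX-treated libraries")

    groups: dict[tuple[str, str], list[CoverageTrack]] = {}
    for t in used:
        groups.setdefault((t.replicon_id, t.strand), []).append(t)

    calls: list[TranscriptCall] = []
    for (replicon, strand), grp in sorted(groups.items()):
        stacked = np.vstack([t.values for t in grp])
        combined = stacked.max(axis=0) if combine == "max" else stacked.min(axis=0)
        mask = combined > cutoff
        for s0, e0 in _bridge_runs(mask, tolerance):
            if e0 - s0 + 1 < min_length:
                continue
            libs = [
                t.library.library_id
                for t in grp
                if bool((t.values[s0 : e0 + 1] > cutoff).any())
            ]
            calls.append(
                TranscriptCall(
                    replicon,
                    strand,
                    s0 + 1,
                    e0 + 1,
                    max_coverage=float(combined[s0 : e0 + 1].max()),
                    supporting_libraries=sorted(libs),
                )
            )
    return calls


def _fuse(a: TranscriptCall, b: TranscriptCall) -> TranscriptCall:
    return TranscriptCall(
        a.replicon_id,
        a.strand,
        min(a.start, b.start),
        max(a.end, b.end),
        max_coverage=max(a.max_coverage, b.max_coverage),
        supporting_libraries=sorted(set(a.supporting_libraries) | set(b.supporting_libraries)),
    )


def merge_with_genes(
    calls: list[TranscriptCall], genes: list[Feature]
) -> list[TranscriptCall]:
    """Merge calls overlapping the same gene and extend calls over full genes.

    Idempotent: merging only grows or fuses calls, never shrinks them, and a
    second application is a no-op.
    """
    genes = [g for g in genes if g.feature_type in GENE_TYPES]
    current = [replace(c) for c in calls]
    changed = True
    while changed:
        changed = False
        # extend calls over genes they partially overlap
        for c in current:
            for g in genes:
                if (
                    g.replicon_id == c.replicon_id
                    and g.strand == c.strand
                    and c.overlaps(g.start, g.end)
                ):
                    new_start = min(c.start, g.start)
                    new_end = max(c.end, g.end)
                    if (new_start, new_end) != (c.start, c.end):
                        c.start, c.end = new_start, new_end
                        changed = True
        # fuse overlapping calls on the same strand
        current.sort(key=lambda c: (c.replicon_id, c.strand, c.start, c.end))
        fused: list[TranscriptCall] = []
        for c in current:
            if (
                fused
                and fused[-1].replicon_id == c.replicon_id
                and fused[-1].strand == c.strand
                and c.start <= fused[-1].end + 1
            ):
                fused[-1] = _fuse(fused[-1], c)
            else:
                fused.append(c)
        if len(fused) != len(current):
            changed = True
        current = fused
    return current


def expression_summary(
    calls: list[TranscriptCall], genes: list[Feature]
) -> tuple[int, int, float]:
    """(genes_total, genes_covered, fraction): a gene counts as covered when
    any same-strand call overlaps it by at least one nucleotide."""
    genes = [g for g in genes if g.feature_type in GENE_TYPES]
    covered = 0
    for g in genes:
        if any(
            c.replicon_id == g.replicon_id
            and c.strand == g.strand
            and c.overlaps(g.start, g.end)
            for c in calls
        ):
            covered += 1
    total = len(genes)
    return total, covered, (covered / total if total else 0.0)
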