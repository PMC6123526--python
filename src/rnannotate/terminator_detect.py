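"""Rho-independent terminator detection.

Intrinsic terminators are a GC-rich hairpin followed by a T-rich tract.  Two
routes produce candidates: a convergent-gene-pair heuristic (hairpin plus
T-tract in a short inter-gene region whose two 3' ends face each other), and
an externally supplied candidate list.  Either way, candidates are confirmed
by a coverage drop: min/max coverage over the region +/- a flank must fall
below a cutoff (default 0.5) in at least one library.

Stems are modeled as two contiguous aligned arms; Watson-Crick and G.T
wobble pairs count as paired, anything else as unpaired.  Printed defaults:
stem arm 4-20 nt, loop 3-10 nt, at most 25% of stem positions unpaired,
inter-gene region <= 80 nt, more than 5 thymines in the T-rich tract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .coverage_model import min_max_ratio, slice_track
from .genome_io import CoverageTrack, Feature, Genome

__all__ = [
    "HairpinConstraints",
    "Hairpin",
    "TerminatorCall",
    "find_hairpins",
    "detect_convergent",
    "confirm_by_coverage",
    "dedupe_per_gene",
]

_PAIRS = {
    ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),  # G.U wobble on the DNA alphabet
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HairpinConstraints:
    stem_min: int = 4
    stem_max: int = 20
    loop_min: int = 3
    loop_max: int = 10
    max_unpaired_frac: float = 0.25


@dataclass(frozen=True)
class Hairpin:
    """One stem-loop: 1-based offset of the left arm within the searched
    sequence, per-arm stem length, loop length and unpaired stem count."""

    stem_start: int
    stem_len: int
    loop_len: int
    unpaired_in_stem: int
    sequence_context: str

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive (start, end) within the searched sequence."""
        return self.stem_start, self.stem_start + 2 * self.stem_len + self.loop_len - 1


@dataclass
class TerminatorCall:
    replicon_id: str
    strand: str  # "+", "-" (or "both" for externally supplied two-sided calls)
    start: int
    end: int
    method: str  # "convergent_heuristic" or "external_confirmed"
    drop_ratio: float | None = None
    confirmed: bool = False

    def to_feature(self, source: str = "rnannotate") -> Feature:
        return Feature(
            self.replicon_id,
            source,
            "terminator",
            self.start,
            self.end,
            self.strand if self.strand in ("+", "-") else "+",
            attributes={
                "method": [self.method],
                "drop_ratio": [
                    "." if self.drop_ratio is None else format(self.drop_ratio, "g")
                ],
                "confirmed": [str(self.confirmed).lower()],
            },
        )


def find_hairpins(
    sequence: str, constraints: HairpinConstraints = HairpinConstraints()
) -> list[Hairpin]:
    """Exhaustively enumerate stem-loops satisfying the constraints.

    For every (offset, stem length, loop length) the left arm is paired
    against the reversed right arm; mismatched positions count as unpaired.
    """
    seq = sequence.upper()
    n = len(seq)
    c = constraints
    out: list[Hairpin] = []
    for stem in range(c.stem_min, c.stem_max + 1):
        max_unpaired = int(c.max_unpaired_frac * stem)
        for loop in range(c.loop_min, c.loop_max + 1):
            total = 2 * stem + loop
            for off in range(0, n - total + 1):
                left = seq[off : off + stem]
                right = seq[off + stem + loop : off + total]
                unpaired = sum(
                    1
                    for k in range(stem)
                    if (left[k], right[stem - 1 - k]) not in _PAIRS
                )
                if unpaired <= max_unpaired:
                    out.append(
                        Hairpin(
                            stem_start=off + 1,
                            stem_len=stem,
                            loop_len=loop,
                            unpaired_in_stem=unpaired,
                            sequence_context=seq[off : off + total],
                        )
                    )
    out.sort(key=lambda h: (h.stem_start, h.stem_len, h.loop_len))
    return out


def _find_t_tract(seq: str, from_offset: int, min_t: int, window: int = 10) -> tuple[int, int] | None:
    """First window (1-based inclusive span) with more than ``min_t`` T at or
    after ``from_offset`` (0-based)."""
    n = len(seq)
    for i in range(from_offset, n):
        win = seq[i : i + window]
        if win.count("T") > min_t:
            return i + 1, min(i + window, n)
    return None


def detect_convergent(
    genes: list[Feature],
    genome: Genome,
    max_region: int = 80,
    min_t: int = 5,
    constraints: HairpinConstraints = HairpinConstraints(),
    t_window: int = 10,
) -> list[TerminatorCall]:
    """Terminator candidates between converging gene pairs.

    Adjacent plus/minus gene pairs whose 3' ends face each other across a
    region of at most ``max_region`` nt are scanned in both orientations
    (each gene's own 3' side): a qualifying hairpin followed downstream by a
    T-rich tract (> ``min_t`` T in a ``t_window`` nt window) yields one call
    per orientation, spanning hairpin plus tract.
    """
    gene_feats = sorted(
        (g for g in genes if g.feature_type in ("gene", "CDS") and g.replicon_id == genome.replicon_id),
        key=lambda g: g.start,
    )
    calls: list[TerminatorCall] = []
    for left, right in zip(gene_feats, gene_feats[1:]):
        if not (left.strand == "+" and right.strand == "-"):
            continue
        region_start = left.end + 1
        region_end = right.start - 1
        region_len = region_end - region_start + 1
        if region_len < 1 or region_len > max_region:
            continue
        region_seq = genome.sequence[region_start - 1 : region_end]
        for strand in ("+", "-"):
            seq = region_seq if strand == "+" else reverse_complement(region_seq)
            hairpins = find_hairpins(seq, constraints)
            call = None
            for hp in hairpins:
                _, hp_end = hp.span
                tract = _find_t_tract(seq, hp_end, min_t, t_window)
                if tract is None:
                    continue
                span_start, span_end = hp.span[0], tract[1]
                if strand == "+":
                    g_start = region_start + span_start - 1
                    g_end = region_start + span_end - 1
                else:
                    g_start = region_end - span_end + 1
                    g_end = region_end - span_start + 1
                call = TerminatorCall(
                    genome.replicon_id, strand, g_start, g_end, "convergent_heuristic"
                )
                break  # at most one call per orientation
            if call is not None:
                calls.append(call)
    calls.sort(key=lambda c: (c.start, c.strand))
    return calls


def confirm_by_coverage(
    candidates: list[TerminatorCall],
    tracks: list[CoverageTrack],
    drop_cutoff: float = 0.5,
    flank: int = 30,
) -> list[TerminatorCall]:
    """Flag candidates whose coverage drops within the region +/- flank.

    A candidate is confirmed when min/max coverage over the padded region is
    at most ``drop_cutoff`` in at least one library of the matching strand;
    ``drop_ratio`` records the minimum ratio observed.  Regions running past
    the replicon ends are clipped.  Candidates are retained either way.
    """
    if not 0 < drop_cutoff <= 1:
        raise ValueError("drop_cutoff must be in (0, 1]")
    out: list[TerminatorCall] = []
    for cand in candidates:
        ratios: list[float] = []
        for t in tracks:
            if t.replicon_id != cand.replicon_id:
                continue
            if cand.strand in ("+", "-") and t.strand != cand.strand:
                continue
            lo = max(1, cand.start - flank)
            hi = min(t.length, cand.end + flank)
            if lo > hi:
                continue
            ratios.append(min_max_ratio(slice_track(t, lo, hi)))
        new = replace(cand)
        if ratios:
            new.drop_ratio = min(ratios)
            new.confirmed = new.drop_ratio <= drop_cutoff
        else:
            new.drop_ratio = None
            new.confirmed = False
        out.append(new)
    return out


def dedupe_per_gene(
    candidates: list[TerminatorCall],
    genes: list[Feature],
    association_distance: int = 300,
) -> list[TerminatorCall]:
    """Keep only the highest-confidence confirmed terminator per gene.

    Confirmed candidates lying downstream of a gene's 3' end within
    ``association_distance`` nt compete; the lowest drop ratio wins, ties
    going to the candidate closest to the gene end.  Candidates associated
    with no gene are kept.
    """
    gene_feats = [g for g in genes if g.feature_type in ("gene", "CDS")]
    discard: set[int] = set()
    for g in gene_feats:
        assoc: list[tuple[float, int, int]] = []  # (drop_ratio, distance, index)
        for i, cand in enumerate(candidates):
            if not cand.confirmed or cand.replicon_id != g.replicon_id:
                continue
            if cand.strand in ("+", "-") and cand.strand != g.strand:
                continue
            if g.strand == "+":
                dist = cand.start - g.end
            else:
                dist = g.start - cand.end
            if 0 <= dist <= association_distance:
                assoc.append((cand.drop_ratio if cand.drop_ratio is not None else 1.0, dist, i))
        if len(assoc) > 1:
            assoc.sort()
            for _, _, i in assoc[1:]:
                discard.add(i)
    return [c for i, c in enumerate(candidates) if i not in discard]
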