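"""UTR derivation and operon/sub-operon assembly.

5' UTRs run from a primary (or, optionally, secondary) TSS to the base
before the gene start inside one transcript; 3' UTRs run from the base after
the gene end to the transcript 3' edge, or to a confirmed terminator end if
one lies within the transcript.  Operons are transcripts overlapping at
least one same-strand gene; internal TSSs that overlap no gene split an
operon into sub-operons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import Feature
from .terminator_detect import TerminatorCall
from .transcript_detect import TranscriptCall
from .tss_ps_detect import SiteCall

__all__ = [
    "UTRCall",
    "OperonCall",
    "derive_utrs",
    "utr_length_histogram",
    "detect_operons",
    "operon_summary",
]

GENE_TYPES = ("gene", "CDS")


@dataclass
class UTRCall:
    utr_type: str  # "five_prime" | "three_prime"
    replicon_id: str
    strand: str
    start: int
    end: int
    gene_id: str
    anchor: str  # "TSS" | "transcript_edge" | "terminator"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_feature(self, source: str = "rnannotate") -> Feature:
        ftype = "5UTR" if self.utr_type == "five_prime" else "3UTR"
        return Feature(
            self.replicon_id, source, ftype, self.start, self.end, self.strand,
            attributes={"Parent": [self.gene_id], "anchor": [self.anchor]},
        )


@dataclass
class OperonCall:
    replicon_id: str
    strand: str
    start: int
    end: int
    gene_ids: list[str] = field(default_factory=list)
    suboperons: list[tuple[int, int, int | None]] = field(default_factory=list)

    @property
    def monocistronic(self) -> bool:
        return len(self.gene_ids) == 1

    def to_features(self, operon_id: str, source: str = "rnannotate") -> list[Feature]:
        feats = [
            Feature(
                self.replicon_id, source, "operon", self.start, self.end, self.strand,
                attributes={
                    "ID": [operon_id],
                    "genes": [",".join(self.gene_ids)],
                    "monocistronic": [str(self.monocistronic).lower()],
                },
            )
        ]
        for i, (s, e, tss_pos) in enumerate(self.suboperons, start=1):
            feats.append(
                Feature(
                    self.replicon_id, source, "sub_operon", s, e, self.strand,
                    attributes={
                        "ID": [f"{operon_id}.{i}"],
                        "Parent": [operon_id],
                        "tss": ["." if tss_pos is None else str(tss_pos)],
                    },
                )
            )
        return feats


def _gene_id(g: Feature, index: int) -> str:
    return g.id or f"{g.feature_type}_{g.replicon_id}_{g.start}_{g.end}"


def derive_utrs(
    tss: list[SiteCall],
    transcripts: list[TranscriptCall],
    terminators: list[TerminatorCall],
    genes: list[Feature],
    include_secondary: bool = False,
) -> list[UTRCall]:
    """Annotate 5' and 3' UTRs from TSS/transcript/terminator/gene anchors.

    A gene with no qualifying TSS in its transcript gets no 5' UTR; a gene
    whose transcript ends exactly at the gene end gets no 3' UTR.  When
    ``include_secondary`` is set, secondary TSSs produce alternative 5' UTR
    records in addition to the primary one.
    """
    gene_feats = [g for g in genes if g.feature_type in GENE_TYPES]

    def _gene_between(g: Feature, lo: int, hi: int) -> bool:
        """Another same-strand gene (partially) inside [lo, hi]?"""
        return any(
            o is not g and o.replicon_id == g.replicon_id and o.strand == g.strand
            and o.start <= hi and lo <= o.end
            for o in gene_feats
        )

    utrs: list[UTRCall] = []
    for gi, g in enumerate(gene_feats):
        gid = _gene_id(g, gi)
        same_tx = [
            t for t in transcripts
            if t.replicon_id == g.replicon_id and t.strand == g.strand
            and t.overlaps(g.start, g.end)
        ]
        for t in same_tx:
            # --- 5' UTR ---
            wanted = {"primary"} | ({"secondary"} if include_secondary else set())
            candidates = [
                s for s in tss
                if s.replicon_id == g.replicon_id and s.strand == g.strand
                and s.classes & wanted
                and t.start <= s.position <= t.end
                and (
                    s.position < g.start if g.strand == "+" else s.position > g.end
                )
            ]
            # canonical UTR: primary first, then strongest step
            candidates.sort(
                key=lambda s: ("primary" not in s.classes, -s.step_height)
            )
            emitted_primary = False
            for s in candidates:
                is_primary = "primary" in s.classes
                if is_primary and emitted_primary:
                    continue
                if not is_primary and not include_secondary:
                    continue
                if g.strand == "+":
                    start, end = s.position, g.start - 1
                else:
                    start, end = g.end + 1, s.position
                if start <= end and not _gene_between(g, start, end):
                    utrs.append(
                        UTRCall("five_prime", g.replicon_id, g.strand, start, end, gid, "TSS")
                    )
                    if is_primary:
                        emitted_primary = True
                if not include_secondary:
                    break
            # --- 3' UTR ---
            term = next(
                (
                    c for c in terminators
                    if c.confirmed and c.replicon_id == g.replicon_id
                    and c.strand in (g.strand, "both")
                    and t.overlaps(c.start, c.end)
                    and (c.end > g.end if g.strand == "+" else c.start < g.start)
                ),
                None,
            )
            if g.strand == "+":
                end3 = min(term.end, t.end) if term else t.end
                start, end = g.end + 1, end3
            else:
                start3 = max(term.start, t.start) if term else t.start
                start, end = start3, g.start - 1
            if start <= end and not _gene_between(g, start, end):
                utrs.append(
                    UTRCall(
                        "three_prime", g.replicon_id, g.strand, start, end, gid,
                        "terminator" if term else "transcript_edge",
                    )
                )
    utrs.sort(key=lambda u: (u.replicon_id, u.start, u.utr_type))
    return utrs


def utr_length_histogram(
    utrs: list[UTRCall], bin_width: int = 100
) -> list[tuple[int, int]]:
    """(bin_start, count) rows over [k*bin_width, (k+1)*bin_width) bins;
    the counts sum to the number of UTRs."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    counts: dict[int, int] = {}
    for u in utrs:
        b = (u.length // bin_width) * bin_width
        counts[b] = counts.get(b, 0) + 1
    return sorted(counts.items())


def detect_operons(
    transcripts: list[TranscriptCall],
    genes: list[Feature],
    tss: list[SiteCall],
) -> list[OperonCall]:
    """Assemble operons from transcripts and split them at internal
    non-genic TSSs.

    Operon boundaries equal transcript boundaries.  A sub-operon runs from
    its TSS to the next such TSS (exclusive) or the operon 3' end; operons
    with zero or one internal non-genic TSS have a single sub-operon.
    """
    gene_feats = [g for g in genes if g.feature_type in GENE_TYPES]
    operons: list[OperonCall] = []
    for t in transcripts:
        overlapping = [
            g for g in gene_feats
            if g.replicon_id == t.replicon_id and g.strand == t.strand
            and t.overlaps(g.start, g.end)
        ]
        if not overlapping:
            continue
        overlapping.sort(key=lambda g: g.start, reverse=(t.strand == "-"))
        gene_ids = [_gene_id(g, i) for i, g in enumerate(overlapping)]
        internal = [
            s for s in tss
            if s.replicon_id == t.replicon_id and s.strand == t.strand
            and t.start <= s.position <= t.end
            and not any(g.start <= s.position <= g.end for g in gene_feats
                        if g.replicon_id == t.replicon_id)
        ]
        # order 5'->3' along the operon strand
        internal.sort(key=lambda s: s.position, reverse=(t.strand == "-"))
        subs: list[tuple[int, int, int | None]] = []
        if len(internal) <= 1:
            tss_pos = internal[0].position if internal else None
            if t.strand == "+":
                subs.append((tss_pos if tss_pos is not None else t.start, t.end, tss_pos))
            else:
                subs.append((t.start, tss_pos if tss_pos is not None else t.end, tss_pos))
        else:
            for i, s in enumerate(internal):
                nxt = internal[i + 1].position if i + 1 < len(internal) else None
                if t.strand == "+":
                    end = (nxt - 1) if nxt is not None else t.end
                    subs.append((s.position, end, s.position))
                else:
                    start = (nxt + 1) if nxt is not None else t.start
                    subs.append((start, s.position, s.position))
        subs.sort(key=lambda x: x[0])
        operons.append(
            OperonCall(t.replicon_id, t.strand, t.start, t.end, gene_ids, subs)
        )
    operons.sort(key=lambda o: (o.replicon_id, o.start))
    return operons


def operon_summary(operons: list[OperonCall]) -> tuple[int, int, int]:
    """(total, monocistronic, polycistronic); total is conserved."""
    mono = sum(1 for o in operons if o.monocistronic)
    return len(operons), mono, len(operons) - mono
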