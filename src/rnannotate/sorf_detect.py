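"""Small ORF detection with ribosome-binding-site support.

CDS-free transcripts and all UTR regions are scanned for ORFs of 30-150 nt
(start codon through first in-frame stop, both included in the length).  A
bona fide sORF additionally needs a Shine-Dalgarno-like RBS whose 3' edge
sits 3-15 nt upstream of the start codon, downstream of the transcript's
TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

from .boundary_annotate import UTRCall
from .genome_io import Feature, Genome
from .terminator_detect import reverse_complement
from .transcript_detect import TranscriptCall
from .tss_ps_detect import SiteCall

__all__ = [
    "SORFParams",
    "SORFCandidate",
    "find_orfs",
    "find_rbs",
    "detect_sorfs",
]

GENE_TYPES = ("gene", "CDS")

DEFAULT_START_CODONS = frozenset({"ATG"})
NONCANONICAL_START_CODONS = frozenset({"GTG", "TTG"})
DEFAULT_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class SORFParams:
    min_len: int = 30
    max_len: int = 150
    start_codons: frozenset[str] = DEFAULT_START_CODONS
    stop_codons: frozenset[str] = DEFAULT_STOP_CODONS
    rbs_consensus: str = "AGGAGG"
    rbs_max_mismatch: int = 1
    rbs_gap_min: int = 3  # nt between RBS 3' edge and base before start codon
    rbs_gap_max: int = 15


@dataclass
class SORFCandidate:
    replicon_id: str
    strand: str
    start: int
    end: int
    frame: int
    start_codon: str
    rbs_position: int  # genome coordinate of the RBS 5' base
    tss_position: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_feature(self, source: str = "rnannotate") -> Feature:
        return Feature(
            self.replicon_id, source, "sORF", self.start, self.end, self.strand,
            attributes={
                "start_codon": [self.start_codon],
                "rbs_position": [str(self.rbs_position)],
                "frame": [str(self.frame)],
            },
        )


def find_orfs(
    region_sequence: str,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
    stop_codons: frozenset[str] = DEFAULT_STOP_CODONS,
    min_len: int = 30,
    max_len: int = 150,
) -> list[tuple[int, int, int]]:
    """(offset, length, frame) of every ORF in a 5'->3' sequence.

    An ORF begins at a start codon and ends at the first in-frame stop
    codon; the length includes both.  Overlapping ORFs in different frames
    are all reported.  Offsets are 1-based, matching the package-wide
    coordinate convention; frame is (offset - 1) mod 3.
    """
    seq = region_sequence.upper()
    n = len(seq)
    out: list[tuple[int, int, int]] = []
    for i in range(n - 2):
        if seq[i : i + 3] not in start_codons:
            continue
        j = i + 3
        while j + 3 <= n:
            codon = seq[j : j + 3]
            if codon in stop_codons:
                length = j + 3 - i
                if min_len <= length <= max_len:
                    out.append((i + 1, length, i % 3))
                break
            j += 3
    return out


def find_rbs(
    upstream_sequence: str,
    consensus: str = "AGGAGG",
    max_mismatch: int = 1,
) -> list[int]:
    """1-based offsets where a |consensus|-length window matches the
    consensus with at most ``max_mismatch`` mismatches."""
    seq = upstream_sequence.upper()
    m = len(consensus)
    out = []
    for i in range(len(seq) - m + 1):
        mismatches = sum(1 for a, b in zip(seq[i : i + m], consensus) if a != b)
        if mismatches <= max_mismatch:
            out.append(i + 1)
    return out


def _oriented_region(genome: Genome, strand: str, start: int, end: int) -> str:
    seq = genome.sequence[start - 1 : end]
    return seq if strand == "+" else reverse_complement(seq)


def _to_genome(strand: str, region_start: int, region_end: int, offset: int) -> int:
    """Genome coordinate of 0-based oriented ``offset`` within the region."""
    return region_start + offset if strand == "+" else region_end - offset


def detect_sorfs(
    transcripts: list[TranscriptCall],
    genes: list[Feature],
    tss: list[SiteCall],
    utrs: list[UTRCall],
    genome: Genome,
    params: SORFParams = SORFParams(),
) -> list[SORFCandidate]:
    """Scan CDS-free transcripts and UTRs for RBS-supported small ORFs.

    The RBS must lie between the transcript's TSS and 3-15 nt upstream of
    the start codon (gap measured from the RBS 3' edge to the base before
    the start).  When a transcript has several TSSs, any one yielding a
    valid window is accepted.
    """
    gene_feats = [g for g in genes if g.feature_type in GENE_TYPES]

    # search space: (region span, owning-transcript span) pairs per strand
    regions: list[tuple[str, str, int, int]] = []
    for t in transcripts:
        has_cds = any(
            g.replicon_id == t.replicon_id and g.strand == t.strand
            and t.overlaps(g.start, g.end)
            for g in gene_feats
        )
        if not has_cds:
            regions.append((t.replicon_id, t.strand, t.start, t.end))
    for u in utrs:
        regions.append((u.replicon_id, u.strand, u.start, u.end))

    out: list[SORFCandidate] = []
    seen: set[tuple[str, str, int, int]] = set()
    for replicon, strand, r_start, r_end in regions:
        if genome.replicon_id != replicon:
            continue
        seq = _oriented_region(genome, strand, r_start, r_end)
        pad = params.rbs_gap_max + len(params.rbs_consensus)
        tss_here = [
            s for s in tss
            if s.replicon_id == replicon and s.strand == strand
            and r_start - pad <= s.position <= r_end + pad
        ]
        if not tss_here:
            continue
        for off1, length, frame in find_orfs(
            seq, params.start_codons, params.stop_codons, params.min_len, params.max_len
        ):
            off = off1 - 1  # 0-based oriented offset of the start codon
            # RBS window: ends 3-15 nt upstream of the start codon
            win_hi = off - params.rbs_gap_min  # exclusive oriented end
            win_lo = off - params.rbs_gap_max - len(params.rbs_consensus)
            if win_lo < 0:
                win_lo = 0
            if win_hi - win_lo < len(params.rbs_consensus):
                continue
            window = seq[win_lo:win_hi]
            for rbs_off1 in find_rbs(window, params.rbs_consensus, params.rbs_max_mismatch):
                rbs_start_or = win_lo + rbs_off1 - 1  # oriented offset of RBS 5' base
                rbs_end_or = rbs_start_or + len(params.rbs_consensus) - 1
                gap = off - rbs_end_or - 1
                if not params.rbs_gap_min <= gap <= params.rbs_gap_max:
                    continue
                rbs_genome = _to_genome(strand, r_start, r_end, rbs_start_or)
                # RBS must lie between a TSS and the start codon
                tss_ok = None
                for s in tss_here:
                    or_tss = (
                        s.position - r_start if strand == "+" else r_end - s.position
                    )
                    if or_tss <= rbs_start_or:
                        tss_ok = s
                        break
                if tss_ok is None:
                    continue
                g1 = _to_genome(strand, r_start, r_end, off)
                g2 = _to_genome(strand, r_start, r_end, off + length - 1)
                start, end = min(g1, g2), max(g1, g2)
                key = (replicon, strand, start, end)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    SORFCandidate(
                        replicon, strand, start, end, frame,
                        start_codon=seq[off : off + 3],
                        rbs_position=rbs_genome,
                        tss_position=tss_ok.position,
                    )
                )
                break  # one RBS suffices for this ORF
    out.sort(key=lambda c: (c.replicon_id, c.start, c.strand))
    return out
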