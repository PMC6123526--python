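"""Small noncoding RNA candidate detection and quality filtering.

Candidates arise from five origins: intergenic and antisense transcripts
(no same-strand gene overlap), 5'/3'-UTR-derived and inter-CDS-derived
regions of coding transcripts.  Quality filters: length 30-500 nt, an
origin-specific 5' anchor (TSS, or PS where the origin allows it) and a
stable predicted secondary structure.  Each filter can be switched off
individually.

The built-in folding score is a Nussinov-style maximum non-crossing
base-pairing count (Watson-Crick plus G.T wobble, minimum loop 3),
normalized per nucleotide and negated so that lower means more stable.  Any
callable with the same contract (sequence -> per-nt score, deterministic)
can be plugged in instead, e.g. an adapter to a thermodynamic folder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .coverage_model import find_drop_point, slice_track
from .genome_io import CoverageTrack, Feature, Genome
from .terminator_detect import reverse_complement
from .transcript_detect import TranscriptCall
from .tss_ps_detect import SiteCall
from .boundary_annotate import UTRCall

__all__ = [
    "SRNACandidate",
    "SRNAParams",
    "detect_intergenic",
    "detect_utr_derived",
    "apply_quality_filters",
    "builtin_fold_score",
]

GENE_TYPES = ("gene", "CDS")

FoldingProvider = Callable[[str], float]


@dataclass
class SRNAParams:
    min_len: int = 30
    max_len: int = 500
    tss_tolerance: int = 3  # candidate 5' end vs TSS
    fold_cutoff: float = -0.05  # per-nt, built-in provider scale
    drop_ratio: float = 0.5  # 3'-end refinement drop threshold


@dataclass
class SRNACandidate:
    replicon_id: str
    strand: str
    start: int
    end: int
    origin: str  # intergenic | antisense | five_utr | three_utr | inter_cds
    tss_position: int | None = None
    ps_position: int | None = None
    end_anchor: str = "transcript_edge"  # | drop_point | processing_site
    fold_score: float = 0.0
    passed_filters: bool = False
    reject_reasons: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sequence(self, genome: Genome) -> str:
        seq = genome.sequence[self.start - 1 : self.end]
        return seq if self.strand == "+" else reverse_complement(seq)

    def to_feature(self, source: str = "rnannotate") -> Feature:
        return Feature(
            self.replicon_id, source, "sRNA", self.start, self.end, self.strand,
            attributes={
                "origin": [self.origin],
                "end_anchor": [self.end_anchor],
                "fold_score": [format(self.fold_score, "g")],
                "reject_reasons": self.reject_reasons or ["."],
            },
        )


# ---------------------------------------------------------------------------
# 5'/3' anchor helpers

def _sites_in(
    sites: list[SiteCall], replicon: str, strand: str, start: int, end: int
) -> list[SiteCall]:
    out = [
        s for s in sites
        if s.replicon_id == replicon and s.strand == strand and start <= s.position <= end
    ]
    out.sort(key=lambda s: s.position, reverse=(strand == "-"))  # 5'->3'
    return out


def _five_end(strand: str, start: int, end: int) -> int:
    return start if strand == "+" else end


def _refine_three_end(
    t: TranscriptCall,
    five_pos: int,
    ps_list: list[SiteCall],
    tracks: list[CoverageTrack],
    params: SRNAParams,
) -> tuple[int, str]:
    """3' end for an over-long candidate: the first drop point or PS
    downstream of the 5' end, whichever comes first 5'->3'."""
    candidates: list[tuple[int, int, str]] = []  # (oriented offset, position, anchor)
    ps_inside = [
        s for s in ps_list
        if s.replicon_id == t.replicon_id and s.strand == t.strand
        and t.start <= s.position <= t.end
    ]
    for s in ps_inside:
        off = (s.position - five_pos) if t.strand == "+" else (five_pos - s.position)
        if off >= params.min_len:
            candidates.append((off, s.position, "processing_site"))
    for trk in tracks:
        if trk.replicon_id != t.replicon_id or trk.strand != t.strand:
            continue
        region = slice_track(trk, t.start, t.end)
        drop = find_drop_point(region, params.drop_ratio)
        if drop is None:
            continue
        off = (drop - five_pos) if t.strand == "+" else (five_pos - drop)
        if off >= params.min_len:
            candidates.append((off, drop, "drop_point"))
    if not candidates:
        return (t.end if t.strand == "+" else t.start), "transcript_edge"
    candidates.sort()
    _, pos, anchor = candidates[0]
    return pos, anchor


def detect_intergenic(
    transcripts: list[TranscriptCall],
    genes: list[Feature],
    tss: list[SiteCall],
    ps: list[SiteCall],
    tracks: list[CoverageTrack],
    params: SRNAParams = SRNAParams(),
) -> list[SRNACandidate]:
    """Intergenic / antisense sRNA candidates from gene-free transcripts.

    A transcript overlapping no same-strand gene is a candidate; if a gene
    overlaps on the opposite strand the origin is antisense.  The 5' end
    must coincide with a TSS (within ``tss_tolerance`` nt); otherwise the
    candidate is emitted rejected with reason "no TSS".  Transcripts longer
    than ``max_len`` get their 3' end refined to the first internal drop
    point or processing site.
    """
    gene_feats = [g for g in genes if g.feature_type in GENE_TYPES]
    out: list[SRNACandidate] = []
    for t in transcripts:
        same = [
            g for g in gene_feats
            if g.replicon_id == t.replicon_id and g.strand == t.strand
            and t.overlaps(g.start, g.end)
        ]
        if same:
            continue
        anti = [
            g for g in gene_feats
            if g.replicon_id == t.replicon_id and g.strand != t.strand
            and t.overlaps(g.start, g.end)
        ]
        origin = "antisense" if anti else "intergenic"
        five = _five_end(t.strand, t.start, t.end)
        lo, hi = five - params.tss_tolerance, five + params.tss_tolerance
        anchors = _sites_in(tss, t.replicon_id, t.strand, lo, hi)
        cand = SRNACandidate(
            t.replicon_id, t.strand, t.start, t.end, origin,
            tss_position=anchors[0].position if anchors else None,
        )
        if t.length > params.max_len:
            pos, anchor = _refine_three_end(t, five, ps, tracks, params)
            cand.end_anchor = anchor
            if t.strand == "+":
                cand.end = pos
            else:
                cand.start = pos
            if anchor == "processing_site":
                cand.ps_position = pos
        out.append(cand)
    return out


def detect_utr_derived(
    transcripts: list[TranscriptCall],
    genes: list[Feature],
    tss: list[SiteCall],
    ps: list[SiteCall],
    tracks: list[CoverageTrack],
    utrs: list[UTRCall],
    params: SRNAParams = SRNAParams(),
) -> list[SRNACandidate]:
    """UTR-derived and inter-CDS sRNA candidates inside coding transcripts.

    five_utr: starts at a TSS inside a 5' UTR, ends at a PS or drop point.
    three_utr: starts at a TSS or PS inside a 3' UTR, ends at the transcript
    edge or a downstream PS.  inter_cds: region between two consecutive CDS
    of one transcript, starting at a PS, ending at a PS or drop point.  When
    both a PS and a drop point qualify, the 5'-most is used.
    """
    gene_feats = [g for g in genes if g.feature_type in GENE_TYPES]
    out: list[SRNACandidate] = []

    def _drop_in(replicon: str, strand: str, start: int, end: int) -> int | None:
        for trk in tracks:
            if trk.replicon_id != replicon or trk.strand != strand:
                continue
            region = slice_track(trk, start, end)
            drop = find_drop_point(region, params.drop_ratio)
            if drop is not None:
                return drop
        return None

    def _oriented_candidates(
        strand: str, anchor5: int, enders: list[tuple[int, str]], edge: int | None
    ) -> tuple[int, str] | None:
        """Pick the 5'-most 3' ender downstream of anchor5."""
        opts = []
        for pos, kind in enders:
            off = (pos - anchor5) if strand == "+" else (anchor5 - pos)
            if off > 0:
                opts.append((off, pos, kind))
        if edge is not None:
            off = (edge - anchor5) if strand == "+" else (anchor5 - edge)
            if off > 0:
                opts.append((off, edge, "transcript_edge"))
        if not opts:
            return None
        opts.sort()
        _, pos, kind = opts[0]
        return pos, kind

    # --- 5' UTR and 3' UTR derived ---
    for u in utrs:
        strand = u.strand
        if u.utr_type == "five_prime":
            starters = _sites_in(tss, u.replicon_id, strand, u.start, u.end)
            if not starters:
                continue
            s0 = starters[0]
            enders = [
                (p.position, "processing_site")
                for p in _sites_in(ps, u.replicon_id, strand, u.start, u.end)
            ]
            drop = _drop_in(u.replicon_id, strand, u.start, u.end)
            if drop is not None:
                enders.append((drop, "drop_point"))
            pick = _oriented_candidates(strand, s0.position, enders, None)
            if pick is None:
                continue
            pos, kind = pick
            start, end = (s0.position, pos) if strand == "+" else (pos, s0.position)
            out.append(
                SRNACandidate(
                    u.replicon_id, strand, start, end, "five_utr",
                    tss_position=s0.position,
                    ps_position=pos if kind == "processing_site" else None,
                    end_anchor=kind,
                )
            )
        else:  # three_prime
            t_starters = _sites_in(tss, u.replicon_id, strand, u.start, u.end)
            p_starters = _sites_in(ps, u.replicon_id, strand, u.start, u.end)
            all_starters = [(s, "TSS") for s in t_starters] + [(s, "PS") for s in p_starters]
            if not all_starters:
                continue
            # 5'-most anchor of either kind
            all_starters.sort(
                key=lambda x: x[0].position, reverse=(strand == "-")
            )
            s0, s0_kind = all_starters[0]
            enders = [
                (p.position, "processing_site")
                for p in p_starters
                if p.position != s0.position
            ]
            edge = u.end if strand == "+" else u.start
            pick = _oriented_candidates(strand, s0.position, enders, edge)
            if pick is None:
                continue
            pos, kind = pick
            start, end = (s0.position, pos) if strand == "+" else (pos, s0.position)
            out.append(
                SRNACandidate(
                    u.replicon_id, strand, start, end, "three_utr",
                    tss_position=s0.position if s0_kind == "TSS" else None,
                    ps_position=(
                        s0.position if s0_kind == "PS"
                        else (pos if kind == "processing_site" else None)
                    ),
                    end_anchor=kind,
                )
            )

    # --- inter-CDS derived ---
    for t in transcripts:
        cds = sorted(
            (
                g for g in gene_feats
                if g.replicon_id == t.replicon_id and g.strand == t.strand
                and t.overlaps(g.start, g.end)
            ),
            key=lambda g: g.start,
        )
        for left, right in zip(cds, cds[1:]):
            region_start, region_end = left.end + 1, right.start - 1
            if region_start > region_end:
                continue
            starters = _sites_in(ps, t.replicon_id, t.strand, region_start, region_end)
            if not starters:
                continue
            s0 = starters[0]
            enders = [
                (p.position, "processing_site")
                for p in starters[1:]
            ]
            drop = _drop_in(t.replicon_id, t.strand, region_start, region_end)
            if drop is not None:
                enders.append((drop, "drop_point"))
            pick = _oriented_candidates(t.strand, s0.position, enders, None)
            if pick is None:
                continue
            pos, kind = pick
            start, end = (
                (s0.position, pos) if t.strand == "+" else (pos, s0.position)
            )
            out.append(
                SRNACandidate(
                    t.replicon_id, t.strand, start, end, "inter_cds",
                    ps_position=s0.position,
                    end_anchor=kind,
                )
            )
    # overlapping UTR records can yield the same candidate twice
    unique: dict[tuple[str, str, str, int, int], SRNACandidate] = {}
    for c in out:
        unique.setdefault((c.origin, c.replicon_id, c.strand, c.start, c.end), c)
    out = list(unique.values())
    out.sort(key=lambda c: (c.replicon_id, c.start, c.origin))
    return out


# ---------------------------------------------------------------------------
# quality filters

_FOLD_PAIRS = {
    ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),
}

MIN_LOOP = 3


def builtin_fold_score(sequence: str) -> float:
    """-(maximum non-crossing base pairs with loop >= 3) / length.

    Nussinov-style dynamic program over Watson-Crick and G.T wobble pairs;
    always in [-0.5, 0].  Deterministic and length-normalized, so the same
    cutoff applies to candidates of any length.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    if n < 1:
        raise ValueError("sequence must be nonempty")
    if n < MIN_LOOP + 2:
        return 0.0
    dp = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1][j]
            if (seq[i], seq[j]) in _FOLD_PAIRS:
                best = max(best, dp[i + 1][j - 1] + 1)
            for k in range(i + 1, j):
                if (seq[i], seq[k]) in _FOLD_PAIRS and k - i > MIN_LOOP:
                    cand = dp[i + 1][k - 1] + 1 + dp[k + 1][j]
                    best = max(best, cand)
            dp[i][j] = best
    return -dp[0][n - 1] / n


_ANCHOR_REQUIREMENTS = {
    "intergenic": ("tss",),
    "antisense": ("tss",),
    "five_utr": ("tss",),
    "three_utr": ("tss", "ps"),  # either suffices
    "inter_cds": ("ps",),
}


def apply_quality_filters(
    candidates: list[SRNACandidate],
    genome: Genome,
    fold: FoldingProvider = builtin_fold_score,
    params: SRNAParams = SRNAParams(),
    check_length: bool = True,
    check_anchor: bool = True,
    check_fold: bool = True,
    known_srnas: list[Feature] | None = None,
) -> list[SRNACandidate]:
    """Apply the sRNA quality filters; every rejection lists its reasons.

    A candidate passes when its length is within [min_len, max_len], its
    origin-specific 5' anchor is present, and its folding score is at most
    ``fold_cutoff``.  Each filter can be deactivated.  Overlap with a
    user-supplied known-sRNA set bypasses all filters (the candidate keeps
    the status of a known sRNA).
    """
    for cand in candidates:
        reasons: list[str] = []
        # folding an over-long candidate is pointless (and the DP is cubic)
        if cand.length <= params.max_len:
            cand.fold_score = fold(cand.sequence(genome))
        else:
            cand.fold_score = 0.0
        if known_srnas is not None and any(
            k.replicon_id == cand.replicon_id and k.strand == cand.strand
            and k.overlaps(cand.start, cand.end)
            for k in known_srnas
        ):
            cand.passed_filters = True
            cand.reject_reasons = []
            continue
        if check_length:
            if cand.length < params.min_len:
                reasons.append(f"length<{params.min_len}")
            elif cand.length > params.max_len:
                reasons.append(f"length>{params.max_len}")
        if check_anchor:
            allowed = _ANCHOR_REQUIREMENTS[cand.origin]
            has = {
                "tss": cand.tss_position is not None,
                "ps": cand.ps_position is not None,
            }
            if not any(has[a] for a in allowed):
                reasons.append("no TSS" if allowed == ("tss",) else "no TSS/PS anchor")
        if check_fold and cand.length <= params.max_len and cand.fold_score > params.fold_cutoff:
            reasons.append("unstable fold")
        cand.reject_reasons = reasons
        cand.passed_filters = not reasons
    return candidates
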