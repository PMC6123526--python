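"""Synthetic genomes, annotations and dRNA-seq/fragmented coverage with
planted ground truth.

The generator lays transcription units along a random genome: operons
(mono- and dicistronic, some with intrinsic terminators), one convergent
gene pair with a terminator motif in the <=80 nt inter-gene region,
TSS-anchored intergenic sRNAs with a planted hairpin, and CDS-free sORF
host transcripts carrying a Shine-Dalgarno RBS.  Coverage emulates the
library chemistry: plateaus at the requested depth, a multiplicative TEX+
boost (>=5x) downstream of every planted TSS, TEX+ depletion plus TEX-
enrichment downstream of every planted processing site, and a coverage
drop across every planted terminator.  Noise is additive Gaussian on
expressed positions (unexpressed positions stay at zero: detectors consume
coverage, and background contamination is not what they are tested on).

Everything is deterministic per seed, and all planted features are returned
in a :class:`TruthTable` for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (
    CoverageTrack,
    Feature,
    Genome,
    Library,
    write_fasta,
    write_gff3,
    write_wiggle,
)
from .terminator_detect import reverse_complement
from .tss_ps_detect import CuratedSet

__all__ = [
    "PlantedSite",
    "PlantedSpan",
    "PlantedSorf",
    "TruthTable",
    "SyntheticDataset",
    "simulate_dataset",
    "simulate_genome",
    "simulate_coverage",
    "curate_subset",
    "default_libraries",
    "write_dataset",
]

BASES = np.array(list("ACGT"))

TSS_BOOST_WINDOW = 15  # nt of TEX+ enrichment downstream of a TSS
PS_WINDOW = 15  # nt of TEX- enrichment downstream of a PS
PS_DEPLETION = 0.2  # TEX+ multiplier downstream of a PS
PS_ENRICHMENT = 4.0  # TEX- multiplier in the PS window

_SAFE_CODONS = ("GCT", "GAA", "CTG", "AAA", "CGT", "GAC", "TTC", "CAT")


@dataclass(frozen=True)
class PlantedSite:
    strand: str
    position: int
    kind: str = ""  # primary | internal | srna | sorf (TSS); "" for PS
    boost: float = 1.0


@dataclass(frozen=True)
class PlantedSpan:
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class PlantedSorf:
    strand: str
    start: int
    end: int
    rbs_position: int
    tss_position: int


@dataclass
class TruthTable:
    replicon_id: str
    seed: int
    transcripts: list[PlantedSpan] = field(default_factory=list)
    tss: list[PlantedSite] = field(default_factory=list)
    ps: list[PlantedSite] = field(default_factory=list)
    terminators: list[PlantedSpan] = field(default_factory=list)
    srnas: list[PlantedSpan] = field(default_factory=list)
    sorfs: list[PlantedSorf] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    genome: Genome
    genes: list[Feature]
    truth: TruthTable


# ---------------------------------------------------------------------------
# blueprint machinery: units are written 5'->3' and pasted forward or
# reverse-complemented; oriented offsets map back to genome coordinates.

@dataclass
class _Unit:
    seq: list[str]  # oriented 5'->3'
    genes: list[tuple[int, int]] = field(default_factory=list)  # oriented spans
    transcript: tuple[int, int] | None = None
    tss: list[tuple[int, str, float]] = field(default_factory=list)  # (off, kind, boost)
    ps: list[int] = field(default_factory=list)
    terminator: tuple[int, int] | None = None
    srna: tuple[int, int] | None = None
    sorf: tuple[int, int, int, int] | None = None  # (start, end, rbs_off, tss_off)

    @property
    def length(self) -> int:
        return len(self.seq)


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(BASES[rng.integers(0, 4, size=n)])


def _hairpin_seq(rng: np.random.Generator, stem: int = 8, loop: int = 4) -> str:
    arm = "".join(rng.choice(["G", "C"], size=stem))
    loop_seq = "".join(_random_seq(rng, loop))
    return arm + loop_seq + reverse_complement(arm)


def _operon_unit(
    rng: np.random.Generator,
    n_genes: int,
    with_terminator: bool,
    with_internal_tss: bool,
    with_ps: bool,
    boost_range: tuple[float, float],
) -> _Unit:
    seq: list[str] = []
    unit = _Unit(seq=seq)
    u5 = int(rng.integers(25, 61))
    unit.tss.append((0, "primary", float(rng.uniform(*boost_range))))
    seq.extend(_random_seq(rng, u5))
    for gi in range(n_genes):
        if gi > 0:
            ig = int(rng.integers(50, 71))
            ig_start = len(seq)
            seq.extend(_random_seq(rng, ig))
            if with_internal_tss:
                unit.tss.append(
                    (ig_start + ig // 2, "internal", float(rng.uniform(*boost_range)))
                )
        g_len = int(rng.integers(300, 601))
        g_start = len(seq)
        seq.extend(_random_seq(rng, g_len))
        unit.genes.append((g_start, g_start + g_len - 1))
    u3 = int(rng.integers(30, 51))
    u3_start = len(seq)
    seq.extend(_random_seq(rng, u3))
    if with_ps:
        unit.ps.append(u3_start + 5)
    if with_terminator:
        hp = _hairpin_seq(rng)
        term_start = len(seq)
        seq.extend(list(hp + "T" * 8))
        unit.terminator = (term_start, len(seq) - 1)
        # the transcript runs ~10 nt into the hairpin so coverage drops
        # inside the terminator window
        unit.transcript = (0, term_start + 9)
        seq.extend(_random_seq(rng, 10))
    else:
        unit.transcript = (0, len(seq) - 1)
    return unit


def _srna_unit(rng: np.random.Generator, boost_range: tuple[float, float]) -> _Unit:
    body = int(rng.integers(80, 151))
    seq = _random_seq(rng, body)
    # plant a strong hairpin mid-body so the fold filter is satisfiable
    hp = _hairpin_seq(rng, stem=12, loop=4)
    mid = (body - len(hp)) // 2
    seq[mid : mid + len(hp)] = list(hp)
    unit = _Unit(seq=seq)
    unit.tss.append((0, "srna", float(rng.uniform(*boost_range))))
    unit.transcript = (0, body - 1)
    unit.srna = (0, body - 1)
    return unit


def _sorf_unit(rng: np.random.Generator, boost_range: tuple[float, float]) -> _Unit:
    seq: list[str] = []
    seq.extend(_random_seq(rng, 10))
    rbs_off = len(seq)
    seq.extend(list("AGGAGG"))
    seq.extend(_random_seq(rng, 8))  # RBS gap: 8 nt, inside the 3-15 bound
    orf_start = len(seq)
    seq.extend(list("ATG"))
    for _ in range(13):
        seq.extend(list(_SAFE_CODONS[int(rng.integers(len(_SAFE_CODONS)))]))
    seq.extend(list("TAA"))
    orf_end = len(seq) - 1  # length 45
    seq.extend(_random_seq(rng, 40))
    unit = _Unit(seq=seq)
    unit.tss.append((0, "sorf", float(rng.uniform(*boost_range))))
    unit.transcript = (0, len(seq) - 1)
    unit.sorf = (orf_start, orf_end, rbs_off, 0)
    return unit


def _convergent_unit(rng: np.random.Generator, boost_range: tuple[float, float]) -> _Unit:
    """A plus-strand gene facing a minus-strand gene across a 60 nt gap
    holding a plus-oriented terminator motif.  Only pasted unflipped."""
    seq: list[str] = []
    unit = _Unit(seq=seq)
    u5 = 40
    unit.tss.append((0, "primary", float(rng.uniform(*boost_range))))
    seq.extend(_random_seq(rng, u5))
    g_len = int(rng.integers(350, 501))
    g_start = len(seq)
    seq.extend(_random_seq(rng, g_len))
    unit.genes.append((g_start, g_start + g_len - 1))
    # 60 nt gap: hairpin (stem 8, loop 4 -> 20 nt) + 8 T + filler
    hp = _hairpin_seq(rng)
    term_start = len(seq)
    seq.extend(list(hp + "T" * 8))
    unit.terminator = (term_start, len(seq) - 1)
    unit.transcript = (0, term_start + 9)
    seq.extend(_random_seq(rng, 60 - len(hp) - 8))
    # minus-strand gene; its features are handled specially in _paste
    g2_len = int(rng.integers(350, 501))
    g2_start = len(seq)
    seq.extend(_random_seq(rng, g2_len))
    unit.genes.append((g2_start, g2_start + g2_len - 1))
    # minus-strand transcript: gene2 plus a 30 nt 5' UTR beyond its right end
    seq.extend(_random_seq(rng, 30))
    unit.sorf = None
    # stash minus-strand sub-blueprint in ad-hoc attributes
    unit.minus_gene = (g2_start, g2_start + g2_len - 1)  # type: ignore[attr-defined]
    unit.minus_transcript = (g2_start, len(seq) - 1)  # type: ignore[attr-defined]
    unit.minus_tss_boost = float(rng.uniform(*boost_range))  # type: ignore[attr-defined]
    return unit


# ---------------------------------------------------------------------------

def _paste(
    unit: _Unit,
    cursor: int,
    strand: str,
    sequence: list[str],
    genes: list[Feature],
    truth: TruthTable,
    replicon_id: str,
    gene_counter: list[int],
) -> None:
    L = unit.length
    text = "".join(unit.seq)
    if strand == "-":
        text = reverse_complement(text)
    sequence[cursor : cursor + L] = list(text)

    def to_genome(off: int) -> int:
        return cursor + 1 + off if strand == "+" else cursor + L - off

    def span(a: int, b: int) -> tuple[int, int]:
        x, y = to_genome(a), to_genome(b)
        return (x, y) if x <= y else (y, x)

    convergent = hasattr(unit, "minus_gene")
    for gi, (a, b) in enumerate(unit.genes):
        g_strand = strand
        if convergent and gi == 1:
            g_strand = "-" if strand == "+" else "+"
        s, e = span(a, b)
        gene_counter[0] += 1
        genes.append(
            Feature(
                replicon_id, "synthetic", "gene", s, e, g_strand,
                attributes={"ID": [f"gene{gene_counter[0]:04d}"]},
            )
        )
    if unit.transcript is not None:
        s, e = span(*unit.transcript)
        truth.transcripts.append(PlantedSpan(strand, s, e))
    for off, kind, boost in unit.tss:
        truth.tss.append(PlantedSite(strand, to_genome(off), kind, boost))
    for off in unit.ps:
        truth.ps.append(PlantedSite(strand, to_genome(off)))
    if unit.terminator is not None:
        s, e = span(*unit.terminator)
        truth.terminators.append(PlantedSpan(strand, s, e))
    if unit.srna is not None:
        s, e = span(*unit.srna)
        truth.srnas.append(PlantedSpan(strand, s, e))
    if unit.sorf is not None:
        a, b, rbs_off, tss_off = unit.sorf
        s, e = span(a, b)
        truth.sorfs.append(
            PlantedSorf(strand, s, e, to_genome(rbs_off), to_genome(tss_off))
        )
    if convergent:
        anti = "-" if strand == "+" else "+"
        s, e = span(*unit.minus_transcript)  # type: ignore[attr-defined]
        truth.transcripts.append(PlantedSpan(anti, s, e))
        # the minus transcript's TSS sits at its own 5' end
        tss_pos = e if anti == "-" else s
        truth.tss.append(
            PlantedSite(anti, tss_pos, "primary", unit.minus_tss_boost)  # type: ignore[attr-defined]
        )


def simulate_dataset(
    length: int = 50_000,
    n_operons: int = 24,
    polycistronic_fraction: float = 0.5,
    n_srnas: int = 16,
    n_sorfs: int = 8,
    seed: int = 0,
    replicon_id: str = "synth1",
    tss_boost: tuple[float, float] = (5.0, 12.0),
    terminator_fraction: float = 0.5,
) -> SyntheticDataset:
    """Build a genome with planted transcription units and full truth.

    One convergent gene pair (with an in-gap terminator motif) is always
    included; half the operons are dicistronic with an internal non-genic
    TSS and a processing site by default; sRNA units carry a planted
    hairpin; sORF units carry an AGGAGG RBS 8 nt upstream of a 45 nt ORF.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    rng = np.random.default_rng(seed)

    units: list[_Unit] = [_convergent_unit(rng, tss_boost)]
    n_poly = int(round(n_operons * polycistronic_fraction))
    for i in range(n_operons):
        poly = i < n_poly
        units.append(
            _operon_unit(
                rng,
                n_genes=2 if poly else 1,
                with_terminator=bool(rng.random() < terminator_fraction),
                with_internal_tss=poly,
                with_ps=poly,
                boost_range=tss_boost,
            )
        )
    for _ in range(n_srnas):
        units.append(_srna_unit(rng, tss_boost))
    for _ in range(n_sorfs):
        units.append(_sorf_unit(rng, tss_boost))

    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    total = sum(u.length for u in units)
    n_gaps = len(units) + 1
    slack = length - total
    min_gap = 80
    if slack < n_gaps * min_gap:
        raise ValueError(
            f"infeasible packing: {total} nt of units exceed genome length {length} "
            f"minus required spacing"
        )
    gap = slack // n_gaps

    sequence = _random_seq(rng, length)
    genes: list[Feature] = []
    truth = TruthTable(replicon_id=replicon_id, seed=seed)
    gene_counter = [0]
    cursor = gap
    for unit in units:
        strand = "+" if (hasattr(unit, "minus_gene") or rng.random() < 0.5) else "-"
        _paste(unit, cursor, strand, sequence, genes, truth, replicon_id, gene_counter)
        cursor += unit.length + gap

    genes.sort(key=lambda g: g.start)
    genome = Genome(replicon_id, "".join(sequence))
    return SyntheticDataset(genome, genes, truth)


def simulate_genome(length: int, n_genes: int, seed: int) -> tuple[Genome, list[Feature]]:
    """Random genome with ``n_genes`` non-overlapping genes, including one
    convergent pair with a plantable terminator region of <= 80 nt."""
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2 (the convergent pair)")
    ds = simulate_dataset(
        length=length,
        n_operons=n_genes - 2,
        polycistronic_fraction=0.0,
        n_srnas=0,
        n_sorfs=0,
        seed=seed,
    )
    return ds.genome, ds.genes


def default_libraries(
    conditions: int = 1, replicates: int = 1
) -> list[Library]:
    libs = []
    for c in range(1, conditions + 1):
        cond = f"cond{c}"
        for r in range(1, replicates + 1):
            for treatment in ("TEX_plus", "TEX_minus", "fragmented"):
                libs.append(Library(f"{treatment}_{cond}_{r}", treatment, cond, r))
    return libs


def simulate_coverage(
    genome: Genome,
    truth: TruthTable,
    libraries: list[Library],
    depth: float = 50.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> list[CoverageTrack]:
    """Per-library, per-strand coverage tracks reproducing the planted
    signal patterns; deterministic per seed."""
    L = genome.length
    rng = np.random.default_rng(seed)

    def tx_of(strand: str, position: int) -> PlantedSpan | None:
        for t in truth.transcripts:
            if t.strand == strand and t.start <= position <= t.end:
                return t
        return None

    base: dict[str, np.ndarray] = {}
    for strand in ("+", "-"):
        arr = np.zeros(L)
        for t in truth.transcripts:
            if t.strand == strand:
                arr[t.start - 1 : t.end] = depth
        base[strand] = arr

    tracks: list[CoverageTrack] = []
    for lib in libraries:
        for strand in ("+", "-"):
            arr = base[strand].copy()
            if lib.treatment == "TEX_plus":
                for site in truth.ps:
                    if site.strand != strand:
                        continue
                    t = tx_of(strand, site.position)
                    if t is None:
                        continue
                    if strand == "+":
                        arr[site.position - 1 : t.end] *= PS_DEPLETION
                    else:
                        arr[t.start - 1 : site.position] *= PS_DEPLETION
                for site in truth.tss:
                    if site.strand != strand:
                        continue
                    if strand == "+":
                        lo, hi = site.position, min(site.position + TSS_BOOST_WINDOW - 1, L)
                        arr[lo - 1 : hi] *= site.boost
                    else:
                        lo = max(site.position - TSS_BOOST_WINDOW + 1, 1)
                        arr[lo - 1 : site.position] *= site.boost
            elif lib.treatment == "TEX_minus":
                for site in truth.ps:
                    if site.strand != strand:
                        continue
                    if strand == "+":
                        lo, hi = site.position, min(site.position + PS_WINDOW - 1, L)
                        arr[lo - 1 : hi] *= PS_ENRICHMENT
                    else:
                        lo = max(site.position - PS_WINDOW + 1, 1)
                        arr[lo - 1 : site.position] *= PS_ENRICHMENT
            if noise_sd > 0:
                noise = rng.normal(0.0, noise_sd, size=L)
                expressed = arr > 0
                arr[expressed] = np.maximum(arr[expressed] + noise[expressed], 0.0)
            tracks.append(CoverageTrack(genome.replicon_id, strand, lib, arr))
    return tracks


def curate_subset(truth: TruthTable, region: tuple[int, int]) -> CuratedSet:
    """Planted TSSs restricted to [start, end], formatted for optimization."""
    start, end = region
    if start < 1 or start > end:
        raise ValueError(f"invalid curation region {region}")
    positions = {
        (truth.replicon_id, s.strand, s.position)
        for s in truth.tss
        if start <= s.position <= end
    }
    if not positions:
        raise ValueError(f"no planted TSSs inside region {region}")
    return CuratedSet(positions=positions, region_start=start, region_end=end)


# ---------------------------------------------------------------------------
# file output (fixtures double as format-conformance tests)

def write_dataset(
    dataset: SyntheticDataset,
    tracks: list[CoverageTrack],
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([dataset.genome], outdir / "genome.fa")
    write_gff3(dataset.genes, outdir / "annotation.gff")
    rows = []
    for t in tracks:
        strand_tag = "fwd" if t.strand == "+" else "rev"
        name = f"{t.library.library_id}_{strand_tag}.wig"
        write_wiggle([t], outdir / name)
        rows.append(
            "\t".join(
                [name, t.library.treatment, t.library.condition,
                 str(t.library.replicate), t.strand]
            )
        )
    (outdir / "libraries.tsv").write_text("\n".join(rows) + "\n")

    truth = dataset.truth
    lines = ["feature\tstrand\tstart\tend\tkind\textra"]
    for t in truth.transcripts:
        lines.append(f"transcript\t{t.strand}\t{t.start}\t{t.end}\t.\t.")
    for s in truth.tss:
        lines.append(f"TSS\t{s.strand}\t{s.position}\t{s.position}\t{s.kind}\tboost={s.boost:g}")
    for s in truth.ps:
        lines.append(f"PS\t{s.strand}\t{s.position}\t{s.position}\t.\t.")
    for t in truth.terminators:
        lines.append(f"terminator\t{t.strand}\t{t.start}\t{t.end}\t.\t.")
    for t in truth.srnas:
        lines.append(f"sRNA\t{t.strand}\t{t.start}\t{t.end}\t.\t.")
    for t in truth.sorfs:
        lines.append(
            f"sORF\t{t.strand}\t{t.start}\t{t.end}\t.\trbs={t.rbs_position};tss={t.tss_position}"
        )
    (outdir / "truth.tsv").write_text("\n".join(lines) + "\n")
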