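"""Readers and writers for FASTA, GFF3 and wiggle, plus the core data model.

All public coordinates are 1-based and inclusive, the native convention of
GFF3 and wiggle.  Coverage vectors are stored as numpy arrays indexed from 0,
so genome position ``p`` lives at ``values[p - 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from gffutils.feature import feature_from_line
import gffutils

__all__ = [
    "FormatError",
    "Genome",
    "Feature",
    "Library",
    "CoverageTrack",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_wiggle",
    "write_wiggle",
    "read_library_table",
]

STRANDS = ("+", "-")
TREATMENTS = ("TEX_plus", "TEX_minus", "fragmented")


class FormatError(ValueError):
    """Raised for malformed input files or invariant-violating records."""


@dataclass(frozen=True)
class Genome:
    """A single replicon: id plus its DNA sequence over {A,C,G,T,N}."""

    replicon_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.replicon_id:
            raise FormatError("replicon_id must be nonempty")
        if not self.sequence:
            raise FormatError(f"empty sequence for replicon {self.replicon_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    """A GFF3 record with 1-based inclusive coordinates.

    ``attributes`` maps keys to lists of values (GFF3 multi-value semantics).
    """

    replicon_id: str
    source: str
    feature_type: str
    start: int
    end: int
    strand: str
    score: float | None = None
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"invalid coordinates {self.start}..{self.end} for {self.feature_type}"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"unknown strand symbol {self.strand!r}")

    @property
    def id(self) -> str | None:
        vals = self.attributes.get("ID")
        return vals[0] if vals else None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class Library:
    """One sequencing library: treatment x condition x replicate."""

    library_id: str
    treatment: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise FormatError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.replicate < 1:
            raise FormatError("replicate must be a positive integer")


@dataclass
class CoverageTrack:
    """Per-nucleotide coverage of one replicon strand for one library."""

    replicon_id: str
    strand: str
    library: Library
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise FormatError(f"unknown strand symbol {self.strand!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FormatError("coverage values must be a 1-D vector")
        if np.any(self.values < 0):
            raise FormatError("coverage values must be non-negative")

    @property
    def length(self) -> int:
        return int(self.values.shape[0])


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[Genome]:
    """Read a FASTA file into Genome records.

    Sequences are uppercased and U is converted to T.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no records in {path}")
    genomes = []
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        genomes.append(Genome(rec.id, seq))
    return genomes


def write_fasta(genomes: Sequence[Genome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.replicon_id}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def _feature_from_gff_line(line: str, lineno: int) -> Feature:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise FormatError(f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
    try:
        gf = feature_from_line(line)
    except Exception as exc:  # gffutils raises assorted types
        raise FormatError(f"line {lineno}: {exc}") from exc
    if cols[6] not in STRANDS:
        raise FormatError(f"line {lineno}: unknown strand symbol {cols[6]!r}")
    try:
        start, end = int(cols[3]), int(cols[4])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer coordinates") from exc
    if start > end:
        raise FormatError(f"line {lineno}: start {start} > end {end}")
    score = None if cols[5] == "." else float(cols[5])
    attrs = {k: list(v) for k, v in gf.attributes.items()}
    try:
        return Feature(cols[0], cols[1], cols[2], start, end, cols[6], score, attrs)
    except FormatError as exc:
        raise FormatError(f"line {lineno}: {exc}") from exc


def read_gff3(path: str | Path) -> list[Feature]:
    """Read a GFF3 file; features are returned sorted by (replicon, start)."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            feats.append(_feature_from_gff_line(line, lineno))
    feats.sort(key=lambda f: (f.replicon_id, f.start, f.end))
    return feats


def _feature_to_gff_line(f: Feature) -> str:
    gf = gffutils.Feature(
        seqid=f.replicon_id,
        source=f.source,
        featuretype=f.feature_type,
        start=f.start,
        end=f.end,
        score="." if f.score is None else format(f.score, "g"),
        strand=f.strand,
        frame=".",
        attributes={k: list(v) for k, v in f.attributes.items()},
    )
    return str(gf)


def write_gff3(features: Sequence[Feature], path: str | Path) -> None:
    """Write features as GFF3; read_gff3(write_gff3(F)) reproduces F."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(_feature_to_gff_line(f) + "\n")


# ---------------------------------------------------------------------------
# Wiggle

def read_wiggle(
    path: str | Path,
    library: Library,
    strand: str,
    replicon_lengths: dict[str, int],
    allow_negative: bool = False,
) -> list[CoverageTrack]:
    """Read a variableStep/fixedStep wiggle file (span=1 only).

    Unlisted positions get coverage 0.  ``allow_negative`` accepts the common
    reverse-strand dialect that stores coverage as negative numbers, taking
    absolute values; the default is strict non-negative.
    """
    if strand not in STRANDS:
        raise FormatError(f"unknown strand symbol {strand!r}")
    tracks: dict[str, np.ndarray] = {}
    mode: str | None = None
    chrom: str | None = None
    pos = step = 0

    def _require_chrom(lineno: int) -> np.ndarray:
        if chrom is None:
            raise FormatError(f"line {lineno}: data before any step declaration")
        if chrom not in tracks:
            if chrom not in replicon_lengths:
                raise FormatError(f"line {lineno}: unknown replicon {chrom!r}")
            tracks[chrom] = np.zeros(replicon_lengths[chrom], dtype=float)
        return tracks[chrom]

    def _store(arr: np.ndarray, p: int, v: float, lineno: int) -> None:
        if v < 0:
            if not allow_negative:
                raise FormatError(f"line {lineno}: negative coverage value {v}")
            v = abs(v)
        if p < 1 or p > arr.shape[0]:
            raise FormatError(
                f"line {lineno}: position {p} outside replicon of length {arr.shape[0]}"
            )
        arr[p - 1] = v

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith(("variableStep", "fixedStep")):
                fields = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                if "chrom" not in fields:
                    raise FormatError(f"line {lineno}: step declaration without chrom")
                if int(fields.get("span", 1)) != 1:
                    raise FormatError(f"line {lineno}: only span=1 is supported")
                chrom = fields["chrom"]
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    try:
                        pos = int(fields["start"])
                        step = int(fields.get("step", 1))
                    except (KeyError, ValueError) as exc:
                        raise FormatError(f"line {lineno}: bad fixedStep header") from exc
                else:
                    mode = "variable"
                _require_chrom(lineno)
                continue
            arr = _require_chrom(lineno)
            parts = line.split()
            try:
                if mode == "variable":
                    if len(parts) != 2:
                        raise ValueError("expected <position> <value>")
                    p, v = int(parts[0]), float(parts[1])
                elif mode == "fixed":
                    if len(parts) != 1:
                        raise ValueError("expected a single value")
                    p, v = pos, float(parts[0])
                    pos += step
                else:
                    raise ValueError("data before any step declaration")
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            _store(arr, p, v, lineno)

    return [
        CoverageTrack(replicon_id=c, strand=strand, library=library, values=vals)
        for c, vals in sorted(tracks.items())
    ]


def write_wiggle(tracks: Sequence[CoverageTrack], path: str | Path) -> None:
    """Write tracks as variableStep wiggle (zero positions omitted)."""
    with open(path, "w") as fh:
        for t in tracks:
            fh.write(f"variableStep chrom={t.replicon_id}\n")
            (idx,) = np.nonzero(t.values)
            for i in idx:
                fh.write(f"{i + 1} {format(t.values[i], 'g')}\n")


# ---------------------------------------------------------------------------
# Library metadata table

def read_library_table(path: str | Path) -> list[tuple[str, Library, str]]:
    """Read the tab-separated library config: path, treatment, condition,
    replicate, strand.  Returns (wiggle_path, Library, strand) triples."""
    out: list[tuple[str, Library, str]] = []
    seen: set[tuple[str, str, int, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise FormatError(
                    f"line {lineno}: expected 5 tab-separated columns, got {len(cols)}"
                )
            wig_path, treatment, condition, replicate_s, strand = cols
            try:
                replicate = int(replicate_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad replicate {replicate_s!r}") from exc
            if strand not in STRANDS:
                raise FormatError(f"line {lineno}: unknown strand symbol {strand!r}")
            key = (treatment, condition, replicate, strand)
            if key in seen:
                raise FormatError(f"line {lineno}: duplicate library {key}")
            seen.add(key)
            lib_id = f"{treatment}_{condition}_{replicate}"
            out.append((wig_path, Library(lib_id, treatment, condition, replicate), strand))
    return out
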