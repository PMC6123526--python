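"""Pipeline orchestration: run the detectors in dependency order from one
config, with per-stage GFF3 output, logging and a summary table.

Stages run topologically: transcript -> tss/ps -> (optimize) -> terminator
-> utr -> operon -> srna -> sorf.  Runs with only fragmented libraries
degrade gracefully: stages that need dRNA-seq pairs are skipped with a
logged reason, provided nothing enabled depends on them.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .boundary_annotate import derive_utrs, detect_operons, operon_summary, utr_length_histogram
from .coverage_model import normalize_tracks
from .genome_io import (
    CoverageTrack,
    read_fasta,
    read_gff3,
    read_library_table,
    read_wiggle,
    write_gff3,
)
from .srna_detect import SRNAParams, apply_quality_filters, detect_intergenic, detect_utr_derived
from .sorf_detect import SORFParams, detect_sorfs
from .terminator_detect import TerminatorCall, confirm_by_coverage, detect_convergent, dedupe_per_gene
from .transcript_detect import call_transcripts, expression_summary, merge_with_genes
from .tss_ps_detect import ParamSet, call_sites, classify_tss
from .synthetic_data import curate_subset  # noqa: F401  (CLI convenience re-export)

__all__ = ["ConfigError", "RunConfig", "run_pipeline", "read_config"]

ALL_STAGES = ("transcript", "tss", "ps", "terminator", "utr", "operon", "srna", "sorf")

# per-stage hard dependencies on other stages
STAGE_DEPS = {
    "transcript": (),
    "tss": (),
    "ps": (),
    "terminator": ("transcript",),
    "utr": ("tss", "transcript", "terminator"),
    "operon": ("tss", "transcript"),
    "srna": ("tss", "transcript", "utr"),
    "sorf": ("tss", "transcript", "utr"),
}

DRNA_STAGES = ("tss", "ps")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    genome: str = ""
    annotation: str = ""
    libraries: str = ""
    output_dir: str = "rnannotate_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    normalize: bool = True
    # per-stage parameter blocks
    transcript_params: dict = field(default_factory=dict)
    site_params: ParamSet = field(default_factory=ParamSet)
    terminator_params: dict = field(default_factory=dict)
    srna_params: SRNAParams = field(default_factory=SRNAParams)
    sorf_params: SORFParams = field(default_factory=SORFParams)

    def validate(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ConfigError(f"unknown stage {s!r}")
        enabled = set(self.stages)
        for s in self.stages:
            missing = [d for d in STAGE_DEPS[s] if d not in enabled]
            if missing:
                raise ConfigError(
                    f"stage {s!r} requires disabled stage(s): {', '.join(missing)}"
                )
        for name, path in (("genome", self.genome), ("annotation", self.annotation),
                           ("libraries", self.libraries)):
            if not path:
                raise ConfigError(f"missing required input path: {name}")
            if not Path(path).exists():
                raise ConfigError(f"{name} file not found: {path}")


def read_config(path: str | Path) -> RunConfig:
    """Flat key=value config with [section] blocks."""
    cfg = RunConfig()
    section = ""
    site_kwargs: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].strip()
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if section in ("", "run"):
                if key in ("genome", "annotation", "libraries", "output_dir"):
                    setattr(cfg, key, value)
                elif key == "stages":
                    cfg.stages = tuple(s.strip() for s in value.split(",") if s.strip())
                elif key == "seed":
                    cfg.seed = int(value)
                elif key == "normalize":
                    cfg.normalize = value.lower() in ("1", "true", "yes")
                else:
                    raise ConfigError(f"line {lineno}: unknown run key {key!r}")
            elif section == "transcript":
                cfg.transcript_params[key] = float(value) if key == "cutoff" else int(value)
            elif section == "site":
                site_kwargs[key] = float(value)
            elif section == "terminator":
                cfg.terminator_params[key] = (
                    float(value) if key == "drop_cutoff" else int(value)
                )
            elif section == "srna":
                setattr(
                    cfg.srna_params, key,
                    float(value) if key in ("fold_cutoff", "drop_ratio") else int(value),
                )
            elif section == "sorf":
                setattr(cfg.sorf_params, key, int(value))
            else:
                raise ConfigError(f"line {lineno}: unknown section {section!r}")
    if site_kwargs:
        cfg.site_params = ParamSet(**site_kwargs)
    return cfg


class _Log:
    def __init__(self, path: Path):
        self.fh = open(path, "w")

    def __call__(self, msg: str) -> None:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        line = f"[{stamp}] {msg}"
        print(line, file=sys.stderr)
        self.fh.write(line + "\n")

    def close(self) -> None:
        self.fh.close()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages; returns the output directory.

    Writes one GFF3 per stage, a run.log with every effective parameter and
    a summary.tsv of per-stage feature counts.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "run.log")
    counts: dict[str, int] = {}
    try:
        log(f"rnannotate {__version__} seed={config.seed} stages={','.join(config.stages)}")
        genomes = read_fasta(config.genome)
        genome_by_id = {g.replicon_id: g for g in genomes}
        lengths = {g.replicon_id: g.length for g in genomes}
        genes = read_gff3(config.annotation)
        log(f"inputs: {len(genomes)} replicon(s), {len(genes)} annotated feature(s)")

        tracks: list[CoverageTrack] = []
        lib_dir = Path(config.libraries).parent
        for wig_path, library, strand in read_library_table(config.libraries):
            p = Path(wig_path)
            if not p.is_absolute():
                p = lib_dir / p
            tracks.extend(read_wiggle(p, library, strand, lengths))
        log(f"loaded {len(tracks)} coverage track(s)")
        if config.normalize:
            tracks = normalize_tracks(tracks)
            log("normalized tracks to the mean library total")

        tex_plus = [t for t in tracks if t.library.treatment == "TEX_plus"]
        tex_minus = [t for t in tracks if t.library.treatment == "TEX_minus"]
        have_drna = bool(tex_plus) and bool(tex_minus)

        enabled = set(config.stages)
        skipped = []
        if not have_drna:
            for s in DRNA_STAGES:
                if s in enabled:
                    skipped.append(s)
                    enabled.discard(s)
                    log(f"stage {s} skipped: no TEX+/TEX- library pairs")
            # stages depending on skipped ones cannot run either
            for s in list(enabled):
                if any(d in skipped for d in STAGE_DEPS[s]):
                    enabled.discard(s)
                    log(f"stage {s} skipped: depends on skipped dRNA-seq stage")

        transcripts = []
        if "transcript" in enabled:
            tp = {"cutoff": 5.0, "tolerance": 5, "min_length": 20}
            tp.update(config.transcript_params)
            log(f"transcript: {tp}")
            transcripts = merge_with_genes(
                call_transcripts(tracks, **tp), genes
            )
            write_gff3([t.to_feature() for t in transcripts], outdir / "transcripts.gff")
            total, covered, frac = expression_summary(transcripts, genes)
            counts["transcript"] = len(transcripts)
            log(
                f"transcript: {len(transcripts)} calls covering {covered}/{total} genes"
                f" ({100 * frac:.1f}%)"
            )

        tss_sites = []
        if "tss" in enabled:
            log(f"tss: params={config.site_params.as_dict()}")
            tss_sites = classify_tss(
                call_sites(tex_plus, tex_minus, config.site_params, mode="TSS"), genes
            )
            write_gff3([s.to_feature() for s in tss_sites], outdir / "tss.gff")
            counts["tss"] = len(tss_sites)
            log(f"tss: {len(tss_sites)} sites")

        ps_sites = []
        if "ps" in enabled:
            ps_sites = call_sites(tex_plus, tex_minus, config.site_params, mode="PS")
            write_gff3([s.to_feature() for s in ps_sites], outdir / "processing_sites.gff")
            counts["ps"] = len(ps_sites)
            log(f"ps: {len(ps_sites)} sites")

        terminators: list[TerminatorCall] = []
        if "terminator" in enabled:
            tp = {"drop_cutoff": 0.5, "flank": 30, "max_region": 80, "min_t": 5}
            tp.update(config.terminator_params)
            log(f"terminator: {tp}")
            frag_tracks = [t for t in tracks if t.library.treatment != "TEX_plus"]
            for g in genomes:
                cands = detect_convergent(
                    genes, g, max_region=tp["max_region"], min_t=tp["min_t"]
                )
                terminators.extend(
                    confirm_by_coverage(
                        cands, frag_tracks, drop_cutoff=tp["drop_cutoff"], flank=tp["flank"]
                    )
                )
            terminators = dedupe_per_gene(terminators, genes)
            write_gff3([t.to_feature() for t in terminators], outdir / "terminators.gff")
            counts["terminator"] = len(terminators)
            counts["terminator_confirmed"] = sum(1 for t in terminators if t.confirmed)
            log(
                f"terminator: {len(terminators)} candidates, "
                f"{counts['terminator_confirmed']} confirmed"
            )

        utrs = []
        if "utr" in enabled:
            utrs = derive_utrs(tss_sites, transcripts, terminators, genes)
            write_gff3([u.to_feature() for u in utrs], outdir / "utrs.gff")
            hist = utr_length_histogram(utrs)
            with open(outdir / "utr_lengths.tsv", "w") as fh:
                fh.write("bin_start\tcount\n")
                for b, n in hist:
                    fh.write(f"{b}\t{n}\n")
            counts["utr"] = len(utrs)
            log(f"utr: {len(utrs)} regions")

        if "operon" in enabled:
            operons = detect_operons(transcripts, genes, tss_sites)
            feats = []
            for i, o in enumerate(operons, start=1):
                feats.extend(o.to_features(f"operon{i:04d}"))
            write_gff3(feats, outdir / "operons.gff")
            total, mono, poly = operon_summary(operons)
            counts["operon"] = total
            log(f"operon: {total} total ({mono} monocistronic, {poly} polycistronic)")

        if "srna" in enabled:
            sp = config.srna_params
            log(f"srna: min_len={sp.min_len} max_len={sp.max_len} fold_cutoff={sp.fold_cutoff}")
            cands = detect_intergenic(transcripts, genes, tss_sites, ps_sites, tracks, sp)
            cands += detect_utr_derived(
                transcripts, genes, tss_sites, ps_sites, tracks, utrs, sp
            )
            for g in genomes:
                mine = [c for c in cands if c.replicon_id == g.replicon_id]
                apply_quality_filters(mine, g, params=sp)
            passed = [c for c in cands if c.passed_filters]
            write_gff3([c.to_feature() for c in passed], outdir / "srnas.gff")
            write_gff3(
                [c.to_feature() for c in cands if not c.passed_filters],
                outdir / "srnas_rejected.gff",
            )
            with open(outdir / "srnas.fa", "w") as fh:
                for i, c in enumerate(passed, start=1):
                    fh.write(f">srna{i:04d} {c.replicon_id}:{c.start}-{c.end}({c.strand})\n")
                    fh.write(c.sequence(genome_by_id[c.replicon_id]) + "\n")
            counts["srna"] = len(passed)
            log(f"srna: {len(passed)} passed of {len(cands)} candidates")

        if "sorf" in enabled:
            sorfs = []
            for g in genomes:
                sorfs.extend(
                    detect_sorfs(transcripts, genes, tss_sites, utrs, g, config.sorf_params)
                )
            write_gff3([s.to_feature() for s in sorfs], outdir / "sorfs.gff")
            counts["sorf"] = len(sorfs)
            log(f"sorf: {len(sorfs)} candidates")

        with open(outdir / "summary.tsv", "w") as fh:
            fh.write("feature\tcount\n")
            for k, v in counts.items():
                fh.write(f"{k}\t{v}\n")
        log("done")
    finally:
        log.close()
    return outdir
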