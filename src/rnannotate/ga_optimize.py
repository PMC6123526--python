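"""Genetic-algorithm optimization of the seven site-calling parameters.

A single-parent hill climb with three move kinds per cycle — random (all
seven parameters resampled), large (exactly two resampled) and small (one
parameter nudged by +/- small_step) — evaluated against a curated site set.
A candidate replaces the incumbent when at least one of six decision
conditions holds; conditions 5 and 6 only apply to curated sets of 100+
sites.  The full trace is recorded for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import CoverageTrack
from .tss_ps_detect import (
    PARAM_NAMES,
    CuratedSet,
    EvalStats,
    ParamSet,
    _call_positions,
    evaluate_positions,
)

__all__ = [
    "OptimizationConfig",
    "TraceEntry",
    "decision_replace",
    "mutate",
    "optimize",
]

MOVE_KINDS = ("random", "large", "small")

DEFAULT_RANGES: dict[str, tuple[float, float, float]] = {
    "height": (0.0, 2.5, 0.1),
    "height_reduction": (0.0, 2.5, 0.1),
    "factor": (0.0, 10.0, 0.1),
    "factor_reduction": (0.0, 10.0, 0.1),
    "enrichment_factor": (0.0, 10.0, 0.1),
    "processing_site_factor": (0.0, 10.0, 0.1),
    "base_height": (0.0, 2.5, 0.1),
}


@dataclass
class OptimizationConfig:
    max_runs: int = 4000
    param_ranges: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    seed: int = 0
    match_tolerance: int = 2
    cluster_width: int = 3

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi, step = self.param_ranges[name]
            if lo > hi:
                raise ValueError(f"min > max for parameter {name}")
            if step <= 0:
                raise ValueError(f"small_step must be > 0 for parameter {name}")


@dataclass(frozen=True)
class TraceEntry:
    run_index: int
    params: ParamSet
    stats: EvalStats
    replaced: bool
    move_kind: str


def decision_replace(current: EvalStats, best: EvalStats) -> bool:
    """True iff the current parameter set should replace the best one.

    The six conditions (disjunction):
      1. TPR_c - TPR_b >= 0.1
      2. TPR_c > TPR_b and FPR_c < FPR_b
      3. TP_b - TP_c > 0 and FP_b - FP_c >= 5 * (TP_b - TP_c)
      4. TP_b - TP_c < 0 and FP_c - FP_b <= 5 * (TP_c - TP_b)
      5. TP_m >= 100 and TPR_c - TPR_b >= 0.01 and FPR_c - FPR_b <= 5e-5
      6. TP_m >= 100 and TPR_b - TPR_c <= 0.01 and FPR_b - FPR_c >= 5e-5
    """
    if current.TP_m != best.TP_m:
        raise ValueError("current and best were evaluated against different curated sets")
    c, b = current, best
    if c.TPR - b.TPR >= 0.1:
        return True
    if c.TPR > b.TPR and c.FPR < b.FPR:
        return True
    d_tp = b.TP - c.TP
    if d_tp > 0 and b.FP - c.FP >= 5 * d_tp:
        return True
    if d_tp < 0 and c.FP - b.FP <= 5 * (c.TP - b.TP):
        return True
    if c.TP_m >= 100:
        if c.TPR - b.TPR >= 0.01 and c.FPR - b.FPR <= 5e-5:
            return True
        if b.TPR - c.TPR <= 0.01 and b.FPR - c.FPR >= 5e-5:
            return True
    return False


def _clamp(value: float, lo: float, hi: float) -> float:
    return min(max(value, lo), hi)


def _impose_invariants(values: dict[str, float]) -> dict[str, float]:
    # reductions may never exceed their base parameter; clamp the reduction
    values["height_reduction"] = min(values["height_reduction"], values["height"])
    values["factor_reduction"] = min(values["factor_reduction"], values["factor"])
    return values


def mutate(
    params: ParamSet,
    kind: str,
    config: OptimizationConfig,
    rng: np.random.Generator,
) -> ParamSet:
    """Produce a candidate: resample all (random), exactly two (large), or
    nudge one parameter by +/- its small_step (small), clamped to range."""
    if kind not in MOVE_KINDS:
        raise ValueError(f"unknown move kind {kind!r}")
    values = params.as_dict()
    if kind == "random":
        for name in PARAM_NAMES:
            lo, hi, _ = config.param_ranges[name]
            values[name] = float(rng.uniform(lo, hi))
    elif kind == "large":
        chosen = rng.choice(len(PARAM_NAMES), size=2, replace=False)
        for ci in chosen:
            name = PARAM_NAMES[int(ci)]
            lo, hi, _ = config.param_ranges[name]
            values[name] = float(rng.uniform(lo, hi))
    else:  # small
        name = PARAM_NAMES[int(rng.integers(len(PARAM_NAMES)))]
        lo, hi, step = config.param_ranges[name]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        values[name] = _clamp(values[name] + sign * step, lo, hi)
    return ParamSet(**_impose_invariants(values))


def _evaluate_candidate(
    tex_plus: list[CoverageTrack],
    tex_minus: list[CoverageTrack],
    params: ParamSet,
    curated: CuratedSet,
    mode: str,
    config: OptimizationConfig,
) -> EvalStats:
    raw = _call_positions(
        tex_plus, tex_minus, params, mode,
        cluster_width=config.cluster_width, with_conditions=False,
    )
    call_positions = {k: v[0] for k, v in raw.items()}
    return evaluate_positions(call_positions, curated, config.match_tolerance)


def _perfect(stats: EvalStats) -> bool:
    return stats.TPR == 1.0 and stats.FPR == 0.0


def optimize(
    tex_plus: list[CoverageTrack],
    tex_minus: list[CoverageTrack],
    curated: CuratedSet,
    mode: str = "TSS",
    config: OptimizationConfig | None = None,
    initial: ParamSet | None = None,
) -> tuple[ParamSet, list[TraceEntry]]:
    """Hill-climb the seven parameters against a curated set.

    Candidates are generated from the incumbent in the cycle
    random -> large -> small; each is evaluated and `decision_replace`
    decides replacement.  Stops after ``max_runs`` evaluated candidates or
    as soon as the incumbent is perfect (TPR 1, FPR 0).  Fully reproducible
    given ``config.seed``.
    """
    if not curated.positions:
        raise ValueError("empty curated set")
    config = config or OptimizationConfig()
    rng = np.random.default_rng(config.seed)
    best = initial if initial is not None else ParamSet()
    best_stats = _evaluate_candidate(tex_plus, tex_minus, best, curated, mode, config)
    trace: list[TraceEntry] = []
    run = 0
    while run < config.max_runs and not _perfect(best_stats):
        for kind in MOVE_KINDS:
            if run >= config.max_runs:
                break
            candidate = mutate(best, kind, config, rng)
            stats = _evaluate_candidate(
                tex_plus, tex_minus, candidate, curated, mode, config
            )
            replaced = decision_replace(stats, best_stats)
            run += 1
            trace.append(TraceEntry(run, candidate, stats, replaced, kind))
            if replaced:
                best, best_stats = candidate, stats
            if _perfect(best_stats):
                break
    return best, trace


def write_params(params: ParamSet, path) -> None:
    with open(path, "w") as fh:
        for name in PARAM_NAMES:
            fh.write(f"{name}={getattr(params, name)!r}\n")


def read_params(path) -> ParamSet:
    values: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = float(val)
    return ParamSet(**values)


def write_trace(trace: list[TraceEntry], path) -> None:
    cols = ["run_index", "move_kind", "replaced", "TP", "FP", "TPR", "FPR"] + list(PARAM_NAMES)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in trace:
            row = [
                str(e.run_index), e.move_kind, str(int(e.replaced)),
                str(e.stats.TP), str(e.stats.FP),
                format(e.stats.TPR, "g"), format(e.stats.FPR, "g"),
            ] + [format(getattr(e.params, n), "g") for n in PARAM_NAMES]
            fh.write("\t".join(row) + "\n")
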