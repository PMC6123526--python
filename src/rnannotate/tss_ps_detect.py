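"""TSS and processing-site calling from dRNA-seq coverage pairs.

A transcriptional start site shows a sharp coverage step in the TEX+ library
together with TEX+/TEX- enrichment (the exonuclease degrades processed
5'-monophosphate RNA, so primary 5' ends survive treatment).  A processing
site is the mirrored pattern: a step in the TEX- library enriched relative
to TEX+.  Calling is governed by seven parameters (height, height_reduction,
factor, factor_reduction, enrichment_factor, processing_site_factor,
base_height) so that a genetic algorithm can tune them against a curated set.

All comparisons use >= so that small parameter steps act predictably.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import CoverageTrack, Feature

__all__ = [
    "ParamSet",
    "SiteCall",
    "CuratedSet",
    "EvalStats",
    "site_statistics",
    "call_sites",
    "classify_tss",
    "evaluate",
]

EPSILON = 1.0  # pseudo-count for coverage ratios

TSS_CLASSES = ("primary", "secondary", "internal", "antisense", "orphan")


@dataclass(frozen=True)
class ParamSet:
    """The seven site-calling thresholds mutated by the optimizer.

    Defaults follow the conventional TSSpredator-style settings for
    normalized dRNA-seq coverage.
    """

    height: float = 0.3
    height_reduction: float = 0.2
    factor: float = 2.0
    factor_reduction: float = 0.5
    enrichment_factor: float = 2.0
    processing_site_factor: float = 1.5
    base_height: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.height_reduction > self.height:
            raise ValueError("height_reduction must not exceed height")
        if self.factor_reduction > self.factor:
            raise ValueError("factor_reduction must not exceed factor")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


PARAM_NAMES = (
    "height",
    "height_reduction",
    "factor",
    "factor_reduction",
    "enrichment_factor",
    "processing_site_factor",
    "base_height",
)


@dataclass
class SiteCall:
    replicon_id: str
    strand: str
    position: int
    site_type: str  # "TSS" or "PS"
    classes: set[str] = field(default_factory=set)
    step_height: float = 0.0
    step_factor: float = 0.0
    enrichment: float = 0.0
    conditions: tuple[str, ...] = ()

    def to_feature(self, source: str = "rnannotate") -> Feature:
        ftype = "TSS" if self.site_type == "TSS" else "processing_site"
        attrs = {
            "step_height": [format(self.step_height, "g")],
            "enrichment": [format(self.enrichment, "g")],
            "condition": [",".join(self.conditions) if self.conditions else "."],
        }
        if self.classes:
            attrs["class"] = sorted(self.classes)
        return Feature(
            self.replicon_id, source, ftype, self.position, self.position,
            self.strand, attributes=attrs,
        )


@dataclass
class CuratedSet:
    """A manually curated site set restricted to a genome region."""

    positions: set[tuple[str, str, int]]
    region_start: int
    region_end: int

    def __post_init__(self) -> None:
        for _, _, pos in self.positions:
            if not self.region_start <= pos <= self.region_end:
                raise ValueError(f"curated position {pos} outside region")

    @property
    def region_length(self) -> int:
        return self.region_end - self.region_start + 1


@dataclass(frozen=True)
class EvalStats:
    TP: int
    FP: int
    TPR: float
    FPR: float
    TP_m: int


# ---------------------------------------------------------------------------
# oriented helpers

def _oriented(values: np.ndarray, strand: str) -> np.ndarray:
    return values if strand == "+" else values[::-1]


def _oriented_index(position: int, strand: str, length: int) -> int:
    """0-based index of a genome position in a 5'->3' oriented array."""
    return position - 1 if strand == "+" else length - position


def site_statistics(
    tex_plus: CoverageTrack, tex_minus: CoverageTrack, position: int
) -> tuple[float, float, float]:
    """(step_height, step_factor, enrichment) at one position.

    step_height = plus(pos) - plus(upstream neighbor); step_factor is the
    same as a ratio with pseudo-count EPSILON; enrichment = plus/minus at the
    position.  Upstream is taken in strand orientation.
    """
    if tex_plus.strand != tex_minus.strand or tex_plus.replicon_id != tex_minus.replicon_id:
        raise ValueError("track pair must share replicon and strand")
    n = tex_plus.length
    a = _oriented(tex_plus.values, tex_plus.strand)
    b = _oriented(tex_minus.values, tex_minus.strand)
    i = _oriented_index(position, tex_plus.strand, n)
    if i < 1 or i >= n:
        raise IndexError("position has no upstream neighbor in strand orientation")
    step_height = float(a[i] - a[i - 1])
    step_factor = float(a[i] / max(a[i - 1], EPSILON))
    enrichment = float(a[i] / max(b[i], EPSILON))
    return step_height, step_factor, enrichment


def _candidate_arrays(
    fg: np.ndarray, bg: np.ndarray, params: ParamSet, enrich_threshold: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized threshold evaluation on oriented arrays.

    ``fg`` is the track carrying the step (TEX+ for TSS, TEX- for PS);
    ``bg`` the opposite treatment.  Returns (oriented indices, step_height,
    step_factor, enrichment) of called positions.
    """
    prev = fg[:-1]
    cur = fg[1:]
    sh = cur - prev
    sf = cur / np.maximum(prev, EPSILON)
    en = cur / np.maximum(bg[1:], EPSILON)
    strict = (sh >= params.height) & (sf >= params.factor)
    reduced = (
        (en >= enrich_threshold)
        & (sh >= params.height - params.height_reduction)
        & (sf >= params.factor - params.factor_reduction)
    )
    mask = (cur >= params.base_height) & (en >= 1.0) & (strict | reduced)
    idx = np.nonzero(mask)[0] + 1
    return idx, sh[idx - 1], sf[idx - 1], en[idx - 1]


def _cluster(
    positions: np.ndarray, heights: np.ndarray, cluster_width: int
) -> np.ndarray:
    """Merge called positions within ``cluster_width`` nt; the highest
    step_height wins, ties going to the 5'-most (here: lowest oriented
    index).  Returns indices into the input arrays, sorted by position."""
    if positions.size == 0:
        return np.array([], dtype=int)
    order = np.argsort(positions, kind="stable")
    pos = positions[order]
    h = heights[order]
    breaks = np.nonzero(np.diff(pos) > cluster_width)[0] + 1
    groups = np.zeros(pos.size, dtype=int)
    groups[breaks] = 1
    groups = np.cumsum(groups)
    # within each group pick max height, tie -> smallest oriented position
    sel = np.lexsort((pos, -h, groups))
    first_of_group = np.ones(pos.size, dtype=bool)
    first_of_group[1:] = groups[sel][1:] != groups[sel][:-1]
    winners = sel[first_of_group]
    return order[winners]


def _pair_tracks(
    tex_plus: list[CoverageTrack], tex_minus: list[CoverageTrack]
) -> list[tuple[CoverageTrack, CoverageTrack]]:
    minus_by_key = {
        (t.replicon_id, t.strand, t.library.condition, t.library.replicate): t
        for t in tex_minus
    }
    pairs = []
    for tp in tex_plus:
        key = (tp.replicon_id, tp.strand, tp.library.condition, tp.library.replicate)
        tm = minus_by_key.get(key)
        if tm is not None:
            pairs.append((tp, tm))
    return pairs


def _call_positions(
    tex_plus: list[CoverageTrack],
    tex_minus: list[CoverageTrack],
    params: ParamSet,
    mode: str,
    cluster_width: int = 3,
    with_conditions: bool = True,
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[tuple[str, ...]]]]:
    """Fast array path shared by call_sites and the optimizer.

    Returns per (replicon, strand): genome positions (sorted), step_height,
    step_factor, enrichment arrays and per-site supporting-condition tuples
    (empty tuples when ``with_conditions`` is off, as in the optimizer's hot
    loop).
    """
    if mode not in ("TSS", "PS"):
        raise ValueError("mode must be 'TSS' or 'PS'")
    pairs = _pair_tracks(tex_plus, tex_minus)
    if not pairs:
        raise ValueError("no TEX+/TEX- library pairs")

    cond_ids: dict[str, int] = {}
    per_key: dict[tuple[str, str], dict] = {}
    for tp, tm in pairs:
        key = (tp.replicon_id, tp.strand)
        a = _oriented(tp.values, tp.strand)
        b = _oriented(tm.values, tm.strand)
        if mode == "TSS":
            idx, sh, sf, en = _candidate_arrays(a, b, params, params.enrichment_factor)
        else:
            idx, sh, sf, en = _candidate_arrays(b, a, params, params.processing_site_factor)
        cid = cond_ids.setdefault(tp.library.condition, len(cond_ids))
        acc = per_key.setdefault(key, {"idx": [], "sh": [], "sf": [], "en": [], "cond": []})
        acc["idx"].append(idx)
        acc["sh"].append(sh)
        acc["sf"].append(sf)
        acc["en"].append(en)
        acc["cond"].append(np.full(idx.shape, cid, dtype=np.int64))
        acc["length"] = tp.length

    cond_names = {v: k for k, v in cond_ids.items()}
    out = {}
    for key, acc in per_key.items():
        idx = np.concatenate(acc["idx"])
        sh = np.concatenate(acc["sh"])
        sf = np.concatenate(acc["sf"])
        en = np.concatenate(acc["en"])
        cond = np.concatenate(acc["cond"])
        keep = _cluster(idx, sh, cluster_width)
        order = np.argsort(idx[keep], kind="stable")
        keep = keep[order]
        kept_idx = idx[keep]
        if with_conditions:
            # supporting conditions: any condition with a raw call in the cluster
            raw_order = np.argsort(idx, kind="stable")
            sorted_idx = idx[raw_order]
            conds = []
            for i in keep:
                lo = np.searchsorted(sorted_idx, idx[i] - cluster_width, side="left")
                hi = np.searchsorted(sorted_idx, idx[i] + cluster_width, side="right")
                near = raw_order[lo:hi]
                conds.append(tuple(sorted({cond_names[int(c)] for c in cond[near]})))
        else:
            conds = [()] * kept_idx.size
        n = acc["length"]
        strand = key[1]
        if strand == "+":
            genome_pos = kept_idx + 1
        else:
            genome_pos = n - kept_idx
        out[key] = (genome_pos, sh[keep], sf[keep], en[keep], conds)
    return out


def call_sites(
    tex_plus: list[CoverageTrack],
    tex_minus: list[CoverageTrack],
    params: ParamSet,
    mode: str = "TSS",
    cluster_width: int = 3,
) -> list[SiteCall]:
    """Call TSSs (TEX+ step + enrichment) or PSs (the reverse pattern).

    A site called in at least one condition is reported, carrying all
    supporting conditions; calls within ``cluster_width`` nt are merged,
    keeping the one with the highest step height (ties: 5'-most).
    """
    raw = _call_positions(tex_plus, tex_minus, params, mode, cluster_width)
    calls: list[SiteCall] = []
    for (replicon, strand), (pos, sh, sf, en, conds) in sorted(raw.items()):
        for p, h, f, e, c in zip(pos, sh, sf, en, conds):
            calls.append(
                SiteCall(
                    replicon, strand, int(p), mode,
                    step_height=float(h), step_factor=float(f),
                    enrichment=float(e), conditions=c,
                )
            )
    calls.sort(key=lambda s: (s.replicon_id, s.position, s.strand))
    return calls


# ---------------------------------------------------------------------------
# classification

def classify_tss(
    sites: list[SiteCall],
    genes: list[Feature],
    utr_window: int = 300,
    antisense_flank: int = 100,
) -> list[SiteCall]:
    """Assign {primary, secondary, internal, antisense, orphan} classes.

    Per gene, the strongest TSS within ``utr_window`` nt upstream of the gene
    start (same strand) is primary (ties: closest to the gene); other TSSs in
    the window are secondary.  TSSs inside a gene body are internal (same
    strand) or antisense (opposite strand, also within ``antisense_flank`` nt
    of the gene boundaries).  A TSS can carry several classes with respect to
    different genes; TSSs matching nothing are orphan.
    """
    sites = [replace(s, classes=set()) for s in sites]
    gene_feats = [g for g in genes if g.feature_type in ("gene", "CDS")]
    for g in gene_feats:
        same = [
            s for s in sites
            if s.replicon_id == g.replicon_id and s.strand == g.strand
        ]
        anti = [
            s for s in sites
            if s.replicon_id == g.replicon_id and s.strand != g.strand
        ]
        if g.strand == "+":
            window = [s for s in same if g.start - utr_window <= s.position < g.start]
            dist = lambda s: g.start - s.position
        else:
            window = [s for s in same if g.end < s.position <= g.end + utr_window]
            dist = lambda s: s.position - g.end
        if window:
            best = min(window, key=lambda s: (-s.step_height, dist(s)))
            best.classes.add("primary")
            for s in window:
                if s is not best:
                    s.classes.add("secondary")
        for s in same:
            if g.start <= s.position <= g.end:
                s.classes.add("internal")
        for s in anti:
            if g.start - antisense_flank <= s.position <= g.end + antisense_flank:
                s.classes.add("antisense")
    for s in sites:
        if not s.classes:
            s.classes.add("orphan")
    return sites


# ---------------------------------------------------------------------------
# evaluation against a curated set

def _match_counts(
    call_positions: dict[tuple[str, str], np.ndarray],
    curated: CuratedSet,
    match_tolerance: int,
) -> tuple[int, int]:
    """Greedy nearest-first matching of calls to curated positions.

    Each call matches at most one curated position and vice versa.  Only
    calls inside the curated region participate.  Returns (TP, FP).
    """
    curated_by_key: dict[tuple[str, str], list[int]] = {}
    for rep, strand, pos in curated.positions:
        curated_by_key.setdefault((rep, strand), []).append(pos)

    tp = 0
    fp = 0
    keys = set(call_positions) | set(curated_by_key)
    for key in keys:
        calls = call_positions.get(key, np.array([], dtype=int))
        calls = calls[(calls >= curated.region_start) & (calls <= curated.region_end)]
        cur = np.sort(np.array(curated_by_key.get(key, []), dtype=int))
        if calls.size == 0:
            continue
        if cur.size == 0:
            fp += int(calls.size)
            continue
        # candidate pairs within tolerance
        pairs: list[tuple[int, int, int]] = []  # (distance, call_idx, curated_idx)
        left = np.searchsorted(cur, calls - match_tolerance, side="left")
        right = np.searchsorted(cur, calls + match_tolerance, side="right")
        for ci, (l, r) in enumerate(zip(left, right)):
            for mi in range(l, r):
                pairs.append((abs(int(calls[ci]) - int(cur[mi])), ci, mi))
        pairs.sort()
        used_calls: set[int] = set()
        used_cur: set[int] = set()
        for _, ci, mi in pairs:
            if ci in used_calls or mi in used_cur:
                continue
            used_calls.add(ci)
            used_cur.add(mi)
        tp += len(used_cur)
        fp += int(calls.size) - len(used_calls)
    return tp, fp


def evaluate(
    sites: list[SiteCall], curated: CuratedSet, match_tolerance: int = 2
) -> EvalStats:
    """TP/FP/TPR/FPR of a call set against a curated set.

    FPR uses the negative-position count N = region length - TP_m; the
    specificity reported elsewhere is 1 - FPR.
    """
    if not curated.positions:
        raise ValueError("empty curated set")
    by_key: dict[tuple[str, str], list[int]] = {}
    for s in sites:
        by_key.setdefault((s.replicon_id, s.strand), []).append(s.position)
    call_positions = {k: np.sort(np.array(v, dtype=int)) for k, v in by_key.items()}
    return evaluate_positions(call_positions, curated, match_tolerance)


def evaluate_positions(
    call_positions: dict[tuple[str, str], np.ndarray],
    curated: CuratedSet,
    match_tolerance: int = 2,
) -> EvalStats:
    """Array-based evaluation used directly by the optimizer's hot loop."""
    if not curated.positions:
        raise ValueError("empty curated set")
    tp, fp = _match_counts(call_positions, curated, match_tolerance)
    tp_m = len(curated.positions)
    negatives = max(curated.region_length - tp_m, 1)
    return EvalStats(TP=tp, FP=fp, TPR=tp / tp_m, FPR=fp / negatives, TP_m=tp_m)
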