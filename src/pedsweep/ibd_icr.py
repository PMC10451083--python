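"""Parent-of-origin IBD tracing and IBD-conserved-region (ICR) calling.

Because both parents are known, fully inbred lines, parent of origin is
traced by direct allele matching at informative markers, smoothed against
genotyping error, scored with a log10 likelihood-ratio (IBD-with-parent vs
random draw from panel allele frequencies), and gaps between segments are
attributed by the minimum-recombination principle. ICRs are maximal runs
of genome bins in which at least a fraction ``tau`` of lines carry the same
parental origin.

Coordinates are 0-based half-open internally; BED output keeps that
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pedsweep.core import GenotypeMatrix

P1, P2 = 1, 2
UNASSIGNED = 0
CONFLICT = -2


@dataclass
class IBDParams:
    min_lod: float = 3.0
    trim_lod: float = 2.5
    error_rate: float = 1e-4
    min_markers: int = 5
    tau: float = 0.9
    icr_window_bp: int = 100_000
    # null model for segment LOD scoring: "balanced" scores against the
    # biparental-inheritance null (either parent with probability 0.5);
    # "panel" scores against observed panel allele frequencies, which zeroes
    # the evidence wherever selection fixed one parent's allele
    null_freq: str = "balanced"

    def __post_init__(self) -> None:
        if self.null_freq not in ("balanced", "panel"):
            raise ValueError("null_freq must be 'balanced' or 'panel'")
        if not (self.min_lod >= self.trim_lod >= 0):
            raise ValueError("require min_lod >= trim_lod >= 0")
        if not (0 < self.tau <= 1):
            raise ValueError("tau must be in (0, 1]")


@dataclass
class IBDSegment:
    line: str
    chrom: str
    start_bp: int  # 0-based half-open
    end_bp: int
    parent: int  # P1 or P2
    n_informative_markers: int
    lod: float

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("segment end must exceed start")


@dataclass
class ICR:
    chrom: str
    start_bp: int
    end_bp: int
    parent: int
    retention: float


@dataclass
class Tiling:
    """Complete parent-of-origin tiling of one line's chromosome."""

    line: str
    chrom: str
    intervals: list[tuple[int, int, int]]  # (start, end, parent); tiles [0, chrom_len)
    assigned: bool = True


def informative_markers(parent1: np.ndarray, parent2: np.ndarray) -> np.ndarray:
    """Indices where the parents carry different, non-missing alleles."""
    return np.flatnonzero((parent1 != parent2) & (parent1 >= 0) & (parent2 >= 0))


def trace_origin(
    line_calls: np.ndarray,
    parent1: np.ndarray,
    parent2: np.ndarray,
    params: IBDParams,
    informative: np.ndarray | None = None,
) -> np.ndarray:
    """Label each informative, non-missing marker with its matching parent.

    Returns a full-length vector: P1/P2 at informative non-missing markers,
    CONFLICT where the call matches neither parent, UNASSIGNED elsewhere.
    Discordant runs shorter than ``min_markers`` flanked by a common label on
    both sides are flipped to that label (error smoothing).
    """
    if informative is None:
        informative = informative_markers(parent1, parent2)
    out = np.full(len(line_calls), UNASSIGNED, dtype=np.int8)
    g = line_calls[informative]
    lab = np.full(len(informative), CONFLICT, dtype=np.int8)
    lab[g == parent1[informative]] = P1
    lab[g == parent2[informative]] = P2
    lab[g < 0] = UNASSIGNED

    # smoothing on the informative-marker track
    called = np.flatnonzero((lab == P1) | (lab == P2))
    if len(called) >= 3:
        sub = lab[called]
        runs = _runs(sub)
        for ri, (s, e, val) in enumerate(runs):
            if e - s >= params.min_markers:
                continue
            left = runs[ri - 1][2] if ri > 0 else None
            right = runs[ri + 1][2] if ri < len(runs) - 1 else None
            if left is not None and left == right and left != val:
                sub[s:e] = left
        lab[called] = sub
    out[informative] = lab
    return out


def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of a 1-D array as (start, end, value)."""
    if len(values) == 0:
        return []
    change = np.flatnonzero(np.diff(values) != 0) + 1
    bounds = np.concatenate([[0], change, [len(values)]])
    return [(int(bounds[i]), int(bounds[i + 1]), int(values[bounds[i]])) for i in range(len(bounds) - 1)]


def _marker_lods(calls: np.ndarray, alt_freq: np.ndarray, eps: float) -> np.ndarray:
    """Per-marker log10[(1 - eps) / panel frequency of the carried allele].

    Markers with panel frequency 0 or 1 (or missing) contribute 0.
    """
    f_carried = np.where(calls == 1, alt_freq, 1.0 - alt_freq)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = np.log10((1.0 - eps) / f_carried)
    bad = (calls < 0) | ~np.isfinite(lod) | (f_carried <= 0) | (f_carried >= 1)
    return np.where(bad, 0.0, lod)


def score_and_call_segments(
    line: str,
    chrom: str,
    assignments: np.ndarray,
    line_calls: np.ndarray,
    alt_freq: np.ndarray,
    pos_bp: np.ndarray,
    params: IBDParams,
) -> list[IBDSegment]:
    """Score maximal same-parent runs; drop lod < min_lod; trim weak ends.

    ``assignments``/``line_calls``/``alt_freq``/``pos_bp`` are chromosome-local
    arrays over all markers of the chromosome.
    """
    contrib = _marker_lods(line_calls, alt_freq, params.error_rate)
    called = np.flatnonzero((assignments == P1) | (assignments == P2))
    if len(called) == 0:
        return []
    segments: list[IBDSegment] = []
    for s, e, parent in _runs(assignments[called]):
        idx = called[s:e]
        lods = contrib[idx]
        total = float(lods.sum())
        if total < params.min_lod:
            continue
        # end rimming: drop each end's maximal sub-run whose cumulative
        # contribution stays below trim_lod
        lo, cum = 0, 0.0
        while lo < len(idx) and cum + lods[lo] < params.trim_lod:
            cum += lods[lo]
            lo += 1
        hi, cum = len(idx), 0.0
        while hi > lo and cum + lods[hi - 1] < params.trim_lod:
            cum += lods[hi - 1]
            hi -= 1
        if hi - lo < max(params.min_markers, 1):
            continue
        kept = idx[lo:hi]
        seg_lod = float(contrib[kept].sum())
        if seg_lod < params.min_lod:
            continue
        segments.append(
            IBDSegment(
                line=line,
                chrom=chrom,
                start_bp=int(pos_bp[kept[0]] - 1),
                end_bp=int(pos_bp[kept[-1]]),
                parent=parent,
                n_informative_markers=int(hi - lo),
                lod=seg_lod,
            )
        )
    return segments


def attribute_gaps(segments: list[IBDSegment], chrom_len: int, line: str = "", chrom: str = "") -> Tiling:
    """Tile the chromosome by assigning every gap with minimum recombination.

    Same-parent flanks absorb the gap (0 extra recombinations); different
    parents place one breakpoint at the gap midpoint; terminal gaps take the
    nearest segment's parent. A chromosome with no segments is returned as a
    single unassigned interval with ``assigned=False``.
    """
    if not segments:
        return Tiling(line=line, chrom=chrom, intervals=[(0, chrom_len, UNASSIGNED)], assigned=False)
    segs = sorted(segments, key=lambda s: s.start_bp)
    line = line or segs[0].line
    chrom = chrom or segs[0].chrom
    intervals: list[tuple[int, int, int]] = []
    cursor = 0
    prev_parent: int | None = None
    for seg in segs:
        if seg.start_bp > cursor:
            if prev_parent is None:
                intervals.append((cursor, seg.start_bp, seg.parent))
            elif prev_parent == seg.parent:
                intervals.append((cursor, seg.start_bp, seg.parent))
            else:
                mid = (cursor + seg.start_bp) // 2
                intervals.append((cursor, mid, prev_parent))
                intervals.append((mid, seg.start_bp, seg.parent))
        intervals.append((seg.start_bp, seg.end_bp, seg.parent))
        cursor = seg.end_bp
        prev_parent = seg.parent
    if cursor < chrom_len:
        intervals.append((cursor, chrom_len, prev_parent))
    # merge adjacent same-parent tiles
    merged: list[tuple[int, int, int]] = []
    for iv in intervals:
        if merged and merged[-1][2] == iv[2] and merged[-1][1] == iv[0]:
            merged[-1] = (merged[-1][0], iv[1], iv[2])
        else:
            merged.append(iv)
    return Tiling(line=line, chrom=chrom, intervals=merged, assigned=True)


def recombination_count(tiling: Tiling) -> int:
    return sum(
        1
        for a, b in zip(tiling.intervals, tiling.intervals[1:])
        if a[2] != b[2] and a[2] != UNASSIGNED and b[2] != UNASSIGNED
    )


def _bin_parent(tiling: Tiling, start: int, end: int) -> int:
    """Majority-bp parent of a bin under a tiling (UNASSIGNED if none or tied)."""
    totals = {P1: 0, P2: 0}
    for s, e, p in tiling.intervals:
        if p not in (P1, P2):
            continue
        ov = min(e, end) - max(s, start)
        if ov > 0:
            totals[p] += ov
    if totals[P1] == totals[P2]:
        return UNASSIGNED
    return P1 if totals[P1] > totals[P2] else P2


def call_icrs(
    tilings: dict[str, Tiling],
    chrom: str,
    chrom_len: int,
    params: IBDParams,
) -> tuple[list[ICR], pd.DataFrame]:
    """Call ICRs for one chromosome from per-line tilings.

    Returns the ICR list (both parents) and the per-bin retention table.
    Bin retention for parent p = fraction of assigned lines whose majority
    origin in the bin is p; maximal runs of bins with retention >= tau merge
    into one ICR.
    """
    if len(tilings) < 2:
        raise ValueError("ICR calling needs at least two lines")
    win = params.icr_window_bp
    edges = list(range(0, chrom_len, win)) + [chrom_len]
    n_bins = len(edges) - 1
    counts = np.zeros((n_bins, 3))  # columns: unassigned, P1, P2
    for tl in tilings.values():
        if not tl.assigned:
            continue
        for b in range(n_bins):
            p = _bin_parent(tl, edges[b], edges[b + 1])
            counts[b, p if p in (P1, P2) else 0] += 1
    assigned = counts[:, 1] + counts[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        ret1 = np.where(assigned > 0, counts[:, 1] / np.maximum(assigned, 1), 0.0)
        ret2 = np.where(assigned > 0, counts[:, 2] / np.maximum(assigned, 1), 0.0)
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": edges[:-1],
            "end": edges[1:],
            "n_assigned": assigned.astype(int),
            "retention_p1": ret1,
            "retention_p2": ret2,
        }
    )
    icrs: list[ICR] = []
    for parent, ret in ((P1, ret1), (P2, ret2)):
        hit = (ret >= params.tau) & (assigned > 0)
        for s, e, val in _runs(hit.astype(np.int8)):
            if val != 1:
                continue
            icrs.append(
                ICR(
                    chrom=chrom,
                    start_bp=edges[s],
                    end_bp=edges[e],
                    parent=parent,
                    retention=float(ret[s:e].mean()),
                )
            )
    if not icrs and params.tau > (ret1.max(initial=0) if n_bins else 0) and params.tau > (ret2.max(initial=0) if n_bins else 0):
        warnings.warn(f"no bins reach tau={params.tau} on {chrom}; empty ICR list", stacklevel=2)
    return icrs, bins


def parental_fractions(tilings: dict[str, dict[str, Tiling]], chrom_lens: dict[str, int]) -> pd.DataFrame:
    """Per-line genome fraction assigned to each parent."""
    rows = []
    total = sum(chrom_lens.values())
    for line, per_chrom in tilings.items():
        bp = {P1: 0, P2: 0, UNASSIGNED: 0}
        for chrom, tl in per_chrom.items():
            for s, e, p in tl.intervals:
                bp[p if p in (P1, P2) else UNASSIGNED] += e - s
        rows.append(
            {
                "line": line,
                "frac_p1": bp[P1] / total,
                "frac_p2": bp[P2] / total,
                "frac_unassigned": bp[UNASSIGNED] / total,
            }
        )
    return pd.DataFrame(rows)


def _overlap_bp(tiling: Tiling, regions: list[tuple[int, int]], parent: int) -> int:
    total = 0
    for rs, re_ in regions:
        for s, e, p in tiling.intervals:
            if p != parent:
                continue
            ov = min(e, re_) - max(s, rs)
            if ov > 0:
                total += ov
    return total


def retention_ratio(
    per_chrom_tilings: dict[str, Tiling],
    icrs: list[ICR],
    over_icrs_only: bool = True,
) -> float | None:
    """Per-line ratio of P1-assigned bp (within P1 ICRs) to P2-assigned bp
    (within P2 ICRs); ``None`` when the denominator is zero.

    With ``over_icrs_only=False`` the ratio is over all assigned bp instead.
    """
    if over_icrs_only:
        p1_regions = {c: [(i.start_bp, i.end_bp) for i in icrs if i.parent == P1 and i.chrom == c] for c in per_chrom_tilings}
        p2_regions = {c: [(i.start_bp, i.end_bp) for i in icrs if i.parent == P2 and i.chrom == c] for c in per_chrom_tilings}
        num = sum(_overlap_bp(tl, p1_regions[c], P1) for c, tl in per_chrom_tilings.items())
        den = sum(_overlap_bp(tl, p2_regions[c], P2) for c, tl in per_chrom_tilings.items())
    else:
        num = sum(e - s for tl in per_chrom_tilings.values() for s, e, p in tl.intervals if p == P1)
        den = sum(e - s for tl in per_chrom_tilings.values() for s, e, p in tl.intervals if p == P2)
    if den == 0:
        return None
    return num / den


def run_panel(
    gm: GenotypeMatrix,
    parent1_id: str,
    parent2_id: str,
    params: IBDParams | None = None,
    chrom_lens: dict[str, int] | None = None,
):
    """End-to-end IBD/ICR analysis of a panel VCF matrix.

    The two parents are excluded from descendant tracing and from the panel
    allele frequencies used in LOD scoring. Returns a dict with segments,
    tilings, ICRs, bin retention tables, parental fractions and per-line
    retention ratios (both the ICR-restricted and all-IBD variants).
    """
    params = params or IBDParams()
    p1 = gm.calls[:, gm.sample_index(parent1_id)]
    p2 = gm.calls[:, gm.sample_index(parent2_id)]
    lines = [s for s in gm.samples if s not in (parent1_id, parent2_id)]
    panel = gm.subset_samples(lines)
    freqs = (
        panel.alt_freq()
        if params.null_freq == "panel"
        else np.full(gm.n_markers, 0.5)
    )
    if chrom_lens is None:
        chrom_lens = {c: int(gm.pos_bp[gm.chrom_mask(c)].max()) for c in gm.chromosomes}
    informative = informative_markers(p1, p2)

    segments: list[IBDSegment] = []
    tilings: dict[str, dict[str, Tiling]] = {ln: {} for ln in lines}
    assignments: dict[str, np.ndarray] = {}
    for ln in lines:
        calls = panel.calls[:, panel.sample_index(ln)]
        assign = trace_origin(calls, p1, p2, params, informative)
        assignments[ln] = assign
        for chrom in gm.chromosomes:
            idx = gm.chrom_index(chrom)
            segs = score_and_call_segments(
                ln, chrom, assign[idx], calls[idx], freqs[idx], gm.pos_bp[idx], params
            )
            segments.extend(segs)
            tilings[ln][chrom] = attribute_gaps(segs, chrom_lens[chrom], line=ln, chrom=chrom)

    icrs: list[ICR] = []
    bin_tables = []
    for chrom in gm.chromosomes:
        per_line = {ln: tilings[ln][chrom] for ln in lines}
        ic, bins = call_icrs(per_line, chrom, chrom_lens[chrom], params)
        icrs.extend(ic)
        bin_tables.append(bins)

    ratios = pd.DataFrame(
        {
            "line": lines,
            "ratio_icr": [retention_ratio(tilings[ln], icrs, True) for ln in lines],
            "ratio_all": [retention_ratio(tilings[ln], icrs, False) for ln in lines],
        }
    )
    return {
        "segments": segments,
        "assignments": assignments,
        "tilings": tilings,
        "icrs": icrs,
        "bins": pd.concat(bin_tables, ignore_index=True),
        "fractions": parental_fractions(tilings, chrom_lens),
        "ratios": ratios,
        "chrom_lens": chrom_lens,
    }


def segments_to_bed(segments: list[IBDSegment]) -> list[tuple]:
    return [
        (s.chrom, s.start_bp, s.end_bp, f"{s.line}:P{s.parent}", min(int(round(s.lod * 100)), 1000))
        for s in segments
    ]


def icrs_to_bed(icrs: list[ICR]) -> list[tuple]:
    return [(i.chrom, i.start_bp, i.end_bp, f"P{i.parent}", f"{i.retention:.4f}") for i in icrs]
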