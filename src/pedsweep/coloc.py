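"""Interval algebra over genome coordinates (0-based half-open) and the
co-localization reports connecting ICRs, sweep regions, QTLs and genes."""

from __future__ import annotations

import numpy as np
import pandas as pd


class IntervalSet:
    """Chromosome-keyed sets of half-open intervals, normalized on build.

    Normalization sorts, rejects empty intervals, and merges overlapping or
    abutting members, so total length is well-defined.
    """

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None):
        self._data: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                self._data[chrom] = self._normalize(ivs)

    @staticmethod
    def _normalize(ivs) -> np.ndarray:
        arr = np.asarray(sorted((int(s), int(e)) for s, e in ivs), dtype=np.int64).reshape(-1, 2)
        for s, e in arr:
            if s >= e:
                raise ValueError(f"invalid interval [{s}, {e}): start must precede end")
        merged = []
        for s, e in arr:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return np.asarray(merged, dtype=np.int64).reshape(-1, 2)

    @classmethod
    def from_tuples(cls, rows) -> "IntervalSet":
        """Build from an iterable of (chrom, start, end)."""
        d: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in rows:
            d.setdefault(str(chrom), []).append((int(s), int(e)))
        return cls(d)

    @classmethod
    def from_bed_frame(cls, df: pd.DataFrame) -> "IntervalSet":
        return cls.from_tuples(zip(df["chrom"], df["start"], df["end"]))

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def tuples(self):
        for chrom in self.chromosomes:
            for s, e in self._data[chrom]:
                yield (chrom, int(s), int(e))

    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values()))

    def union(self, other: "IntervalSet") -> "IntervalSet":
        d: dict[str, list[tuple[int, int]]] = {}
        for src in (self, other):
            for chrom, s, e in src.tuples():
                d.setdefault(chrom, []).append((s, e))
        return IntervalSet(d)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        d: dict[str, list[tuple[int, int]]] = {}
        for chrom in set(self._data) & set(other._data):
            a, b = self._data[chrom], other._data[chrom]
            out, i, j = [], 0, 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    out.append((int(s), int(e)))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if out:
                d[chrom] = out
        return IntervalSet(d)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.overlap_length(chrom, start, end) > 0

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        ivs = self.intervals(chrom)
        if len(ivs) == 0:
            return 0
        lo = np.minimum(np.maximum(ivs[:, 0], start), end)
        hi = np.minimum(np.maximum(ivs[:, 1], start), end)
        return int((hi - lo).sum())

    def distance(self, chrom: str, start: int, end: int) -> float:
        """bp distance from [start, end) to the nearest interval (0 if overlapping)."""
        ivs = self.intervals(chrom)
        if len(ivs) == 0:
            return float("inf")
        gaps = np.maximum(ivs[:, 0] - end, 0) + np.maximum(start - ivs[:, 1], 0)
        gaps[(ivs[:, 0] < end) & (ivs[:, 1] > start)] = 0
        return float(gaps.min())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self.tuples()) == list(other.tuples())


def union_all(sets: list[IntervalSet]) -> IntervalSet:
    out = IntervalSet()
    for s in sets:
        out = out.union(s)
    return out


# ---------------------------------------------------------------------------
# reports


def icr_ssw_coloc(
    icrs: pd.DataFrame,
    ssw_sets: dict[str, IntervalSet],
) -> dict:
    """ICR vs sweep-region co-localization, against the union of all
    statistics' region sets and per statistic.

    ``icrs`` needs columns chrom, start, end, parent. Reports both the
    fraction of ICRs (by count) touching regions and the fraction of ICR
    length covered, overall and per parent.
    """
    target = union_all(list(ssw_sets.values()))

    def _measure(sub: pd.DataFrame, regions: IntervalSet) -> dict:
        n = len(sub)
        if n == 0:
            return {
                "n_icr": 0,
                "pct_count_overlap": float("nan"),
                "pct_length_overlap": float("nan"),
                "total_bp": 0,
            }
        hits = 0
        ov_bp = 0
        tot_bp = 0
        for _, row in sub.iterrows():
            length = int(row["end"]) - int(row["start"])
            tot_bp += length
            ov = regions.overlap_length(str(row["chrom"]), int(row["start"]), int(row["end"]))
            ov_bp += ov
            if ov > 0:
                hits += 1
        return {
            "n_icr": n,
            "pct_count_overlap": 100.0 * hits / n,
            "pct_length_overlap": 100.0 * ov_bp / tot_bp if tot_bp else float("nan"),
            "total_bp": tot_bp,
        }

    report = {"union": {"all": _measure(icrs, target)}}
    for parent, sub in icrs.groupby("parent"):
        report["union"][str(parent)] = _measure(sub, target)
    for stat, regions in ssw_sets.items():
        report[stat] = {"all": _measure(icrs, regions)}
    return report


def qtl_near(
    qtl_intervals: list[tuple[str, int, int]],
    regions: IntervalSet,
    near_dist: int = 1_000_000,
) -> tuple[float, list[bool]]:
    """Fraction of QTL intervals overlapping or within near_dist of regions."""
    flags = [
        regions.distance(chrom, start, end) <= near_dist
        for chrom, start, end in qtl_intervals
    ]
    frac = float(np.mean(flags)) if flags else float("nan")
    return frac, flags


def qtl_near_sensitivity(
    qtl_intervals: list[tuple[str, int, int]],
    regions: IntervalSet,
    dists=(0, 500_000, 1_000_000, 2_000_000),
) -> dict[int, float]:
    return {int(d): qtl_near(qtl_intervals, regions, d)[0] for d in dists}


def genes_in_regions(genes: pd.DataFrame, regions: IntervalSet) -> pd.DataFrame:
    """Genes with >= 1 bp overlap with the region set (half-open coordinates)."""
    keep = [
        regions.overlap_length(str(r.chrom), int(r.start), int(r.end)) > 0
        for r in genes.itertuples()
    ]
    return genes[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def cm_to_bp(map_frame: pd.DataFrame, chrom: str, pos_cm: float) -> float:
    """Piecewise-linear cM -> bp interpolation (clamped to the map span)."""
    sub = map_frame[map_frame["chrom"] == chrom].sort_values("pos_cM")
    if sub.empty:
        raise ValueError(f"empty map for chromosome {chrom!r}")
    return float(np.interp(pos_cm, sub["pos_cM"], sub["pos_bp"]))


def bp_to_cm(map_frame: pd.DataFrame, chrom: str, pos_bp: float) -> float:
    sub = map_frame[map_frame["chrom"] == chrom].sort_values("pos_bp")
    if sub.empty:
        raise ValueError(f"empty map for chromosome {chrom!r}")
    return float(np.interp(pos_bp, sub["pos_bp"], sub["pos_cM"]))
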