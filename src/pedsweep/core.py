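"""Core data containers shared across modules.

Genotypes are stored marker-major for fully inbred material: each line
contributes one effective haplotype, so a call is the homozygous allele
(0 = reference, 1 = alternate) or -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

MAP_COLUMNS = ["chrom", "pos_bp", "pos_cM", "marker_id"]


@dataclass
class GenotypeMatrix:
    """Biallelic homozygous calls for a panel of inbred lines.

    Attributes
    ----------
    samples
        Line identifiers, one per column of ``calls``.
    chrom, pos_bp, pos_cM, marker_id
        Per-marker coordinates; ``pos_bp`` is 1-based physical position,
        ``pos_cM`` the genetic position.
    calls
        ``(n_markers, n_samples)`` int8 array with values 0 (homozygous
        reference), 1 (homozygous alternate) or -1 (missing).
    """

    samples: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cM: np.ndarray
    marker_id: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cM = np.asarray(self.pos_cM, dtype=float)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.pos_bp), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.pos_bp)} markers x {len(self.samples)} samples"
            )

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome ids in order of first appearance."""
        return list(pd.unique(pd.Series(self.chrom)))

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom == chrom

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in genotype matrix") from None

    def subset_samples(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(n) for n in names]
        return GenotypeMatrix(
            samples=list(names),
            chrom=self.chrom,
            pos_bp=self.pos_bp,
            pos_cM=self.pos_cM,
            marker_id=list(self.marker_id),
            calls=self.calls[:, idx],
        )

    def map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "pos_cM": self.pos_cM,
                "marker_id": self.marker_id,
            }
        )

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker over non-missing lines (NaN if all missing)."""
        ok = self.calls >= 0
        n = ok.sum(axis=1)
        alt = np.where(ok, self.calls, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)


@dataclass
class GeneticMap:
    """Marker map with piecewise-linear cM <-> bp interpolation per chromosome."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in MAP_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"map is missing columns: {missing}")
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            bp = grp["pos_bp"].to_numpy()
            cm = grp["pos_cM"].to_numpy()
            order = np.argsort(bp, kind="stable")
            if np.any(np.diff(cm[order]) < 0):
                raise ValueError(f"non-monotone genetic map on chromosome {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.frame["chrom"]))

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        sub = self.frame[self.frame["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return sub.sort_values("pos_bp")

    def cm_to_bp(self, chrom: str, pos_cm: float) -> float:
        tab = self.chrom_table(chrom)
        return float(np.interp(pos_cm, tab["pos_cM"], tab["pos_bp"]))

    def bp_to_cm(self, chrom: str, pos_bp: float) -> float:
        tab = self.chrom_table(chrom)
        return float(np.interp(pos_bp, tab["pos_bp"], tab["pos_cM"]))
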