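"""Two-parent breeding simulator with known ground truth.

Generates (a) a small panel of descendant inbred lines produced by repeated
DH-line extraction plus truncation selection at chosen loci, and (b) a DH
mapping population with additive-QTL phenotypes measured in several
environments. All randomness flows through a single seed; reference alleles
in the emitted VCF are parent 1's alleles.

Crossovers are simulated as a Poisson process on the cM scale (no
interference); the mapping side of the pipeline deliberately uses the
Kosambi convention instead — map functions are analysis conventions, not
generative truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pedsweep.core import GeneticMap, GenotypeMatrix
from pedsweep import io as psio

P1, P2 = 1, 2  # parent-of-origin codes


@dataclass
class SelectedLocus:
    """A locus under truncation selection: lines carrying ``favored`` parent's
    allele at the nearest marker gain ``weight`` in the selection score."""

    chrom: str
    pos_bp: int
    weight: float = 1.0
    favored: int = P1


@dataclass
class QTLSpec:
    trait: str
    chrom: str
    pos_cM: float
    a: float  # additive effect of carrying parent-1's allele (+1 coding)


@dataclass
class SimConfig:
    n_chrom: int = 2
    markers_per_chrom: int = 500
    chrom_len_bp: int = 10_000_000
    chrom_len_cM: float = 100.0
    delta: float = 0.5  # fraction of markers at which the parents differ
    n_descendants: int = 15
    n_candidates_per_cycle: int = 60
    n_cycles: int = 3
    selected_loci: list[SelectedLocus] = field(default_factory=list)
    dh_n: int = 240
    qtls: list[QTLSpec] = field(default_factory=list)
    h2: dict[str, float] = field(default_factory=dict)
    n_env: int = 3
    n_rep: int = 2
    env_sd: float = 0.5
    genotype_error: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.delta <= 1):
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")
        for trait, h2 in self.h2.items():
            if not (0 < h2 <= 1):
                raise ValueError(f"h2 for {trait!r} must be in (0, 1], got {h2}")
        if self.dh_n <= 0:
            raise ValueError("dh_n must be positive")
        if round(self.delta * self.markers_per_chrom) < 1:
            raise ValueError("delta * markers_per_chrom < 1: no informative markers")
        for loc in self.selected_loci:
            if not (1 <= loc.pos_bp <= self.chrom_len_bp):
                raise ValueError(f"selected locus {loc} outside chromosome bounds")
        for q in self.qtls:
            if not (0 <= q.pos_cM <= self.chrom_len_cM):
                raise ValueError(f"QTL {q} outside chromosome bounds")
        if self.n_cycles > 0 and not self.selected_loci:
            raise ValueError("selected_loci must be non-empty when n_cycles > 0")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["selected_loci"] = [
            SelectedLocus(**x) if isinstance(x, dict) else x
            for x in d.get("selected_loci", [])
        ]
        d["qtls"] = [QTLSpec(**x) if isinstance(x, dict) else x for x in d.get("qtls", [])]
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of a simulated panel.

    ``origin`` holds, per line and marker, which founder (1 or 2) contributed
    the allele; ``crossovers`` are the cM positions of the origin breakpoints
    of each line (for single-meiosis DH lines these are the true crossover
    points of that meiosis; for multi-cycle lines they are the effective
    breakpoints of the accumulated mosaic).
    """

    samples: list[str]
    chrom: np.ndarray
    pos_cM: np.ndarray
    origin: np.ndarray  # (n_lines, n_markers) int8 in {1, 2}
    crossovers: list[dict[str, list[float]]]
    selected_loci: list[SelectedLocus] = field(default_factory=list)
    qtls: list[QTLSpec] = field(default_factory=list)
    h2_realized: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "samples": self.samples,
            "chrom": [str(c) for c in self.chrom],
            "pos_cM": [float(x) for x in self.pos_cM],
            "origin": self.origin.tolist(),
            "crossovers": self.crossovers,
            "selected_loci": [vars(s) for s in self.selected_loci],
            "qtls": [vars(q) for q in self.qtls],
            "h2_realized": self.h2_realized,
        }


def _derive_crossovers(origin_row: np.ndarray, chrom: np.ndarray, pos_cm: np.ndarray) -> dict[str, list[float]]:
    """Breakpoints (midpoints between flanking markers, in cM) of an origin path."""
    out: dict[str, list[float]] = {}
    for c in pd.unique(pd.Series(chrom)):
        idx = np.flatnonzero(chrom == c)
        o, cm = origin_row[idx], pos_cm[idx]
        switch = np.flatnonzero(np.diff(o) != 0)
        out[str(c)] = [float((cm[s] + cm[s + 1]) / 2) for s in switch]
    return out


def make_founders(config: SimConfig, rng: np.random.Generator | None = None):
    """Build the two parental haplotypes and the marker map.

    Returns ``(parents, genetic_map)`` where ``parents`` is a (2, M) int8
    array of alleles (0 = parent-1 allele = VCF REF). Exactly
    round(delta * markers_per_chrom) markers per chromosome are informative.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.markers_per_chrom
    rows = []
    parent2_chunks = []
    for chrom in config.chrom_names():
        pos = np.sort(rng.choice(np.arange(1, config.chrom_len_bp + 1), size=m, replace=False))
        pos_cm = (pos - 1) / max(config.chrom_len_bp - 1, 1) * config.chrom_len_cM
        n_inf = int(round(config.delta * m))
        inf_idx = rng.choice(m, size=n_inf, replace=False)
        hap2 = np.zeros(m, dtype=np.int8)
        hap2[inf_idx] = 1
        parent2_chunks.append(hap2)
        for j in range(m):
            rows.append((chrom, int(pos[j]), float(pos_cm[j]), f"{chrom}_m{j + 1}"))
    frame = pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cM", "marker_id"])
    parents = np.vstack(
        [np.zeros(config.n_chrom * m, dtype=np.int8), np.concatenate(parent2_chunks)]
    )
    return parents, GeneticMap(frame)


def simulate_gamete(gmap: GeneticMap, rng: np.random.Generator):
    """One meiosis of a two-line cross.

    Returns ``(choose, crossovers)``: ``choose`` selects line A (0) or B (1)
    per marker; ``crossovers`` maps chromosome to the sampled cM positions.
    Crossover counts are Poisson(len_cM / 100), positions uniform on the map.
    """
    choose_chunks = []
    crossovers: dict[str, list[float]] = {}
    for chrom in gmap.chromosomes:
        tab = gmap.chrom_table(chrom)
        cm = tab["pos_cM"].to_numpy()
        length = float(cm[-1] - cm[0]) if len(cm) > 1 else 0.0
        n_x = rng.poisson(length / 100.0) if length > 0 else 0
        xpos = np.sort(rng.uniform(cm[0], cm[-1], size=n_x)) if n_x else np.empty(0)
        start = int(rng.integers(2))
        # parity of crossovers to the left of each marker decides the source line
        n_left = np.searchsorted(xpos, cm, side="left")
        choose_chunks.append(((start + n_left) % 2).astype(np.int8))
        crossovers[str(chrom)] = [float(x) for x in xpos]
    return np.concatenate(choose_chunks), crossovers


def _dh_from_cross(hap_a, origin_a, hap_b, origin_b, gmap, rng):
    choose, xov = simulate_gamete(gmap, rng)
    hap = np.where(choose == 0, hap_a, hap_b).astype(np.int8)
    origin = np.where(choose == 0, origin_a, origin_b).astype(np.int8)
    return hap, origin, xov


def _apply_noise(calls: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    calls = calls.copy()
    if config.genotype_error > 0:
        flip = rng.random(calls.shape) < config.genotype_error
        calls = np.where(flip, 1 - calls, calls).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls = np.where(miss, np.int8(-1), calls).astype(np.int8)
    return calls


def simulate_descendants(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    founders=None,
):
    """Breed ``n_descendants`` inbred lines by cycles of DH extraction and
    truncation selection at ``config.selected_loci``.

    Each cycle draws ``n_candidates_per_cycle`` doubled gametes from crosses
    among the current pool (cycle 1: the F1 of the two founders) and keeps the
    top ``n_descendants`` by weighted favored-allele score. ``n_cycles == 0``
    yields plain F1-derived DH lines.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parents, gmap = founders if founders is not None else make_founders(config, rng)
    frame = gmap.frame
    m_total = len(frame)
    origin_p = [np.full(m_total, P1, dtype=np.int8), np.full(m_total, P2, dtype=np.int8)]

    if config.n_cycles > 0 and config.selected_loci and all(
        loc.weight == 0 for loc in config.selected_loci
    ):
        warnings.warn("all selection weights are zero: selection is neutral", stacklevel=2)

    # anchor each selected locus to the nearest *informative* marker: at a
    # marker where the parents agree every candidate matches and selection
    # would silently become neutral
    informative = parents[0] != parents[1]
    sel_idx = []
    for loc in config.selected_loci:
        sub = frame[(frame["chrom"] == loc.chrom) & informative]
        if sub.empty:
            raise ValueError(f"no informative marker on {loc.chrom} for selected locus {loc}")
        sel_idx.append((int((sub["pos_bp"] - loc.pos_bp).abs().idxmin()), loc))

    def score(hap: np.ndarray) -> float:
        s = 0.0
        for idx, loc in sel_idx:
            favored_allele = parents[loc.favored - 1, idx]
            if hap[idx] == favored_allele:
                s += loc.weight
        return s

    pool = [
        (parents[0], origin_p[0]),
        (parents[1], origin_p[1]),
    ]
    final: list[tuple[np.ndarray, np.ndarray, dict]] = []
    if config.n_cycles == 0:
        final = [
            _dh_from_cross(parents[0], origin_p[0], parents[1], origin_p[1], gmap, rng)
            for _ in range(config.n_descendants)
        ]
    else:
        for _cycle in range(config.n_cycles):
            candidates = []
            for _ in range(config.n_candidates_per_cycle):
                if len(pool) == 2:
                    a, b = 0, 1
                else:
                    a, b = rng.choice(len(pool), size=2, replace=False)
                hap, origin, xov = _dh_from_cross(*pool[a], *pool[b], gmap, rng)
                candidates.append((score(hap), hap, origin, xov))
            # stable sort: ties resolved by candidate index, reproducible under seed
            order = sorted(range(len(candidates)), key=lambda i: (-candidates[i][0], i))
            keep = order[: config.n_descendants]
            final = [(candidates[i][1], candidates[i][2], candidates[i][3]) for i in keep]
            pool = [(h, o) for h, o, _ in final]

    samples = [f"X{i + 1:02d}" for i in range(len(final))]
    haps = np.vstack([h for h, _, _ in final]).T  # markers x lines
    origin = np.vstack([o for _, o, _ in final])
    chrom_arr = frame["chrom"].to_numpy(dtype=object)
    pos_cm = frame["pos_cM"].to_numpy()
    crossovers = (
        [xov for _, _, xov in final]
        if config.n_cycles <= 1
        else [_derive_crossovers(origin[i], chrom_arr, pos_cm) for i in range(len(final))]
    )
    calls = _apply_noise(haps.astype(np.int8), config, rng)
    gm = GenotypeMatrix(
        samples=samples,
        chrom=chrom_arr,
        pos_bp=frame["pos_bp"].to_numpy(),
        pos_cM=pos_cm,
        marker_id=list(frame["marker_id"]),
        calls=calls,
    )
    truth = SimTruth(
        samples=samples,
        chrom=chrom_arr,
        pos_cM=pos_cm,
        origin=origin,
        crossovers=crossovers,
        selected_loci=config.selected_loci,
        qtls=config.qtls,
    )
    return gm, truth


def simulate_dh_population(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    founders=None,
):
    """Draw ``dh_n`` doubled haploids of the founder F1 (one meiosis each)."""
    config.validate()
    if config.dh_n < 2:
        raise ValueError("dh_n must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parents, gmap = founders if founders is not None else make_founders(config, rng)
    frame = gmap.frame
    m_total = len(frame)
    origin_p = [np.full(m_total, P1, dtype=np.int8), np.full(m_total, P2, dtype=np.int8)]
    lines, origins, xovs = [], [], []
    for _ in range(config.dh_n):
        hap, origin, xov = _dh_from_cross(parents[0], origin_p[0], parents[1], origin_p[1], gmap, rng)
        lines.append(hap)
        origins.append(origin)
        xovs.append(xov)
    samples = [f"DH{i + 1:03d}" for i in range(config.dh_n)]
    chrom_arr = frame["chrom"].to_numpy(dtype=object)
    calls = _apply_noise(np.vstack(lines).T.astype(np.int8), config, rng)
    gm = GenotypeMatrix(
        samples=samples,
        chrom=chrom_arr,
        pos_bp=frame["pos_bp"].to_numpy(),
        pos_cM=frame["pos_cM"].to_numpy(),
        marker_id=list(frame["marker_id"]),
        calls=calls,
    )
    truth = SimTruth(
        samples=samples,
        chrom=chrom_arr,
        pos_cM=frame["pos_cM"].to_numpy(),
        origin=np.vstack(origins),
        crossovers=xovs,
        qtls=config.qtls,
    )
    return gm, truth


def qtl_genotype_scores(
    gm: GenotypeMatrix,
    qtls: list[QTLSpec],
    origin: np.ndarray | None = None,
) -> np.ndarray:
    """Per-line +1/-1 codes at each QTL (+1 = parent-1 allele).

    When the simulator's parent-of-origin ``origin`` matrix is available the
    code is read from it directly (defined at every marker). Otherwise the
    nearest *segregating* marker stands in for the QTL; missing calls
    contribute 0.
    """
    frame = gm.map_frame()
    x = np.zeros((len(qtls), gm.n_samples))
    for qi, q in enumerate(qtls):
        sub = frame[frame["chrom"] == q.chrom]
        if sub.empty:
            raise ValueError(f"QTL chromosome {q.chrom!r} not on map")
        if origin is not None:
            idx = int((sub["pos_cM"] - q.pos_cM).abs().idxmin())
            x[qi] = np.where(origin[:, idx] == P1, 1.0, -1.0)
            continue
        def _segregating(i: int) -> bool:
            c = gm.calls[i][gm.calls[i] >= 0]
            return len(c) > 0 and c.min() != c.max()

        seg = sub[[_segregating(i) for i in sub.index]]
        if seg.empty:
            raise ValueError(f"no segregating marker near QTL on {q.chrom}")
        idx = int((seg["pos_cM"] - q.pos_cM).abs().idxmin())
        calls = gm.calls[idx]
        x[qi] = np.where(calls < 0, 0.0, np.where(calls == 0, 1.0, -1.0))
    return x


def simulate_phenotypes(
    gm: GenotypeMatrix,
    qtls: list[QTLSpec],
    h2: dict[str, float],
    n_env: int = 3,
    n_rep: int = 2,
    env_sd: float = 0.5,
    rng: np.random.Generator | None = None,
    truth: "SimTruth | None" = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Additive phenotypes: y = sum(a_q x_q) + env effect + residual noise.

    Residual variance is set so the heritability of line means (averaged over
    all env x rep observations) equals h2 for each trait. Returns the long
    table and the realized per-trait line-mean h2.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    traits = sorted({q.trait for q in qtls}) or sorted(h2)
    for t in traits:
        if t not in h2:
            raise ValueError(f"no h2 given for trait {t!r}")
        if not (0 < h2[t] <= 1):
            raise ValueError(f"h2 must be in (0, 1], got {h2[t]} for {t!r}")
    origin = truth.origin if truth is not None else None
    x = qtl_genotype_scores(gm, qtls, origin) if qtls else np.zeros((0, gm.n_samples))
    n_obs = n_env * n_rep
    rows = {"line": [], "env": [], "rep": []}
    for line in gm.samples:
        for e in range(n_env):
            for r in range(n_rep):
                rows["line"].append(line)
                rows["env"].append(f"E{e + 1}")
                rows["rep"].append(r + 1)
    table = pd.DataFrame(rows)
    realized: dict[str, float] = {}
    for t in traits:
        a = np.array([q.a for q in qtls if q.trait == t])
        xq = x[[i for i, q in enumerate(qtls) if q.trait == t]] if qtls else x
        g = a @ xq if len(a) else np.zeros(gm.n_samples)
        vg = float(np.var(g))
        if h2[t] >= 1.0:
            sd_e = 0.0
        else:
            base = vg if vg > 0 else 1.0
            sd_e = float(np.sqrt(base * (1.0 / h2[t] - 1.0) * n_obs))
        env_eff = rng.normal(0.0, env_sd, size=n_env)
        y = np.empty(gm.n_samples * n_obs)
        k = 0
        for i in range(gm.n_samples):
            for e in range(n_env):
                for _r in range(n_rep):
                    y[k] = g[i] + env_eff[e] + rng.normal(0.0, sd_e)
                    k += 1
        table[t] = y
        means = table.groupby("line", sort=False)[t].mean().to_numpy()
        vt = float(np.var(means))
        realized[t] = vg / vt if vt > 0 else float("nan")
    return table, realized


def write_outputs(gm, gmap: GeneticMap, pheno: pd.DataFrame, truth: SimTruth, outdir) -> dict[str, Path]:
    """Write VCF + map TSV + phenotype TSV + truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "map": outdir / "map.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.json",
    }
    try:
        psio.write_vcf(gm, paths["vcf"])
        psio.write_map(gmap.frame, paths["map"])
        psio.write_phenotypes(pheno, paths["phenotypes"])
        psio.write_truth(truth, paths["truth"])
    except OSError as exc:
        raise OSError(f"failed writing simulator outputs under {outdir}: {exc}") from exc
    return paths
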