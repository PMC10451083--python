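"""Inclusive composite interval mapping (ICIM) for doubled-haploid populations.

The scan is the regression form of ICIM: stepwise marker regression picks
background cofactors at a stringent entry/exit p-value, the phenotype is
pre-adjusted for cofactors outside the interval being tested, and a
Haley-Knott style regression of the adjusted phenotype on the expected
genotype score (from flanking markers via Kosambi recombination fractions)
yields LOD = (n/2) * log10(RSS0 / RSS1) on a 0.5-cM grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pedsweep.core import GeneticMap, GenotypeMatrix


@dataclass
class ScanParams:
    step_cM: float = 0.5
    p_in: float = 0.001
    p_out: float = 0.001
    lod_threshold: float = 2.5
    peak_sep_cM: float = 20.0
    valley_drop_lod: float = 1.0
    cofactor_excl_cM: float = 20.0  # cofactors this close to the scan position are left in y*

    def __post_init__(self) -> None:
        if self.step_cM <= 0:
            raise ValueError("step_cM must be positive")
        if not (0 < self.p_in <= 1):
            raise ValueError("p_in must be in (0, 1]")


@dataclass
class QTL:
    trait: str
    environment: str
    chrom: str
    peak_cM: float
    lod: float
    a: float  # additive effect; positive = parent-1 allele raises the trait
    pve: float  # percent phenotypic variance explained
    ci_lo_cM: float  # 1-LOD support interval
    ci_hi_cM: float
    flank_lo: str = ""
    flank_hi: str = ""


@dataclass
class QTLCluster:
    chrom: str
    start_bp: int
    end_bp: int
    members: list[QTL] = field(default_factory=list)

    @property
    def traits(self) -> list[str]:
        return sorted({q.trait for q in self.members})


# ---------------------------------------------------------------------------
# phenotype utilities and map functions


def adjust_moisture(value: float, wc: float, target: float = 0.13) -> float:
    """Rescale a weight-type trait to a standard water content.

    adjusted = value * (1 - wc) / (1 - target).
    """
    wc = np.asarray(wc, dtype=float)
    if np.any(wc >= 1) or np.any(wc < 0):
        raise ValueError("water content must be in [0, 1)")
    return value * (1.0 - wc) / (1.0 - target)


def kosambi(r):
    """Recombination fraction -> Morgans: d = 0.25 ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return 0.25 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inv(d_cm):
    """Genetic distance in cM -> recombination fraction: r = 0.5 tanh(2d)."""
    d = np.asarray(d_cm, dtype=float) / 100.0
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    return 0.5 * np.tanh(2.0 * d)


def line_means(pheno: pd.DataFrame, trait: str, env: str | None = None) -> pd.Series:
    """Average replicates (and environments if env is None) to line means."""
    df = pheno if env is None else pheno[pheno["env"] == env]
    return df.groupby("line", sort=False)[trait].mean()


# ---------------------------------------------------------------------------
# stepwise cofactor selection


def _ols_rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def stepwise_select(
    x: np.ndarray,
    y: np.ndarray,
    p_in: float = 0.001,
    p_out: float = 0.001,
    order_key: np.ndarray | None = None,
    max_steps: int | None = None,
) -> list[int]:
    """Forward/backward stepwise regression on +/-1 marker codes.

    Forward step adds the marker with the smallest partial-F p-value < p_in;
    backward step drops any included marker whose p-value exceeds p_out;
    iterate to a fixed point. Ties are broken by ``order_key`` (defaults to
    column index, i.e. map order). Collinear candidates are skipped.
    """
    n, m = x.shape
    if order_key is None:
        order_key = np.arange(m)
    max_steps = max_steps or min(m, n - 2)
    included: list[int] = []
    while True:
        changed = False
        # forward
        base = np.column_stack([np.ones(n)] + [x[:, c] for c in included])
        rss0 = _ols_rss(base, y)
        df0 = n - base.shape[1]
        best_p, best_c = None, None
        if len(included) < max_steps and df0 > 1:
            for c in range(m):
                if c in included:
                    continue
                cand = np.column_stack([base, x[:, c]])
                if np.linalg.matrix_rank(cand) <= base.shape[1]:
                    continue
                rss1 = _ols_rss(cand, y)
                df1 = n - cand.shape[1]
                if rss1 <= 0 or df1 <= 0:
                    continue
                f = (rss0 - rss1) / (rss1 / df1)
                p = float(stats.f.sf(f, 1, df1))
                if p < p_in and (
                    best_p is None
                    or p < best_p
                    or (p == best_p and order_key[c] < order_key[best_c])
                ):
                    best_p, best_c = p, c
        if best_c is not None:
            included.append(best_c)
            changed = True
        # backward
        while len(included) > 0:
            full = np.column_stack([np.ones(n)] + [x[:, c] for c in included])
            rss_full = _ols_rss(full, y)
            df_full = n - full.shape[1]
            if df_full <= 0:
                break
            worst_p, worst_i = None, None
            for i, c in enumerate(included):
                rest = [cc for cc in included if cc != c]
                red = np.column_stack([np.ones(n)] + [x[:, cc] for cc in rest])
                rss_red = _ols_rss(red, y)
                f = (rss_red - rss_full) / (rss_full / df_full) if rss_full > 0 else np.inf
                p = float(stats.f.sf(f, 1, df_full))
                if p > p_out and (worst_p is None or p > worst_p):
                    worst_p, worst_i = p, i
            if worst_i is None:
                break
            included.pop(worst_i)
            changed = True
        if not changed:
            break
    return sorted(included, key=lambda c: order_key[c])


# ---------------------------------------------------------------------------
# interval scan


def filter_segregating(gm: GenotypeMatrix, lines: list[str]) -> tuple[GenotypeMatrix, GeneticMap]:
    """Drop markers monomorphic (or all-missing) among ``lines``.

    Monomorphic markers carry no linkage information and would otherwise act
    as dead flanking markers in the interval scan.
    """
    sub = gm.subset_samples(lines)
    keep = []
    for i in range(sub.n_markers):
        c = sub.calls[i][sub.calls[i] >= 0]
        if len(c) and c.min() != c.max():
            keep.append(i)
    keep = np.asarray(keep, dtype=int)
    out = GenotypeMatrix(
        samples=lines,
        chrom=sub.chrom[keep],
        pos_bp=sub.pos_bp[keep],
        pos_cM=sub.pos_cM[keep],
        marker_id=[sub.marker_id[i] for i in keep],
        calls=sub.calls[keep],
    )
    return out, GeneticMap(out.map_frame())


def _marker_codes(gm: GenotypeMatrix, lines: list[str]) -> np.ndarray:
    """(n_lines, n_markers) +/-1 codes; missing -> 0 (mean imputation)."""
    sub = gm.subset_samples(lines)
    calls = sub.calls.T.astype(float)
    return np.where(calls < 0, 0.0, np.where(calls == 0, 1.0, -1.0))


def _expected_score(x_l, x_r, d_l_cm, d_r_cm):
    """E[x] at a grid point for DH lines given flanking +/-1 codes.

    Uses Kosambi recombination fractions and the no-interference product rule
    for the flank-to-flank fraction.
    """
    r1 = float(kosambi_inv(d_l_cm))
    r2 = float(kosambi_inv(d_r_cm))
    r12 = r1 + r2 - 2.0 * r1 * r2
    if r12 <= 0 or r12 >= 1:
        return x_l.copy()
    p_l = np.clip((1.0 + x_l) / 2.0, 0.0, 1.0)  # P(flank-left = parent1)
    p_r = np.clip((1.0 + x_r) / 2.0, 0.0, 1.0)
    # P(Q = parent1 | flanks) for the four flank classes, Haley-Knott style
    p11 = (1.0 - r1) * (1.0 - r2) / (1.0 - r12)
    p10 = (1.0 - r1) * r2 / r12
    p01 = r1 * (1.0 - r2) / r12
    p00 = r1 * r2 / (1.0 - r12)
    pq = (
        p_l * p_r * p11
        + p_l * (1.0 - p_r) * p10
        + (1.0 - p_l) * p_r * p01
        + (1.0 - p_l) * (1.0 - p_r) * p00
    )
    return 2.0 * pq - 1.0


def icim_scan(
    gm: GenotypeMatrix,
    gmap: GeneticMap,
    y: pd.Series,
    params: ScanParams | None = None,
    cofactors: list[int] | None = None,
) -> pd.DataFrame:
    """Genome scan; returns chrom, pos_cM, lod, a, pve per grid point.

    ``y`` is a line-mean Series indexed by line id; its index order defines
    the genotype rows. Cofactors (marker column indices into ``gm``) default
    to a fresh stepwise selection.
    """
    params = params or ScanParams()
    lines = [str(ln) for ln in y.index]
    codes = _marker_codes(gm, lines)  # (n_lines, M)
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    frame = gm.map_frame()
    if cofactors is None:
        cofactors = stepwise_select(codes, yv, params.p_in, params.p_out)
    cof = np.asarray(cofactors, dtype=int)
    if len(cof):
        design = np.column_stack([np.ones(n), codes[:, cof]])
        beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
        cof_beta = beta[1:]
    else:
        cof_beta = np.empty(0)

    rows = []
    for chrom in gmap.chromosomes:
        tab = gmap.chrom_table(chrom)
        marker_rows = tab.index.to_numpy()
        cms = tab["pos_cM"].to_numpy()
        ids = tab["marker_id"].to_numpy()
        grid = np.arange(cms[0], cms[-1] + 1e-9, params.step_cM)
        for pos in grid:
            ri = int(np.searchsorted(cms, pos, side="right"))
            li = max(ri - 1, 0)
            ri = min(ri, len(cms) - 1)
            if cms[li] > pos or cms[ri] < pos:
                continue
            il, ir = marker_rows[li], marker_rows[ri]
            x = (
                codes[:, il]
                if li == ri or np.isclose(cms[li], pos)
                else _expected_score(codes[:, il], codes[:, ir], pos - cms[li], cms[ri] - pos)
            )
            # adjust phenotype for cofactors away from the current position;
            # nearby ones (flanks or within the exclusion window) stay in y*
            if len(cof):
                keep = np.array(
                    [
                        c not in (il, ir)
                        and not (
                            str(frame["chrom"].iloc[c]) == str(chrom)
                            and abs(frame["pos_cM"].iloc[c] - pos) <= params.cofactor_excl_cM
                        )
                        for c in cof
                    ]
                )
                y_adj = yv - codes[:, cof[keep]] @ cof_beta[keep] if keep.any() else yv.copy()
            else:
                y_adj = yv
            x0 = np.column_stack([np.ones(n)])
            x1 = np.column_stack([np.ones(n), x])
            rss0 = _ols_rss(x0, y_adj)
            rss1 = _ols_rss(x1, y_adj)
            if rss1 <= 0:
                lod = np.inf if rss0 > 0 else 0.0
                pve = 100.0
            else:
                lod = (n / 2.0) * np.log10(rss0 / rss1)
                pve = 100.0 * (1.0 - rss1 / rss0) if rss0 > 0 else 0.0
            plus = x > 0
            minus = x < 0
            a = (
                (y_adj[plus].mean() - y_adj[minus].mean()) / 2.0
                if plus.any() and minus.any()
                else 0.0
            )
            rows.append(
                {
                    "chrom": chrom,
                    "pos_cM": float(pos),
                    "lod": float(lod),
                    "a": float(a),
                    "pve": float(pve),
                    "flank_lo": ids[li],
                    "flank_hi": ids[ri],
                }
            )
    return pd.DataFrame(rows)


def call_qtls(
    profile: pd.DataFrame,
    lod_threshold: float = 2.5,
    trait: str = "",
    environment: str = "",
    peak_sep_cM: float = 20.0,
    valley_drop_lod: float = 1.0,
) -> list[QTL]:
    """Call local LOD maxima >= threshold as QTLs with 1-LOD support intervals.

    Peaks on the same chromosome must be separated by >= peak_sep_cM or by a
    valley dropping >= valley_drop_lod below the smaller peak.
    """
    qtls: list[QTL] = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        sub = sub.sort_values("pos_cM").reset_index(drop=True)
        lod = sub["lod"].to_numpy()
        cm = sub["pos_cM"].to_numpy()
        cand = [
            i
            for i in range(len(lod))
            if lod[i] >= lod_threshold
            and (i == 0 or lod[i] >= lod[i - 1])
            and (i == len(lod) - 1 or lod[i] >= lod[i + 1])
        ]
        cand.sort(key=lambda i: -lod[i])
        accepted: list[int] = []
        for i in cand:
            ok = True
            for j in accepted:
                lo, hi = sorted((i, j))
                valley = lod[lo : hi + 1].min()
                sep = abs(cm[i] - cm[j])
                if sep < peak_sep_cM and valley > min(lod[i], lod[j]) - valley_drop_lod:
                    ok = False
                    break
            if ok:
                accepted.append(i)
        for i in sorted(accepted):
            target = lod[i] - 1.0
            lo = i
            while lo > 0 and lod[lo - 1] >= target:
                lo -= 1
            hi = i
            while hi < len(lod) - 1 and lod[hi + 1] >= target:
                hi += 1
            qtls.append(
                QTL(
                    trait=trait,
                    environment=environment,
                    chrom=str(chrom),
                    peak_cM=float(cm[i]),
                    lod=float(lod[i]),
                    a=float(sub["a"].iloc[i]),
                    pve=float(sub["pve"].iloc[i]),
                    ci_lo_cM=float(cm[lo]),
                    ci_hi_cM=float(cm[hi]),
                    flank_lo=str(sub["flank_lo"].iloc[i]),
                    flank_hi=str(sub["flank_hi"].iloc[i]),
                )
            )
    return qtls


def scan_trait(
    gm: GenotypeMatrix,
    gmap: GeneticMap,
    pheno: pd.DataFrame,
    trait: str,
    env: str,
    params: ScanParams | None = None,
) -> tuple[pd.DataFrame, list[QTL]]:
    """Line means for one trait/environment, stepwise cofactors, scan, call."""
    params = params or ScanParams()
    y = line_means(pheno, trait, env)
    missing = [ln for ln in y.index if ln not in gm.samples]
    if missing:
        warnings.warn(f"{len(missing)} phenotyped lines absent from genotypes: {missing[:5]}", stacklevel=2)
        y = y[[ln for ln in y.index if ln in gm.samples]]
    gm, gmap = filter_segregating(gm, [str(ln) for ln in y.index])
    profile = icim_scan(gm, gmap, y, params)
    qtls = call_qtls(
        profile,
        params.lod_threshold,
        trait=trait,
        environment=env,
        peak_sep_cM=params.peak_sep_cM,
        valley_drop_lod=params.valley_drop_lod,
    )
    return profile, qtls


# ---------------------------------------------------------------------------
# stability, clustering, cumulative effects


def stable_qtls(qtls: list[QTL], min_envs: int = 2) -> list[list[QTL]]:
    """Group same-trait, same-chromosome QTLs whose support intervals overlap
    across >= min_envs distinct environments."""
    groups: list[list[QTL]] = []
    by_key: dict[tuple[str, str], list[QTL]] = {}
    for q in qtls:
        by_key.setdefault((q.trait, q.chrom), []).append(q)
    for members in by_key.values():
        members = sorted(members, key=lambda q: q.ci_lo_cM)
        chain: list[QTL] = []
        chain_hi = -np.inf
        for q in members:
            if chain and q.ci_lo_cM <= chain_hi:
                chain.append(q)
                chain_hi = max(chain_hi, q.ci_hi_cM)
            else:
                if len({m.environment for m in chain}) >= min_envs:
                    groups.append(chain)
                chain = [q]
                chain_hi = q.ci_hi_cM
        if len({m.environment for m in chain}) >= min_envs:
            groups.append(chain)
    return groups


def qtl_bp_intervals(qtls: list[QTL], gmap: GeneticMap) -> list[tuple[str, int, int]]:
    """Support intervals converted to physical coordinates via the map."""
    out = []
    for q in qtls:
        lo = gmap.cm_to_bp(q.chrom, q.ci_lo_cM)
        hi = gmap.cm_to_bp(q.chrom, q.ci_hi_cM)
        out.append((q.chrom, int(min(lo, hi)), int(max(lo, hi)) + 1))
    return out


def qtl_clusters(
    qtls: list[QTL],
    gmap: GeneticMap,
    cluster_gap_bp: int = 2_000_000,
    min_size: int = 4,
) -> list[QTLCluster]:
    """Single-linkage chaining of QTL physical intervals with gap <= cluster_gap."""
    ivs = qtl_bp_intervals(qtls, gmap)
    by_chrom: dict[str, list[tuple[int, int, QTL]]] = {}
    for (chrom, s, e), q in zip(ivs, qtls):
        by_chrom.setdefault(chrom, []).append((s, e, q))
    clusters: list[QTLCluster] = []
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: t[0])
        cur: list[tuple[int, int, QTL]] = []
        cur_end = -np.inf
        for s, e, q in items + [(int(1e18), int(1e18) + 1, None)]:
            if cur and s - cur_end <= cluster_gap_bp and q is not None:
                cur.append((s, e, q))
                cur_end = max(cur_end, e)
            else:
                if len(cur) >= min_size:
                    clusters.append(
                        QTLCluster(
                            chrom=chrom,
                            start_bp=min(c[0] for c in cur),
                            end_bp=max(c[1] for c in cur),
                            members=[c[2] for c in cur],
                        )
                    )
                cur = [(s, e, q)] if q is not None else []
                cur_end = e
    return clusters


def cae(gm: GenotypeMatrix, gmap: GeneticMap, qtls: list[QTL]) -> pd.DataFrame:
    """Per-line cumulative additive effect: sum of a_q * x_q over QTL peaks.

    x is the +/-1 parental code at the marker nearest each QTL peak; missing
    genotypes skip the term (count reported).
    """
    frame = gm.map_frame()
    peak_idx = []
    for q in qtls:
        sub = frame[frame["chrom"] == q.chrom]
        peak_bp = gmap.cm_to_bp(q.chrom, q.peak_cM)
        peak_idx.append(int((sub["pos_bp"] - peak_bp).abs().idxmin()))
    rows = []
    for si, line in enumerate(gm.samples):
        total, skipped = 0.0, 0
        for q, mi in zip(qtls, peak_idx):
            call = gm.calls[mi, si]
            if call < 0:
                skipped += 1
                continue
            x = 1.0 if call == 0 else -1.0
            total += q.a * x
        rows.append({"line": line, "cae": total, "n_skipped": skipped})
    return pd.DataFrame(rows)


def qtl_table(qtls: list[QTL]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": q.trait,
                "environment": q.environment,
                "chrom": q.chrom,
                "peak_cM": q.peak_cM,
                "lod": q.lod,
                "a": q.a,
                "pve": q.pve,
                "ci_lo_cM": q.ci_lo_cM,
                "ci_hi_cM": q.ci_hi_cM,
                "flank_lo": q.flank_lo,
                "flank_hi": q.flank_hi,
            }
            for q in qtls
        ]
    )
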