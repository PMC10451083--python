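"""Windowed diversity statistics and composite-likelihood-ratio sweep scan.

Per 10-kb tile: segregating sites S, nucleotide diversity pi, Watterson's
theta and Tajima's D from the unfolded SFS (ancestral = VCF reference
allele). The CLR compares a sweep-distorted SFS model against the
genome-wide background SFS on a grid of proposed sweep sites, maximizing
over a log-spaced sweep-intensity grid. Statistics are aggregated to 100-kb
tiles; per statistic, the most sweep-like 10% of the defined genome is
selected and coordinate-adjacent windows merge into sweep regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from pedsweep.core import GenotypeMatrix

# ranking direction per statistic: sweeps depress diversity and Tajima's D
# but raise the CLR
SWEEP_DIRECTION = {"pi": "low", "tajima_d": "low", "clr": "high"}


@dataclass
class SweepModelParams:
    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-8, -2, 20)
    )
    window_bp: int = 10_000
    agg_bp: int = 100_000
    clr_site_radius_bp: int = 100_000
    top_fraction: float = 0.10
    folded: bool = False


# ---------------------------------------------------------------------------
# per-window SFS and classic statistics


def window_edges(chrom_len: int, width: int) -> list[tuple[int, int]]:
    edges = list(range(0, chrom_len, width))
    return [(s, min(s + width, chrom_len)) for s in edges]


def site_spectrum(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site derived counts: columns chrom, pos_bp, j (derived), n (local)."""
    ok = gm.calls >= 0
    n_loc = ok.sum(axis=1)
    j = np.where(ok, gm.calls, 0).sum(axis=1)
    return pd.DataFrame(
        {"chrom": gm.chrom, "pos_bp": gm.pos_bp, "j": j, "n": n_loc}
    )


def _segregating(df: pd.DataFrame) -> pd.DataFrame:
    return df[(df["j"] > 0) & (df["j"] < df["n"])]


def harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


def pi_theta(j: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Window totals of pi and Watterson's theta from per-site derived counts.

    pi_site = 2 j (n - j) / (n (n - 1)); theta_site = 1 / a1(n). Sites with
    local n < 2 are skipped.
    """
    j = np.asarray(j, dtype=float)
    n = np.asarray(n, dtype=float)
    keep = (n >= 2) & (j > 0) & (j < n)
    j, n = j[keep], n[keep]
    pi = float(np.sum(2.0 * j * (n - j) / (n * (n - 1.0))))
    theta = float(np.sum([1.0 / harmonic(int(nn)) for nn in n])) if len(n) else 0.0
    return pi, theta


def tajimas_d(j: np.ndarray, n: np.ndarray) -> float:
    """Tajima's D for one window; NaN if S = 0 or the variance term vanishes.

    The sample size for the normalizing constants is the modal local n of
    the window's segregating sites.
    """
    j = np.asarray(j, dtype=float)
    n = np.asarray(n, dtype=float)
    keep = (n >= 2) & (j > 0) & (j < n)
    j, n = j[keep], n[keep]
    s = len(j)
    if s == 0:
        return float("nan")
    vals, counts = np.unique(n.astype(int), return_counts=True)
    nn = int(vals[np.argmax(counts)])
    if nn < 2:
        return float("nan")
    pi, theta = pi_theta(j, n)
    a1 = harmonic(nn)
    a2 = harmonic(nn, 2)
    b1 = (nn + 1.0) / (3.0 * (nn - 1.0))
    b2 = 2.0 * (nn * nn + nn + 3.0) / (9.0 * nn * (nn - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (nn + 2.0) / (a1 * nn) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1.0)
    if var <= 0:
        return float("nan")
    return (pi - theta) / np.sqrt(var)


def window_stats(gm: GenotypeMatrix, chrom_lens: dict[str, int], width: int = 10_000) -> pd.DataFrame:
    """Tile each chromosome and compute n, S, pi, theta_w, tajima_d per tile."""
    sites = site_spectrum(gm)
    rows = []
    for chrom, length in chrom_lens.items():
        sub = sites[sites["chrom"] == chrom]
        for start, end in window_edges(length, width):
            w = sub[(sub["pos_bp"] > start) & (sub["pos_bp"] <= end)]
            seg = _segregating(w)
            pi, theta = pi_theta(seg["j"].to_numpy(), seg["n"].to_numpy())
            d = tajimas_d(seg["j"].to_numpy(), seg["n"].to_numpy())
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_sites": len(w),
                    "n": gm.n_samples,
                    "S": len(seg),
                    "pi": pi,
                    "theta_w": theta,
                    "tajima_d": d,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# background SFS and CLR


def background_sfs(gm: GenotypeMatrix, folded: bool = False) -> np.ndarray:
    """Genome-wide SFS over derived counts 1..n-1, from complete sites only."""
    n = gm.n_samples
    sites = site_spectrum(gm)
    full = sites[(sites["n"] == n) & (sites["j"] > 0) & (sites["j"] < n)]
    if full.empty:
        raise ValueError("no complete polymorphic sites for background SFS")
    counts = np.bincount(full["j"].to_numpy().astype(int), minlength=n)[1:n].astype(float)
    if folded:
        folded_counts = counts + counts[::-1]
        folded_counts[(n - 1) // 2 :] = 0.0
        if n % 2 == 0:
            folded_counts[n // 2 - 1] = counts[n // 2 - 1]
        counts = folded_counts
    return counts / counts.sum()


def _sweep_kernel(phi: np.ndarray, n: int) -> np.ndarray:
    """T[k, j]: probability of observing derived count j (1-based j index)
    given k lineages escaped the sweep, marginalized over the background SFS.

    Escaped lineages draw the derived allele independently with probability
    i/n (binomial approximation to the hypergeometric draw); the n - k swept
    lineages all inherit the allele carried by the sweeping haplotype, which
    is derived with probability i/n.
    """
    j_idx = np.arange(1, n)  # observable derived counts
    k_idx = np.arange(0, n + 1)
    T = np.zeros((n + 1, n - 1))
    for ii, f in enumerate(phi, start=1):
        if f == 0:
            continue
        p = ii / n
        for k in k_idx:
            # hitchhiked lineages carry derived: escaped must supply j-(n-k)
            a = binom.pmf(j_idx - (n - k), k, p)
            b = binom.pmf(j_idx, k, p)
            T[k] += f * (p * a + (1.0 - p) * b)
    return T


def clr_scan(
    pos_bp: np.ndarray,
    j: np.ndarray,
    n: int,
    phi: np.ndarray,
    grid_bp: np.ndarray,
    params: SweepModelParams | None = None,
) -> np.ndarray:
    """CLR at each proposed sweep site in ``grid_bp``.

    For a site at distance d from the sweep, the per-lineage escape
    probability is 1 - exp(-alpha * d); the likelihood under the sweep model
    mixes over the escaped-lineage count and is renormalized over observable
    counts 1..n-1. CLR = 2 * (max_alpha sweep loglik - background loglik),
    floored at 0. Only sites within ``clr_site_radius_bp`` of the grid point
    contribute; a grid point with no nearby site scores 0.
    """
    params = params or SweepModelParams()
    pos_bp = np.asarray(pos_bp, dtype=float)
    j = np.asarray(j, dtype=int)
    T = _sweep_kernel(phi, n)  # (n+1, n-1)
    log_phi = np.log(np.where(phi > 0, phi, 1.0))
    k_idx = np.arange(0, n + 1)
    out = np.zeros(len(grid_bp))
    order = np.argsort(pos_bp)
    pos_s, j_s = pos_bp[order], j[order]
    for gi, x0 in enumerate(grid_bp):
        lo = np.searchsorted(pos_s, x0 - params.clr_site_radius_bp)
        hi = np.searchsorted(pos_s, x0 + params.clr_site_radius_bp)
        if hi <= lo:
            continue
        d = np.abs(pos_s[lo:hi] - x0)
        jj = j_s[lo:hi] - 1  # column index into T
        bg = float(log_phi[jj].sum())
        best = -np.inf
        for alpha in params.alpha_grid:
            pe = 1.0 - np.exp(-alpha * d)
            w = binom.pmf(k_idx[None, :], n, pe[:, None])  # (sites, n+1)
            p = w @ T  # (sites, n-1)
            # a zero row (p_e = 0: site cannot be polymorphic under the model)
            # is left at zero and floors to ~log(0) below
            p /= np.maximum(p.sum(axis=1, keepdims=True), 1e-300)
            ll = float(np.sum(np.log(np.maximum(p[np.arange(len(jj)), jj], 1e-300))))
            if ll > best:
                best = ll
        out[gi] = max(0.0, 2.0 * (best - bg))
    return out


def clr_windows(
    gm: GenotypeMatrix,
    chrom_lens: dict[str, int],
    params: SweepModelParams | None = None,
) -> pd.DataFrame:
    """Run the CLR scan with one grid point per 10-kb window center."""
    params = params or SweepModelParams()
    if params.folded:
        raise ValueError("the unfolded CLR model is disabled for folded spectra")
    phi = background_sfs(gm)
    n = gm.n_samples
    sites = site_spectrum(gm)
    full = sites[(sites["n"] == n) & (sites["j"] > 0) & (sites["j"] < n)]
    rows = []
    for chrom, length in chrom_lens.items():
        sub = full[full["chrom"] == chrom]
        wins = window_edges(length, params.window_bp)
        grid = np.array([(s + e) / 2.0 for s, e in wins])
        clr = clr_scan(
            sub["pos_bp"].to_numpy(), sub["j"].to_numpy(), n, phi, grid, params
        )
        for (s, e), c in zip(wins, clr):
            rows.append({"chrom": chrom, "start": s, "end": e, "clr": c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation, selection, merging


def aggregate_100kb(windows: pd.DataFrame, value_cols: list[str], agg_bp: int = 100_000) -> pd.DataFrame:
    """Mean of defined fine-window values whose centers fall in each coarse tile."""
    df = windows.copy()
    df["center"] = (df["start"] + df["end"]) / 2.0
    df["agg_start"] = (df["center"] // agg_bp).astype(int) * agg_bp
    out = (
        df.groupby(["chrom", "agg_start"], sort=True)[value_cols]
        .mean()  # NaN contributors are skipped by pandas mean
        .reset_index()
        .rename(columns={"agg_start": "start"})
    )
    out["end"] = out["start"] + agg_bp
    ends = df.groupby(["chrom", "agg_start"])["end"].max().reset_index()
    out["end"] = np.minimum(out["end"], ends["end"])
    return out[["chrom", "start", "end"] + value_cols]


@dataclass
class SweepRegion:
    chrom: str
    start_bp: int
    end_bp: int
    statistic: str
    peak_value: float
    n_windows: int


def select_top_and_merge(
    windows: pd.DataFrame,
    statistic: str,
    fraction: float = 0.10,
    direction: str | None = None,
) -> tuple[list[SweepRegion], pd.DataFrame]:
    """Select the most sweep-like windows totalling >= fraction of the defined
    genome length and merge coordinate-adjacent selections into regions.

    Ties at the cutoff value are all included (deterministic).
    """
    direction = direction or SWEEP_DIRECTION[statistic]
    df = windows.dropna(subset=[statistic]).copy()
    if len(df) < 1:
        return [], df.assign(selected=False)
    df["length"] = df["end"] - df["start"]
    total = df["length"].sum()
    sign = -1.0 if direction == "high" else 1.0
    df = df.sort_values([statistic, "chrom", "start"], ascending=[direction == "low", True, True])
    cum = df["length"].cumsum()
    k = int(np.searchsorted(cum.to_numpy(), fraction * total) + 1)
    k = min(k, len(df))
    cutoff = df[statistic].iloc[k - 1]
    if direction == "low":
        sel_mask = df[statistic] <= cutoff
    else:
        sel_mask = df[statistic] >= cutoff
    df["selected"] = sel_mask
    sel = df[df["selected"]].sort_values(["chrom", "start"])
    regions: list[SweepRegion] = []
    for _, row in sel.iterrows():
        if (
            regions
            and regions[-1].chrom == row["chrom"]
            and regions[-1].end_bp == row["start"]
        ):
            r = regions[-1]
            r.end_bp = int(row["end"])
            r.n_windows += 1
            r.peak_value = (
                min(r.peak_value, row[statistic])
                if direction == "low"
                else max(r.peak_value, row[statistic])
            )
        else:
            regions.append(
                SweepRegion(
                    chrom=str(row["chrom"]),
                    start_bp=int(row["start"]),
                    end_bp=int(row["end"]),
                    statistic=statistic,
                    peak_value=float(row[statistic]),
                    n_windows=1,
                )
            )
    _ = sign  # direction handled via sort order
    marked = windows.merge(
        df[["chrom", "start", "selected"]], on=["chrom", "start"], how="left"
    )
    marked["selected"] = marked["selected"].eq(True)
    return regions, marked


# ---------------------------------------------------------------------------
# panel diagnostics


def popstats(gm: GenotypeMatrix) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-marker MAF and PIC plus rare-allele proportions.

    PIC (biallelic) = 1 - p^2 - q^2 - 2 p^2 q^2. All-missing markers are
    excluded.
    """
    freq = gm.alt_freq()
    keep = np.isfinite(freq)
    p = freq[keep]
    q = 1.0 - p
    maf = np.minimum(p, q)
    pic = 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2
    table = pd.DataFrame(
        {
            "marker_id": np.asarray(gm.marker_id, dtype=object)[keep],
            "chrom": gm.chrom[keep],
            "pos_bp": gm.pos_bp[keep],
            "maf": maf,
            "pic": pic,
        }
    )
    summary = {
        "n_markers": int(keep.sum()),
        "prop_maf_lt_0.01": float(np.mean(maf < 0.01)) if len(maf) else float("nan"),
        "prop_maf_lt_0.02": float(np.mean(maf < 0.02)) if len(maf) else float("nan"),
        "mean_pic": float(np.mean(pic)) if len(pic) else float("nan"),
    }
    return table, summary


def regions_to_bed(regions: list[SweepRegion]) -> list[tuple]:
    return [
        (r.chrom, r.start_bp, r.end_bp, r.statistic, f"{r.peak_value:.6g}")
        for r in regions
    ]
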