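"""The selection scan: windowed nucleotide diversity, Akey Fst, and a
cross-population composite-likelihood sweep statistic.

The scan contrasts a diverse reference group ("wild") against an object group
("classical_inbred") in which selection is hypothesised to have acted. Three
statistics are computed per sliding window (40 kb, 20 kb step by default):

* **pi ratio** — per-bp nucleotide diversity pi_wild / pi_inbred. A selective
  sweep fixes the inbred panel locally, driving pi_inbred toward 0 and the
  ratio up; complete fixation yields a +infinity sentinel that ranks first.
* **Akey Fst** — the ANOVA (mean-square) two-population estimator, averaged
  over informative sites in the window; raw per-site values may be negative
  and are not clipped.
* **XP-CLR score** — a composite likelihood ratio per window comparing a
  selected model (allele frequencies dragged to fixation with an escape
  probability that grows with distance from the putative sweep centre) against
  a neutral drift model (truncated-normal frequency change scaled by a drift
  variance parameter omega). The sweep centre is fixed at the window centre
  and the sweep scale is maximised over a log-spaced grid. Scores are
  comparable within a run, not to other implementations.

Top-fraction windows of each statistic are intersected through gene overlap
to produce the positively-selected-gene (PSG) list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variantio import GenotypeMatrix, GeneModel, biallelic_group_counts, WILD, INBRED

WINDOW_SIZE = 40_000
WINDOW_STEP = 20_000
TOP_FRACTION = 0.05
MIN_SNPS = 10


@dataclass
class XpclrParams:
    """Parameters of the composite-likelihood sweep model.

    omega is the variance scale of neutral drift between the groups (estimated
    from genome-wide Fst when not supplied); theta_grid is the grid of sweep
    length scales in bp over which the per-window likelihood is maximised and
    must include a near-neutral (small) value so the ratio is nested at 0.
    """

    omega: float = 0.5
    theta_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(2, 7, 15)
    )
    freq_grid_size: int = 200
    min_snps: int = MIN_SNPS

    def __post_init__(self) -> None:
        if not (0 < self.omega < 10):
            raise ValueError("omega must lie in (0, 10)")
        tg = np.asarray(self.theta_grid, dtype=float)
        if np.any(np.diff(tg) <= 0):
            raise ValueError("theta_grid must be sorted ascending")
        self.theta_grid = tg


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_windows(
    chrom_lengths: dict[str, int], size: int = WINDOW_SIZE, step: int = WINDOW_STEP
) -> pd.DataFrame:
    """Sliding windows anchored at 0 per chromosome.

    Returns a DataFrame (chrom, start, end, short) with half-open [start, end)
    intervals. Starts advance by ``step`` while start + step <= L (start 0 is
    always emitted); the final windows are clipped at the chromosome end and
    flagged ``short`` when below full size.
    """
    if step > size:
        raise ValueError("step must not exceed window size")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        start = 0
        while start == 0 or start + step <= length:
            end = min(start + size, length)
            rows.append((chrom, start, end, end - start < size))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "short"])


def assign_sites_to_windows(sites: pd.DataFrame, windows: pd.DataFrame):
    """Indices of sites in each window (1-based pos -> 0-based pos-1, half-open)."""
    pos0 = sites["pos"].to_numpy() - 1
    chrom = sites["chrom"].to_numpy()
    out = []
    for w in windows.itertuples(index=False):
        mask = (chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        out.append(np.nonzero(mask)[0])
    return out


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def site_heterozygosity(counts: np.ndarray, n_called: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity h = n/(n-1) * (1 - sum p_a^2).

    ``counts`` is (n_sites, n_alleles) over called alleles. Sites with fewer
    than two called alleles contribute 0.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n = np.asarray(n_called, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n[:, None]
        h = n / (n - 1.0) * (1.0 - np.nansum(p**2, axis=1))
    h[n < 2] = 0.0
    return h


def windowize(values, site_idx_per_window, windows: pd.DataFrame, mode: str):
    """Aggregate per-site values per window.

    mode="sum_per_bp": sum / window length (diversity per bp).
    mode="mean": arithmetic mean over sites with finite values; NaN if none.
    Returns (aggregate array, n_snps array) where n_snps counts sites in the
    window (finite-valued sites for mode="mean"'s denominator).
    """
    values = np.asarray(values, dtype=float)
    agg = np.empty(len(windows))
    n_snps = np.zeros(len(windows), dtype=int)
    lengths = (windows["end"] - windows["start"]).to_numpy()
    for k, idx in enumerate(site_idx_per_window):
        v = values[idx]
        if mode == "sum_per_bp":
            n_snps[k] = len(idx)
            agg[k] = np.nansum(v) / lengths[k]
        elif mode == "mean":
            finite = np.isfinite(v)
            n_snps[k] = int(finite.sum())
            agg[k] = v[finite].mean() if finite.any() else np.nan
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return agg, n_snps


def pi_ratio(pi_wild: np.ndarray, pi_inbred: np.ndarray) -> np.ndarray:
    """pi_wild / pi_inbred with +inf when the inbred panel is invariant.

    Both zero -> NaN (window carries no information for this statistic).
    """
    pi_wild = np.asarray(pi_wild, dtype=float)
    pi_inbred = np.asarray(pi_inbred, dtype=float)
    if (pi_wild < 0).any() or (pi_inbred < 0).any():
        raise ValueError("negative diversity input")
    out = np.full(pi_wild.shape, np.nan)
    pos = pi_inbred > 0
    out[pos] = pi_wild[pos] / pi_inbred[pos]
    out[(pi_inbred == 0) & (pi_wild > 0)] = np.inf
    return out


# ---------------------------------------------------------------------------
# Akey Fst (ANOVA estimator, k = 2 populations)
# ---------------------------------------------------------------------------

def akey_fst_site(n1, p1, n2, p2):
    """Per-site ANOVA Fst for two populations from allele counts/frequencies.

    n1, n2 are called allele counts; p1, p2 reference (or alt — symmetric)
    allele frequencies. Returns the raw estimate (may be negative); NaN where
    both populations are monomorphic (MSP = MSG = 0) or a group has < 2
    called alleles.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # / (k-1) with k=2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 - 1 + n2 - 1)
    nc = n - (n1**2 + n2**2) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (msp - msg) / (msp + (nc - 1) * msg)
    fst = np.where((msp == 0) & (msg == 0), np.nan, fst)
    fst = np.where((n1 < 2) | (n2 < 2), np.nan, fst)
    return fst


def estimate_omega(site_fst: np.ndarray, min_sites: int = 100) -> float:
    """Drift variance scale from mean positive per-site Fst: omega = F/(1-F)."""
    f = np.asarray(site_fst, dtype=float)
    f = f[np.isfinite(f) & (f > 0)]
    if f.size < min_sites:
        raise ValueError(f"need >= {min_sites} informative sites, got {f.size}")
    fbar = float(np.clip(f.mean(), 1e-3, 0.99))
    return fbar / (1.0 - fbar)


# ---------------------------------------------------------------------------
# XP-CLR-style composite likelihood
# ---------------------------------------------------------------------------

def _neutral_site_likelihood(m1, n1, m2, n2, omega: float, grid_size: int):
    """L0 per site: object counts under drift from the reference frequency.

    The latent post-drift frequency q follows Normal(p1, omega*p1*(1-p1))
    truncated to (0,1), with the out-of-range mass collapsed to point masses
    at 0 and 1 (loss/fixation). p1 is the reference alt frequency clamped away
    from 0/1 by half a haplotype count. Vectorised over sites.
    """
    m1 = np.asarray(m1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    lo = 1.0 / (2.0 * n1)
    p1 = np.clip(m1 / n1, lo, 1.0 - lo)
    sd = np.sqrt(omega * p1 * (1.0 - p1))

    # interior grid at cell midpoints
    edges = np.linspace(0.0, 1.0, grid_size + 1)
    q = 0.5 * (edges[:-1] + edges[1:])  # (G,)
    cdf = stats.norm.cdf(edges[None, :], loc=p1[:, None], scale=sd[:, None])
    w_interior = np.diff(cdf, axis=1)  # (S, G)
    mass0 = cdf[:, 0]
    mass1 = 1.0 - cdf[:, -1]

    binom_q = stats.binom.pmf(m2[:, None], n2[:, None], q[None, :])  # (S, G)
    l0 = (
        (w_interior * binom_q).sum(axis=1)
        + mass0 * (m2 == 0)
        + mass1 * (m2 == n2)
    )
    return l0, p1


def xpclr_site_loglik(m1, n1, m2, n2, omega, theta, distance_bp, grid_size=200):
    """(logL0, logL1) for one or more sites at one sweep scale theta.

    Neutral (L0): drift-only, see _neutral_site_likelihood. Selected (L1):
    with escape probability c = 1 - exp(-d/theta), a fraction c of lineages
    escapes the sweep and drifts from p1 as under neutrality, while the
    remainder is dragged to fixation of one allele (alt with probability p1):
    L1 = c*L0 + (1-c)*(p1*[m2==n2] + (1-p1)*[m2==0]). The fixation components
    have zero drift variance, so they remain point masses. As theta -> 0,
    c -> 1 and the models coincide.
    """
    m2 = np.asarray(m2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    d = np.maximum(np.asarray(distance_bp, dtype=float), 1.0)
    l0, p1 = _neutral_site_likelihood(m1, n1, m2, n2, omega, grid_size)
    c = 1.0 - np.exp(-d / float(theta))
    l1 = c * l0 + (1.0 - c) * (p1 * (m2 == n2) + (1.0 - p1) * (m2 == 0))
    with np.errstate(divide="ignore"):
        return np.log(l0), np.log(l1)


def xpclr_window_scores(
    m1, n1, m2, n2, pos, site_idx_per_window, windows: pd.DataFrame, params: XpclrParams
):
    """CLR score per window: max(0, 2 * max_theta sum_sites (logL1 - logL0)).

    The sweep position is fixed at the window centre; sites with a
    non-positive likelihood under either model are skipped. Windows with fewer
    than ``params.min_snps`` sites get NaN.
    """
    m2 = np.asarray(m2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    pos = np.asarray(pos, dtype=float)
    l0_all, p1_all = _neutral_site_likelihood(
        m1, n1, m2, n2, params.omega, params.freq_grid_size
    )
    fix_term = p1_all * (m2 == n2) + (1.0 - p1_all) * (m2 == 0)

    scores = np.full(len(windows), np.nan)
    centers = 0.5 * (windows["start"].to_numpy() + windows["end"].to_numpy())
    for k, idx in enumerate(site_idx_per_window):
        if len(idx) < params.min_snps:
            continue
        l0 = l0_all[idx]
        ok = l0 > 0
        if ok.sum() < params.min_snps:
            continue
        l0 = l0[ok]
        fix = fix_term[idx][ok]
        d = np.maximum(np.abs(pos[idx][ok] - 1 - centers[k]), 1.0)
        logl0 = np.log(l0)
        best = -np.inf
        for theta in params.theta_grid:
            c = 1.0 - np.exp(-d / theta)
            l1 = c * l0 + (1.0 - c) * fix
            good = l1 > 0
            with np.errstate(divide="ignore"):
                s = float(np.sum(np.log(l1[good]) - logl0[good]))
            best = max(best, s)
        scores[k] = max(0.0, 2.0 * best)
    return scores


# ---------------------------------------------------------------------------
# Ranking, gene mapping, intersection
# ---------------------------------------------------------------------------

def select_top_windows(
    stats_df: pd.DataFrame, column: str, fraction: float = TOP_FRACTION
) -> pd.DataFrame:
    """Top-fraction unmasked windows of a statistic, deterministically ordered.

    Eligible windows are unmasked with a defined (non-NaN) statistic; the
    count is ceil(fraction * eligible). Ordering: statistic descending
    (+inf first), ties by (chrom, start) ascending.
    """
    eligible = stats_df[~stats_df["masked"] & stats_df[column].notna()]
    if eligible.empty:
        import warnings

        warnings.warn("no eligible windows to rank")
        return eligible
    k = math.ceil(fraction * len(eligible))
    ordered = eligible.sort_values(
        by=[column, "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    return ordered.head(k)


def windows_to_genes(window_df: pd.DataFrame, genes: list[GeneModel]) -> set[str]:
    """Genes whose span overlaps any selected window by >= 1 bp."""
    out = set()
    by_chrom: dict[str, list] = {}
    for w in window_df.itertuples(index=False):
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end))
    for g in genes:
        for s, e in by_chrom.get(g.chrom, ()):
            if g.start < e and s < g.end:
                out.add(g.gene_id)
                break
    return out


def intersect_psgs(genes_pi: set, genes_fst: set, genes_xpclr: set):
    """Three-way intersection plus Venn counts.

    Returns (sorted PSG list, dict of set sizes and pairwise/triple overlaps).
    """
    psg = sorted(genes_pi & genes_fst & genes_xpclr)
    venn = {
        "n_pi": len(genes_pi),
        "n_fst": len(genes_fst),
        "n_xpclr": len(genes_xpclr),
        "n_pi_fst": len(genes_pi & genes_fst),
        "n_pi_xpclr": len(genes_pi & genes_xpclr),
        "n_fst_xpclr": len(genes_fst & genes_xpclr),
        "n_all": len(psg),
    }
    return psg, venn


# ---------------------------------------------------------------------------
# Full scan
# ---------------------------------------------------------------------------

def scan_windows(
    gm: GenotypeMatrix,
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    params: XpclrParams | None = None,
    min_snps: int = MIN_SNPS,
    wild: str = WILD,
    inbred: str = INBRED,
) -> pd.DataFrame:
    """Compute all three per-window statistics on bi-allelic genotypes.

    Returns the WindowStats table: chrom, start, end, n_snps, pi_wild,
    pi_inbred, pi_ratio, fst, xpclr, masked. The wild group is the XP-CLR
    reference; the inbred group is the object in which sweeps are sought.
    Windows that are short or carry fewer than ``min_snps`` SNPs are masked.
    """
    windows = make_windows(chrom_lengths, size, step)
    idx_per_win = assign_sites_to_windows(sites, windows)

    m_w, n_w = biallelic_group_counts(gm, wild)
    m_i, n_i = biallelic_group_counts(gm, inbred)

    h_w = site_heterozygosity(
        np.stack([n_w - m_w, m_w], axis=1), n_w
    )
    h_i = site_heterozygosity(
        np.stack([n_i - m_i, m_i], axis=1), n_i
    )
    pi_w, n_snps = windowize(h_w, idx_per_win, windows, "sum_per_bp")
    pi_i, _ = windowize(h_i, idx_per_win, windows, "sum_per_bp")

    with np.errstate(invalid="ignore", divide="ignore"):
        fst_site = akey_fst_site(n_w, m_w / n_w, n_i, m_i / n_i)
    fst_win, _ = windowize(fst_site, idx_per_win, windows, "mean")

    if params is None:
        params = XpclrParams(omega=estimate_omega(fst_site), min_snps=min_snps)
    xp = xpclr_window_scores(
        m_w, n_w, m_i, n_i, sites["pos"].to_numpy(), idx_per_win, windows, params
    )

    out = windows.copy()
    out["n_snps"] = n_snps
    out["pi_wild"] = pi_w
    out["pi_inbred"] = pi_i
    out["pi_ratio"] = pi_ratio(pi_w, pi_i)
    out["fst"] = fst_win
    out["xpclr"] = xp
    out["masked"] = out["short"] | (out["n_snps"] < min_snps)
    return out


def run_scan(
    gm,
    sites,
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    fraction: float = TOP_FRACTION,
    params: XpclrParams | None = None,
    min_snps: int = MIN_SNPS,
):
    """Scan + top-window selection + gene mapping + PSG intersection.

    Returns dict with window_stats, top tables, per-statistic gene sets,
    psgs list and venn counts.
    """
    ws = scan_windows(gm, sites, chrom_lengths, size, step, params, min_snps)
    tops = {
        stat: select_top_windows(ws, stat, fraction)
        for stat in ("pi_ratio", "fst", "xpclr")
    }
    gene_sets = {stat: windows_to_genes(df, genes) for stat, df in tops.items()}
    psgs, venn = intersect_psgs(
        gene_sets["pi_ratio"], gene_sets["fst"], gene_sets["xpclr"]
    )
    return {
        "window_stats": ws,
        "top_windows": tops,
        "gene_sets": gene_sets,
        "psgs": psgs,
        "venn": venn,
    }
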