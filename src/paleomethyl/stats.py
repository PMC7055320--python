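"""Downstream statistics over DMR sets: density, correlation scanning,
enrichment, matched permutations and direction tests.

These are generic, annotation-table-driven analyses: the caller supplies
gene/term tables, expression matrices, interval sets and genome composition
bins; the functions supply the arithmetic — per-window derived-CpG density,
best-window methylation–expression correlation with Benjamini–Hochberg
control, hypergeometric term enrichment, GC/CpG-matched interval
permutation, nearest-feature distance permutation, and exact binomial
direction tests.  All permutation p-values use the add-one estimator
p = (1 + #{null ≥ observed}) / (1 + n_perm), bounded away from zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "beta_value",
    "derived_cpg_density",
    "methylation_expression_scan",
    "correlation_scan_table",
    "term_enrichment",
    "GenomeBins",
    "matched_interval_permutation",
    "nearest_feature_distance_test",
    "phenotype_direction_binomial",
    "chi_square_counts",
    "bh_adjust",
]


def beta_value(methylated_signal, unmethylated_signal):
    """Array beta value: methylated / (methylated + unmethylated).

    Zero total signal is undefined and returns NaN (such probes are
    dropped upstream by detection-P filtering).
    """
    m = np.asarray(methylated_signal, float)
    u = np.asarray(unmethylated_signal, float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("signals must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, m / np.where(total > 0, total, 1), np.nan)
    return out if out.ndim else float(out)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# derived-CpG density

def derived_cpg_density(
    dmrs: pd.DataFrame,
    cpg_positions: dict[str, np.ndarray],
    mode: str = "dmr_centered",
    window_size: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Fraction of CpGs inside any DMR, per 100-kb window.

    ``dmr_centered`` places one window at the midpoint of each DMR;
    ``tiled`` partitions each chromosome into non-overlapping windows from
    position 0.  Windows containing no CpGs report NaN.
    """
    in_dmr = {}
    for chrom, pos in cpg_positions.items():
        flags = np.zeros(pos.size, dtype=bool)
        for _, r in dmrs[dmrs["chrom"] == chrom].iterrows():
            lo = np.searchsorted(pos, r["start"])
            hi = np.searchsorted(pos, r["end"])
            flags[lo:hi] = True
        in_dmr[chrom] = flags

    def window_fraction(chrom, w_start, w_end):
        pos = cpg_positions[chrom]
        lo, hi = np.searchsorted(pos, [w_start, w_end])
        if hi == lo:
            return np.nan, 0
        return float(in_dmr[chrom][lo:hi].mean()), int(hi - lo)

    rows = []
    if mode == "dmr_centered":
        for _, r in dmrs.iterrows():
            mid = (int(r["start"]) + int(r["end"])) // 2
            w_start, w_end = mid - window_size // 2, mid + window_size // 2
            frac, n = window_fraction(r["chrom"], w_start, w_end)
            rows.append(dict(chrom=r["chrom"], start=w_start, end=w_end,
                             fraction=frac, n_cpgs=n))
    elif mode == "tiled":
        for chrom, pos in cpg_positions.items():
            length = (chrom_lengths or {}).get(chrom, int(pos[-1]) + 1 if pos.size else 0)
            for w_start in range(0, length, window_size):
                w_end = w_start + window_size
                frac, n = window_fraction(chrom, w_start, w_end)
                rows.append(dict(chrom=chrom, start=w_start, end=w_end,
                                 fraction=frac, n_cpgs=n))
    else:
        raise ValueError("mode must be dmr_centered or tiled")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fraction", "n_cpgs"])


# ---------------------------------------------------------------------------
# methylation-expression correlation scan

def methylation_expression_scan(
    meth_by_tissue: pd.DataFrame,
    expression: pd.Series | np.ndarray,
    window: int = 25,
) -> tuple[int, float, float] | None:
    """Best-correlated window of a DMR against one gene's expression.

    ``meth_by_tissue`` is a CpG × tissue matrix of methylation over the
    DMR; ``expression`` the gene's expression across the same tissues.
    Windows of ``window`` CpGs slide one CpG at a time (a DMR shorter than
    the window is one window); per window, mean methylation per tissue is
    correlated with expression (Pearson).  Returns (window_start_index, r,
    p) for the window with max |r|, or None when fewer than 3 tissues have
    data or methylation is constant in every window.
    """
    expr = np.asarray(expression, float)
    meth = meth_by_tissue.to_numpy(float)
    n_sites = meth.shape[0]
    w = min(window, n_sites)
    best = None
    for s in range(0, n_sites - w + 1):
        win_mean = np.nanmean(meth[s : s + w], axis=0)
        ok = np.isfinite(win_mean) & np.isfinite(expr)
        if ok.sum() < 3:
            continue
        x, y = win_mean[ok], expr[ok]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r, p = sps.pearsonr(x, y)
        if best is None or abs(r) > abs(best[1]):
            best = (s, float(r), float(p))
    return best


def correlation_scan_table(
    dmr_meth: dict[str, pd.DataFrame],
    gene_candidates: dict[str, list[str]],
    expression: pd.DataFrame,
    window: int = 25,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Scan every DMR against its candidate genes; BH across all best windows.

    ``dmr_meth`` maps DMR id → CpG × tissue methylation frame;
    ``gene_candidates`` maps DMR id → genes to test (overlapping plus
    nearest up/downstream); ``expression`` is a gene × tissue matrix.
    """
    rows = []
    for dmr_id, meth in dmr_meth.items():
        for gene in gene_candidates.get(dmr_id, []):
            if gene not in expression.index:
                continue
            expr = expression.loc[gene].reindex(meth.columns)
            hit = methylation_expression_scan(meth, expr, window=window)
            if hit is None:
                continue
            rows.append(dict(dmr=dmr_id, gene=gene, window_start=hit[0],
                             r=hit[1], p=hit[2]))
    out = pd.DataFrame(rows, columns=["dmr", "gene", "window_start", "r", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"])
        out["significant"] = out["q"] < fdr
    else:
        out["q"] = []
        out["significant"] = []
    return out


# ---------------------------------------------------------------------------
# term enrichment

def term_enrichment(
    query_genes,
    background_genes,
    table: pd.DataFrame,
    gene_col: str = "gene",
    term_col: str = "term",
) -> pd.DataFrame:
    """Per-term fold enrichment with one-sided hypergeometric upper tails.

    fold = (query hits / query size) / (background hits / background size);
    p = P(X ≥ k) drawing |query| genes from the background without
    replacement; Benjamini–Hochberg across terms.
    """
    query = set(query_genes)
    background = set(background_genes)
    if not query:
        raise ValueError("empty query gene set")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    table = table[table[gene_col].isin(background)]
    rows = []
    N, n = len(background), len(query)
    for term, sub in table.groupby(term_col):
        members = set(sub[gene_col])
        K = len(members)
        k = len(members & query)
        fold = (k / n) / (K / N) if K else np.nan
        p = sps.hypergeom.sf(k - 1, N, K, n)
        rows.append(dict(term=term, query_hits=k, term_size=K, fold=fold, p=float(p)))
    out = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    out["q"] = bh_adjust(out["p"])
    return out


def chi_square_counts(table) -> tuple[float, float]:
    """Chi-square test on a 2×2 / 2×k contingency table of counts."""
    chi2, p, _, _ = sps.chi2_contingency(np.asarray(table, float))
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# matched interval permutation

@dataclass
class GenomeBins:
    """Binned genome composition used to place matched random intervals.

    Per chromosome: total length and per-bin GC content and CpG density at
    ``bin_size`` resolution.  An interval's GC/CpG value is the mean over
    the bins it covers.
    """

    chrom_lengths: dict[str, int]
    bin_size: int
    gc: dict[str, np.ndarray]
    cpg_density: dict[str, np.ndarray]

    def interval_stats(self, chrom: str, start: int, end: int) -> tuple[float, float]:
        lo = start // self.bin_size
        hi = max(lo + 1, -(-end // self.bin_size))
        return (
            float(self.gc[chrom][lo:hi].mean()),
            float(self.cpg_density[chrom][lo:hi].mean()),
        )

    @classmethod
    def from_cpg_positions(
        cls, cpg_positions: dict[str, np.ndarray], bin_size: int = 1000,
        gc: dict[str, np.ndarray] | None = None,
        chrom_lengths: dict[str, int] | None = None,
    ) -> "GenomeBins":
        """Build composition bins from CpG positions (CpG density is counts
        per bin; GC defaults to a density-correlated proxy when no sequence
        composition is supplied)."""
        lengths = dict(chrom_lengths or {})
        dens, gcs = {}, {}
        for chrom, pos in cpg_positions.items():
            L = lengths.get(chrom, int(pos[-1]) + 1)
            lengths[chrom] = L
            nbins = -(-L // bin_size)
            counts = np.bincount(pos // bin_size, minlength=nbins).astype(float)
            dens[chrom] = counts / bin_size
            gcs[chrom] = (
                gc[chrom] if gc is not None
                else 0.4 + 10.0 * dens[chrom]  # proxy: CpG-dense bins are GC-rich
            )
        return cls(chrom_lengths=lengths, bin_size=bin_size, gc=gcs, cpg_density=dens)


def _overlap_count(intervals: pd.DataFrame, targets: pd.DataFrame) -> int:
    count = 0
    by_chrom = {c: sub.sort_values("start")[["start", "end"]].to_numpy()
                for c, sub in targets.groupby("chrom")}
    for _, r in intervals.iterrows():
        t = by_chrom.get(r["chrom"])
        if t is None:
            continue
        i = np.searchsorted(t[:, 0], r["end"])
        if (t[:i, 1] > r["start"]).any():
            count += 1
    return count


def matched_interval_permutation(
    dmrs: pd.DataFrame,
    target_intervals: pd.DataFrame,
    genome: GenomeBins,
    n_perm: int = 10_000,
    seed: int = 0,
    n_bins: int = 10,
    max_retries: int = 1000,
) -> dict:
    """Permutation test of DMR overlap with a target interval set.

    Each DMR is re-placed uniformly on its own chromosome, keeping its
    length, resampling until the placement falls in the same decile bin of
    both GC content and CpG density as the original (10-bin histograms
    computed over the DMR list); after ``max_retries`` failures the
    placement is length-and-chromosome-matched only and flagged.  The
    statistic is the number of DMRs overlapping ≥ 1 target.
    """
    rng = np.random.default_rng(seed)
    obs_stats = np.array(
        [genome.interval_stats(r["chrom"], int(r["start"]), int(r["end"]))
         for _, r in dmrs.iterrows()]
    )
    gc_edges = np.quantile(obs_stats[:, 0], np.linspace(0, 1, n_bins + 1))
    cpg_edges = np.quantile(obs_stats[:, 1], np.linspace(0, 1, n_bins + 1))

    def bin_of(val, edges):
        return int(np.clip(np.searchsorted(edges, val, side="right") - 1, 0, n_bins - 1))

    obs_bins = [(bin_of(g, gc_edges), bin_of(c, cpg_edges)) for g, c in obs_stats]
    observed = _overlap_count(dmrs, target_intervals)

    null = np.empty(n_perm, dtype=int)
    n_relaxed = 0
    lengths = (dmrs["end"] - dmrs["start"]).to_numpy()
    chroms = dmrs["chrom"].to_numpy()
    for it in range(n_perm):
        rows = []
        for k in range(len(dmrs)):
            L = int(lengths[k])
            chrom = chroms[k]
            hi = genome.chrom_lengths[chrom] - L
            placed = None
            for _ in range(max_retries):
                s = int(rng.integers(0, max(hi, 1)))
                g, c = genome.interval_stats(chrom, s, s + L)
                if (bin_of(g, gc_edges), bin_of(c, cpg_edges)) == obs_bins[k]:
                    placed = s
                    break
            if placed is None:
                placed = int(rng.integers(0, max(hi, 1)))
                n_relaxed += 1
            rows.append(dict(chrom=chrom, start=placed, end=placed + L))
        null[it] = _overlap_count(pd.DataFrame(rows), target_intervals)

    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    if n_relaxed:
        logger.warning("%d placements relaxed to length/chromosome matching", n_relaxed)
    return {
        "observed": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_perm > 1 else float("nan"),
        "p": float(p),
        "n_perm": n_perm,
        "n_relaxed_placements": n_relaxed,
    }


# ---------------------------------------------------------------------------
# nearest-feature distance permutation

def nearest_feature_distance_test(
    dmrs: pd.DataFrame,
    features: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Are DMRs closer to a set of point features than chance allows?

    The statistic is the median distance from each DMR midpoint to its
    nearest feature on the same chromosome; the null redraws feature
    positions uniformly per chromosome (keeping per-chromosome counts).
    DMRs on chromosomes without features are excluded (logged).
    """
    rng = np.random.default_rng(seed)
    mids, mid_chroms = [], []
    for _, r in dmrs.iterrows():
        if r["chrom"] not in features or len(features[r["chrom"]]) == 0:
            logger.info("DMR on %s excluded: no features on chromosome", r["chrom"])
            continue
        mids.append((int(r["start"]) + int(r["end"])) // 2)
        mid_chroms.append(r["chrom"])
    if not mids:
        raise ValueError("no DMRs on chromosomes with features")
    mids = np.asarray(mids)
    mid_chroms = np.asarray(mid_chroms)

    def median_distance(feat: dict[str, np.ndarray]) -> float:
        d = np.empty(mids.size)
        for chrom in np.unique(mid_chroms):
            f = np.sort(feat[chrom])
            sel = mid_chroms == chrom
            idx = np.searchsorted(f, mids[sel])
            left = np.abs(mids[sel] - f[np.clip(idx - 1, 0, f.size - 1)])
            right = np.abs(f[np.clip(idx, 0, f.size - 1)] - mids[sel])
            d[sel] = np.minimum(left, right)
        return float(np.median(d))

    observed = median_distance(features)
    null = np.empty(n_perm)
    for it in range(n_perm):
        perm = {
            chrom: rng.integers(0, chrom_lengths[chrom], size=len(f))
            for chrom, f in features.items()
        }
        null[it] = median_distance(perm)
    p = (1 + int((null <= observed).sum())) / (1 + n_perm)
    return {
        "observed_median": observed,
        "null_mean": float(null.mean()),
        "fold_closer": float(null.mean() / observed) if observed > 0 else float("inf"),
        "p": float(p),
        "n_perm": n_perm,
        "n_dmrs": int(mids.size),
    }


# ---------------------------------------------------------------------------
# direction binomial test

def phenotype_direction_binomial(matches: int, total: int, p0: float = 0.5) -> float:
    """Exact one-sided binomial upper tail P(X ≥ matches | total, p0).

    Used for phenotype-direction concordance: out of ``total`` phenotypes
    with a defined direction, ``matches`` point the way the model predicts.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= matches <= total:
        raise ValueError("matches must lie in [0, total]")
    return float(sps.binom.sf(matches - 1, total, p0))
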