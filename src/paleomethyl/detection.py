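"""Binomial log-likelihood CUSUM detection of differentially methylated regions.

The detector compares a deamination count map (t_i, n_i per CpG) against a
reference methylome φ_i.  Under the model t_i ~ Binomial(n_i, π·ψ_i), where
ψ_i is the test sample's (unknown) methylation and π its deamination rate,
the per-site log-likelihood ratio for hypermethylation by at least Δ is

    ℓ⁺_i = ln Pr(t_i | n_i, π(φ_i+Δ)) − ln Pr(t_i | n_i, π·φ_i)
         = t_i·[ln(1+Δ/φ_i) − A_i] + n_i·A_i,   A_i = ln((1−π(φ_i+Δ))/(1−π·φ_i)),

and symmetrically ℓ⁻ with φ_i−Δ for hypomethylation.  ℓ has negative drift
under the null and positive drift inside a true DMR, so the one-sided
cumulative sum

    Q_0 = 0,   Q_i = max(Q_{i−1} + ℓ_i, 0)

stays near zero outside DMRs and climbs inside them.  Every positive
excursion of Q delimited by zeros, truncated at its peak m, yields a
candidate region [a, m] scored by the peak value Q_m.  Candidates shorter
than ``min_cpgs`` (default 50, twice the smoothing window) are removed, Q
is reset to zero across inter-CpG gaps larger than δ (default 1000 nt), and
the score threshold Q_T comes from simulation-based FDR calibration.

Power is asymmetric by construction: ℓ⁺ gains evidence from observed T's
while ℓ⁻ mostly loses it, so hypermethylation of the test sample is easier
to detect than hypomethylation at equal Δ.

A separate Fisher-window detector (:func:`fisher_window_dmrs`) serves
WGBS-vs-WGBS comparisons, where both samples carry read counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .tracks import CpGCountTrack, MethylationTrack, intersect_positions

__all__ = [
    "DetectorParams",
    "llr_plus",
    "llr_minus",
    "cusum",
    "extract_excursions",
    "detect_dmrs",
    "DeaminationDMRModel",
    "DMRScanResults",
    "fisher_window_dmrs",
]

DMR_COLUMNS = ["chrom", "start", "end", "n_cpgs", "direction", "q_max"]


@dataclass
class DetectorParams:
    delta: float = 0.5
    min_cpgs: int = 50
    gap_nt: int = 1000
    q_threshold_plus: float = 0.0
    q_threshold_minus: float = 0.0
    pi: float | None = None
    phi_eps: float = 0.01     # reference methylation clipped to [eps, 1-eps]
    llr_floor: float = -745.0  # per-site floor against -inf at boundary rates
    # a run of >= this many consecutive sites where the tested alternative is
    # infeasible (phi+delta > 1 resp. phi-delta < 0) resets Q; shorter runs
    # are treated as reference noise at the eligibility boundary and
    # contribute 0 without breaking the excursion
    infeasible_reset_run: int = 5

    def __post_init__(self):
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if self.min_cpgs < 1 or self.gap_nt <= 0:
            raise ValueError("min_cpgs >= 1 and gap_nt > 0 required")
        if self.q_threshold_plus < 0 or self.q_threshold_minus < 0:
            raise ValueError("thresholds must be non-negative")


def _llr(t, n, p1, p0, floor):
    """log Pr(t|n,p1) - log Pr(t|n,p0) for binomial pmfs, elementwise."""
    t = np.asarray(t, float)
    n = np.asarray(n, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lt = np.log(p1) - np.log(p0)
        lc = np.log1p(-p1) - np.log1p(-p0)
        out = np.where(t > 0, t * lt, 0.0) + np.where(n - t > 0, (n - t) * lc, 0.0)
    return np.maximum(np.nan_to_num(out, nan=floor, neginf=floor), floor)


def llr_plus(t, n, phi, pi, delta, floor=-745.0):
    """Per-site ℓ⁺: evidence for ψ ≥ φ+Δ over ψ = φ.

    Sites with φ+Δ > 1 are ineligible for the hyper test and contribute 0
    (preserving excursion contiguity).
    """
    phi = np.asarray(phi, float)
    val = _llr(t, n, pi * (phi + delta), pi * phi, floor)
    return np.where(phi + delta > 1.0, 0.0, val)


def llr_minus(t, n, phi, pi, delta, floor=-745.0):
    """Per-site ℓ⁻: evidence for ψ ≤ φ−Δ over ψ = φ.

    Sites with φ−Δ < 0 are ineligible and contribute 0; at φ−Δ = 0 any
    observed T makes the alternative impossible and the value hits the
    (finite) floor.
    """
    phi = np.asarray(phi, float)
    val = _llr(t, n, pi * (phi - delta), pi * phi, floor)
    return np.where(phi - delta < 0.0, 0.0, val)


def cusum(site_values, positions, gap_nt: float, reset_mask=None) -> np.ndarray:
    """One-sided cumulative sum Q_i = max(Q_{i−1} + ℓ_i, 0) with gap resets.

    ``positions`` must be sorted coordinates of a single chromosome.  At
    every site whose distance to its predecessor exceeds ``gap_nt``, Q is
    forced to 0 and the following site restarts the scan from 0 — a fresh
    scan after each large gap.  ``reset_mask`` marks additional reset
    sites (e.g. sites where the tested alternative is infeasible); they
    get the same treatment.
    """
    l = np.asarray(site_values, float)
    pos = np.asarray(positions)
    if l.size == 0:
        return np.zeros(0)
    resets = np.zeros(l.size, dtype=bool)
    resets[np.flatnonzero(np.diff(pos) > gap_nt) + 1] = True
    if reset_mask is not None:
        resets |= np.asarray(reset_mask, bool)
    q = np.empty_like(l)
    reset_sites = np.flatnonzero(resets)
    bounds = np.concatenate([[0], reset_sites, [l.size]])
    for k in range(len(bounds) - 1):
        s, e = bounds[k], bounds[k + 1]
        if k > 0:
            q[s] = 0.0  # the reset site itself is zeroed
            s += 1
            if s >= e:
                continue
        cs = np.cumsum(l[s:e])
        runmin = np.minimum(np.minimum.accumulate(cs), 0.0)
        q[s:e] = cs - runmin
    return q


def extract_excursions(
    q: np.ndarray,
    positions: np.ndarray,
    min_cpgs: int = 1,
    q_threshold: float = 0.0,
) -> pd.DataFrame:
    """Candidate DMRs from positive excursions of Q (single chromosome).

    Each maximal run of Q > 0 yields one candidate spanning CpGs a..m,
    where m is the leftmost site attaining the run's maximum; the score is
    Q_m.  Candidates with fewer than ``min_cpgs`` CpGs or Q_m below
    ``q_threshold`` are dropped.  Genomic interval is half-open
    [positions[a], positions[m]+1).
    """
    q = np.asarray(q, float)
    pos = np.asarray(positions)
    pos_mask = q > 0
    if not pos_mask.any():
        return pd.DataFrame(columns=["cpg_a", "cpg_m", "start", "end", "n_cpgs", "q_max"])
    edges = np.diff(pos_mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if pos_mask[0]:
        starts = np.concatenate([[0], starts])
    if pos_mask[-1]:
        ends = np.concatenate([ends, [q.size]])
    rows = []
    for a, b in zip(starts, ends):
        m = a + int(np.argmax(q[a:b]))  # leftmost maximum
        n_cpgs = m - a + 1
        qm = q[m]
        if n_cpgs < min_cpgs or qm < q_threshold:
            continue
        rows.append(
            dict(cpg_a=int(a), cpg_m=int(m), start=int(pos[a]), end=int(pos[m]) + 1,
                 n_cpgs=int(n_cpgs), q_max=float(qm))
        )
    return pd.DataFrame(rows, columns=["cpg_a", "cpg_m", "start", "end", "n_cpgs", "q_max"])


def _infeasible_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Sites belonging to runs of >= min_run consecutive True values."""
    mask = np.asarray(mask, bool)
    if min_run <= 1 or mask.size == 0:
        return mask
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    out = np.zeros_like(mask)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            out[s:e] = True
    return out


class DeaminationDMRModel:
    """DMR scan of a deamination count map against a reference methylome.

    Parameters
    ----------
    test : CpGCountTrack
        Filtered per-CpG counts of the test sample (raw, unsmoothed — the
        binomial statistic is defined on counts).
    reference : MethylationTrack
        Smoothed methylation of the reference sample; clipped to
        [phi_eps, 1−phi_eps] so both likelihood branches stay finite.
    params : DetectorParams
        Must carry the test sample's deamination rate ``pi``.

    ``fit()`` returns a :class:`DMRScanResults` holding the hyper- and
    hypomethylation DMR table and the per-site statistics.
    """

    def __init__(
        self,
        test: CpGCountTrack,
        reference: MethylationTrack,
        params: DetectorParams,
    ):
        if params.pi is None or not 0 < params.pi < 1:
            raise ValueError("DetectorParams.pi (deamination rate) required in (0, 1)")
        self.params = params
        merged = intersect_positions(
            test.df[["chrom", "pos", "c", "t"]],
            reference.df[["chrom", "pos", "methylation"]],
        )
        if len(merged) == 0:
            raise ValueError("test and reference tracks share no CpG sites")
        merged["n"] = merged["c"] + merged["t"]
        merged["phi"] = merged["methylation"].clip(params.phi_eps, 1 - params.phi_eps)
        self.sites = merged
        self.test_meta = dict(test.meta)
        self.reference_meta = dict(reference.meta)

    def fit(self, keep_site_stats: bool = False) -> "DMRScanResults":
        p = self.params
        dmr_frames = []
        stats_frames = [] if keep_site_stats else None
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            t = sub["t"].to_numpy(float)
            n = sub["n"].to_numpy(float)
            phi = sub["phi"].to_numpy(float)
            pos = sub["pos"].to_numpy()
            branches = (
                ("hyper", llr_plus(t, n, phi, p.pi, p.delta, p.llr_floor),
                 p.q_threshold_plus, phi + p.delta > 1.0),
                ("hypo", llr_minus(t, n, phi, p.pi, p.delta, p.llr_floor),
                 p.q_threshold_minus, phi - p.delta < 0.0),
            )
            for direction, l, thr, infeasible in branches:
                # regions where the tested alternative is infeasible cannot
                # belong to a Δ-sized DMR: they break the excursion
                resets = _infeasible_runs(infeasible, p.infeasible_reset_run)
                q = cusum(l, pos, p.gap_nt, reset_mask=resets)
                exc = extract_excursions(q, pos, p.min_cpgs, thr)
                if len(exc):
                    exc.insert(0, "chrom", chrom)
                    exc["direction"] = direction
                    dmr_frames.append(exc)
                if keep_site_stats:
                    stats_frames.append(
                        pd.DataFrame(
                            {"chrom": chrom, "pos": pos, "direction": direction,
                             "llr": l, "q": q}
                        )
                    )
        if dmr_frames:
            dmrs = pd.concat(dmr_frames, ignore_index=True)
            dmrs = dmrs[["chrom", "start", "end", "n_cpgs", "direction", "q_max"]]
            dmrs = dmrs.sort_values(["chrom", "start"]).reset_index(drop=True)
        else:
            dmrs = pd.DataFrame(columns=DMR_COLUMNS)
        site_stats = (
            pd.concat(stats_frames, ignore_index=True) if keep_site_stats else None
        )
        return DMRScanResults(self, dmrs, site_stats)


class DMRScanResults:
    """Results of a deamination-vs-reference DMR scan."""

    def __init__(self, model: DeaminationDMRModel, dmrs: pd.DataFrame, site_stats):
        self.model = model
        self.params = model.params
        self.dmrs = dmrs
        self.site_stats = site_stats

    @property
    def n_dmrs(self) -> int:
        return len(self.dmrs)

    def peak_scores(self, direction: str) -> np.ndarray:
        return self.dmrs.loc[self.dmrs["direction"] == direction, "q_max"].to_numpy()

    def summary(self) -> str:
        p = self.params
        by_dir = self.dmrs["direction"].value_counts().to_dict() if self.n_dmrs else {}
        lines = [
            "Deamination DMR scan",
            "====================",
            f"sites scanned:      {len(self.model.sites)}",
            f"pi (deamination):   {p.pi:.4g}",
            f"delta:              {p.delta}",
            f"min CpGs / gap nt:  {p.min_cpgs} / {p.gap_nt}",
            f"Q thresholds (+/-): {p.q_threshold_plus:.4g} / {p.q_threshold_minus:.4g}",
            f"DMRs (hyper/hypo):  {by_dir.get('hyper', 0)} / {by_dir.get('hypo', 0)}",
        ]
        return "\n".join(lines)

    def to_bed(self, path, score_cap: float = 1000.0) -> None:
        """BED6+ output; score column is Q_m capped and rescaled to 0-1000."""
        d = self.dmrs
        score = np.minimum(d["q_max"].to_numpy(float), score_cap)
        score = np.round(1000 * score / score_cap).astype(int) if len(d) else score
        bed = pd.DataFrame(
            {
                "chrom": d["chrom"],
                "start": d["start"],
                "end": d["end"],
                "name": [f"DMR{i + 1}" for i in range(len(d))],
                "score": score,
                "strand": ".",
                "n_cpgs": d["n_cpgs"],
                "direction": d["direction"],
                "q_max": d["q_max"],
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)

    def plot_q(self, chrom=None, ax=None):
        """Plot the per-site Q statistic (requires fit(keep_site_stats=True))."""
        if self.site_stats is None:
            raise ValueError("refit with keep_site_stats=True to plot Q")
        import matplotlib.pyplot as plt

        stats = self.site_stats
        if chrom is not None:
            stats = stats[stats["chrom"] == chrom]
        if ax is None:
            _, ax = plt.subplots()
        for direction, sub in stats.groupby("direction"):
            sign = 1 if direction == "hyper" else -1
            ax.plot(sub["pos"], sign * sub["q"], lw=0.7, label=f"Q {direction}")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("position (nt)")
        ax.set_ylabel("Q (hyper up / hypo down)")
        ax.legend()
        return ax


def detect_dmrs(
    test: CpGCountTrack, reference: MethylationTrack, params: DetectorParams
) -> pd.DataFrame:
    """One-call wrapper: scan and return the DMR table."""
    return DeaminationDMRModel(test, reference, params).fit().dmrs


# ---------------------------------------------------------------------------
# WGBS-vs-WGBS Fisher-window detector

def fisher_window_dmrs(
    sample_a: pd.DataFrame,
    sample_b: pd.DataFrame,
    window: int = 25,
    delta: float = 0.5,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """DMRs between two bisulfite count maps by sliding Fisher windows.

    Inputs carry per-CpG methylated/unmethylated read counts (columns
    chrom, pos, meth, unmeth).  Windows of ``window`` CpGs slide one CpG at
    a time; in each, summed counts form a 2×2 table tested with Fisher's
    exact test.  Windows with Benjamini–Hochberg FDR above ``fdr`` or mean
    methylation difference below ``delta`` are discarded and the surviving
    overlapping windows merged (per direction) into maximal intervals.
    """
    merged = sample_a.merge(
        sample_b, on=["chrom", "pos"], how="inner", suffixes=("_a", "_b")
    )
    win_rows = []
    for chrom, sub in merged.groupby("chrom", sort=False):
        ma = sub["meth_a"].to_numpy(float)
        ua = sub["unmeth_a"].to_numpy(float)
        mb = sub["meth_b"].to_numpy(float)
        ub = sub["unmeth_b"].to_numpy(float)
        pos = sub["pos"].to_numpy()
        m = len(sub)
        if m < window:
            continue

        def winsum(x):
            c = np.concatenate([[0.0], np.cumsum(x)])
            return c[window:] - c[:-window]

        sma, sua, smb, sub_ = winsum(ma), winsum(ua), winsum(mb), winsum(ub)
        na, nb = sma + sua, smb + sub_
        with np.errstate(invalid="ignore"):
            fa = np.where(ma + ua > 0, ma / np.maximum(ma + ua, 1), np.nan)
            fb = np.where(mb + ub > 0, mb / np.maximum(mb + ub, 1), np.nan)
        # mean per-site methylation difference over the window
        cfa = np.concatenate([[0.0], np.nancumsum(fa)])
        ca = np.concatenate([[0.0], np.cumsum(~np.isnan(fa))])
        cfb = np.concatenate([[0.0], np.nancumsum(fb)])
        cb = np.concatenate([[0.0], np.cumsum(~np.isnan(fb))])
        cnt_a = ca[window:] - ca[:-window]
        cnt_b = cb[window:] - cb[:-window]
        mean_a = np.where(cnt_a > 0, (cfa[window:] - cfa[:-window]) / np.maximum(cnt_a, 1), np.nan)
        mean_b = np.where(cnt_b > 0, (cfb[window:] - cfb[:-window]) / np.maximum(cnt_b, 1), np.nan)
        diff = mean_a - mean_b
        for w in range(m - window + 1):
            if na[w] == 0 or nb[w] == 0:
                continue  # zero-count window
            table = [[sma[w], sua[w]], [smb[w], sub_[w]]]
            _, pval = fisher_exact(np.asarray(table, dtype=np.int64))
            win_rows.append(
                dict(chrom=chrom, start=int(pos[w]), end=int(pos[w + window - 1]) + 1,
                     p=pval, diff=diff[w], n_cpgs=window)
            )
    if not win_rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows", "direction", "min_q"])
    wins = pd.DataFrame(win_rows)
    wins["q"] = multipletests(wins["p"], method="fdr_bh")[1]
    keep = (wins["q"] <= fdr) & (wins["diff"].abs() >= delta)
    wins = wins[keep]
    if len(wins) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows", "direction", "min_q"])
    wins = wins.assign(direction=np.where(wins["diff"] > 0, "hyper", "hypo"))

    merged_rows = []
    for (chrom, direction), sub in wins.groupby(["chrom", "direction"], sort=False):
        sub = sub.sort_values("start")
        cur_s, cur_e, n_win, min_q = None, None, 0, np.inf
        for _, r in sub.iterrows():
            if cur_s is None or r["start"] >= cur_e:
                if cur_s is not None:
                    merged_rows.append(
                        dict(chrom=chrom, start=cur_s, end=cur_e, n_windows=n_win,
                             direction=direction, min_q=min_q)
                    )
                cur_s, cur_e, n_win, min_q = r["start"], r["end"], 0, np.inf
            cur_e = max(cur_e, r["end"])
            n_win += 1
            min_q = min(min_q, r["q"])
        merged_rows.append(
            dict(chrom=chrom, start=cur_s, end=cur_e, n_windows=n_win,
                 direction=direction, min_q=min_q)
        )
    out = pd.DataFrame(merged_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return out
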