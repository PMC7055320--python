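"""Reconstruct methylation from ancient-DNA deamination counts.

Post-mortem deamination converts methylated cytosines to thymines at a low,
roughly genome-constant rate π, so the per-CpG C→T ratio t/(c+t) is an
attenuated readout of methylation.  Reconstruction proceeds in three steps:

1. **Pre-mortem mutation filters** — sites whose C→T signal plausibly
   reflects a germline mutation or artifact rather than deamination are
   dropped: excess A+G reads, a suspicious opposite-strand G→A ratio (for
   single-stranded libraries), a C→T ratio above a cap, and coverage above
   a maximum (suspected PCR duplicates).
2. **Smoothing** — the ratio is pooled over a fixed sliding window of
   consecutive CpGs (default 25; 50 for low-coverage samples), trading
   resolution for power at a ~5% deamination rate.
3. **Linear transformation** — a ratio of 0 maps to 0% methylation and
   μ₁₀₀, the mean C→T ratio at fully methylated reference positions, maps
   to 100%; ratios above μ₁₀₀ are capped at 100%.  For teeth, with no
   matched reference, μ₁₀₀ is set to (1/0.75)× the genome-wide mean ratio,
   anchoring the genome-wide mean at 75% methylation.

Counts are pooled (Σt/Σn) within smoothing windows rather than averaging
per-site ratios: with a shared binomial rate across the window this is the
minimum-variance estimate, and it weights sites by their coverage.  A
ratio-mean mode is kept for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .tracks import CpGCountTrack, MethylationTrack, intersect_positions

logger = logging.getLogger(__name__)

__all__ = [
    "ReconstructionParams",
    "apply_premortem_filters",
    "ct_ratio",
    "smooth",
    "estimate_pi",
    "to_methylation",
    "reconstruct",
    "TOOTH_MU100_FACTOR",
]

# tooth mode: genome-wide mean ratio represents 75% methylation
TOOTH_MU100_FACTOR = 1.0 / 0.75


@dataclass
class ReconstructionParams:
    ct_ratio_cap: float = 0.25     # 0.5 for low-coverage samples
    max_coverage: int = 100
    window_cpgs: int = 25          # 50 for low-coverage samples
    mu100: float | None = None     # C->T ratio mapping to 100% methylation
    tissue_mode: str = "bone"      # bone | tooth
    smoothing: str = "pooled"      # pooled (sum t / sum n) | ratio_mean
    pi_reference_min_level: float = 1.0  # reference level counted as "fully methylated"

    def __post_init__(self):
        if self.window_cpgs < 1:
            raise ValueError("window_cpgs must be >= 1")
        if self.mu100 is not None and not 0 < self.mu100 <= 1:
            raise ValueError("mu100 must lie in (0, 1]")
        if self.tissue_mode not in ("bone", "tooth"):
            raise ValueError("tissue_mode must be bone or tooth")


def apply_premortem_filters(
    track: CpGCountTrack, params: ReconstructionParams
) -> CpGCountTrack:
    """Drop sites whose C→T signal likely predates death.

    Filters requiring auxiliary columns the track does not carry are
    skipped with a logged warning.  Per-filter removal tallies are stored
    in the returned track's ``meta["filter_tallies"]``.
    """
    df = track.df
    keep = np.ones(len(df), dtype=bool)
    tallies: dict[str, int] = {}

    n = (df["c"] + df["t"]).to_numpy()

    # (i) more A+G than C+T reads: likely a C->T (or other) germline variant
    if "ag" in df.columns:
        bad = df["ag"].to_numpy() > n
        tallies["ag_excess"] = int((bad & keep).sum())
        keep &= ~bad
    else:
        logger.debug("filter (i) skipped: no A+G read column")

    # (ii) opposite-strand G->A check, single-stranded libraries only
    if track.meta.get("library") == "single":
        if "ga_ratio" in df.columns:
            cov = n[n > 0].mean() if (n > 0).any() else 0.0
            thr = 1.0 / cov if cov > 0 else np.inf
            bad = df["ga_ratio"].to_numpy() > thr
            tallies["ga_opposite_strand"] = int((bad & keep).sum())
            keep &= ~bad
        else:
            logger.debug("filter (ii) skipped: no opposite-strand G->A column")

    # (iii) C->T ratio above the cap
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(n > 0, df["t"].to_numpy() / np.maximum(n, 1), 0.0)
    bad = ratio > params.ct_ratio_cap
    tallies["ct_ratio_cap"] = int((bad & keep).sum())
    keep &= ~bad

    # (iv) coverage above the maximum: suspected PCR duplicates
    bad = n > params.max_coverage
    tallies["max_coverage"] = int((bad & keep).sum())
    keep &= ~bad

    meta = dict(track.meta)
    meta["filter_tallies"] = tallies
    return CpGCountTrack(df[keep].reset_index(drop=True), meta=meta, validate=False)


def ct_ratio(track: CpGCountTrack) -> pd.DataFrame:
    """Raw per-site deamination ratio t_i/n_i; zero-coverage sites excluded."""
    n = track.n
    covered = n > 0
    df = track.df[covered]
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "ratio": df["t"].to_numpy() / n[covered],
        }
    ).reset_index(drop=True)


def _window_bounds(n_sites: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(n_sites)
    left = np.maximum(i - (window - 1) // 2, 0)
    right = np.minimum(i + window // 2, n_sites - 1)
    return left, right


def smooth(track: CpGCountTrack, window_cpgs: int, mode: str = "pooled") -> pd.DataFrame:
    """Sliding-window smoothed C→T ratio, centered and truncated at ends.

    Windows never span chromosomes; a chromosome with fewer CpGs than the
    window collapses to its whole-chromosome pooled value (flagged by a
    logged warning).  Returns a frame (chrom, pos, t_sum, n_sum, ratio).
    """
    frames = []
    for chrom, sub in track.df.groupby("chrom", sort=False):
        t = sub["t"].to_numpy(float)
        n = (sub["c"] + sub["t"]).to_numpy(float)
        m = len(sub)
        if m < window_cpgs:
            logger.warning("chromosome %s has %d < %d CpGs; whole-chromosome pool",
                           chrom, m, window_cpgs)
        left, right = _window_bounds(m, window_cpgs)
        ct = np.concatenate([[0.0], np.cumsum(t)])
        cn = np.concatenate([[0.0], np.cumsum(n)])
        t_sum = ct[right + 1] - ct[left]
        n_sum = cn[right + 1] - cn[left]
        if mode == "pooled":
            with np.errstate(invalid="ignore"):
                ratio = np.where(n_sum > 0, t_sum / np.maximum(n_sum, 1), np.nan)
        elif mode == "ratio_mean":
            with np.errstate(invalid="ignore"):
                r = np.where(n > 0, t / np.maximum(n, 1), np.nan)
            cr = np.concatenate([[0.0], np.nancumsum(r)])
            cc = np.concatenate([[0.0], np.cumsum(~np.isnan(r))])
            cnt = cc[right + 1] - cc[left]
            ratio = np.where(cnt > 0, (cr[right + 1] - cr[left]) / np.maximum(cnt, 1), np.nan)
        else:
            raise ValueError(f"unknown smoothing mode {mode!r}")
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": sub["pos"].to_numpy(),
                 "t_sum": t_sum, "n_sum": n_sum, "ratio": ratio}
            )
        )
    return pd.concat(frames, ignore_index=True)


def estimate_pi(
    track: CpGCountTrack, reference: MethylationTrack, min_level: float = 1.0
) -> float:
    """Deamination rate π from the pooled C→T ratio at fully methylated
    reference positions (methylation ≥ ``min_level``)."""
    merged = intersect_positions(
        track.df[["chrom", "pos", "c", "t"]],
        reference.df[["chrom", "pos", "methylation"]],
    )
    full = merged[merged["methylation"] >= min_level]
    n_tot = (full["c"] + full["t"]).sum()
    if len(full) == 0 or n_tot == 0:
        raise ValueError(
            "no fully methylated reference sites intersect the track; "
            "relax min_level (e.g. 0.95)"
        )
    pi = full["t"].sum() / n_tot
    if not 0 < pi < 1:
        raise ValueError(f"estimated pi={pi} outside (0, 1)")
    return float(pi)


def to_methylation(
    smoothed: pd.DataFrame, params: ReconstructionParams
) -> MethylationTrack:
    """Linear transformation of the smoothed ratio to methylation.

    methylation = min(ratio / μ₁₀₀, 1).  In tooth mode μ₁₀₀ is derived from
    the genome-wide pooled ratio: mean ratio ↦ 75%, i.e. μ₁₀₀ = ratio/0.75.
    """
    if params.tissue_mode == "tooth":
        genome_ratio = smoothed["t_sum"].sum() / smoothed["n_sum"].sum()
        mu100 = TOOTH_MU100_FACTOR * genome_ratio
    else:
        mu100 = params.mu100
    if not mu100 or mu100 <= 0:
        raise ValueError("mu100 must be positive (supply it or use tooth mode)")
    ok = smoothed["n_sum"].to_numpy() > 0
    sub = smoothed[ok]
    meth = np.clip(sub["ratio"].to_numpy() / mu100, 0.0, 1.0)
    df = pd.DataFrame({"chrom": sub["chrom"], "pos": sub["pos"], "methylation": meth})
    window = int(params.window_cpgs)
    return MethylationTrack(
        df.reset_index(drop=True),
        smoothing_window=window,
        meta={"mu100": float(mu100)},
    )


def reconstruct(
    track: CpGCountTrack,
    params: ReconstructionParams,
    reference: MethylationTrack | None = None,
) -> tuple[MethylationTrack, dict]:
    """Full reconstruction: filters → smoothing → linear transformation.

    In bone mode μ₁₀₀ (and π, as the same pooled ratio at fully methylated
    sites) comes from ``reference``; in tooth mode from the genome-wide
    mean.  Returns the methylation track and an info dict (π, μ₁₀₀, filter
    tallies) suitable for a JSON sidecar.
    """
    params = replace(params)
    filtered = apply_premortem_filters(track, params)
    info: dict = {"filter_tallies": filtered.meta.get("filter_tallies", {})}

    pi = track.meta.get("pi")
    if params.tissue_mode == "bone" and params.mu100 is None:
        if reference is None:
            raise ValueError("bone mode needs a reference methylation map or mu100")
        mu100 = estimate_pi(filtered, reference, min_level=params.pi_reference_min_level)
        params.mu100 = mu100
        if pi is None:
            pi = mu100
    smoothed = smooth(filtered, params.window_cpgs, mode=params.smoothing)
    meth = to_methylation(smoothed, params)
    if pi is None and params.tissue_mode == "tooth" and reference is not None:
        pi = estimate_pi(filtered, reference, min_level=params.pi_reference_min_level)
    info.update(
        {
            "pi": float(pi) if pi is not None else None,
            "mu100": meth.meta["mu100"],
            "n_sites_in": len(track),
            "n_sites_out": len(meth),
        }
    )
    meth.meta.update(track.meta)
    meth.meta["mu100"] = info["mu100"]
    return meth, info
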