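"""Simulation-based empirical FDR calibration of the DMR score thresholds.

Reconstruction noise — binomial deamination sampling, sliding-window
smoothing, uneven read depth — produces spurious excursions of the CUSUM
statistic.  To bound their rate, deamination maps are re-simulated from the
reference methylome itself (t_i ~ Binomial(n_i, π·ψ_i) with the test
sample's observed coverage), pushed through the identical filtering,
smoothing and detection machinery, and compared to the reference: every
DMR detected there is noise.  The score thresholds Q_T⁺/Q_T⁻ are then set
to the smallest observed peak scores at which

    mean simulated DMR count / real DMR count  <  target  (default 0.05),

scanned over the sorted peak scores of the real comparison (the empirical
FDR is a step function of the threshold on exactly that grid).  Thresholds
are calibrated per direction; if no threshold achieves the target the
threshold is +inf (no DMRs pass — the safe failure mode).

A companion sanity check compares a deamination map against its own
reconstruction, where every detected DMR is by construction noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd

from .detection import DeaminationDMRModel, DetectorParams
from .reconstruction import ReconstructionParams, apply_premortem_filters
from .tracks import CpGCountTrack, MethylationTrack, intersect_positions

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationResult",
    "simulate_null_map",
    "calibrate_thresholds",
    "self_comparison_check",
]


@dataclass
class CalibrationResult:
    q_threshold_plus: float
    q_threshold_minus: float
    n_simulations: int
    target_fdr: float
    seed: int
    real_dmr_count: dict          # per direction, at the calibrated thresholds
    mean_simulated_dmr_count: dict
    achieved_fdr: dict            # per direction + "pooled"

    def thresholds(self) -> tuple[float, float]:
        return self.q_threshold_plus, self.q_threshold_minus

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def simulate_null_map(
    reference: MethylationTrack,
    coverage_template: CpGCountTrack,
    pi: float,
    rng=None,
    seed: int | None = None,
) -> CpGCountTrack:
    """A noise-only deamination map: reference methylation treated as truth.

    Coverage n_i is taken from the template sample at shared sites and
    t_i ~ Binomial(n_i, π·ψ_i), so any DMR detected between the result and
    the reference is pure sampling/smoothing noise.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    merged = intersect_positions(
        coverage_template.df[["chrom", "pos", "c", "t"]],
        reference.df[["chrom", "pos", "methylation"]],
    )
    n = (merged["c"] + merged["t"]).to_numpy()
    psi = merged["methylation"].to_numpy(float)
    t = rng.binomial(n, pi * psi)
    df = pd.DataFrame({"chrom": merged["chrom"], "pos": merged["pos"], "c": n - t, "t": t})
    return CpGCountTrack(df, meta={"sample_id": "simulated_null", "pi_true": pi})


def _counts_at(peaks: np.ndarray, threshold: float) -> int:
    return int((peaks >= threshold).sum())


def calibrate_thresholds(
    test: CpGCountTrack,
    reference: MethylationTrack,
    detector_params: DetectorParams,
    recon_params: ReconstructionParams | None = None,
    n_sims: int = 100,
    target_fdr: float = 0.05,
    seed: int = 0,
) -> CalibrationResult:
    """Choose Q_T⁺/Q_T⁻ so the empirical FDR stays below ``target_fdr``.

    ``test`` should be the already-filtered count track used in the real
    comparison; simulated maps are passed through the same pre-mortem
    filters when ``recon_params`` is given.  The master seed spawns one
    deterministic child seed per simulation.
    """
    open_params = replace(detector_params, q_threshold_plus=0.0, q_threshold_minus=0.0)
    pi = open_params.pi
    real = DeaminationDMRModel(test, reference, open_params).fit()
    real_peaks = {d: real.peak_scores(d) for d in ("hyper", "hypo")}

    sim_peaks: dict[str, list[np.ndarray]] = {"hyper": [], "hypo": []}
    child_seeds = np.random.SeedSequence(seed).spawn(n_sims)
    for k in range(n_sims):
        rng = np.random.default_rng(child_seeds[k])
        sim = simulate_null_map(reference, test, pi, rng=rng)
        if recon_params is not None:
            sim = apply_premortem_filters(sim, recon_params)
        res = DeaminationDMRModel(sim, reference, open_params).fit()
        for d in ("hyper", "hypo"):
            sim_peaks[d].append(res.peak_scores(d))

    thresholds = {}
    for d in ("hyper", "hypo"):
        grid = np.sort(np.unique(real_peaks[d]))
        chosen = np.inf
        for q in grid:
            real_count = _counts_at(real_peaks[d], q)
            if real_count == 0:
                continue
            sim_mean = float(np.mean([_counts_at(p, q) for p in sim_peaks[d]]))
            if sim_mean / real_count < target_fdr:
                chosen = float(q)
                break
        if not np.isfinite(chosen):
            logger.warning("no %s threshold achieves FDR < %g; using +inf", d, target_fdr)
        thresholds[d] = chosen

    real_count = {d: _counts_at(real_peaks[d], thresholds[d]) for d in ("hyper", "hypo")}
    sim_mean = {
        d: float(np.mean([_counts_at(p, thresholds[d]) for p in sim_peaks[d]]))
        for d in ("hyper", "hypo")
    }
    achieved = {
        d: (sim_mean[d] / real_count[d]) if real_count[d] else 0.0 for d in ("hyper", "hypo")
    }
    tot_real = sum(real_count.values())
    achieved["pooled"] = (sum(sim_mean.values()) / tot_real) if tot_real else 0.0
    return CalibrationResult(
        q_threshold_plus=thresholds["hyper"],
        q_threshold_minus=thresholds["hypo"],
        n_simulations=n_sims,
        target_fdr=target_fdr,
        seed=seed,
        real_dmr_count=real_count,
        mean_simulated_dmr_count=sim_mean,
        achieved_fdr=achieved,
    )


def self_comparison_check(
    sample: CpGCountTrack,
    own_reconstruction: MethylationTrack,
    params: DetectorParams,
) -> int:
    """DMR count when a deamination map is scanned against its own
    reconstruction — every hit is noise.  Should be a negligible fraction
    (≤ ~1%) of the count from a genuine between-group comparison."""
    res = DeaminationDMRModel(sample, own_reconstruction, params).fit()
    return res.n_dmrs
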