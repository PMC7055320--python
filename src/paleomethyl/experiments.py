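"""Study-scale experiments: parameter recovery, noise quantification and
calibration verification on the standard synthetic panel.

These drive the whole pipeline under the standard study conditions
(2 chromosomes × 20,000 CpGs, coverage 30, π = 0.05, ten planted 60-CpG
Δ = 0.6 DMRs per lineage) and are used both by the acceptance test-suite
and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .calibration import calibrate_thresholds, self_comparison_check, simulate_null_map
from .detection import DeaminationDMRModel, DetectorParams
from .panel import HOMININ_GROUPS
from .pipeline import ComparativePanelModel
from .reconstruction import (
    ReconstructionParams,
    apply_premortem_filters,
    reconstruct,
    smooth,
)
from .simulate import SimulationConfig, default_config, generate_panel, score_against_truth

__all__ = [
    "recovery_experiment",
    "noise_experiment",
    "calibration_ratio_check",
    "tooth_transform_factor",
]

DIRECTED_RUNS = [
    ("AMH", "Neanderthal"), ("AMH", "Denisovan"),
    ("Neanderthal", "Denisovan"), ("Neanderthal", "AMH"),
    ("Denisovan", "AMH"), ("Denisovan", "Neanderthal"),
]


def recovery_experiment(seeds=range(1, 21), n_sims: int = 25) -> dict:
    """Planted-DMR recovery across replicate panels.

    Runs the full five-step pipeline (with per-run FDR calibration) on one
    standard panel per seed and scores the final labeled DMRs against the
    planted truth.  Returns pooled sensitivity, label accuracy on
    recovered DMRs, and the number of final DMRs outside any planted
    region, plus the per-seed breakdown.
    """
    per_seed = []
    n_planted = n_recovered = n_false = 0
    label_ok = True
    for seed in seeds:
        panel, truth = generate_panel(default_config(seed=seed))
        res = ComparativePanelModel(panel).fit(seed=seed, calibrate=True,
                                               n_sims=n_sims)
        score = score_against_truth(res.dmrs, truth)
        per_seed.append({"seed": int(seed), **score})
        n_planted += score["n_planted"]
        n_recovered += score["n_recovered"]
        n_false += score["n_false"]
        if score["n_recovered"] and score["label_accuracy"] < 1.0:
            label_ok = False
    return {
        "sensitivity": n_recovered / n_planted,
        "label_accuracy_all_one": label_ok,
        "n_false": n_false,
        "n_planted": n_planted,
        "n_recovered": n_recovered,
        "per_seed": per_seed,
    }


def _calibrated_runs(seed: int, n_sims: int, runs=DIRECTED_RUNS):
    """Reconstruct the standard panel's core samples and calibrate every
    directed comparison; yields (test_group, ref_group, core, calibration)."""
    panel, _ = generate_panel(default_config(seed=seed))
    model = ComparativePanelModel(panel)
    core, _ = model._reconstruct_all()
    children = np.random.SeedSequence(seed).spawn(len(runs))
    out = []
    for k, (tg, rg) in enumerate(runs):
        cal = calibrate_thresholds(
            core[tg].filtered, core[rg].recon,
            replace(model.detector_params, pi=core[tg].pi),
            recon_params=model.recon_params,
            n_sims=n_sims,
            seed=int(children[k].generate_state(1)[0] % (2**31)),
        )
        out.append((tg, rg, core, cal))
    return out


def noise_experiment(seed: int = 1, n_sims: int = 100, runs=DIRECTED_RUNS) -> dict:
    """Self-comparison noise relative to genuine between-group detection.

    For every directed run of the standard panel, thresholds are
    calibrated (``n_sims`` null simulations), the between-group DMR count
    is taken at those thresholds, and the same sample's deamination map is
    scanned against its own reconstruction — where every DMR is noise.
    Reports 100 × (total self count) / (total between count).
    """
    between_total = self_total = 0
    per_run = []
    for tg, rg, core, cal in _calibrated_runs(seed, n_sims, runs):
        params = DetectorParams(
            pi=core[tg].pi,
            q_threshold_plus=cal.q_threshold_plus,
            q_threshold_minus=cal.q_threshold_minus,
        )
        between = DeaminationDMRModel(core[tg].filtered, core[rg].recon, params).fit().n_dmrs
        self_count = self_comparison_check(core[tg].filtered, core[tg].recon, params)
        per_run.append(dict(test=tg, reference=rg, between=between, self=self_count,
                            achieved_fdr=cal.achieved_fdr))
        between_total += between
        self_total += self_count
    return {
        "self_total": self_total,
        "between_total": between_total,
        "self_pct_of_between": 100.0 * self_total / between_total,
        "per_run": per_run,
    }


def calibration_ratio_check(seed: int = 1, n_sims: int = 100,
                            pair=("AMH", "Neanderthal"),
                            n_fresh_sims: int = 100) -> dict:
    """Out-of-sample verification of the calibrated FDR bound.

    Calibrates both directed runs of one pairwise comparison, then draws a
    fresh batch of null simulations and recomputes mean simulated DMR
    count / real DMR count at the returned thresholds (pooled over the two
    runs and both directions).
    """
    runs = [pair, (pair[1], pair[0])]
    fresh_ss = np.random.SeedSequence(seed + 7_000_000).spawn(len(runs))
    real_total = 0
    sim_mean_total = 0.0
    details = []
    for k, (tg, rg, core, cal) in enumerate(_calibrated_runs(seed, n_sims, runs)):
        params = DetectorParams(
            pi=core[tg].pi,
            q_threshold_plus=cal.q_threshold_plus,
            q_threshold_minus=cal.q_threshold_minus,
        )
        real = DeaminationDMRModel(core[tg].filtered, core[rg].recon, params).fit().n_dmrs
        counts = []
        for child in fresh_ss[k].spawn(n_fresh_sims):
            rng = np.random.default_rng(child)
            sim = simulate_null_map(core[rg].recon, core[tg].filtered, params.pi, rng=rng)
            sim = apply_premortem_filters(sim, ReconstructionParams())
            counts.append(DeaminationDMRModel(sim, core[rg].recon, params).fit().n_dmrs)
        sim_mean = float(np.mean(counts))
        details.append(dict(test=tg, reference=rg, real=real, sim_mean=sim_mean,
                            thresholds=cal.thresholds()))
        real_total += real
        sim_mean_total += sim_mean
    return {
        "ratio": sim_mean_total / real_total if real_total else 0.0,
        "real_total": real_total,
        "sim_mean_total": sim_mean_total,
        "per_run": details,
    }


def tooth_transform_factor(seed: int = 1) -> dict:
    """The tooth-mode transformation anchor, computed from a simulated sample.

    With no matched reference map, tooth-mode reconstruction anchors the
    genome-wide mean C→T ratio at 75% methylation, so μ₁₀₀ divided by the
    genome-wide mean smoothed ratio is the transformation factor
    (1/0.75 ≈ 1.33).  Both quantities are measured on a freshly simulated
    deamination map.
    """
    from .simulate import generate_cpg_positions, generate_lineage_methylomes, simulate_deamination

    cfg = SimulationConfig(n_chromosomes=1, cpgs_per_chromosome=20_000, seed=seed)
    positions = generate_cpg_positions(cfg)
    tracks, _ = generate_lineage_methylomes(cfg, positions, {"tooth_sample": "AMH"})
    counts = simulate_deamination(tracks["tooth_sample"], cfg.coverage_model,
                                  cfg.default_pi, seed=seed)
    params = ReconstructionParams(tissue_mode="tooth")
    meth, info = reconstruct(counts, params)
    filtered = apply_premortem_filters(counts, params)
    smoothed = smooth(filtered, params.window_cpgs)
    genome_ratio = smoothed["t_sum"].sum() / smoothed["n_sum"].sum()
    return {
        "mu100": info["mu100"],
        "genome_mean_ratio": float(genome_ratio),
        "factor": info["mu100"] / float(genome_ratio),
    }
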