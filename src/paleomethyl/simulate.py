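"""Synthetic methylomes, deamination maps and panels with planted DMRs.

The generator emulates the statistical structure the comparison pipeline
assumes:

* CpG positions with configurable inter-CpG spacing (geometric by default,
  so occasional gaps longer than the detector's reset distance occur).
* A regionally structured bimodal baseline methylome — long hypermethylated
  stretches interleaved with short hypomethylated islands, drawn from a
  two-state Markov chain along consecutive CpGs with Beta-distributed
  per-site levels.  Genome-wide mean ≈ 0.75, matching typical skeletal
  WGBS maps.
* A four-taxon design (AMH, Neanderthal, Denisovan, chimpanzee) with
  group-specific methylation shifts planted on a chosen lineage: the derived
  group(s) are moved by Δ over a contiguous span of CpGs while every other
  group (and the chimpanzee outgroup) keeps the shared baseline.
* Per-sample within-group variability as additive Gaussian noise on the
  logit scale.
* Post-mortem deamination counts t_i ~ Binomial(n_i, π·ψ_i) with
  sample-specific deamination rate π and overdispersed (negative-binomial)
  coverage, and optional WGBS read sampling and array-probe subsampling.

Everything is driven by a single integer seed; identical config + seed
reproduces identical tracks, counts and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .panel import Sample, SamplePanel
from .tracks import CpGCountTrack, MethylationTrack

__all__ = [
    "PlantedDmr",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_cpg_positions",
    "generate_lineage_methylomes",
    "simulate_deamination",
    "simulate_wgbs_counts",
    "subsample_array_probes",
    "generate_panel",
    "default_config",
    "score_against_truth",
]

# which sample groups carry a shift planted on each lineage
LINEAGE_GROUPS = {
    "AMH": ("AMH",),
    "archaic": ("Neanderthal", "Denisovan"),
    "Neanderthal": ("Neanderthal",),
    "Denisovan": ("Denisovan",),
}

# baseline anchor inside a planted span: hyper DMRs rise from a low anchor,
# hypo DMRs fall from a high one, so the full shift fits inside [0, 1]
ANCHOR_HYPER = 0.2
ANCHOR_HYPO = 0.8


@dataclass
class PlantedDmr:
    lineage: str                 # AMH | archaic | Neanderthal | Denisovan
    span_cpgs: int = 60
    delta: float = 0.6
    direction: str = "hyper"     # derived group relative to the others

    def __post_init__(self):
        if self.lineage not in LINEAGE_GROUPS:
            raise ValueError(f"unknown lineage {self.lineage!r}")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be hyper/hypo, got {self.direction!r}")


@dataclass
class SimulationConfig:
    n_chromosomes: int = 2
    cpgs_per_chromosome: int = 20_000
    inter_cpg_spacing_model: dict = field(
        default_factory=lambda: {"kind": "geometric", "mean": 100}
    )
    baseline_methylation_model: dict = field(
        default_factory=lambda: {
            "kind": "segmented_bimodal",
            "high_level": 0.92,
            "low_level": 0.05,
            "concentration": 50.0,
            "mean_high_run": 124,   # CpGs; with 30-CpG islands -> mean ~0.75
            "mean_low_run": 30,
            "shore_cpgs": 15,       # gradual island-shore transitions
        }
    )
    coverage_model: dict = field(
        default_factory=lambda: {"kind": "negative_binomial", "mean": 30, "r": 5}
    )
    deamination_rate_per_sample: dict = field(default_factory=dict)  # sample id -> pi
    default_pi: float = 0.05
    planted_dmrs: list = field(default_factory=list)  # list[PlantedDmr]
    within_group_sd: float = 0.2       # sd of logit-scale per-sample deviations
    dmr_margin_cpgs: int = 150         # min CpGs between planted spans
    wgbs_coverage: int = 30            # read depth for simulated WGBS maps
    seed: int = 0

    def __post_init__(self):
        for pi in self.deamination_rate_per_sample.values():
            if not 0 < pi < 1:
                raise ValueError("deamination rates must lie in (0, 1)")
        if not 0 < self.default_pi < 1:
            raise ValueError("default_pi must lie in (0, 1)")
        self.planted_dmrs = [
            d if isinstance(d, PlantedDmr) else PlantedDmr(**d)
            for d in self.planted_dmrs
        ]

    def pi_for(self, sample_id: str) -> float:
        return self.deamination_rate_per_sample.get(sample_id, self.default_pi)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted DMR intervals plus each sample's true methylation track."""

    planted: pd.DataFrame  # chrom,start,end,cpg_start,cpg_end,lineage,direction,delta_true,delta_eff
    per_sample_true: dict  # sample id -> MethylationTrack

    def to_bed(self, path) -> None:
        bed = pd.DataFrame(
            {
                "chrom": self.planted["chrom"],
                "start": self.planted["start"],
                "end": self.planted["end"],
                "name": self.planted["lineage"],
                "score": (self.planted["delta_eff"] * 1000).round().astype(int),
                "strand": np.where(self.planted["direction"] == "hyper", "+", "-"),
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# positions

def _draw_spacings(model: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = model["kind"]
    if kind == "constant":
        return np.full(size, int(model["value"]))
    if kind == "geometric":
        # support {1, 2, ...}; mean = 1/p
        p = 1.0 / float(model["mean"])
        draws = rng.geometric(p, size=size)
        return draws
    if kind == "uniform":
        return rng.integers(int(model["low"]), int(model["high"]) + 1, size=size)
    raise ValueError(f"unknown spacing model {kind!r}")


def generate_cpg_positions(config: SimulationConfig, rng=None) -> dict[str, np.ndarray]:
    """Ordered CpG coordinates per chromosome.

    Spacings are drawn from the configured model; non-positive draws are
    rejected and redrawn (bounded retries).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    positions = {}
    for c in range(config.n_chromosomes):
        n = config.cpgs_per_chromosome
        spacings = _draw_spacings(config.inter_cpg_spacing_model, n, rng)
        for _ in range(100):
            bad = spacings <= 0
            if not bad.any():
                break
            spacings[bad] = _draw_spacings(
                config.inter_cpg_spacing_model, int(bad.sum()), rng
            )
        else:
            raise RuntimeError("spacing model keeps yielding non-positive draws")
        pos = np.cumsum(spacings)
        pos -= pos[0]  # first CpG at 0
        positions[f"chr{c + 1}"] = pos.astype(np.int64)
    return positions


# ---------------------------------------------------------------------------
# baseline methylome and planted shifts

def _baseline_methylome(model: dict, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    kind = model["kind"]
    if kind == "segmented_bimodal":
        high, low = float(model["high_level"]), float(model["low_level"])
        conc = float(model.get("concentration", 50.0))
        mean_high = float(model["mean_high_run"])
        mean_low = float(model["mean_low_run"])
        shore = int(model.get("shore_cpgs", 15))
        # alternate high/low runs of geometric length until the chromosome is full
        state_high = rng.random() < mean_high / (mean_high + mean_low)
        level = np.empty(n_sites)
        i = 0
        while i < n_sites:
            mean_run = mean_high if state_high else mean_low
            run = int(rng.geometric(1.0 / mean_run))
            run = min(run, n_sites - i)
            level[i : i + run] = high if state_high else low
            i += run
            state_high = not state_high
        # gradual island shores: real methylomes transition over ~1 kb,
        # not site-to-site
        if shore > 1:
            kernel = np.ones(shore) / shore
            pad = np.pad(level, (shore // 2, shore - 1 - shore // 2), mode="edge")
            level = np.convolve(pad, kernel, mode="valid")
        a = level * conc
        b = (1 - level) * conc
        return rng.beta(a, b)
    if kind == "uniform":
        return rng.uniform(0, 1, size=n_sites)
    if kind == "constant":
        return np.full(n_sites, float(model["value"]))
    raise ValueError(f"unknown baseline model {kind!r}")


def _place_spans(
    planted: list[PlantedDmr],
    positions: dict[str, np.ndarray],
    margin: int,
    rng: np.random.Generator,
) -> list[tuple[str, int, int, PlantedDmr]]:
    """Assign non-overlapping CpG-index spans (with margin) to planted DMRs."""
    chroms = list(positions)
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out = []
    order = rng.permutation(len(planted))
    for k in order:
        dmr = planted[k]
        placed = False
        for _ in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            n = len(positions[chrom])
            if n < dmr.span_cpgs + 2 * margin:
                continue
            a = int(rng.integers(margin, n - margin - dmr.span_cpgs))
            b = a + dmr.span_cpgs  # half-open CpG-index span
            if all(b + margin <= s or e + margin <= a for s, e in taken[chrom]):
                taken[chrom].append((a, b))
                out.append((chrom, a, b, dmr))
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place planted DMRs without overlap")
    return out


def generate_lineage_methylomes(
    config: SimulationConfig,
    positions: dict[str, np.ndarray],
    sample_groups: dict[str, str],
    rng=None,
) -> tuple[dict[str, MethylationTrack], SyntheticTruth]:
    """True per-sample methylomes for a lineage design with planted shifts.

    ``sample_groups`` maps sample id -> group.  Inside a planted span the
    baseline of every sample is pinned to a feasibility anchor (0.2 for
    hyper shifts, 0.8 for hypo) and the derived group(s) are moved by Δ;
    shifts that would leave [0, 1] are clamped and the effective Δ recorded
    in the truth table.  Outside planted spans all groups share the
    baseline, up to within-group logit-normal noise.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    chroms = list(positions)
    base = {c: _baseline_methylome(config.baseline_methylation_model, len(positions[c]), rng)
            for c in chroms}

    spans = _place_spans(config.planted_dmrs, positions, config.dmr_margin_cpgs, rng)

    # group-level means: start from the shared baseline, pin anchors, shift derived
    groups = sorted(set(sample_groups.values()))
    group_base = {g: {c: base[c].copy() for c in chroms} for g in groups}
    shore = int(config.baseline_methylation_model.get("shore_cpgs", 15))
    truth_rows = []
    for chrom, a, b, dmr in spans:
        anchor = ANCHOR_HYPER if dmr.direction == "hyper" else ANCHOR_HYPO
        shift = dmr.delta if dmr.direction == "hyper" else -dmr.delta
        derived_level = float(np.clip(anchor + shift, 0.0, 1.0))
        delta_eff = abs(derived_level - anchor)
        derived_groups = LINEAGE_GROUPS[dmr.lineage]
        n_chr = len(positions[chrom])
        lo = max(a - shore, 0)
        hi = min(b + shore, n_chr)
        # shared flanking ramps ease baseline -> anchor outside the span, so
        # the only sharp edge is the derived group's true DMR boundary
        w_left = np.linspace(0, 1, a - lo, endpoint=False) if a > lo else np.empty(0)
        w_right = np.linspace(1, 0, hi - b + 1)[1:] if hi > b else np.empty(0)
        for g in groups:
            tr = group_base[g][chrom]
            tr[lo:a] = (1 - w_left) * tr[lo:a] + w_left * anchor
            tr[b:hi] = (1 - w_right) * tr[b:hi] + w_right * anchor
            tr[a:b] = derived_level if g in derived_groups else anchor
        pos = positions[chrom]
        truth_rows.append(
            dict(
                chrom=chrom, start=int(pos[a]), end=int(pos[b - 1]) + 1,
                cpg_start=a, cpg_end=b, lineage=dmr.lineage,
                direction=dmr.direction, delta_true=dmr.delta, delta_eff=delta_eff,
            )
        )
    planted = (
        pd.DataFrame(
            truth_rows,
            columns=["chrom", "start", "end", "cpg_start", "cpg_end",
                     "lineage", "direction", "delta_true", "delta_eff"],
        )
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )

    # per-sample tracks with logit-scale noise
    eps = 1e-4
    tracks = {}
    for sid, group in sample_groups.items():
        frames = []
        for c in chroms:
            mu = np.clip(group_base[group][c], eps, 1 - eps)
            noise = rng.normal(0.0, config.within_group_sd, size=mu.size)
            psi = expit(logit(mu) + noise)
            frames.append(pd.DataFrame({"chrom": c, "pos": positions[c], "methylation": psi}))
        df = pd.concat(frames, ignore_index=True)
        tracks[sid] = MethylationTrack(df, meta={"sample_id": sid, "group": group})
    return tracks, SyntheticTruth(planted=planted, per_sample_true=tracks)


# ---------------------------------------------------------------------------
# measurement processes

def _draw_coverage(model: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = model["kind"]
    if kind == "constant":
        return np.full(size, int(model["value"]))
    if kind == "poisson":
        return rng.poisson(float(model["mean"]), size=size)
    if kind == "negative_binomial":
        mean, r = float(model["mean"]), float(model["r"])
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size)
    raise ValueError(f"unknown coverage model {kind!r}")


def simulate_deamination(
    true_methylation: MethylationTrack,
    coverage_model: dict,
    pi: float,
    rng=None,
    seed: int | None = None,
) -> CpGCountTrack:
    """Draw deamination counts t_i ~ Binomial(n_i, π·ψ_i) at every CpG.

    Sites drawing zero coverage are kept with c = t = 0 (flagged uncovered
    by their coverage); downstream pooling handles them naturally.
    """
    if not 0 < pi < 1:
        raise ValueError("pi must lie in (0, 1)")
    rng = np.random.default_rng(seed) if rng is None else rng
    psi = true_methylation.values
    if np.nanmin(psi) < 0 or np.nanmax(psi) > 1:
        raise ValueError("methylation outside [0, 1]")
    n = _draw_coverage(coverage_model, psi.size, rng)
    t = rng.binomial(n, pi * psi)
    df = pd.DataFrame(
        {
            "chrom": true_methylation.df["chrom"],
            "pos": true_methylation.df["pos"],
            "c": n - t,
            "t": t,
        }
    )
    meta = dict(true_methylation.meta)
    meta.update({"pi_true": pi, "library": "double"})
    return CpGCountTrack(df, meta=meta)


def simulate_wgbs_counts(
    true_methylation: MethylationTrack, coverage_model: dict, rng=None, seed=None
) -> pd.DataFrame:
    """Bisulfite-style per-CpG methylated/unmethylated read counts.

    Returns a frame (chrom, pos, meth, unmeth) with meth ~ B(n_i, ψ_i);
    the substrate of the Fisher-window chimp-vs-human detector.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    psi = true_methylation.values
    n = _draw_coverage(coverage_model, psi.size, rng)
    meth = rng.binomial(n, psi)
    return pd.DataFrame(
        {
            "chrom": true_methylation.df["chrom"],
            "pos": true_methylation.df["pos"],
            "meth": meth,
            "unmeth": n - meth,
        }
    )


def measure_wgbs(
    true_methylation: MethylationTrack, coverage: int, rng=None, seed=None
) -> MethylationTrack:
    """A WGBS methylation map: per-site fraction from binomial read sampling."""
    rng = np.random.default_rng(seed) if rng is None else rng
    counts = simulate_wgbs_counts(
        true_methylation, {"kind": "constant", "value": coverage}, rng=rng
    )
    n = (counts["meth"] + counts["unmeth"]).to_numpy()
    frac = np.where(n > 0, counts["meth"] / np.maximum(n, 1), np.nan)
    df = pd.DataFrame(
        {"chrom": counts["chrom"], "pos": counts["pos"], "methylation": frac}
    )
    return MethylationTrack(df, meta=dict(true_methylation.meta))


def subsample_array_probes(
    track: MethylationTrack,
    probe_fraction: float,
    seed: int | None = None,
    rng=None,
    bias: float = 0.0,
    noise_sd: float = 0.0,
) -> MethylationTrack:
    """Array-style probe subsample of a methylation track.

    ``bias`` > 0 skews probe placement toward unmethylated sites (selection
    weight ∝ exp(-bias·ψ)), emulating RRBS-like bias; 0 is uniform.  Probe
    beta values are copied from the source, optionally with Gaussian
    measurement noise (clipped to [0, 1]).
    """
    if not 0 < probe_fraction <= 1:
        raise ValueError("probe_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = len(track)
    k = int(round(probe_fraction * n))
    psi = track.values
    if bias != 0.0:
        w = np.exp(-bias * np.nan_to_num(psi, nan=0.5))
        w /= w.sum()
        idx = np.sort(rng.choice(n, size=k, replace=False, p=w))
    else:
        idx = np.sort(rng.choice(n, size=k, replace=False))
    df = track.df.iloc[idx].reset_index(drop=True).copy()
    if noise_sd > 0:
        df["methylation"] = np.clip(
            df["methylation"] + rng.normal(0, noise_sd, size=len(df)), 0, 1
        )
    meta = dict(track.meta)
    meta["probe_fraction"] = probe_fraction
    return MethylationTrack(df, meta=meta)


# ---------------------------------------------------------------------------
# panels

def default_config(seed: int = 0, dmrs_per_lineage: int = 10) -> SimulationConfig:
    """The standard study-scale simulation: 2 chromosomes x 20,000 CpGs,
    coverage 30, π = 0.05, ``dmrs_per_lineage`` planted 60-CpG Δ = 0.6 DMRs
    on each of the four lineages (alternating hyper/hypo)."""
    planted = []
    for lineage in ("AMH", "archaic", "Neanderthal", "Denisovan"):
        for k in range(dmrs_per_lineage):
            planted.append(
                PlantedDmr(
                    lineage=lineage,
                    span_cpgs=60,
                    delta=0.6,
                    direction="hyper" if k % 2 == 0 else "hypo",
                )
            )
    return SimulationConfig(planted_dmrs=planted, seed=seed)


DEFAULT_SAMPLES = (
    # id, group, technology, tissue
    ("amh_reconstructed", "AMH", "reconstructed", "bone"),
    ("neanderthal_reconstructed", "Neanderthal", "reconstructed", "bone"),
    ("denisovan_reconstructed", "Denisovan", "reconstructed", "bone"),
    ("neanderthal_lowcov", "Neanderthal", "reconstructed", "bone"),
    ("amh_wgbs_1", "AMH", "WGBS", "bone"),
    ("amh_wgbs_2", "AMH", "WGBS", "bone"),
    ("chimp_wgbs", "chimpanzee", "WGBS", "bone"),
)

# per-sample overrides: the low-coverage Neanderthal emulates a ~8x genome
# used only for variability filtering, with the wider 50-CpG window and the
# relaxed 0.5 ratio cap such samples get
SAMPLE_OVERRIDES = {
    "neanderthal_lowcov": {
        "coverage_model": {"kind": "negative_binomial", "mean": 8, "r": 5},
        "window": 50,
    },
}


def generate_panel(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    samples: tuple = DEFAULT_SAMPLES,
    include_arrays: bool = False,
) -> tuple[SamplePanel, SyntheticTruth]:
    """Build the standard 4-group synthetic panel.

    Three reconstructed hominin samples carry deamination counts; two AMH
    WGBS maps and a chimpanzee WGBS map provide references, π estimation
    and variability filtering.  ``include_arrays`` adds a chimpanzee 850K-
    style and an AMH 450K-style probe subsample for strict-mode filtering.
    """
    config = default_config() if config is None else config
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)
    positions = generate_cpg_positions(config, rng=rng)
    sample_groups = {sid: group for sid, group, _, _ in samples}
    if include_arrays:
        sample_groups["chimp_array"] = "chimpanzee"
        sample_groups["amh_array"] = "AMH"
    true_tracks, truth = generate_lineage_methylomes(
        config, positions, sample_groups, rng=rng
    )

    panel = SamplePanel()
    for sid, group, tech, tissue in samples:
        over = SAMPLE_OVERRIDES.get(sid, {})
        s = Sample(id=sid, group=group, technology=tech, tissue=tissue,
                   window=over.get("window"))
        if tech == "reconstructed":
            s.counts = simulate_deamination(
                true_tracks[sid],
                over.get("coverage_model", config.coverage_model),
                config.pi_for(sid), rng=rng,
            )
        else:
            s.methylation = measure_wgbs(true_tracks[sid], config.wgbs_coverage, rng=rng)
        panel.samples.append(s)
    if include_arrays:
        for sid, group, tech in (
            ("chimp_array", "chimpanzee", "array850K"),
            ("amh_array", "AMH", "array450K"),
        ):
            s = Sample(id=sid, group=group, technology=tech)
            s.methylation = subsample_array_probes(
                true_tracks[sid], probe_fraction=0.03, rng=rng, noise_sd=0.02
            )
            panel.samples.append(s)
    return panel, truth


# ---------------------------------------------------------------------------
# scoring against truth

def score_against_truth(dmrs: pd.DataFrame, truth: SyntheticTruth) -> dict:
    """Recovery metrics of a final DMR table against the planted truth.

    A planted interval counts as recovered when at least one reported DMR
    overlaps it; label accuracy is scored on recovered intervals whose
    overlapping DMR carries a lineage label.  DMRs overlapping no planted
    interval are false calls.
    """
    planted = truth.planted
    recovered = 0
    label_ok = 0
    labelled = 0
    dmr_hit = np.zeros(len(dmrs), dtype=bool)
    for _, row in planted.iterrows():
        mask = (
            (dmrs["chrom"] == row["chrom"])
            & (dmrs["start"] < row["end"])
            & (dmrs["end"] > row["start"])
        )
        hits = dmrs[mask]
        if len(hits) == 0:
            continue
        recovered += 1
        dmr_hit |= mask.to_numpy()
        if "lineage" in hits.columns:
            labelled += 1
            if (hits["lineage"] == row["lineage"]).any():
                label_ok += 1
    n_false = int((~dmr_hit).sum())
    return {
        "n_planted": len(planted),
        "n_recovered": recovered,
        "sensitivity": recovered / len(planted) if len(planted) else float("nan"),
        "label_accuracy": label_ok / labelled if labelled else float("nan"),
        "n_false": n_false,
    }
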