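"""Comparative pipeline: reciprocal comparisons, intersection, lineage
assignment against the chimpanzee outgroup, and within-group variability
filtering.

The five steps mirror the comparative design the detector serves:

1. **Reciprocal two-way comparisons** between the reconstructed hominin
   samples — each pair is scanned twice, once per choice of which sample
   provides the counts and which the reference methylome, so reconstruction
   bias cannot favour one side.
2. **Three-way intersection** — a region specific to hominin 1 must appear
   both in the 1-vs-2 and the 1-vs-3 comparison; only the overlapping
   portion is kept, with agreeing direction.
3. **FDR filtering** — the score thresholds applied during detection come
   from simulation-based calibration (:mod:`paleomethyl.calibration`).
4. **Lineage assignment** — the chimpanzee map polarizes each DMR: the
   hominin whose methylation sits farthest from the chimpanzee carries the
   derived state.  A change specific to the AMH sample but with the
   chimpanzee clustering with AMH instead marks the archaic ancestor
   branch.  Inconclusive configurations are discarded.
5. **Within-group variability filtering** — a DMR is kept as fixed only if
   every sample of the derived group lies strictly outside the methylation
   range of all other samples, on the side the direction dictates.  In
   strict mode, array samples join the filter with their probe means
   adjusted for probe placement (m' = min(m·r, 1), with r the ratio of the
   reference-map mean over all DMR CpGs to its mean over probed CpGs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, calibrate_thresholds
from .detection import DMR_COLUMNS, DeaminationDMRModel, DetectorParams
from .panel import HOMININ_GROUPS, Sample, SamplePanel
from .reconstruction import ReconstructionParams, apply_premortem_filters, reconstruct
from .tracks import CpGCountTrack, MethylationTrack

logger = logging.getLogger(__name__)

__all__ = [
    "reciprocal_two_way",
    "three_way_intersect",
    "assign_lineage",
    "adjust_array_methylation",
    "variability_filter",
    "run_pipeline",
    "ComparativePanelModel",
    "ComparativePanelResults",
]

_FLIP = {"hyper": "hypo", "hypo": "hyper"}


# ---------------------------------------------------------------------------
# step 1: reciprocal two-way comparison

def _merge_union(dmrs: pd.DataFrame, positions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Union-merge overlapping same-direction DMRs; recount CpGs over the
    merged interval from the shared site positions."""
    if len(dmrs) == 0:
        return dmrs
    rows = []
    for (chrom, direction), sub in dmrs.groupby(["chrom", "direction"], sort=False):
        sub = sub.sort_values("start")
        cur = None
        for _, r in sub.iterrows():
            if cur is None or r["start"] >= cur["end"]:
                if cur is not None:
                    rows.append(cur)
                cur = dict(chrom=chrom, start=int(r["start"]), end=int(r["end"]),
                           direction=direction, q_max=float(r["q_max"]),
                           support=set(r["support"]))
            else:
                cur["end"] = max(cur["end"], int(r["end"]))
                cur["q_max"] = max(cur["q_max"], float(r["q_max"]))
                cur["support"] |= set(r["support"])
        rows.append(cur)
    out = pd.DataFrame(rows)
    pos_count = []
    for _, r in out.iterrows():
        pos = positions.get(r["chrom"], np.empty(0, dtype=np.int64))
        pos_count.append(int(np.searchsorted(pos, r["end"]) - np.searchsorted(pos, r["start"])))
    out["n_cpgs"] = pos_count
    out["support"] = out["support"].map(frozenset)
    return out[["chrom", "start", "end", "n_cpgs", "direction", "q_max", "support"]] \
        .sort_values(["chrom", "start"]).reset_index(drop=True)


def reciprocal_two_way(
    counts1: CpGCountTrack,
    recon1: MethylationTrack,
    pi1: float,
    counts2: CpGCountTrack,
    recon2: MethylationTrack,
    pi2: float,
    params: DetectorParams,
    thresholds_12: tuple[float, float] | None = None,
    thresholds_21: tuple[float, float] | None = None,
    label1: str = "sample1",
    label2: str = "sample2",
    support_fraction: float = 0.5,
) -> pd.DataFrame:
    """Union of both reciprocal runs between two samples.

    Directions in the output are relative to sample 1 (``hyper`` = sample 1
    more methylated).  A DMR found in only one of the two runs is retained
    and flagged; the reciprocity serves as bias control, with real
    stringency coming from the three-way intersection.

    The ``support`` column records which samples' counts corroborate each
    DMR: a sample supports a DMR if its scan shows an overlapping
    same-direction excursion reaching ``support_fraction`` of that run's
    score threshold and half the CpG minimum.  A genuine methylation
    difference is visible (if weakly) from either sample's counts, whereas
    a count-noise excursion exists only in the sample that produced it.
    """
    thr12 = thresholds_12 or (params.q_threshold_plus, params.q_threshold_minus)
    thr21 = thresholds_21 or (params.q_threshold_plus, params.q_threshold_minus)
    # scan open (threshold 0, half CpG minimum); candidates then need the
    # full minimum and their run's score threshold, corroboration the
    # relaxed one
    open_params = replace(params, q_threshold_plus=0.0, q_threshold_minus=0.0,
                          min_cpgs=max(params.min_cpgs // 2, 1))
    open_a = DeaminationDMRModel(counts1, recon2, replace(open_params, pi=pi1)).fit().dmrs
    open_b = DeaminationDMRModel(counts2, recon1, replace(open_params, pi=pi2)).fit().dmrs
    open_b["direction"] = open_b["direction"].map(_FLIP)  # make relative to sample 1

    def passed(df, thr, flip):
        t_hyper, t_hypo = (thr[1], thr[0]) if flip else thr
        keep = np.where(df["direction"] == "hyper",
                        df["q_max"] >= t_hyper, df["q_max"] >= t_hypo)
        keep &= (df["n_cpgs"] >= params.min_cpgs).to_numpy()
        return df[keep]

    both = pd.concat(
        [passed(open_a, thr12, flip=False), passed(open_b, thr21, flip=True)],
        ignore_index=True,
    )
    if len(both) == 0:
        return pd.DataFrame(columns=DMR_COLUMNS + ["found_in", "support"])
    both["support"] = [frozenset()] * len(both)
    positions = {
        chrom: sub["pos"].to_numpy()
        for chrom, sub in counts1.df.groupby("chrom", sort=False)
    }
    merged = _merge_union(both, positions)

    def corroborates(cands, thr, flip, row):
        t_hyper, t_hypo = (thr[1], thr[0]) if flip else thr
        need = (t_hyper if row["direction"] == "hyper" else t_hypo) * support_fraction
        hits = cands[
            (cands["chrom"] == row["chrom"])
            & (cands["direction"] == row["direction"])
            & (cands["start"] < row["end"])
            & (cands["end"] > row["start"])
            & (cands["q_max"] >= need)
        ]
        return len(hits) > 0

    support = []
    for _, row in merged.iterrows():
        s = set()
        if corroborates(open_a, thr12, False, row):
            s.add(label1)
        if corroborates(open_b, thr21, True, row):
            s.add(label2)
        support.append(frozenset(s))
    merged["support"] = support
    merged["found_in"] = merged["support"].map(
        lambda s: "both" if len(s) > 1 else (next(iter(s)) if s else "none")
    )
    return merged


# ---------------------------------------------------------------------------
# step 2: three-way intersection

def three_way_intersect(
    dmrs_1v2: pd.DataFrame,
    dmrs_1v3: pd.DataFrame,
    min_cpgs: int,
    positions: dict[str, np.ndarray],
    min_support_samples: int = 1,
) -> pd.DataFrame:
    """Hominin-1-specific DMRs: overlapping portions of the two lists.

    Both inputs must carry directions relative to hominin 1; a candidate
    needs agreeing direction in both lists.  Only the overlapping portion
    is kept (half-open interval intersection), re-checked against
    ``min_cpgs`` over the shared CpG positions; the score is the smaller of
    the two source scores.

    ``min_support_samples`` > 1 additionally requires count evidence from
    that many distinct samples across the two source DMRs (``support``
    column): both comparisons share hominin 1's counts, so a count-noise
    excursion in that one sample survives the intersection unless a second
    sample's counts corroborate it.
    """
    has_support = "support" in dmrs_1v2.columns and "support" in dmrs_1v3.columns
    rows = []
    for (chrom, direction), a_sub in dmrs_1v2.groupby(["chrom", "direction"], sort=False):
        b_all = dmrs_1v3[dmrs_1v3["chrom"] == chrom]
        b_same = b_all[b_all["direction"] == direction]
        b_conflict = b_all[b_all["direction"] != direction]
        pos = positions.get(chrom, np.empty(0, dtype=np.int64))
        for _, ra in a_sub.iterrows():
            conflict = b_conflict[
                (b_conflict["start"] < ra["end"]) & (b_conflict["end"] > ra["start"])
            ]
            if len(conflict):
                logger.info("direction conflict at %s:%d-%d dropped",
                            chrom, ra["start"], ra["end"])
            hits = b_same[(b_same["start"] < ra["end"]) & (b_same["end"] > ra["start"])]
            for _, rb in hits.iterrows():
                start = int(max(ra["start"], rb["start"]))
                end = int(min(ra["end"], rb["end"]))
                n_cpgs = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
                if n_cpgs < min_cpgs:
                    continue
                support = (
                    frozenset(ra["support"]) | frozenset(rb["support"])
                    if has_support else frozenset()
                )
                if has_support and len(support) < min_support_samples:
                    logger.info(
                        "candidate %s:%d-%d dropped: single-sample support %s",
                        chrom, start, end, set(support),
                    )
                    continue
                rows.append(
                    dict(chrom=chrom, start=start, end=end, n_cpgs=n_cpgs,
                         direction=direction,
                         q_max=float(min(ra["q_max"], rb["q_max"])),
                         support=support)
                )
    out = pd.DataFrame(rows, columns=DMR_COLUMNS + ["support"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# step 4: lineage assignment

def _region_values(track: MethylationTrack, chrom: str, start: int, end: int) -> pd.DataFrame:
    df = track.df
    sub = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)]
    return sub[["pos", "methylation"]]


def _outgroup_distance(
    hominin: MethylationTrack, outgroup: MethylationTrack,
    chrom: str, start: int, end: int, min_shared: int,
) -> float | None:
    h = _region_values(hominin, chrom, start, end)
    c = _region_values(outgroup, chrom, start, end)
    merged = h.merge(c, on="pos", suffixes=("_h", "_c")).dropna()
    if len(merged) < min_shared:
        return None
    return float(np.mean(np.abs(merged["methylation_h"] - merged["methylation_c"])))


def assign_lineage(
    dmr: pd.Series | dict,
    hominin_maps: dict[str, MethylationTrack],
    outgroup_map: MethylationTrack,
    specific_to: str,
    min_shared: int = 10,
) -> str:
    """Parsimony lineage label for a hominin-specific DMR.

    The distance of hominin H to the chimpanzee over the DMR is the mean
    absolute per-CpG methylation difference.  For an AMH-specific DMR:
    both archaics closer to the chimpanzee → the change arose on the AMH
    branch; AMH closer than both archaics → it arose on the branch of the
    Neanderthal–Denisovan ancestor ("archaic"); anything else is
    inconclusive.  Neanderthal-/Denisovan-specific DMRs require both other
    hominins closer to the chimpanzee.  Ties are inconclusive; fewer than
    ``min_shared`` shared CpGs with the outgroup → ``no_outgroup_data``.
    """
    chrom, start, end = dmr["chrom"], int(dmr["start"]), int(dmr["end"])
    d = {}
    for g in HOMININ_GROUPS:
        d[g] = _outgroup_distance(hominin_maps[g], outgroup_map, chrom, start, end, min_shared)
    if any(v is None for v in d.values()):
        return "no_outgroup_data"
    others = [g for g in HOMININ_GROUPS if g != specific_to]
    if all(d[g] < d[specific_to] for g in others):
        return specific_to if specific_to != "AMH" else "AMH"
    if specific_to == "AMH" and all(d["AMH"] < d[g] for g in others):
        return "archaic"
    return "inconclusive"


# ---------------------------------------------------------------------------
# array adjustment (Eq.-style probe-placement correction)

def adjust_array_methylation(
    probe_values: np.ndarray,
    reference_all: np.ndarray,
    reference_probed: np.ndarray,
) -> float:
    """Correct an array-probe DMR mean for unrepresentative probe placement.

    m' = min(m · r, 1) with m the mean probe beta, and r the ratio of the
    reference full-map mean over all DMR CpGs to its mean over the probed
    CpGs.  Representative probes (equal means) leave m unchanged; if the
    probed reference mean is zero the uncorrected m is returned (flagged by
    a logged warning).
    """
    probe_values = np.asarray(probe_values, float)
    if probe_values.size == 0:
        raise ValueError("no probes in DMR")
    m = float(np.nanmean(probe_values))
    m_all = float(np.nanmean(np.asarray(reference_all, float)))
    m_probed = float(np.nanmean(np.asarray(reference_probed, float)))
    if m_probed == 0:
        logger.warning("probed reference mean is 0; returning uncorrected array mean")
        return m
    return float(min(m * m_all / m_probed, 1.0))


# ---------------------------------------------------------------------------
# step 5: within-group variability filter

LINEAGE_DERIVED_GROUPS = {
    "AMH": ("AMH",),
    "archaic": ("Neanderthal", "Denisovan"),
    "Neanderthal": ("Neanderthal",),
    "Denisovan": ("Denisovan",),
}


def _sample_dmr_mean(
    sample: Sample,
    methylation: MethylationTrack | None,
    chrom: str,
    start: int,
    end: int,
    reference_map: MethylationTrack | None,
) -> float | None:
    track = methylation if methylation is not None else sample.methylation
    if track is None:
        return None
    vals = _region_values(track, chrom, start, end)["methylation"].dropna()
    if len(vals) == 0:
        return None
    if sample.is_array and reference_map is not None:
        ref = _region_values(reference_map, chrom, start, end)
        probed = ref[ref["pos"].isin(_region_values(track, chrom, start, end)["pos"])]
        if len(ref) and len(probed):
            return adjust_array_methylation(
                vals.to_numpy(), ref["methylation"].to_numpy(), probed["methylation"].to_numpy()
            )
    return float(vals.mean())


def variability_filter(
    dmr: pd.Series | dict,
    panel: SamplePanel,
    derived_lineage: str,
    mode: str = "wgbs",
    reconstructions: dict[str, MethylationTrack] | None = None,
    array_references: dict[str, str] | None = None,
) -> bool:
    """Keep a DMR only if the derived group is completely outside the
    methylation range of every other sample, on the side of its direction.

    ``mode='wgbs'`` uses reconstructed and bisulfite samples only (unbiased
    genomic distribution); ``mode='strict'`` adds array samples, their DMR
    means corrected for probe placement against a same-group full map.
    Samples with no data over the DMR drop out of the range with a note.
    """
    reconstructions = reconstructions or {}
    derived_groups = LINEAGE_DERIVED_GROUPS[derived_lineage]
    chrom, start, end = dmr["chrom"], int(dmr["start"]), int(dmr["end"])
    direction = dmr["direction"]

    derived_vals, comparison_vals = [], []
    for s in panel:
        if s.is_array and mode != "strict":
            continue
        ref_map = None
        if s.is_array:
            ref_id = (array_references or {}).get(s.id)
            if ref_id is None:
                wgbs = [x for x in panel.by_group(s.group) if x.technology == "WGBS"]
                ref_map = wgbs[0].methylation if wgbs else None
            else:
                ref_map = panel.get(ref_id).methylation
        mean = _sample_dmr_mean(s, reconstructions.get(s.id), chrom, start, end, ref_map)
        if mean is None:
            logger.info("sample %s has no data over %s:%d-%d", s.id, chrom, start, end)
            continue
        if s.group in derived_groups:
            derived_vals.append(mean)
        else:
            comparison_vals.append(mean)
    if not derived_vals or not comparison_vals:
        return False
    lo, hi = min(comparison_vals), max(comparison_vals)
    if direction == "hyper":
        return all(v > hi for v in derived_vals)
    return all(v < lo for v in derived_vals)


# ---------------------------------------------------------------------------
# the full pipeline as a fitted panel model

@dataclass
class _CoreSample:
    sample: Sample
    filtered: CpGCountTrack
    recon: MethylationTrack
    pi: float


@dataclass
class PipelineFit:
    """Bookkeeping of one fitted pipeline run."""

    funnel: dict = field(default_factory=dict)
    calibrations: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)
    specific: dict = field(default_factory=dict)


class ComparativePanelModel:
    """Full comparative analysis of a sample panel.

    Statsmodels-style: construct from the data (panel) and parameters, call
    :meth:`fit`, inspect the returned results object.

    Parameters
    ----------
    panel : SamplePanel
        Must contain one reconstructed (count-carrying) sample per hominin
        group, at least one AMH WGBS map (π estimation and filtering) and a
        chimpanzee WGBS map (outgroup; without it the run stops after the
        intersection step with unpolarized DMRs).
    detector_params, recon_params : defaults match the standard analysis
        (Δ = 0.5, ≥ 50 CpGs, δ = 1000 nt, 25-CpG smoothing, ratio cap 0.25,
        coverage cap 100).
    """

    def __init__(
        self,
        panel: SamplePanel,
        detector_params: DetectorParams | None = None,
        recon_params: ReconstructionParams | None = None,
    ):
        self.panel = panel
        self.detector_params = detector_params or DetectorParams()
        self.recon_params = recon_params or ReconstructionParams()
        core = panel.core_samples()
        missing = [g for g in HOMININ_GROUPS if g not in core]
        if missing:
            raise ValueError(f"panel lacks reconstructed samples for {missing}")
        self.core_groups = core
        wgbs = [s for s in panel.by_group("AMH") if s.technology == "WGBS"]
        if not wgbs:
            raise ValueError("panel needs an AMH WGBS map for pi estimation")
        self.pi_reference = wgbs[0]

    # -- internals ---------------------------------------------------------

    def _reconstruct_all(self) -> tuple[dict[str, _CoreSample], dict[str, MethylationTrack]]:
        core: dict[str, _CoreSample] = {}
        recon_by_id: dict[str, MethylationTrack] = {}
        for s in self.panel:
            if s.technology != "reconstructed" or s.counts is None:
                continue
            rp = self.recon_params
            if s.window is not None:
                rp = replace(rp, window_cpgs=s.window, ct_ratio_cap=max(rp.ct_ratio_cap, 0.5))
            track = s.counts
            if s.pi is not None:
                track = CpGCountTrack(track.df, meta={**track.meta, "pi": s.pi})
            try:
                recon, info = reconstruct(track, rp, reference=self.pi_reference.methylation)
            except ValueError:
                # reference map has no fully methylated sites at this
                # coverage; relax the "fully methylated" definition
                logger.warning("no fully methylated reference sites for %s; "
                               "relaxing to 0.95", s.id)
                rp = replace(rp, pi_reference_min_level=0.95)
                recon, info = reconstruct(track, rp, reference=self.pi_reference.methylation)
            recon.meta["sample_id"] = s.id
            recon_by_id[s.id] = recon
            for g, cs in self.core_groups.items():
                if cs.id == s.id:
                    filtered = apply_premortem_filters(track, rp)
                    core[g] = _CoreSample(s, filtered, recon, info["pi"])
        return core, recon_by_id

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        calibrate: bool = True,
        n_sims: int = 100,
        target_fdr: float = 0.05,
        mode: str = "wgbs",
        min_shared_outgroup: int = 10,
        min_support_samples: int = 2,
    ) -> "ComparativePanelResults":
        state = PipelineFit()
        core, recon_by_id = self._reconstruct_all()
        outgroup = self.panel.outgroup_sample()

        pairs = [
            ("AMH", "Neanderthal"),
            ("AMH", "Denisovan"),
            ("Neanderthal", "Denisovan"),
        ]
        # one deterministic calibration seed per directed run
        run_seeds = {}
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(2 * len(pairs))
        for k, (g1, g2) in enumerate(pairs):
            run_seeds[(g1, g2)] = children[2 * k]
            run_seeds[(g2, g1)] = children[2 * k + 1]

        def run_thresholds(test_g, ref_g):
            if not calibrate:
                return (self.detector_params.q_threshold_plus,
                        self.detector_params.q_threshold_minus)
            cal = calibrate_thresholds(
                core[test_g].filtered,
                core[ref_g].recon,
                replace(self.detector_params, pi=core[test_g].pi),
                recon_params=self.recon_params,
                n_sims=n_sims,
                target_fdr=target_fdr,
                seed=int(run_seeds[(test_g, ref_g)].generate_state(1)[0] % (2**31)),
            )
            state.calibrations[(test_g, ref_g)] = cal
            return cal.thresholds()

        for g1, g2 in pairs:
            dmrs = reciprocal_two_way(
                core[g1].filtered, core[g1].recon, core[g1].pi,
                core[g2].filtered, core[g2].recon, core[g2].pi,
                self.detector_params,
                thresholds_12=run_thresholds(g1, g2),
                thresholds_21=run_thresholds(g2, g1),
                label1=g1, label2=g2,
            )
            state.pairwise[(g1, g2)] = dmrs
        state.funnel["step1_pairwise"] = {
            f"{a}_vs_{b}": len(v) for (a, b), v in state.pairwise.items()
        }

        def pair_dmrs(g1, g2):
            """DMRs of pair (g1, g2) with direction relative to g1."""
            if (g1, g2) in state.pairwise:
                return state.pairwise[(g1, g2)]
            d = state.pairwise[(g2, g1)].copy()
            d["direction"] = d["direction"].map(_FLIP)
            return d

        specific = {}
        for g1 in HOMININ_GROUPS:
            others = [g for g in HOMININ_GROUPS if g != g1]
            positions = {
                chrom: sub["pos"].to_numpy()
                for chrom, sub in core[g1].filtered.df.groupby("chrom", sort=False)
            }
            specific[g1] = three_way_intersect(
                pair_dmrs(g1, others[0]), pair_dmrs(g1, others[1]),
                self.detector_params.min_cpgs, positions,
                min_support_samples=min_support_samples,
            ).assign(specific_to=g1)
        state.specific = specific
        state.funnel["step2_specific"] = {g: len(v) for g, v in specific.items()}

        nonempty = [v for v in specific.values() if len(v)]
        all_specific = (
            pd.concat(nonempty, ignore_index=True) if nonempty
            else next(iter(specific.values())).copy()
        )
        if outgroup is None or len(all_specific) == 0:
            all_specific["lineage"] = "unassigned"
            state.funnel["step4_assigned"] = {}
            state.funnel["step5_final"] = {}
            return ComparativePanelResults(self, all_specific, state, mode)

        hominin_maps = {g: core[g].recon for g in HOMININ_GROUPS}
        labels = [
            assign_lineage(row, hominin_maps, outgroup.methylation,
                           row["specific_to"], min_shared=min_shared_outgroup)
            for _, row in all_specific.iterrows()
        ]
        all_specific["lineage"] = labels
        assigned = all_specific[
            ~all_specific["lineage"].isin(["inconclusive", "no_outgroup_data"])
        ].copy()
        # direction is stored relative to the hominin the DMR is specific to;
        # for archaic-ancestor changes the derived side is the other one
        flip = (assigned["specific_to"] == "AMH") & (assigned["lineage"] == "archaic")
        assigned.loc[flip, "direction"] = assigned.loc[flip, "direction"].map(_FLIP)
        state.funnel["step4_assigned"] = assigned["lineage"].value_counts().to_dict()
        state.funnel["step4_discarded"] = (
            all_specific["lineage"].value_counts()
            .reindex(["inconclusive", "no_outgroup_data"], fill_value=0).to_dict()
        )

        keep = [
            variability_filter(row, self.panel, row["lineage"], mode=mode,
                               reconstructions=recon_by_id)
            for _, row in assigned.iterrows()
        ]
        final = assigned[np.asarray(keep, bool)].reset_index(drop=True)
        state.funnel["step5_final"] = final["lineage"].value_counts().to_dict()
        return ComparativePanelResults(self, final, state, mode)


class ComparativePanelResults:
    """Labeled DMR set plus the per-step funnel of a fitted panel model."""

    def __init__(self, model: ComparativePanelModel, dmrs: pd.DataFrame,
                 state: PipelineFit, mode: str):
        self.model = model
        self.dmrs = dmrs.sort_values(["chrom", "start"]).reset_index(drop=True)
        self.funnel = state.funnel
        self.calibrations = state.calibrations
        self.pairwise = state.pairwise
        self.mode = mode

    @property
    def n_dmrs(self) -> int:
        return len(self.dmrs)

    def summary(self) -> str:
        lines = [
            "Comparative methylome analysis",
            "==============================",
            f"filtering mode:     {self.mode}",
        ]
        for step, counts in self.funnel.items():
            pretty = ", ".join(f"{k}: {v}" for k, v in counts.items()) or "-"
            lines.append(f"{step:<18}  {pretty}")
        lines.append(f"final DMRs:         {self.n_dmrs}")
        return "\n".join(lines)

    def to_bed(self, path, score_cap: float = 1000.0) -> None:
        d = self.dmrs
        if len(d):
            score = np.round(
                1000 * np.minimum(d["q_max"].to_numpy(float), score_cap) / score_cap
            ).astype(int)
        else:
            score = []
        bed = pd.DataFrame(
            {
                "chrom": d["chrom"], "start": d["start"], "end": d["end"],
                "name": d["lineage"] if "lineage" in d else "unassigned",
                "score": score,
                "strand": np.where(d["direction"] == "hyper", "+", "-") if len(d) else [],
                "n_cpgs": d["n_cpgs"],
                "direction": d["direction"],
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)

    def plot_funnel(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        steps, totals = [], []
        for step, counts in self.funnel.items():
            if not step.endswith(("pairwise", "specific", "assigned", "final")):
                continue
            steps.append(step)
            totals.append(sum(counts.values()))
        ax.bar(range(len(steps)), totals)
        ax.set_xticks(range(len(steps)), steps, rotation=30, ha="right")
        ax.set_ylabel("DMR count")
        return ax


def run_pipeline(
    panel: SamplePanel,
    detector_params: DetectorParams | None = None,
    recon_params: ReconstructionParams | None = None,
    mode: str = "wgbs",
    seed: int = 0,
    calibrate: bool = True,
    n_sims: int = 100,
    target_fdr: float = 0.05,
) -> ComparativePanelResults:
    """One-call wrapper over :class:`ComparativePanelModel`."""
    model = ComparativePanelModel(panel, detector_params, recon_params)
    return model.fit(seed=seed, calibrate=calibrate, n_sims=n_sims,
                     target_fdr=target_fdr, mode=mode)
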