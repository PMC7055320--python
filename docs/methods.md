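# Methods

This note documents the statistical model behind `paleomethyl`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## The deamination model

In UDG-treated ancient DNA libraries, methylated cytosines in CpG context
deaminate post mortem to thymines while unmethylated cytosines are
excised. At CpG i with coverage n_i and true methylation ψ_i ∈ [0, 1],
the thymine read count is modelled as

    t_i ~ Binomial(n_i, π · ψ_i),

with π the deamination rate, assumed constant along the genome. π is a
property of the sample (age, preservation); values around 0.02–0.08 are
typical, with coverage 20–50× for the genomes this analysis targets.
Because π·ψ is a few percent at most, single CpGs are nearly
uninformative and all inference pools across sites.

## Reconstruction

1. **Pre-mortem filters.** Sites whose C→T signal plausibly predates
   death are removed: (i) more A+G than C+T reads (germline variant),
   (ii) for single-stranded libraries, an opposite-strand G→A ratio above
   one sequencing error per position, (iii) C→T ratio above a cap
   (default 0.25; 0.5 for low-coverage samples, where a single read moves
   the ratio a lot), (iv) coverage above 100 reads (suspected PCR
   duplicates). Filters whose auxiliary columns are absent are skipped
   with a warning and counted in the filter tally.
2. **Smoothing.** The ratio is smoothed over a centered sliding window of
   25 consecutive CpGs (50 for low-coverage samples), truncated at
   chromosome ends and never crossing chromosomes. Windows pool counts
   (Σt/Σn) rather than averaging per-site ratios: under a shared binomial
   rate this is the minimum-variance estimate and weights sites by
   coverage. A ratio-averaging mode exists for sensitivity checks. The
   choice matters only where coverage varies strongly within a window.
3. **Linear transformation.** Methylation = min(ratio / μ₁₀₀, 1), where
   μ₁₀₀ is the pooled C→T ratio at reference positions whose methylation
   is 1 — under the model, μ₁₀₀ = π. For teeth, with no matched modern
   reference, μ₁₀₀ = (1/0.75) × the genome-wide mean smoothed ratio,
   anchoring the genome mean at 75% methylation (the genome-wide mean of
   modern skeletal WGBS maps). The factor is computed as 1/0.75 exactly;
   the rounded 1.33 is accepted within tolerance.

Sites are selected for the μ₁₀₀/π estimate by *measured* reference
methylation equal to 1. Selecting by a relaxed cutoff (e.g. ≥ 0.95)
under-estimates π noticeably, because the conditional mean methylation of
the selected sites drops; the pipeline therefore uses the strict
definition and relaxes to 0.95 (with a warning) only when the reference
has no fully methylated sites at all.

## The detector

For a test sample's counts (t_i, n_i) scanned against a reference
methylome φ_i, the per-site log-likelihood ratio for hypermethylation by
at least Δ is

    ℓ⁺_i = log Pr(t_i | n_i, π(φ_i+Δ)) − log Pr(t_i | n_i, π·φ_i),

and symmetrically ℓ⁻ with φ_i−Δ. Both are exact binomial log-pmf
differences (the binomial coefficient cancels). Under the null
(ψ_i = φ_i) the expectation of ℓ is negative; inside a true DMR it is
positive, so the one-sided cumulative sum

    Q_0 = 0,  Q_i = max(Q_{i−1} + ℓ_i, 0)

hovers near zero outside DMRs and climbs inside them. Every maximal run
of Q > 0 yields one candidate spanning CpGs a..m, where m is the
(leftmost) peak of the run; the candidate's score is Q_m and its genomic
interval is [pos_a, pos_m + 1). Candidates with fewer than 50 CpGs
(twice the smoothing window) are removed; Q is forced to zero at any site
more than δ = 1000 nt from its predecessor, so no DMR bridges assembly
gaps or CpG deserts. Defaults are Δ = 0.5 (a substantial, "switch-like"
methylation change), min 50 CpGs, δ = 1000 nt.

The reference φ is the *smoothed* reconstructed (or measured) methylation
of the reference sample; the test enters as *raw* filtered counts,
because the binomial statistic is defined on counts and smoothing them
would break the model. φ is clipped to [0.01, 0.99] so both branches stay
finite; the clip bounds any single site's influence.

**Infeasible sites.** Where φ+Δ > 1 the hypermethylation alternative does
not exist (symmetrically φ−Δ < 0 for ℓ⁻). Such sites cannot belong to a
Δ-sized DMR. ℓ returns 0 there, and a run of ≥ 5 consecutive infeasible
sites resets Q exactly like the gap rule. The run threshold matters: with
Δ = 0.5 most of a ~75%-methylated genome is infeasible for the hyper
branch, and letting Q merely coast (contribute 0) across such stretches
lets excursions bridge genuinely distinct DMRs tens of kb apart and lets
noise spans meet the 50-CpG minimum without evidence; resetting at every
single infeasible site, conversely, fragments genuine excursions whenever
reference noise wobbles across the eligibility boundary. Short infeasible
runs are treated as that boundary noise; long runs as genuinely
infeasible regions.

Power is asymmetric by construction: observed T's add evidence in the
hyper branch but mostly subtract it in the hypo branch, so
hypermethylation of the test sample is easier to detect at equal Δ. This
shows up in the recovery experiments as slightly lower sensitivity for
planted hypomethylation.

A separate detector serves WGBS-vs-WGBS comparisons (e.g. chimpanzee vs
modern human maps): sliding 25-CpG windows, Fisher's exact test on summed
methylated/unmethylated read counts, Benjamini–Hochberg control at 0.05,
a mean-difference filter at Δ = 0.5, and merging of surviving overlapping
windows per direction.

## Empirical FDR calibration

Reconstruction noise — binomial sampling, the sliding window, uneven
depth — produces spurious excursions. To bound them, noise-only
deamination maps are simulated from the reference itself: the reference
methylome is treated as truth, coverage is copied from the test sample,
t_i is redrawn from the binomial model, and the simulated map is pushed
through the identical filters and detector. Every DMR found there is
noise. The thresholds Q_T⁺/Q_T⁻ are the smallest observed real peak
scores at which

    mean simulated DMR count / real DMR count < 0.05,

scanned over the sorted peak scores of the real comparison (the empirical
FDR is a step function of the threshold on exactly that grid), separately
per direction and per directed comparison. 100 simulations per comparison
is the default; the threshold estimate is stable well below that (the
test suite checks that doubling the count moves thresholds by at most one
grid step). When no threshold achieves the target the threshold is +inf —
zero DMRs pass, the safe failure mode. A companion check scans each
deamination map against its own reconstruction, where every hit is noise;
this stays at or near zero — at most ~1% of a genuine between-sample
count at the same thresholds.

## The comparative pipeline

Five steps, run by `ComparativePanelModel.fit`:

1. **Reciprocal two-way comparisons** among the three reconstructed
   hominin samples (AMH, Neanderthal, Denisovan). Each pair is scanned
   twice — each sample's counts against the other's reconstruction — so
   reconstruction bias cannot systematically favour one side. The two
   runs are union-merged per direction; provenance records which
   sample's counts support each region. A region found in only one run
   is kept and flagged: reciprocity is bias control, the stringency
   comes from step 2.
2. **Three-way intersection.** A region specific to hominin 1 must
   appear in both the 1-vs-2 and 1-vs-3 lists with agreeing direction;
   only the overlapping portion is kept (scored by the smaller Q_m,
   re-checked against the 50-CpG minimum). Additionally, the combined
   evidence must come from at least two distinct samples' counts. The
   two lists share hominin 1's counts, so a count-noise excursion in
   that single sample survives the intersection with high probability;
   a genuine difference is also visible — if weakly — from the other
   samples' counts, so corroboration is assessed on a relaxed scan
   (half the score threshold, half the CpG minimum). This was the
   dominant residual false-call mode in development and the support
   requirement removes it at a small sensitivity cost.
3. **FDR thresholds** (from the calibration above) are applied during
   detection.
4. **Lineage assignment.** The chimpanzee WGBS map polarizes each DMR
   through the distance d_{H,C} = mean |ψ_i^H − ψ_i^C| over CpGs shared
   between hominin H's map and the chimpanzee's (at least 10 shared CpGs,
   else the DMR is discarded as having no outgroup data). For an
   AMH-specific DMR: both archaics closer to the chimpanzee → the change
   arose on the AMH branch; AMH closer than both → on the
   Neanderthal–Denisovan ancestor branch; anything else (ties included)
   is inconclusive and discarded. Neanderthal-/Denisovan-specific DMRs
   require both other hominins closer to the chimpanzee.
5. **Within-group variability filter.** A DMR is kept as fixed only if
   every sample of the derived group lies strictly outside the
   methylation range of all other samples, on the side its direction
   dictates (ties discard — conservative). All panel samples
   participate: reconstructed maps (including low-coverage filter-only
   samples scanned with the 50-CpG window), WGBS maps, and — in strict
   mode — array samples, whose probe means are corrected for probe
   placement by m′ = min(m · r, 1), r being the ratio of the reference
   full-map mean over all DMR CpGs to its mean over the probed CpGs
   (means, not raw sums, so that representative probes leave m
   unchanged). Strict mode only adds range constraints, so its result
   set is a subset of the WGBS-only mode's.

Funnel counts are recorded at every step; `summary()` prints them.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
at a scale a workstation handles in seconds:

* **Positions**: geometric inter-CpG spacing, mean 100 nt, so ~2% of a
  chromosome's extent lies in gaps long enough to exercise the δ rule.
* **Baseline methylome**: a two-state Markov chain along CpGs — long
  hypermethylated runs (mean 124 CpGs, level 0.92) interleaved with
  short hypomethylated islands (mean 30 CpGs, level 0.05) — giving a
  genome-wide mean of ≈ 0.75, the typical skeletal WGBS mean. The state
  level is smoothed over a 15-CpG shore before per-site Beta draws
  (concentration 50), because real methylomes transition gradually over
  ~1 kb at island shores; instantaneous jumps are an artifact no real
  map has, and — because the detector scans raw counts against a
  smoothed reference — shared step edges would create correlated noise
  excursions in every comparison at once.
* **Planted DMRs**: non-overlapping spans (default 60 CpGs, Δ = 0.6,
  ≥150 CpGs apart) on one of four lineages — AMH, the
  Neanderthal–Denisovan ancestor ("archaic"), Neanderthal, Denisovan.
  Inside a span, every sample's baseline is pinned to an anchor (0.2 for
  hyper shifts, 0.8 for hypo) and the derived group is moved by Δ;
  the shared anchor plateau ramps linearly over 15 CpGs in the flanks,
  so the only sharp edge is the derived group's true DMR boundary.
  Shifts that would leave [0, 1] are clamped, with the effective Δ
  recorded in the truth table.
* **Within-group variability**: i.i.d. Gaussian noise on the logit scale
  per sample per site, sd 0.2 (≈ ±0.03 at methylation 0.2). No estimate
  of the true between-individual variance of skeletal methylomes
  exists in this setting; this is a free parameter chosen to be small
  but non-zero, not an estimate.
* **Measurement**: deamination counts with per-sample π (default 0.05)
  and negative-binomial coverage (mean 30, dispersion r = 5, so the
  100-read cap is occasionally exercised); WGBS maps as binomial read
  sampling at depth 30; array tracks as probe subsamples with optional
  noise and an optional bias toward unmethylated sites (the RRBS-like
  scenario).
* **Default panel**: three reconstructed hominins at coverage 30, a
  low-coverage (8×, 50-CpG window, 0.5 ratio cap) Neanderthal used only
  for variability filtering, two modern human WGBS maps and a chimpanzee
  WGBS outgroup — a scaled-down version of a realistic study design
  (deep archaic genomes, a shallow second Neanderthal, modern reference
  maps, one outgroup).

What the generator does **not** emulate: read-level artifacts (mapping,
sequencing error, strand effects, M-bias), non-CpG methylation,
tissue/sex/age covariate structure (the panel metadata carries them but
no effect is simulated), CpG-density covariation with methylation, and
regional correlation of within-group variability. Passing recovery tests
therefore demonstrate the statistical machinery under the model's own
assumptions — they do not certify performance against real ancient
libraries, where filter (i)/(ii) inputs, contamination and reference
bias add failure modes outside this model.

## Recovery performance

Under the standard study conditions (2 chromosomes × 20,000 CpGs,
coverage 30, π = 0.05, ten planted 60-CpG Δ = 0.6 DMRs per lineage,
calibration at 25 simulations per directed run, 20 replicate panels —
sizes chosen so the whole experiment runs in minutes on one CPU), the
full pipeline attains pooled sensitivity ≈ 0.90 with every lineage label
correct and no DMR reported outside a planted span. The binding
constraint on sensitivity is structural: a 60-CpG span, eroded by
reference smoothing at its edges and truncated at the excursion peak,
sits close to the 50-CpG minimum — exactly the regime the 25-CpG window
trades resolution for power in. Hypomethylated planted DMRs account for
most misses (the power asymmetry above).

## Numerical choices and degenerate inputs

* ℓ values are floored at −745 per site (the order of the smallest
  representable log-density); the floor only engages at genuinely
  impossible configurations, e.g. t > 0 when the alternative rate is 0.
* Zero-coverage sites carry ℓ = 0 and pass through pooling harmlessly.
* Q_m ties break to the leftmost peak; candidate DMRs are ordered by
  chromosome, then start.
* Excursions are computed segment-wise with a cumulative-sum/running-min
  identity, exactly equal to the per-site recursion.
* Permutation p-values use (1 + #{null ≥ observed}) / (1 + n_perm),
  bounded away from zero; matched placements resample until the decile
  bins of both GC content and CpG density match the original interval,
  relaxing (flagged) after 1000 retries.
* An empty intersection of test and reference sites, a panel without a
  reconstructed sample per hominin group, Δ outside (0, 1) and
  non-positive thresholds all raise immediately with field names.

## Known limitations

* The calibration bounds the *rate* of noise DMRs at 5% of the real
  count; it does not make individual calls probabilistic. No per-DMR
  significance is reported beyond Q_m.
* Lineage assignment assumes the four-taxon topology and a single
  outgroup map; incomplete lineage sorting and within-chimpanzee
  variation are not modelled.
* The variability filter's power scales with panel size; with few
  samples per group, fixation claims are weak (a known asymmetry: groups
  with many samples are filtered harder, and single-sample groups — the
  Denisovan here — cannot be filtered for their own within-group
  variation at all).
* The phenotype-direction binomial test exposes exact one-sided tails
  per phenotype set; combined statements over several sets are left to
  the caller, as there is more than one defensible pooling.
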