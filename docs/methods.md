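# Methods

## Upstream-input mapping

The mapping operates on two delimited-text tables: `edges`
(`pre_id, post_id, synapse_count[, post_site_class]`) and `neurons`
(`neuron_id, type_label, category, hemisphere, sez_associated`). The DAN
catalog is resolved from the annotation table by type-label prefix:
PAM02 (β′2a, 8 members), PAM06 (β′2m, 15), PAM05 (β′2p, 10), PAM08 (γ4,
26), PAM07 (γ4<γ1γ2, 5), PAM01 (γ5, 19), PAM15 (γ5β′2a, 3) — 86 DANs
with the standard catalog. Which PAM type carries which β′2 subtype
letter follows the hemibrain naming convention; only the per-type
member counts matter to any computation here.

A neuron is a USN when it has at least one dendritic synapse onto any
catalog DAN and its type label matches no exclusion pattern. The default
pattern list (`KC`, `PAM`, `PPL`, `APL`, `DPM`, `MBON05`, `MBON09`,
`MBON11`, prefix match) implements exactly the documented exclusion
classes and nothing more; neurons with empty type labels are retained as
candidates (with a logged count) since an unannotated neuron is not
evidence of an excluded class. Supplementary design choices:

- **Post-site class.** A plain edge table cannot re-derive a dendritic
  restriction, so edges of class `unknown` count as dendritic by
  default; `dendritic_only=True` (CLI `--dendritic-only`) drops them.
  Class `axonal` never counts. Self-loops and DAN→DAN edges are dropped
  before any computation.
- **Denominator.** Percentage dendritic input divides by the DAN's total
  input *from included USNs only*, so excluded classes neither appear as
  inputs nor inflate the denominator. Fractions per DAN then sum to 100
  (asserted at 1e-9 relative tolerance); a DAN with no included input
  yields an empty fraction list plus a warning, not an error.

## Clustering, ranking and specificity calls

Non-SEZ USNs are clustered by annotation type (empty labels become
singletons). SEZ-associated USNs are clustered by morphology:
caller-supplied numeric feature vectors (skeleton processing is out of
scope), Manhattan distance, average linkage, cut at a caller-chosen
dendrogram height; left-hemisphere vectors are mirrored by sign-flipping
the designated mediolateral axis column first. "Fine granularity" is not
quantified anywhere authoritative, so the default cut-height fallback
halves the height until no cluster exceeds 34 members, the largest
cluster size the reference data contains.

The cluster × DAN matrix sums member percentages, conserving column sums
at 100. Ranking by a DAN type selection (`all7` or `b2g4`) sums matrix
values over all DANs of the selected types and sorts descending;
**ties break by ascending cluster id** — a documented, stable, otherwise
arbitrary rule. Top-set overlap reports are computed on the
unthresholded rankings.

Connection calls use two nested thresholds, applied in this order:

1. **Edge threshold** τ (default 0.4 %): a cluster-to-DAN edge survives
   when its summed percentage is ≥ τ (boundary inclusive).
2. **Coverage** (default 0.2): a cluster is connected to a DAN *type*
   when surviving edges reach ≥ 20 % of that type's members (boundary
   inclusive; for PAM07's 5 members a single covered DAN suffices).

Exclusivity is evaluated over three compartment groups — β′2
(PAM02/05/06), γ4 (PAM08), γ5 (PAM01 and PAM15) — and γ4<γ1γ2 (PAM07)
connectivity is a separate boolean flag. Whether γ5β′2a counts toward γ5
is a judgement call (the type spans both compartments); it is included
by default and the grouping is a plain dict argument.

**Silhouette threshold scan.** The published account names only "the
silhouette method"; the concrete procedure here is: for each τ on the
grid 0.1–5.0 % (step 0.1, 50 points), binarise the matrix at τ,
represent each DAN by its binary upstream-connectivity profile over
clusters, and score the known DAN type labels by the mean silhouette
coefficient under Manhattan distance (scikit-learn's
`silhouette_score`). The selected threshold is the smallest grid value
attaining the maximum. A τ at which some DAN has an all-zero profile is
scored but flagged (selection still considers it); a grid that is
entirely flagged, or degenerate profiles that make the coefficient
undefined, fail loudly. A continuous-profile variant (`profile=
"continuous"`, values masked below τ) is available; binary is the
default because the scan's purpose is to pick a *binarisation* point.

**Heat map.** Rows (clusters) are divided by their row sum (an
alternative row-max normalisation is a flag), all-zero rows are left
unnormalised and flagged, and rows are ordered by the dendrogram leaf
order of Ward linkage on Manhattan distances. SciPy's `linkage` only
accepts Euclidean input for `method="ward"` when given raw observations,
so the linkage is computed from a precomputed condensed cityblock
distance matrix — the Lance–Williams Ward update on L1 distances,
matching R `hclust`'s behaviour on an arbitrary distance object. Columns
are DANs sorted by type, then id.

**Edge styling.** Display transparency is the affine map
`49 + 100·(p − 0.1)/(12.17 − 0.1)` clamped to [49, 149] pixel values;
weight is the percentage passed through. The 0.1 % anchor sits below the
0.4 % edge threshold by design: the map is anchored where the source
visualisation anchored it, and sub-threshold edges simply never reach
styling. The network export writes deterministic GraphML (nodes and
edges inserted in sorted order) with DAN type/subtype/group, cluster
connectivity class and flag, and per-edge percent/weight/transparency.

## Ratiometric trace analysis

Frames are acquired at 5.74 Hz by default. Times map to frame indices by
nearest-frame rounding; all windows are half-open `[start, end)`.
Processing order per fly and ROI: per-hemisphere ratio
R = signal/reference (hard error naming the first nonpositive reference
frame), frame-wise hemisphere mean (single hemisphere passes through,
flagged), then ΔR/R₀ per stimulus presentation with R₀ the mean of the
*averaged* trace over the 5 s before onset (10 s for the feeding-state
protocol — a per-protocol parameter). Normalising the averaged trace
rather than averaging normalised traces is deliberate and asserted by a
test; the two differ whenever hemispheres have unequal baselines.

Peaks are maxima over `[onset, onset + 20 s)`; shorter traces truncate
the window. Mean-difference curves use the classical pooled-variance
two-sided unpaired t interval per frame at 1 − α (default 0.95),
uncorrected for multiple comparisons, with a frame flagged significant
when its CI excludes zero; a Welch variant is available via
`equal_var=False`. Baseline signals divide the signal-channel mean over
60 s pre-onset by the matching background-ROI mean per hemisphere, then
average hemispheres.

## Behavioural indices

PI = (N_target − N_other)/total. Flies that enter neither arm are
excluded from the total by default (the counts come from flies
transferred out of the two choice tubes); `include_center=True` dilutes
the index instead. Reciprocal averaging is the arithmetic mean of two
same-kind indices. Pulse trains place the first pulse at t = 0 of the
stimulus period with onsets strictly below the period end, so a 60 s
period at 0.2 Hz contains ceil(60 × 0.2) = 12 pulses.

## Synthetic data

`synth_connectome` emulates the *structure* the mapping assumes: a
standard 86-DAN catalog; 105 planted USN clusters in five specificity
classes (40 β′2-exclusive, 8 γ4, 33 γ5, 10 shared β′2+γ4 only,
14 shared by all three — the class tallies of the reference input map);
cluster sizes 1–34 (geometric, p = 0.45, mostly 1–6 members); per-type
coverage drawn uniformly in [0.25, 1] of members, never below the 20 %
call boundary; log-normal synapse weights (μ = 2.5, σ = 0.8 on the log
scale, median ≈ 12 synapses); excluded-class distractors (Kenyon cells,
non-target PAMs, PPL, APL, DPM, MBONs) with real dendritic edges;
axonal-only partners; DAN→DAN edges; and optional background noise
(default: each USN × non-assigned DAN pair gains a 1–2-synapse edge of
`unknown` site class with probability 0.01).

Because percentages within one DAN are independent of every other DAN,
the generator enforces its own contract — every planted cluster-to-DAN
edge stays above a guard level (0.8 %, twice the display threshold) — by
a per-DAN closed-form floor: below-floor clusters are raised to exactly
the floor share of the diluted total; the below-floor set can only grow,
so the solve terminates, and a configuration whose floor demand exceeds
100 % errors out rather than silently violating the manifest.

Recovery on this generator's output is measured on the five specificity
classes. The γ4<γ1γ2 flag is additionally checked in the noise-free
setting only: PAM07 is innervated by a small minority of clusters
(10 % flag probability), so its total input base is small and
single-synapse noise edges can legitimately cross the 0.4 % threshold
there — a property of sparsely innervated types, reproduced rather than
patched away.

What the generator does **not** emulate: real morphology (type-label
clustering is exact by construction, so cluster-assignment noise is
absent), hemispheric asymmetry, distance-dependent connectivity,
heavy-tailed hub USNs, or the empirical ~20:1 USN-to-DAN convergence
(the synthetic pool is ~200–250 USNs for tractability; the convergence
ratio is reported, not matched). Passing recovery tests therefore shows
the pipeline's rules are implemented correctly and are robust to weak
background edges — not that the thresholds are optimal for real data.

`synth_traces` builds
`signal = B·(1 + r(t))·a(t) + ε`, `reference = B_ref·a(t) + ε`, with
r(t) a unit-peak double-exponential kernel (rise 0.5 s, decay 2 s)
scaled by amplitude (default 1.0 ΔR/R₀), a physiological-state
multiplier (starved 1.5, dehydrated 1.2, satiated 1.0) and a per-trial
adaptation factor ρ^k (default ρ = 0.8); a(t) is a shared multiplicative
artifact (default 10 % amplitude, 0.3 Hz sine); ε is white noise
(default σ = 0.5 intensity units on baselines of 100/50). The kernel's
analytic peak time and value give closed-form expected peaks for tests.
Not emulated: photobleaching, slow baseline drift, channel-specific
artifacts (which the ratio would *not* cancel), or sensor
nonlinearities.

`synth_arm_counts` draws the target-arm count from Binomial(n, p), so
the index estimates 2p − 1 with binomial standard error — the basis of
the consistency checks.

## Problem sizes and tolerances

Tests and the acceptance script run the full pipeline on the default
synthetic conditions (105 clusters, ~200–250 USNs, 86 DANs, ~30k edges;
seconds on one core). Brute-force oracles (hand-written silhouette,
per-frame t intervals, hand dendrograms) run on ≤ 20 × 20 matrices or
≤ 50-frame groups. Normalisation contracts are asserted at 1e-9
relative tolerance; kernel-peak checks allow half a frame of sampling
error; Monte-Carlo index checks use 100–200 seeded replicates.

## Known limitations

- Real-data counts can only be checked against a local connectome
  export (`data/hemibrain/`); the repository ships none.
- Morphology clustering consumes pre-computed feature vectors; skeleton
  processing and registration are out of scope.
- The silhouette scan concretises an under-specified procedure; the
  binary-profile default is one defensible reading, and the continuous
  variant is provided for sensitivity checks.
- Group statistics beyond the per-frame unpaired t-test (ANOVA, post
  hoc comparisons) are deliberately not implemented; peaks and indices
  are exported for external tools.
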