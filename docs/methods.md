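# Methods

## Data model and conventions

Epoched recordings are leads × trials × samples arrays at 1000 Hz with a
(−200, 700) ms half-open window around stimulus onset, each trial labelled
smiling, fearful or neutral. Coordinates are millimetres in a right-handed
space; time is milliseconds relative to onset; amplitudes are arbitrary
(microvolt-like) units. Only grey-matter leads enter any analysis; the
lead table's white-matter rows are retained solely for bookkeeping.

## Responsiveness: bin-wise tests with a run-length rule

Each trial's prestimulus mean over [−200, 0) ms is subtracted before
averaging (subtractive baseline correction; idempotent by construction).
The post-onset window [0, 700) ms is divided into 35 adjacent 20-ms bins.
For each bin, the per-trial bin mean minus that trial's baseline mean is
tested against zero with a two-sided one-sample (paired) *t*-test at
α = 0.05. A lead-condition pair is *responsive* only when some run of at
least `min_consecutive_bins` = 4 consecutive bins is significant.

The run-length rule is the pipeline's false-positive control. Under
independent per-bin tests at level p the exact flag probability is a
run-length functional of 35 Bernoulli(p) draws, computed here by dynamic
programming (`consecutive_run_null_rate`): 1.9 × 10⁻⁴ at p = 0.05 —
roughly 260× below the per-bin level. Two caveats are deliberate parts of
the model and are surfaced in tests rather than hidden:

- the 35 paired differences share each trial's baseline mean, giving a
  between-bin correlation of (1/200)/(1/20 + 1/200) = 1/11. For two-sided
  events the induced indicator correlation is O(ρ²) ≈ 0.8 %, so the iid
  enumeration remains the reference rate within Monte-Carlo error;
- 1/f ("pink") noise correlates neighbouring bins strongly and can
  inflate the flag rate well above the white-noise value. This mirrors
  real electrophysiological autocorrelation and is the reason
  selectivity is additionally gated on an interaction test.

A `pooled` variant (independent-samples *t*-test of bin means against
baseline means) is available behind a flag; the paired reading is the
default and the one used throughout.

## Selectivity: mixed Condition × Time ANOVA

For each contrast (smiling vs neutral, fearful vs neutral, smiling vs
fearful) a two-way ANOVA is run on per-trial bin means with factors
Condition and Time. Because smiling/fearful/neutral trials are distinct
events with no pairing across conditions, trials are treated as the
random unit: Condition is a between-trial factor and Time (35 bins) is
repeated within trials — a split-plot design, computed via
`pingouin.mixed_anova` and verified in the tests against a from-scratch
sums-of-squares implementation to 10⁻⁸. No sphericity correction is
applied by default (available as an option). A lead is *selective* when
the interaction is significant and at least one main effect is
significant; this compound criterion is conservative relative to α and is
only evaluated on leads already responsive in at least one emotional
condition, so selective ⊆ responsive holds at the pipeline level.
Planned per-bin contrasts (two-sample *t*-tests, uncorrected within the
planned-comparison frame) then localise the difference in time.

Degenerate designs (e.g. identical groups, zero within-cell variance)
yield undefined F ratios; the affected p-values are reported as 1, never
as spurious significance.

## Peak latency

The peak is the argmax of |iERP| over (0, 700] ms — polarity-free because
iERP polarity is reference-dependent — with ties resolved to the earliest
sample. Latencies are classed into {100, …, 500} ms families with
half-open bins [c − 50, c + 50); values below 50 ms fall into the 100-ms
class and values at or above 550 ms into the 500-ms class.

## Continuous surface maps

Geodesic distances are shortest paths on the mesh edge graph with
Euclidean edge lengths (Dijkstra), not exact polyhedral geodesics: the
edge-graph overestimate is a few percent on reasonable triangulations and
is immaterial under the soft kernel; an exact-geodesic backend could be
slotted in behind the same interface. Each node's disk is the set of
nodes within `map_radius_mm` = 10 mm, weighted by a unit-amplitude
logistic kernel with midpoint 7.5 mm and steepness 2 per mm, so nodes
within ~5 mm contribute maximally and those between 5 and 10 mm fade out.
The steepness is interpreted per millimetre; that reading reproduces the
intended "full weight inside 5 mm, graded to 10 mm" behaviour.

Each lead is represented by the 7 mesh nodes nearest its position (an
explicit assignment emitted by the generator; image-based assignments can
be supplied instead). Per node,

- density = (Σ weighted explored nodes / 7) / (π r²) in leads/cm², with
  r the nominal disk radius in cm. The radius defaults to 1 cm; sampling-
  density figures are sometimes drawn with a 2-cm disk, so the radius is
  a parameter rather than a constant.
- overall = 100 × (weighted responsive) / (weighted explored);
- relative = 100 × (weighted selective) / (weighted responsive).

Percentage maps are masked where the denominator weight is zero and
wherever the value falls below `map_threshold_pct` = 10 %, suppressing
sparsely responsive territory. "Responsive" for overall maps means
responsive in ≥ 1 emotional condition; "selective" for relative maps
means significant in the relevant contrast.

## Regional summaries and lateralization

Each lead inherits the majority region among its 7 nodes (ties broken by
the nearest node's region; leads with no labelled node are dropped from
regional tables only). Per region and hemisphere the significant-lead
percentage is kept exact internally and rounded half-away-from-zero for
display. A region is selected for connectivity analysis when significant
leads are ≥ 10 % of its recorded leads *and* number ≥ 4 — the flag is
monotone in added significant leads. Lateralization uses a 2 × 2
chi-squared on (significant, non-significant) × hemisphere; Yates
correction is off by default (the printed significance patterns reproduce
either way) and a zero expected cell raises an error advising an exact
test instead of returning a misleading statistic.

## Stimulation tabulation

Stimulation outcomes use a closed six-category vocabulary (sensorimotor,
interoceptive, emotional, language, unspecific subjective, unresponsive);
a body district (face/mouth, eye/neck, hand/arm) is required exactly for
sensorimotor records. The headline unresponsive percentage is derived as
stimulated − responsive over stimulated, rounded to an integer. Published
tallies of this kind can be internally inconsistent by one site between
the responsive and unresponsive counts; deriving the complement makes the
summary self-consistent by construction.

## Effective connectivity

Edges keep off-diagonal probabilities at or above `conn_threshold` = 0.5.
The boundary is inclusive by default (reported figures use "n ≥ 50 %"
phrasing even where accompanying text says "> 0.5"); `strict_gt` restores
the strict reading. Clustering is agglomerative over each region's row of
the probability matrix, with Euclidean distances that mask the two
self-connection entries of every pair, and average linkage. Distance and
linkage are configurable — the analysis is validated by planted-partition
recovery, not by a specific linkage — and a binarized variant (cluster
the thresholded matrix) exists but is not the default. The dendrogram
exports to Newick with height-difference branch lengths. Direction
comparison reports off-diagonal Pearson correlation, Jaccard agreement of
thresholded edge sets, and whether the afferent and efferent trees induce
the same flat partition at k = 4.

## Synthetic data: what it emulates and what it does not

Evoked responses are Gaussian bumps (amplitude, peak latency 100-500 ms,
FWHM width, polarity), zeroed before onset so baselines are clean; the
simplest waveform with a well-defined peak latency (a biphasic option is
deferred). Noise is white Gaussian plus an optional spectrally shaped 1/f
component that reproduces EEG-like autocorrelation. Trial counts default
to 54 per condition, matching a paradigm in which each stimulus class is
presented 54 times; whether repetitions count per image or per condition
is left as a parameter. Meshes come in three kinds: a collinear strip
(chained by explicit edges, since collinear nodes cannot carry
non-degenerate triangles — its purpose is exact chain-sum geodesics), a
flat triangulated grid, and a Fibonacci sphere triangulated by its convex
hull. Leads sit on mesh nodes with pairwise-disjoint 7-node footprints.
Connectivity matrices are block matrices (within/between probabilities,
clipped Gaussian noise). All generators are pure functions of their
parameters and an explicit integer seed.

What passing tests therefore show: the decision rules, kernels, counting
schemes and clustering recover known planted structure at realistic sizes
(54 trials, 5-σ effects, 0.8/0.1 block contrast). What they do not show:
robustness to artefacts, epileptiform activity, volume conduction,
re-referencing choices or real cortical geometry — none of which the
generators model.

## Problem sizes and numerical choices

Calibration experiments use 2000 null leads (flag rate vs the exact DP
rate, agreement band fixed a priori at four binomial standard errors),
100 planted-response replicates for power and peak-class recovery, and
100 planted 4-block matrices (9 regions shaped like the frontal/insular
ROI set) for cluster recovery. Tolerances: ANOVA vs sums-of-squares
oracle 10⁻⁸; chi-squared vs definition 10⁻¹⁰; geodesics vs all-paths
oracle 10⁻⁹; map values vs definitional recomputation 10⁻⁹. Argmax ties
take the earliest index; scipy's linkage resolves exact distance ties by
cluster index order, making the tree deterministic for a given matrix.

## Known limitations

- The mixed-design reading of the Condition factor is a modelling choice;
  a fully within-subject reading is impossible without cross-condition
  trial pairing.
- Edge-graph geodesics overestimate true surface distance on coarse
  meshes; use denser meshes or an exact backend if sub-millimetre
  fidelity matters.
- Regional pooling across hand-picked region groups (e.g. a functional
  area straddling several parcels) is supported by relabelling but no
  canonical grouping is encoded.
- The stimulation module tabulates; it does not model stimulation-
  threshold statistics or link outcomes to iERP selectivity beyond joint
  tables.
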