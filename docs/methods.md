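# Methods

## Model and assumptions

`labelseg` assigns relative copy-number states to tumor segment profiles
under two assumptions. First, most detected copy-number events are driven
by a predominant clone, so segments of one underlying state concentrate
around one logR value and the per-sample logR distribution is a mixture
of near-point masses. Second, the length–amplitude relationship of
somatic copy-number alterations: arm-scale (broad) events are low copy
changes while focal events can reach high amplitude. The first assumption
makes 1-D density clustering of logR meaningful; the second justifies
estimating low-level thresholds from *long* segments and high-level
thresholds from *short* segments, and guarding high-level calls against
the entire long-segment range.

The five states are defined relative to sample ploidy: `+2` = gain of
three or more copies, `+1` = gain of one or two, `0` = neutral, `-1` =
partial loss, `-2` = complete absence. The caller never estimates
absolute copy number, purity or ploidy; it only places four per-sample
thresholds on the logR axis.

## Pipeline and parameters

Segments covering ≥ 20 % of their chromosome (inclusive, relative to the
whole chromosome, not the arm) are long; the rest short. Parameters below
are the package defaults; all are exposed on `ClusterParams` /
`ThresholdParams` and as CLI flags.

| parameter | default | meaning |
|---|---|---|
| `minPts` | 1 | DBSCAN density minimum; 1 lets a single focal amplification form a cluster |
| `eps_init_long` / `eps_init_short` | 0.05 / 0.10 (logR) | starting DBSCAN radius per partition |
| `sd_cap_long` / `sd_cap_short` | 0.05 / 0.10 (logR) | variance control: ε is reduced by `eps_step` = 0.01 until every cluster SD is below the cap |
| `eps_floor` | 0.01 | adaptive-loop stop; below the step size, further shrinking is meaningless |
| `low_bound` | 0.15 | minimum distance of a low-level target's V from baseline (noise filter) |
| `dup_upper` / `del_lower` | 0.7 / −1.5 | window caps keeping high-level events out of the low-level targets |
| `sigma_mult` | 2 | sensitivity margin: low thresholds are V ∓ 2σ of the target cluster |
| `ratio_dup_const`, `ratio_dup_slope` | 2.2, 0.6 | amplification ratio cut (V−b)/s₁ ≥ 2.2 − 0.6·s₁ |
| `ratio_del_min` | 2 | deep-deletion ratio cut (b−V)/s₂ ≥ 2 |
| `guard_offset` | 0.01 | high thresholds exceed the long-segment range by this margin |
| `baseline_cov_start/floor/step` | 0.40 / 0.20 / 0.10 | genome-coverage requirement for the baseline cluster and its relaxation |
| `default_s1` / `default_s2` | 0.30 / 0.35 | stand-in low-level steps when a side has no low-level target; ≈ one-copy gain/loss at ~50 % purity |

Cluster SD is the population SD (0 for singletons). Long clusters are
ranked for target selection by cumulative raw bp length (ties: smaller
|V|); short clusters by V.

## Numerical choices and degenerate inputs

- **Baseline ties** (equal |V|): larger genome coverage wins, then
  smaller V. The coverage comparison carries a 1e-9 tolerance so the
  stepped-down bound (0.4 − 0.1 in floating point) cannot exclude a
  cluster sitting exactly on it.
- **Interactive baseline shift** (`baseline_shift = ±1`) moves the
  selection to the nearest qualifying cluster with larger/smaller V; if
  none qualifies the unshifted baseline is kept with a warning.
- **Disabled sides** are encoded as ±∞ thresholds, keeping label
  assignment a pure comparison; a sample with a single cluster gets all
  four sides disabled and labels everything `0`.
- **Ordering guard.** With the SD caps in force, V − 2σ cannot cross the
  baseline (2σ ≤ 0.10 < 0.15 ≤ V − b). If the adaptive loop bottoms out
  at `eps_floor` with SD above the cap, a crossing low-level threshold is
  clamped to the midpoint between baseline V and target V and flagged
  (`low_dup_threshold_clamped` / `low_del_…`), preserving the invariant
  T₋₂ ≤ T₋₁ < b < T₊₁ ≤ T₊₂.
- **Constant clusters** return their member value as feature value
  exactly (bypassing the weighted mean) so that a noise-free threshold
  V − 2·0 compares equal, not one ulp above, under the ≥ calling rule.
- **Exception paths** (always flagged in diagnostics, never silent):
  no long segments → pseudo-baseline from short clusters (minimal |V|,
  ties to larger cumulative length) and the long-segment guard is
  omitted; no baseline at the 20 % floor → pseudo-baseline over long
  clusters; a missing low-level target → `default_s1`/`default_s2` for
  the corresponding high-level side.
- **Sex chromosomes** are excluded from estimation by default (a
  hemizygous X would drag the baseline in male samples) but are still
  labeled; `include_sex=True` restores them.
- **Backends.** DBSCAN runs through scikit-learn on sorted values, which
  makes border-point attachment (minPts > 1) canonical and the whole
  assignment permutation-invariant; cluster ids are renumbered by
  ascending cluster mean. The OPTICS backend is an ordering cut at the
  same ε (DBSCAN-equivalent extraction; with minPts = 1 that is
  literally DBSCAN, and is computed as such). The HDBSCAN backend adds a
  post-extraction merge of value-adjacent clusters separated by ≤ 0.05
  (`hdbscan_selection_eps`): the excess-of-mass criterion otherwise
  splits one tight state into subclusters on small 1-D inputs, and
  states of interest differ by well over 0.05. With `uniform=True` one
  joint clustering is computed and re-split into long/short views
  sharing cluster ids.
- Points labeled noise by a backend (possible when minPts > 1) are
  excluded from feature values, ranking and target selection but are
  still labeled by the final thresholds; if *everything* is noise, a
  single catch-all cluster is formed and flagged.

## Synthetic data generator

`simulate` emulates the segment-level output of a segmentation pipeline
on an impure clonal tumor. Defaults: 22 chromosomes × 100 Mb; per sample
Poisson(4) broad events (uniform 20–100 % of a chromosome, copy number 1
or 3) and Poisson(3) focal events (1–10 Mb, copy number 0 or 5–8), placed
without overlap; the rest of the genome is neutral (cn = ploidy, default
2). Observed logR is the mixture-model expectation plus Gaussian noise
with SD `noise_sd / sqrt(max(1, norm_length × 1000))` — long segments
average more markers, hence tighter segment means; the floor keeps
arbitrarily small gap segments at finite noise. Presets: `moderate`
= 0.10, `high` = 0.25 base SD. A pure homozygous deletion (cn = 0 at
purity 1) has logR −∞ and is reported at a floor of −8. Optional
over-segmentation applies n random cuts genome-wide, pieces sharing the
truth but drawing independent noise. All randomness flows from one seed
through spawned per-sample streams.

What the generator does **not** emulate: subclonal events (an optional
fraction knob exists but is off by default — the caller's clonal
assumption would be violated by design), whole-genome doubling as an
event grammar, allele-specific signal (BAF), probe-level noise
correlation, wave artifacts, and platform-specific segmentation errors
beyond the over-segmentation knob. Passing tests on these cohorts
therefore demonstrate correctness of the threshold logic under the
method's own model assumptions, not performance on any particular real
platform.

## Evaluation

Per-sample scoring is one-vs-rest precision/recall/F1 per state;
macro-F1 averages over the states present in truth or prediction
(classes absent from both are excluded rather than scored 0, so a sample
without high-level events is not penalised for classes it cannot
contain; `strict_macro=True` scores all five). Segment-level counting is
the default; base-pair weighting is available. Cohort summaries are
unweighted across-sample means with per-sample distributions retained.
Bin frequencies report, per 1 Mb bin and SCNA class, the fraction of
samples with ≥ 1 overlapping segment of that class, raw (no background
filtering).

## Problem sizes in the shipped checks

The acceptance script and test suite use cohorts of 100–200 samples per
condition (500 profiles for the invariant sweep, 1000 random instances
for the clustering oracle), which gives sub-percent Monte-Carlo spread
on the reported means while keeping a full run in the tens of seconds.

## Known limitations

- Thresholds are per-sample; nothing is shared across samples, so
  systematic platform shifts are absorbed only via each sample's own
  baseline.
- Heavily over-segmented or very noisy profiles can leave no cluster
  covering 20 % of the genome; the pseudo-baseline fallback then hinges
  on the smallest-|V| cluster, which assumes the neutral state is at
  least present.
- A genome dominated by one altered state (e.g. near-complete
  aneuploidy) can make that state the baseline; the `baseline_shift`
  knob is the manual escape hatch.
- The default bounds (±0.15, 0.7, −1.5, ratio cuts) are empirical
  constants in logR space; profiles on a different scale (e.g. already
  ploidy-corrected) need adjusted bounds.
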