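# Methods

## Acquisition model

The simulator (`fimsopt.simulate`) is a deliberately minimal forward
model of direct-infusion Orbitrap acquisition, built around the one
mechanism that matters for scan-range optimization: AGC-limited ion
accumulation. For a scan range `[low, high)` the total transmitted flux
is

    Φ = Σ flux_i   over ions with m/z ∈ [low, high),

and the realized injection (accumulation) time is exactly

    t(Φ) = min(T_max, N_max / Φ),

with `N_max = 5×10⁶` ions (AGC target) and `T_max = 100 ms` by default.
An empty range accumulates for the full `T_max`.

**Reported intensity is the accumulated ion count** `flux · t`, not the
flux. The instrument's internal intensity normalization is not modelled;
accumulated counts are chosen for mechanistic transparency: shortening
`t` depresses every intensity in the range and pushes low-flux ions
below the detection floor, which is precisely the intensity-ordered
dropout that makes wide ranges lose features. A consequence worth
knowing: when the trap is AGC-limited (`t < T_max`), a uniform loss of
source flux is exactly compensated by a longer `t`, so accumulated
intensities are invariant — source suppression only bites once `t`
saturates at `T_max`.

Electrospray suppression is a separate, weaker term applied to *all*
fluxes regardless of the quadrupole setting: `flux_eff = flux / (1 +
κ·L)` with `L` the total load of the spray. The default `κ = 10⁻⁸`
(per ion/ms of load) makes a dominant spike excluded from the scan range
remove only a few percent of features — well under the ~25% empirical
ceiling observed for source suppression — while the same spike *inside*
the range removes the large majority through trap competition. No
droplet-physics realism is claimed; κ is a single tunable.

Measurement noise: multiplicative Gaussian intensity noise (CV 10% by
default, averaged over 3 micro scans) and Gaussian m/z error with σ =
1 ppm, so the 5 ppm grouping tolerance is exercised non-trivially.
Detection floor θ = 500 accumulated counts — deliberately below the
1000-unit median-intensity filter criterion, so detectability and the
filter remain distinct thresholds.

## Synthetic metabolome

`generate_metabolome` emulates the statistical structure of a serum-like
sample, not its chemistry:

* m/z density: truncated Gaussian mixture, 80% of compounds at
  N(500, 100) and 20% at N(1650, 300) over [70, 2500] — a dense low-mass
  region and a sparse high-mass tail, the regime in which equal-feature
  ranges beat uniform ones.
* Ion flux: log-uniform over 10^1.5–10^5 ions/ms (3.5 decades), so
  competition removes ions in intensity order.
* Each compound with k carbons (k estimated from mass at ~50% carbon by
  weight) emits a first ¹³C isotopologue at +1.0033554 m/z with relative
  flux 1−(1−0.0107)^k, and with probability 0.2 an adduct satellite
  ([M−H₂O−H]⁻ in negative mode, [M+Na]⁺ in positive) at 10–50% of the
  parent flux.
* 30 low-flux background contaminant ions (20–300 ions/ms) present in
  biological *and* blank injections; blanks contain nothing else.

`cohort_intensity_matrix` produces cross-sample profiles for clustering
and variability statistics directly from the ground truth: each compound
gets an independent per-sample log-normal abundance factor (σ = 0.8 in
log space) shared by all its ions, times per-ion measurement noise. This
bypasses per-sample acquisition simulation on purpose — correlation
clustering consumes only the co-variation structure, and the shortcut
makes a 250-compound × 30-sample cohort essentially instant.

What the generator does **not** emulate: real serum composition and
absolute feature counts (which depend on the actual matrix), in-source
fragments, multiply charged lipids, peak-shape/resolution effects, and
correlated biological covariation between different metabolites.
Passing tests therefore demonstrate the *mechanisms* (competition,
stitching, optimization gain, satellite clustering), not instrument-
grade performance numbers.

## Feature detection

Peaks from all injections are sorted by m/z and swept once; a peak opens
a new group when it is more than 5 ppm from the running median m/z of
the current group. This is deterministic, invariant to input row order,
and O(n log n); the reference m/z of a group is the median of its
members (robust to a single outlier centroid).

The four-criterion filter keeps a group iff

1. presence in ≥ ⌈0.9·n_bio⌉ biological injections (= 6 of 6 — the only
   reading of "90%" consistent with six replicates; the fraction is a
   parameter),
2. median biological intensity > 1000,
3. median biological intensity / max blank intensity > 4 (an all-zero
   blank is replaced by 1 intensity unit to keep the ratio defined),
4. RSD < 30%, computed as sample SD/mean × 100 over the biological
   injections in which the feature is present — absent injections count
   against presence, not precision.

## Scan-range optimizer

Boundaries live on the integer m/z grid of the feature histogram, with
half-open `[r_{j−1}, r_j)` ranges and the last range closed at β. The
strict inequality in `r_j = min{i : C_i > j·C_β/n}` is implemented
verbatim, including its asymmetric tie behaviour (eight unit bins split
4 ways as 3/2/2/1, not 2/2/2/2); a `tie_rule="balanced"` variant using ≥
is available, default off. Per-range counts are guaranteed within
±max_i(X_i) of the ideal C_β/n — equality up to bin granularity. An
infeasible n (boundaries would collide) raises an error reporting the
maximum feasible n rather than silently merging ranges.

Equal-TIC ranges reuse the same machinery with per-bin summed intensity
in place of feature counts. Exhaustive tiling clips its last window at β
(70–2500 at width 20 → 122 windows); injection planning chunks ranges
into consecutive groups of ≤ 8 scans per polarity per injection.

## Annotation, clustering, quantification

Annotation is level-2 (accurate mass only): [M+H]⁺ or [M−H]⁻ by
polarity, 5 ppm tolerance, all isobaric hits reported sorted by |ppm
error|, never arbitrated. An optional constant-ppm shift models the
internal-standard mass-accuracy correction (default 0 — whether to
correct before matching is a user decision). The sodium-adduct constant
is the theoretical Na−H difference (21.9819 Da); the commonly quoted
21.985 spacing is a rounding of measured values, and no attempt is made
to force agreement.

Clustering is greedy single-link: features in descending median
intensity (ties by row order), joining the first existing cluster with
*any* member correlated above 0.95 (Pearson, pairwise-complete over ≥
max(10, half the samples) co-detected samples — small overlaps produce
spuriously high correlations at this threshold). Iteration order and
the missing-value policy are parameters, since reasonable alternatives
exist.

Standard addition fits raw intensity against added concentration by OLS
and reports ĉ = a/b with the classical x-intercept propagation CI,
`s_x0 = (s/b)·sqrt(1/n + ȳ²/(b²·Sxx))`, times the t quantile; a Fieller
interval is available (`method="fieller"`) and agrees to within
Monte-Carlo error at well-determined slopes. Non-positive slopes are an
error — extrapolation is undefined. Estimates are scale-equivariant in
intensity.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng` seeds; fixed
  seed ⇒ bitwise-identical scan events.
* Deep tests use a noise-off configuration (CV = 0, m/z σ = 0), where
  the acquisition ordering optimized-8 > uniform-8 > single-range and
  the dominance of exhaustive stitching are deterministic consequences
  of `t(Φ)` monotonicity.
* Test problem sizes — 150–800 compounds, 6+6 injections, 30-sample
  cohorts, 500 Monte-Carlo replicates — were chosen as the smallest
  sizes at which the relevant effects are unambiguous.
* m/z values are serialized at 6 decimals (sub-0.01 ppm at m/z 100,
  below simulated measurement error); table round trips are exact at
  the serialized precision.

## Known limitations

* The optimizer equalizes *feature counts*, which is a proxy for flux;
  a range containing one enormous ion and few features still throttles
  itself. The equal-TIC mode exists precisely to explore that trade-off
  (and loses on feature yield, as expected).
* mzML reading covers the centroided-MS1 subset this toolkit consumes
  (scan window, polarity, injection time, 32/64-bit zlib/uncompressed
  arrays); mzXML goes through pyteomics. Vendor RAW files must be
  converted upstream.
* Only singly charged species are modelled and annotated; multiply
  charged lipids and charge-state deconvolution are out of scope.
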