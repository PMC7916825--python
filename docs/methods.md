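# Methods

## The model

A metabolite set is any grouping of LC–MS features: a metabolic pathway
(members given as molecular formulae), a molecular family from spectral
networking, or a Mass2Motif substructure (members given as feature ids).
For a set with mapped feature submatrix `X` (features × samples, row
standardised), the singular value decomposition

    X = U Σ Vᵀ

yields "metacompounds" (columns of `U`) and per-sample coefficients of
the leading metacompound: the first row of `Vᵀ`, a unit-norm vector `v`
of **activity-level (AL) scores**.  The AL score summarises how strongly
the set's dominant coordinated intensity pattern is expressed in each
sample.  Because the SVD is sign-blind, coordinated increases and
decreases both contribute; a pathway whose up- and downstream halves
move in opposite directions after an enzymatic lesion still yields a
coherent first component.

Group differences in activity are measured by a two-sample t-statistic
on the AL scores between the case and control factor groups.  Welch
(unequal variance) is the default flavour; pooled-variance is available.
The t-statistic is a descriptive ranking statistic here — its reference
distribution comes from permutation, not from a t distribution.

### Permutation null and GEV calibration

Sample labels are reshuffled once per permutation round and applied to
*all* sets jointly; each round contributes the minimum and maximum
t-statistic across sets.  The per-round maxima (and negated minima) are
modelled with maximum-likelihood generalised-extreme-value (GEV) fits
(`scipy.stats.genextreme`; our `shape` ξ equals scipy's `-c`).  The
two-sided p-value of a set with observed statistic `t` is

    p = min(1, 2·min( S_max(t), P_min(t) ))

with `S_max` the upper-tail survival of the maxima fit and
`P_min(t) = S(−t)` from the fit to negated minima.  Modelling the
extreme tails analytically is what allows p-values below the raw
permutation resolution `1/n_perm`; by default the result is clipped
only at machine epsilon (a `floor_at_resolution` flag restores the
conservative `1/(n_perm+1)` floor).

**Calibration caveat (deliberate).**  Because the reference distribution
is the per-round extreme over the whole collection of sets, this is a
familywise-style calibration: under a fully null dataset the typical
set's t sits far inside the extremes' bulk and its p-value is ~1.  Null
p-values are therefore *not* uniform on [0,1] — they are strongly
conservative (with 200 null sets, essentially all p-values equal 1).
This is intrinsic to calibrating against extremes and is the behaviour
of the published method as described; a `scope="per_set"` option
computes ordinary per-set empirical permutation p-values, which are
approximately uniform under the null but cannot go below `1/n_perm`.
Interpret the default p-values as corrected for the multiplicity of the
set collection, not as per-set marginal p-values.

With the standard 4 vs 4 design only C(8,4) = 70 distinct labelings
exist; rounds sample labelings with replacement and the library warns
once.  The GEV fits then smooth a 70-atom discrete distribution, which
is exactly the "occasional extreme permutation value" problem the
calibration addresses.

### Degenerate inputs

* All-constant activity vector → t undefined; the set is flagged
  `degenerate_al` and assigned p = 1.
* Zero-variance t denominator with non-zero mean difference → t is
  clamped to a ±1e6 sentinel and flagged `zero_variance_t`.
* GEV fit failure → empirical extreme-tail p-values, flagged
  `gev_fallback_empirical`.
* Sets mapping fewer than `min_set_size` (default 2; a single-feature
  set has a rank-1, pseudo-replicated SVD) are reported with reason
  rather than scored.

## Preprocessing

Missing peak intensities are encoded as 0 (blank/NA cells are coerced).
Imputation works per feature × factor-group block: an all-zero block
becomes a user-settable minimum intensity (default 5000, an arbitrary
instrument-count scale); partially-zero blocks take the mean of the
non-zero samples.  The operation is idempotent and never touches
observed values.

Optional normalisation log-transforms (natural log; the base cancels in
any downstream t-statistic) and standardises each feature row to zero
mean, unit variance (sample variance, n−1) **across all samples**.  An
alternative axis — standardising within each factor group — is exposed
behind a flag but documented as signal-destroying: centring a feature
within each group forces both group means to zero, so every
between-group statistic collapses.  We adopted the whole-row axis as
the default after observing exactly that collapse; it is also the
standardisation the PLAGE-style decomposition assumes.

Only (M+H)+ and (M−H)− adduct annotations are used when mapping
features to formulae, limiting false-positive identifications from
rarer ion forms.  Formula strings are compared verbatim after
whitespace stripping — no chemical canonicalisation is attempted, so
`C6H12O6` and an equivalent but differently-written formula would not
match.

## Comparators

*ORA*: per-feature Welch t-tests at `alpha_feature = 0.05` define the
differentially-expressed features; each set is tested with the
one-sided hypergeometric upper tail against the background of all
set-mapped features (a flag widens the background to all features).

*GSEA*: original formulation — signal-to-noise ranking metric (SD floored
at 0.2·|mean|), weighted running-sum enrichment score with weight
exponent 1, sample-label permutation of the metric.  The p-value is the
add-one-smoothed sign-conditional permutation fraction (observed ES
against same-sign permuted ES); a two-sided convention
(`#{|ES_perm| ≥ |ES_obs|}` over all permutations) is available behind a
flag.  The two differ by about 2× here and neither can resolve below a
few parts in 70 with a 4 vs 4 design — the observed labeling always
recurs among the 70 distinct permutations — which is why GSEA hovers at
the 0.05 threshold in the benchmark.

## Synthetic benchmark

The generator states a small two-condition experiment: 4 + 4 samples,
seven planted pathways of sizes {2, 4, 6, 10, 20, 40, 80} (162 features)
whose features all shift between groups, and 100 background pathways of
5–50 unique features with no effect.  Intensities are standard normal;
planted features add a mean shift Δ in the case group; all rows are
standardised before use.  One feature ↔ one synthetic formula, mapped
through a real annotation table so the full mapping path is exercised.

**Effect size.**  The benchmark's description fixes the design but not
Δ/σ ("clear block structure").  We calibrated once, before freezing the
tests, by sweeping Δ/σ ∈ {1.8, 2.0, 2.2, 2.5, 3.0, 4.0} at 40
replicates and comparing the three methods' 0%- and 100%-decoy median
true-pathway p-values with the published medians; Δ/σ = 2.2 brackets
them (ORA a few-fold below, the activity scorer a few-fold above) and
is the frozen default.  At this effect size the per-feature Welch power
at α = 0.05 is ≈ 0.7.  Δ is an explicit parameter of
`generate_base`.

**Perturbations.**  `add_decoys(level%)` appends
round-half-away-from-zero(level/100 × size) normally-distributed
non-changing features to each planted pathway (background pathways
untouched); `drop_features(p)` removes every feature independently with
probability p from the matrix and annotations, leaving set definitions
in place so emptied sets surface as unscoreable.  Both are
deterministic functions of the dataset seed and the level, so all
methods within a replicate see byte-identical inputs.

**What the generator does not emulate:** correlated noise between
features, heteroscedastic intensity-dependent variance, retention-time
structure, adduct ambiguity, set overlap (background sets are disjoint
by construction; planted features belong to exactly one pathway), and
non-normal intensity distributions.  A green benchmark test therefore
establishes method behaviour under idealised coordinated shifts and
clean annotations — not performance on real LC–MS data.

## Evaluation

Positives are sets with p strictly below α = 0.05; precision, recall
and F1 use the zero-denominator-→-0 convention.  The full-data
robustness protocol defines each method's truth as its own significant
sets on unperturbed data (α = 0.05; 0.25 for GSEA, whose permutation
p-values are coarse) and measures F1 after feature removal; it is
exercised on synthetic data because the original real dataset requires
an external accession and a bespoke processing pipeline.

## Reproducibility

Every stochastic step takes an explicit seed; benchmark replicate seeds
are derived deterministically from a base seed.  Output files are
byte-reproducible from their recorded config + seed (metadata sidecars
record both).  Tie-breaks in ranked tables are by set_id under a stable
sort.

## Known limitations

* The global-extremes p-values are conservative by construction (see
  above); they rank well but understate marginal significance for
  individual sets.
* With tiny designs the permutation space is exhausted quickly; the GEV
  smooths but cannot add information beyond the 70 labelings.
* Formula-level mapping cannot distinguish isomers; all features
  sharing a formula enter every set containing it.
* No FDR correction is applied to ranked lists; reported p-values are
  raw, as in the benchmark's α = 0.05 usage.
* In this idealised generator — one shared effect size, independent
  normal noise, clean annotations — per-feature t-tests are unusually
  powerful, so ORA attains higher F1 than the activity scorer even at
  high decoy levels (the benchmark driver computes this directly).  The
  activity scorer's advantage is its precision under noise (its
  precision stays ≈ 1.0 where ORA's drops) and its graceful ranking
  degradation; claims beyond that are not supported by the synthetic
  world.
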