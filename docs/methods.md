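# Methods

## Model

Each pesticide class (herbicide H, insecticide I, fungicide F) is
described by six independent one-dimensional desirability curves, one
per molecular descriptor (MW, LogP, HBA, HBD, RB, arR).  All curves
share one functional family, a right-skewed Gumbel-like peak

    f(x) = o + a * exp( -exp(-t) - t + 1 ),   t = (x - b) / c

with offset `o >= 0`, amplitude `a > 0`, mode `b` and width `c > 0`
(both in descriptor units).  `f` is unimodal with `f(b) = o + a`
exactly and decays to `o` in both tails; the left tail (double
exponential) falls much faster than the right (single exponential), so
the curve is right-skewed — a reasonable shape for descriptors such as
MW or RB whose empirical distributions have a short left and a long
right tail.  The desirability is `df(x) = max(f(x), 0) / (o + a)`,
clamped to [0, 1]; with the fitted `o >= 0` the clamp only ever acts at
numerical underflow.

The class score is the unweighted geometric mean of the six
desirabilities, zero if any desirability is zero.  This inherits the
Derringer–Suich properties: range [0, 1], growth as the balance of
properties improves, and a veto for any single unacceptable property.
QEP_max and QEP_avg fuse the three class scores by maximum and
arithmetic mean; QEP_avg <= QEP_max always.

Assumptions worth keeping in mind: descriptors enter independently (no
covariance between, say, MW and RB is modeled), the same curve family
must suit all 18 descriptor/class pairs, and the scores are ranking
indicators, not calibrated probabilities.

## Descriptors

* **MW** — average atomic masses (the conventional MW descriptor).
* **LogP** — Wildman–Crippen atom-contribution estimate.  The rule
  thresholds in the literature were calibrated against vendor models
  (MLogP, ClogP); a single open estimator is used for all scores and
  filters, which shifts absolute filter pass rates by the typical
  inter-model offset (roughly ±0.5 log units).  A descriptor-table
  column or `--logp-column` substitutes vendor values when available.
* **HBA / HBD** — toolkit Lipinski-style perception: amide nitrogens
  are not acceptors; each O-H/N-H-bearing atom counts once as a donor
  (urea: HBD = 2).  `hba_mode="no_count"` switches HBA to a plain N+O
  count.  Perception on edge-case heteroaromatics can deviate from
  other toolkits; the frozen fixture table pins this package's
  convention.
* **RB** — acyclic single bonds between non-terminal heavy atoms,
  amide C–N excluded (strict definition).
* **arR / arB** — aromatic rings in the SSSR; aromatic bonds counted
  once each, so fused systems share bonds (naphthalene: arR 2, arB 11).
  arB feeds only the Hao filter.

Input structures are normalized before descriptor computation: largest
organic fragment (salt stripping), charge neutralization where
chemically valid, canonicalization.  Salts are therefore scored as
their parent acids/bases — a documented choice, since scoring "as
drawn" is equally defensible.  Tautomer and stereochemistry
normalization are out of scope.

## Histograms and bin width

Continuous descriptors are binned at the width minimizing the
Shimazaki–Shinomoto (2007) cost `C(w) = (2*mean(k) - var(k)) / w^2`
(biased variance over bin counts), scanned over 100 widths log-spaced
in [range/100, range/2]; ties break toward the smaller width.  Count
descriptors use unit bins.  Bins are half-open, last bin closed,
anchored at the data minimum, so counts always total the sample size.
Absolute counts (not relative frequencies) are fitted; any overall
scaling is absorbed by the amplitude `a`.

## Curve fitting

Counts are regressed on bin centers by bounded nonlinear least squares
(sum of squared absolute errors; trust-region reflective with
`xtol = ftol = 1e-12`), bounds `o >= 0`, `a > 0`, `c > 0`.  `c` is kept
positive so the peak orientation is fixed; a sign flip would create a
degenerate mirror solution.  A deterministic multi-start scheme guards
against local minima: start 1 uses the heuristic `o = min count`,
`a = count range`, `b = modal bin center`, `c = count-weighted standard
deviation`; further starts (8 by default) perturb `b` and `c` by up to
±50% with a seeded RNG, and the lowest-SSE converged start wins.
Fewer than 5 bins (4 free parameters) is an error.

One fitting subtlety is specific to count descriptors whose mode sits
at zero (e.g. aromatic rings for insecticides): a half-peak truncated
at the domain edge leaves `(a, b)` unidentified along an exponential
ridge — the optimizer can push `b` far negative with an enormous
amplitude, crushing the desirability of the actual modal value.  Since
negative counts are structurally impossible, a zero-count bin at −1 is
prepended whenever a count descriptor's modal bin is its lowest bin at
zero; this anchors the peak near the edge without distorting any
interior-mode fit.  Narrow count distributions (< 5 unit bins) are
symmetrically padded with empty bins to keep the fit determined.

Scaling uses the analytic maximum `o + a` rather than a tabulated
per-fit maximum: it is exact, parameter-free, and attained at `x = b`
by construction.

## Synthetic populations

Because no public pesticide training set exists at the original scale,
the generator samples descriptor values independently per molecule by
rejection sampling from offset-free (`o = 0`) curves of the same family
(uniform envelope over `[b - 10c, b + 10c]`, height `o + a`; an
acceptance rate below 1% or an empty domain is a degenerate-spec
error).  The class shapes are fixed study conditions chosen to echo the
qualitative class contrasts — insecticides more lipophilic (LogP mode
4.5 vs 2.5/3.0), often non-aromatic (arR mode 0) and more flexible (RB
mode 6); fungicides more rigid (RB mode 2); all MW modes near 300 Da.
Count descriptors are rounded to integers and clamped at zero; MW is
kept positive.  Decoys are uniform over MW ∈ [50, 1200], LogP ∈
[−5, 12], HBA/RB ∈ [0, 25], HBD/arR ∈ [0, 10] — broad enough to
straddle every class mode, mirroring a 10× random background.
Aromatic-bond counts are derived from the sampled ring count by a
linearly-fused-ring convention (arB = 5·arR + 1 for arR ≥ 1) purely so
the Hao filter can run on synthetic tables.

What the generator does **not** emulate: inter-descriptor correlation,
real chemotype structure, multimodal or heavy-tailed empirical
distributions, and any structure–activity signal.  Passing tests
therefore demonstrate that the pipeline recovers what it assumes
(self-consistency, enrichment of the generating class over broad
decoys), not predictive power on real chemistry.

The packaged default profiles (`src/qepest/data/default_profiles.json`)
are fitted on these synthetic reference populations (n = 2000 per
class, fixed seeds) and are labeled accordingly: they demonstrate the
scorer end to end but carry no empirically calibrated coefficients.
User-supplied coefficient JSONs override them.

## Evaluation

ROC curves come from a descending-score threshold sweep; AUC from the
Mann–Whitney rank statistic with tied pairs crediting 1/2, which equals
the trapezoidal area under the curve.  Quantile cutoffs interpolate
linearly between order statistics.  The optimal-cutoff utility
maximizes Youden's J = TPR − FPR over observed scores (ties toward the
smaller threshold); it is an exploratory extension — continuous
likeness scores are meant for ranking, and any single qualitative
cutoff is discouraged.

## Problem sizes and numerical choices

The test suite and the acceptance script work at n = 2000 molecules
per class with 10× decoy sets (20000), the scale at which the fitted
profiles stabilize (disjoint-half profiles correlate > 0.95 on probe
scores) while the full pipeline still runs in seconds.  Curve
evaluation is numerically stable for |t| up to ~700 by clipping the
inner exponential; beyond that the tail underflows cleanly to `o`
(never overflow or NaN), which is what makes the exact-zero veto in
the geometric mean well defined.  Scores are reported with 4 decimals.

## Known limitations

* Coefficients are not numerically comparable to any vendor-fitted
  original; only the method is reproduced.
* LogP-dependent results shift with the chosen logP estimator.
* The synthetic study conditions are favorable by construction;
  enrichment AUCs near 1 reflect the separation between the generating
  shapes and uniform decoys, not expected real-world performance (on
  real patented-pesticide data, likeness scores of this family
  separate far more weakly).
* Charged species are scored as neutralized parents; no tautomer
  handling.
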