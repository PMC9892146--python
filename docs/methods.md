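# Methods

## Condition truth labels

Samples are labelled by the Biological Assessment Profile (BAP), a 0–10
multimetric index computed by the state monitoring program. `wavebio`
never computes BAP; it consumes the score as the reference truth. Banding:
non-impacted 7.5–10, slightly impacted 5.0–7.5, moderately impacted
2.5–5.0, severely impacted 0–2.5, with boundary scores resolving upward
(7.5 → non, 5.0 → slight, 2.5 → severe). The two-way grouping used for
evaluation cuts at BAP ≤ 5 = impaired, so a score of exactly 5.0 is
"slight" in the four-tier banding yet grouped as impaired; the package
follows the evaluation-table convention rather than the (mutually
inconsistent) prose variants of the source program's documentation.
Moderate and severe are pooled into a single "impaired" class everywhere
frequencies and priors are estimated, because severely impacted samples
are rare.

## Taxonomic resolution

All identifications collapse to family, except five clades volunteers
cannot reliably separate in the field: Pelecypoda, Hirudinea and
Turbellaria collapse to class, Amphipoda to order, and the genus
*Chironomus* (recognizable by red coloration) stays at genus while the
rest of Chironomidae remains at family. Matching is case-insensitive and
whitespace-trimmed with no fuzzy matching: a typo yields an explicit
unrecognized-taxon flag rather than a silent misassignment. The packaged
taxon dictionary covers the indicator taxa and common member families of
the five exception clades; any other input passes through at family rank
when a family name is available, since the resolution rules — not a
complete checklist — are what define the method. The reduction is
idempotent.

## Indicator selection

Within each reference pool (non-impacted samples only for the unimpaired
direction, to sharpen the contrast; moderate + severe samples for the
impaired direction) the package computes each taxon's occurrence frequency
(proportion of samples containing it — the method is presence-only, so
"more abundant" is read as occurrence frequency, never mean count) and its
contribution to within-pool Sørensen similarity. The Sørensen index
between two samples is 2C/(A+B); a taxon's contribution is defined here as
its share of the summed pairwise numerator:

    c_t = [ Σ_{pairs with t in both} 2/(|a|+|b|) ] / [ Σ_{pairs} 2|a∩b|/(|a|+|b|) ]

so contributions sum to 1 whenever any pair shares a taxon. This
pairwise-share definition is this package's construction (the field
literature names the quantity without defining it); an alternative reading
against a pooled category composite would weight rare taxa differently.
The computation is quadratic in pool size and implemented as dense matrix
products; pools of a few thousand samples take well under a second.

Selection rule: taxon *t* is an unimpaired indicator iff
freq(t | non-impacted pool) > freq(t | impaired pool) **and** its
contribution in the impaired pool is < 2% (`contribution_cutoff = 0.02`);
impaired indicators are the mirror image. Because the two frequency
conditions are strict inequalities in opposite directions, no taxon can
qualify for both directions and no tie-break is ever needed. No
minimum-difference or significance criterion is applied beyond the strict
inequality.

## Frequencies, priors, and the posterior

Class-conditional frequencies are exact containment proportions — zeros
included, no smoothing at estimation time — so the packaged table
reproduces the printed reference arithmetic exactly. Priors are the class
proportions of the training set (0.2857 / 0.5123 / 0.2020 for the packaged
406 / 728 / 287 composition).

The TPI posterior multiplies the prior of each class by the class
frequencies of every indicator taxon *present* in the sample, both
directions — the literal reading of "each indicator taxon found in the
sample" — and normalizes over the three classes. Absent taxa contribute
nothing (the presence-only contract). An empty product returns the priors.
A present taxon with zero frequency in a class zeroes that class's
posterior; if all three classes are zeroed the posterior is reported as
explicitly undefined (never a silent 0/0) and any threshold call becomes
"no conclusion". An optional additive-smoothing parameter
(f → (f + a)/(1 + 2a), default off) guards the all-zero case at the cost
of no longer reproducing the exact table arithmetic. Products run over at
most ~48 factors, so plain floating-point products are used (no log-space
needed; underflow is impossible at this scale).

Threshold comparisons are inclusive (≥) for both metrics, matching the
"minimum number" / "minimum probability" reading. Defaults: k = 6 for
PTIT (the program operating point) and 0.90 for TPI; the evaluation grids
are k ∈ {3,4,5,6,7} and probability ∈ {0.50, 0.70, 0.90, 0.95, 0.98}.

## Sweep evaluation

For a target direction at a given threshold: matching% = triggered
samples among the target truth class / size of that class;
type-1% = triggered samples of the *opposite* truth class / **all** test
samples. The asymmetric denominators are deliberate and follow the
reference evaluation design (an error rate per monitoring effort, an
efficiency per opportunity); "no conclusion" samples stay in the matching
denominator. Both columns are non-increasing in the threshold because the
trigger sets are nested; the sweep code asserts this. Report rounding:
matching to whole percent, type-1 to one decimal, half-up.

Trend summaries report the mean successive decrease of the matching column
and the maximum successive ratio of the type-1 column (steps from a zero
excluded) — the "each added indicator costs X points of efficiency and at
least halves the error rate" arithmetic.

Ranking for follow-up sorts by the impaired posterior descending, ties
broken by impaired-indicator count then sample id (stable and
deterministic); undefined posteriors sort last, flagged.

## Synthetic data and oracles

The generator draws each sample's class from configured proportions
(default: the packaged 406:728:287 training composition), then each
taxon's presence independently as Bernoulli(f_{taxon,class}) — exactly the
independence the naïve-Bayes posterior assumes. A pseudo-BAP is drawn
uniformly within the class's band (the slight band is open at 5.0 so the
two-way grouping round-trips) purely to exercise the banding code; it
carries no signal beyond the class. All randomness flows through one
seeded `numpy.random.default_rng` generator, making output byte-identical
across runs and platforms for a fixed seed.

Real communities are correlated, compositionally constrained by the
100-organism subsample, and contain many non-indicator taxa; the generator
emulates none of that by default. Consequently simulated sweep
percentages characterize the independence model, not any field data set,
and passing tests demonstrate internal consistency of the machinery — not
field performance. An optional background-taxa pool (class-independent
frequencies) and an optional fixed-size subsample mode (latent geometric
abundances, mean 5 per present taxon, hypergeometric subsample collapsed
back to presence/absence) let users probe those gaps explicitly; both are
off by default because the metrics consume presence only.

Under the model, the number of indicator taxa present is Poisson-binomial,
giving exact expressions computed by an O(n²) dynamic-programming
convolution (cross-checked against exhaustive enumeration in tests):

* PTIT sweep cells: matching = 100·(p_NI·T_NI + p_SL·T_SL)/(p_NI + p_SL)
  and type-1 = 100·p_IM·T_IM for the unimpaired direction (mirror for
  impaired), with T_c the tail P(count ≥ k) in class *c*. With the
  packaged parameters the analytic k = 6 operating point is matching
  ≈ 54% at type-1 ≈ 0.02% — the efficiency/error trade-off the
  six-indicator rule is built on.
* Sørensen contributions: the empirical pairwise statistic converges to
  c_t ∝ f_t² · E[2/(2 + S + S′)] with S, S′ independent Poisson-binomial
  counts of the other taxa; this closed form is the oracle for the
  indicator-selection recovery test. Note that in the 48-taxon packaged
  universe several genuinely directional taxa (e.g. Heptageniidae) exceed
  the 2% contribution screen in the opposing pool simply because the
  simulated community is small; in species-rich field data contributions
  are more dilute.

## Numerical and interface choices

* Quantiles: linear interpolation of order statistics at h = (n−1)p + 1
  (numpy's default), reported half-up at 2 decimals. The packaged
  frequency table's interquartile endpoints reproduce the reference
  summaries exactly under this convention; two of the medians land half a
  cent above the reference values (0.175 → 0.18 vs 0.17; 0.115 → 0.12 vs
  0.11), consistent with the reference having rounded from unrounded
  frequencies, so the package asserts only the IQR endpoints.
* Frequencies are validated to [0,1]; priors to simplex membership at
  1e-9; posterior normalization is checked at 1e-9 and order-invariance
  holds at 1e-12.
* Problem sizes for the simulation-based checks — 5000 samples for the
  sweep-vs-oracle agreement (three Monte-Carlo standard errors), 6000
  balanced samples for frequency recovery (99% exact binomial intervals,
  ≥95% of taxon × class cells) and selection recovery — were chosen so
  Monte-Carlo error is small against the decision margins while the whole
  suite stays interactive (~10 s).
* Degenerate inputs: empty taxa sets are valid samples (posterior =
  priors, PTIT no-conclusion); an empty training category, a pool smaller
  than two samples, or a sweep truth class with no members raise errors
  naming the offender; unlabelled test samples are excluded from sweeps
  with a logged count.

## Known limitations

* The independence assumption is the model's, not nature's; co-occurring
  indicator taxa make the TPI posterior overconfident on real data.
* The packaged parameters are regional (New York State streams, riffle
  kick samples, July–September index period); applying them elsewhere
  requires retraining via `select_indicators` / `estimate_frequencies` on
  local labelled data.
* Indicator selection near the 2% contribution cutoff is sensitive to
  community richness (see above); cutoffs should be re-examined when the
  taxon universe changes substantially.
* BAP itself, and its component metrics, are out of scope: truth labels
  must be supplied.
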