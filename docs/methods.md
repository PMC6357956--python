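# Methods

## Model

The analysis treats six obstetric conditions as life-saving indications for
caesarean section (CS): cord prolapse or fetal distress, major antepartum
haemorrhage, obstructed or prolonged labour, severe pre-eclampsia or
eclampsia, transverse/oblique lie or breech presentation, and uterine
rupture.  Six further categories (previous caesarean, previous fistula
repair, maternal request, other, no clear indication, no data) complete the
taxonomy; they are kept distinct for reporting but all count as
non-life-saving.

For a site with `N` deliveries in its catchment and `c_i` caesareans for
indication `i`, the *specific caesarean prevalence* is `p_i = c_i / N`.
The denominator is deliberately the whole catchment population — home
births included — because the question is whether the population's
life-saving need is covered, not how facilities behave.  A direct
consequence is that sites with many home births can show low `p_i` both
from true under-provision and from under-ascertainment; the analysis does
not attempt to separate the two (see Limitations).

A *reference band* per indication is the (p10, p25, p50, p75) vector of
`p_i` across published studies, each study weighted equally.  Provision is
classified per indication by inclusive comparison: `below_minimum` if
`p_i < p25`, `above_maximum` if `p_i ≥ p75`, otherwise `acceptable`.
Thresholds are compared with a relative tolerance of 1e-9 so that a
prevalence constructed to sit exactly on a band value classifies as at it;
no real data point is affected by the tolerance.

Derived site-level quantities:

* counts of indications at/above each percentile level (0–6 per level,
  non-increasing from p10 to p75);
* the life-saving/other decomposition: caesareans for the six indications
  versus all others, both over total deliveries (the two counts always sum
  to the caesarean total);
* per-indication shares of the caesareans themselves (denominator = number
  of procedures, used e.g. for the share of repeat caesareans).

Across a set of sites, `minimum_adequate_cs_rate` returns the smallest
overall CS prevalence among sites meeting at least `min_indications` of
the six p25 minima.  The default `min_indications = 3` encodes the reading
that meeting half the minima separates clearly under-served populations
from those approaching adequacy; it is an explicit keyword so analysts can
tighten it to 6 (full coverage) or relax it.  `band_sum_minimum` gives the
complementary literature-only floor: the sum of the six p25 values (4.34%
for the bundled bands).

## Percentile estimation

Percentiles use linear interpolation between order statistics, the k-th of
n placed at probability (k−1)/(n−1) (numpy's default quantile method).
Published reviews rarely state their estimator; this one is fixed here for
reproducibility, and the bundled band table is *not* recomputed from
per-study values (which were never published) but carries the published
percentiles verbatim: p10/p50 at one-decimal percent precision, p25/p75 at
two decimals.  The six p25 values sum to exactly 4.34% and the p75 values
to 17.66%.  The published one-decimal p50 values sum to 7.7% while the
source prints a 7.6% total, implying unprinted extra precision; the package
reports the sum of the printed per-indication values and notes the
0.1-point discrepancy here rather than adjusting any cell.

## Bundled MNHR site data and their reconciliation

The bundled registry is site-level: total deliveries, facility deliveries,
caesarean totals and the 12-category indication breakdown for the seven
MNHR research sites (Argentina, Guatemala, Nagpur, Belgaum, Pakistan,
Kenya, Zambia; 271 855 deliveries, 2010–13).  The published tables are not
fully mutually consistent, and the package resolves this with one rule:
**the life-saving counts and the life-saving/other split are authoritative;
the catch-all `other` category absorbs any residual.**  Concretely:

* The published per-indication breakdown and the published life-saving
  summary differ for Argentina (e.g. antepartum haemorrhage 68 vs 61,
  severe pre-eclampsia 378 vs 316); the life-saving summary values are
  used.  Both variants put Argentina at 5 of 6 p25 minima.
* The 12-category breakdown fails to sum to the printed caesarean total for
  Pakistan (by 3) and Zambia (by 101), whereas the life-saving + other
  split sums exactly for every site.  The bundled summaries therefore keep
  the published counts for the five specific non-life-saving categories and
  set `other = caesarean_total − everything else` (affected cells:
  Argentina 153 vs printed 173, Pakistan 41 vs 44, Zambia 104 vs 3).
* Three published derived cells are irreproducible from the same tables'
  own counts and thresholds — the entire above-p75 column, Argentina's
  above-p50 count, and a narrative "three of six" for Nagpur that
  contradicts the printed 4.  None of these is asserted anywhere; the
  recomputed values are reported instead.
* One site's obstructed-labour percentage is printed as "1%" for a count
  of 2 in 27 600 (clearly "<1%"); counts, not printed percentages, are
  always the source of truth.
* Display rounding is half-up at the stated precision; several published
  percentages are inconsistent with any single rounding rule, so no
  internal value ever depends on display rounding.

## Synthetic registry generator

`default_profiles()` turns the bundled site data into generative profiles:
delivery count, birth-location probabilities (hospital/clinic/home),
overall CS probability, the conditional indication distribution among
caesareans, and marginal rates for the four complications reported among
all deliveries (antepartum haemorrhage, obstructed/prolonged labour,
severe pre-eclampsia/eclampsia, malpresentation).

Sampling per delivery is two-stage: location is multinomial; among facility
births, caesarean is Bernoulli with probability
`p_caesarean / P(facility)`, so the marginal CS rate is preserved exactly
in expectation while caesareans occur only in facilities (a profile whose
CS probability exceeds its facility probability is rejected as
infeasible).  Indications are multinomial among caesareans.  A caesarean
with a life-saving indication always carries the matching complication
flag; all other records draw flags independently at a background rate
`max(0, (t − f) / (1 − f))` where `t` is the target marginal and
`f = p_caesarean · P(indication)` is the probability forced through the
indication channel.  The clip at zero matters only where the source tables
disagree (Argentina malpresentation: 295 caesareans for the indication but
only 205 reported complications), in which case the generated marginal
equals `f` rather than `t`.  No correlation structure beyond the
indication→complication link is modelled, because only marginals are
published.

Randomness: one mandatory global seed; each site draws from an independent
substream keyed on `(seed, crc32(site_id))`, so per-site output is
invariant to the order in which profiles are listed and identical seeds
give byte-identical registries.

What the generator does *not* emulate: cluster-level structure within
sites, covariate effects (age, parity, education) on CS probability,
correlated complications, under-reporting at high-home-birth sites, and
seasonal/temporal trends.  Tests that pass on synthetic data therefore
validate the pipeline's arithmetic and classification logic, not the
epidemiology of any real population.

## Numerical and testing choices

* All proportions are kept at full double precision; rounding is
  display-only (half-up, `decimal`-based to avoid float-tie surprises).
* The percentile engine is verified against an independent sort-and-
  interpolate oracle, exhaustively on small value grids and by randomised
  property tests.
* Generator calibration is checked at reduced size (n = 5 000 per site,
  200 seeds): empirical overall and indication-specific prevalences must
  lie within 3 binomial standard errors of the configured values for at
  least 99% of the pooled seed × site × quantity checks.  The criterion is
  pooled because indications with expected counts below ~1 at n = 5 000
  exceed a ±3·SE normal band more than 1% of the time by construction, so
  a per-quantity bound would test the normal approximation, not the
  generator.  The end-to-end classification test similarly skips
  site-indication pairs whose configured prevalence lies within 3 sampling
  standard errors of a band edge (e.g. Argentina's uterine rupture, 0.192%
  against a 0.20% minimum) — those are borderline by construction, and a
  single draw landing on either side is correct behaviour.
* Zero-caesarean sites produce complete reports (everything
  `below_minimum`) rather than errors: severely under-served sites are the
  central use case.  Zero total deliveries is an error, as no prevalence
  is defined.

## Limitations

* Reference bands inherit the heterogeneity of the underlying studies
  (settings, definitions, eras); no meta-analytic weighting or
  heterogeneity modelling is attempted, matching the equal-weight design.
* Indication labels come from clinician report without validation;
  cord prolapse and fetal distress, and the malpresentations, are fused
  categories and cannot be disentangled.
* The minimum adequate rate is the smallest *observed* adequate rate among
  supplied sites, not an extrapolated optimum, and it says nothing about
  mortality: no outcome association is modelled.
* Confidence intervals on prevalences are out of scope; with denominators
  of 10⁴–10⁵ the sampling error is small relative to the band widths, but
  for small registries users should treat near-threshold classifications
  as uncertain.
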