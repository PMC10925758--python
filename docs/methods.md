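# Methods

This note documents the models, estimators and numerical choices behind
`volerange`, what the synthetic-data generator does and does not emulate,
and the known limitations of both.

## The analysis chain

### Peeled-core MCP home ranges

A home range is estimated as a minimum convex polygon (MCP) over an
animal's radio-fixes. Raw 100 % MCPs are driven by the most extreme fixes,
so the *core* home range at inclusion percentage *p* retains only the
`k = floor(n·p/100)` fixes nearest a centre of activity and takes the hull
of those. Distance ties break toward the chronologically earlier fix so
peeling is deterministic and order-stable. Fewer than three distinct
retained fixes yield a degenerate polygon with area 0, flagged rather than
dropped; likewise animals with fewer than 28 total fixes (the conventional
minimum for a reliable MCP) are flagged `sufficient_fixes = False` and
excluded from population-level curves but never deleted.

**Harmonic-mean centre.** The centre of activity is the point minimising
the harmonic mean of distances to all fixes, evaluated on a 0.5 m grid over
the fixes' padded bounding box. Because the harmonic mean is dominated by
the shortest distances, this centre sits in the densest part of the fix
cloud — the intended behaviour for nest-anchored animals — and, for the
same reason, the raw objective is singular at the fixes themselves: without
regularisation the minimiser is always whichever grid node falls closest to
a fix. Distances are therefore floored at half the grid resolution
(0.25 m), the scale below which the evaluation grid cannot resolve location
anyway. The floor and resolution are arguments of
`harmonic_mean_center`. The centre is computed once from all fixes and
reused at every peel level (recomputing it between peels was tried and is
slightly worse at recovering planted pairs; the single computation is also
simpler and is the default contract).

**Choosing the inclusion percentage.** `core_inclusion_curve` averages
per-animal MCP areas over inclusion levels 100, 95, …, 25 %. The
conventional reading of such a curve is visual: the knee where outlying
excursions stop inflating the estimate. `select_core_percentage`
formalises this as the interior point lying farthest below the chord
joining the curve's endpoints (both axes scaled to [0, 1]; the standard
"kneedle" criterion), constrained to [30, 95]. A
maximum-second-difference variant is kept behind `method=
"second_difference"`, but note that mean MCP area is convex in the
inclusion percentage for unimodal fix clouds, so that variant pins to the
upper constraint on essentially any data and is not recommended. A flat
curve falls back to the conventional 75 % with a warning, and `pin`
overrides the procedure entirely. The pipeline default is a fixed 75 %
core (`AnalysisConfig.core_percent = 75`); pass `core_percent=None` to
select from the data.

### Encounter rates and mating tactics

All socio-spatial quantities are computed on the selected cores, per
enclosure. Directed overlap is `100·area(A∩B)/area(A)` via exact convex
clipping (shapely); a degenerate subject contributes 0. The pairwise
encounter rate multiplies the two directed overlaps (so it is symmetric
and zero unless *both* animals use shared space), and each animal's PER
row over the opposite sex is normalised to relative encounter rates (RER).
Animals whose PER row is all zero get an all-zero RER profile rather than
an undefined one; degenerate home ranges therefore still appear in every
denominator.

Classification: male *m* and female *f* are a resident pair iff
RER_m(f) ≥ 0.5 **and** RER_f(m) ≥ 0.5, boundary inclusive. Since RER rows
sum to one, the criterion can be met by two candidates only on an exact
0.5 tie, which resolves by larger raw PER and then smaller id; the pairing
is a partial matching by construction. Females are classified only
implicitly (their profiles supply the reciprocity check). Overlap counts
(same-sex, opposite-sex, total) count any individual whose core intersects
the male's in either direction above a configurable threshold (default:
any positive intersection); the partner of a resident male is excluded
from his opposite-sex count, since a bonded pair's near-total overlap is
not extra social exposure.

### Parentage

Mothers are known; candidates are the males of the embryo's enclosure.
Per-locus allele frequencies are estimated from the sampled adults with
add-one smoothing over the observed allele set; alleles seen only in an
embryo receive the single-pseudo-count floor so they cannot zero a
likelihood. The trio LOD sums, over loci typed in the whole trio,
`log P(embryo | mother, candidate) − log P(embryo | mother, random male)`
where each parental transmission follows Mendel with probability `1 − e`
and draws from the population frequencies with probability `e`
(`e = 1e-5` by default, the literal reading of an assumed error rate of
"0.001 %"; conventional parentage software often uses 0.01 — the value is
a config knob, and at the recovery rates reported below the choice is
immaterial). The best candidate is accepted iff its LOD gap over the
runner-up is Δ ≥ ln 2 ≈ 0.69 — i.e. at least twice as likely — and both
embryo and candidate are typed at ≥ 20 of the 41 loci. With a single
eligible candidate the gap is measured against the random-male null (the
LOD itself), the natural degenerate case of the same rule. Fidelity
tabulation: for each resident pair with ≥ 1 assigned embryo, the male is
IPF iff all embryos assigned to him were mothered by his partner, the
female IPF iff all her assigned embryos were sired by her partner; counts
split by male surgery group, with proportions over all reproductively
successful pairs. The doubly-extra-pair category is carried even when
empty.

### Exact tests and PCA

The resident/wanderer imbalance uses the exact two-tailed sign test
`p = min(1, 2·P(X ≥ max(a,b)))`, `X ~ Binomial(a+b, ½)`; tactic × surgery
independence uses two-sided Fisher's exact test (minimum-likelihood rule
with a `1 + 1e-7` relative slack for float ties; the reported statistic is
the sample odds ratio). Both are verified against full-enumeration oracles
for all tables with n ≤ 30. The PCA screen z-scores the per-male feature
table (core area, same-sex overlaps, non-partner opposite-sex overlaps,
number of mating partners, number of offspring sired, RER_PRIMARY,
RER_SECONDARY), eigendecomposes the correlation matrix, and flips each
component's sign so its largest-magnitude loading is positive — real-data
sign conventions are arbitrary and not reproducible. Loadings at
|λ| ≥ 0.4 are the reportable set. Zero-variance columns are dropped with a
warning. p-values are kept at full precision; rounding happens only at
presentation.

## The synthetic enclosure generator

The generator's defaults are the study design itself: 9 replicate
enclosures, each 10 females + 5 sham + 5 lesioned males, 36 fix slots per
animal (2/day × 18 days) in a 33 × 18 m arena, ~3 % of fixes lost, 41
microsatellite loci with up to 6 alleles each.

Movement is an isotropic bivariate normal mixture — the simplest model
that gives controllable MCP cores. Each female holds one nest centre
(uniform in the arena, ≥ 4 m from other nests); a resident male (drawn
with probability 0.72) shares his partner's nest exactly; a wanderer draws
each fix around one of 3 centres with σ = 9 m versus the residents' 3 m.
Draws are truncated to the arena by resampling (clipping would pile mass
on the walls). Coordinates are continuous; an optional snap-to-metre
switch emulates field recording precision but is off by default (the flag
grid was a recording aid, not a property of vole movement). The lesion
effect enters through exactly one dial, `lesion_wanderer_shrink`
(default 0.4): a lesioned wanderer's dispersion and centre count are
multiplied by it, contracting his space use toward the resident pattern;
at 1.0 lesioned and sham wanderers are statistically identical.

Genetics: allele frequencies are Dirichlet(1,…,1) per locus
(concentration configurable); adults are Hardy–Weinberg draws. Every
female carries a litter of `1 + Poisson(litter_size_mean − 1)` embryos
(mean 4, a typical vole litter). A paired female's litter is sired by her
partner except that, with probability `epf_rate` (default 0.36, the
fraction of pairs with any extra-pair fertilization in the motivating
field data), one guaranteed extra-pair embryo plus a Binomial(rest, 0.3)
extra are sired by a non-partner male sampled with weight proportional to
the Gaussian overlap of the true nest-centre distributions. An unpaired
female's litter is sired by the overlap-weighted male, with paired males
eligible only with probability `epf_rate` — a paired male siring such a
litter is itself an extra-pair event, so `epf_rate = 0` guarantees a
population with no extra-pair sires at all. Embryos inherit one allele
uniformly from each parent's pair (no mutation model); per-allele dropout
is available (default 0) for exercising the ≥ 20-typed-loci rule.

One master seed drives per-stage `SeedSequence` substreams, so a config
reproduces its dataset — and the written CSV files — byte-for-byte.

**What passing tests on this generator do and do not show.** The
generator reproduces the *structure* the analysis assumes (nest-anchored
unimodal residents, diffuse multimodal wanderers, Mendelian litters with
proximity-weighted extra-pair sires), not the field system: no
territorial avoidance or interaction between animals, no temporal
autocorrelation in fixes, no collar loss beyond uniform dropout, no
survival process, and Gaussian tails rather than genuine excursion
behaviour. Two visible consequences, measured with this package: (1) real
wanderers' ranges were reported comparable in size to residents' at this
density, whereas the σ = 9 m default makes synthetic wanderer cores
(~200–270 m²) blanket every female's core; the resulting dilution of
paired females' RER rows caps planted-tactic recovery near ~89 % (the
recovery losses are almost entirely paired females failing the 0.5
reciprocity bar, not males), slightly below the 90 % nominal target and
with the classified resident fraction (~66 %) a few points under the
planted 72 %. (2) The synthetic inclusion curves place the knee at
70–85 % depending on the seed, a band that brackets — but is wider
than — the 70–80 % reported for field curves, whose outlier structure is
sharper than Gaussian tails. Parentage recovery, by contrast, is
essentially perfect (≥ 99 % of assignments correct at default
informativeness), and degrades as loci become less informative, as it
should.

## File formats

- `fixes.csv`: `enclosure_id, animal_id, sex, surgery, day, session,
  x_m, y_m` (session AM/PM; missing fixes are absent rows).
- `adults.csv`: `animal_id, enclosure_id, sex, surgery,
  locus01_a … locus41_b`; `embryos.csv`: `embryo_id, enclosure_id,
  mother_id, true_sire_id, locus…` (the true-sire column exists only in
  simulated data). Missing allele calls are empty fields.
- `manifest.yaml`: full config echo + seed, for byte-identical
  regeneration.
- Outputs: `homeranges.csv` (+ WKT polygons in `homeranges.wkt`),
  `tactics.csv`, `rer_matrix.csv`, `parentage.csv`, `fidelity_table.csv`,
  `tests.csv`, `pca_loadings.csv`, `pca_scores.csv`, `report.md`.

## Problem sizes used in the shipped checks

The test-suite and acceptance script run at the study's own scale: single
enclosures (20 animals, ~700 fixes) for replicated properties (20 seeds
for tactic recovery and the lesion contrast, 10 for parentage recovery),
and one full nine-enclosure study (180 animals, ~6 300 fixes, ~350
embryos) for pipeline-level quantities. Geometry is verified against an
O(n³) hull oracle (≤ 60 points) and a 10⁶-sample Monte-Carlo area oracle
(200 polygon pairs); exact tests against full enumeration (tables to
n = 30); the trio LOD against exhaustive transmission-event enumeration
at 5 loci.

## Known limitations

- RER is purely areal: simultaneous proximity, timing and avoidance are
  invisible to it.
- The harmonic-mean centre estimator is intrinsically attracted to fix
  clumps; on 36-fix clouds its dispersion around the true activity centre
  is ~2 m, which is the dominant noise source in partner-overlap
  statistics.
- Mixed-effects modelling (enclosure random effects, post-hoc contrasts)
  is deliberately out of scope; `tactics.csv` is the tidy interface to
  external tools.
- The delta-acceptance rule is implemented as the operative decision
  criterion; simulation-calibrated confidence levels of dedicated
  parentage software are not re-implemented.
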