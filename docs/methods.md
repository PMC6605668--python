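# Methods

## Tetrad classification

For an interval between two linked heterozygous markers, a tetrad is scored
from the four spores' two-marker genotypes: PD (two spores of each parental
combination), NPD (two of each recombinant combination) or TT (one of each of
the four combinations). A tetrad is *unscorable* for an interval when any
spore is inviable or uncalled at either marker, or when either marker fails
to segregate 2:2. Tetrads with a gene conversion at an interval-defining
marker are therefore excluded from that interval's tally rather than
repaired; conversions are counted separately (below). Classification is
invariant under spore permutation, and swapping the parental labels at
exactly one marker exchanges PD and NPD while fixing TT — both properties are
enforced by tests.

Intervals that reference markers absent from a strain's map (some strains
carry fewer markers) are skipped with a logged warning rather than an error.

## Map distance and its uncertainty

The Perkins estimator corrects the single-crossover frequency for double
crossovers detectable as NPDs:

    cM = 100 · (TT/2 + 3·NPD) / n,    n = PD + TT + NPD.

It is exact under no chromatid interference when no tetrad carries more than
two crossovers in the interval; with a Poisson (interference-free) crossover
process it underestimates long intervals slightly because three-crossover
tetrads are under-corrected (the tests check the estimate against the exact
Poisson-mixture expectation in that regime, and against the configured truth
under strong interference, where multi-crossover tetrads are rare).

The standard error treats (PD, TT, NPD) as one multinomial draw. Because the
estimator is linear in the class counts, the delta-method variance

    SE = (100/√n) · √( fT/4 + 9·fN − (fT/2 + 3·fN)² )

is the exact sampling variance of the estimate under multinomial resampling;
a 10⁵-replicate multinomial bootstrap agrees within Monte-Carlo error (2%)
on every bundled count row.

## Crossover interference: the NPD ratio

Under no interference and no chromatid interference, the expected NPD
frequency implied by an observed tetratype frequency fT is (Papazian)

    fN_exp = ½ · [ 1 − fT − (1 − 3·fT/2)^(2/3) ].

The interference statistic is observed NPD divided by `n·fN_exp`. It is
reported as undefined ("n.d.") when no NPDs were observed or when fT ≥ 2/3
makes the expectation non-positive. Its standard error treats the observed
NPD count as Poisson: `√NPD / (n·fN_exp)`. The uncertainty convention used
by the original online tools behind the bundled tables is not documented;
the Poisson convention reproduces most of their printed SEs to the display
precision, and the regression tests freeze the exact set of cells where it
does not (together with a handful of cells in the source tables that are
arithmetically inconsistent with their own printed counts — e.g. a printed
51.0 cM where the printed counts give 50.947 under every rounding
convention). Those frozen exceptions are listed in `tests/test_linkage.py`.

## Reporting conventions

Matching standard spreadsheet practice in yeast linkage work:

* cM and SE are displayed to one decimal, NPD ratios and their SEs to two,
  percents of control as integers; halves round away from zero.
* Tetrad-based chromosome map totals are sums of the *display-rounded*
  interval values; random-spore chromosome totals are sums of the unrounded
  percents. These two conventions are what the bundled tables themselves
  follow (each reproduces its column; neither reproduces the other's).
* Percent-of-control values are ratios of display-rounded quantities.
* Whole-map comparisons between strains (`percent_of`) are restricted to the
  intervals scored in both strains, since some strains lack markers.

## Random-spore analysis

Recombinant fraction `100·r/t` for `r` recombinant colonies of `t` assessed,
with binomial SE `100·√((r/t)(1−r/t)/t)`; `t` is shared across intervals of
a strain (one pool of colonies scored for every interval).

## Gene conversion and viability summaries

Per-locus segregation in four-spore-viable tetrads is classed 2:2, 3:1, 1:3,
4:0 or 0:4 (P1:P2); 4:0/0:4 takes precedence by construction since the
classes are mutually exclusive. Runs of *adjacent* non-2:2 loci (consecutive
map order on the same chromosome, regardless of physical distance) are
merged into single conversion events; conversion-rate analyses retain only
four-spore-viable tetrads with at most two merged events. The event count
equals the number of maximal non-2:2 runs, which tests verify against an
independent run-finding oracle. Viability summaries report the distribution
of tetrads by number of viable spores and the overall spore-viability
percent; sporulation efficiency is the percent of cells forming 2-, 3- or
4-spore asci.

## Exact tests

`fisher_exact_two_tailed` uses the probability-mass definition of the
two-tailed P: with margins fixed, all admissible 2×2 tables whose
hypergeometric point probability does not exceed the observed table's are
summed. Point probabilities are computed in exact rational arithmetic
(`math.comb` over `Fraction`), so ties are resolved exactly rather than by
floating-point tolerance. `mann_whitney_two_tailed` uses the exact null
distribution of U (standard counting recurrence) for combined sample sizes
up to 20 without ties, and otherwise the normal approximation with tie and
continuity corrections. Tests check both against brute-force enumeration and
against an independent library implementation.

## The meiosis simulator

Crossovers on a bivalent are a renewal process on genetic distance: gaps are
Gamma with integer shape `m + 1` and mean 1/2 Morgan, i.e. the chiasma
process keeps every (m+1)-th event of a Poisson process of rate `2(m+1)` per
Morgan (the counting model of crossover interference). Events occur at rate
2 per Morgan on the bivalent, so per-chromatid recombination equals map
length. `m = 0` reduces exactly to a homogeneous Poisson process (no
interference); larger `m` under-disperses inter-crossover distances and
drives the NPD ratio below 1. By default the first gap is drawn from the
process's equilibrium (length-biased residual) distribution — a uniform
mixture of Gamma(j, ·), j = 1..m+1 — so the process is stationary along the
chromosome and free of origin-edge artifacts; an `origin`-anchored start is
available for comparison.

Each crossover involves one chromatid from each homolog, chosen uniformly
and independently (no chromatid interference). Chromatid labels refer to the
four slot positions of the pachytene bundle: a gamete is assembled by
following its centromere's slot rightward and switching to the partner slot
at each crossover involving its current slot. This construction guarantees
the classical marginals — exactly one crossover in an interval always yields
a tetratype, and P(TT | k crossovers) = (2/3)(1 − (−1/2)^k), so at m = 0 the
TT frequency is (2/3)(1 − e^(−3λ/2)) for a bivalent mean λ (verified at 10⁵
meioses).

Gene conversion is overlaid marker-locally and independently of crossover
placement (no co-conversion with crossovers — a deliberate simplification
sufficient for exercising segregation tallies): each locus converts with a
per-meiosis probability, to a class drawn from a 3:1/1:3/4:0/0:4 mixture,
implemented by overwriting one (3:1/1:3) or both (4:0/0:4) recipient spores'
calls. Spores are then independently inviable with probability
1 − viability, blanking their calls. A single seeded generator drives all
randomness; identical seeds give byte-identical output files.

### Default study conditions

The simulator defaults emulate the wild-type cross of the bundled study:
seven intervals over two chromosomes at the wild-type map lengths
(26.7, 20.1, 36.3, 22.9 cM on III; 39.2, 7.6, 29.5 cM on VIII), 675 tetrads
per dataset (the wild-type sample size), interference `m = 4` (a canonical
strong-interference setting for budding yeast, giving observed/expected NPD
well below 1 as in the wild-type rows), 98% spore viability and a 1%
per-locus conversion rate with mix (0.475, 0.475, 0.025, 0.025) — the
viability and conversion tables of the source are not machine-readable, so
these are field-typical values for a healthy wild-type background, chosen
once and fixed.

What the simulator does *not* model: obligate crossover assurance,
centromere-proximal interference gradients, chromatid interference,
co-conversion of crossover-adjacent markers, and any mechanistic coupling
between viability and genotype. Passing recovery tests therefore shows that
the estimators are correct under the counting model's assumptions, not that
real data satisfy those assumptions.

## Problem sizes used in the checks

Estimator-recovery checks run 100 simulated replicates of the wild-type
cross (675 tetrads each) per interference setting; closed-form simulator
checks use 10⁵ meioses; bootstrap SE checks use 10⁵ multinomial resamples
per count row; Fisher-test equivalence sweeps all 2×2 tables with total up
to ~12 exhaustively plus random tables with margins up to 30. These sizes
keep the full suite under a minute while leaving Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* The NPD-ratio SE convention of the original analysis tools is unknown; the
  Poisson convention here deviates by >0.01 on a frozen list of cells.
* Perkins map distances are mildly biased downward for long intervals under
  weak interference (a property of the estimator, not the implementation).
* Percent-of-control values for a few published cells differ by one display
  unit from any recomputation of the printed counts; they trace to the
  inconsistent printed cells documented in the regression tests.
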