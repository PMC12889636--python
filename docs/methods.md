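# Methods notes

## The carrier model

Each individual carries a two-state latent variable *C*; the observed
data are the recorded sexes and the parent-child structure, nothing else.
The two states encode the two competing explanations directly in the
conditional probability tables: *C* = 0 means offspring sex is a fair
coin and carrier status is not heritable beyond the de novo rate;
*C* = 1 means a carrier father's children are of the favored sex with
probability equal to the penetrance, and the state follows the relevant
sex chromosome.

Y mode (`male_bias_Y`): only males can carry. A carrier father's sons
inherit with probability 1−μ (μ = de novo rate); daughters never carry;
a non-carrier's sons gain the state with probability μ. Males without a
recorded father take the founder prior π; females and sex-unknown
individuals are pinned to *C* = 0 (a sex-unknown individual is never
silently assumed male).

X mode (`female_bias_X`): either sex can carry, capped at one copy (no
homozygote state — with π = 0.01 the homozygote mass is ~10⁻⁴ and the
paper-level model never needs it; this is an explicit approximation).
The paternal route reaches daughters only, the maternal route reaches
each child with probability ½(1−μ), and de novo gain adds μ. The three
acquisition routes combine as independent channels:

P(C_child = 1) = 1 − (1−p_pat)(1−p_mat)(1−μ)

This differs from quoting each channel separately by O(μ²) ≈ 10⁻¹²
terms; the enumeration oracle uses the identical formula, so the
cross-checks are exact. Distortion of offspring sex acts only through
fathers in both modes — a carrier mother transmits the chromosome but
does not skew her children's sexes, matching the biology of a distorter
acting in male gametogenesis.

Sex-unknown children contribute no sex evidence (their evidence term is
1) and count as non-favored for paternal transmission.

## Inference

Belief propagation runs on a factor graph with one factor per nuclear
family (children grouped by father in Y mode, by couple in X mode; an
absent parent contributes a fixed non-carrier channel). Messages sweep
from the deepest families to the founders and back, once per iteration;
convergence is declared when no posterior moves by more than `tol`
(default 10⁻⁹, `max_sweeps` 100). Grouping whole sibships into single
factors removes the short parent-couple loops that plague pairwise
formulations, so on non-inbred pedigrees the algorithm is exact and
stabilizes after one sweep (the second sweep only confirms it).

Inbreeding creates genuine cycles; the same sweeps then implement loopy
belief propagation. It converges in the cases we exercise (optionally
aided by `damping`) but its fixed point is an approximation — on a
deliberately incestuous 5-person test pedigree the X-mode marginals sit
~2×10⁻³ from the enumerated truth. Non-convergence is reported via the
`converged` flag rather than an exception, because permutation suites
must keep running.

All message and posterior arithmetic uses plain double precision with
per-message normalization; messages from forced-zero states (females in
Y mode) propagate exact zeros rather than small numbers.

## Parameter defaults and the sweep

Defaults are penetrance 0.90, founder prior 0.01, de novo rate 10⁻⁶,
null sex probability 0.5. The published sweep grid (14 penetrances ×
4 allele frequencies × 5 de novo rates) is exposed as constants; note
the grid's allele frequencies stop at 10⁻³ while the chosen default is
0.01 — we follow the stated chosen combination and keep the grid as
printed, without resolving that tension.

One behavior worth understanding: a lineage at 67% male is *less* likely
than a fair-coin lineage under penetrance 0.9 (every daughter costs a
factor 0.1/0.5). The carrier posterior for such a family peaks when the
penetrance tracks the observed proportion (≈ 0.66–0.70 for the focal
reconstruction). The sweep, which selects the combination maximizing the
top posterior, is therefore the discovery instrument; a single parameter
point is not.

## Permutation null

`permute_sexes` shuffles the exact multiset of sex labels over the fixed
topology (sex-unknowns shuffled along with the rest) and reloads the
result in permissive mode, so female labels can land in father roles.
All counting rules use strict ">" (count/N), so p = 0 is attainable; the
more common add-one convention is available via `add_one=True`. Rank
ties use competition (minimum) ranking.

Two caveats established while calibrating on synthetic nulls:

- With the focal individual defined as the true run's argmax, its true
  rank is 1 by construction and the rank-comparison p-value is
  identically 0 — that comparison is informative only when the focal
  individual is chosen independently (e.g., a suspected progenitor).
- Because females cannot carry in Y mode, a permuted pedigree has about
  half as many carrier-eligible fathers as a sex-consistent true
  pedigree, so its maximum posterior is stochastically smaller and the
  max-likelihood p-value is anti-conservative on real (strict) data.
  Calibration is clean when the null data are themselves an iid sex
  assignment over fixed topology (then true and permuted runs are
  exchangeable): measured over 200 such datasets with 99 permutations,
  p > 0.05 in 94.5% (max-likelihood) and 97% (z-max), with
  P(p ≤ 0.10) ≈ 0.13.

## TDT scan and family tests

The lineage statistic is the uncorrected 1-df chi-squared against equal
male and female counts (no Yates correction — the printed worked value
for 60:29, p = 0.00102, matches the uncorrected statistic).
Benjamini–Hochberg adjustment runs across lineages with strictly more
than 75 transmissions (the published arbitrary cutoff); smaller lineages
keep a raw p-value only. The confidence envelope uses exact binomial
quantiles at 0.005/0.995. The Monte Carlo family test randomizes the n
transmission sexes directly (not the whole internal family structure,
which is unpublished for the real family); extremeness is two-sided to
match the chi-squared test, with a one-sided option.

Patriline membership follows the father role: a child continues the
lineage if male or itself occupying a father role. On strict pedigrees
this is exactly the father→son chain; on permuted pedigrees it keeps
every lineage's transmission count invariant, which is what makes
permutation-based comparisons well defined.

## Synthetic data

The forward simulator emulates a stable historical population: founder
couples, Poisson family sizes (mean 2.5 by default, echoing large
historical families), spouses marrying in from outside (so pedigrees
are non-inbred trees), and an optional distorter planted in a founder
father whose offspring sexes follow the true penetrance (0.9 default)
and whose carrier state follows the mode's chromosome. Ground-truth
carrier labels default to zero de novo noise so truth chains are exact.
It does not model mortality, remarriage, migration, inbreeding (unless
loops are requested) or record-linkage error — a green calibration test
therefore speaks to the statistics on clean genealogies, not to
robustness against recording biases.

The focal-family fixture is a totals-matching reconstruction: the four
printed sibships are embedded exactly, and padding sibships (each no
more male-biased than the printed ones) bring the patriline to 33
transmitting fathers and 89 transmissions (60 male, 29 female) over
seven generations. The true family's internal structure beyond the
printed sibships is unpublished; only the totals and the printed
sub-sibships are faithful.

For distribution-level null checks of the TDT we use a fixed topology of
500 patrilines with 1024 transmissions each and draw iid fair-coin
sexes. The size is deliberate: chi-squared p-values on balanced
binomials live on a lattice whose CDF deviates from uniform by about
√(2/πn), so small lineages fail any Kolmogorov–Smirnov comparison no
matter how correct the code; 1024 transmissions put the lattice error
(~0.025) safely under the 1% KS critical value at 500 lineages (0.0728).

## Numerical and policy choices

- Missing parents are "0" or empty; both accepted, "0" written.
- "Above 40%" for clustering is strict (> 0.40), threshold configurable.
- Half-siblings are at distance 2, like full siblings — edges are
  counted, not shared parents.
- Cluster distances are measured in the full pedigree, so low-likelihood
  relatives can bridge two high-likelihood individuals.
- The z-normalization uses the population standard deviation of the
  run's posteriors (the run is the whole population, not a sample).
- All randomness flows from user-supplied integer seeds through numpy
  `SeedSequence` derivation; belief propagation itself is deterministic.

## Known limitations

- Loopy (inbred) pedigrees get approximate marginals; heavy inbreeding
  may need damping and still converge to a biased fixed point.
- Autosomal distorters are out of scope by design — without genotypes
  there is no signal to follow.
- The X mode cannot distinguish a female-biased distorter from an
  X-linked male-lethal; that ambiguity is inherent to sex-only data.
- Exact enumeration is limited to 20 individuals (2^n cost) and exists
  as a testing oracle, not an analysis path.
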