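# Methods

## The two-generation fitness model

A founder female of a gregarious idiobiont egg parasitoid distributes a
fixed load of eggs (pro-ovigeny) over the host eggs she accepts. Each
parasitized host receives a clutch of 1–7 offspring in any sex ratio —
with any sex split, 35 distinct clutch configurations. The host egg is
the entire larval food supply, so per-capita resources, adult body size
and finally a daughter's lifetime fertility fall with clutch size. The
package collapses that causal chain (clutch size → body size →
fertility) into the direct empirical mapping

    fertility(c) = round(base − √c),  base = 20,

rounded to the nearest integer, ties away from zero. A tie never occurs
at the defaults (√c is irrational for c = 2, 3, 5, 6, 7 and exact for
1, 4), but the rule is pinned so configurable variants (`base`,
`decay ∈ {sqrt, linear, none}`, `rounding`) stay deterministic. The
mapping is non-increasing and convex-decreasing on the support 1–7;
`max_clutch` above 7 is allowed but logged as extrapolation beyond the
observed biology.

A founder's projected F2 fertility is

    F2 = Σ over parasitized native hosts h: females(h) × fertility(size(h)),

so only emerged daughters count, each weighted by the fertility her
natal clutch size predicts. Eggs laid into "fictitious" hosts (a beetle
species accepted for oviposition but unable to support larval
development) consume the egg budget and contribute to eggs-laid, but to
neither F1 nor F2 fertility.

### What monotonicity does — and does not — imply

Any *refinement* of a clutch profile (splitting clutches so that every
daughter's natal clutch is weakly smaller, with total offspring and
female counts preserved) never decreases F2; this is tested on 1,000
random instances. The superficially similar statement "moving one
offspring from a larger clutch to a smaller one never lowers F2" is
false: the map is convex-decreasing, so the daughters in the receiving
clutch can lose more than the donors gain (e.g. clutches (4,0)+(2,2) →
(3,0)+(3,2) drops F2 from 2×19 to 2×18). The single-move form holds
when the receiving clutch carries no females, and that restricted form
is what the suite asserts.

### Group summaries

Per-offspring F2 fertility of a group is the ratio of sums (total F2 /
total emerged daughters), not the mean of per-founder ratios — it stays
defined when some founders emerge no daughters, and weights every
daughter equally. Percent differences between groups are printed in
both directions ((a−b)/b and (b−a)/a); when one group emerges no
daughters at all it is excluded with a warning.

## Offspring allocation and sex assignment

`allocate_offspring` distributes a given offspring total over at most
`n_hosts` hosts according to a clutch-size frequency distribution.

- *expected* mode is deterministic: the number of clutches is the total
  divided by the distribution's mean clutch (rounded), per-size clutch
  counts are frequency-proportional expectations rounded by largest
  remainder, and a canonical repair walk fixes any residual
  infeasibility — overshoot shaved off the largest clutches, undershoot
  added to the smallest, excess clutches merged smallest-first while the
  merge respects `max_clutch`. The repair is deterministic so expected
  mode is bit-reproducible and testable.
- *sampled* mode draws clutch sizes sequentially from the distribution
  truncated to the remaining total, restarting on dead ends (bounded at
  1,000 attempts, then falling back to expected mode with a warning).
  The induced law is therefore the sequential truncated-draw law
  conditioned on hitting the total exactly; the test suite checks
  sampled draws against that law enumerated by brute force, not against
  the naive product of frequencies. Without a seed, one is drawn from
  entropy and logged.

`assign_sexes` defaults to `p_female = 0.25`, the species' 3:1
male:female offspring ratio. Expected mode places
`round(p_female × total)` daughters one per clutch in descending
clutch-size order (ties by host order), wrapping; sampled mode is
independent binomial per clutch. The descending-order convention is one
of several defensible deterministic spreads; it is documented rather
than biologically claimed.

## The synthetic experiment generator

`generate_trials` emulates dish-level oviposition assays with the
layouts of the motivating study: three no-choice groups (12 native host
eggs on wheat / dock / filter paper, 20 founders each), a choice test
(4+4+4 eggs across the three substrates in one dish, 20 founders), and
a fictitious-host experiment (6 native + 6 fictitious eggs on dock,
n = 15, against 6-egg and 12-egg native controls, n = 11 and 19).
Per founder:

1. a dish intercept ~ Normal(0, `dish_sd`) shifts the parasitism logit —
   this is exactly the overdispersion a dish random factor absorbs, so
   the mixed models in the stats module are the correctly specified
   estimator;
2. each offered egg is parasitized independently at the logit-shifted
   substrate × host-species probability while the egg budget lasts;
3. clutch sizes are drawn from the substrate's distribution truncated
   to the remaining budget (truncate-and-renormalize — generator
   semantics, not biology; a budget below the distribution's smallest
   clutch ends laying);
4. sexes are binomial with `p_female`;
5. offspring emerge only from native hosts. For each fictitious egg the
   *host beetle's* own emergence is an independent Bernoulli — 0.22 if
   parasitized, 0.94 if an unparasitized control — decoupled from the
   parasitoid's fate. These two rates are the study's empirical values;
   they are the only generator defaults that are.

Defaults chosen as package conventions (the study's raw frequency
tables are not publicly deposited): parasitism probabilities 0.60 /
0.45 / 0.50 for native eggs on wheat / dock / paper and 0.35 for
fictitious eggs; clutch-size presets with mode 2–3, smaller on the
less-preferred substrates; `dish_sd = 0.5`; `egg_budget = 32`. The egg
budget in particular is a configurable package choice — the species'
true egg load is not printed in the source material. All presets are
plainly labelled synthetic and replaceable through the YAML config or
a user-supplied frequency CSV.

What the generator does *not* emulate: oviposition learning or
behavioural sequence effects (substrate preference enters only through
the static probabilities), within-dish spatial structure, founder
mortality, and host-quality variation beyond the substrate factor.
Passing calibration tests therefore show the estimators are correct
for this mechanism, not that the mechanism exhausts real dish data.

`recover_params` closes the loop with method-of-moments estimates:
per-cell parasitism with Clopper–Pearson 95% intervals, per-substrate
clutch means with t-intervals, pooled daughter proportion with its
Clopper–Pearson interval. Recovery calibration runs use `dish_sd = 0`
and an effectively unlimited egg budget so the estimands equal the
configured parameters exactly (with truncation active, the realized
clutch law is the truncated one by design).

## Statistical battery

Responses and families mirror the study's analysis grid: per-dish
offspring totals by LM; parasitism rate by binomial GLM; offspring sex
ratio by binomial GLMM; clutch size by Poisson GLMM on the shifted
response `clutch − 1` (clutch sizes are ≥ 1 by definition, so the shift
gives proper Poisson support; fitted means are shifted back for
reporting) or by Gaussian LMM. All mixed models use the dish (founder)
identity as a random intercept. Each factor is assessed by a
likelihood-ratio test against the nested model without it, χ² with
df = the parameter-count difference; numerically negative statistics
are clamped to zero with a warning. One source contrast was reported as
an F statistic; the battery uses the LRT uniformly for consistency. No
multiplicity correction is applied, matching per-contrast reporting;
α = 0.05 two-sided throughout.

LM, GLM and the Gaussian LMM (ML, not REML, so LRTs are valid) are
statsmodels fits. The binomial and Poisson random-intercept marginal
likelihoods are maximized directly: the random-effect integral is
evaluated by Gauss–Hermite quadrature with 61 nodes (at the cluster
sizes used here — a dozen eggs per dish — 61 non-adaptive nodes match a
101-node reference to < 1e-5 log-likelihood units), σ is optimized on
its natural [0, ∞) boundary by L-BFGS-B with a two-stage
coarse-then-polish schedule, and standard errors come from the
numerical Hessian. With σ fixed at 0 the fit reproduces the GLM
estimates to < 1e-6, and the test suite cross-checks estimates, σ and
LRT statistics against `lme4::glmer` (nAGQ = 25) on simulated data —
note `glmer`'s reported log-likelihood differs by the saturated-model
constant, which cancels in every LRT. Boundary variance estimates and
suspected complete separation are flagged in the fit's notes, never
silently.

Exact intervals: Clopper–Pearson (beta quantiles) for binomial
proportions, the chi-square construction for Poisson rates, t-intervals
for Gaussian means (width undefined and flagged at n = 1).

## Calibration experiments (acceptance script and tests)

- Type-I error: 1,000 null replicates of 20 founders × 12 eggs (two
  substrates, equal parasitism 0.5, `dish_sd = 0` so the binomial GLM —
  the parasitism model of the analysis grid — is correctly specified);
  the LRT rejection rate at α = 0.05 must lie in (0.03, 0.07).
- Coverage: 400 replicates with a true substrate log-odds ratio of
  log 3; 95% Wald intervals must cover the truth at ≈ 0.95.
- Parameter recovery: 100 replicates of 20 founders; the three
  method-of-moments intervals must each cover their generating value in
  ≥ 90% of replicates.
- Generator fidelity: at 500 founders of the mixed fictitious-host
  design, observed host-beetle emergence must sit within three binomial
  standard errors of 0.22 (parasitized) and 0.94 (control).

Replicate counts are chosen so each check's Monte-Carlo error is small
against its acceptance band while the whole suite runs in well under a
minute per check on one core.

## Known limitations

- The fertility mapping is taken as given; the underlying
  clutch-size–body-size–fecundity regressions are not refit here.
- The per-offspring F2 percent gain between choice and no-choice
  strategies is entirely determined by the clutch-size frequency tables
  supplied; with the package's synthetic presets it is ≈ 1%, and
  reproducing any empirically reported gain requires the observed
  frequency tables as input.
- No F3 projection, and no optimal-clutch-size search: the package
  evaluates given strategies, it does not optimize them.
- The expected-mode allocation repair and sex-placement conventions are
  canonical-but-arbitrary deterministic choices; alternative
  conventions would change individual founders, not group-level sums.
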