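# Methods

This note documents the models implemented in `vulturedyn`, their
assumptions, the parameter choices that matter, and the numerical decisions
taken where the design was genuinely open. The study system is the African
white-backed vulture in two South African regions: the Greater Kruger
National Park ("Kruger", largely protected) and KwaZulu-Natal ("KZN",
largely non-protected), roughly 200 km apart.

## Mark–resighting survival (CJS)

The Cormack–Jolly–Seber model conditions on first capture and factorizes a
bird's annual 0/1 detection history into per-interval apparent survival φ
and per-occasion resighting probability p, closing each history with
χ_t = (1−φ_t) + φ_t (1−p_{t+1}) χ_{t+1}, the probability of never being
seen again. Both rates are modelled additively on the logit scale with
terms drawn from *site* (region), *age* (class) and *time* (occasion),
written in the conventional `Phi(site + age), p(site + t)` notation.

Assumptions and choices:

* **Age classes are time-varying covariates.** Juvenile = years 1–2,
  subadult = 3–5, adult = 6+, advancing deterministically by calendar year
  from the class at tagging (a tagged juvenile is treated as entering year
  1 of its class). This mirrors the age-structured survival design of the
  original analysis.
* **Link and fitting.** Logit link for φ and p; maximum likelihood by
  multi-start L-BFGS-B (default three starts, tolerance 1e−8 on the
  likelihood); standard errors from the numerically differentiated observed
  information; cell probabilities near 0/1 are flagged as boundary fits.
  Identical histories are pooled into weighted groups, so cost scales with
  distinct histories, not birds.
* **AICc effective sample size.** Program conventions differ and the
  original report does not state one. The default here is the total number
  of post-release detection opportunities, Σ_i (T − r_i); it is an explicit
  argument of `fit_cjs` because it shifts AICc by a model-independent
  structure within a ranking set.
* **Parameter counting.** The published ranking's parameter counts follow
  the numerical rank a specific program computed on specific (undeposited)
  data and cannot be reproduced exactly by any single design convention; we
  count identifiable design columns and document that final φ·p products
  are confounded when both rates carry time terms (a warning is raised).
  Ranking arithmetic (Δ AICc, Akaike weights) is independent of this.
* **Combined survival** pools a region's age-class estimates weighted by
  the region's released-bird age composition, with a delta-method SE.

The published absolute estimates (combined survival 0.858 Kruger / 0.683
KZN; absolute AICc values) depend on the undeposited field data; only the
ranking table's internal arithmetic and machinery properties (probability
conservation, nesting monotonicity, parameter recovery on synthetic data)
are test surfaces.

## Synthetic tagging studies

`synthetic_data` simulates the study design: cohorts released by (region,
age class, occasion), per-year Bernoulli survival using the bird's current
age class, then Bernoulli detection given alive. Dead birds emit zeros
forever; dead recoveries are never generated (the original analysis
excluded its two). Tag loss is off by default (`tag_retention = 1.0`); when
enabled it acts as an additional annual Bernoulli exit, indistinguishable
from death, matching how tag loss biases apparent survival.

The study-like default (`study_like_spec`) releases 183 birds — 79 Kruger,
104 KZN, mostly juveniles, staggered over the first six of seven annual
occasions — with true survival following the published pattern (similar
juvenile survival in both regions; markedly lower subadult/adult survival
in KZN) and moderate region/year-varying resighting probability. What these
simulations do *not* emulate: heterogeneous individual detectability,
within-year pulse violations (the real observation window spanned whole
years; the generator uses clean annual pulses), emigration, and tag wear.
Parameter-recovery results therefore demonstrate correctness of the
machinery, not robustness to those field realities.

`annualize` collapses dated opportunistic sightings into annual occasions
(multiple sightings in one year count once) and reports the bookkeeping
counts used to describe such datasets: total records, unique bird-year
re-sightings, birds ever re-seen.

## Matrix population models

Female-only, pre-breeding census with five single-year stages; the adult
(5+) stage self-loops:

```
     [ 0   0   0   0   f  ]
     [ s1  0   0   0   0  ]
A =  [ 0   s1  0   0   0  ]
     [ 0   0   s2  0   0  ]
     [ 0   0   0   s2  s3 ]
```

f = breeding propensity × (clutch/2) × hatching × fledging × first-year
survival, folded into a single rate. λ is the dominant eigenvalue;
sensitivities use the standard v w'/⟨v,w⟩ outer product of the dominant
left/right eigenvectors; elasticities over realized arcs sum to 1;
reproductive values are normalized so stage 1 equals 1.

**Vital-rate reconstruction.** The component rates behind the published
matrices are not printed, but each matrix entry satisfies
elasticity = (a/λ)·sensitivity, so the printed per-arc sensitivity and
elasticity values invert to a = e·λ/s. Duplicated arcs (s1, s2 each appear
twice) are averaged. Kruger adult survival inverts to 1.0044 — above 1 from
three-decimal rounding in the printed table — and is clipped to 1.0 with an
explicit warning, not silently accepted as an estimate. The reconstruction
reproduces λ = 1.0357 (Kruger, printed 1.04) and 0.6517 (KZN, printed
0.65), with fecundity ≈ 0.076 in both regions.

**Metapopulation.** The 10×10 matrix places Kruger upper-left, KZN
lower-right, and splits every life-cycle arc of a source region into
rate·(1−d) within-region and rate·d cross-region flow (column mass
conserved), with d = 0.05 for first-year birds and 0.02 for older stages,
equal in both directions. The printed source matrix contains subscript
inconsistencies; this column-conserving construction follows the stated
verbal description. With zero dispersal the spectrum reduces to the union
of the regional spectra (λ = max of regional λs); with the stated dispersal
λ = 1.0149 (printed 1.01).

**Quasi-extinction.** Each year is a catastrophe with probability
1/interval (Bernoulli); in catastrophe years Kruger s2 and s3 are replaced
by the KZN values, reverting afterwards. The only stochasticity is that
indicator — projection is deterministic matrix multiplication, with no
demographic or environmental noise and no density dependence. The starting
vector distributes 1200 Kruger and 425 KZN females as 9% stage 1, 24%
split equally over stages 2–4, and 67% adults. Extinction is first passage
below 10 total females within 100 years (an endpoint-only variant is
switchable); default 10,000 replicates. At intervals of 15/10/5 years the
probabilities are ≈ 0.016/0.19/0.97 (printed: 0.016/0.202/0.960); exact
agreement is not expected because the underlying vital rates are
reconstructed, not printed.

## Agent-based foraging model

A 200×200 km arena of 1×1 km patches. The central circle of 20,000 km²
(radius ≈ 79.79 km) is one habitat and the equal-area exterior the other;
the *focus* names the region occupying the circle. Nested inside are an
8-km colony circle (≈ 200 km²) and a 50-km foraging circle. Roost patches
(5/10/20, a sensitivity dimension) are placed uniformly at random each
replicate.

Agents: 26 adults (13 birds per 100 km² over the colony area), 13
subadults, 13 juveniles. Adults start in the colony and are confined to the
50-km foraging circle until day 240 (the breeding season), then roost like
juveniles; subadults choose nightly between the colony (prospecting) and
the nearest roost with even odds; juveniles always use the nearest roost.

Movement: correlated random walk at 24 km/h with ±15° turns per 10-minute
tick, nine foraging hours per day (54 ticks), headings randomized at dawn.
Carcass detection is Euclidean within 6 km, extended to 7 km when the
carcass is occupied (local enhancement) or large (> 1000 kg). Target
priority each tick: nearest visible carcass, else the remembered patch,
else the random walk. Landing on a poisoned carcass kills instantly; the
corpse remains on the carcass and counts toward the local-enhancement
radius — the sentinel-poisoning cascade in which one death recruits further
victims. Otherwise the bird feeds for the rest of the window and remembers
the patch. Overnight memory is kept only when the food will still be there
the next morning, i.e. after feeding on a large (two-day) carcass; within a
day, birds en route to a remembered patch still divert to any carcass they
pass. Nightly homing at 48 km/h is modelled as guaranteed arrival at the
roost. Boundaries reflect (a torus would let the exterior habitat wrap into
itself); confined adults likewise reflect at the 50-km circle.

Carcasses: each dawn, expired carcasses are removed (small after one day,
large after two) and new ones are drawn per habitat until standing mass
reaches the habitat budget — 0.15 kg km⁻² (3,000 kg) in protected habitat
with Gamma(shape 1.2, rate 0.004) masses (P(mass > 1000) = 0.02745), and
0.3 kg km⁻² (6,000 kg) in non-protected habitat with Normal(500, 100)
truncated at zero. The final draw is kept, so a budget can be exceeded by
at most one carcass. Each new carcass is poisoned independently with its
habitat's probability 1/R (R = 1000 and 100 in the headline scenario;
infinity disables poisoning). Poisoning is the model's only mortality
source, so reported survival is relative, not absolute; there are no
energetics, breeding, stage transitions or other mortality within the year.

Runs last 365 days with 30 replicates per variant; per-stage survival is
100 × alive/initial. The hot loop is numba-compiled; a (config, seed) pair
is bit-for-bit reproducible, and replicate seeds come from named substreams
so extending a replicate set never perturbs existing runs. At rates
1000/100 with 10 roosts the model yields mean adult survival ≈ 53% with the
colony in the protected habitat versus ≈ 8% with it in the non-protected
habitat (published: 48.98 and 7.05, SDs 17.6 and 6.15 over 30 replicates),
and reproduces the empirical anomaly of KZN juveniles outliving KZN adults.
These are 30-replicate means of a highly variable process; comparisons
should carry their Monte-Carlo standard errors (≈ SD/√30).

## Rank statistics

Survival percentages are bounded and non-normal, so comparisons are
rank-based throughout (the original analysis likewise rejected ANOVA after
residual inspection). The Wilcoxon rank-sum statistic is reported as the
Mann–Whitney U of the first sample (the R convention); small tie-free
samples use exact enumeration via the classic partition recurrence, larger
or tied samples the normal approximation with midrank tie correction and
continuity correction. Kruskal–Wallis uses the tie-corrected H with a
chi-square reference on k−1 degrees of freedom. Dunn's post hoc Z uses
mean-rank differences over the tie-corrected pooled variance; p-values are
adjusted by Holm by default (Bonferroni and Benjamini–Hochberg selectable —
the original report does not state its method). Degenerate inputs
(all-identical samples) are flagged rather than erroring.

## Pipeline and reproducibility

`cli_io.run_pipeline` chains the stages through serialized CSV artifacts
only, writing a JSON manifest with content hashes; identical config and
seed reproduce identical hashes. Every stochastic stage and replicate draws
its seed from the global seed through a named `SeedSequence` substream.

## Problem sizes

Defaults are chosen so the full test suite and the demonstration pipeline
run on a single CPU in minutes: parameter-recovery studies use 50
simulated studies of ~5,000 birds; quasi-extinction uses 10,000 replicates;
foraging experiments use the study's own 30 replicates of 365 days at
10-minute ticks.

## Known limitations

* CJS machinery assumes pulse sampling and homogeneous detectability
  within (region, occasion); the real study's year-round observation window
  violates pulse assumptions, which the original authors note chiefly
  inflates variance.
* The vital-rate reconstruction inherits three-decimal rounding from the
  published table (hence the clipped Kruger adult survival and small λ
  discrepancies).
* The foraging model's Kruger-focus juvenile survival (~25%) runs above
  the published 14.36%; the adult means and all qualitative stage/region
  orderings agree. The behavioural rules leave latitude (memory horizon,
  boundary treatment) that plausibly accounts for the residual gap.
* No density dependence, environmental autocorrelation, sex structure, or
  mortality sources other than poisoning anywhere in the chain.
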