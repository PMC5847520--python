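# vulturedyn

Demographic modelling of African white-backed vultures (*Gyps africanus*)
under spatially variable carcass poisoning.

African white-backed vultures tagged in two South African regions only
~200 km apart — the Greater Kruger National Park and KwaZulu-Natal (KZN) —
show starkly different apparent survival, with the unusual twist that KZN
juveniles outlive KZN adults and subadults. `vulturedyn` implements the full
computational chain needed to study that pattern, for quantitative
ecologists and conservation modellers:

1. **Mark–resighting survival** (`cjs_survival`): Cormack–Jolly–Seber
   likelihood with additive logit-scale structures over region (*site*), age
   class (*age*, advancing annually) and occasion (*time*); maximum
   likelihood fitting, AICc ranking and Akaike weights
   `w_i = exp(-Δ_i/2) / Σ_j exp(-Δ_j/2)`.
2. **Matrix population models** (`matrix_models`): female-only,
   pre-breeding-census 5×5 stage matrices per region; λ as the dominant
   eigenvalue; sensitivities `s_ij = v_i w_j / ⟨v, w⟩`, elasticities
   `e_ij = (a_ij/λ) s_ij`, reproductive values; a 10×10 two-region
   metapopulation matrix with symmetric dispersal; and a
   Bernoulli-catastrophe Monte Carlo for quasi-extinction probability
   (threshold 10 females, 100-year horizon).
3. **Agent-based foraging model** (`abm_core`): vultures moving by
   correlated random walk over a 200×200 km arena split into protected and
   non-protected habitat, with daily carcass budgets, habitat-specific
   per-carcass poisoning probabilities, local enhancement, memory, colony
   and roost dynamics. Survival differences between life stages emerge
   purely from movement ecology.
4. **Rank statistics** (`abm_stats`): Wilcoxon rank-sum, Kruskal–Wallis and
   Dunn's post hoc comparisons with multiplicity adjustment for the
   simulation output.
5. **Synthetic data** (`synthetic_data`): capture–resighting studies with
   known ground truth, shaped like the real 183-bird tagging design, so
   every stage is testable without field data (which were never deposited).

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Reconstruct the regional vital rates by inverting the published
sensitivity/elasticity table (`a = e·λ/s`) and project the populations:

```sh
$ vulturedyn project --region Kruger
{"region": "Kruger", "s1": 0.821, "s2": 0.891, "s3": 1.0, "f": 0.0767, "lambda": 1.0357}
$ vulturedyn project --region KZN
{"region": "KZN", "s1": 0.856, "s2": 0.504, "s3": 0.573, "f": 0.0760, "lambda": 0.6517}
$ vulturedyn project --region metapopulation
{"region": "metapopulation", "lambda": 1.0149}
```

Kruger grows (λ ≈ 1.04), KZN declines steeply (λ ≈ 0.65), and linking the
two with 5% first-year / 2% older-stage dispersal still yields growth
(λ ≈ 1.01). Note the reconstructed KZN juvenile survival (0.856) exceeding
adult survival (0.573) — the anomaly the foraging model explains. If
catastrophic poisoning years (Kruger subadult/adult survival dropping to KZN
levels) recur on average every 15, 10 or 5 years:

```sh
$ vulturedyn extinction --interval 5 --reps 10000 --seed 105
{"interval_years": 5.0, "extinction_probability": 0.9702, "replicates": 10000}
```

(0.0156 at 15-year and 0.1941 at 10-year intervals: extinction within a
century becomes near-certain as catastrophe frequency rises.)

Run the foraging simulation with the colony inside the protected area,
poisoning 10× rarer there (1-in-1000 vs 1-in-100 per carcass), 10 roosts,
30 replicate years:

```sh
$ vulturedyn abm --focus kruger --rate-protected 1000 \
      --rate-nonprotected 100 --roosts 10 --reps 30 --seed 1 --out reps.csv
 focus  rate_protected  rate_nonprotected  roosts    stage  mean_survival  sd_survival  n_replicates
Kruger          1000.0              100.0      10    adult      53.333333    19.500321            30
Kruger          1000.0              100.0      10 juvenile      25.641026    16.576304            30
Kruger          1000.0              100.0      10 subadult      33.589744    14.494591            30
```

Flipping the focus to KZN (colony in the non-protected habitat) collapses
mean adult survival to 8.2% while juveniles — never tied to the colony — do
better (13.6%), reproducing the empirical stage ordering. Compare stages
with `vulturedyn stats --input reps.csv --by stage --adjust holm`, or chain
everything (synthetic data → CJS → matrices → ABM → statistics) with
`vulturedyn all --seed 1 --out-dir out/`.

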