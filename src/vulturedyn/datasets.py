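"""Published reference values for the South African white-backed vulture system.

These are the printed outputs of the original Kruger / KwaZulu-Natal (KZN)
tagging study that this package re-implements around: the AICc model-ranking
table from the MARK survival analysis, the sensitivity/elasticity table of the
two regional matrix population models, and the demographic totals used to seed
projections.  The underlying field data were never deposited, so the absolute
survival estimates are not reproducible; these tables serve as *inputs* — for
AICc arithmetic, and for reconstructing the unprinted vital rates by inverting
elasticity = (a / lambda) * sensitivity.
"""

from __future__ import annotations

# AICc values of the seven candidate mark-resighting models, best first.
# Model names use MARK notation: Phi = annual apparent survival, p = resighting
# probability; "site" = region (Kruger vs KZN), "age" = age class, "t" = time.
PUBLISHED_MODEL_AICC: dict[str, float] = {
    "Phi(site + age), p(site + t)": 619.6521,
    "Phi(site + age), p(t)": 630.4739,
    "Phi(site), p(site + t)": 633.4523,
    "Phi(age), p(site + t)": 637.2545,
    "Phi(site + t), p(site + t)": 637.6956,
    "Phi(site + age), p(.)": 644.6853,
    "Phi(.), p(t)": 645.7124,
}

# Published population growth rates (dominant eigenvalues).
PUBLISHED_LAMBDA = {"Kruger": 1.04, "KZN": 0.65, "metapopulation": 1.01}

# Sensitivity / elasticity table of the two regional 5x5 stage matrices.
# Rows follow the matrix arcs: second/third-year survival (s1, twice),
# fourth/fifth-year survival (s2, twice), adult 5+ survival (s3), fecundity f.
# Each entry is (sensitivity, elasticity).
SENSITIVITY_ELASTICITY_TABLE = {
    "Kruger": {
        "s1_yr2": (0.038, 0.030),
        "s1_yr3": (0.038, 0.030),
        "s2_yr4": (0.035, 0.030),
        "s2_yr5": (0.035, 0.030),
        "s3": (0.879, 0.849),
        "f": (0.407, 0.030),
    },
    "KZN": {
        "s1_yr2": (0.063, 0.083),
        "s1_yr3": (0.063, 0.083),
        "s2_yr4": (0.107, 0.083),
        "s2_yr5": (0.107, 0.083),
        "s3": (0.660, 0.582),
        "f": (0.710, 0.083),
    },
}

# Estimated female population sizes and the stage composition used to
# distribute them (under-2s : 3-5 year olds : over-5 adults).
FEMALE_POPULATION = {"Kruger": 1200.0, "KZN": 425.0}
STAGE_COMPOSITION = {"under_2": 0.09, "between_3_5": 0.24, "adult": 0.67}

# Dispersal fractions between the two regions, assumed symmetric: 5% of
# first-year birds and 2% of the remaining stages.
DISPERSAL_FIRST_YEAR = 0.05
DISPERSAL_OLDER = 0.02

# Combined (age-pooled) apparent survival estimates with standard errors.
PUBLISHED_COMBINED_SURVIVAL = {"Kruger": (0.858, 0.04823), "KZN": (0.683, 0.03947)}

# Parameters of the carcass-mass distributions in the foraging simulation:
# protected habitat ~ Gamma(shape, rate); non-protected ~ Normal(mean, sd).
CARCASS_GAMMA_SHAPE = 1.2
CARCASS_GAMMA_RATE = 0.004
CARCASS_NORMAL_MEAN = 500.0
CARCASS_NORMAL_SD = 100.0
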