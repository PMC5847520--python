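"""Stage-structured matrix population models for the two vulture regions.

A female-only, pre-breeding-census projection with five single-year stages:
1-year-olds through 4-year-olds plus a self-looping adult (5+) stage.  Annual
survival is s1 for 1-3 year olds (juveniles), s2 for 3-5 year olds
(subadults) and s3 for adults; fecundity f folds breeding propensity, half the
clutch, hatching and fledging success, and first-year survival into a single
per-adult-female rate.  The projection matrix is

        [ 0   0   0   0   f  ]
        [ s1  0   0   0   0  ]
        [ 0   s1  0   0   0  ]
        [ 0   0   s2  0   0  ]
        [ 0   0   0   s2  s3 ]

Two regional matrices (Kruger, KZN) combine into a 10x10 metapopulation
matrix with symmetric dispersal; a Bernoulli-catastrophe Monte Carlo projects
the metapopulation against a quasi-extinction threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import datasets

__all__ = [
    "VitalRates",
    "ExtinctionScenario",
    "build_stage_matrix",
    "growth_rate",
    "eigen_system",
    "sensitivity_matrix",
    "elasticity_matrix",
    "reproductive_values",
    "derive_vitals_from_elasticities",
    "reference_vital_rates",
    "build_metapop_matrix",
    "initial_population_vector",
    "simulate_pseudo_extinction",
]

#: boolean mask of the realized life-cycle arcs in the 5x5 stage matrix
STAGE_ARCS = np.array(
    [
        [0, 0, 0, 0, 1],
        [1, 0, 0, 0, 0],
        [0, 1, 0, 0, 0],
        [0, 0, 1, 0, 0],
        [0, 0, 0, 1, 1],
    ],
    dtype=bool,
)


@dataclass(frozen=True)
class VitalRates:
    """Annual vital rates of one region.

    s1: survival of 1-3 year olds; s2: survival of 3-5 year olds;
    s3: adult (5+) survival; f: per-adult-female fecundity (first-year
    survival folded in, pre-breeding census).
    """

    s1: float
    s2: float
    s3: float
    f: float
    region: str = ""

    def __post_init__(self) -> None:
        for name in ("s1", "s2", "s3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"survival rate {name}={v} outside [0, 1]")
        if self.f < 0:
            raise ValueError(f"fecundity f={self.f} must be non-negative")


def build_stage_matrix(v: VitalRates) -> np.ndarray:
    """Assemble the 5x5 projection matrix from one region's vital rates."""
    A = np.zeros((5, 5))
    A[0, 4] = v.f
    A[1, 0] = A[2, 1] = v.s1
    A[3, 2] = A[4, 3] = v.s2
    A[4, 4] = v.s3
    return A


def growth_rate(A: np.ndarray) -> float:
    """Asymptotic population growth rate: the dominant eigenvalue of ``A``."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"projection matrix must be square, got {A.shape}")
    eigvals = np.linalg.eigvals(A)
    return float(eigvals[np.argmax(np.abs(eigvals))].real)


def eigen_system(A: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Dominant eigenvalue with right (w) and left (v) eigenvectors.

    w is scaled to sum to 1 (stable stage distribution); v is scaled so the
    first stage has reproductive value 1.  Raises for matrices whose dominant
    eigenvalue is complex or degenerate (reducible/defective cases).
    """
    A = np.asarray(A, dtype=float)
    lam_r, W = np.linalg.eig(A)
    k = int(np.argmax(np.abs(lam_r)))
    if abs(lam_r[k].imag) > 1e-9 * max(1.0, abs(lam_r[k])):
        raise np.linalg.LinAlgError("dominant eigenvalue is complex; matrix not primitive")
    lam = float(lam_r[k].real)
    w = W[:, k].real
    lam_l, V = np.linalg.eig(A.T)
    kl = int(np.argmin(np.abs(lam_l - lam_r[k])))
    v = V[:, kl].real
    # fix signs: dominant eigenvectors of a primitive nonnegative matrix are
    # one-signed; normalize to the positive orthant
    if w.sum() < 0:
        w = -w
    if v.sum() < 0:
        v = -v
    if np.any(w < -1e-9) or np.any(v < -1e-9):
        raise np.linalg.LinAlgError("dominant eigenvectors not one-signed; matrix reducible?")
    w = np.clip(w, 0.0, None)
    v = np.clip(v, 0.0, None)
    w = w / w.sum()
    if v[0] <= 0:
        raise np.linalg.LinAlgError("stage-1 reproductive value is zero; cannot normalize")
    v = v / v[0]
    return lam, w, v


def sensitivity_matrix(A: np.ndarray) -> np.ndarray:
    """Sensitivities d(lambda)/d(a_ij) = v_i w_j / <v, w> for every entry."""
    _, w, v = eigen_system(A)
    return np.outer(v, w) / float(v @ w)


def elasticity_matrix(A: np.ndarray) -> np.ndarray:
    """Proportional sensitivities (a_ij / lambda) d(lambda)/d(a_ij).

    Over the realized (nonzero) entries of a primitive matrix these sum to 1.
    """
    A = np.asarray(A, dtype=float)
    lam, w, v = eigen_system(A)
    S = np.outer(v, w) / float(v @ w)
    return A * S / lam


def reproductive_values(A: np.ndarray) -> np.ndarray:
    """Left dominant eigenvector scaled so stage 1 has value 1."""
    return eigen_system(A)[2]


def derive_vitals_from_elasticities(
    lam: float,
    table: dict[str, tuple[float, float]],
    region: str = "",
) -> VitalRates:
    """Reconstruct vital rates from a printed sensitivity/elasticity table.

    Each matrix entry satisfies elasticity = (a / lambda) * sensitivity, so
    a = elasticity * lambda / sensitivity.  ``table`` maps arc labels
    (s1_yr2, s1_yr3, s2_yr4, s2_yr5, s3, f) to (sensitivity, elasticity)
    pairs; the duplicated s1/s2 arcs are averaged.  Survival rates that invert
    to slightly above 1 (printed-table rounding) are clipped to 1 with a
    warning, never silently.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")

    def arc(key: str) -> float:
        s, e = table[key]
        if s == 0:
            raise ZeroDivisionError(f"zero sensitivity for arc {key!r}")
        return e * lam / s

    s1 = (arc("s1_yr2") + arc("s1_yr3")) / 2.0
    s2 = (arc("s2_yr4") + arc("s2_yr5")) / 2.0
    s3 = arc("s3")
    f = arc("f")
    clipped = {}
    for name, val in (("s1", s1), ("s2", s2), ("s3", s3)):
        if val > 1.0:
            clipped[name] = val
    if clipped:
        warnings.warn(
            f"survival rates inverted above 1 and clipped: {clipped} "
            "(rounding in the printed sensitivity/elasticity values)",
            stacklevel=2,
        )
        s1, s2, s3 = (min(x, 1.0) for x in (s1, s2, s3))
    return VitalRates(s1=s1, s2=s2, s3=s3, f=f, region=region)


def reference_vital_rates(region: str) -> VitalRates:
    """Vital rates reconstructed from the published regional tables."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Kruger s3 inverts to 1.004, clipped
        return derive_vitals_from_elasticities(
            datasets.PUBLISHED_LAMBDA[region],
            datasets.SENSITIVITY_ELASTICITY_TABLE[region],
            region=region,
        )


def _dispersal_mask(d_older: float, d_first: float) -> np.ndarray:
    D = np.full((5, 5), d_older)
    D[0, 4] = d_first
    return D


def build_metapop_matrix(
    v_kr: VitalRates,
    v_kzn: VitalRates,
    gb: float = datasets.DISPERSAL_OLDER,
    bg: float = datasets.DISPERSAL_OLDER,
    gb0: float = datasets.DISPERSAL_FIRST_YEAR,
    bg0: float = datasets.DISPERSAL_FIRST_YEAR,
) -> np.ndarray:
    """10x10 two-region matrix with Kruger upper-left and KZN lower-right.

    gb / gb0: fraction of Kruger older-stage / first-year birds dispersing to
    KZN; bg / bg0 the reverse.  Each life-cycle arc of a source region is
    split rate*(1-d) within region and rate*d across, so column mass is
    conserved: within + cross = the original rate.
    """
    for name, d in (("gb", gb), ("bg", bg), ("gb0", gb0), ("bg0", bg0)):
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"dispersal fraction {name}={d} outside [0, 1]")
    A_kr = build_stage_matrix(v_kr)
    A_kz = build_stage_matrix(v_kzn)
    D_kr = _dispersal_mask(gb, gb0)
    D_kz = _dispersal_mask(bg, bg0)
    M = np.zeros((10, 10))
    M[0:5, 0:5] = A_kr * (1 - D_kr)
    M[5:10, 0:5] = A_kr * D_kr
    M[5:10, 5:10] = A_kz * (1 - D_kz)
    M[0:5, 5:10] = A_kz * D_kz
    return M


def initial_population_vector(
    totals: dict[str, float] | None = None,
    composition: dict[str, float] | None = None,
) -> np.ndarray:
    """Stage-structured female starting vector for the two linked regions.

    The regional totals are split with the published composition: the
    under-2 fraction into stage 1, the 3-5 year-old fraction equally over
    stages 2-4, and the adult fraction into stage 5.
    """
    totals = dict(datasets.FEMALE_POPULATION if totals is None else totals)
    comp = dict(datasets.STAGE_COMPOSITION if composition is None else composition)
    shares = np.array(
        [
            comp["under_2"],
            comp["between_3_5"] / 3.0,
            comp["between_3_5"] / 3.0,
            comp["between_3_5"] / 3.0,
            comp["adult"],
        ]
    )
    return np.concatenate([totals["Kruger"] * shares, totals["KZN"] * shares])


@dataclass(frozen=True)
class ExtinctionScenario:
    """Catastrophe regime for the quasi-extinction Monte Carlo.

    interval_years: mean recurrence of catastrophic poisoning years; each
    year is a catastrophe with probability 1/interval_years.  In catastrophe
    years Kruger subadult and adult survival (s2, s3) drop to the KZN values,
    reverting the following year.  Extinction = total female count below
    ``threshold`` at any point within ``horizon`` years (first passage) or,
    with first_passage=False, at the horizon only.
    """

    interval_years: float
    horizon: int = 100
    threshold: float = 10.0
    replicates: int = 10_000
    seed: int = 0
    first_passage: bool = True
    initial_population: np.ndarray = field(
        default_factory=initial_population_vector, compare=False
    )

    def __post_init__(self) -> None:
        if self.interval_years <= 0 and not np.isinf(self.interval_years):
            raise ValueError("interval_years must be positive (inf = never)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.horizon < 1:
            raise ValueError("horizon must be at least one year")


def simulate_pseudo_extinction(
    scenario: ExtinctionScenario,
    v_kr: VitalRates | None = None,
    v_kzn: VitalRates | None = None,
    gb: float = datasets.DISPERSAL_OLDER,
    bg: float = datasets.DISPERSAL_OLDER,
    gb0: float = datasets.DISPERSAL_FIRST_YEAR,
    bg0: float = datasets.DISPERSAL_FIRST_YEAR,
) -> float:
    """Quasi-extinction probability of the metapopulation under catastrophes.

    The only stochastic element is the yearly Bernoulli catastrophe
    indicator; projection itself is deterministic matrix multiplication.
    Returns the fraction of replicates that crossed the threshold.
    """
    v_kr = reference_vital_rates("Kruger") if v_kr is None else v_kr
    v_kzn = reference_vital_rates("KZN") if v_kzn is None else v_kzn
    M = build_metapop_matrix(v_kr, v_kzn, gb, bg, gb0, bg0)
    v_kr_cat = VitalRates(
        s1=v_kr.s1, s2=v_kzn.s2, s3=v_kzn.s3, f=v_kr.f, region=v_kr.region
    )
    M_cat = build_metapop_matrix(v_kr_cat, v_kzn, gb, bg, gb0, bg0)

    rng = np.random.default_rng(scenario.seed)
    p_cat = 0.0 if np.isinf(scenario.interval_years) else 1.0 / scenario.interval_years
    R = scenario.replicates
    pop = np.tile(np.asarray(scenario.initial_population, dtype=float), (R, 1))
    extinct = np.zeros(R, dtype=bool)
    for _ in range(scenario.horizon):
        cat = rng.random(R) < p_cat
        if cat.any():
            pop[cat] = pop[cat] @ M_cat.T
        if (~cat).any():
            pop[~cat] = pop[~cat] @ M.T
        if scenario.first_passage:
            extinct |= pop.sum(axis=1) < scenario.threshold
    if not scenario.first_passage:
        extinct = pop.sum(axis=1) < scenario.threshold
    return float(extinct.mean())
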