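"""Cormack-Jolly-Seber survival estimation with AICc model ranking.

Open-population mark-resighting analysis for the two-region vulture tagging
design: apparent annual survival (phi) may vary additively on the logit scale
with region ("site"), age class ("age", advancing annually from the class at
tagging) and interval ("time"); resighting probability (p) with site and
occasion.  The likelihood conditions on first capture; a bird's contribution
multiplies per-interval survival and per-occasion detection terms up to its
last sighting, times the probability chi of never being seen again.

Models are fitted by maximum likelihood (multi-start L-BFGS-B), compared by
AICc and summarized with Akaike weights, mirroring the conventional MARK
workflow for these data.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

REGIONS = ("Kruger", "KZN")
AGE_CLASSES = ("juvenile", "subadult", "adult")

# first year-of-life of each class at tagging (juvenile = years 1-2,
# subadult = 3-5, adult = 6+); age advances by calendar year
_CLASS_ENTRY_YEAR = {"juvenile": 1, "subadult": 3, "adult": 6}

__all__ = [
    "CaptureHistorySet",
    "CJSModelSpec",
    "CJSFit",
    "ModelRankingTable",
    "age_class_at",
    "cjs_log_likelihood",
    "n_design_parameters",
    "fit_cjs",
    "rank_models",
    "rank_from_aicc",
    "combined_survival",
    "aicc",
]


def age_class_at(age_at_release: str, years_since_release: int) -> str:
    """Age class of a bird a given number of whole years after tagging."""
    year = _CLASS_ENTRY_YEAR[age_at_release] + years_since_release
    if year <= 2:
        return "juvenile"
    if year <= 5:
        return "subadult"
    return "adult"


@dataclass
class CaptureHistorySet:
    """Annualized 0/1 detection histories with per-bird covariates.

    histories[i, t] is 1 if bird i was seen in occasion t; entries before the
    release occasion are structurally absent (the CJS likelihood conditions
    on first capture) and stored as 0.
    """

    histories: np.ndarray
    region: np.ndarray
    age_at_release: np.ndarray
    release_occasion: np.ndarray
    bird_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.histories = np.asarray(self.histories, dtype=np.int8)
        self.region = np.asarray(self.region)
        self.age_at_release = np.asarray(self.age_at_release)
        self.release_occasion = np.asarray(self.release_occasion, dtype=int)
        n = self.histories.shape[0]
        if self.bird_id is None:
            self.bird_id = np.array([f"bird{i:04d}" for i in range(n)])
        if not (len(self.region) == len(self.age_at_release) == len(self.release_occasion) == n):
            raise ValueError("covariate lengths do not match history count")
        if np.any(self.release_occasion < 0) or np.any(
            self.release_occasion >= self.n_occasions
        ):
            raise ValueError("release occasions outside the study window")
        seen_at_release = self.histories[np.arange(n), self.release_occasion]
        if n and not np.all(seen_at_release == 1):
            raise ValueError("every history must be 1 at its release occasion")

    @property
    def n_birds(self) -> int:
        return self.histories.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.histories.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bird_id": self.bird_id,
                "region": self.region,
                "age_at_release": self.age_at_release,
            }
        )
        for t in range(self.n_occasions):
            df[f"occ{t + 1}"] = self.histories[:, t]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CaptureHistorySet":
        df = pd.read_csv(path)
        occ_cols = [c for c in df.columns if re.fullmatch(r"occ\d+", c)]
        occ_cols.sort(key=lambda c: int(c[3:]))
        hist = df[occ_cols].to_numpy(dtype=np.int8)
        release = np.argmax(hist == 1, axis=1)
        return cls(
            histories=hist,
            region=df["region"].to_numpy(),
            age_at_release=df["age_at_release"].to_numpy(),
            release_occasion=release,
            bird_id=df["bird_id"].to_numpy(),
        )


@dataclass(frozen=True)
class CJSModelSpec:
    """Additive model structure in MARK-style notation.

    phi_terms is a subset of {"site", "age", "time"} and p_terms a subset of
    {"site", "time"}; empty sets mean a constant rate, e.g.
    ``Phi(site + age), p(.)``.
    """

    phi_terms: frozenset = frozenset()
    p_terms: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi_terms", frozenset(self.phi_terms))
        object.__setattr__(self, "p_terms", frozenset(self.p_terms))
        if not self.phi_terms <= {"site", "age", "time"}:
            raise ValueError(f"unknown phi terms: {set(self.phi_terms) - {'site', 'age', 'time'}}")
        if not self.p_terms <= {"site", "time"}:
            raise ValueError(f"unknown p terms: {set(self.p_terms) - {'site', 'time'}}")

    @property
    def name(self) -> str:
        def block(terms, order):
            kept = [t for t in order if t in terms]
            return " + ".join("t" if t == "time" else t for t in kept) or "."

        return (
            f"Phi({block(self.phi_terms, ('site', 'age', 'time'))}), "
            f"p({block(self.p_terms, ('site', 'time'))})"
        )

    @classmethod
    def parse(cls, text: str) -> "CJSModelSpec":
        m = re.fullmatch(
            r"\s*Phi\(([^)]*)\)\s*,\s*p\(([^)]*)\)\s*", text, flags=re.IGNORECASE
        )
        if not m:
            raise ValueError(f"cannot parse model name {text!r}")

        def terms(block: str) -> frozenset:
            block = block.strip()
            if block in (".", ""):
                return frozenset()
            out = set()
            for tok in (s.strip() for s in block.split("+")):
                out.add({"t": "time", "time": "time", "site": "site", "age": "age"}[tok.lower()])
            return frozenset(out)

        return cls(phi_terms=terms(m.group(1)), p_terms=terms(m.group(2)))


class _Design:
    """Pre-computed cell indexing and design matrices for one data/model pair.

    Birds with identical (region, age class at release, release occasion,
    history) collapse into weighted groups, so likelihood cost scales with
    the number of distinct histories, not birds.
    """

    def __init__(self, data: CaptureHistorySet, spec: CJSModelSpec):
        if data.n_birds == 0:
            raise ValueError("empty capture-history set")
        self.spec = spec
        T = data.n_occasions
        self.T = T

        key = pd.DataFrame(
            {
                "region": data.region,
                "age": data.age_at_release,
                "release": data.release_occasion,
            }
        )
        for t in range(T):
            key[f"h{t}"] = data.histories[:, t]
        grouped = key.groupby(list(key.columns), sort=True).size().reset_index(name="w")
        self.weights = grouped["w"].to_numpy(dtype=float)
        self.g_region = grouped["region"].to_numpy()
        self.g_age = grouped["age"].to_numpy()
        self.g_release = grouped["release"].to_numpy(dtype=int)
        self.g_hist = grouped[[f"h{t}" for t in range(T)]].to_numpy(dtype=np.int8)
        G = len(self.weights)
        self.G = G

        # phi cell index per (group, interval t->t+1); p cell per (group, occasion)
        phi_cells: dict[tuple, int] = {}
        p_cells: dict[tuple, int] = {}
        self.phi_idx = np.zeros((G, T - 1), dtype=int)
        self.p_idx = np.zeros((G, T), dtype=int)
        for g in range(G):
            reg = self.g_region[g]
            for t in range(T - 1):
                age = age_class_at(self.g_age[g], max(t - self.g_release[g], 0))
                cell = (
                    reg if "site" in spec.phi_terms else None,
                    age if "age" in spec.phi_terms else None,
                    t if "time" in spec.phi_terms else None,
                )
                self.phi_idx[g, t] = phi_cells.setdefault(cell, len(phi_cells))
            for t in range(1, T):
                cell = (
                    reg if "site" in spec.p_terms else None,
                    t if "time" in spec.p_terms else None,
                )
                self.p_idx[g, t] = p_cells.setdefault(cell, len(p_cells))

        self.phi_cells = sorted(phi_cells, key=phi_cells.get)
        self.p_cells = sorted(p_cells, key=p_cells.get)

        self.X_phi = self._design_matrix(self.phi_cells, ("site", "age", "time"))
        self.X_p = self._design_matrix(self.p_cells, ("site", "time"))
        self.n_phi_beta = self.X_phi.shape[1]
        self.n_p_beta = self.X_p.shape[1]
        self.n_params = self.n_phi_beta + self.n_p_beta

        self.active = np.zeros((G, T), dtype=bool)  # post-release occasions
        for g in range(G):
            self.active[g, self.g_release[g] + 1 :] = True
        self.obs = self.g_hist.astype(float)
        nz = np.where(self.g_hist == 1, np.arange(T), -1)
        self.last = nz.max(axis=1)

    @staticmethod
    def _design_matrix(cells: list[tuple], order: tuple) -> np.ndarray:
        levels = [sorted({c[i] for c in cells}, key=str) for i in range(len(order))]
        cols = 1
        for lv in levels:
            cols += max(len(lv) - 1, 0) if lv != [None] else 0
        X = np.zeros((len(cells), cols))
        X[:, 0] = 1.0
        j = 1
        for i, lv in enumerate(levels):
            if lv == [None] or len(lv) < 2:
                continue
            for level in lv[1:]:
                for r, c in enumerate(cells):
                    if c[i] == level:
                        X[r, j] = 1.0
                j += 1
        return X[:, : j if j > 1 else 1]

    def rates(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta_phi = params[: self.n_phi_beta]
        beta_p = params[self.n_phi_beta :]
        return expit(self.X_phi @ beta_phi), expit(self.X_p @ beta_p)

    def log_likelihood(self, params: np.ndarray) -> float:
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"expected {self.n_params} parameters, got {params.shape}"
            )
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite parameters")
        phi_cells, p_cells = self.rates(params)
        G, T = self.G, self.T
        phi = phi_cells[self.phi_idx]  # (G, T-1)
        p = p_cells[self.p_idx]  # (G, T); column 0 unused

        with np.errstate(divide="ignore"):
            log_phi = np.log(phi)
            log_p = np.log(p)
            log_1mp = np.log1p(-p)

        ll = np.zeros(G)
        for t in range(1, T):
            seen_later = self.active[:, t] & (self.last >= t)
            y = self.obs[:, t]
            term = log_phi[:, t - 1] + y * log_p[:, t] + (1 - y) * log_1mp[:, t]
            ll += np.where(seen_later, term, 0.0)

        # chi_t = P(never seen after t | alive at t)
        chi = np.ones((G, T))
        for t in range(T - 2, -1, -1):
            chi[:, t] = (1 - phi[:, t]) + phi[:, t] * (1 - p[:, t + 1]) * chi[:, t + 1]
        with np.errstate(divide="ignore"):
            ll += np.log(chi[np.arange(G), self.last])

        total = float(np.dot(self.weights, ll))
        if np.isnan(total):
            raise FloatingPointError("non-finite log-likelihood")
        return total


def cjs_log_likelihood(
    data: CaptureHistorySet, spec: CJSModelSpec, params: np.ndarray
) -> float:
    """CJS log-likelihood of the parameter vector under an additive model.

    The parameter vector stacks the logit-scale phi coefficients (intercept
    followed by non-reference site/age/time effects) then the p coefficients.
    """
    return _Design(data, spec).log_likelihood(params)


def n_design_parameters(data: CaptureHistorySet, spec: CJSModelSpec) -> int:
    """Number of identifiable design columns for this data/model pair.

    Factor levels never visited by any bird (an age class nobody passes
    through, say) contribute no column, so the count is data-dependent.
    """
    return _Design(data, spec).n_params


def aicc(logL: float, k: int, ess: int) -> float:
    """Small-sample Akaike information criterion."""
    if ess - k - 1 <= 0:
        return np.inf
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (ess - k - 1)


@dataclass
class CJSFit:
    """Maximum-likelihood fit of one CJS model."""

    spec: CJSModelSpec
    beta: np.ndarray
    beta_se: np.ndarray
    cov: np.ndarray
    logL: float
    n_params: int
    ess: int
    aicc: float
    converged: bool
    phi_estimates: pd.DataFrame
    p_estimates: pd.DataFrame
    data_fingerprint: str = ""
    boundary: bool = False
    message: str = ""

    @property
    def name(self) -> str:
        return self.spec.name

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.name,
                "logL": self.logL,
                "n_params": self.n_params,
                "ess": self.ess,
                "aicc": self.aicc,
                "converged": self.converged,
                "boundary": self.boundary,
                "beta": self.beta.tolist(),
                "beta_se": self.beta_se.tolist(),
                "phi": self.phi_estimates.to_dict(orient="records"),
                "p": self.p_estimates.to_dict(orient="records"),
            },
            indent=2,
        )


def _fingerprint(data: CaptureHistorySet) -> str:
    h = pd.util.hash_pandas_object(data.to_frame(), index=False).to_numpy()
    return f"{data.n_birds}x{data.n_occasions}:{int(h.sum()) & 0xFFFFFFFF:08x}"


def _numeric_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    hs = step * (1.0 + np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = hs[i]
            ej[j] = hs[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def effective_sample_size(data: CaptureHistorySet) -> int:
    """Detection opportunities: sum over birds of post-release occasions.

    The convention MARK uses for the AICc denominator is not uniquely
    documented; this package defaults to the total number of Bernoulli
    detection opportunities and exposes ``ess`` as an argument to
    :func:`fit_cjs` because the choice shifts AICc by the same constant
    structure within a model set.
    """
    return int(np.sum(data.n_occasions - 1 - data.release_occasion))


def fit_cjs(
    data: CaptureHistorySet,
    spec: CJSModelSpec | str,
    ess: int | None = None,
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
) -> CJSFit:
    """Fit a CJS model by multi-start quasi-Newton maximum likelihood.

    Standard errors come from the observed information (numerical Hessian of
    the negative log-likelihood at the optimum); estimates within 1e-3 of the
    0/1 boundary on the probability scale are flagged via ``boundary``.
    """
    if isinstance(spec, str):
        spec = CJSModelSpec.parse(spec)
    design = _Design(data, spec)
    if "time" in spec.phi_terms and "time" in spec.p_terms:
        # final-interval phi and final-occasion p only enter as a product
        import warnings

        warnings.warn(
            "phi and p both time-dependent: the final survival/detection "
            "product is confounded; treat the last-interval estimates with care",
            stacklevel=2,
        )

    nll = lambda b: -design.log_likelihood(b)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(n_starts, 1)):
        x0 = np.zeros(design.n_params) if s == 0 else rng.normal(0.0, 1.0, design.n_params)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", options={"maxiter": 2000, "ftol": tol, "gtol": 1e-8}
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    beta = best.x

    H = _numeric_hessian(nll, beta)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((design.n_params, design.n_params), np.nan)
        se = np.full(design.n_params, np.nan)

    phi_cells, p_cells = design.rates(beta)
    boundary = bool(
        np.any(phi_cells > 1 - 1e-3)
        or np.any(p_cells > 1 - 1e-3)
        or np.any(phi_cells < 1e-3)
        or np.any(p_cells < 1e-3)
    )

    def cell_table(cells, values, X, block) -> pd.DataFrame:
        rows = []
        offset = 0 if block == "phi" else design.n_phi_beta
        ncol = X.shape[1]
        sub_cov = cov[offset : offset + ncol, offset : offset + ncol]
        for r, cell in enumerate(cells):
            eta_var = float(X[r] @ sub_cov @ X[r])
            prob = values[r]
            rows.append(
                {
                    "site": cell[0],
                    ("age" if block == "phi" else "occasion"): cell[1],
                    **({"interval": cell[2]} if block == "phi" else {}),
                    "estimate": prob,
                    "se": prob * (1 - prob) * np.sqrt(max(eta_var, 0.0)),
                }
            )
        return pd.DataFrame(rows)

    ess_val = effective_sample_size(data) if ess is None else int(ess)
    logL = float(-best.fun)
    fit = CJSFit(
        spec=spec,
        beta=beta,
        beta_se=se,
        cov=cov,
        logL=logL,
        n_params=design.n_params,
        ess=ess_val,
        aicc=aicc(logL, design.n_params, ess_val),
        converged=bool(best.success),
        phi_estimates=cell_table(design.phi_cells, phi_cells, design.X_phi, "phi"),
        p_estimates=cell_table(design.p_cells, p_cells, design.X_p, "p"),
        data_fingerprint=_fingerprint(data),
        boundary=boundary,
        message=str(best.message),
    )
    return fit


@dataclass
class ModelRankingTable:
    """AICc ranking with deltas and Akaike weights, best model first."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"model", "aicc", "delta_aicc", "weight"}
        if not required <= set(self.table.columns):
            raise ValueError(f"ranking table missing columns {required - set(self.table.columns)}")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_from_aicc(
    aicc_values: dict[str, float], n_params: dict[str, int] | None = None
) -> ModelRankingTable:
    """Rank models from bare AICc values (e.g. a published table).

    delta_i = AICc_i - min AICc; weight_i = exp(-delta_i/2) / sum_j exp(-delta_j/2).
    """
    if not aicc_values:
        raise ValueError("no models to rank")
    df = pd.DataFrame(
        {
            "model": list(aicc_values),
            "aicc": list(aicc_values.values()),
            "n_params": [
                (n_params or {}).get(m, np.nan) for m in aicc_values
            ],
        }
    )
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    rel = np.exp(-df["delta_aicc"] / 2.0)
    df["weight"] = rel / rel.sum()
    df = df.sort_values(
        ["aicc", "n_params", "model"], kind="mergesort"
    ).reset_index(drop=True)
    return ModelRankingTable(df[["model", "aicc", "delta_aicc", "weight", "n_params"]])


def rank_models(fits: list[CJSFit]) -> ModelRankingTable:
    """Rank fitted models by AICc; rejects fits on differing data."""
    if not fits:
        raise ValueError("no fits to rank")
    fps = {f.data_fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError("fits were made on different data sets; cannot rank together")
    return rank_from_aicc(
        {f.name: f.aicc for f in fits}, {f.name: f.n_params for f in fits}
    )


def combined_survival(
    fit: CJSFit, data: CaptureHistorySet, region: str
) -> tuple[float, float]:
    """Age-pooled survival for one region with a delta-method SE.

    Age-class estimates are weighted by the region's released-bird age
    composition.  Requires a model without time-varying survival (phi cells
    are then region x age).
    """
    if region not in data.region:
        raise ValueError(f"region {region!r} absent from data")
    if "time" in fit.spec.phi_terms:
        raise ValueError("combined survival is defined for time-constant phi models")

    mask = data.region == region
    ages, counts = np.unique(data.age_at_release[mask], return_counts=True)
    weights = dict(zip(ages, counts / counts.sum()))

    design_spec = fit.spec
    phi_tab = fit.phi_estimates
    # map each age class to its phi cell row
    total = 0.0
    grad = np.zeros(len(fit.beta))
    # rebuild the phi design rows to get gradients
    d = _Design(data, design_spec)
    phi_cells, _ = d.rates(fit.beta)
    for age, w in weights.items():
        cell = (
            region if "site" in design_spec.phi_terms else None,
            age if "age" in design_spec.phi_terms else None,
            None,
        )
        r = d.phi_cells.index(cell)
        prob = phi_cells[r]
        total += w * prob
        grad[: d.n_phi_beta] += w * prob * (1 - prob) * d.X_phi[r]
    var = float(grad @ fit.cov @ grad)
    _ = phi_tab  # tables retained for reporting; gradients use the design
    return float(total), float(np.sqrt(max(var, 0.0)))


def standard_model_set() -> list[CJSModelSpec]:
    """The seven-candidate model set of the original analysis."""
    names = [
        "Phi(site + age), p(site + t)",
        "Phi(site + age), p(t)",
        "Phi(site), p(site + t)",
        "Phi(age), p(site + t)",
        "Phi(site + t), p(site + t)",
        "Phi(site + age), p(.)",
        "Phi(.), p(t)",
    ]
    return [CJSModelSpec.parse(n) for n in names]


def enumerate_history_probabilities(
    region: str,
    age_at_release: str,
    release_occasion: int,
    n_occasions: int,
    spec: CJSModelSpec,
    params: np.ndarray,
) -> dict[str, float]:
    """Probability of every possible post-release history for one cohort.

    Utility for conservation checks: the returned probabilities sum to 1 for
    any parameter values (the CJS likelihood is a proper distribution over
    suffix histories).
    """
    T = n_occasions
    out = {}
    suffixes = itertools.product([0, 1], repeat=T - release_occasion - 1)
    for suffix in suffixes:
        hist = np.zeros((1, T), dtype=np.int8)
        hist[0, release_occasion] = 1
        hist[0, release_occasion + 1 :] = suffix
        data = CaptureHistorySet(
            histories=hist,
            region=np.array([region]),
            age_at_release=np.array([age_at_release]),
            release_occasion=np.array([release_occasion]),
        )
        ll = cjs_log_likelihood(data, spec, params)
        out["".join(map(str, hist[0]))] = float(np.exp(ll))
    return out
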