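"""Synthetic person-level survey generator.

Generates datasets with the statistical structure the analysis assumes: two
correlated Gaussian latent physical-activity dimensions ("Screens use",
"Active transportation") shifted by leisure-time physical activity, six
strictly positive weekly-minute indicators drawn from Weibull distributions
whose log scale is linear in the latent, and a binary obesity outcome drawn
from a log-link Bernoulli model on the latents and sociodemographic
covariates. Default parameter values reproduce the published survey margins
(female share, age distribution, ethnicity/schooling/wealth proportions,
indicator medians, ~19.1% obesity prevalence) and the published measurement
loadings and prevalence ratios; see docs/methods.md for the full table.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .errors import ConfigError, DomainError

__all__ = [
    "child_seed",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_measurement_dataset",
    "sample_weibull_indicator",
    "sample_obesity",
    "apply_exclusions",
    "calibrate_log_intercept",
    "write_dataset",
    "DEPARTMENT_CODES",
]

#: DIVIPOLA two-digit codes of the 32 Colombian departments plus Bogotá (11).
DEPARTMENT_CODES = (
    "05", "08", "11", "13", "15", "17", "18", "19", "20", "23", "25",
    "27", "41", "44", "47", "50", "52", "54", "63", "66", "68", "70",
    "73", "76", "81", "85", "86", "88", "91", "94", "95", "97", "99",
)

INDICATORS = (
    "computer_smartphone", "tv", "videogames", "motor_vehicle", "cycling", "walking",
)

_LN = math.log


def child_seed(base: int, stream: int) -> int:
    """Deterministic sub-seed for an independent random stream (< 2^31)."""
    return int(np.random.SeedSequence([int(base), int(stream)]).generate_state(1)[0] % (2**31))


def _default_loadings() -> dict[str, float]:
    # Published point estimates; references fixed at 1.
    return {
        "computer_smartphone": 1.0,
        "tv": 3.9,
        "videogames": -20.3,
        "motor_vehicle": 1.0,
        "cycling": -5.4,
        "walking": 0.8,
    }


def _default_intercepts() -> dict[str, float]:
    # log minutes/week, anchored at the published indicator medians.
    return {
        "computer_smartphone": _LN(45.0),
        "tv": _LN(420.0),
        "videogames": _LN(30.0),
        "motor_vehicle": _LN(140.0),
        "cycling": _LN(20.0),
        "walking": _LN(70.0),
    }


def _default_shapes() -> dict[str, float]:
    return {j: 1.3 for j in INDICATORS}


def _default_disease_coefs() -> dict[str, float]:
    # Log prevalence ratios; intercept None means "calibrate to target_prevalence".
    return {
        "intercept": None,
        "L_screens": _LN(1.19),
        "L_transport": _LN(0.86),
        "female": _LN(1.71),
        "age": _LN(1.02),
        "eth_afro": _LN(1.36),
        "eth_indigenous": _LN(1.09),
        "school_secondary": 0.05,
        "school_tertiary": -0.10,
        "wealth_q2": _LN(1.23),
        "wealth_q3": _LN(1.13),
        "wealth_q4": _LN(1.04),
        "energy_kcal": 0.0,
        "leisure_pa": _LN(0.9996),
    }


def _default_covariate_margins() -> dict:
    return {
        "female_prob": 0.562,
        "age_mean": 38.5,
        "age_sd": 13.1,
        "age_range": (18.0, 64.0),
        "ethnicity_probs": {"afro": 0.071, "indigenous": 0.020, "other": 0.909},
        "schooling_probs": {"primary": 0.158, "secondary": 0.753, "tertiary": 0.089},
        "wealth_probs": {"q1": 0.295, "q2": 0.237, "q3": 0.244, "q4": 0.224},
        "energy_log_mean": _LN(2000.0),
        "energy_log_sd": 0.30,
        "leisure_pa_zero_prob": 0.35,
        "leisure_pa_gamma_shape": 1.3,
        "leisure_pa_gamma_scale": 120.0,
    }


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults are the study conditions."""

    n_persons: int = 9658
    seed: int = 0
    latent_sds: tuple[float, float] = (0.1, 0.5)
    latent_corr: float = 0.2
    loadings: dict[str, float] = field(default_factory=_default_loadings)
    indicator_intercepts: dict[str, float] = field(default_factory=_default_intercepts)
    weibull_shapes: dict[str, float] = field(default_factory=_default_shapes)
    gamma_screens: float = -0.00098
    gamma_transport: float = 0.00424
    disease_coefs: dict[str, float | None] = field(default_factory=_default_disease_coefs)
    target_prevalence: float = 0.191
    covariate_margins: dict = field(default_factory=_default_covariate_margins)
    department_count: int = 33
    department_probs: tuple[float, ...] | None = None
    dept_prevalence_shift_sd: float = 0.10
    dept_transport_shift_sd: float = 0.15
    weight_model: str = "unit"
    weight_cv: float = 0.5

    def __post_init__(self):
        if not isinstance(self.n_persons, (int, np.integer)) or self.n_persons < 0:
            raise ConfigError("n_persons", "must be a nonnegative integer")
        if not -1.0 < float(self.latent_corr) < 1.0:
            raise ConfigError("latent_corr", "must lie strictly inside (-1, 1)")
        if len(self.latent_sds) != 2 or any(s <= 0 for s in self.latent_sds):
            raise ConfigError("latent_sds", "must be two positive reals")
        for j in INDICATORS:
            if j not in self.weibull_shapes or not self.weibull_shapes[j] > 0:
                raise ConfigError("weibull_shapes", f"shape for {j!r} must be > 0")
            if j not in self.indicator_intercepts:
                raise ConfigError("indicator_intercepts", f"missing indicator {j!r}")
            if j not in self.loadings:
                raise ConfigError("loadings", f"missing indicator {j!r}")
        for key in ("ethnicity_probs", "schooling_probs", "wealth_probs"):
            probs = self.covariate_margins.get(key)
            if probs is None or abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ConfigError(f"covariate_margins.{key}", "probabilities must sum to 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"covariate_margins.{key}", "probabilities must be >= 0")
        p = self.covariate_margins.get("female_prob", -1.0)
        if not 0.0 <= p <= 1.0:
            raise ConfigError("covariate_margins.female_prob", "must be in [0, 1]")
        if self.department_count < 1:
            raise ConfigError("department_count", "must be a positive count")
        if self.department_probs is not None:
            dp = np.asarray(self.department_probs, dtype=float)
            if dp.shape != (self.department_count,) or abs(dp.sum() - 1.0) > 1e-6 or (dp < 0).any():
                raise ConfigError("department_probs", "must be department_count probabilities summing to 1")
        if self.weight_model not in ("unit", "gamma"):
            raise ConfigError("weight_model", "must be 'unit' or 'gamma'")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigError("target_prevalence", "must be in (0, 1)")

    # ------------------------------------------------------------------
    def department_codes(self) -> tuple[str, ...]:
        if self.department_count == len(DEPARTMENT_CODES):
            return DEPARTMENT_CODES
        return tuple(f"D{i + 1:02d}" for i in range(self.department_count))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["latent_sds"] = list(self.latent_sds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "latent_sds" in d:
            d["latent_sds"] = tuple(d["latent_sds"])
        base = cls()
        for key in ("loadings", "indicator_intercepts", "weibull_shapes", "disease_coefs"):
            if key in d:
                merged = dict(getattr(base, key))
                merged.update(d[key])
                d[key] = merged
        if "covariate_margins" in d:
            merged = dict(_default_covariate_margins())
            merged.update(d["covariate_margins"])
            d["covariate_margins"] = merged
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SyntheticDataset:
    """Generated person table plus generation metadata.

    ``data`` has one row per person; the hidden columns ``true_L1`` and
    ``true_L2`` carry the simulated latents and exist only in synthetic
    output. ``meta`` records the config, seed, calibrated disease intercept,
    capped-probability fraction and per-department effect shifts.
    """

    data: pd.DataFrame
    meta: dict


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------

def sample_weibull_indicator(latent_values, loading, intercept, shape, rng) -> np.ndarray:
    """Draw weekly minutes from a Weibull with scale ``exp(intercept +
    loading * L)`` and the given shape (accelerated-failure-time form).

    The conditional median is ``scale * ln(2)**(1/shape)``.
    """
    if not shape > 0:
        raise DomainError(f"Weibull shape must be > 0, got {shape}")
    latent_values = np.asarray(latent_values, dtype=float)
    scale = np.exp(intercept + loading * latent_values)
    return scale * rng.weibull(shape, size=latent_values.shape)


def sample_obesity(eta, rng) -> tuple[np.ndarray, float]:
    """Draw binary outcomes from ``Bernoulli(min(exp(eta), 1))``.

    Returns the flags and the fraction of observations whose probability had
    to be capped at 1; a capped fraction above 1% triggers a warning (the
    log-link Bernoulli model is not self-consistent at large eta).
    """
    eta = np.asarray(eta, dtype=float)
    pi = np.exp(np.minimum(eta, 0.0))
    capped = float(np.mean(eta > 0.0)) if eta.size else 0.0
    if capped > 0.01:
        warnings.warn(
            f"{capped:.1%} of linear predictors exceed 0 (probability capped at 1)",
            RuntimeWarning,
            stacklevel=2,
        )
    flags = (rng.random(eta.shape) < pi).astype(np.int64)
    return flags, capped


def calibrate_log_intercept(eta0, target) -> float:
    """Intercept ``a`` such that ``mean(min(exp(eta0 + a), 1)) == target``.

    Monotone in ``a``; solved by bracketed root finding on the realized
    linear predictors, so the calibration is deterministic given the sample.
    """
    eta0 = np.asarray(eta0, dtype=float)
    if eta0.size == 0:
        raise DomainError("cannot calibrate an intercept on an empty sample")

    def f(a):
        return float(np.mean(np.exp(np.minimum(eta0 + a, 0.0)))) - target

    return float(optimize.brentq(f, -30.0, 30.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# Full-dataset generation
# ---------------------------------------------------------------------------

def _sample_categorical(rng, probs: dict[str, float], n: int) -> np.ndarray:
    labels = list(probs.keys())
    p = np.asarray([probs[k] for k in labels], dtype=float)
    return rng.choice(labels, size=n, p=p / p.sum())


def generate_dataset(config: SyntheticConfig, seed: int | None = None) -> SyntheticDataset:
    """Generate ``config.n_persons`` synthetic survey participants.

    Deterministic given ``(config, seed)``; ``seed`` overrides
    ``config.seed`` when given.
    """
    if seed is None:
        seed = config.seed
    n = int(config.n_persons)
    m = config.covariate_margins
    ss = np.random.SeedSequence(seed)
    (rng_cov, rng_dept, rng_lat, rng_ind, rng_dis, rng_bmi, rng_w) = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )

    # Covariates -------------------------------------------------------
    female = (rng_cov.random(n) < m["female_prob"]).astype(float)
    lo, hi = m["age_range"]
    a, b = (lo - m["age_mean"]) / m["age_sd"], (hi - m["age_mean"]) / m["age_sd"]
    age = stats.truncnorm.rvs(
        a, b, loc=m["age_mean"], scale=m["age_sd"], size=n, random_state=rng_cov
    )
    ethnicity = _sample_categorical(rng_cov, m["ethnicity_probs"], n)
    schooling = _sample_categorical(rng_cov, m["schooling_probs"], n)
    wealth = _sample_categorical(rng_cov, m["wealth_probs"], n)
    energy = np.exp(rng_cov.normal(m["energy_log_mean"], m["energy_log_sd"], size=n))
    pa = np.where(
        rng_cov.random(n) < m["leisure_pa_zero_prob"],
        0.0,
        rng_cov.gamma(m["leisure_pa_gamma_shape"], m["leisure_pa_gamma_scale"], size=n),
    )

    # Departments ------------------------------------------------------
    codes = config.department_codes()
    if config.department_probs is not None:
        dept_p = np.asarray(config.department_probs, dtype=float)
    else:
        dept_p = np.exp(-0.07 * np.arange(config.department_count))
    dept_p = dept_p / dept_p.sum()
    dept_idx = rng_dept.choice(config.department_count, size=n, p=dept_p)
    dept_prev_shift = rng_dept.normal(0.0, config.dept_prevalence_shift_sd, config.department_count)
    dept_trans_shift = rng_dept.normal(0.0, config.dept_transport_shift_sd, config.department_count)

    # Latents ----------------------------------------------------------
    s1, s2 = config.latent_sds
    rho = config.latent_corr
    cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
    chol = np.linalg.cholesky(cov)
    z = rng_lat.standard_normal((n, 2))
    resid = z @ chol.T
    L1 = config.gamma_screens * pa + resid[:, 0]
    L2 = config.gamma_transport * pa + dept_trans_shift[dept_idx] + resid[:, 1]

    # Indicators -------------------------------------------------------
    times = {}
    for j in INDICATORS:
        lat = L1 if j in ("computer_smartphone", "tv", "videogames") else L2
        times[j] = sample_weibull_indicator(
            lat,
            config.loadings[j],
            config.indicator_intercepts[j],
            config.weibull_shapes[j],
            rng_ind,
        )

    # Obesity ----------------------------------------------------------
    c = config.disease_coefs
    eta0 = (
        c["L_screens"] * L1
        + c["L_transport"] * L2
        + c["female"] * female
        + c["age"] * age
        + c["eth_afro"] * (ethnicity == "afro")
        + c["eth_indigenous"] * (ethnicity == "indigenous")
        + c["school_secondary"] * (schooling == "secondary")
        + c["school_tertiary"] * (schooling == "tertiary")
        + c["wealth_q2"] * (wealth == "q2")
        + c["wealth_q3"] * (wealth == "q3")
        + c["wealth_q4"] * (wealth == "q4")
        + c["energy_kcal"] * energy
        + c["leisure_pa"] * pa
        + dept_prev_shift[dept_idx]
    )
    if c.get("intercept") is None:
        alpha = calibrate_log_intercept(eta0, config.target_prevalence) if n else 0.0
    else:
        alpha = float(c["intercept"])
    obesity, capped = sample_obesity(eta0 + alpha, rng_dis) if n else (np.zeros(0, int), 0.0)

    # BMI consistent with the obesity flag (flag is the analysis truth) --
    bmi = np.where(
        obesity == 1,
        30.0 + rng_bmi.gamma(1.8, 2.0, size=n),
        18.5 + 11.49 * rng_bmi.beta(2.2, 1.8, size=n),
    )

    # Expansion factors ------------------------------------------------
    if config.weight_model == "unit":
        weights = np.ones(n)
    else:
        cv = config.weight_cv
        weights = rng_w.gamma(1.0 / cv**2, cv**2, size=n)

    data = pd.DataFrame(
        {
            "sex": np.where(female == 1.0, "female", "male"),
            "age": age,
            "ethnicity": ethnicity,
            "schooling": schooling,
            "wealth_quartile": wealth,
            "energy_kcal": energy,
            "leisure_pa": pa,
            **{j: times[j] for j in INDICATORS},
            "bmi": bmi,
            "obesity": obesity,
            "expansion_factor": weights,
            "department": [codes[i] for i in dept_idx],
            "true_L1": L1,
            "true_L2": L2,
        }
    )
    meta = {
        "config": config.to_dict(),
        "seed": int(seed),
        "disease_intercept": float(alpha),
        "capped_fraction": float(capped),
        "department_codes": list(codes),
        "department_prevalence_shift": dept_prev_shift.tolist(),
        "department_transport_shift": dept_trans_shift.tolist(),
    }
    return SyntheticDataset(data=data, meta=meta)


def generate_measurement_dataset(
    latent: str, n: int, seed: int, config: SyntheticConfig | None = None
) -> pd.DataFrame:
    """Simulate one measurement block alone: ``L ~ N(0, sigma^2)`` and that
    latent's three Weibull indicators, with parameters from ``config``
    (defaults are the study conditions). ``latent`` is "screens" or
    "transport". Returns the indicator columns plus hidden ``true_L``."""
    config = config or SyntheticConfig()
    if latent == "screens":
        sigma, inds = config.latent_sds[0], INDICATORS[:3]
    elif latent == "transport":
        sigma, inds = config.latent_sds[1], INDICATORS[3:]
    else:
        raise DomainError(f"unknown latent {latent!r}")
    ss = np.random.SeedSequence(seed)
    rng_lat, rng_ind = (np.random.default_rng(s) for s in ss.spawn(2))
    L = sigma * rng_lat.standard_normal(n)
    cols = {
        j: sample_weibull_indicator(
            L, config.loadings[j], config.indicator_intercepts[j],
            config.weibull_shapes[j], rng_ind,
        )
        for j in inds
    }
    cols["true_L"] = L
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Exclusions and output
# ---------------------------------------------------------------------------

def apply_exclusions(
    records: pd.DataFrame,
    age_range: tuple[float, float] = (18.0, 64.0),
    energy_percentile_bounds: tuple[float, float] = (1.0, 99.0),
) -> tuple[pd.DataFrame, dict]:
    """Apply the study's eligibility filter: age inside ``age_range`` and
    energy intake within the empirical percentile bounds (inclusive).

    Energy percentiles (linear-interpolation convention) are computed on the
    age-eligible subset, mirroring sequential application of the criteria.
    Returns the retained rows and a log of counts removed per criterion.
    """
    log = {"n_input": int(len(records)), "removed_age": 0, "removed_energy": 0}
    if len(records) == 0:
        log["n_retained"] = 0
        return records.copy(), log
    ok_age = (records["age"] >= age_range[0]) & (records["age"] <= age_range[1])
    log["removed_age"] = int((~ok_age).sum())
    kept = records.loc[ok_age]
    if len(kept):
        lo, hi = np.percentile(kept["energy_kcal"], list(energy_percentile_bounds))
        ok_energy = (kept["energy_kcal"] >= lo) & (kept["energy_kcal"] <= hi)
        log["removed_energy"] = int((~ok_energy).sum())
        kept = kept.loc[ok_energy]
    log["n_retained"] = int(len(kept))
    return kept.copy(), log


def write_dataset(dataset: SyntheticDataset, path) -> None:
    """Write the person table as CSV with a JSON sidecar holding the
    generating config, seed and calibration metadata."""
    path = str(path)
    dataset.data.to_csv(path, index=False)
    sidecar = path[: -len(".csv")] + ".meta.json" if path.endswith(".csv") else path + ".meta.json"
    with open(sidecar, "w") as fh:
        json.dump(dataset.meta, fh, indent=2)
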