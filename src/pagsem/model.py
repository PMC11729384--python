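"""Model structure for the generalized SEM.

A :class:`GsemSpec` declares the joint model: latent constructs measured by
strictly positive weekly-minute indicators (Weibull, accelerated-failure-time
form ``log scale = kappa_j + lambda_j * L``), optional structural regressions
of each latent on observed covariates, and an optional log-link Bernoulli
("modified Poisson") disease model for a binary outcome.

:class:`ParameterVector` holds every free parameter on its natural scale and
defines a fixed packing order into a flat vector, used by the likelihood and
the optimizer. Internally shapes are log-parameterized and the latent residual
covariance is log-Cholesky-parameterized, so the flat vector is unconstrained.

Packing order (documented contract):

1. indicator intercepts ``kappa_j`` (latents in declared order, indicators in
   declared order within each latent);
2. free loadings ``lambda_j`` (same order, skipping each latent's reference
   indicator, whose loading is fixed at 1);
3. indicator log shapes ``log k_j`` (same order as the intercepts);
4. structural coefficients ``gamma`` (latents in order, covariates in order);
5. latent residual covariance, lower Cholesky with log diagonal
   (``log l11`` for one latent; ``log l11, l21, log l22`` for two);
6. disease coefficients: intercept, then one coefficient per latent (declared
   order), then one per covariate term (declared order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DomainError

__all__ = [
    "LatentSpec",
    "DiseaseSpec",
    "GsemSpec",
    "ParameterVector",
    "default_study_spec",
    "screens_measurement_spec",
    "transport_measurement_spec",
    "encode_study_covariates",
    "STUDY_DISEASE_COVARIATES",
]


@dataclass(frozen=True)
class LatentSpec:
    """One latent construct and its indicator block."""

    name: str
    indicators: tuple[str, ...]
    reference: str

    def __post_init__(self):
        object.__setattr__(self, "indicators", tuple(self.indicators))
        if len(set(self.indicators)) != len(self.indicators):
            raise ConfigError("indicators", f"duplicate indicator in latent {self.name!r}")
        if self.reference not in self.indicators:
            raise ConfigError(
                "reference",
                f"reference {self.reference!r} is not an indicator of latent {self.name!r}",
            )


@dataclass(frozen=True)
class DiseaseSpec:
    """Log-link model for a binary outcome on covariates and latents."""

    outcome: str
    covariates: tuple[str, ...]
    family: str = "bernoulli-log"

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.family not in ("bernoulli-log", "poisson-log"):
            raise ConfigError("family", f"unknown disease family {self.family!r}")


@dataclass(frozen=True)
class GsemSpec:
    """Declarative structure of the joint model.

    ``structural`` maps a latent name to the covariate columns its mean is
    regressed on (no intercept: latent location is absorbed by the indicator
    intercepts). ``weight_col`` names a per-person expansion-factor column;
    weights multiply each person's log-likelihood contribution.
    """

    latents: tuple[LatentSpec, ...]
    structural: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    disease: DiseaseSpec | None = None
    weight_col: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "latents", tuple(self.latents))
        object.__setattr__(
            self, "structural", {k: tuple(v) for k, v in dict(self.structural).items()}
        )
        seen: set[str] = set()
        for lat in self.latents:
            for ind in lat.indicators:
                if ind in seen:
                    raise ConfigError(
                        "latents", f"indicator {ind!r} belongs to more than one latent"
                    )
                seen.add(ind)
        names = [lat.name for lat in self.latents]
        if len(set(names)) != len(names):
            raise ConfigError("latents", "duplicate latent names")
        for key in self.structural:
            if key not in names:
                raise ConfigError("structural", f"unknown latent {key!r}")
        if len(self.latents) > 2:
            raise ConfigError("latents", "at most two latent dimensions are supported")
        if self.disease is None and not self.latents:
            raise ConfigError("latents", "model must contain latents or a disease model")

    # -- derived ---------------------------------------------------------
    @property
    def latent_names(self) -> tuple[str, ...]:
        return tuple(lat.name for lat in self.latents)

    @property
    def indicator_names(self) -> tuple[str, ...]:
        return tuple(ind for lat in self.latents for ind in lat.indicators)

    @property
    def n_latents(self) -> int:
        return len(self.latents)

    def structural_covariates(self, latent: str) -> tuple[str, ...]:
        return tuple(self.structural.get(latent, ()))

    # -- (de)serialization -----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "latents": [
                {"name": l.name, "indicators": list(l.indicators), "reference": l.reference}
                for l in self.latents
            ],
            "structural": {k: list(v) for k, v in self.structural.items()},
            "disease": None
            if self.disease is None
            else {
                "outcome": self.disease.outcome,
                "covariates": list(self.disease.covariates),
                "family": self.disease.family,
            },
            "weight_col": self.weight_col,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GsemSpec":
        disease = d.get("disease")
        return cls(
            latents=tuple(
                LatentSpec(x["name"], tuple(x["indicators"]), x["reference"])
                for x in d.get("latents", [])
            ),
            structural={k: tuple(v) for k, v in (d.get("structural") or {}).items()},
            disease=None
            if disease is None
            else DiseaseSpec(
                outcome=disease["outcome"],
                covariates=tuple(disease["covariates"]),
                family=disease.get("family", "bernoulli-log"),
            ),
            weight_col=d.get("weight_col"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GsemSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- parameter bookkeeping -------------------------------------------
    def free_parameter_names(self) -> list[str]:
        """Names of the free parameters in packing order."""
        names: list[str] = []
        names += [f"kappa[{j}]" for j in self.indicator_names]
        for lat in self.latents:
            names += [f"loading[{j}]" for j in lat.indicators if j != lat.reference]
        names += [f"log_shape[{j}]" for j in self.indicator_names]
        for lat in self.latents:
            names += [
                f"gamma[{lat.name}~{c}]" for c in self.structural_covariates(lat.name)
            ]
        d = self.n_latents
        if d == 1:
            names += ["psi[log_l11]"]
        elif d == 2:
            names += ["psi[log_l11]", "psi[l21]", "psi[log_l22]"]
        if self.disease is not None:
            names += ["disease[const]"]
            names += [f"disease[L:{name}]" for name in self.latent_names]
            names += [f"disease[{c}]" for c in self.disease.covariates]
        return names

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_parameter_names())


@dataclass
class ParameterVector:
    """All free parameters on their natural scale.

    ``psi`` is the latent residual covariance (d x d, SPD). ``loadings``
    includes the reference indicators with value 1; they are not packed.
    """

    spec: GsemSpec
    kappa: dict[str, float]
    loadings: dict[str, float]
    shapes: dict[str, float]
    gamma: dict[tuple[str, str], float]
    psi: np.ndarray
    disease: dict[str, float]

    def __post_init__(self):
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        d = self.spec.n_latents
        if d and self.psi.shape != (d, d):
            raise DomainError(f"psi must be {d}x{d}, got {self.psi.shape}")
        if d:
            if not np.allclose(self.psi, self.psi.T):
                raise DomainError("psi must be symmetric")
            if np.any(np.linalg.eigvalsh(self.psi) <= 0):
                raise DomainError("psi must be positive definite")
        for j, k in self.shapes.items():
            if not k > 0:
                raise DomainError(f"Weibull shape for {j!r} must be > 0, got {k}")
        for lat in self.spec.latents:
            self.loadings.setdefault(lat.reference, 1.0)

    # ------------------------------------------------------------------
    def pack(self) -> np.ndarray:
        """Flatten to the unconstrained vector in the documented order."""
        spec = self.spec
        out: list[float] = []
        out += [self.kappa[j] for j in spec.indicator_names]
        for lat in spec.latents:
            out += [self.loadings[j] for j in lat.indicators if j != lat.reference]
        out += [float(np.log(self.shapes[j])) for j in spec.indicator_names]
        for lat in spec.latents:
            out += [self.gamma[(lat.name, c)] for c in spec.structural_covariates(lat.name)]
        d = spec.n_latents
        if d:
            L = np.linalg.cholesky(self.psi)
            if d == 1:
                out += [float(np.log(L[0, 0]))]
            else:
                out += [float(np.log(L[0, 0])), float(L[1, 0]), float(np.log(L[1, 1]))]
        if spec.disease is not None:
            out += [self.disease["const"]]
            out += [self.disease[f"L:{name}"] for name in spec.latent_names]
            out += [self.disease[c] for c in spec.disease.covariates]
        return np.asarray(out, dtype=float)

    @classmethod
    def unpack(cls, x: np.ndarray, spec: GsemSpec) -> "ParameterVector":
        """Inverse of :meth:`pack`."""
        x = np.asarray(x, dtype=float)
        if x.shape != (spec.n_free_parameters,):
            raise DomainError(
                f"expected {spec.n_free_parameters} free parameters, got {x.shape}"
            )
        pos = 0

        def take(k: int) -> np.ndarray:
            nonlocal pos
            out = x[pos : pos + k]
            pos += k
            return out

        inds = spec.indicator_names
        kappa = dict(zip(inds, take(len(inds))))
        loadings: dict[str, float] = {}
        for lat in spec.latents:
            free = [j for j in lat.indicators if j != lat.reference]
            loadings.update(zip(free, take(len(free))))
            loadings[lat.reference] = 1.0
        shapes = dict(zip(inds, np.exp(take(len(inds)))))
        gamma: dict[tuple[str, str], float] = {}
        for lat in spec.latents:
            covs = spec.structural_covariates(lat.name)
            gamma.update({(lat.name, c): v for c, v in zip(covs, take(len(covs)))})
        d = spec.n_latents
        if d == 0:
            psi = np.zeros((0, 0))
        elif d == 1:
            l11 = np.exp(take(1)[0])
            psi = np.array([[l11**2]])
        else:
            log_l11, l21, log_l22 = take(3)
            L = np.array([[np.exp(log_l11), 0.0], [l21, np.exp(log_l22)]])
            psi = L @ L.T
        disease: dict[str, float] = {}
        if spec.disease is not None:
            disease["const"] = take(1)[0]
            for name in spec.latent_names:
                disease[f"L:{name}"] = take(1)[0]
            for c in spec.disease.covariates:
                disease[c] = take(1)[0]
        return cls(
            spec=spec,
            kappa={k: float(v) for k, v in kappa.items()},
            loadings={k: float(v) for k, v in loadings.items()},
            shapes={k: float(v) for k, v in shapes.items()},
            gamma={k: float(v) for k, v in gamma.items()},
            psi=psi,
            disease={k: float(v) for k, v in disease.items()},
        )


# ---------------------------------------------------------------------------
# Study model: two latent dimensions, six indicators, obesity outcome.
# ---------------------------------------------------------------------------

SCREENS_INDICATORS = ("computer_smartphone", "tv", "videogames")
TRANSPORT_INDICATORS = ("motor_vehicle", "cycling", "walking")

#: Disease-model covariate terms (dummy-encoded; see encode_study_covariates).
STUDY_DISEASE_COVARIATES = (
    "female",
    "age",
    "eth_afro",
    "eth_indigenous",
    "school_secondary",
    "school_tertiary",
    "wealth_q2",
    "wealth_q3",
    "wealth_q4",
    "energy_kcal",
    "leisure_pa",
)


def screens_measurement_spec(structural: bool = False) -> GsemSpec:
    """Measurement model for the "Screens use" latent alone."""
    return GsemSpec(
        latents=(LatentSpec("screens", SCREENS_INDICATORS, "computer_smartphone"),),
        structural={"screens": ("leisure_pa",)} if structural else {},
    )


def transport_measurement_spec(structural: bool = False) -> GsemSpec:
    """Measurement model for the "Active transportation" latent alone."""
    return GsemSpec(
        latents=(LatentSpec("transport", TRANSPORT_INDICATORS, "motor_vehicle"),),
        structural={"transport": ("leisure_pa",)} if structural else {},
    )


def default_study_spec(weight_col: str | None = "expansion_factor") -> GsemSpec:
    """Full joint model: both latents, structural paths from leisure-time
    physical activity, and the log-link obesity model."""
    return GsemSpec(
        latents=(
            LatentSpec("screens", SCREENS_INDICATORS, "computer_smartphone"),
            LatentSpec("transport", TRANSPORT_INDICATORS, "motor_vehicle"),
        ),
        structural={"screens": ("leisure_pa",), "transport": ("leisure_pa",)},
        disease=DiseaseSpec(outcome="obesity", covariates=STUDY_DISEASE_COVARIATES),
        weight_col=weight_col,
    )


def encode_study_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Append dummy-encoded covariate columns used by the disease model.

    Reference categories: male, "other" ethnicity, primary schooling,
    wealth quartile 1 — matching the study's reporting.
    """
    out = df.copy()
    if "sex" in out:
        out["female"] = (out["sex"] == "female").astype(float)
    if "ethnicity" in out:
        out["eth_afro"] = (out["ethnicity"] == "afro").astype(float)
        out["eth_indigenous"] = (out["ethnicity"] == "indigenous").astype(float)
    if "schooling" in out:
        out["school_secondary"] = (out["schooling"] == "secondary").astype(float)
        out["school_tertiary"] = (out["schooling"] == "tertiary").astype(float)
    if "wealth_quartile" in out:
        for q in (2, 3, 4):
            out[f"wealth_q{q}"] = (out["wealth_quartile"] == f"q{q}").astype(float)
    return out
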