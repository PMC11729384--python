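"""Direct and indirect effects from a fitted joint model.

Direct effects are prevalence ratios ``exp(beta)`` per disease-model term
with Wald intervals ``exp(beta +/- 1.96 se)``. Indirect effects of a
structural predictor through a latent are products of the path coefficient
into the latent and that latent's disease coefficient, reported on the
coefficient (log) scale — they are small signed numbers, not ratios — with
delta-method standard errors using the joint covariance of the two
coefficients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .fitting import FittedModel

__all__ = ["prevalence_ratio_table", "indirect_effects", "effect_table"]

_Z95 = 1.959963984540054


def _check_vcov_choice(vcov: str) -> bool:
    if vcov not in ("model", "robust"):
        raise DomainError(f"vcov must be 'model' or 'robust', got {vcov!r}")
    return vcov == "robust"


def prevalence_ratio_table(fitted: FittedModel, vcov: str = "robust",
                           include_intercept: bool = False) -> pd.DataFrame:
    """Prevalence ratios for every disease-model term.

    The choice of covariance affects intervals and p-values only, never the
    point estimates.
    """
    robust = _check_vcov_choice(vcov)
    if fitted.spec.disease is None:
        raise DomainError("fitted model has no disease model")
    if not fitted.converged:
        raise DomainError("effects require a converged fit")
    terms = []
    if include_intercept:
        terms.append(("const", "disease[const]"))
    terms += [(f"L:{name}", f"disease[L:{name}]") for name in fitted.spec.latent_names]
    terms += [(c, f"disease[{c}]") for c in fitted.spec.disease.covariates]
    rows = []
    for label, pname in terms:
        b = fitted.estimate(pname)
        se = fitted.se(pname, robust=robust)
        z = b / se if se > 0 else np.inf * np.sign(b)
        rows.append(
            {
                "term": label,
                "effect_type": "direct",
                "coef": b,
                "se": se,
                "pr": float(np.exp(b)),
                "ci_low": float(np.exp(b - _Z95 * se)),
                "ci_high": float(np.exp(b + _Z95 * se)),
                "p_value": float(2.0 * stats.norm.sf(abs(z))),
            }
        )
    return pd.DataFrame(rows)


def indirect_effects(fitted: FittedModel, vcov: str = "robust") -> pd.DataFrame:
    """Product-of-paths indirect effects for every (structural predictor,
    latent) pair: ``gamma_hat * beta_hat`` on the log scale, delta-method
    standard error ``se^2 = beta^2 se(g)^2 + g^2 se(b)^2 + 2 g b cov``."""
    robust = _check_vcov_choice(vcov)
    if fitted.spec.disease is None:
        raise DomainError("fitted model has no disease model")
    V = fitted.vcov(robust=robust)
    rows = []
    for lat in fitted.spec.latents:
        bname = f"disease[L:{lat.name}]"
        for cov_name in fitted.spec.structural_covariates(lat.name):
            gname = f"gamma[{lat.name}~{cov_name}]"
            gi, bi = fitted.index_of(gname), fitted.index_of(bname)
            g, b = fitted.estimate(gname), fitted.estimate(bname)
            var = (
                b**2 * V[gi, gi] + g**2 * V[bi, bi] + 2.0 * g * b * V[gi, bi]
            )
            if not np.isfinite(var):
                raise DomainError(f"missing covariance entries for {gname}, {bname}")
            se = float(np.sqrt(max(var, 0.0)))
            est = g * b
            z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
            rows.append(
                {
                    "term": f"{cov_name} -> {lat.name}",
                    "effect_type": "indirect",
                    "coef": est,
                    "se": se,
                    "pr": np.nan,
                    "ci_low": est - _Z95 * se,
                    "ci_high": est + _Z95 * se,
                    "p_value": float(2.0 * stats.norm.sf(abs(z))),
                }
            )
    return pd.DataFrame(rows)


def effect_table(fitted: FittedModel, vcov: str = "robust") -> pd.DataFrame:
    """Direct prevalence ratios followed by indirect path products."""
    return pd.concat(
        [prevalence_ratio_table(fitted, vcov), indirect_effects(fitted, vcov)],
        ignore_index=True,
    )
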