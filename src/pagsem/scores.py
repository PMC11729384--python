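"""Empirical-Bayes latent scores ("adherence") and tertile categories.

Per person, the posterior mean and SD of each latent given the observed
indicators, covariates and (by default) the outcome, computed with the same
adaptive Gauss-Hermite machinery as the likelihood. Tertiles of the score
distribution define low / moderate / high adherence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DomainError
from .fitting import FittedModel
from .likelihood import JointModel

__all__ = ["LatentScores", "eb_scores", "adherence_tertiles"]

TERTILE_LABELS = ("low", "moderate", "high")


@dataclass
class LatentScores:
    """Per-person posterior summaries, one column block per latent:
    ``<latent>_mean``, ``<latent>_sd``, ``<latent>_tertile``."""

    frame: pd.DataFrame
    latents: tuple[str, ...]

    def means(self, latent: str) -> np.ndarray:
        return self.frame[f"{latent}_mean"].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LatentScores":
        frame = pd.read_csv(path)
        latents = tuple(c[: -len("_mean")] for c in frame.columns if c.endswith("_mean"))
        return cls(frame=frame, latents=latents)


def eb_scores(
    fitted: FittedModel,
    data: pd.DataFrame,
    n_quad: int | None = None,
    condition_on_outcome: bool = True,
) -> LatentScores:
    """Empirical-Bayes posterior means and SDs of the latents.

    ``condition_on_outcome=False`` scores from the indicators (and the
    structural prior) alone. Records with missing indicators raise: the
    model is a complete-case likelihood.
    """
    if not fitted.converged:
        raise ConvergenceError("empirical-Bayes scores require a converged fit")
    if fitted.spec.n_latents == 0:
        raise DomainError("fitted model has no latent variables")
    mm = JointModel(
        fitted.spec,
        data,
        n_quad=n_quad if n_quad is not None else 15,
        include_disease=condition_on_outcome,
    )
    mean, sd = mm.posterior_moments(fitted.estimates)
    cols = {}
    for li, name in enumerate(fitted.spec.latent_names):
        cols[f"{name}_mean"] = mean[:, li]
        cols[f"{name}_sd"] = sd[:, li]
        cols[f"{name}_tertile"] = adherence_tertiles(mean[:, li])
    return LatentScores(frame=pd.DataFrame(cols), latents=fitted.spec.latent_names)


def adherence_tertiles(scores, weights=None) -> np.ndarray:
    """Cut scores at the empirical 1/3 and 2/3 quantiles (type-7,
    linear-interpolation convention) into low / moderate / high.

    Intervals are left-closed on the upper side: ``low`` below the first
    tertile, ``moderate`` in [t1, t2), ``high`` at or above the second.
    Ties share the category of their interval. A degenerate (constant)
    distribution yields all-"low" with a warning. ``weights`` switches to
    weighted quantiles (interpolated weighted CDF).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise DomainError("tertiles need at least 3 observations")
    if weights is None:
        t1, t2 = np.quantile(scores, [1.0 / 3.0, 2.0 / 3.0])
    else:
        weights = np.asarray(weights, dtype=float)
        order = np.argsort(scores, kind="stable")
        cw = np.cumsum(weights[order])
        cdf = (cw - 0.5 * weights[order]) / cw[-1]
        t1, t2 = np.interp([1.0 / 3.0, 2.0 / 3.0], cdf, scores[order])
    if t1 == t2 and np.all(scores == scores[0]):
        warnings.warn("degenerate score distribution; all tertiles set to 'low'",
                      RuntimeWarning, stacklevel=2)
        return np.full(scores.shape, TERTILE_LABELS[0], dtype=object)
    out = np.full(scores.shape, TERTILE_LABELS[1], dtype=object)
    out[scores < t1] = TERTILE_LABELS[0]
    out[scores >= t2] = TERTILE_LABELS[2]
    return out
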