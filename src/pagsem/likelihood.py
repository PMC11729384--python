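"""Joint marginal likelihood of the generalized SEM.

Each person's contribution integrates, over the (at most bivariate) Gaussian
latent vector, the product of the Weibull indicator densities, the log-link
Bernoulli outcome probability and the latent prior density. The integral is
approximated by adaptive Gauss--Hermite quadrature: per person, a damped
Newton search locates the posterior mode of the integrand, the quadrature
grid is recentered and rescaled by the mode curvature, and the log integral
is accumulated with log-sum-exp.

Analytic parameter scores are propagated through the quadrature (nodes held
fixed, the standard treatment: the value of an adaptively centered rule is
insensitive to the center to quadrature accuracy), giving per-person score
vectors for the total gradient and the sandwich variance.

To keep the Bernoulli density proper when the log link would give
``pi >= 1``, the linear predictor is passed through a smooth soft-min cap at
``-1e-8`` (log-sum-exp with sharpness 200); the cap is inactive to machine
precision for any predictor below about -0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import DomainError, NumericalError
from .model import GsemSpec, ParameterVector

__all__ = ["JointModel", "joint_loglikelihood"]

_CAP_C = -1e-8  # soft upper cap on the disease linear predictor
_CAP_S = 200.0  # sharpness of the soft-min
# Clip on exponents just below overflow: keeps exp() finite while preserving
# w - e^w <= -1, so the log-density can never become spuriously positive.
_W_CLIP = 700.0
_LOG2PI = float(np.log(2.0 * np.pi))


def _soft_cap(eta):
    """Smooth min(eta, _CAP_C); returns (capped value, d capped / d eta).

    Below -0.1 the cap is inactive to double precision (the correction is
    O(exp(-20))), so the transcendental work is restricted to the rare
    near-zero predictors.
    """
    eta = np.asarray(eta, dtype=float)
    m = eta.copy()
    sig = np.ones_like(eta)
    hot = eta > -0.1
    if hot.any():
        a1 = -_CAP_S * eta[hot]
        a2 = -_CAP_S * _CAP_C
        lse = np.logaddexp(a1, a2)
        m[hot] = -lse / _CAP_S
        sig[hot] = np.exp(a1 - lse)
    return m, sig


class _Params:
    """Internal unpacked parameter block (log/Cholesky transforms applied)."""

    __slots__ = ("kappa", "lam", "shape", "gamma", "chol", "psi_inv", "logdet_chol", "x")

    def __init__(self, x: np.ndarray, mm: "JointModel"):
        self.x = np.asarray(x, dtype=float)
        if self.x.shape != (mm.n_free,):
            raise DomainError(f"expected {mm.n_free} free parameters, got {self.x.shape}")
        s = mm._slices
        self.kappa = self.x[s["kappa"]]
        lam = np.ones(mm.J)
        lam[mm._free_loading_idx] = self.x[s["loading"]]
        self.lam = lam
        self.shape = np.exp(self.x[s["log_shape"]])
        self.gamma = [self.x[sl] for sl in s["gamma"]]
        d = mm.d
        if d == 1:
            l11 = np.exp(self.x[s["psi"]][0])
            self.chol = np.array([[l11]])
        elif d == 2:
            p = self.x[s["psi"]]
            self.chol = np.array([[np.exp(p[0]), 0.0], [p[1], np.exp(p[2])]])
        else:
            self.chol = np.zeros((0, 0))
        if d:
            cinv = np.linalg.inv(self.chol)
            self.psi_inv = cinv.T @ cinv
            self.logdet_chol = float(np.sum(np.log(np.diag(self.chol))))
        else:
            self.psi_inv = np.zeros((0, 0))
            self.logdet_chol = 0.0


class JointModel:
    """Likelihood evaluator bound to one (spec, dataset) pair.

    Zero indicator times are shifted to 1 minute before log/Weibull
    modelling (the generator never produces zeros; this is the real-data
    contract). Negative times and missing values raise.
    """

    def __init__(self, spec: GsemSpec, data: pd.DataFrame, n_quad: int = 15,
                 adaptive: bool = True, include_disease: bool = True):
        if n_quad < 3:
            raise DomainError("quadrature needs at least 3 nodes per dimension")
        self.spec = spec
        self.n_quad = int(n_quad)
        self.adaptive = bool(adaptive)
        self.d = spec.n_latents
        # has_disease: disease parameters exist in the packed vector;
        # use_disease: the disease term enters the integrand (scores condition
        # on the outcome only when it does).
        self.has_disease = spec.disease is not None
        self.use_disease = self.has_disease and include_disease

        inds = spec.indicator_names
        self.J = len(inds)
        missing = [c for c in inds if c not in data.columns]
        if missing:
            raise DomainError(f"data is missing indicator columns {missing}")
        T = data[list(inds)].to_numpy(dtype=float, copy=True)
        if np.isnan(T).any():
            bad = int(np.where(np.isnan(T).any(axis=1))[0][0])
            raise DomainError(f"record {bad} has a missing indicator (complete cases only)")
        if (T < 0).any():
            raise DomainError("indicator times must be nonnegative")
        T[T == 0.0] = 1.0
        self.logT = np.log(T)
        self.n = len(data)

        # indicator -> latent index
        lat_of = {}
        for li, lat in enumerate(spec.latents):
            for j in lat.indicators:
                lat_of[j] = li
        self._lat_idx = np.array([lat_of[j] for j in inds], dtype=int)
        ref = {lat.reference for lat in spec.latents}
        self._free_loading_idx = np.array(
            [i for i, j in enumerate(inds) if j not in ref], dtype=int
        )

        # disease design
        if self.use_disease:
            dis = spec.disease
            if dis.outcome not in data.columns:
                raise DomainError(f"data is missing outcome column {dis.outcome!r}")
            y = data[dis.outcome].to_numpy(dtype=float)
            if not np.isin(y, (0.0, 1.0)).all():
                raise DomainError("disease outcome must be binary 0/1")
            self.y = y
            miss = [c for c in dis.covariates if c not in data.columns]
            if miss:
                raise DomainError(f"data is missing covariate columns {miss}")
            self.X = np.column_stack(
                [np.ones(self.n)] + [data[c].to_numpy(dtype=float) for c in dis.covariates]
            )
            if np.isnan(self.X).any():
                raise DomainError("missing values in disease covariates")
            self.family = dis.family
        else:
            self.y = self.X = None
            self.family = None

        # structural designs
        self.S = []
        for lat in spec.latents:
            covs = spec.structural_covariates(lat.name)
            if covs:
                self.S.append(np.column_stack([data[c].to_numpy(dtype=float) for c in covs]))
            else:
                self.S.append(np.zeros((self.n, 0)))

        # weights
        if spec.weight_col is not None:
            if spec.weight_col not in data.columns:
                raise DomainError(f"data is missing weight column {spec.weight_col!r}")
            w = data[spec.weight_col].to_numpy(dtype=float)
            if (w <= 0).any():
                raise DomainError("expansion factors must be strictly positive")
            self.weights = w
        else:
            self.weights = np.ones(self.n)

        # free-parameter slices in packing order
        names = spec.free_parameter_names()
        self.n_free = len(names)
        self.param_names = names
        pos = 0
        sl = {}
        sl["kappa"] = slice(pos, pos + self.J); pos += self.J
        nfree = len(self._free_loading_idx)
        sl["loading"] = slice(pos, pos + nfree); pos += nfree
        sl["log_shape"] = slice(pos, pos + self.J); pos += self.J
        sl["gamma"] = []
        for lat in spec.latents:
            k = len(spec.structural_covariates(lat.name))
            sl["gamma"].append(slice(pos, pos + k)); pos += k
        npsi = {0: 0, 1: 1, 2: 3}[self.d]
        sl["psi"] = slice(pos, pos + npsi); pos += npsi
        if self.has_disease:
            nb = 1 + len(spec.disease.covariates)
            # disease vector order: const, latent terms, covariates
            sl["disease_const"] = pos
            sl["disease_bL"] = slice(pos + 1, pos + 1 + self.d)
            sl["disease_cov"] = slice(pos + 1 + self.d, pos + self.d + nb)
            pos += self.d + nb
        self._slices = sl
        if pos != self.n_free:
            raise NumericalError("parameter bookkeeping mismatch")

        # quadrature grid
        u, wq = np.polynomial.hermite.hermgauss(self.n_quad)
        if self.d == 2:
            U1, U2 = np.meshgrid(u, u, indexing="ij")
            self.U = np.column_stack([U1.ravel(), U2.ravel()])
            logw = np.add.outer(np.log(wq), np.log(wq)).ravel()
        elif self.d == 1:
            self.U = u[:, None]
            logw = np.log(wq)
        else:
            self.U = np.zeros((0, 0))
            logw = np.zeros(0)
        if self.d:
            self.Q = self.U.shape[0]
            self.logw_base = logw + (self.U**2).sum(axis=1) + 0.5 * self.d * np.log(2.0)
        self._modes = None  # warm-start cache for posterior modes
        self._frozen = None  # (zeta, loga) when the adaptation is frozen

    # -- parameter access ----------------------------------------------
    def _dis_b(self, P: _Params) -> tuple[np.ndarray, np.ndarray]:
        """(b over [const, covariates], bL over latents)."""
        x = P.x
        b = np.concatenate(([x[self._slices["disease_const"]]], x[self._slices["disease_cov"]]))
        bL = x[self._slices["disease_bL"]]
        return b, bL

    # -- disease pieces --------------------------------------------------
    def _dis_terms(self, eta, order: int):
        """Log-likelihood of the outcome given the linear predictor, with
        derivatives w.r.t. eta up to ``order``."""
        y = self.y
        if self.family == "poisson-log":
            pi = np.exp(np.minimum(eta, _W_CLIP))
            ll = y * eta - pi
            if order == 0:
                return ll, None, None
            d1 = y - pi
            if order == 1:
                return ll, d1, None
            return ll, d1, -pi
        m, sig = _soft_cap(eta)
        em = -np.expm1(m)  # 1 - e^m in (0, 1)
        ll = y * m + (1.0 - y) * np.log(em)
        if order == 0:
            return ll, None, None
        ratio = np.exp(m) / em
        dldm = y - (1.0 - y) * ratio
        d1 = dldm * sig
        if order == 1:
            return ll, d1, None
        d2ldm = -(1.0 - y) * ratio / em
        dsig = -_CAP_S * sig * (1.0 - sig)
        d2 = d2ldm * sig**2 + dldm * dsig
        return ll, d1, d2

    # -- integrand pieces at arbitrary latent values ---------------------
    def _h_value(self, P: _Params, L: np.ndarray) -> np.ndarray:
        """Complete-data log density h(L) per person, L of shape (n, d)."""
        h = np.zeros(self.n)
        for j in range(self.J):
            k, lam = P.shape[j], P.lam[j]
            w = k * (self.logT[:, j] - P.kappa[j] - lam * L[:, self._lat_idx[j]])
            h += np.log(k) - self.logT[:, j] + w - np.exp(np.minimum(w, _W_CLIP))
        if self.use_disease:
            b, bL = self._dis_b(P)
            eta = self.X @ b + L @ bL
            ll, _, _ = self._dis_terms(eta, order=0)
            h += ll
        mu = self._latent_means(P)
        delta = L - mu
        z = np.linalg.solve(P.chol, delta.T).T if self.d else delta
        h += -0.5 * self.d * _LOG2PI - P.logdet_chol - 0.5 * (z**2).sum(axis=1)
        return h

    def _latent_means(self, P: _Params) -> np.ndarray:
        mu = np.zeros((self.n, self.d))
        for li in range(self.d):
            if self.S[li].shape[1]:
                mu[:, li] = self.S[li] @ P.gamma[li]
        return mu

    def _h_grad_hess(self, P: _Params, L: np.ndarray):
        """Gradient (n,d) and Hessian (n,d,d) of h at L."""
        n, d = self.n, self.d
        g = np.zeros((n, d))
        H = np.zeros((n, d, d))
        for j in range(self.J):
            k, lam = P.shape[j], P.lam[j]
            li = self._lat_idx[j]
            w = k * (self.logT[:, j] - P.kappa[j] - lam * L[:, li])
            ew = np.exp(np.minimum(w, _W_CLIP))
            g[:, li] += k * lam * (ew - 1.0)
            H[:, li, li] += -(k * lam) ** 2 * ew
        if self.use_disease:
            b, bL = self._dis_b(P)
            eta = self.X @ b + L @ bL
            _, d1, d2 = self._dis_terms(eta, order=2)
            g += d1[:, None] * bL[None, :]
            H += d2[:, None, None] * np.einsum("i,j->ij", bL, bL)[None, :, :]
        mu = self._latent_means(P)
        g += -(L - mu) @ P.psi_inv
        H += -P.psi_inv[None, :, :]
        return g, H

    # -- posterior modes -------------------------------------------------
    def _find_modes(self, P: _Params, tol: float = 1e-8, max_iter: int = 60) -> np.ndarray:
        mu = self._latent_means(P)
        L = self._modes.copy() if self._modes is not None else mu.copy()
        # sanitize the warm-start cache (a previous evaluation at absurd
        # parameters must not poison this one) and start each person from
        # the better of the cached mode and the prior mean: Newton creeps
        # on the double-exponential tail of the Weibull term, so a far-off
        # start may not be recoverable within the iteration budget.
        L = np.clip(L, -1e6, 1e6)
        bad = ~np.isfinite(L).all(axis=1)
        if bad.any():
            L[bad] = mu[bad]
        hval = self._h_value(P, L)
        h_mu = self._h_value(P, mu)
        worse = ~(hval >= h_mu)  # catches NaN as well
        if worse.any():
            L[worse] = mu[worse]
            hval = np.where(worse, h_mu, hval)
        L, hval = self._newton_modes(P, L, hval, tol, max_iter)
        # rescue stragglers with a fresh start from the prior mean
        g, _ = self._h_grad_hess(P, L)
        bad = np.abs(g).max(axis=1) > 1e-4
        if bad.any():
            L2 = L.copy()
            L2[bad] = mu[bad]
            hv2 = self._h_value(P, L2)
            L2, hv2 = self._newton_modes(P, L2, hv2, tol, max_iter)
            better = hv2 > hval
            L[better] = L2[better]
        bad = ~np.isfinite(L).all(axis=1)
        if bad.any():
            L[bad] = mu[bad]
        self._modes = L.copy()
        return L

    def _newton_modes(self, P: _Params, L, hval, tol, max_iter):
        for _ in range(max_iter):
            g, H = self._h_grad_hess(P, L)
            if np.max(np.abs(g)) < tol:
                break
            step = self._solve_neg(H, g)
            step = np.clip(np.nan_to_num(step, nan=0.0, posinf=1e3, neginf=-1e3),
                           -1e3, 1e3)
            t = np.ones(self.n)
            active = np.ones(self.n, dtype=bool)
            for _ in range(12):
                Lnew = L + t[:, None] * step
                hnew = self._h_value(P, Lnew)
                worse = active & (hnew < hval - 1e-12) & np.isfinite(hval)
                worse |= active & ~np.isfinite(hnew)
                if not worse.any():
                    L = np.where(active[:, None], Lnew, L)
                    hval = np.where(active, hnew, hval)
                    break
                ok = active & ~worse
                if ok.any():
                    L[ok] = Lnew[ok]
                    hval[ok] = hnew[ok]
                    active &= worse
                t[worse] *= 0.5
            else:
                pass
        return L, hval

    def _solve_neg(self, H, g):
        """Solve (-H) step = g per person with a ridge fallback."""
        if self.d == 1:
            a = -H[:, 0, 0]
            a = np.where(a > 1e-12, a, 1e-12)
            return (g[:, 0] / a)[:, None]
        a, bq, c = -H[:, 0, 0], -H[:, 0, 1], -H[:, 1, 1]
        det = a * c - bq**2
        bad = (det <= 1e-12) | (a <= 1e-12)
        if bad.any():
            r = 1e-6 + np.where(bad, np.maximum(np.abs(bq) - np.sqrt(
                np.maximum(a, 0) * np.maximum(c, 0)), 0.0), 0.0)
            a, c = a + r, c + r
            det = a * c - bq**2
        s0 = (c * g[:, 0] - bq * g[:, 1]) / det
        s1 = (-bq * g[:, 0] + a * g[:, 1]) / det
        return np.column_stack([s0, s1])

    # -- quadrature ------------------------------------------------------
    def freeze_adaptation(self, x) -> None:
        """Fix the quadrature grid at the adaptation for parameters ``x``.

        On the frozen grid the objective is smooth with the posterior-
        expectation score as its exact gradient; callers re-freeze as the
        parameters move (an EM-style outer loop).
        """
        P = _Params(np.asarray(x, dtype=float), self)
        self._frozen = None
        self._frozen = self._nodes(P)

    def unfreeze_adaptation(self) -> None:
        self._frozen = None

    def _nodes(self, P: _Params):
        """Quadrature nodes (n,Q,d) and log weights (n,Q)."""
        if self._frozen is not None:
            return self._frozen
        if self.adaptive:
            mode = self._find_modes(P)
            _, H = self._h_grad_hess(P, mode)
            if self.d == 1:
                a = np.maximum(-H[:, 0, 0], 1e-12)
                c11 = 1.0 / np.sqrt(a)
                zeta = mode[:, None, :] + np.sqrt(2.0) * c11[:, None, None] * self.U[None, :, :]
                logdetC = np.log(c11)
            else:
                a, bq, c = -H[:, 0, 0], -H[:, 0, 1], -H[:, 1, 1]
                det = np.maximum(a * c - bq**2, 1e-24)
                a = np.maximum(a, 1e-12)
                m11, m12, m22 = c / det, -bq / det, a / det
                l11 = np.sqrt(np.maximum(m11, 1e-24))
                l21 = m12 / l11
                l22 = np.sqrt(np.maximum(m22 - l21**2, 1e-24))
                z0 = mode[:, None, 0] + np.sqrt(2.0) * l11[:, None] * self.U[None, :, 0]
                z1 = mode[:, None, 1] + np.sqrt(2.0) * (
                    l21[:, None] * self.U[None, :, 0] + l22[:, None] * self.U[None, :, 1]
                )
                zeta = np.stack([z0, z1], axis=2)
                logdetC = np.log(l11 * l22)
        else:
            mu = self._latent_means(P)
            Cg = P.chol
            zeta = mu[:, None, :] + np.sqrt(2.0) * self.U[None, :, :] @ Cg.T
            logdetC = np.full(self.n, P.logdet_chol)
        loga = self.logw_base[None, :] + logdetC[:, None]
        return zeta, loga

    def _h_at_nodes(self, P: _Params, zeta, keep: list | None = None):
        h = np.zeros((self.n, zeta.shape[1]))
        for j in range(self.J):
            k, lam = P.shape[j], P.lam[j]
            w = k * (self.logT[:, j, None] - P.kappa[j] - lam * zeta[:, :, self._lat_idx[j]])
            ew = np.exp(np.minimum(w, _W_CLIP))
            if keep is not None:
                keep.append((w, ew))
            h += np.log(k) - self.logT[:, j, None] + w - ew
        if self.use_disease:
            b, bL = self._dis_b(P)
            eta = (self.X @ b)[:, None] + zeta @ bL
            y = self.y[:, None]
            if self.family == "poisson-log":
                h += y * eta - np.exp(np.minimum(eta, _W_CLIP))
            else:
                m, _ = _soft_cap(eta)
                h += y * m + (1.0 - y) * np.log(-np.expm1(m))
        mu = self._latent_means(P)
        delta = zeta - mu[:, None, :]
        if self.d == 1:
            z1 = delta[:, :, 0] / P.chol[0, 0]
            quad = z1**2
        else:
            z1 = delta[:, :, 0] / P.chol[0, 0]
            z2 = (delta[:, :, 1] - P.chol[1, 0] * z1) / P.chol[1, 1]
            quad = z1**2 + z2**2
        h += -0.5 * self.d * _LOG2PI - P.logdet_chol - 0.5 * quad
        return h

    # -- public evaluation ----------------------------------------------
    def loglik(self, x, want_score: bool = False):
        """Evaluate the marginal log-likelihood at packed parameters ``x``.

        Returns ``(total, contrib)`` or ``(total, contrib, grad, scores)``
        where ``contrib`` are per-person log-likelihoods (unweighted),
        ``grad`` is the gradient of the weighted total and ``scores`` the
        per-person score vectors (rows; unweighted).
        """
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            return self._loglik_impl(x, want_score)

    def _loglik_impl(self, x, want_score: bool):
        P = _Params(x, self)
        if self.d == 0:
            return self._loglik_latent_free(P, want_score)
        zeta, loga = self._nodes(P)
        keep: list | None = [] if want_score else None
        h = self._h_at_nodes(P, zeta, keep=keep)
        hw = loga + h
        contrib = logsumexp(hw, axis=1)
        if np.isnan(contrib).any():
            bad = int(np.where(np.isnan(contrib))[0][0])
            raise NumericalError(f"non-finite likelihood contribution for record {bad}")
        # floor astronomically negative contributions so the total stays
        # finite (and rejectable) at absurd trial parameters
        contrib = np.maximum(contrib, -1e12)
        total = float(self.weights @ contrib)
        if not want_score:
            return total, contrib
        r = np.exp(hw - contrib[:, None])
        S = np.zeros((self.n, self.n_free))
        sl = self._slices
        # measurement blocks (w, e^w cached from the value pass)
        free_col = {j: fi for fi, j in enumerate(self._free_loading_idx)}
        for j in range(self.J):
            k = P.shape[j]
            li = self._lat_idx[j]
            w, ew = keep[j]
            rew = r * (ew - 1.0)
            S[:, sl["kappa"].start + j] = k * np.sum(rew, axis=1)
            S[:, sl["log_shape"].start + j] = np.sum(r * (1.0 + w * (1.0 - ew)), axis=1)
            if j in free_col:
                S[:, sl["loading"].start + free_col[j]] = k * np.sum(
                    rew * zeta[:, :, li], axis=1
                )
        # disease block
        if self.use_disease:
            b, bL = self._dis_b(P)
            eta = (self.X @ b)[:, None] + zeta @ bL
            y2 = self.y[:, None]
            if self.family == "poisson-log":
                d1 = y2 - np.exp(np.minimum(eta, _W_CLIP))
            else:
                m, sig = _soft_cap(eta)
                em = -np.expm1(m)
                d1 = (y2 - (1.0 - y2) * np.exp(m) / em) * sig
            u = np.sum(r * d1, axis=1)
            S[:, sl["disease_const"]] = u
            for li in range(self.d):
                S[:, sl["disease_bL"].start + li] = np.sum(r * d1 * zeta[:, :, li], axis=1)
            S[:, sl["disease_cov"]] = u[:, None] * self.X[:, 1:]
        # prior block: structural coefficients and covariance
        mu = self._latent_means(P)
        delta = zeta - mu[:, None, :]
        if self.d == 1:
            l11 = P.chol[0, 0]
            z1 = delta[:, :, 0] / l11
            v1 = z1 / l11
            vbar = [np.sum(r * v1, axis=1)]
            S[:, sl["psi"].start] = np.sum(r * (z1**2 - 1.0), axis=1)
        else:
            l11, l21, l22 = P.chol[0, 0], P.chol[1, 0], P.chol[1, 1]
            z1 = delta[:, :, 0] / l11
            z2 = (delta[:, :, 1] - l21 * z1) / l22
            v2 = z2 / l22
            v1 = (z1 - l21 * v2) / l11
            vbar = [np.sum(r * v1, axis=1), np.sum(r * v2, axis=1)]
            S[:, sl["psi"].start] = np.sum(r * (z1**2 - 1.0 - z1 * z2 * l21 / l22), axis=1)
            S[:, sl["psi"].start + 1] = np.sum(r * z1 * z2 / l22, axis=1)
            S[:, sl["psi"].start + 2] = np.sum(r * (z2**2 - 1.0), axis=1)
        for li in range(self.d):
            if self.S[li].shape[1]:
                S[:, sl["gamma"][li]] = vbar[li][:, None] * self.S[li]
        grad = self.weights @ S
        return total, contrib, grad, S

    def _loglik_latent_free(self, P: _Params, want_score: bool):
        b, _ = self._dis_b(P)
        eta = self.X @ b
        ll, d1, _ = self._dis_terms(eta, order=1 if want_score else 0)
        ll = np.maximum(ll, -1e12)
        total = float(self.weights @ ll)
        if not want_score:
            return total, ll
        S = d1[:, None] * self.X
        # reorder: const at disease_const, covariates at disease_cov
        full = np.zeros((self.n, self.n_free))
        full[:, self._slices["disease_const"]] = S[:, 0]
        full[:, self._slices["disease_cov"]] = S[:, 1:]
        grad = self.weights @ full
        return total, ll, grad, full

    # -- posterior moments (used by empirical-Bayes scoring) -------------
    def posterior_moments(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and SD of the latents per person, (n,d) each."""
        P = _Params(x, self)
        if self.d == 0:
            raise DomainError("model has no latent variables")
        zeta, loga = self._nodes(P)
        h = self._h_at_nodes(P, zeta)
        hw = loga + h
        contrib = logsumexp(hw, axis=1)
        r = np.exp(hw - contrib[:, None])
        mean = np.einsum("nq,nqd->nd", r, zeta)
        second = np.einsum("nq,nqd->nd", r, zeta**2)
        var = np.maximum(second - mean**2, 0.0)
        return mean, np.sqrt(var)


def joint_loglikelihood(
    theta: ParameterVector, data: pd.DataFrame, spec: GsemSpec, quad: int = 15,
    adaptive: bool = True,
) -> tuple[float, np.ndarray]:
    """Total weighted log-likelihood and per-person contributions."""
    mm = JointModel(spec, data, n_quad=quad, adaptive=adaptive)
    return mm.loglik(theta.pack(), want_score=False)
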