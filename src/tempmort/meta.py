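"""Multivariate random-effects meta-analysis and BLUP shrinkage.

Pools the per-city reduced (overall-cumulative) coefficient vectors under
the model theta_i ~ N(mu, Psi + S_i). Psi is estimated by REML on the
profiled restricted likelihood with a Cholesky parameterization (method of
moments as fallback), and per-city best linear unbiased predictions shrink
each city's curve toward the pooled mean in proportion to its first-stage
uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .crossbasis import ReducedFit

__all__ = ["PooledModel", "BlupSet", "pool", "blup", "heterogeneity"]


@dataclass
class PooledModel:
    fixed: np.ndarray
    fixed_vcov: np.ndarray
    psi: np.ndarray
    method: str
    q: float | None = None
    q_df: int | None = None
    i2: float | None = None
    converged: bool = True
    n_cities: int = 0


@dataclass
class BlupSet:
    city_ids: list[str]
    coefs: list[np.ndarray]
    vcovs: list[np.ndarray]

    def __getitem__(self, city_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.city_ids.index(city_id)
        return self.coefs[i], self.vcovs[i]


def _stack(fits: list[ReducedFit]) -> tuple[np.ndarray, np.ndarray]:
    thetas = np.stack([f.coef for f in fits])
    Ss = np.stack([f.vcov for f in fits])
    for i, S in enumerate(Ss):
        if np.linalg.cond(S) > 1e12:
            raise ValueError(f"within-city covariance {i} is singular or near-singular")
    return thetas, Ss


def _gls_mu(thetas: np.ndarray, Vs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GLS mean and its covariance given per-city total covariances Vs."""
    Ws = np.stack([np.linalg.inv(V) for V in Vs])
    Wsum = Ws.sum(axis=0)
    U = np.linalg.inv(Wsum)
    mu = U @ np.einsum("ijk,ik->j", Ws, thetas)
    return mu, U


def _neg_restricted_loglik(lvec: np.ndarray, thetas: np.ndarray, Ss: np.ndarray, k: int) -> float:
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = lvec
    psi = L @ L.T
    Vs = Ss + psi
    try:
        Ws = np.stack([np.linalg.inv(V) for V in Vs])
    except np.linalg.LinAlgError:
        return 1e12
    Wsum = Ws.sum(axis=0)
    sign, logdet_wsum = np.linalg.slogdet(Wsum)
    if sign <= 0:
        return 1e12
    mu = np.linalg.solve(Wsum, np.einsum("ijk,ik->j", Ws, thetas))
    val = logdet_wsum
    for theta, V, W in zip(thetas, Vs, Ws):
        s, ld = np.linalg.slogdet(V)
        if s <= 0:
            return 1e12
        r = theta - mu
        val += ld + r @ W @ r
    return 0.5 * val


def _psi_moments(thetas: np.ndarray, Ss: np.ndarray) -> np.ndarray:
    """Method-of-moments Psi: sample scatter about the GLS fixed-effects mean
    minus the average within-city covariance, projected onto the PSD cone."""
    m = len(thetas)
    mu, _ = _gls_mu(thetas, Ss)
    r = thetas - mu
    scatter = r.T @ r / max(m - 1, 1)
    psi = scatter - Ss.mean(axis=0)
    w, v = np.linalg.eigh(0.5 * (psi + psi.T))
    return (v * np.maximum(w, 0.0)) @ v.T


def pool(fits: list[ReducedFit], method: str = "reml") -> PooledModel:
    """Pool per-city reduced coefficients by multivariate meta-analysis."""
    if method not in ("reml", "mm", "fixed"):
        raise ValueError(f"unknown pooling method {method!r}")
    if len(fits) == 0:
        raise ValueError("need at least one city")
    k = fits[0].coef.size
    if any(f.coef.size != k for f in fits):
        raise ValueError("cities have incompatible coefficient dimensions")

    if len(fits) == 1:
        f = fits[0]
        model = PooledModel(
            fixed=f.coef.copy(),
            fixed_vcov=f.vcov.copy(),
            psi=np.zeros((k, k)),
            method="degenerate",
            n_cities=1,
        )
        return model

    thetas, Ss = _stack(fits)
    m = len(fits)

    if method == "fixed":
        psi = np.zeros((k, k))
        used = "fixed"
        converged = True
    elif method == "mm":
        psi = _psi_moments(thetas, Ss)
        used = "mm"
        converged = True
    else:
        psi0 = _psi_moments(thetas, Ss)
        # jitter keeps the Cholesky start strictly feasible
        L0 = np.linalg.cholesky(psi0 + 1e-8 * np.mean(np.trace(Ss, axis1=1, axis2=2)) / k * np.eye(k))
        x0 = L0[np.tril_indices(k)]
        res = optimize.minimize(
            _neg_restricted_loglik,
            x0,
            args=(thetas, Ss, k),
            method="BFGS",
            options={"gtol": 1e-7, "maxiter": 500},
        )
        converged = bool(res.success) or np.linalg.norm(res.jac) < 1e-4
        if not converged:
            warnings.warn(
                f"REML did not converge (|grad|={np.linalg.norm(res.jac):.2e}); "
                "falling back to method of moments",
                stacklevel=2,
            )
            psi = _psi_moments(thetas, Ss)
            used = "mm"
        else:
            Lhat = np.zeros((k, k))
            Lhat[np.tril_indices(k)] = res.x
            psi = Lhat @ Lhat.T
            used = "reml"

    mu, U = _gls_mu(thetas, Ss + psi)
    model = PooledModel(
        fixed=mu, fixed_vcov=U, psi=psi, method=used, converged=converged, n_cities=m
    )
    model.q, model.q_df, model.i2 = heterogeneity(fits)
    return model


def heterogeneity(fits: list[ReducedFit]):
    """Multivariate Cochran Q against the fixed-effects (Psi=0) mean, with
    its chi-square df and I-squared. Returns (None, None, None) for < 2 cities."""
    if len(fits) < 2:
        return None, None, None
    thetas, Ss = _stack(fits)
    k = thetas.shape[1]
    mu_fe, _ = _gls_mu(thetas, Ss)
    q = 0.0
    for theta, S in zip(thetas, Ss):
        r = theta - mu_fe
        q += float(r @ np.linalg.solve(S, r))
    df = (len(fits) - 1) * k
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, i2


def blup(pooled: PooledModel, fits: list[ReducedFit], city_ids: list[str] | None = None) -> BlupSet:
    """Per-city BLUPs: mu + Psi (Psi + S_i)^-1 (theta_i - mu).

    The BLUP covariance combines the conditional variance
    Psi - Psi (Psi+S_i)^-1 Psi with the uncertainty of the pooled mean.
    """
    k = pooled.fixed.size
    coefs, vcovs = [], []
    for f in fits:
        if f.coef.size != k:
            raise ValueError("dimension mismatch between pooled model and city fit")
        V = pooled.psi + f.vcov
        A = pooled.psi @ np.linalg.inv(V)
        b = pooled.fixed + A @ (f.coef - pooled.fixed)
        IA = np.eye(k) - A
        vb = pooled.psi - A @ pooled.psi + IA @ pooled.fixed_vcov @ IA.T
        vb = 0.5 * (vb + vb.T)
        coefs.append(b)
        vcovs.append(vb)
    if city_ids is None:
        city_ids = [str(i) for i in range(len(fits))]
    return BlupSet(city_ids=list(city_ids), coefs=coefs, vcovs=vcovs)
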