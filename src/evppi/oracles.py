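"""Deterministic oracles and toy decision models for validating estimators.

Every estimator in this package is checked against an independent route:
Gauss-Hermite quadrature for expectations of smooth functions of a normal
variable, and nested deterministic quadrature for EVPI/EVPPI on small
Gaussian toy models (dimension <= 3).  The oracles live in the installed
package, not just the tests, so custom models can be validated the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, roots_hermitenorm

__all__ = [
    "gh_expectation",
    "ToyModel",
    "quadrature_evppi",
    "quadrature_evpi",
    "nested_mc_evppi",
    "toy_suite",
]

_MAX_NODES = 512


def gh_expectation(h: Callable, mean: float, sd: float,
                   n_nodes: int = 64, tol: float = 1e-10) -> float:
    """``E[h(X)]`` for ``X ~ Normal(mean, sd^2)`` by Gauss-Hermite quadrature.

    Node counts are doubled until the estimate changes by less than ``tol``;
    raises if 512 nodes do not suffice.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n_nodes < 16:
        raise ValueError("n_nodes must be >= 16")
    if sd == 0:
        return float(h(np.asarray(mean, dtype=float)))
    prev = None
    n = n_nodes
    while n <= _MAX_NODES:
        x, w = roots_hermitenorm(n)
        est = float((w * h(mean + sd * x)).sum() / w.sum())
        if prev is not None and abs(est - prev) < tol:
            return est
        prev = est
        n *= 2
    raise RuntimeError("Gauss-Hermite expectation did not converge by 512 nodes")


@dataclass(frozen=True)
class ToyModel:
    """A small Gaussian decision model with a quadrature-computable EVPPI.

    ``nb`` maps a mapping of parameter arrays to an ``(n, n_arms)`` net-benefit
    array whose reference column is identically zero.  The joint distribution
    of the parameters is multivariate normal with the given mean and
    covariance (dimension <= 3).
    """

    label: str
    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    nb: Callable[[Mapping[str, np.ndarray]], np.ndarray]
    method_hint: str = "nested"

    def __post_init__(self):
        if len(self.names) > 3:
            raise ValueError("toy models are limited to dimension 3")

    def sample(self, n: int, seed=None, rng=None) -> pd.DataFrame:
        gen = rng if rng is not None else np.random.default_rng(seed)
        draws = gen.multivariate_normal(self.mean, self.cov, size=n,
                                        method="cholesky" if
                                        _is_pd(self.cov) else "eigh")
        return pd.DataFrame(draws, columns=list(self.names))

    def nb_frame(self, frame: pd.DataFrame) -> np.ndarray:
        return self.nb({k: frame[k].to_numpy(dtype=float)
                        for k in self.names})


def _is_pd(cov: np.ndarray) -> bool:
    return bool(np.linalg.eigvalsh(cov).min() > 1e-12)


@lru_cache(maxsize=64)
def _gh_grid(dim: int, n: int):
    if dim == 0:
        return np.zeros((1, 0)), np.ones(1)
    x, w = roots_hermitenorm(n)
    w = w / w.sum()
    grids = np.meshgrid(*([x] * dim), indexing="ij")
    nodes = np.column_stack([g.ravel() for g in grids])
    weights = np.ones(len(nodes))
    wgrids = np.meshgrid(*([w] * dim), indexing="ij")
    for g in wgrids:
        weights *= g.ravel()
    return nodes, weights


def _nb_at(toy: ToyModel, values: np.ndarray) -> np.ndarray:
    return toy.nb({k: values[:, i] for i, k in enumerate(toy.names)})


def _sqrt_factor(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((cov + cov.T) / 2)
    return v @ np.diag(np.sqrt(np.clip(w, 0, None)))


_Z_RANGE = 8.5  # standardized integration half-width; N(0,1) tail < 1e-17


def _gauss_integral(f, dim: int, tol: float) -> float:
    """Integral of ``f(z) * N(z; 0, I)`` over the standardized domain.

    Adaptive quadrature is used because ``f`` may have kinks (the max over
    treatments); adaptive subdivision recovers full accuracy without knowing
    the kink locations.
    """
    from scipy import integrate, stats

    if dim == 0:
        return float(f(np.zeros(0)))
    pdf = stats.norm.pdf
    if dim == 1:
        val, err = integrate.quad(lambda z: f(np.array([z])) * pdf(z),
                                  -_Z_RANGE, _Z_RANGE, limit=400,
                                  epsabs=tol, epsrel=tol)
    else:
        ranges = [(-_Z_RANGE, _Z_RANGE)] * dim
        val, err = integrate.nquad(
            lambda *z: f(np.array(z)) * np.prod(pdf(np.array(z))),
            ranges, opts={"limit": 120, "epsabs": tol * 10,
                          "epsrel": tol * 10})
    return float(val)


def quadrature_evppi(toy: ToyModel, focal: Sequence[str],
                     tol: float = 1e-8, n_inner_nodes: int = 64) -> float:
    """EVPPI by nested deterministic quadrature.

    The smooth inner conditional expectations use tensor Gauss-Hermite rules
    (node counts doubled until the change is below ``tol``); the outer
    expectation of the kinked ``max_j`` regret uses adaptive Gaussian-weight
    quadrature.  Limited to dimension <= 3.
    """
    focal = [focal] if isinstance(focal, str) else list(focal)
    unknown = set(focal) - set(toy.names)
    if unknown:
        raise KeyError(f"unknown focal parameters {sorted(unknown)}")
    names = list(toy.names)
    f_idx = [names.index(f) for f in focal]
    c_idx = [i for i in range(len(names)) if i not in f_idx]
    mu = np.asarray(toy.mean, dtype=float)
    S = np.asarray(toy.cov, dtype=float)
    chol_f = _sqrt_factor(S[np.ix_(f_idx, f_idx)])
    if c_idx:
        Scf = S[np.ix_(c_idx, f_idx)]
        A = Scf @ np.linalg.pinv(S[np.ix_(f_idx, f_idx)])
        cond_cov = S[np.ix_(c_idx, c_idx)] - A @ Scf.T
        chol_c = _sqrt_factor(cond_cov)

    def inner_means(phi: np.ndarray, n_nodes: int) -> np.ndarray:
        """E[B_j | focal = phi] by tensor Gauss-Hermite over the conditional."""
        c_nodes, c_weights = _gh_grid(len(c_idx), n_nodes)
        full = np.tile(mu, (len(c_nodes), 1))
        full[:, f_idx] = phi
        if c_idx:
            cond_mean = mu[c_idx] + A @ (phi - mu[f_idx])
            full[:, c_idx] = cond_mean[None, :] + c_nodes @ chol_c.T
        return (c_weights[:, None] * _nb_at(toy, full)).sum(axis=0)

    def converged_inner(phi: np.ndarray) -> np.ndarray:
        if not c_idx:  # no complement: the "inner expectation" is exact
            return inner_means(phi, n_inner_nodes)
        n = n_inner_nodes
        prev = inner_means(phi, n)
        while n < _MAX_NODES:
            n *= 2
            cur = inner_means(phi, n)
            if np.max(np.abs(cur - prev)) <= tol * max(1.0, np.max(np.abs(cur))):
                return cur
            prev = cur
        raise RuntimeError("inner Gauss-Hermite expectation did not converge")

    # j* from the unconditional mean net benefit (smooth; joint GH)
    e_b = None
    f_nodes, f_weights = _gh_grid(len(f_idx), 64)
    for fw, fz in zip(f_weights, f_nodes):
        m_j = converged_inner(mu[f_idx] + chol_f @ fz)
        e_b = fw * m_j if e_b is None else e_b + fw * m_j
    j_star = int(e_b.argmax())

    def regret(z: np.ndarray) -> float:
        m_j = converged_inner(mu[f_idx] + chol_f @ z)
        return float(m_j.max() - m_j[j_star])

    return _gauss_integral(regret, len(f_idx), tol)


def quadrature_evpi(toy: ToyModel, tol: float = 1e-8) -> float:
    """EVPI of a toy model (EVPPI with every parameter focal)."""
    return quadrature_evppi(toy, list(toy.names), tol=tol)


def nested_mc_evppi(toy: ToyModel, focal: Sequence[str], n_outer: int,
                    n_inner: int, seed=None, conditional: bool = True):
    """Nested Monte Carlo EVPPI on a toy model.

    With ``conditional=True`` inner draws come from the exact Gaussian
    conditional law of the complement; with ``conditional=False`` they come
    from the complement's marginal (the shortcut that is downward biased when
    focal and nonfocal parameters are correlated).  Returns ``(value, mc_se)``.
    """
    focal = [focal] if isinstance(focal, str) else list(focal)
    names = list(toy.names)
    f_idx = [names.index(f) for f in focal]
    c_idx = [i for i in range(len(names)) if i not in f_idx]
    mu = np.asarray(toy.mean, dtype=float)
    S = np.asarray(toy.cov, dtype=float)
    gen = np.random.default_rng(seed)

    Sf = S[np.ix_(f_idx, f_idx)]
    wf, vf = np.linalg.eigh((Sf + Sf.T) / 2)
    chol_f = vf @ np.diag(np.sqrt(np.clip(wf, 0, None)))
    phi = mu[f_idx] + gen.standard_normal((n_outer, len(f_idx))) @ chol_f.T

    if c_idx:
        Scf = S[np.ix_(c_idx, f_idx)]
        A = Scf @ np.linalg.pinv(Sf)
        cond_cov = S[np.ix_(c_idx, c_idx)] - A @ Scf.T
        marg_cov = S[np.ix_(c_idx, c_idx)]
        wc, vc = np.linalg.eigh(((cond_cov if conditional else marg_cov)
                                 + (cond_cov if conditional else marg_cov).T) / 2)
        chol_c = vc @ np.diag(np.sqrt(np.clip(wc, 0, None)))

    # j* from a plain joint simulation of the same total size
    joint = toy.sample(n_outer * min(n_inner, 100), rng=gen)
    e_b = toy.nb_frame(joint).mean(axis=0)
    j_star = int(e_b.argmax())

    per_outer = np.empty(n_outer)
    chunk = max(1, int(2_000_000 // max(n_inner, 1)))
    for start in range(0, n_outer, chunk):
        stop = min(n_outer, start + chunk)
        m = stop - start
        full = np.tile(mu, (m * n_inner, 1))
        full[:, f_idx] = np.repeat(phi[start:stop], n_inner, axis=0)
        if c_idx:
            eps = gen.standard_normal((m * n_inner, len(c_idx))) @ chol_c.T
            if conditional:
                base = mu[c_idx] + (phi[start:stop] - mu[f_idx]) @ A.T
                full[:, c_idx] = np.repeat(base, n_inner, axis=0) + eps
            else:
                full[:, c_idx] = mu[c_idx] + eps
        B = _nb_at(toy, full).reshape(m, n_inner, -1)
        inner = B.mean(axis=1)
        per_outer[start:stop] = inner.max(axis=1) - inner[:, j_star]
    return float(per_outer.mean()), float(per_outer.std(ddof=1)
                                          / np.sqrt(n_outer))


def toy_suite() -> list[ToyModel]:
    """Four fixtures spanning the single-step strategies.

    (a) linear net benefit (mean plug-in exact);
    (b) product of independent parameters (multilinear plug-in exact);
    (c) inverse-logit of a sum of independent parameters (Taylor territory);
    (d) the same with correlated parameters (spline territory; marginal inner
        resampling in nested MC is downward biased here).
    """

    def linear_nb(p):
        zero = np.zeros_like(p["x1"])
        return np.column_stack([zero, 100.0 * p["x1"] + 50.0 * p["x2"] - 120.0])

    def product_nb(p):
        zero = np.zeros_like(p["x1"])
        return np.column_stack([zero, 50.0 * p["x1"] * p["x2"] - 20.0])

    def expit_nb(p):
        zero = np.zeros_like(p["x1"])
        return np.column_stack([zero, 1000.0 * expit(p["x1"] + p["x2"]) - 450.0])

    ind = np.diag([1.0, 0.64])
    corr = np.array([[1.0, 0.5 * 0.8], [0.5 * 0.8, 0.64]])
    return [
        ToyModel("linear", ("x1", "x2"), np.array([1.0, 0.8]),
                 np.diag([0.25, 0.09]), linear_nb, "m1"),
        ToyModel("product", ("x1", "x2"), np.array([1.0, 0.8]),
                 np.diag([0.25, 0.09]), product_nb, "m2"),
        ToyModel("expit-independent", ("x1", "x2"), np.array([0.0, 0.5]),
                 ind, expit_nb, "m4-taylor"),
        ToyModel("expit-correlated", ("x1", "x2"), np.array([0.0, 0.5]),
                 corr, expit_nb, "m5-spline"),
    ]
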