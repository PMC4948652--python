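"""Taylor-series approximation of conditional expectations (method 4).

When the net benefit contains a smooth nonlinear function ``h(phi_iC + phi)``
of a single nonfocal coordinate, its conditional expectation given the focal
parameters can be approximated by a Taylor expansion of ``h`` about the
nonfocal mean:

    E[h | phi] ~= h(mu) + sum_{r>=2} h^(r)(mu) * m_r / r!

with ``m_r`` the central moments of the nonfocal coordinate.  A single
expansion degrades as the nonfocal variance grows; accuracy is recovered by
splitting the nonfocal distribution into equal-probability quantile segments,
expanding about each segment mean, and averaging the per-segment expansions
weighted by segment mass (with four segments, the "interquartile means").
This quantile-averaged second-order form is the default: each expansion is
local to its segment, so the error of any single expansion is bounded by the
within-segment spread.

Closed-form derivatives are supplied for the two link inverses that arise in
probability models: the inverse logit (to fourth order) and the inverse
complementary log-log (to second order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .decision_model import DecisionContext, EconomicConstants
from .posterior import as_frame
from .voi import (AdmissibilityError, ConditionalNB, DM_COMPONENTS,
                  VoiEstimate, evppi_single_step, normalize_focal)

__all__ = [
    "TaylorSpec",
    "SegmentMoments",
    "segment_moments",
    "normal_segment_moments",
    "taylor_expect",
    "expit_derivatives",
    "cloglog_derivatives",
    "taylor2_expit",
    "taylor2_cloglog",
    "segment_taylor_expit",
    "evppi_taylor",
]

log = logging.getLogger(__name__)

_FACTORIAL = {2: 2.0, 3: 6.0, 4: 24.0}


@dataclass(frozen=True)
class TaylorSpec:
    """Expansion order (2 or 4) and number of quantile segments (1 = single
    expansion about the mean; 4 = interquartile means)."""

    order: int = 2
    n_segments: int = 4

    def __post_init__(self):
        if self.order not in (2, 4):
            raise ValueError("order must be 2 or 4")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")


@dataclass(frozen=True)
class SegmentMoments:
    """Per-segment probability mass, mean, and central moments."""

    weights: np.ndarray
    means: np.ndarray
    central: dict  # order -> array of per-segment central moments

    def __post_init__(self):
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("segment weights must sum to 1")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("segment means must be nondecreasing")


def segment_moments(values, n_segments: int, order: int = 4) -> SegmentMoments:
    """Empirical equal-probability segment moments of a sample.

    Splits the sample at its quantiles into ``n_segments`` segments and
    returns each segment's mass, mean, and central moments up to ``order``.
    With one segment this reduces to the overall mean and moments.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < n_segments:
        raise ValueError("fewer samples than segments")
    if n < 100 * n_segments:
        log.warning("fewer than 100 samples per segment; moments are noisy")
    edges = np.linspace(0, n, n_segments + 1).astype(int)
    weights, means = np.empty(n_segments), np.empty(n_segments)
    central = {r: np.empty(n_segments) for r in range(2, order + 1)}
    for q in range(n_segments):
        seg = x[edges[q]:edges[q + 1]]
        weights[q] = len(seg) / n
        means[q] = seg.mean()
        d = seg - means[q]
        for r in central:
            central[r][q] = (d ** r).mean()
    return SegmentMoments(weights, means, central)


def normal_segment_moments(mean: float, sd: float, n_segments: int,
                           order: int = 4) -> SegmentMoments:
    """Exact equal-probability segment moments of a Normal(mean, sd^2):
    truncated-normal means and central moments per quantile segment."""
    from scipy import stats

    if sd <= 0:
        raise ValueError("sd must be > 0")
    edges = stats.norm.ppf(np.linspace(0.0, 1.0, n_segments + 1), mean, sd)
    weights = np.full(n_segments, 1.0 / n_segments)
    means = np.empty(n_segments)
    central = {r: np.empty(n_segments) for r in range(2, order + 1)}
    for q in range(n_segments):
        a = (edges[q] - mean) / sd
        b = (edges[q + 1] - mean) / sd
        dist = stats.truncnorm(a, b, loc=mean, scale=sd)
        mu = dist.mean()
        means[q] = mu
        raw = {r: dist.moment(r) for r in range(1, order + 1)}
        central[2][q] = raw[2] - mu**2
        if order >= 3:
            central[3][q] = raw[3] - 3 * mu * raw[2] + 2 * mu**3
        if order >= 4:
            central[4][q] = (raw[4] - 4 * mu * raw[3] + 6 * mu**2 * raw[2]
                             - 3 * mu**4)
    return SegmentMoments(weights, means, central)


def taylor_expect(h_derivs, moments: SegmentMoments,
                  spec: TaylorSpec = TaylorSpec()) -> float:
    """Quantile-averaged Taylor approximation of ``E[h(X)]``.

    ``h_derivs(x, order)`` must return ``[h(x), h'(x), ..., h^(order)(x)]``.
    The first-order term vanishes because each expansion is centred on its
    segment mean.
    """
    derivs_available = len(h_derivs(np.array([0.0]), spec.order)) - 1
    if derivs_available < spec.order:
        raise ValueError("derivatives not available to the requested order")
    total = 0.0
    for q in range(len(moments.weights)):
        d = h_derivs(np.asarray(moments.means[q]), spec.order)
        val = d[0]
        for r in range(2, spec.order + 1):
            val = val + d[r] * moments.central[r][q] / _FACTORIAL[r]
        total += moments.weights[q] * val
    return float(total)


def expit_derivatives(x, order: int = 4):
    """Inverse logit and its derivatives up to fourth order, in closed form."""
    H = expit(np.asarray(x, dtype=float))
    g = H * (1.0 - H)
    out = [H, g]
    if order >= 2:
        out.append(g * (1.0 - 2.0 * H))
    if order >= 3:
        out.append(g * (1.0 - 6.0 * H + 6.0 * H * H))
    if order >= 4:
        out.append(g * (1.0 - 2.0 * H) * (1.0 - 6.0 * H + 6.0 * H * H)
                   + g * g * (12.0 * H - 6.0))
    return out[:order + 1]


def cloglog_derivatives(x, order: int = 2):
    """Inverse complementary log-log ``1 - exp(-exp(x))`` and derivatives.

    With ``H = exp(-exp(x))`` (so ``ln H = -exp(x)``):
    ``h' = -H ln H`` and ``h'' = -H ln H (1 + ln H)``.
    """
    if order > 2:
        raise ValueError("cloglog derivatives implemented to order 2")
    u = np.exp(np.asarray(x, dtype=float))
    H = np.exp(-u)
    out = [1.0 - H, u * H]
    if order >= 2:
        out.append(u * H * (1.0 - u))
    return out[:order + 1]


def taylor2_expit(mean_shift, var):
    """Second-order expansion of ``E[expit(X + shift)]`` about the mean:
    ``H + H(1-H)(1-2H) var/2`` with ``H = expit(mean_shift)``."""
    var = np.asarray(var, dtype=float)
    if np.any(var < 0):
        raise ValueError("variance must be >= 0")
    H = expit(np.asarray(mean_shift, dtype=float))
    return H + H * (1.0 - H) * (1.0 - 2.0 * H) * var / 2.0


def taylor2_cloglog(mean_shift, var):
    """Second-order expansion of the inverse complementary log-log:
    ``(1 - H) + h''(mean_shift) var/2`` with ``h'' = -H ln H (1 + ln H)``,
    ``H = exp(-exp(mean_shift))``."""
    var = np.asarray(var, dtype=float)
    if np.any(var < 0):
        raise ValueError("variance must be >= 0")
    u = np.exp(np.asarray(mean_shift, dtype=float))
    H = np.exp(-u)
    return (1.0 - H) + u * H * (1.0 - u) * var / 2.0


def segment_taylor_expit(shifts, moments: SegmentMoments, order: int = 2):
    """Vectorized quantile-averaged expansion of ``E[expit(X + s)]`` over an
    array of shifts ``s``, with ``X`` summarized by ``moments``."""
    shifts = np.asarray(shifts, dtype=float)
    total = np.zeros_like(shifts)
    for q in range(len(moments.weights)):
        d = expit_derivatives(moments.means[q] + shifts, order)
        val = d[0]
        for r in range(2, order + 1):
            val = val + d[r] * moments.central[r][q] / _FACTORIAL[r]
        total += moments.weights[q] * val
    return total


def _clip_unit(values: np.ndarray, what: str) -> tuple[np.ndarray, int]:
    clipped = np.clip(values, 0.0, 1.0)
    n_out = int(np.count_nonzero(clipped != values))
    if n_out:
        log.info("clipped %d %s expectations into [0, 1]", n_out, what)
    return clipped, n_out


_TAYLOR_FOCALS = (frozenset(DM_COMPONENTS) | {"dS"}, frozenset({"alpha", "pB"}))


def evppi_taylor(samples, focal, econ: EconomicConstants, ctx: DecisionContext,
                 spec: TaylorSpec = TaylorSpec()) -> VoiEstimate:
    """Single-step EVPPI with Taylor-approximated conditional expectations.

    Admissible focal sets for the case-study model:

    * ``{d2M, d3M, d4M, dS}`` — the conditional net benefit factorizes as
      ``(E[expit(alpha)] - E[expit(alpha + dM_j)|dM_j]) *
      (beta1_bar - E[h2|dS] * beta2_bar) - CF_j``; the two inner expectations
      (over ``alpha`` and over ``ln pB``) are Taylor-approximated.
    * ``{alpha, pB}`` — expansions run over each ``dM_j`` and over ``dS``;
      because ``dM_j`` and ``dS`` are correlated, the cross term
      ``E[expit(alpha+dM_j) h2]`` picks up a first-order (delta-method)
      covariance correction ``expit'(alpha+mu_dM) expit'(ln pB+mu_dS)
      cov(dM_j, dS)``.

    Approximated probabilities are clipped into [0, 1]; the number of clipped
    values is recorded in the estimate settings.
    """
    draws = as_frame(samples)
    focal = normalize_focal(focal)
    if focal not in _TAYLOR_FOCALS:
        raise AdmissibilityError(
            "Taylor strategy supports focal sets {dM, dS} and {alpha, pB}")
    beta1_bar = ctx.wtp * draws["qM"].mean() - econ.hospital_cost
    beta2_bar = draws["pL"].mean() * (ctx.wtp * draws["qS"].mean()
                                      + econ.ns_lifetime_cost)
    cf = np.array([econ.fluid_cost[t.name] for t in ctx.treatments])
    clip_count = 0

    if "dS" in focal:
        mom_alpha = segment_moments(draws["alpha"], spec.n_segments, spec.order)
        mom_lnpb = segment_moments(np.log(draws["pB"]), spec.n_segments,
                                   spec.order)

        def fn(frame: pd.DataFrame) -> np.ndarray:
            nonlocal clip_count
            n = len(frame)
            base = segment_taylor_expit(np.zeros(n), mom_alpha, spec.order)
            eh2, c = _clip_unit(segment_taylor_expit(
                frame["dS"].to_numpy(), mom_lnpb, spec.order), "h2")
            clip_count += c
            out = np.zeros((n, len(ctx.treatments)))
            for j, t in enumerate(ctx.treatments):
                if t.dm is None:
                    continue
                e1, c1 = _clip_unit(segment_taylor_expit(
                    frame[t.dm].to_numpy(), mom_alpha, spec.order), "mortality")
                clip_count += c1
                out[:, j] = ((base - e1)
                             * (beta1_bar - eh2 * beta2_bar) - cf[j])
            return out

    else:  # focal == {alpha, pB}
        mom_d = {d: segment_moments(draws[d], spec.n_segments, spec.order)
                 for d in DM_COMPONENTS}
        mom_ds = segment_moments(draws["dS"], spec.n_segments, spec.order)
        mu_ds = float(draws["dS"].mean())
        cov_d_ds = {d: float(np.cov(draws[d], draws["dS"])[0, 1])
                    for d in DM_COMPONENTS}

        def fn(frame: pd.DataFrame) -> np.ndarray:
            nonlocal clip_count
            alpha = frame["alpha"].to_numpy(dtype=float)
            ln_pb = np.log(frame["pB"].to_numpy(dtype=float))
            n = len(frame)
            p0 = expit(alpha)
            eh2, c = _clip_unit(segment_taylor_expit(ln_pb, mom_ds, spec.order),
                                "h2")
            clip_count += c
            d_h2 = expit_derivatives(ln_pb + mu_ds, 1)[1]
            out = np.zeros((n, len(ctx.treatments)))
            for j, t in enumerate(ctx.treatments):
                if t.dm is None:
                    continue
                mu_d = float(np.dot(mom_d[t.dm].weights, mom_d[t.dm].means))
                e1, c1 = _clip_unit(segment_taylor_expit(
                    alpha, mom_d[t.dm], spec.order), "mortality")
                clip_count += c1
                # E[expit(alpha+dM) h2] ~= E[expit(alpha+dM)] E[h2] + cov term
                cross = e1 * eh2 + (expit_derivatives(alpha + mu_d, 1)[1]
                                    * d_h2 * cov_d_ds[t.dm])
                e_dp = p0 - e1
                e_dp_h2 = p0 * eh2 - cross
                out[:, j] = beta1_bar * e_dp - beta2_bar * e_dp_h2 - cf[j]
            return out

    cond = ConditionalNB("m4-taylor", fn,
                         {"order": spec.order, "n_segments": spec.n_segments})
    est = evppi_single_step(samples, focal, cond, econ, ctx)
    settings = dict(est.settings)
    settings["n_clipped"] = clip_count
    return VoiEstimate(est.value, est.mc_se, est.method, est.focal, est.wtp,
                       est.n, settings)
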