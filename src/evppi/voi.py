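"""EVPI and single-step EVPPI estimation.

The expected value of partial perfect information for a focal parameter
subset ``phi`` is

    EVPPI(phi) = E_phi[ max_j E_{phiC|phi}[ B_j - B_j* ] ]

where ``j*`` is the optimum under current information and ``phiC`` the
nonfocal complement.  Every estimator here replaces the inner conditional
expectation with a closed form or an approximation evaluated draw-by-draw,
so a single pass over the joint sample suffices ("single-step" estimation).
The nested two-level Monte Carlo estimator is provided as the baseline it
replaces, together with its upward-bias diagnostics.

Plug-in strategies implemented here:

* mean plug-in (valid when the net benefit is linear, or multilinear with
  independence, in the nonfocal parameters) — substitutes nonfocal sample
  means directly;
* reparameterized plug-in — substitutes sample means of the nonlinear
  nonfocal blocks ``beta1_j = expit(alpha) - expit(alpha + dM_j)`` and
  ``beta2_j = beta1_j * h2(pB, dS)``, valid whenever the focal set is a
  subset of {qM, qS, pL}.

Admissibility is enforced by an explicit registry of focal sets for the
case-study model rather than symbolic analysis; an inadmissible plug-in
raises instead of silently returning a biased number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .decision_model import DecisionContext, EconomicConstants, net_benefit_matrix
from .posterior import PosteriorSpec, as_frame, latent_conditional

__all__ = [
    "FocalSet",
    "VoiEstimate",
    "ConditionalNB",
    "AdmissibilityError",
    "evpi",
    "evppi_single_step",
    "plugin_mean_conditional_nb",
    "reparam_conditional_nb",
    "evppi_nested",
    "admissibility_registry",
    "select_method",
    "normalize_focal",
]

log = logging.getLogger(__name__)

DM_COMPONENTS = ("d2M", "d3M", "d4M")
ALL_PARAMETERS = ("alpha",) + DM_COMPONENTS + ("pB", "dS", "pL", "qM", "qS")


class AdmissibilityError(ValueError):
    """The requested plug-in strategy is invalid for this focal set."""


def normalize_focal(focal: Iterable[str]) -> frozenset:
    """Expand the ``dM`` shorthand into its three components.

    Names are not otherwise validated here: each estimator checks membership
    against the parameters it supports (toy models use their own names).
    """
    out = set()
    for name in ([focal] if isinstance(focal, str) else focal):
        if name == "dM":
            out.update(DM_COMPONENTS)
        else:
            out.add(str(name))
    return frozenset(out)


FocalSet = frozenset  # focal sets are plain frozensets of parameter symbols


@dataclass(frozen=True)
class VoiEstimate:
    """A value-of-information estimate in USD per person."""

    value: float
    mc_se: float
    method: str
    focal: frozenset
    wtp: float
    n: int
    settings: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.mc_se < 0:
            raise ValueError("mc_se must be >= 0")


@dataclass(frozen=True)
class ConditionalNB:
    """Approximation of ``E[B_j | phi]`` for every treatment.

    ``fn`` maps a draws frame (only focal columns are read) to an
    ``(n, n_treatments)`` array whose reference column is identically zero.
    """

    label: str
    fn: Callable[[pd.DataFrame], np.ndarray]
    settings: Mapping = field(default_factory=dict)

    def __call__(self, draws) -> np.ndarray:
        return self.fn(as_frame(draws))


def _regret_estimate(per_draw: np.ndarray) -> tuple[float, float]:
    value = float(per_draw.mean())
    mc_se = float(per_draw.std(ddof=1) / np.sqrt(len(per_draw)))
    return value, mc_se


def evpi(samples, econ: EconomicConstants, ctx: DecisionContext,
         nb: Callable[[pd.DataFrame], np.ndarray] | None = None) -> VoiEstimate:
    """Expected value of perfect information: ``E[max_j B_j] - E[B_j*]``.

    ``j*`` maximizes the sample-mean net benefit, so the estimate is
    nonnegative by construction.  ``nb`` overrides the net-benefit function
    (used for toy models); by default the case-study model is evaluated.
    """
    draws = as_frame(samples)
    if len(draws) < 2:
        raise ValueError("need at least 2 draws")
    B = nb(draws) if nb is not None else net_benefit_matrix(draws, econ, ctx)
    j_star = int(B.mean(axis=0).argmax())
    value, mc_se = _regret_estimate(B.max(axis=1) - B[:, j_star])
    return VoiEstimate(value, mc_se, "evpi", frozenset(ALL_PARAMETERS),
                       ctx.wtp if ctx is not None else np.nan, len(draws))


def evppi_single_step(samples, focal, cond_nb: ConditionalNB,
                      econ: EconomicConstants, ctx: DecisionContext,
                      nb: Callable | None = None) -> VoiEstimate:
    """Single-pass EVPPI with a pluggable conditional-expectation model.

    For each draw's focal values, ``cond_nb`` supplies the (approximate)
    conditional mean net benefit of every treatment; the estimate averages
    ``max_j`` minus the ``j*`` entry, with ``j*`` fixed from the full-sample
    mean net benefits.
    """
    draws = as_frame(samples)
    focal = normalize_focal(focal)
    B = nb(draws) if nb is not None else net_benefit_matrix(draws, econ, ctx)
    j_star = int(B.mean(axis=0).argmax())
    M = cond_nb(draws)
    if M.shape != B.shape:
        raise ValueError("conditional net benefit has wrong shape")
    value, mc_se = _regret_estimate(M.max(axis=1) - M[:, j_star])
    return VoiEstimate(value, mc_se, cond_nb.label, focal,
                       ctx.wtp if ctx is not None else np.nan, len(draws),
                       dict(cond_nb.settings))


# ---------------------------------------------------------------------------
# Plug-in conditional-expectation models (mean plug-in and reparameterization)
# ---------------------------------------------------------------------------

_PLUGIN_SAFE = frozenset({"qM", "qS", "pL"})


def _plugin_method_label(phi_c: frozenset) -> str:
    # pL*qS is the only product of nonfocal parameters; its presence makes the
    # net benefit multilinear rather than linear in the complement.
    return "m2" if {"pL", "qS"} <= phi_c else "m1"


def plugin_mean_conditional_nb(samples, focal, econ: EconomicConstants,
                               ctx: DecisionContext) -> ConditionalNB:
    """Mean plug-in: evaluate the net benefit with each nonfocal parameter
    replaced by its full-sample mean.

    Exact when the net benefit is linear (or multilinear with independent
    factors) in the complement — here, when the complement is a subset of
    {qM, qS, pL}.  Any other complement member enters through the
    inverse-logit (``alpha``, ``dM``) or the saved-patient NS odds
    (``pB``, ``dS``, which are also mutually correlated with ``dM``), and the
    plug-in would be biased: those sets are rejected.
    """
    draws = as_frame(samples)
    focal = normalize_focal(focal)
    phi_c = frozenset(ALL_PARAMETERS) - focal
    if not phi_c or not focal:
        raise AdmissibilityError("focal set must be a non-empty proper subset")
    offending = sorted(phi_c - _PLUGIN_SAFE)
    if offending:
        raise AdmissibilityError(
            f"mean plug-in invalid: net benefit is nonlinear in nonfocal "
            f"{offending} (inverse-logit / saved-patient NS terms); use the "
            f"reparameterized, Taylor or spline strategies instead")
    means = {p: float(draws[p].mean()) for p in phi_c}
    label = _plugin_method_label(phi_c)

    def fn(frame: pd.DataFrame) -> np.ndarray:
        cols = {p: frame[p].to_numpy(dtype=float) for p in focal}
        n = len(frame)
        for p, m in means.items():
            cols[p] = np.full(n, m)
        return net_benefit_matrix(pd.DataFrame(cols), econ, ctx)

    return ConditionalNB(label, fn, {"plugged": means})


def reparam_conditional_nb(samples, focal, econ: EconomicConstants,
                           ctx: DecisionContext) -> ConditionalNB:
    """Reparameterized plug-in for focal subsets of {qM, qS, pL}.

    The net benefit is linear in the blocks
    ``beta1_j = expit(alpha) - expit(alpha + dM_j)`` and
    ``beta2_j = beta1_j * h2(pB, dS)``, which are independent of
    {qM, qS, pL}; their full-sample means are substituted, and any nonfocal
    member of {qM, qS, pL} is substituted by its mean as well:

        E[B_j | phi] = f1(qM) * E[beta1_j] - f2(pL, qS) * E[beta2_j] - CF_j
    """
    draws = as_frame(samples)
    focal = normalize_focal(focal)
    if not focal or not focal <= _PLUGIN_SAFE:
        raise AdmissibilityError(
            "reparameterized plug-in requires a non-empty focal subset of "
            "{qM, qS, pL}")
    alpha = draws["alpha"].to_numpy(dtype=float)
    p0 = expit(alpha)
    h2 = (draws["pB"].to_numpy(dtype=float)
          * np.exp(draws["dS"].to_numpy(dtype=float)))
    h2 = h2 / (1.0 + h2)
    e_beta1 = np.zeros(len(ctx.treatments))
    e_beta2 = np.zeros(len(ctx.treatments))
    for j, t in enumerate(ctx.treatments):
        if t.dm is None:
            continue
        dp = p0 - expit(alpha + draws[t.dm].to_numpy(dtype=float))
        e_beta1[j] = dp.mean()
        e_beta2[j] = (dp * h2).mean()
    cf = np.array([econ.fluid_cost[t.name] for t in ctx.treatments])
    means = {p: float(draws[p].mean()) for p in _PLUGIN_SAFE - focal}

    def col(frame: pd.DataFrame, name: str) -> np.ndarray:
        if name in focal:
            return frame[name].to_numpy(dtype=float)
        return np.full(len(frame), means[name])

    def fn(frame: pd.DataFrame) -> np.ndarray:
        f1 = ctx.wtp * col(frame, "qM") - econ.hospital_cost
        f2 = col(frame, "pL") * (ctx.wtp * col(frame, "qS")
                                 + econ.ns_lifetime_cost)
        return (f1[:, None] * e_beta1[None, :]
                - f2[:, None] * e_beta2[None, :] - cf[None, :])

    return ConditionalNB("m3", fn, {"e_beta1": e_beta1.tolist(),
                                    "e_beta2": e_beta2.tolist()})


# ---------------------------------------------------------------------------
# Nested (two-level) Monte Carlo baseline
# ---------------------------------------------------------------------------

def evppi_nested(samples, focal, econ: EconomicConstants, ctx: DecisionContext,
                 n_outer: int, n_inner: int,
                 spec: PosteriorSpec | None = None,
                 conditional: bool = False,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None,
                 nb: Callable | None = None) -> VoiEstimate:
    """Two-level Monte Carlo EVPPI: outer focal draws, inner nonfocal draws.

    The first ``n_outer`` rows of ``samples`` supply the outer focal values;
    inner nonfocal values are resampled from the joint sample (marginal
    resampling, the conventional shortcut) or, with ``conditional=True``,
    drawn from the copula conditional law of the complement given each outer
    focal value (requires ``spec``).  With marginal resampling and a focal
    set correlated with its complement the estimate is downward biased — a
    warning is logged.  For finite ``n_inner`` the estimator is upward biased
    by the max over noisy inner means.
    """
    draws = as_frame(samples)
    focal = normalize_focal(focal)
    focal_cols = sorted(focal)
    comp_cols = [p for p in draws.columns if p not in focal]
    if n_outer > len(draws):
        raise ValueError("n_outer exceeds the available draws")
    gen = rng if rng is not None else np.random.default_rng(seed)

    model = nb if nb is not None else (
        lambda frame: net_benefit_matrix(frame, econ, ctx))
    B = model(draws)
    j_star = int(B.mean(axis=0).argmax())
    n_arms = B.shape[1]

    correlated = False
    if spec is not None:
        names = list(spec.names)
        fi = [names.index(c) for c in focal_cols if c in names]
        ci = [names.index(c) for c in comp_cols if c in names]
        correlated = bool(np.any(spec.correlation[np.ix_(fi, ci)] != 0.0))
    if correlated and not conditional:
        warnings.warn(
            "focal set is correlated with its complement but inner sampling "
            "is marginal: the nested EVPPI estimate will be downward biased",
            stacklevel=2)
    if conditional and spec is None:
        raise ValueError("conditional inner sampling requires a posterior spec")

    outer = draws.iloc[:n_outer]
    per_outer = np.empty(n_outer)

    if conditional:
        comp_names, A, chol = latent_conditional(spec, focal_cols)
        z_f = np.column_stack([
            _latent_scores_frame(spec, c, outer[c].to_numpy()) for c in focal_cols])
        mean_c = z_f @ A.T  # (n_outer, k_c)

    chunk = max(1, int(2_000_000 // max(n_inner, 1)))
    for start in range(0, n_outer, chunk):
        stop = min(n_outer, start + chunk)
        m = stop - start
        if conditional:
            eps = gen.standard_normal((m, n_inner, len(comp_names)))
            z_c = mean_c[start:stop, None, :] + eps @ chol.T
            from scipy.special import ndtr
            u = np.clip(ndtr(z_c), np.finfo(float).tiny, 1 - 1e-16)
            inner_cols = {}
            for k, name in enumerate(comp_names):
                dist = spec.marginal(name).distribution()
                inner_cols[name] = np.asarray(
                    dist.ppf(u[:, :, k].ravel()), dtype=float)
        else:
            idx = gen.integers(0, len(draws), size=(m, n_inner))
            inner_cols = {c: draws[c].to_numpy()[idx].ravel() for c in comp_cols}
        for c in focal_cols:
            inner_cols[c] = np.repeat(outer[c].to_numpy()[start:stop], n_inner)
        frame = pd.DataFrame(inner_cols)
        Bi = model(frame).reshape(m, n_inner, n_arms)
        inner_means = Bi.mean(axis=1)
        per_outer[start:stop] = inner_means.max(axis=1) - inner_means[:, j_star]

    value, mc_se = _regret_estimate(per_outer)
    return VoiEstimate(value, mc_se, "nested", focal,
                       ctx.wtp if ctx is not None else np.nan, n_outer,
                       {"n_inner": n_inner, "conditional": conditional})


def _latent_scores_frame(spec: PosteriorSpec, name: str, values) -> np.ndarray:
    dist = spec.marginal(name).distribution()
    u = np.clip(np.asarray(dist.cdf(values), dtype=float), 1e-12, 1 - 1e-12)
    return ndtri(u)


# ---------------------------------------------------------------------------
# Focal-set -> method registry for the case-study model
# ---------------------------------------------------------------------------

def admissibility_registry() -> dict:
    """Map each analyzed focal set to its single-step strategy."""
    dM = set(DM_COMPONENTS)
    reg: dict[frozenset, str] = {
        frozenset(dM | {"alpha", "pB", "dS", "pL"}): "m1",
        frozenset(dM | {"alpha", "pB", "dS", "qM"}): "m2",
        frozenset(dM | {"dS"}): "m4-taylor",
        frozenset({"alpha", "pB"}): "m4-taylor",
    }
    for single in ("qM", "qS", "pL"):
        reg[frozenset({single})] = "m3"
    reg[frozenset({"qM", "qS"})] = "m3"
    reg[frozenset({"qM", "pL"})] = "m3"
    reg[frozenset({"qS", "pL"})] = "m3"
    reg[frozenset({"qM", "qS", "pL"})] = "m3"
    for single in ("alpha", "pB", "dS") + DM_COMPONENTS:
        reg.setdefault(frozenset({single}), "m5-spline")
    return reg


def select_method(focal) -> str:
    """Registered single-step method for a focal set, or ``"nested"``."""
    focal = normalize_focal(focal)
    if focal == frozenset(ALL_PARAMETERS):
        return "evpi"
    return admissibility_registry().get(focal, "nested")
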