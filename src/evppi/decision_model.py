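"""Incremental net benefit model for fluid resuscitation in severe childhood malaria.

Four strategies are compared for children hospitalized with severe malaria:
no fluid resuscitation (reference) and three resuscitation fluids (albumin,
saline, gelofusine).  Each patient reaches one of four outcomes — death,
neurological-sequelae-free (NS-free) survival, survival with short-term NS,
or survival with long-term NS.  The incremental net monetary benefit of fluid
``j`` relative to no fluid, at willingness to pay ``W`` per QALY, is

    B_j(theta) = (expit(alpha) - expit(alpha + dM_j))
                 * (W*qM - CH - pL * h2(pB, dS) * (W*qS + CS)) - CF_j

with ``h2(pB, dS) = pB*exp(dS) / (1 + pB*exp(dS))`` the NS probability among
patients "saved" by treatment (their NS log-odds are shifted by ``dS`` applied
to ``ln pB`` — as the model is stated, the shift composes with ``ln pB``, not
``logit pB``).  ``CH`` is the incremental hospital cost of survival, ``CS`` the
discounted lifetime cost of long-term NS, ``CF_j`` the fluid cost.

The treatment-effect symbols follow the published posterior summary:
``d2M`` (posterior mean -0.31), ``d3M`` (-2.34), ``d4M`` (-0.19).  The
symbol-to-fluid pairing used throughout pairs ``d2M`` with saline ($1),
``d3M`` with albumin ($35) and ``d4M`` with gelofusine ($12.50): it is the
only pairing consistent with the published results (albumin the sole effect
whose credible interval excludes zero; the albumin/gelofusine switching
threshold), the source tables themselves being internally contradictory about
the fluid names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .posterior import as_frame

__all__ = [
    "EconomicConstants",
    "Treatment",
    "DecisionContext",
    "DEFAULT_TREATMENTS",
    "InvalidParameterError",
    "ModelConsistencyError",
    "prob_death",
    "prob_ns_saved",
    "net_benefit_matrix",
    "incremental_net_benefit",
    "outcome_probabilities",
    "outcome_accounting_net_benefit",
    "ceac",
    "switching_threshold",
    "evpi_curve",
    "NO_SWITCH",
]

log = logging.getLogger(__name__)


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible domain."""


class ModelConsistencyError(RuntimeError):
    """Outcome probabilities failed an internal total-probability check."""


@dataclass(frozen=True)
class Treatment:
    """A strategy: its label and the mortality log-odds-ratio symbol it uses.

    The reference strategy (no fluid) has ``dm=None``: its log-odds-ratio is
    identically zero and its fluid cost must be zero.
    """

    name: str
    dm: str | None


DEFAULT_TREATMENTS: tuple[Treatment, ...] = (
    Treatment("no_fluid", None),
    Treatment("albumin", "d3M"),
    Treatment("saline", "d2M"),
    Treatment("gelofusine", "d4M"),
)

_DEFAULT_FLUID_COST = {"no_fluid": 0.0, "albumin": 35.0, "saline": 1.0,
                       "gelofusine": 12.5}


@dataclass(frozen=True)
class EconomicConstants:
    """Costs in USD: per-treatment fluid cost, incremental hospital cost of
    survival (5 days at $12/day), and discounted lifetime NS management cost."""

    fluid_cost: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FLUID_COST))
    hospital_cost: float = 60.0
    ns_lifetime_cost: float = 20000.0

    def __post_init__(self):
        if any(c < 0 for c in self.fluid_cost.values()):
            raise ValueError("fluid costs must be >= 0")
        if self.hospital_cost < 0 or self.ns_lifetime_cost < 0:
            raise ValueError("costs must be >= 0")


@dataclass(frozen=True)
class DecisionContext:
    """Willingness to pay (USD/QALY) and the ordered strategy list."""

    wtp: float = 250.0
    treatments: tuple[Treatment, ...] = DEFAULT_TREATMENTS

    def __post_init__(self):
        if self.wtp < 0:
            raise ValueError("willingness to pay must be >= 0")
        if self.treatments[0].dm is not None:
            raise ValueError("first treatment must be the no-fluid reference")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.treatments)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown treatment {name!r}") from None


def prob_death(alpha, dm_j=0.0):
    """Death probability: inverse-logit of baseline log-odds plus the
    treatment log-odds-ratio (zero for the reference arm)."""
    alpha = np.asarray(alpha, dtype=float)
    dm_j = np.asarray(dm_j, dtype=float)
    if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(dm_j))):
        raise InvalidParameterError("non-finite log-odds input")
    return expit(alpha + dm_j)


def prob_ns_saved(pB, dS):
    """NS probability among patients saved by treatment:
    ``pB*exp(dS) / (1 + pB*exp(dS))``, i.e. ``expit(dS + ln pB)``.

    The shift ``dS`` composes with ``ln pB`` (not ``logit pB``), so the
    boundary values are ``0`` at ``pB=0`` and ``exp(dS)/(1+exp(dS))`` at
    ``pB=1`` — the latter is below 1 for finite ``dS``.  Boundary inputs are
    permitted (they are measure-zero under the Beta(1,9) marginal) but logged.
    """
    pB = np.asarray(pB, dtype=float)
    dS = np.asarray(dS, dtype=float)
    if np.any(pB < 0) or np.any(pB > 1):
        raise InvalidParameterError("pB must lie in [0, 1]")
    if np.any((pB == 0) | (pB == 1)):
        log.warning("prob_ns_saved evaluated at a pB boundary (0 or 1)")
    odds = pB * np.exp(dS)
    return odds / (1.0 + odds)


def _column(draws: pd.DataFrame, name: str) -> np.ndarray:
    return draws[name].to_numpy(dtype=float)


def net_benefit_matrix(samples, econ: EconomicConstants,
                       ctx: DecisionContext) -> np.ndarray:
    """Incremental net benefit of every treatment for every draw.

    Returns an ``(n_draws, n_treatments)`` array; the reference column is
    identically zero.
    """
    draws = as_frame(samples)
    alpha = _column(draws, "alpha")
    p0 = prob_death(alpha)
    h2 = prob_ns_saved(_column(draws, "pB"), _column(draws, "dS"))
    bracket = (ctx.wtp * _column(draws, "qM") - econ.hospital_cost
               - _column(draws, "pL") * h2
               * (ctx.wtp * _column(draws, "qS") + econ.ns_lifetime_cost))
    out = np.zeros((len(draws), len(ctx.treatments)))
    for j, t in enumerate(ctx.treatments):
        if t.dm is None:
            continue
        dp = p0 - prob_death(alpha, _column(draws, t.dm))
        out[:, j] = dp * bracket - econ.fluid_cost[t.name]
    return out


def incremental_net_benefit(draw, treatment: str, econ: EconomicConstants,
                            ctx: DecisionContext):
    """Incremental net benefit of one treatment (scalar or vectorized draws)."""
    j = ctx.index(treatment)
    frame = as_frame({k: np.atleast_1d(v) for k, v in dict(draw).items()}
                     if not isinstance(draw, pd.DataFrame) else draw)
    values = net_benefit_matrix(frame, econ, ctx)[:, j]
    return float(values[0]) if values.size == 1 else values


# ---------------------------------------------------------------------------
# Outcome accounting: the four-outcome enumeration used as an independent
# oracle for the closed-form net-benefit expression.
# ---------------------------------------------------------------------------

def outcome_probabilities(draw, treatment: str, ctx: DecisionContext):
    """Probabilities of (death, NS-free survival, short-term NS, long-term NS).

    With fluid ``j``, survivors split into those who would have survived
    without fluids (NS risk ``pB``) and those saved by treatment (NS risk
    ``prob_ns_saved``); short-term NS persists long term with probability
    ``pL``.  Accepts scalar draws (returns shape ``(4,)``) or vectorized
    draws (returns ``(n, 4)``).
    """
    t = ctx.treatments[ctx.index(treatment)]
    d = dict(draw)
    alpha = np.asarray(d["alpha"], dtype=float)
    pB = np.asarray(d["pB"], dtype=float)
    pL = np.asarray(d["pL"], dtype=float)
    p0 = prob_death(alpha)
    if t.dm is None:
        p_die = p0
        ns28 = (1.0 - p0) * pB
    else:
        p_die = prob_death(alpha, np.asarray(d[t.dm], dtype=float))
        saved = p0 - p_die
        ns28 = (1.0 - p0) * pB + saved * prob_ns_saved(pB, d["dS"])
    probs = np.stack(np.broadcast_arrays(
        p_die,
        1.0 - p_die - ns28,
        ns28 * (1.0 - pL),
        ns28 * pL,
    ), axis=-1)
    if np.max(np.abs(probs.sum(axis=-1) - 1.0)) > 1e-12:
        raise ModelConsistencyError("outcome probabilities do not sum to 1")
    return probs


def outcome_accounting_net_benefit(draw, treatment: str,
                                   econ: EconomicConstants,
                                   ctx: DecisionContext):
    """Expected ``W*utility - cost`` by outcome enumeration, minus the same
    for the reference arm.  Algebraically identical to
    :func:`incremental_net_benefit`; kept as an independent derivation and
    used to validate the closed form."""

    def arm_total(name: str):
        t = ctx.treatments[ctx.index(name)]
        probs = outcome_probabilities(draw, name, ctx)
        d = dict(draw)
        qM = np.asarray(d["qM"], dtype=float)
        qS = np.asarray(d["qS"], dtype=float)
        cf = econ.fluid_cost[t.name]
        utility = np.stack(np.broadcast_arrays(
            np.zeros_like(qM), qM, qM, qM - qS), axis=-1)
        cost = np.array([
            cf,
            econ.hospital_cost + cf,
            econ.hospital_cost + cf,
            econ.hospital_cost + econ.ns_lifetime_cost + cf,
        ])
        return (probs * (ctx.wtp * utility - cost)).sum(axis=-1)

    value = arm_total(treatment) - arm_total(ctx.treatments[0].name)
    return float(value) if np.ndim(value) == 0 else value


# ---------------------------------------------------------------------------
# Decision summaries
# ---------------------------------------------------------------------------

def ceac(samples, econ: EconomicConstants, ctx: DecisionContext) -> pd.Series:
    """Cost-effectiveness acceptability: per-treatment probability of having
    the maximal incremental net benefit (ties to the lowest index)."""
    draws = as_frame(samples)
    if len(draws) == 0:
        raise ValueError("empty sample")
    best = net_benefit_matrix(draws, econ, ctx).argmax(axis=1)
    counts = np.bincount(best, minlength=len(ctx.treatments))
    return pd.Series(counts / len(draws), index=list(ctx.names))


#: Sentinel returned by :func:`switching_threshold` when the optimum never
#: changes on the supplied grid.
NO_SWITCH = None


def switching_threshold(samples, econ: EconomicConstants,
                        w_grid: Sequence[float],
                        treatments: tuple[Treatment, ...] = DEFAULT_TREATMENTS,
                        resolution: float = 1.0):
    """Smallest willingness to pay at which the expected-net-benefit optimum
    changes, refined by bisection between bracketing grid points.

    Returns ``NO_SWITCH`` (None) if the optimum is the same at every grid
    point.
    """
    w_grid = np.asarray(w_grid, dtype=float)
    if len(w_grid) < 2 or np.any(np.diff(w_grid) <= 0):
        raise ValueError("w_grid must be strictly increasing with >= 2 points")
    draws = as_frame(samples)

    def best(w: float) -> int:
        ctx = DecisionContext(wtp=w, treatments=treatments)
        return int(net_benefit_matrix(draws, econ, ctx).mean(axis=0).argmax())

    choices = [best(w) for w in w_grid]
    switch_at = next((i for i in range(1, len(choices))
                      if choices[i] != choices[i - 1]), None)
    if switch_at is None:
        return NO_SWITCH
    lo, hi = w_grid[switch_at - 1], w_grid[switch_at]
    b_lo = choices[switch_at - 1]
    while hi - lo > resolution:
        mid = (lo + hi) / 2.0
        if best(mid) == b_lo:
            lo = mid
        else:
            hi = mid
    return float(hi)


def evpi_curve(samples, econ: EconomicConstants, w_grid: Sequence[float],
               treatments: tuple[Treatment, ...] = DEFAULT_TREATMENTS
               ) -> pd.DataFrame:
    """EVPI at each willingness-to-pay value; columns W, value, mc_se."""
    from . import voi  # local import to avoid a cycle

    w_grid = np.asarray(w_grid, dtype=float)
    if len(w_grid) < 1:
        raise ValueError("w_grid must be non-empty")
    rows = []
    for w in w_grid:
        est = voi.evpi(samples, econ, DecisionContext(wtp=float(w),
                                                      treatments=treatments))
        rows.append({"W": float(w), "value": est.value, "mc_se": est.mc_se})
    return pd.DataFrame(rows)
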