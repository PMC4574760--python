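"""Core five-stage kinetics: state, rates, feedback, smooth switches, RHS.

The model tracks cell numbers in five myogenic stages of adipose-derived
stem cells (ASCs):

    stage 0  naive ASC (no myogenic marker)
    stage 1  PAX7+ activated cell
    stage 2  Desmin+ (MyoD-) committed progenitor
    stage 3  MyoD+ (MHC-) myoblast
    stage 4  MHC+ terminally differentiated cell

Cells progress stage-to-stage via asymmetric division (a dividing stage-i
cell keeps a daughter in stage i with probability r_i; the 2(1-r_i) excess
daughters per division enter stage i+1) and, from stage 3 to 4 only, via a
division-free direct differentiation rate D.  All fluxes are multiplied by
a logistic crowding factor f(n_tot) that encodes a density ceiling in the
culture.  All rates are per day; time is in days; cell numbers are
continuous and non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "N_STAGES",
    "StageState",
    "RateSet",
    "FeedbackConfig",
    "SwitchConfig",
    "Direction",
    "feedback_factor",
    "l_composite",
    "l3_composite",
    "smooth_l1",
    "smooth_D",
    "rhs",
    "apply_stage1_suppression",
]

N_STAGES = 5

Direction = Literal["ascending", "descending"]

#: Exponent clamp for the logistic feedback factor (avoids overflow; the
#: factor saturates to 0 or 1 far beyond the threshold anyway).
_EXP_CLAMP = 700.0


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class StageState:
    """Cell numbers in the five stages at one time point."""

    n0: float
    n1: float = 0.0
    n2: float = 0.0
    n3: float = 0.0
    n4: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n0", "n1", "n2", "n3", "n4"):
            v = _check_finite(name, getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        _check_finite("t", self.t)

    @property
    def n_tot(self) -> float:
        return self.n0 + self.n1 + self.n2 + self.n3 + self.n4

    def as_array(self) -> np.ndarray:
        return np.array([self.n0, self.n1, self.n2, self.n3, self.n4], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float], t: float = 0.0) -> "StageState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STAGES,):
            raise ValueError(f"expected a length-{N_STAGES} vector, got shape {y.shape}")
        return cls(*(float(v) for v in y), t=float(t))


@dataclass(frozen=True)
class RateSet:
    """Per-stage kinetic rates active during one epoch.

    r, p, d are length-5 tuples of self-renewal ratios (dimensionless,
    0..1), proliferation rates (1/day) and death rates (1/day); ``D`` is
    the direct stage-3 -> stage-4 differentiation rate (1/day, nonzero
    only in the final epoch).  Stage 4 never divides (r4 = p4 = 0).
    """

    r: tuple[float, float, float, float, float]
    p: tuple[float, float, float, float, float]
    d: tuple[float, float, float, float, float]
    D: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r", "p", "d"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != N_STAGES:
                raise ValueError(f"{name} must have {N_STAGES} entries")
            object.__setattr__(self, name, vals)
        for i, ri in enumerate(self.r):
            if not 0.0 <= ri <= 1.0:
                raise ValueError(f"r{i} must lie in [0, 1], got {ri}")
        for name in ("p", "d"):
            for i, v in enumerate(getattr(self, name)):
                if v < 0:
                    raise ValueError(f"{name}{i} must be non-negative, got {v}")
        if self.D < 0:
            raise ValueError(f"D must be non-negative, got {self.D}")
        object.__setattr__(self, "D", float(self.D))
        if self.r[4] != 0.0 or self.p[4] != 0.0:
            raise ValueError("stage 4 does not divide: r4 and p4 must be 0")

    def l(self, i: int) -> float:
        """Net per-capita growth rate of stage i (stage 3 subtracts D)."""
        if i == 3:
            return l3_composite(self.p[3], self.d[3], self.D)
        return l_composite(self.r[i], self.p[i], self.d[i])

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        return (
            np.array(self.r, dtype=float),
            np.array(self.p, dtype=float),
            np.array(self.d, dtype=float),
            self.D,
        )


@dataclass(frozen=True)
class FeedbackConfig:
    """Logistic density-feedback parameters.

    ``n_dagger`` is the cell-count ceiling at which every flux is halved;
    ``s`` sets how sharply the multiplier falls past the ceiling.  Defaults
    are the midpoints of the ranges used to train the model
    (n_dagger in [3e5, 3.5e5], s in [3e-5, 4e-5]).
    """

    n_dagger: float = 3.25e5
    s: float = 3.5e-5

    def __post_init__(self) -> None:
        if not (_check_finite("n_dagger", self.n_dagger) > 0):
            raise ValueError(f"n_dagger must be positive, got {self.n_dagger}")
        if not (_check_finite("s", self.s) > 0):
            raise ValueError(f"s must be positive, got {self.s}")


@dataclass(frozen=True)
class SwitchConfig:
    """Thresholds and ramp parameters for the hysteretic smooth switches.

    Two state-based switches are smoothed by piecewise-linear ramps:

    * the stage-1 (PAX7) peak: the composite rate l1 declines linearly
      from ``l_plus`` as n1 climbs from ``n1_star`` to ``n1_dstar``
      (the upper knot, 1.05-1.1 x n1_star, where dn1/dt = 0), then on the
      way back down follows a second linear segment joining ``l_minus``
      at ``n1_star``;
    * the MHC release: the direct differentiation rate D ramps up with
      slope ``k`` once n3 exceeds ``n3_star``, and on descent joins the
      plateau ``D_plus`` at ``n3_star``.

    ``n1_release`` is the lower stage-1 threshold whose downward crossing
    triggers MyoD release (activation of the stage-3 equation).  After
    that event, mutual PAX7/MyoD inhibition is modelled by a suppression
    clamp: dn1/dt may not be positive while n1 >= ``n1_sup``.

    Fields left ``None`` are derived at run time by the engine:
    ``l_plus``/``l_minus`` from the effective epoch rate tables,
    ``slope_up_l1`` from the frozen stage-0 influx at the moment n1 first
    crosses ``n1_star`` (so that dn1/dt vanishes at ``n1_dstar``),
    ``slope_down_l1`` from the knot geometry, ``D_plus`` from the final
    epoch's D, ``k`` as D_plus / (n3_dstar - n3_star), and ``n1_sup`` as
    the value of n1 frozen at the MyoD-release event.
    """

    n1_star: float
    n3_star: float
    n1_dstar: float | None = None
    n3_dstar: float | None = None
    n1_release: float | None = None
    slope_up_l1: float | None = None
    slope_down_l1: float | None = None
    k: float | None = None
    D_plus: float | None = None
    l_plus: float | None = None
    l_minus: float | None = None
    suppression_enabled: bool = True
    n1_sup: float | None = None

    #: default upper-knot placement relative to the lower knot
    DSTAR_FACTOR_N1 = 1.075
    DSTAR_FACTOR_N3 = 1.1
    #: default MyoD-release threshold relative to n1_star
    RELEASE_FACTOR = 0.4

    def __post_init__(self) -> None:
        if not (_check_finite("n1_star", self.n1_star) > 0):
            raise ValueError("n1_star must be positive")
        if not (_check_finite("n3_star", self.n3_star) > 0):
            raise ValueError("n3_star must be positive")
        if self.n1_dstar is None:
            object.__setattr__(self, "n1_dstar", self.DSTAR_FACTOR_N1 * self.n1_star)
        if self.n3_dstar is None:
            object.__setattr__(self, "n3_dstar", self.DSTAR_FACTOR_N3 * self.n3_star)
        if self.n1_release is None:
            object.__setattr__(self, "n1_release", self.RELEASE_FACTOR * self.n1_star)
        ratio = self.n1_dstar / self.n1_star
        if not (1.05 - 1e-9 <= ratio <= 1.1 + 1e-9):
            raise ValueError(
                f"n1_dstar must lie in [1.05, 1.1] x n1_star, got ratio {ratio:.4f}"
            )
        if not self.n3_dstar > self.n3_star:
            raise ValueError("n3_dstar must exceed n3_star")
        if not 0 < self.n1_release < self.n1_star:
            raise ValueError("n1_release must lie in (0, n1_star)")
        if self.k is not None and self.k < 0:
            raise ValueError("k must be non-negative")
        if self.D_plus is not None and not self.D_plus > 0:
            raise ValueError("D_plus must be positive")
        if self.l_plus is not None and self.l_minus is not None:
            if not (self.l_plus > 0 > self.l_minus):
                raise ValueError("need l_plus > 0 > l_minus")

    # -- resolved accessors (raise if the engine has not filled them in) --
    def _req(self, name: str) -> float:
        v = getattr(self, name)
        if v is None:
            raise ValueError(f"SwitchConfig.{name} is unset; resolve it before use")
        return v

    def resolved_slope_down(self) -> float:
        """Slope of the descending l1 segment implied by the knots."""
        if self.slope_down_l1 is not None:
            return self.slope_down_l1
        span = self._req("n1_dstar") - self.n1_star
        l_top = self._req("l_plus") - self._req("slope_up_l1") * span
        return (l_top - self._req("l_minus")) / span


def feedback_factor(n_tot: float, cfg: FeedbackConfig) -> float:
    """Logistic crowding multiplier f = 1 / (1 + exp(s (n_tot - n_dagger))).

    Strictly decreasing in ``n_tot``, bounded in (0, 1), and exactly 0.5 at
    the ceiling ``n_dagger`` (a 50% cut of every flux).
    """
    n_tot = _check_finite("n_tot", n_tot)
    if n_tot < 0:
        raise ValueError(f"n_tot must be non-negative, got {n_tot}")
    z = cfg.s * (n_tot - cfg.n_dagger)
    z = min(max(z, -_EXP_CLAMP), _EXP_CLAMP)
    return 1.0 / (1.0 + math.exp(z))


def l_composite(r: float, p: float, d: float) -> float:
    """Net per-capita rate of an asymmetrically dividing stage: (2r-1)p - d."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must lie in [0, 1], got {r}")
    if p < 0 or d < 0:
        raise ValueError("p and d must be non-negative")
    return (2.0 * r - 1.0) * p - d


def l3_composite(p3: float, d3: float, D: float) -> float:
    """Net per-capita rate of stage 3 (full self-renewal, r3 = 1): p3 - d3 - D."""
    if p3 < 0 or d3 < 0 or D < 0:
        raise ValueError("p3, d3 and D must be non-negative")
    return p3 - d3 - D


def smooth_l1(n1: float, direction: Direction, cfg: SwitchConfig) -> float:
    """Hysteretic piecewise-linear ramp for the stage-1 composite rate l1.

    Ascending (dn1/dt >= 0): ``l_plus`` below ``n1_star``, then a linear
    decline with slope ``-slope_up_l1`` (the line is extended above the
    upper knot; it is self-limiting because the implied dn1/dt turns
    negative there).  Descending: a linear segment joining the ascending
    ramp's value at ``n1_dstar`` to ``l_minus`` at ``n1_star``, and
    ``l_minus`` below ``n1_star``.
    """
    if n1 < 0:
        raise ValueError(f"n1 must be non-negative, got {n1}")
    l_plus = cfg._req("l_plus")
    l_minus = cfg._req("l_minus")
    if direction == "ascending":
        if n1 <= cfg.n1_star:
            return l_plus
        return l_plus - cfg._req("slope_up_l1") * (n1 - cfg.n1_star)
    elif direction == "descending":
        if n1 < cfg.n1_star:
            return l_minus
        return l_minus + cfg.resolved_slope_down() * (n1 - cfg.n1_star)
    raise ValueError(f"direction must be 'ascending' or 'descending', got {direction!r}")


def smooth_D(n3: float, direction: Direction, cfg: SwitchConfig) -> float:
    """Hysteretic piecewise-linear ramp for the direct differentiation rate D.

    Ascending: 0 below ``n3_star``, then ``k (n3 - n3_star)`` (the line is
    extended above the upper knot).  Descending: a linear segment joining
    ``k (n3_dstar - n3_star)`` at ``n3_dstar`` to the plateau ``D_plus``
    at ``n3_star``, and ``D_plus`` below ``n3_star``.  Never negative.
    """
    if n3 < 0:
        raise ValueError(f"n3 must be non-negative, got {n3}")
    k = cfg._req("k")
    if k < 0:
        raise ValueError("k must be non-negative")
    if direction == "ascending":
        return max(0.0, k * (n3 - cfg.n3_star))
    elif direction == "descending":
        D_plus = cfg._req("D_plus")
        if n3 < cfg.n3_star:
            return D_plus
        span = cfg._req("n3_dstar") - cfg.n3_star
        top = k * span
        return max(0.0, D_plus + (top - D_plus) * (n3 - cfg.n3_star) / span)
    raise ValueError(f"direction must be 'ascending' or 'descending', got {direction!r}")


def rhs(
    state: StageState | np.ndarray,
    rates: RateSet,
    cfg: FeedbackConfig,
    active_stages: tuple[bool, bool] = (True, True),
    *,
    l1_override: float | None = None,
    D_override: float | None = None,
) -> np.ndarray:
    """Flux-balance right-hand side of the five-stage system (cells/day).

    Every term — self-renewal, death, asymmetric-division influx, direct
    differentiation — is multiplied by the crowding factor f(n_tot).
    ``active_stages`` = (stage-3 integrated, stage-4 integrated): before
    MyoD release the stage-3 equation is held at zero (and stage 2 has no
    outflow, which the rate tables already encode via r2 = 1); before MHC
    release D = 0 and the stage-4 equation is held at zero.

    ``l1_override`` / ``D_override`` substitute the smooth-switch ramp
    values for the table-implied l1 and D (used by the engine; the
    override changes the effective stage-1 death rate, so the flux-balance
    identity holds with d1_eff = (2 r1 - 1) p1 - l1_eff).
    """
    if isinstance(state, StageState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    if y.min() < -1e-9 * max(1.0, y.max()):
        raise ValueError(f"negative state components: {y}")
    y = np.maximum(y, 0.0)
    r, p, d, D_tab = rates.as_arrays()
    active3, active4 = active_stages

    f = feedback_factor(float(y.sum()), cfg)
    l1 = l1_override if l1_override is not None else l_composite(r[1], p[1], d[1])
    if not active4:
        D = 0.0
    else:
        D = D_override if D_override is not None else D_tab

    influx = 2.0 * (1.0 - r) * p * y  # influx[i] feeds stage i+1

    dy = np.empty(N_STAGES)
    dy[0] = l_composite(r[0], p[0], d[0]) * y[0]
    dy[1] = l1 * y[1] + influx[0]
    dy[2] = l_composite(r[2], p[2], d[2]) * y[2] + influx[1]
    if active3:
        dy[3] = (p[3] - d[3] - D) * y[3] + influx[2]
    else:
        dy[3] = 0.0
    if active4:
        dy[4] = D * y[3] - d[4] * y[4]
    else:
        dy[4] = 0.0
    return f * dy


def apply_stage1_suppression(
    derivative: float,
    n1: float,
    stage3_active: bool,
    cfg: SwitchConfig,
) -> float:
    """Clamp dn1/dt to be non-positive above the suppression threshold.

    Models the mutual PAX7/MyoD inhibition: once MyoD is released
    (stage 3 active), n1 may not increase above ``n1_sup``.  The clamp
    only blocks growth; decline passes through unchanged.
    """
    if not (cfg.suppression_enabled and stage3_active and cfg.n1_sup is not None):
        return derivative
    if n1 >= cfg.n1_sup:
        return min(derivative, 0.0)
    return derivative
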