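"""Switched-ODE integration engine, trajectory summaries and strain sweeps.

The five-stage system is integrated segment by segment.  Each segment has
a fixed discrete mode (active epoch, which stage equations are integrated,
which smooth-switch ramp is engaged) and ends at the first switching
event, located by root finding on the dense solver output:

    day t_strain   strain applied            (clocked)
    n1 ↑ n1*       stage-1 ramp engages      (state)
    dn1/dt ↓ 0     stage-1 peak              (state; or n1 ↑ n1**)
    n1 ↓ n1_rel    MyoD release, stage 3 on  (state)
    n3 ↑ n3*       MHC release, stage 4 on   (state)
    dn3/dt ↓ 0     stage-3 peak, D descends  (state)

Clocked parameter changes (strain application, MyoD release) are blended
over ``blend_width`` days with a logistic weight so the trajectory has no
slope discontinuities.  The stage-1 composite rate follows the
piecewise-linear ascending ramp in state; after the peak it relaxes to
the post-switch value l⁻ over the same blend width (see docs/methods.md
for why the descent is clocked rather than state-based).  The direct
differentiation rate D follows its state-based ramp in both directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import RunConfig, config_fingerprint
from .kinetics import N_STAGES, feedback_factor
from .regimes import RegimeState, interpolate_rates

__all__ = [
    "SimulationResult",
    "SweepSummary",
    "IntegrationError",
    "NoCrossingError",
    "simulate",
    "summarize",
    "strain_sweep",
    "critical_strain",
    "flux_audit",
]

#: experiment horizon (days) over which summaries are defined
EXPERIMENT_DAY = 21.0


class IntegrationError(RuntimeError):
    """Solver failure or inadmissible negative excursion."""


class NoCrossingError(ValueError):
    """Bisection classifier does not change value on the bracket."""


def _expit(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-min(z, 700.0)))
    e = math.exp(max(z, -700.0))
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Dense trajectory of one run plus its event log and provenance."""

    t: np.ndarray
    stages: np.ndarray          # shape (T, 5)
    f: np.ndarray               # feedback factor along the trajectory
    regime: np.ndarray          # active epoch index (1..5) per point
    event_times: dict
    config_fingerprint: str
    ramp_info: dict
    _segments: list = field(default_factory=list, repr=False)

    @property
    def n_tot(self) -> np.ndarray:
        return self.stages.sum(axis=1)

    def interp(self, t: float) -> np.ndarray:
        """Stage vector at time ``t`` from the solver's dense output."""
        for seg in self._segments:
            if seg["t0"] - 1e-12 <= t <= seg["t1"] + 1e-12:
                return np.maximum(seg["dense"](min(max(t, seg["t0"]), seg["t1"])), 0.0)
        raise ValueError(f"t={t} outside the simulated range")

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stages, columns=[f"n{i}" for i in range(N_STAGES)])
        df.insert(0, "t_day", self.t)
        df["n_tot"] = self.n_tot
        df["f"] = self.f
        df["regime"] = self.regime
        return df

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class SweepSummary:
    """Qualitative pattern descriptors of one run (day-21 window)."""

    epsilon: float
    frac_stem_day21: float
    frac_term_day21: float
    day_n0_max: float
    day_n4_onset: float | None
    n4_end: float
    day_n3_threshold: float | None
    pattern: str  # "static-like" or "dynamic-like"


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

class _Engine:
    """One simulation run; mutable mode state lives here."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.sw = config.switches
        self.fb = config.feedback
        self.sol = config.solver
        self.proto = config.protocol
        schedule = interpolate_rates(config.table, self.proto.epsilon)
        self.schedule = schedule
        self.epoch_arrays = [rs.as_arrays() for rs in schedule.epochs]

        # discrete mode, updated at events
        self.epoch = 1
        self.prev_arr = None          # snapshot rates blended FROM
        self.cur_arr = self.epoch_arrays[0]
        self.blend_t0 = None
        self.active3 = False
        self.active4 = False
        self.l1_mode = None           # None | "asc" | "desc"
        self.l_plus = None
        self.l_minus = None
        self.slope_up = None
        self.I_frozen = None
        self.t_pk = None
        self.l1_pk = None
        self.D_mode = None            # None | "asc" | "desc"
        self.k = None
        self.D_plus = None
        self.n3_pk = None
        self.D_pk = None
        self.n1_sup = None

        self.regime = RegimeState()
        self.segments: list[dict] = []
        self.event_times: dict[str, float] = {}

    # -- effective, possibly blended, rate arrays ---------------------------
    def _eff(self, t: float):
        r, p, d, D = self.cur_arr
        if self.blend_t0 is not None and self.prev_arr is not None:
            w = self.sol.blend_width
            dt = t - self.blend_t0
            if dt < 4.0 * w:
                b = _expit((dt - 0.5 * w) * 8.0 / w)
                r0, p0, d0, D0 = self.prev_arr
                r = r0 + (r - r0) * b
                p = p0 + (p - p0) * b
                d = d0 + (d - d0) * b
                D = D0 + (D - D0) * b
        return r, p, d, D

    def _l1_eff(self, t: float, n1: float, r, p, d) -> float:
        if self.l1_mode is None:
            return (2.0 * r[1] - 1.0) * p[1] - d[1]
        if self.l1_mode == "asc":
            if n1 <= self.sw.n1_star:
                return self.l_plus
            return self.l_plus - self.slope_up * (n1 - self.sw.n1_star)
        # "desc": relax from the frozen peak value to l_minus over blend_width
        w = self.sol.blend_width
        b = _expit((t - self.t_pk - 0.5 * w) * 8.0 / w)
        return self.l1_pk + (self.l_minus - self.l1_pk) * b

    def _D_eff(self, n3: float) -> float:
        if not self.active4 or self.D_mode is None:
            return 0.0
        if self.D_mode == "asc":
            return max(0.0, self.k * (n3 - self.sw.n3_star))
        if n3 < self.sw.n3_star:
            return self.D_plus
        span = self.n3_pk - self.sw.n3_star
        if span <= 0:
            return self.D_plus
        return max(0.0, self.D_plus + (self.D_pk - self.D_plus)
                   * (n3 - self.sw.n3_star) / span)

    def _suppression_factor(self, n1: float) -> float:
        # smooth clamp: growth is shut off over a narrow band below n1_sup
        delta = max(1.0, 1e-3 * self.n1_sup)
        return _expit((self.n1_sup - n1) / delta)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        y = np.maximum(y, 0.0)
        r, p, d, D_tab = self._eff(t)
        f = feedback_factor(float(y.sum()), self.fb)
        l1 = self._l1_eff(t, y[1], r, p, d)
        D = self._D_eff(y[3])

        dy = np.empty(N_STAGES)
        dy[0] = ((2.0 * r[0] - 1.0) * p[0] - d[0]) * y[0]
        d1 = l1 * y[1] + 2.0 * (1.0 - r[0]) * p[0] * y[0]
        if (self.sw.suppression_enabled and self.active3
                and self.n1_sup is not None and d1 > 0.0):
            d1 *= self._suppression_factor(y[1])
        dy[1] = d1
        dy[2] = ((2.0 * r[2] - 1.0) * p[2] - d[2]) * y[2] \
            + 2.0 * (1.0 - r[1]) * p[1] * y[1]
        dy[3] = ((p[3] - d[3] - D) * y[3]
                 + 2.0 * (1.0 - r[2]) * p[2] * y[2]) if self.active3 else 0.0
        dy[4] = (D * y[3] - d[4] * y[4]) if self.active4 else 0.0
        return f * dy

    def rhs_parts(self, t: float, y: np.ndarray):
        """Effective per-stage (p, d_eff) and f for the flux audit.

        d_eff folds the stage-1 ramp into an effective death rate
        (d1_eff = (2 r1 - 1) p1 - l1_eff) so that the flux-balance
        identity  d n_tot/dt = f (Σ p_i n_i - Σ d_eff_i n_i)  holds
        exactly whenever the suppression clamp is inactive.
        """
        y = np.maximum(y, 0.0)
        r, p, d, _ = self._eff(t)
        l1 = self._l1_eff(t, y[1], r, p, d)
        f = feedback_factor(float(y.sum()), self.fb)
        p_eff = p.copy()
        d_eff = d.copy()
        d_eff[1] = (2.0 * r[1] - 1.0) * p[1] - l1
        if not self.active3:
            # stage 2 keeps r2=1 here so its outflow is zero; stages 3/4 inert
            p_eff[3] = d_eff[3] = 0.0
        if not self.active4:
            p_eff[4] = d_eff[4] = 0.0
        clamped = bool(self.sw.suppression_enabled and self.active3
                       and self.n1_sup is not None
                       and y[1] > self.n1_sup - max(1.0, 1e-3 * self.n1_sup))
        return p_eff, d_eff, f, clamped

    # -- mode snapshot for replay -------------------------------------------
    _MODE_FIELDS = (
        "epoch", "prev_arr", "cur_arr", "blend_t0", "active3", "active4",
        "l1_mode", "l_plus", "l_minus", "slope_up", "I_frozen", "t_pk",
        "l1_pk", "D_mode", "k", "D_plus", "n3_pk", "D_pk", "n1_sup",
    )

    def _snapshot(self) -> dict:
        return {f: getattr(self, f) for f in self._MODE_FIELDS}

    def _restore(self, snap: dict) -> None:
        for f in self._MODE_FIELDS:
            setattr(self, f, snap[f])

    # -- segment integration -------------------------------------------------
    def _integrate(self, t0: float, t1: float, y0: np.ndarray, events: list):
        """Integrate rhs on [t0, t1]; stop at the first terminal event.

        Returns (t_stop, y_stop, dense, event_index) with event_index None
        if the horizon was reached.
        """
        if self.sol.method == "RK4":
            return self._integrate_rk4(t0, t1, y0, events)
        sol = solve_ivp(
            self.rhs, (t0, t1), y0, method=self.sol.method,
            rtol=self.sol.rtol, atol=self.sol.atol,
            max_step=self.sol.max_step, dense_output=True, events=events,
        )
        if sol.status == -1:
            raise IntegrationError(
                f"solver failed at t={sol.t[-1]:.4f}: {sol.message}; "
                f"last state {sol.y[:, -1]}"
            )
        if sol.status == 1:
            idx = next(i for i, te in enumerate(sol.t_events) if len(te))
            t_stop = float(sol.t_events[idx][0])
            y_stop = sol.y_events[idx][0].copy()
        else:
            idx = None
            t_stop = float(sol.t[-1])
            y_stop = sol.y[:, -1].copy()
        self._check_negativity(y_stop)
        return t_stop, y_stop, sol.sol, idx

    def _integrate_rk4(self, t0: float, t1: float, y0: np.ndarray, events: list):
        dt = self.sol.rk4_dt
        ts = [t0]
        ys = [np.asarray(y0, dtype=float)]
        ev_prev = [ev(t0, ys[0]) for ev in events]

        def step(t, y, h):
            k1 = self.rhs(t, y)
            k2 = self.rhs(t + h / 2, y + h / 2 * k1)
            k3 = self.rhs(t + h / 2, y + h / 2 * k2)
            k4 = self.rhs(t + h, y + h * k3)
            return y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        t, y = t0, ys[0]
        hit = None
        while t < t1 - 1e-12 and hit is None:
            h = min(dt, t1 - t)
            y_new = step(t, y, h)
            t_new = t + h
            for i, ev in enumerate(events):
                v_new = ev(t_new, y_new)
                direction = getattr(ev, "direction", 0)
                crossed = (ev_prev[i] < 0 <= v_new) if direction >= 0 else False
                crossed = crossed or ((ev_prev[i] > 0 >= v_new) if direction <= 0 else False)
                if crossed and not (ev_prev[i] == 0.0):
                    # bisect inside the step for the crossing time
                    a, b = 0.0, h
                    for _ in range(60):
                        m = 0.5 * (a + b)
                        ym = step(t, y, m)
                        vm = ev(t + m, ym)
                        if (vm >= 0) == (v_new >= 0):
                            b = m
                        else:
                            a = m
                    hit = (i, t + b, step(t, y, b))
                    break
                ev_prev[i] = v_new
            if hit is None:
                t, y = t_new, y_new
                ts.append(t)
                ys.append(y)
        if hit is not None:
            idx, t_stop, y_stop = hit
            ts.append(t_stop)
            ys.append(y_stop)
        else:
            idx, t_stop, y_stop = None, t, y
        ts_a = np.array(ts)
        ys_a = np.array(ys)

        def dense(tq):
            tq = np.atleast_1d(tq)
            out = np.empty((N_STAGES, len(tq)))
            for j in range(N_STAGES):
                out[j] = np.interp(tq, ts_a, ys_a[:, j])
            return out[:, 0] if len(tq) == 1 else out

        self._check_negativity(y_stop)
        return t_stop, y_stop.copy(), dense, idx

    def _check_negativity(self, y: np.ndarray) -> None:
        ntot = max(float(np.sum(np.maximum(y, 0.0))), 1.0)
        if y.min() < -1e-6 * ntot:
            raise IntegrationError(
                f"negative excursion beyond tolerance: {y} (n_tot={ntot:.3g})"
            )

    def _push_segment(self, t0, t1, dense):
        self.segments.append(
            {"t0": t0, "t1": t1, "dense": dense, "mode": self._snapshot()}
        )

    # -- the protocol state machine -----------------------------------------
    def run(self) -> SimulationResult:
        proto = self.proto
        y = self.cfg.initial.as_array()
        t = 0.0
        t_end = proto.t_end

        if t_end <= 0.0:
            # degenerate horizon: echo the initial state
            dense = (lambda tq, y0=y.copy():
                     np.tile(y0[:, None], (1, np.size(tq))).squeeze())
            self._push_segment(0.0, 0.0, dense)
            return self._finish(np.array([0.0]))

        # --- epoch 1: myogenic medium, before strain -----------------------
        if t < min(proto.t_strain, t_end):
            t1 = min(proto.t_strain, t_end)
            t_stop, y, dense, _ = self._integrate(t, t1, y, [])
            self._push_segment(t, t_stop, dense)
            t = t_stop

        # --- strain application (clocked) ----------------------------------
        if t_end > proto.t_strain:
            self.regime = self.regime.fire("strain_applied", proto.t_strain)
            self.event_times["strain_applied"] = proto.t_strain
            self.prev_arr = self._eff(t)
            self.cur_arr = self.epoch_arrays[1]
            self.blend_t0 = t
            self.epoch = 2

            # --- epoch 2: until n1 reaches n1* -----------------------------
            if y[1] < self.sw.n1_star:
                ev = _event(lambda tt, yy: yy[1] - self.sw.n1_star, direction=1)
                t_stop, y, dense, idx = self._integrate(t, t_end, y, [ev])
                self._push_segment(t, t_stop, dense)
                t = t_stop
                if idx is None:
                    return self._finish_grid(t_end)

            self._enter_ramp(t, y)

            # --- stage-1 ramp, ascending ------------------------------------
            # the peak fires when dn1/dt falls below a small relative floor:
            # with zero influx the derivative only approaches zero
            # asymptotically at the upper knot, so an exact zero crossing
            # would never trigger
            dpk = 1e-3 * self.sw.n1_star
            if self.rhs(t, y)[1] - dpk <= 0.0 or y[1] >= self.sw.n1_dstar:
                # already at/past the turning point when the ramp engages
                idx = 0
            else:
                ev_peak = _event(lambda tt, yy: self.rhs(tt, yy)[1] - dpk,
                                 direction=-1)
                ev_knot = _event(lambda tt, yy: yy[1] - self.sw.n1_dstar,
                                 direction=1)
                t_stop, y, dense, idx = self._integrate(
                    t, t_end, y, [ev_peak, ev_knot])
                self._push_segment(t, t_stop, dense)
                t = t_stop
            if idx is not None:
                self._enter_descent(t, y)

                # --- descent until MyoD release -----------------------------
                ev = _event(lambda tt, yy: yy[1] - self.sw.n1_release, direction=-1)
                t_stop, y, dense, idx = self._integrate(t, t_end, y, [ev])
                self._push_segment(t, t_stop, dense)
                t = t_stop
                if idx is not None:
                    self._enter_post_myod(t, y)

                    # --- stage 3 active, until n3 reaches n3* ---------------
                    ev = _event(lambda tt, yy: yy[3] - self.sw.n3_star, direction=1)
                    t_stop, y, dense, idx = self._integrate(t, t_end, y, [ev])
                    self._push_segment(t, t_stop, dense)
                    t = t_stop
                    if idx is not None:
                        self._enter_post_mhc(t, y)

                        # --- D ramp ascending, until the n3 peak ------------
                        if self.rhs(t, y)[3] <= 0.0:
                            idx = 0
                        else:
                            ev = _event(lambda tt, yy: self.rhs(tt, yy)[3],
                                        direction=-1)
                            t_stop, y, dense, idx = self._integrate(
                                t, t_end, y, [ev])
                            self._push_segment(t, t_stop, dense)
                            t = t_stop
                        if idx is not None:
                            self.n3_pk = float(y[3])
                            self.D_pk = self._D_eff(self.n3_pk)
                            self.D_mode = "desc"
                            self.event_times["n3_peak"] = t

        # --- run out the horizon in the final reached mode ------------------
        if t < t_end - 1e-12:
            t_stop, y, dense, _ = self._integrate(t, t_end, y, [])
            self._push_segment(t, t_stop, dense)
        return self._finish_grid(t_end)

    # -- event-entry helpers --------------------------------------------------
    def _enter_ramp(self, t: float, y: np.ndarray) -> None:
        self.regime = self.regime.fire("n1_upper_met", t)
        self.event_times["n1_upper_met"] = t
        r, p, d, _ = self._eff(t)
        self.I_frozen = 2.0 * (1.0 - r[0]) * p[0] * float(y[0])
        self.l_plus = (self.sw.l_plus if self.sw.l_plus is not None
                       else (2.0 * r[1] - 1.0) * p[1] - d[1])
        e3 = self.epoch_arrays[2]
        self.l_minus = (self.sw.l_minus if self.sw.l_minus is not None
                        else (2.0 * e3[0][1] - 1.0) * e3[1][1] - e3[2][1])
        span = self.sw.n1_dstar - self.sw.n1_star
        self.slope_up = (self.sw.slope_up_l1 if self.sw.slope_up_l1 is not None
                         else (self.l_plus + self.I_frozen / self.sw.n1_dstar) / span)
        self.prev_arr = self._eff(t)
        self.cur_arr = self.epoch_arrays[2]
        self.blend_t0 = t
        self.l1_mode = "asc"
        self.epoch = 3

    def _enter_descent(self, t: float, y: np.ndarray) -> None:
        self.t_pk = t
        n1_pk = float(y[1])
        self.l1_pk = self._l1_eff(t, n1_pk, *self._eff(t)[:3])
        self.l1_mode = "desc"
        self.event_times["n1_peak"] = t

    def _enter_post_myod(self, t: float, y: np.ndarray) -> None:
        self.regime = self.regime.fire("n1_lower_met", t)
        self.event_times["n1_lower_met"] = t
        self.active3 = True
        self.n1_sup = (self.sw.n1_sup if self.sw.n1_sup is not None
                       else float(y[1]))
        self.prev_arr = self._eff(t)
        self.cur_arr = self.epoch_arrays[3]
        self.blend_t0 = t
        self.epoch = 4

    def _enter_post_mhc(self, t: float, y: np.ndarray) -> None:
        self.regime = self.regime.fire("n3_upper_met", t)
        self.event_times["n3_upper_met"] = t
        self.active4 = True
        e5 = self.epoch_arrays[4]
        self.D_plus = self.sw.D_plus if self.sw.D_plus is not None else e5[3]
        span = self.sw.n3_dstar - self.sw.n3_star
        self.k = self.sw.k if self.sw.k is not None else self.D_plus / span
        self.D_mode = "asc"
        self.prev_arr = self._eff(t)
        self.cur_arr = self.epoch_arrays[4]
        self.blend_t0 = t
        self.epoch = 5

    # -- output assembly -------------------------------------------------------
    def _finish_grid(self, t_end: float) -> SimulationResult:
        n = int(round(t_end / self.sol.dense_dt))
        grid = np.linspace(0.0, t_end, n + 1)
        return self._finish(grid)

    def _finish(self, grid: np.ndarray) -> SimulationResult:
        T = len(grid)
        Y = np.empty((T, N_STAGES))
        regime = np.empty(T, dtype=int)
        seg_i = 0
        for i, tq in enumerate(grid):
            while (seg_i + 1 < len(self.segments)
                   and tq > self.segments[seg_i]["t1"] + 1e-12):
                seg_i += 1
            seg = self.segments[seg_i]
            tt = min(max(tq, seg["t0"]), seg["t1"])
            Y[i] = np.maximum(np.asarray(seg["dense"](tt)).reshape(N_STAGES), 0.0)
            regime[i] = seg["mode"]["epoch"]
        f = np.array([feedback_factor(float(row.sum()), self.fb) for row in Y])
        ramp_info = {
            "l_plus": self.l_plus, "l_minus": self.l_minus,
            "slope_up_l1": self.slope_up, "I_frozen": self.I_frozen,
            "l1_peak_value": self.l1_pk, "D_plus": self.D_plus, "k": self.k,
            "n3_peak": self.n3_pk, "n1_sup": self.n1_sup,
        }
        return SimulationResult(
            t=grid, stages=Y, f=f, regime=regime,
            event_times=dict(self.event_times),
            config_fingerprint=config_fingerprint(self.cfg),
            ramp_info=ramp_info,
            _segments=self.segments,
        )


def _event(fn: Callable, direction: int):
    fn.terminal = True
    fn.direction = direction
    return fn


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate(config: RunConfig) -> SimulationResult:
    """Integrate the five-stage system over the configured protocol.

    Deterministic given the configuration.  Inactive stages are held at
    zero until their release events; smooth switches and the density
    feedback are applied as described in the module docstring.
    """
    engine = _Engine(config)
    result = engine.run()
    result._engine = engine  # kept for the flux audit
    return result


def summarize(result: SimulationResult, onset_tol: float = 1.0) -> SweepSummary:
    """Pattern descriptors of a run over the day-21 experimental window.

    The run must cover at least 21 days.  Day-21 values use the dense
    solver interpolant.  The pattern is dynamic-like iff the stem-cell
    maximum moves off the horizon end AND terminally differentiated
    cells appear.
    """
    if result.t[-1] < EXPERIMENT_DAY - 1e-9:
        raise ValueError(
            f"summary needs a horizon of at least {EXPERIMENT_DAY} days, "
            f"got {result.t[-1]}"
        )
    y21 = result.interp(EXPERIMENT_DAY)
    ntot21 = float(y21.sum())
    if ntot21 <= 0:
        raise ValueError("total cell number vanished; fractions undefined")
    mask = result.t <= EXPERIMENT_DAY + 1e-9
    n0 = result.stages[mask, 0]
    day_n0_max = float(result.t[mask][int(np.argmax(n0))])

    n4 = result.stages[:, 4]
    above = np.nonzero(n4 > onset_tol)[0]
    day_n4_onset = float(result.t[above[0]]) if len(above) else None
    day_n3_threshold = result.event_times.get("n3_upper_met")

    dynamic_like = (day_n0_max < EXPERIMENT_DAY - 0.5) and (day_n4_onset is not None)
    # epsilon is not stored in the result; caller-facing wrappers fill it in
    return SweepSummary(
        epsilon=float("nan"),
        frac_stem_day21=float(y21[0] / ntot21),
        frac_term_day21=float(y21[4] / ntot21),
        day_n0_max=day_n0_max,
        day_n4_onset=day_n4_onset,
        n4_end=float(result.stages[-1, 4]),
        day_n3_threshold=day_n3_threshold,
        pattern="dynamic-like" if dynamic_like else "static-like",
    )


def strain_sweep(config: RunConfig, epsilons: Sequence[float]) -> list[SweepSummary]:
    """One :class:`SweepSummary` per strain, same configuration otherwise."""
    out = []
    for eps in epsilons:
        res = simulate(config.with_epsilon(float(eps)))
        summ = summarize(res, onset_tol=config.solver.onset_tol)
        out.append(replace(summ, epsilon=float(eps)))
    return out


def sweep_frame(summaries: Sequence[SweepSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def critical_strain(
    config: RunConfig,
    lo: float,
    hi: float,
    criterion: str = "n0max_switch",
    tol: float = 1e-3,
) -> float:
    """Bisect for the strain at which the kinetic pattern flips.

    ``criterion``:

    * ``"n0max_switch"`` — the day of the stem-cell maximum over the
      21-day window moves off the horizon end;
    * ``"n4_appearance"`` — terminally differentiated cells exceed the
      onset tolerance at day 21.

    Raises :class:`NoCrossingError` if the classifier takes the same
    value at both bracket ends.
    """
    if criterion not in ("n0max_switch", "n4_appearance"):
        raise ValueError(f"unknown criterion {criterion!r}")

    def dynamic_side(eps: float) -> bool:
        res = simulate(config.with_epsilon(eps))
        if criterion == "n0max_switch":
            s = summarize(res, onset_tol=config.solver.onset_tol)
            return s.day_n0_max < EXPERIMENT_DAY - 0.5
        y21 = res.interp(EXPERIMENT_DAY)
        return float(y21[4]) > config.solver.onset_tol

    f_lo, f_hi = dynamic_side(lo), dynamic_side(hi)
    if f_lo == f_hi:
        raise NoCrossingError(
            f"criterion {criterion!r} is {f_lo} at both eps={lo} and eps={hi}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if dynamic_side(mid) == f_hi:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def flux_audit(result: SimulationResult) -> pd.DataFrame:
    """Recompute the flux-balance identity along a stored trajectory.

    For each dense grid point, evaluates the engine's right-hand side in
    the mode that was active there and returns the total-flux identity
      d n_tot/dt  =  f · (Σ p_i n_i − Σ d_eff,i n_i)
    (asymmetric-division and direct-differentiation terms cancel in the
    sum).  ``clamped`` marks points where the stage-1 suppression clamp
    may be active, where the identity intentionally does not hold.
    """
    engine = getattr(result, "_engine", None)
    if engine is None:
        raise ValueError("flux_audit needs a result produced by simulate()")
    rows = []
    saved = engine._snapshot()
    try:
        seg_i = 0
        for i, t in enumerate(result.t):
            while (seg_i + 1 < len(engine.segments)
                   and t > engine.segments[seg_i]["t1"] + 1e-12):
                seg_i += 1
            engine._restore(engine.segments[seg_i]["mode"])
            y = result.stages[i]
            dy = engine.rhs(t, y)
            p_eff, d_eff, f, clamped = engine.rhs_parts(t, y)
            rows.append({
                "t": t,
                "dntot_rhs": float(dy.sum()),
                "dntot_identity": float(f * (p_eff @ y - d_eff @ y)),
                "f": f,
                "clamped": clamped,
            })
    finally:
        engine._restore(saved)
    return pd.DataFrame(rows)
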