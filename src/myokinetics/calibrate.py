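"""Calibration of unreported quantities and synthetic-data generation.

The training experiment reports marker counts on days 1, 3, 7, 14 and 21
under the static (0% strain) and dynamic (10% strain) conditions, but its
raw counts are not reproduced here and the switch thresholds and initial
cell number were never published.  This module therefore provides

* :func:`calibrate_thresholds` — the procedure that produced the shipped
  calibration: a grid search placing the initial population, the switch
  thresholds and the MyoD-release level against every reported anchor
  (event days, day-40 terminal counts, day-21 fractions);
* :func:`generate_synthetic` — stage-count series with the model's
  assumed structure, sampled at the experimental days with multiplicative
  lognormal noise, for parameter-recovery studies;
* :func:`objective` / :func:`fit` — a weighted least-squares refit of a
  chosen free-parameter set (the experiment itself was matched by manual
  adjustment; the SSE objective is this package's stand-in for that).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config import RunConfig, SolverSettings, default_config
from .engine import simulate
from .kinetics import StageState, SwitchConfig
from .markers import MarkerCounts, markers_to_stages, stages_to_markers

__all__ = [
    "SAMPLING_DAYS",
    "ObservedSeries",
    "CalibrationResult",
    "generate_synthetic",
    "apply_counting_noise",
    "objective",
    "fit",
    "calibrate_thresholds",
    "FREE_PARAMETERS",
]

#: sampling design of the training experiment
SAMPLING_DAYS = (1.0, 3.0, 7.0, 14.0, 21.0)

#: regularizing floor (cells) for log-scale residuals and scalings
OBJECTIVE_FLOOR = 1e2
#: objective value returned when a simulation fails
PENALTY = 1e12

#: parameters exposed to `fit`, with the rule applying each to a config
FREE_PARAMETERS = ("n1_star", "n1_release", "n3_star", "n0_init")

#: solver settings used inside the objective (speed over ultimate accuracy)
_FIT_SOLVER = SolverSettings(rtol=1e-6, atol=1e-3, dense_dt=0.5)


@dataclass(frozen=True)
class ObservedSeries:
    """A marker time series observed under one culture condition."""

    condition: str                 # "static" or "dynamic"
    epsilon: float                 # 0.0 for static
    rows: tuple[MarkerCounts, ...]

    def __post_init__(self) -> None:
        if self.condition not in ("static", "dynamic"):
            raise ValueError("condition must be 'static' or 'dynamic'")
        days = [m.day for m in self.rows]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling days must be strictly increasing")
        object.__setattr__(self, "rows", tuple(self.rows))

    @property
    def days(self) -> tuple[float, ...]:
        return tuple(m.day for m in self.rows)

    def stage_matrix(self) -> np.ndarray:
        """(n_days, 5) stage counts implied by the marker rows."""
        return np.array([markers_to_stages(m).as_array() for m in self.rows])


@dataclass(frozen=True)
class CalibrationResult:
    params: dict
    objective_value: float
    converged: bool
    seed: int
    n_starts: int
    residuals: pd.DataFrame | None = None
    start_values: tuple[float, ...] = ()


def _apply_params(config: RunConfig, params: dict) -> RunConfig:
    """Return a config with the named free parameters substituted.

    ``n1_star`` moves its tied upper knot along with it (constant ratio);
    an explicit ``n1_release`` overrides the 0.4 x n1_star default.
    """
    unknown = set(params) - set(FREE_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")
    sw = config.switches
    kw = {}
    if "n1_star" in params:
        kw["n1_star"] = float(params["n1_star"])
        kw["n1_dstar"] = float(params["n1_star"]) * (sw.n1_dstar / sw.n1_star)
        kw["n1_release"] = float(params["n1_star"]) * (sw.n1_release / sw.n1_star)
    if "n1_release" in params:
        kw["n1_release"] = float(params["n1_release"])
    if "n3_star" in params:
        kw["n3_star"] = float(params["n3_star"])
        kw["n3_dstar"] = float(params["n3_star"]) * (sw.n3_dstar / sw.n3_star)
    switches = replace(sw, **kw) if kw else sw
    initial = config.initial
    if "n0_init" in params:
        initial = StageState(n0=float(params["n0_init"]), n1=initial.n1,
                             n2=initial.n2, n3=initial.n3, n4=initial.n4)
    return replace(config, switches=switches, initial=initial)


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

def apply_counting_noise(
    rows: list[MarkerCounts], noise_cv: float, rng: np.random.Generator
) -> list[MarkerCounts]:
    """Multiply each count by lognormal noise with median 1 and CV ``noise_cv``.

    Imaging-based counts are positive with a roughly constant coefficient
    of variation, hence the multiplicative model.  The marker nesting is
    re-imposed afterwards by sorting each (Des, MyoD, MHC) triple in
    descending order, and the total is floored at the labelled total so
    the naive compartment stays non-negative.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if noise_cv == 0:
        return list(rows)
    sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
    out = []
    for m in rows:
        noisy = {
            name: getattr(m, name) * float(np.exp(rng.normal(0.0, sigma)))
            for name in ("n_PAX7", "n_Des", "n_MyoD", "n_MHC", "n_tot")
        }
        des, myod, mhc = sorted(
            (noisy["n_Des"], noisy["n_MyoD"], noisy["n_MHC"]), reverse=True
        )
        n_tot = max(noisy["n_tot"], noisy["n_PAX7"] + des)
        out.append(MarkerCounts(day=m.day, n_PAX7=noisy["n_PAX7"], n_Des=des,
                                n_MyoD=myod, n_MHC=mhc, n_tot=n_tot))
    return out


def generate_synthetic(
    true_config: RunConfig,
    noise_cv: float = 0.10,
    seed: int = 0,
    *,
    epsilon: float | None = None,
    days: tuple[float, ...] = SAMPLING_DAYS,
) -> ObservedSeries:
    """Simulate the model and sample a noisy marker series from it.

    ``epsilon`` defaults to the configuration's protocol strain; pass 0.0
    for a static series.  Deterministic given ``seed``.
    """
    eps = true_config.protocol.epsilon if epsilon is None else float(epsilon)
    cfg = true_config.with_epsilon(eps)
    if cfg.protocol.t_end < max(days):
        cfg = cfg.with_horizon(max(days))
    res = simulate(cfg)
    rows = [stages_to_markers(StageState.from_array(res.interp(d), t=d))
            for d in days]
    rng = np.random.default_rng(seed)
    rows = apply_counting_noise(rows, noise_cv, rng)
    return ObservedSeries(
        condition="static" if eps == 0.0 else "dynamic",
        epsilon=eps, rows=tuple(rows),
    )


# ---------------------------------------------------------------------------
# objective and fit
# ---------------------------------------------------------------------------

def _as_series_list(observed) -> list[ObservedSeries]:
    if isinstance(observed, ObservedSeries):
        return [observed]
    return list(observed)


def objective(params: dict, observed, config: RunConfig | None = None) -> float:
    """Weighted SSE between simulated and observed stage counts.

    Simulates once per observed condition and converts to stage counts
    at the observed days.  Residuals for the directly measured stages
    (1-4) are taken on the log scale, log((sim+floor)/(obs+floor)) — the
    homoscedastic scale for multiplicative counting noise, with the
    100-cell floor regularizing near-empty stages.  The naive
    compartment n0 is not measured directly but derived as total minus
    labelled cells, so its noise is on the scale of the total count; its
    residual is scaled by max(n_tot, floor) instead.  Simulation
    failures yield a large penalty value instead of raising.
    """
    config = default_config() if config is None else config
    series = _as_series_list(observed)
    if not series:
        raise ValueError("no observed series given")
    cfg = _apply_params(config, params)
    cfg = replace(cfg, solver=_FIT_SOLVER)
    sse = 0.0
    for obs in series:
        run = cfg.with_epsilon(obs.epsilon).with_horizon(max(obs.days))
        try:
            res = simulate(run)
            sim = np.array([res.interp(d) for d in obs.days])
        except Exception:
            return PENALTY
        tgt = obs.stage_matrix()
        c = OBJECTIVE_FLOOR
        r_meas = np.log((sim[:, 1:] + c) / (tgt[:, 1:] + c))
        r0 = (sim[:, 0] - tgt[:, 0]) / np.maximum(tgt.sum(axis=1), c)
        sse += float((r_meas ** 2).sum() + (r0 ** 2).sum())
    return sse


def fit(
    observed,
    free_params: dict[str, tuple[float, float]],
    seed: int = 0,
    *,
    config: RunConfig | None = None,
    n_starts: int = 16,
    maxfev: int = 400,
) -> CalibrationResult:
    """Bounded multi-start Nelder-Mead fit of the free parameters.

    The objective is piecewise smooth (switch events move with the
    parameters), so a derivative-free local search from ``n_starts``
    starting points drawn uniformly from the bounds (plus the bound-box
    midpoint) is used; the best local optimum wins.  Deterministic given
    ``seed``.
    """
    if not free_params:
        raise ValueError("free_params must name at least one parameter")
    unknown = set(free_params) - set(FREE_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")
    for name, (lo, hi) in free_params.items():
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError(f"bounds for {name} must be finite with lo < hi")
    config = default_config() if config is None else config
    names = list(free_params)
    lo = np.array([free_params[n][0] for n in names])
    hi = np.array([free_params[n][1] for n in names])

    def unit_to_params(x: np.ndarray) -> dict:
        x = np.clip(x, 0.0, 1.0)
        return dict(zip(names, lo + x * (hi - lo)))

    def func(x: np.ndarray) -> float:
        return objective(unit_to_params(x), observed, config)

    rng = np.random.default_rng(seed)
    starts = [np.full(len(names), 0.5)]
    starts += [rng.uniform(size=len(names)) for _ in range(max(0, n_starts - 1))]

    best = None
    start_values = []
    errors = []
    for x0 in starts:
        try:
            res = minimize(
                func, x0, method="Nelder-Mead",
                bounds=[(0.0, 1.0)] * len(names),
                options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-8},
            )
        except Exception as exc:  # pragma: no cover - defensive
            errors.append(str(exc))
            continue
        start_values.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {n_starts} starts failed: {errors}")

    params = unit_to_params(best.x)
    resid = _residual_frame(params, observed, config)
    return CalibrationResult(
        params=params,
        objective_value=float(best.fun),
        converged=bool(best.success or best.fun < PENALTY),
        seed=seed,
        n_starts=len(starts),
        residuals=resid,
        start_values=tuple(start_values),
    )


def _residual_frame(params: dict, observed, config: RunConfig) -> pd.DataFrame:
    cfg = replace(_apply_params(config, params), solver=_FIT_SOLVER)
    rows = []
    for obs in _as_series_list(observed):
        run = cfg.with_epsilon(obs.epsilon).with_horizon(max(obs.days))
        res = simulate(run)
        tgt = obs.stage_matrix()
        for i, day in enumerate(obs.days):
            sim = res.interp(day)
            for s in range(5):
                rows.append({"condition": obs.condition, "day": day,
                             "stage": s, "observed": tgt[i, s],
                             "simulated": float(sim[s]),
                             "residual": float(sim[s] - tgt[i, s])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the shipped threshold calibration
# ---------------------------------------------------------------------------

#: reported anchors the shipped calibration targets: MHC-release days per
#: strain and the static MyoD-release day (tolerance "about" 3 days),
#: day-40 terminal cell counts and day-21 population fractions
#: (tolerance ~25%, the "about" precision of the reported values)
CALIBRATION_ANCHORS = {
    "mhc_day": {0.10: 12.0, 0.15: 10.0, 0.04: 19.0},
    "myod_day_static": 7.0,
    "n4_day40": {0.15: 3.7e5, 0.04: 2.5e5},
    "frac_term_day21": {0.15: 0.80},
    "frac_stem_day21_static": 0.50,
}


def _anchor_score(cfg: RunConfig) -> float:
    """Normalized squared mismatch of a config against the printed anchors.

    Day anchors are scaled by 3 days, count/fraction anchors by 25% of
    the target, so every anchor contributes ~1 at its stated tolerance.
    A static run that produces terminal cells, or one that never
    releases MyoD, is heavily penalized (the experiment shows neither).
    """
    runs = {eps: simulate(cfg.with_epsilon(eps).with_horizon(40.0))
            for eps in (0.0, 0.04, 0.10, 0.15)}
    A = CALIBRATION_ANCHORS
    sse = 0.0
    for eps, day in A["mhc_day"].items():
        got = runs[eps].event_times.get("n3_upper_met", 60.0)
        sse += ((got - day) / 3.0) ** 2
    got = runs[0.0].event_times.get("n1_lower_met", 60.0)
    sse += ((got - A["myod_day_static"]) / 3.0) ** 2
    for eps, n4 in A["n4_day40"].items():
        sse += ((runs[eps].stages[-1, 4] - n4) / (0.25 * n4)) ** 2
    for eps, frac in A["frac_term_day21"].items():
        y21 = runs[eps].interp(21.0)
        sse += ((y21[4] / y21.sum() - frac) / (0.25 * frac)) ** 2
    y21s = runs[0.0].interp(21.0)
    tgt = A["frac_stem_day21_static"]
    sse += ((y21s[0] / y21s.sum() - tgt) / (0.25 * tgt)) ** 2
    if runs[0.0].stages[:, 4].max() > 0:
        sse += 100.0
    return sse


def calibrate_thresholds(
    base: RunConfig | None = None,
    *,
    n0_grid: tuple[float, ...] = (7e4, 8e4, 9e4, 1e5),
    n1_ratio_grid: tuple[float, ...] = (0.75,),
    release_ratio_grid: tuple[float, ...] = (0.40, 0.45, 0.50),
    n3_ratio_grid: tuple[float, ...] = (1.2, 1.3, 1.4, 1.5),
) -> RunConfig:
    """Grid calibration of the unreported initial population and thresholds.

    Scans the initial stem-cell number n0(0), the two switch thresholds
    and the MyoD-release level (all parameterized as ratios to n0(0) or
    n1*) against the reported anchors in :data:`CALIBRATION_ANCHORS` and
    returns the best configuration.  The day-40 terminal counts pin the
    population scale — they are absolute cell numbers, so they cannot be
    matched by thresholds alone — and the static MyoD-release day pins
    the release level: too low a release threshold is overtaken by the
    rising quasi-steady floor of n1 in the static culture and MyoD never
    releases.  Deterministic (no randomness involved).
    """
    base = default_config() if base is None else base
    best = None
    for n0 in n0_grid:
        for r1 in n1_ratio_grid:
            for rr in release_ratio_grid:
                for r3 in n3_ratio_grid:
                    sw = SwitchConfig(n1_star=r1 * n0, n3_star=r3 * n0,
                                      n1_release=rr * r1 * n0)
                    cand = replace(base, switches=sw,
                                   initial=StageState(n0=n0))
                    score = _anchor_score(cand)
                    if best is None or score < best[0]:
                        best = (score, cand)
    return best[1]
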