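"""Strain protocol, epoch switching logic and strain interpolation.

The switching conditions are the same for every strain; only their firing
times move.  Events fire once, in a fixed order:

    strain_applied -> n1_upper_met -> n1_lower_met -> n3_upper_met

``strain_applied`` is clocked (day ``t_strain``); the rest are threshold
crossings of the state.  The active epoch index is a function of how many
events have fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kinetics import RateSet, StageState, SwitchConfig
from .rates import EpochRateTable, EpochSchedule

__all__ = [
    "EVENT_ORDER",
    "StrainProtocol",
    "RegimeState",
    "interpolate_rates",
    "active_rates",
    "update_events",
]

EVENT_ORDER = ("strain_applied", "n1_upper_met", "n1_lower_met", "n3_upper_met")

#: Strain at which the dynamic rate column was fitted; the linear map is
#: exact there and applied up to EPSILON_MAX.
EPSILON_REF = 0.10
EPSILON_MAX = 0.15


@dataclass(frozen=True)
class StrainProtocol:
    """Applied-strain protocol: amplitude and timing.

    ``epsilon`` is the cyclic-strain amplitude as a dimensionless decimal
    (0.10 = 10%).  Frequency and duty cycle of the cyclic loading enter
    the model only through this amplitude.  Strain is applied from day
    ``t_strain`` (default 3) to the end of the run.
    """

    epsilon: float = 0.10
    t_strain: float = 3.0
    t_end: float = 21.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= EPSILON_MAX:
            raise ValueError(
                f"epsilon must lie in [0, {EPSILON_MAX}] (linear strain map), "
                f"got {self.epsilon}"
            )
        if self.t_strain < 0:
            raise ValueError("t_strain must be non-negative")
        if self.t_end < 0:
            raise ValueError("t_end must be non-negative")


@dataclass(frozen=True)
class RegimeState:
    """Which switching events have fired, and when."""

    events_seen: frozenset[str] = frozenset()
    event_times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.events_seen) - set(EVENT_ORDER)
        if unknown:
            raise ValueError(f"unknown events: {sorted(unknown)}")
        # events must form a prefix of the canonical order
        n = len(self.events_seen)
        if set(EVENT_ORDER[:n]) != set(self.events_seen):
            raise ValueError(
                f"events must fire in order {EVENT_ORDER}, got {sorted(self.events_seen)}"
            )

    @property
    def epoch_index(self) -> int:
        """Active epoch, 1-based (1 = medium ... 5 = post-MHC)."""
        return 1 + len(self.events_seen)

    @property
    def next_pending(self) -> str | None:
        n = len(self.events_seen)
        return EVENT_ORDER[n] if n < len(EVENT_ORDER) else None

    def fire(self, event: str, t: float) -> "RegimeState":
        if event in self.events_seen:
            return self  # idempotent
        if event != self.next_pending:
            raise ValueError(
                f"event {event!r} cannot fire while {self.next_pending!r} is pending"
            )
        times = dict(self.event_times)
        times[event] = float(t)
        return RegimeState(self.events_seen | {event}, times)


def interpolate_rates(table: EpochRateTable, epsilon: float) -> EpochSchedule:
    """Linear strain interpolation of every kinetic coefficient.

    Each coefficient k is mapped to ``k_st + (k_dyn - k_st) * (eps/0.10)``;
    the map is exact at the two fitted conditions (0 and 10% strain) and
    extrapolates linearly up to 15%.  After interpolation self-renewal
    ratios are clipped to [0, 1] and rates to >= 0.
    """
    if not 0.0 <= epsilon <= EPSILON_MAX:
        raise ValueError(f"epsilon must lie in [0, {EPSILON_MAX}], got {epsilon}")
    # exact at the anchors (and bit-identical to the raw columns)
    if epsilon == 0.0:
        return table.static
    if epsilon == EPSILON_REF:
        return table.dynamic

    w = epsilon / EPSILON_REF
    epochs = []
    for st, dy in zip(table.static.epochs, table.dynamic.epochs):
        r = tuple(
            min(1.0, max(0.0, rs + (rd - rs) * w)) for rs, rd in zip(st.r, dy.r)
        )
        p = tuple(max(0.0, ps + (pd - ps) * w) for ps, pd in zip(st.p, dy.p))
        d = tuple(max(0.0, ds + (dd - ds) * w) for ds, dd in zip(st.d, dy.d))
        D = max(0.0, st.D + (dy.D - st.D) * w)
        epochs.append(RateSet(r=r, p=p, d=d, D=D))
    return EpochSchedule(tuple(epochs))


def active_rates(regime: RegimeState, t: float, schedule: EpochSchedule) -> RateSet:
    """Rate set of the epoch selected by the fired events.

    Before strain application the first-epoch rates apply even when
    epsilon > 0 (the columns are identical there); D is nonzero only in
    the final epoch; stage 2 has r2 = 1 (no outflow) until MyoD release.
    """
    if "strain_applied" in regime.events_seen and t < regime.event_times.get(
        "strain_applied", -float("inf")
    ):
        raise ValueError(f"t={t} precedes the recorded strain-application day")
    return schedule[regime.epoch_index - 1]


def update_events(
    regime: RegimeState,
    state: StageState,
    t: float,
    cfg: SwitchConfig,
    protocol: StrainProtocol,
) -> RegimeState:
    """Fire every pending event whose condition holds at (state, t).

    Conditions, checked strictly in canonical order (a later event never
    fires while an earlier one is pending):

    * ``strain_applied``   — t >= t_strain
    * ``n1_upper_met``     — n1 has reached the lower smoothing knot n1*
    * ``n1_lower_met``     — n1 has fallen to the MyoD-release threshold
      (necessarily after its peak, since n1_release < n1*)
    * ``n3_upper_met``     — n3 has reached n3* (MHC release)

    Events are idempotent; each fires at most once.
    """
    while True:
        pending = regime.next_pending
        if pending is None:
            return regime
        if pending == "strain_applied":
            ok = t >= protocol.t_strain
        elif pending == "n1_upper_met":
            ok = state.n1 >= cfg.n1_star
        elif pending == "n1_lower_met":
            ok = state.n1 <= cfg.n1_release
        else:  # n3_upper_met
            ok = state.n3 >= cfg.n3_star
        if not ok:
            return regime
        regime = regime.fire(pending, t)
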