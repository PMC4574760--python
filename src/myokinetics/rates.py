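"""Epoch rate schedule for the static and strained (dynamic) conditions.

The kinetic coefficients are piecewise constant over five epochs delimited
by the switching events of the protocol:

    1. medium      — day 0 (myogenic medium applied) to day 3 (strain applied)
    2. pre_peak    — day 3 until the upper stage-1 threshold n1* is met
    3. decline     — n1* met until n1 falls below the MyoD-release threshold
    4. post_myod   — MyoD released (stage 3 active) until n3 reaches n3*
    5. post_mhc    — MHC released (stage 4 active, direct differentiation on)

Each epoch carries a static (0% strain) and a dynamic (10% strain) rate
column, fitted to the marker time-course experiment; intermediate strains
are obtained by linear interpolation of every coefficient between the two
columns (see :mod:`myokinetics.regimes`).  Entries not involved in an
epoch (stage 3 before MyoD release, stage 4 and D before MHC release) are
stored as inert placeholders: r = 1 (no outflow), p = d = D = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetics import RateSet

__all__ = ["EPOCH_LABELS", "EpochRateTable", "EpochSchedule", "default_table"]

EPOCH_LABELS = ("medium", "pre_peak", "decline", "post_myod", "post_mhc")
N_EPOCHS = 5

#: Coefficients interpolated linearly in strain (all entries present in the
#: fitted table; r4 and p4 are structurally zero).
INTERPOLATED_COEFFS = (
    "r0", "p0", "d0", "r1", "p1", "d1", "r2", "p2", "d2",
    "r3", "p3", "d3", "D", "d4",
)


@dataclass(frozen=True)
class EpochSchedule:
    """A single effective rate column: one :class:`RateSet` per epoch."""

    epochs: tuple[RateSet, RateSet, RateSet, RateSet, RateSet]

    def __post_init__(self) -> None:
        if len(self.epochs) != N_EPOCHS:
            raise ValueError(f"expected exactly {N_EPOCHS} epochs")
        object.__setattr__(self, "epochs", tuple(self.epochs))
        final = self.epochs[-1]
        if final.r[3] != 1.0:
            raise ValueError("final epoch must have r3 = 1 (stage 3 fully self-renews)")

    def __getitem__(self, i: int) -> RateSet:
        return self.epochs[i]


@dataclass(frozen=True)
class EpochRateTable:
    """Static and dynamic rate columns over the five protocol epochs."""

    static: EpochSchedule
    dynamic: EpochSchedule

    def column(self, name: str) -> EpochSchedule:
        if name not in ("static", "dynamic"):
            raise ValueError(f"unknown column {name!r}")
        return getattr(self, name)


def _rs(r, p, d, D=0.0) -> RateSet:
    # pad inert stages: r=1 -> no asymmetric outflow, p=d=0 -> no flux
    # (stage 4 is padded with r=0 since it never divides)
    pad = 5 - len(r)
    r = tuple(r) + (1.0,) * pad
    if len(r) == 5 and pad:
        r = r[:4] + (0.0,)
    return RateSet(
        r=r,
        p=tuple(p) + (0.0,) * pad,
        d=tuple(d) + (0.0,) * pad,
        D=D,
    )


def default_table() -> EpochRateTable:
    """The fitted rate table for the 0% (static) and 10% (dynamic) conditions."""
    static = EpochSchedule((
        # medium: day 0-3, identical in both conditions
        _rs(r=(0.8, 0.9, 1.0), p=(0.4, 0.6, 0.2), d=(0.2, 0.2, 0.2)),
        # pre_peak: day 3 -> n1*
        _rs(r=(0.8, 0.9, 1.0), p=(0.4, 0.6, 0.2), d=(0.2, 0.2, 0.2)),
        # decline: n1* -> MyoD release
        _rs(r=(0.8, 0.0, 1.0), p=(0.4, 0.1, 0.2), d=(0.2, 0.6, 0.2)),
        # post_myod: stage 3 active
        _rs(r=(0.8, 0.0, 0.8, 1.0), p=(0.4, 0.1, 0.2, 0.1), d=(0.2, 0.6, 0.2, 0.25)),
        # post_mhc: stage 4 active, direct differentiation on
        _rs(r=(0.8, 0.0, 0.8, 1.0, 0.0), p=(0.4, 0.1, 0.2, 0.1, 0.0),
            d=(0.2, 0.6, 0.2, 0.25, 0.0), D=0.05),
    ))
    dynamic = EpochSchedule((
        _rs(r=(0.8, 0.9, 1.0), p=(0.4, 0.6, 0.2), d=(0.2, 0.2, 0.2)),
        _rs(r=(0.6, 0.9, 1.0), p=(0.1, 0.3, 0.4), d=(0.2, 0.0, 0.1)),
        _rs(r=(0.6, 0.0, 1.0), p=(0.1, 0.2, 0.4), d=(0.2, 0.35, 0.3)),
        _rs(r=(0.6, 0.0, 0.5, 1.0), p=(0.1, 0.2, 0.4, 0.3), d=(0.2, 0.35, 0.1, 0.20)),
        _rs(r=(0.6, 0.0, 0.5, 1.0, 0.0), p=(0.1, 0.2, 0.4, 0.3, 0.0),
            d=(0.2, 0.35, 0.1, 0.20, 0.0), D=0.55),
    ))
    return EpochRateTable(static=static, dynamic=dynamic)
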