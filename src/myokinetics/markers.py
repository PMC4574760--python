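"""Conversion between myogenic marker counts and model stage counts.

The experiment reports, at each sampling day, the number of cells
expressing each of four myogenic markers (PAX7, Desmin, MyoD, MHC) plus
the total cell number.  The markers are nested (every MHC+ cell is MyoD+,
every MyoD+ cell is Desmin+), so stage counts follow by differencing:

    n1 = n_PAX7
    n2 = n_Des  - n_MyoD
    n3 = n_MyoD - n_MHC
    n4 = n_MHC
    n0 = n_tot  - (n1 + n2 + n3 + n4)     (naive cells, not stained)

Real panels may violate the nesting; violations are flagged as errors,
never silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .kinetics import StageState

__all__ = [
    "MarkerCounts",
    "MarkerValidationError",
    "markers_to_stages",
    "stages_to_markers",
    "read_markers_csv",
    "write_markers_csv",
    "MARKER_COLUMNS",
]

MARKER_COLUMNS = ["day", "n_PAX7", "n_Des", "n_MyoD", "n_MHC", "n_tot"]


class MarkerValidationError(ValueError):
    """Marker counts violate the nesting or totality invariants."""


@dataclass(frozen=True)
class MarkerCounts:
    """Observed marker-positive cell counts at one sampling day."""

    day: float
    n_PAX7: float
    n_Des: float
    n_MyoD: float
    n_MHC: float
    n_tot: float | None = None

    def __post_init__(self) -> None:
        for name in ("n_PAX7", "n_Des", "n_MyoD", "n_MHC"):
            if getattr(self, name) < 0:
                raise MarkerValidationError(f"{name} must be non-negative")
        if self.n_MyoD > self.n_Des:
            raise MarkerValidationError(
                f"marker nesting violated: n_MyoD ({self.n_MyoD}) > n_Des ({self.n_Des})"
            )
        if self.n_MHC > self.n_MyoD:
            raise MarkerValidationError(
                f"marker nesting violated: n_MHC ({self.n_MHC}) > n_MyoD ({self.n_MyoD})"
            )
        if self.n_tot is not None:
            labelled = self.n_PAX7 + self.n_Des
            if self.n_tot < labelled - 1e-9 * max(1.0, labelled):
                raise MarkerValidationError(
                    f"n_tot ({self.n_tot}) is below the labelled total "
                    f"n_PAX7 + n_Des ({labelled}); n0 would be negative"
                )


def markers_to_stages(m: MarkerCounts) -> StageState:
    """Stage counts implied by a nested marker panel.

    ``n0`` requires ``n_tot``; without it the naive compartment is set to
    zero (it is not directly reported by the experiment).
    """
    n1 = m.n_PAX7
    n2 = m.n_Des - m.n_MyoD
    n3 = m.n_MyoD - m.n_MHC
    n4 = m.n_MHC
    n0 = 0.0 if m.n_tot is None else m.n_tot - (n1 + n2 + n3 + n4)
    if n0 < 0:
        if n0 >= -1e-9 * max(1.0, m.n_tot or 1.0):  # rounding slack
            n0 = 0.0
        else:
            raise MarkerValidationError(f"derived n0 is negative ({n0})")
    return StageState(n0=n0, n1=n1, n2=n2, n3=n3, n4=n4, t=m.day)


def stages_to_markers(s: StageState) -> MarkerCounts:
    """Marker panel implied by a stage state (exact inverse of
    :func:`markers_to_stages`)."""
    return MarkerCounts(
        day=s.t,
        n_PAX7=s.n1,
        n_Des=s.n2 + s.n3 + s.n4,
        n_MyoD=s.n3 + s.n4,
        n_MHC=s.n4,
        n_tot=s.n_tot,
    )


def read_markers_csv(path: str | Path) -> list[MarkerCounts]:
    """Read an observed marker time series (comma-delimited, header required)."""
    df = pd.read_csv(path)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns and c != "n_tot"]
    if missing:
        raise MarkerValidationError(f"missing column(s): {missing}")
    has_tot = "n_tot" in df.columns
    out = []
    for _, row in df.iterrows():
        out.append(MarkerCounts(
            day=float(row["day"]),
            n_PAX7=float(row["n_PAX7"]),
            n_Des=float(row["n_Des"]),
            n_MyoD=float(row["n_MyoD"]),
            n_MHC=float(row["n_MHC"]),
            n_tot=float(row["n_tot"]) if has_tot else None,
        ))
    return out


def write_markers_csv(rows: list[MarkerCounts], path: str | Path) -> None:
    df = pd.DataFrame([{
        "day": m.day, "n_PAX7": m.n_PAX7, "n_Des": m.n_Des,
        "n_MyoD": m.n_MyoD, "n_MHC": m.n_MHC,
        "n_tot": m.n_tot if m.n_tot is not None else "",
    } for m in rows])
    df.to_csv(path, index=False, lineterminator="\n")
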