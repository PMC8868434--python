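"""Radical-scavenging / ACE-inhibition percentages and IC50 estimation.

Percent activity comes straight from blank-corrected absorbances; DPPH and
ABTS share the same formula.  IC50 is estimated from a dose-response series
by a four-parameter logistic (4PL) least-squares fit on log-concentration,
falling back to log-linear interpolation between the two points bracketing
50% activity when the fit cannot be obtained.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit

from .errors import AssayValueError, NoEstimateError, UndefinedIndexError, UnitMismatchError

__all__ = [
    "AbsorbanceTriple",
    "DoseResponse",
    "Ic50Estimate",
    "scavenging_percent",
    "ace_inhibition_percent",
    "estimate_ic50",
    "four_param_logistic",
    "read_plate_csv",
    "ActivityRangeWarning",
]


class ActivityRangeWarning(UserWarning):
    """Computed activity falls outside [0, 100]%; value is kept as-is."""


@dataclass(frozen=True)
class AbsorbanceTriple:
    """One well-set of absorbance readings.

    ``a_control`` is the radical/enzyme reaction without sample (Ac / C),
    ``a_sample`` the reaction with sample (As / S), ``a_sample_blank`` the
    sample-only blank (Asc / Bs).  ``a_inhibitor_blank`` (Bi) applies to the
    ACE assay only and defaults to 0.
    """

    a_control: float
    a_sample: float
    a_sample_blank: float = 0.0
    a_inhibitor_blank: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a_control", "a_sample", "a_sample_blank", "a_inhibitor_blank"):
            if getattr(self, name) < 0:
                raise AssayValueError(f"{name} must be >= 0")


def scavenging_percent(t: AbsorbanceTriple) -> float:
    """Percent radical scavenging, 100 * (Ac - (As - Asc)) / Ac.

    Serves both DPPH and ABTS readouts.  Values outside [0, 100] are
    reported as-is with an :class:`ActivityRangeWarning`.
    """
    if t.a_control <= 0:
        raise UndefinedIndexError("scavenging_percent", "control absorbance is zero")
    pct = 100.0 * (t.a_control - (t.a_sample - t.a_sample_blank)) / t.a_control
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"scavenging activity {pct:.2f}% outside [0, 100]",
                      ActivityRangeWarning, stacklevel=2)
    return pct


def ace_inhibition_percent(t: AbsorbanceTriple) -> float:
    """Percent ACE inhibition, 100 * [(C - Bi) - (S - Bs)] / (C - Bi)."""
    denom = t.a_control - t.a_inhibitor_blank
    if denom <= 0:
        raise UndefinedIndexError("ace_inhibition_percent",
                                  "control minus inhibitor blank is not positive")
    pct = 100.0 * (denom - (t.a_sample - t.a_sample_blank)) / denom
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"ACE inhibition {pct:.2f}% outside [0, 100]",
                      ActivityRangeWarning, stacklevel=2)
    return pct


@dataclass(frozen=True)
class DoseResponse:
    """Concentration series with measured percent activities."""

    concentrations: tuple[float, ...]
    activities: tuple[float, ...]
    unit: str = "mg/mL"

    def __post_init__(self) -> None:
        c = self.concentrations
        if len(c) != len(self.activities):
            raise AssayValueError("concentrations and activities differ in length")
        if any(x <= 0 for x in c):
            raise AssayValueError("concentrations must be strictly positive")
        if any(c[i] >= c[i + 1] for i in range(len(c) - 1)):
            raise AssayValueError("concentrations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class Ic50Estimate:
    """IC50 in the units of the input series.

    ``method`` records how the number was obtained; ``fit_params`` carries
    the fitted (bottom, top, ic50, hill) when the 4PL route succeeded.
    """

    ic50: float
    unit: str
    method: str  # "logistic-fit" | "interpolation"
    fit_params: Optional[tuple[float, float, float, float]] = None

    def to_dict(self) -> dict:
        return {
            "ic50": self.ic50,
            "unit": self.unit,
            "method": self.method,
            "fit_params": None if self.fit_params is None else list(self.fit_params),
        }


def four_param_logistic(x, bottom: float, top: float, ic50: float, hill: float):
    """4PL response: bottom + (top - bottom) / (1 + (ic50/x)**hill)."""
    x = np.asarray(x, dtype=float)
    # optimizer trial steps may probe ic50 < 0, where the power is nan;
    # those trials are simply rejected by the solver
    with np.errstate(invalid="ignore", over="ignore"):
        return bottom + (top - bottom) / (1.0 + (ic50 / x) ** hill)


def _interpolate_ic50(d: DoseResponse) -> float:
    """Log-linear interpolation at the first 50% crossing; raises if the
    activities never bracket 50%."""
    conc = np.asarray(d.concentrations, dtype=float)
    act = np.asarray(d.activities, dtype=float)
    exact = np.nonzero(act == 50.0)[0]
    if exact.size:
        return float(conc[exact[0]])
    for i in range(len(act) - 1):
        lo, hi = act[i], act[i + 1]
        if (lo - 50.0) * (hi - 50.0) < 0:
            lx, ly = math.log(conc[i]), math.log(conc[i + 1])
            frac = (50.0 - lo) / (hi - lo)
            return float(math.exp(lx + frac * (ly - lx)))
    raise NoEstimateError(
        f"activities ({act.min():.1f}..{act.max():.1f}%) never cross 50%; "
        "no interpolation possible"
    )


def _fit_4pl(d: DoseResponse) -> tuple[float, tuple[float, float, float, float]]:
    conc = np.asarray(d.concentrations, dtype=float)
    act = np.asarray(d.activities, dtype=float)
    increasing = act[-1] >= act[0]
    bottom0 = float(act.min())
    top0 = float(act.max())
    # midpoint guess: geometric mean of the dose range
    ic50_0 = float(np.exp(np.mean(np.log(conc))))
    hill0 = 1.0 if increasing else -1.0
    params, _ = curve_fit(
        four_param_logistic,
        conc,
        act,
        p0=[bottom0, top0, ic50_0, hill0],
        maxfev=20000,
    )
    bottom, top, ic50, hill = (float(v) for v in params)
    if not (np.isfinite(ic50) and ic50 > 0):
        raise RuntimeError(f"fit returned non-physical ic50={ic50}")
    return ic50, (bottom, top, ic50, hill)


def estimate_ic50(d: DoseResponse, method: str = "auto") -> Ic50Estimate:
    """Estimate the half-maximal concentration of a dose-response series.

    ``method`` is ``"auto"`` (4PL fit, interpolation fallback),
    ``"logistic"`` (fit only) or ``"interpolation"``.  The 4PL midpoint
    parameter is reported for the fit route; the interpolation route
    returns the log-linear 50%-activity crossing.  Monotone-decreasing
    series are handled by the sign of the fitted hill slope.
    """
    if len(d) < 3:
        raise AssayValueError("IC50 estimation needs at least 3 doses")
    if method not in {"auto", "logistic", "interpolation"}:
        raise ValueError(f"unknown method {method!r}")

    if method == "interpolation":
        return Ic50Estimate(_interpolate_ic50(d), d.unit, "interpolation")

    fit_error: Optional[Exception] = None
    if len(d) >= 4:
        try:
            ic50, params = _fit_4pl(d)
            return Ic50Estimate(ic50, d.unit, "logistic-fit", fit_params=params)
        except Exception as exc:  # unconverged or degenerate fit
            fit_error = exc
    if method == "logistic":
        raise NoEstimateError(f"4PL fit failed: {fit_error}")
    try:
        return Ic50Estimate(_interpolate_ic50(d), d.unit, "interpolation")
    except NoEstimateError as exc:
        detail = f"; 4PL fit also failed: {fit_error}" if fit_error else ""
        raise NoEstimateError(str(exc) + detail) from exc


def read_plate_csv(
    path: Union[str, Path, io.TextIOBase],
) -> list[tuple[float, str, AbsorbanceTriple]]:
    """Read plate readings: ``concentration,unit,a_control,a_sample,
    a_sample_blank[,a_inhibitor_blank]``.

    Returns (concentration, unit, triple) per row; mixing units within one
    file raises :class:`UnitMismatchError`.
    """
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        handle = Path(path).open(newline="", encoding="utf-8")
        close = True
    try:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise AssayValueError("empty plate file: no header row")
        required = {"concentration", "unit", "a_control", "a_sample", "a_sample_blank"}
        missing = required - set(f.strip() for f in reader.fieldnames)
        if missing:
            raise AssayValueError(f"missing plate columns: {sorted(missing)}")
        rows: list[tuple[float, str, AbsorbanceTriple]] = []
        units_seen: set[str] = set()
        for rownum, row in enumerate(reader, start=2):
            unit = row["unit"].strip()
            units_seen.add(unit)
            if len(units_seen) > 1:
                raise UnitMismatchError(
                    f"row {rownum}: mixed concentration units {sorted(units_seen)}"
                )
            bi = row.get("a_inhibitor_blank", "") or "0"
            try:
                triple = AbsorbanceTriple(
                    a_control=float(row["a_control"]),
                    a_sample=float(row["a_sample"]),
                    a_sample_blank=float(row["a_sample_blank"]),
                    a_inhibitor_blank=float(bi),
                )
                conc = float(row["concentration"])
            except ValueError as exc:
                raise AssayValueError(f"row {rownum}: {exc}") from exc
            rows.append((conc, unit, triple))
        if not rows:
            raise AssayValueError("plate file has no data rows")
        return rows
    finally:
        if close:
            handle.close()
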