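"""Agro-meteorological features: biomass scaling, growing degree days, growth process ratio.

Above-ground biomass (AGB) is measured per plant by destructive sampling and
scaled to ton/ha with the planting density.  Growing degree days (GDD)
accumulate daily mean temperature above a crop base temperature.  The growth
process ratio (GPR) places a flight date on a cultivar's phenological
timeline: days after emergence divided by the cultivar's total growth-period
length, so early- and late-maturing cultivars observed on the same calendar
day map to different points of their growth cycles.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GDDValue",
    "GPRValue",
    "agb_per_ha",
    "accumulate_gdd",
    "gpr",
    "anchor_t1",
]

#: default base temperature for potato development, degrees Celsius
DEFAULT_BASE_TEMP = 7.0


@dataclass(frozen=True)
class GDDValue:
    """Accumulated growing degree days up to a flight date."""

    plot_id: str
    flight_date: dt.date
    gdd: float  # degree-days
    t_base: float  # degrees C


@dataclass(frozen=True)
class GPRValue:
    """Growth process ratio of a cultivar at a flight date."""

    cultivar_id: str
    flight_date: dt.date
    t1_days: float  # days after emergence
    t_total_days: int  # total growth-period length
    gpr: float  # dimensionless, stored full precision

    @property
    def reported(self) -> float:
        """Two-decimal value used in reports."""
        return round(self.gpr, 2)


def agb_per_ha(agb_ave: float, n: float, unit: str = "kg") -> float:
    """Scale mean per-plant biomass to ton/ha.

    Parameters
    ----------
    agb_ave : mean fresh biomass of the sampled plants, in ``unit`` per plant.
    n : planting density, plants per hectare.
    unit : ``"kg"`` or ``"ton"`` per plant.

    Returns
    -------
    AGB in ton/ha.
    """
    if agb_ave < 0:
        raise ValueError(f"agb_ave must be non-negative, got {agb_ave}")
    if n <= 0:
        raise ValueError(f"plant density must be positive, got {n}")
    if unit == "kg":
        factor = 1e-3
    elif unit == "ton":
        factor = 1.0
    else:
        raise ValueError(f"unknown unit {unit!r}; expected 'kg' or 'ton'")
    return agb_ave * factor * n


def accumulate_gdd(
    weather: pd.DataFrame,
    t_base: float,
    start_date: dt.date,
    end_date: dt.date,
    *,
    allow_negative: bool = False,
) -> float:
    """Accumulate growing degree days over ``[start_date, end_date]`` inclusive.

    ``weather`` must have columns ``date``, ``tmax``, ``tmin`` covering every
    day of the interval.  Each day contributes ``(tmax + tmin)/2 - t_base``;
    by default negative daily increments are floored at zero (standard
    agronomic practice), set ``allow_negative=True`` to accumulate the raw
    increments instead.
    """
    if start_date > end_date:
        raise ValueError(f"start_date {start_date} is after end_date {end_date}")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"]).dt.date
    w = w.set_index("date")
    wanted = pd.date_range(start_date, end_date, freq="D").date
    missing = [d for d in wanted if d not in w.index]
    if missing:
        raise ValueError(
            f"weather series is missing {len(missing)} day(s): "
            f"{', '.join(str(d) for d in missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    sub = w.loc[list(wanted)]
    daily = (sub["tmax"].to_numpy() + sub["tmin"].to_numpy()) / 2.0 - t_base
    if not allow_negative:
        daily = np.maximum(daily, 0.0)
    return float(daily.sum())


def gpr(t1: float, t_total: float) -> float:
    """Growth process ratio: days after emergence over total growth-period days.

    Values above 1 (observation past the nominal growth period) are allowed
    with a warning; they occur when harvest is delayed past maturity.
    """
    if t_total <= 0:
        raise ValueError(f"total growth period must be positive, got {t_total}")
    if t1 < 0:
        raise ValueError(f"days after emergence must be non-negative, got {t1}")
    value = t1 / t_total
    if value > 1:
        warnings.warn(
            f"GPR {value:.2f} exceeds 1: observation past the nominal growth period",
            stacklevel=2,
        )
    return value


def anchor_t1(
    gpr_s1: float,
    t_total: int,
    s1_date: dt.date,
    flight_date: dt.date,
) -> int:
    """Reconstruct days-after-emergence at ``flight_date`` from a first-stage anchor.

    When emergence dates are not recorded, a known GPR at the first flight
    (tuber formation) anchors the timeline: ``T1`` at the anchor is
    ``round(gpr_s1 * t_total)`` and later flights add the calendar gap.
    """
    if not 0.0 < gpr_s1 < 1.0:
        raise ValueError(f"anchor GPR must lie in (0, 1), got {gpr_s1}")
    if flight_date < s1_date:
        raise ValueError(
            f"flight_date {flight_date} precedes the anchor date {s1_date}"
        )
    base = int(round(gpr_s1 * t_total))
    return base + (flight_date - s1_date).days


def gpr_at(
    cultivar_id: str,
    t_total: int,
    emergence_date: dt.date,
    flight_date: dt.date,
) -> GPRValue:
    """GPR of a cultivar at a flight date, from its emergence date."""
    if flight_date < emergence_date:
        raise ValueError(
            f"flight_date {flight_date} precedes emergence {emergence_date}"
        )
    t1 = (flight_date - emergence_date).days
    return GPRValue(
        cultivar_id=cultivar_id,
        flight_date=flight_date,
        t1_days=t1,
        t_total_days=t_total,
        gpr=gpr(t1, t_total),
    )
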