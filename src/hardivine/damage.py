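"""Freezing-damage potential from predicted LT50 and daily minimum temperature.

The damage potential P (percent, 0–100) for a day is a logistic function of
the gap between the daily minimum temperature T and the predicted LT50::

    P = 100 / (1 + exp(-(ln(1 - P_h) - ln(P_h)) / g * (T - LT50_pred)))

P_h and g shape the sigmoid: P reaches (1 - P_h)·100 % when T sits g °C
*above* the predicted LT50 and P_h·100 % when T sits g °C *below* it.  With
the defaults P_h = 0.9, g = 2 °C, that is 10 % and 90 % at ±2 °C, and always
50 % exactly at T = LT50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DamageParams", "damage_potential", "daily_damage_table", "season_summary"]


@dataclass(frozen=True)
class DamageParams:
    """Sigmoid constants: P_h ∈ (0.5, 1) attained at a gap of g °C below LT50."""

    p_h: float = 0.9
    g: float = 2.0

    def __post_init__(self) -> None:
        if not 0.5 < self.p_h < 1.0:
            raise ValueError(f"P_h must be in (0.5, 1), got {self.p_h}")
        if self.g <= 0:
            raise ValueError(f"g must be > 0, got {self.g}")

    @property
    def slope(self) -> float:
        return (math.log(1.0 - self.p_h) - math.log(self.p_h)) / self.g


def damage_potential(t_min, lt50_pred, params: DamageParams = DamageParams()):
    """Damage potential in percent; strictly decreasing in T − LT50_pred."""
    gap = np.asarray(t_min, dtype=float) - np.asarray(lt50_pred, dtype=float)
    p = 100.0 / (1.0 + np.exp(-params.slope * gap))
    return float(p) if p.ndim == 0 else p


def daily_damage_table(
    dates, t_min, lt50_pred, params: DamageParams = DamageParams()
) -> pd.DataFrame:
    """Per-day table: date, T_min, predicted LT50, damage potential P."""
    df = pd.DataFrame({"date": dates, "t_min": t_min, "lt50_pred": lt50_pred})
    df["damage_potential"] = damage_potential(
        df["t_min"].to_numpy(), df["lt50_pred"].to_numpy(), params
    )
    return df


def season_summary(daily: pd.DataFrame) -> dict:
    """Season extremes: maximum damage potential and deepest predicted LT50."""
    if daily.empty:
        raise ValueError("empty damage table")
    i_max = daily["damage_potential"].idxmax()
    i_min = daily["lt50_pred"].idxmin()
    return {
        "max_damage_potential": float(daily["damage_potential"].max()),
        "max_damage_date": str(daily.loc[i_max, "date"]),
        "min_predicted_lt50": float(daily["lt50_pred"].min()),
        "min_lt50_date": str(daily.loc[i_min, "date"]),
    }
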