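"""Growing degree days (GDD) from daily min/max temperatures.

Phenology dates (heading, anthesis) are expressed as thermal time: degree
days accumulate from an onset day — the day after the first five consecutive
days whose average temperature exceeds 32 °F — with daily temperatures
clamped to the [32, 86] °F range before averaging.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

BASE_F = 32.0
CEILING_F = 86.0
ONSET_RUN_DAYS = 5


def load_temperature_series(path: str | Path) -> pd.DataFrame:
    """Read a daily series CSV with columns date, t_min_f, t_max_f."""
    ts = pd.read_csv(path, parse_dates=["date"])
    return validate_temperature_series(ts)


def validate_temperature_series(ts: pd.DataFrame) -> pd.DataFrame:
    ts = ts.sort_values("date").reset_index(drop=True)
    if (ts["t_min_f"] > ts["t_max_f"]).any():
        bad = ts.loc[ts["t_min_f"] > ts["t_max_f"], "date"].iloc[0]
        raise ValueError(f"t_min > t_max on {bad}")
    if len(ts) > 1:
        gaps = ts["date"].diff().dropna()
        if (gaps != pd.Timedelta(days=1)).any():
            raise ValueError("dates must be consecutive days")
    return ts


def gdd_onset_day(ts: pd.DataFrame) -> pd.Timestamp:
    """Day accumulation starts: the day after the first run of
    ``ONSET_RUN_DAYS`` consecutive days with mean temperature strictly
    above 32 °F."""
    ts = validate_temperature_series(ts)
    if len(ts) < ONSET_RUN_DAYS:
        raise ValueError(f"need at least {ONSET_RUN_DAYS} days")
    avg = (ts["t_min_f"].to_numpy() + ts["t_max_f"].to_numpy()) / 2.0
    warm = avg > BASE_F
    run = 0
    for i, w in enumerate(warm):
        run = run + 1 if w else 0
        if run == ONSET_RUN_DAYS:
            return ts["date"].iloc[i] + pd.Timedelta(days=1)
    raise ValueError("onset not reached: no 5-day run above 32 °F")


def daily_gdd(t_min: float, t_max: float) -> float:
    """Degree days for one day: ((Adj.Min + Adj.Max)/2 - 32), floored at 0,
    with Adj.Min = max(t_min, 32) and Adj.Max = min(t_max, 86)."""
    if t_min > t_max:
        raise ValueError(f"t_min {t_min} exceeds t_max {t_max}")
    adj_min = max(t_min, BASE_F)
    adj_max = min(t_max, CEILING_F)
    return max(0.0, (adj_min + adj_max) / 2.0 - BASE_F)


def cumulative_gdd(ts: pd.DataFrame, event_date) -> float:
    """Sum of daily GDD from the onset day through ``event_date`` inclusive."""
    ts = validate_temperature_series(ts)
    event_date = pd.Timestamp(event_date)
    onset = gdd_onset_day(ts)
    if event_date < onset:
        raise ValueError(f"event {event_date.date()} precedes onset {onset.date()}")
    window = ts[(ts["date"] >= onset) & (ts["date"] <= event_date)]
    return float(
        sum(daily_gdd(lo, hi) for lo, hi in zip(window["t_min_f"], window["t_max_f"]))
    )


def make_temperature_series(start: str, t_min, t_max) -> pd.DataFrame:
    """Convenience constructor from parallel min/max arrays (°F)."""
    t_min = np.atleast_1d(np.asarray(t_min, dtype=float))
    t_max = np.atleast_1d(np.asarray(t_max, dtype=float))
    dates = pd.date_range(start, periods=len(t_min), freq="D")
    return pd.DataFrame({"date": dates, "t_min_f": t_min, "t_max_f": t_max})
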