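"""Pseudo-steady-state rate summaries from reactor time-series records.

Each temperature stage is reduced to a single summary computed from the
final daily samples before the stage's biofilm harvest (default: the last
three), by which point the 48 h residence-time transient from the previous
stage has decayed.  Bulk concentrations average the four in-reactor ports;
the effluent port is kept separate so that surface-dominated sulphide
oxidation can be compared against the bulk volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import EFFLUENT, PORTS
from .reactor import FeedSpec, Schedule


class MissingStageError(ValueError):
    """A scheduled stage has no samples inside its averaging window."""


@dataclass(frozen=True)
class StageWindow:
    stage: int
    temperature_c: float
    start_h: float
    end_h: float
    sample_times: tuple


def conversion_efficiency(c_feed: float, c_residual: float) -> float:
    """Fractional conversion (c_feed - c_residual)/c_feed, clipped to [0, 1].

    A residual above the feed (measurement noise) clips to zero with a
    warning rather than reporting negative conversion.
    """
    if c_feed <= 0:
        raise ValueError("c_feed must be positive")
    if c_residual < 0:
        raise ValueError("c_residual must be >= 0")
    x = (c_feed - c_residual) / c_feed
    if x < 0:
        warnings.warn(f"residual {c_residual} exceeds feed {c_feed}; conversion clipped to 0")
        return 0.0
    return min(x, 1.0)


def volumetric_rate(conversion: float, c_feed: float, hrt: float) -> float:
    """Volumetric removal rate X * c_feed / HRT in mmol/L.h."""
    if hrt <= 0:
        raise ValueError("hrt must be positive")
    return conversion * c_feed / hrt


def vsor_estimate(expected_sulphide: float, measured_sulphide: float, hrt: float) -> float:
    """Volumetric sulphide oxidation rate from expected minus measured sulphide.

    Expected sulphide is the stoichiometric 1:1 yield of reduced sulphate;
    measured above expected floors the estimate at zero with a warning.
    """
    if hrt <= 0:
        raise ValueError("hrt must be positive")
    if expected_sulphide < 0:
        raise ValueError("expected_sulphide must be >= 0")
    rate = (expected_sulphide - measured_sulphide) / hrt
    if rate < 0:
        warnings.warn("measured sulphide exceeds expected; VSOR floored at 0")
        return 0.0
    return rate


def stage_windows(schedule: Schedule, records: pd.DataFrame, n_last: int = 3) -> list[StageWindow]:
    """Last ``n_last`` sample times of each temperature stage."""
    windows = []
    times = np.sort(records["time_h"].unique())
    for i, (t0, t1, temp) in enumerate(schedule.stage_bounds()):
        in_stage = times[(times > t0) & (times <= t1)]
        chosen = tuple(in_stage[-n_last:])
        if not chosen:
            raise MissingStageError(f"stage {i} ({temp} degC, {t0}-{t1} h) has no samples")
        windows.append(StageWindow(i, temp, t0, t1, chosen))
    return windows


SUMMARY_COLUMNS = (
    "stage", "temperature_C", "window_start_h", "window_end_h", "n_samples",
    "sulphate_bulk_mmol_L", "sulphate_effluent_mmol_L", "conversion",
    "vsrr_mmol_L_h", "expected_sulphide_mmol_L",
    "sulphide_bulk_mmol_L", "sulphide_effluent_mmol_L",
    "vsor_bulk_mmol_L_h", "vsor_effluent_mmol_L_h",
    "lactate_util_mmol_L_h", "acetate_util_mmol_L_h",
    "acetate_net_prod_mmol_L_h", "propionate_prod_mmol_L_h",
)


def stage_summaries(records: pd.DataFrame, feed: FeedSpec, schedule: Schedule,
                    n_last: int = 3) -> pd.DataFrame:
    """Per-stage pseudo-steady-state summary table.

    Utilisation rates are (feed - residual)/HRT for fed species; production
    rates are residual/HRT for species absent from the feed.  A negative
    utilisation (residual above feed, as happens for acetate when yeast
    extract ferments) shows up as a positive net production.
    """
    hrt = schedule.hrt
    c_feed = feed.sulphate_molar
    lact_in = feed.carbon_molar if feed.carbon_source == "lactate" else 0.0
    acet_in = feed.carbon_molar if feed.carbon_source == "acetate" else 0.0
    rows = []
    for w in stage_windows(schedule, records, n_last):
        sel = records[records["time_h"].isin(w.sample_times)]
        bulk = sel[sel["port"].isin(PORTS)].mean(numeric_only=True)
        eff = sel[sel["port"] == EFFLUENT].mean(numeric_only=True)
        if np.isnan(eff.get("sulphate_mmol_L", np.nan)):
            raise MissingStageError(f"stage {w.stage} has no effluent samples in window")
        x = conversion_efficiency(c_feed, bulk["sulphate_mmol_L"])
        expected = x * c_feed
        lact_util = (lact_in - bulk["lactate_mmol_L"]) / hrt
        acet_util = (acet_in - bulk["acetate_mmol_L"]) / hrt
        rows.append({
            "stage": w.stage,
            "temperature_C": w.temperature_c,
            "window_start_h": w.sample_times[0],
            "window_end_h": w.sample_times[-1],
            "n_samples": len(w.sample_times),
            "sulphate_bulk_mmol_L": bulk["sulphate_mmol_L"],
            "sulphate_effluent_mmol_L": eff["sulphate_mmol_L"],
            "conversion": x,
            "vsrr_mmol_L_h": volumetric_rate(x, c_feed, hrt),
            "expected_sulphide_mmol_L": expected,
            "sulphide_bulk_mmol_L": bulk["sulphide_mmol_L"],
            "sulphide_effluent_mmol_L": eff["sulphide_mmol_L"],
            "vsor_bulk_mmol_L_h": vsor_estimate(expected, bulk["sulphide_mmol_L"], hrt),
            "vsor_effluent_mmol_L_h": vsor_estimate(expected, eff["sulphide_mmol_L"], hrt),
            "lactate_util_mmol_L_h": lact_util,
            "acetate_util_mmol_L_h": acet_util,
            "acetate_net_prod_mmol_L_h": -acet_util,
            "propionate_prod_mmol_L_h": bulk["propionate_mmol_L"] / hrt,
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
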