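"""Day-night differential calling and feeding-regime response classification.

Site-level TMT data sampled at two antiphase timepoints (day ZT11, night
ZT23) are tested for a day-night difference: the symmetric fold change
``100 * (max(r, 1/r) - 1)`` with ``r = night/day`` must strictly exceed the
threshold (default 20%).  A Student t p-value is reported alongside; gating
on it is optional and off by default, since the differential-site counts are
defined by the fold criterion alone.

Comparing night-restricted (NRF) and day-restricted (DRF) feeding, each
site's pair of day-night results is classified as inverted / dampened /
unaltered / emergent / absent — a total partition of the outcomes.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .identify import pooled_t
from .types import InputError, TimeCourseTable

log = logging.getLogger("ptmrhythm")

REGIME_CLASSES = ("inverted", "dampened", "unaltered", "emergent", "absent")


def daynight_test(table: TimeCourseTable, *, day: float = 11.0,
                  night: float = 23.0, fold_threshold_pct: float = 20.0,
                  p_gate: float | None = None,
                  log_transform: bool = False) -> pd.DataFrame:
    """Per-feature day-night differential call on a two-timepoint table."""
    tps = table.timepoints
    if day not in tps or night not in tps:
        raise InputError(f"table lacks day/night timepoints {day}/{night}; has {tps}")
    day_cols = [c for c in table.data.columns if float(c[0]) == day]
    night_cols = [c for c in table.data.columns if float(c[0]) == night]
    rows = []
    for fid in table.feature_ids:
        d = table.data.loc[fid, day_cols].to_numpy(dtype=float)
        n = table.data.loc[fid, night_cols].to_numpy(dtype=float)
        d, n = d[np.isfinite(d)], n[np.isfinite(n)]
        row = {"feature_id": fid, "day_mean": float("nan"),
               "night_mean": float("nan"), "log2_ratio": float("nan"),
               "fold_pct": float("nan"), "p": float("nan"),
               "differential": False, "direction": "none", "evaluable": False}
        if d.size >= 2 and n.size >= 2:
            dm, nm = float(d.mean()), float(n.mean())
            row.update(day_mean=dm, night_mean=nm)
            if dm > 0 and nm > 0:
                r = nm / dm
                fold = 100.0 * (max(r, 1.0 / r) - 1.0)
                if log_transform:
                    t, p, _ = pooled_t(np.log(n), np.log(d))
                else:
                    t, p, _ = pooled_t(n, d)
                differential = fold > fold_threshold_pct
                if p_gate is not None:
                    differential = differential and p < p_gate
                direction = "night-high" if r > 1 else ("day-high" if r < 1 else "none")
                row.update(log2_ratio=math.log2(r), fold_pct=fold, p=p,
                           differential=bool(differential),
                           direction=direction, evaluable=True)
        rows.append(row)
    out = pd.DataFrame(rows)
    log.info("daynight_test: %d/%d differential at >%g%% fold",
             int(out["differential"].sum()), len(out), fold_threshold_pct)
    return out


def classify_regime_response(nrf_differential: bool, nrf_direction: str,
                             drf_differential: bool, drf_direction: str) -> str:
    """Classify one site's NRF vs DRF day-night behavior (total function)."""
    if nrf_differential and drf_differential:
        return "inverted" if nrf_direction != drf_direction else "unaltered"
    if nrf_differential:
        return "dampened"
    if drf_differential:
        return "emergent"
    return "absent"


def classify_regimes(nrf: pd.DataFrame, drf: pd.DataFrame) -> pd.DataFrame:
    """Join per-regime day-night results and classify every shared feature."""
    n = nrf.set_index("feature_id")
    d = drf.set_index("feature_id")
    if set(n.index) != set(d.index):
        offenders = sorted(set(n.index) ^ set(d.index))
        raise InputError(f"mismatched feature universes: {offenders[:10]}")
    rows = []
    for fid in n.index:
        klass = classify_regime_response(
            bool(n.loc[fid, "differential"]), str(n.loc[fid, "direction"]),
            bool(d.loc[fid, "differential"]), str(d.loc[fid, "direction"]))
        rows.append({"feature_id": fid,
                     "nrf_differential": bool(n.loc[fid, "differential"]),
                     "nrf_direction": n.loc[fid, "direction"],
                     "nrf_fold_pct": n.loc[fid, "fold_pct"],
                     "drf_differential": bool(d.loc[fid, "differential"]),
                     "drf_direction": d.loc[fid, "direction"],
                     "drf_fold_pct": d.loc[fid, "fold_pct"],
                     "klass": klass})
    out = pd.DataFrame(rows)
    counts = out["klass"].value_counts().to_dict()
    log.info("classify_regimes: %s", counts)
    return out


def compare_regime_medians(nrf_series, drf_series) -> tuple[float, float, float]:
    """Median global signal per regime plus a two-sample t p-value.

    Inputs are per-timepoint global signals (e.g., column means of the two
    regime tables); the medians mirror the dashed median lines drawn across
    regime comparisons, and the t test assesses whether overall O-GlcNAc
    level differs between feeding regimes.
    """
    a = np.asarray(nrf_series, dtype=float)
    b = np.asarray(drf_series, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise InputError("need >= 3 values per regime")
    _, p, _ = pooled_t(a, b)
    return float(np.median(a)), float(np.median(b)), float(p)
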