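"""Nonparametric 24-h rhythm detection with phase estimation.

Two rank-based detectors are provided:

* a JTK-style test: Kendall tau-b of the observed values against the rank
  pattern of a phased 24-h cosine, maximized over a grid of candidate peak
  phases;
* an umbrella test in the spirit of RAIN: a Mack-Wolfe umbrella statistic
  computed for every candidate peak timepoint on the circularly reordered
  groups, allowing asymmetric (rise fast / fall slow) waveforms.

Both absorb the max-over-candidates selection into a seeded permutation
null (values shuffled across samples, statistic recomputed per shuffle), so
no extra multiplicity correction across phases is needed.  For very small
designs (<= 8 samples) the null is enumerated exactly.  Because both
statistics are discrete, the default p-value uses a seeded randomized
tie-break, which is exactly uniform under exchangeability; the standard
conservative convention ``(1 + #{null >= obs}) / (B + 1)`` is available via
``tie_break="conservative"``.  Degenerate all-tied series short-circuit to
p = 1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import InputError, TimeCourseTable

log = logging.getLogger("ptmrhythm")

_EPS = 1e-9
_EXACT_MAX_SAMPLES = 8


@dataclass
class RhythmResult:
    feature_id: str
    method: str  # "jtk" | "umbrella"
    p: float
    q: float = float("nan")
    period: float = 24.0
    phase: float = float("nan")
    amplitude_proxy: float = float("nan")
    statistic: float = float("nan")
    n_used: int = 0
    evaluable: bool = True


def kendall_tau_ref(values, ref_ranks) -> float:
    """Kendall tau-b of observed values against a reference rank pattern.

    Replicates inherit their timepoint's reference rank, so the reference
    side is tied by construction; the tau-b denominator discounts tied
    pairs on both sides.  Returns 0 when either side is constant.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(ref_ranks, dtype=float)
    if x.shape != y.shape:
        raise InputError("values and reference ranks differ in length")
    n = x.size
    if n < 2:
        return 0.0
    i, j = np.triu_indices(n, 1)
    sx = np.sign(x[j] - x[i])
    sy = np.sign(y[j] - y[i])
    nx = int(np.count_nonzero(sx))
    ny = int(np.count_nonzero(sy))
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.sum(sx * sy) / math.sqrt(nx * ny))


def _randomized_p(null: np.ndarray, obs: float, rng, tie_break: str,
                  include_obs: bool = True) -> float:
    """Permutation p-value; randomized tie-break is exactly uniform."""
    greater = int(np.sum(null > obs + _EPS))
    equal = int(np.sum(np.abs(null - obs) <= _EPS))
    total = null.size + (1 if include_obs else 0)
    if tie_break == "conservative":
        return (greater + equal + (1 if include_obs else 0)) / total
    u = float(rng.uniform())
    return (greater + u * (equal + (1 if include_obs else 0))) / total


def _amplitude_proxy(x: np.ndarray, timepoints: np.ndarray) -> float:
    med_all = float(np.nanmedian(x))
    if med_all == 0 or not np.isfinite(med_all):
        return float("nan")
    tps = np.unique(timepoints)
    meds = np.array([np.nanmedian(x[timepoints == t]) for t in tps])
    return float((np.nanmax(meds) - np.nanmin(meds)) / med_all)


def _perm_matrix(n: int, n_perm: int, rng) -> np.ndarray:
    if n <= _EXACT_MAX_SAMPLES:
        return np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    return np.array([rng.permutation(n) for _ in range(n_perm)], dtype=np.intp)


class _JtkEngine:
    """Shared precomputation for JTK scans over a fixed sampling design."""

    def __init__(self, timepoints: np.ndarray, phase_grid, period: float,
                 n_perm: int, rng):
        self.timepoints = np.asarray(timepoints, dtype=float)
        n = self.timepoints.size
        if phase_grid is None:
            # hourly grid: at 4-h sampling, distinct hourly phases still
            # produce distinct cosine rank patterns (tie structure changes at
            # timepoint midpoints), so peaks between samples are resolvable
            phase_grid = np.arange(0.0, period, period / 24.0)
        self.phase_grid = np.asarray(sorted(phase_grid), dtype=float)
        self.period = float(period)
        self.rng = rng
        self.i, self.j = np.triu_indices(n, 1)
        ref = np.cos(
            2.0 * np.pi * (self.timepoints[None, :] - self.phase_grid[:, None])
            / self.period
        )
        self.ref_signs = np.sign(ref[:, self.j] - ref[:, self.i])  # G x m
        self.ny = np.count_nonzero(self.ref_signs, axis=1)  # non-tied ref pairs
        if np.any(self.ny == 0):
            raise InputError("degenerate cosine reference (all ties)")
        self.perms = _perm_matrix(n, n_perm, rng)
        self.exact = n <= _EXACT_MAX_SAMPLES

    def _tau_profile(self, X: np.ndarray) -> np.ndarray:
        """Rows of X -> tau-b against every grid phase (rows x G)."""
        D = np.sign(X[:, self.j] - X[:, self.i])
        nx = np.count_nonzero(D[0])  # tie pattern is permutation-invariant
        if nx == 0:
            return np.zeros((X.shape[0], self.phase_grid.size))
        denom = np.sqrt(nx * self.ny)[None, :]
        return (D @ self.ref_signs.T) / denom

    def stat_and_phase(self, x: np.ndarray) -> tuple[float, float]:
        taus = self._tau_profile(x[None, :])[0]
        best = float(np.max(taus))
        # earliest grid phase on ties
        phase = float(self.phase_grid[np.argmax(taus >= best - _EPS)])
        return best, phase

    def null_stats(self, x: np.ndarray) -> np.ndarray:
        Xp = x[self.perms]
        return np.max(self._tau_profile(Xp), axis=1)


class _UmbrellaEngine:
    """Mack-Wolfe umbrella statistics over circular (peak, trough) layouts.

    For every candidate peak group and every candidate trough group the
    groups are reordered circularly from just after the trough back to the
    trough, and the umbrella statistic sums Mann-Whitney counts upward
    along the rising limb and downward along the falling limb.  Scanning
    all troughs (not only the antipodal one) is what lets the test track
    asymmetric rise-fast/fall-slow waveforms.  Per-layout statistics are
    studentized against the permutation sample (max-T) before taking the
    max, so neither unbalanced designs nor the layout count biases peak
    selection.
    """

    def __init__(self, timepoints: np.ndarray, period: float, n_perm: int, rng):
        self.timepoints = np.asarray(timepoints, dtype=float)
        self.period = float(period)
        self.rng = rng
        n = self.timepoints.size
        self.groups = np.unique(self.timepoints)
        k = self.groups.size
        if k < 3:
            raise InputError("umbrella test needs >= 3 timepoints")
        gidx = np.searchsorted(self.groups, self.timepoints)
        layouts = [(m, t) for m in range(k) for t in range(k) if t != m]
        # C[l, a, b] = 1 when a pair (x_a < x_b rising, x_a > x_b falling)
        # counts toward layout l's umbrella statistic
        self.C = np.zeros((len(layouts), n, n))
        self.layout_peak = np.array([m for m, _ in layouts])
        for li, (m, trough) in enumerate(layouts):
            order = [(trough + 1 + s) % k for s in range(k)]
            pos = {g: s for s, g in enumerate(order)}
            peak_pos = pos[m]
            for a in range(n):
                for b in range(n):
                    ga, gb = pos[gidx[a]], pos[gidx[b]]
                    if ga == gb:
                        continue
                    if ga < gb <= peak_pos:  # rising limb: count x_a < x_b
                        self.C[li, a, b] = 1.0
                    elif peak_pos <= gb < ga:  # falling limb: count x_b < x_a
                        self.C[li, a, b] = 1.0
        self.Cflat = self.C.reshape(len(layouts), -1)
        self.perms = _perm_matrix(n, n_perm, rng)
        self.exact = n <= _EXACT_MAX_SAMPLES

    def _raw(self, X: np.ndarray) -> np.ndarray:
        """Rows of X -> raw umbrella statistic per candidate layout."""
        H = 0.5 * (np.sign(X[:, None, :] - X[:, :, None]) + 1.0)  # H[a,b]=P(x_b>x_a)
        return H.reshape(X.shape[0], -1) @ self.Cflat.T

    def stats(self, x: np.ndarray) -> tuple[float, float, np.ndarray]:
        """Observed studentized max statistic, phase, and null max stats."""
        null_raw = self._raw(x[self.perms])          # B x layouts
        mu = null_raw.mean(axis=0)
        sd = null_raw.std(axis=0)
        sd[sd == 0] = 1.0
        obs_z = (self._raw(x[None, :])[0] - mu) / sd
        null_z = (null_raw - mu) / sd
        best = float(np.max(obs_z))
        # earliest peak timepoint among tying layouts
        peaks = self.layout_peak[obs_z >= best - _EPS]
        phase = float(self.groups[int(np.min(peaks))])
        return best, phase, np.max(null_z, axis=1)


def _not_evaluable(fid: str, method: str, n: int) -> RhythmResult:
    return RhythmResult(feature_id=fid, method=method, p=float("nan"),
                        n_used=n, evaluable=False)


def _check_series(x: np.ndarray, timepoints: np.ndarray) -> bool:
    ok = np.isfinite(x)
    return ok.sum() >= 4 and np.unique(timepoints[ok]).size >= 3


def jtk_test(values, timepoints, *, period: float = 24.0, phase_grid=None,
             n_perm: int = 10000, seed: int = 0, tie_break: str = "random",
             feature_id: str = "feature") -> RhythmResult:
    """JTK-style max-tau test of a single series against phased cosines."""
    x = np.asarray(values, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if not _check_series(x, t):
        return _not_evaluable(feature_id, "jtk", int(np.isfinite(x).sum()))
    keep = np.isfinite(x)
    x, t = x[keep], t[keep]
    rng = np.random.default_rng(seed)
    engine = _JtkEngine(t, phase_grid, period, n_perm, rng)
    return _run_jtk(engine, x, feature_id, tie_break, rng)


def _run_jtk(engine: _JtkEngine, x: np.ndarray, fid: str, tie_break: str,
             rng) -> RhythmResult:
    if np.all(x == x[0]):
        return RhythmResult(fid, "jtk", p=1.0, phase=float(engine.phase_grid[0]),
                            amplitude_proxy=0.0, statistic=0.0, n_used=x.size)
    stat, phase = engine.stat_and_phase(x)
    null = engine.null_stats(x)
    p = _randomized_p(null, stat, rng, tie_break, include_obs=not engine.exact)
    return RhythmResult(fid, "jtk", p=p, phase=phase,
                        amplitude_proxy=_amplitude_proxy(x, engine.timepoints),
                        statistic=stat, n_used=x.size)


def umbrella_test(values, timepoints, *, period: float = 24.0,
                  n_perm: int = 10000, seed: int = 0, tie_break: str = "random",
                  feature_id: str = "feature") -> RhythmResult:
    """Umbrella (Mack-Wolfe style) test with circular candidate peaks."""
    x = np.asarray(values, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if not _check_series(x, t):
        return _not_evaluable(feature_id, "umbrella", int(np.isfinite(x).sum()))
    keep = np.isfinite(x)
    x, t = x[keep], t[keep]
    rng = np.random.default_rng(seed)
    engine = _UmbrellaEngine(t, period, n_perm, rng)
    return _run_umbrella(engine, x, feature_id, tie_break, rng)


def _run_umbrella(engine: _UmbrellaEngine, x: np.ndarray, fid: str,
                  tie_break: str, rng) -> RhythmResult:
    if np.all(x == x[0]):
        return RhythmResult(fid, "umbrella", p=1.0, phase=float(engine.groups[0]),
                            amplitude_proxy=0.0, statistic=0.0, n_used=x.size)
    stat, phase, null = engine.stats(x)
    p = _randomized_p(null, stat, rng, tie_break, include_obs=not engine.exact)
    return RhythmResult(fid, "umbrella", p=p, phase=phase,
                        amplitude_proxy=_amplitude_proxy(x, engine.timepoints),
                        statistic=stat, n_used=x.size)


def bh_adjust(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rhythm_scan(table: TimeCourseTable, *, method: str = "jtk",
                period: float = 24.0, phase_grid=None, n_perm: int = 10000,
                seed: int = 0, tie_break: str = "random") -> pd.DataFrame:
    """Run a rhythm detector over every feature of a table.

    Features sharing the complete-case sampling design share one seeded
    permutation set (their p-values stay independent because each feature's
    null statistics depend only on its own values); features with missing
    samples get a per-feature engine.  q-values are BH-adjusted across all
    evaluable features.
    """
    if method == "both":
        parts = [
            rhythm_scan(table, method=m, period=period, phase_grid=phase_grid,
                        n_perm=n_perm, seed=seed, tie_break=tie_break)
            for m in ("jtk", "umbrella")
        ]
        return pd.concat(parts, ignore_index=True)
    if method not in ("jtk", "umbrella"):
        raise InputError(f"unknown rhythm method {method!r}")

    t_all = table.sample_timepoints
    rng = np.random.default_rng(seed)
    shared = None
    results: list[RhythmResult] = []
    for fid in table.feature_ids:
        x = table.values_for(fid)
        if not _check_series(x, t_all):
            results.append(_not_evaluable(str(fid), method, int(np.isfinite(x).sum())))
            continue
        keep = np.isfinite(x)
        if keep.all():
            if shared is None:
                if method == "jtk":
                    shared = _JtkEngine(t_all, phase_grid, period, n_perm, rng)
                else:
                    shared = _UmbrellaEngine(t_all, period, n_perm, rng)
            engine = shared
            xx, rr = x, rng
        else:
            sub_rng = np.random.default_rng([seed, hash(str(fid)) & 0x7FFFFFFF])
            if method == "jtk":
                engine = _JtkEngine(t_all[keep], phase_grid, period, n_perm, sub_rng)
            else:
                engine = _UmbrellaEngine(t_all[keep], period, n_perm, sub_rng)
            xx, rr = x[keep], sub_rng
        if method == "jtk":
            results.append(_run_jtk(engine, xx, str(fid), tie_break, rr))
        else:
            results.append(_run_umbrella(engine, xx, str(fid), tie_break, rr))

    df = pd.DataFrame([r.__dict__ for r in results])
    df["q"] = float("nan")
    mask = df["evaluable"].to_numpy()
    if mask.any():
        df.loc[mask, "q"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    log.info("rhythm_scan(%s): %d features, %d evaluable, %d with q<0.2",
             method, len(df), int(mask.sum()),
             int((df["q"] < 0.2).sum()))
    return df


def gate_rhythmic(results: pd.DataFrame, q_cutoff: float = 0.2) -> list[str]:
    """Feature ids passing the strict ``q < q_cutoff`` gate."""
    passed = results.loc[results["q"] < q_cutoff, "feature_id"].tolist()
    log.info("gate_rhythmic: %d of %d features at q < %g",
             len(passed), len(results), q_cutoff)
    return passed
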