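"""Trajectory and count analysis: MSD, anomalous exponent, enrichment.

The mean square displacement MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩ is averaged over
particles and over all time origins (overlapping windows). For normal
diffusion on a surface it is linear with slope 4D; heterogeneous per-surface
coefficients make it sublinear, MSD ∝ τ^α with α < 1, which is quantified by
a least-squares fit of log MSD against log τ over a declared lag window.

Also provided: per-surface enrichment time courses from count series, and an
independent 1-D two-zone random-walk oracle for the steady-state occupancy
ratio induced by the start-position step rule. The oracle shares nothing with
the mesh engine beyond the step rule itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MSDCurve",
    "EnrichmentSeries",
    "msd",
    "trajectories_from_frame",
    "enrichment",
    "two_zone_occupancy_oracle",
]


@dataclass
class MSDCurve:
    """MSD(τ) with its power-law fit.

    ``alpha`` is the anomalous exponent fitted on ``fit_window`` (a lag-index
    slice into ``lags``); ``slope`` is the through-origin linear slope on the
    same window, equal to 4D for free surface diffusion. Both are ``nan`` for
    degenerate (e.g. stationary) input, flagged by ``degenerate``.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_particles: int
    slope: float
    alpha: float
    fit_window: tuple[int, int]
    degenerate: bool = False


def trajectories_from_frame(frame: pd.DataFrame) -> list[np.ndarray]:
    """Split a trajectory table (time, id, x, y, z, ...) into per-particle arrays.

    Requires a uniform sampling interval; raises otherwise.
    """
    trajs = []
    for _, grp in frame.groupby("id", sort=True):
        grp = grp.sort_values("time")
        t = grp["time"].to_numpy()
        if len(t) > 2:
            dts = np.diff(t)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
                raise ValueError("trajectory sampling interval is not uniform")
        trajs.append(grp[["x", "y", "z"]].to_numpy())
    return trajs


def _default_fit_window(n_lags: int) -> tuple[int, int]:
    """Lags spanning the second decade of sampled τ (indices 10..100), clipped."""
    lo = min(10, max(n_lags // 10, 1))
    hi = min(100, n_lags)
    if hi <= lo + 1:
        lo, hi = 1, n_lags
    return lo, hi


def msd(
    trajectories,
    interval: float,
    max_lag: int | None = None,
    fit_window: tuple[int, int] | None = None,
) -> MSDCurve:
    """Time-origin-averaged MSD over a set of equally sampled trajectories.

    Parameters
    ----------
    trajectories
        List of (T, 3) position arrays sampled every ``interval`` seconds
        (lengths may differ).
    max_lag
        Largest lag in samples; defaults to half the shortest trajectory.
    fit_window
        (lo, hi) lag-index window for the α and slope fits; defaults to the
        second decade of sampled lags.
    """
    trajectories = [np.asarray(t, dtype=float) for t in trajectories]
    if not trajectories:
        raise ValueError("at least one trajectory required")
    shortest = min(len(t) for t in trajectories)
    if shortest < 2:
        raise ValueError("trajectories must have at least two samples")
    if max_lag is None:
        max_lag = max(shortest // 2, 1)
    if max_lag >= shortest:
        raise ValueError(
            f"max_lag {max_lag} exceeds shortest trajectory ({shortest} samples)"
        )
    lags = np.arange(1, max_lag + 1)
    acc = np.zeros(max_lag)
    cnt = np.zeros(max_lag, dtype=np.int64)
    for tr in trajectories:
        n = len(tr)
        for k in lags[lags < n]:
            d = tr[k:] - tr[:-k]
            acc[k - 1] += float(np.einsum("ij,ij->", d, d))
            cnt[k - 1] += n - k
    curve = acc / np.maximum(cnt, 1)
    taus = lags * interval

    if fit_window is None:
        fit_window = _default_fit_window(max_lag)
    lo, hi = fit_window
    w_tau = taus[lo:hi]
    w_msd = curve[lo:hi]
    if w_tau.size < 2 or np.any(w_msd <= 0.0):
        return MSDCurve(
            taus, curve, len(trajectories), math.nan, math.nan, fit_window, True
        )
    slope = float(np.dot(w_tau, w_msd) / np.dot(w_tau, w_tau))
    alpha = float(np.polyfit(np.log(w_tau), np.log(w_msd), 1)[0])
    return MSDCurve(taus, curve, len(trajectories), slope, alpha, fit_window)


@dataclass
class EnrichmentSeries:
    """Fraction of a species' molecules residing on a named surface over time."""

    times: np.ndarray
    fraction: np.ndarray
    species: str
    surface: str

    def mean_over(self, t_min: float) -> float:
        sel = self.times >= t_min
        return float(self.fraction[sel].mean())


def enrichment(
    counts: pd.DataFrame,
    species: str,
    surface: str,
    include_species: tuple[str, ...] = (),
) -> EnrichmentSeries:
    """Per-time fraction of a species' molecules on one surface.

    ``include_species`` adds bound forms (e.g. the AMPAR–scaffold complex) to
    both numerator and denominator, so a receptor bound inside the PSD still
    counts as at the PSD.
    """
    names = (species,) + tuple(include_species)
    sub = counts[counts["species"].isin(names)]
    if sub.empty:
        raise ValueError(f"species {species!r} not present in the count series")
    if surface not in set(counts["surface"]):
        raise ValueError(f"surface {surface!r} not present in the count series")
    tot = sub.groupby("time", sort=True)["count"].sum()
    on = (
        sub[sub["surface"] == surface]
        .groupby("time", sort=True)["count"]
        .sum()
        .reindex(tot.index, fill_value=0)
    )
    frac = np.where(tot.to_numpy() > 0, on.to_numpy() / tot.to_numpy(), 0.0)
    return EnrichmentSeries(tot.index.to_numpy(float), frac, species, surface)


def two_zone_occupancy_oracle(
    D_fast: float,
    D_slow: float,
    dt: float,
    n_walkers: int = 4000,
    n_steps: int = 20000,
    zone_length: float = 1.0,
    seed: int = 12345,
    burn_in: float = 0.5,
) -> float:
    """Steady-state slow:fast occupancy ratio of a 1-D two-zone random walk.

    Walkers live on [0, 2L] with reflecting ends; the left half is the slow
    zone. Each step is Gaussian with standard deviation sqrt(2·D(zone)·dt)
    where the zone is taken at the step's start — the same start-position rule
    the surface simulator uses. Returns the time-averaged count ratio
    slow/fast after discarding the first ``burn_in`` fraction of steps.
    """
    rng = np.random.default_rng(seed)
    L = zone_length
    x = rng.random(n_walkers) * 2.0 * L
    s_slow = math.sqrt(2.0 * D_slow * dt)
    s_fast = math.sqrt(2.0 * D_fast * dt)
    slow_time = 0.0
    fast_time = 0.0
    start = int(n_steps * burn_in)
    for step in range(n_steps):
        sigma = np.where(x < L, s_slow, s_fast)
        x = x + rng.standard_normal(n_walkers) * sigma
        # reflect at 0 and 2L (repeat for rare large excursions)
        for _ in range(4):
            x = np.abs(x)
            x = 2.0 * L - np.abs(2.0 * L - x)
        if step >= start:
            n_slow = float(np.count_nonzero(x < L))
            slow_time += n_slow
            fast_time += n_walkers - n_slow
    return slow_time / fast_time
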