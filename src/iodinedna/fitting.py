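"""Grid-search fits of damage-model parameters to fragment distributions.

The fitting protocol mirrors the two experimental scavenging conditions:

* **high scavenging** (radicals quenched, e.g. by DMSO) — all breaks are
  direct, so the energy threshold ``e_thresh`` is fitted alone by scanning a
  grid (default 10–40 eV, 0.25 eV steps) and minimising the log-SSE between
  the modelled and observed fragment distributions;
* **low scavenging** — direct plus indirect damage; ``e_thresh`` is frozen
  at its high-scavenging best fit and the per-OH-hit break probability
  ``p_oh`` is fitted on its own grid (default 0–1, step 0.01).

One scored-event dataset is reused across all grid points (one simulation,
many thresholds); the stochastic window/indirect calls are re-seeded
deterministically per grid point.  The quoted uncertainty is half the grid
step, and the exported SSE curve makes the breadth of the minimum explicit
— normalised fragment data constrain the threshold only weakly, because
they carry no information about the absolute break yield.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .damage import call_direct_threshold, call_direct_window, call_indirect, dsb_yield, ssb_yield
from .fragments import (
    FragmentDistribution,
    _fragments_from_mask,
    read_fragment_distribution,
    sse_log,
)
from .tracks import TrackDataset

__all__ = [
    "ExperimentalData",
    "FitResult",
    "default_energy_grid",
    "default_poh_grid",
    "fit_poh",
    "fit_threshold",
    "fit_window",
    "read_experimental_data",
    "residual_curve",
    "yield_curves",
]

CONDITIONS = ("high", "low")


def default_energy_grid() -> np.ndarray:
    """10 to 40 eV in 0.25 eV steps (±0.125 eV quoting convention)."""
    return np.round(np.arange(10.0, 40.0 + 1e-9, 0.25), 6)


def default_poh_grid() -> np.ndarray:
    """0 to 1 in 0.01 steps."""
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 6)


@dataclass(frozen=True)
class ExperimentalData:
    """An observed fragment distribution and its scavenging condition.

    ``distribution`` must be ``breaks_only`` (a gel only sees broken
    strands); ``max_site`` is the most distant measured site — the model is
    only evaluated out to there, as farther unmeasured breaks cannot affect
    the observation.
    """

    distribution: FragmentDistribution
    condition: str
    max_site: int = -1

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.distribution.mode != "breaks_only":
            raise ValueError("experimental fragment data must be breaks_only")
        if self.max_site < 0:
            object.__setattr__(self, "max_site", self.distribution.max_base)
        if self.max_site != self.distribution.max_base:
            raise ValueError("max_site must equal the distribution's last site")


def read_experimental_data(path, condition: str) -> ExperimentalData:
    """Load an observed fragment-fraction table (columns site, fraction)."""
    return ExperimentalData(read_fragment_distribution(path), condition)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a 1-D grid scan.

    ``best`` attains the minimum SSE on the grid (ties broken toward the
    lower parameter value); ``uncertainty`` is half the grid step.
    """

    param: str
    grid: np.ndarray
    sse: np.ndarray
    best: float
    uncertainty: float
    best_index: int
    model_distribution: FragmentDistribution
    n_bins_used: int
    n_bins_excluded: int

    def values_within(self, factor: float = 2.0) -> np.ndarray:
        """Grid values whose SSE is within ``factor`` times the minimum —
        the breadth-of-minimum diagnostic."""
        finite = np.isfinite(self.sse)
        lo = self.sse[finite].min()
        return self.grid[finite & (self.sse <= factor * lo)]


def _check_grid(grid) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("parameter grid must not be empty")
    if (np.diff(grid) <= 0).any():
        raise ValueError("parameter grid must be sorted ascending, no repeats")
    return grid


def _finish(param, grid, sse, details, obs) -> FitResult:
    sse = np.asarray(sse)
    if not np.isfinite(sse).any():
        raise RuntimeError("no grid point produced any breaks; cannot fit")
    best = int(np.nanargmin(np.where(np.isfinite(sse), sse, np.inf)))
    step = float(grid[1] - grid[0]) if grid.size > 1 else 0.0
    fd, used, excl = details[best]
    return FitResult(
        param=param,
        grid=grid,
        sse=sse,
        best=float(grid[best]),
        uncertainty=0.5 * step,
        best_index=best,
        model_distribution=fd,
        n_bins_used=used,
        n_bins_excluded=excl,
    )


def _threshold_fragments(Es: np.ndarray, e: float, n_decays: int) -> FragmentDistribution | None:
    """breaks_only fragment distribution of strict-threshold breaks on a
    pre-sliced (n_events, max_site+1) energy matrix; None when no breaks."""
    try:
        return _fragments_from_mask(Es > e, "breaks_only", n_decays)
    except ValueError:
        return None


def _score(obs: ExperimentalData, fd: FragmentDistribution | None, policy: str):
    if fd is None:
        return np.inf, (None, 0, 0)
    s, used, excl = sse_log(obs.distribution, fd, bin_policy=policy, return_detail=True)
    return s, (fd, used, excl)


def fit_threshold(
    dataset: TrackDataset,
    obs: ExperimentalData,
    grid=None,
    strand: int = 0,
    bin_policy: str = "exclude_zeros",
) -> FitResult:
    """Fit the direct-break energy threshold to high-scavenging data."""
    if obs.condition != "high":
        raise ValueError("threshold fitting requires high-scavenging data")
    grid = _check_grid(default_energy_grid() if grid is None else grid)
    Es = dataset.energy_matrix()[:, strand, : obs.max_site + 1]
    sse, details = [], []
    for e in grid:
        s, d = _score(obs, _threshold_fragments(Es, e, dataset.n_decays), bin_policy)
        sse.append(s)
        details.append(d)
    return _finish("e_thresh_eV", grid, sse, details, obs)


def fit_window(
    dataset: TrackDataset,
    obs: ExperimentalData,
    widths: Sequence[float],
    grid=None,
    strand: int = 0,
    seed: int = 1,
    bin_policy: str = "exclude_zeros",
) -> dict[float, FitResult]:
    """Fit the window median energy for each window width.

    The parameter scanned is the window's median energy (the energy of 50%
    break probability); a width of 0 reduces exactly to the sharp-threshold
    fit.  For ``width=32.5`` a median of 21.25 eV reproduces the classic
    (5, 37.5) eV window.
    """
    if obs.condition != "high":
        raise ValueError("window fitting requires high-scavenging data")
    grid = _check_grid(default_energy_grid() if grid is None else grid)
    out: dict[float, FitResult] = {}
    for wi, width in enumerate(widths):
        if width < 0:
            raise ValueError("window width must be >= 0")
        if width == 0:
            out[width] = fit_threshold(dataset, obs, grid, strand, bin_policy)
            continue
        sse, details = [], []
        for gi, med in enumerate(grid):
            e_low = max(med - width / 2.0, 0.0)
            e_high = med + width / 2.0
            call = call_direct_window(dataset, e_low, e_high, seed=_combine(seed, wi, gi))
            sub = call.broken[:, strand, : obs.max_site + 1]
            try:
                fd = _fragments_from_mask(sub, "breaks_only", dataset.n_decays)
            except ValueError:
                fd = None
            s, d = _score(obs, fd, bin_policy)
            sse.append(s)
            details.append(d)
        out[width] = _finish("window_median_eV", grid, sse, details, obs)
    return out


def fit_poh(
    dataset: TrackDataset,
    obs: ExperimentalData,
    e_thresh: float,
    grid=None,
    strand: int = 0,
    seed: int = 1,
    bin_policy: str = "exclude_zeros",
) -> FitResult:
    """Fit the per-OH-hit break probability to low-scavenging data.

    ``e_thresh`` is taken from the high-scavenging fit and held fixed; each
    grid probability generates indirect breaks (re-seeded deterministically),
    which are merged with the direct threshold breaks before comparing
    fragment distributions.
    """
    if obs.condition != "low":
        raise ValueError("p_oh fitting requires low-scavenging data")
    grid = _check_grid(default_poh_grid() if grid is None else grid)
    direct = call_direct_threshold(dataset, e_thresh)
    direct_sub = direct.broken[:, strand, : obs.max_site + 1]
    sse, details = [], []
    for gi, p in enumerate(grid):
        indirect = call_indirect(dataset, p, seed=_combine(seed, 0, gi))
        sub = direct_sub | indirect.broken[:, strand, : obs.max_site + 1]
        try:
            fd = _fragments_from_mask(sub, "breaks_only", dataset.n_decays)
        except ValueError:
            fd = None
        s, d = _score(obs, fd, bin_policy)
        sse.append(s)
        details.append(d)
    return _finish("p_oh", grid, sse, details, obs)


def _combine(seed: int, *idx: int) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and indices."""
    x = int(seed) & 0x7FFFFFFF
    for k in idx:
        x = (x * 1000003 + int(k) + 1) % 2147483647
    return x


def residual_curve(fit: FitResult) -> pd.DataFrame:
    """The full grid scan as a table (parameter, SSE)."""
    return pd.DataFrame({fit.param: fit.grid, "sse": fit.sse})


def yield_curves(dataset: TrackDataset, grid, dsb_max_sep: int = 10) -> pd.DataFrame:
    """SSB (strand 0) and DSB yields per decay across threshold energies."""
    grid = _check_grid(grid)
    rows = []
    for e in grid:
        call = call_direct_threshold(dataset, e)
        s = ssb_yield(call, 0)
        d = dsb_yield(call, dsb_max_sep)
        rows.append((e, s.value, s.se, d.value, d.se))
    return pd.DataFrame(
        rows, columns=["e_thresh_eV", "ssb_per_decay", "ssb_se", "dsb_per_decay", "dsb_se"]
    )
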