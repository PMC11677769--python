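"""Concentration-sweep experiments and extremum detection.

The central observable is the normalized binding energy: for each replicate
seed the undoped system is minimized once to get the baseline ``Ep0`` and
every doped run's best energy ``Ep`` is reported as the signed ratio
``Ep/|Ep0|``.  Binding energies are negative, so the undoped level is
exactly -1 and a doping-induced *stiffening* (stronger binding) shows up as
a dip below -1; the depth of the interior minimum and the concentration at
which it occurs are the quantities the experiments track.

Concentration is defined as dopant count in percent of the dipole count,
rounded to the nearest whole dopant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import MoveSchedule, run_minimization, initialize_system
from .model import SystemConfig

__all__ = ["SweepResult", "ExtremumSummary", "run_sweep", "find_extremum",
           "grid_experiment", "GridExperiment", "experiment_config",
           "default_c_grid"]


def experiment_config(**overrides) -> SystemConfig:
    """The package's standard configuration for concentration-sweep
    experiments: the full 20x20 lattice at 295 K with a fixed sweep budget
    (1000 sweeps, convergence checked over 400-sweep windows), a 4 nm
    dipole-dipole truncation, and the hydrated charge-site contact
    distance of 0.4 nm as the Coulomb soft core.  A fixed budget keeps
    replicate energies exchangeable across concentrations; the truncation
    affects only the r^-3 dipole-pair far field.  Any field can be
    overridden."""
    base = dict(max_sweeps=1000, convergence_window=400,
                convergence_tol=1e-5, dipole_cutoff=4.0,
                coulomb_soft_core=0.4)
    base.update(overrides)
    return SystemConfig(**base)


def default_c_grid(step: float = 0.25, stop: float = 5.0) -> list[float]:
    """Dopant concentration grid 0..stop % in the given step."""
    n = int(round(stop / step))
    return [round(i * step, 10) for i in range(n + 1)]


@dataclass
class SweepResult:
    """Replicate-resolved normalized binding-energy curve for one (q, L)."""

    concentrations: np.ndarray        # % grid, sorted, starts at 0
    energies: np.ndarray              # (n_conc, n_replicates) raw Ep, kBT
    baselines: np.ndarray             # (n_replicates,) Ep0, kBT
    q: int
    L: float
    base_seed: int
    replicate_seeds: np.ndarray       # (n_conc, n_replicates) engine seeds
    converged: np.ndarray             # (n_conc, n_replicates) bool

    @property
    def n_replicates(self) -> int:
        return self.energies.shape[1]

    @property
    def normalized(self) -> np.ndarray:
        """Signed Ep/|Ep0| per replicate; row 0 (c = 0) is exactly -1."""
        return self.energies / np.abs(self.baselines)[None, :]

    @property
    def mean_normalized(self) -> np.ndarray:
        return self.normalized.mean(axis=1)

    @property
    def sem_normalized(self) -> np.ndarray:
        n = self.n_replicates
        if n < 2:
            return np.zeros(len(self.concentrations))
        return self.normalized.std(axis=1, ddof=1) / np.sqrt(n)

    def to_frame(self, run_id: str = "") -> pd.DataFrame:
        """Long-format table, one row per (concentration, replicate)."""
        rows = []
        norm = self.normalized
        for ic, c in enumerate(self.concentrations):
            for r in range(self.n_replicates):
                rows.append({
                    "run_id": run_id,
                    "q": self.q,
                    "L_nm": self.L,
                    "concentration_pct": float(c),
                    "replicate": r,
                    "seed": int(self.replicate_seeds[ic, r]),
                    "Ep_kT": float(self.energies[ic, r]),
                    "Ep0_kT": float(self.baselines[r]),
                    "Ep_norm": float(norm[ic, r]),
                    "converged": bool(self.converged[ic, r]),
                })
        return pd.DataFrame(rows)


@dataclass
class ExtremumSummary:
    """Interior-minimum call on a mean normalized-energy curve."""

    has_interior_minimum: bool
    c_min: Optional[float] = None       # %, quadratic-vertex location
    depth: Optional[float] = None       # drop below the c = 0 level (>= 0)
    c_min_se: Optional[float] = None    # bootstrap SE over replicates


def _seed_for(base_seed: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(base_seed)] + [int(p) for p in path])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _one_run(cfg: SystemConfig, c: float, q: int, L: float, seed: int,
             sched: Optional[MoveSchedule]):
    state = initialize_system(cfg, c, q, L, seed)
    res = run_minimization(state, cfg, sched, rng=seed + 1)
    return res.best_energy, res.converged


def run_sweep(cfg: SystemConfig, c_grid: Sequence[float], q: int, L: float,
              n_replicates: int = 10, base_seed: int = 0,
              sched: Optional[MoveSchedule] = None,
              baseline_cache: Optional[dict] = None) -> SweepResult:
    """Replicated concentration sweep at fixed dopant charge and size.

    For each replicate ``r`` the undoped baseline ``Ep0`` is minimized with
    a seed derived from (base_seed, r); each doped point uses a seed derived
    from (base_seed, r, grid index).  ``baseline_cache`` (keyed by replicate
    seed) lets a grid of sweeps share undoped runs, which depend on neither
    q nor L.
    """
    c_grid = np.asarray(sorted(float(c) for c in c_grid))
    if len(c_grid) == 0 or c_grid[0] != 0.0:
        raise ValueError("c_grid must be sorted and include 0")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")

    baselines = np.empty(n_replicates)
    base_conv = np.empty(n_replicates, dtype=bool)
    for r in range(n_replicates):
        seed0 = _seed_for(base_seed, r)
        if baseline_cache is not None and seed0 in baseline_cache:
            baselines[r], base_conv[r] = baseline_cache[seed0]
        else:
            baselines[r], base_conv[r] = _one_run(cfg, 0.0, q, L, seed0, sched)
            if baseline_cache is not None:
                baseline_cache[seed0] = (baselines[r], base_conv[r])

    n_c = len(c_grid)
    energies = np.empty((n_c, n_replicates))
    seeds = np.empty((n_c, n_replicates), dtype=np.int64)
    converged = np.empty((n_c, n_replicates), dtype=bool)
    for ic, c in enumerate(c_grid):
        for r in range(n_replicates):
            if c == 0.0:
                energies[ic, r] = baselines[r]
                seeds[ic, r] = _seed_for(base_seed, r)
                converged[ic, r] = base_conv[r]
            else:
                seed = _seed_for(base_seed, r, ic)
                energies[ic, r], converged[ic, r] = _one_run(
                    cfg, c, q, L, seed, sched)
                seeds[ic, r] = seed
    return SweepResult(concentrations=c_grid, energies=energies,
                       baselines=baselines, q=q, L=L, base_seed=base_seed,
                       replicate_seeds=seeds, converged=converged)


def _fit_vertex(c: np.ndarray, y: np.ndarray, i_min: int,
                half_window: int = 2) -> tuple[float, float]:
    """Quadratic fit around index i_min (window of up to 5 points, clipped
    at the edges); returns (c_vertex clamped to window, y_vertex)."""
    lo = max(0, i_min - half_window)
    hi = min(len(c), i_min + half_window + 1)
    cw, yw = c[lo:hi], y[lo:hi]
    if len(cw) >= 3:
        a, b, c0 = np.polyfit(cw, yw, 2)
        if a > 0:
            cv = -b / (2 * a)
            cv = min(max(cv, cw[0]), cw[-1])
            yv = a * cv * cv + b * cv + c0
            return float(cv), float(yv)
    return float(c[i_min]), float(y[i_min])


def find_extremum(sr: SweepResult) -> ExtremumSummary:
    """Detect an interior minimum of the mean normalized energy.

    The discrete argmin must be interior and lie below *both* endpoints by
    more than twice the pooled standard error; the reported location is the
    vertex of a local quadratic fit (5-point window), and the depth is how
    far the vertex lies below the curve's c = 0 level (which is exactly -1
    for normalized sweep curves).
    """
    c = sr.concentrations
    if len(c) < 4:
        raise ValueError("need at least 4 grid points")
    y = sr.mean_normalized
    se = sr.sem_normalized
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite mean energies")

    i_min = int(np.argmin(y))
    interior = 0 < i_min < len(c) - 1
    if interior:
        below_left = (y[0] - y[i_min]) > 2.0 * np.hypot(se[0], se[i_min])
        below_right = (y[-1] - y[i_min]) > 2.0 * np.hypot(se[-1], se[i_min])
        interior = bool(below_left and below_right)
    if not interior:
        return ExtremumSummary(has_interior_minimum=False)

    c_min, y_min = _fit_vertex(c, y, i_min)
    depth = max(0.0, float(y[0]) - y_min)

    # replicate-bootstrap uncertainty of the vertex location
    rng = np.random.default_rng(sr.base_seed)
    norm = sr.normalized
    n_rep = sr.n_replicates
    locs = []
    for _ in range(200):
        idx = rng.integers(0, n_rep, size=n_rep)
        yb = norm[:, idx].mean(axis=1)
        ib = int(np.argmin(yb))
        if 0 < ib < len(c) - 1:
            locs.append(_fit_vertex(c, yb, ib)[0])
    c_min_se = float(np.std(locs)) if len(locs) >= 2 else None
    return ExtremumSummary(True, c_min=c_min, depth=depth, c_min_se=c_min_se)


@dataclass
class GridExperiment:
    """Cross-product of charge and size sweeps with per-cell summaries."""

    sweeps: dict                      # (q, L) -> SweepResult
    summaries: dict                   # (q, L) -> ExtremumSummary

    def long_frame(self) -> pd.DataFrame:
        frames = [sr.to_frame(run_id=f"q{q}_L{L}")
                  for (q, L), sr in self.sweeps.items()]
        return pd.concat(frames, ignore_index=True)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (q, L), summ in self.summaries.items():
            sr = self.sweeps[(q, L)]
            rows.append({
                "q": q, "L_nm": L,
                "c_min_pct": summ.c_min,
                "depth": summ.depth,
                "has_minimum": summ.has_interior_minimum,
                "n_replicates": sr.n_replicates,
            })
        return pd.DataFrame(rows)


def grid_experiment(cfg: SystemConfig, q_list: Sequence[int],
                    L_list: Sequence[float], c_grid: Sequence[float],
                    n_replicates: int = 10, base_seed: int = 0,
                    sched: Optional[MoveSchedule] = None) -> GridExperiment:
    """Run a q x L grid of concentration sweeps with shared baselines and
    shared derived seeds."""
    cache: dict = {}
    sweeps = {}
    summaries = {}
    for q in q_list:
        for L in L_list:
            sr = run_sweep(cfg, c_grid, q, L, n_replicates, base_seed,
                           sched=sched, baseline_cache=cache)
            sweeps[(q, L)] = sr
            summaries[(q, L)] = find_extremum(sr)
    return GridExperiment(sweeps=sweeps, summaries=summaries)
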