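"""Metropolis Monte Carlo driver.

A *sweep* is one attempted move per particle in randomized order.  Dipoles
receive a translation uniform in the square [-dx, dx]^2 plus a rotation
uniform in [-dalpha, +dalpha]; dopants translate only.  Moves are accepted
with probability min(1, exp(-dE)) (energies already in kBT), the best-seen
configuration is tracked, and the run stops when the best energy has
stopped improving (relative tolerance over a sweep window) or at
``max_sweeps``.  Plain fixed-temperature Metropolis is the default; an
optional geometric cooling schedule is available for annealed searches.

The sweep loop itself runs in a compiled kernel seeded with a 31-bit
integer, so identical seeds give bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import _kernels
from .model import (DipoleState, DopantState, SystemConfig, SystemState,
                    TWO_PI, make_state, total_energy)

__all__ = ["MoveSchedule", "RunResult", "initialize_system", "propose_move",
           "metropolis_accept", "run_minimization"]


@dataclass
class MoveSchedule:
    """Move-scale parameters of the Metropolis sweep.

    ``k = pi*l/(dx*dalpha)`` is the dimensionless range parameter derived
    from the two step sizes and the dipole length; it is reported, not set.
    Zero step sizes are allowed and produce identity proposals.
    """

    dx: float = 0.1                       # nm
    dalpha: float = math.pi / 6.0         # rad
    dipole_length: float = 0.5            # nm, l in k = pi*l/(dx*dalpha)
    dopants_mobile: bool = True
    sweeps_per_check: Optional[int] = None  # None -> cfg.convergence_window

    def __post_init__(self):
        if self.dx < 0 or self.dalpha < 0:
            raise ValueError("step sizes must be >= 0")

    @property
    def k(self) -> float:
        if self.dx == 0 or self.dalpha == 0:
            return math.inf
        return math.pi * self.dipole_length / (self.dx * self.dalpha)

    @classmethod
    def from_config(cls, cfg: SystemConfig) -> "MoveSchedule":
        return cls(dx=cfg.dx, dalpha=cfg.dalpha,
                   dipole_length=cfg.dipole_length,
                   sweeps_per_check=cfg.convergence_window)


@dataclass
class RunResult:
    """Outcome of one minimization run."""

    best_energy: float                 # kBT, exact energy of best_state
    best_state: SystemState
    energy_trace: np.ndarray           # rows (sweep, current, best)
    sweeps_run: int
    converged: bool
    seed: int
    acceptance_rate: float
    final_state: SystemState           # last sampled configuration


def _as_seed(rng: Union[int, np.random.Generator, None]) -> int:
    """Map an int seed or a Generator to a 31-bit kernel seed."""
    if rng is None:
        return 0
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2 ** 31)
    return int(rng.integers(2 ** 31))


def initialize_system(cfg: SystemConfig, concentration: float, q: int,
                      L: float, rng: Union[int, np.random.Generator, None] = None,
                      max_retries: int = 200) -> SystemState:
    """Random initial configuration.

    Dipoles sit on the ``lattice_rows x lattice_cols`` grid with spacing
    ``cfg.spacing`` and independent uniform orientations;
    ``round(concentration/100 * n_dipoles)`` dopants of charge ``q`` and
    diameter ``L`` are placed uniformly in the bounding region, rejection
    sampled against the hard-core floor.
    """
    if not 0 <= concentration <= 100:
        raise ValueError(f"concentration must be in [0, 100], got {concentration}")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    dipoles = []
    for r in range(cfg.lattice_rows):
        for c in range(cfg.lattice_cols):
            dipoles.append(DipoleState(
                position=np.array([c * cfg.spacing, r * cfg.spacing]),
                orientation=gen.uniform(0.0, TWO_PI),
                arm_length=cfg.arm_length,
                end_charge=cfg.dipole_end_charge))

    n_dop = int(round(concentration / 100.0 * len(dipoles)))
    x0, y0, x1, y1 = cfg.box
    floor2 = cfg.hard_core_floor ** 2
    placed: list[np.ndarray] = [d.position for d in dipoles]
    dopants = []
    for _ in range(n_dop):
        for _attempt in range(max_retries):
            p = np.array([gen.uniform(x0, x1), gen.uniform(y0, y1)])
            d2 = min(((p - o) ** 2).sum() for o in placed)
            if d2 >= floor2:
                placed.append(p)
                dopants.append(DopantState(position=p, charge=q, size=L))
                break
        else:
            raise RuntimeError(
                f"could not place dopant {len(dopants) + 1}/{n_dop} after "
                f"{max_retries} attempts (overcrowded domain)")
    return make_state(dipoles, dopants, cfg)


def propose_move(state: SystemState, particle_id: int, sched: MoveSchedule,
                 rng: np.random.Generator) -> tuple[np.ndarray, Optional[float]]:
    """Trial (position, orientation) for one particle.

    Translation uniform in the square [-dx, dx]^2; dipole rotation uniform
    in [-dalpha, +dalpha]; dopants keep orientation None.
    """
    if not 0 <= particle_id < state.n_particles:
        raise IndexError(f"no particle {particle_id}")
    step = rng.uniform(-sched.dx, sched.dx, size=2) if sched.dx > 0 else np.zeros(2)
    new_pos = state.pos[particle_id] + step
    if particle_id < state.n_dipoles:
        da = rng.uniform(-sched.dalpha, sched.dalpha) if sched.dalpha > 0 else 0.0
        return new_pos, (state.alpha[particle_id] + da) % TWO_PI
    return new_pos, None


def metropolis_accept(delta_e: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-delta_e)), delta_e in kBT."""
    if not math.isfinite(delta_e):
        raise ValueError("delta_e must be finite")
    if delta_e <= 0.0:
        return True
    return rng.random() < math.exp(-delta_e)


def run_minimization(state: SystemState, cfg: SystemConfig,
                     sched: Optional[MoveSchedule] = None,
                     rng: Union[int, np.random.Generator, None] = None,
                     record_every: int = 10,
                     annealing_factor: float = 1.0,
                     annealing_stages: int = 1) -> RunResult:
    """Search for the minimum-binding-energy configuration.

    The input ``state`` is not modified.  With ``annealing_factor < 1`` the
    run is split into ``annealing_stages`` stages whose Boltzmann energies
    are rescaled geometrically (optional cooling; off by default).
    """
    if sched is None:
        sched = MoveSchedule.from_config(cfg)
    seed = _as_seed(rng)
    window = sched.sweeps_per_check or cfg.convergence_window
    work = state.copy()
    a_eff, eps, floor2, soft, periodic, lx, ly, rc2 = cfg._kernel_args()
    x0, y0, x1, y1 = cfg.box

    if annealing_factor >= 1.0 or annealing_stages <= 1:
        stage_scales = [1.0]
    else:
        stage_scales = [annealing_factor ** (annealing_stages - 1 - s)
                        for s in range(annealing_stages)]

    traces = []
    best_e = math.inf
    best_pos, best_alpha = work.pos.copy(), work.alpha.copy()
    sweeps_total = 0
    accepted = attempted = 0
    converged = False
    sweeps_per_stage = max(1, cfg.max_sweeps // len(stage_scales))
    for si, scale in enumerate(stage_scales):
        # energy rescaling by 1/scale == temperature scaled by `scale`
        (e, bpos, balpha, trace, n_trace, sweeps, conv, acc, att) = _kernels.mc_run(
            work.pos, work.alpha, work.q, work.arm, work.sig, work.n_dipoles,
            a_eff / scale, eps / scale, floor2, soft, periodic, lx, ly, rc2,
            x0, y0, x1, y1,
            sched.dx, sched.dalpha, sched.dopants_mobile,
            sweeps_per_stage, window, cfg.convergence_tol,
            (seed + si) % (2 ** 31), record_every)
        e_unscaled = e * scale
        t = trace[:n_trace].copy()
        t[:, 0] += sweeps_total
        t[:, 1:] *= scale
        traces.append(t)
        sweeps_total += sweeps
        accepted += acc
        attempted += att
        converged = bool(conv)
        if e_unscaled < best_e:
            best_e = e_unscaled
            best_pos, best_alpha = bpos.copy(), balpha.copy()

    best_state = SystemState(best_pos, best_alpha, work.q.copy(),
                             work.arm.copy(), work.sig.copy(), work.n_dipoles)
    breakdown = total_energy(best_state, cfg)
    best_state.cached_energy = breakdown.total
    work.cached_energy = None
    return RunResult(
        best_energy=breakdown.total,
        best_state=best_state,
        energy_trace=np.vstack(traces) if traces else np.empty((0, 3)),
        sweeps_run=sweeps_total,
        converged=converged,
        seed=seed,
        acceptance_rate=accepted / attempted if attempted else 0.0,
        final_state=work)
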