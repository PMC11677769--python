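"""Domain types and the interaction-energy model of the membrane surface layer.

The surface of the bilayer is coarse-grained as a planar system of mobile,
rotating electric dipoles (the zwitterionic headgroups) doped with charged
or neutral guest particles.  A dipole of length ``l`` carries two opposite
point charges of magnitude ``end_charge`` at ``position +/- arm_length *
(cos a, sin a)`` with ``arm_length = l/2``; a dopant is a single point
charge of integer charge ``q`` and diameter ``L``.

The pair interaction is Coulomb (signed sum over the point-charge pairs,
screened by a relative permittivity) plus a Lennard-Jones term
``4*eps*[(sigma/d)^12 - (sigma/d)^6]`` on the center-center distance with
``sigma`` mixed arithmetically.  Energies are expressed in kB*T at the
configured temperature, lengths in nm, charges in elementary charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .constants import coulomb_prefactor_kT_nm

TWO_PI = 2.0 * math.pi

__all__ = [
    "DipoleState", "DopantState", "SystemConfig", "SystemState",
    "EnergyBreakdown", "OverlapError", "make_state",
    "dipole_pair_energy", "dipole_dopant_energy", "dopant_pair_energy",
    "total_energy", "delta_energy_for_move",
]


class OverlapError(ValueError):
    """Two particle centers closer than the hard-core floor."""

    def __init__(self, i: int, j: int, message: str | None = None):
        self.pair = (i, j)
        super().__init__(message or
                         f"hard-core overlap between particles {i} and {j}")


@dataclass
class DipoleState:
    """One headgroup dipole in the XY plane.

    The dipole axis lies in the plane and rotates about the vertical axis
    through its center; ``mass`` and ``moment_of_inertia`` are carried as
    metadata only (configurational Metropolis sampling never uses them).
    """

    position: np.ndarray            # nm, shape (2,)
    orientation: float              # rad, wrapped to [0, 2*pi)
    arm_length: float = 0.25        # nm, = l/2 for l = 0.5 nm
    end_charge: float = 1.0         # e, magnitude of the +/- end charges
    mass: Optional[float] = None
    moment_of_inertia: Optional[float] = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (2,):
            raise ValueError("position must be a 2-vector")
        if not self.arm_length > 0:
            raise ValueError("arm_length must be positive")
        self.orientation = float(self.orientation) % TWO_PI

    @property
    def end_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(positive end, negative end) positions in nm."""
        u = self.arm_length * np.array([math.cos(self.orientation),
                                        math.sin(self.orientation)])
        return self.position + u, self.position - u


@dataclass
class DopantState:
    """One dopant particle: point charge ``charge`` (e) with LJ diameter
    ``size`` (nm)."""

    position: np.ndarray
    charge: int
    size: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (2,):
            raise ValueError("position must be a 2-vector")
        if not self.size > 0:
            raise ValueError("size must be positive")
        if self.charge != int(self.charge):
            raise ValueError("charge must be an integer number of e")
        self.charge = int(self.charge)


@dataclass
class SystemConfig:
    """All physical and algorithmic parameters of a run.

    Defaults describe a 20x20 lattice of l = 0.5 nm dipoles spaced 2l apart
    at 295 K over an aqueous interface (relative permittivity 80), LJ well
    depth 1 kBT and dipole LJ diameter 0.5 nm.
    """

    lattice_rows: int = 20
    lattice_cols: int = 20
    spacing: float = 1.0                  # nm, = 2l
    temperature: float = 295.0            # K
    relative_permittivity: float = 80.0
    lj_epsilon: float = 1.0               # kBT
    lj_sigma_dipole: float = 0.5          # nm
    dipole_length: float = 0.5            # nm, l; arm a = l/2
    dipole_end_charge: float = 1.0        # e
    boundary: str = "open"                # "open" | "periodic"
    dx: float = 0.1                       # nm, max translation per move
    dalpha: float = math.pi / 6.0         # rad, max rotation per move
    max_sweeps: int = 5000
    convergence_window: int = 500
    convergence_tol: float = 1e-6         # relative, on |best energy|
    hard_core_floor: float = 1e-4         # nm, center-center rejection
    coulomb_soft_core: float = 0.3        # nm, finite charge-site size
    dipole_cutoff: float = math.inf       # nm, dipole-dipole truncation
    seed: int = 0

    def __post_init__(self):
        if self.boundary not in ("open", "periodic"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.spacing < self.dipole_length:
            raise ValueError("spacing must be >= dipole length (2*arm)")
        if not self.relative_permittivity > 0:
            raise ValueError("relative_permittivity must be positive")
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be >= 0")
        if not (self.dx > 0 and self.dalpha > 0):
            raise ValueError("dx and dalpha must be positive")
        if self.dx > self.spacing / 2:
            raise ValueError("dx must be <= spacing/2")

    @property
    def arm_length(self) -> float:
        return self.dipole_length / 2.0

    @property
    def coulomb_prefactor(self) -> float:
        """e^2/(4 pi eps0) in kBT*nm at cfg.temperature (before 1/epsr)."""
        return coulomb_prefactor_kT_nm(self.temperature)

    @property
    def k(self) -> float:
        """Dimensionless move-range parameter k = pi*l/(dx*dalpha)."""
        return math.pi * self.dipole_length / (self.dx * self.dalpha)

    @property
    def box(self) -> tuple[float, float, float, float]:
        """Open-boundary domain (x0, y0, x1, y1): the lattice bounding
        region padded by half a spacing on every side."""
        h = self.spacing / 2.0
        return (-h, -h,
                (self.lattice_cols - 0.5) * self.spacing,
                (self.lattice_rows - 0.5) * self.spacing)

    def _kernel_args(self) -> tuple:
        """(A, eps, floor^2, soft, periodic, lx, ly, rc^2) for the kernels.

        ``dipole_cutoff`` truncates dipole-dipole pairs only; pairs that
        involve a dopant are always evaluated in full, because the dopant
        monopole tail (~1/r) is long-ranged while a neutral dipole pair
        decays as r^-3.
        """
        a_eff = self.coulomb_prefactor / self.relative_permittivity
        x0, y0, x1, y1 = self.box
        rc2 = (self.dipole_cutoff ** 2
               if self.dipole_cutoff < 1e150 else 1e300)
        return (a_eff, self.lj_epsilon, self.hard_core_floor ** 2,
                self.coulomb_soft_core, self.boundary == "periodic",
                x1 - x0, y1 - y0, rc2)


@dataclass
class EnergyBreakdown:
    """Total interaction energy split by pair category, in kBT."""

    dipole_dipole_coulomb: float
    dipole_dopant_coulomb: float
    dopant_dopant_coulomb: float
    lj_total: float

    @property
    def total(self) -> float:
        return (self.dipole_dipole_coulomb + self.dipole_dopant_coulomb +
                self.dopant_dopant_coulomb + self.lj_total)


class SystemState:
    """Configuration of all dipoles and dopants, stored as flat arrays
    (dipoles first) with a cached total energy.

    The cache is maintained incrementally by :meth:`apply_move`; the
    from-scratch value is always available via :func:`total_energy`.
    """

    def __init__(self, pos: np.ndarray, alpha: np.ndarray, q: np.ndarray,
                 arm: np.ndarray, sig: np.ndarray, n_dipoles: int):
        self.pos = np.ascontiguousarray(pos, dtype=float)
        self.alpha = np.ascontiguousarray(alpha, dtype=float)
        self.q = np.ascontiguousarray(q, dtype=float)
        self.arm = np.ascontiguousarray(arm, dtype=float)
        self.sig = np.ascontiguousarray(sig, dtype=float)
        self.n_dipoles = int(n_dipoles)
        self.cached_energy: Optional[float] = None
        if not (self.pos.shape[0] == self.alpha.shape[0] == self.q.shape[0]
                == self.arm.shape[0] == self.sig.shape[0]):
            raise ValueError("array length mismatch")

    @property
    def n_dopants(self) -> int:
        return self.pos.shape[0] - self.n_dipoles

    @property
    def n_particles(self) -> int:
        return self.pos.shape[0]

    @property
    def dipoles(self) -> list[DipoleState]:
        return [DipoleState(self.pos[i].copy(), self.alpha[i],
                            self.arm[i], self.q[i])
                for i in range(self.n_dipoles)]

    @property
    def dopants(self) -> list[DopantState]:
        return [DopantState(self.pos[i].copy(), int(round(self.q[i])),
                            self.sig[i])
                for i in range(self.n_dipoles, self.n_particles)]

    def copy(self) -> "SystemState":
        s = SystemState(self.pos.copy(), self.alpha.copy(), self.q.copy(),
                        self.arm.copy(), self.sig.copy(), self.n_dipoles)
        s.cached_energy = self.cached_energy
        return s

    def apply_move(self, particle_id: int, position, orientation,
                   delta_e: float) -> None:
        """Commit an accepted move and update the cached energy."""
        self.pos[particle_id] = position
        if orientation is not None and particle_id < self.n_dipoles:
            self.alpha[particle_id] = float(orientation) % TWO_PI
        if self.cached_energy is not None:
            self.cached_energy += delta_e

    def validate_distinct_centers(self, floor: float) -> None:
        d = self.pos[:, None, :] - self.pos[None, :, :]
        r2 = (d ** 2).sum(-1)
        np.fill_diagonal(r2, np.inf)
        i, j = np.unravel_index(np.argmin(r2), r2.shape)
        if r2[i, j] < floor ** 2:
            raise OverlapError(int(i), int(j))


def make_state(dipoles: Sequence[DipoleState],
               dopants: Sequence[DopantState],
               cfg: SystemConfig) -> SystemState:
    """Build a :class:`SystemState` from particle objects; the dipole LJ
    diameter is taken from ``cfg.lj_sigma_dipole``, the dopant one from each
    dopant's ``size``."""
    n_d = len(dipoles)
    n = n_d + len(dopants)
    pos = np.zeros((n, 2))
    alpha = np.zeros(n)
    q = np.zeros(n)
    arm = np.zeros(n)
    sig = np.zeros(n)
    for i, d in enumerate(dipoles):
        pos[i] = d.position
        alpha[i] = d.orientation
        q[i] = d.end_charge
        arm[i] = d.arm_length
        sig[i] = cfg.lj_sigma_dipole
    for k, p in enumerate(dopants):
        i = n_d + k
        pos[i] = p.position
        q[i] = p.charge
        sig[i] = p.size
    s = SystemState(pos, alpha, q, arm, sig, n_d)
    if n > 1:
        s.validate_distinct_centers(cfg.hard_core_floor)
    return s


def _pair(cfg: SystemConfig,
          xi, yi, ai, qi, armi, sigi, i_dip,
          xj, yj, aj, qj, armj, sigj, j_dip) -> float:
    u = _kernels.pair_energy(xi, yi, ai, qi, armi, sigi, i_dip,
                             xj, yj, aj, qj, armj, sigj, j_dip,
                             *cfg._kernel_args())
    if u >= _kernels.OVERLAP_ENERGY:
        raise OverlapError(0, 1, "pair centers closer than the hard-core floor")
    return float(u)


def dipole_pair_energy(d1: DipoleState, d2: DipoleState,
                       cfg: SystemConfig) -> float:
    """Coulomb (four signed end-charge terms) + LJ energy of two dipoles,
    in kBT.  Symmetric in its arguments."""
    return _pair(cfg,
                 d1.position[0], d1.position[1], d1.orientation,
                 d1.end_charge, d1.arm_length, cfg.lj_sigma_dipole, True,
                 d2.position[0], d2.position[1], d2.orientation,
                 d2.end_charge, d2.arm_length, cfg.lj_sigma_dipole, True)


def dipole_dopant_energy(d: DipoleState, p: DopantState,
                         cfg: SystemConfig) -> float:
    """Coulomb (two signed terms against the dopant point charge) + LJ with
    mixed sigma = (lj_sigma_dipole + L)/2, in kBT."""
    return _pair(cfg,
                 d.position[0], d.position[1], d.orientation,
                 d.end_charge, d.arm_length, cfg.lj_sigma_dipole, True,
                 p.position[0], p.position[1], 0.0,
                 float(p.charge), 0.0, p.size, False)


def dopant_pair_energy(p1: DopantState, p2: DopantState,
                       cfg: SystemConfig) -> float:
    """Point-charge Coulomb + LJ with sigma = (L1 + L2)/2, in kBT."""
    return _pair(cfg,
                 p1.position[0], p1.position[1], 0.0,
                 float(p1.charge), 0.0, p1.size, False,
                 p2.position[0], p2.position[1], 0.0,
                 float(p2.charge), 0.0, p2.size, False)


def total_energy(state: SystemState, cfg: SystemConfig) -> EnergyBreakdown:
    """From-scratch energy over all unordered pairs, split by category."""
    dd, dp, pp, lj, tot, oi, oj = _kernels.total_energy(
        state.pos, state.alpha, state.q, state.arm, state.sig,
        state.n_dipoles, *cfg._kernel_args())
    if oi >= 0:
        raise OverlapError(int(oi), int(oj))
    return EnergyBreakdown(dd, dp, pp, lj)


def delta_energy_for_move(state: SystemState, particle_id: int,
                          trial_position, trial_orientation,
                          cfg: SystemConfig) -> float:
    """Energy change of moving one particle, computed in O(N).

    ``trial_orientation`` is ignored for dopants (may be None).  Raises
    :class:`OverlapError` if the trial position overlaps another center;
    Metropolis callers treat that as a rejection.
    """
    n = state.n_particles
    if not 0 <= particle_id < n:
        raise IndexError(f"no particle {particle_id}")
    tp = np.asarray(trial_position, dtype=float)
    if particle_id < state.n_dipoles:
        ta = (float(trial_orientation) % TWO_PI
              if trial_orientation is not None
              else state.alpha[particle_id])
        tax = state.arm[particle_id] * math.cos(ta)
        tay = state.arm[particle_id] * math.sin(ta)
    else:
        tax = tay = 0.0
    ax = np.zeros(n)
    ay = np.zeros(n)
    nd = state.n_dipoles
    ax[:nd] = state.arm[:nd] * np.cos(state.alpha[:nd])
    ay[:nd] = state.arm[:nd] * np.sin(state.alpha[:nd])
    de = _kernels.move_delta(
        state.pos, ax, ay, state.q, state.sig, nd, particle_id,
        tp[0], tp[1], tax, tay, *cfg._kernel_args())
    if de >= _kernels.OVERLAP_ENERGY:
        raise OverlapError(particle_id, -1,
                           f"trial position of particle {particle_id} "
                           "overlaps another center")
    return float(de)
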