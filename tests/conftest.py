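"""Shared fixtures and the independent brute-force energy oracle.

The oracle reimplements the pair-energy model directly from its physical
definition (explicit point-charge lists, soft-core Coulomb, center-center
LJ) in plain numpy, with no code shared with the package's kernels.
"""

import math

import numpy as np
import pytest

from lipidmc import (DipoleState, DopantState, SystemConfig, make_state)
from lipidmc.constants import COULOMB_EV_NM, KB_EV_PER_K


@pytest.fixture
def cfg():
    """Default full-physics configuration (no cutoff)."""
    return SystemConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# --- independent oracle -------------------------------------------------

def oracle_charges(particle, cfg):
    """Explicit (x, y, q) point-charge list of one particle."""
    if isinstance(particle, DipoleState):
        ux = particle.arm_length * math.cos(particle.orientation)
        uy = particle.arm_length * math.sin(particle.orientation)
        x, y = particle.position
        return [(x + ux, y + uy, particle.end_charge),
                (x - ux, y - uy, -particle.end_charge)]
    x, y = particle.position
    return [(x, y, float(particle.charge))]


def oracle_sigma(particle, cfg):
    if isinstance(particle, DipoleState):
        return cfg.lj_sigma_dipole
    return particle.size


def oracle_pair_energy(p1, p2, cfg):
    """Coulomb + LJ energy of one pair, from first principles."""
    prefactor = COULOMB_EV_NM / (KB_EV_PER_K * cfg.temperature)
    a = prefactor / cfg.relative_permittivity
    u = 0.0
    for (x1, y1, q1) in oracle_charges(p1, cfg):
        for (x2, y2, q2) in oracle_charges(p2, cfg):
            if q1 == 0 or q2 == 0:
                continue
            r = math.hypot(x2 - x1, y2 - y1)
            u += a * q1 * q2 / max(r, cfg.coulomb_soft_core)
    d = math.hypot(*(np.asarray(p2.position) - np.asarray(p1.position)))
    if cfg.lj_epsilon > 0:
        s = 0.5 * (oracle_sigma(p1, cfg) + oracle_sigma(p2, cfg))
        u += 4.0 * cfg.lj_epsilon * ((s / d) ** 12 - (s / d) ** 6)
    return u


def oracle_total_energy(dipoles, dopants, cfg):
    """O(N^2) double loop over all unordered pairs."""
    parts = list(dipoles) + list(dopants)
    return sum(oracle_pair_energy(parts[i], parts[j], cfg)
               for i in range(len(parts)) for j in range(i + 1, len(parts)))


def random_small_system(gen, cfg, n_dip=None, n_dop=None, span=6.0,
                        min_sep=0.45):
    """Random dilute system of a few dipoles and dopants (as particle
    objects plus the corresponding SystemState)."""
    if n_dip is None:
        n_dip = int(gen.integers(1, 7))
    if n_dop is None:
        n_dop = int(gen.integers(0, 4))
    positions = []
    while len(positions) < n_dip + n_dop:
        p = gen.uniform(0, span, size=2)
        if all(np.hypot(*(p - o)) > min_sep for o in positions):
            positions.append(p)
    dipoles = [DipoleState(position=positions[i],
                           orientation=gen.uniform(0, 2 * math.pi),
                           arm_length=cfg.arm_length,
                           end_charge=cfg.dipole_end_charge)
               for i in range(n_dip)]
    dopants = [DopantState(position=positions[n_dip + k],
                           charge=int(gen.integers(-3, 4)),
                           size=float(gen.uniform(0.1, 0.7)))
               for k in range(n_dop)]
    return dipoles, dopants, make_state(dipoles, dopants, cfg)
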