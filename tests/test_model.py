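"""Energy-model tests against the independent point-charge oracle."""

import math

import numpy as np
import pytest

from lipidmc import (DipoleState, DopantState, OverlapError, SystemConfig,
                     delta_energy_for_move, dipole_dopant_energy,
                     dipole_pair_energy, dopant_pair_energy, make_state,
                     total_energy)
from conftest import oracle_pair_energy, oracle_total_energy, random_small_system

RMIN = 2.0 ** (1.0 / 6.0)


def dip(x, y, alpha, cfg, q=None):
    return DipoleState(position=np.array([x, y]), orientation=alpha,
                       arm_length=cfg.arm_length,
                       end_charge=cfg.dipole_end_charge if q is None else q)


class TestDipolePair:
    def test_lj_minimum_neutral(self, cfg):
        """Two chargeless dipoles at the LJ minimum distance feel exactly -eps."""
        d = RMIN * cfg.lj_sigma_dipole
        u = dipole_pair_energy(dip(0, 0, 0, cfg, q=0.0), dip(d, 0, 0, cfg, q=0.0), cfg)
        assert u == pytest.approx(-cfg.lj_epsilon, rel=1e-12)

    def test_decay_to_zero(self, cfg):
        u = dipole_pair_energy(dip(0, 0, 0.3, cfg), dip(1e4, 0, 1.1, cfg), cfg)
        assert abs(u) < 1e-6

    def test_four_term_coulomb_oracle(self, cfg):
        """Head-to-tail aligned pair at 1 nm: four point-charge terms at
        separations (1.0, 0.5, 1.5, 1.0) nm with signs given by the charge
        products; net attraction."""
        cfg = SystemConfig(lj_epsilon=0.0)
        d1 = dip(0, 0, 0.0, cfg)
        d2 = dip(1.0, 0, 0.0, cfg)
        a = cfg.coulomb_prefactor / cfg.relative_permittivity
        expected = a * (1 / 1.0 + 1 / 1.0 - 1 / 0.5 - 1 / 1.5)
        u = dipole_pair_energy(d1, d2, cfg)
        assert u == pytest.approx(expected, rel=1e-12)
        assert u == pytest.approx(oracle_pair_energy(d1, d2, cfg), rel=1e-12)
        assert u < 0

    def test_symmetric(self, cfg, rng):
        for _ in range(20):
            d1 = dip(*rng.uniform(0, 5, 2), rng.uniform(0, 7), cfg)
            d2 = dip(*rng.uniform(6, 10, 2), rng.uniform(0, 7), cfg)
            assert dipole_pair_energy(d1, d2, cfg) == pytest.approx(
                dipole_pair_energy(d2, d1, cfg), rel=1e-12)

    def test_overlap_raises(self, cfg):
        with pytest.raises(OverlapError):
            dipole_pair_energy(dip(0, 0, 0, cfg), dip(1e-6, 0, 1, cfg), cfg)


class TestDipoleDopant:
    def test_neutral_dopant_pure_lj(self, cfg):
        L = 0.3
        d = RMIN * 0.5 * (cfg.lj_sigma_dipole + L)
        u = dipole_dopant_energy(
            dip(0, 0, 0.7, cfg),
            DopantState(position=np.array([d, 0.0]), charge=0, size=L), cfg)
        assert u == pytest.approx(-cfg.lj_epsilon, rel=1e-12)

    def test_perpendicular_bisector_cancels(self):
        """A charge equidistant from both dipole ends sees zero Coulomb."""
        cfg = SystemConfig(lj_epsilon=0.0)
        d = dip(0, 0, 0.0, cfg)
        p = DopantState(position=np.array([0.0, 1.3]), charge=3, size=0.2)
        assert dipole_dopant_energy(d, p, cfg) == pytest.approx(0.0, abs=1e-14)

    def test_two_term_oracle(self):
        """q=+2 dopant on the dipole axis: point-charge terms at 0.35 and
        0.85 nm."""
        cfg = SystemConfig(lj_epsilon=0.0)
        d = dip(0, 0, 0.0, cfg)
        p = DopantState(position=np.array([0.6, 0.0]), charge=2, size=0.1)
        a = cfg.coulomb_prefactor / cfg.relative_permittivity
        expected = a * 2.0 * (1 / 0.35 - 1 / 0.85)
        u = dipole_dopant_energy(d, p, cfg)
        assert u == pytest.approx(expected, rel=1e-12)
        assert u == pytest.approx(oracle_pair_energy(d, p, cfg), rel=1e-12)


class TestDopantPair:
    def test_neutral_lj_minimum(self, cfg):
        p1 = DopantState(position=np.zeros(2), charge=0, size=0.4)
        p2 = DopantState(position=np.array([RMIN * 0.4, 0.0]), charge=0, size=0.4)
        assert dopant_pair_energy(p1, p2, cfg) == pytest.approx(
            -cfg.lj_epsilon, rel=1e-12)

    def test_like_charges_repel(self):
        cfg = SystemConfig(lj_epsilon=0.0)
        p1 = DopantState(position=np.zeros(2), charge=2, size=0.1)
        p2 = DopantState(position=np.array([2.5, 1.0]), charge=2, size=0.1)
        a = cfg.coulomb_prefactor / cfg.relative_permittivity
        d = math.hypot(2.5, 1.0)
        assert dopant_pair_energy(p1, p2, cfg) == pytest.approx(4 * a / d, rel=1e-12)
        assert dopant_pair_energy(p1, p2, cfg) > 0

    def test_unlike_charges_hand_value(self):
        cfg = SystemConfig(lj_epsilon=0.0)
        p1 = DopantState(position=np.zeros(2), charge=1, size=0.1)
        p2 = DopantState(position=np.array([1.0, 0.0]), charge=-1, size=0.1)
        expected = -cfg.coulomb_prefactor / (80.0 * 1.0)
        assert dopant_pair_energy(p1, p2, cfg) == pytest.approx(expected, rel=1e-12)


class TestTotalEnergy:
    def test_empty_and_single(self, cfg):
        s = make_state([dip(0, 0, 1.0, cfg)], [], cfg)
        eb = total_energy(s, cfg)
        assert eb.total == 0.0
        assert eb.lj_total == 0.0

    def test_oracle_equivalence_many_random_systems(self, cfg):
        """Brute-force O(N^2) oracle agreement to 1e-9 relative on 100
        random small systems."""
        gen = np.random.default_rng(42)
        for _ in range(100):
            dipoles, dopants, state = random_small_system(gen, cfg)
            expected = oracle_total_energy(dipoles, dopants, cfg)
            got = total_energy(state, cfg).total
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_breakdown_sums(self, cfg, rng):
        _, _, state = random_small_system(rng, cfg, n_dip=5, n_dop=2)
        eb = total_energy(state, cfg)
        assert eb.total == pytest.approx(
            eb.dipole_dipole_coulomb + eb.dipole_dopant_coulomb
            + eb.dopant_dopant_coulomb + eb.lj_total, rel=1e-12)
        assert np.isfinite(eb.total)

    def test_translation_invariance(self, cfg, rng):
        dipoles, dopants, state = random_small_system(rng, cfg, n_dip=5, n_dop=2)
        shift = np.array([3.7, -1.2])
        moved = make_state(
            [DipoleState(d.position + shift, d.orientation, d.arm_length,
                         d.end_charge) for d in dipoles],
            [DopantState(p.position + shift, p.charge, p.size)
             for p in dopants], cfg)
        e1 = total_energy(state, cfg)
        e2 = total_energy(moved, cfg)
        for f in ("dipole_dipole_coulomb", "dipole_dopant_coulomb",
                  "dopant_dopant_coulomb", "lj_total"):
            assert getattr(e1, f) == pytest.approx(getattr(e2, f),
                                                   rel=1e-9, abs=1e-12)

    def test_rotation_invariance(self, cfg, rng):
        """Global 90-degree rotation about the lattice center (open
        boundary) leaves every component unchanged."""
        dipoles, dopants, state = random_small_system(rng, cfg, n_dip=6, n_dop=2)
        cx, cy = 2.0, 3.0
        rot = lambda p: np.array([cx - (p[1] - cy), cy + (p[0] - cx)])
        moved = make_state(
            [DipoleState(rot(d.position), d.orientation + math.pi / 2,
                         d.arm_length, d.end_charge) for d in dipoles],
            [DopantState(rot(p.position), p.charge, p.size) for p in dopants],
            cfg)
        assert total_energy(moved, cfg).total == pytest.approx(
            total_energy(state, cfg).total, rel=1e-9)

    def test_neutral_system_pure_lj(self, rng):
        cfg = SystemConfig(dipole_end_charge=0.0)
        dipoles, _, _ = random_small_system(rng, cfg, n_dip=6, n_dop=0)
        dopants = [DopantState(position=np.array([10.0, 10.0]), charge=0, size=0.3)]
        state = make_state(dipoles, dopants, cfg)
        eb = total_energy(state, cfg)
        assert eb.dipole_dipole_coulomb == 0.0
        assert eb.dipole_dopant_coulomb == 0.0
        assert eb.dopant_dopant_coulomb == 0.0
        assert eb.total == eb.lj_total

    def test_overlap_identifies_pair(self, cfg):
        d1 = dip(0, 0, 0, cfg)
        d2 = dip(5, 5, 0, cfg)
        p = DopantState(position=np.array([5.0 + 1e-6, 5.0]), charge=1, size=0.1)
        state = make_state([d1, d2], [], cfg)
        state.pos[1] = [1e-6, 0.0]   # force the overlap past construction
        with pytest.raises(OverlapError) as err:
            total_energy(state, cfg)
        assert err.value.pair == (0, 1)

    def test_periodic_minimum_image(self):
        """Near-edge pair under periodic boundary equals the explicitly
        image-shifted open-boundary pair."""
        cfg = SystemConfig(boundary="periodic", lattice_rows=10,
                           lattice_cols=10, lj_epsilon=0.5)
        lx = cfg.lattice_cols * cfg.spacing
        d1 = dip(0.1, 2.0, 0.4, cfg)
        d2 = dip(lx - 0.6, 2.0, 2.2, cfg)       # true separation 0.7 via image
        u_per = dipole_pair_energy(d1, d2, cfg)
        cfg_open = SystemConfig(lj_epsilon=0.5)
        d2_shift = dip(0.1 - 0.7, 2.0, 2.2, cfg_open)
        assert u_per == pytest.approx(
            dipole_pair_energy(d1, d2_shift, cfg_open), rel=1e-12)


class TestDeltaEnergy:
    def test_identity_move_is_zero(self, cfg, rng):
        _, _, state = random_small_system(rng, cfg, n_dip=4, n_dop=2)
        de = delta_energy_for_move(state, 2, state.pos[2].copy(),
                                   state.alpha[2], cfg)
        assert de == pytest.approx(0.0, abs=1e-12)

    def test_matches_from_scratch(self, cfg):
        gen = np.random.default_rng(7)
        for _ in range(25):
            dipoles, dopants, state = random_small_system(gen, cfg)
            i = int(gen.integers(0, state.n_particles))
            new_pos = state.pos[i] + gen.uniform(-0.3, 0.3, 2)
            new_alpha = gen.uniform(0, 2 * math.pi)
            before = total_energy(state, cfg).total
            try:
                de = delta_energy_for_move(state, i, new_pos, new_alpha, cfg)
            except OverlapError:
                continue
            state.apply_move(i, new_pos, new_alpha, de)
            after = total_energy(state, cfg).total
            assert de == pytest.approx(after - before, rel=1e-9, abs=1e-9)

    def test_isolated_dipole_rotation(self, cfg):
        state = make_state([dip(0, 0, 0.0, cfg)], [], cfg)
        de = delta_energy_for_move(state, 0, np.zeros(2), 1.7, cfg)
        assert de == 0.0

    def test_cache_consistency_many_updates(self, cfg):
        """Cached energy tracks the from-scratch value to 1e-6 relative
        after 10^4 accepted incremental updates."""
        gen = np.random.default_rng(99)
        _, _, state = random_small_system(gen, cfg, n_dip=6, n_dop=3, span=5.0)
        state.cached_energy = total_energy(state, cfg).total
        applied = 0
        while applied < 10_000:
            i = int(gen.integers(0, state.n_particles))
            new_pos = np.clip(state.pos[i] + gen.uniform(-0.2, 0.2, 2), 0.0, 5.0)
            new_alpha = gen.uniform(0, 2 * math.pi)
            try:
                de = delta_energy_for_move(state, i, new_pos, new_alpha, cfg)
            except OverlapError:
                continue
            if de < 50.0:   # skip absurd moves, as Metropolis would
                state.apply_move(i, new_pos, new_alpha, de)
                applied += 1
        exact = total_energy(state, cfg).total
        assert state.cached_energy == pytest.approx(exact, rel=1e-6, abs=1e-8)
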