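"""Structure-based force field, Langevin dynamics and link stability."""

import numpy as np
import pytest

from chromolink.chain_io import Chromosome, GenomeModel, Polyline
from chromolink.gln import gln
from chromolink.relaxation import (ForceFieldParams, SimulationConfig, System,
                                   Trajectory, build_contacts, build_system,
                                   energy, prune_beads, rmsd, simulate,
                                   stability, stability_vs_temperature)
from chromolink.synthetic import hopf_pair, threaded_pair

from conftest import random_open_chain


def _model(chains, names="abcdefgh"):
    return GenomeModel("t", "1", [Chromosome(names[i], c)
                                  for i, c in enumerate(chains)])


def _line_chain(spacing, n):
    return Polyline(np.c_[np.arange(n) * spacing, np.zeros(n), np.zeros(n)])


class TestPrune:
    def test_unit_spacing_unchanged(self):
        m = prune_beads(_model([_line_chain(1.0, 10)]))
        assert m.chromosomes[0].chain.n_vertices == 10

    def test_half_spacing_keeps_every_other_bead(self):
        m = prune_beads(_model([_line_chain(0.5, 10)]))
        kept = m.chromosomes[0].chain.vertices[:, 0]
        assert np.allclose(kept, np.arange(5) * 1.0)

    def test_exact_r_min_spacing_kept(self):
        m = prune_beads(_model([_line_chain(0.6, 10)]))
        assert m.chromosomes[0].chain.n_vertices == 10

    def test_chain_collapsing_to_one_bead_rejected(self):
        with pytest.raises(ValueError):
            prune_beads(_model([_line_chain(0.1, 5)]))


class TestContacts:
    def test_native_contact_sigma_at_minimum(self):
        a = _line_chain(1.0, 2)
        b = Polyline(np.c_[np.arange(2) * 1.0, np.ones(2), np.zeros(2)])
        contacts = build_contacts(_model([a, b]))
        assert len(contacts.pairs) == 4  # all cross-chain pairs near 1 nm
        i = np.flatnonzero((contacts.pairs == [0, 2]).all(axis=1))[0]
        assert contacts.r0[i] == pytest.approx(1.0)
        assert contacts.sigma[i] == pytest.approx(2.0 ** (-1 / 6))

    def test_beyond_cutoff_is_repulsive_only(self):
        a = _line_chain(1.0, 2)
        b = Polyline(np.c_[np.arange(2) * 1.0, np.full(2, 2.5), np.zeros(2)])
        contacts = build_contacts(_model([a, b]))
        assert len(contacts.pairs) == 0
        sys_ = build_system(_model([a, b]))
        assert len(sys_.rep_i) == 4

    def test_initial_overlap_excluded_from_everything(self):
        a = _line_chain(1.0, 2)
        b = Polyline(np.c_[np.arange(2) * 1.0, np.full(2, 0.4), np.zeros(2)])
        contacts = build_contacts(_model([a, b]))
        assert len(contacts.excluded) == 2  # the two 0.4 nm pairs
        # the 1.08 nm diagonals remain ordinary native contacts
        assert sorted(map(tuple, contacts.pairs)) == [(0, 3), (1, 2)]
        sys_ = build_system(_model([a, b]))
        flat = set(zip(sys_.rep_i.tolist(), sys_.rep_j.tolist()))
        assert (0, 2) not in flat and (1, 3) not in flat

    def test_chain_neighbours_excluded(self, rng):
        chain = random_open_chain(rng, 8)
        contacts = build_contacts(_model([chain]))
        for i, j in contacts.pairs:
            assert j - i > 3


class TestEnergy:
    def test_input_structure_has_zero_bonded_terms(self, rng):
        m = _model([random_open_chain(rng, 20),
                    random_open_chain(rng, 15, start=(3.0, 0, 0))])
        terms = energy(m)
        assert terms["bond"] == pytest.approx(0.0, abs=1e-20)
        assert terms["angle"] == pytest.approx(0.0, abs=1e-20)
        assert terms["dihedral"] == pytest.approx(0.0, abs=1e-16)

    def test_contact_minimum_depth_is_alpha_eps(self):
        a = _line_chain(1.0, 2)
        b = Polyline(np.c_[np.arange(2) * 1.0, np.ones(2), np.zeros(2)])
        m = _model([a, b])
        terms = energy(m)
        # 4 contacts, each exactly at its Lennard-Jones minimum of -0.2 eps
        assert terms["contact"] == pytest.approx(-0.2 * 4, abs=1e-12)

    def test_forces_match_finite_differences(self, rng):
        m = _model([random_open_chain(rng, 15),
                    random_open_chain(rng, 15, start=(1.5, 0.5, 0))])
        sys_ = build_system(m)
        x = sys_.x0 + rng.normal(scale=0.05, size=sys_.x0.shape)
        F, _ = sys_.forces(x)
        h = 1e-6
        for idx in rng.choice(sys_.n, size=10, replace=False):
            for dim in range(3):
                xp = x.copy()
                xp[idx, dim] += h
                xm = x.copy()
                xm[idx, dim] -= h
                num = -(sys_.forces(xp)[1] - sys_.forces(xm)[1]) / (2 * h)
                assert num == pytest.approx(F[idx, dim], abs=1e-5)


class TestDynamics:
    def test_damped_descent_lowers_energy(self, rng):
        m = _model([random_open_chain(rng, 20)])
        sys_ = build_system(m)
        x0 = sys_.x0 + rng.normal(scale=0.05, size=sys_.x0.shape)
        sys_.x0 = x0
        traj = simulate(m, SimulationConfig(temperature=0.0, n_steps=2000,
                                            seed=1, frame_stride=200),
                        system=sys_)
        energies = [sys_.energy_terms(f)["total"] for f in traj.frames]
        assert energies[-1] < energies[0]

    def test_no_secular_energy_drift_without_thermostat(self, rng):
        """Velocity Verlet (gamma = 0) shows only the bounded symplectic
        oscillation: the fitted drift is below 1e-4 eps per 1k steps."""
        m = _model([random_open_chain(rng, 20)])
        sys_ = build_system(m)
        dt = 0.0005
        x = sys_.x0.copy() + rng.normal(scale=0.002, size=sys_.x0.shape)
        v = np.zeros_like(x)
        F, _ = sys_.forces(x)
        energies = []
        for _ in range(5000):
            v += 0.5 * dt * F
            x += dt * v
            F, V = sys_.forces(x)
            v += 0.5 * dt * F
            energies.append(V + 0.5 * float(np.sum(v * v)))
        slope = np.polyfit(np.arange(5000), energies, 1)[0]
        assert abs(slope) * 1000 < 1e-4

    def test_same_seed_bitwise_identical(self, rng):
        m = _model([random_open_chain(rng, 15)])
        cfg = SimulationConfig(temperature=120.0, n_steps=500, seed=42,
                               frame_stride=100)
        t1 = simulate(m, cfg)
        t2 = simulate(m, cfg)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1, f2)

    def test_bonds_stay_stiff_at_operating_temperature(self, rng):
        m = prune_beads(_model(threaded_pair(turns=2, rod_len=15.0)))
        traj = simulate(m, SimulationConfig(temperature=120.0, n_steps=3000,
                                            seed=3, frame_stride=500))
        sys_ = traj.system
        for frame in traj.frames:
            r = np.linalg.norm(frame[sys_.bonds[:, 1]]
                               - frame[sys_.bonds[:, 0]], axis=1)
            assert np.all(np.abs(r - sys_.bond_r0) < 0.1 * sys_.bond_r0)

    def test_momentum_bounded_under_thermostat(self, rng):
        m = _model([random_open_chain(rng, 25)])
        traj = simulate(m, SimulationConfig(temperature=120.0, n_steps=3000,
                                            seed=5, frame_stride=500))
        drift = np.linalg.norm(traj.frames[-1].mean(axis=0)
                               - traj.frames[0].mean(axis=0))
        # center of mass diffuses like a free particle of mass N, no flight
        assert drift < 2.0


class TestStability:
    def _frozen_traj(self, chains, n_frames=20):
        m = _model(chains)
        sys_ = build_system(m)
        return Trajectory(system=sys_, frames=[sys_.x0.copy()] * n_frames,
                          times=list(range(n_frames)))

    def _mixed_traj(self, linked_fraction, n_frames=20):
        """Frames alternating between a linked Hopf pose and a pulled-apart
        pose, linked in the requested fraction of frames."""
        a, b = hopf_pair(30, radius=2.0)
        m = _model([a, b])
        sys_ = build_system(m)
        x_link = sys_.x0.copy()
        x_far = x_link.copy()
        x_far[sys_.slices["b"][0]:] += np.array([50.0, 0, 0])
        n_linked = int(round(linked_fraction * n_frames))
        frames = [x_link.copy() if i < n_linked else x_far.copy()
                  for i in range(n_frames)]
        return Trajectory(system=sys_, frames=frames,
                          times=list(range(n_frames))), gln(a, b)

    def test_frozen_hopf_is_stable_under_both_criteria(self):
        traj = self._frozen_traj(hopf_pair(30, radius=2.0))
        rep = stability(traj, ("a", "b"))
        assert rep.fraction_linked == 1.0
        assert rep.max_gln_drift == pytest.approx(0.0, abs=1e-12)
        assert rep.stable_strict and rep.stable_nondecreasing

    def test_quarter_linked_trajectory_unstable(self):
        traj, g0 = self._mixed_traj(0.25)
        rep = stability(traj, ("a", "b"), reference_gln=g0)
        assert rep.fraction_linked == pytest.approx(0.25)
        assert not rep.stable_strict

    def test_exactly_90_percent_boundary(self):
        traj, g0 = self._mixed_traj(0.9)
        rep = stability(traj, ("a", "b"), reference_gln=g0)
        assert rep.fraction_linked == pytest.approx(0.9)
        assert not rep.stable_strict  # drift to the far pose exceeds 0.2

    def test_high_fraction_but_large_drift_fails_strict(self):
        traj = self._frozen_traj(hopf_pair(30, radius=2.0))
        g = stability(traj, ("a", "b")).glns[0]
        rep = stability(traj, ("a", "b"), reference_gln=g + 0.5)
        assert rep.fraction_linked == 1.0
        assert rep.max_gln_drift == pytest.approx(0.5, abs=1e-9)
        assert not rep.stable_strict

    def test_unknown_pair_rejected(self):
        traj = self._frozen_traj(hopf_pair(30, radius=2.0))
        with pytest.raises(KeyError):
            stability(traj, ("a", "z"))

    def test_too_few_frames_rejected(self):
        traj = self._frozen_traj(hopf_pair(30, radius=2.0), n_frames=5)
        with pytest.raises(ValueError):
            stability(traj, ("a", "b"))

    def test_threaded_pair_stable_at_operating_temperature(self):
        """The package's own stability criterion passes on a construct that
        is stable by construction: a chain wound three times around a rod,
        relaxed for 20k steps at reduced temperature 120."""
        m = prune_beads(_model(threaded_pair(turns=3)))
        g0 = gln(m["a"].chain, m["b"].chain)
        traj = simulate(m, SimulationConfig(temperature=120.0, n_steps=20_000,
                                            seed=2, frame_stride=500))
        rep = stability(traj, ("a", "b"), reference_gln=g0)
        assert rep.fraction_linked >= 0.9
        drifts = np.abs(np.asarray(rep.glns) - g0)
        assert np.mean(drifts < 0.2) >= 0.9


class TestTemperatureScan:
    def test_row_count_and_t0_fraction(self):
        m = prune_beads(_model(threaded_pair(turns=2, rod_len=15.0,
                                             tail=3.0)))
        rows = stability_vs_temperature(
            m, ("a", "b"), temperatures=[0.0, 300.0],
            config=SimulationConfig(n_steps=4000, frame_stride=200, seed=6))
        assert len(rows) == 2
        assert rows[0]["fraction_linked"] == 1.0

    def test_weakly_linked_pair_melts_at_high_temperature(self):
        a, b = hopf_pair(24, radius=2.0)
        from chromolink.synthetic import open_chain
        m = prune_beads(_model([open_chain(a, 1 / 24), open_chain(b, 1 / 24)]))
        rows = stability_vs_temperature(
            m, ("a", "b"), temperatures=[0.0, 600.0],
            config=SimulationConfig(n_steps=6000, frame_stride=200, seed=7))
        assert rows[1]["fraction_linked"] <= rows[0]["fraction_linked"]


class TestRmsd:
    def test_zero_for_frozen_start(self, rng):
        m = _model([random_open_chain(rng, 12)])
        traj = simulate(m, SimulationConfig(temperature=120.0, n_steps=200,
                                            seed=8, frame_stride=100))
        r = rmsd(traj)
        assert r[0] == 0.0 and np.all(np.diff(r) > -1.0)
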