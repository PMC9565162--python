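import math

import numpy as np
import pytest
from scipy import stats

from crowdhop.docking import PoseLibrary, PoseTable, RotationSet
from crowdhop.engine import (MoveProposal, SimulationConfig, TimeModel,
                             acceptance_probability, apply_move,
                             collision_check, propose_move, run_simulation,
                             run_step)
from crowdhop.fixtures import build_toy_scenario
from crowdhop.structures import Protein
from crowdhop.system import SystemState


def _identity_rotations():
    return RotationSet(quats=np.array([[0.0, 0.0, 0.0, 1.0]]),
                       matrices=np.eye(3)[None], spacing=90.0)


def _library(n_types, disps, scores):
    disps = np.asarray(disps, float)
    scores = np.asarray(scores, float)
    order = np.argsort(-scores, kind="stable")
    table = PoseTable(rot_index=np.zeros(len(scores), np.int32),
                      trans=np.zeros((len(scores), 3), np.int32),
                      score=scores[order], disp=disps[order])
    return PoseLibrary(rotations=_identity_rotations(),
                       pairs={(i, j): table for i in range(n_types)
                              for j in range(n_types)},
                       ids=[f"t{i}" for i in range(n_types)])


def _point_protein(tag="pt"):
    at = np.array([[0.0, 0.0, 0.0]])
    return Protein(id=tag, atom_coords=at, atom_elements=["C"],
                   atom_names=["CA"], atom_resid=np.array([0]), calphas=at)


class TestAcceptanceProbability:
    def test_hand_computed_values(self):
        assert acceptance_probability(0.0, 0.0, 100.0, 3, 3) == 1.0
        assert acceptance_probability(0.0, -50.0, 100.0, 5, 5) == 1.0
        assert acceptance_probability(0.0, 100.0, 100.0, 4, 2) == \
            pytest.approx(2.0 / math.e, abs=1e-12)
        # move-count asymmetry alone can reject
        assert acceptance_probability(0.0, 0.0, 100.0, 1, 4) == 0.25

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            acceptance_probability(0.0, 1.0, 100.0, 3, 0)
        with pytest.raises(ValueError):
            acceptance_probability(0.0, 1.0, 0.0, 3, 3)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(200):
            p = acceptance_probability(
                rng.uniform(-500, 0), rng.uniform(-500, 0),
                rng.uniform(1, 1e4), rng.integers(1, 20),
                rng.integers(1, 20))
            assert 0.0 <= p <= 1.0


class TestProposeMove:
    def _star_state(self, protein):
        # copy 0 in the middle, four copies just inside the cutoff, one far
        r = protein.radius
        d = 2 * r + 40.0
        far = 2 * r + 200.0
        pos = np.array([
            [250.0, 250.0, 250.0],
            [250.0 + d, 250.0, 250.0],
            [250.0 - d, 250.0, 250.0],
            [250.0, 250.0 + d, 250.0],
            [250.0, 250.0 - d, 250.0],
            [250.0, 250.0, 250.0 + far],
        ])
        return SystemState([protein], np.zeros(6, int), pos,
                           np.stack([np.eye(3)] * 6), 1000.0)

    def test_receptor_uniform_over_neighbors(self, globule20, rng):
        state = self._star_state(globule20)
        lib = _library(1, [[12.0, 0, 0]], [10.0])
        counts = np.zeros(6)
        for _ in range(10_000):
            prop = propose_move(state, 0, lib, rng)
            counts[prop.receptor] += 1
        assert counts[0] == 0 and counts[5] == 0
        np.testing.assert_allclose(counts[1:5] / 10_000, 0.25, atol=0.02)

    def test_single_choice_is_deterministic(self, globule20, rng):
        state = self._star_state(globule20)
        # keep only the central copy and one neighbor
        sub = SystemState([globule20], [0, 0], state.pos[:2],
                          state.rot[:2], 1000.0)
        lib = _library(1, [[12.0, 0, 0]], [10.0])
        prop = propose_move(sub, 0, lib, rng)
        assert prop.receptor == 1 and prop.pose_index == 0
        assert prop.N_i == 1

    def test_isolated_ligand_returns_null(self, globule20, rng):
        pos = np.array([[100.0, 100, 100], [400.0, 400, 400]])
        state = SystemState([globule20], [0, 0], pos,
                            np.stack([np.eye(3)] * 2), 1000.0)
        lib = _library(1, [[12.0, 0, 0]], [10.0])
        assert propose_move(state, 0, lib, rng) is None


class TestCollisionCheck:
    def _proposal(self, state, new_pos, receptor=1):
        return MoveProposal(
            ligand=0, receptor=receptor, pose_index=0,
            new_rot=np.eye(3), new_pos=np.asarray(new_pos, float),
            displacement=np.zeros(3), e_new=-10.0, e_old=0.0,
            E_i=0.0, E_j=-10.0, N_i=1, N_j=1)

    def test_bystander_distance_thresholds(self):
        p = _point_protein()
        pos = np.array([[100.0, 100, 100],     # ligand
                        [140.0, 100, 100],     # receptor
                        [120.0, 100, 100]])    # bystander
        state = SystemState([p], [0, 0, 0], pos,
                            np.stack([np.eye(3)] * 3), 500.0,
                            collision_cutoff=8.0)
        # ligand lands 7.9 A from the bystander C-alpha: reject
        assert not collision_check(state, self._proposal(state,
                                                         [127.9, 100, 100]))
        # 8.1 A away: pass (receptor itself is exempt)
        assert collision_check(state, self._proposal(state,
                                                     [128.1, 100, 100]))

    def test_receptor_is_exempt(self):
        p = _point_protein()
        pos = np.array([[100.0, 100, 100], [140.0, 100, 100]])
        state = SystemState([p], [0, 0], pos, np.stack([np.eye(3)] * 2),
                            500.0, collision_cutoff=8.0)
        assert collision_check(state, self._proposal(state,
                                                     [139.0, 100, 100]))

    def test_disabled_by_nonpositive_cutoff(self):
        p = _point_protein()
        pos = np.array([[100.0, 100, 100], [140.0, 100, 100],
                        [101.0, 100, 100]])
        state = SystemState([p], [0, 0, 0], pos, np.stack([np.eye(3)] * 3),
                            500.0, collision_cutoff=0.0)
        assert collision_check(state, self._proposal(state,
                                                     [101.5, 100, 100]))

    def test_matches_brute_force_scan(self, globule20, globule30, rng):
        box = 300.0
        n = 50
        types = rng.integers(0, 2, n)
        pos = rng.uniform(0, box, (n, 3))
        from scipy.spatial.transform import Rotation
        rots = Rotation.random(n, rng=rng).as_matrix()
        state = SystemState([globule20, globule30], types, pos, rots, box,
                            collision_cutoff=8.0)
        for _ in range(40):
            lig = int(rng.integers(n))
            rec = int(rng.integers(n))
            if rec == lig:
                continue
            new_pos = rng.uniform(0, box, 3)
            new_rot = Rotation.random(rng=rng).as_matrix()
            prop = MoveProposal(
                ligand=lig, receptor=rec, pose_index=0, new_rot=new_rot,
                new_pos=new_pos, displacement=np.zeros(3), e_new=-1.0,
                e_old=0.0, E_i=0.0, E_j=-1.0, N_i=1, N_j=1)
            got = collision_check(state, prop)
            # oracle: all-pairs minimum-image CA scan
            lig_ca = new_pos + state.ca_templates[types[lig]] @ new_rot.T
            collide = False
            for c in range(n):
                if c in (lig, rec):
                    continue
                other = state.pos[c] + \
                    state.ca_templates[types[c]] @ state.rot[c].T
                d = lig_ca[:, None, :] - other[None, :, :]
                d -= box * np.rint(d / box)
                if np.sqrt((d ** 2).sum(axis=2)).min() < 8.0:
                    collide = True
                    break
            assert got == (not collide)


class TestApplyMove:
    def test_first_move_of_monomer(self):
        sc = build_toy_scenario("two_state")
        state = sc.state
        prop = MoveProposal(
            ligand=0, receptor=1, pose_index=0, new_rot=np.eye(3),
            new_pos=state.pos[1] + [10.0, 0, 0], displacement=np.zeros(3),
            e_new=-100.0, e_old=0.0, E_i=0.0, E_j=-100.0, N_i=1, N_j=1)
        apply_move(state, prop)
        assert state.energy[0] == -100.0 and state.energy[1] == -100.0
        assert state.total_energy == -100.0

    def test_receptor_transfer(self, globule20, rng):
        p = _point_protein()
        pos = np.array([[100.0, 100, 100], [130.0, 100, 100],
                        [100.0, 130, 100]])
        state = SystemState([p], [0, 0, 0], pos, np.stack([np.eye(3)] * 3),
                            500.0)
        move1 = MoveProposal(0, 1, 0, np.eye(3), pos[1] + [10.0, 0, 0],
                             np.zeros(3), -60.0, 0.0, 0.0, -60.0, 2, 2)
        apply_move(state, move1)
        move2 = MoveProposal(0, 2, 0, np.eye(3), pos[2] + [10.0, 0, 0],
                             np.zeros(3), -40.0, -60.0, -60.0, -40.0, 2, 2)
        apply_move(state, move2)
        assert state.energy[1] == 0.0          # old receptor released
        assert state.energy[2] == -40.0
        assert state.energy[0] == -40.0
        assert state.total_energy == -40.0

    def test_incremental_equals_recomputation_after_many_moves(self, rng):
        sc = build_toy_scenario("uniform_walk", n_copies=64, box=250.0)
        lib = _library(1, rng.normal(size=(8, 3)) * 10,
                       rng.uniform(5, 80, 8))
        state = sc.state
        applied = 0
        for _ in range(2000):
            i = int(rng.integers(state.n))
            prop = propose_move(state, i, lib, rng)
            if prop is None:
                continue
            apply_move(state, prop)
            applied += 1
        assert applied > 500
        np.testing.assert_allclose(state.energy, state.recompute_energies(),
                                   atol=1e-9)
        # each match contributes to both partners
        assert state.energy.sum() == pytest.approx(
            2 * state.out_energy[state.out_rec >= 0].sum(), abs=1e-9)


class TestRunStep:
    def test_every_copy_attempts_once(self, rng):
        sc = build_toy_scenario("uniform_walk", n_copies=27, box=200.0)
        stats_d = run_step(sc.state, sc.library, sc.config, rng)
        assert stats_d["attempts"] == 27

    def test_frozen_at_low_temperature(self, rng):
        sc = build_toy_scenario("frozen_pair", temperature=1.0)
        cfg = SimulationConfig(**{**sc.config.to_dict(), "steps": 200,
                                  "temperature": 1.0})
        traj = run_simulation(cfg, sc.proteins, sc.library, state=sc.state)
        deep = traj.bond_pose[1:]
        # once both molecules sit in the deep -10000 pose the chain cannot
        # leave it at T=1 (escape probability ~ exp(-9950))
        first_locked = np.flatnonzero((deep == 0).all(axis=1))
        assert len(first_locked) > 0
        locked_from = first_locked[0]
        assert (deep[locked_from:] == 0).all()

    def test_high_temperature_accepts_nearly_all(self):
        # two molecules: N_i = N_j = 1 and exp(-dE/T) -> 1, so every
        # collision-free proposal is accepted in the overheated limit
        sc = build_toy_scenario("two_state", temperature=1e6)
        cfg = SimulationConfig(**{**sc.config.to_dict(), "steps": 200,
                                  "temperature": 1e6})
        traj = run_simulation(cfg, sc.proteins, sc.library, state=sc.state)
        assert traj.acceptance.mean() > 0.99


class TestRunSimulation:
    def test_zero_steps_returns_initial_state(self):
        sc = build_toy_scenario("two_state")
        traj = run_simulation(sc.config, sc.proteins, sc.library,
                              state=sc.state)
        assert traj.n_steps == 0
        assert traj.unwrapped.shape == (1, 2, 3)

    def test_same_seed_bitwise_identical(self):
        sc1 = build_toy_scenario("uniform_walk", seed=9, n_copies=27,
                                 box=200.0)
        sc2 = build_toy_scenario("uniform_walk", seed=9, n_copies=27,
                                 box=200.0)
        cfg = SimulationConfig(**{**sc1.config.to_dict(), "steps": 40,
                                  "seed": 9})
        t1 = run_simulation(cfg, sc1.proteins, sc1.library, state=sc1.state)
        t2 = run_simulation(cfg, sc2.proteins, sc2.library, state=sc2.state)
        np.testing.assert_array_equal(t1.unwrapped, t2.unwrapped)
        np.testing.assert_array_equal(t1.bond_rec, t2.bond_rec)
        np.testing.assert_array_equal(t1.energy, t2.energy)

    def test_energy_never_positive_and_monomers_zero(self):
        sc = build_toy_scenario("uniform_walk", n_copies=27, box=200.0)
        cfg = SimulationConfig(**{**sc.config.to_dict(), "steps": 50})
        traj = run_simulation(cfg, sc.proteins, sc.library, state=sc.state)
        state = traj.final_state
        assert np.all(state.energy <= 1e-12)
        monomers = (state.out_rec < 0) & (state.in_deg == 0)
        assert np.all(state.energy[monomers] == 0.0)

    def test_unwrapped_consistent_with_wrapped(self):
        sc = build_toy_scenario("uniform_walk", n_copies=27, box=200.0)
        cfg = SimulationConfig(**{**sc.config.to_dict(), "steps": 50})
        traj = run_simulation(cfg, sc.proteins, sc.library, state=sc.state)
        state = traj.final_state
        diff = (state.unwrapped - state.pos) / state.box
        np.testing.assert_allclose(diff, np.rint(diff), atol=1e-9)

    def test_boltzmann_stationarity_three_poses(self):
        # two molecules, three poses: empirical pose occupancy must match
        # the exact Boltzmann law (chi-square test at alpha = 0.01)
        energies = np.array([-100.0, -80.0, -50.0])
        lib = _library(1, [[10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]],
                       -energies)
        sc = build_toy_scenario("two_state", temperature=100.0, seed=5)
        cfg = SimulationConfig(**{**sc.config.to_dict(), "steps": 30_000,
                                  "temperature": 100.0, "seed": 5})
        traj = run_simulation(cfg, sc.proteins, lib, state=sc.state)
        bp = traj.bond_pose[1000:]
        bp = bp[bp >= 0]
        counts = np.bincount(bp, minlength=3)
        w = np.exp(-energies / 100.0)
        expected = w / w.sum() * counts.sum()
        # thin the samples to decorrelate before the chi-square test
        thin = traj.bond_pose[1000::20]
        thin = thin[thin >= 0]
        c2 = np.bincount(thin, minlength=3)
        e2 = w / w.sum() * c2.sum()
        chi2 = float(((c2 - e2) ** 2 / e2).sum())
        assert stats.chi2.sf(chi2, df=2) > 0.01
        np.testing.assert_allclose(counts / counts.sum(), w / w.sum(),
                                   atol=0.02)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(box=250.0, steps=10, seed=3)
        path = tmp_path / "sim.yaml"
        import yaml
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        loaded = SimulationConfig.from_yaml(path)
        assert loaded == cfg
        assert loaded.hash() == cfg.hash()

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text("bogus_key: 1\n")
        with pytest.raises(ValueError, match="unknown config"):
            SimulationConfig.from_yaml(path)

    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(temperature=-1.0)
        with pytest.raises(ValueError):
            TimeModel(ns_per_step=0.0)
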