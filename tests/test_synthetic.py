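"""The synthetic-complex generator: ground truth, determinism, validity."""

import dataclasses
import json
import warnings

import numpy as np
import pytest

from contactsar import synthetic as syn
from contactsar.chem import pic50
from contactsar.contacts import collapse_equivalents, enumerate_candidates, filter_contacts
from contactsar.occupancy import distance_timeseries, occupancy_percent
from contactsar.structure import read_topology, read_trajectory
from contactsar.synthetic import (
    ContactProgram,
    SyntheticSpec,
    build_topology,
    default_spec,
    generate_sar_dataset,
    markov_state_series,
    paper_preset,
    simulate_trajectory,
    total_sampling_us_per_ligand,
    write_sar_dataset,
)


def _single_program_spec(target, frames, kind="salt_bridge", seed=0):
    prog = ContactProgram(kind, "ARG929", (target,), d_on=4.0, d_off=8.0, beta_true=-1.5)
    return SyntheticSpec(
        n_ligands=1, replicates_per_ligand=1, frames_per_replicate=frames,
        programs=(prog,), noise_sd=0.0, seed=seed,
    )


class TestSpecValidation:
    def test_rejects_d_on_near_cutoff(self):
        prog = ContactProgram("salt_bridge", "ARG929", (0.5,), d_on=4.9, d_off=8.0)
        with pytest.raises(ValueError, match="d_on"):
            SyntheticSpec(n_ligands=1, programs=(prog,))

    def test_rejects_occupancy_outside_unit_interval(self):
        prog = ContactProgram("salt_bridge", "ARG929", (1.5,), d_on=4.0, d_off=8.0)
        with pytest.raises(ValueError, match="occupancy"):
            SyntheticSpec(n_ligands=1, programs=(prog,))

    def test_rejects_target_count_mismatch(self):
        prog = ContactProgram("salt_bridge", "ARG929", (0.5, 0.5), d_on=4.0, d_off=8.0)
        with pytest.raises(ValueError, match="target"):
            SyntheticSpec(n_ligands=3, programs=(prog,))

    def test_paper_preset_sampling_arithmetic(self):
        assert total_sampling_us_per_ligand(paper_preset()) == pytest.approx(1.5)


class TestTopology:
    def test_single_ligand_entity(self):
        topo, _ = build_topology(default_spec())
        assert {a.residue_label for a in topo.atoms if a.is_ligand} == {"LIG1"}

    def test_two_arg_programs_give_two_guanidinium_groups(self):
        topo, _ = build_topology(default_spec())
        reps = {
            g.residue_label: topo.atoms[g.representative_index].atom_name
            for g in topo.groups
            if g.kind == "guanidinium"
        }
        # programmed ARG929/ARG439 plus the static control arginine
        assert reps == {"ARG929": "CZ", "ARG439": "CZ", "ARG100": "CZ"}

    def test_round_trips_through_pdb_without_warnings(self):
        from contactsar.structure import annotate_groups, write_topology

        spec = default_spec()
        topo, base = build_topology(spec)
        text = write_topology(topo, base)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            back = read_topology(text)
            back = annotate_groups(back, **spec.annotation_rules)
        assert [a.atom_name for a in back.atoms] == [a.atom_name for a in topo.atoms]
        assert len(back.groups) == len(topo.groups)
        assert len(back.rings) == len(topo.rings)


class TestTrajectorySimulation:
    @pytest.mark.parametrize("target,expected", [(1.0, 100.0), (0.0, 0.0)])
    def test_extreme_targets(self, target, expected):
        spec = _single_program_spec(target, frames=200)
        topo, base = build_topology(spec)
        traj = simulate_trajectory(topo, base, spec, 0, 0)
        pairs = enumerate_candidates(traj, topo)
        kept, rings = filter_contacts(pairs, topo, traj)
        cs = collapse_equivalents(kept, topo, ring_pairs=rings)
        by_id = {c.contact_id: c for c in cs}
        if target == 0.0:
            assert "C_COOH-ARG929:CZ" not in by_id  # never within candidate cutoff
        else:
            occ = occupancy_percent(
                distance_timeseries(traj, topo, by_id["C_COOH-ARG929:CZ"])
            )
            assert occ == expected

    def test_intermediate_target_concentrates(self):
        spec = _single_program_spec(0.5, frames=10000)
        topo, base = build_topology(spec)
        traj = simulate_trajectory(topo, base, spec, 0, 0)
        pairs = enumerate_candidates(traj, topo)
        kept, rings = filter_contacts(pairs, topo, traj)
        cs = {c.contact_id: c for c in collapse_equivalents(kept, topo, ring_pairs=rings)}
        occ = occupancy_percent(distance_timeseries(traj, topo, cs["C_COOH-ARG929:CZ"]))
        assert occ == pytest.approx(50.0, abs=3.0)

    def test_occupancy_error_shrinks_with_length(self):
        errs = {}
        for frames in (100, 1000, 10000):
            spec = _single_program_spec(0.7, frames=frames, seed=5)
            topo, base = build_topology(spec)
            traj = simulate_trajectory(topo, base, spec, 0, 0)
            prog = spec.programs[0]
            # governing distance directly: C1 (index 0) to ARG929 CZ
            cz = next(
                a.atom_index
                for a in topo.atoms
                if a.residue_label == "ARG929" and a.atom_name == "CZ"
            )
            d = np.linalg.norm(
                traj.coordinates[:, 0] - traj.coordinates[:, cz], axis=1
            )
            errs[frames] = abs(100 * (d <= prog.cutoff).mean() - 70.0)
        assert errs[10000] < 2.0
        assert errs[10000] <= errs[100] + 1e-9

    def test_deterministic_for_fixed_seed(self):
        spec = _single_program_spec(0.5, frames=50, seed=9)
        topo, base = build_topology(spec)
        a = simulate_trajectory(topo, base, spec, 0, 0)
        b = simulate_trajectory(topo, base, spec, 0, 0)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_replicates_differ(self):
        spec = SyntheticSpec(
            n_ligands=1,
            replicates_per_ligand=2,
            frames_per_replicate=50,
            programs=(ContactProgram("salt_bridge", "ARG929", (0.5,), 4.0, 8.0),),
            seed=9,
        )
        topo, base = build_topology(spec)
        a = simulate_trajectory(topo, base, spec, 0, 0)
        b = simulate_trajectory(topo, base, spec, 0, 1)
        assert not np.array_equal(a.coordinates, b.coordinates)


class TestMarkovChain:
    def test_stationary_start_exact_extremes(self):
        rng = np.random.default_rng(0)
        assert markov_state_series(rng, 10, 0.0, 0.5).sum() == 0
        assert markov_state_series(rng, 10, 1.0, 0.5).sum() == 10

    @pytest.mark.parametrize("target", [0.25, 0.5, 0.7])
    def test_occupancy_concentration(self, target):
        rng = np.random.default_rng(77)
        states = markov_state_series(rng, 20000, target, 0.5)
        assert states.mean() == pytest.approx(target, abs=0.02)


class TestSarDataset:
    def test_affinity_model(self):
        spec = default_spec(seed=4, noise_sd=0.0, frames_per_replicate=10)
        ds = generate_sar_dataset(spec)
        targets = np.array([p.target_occupancy for p in spec.programs])
        betas = np.array([p.beta_true for p in spec.programs])
        expected = spec.intercept + betas @ targets
        np.testing.assert_allclose(ds.pic50, expected, atol=1e-12)
        for p, ic in zip(ds.pic50, ds.ic50_nM):
            assert pic50(ic) == pytest.approx(p, abs=1e-9)

    def test_zero_beta_zero_noise_constant_pic50(self):
        spec = default_spec(seed=0, noise_sd=0.0, frames_per_replicate=10)
        spec = dataclasses.replace(
            spec,
            programs=tuple(dataclasses.replace(p, beta_true=0.0) for p in spec.programs),
        )
        ds = generate_sar_dataset(spec)
        np.testing.assert_allclose(ds.pic50, spec.intercept)
        np.testing.assert_allclose(ds.ic50_nM, 100.0)  # 10^(9-7) nM

    def test_written_files_reload_cleanly(self, tmp_path, default_dataset):
        from contactsar.structure import annotate_groups

        manifest = write_sar_dataset(default_dataset, tmp_path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            topo = read_topology((tmp_path / "topology.pdb").read_text())
            topo = annotate_groups(topo, **default_dataset.spec.annotation_rules)
            first = manifest["trajectories"][0]
            traj = read_trajectory((tmp_path / first["path"]).read_text(), topo)
        assert traj.n_frames == default_dataset.spec.frames_per_replicate
        truth = json.loads((tmp_path / "ground_truth.json").read_text())
        assert truth["programs"][0]["residue_label"] == "ARG929"

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        spec = default_spec(seed=21, frames_per_replicate=20)
        for sub in ("a", "b"):
            write_sar_dataset(generate_sar_dataset(spec), tmp_path / sub)
        for name in ("topology.pdb", "traj_lig1_rep1.pdb", "ligands.csv", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
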