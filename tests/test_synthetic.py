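"""Ground-truth round trips of the synthetic generators."""

import numpy as np
import pytest

import glycocover as gc
from glycocover.errors import GenerationError
from glycocover.synthetic import (
    TOY_PLANTED_OCCLUSION,
    ShieldScenario,
    TitrationScenario,
    gen_shielded_replicas,
    gen_shielded_trajectory,
    gen_titration_peaks,
)


def glycan_coverage(sysm):
    series = gc.min_distance_per_residue(sysm, "entity receptor", "entity glycan_*")
    return gc.contact_fraction(series)


class TestShieldedTrajectory:
    def test_zero_occlusion_gives_zero_coverage(self):
        scn = ShieldScenario(seed=1, n_frames=50, planted_occlusion={},
                             binding_schedule=[])
        sysm, _ = gen_shielded_trajectory(scn)
        cov = glycan_coverage(sysm)
        np.testing.assert_array_equal(cov.coverage, 0.0)

    def test_planted_half_recovered_exactly(self):
        scn = ShieldScenario(seed=2, n_frames=400, planted_occlusion={25: 0.5},
                             binding_schedule=[])
        sysm, truth = gen_shielded_trajectory(scn)
        cov = glycan_coverage(sysm).as_dict()
        assert cov[25] == 0.5  # exact by frame-count construction
        assert truth.planted_occlusion.set_index("residue_id").loc[25, "n_contact_frames"] == 200

    def test_all_toy_fractions_recovered_exactly(self):
        scn = ShieldScenario(seed=3, n_frames=200, binding_schedule=[])
        sysm, _ = gen_shielded_trajectory(scn)
        cov = glycan_coverage(sysm).as_dict()
        for rid, p in TOY_PLANTED_OCCLUSION.items():
            assert cov[rid] == round(p * 200) / 200
        spurious = [r for r, c in cov.items() if c > 0 and r not in TOY_PLANTED_OCCLUSION]
        assert spurious == []

    def test_scripted_episodes_become_events(self):
        scn = ShieldScenario(seed=4, n_frames=500,
                             binding_schedule=[(2.0, 10.0), (20.0, 26.0), (35.0, 49.0)])
        sysm, truth = gen_shielded_trajectory(scn)
        evs = gc.binding_events(sysm, "entity ligand_HA6_1", "entity receptor")
        assert len(evs) == 3
        np.testing.assert_allclose([e.duration_ns for e in evs],
                                   truth.schedule["duration_ns"], atol=1e-9)

    def test_seed_reproducibility_contract(self):
        scn = ShieldScenario(seed=5, n_frames=30, binding_schedule=[])
        s1, _ = gen_shielded_trajectory(scn)
        s2, _ = gen_shielded_trajectory(ShieldScenario(seed=5, n_frames=30,
                                                       binding_schedule=[]))
        np.testing.assert_array_equal(s1.frames, s2.frames)  # bit-identical
        s3, _ = gen_shielded_trajectory(ShieldScenario(seed=6, n_frames=30,
                                                       binding_schedule=[]))
        assert not np.array_equal(s1.frames, s3.frames)

    def test_replicas_identical_planted_coverage(self):
        scn = ShieldScenario(seed=7, n_frames=100, binding_schedule=[])
        systems, _ = gen_shielded_replicas(scn, 3)
        covs = [glycan_coverage(s).coverage for s in systems]
        np.testing.assert_array_equal(covs[0], covs[1])
        np.testing.assert_array_equal(covs[0], covs[2])
        # but the frame subsets differ between replicas
        assert not np.array_equal(systems[0].frames, systems[1].frames)

    def test_infeasible_scenarios_rejected(self):
        with pytest.raises(GenerationError, match="beads"):
            ShieldScenario(
                seed=1,
                glycans=[gc.GlycanChainSpec(25, n_beads=2)],
                planted_occlusion={r: 0.5 for r in range(20, 30)},
            ).validate()
        with pytest.raises(GenerationError, match="outside"):
            ShieldScenario(seed=1, n_frames=10,
                           binding_schedule=[(0.0, 99.0)]).validate()
        with pytest.raises(GenerationError, match="outside receptor"):
            ShieldScenario(seed=1, planted_occlusion={5000: 0.5}).validate()

    def test_generated_files_parse_independently(self, tmp_path):
        """io_model reload plus an independent reader (mdtraj) both accept the files."""
        mdtraj = pytest.importorskip("mdtraj")
        import yaml

        scn = ShieldScenario(seed=8, n_frames=15, binding_schedule=[])
        sysm, _ = gen_shielded_trajectory(scn, tmp_path)
        emap = yaml.safe_load((tmp_path / "entity_map.yaml").read_text())
        ours = gc.load_trajectory(
            tmp_path / "toy.xtc",
            gc.load_structure(tmp_path / "toy.gro", entity_map=emap),
            replace=True,
        )
        theirs = mdtraj.load(str(tmp_path / "toy.xtc"), top=str(tmp_path / "toy.gro"))
        assert theirs.n_atoms == sysm.n_atoms
        assert theirs.n_frames == scn.n_frames
        np.testing.assert_allclose(theirs.xyz[0], ours.frames[0], atol=1e-3)

    def test_scenario_yaml_round_trip(self, tmp_path):
        import yaml

        spec = {
            "seed": 9, "n_frames": 40,
            "planted_occlusion": {"41": 0.25},
            "binding_schedule": [[0.5, 2.0]],
            "glycans": [{"attachment_residue": 25, "n_beads": 4}],
        }
        p = tmp_path / "scn.yaml"
        p.write_text(yaml.safe_dump(spec))
        scn = ShieldScenario.from_yaml(p)
        assert scn.planted_occlusion == {41: 0.25}
        sysm, _ = gen_shielded_trajectory(scn)
        assert glycan_coverage(sysm).as_dict()[41] == 0.25

    def test_yaml_without_seed_rejected(self, tmp_path):
        import yaml

        p = tmp_path / "scn.yaml"
        p.write_text(yaml.safe_dump({"n_frames": 10}))
        with pytest.raises(GenerationError, match="seed"):
            gc.ShieldScenario.from_yaml(p)


class TestTitrationPeaks:
    def test_zero_noise_instant_recovery(self):
        scn = TitrationScenario(
            residues=list(range(20, 40)),
            planted_categories={25: "instant_shift"},
            perturbations={25: (0.1, 0.5)},
            doubled=[], noise_sigma=0.0, seed=1,
        )
        lists, truth = gen_titration_peaks(scn)
        df = gc.classify_titration([lists["free"], lists["1:1"], lists["2:1"],
                                    lists["3:1"]])
        assert df.set_index("residue_id").loc[25, "category"] == "instant_shift"
        prof = gc.minimal_csp_profile(lists["free"], lists["1:1"])
        i = int(np.nonzero(prof.residue_ids == 25)[0][0])
        assert prof.csp_assigned[i] == pytest.approx(0.14142135, abs=1e-7)

    def test_all_unperturbed(self):
        scn = TitrationScenario(residues=list(range(20, 30)),
                                planted_categories={}, doubled=[], seed=2)
        lists, _ = gen_titration_peaks(scn)
        prof = gc.minimal_csp_profile(lists["free"], lists["3:1"])
        np.testing.assert_allclose(prof.csp, 0.0, atol=1e-12)
        df = gc.classify_titration(list(lists.values()))
        assert (df["category"] == "unperturbed").all()

    def test_full_planted_category_recovery_at_zero_noise(self):
        scn = TitrationScenario(seed=3, noise_sigma=0.0)
        lists, truth = gen_titration_peaks(scn)
        df = gc.classify_titration(list(lists.values()))
        merged = df.merge(truth, on="residue_id", suffixes=("_got", "_want"))
        assert (merged["category_got"] == merged["category_want"]).all()
        assert (merged["doubled_got"] == merged["doubled_want"]).all()

    def test_seed_contract(self):
        a, _ = gen_titration_peaks(TitrationScenario(seed=4, noise_sigma=0.002))
        b, _ = gen_titration_peaks(TitrationScenario(seed=4, noise_sigma=0.002))
        c, _ = gen_titration_peaks(TitrationScenario(seed=5, noise_sigma=0.002))
        np.testing.assert_array_equal(a["free"].dH, b["free"].dH)
        assert not np.array_equal(a["free"].dH, c["free"].dH)

    def test_peaklist_tsv_round_trip(self, tmp_path):
        from glycocover.tabular import write_tsv

        lists, _ = gen_titration_peaks(TitrationScenario(seed=6))
        p = tmp_path / "free.tsv"
        write_tsv(lists["free"].to_dataframe(), p)
        back = gc.PeakList.read(p, "free")
        np.testing.assert_array_equal(back.residue_ids, lists["free"].residue_ids)
        np.testing.assert_allclose(back.dH, lists["free"].dH)
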