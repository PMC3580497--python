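"""Synthetic-data generators: plates, libraries, acute readouts."""

import numpy as np
import pytest
from rdkit import Chem

from algscreen import acute, fitness, simulate
from algscreen.simulate import (
    LibrarySimConfig,
    PlateSimConfig,
    assign_mechanisms,
    expected_growth_ratio,
    generate_library,
    simulate_acute,
    simulate_plate,
    simulate_screen,
)


class TestPlateSimulation:
    def test_no_effect_compounds_score_exactly_one(self):
        cfg = PlateSimConfig(noise_sd=0.0, inhibition={f"c{i}": 1.0 for i in range(10)})
        layout, series = simulate_plate(cfg)
        ratios = fitness.score_plate(layout, series)
        assert all(r == pytest.approx(1.0, abs=1e-12) for r in ratios.values())

    def test_full_inhibition_scores_zero(self):
        cfg = PlateSimConfig(noise_sd=0.0, inhibition={"dead": 0.0})
        layout, series = simulate_plate(cfg)
        assert fitness.score_plate(layout, series)["dead"] == pytest.approx(0.0)

    def test_closed_form_recovery_noise_free(self):
        # fine sampling keeps the trapezoid discretization error below the
        # closed-form comparison tolerance
        phis = {"a": 0.25, "b": 0.5, "c": 0.75, "d": 0.9}
        cfg = PlateSimConfig(noise_sd=0.0, interval=0.02, inhibition=phis)
        layout, series = simulate_plate(cfg)
        ratios = fitness.score_plate(layout, series)
        for cid, phi in phis.items():
            assert ratios[cid] == pytest.approx(expected_growth_ratio(phi, cfg), abs=1e-6)

    def test_noisy_triplicates_recover_target_ratio(self):
        cfg = PlateSimConfig(noise_sd=0.005, inhibition={"x": 0.5}, n_replicates=3, seed=42)
        plates = simulate_screen(cfg)
        assert len(plates) == 3
        per_rep = [fitness.score_plate(l, s)["x"] for l, s in plates]
        target = expected_growth_ratio(0.5, cfg)
        assert abs(np.mean(per_rep) - target) < 0.1

    def test_bit_identical_under_fixed_seed(self):
        cfg = PlateSimConfig(inhibition={"a": 0.3, "b": 0.8}, seed=5)
        _, s1 = simulate_plate(cfg)
        _, s2 = simulate_plate(cfg)
        for x, y in zip(s1, s2):
            assert np.array_equal(x.od, y.od)

    def test_replicates_differ_but_seeds_reproduce(self):
        cfg = PlateSimConfig(inhibition={"a": 0.5}, n_replicates=2, seed=5)
        plates = simulate_screen(cfg)
        a = next(s for l, s in plates if l.plate_id == "sim-r1p1")
        b = next(s for l, s in plates if l.plate_id == "sim-r2p1")
        assert not np.array_equal(a[0].od, b[0].od)  # replicate noise differs
        again = simulate_screen(cfg)
        for (l1, s1), (l2, s2) in zip(plates, again):
            assert l1.wells == l2.wells
            for x, y in zip(s1, s2):
                assert np.array_equal(x.od, y.od)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PlateSimConfig(geometry=48)
        with pytest.raises(ValueError):
            PlateSimConfig(inhibition={"a": 1.5})
        with pytest.raises(ValueError):
            PlateSimConfig(noise_sd=-0.1)

    def test_campaign_splits_across_plates(self):
        cfg = PlateSimConfig(
            noise_sd=0.0,
            inhibition={f"c{i:03d}": 1.0 for i in range(100)},  # > 88-well capacity
            n_replicates=1,
        )
        plates = simulate_screen(cfg)
        assert len(plates) == 2
        compounds = {
            layout.wells[w].compound_id for layout, _ in plates for w in layout.compound_wells()
        }
        assert len(compounds) == 100


class TestLibraryGeneration:
    def test_all_smiles_valid_and_ids_unique(self):
        lib = generate_library(LibrarySimConfig(n_compounds=300, seed=1))
        assert len(lib.records) == 300
        ids = [r.compound_id for r in lib.records]
        assert len(set(ids)) == 300
        assert all(Chem.MolFromSmiles(r.smiles) is not None for r in lib.records)

    def test_null_library_labels_independent_of_structure(self):
        lib = generate_library(LibrarySimConfig(n_compounds=500, p0=0.3, p1=0.3, seed=2))
        planted = np.array(lib.has_pharmacophore)
        y = np.array(lib.labels)
        # rates in the two structural arms differ only by sampling noise
        r1, r0 = y[planted].mean(), y[~planted].mean()
        se = np.sqrt(0.3 * 0.7 * (1 / planted.sum() + 1 / (~planted).sum()))
        assert abs(r1 - r0) < 4 * se

    def test_deterministic_sar_extremes(self):
        lib = generate_library(LibrarySimConfig(n_compounds=200, p0=0.0, p1=1.0, seed=3))
        assert lib.labels == lib.has_pharmacophore

    def test_realized_hit_rate_matches_expectation(self):
        # defaults: prevalence 0.3, p1 0.8, p0 0.1 -> expected rate 0.31
        lib = generate_library(LibrarySimConfig(n_compounds=2000, seed=4))
        rate = np.mean(lib.labels)
        sd = np.sqrt(0.31 * 0.69 / 2000)
        assert abs(rate - 0.31) < 3 * sd

    def test_seed_reproducibility(self):
        a = generate_library(LibrarySimConfig(n_compounds=100, seed=9))
        b = generate_library(LibrarySimConfig(n_compounds=100, seed=9))
        assert [r.smiles for r in a.records] == [r.smiles for r in b.records]
        assert a.labels == b.labels

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            LibrarySimConfig(p0=0.5, p1=0.2)
        with pytest.raises(ValueError):
            LibrarySimConfig(pharmacophores=("not_a_molecule",))


class TestAcuteSimulation:
    def test_general_mechanism_gives_no_acute_hits(self):
        mech = {f"c{i}": frozenset({simulate.MECH_GENERAL}) for i in range(30)}
        readouts, control = simulate_acute(mech, seed=1)
        calls = acute.call_phenotypes(readouts, control_fluorescence_mean=control)
        s = acute.summarize_acute(calls)
        assert s.n_unique_acute == 0

    def test_planted_counts_reproduce_overlap_accounting(self):
        ids = [f"c{i:03d}" for i in range(600)]
        mech = assign_mechanisms(
            ids, n_motility=144, n_photosynthesis=350, n_dual=18, n_sign_reversed=38, seed=0
        )
        readouts, control = simulate_acute(mech, seed=0)
        calls = acute.call_phenotypes(readouts, control_fluorescence_mean=control)
        s = acute.summarize_acute(calls)
        assert (s.n_motility, s.n_photosynthesis, s.n_both) == (144, 350, 18)
        assert s.n_unique_acute == 476

    def test_sign_reversed_count_planted(self):
        ids = [f"c{i}" for i in range(50)]
        mech = assign_mechanisms(ids, 20, 10, 0, n_sign_reversed=8, seed=1)
        readouts, control = simulate_acute(mech, seed=1)
        calls = acute.call_phenotypes(readouts, control_fluorescence_mean=control)
        n_rev = sum(c.motility_class == acute.SIGN_REVERSED for c in calls)
        assert n_rev == 8

    def test_zero_cytocidal_fraction_means_no_cytocidal_calls(self):
        from algscreen.fitness import FitnessResult

        ids = [f"c{i}" for i in range(20)]
        mech = assign_mechanisms(ids, 5, 5, 0, seed=2)
        inhibited = {cid: True for cid in ids}
        readouts, control = simulate_acute(
            mech, seed=2, growth_inhibited=inhibited, cytocidal_fraction=0.0
        )
        fit = {cid: FitnessResult(cid, 0.3, None, 3, True) for cid in ids}
        calls = acute.call_phenotypes(readouts, control, fitness=fit)
        assert all(c.cytotoxicity == acute.CYTOSTATIC for c in calls)

    def test_mechanism_assignment_validation(self):
        with pytest.raises(ValueError):
            assign_mechanisms(["a"], 5, 5, 0)
        with pytest.raises(ValueError):
            assign_mechanisms(["a", "b"], 1, 1, 2)
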