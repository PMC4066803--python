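"""The synthetic-trace generator: condition tables, Bell-Evans rupture
statistics, dataset determinism and the FPP folding law."""

import numpy as np
import pytest

from quadpop.simulate import (
    EULER_GAMMA,
    ProtocolSpec,
    SpeciesSpec,
    bell_evans_mode,
    construct_sequences,
    draw_species,
    fold_probability,
    make_condition,
    sample_rupture_force,
    simulate_fpp_series,
    simulate_fx_dataset,
)
from quadpop.wlc import WLCParams

KT = WLCParams().thermal_energy


class TestConditions:
    def test_transcription_prevalences(self):
        cond = make_condition("transcription")
        assert cond.prevalence["none"] == pytest.approx(0.573)
        assert cond.prevalence["2G-HQ"] == pytest.approx(0.173)
        assert cond.prevalence["3G-HQ"] == pytest.approx(0.094)
        assert cond.prevalence["GT"] == pytest.approx(0.038)
        assert cond.prevalence["GQ"] == pytest.approx(0.122)

    def test_deaza_lacks_hybrid_species(self):
        cond = make_condition("deaza")
        assert "2G-HQ" not in cond.prevalence
        assert cond.prevalence["GQ"] == pytest.approx(0.259)
        assert cond.prevalence["GT"] == pytest.approx(0.081)

    @pytest.mark.parametrize(
        "name", ["transcription", "deaza", "no_transcription", "lithium", "mutant", "spacer"]
    )
    def test_prevalences_normalized(self, name):
        assert sum(make_condition(name).prevalence.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_condition(self):
        with pytest.raises(ValueError, match="unknown condition"):
            make_condition("heat")

    def test_species_frequencies_match_prevalence(self):
        cond = make_condition("transcription")
        rng = np.random.default_rng(8)
        n = 100_000
        names = draw_species(cond, n, rng)
        for sp, p in cond.prevalence.items():
            freq = float(np.mean(names == sp))
            assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestBellEvans:
    def test_empirical_mode_matches_closed_form(self):
        sp = make_condition("transcription").species("2G-HQ")
        rng = np.random.default_rng(5)
        f = sample_rupture_force(sp, 5.5, rng, size=100_000)
        mode_cf = bell_evans_mode(5.5, sp.barrier_distance, sp.intrinsic_rate)
        hist, edges = np.histogram(f, bins=np.arange(20.0, 45.0, 0.2))
        mode_emp = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert abs(mode_emp - mode_cf) < 0.5

    @pytest.mark.parametrize(
        "species,target", [("2G-HQ", 31.0), ("GQ", 25.0), ("GT", 25.0)]
    )
    def test_calibrated_means(self, species, target):
        sp = make_condition("transcription").species(species)
        rng = np.random.default_rng(3)
        f = sample_rupture_force(sp, 5.5, rng, size=10_000)
        assert float(np.mean(f)) == pytest.approx(target, abs=0.5)

    def test_mean_sits_gamma_below_mode(self):
        sp = make_condition("transcription").species("GQ")
        mode = bell_evans_mode(5.5, sp.barrier_distance, sp.intrinsic_rate)
        rng = np.random.default_rng(9)
        f = sample_rupture_force(sp, 5.5, rng, size=200_000)
        assert float(np.mean(f)) == pytest.approx(
            mode - EULER_GAMMA * KT / sp.barrier_distance, abs=0.05
        )

    def test_loading_rate_validated(self):
        sp = make_condition("transcription").species("GQ")
        with pytest.raises(ValueError):
            sample_rupture_force(sp, 0.0, np.random.default_rng(0))


class TestFxDatasets:
    def test_cycle_counts(self):
        cond = make_condition("transcription")
        assert simulate_fx_dataset(cond, n_curves=1, seed=1).n_curves == 1
        with pytest.raises(ValueError):
            simulate_fx_dataset(cond, n_curves=0, seed=1)

    def test_mutant_rarely_folds(self):
        ts = simulate_fx_dataset(make_condition("mutant"), n_curves=200, seed=2)
        assert (ts.manifest.species != "none").mean() <= 0.05

    def test_lithium_folded_fraction(self):
        ts = simulate_fx_dataset(make_condition("lithium"), n_curves=10_000, seed=2)
        assert (ts.manifest.species != "none").mean() == pytest.approx(0.067, abs=0.01)

    def test_same_seed_byte_identical(self, tmp_path):
        cond = make_condition("transcription")
        paths = []
        for i in range(2):
            ts = simulate_fx_dataset(cond, n_curves=5, seed=42)
            p = tmp_path / f"run{i}.tsv"
            ts.to_tsv(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_different_seed_differs(self):
        cond = make_condition("transcription")
        a = simulate_fx_dataset(cond, n_curves=50, seed=1).manifest
        b = simulate_fx_dataset(cond, n_curves=50, seed=2).manifest
        assert not a.equals(b)

    def test_trace_schema(self):
        ts = simulate_fx_dataset(make_condition("deaza"), n_curves=2, seed=3)
        frame = ts.to_frame()
        assert list(frame.columns) == [
            "time_s", "force_pN", "extension_nm", "cycle_id", "phase",
        ]
        for _, grp in frame.groupby("cycle_id"):
            assert np.all(np.diff(grp["time_s"]) > 0)
            assert set(grp["phase"]) <= {"stretch", "relax"}


class TestFpp:
    def test_zero_incubation_never_folded(self):
        cond = make_condition("transcription")
        for sp in cond.prevalence:
            if sp != "none":
                assert fold_probability(cond, sp, 0.0) == 0.0

    def test_long_incubation_saturates_to_prevalence(self):
        cond = make_condition("transcription")
        assert fold_probability(cond, "2G-HQ", 5.0) == pytest.approx(
            cond.prevalence["2G-HQ"], rel=1e-6
        )

    def test_one_tau_incubation(self):
        """At t = tau the generator law gives (1 - 1/e) of steady state,
        and the simulated manifest agrees within binomial error."""
        cond = make_condition("transcription")
        tau = cond.species("2G-HQ").fold_tau
        expected = cond.prevalence["2G-HQ"] * (1 - np.exp(-1))
        assert fold_probability(cond, "2G-HQ", tau) == pytest.approx(expected, rel=1e-9)
        ts = simulate_fpp_series(cond, [tau], n_cycles=2000, seed=6)
        frac = (ts.manifest.species == "2G-HQ").mean()
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / 2000)

    def test_gq_reaches_steady_state_within_deadtime(self):
        # with RNA present the DNA quadruplex folds faster than the 20 ms
        # force-jump dead time
        cond = make_condition("transcription")
        assert cond.species("GQ").fold_tau < 0.02

    def test_input_validation(self):
        cond = make_condition("transcription")
        with pytest.raises(ValueError):
            simulate_fpp_series(cond, [], n_cycles=10, seed=1)
        with pytest.raises(ValueError):
            simulate_fpp_series(cond, [-0.1], n_cycles=10, seed=1)

    def test_protocol_invariants(self):
        with pytest.raises(ValueError):
            ProtocolSpec(probe_start=50.0)  # probe above the jump force


def test_bundled_construct_sequences():
    seqs = construct_sequences()
    assert seqs["g_core"] == "GGGGA" * 4
    assert "GGGG" not in seqs["mutant"]
    assert "ATTTTA" in seqs["spacer"]


def test_species_spec_validation():
    with pytest.raises(ValueError):
        SpeciesSpec("none", 1.0, 0.0, 1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        SpeciesSpec("GQ", 6.0, -0.1, 1.0, 1.0, 1.0)
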