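import numpy as np
import pytest

from msapdiv import (
    MarkerType,
    SynthConfig,
    expected_state_fractions,
    extract_epigenotypes,
    pair_replicates,
    read_marker_matrix,
    simulate_dataset,
    write_marker_matrix,
)

TINY = dict(n_genera=1, individuals_per_population=8, n_aflp_loci=40, n_msap_epiloci=30)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = simulate_dataset(SynthConfig(seed=9, **TINY))
        b = simulate_dataset(SynthConfig(seed=9, **TINY))
        for name in a:
            assert a[name].aflp.equals(b[name].aflp)
            assert a[name].msap.hpa.equals(b[name].msap.hpa)
            assert a[name].msap.msp.equals(b[name].msap.msp)

    def test_different_seed_differs(self):
        a = simulate_dataset(SynthConfig(seed=9, **TINY))
        b = simulate_dataset(SynthConfig(seed=10, **TINY))
        assert not np.array_equal(
            a["genus01_restricted"].aflp.values, b["genus01_restricted"].aflp.values
        )


class TestStructure:
    def test_design_dimensions(self):
        cfg = SynthConfig(seed=1, n_genera=3, replicate_fraction=0.0)
        data = simulate_dataset(cfg)
        assert len(data) == 6  # one restricted + one widespread per genus
        ds = data["genus02_widespread"]
        assert ds.aflp.n_samples == 75  # 3 pops x 25
        assert ds.aflp.n_loci == 300
        assert ds.msap.n_epiloci == 250
        assert len(set(ds.aflp.populations)) == 3

    def test_output_passes_marker_io_validation(self, tmp_path):
        data = simulate_dataset(SynthConfig(seed=3, replicate_fraction=0.2, **TINY))
        ds = data["genus01_widespread"]
        path = tmp_path / "aflp.csv"
        write_marker_matrix(ds.aflp, path)
        back = read_marker_matrix(path, MarkerType.AFLP)
        assert back.equals(ds.aflp)
        assert pair_replicates(back)  # replicate links valid and present

    def test_impossible_config_rejected(self):
        with pytest.raises(ValueError, match="replicate_fraction"):
            SynthConfig(seed=0, replicate_fraction=1.5).validate()
        with pytest.raises(ValueError, match="individuals"):
            SynthConfig(seed=0, individuals_per_population=1).validate()


class TestStateModel:
    def test_forced_unmethylated_state_gives_all_present_profiles(self):
        cfg = SynthConfig(
            seed=4,
            state_dirichlet=(1e6, 1e-6, 1e-6, 1e-6),
            scoring_error=0.0,
            **TINY,
        )
        data = simulate_dataset(cfg)
        ds = data["genus01_restricted"]
        assert ds.msap.hpa.values.all()
        assert ds.msap.msp.values.all()
        with pytest.raises(ValueError, match="no polymorphic"):
            extract_epigenotypes(ds.msap)

    def test_symmetric_dirichlet_expected_quarter_each(self):
        cfg = SynthConfig(seed=0, state_dirichlet=(1.0, 1.0, 1.0, 1.0), scoring_error=0.0)
        assert np.allclose(expected_state_fractions(cfg), 0.25)

    def test_expected_fractions_include_scoring_noise_channel(self):
        cfg = SynthConfig(seed=0, state_dirichlet=(1e6, 1e-6, 1e-6, 1e-6), scoring_error=0.1)
        frac = expected_state_fractions(cfg)
        # true pair (1,1); independent flips at 0.1 per bit
        assert frac == pytest.approx([0.81, 0.09, 0.09, 0.01], abs=1e-6)

    def test_empirical_state_tallies_match_expectation(self):
        cfg = SynthConfig(
            seed=15,
            n_genera=2,
            individuals_per_population=25,
            n_aflp_loci=10,
            n_msap_epiloci=300,
            replicate_fraction=0.0,
            state_species_concentration=1e6,
            state_pop_concentration=1e6,
        )
        data = simulate_dataset(cfg)
        hpa = np.vstack([d.msap.hpa.values for d in data.values()])
        msp = np.vstack([d.msap.msp.values for d in data.values()])
        pair = hpa * 2 + msp  # 3=(1,1), 2=(1,0), 1=(0,1), 0=(0,0)
        observed = np.array([(pair == c).mean() for c in (3, 2, 1, 0)])
        expected = expected_state_fractions(cfg)
        # cells within an epilocus share its Dirichlet draw, so the
        # effective sample size is the number of independent epilocus draws
        n_draws = cfg.n_msap_epiloci * cfg.n_genera
        se = np.sqrt(expected * (1 - expected) / n_draws)
        assert np.all(np.abs(observed - expected) < 4 * se)


class TestScoringNoise:
    def test_replicate_mismatch_rate_two_eps_one_minus_eps(self):
        """Original and replicate are independent noisy reads of the same
        truth, so per-locus mismatch probability is 2e(1-e)."""
        eps = 0.02
        cfg = SynthConfig(
            seed=77,
            n_genera=1,
            individuals_per_population=10,
            n_aflp_loci=2000,
            n_msap_epiloci=10,
            replicate_fraction=0.3,
            scoring_error=eps,
        )
        data = simulate_dataset(cfg)
        mism = trials = 0
        for ds in data.values():
            m = ds.aflp
            idx = {s.individual_id: i for i, s in enumerate(m.samples)}
            for orig, rep in pair_replicates(m):
                mism += (m.values[idx[orig]] != m.values[idx[rep]]).sum()
                trials += m.n_loci
        expected = 2 * eps * (1 - eps)
        se = np.sqrt(expected * (1 - expected) / trials)
        assert abs(mism / trials - expected) < 4 * se

    def test_zero_error_replicates_identical(self):
        cfg = SynthConfig(seed=6, replicate_fraction=0.25, scoring_error=0.0, **TINY)
        data = simulate_dataset(cfg)
        m = data["genus01_restricted"].aflp
        idx = {s.individual_id: i for i, s in enumerate(m.samples)}
        for orig, rep in pair_replicates(m):
            assert np.array_equal(m.values[idx[orig]], m.values[idx[rep]])
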