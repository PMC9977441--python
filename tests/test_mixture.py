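"""EM mixture fitting, segment state calling, and PGA arithmetic."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylcna as m


def _seg_table(means, lengths=None, chrom="chr1", sample_id="s1"):
    means = np.asarray(means, float)
    n = len(means)
    if lengths is None:
        lengths = np.full(n, 1000, dtype=np.int64)
    bounds = np.r_[0, np.cumsum(lengths)]
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": chrom,
            "start": bounds[:-1],
            "end": bounds[1:],
            "n_bins": 1,
            "seg_mean": means,
        }
    )


class TestFitMixture:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        truth_mu = np.array([-0.5, 0.0, 0.5])
        truth_pi = np.array([0.1, 0.8, 0.1])
        states = rng.choice(3, size=10_000, p=truth_pi)
        x = rng.normal(truth_mu[states], 0.08)
        fit = m.fit_mixture(_seg_table(x), weighting="none", seed=0)
        assert fit.converged and not fit.degenerate
        assert np.abs(fit.means - truth_mu).max() < 0.02
        assert np.abs(fit.weights - truth_pi).max() < 0.02

    def test_loglik_monotone(self):
        rng = np.random.default_rng(1)
        x = np.r_[rng.normal(-0.6, 0.1, 300), rng.normal(0, 0.1, 800),
                  rng.normal(0.6, 0.1, 300)]
        fit = m.fit_mixture(_seg_table(x), weighting="none", seed=1)
        assert (np.diff(fit.log_likelihood) >= -1e-7).all()

    def test_degenerate_constant_input(self):
        fit = m.fit_mixture(_seg_table(np.zeros(100)), weighting="none", seed=0)
        assert fit.degenerate

    def test_two_point_symmetric_extremes(self):
        x = np.r_[np.full(200, -1.0), np.full(200, 1.0)]
        fit = m.fit_mixture(_seg_table(x), weighting="none", seed=0)
        assert fit.means[0] == pytest.approx(-1.0, abs=0.05)
        assert fit.means[2] == pytest.approx(1.0, abs=0.05)
        assert fit.weights[1] < 0.05

    def test_requires_enough_segments(self):
        with pytest.raises(ValueError, match="30"):
            m.fit_mixture(_seg_table(np.zeros(10)))

    def test_sign_flip_swaps_labels(self, small_cohort):
        segs = small_cohort.segments
        flipped = segs.assign(seg_mean=-segs["seg_mean"])
        fit = m.fit_mixture(segs, seed=7)
        fit_f = m.fit_mixture(flipped, seed=7)
        genome = m.GenomeModel.toy()
        pga = m.compute_pga(m.call_segments(segs, fit), genome).set_index("sample_id")
        pga_f = m.compute_pga(m.call_segments(flipped, fit_f), genome).set_index("sample_id")
        assert np.allclose(pga["pga_gain"], pga_f.loc[pga.index, "pga_loss"])
        assert np.allclose(pga["pga_loss"], pga_f.loc[pga.index, "pga_gain"])


class TestCallSegments:
    @pytest.fixture()
    def fit(self):
        return m.MixtureFit(
            weights=np.array([0.2, 0.6, 0.2]),
            means=np.array([-0.5, 0.0, 0.5]),
            sds=np.array([0.1, 0.1, 0.1]),
            log_likelihood=np.array([0.0]),
            converged=True,
        )

    def test_at_component_mean(self, fit):
        calls = m.call_segments(_seg_table([0.0]), fit)
        assert calls["state"].iloc[0] == "neutral"
        assert calls["p_neutral"].iloc[0] > calls["p_gain"].iloc[0]

    def test_equidistant_tie_broken_to_neutral(self):
        fit = m.MixtureFit(
            weights=np.array([1 / 3, 1 / 3, 1 / 3]),
            means=np.array([-0.5, 0.0, 0.5]),
            sds=np.array([0.1, 0.1, 0.1]),
            log_likelihood=np.array([0.0]),
            converged=True,
        )
        calls = m.call_segments(_seg_table([0.25]), fit)
        assert calls["state"].iloc[0] == "neutral"

    def test_matches_weighted_density_oracle(self, fit):
        rng = np.random.default_rng(2)
        x = rng.uniform(-1, 1, 500)
        calls = m.call_segments(_seg_table(x), fit)
        dens = fit.weights * np.exp(
            stats.norm.logpdf(x[:, None], fit.means, fit.sds)
        )
        oracle = np.array(["loss", "neutral", "gain"])[dens.argmax(axis=1)]
        assert (calls["state"].astype(str).values == oracle).all()

    def test_posteriors_sum_to_one(self, fit):
        calls = m.call_segments(_seg_table(np.linspace(-2, 2, 50)), fit)
        total = calls[["p_loss", "p_neutral", "p_gain"]].sum(axis=1)
        assert np.allclose(total, 1.0)


class TestComputePGA:
    def _calls(self, states, lengths, sample_id="s1"):
        tab = _seg_table(np.zeros(len(states)), lengths=lengths, sample_id=sample_id)
        tab["state"] = pd.Categorical(states, categories=["loss", "neutral", "gain"])
        return tab

    def test_single_gain_segment(self):
        genome = m.GenomeModel(("chr1",), (1_000_000,))
        calls = self._calls(["gain", "neutral"], [100_000, 900_000])
        pga = m.compute_pga(calls, genome)
        assert pga["pga_total"].iloc[0] == pytest.approx(10.0)
        assert pga["pga_gain"].iloc[0] == pytest.approx(10.0)
        assert pga["pga_loss"].iloc[0] == 0.0
        assert not pga["excluded"].iloc[0]

    def test_no_altered_segments_excluded(self):
        genome = m.GenomeModel(("chr1",), (1_000_000,))
        pga = m.compute_pga(self._calls(["neutral", "neutral"], [500_000, 500_000]), genome)
        assert pga["pga_total"].iloc[0] == 0.0
        assert pga["excluded"].iloc[0]

    def test_matches_hand_tally_multichromosome(self):
        genome = m.GenomeModel(("chr1", "chr2"), (1_000_000, 2_000_000))
        c1 = self._calls(["gain", "loss", "neutral"], [100_000, 200_000, 700_000])
        c2 = self._calls(["loss", "neutral"], [300_000, 1_700_000])
        c2["chrom"] = "chr2"
        calls = pd.concat([c1, c2], ignore_index=True)
        pga = m.compute_pga(calls, genome)
        g = 3_000_000
        assert pga["pga_gain"].iloc[0] == pytest.approx(100_000 / g * 100)
        assert pga["pga_loss"].iloc[0] == pytest.approx(500_000 / g * 100)
        assert pga["pga_total"].iloc[0] == pytest.approx(600_000 / g * 100)
        assert pga["n_altered_segments"].iloc[0] == 3

    def test_out_of_bounds_segment_rejected(self):
        genome = m.GenomeModel(("chr1",), (100,))
        with pytest.raises(ValueError):
            m.compute_pga(self._calls(["gain"], [200]), genome)


def test_pipeline_pga_recovers_planted_truth(small_cohort, small_fit, toy_genome):
    calls = m.call_segments(small_cohort.segments, small_fit)
    pga = m.compute_pga(calls, toy_genome).set_index("sample_id")
    truth = small_cohort.truth.samples.query("cohort == 'tumor'").set_index("sample_id")
    err = (pga["pga_total"] - truth.loc[pga.index, "true_pga"]).abs()
    assert err.mean() < 1.0
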