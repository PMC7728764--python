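import numpy as np
import pytest

from isoniche.mixing import (
    ConfoundingError,
    SourceSpec,
    build_predation_scenario,
    fit_mixing_model,
    prey_contribution_probability,
)
from isoniche.standardization import standardize_community, superimpose
from isoniche.synthetic import mixture_scenario
from isoniche.trophic import MCMCConfig

FAST = MCMCConfig(chains=4, iterations=3000, seed=0)


def _sources(sep=12.0):
    return [
        SourceSpec("left", mean=(-sep / 2, 2.0), sd=(0.5, 0.5)),
        SourceSpec("right", mean=(sep / 2, 6.0), sd=(0.5, 0.5)),
    ]


class TestFitMixingModel:
    def test_single_source_gets_full_proportion(self, make_group):
        src = [SourceSpec("only", mean=(-5.0, 3.0), sd=(0.5, 0.5))]
        scen = mixture_scenario((1.0,), src, n_consumers=10, seed=1)
        res = fit_mixing_model(scen.consumer, src, mcmc=FAST)
        assert res.posterior_means[0] == 1.0
        assert np.all(res.proportion_draws == 1.0)

    def test_symmetric_sources_split_evenly_at_midpoint(self, make_group):
        srcs = _sources()
        # consumer pinned at the TDF-corrected midpoint of two mirror sources
        mid = (np.array(srcs[0].mean) + srcs[0].tdf_mean
               + np.array(srcs[1].mean) + srcs[1].tdf_mean) / 2
        rng = np.random.default_rng(2)
        consumer = make_group(mid + rng.normal(0, 0.3, (20, 2)), species="c")
        res = fit_mixing_model(consumer, srcs, mcmc=FAST)
        assert res.posterior_means == pytest.approx([0.5, 0.5], abs=0.05)

    def test_recovers_known_mixture_within_credible_intervals(self):
        scen = mixture_scenario((0.7, 0.3), _sources(), n_consumers=30, seed=3)
        res = fit_mixing_model(
            scen.consumer, list(scen.sources), mcmc=MCMCConfig(chains=4, seed=4)
        )
        for name, true_p in zip(("left", "right"), scen.proportions):
            lo, hi = res.ci95[name]
            assert lo <= true_p <= hi
        assert max(res.rhat.values()) < 1.1

    def test_every_draw_lies_on_the_simplex(self):
        scen = mixture_scenario((0.5, 0.2, 0.3), [
            SourceSpec("a", mean=(-6.0, 1.0), sd=(0.4, 0.4)),
            SourceSpec("b", mean=(0.0, 5.0), sd=(0.4, 0.4)),
            SourceSpec("c", mean=(6.0, 1.0), sd=(0.4, 0.4)),
        ], n_consumers=25, seed=5)
        res = fit_mixing_model(scen.consumer, list(scen.sources), mcmc=FAST)
        assert np.all(res.proportion_draws >= 0)
        np.testing.assert_allclose(res.proportion_draws.sum(axis=1), 1.0, atol=1e-12)

    def test_source_permutation_equivariance_under_same_seed(self):
        scen = mixture_scenario((0.7, 0.3), _sources(), n_consumers=20, seed=6)
        srcs = list(scen.sources)
        res_ab = fit_mixing_model(scen.consumer, srcs, mcmc=FAST)
        res_ba = fit_mixing_model(scen.consumer, srcs[::-1], mcmc=FAST)
        np.testing.assert_array_equal(
            res_ab.proportion_draws, res_ba.proportion_draws[:, ::-1]
        )

    def test_prior_only_recovers_uniform_dirichlet(self):
        srcs = [SourceSpec(n, mean=(0, 0), sd=(1, 1)) for n in "abc"]
        res = fit_mixing_model(
            _dummy_consumer(), srcs,
            mcmc=MCMCConfig(chains=2, iterations=6000, seed=7), prior_only=True,
        )
        assert res.posterior_means == pytest.approx([1 / 3] * 3, abs=0.03)
        # Dirichlet(1,1,1) marginals are Beta(1,2): var = 1/18
        assert res.proportion_draws[:, 0].var() == pytest.approx(1 / 18, rel=0.15)

    def test_identifiability_warning_single_point_many_sources(self, make_group):
        one_pt = make_group([(0.0, 0.0)], species="c")
        srcs = [SourceSpec(n, mean=(0, 0), sd=(1, 1)) for n in "abc"]
        res = fit_mixing_model(one_pt, srcs, mcmc=FAST)
        assert any("identified" in w for w in res.warnings)


@pytest.fixture(scope="module")
def recovery():
    scen = mixture_scenario((0.7, 0.3), _sources(), n_consumers=30, seed=8)
    return fit_mixing_model(scen.consumer, list(scen.sources), mcmc=FAST)


class TestPreyContributionProbability:

    def test_threshold_bounds(self, recovery):
        assert prey_contribution_probability(recovery, "left", 0.0) == 1.0
        assert prey_contribution_probability(recovery, "left", 1.0) == 0.0

    def test_dominant_source_exceeds_half_with_high_probability(self, recovery):
        assert prey_contribution_probability(recovery, "left", 0.5) > 0.95

    def test_unknown_source_rejected(self, recovery):
        with pytest.raises(KeyError):
            prey_contribution_probability(recovery, "nope", 0.5)


@pytest.fixture(scope="module")
def tinca_community(arreo):
    target, donors = arreo
    std = standardize_community(target)
    return superimpose(std, standardize_community(donors["T. tinca"]), "T. tinca")


class TestBuildPredationScenario:

    def test_predator_with_superimposed_prey_is_valid(self, tinca_community):
        consumer, sources = build_predation_scenario(
            tinca_community, "M. salmoides", ["T. tinca", "C. carpio", "P. clarkii"]
        )
        assert consumer.species == "M. salmoides"
        assert [s.name for s in sources] == ["T. tinca", "C. carpio", "P. clarkii"]
        tinca = sources[0]
        xy = tinca_community.group("T. tinca").xy
        assert tinca.mean == pytest.approx(tuple(xy.mean(axis=0)))

    def test_two_superimposed_natives_confound(self, arreo):
        target, donors = arreo
        std = standardize_community(target)
        both = superimpose(
            superimpose(std, standardize_community(donors["T. tinca"]), "T. tinca"),
            standardize_community(donors["Gyrinus sp."]),
            "Gyrinus sp.",
        )
        with pytest.raises(ConfoundingError):
            build_predation_scenario(
                both, "M. salmoides", ["T. tinca", "Gyrinus sp."]
            )

    def test_empty_prey_list_rejected(self, tinca_community):
        with pytest.raises(ValueError):
            build_predation_scenario(tinca_community, "M. salmoides", [])


def _dummy_consumer():
    from isoniche.io import IsotopeSample, SpeciesGroup

    return SpeciesGroup("d", [IsotopeSample("d", "e", "consumer", 0.0, 0.0)] * 2)
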