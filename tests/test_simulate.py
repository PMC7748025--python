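"""Forward simulator and Monte-Carlo coalescent oracle."""

import numpy as np
import pytest

from polykmer.coalescent import (
    BlockParams,
    PartitionDistribution,
    integer_partitions,
    panmictic_partition_probs,
    structured_partition_probs,
)
from polykmer.model import ModelParams, expected_spectrum
from polykmer.simulate import (
    SimulationConfig,
    chisq_consistency,
    simulate_partitions_mc,
    simulate_spectrum,
)


def test_simulation_reproducible_under_seed(allo_params):
    cfg = SimulationConfig(params=allo_params, n_loci=50_000, seed=9,
                           error_kmers_per_locus=0.2)
    a = simulate_spectrum(cfg)
    b = simulate_spectrum(cfg)
    np.testing.assert_array_equal(a.counts, b.counts)
    c = simulate_spectrum(SimulationConfig(params=allo_params,
                                           n_loci=50_000, seed=10,
                                           error_kmers_per_locus=0.2))
    assert not np.array_equal(a.counts, c.counts)


def test_monomorphic_diploid_single_peak():
    params = ModelParams(model="diploid", c=20.0, G=1e5, b=1.0, theta=0.0)
    spec = simulate_spectrum(SimulationConfig(params=params, n_loci=100_000,
                                              seed=3))
    # every locus yields one 2x-coverage k-mer; depth-zero loss is ~e^-40
    assert spec.total == pytest.approx(100_000, abs=3)
    assert spec.depths[np.argmax(spec.counts)] == pytest.approx(40, abs=2)


def test_simulator_matches_expected_spectrum(allo_params):
    """Per-bin agreement with the analytic expectation at 10^6 loci:
    fewer than 1% of informative bins outside 4 sigma."""
    from dataclasses import replace

    spec = simulate_spectrum(SimulationConfig(params=allo_params,
                                              n_loci=1_000_000, seed=5))
    params = replace(allo_params, G=1_000_000.0)
    bins = spec.depths
    exp = expected_spectrum(params, bins)
    informative = exp >= 10
    z = (spec.counts[informative] - exp[informative]) / np.sqrt(
        exp[informative])
    assert np.mean(np.abs(z) > 4) < 0.01


def test_split_time_inflates_doubleton_peak(allo_params):
    theta = allo_params.theta
    masses = []
    for T in (0.0, allo_params.T):
        params = ModelParams(model="allotetraploid", c=30.0, G=1e6, b=2.0,
                             theta=theta, T=T)
        spec = simulate_spectrum(SimulationConfig(params=params,
                                                  n_loci=1_000_000, seed=8))
        lo, hi = int(1.5 * 30), int(2.5 * 30)  # 2x peak region
        masses.append(spec.counts[lo - 1:hi].sum())
    assert masses[1] > masses[0]


def test_error_noise_adds_low_multiplicity_kmers(allo_params):
    clean = simulate_spectrum(SimulationConfig(params=allo_params,
                                               n_loci=100_000, seed=6))
    noisy = simulate_spectrum(SimulationConfig(params=allo_params,
                                               n_loci=100_000, seed=6,
                                               error_kmers_per_locus=0.5))
    assert noisy.counts[0] > clean.counts[0] + 10_000


def test_mc_oracle_pairwise(diploid_params):
    emp, se = simulate_partitions_mc("diploid", BlockParams(theta=1.0),
                                     100_000, seed=13)
    assert abs(emp[(1, 1)] - 0.5) < 3 * se[(1, 1)]


def test_mc_oracle_monomorphic_without_mutation():
    emp, _ = simulate_partitions_mc("allotetraploid",
                                    BlockParams(theta=0.0, T=3.0),
                                    10_000, seed=1)
    assert emp[(4,)] == 1.0


def test_mc_oracle_structured_continuity():
    """At T=0 the structured sample is panmictic: the empirical 2+2
    partition frequencies match the four-sample Ewens formula."""
    emp, se = simulate_partitions_mc("allotetraploid",
                                     BlockParams(theta=1.0, T=0.0),
                                     200_000, seed=17)
    ana = panmictic_partition_probs(4, 1.0)
    for part in integer_partitions(4):
        assert abs(emp[part] - ana[part]) < 3 * max(se[part], 1e-6)


def test_mc_oracle_reproducible():
    a, _ = simulate_partitions_mc("autotetraploid", BlockParams(theta=0.5),
                                  20_000, seed=2)
    b, _ = simulate_partitions_mc("autotetraploid", BlockParams(theta=0.5),
                                  20_000, seed=2)
    assert a.probs == b.probs


def test_chisq_consistency():
    ana = structured_partition_probs(BlockParams(theta=0.5, T=1.0))
    gof = chisq_consistency(ana, ana, 10**6)
    assert gof["statistic"] == pytest.approx(0.0, abs=1e-9)
    assert gof["pvalue"] == pytest.approx(1.0)
    # grossly wrong model: swap the monomorphic and doubleton masses
    swapped = dict(ana.probs)
    swapped[(4,)], swapped[(2, 2)] = swapped[(2, 2)], swapped[(4,)]
    wrong = PartitionDistribution(m=4, probs=swapped)
    gof = chisq_consistency(ana, wrong, 10**6)
    assert gof["pvalue"] < 1e-6


def test_chisq_support_mismatch():
    a = panmictic_partition_probs(2, 0.5)
    b = panmictic_partition_probs(4, 0.5)
    with pytest.raises(ValueError, match="support"):
        chisq_consistency(a, b, 1000)


def test_config_validation(allo_params):
    with pytest.raises(ValueError):
        SimulationConfig(params=allo_params, n_loci=0)
    with pytest.raises(ValueError):
        SimulationConfig(params=allo_params, n_loci=10,
                         error_kmers_per_locus=-1.0)
    with pytest.raises(ValueError):
        simulate_partitions_mc("diploid", BlockParams(theta=1.0), 0)
    with pytest.raises(ValueError):
        simulate_partitions_mc("triploid", BlockParams(theta=1.0), 10)
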