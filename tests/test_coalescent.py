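"""Closed-form allele-partition distributions and conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polykmer.coalescent import (
    BlockParams,
    PartitionDistribution,
    block_to_site,
    class_multiplicities,
    integer_partitions,
    pair_identity_between,
    pair_identity_within,
    panmictic_partition_probs,
    site_to_block,
    structured_partition_probs,
)

THETAS = [0.0, 0.01, 0.1, 0.5, 1.0, 3.0]
TIMES = [0.0, 0.5, 2.0, 10.0]


def test_pairwise_closed_forms():
    # P({2}) = 1/(1+θ) is the classic pairwise identity
    d = panmictic_partition_probs(2, 1.0)
    assert d[(2,)] == pytest.approx(0.5)
    assert d[(1, 1)] == pytest.approx(0.5)
    d0 = panmictic_partition_probs(2, 0.0)
    assert d0[(2,)] == 1.0


def test_quadruplet_monomorphism():
    # P(all four identical) = prod_{i=1..3} i/(i+θ)
    for theta in THETAS:
        d = panmictic_partition_probs(4, theta)
        expected = math.prod(i / (i + theta) for i in (1, 2, 3))
        assert d[(4,)] == pytest.approx(expected, rel=1e-12)
    assert panmictic_partition_probs(4, 1.0)[(4,)] == pytest.approx(0.25)


def test_esf_against_hoppe_urn_enumeration():
    """ESF must match an independent forward Hoppe-urn recursion.

    The urn adds copies one at a time: copy i+1 starts a new allele
    with probability θ/(i+θ), otherwise duplicates a uniformly chosen
    existing copy.  Exhaustive recursion over these choices is an
    independent route to the same partition law.
    """

    def urn(n, theta):
        probs = {(1,): 1.0}
        for i in range(1, n):
            nxt = {}
            for part, p in probs.items():
                new = tuple(sorted(part + (1,), reverse=True))
                nxt[new] = nxt.get(new, 0.0) + p * theta / (i + theta)
                for idx, size in enumerate(part):
                    grown = list(part)
                    grown[idx] = size + 1
                    grown = tuple(sorted(grown, reverse=True))
                    w = p * size / (i + theta)
                    nxt[grown] = nxt.get(grown, 0.0) + w
            probs = nxt
        return probs

    for theta in [0.01, 0.3, 1.0, 2.5]:
        expected = urn(4, theta)
        got = panmictic_partition_probs(4, theta)
        for part in integer_partitions(4):
            assert got[part] == pytest.approx(expected.get(part, 0.0),
                                              abs=1e-12)


@settings(deadline=None, derandomize=True)
@given(st.floats(0.0, 10.0), st.floats(0.0, 50.0))
def test_partition_distributions_normalised(theta, T):
    for dist in (panmictic_partition_probs(2, theta),
                 panmictic_partition_probs(4, theta),
                 structured_partition_probs(BlockParams(theta=theta, T=T))):
        assert abs(sum(dist.probs.values()) - 1.0) < 1e-12
        assert all(p >= 0 for p in dist.probs.values())
        ea = class_multiplicities(dist)
        assert np.dot(np.arange(1, dist.m + 1), ea) == pytest.approx(
            dist.m, abs=1e-12)


def test_structured_reduces_to_panmictic_at_split():
    for theta in THETAS:
        s = structured_partition_probs(BlockParams(theta=theta, T=0.0))
        p = panmictic_partition_probs(4, theta)
        for part in integer_partitions(4):
            assert abs(s[part] - p[part]) <= 1e-9


def test_structured_monomorphic_without_mutation():
    for T in TIMES + [50.0]:
        s = structured_partition_probs(BlockParams(theta=0.0, T=T))
        assert s[(4,)] == pytest.approx(1.0, abs=1e-12)


def test_structured_deep_split_limit():
    # each sub-genome pair independently monomorphic; cross identity -> 0
    for theta in [0.5, 1.0]:
        s = structured_partition_probs(BlockParams(theta=theta, T=50.0))
        assert s[(2, 2)] == pytest.approx((1 / (1 + theta)) ** 2, abs=1e-6)


def test_doubleton_mass_monotone_in_split_time():
    for theta in [0.05, 0.5, 1.0]:
        masses = [structured_partition_probs(
            BlockParams(theta=theta, T=T))[(2, 2)]
            for T in np.linspace(0.0, 10.0, 21)]
        assert np.all(np.diff(masses) > 0)


def test_monomorphism_strictly_decreasing_in_theta():
    for T in TIMES:
        monos = [structured_partition_probs(
            BlockParams(theta=th, T=T)).monomorphic()
            for th in [0.0, 0.01, 0.1, 0.5, 1.0, 2.0]]
        assert np.all(np.diff(monos) < 0)
    monos = [panmictic_partition_probs(4, th).monomorphic()
             for th in [0.0, 0.01, 0.1, 0.5, 1.0, 2.0]]
    assert np.all(np.diff(monos) < 0)


def test_class_multiplicity_point_masses():
    d22 = PartitionDistribution(m=4, probs={(2, 2): 1.0})
    assert class_multiplicities(d22).tolist() == [0.0, 2.0, 0.0, 0.0]
    d4 = PartitionDistribution(m=4, probs={(4,): 1.0})
    assert class_multiplicities(d4).tolist() == [0.0, 0.0, 0.0, 1.0]


def test_block_site_conversion():
    assert block_to_site(1.0, 21) == 0.0
    assert site_to_block(0.05, 21) == pytest.approx(0.3406, abs=2e-4)
    for d in [0.0, 0.002, 0.05, 0.3]:
        assert block_to_site(site_to_block(d, 21), 21) == pytest.approx(
            d, abs=1e-12)
    with pytest.raises(ValueError):
        block_to_site(1.5, 21)


def test_pair_identities():
    assert pair_identity_within(1.0) == 0.5
    assert pair_identity_between(0.5, 0.0) == pair_identity_within(0.5)
    # between-deme identity decays with split time
    vals = [pair_identity_between(0.5, T) for T in TIMES]
    assert np.all(np.diff(vals) < 0)


def test_parameter_validation():
    with pytest.raises(ValueError):
        panmictic_partition_probs(3, 1.0)
    with pytest.raises(ValueError):
        panmictic_partition_probs(2, -0.1)
    with pytest.raises(ValueError):
        BlockParams(theta=-1.0)
    with pytest.raises(ValueError):
        BlockParams(theta=0.1, T=-2.0)
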