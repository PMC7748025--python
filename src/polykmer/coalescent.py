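"""Allele-partition distributions at a k-mer block under infinite alleles.

A k-mer block is treated as a non-recombining locus carried by ``m``
genome copies.  Under the infinite-alleles model every mutation creates
a novel allele, so the copies group into an *allele partition* of ``m``
(e.g. 2/2 = two pairs of identical copies).  Three sampling schemes are
covered:

* diploid — two copies from one panmictic population,
* autotetraploid — four copies from one panmictic population,
* allotetraploid — two copies from each of two populations that split
  ``T`` coalescent time units (2·N_e generations) ago, with no later
  gene flow and equal, constant population sizes (the ancestral
  population included).

Panmictic samples follow the Ewens sampling formula with block-scaled
mutation rate θ.  The structured 2+2 distribution is obtained exactly by
tracking the coalescent-with-killing through the isolated phase
``[0, T]`` (per-pair coalescence rate 1, per-lineage mutation/killing
rate θ/2, demes independent) and applying the Ewens partition (EPPF) to
the lineages that survive to the merge at ``T``.  An independent
time-explicit Monte-Carlo oracle for these formulas lives in
:mod:`polykmer.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "BlockParams",
    "PartitionDistribution",
    "integer_partitions",
    "panmictic_partition_probs",
    "structured_partition_probs",
    "class_multiplicities",
    "block_to_site",
    "site_to_block",
    "pair_identity_within",
    "pair_identity_between",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class BlockParams:
    """Population-genetic parameters of one k-mer block.

    theta
        Population-scaled mutation rate per block (2·N_e·μ_block),
        dimensionless, >= 0.
    T
        Split time between the two sub-genome source populations in
        units of 2·N_e generations; only meaningful for the
        allotetraploid scheme.
    k
        k-mer length (used when converting block-level probabilities to
        per-nucleotide rates).
    """

    theta: float
    T: float = 0.0
    k: int = 21

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class PartitionDistribution:
    """Probability distribution over integer partitions of ``m`` copies."""

    m: int
    probs: dict[tuple[int, ...], float]

    def __post_init__(self) -> None:
        total = 0.0
        for part, p in self.probs.items():
            if sum(part) != self.m:
                raise ValueError(f"partition {part} does not sum to m={self.m}")
            if not -_SUM_TOL <= p <= 1 + _SUM_TOL:
                raise ValueError(f"probability {p} for {part} out of [0, 1]")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"partition probabilities sum to {total}, not 1")

    def __getitem__(self, part: Iterable[int]) -> float:
        return self.probs.get(canonical(part), 0.0)

    @property
    def support(self) -> list[tuple[int, ...]]:
        return sorted(self.probs, key=lambda t: (-len(t), t))

    def as_array(self) -> np.ndarray:
        """Probabilities ordered as :func:`integer_partitions` of m."""
        return np.array([self.probs.get(p, 0.0)
                         for p in integer_partitions(self.m)])

    def monomorphic(self) -> float:
        """Probability all m copies carry the same allele."""
        return self.probs.get((self.m,), 0.0)


def canonical(part: Iterable[int]) -> tuple[int, ...]:
    """Canonical (descending) form of an allele partition."""
    return tuple(sorted((int(x) for x in part), reverse=True))


@lru_cache(maxsize=None)
def integer_partitions(m: int) -> tuple[tuple[int, ...], ...]:
    """All integer partitions of m in canonical descending order."""

    def gen(n: int, cap: int) -> Iterator[tuple[int, ...]]:
        if n == 0:
            yield ()
            return
        for first in range(min(n, cap), 0, -1):
            for rest in gen(n - first, first):
                yield (first,) + rest

    return tuple(gen(m, m))


def _esf_prob(part: tuple[int, ...], theta: float) -> float:
    """Ewens sampling formula probability of one allele partition.

    P(a) = n!/θ_(n) · Π_j θ^{a_j} / (j^{a_j} a_j!) with θ_(n) the rising
    factorial.  Evaluated in a θ→0-safe form: the single-block partition
    carries no θ factor once one power is cancelled against θ_(n).
    """
    n = sum(part)
    a: dict[int, int] = {}
    for j in part:
        a[j] = a.get(j, 0) + 1
    n_blocks = len(part)
    # θ^{n_blocks} / θ_(n) = θ^{n_blocks - 1} / Π_{l=1}^{n-1}(l + θ)
    denom = 1.0
    for l in range(1, n):
        denom *= l + theta
    value = theta ** (n_blocks - 1) / denom * math.factorial(n)
    for j, aj in a.items():
        value /= (j ** aj) * math.factorial(aj)
    return value


def panmictic_partition_probs(n: int, theta: float) -> PartitionDistribution:
    """Ewens sampling formula over allele partitions of an n-sample.

    For n=2: P({2}) = 1/(1+θ), P({1,1}) = θ/(1+θ).
    """
    if n not in (2, 4):
        raise ValueError("panmictic model supports n in {2, 4}")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    probs = {p: _esf_prob(p, theta) for p in integer_partitions(n)}
    return PartitionDistribution(m=n, probs=probs)


# --- structured 2+2 sample ------------------------------------------------

def _deme_phase_probs(theta: float, T: float) -> dict[str, float]:
    """State distribution of one deme's two lineages at the split time T.

    Backward in time each deme starts with two sample lineages;
    coalescence occurs at rate 1, mutation kills a lineage at rate θ/2
    (its carried samples then form one finished allele class).  States:

    ==  =======================  =================
    A   surviving {1},{1}        nothing finished
    B   surviving {2}            nothing finished
    C   surviving {1}            finished {1}
    D   none surviving           finished {2}
    E   none surviving           finished {1},{1}
    ==  =======================  =================
    """
    lam = 1.0 + theta
    pA = math.exp(-lam * T)
    # A→B (rate 1) then survive B's killing (rate θ/2) until T
    r = 1.0 + theta / 2.0
    pB = math.exp(-theta * T / 2.0) * (-math.expm1(-r * T)) / r
    pC = theta * pB  # A→C at rate θ, same survival kernel afterwards
    # total probability of having left A via coalescence is (1-pA)/(1+θ)
    pD = -math.expm1(-lam * T) / lam - pB
    pD = max(pD, 0.0)
    pE = theta * pD
    return {"A": pA, "B": pB, "C": pC, "D": pD, "E": pE}


# surviving lineage block sizes / finished allele-class sizes per state
_DEME_STATES: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    "A": ((1, 1), ()),
    "B": ((2,), ()),
    "C": ((1,), (1,)),
    "D": ((), (2,)),
    "E": ((), (1, 1)),
}


def _set_partitions(items: tuple[int, ...]) -> Iterator[list[list[int]]]:
    """All set partitions of ``items`` (by position)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield [[first]] + part


def _ewens_grouping(block_sizes: tuple[int, ...], theta: float
                    ) -> Iterator[tuple[tuple[int, ...], float]]:
    """Ewens (EPPF) random grouping of surviving lineage blocks.

    After the demes merge, the surviving lineages are exchangeable units
    of a panmictic coalescent-with-killing, so the set partition of the
    ``i`` lineages into allele classes has EPPF weight
    θ^{K-1} Π_cells (|cell|-1)! / Π_{l=1}^{i-1}(l+θ).  Each cell's
    allele-class size is the sum of the sample counts its lineages
    carry.  Yields ``(class_sizes, probability)`` pairs.
    """
    i = len(block_sizes)
    if i == 0:
        yield (), 1.0
        return
    denom = 1.0
    for l in range(1, i):
        denom *= l + theta
    for grouping in _set_partitions(tuple(range(i))):
        k_cells = len(grouping)
        w = theta ** (k_cells - 1) / denom
        sizes = []
        for cell in grouping:
            w *= math.factorial(len(cell) - 1)
            sizes.append(sum(block_sizes[j] for j in cell))
        yield tuple(sizes), w


def structured_partition_probs(params: BlockParams) -> PartitionDistribution:
    """Allele-partition distribution for a 2+2 sample from a split pair.

    Exact for two populations of equal constant size that separated
    ``T`` coalescent units ago with no later gene flow, ancestral
    population of the same size.  Continuous in T: at T=0 it equals
    ``panmictic_partition_probs(4, θ)``; at θ=0 it is a point mass on
    {4} for any T.
    """
    theta, T = params.theta, params.T
    deme = _deme_phase_probs(theta, T)
    probs: dict[tuple[int, ...], float] = {p: 0.0 for p in integer_partitions(4)}
    for sA, pA in deme.items():
        if pA == 0.0:
            continue
        survA, doneA = _DEME_STATES[sA]
        for sB, pB in deme.items():
            if pB == 0.0:
                continue
            survB, doneB = _DEME_STATES[sB]
            joint = pA * pB
            surviving = survA + survB
            finished = doneA + doneB
            for merged, w in _ewens_grouping(surviving, theta):
                part = canonical(finished + merged)
                probs[part] += joint * w
    total = sum(probs.values())
    probs = {p: v / total for p, v in probs.items()}  # strip float residue
    return PartitionDistribution(m=4, probs=probs)


def class_multiplicities(dist: PartitionDistribution) -> np.ndarray:
    """Expected allele-class counts E[a_j], j = 1..m.

    ``E[a_j]`` is the expected number of allele classes carried by
    exactly j of the m copies; conservation Σ_j j·E[a_j] = m holds
    exactly.  Returned as an array indexed ``[j-1]``.
    """
    ea = np.zeros(dist.m)
    for part, p in dist.probs.items():
        for j in part:
            ea[j - 1] += p
    return ea


# --- block <-> per-nucleotide conversions ---------------------------------

def block_to_site(identity: float, k: int) -> float:
    """Per-nucleotide difference rate from a block identity probability.

    With independent sites, a k-mer block is identical iff all k sites
    are, so d_site = 1 - I^(1/k).
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError("block identity must be in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - identity ** (1.0 / k)


def site_to_block(d_site: float, k: int) -> float:
    """Block identity probability from a per-nucleotide difference rate."""
    if not 0.0 <= d_site <= 1.0:
        raise ValueError("per-site rate must be in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return (1.0 - d_site) ** k


def pair_identity_within(theta: float) -> float:
    """Block identity probability of two copies from one population."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return 1.0 / (1.0 + theta)


def pair_identity_between(theta: float, T: float) -> float:
    """Block identity of two copies drawn from the two diverged demes.

    Both lineages must escape mutation through the isolated phase
    (probability e^{-θT}) and then coalesce mutation-free in the
    ancestral population (probability 1/(1+θ)); includes ancestral
    polymorphism, i.e. this is total, not net, divergence.
    """
    if theta < 0 or T < 0:
        raise ValueError("theta and T must be >= 0")
    return math.exp(-theta * T) / (1.0 + theta)
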