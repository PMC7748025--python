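"""Expected k-mer spectra from a generative coalescent + coverage model.

An individual's single-copy genome is ``G`` independent k-mer blocks.
At each block the ``m`` genome copies group into allele classes (see
:mod:`polykmer.coalescent`); an allele class carried by ``j`` copies is
sequenced at roughly ``j`` times the per-copy depth ``c``, so the
spectrum is a mixture of peaks at 1×..m× coverage whose masses are
``G · E[a_j]``.  Peak widths are over-dispersed relative to Poisson by a
bias factor ``b`` (variance = b · mean; negative binomial, b = 1 being
the Poisson limit).  Depth-zero draws are unobservable, so each peak is
renormalised over d >= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .coalescent import (
    BlockParams,
    PartitionDistribution,
    block_to_site,
    class_multiplicities,
    pair_identity_between,
    pair_identity_within,
    panmictic_partition_probs,
    site_to_block,
    structured_partition_probs,
)

__all__ = [
    "MODEL_KINDS",
    "ModelParams",
    "partition_distribution",
    "peak_shape",
    "expected_spectrum",
    "expected_class_masses",
    "derived_stats",
    "calibrate_theta_T",
]

MODEL_KINDS = ("diploid", "autotetraploid", "allotetraploid")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of one generative spectrum model.

    model
        One of ``diploid``, ``autotetraploid``, ``allotetraploid``.
    c
        Per-copy (1×) sequencing depth, > 0.
    G
        Haploid single-copy genome size in k-mer blocks, > 0 (one block
        is roughly one base of single-copy sequence).
    b
        Peak-width bias: depth variance is ``b`` times the mean; b >= 1,
        b = 1 is the Poisson limit.
    theta
        Population-scaled mutation rate per block.
    T
        Sub-genome split time (coalescent units); ignored unless
        ``model == "allotetraploid"``.
    k
        k-mer length.
    """

    model: str
    c: float
    G: float
    b: float = 1.0
    theta: float = 0.0
    T: float = 0.0
    k: int = 21

    def __post_init__(self) -> None:
        if self.model not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model!r}")
        if self.c <= 0:
            raise ValueError("per-copy depth c must be > 0")
        if self.G <= 0:
            raise ValueError("genome size G must be > 0")
        if self.b < 1:
            raise ValueError("bias b must be >= 1")
        if self.theta < 0 or self.T < 0:
            raise ValueError("theta and T must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def m(self) -> int:
        """Number of genome copies."""
        return 2 if self.model == "diploid" else 4

    @property
    def block(self) -> BlockParams:
        return BlockParams(theta=self.theta, T=self.T, k=self.k)


def partition_distribution(params: ModelParams) -> PartitionDistribution:
    """Allele-partition distribution implied by the model kind."""
    if params.model == "allotetraploid":
        return structured_partition_probs(params.block)
    return panmictic_partition_probs(params.m, params.theta)


def peak_shape(d, j: int, c: float, b: float) -> np.ndarray:
    """Depth distribution of a j-copy allele class, truncated at d >= 1.

    Negative binomial with mean j·c and variance b·j·c (Poisson when
    b = 1), renormalised over d >= 1 because depth-zero k-mers are never
    observed.
    """
    if j < 1:
        raise ValueError("copy-number class j must be >= 1")
    if c <= 0:
        raise ValueError("per-copy depth c must be > 0")
    if b < 1:
        raise ValueError("bias b must be >= 1")
    d = np.asarray(d)
    mu = j * c
    if b == 1.0:
        pmf = stats.poisson.pmf(d, mu)
        p0 = stats.poisson.pmf(0, mu)
    else:
        r = mu / (b - 1.0)
        p = 1.0 / b
        pmf = stats.nbinom.pmf(d, r, p)
        p0 = stats.nbinom.pmf(0, r, p)
    out = np.where(d >= 1, pmf, 0.0) / (1.0 - p0)
    return out


def peak_p0(j: int, c: float, b: float) -> float:
    """Probability a j-copy class is sequenced to depth zero (unseen)."""
    mu = j * c
    if b == 1.0:
        return math.exp(-mu)
    return float(stats.nbinom.pmf(0, mu / (b - 1.0), 1.0 / b))


def expected_class_masses(params: ModelParams) -> np.ndarray:
    """Expected number of distinct k-mers per copy-number class, G·E[a_j]."""
    ea = class_multiplicities(partition_distribution(params))
    return params.G * ea


def expected_spectrum(params: ModelParams, bins) -> np.ndarray:
    """Expected distinct-k-mer count per depth bin.

    ``E[n_d] = G · Σ_j E[a_j] · peak_shape(d, j, c, b)``; summed over
    all d >= 1 this totals ``G · Σ_j E[a_j]`` distinct k-mers.
    """
    bins = np.asarray(bins)
    if np.any(bins < 1):
        raise ValueError("depth bins start at 1")
    masses = expected_class_masses(params)
    out = np.zeros(bins.shape, dtype=float)
    for j, mass in enumerate(masses, start=1):
        if mass > 0:
            out += mass * peak_shape(bins, j, params.c, params.b)
    return out


def derived_stats(params: ModelParams) -> dict[str, float]:
    """Per-nucleotide summary statistics implied by the block model.

    heterozygosity_pct
        100 × per-site difference rate of two copies from one
        population (one sub-genome for the allotetraploid).
    subgenome_divergence_pct  (allotetraploid only)
        100 × per-site difference rate between copies from the two
        sub-genomes — total divergence, ancestral polymorphism
        included.  The within/ancestral contribution is
        ``heterozygosity_pct``, reported alongside.
    genome_size_mb
        Haploid single-copy genome size in megabases.
    """
    het = block_to_site(pair_identity_within(params.theta), params.k)
    out = {
        "heterozygosity_pct": 100.0 * het,
        "genome_size_mb": params.G * 1e-6,
        "theta_per_site": params.theta / params.k,
    }
    if params.model == "allotetraploid":
        div = block_to_site(
            pair_identity_between(params.theta, params.T), params.k)
        out["subgenome_divergence_pct"] = 100.0 * div
        out["ancestral_component_pct"] = out["heterozygosity_pct"]
    return out


def calibrate_theta_T(heterozygosity_pct: float, divergence_pct: float | None,
                      k: int = 21) -> tuple[float, float]:
    """Invert the per-nucleotide statistics to block-level (θ, T).

    Solves ``1/(1+θ) = (1-h)^k`` for θ and, when a divergence target is
    given, ``e^{-θT}/(1+θ) = (1-d)^k`` for T.  The divergence must
    exceed the heterozygosity (total divergence includes the ancestral
    within-population component), and T is undefined at θ = 0.
    """
    h = heterozygosity_pct / 100.0
    if not 0 <= h < 1:
        raise ValueError("heterozygosity_pct must be in [0, 100)")
    theta = 1.0 / site_to_block(h, k) - 1.0
    if divergence_pct is None:
        return theta, 0.0
    d = divergence_pct / 100.0
    identity_x = site_to_block(d, k)
    target = identity_x * (1.0 + theta)
    if target > 1.0 + 1e-12:
        raise ValueError("divergence must be >= heterozygosity")
    if theta == 0.0:
        raise ValueError("T is undefined at theta = 0; need heterozygosity > 0")
    T = -math.log(min(target, 1.0)) / theta
    return theta, T


def with_params(params: ModelParams, **updates) -> ModelParams:
    """Copy ``params`` with some fields replaced."""
    return replace(params, **updates)
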