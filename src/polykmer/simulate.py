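"""Forward simulation of k-mer spectra and a Monte-Carlo coalescent oracle.

Two independent routes live here:

* :func:`simulate_spectrum` draws synthetic spectra *from the generative
  model itself* (partition draw per block, then a depth draw per allele
  class) — used for parameter-recovery experiments where the fitter,
  not the model, is under test.

* :func:`simulate_partitions_mc` is a *time-explicit* structured
  coalescent with Poisson mutations placed on branches; two copies are
  the same allele iff no mutation falls on the path connecting them.
  It never uses the killing/EPPF construction behind the closed forms
  in :mod:`polykmer.coalescent`, so it serves as an independent oracle
  for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .coalescent import (
    BlockParams,
    PartitionDistribution,
    integer_partitions,
)
from .model import ModelParams, partition_distribution
from .spectra import KmerSpectrum

__all__ = [
    "SimulationConfig",
    "simulate_spectrum",
    "simulate_partitions_mc",
    "chisq_consistency",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic spectrum.

    n_loci
        Number of independent k-mer blocks (this plays the role of G).
    error_kmers_per_locus
        Expected number of low-multiplicity noise k-mers per block
        (sequencing-error artefacts); 0 disables noise.
    error_depth_mean
        Mean multiplicity of noise k-mers (geometric on 1, 2, ...).
    seed
        Seed for full reproducibility.
    """

    params: ModelParams
    n_loci: int
    error_kmers_per_locus: float = 0.0
    error_depth_mean: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.error_kmers_per_locus < 0:
            raise ValueError("error_kmers_per_locus must be >= 0")
        if self.error_depth_mean < 1:
            raise ValueError("error_depth_mean must be >= 1")


def _draw_depths(rng: np.random.Generator, n: int, mean: float, b: float
                 ) -> np.ndarray:
    if b == 1.0:
        return rng.poisson(mean, n)
    r = mean / (b - 1.0)
    return rng.negative_binomial(r, 1.0 / b, n)


def simulate_spectrum(config: SimulationConfig) -> KmerSpectrum:
    """Draw a synthetic k-mer spectrum from the generative model.

    Per block: draw an allele partition, then one depth per allele
    class from the class's coverage peak; depth-zero draws are
    discarded (those k-mers are never observed).  Optional noise
    k-mers are added at geometric low multiplicity.
    """
    p = config.params
    rng = np.random.default_rng(config.seed)
    dist = partition_distribution(p)
    parts = list(dist.probs)
    probs = np.array([dist.probs[q] for q in parts])
    n_per_part = rng.multinomial(config.n_loci, probs)
    # total number of depth draws needed per copy-number class j
    draws_per_class = np.zeros(p.m + 1, dtype=np.int64)
    for part, n_part in zip(parts, n_per_part):
        for j in part:
            draws_per_class[j] += n_part
    max_d = 0
    per_class_hist: list[tuple[np.ndarray, np.ndarray]] = []
    for j in range(1, p.m + 1):
        n = int(draws_per_class[j])
        if n == 0:
            continue
        depths = _draw_depths(rng, n, j * p.c, p.b)
        depths = depths[depths > 0]
        if depths.size:
            vals, cnts = np.unique(depths, return_counts=True)
            per_class_hist.append((vals, cnts))
            max_d = max(max_d, int(vals[-1]))
    n_err = rng.poisson(config.error_kmers_per_locus * config.n_loci)
    if n_err > 0:
        err_depths = rng.geometric(1.0 / config.error_depth_mean, n_err)
        vals, cnts = np.unique(err_depths, return_counts=True)
        per_class_hist.append((vals, cnts))
        max_d = max(max_d, int(vals[-1]))
    counts = np.zeros(max_d, dtype=float)
    for vals, cnts in per_class_hist:
        counts[vals - 1] += cnts
    return KmerSpectrum(counts=counts, d_min=1, k=p.k,
                        label=f"simulated:{p.model}")


# --- time-explicit Monte-Carlo coalescent oracle --------------------------

@njit(cache=False)
def _mc_partitions(n_samples: int, structured: bool, theta: float, T: float,
                   n_reps: int, seed: int) -> np.ndarray:  # pragma: no cover
    """Count allele partitions over replicate coalescent simulations.

    Lineages carry sample bitmasks; a mutation on a lineage marks every
    (inside, outside) sample pair as different.  Coalescence merges
    masks; demes (first half vs second half of the samples) cannot
    coalesce before time T when ``structured``.  Partition index is the
    position in the canonical integer-partition list for n_samples.
    """
    np.random.seed(seed)
    n_partitions = 5 if n_samples == 4 else 2
    counts = np.zeros(n_partitions, dtype=np.int64)
    masks = np.zeros(n_samples, dtype=np.int64)
    demes = np.zeros(n_samples, dtype=np.int64)
    diff = np.zeros((n_samples, n_samples), dtype=np.bool_)
    for _ in range(n_reps):
        n_lin = n_samples
        for i in range(n_samples):
            masks[i] = 1 << i
            demes[i] = 0 if (not structured or i < n_samples // 2) else 1
        diff[:, :] = False
        t = 0.0
        merged = not structured
        while n_lin > 1:
            n_pairs = 0
            for i in range(n_lin):
                for j in range(i + 1, n_lin):
                    if merged or demes[i] == demes[j]:
                        n_pairs += 1
            mut_rate = n_lin * theta / 2.0
            total = n_pairs + mut_rate
            if total <= 0.0:
                t = T
                merged = True
                continue
            dt = np.random.exponential(1.0 / total)
            if (not merged) and (t + dt > T):
                t = T
                merged = True
                continue
            t = t + dt
            if np.random.random() < mut_rate / total:
                li = np.random.randint(0, n_lin)
                m = masks[li]
                for i in range(n_samples):
                    for j in range(n_samples):
                        if ((m >> i) & 1) != ((m >> j) & 1):
                            diff[i, j] = True
            else:
                target = np.random.randint(0, n_pairs)
                seen = 0
                ai = -1
                bj = -1
                for i in range(n_lin):
                    if ai >= 0:
                        break
                    for j in range(i + 1, n_lin):
                        if merged or demes[i] == demes[j]:
                            if seen == target:
                                ai = i
                                bj = j
                                break
                            seen += 1
                masks[ai] = masks[ai] | masks[bj]
                masks[bj] = masks[n_lin - 1]
                demes[bj] = demes[n_lin - 1]
                n_lin -= 1
        # allele classes: same type iff never separated by a mutation
        assigned = np.zeros(n_samples, dtype=np.bool_)
        sizes = np.zeros(n_samples, dtype=np.int64)
        n_classes = 0
        for i in range(n_samples):
            if assigned[i]:
                continue
            size = 0
            for j in range(n_samples):
                if not assigned[j] and not diff[i, j]:
                    assigned[j] = True
                    size += 1
            sizes[n_classes] = size
            n_classes += 1
        # sort descending (tiny array)
        for a in range(n_classes):
            for bb in range(a + 1, n_classes):
                if sizes[bb] > sizes[a]:
                    tmp = sizes[a]
                    sizes[a] = sizes[bb]
                    sizes[bb] = tmp
        if n_samples == 2:
            idx = 0 if sizes[0] == 2 else 1
        else:
            # canonical order: (4) (3,1) (2,2) (2,1,1) (1,1,1,1)
            if sizes[0] == 4:
                idx = 0
            elif sizes[0] == 3:
                idx = 1
            elif sizes[0] == 2 and sizes[1] == 2:
                idx = 2
            elif sizes[0] == 2:
                idx = 3
            else:
                idx = 4
        counts[idx] += 1
    return counts


def simulate_partitions_mc(model: str, block: BlockParams, n_replicates: int,
                           seed: int = 0) -> tuple[PartitionDistribution,
                                                   dict[tuple[int, ...], float]]:
    """Empirical allele-partition distribution from coalescent replicates.

    Simulates the (structured) coalescent for 2, 4 or 2+2 lineages with
    Poisson mutations on branches under infinite alleles.  Returns the
    empirical distribution and per-partition binomial standard errors.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if model == "diploid":
        n, structured = 2, False
    elif model == "autotetraploid":
        n, structured = 4, False
    elif model == "allotetraploid":
        n, structured = 4, True
    else:
        raise ValueError(f"unknown model kind {model!r}")
    counts = _mc_partitions(n, structured, block.theta, block.T,
                            n_replicates, seed & 0x7FFFFFFF)
    parts = integer_partitions(n)
    freqs = counts / n_replicates
    probs = {p: float(f) for p, f in zip(parts, freqs)}
    se = {p: float(np.sqrt(max(f * (1 - f), 1e-12) / n_replicates))
          for p, f in zip(parts, freqs)}
    return PartitionDistribution(m=n, probs=probs), se


def chisq_consistency(empirical: PartitionDistribution,
                      analytic: PartitionDistribution, n: int,
                      min_expected: float = 5.0) -> dict[str, float]:
    """Chi-square goodness of fit of empirical vs analytic partition
    frequencies from ``n`` replicates.

    Cells with expected count below ``min_expected`` are pooled into
    one to keep the asymptotic reference valid.  Returns the statistic,
    degrees of freedom and upper-tail probability.
    """
    if empirical.m != analytic.m:
        raise ValueError("distributions have different support")
    parts = integer_partitions(empirical.m)
    obs = np.array([empirical.probs.get(p, 0.0) for p in parts]) * n
    exp = np.array([analytic.probs.get(p, 0.0) for p in parts]) * n
    big = exp >= min_expected
    if big.sum() < len(parts):
        obs = np.append(obs[big], obs[~big].sum())
        exp = np.append(exp[big], exp[~big].sum())
    keep = exp > 0
    obs, exp = obs[keep], exp[keep]
    exp = exp * obs.sum() / exp.sum()  # guard float residue
    statistic = float(((obs - exp) ** 2 / exp).sum())
    dof = max(len(obs) - 1, 1)
    pvalue = float(stats.chi2.sf(statistic, dof))
    return {"statistic": statistic, "dof": dof, "pvalue": pvalue}
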