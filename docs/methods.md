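# Methods

## Generative model

A single-copy haploid genome is idealised as `G` independent k-mer
blocks, each a non-recombining locus with no overlap between adjacent
k-mers. An individual carries `m` genome copies (diploid m=2,
tetraploid m=4). At one block, the copies group into an allele
partition of `m` under the infinite-alleles model: every mutation
creates a novel allele, so two copies are identical iff no mutation
falls on the genealogical path between them.

Three sampling schemes map ploidy and origin onto a coalescent:

* **diploid** — 2 copies from one panmictic population;
* **autotetraploid** — 4 copies from one panmictic population (polysomic
  inheritance makes the four copies exchangeable samples);
* **allotetraploid** — 2 copies from each of two populations that split
  `T` coalescent units (2·N_e generations) ago with no later gene flow.

Panmictic partitions follow the Ewens sampling formula (ESF) with block
mutation rate θ = 2·N_e·μ_block. For the structured 2+2 sample the
distribution is computed exactly in two stages:

1. **Isolated phase, [0, T] backward.** Within each deme the two
   lineages coalesce at rate 1 and are killed by mutation at rate θ/2
   each (killing representation of infinite alleles: the first mutation
   above a lineage fixes the allele of the samples it carries). The
   five reachable per-deme states (pairs survive/coalesce/finish) have
   closed-form probabilities from the linear pure-jump process.
2. **Merged phase.** Lineages surviving at T are exchangeable units of
   a panmictic coalescent-with-killing, so their grouping into allele
   classes follows the Ewens partition (EPPF)
   θ^(K−1) Π(|cell|−1)! / Π_{l=1..i−1}(l+θ) for i surviving lineages.

Both demes, the ancestral population and the daughters share one
population size; migration after the split is excluded. These are the
minimal symmetric assumptions consistent with "two diverged
populations", and they are stated here because the estimates inherit
them. The closed forms are verified against two independent oracles: a
time-explicit Monte-Carlo structured coalescent (exponential waiting
times, Poisson branch mutations, pairwise path identity — no killing
construction shared with the analytic route), and msprime with an
infinite-alleles mutation model on one grid point.

Limits worth knowing: at T=0 the structured law reduces to the n=4 ESF;
at θ=0 it is a point mass on the monomorphic partition {4}; as T→∞ the
doubleton mass tends to (1/(1+θ))², each sub-genome pair independently
monomorphic.

## From partitions to spectra

An allele class carried by j copies is sequenced at depth ~ j·c. Depth
is negative binomial with mean j·c and variance b·j·c — the bias b ≥ 1
absorbs library and mapping overdispersion, with b = 1 the Poisson
limit. Depth-zero draws are unobservable; each peak is renormalised
over d ≥ 1 (at c ≥ 15 the correction is ~e^{-c}, negligible, but it
keeps the total-mass identity exact). The expected spectrum is

    E[n_d] = G · Σ_j E[a_j] · peak(d; j·c, b),

so Σ_d E[n_d] = G·Σ_j E[a_j] and the occurrence mass Σ_d d·E[n_d]
equals m·c·G by the conservation Σ_j j·E[a_j] = m.

Not modelled: repetitive k-mers (multiplicity ≫ m·c), sequencing-error
k-mers, contamination, GC bias. Errors and repeats are excluded by the
fit window rather than modelled; see below.

## Per-nucleotide statistics

Block identities convert to per-site rates by the geometric root:
d_site = 1 − I^(1/k) (a linear d ≈ D/k approximation breaks down at the
5%-divergence scale, where it exceeds one). With within-population pair
identity 1/(1+θ) this gives heterozygosity; with cross-deme identity
e^{−θT}/(1+θ) it gives total sub-genome divergence, ancestral
polymorphism included (the within/ancestral component is reported
separately as `ancestral_component_pct`). θ is exposed both per block
and per site (θ/k). `calibrate_theta_T` inverts the two statistics to
(θ, T), which is how study-regime simulations are parameterised.

## Fitting (Autofit)

Weighted least squares on the windowed histogram,
Σ_d (n_d − E[n_d])²/max(n_d, 1), minimised by bounded trust-region
least squares (scipy `trf`, numerical derivatives) with bounds
c ∈ [1, 10⁴], G ∈ [10³, 10¹⁰], b ∈ [1, 50], θ ∈ [0, 10], T ∈ [0, 50].
WLS rather than a Poisson likelihood is deliberate: distinct-k-mer bin
counts are overdispersed and correlated across bins, and WLS matches
the visual-fit semantics of interactive spectrum fitting; the objective
is isolated in one function and swappable.

Initialisation is data-driven: the dominant smoothed peak is read as 2×
coverage for diploids and allotetraploids and 4× for autotetraploids,
with the alternative assignment kept as a second start (a zero-diversity
allotetraploid spectrum is a lone 4× peak, so the allotetraploid fit
also starts from the 4× reading); G starts at (windowed occurrence
mass)/(m·c); b = 2, θ = 0.01, T = 1. Multi-start winners are chosen by
objective with deterministic tie-breaks (smaller T, then smaller θ), so
identical inputs give identical results.

Default window: lower bound at the first local minimum of the 3-bin
median-smoothed spectrum (the error trough; first bin when the spectrum
rises from the start), upper bound at 1.5·m·ĉ to exclude the repetitive
tail. A monotonically decreasing spectrum (pure error tail) raises an
initialisation error pointing to manual mode.

Diagnostics: fits with c below 15× warn that k-mer models are
unreliable at low coverage; allotetraploid fits with θ̂ < 10⁻³ (implied
heterozygosity below 0.005%) flag T as unidentifiable — without
within-population diversity the split time has no effect on the
spectrum, and its fitted value must not be interpreted.

Model selection fits the three kinds on one shared window (trough to
3× the dominant peak) and ranks by AICc computed from the WLS objective
with parameter counts 4/4/5; the small-sample correction matters
because a window holds only ~100–300 bins.

## Synthetic data generator

`simulate_spectrum` draws, per block, an allele partition from the
model's exact partition law, then one depth per allele class from the
matching negative-binomial peak, discarding depth-zero draws. Loci are
independent — matching the fitted model exactly, so recovery
experiments isolate the estimator rather than model misfit. Optional
error k-mers are added with geometric multiplicity (default mean 1.2,
default off), which reproduces the error trough that windowing must
handle without pretending to model sequencing chemistry. What passing
recovery tests therefore show: the estimator inverts spectra whose
structure the model describes. What they cannot show: robustness to
repeat content, contamination, k-mer overlap correlation, or depth
profiles real libraries produce.

Default study conditions used throughout tests and the acceptance
script mirror the regime the method targets: heterozygosity 0.2% and
sub-genome divergence 5% (θ ≈ 0.0429, T ≈ 24.1 at k = 21), per-copy
depth 30×, bias 2, 2×10⁶ single-copy blocks — a deliberately scaled-down
genome (2 Mb vs the ~200 Mb of a typical target species) that keeps a
simulation+fit cycle under two seconds while leaving every peak with
10⁴–10⁶ k-mers, ample for the estimator. The outcrossed-diploid case
uses 1.1% heterozygosity.

## Numerical choices

* Partition distributions are exact rational-in-θ expressions evaluated
  in floating point; normalisation is enforced to strip accumulated
  rounding (residue < 10⁻¹²).
* The θ→0 limits are algebraically safe: EPPF and ESF are coded with
  one θ power cancelled, so no 0/0 arises.
* Monte-Carlo oracle: per-replicate event loop JIT-compiled with numba;
  the legacy per-thread RNG is seeded explicitly per call, making every
  empirical distribution reproducible.
* Spectrum sums "to a far tail" use d ≤ 3000, beyond 10 standard
  deviations of the widest default peak.

## Known limitations

* Hexaploids and higher, unequal sub-genome sizes, and post-split gene
  flow are out of scope; the symmetric two-deme model is the only
  structured option.
* Heterozygosity estimates lean on the 1× peak, which real data often
  buries under error k-mers; expect them to be noisy (the recovery
  tests hold them only to a factor of two at the study regime).
* The bias parameter is a variance inflation shared across peaks; peak
  asymmetries from GC bias or duplicate reads are absorbed, not
  modelled.
* No confidence intervals yet; the identifiability flag is a binary
  guard, not an interval.
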