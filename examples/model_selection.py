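"""Rank ploidy models on simulated spectra.

Simulates one spectrum per model kind at matched diversity and asks the
model-selection routine (shared fit window, small-sample-corrected
information criterion) to identify the generating model.
"""

from polykmer import (ModelParams, SimulationConfig, calibrate_theta_T,
                      select_model, simulate_spectrum)

theta, T = calibrate_theta_T(heterozygosity_pct=0.2, divergence_pct=5.0)

for kind in ("diploid", "autotetraploid", "allotetraploid"):
    params = ModelParams(model=kind, c=30.0, G=1_000_000, b=2.0,
                         theta=theta,
                         T=T if kind == "allotetraploid" else 0.0, k=21)
    spectrum = simulate_spectrum(SimulationConfig(params=params,
                                                  n_loci=1_000_000, seed=3))
    ranked = select_model(spectrum)
    print(f"simulated {kind}:")
    for rank, fit in enumerate(ranked, start=1):
        print(f"  {rank}. {fit.params.model:<15} AICc={fit.aicc:,.1f}")
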