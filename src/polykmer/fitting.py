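"""Fitting spectrum models to observed k-mer histograms.

``autofit`` estimates (c, G, b, θ[, T]) by bounded weighted least
squares on the windowed histogram, with data-driven initialisation and
multi-start over peak-assignment alternatives; ``manual_curve``
evaluates a user-chosen parameter set for overlay, mirroring the
original app's two modes.  ``select_model`` ranks the three model kinds
by a small-sample-corrected information criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import least_squares

from .model import (
    MODEL_KINDS,
    ModelParams,
    derived_stats,
    expected_spectrum,
)
from .spectra import KmerSpectrum, window

__all__ = [
    "FitResult",
    "InitializationError",
    "initialize",
    "default_window",
    "autofit",
    "manual_curve",
    "select_model",
]

# optimisation bounds: c, G, b, theta, T
_BOUNDS = {
    "c": (1.0, 1e4),
    "G": (1e3, 1e10),
    "b": (1.0, 50.0),
    "theta": (0.0, 10.0),
    "T": (0.0, 50.0),
}

# below this fitted theta (implied heterozygosity < 0.005%) the
# allotetraploid split time carries no signal
_THETA_IDENTIFIABLE = 1e-3

# per the app's guidance, fits degrade below a 15x haploid peak
_LOW_COVERAGE = 15.0


class InitializationError(ValueError):
    """The spectrum has no usable peak to initialise from."""


@dataclass
class FitResult:
    """Outcome of one model fit."""

    params: ModelParams
    derived: dict[str, float]
    objective: float
    window: tuple[int, int]
    converged: bool
    n_evaluations: int
    start: ModelParams
    warnings: list[str] = field(default_factory=list)
    aicc: float | None = None

    def summary(self) -> str:
        p = self.params
        lines = [
            f"model            : {p.model}",
            f"window           : {self.window[0]}..{self.window[1]}",
            f"per-copy depth c : {p.c:.3f}",
            f"genome size G    : {p.G:.4g} blocks"
            f" ({self.derived['genome_size_mb']:.3f} Mb)",
            f"bias b           : {p.b:.3f}",
            f"theta (block)    : {p.theta:.5g}",
            f"heterozygosity   : {self.derived['heterozygosity_pct']:.3f} %",
        ]
        if p.model == "allotetraploid":
            lines.append(f"split time T     : {p.T:.4g}")
            lines.append("sub-genome diverg: "
                         f"{self.derived['subgenome_divergence_pct']:.3f} %")
        lines.append(f"objective (WLS)  : {self.objective:.6g}")
        lines.append(f"converged        : {self.converged}")
        for w in self.warnings:
            lines.append(f"warning          : {w}")
        return "\n".join(lines)


def _smoothed(spectrum: KmerSpectrum) -> np.ndarray:
    """3-bin median filter; robust to single-bin jitter."""
    return median_filter(spectrum.counts.astype(float), size=3,
                         mode="nearest")


def _error_trough(spectrum: KmerSpectrum) -> int:
    """Depth of the first local minimum of the smoothed spectrum.

    This separates the sequencing-error tail from the signal peaks;
    when the spectrum rises from its first bin there is no error tail
    and the trough is the first bin.
    """
    s = _smoothed(spectrum)
    for i in range(1, len(s) - 1):
        if s[i] <= s[i - 1] and s[i] < s[i + 1]:
            return spectrum.d_min + i
        if s[i] > s[i - 1]:  # rising from the start: no error tail
            return spectrum.d_min
    return spectrum.d_min


def _dominant_peak(spectrum: KmerSpectrum, trough: int) -> int:
    """Depth of the highest smoothed bin at or beyond the trough."""
    s = _smoothed(spectrum)
    i0 = trough - spectrum.d_min
    seg = s[i0:]
    if seg.size == 0 or seg.max() <= 0:
        raise InitializationError("no signal beyond the error trough")
    peak = i0 + int(np.argmax(seg))
    # a peak on the boundary of a decreasing tail is not a real maximum
    if peak == len(s) - 1 and s[-1] < s[max(0, len(s) - 2)]:
        raise InitializationError("no interior peak found")
    if peak == i0 == 0 and np.all(np.diff(s) <= 0):
        raise InitializationError(
            "spectrum decreases monotonically (pure error tail); "
            "choose parameters manually")
    return spectrum.d_min + peak


def initialize(spectrum: KmerSpectrum, model: str) -> list[ModelParams]:
    """Data-driven starting points for ``autofit``.

    The dominant peak is read as the 2× peak for diploids and
    allotetraploids (the expected prominent peak) and as the 4× peak
    for autotetraploids, with the 2× assignment kept as an alternative
    start; G comes from total k-mer occurrences / (m·c).
    """
    if model not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model!r}")
    trough = _error_trough(spectrum)
    peak = _dominant_peak(spectrum, trough)
    m = 2 if model == "diploid" else 4
    if model == "diploid":
        c_candidates = [peak / 2.0]
    elif model == "autotetraploid":
        c_candidates = [peak / 4.0, peak / 2.0]
    else:
        # dominant peak is expected at 2x, but a low-diversity spectrum
        # is a lone 4x peak, so keep that assignment as an alternative
        c_candidates = [peak / 2.0, peak / 4.0]
    occurrences = float(np.dot(spectrum.depths[trough - spectrum.d_min:],
                               spectrum.counts[trough - spectrum.d_min:]))
    starts = []
    for c0 in c_candidates:
        c0 = min(max(c0, _BOUNDS["c"][0]), _BOUNDS["c"][1])
        G0 = min(max(occurrences / (m * c0), _BOUNDS["G"][0]),
                 _BOUNDS["G"][1])
        starts.append(ModelParams(model=model, c=c0, G=G0, b=2.0,
                                  theta=0.01,
                                  T=1.0 if model == "allotetraploid" else 0.0,
                                  k=spectrum.k))
    return starts


def default_window(spectrum: KmerSpectrum, model: str,
                   start: ModelParams | None = None) -> tuple[int, int]:
    """Default fit window: error trough to 1.5 × m × ĉ.

    The lower bound excludes error k-mers, the upper bound excludes
    repetitive k-mers, which the model deliberately does not describe.
    """
    if start is None:
        start = initialize(spectrum, model)[0]
    m = 2 if model == "diploid" else 4
    lo = _error_trough(spectrum)
    hi = int(math.ceil(1.5 * m * start.c))
    hi = min(max(hi, lo + 1), spectrum.d_max)
    return lo, hi


def _pack(params: ModelParams) -> tuple[np.ndarray, list[str]]:
    names = ["c", "G", "b", "theta"]
    if params.model == "allotetraploid":
        names.append("T")
    return np.array([getattr(params, n) for n in names]), names


def _unpack(x: np.ndarray, names: list[str], template: ModelParams
            ) -> ModelParams:
    return replace(template, **{n: float(v) for n, v in zip(names, x)})


def _residuals(x, names, template, depths, obs):
    params = _unpack(x, names, template)
    exp = expected_spectrum(params, depths)
    return (obs - exp) / np.sqrt(np.maximum(obs, 1.0))


def autofit(spectrum: KmerSpectrum, model: str,
            fit_window: tuple[int, int] | None = None,
            starts: list[ModelParams] | None = None,
            xtol: float = 1e-12, ftol: float = 1e-12,
            max_nfev: int | None = None) -> FitResult:
    """Estimate model parameters by bounded weighted least squares.

    Minimises Σ_d (n_d − E[n_d])² / max(n_d, 1) over the fit window.
    Deterministic: identical inputs and options give identical results.
    Multi-start over the initializer's peak assignments; ties broken by
    smaller T, then smaller θ.
    """
    if starts is None:
        starts = initialize(spectrum, model)
    if fit_window is None:
        fit_window = default_window(spectrum, model, starts[0])
    lo, hi = fit_window
    windowed = window(spectrum, lo, hi)
    if windowed.counts.size < 2:
        raise ValueError("fit window must contain more than one bin")
    depths = windowed.depths
    obs = windowed.counts.astype(float)

    best: FitResult | None = None
    for start in starts:
        x0, names = _pack(start)
        lb = np.array([_BOUNDS[n][0] for n in names])
        ub = np.array([_BOUNDS[n][1] for n in names])
        x0 = np.clip(x0, lb, ub)
        scale = np.maximum(np.abs(x0), [1.0, 1e3, 0.5, 0.01, 0.5][:len(names)])
        res = least_squares(
            _residuals, x0, bounds=(lb, ub),
            args=(names, start, depths, obs),
            x_scale=scale, xtol=xtol, ftol=ftol, gtol=1e-12,
            max_nfev=max_nfev, method="trf")
        fitted = _unpack(res.x, names, start)
        candidate = FitResult(
            params=fitted,
            derived=derived_stats(fitted),
            objective=float(2.0 * res.cost),
            window=(lo, hi),
            converged=bool(res.status > 0),
            n_evaluations=int(res.nfev),
            start=start,
        )
        if best is None or _better(candidate, best):
            candidate.n_evaluations += 0 if best is None else best.n_evaluations
            best = candidate
        else:
            best.n_evaluations += candidate.n_evaluations
    assert best is not None
    _attach_warnings(best)
    return best


def _better(a: FitResult, b: FitResult) -> bool:
    if abs(a.objective - b.objective) > 1e-9 * max(b.objective, 1e-30):
        return a.objective < b.objective
    if a.params.T != b.params.T:
        return a.params.T < b.params.T
    return a.params.theta < b.params.theta


def _attach_warnings(result: FitResult) -> None:
    p = result.params
    if p.c < _LOW_COVERAGE:
        result.warnings.append(
            f"fitted per-copy depth {p.c:.1f}x is below {_LOW_COVERAGE:.0f}x;"
            " k-mer model fits are unreliable at low coverage")
    if p.model == "allotetraploid" and p.theta < _THETA_IDENTIFIABLE:
        result.warnings.append(
            "theta is (near) zero: the split time T is unidentifiable "
            "and its fitted value should not be interpreted")
    if not result.converged:
        result.warnings.append("optimizer did not report convergence")


def manual_curve(params: ModelParams, bins) -> np.ndarray:
    """Expected spectrum for a user-chosen parameter set (Manual mode)."""
    return expected_spectrum(params, bins)


def _aicc(objective: float, n_bins: int, n_params: int) -> float:
    """Small-sample-corrected information criterion from WLS residuals."""
    rss = max(objective, 1e-300)
    aic = n_bins * math.log(rss / n_bins) + 2 * n_params
    corr_den = n_bins - n_params - 1
    if corr_den > 0:
        aic += 2 * n_params * (n_params + 1) / corr_den
    return aic


def select_model(spectrum: KmerSpectrum,
                 candidates: tuple[str, ...] = MODEL_KINDS,
                 fit_window: tuple[int, int] | None = None
                 ) -> list[FitResult]:
    """Fit each candidate model kind on a shared window and rank them.

    Ranking is by AICc computed from the weighted residual sum of
    squares with parameter counts 4 (diploid, autotetraploid) and 5
    (allotetraploid).  Returns fits best-first; models whose fit raises
    are dropped from the ranking.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate model")
    if fit_window is None:
        # shared window: trough to 3 x dominant peak, wide enough to
        # cover the 4x peak under the 2x reading of the dominant peak
        trough = _error_trough(spectrum)
        peak = _dominant_peak(spectrum, trough)
        fit_window = (trough, min(3 * peak, spectrum.d_max))
    lo, hi = fit_window
    windowed = window(spectrum, lo, hi)
    n_bins = windowed.counts.size
    results = []
    for model in candidates:
        try:
            fit = autofit(spectrum, model, fit_window=fit_window)
        except (ValueError, InitializationError):
            continue
        n_params = 5 if model == "allotetraploid" else 4
        fit.aicc = _aicc(fit.objective, n_bins, n_params)
        results.append(fit)
    if not results:
        raise ValueError("no candidate model could be fitted")
    results.sort(key=lambda r: (r.aicc, r.params.model))
    return results
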