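"""Reading, writing and windowing of k-mer count histograms.

A k-mer spectrum is the histogram of distinct k-mers by multiplicity
(depth): line ``d  n_d`` means *n_d* distinct k-mers were seen exactly
*d* times in the read set.  Both jellyfish ``histo`` output
(space-separated) and KMC ``transform histogram`` output (tab-separated)
are plain two-column text and are accepted here.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KmerSpectrum",
    "SpectrumParseError",
    "SpectrumValidationError",
    "read_histogram",
    "write_histogram",
    "window",
]


class SpectrumParseError(ValueError):
    """A histogram line could not be parsed."""


class SpectrumValidationError(ValueError):
    """A histogram violates the spectrum invariants."""


@dataclass
class KmerSpectrum:
    """Dense histogram of distinct k-mers by multiplicity.

    Parameters
    ----------
    counts
        ``counts[i]`` is the number of distinct k-mers with multiplicity
        ``d_min + i``.  Internally dense (gap bins hold zero).
    d_min
        Multiplicity of the first bin (>= 1).
    k
        k-mer length the histogram was counted with.
    label
        Free-text sample identifier.
    """

    counts: np.ndarray
    d_min: int = 1
    k: int = 21
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise SpectrumValidationError("spectrum needs at least one bin")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise SpectrumValidationError("bin counts must be finite and >= 0")
        if self.d_min < 1:
            raise SpectrumValidationError("multiplicities start at 1")
        if self.k < 1:
            raise SpectrumValidationError("k must be a positive integer")
        if self.total == 0:
            raise SpectrumValidationError("spectrum holds no k-mers")

    @property
    def depths(self) -> np.ndarray:
        """Multiplicity value of each bin."""
        return np.arange(self.d_min, self.d_min + self.counts.size)

    @property
    def d_max(self) -> int:
        return self.d_min + self.counts.size - 1

    @property
    def total(self) -> float:
        """Total number of distinct k-mers."""
        return float(self.counts.sum())

    @property
    def total_occurrences(self) -> float:
        """Total k-mer occurrences, sum of d * n_d."""
        return float(np.dot(self.depths, self.counts))

    def as_dict(self) -> dict[int, int]:
        return {int(d): int(n) for d, n in zip(self.depths, self.counts)}


def _split_line(line: str) -> list[str]:
    # tab first (KMC), fall back to any whitespace (jellyfish)
    if "\t" in line:
        return [f for f in line.split("\t") if f != ""]
    return line.split()


def read_histogram(source, k: int = 21, dialect: str = "auto",
                   label: str = "") -> KmerSpectrum:
    """Read a two-column multiplicity/count histogram.

    ``source`` may be a path or an open text stream.  ``dialect`` is one
    of ``auto`` (sniff separator), ``jellyfish`` (whitespace) or ``kmc``
    (tab); all three accept the same grammar, the flag only documents
    intent.  Gaps between observed multiplicities are zero-filled.
    """
    if dialect not in ("auto", "jellyfish", "kmc"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt", encoding="utf-8") as fh:
            return read_histogram(fh, k=k, dialect=dialect,
                                  label=label or os.fspath(source))
    bins: dict[int, float] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = _split_line(line) if dialect != "kmc" else \
            [f for f in line.split("\t") if f != ""]
        if len(fields) != 2:
            raise SpectrumParseError(
                f"line {lineno}: expected two fields, got {len(fields)}")
        try:
            d = int(fields[0])
            n = float(fields[1])
        except ValueError as exc:
            raise SpectrumParseError(f"line {lineno}: non-numeric field "
                                     f"({line!r})") from exc
        if d < 1:
            raise SpectrumValidationError(
                f"line {lineno}: multiplicity must be >= 1, got {d}")
        if n < 0:
            raise SpectrumValidationError(
                f"line {lineno}: negative count {n}")
        if d in bins:
            raise SpectrumValidationError(
                f"line {lineno}: duplicate multiplicity {d}")
        bins[d] = n
    if not bins:
        raise SpectrumValidationError("empty histogram")
    d_hi = max(bins)
    counts = np.zeros(d_hi, dtype=float)
    for d, n in bins.items():
        counts[d - 1] = n
    return KmerSpectrum(counts=counts, d_min=1, k=k, label=label)


def write_histogram(spectrum: KmerSpectrum, sink, dialect: str = "jellyfish"
                    ) -> None:
    """Write a spectrum as canonical two-column text, ascending depth.

    jellyfish dialect separates with a single space, KMC with a tab.
    """
    sep = "\t" if dialect == "kmc" else " "
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "wt", encoding="utf-8") as fh:
            write_histogram(spectrum, fh, dialect=dialect)
        return
    for d, n in zip(spectrum.depths, spectrum.counts):
        n_out = int(n) if float(n).is_integer() else n
        sink.write(f"{d}{sep}{n_out}\n")


def to_text(spectrum: KmerSpectrum, dialect: str = "jellyfish") -> str:
    buf = io.StringIO()
    write_histogram(spectrum, buf, dialect=dialect)
    return buf.getvalue()


def window(spectrum: KmerSpectrum, d_min: int, d_max: int) -> KmerSpectrum:
    """Restrict a spectrum to multiplicities in ``[d_min, d_max]``.

    Counts outside the window are dropped, not redistributed.  Raises if
    the window is empty or excludes all k-mers.
    """
    if not (1 <= d_min <= d_max):
        raise SpectrumValidationError(
            f"invalid window [{d_min}, {d_max}]")
    lo = max(d_min, spectrum.d_min)
    hi = min(d_max, spectrum.d_max)
    if lo > hi:
        raise SpectrumValidationError(
            f"window [{d_min}, {d_max}] excludes the whole spectrum "
            f"[{spectrum.d_min}, {spectrum.d_max}]")
    counts = spectrum.counts[lo - spectrum.d_min: hi - spectrum.d_min + 1]
    if counts.sum() == 0:
        raise SpectrumValidationError(
            f"window [{d_min}, {d_max}] contains no k-mers")
    return KmerSpectrum(counts=counts.copy(), d_min=lo, k=spectrum.k,
                        label=spectrum.label)
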