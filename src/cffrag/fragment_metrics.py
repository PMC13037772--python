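"""Fragment-length histograms and size-derived features.

All size features are computed from a :class:`LengthHistogram` over lengths
1..10,000 bp (longer fragments go to an overflow bucket that still counts in
every denominator).  The canonical ranges are the short-fragment window
100-155 bp, the long window 250-10,000 bp, and the electrophoresis window
50-700 bp; both the classifier short window [100, 155] and the
correlation-analysis window [50, 150] are exposed as named presets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import MAX_FRAGMENT_LENGTH, Fragment, fragment_lengths

__all__ = [
    "LengthHistogram",
    "SizeFeatures",
    "RANGE_SHORT_FEATURE",
    "RANGE_SHORT_CORR",
    "RANGE_LONG",
    "RANGE_ELECTRO",
    "length_histogram",
    "proportion_in_range",
    "modal_size",
    "median_density_profile",
    "periodicity_score",
    "periodicity_spectrum",
    "size_features",
]

RANGE_SHORT_FEATURE = (100, 155)   # classifier short-fragment window
RANGE_SHORT_CORR = (50, 150)       # window used for TF correlation analyses
RANGE_LONG = (250, MAX_FRAGMENT_LENGTH)
RANGE_ELECTRO = (50, 700)          # electrophoresis comparison window


@dataclass
class LengthHistogram:
    """Integer counts per fragment length 1..10,000 plus an overflow bucket."""

    counts: np.ndarray  # shape (MAX_FRAGMENT_LENGTH + 1,); index = length, 0 unused
    overflow: int
    n_total: int

    def __post_init__(self):
        assert self.counts.shape == (MAX_FRAGMENT_LENGTH + 1,)
        assert int(self.counts.sum()) + self.overflow == self.n_total

    @property
    def density(self) -> np.ndarray:
        """Counts normalized to sum 1 over lengths 1..10,000 (overflow excluded)."""
        total = self.counts.sum()
        if total == 0:
            raise ValueError("histogram has no in-range mass")
        return self.counts / total


def length_histogram(fragments: Iterable[Fragment] | np.ndarray) -> LengthHistogram:
    """Exact histogram of fragment lengths; lengths > 10 kb go to overflow."""
    if isinstance(fragments, np.ndarray):
        lengths = fragments.astype(np.int64)
    else:
        lengths = fragment_lengths(fragments)
    if lengths.size == 0:
        raise ValueError("cannot histogram an empty sample; handle empty samples upstream")
    if np.any(lengths < 1):
        raise ValueError("fragment lengths must be >= 1")
    over = int((lengths > MAX_FRAGMENT_LENGTH).sum())
    in_range = lengths[lengths <= MAX_FRAGMENT_LENGTH]
    counts = np.bincount(in_range, minlength=MAX_FRAGMENT_LENGTH + 1).astype(np.int64)
    return LengthHistogram(counts, over, int(lengths.size))


def proportion_in_range(hist: LengthHistogram, lo: int, hi: int) -> float:
    """Fraction of all fragments with length in [lo, hi] (inclusive ends).

    The denominator is the total fragment count including overflow, so
    proportions over a partition of 1..10,000 sum to 1 minus the overflow
    fraction.
    """
    if not (1 <= lo <= hi <= MAX_FRAGMENT_LENGTH):
        raise ValueError(f"range [{lo}, {hi}] must satisfy 1 <= lo <= hi <= {MAX_FRAGMENT_LENGTH}")
    return float(hist.counts[lo : hi + 1].sum() / hist.n_total)


def modal_size(hist: LengthHistogram, search_lo: int = 100, search_hi: int = 200) -> int:
    """Most frequent fragment length within the mononucleosome search window.

    Ties resolve to the smallest length.
    """
    window = hist.counts[search_lo : search_hi + 1]
    if window.sum() == 0:
        raise ValueError(f"no fragments in modal search window [{search_lo}, {search_hi}]")
    return search_lo + int(np.argmax(window))


def median_density_profile(histograms: Sequence[LengthHistogram]) -> np.ndarray:
    """Per-length median of sample-normalized densities (index = length, 0 unused).

    Each sample's histogram is normalized to sum 1 over 1..10,000 first, so
    deep and shallow samples weigh equally; the output is the raw per-length
    median and is not renormalized.
    """
    if len(histograms) == 0:
        raise ValueError("need at least one histogram")
    mat = np.stack([h.density for h in histograms])
    return np.median(mat, axis=0)


def periodicity_spectrum(
    hist: LengthHistogram, band: tuple[int, int] = (80, 150)
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum of the detrended log-density over a length band.

    The log of the in-band counts (+0.5 to tolerate zeros) is linearly
    detrended, then power |sum r_l exp(-2 pi i f l)|^2 is evaluated on a grid
    of frequencies 1/40..1/4 cycles per bp.  Returns (frequencies, power).
    """
    lo, hi = band
    x = hist.counts[lo : hi + 1].astype(float)
    if x.sum() == 0:
        raise ValueError(f"no counts in periodicity band [{lo}, {hi}]")
    ell = np.arange(lo, hi + 1, dtype=float)
    logd = np.log(x + 0.5)
    coef = np.polyfit(ell, logd, 1)
    resid = logd - np.polyval(coef, ell)
    freqs = np.linspace(1 / 40, 1 / 4, 400)
    phase = np.exp(-2j * np.pi * np.outer(freqs, ell))
    power = np.abs(phase @ resid) ** 2
    return freqs, power


def periodicity_score(
    hist: LengthHistogram,
    band: tuple[int, int] = (80, 150),
    period: float = 10.0,
) -> float:
    """Strength of the ~10 bp sub-mononucleosomal comb.

    Score = spectral power at 1/period divided by the median power at
    neighboring frequencies (within a factor of two of 1/period, excluding a
    small guard band around it).  A flat or unstructured density scores <= ~1;
    a strong comb scores far above.
    """
    freqs, power = periodicity_spectrum(hist, band)
    f0 = 1.0 / period
    if power.sum() < 1e-12:  # perfectly flat after detrend: no periodicity
        return 0.0
    p0 = float(np.interp(f0, freqs, power))
    neighbors = (freqs > f0 / 2) & (freqs < f0 * 2) & (np.abs(freqs - f0) > 0.015)
    med = float(np.median(power[neighbors]))
    if med <= 1e-12:
        return 0.0 if p0 <= 1e-12 else np.inf
    return p0 / med


@dataclass
class SizeFeatures:
    """Per-sample size features used downstream (classifier + statistics)."""

    prop_short: float     # fraction in [100, 155] bp
    prop_long: float      # fraction in [250, 10000] bp
    prop_electro: float   # fraction in [50, 700] bp
    modal_size: int
    periodicity: float
    n_total: int


def size_features(hist: LengthHistogram) -> SizeFeatures:
    return SizeFeatures(
        prop_short=proportion_in_range(hist, *RANGE_SHORT_FEATURE),
        prop_long=proportion_in_range(hist, *RANGE_LONG),
        prop_electro=proportion_in_range(hist, *RANGE_ELECTRO),
        modal_size=modal_size(hist),
        periodicity=periodicity_score(hist),
        n_total=hist.n_total,
    )
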