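"""Fourier period spectrum of the nightly mode series; brood-band detection.

A healthy laying queen refills the comb near the sensor on the worker
brood-development rhythm, so the nightly mode amplitude oscillates with a
period slightly above 21 days.  Fourier transformation of the mode time
series, re-indexed on a period-in-days axis and normalized, makes that
cycle a single dominant maximum in the 21-26 day band; colonies that
swarmed, went drone-laying or failed lose or distort the peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend, find_peaks

from .distributions import ModeSeries

logger = logging.getLogger(__name__)

BROOD_BAND_DAYS = (21.0, 26.0)
#: A "clear" peak must rise by at least this fraction of the normalized scale.
PEAK_PROMINENCE = 0.3
#: ... and stand at least this factor above the median spectral magnitude,
#: so that the bumps of a featureless (noise-like) spectrum never qualify.
MEDIAN_HEIGHT_FACTOR = 3.0
#: Seasonal periods longer than this are excluded before normalization.
MAX_PERIOD_DAYS = 60.0
ZERO_PAD_FACTOR = 4
MIN_NIGHTS = 42  # two nominal 21-day cycles
MAX_GAP_FRACTION = 0.20


@dataclass
class PeriodSpectrum:
    """Normalized Fourier magnitude of a mode series on a period axis."""

    colony_id: str
    periods: np.ndarray  # days, descending
    magnitude: np.ndarray  # normalized to max 1 over periods <= 60 d
    dominant_period: float
    has_brood_band_peak: bool
    n_nights: int
    prep: dict = field(default_factory=dict)


def _prepare_series(series: ModeSeries) -> np.ndarray:
    """Daily-grid values with gaps linearly interpolated and trend removed."""
    dates, amps = series.dates, series.mode_amps
    span = (dates[-1] - dates[0]).days + 1
    grid = np.full(span, np.nan)
    for d, a in zip(dates, amps):
        grid[(d - dates[0]).days] = a
    n_missing = int(np.isnan(grid).sum())
    if span < MIN_NIGHTS:
        raise ValueError(
            f"series spans {span} nights; at least {MIN_NIGHTS} (two nominal cycles) required"
        )
    if n_missing > MAX_GAP_FRACTION * span:
        raise ValueError(
            f"{n_missing}/{span} nights missing exceeds the {MAX_GAP_FRACTION:.0%} gap budget"
        )
    idx = np.arange(span)
    ok = ~np.isnan(grid)
    filled = np.interp(idx, idx[ok], grid[ok])
    return detrend(filled, type="linear")


def period_spectrum(
    series: ModeSeries,
    zero_pad_factor: int = ZERO_PAD_FACTOR,
    max_period_days: float = MAX_PERIOD_DAYS,
    prominence: float = PEAK_PROMINENCE,
) -> PeriodSpectrum:
    """Fourier magnitude of the mode series as a function of period in days.

    Preparation: linear interpolation of gaps, linear detrend, zero padding
    (x4 by default) for a smooth period grid, no taper.  The magnitude is
    re-indexed as period = padded_length / k (days) and normalized to its
    maximum over periods <= ``max_period_days``, so the seasonal trend does
    not set the scale.
    """
    y = _prepare_series(series)
    n = y.size
    n_pad = zero_pad_factor * n
    mag = np.abs(np.fft.rfft(y, n=n_pad))
    k = np.arange(1, mag.size)  # drop the DC term
    periods = n_pad / k  # days per cycle, descending
    mag = mag[1:]
    keep = periods <= max_period_days
    periods, mag = periods[keep], mag[keep]
    peak_mag = mag.max()
    if peak_mag > 0:
        mag = mag / peak_mag
    dominant = float(periods[np.argmax(mag)])
    ps = PeriodSpectrum(
        colony_id=series.colony_id,
        periods=periods,
        magnitude=mag,
        dominant_period=dominant,
        has_brood_band_peak=False,
        n_nights=n,
        prep={
            "gap_fill": "linear",
            "detrend": "linear",
            "zero_pad_factor": zero_pad_factor,
            "max_period_days": max_period_days,
        },
    )
    ps.has_brood_band_peak = has_peak_in_range(ps, prominence=prominence)
    return ps


def has_peak_in_range(
    ps: PeriodSpectrum,
    lo: float = BROOD_BAND_DAYS[0],
    hi: float = BROOD_BAND_DAYS[1],
    prominence: float = PEAK_PROMINENCE,
    median_factor: float = MEDIAN_HEIGHT_FACTOR,
) -> bool:
    """True iff a clear local maximum lies in the [lo, hi] day band.

    "Clear" means both prominent (>= ``prominence`` on the normalized scale)
    and standing at least ``median_factor`` times above the median spectral
    magnitude.  The second condition separates a genuine oscillation from
    the bumps of a noise-like spectrum, whose maxima are prominent after
    normalization but sit barely above the rest of the spectrum.
    """
    peaks, _ = find_peaks(ps.magnitude, prominence=prominence)
    floor = float(np.median(ps.magnitude))
    tall = ps.magnitude[peaks] >= median_factor * floor
    in_band = (ps.periods[peaks] >= lo) & (ps.periods[peaks] <= hi)
    return bool(np.any(tall & in_band))


def sort_colonies(spectra: list[PeriodSpectrum]) -> list[PeriodSpectrum]:
    """Stable ordering by dominant period ascending, ties by colony id."""
    return sorted(spectra, key=lambda ps: (ps.dominant_period, ps.colony_id))
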