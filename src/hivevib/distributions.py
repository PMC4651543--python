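"""Overnight amplitude distributions and their most-frequent amplitude.

Pooling every amplitude value from every night-window spectrum (over one
hundred 3-minute spectra per night, each contributing all retained frequency
bins) gives a smooth single-peaked histogram whose maximum — the amplitude
the comb most often vibrates at — oscillates with the brood cycle: brood,
honey and pollen load the comb and damp the measured acceleration.  This
module builds those histograms, extracts the mode by a local Gaussian fit,
and stacks the per-night normalized histograms into the colour-coded
distribution image (black = 0, red = 1) used for visual inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .spectra_io import SpectrumFrame

logger = logging.getLogger(__name__)

#: Histogram bin-width range, m/s^2: tailored to colony strength.
BIN_WIDTH_MIN = 0.1e-7
BIN_WIDTH_MAX = 0.4e-7
#: Median night amplitude is divided by this to choose the bin width.
BIN_WIDTH_DIVISOR = 100.0
#: Half-width (in bins) of the Gaussian fit window around the argmax.
MODE_FIT_HALFWIDTH = 5


@dataclass
class NightHistogram:
    """Pooled amplitude distribution for one colony-night."""

    date: date
    bin_edges: np.ndarray
    counts: np.ndarray
    mode_amp: float
    bin_width: float
    n_frames: int
    n_freq_bins: int

    @property
    def normalized(self) -> np.ndarray:
        """Counts scaled to a maximum of one (all-zero stays all-zero)."""
        m = self.counts.max()
        return self.counts / m if m > 0 else self.counts.astype(float)

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ModeSeries:
    """Nightly mode amplitudes for one colony; gaps are explicit NaNs."""

    colony_id: str
    dates: list[date]
    mode_amps: np.ndarray

    def __post_init__(self) -> None:
        self.mode_amps = np.asarray(self.mode_amps, dtype=float)
        if len(self.dates) != self.mode_amps.size:
            raise ValueError("dates and mode_amps must have equal length")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")

    @property
    def n_gaps(self) -> int:
        return int(np.isnan(self.mode_amps).sum())


def auto_bin_width(amplitudes: Iterable[float] | np.ndarray) -> float:
    """Histogram bin width tailored to the colony's vibrational strength.

    The pooled night amplitudes' median, divided by 100, clipped to the
    0.1e-7 to 0.4e-7 m/s^2 range: weak colonies get the fine width, strong
    colonies the coarse one.  Deterministic in its input.
    """
    amps = np.asarray(list(amplitudes) if not isinstance(amplitudes, np.ndarray) else amplitudes)
    if amps.size == 0:
        raise ValueError("no amplitudes to choose a bin width from")
    med = float(np.median(amps))
    return float(np.clip(med / BIN_WIDTH_DIVISOR, BIN_WIDTH_MIN, BIN_WIDTH_MAX))


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def extract_mode(bin_edges: np.ndarray, counts: np.ndarray) -> float:
    """Amplitude at the distribution maximum, by a local Gaussian fit.

    A Gaussian is fitted to the +-5 bins around the argmax (the distribution
    is single-peaked there but not symmetric overall); the fitted centre is
    returned, falling back to the argmax bin centre when fewer than three
    bins are occupied or the fit fails.  Ties at the maximum are broken
    toward lower amplitude.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("empty histogram has no mode")
    centres = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    k = int(np.argmax(counts))  # first maximum -> lower amplitude on ties
    lo = max(0, k - MODE_FIT_HALFWIDTH)
    hi = min(counts.size, k + MODE_FIT_HALFWIDTH + 1)
    x, y = centres[lo:hi], counts[lo:hi]
    if np.count_nonzero(counts) < 3 or np.count_nonzero(y) < 3:
        return float(centres[k])
    width = bin_edges[1] - bin_edges[0]
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            y,
            p0=(counts[k], centres[k], 2 * width),
            maxfev=2000,
        )
    except RuntimeError:
        return float(centres[k])
    mu = float(popt[1])
    # a centre outside the local fit window means the fit latched onto
    # something other than the peak: fall back to the argmax centre
    if not centres[lo] - width <= mu <= centres[hi - 1] + width:
        return float(centres[k])
    return mu


def night_histogram(
    frames: Sequence[SpectrumFrame], bin_width: float, night: date | None = None
) -> NightHistogram:
    """Pool all amplitudes of one night's (cropped) frames into a histogram.

    Every retained frequency bin of every frame contributes one value; bin
    edges start at 0 m/s^2 (so images across nights share an axis) and
    extend past the largest amplitude.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not frames:
        raise ValueError("no frames in the night window")
    amps = np.concatenate([fr.amps for fr in frames])
    if amps.size == 0:
        raise ValueError("frames contain an empty frequency band")
    n_edges = int(np.floor(amps.max() / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    counts, _ = np.histogram(amps, bins=edges)
    mode = extract_mode(edges, counts)
    return NightHistogram(
        date=night if night is not None else frames[0].timestamp.date(),
        bin_edges=edges,
        counts=counts,
        mode_amp=mode,
        bin_width=bin_width,
        n_frames=len(frames),
        n_freq_bins=frames[0].amps.size,
    )


def mode_series(
    colony_id: str,
    dates: Sequence[date],
    histograms: Sequence[NightHistogram | None],
) -> ModeSeries:
    """Assemble nightly modes into a series; missing nights become NaN."""
    if len(dates) != len(histograms):
        raise ValueError("dates and histograms must align")
    amps = np.array([h.mode_amp if h is not None else np.nan for h in histograms])
    return ModeSeries(colony_id=colony_id, dates=list(dates), mode_amps=amps)


@dataclass
class DistributionImage:
    """Amplitude-bin x date matrix of per-night normalized histograms."""

    amplitude_edges: np.ndarray
    dates: list[date]
    matrix: np.ndarray  # shape (n_amplitude_bins, n_dates), values in [0, 1]
    missing: np.ndarray  # boolean per date
    #: Rendering hint for the canonical colour coding.
    colormap: str = "black=0 -> red=1 (e.g. matplotlib 'hot' clipped)"


def distribution_image(
    dates: Sequence[date], histograms: Sequence[NightHistogram | None]
) -> DistributionImage:
    """Stack per-night normalized histograms on a common amplitude axis.

    All histograms must share the bin width and the zero origin; shorter
    histograms are zero-padded upward.  Missing nights produce all-zero
    columns and are flagged.
    """
    if len(dates) != len(histograms):
        raise ValueError("dates and histograms must align")
    present = [h for h in histograms if h is not None]
    if not present:
        raise ValueError("no histograms to image")
    widths = {round(h.bin_width, 12) for h in present}
    if len(widths) > 1:
        raise ValueError("histograms mix bin widths; re-bin with a common width first")
    n_bins = max(h.counts.size for h in present)
    width = present[0].bin_width
    matrix = np.zeros((n_bins, len(dates)))
    missing = np.zeros(len(dates), dtype=bool)
    for j, h in enumerate(histograms):
        if h is None:
            missing[j] = True
            continue
        matrix[: h.counts.size, j] = h.normalized
    return DistributionImage(
        amplitude_edges=np.arange(n_bins + 1) * width,
        dates=list(dates),
        matrix=matrix,
        missing=missing,
    )
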