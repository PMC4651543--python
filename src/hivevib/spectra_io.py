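"""Day files of averaged vibrational spectra: read/write, night window, band crop.

A comb-embedded accelerometer produces one amplitude spectrum every three
minutes, averaged over that interval: 1761 bins at 3.125 Hz spacing covering
0-5500 Hz, amplitudes in m/s^2.  The acquisition machine rolls its output
file at midnight, so the natural storage unit is one civil day per colony
and sensor.  This module defines an open, plain-text dialect for those day
files plus the two selection primitives every downstream stage relies on:
the night window (foraging and beekeeper interventions make daytime data
unusable) and the frequency-band crop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, time
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical acquisition axis: 3.125 Hz resolution over a 5500 Hz bandwidth.
FREQ_SPACING_HZ = 3.125
FREQ_MAX_HZ = 5500.0
N_BINS = 1761  # 0, 3.125, ..., 5500 inclusive

DAYFILE_MAGIC = "# hivevib-dayfile v1"


def standard_axis() -> np.ndarray:
    """The canonical 0-5500 Hz frequency grid at 3.125 Hz spacing."""
    return np.arange(N_BINS) * FREQ_SPACING_HZ


@dataclass
class SpectrumFrame:
    """One timestamped 3-minute-averaged amplitude spectrum for one sensor.

    Parameters
    ----------
    timestamp : datetime
        Local civil time of the start of the averaging interval.  No DST
        arithmetic is applied anywhere in the package.
    colony_id : str
    sensor : str
        ``"comb"`` (embedded in the honey comb) or ``"wall"`` (screwed to
        the outside of the brood box; a stimulus-only control channel).
    freqs : ndarray
        Strictly increasing grid with constant spacing, in Hz.
    amps : ndarray
        Non-negative amplitudes in m/s^2, same length as ``freqs``.
    """

    timestamp: datetime
    colony_id: str
    sensor: str
    freqs: np.ndarray
    amps: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.amps = np.asarray(self.amps, dtype=np.float64)
        if self.sensor not in ("comb", "wall"):
            raise ValueError(f"sensor must be 'comb' or 'wall', got {self.sensor!r}")
        if self.freqs.ndim != 1 or self.freqs.size < 2:
            raise ValueError("freqs must be a 1-D grid with at least two bins")
        if self.amps.shape != self.freqs.shape:
            raise ValueError("amps and freqs must have the same length")
        d = np.diff(self.freqs)
        if not np.all(d > 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.allclose(d, d[0], rtol=0, atol=1e-9):
            raise ValueError("freqs must have constant spacing")
        if np.any(self.amps < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def spacing_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectrumFrame):
            return NotImplemented
        return (
            self.timestamp == other.timestamp
            and self.colony_id == other.colony_id
            and self.sensor == other.sensor
            and np.array_equal(self.freqs, other.freqs)
            and np.array_equal(self.amps, other.amps)
        )


@dataclass
class DayFile:
    """Ordered frames for one colony, sensor and civil day on a shared axis."""

    colony_id: str
    sensor: str
    day: date
    freqs: np.ndarray
    frames: list[SpectrumFrame]
    warnings: list[str] = field(default_factory=list)


def _check_single_day_axis(frames: Sequence[SpectrumFrame]) -> None:
    if not frames:
        raise ValueError("no frames to write")
    first = frames[0]
    for fr in frames[1:]:
        if not np.array_equal(fr.freqs, first.freqs):
            raise ValueError("frames have mixed frequency axes")
        if fr.colony_id != first.colony_id or fr.sensor != first.sensor:
            raise ValueError("frames mix colonies or sensors")
        if fr.timestamp.date() != first.timestamp.date():
            raise ValueError("frames span more than one civil day")
    ts = [fr.timestamp for fr in frames]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("frame timestamps must be strictly increasing (not re-sorted)")


def write_day_file(frames: Sequence[SpectrumFrame], path: str | Path) -> Path:
    """Write one day of frames as a plain-text day file.

    Amplitudes are written with 17 significant digits so that
    ``read_day_file(write_day_file(x)) == x`` bit-exactly for 64-bit floats.
    Frames must be pre-sorted, share one axis, and belong to a single civil
    day; violations raise rather than being silently repaired.
    """
    _check_single_day_axis(frames)
    first = frames[0]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(DAYFILE_MAGIC + "\n")
        fh.write(f"# colony: {first.colony_id}\n")
        fh.write(f"# sensor: {first.sensor}\n")
        fh.write(f"# date: {first.timestamp.date().isoformat()}\n")
        fh.write(f"# n_bins: {first.freqs.size}\n")
        fh.write(f"# f0_hz: {first.freqs[0]:.17g}\n")
        fh.write(f"# spacing_hz: {first.spacing_hz:.17g}\n")
        for fr in frames:
            row = ",".join(f"{a:.17g}" for a in fr.amps)
            fh.write(fr.timestamp.isoformat() + "," + row + "\n")
    return path


def read_day_file(path: str | Path) -> DayFile:
    """Read a day file written by :func:`write_day_file`.

    Files whose bin spacing differs from the canonical 3.125 Hz are accepted
    but flagged with a warning record on the returned :class:`DayFile`.
    """
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[datetime, np.ndarray]] = []
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != DAYFILE_MAGIC:
            raise ValueError(f"{path}: not a hivevib day file (bad magic line)")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
                continue
            ts_str, _, rest = line.partition(",")
            rows.append(
                (datetime.fromisoformat(ts_str), np.fromstring(rest, sep=","))
            )
    n_bins = int(header["n_bins"])
    f0 = float(header["f0_hz"])
    spacing = float(header["spacing_hz"])
    freqs = f0 + np.arange(n_bins) * spacing
    warn_records: list[str] = []
    if spacing != FREQ_SPACING_HZ:
        msg = f"{path}: non-canonical bin spacing {spacing} Hz (expected {FREQ_SPACING_HZ})"
        warn_records.append(msg)
        warnings.warn(msg, stacklevel=2)
    colony, sensor = header["colony"], header["sensor"]
    frames = [
        SpectrumFrame(timestamp=ts, colony_id=colony, sensor=sensor, freqs=freqs, amps=amps)
        for ts, amps in rows
    ]
    _check_single_day_axis(frames)
    return DayFile(
        colony_id=colony,
        sensor=sensor,
        day=date.fromisoformat(header["date"]),
        freqs=freqs,
        frames=frames,
        warnings=warn_records,
    )


def _parse_clock(s: str | time) -> time:
    if isinstance(s, time):
        return s
    return time.fromisoformat(s)


def select_night_window(
    frames: Iterable[SpectrumFrame],
    start: str | time = "00:00",
    end: str | time = "06:00",
) -> list[SpectrumFrame]:
    """Frames with clock time in the half-open window [start, end).

    Night-time restriction removes the daytime foraging signal and the
    occasional large human-intervention spikes.  A frame stamped exactly at
    ``end`` is excluded.  An empty selection is returned (and logged), not
    raised: a night can legitimately be missing.
    """
    t0, t1 = _parse_clock(start), _parse_clock(end)
    if not t0 < t1:
        raise ValueError(f"degenerate night window {t0}-{t1}: start must precede end")
    out = [fr for fr in frames if t0 <= fr.timestamp.time() < t1]
    if not out:
        logger.info("night window %s-%s selected no frames", t0, t1)
    return out


def dominant_harmonics(frame: SpectrumFrame, n_peaks: int = 2) -> list[float]:
    """Frequencies of the strongest harmonic peaks, rounded to the grid.

    Local maxima are ranked by prominence above the broadband floor, and the
    ``n_peaks`` strongest are refined to sub-bin precision by one joint
    least-squares fit of Gaussian peaks on a linear baseline over the region
    spanning all of them (relative weighting, so the noisy peak tops do not
    dominate the flanks that carry the position information).  Each fitted
    centre is snapped back to the nearest axis bin; the argmax bin is kept
    for any peak the fit cannot improve.  Returned ascending.
    """
    from scipy.optimize import curve_fit
    from scipy.signal import find_peaks

    peaks, props = find_peaks(frame.amps, prominence=0.1 * frame.amps.max())
    if peaks.size < n_peaks:
        raise ValueError(f"found only {peaks.size} peaks, wanted {n_peaks}")
    top = np.sort(peaks[np.argsort(props["prominences"])[::-1][:n_peaks]])
    d = frame.spacing_hz
    lo = max(0, int(top[0]) - 18)
    hi = min(frame.amps.size, int(top[-1]) + 19)
    x, y = frame.freqs[lo:hi], frame.amps[lo:hi]
    mus = [float(frame.freqs[k]) for k in top]

    def model(f, *p):
        out = p[-2] + p[-1] * f
        for j in range(n_peaks):
            a, mu, s = p[3 * j : 3 * j + 3]
            out = out + a * np.exp(-((f - mu) ** 2) / (2 * s**2))
        return out

    span = float(y.max() - y.min())
    p0, lower, upper = [], [], []
    for mu in mus:
        p0 += [span, mu, 4 * d]
        lower += [0.05 * span, mu - 8 * d, 1.0 * d]
        upper += [10 * span, mu + 8 * d, 20.0 * d]
    p0 += [float(y.min()), 0.0]
    lower += [0.0, -span / (5 * d)]
    upper += [float(y.max()), span / (5 * d)]
    try:
        popt, _ = curve_fit(
            model, x, y, p0=p0, sigma=y, bounds=(lower, upper), maxfev=10000
        )
        mus = [float(popt[3 * j + 1]) for j in range(n_peaks)]
    except RuntimeError:
        pass  # keep the argmax bins
    return sorted(
        float(frame.freqs[np.argmin(np.abs(frame.freqs - mu))]) for mu in mus
    )


def crop_band(frame: SpectrumFrame, f_lo: float = 10.0, f_hi: float = 600.0) -> SpectrumFrame:
    """Restrict a frame to the frequency band [f_lo, f_hi], inclusive both ends.

    The 10-600 Hz default is the band in which the overnight amplitude
    distribution shows a single stable mode; it is swept in
    :func:`hivevib.pipeline.band_sweep`.
    """
    if not 0 <= f_lo < f_hi <= FREQ_MAX_HZ:
        raise ValueError(f"invalid band [{f_lo}, {f_hi}]")
    mask = (frame.freqs >= f_lo) & (frame.freqs <= f_hi)
    if not mask.any():
        raise ValueError(f"band [{f_lo}, {f_hi}] contains no frequency bins")
    return SpectrumFrame(
        timestamp=frame.timestamp,
        colony_id=frame.colony_id,
        sensor=frame.sensor,
        freqs=frame.freqs[mask],
        amps=frame.amps[mask],
    )
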