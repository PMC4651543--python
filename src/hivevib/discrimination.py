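"""Spectral-shape discrimination of the brood-cycle state (PCA -> DFA).

The nightly mode amplitude tracks the brood cycle but needs a whole night of
data and drifts with the colony's overall vibrational strength.  The
frequency-resolved alternative: average spectra over 30-60 minutes, select
training spectra at the maxima and minima of each training colony's
amplitude oscillation, compress them with PCA to 10 scores, and run a
multi-group Fisher discriminant analysis that collapses those onto 3 DF
scores.  The low-amplitude states of all training colonies form one shared
cloud (brood present near the sensor damps the signal the same way in every
hive) while each colony's high-amplitude state gets its own cloud.

Because both PCA and DFA are linear, the three discriminant functions can be
expressed back on the frequency grid: cross-correlating (taking the inner
product of) a mean-centred averaged spectrum with each function yields its
three DF scores directly — no further numerics needed by a user.  The
indicator D2/D1 — distance of the projected spectrum to the pooled
high-state centroid over distance to the shared low-state centroid — then
tracks the brood cycle from one hour of night-time data: large values mean
the spectrum sits near the low-amplitude (brood-present) cloud.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.signal import find_peaks

from .distributions import ModeSeries
from .spectra_io import SpectrumFrame

logger = logging.getLogger(__name__)

N_PCA_COMPONENTS = 10
N_DISCRIMINANT_FUNCTIONS = 3
LOW_STATE = "low_amplitude_state"
#: Within-scatter ridge, as a fraction of its trace, applied when needed.
DFA_RIDGE = 1e-8
#: Default number of training extrema per state per colony.
N_EXTREMA_PER_STATE = 6
SMOOTH_NIGHTS = 5  # running-median window for extremum detection


# ---------------------------------------------------------------------------
# Averaged spectra
# ---------------------------------------------------------------------------

@dataclass
class AveragedSpectrum:
    """Mean of consecutive 3-minute spectra over a 30/60-minute window."""

    colony_id: str
    start: datetime
    duration_minutes: int
    freqs: np.ndarray
    amps: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        if self.duration_minutes % 3 != 0:
            raise ValueError("duration must be a multiple of the 3-minute cadence")


def average_spectra(
    frames: Sequence[SpectrumFrame], duration_minutes: int, normalize: bool
) -> AveragedSpectrum:
    """Arithmetic mean of ``duration/3`` consecutive frames.

    With ``normalize`` the averaged spectrum is divided by its own maximum,
    discarding amplitude and keeping shape only (this is what makes the
    indicator robust to drifts in overall vibrational strength, at the cost
    of needing longer averaging).
    """
    need = duration_minutes // 3
    if duration_minutes % 3 != 0:
        raise ValueError("duration must be a multiple of the 3-minute cadence")
    if len(frames) < need:
        raise ValueError(
            f"need {need} consecutive frames for {duration_minutes} min, got {len(frames)}"
        )
    use = frames[:need]
    amps = np.mean([fr.amps for fr in use], axis=0)
    if normalize:
        amps = amps / amps.max()
    return AveragedSpectrum(
        colony_id=use[0].colony_id,
        start=use[0].timestamp,
        duration_minutes=duration_minutes,
        freqs=use[0].freqs,
        amps=amps,
        normalized=normalize,
    )


# ---------------------------------------------------------------------------
# Training-date selection at oscillation extrema
# ---------------------------------------------------------------------------

def label_extrema(
    series: ModeSeries, n_per_state: int = N_EXTREMA_PER_STATE
) -> dict[str, list[date]]:
    """Dates of the mode-series oscillation extrema, labelled by state.

    The series is smoothed with a 5-night running median; local maxima and
    minima are detected with a minimum separation of a half nominal cycle.
    Note the state naming is on the *amplitude* axis: ``low_amplitude_state``
    nights are the oscillation minima, which is when brood fills the comb
    near the sensor.  Returns the ``n_per_state`` most prominent dates per
    state.  A flat series has no extrema and raises.
    """
    amps = pd.Series(series.mode_amps).interpolate(limit_direction="both")
    smooth = amps.rolling(SMOOTH_NIGHTS, center=True, min_periods=1).median().to_numpy()
    span = float(np.ptp(smooth))
    if span == 0:
        raise ValueError("flat mode series: no oscillation extrema to label")
    out: dict[str, list[date]] = {}
    for state, sign in (("high_amplitude_state", 1.0), (LOW_STATE, -1.0)):
        peaks, props = find_peaks(sign * smooth, distance=10, prominence=0.1 * span)
        if peaks.size == 0:
            raise ValueError(f"no {state} extrema found in the mode series")
        order = np.argsort(props["prominences"])[::-1][:n_per_state]
        out[state] = sorted(series.dates[int(i)] for i in peaks[order])
    return out


@dataclass
class TrainingSet:
    """Labelled averaged spectra at amplitude-oscillation extrema.

    Labels: the single shared ``low_amplitude_state`` group pooling every
    training colony, plus one ``high_amplitude_state:<colony>`` group per
    colony.
    """

    spectra: list[AveragedSpectrum]
    labels: list[str]

    def __post_init__(self) -> None:
        counts = pd.Series(self.labels).value_counts()
        if (counts < 2).any():
            small = list(counts[counts < 2].index)
            raise ValueError(f"groups with fewer than 2 spectra: {small}")
        low = [l for l in self.labels if l == LOW_STATE]
        if not low:
            raise ValueError("training set must contain the shared low-amplitude group")

    @property
    def matrix(self) -> np.ndarray:
        return np.vstack([s.amps for s in self.spectra])


def high_label(colony_id: str) -> str:
    return f"high_amplitude_state:{colony_id}"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(X: np.ndarray, n_components: int = N_PCA_COMPONENTS):
    """Mean-centred PCA via SVD: (mean, loadings, scores).

    Loadings are the top right singular vectors (rows of shape
    ``(n_components, n_bins)``), ordered by descending singular value, each
    signed so its largest-magnitude element is positive.  Scores are the
    projections of the centred data.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < n_components + 1:
        raise ValueError(
            f"{X.shape[0]} spectra cannot support {n_components} principal components"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[:n_components]
    flip = np.sign(loadings[np.arange(n_components), np.argmax(np.abs(loadings), axis=1)])
    loadings = loadings * flip[:, None]
    scores = Xc @ loadings.T
    return mean, loadings, scores


# ---------------------------------------------------------------------------
# Multi-group Fisher discriminant analysis
# ---------------------------------------------------------------------------

def fit_dfa(
    scores: np.ndarray,
    labels: Sequence[str],
    n_functions: int = N_DISCRIMINANT_FUNCTIONS,
):
    """Canonical (multi-group Fisher) discriminant analysis.

    Solves the generalized eigenproblem Sb w = lambda Sw w for the
    between-group and within-group scatter of the PCA scores, keeps the
    ``n_functions`` leading directions, and scales each so the projected
    within-group variance is one (so Euclidean distance in DF space is a
    Mahalanobis-like metric).  A ridge of 1e-8 x trace is added to Sw if it
    is not invertible as given.

    Returns ``(weights, centroids, eigenvalues)`` where ``weights`` has
    shape ``(n_functions, n_scores)`` and ``centroids`` maps each label to
    its group mean in DF space.
    """
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups for discriminant analysis")
    n, d = scores.shape
    overall = scores.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    lab_arr = np.array(labels)
    for g in groups:
        Xg = scores[lab_arr == g]
        mu = Xg.mean(axis=0)
        Sw += (Xg - mu).T @ (Xg - mu)
        Sb += len(Xg) * np.outer(mu - overall, mu - overall)
    ridge = DFA_RIDGE * np.trace(Sw)
    try:
        np.linalg.cholesky(Sw)
        Sw_use = Sw
    except np.linalg.LinAlgError:
        Sw_use = Sw + ridge * np.eye(d)
        try:
            np.linalg.cholesky(Sw_use)
        except np.linalg.LinAlgError:
            raise ValueError("within-group scatter singular even after regularization")
    evals, evecs = eigh(Sb, Sw_use)  # ascending
    order = np.argsort(evals)[::-1][:n_functions]
    W = evecs[:, order].T  # rows w satisfy w Sw w^T = 1 (scipy B-normalization)
    W = W * np.sqrt(n - len(groups))  # unit *variance* within groups
    flip = np.sign(W[np.arange(W.shape[0]), np.argmax(np.abs(W), axis=1)])
    W = W * flip[:, None]
    centroids = {g: (scores[lab_arr == g] @ W.T).mean(axis=0) for g in groups}
    return W, centroids, evals[order]


# ---------------------------------------------------------------------------
# The trained model and the D2/D1 indicator
# ---------------------------------------------------------------------------

@dataclass
class DiscriminantModel:
    """Everything needed to project a spectrum and compute D2/D1.

    ``discriminant_functions`` live on the frequency grid: DF score k of a
    spectrum x is the cross-correlation (inner product) of (x - mean) with
    function k.  ``centroid_low`` is the shared low-amplitude (brood
    present) cloud centre; ``centroid_high`` pools all high-state training
    points; per-colony high centroids are kept for diagnostics.  Large
    D2/D1 therefore means "near the brood-present state".
    """

    freqs: np.ndarray
    mean_spectrum: np.ndarray
    pca_loadings: np.ndarray  # (10, n_bins)
    df_weights: np.ndarray  # (3, 10)
    discriminant_functions: np.ndarray  # (3, n_bins)
    centroid_low: np.ndarray  # (3,)
    centroid_high: np.ndarray  # (3,)
    colony_centroids: dict[str, np.ndarray]
    eigenvalues: np.ndarray
    duration_minutes: int
    normalized: bool
    version: str = "hivevib-dfa-1"
    orientation_note: str = (
        "large D2/D1 = close to the shared low-amplitude (brood-present) cloud"
    )

    def project(self, spectrum: AveragedSpectrum | np.ndarray) -> np.ndarray:
        """3-D DF scores by cross-correlation with the discriminant functions."""
        amps = spectrum.amps if isinstance(spectrum, AveragedSpectrum) else np.asarray(spectrum)
        return self.discriminant_functions @ (amps - self.mean_spectrum)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "version": self.version,
            "orientation_note": self.orientation_note,
            "duration_minutes": self.duration_minutes,
            "normalized": self.normalized,
            "freqs": self.freqs.tolist(),
            "mean_spectrum": self.mean_spectrum.tolist(),
            "pca_loadings": self.pca_loadings.tolist(),
            "df_weights": self.df_weights.tolist(),
            "discriminant_functions": self.discriminant_functions.tolist(),
            "centroid_low": self.centroid_low.tolist(),
            "centroid_high": self.centroid_high.tolist(),
            "colony_centroids": {k: v.tolist() for k, v in self.colony_centroids.items()},
            "eigenvalues": self.eigenvalues.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DiscriminantModel":
        d = json.loads(Path(path).read_text())
        if d.get("version") != "hivevib-dfa-1":
            raise ValueError(f"unsupported model version {d.get('version')!r}")
        return cls(
            freqs=np.array(d["freqs"]),
            mean_spectrum=np.array(d["mean_spectrum"]),
            pca_loadings=np.array(d["pca_loadings"]),
            df_weights=np.array(d["df_weights"]),
            discriminant_functions=np.array(d["discriminant_functions"]),
            centroid_low=np.array(d["centroid_low"]),
            centroid_high=np.array(d["centroid_high"]),
            colony_centroids={k: np.array(v) for k, v in d["colony_centroids"].items()},
            eigenvalues=np.array(d["eigenvalues"]),
            duration_minutes=d["duration_minutes"],
            normalized=d["normalized"],
            orientation_note=d["orientation_note"],
        )


def compose_discriminant_functions(
    pca_loadings: np.ndarray, df_weights: np.ndarray
) -> np.ndarray:
    """Express the DF axes on the frequency grid.

    Function k = sum over PCA components of df_weight[k, j] * loading[j], so
    (x - mean) . function_k == DF score k exactly (both maps are linear and
    the loadings are orthonormal)."""
    return df_weights @ pca_loadings


def train_discriminant_model(training: TrainingSet) -> DiscriminantModel:
    """PCA (10 components) -> Fisher DFA (3 functions) -> composed model."""
    X = training.matrix
    mean, loadings, scores = fit_pca(X)
    W, centroids, evals = fit_dfa(scores, training.labels)
    functions = compose_discriminant_functions(loadings, W)
    lab_arr = np.array(training.labels)
    df_points = scores @ W.T
    high_mask = lab_arr != LOW_STATE
    colony_centroids = {
        g.split(":", 1)[1]: centroids[g] for g in centroids if g != LOW_STATE
    }
    first = training.spectra[0]
    return DiscriminantModel(
        freqs=first.freqs,
        mean_spectrum=mean,
        pca_loadings=loadings,
        df_weights=W,
        discriminant_functions=functions,
        centroid_low=centroids[LOW_STATE],
        centroid_high=df_points[high_mask].mean(axis=0),
        colony_centroids=colony_centroids,
        eigenvalues=evals,
        duration_minutes=first.duration_minutes,
        normalized=first.normalized,
    )


def indicator(spectrum: AveragedSpectrum | np.ndarray, model: DiscriminantModel) -> float:
    """D2/D1 for one averaged spectrum.

    D1 = distance to the shared low-amplitude centroid, D2 = distance to the
    pooled high-state centroid, in the 3-D DF space.  A spectrum exactly at
    the low centroid returns +inf (flagged by the caller via isinf)."""
    p = model.project(spectrum)
    d1 = float(np.linalg.norm(p - model.centroid_low))
    d2 = float(np.linalg.norm(p - model.centroid_high))
    if d1 == 0:
        logger.warning("spectrum coincides with the low-state centroid; indicator is +inf")
        return float("inf")
    return d2 / d1


def nearest_centroid_labels(
    scores_3d: np.ndarray, centroids: Mapping[str, np.ndarray]
) -> list[str]:
    """Assign each DF-space point to the nearest group centroid."""
    names = sorted(centroids)
    C = np.vstack([centroids[g] for g in names])
    d = np.linalg.norm(scores_3d[:, None, :] - C[None, :, :], axis=2)
    return [names[i] for i in np.argmin(d, axis=1)]


# ---------------------------------------------------------------------------
# The indicator image (night x hour-slot)
# ---------------------------------------------------------------------------

@dataclass
class IndicatorSeries:
    """Per-(night, hour-slot) D2/D1 values for one colony."""

    colony_id: str
    dates: list[date]
    values: np.ndarray  # (n_nights, n_slots); NaN for missing slots
    slot_minutes: int

    @property
    def nightly_mean(self) -> np.ndarray:
        """Geometric mean over the night's slots.

        D2/D1 is a ratio, so its natural averaging scale is logarithmic: the
        geometric mean keeps one near-centroid slot (ratio spike) from
        dominating a night."""
        with np.errstate(invalid="ignore", divide="ignore"):
            logs = np.log(np.where(self.values > 0, self.values, np.nan))
            logs = np.where(np.isfinite(logs), logs, np.nan)
            return np.exp(np.nanmean(logs, axis=1))


def indicator_image(
    night_frames: Mapping[date, Sequence[SpectrumFrame]],
    model: DiscriminantModel,
    duration_minutes: int = 60,
    normalize: bool = True,
) -> IndicatorSeries:
    """Indicator over every night, one value per ``duration_minutes`` slot.

    With the 00:00-06:00 window and 60-minute averaging this is the 6-slot
    per-night colour-coded image; partial nights yield NaN for the slots
    they cannot fill."""
    dates = sorted(night_frames)
    per_slot = duration_minutes // 3
    n_slots_ref = max(len(night_frames[d]) // per_slot for d in dates) if dates else 0
    if n_slots_ref == 0:
        raise ValueError("no night has enough frames for a single slot")
    values = np.full((len(dates), n_slots_ref), np.nan)
    colony = None
    for i, d in enumerate(dates):
        frames = sorted(night_frames[d], key=lambda fr: fr.timestamp)
        if frames:
            colony = frames[0].colony_id
        for s in range(len(frames) // per_slot):
            chunk = frames[s * per_slot : (s + 1) * per_slot]
            avg = average_spectra(chunk, duration_minutes, normalize)
            values[i, s] = indicator(avg, model)
    return IndicatorSeries(
        colony_id=colony or "?",
        dates=dates,
        values=values,
        slot_minutes=duration_minutes,
    )


def tracking_correlation(ind: IndicatorSeries, series: ModeSeries) -> float:
    """Pearson r between the nightly log-indicator and the negated log mode.

    -log is the fixed monotone transform aligning the two: brood filling the
    comb lowers the mode amplitude and raises D2/D1, and both quantities are
    multiplicative (a ratio of distances; an attenuated amplitude), so the
    comparison lives on the log scale, where the indicator's near-centroid
    spikes carry no outsized weight."""
    by_date = dict(zip(series.dates, series.mode_amps))
    x, y = [], []
    for d, v in zip(ind.dates, ind.nightly_mean):
        m = by_date.get(d, np.nan)
        if np.isfinite(v) and v > 0 and np.isfinite(m) and m > 0:
            x.append(np.log(v))
            y.append(-np.log(m))
    if len(x) < 3:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Training-set assembly from night frames
# ---------------------------------------------------------------------------

def build_training_set(
    night_frames_by_colony: Mapping[str, Mapping[date, Sequence[SpectrumFrame]]],
    mode_series_by_colony: Mapping[str, ModeSeries],
    duration_minutes: int = 60,
    normalize: bool = True,
    n_per_state: int = N_EXTREMA_PER_STATE,
) -> TrainingSet:
    """Select extremum nights per training colony and average their spectra.

    Every full ``duration_minutes`` slot of each selected night becomes one
    training spectrum, labelled low (shared across colonies) or high (per
    colony)."""
    spectra: list[AveragedSpectrum] = []
    labels: list[str] = []
    per_slot = duration_minutes // 3
    for cid, series in mode_series_by_colony.items():
        extrema = label_extrema(series, n_per_state=n_per_state)
        frames_by_date = night_frames_by_colony[cid]
        for state, dates in extrema.items():
            label = LOW_STATE if state == LOW_STATE else high_label(cid)
            for d in dates:
                frames = sorted(frames_by_date.get(d, []), key=lambda fr: fr.timestamp)
                for s in range(len(frames) // per_slot):
                    chunk = frames[s * per_slot : (s + 1) * per_slot]
                    spectra.append(average_spectra(chunk, duration_minutes, normalize))
                    labels.append(label)
    return TrainingSet(spectra=spectra, labels=labels)
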