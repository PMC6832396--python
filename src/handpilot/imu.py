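"""IMU movement detection, RMS features and PCA nearest-centroid classification.

The inertial interface turns short, repeatable shoulder/arm movements into
hand commands.  The stream (3-axis accelerometer + 3-axis gyroscope at a
nominal ~47 Hz with irregular timestamps) is first differenced per sample,
which removes the constant gravity offset and turns bursts of motion into
large excursions.  Per-axis activation thresholds are half the calibration
maxima; an onset fires when any axis exceeds its threshold, with a 1 s
refractory so one movement triggers once.  Around each onset a 1 s window
of the differenced signal yields a 6-dimensional per-axis RMS feature; the
window length tracks the realized local sample rate because wireless IMUs
occasionally drop samples.  Features are projected onto the top two
principal components of the calibration set and labelled by the nearest
class centroid (Euclidean distance, ties to class 1, no reject class by
default).

Because the RMS window is centered on the onset, a decision can only be
emitted once the trailing edge of the window has been observed — about
half the window (0.5 s) after the movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CalibrationError
from .fsm import (
    HandState,
    Modality,
    MovementClass,
    MovementTrigger,
    TransitionEvent,
    run_session,
)

#: RMS feature window length (s), centered on the detected onset.
FEATURE_WINDOW_S = 1.0
#: Refractory period after an onset (s); calibration movements are spaced
#: by 1 s rests, so one movement never triggers twice.
ONSET_REFRACTORY_S = 1.0

CHANNEL_ORDER = ("ax", "ay", "az", "gx", "gy", "gz")


@dataclass
class ImuStream:
    """6-axis inertial stream with (possibly irregular) timestamps."""

    timestamps: np.ndarray  # (n,), seconds, strictly increasing
    accel: np.ndarray  # (n, 3)
    gyro: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must both be (n, 3) aligned with timestamps")
        if n >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def data(self) -> np.ndarray:
        """(n, 6) array in fixed channel order: accel x,y,z then gyro x,y,z."""
        return np.hstack([self.accel, self.gyro])


@dataclass
class DiffSignal:
    """First differences of the 6 sensor channels (no dt scaling).

    ``timestamps[k]`` is the time of the later sample of difference ``k``,
    so onset indices refer to the moment the change was observed.
    """

    X: np.ndarray  # (n-1, 6)
    timestamps: np.ndarray  # (n-1,)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 6:
            raise ValueError("differenced signal must be (n, 6)")
        if self.X.shape[0] != self.timestamps.shape[0]:
            raise ValueError("timestamps misaligned with differences")


@dataclass
class ActivationThresholds:
    """Per-axis onset thresholds: half the calibration maximum |difference|."""

    alpha: np.ndarray  # (6,), >= 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (6,):
            raise ValueError("expected 6 per-axis thresholds")
        if np.any(self.alpha < 0):
            raise ValueError("thresholds must be non-negative")


@dataclass
class MovementFeature:
    """6-dim per-axis RMS of the differenced signal around one onset."""

    theta: np.ndarray  # (6,), >= 0
    onset_index: int
    window_samples: int  # N, realized samples per second at the onset
    local_rate: float  # f (Hz)
    onset_time: float = 0.0
    decision_time: float = 0.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (6,):
            raise ValueError("feature must be 6-dimensional")
        if self.window_samples < 2:
            raise ValueError("window must span at least 2 samples")


@dataclass
class PcaModel:
    """Top-2 principal directions, feature mean and the two class centroids."""

    mean: np.ndarray  # (6,)
    components: np.ndarray  # (2, 6), orthonormal rows
    centroids: np.ndarray  # (2, 2): row 0 = class 1, row 1 = class 2
    calibration_points: list = field(default_factory=list)  # (label, (x, y))

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.components.shape != (2, 6) or self.centroids.shape != (2, 2):
            raise ValueError("expected a 2x6 projection and two 2-D centroids")
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(2), atol=1e-8):
            raise ValueError("projection rows must be orthonormal")

    def project(self, theta: np.ndarray) -> np.ndarray:
        return self.components @ (np.asarray(theta, dtype=float) - self.mean)


@dataclass(frozen=True)
class Classification:
    label: MovementClass
    point: np.ndarray  # (2,)
    distances: np.ndarray  # (2,): distance to class-1 and class-2 centroids


def differentiate(stream: ImuStream) -> DiffSignal:
    """Per-sample first differences of all 6 channels.

    No division by dt: thresholds, features and classification all live in
    the same differenced units, and the realized-rate bookkeeping in
    :func:`extract_feature` absorbs sample-rate variation.
    """
    if stream.n_samples < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return DiffSignal(np.diff(stream.data, axis=0), stream.timestamps[1:])


def compute_thresholds(calib: DiffSignal) -> ActivationThresholds:
    """alpha_i = max_k |X_i,k| / 2 over a calibration segment.

    The absolute value makes the threshold symmetric: movements produce
    signed excursions in either direction.  An all-zero channel yields a
    zero threshold and a degenerate-channel warning (it would fire on any
    noise at decode time).
    """
    alpha = np.max(np.abs(calib.X), axis=0) / 2.0
    dead = np.flatnonzero(alpha == 0)
    if dead.size:
        warnings.warn(
            f"degenerate (all-zero) calibration channel(s) {dead.tolist()}: "
            "threshold 0 will fire on any activity",
            stacklevel=2,
        )
    return ActivationThresholds(alpha)


def detect_movement(
    X: DiffSignal,
    alpha: ActivationThresholds,
    refractory: float = ONSET_REFRACTORY_S,
    mode: str = "any",
) -> list[int]:
    """Indices where the differenced signal crosses its activation threshold.

    ``mode='any'`` (default) fires when any axis exceeds its threshold;
    ``mode='all'`` requires all six simultaneously.  After each onset,
    crossings within ``refractory`` seconds are suppressed so a single
    movement is counted once.
    """
    exceed = np.abs(X.X) > alpha.alpha
    hits = exceed.any(axis=1) if mode == "any" else exceed.all(axis=1)
    onsets: list[int] = []
    blocked_until = -np.inf
    for k in np.flatnonzero(hits):
        t = X.timestamps[k]
        if t >= blocked_until:
            onsets.append(int(k))
            blocked_until = t + refractory
    return onsets


def local_sample_rate(timestamps: np.ndarray, k: int, span: float = 1.0) -> float:
    """Realized sample rate: number of samples in the trailing ``span`` seconds.

    Recomputed at every onset because wireless links drop samples; the
    feature window length must track the rate actually achieved.
    """
    t = timestamps[k]
    return float(np.count_nonzero((timestamps > t - span) & (timestamps <= t)))


def extract_feature(
    X: DiffSignal,
    k: int,
    window: float = FEATURE_WINDOW_S,
    allow_truncated: bool = False,
) -> MovementFeature:
    """Per-axis RMS over a ``window``-second span centered on onset ``k``.

    The window holds N = round(f * window) samples, where f is the realized
    local sample rate; it extends N//2 samples on each side of the onset,
    so the decision can be emitted only ~window/2 after the movement.

    If the trailing edge exceeds the stream, the feature is deferred
    (``ValueError``) unless ``allow_truncated`` is set for offline use, in
    which case the window is clipped with a warning.
    """
    f = local_sample_rate(X.timestamps, k, span=1.0)
    n = int(round(f * window))
    if n < 2:
        raise ValueError(f"local rate {f} Hz too low for a {window} s feature window")
    half = n // 2
    lo, hi = k - half, k + half
    if lo < 0 or hi >= X.X.shape[0]:
        if not allow_truncated:
            raise ValueError(
                f"feature window [{lo}, {hi}] exceeds stream bounds; "
                "defer until enough data is available"
            )
        warnings.warn("feature window truncated at stream boundary", stacklevel=2)
        lo, hi = max(lo, 0), min(hi, X.X.shape[0] - 1)
    seg = X.X[lo: hi + 1]
    theta = np.sqrt(np.mean(seg**2, axis=0))
    return MovementFeature(
        theta=theta,
        onset_index=k,
        window_samples=n,
        local_rate=f,
        onset_time=float(X.timestamps[k]),
        decision_time=float(X.timestamps[hi]),
    )


def fit_classifier(
    features: Sequence[MovementFeature] | np.ndarray,
    labels: Sequence[MovementClass | int],
) -> PcaModel:
    """PCA (top 2 components) + per-class centroids on calibration movements.

    Features are mean-centered before the decomposition; the same mean is
    subtracted again at classify time, so the geometry between points and
    centroids is unaffected.  Sign convention: within each component the
    largest-magnitude loading is made positive, which pins the otherwise
    arbitrary eigenvector signs.
    """
    thetas = np.asarray(
        [f.theta if isinstance(f, MovementFeature) else f for f in features],
        dtype=float,
    )
    labs = np.asarray([int(l) for l in labels])
    if thetas.shape[0] != labs.shape[0]:
        raise ValueError("features and labels differ in length")
    if thetas.shape[0] < 3:
        raise CalibrationError("need at least 3 calibration movements")
    for cls in (1, 2):
        if np.count_nonzero(labs == cls) < 2:
            raise CalibrationError(
                f"movement class {cls} has fewer than 2 calibration examples"
            )

    mean = thetas.mean(axis=0)
    centered = thetas - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if np.sum(s > s[0] * 1e-10) < 2:
        warnings.warn(
            "calibration features are effectively rank-deficient; "
            "second component is arbitrary within the null space",
            stacklevel=2,
        )
    components = vt[:2].copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0

    proj = centered @ components.T
    centroids = np.vstack([proj[labs == 1].mean(axis=0), proj[labs == 2].mean(axis=0)])
    points = [(MovementClass(l), (float(p[0]), float(p[1]))) for l, p in zip(labs, proj)]
    return PcaModel(mean=mean, components=components, centroids=centroids,
                    calibration_points=points)


def classify(theta_new: MovementFeature | np.ndarray, model: PcaModel) -> Classification:
    """Project a new feature and label it by the nearest class centroid.

    Every movement is assigned a class; ties go to class 1.  (An optional
    reject radius could be layered on top, but by default there is no
    "do nothing" class.)
    """
    theta = theta_new.theta if isinstance(theta_new, MovementFeature) else theta_new
    point = model.project(theta)
    dists = np.linalg.norm(model.centroids - point, axis=1)
    label = MovementClass.CLASS1 if dists[0] <= dists[1] else MovementClass.CLASS2
    return Classification(label=label, point=point, distances=dists)


def calibrate_imu(
    stream: ImuStream,
    truth_times: Sequence[float],
    truth_labels: Sequence[MovementClass | int],
    match_tolerance: float = 0.75,
) -> tuple[ActivationThresholds, PcaModel]:
    """Fit thresholds and classifier from a labelled calibration session.

    ``truth_times`` are the instructed movement center times; each detected
    onset is labelled by the nearest instructed movement within
    ``match_tolerance`` seconds (unmatched onsets are dropped).
    """
    X = differentiate(stream)
    alpha = compute_thresholds(X)
    onsets = detect_movement(X, alpha)
    feats, labs = [], []
    truth_times = np.asarray(truth_times, dtype=float)
    for k in onsets:
        t = X.timestamps[k]
        j = int(np.argmin(np.abs(truth_times - t)))
        if abs(truth_times[j] - t) <= match_tolerance:
            feats.append(extract_feature(X, k, allow_truncated=True))
            labs.append(int(truth_labels[j]))
    model = fit_classifier(feats, labs)
    return alpha, model


def decode_imu(
    stream: ImuStream,
    model: PcaModel,
    alpha: ActivationThresholds,
    window: float = FEATURE_WINDOW_S,
    refractory: float = ONSET_REFRACTORY_S,
    initial: HandState = HandState.RS,
) -> list[TransitionEvent]:
    """Full chain: difference -> detect -> feature -> classify -> state machine.

    Each event's trigger payload records the projected 2-D point and the
    distances to both centroids; event times are decision-emission times
    (trailing edge of the RMS window).
    """
    X = differentiate(stream)
    triggers = []
    for k in detect_movement(X, alpha, refractory=refractory):
        try:
            feat = extract_feature(X, k, window=window)
        except ValueError:
            continue  # window not yet complete at stream end
        res = classify(feat, model)
        triggers.append(
            MovementTrigger(
                time=feat.decision_time,
                movement=res.label,
                point=(float(res.point[0]), float(res.point[1])),
                distances=(float(res.distances[0]), float(res.distances[1])),
            )
        )
    triggers.sort(key=lambda tr: tr.time)
    return run_session(initial, triggers, Modality.IMU)
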