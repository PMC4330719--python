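"""Band-pass filtering, bad-channel rejection, and artifact subspace
reconstruction (ASR).

All quality-control statistics are meant to be fitted on a training span and
applied unchanged to held-out data; the functions here are span-agnostic and
the train/test contract is enforced by the pipeline orchestration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synth import Recording

__all__ = [
    "FilterSpec",
    "BadChannelCriteria",
    "AsrModel",
    "design_fir_bandpass",
    "apply_filter",
    "detect_bad_channels",
    "select_calibration_mask",
    "asr_fit",
    "asr_process",
]


@dataclass
class FilterSpec:
    """Linear-phase FIR band-pass filter (windowed sinc)."""

    low_hz: float
    high_hz: float
    order: int
    fs: float
    coefficients: np.ndarray

    @property
    def group_delay_samples(self) -> int:
        return self.order // 2


def design_fir_bandpass(low_hz: float = 2.0, high_hz: float = 30.0,
                        order: int = 496, fs: float = 300.0) -> FilterSpec:
    """Design an even-order, linear-phase windowed-sinc band-pass filter.

    The even order gives an integer group delay of ``order/2`` samples and
    symmetric taps (type-I linear phase).
    """
    if order % 2 != 0:
        raise ValueError(f"order must be even for integer group delay, got {order}")
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")
    taps = sps.firwin(order + 1, [low_hz, high_hz], pass_zero=False,
                      window="hamming", fs=fs)
    return FilterSpec(low_hz=low_hz, high_hz=high_hz, order=order, fs=fs,
                      coefficients=taps)


def filter_array(spec: FilterSpec, data: np.ndarray) -> np.ndarray:
    """Zero-phase (forward-backward) filtering along the last axis.

    Edges are padded by reflection.  Requires the signal to be longer than
    three filter lengths so the edge transients are absorbed by the padding.
    """
    n = data.shape[-1]
    ntaps = len(spec.coefficients)
    if n <= 3 * ntaps:
        raise ValueError(
            f"signal of {n} samples is shorter than 3x the filter length "
            f"({3 * ntaps}); cannot filter"
        )
    return sps.filtfilt(spec.coefficients, [1.0], data, axis=-1,
                        padtype="even", padlen=3 * ntaps)


def apply_filter(spec: FilterSpec, recording: Recording) -> Recording:
    """Filter every channel of a recording; events pass through unchanged."""
    if recording.fs != spec.fs:
        raise ValueError(
            f"filter designed for fs={spec.fs} applied to fs={recording.fs}"
        )
    return recording.copy_with(data=filter_array(spec, recording.data))


@dataclass
class BadChannelCriteria:
    """Thresholds of the four channel-rejection rules.

    1. maximum absolute amplitude above ``max_amp_uv``;
    2. flatline (sample-to-sample change below ``flat_eps_uv``) lasting
       longer than ``flatline_s``;
    3. median windowed correlation with the channel's ridge-regression
       prediction from all other channels below ``min_robust_corr``;
    4. line-noise score (high-/low-band RMS ratio, split at 45 Hz) more than
       ``line_noise_sd`` standard deviations above the channel-population
       mean.
    """

    max_amp_uv: float = 100.0
    flatline_s: float = 5.0
    min_robust_corr: float = 0.8
    line_noise_sd: float = 4.0
    window_s: float = 1.0
    flat_eps_uv: float = 1e-6
    ridge_rel: float = 1e-3  # ridge weight relative to mean channel variance

    def __post_init__(self) -> None:
        if not 0 < self.min_robust_corr <= 1:
            raise ValueError("min_robust_corr must lie in (0, 1]")
        for name in ("max_amp_uv", "flatline_s", "line_noise_sd", "window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _longest_flat_run(x: np.ndarray, eps: float) -> int:
    """Longest run of consecutive samples with |diff| < eps, in samples."""
    flat = np.abs(np.diff(x)) < eps
    if not flat.any():
        return 1
    # lengths of runs of True in `flat`; a run of k True diffs spans k+1 samples
    edges = np.diff(np.concatenate(([0], flat.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max()) + 1


def _robust_correlations(data: np.ndarray, window: int, ridge_rel: float) -> np.ndarray:
    """Median over windows of corr(channel, ridge prediction from others)."""
    n_ch, n = data.shape
    n_win = n // window
    corrs = np.full((n_ch, n_win), np.nan)
    for w in range(n_win):
        X = data[:, w * window:(w + 1) * window]
        X = X - X.mean(axis=1, keepdims=True)
        cov = (X @ X.T) / window
        lam = ridge_rel * np.mean(np.diag(cov))
        for i in range(n_ch):
            idx = np.arange(n_ch) != i
            A = cov[np.ix_(idx, idx)] + lam * np.eye(n_ch - 1)
            b = cov[idx, i]
            try:
                wgt = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                continue
            num = wgt @ b
            den = np.sqrt(max(wgt @ cov[np.ix_(idx, idx)] @ wgt, 0.0) * cov[i, i])
            corrs[i, w] = num / den if den > 0 else 0.0
    return np.nanmedian(corrs, axis=1)


def _line_noise_scores(data: np.ndarray, fs: float) -> np.ndarray | None:
    """RMS(high band)/RMS(low band) per channel, split at 45 Hz."""
    if fs / 2 <= 45.0:
        return None
    b, a = sps.butter(4, 45.0, btype="lowpass", fs=fs)
    low = sps.filtfilt(b, a, data, axis=-1)
    rms_low = np.sqrt(np.mean(low**2, axis=-1))
    rms_high = np.sqrt(np.mean((data - low) ** 2, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(rms_low > 0, rms_high / rms_low, np.inf)
    return score


def detect_bad_channels(
    recording: Recording,
    criteria: BadChannelCriteria | None = None,
    return_reasons: bool = False,
):
    """Apply the four rejection rules; return flagged channel labels.

    With ``return_reasons=True`` additionally returns a mapping
    ``label -> list of rule names``.
    """
    crit = criteria or BadChannelCriteria()
    data, fs = recording.data, recording.fs
    n_ch, n = data.shape
    if n_ch < 8:
        raise ValueError("robust-correlation rule needs at least 8 channels")
    window = int(round(crit.window_s * fs))
    if n < window:
        raise ValueError("recording shorter than one correlation window")

    reasons: dict[str, list[str]] = {l: [] for l in recording.channel_labels}

    amp = np.abs(data).max(axis=1)
    flat = np.array([_longest_flat_run(ch, crit.flat_eps_uv) for ch in data])
    corr = _robust_correlations(data, window, crit.ridge_rel)
    line = _line_noise_scores(data, fs)

    for i, label in enumerate(recording.channel_labels):
        if amp[i] > crit.max_amp_uv:
            reasons[label].append("amplitude")
        if flat[i] > crit.flatline_s * fs:
            reasons[label].append("flatline")
        if corr[i] < crit.min_robust_corr:
            reasons[label].append("correlation")
    if line is not None:
        mu, sd = line.mean(), line.std()
        if sd > 0:
            z = (line - mu) / sd
            for i, label in enumerate(recording.channel_labels):
                if z[i] > crit.line_noise_sd:
                    reasons[label].append("line_noise")

    bad = [l for l in recording.channel_labels if reasons[l]]
    if return_reasons:
        return bad, {l: r for l, r in reasons.items() if r}
    return bad


def select_calibration_mask(
    recording: Recording,
    z_bounds: tuple[float, float] = (-3.5, 5.5),
    window_s: float = 1.0,
    min_clean_s: float = 30.0,
    channel_fraction: float = 0.9375,
) -> np.ndarray:
    """Boolean sample mask of artifact-light windows for ASR calibration.

    A window is kept when, for at least ``channel_fraction`` of the channels,
    the robust z-score (median/MAD across windows) of its RMS lies inside
    ``z_bounds``.
    """
    data, fs = recording.data, recording.fs
    n_ch, n = data.shape
    window = int(round(window_s * fs))
    n_win = n // window
    if n_win < 1:
        raise ValueError("recording shorter than one calibration window")

    seg = data[:, : n_win * window].reshape(n_ch, n_win, window)
    rms = np.sqrt(np.mean(seg**2, axis=2))  # channels x windows
    med = np.median(rms, axis=1, keepdims=True)
    mad = np.median(np.abs(rms - med), axis=1, keepdims=True) * 1.4826
    mad = np.where(mad > 0, mad, 1e-12)
    z = (rms - med) / mad
    ok = (z > z_bounds[0]) & (z < z_bounds[1])
    clean_win = ok.mean(axis=0) >= channel_fraction

    mask = np.zeros(n, dtype=bool)
    for w in np.flatnonzero(clean_win):
        mask[w * window:(w + 1) * window] = True
    clean_s = mask.sum() / fs
    if clean_s < min_clean_s:
        raise ValueError(
            f"only {clean_s:.1f} s of clean calibration data "
            f"({mask.mean():.1%} of the recording); need {min_clean_s:.0f} s"
        )
    return mask


@dataclass
class AsrModel:
    """Calibration statistics of artifact subspace reconstruction.

    ``mixing_sqrt`` is the principal square root of the robust calibration
    covariance; ``thresholds`` are mean + cutoff*SD of calibration RMS
    projected on the calibration eigendirections (columns of
    ``calib_eigvecs``).
    """

    mixing_sqrt: np.ndarray
    calib_eigvecs: np.ndarray
    thresholds: np.ndarray
    cutoff: float = 5.0
    window_s: float = 0.5
    window_step_s: float = 0.25
    fs: float = 300.0
    channel_labels: tuple[str, ...] = field(default_factory=tuple)


def asr_fit(
    calibration: np.ndarray | Recording,
    fs: float | None = None,
    cutoff: float = 5.0,
    window_s: float = 0.5,
    window_step_s: float = 0.25,
) -> AsrModel:
    """Fit ASR statistics from clean calibration data.

    The robust covariance is the elementwise median of per-window sample
    covariances; per-direction burst thresholds come from the distribution of
    windowed RMS in the calibration eigenbasis.
    """
    labels: tuple[str, ...] = ()
    if isinstance(calibration, Recording):
        labels = calibration.channel_labels
        fs = calibration.fs
        calibration = calibration.data
    if fs is None:
        raise ValueError("fs is required when calibration is a bare array")
    data = np.asarray(calibration, dtype=float)
    n_ch, n = data.shape
    window = int(round(window_s * fs))
    n_win = n // window
    if n_win * window_s < 30.0:
        raise ValueError(
            f"calibration spans {n / fs:.1f} s; at least 30 s are required"
        )

    seg = data[:, : n_win * window].reshape(n_ch, n_win, window)
    covs = np.einsum("iwt,jwt->wij", seg, seg) / window
    robust_cov = np.median(covs, axis=0)

    diag = np.diag(robust_cov)
    if np.any(diag <= diag.max() * 1e-12):
        degenerate = np.flatnonzero(diag <= diag.max() * 1e-12)
        name = [labels[i] if labels else str(i) for i in degenerate]
        raise ValueError(
            f"rank-deficient calibration covariance; channels {name} carry "
            f"no variance — remove flat/duplicated channels first"
        )
    evals, evecs = np.linalg.eigh(robust_cov)
    # the elementwise median of PSD matrices can leave the PSD cone; clip
    # small/negative eigenvalues so the principal square root exists
    evals = np.maximum(evals, evals.max() * 1e-9)
    mixing_sqrt = (evecs * np.sqrt(evals)) @ evecs.T

    proj = np.einsum("dc,cwt->dwt", evecs.T, seg)  # directions x windows x t
    rms = np.sqrt(np.mean(proj**2, axis=2))        # directions x windows
    thresholds = rms.mean(axis=1) + cutoff * rms.std(axis=1)
    thresholds = np.maximum(thresholds, 1e-12)
    return AsrModel(mixing_sqrt=mixing_sqrt, calib_eigvecs=evecs,
                    thresholds=thresholds, cutoff=cutoff, window_s=window_s,
                    window_step_s=window_step_s, fs=fs, channel_labels=labels)


def asr_process(model: AsrModel, recording: Recording | np.ndarray) -> Recording | np.ndarray:
    """Reconstruct burst-contaminated subspaces window by window.

    Each sliding window is eigendecomposed; directions whose RMS exceeds the
    calibration threshold mapped into the window basis are zeroed and the
    data reprojected through the calibration mixing matrix.  Overlapping
    windows are blended with a raised-cosine ramp.
    """
    is_rec = isinstance(recording, Recording)
    data = recording.data if is_rec else np.asarray(recording, dtype=float)
    n_ch, n = data.shape
    if n_ch != model.mixing_sqrt.shape[0]:
        raise ValueError("channel count does not match the fitted ASR model")

    window = int(round(model.window_s * model.fs))
    step = max(int(round(model.window_step_s * model.fs)), 1)
    if n < window:
        return recording.copy_with(data=data.copy()) if is_rec else data.copy()

    M = model.mixing_sqrt
    Vc = model.calib_eigvecs
    t = model.thresholds
    # calibration thresholds carried into an arbitrary window basis:
    # thr_d^2 = sum_j (t_j * <v_c_j, v_d>)^2
    TVc = Vc * t  # columns scaled by thresholds

    starts = list(range(0, n - window + 1, step))
    if starts[-1] != n - window:
        starts.append(n - window)
    ramp = np.hanning(window + 2)[1:-1]

    out = np.zeros_like(data)
    weight = np.zeros(n)
    for s in starts:
        X = data[:, s:s + window]
        cov = (X @ X.T) / window
        evals, V = np.linalg.eigh(cov)
        rms = np.sqrt(np.maximum(evals, 0.0))
        thr = np.sqrt(np.sum((TVc.T @ V) ** 2, axis=0))
        keep = rms <= thr
        if keep.all():
            Xc = X
        else:
            T2 = V.T @ M                   # window basis -> calibration sqrt
            T2[~keep, :] = 0.0
            R = M @ np.linalg.pinv(T2) @ V.T
            Xc = R @ X
        out[:, s:s + window] += Xc * ramp
        weight[s:s + window] += ramp

    nz = weight > 1e-12
    out[:, nz] /= weight[nz]
    out[:, ~nz] = data[:, ~nz]
    if is_rec:
        return recording.copy_with(data=out)
    return out
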