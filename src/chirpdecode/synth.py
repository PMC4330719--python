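"""Synthetic EEG sessions with known ground truth.

Emulates a passive auditory-probe protocol: a short chirp sound presented a
few hundred times separated by random silences, with an equal number of
silent control epochs extracted from the gaps.  The recording is built from
an explicit linear mixing model (sources x smooth topographies) so that every
downstream stage — bad-channel rejection, artifact subspace reconstruction,
ICA, Kalman ERP estimation, classification — can be validated against the
generating truth.

Sources emulated: an evoked N100/P300 response with trial-to-trial latency
and amplitude variability, 1/f background and 10 Hz alpha, frontal blink
transients, 20-80 Hz muscle bursts, a low-frequency vibration component, an
optional mains sinusoid, and independent per-channel sensor noise.  Channels
can additionally be overwritten with planted faults (flatline, high-amplitude
excursions, decorrelated noise) to exercise quality-control rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

CHIRP = "chirp"
SILENT = "silent"

__all__ = [
    "Event",
    "EventList",
    "SessionConfig",
    "Recording",
    "GroundTruth",
    "generate_events",
    "canonical_erp",
    "simulate_recording",
]


@dataclass(frozen=True)
class Event:
    """A labeled trial onset in sample units (0-based)."""

    onset_sample: int
    label: str

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise ValueError(f"onset_sample must be >= 0, got {self.onset_sample}")
        if self.label not in (CHIRP, SILENT):
            raise ValueError(f"label must be {CHIRP!r} or {SILENT!r}, got {self.label!r}")


@dataclass(frozen=True)
class EventList:
    """Ordered trial onsets with the sampling rate they refer to."""

    events: tuple[Event, ...]
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for lab in (CHIRP, SILENT):
            on = self.onsets(lab)
            if np.any(np.diff(on) <= 0):
                raise ValueError(f"{lab} onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def onsets(self, label: str | None = None) -> np.ndarray:
        """Onset samples, optionally restricted to one label."""
        return np.array(
            [e.onset_sample for e in self.events if label is None or e.label == label],
            dtype=int,
        )

    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.events])


@dataclass
class SessionConfig:
    """Parameters of one synthetic session.

    ``erp_snr`` is the ratio of ERP RMS (within chirp epochs) to background
    RMS, both measured at the channel where the ERP topography peaks.  May be
    ``np.inf`` for a noise-free session.  ``artifact_severity`` selects the
    "off" (bench-quiet) or "on" (in-operation) artifact regime.
    """

    n_channels: int = 64
    fs: float = 300.0
    n_chirp: int = 200
    chirp_dur_s: float = 0.1
    isi_min_s: float = 0.6
    isi_max_s: float = 2.5
    epoch_s: float = 0.5
    erp_snr: float = 0.2
    artifact_severity: str = "off"
    latency_jitter_s: float = 0.010
    amplitude_jitter: float = 0.20
    planted_bad_channels: Sequence[tuple[int, str]] = field(default_factory=tuple)
    line_freq_hz: float | None = 60.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.isi_min_s <= self.isi_max_s:
            raise ValueError("need 0 < isi_min_s <= isi_max_s")
        if self.erp_snr < 0:
            raise ValueError("erp_snr must be >= 0")
        if self.artifact_severity not in ("off", "on"):
            raise ValueError("artifact_severity must be 'off' or 'on'")
        idx = [c for c, _ in self.planted_bad_channels]
        if len(idx) != len(set(idx)):
            raise ValueError("planted bad-channel indices collide")
        for c, kind in self.planted_bad_channels:
            if not 0 <= c < self.n_channels:
                raise ValueError(f"planted channel {c} out of range")
            if kind not in ("flatline", "high_amplitude", "decorrelated"):
                raise ValueError(f"unknown bad-channel kind {kind!r}")


@dataclass
class Recording:
    """Multichannel EEG in microvolts with its event table."""

    data: np.ndarray  # channels x samples
    fs: float
    channel_labels: tuple[str, ...]
    events: EventList

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray | None = None,
                  channel_labels: Sequence[str] | None = None,
                  events: EventList | None = None) -> "Recording":
        return Recording(
            data=self.data.copy() if data is None else data,
            fs=self.fs,
            channel_labels=tuple(self.channel_labels if channel_labels is None
                                 else channel_labels),
            events=self.events if events is None else events,
        )

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Sub-recording restricted to the given channels, order preserved."""
        idx = [self.channel_labels.index(l) for l in labels]
        return self.copy_with(data=self.data[idx].copy(), channel_labels=labels)

    def drop(self, labels: Sequence[str]) -> "Recording":
        keep = [l for l in self.channel_labels if l not in set(labels)]
        return self.pick(keep)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    mixing: np.ndarray                 # channels x sources
    sources: np.ndarray                # sources x samples
    source_names: tuple[str, ...]
    erp_waveform_per_trial: np.ndarray  # trials x epoch samples (source scale)
    bad_channels: tuple[tuple[int, str], ...]
    jitters: dict                      # latency_samples, amplitude (per trial)


def generate_events(
    n_chirp: int = 200,
    isi_min_s: float = 0.6,
    isi_max_s: float = 2.5,
    chirp_dur_s: float = 0.1,
    epoch_s: float = 0.5,
    fs: float = 300.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    lead_in_s: float = 2.0,
    tail_s: float = 2.0,
) -> EventList:
    """Draw a chirp/silent event schedule.

    Chirp-to-chirp silences (onset-to-onset gap minus the chirp duration) are
    drawn Uniform[isi_min_s, isi_max_s].  An equal number of silent control
    epochs of length ``epoch_s`` is placed uniformly inside the silences so
    that no silent epoch overlaps a chirp epoch or another silent epoch.

    Raises ``ValueError`` when the silences cannot host ``n_chirp``
    non-overlapping silent epochs, naming the deficit.
    """
    if n_chirp < 1:
        raise ValueError("n_chirp must be >= 1")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not 0 < isi_min_s <= isi_max_s:
        raise ValueError("need 0 < isi_min_s <= isi_max_s")
    if rng is None:
        rng = np.random.default_rng(seed)

    L = int(round(epoch_s * fs))  # epoch length in samples
    silences = rng.uniform(isi_min_s, isi_max_s, size=n_chirp - 1)
    chirp_onsets = np.empty(n_chirp, dtype=int)
    chirp_onsets[0] = int(round(lead_in_s * fs))
    for i, sil in enumerate(silences):
        chirp_onsets[i + 1] = chirp_onsets[i] + int(round((chirp_dur_s + sil) * fs))

    n_samples = chirp_onsets[-1] + L + int(round(tail_s * fs))

    # Candidate start-sample ranges [lo, hi] for silent epochs: before the
    # first chirp epoch, between consecutive chirp epochs, and after the last.
    ranges: list[tuple[int, int]] = []
    lo = 0
    for on in chirp_onsets:
        hi = on - L
        if hi >= lo:
            ranges.append((lo, hi))
        lo = on + L
    hi = n_samples - L
    if hi >= lo:
        ranges.append((lo, hi))

    caps = np.array([(hi - lo) // L + 1 for lo, hi in ranges], dtype=int)
    total = int(caps.sum())
    if total < n_chirp:
        raise ValueError(
            f"cannot place {n_chirp} silent epochs: silences host at most "
            f"{total} (deficit {n_chirp - total}); lengthen the session or "
            f"shorten epoch_s"
        )

    # Choose which slot of which gap hosts a silent epoch, uniformly over the
    # capacity multiset, then place epochs inside each gap by stick-breaking.
    slot_owner = np.repeat(np.arange(len(ranges)), caps)
    chosen = rng.permutation(slot_owner)[:n_chirp]
    counts = np.bincount(chosen, minlength=len(ranges))

    silent_onsets: list[int] = []
    for (lo, hi), c in zip(ranges, counts):
        if c == 0:
            continue
        slack = (hi - lo) - (c - 1) * L
        offs = np.sort(rng.integers(0, slack + 1, size=c))
        for j, off in enumerate(offs):
            silent_onsets.append(int(lo + off + j * L))

    events = sorted(
        [Event(int(o), CHIRP) for o in chirp_onsets]
        + [Event(o, SILENT) for o in silent_onsets],
        key=lambda e: (e.onset_sample, e.label),
    )
    return EventList(events=tuple(events), fs=fs)


def canonical_erp(
    fs: float = 300.0,
    epoch_s: float = 0.5,
    amp_early: float = -1.0,
    amp_late: float = 1.0,
    tau_early_s: float = 0.050,
    tau_late_s: float = 0.150,
) -> np.ndarray:
    """Two-wave auditory ERP template on the epoch grid.

    Each wave is a third-order gamma kernel h(t; tau) = t^2 exp(-t/tau),
    normalized to unit peak magnitude (the continuous peak (2*tau)^2 e^-2 at
    t = 2*tau), so the early wave peaks at 2*tau_early_s (100 ms by default,
    negative — the N100) and the late wave at 2*tau_late_s (300 ms, positive —
    the P300).
    """
    if tau_early_s <= 0 or tau_late_s <= 0:
        raise ValueError("time constants must be positive")
    t = np.arange(int(round(epoch_s * fs))) / fs

    def wave(tau: float) -> np.ndarray:
        peak = (2 * tau) ** 2 * np.exp(-2.0)
        return t**2 * np.exp(-t / tau) / peak

    return amp_early * wave(tau_early_s) + amp_late * wave(tau_late_s)


def _one_over_f(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with ~1/f power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** -0.5
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _narrowband(n: int, fs: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    b, a = sps.butter(4, [lo, hi], btype="bandpass", fs=fs)
    x = sps.lfilter(b, a, rng.standard_normal(n))
    return x / x.std()


def _bump_topography(pos: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((pos - center) ** 2) / (2 * width**2))


def _smooth_random_topography(pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    t = np.zeros_like(pos)
    for _ in range(2):
        t += rng.normal() * _bump_topography(
            pos, rng.uniform(0, 1), rng.uniform(0.15, 0.4)
        )
    m = np.abs(t).max()
    return t / m if m > 0 else t + 1.0


# artifact regime presets (amplitudes in microvolts, rates per minute)
_SEVERITY = {
    "off": dict(blink_peak=60.0, blink_rate=4.0, muscle_rms=30.0,
                muscle_rate=6.0, vib_rms=5.0, line_rms=1.0),
    "on": dict(blink_peak=150.0, blink_rate=12.0, muscle_rms=100.0,
               muscle_rate=20.0, vib_rms=20.0, line_rms=2.0),
}

_BG_RMS_UV = 10.0       # background RMS at the best ERP channel
_SENSOR_RMS_UV = 0.7    # per-channel instrumentation noise floor
_ERP_PEAK_UV = 5.0      # best-channel ERP peak in the noise-free limit


def simulate_recording(config: SessionConfig) -> tuple[Recording, GroundTruth]:
    """Generate one session and its generating ground truth.

    The recording is ``mixing @ sources`` exactly, after which planted bad
    channels (if any) overwrite their rows.  All channel data are microvolts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs

    events = generate_events(
        n_chirp=cfg.n_chirp, isi_min_s=cfg.isi_min_s, isi_max_s=cfg.isi_max_s,
        chirp_dur_s=cfg.chirp_dur_s, epoch_s=cfg.epoch_s, fs=fs, rng=rng,
    )
    L = int(round(cfg.epoch_s * fs))
    chirp_onsets = events.onsets(CHIRP)
    n = int(chirp_onsets[-1] + L + round(2.0 * fs))
    if n <= 0:
        raise ValueError("zero-duration session")

    pos = (np.linspace(0.0, 1.0, cfg.n_channels) if cfg.n_channels > 1
           else np.array([0.3]))
    # erp_snr = inf is the noise-free limit: evoked activity only
    noise_free = not np.isfinite(cfg.erp_snr)
    sev = _SEVERITY[cfg.artifact_severity]
    if noise_free:
        sev = {k: 0.0 for k in sev}

    names: list[str] = []
    topos: list[np.ndarray] = []
    waves: list[np.ndarray] = []
    gains: list[float] = []

    # --- evoked source: jittered template train at chirp onsets -------------
    template = canonical_erp(fs=fs, epoch_s=cfg.epoch_s)
    lat_jit = np.round(
        rng.normal(0.0, cfg.latency_jitter_s * fs, size=len(chirp_onsets))
    ).astype(int)
    amp_jit = 1.0 + rng.normal(0.0, cfg.amplitude_jitter, size=len(chirp_onsets))
    erp_src = np.zeros(n)
    per_trial = np.zeros((len(chirp_onsets), L))
    for i, (on, dl, am) in enumerate(zip(chirp_onsets, lat_jit, amp_jit)):
        start = int(on + dl)
        sl = slice(max(start, 0), min(start + L, n))
        seg = template[(sl.start - start):(sl.stop - start)]
        erp_src[sl] += am * seg
        per_trial[i, :sl.stop - sl.start] = am * seg  # contribution inside epoch
    erp_topo = _bump_topography(pos, 0.3, 0.2)
    best = int(np.argmax(erp_topo))

    # --- background: 1/f processes + alpha ----------------------------------
    n_bg = max(4, cfg.n_channels // 8)
    bg_topos = [_smooth_random_topography(pos, rng) for _ in range(n_bg)]
    bg_waves = [_one_over_f(n, rng) for _ in range(n_bg)]
    alpha_topo = _smooth_random_topography(pos, rng)
    alpha_wave = _narrowband(n, fs, 8.0, 12.0, rng)
    bg_topos.append(alpha_topo)
    bg_waves.append(alpha_wave)
    # scale the set so combined background RMS at the best ERP channel is fixed
    denom = np.sqrt(sum(t[best] ** 2 for t in bg_topos))
    bg_gain = 0.0 if (denom == 0 or noise_free) else _BG_RMS_UV / denom
    for j, (t, w) in enumerate(zip(bg_topos, bg_waves)):
        names.append("alpha" if j == n_bg else f"background_{j}")
        topos.append(t)
        waves.append(w)
        gains.append(bg_gain)

    # --- evoked gain from the requested SNR ---------------------------------
    epoch_mask = np.zeros(n, dtype=bool)
    for on in chirp_onsets:
        epoch_mask[on:on + L] = True
    erp_unit_rms = np.sqrt(np.mean((erp_topo[best] * erp_src[epoch_mask]) ** 2))
    if noise_free:
        erp_gain = _ERP_PEAK_UV / (erp_topo[best] * np.abs(template).max())
    elif erp_unit_rms == 0:
        erp_gain = 0.0
    else:
        erp_gain = cfg.erp_snr * _BG_RMS_UV / erp_unit_rms
    names.insert(0, "erp")
    topos.insert(0, erp_topo)
    waves.insert(0, erp_src)
    gains.insert(0, erp_gain)

    # --- artifacts -----------------------------------------------------------
    dur_min = n / fs / 60.0
    blink = np.zeros(n)
    n_blinks = rng.poisson(sev["blink_rate"] * dur_min)
    bw = int(round(0.4 * fs))
    bshape = np.exp(-((np.arange(bw) - bw / 2) ** 2) / (2 * (0.08 * fs) ** 2))
    for start in rng.integers(0, max(n - bw, 1), size=n_blinks):
        blink[start:start + bw] += bshape[: n - start]
    names.append("blink")
    topos.append(_bump_topography(pos, 0.0, 0.1))
    waves.append(blink)
    gains.append(sev["blink_peak"])

    for m in range(2):
        musc = np.zeros(n)
        n_bursts = rng.poisson(sev["muscle_rate"] * dur_min / 2)
        for _ in range(n_bursts):
            bl = int(round(rng.uniform(0.3, 1.0) * fs))
            start = int(rng.integers(0, max(n - bl, 1)))
            burst = _narrowband(max(bl, int(fs)), fs, 20.0,
                                min(80.0, 0.45 * fs), rng)[:bl]
            musc[start:start + bl] += burst * np.hanning(bl)[: n - start]
        names.append(f"muscle_{m}")
        topos.append(_bump_topography(pos, float(rng.choice([0.05, 0.95])), 0.08))
        waves.append(musc)
        gains.append(sev["muscle_rms"])

    # vibration couples mainly into a patch of poorly seated sensors
    names.append("vibration")
    topos.append(0.2 + 0.8 * _bump_topography(pos, rng.uniform(0, 1), 0.25))
    waves.append(_narrowband(n, fs, 3.0, 8.0, rng))
    gains.append(sev["vib_rms"])

    if cfg.line_freq_hz is not None and cfg.line_freq_hz < fs / 2:
        t = np.arange(n) / fs
        wave = np.sqrt(2.0) * np.sin(2 * np.pi * cfg.line_freq_hz * t + rng.uniform(0, 2 * np.pi))
        names.append("line")
        topos.append(np.abs(_smooth_random_topography(pos, rng)) * 0.5 + 0.5)
        waves.append(wave)
        gains.append(sev["line_rms"])

    # --- per-channel sensor noise -------------------------------------------
    sensor_gain = 0.0 if noise_free else _SENSOR_RMS_UV
    for c in range(cfg.n_channels):
        names.append(f"sensor_{c}")
        topo = np.zeros(cfg.n_channels)
        topo[c] = 1.0
        topos.append(topo)
        waves.append(rng.standard_normal(n))
        gains.append(sensor_gain)

    mixing = np.column_stack(topos) * np.asarray(gains)
    sources = np.vstack(waves)
    data = mixing @ sources

    # --- planted bad channels overwrite mixed data --------------------------
    for ch, kind in cfg.planted_bad_channels:
        if kind == "flatline":
            data[ch] = 0.0
        elif kind == "high_amplitude":
            t = np.arange(n) / fs
            data[ch] = data[ch] + 350.0 * np.sin(2 * np.pi * 5.0 * t)
        elif kind == "decorrelated":
            data[ch] = 10.0 * _one_over_f(n, rng)

    labels = tuple(f"EEG{c:02d}" for c in range(cfg.n_channels))
    rec = Recording(data=data, fs=fs, channel_labels=labels, events=events)
    gt = GroundTruth(
        mixing=mixing,
        sources=sources,
        source_names=tuple(names),
        erp_waveform_per_trial=erp_gain * per_trial,
        bad_channels=tuple(cfg.planted_bad_channels),
        jitters={"latency_samples": lat_jit, "amplitude": amp_jit},
    )
    return rec, gt
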