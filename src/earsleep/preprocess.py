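"""Signal conditioning, artifact detection and recording-level QC.

The cleaning recipe for each channel:

1. zero-phase bandpass 0.1–100 Hz plus 50/100 Hz notches,
2. four artifact detectors run in precedence order —
   periodic device spikes (200 ms repetition), short transient spikes,
   long (>30 s) high-frequency noise, and samples beyond 350 uV,
3. spike-type artifacts (periodic + transient) are removed and the gap
   linearly interpolated from the neighbouring clean samples; HF and
   amplitude artifacts stay masked and are never repaired,
4. per-epoch per-channel validity flags feed channel selection, and a
   recording is rejected outright when more than 30% of the signal is
   noisy or the recording is shorter than 5 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps

from .io_core import DATA_CHANNELS, RawRecording
from .synthetic import ARTIFACT_CATEGORIES, CAT_TO_INT


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters (units in names)."""

    band_hz: tuple[float, float] = (0.1, 100.0)
    notch_hz: tuple[float, ...] = (50.0, 100.0)
    periodic_period_s: float = 0.2
    periodic_min_train: int = 3  # spikes in a row to call it device noise
    amp_threshold_uv: float = 350.0
    hf_min_duration_s: float = 30.0
    hf_band_hz: tuple[float, float] = (40.0, 100.0)
    hf_threshold_factor: float = 5.0  # x median 1 s-window HF power
    spike_mad_factor: float = 8.0
    spike_candidate_mad_factor: float = 6.0  # on the highpass residual, for periodic grouping
    spike_max_duration_s: float = 0.1
    spike_guard_s: float = 0.02
    reject_noisy_fraction: float = 0.30
    min_duration_h: float = 5.0
    epoch_len_s: float = 30.0
    epoch_hard_fraction: float = 0.10  # max non-repaired (hf/amplitude) fraction
    epoch_any_fraction: float = 0.25  # max any-artifact fraction

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError(f"bad bandpass {self.band_hz}")


@dataclass
class ArtifactMask:
    """Per-channel per-sample artifact category codes (see ARTIFACT_CATEGORIES)."""

    codes: dict[str, np.ndarray]

    def fraction(self, channel: str, categories: tuple[str, ...] | None = None) -> float:
        m = self.codes[channel]
        if len(m) == 0:
            return 0.0
        if categories is None:
            return float(np.mean(m != 0))
        sel = np.isin(m, [CAT_TO_INT[c] for c in categories])
        return float(np.mean(sel))


@dataclass
class EpochValidity:
    """Per-channel, per-epoch usability flags derived from the mask."""

    valid: dict[str, np.ndarray]  # bool per epoch
    masked_fraction: dict[str, np.ndarray]  # any-category fraction per epoch

    @property
    def n_epochs(self) -> int:
        return len(next(iter(self.valid.values())))


@dataclass
class QCReport:
    """Recording-level quality summary and accept/reject verdict."""

    per_channel_fraction: dict[str, dict[str, float]]  # channel -> category -> fraction
    overall_rejected_fraction: float  # non-repaired (hf + amplitude) mean over channels
    overall_noisy_fraction: float  # any-category mean over channels
    repaired_fraction: float  # interpolated (periodic + spike) mean over channels
    duration_h: float
    noisy_threshold: float = 0.30
    min_duration_h: float = 5.0
    accepted: bool = field(init=False)
    reason: str = field(init=False, default="")

    def __post_init__(self) -> None:
        self.accepted = True
        reasons = []
        if self.overall_noisy_fraction > self.noisy_threshold:
            self.accepted = False
            reasons.append(
                f"more than {self.noisy_threshold:.0%} of the signal was noisy"
            )
        if self.duration_h < self.min_duration_h:
            self.accepted = False
            reasons.append(
                f"duration of the recording was less than {self.min_duration_h:g} h"
            )
        self.reason = "; ".join(reasons)

    def to_dict(self) -> dict:
        return {
            "per_channel_fraction": self.per_channel_fraction,
            "overall_rejected_fraction": self.overall_rejected_fraction,
            "overall_noisy_fraction": self.overall_noisy_fraction,
            "repaired_fraction": self.repaired_fraction,
            "duration_h": self.duration_h,
            "accepted": self.accepted,
            "reason": self.reason,
        }


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def apply_filters(rec: RawRecording, cfg: PreprocessConfig | None = None) -> RawRecording:
    """Zero-phase bandpass + notch filtering of all channels.

    4th-order Butterworth bandpass and 2nd-order IIR notches, both
    applied forward-backward (`sosfiltfilt`/`filtfilt`) so the output
    is phase-neutral and the DC offset is removed.
    """
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.band_hz
    hi = min(hi, 0.45 * rec.fs)
    for f0 in cfg.notch_hz:
        if f0 >= rec.fs / 2:
            raise ValueError(
                f"notch at {f0} Hz impossible at fs={rec.fs} Hz (Nyquist {rec.fs / 2})"
            )
    sos = sps.butter(4, [lo, hi], btype="band", fs=rec.fs, output="sos")
    out = rec.copy()
    for c in DATA_CHANNELS:
        x = out.channels[c]
        if len(x) == 0:
            continue
        # notches first: with strong line noise present, running the
        # wide bandpass first would smear tone energy into its (slow)
        # 0.1 Hz edge transient where the notch cannot remove it
        y = x
        for f0 in cfg.notch_hz:
            b, a = sps.iirnotch(f0, Q=30.0, fs=rec.fs)
            y = sps.filtfilt(b, a, y)
        out.channels[c] = sps.sosfiltfilt(sos, y)
    return out


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def _robust_baseline(x: np.ndarray, fs: float) -> np.ndarray:
    """Running-median baseline, computed on a decimated copy for speed."""
    step = max(1, int(fs // 50))
    sub = x[::step]
    size = max(3, int(round(0.5 * fs / step)) | 1)
    base = ndimage.median_filter(sub, size=size, mode="nearest")
    return np.repeat(base, step)[: len(x)]


def _mad(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _spike_candidates(
    x: np.ndarray, fs: float, mad_factor: float, max_dur_s: float, guard_s: float
) -> list[tuple[int, int]]:
    """Short, isolated high-deviation runs (with guard), as [start, stop).

    A run qualifies only when it is brief (<= max_dur_s) AND isolated:
    sustained noisy stretches also produce many short supra-threshold
    runs, so runs whose 2 s neighbourhood is dense in moderate
    deviations are left for the HF / amplitude detectors.
    """
    spans, _, _ = _spike_candidates_full(x, fs, mad_factor, max_dur_s, guard_s)
    return spans


def _spike_candidates_full(
    x: np.ndarray,
    fs: float,
    mad_factor: float,
    max_dur_s: float,
    guard_s: float,
    resid: np.ndarray | None = None,
    isolation: bool = True,
) -> tuple[list[tuple[int, int]], np.ndarray, float]:
    """As :func:`_spike_candidates`, also returning (residual, sigma).

    ``resid`` overrides the default running-median residual (used by the
    periodic detector, which looks at a highpassed residual instead).
    ``isolation=False`` disables the neighbourhood-density veto — the
    periodic detector gets its specificity from phase support, and its
    highpass ringing would otherwise veto dense spike trains.
    """
    if resid is None:
        resid = x - _robust_baseline(x, fs)
    sigma = _mad(resid)
    if sigma == 0:
        sigma = np.inf
    over = np.abs(resid) > mad_factor * sigma
    # local density of moderate deviations (half threshold) in a 2 s window
    moderate = (np.abs(resid) > 0.5 * mad_factor * sigma).astype(float)
    win = max(1, int(round(2.0 * fs)))
    kernel = np.ones(win) / win
    density = np.convolve(moderate, kernel, mode="same")
    max_run = int(round(max_dur_s * fs))
    guard = int(round(guard_s * fs))
    spans = []
    for a, b in _runs(over):
        if b - a > max_run:
            continue
        if isolation and density[a : b + 1].mean() > 0.2:
            continue
        spans.append((max(0, a - guard), min(len(x), b + guard)))
    return spans, resid, sigma


def detect_transient_spikes(
    x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Mark short-duration, high-amplitude deviations.

    A sample is flagged when its deviation from a running-median
    baseline exceeds ``spike_mad_factor`` robust standard deviations,
    the offending run is no longer than ``spike_max_duration_s``, and a
    ±``spike_guard_s`` guard band is added.  Long deviations are left
    for the HF / amplitude detectors.
    """
    cfg = cfg or PreprocessConfig()
    mask = np.zeros(len(x), dtype=bool)
    for a, b in _spike_candidates(
        x, fs, cfg.spike_mad_factor, cfg.spike_max_duration_s, cfg.spike_guard_s
    ):
        mask[a:b] = True
    return mask


def detect_periodic_spikes(
    x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Mark spike trains repeating at the device period (200 ms).

    Candidate spikes come from the transient detector at a reduced
    threshold; onsets are then grouped into trains whose inter-onset
    interval is ``period*fs`` samples (±1 sample of jitter), and only
    trains of at least ``periodic_min_train`` spikes are marked.
    """
    cfg = cfg or PreprocessConfig()
    mask = np.zeros(len(x), dtype=bool)
    # device spikes are ~2 samples wide and spectrally flat; a 20 Hz
    # highpass residual removes the (large, low-frequency) sleep EEG
    # while keeping most of the spike energy, so weak spikes on
    # deep-sleep background remain detectable
    if len(x) > 30:
        sos_hp = sps.butter(4, 20.0, btype="high", fs=fs, output="sos")
        hp_resid = sps.sosfiltfilt(sos_hp, x)
    else:
        hp_resid = x.copy()
    spans, resid, sigma = _spike_candidates_full(
        x,
        fs,
        cfg.spike_candidate_mad_factor,
        cfg.spike_max_duration_s,
        cfg.spike_guard_s,
        resid=hp_resid,
        isolation=False,
    )
    if len(spans) < cfg.periodic_min_train:
        return mask
    onsets = np.array(sorted(a for a, _ in spans))
    period = int(round(cfg.periodic_period_s * fs))
    # grid purity: a candidate belongs to a device-noise train when the
    # other candidates in its neighbourhood predominantly sit on its
    # 200 ms grid.  True trains have purity near 1 (even interleaved
    # ones, per grid); dense crossings inside sustained HF noise are
    # uniformly distributed in phase and fail the purity gate, so the
    # periodic detector does not swallow HF segments.
    window = 5 * period
    min_train = cfg.periodic_min_train
    periodic = np.zeros(len(onsets), dtype=bool)
    for i, o in enumerate(onsets):
        lo = np.searchsorted(onsets, o - window)
        hi = np.searchsorted(onsets, o + window, side="right")
        local = onsets[lo:hi]
        if len(local) < min_train:
            continue
        phase = (local - o) % period
        on_grid = (phase <= 2) | (phase >= period - 2)
        periodic[i] = on_grid.sum() >= min_train and on_grid.mean() >= 0.35
    guard = int(round(cfg.spike_guard_s * fs))
    for flag, (a, b) in zip(periodic, spans):
        if flag:
            mask[max(0, a - guard) : min(len(x), b + guard)] = True
    # grid completion: spikes inside a confirmed train can individually
    # fall below the candidate threshold (the threshold is global while
    # the background varies with sleep depth).  Walk the period grid
    # outward from confirmed onsets and claim positions where a weaker
    # local deviation test still sees a spike.
    confirmed = sorted(onsets[periodic])
    if confirmed and np.isfinite(sigma):
        n = len(x)
        width = max(2, int(round(0.008 * fs)))  # device spike ~8 ms
        # claim a window wide enough to cover the bandpass ringing tails
        # around each spike, or re-runs would find the tails periodic
        wide = 2 * guard

        def claim(target: int) -> None:
            mask[max(0, target - 2 - wide) : min(n, target + width + 2 + wide)] = True

        # gap filling: the device noise sits on a strict grid, so grid
        # positions between two phase-consistent confirmed onsets are
        # spike times even when the spike itself stayed under the
        # candidate threshold (single-sample spikes lose height in the
        # anti-aliasing filtering, especially on deep-sleep background)
        for o1, o2 in zip(confirmed[:-1], confirmed[1:]):
            gap = o2 - o1
            k = int(round(gap / period))
            if 2 <= k <= 30 and abs(gap - k * period) <= 3:
                step = gap / k
                for j in range(1, k):
                    claim(int(round(o1 + j * step)))

        # outward extension at bout edges: walk the grid while a weak
        # local deviation test still sees a spike
        claimed = np.zeros(n, dtype=bool)
        claimed[list(confirmed)] = True
        stack = list(confirmed)
        while stack:
            o = stack.pop()
            for target in (o - period, o + period):
                if target < 0 or target >= n:
                    continue
                if claimed[max(0, target - 2) : target + 3].any():
                    continue
                lo, hi = max(0, target - 2), min(n, target + width + 2)
                if hi > lo and np.abs(resid[lo:hi]).max() > 2.5 * sigma:
                    mask[max(0, lo - wide) : min(n, hi + wide)] = True
                    claimed[target] = True
                    stack.append(target)
    return mask


def detect_hf_noise(x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Mark long (>30 s) stretches of elevated high-frequency power.

    HF power is the mean squared 40–100 Hz bandpassed signal per 1 s
    window; windows above ``hf_threshold_factor`` times the recording's
    median window power are candidates, and maximal candidate runs
    longer than ``hf_min_duration_s`` are marked.
    """
    cfg = cfg or PreprocessConfig()
    n = len(x)
    mask = np.zeros(n, dtype=bool)
    win = int(round(fs))
    if n < win:
        return mask
    lo, hi = cfg.hf_band_hz
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        return mask
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    hf = sps.sosfiltfilt(sos, x)
    n_win = n // win
    p = (hf[: n_win * win] ** 2).reshape(n_win, win).mean(axis=1)
    thresh = cfg.hf_threshold_factor * np.median(p)
    if thresh <= 0:
        return mask
    over = p > thresh
    min_windows = int(round(cfg.hf_min_duration_s))
    for a, b in _runs(over):
        if (b - a) * (win / fs) > cfg.hf_min_duration_s or (b - a) > min_windows:
            mask[a * win : b * win] = True
    return mask


def detect_amplitude(x: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Mark samples with absolute value strictly greater than 350 uV."""
    cfg = cfg or PreprocessConfig()
    return np.abs(x) > cfg.amp_threshold_uv


# ---------------------------------------------------------------------------
# Repair
# ---------------------------------------------------------------------------

def remove_and_interpolate(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked samples by linear interpolation from clean neighbours.

    Masked runs touching the signal edges hold the nearest clean value.
    Unmasked samples pass through bit-exact.
    """
    x = np.asarray(x, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.shape:
        raise ValueError("mask and signal lengths differ")
    if not mask.any():
        return x.copy()
    if mask.all():
        raise ValueError("cannot interpolate an all-masked signal")
    out = x.copy()
    idx = np.arange(len(x))
    out[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    return out


# ---------------------------------------------------------------------------
# Full per-recording pipeline
# ---------------------------------------------------------------------------

def preprocess_recording(
    rec: RawRecording, cfg: PreprocessConfig | None = None
) -> tuple[RawRecording, ArtifactMask, EpochValidity, QCReport]:
    """Filter, detect, repair and QC one recording.

    Detector precedence: device_periodic → spike → hf → amplitude (the
    first detector to claim a sample wins).  Periodic and transient
    spikes are interpolated away; HF and amplitude samples remain in
    the signal but stay masked, making their epochs ineligible for
    channel selection when the masked fraction is too high.
    """
    cfg = cfg or PreprocessConfig()
    filtered = apply_filters(rec, cfg)
    codes: dict[str, np.ndarray] = {}
    clean = filtered.copy()
    for c in DATA_CHANNELS:
        x = filtered.channels[c]
        # the +/-350 uV rule concerns recorded physical amplitude, so it
        # is evaluated on the DC-corrected raw signal, not the filtered
        # one (the highpass shaves the peaks of borderline excursions)
        raw = rec.channels[c]
        raw = raw - np.median(raw) if len(raw) else raw
        code = np.zeros(len(x), dtype=np.int8)
        for name, m in (
            ("device_periodic", detect_periodic_spikes(x, rec.fs, cfg)),
            ("spike", detect_transient_spikes(x, rec.fs, cfg)),
            ("hf", detect_hf_noise(x, rec.fs, cfg)),
            ("amplitude", detect_amplitude(raw, cfg)),
        ):
            code[(code == 0) & m] = CAT_TO_INT[name]
        repair = np.isin(code, [CAT_TO_INT["device_periodic"], CAT_TO_INT["spike"]])
        if repair.any() and not repair.all():
            clean.channels[c] = remove_and_interpolate(x, repair)
        codes[c] = code

    mask = ArtifactMask(codes=codes)
    spe = int(round(cfg.epoch_len_s * rec.fs))
    n_epochs = rec.n_samples // spe if spe else 0
    valid: dict[str, np.ndarray] = {}
    frac: dict[str, np.ndarray] = {}
    hard_codes = [CAT_TO_INT["hf"], CAT_TO_INT["amplitude"]]
    for c in DATA_CHANNELS:
        code = codes[c][: n_epochs * spe].reshape(n_epochs, spe) if n_epochs else np.zeros((0, spe))
        any_frac = (code != 0).mean(axis=1) if n_epochs else np.zeros(0)
        hard_frac = np.isin(code, hard_codes).mean(axis=1) if n_epochs else np.zeros(0)
        valid[c] = (hard_frac <= cfg.epoch_hard_fraction) & (any_frac <= cfg.epoch_any_fraction)
        frac[c] = any_frac
    validity = EpochValidity(valid=valid, masked_fraction=frac)

    per_channel = {
        c: {
            cat: mask.fraction(c, (cat,))
            for cat in ARTIFACT_CATEGORIES
            if cat != "none"
        }
        for c in DATA_CHANNELS
    }
    noisy = float(np.mean([mask.fraction(c) for c in DATA_CHANNELS]))
    rejected = float(np.mean([mask.fraction(c, ("hf", "amplitude")) for c in DATA_CHANNELS]))
    repaired = float(np.mean([mask.fraction(c, ("device_periodic", "spike")) for c in DATA_CHANNELS]))
    report = QCReport(
        per_channel_fraction=per_channel,
        overall_rejected_fraction=rejected,
        overall_noisy_fraction=noisy,
        repaired_fraction=repaired,
        duration_h=rec.duration_s / 3600.0,
        noisy_threshold=cfg.reject_noisy_fraction,
        min_duration_h=cfg.min_duration_h,
    )
    return clean, mask, validity, report
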