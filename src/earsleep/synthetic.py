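"""Ground-truthed synthetic ear-EEG nights.

Real at-home ear-EEG sleep recordings cannot be shared, so this module
generates stand-ins with known answers: a Markov-chain hypnogram, a
four-channel signal whose spectral content tracks the sleep stage, and
injected artifacts of the four classes the preprocessing stage must
detect (periodic 200 ms device spikes, short transient spikes,
high-frequency noise segments longer than 30 s, and amplitude
excursions beyond 350 uV), each with an exact per-sample mask.

The signal model is deliberately simple: per stage, a common source is
built as a sum of band-limited filtered Gaussian noise components
(delta/theta/alpha/sigma/beta) plus stage-specific transient events
(1 s, 13 Hz spindle bursts in N2; slow biphasic eye-movement
deflections, anti-correlated across the two ears, in REM).  All four
channels see the common source scaled by a per-channel gain, plus
independent sensor noise — so cross-ear derivations retain the stage
signal while uncorrelated noise partially cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io_core import DATA_CHANNELS, Hypnogram, RawRecording, STAGES

#: EEG band edges in Hz used throughout the package.
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (11.0, 16.0),
    "beta": (16.0, 40.0),
}


@dataclass
class StageTransitionModel:
    """First-order Markov model over the five sleep stages."""

    P: np.ndarray  # 5x5 row-stochastic, rows/cols in STAGES order
    initial: str = "W"

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (5, 5):
            raise ValueError(f"P must be 5x5, got {self.P.shape}")
        if (self.P < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each row of P must sum to 1")
        if self.initial not in STAGES:
            raise ValueError(f"initial stage {self.initial!r} not in {STAGES}")

    def stationary(self) -> np.ndarray:
        """Stationary distribution (leading left eigenvector of P)."""
        w, v = np.linalg.eig(self.P.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        return pi / pi.sum()


def default_transition_model() -> StageTransitionModel:
    """Default nightly stage dynamics.

    Tuned so the stationary stage fractions roughly match healthy adult
    sleep (W 10%, N1 10%, N2 45%, N3 15%, REM 20%) while keeping
    realistic bout structure (sticky N2/N3, fragile N1, REM periods).
    """
    #           W      N1     N2     N3     REM
    P = np.array(
        [
            [0.60, 0.32, 0.05, 0.00, 0.03],  # W
            [0.09, 0.45, 0.42, 0.01, 0.03],  # N1
            [0.015, 0.03, 0.875, 0.05, 0.03],  # N2
            [0.005, 0.005, 0.135, 0.85, 0.005],  # N3
            [0.02, 0.035, 0.045, 0.00, 0.90],  # REM
        ]
    )
    return StageTransitionModel(P=P, initial="W")


@dataclass
class StageSpectrumSpec:
    """Per-stage band-power weights (uV^2) plus transient-event settings.

    ``weights`` maps stage -> dict of band -> power weight; ``noise_uv``
    is the per-channel independent sensor-noise standard deviation.
    Spindles are 1 s, 13 Hz amplitude-modulated bursts at a Poisson rate
    in N2; the REM proxy is slow (0.5–1 Hz) biphasic deflections with
    opposite sign on the two ears, mimicking conjugate eye movements
    seen from ear electrodes.
    """

    weights: dict[str, dict[str, float]] = field(default_factory=lambda: _default_weights())
    noise_uv: float = 3.0
    spindle_rate_per_min: float = 2.0
    spindle_amp_uv: float = 12.0
    rem_deflection_rate_per_min: float = 4.0
    rem_deflection_amp_uv: float = 25.0

    def __post_init__(self) -> None:
        for stage, w in self.weights.items():
            if any(v < 0 for v in w.values()):
                raise ValueError(f"negative band weight for stage {stage}")
            if not any(v > 0 for v in w.values()) and self.noise_uv == 0:
                pass  # all-zero spec is allowed (produces silence)


def _default_weights() -> dict[str, dict[str, float]]:
    # Band powers (uV^2) chosen to mimic the canonical stage spectra:
    # wake alpha/beta, N1 theta, N2 theta+sigma, N3 delta-dominant,
    # REM mixed low-amplitude theta.
    return {
        "W": {"delta": 10, "theta": 12, "alpha": 110, "sigma": 6, "beta": 55},
        "N1": {"delta": 20, "theta": 110, "alpha": 18, "sigma": 4, "beta": 6},
        "N2": {"delta": 120, "theta": 40, "alpha": 8, "sigma": 35, "beta": 4},
        "N3": {"delta": 500, "theta": 35, "alpha": 6, "sigma": 6, "beta": 3},
        "REM": {"delta": 12, "theta": 35, "alpha": 8, "sigma": 3, "beta": 30},
    }


@dataclass
class ArtifactSpec:
    """Rates and amplitudes for the four injected artifact classes."""

    periodic_period_s: float = 0.2
    periodic_amp_uv: float = 120.0
    periodic_channel_prob: float = 0.5  # chance a channel carries periodic noise
    periodic_duty_s: float = 60.0  # length of each periodic-noise bout
    periodic_bouts_per_hour: float = 1.0
    transient_rate_per_min: float = 0.5
    transient_amp_uv: float = 300.0
    transient_width_s: float = 0.04
    hf_segment_s: float = 60.0  # must exceed the 30 s detection rule
    hf_band: tuple[float, float] = (40.0, 100.0)
    hf_power_uv2: float = 400.0
    hf_segments_per_recording: float = 1.0
    excursion_rate_per_hour: float = 2.0
    excursion_amp_uv: float = 450.0  # must exceed the 350 uV bound
    excursion_width_s: float = 0.5

    def __post_init__(self) -> None:
        if self.periodic_period_s <= 0:
            raise ValueError("periodic period must be positive")
        if self.hf_segment_s <= 30.0:
            raise ValueError("hf segment duration must exceed 30 s")
        if self.excursion_amp_uv <= 350.0:
            raise ValueError("excursion amplitude must exceed 350 uV")


#: Artifact mask categories, in detector-precedence order.
ARTIFACT_CATEGORIES = ("none", "device_periodic", "spike", "hf", "amplitude")
CAT_TO_INT = {c: i for i, c in enumerate(ARTIFACT_CATEGORIES)}


@dataclass
class GroundTruth:
    """Oracle container: true hypnogram + per-channel per-sample mask codes."""

    hypnogram: Hypnogram
    artifact_mask: dict[str, np.ndarray]  # int codes per CAT_TO_INT

    def mask_fraction(self, channel: str) -> float:
        m = self.artifact_mask[channel]
        return float(np.mean(m != 0)) if len(m) else 0.0


# ---------------------------------------------------------------------------
# Hypnogram generation
# ---------------------------------------------------------------------------

def generate_hypnogram(
    n_epochs: int,
    model: StageTransitionModel | None = None,
    seed: int | np.random.Generator = 0,
) -> Hypnogram:
    """Draw a Markov-chain hypnogram of ``n_epochs`` 30 s epochs."""
    if n_epochs < 0:
        raise ValueError("n_epochs must be >= 0")
    model = model or default_transition_model()
    rng = np.random.default_rng(seed)
    labels = []
    state = STAGES.index(model.initial)
    for _ in range(n_epochs):
        labels.append(STAGES[state])
        state = rng.choice(5, p=model.P[state])
    return Hypnogram(labels=tuple(labels))


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _band_noise(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz."""
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        return np.zeros(n)
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def synthesize_recording(
    h: Hypnogram,
    spec: StageSpectrumSpec | None = None,
    fs: float = 250.0,
    channel_gains: Sequence[float] = (1.0, 0.95, 1.0, 0.9),
    seed: int | np.random.Generator = 0,
    meta: dict | None = None,
) -> RawRecording:
    """Render a hypnogram into a four-channel recording.

    Every epoch's common source is stage-dependent band noise plus
    stage events; each channel is ``gain * source + sensor noise``, the
    REM eye-movement proxy entering with opposite sign on left and
    right ears.
    """
    spec = spec or StageSpectrumSpec()
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {fs}")
    rng = np.random.default_rng(seed)
    spe = int(round(h.epoch_len * fs))
    n = spe * len(h)
    if n == 0:
        return RawRecording(fs=fs, channels={c: np.zeros(0) for c in DATA_CHANNELS}, meta=meta or {})

    # One full-length noise carrier per band, scaled per epoch by the
    # stage's band weight: cheap, and the band powers are exactly what
    # the downstream spectral features measure.
    carriers = {b: _band_noise(n, fs, lo, hi, rng) for b, (lo, hi) in BANDS.items()}
    stage_per_epoch = list(h.labels)
    scale = np.zeros((len(BANDS), len(h)))
    for j, b in enumerate(BANDS):
        for i, st in enumerate(stage_per_epoch):
            w = spec.weights.get(st, {}).get(b, 0.0)
            scale[j, i] = np.sqrt(w)
    common = np.zeros(n)
    for j, b in enumerate(BANDS):
        common += carriers[b] * np.repeat(scale[j], spe)

    rem_proxy = np.zeros(n)  # added with opposite sign left vs right
    t_epoch = np.arange(spe) / fs
    for i, st in enumerate(stage_per_epoch):
        sl = slice(i * spe, (i + 1) * spe)
        if st == "N2" and spec.spindle_rate_per_min > 0:
            k = rng.poisson(spec.spindle_rate_per_min * h.epoch_len / 60.0)
            for _ in range(k):
                onset = rng.uniform(0, h.epoch_len - 1.0)
                tt = t_epoch - onset
                env = np.exp(-0.5 * ((tt - 0.5) / 0.2) ** 2) * (tt >= 0) * (tt <= 1.0)
                common[sl] += spec.spindle_amp_uv * env * np.sin(2 * np.pi * 13.0 * tt)
        elif st == "REM" and spec.rem_deflection_rate_per_min > 0:
            k = rng.poisson(spec.rem_deflection_rate_per_min * h.epoch_len / 60.0)
            for _ in range(k):
                onset = rng.uniform(0, h.epoch_len - 2.0)
                f = rng.uniform(0.5, 1.0)
                tt = t_epoch - onset
                dur = 1.0 / f
                win = (tt >= 0) & (tt <= dur)
                rem_proxy[sl] += np.where(
                    win, spec.rem_deflection_amp_uv * np.sin(2 * np.pi * f * tt), 0.0
                )

    # The common source projects with opposite polarity at the two ears
    # (a tangential dipole seen from either side of the head).  This is
    # what makes cross-ear derivations signal-bearing: R(t) - L(t)
    # sums the projections instead of cancelling them, while
    # independent sensor noise partially cancels.
    channels = {}
    for g, c in zip(channel_gains, DATA_CHANNELS):
        side = -1.0 if c.startswith("EL") else 1.0
        channels[c] = side * g * (common + rem_proxy) + spec.noise_uv * rng.standard_normal(n)
    return RawRecording(fs=fs, channels=channels, meta=meta or {})


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

def inject_artifacts(
    rec: RawRecording,
    spec: ArtifactSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[RawRecording, GroundTruth]:
    """Contaminate a recording with the four artifact classes.

    Returns the contaminated copy and a :class:`GroundTruth` whose mask
    labels every injected sample with its category.  Periodic spikes
    sit on a strict 0.2 s grid within each affected bout.
    """
    if rec.n_samples == 0:
        raise ValueError("cannot inject artifacts into an empty recording")
    spec = spec or ArtifactSpec()
    rng = np.random.default_rng(seed)
    fs = rec.fs
    n = rec.n_samples
    out = rec.copy()
    masks = {c: np.zeros(n, dtype=np.int8) for c in DATA_CHANNELS}
    hours = n / fs / 3600.0

    period = int(round(spec.periodic_period_s * fs))
    spike_half = max(1, int(round(0.004 * fs)))  # ~8 ms device spike

    for c in DATA_CHANNELS:
        x = out.channels[c]
        m = masks[c]

        # 1) periodic device spikes: bouts on an exact period grid
        if rng.random() < spec.periodic_channel_prob and spec.periodic_bouts_per_hour > 0:
            n_bouts = rng.poisson(spec.periodic_bouts_per_hour * hours)
            for _ in range(n_bouts):
                dur = int(spec.periodic_duty_s * fs)
                if n <= dur:
                    start = 0
                else:
                    start = int(rng.integers(0, n - dur))
                for onset in range(start, min(start + dur, n), period):
                    lo, hi = onset, min(onset + spike_half, n)
                    x[lo:hi] += spec.periodic_amp_uv
                    m[lo:hi] = np.where(m[lo:hi] == 0, CAT_TO_INT["device_periodic"], m[lo:hi])

        # 2) transient spikes
        k = rng.poisson(spec.transient_rate_per_min * (n / fs / 60.0))
        w = max(1, int(round(spec.transient_width_s * fs)))
        for _ in range(k):
            onset = int(rng.integers(0, max(1, n - w)))
            sign = rng.choice([-1.0, 1.0])
            shape = np.hanning(max(w, 3))[:w] if w >= 3 else np.ones(w)
            x[onset : onset + w] += sign * spec.transient_amp_uv * shape
            seg = m[onset : onset + w]
            m[onset : onset + w] = np.where(seg == 0, CAT_TO_INT["spike"], seg)

        # 3) long high-frequency noise segments (>30 s)
        n_hf = rng.poisson(spec.hf_segments_per_recording)
        dur = int(spec.hf_segment_s * fs)
        for _ in range(n_hf):
            if n <= dur:
                start = 0
            else:
                start = int(rng.integers(0, n - dur))
            noise = _band_noise(min(dur, n - start), fs, *spec.hf_band, rng)
            x[start : start + dur] += np.sqrt(spec.hf_power_uv2) * noise
            seg = m[start : start + dur]
            m[start : start + dur] = np.where(seg == 0, CAT_TO_INT["hf"], seg)

        # 4) amplitude excursions beyond 350 uV
        k = rng.poisson(spec.excursion_rate_per_hour * hours)
        w = max(3, int(round(spec.excursion_width_s * fs)))
        for _ in range(k):
            onset = int(rng.integers(0, max(1, n - w)))
            sign = rng.choice([-1.0, 1.0])
            bump = sign * spec.excursion_amp_uv * np.hanning(w)
            x[onset : onset + w] += bump
            over = np.abs(x[onset : onset + w]) > 350.0
            seg = m[onset : onset + w]
            m[onset : onset + w] = np.where((seg == 0) & over, CAT_TO_INT["amplitude"], seg)

    # callers that know the recording's hypnogram (simulate_night)
    # attach it to the returned GroundTruth afterwards
    gt = GroundTruth(hypnogram=Hypnogram(labels=()), artifact_mask=masks)
    return out, gt


# ---------------------------------------------------------------------------
# Whole-night convenience
# ---------------------------------------------------------------------------

def simulate_night(
    n_epochs: int,
    seed: int,
    fs: float = 250.0,
    transition: StageTransitionModel | None = None,
    spectrum: StageSpectrumSpec | None = None,
    artifacts: ArtifactSpec | None = None,
    meta: dict | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Generate one complete synthetic night: hypnogram, signal, artifacts.

    ``artifacts=None`` means a clean night (empty mask).  All randomness
    derives from ``seed``; identical calls are bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    h = generate_hypnogram(n_epochs, transition, rng)
    rec = synthesize_recording(h, spectrum, fs=fs, seed=rng, meta=meta)
    if artifacts is None:
        gt = GroundTruth(
            hypnogram=h,
            artifact_mask={c: np.zeros(rec.n_samples, dtype=np.int8) for c in DATA_CHANNELS},
        )
        return rec, gt
    dirty, gt = inject_artifacts(rec, artifacts, rng)
    gt.hypnogram = h
    return dirty, gt
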