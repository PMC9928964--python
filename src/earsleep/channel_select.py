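"""Cross-ear channel selection by minimum RMS.

Noisy ear-EEG channels tend to have higher RMS, so for every 30 s
epoch the pipeline evaluates all cross-ear derivations — each right-ear
option (ER1, ER2, their average) referenced to each left-ear option
(EL1, EL2, their average, or the bare reference electrode) — and keeps
the one with the lowest RMS.  Because the channels are recorded against
a common left-ear reference, "referencing to REF" simply returns the
recorded right-side channel.  The result is a single-channel signal
with per-epoch provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import DATA_CHANNELS, RawRecording
from .preprocess import EpochValidity

RIGHT_OPTIONS = ("ER1", "ER2", "AVG_R")
LEFT_OPTIONS = ("EL1", "EL2", "AVG_L", "REF")


@dataclass(frozen=True)
class Derivation:
    """One cross-ear combination: a right-side pick minus a left-side pick."""

    right: str
    left: str

    def __post_init__(self) -> None:
        if self.right not in RIGHT_OPTIONS or self.left not in LEFT_OPTIONS:
            raise ValueError(f"invalid derivation ({self.right}, {self.left})")

    def constituents(self) -> tuple[str, ...]:
        """Data channels whose validity this derivation depends on."""
        chans: list[str] = []
        chans += ["ER1", "ER2"] if self.right == "AVG_R" else [self.right]
        if self.left == "AVG_L":
            chans += ["EL1", "EL2"]
        elif self.left != "REF":  # REF carries no validity of its own
            chans.append(self.left)
        return tuple(chans)

    def __str__(self) -> str:
        return f"{self.right}-{self.left}"


def enumerate_derivations() -> list[Derivation]:
    """All 12 cross-ear derivations in fixed (right, left) order."""
    return [Derivation(r, l) for r in RIGHT_OPTIONS for l in LEFT_OPTIONS]


DERIVATIONS = enumerate_derivations()


def derive_epoch(epoch: dict[str, np.ndarray] | np.ndarray, d: Derivation) -> np.ndarray:
    """Derived samples R(t) − L(t) for one epoch.

    ``epoch`` is either a dict label -> samples or a (4, n) array in
    DATA_CHANNELS order.  AVG_R = (ER1+ER2)/2, AVG_L = (EL1+EL2)/2, and
    REF contributes zero (the channels are already referenced to it).
    """
    if isinstance(epoch, np.ndarray):
        epoch = {c: epoch[i] for i, c in enumerate(DATA_CHANNELS)}
    for c in d.constituents():
        if c not in epoch:
            raise KeyError(f"derivation {d} needs missing channel {c}")
    if d.right == "AVG_R":
        r = 0.5 * (epoch["ER1"] + epoch["ER2"])
    else:
        r = np.asarray(epoch[d.right], dtype=float)
    if d.left == "REF":
        return r.copy() if d.right != "AVG_R" else r
    if d.left == "AVG_L":
        l = 0.5 * (epoch["EL1"] + epoch["EL2"])
    else:
        l = epoch[d.left]
    return r - l


def select_derivation(
    epoch: dict[str, np.ndarray] | np.ndarray,
    validity: dict[str, bool] | None = None,
) -> tuple[Derivation | None, float]:
    """Lowest-RMS admissible derivation for one epoch.

    A derivation is admissible when every constituent data channel is
    valid this epoch (REF is always admissible).  Returns
    ``(None, nan)`` when no derivation is admissible; exact RMS ties go
    to the first derivation in enumeration order.
    """
    if isinstance(epoch, np.ndarray):
        epoch = {c: epoch[i] for i, c in enumerate(DATA_CHANNELS)}
    validity = validity or {c: True for c in DATA_CHANNELS}
    best: Derivation | None = None
    best_rms = np.inf
    for d in DERIVATIONS:
        if not all(validity.get(c, False) for c in d.constituents()):
            continue
        y = derive_epoch(epoch, d)
        rms = float(np.sqrt(np.mean(y**2)))
        if rms < best_rms:
            best, best_rms = d, rms
    if best is None:
        return None, float("nan")
    return best, best_rms


@dataclass
class SingleChannelSignal:
    """Per-epoch chosen derivation and the concatenated derived signal.

    ``derivations[i]`` is None for rejected epochs, which carry no
    samples; ``epoch_samples`` maps accepted epoch index -> samples.
    """

    fs: float
    epoch_len: float
    derivations: list[Derivation | None]
    rms_uv: np.ndarray  # nan where rejected
    epoch_samples: dict[int, np.ndarray] = field(repr=False)

    @property
    def n_epochs(self) -> int:
        return len(self.derivations)

    @property
    def accepted(self) -> np.ndarray:
        return np.array([d is not None for d in self.derivations])

    @property
    def rejected_fraction(self) -> float:
        if self.n_epochs == 0:
            return 0.0
        return 1.0 - float(self.accepted.mean())

    def provenance(self):
        """Per-epoch provenance table (epoch, right, left, rms_uv, rejected)."""
        import pandas as pd

        rows = []
        for i, d in enumerate(self.derivations):
            rows.append(
                {
                    "epoch": i,
                    "right": d.right if d else "",
                    "left": d.left if d else "",
                    "rms_uv": self.rms_uv[i],
                    "rejected": d is None,
                }
            )
        return pd.DataFrame(rows)


def build_single_channel(
    rec: RawRecording, validity: EpochValidity | None = None
) -> SingleChannelSignal:
    """Apply per-epoch RMS channel selection to a preprocessed recording."""
    n_epochs = rec.n_epochs
    if n_epochs == 0:
        raise ValueError("recording contains no full 30 s epoch")
    spe = int(round(30.0 * rec.fs))
    data = rec.as_array()
    derivs: list[Derivation | None] = []
    rms = np.full(n_epochs, np.nan)
    samples: dict[int, np.ndarray] = {}
    for i in range(n_epochs):
        epoch = {c: data[j, i * spe : (i + 1) * spe] for j, c in enumerate(DATA_CHANNELS)}
        v = (
            {c: bool(validity.valid[c][i]) for c in DATA_CHANNELS}
            if validity is not None
            else None
        )
        d, r = select_derivation(epoch, v)
        derivs.append(d)
        if d is not None:
            rms[i] = r
            samples[i] = derive_epoch(epoch, d)
    return SingleChannelSignal(
        fs=rec.fs, epoch_len=30.0, derivations=derivs, rms_uv=rms, epoch_samples=samples
    )
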