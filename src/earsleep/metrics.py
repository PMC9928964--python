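"""Hypnogram-level sleep metrics.

Seven dimensionless metrics summarize each night:

- ``REMfr``  = #REM epochs / #epochs
- ``N3fr``   = #N3 epochs / #epochs
- ``SE``     = sleep duration / duration of the recording after the
  first sleep epoch (inclusive); "sleep" = any non-wake stage
- ``NREMtoNREM`` = #(NREM -> NREM consecutive pairs) / #NREM epochs
- ``NREMtoREM``  = #(NREM -> REM pairs) / #NREM epochs
- ``REMtoREM``   = #(REM -> REM pairs) / #REM epochs
- ``REMtoNREM``  = #(REM -> NREM pairs) / #REM epochs

NREM = {N1, N2, N3}.  Self-pairs (e.g. N2 -> N2) count as transitions.
UNSCORED epochs are excluded from the stage counts and break pair
adjacency.  Zero-denominator transition metrics are 0 by convention;
a night with no sleep at all has no sleep onset, so SE is missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import Hypnogram, UNSCORED

NREM = frozenset({"N1", "N2", "N3"})

METRIC_NAMES = ("REMfr", "N3fr", "SE", "NREMtoNREM", "NREMtoREM", "REMtoREM", "REMtoNREM")


@dataclass
class SleepMetricSet:
    REMfr: float
    N3fr: float
    SE: float | None  # None when the night contains no sleep epoch
    NREMtoNREM: float
    NREMtoREM: float
    REMtoREM: float
    REMtoNREM: float
    se_missing_reason: str = ""

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def _collapse(stage: str) -> str:
    if stage in NREM:
        return "NREM"
    return stage  # W, REM, UNSCORED


def transition_counts(h: Hypnogram):
    """3x3 ordered pair counts over {W, NREM, REM}.

    Pairs containing an UNSCORED epoch are skipped (the UNSCORED epoch
    breaks adjacency).  Returns a dict (from, to) -> count.
    """
    if len(h) == 0:
        raise ValueError("empty hypnogram")
    states = ("W", "NREM", "REM")
    counts = {(a, b): 0 for a in states for b in states}
    labels = [_collapse(s) for s in h.labels]
    for a, b in zip(labels[:-1], labels[1:]):
        if a == UNSCORED or b == UNSCORED:
            continue
        counts[(a, b)] += 1
    return counts


def compute_sleep_metrics(h: Hypnogram) -> SleepMetricSet:
    """The seven sleep metrics of one hypnogram (see module docstring)."""
    if len(h) == 0:
        raise ValueError("empty hypnogram")
    labels = [s for s in h.labels]
    scored = [s for s in labels if s != UNSCORED]
    n_total = len(scored)
    if n_total == 0:
        raise ValueError("hypnogram contains no scored epoch")
    n_rem = sum(s == "REM" for s in scored)
    n_n3 = sum(s == "N3" for s in scored)
    n_nrem = sum(s in NREM for s in scored)

    # SE: denominator runs from the first non-wake scored epoch
    # (inclusive) to the end of the recording.
    sleep_onset = next(
        (i for i, s in enumerate(labels) if s != "W" and s != UNSCORED), None
    )
    if sleep_onset is None:
        se = None
        reason = "no sleep epoch (sleep onset undefined)"
    else:
        tail = [s for s in labels[sleep_onset:] if s != UNSCORED]
        n_sleep = sum(s != "W" for s in tail)
        se = n_sleep / len(tail)
        reason = ""

    tc = transition_counts(h)
    nrem_to_nrem = tc[("NREM", "NREM")] / n_nrem if n_nrem else 0.0
    nrem_to_rem = tc[("NREM", "REM")] / n_nrem if n_nrem else 0.0
    rem_to_rem = tc[("REM", "REM")] / n_rem if n_rem else 0.0
    rem_to_nrem = tc[("REM", "NREM")] / n_rem if n_rem else 0.0

    return SleepMetricSet(
        REMfr=n_rem / n_total,
        N3fr=n_n3 / n_total,
        SE=se,
        NREMtoNREM=nrem_to_nrem,
        NREMtoREM=nrem_to_rem,
        REMtoREM=rem_to_rem,
        REMtoNREM=rem_to_nrem,
        se_missing_reason=reason,
    )


def metrics_row(h: Hypnogram) -> dict:
    """Flat dict for one recording row of a study table."""
    m = compute_sleep_metrics(h)
    row = m.as_dict()
    row["n_epochs"] = len(h)
    row["n_scored"] = int(np.sum([s != UNSCORED for s in h.labels]))
    return row
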