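"""Study-level statistics: mixed-model metric comparison and the
confidence-percentile analysis for unlabeled recordings.

Each sleep metric is modelled, in Wilkinson notation, as::

    metric ~ 1 + subject + part + equipment + (1 | recording)

with subject, part (A: with reference PSG, B: ear-EEG only) and
equipment (individualized vs generic earpieces) as fixed effects and a
random intercept per recording night.  Fits use REML; per-effect
p-values come from likelihood-ratio tests of ML refits with and
without the effect.

For nights without manual scoring, the classifier's vote confidence
stands in for kappa: the 25/50/75th percentiles of the labeled set's
kappa values are mapped to confidence thresholds through the labeled
recording whose kappa is nearest each percentile, and the report gives
the fraction of unlabeled recordings above each threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_NAMES

FIXED_EFFECTS = ("subject", "part", "equipment")


@dataclass
class LMMFit:
    """One metric's mixed-model fit: coefficients and LRT p-values."""

    metric: str
    converged: bool
    coefficients: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float | None] = field(default_factory=dict)  # None = NA
    random_intercept_var: float = float("nan")

    def as_row(self) -> dict:
        row = {"metric": self.metric, "converged": self.converged}
        for eff in FIXED_EFFECTS:
            row[f"p_{eff}"] = self.p_values.get(eff)
        row["recording_var"] = self.random_intercept_var
        return row


def _fit_mixedlm(df: pd.DataFrame, formula: str, reml: bool):
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["recording"])
        # gradient-free optimizer: the profiled likelihood is prone to
        # singular score matrices when the random-effect variance
        # collapses to zero, which L-BFGS cannot cross
        try:
            fit = model.fit(reml=reml, method="powell", maxiter=2000)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=reml, method="nm", maxiter=5000)
    return fit


def _identifiable(df: pd.DataFrame, effects: set[str]) -> bool:
    """True when the fixed-effect design matrix has full column rank."""
    X = [np.ones(len(df))]
    for eff in FIXED_EFFECTS:
        if eff in effects:
            d = pd.get_dummies(df[eff], drop_first=True).to_numpy(dtype=float)
            if d.ndim == 1:
                d = d[:, None]
            X.append(d)
    M = np.column_stack(X)
    return np.linalg.matrix_rank(M) == M.shape[1]


def fit_metric_lmm(table: pd.DataFrame, metric: str) -> LMMFit:
    """Fit ``metric ~ subject + part + equipment + (1|recording)``.

    ``table`` needs columns subject, part, equipment, recording and the
    metric.  Effects with fewer than two observed levels are reported
    NA (this mirrors designs where equipment never varies).  Rows with
    a missing metric value are dropped.
    """
    if metric not in table.columns:
        raise ValueError(f"metric {metric!r} not in table")
    df = table.dropna(subset=[metric]).copy()
    df["subject"] = df["subject"].astype("category")
    df["part"] = df["part"].astype("category")
    df["equipment"] = df["equipment"].astype("category")
    df = df.rename(columns={metric: "_y"})
    if df["_y"].std() == 0 or len(df) < len(df["subject"].unique()) + 4:
        return LMMFit(metric=metric, converged=False)

    terms = {
        "subject": "C(subject)",
        "part": "C(part)",
        "equipment": "C(equipment)",
    }
    testable = {e for e in FIXED_EFFECTS if df[e].nunique() >= 2}
    # drop effects that are collinear with the rest of the design
    # (e.g. equipment constant within part); they are reported NA
    for eff in ("equipment", "part"):
        if eff in testable and not _identifiable(df, testable):
            testable.discard(eff)
    if not _identifiable(df, testable):
        return LMMFit(metric=metric, converged=False)
    rhs_full = " + ".join(terms[e] for e in FIXED_EFFECTS if e in testable) or "1"
    full_formula = f"_y ~ {rhs_full}"

    try:
        reml_fit = _fit_mixedlm(df, full_formula, reml=True)
        converged = bool(getattr(reml_fit, "converged", True))
    except Exception:
        return LMMFit(metric=metric, converged=False)

    coefficients = dict(reml_fit.fe_params)
    rand_var = float(np.asarray(reml_fit.cov_re).ravel()[0]) if reml_fit.cov_re.size else np.nan

    p_values: dict[str, float | None] = {}
    if not converged:
        return LMMFit(
            metric=metric,
            converged=False,
            coefficients=coefficients,
            random_intercept_var=rand_var,
        )
    try:
        full_ml = _fit_mixedlm(df, full_formula, reml=False)
    except Exception:
        return LMMFit(metric=metric, converged=False, coefficients=coefficients)
    for eff in FIXED_EFFECTS:
        if eff not in testable:
            p_values[eff] = None
            continue
        reduced_terms = [terms[e] for e in FIXED_EFFECTS if e in testable and e != eff]
        reduced_formula = "_y ~ " + (" + ".join(reduced_terms) if reduced_terms else "1")
        try:
            red_ml = _fit_mixedlm(df, reduced_formula, reml=False)
            lr = 2.0 * (full_ml.llf - red_ml.llf)
            dof = df[eff].nunique() - 1
            p_values[eff] = float(stats.chi2.sf(max(lr, 0.0), dof))
        except Exception:
            p_values[eff] = None
    return LMMFit(
        metric=metric,
        converged=True,
        coefficients=coefficients,
        p_values=p_values,
        random_intercept_var=rand_var,
    )


def fit_all_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """One LMM per sleep metric; returns a metric x effect p-value table."""
    rows = [fit_metric_lmm(table, m).as_row() for m in METRIC_NAMES if m in table.columns]
    return pd.DataFrame(rows)


def simulate_metric_table(
    n_subjects: int = 20,
    n_nights: int = 12,
    subject_sd: float = 0.03,
    resid_sd: float = 0.01,
    recording_sd: float = 0.005,
    equipment_effect: float = 0.0,
    part_effect: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a study table under the mixed model, for calibration.

    Each subject contributes ``n_nights`` nights; the first half are
    part A, and equipment alternates within subject with opposite phase
    across subjects so both effects are identifiable.  The metric is
    ``0.2 + subject + recording + equipment + part + noise`` with
    Gaussian subject effects (sd ``subject_sd``), Gaussian random
    night-index intercepts (sd ``recording_sd``) and residual sd
    ``resid_sd``.
    """
    rng = np.random.default_rng(seed)
    subj_eff = subject_sd * rng.standard_normal(n_subjects)
    rec_eff = recording_sd * rng.standard_normal(n_nights)
    rows = []
    for s in range(n_subjects):
        for n in range(n_nights):
            part = "A" if n < n_nights // 2 else "B"
            equip = "custom" if (n + s) % 2 == 0 else "generic"
            y = (
                0.2
                + subj_eff[s]
                + rec_eff[n]
                + (equipment_effect if equip == "generic" else 0.0)
                + (part_effect if part == "B" else 0.0)
                + resid_sd * rng.standard_normal()
            )
            rows.append(
                dict(subject=f"S{s:02d}", part=part, equipment=equip, recording=n, metric=y)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# confidence percentile analysis
# ---------------------------------------------------------------------------

@dataclass
class PercentileReport:
    """Kappa percentiles of the labeled set, matched confidence
    thresholds, and the fractions of unlabeled recordings above each."""

    kappa_percentiles: dict[int, float]
    confidence_thresholds: dict[int, float]
    fractions_above: dict[int, float]

    def as_dict(self) -> dict:
        return {
            "kappa_percentiles": self.kappa_percentiles,
            "confidence_thresholds": self.confidence_thresholds,
            "fractions_above": self.fractions_above,
        }


def confidence_percentile_report(labeled, unlabeled) -> PercentileReport:
    """Map labeled kappa percentiles to confidence thresholds and grade
    the unlabeled recordings against them.

    ``labeled`` is a sequence of (kappa, confidence) pairs; the 25/50/
    75th kappa percentiles (linear interpolation) are each matched to
    the labeled pair whose kappa is nearest (ties -> the pair with the
    lower confidence), and that pair's confidence becomes the
    threshold.  ``unlabeled`` is a sequence of confidences; the report
    gives the fraction strictly above each threshold.
    """
    labeled = [(float(k), float(c)) for k, c in labeled]
    if len(labeled) < 4:
        raise ValueError("need at least 4 labeled (kappa, confidence) pairs")
    unlabeled = np.asarray(list(unlabeled), dtype=float)
    if unlabeled.size == 0:
        raise ValueError("empty unlabeled confidence set")
    kappas = np.array([k for k, _ in labeled])
    percentiles = {q: float(np.percentile(kappas, q)) for q in (25, 50, 75)}
    thresholds = {}
    for q, kp in percentiles.items():
        d = np.abs(kappas - kp)
        nearest = np.where(d == d.min())[0]
        thresholds[q] = float(min(labeled[i][1] for i in nearest))
    # a higher kappa percentile must never demand a lower confidence:
    # enforce monotone thresholds so the reported fractions are
    # non-increasing even when the labeled pairs are noisy
    running = -np.inf
    for q in (25, 50, 75):
        running = max(running, thresholds[q])
        thresholds[q] = float(running)
    fractions = {q: float(np.mean(unlabeled > t)) for q, t in thresholds.items()}
    return PercentileReport(
        kappa_percentiles=percentiles,
        confidence_thresholds=thresholds,
        fractions_above=fractions,
    )
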