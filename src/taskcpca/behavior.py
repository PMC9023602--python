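"""Brain-behaviour association via peak component scores.

For every (component, event type) cell, the subject's peak response —
the signed value at the lag maximizing |estimate|, earliest lag on ties
— predicts the rank of task accuracy in an OLS model with age, sex,
total brain volume, mean framewise displacement and handedness as
covariates.  Ranks (average ranks for ties) are used instead of raw
accuracy so outliers do not dominate the fit.  The 20 case-group models
(5 components x 4 response events) form the FDR family; control-group
and group-interaction analyses are reported separately without joint
correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .datatypes import EVENT_TYPES, MODELED_EVENT_TYPES, ValidationError, event_label
from .curves import ResponseCurveSet

logger = logging.getLogger(__name__)

__all__ = [
    "extract_peak_scores",
    "rank_accuracy_regression",
    "fdr_adjust",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = [
    "age",
    "sex",
    "total_brain_volume",
    "mean_framewise_displacement",
    "handedness",
]


def extract_peak_scores(
    curveset: ResponseCurveSet,
    convention: str = "max_abs",
    event_types=MODELED_EVENT_TYPES,
    min_trials: int = 3,
) -> pd.DataFrame:
    """Per-(subject, component, event type) peak score and peak lag.

    ``convention="max_abs"`` (default) takes the signed value at the
    lag with the largest |estimate|; ``"signed_max"`` takes the largest
    signed value.  Ties are broken toward the earliest lag.  Absent
    event types yield no row, as do cells estimated from fewer than
    ``min_trials`` trials (a peak read off an unreliable curve is
    treated as missing, so each association model drops those
    subjects); subjects with every cell absent are excluded with a log
    entry.
    """
    if convention not in ("max_abs", "signed_max"):
        raise ValidationError(f"unknown peak convention {convention!r}")
    type_idx = [EVENT_TYPES.index(et) for et in event_types]
    rows = []
    for s, sid in enumerate(curveset.subject_ids):
        any_present = False
        for k, comp in enumerate(curveset.component_labels):
            for e in type_idx:
                curve = curveset.estimates[s, k, e]
                if np.all(np.isnan(curve)):
                    continue
                if (
                    curveset.event_counts is not None
                    and curveset.event_counts[s, e] < min_trials
                ):
                    continue
                any_present = True
                key = np.abs(curve) if convention == "max_abs" else curve
                j = int(np.argmax(key))  # argmax returns the earliest tie
                rows.append(
                    (
                        sid,
                        comp,
                        event_label(*EVENT_TYPES[e]),
                        float(curve[j]),
                        float(curveset.lag_times[j]),
                    )
                )
        if not any_present:
            logger.warning("subject %s has no estimable event types; excluded", sid)
    return pd.DataFrame(
        rows, columns=["subject", "component", "event_type", "peak", "peak_lag_s"]
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_accuracy_regression(
    peaks: pd.DataFrame,
    covariates: pd.DataFrame,
    group: str | None = "case",
    interaction: bool = False,
    min_subjects: int = 10,
) -> pd.DataFrame:
    """Peak-score -> accuracy-rank OLS per (component, event type).

    Parameters
    ----------
    peaks : DataFrame from :func:`extract_peak_scores`.
    covariates : DataFrame with subject_id, group, accuracy and the
        adjustment covariates.
    group : restrict to one group ("case" by default, mirroring the
        within-patient analysis); None uses all subjects.
    interaction : add a group x peak interaction term (full sample);
        the reported row then tests that interaction.

    Returns one row per cell with the standardized beta for the peak
    (or interaction) term, SE, p, BH-FDR q over the tested family,
    residual df and n.  Missing peaks are dropped per model.
    """
    cov = covariates.copy()
    if group is not None and not interaction:
        cov = cov[cov["group"] == group]
    if cov["accuracy"].nunique() <= 1:
        raise ValidationError("outcome has zero variance (constant accuracy)")
    cov = cov.set_index("subject_id")
    rows = []
    for (comp, etype), cell in peaks.groupby(["component", "event_type"], sort=True):
        cell = cell.set_index("subject")
        common = cell.index.intersection(cov.index)
        if len(common) < min_subjects:
            raise ValidationError(
                f"cell ({comp}, {etype}) has {len(common)} subjects; "
                f"need at least {min_subjects}"
            )
        sub = cov.loc[common]
        peak = cell.loc[common, "peak"].to_numpy(dtype=float)
        y = rankdata(sub["accuracy"].to_numpy(), method="average")
        y = (y - y.mean()) / y.std(ddof=0)
        x = (peak - peak.mean()) / peak.std(ddof=0)
        X = pd.DataFrame({"peak": x}, index=common)
        for c in COVARIATE_COLUMNS:
            X[c] = sub[c].to_numpy(dtype=float)
        term = "peak"
        if interaction:
            X["group_case"] = (sub["group"] == "case").astype(float).to_numpy()
            X["peak_x_group"] = X["peak"] * X["group_case"]
            term = "peak_x_group"
        X = sm.add_constant(X)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ValidationError(
                f"rank-deficient covariates in cell ({comp}, {etype}): "
                f"columns {list(X.columns)}"
            )
        fit = sm.OLS(y, X).fit()
        rows.append(
            {
                "component": comp,
                "event_type": etype,
                "beta": float(fit.params[term]),
                "se": float(fit.bse[term]),
                "p": float(fit.pvalues[term]),
                "df": int(fit.df_resid),
                "n": int(len(common)),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out
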