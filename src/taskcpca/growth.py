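"""Multilevel growth models of component response curves.

For one component, the estimated score at each post-event acquisition
(four response event types x six lags per subject) is modelled with a
linear mixed-effects model: subject random intercepts (optionally
random time slopes), mandatory between-subject covariates (age, sex,
total brain volume, mean framewise displacement, handedness, group),
and forward-selected fixed effects of time polynomials, stimulus type,
response type, and their interactions with group.  Selection compares
maximum-likelihood fits with likelihood-ratio tests; the final model is
refit by REML.

Time is expressed in seconds from event onset at the acquisition-bin
midpoints and centred at the window midpoint before raising to powers,
which tames polynomial collinearity while keeping raw-polynomial
coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from scipy import stats

from .datatypes import EVENT_TYPES, MODELED_EVENT_TYPES, ValidationError
from .curves import ResponseCurveSet

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthModelSpec",
    "GrowthModelFit",
    "GrowthModel",
    "GrowthConvergenceError",
    "build_growth_frame",
    "fit_growth_model",
    "select_growth_model",
    "default_candidate_ladder",
]

MANDATORY_COVARIATES = [
    "age",
    "sex",
    "total_brain_volume",
    "mean_framewise_displacement",
    "handedness",
    "group",
]

_OPTIMIZERS = ("lbfgs", "bfgs", "cg", "powell")


class GrowthConvergenceError(RuntimeError):
    """Mixed-model optimizer failed to converge; carries the trace."""

    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# term algebra

def _parse_term(term: str) -> tuple[int, bool, bool, bool]:
    """-> (time_power, threat, correct, group)."""
    power, threat, correct, group = 0, False, False, False
    for factor in term.split(":"):
        if factor == "t":
            power = max(power, 1)
        elif factor.startswith("t") and factor[1:].isdigit():
            power = max(power, int(factor[1:]))
        elif factor == "threat":
            threat = True
        elif factor == "correct":
            correct = True
        elif factor == "group":
            group = True
        else:
            raise ValidationError(f"unknown term factor {factor!r} in {term!r}")
    return power, threat, correct, group


def canonical_term(power: int, threat: bool, correct: bool, group: bool) -> str:
    parts = []
    if power == 1:
        parts.append("t")
    elif power > 1:
        parts.append(f"t{power}")
    if threat:
        parts.append("threat")
    if correct:
        parts.append("correct")
    if group:
        parts.append("group")
    if not parts:
        raise ValidationError("empty model term")
    return ":".join(parts)


def required_main_effects(term: str) -> list[str]:
    """Main effects an interaction presumes: all lower time powers and
    the threat / correct indicators involved (group is mandatory)."""
    power, threat, correct, _ = _parse_term(term)
    req = [canonical_term(k, False, False, False) for k in range(1, power + 1)]
    if threat:
        req.append("threat")
    if correct:
        req.append("correct")
    req = [r for r in req if r != term]
    return req


def _term_column(frame: pd.DataFrame, term: str) -> np.ndarray:
    power, threat, correct, group = _parse_term(term)
    col = np.ones(len(frame))
    if power:
        col = col * frame["t"].to_numpy() ** power
    if threat:
        col = col * frame["threat"].to_numpy()
    if correct:
        col = col * frame["correct"].to_numpy()
    if group:
        col = col * frame["group"].to_numpy()
    return col


@dataclass
class GrowthModelSpec:
    """Model specification: selected fixed terms on top of the
    mandatory covariates; random structure is a subject intercept, a
    nested subject x event-type intercept (time points for different
    stimuli are nested within participants), and optionally a random
    time slope."""

    fixed_terms: list[str] = field(default_factory=list)
    random_slope: bool = False
    mandatory: list[str] = field(default_factory=lambda: list(MANDATORY_COVARIATES))
    nested_event_intercept: bool = True

    def with_term(self, term: str) -> "GrowthModelSpec":
        return GrowthModelSpec(
            fixed_terms=self.fixed_terms + [term],
            random_slope=self.random_slope,
            mandatory=self.mandatory,
            nested_event_intercept=self.nested_event_intercept,
        )

    def exog_columns(self) -> list[str]:
        return list(self.mandatory) + list(self.fixed_terms)


# ---------------------------------------------------------------------------
# data frame construction

def build_growth_frame(
    curves: ResponseCurveSet,
    covariates: pd.DataFrame,
    component: int | str = 0,
    event_types=MODELED_EVENT_TYPES,
    center_covariates: bool = True,
) -> pd.DataFrame:
    """Long-format modelling frame for one component.

    One row per (subject, event type, lag) with the curve estimate as
    ``score``; the two non-response event types are excluded.  Subjects
    with incomplete covariates are dropped listwise with a log entry.
    """
    if isinstance(component, str):
        component = curves.component_labels.index(component)
    cov = covariates.set_index("subject_id")
    needed = ["group", "age", "sex", "total_brain_volume",
              "mean_framewise_displacement", "handedness"]
    rows = []
    t_centered = curves.lag_times - curves.lag_times.mean()
    type_idx = [EVENT_TYPES.index(et) for et in event_types]
    for s, sid in enumerate(curves.subject_ids):
        if sid not in cov.index or cov.loc[sid, needed].isna().any():
            logger.warning("subject %s dropped: incomplete covariates", sid)
            continue
        c = cov.loc[sid]
        for e in type_idx:
            stim, resp = EVENT_TYPES[e]
            est = curves.estimates[s, component, e]
            if np.all(np.isnan(est)):
                continue
            for j, tc in enumerate(t_centered):
                if np.isnan(est[j]):
                    continue
                rows.append(
                    {
                        "subject": sid,
                        "score": est[j],
                        "t": tc,
                        "lag_time_s": curves.lag_times[j],
                        "threat": 1.0 if stim == "threat" else 0.0,
                        "correct": 1.0 if resp == "correct" else 0.0,
                        "group": 1.0 if c["group"] == "case" else 0.0,
                        "age": float(c["age"]),
                        "sex": float(c["sex"]),
                        "total_brain_volume": float(c["total_brain_volume"]),
                        "mean_framewise_displacement": float(
                            c["mean_framewise_displacement"]
                        ),
                        "handedness": float(c["handedness"]),
                    }
                )
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValidationError("no usable observations for growth modelling")
    if center_covariates:
        for c in ("age", "total_brain_volume", "mean_framewise_displacement"):
            frame[c] = frame[c] - frame[c].mean()
    return frame


# ---------------------------------------------------------------------------
# fitting

@dataclass
class GrowthModelFit:
    """Fitted growth model: term table, random-effect variances, fit
    statistics and fitted group trajectories."""

    spec: GrowthModelSpec
    params: pd.DataFrame
    random_effects: dict
    llf: float
    aic: float
    bic: float
    n_obs: int
    n_subjects: int
    reml: bool
    converged: bool
    result: object = None  # statsmodels MixedLMResults
    frame: pd.DataFrame | None = None

    def term(self, name: str) -> pd.Series:
        row = self.params[self.params["term"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]

    def fitted_trajectories(self, lag_times: np.ndarray | None = None) -> pd.DataFrame:
        """Fixed-effect trajectories per group x event type at covariate
        reference values (centred continuous covariates at 0, binary
        covariates at their sample mean)."""
        frame = self.frame
        if lag_times is None:
            lags = np.sort(frame["lag_time_s"].unique())
        else:
            lags = np.asarray(lag_times)
        t_mid = frame["lag_time_s"].mean() - frame["t"].mean()
        beta = dict(zip(self.params["term"], self.params["beta"]))
        ref = {
            "sex": frame["sex"].mean(),
            "handedness": frame["handedness"].mean(),
            "age": 0.0,
            "total_brain_volume": 0.0,
            "mean_framewise_displacement": 0.0,
        }
        rows = []
        for group in (0.0, 1.0):
            for stim, resp in MODELED_EVENT_TYPES:
                for lag in lags:
                    pseudo = pd.DataFrame(
                        {
                            "t": [lag - t_mid],
                            "threat": [1.0 if stim == "threat" else 0.0],
                            "correct": [1.0 if resp == "correct" else 0.0],
                            "group": [group],
                            **{k: [v] for k, v in ref.items()},
                        }
                    )
                    y = beta.get("const", 0.0)
                    for term in self.spec.exog_columns():
                        if term not in beta:  # dropped (constant) covariate
                            continue
                        if term in ("age", "sex", "total_brain_volume",
                                    "mean_framewise_displacement", "handedness",
                                    "group"):
                            y += beta[term] * float(pseudo[term].iloc[0])
                        else:
                            y += beta[term] * float(_term_column(pseudo, term)[0])
                    rows.append(
                        {
                            "group": "case" if group == 1.0 else "control",
                            "stimulus_class": stim,
                            "response_class": resp,
                            "lag_time_s": lag,
                            "fitted": y,
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Multilevel growth model"
            + (" (REML)" if self.reml else " (ML)"),
            f"  observations: {self.n_obs}   subjects: {self.n_subjects}",
            f"  logLik {self.llf:.2f}   AIC {self.aic:.2f}   BIC {self.bic:.2f}",
            f"  random effects: {self.random_effects}",
            "",
            self.params.to_string(index=False),
        ]
        return "\n".join(lines)


def _design(frame: pd.DataFrame, spec: GrowthModelSpec) -> pd.DataFrame:
    X = pd.DataFrame(index=frame.index)
    X["const"] = 1.0
    for term in spec.mandatory:
        col = frame[term].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            # constant covariate is unidentifiable next to the intercept
            logger.warning("mandatory covariate %r is constant; dropped", term)
            continue
        X[term] = col
    for term in spec.fixed_terms:
        X[term] = _term_column(frame, term)
    return X


def fit_growth_model(
    frame: pd.DataFrame,
    spec: GrowthModelSpec | None = None,
    reml: bool = True,
) -> GrowthModelFit:
    """Fit one growth model by (RE)ML.

    A singular random-slope covariance triggers a logged refit without
    the slope; failure of every optimizer raises
    :class:`GrowthConvergenceError` with the optimizer trace.
    """
    if spec is None:
        spec = GrowthModelSpec()
    counts = frame.groupby("subject")["t"].nunique()
    if (counts < 2).any():
        raise ValidationError("every subject needs at least 2 time points")
    X = _design(frame, spec)
    safe = {c: c.replace(":", "_x_") for c in X.columns if c != "const"}
    data = X.rename(columns=safe).drop(columns="const")
    data["score"] = frame["score"].to_numpy(dtype=float)
    data["subject"] = frame["subject"].to_numpy()
    data["t_re"] = frame["t"].to_numpy()
    data["event_cell"] = (
        frame["threat"].astype(int).astype(str)
        + frame["correct"].astype(int).astype(str)
    )
    rhs = " + ".join(safe.values()) if safe else "1"
    vc_formula = None
    if spec.nested_event_intercept and data["event_cell"].nunique() > 1:
        vc_formula = {"event_cell": "0 + C(event_cell)"}
    model = sm.MixedLM.from_formula(
        f"score ~ {rhs}",
        data=data,
        groups="subject",
        re_formula="1 + t_re" if spec.random_slope else "1",
        vc_formula=vc_formula,
    )
    trace: list[dict] = []
    result = None
    fallback = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in _OPTIMIZERS:
            try:
                res = model.fit(reml=reml, method=method, maxiter=500, disp=False)
            except (np.linalg.LinAlgError, ValueError) as err:
                trace.append({"method": method, "error": str(err)})
                continue
            trace.append(
                {"method": method, "converged": bool(res.converged),
                 "llf": float(res.llf)}
            )
            if res.converged and np.isfinite(res.llf):
                result = res
                break
            if np.isfinite(res.llf) and (
                fallback is None or res.llf > fallback.llf
            ):
                fallback = res
    if result is None and fallback is not None:
        # boundary fits (random variance -> 0) sometimes miss the
        # convergence flag; the best finite-likelihood fit is still usable
        logger.warning("growth model: no optimizer flagged convergence; "
                       "using the best finite-likelihood fit (%s)", trace)
        result = fallback
    if result is None:
        raise GrowthConvergenceError("growth model failed to converge", trace)

    if spec.random_slope:
        cov_re = np.atleast_2d(result.cov_re)
        eig = np.linalg.eigvalsh(cov_re)
        slope_var = cov_re[1, 1] if cov_re.shape[0] > 1 else 0.0
        # boundary fits: (near-)singular covariance or a slope variance
        # indistinguishable from zero relative to the residual scale
        if eig.min() < 1e-10 * max(eig.max(), 1.0) or (
            slope_var < 1e-3 * float(result.scale)
        ):
            logger.warning(
                "singular/boundary random-slope covariance; refitting "
                "without the slope"
            )
            return fit_growth_model(
                frame,
                GrowthModelSpec(
                    fixed_terms=list(spec.fixed_terms),
                    random_slope=False,
                    mandatory=spec.mandatory,
                    nested_event_intercept=spec.nested_event_intercept,
                ),
                reml=reml,
            )

    k_fe = X.shape[1]
    fe = result.fe_params
    se = result.bse_fe
    zvals = fe / se
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))
    params = pd.DataFrame(
        {
            "term": list(X.columns),
            "beta": np.asarray(fe),
            "se": np.asarray(se),
            "z": np.asarray(zvals),
            "p": np.asarray(pvals),
            "df": len(frame) - k_fe,
        }
    )
    rand = {"subject_intercept_var": float(np.atleast_2d(result.cov_re)[0, 0])}
    if spec.random_slope and np.atleast_2d(result.cov_re).shape[0] > 1:
        cov_re = np.atleast_2d(result.cov_re)
        rand["subject_slope_var"] = float(cov_re[1, 1])
        rand["intercept_slope_cov"] = float(cov_re[0, 1])
    if result.vcomp is not None and len(np.atleast_1d(result.vcomp)):
        rand["subject_event_var"] = float(np.atleast_1d(result.vcomp)[0])
    rand["residual_var"] = float(result.scale)
    return GrowthModelFit(
        spec=spec,
        params=params,
        random_effects=rand,
        llf=float(result.llf),
        aic=float(result.aic) if np.isfinite(result.aic) else np.nan,
        bic=float(result.bic) if np.isfinite(result.bic) else np.nan,
        n_obs=len(frame),
        n_subjects=int(frame["subject"].nunique()),
        reml=reml,
        converged=bool(result.converged),
        result=result,
        frame=frame,
    )


# ---------------------------------------------------------------------------
# selection

def default_candidate_ladder(max_degree: int = 5) -> list[str]:
    """Static view of the default forward hierarchy (time polynomials,
    then stimulus/response terms and their time interactions, then
    group interactions)."""
    ladder = [canonical_term(k, False, False, False) for k in range(1, max_degree + 1)]
    ladder += ["threat", "correct"]
    for f_threat, f_correct in ((True, False), (False, True)):
        ladder += [
            canonical_term(k, f_threat, f_correct, False)
            for k in range(1, max_degree + 1)
        ]
    ladder += ["threat:correct"]
    ladder += [canonical_term(k, True, True, False) for k in range(1, max_degree + 1)]
    ladder += ["group:threat", "group:correct"]
    ladder += [canonical_term(k, False, False, True) for k in range(1, max_degree + 1)]
    for f_threat, f_correct in ((True, False), (False, True)):
        ladder += [
            canonical_term(k, f_threat, f_correct, True)
            for k in range(1, max_degree + 1)
        ]
    return ladder


def validate_ladder(ladder: list[str]) -> None:
    """Hierarchy check: every interaction's main effects must appear
    earlier in the ladder (group is mandatory and always available)."""
    seen: set[str] = set()
    for term in ladder:
        for parent in required_main_effects(term):
            if parent not in seen:
                raise ValidationError(
                    f"ladder term {term!r} appears before its main effect "
                    f"{parent!r}"
                )
        seen.add(term)


def select_growth_model(
    frame: pd.DataFrame,
    ladder: list[str] | None = None,
    alpha_select: float = 0.05,
    max_degree: int = 5,
    random_slope: str | bool = "auto",
) -> tuple[GrowthModelSpec, GrowthModelFit, pd.DataFrame]:
    """Partially supervised forward selection over the candidate ladder.

    Each candidate is added when the ML likelihood-ratio test against
    the current model is significant at ``alpha_select``; consecutive
    time polynomials stop at the first non-significant degree;
    candidates whose main effects were not admitted are skipped.
    Mandatory covariates are never dropped.  Returns the selected spec,
    its REML refit, and the full selection trace.
    """
    if ladder is None:
        ladder = default_candidate_ladder(max_degree)
    validate_ladder(ladder)
    spec = GrowthModelSpec(random_slope=False)
    current = fit_growth_model(frame, spec, reml=False)
    trace_rows: list[dict] = []
    time_chain_broken = False
    for term in ladder:
        power, threat, correct, group = _parse_term(term)
        is_pure_time = power >= 1 and not (threat or correct or group)
        if is_pure_time and time_chain_broken:
            trace_rows.append(
                {"term": term, "lrt": np.nan, "p": np.nan,
                 "decision": "skipped: lower time degree rejected"}
            )
            continue
        missing = [
            m for m in required_main_effects(term) if m not in spec.fixed_terms
        ]
        if missing:
            trace_rows.append(
                {"term": term, "lrt": np.nan, "p": np.nan,
                 "decision": f"skipped: main effect(s) {missing} absent"}
            )
            if is_pure_time:
                time_chain_broken = True
            continue
        try:
            candidate = fit_growth_model(frame, spec.with_term(term), reml=False)
        except GrowthConvergenceError as err:
            trace_rows.append(
                {"term": term, "lrt": np.nan, "p": np.nan,
                 "decision": f"skipped: no convergence ({err})"}
            )
            continue
        lrt = 2.0 * (candidate.llf - current.llf)
        p = stats.chi2.sf(max(lrt, 0.0), df=1)
        if p < alpha_select:
            spec = spec.with_term(term)
            current = candidate
            decision = "added"
        else:
            decision = "rejected"
            if is_pure_time:
                time_chain_broken = True
        trace_rows.append({"term": term, "lrt": lrt, "p": p, "decision": decision})

    want_slope = random_slope is True or (
        random_slope == "auto" and any(
            _parse_term(t)[0] >= 1 for t in spec.fixed_terms
        )
    )
    if want_slope:
        slope_spec = GrowthModelSpec(
            fixed_terms=list(spec.fixed_terms), random_slope=True,
            mandatory=spec.mandatory,
            nested_event_intercept=spec.nested_event_intercept,
        )
        try:
            cand = fit_growth_model(frame, slope_spec, reml=False)
            lrt = 2.0 * (cand.llf - current.llf)
            p = stats.chi2.sf(max(lrt, 0.0), df=2)
            if cand.spec.random_slope and p < alpha_select:
                spec, current = slope_spec, cand
                decision = "added"
            else:
                decision = "rejected"
            trace_rows.append(
                {"term": "random slope (t)", "lrt": lrt, "p": p,
                 "decision": decision}
            )
        except GrowthConvergenceError:
            trace_rows.append(
                {"term": "random slope (t)", "lrt": np.nan, "p": np.nan,
                 "decision": "skipped: no convergence"}
            )

    final = fit_growth_model(frame, spec, reml=True)
    return spec, final, pd.DataFrame(trace_rows)


class GrowthModel:
    """Model wrapper: build from a response-curve set + covariates.

    >>> gm = GrowthModel(curveset, covariates, component="PC2")
    >>> spec, fit, trace = gm.select()
    >>> print(fit.summary())
    """

    def __init__(
        self,
        curves: ResponseCurveSet,
        covariates: pd.DataFrame,
        component: int | str = 0,
        event_types=MODELED_EVENT_TYPES,
    ):
        self.frame = build_growth_frame(curves, covariates, component, event_types)

    def fit(self, spec: GrowthModelSpec | None = None, reml: bool = True) -> GrowthModelFit:
        return fit_growth_model(self.frame, spec, reml=reml)

    def select(self, **kwargs):
        return select_growth_model(self.frame, **kwargs)
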