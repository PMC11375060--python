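"""Survival screening: Kaplan–Meier, Cox proportional hazards, marker
dichotomization, early/late follow-up windows, per-gene prognostic flags and
2x2 association statistics.

The per-gene screen fits a univariate Cox model on standardized expression
(hazard ratio per standard deviation); genes pass when HR >= 1.2 or <= 0.8
at Wald p < 0.01, and univariately significant genes are re-tested in a
multivariable model adjusted for age, tumor size, nodal status, hormone-
receptor status, HER2 and grade.  Late-window ("5-20 years") analyses use a
landmark at 5 years: subjects event-free at 5 years enter with the clock
reset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.stats import chi2_contingency, norm

from .datatypes import MULTIVARIABLE_COVARIATES, CohortTable


class SingularDesignError(ValueError):
    """Raised when the Cox design matrix is degenerate (e.g. duplicated or
    constant covariates, complete separation)."""


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate, defined at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray


@dataclass(frozen=True)
class SurvivalFit:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    converged: bool
    covariate_hrs: dict[str, tuple[float, float]] = field(default_factory=dict)


def km_estimate(times, events) -> KMEstimate:
    """Kaplan–Meier product-limit estimator.

    Censored subjects leave the risk set after their recorded time (at ties,
    censorings are counted as at risk for the simultaneous event).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no subjects")
    if not np.all(times > 0):
        raise ValueError("times must be > 0")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in event_times:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        n_ev.append(d)
    return KMEstimate(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
    )


def cox_fit(
    design,
    times,
    events,
    marker: str | None = None,
    ties: str = "efron",
    pvalue: str = "wald",
) -> SurvivalFit:
    """Cox proportional-hazards fit; ``hr`` is for the marker covariate.

    ``design`` is a 1-D array (single marker) or a DataFrame whose ``marker``
    column (default: first) is the covariate of interest.  Tie handling is
    Efron's; Wald p-values and 95% CIs come from the observed information.
    """
    if ties != "efron":
        raise NotImplementedError(
            "only Efron tie handling is available in this build"
        )
    if pvalue not in ("wald", "likelihood-ratio"):
        raise ValueError(f"unknown p-value method {pvalue!r}")
    if isinstance(design, pd.DataFrame):
        X = design.reset_index(drop=True).astype(float)
    else:
        X = pd.DataFrame({"marker": np.asarray(design, dtype=float)})
    marker = marker or X.columns[0]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise SingularDesignError(f"covariate {col!r} is constant")
    if X.T.duplicated().any():
        raise SingularDesignError("duplicated covariate columns: singular information")

    df = X.copy()
    df["_time"], df["_event"] = times, events
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event",
                    fit_options={"precision": 1e-9, "max_steps": 500})
    except ConvergenceError as err:
        if "inversion" in str(err) or "singular" in str(err).lower():
            raise SingularDesignError(str(err)) from err
        return SurvivalFit(
            hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
            n=len(times), n_events=int(events.sum()), converged=False,
        )
    summ = cph.summary
    if pvalue == "wald":
        p = float(summ.loc[marker, "p"])
    else:
        ll_full = cph.log_likelihood_
        reduced = df.drop(columns=[marker])
        if reduced.shape[1] == 2:  # only _time/_event left: null model
            ll_red = _null_partial_loglik(times, events)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ll_red = (
                    CoxPHFitter()
                    .fit(reduced, duration_col="_time", event_col="_event")
                    .log_likelihood_
                )
        from scipy.stats import chi2

        p = float(chi2.sf(2.0 * (ll_full - ll_red), df=1))
    covariate_hrs = {
        c: (float(np.exp(summ.loc[c, "coef"])), float(summ.loc[c, "p"]))
        for c in X.columns
        if c != marker
    }
    return SurvivalFit(
        hr=float(np.exp(summ.loc[marker, "coef"])),
        ci_low=float(np.exp(summ.loc[marker, "coef lower 95%"])),
        ci_high=float(np.exp(summ.loc[marker, "coef upper 95%"])),
        p=p,
        n=len(times),
        n_events=int(events.sum()),
        converged=True,
        covariate_hrs=covariate_hrs,
    )


def _null_partial_loglik(times: np.ndarray, events: np.ndarray) -> float:
    """Partial log-likelihood at beta = 0 (Efron and Breslow coincide)."""
    ll = 0.0
    for t in np.unique(times[events == 1]):
        d = int(((times == t) & (events == 1)).sum())
        n_risk = int((times >= t).sum())
        ll -= sum(np.log(n_risk - j) for j in range(d))
    return ll


def dichotomize_by_mean(values, reference_subset=None) -> np.ndarray:
    """HIGH/LOW labels: HIGH iff value >= mean over the reference subset.

    ``reference_subset`` is a boolean mask (default: all samples); values
    exactly at the mean are HIGH.
    """
    values = np.asarray(values, dtype=float)
    if reference_subset is None:
        reference_subset = np.ones(values.shape, dtype=bool)
    reference_subset = np.asarray(reference_subset).astype(bool)
    if not reference_subset.any():
        raise ValueError("reference subset is empty")
    mean = values[reference_subset].mean()
    return np.where(values >= mean, "HIGH", "LOW")


#: follow-up windows in years: early is [0, 5), late is the landmark 5-20
WINDOWS = {"early": (0.0, 5.0), "late": (5.0, 20.0)}


def restrict_window(times, events, window: str) -> tuple[np.ndarray, np.ndarray]:
    """Restrict follow-up to the early (0-5 y) or late (5-20 y) window.

    early — events at or beyond 5 years become censorings at 5 years.
    late — landmark analysis: subjects with time < 5 years are excluded,
    survivors enter with the clock reset (times shifted by -5, capped at 15
    years, later events censored).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {sorted(WINDOWS)}")
    if window == "early":
        new_events = np.where(times < 5.0, events, 0)
        new_times = np.minimum(times, 5.0)
        return new_times, new_events
    keep = times >= 5.0
    t = times[keep] - 5.0
    ev = events[keep]
    new_events = np.where(t <= 15.0, ev, 0)
    new_times = np.maximum(np.minimum(t, 15.0), 1e-9)
    return new_times, new_events


def prognostic_screen(
    cohort: CohortTable,
    hr_hi: float = 1.2,
    hr_lo: float = 0.8,
    alpha: float = 0.01,
    marker_mode: str = "continuous",
    window: str | None = None,
    multivariable: bool = True,
) -> pd.DataFrame:
    """Per-gene univariate Cox screen with optional multivariable follow-up.

    ``marker_mode='continuous'`` standardizes expression (HR per SD);
    ``'mean-split'`` dichotomizes at the cohort mean.  A gene is flagged
    ``significant_uni`` when HR >= hr_hi or <= hr_lo with p < alpha; only
    those genes get a multivariable fit (marker + clinical covariates).
    Genes whose fit fails to converge are retained with ``converged=False``.
    """
    times = cohort.samples["time"].to_numpy(float)
    events = cohort.samples["event"].to_numpy(int)
    if window is not None:
        # recompute per-subject inclusion for the landmark consistently
        times, events, keep = _windowed(times, events, window)
    else:
        keep = np.ones(len(times), dtype=bool)
    covs = cohort.samples.loc[cohort.samples.index[keep], list(MULTIVARIABLE_COVARIATES)]
    rows = []
    for gene in cohort.genes:
        vals = cohort.expression.loc[gene].to_numpy(float)[keep]
        if marker_mode == "continuous":
            marker = (vals - vals.mean()) / vals.std(ddof=0)
        elif marker_mode == "mean-split":
            marker = (dichotomize_by_mean(vals) == "HIGH").astype(float)
        else:
            raise ValueError(f"unknown marker mode {marker_mode!r}")
        fit = cox_fit(marker, times, events)
        sig_uni = bool(
            fit.converged
            and (fit.hr >= hr_hi or fit.hr <= hr_lo)
            and fit.p < alpha
        )
        row = {
            "gene": gene,
            "hr_uni": fit.hr,
            "ci_low": fit.ci_low,
            "ci_high": fit.ci_high,
            "p_uni": fit.p,
            "converged": fit.converged,
            "significant_uni": sig_uni,
            "direction": "bad" if fit.hr > 1 else "good",
            "hr_multi": np.nan,
            "p_multi": np.nan,
            "significant_multi": False,
        }
        if sig_uni and multivariable:
            design = covs.copy()
            design.insert(0, "marker", marker)
            mfit = cox_fit(design, times, events, marker="marker")
            row["hr_multi"] = mfit.hr
            row["p_multi"] = mfit.p
            row["significant_multi"] = bool(mfit.converged and mfit.p < alpha)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def _windowed(times, events, window):
    if window == "early":
        t, e = restrict_window(times, events, "early")
        return t, e, np.ones(len(times), dtype=bool)
    keep = np.asarray(times, dtype=float) >= 5.0
    t, e = restrict_window(times, events, "late")
    return t, e, keep


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float, float]:
    """Odds ratio with Woolf 95% CI and Pearson chi-square p (no continuity
    correction).  Haldane's 0.5 correction is applied to all cells when any
    cell is zero."""
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any() or not np.allclose(cells, np.round(cells)):
        raise ValueError("cell counts must be non-negative integers")
    if cells.sum() == 0:
        raise ValueError("all-zero table")
    table = cells.reshape(2, 2)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("row and column totals must be positive")
    aa, bb, cc, dd = cells + 0.5 if (cells == 0).any() else cells
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = norm.ppf(0.975)
    ci_low, ci_high = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return float(or_), float(ci_low), float(ci_high), float(p)
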