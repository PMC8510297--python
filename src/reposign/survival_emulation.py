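"""Target-trial-style retrospective cohort construction and survival analysis.

Pipeline: assemble an analysis cohort from a subject-level event stream
(diagnoses, prescriptions, procedures, visits) under new-user /
active-comparator rules; estimate survival by Kaplan–Meier; fit Cox
proportional-hazards models by Newton–Raphson on the partial likelihood
(Efron or Breslow tie handling); check the PH assumption with a scaled
Schoenfeld residual score test; and run the design sensitivity analyses —
propensity-score matching, treatment-duration thresholds, a long- vs
short-term contrast, and a negative-control outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

MAX_NEWTON_ITER = 25
SCORE_TOL = 1e-9
#: |coef| beyond which the partial likelihood is treated as monotone
MONOTONE_COEF_LIMIT = 50.0


class CohortError(ValueError):
    pass


class FitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# code matching and cohort assembly
# ---------------------------------------------------------------------------

def _compile_patterns(codes: Iterable[str]) -> list[tuple[str, bool]]:
    """Normalize code patterns: trailing '.x' (or '*') marks a prefix match."""
    out = []
    for c in codes:
        c = str(c).strip()
        if not c or c.startswith("#"):
            continue
        if c.endswith(".x") or c.endswith(".X"):
            out.append((c[:-2], True))
        elif c.endswith("*"):
            out.append((c.rstrip("*").rstrip("."), True))
        else:
            out.append((c, False))
    return out


def code_matches(code: str, patterns: list[tuple[str, bool]]) -> bool:
    code = str(code)
    for base, is_prefix in patterns:
        if is_prefix:
            if code == base or code.startswith(base + ".") or (
                code.startswith(base) and len(code) > len(base)
            ):
                return True
        elif code == base:
            return True
    return False


def load_code_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def build_cohort(
    events: pd.DataFrame,
    diagnosis_codes: Sequence[str],
    exposure_drugs: Sequence[str],
    comparator_drugs: Sequence[str],
    exclusion_dx: Sequence[str],
    outcome_codes: Sequence[str],
    demographics: pd.DataFrame | None = None,
    comorbidity_codes: Mapping[str, Sequence[str]] | None = None,
    extra_outcomes: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assemble the analysis cohort from an event stream.

    ``events`` columns: subject_id, date (ISO-8601), kind in
    {dx, rx, px, visit}, code.  A subject qualifies with a qualifying
    diagnosis, no exclusion diagnosis at any time, and an exposure or
    comparator prescription strictly after the first qualifying diagnosis.
    Exposure wins over comparator (intention-to-treat at initiation: index
    at the first exposure-drug date); otherwise index is the first
    comparator prescription.  Follow-up runs from index to the first outcome
    code, else censoring at the last recorded event; subjects with the
    outcome on or before index are excluded.  Covariate flags (comorbidity
    and per-comparator-drug use) count any occurrence on or before index.

    Returns the cohort table and an attrition report (counts per rule).
    """
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    dx_pat = _compile_patterns(diagnosis_codes)
    excl_pat = _compile_patterns(exclusion_dx)
    out_pat = _compile_patterns(outcome_codes)
    expo = {str(d).lower() for d in exposure_drugs}
    comp = [str(d).lower() for d in comparator_drugs]
    extra_pat = {name: _compile_patterns(codes) for name, codes in (extra_outcomes or {}).items()}
    com_pat = {name: _compile_patterns(codes) for name, codes in (comorbidity_codes or {}).items()}

    demo = None
    if demographics is not None:
        demo = demographics.set_index("subject_id")
        if "birth_date" in demo.columns:
            demo["birth_date"] = pd.to_datetime(demo["birth_date"])

    attrition = {
        "total_subjects": 0, "no_diagnosis": 0, "exclusion_dx": 0,
        "no_qualifying_rx": 0, "rx_only_before_dx": 0, "prior_or_index_outcome": 0,
        "both_drug_classes": 0, "included": 0,
    }
    rows = []
    for sid, sub in ev.sort_values("date").groupby("subject_id", sort=True):
        attrition["total_subjects"] += 1
        dx = sub[sub["kind"] == "dx"]
        if dx["code"].apply(lambda c: code_matches(c, excl_pat)).any():
            attrition["exclusion_dx"] += 1
            continue
        qual_dx = dx[dx["code"].apply(lambda c: code_matches(c, dx_pat))]
        if qual_dx.empty:
            attrition["no_diagnosis"] += 1
            continue
        first_dx = qual_dx["date"].min()

        rx = sub[sub["kind"] == "rx"].copy()
        rx["drug"] = rx["code"].astype(str).str.lower()
        is_study_drug = rx["drug"].isin(expo | set(comp))
        qual_rx = rx[is_study_drug & (rx["date"] > first_dx)]
        if qual_rx.empty:
            if (is_study_drug & (rx["date"] <= first_dx)).any():
                attrition["rx_only_before_dx"] += 1
            else:
                attrition["no_qualifying_rx"] += 1
            continue
        expo_rx = qual_rx[qual_rx["drug"].isin(expo)]
        comp_rx = qual_rx[~qual_rx["drug"].isin(expo)]
        if not expo_rx.empty:
            arm, index_date = "treatment", expo_rx["date"].min()
            if not comp_rx.empty:
                attrition["both_drug_classes"] += 1
        else:
            arm, index_date = "comparator", comp_rx["date"].min()

        outcome_ev = sub[sub["kind"].isin(["px", "dx"]) &
                         sub["code"].apply(lambda c: code_matches(c, out_pat))]
        if not outcome_ev.empty and outcome_ev["date"].min() <= index_date:
            attrition["prior_or_index_outcome"] += 1
            continue
        last_date = sub["date"].max()
        if outcome_ev.empty:
            event, end = 0, last_date
        else:
            event, end = 1, outcome_ev["date"].min()
        time_days = (end - index_date).days
        if time_days <= 0:
            attrition["prior_or_index_outcome"] += 1
            continue

        row = {
            "subject_id": sid,
            "exposure": 1 if arm == "treatment" else 0,
            "index_date": index_date,
            "time_days": float(time_days),
            "event": event,
        }
        if demo is not None and sid in demo.index:
            if "birth_date" in demo.columns:
                row["age"] = (index_date - demo.loc[sid, "birth_date"]).days / 365.25
            if "sex" in demo.columns:
                sex = str(demo.loc[sid, "sex"]).lower()
                row["sex"] = 1 if sex in ("m", "male", "1") else 0
        before = sub[sub["date"] <= index_date]
        for name, pat in com_pat.items():
            row[name] = int(before[(before["kind"] == "dx")]["code"]
                            .apply(lambda c: code_matches(c, pat)).any())
        for drug in comp:
            row[f"rx_{drug}"] = int((rx["drug"] == drug).any() and
                                    (rx[rx["drug"] == drug]["date"] <= index_date).any())
        for name, pat in extra_pat.items():
            alt = sub[sub["kind"].isin(["px", "dx"]) &
                      sub["code"].apply(lambda c: code_matches(c, pat))]
            alt = alt[alt["date"] > index_date]
            if alt.empty:
                row[f"time_{name}_days"] = float((last_date - index_date).days)
                row[f"event_{name}"] = 0
            else:
                row[f"time_{name}_days"] = float((alt["date"].min() - index_date).days)
                row[f"event_{name}"] = 1
        rows.append(row)
        attrition["included"] += 1

    cohort = pd.DataFrame(rows)
    logger.info("build_cohort attrition: %s", attrition)
    return cohort, attrition


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimator(time, event) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood variance.

    Rows at each distinct event time: t, n_at_risk, n_events, S(t) and
    Greenwood variance of S(t).  Censored-only times shrink the risk set
    but add no row.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(bool)
    if t.size == 0:
        raise FitError("empty input")
    order = np.argsort(t, kind="mergesort")
    t, d = t[order], d[order]
    rows = []
    s = 1.0
    gw = 0.0  # running sum d_i / (n_i (n_i - d_i))
    n = t.size
    i = 0
    while i < n:
        ti = t[i]
        j = i
        deaths = 0
        while j < n and t[j] == ti:
            deaths += int(d[j])
            j += 1
        at_risk = n - i
        if deaths > 0:
            s *= 1.0 - deaths / at_risk
            if at_risk > deaths:
                gw += deaths / (at_risk * (at_risk - deaths))
                var = s * s * gw
            else:
                var = 0.0
            rows.append({"t": ti, "n_at_risk": at_risk, "n_events": deaths,
                         "survival": s, "greenwood_var": var})
        i = j
    return pd.DataFrame(rows, columns=["t", "n_at_risk", "n_events",
                                       "survival", "greenwood_var"])


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton-Raphson on the partial likelihood)
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """Fitted Cox model: per-covariate log-HRs with Wald inference."""

    coef: dict[str, float]
    se: dict[str, float]
    hr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p: dict[str, float]
    loglik: float
    n: int
    n_events: int
    ties_method: str
    covariates: list[str] = field(default_factory=list)
    _design: tuple | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.covariates:
            lo, hi = self.ci95[c]
            rows.append({"covariate": c, "coef": self.coef[c], "se": self.se[c],
                         "hr": self.hr[c], "hr_lo95": lo, "hr_hi95": hi, "p": self.p[c]})
        return pd.DataFrame(rows)


def _time_groups(T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and sizes of equal-time groups in a descending-sorted T."""
    starts = np.flatnonzero(np.r_[True, T[1:] != T[:-1]])
    sizes = np.diff(np.r_[starts, len(T)])
    return starts, sizes


def _cox_loglik(beta: np.ndarray, T: np.ndarray, D: np.ndarray, X: np.ndarray,
                ties: str) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, score and observed information (vectorized).

    Subjects must be sorted by time descending so risk-set sums are
    cumulative sums down the array.  Efron downweights the tied event mass
    by l/m within each tied group; Breslow keeps the full risk set for
    every tied event.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard exp overflow; cancels in ratios
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]   # (n, p, p)

    starts, sizes = _time_groups(T)
    ends = starts + sizes - 1
    # risk-set sums at each group = cumulative sums through the group end
    rs0 = np.cumsum(w)[ends]
    rs1 = np.cumsum(wx, axis=0)[ends]
    rs2 = np.cumsum(wxx.reshape(n, p * p), axis=0)[ends].reshape(-1, p, p)

    # tied-event mass per group
    dw = np.where(D, w, 0.0)
    dwx = np.where(D[:, None], wx, 0.0)
    dwxx = np.where(D[:, None, None], wxx, 0.0)
    d0 = np.add.reduceat(dw, starts)
    d1 = np.add.reduceat(dwx, starts, axis=0)
    d2 = np.add.reduceat(dwxx.reshape(n, p * p), starts, axis=0).reshape(-1, p, p)
    m = np.add.reduceat(D.astype(float), starts)

    has = m > 0
    g_idx = np.flatnonzero(has)
    m_ev = m[g_idx].astype(int)
    rep = np.repeat(np.arange(len(g_idx)), m_ev)          # event -> local group
    offs = np.arange(m_ev.sum()) - np.repeat(np.cumsum(m_ev) - m_ev, m_ev)
    if ties == "efron":
        phi = offs / np.repeat(m_ev, m_ev)
    else:
        phi = np.zeros(m_ev.sum())

    den = rs0[g_idx][rep] - phi * d0[g_idx][rep]
    z1 = (rs1[g_idx][rep] - phi[:, None] * d1[g_idx][rep]) / den[:, None]
    z2 = (rs2[g_idx][rep] - phi[:, None, None] * d2[g_idx][rep]) / den[:, None, None]

    ll = float(eta[D].sum() - np.log(den).sum())
    score = X[D].sum(axis=0) - z1.sum(axis=0)
    info = z2.sum(axis=0) - np.einsum("ij,ik->jk", z1, z1)
    return ll, score, info


def cox_fit(
    cohort: pd.DataFrame,
    covariate_names: Sequence[str],
    ties: str = "efron",
    time_col: str = "time_days",
    event_col: str = "event",
) -> SurvivalFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Analytic score and observed information; convergence when the maximum
    absolute score component falls below 1e-9, capped at 25 iterations with
    step-halving.  Standard errors come from the inverse observed
    information; CIs and p-values are Wald.  Collinear covariates raise a
    singular-information error; a monotone partial likelihood (perfect
    separation) raises an error suggesting a penalized remedy.
    """
    if ties not in ("efron", "breslow"):
        raise FitError(f"unknown ties method {ties!r}")
    covariate_names = list(covariate_names)
    data = cohort[[time_col, event_col, *covariate_names]].dropna()
    T = data[time_col].to_numpy(dtype=float)
    D = data[event_col].to_numpy().astype(bool)
    X = data[covariate_names].to_numpy(dtype=float)
    n, p = X.shape
    if D.sum() < 1:
        raise FitError("no events in the cohort")
    if (T <= 0).any():
        raise FitError("all follow-up times must be positive")
    const = [c for c, s in zip(covariate_names, X.std(axis=0)) if s == 0]
    if const:
        raise FitError(f"constant covariates: {const}")

    order = np.argsort(-T, kind="mergesort")
    T, D, X = T[order], D[order], X[order]
    center = X.mean(axis=0)
    Xc = X - center  # centering: invariant for beta, stabilizes exp()

    beta = np.zeros(p)
    ll, score, info = _cox_loglik(beta, T, D, Xc, ties)
    for _ in range(MAX_NEWTON_ITER):
        if np.abs(score).max() < SCORE_TOL:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise FitError(
                f"singular information matrix: collinear covariates among {covariate_names}"
            )
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_loglik(new_beta, T, D, Xc, ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 10:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_loglik(new_beta, T, D, Xc, ties)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.abs(beta).max() > MONOTONE_COEF_LIMIT:
            raise FitError(
                "monotone partial likelihood (perfect separation); "
                "a Firth-style penalized fit would be needed"
            )
    else:
        if np.abs(score).max() >= 1e-4:
            raise FitError(
                f"Newton-Raphson did not converge in {MAX_NEWTON_ITER} iterations "
                f"(max |score| = {np.abs(score).max():.3g})"
            )

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise FitError("singular information matrix at the optimum")
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    zc = stats.norm.ppf(0.975)

    fit = SurvivalFit(
        coef={c: float(b) for c, b in zip(covariate_names, beta)},
        se={c: float(s) for c, s in zip(covariate_names, se)},
        hr={c: float(np.exp(b)) for c, b in zip(covariate_names, beta)},
        ci95={c: (float(np.exp(b - zc * s)), float(np.exp(b + zc * s)))
              for c, b, s in zip(covariate_names, beta, se)},
        p={c: float(v) for c, v in zip(covariate_names, pvals)},
        loglik=float(ll),
        n=int(n),
        n_events=int(D.sum()),
        ties_method=ties,
        covariates=covariate_names,
        _design=(T, D, Xc, beta, cov),
    )
    return fit


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def _schoenfeld_residuals(T, D, Xc, beta):
    """Schoenfeld residuals x_i - xbar(t_i) at each event; input sorted by
    time descending, output in ascending event-time order."""
    w = np.exp(Xc @ beta)
    starts, sizes = _time_groups(T)
    ends = starts + sizes - 1
    rs0 = np.cumsum(w)[ends]
    rs1 = np.cumsum(w[:, None] * Xc, axis=0)[ends]
    xbar = rs1 / rs0[:, None]
    group_of = np.repeat(np.arange(len(starts)), sizes)
    res = Xc[D] - xbar[group_of[D]]
    times = T[D]
    order = np.argsort(times, kind="mergesort")
    return times[order], res[order]


def ph_test(fit: SurvivalFit, time_transform: str = "km") -> dict[str, float]:
    """Grambsch-Therneau scaled-Schoenfeld score test of proportional hazards.

    Regresses the scaled Schoenfeld residuals on a transform of event time
    (``km``: 1 - left-continuous Kaplan-Meier; ``rank``; ``identity``) and
    returns a chi-square(1) p-value per covariate plus ``GLOBAL``.
    """
    if fit._design is None:
        raise FitError("fit carries no design information")
    T, D, Xc, beta, cov = fit._design
    times, sres = _schoenfeld_residuals(T, D, Xc, beta)
    d = len(times)
    if d < 3:
        raise FitError("too few events for a PH test")
    if time_transform == "km":
        km = km_estimator(T, D)
        # left-continuous KM at each event time
        surv_before = {}
        prev = 1.0
        for r in km.itertuples():
            surv_before[r.t] = prev
            prev = r.survival
        g = np.array([1.0 - surv_before[t] for t in times])
    elif time_transform == "rank":
        g = stats.rankdata(times).astype(float)
    elif time_transform == "identity":
        g = times.astype(float)
    else:
        raise FitError(f"unknown time transform {time_transform!r}")
    gc = g - g.mean()
    ssg = float((gc ** 2).sum())

    u = gc @ sres                      # p-vector
    # per-covariate: T_j = d * (u V)_j^2 / (V_jj * sum gc^2)
    uv = u @ cov
    out: dict[str, float] = {}
    for j, name in enumerate(fit.covariates):
        chi2 = d * uv[j] ** 2 / (cov[j, j] * ssg)
        out[name] = float(stats.chi2.sf(chi2, df=1))
    chi2_glob = d * float(u @ cov @ u) / ssg
    out["GLOBAL"] = float(stats.chi2.sf(chi2_glob, df=len(fit.covariates)))
    return out


# ---------------------------------------------------------------------------
# propensity matching
# ---------------------------------------------------------------------------

def standardized_mean_differences(
    cohort: pd.DataFrame, covariate_names: Sequence[str], exposure_col: str = "exposure"
) -> pd.Series:
    t = cohort[cohort[exposure_col] == 1]
    c = cohort[cohort[exposure_col] == 0]
    out = {}
    for cov in covariate_names:
        mt, mc = t[cov].mean(), c[cov].mean()
        pooled = np.sqrt((t[cov].var(ddof=1) + c[cov].var(ddof=1)) / 2.0)
        out[cov] = 0.0 if pooled == 0 else (mt - mc) / pooled
    return pd.Series(out, name="smd")


def propensity_match(
    cohort: pd.DataFrame,
    covariate_names: Sequence[str],
    caliper_logit: float = 0.0,
    exposure_col: str = "exposure",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """1:1 nearest-neighbor propensity matching without replacement.

    The propensity score is an L1-penalized logistic regression of exposure
    on the covariates (penalty chosen by 5-fold cross-validated deviance);
    matching is greedy in descending treated propensity on the logit scale.
    ``caliper_logit = 0`` means no caliper constraint; a positive value
    caps the logit distance of an acceptable match.

    Returns the matched cohort and a balance report with standardized mean
    differences before and after matching.
    """
    treated = cohort[cohort[exposure_col] == 1]
    control = cohort[cohort[exposure_col] == 0]
    if control.empty:
        raise CohortError("no comparator subjects to match against")
    if treated.empty:
        raise CohortError("no treated subjects to match")

    Xs = StandardScaler().fit_transform(cohort[list(covariate_names)].to_numpy(dtype=float))
    y = cohort[exposure_col].to_numpy().astype(int)
    model = LogisticRegressionCV(
        l1_ratios=(1.0,), solver="saga", Cs=10,
        cv=StratifiedKFold(5, shuffle=True, random_state=seed),
        scoring="neg_log_loss", max_iter=5000, random_state=seed,
        use_legacy_attributes=False,
    ).fit(Xs, y)
    ps = np.clip(model.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
    logit = np.log(ps / (1 - ps))
    cohort = cohort.copy()
    cohort["_propensity"] = ps
    cohort["_logit_ps"] = logit

    t_idx = cohort.index[cohort[exposure_col] == 1]
    c_idx = cohort.index[cohort[exposure_col] == 0]
    lt = cohort.loc[t_idx, "_logit_ps"].to_numpy()
    lc = cohort.loc[c_idx, "_logit_ps"].to_numpy()
    available = np.ones(len(c_idx), dtype=bool)
    pairs = []
    for ti in np.argsort(-lt, kind="mergesort"):
        dist = np.abs(lc - lt[ti])
        dist[~available] = np.inf
        j = int(np.argmin(dist))
        if not np.isfinite(dist[j]):
            break
        if caliper_logit > 0 and dist[j] > caliper_logit:
            continue
        available[j] = False
        pairs.append((t_idx[ti], c_idx[j]))

    matched_idx = [i for pair in pairs for i in pair]
    matched = cohort.loc[matched_idx].drop(columns=["_propensity", "_logit_ps"])
    balance = pd.DataFrame({
        "smd_before": standardized_mean_differences(cohort, covariate_names, exposure_col),
        "smd_after": standardized_mean_differences(matched, covariate_names, exposure_col),
    })
    return matched, balance


# ---------------------------------------------------------------------------
# sensitivity and bias analyses
# ---------------------------------------------------------------------------

MIN_STABLE_TREATED = 5


def duration_sensitivity(
    cohort: pd.DataFrame,
    rx_durations: pd.Series,
    min_duration_grid: Sequence[float],
    covariate_names: Sequence[str] = ("exposure",),
    ties: str = "efron",
) -> pd.DataFrame:
    """Refit the Cox model under increasing minimum treatment duration.

    At each threshold the treated arm is restricted to subjects whose
    on-therapy duration meets it (comparators unchanged); grid points
    leaving fewer than 5 treated subjects are marked unstable.
    """
    rows = []
    dur = cohort["subject_id"].map(rx_durations)
    for thr in min_duration_grid:
        keep = (cohort["exposure"] == 0) | (dur >= thr)
        sub = cohort[keep]
        n_treated = int((sub["exposure"] == 1).sum())
        row = {"min_duration": thr, "n_treated": n_treated,
               "stable": n_treated >= MIN_STABLE_TREATED}
        if row["stable"]:
            try:
                fit = cox_fit(sub, covariate_names, ties=ties)
                lo, hi = fit.ci95["exposure"]
                row.update(hr=fit.hr["exposure"], hr_lo95=lo, hr_hi95=hi,
                           se_log_hr=fit.se["exposure"], p=fit.p["exposure"])
            except FitError as exc:
                logger.warning("duration threshold %s: %s", thr, exc)
                row["stable"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def long_short_term_contrast(
    cohort: pd.DataFrame,
    rx_durations: pd.Series,
    min_followup_days: float = 720.0,
    short_max_days: float = 182.5,
    covariate_names: Sequence[str] = (),
    ties: str = "efron",
) -> SurvivalFit:
    """Among treated subjects followed at least ``min_followup_days``,
    compare long-term (on therapy > ~6 months) against short-term use."""
    treated = cohort[(cohort["exposure"] == 1) &
                     (cohort["time_days"] >= min_followup_days)].copy()
    if treated.empty:
        raise CohortError("no treated subject with the required follow-up")
    dur = treated["subject_id"].map(rx_durations)
    treated["long_term"] = (dur >= short_max_days).astype(int)
    return cox_fit(treated, ["long_term", *covariate_names], ties=ties)


def negative_control(
    cohort: pd.DataFrame,
    covariate_names: Sequence[str] = ("exposure",),
    time_col: str = "time_control_days",
    event_col: str = "event_control",
    ties: str = "efron",
) -> SurvivalFit:
    """Refit the Cox model on a negative-control outcome.

    The control outcome shares the confounding structure of the primary
    outcome but carries no true treatment effect; a CI excluding 1 flags
    residual (e.g. healthy-user) bias in the design or adjustment.
    """
    if time_col not in cohort.columns or event_col not in cohort.columns:
        raise CohortError(f"cohort lacks control outcome columns {time_col}/{event_col}")
    return cox_fit(cohort, covariate_names, ties=ties,
                   time_col=time_col, event_col=event_col)
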