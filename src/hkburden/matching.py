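"""Two-stage matching and balance diagnostics.

Stage 1 (:func:`coarse_match`) builds a candidate pool: exact match on
sex and CKD-diagnosis calendar year, nearest by age at diagnosis, up to
a configurable ratio (default 1:30), without replacement. Each selected
control inherits its HK partner's index date, after which the enrollment
filter is re-applied.

Stage 2 (:class:`PropensityMatcher`) fits a logistic propensity model of
HK membership on the baseline covariates and performs greedy 1:1
nearest-neighbor matching without replacement on the logit propensity
scale, HK members processed in descending score order, with a caliper of
0.2 pooled SD of the logit score by default (the standard Austin
recommendation; configurable, including no caliper).

Balance is assessed with signed standardized differences (HK minus
control); |d| <= 0.10 is conventionally considered inconsequential.
All tie-breaks are by ascending patient_id so matching is deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .cohorts import apply_enrollment_filter
from .dataset import NON_HK, ClaimsDataset, to_day

log = logging.getLogger(__name__)

BALANCE_THRESHOLD = 0.10


class MatchingError(ValueError):
    pass


# ---------------------------------------------------------------------
# standardized differences


def standardized_difference(x_hk, x_control, kind: str) -> float:
    """Signed standardized difference (HK minus control).

    ``kind="continuous"``: d = (m1 - m2) / sqrt((s1^2 + s2^2) / 2) with
    sample SDs. ``kind="binary"``: d = (p1 - p2) / sqrt((p1(1-p1) +
    p2(1-p2)) / 2); inputs are 0/1 arrays or ``(successes, n)`` tuples.
    A 0/0 ratio returns 0; zero pooled variance with unequal means is
    undefined and raises.
    """
    if kind == "binary":
        p1, n1 = _as_proportion(x_hk)
        p2, n2 = _as_proportion(x_control)
        if n1 < 1 or n2 < 1:
            raise MatchingError("binary standardized difference needs n >= 1 per group")
        num = p1 - p2
        denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    elif kind == "continuous":
        a = np.asarray(x_hk, dtype=float)
        b = np.asarray(x_control, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise MatchingError("continuous standardized difference needs n >= 2 per group")
        num = a.mean() - b.mean()
        denom = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    else:
        raise MatchingError(f"unknown kind {kind!r}")
    if denom == 0.0:
        if num == 0.0:
            return 0.0
        raise MatchingError("zero pooled variance with unequal means: d undefined")
    return float(num / denom)


def _as_proportion(x) -> tuple[float, int]:
    if isinstance(x, tuple) and len(x) == 2:
        successes, n = x
        return (successes / n if n else np.nan), int(n)
    arr = np.asarray(x, dtype=float)
    return (arr.mean() if arr.size else np.nan), arr.size


# ---------------------------------------------------------------------
# stage 1: coarse match


def coarse_match(
    hk_members: pd.DataFrame,
    non_hk_candidates: pd.DataFrame,
    data: ClaimsDataset,
    ratio: int = 30,
    pre_days: int = 360,
    post_days: int = 360,
    study_end: str | None = None,
) -> tuple[pd.DataFrame, list]:
    """Select up to ``ratio`` controls per HK member (exact on sex and
    CKD-diagnosis year, nearest by age at diagnosis), assign the HK
    partner's index date, and re-apply the enrollment filter.

    Controls are drawn without replacement. Selection is round-robin
    (every HK member, in ascending patient_id, takes its nearest unused
    candidate before anyone takes a second), so a scarce stratum is
    shared instead of exhausted by the first members processed; age ties
    break toward the smaller patient_id. Returns (control pool with
    inherited index dates, HK ids with zero eligible candidates).
    """
    patients = data.patients.set_index("patient_id")
    unmatched: list = []
    pool_rows: list[pd.DataFrame] = []

    def _prep(frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        diag_day = to_day(out["ckd_diagnosis_date"])
        birth_day = to_day(out["patient_id"].map(patients["birth_date"]))
        out["sex"] = out["patient_id"].map(patients["sex"]).to_numpy()
        out["diag_year"] = out["ckd_diagnosis_date"].dt.year.to_numpy()
        out["age_at_diag"] = (diag_day - birth_day) / 365.25
        return out

    hk = _prep(hk_members).sort_values("patient_id")
    cand = _prep(non_hk_candidates)

    for (sex, year), hk_grp in hk.groupby(["sex", "diag_year"], sort=True):
        grp = cand[(cand["sex"] == sex) & (cand["diag_year"] == year)]
        grp = grp.sort_values(["age_at_diag", "patient_id"], ignore_index=True)
        ages = grp["age_at_diag"].to_numpy()
        pids = grp["patient_id"].to_numpy()
        m = len(grp)
        # path-compressed jump pointers over the age-sorted candidates:
        # rj[i] = smallest live index >= i (m = none), lj[i+1] = largest
        # live index <= i (slot 0 = none)
        rj = list(range(m + 1))
        lj = list(range(m + 1))
        taken: dict = {hk_row.patient_id: [] for hk_row in hk_grp.itertuples()}
        hk_rows = list(hk_grp.itertuples())
        searches = {
            hk_row.patient_id: int(np.searchsorted(ages, hk_row.age_at_diag))
            for hk_row in hk_rows
        }
        # round-robin: everyone takes their nearest unused candidate
        # before anyone takes a second
        for _round in range(ratio):
            if not m:
                break
            any_taken = False
            for hk_row in hk_rows:
                target = hk_row.age_at_diag
                pos = searches[hk_row.patient_id]
                right = _jump(rj, pos)
                left = _jump(lj, pos) - 1
                dl = target - ages[left] if left >= 0 else np.inf
                dr = ages[right] - target if right < m else np.inf
                if np.isinf(dl) and np.isinf(dr):
                    continue
                if dl < dr or (
                    dl == dr and left >= 0
                    and (right >= m or pids[left] < pids[right])
                ):
                    pick = left
                else:
                    pick = right
                taken[hk_row.patient_id].append(pick)
                any_taken = True
                rj[pick] = pick + 1
                lj[pick + 1] = pick
            if not any_taken:
                break
        for hk_row in hk_rows:
            picks = taken[hk_row.patient_id]
            if not picks:
                unmatched.append(hk_row.patient_id)
                continue
            sel = grp.loc[picks, ["patient_id", "ckd_diagnosis_date"]].copy()
            sel["cohort"] = NON_HK
            sel["index_date"] = hk_row.index_date
            sel["hk_partner"] = hk_row.patient_id
            pool_rows.append(sel)

    if pool_rows:
        pool = pd.concat(pool_rows, ignore_index=True)
    else:
        pool = pd.DataFrame(
            columns=["patient_id", "ckd_diagnosis_date", "cohort", "index_date", "hk_partner"]
        )
    n0 = len(pool)
    pool = apply_enrollment_filter(
        pool, data, pre_days=pre_days, post_days=post_days, study_end=study_end
    )
    log.info("coarse match: %d controls pooled, %d after enrollment filter, %d HK unmatched",
             n0, len(pool), len(unmatched))
    return pool, unmatched


def _jump(arr: list, i: int) -> int:
    """Follow (and compress) jump pointers to the nearest live slot."""
    root = i
    while arr[root] != root:
        root = arr[root]
    while arr[i] != root:
        arr[i], i = root, arr[i]
    return root


# ---------------------------------------------------------------------
# stage 2: propensity model + 1:1 match


@dataclasses.dataclass
class PropensityModel:
    """Fitted logistic propensity model for HK membership."""

    coefficients: dict[str, float]
    intercept: float
    scores: pd.Series  # patient_id -> P(HK | covariates)
    converged: bool
    dropped_constant: tuple[str, ...] = ()
    separation_fallback: bool = False

    def logit_scores(self) -> pd.Series:
        p = self.scores.clip(1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))


@dataclasses.dataclass
class MatchedPairSet:
    """1:1 HK-control pairing on the logit propensity scale."""

    pairs: pd.DataFrame  # hk_id, control_id, ps_hk, ps_control
    unmatched_hk: tuple
    caliper: float | None

    def __len__(self) -> int:
        return len(self.pairs)


def fit_propensity(covariates: pd.DataFrame, labels: pd.Series) -> PropensityModel:
    """Maximum-likelihood logistic fit of HK membership on the covariates.

    Constant columns are dropped (logged). Perfect separation triggers a
    warning and a fallback to a lightly ridge-penalized fit (1e-6).
    """
    if covariates.empty:
        raise MatchingError("empty covariate pool")
    labels = pd.Series(labels).loc[covariates.index].astype(float)
    if labels.nunique() != 2:
        raise MatchingError("propensity fit needs both cohorts in the pool")
    keep = [c for c in covariates.columns if covariates[c].nunique() > 1]
    dropped = tuple(c for c in covariates.columns if c not in keep)
    if dropped:
        log.info("propensity fit: dropping constant covariates %s", list(dropped))
    X = covariates[keep].astype(float)
    fallback = False
    try:
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = sm.Logit(labels, sm.add_constant(X, has_constant="add")).fit(
                disp=False, maxiter=100, tol=1e-8
            )
        params = res.params
        converged = bool(res.mle_retvals.get("converged", True))
        scores = pd.Series(np.asarray(res.predict()), index=covariates.index)
        if not converged:
            raise RuntimeError("logit did not converge")
    except Exception as exc:  # separation / non-convergence
        warnings.warn(
            f"propensity model fell back to a ridge penalty (1e-6): {exc}",
            RuntimeWarning, stacklevel=2,
        )
        fallback = True
        clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
        clf.fit(X.to_numpy(), labels.to_numpy())
        params = pd.Series(
            np.concatenate([[clf.intercept_[0]], clf.coef_[0]]), index=["const"] + keep
        )
        scores = pd.Series(
            clf.predict_proba(X.to_numpy())[:, 1], index=covariates.index
        )
        converged = True
    return PropensityModel(
        coefficients={c: float(params[c]) for c in keep},
        intercept=float(params["const"]),
        scores=scores.clip(1e-12, 1 - 1e-12),
        converged=converged,
        dropped_constant=dropped,
        separation_fallback=fallback,
    )


class PropensityMatcher(BaseEstimator):
    """Propensity-score 1:1 matcher with the sklearn estimator protocol.

    ``fit(X, y)`` takes baseline covariates indexed by patient_id and a
    binary label (1 = HK). It fits the logistic propensity model and runs
    greedy nearest-neighbor matching without replacement on the logit
    score, processing HK members in descending score order.

    Parameters
    ----------
    caliper_sd : float or None
        Caliper as a multiple of the SD of the logit score over the
        pool (default 0.2); ``None`` disables the caliper.
    caliper : float or None
        Absolute caliper on the logit scale; overrides ``caliper_sd``.

    Attributes
    ----------
    model_ : PropensityModel
    pairs_ : MatchedPairSet
    caliper_ : float or None
    """

    def __init__(self, caliper_sd: float | None = 0.2, caliper: float | None = None):
        self.caliper_sd = caliper_sd
        self.caliper = caliper

    def fit(self, X: pd.DataFrame, y) -> "PropensityMatcher":
        y = pd.Series(np.asarray(y), index=X.index)
        self.model_ = fit_propensity(X, y)
        logit = self.model_.logit_scores()
        if self.caliper is not None:
            caliper = float(self.caliper)
        elif self.caliper_sd is not None:
            caliper = float(self.caliper_sd) * float(logit.std(ddof=1))
        else:
            caliper = None
        hk_ids = X.index[y == 1]
        ctrl_ids = X.index[y == 0]
        pairs, unmatched = _greedy_match(
            hk_ids.to_numpy(), logit.loc[hk_ids].to_numpy(),
            ctrl_ids.to_numpy(), logit.loc[ctrl_ids].to_numpy(),
            caliper,
        )
        ps = self.model_.scores
        pairs["ps_hk"] = pairs["hk_id"].map(ps).to_numpy()
        pairs["ps_control"] = pairs["control_id"].map(ps).to_numpy()
        self.pairs_ = MatchedPairSet(pairs=pairs, unmatched_hk=tuple(unmatched), caliper=caliper)
        self.caliper_ = caliper
        return self


def _greedy_match(hk_ids, hk_logit, ctrl_ids, ctrl_logit, caliper):
    """Greedy 1:1 nearest neighbor without replacement on the logit scale."""
    order = np.lexsort((hk_ids, -hk_logit))  # descending score, id tie-break
    sort_c = np.lexsort((ctrl_ids, ctrl_logit))
    c_logit = ctrl_logit[sort_c]
    c_ids = ctrl_ids[sort_c]
    m = len(c_ids)
    nxt = np.arange(1, m + 1)
    prv = np.arange(-1, m)
    rows = []
    unmatched = []
    for i in order:
        target = hk_logit[i]
        pos = int(np.searchsorted(c_logit, target))
        right = pos
        while right < m and nxt[right] == -2:
            right += 1
        left = prv[right] if right < m else (m - 1 if m else -1)
        while left >= 0 and nxt[left] == -2:
            left -= 1
        dl = target - c_logit[left] if left >= 0 else np.inf
        dr = c_logit[right] - target if right < m else np.inf
        if np.isinf(dl) and np.isinf(dr):
            unmatched.append(hk_ids[i]); continue
        if dl < dr or (dl == dr and left >= 0 and (right >= m or c_ids[left] < c_ids[right])):
            pick, dist = left, dl
        else:
            pick, dist = right, dr
        if caliper is not None and dist > caliper:
            unmatched.append(hk_ids[i]); continue
        rows.append((hk_ids[i], c_ids[pick]))
        p, q = prv[pick], nxt[pick]
        if p >= 0:
            nxt[p] = q
        if 0 <= q < m:
            prv[q] = p
        nxt[pick] = -2
    pairs = pd.DataFrame(rows, columns=["hk_id", "control_id"])
    return pairs, unmatched


def match_1to1(model: PropensityModel, pool_labels: pd.Series,
               caliper_sd: float | None = 0.2, caliper: float | None = None) -> MatchedPairSet:
    """Functional wrapper over :class:`PropensityMatcher` matching.

    ``pool_labels`` maps patient_id -> 1 (HK) / 0 (control) for the pool
    scored by ``model``.
    """
    logit = model.logit_scores()
    labels = pd.Series(pool_labels).loc[logit.index]
    if caliper is None and caliper_sd is not None:
        caliper = caliper_sd * float(logit.std(ddof=1))
    hk_ids = logit.index[labels == 1].to_numpy()
    ctrl_ids = logit.index[labels == 0].to_numpy()
    pairs, unmatched = _greedy_match(
        hk_ids, logit.loc[labels == 1].to_numpy(),
        ctrl_ids, logit.loc[labels == 0].to_numpy(), caliper,
    )
    pairs["ps_hk"] = pairs["hk_id"].map(model.scores).to_numpy()
    pairs["ps_control"] = pairs["control_id"].map(model.scores).to_numpy()
    return MatchedPairSet(pairs=pairs, unmatched_hk=tuple(unmatched), caliper=caliper)


# ---------------------------------------------------------------------
# balance report


def balance_report(cov_hk: pd.DataFrame, cov_control: pd.DataFrame) -> pd.DataFrame:
    """Per-covariate balance table: group means/proportions, two-sided
    p-value (t-test continuous, chi-square binary), and the signed
    standardized difference (also rounded to 2 dp for display)."""
    rows = []
    for col in cov_hk.columns:
        a = cov_hk[col].to_numpy(dtype=float)
        b = cov_control[col].to_numpy(dtype=float)
        binary = set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0}
        if binary:
            d = standardized_difference(a, b, "binary")
            table = np.array(
                [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]]
            )
            if (table.sum(axis=0) == 0).any():
                p = 1.0
            else:
                p = float(stats.chi2_contingency(table, correction=False)[1])
        else:
            d = standardized_difference(a, b, "continuous")
            t = stats.ttest_ind(a, b, equal_var=False)
            p = 1.0 if np.isnan(t.pvalue) else float(t.pvalue)
        rows.append(
            {
                "covariate": col,
                "kind": "binary" if binary else "continuous",
                "mean_hk": a.mean(),
                "mean_control": b.mean(),
                "p_value": p,
                "standardized_difference": d,
                "smd_2dp": round(d, 2),
                "imbalanced": abs(d) > BALANCE_THRESHOLD,
            }
        )
    return pd.DataFrame(rows)
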