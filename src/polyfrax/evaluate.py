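"""Evaluation statistics for fracture-risk prediction.

Implements the complete reporting battery: percentile stratification of a
score, per-group incidence with binomial proportion intervals,
age/sex-adjusted logistic associations with likelihood-ratio model
comparison, prevalence-matched binarization, ROC/PR discrimination with
DeLong's test and stratified bootstrap intervals, Kaplan-Meier and Cox
survival analyses on the age time scale with delayed entry (subjects enter
the risk set at their baseline age), Harrell's C-index, and net
reclassification / integrated discrimination indices.

Logistic fits go through statsmodels GLM (IRLS); Kaplan-Meier through
lifelines. The Cox partial likelihood is fit here directly because the
required combination — Breslow tie handling with left truncation — is what
age-as-time-scale cohort data demand.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILE_EDGES = (0.01, 0.05, 0.20, 0.40, 0.60, 0.80, 0.95, 0.99)
#: treatment-recommendation cutoffs for 10-year MOF and hip probabilities
MOF_CUTOFF = 0.20
HIP_CUTOFF = 0.03


@dataclasses.dataclass
class MetricResult:
    """A named point estimate with its interval and provenance."""

    metric: str
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    n_used: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# stratified incidence


def percentile_stratify(
    z: np.ndarray,
    edges: tuple[float, ...] = DEFAULT_PERCENTILE_EDGES,
) -> np.ndarray:
    """Group labels 0..len(edges) from score percentiles.

    Individuals are ranked (average ranks for ties); individual i falls in
    group g iff rank_i/n lies in (edge_{g-1}, edge_g]. With the default
    edges this yields the nine canonical groups <=1%, 1-5%, ..., >99%.
    """
    edges_arr = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges_arr) <= 0) or edges_arr.min() <= 0 or edges_arr.max() >= 1:
        raise ValueError("edges must be strictly ascending within (0, 1)")
    z = np.asarray(z, dtype=float)
    q = rankdata(z, method="average") / len(z)
    return np.searchsorted(edges_arr, q, side="left")


def incidence_by_group(
    groups: np.ndarray,
    events: np.ndarray,
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Per-group event proportion with a binomial CI (Wilson default,
    Clopper-Pearson via ``ci_method='clopper_pearson'``)."""
    groups = np.asarray(groups)
    events = np.asarray(events)
    if len(groups) != len(events):
        raise ValueError("groups and events must be aligned")
    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}[ci_method]
    rows = []
    for g in np.unique(groups):
        mask = groups == g
        size = int(mask.sum())
        x = int(events[mask].sum())
        if size == 0:
            rows.append((g, 0, 0, np.nan, np.nan, np.nan, True))
            continue
        lo, hi = proportion_confint(x, size, alpha=0.05, method=sm_method)
        rows.append((g, size, x, x / size, float(lo), float(hi), False))
    return pd.DataFrame(
        rows,
        columns=["group", "size", "events", "proportion", "ci_low", "ci_high", "empty"],
    )


# ---------------------------------------------------------------------------
# logistic association


@dataclasses.dataclass
class LogisticFit:
    params: np.ndarray
    se: np.ndarray
    odds_ratios: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    pvalues: np.ndarray
    loglik: float
    n: int
    converged: bool
    separation_flag: bool
    names: list[str]


def logistic_fit(X: np.ndarray, y: np.ndarray, names: list[str] | None = None,
                 add_intercept: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS (statsmodels GLM).

    Returns coefficients, Wald CIs on the odds-ratio scale, p-values and
    the log-likelihood for likelihood-ratio model comparison. Fits showing
    signs of complete separation (a coefficient beyond 15 on the
    standardized scale) are flagged rather than silently returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    params = np.asarray(res.params)
    se = np.asarray(res.bse)
    scale = design.std(axis=0)
    scale[scale == 0] = 1.0
    separation = bool(np.any(np.abs(params * scale) > 15))
    if separation:
        logger.warning("possible complete separation: |standardized coef| > 15")
    zcrit = stats.norm.ppf(0.975)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    all_names = (["intercept"] if add_intercept else []) + list(names)
    return LogisticFit(
        params=params,
        se=se,
        odds_ratios=np.exp(params),
        or_ci_low=np.exp(params - zcrit * se),
        or_ci_high=np.exp(params + zcrit * se),
        pvalues=np.asarray(res.pvalues),
        loglik=float(res.llf),
        n=len(y),
        converged=bool(res.converged),
        separation_flag=separation,
        names=all_names,
    )


def likelihood_ratio_test(ll_nested: float, ll_full: float, df: int) -> float:
    """Upper-tail chi-square p-value for 2*(ll_full - ll_nested) at df."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if ll_full < ll_nested - 1e-9:
        raise ValueError(
            "full-model log-likelihood is below the nested model's; models are "
            "not nested or a fit failed"
        )
    stat = max(0.0, 2.0 * (ll_full - ll_nested))
    return float(stats.chi2.sf(stat, df))


def prevalence_match_binarize(z: np.ndarray, target_prevalence: float) -> np.ndarray:
    """Indicator of the floor(n*target) lowest scores (stable tie order).

    Used to compare a score against a binary clinical risk factor at a
    matched population frequency: flag the individuals with the most
    adverse (lowest) score.
    """
    if not (0 < target_prevalence < 1):
        raise ValueError(f"target_prevalence must be in (0, 1); got {target_prevalence}")
    z = np.asarray(z, dtype=float)
    n = len(z)
    k = int(np.floor(n * target_prevalence))
    indicator = np.zeros(n, dtype=int)
    order = np.argsort(z, kind="stable")
    indicator[order[:k]] = 1
    return indicator


# ---------------------------------------------------------------------------
# discrimination


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the normalized Mann-Whitney U statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def bootstrap_ci(
    statistic,
    scores: np.ndarray,
    labels: np.ndarray,
    B: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile interval over B outcome-stratified resamples."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    vals = np.empty(B)
    for b in range(B):
        idx = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        vals[b] = statistic(scores[idx], labels[idx])
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: per-case and per-control placement
    values (mid-rank handling of ties)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # V10_i = fraction of controls below case i (+ half of ties)
    v10 = np.array([np.mean((x > neg) + 0.5 * (x == neg)) for x in pos])
    v01 = np.array([np.mean((pos > x) + 0.5 * (pos == x)) for x in neg])
    return v10, v01


def delong_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, float, float]:
    """DeLong's paired test for two correlated AUROCs.

    Returns (AUROC_a - AUROC_b, variance of the difference, two-sided
    normal p). Degenerate variance (e.g. identical scores) gives p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("scores and labels must be paired on the same individuals")
    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    n1, n0 = len(v10a), len(v01a)
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least two cases and two controls")
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = d10.var(ddof=1) / n1 + d01.var(ddof=1) / n0
    diff = auc_a - auc_b
    if var <= 1e-300:
        logger.warning("degenerate DeLong variance; returning p = 1")
        return float(diff), float(var), 1.0
    z = diff / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(diff), float(var), float(p)


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve as a step integral.

    Thresholds descend over distinct scores; precision is integrated over
    recall as sum((R_k - R_{k-1}) * P_k) with no interpolation between
    operating points. With all scores tied this reduces to the prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("at least one positive is required")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # operating points only at distinct thresholds (last index of each run)
    distinct = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    tp, fp = tp[distinct], fp[distinct]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


# ---------------------------------------------------------------------------
# survival on the age time scale


@dataclasses.dataclass
class KMcurve:
    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, len(self.times) - 1)])
        return float(out) if out.ndim == 0 else out


def km_estimator(
    entry_age: np.ndarray,
    exit_age: np.ndarray,
    event: np.ndarray,
    censor_age: float = 90.0,
) -> KMcurve:
    """Product-limit survival with delayed entry, censored at ``censor_age``.

    The risk set at time t is {i : entry_i < t <= exit_i}; events past the
    censoring age are treated as censored there. Computed with lifelines'
    Kaplan-Meier fitter (left-truncation aware).
    """
    entry_age = np.asarray(entry_age, dtype=float)
    exit_age = np.asarray(exit_age, dtype=float)
    event = np.asarray(event).astype(int)
    if np.any(exit_age < entry_age):
        raise ValueError("exit_age must be >= entry_age (negative duration)")
    event = np.where(exit_age > censor_age, 0, event)
    exit_c = np.minimum(exit_age, censor_age)
    # lifelines requires entry strictly before exit
    eps = 1e-9
    exit_c = np.maximum(exit_c, entry_age + eps)
    kmf = KaplanMeierFitter()
    kmf.fit(durations=exit_c, event_observed=event, entry=entry_age)
    sf = kmf.survival_function_
    return KMcurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


@dataclasses.dataclass
class CoxFit:
    params: np.ndarray
    se: np.ndarray
    hazard_ratios: np.ndarray
    loglik: float
    c_index: float
    n: int
    n_events: int
    names: list[str]
    monotone_flag: bool = False


def _cox_breslow_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
    event_times: np.ndarray,
):
    """Breslow partial log-likelihood, gradient and Hessian with left
    truncation: the risk set at t contains i iff entry_i < t <= exit_i."""
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(len(beta))
    hess = np.zeros((len(beta), len(beta)))
    for t in event_times:
        at_risk = (entry < t) & (exit_ >= t)
        dead = (exit_ == t) & (event == 1)
        d = int(dead.sum())
        wr = w[at_risk]
        Xr = X[at_risk]
        s0 = wr.sum()
        s1 = Xr.T @ wr
        s2 = (Xr * wr[:, None]).T @ Xr
        ll += eta[dead].sum() - d * np.log(s0)
        mu = s1 / s0
        grad += X[dead].sum(axis=0) - d * mu
        hess -= d * (s2 / s0 - np.outer(mu, mu))
    return ll, grad, hess


def harrell_c(
    risk: np.ndarray,
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
) -> float:
    """Harrell's concordance over usable pairs under left truncation.

    A pair is usable iff the earlier exit is an event and the other member
    is in the risk set at that time (entered before it, exits at or after
    it). Concordant when the failing member carries the higher risk score;
    tied risks count 1/2.
    """
    risk = np.asarray(risk, dtype=float)
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    event = np.asarray(event).astype(int)
    conc = 0.0
    usable = 0
    cases = np.flatnonzero(event == 1)
    for i in cases:
        t = exit_[i]
        # peers at risk when i fails, failing strictly later or censored later
        mask = (entry < t) & (exit_ > t)
        # events at the same time are not comparable (tied failure)
        m = int(mask.sum())
        if m == 0:
            continue
        usable += m
        conc += np.sum(risk[i] > risk[mask]) + 0.5 * np.sum(risk[i] == risk[mask])
    if usable == 0:
        raise ValueError("no usable pairs for the concordance index")
    return float(conc / usable)


def cox_fit(
    entry_age: np.ndarray,
    exit_age: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional hazards with Breslow ties and delayed entry.

    Newton-Raphson on the partial likelihood to gradient max-norm below
    ``tol``; returns log hazard ratios, standard errors from the observed
    information, and Harrell's C-index of the fitted risk score.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(np.asarray(entry_age)):
        X = X.T
    entry = np.asarray(entry_age, dtype=float)
    exit_ = np.asarray(exit_age, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    Xc = X - X.mean(axis=0)  # centering stabilizes exp(eta)
    event_times = np.unique(exit_[event == 1])
    beta = np.zeros(X.shape[1])
    monotone = False
    for _ in range(max_iter):
        ll, grad, hess = _cox_breslow_loglik(beta, Xc, entry, exit_, event, event_times)
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix in Cox fit") from exc
        beta = beta - step
        if np.max(np.abs(beta)) > 50:
            monotone = True
            logger.warning("monotone partial likelihood suspected (|beta| > 50)")
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(gradient max {np.max(np.abs(grad)):.3g})"
        )
    ll, grad, hess = _cox_breslow_loglik(beta, Xc, entry, exit_, event, event_times)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    c = harrell_c(Xc @ beta, entry, exit_, event)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return CoxFit(
        params=beta,
        se=se,
        hazard_ratios=np.exp(beta),
        loglik=float(ll),
        c_index=c,
        n=len(event),
        n_events=int(event.sum()),
        names=list(names),
        monotone_flag=monotone,
    )


# ---------------------------------------------------------------------------
# reclassification


def _nri_components(up_e, down_e, up_ne, down_ne, n_e, n_ne):
    p_up_e, p_down_e = up_e / n_e, down_e / n_e
    p_up_ne, p_down_ne = up_ne / n_ne, down_ne / n_ne
    est = (p_up_e - p_down_e) + (p_down_ne - p_up_ne)
    var = (
        (p_up_e + p_down_e - (p_up_e - p_down_e) ** 2) / n_e
        + (p_up_ne + p_down_ne - (p_down_ne - p_up_ne) ** 2) / n_ne
    )
    return est, var


def nri(
    p_old: np.ndarray,
    p_new: np.ndarray,
    y: np.ndarray,
    cutoffs: float | tuple[float, ...] | None = None,
    ci_method: str = "analytic",
    B: int = 200,
    seed: int = 0,
) -> dict[str, MetricResult]:
    """Net reclassification index, categorical and continuous.

    Categorical: two categories split at the clinical cutoff; NRI =
    [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)].
    Continuous: "up" is any increase in predicted probability. CIs are
    asymptotic normal by default, or percentile bootstrap.
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(y).astype(int)
    if not (len(p_old) == len(p_new) == len(y)):
        raise ValueError("inputs must be aligned")
    n_e = int(y.sum())
    n_ne = int((1 - y).sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("both events and nonevents are required")

    def _counts(up_mask, down_mask):
        return (
            int(up_mask[y == 1].sum()),
            int(down_mask[y == 1].sum()),
            int(up_mask[y == 0].sum()),
            int(down_mask[y == 0].sum()),
        )

    results: dict[str, MetricResult] = {}
    zcrit = stats.norm.ppf(0.975)

    variants: list[tuple[str, np.ndarray, np.ndarray]] = []
    if cutoffs is not None:
        cuts = np.atleast_1d(np.asarray(cutoffs, dtype=float))
        if np.any((cuts <= 0) | (cuts >= 1)):
            raise ValueError("cutoffs must lie within (0, 1)")
        # a probability exactly at the cutoff counts as the high category
        cat_old = np.searchsorted(np.sort(cuts), p_old, side="right")
        cat_new = np.searchsorted(np.sort(cuts), p_new, side="right")
        variants.append(("categorical_nri", cat_new > cat_old, cat_new < cat_old))
    variants.append(("continuous_nri", p_new > p_old, p_new < p_old))

    for name, up, down in variants:
        ue, de, une, dne = _counts(up, down)
        est, var = _nri_components(ue, de, une, dne, n_e, n_ne)
        if ci_method == "analytic":
            lo, hi = est - zcrit * np.sqrt(var), est + zcrit * np.sqrt(var)
            method = "analytic"
        elif ci_method == "bootstrap":
            rng = np.random.default_rng(seed)
            pos = np.flatnonzero(y == 1)
            neg = np.flatnonzero(y == 0)
            vals = np.empty(B)
            for b in range(B):
                idx = np.concatenate(
                    [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
                )
                ue_b, de_b, une_b, dne_b = (
                    int(up[idx][y[idx] == 1].sum()),
                    int(down[idx][y[idx] == 1].sum()),
                    int(up[idx][y[idx] == 0].sum()),
                    int(down[idx][y[idx] == 0].sum()),
                )
                vals[b], _ = _nri_components(ue_b, de_b, une_b, dne_b, n_e, n_ne)
            lo, hi = np.quantile(vals, [0.025, 0.975])
            method = f"bootstrap:{B}"
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        results[name] = MetricResult(name, float(est), float(lo), float(hi), method, len(y))
    return results


def idi(
    p_old: np.ndarray,
    p_new: np.ndarray,
    y: np.ndarray,
) -> MetricResult:
    """Integrated discrimination index with an asymptotic CI.

    IDI = [mean(p_new|event) - mean(p_old|event)]
        - [mean(p_new|nonevent) - mean(p_old|nonevent)].
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(y).astype(int)
    n_e = int(y.sum())
    n_ne = int((1 - y).sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("both events and nonevents are required")
    d = p_new - p_old
    d_e, d_ne = d[y == 1], d[y == 0]
    est = d_e.mean() - d_ne.mean()
    var = (d_e.var(ddof=1) / n_e if n_e > 1 else 0.0) + (
        d_ne.var(ddof=1) / n_ne if n_ne > 1 else 0.0
    )
    zcrit = stats.norm.ppf(0.975)
    half = zcrit * np.sqrt(var)
    return MetricResult("idi", float(est), float(est - half), float(est + half), "analytic", len(y))
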