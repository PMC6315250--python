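"""Trial-level statistics for the cluster-randomized evaluation.

The primary analysis is a linear mixed model on log-transformed event
counts with fixed effects for arm, time and their interaction (plus
baseline covariates in the adjusted variant) and random intercepts for
cluster (construction gang) and for individual nested in cluster, fitted by
REML and analyzed by intention-to-treat (likelihood-based handling of
missing follow-ups, no imputation).  Small-sample Kenward-Roger degrees of
freedom are not available in this ecosystem; fixed-effect inference uses
Wald statistics on the REML fit and the result records the method tag.

Supporting pieces: the two-sample t-test power iteration behind the trial's
sample size, the cluster design-effect inflation, pooled-variance baseline
t-tests, and an exact conditional r x c independence test by full
enumeration of tables with fixed margins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as spstats
from scipy.special import gammaln

from ergoload.errors import DesignError

logger = logging.getLogger(__name__)

TIME_POINTS = ("baseline", "fu1", "fu2")
ARMS = ("intervention", "control")
ADJUSTMENT_COVARIATES = (
    "baseline_outcome",
    "age",
    "gender",
    "duration_h",
    "mean_hr_bpm",
    "steps",
    "strength",
)


def log_transform_outcome(counts) -> tuple[np.ndarray, dict]:
    """Natural log of (count + 1); the offset is recorded in the metadata.

    Event counts can be 0 on short or quiet days, so a +1 offset keeps the
    transform defined; raises on negative counts.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("event counts must be non-negative")
    return np.log1p(counts), {"transform": "log", "offset": 1}


def validate_trial_dataset(d: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format trial table invariants.

    Each subject must sit in exactly one cluster and one arm and have a
    baseline row; missing follow-ups are allowed (ITT).
    """
    required = {"subject", "cluster", "arm", "time", "log_events"}
    missing = required - set(d.columns)
    if missing:
        raise DesignError(f"trial dataset missing columns: {sorted(missing)}")
    per_subj = d.groupby("subject").agg(n_cluster=("cluster", "nunique"), n_arm=("arm", "nunique"))
    bad = per_subj[(per_subj.n_cluster > 1) | (per_subj.n_arm > 1)]
    if len(bad):
        raise DesignError(f"subjects in multiple clusters/arms: {list(bad.index[:5])}")
    no_baseline = set(d.subject) - set(d.loc[d.time == "baseline", "subject"])
    if no_baseline:
        raise DesignError(f"subjects without a baseline row: {sorted(no_baseline)[:5]}")
    return d


@dataclass
class MixedModelResult:
    """Fixed-effect contrasts and variance components of the trial model."""

    params: pd.Series
    conf_int: pd.DataFrame
    interaction_wald: float
    interaction_df: int
    interaction_p: float
    between_group: dict[str, tuple[float, float, float]]  # time -> (est, lo, hi)
    within_group: dict[str, dict[str, tuple[float, float, float]]]  # arm -> time -> ...
    vc: dict[str, float]
    method: str
    adjusted: bool
    singular: bool
    n_obs: int
    n_subjects: int
    n_clusters: int
    dropped_covariates: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "interaction_p": self.interaction_p,
            "between_group": self.between_group,
            "within_group": self.within_group,
            "variance_components": self.vc,
            "method": self.method,
            "adjusted": self.adjusted,
            "singular": self.singular,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "n_clusters": self.n_clusters,
            "dropped_covariates": self.dropped_covariates,
        }


def _contrast(names: list[str], weights: dict[str, float]) -> np.ndarray:
    c = np.zeros(len(names))
    for name, w in weights.items():
        c[names.index(name)] = w
    return c


def fit_itt_model(
    d: pd.DataFrame,
    adjusted: bool = False,
    outcome: str = "log_events",
    alpha: float = 0.05,
) -> MixedModelResult:
    """REML linear mixed model for the cluster-randomized trial.

    Unadjusted: ``outcome ~ arm * time`` over all rows.  Adjusted: follow-up
    rows only, additionally conditioning on the subject's baseline outcome
    and the measurement-day covariates; constant covariates (e.g. gender in
    an all-male cohort) are dropped with a log message.  Random intercepts
    for cluster and individual-within-cluster.  A singular fit (a variance
    component pinned at zero) is flagged, not raised.
    """
    import statsmodels.formula.api as smf

    d = validate_trial_dataset(d).copy()
    n_cl = d.groupby("arm")["cluster"].nunique()
    if (n_cl < 2).any() or len(n_cl) < 2:
        raise DesignError(f"need >= 2 clusters in each of two arms, got {n_cl.to_dict()}")

    arm_t = "C(arm, Treatment('control'))"
    follow_ups = [t for t in TIME_POINTS if t != "baseline" and (d.time == t).any()]
    # adjusted model conditions on the baseline outcome, so it is fitted on
    # follow-up occasions only and the time reference becomes the first one
    time_ref = "baseline" if not adjusted else follow_ups[0]
    time_t = f"C(time, Treatment('{time_ref}'))"
    dropped: list[str] = []
    if adjusted:
        base = d[d.time == "baseline"].set_index("subject")[outcome].rename("baseline_outcome")
        d = d[d.time != "baseline"].join(base, on="subject")
        covs = []
        for c in ADJUSTMENT_COVARIATES:
            if c not in d.columns:
                dropped.append(c)
                continue
            if d[c].nunique() <= 1:
                logger.info("dropping constant covariate %r from the adjusted model", c)
                dropped.append(c)
                continue
            covs.append(c if np.issubdtype(d[c].dtype, np.number) else f"C({c})")
        formula = f"{outcome} ~ {arm_t} * {time_t} + " + " + ".join(covs)
    else:
        formula = f"{outcome} ~ {arm_t} * {time_t}"

    model = smf.mixedlm(
        formula, d, groups="cluster", re_formula="1", vc_formula={"subject": "0 + C(subject)"}
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method=["lbfgs", "bfgs"])

    k_fe = model.k_fe
    fe_names = list(res.model.exog_names)
    beta = np.asarray(res.params)[:k_fe]
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    z = spstats.norm.ppf(1 - alpha / 2)

    def ct(weights: dict[str, float]) -> tuple[float, float, float]:
        c = _contrast(fe_names, weights)
        est = float(c @ beta)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        return est, est - z * se, est + z * se

    arm_term = f"{arm_t}[T.intervention]"
    inter_names = [n for n in fe_names if ":" in n and arm_term.split("[")[0] in n]
    bi = np.array([fe_names.index(n) for n in inter_names])
    if len(bi):
        b_int = beta[bi]
        v_int = cov[np.ix_(bi, bi)]
        wald = float(b_int @ np.linalg.solve(v_int, b_int))
        df = len(bi)
        p_int = float(spstats.chi2.sf(wald, df))
    else:
        wald, df, p_int = 0.0, 0, 1.0

    between: dict[str, tuple[float, float, float]] = {}
    within: dict[str, dict[str, tuple[float, float, float]]] = {"intervention": {}, "control": {}}
    in_model_baseline = not adjusted
    if in_model_baseline:
        between["baseline"] = ct({arm_term: 1.0})
    for t in follow_ups:
        time_term = f"{time_t}[T.{t}]"
        int_term_candidates = [n for n in inter_names if f"[T.{t}]" in n]
        w_between = {arm_term: 1.0}
        if int_term_candidates:
            w_between[int_term_candidates[0]] = 1.0
        between[t] = ct(w_between)
        if time_term in fe_names:
            within["control"][t] = ct({time_term: 1.0})
            w_iv = {time_term: 1.0}
            if int_term_candidates:
                w_iv[int_term_candidates[0]] = 1.0
            within["intervention"][t] = ct(w_iv)

    vc_subject = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    vc_cluster = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
    vc = {"cluster": vc_cluster, "subject": vc_subject, "residual": float(res.scale)}
    singular = (not res.converged) or min(vc_cluster, vc_subject) <= 1e-8

    se_diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    ci = pd.DataFrame(
        {"lower": beta - z * se_diag, "upper": beta + z * se_diag}, index=fe_names
    )
    return MixedModelResult(
        params=pd.Series(beta, index=fe_names),
        conf_int=ci,
        interaction_wald=wald,
        interaction_df=df,
        interaction_p=p_int,
        between_group=between,
        within_group=within,
        vc=vc,
        method="REML (lbfgs), Wald z inference; Kenward-Roger df unavailable",
        adjusted=adjusted,
        singular=bool(singular),
        n_obs=len(d),
        n_subjects=d.subject.nunique(),
        n_clusters=d.cluster.nunique(),
        dropped_covariates=dropped,
    )


def power_sample_size(
    delta: float, sd: float, alpha: float = 0.05, power: float = 0.80, n_max: int = 100000
) -> int:
    """Smallest per-group n for a two-sample two-sided t-test.

    Iterates the exact noncentral-t power curve (not the normal
    approximation): with per-group n, df = 2n - 2 and noncentrality
    ``(delta/sd) * sqrt(n/2)``.
    """
    if not (delta > 0 and sd > 0 and 0 < alpha < 1 and 0 < power < 1):
        raise ValueError("need delta > 0, sd > 0, alpha and power in (0, 1)")
    es = delta / sd
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        tcrit = spstats.t.ppf(1 - alpha / 2, df)
        nc = es * np.sqrt(n / 2.0)
        achieved = spstats.nct.sf(tcrit, df, nc) + spstats.nct.cdf(-tcrit, df, nc)
        if achieved >= power:
            return n
    raise ValueError(f"no n <= {n_max} reaches power {power} at effect {es}")


def apply_design_effect(n: int, deff: float = 1.5) -> int:
    """Inflate a per-group sample size for cluster randomization: ceil(n * deff)."""
    if n < 2:
        raise ValueError("per-group n must be >= 2")
    if deff < 1:
        raise ValueError("design effect must be >= 1")
    return int(np.ceil(n * deff - 1e-12))


def baseline_tests(
    d: pd.DataFrame,
    variables: list[str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample t-tests on continuous baseline variables between arms.

    Pooled-variance by default; ``welch=True`` switches to the unequal-
    variance form.  One row per variable with group means, t and p.
    """
    base = d[d.time == "baseline"]
    arms = sorted(base.arm.unique())
    if len(arms) != 2:
        raise DesignError(f"need exactly two arms at baseline, got {arms}")
    if variables is None:
        skip = {"log_events"}
        variables = [
            c
            for c in base.columns
            if c not in {"subject", "cluster", "arm", "time"} | skip
            and np.issubdtype(base[c].dtype, np.number)
        ]
        variables = ["log_events"] + variables if "log_events" in base.columns else variables
    rows = []
    for v in variables:
        a = base.loc[base.arm == arms[0], v].dropna().to_numpy()
        b = base.loc[base.arm == arms[1], v].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise DesignError(f"variable {v!r}: need >= 2 subjects per arm")
        t, p = spstats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "variable": v,
                f"mean_{arms[0]}": float(np.mean(a)),
                f"mean_{arms[1]}": float(np.mean(b)),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# exact conditional r x c test
# --------------------------------------------------------------------------

MAX_FISHER_TOTAL = 500
MAX_FISHER_DIM = 3


def _enumerate_tables(rows: tuple[int, ...], cols: tuple[int, ...]):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(rows), len(cols)

    def rec(row_idx: int, col_rem: tuple[int, ...], acc: list[tuple[int, ...]]):
        if row_idx == r - 1:
            yield acc + [col_rem]
            return
        target = rows[row_idx]

        def fill(j: int, remaining: int, cells: list[int]):
            if j == c - 1:
                if remaining <= col_rem[j]:
                    yield cells + [remaining]
                return
            for v in range(min(remaining, col_rem[j]) + 1):
                yield from fill(j + 1, remaining - v, cells + [v])

        for row in fill(0, target, []):
            new_rem = tuple(col_rem[j] - row[j] for j in range(c))
            yield from rec(row_idx + 1, new_rem, acc + [tuple(row)])

    yield from rec(0, cols, [])


# log k! for k = 0..MAX_FISHER_TOTAL (cell values never exceed the total)
_LOG_FACT = gammaln(np.arange(0, 502, dtype=float) + 1.0)


@lru_cache(maxsize=None)
def _log_const(rows: tuple[int, ...], cols: tuple[int, ...]) -> float:
    n = sum(rows)
    return float(_LOG_FACT[list(rows)].sum() + _LOG_FACT[list(cols)].sum() - _LOG_FACT[n])


@lru_cache(maxsize=None)
def _margin_distribution(
    rows: tuple[int, ...], cols: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted log-probabilities of every table with the given margins, plus
    their cumulative probabilities."""
    all_tables = np.asarray(list(_enumerate_tables(rows, cols)), dtype=int)
    lps = np.sort(_log_const(rows, cols) - _LOG_FACT[all_tables].sum(axis=(1, 2)))
    return lps, np.cumsum(np.exp(lps))


def _canonical_margins(rows: tuple[int, ...], cols: tuple[int, ...]):
    """Margins up to row/col permutation and transpose (probability multiset invariant)."""
    a, b = tuple(sorted(rows)), tuple(sorted(cols))
    return (a, b) if (len(a), a) <= (len(b), b) else (b, a)


def fisher_exact_rxc(table) -> float:
    """Exact conditional independence p-value for an r x c count table.

    Full enumeration of tables with the observed margins under the
    multivariate hypergeometric null; the p-value sums the probabilities of
    all tables no more probable than the observed one (two-sided, the
    convention of the classical exact test).  Limited to tables up to 3 x 3
    with total <= 500; larger tables raise with a suggestion to use a
    Monte-Carlo approximation instead.
    """
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if t.shape[0] > MAX_FISHER_DIM or t.shape[1] > MAX_FISHER_DIM:
        raise ValueError(
            f"table shape {t.shape} exceeds the {MAX_FISHER_DIM}x{MAX_FISHER_DIM} "
            "enumeration bound; use a Monte-Carlo approximation"
        )
    n = int(t.sum())
    if n > MAX_FISHER_TOTAL:
        raise ValueError(
            f"table total {n} exceeds the enumeration bound {MAX_FISHER_TOTAL}; "
            "use a Monte-Carlo approximation"
        )
    if n == 0:
        return 1.0
    rows = tuple(int(x) for x in t.sum(axis=1))
    cols = tuple(int(x) for x in t.sum(axis=0))
    lp_obs = _log_const(rows, cols) - float(_LOG_FACT[t].sum())
    lps, cum = _margin_distribution(*_canonical_margins(rows, cols))
    # sum P(T) over tables with P(T) <= P(obs), with a relative tolerance for ties
    k = int(np.searchsorted(lps, lp_obs + 1e-9, side="right"))
    p = float(cum[k - 1]) if k > 0 else float(np.exp(lp_obs))
    return min(1.0, max(p, float(np.exp(lp_obs))))
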