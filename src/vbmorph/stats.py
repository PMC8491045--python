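"""Statistical battery for the cohort analysis.

Implements the tests the cohort comparisons rely on, with explicit
internals where conventions matter:

* Mann-Whitney U with the tie-corrected normal approximation (no continuity
  correction by default) and the effect size r = |z| / sqrt(N);
* Fisher's exact test with the two-sided p by probability ordering, and the
  odds ratio reported as the conditional maximum-likelihood estimate — the
  value of the noncentral hypergeometric odds parameter whose expected
  first cell equals the observed count, found by monotone root-finding;
* Spearman rank correlation on laterality codes (right = -1, even = 0,
  left = +1) with average-rank tie handling;
* logistic regression (Newton/IRLS via statsmodels) with separation
  detection;
* ``analysis_battery`` running the full comparison set with raw and
  Bonferroni-adjusted p values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps
from scipy.special import gammaln

from .wmh import pcom_subset

__all__ = [
    "StatTestResult",
    "ContingencyTable2x2",
    "mann_whitney",
    "fisher_exact_2x2",
    "spearman_assoc",
    "fit_logistic",
    "analysis_battery",
    "effect_size_r",
    "odds_ratio_from_coef",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.001
_LAT_CODE = {"right": -1.0, "even": 0.0, "left": 1.0}


@dataclass
class StatTestResult:
    """Uniform result record for every test in the battery."""

    name: str
    statistic: float
    p: float
    n: int
    z: float | None = None
    r: float | None = None                 # effect size
    odds_ratio: float | None = None
    sample_odds_ratio: float | None = None
    coef: dict | None = None               # term -> (b, se, p) for logistic
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p value {self.p} outside [0, 1]")
        if self.z is not None and self.r is not None and self.n > 0:
            if abs(self.r - abs(self.z) / math.sqrt(self.n)) > 1e-9:
                raise ValueError("effect size r must equal |z|/sqrt(n)")
        if self.odds_ratio is not None and not math.isnan(self.odds_ratio):
            if self.odds_ratio < 0:
                raise ValueError("odds ratio must be >= 0")


def effect_size_r(z: float, n: int) -> float:
    """Rank-test effect size r = |z| / sqrt(N)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return abs(z) / math.sqrt(n)


def odds_ratio_from_coef(b: float) -> float:
    """Per-unit odds ratio implied by a logistic coefficient: exp(b)."""
    return math.exp(b)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney(x, y, continuity: bool = False) -> StatTestResult:
    """Mann-Whitney U with the tie-corrected normal approximation.

    Reports U = min(U_x, U_y); z is signed by the direction of x relative
    to y; the two-sided p uses the normal approximation without continuity
    correction unless requested; r = |z| / sqrt(n_x + n_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:nx].sum()
    u_x = r1 - nx * (nx + 1) / 2.0
    u_y = nx * ny - u_x
    u = min(u_x, u_y)
    mean_u = nx * ny / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1.0))) if n > 1 else 0.0
    var_u = nx * ny / 12.0 * ((n + 1.0) - tie_term)
    if var_u <= 0:
        z = 0.0
    else:
        num = u_x - mean_u
        if continuity:
            num = np.sign(num) * max(abs(num) - 0.5, 0.0)
        z = num / math.sqrt(var_u)
    p = 2.0 * sps.norm.sf(abs(z)) if var_u > 0 else 1.0
    return StatTestResult(name="mann_whitney", statistic=float(u), p=min(p, 1.0),
                          n=n, z=float(z), r=effect_size_r(z, n),
                          extra={"U_x": float(u_x), "U_y": float(u_y)})


# ---------------------------------------------------------------------------
# Fisher exact test with conditional-MLE odds ratio
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with optional axis labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("row1", "row2")
    col_labels: tuple = ("col1", "col2")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("table counts must be non-negative integers")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_array(cls, arr, **kw) -> "ContingencyTable2x2":
        arr = np.asarray(arr)
        return cls(int(arr[0, 0]), int(arr[0, 1]), int(arr[1, 0]), int(arr[1, 1]), **kw)


def _support(row1: int, row2: int, col1: int) -> np.ndarray:
    return np.arange(max(0, col1 - row2), min(col1, row1) + 1)


def _log_hyper_weights(k: np.ndarray, row1: int, row2: int, col1: int) -> np.ndarray:
    """log C(row1, k) + log C(row2, col1 - k)."""
    return (gammaln(row1 + 1) - gammaln(k + 1) - gammaln(row1 - k + 1)
            + gammaln(row2 + 1) - gammaln(col1 - k + 1) - gammaln(row2 - col1 + k + 1))


def _cmle_odds_ratio(a: int, row1: int, row2: int, col1: int) -> float:
    """Conditional MLE of the odds ratio: solve E_psi[A] = a.

    Under the noncentral hypergeometric model the conditional expectation
    of the first cell is strictly increasing in the odds parameter psi, so
    the root is found by bracketing + Brent to relative tolerance 1e-8.
    """
    supp = _support(row1, row2, col1)
    if len(supp) == 1:
        return math.nan  # degenerate margins: OR not estimable
    if a == supp[0]:
        return 0.0
    if a == supp[-1]:
        return math.inf
    logw = _log_hyper_weights(supp, row1, row2, col1)

    def mean_minus_a(log_psi: float) -> float:
        lp = logw + supp * log_psi
        lp -= lp.max()
        w = np.exp(lp)
        return float((supp * w).sum() / w.sum()) - a

    lo, hi = -1.0, 1.0
    while mean_minus_a(lo) > 0:
        lo *= 2.0
    while mean_minus_a(hi) < 0:
        hi *= 2.0
    log_psi = optimize.brentq(mean_minus_a, lo, hi, rtol=1e-10, xtol=1e-12)
    return math.exp(log_psi)


def fisher_exact_2x2(table) -> StatTestResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p by probability ordering: the sum of hypergeometric
    probabilities of all tables with the observed margins that are no more
    probable than the observed one. The odds ratio is the conditional MLE;
    an observed count at the edge of its support is flagged as 0 or inf.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2.from_array(table)
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2, col1 = a + b, c + d, a + c
    supp = _support(row1, row2, col1)
    if len(supp) == 1:  # a margin is zero: only one table possible
        return StatTestResult(name="fisher_exact", statistic=1.0, p=1.0,
                              n=table.total, odds_ratio=math.nan,
                              sample_odds_ratio=math.nan,
                              extra={"table": table.counts.tolist(),
                                     "degenerate_margins": True})
    logp = _log_hyper_weights(supp, row1, row2, col1)
    logp -= gammaln(table.total + 1) - gammaln(col1 + 1) - gammaln(table.total - col1 + 1)
    pmf = np.exp(logp)
    p_obs = pmf[supp == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    sample_or = (a * d) / (b * c) if b * c > 0 else math.inf
    cmle = _cmle_odds_ratio(a, row1, row2, col1)
    return StatTestResult(name="fisher_exact", statistic=float(p_obs),
                          p=min(p, 1.0), n=table.total,
                          odds_ratio=cmle, sample_odds_ratio=float(sample_or),
                          extra={"table": table.counts.tolist()})


# ---------------------------------------------------------------------------
# Spearman on laterality codes
# ---------------------------------------------------------------------------

def spearman_assoc(a, b) -> StatTestResult:
    """Spearman rank correlation with average-rank ties; p by the
    t-approximation. Inputs may be numeric codes or left/even/right labels
    (coded right = -1, even = 0, left = +1)."""
    a = _codes(a)
    b = _codes(b)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance: Spearman undefined")
    rho, p = sps.spearmanr(a, b)
    return StatTestResult(name="spearman", statistic=float(rho), p=float(p),
                          n=len(a), r=float(rho))


def _codes(v) -> np.ndarray:
    arr = np.asarray(v)
    if arr.dtype.kind in "OUS":
        return np.array([_LAT_CODE[str(x)] for x in arr], dtype=float)
    return arr.astype(float)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def fit_logistic(design, outcome, names: list[str] | None = None) -> StatTestResult:
    """Binary logistic regression with an intercept (Newton/IRLS).

    Raises on no events / all events, rank-deficient designs, and perfect
    separation (detected by statsmodels or by diverging coefficients).
    Reports per-term (b, se, p) and the per-unit odds ratios exp(b).
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(outcome)) == X.shape[1]:
        X = X.T
    y = np.asarray(outcome, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("design and outcome lengths differ")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")
    if y.min() < 0 or y.max() > 1 or not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome has no events (or no non-events)")
    Xc = sm.add_constant(X, has_constant="raise")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    names = ["intercept"] + (names or [f"x{i+1}" for i in range(X.shape[1])])
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=100, tol=1e-8)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as e:
        raise ValueError(f"perfect separation or singular fit: {e}") from e
    if not fit.mle_retvals.get("converged", True) or np.abs(fit.params).max() > 50:
        raise ValueError("perfect separation suspected: coefficients diverged")
    coef = {nm: (float(b), float(se), float(p))
            for nm, b, se, p in zip(names, fit.params, fit.bse, fit.pvalues)}
    slope_p = float(fit.pvalues[1]) if len(fit.params) > 1 else float(fit.pvalues[0])
    return StatTestResult(
        name="logistic", statistic=float(fit.llr), p=slope_p, n=len(y),
        odds_ratio=float(np.exp(fit.params[1])) if len(fit.params) > 1 else None,
        coef=coef,
        extra={"odds_ratios": {nm: math.exp(c[0]) for nm, c in coef.items()},
               "llr_p": float(fit.llr_pvalue)})


# ---------------------------------------------------------------------------
# The full battery
# ---------------------------------------------------------------------------

def _fisher_from_frame(df: pd.DataFrame, col_a: str, col_b: str,
                       a_levels, b_levels, name: str) -> StatTestResult | None:
    sub = df[df[col_a].isin(a_levels) & df[col_b].isin(b_levels)]
    if len(sub) == 0:
        return None
    tab = np.zeros((2, 2), dtype=int)
    for i, av in enumerate(a_levels):
        for j, bv in enumerate(b_levels):
            tab[i, j] = int(((sub[col_a] == av) & (sub[col_b] == bv)).sum())
    if tab.sum() == 0:
        return None
    res = fisher_exact_2x2(tab)
    res.name = name
    return res


def analysis_battery(cohort: pd.DataFrame, lesions: pd.DataFrame,
                     alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Run the cohort's full comparison set.

    Group differences (Mann-Whitney: age, basilar length / tortuosity /
    cross-section), risk-factor associations with group and laterality
    associations with dominance and curve direction (Fisher exact),
    dominance x curve direction (Spearman), and the two PCA-region logistic
    regressions (severity on age + hypertension in the whole cohort;
    laterality on signed basilar deviation in the bilateral-PCom-absent
    subset). Returns one row per test with raw p, Bonferroni-adjusted p and
    a significance flag at ``alpha``.
    """
    required = {"group", "age", "dominance", "curve_direction",
                "lat_VA", "lat_BA", "lat_PCA", "ba_deviation_signed_mm"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing required columns: {sorted(missing)}")
    if len(cohort) < 2:
        raise ValueError("battery needs a cohort of more than one subject")
    wmh = cohort[cohort["group"] == "WMH"]
    ctl = cohort[cohort["group"] == "control"]
    results: list[StatTestResult] = []

    def add(res: StatTestResult | None, name: str | None = None):
        if res is not None:
            if name:
                res.name = name
            results.append(res)

    for col, nm in (("age", "age_by_group"),
                    ("ba_length_mm", "ba_length_by_group"),
                    ("ba_tortuosity", "ba_tortuosity_by_group"),
                    ("ba_mean_area_mm2", "ba_area_by_group")):
        if col in cohort.columns and len(wmh) and len(ctl):
            add(mann_whitney(wmh[col], ctl[col]), nm)

    for rf in ("hypertension", "diabetes", "hyperlipidemia"):
        if rf in cohort.columns:
            tab = np.array([
                [int((wmh[rf]).sum()), int((~wmh[rf].astype(bool)).sum())],
                [int((ctl[rf]).sum()), int((~ctl[rf].astype(bool)).sum())]])
            if tab.sum() > 0:
                add(fisher_exact_2x2(tab), f"{rf}_by_group")

    add(_fisher_from_frame(cohort, "lat_VA", "dominance",
                           ("left", "right"), ("left", "right"),
                           "va_laterality_by_dominance"))
    add(_fisher_from_frame(cohort, "lat_BA", "curve_direction",
                           ("left", "right"), ("left", "right"),
                           "ba_laterality_by_curve"))
    try:
        add(spearman_assoc(cohort["dominance"], cohort["curve_direction"]),
            "dominance_by_curve_spearman")
    except ValueError:
        pass

    # PCA severity ~ age + hypertension, whole cohort
    if {"score_PCA_left", "score_PCA_right", "hypertension"}.issubset(cohort.columns):
        sev = ((cohort["score_PCA_left"] + cohort["score_PCA_right"]) > 0).astype(float)
        try:
            add(fit_logistic(np.column_stack([cohort["age"],
                                              cohort["hypertension"].astype(float)]),
                             sev, names=["age", "hypertension"]),
                "pca_wmh_logistic_full")
        except ValueError:
            pass

    # PCA laterality ~ signed deviation, bilateral PCom-absent subset
    try:
        sub = pcom_subset(cohort, lesions)
        sub = sub[sub["lat_PCA"].isin(("left", "right"))]
        if len(sub) > 5:
            add(fit_logistic(sub[["ba_deviation_signed_mm"]].to_numpy(),
                             (sub["lat_PCA"] == "left").astype(float),
                             names=["ba_deviation_signed_mm"]),
                "pca_laterality_logistic_pcom_subset")
    except ValueError:
        pass

    m = len(results)
    rows = []
    for res in results:
        p_adj = min(res.p * m, 1.0)
        rows.append({
            "test": res.name, "n": res.n, "statistic": res.statistic,
            "z": res.z, "effect_r": res.r, "odds_ratio": res.odds_ratio,
            "p_raw": res.p, "p_bonferroni": p_adj,
            "significant": bool(p_adj < alpha),
        })
    report = pd.DataFrame(rows)
    report.attrs["alpha"] = alpha
    report.attrs["family_size"] = m
    return report
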