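"""Two-sample test selection and the component tests.

Comparisons are dispatched through a diagnostic decision tree: each group is
checked for normality (Shapiro-Wilk) and the pair for homogeneity of
variances (Levene, mean-centered by default).  Normal data with homogeneous
variances get Student's t; normal with heterogeneous variances, Welch's t;
non-normal with homogeneous variances, Mann-Whitney U; non-normal with
heterogeneous variances, a bootstrap randomization t-test.  All p-values are
two-tailed.

The randomization t-test builds its null by centering both groups to the
pooled mean and resampling with replacement within each group; the p-value
is the add-one estimator (1 + #{|t*| >= |t_obs|}) / (1 + reps).  A
label-permutation null is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError

STUDENT_T = "student_t"
WELCH_T = "welch_t"
MANN_WHITNEY = "mann_whitney"
RANDOMIZATION_T = "randomization_t"
KRUSKAL_WALLIS = "kruskal_wallis"


@dataclass(frozen=True)
class TestResult:
    """A completed two-sample (or k-sample) comparison with diagnostics."""

    test_name: str
    statistic: float
    p_two_tailed: float
    n: tuple[int, ...]
    normality_p: tuple[float, ...] = ()
    variance_homogeneity_p: float | None = None
    alpha_used: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.p_two_tailed <= 1:
            raise ValueError("p-value outside [0, 1]")


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 3:
        raise InsufficientDataError(
            f"sample {name!r} has n={arr.size}; need n >= 3 "
            "(Shapiro-Wilk is undefined below that)"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name!r} contains non-finite values")
    return arr


def select_test(a, b, diag_alpha: float = 0.05, levene_center: str = "mean"):
    """Choose the two-sample test implied by the diagnostic decision tree.

    Returns ``(test_name, diagnostics)`` where diagnostics carries the
    per-group Shapiro-Wilk p-values and the Levene p-value.  ``"normal"``
    requires both groups to pass at ``diag_alpha``; ``levene_center`` may be
    ``"median"`` for the Brown-Forsythe variant.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    sw_a = float(sps.shapiro(a).pvalue)
    sw_b = float(sps.shapiro(b).pvalue)
    lev = float(sps.levene(a, b, center=levene_center).pvalue)
    normal = sw_a > diag_alpha and sw_b > diag_alpha
    homogeneous = lev > diag_alpha
    if normal:
        name = STUDENT_T if homogeneous else WELCH_T
    else:
        name = MANN_WHITNEY if homogeneous else RANDOMIZATION_T
    return name, {
        "normality_p": (sw_a, sw_b),
        "variance_homogeneity_p": lev,
        "diag_alpha": diag_alpha,
    }


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    if se2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float((a.mean() - b.mean()) / np.sqrt(se2))


def student_t_test(a, b) -> tuple[float, float]:
    """Two-tailed pooled-variance t-test: (statistic, p)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def welch_t_test(a, b) -> tuple[float, float]:
    """Two-tailed unequal-variance (Welch) t-test: (statistic, p)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                        equal_var=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_test(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U: (U statistic of the first sample, p).

    Exact p for combined n <= 20 without ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def randomization_t_test(a, b, reps: int = 10000, seed: int | None = None,
                         mode: str = "bootstrap") -> float:
    """Two-tailed bootstrap/permutation p-value for the Welch t statistic.

    ``mode="bootstrap"`` (default): both groups are centered to the pooled
    mean and resampled with replacement within group.  ``mode="permutation"``
    shuffles pooled group labels instead.  Deterministic for a given seed.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise DegenerateDataError("zero variance in both groups")
    t_obs = _welch_t(a, b)
    rng = np.random.default_rng(seed)
    na, nb = a.size, b.size

    if mode == "bootstrap":
        pooled_mean = np.concatenate([a, b]).mean()
        ac = a - a.mean() + pooled_mean
        bc = b - b.mean() + pooled_mean
        sa = ac[rng.integers(0, na, size=(reps, na))]
        sb = bc[rng.integers(0, nb, size=(reps, nb))]
    elif mode == "permutation":
        pooled = np.concatenate([a, b])
        perm = rng.permuted(np.tile(pooled, (reps, 1)), axis=1)
        sa, sb = perm[:, :na], perm[:, na:]
    else:
        raise ValueError("mode must be 'bootstrap' or 'permutation'")

    ma, mb = sa.mean(axis=1), sb.mean(axis=1)
    va, vb = sa.var(axis=1, ddof=1), sb.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = (ma - mb) / np.sqrt(se2)
    t_star = np.where(se2 == 0, np.where(ma == mb, 0.0, np.inf), t_star)
    p = (1 + np.count_nonzero(np.abs(t_star) >= abs(t_obs))) / (1 + reps)
    return float(p)


def compare_two_groups(a, b, diag_alpha: float = 0.05, seed: int | None = None,
                       reps: int = 10000, levene_center: str = "mean",
                       randomization_mode: str = "bootstrap") -> TestResult:
    """Run the decision-tree-selected two-sample test on a and b."""
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    name, diag = select_test(a, b, diag_alpha, levene_center)
    if name == STUDENT_T:
        stat, p = student_t_test(a, b)
    elif name == WELCH_T:
        stat, p = welch_t_test(a, b)
    elif name == MANN_WHITNEY:
        stat, p = mann_whitney_test(a, b)
    else:
        stat = _welch_t(a, b)
        p = randomization_t_test(a, b, reps=reps, seed=seed,
                                 mode=randomization_mode)
    return TestResult(
        test_name=name,
        statistic=stat,
        p_two_tailed=min(1.0, p),
        n=(a.size, b.size),
        normality_p=diag["normality_p"],
        variance_homogeneity_p=diag["variance_homogeneity_p"],
        alpha_used=diag_alpha,
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis one-way ANOVA on ranks across >= 3 groups.

    H is tie-corrected and referred to a chi-square with k-1 degrees of
    freedom.  All values identical is a legitimate degenerate case
    (H = 0, p = 1), not an error.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 3:
        raise InsufficientDataError("Kruskal-Wallis here requires >= 3 groups")
    if any(g.size < 2 for g in arrays):
        raise InsufficientDataError("each group needs n >= 2")
    ns = tuple(g.size for g in arrays)
    combined = np.concatenate(arrays)
    if np.ptp(combined) == 0:
        return TestResult(KRUSKAL_WALLIS, 0.0, 1.0, ns)
    res = sps.kruskal(*arrays)
    return TestResult(KRUSKAL_WALLIS, float(res.statistic), float(res.pvalue), ns)
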