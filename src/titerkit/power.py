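"""Subsampling bootstrap power analysis.

For each candidate sample size n, values are drawn with replacement (n per
group, independently) from the two titer datasets being compared, the
selected two-tailed test is applied, and the fraction of draws reaching
p < alpha over many iterations estimates the probability that an experiment
of size n would detect the observed difference.  Defaults mirror the
validated procedure: n from 2 to 35, 10,000 iterations per n, alpha = 0.01
two-tailed.

The test is chosen once from the full datasets via the diagnostic decision
tree, restricted to Student's t, Welch's t and Mann-Whitney U (a
randomization-test verdict maps to Welch's t inside the loop).  Subsamples
in which both groups are constant cannot reach significance and are counted
as non-significant; at n = 2 the Mann-Whitney U test cannot reach p < 0.01
at all, which is a property of the procedure, not a defect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from . import stats as _stats
from .errors import InsufficientDataError

_INNER_TESTS = (_stats.STUDENT_T, _stats.WELCH_T, _stats.MANN_WHITNEY)


@dataclass(frozen=True)
class PowerConfig:
    """Configuration of a power-curve run."""

    n_min: int = 2
    n_max: int = 35
    iterations: int = 10000
    alpha: float = 0.01
    test_policy: str = "auto_once"  # auto_once | auto_per_iteration | a test name
    replace: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.n_min < 2 or self.n_max < self.n_min:
            raise ValueError("need 2 <= n_min <= n_max")


@dataclass
class PowerCurve:
    """Proportion of significant subsample comparisons per sample size."""

    ns: np.ndarray
    proportion_significant: np.ndarray
    mc_se: np.ndarray
    config: PowerConfig
    tests_used: list[str] = field(default_factory=list)
    n_degenerate: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n": self.ns,
                "proportion_significant": self.proportion_significant,
                "mc_se": self.mc_se,
            }
        )

    def min_n_for_power(self, target: float) -> int | None:
        return min_n_for_power(self, target)

    def plot(self, ax=None, **kwargs):
        """Plot the curve (proportion significant vs subsample size)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.ns, self.proportion_significant, yerr=self.mc_se,
                    marker="o", **kwargs)
        ax.axhline(self.config.alpha, ls="--", color="grey", lw=1)
        ax.set_xlabel("subsample size n (per group)")
        ax.set_ylabel(f"proportion significant at alpha={self.config.alpha}")
        ax.set_ylim(-0.02, 1.02)
        return ax


def _student_p(sa: np.ndarray, sb: np.ndarray) -> np.ndarray:
    n = sa.shape[1]
    ma, mb = sa.mean(1), sb.mean(1)
    va, vb = sa.var(1, ddof=1), sb.var(1, ddof=1)
    df = 2 * n - 2
    sp2 = ((n - 1) * va + (n - 1) * vb) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * 2.0 / n)
    p = special.stdtr(df, -np.abs(t)) * 2.0
    degenerate = sp2 == 0
    p = np.where(degenerate, 1.0, p)
    return p, degenerate


def _welch_p(sa: np.ndarray, sb: np.ndarray) -> np.ndarray:
    n = sa.shape[1]
    ma, mb = sa.mean(1), sb.mean(1)
    va, vb = sa.var(1, ddof=1), sb.var(1, ddof=1)
    se2 = va / n + vb / n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (
            (va / n) ** 2 / (n - 1) + (vb / n) ** 2 / (n - 1)
        )
    degenerate = se2 == 0
    df = np.where(degenerate, 1.0, df)
    p = special.stdtr(df, -np.abs(np.where(degenerate, 0.0, t))) * 2.0
    p = np.where(degenerate, 1.0, p)
    return p, degenerate


def _mw_p(sa: np.ndarray, sb: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Mann-Whitney normal approximation with tie and
    continuity corrections (one subsample comparison per row)."""
    from scipy.stats import rankdata

    n = sa.shape[1]
    rows = sa.shape[0]
    comb = np.concatenate([sa, sb], axis=1)
    big_n = 2 * n
    r = rankdata(comb, axis=1)
    u1 = r[:, :n].sum(1) - n * (n + 1) / 2.0
    u = np.maximum(u1, n * n - u1)
    mu = n * n / 2.0
    # tie term sum(t^3 - t) per row, via padded per-row run-length counts
    s = np.sort(comb, axis=1)
    starts = np.ones_like(s, dtype=bool)
    starts[:, 1:] = s[:, 1:] != s[:, :-1]
    run_id = np.cumsum(starts, axis=1) - 1
    flat_id = (np.arange(rows)[:, None] * big_n + run_id).ravel()
    counts = np.bincount(flat_id, minlength=rows * big_n).reshape(rows, big_n)
    tie_term = (counts**3 - counts).sum(1)
    sigma2 = (n * n / 12.0) * (big_n + 1 - tie_term / (big_n * (big_n - 1.0)))
    degenerate = sigma2 <= 0
    sigma = np.sqrt(np.where(degenerate, 1.0, sigma2))
    z = (u - mu - 0.5) / sigma
    p = np.minimum(1.0, 2.0 * special.ndtr(-z))
    p = np.where(degenerate, 1.0, p)
    return p, degenerate


_VECTOR_TESTS = {
    _stats.STUDENT_T: _student_p,
    _stats.WELCH_T: _welch_p,
    _stats.MANN_WHITNEY: _mw_p,
}


def resolve_inner_test(a, b, policy: str, diag_alpha: float = 0.05) -> str:
    """Map a test policy to the concrete test used inside the loop."""
    if policy in _VECTOR_TESTS:
        return policy
    if policy in ("auto", "auto_once"):
        name, _ = _stats.select_test(a, b, diag_alpha)
        return _stats.WELCH_T if name == _stats.RANDOMIZATION_T else name
    raise ValueError(f"unknown test policy {policy!r}")


def _draw(rng: np.random.Generator, data: np.ndarray, n: int, iterations: int,
          with_replacement: bool) -> np.ndarray:
    if with_replacement:
        return data[rng.integers(0, data.size, size=(iterations, n))]
    if n > data.size:
        raise InsufficientDataError(
            f"subsample n={n} exceeds dataset size {data.size} without replacement"
        )
    idx = rng.permuted(
        np.tile(np.arange(data.size), (iterations, 1)), axis=1
    )[:, :n]
    return data[idx]


def power_at_n(
    a,
    b,
    n: int,
    iterations: int = 10000,
    alpha: float = 0.01,
    test: str = "auto_once",
    seed: int | None = None,
    with_replacement: bool = True,
) -> float:
    """Proportion of n-per-group subsample comparisons reaching p < alpha."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if n < 2:
        raise ValueError("n must be >= 2")
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both datasets must be non-empty")
    rng = np.random.default_rng(seed)
    if test == "auto_per_iteration":
        hits = 0
        for _ in range(iterations):
            sa = _draw(rng, a, n, 1, with_replacement)[0]
            sb = _draw(rng, b, n, 1, with_replacement)[0]
            if sa.var(ddof=1) == 0 and sb.var(ddof=1) == 0:
                continue
            try:
                inner = resolve_inner_test(sa, sb, "auto")
            except Exception:
                inner = _stats.WELCH_T
            p, _ = _VECTOR_TESTS[inner](sa[None, :], sb[None, :])
            hits += int(p[0] < alpha)
        return hits / iterations
    inner = resolve_inner_test(a, b, test)
    sa = _draw(rng, a, n, iterations, with_replacement)
    sb = _draw(rng, b, n, iterations, with_replacement)
    p, _ = _VECTOR_TESTS[inner](sa, sb)
    return float(np.count_nonzero(p < alpha) / iterations)


def power_curve(a, b, config: PowerConfig | None = None, **overrides) -> PowerCurve:
    """Power-at-n over the configured range, with independent seeded streams
    per sample size."""
    config = replace(config or PowerConfig(), **overrides)
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    ns = np.arange(config.n_min, config.n_max + 1)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(ns))
    if config.test_policy in ("auto", "auto_once"):
        inner_fixed = resolve_inner_test(a, b, "auto_once")
    elif config.test_policy == "auto_per_iteration":
        inner_fixed = None
    else:
        inner_fixed = resolve_inner_test(a, b, config.test_policy)

    props = np.empty(len(ns))
    tests_used: list[str] = []
    for i, (n, child) in enumerate(zip(ns, children)):
        rng = np.random.default_rng(child)
        if inner_fixed is None:
            props[i] = power_at_n(
                a, b, int(n), config.iterations, config.alpha,
                "auto_per_iteration", seed=child,
                with_replacement=config.replace,
            )
            tests_used.append("auto_per_iteration")
            continue
        sa = _draw(rng, a, int(n), config.iterations, config.replace)
        sb = _draw(rng, b, int(n), config.iterations, config.replace)
        p, _ = _VECTOR_TESTS[inner_fixed](sa, sb)
        props[i] = np.count_nonzero(p < config.alpha) / config.iterations
        tests_used.append(inner_fixed)
    se = np.sqrt(props * (1 - props) / config.iterations)
    return PowerCurve(
        ns=ns,
        proportion_significant=props,
        mc_se=se,
        config=config,
        tests_used=tests_used,
    )


def min_n_for_power(curve: PowerCurve, target: float) -> int | None:
    """Smallest n whose proportion of significant outcomes reaches target."""
    if not 0 < target <= 1:
        raise ValueError("target power must be in (0, 1]")
    hits = np.flatnonzero(curve.proportion_significant >= target)
    return int(curve.ns[hits[0]]) if hits.size else None
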