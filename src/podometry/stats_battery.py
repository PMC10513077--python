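"""Pre-test screening and test-selection tree for multi-group comparisons.

Before any group comparison the data are screened for normality
(Anderson-Darling and Shapiro-Wilk, both must pass in every group),
homoscedasticity (Brown-Forsythe) and outliers (Grubbs).  The branch is
then chosen:

* normal and homoscedastic   -> one-way ANOVA + Bonferroni pairwise t-tests
* normal but heteroscedastic -> Welch ANOVA + Games-Howell pairwise tests
* not normal                 -> Kruskal-Wallis + pairwise Mann-Whitney U
                                (Bonferroni-adjusted)

p-values are annotated with the conventional significance codes
(ns, *, **, ***, ****).

The screening tests are diagnostics, not the inference itself, so they
run at a stricter level (``screen_alpha``, default 0.01) than the
comparison level ``alpha``: at the conventional 0.05 the conjunction of
two normality tests per group across several groups would route a
substantial share of genuinely normal datasets down the nonparametric
branch.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import normal_ad

__all__ = [
    "StatsConfig",
    "StatReport",
    "PairwiseResult",
    "grubbs",
    "choose_branch",
    "games_howell",
    "annotate",
    "run_battery",
]

Branch = Literal["ANOVA_Bonferroni", "ANOVA_GamesHowell", "KW_MWU"]


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05          # comparison level
    screen_alpha: float = 0.01   # level of the normality/variance screens
    grubbs_alpha: float = 0.05
    remove_outliers: bool = True  # drop the Grubbs-flagged value once
    min_group_size: int = 3

    def __post_init__(self) -> None:
        for a in (self.alpha, self.screen_alpha, self.grubbs_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError("alpha levels must be in (0, 1)")


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    code: str


@dataclass
class StatReport:
    """Full trace of the decision tree for one dataset."""

    branch: Branch
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    omnibus_code: str
    pairwise: list[PairwiseResult]
    screens: dict = field(default_factory=dict)
    outliers_removed: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "omnibus_test": self.omnibus_test,
            "omnibus_statistic": self.omnibus_statistic,
            "omnibus_p": self.omnibus_p,
            "omnibus_code": self.omnibus_code,
            "pairwise": [p.__dict__ for p in self.pairwise],
            "screens": self.screens,
            "outliers_removed": {k: float(v) for k, v in self.outliers_removed.items()},
        }


def annotate(p: float) -> str:
    """Significance code: ns, *, **, ***, **** (strict inequalities)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def grubbs(sample, alpha: float = 0.05) -> int | None:
    """Two-sided Grubbs test; index of the single most extreme outlier.

    G = max|x − x̄|/s is compared to the t-based critical value
    ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) quantile at n−2 df.
    At most one index is flagged; ``None`` when nothing exceeds the
    critical value.  A constant sample yields ``None`` with a warning.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        warnings.warn("constant sample: Grubbs test undefined", stacklevel=2)
        return None
    dev = np.abs(x - x.mean())
    g = dev.max() / s
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    g_crit = ((n - 1) / math.sqrt(n)) * math.sqrt(t**2 / (n - 2 + t**2))
    if g > g_crit:
        return int(dev.argmax())
    return None


def _screen(groups: dict[str, np.ndarray], cfg: StatsConfig) -> dict:
    """Run the normality and variance screens; return the trace."""
    trace: dict = {"normality": {}, "variance": {}}
    normal = True
    for name, x in groups.items():
        sw_stat, sw_p = sps.shapiro(x)
        ad_stat, ad_p = normal_ad(np.asarray(x, dtype=float))
        trace["normality"][name] = {
            "shapiro_w": float(sw_stat), "shapiro_p": float(sw_p),
            "anderson_darling_a2": float(ad_stat), "anderson_darling_p": float(ad_p),
        }
        if sw_p < cfg.screen_alpha or ad_p < cfg.screen_alpha:
            normal = False
    bf_stat, bf_p = sps.levene(*groups.values(), center="median")
    trace["variance"] = {"brown_forsythe_f": float(bf_stat), "brown_forsythe_p": float(bf_p)}
    trace["normal"] = normal
    trace["homoscedastic"] = bool(bf_p >= cfg.screen_alpha)
    return trace


def _prepare(groups: dict[str, Sequence[float]], cfg: StatsConfig):
    """Validate, optionally trim one Grubbs outlier per group."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    cleaned: dict[str, np.ndarray] = {}
    removed: dict[str, float] = {}
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        if x.size < cfg.min_group_size:
            raise ValueError(
                f"group {name!r} has n={x.size} < {cfg.min_group_size}"
            )
        if cfg.remove_outliers and x.std(ddof=1) > 0:
            idx = grubbs(x, cfg.grubbs_alpha)
            if idx is not None:
                removed[name] = float(x[idx])
                x = np.delete(x, idx)
        cleaned[name] = x
    return cleaned, removed


def choose_branch(groups: dict[str, Sequence[float]],
                  config: StatsConfig = StatsConfig()) -> tuple[Branch, dict]:
    """Select the comparison branch from the screening results.

    Returns the branch and the full screening trace (per-group normality
    statistics/p-values, Brown-Forsythe result, removed outliers).
    """
    cleaned, removed = _prepare(groups, config)
    trace = _screen(cleaned, config)
    trace["outliers_removed"] = removed
    if trace["normal"] and trace["homoscedastic"]:
        branch: Branch = "ANOVA_Bonferroni"
    elif trace["normal"]:
        branch = "ANOVA_GamesHowell"
    else:
        branch = "KW_MWU"
    return branch, trace


def games_howell(groups: dict[str, Sequence[float]]) -> list[PairwiseResult]:
    """Games-Howell pairwise comparisons for unequal variances.

    For each pair: t = (x̄i − x̄j)/√(si²/ni + sj²/nj) with
    Welch–Satterthwaite degrees of freedom; the p-value comes from the
    studentized-range distribution with k groups, via q = √2·|t|.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {n: np.asarray(groups[n], dtype=float) for n in names}
    for n, x in data.items():
        if x.size < 2:
            raise ValueError(f"group {n!r} needs n >= 2")
    k = len(names)
    out = []
    for a, b in itertools.combinations(names, 2):
        xa, xb = data[a], data[b]
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        na, nb = xa.size, xb.size
        se2 = va / na + vb / nb
        if se2 == 0:
            raise ZeroDivisionError("zero variance in both groups")
        t = (xa.mean() - xb.mean()) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        q = math.sqrt(2.0) * abs(t)
        p = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
        out.append(PairwiseResult(a, b, float(t), p, p, annotate(p)))
    return out


def _bonferroni(pairs: list[tuple[str, str, float, float]]) -> list[PairwiseResult]:
    m = len(pairs)
    out = []
    for a, b, stat, p in pairs:
        p_adj = min(1.0, m * p)
        out.append(PairwiseResult(a, b, float(stat), float(p), p_adj, annotate(p_adj)))
    return out


def run_battery(groups: dict[str, Sequence[float]],
                config: StatsConfig = StatsConfig()) -> StatReport:
    """Run the full screening + comparison tree on labeled groups."""
    cleaned, removed = _prepare(groups, config)
    trace = _screen(cleaned, config)
    trace["outliers_removed"] = removed
    names = list(cleaned)
    arrays = [cleaned[n] for n in names]

    if trace["normal"] and trace["homoscedastic"]:
        branch: Branch = "ANOVA_Bonferroni"
        stat, p = sps.f_oneway(*arrays)
        omnibus = "one-way ANOVA"
        raw = [
            (a, b, *_welchless_t(cleaned[a], cleaned[b]))
            for a, b in itertools.combinations(names, 2)
        ]
        pairwise = _bonferroni(raw)
    elif trace["normal"]:
        branch = "ANOVA_GamesHowell"
        res = sps.alexandergovern(*arrays)  # Welch-type heteroscedastic omnibus
        stat, p = res.statistic, res.pvalue
        omnibus = "Alexander-Govern ANOVA"
        pairwise = games_howell(cleaned)
    else:
        branch = "KW_MWU"
        stat, p = sps.kruskal(*arrays)
        omnibus = "Kruskal-Wallis"
        raw = []
        for a, b in itertools.combinations(names, 2):
            u, pu = sps.mannwhitneyu(cleaned[a], cleaned[b], alternative="two-sided")
            raw.append((a, b, u, pu))
        pairwise = _bonferroni(raw)

    if not math.isfinite(p):
        raise RuntimeError(f"non-finite omnibus p-value in branch {branch}")
    return StatReport(
        branch=branch,
        omnibus_test=omnibus,
        omnibus_statistic=float(stat),
        omnibus_p=float(p),
        omnibus_code=annotate(float(p)),
        pairwise=pairwise,
        screens=trace,
        outliers_removed=removed,
    )


def _welchless_t(xa, xb) -> tuple[float, float]:
    """Pooled-variance two-sample t-test (the post-ANOVA pairwise test)."""
    stat, p = sps.ttest_ind(xa, xb, equal_var=True)
    return float(stat), float(p)
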