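"""Statistical utilities for clinicopathologic comparisons.

Ordinal clinical variables (histologic pattern, differentiation grade,
IHC scores ...) are compared between tumor subtypes with a Mann-Whitney
U test that scores categories by their printed order and handles ties by
midranks.  An exact null distribution is available by enumerating group
compositions over the ordinal categories (multivariate hypergeometric),
which is feasible for the cohort sizes these tables have.  Survival is
analysed with Kaplan-Meier curves, the log-rank test and a univariate
proportional-hazards fit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OrdinalTable",
    "SurvivalData",
    "SurvivalGroupResult",
    "KMResult",
    "mann_whitney",
    "mann_whitney_values",
    "kruskal_wallis",
    "km_logrank",
    "bh_fdr",
]


@dataclass(frozen=True)
class OrdinalTable:
    """Counts of two or more groups over ordered categories.

    ``categories`` are in increasing order of the ordinal scale as printed
    in a clinical table (e.g. follicular < follicular-compact < compact).
    ``counts`` maps group label -> per-category nonnegative counts.
    """

    categories: tuple
    counts: dict

    def __post_init__(self):
        if len(self.categories) < 2:
            raise ValueError("OrdinalTable needs >= 2 categories")
        if len(self.counts) < 2:
            raise ValueError("OrdinalTable needs >= 2 groups")
        for g, row in self.counts.items():
            if len(row) != len(self.categories):
                raise ValueError(f"group {g!r} has {len(row)} counts, expected {len(self.categories)}")
            if any(c < 0 for c in row):
                raise ValueError(f"group {g!r} has negative counts")
        if self.total_n < 2:
            raise ValueError("OrdinalTable needs total n >= 2")

    @property
    def total_n(self) -> int:
        return int(sum(sum(row) for row in self.counts.values()))

    @classmethod
    def from_values(cls, x: Sequence[float], y: Sequence[float], labels=("group1", "group2")) -> "OrdinalTable":
        """Build a two-group table from raw numeric samples (each unique
        value becomes a category, preserving numeric order)."""
        cats = tuple(sorted(set(x) | set(y)))
        cx = [sum(1 for v in x if v == c) for c in cats]
        cy = [sum(1 for v in y if v == c) for c in cats]
        return cls(categories=cats, counts={labels[0]: cx, labels[1]: cy})


def _midranks(category_totals: np.ndarray) -> np.ndarray:
    cum = np.concatenate([[0], np.cumsum(category_totals)])
    return cum[:-1] + (category_totals + 1) / 2.0


def _compositions(total: int, caps: Sequence[int]):
    """All ways to place `total` items into len(caps) cells with cell caps."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for a in range(min(total, caps[0]) + 1):
        for rest in _compositions(total - a, caps[1:]):
            yield (a,) + rest


def _u_statistic(group1: np.ndarray, midranks: np.ndarray) -> float:
    n1 = group1.sum()
    r1 = float(np.dot(group1, midranks))
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(table: OrdinalTable, mode: str = "auto", two_sided: str = "symmetric"):
    """Two-sided Mann-Whitney U test on an ordinal 2-group table.

    Parameters
    ----------
    mode:
        ``"exact"`` enumerates group compositions over categories under the
        multivariate hypergeometric null; ``"asymptotic"`` uses the normal
        approximation with tie-corrected variance; ``"auto"`` picks exact
        when total n <= 60 and the composition enumeration stays small
        (heavily tied ordinal tables), else asymptotic.
    two_sided:
        ``"symmetric"`` sums null probability of outcomes at least as far
        from E[U] as observed; ``"double"`` doubles the smaller tail.

    Returns
    -------
    (U, p) for the first group (insertion order of ``table.counts``).
    """
    if len(table.counts) != 2:
        raise ValueError("mann_whitney requires exactly 2 groups; use kruskal_wallis")
    groups = list(table.counts)
    a = np.asarray(table.counts[groups[0]], dtype=float)
    b = np.asarray(table.counts[groups[1]], dtype=float)
    totals = a + b
    n1, n2 = a.sum(), b.sum()
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    mid = _midranks(totals)
    u_obs = _u_statistic(a, mid)
    mean_u = n1 * n2 / 2.0

    if mode == "auto":
        # bound the enumeration size: prod over categories of the number of
        # admissible group-1 counts; continuous data (one subject per
        # category) would blow this up exponentially
        log_bound = sum(math.log(min(n1, t) + 1) for t in totals.astype(int))
        mode = "exact" if table.total_n <= 60 and log_bound <= math.log(5e5) else "asymptotic"

    if mode == "asymptotic":
        n = n1 + n2
        tie_term = np.sum(totals**3 - totals) / (n * (n - 1)) if n > 1 else 0.0
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            return u_obs, 1.0
        z = (u_obs - mean_u) / math.sqrt(var_u)
        return u_obs, float(2 * sps.norm.sf(abs(z)))

    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")

    caps = [int(t) for t in totals]
    log_denom = math.lgamma(n1 + n2 + 1) - math.lgamma(n1 + 1) - math.lgamma(n2 + 1)
    obs_dev = abs(u_obs - mean_u)
    p_sym = 0.0
    p_lo = 0.0
    p_hi = 0.0
    for comp in _compositions(int(n1), caps):
        logp = -log_denom
        for c, t in zip(comp, caps):
            logp += math.lgamma(t + 1) - math.lgamma(c + 1) - math.lgamma(t - c + 1)
        prob = math.exp(logp)
        u = _u_statistic(np.asarray(comp, dtype=float), mid)
        if abs(u - mean_u) >= obs_dev - 1e-9:
            p_sym += prob
        if u <= u_obs + 1e-9:
            p_lo += prob
        if u >= u_obs - 1e-9:
            p_hi += prob
    if two_sided == "symmetric":
        return u_obs, min(1.0, p_sym)
    if two_sided == "double":
        return u_obs, min(1.0, 2 * min(p_lo, p_hi))
    raise ValueError(f"unknown two_sided convention {two_sided!r}")


def mann_whitney_values(x: Sequence[float], y: Sequence[float], mode: str = "auto", **kw):
    """Mann-Whitney / Wilcoxon rank-sum on raw numeric samples (ties allowed)."""
    return mann_whitney(OrdinalTable.from_values(x, y), mode=mode, **kw)


def kruskal_wallis(groups: dict):
    """Tie-corrected Kruskal-Wallis H with chi-square p (g-1 df).

    ``groups`` maps label -> list of real values.  Degenerate input where
    all pooled values are identical returns (0.0, 1.0) rather than raising.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


@dataclass
class SurvivalData:
    """Per-subject survival times in days with event indicators."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray
    excluded: np.ndarray = None
    exclusion_log: list = field(default_factory=list)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        self.group = np.asarray(self.group)
        if self.excluded is None:
            self.excluded = np.zeros(len(self.time), dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if np.any(self.time[~self.excluded] <= 0):
            raise ValueError("survival times must be positive")

    def analysis_frame(self) -> pd.DataFrame:
        keep = ~self.excluded
        return pd.DataFrame({"time": self.time[keep], "event": self.event[keep].astype(int), "group": self.group[keep]})


@dataclass
class SurvivalGroupResult:
    median: float  # np.inf when the curve never crosses 0.5
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


@dataclass
class KMResult:
    groups: dict  # label -> SurvivalGroupResult
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple
    reference_group: str


def km_logrank(data: SurvivalData, reference_group: str = None) -> KMResult:
    """Kaplan-Meier medians, two-sided log-rank p and univariate Cox HR.

    The hazard ratio contrasts the non-reference group against
    ``reference_group`` (first group lexicographically when not given);
    95% CI via normal approximation on the log hazard.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = data.analysis_frame()
    labels = sorted(pd.unique(df["group"]))
    if any((df["group"] == g).sum() == 0 for g in labels):
        raise ValueError("a group has zero subjects")
    if df["event"].sum() < 1:
        raise ValueError("need >= 1 event overall")

    groups = {}
    for g in labels:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        groups[g] = SurvivalGroupResult(
            median=float(kmf.median_survival_time_), n=len(sub), n_events=int(sub["event"].sum())
        )

    lr = multivariate_logrank_test(df["time"], df["group"], df["event"])
    logrank_p = float(lr.p_value)

    hr = math.nan
    ci = (math.nan, math.nan)
    ref = reference_group or labels[0]
    if len(labels) == 2:
        other = [g for g in labels if g != ref][0]
        cox_df = df.copy()
        cox_df["x"] = (cox_df["group"] == other).astype(float)
        cph = CoxPHFitter()
        cph.fit(cox_df[["time", "event", "x"]], duration_col="time", event_col="event")
        beta = float(cph.params_["x"])
        se = float(cph.standard_errors_["x"])
        def _safe_exp(x: float) -> float:
            # complete separation can give effectively infinite SEs
            return math.inf if x > 700 else math.exp(x)

        hr = _safe_exp(beta)
        ci = (_safe_exp(beta - 1.959963984540054 * se), _safe_exp(beta + 1.959963984540054 * se))
    return KMResult(groups=groups, logrank_p=logrank_p, hazard_ratio=hr, hr_ci=ci, reference_group=ref)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
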