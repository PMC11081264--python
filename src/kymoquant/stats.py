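"""Group-comparison decision procedure and reports.

Each metric is compared across genotype groups with the standard gate:
Shapiro-Wilk normality per group at alpha; if every group is consistent
with normality the comparison is parametric (two-sided Student's t for two
groups, one-way ANOVA with Tukey's post-hoc for more), otherwise
nonparametric (Mann-Whitney U for two groups, Kruskal-Wallis with Dunn's
post-hoc for more). Significance is declared at p < alpha (0.05).

Any single non-normal group switches the whole comparison to the
nonparametric branch. Dunn's post-hoc is implemented here (rank z-tests
with tie correction, Holm-adjusted within the post-hoc family).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["ComparisonSpec", "TestResult", "choose_and_run_test", "dunn_posthoc"]


@dataclass(frozen=True)
class ComparisonSpec:
    metric: str
    groups: tuple[str, ...]
    reference: str | None = None
    alpha: float = 0.05
    paired: bool = False  # unpaired throughout

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.paired:
            raise NotImplementedError("only unpaired comparisons are supported")


@dataclass
class TestResult:
    test_name: str  # {"student_t", "mann_whitney", "anova_tukey", "kruskal_dunn"}
    statistic: float
    p_value: float
    significant: bool
    normality: dict = field(default_factory=dict)  # group -> Shapiro-Wilk p
    posthoc: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            f"test: {self.test_name}",
            f"statistic: {self.statistic:.4g}",
            f"p-value: {self.p_value:.4g}",
            f"significant: {self.significant}",
        ]
        for g, p in self.normality.items():
            lines.append(f"  Shapiro-Wilk {g}: p={p:.4g}")
        if self.posthoc is not None:
            lines.append(self.posthoc.to_string(index=False))
        return "\n".join(lines)


def dunn_posthoc(samples: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after Kruskal-Wallis.

    z_ij = (mean rank_i - mean rank_j) / sqrt(S^2 (1/n_i + 1/n_j)) with the
    tie-corrected variance S^2 = N(N+1)/12 - T/(12(N-1)), T = sum(t^3 - t)
    over tie groups of the pooled ranks.
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    n_tot = len(pooled)
    ranks = sstats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(samples[g]) for g in names])
    mean_ranks = {
        g: ranks[offsets[i]: offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    s2 = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))

    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        n1, n2 = len(samples[g1]), len(samples[g2])
        se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * sstats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "statistic": z, "p_raw": p})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        m = len(out)
        order = np.argsort(out["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_adj"] = adj
    else:
        out["p_adj"] = np.minimum(out["p_raw"] * len(out), 1.0)
    return out


def choose_and_run_test(spec: ComparisonSpec, records: pd.DataFrame) -> TestResult:
    """Gate on per-group normality and run the appropriate comparison.

    ``records`` is a long-format table with at least ``genotype`` and
    ``value`` columns (optionally filtered by ``metric``).
    """
    df = pd.DataFrame(records)
    if "metric" in df.columns:
        df = df[df["metric"] == spec.metric]
    samples: dict[str, np.ndarray] = {}
    for g in spec.groups:
        vals = df.loc[df["genotype"] == g, "value"].to_numpy(dtype=float)
        if len(vals) < 3:
            raise ValueError(f"group {g!r} has {len(vals)} observations; need >= 3")
        samples[g] = vals

    normality = {g: float(sstats.shapiro(v).pvalue) for g, v in samples.items()}
    all_normal = all(p >= spec.alpha for p in normality.values())
    arrays = [samples[g] for g in spec.groups]

    posthoc = None
    if all_normal:
        if len(arrays) == 2:
            res = sstats.ttest_ind(arrays[0], arrays[1], equal_var=True)
            name, stat, p = "student_t", float(res.statistic), float(res.pvalue)
        else:
            res = sstats.f_oneway(*arrays)
            name, stat, p = "anova_tukey", float(res.statistic), float(res.pvalue)
            tk = sstats.tukey_hsd(*arrays)
            rows = []
            for i, j in itertools.combinations(range(len(arrays)), 2):
                rows.append(
                    {
                        "group1": spec.groups[i],
                        "group2": spec.groups[j],
                        "statistic": float(tk.statistic[i, j]),
                        "p_adj": float(tk.pvalue[i, j]),
                    }
                )
            posthoc = pd.DataFrame(rows)
    else:
        if len(arrays) == 2:
            res = sstats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
            name, stat, p = "mann_whitney", float(res.statistic), float(res.pvalue)
        else:
            res = sstats.kruskal(*arrays)
            name, stat, p = "kruskal_dunn", float(res.statistic), float(res.pvalue)
            posthoc = dunn_posthoc(samples)

    return TestResult(
        test_name=name,
        statistic=stat,
        p_value=p,
        significant=bool(p < spec.alpha),
        normality=normality,
        posthoc=posthoc,
    )
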