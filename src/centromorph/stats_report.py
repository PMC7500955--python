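"""Group statistics and run-level reporting.

Implements the statistical battery used for the morphometry comparisons:
two-sided Mann-Whitney U (exact by enumeration for small samples, normal
approximation with tie correction otherwise), one-way ANOVA with
Holm-Sidak step-down adjusted all-pairs comparisons, Fisher's exact test
for 2x2 count tables, and the unpaired Student/Welch t-test.  Significance
stars follow the usual convention (*p<0.05, **p<0.01, ***p<0.001,
****p<0.0001).

``build_report`` assembles measurement tables into per-condition
mean +/- SD summaries (sample SD, n-1 denominator) with the chosen test
per metric and a run log of every parameter.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError, MissingGroupError

__all__ = [
    "GroupSample",
    "StatsSummary",
    "significance_stars",
    "mann_whitney",
    "holm_sidak",
    "anova_holm_sidak",
    "fisher_exact",
    "unpaired_t",
    "build_report",
    "ReportBundle",
]

P_FLOOR = 1e-16  # stand-in for "p < 1e-15" in degenerate zero-variance cases


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: np.ndarray

    def __init__(self, label: str, values):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "values", np.asarray(values, dtype=float))
        if self.values.size < 1:
            raise InvalidInputError(f"group {label!r} is empty")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.n > 1 else 0.0


@dataclass(frozen=True)
class StatsSummary:
    test: str
    statistic: float
    p_value: float
    groups: tuple
    pairwise: tuple | None = None
    stars: str = ""


def significance_stars(p: float) -> str:
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _group_stats(groups) -> tuple:
    return tuple({"label": g.label, "mean": g.mean, "sd": g.sd, "n": g.n} for g in groups)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a over b, counting ties as half."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(a: GroupSample, b: GroupSample, exact_max_n: int = 12) -> StatsSummary:
    """Two-sided Mann-Whitney U test.

    For combined sample sizes up to ``exact_max_n`` the null distribution
    of U is enumerated exhaustively over all group labelings of the pooled
    values (ties handled by construction); larger samples use the normal
    approximation with tie correction.
    """
    x, y = a.values, b.values
    na, nb = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = na * nb / 2.0

    if na + nb <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = range(na + nb)
        total = 0
        extreme = 0
        d_obs = abs(u_obs - mu)
        for combo in itertools.combinations(idx, na):
            mask = np.zeros(na + nb, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= d_obs - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        tie_groups = np.unique(np.concatenate([x, y]), return_counts=True)[1]
        n = na + nb
        tie_term = (tie_groups**3 - tie_groups).sum() / (n * (n - 1))
        var = na * nb / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)  # continuity corrected
            p = float(2.0 * sps.norm.sf(max(z, 0.0)))
    p = min(p, 1.0)
    return StatsSummary(
        test="mann_whitney",
        statistic=u_obs,
        p_value=p,
        groups=_group_stats([a, b]),
        stars=significance_stars(p),
    )


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    With ordered raw p-values p(1) <= ... <= p(m), the adjusted value is
    adj(i) = max_{j<=i} [1 - (1 - p(j))^(m - j + 1)], capped at 1, mapped
    back to the input order.  Adjusted values are never smaller than the
    raw values and are invariant to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, j in enumerate(order):
        step = 1.0 - (1.0 - p[j]) ** (m - i)
        running = max(running, step)
        adj_sorted[i] = min(running, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def anova_holm_sidak(groups: list[GroupSample]) -> StatsSummary:
    """One-way ANOVA with Holm-Sidak adjusted all-pairs comparisons.

    Pairwise comparisons use t statistics on the pooled within-group mean
    square (the post-hoc convention following a one-way ANOVA), adjusted
    by the Holm-Sidak step-down rule.
    """
    if len(groups) < 3:
        raise InvalidInputError("anova_holm_sidak needs >= 3 groups")
    for g in groups:
        if g.n < 2:
            raise InvalidInputError(f"group {g.label!r} needs n >= 2")
    values = [g.values for g in groups]
    n_total = sum(g.n for g in groups)
    k = len(groups)
    df_w = n_total - k
    ss_w = sum(((v - v.mean()) ** 2).sum() for v in values)
    mse = ss_w / df_w

    if mse == 0:
        means = [g.mean for g in groups]
        equal = all(m == means[0] for m in means)
        f_stat, p = (0.0, 1.0) if equal else (np.inf, P_FLOOR)
    else:
        f_stat, p = sps.f_oneway(*values)
        f_stat, p = float(f_stat), float(p)

    raw = []
    pairs = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(groups), 2):
        if mse == 0:
            p_raw = 1.0 if gi.mean == gj.mean else P_FLOOR
            t = 0.0 if gi.mean == gj.mean else np.inf
        else:
            se = np.sqrt(mse * (1.0 / gi.n + 1.0 / gj.n))
            t = (gi.mean - gj.mean) / se
            p_raw = float(2.0 * sps.t.sf(abs(t), df_w))
        raw.append(p_raw)
        pairs.append((gi.label, gj.label, float(t)))
    adj = holm_sidak(raw)
    pairwise = tuple(
        {
            "a": la,
            "b": lb,
            "t": t,
            "p_raw": pr,
            "p_adj": float(pa),
            "stars": significance_stars(float(pa)),
        }
        for (la, lb, t), pr, pa in zip(pairs, raw, adj)
    )
    return StatsSummary(
        test="anova_holm_sidak",
        statistic=f_stat,
        p_value=float(p),
        groups=_group_stats(groups),
        pairwise=pairwise,
        stars=significance_stars(float(p)),
    )


def fisher_exact(table) -> StatsSummary:
    """Two-sided Fisher exact test on a 2x2 count table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's.  A zero margin gives p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise InvalidInputError("fisher_exact needs a 2x2 table of counts")
        t = np.round(t).astype(int)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    groups = tuple(
        {"label": f"row{i}", "mean": float(t[i, 0]), "sd": 0.0, "n": int(t[i].sum())}
        for i in range(2)
    )
    return StatsSummary(
        test="fisher_exact",
        statistic=float(odds) if np.isfinite(odds) else np.inf,
        p_value=float(p),
        groups=groups,
        stars=significance_stars(float(p)),
    )


def unpaired_t(a: GroupSample, b: GroupSample, welch: bool = False) -> StatsSummary:
    """Two-sided unpaired t-test (pooled variance; Welch selectable)."""
    va = a.values.var(ddof=1) if a.n > 1 else 0.0
    vb = b.values.var(ddof=1) if b.n > 1 else 0.0
    if a.n < 2 or b.n < 2:
        raise InvalidInputError("unpaired_t needs n >= 2 per group")
    if va == 0 and vb == 0:
        if a.mean == b.mean:
            t, p = 0.0, 1.0
        else:
            t, p = np.inf, P_FLOOR
    else:
        t, p = sps.ttest_ind(a.values, b.values, equal_var=not welch)
        t, p = float(t), float(p)
    return StatsSummary(
        test="welch_t" if welch else "student_t",
        statistic=t,
        p_value=p,
        groups=_group_stats([a, b]),
        stars=significance_stars(p),
    )


# --------------------------------------------------------------------------
# run-level report
# --------------------------------------------------------------------------

_TESTS = {
    "mann_whitney": mann_whitney,
    "unpaired_t": unpaired_t,
    "welch_t": lambda a, b: unpaired_t(a, b, welch=True),
    "anova_holm_sidak": anova_holm_sidak,
}


@dataclass
class ReportBundle:
    summary: pd.DataFrame
    stats: dict
    log: list = dataclass_field(default_factory=list)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / "summary.csv", index=False)
        with open(outdir / "stats.json", "w") as fh:
            json.dump(self.stats, fh, indent=2, default=_json_default)
        with open(outdir / "run.log", "w") as fh:
            fh.write("\n".join(self.log) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def build_report(
    measurements: pd.DataFrame,
    tests: dict[str, str] | None = None,
    round_rules: dict[str, int] | None = None,
) -> ReportBundle:
    """Per-condition summaries and group tests for a tidy measurement table.

    ``measurements`` must have columns ``metric``, ``group``, ``value``.
    ``tests`` maps metric name to a test ("mann_whitney", "unpaired_t",
    "welch_t", "anova_holm_sidak"); metrics without an entry (or with a
    single group) are summarized without a test.  ``round_rules`` maps a
    metric to the number of decimals in the summary (coverage percent and
    lengths are conventionally reported as integers).
    """
    required = {"metric", "group", "value"}
    if not required.issubset(measurements.columns):
        raise InvalidInputError(f"measurement table needs columns {sorted(required)}")
    tests = tests or {}
    round_rules = round_rules or {}
    log = [f"metrics: {sorted(measurements['metric'].unique())}"]

    rows = []
    stats_out: dict[str, dict] = {}
    for metric, sub in measurements.groupby("metric", sort=False):
        groups = [
            GroupSample(str(lab), g["value"].to_numpy())
            for lab, g in sub.groupby("group", sort=False)
        ]
        nd = round_rules.get(metric)
        for g in groups:
            rows.append(
                {
                    "metric": metric,
                    "group": g.label,
                    "mean": round(g.mean, nd) if nd is not None else g.mean,
                    "sd": round(g.sd, nd) if nd is not None else g.sd,
                    "n": g.n,
                }
            )
        test_name = tests.get(metric)
        if test_name is None or len(groups) < 2:
            log.append(f"{metric}: summary only ({len(groups)} group(s))")
            continue
        if test_name not in _TESTS:
            raise InvalidInputError(f"unknown test {test_name!r} for metric {metric!r}")
        if test_name == "anova_holm_sidak":
            summary = anova_holm_sidak(groups)
        else:
            if len(groups) != 2:
                raise InvalidInputError(
                    f"{test_name} needs exactly 2 groups for metric {metric!r}"
                )
            summary = _TESTS[test_name](groups[0], groups[1])
        stats_out[metric] = {
            "test": summary.test,
            "statistic": summary.statistic,
            "p_value": summary.p_value,
            "stars": summary.stars,
            "groups": list(summary.groups),
            "pairwise": list(summary.pairwise) if summary.pairwise else None,
        }
        log.append(f"{metric}: {summary.test} p={summary.p_value:.4g} {summary.stars}")

    summary_df = pd.DataFrame(rows)
    missing = set(tests) - set(measurements["metric"].unique())
    if missing:
        raise MissingGroupError(f"tests requested for absent metrics: {sorted(missing)}")
    return ReportBundle(summary=summary_df, stats=stats_out, log=log)
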