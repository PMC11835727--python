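"""Between-subject statistics: inclusion filters, Pearson correlation
matrices, and Steiger's test for dependent overlapping correlations.

Exclusion rules follow the strict-inequality semantics of the study
protocol they encode: a block is dropped when one option was picked on
MORE than 94% of its trials; a subject is dropped when the high-effort
option was picked on MORE than 95% of one task's trials; a value is an
outlier when it lies MORE than k (default 3) sample standard deviations
from the variable's median. Filters are applied per analysis, not
globally, so different analyses can retain different Ns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    variables: tuple[str, str]


@dataclass(frozen=True)
class SteigerResult:
    z: float
    p: float
    n: int
    r12: float
    r13: float
    r23: float
    tail: str


def outlier_filter(table: pd.DataFrame, variables: list[str],
                   k: float = 3.0) -> pd.Series:
    """Per-analysis inclusion mask over the rows of ``table``.

    A row is included iff every listed variable is non-missing and
    within k sample SDs of that variable's median; median and SD are
    computed over the variable's full non-missing sample (outlier
    candidates included). Applying the mask twice is idempotent because
    the reference median/SD never change.
    """
    mask = pd.Series(True, index=table.index)
    for var in variables:
        vals = table[var]
        ok = vals.notna()
        if ok.sum() < 4:
            raise ValueError(f"variable {var!r} has <4 non-missing values")
        med = vals[ok].median()
        sd = vals[ok].std(ddof=1)
        within = ok & ((vals - med).abs() <= k * sd)
        mask &= within
    return mask


def block_exclusion(choices: pd.DataFrame, threshold: float = 0.94,
                    block_col: str = "block_index") -> list:
    """Blocks where one option was chosen more than ``threshold`` of
    the time (boundary retained)."""
    excluded = []
    for blk, grp in choices.groupby(block_col):
        n = len(grp)
        n_he = int(grp["choice"].sum())
        if max(n_he, n - n_he) / n > threshold:
            excluded.append(blk)
    return excluded


def subject_exclusion(choices_by_task: pd.DataFrame,
                      threshold: float = 0.95,
                      subject_col: str = "subject",
                      task_col: str = "domain") -> list:
    """Subjects choosing the HE option on more than ``threshold`` of
    one task's pooled trials (the rule is HE-specific: uniform LE
    choosers are retained)."""
    excluded = []
    for subj, grp in choices_by_task.groupby(subject_col):
        for _, task_grp in grp.groupby(task_col):
            if task_grp["choice"].mean() > threshold:
                excluded.append(subj)
                break
    return excluded


def pearson(x, y, variables: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson r with the two-sided t-distributed p-value, on pairwise
    complete cases."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=len(x), variables=variables)


def steiger_test(r12: float, r13: float, r23: float, n: int,
                 tail: str) -> SteigerResult:
    """Steiger's (1980) Z comparing two dependent overlapping
    correlations r12 and r13 that share variable 1, with r23 their
    intercorrelation.

    Uses the Fisher-z difference scaled by the Dunn & Clark covariance
    evaluated at the pooled correlation rbar = (r12 + r13)/2. ``tail``
    states the directional hypothesis explicitly: ``"greater"`` tests
    r12 > r13, ``"less"`` tests r12 < r13, ``"two-sided"`` is also
    available.
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not abs(r) < 1:
            raise ValueError(f"|{name}| must be < 1")
    if n <= 3:
        raise ValueError("n must exceed 3")
    R = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlations do not form a PSD matrix")
    rbar = 0.5 * (r12 + r13)
    cov = (r23 * (1 - 2 * rbar**2)
           - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)) / (1 - rbar**2) ** 2
    z = (np.arctanh(r12) - np.arctanh(r13)) * np.sqrt(n - 3) \
        / np.sqrt(2 - 2 * cov)
    if tail == "greater":
        p = sps.norm.sf(z)
    elif tail == "less":
        p = sps.norm.cdf(z)
    elif tail == "two-sided":
        p = 2 * sps.norm.sf(abs(z))
    else:
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")
    return SteigerResult(z=float(z), p=float(p), n=n,
                         r12=r12, r13=r13, r23=r23, tail=tail)


def steiger_from_table(table: pd.DataFrame, shared: str, v1: str, v2: str,
                       tail: str, k_outlier: float = 3.0) -> SteigerResult:
    """Recompute the three correlations on the common-subject subset
    (complete cases, per-analysis outlier filter over all three
    variables), then run Steiger's test — the subset entry point."""
    mask = outlier_filter(table, [shared, v1, v2], k=k_outlier)
    sub = table.loc[mask]
    r12 = pearson(sub[shared], sub[v1]).r
    r13 = pearson(sub[shared], sub[v2]).r
    r23 = pearson(sub[v1], sub[v2]).r
    return steiger_test(r12, r13, r23, n=len(sub), tail=tail)


STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


def correlation_heatmap(table: pd.DataFrame,
                        variables: list[str],
                        k_outlier: float = 3.0) -> dict[str, pd.DataFrame]:
    """All pairwise Pearson correlations with per-analysis filtering.

    For each pair, rows are filtered on that pair's variables only
    (complete cases + the 3-SD-from-median rule), so each cell can have
    its own N. Returns matrices ``r``, ``p``, ``n`` and ``stars``.
    """
    m = len(variables)
    r = pd.DataFrame(np.eye(m), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((m, m)), index=variables, columns=variables)
    n = pd.DataFrame(0, index=variables, columns=variables)
    stars = pd.DataFrame("", index=variables, columns=variables)
    for i, a in enumerate(variables):
        n.loc[a, a] = int(table[a].notna().sum())
        for b in variables[i + 1:]:
            mask = outlier_filter(table, [a, b], k=k_outlier)
            res = pearson(table.loc[mask, a], table.loc[mask, b],
                          variables=(a, b))
            r.loc[a, b] = r.loc[b, a] = res.r
            p.loc[a, b] = p.loc[b, a] = res.p
            n.loc[a, b] = n.loc[b, a] = res.n
            stars.loc[a, b] = stars.loc[b, a] = significance_stars(res.p)
    return {"r": r, "p": p, "n": n, "stars": stars}


def plot_heatmap(heatmap: dict[str, pd.DataFrame], path=None, title=None):
    """Render a correlation heatmap with significance stars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r, stars = heatmap["r"], heatmap["stars"]
    fig, ax = plt.subplots(figsize=(1 + 0.8 * len(r), 1 + 0.8 * len(r)))
    im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(r)), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(r)), r.index)
    for i in range(len(r)):
        for j in range(len(r)):
            if i != j:
                ax.text(j, i, f"{r.iat[i, j]:.2f}{stars.iat[i, j]}",
                        ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
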