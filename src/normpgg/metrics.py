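"""Measurement layer: block means, punishment frequency/intensity, percent
comparisons, earnings summaries, and the nonparametric test battery.

All panel-level summaries average group-level means first and only then
average across groups: the fixed group is the independent unit of analysis,
matching the group-level nonparametric tests used on such experiments.

Punishment frequency is the share of sender-to-target opportunities in which
any points were sent (4x3 = 12 opportunities per group-round, regardless of
the amount); punishment intensity is the mean number of points per punishing
act, excluding all zero-point instances — with no acts it is explicitly
undefined (None), never zero.

The rank tests use midranks throughout.  Mann-Whitney and Wilcoxon p-values
are exact (full enumeration over group assignments / sign patterns) for small
samples and tie-corrected normal approximations otherwise; Kruskal-Wallis
uses the tie-corrected H with its chi-square approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats

from .game import ValidationError

__all__ = [
    "BlockSummary",
    "TestResult",
    "DEFAULT_BLOCKS",
    "parse_block",
    "block_means",
    "punishment_frequency",
    "punishment_intensity",
    "percent_excess",
    "percent_excess_exact",
    "kruskal_wallis",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "earnings_summary",
    "summarize",
    "replication_means",
    "frequency_by_replication",
]

#: Round blocks used throughout the analysis (baseline, instrumented halves, baseline).
DEFAULT_BLOCKS = ("1-10", "1-5", "6-10", "11-20", "11-15", "16-20", "21-30")


@dataclass(frozen=True)
class BlockSummary:
    """Summary of one treatment x block cell."""

    treatment: str
    block: str
    mean_contribution: float
    punishment_frequency: Optional[float] = None
    mean_intensity: Optional[float] = None  # None = undefined (no punishing acts)
    mean_net_earnings: Optional[float] = None


@dataclass(frozen=True)
class TestResult:
    """Statistic and p-value of a nonparametric test."""

    statistic: float
    pvalue: float
    degenerate: bool = False


def parse_block(block: str) -> tuple[int, int]:
    """Parse a block label like ``"11-20"`` into inclusive round bounds."""
    lo, hi = (int(x) for x in block.split("-"))
    if lo > hi or lo < 1:
        raise ValidationError(f"invalid block {block!r}")
    return lo, hi


def _block_rows(panel: pd.DataFrame, block: str) -> pd.DataFrame:
    lo, hi = parse_block(block)
    sub = panel[(panel["round"] >= lo) & (panel["round"] <= hi)]
    if sub.empty:
        raise ValidationError(f"block {block!r} selects no rounds")
    return sub


def _group_unit_means(sub: pd.DataFrame, column: str) -> pd.Series:
    """Per-(treatment, replication, group) means — the independent units."""
    return sub.groupby(["treatment", "replication", "group"], sort=True)[column].mean()


def block_means(
    panel: pd.DataFrame, blocks: Sequence[str] = ("1-10", "11-20", "21-30")
) -> pd.DataFrame:
    """Mean contribution per treatment and block, group-level means first.

    ``panel`` is a long round table with at least treatment / replication /
    group / round / contribution columns, or a
    :class:`~normpgg.fixtures.FixtureTable` of already-aggregated block means.
    """
    from .fixtures import FixtureTable

    if isinstance(panel, FixtureTable):
        df = panel.to_summary()
        df = df[df["block"].isin(blocks)].reset_index(drop=True)
        missing = set(blocks) - set(df["block"])
        if missing:
            raise ValidationError(f"fixture table lacks blocks: {sorted(missing)}")
        return df

    records = []
    for block in blocks:
        sub = _block_rows(panel, block)
        means = _group_unit_means(sub, "contribution").groupby("treatment").mean()
        for treatment, value in means.items():
            records.append((treatment, block, float(value)))
    return pd.DataFrame(records, columns=["treatment", "block", "mean_contribution"])


def _detail_points(detail: pd.Series) -> list[int]:
    pts = []
    for s in detail:
        if s:
            pts.extend(int(part.split(":")[1]) for part in s.split(";"))
    return pts


def punishment_frequency(
    panel: pd.DataFrame,
    block: str = "11-20",
    treatment: Optional[str] = None,
    group_size: int = 4,
) -> float:
    """Share of sender-to-target opportunities in which any points were sent.

    Every agent-round contributes ``group_size - 1`` opportunities, used or
    not, so a 4-member round has 12.  The number of points sent is irrelevant;
    only whether each allocation was nonzero counts.
    """
    sub = _block_rows(panel, block)
    if treatment is not None:
        sub = sub[sub["treatment"] == treatment]
    if sub.empty:
        raise ValidationError("scope selects no opportunities")
    acts = int(sub["points_detail"].str.count(":").sum())
    opportunities = len(sub) * (group_size - 1)
    return acts / opportunities


def punishment_intensity(
    panel: pd.DataFrame, block: str = "11-20", treatment: Optional[str] = None
) -> Optional[float]:
    """Mean points per punishing act, zero-point instances excluded.

    Returns None (explicitly undefined) when the scope contains no acts.
    """
    sub = _block_rows(panel, block)
    if treatment is not None:
        sub = sub[sub["treatment"] == treatment]
    pts = _detail_points(sub["points_detail"])
    return float(np.mean(pts)) if pts else None


def percent_excess_exact(a: float, b: float) -> float:
    """Unrounded percent by which ``a`` exceeds ``b``: ``100 * (a - b) / b``."""
    if b <= 0:
        raise ValidationError(f"baseline must be > 0, got {b}")
    return 100.0 * (a - b) / b


def percent_excess(a: float, b: float) -> int:
    """Percent by which ``a`` exceeds ``b``, rounded to the nearest integer."""
    return int(np.rint(percent_excess_exact(a, b)))


# --------------------------------------------------------------------------
# nonparametric tests


def kruskal_wallis(*samples: Sequence[float]) -> TestResult:
    """Kruskal-Wallis H (midranks, tie-corrected) with chi-square p-value."""
    if len(samples) < 2:
        raise ValidationError("need at least 2 samples")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("samples must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # scipy refuses the all-identical case; H is 0 by definition
        return TestResult(0.0, 1.0, degenerate=True)
    h, p = scipy.stats.kruskal(*arrays)
    return TestResult(float(h), float(p))


def _mw_u(ranks_x: np.ndarray, nx: int) -> float:
    return float(ranks_x.sum() - nx * (nx + 1) / 2)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test.

    U counts, over all (x, y) pairs, the times x exceeds y (ties count 1/2).
    The p-value is exact — full enumeration over the C(nx+ny, nx) group
    assignments of the pooled midranks, so ties are handled — for combined
    n <= 10, and a tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("samples must be nonempty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = _mw_u(ranks[:nx], nx)
    if nx + ny <= 10:
        us = np.array(
            [_mw_u(ranks[list(idx)], nx) for idx in combinations(range(nx + ny), nx)]
        )
        mu = nx * ny / 2
        if alternative == "two-sided":
            p = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12))
        elif alternative == "greater":
            p = float(np.mean(us >= u_obs - 1e-12))
        elif alternative == "less":
            p = float(np.mean(us <= u_obs + 1e-12))
        else:
            raise ValidationError(f"unknown alternative {alternative!r}")
        return TestResult(u_obs, p)
    res = scipy.stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon signed-rank test on paired samples (differences ``x - y``).

    Zero differences are dropped; if none remain the result is degenerate
    (statistic 0, p 1).  The statistic is the smaller of the positive- and
    negative-rank sums.  For n <= 12 nonzero pairs the p-value is exact by
    enumeration of all sign patterns on the midranks of |d| (ties handled);
    larger samples use the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return TestResult(0.0, 1.0, degenerate=True)
    n = d.size
    ranks = scipy.stats.rankdata(np.abs(d))
    s_plus = float(ranks[d > 0].sum())
    s_minus = float(ranks[d < 0].sum())
    w = min(s_plus, s_minus)
    if n <= 12:
        # distribution of the positive-rank sum over all 2^n sign patterns
        signs = np.array(np.meshgrid(*([[0, 1]] * n))).reshape(n, -1)
        sums = ranks @ signs
        if alternative == "two-sided":
            p = float(np.mean((sums <= w + 1e-12) | (sums >= (s_plus + s_minus) - w - 1e-12)))
        elif alternative == "greater":  # x tends to exceed y
            p = float(np.mean(sums >= s_plus - 1e-12))
        elif alternative == "less":
            p = float(np.mean(sums <= s_plus + 1e-12))
        else:
            raise ValidationError(f"unknown alternative {alternative!r}")
        return TestResult(w, p)
    res = scipy.stats.wilcoxon(
        x, y, alternative=alternative, zero_method="wilcox", method="approx"
    )
    return TestResult(float(res.statistic), float(res.pvalue))


# --------------------------------------------------------------------------
# panel summaries


def earnings_summary(
    panel: pd.DataFrame, blocks: Sequence[str] = ("1-10", "11-20", "21-30")
) -> pd.DataFrame:
    """Mean final payoff per member per round, by treatment and block."""
    records = []
    for block in blocks:
        sub = _block_rows(panel, block)
        means = _group_unit_means(sub, "final_payoff").groupby("treatment").mean()
        for treatment, value in means.items():
            records.append((treatment, block, float(value)))
    return pd.DataFrame(records, columns=["treatment", "block", "mean_net_earnings"])


def summarize(
    panel: pd.DataFrame, blocks: Sequence[str] = DEFAULT_BLOCKS, group_size: int = 4
) -> pd.DataFrame:
    """Full per-treatment, per-block summary table.

    Columns: mean_contribution, punishment_frequency, mean_intensity (NaN
    where undefined), mean_net_earnings.
    """
    records = []
    for block in blocks:
        sub = _block_rows(panel, block)
        for treatment, tsub in sub.groupby("treatment", sort=True):
            units = tsub.groupby(["replication", "group"])
            intensity = punishment_intensity(tsub, block)
            records.append(
                BlockSummary(
                    treatment=str(treatment),
                    block=block,
                    mean_contribution=float(units["contribution"].mean().mean()),
                    punishment_frequency=punishment_frequency(
                        tsub, block, group_size=group_size
                    ),
                    mean_intensity=intensity,
                    mean_net_earnings=float(units["final_payoff"].mean().mean()),
                )
            )
    return pd.DataFrame([vars(r) for r in records])


def replication_means(
    panel: pd.DataFrame, block: str, column: str = "contribution"
) -> pd.DataFrame:
    """Per-treatment, per-replication means (groups averaged first).

    The natural sampling unit for comparing treatments across replicated
    simulation runs; returns a tidy frame treatment / replication / value.
    """
    sub = _block_rows(panel, block)
    unit = _group_unit_means(sub, column)
    reps = unit.groupby(["treatment", "replication"]).mean().rename("value")
    return reps.reset_index()


def frequency_by_replication(
    panel: pd.DataFrame, block: str, treatment: str, group_size: int = 4
) -> np.ndarray:
    """Punishment frequency computed separately within each replication."""
    sub = _block_rows(panel, block)
    sub = sub[sub["treatment"] == treatment]
    if sub.empty:
        raise ValidationError(f"no rows for treatment {treatment!r} in block {block!r}")
    acts = sub.groupby("replication")["points_detail"].apply(
        lambda s: int(s.str.count(":").sum())
    )
    opportunities = sub.groupby("replication").size() * (group_size - 1)
    return (acts / opportunities).to_numpy(dtype=float)
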