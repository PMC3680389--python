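"""Reference results from the human laboratory experiment, and the
qualitative (ordering) comparison between simulated panels and those results.

The fixture table holds the reported group-average contribution levels by
treatment and round block from the laboratory sessions (12 fixed groups of 4,
30 rounds, treatments punishment / message / sanction).  The simulation is a
binary-choice abstraction of that game, so the comparison contract is
qualitative: the orderings and trends must agree, not the levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Optional

import pandas as pd

from .game import ValidationError

__all__ = [
    "FixtureCell",
    "FixtureTable",
    "HUMAN_BLOCK_MEANS",
    "OrderingCheck",
    "OrderingReport",
    "compare_to_fixtures",
]


@dataclass(frozen=True)
class FixtureCell:
    """One reported block mean with its provenance tag."""

    value: float
    provenance: str


@dataclass(frozen=True)
class FixtureTable:
    """Immutable table of reported human block means, keyed (treatment, block)."""

    cells: Mapping[tuple[str, str], FixtureCell]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", MappingProxyType(dict(self.cells)))

    def value(self, treatment: str, block: str) -> float:
        try:
            return self.cells[(treatment, block)].value
        except KeyError:
            raise ValidationError(f"no fixture cell for ({treatment!r}, {block!r})")

    @property
    def blocks(self) -> list[str]:
        return sorted({b for _, b in self.cells})

    def to_summary(self) -> pd.DataFrame:
        """The fixture as a block-summary frame (mean contributions only)."""
        return pd.DataFrame(
            [
                {"treatment": t, "block": b, "mean_contribution": c.value}
                for (t, b), c in self.cells.items()
            ]
        )


def _human(block: str, treatment: str) -> str:
    return f"human experiment, group-average contribution, {treatment} treatment, rounds {block}"


#: Reported mean contributions (ECU out of 20) from the laboratory sessions.
HUMAN_BLOCK_MEANS = FixtureTable(
    cells={
        ("message", "1-10"): FixtureCell(8.33, _human("1-10", "message")),
        ("punishment", "1-10"): FixtureCell(6.25, _human("1-10", "punishment")),
        ("sanction", "1-10"): FixtureCell(8.23, _human("1-10", "sanction")),
        ("message", "16-20"): FixtureCell(9.90, _human("16-20", "message")),
        ("punishment", "16-20"): FixtureCell(10.65, _human("16-20", "punishment")),
        ("sanction", "16-20"): FixtureCell(14.46, _human("16-20", "sanction")),
        ("message", "21-30"): FixtureCell(5.05, _human("21-30", "message")),
        ("punishment", "21-30"): FixtureCell(3.75, _human("21-30", "punishment")),
        ("sanction", "21-30"): FixtureCell(9.08, _human("21-30", "sanction")),
    }
)


@dataclass(frozen=True)
class OrderingCheck:
    """One qualitative agreement check: pass / fail / not-evaluated."""

    name: str
    status: str  # "pass" | "fail" | "not-evaluated"
    detail: str = ""


@dataclass(frozen=True)
class OrderingReport:
    """Result of the qualitative simulated-vs-human comparison."""

    checks: tuple[OrderingCheck, ...]

    @property
    def evaluated(self) -> list[OrderingCheck]:
        return [c for c in self.checks if c.status != "not-evaluated"]

    @property
    def all_pass(self) -> bool:
        """True iff every check that could be evaluated passed."""
        return all(c.status == "pass" for c in self.evaluated)

    def __str__(self) -> str:
        width = max(len(c.name) for c in self.checks)
        return "\n".join(
            f"{c.name:<{width}}  {c.status:>13}  {c.detail}" for c in self.checks
        )


def _lookup(summary: pd.DataFrame, treatment: str, block: str, column: str) -> Optional[float]:
    if column not in summary.columns:
        return None
    rows = summary[(summary["treatment"] == treatment) & (summary["block"] == block)]
    if rows.empty:
        return None
    v = rows.iloc[0][column]
    return None if pd.isna(v) else float(v)


def compare_to_fixtures(
    summary: pd.DataFrame, fixtures: FixtureTable = HUMAN_BLOCK_MEANS
) -> OrderingReport:
    """Check the sign/ordering agreements claimed between simulation and humans.

    ``summary`` is a block-summary frame (``metrics.summarize`` output, or the
    fixture's own ``to_summary()``).  Checks whose inputs are missing from the
    summary are reported as ``not-evaluated`` rather than failed:

    i.   sanction > punishment and sanction > message mean contribution, in
         blocks 16-20 and 21-30;
    ii.  contribution decline within rounds 1-10 (mean 1-5 > mean 6-10) in
         every treatment present;
    iii. punishment frequency in rounds 11-20 higher in the punishment than
         in the sanction treatment.
    """
    checks: list[OrderingCheck] = []

    for block in ("16-20", "21-30"):
        for other in ("punishment", "message"):
            name = f"contribution[{block}]: sanction > {other}"
            a = _lookup(summary, "sanction", block, "mean_contribution")
            b = _lookup(summary, other, block, "mean_contribution")
            if a is None or b is None:
                checks.append(OrderingCheck(name, "not-evaluated", "block missing"))
            else:
                checks.append(
                    OrderingCheck(
                        name, "pass" if a > b else "fail", f"{a:.2f} vs {b:.2f}"
                    )
                )

    treatments = sorted(summary["treatment"].unique())
    for treatment in treatments:
        name = f"decline within rounds 1-10: {treatment}"
        early = _lookup(summary, treatment, "1-5", "mean_contribution")
        late = _lookup(summary, treatment, "6-10", "mean_contribution")
        if early is None or late is None:
            checks.append(OrderingCheck(name, "not-evaluated", "sub-blocks missing"))
        else:
            checks.append(
                OrderingCheck(
                    name, "pass" if early > late else "fail", f"{early:.2f} vs {late:.2f}"
                )
            )

    name = "punishment frequency[11-20]: punishment > sanction"
    fp = _lookup(summary, "punishment", "11-20", "punishment_frequency")
    fs = _lookup(summary, "sanction", "11-20", "punishment_frequency")
    if fp is None or fs is None:
        checks.append(OrderingCheck(name, "not-evaluated", "frequencies missing"))
    else:
        checks.append(
            OrderingCheck(name, "pass" if fp > fs else "fail", f"{fp:.3f} vs {fs:.3f}")
        )

    return OrderingReport(tuple(checks))
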