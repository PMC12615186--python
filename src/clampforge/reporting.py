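"""Host-vs-microbial read-fraction reports.

Consumes already-labeled read counts (taxonomic classification is a
third-party pipeline concern) and reports the microbial percentage of each
condition at full precision and at one-decimal / integer rounding.
Rounding is half-away-from-zero, the convention under which e.g. 99.7785%
prints as 99.8% and 66.75% prints as 67%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ConditionFractions",
    "FractionReport",
    "round_half_away",
    "read_fraction_report",
    "condition_summary",
    "read_counts_tsv",
]

HOST_PREFIX = "host"


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (Python's round() is half-to-even)."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def _is_host(component: str) -> bool:
    return component.startswith(HOST_PREFIX)


def _is_microbial(component: str) -> bool:
    return component == "microbial" or component.startswith("taxon:")


@dataclass(frozen=True)
class ConditionFractions:
    condition: str
    host_reads: int
    microbial_reads: int
    host_components: dict[str, int]
    microbial_percent: float       # full precision
    host_percent: float
    microbial_percent_1dp: float   # half away from zero
    microbial_percent_int: int


@dataclass
class FractionReport:
    conditions: list[ConditionFractions]
    rounding: str = "half_away_from_zero"

    def __getitem__(self, condition: str) -> ConditionFractions:
        for c in self.conditions:
            if c.condition == condition:
                return c
        raise KeyError(condition)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "condition": c.condition,
            "host_reads": c.host_reads,
            "microbial_reads": c.microbial_reads,
            "microbial_percent": c.microbial_percent,
            "microbial_percent_1dp": c.microbial_percent_1dp,
            "microbial_percent_int": c.microbial_percent_int,
        } for c in self.conditions])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_fraction_report(
    counts: Mapping[str, Mapping[str, int]],
) -> FractionReport:
    """Per-condition microbial percentage from labeled read counts.

    ``counts`` maps condition -> component -> count, where components are
    ``host_*`` (chloroplast/mitochondrial/nuclear sub-counts allowed),
    ``microbial``, or ``taxon:<name>`` (counted as microbial).
    """
    out: list[ConditionFractions] = []
    for cond, comp in counts.items():
        host_components: dict[str, int] = {}
        microbial = 0
        for name, c in comp.items():
            if c < 0:
                raise ValueError(f"condition {cond!r}: negative count for {name!r}")
            if _is_host(name):
                host_components[name] = host_components.get(name, 0) + int(c)
            elif _is_microbial(name):
                microbial += int(c)
            else:
                raise ValueError(f"condition {cond!r}: unknown component {name!r}")
        host = sum(host_components.values())
        total = host + microbial
        if total == 0:
            raise ValueError(f"condition {cond!r}: all counts are zero")
        pct = 100.0 * microbial / total
        out.append(ConditionFractions(
            condition=cond,
            host_reads=host,
            microbial_reads=microbial,
            host_components=host_components,
            microbial_percent=pct,
            host_percent=100.0 - pct,
            microbial_percent_1dp=round_half_away(pct, 1),
            microbial_percent_int=int(round_half_away(pct, 0)),
        ))
    return FractionReport(out)


def condition_summary(report: FractionReport) -> dict[str, object]:
    """Extremes of the microbial percentage across conditions.

    Extremes are located on the full-precision values; ties resolve to the
    first condition in input order.  Rounded forms are included.
    """
    if not report.conditions:
        raise ValueError("empty report")
    lo = min(report.conditions, key=lambda c: c.microbial_percent)
    hi = max(report.conditions, key=lambda c: c.microbial_percent)
    return {
        "min_condition": lo.condition,
        "min_percent": lo.microbial_percent,
        "min_percent_int": lo.microbial_percent_int,
        "max_condition": hi.condition,
        "max_percent": hi.microbial_percent,
        "max_percent_int": hi.microbial_percent_int,
    }


def read_counts_tsv(path: str | Path) -> dict[str, dict[str, int]]:
    """Read a (condition, component, count) TSV into the report input form."""
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "component", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts TSV needs columns {sorted(required)}")
    counts: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        cond = counts.setdefault(str(row["condition"]), {})
        comp = str(row["component"])
        cond[comp] = cond.get(comp, 0) + int(row["count"])
    return counts
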