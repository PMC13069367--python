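"""Diversity report tables with an Average row, in the published layout.

One row per metric, one column per system, plus an ``Average`` row. Two
rounding modes are provided because published tables are ambiguous about
whether their Average row was computed from the rounded cells readers see or
from full-precision values:

``from_rounded_cells``
    Each cell is rounded half-up to 2 decimals first; the Average is the mean
    of those rounded cells, itself rounded half-up to 2 decimals. This is the
    mode that reproduces a printed Average row from printed cells.
``from_unrounded``
    The Average is computed from full-precision values; rounding happens only
    at display time.

Every report embeds the decision metadata (score component, skip-bigram gap,
p-value convention, seeds) needed to compare two reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .semantic import SemanticDiversityResult
from .surface import SKIP_BIGRAM_MAX_GAP, SelfRougeResult

__all__ = ["ReportTable", "build_report", "build_report_from_cells", "round_half_up"]

ROUNDING_MODES = ("from_rounded_cells", "from_unrounded")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReportTable:
    """A metric x system grid plus its Average row and decision metadata."""

    metrics: tuple[str, ...]
    systems: tuple[str, ...]
    cells: Mapping[tuple[str, str], float]  # (metric, system) -> value
    average_row: Mapping[str, float]
    rounding: str
    metadata: Mapping[str, object] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Display frame: cells rounded half-up to 2 decimals, Average last."""
        rows = []
        for metric in self.metrics:
            rows.append(
                {"metric": metric}
                | {
                    s: round_half_up(self.cells[(metric, s)])
                    for s in self.systems
                }
            )
        rows.append(
            {"metric": "Average"}
            | {s: round_half_up(self.average_row[s]) for s in self.systems}
        )
        return pd.DataFrame(rows, columns=["metric", *self.systems])


def build_report_from_cells(
    cells: Mapping[str, Mapping[str, float]],
    rounding: str = "from_unrounded",
    metadata: Mapping[str, object] | None = None,
) -> ReportTable:
    """Build a report from a {metric -> {system -> value}} grid.

    Every metric must provide a value for every system; a missing cell is an
    error naming the (system, metric) hole.
    """
    if rounding not in ROUNDING_MODES:
        raise ValueError(
            f"unknown rounding mode {rounding!r}; expected one of "
            f"{ROUNDING_MODES}"
        )
    metrics = tuple(cells)
    if not metrics:
        raise ValidationError("report needs at least one metric row")
    systems = tuple(cells[metrics[0]])
    for metric in metrics:
        for system in systems:
            if system not in cells[metric]:
                raise ValidationError(
                    f"missing report cell for system {system!r}, "
                    f"metric {metric!r}"
                )
        extra = set(cells[metric]) - set(systems)
        if extra:
            raise ValidationError(
                f"metric {metric!r} has systems {sorted(extra)} absent from "
                f"the first metric row"
            )
    flat = {
        (metric, system): float(cells[metric][system])
        for metric in metrics
        for system in systems
    }
    average_row: dict[str, float] = {}
    for system in systems:
        values = [flat[(metric, system)] for metric in metrics]
        if rounding == "from_rounded_cells":
            rounded = [round_half_up(v) for v in values]
            average_row[system] = round_half_up(sum(rounded) / len(rounded))
        else:
            average_row[system] = sum(values) / len(values)
    meta = {
        "rounding": rounding,
        "score_component": "fmeasure",
        "skip_bigram_max_gap": SKIP_BIGRAM_MAX_GAP,
        "p_value_convention": "two-sided, |perm| >= |obs|, add-one smoothing",
    }
    if metadata:
        meta.update(metadata)
    return ReportTable(
        metrics=metrics,
        systems=systems,
        cells=flat,
        average_row=average_row,
        rounding=rounding,
        metadata=meta,
    )


def build_report(
    surface: Sequence[SelfRougeResult] = (),
    semantic: Sequence[SemanticDiversityResult] = (),
    rounding: str = "from_unrounded",
    metadata: Mapping[str, object] | None = None,
) -> ReportTable:
    """Assemble the diversity grid from self-ROUGE and semantic results.

    Surface rows are keyed by ROUGE variant, semantic rows by embedder id;
    columns are systems. Every (metric, system) cell must be present.
    """
    cells: dict[str, dict[str, float]] = {}
    for res in surface:
        cells.setdefault(res.variant, {})[res.system_id] = res.value
    for res in semantic:
        cells.setdefault(f"semantic:{res.embedder_id}", {})[
            res.system_id
        ] = res.value
    if not cells:
        raise ValidationError("no results supplied to build_report")
    systems = sorted({s for row in cells.values() for s in row})
    for metric, row in cells.items():
        for system in systems:
            if system not in row:
                raise ValidationError(
                    f"missing report cell for system {system!r}, "
                    f"metric {metric!r}"
                )
    return build_report_from_cells(cells, rounding=rounding, metadata=metadata)
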