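"""Range analysis for orthogonal (Taguchi) experiments.

For a balanced orthogonal design, the level mean ``k_ij`` of factor *j* at
level *i* is the mean response over the runs where that factor sits at that
level, and the range ``R_j = max_i k_ij - min_i k_ij`` measures how strongly
the factor moves the response.  Factors are ranked by R, and the optimal
setting takes, per factor, the level with the largest mean (the response here
is a yield — bigger is better).

Also provides the specific-fluorescence transform (cellular fluorescence
normalised by OD600 biomass) used as the response variable when optimising
sfGFP induction conditions, and the L9(3^4) induction design — factors:
induction start time IT (h), IPTG amount IA (mmol/L), and the DO-stat feed
start/stop threshold pair SSH (%/%) — shipped with the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OrthogonalDesign",
    "RangeAnalysisResult",
    "UnbalancedDesignError",
    "level_means",
    "ranges",
    "rank_and_optimize",
    "range_analysis",
    "specific_fluorescence",
    "percent_change",
    "load_design_csv",
    "sfgfp_induction_design",
]

RESPONSE_COLUMN = "response"


class UnbalancedDesignError(ValueError):
    """Raised when some level of a factor appears an unequal number of times."""


@dataclass
class OrthogonalDesign:
    """Runs of an orthogonal experiment: factor level assignments + response.

    ``runs`` holds one row per experimental run with one column per factor and
    a ``response`` column.  Unassigned array columns are simply omitted (the
    L9(3^4) array has a spare fourth column that the induction study left
    empty).
    """

    runs: pd.DataFrame

    def __post_init__(self) -> None:
        if RESPONSE_COLUMN not in self.runs.columns:
            raise ValueError(f"design needs a {RESPONSE_COLUMN!r} column")
        if not np.isfinite(self.runs[RESPONSE_COLUMN]).all():
            raise ValueError("responses must be finite")
        if not self.factors:
            raise ValueError("design needs at least one factor column")

    @property
    def factors(self) -> list[str]:
        return [c for c in self.runs.columns if c != RESPONSE_COLUMN]

    def check_balanced(self) -> None:
        for f in self.factors:
            counts = self.runs[f].value_counts()
            if counts.nunique() != 1:
                raise UnbalancedDesignError(
                    f"factor {f!r} is unbalanced: level counts {dict(counts)}"
                )


def level_means(design: OrthogonalDesign) -> pd.Series:
    """Level means k_ij as a Series indexed by (factor, level).

    Levels may be numeric (IT hours, IA mmol/L) or categorical strings (the
    SSH threshold pair), so the table is long-form rather than a rectangular
    level-by-factor frame.
    """
    design.check_balanced()
    resp = design.runs[RESPONSE_COLUMN]
    parts = []
    for f in design.factors:
        k = resp.groupby(design.runs[f]).mean()
        k.index = pd.MultiIndex.from_product([[f], k.index], names=["factor", "level"])
        parts.append(k)
    k = pd.concat(parts)
    k.name = "k"
    return k


def ranges(k_table: pd.Series) -> pd.Series:
    """Range R_j = max_i k_ij - min_i k_ij per factor."""
    grouped = k_table.groupby(level="factor", sort=False)
    r = grouped.max() - grouped.min()
    r.name = "R"
    return r


@dataclass
class RangeAnalysisResult:
    """Level means, ranges, importance ranking and optimal levels."""

    level_means: pd.Series
    ranges: pd.Series
    factor_ranking: list[str]
    optimal_levels: dict[str, object]

    def summary(self) -> str:
        lines = ["Orthogonal-design range analysis", "=" * 34]
        with pd.option_context("display.float_format", "{:.4g}".format):
            lines.append("level means k_ij:")
            lines.append(self.level_means.to_string())
            lines.append("")
            lines.append("ranges R_j:")
            lines.append(self.ranges.to_string())
        lines.append("")
        lines.append("factor importance: " + " > ".join(self.factor_ranking))
        opt = ", ".join(f"{f}={v}" for f, v in self.optimal_levels.items())
        lines.append(f"optimal levels:    {opt}")
        return "\n".join(lines)


def rank_and_optimize(
    k_table: pd.Series, r: pd.Series | None = None
) -> tuple[list[str], dict[str, object]]:
    """Factors sorted by R descending; per factor, the level with maximal mean.

    Ties (equal means within a factor, or equal ranges) are broken toward the
    lowest level index / first factor, with a warning.
    """
    if r is None:
        r = ranges(k_table)
    factors = list(r.index)
    order = sorted(factors, key=lambda f: (-r[f], factors.index(f)))
    if r.duplicated().any():
        warnings.warn("tied ranges: factor ranking order is by column position")
    optimal: dict[str, object] = {}
    for f in factors:
        col = k_table.loc[f]
        winners = col.index[col == col.max()]
        if len(winners) > 1:
            warnings.warn(
                f"factor {f!r}: tied optimal levels {list(winners)}; taking the first"
            )
        optimal[f] = winners[0]
    return order, optimal


def range_analysis(design: OrthogonalDesign) -> RangeAnalysisResult:
    """Full range analysis of a balanced orthogonal design."""
    k = level_means(design)
    r = ranges(k)
    ranking, optimal = rank_and_optimize(k, r)
    return RangeAnalysisResult(k, r, ranking, optimal)


def specific_fluorescence(cellular_flu: float, od600: float) -> float:
    """Cellular fluorescence intensity per unit biomass (OD600)."""
    if od600 <= 0:
        raise ValueError("od600 must be > 0")
    return cellular_flu / od600


def percent_change(a: float, b: float) -> float:
    """Relative change of ``a`` versus reference ``b``, in percent."""
    if b <= 0:
        raise ValueError("reference value must be > 0")
    return (a - b) / b * 100.0


def load_design_csv(path: str | Path) -> OrthogonalDesign:
    """Read a design from CSV: one row per run, factor columns + ``response``."""
    df = pd.read_csv(path)
    return OrthogonalDesign(df)


def sfgfp_induction_design() -> OrthogonalDesign:
    """The packaged L9(3^4) sfGFP-induction design with measured responses.

    Three factors over nine fermentation batches: induction start time IT
    (10/15/20 h), IPTG amount IA (0.1/0.3/0.5 mmol/L) and the feed start/stop
    threshold pair SSH (15/10, 30/25 or 50/45 %/%); the response is the final
    specific fluorescence intensity (au).
    """
    with resources.files("neurostat").joinpath("data/table1.csv").open() as fh:
        df = pd.read_csv(fh)
    batches = df.pop("batch")
    design = OrthogonalDesign(df)
    design.runs.index = batches
    return design
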