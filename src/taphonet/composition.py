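"""Relative-abundance composition and taphonomic-grade summaries.

Composition profiles normalise each plot's taxon counts to fractions,
exposing dominance structure (a clam-shrimp shoal plot may put >90% of
its specimens in a single OTU). Grade summaries tabulate the five
ordinal preservation grades A-E per taxon or per plot; ungraded
specimens never enter the A-E denominator but are tallied so nothing
disappears silently. Immature ("(l)") forms are kept separate from
adults of the same taxon because their preservation and habitat differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .sample_io import GRADES, AbundanceMatrix, SpecimenTable

__all__ = [
    "CompositionProfile",
    "GradeDistribution",
    "composition",
    "grade_distribution",
    "fraction_at_grades",
]


@dataclass
class CompositionProfile:
    """Per-plot proportions over taxa; columns sum to 1 for non-empty plots."""

    rank: str
    proportions: pd.DataFrame
    empty_plots: list[str] = field(default_factory=list)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.proportions.reset_index()
            .melt(id_vars=self.proportions.index.name or "taxon",
                  var_name="plot", value_name="proportion")
        )
        long.columns = ["taxon", "plot", "proportion"]
        return long


def composition(matrix: AbundanceMatrix) -> CompositionProfile:
    """Column-normalise an abundance matrix into per-plot proportions.

    All-zero plots are flagged (their column becomes NaN) rather than
    silently zero-filled.
    """
    if matrix.counts.empty:
        raise ValueError("abundance matrix has no taxa")
    totals = matrix.counts.sum(axis=0)
    empty = list(totals.index[totals == 0])
    props = matrix.counts / totals.replace(0, np.nan)
    return CompositionProfile(rank=matrix.rank, proportions=props,
                              empty_plots=empty)


def _taxon_group_labels(table: SpecimenTable, rank: str,
                        split_stage: bool) -> pd.Series:
    if rank == "otu":
        # "(l)" already distinguishes stages at OTU level
        return table.data["otu_label"]
    labels = table.data[rank]
    if split_stage:
        suffix = table.data["life_stage"].map({"adult": "", "immature": " (l)"})
        labels = labels.where(labels == "", labels + suffix)
    return labels


@dataclass
class GradeDistribution:
    """Grade A-E counts and proportions per group (taxon or plot).

    ``ungraded`` counts specimens with unknown grade per group;
    ``empty_groups`` lists groups with no graded specimen at all (these
    carry no proportion row).
    """

    grouping: str
    counts: pd.DataFrame
    proportions: pd.DataFrame
    ungraded: pd.Series
    empty_groups: list[str] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        return list(self.counts.index)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for grade in GRADES:
                rows.append({
                    "group": g, "grade": grade,
                    "count": int(self.counts.loc[g, grade]),
                    "proportion": (float(self.proportions.loc[g, grade])
                                   if g in self.proportions.index else np.nan),
                })
        return pd.DataFrame(rows)


def grade_distribution(
    table: SpecimenTable,
    grouping: str = "by_taxon_at_rank",
    rank: str = "order",
    *,
    split_stage: bool = True,
) -> GradeDistribution:
    """Tally preservation grades per taxon (at ``rank``) or per plot.

    With ``split_stage`` (default), immature forms are reported as their
    own group, suffixed ``(l)``, mirroring how the labels distinguish
    naiads/larvae from adults in the field.
    """
    if grouping not in ("by_taxon_at_rank", "by_plot"):
        raise ValueError("grouping must be 'by_taxon_at_rank' or 'by_plot'")
    df = table.data
    if grouping == "by_plot":
        labels = df["plot"]
    else:
        labels = _taxon_group_labels(table, rank, split_stage)
    keep = labels != ""
    labels, grades = labels[keep], df.loc[keep, "grade"]

    graded = grades.isin(GRADES)
    counts = (
        pd.crosstab(labels[graded], grades[graded])
        .reindex(columns=list(GRADES), fill_value=0)
    )
    order = list(dict.fromkeys(labels))
    counts = counts.reindex(order, fill_value=0).astype(np.int64)
    counts.index.name = "group"

    ungraded = (
        labels[~graded].value_counts().reindex(order, fill_value=0)
        .astype(np.int64)
    )
    totals = counts.sum(axis=1)
    empty = list(totals.index[totals == 0])
    props = counts.loc[totals > 0].div(totals[totals > 0], axis=0)
    return GradeDistribution(
        grouping=grouping, counts=counts, proportions=props,
        ungraded=ungraded, empty_groups=empty,
    )


def fraction_at_grades(
    dist: GradeDistribution, group: str, grades: Iterable[str]
) -> float:
    """Fraction of a group's graded specimens falling in a grade set.

    E.g. the share of Trichoptera adults preserved at grade A or B.
    Additive over disjoint grade sets; the full set A-E returns 1.
    """
    if group not in dist.counts.index:
        raise KeyError(f"unknown group {group!r}")
    grades = set(grades)
    bad = grades - set(GRADES)
    if bad:
        raise ValueError(f"unknown grade(s): {sorted(bad)}")
    if group not in dist.proportions.index:
        raise ValueError(f"group {group!r} has no graded specimens")
    return float(dist.proportions.loc[group, sorted(grades)].sum()) if grades else 0.0
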