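"""Read, validate and reshape specimen-level quadrat sample tables.

The unit of observation is a single fossil specimen collected from a
named excavation plot. A delimited text table (one row per specimen,
header row, CSV or TSV) is parsed into a :class:`SpecimenTable`, the
single source of truth for every downstream summary. From it,
taxon-by-plot count matrices (:class:`AbundanceMatrix`) are built at the
order, family or OTU level.

Immature individuals (naiads, larvae) are flagged in the field by a
trailing ``(l)`` token on the OTU label; they are treated as ecological
units distinct from the adults of the same taxon, so the marker is kept
in the label and additionally recorded in a ``life_stage`` field.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GRADES",
    "ParseReport",
    "SpecimenTable",
    "AbundanceMatrix",
    "parse_sample_table",
    "build_abundance_matrix",
    "filter_min_total",
]

#: The five ordinal preservation grades, best (articulated) to worst (fragments).
GRADES = ("A", "B", "C", "D", "E")

RANKS = ("order", "family", "otu")

#: Semantic fields a column map may address. Only ``plot`` and
#: ``otu_label`` are mandatory.
FIELDS = (
    "specimen_id",
    "locality",
    "plot",
    "order",
    "family",
    "otu_label",
    "grade",
    "habitat",
)

_MANDATORY = ("plot", "otu_label")

_WS_RUN = re.compile(r"\s+")
_IMMATURE_SUFFIX = re.compile(r"\(l\)$")


def _normalize_label(raw: object) -> str:
    """Trim and collapse internal whitespace; keep case as-is.

    Labels like ``"Orthophlebiidae gen. sp1."`` are fragile, so no
    case-folding is performed.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ""
    s = _WS_RUN.sub(" ", str(raw)).strip()
    return "" if s.lower() in {"nan", "none"} else s


def _locality_from_plot(plot: str) -> str:
    """Default locality: the plot id with any trailing digits stripped."""
    return re.sub(r"\d+$", "", plot) or plot


@dataclass
class ParseReport:
    """Row-level diagnostics from parsing: nothing is silently dropped."""

    n_rows: int = 0
    patched: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def n_patched(self) -> int:
        return len(self.patched)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


@dataclass
class SpecimenTable:
    """Validated specimen records.

    ``data`` has canonical columns ``specimen_id, locality, plot, order,
    family, otu_label, life_stage, grade, habitat``; unknown values are
    empty strings except ``grade``/``habitat``/``life_stage`` which use
    the literal ``"unknown"`` / ``"adult"`` defaults.
    """

    data: pd.DataFrame
    report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        dup = self.data["specimen_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate specimen_id values: "
                f"{sorted(self.data.loc[dup, 'specimen_id'].unique())[:5]}"
            )
        if (self.data["plot"] == "").any():
            raise ValueError("every specimen must carry a non-empty plot id")
        by_plot = self.data.groupby("plot", sort=False)["locality"].nunique()
        multi = by_plot[by_plot > 1]
        if len(multi):
            raise ValueError(
                f"plot(s) assigned to more than one locality: {list(multi.index)}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def plots(self) -> list[str]:
        """Plot ids in first-appearance order."""
        return list(dict.fromkeys(self.data["plot"]))

    @property
    def localities(self) -> list[str]:
        return list(dict.fromkeys(self.data["locality"]))

    def plot_counts(self) -> pd.Series:
        return self.data["plot"].value_counts().reindex(self.plots)

    def otu_to_family(self) -> dict[str, str]:
        """Map each OTU label to its (first seen) family label."""
        sub = self.data[self.data["otu_label"] != ""]
        return sub.groupby("otu_label", sort=False)["family"].first().to_dict()

    def otu_to_order(self) -> dict[str, str]:
        sub = self.data[self.data["otu_label"] != ""]
        return sub.groupby("otu_label", sort=False)["order"].first().to_dict()


@dataclass
class AbundanceMatrix:
    """Nonnegative integer taxon-by-plot counts at one taxonomic rank.

    ``counts`` is a DataFrame indexed by taxon label with one column per
    plot. Specimens whose label at the chosen rank is unknown are
    excluded from the matrix and tallied in ``n_excluded`` — they remain
    in the originating :class:`SpecimenTable`.
    """

    rank: str
    counts: pd.DataFrame
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"rank must be one of {RANKS}, got {self.rank!r}")
        arr = self.counts.to_numpy()
        if arr.size and ((arr < 0).any() or not np.issubdtype(arr.dtype, np.integer)):
            raise ValueError("abundance counts must be nonnegative integers")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def plots(self) -> list[str]:
        return list(self.counts.columns)

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def pooled(self) -> pd.Series:
        """Counts pooled over all plots (one entry per taxon)."""
        return self.row_totals()

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_csv(self, path_or_buf) -> None:
        self.counts.to_csv(path_or_buf, index_label=self.rank)


def parse_sample_table(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
) -> SpecimenTable:
    """Parse a delimited specimen table into a :class:`SpecimenTable`.

    Parameters
    ----------
    source:
        Path or open text stream; must have a header row. Comma and tab
        delimiters are auto-detected unless ``delimiter`` is given.
    column_map:
        Maps semantic field names (see :data:`FIELDS`) to the header
        names actually used in the file. Must cover at least ``plot``
        and ``otu_label``; identity mapping by default.

    Rows with a missing grade are retained with ``grade="unknown"`` and
    noted in the parse report. A trailing ``(l)`` token on the OTU label
    sets ``life_stage="immature"`` and stays part of the label, so
    immatures and adults count as distinct OTUs.
    """
    column_map = dict(column_map or {})
    for fld in column_map:
        if fld not in FIELDS:
            raise ValueError(f"unknown semantic field {fld!r} in column_map")

    if isinstance(source, (str,)) and "\n" not in source:
        raw = pd.read_csv(source, sep=delimiter, engine="python", dtype=str)
    else:
        buf = io.StringIO(source) if isinstance(source, str) else source
        raw = pd.read_csv(buf, sep=delimiter, engine="python", dtype=str)
    if raw.empty:
        raise ValueError("sample table contains no specimen rows")
    raw.columns = [str(c).strip() for c in raw.columns]

    def col(fieldname: str) -> str | None:
        name = column_map.get(fieldname, fieldname)
        return name if name in raw.columns else None

    for fld in _MANDATORY:
        if col(fld) is None:
            raise ValueError(
                f"mandatory column for field {fld!r} "
                f"(header {column_map.get(fld, fld)!r}) is missing"
            )

    report = ParseReport(n_rows=len(raw))
    out = pd.DataFrame(index=raw.index)

    for fld in ("plot", "order", "family", "otu_label", "locality"):
        c = col(fld)
        out[fld] = raw[c].map(_normalize_label) if c else ""

    c = col("specimen_id")
    if c:
        out["specimen_id"] = raw[c].map(_normalize_label)
    else:
        out["specimen_id"] = [f"s{i + 1}" for i in range(len(raw))]

    if col("locality") is None:
        out["locality"] = out["plot"].map(_locality_from_plot)
    else:
        blank = out["locality"] == ""
        out.loc[blank, "locality"] = out.loc[blank, "plot"].map(_locality_from_plot)

    c = col("grade")
    grades = raw[c].map(_normalize_label).str.upper() if c else pd.Series("", index=raw.index)
    bad = ~grades.isin(GRADES)
    for idx in out.index[bad & (grades != "")]:
        report.patched.append(
            f"row {idx}: unrecognized grade {grades[idx]!r} set to unknown"
        )
    for idx in out.index[grades == ""]:
        report.patched.append(f"row {idx}: missing grade set to unknown")
    out["grade"] = grades.where(~bad, "unknown")

    c = col("habitat")
    if c:
        hab = raw[c].map(_normalize_label).str.lower()
        out["habitat"] = hab.where(hab.isin(["aquatic", "terrestrial"]), "unknown")
    else:
        out["habitat"] = "unknown"

    out["life_stage"] = np.where(
        out["otu_label"].str.contains(_IMMATURE_SUFFIX), "immature", "adult"
    )

    # rows without a plot or OTU label cannot be placed anywhere: skip, loudly
    unusable = (out["plot"] == "") | (out["otu_label"] == "")
    for idx in out.index[unusable]:
        report.skipped.append(f"row {idx}: empty plot or otu_label, row skipped")
    out = out[~unusable].reset_index(drop=True)
    if out.empty:
        raise ValueError("sample table contains no usable specimen rows")

    cols = ["specimen_id", "locality", "plot", "order", "family",
            "otu_label", "life_stage", "grade", "habitat"]
    return SpecimenTable(out[cols], report)


def build_abundance_matrix(table: SpecimenTable, rank: str = "otu") -> AbundanceMatrix:
    """Count specimens per taxon (at ``rank``) per plot.

    Specimens whose label at that rank is unknown/empty are excluded
    from the matrix and reported in ``n_excluded``; they are never
    removed from the table itself.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    label_col = "otu_label" if rank == "otu" else rank
    df = table.data
    known = df[label_col] != ""
    sub = df[known]
    counts = (
        pd.crosstab(sub[label_col], sub["plot"])
        .reindex(columns=table.plots, fill_value=0)
    )
    # preserve first-appearance order of taxa
    order = list(dict.fromkeys(sub[label_col]))
    counts = counts.reindex(order)
    counts.index.name = rank
    return AbundanceMatrix(
        rank=rank,
        counts=counts.astype(np.int64),
        n_excluded=int((~known).sum()),
    )


def filter_min_total(
    matrix: AbundanceMatrix,
    min_total: int,
    keep_list: Iterable[str] | None = None,
) -> AbundanceMatrix:
    """Keep taxa whose pooled count is *strictly greater* than ``min_total``.

    If ``keep_list`` is given (e.g. a curated aquatic-OTU list) the
    matrix is first restricted to those taxa, then the abundance filter
    is applied.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    counts = matrix.counts
    if keep_list is not None:
        keep = set(keep_list)
        counts = counts.loc[[t for t in counts.index if t in keep]]
    mask = counts.sum(axis=1) > min_total
    kept = counts.loc[mask]
    if kept.empty:
        raise ValueError(
            f"no taxa exceed min_total={min_total}; relax the threshold "
            "or widen the keep list"
        )
    return AbundanceMatrix(rank=matrix.rank, counts=kept.copy(),
                           n_excluded=matrix.n_excluded)
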