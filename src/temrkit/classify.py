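"""TEMR categorization: intersect SV breakpoints with the TE annotation.

An SV is a transposable element-mediated rearrangement (TEMR) when its two
breakpoints fall inside *different* TE copies of the *same* element class
(RepeatMasker family level: Alu, L1/LINE-1, ERVL-MaLR, ...).  SVs with zero
or one breakpoint in a TE, with both breakpoints in the same single copy,
or in TEs of different classes are non-TEMR.  The orientation class is
``direct`` when the two copies share a strand and ``inverted`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "BreakpointTE",
    "TEAnnotationIndex",
    "assign_breakpoint_te",
    "classify_temr",
    "classify_callset",
    "summarize_callset",
]


@dataclass
class BreakpointTE:
    """The TE copy containing one SV breakpoint."""

    te_id: str
    family: str
    subfamily: str
    strand: str
    offset: int          # bp from the TE's genomic start
    te_start: int
    te_end: int
    cons_start: int
    cons_end: int
    ambiguous: bool = False   # overlapping annotations at the position

    @property
    def length(self) -> int:
        return self.te_end - self.te_start


class TEAnnotationIndex:
    """Interval index over a TE annotation table for point queries."""

    def __init__(self, annotation: pd.DataFrame):
        self.annotation = annotation
        self._trees: dict[str, IntervalTree] = {}
        for row in annotation.itertuples():
            self._trees.setdefault(row.chrom, IntervalTree()).addi(
                row.start, row.end, row.Index)

    def query(self, chrom: str, pos: int) -> BreakpointTE | None:
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos]
        if not hits:
            return None
        # nested annotations resolve to the smallest containing element
        best = min(hits, key=lambda iv: (iv.end - iv.begin, iv.begin))
        row = self.annotation.loc[best.data]
        return BreakpointTE(
            te_id=row.copy_id, family=row.family, subfamily=row.subfamily,
            strand=row.strand, offset=pos - int(row.start),
            te_start=int(row.start), te_end=int(row.end),
            cons_start=int(row.get("cons_start", 0)),
            cons_end=int(row.get("cons_end", row.end - row.start)),
            ambiguous=len(hits) > 1,
        )


def assign_breakpoint_te(chrom: str, pos: int, annotation) -> BreakpointTE | None:
    """TE copy whose half-open interval contains the breakpoint, or None."""
    index = annotation if isinstance(annotation, TEAnnotationIndex) else TEAnnotationIndex(annotation)
    return index.query(chrom, pos)


def classify_temr(sv, te5: BreakpointTE | None, te3: BreakpointTE | None):
    """(is_temr, family, orientation_class) for one SV given its breakpoint TEs."""
    if te5 is None or te3 is None:
        return False, None, None
    if te5.te_id == te3.te_id:
        return False, None, None          # both ends inside one and the same copy
    if te5.family != te3.family:
        return False, None, None
    orientation = "direct" if te5.strand == te3.strand else "inverted"
    return True, te5.family, orientation


def classify_callset(merged: pd.DataFrame, annotation) -> pd.DataFrame:
    """Annotate a merged callset with TEMR status, family and orientation.

    The 5' breakpoint is the record's start, the 3' breakpoint its end
    (outer coordinates), matching deletion/duplication junction geometry;
    inversion endpoints are used as-is.
    """
    index = annotation if isinstance(annotation, TEAnnotationIndex) else TEAnnotationIndex(annotation)
    rows = []
    for sv in merged.itertuples(index=False):
        te5 = index.query(sv.chrom, sv.start)
        te3 = index.query(sv.chrom, sv.end)
        is_temr, family, orientation = classify_temr(sv, te5, te3)
        row = sv._asdict()
        row.update({
            "is_temr": is_temr,
            "te_family": family,
            "orientation_class": orientation,
            "te5_id": te5.te_id if te5 else None,
            "te3_id": te3.te_id if te3 else None,
            "te5_strand": te5.strand if te5 else None,
            "te3_strand": te3.strand if te3 else None,
            "te5_subfamily": te5.subfamily if te5 else None,
            "te3_subfamily": te3.subfamily if te3 else None,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_callset(classified: pd.DataFrame) -> dict:
    """Cohort summary: TEMR fraction, counts by family/type/orientation, sizes.

    Percentages are 100*count/total rounded to two decimals (printed to one
    decimal in reports).
    """
    total = len(classified)
    temrs = classified[classified.is_temr]
    sizes = temrs.end - temrs.start
    by_family = temrs.groupby("te_family").size().to_dict() if len(temrs) else {}
    by_type = temrs.groupby("sv_type").size().to_dict() if len(temrs) else {}
    by_orientation = temrs.groupby("orientation_class").size().to_dict() if len(temrs) else {}
    cross = (temrs.groupby(["te_family", "sv_type", "orientation_class"]).size()
             .reset_index(name="n").to_dict("records")) if len(temrs) else []
    return {
        "n_sv": total,
        "n_temr": int(len(temrs)),
        "temr_percent": round(100.0 * len(temrs) / total, 2) if total else 0.0,
        "by_family": by_family,
        "by_sv_type": by_type,
        "by_orientation": by_orientation,
        "by_family_type_orientation": cross,
        "median_temr_size": float(sizes.median()) if len(temrs) else None,
        "median_size_by_family": {k: float(v) for k, v in
                                  temrs.groupby("te_family")
                                  .apply(lambda d: (d.end - d.start).median(),
                                         include_groups=False).items()} if len(temrs) else {},
    }
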