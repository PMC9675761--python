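"""SV filtering and ensemble merging by reciprocal overlap with caller ranks.

Per-caller callsets are first filtered (size, proximity to assembly gaps /
centromeres, simple-repeat content, read support, depth ratio), then merged
into a nonredundant consensus: calls of the same type whose pairwise
reciprocal overlap (RO) reaches the threshold are clustered by single
linkage, and each cluster is represented by the coordinates of the
highest-ranking caller (short-read rank Manta > DELLY > LUMPY; long-read
pbsv > Sniffles > SVIM).  A record enters the high-confidence set when it
has within-technology consensus (>= 2 callers) in either technology, or
cross-technology support (an SRS and an LRS record at RO >= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "filter_calls",
    "reciprocal_overlap",
    "merge_by_rank",
    "merge_across_samples",
    "curate_duplications",
]

SV_TYPES = ("DEL", "DUP", "INV")


@dataclass
class FilterConfig:
    """Thresholds of the filtering/merging funnel."""

    min_size: int = 50
    max_size: int = 50_000
    exclusion_buffer: int = 500
    simple_repeat_overlap: float = 0.5
    sr_min: int = 5
    pr_min: int = 10
    rs_min: int = 5
    rd_del_max: float = 0.7
    rd_dup_min: float = 1.3
    ro_threshold: float = 0.8
    caller_rank: dict = field(default_factory=lambda: {
        "SRS": ["Manta", "DELLY", "LUMPY"],
        "LRS": ["pbsv", "Sniffles", "SVIM"],
    })
    min_callers: int = 2          # within-technology consensus requirement
    prefer_technology: str = "SRS"  # coordinate source when both technologies agree

    def __post_init__(self):
        if not 0 < self.ro_threshold <= 1:
            raise ValueError("ro_threshold must be in (0, 1]")
        if self.min_size > self.max_size:
            raise ValueError("min_size must not exceed max_size")

    def rank_of(self, technology: str, caller: str) -> int:
        order = self.caller_rank.get(technology, [])
        return order.index(caller) if caller in order else len(order)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)) for two half-open intervals."""
    (a0, a1), (b0, b1) = a, b
    if a1 <= a0 or b1 <= b0:
        raise ValueError("zero-length interval")
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return min(ov / (a1 - a0), ov / (b1 - b0))


def _coverage_fraction(start: int, end: int, regions) -> float:
    """Fraction of [start, end) covered by the (possibly overlapping) regions."""
    ivs = sorted((max(start, s), min(end, e)) for _, s, e in regions)
    covered, cur_s, cur_e = 0, None, None
    for s, e in ivs:
        if e <= s:
            continue
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / (end - start)


def _region_index(regions):
    """chrom -> sorted interval list from an iterable/DataFrame of BED rows."""
    idx: dict[str, list] = {}
    if regions is None:
        return idx
    if isinstance(regions, pd.DataFrame):
        it = regions[["chrom", "start", "end"]].itertuples(index=False)
    else:
        it = regions
    for chrom, s, e in it:
        idx.setdefault(chrom, []).append((chrom, int(s), int(e)))
    for v in idx.values():
        v.sort(key=lambda r: r[1])
    return idx


def filter_calls(calls: pd.DataFrame, exclusion_regions=None, simple_repeats=None,
                 cfg: FilterConfig | None = None):
    """Apply the SV filter funnel; returns (retained, rejected-with-reason).

    Retained calls satisfy, in this order of precedence for the logged
    reason: known type (DEL/DUP/INV); size within [min_size, max_size];
    neither breakpoint within ``exclusion_buffer`` of an exclusion region;
    less than ``simple_repeat_overlap`` of the span covered by simple
    repeats; read support (SR >= 5 or PR >= 10 for short reads, RS >= 5 for
    long reads); depth ratio (RD < 0.7 for DEL, RD > 1.3 for DUP; not
    applied to copy-neutral INV).
    """
    cfg = cfg or FilterConfig()
    excl = _region_index(exclusion_regions)
    srs = _region_index(simple_repeats)
    reasons = []
    for row in calls.itertuples(index=False):
        size = row.end - row.start
        reason = None
        if row.sv_type not in SV_TYPES:
            reason = "bad_type"
        elif size < cfg.min_size:
            reason = "size_min"
        elif size > cfg.max_size:
            reason = "size_max"
        elif any(
            s - cfg.exclusion_buffer < bp < e + cfg.exclusion_buffer
            for bp in (row.start, row.end)
            for _, s, e in excl.get(row.chrom, [])
        ):
            reason = "exclusion_proximity"
        elif row.chrom in srs and _coverage_fraction(
                row.start, row.end, srs[row.chrom]) >= cfg.simple_repeat_overlap:
            reason = "simple_repeat_overlap"
        else:
            if row.technology == "SRS":
                sr = -1 if pd.isna(row.SR) else row.SR
                pr = -1 if pd.isna(row.PR) else row.PR
                if not (sr >= cfg.sr_min or pr >= cfg.pr_min):
                    reason = "support"
            else:
                rs = -1 if pd.isna(row.RS) else row.RS
                if not rs >= cfg.rs_min:
                    reason = "support"
            if reason is None and not pd.isna(row.RD):
                if row.sv_type == "DEL" and not row.RD < cfg.rd_del_max:
                    reason = "depth"
                elif row.sv_type == "DUP" and not row.RD > cfg.rd_dup_min:
                    reason = "depth"
        reasons.append(reason)
    reasons = pd.Series(reasons, index=calls.index, dtype=object)
    retained = calls[reasons.isna()].reset_index(drop=True)
    rejected = calls[reasons.notna()].copy()
    rejected["reason"] = reasons[reasons.notna()]
    return retained, rejected.reset_index(drop=True)


def _cluster_by_ro(df: pd.DataFrame, ro: float):
    """Single-linkage clusters of same-chrom/type calls at RO >= threshold.

    Returns a list of index lists (positions into df).  A sorted sweep keeps
    it near-linear for well-separated calls.
    """
    parent = list(range(len(df)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    order = np.lexsort((df["start"].to_numpy(), df["chrom"].to_numpy()))
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    chroms = df["chrom"].to_numpy()
    types = df["sv_type"].to_numpy()
    active: list[int] = []
    for oi in order:
        i = int(oi)
        active = [j for j in active if ends[j] > starts[i] and chroms[j] == chroms[i]]
        for j in active:
            if types[j] != types[i] or chroms[j] != chroms[i]:
                continue
            if reciprocal_overlap((starts[i], ends[i]), (starts[j], ends[j])) >= ro:
                union(i, j)
        active.append(i)
    clusters: dict[int, list[int]] = {}
    for i in range(len(df)):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def _representative(df: pd.DataFrame, members, cfg: FilterConfig):
    """Highest-ranked caller's record; ties broken by smaller start, then end."""
    sub = df.iloc[members]
    keys = [
        (cfg.rank_of(r.technology, r.caller), r.start, r.end)
        for r in sub.itertuples(index=False)
    ]
    return members[min(range(len(members)), key=keys.__getitem__)]


def merge_by_rank(calls: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Merge filtered per-caller calls into a high-confidence consensus set.

    ``calls`` holds all callers' (already filtered) records for one sample,
    both technologies.  Within each technology, RO clusters collapse to the
    highest-ranked caller's coordinates with the full supporter list; the
    final set keeps records with within-technology consensus (>= 2 callers)
    in either technology or cross-technology RO support.  When both
    technologies retain the same event, the preferred technology's
    coordinates (default SRS, whose top-ranked caller carries the most
    precise junctions) are kept.
    """
    cfg = cfg or FilterConfig()
    if calls.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "sv_type", "caller",
                                     "technology", "sample", "supporters", "n_callers",
                                     "cross_tech"])
    def _supporters(sub, members):
        out = set()
        for _, row in sub.iloc[members].iterrows():
            prior = row.get("supporters")
            if isinstance(prior, str) and prior:
                out.update(prior.split(","))
            else:
                out.add(row["caller"])
        return sorted(out)

    reps = []
    for tech in ("SRS", "LRS"):
        sub = calls[calls.technology == tech].reset_index(drop=True)
        if sub.empty:
            continue
        for members in _cluster_by_ro(sub, cfg.ro_threshold):
            callers = _supporters(sub, members)
            best = _representative(sub, members, cfg)
            rec = sub.iloc[best].to_dict()
            rec["supporters"] = ",".join(callers)
            rec["n_callers"] = len(callers)
            rec["cross_tech"] = (bool(sub.iloc[members]["cross_tech"].any())
                                 if "cross_tech" in sub.columns else False)
            reps.append(rec)
    rep_df = pd.DataFrame(reps)

    # cross-technology support at RO >= threshold, same type
    cross = np.zeros(len(rep_df), dtype=bool)
    tech = rep_df["technology"].to_numpy()
    chrom = rep_df["chrom"].to_numpy()
    svt = rep_df["sv_type"].to_numpy()
    start = rep_df["start"].to_numpy()
    end = rep_df["end"].to_numpy()
    srs_idx = np.flatnonzero(tech == "SRS")
    lrs_idx = np.flatnonzero(tech == "LRS")
    for i in srs_idx:
        for j in lrs_idx:
            if chrom[i] != chrom[j] or svt[i] != svt[j]:
                continue
            if reciprocal_overlap((start[i], end[i]), (start[j], end[j])) >= cfg.ro_threshold:
                cross[i] = cross[j] = True
    rep_df["cross_tech"] = cross | rep_df["cross_tech"].to_numpy(dtype=bool)

    keep = (rep_df["n_callers"] >= cfg.min_callers) | rep_df["cross_tech"]
    kept = rep_df[keep].reset_index(drop=True)

    # deduplicate the same event found by both technologies: cluster again and
    # retain the preferred technology's coordinates
    out_rows = []
    for members in _cluster_by_ro(kept, cfg.ro_threshold):
        sub = kept.iloc[members]
        pref = sub[sub.technology == cfg.prefer_technology]
        row = (pref.iloc[0] if not pref.empty else sub.iloc[0]).to_dict()
        row["supporters"] = ",".join(sorted(set(
            c for s in sub["supporters"] for c in s.split(","))))
        row["n_callers"] = len(row["supporters"].split(","))
        row["cross_tech"] = bool(sub["cross_tech"].any()) or sub["technology"].nunique() > 1
        out_rows.append(row)
    out = pd.DataFrame(out_rows)
    return out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def merge_across_samples(per_sample: dict[str, pd.DataFrame],
                         cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Nonredundant union across samples with per-sample carrier flags.

    Records clustering at RO >= threshold collapse to one row that keeps the
    coordinates contributed by the first sample in lexicographic order;
    ``carriers`` lists every sample supporting the cluster.
    """
    cfg = cfg or FilterConfig()
    frames = []
    for sample in sorted(per_sample):
        df = per_sample[sample].copy()
        df["sample"] = sample
        frames.append(df)
    allc = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if allc.empty:
        return allc
    rows = []
    for members in _cluster_by_ro(allc, cfg.ro_threshold):
        sub = allc.iloc[members].sort_values(["sample", "start", "end"])
        row = sub.iloc[0].to_dict()
        row["carriers"] = ",".join(sorted(set(sub["sample"])))
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def curate_duplications(duplications: pd.DataFrame, insertions: pd.DataFrame,
                        window: int = 500, size_match: float = 0.9) -> pd.DataFrame:
    """Validate duplications against assembly insertion calls.

    A duplication is kept iff an insertion falls inside the duplication span
    extended by ``window`` on both sides and the two sizes agree at
    ``size_match`` (min/max >= 0.9).  ``insertions`` needs chrom, position
    (``start``) and inserted-sequence ``length`` columns.
    """
    validated = []
    for d in duplications.itertuples(index=False):
        dup_len = d.end - d.start
        ok = False
        for ins in insertions.itertuples(index=False):
            if ins.chrom != d.chrom:
                continue
            if not (d.start - window <= ins.start <= d.end + window):
                continue
            ins_len = int(ins.length)
            if min(dup_len, ins_len) / max(dup_len, ins_len) >= size_match:
                ok = True
                break
        validated.append(ok)
    return duplications[pd.Series(validated, index=duplications.index)].reset_index(drop=True)
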