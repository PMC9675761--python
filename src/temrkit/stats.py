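"""Enrichment and association statistics for TEMR callsets.

Thin, explicit wrappers around scipy's exact/asymptotic tests (Welch's
unequal-variance t, exact two-tailed binomial, Fisher's exact, Spearman)
plus the genomic summary statistics used alongside them: TE density in
50 kbp windows with rejection-sampled random-window controls, GC content,
event density over callable regions, read-depth copy-number estimation for
multi-copy CNVs, ancestral deletion/insertion size matching, and genic
annotation of events against a simple gene model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._seq import as_rng

__all__ = [
    "welch_t",
    "binom_two_tailed",
    "fisher_exact_2x2",
    "spearman",
    "gc_content",
    "te_density",
    "sample_control_windows",
    "callable_density",
    "depth_copy_number",
    "match_ancestral",
    "annotate_genic",
    "genic_enrichment",
    "DepthProfile",
]


def welch_t(x, y):
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, Welch-Satterthwaite df, p).  Two identical constant samples
    are a degenerate case reported as (0.0, nan, 1.0) with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per sample")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.all(x == y[0]) and np.all(y == y[0]):
            return {"t": 0.0, "df": float("nan"), "p": 1.0, "degenerate_variance": True}
    res = sps.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue),
            "degenerate_variance": False}


def binom_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial p-value (small point-probability method).

    Sums the probabilities of all outcomes whose point probability does not
    exceed that of the observed count.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be within [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(min(1.0, sps.binomtest(k, n, p0).pvalue))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact p for the table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def spearman(x, y):
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, p); constant input is flagged as undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) != len(x):
        raise ValueError("need paired samples of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": float("nan"), "p": float("nan"), "undefined": True}
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "undefined": False}


def gc_content(seq: str) -> float:
    """GC percent of a DNA string."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


# ---------------------------------------------------------------------------
# TE density


def _family_intervals(te_annotation: pd.DataFrame, family: str, chrom: str):
    sub = te_annotation[(te_annotation.family == family) & (te_annotation.chrom == chrom)]
    return sub[["start", "end"]].to_numpy(int)


def _covered_bp(ivs: np.ndarray, lo: int, hi: int) -> int:
    if len(ivs) == 0:
        return 0
    s = np.clip(ivs[:, 0], lo, hi)
    e = np.clip(ivs[:, 1], lo, hi)
    return int(np.maximum(0, e - s).sum())


def te_density(sv, te_annotation: pd.DataFrame, family: str, window: int = 50_000,
               genome_sizes: dict | None = None) -> float:
    """Percent of family TE sequence in the window centred on the SV midpoint.

    The window spans window/2 on either side of the SV centre and is clipped
    at chromosome ends with the denominator renormalized to the evaluated
    length.
    """
    chrom, mid = sv[0], (int(sv[1]) + int(sv[2])) // 2
    size = (genome_sizes or {}).get(chrom)
    if size is not None and not 0 <= mid <= size:
        raise ValueError("SV midpoint off the chromosome")
    lo = max(0, mid - window // 2)
    hi = mid + window // 2
    if size is not None:
        hi = min(hi, size)
    ivs = _family_intervals(te_annotation, family, chrom)
    if hi <= lo:
        raise ValueError("degenerate window")
    return 100.0 * _covered_bp(ivs, lo, hi) / (hi - lo)


def sample_control_windows(n: int, genome_sizes: dict, te_annotation: pd.DataFrame,
                           family: str, window: int = 50_000, min_te_count: int = 2,
                           seed=0, max_iter_factor: int = 1000):
    """Densities of n random windows containing >= min_te_count family TEs.

    Rejection sampling over uniformly placed windows; deterministic under
    ``seed``.  Raises after ``max_iter_factor * n`` draws without filling the
    quota (genome too TE-poor for the constraint).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(seed)
    chroms = sorted(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    by_chrom = {c: _family_intervals(te_annotation, family, c) for c in chroms}
    out = []
    tries = 0
    cap = max_iter_factor * n
    while len(out) < n:
        tries += 1
        if tries > cap:
            raise RuntimeError(
                f"control-window sampling exhausted {cap} draws; "
                f"{len(out)}/{n} windows found with >= {min_te_count} {family} TEs")
        ci = int(rng.choice(len(chroms), p=probs))
        chrom = chroms[ci]
        if genome_sizes[chrom] <= window:
            continue
        lo = int(rng.integers(0, genome_sizes[chrom] - window))
        hi = lo + window
        ivs = by_chrom[chrom]
        if len(ivs) == 0:
            continue
        inside = (ivs[:, 0] < hi) & (ivs[:, 1] > lo)
        if int(inside.sum()) < min_te_count:
            continue
        out.append(100.0 * _covered_bp(ivs, lo, hi) / window)
    return out


def callable_density(events: pd.DataFrame, callable_regions: pd.DataFrame,
                     per: float = 1e7) -> dict:
    """Event density per ``per`` bp of callable sequence.

    Only events whose midpoint falls in callable space count.  Returns
    per-chromosome and genome-wide densities.
    """
    if callable_regions is None or callable_regions.empty:
        raise ValueError("empty callable region set")
    result = {}
    total_events = 0
    total_bp = 0
    for chrom, sub in callable_regions.groupby("chrom"):
        ivs = sub[["start", "end"]].to_numpy(int)
        bp = int((ivs[:, 1] - ivs[:, 0]).sum())
        ev = events[events.chrom == chrom]
        mids = ((ev.start + ev.end) // 2).to_numpy(int) if len(ev) else np.array([], int)
        inside = sum(bool(((ivs[:, 0] <= m) & (m < ivs[:, 1])).any()) for m in mids)
        result[chrom] = {"events": int(inside), "callable_bp": bp,
                         "density": per * inside / bp if bp else 0.0}
        total_events += inside
        total_bp += bp
    result["genome"] = {"events": total_events, "callable_bp": total_bp,
                        "density": per * total_events / total_bp if total_bp else 0.0}
    return result


@dataclass
class DepthProfile:
    """Binned per-base read depth over a genome plus its genome-wide mean."""

    bin_size: int
    depth: np.ndarray
    genome_mean: float | None = None

    def mean_over(self, start: int, end: int) -> float:
        lo = start // self.bin_size
        hi = max(lo + 1, -(-end // self.bin_size))
        return float(np.mean(self.depth[lo:hi]))


def depth_copy_number(profile: DepthProfile, locus: tuple[int, int],
                      te_annotation: pd.DataFrame | None = None,
                      chrom: str | None = None, min_unique_fraction: float = 0.07):
    """Read-depth copy number at a locus: ratio to genome mean, CN = round(2*ratio).

    The estimate is flagged ``low_unique`` when less than
    ``min_unique_fraction`` of the locus lies outside TE annotation, where
    read-depth is unreliable.
    """
    gmean = profile.genome_mean if profile.genome_mean is not None else float(np.mean(profile.depth))
    if gmean <= 0:
        raise ValueError("genome mean depth must be positive")
    start, end = locus
    ratio = profile.mean_over(start, end) / gmean
    cn = int(round(2.0 * ratio))
    low_unique = False
    if te_annotation is not None and chrom is not None:
        ivs = te_annotation[te_annotation.chrom == chrom][["start", "end"]].to_numpy(int)
        te_bp = _covered_bp(ivs, start, end)
        low_unique = (1.0 - te_bp / (end - start)) < min_unique_fraction
    return {"ratio": ratio, "copy_number": cn, "low_unique": low_unique}


def match_ancestral(deletions: pd.DataFrame, insertions: pd.DataFrame,
                    window: int, size_match: float = 0.9) -> pd.DataFrame:
    """Pair ancestral deletions with present-day insertions.

    A deletion matches an insertion when their positions fall within
    ``window`` bp (the consensus length of the mediating TE family) and the
    two sizes agree at min/max >= ``size_match``.  Both tables need chrom,
    start and a ``size`` column.
    """
    pairs = []
    for d in deletions.itertuples(index=False):
        for i in insertions.itertuples(index=False):
            if d.chrom != i.chrom:
                continue
            if abs(int(d.start) - int(i.start)) > window:
                continue
            ratio = min(d.size, i.size) / max(d.size, i.size)
            if ratio >= size_match:
                pairs.append({"del_chrom": d.chrom, "del_start": d.start, "del_size": d.size,
                              "ins_start": i.start, "ins_size": i.size,
                              "size_ratio": ratio})
    return pd.DataFrame(pairs)


def annotate_genic(events: pd.DataFrame, gene_model: pd.DataFrame,
                   proximal: int = 5000) -> pd.DataFrame:
    """Categorize events as exonic / intronic / proximal / intergenic.

    ``gene_model`` rows carry chrom, start, end, name and feature in
    {gene, exon}.  Precedence: exonic (overlaps any exon) > intronic (within
    a gene, no exon overlap) > proximal (within ``proximal`` bp of a gene) >
    intergenic.
    """
    required = {"chrom", "start", "end", "feature"}
    if not required.issubset(gene_model.columns):
        raise ValueError(f"gene model must carry columns {sorted(required)}")
    genes = gene_model[gene_model.feature == "gene"]
    exons = gene_model[gene_model.feature == "exon"]
    cats = []
    for ev in events.itertuples(index=False):
        g = genes[(genes.chrom == ev.chrom) & (genes.start < ev.end) & (ev.start < genes.end)]
        x = exons[(exons.chrom == ev.chrom) & (exons.start < ev.end) & (ev.start < exons.end)]
        if len(x):
            cats.append("exonic")
        elif len(g):
            cats.append("intronic")
        else:
            near = genes[(genes.chrom == ev.chrom)
                         & (genes.start - proximal < ev.end)
                         & (ev.start < genes.end + proximal)]
            cats.append("proximal" if len(near) else "intergenic")
    out = events.copy()
    out["genic_category"] = cats
    return out


def genic_enrichment(temr_categories, non_temr_categories) -> dict:
    """Fisher's exact test of genic (non-intergenic) status, TEMR vs non-TEMR."""
    def split(cats):
        genic = sum(c != "intergenic" for c in cats)
        return genic, len(cats) - genic

    a, b = split(temr_categories)
    c, d = split(non_temr_categories)
    return {"table": (a, b, c, d), "p": fisher_exact_2x2(a, b, c, d)}
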