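"""Mechanism inference: homologous recombination vs non-homologous repair.

For a TEMR, the two junction flanks are read in consensus orientation and
aligned to the family consensus (an Alu-family consensus for Alu TEMRs, an
L1 consensus for LINE-1 TEMRs).  Writing ``e1`` for the consensus end of
the 5' flank's alignment and ``s2`` for the consensus start of the 3'
flank's alignment, the flanks overlap by ``e1 - s2`` bases along the
consensus.  The event is called HR when the flanks overlap and the overlap
equals the junction microhomology — the chimeric element then reconstructs
a full-length TE with the microhomology at the breakpoint.  Alu events
failing that test but retaining microhomology are retried against each
~150 bp monomer separately, which recognises chimeras recombined between
homologous positions of different monomers (single-monomer and
three-monomer chimeric Alus).  Events with no microhomology whose flanks
fail to overlap along the consensus are NHE.  Everything else is emitted
as MANUAL_REVIEW with a machine-readable reason (poly-A microhomology,
truncated-element alignment, or an overlap discordant with the
microhomology) rather than silently guessed.
"""

from __future__ import annotations

from dataclasses import dataclass


from ._seq import revcomp
from .consensus import TEConsensus

__all__ = [
    "AlignScoring",
    "ConsensusAlignment",
    "MechanismCall",
    "FlankPair",
    "local_align",
    "percent_similarity",
    "extract_flanks",
    "infer_mechanism",
    "map_mh_to_consensus",
    "classify_cohort",
]


@dataclass(frozen=True)
class AlignScoring:
    """EDNAFULL-style scoring: match +5, mismatch -4, gap open 10, extend 0.5.

    A gap of length L costs ``gap_open + gap_extend*(L-1)``.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class ConsensusAlignment:
    """Best local alignment of a query flank against a consensus."""

    consensus_name: str
    consensus_span: tuple[int, int]
    query_span: tuple[int, int]
    identity_percent: float
    score: float
    strand: str = "+"
    n_columns: int = 0
    n_query: int = 0

    @property
    def query_coverage(self) -> float:
        return 0.0 if self.n_query == 0 else (self.query_span[1] - self.query_span[0]) / self.n_query


def _aligner(scoring: AlignScoring):
    from Bio import Align

    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = -scoring.gap_open
    al.extend_gap_score = -scoring.gap_extend
    return al


def local_align(query: str, consensus: str | TEConsensus,
                scoring: AlignScoring | None = None,
                consensus_name: str | None = None) -> ConsensusAlignment:
    """Smith-Waterman local alignment of ``query`` against a consensus."""
    scoring = scoring or AlignScoring()
    if isinstance(consensus, TEConsensus):
        target = consensus.sequence
        consensus_name = consensus_name or consensus.name
    else:
        target = str(consensus)
        consensus_name = consensus_name or "consensus"
    if not query or not target:
        raise ValueError("empty sequence in local alignment")
    al = _aligner(scoring)
    best = al.align(target, query)[0]
    t_blocks, q_blocks = best.aligned
    tspan = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    qspan = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    matches = 0
    columns = 0
    # columns include internal gaps: count from the block structure
    prev_t, prev_q = t_blocks[0][0], q_blocks[0][0]
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        columns += (ts - prev_t) + (qs - prev_q)      # gap columns
        for a, b in zip(target[ts:te], query[qs:qe]):
            matches += a == b
        columns += te - ts
        prev_t, prev_q = te, qe
    identity = 100.0 * matches / columns if columns else 0.0
    return ConsensusAlignment(
        consensus_name=consensus_name, consensus_span=tspan, query_span=qspan,
        identity_percent=identity, score=float(best.score), n_columns=columns,
        n_query=len(query))


def percent_similarity(te1_seq: str, te2_seq: str,
                       scoring: AlignScoring | None = None) -> float:
    """Percent identity over the best local alignment of two TE sequences.

    Both sequences must be in consensus orientation; identity is counted
    over alignment columns including gaps.  The pair is aligned in a
    canonical order so the result is symmetric even when co-optimal
    alignments with different gap placements exist.
    """
    if not te1_seq or not te2_seq:
        raise ValueError("empty sequence")
    a, b = sorted((te1_seq, te2_seq))
    return local_align(a, b, scoring=scoring).identity_percent


@dataclass
class FlankPair:
    """Junction flanks read in consensus orientation.

    ``flank5`` contributes the chimera's consensus-5' part (up to and
    including the microhomology), ``flank3`` the consensus-3' part (starting
    with the microhomology); both therefore contain the mh tract.
    """

    flank5: str
    flank3: str
    mh_cons: int            # mh length recomputed in consensus space
    head_is_te5: bool       # whether the 5' genomic element contributes the head
    c_head: int             # consensus offset of the junction in the head element
    c_tail: int


def _cons_offset(bp: int, te) -> int:
    off = bp - te.te_start
    if te.strand == "+":
        return te.cons_start + off
    return te.cons_end - off


def extract_flanks(refseq: str, sv_type: str, bp5: int, bp3: int, te5, te3) -> FlankPair:
    """Extract consensus-oriented junction flanks for mechanism inference.

    The chimeric element takes the consensus head (5' part) from one TE copy
    and the tail from the other; which copy contributes the head depends on
    the SV geometry and strand (e.g. for a deletion between plus-strand
    copies the 5' element contributes the head, between minus-strand copies
    the 3' element does).  Flanks are extended through the microhomology so
    both carry the full tract, making the expected consensus overlap equal
    to the microhomology length for HR events.
    """
    for bp, te, label in ((bp5, te5, "5'"), (bp3, te3, "3'")):
        if not te.te_start <= bp <= te.te_end:
            raise ValueError(f"{label} breakpoint {bp} outside its assigned TE")
    slice5 = refseq[te5.te_start:te5.te_end]
    slice3 = refseq[te3.te_start:te3.te_end]
    cs5 = revcomp(slice5) if te5.strand == "-" else slice5
    cs3 = revcomp(slice3) if te3.strand == "-" else slice3
    c5 = _cons_offset(bp5, te5)
    c3 = _cons_offset(bp3, te3)

    if sv_type == "INV":
        head_is_te5 = True
    elif sv_type == "DEL":
        head_is_te5 = te5.strand == "+"
    else:  # DUP / mCNV
        head_is_te5 = te3.strand == "-"
    if head_is_te5:
        cs_h, t_h, c_h = cs5, te5.cons_start, c5
        cs_t, t_t, c_t = cs3, te3.cons_start, c3
    else:
        cs_h, t_h, c_h = cs3, te3.cons_start, c3
        cs_t, t_t, c_t = cs5, te5.cons_start, c5

    ih, it = c_h - t_h, c_t - t_t
    r = 0
    while ih + r < len(cs_h) and it + r < len(cs_t) and cs_h[ih + r] == cs_t[it + r]:
        r += 1
    l = 0
    while ih - 1 - l >= 0 and it - 1 - l >= 0 and cs_h[ih - 1 - l] == cs_t[it - 1 - l]:
        l += 1
    return FlankPair(
        flank5=cs_h[:ih + r],
        flank3=cs_t[it - l:],
        mh_cons=l + r,
        head_is_te5=head_is_te5,
        c_head=c_h,
        c_tail=c_t,
    )


@dataclass
class MechanismCall:
    """HR/NHE decision for one TEMR."""

    label: str                               # HR | NHE | MANUAL_REVIEW
    overlap_bp: int
    consensus_junction_position: int | None  # s2 on the consensus (HR only)
    monomer_cross: str | None                # None | left-to-right | right-to-left
    review_reason: str                       # polyA | truncated | discordant | none
    align5: ConsensusAlignment | None = None
    align3: ConsensusAlignment | None = None

    def __post_init__(self):
        if self.label == "HR":
            assert self.overlap_bp >= 1


def infer_mechanism(flanks: FlankPair, mh_sequence: str, consensus: TEConsensus,
                    scoring: AlignScoring | None = None, overlap_tolerance: int = 0,
                    align_cap: int = 1500, truncated_coverage: float = 0.5,
                    polya_fraction: float = 0.9) -> MechanismCall:
    """Classify one TEMR as HR, NHE or MANUAL_REVIEW.

    Steps: (1) align both flanks to the family consensus and test whether
    the consensus overlap ``e1 - s2`` equals the microhomology; (2) for Alu
    events that fail with nonzero microhomology, re-test the overlap in
    monomer-relative coordinates to recognise monomer-crossing chimeras;
    (3) call NHE when the flanks fail to overlap; (4) otherwise
    emit MANUAL_REVIEW with a reason.  A microhomology of >= 5 bp composed
    of >= 90% A (or T) is flagged poly-A up front, and a flank whose
    consensus alignment covers < half of it is flagged truncated.

    Long flanks are aligned through their junction-proximal ``align_cap``
    bases; only the junction-side endpoint of the consensus span enters the
    overlap test.
    """
    scoring = scoring or AlignScoring()
    mh_length = len(mh_sequence)

    if mh_length >= 5 and mh_sequence:
        a_frac = mh_sequence.count("A") / mh_length
        t_frac = mh_sequence.count("T") / mh_length
        if a_frac >= polya_fraction or t_frac >= polya_fraction:
            return MechanismCall("MANUAL_REVIEW", 0, None, None, "polyA")

    if not flanks.flank5 or not flanks.flank3:
        return MechanismCall("MANUAL_REVIEW", 0, None, None, "truncated")

    q5 = flanks.flank5[-align_cap:]
    q3 = flanks.flank3[:align_cap]
    a5 = local_align(q5, consensus, scoring=scoring)
    a3 = local_align(q3, consensus, scoring=scoring)
    # consensus endpoint adjusted for any unaligned junction-side query bases
    e1 = a5.consensus_span[1] + (len(q5) - a5.query_span[1])
    s2 = a3.consensus_span[0] - a3.query_span[0]
    overlap = e1 - s2

    if overlap >= 1 and abs(overlap - mh_length) <= overlap_tolerance and mh_length >= 1:
        return MechanismCall("HR", overlap, s2, None, "none", a5, a3)

    # Alu monomer retry: chimeras recombined between homologous positions of
    # different monomers fail the full-consensus overlap by about one monomer
    # length.  Re-test in monomer-relative coordinates: project the flank
    # endpoints into the monomers containing them and compare the
    # monomer-relative overlap against the microhomology.
    if mh_length >= 1 and len(consensus.monomer_bounds) >= 2:
        mi = consensus.monomer_of(e1 - 1)     # monomer of the last 5'-flank base
        mj = consensus.monomer_of(s2)         # monomer of the first 3'-flank base
        if mi is not None and mj is not None and mi != mj:
            ov = (e1 - consensus.monomer_bounds[mi][0]) - (s2 - consensus.monomer_bounds[mj][0])
            if ov >= 1 and abs(ov - mh_length) <= overlap_tolerance:
                cross = "left-to-right" if mi < mj else "right-to-left"
                return MechanismCall("HR", ov, s2, cross, "none", a5, a3)

    if consensus.family == "LINE-1" and min(a5.query_coverage, a3.query_coverage) < truncated_coverage:
        return MechanismCall("MANUAL_REVIEW", overlap, None, None, "truncated", a5, a3)

    if overlap <= 0:
        return MechanismCall("NHE", overlap, None, None, "none", a5, a3)

    return MechanismCall("MANUAL_REVIEW", overlap, None, None, "discordant", a5, a3)


def map_mh_to_consensus(call: MechanismCall, mh_length: int,
                        consensus: TEConsensus | None = None):
    """Consensus interval [s2, s2+mh) of an HR call's microhomology.

    When the consensus carries box annotations (A-Box/B-Box/A'-Box), the
    returned dict lists the boxes the interval touches.
    """
    if call.label != "HR":
        raise ValueError("microhomology mapping applies to HR calls only")
    s2 = call.consensus_junction_position
    interval = (s2, s2 + mh_length)
    touched = []
    if consensus is not None:
        for name, (bs, be) in consensus.boxes.items():
            if interval[0] < be and bs < interval[1]:
                touched.append(name)
    return {"interval": interval, "boxes": touched}


def classify_cohort(calls: "list | object") -> dict:
    """Cohort-level mechanism summary.

    Accepts a DataFrame (columns mechanism, te_family, monomer_cross,
    review_reason) or a list of (family, MechanismCall) pairs.  Reports
    label-by-family counts, the fraction systematically categorized, the
    single- vs three-monomer chimera tally, and both published-style ratios
    whose denominators differ (share of HR events that are Alu, and share
    of Alu events that are HR).
    """
    import pandas as pd

    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame(
            [{"te_family": fam, "mechanism": c.label, "monomer_cross": c.monomer_cross,
              "review_reason": c.review_reason} for fam, c in calls])
    n = len(calls)
    counts = calls.groupby(["mechanism", "te_family"]).size()
    table = {f"{mech}/{fam}": int(v) for (mech, fam), v in counts.items()}
    n_review = int((calls.mechanism == "MANUAL_REVIEW").sum())
    hr = calls[calls.mechanism == "HR"]
    alu = calls[calls.te_family == "Alu"]
    single = int((calls.monomer_cross == "left-to-right").sum())
    triple = int((calls.monomer_cross == "right-to-left").sum())
    out = {
        "n_events": n,
        "counts": table,
        "n_hr": int(len(hr)),
        "n_nhe": int((calls.mechanism == "NHE").sum()),
        "n_manual_review": n_review,
        "percent_categorized": round(100.0 * (n - n_review) / n, 2) if n else 0.0,
        "hr_fraction_percent": round(100.0 * len(hr) / max(1, n - n_review), 2),
        "monomer_chimeras": {"single": single, "three": triple},
    }
    if len(hr):
        out["alu_share_of_hr_percent"] = round(100.0 * (hr.te_family == "Alu").sum() / len(hr), 2)
    if len(alu):
        out["hr_share_of_alu_percent"] = round(100.0 * (alu.mechanism == "HR").sum() / len(alu), 2)
    return out
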