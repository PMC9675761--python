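"""Breakpoint-junction analysis: microhomology, insertions, complexities.

A rearrangement junction is ambiguous whenever the two joined flanks share
sequence: any breakpoint position inside the shared tract reconstructs the
same alternate allele.  We call that maximal shared tract the breakpoint
*microhomology* (mh).  For a deletion/duplication with 5' breakpoint ``bp5``
and 3' breakpoint ``bp3`` on the reference:

* right extension r = max k with ref[bp5 : bp5+k) == ref[bp3 : bp3+k)
* left  extension l = max j with ref[bp5-j : bp5) == ref[bp3-j : bp3)
* mh = ref[bp5-l : bp5+r), of length l + r

For an inversion the distal flank is read in reverse complement.  Writing
the two junction tracts out shows they are mirror images of each other
(the left extension of one junction is the right extension of the other),
so a single mh length describes both inversion junctions; both values are
stored on the call.

Only perfect identity counts toward mh.  Imperfect ("homeologous") tracts
are reported separately by :func:`homeology_scan`, and junction insertions
never contribute to mh.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp

__all__ = [
    "JunctionCall",
    "compute_microhomology",
    "infer_junction_insertion",
    "homeology_scan",
    "reconstruct_junction_text",
    "detect_complex_breakpoints",
    "apply_sv",
]


@dataclass
class JunctionCall:
    """Microhomology/insertion annotation of one junction."""

    mh_sequence: str
    mh_length: int
    junction_insertion: str
    left_extension: int
    right_extension: int
    breakpoint_ambiguity_range: tuple[int, int]
    # inversions carry the tract at both junctions; equal lengths by symmetry
    mh_length_5p: int | None = None
    mh_length_3p: int | None = None

    def __post_init__(self):
        assert self.mh_length == len(self.mh_sequence)
        assert self.mh_length == self.left_extension + self.right_extension
        lo, hi = self.breakpoint_ambiguity_range
        assert hi - lo == self.mh_length + 1


def _ext_fwd(ref: str, i: int, j: int, cap: int) -> int:
    """Shared run length comparing ref[i+k] to ref[j+k]."""
    k = 0
    n = len(ref)
    while k < cap and i + k < n and j + k < n and ref[i + k] == ref[j + k]:
        k += 1
    return k


def _ext_back(ref: str, i: int, j: int, cap: int) -> int:
    k = 0
    while k < cap and i - k > 0 and j - k > 0 and ref[i - 1 - k] == ref[j - 1 - k]:
        k += 1
    return k


def compute_microhomology(refseq: str, bp5: int, bp3: int, sv_type: str = "DEL",
                          junction_insertion: str = "") -> JunctionCall:
    """Microhomology at the junction defined by (bp5, bp3) on the reference.

    ``sv_type`` selects the geometry: DEL/DUP/mCNV compare the two forward
    flanks; INV compares each flank with the reverse complement of the
    distal flank of the inverted segment.  ``junction_insertion`` is carried
    through from the alternate allele when known (synthetic truth or
    assembly sequence); it is not inferred here (see
    :func:`infer_junction_insertion`).
    """
    if not 0 <= bp5 < bp3 <= len(refseq):
        raise ValueError(f"require 0 <= bp5 < bp3 <= len(ref); got {bp5}, {bp3}")
    svlen = bp3 - bp5
    if sv_type in ("DEL", "DUP", "mCNV"):
        r = _ext_fwd(refseq, bp5, bp3, cap=svlen)
        l = _ext_back(refseq, bp5, bp3, cap=svlen - r)
        mh = refseq[bp5 - l: bp5 + r]
        mh5 = mh3 = None
    elif sv_type == "INV":
        # 5' junction joins ref[..bp5) to revcomp(ref[bp5..bp3)); ambiguity:
        #   right: ref[bp5+k] == comp(ref[bp3-1-k]); left: ref[bp5-1-j] == comp(ref[bp3+j])
        n = len(refseq)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        r = 0
        while r < svlen and bp5 + r < n and bp3 - 1 - r >= bp5 and \
                refseq[bp5 + r] == comp.get(refseq[bp3 - 1 - r], "N"):
            r += 1
        l = 0
        while l < svlen - r and bp5 - 1 - l >= 0 and bp3 + l < n and \
                refseq[bp5 - 1 - l] == comp.get(refseq[bp3 + l], "N"):
            l += 1
        mh = refseq[bp5 - l: bp5 + r]
        mh5 = mh3 = l + r  # mirror-image tracts: both junctions share the length
    else:
        raise ValueError(f"unknown sv_type {sv_type!r}")
    return JunctionCall(
        mh_sequence=mh,
        mh_length=l + r,
        junction_insertion=junction_insertion,
        left_extension=l,
        right_extension=r,
        breakpoint_ambiguity_range=(bp5 - l, bp5 + r + 1),
        mh_length_5p=mh5,
        mh_length_3p=mh3,
    )


def apply_sv(refseq: str, bp5: int, bp3: int, sv_type: str = "DEL",
             junction_insertion: str = "", copy_number: int = 2) -> str:
    """Reconstruct the alternate haplotype implied by an SV on ``refseq``.

    DEL removes [bp5, bp3) (and places the junction insertion, if any);
    DUP/mCNV tandemly repeat the segment so that ``copy_number`` copies are
    present (2 for a simple duplication); INV reverse-complements it.
    """
    seg = refseq[bp5:bp3]
    if sv_type == "DEL":
        return refseq[:bp5] + junction_insertion + refseq[bp3:]
    if sv_type in ("DUP", "mCNV"):
        extra = copy_number - 1
        if extra < 1:
            raise ValueError("copy_number must be >= 2 for DUP/mCNV")
        return refseq[:bp3] + (junction_insertion + seg) * extra + refseq[bp3:]
    if sv_type == "INV":
        return refseq[:bp5] + revcomp(seg) + refseq[bp3:]
    raise ValueError(f"unknown sv_type {sv_type!r}")


def infer_junction_insertion(refseq: str, altseq: str, bp5: int, bp3: int,
                             sv_type: str = "DEL") -> str:
    """Recover inserted bases at a deletion junction from the alternate allele.

    ``altseq`` is the full alternate haplotype (or a window produced with the
    same flank coordinates).  Returns the inserted sequence, "" for a clean
    junction.  Only meaningful for DEL-geometry junctions; the insertion is
    defined up to rotation within the junction ambiguity.
    """
    if sv_type != "DEL":
        raise ValueError("insertion inference implemented for DEL geometry")
    expected_len = len(refseq) - (bp3 - bp5)
    ins_len = len(altseq) - expected_len
    if ins_len <= 0:
        return ""
    # the inserted tract occupies alt[bp5 : bp5+ins_len] when breakpoints are
    # reported at the junction; defined up to rotation within the ambiguity
    return altseq[bp5: bp5 + ins_len]


def homeology_scan(refseq: str, bp5: int, bp3: int, min_identity: float = 0.90,
                   max_len: int = 400) -> int:
    """Length of the longest near-perfect (>= ``min_identity``) shared tract.

    Auxiliary annotation for junctions flanked by homeologous rather than
    identical sequence; scans outward from the junction in both directions
    and reports the longest window whose per-base identity stays at or above
    the threshold.  Perfect microhomology is a lower bound of the result.
    """
    n = len(refseq)
    best = 0
    for L in range(1, max_len + 1):
        # forward windows starting at the breakpoints
        if bp5 + L <= n and bp3 + L <= n:
            w5, w3 = refseq[bp5:bp5 + L], refseq[bp3:bp3 + L]
            if sum(x == y for x, y in zip(w5, w3)) / L >= min_identity:
                best = max(best, L)
        # backward windows ending at the breakpoints
        if bp5 - L >= 0 and bp3 - L >= 0:
            w5, w3 = refseq[bp5 - L:bp5], refseq[bp3 - L:bp3]
            if sum(x == y for x, y in zip(w5, w3)) / L >= min_identity:
                best = max(best, L)
    return best


def reconstruct_junction_text(refseq: str, altseq: str, bp5: int, bp3: int,
                              call: JunctionCall, context: int = 60) -> str:
    """Three-line, byte-stable rendering of a junction reconstruction.

    Line 1: 5' reference flank; line 2: alternate allele through the
    junction; line 3: 3' reference flank.  The microhomology tract is
    bracketed on the alternate line; a junction insertion is shown in
    lower case.
    """
    if refseq == altseq:
        raise ValueError("reference and alternate are identical: no junction to render")
    l, r = call.left_extension, call.right_extension
    c5 = refseq[max(bp5 - context, 0): bp5 + r]
    c3 = refseq[bp3 - l: min(bp3 + context, len(refseq))]
    mh = call.mh_sequence
    ins = call.junction_insertion.lower()
    left_flank = refseq[max(bp5 - context, 0): bp5 - l]
    right_flank = refseq[bp3 + r: min(bp3 + context, len(refseq))]
    alt_line = left_flank + ("[" + mh + "]" if mh else "") + ins + right_flank
    pad = " " * 5
    lines = [
        f"5'REF{pad}{c5}...",
        f"ALT  {pad}{alt_line}",
        f"3'REF{pad}...{c3}",
    ]
    return "\n".join(lines)


def detect_complex_breakpoints(refseq: str, altseq: str | None, bp5: int, bp3: int,
                               sv_type: str = "INV", copy_number: int = 2,
                               min_size: int = 5, junction_radius: int = 500):
    """Secondary deletions/insertions at the junctions of an SV.

    Aligns the observed alternate allele against the alternate expected from
    a clean rearrangement (same breakpoints, no extra edits) and reports
    gaps of at least ``min_size`` bp that fall within ``junction_radius`` of
    a junction.  Returns a list of dicts with keys kind ('DEL'|'INS'), size,
    position (on the expected alternate); or the string "not evaluable" when
    no alternate sequence is available.
    """
    if altseq is None:
        return "not evaluable"
    from Bio import Align

    expected = apply_sv(refseq, bp5, bp3, sv_type=sv_type, copy_number=copy_number)
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 5
    al.mismatch_score = -4
    al.open_gap_score = -10      # affine gaps keep indels contiguous
    al.extend_gap_score = -0.5
    best = al.align(expected, altseq)[0]
    t_blocks, q_blocks = best.aligned
    # junction positions on the expected alternate
    if sv_type == "DEL":
        junctions = [bp5]
    elif sv_type == "INV":
        junctions = [bp5, bp3]
    else:
        seglen = bp3 - bp5
        junctions = [bp3 + i * seglen for i in range(copy_number - 1)]
    events = []

    def near_junction(pos):
        return any(abs(pos - j) <= junction_radius for j in junctions)

    if len(t_blocks) and t_blocks[0][0] >= min_size and near_junction(0):
        events.append({"kind": "DEL", "size": int(t_blocks[0][0]), "position": 0})
    for k in range(1, len(t_blocks)):
        pos = int(t_blocks[k - 1][1])
        dt = int(t_blocks[k][0] - t_blocks[k - 1][1])   # expected-only bases: deletion in alt
        dq = int(q_blocks[k][0] - q_blocks[k - 1][1])   # alt-only bases: insertion in alt
        if dt >= min_size and near_junction(pos):
            events.append({"kind": "DEL", "size": dt, "position": pos})
        if dq >= min_size and near_junction(pos):
            events.append({"kind": "INS", "size": dq, "position": pos})
    return events
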