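"""Synthetic reference genomes with planted TEMRs of known truth.

The generator emulates the raw material of a TEMR study: a background
genome seeded with consensus-derived TE copies at controlled divergence,
rearrangements (DEL/DUP/INV/mCNV) whose two breakpoints fall in distinct
same-family TE copies, and noisy multi-caller callsets.  Every planted
event carries a :class:`TruthRecord` so that downstream stages (ensemble
merging, TEMR classification, junction reconstruction, mechanism
inference) can be scored against ground truth.

Mechanism control
-----------------
* HR events are planted so both TE copies retain an *identical,
  substitution-free* window of exactly ``mh_length`` bases at the same
  consensus offset (boundaries are forced to mismatch so the realized
  microhomology equals the requested length), and the junction lies inside
  that window.  The resulting chimera reconstructs a full-length element.
* NHE events place the two breakpoints at distinct consensus offsets so the
  flanks cannot overlap along the consensus; a 0-4 bp microhomology tract
  is copied between the elements, and an optional 1-23 bp junction
  insertion is added.
* Monomer-crossing Alu events place the two breakpoints at homologous
  offsets of *different* monomers, producing single-monomer (~150 bp) or
  three-monomer (~450 bp) chimeric elements.

TE mutation is substitution-only by default, which keeps microhomology
tracts analytically controllable; coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import BASES, as_rng, child_rng, random_dna, revcomp
from .consensus import TEConsensus, default_consensus_set
from .junction import apply_sv, compute_microhomology

__all__ = [
    "PlantSpec",
    "TruthRecord",
    "TEPlacement",
    "SyntheticReference",
    "mutate_from_consensus",
    "build_reference",
    "plant_temr",
    "simulate_callsets",
    "simulate_depth_profile",
    "simulate_study",
    "StudySimulation",
    "DEFAULT_CALLERS",
]

ANNOTATION_COLUMNS = ["chrom", "start", "end", "subfamily", "divergence", "strand",
                      "family", "copy_id", "cons_start", "cons_end"]


class PlantingError(ValueError):
    """Raised when a TEMR cannot be planted as requested."""


# ---------------------------------------------------------------------------
# specs and records


@dataclass
class PlantSpec:
    """Parameters of one planted TEMR."""

    sv_type: str = "DEL"                 # DEL | DUP | INV | mCNV
    mechanism: str = "HR"                # HR | NHE
    te_family: str = "Alu"
    te_orientation: str = "direct"       # direct | inverted
    mh_length: int = 15
    junction_insertion: str = ""
    divergence_5p: float = 0.05
    divergence_3p: float = 0.05
    copy_number: int = 2                 # total diploid copies of the segment (DUP=3, mCNV>=4)
    seed: int = 0
    # optional explicit targets (filled by simulate_study; searched otherwise)
    te5_id: str | None = None
    te3_id: str | None = None
    window_start: int | None = None      # consensus offset of the mh window
    c5: int | None = None                # consensus offset of the 5' breakpoint
    c3: int | None = None
    monomer_cross: str | None = None     # None | "single" | "triple"

    def __post_init__(self):
        if self.mh_length < 0:
            raise ValueError("mh_length must be >= 0")
        if self.mechanism == "HR":
            if self.mh_length < 5:
                raise ValueError("HR events require mh_length >= 5")
            if self.junction_insertion:
                raise ValueError("HR events carry no junction insertion")
        elif self.mechanism == "NHE":
            if self.mh_length > 4:
                raise ValueError("NHE events require mh_length <= 4")
        else:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.sv_type not in ("DEL", "DUP", "INV", "mCNV"):
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type == "INV" and self.te_orientation != "inverted":
            raise ValueError("inversions are mediated by TEs in opposite orientation")
        if self.sv_type == "mCNV" and self.copy_number < 4:
            raise ValueError("mCNV requires copy_number >= 4 (diploid total)")


@dataclass
class TruthRecord:
    """Ground truth for one planted event (reference coordinates)."""

    chrom: str
    start: int
    end: int
    sv_type: str
    mechanism: str
    mh_sequence: str
    junction_insertion: str
    te5_id: str | None
    te3_id: str | None
    consensus_junction_position: int | None   # HR only: consensus offset of the mh window start
    te_family: str | None = None
    te_orientation: str | None = None
    copy_number: int = 2
    monomer_cross: str | None = None
    is_temr: bool = True
    sample: str = "S1"

    @property
    def mh_length(self) -> int:
        return len(self.mh_sequence)

    @property
    def svlen(self) -> int:
        return self.end - self.start


def truth_to_frame(records) -> pd.DataFrame:
    rows = []
    for t in records:
        rows.append({
            "chrom": t.chrom, "start": t.start, "end": t.end, "sv_type": t.sv_type,
            "mechanism": t.mechanism, "mh_length": t.mh_length, "mh_sequence": t.mh_sequence,
            "junction_insertion": t.junction_insertion, "te5_id": t.te5_id, "te3_id": t.te3_id,
            "consensus_junction_position": t.consensus_junction_position,
            "te_family": t.te_family, "te_orientation": t.te_orientation,
            "copy_number": t.copy_number, "monomer_cross": t.monomer_cross,
            "is_temr": t.is_temr, "sample": t.sample,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TE copy generation


def mutate_from_consensus(consensus: TEConsensus | str, divergence: float,
                          strand: str = "+", truncate_5p: int = 0, seed=0,
                          protected=(), forced=None):
    """Derive a TE copy from its consensus by i.i.d. substitutions.

    Returns ``(genomic_seq, substitutions)`` where substitutions is a list of
    ``(consensus_pos, consensus_base, new_base)``.  The copy covers consensus
    positions ``[truncate_5p, len)`` (5' truncation, as in truncated LINE-1s)
    and is reverse-complemented when ``strand`` is '-'.  ``protected``
    consensus intervals receive no substitutions; ``forced`` maps consensus
    positions to explicit bases (recorded as substitutions when they differ).
    """
    seq = consensus.sequence if isinstance(consensus, TEConsensus) else str(consensus).upper()
    if not 0.0 <= divergence < 1.0:
        raise ValueError(f"divergence must be in [0,1), got {divergence}")
    if not 0 <= truncate_5p < len(seq):
        raise ValueError("truncate_5p must be smaller than the consensus length")
    rng = as_rng(seed)
    out = list(seq[truncate_5p:])
    n = len(out)
    subs = []
    is_protected = np.zeros(n, dtype=bool)
    for s, e in protected:
        s, e = max(s, truncate_5p), min(e, len(seq))
        if s < e:
            is_protected[s - truncate_5p:e - truncate_5p] = True
    if divergence > 0:
        hits = np.flatnonzero(rng.random(n) < divergence)
        for i in hits:
            if is_protected[i]:
                continue
            ref = out[i]
            alts = [b for b in BASES if b != ref]
            out[i] = alts[int(rng.integers(3))]
            subs.append((int(i) + truncate_5p, ref, out[i]))
    if forced:
        for pos, base in sorted(forced.items()):
            i = pos - truncate_5p
            if not 0 <= i < n:
                continue
            if out[i] != base:
                # replace any earlier substitution record at this position
                subs = [s for s in subs if s[0] != pos]
                if base != seq[pos]:
                    subs.append((pos, seq[pos], base))
                out[i] = base
    subs.sort()
    cons_oriented = "".join(out)
    return (revcomp(cons_oriented) if strand == "-" else cons_oriented), subs


@dataclass
class TEPlacement:
    """One TE copy to place on the background genome."""

    position: int
    consensus: TEConsensus
    divergence: float = 0.0
    strand: str = "+"
    truncate_5p: int = 0
    protected: tuple = ()
    forced: dict | None = None
    copy_id: str | None = None


@dataclass
class SyntheticReference:
    """A synthetic reference genome plus its TE annotation and mutation log."""

    chrom: str
    sequence: str
    annotation: pd.DataFrame
    mutation_log: dict = field(default_factory=dict)   # copy_id -> substitution list

    def copy_sequence(self, copy_id: str) -> str:
        """Consensus-oriented sequence of a planted copy."""
        row = self.annotation.set_index("copy_id").loc[copy_id]
        seq = self.sequence[int(row.start):int(row.end)]
        return revcomp(seq) if row.strand == "-" else seq


def build_reference(background_length: int, te_placements, seed=0, chrom: str = "chr1",
                    gc: float = 0.41) -> SyntheticReference:
    """Random background genome with TE copies written in at fixed positions.

    Placements overwrite the background (no length change) and must not
    overlap.  The annotation records realized divergence (computed from the
    mutation log, not the requested rate) and the consensus interval each
    copy covers (``cons_start``/``cons_end``, RepeatMasker repStart-style).
    """
    rng = as_rng(seed)
    genome = np.frombuffer(random_dna(rng, background_length, gc=gc).encode(), dtype="S1").copy()
    rows = []
    log = {}
    placed = []
    for k, pl in enumerate(te_placements):
        if not isinstance(pl, TEPlacement):
            pl = TEPlacement(*pl)
        copy_id = pl.copy_id or f"{pl.consensus.name}_{k}"
        seq, subs = mutate_from_consensus(
            pl.consensus, pl.divergence, strand=pl.strand, truncate_5p=pl.truncate_5p,
            seed=rng, protected=pl.protected, forced=pl.forced)
        start, end = pl.position, pl.position + len(seq)
        if end > background_length:
            raise PlantingError(f"placement {copy_id} extends past the background end")
        for s, e in placed:
            if start < e and s < end:
                raise PlantingError(f"placement {copy_id} overlaps a previous placement")
        placed.append((start, end))
        genome[start:end] = np.frombuffer(seq.encode(), dtype="S1")
        realized = 100.0 * len(subs) / len(seq)
        rows.append({
            "chrom": chrom, "start": start, "end": end, "subfamily": pl.consensus.name,
            "divergence": realized, "strand": pl.strand, "family": pl.consensus.family,
            "copy_id": copy_id, "cons_start": pl.truncate_5p, "cons_end": len(pl.consensus.sequence),
        })
        log[copy_id] = subs
    ann = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).sort_values(["start", "end"]).reset_index(drop=True)
    return SyntheticReference(chrom, genome.tobytes().decode(), ann, log)


# ---------------------------------------------------------------------------
# breakpoint geometry helpers (consensus offset <-> genomic position)


def _genomic_pos(row, cons_offset: int) -> int:
    """Genomic position of a consensus offset within an annotated copy."""
    L = int(row.cons_end)
    t = int(row.cons_start)
    if not t <= cons_offset <= L:
        raise PlantingError(f"consensus offset {cons_offset} outside copy {row.copy_id}")
    if row.strand == "+":
        return int(row.start) + (cons_offset - t)
    return int(row.start) + (L - cons_offset)


def _shared_runs(cs5: str, cs3: str, lo: int, hi: int, t5: int, t3: int):
    """Maximal runs of identity between two consensus-oriented copies.

    Positions are consensus offsets; copies start at consensus offsets t5/t3.
    Returns a list of (run_start, run_len) over [lo, hi).
    """
    a = np.frombuffer(cs5[lo - t5:hi - t5].encode(), dtype="S1")
    b = np.frombuffer(cs3[lo - t3:hi - t3].encode(), dtype="S1")
    eq = a == b
    runs = []
    i = 0
    n = len(eq)
    while i < n:
        if eq[i]:
            j = i
            while j < n and eq[j]:
                j += 1
            runs.append((lo + i, j - i))
            i = j
        else:
            i += 1
    return runs


def plant_temr(reference: SyntheticReference, spec: PlantSpec, seed=0):
    """Apply one TEMR to a synthetic reference; return (alt_sequence, truth).

    The TE pair is taken from ``spec`` when given, otherwise searched in the
    annotation (first eligible pair of the requested family and relative
    orientation, seeded choice).  For HR the junction is placed inside an
    identical substitution-free window shared by the two copies; a
    :class:`PlantingError` is raised when no window of exactly
    ``spec.mh_length`` exists.
    """
    rng = child_rng(seed, 11, spec.seed)
    ann = reference.annotation
    ref = reference.sequence

    row5, row3 = _resolve_pair(ann, spec, rng)
    cs5, cs3 = reference.copy_sequence(row5.copy_id), reference.copy_sequence(row3.copy_id)
    t5, t3 = int(row5.cons_start), int(row3.cons_start)
    L = int(row5.cons_end)

    # chimera roles: which element contributes the consensus-5' part
    swap = spec.sv_type in ("DUP", "mCNV")

    if spec.mechanism == "HR" and spec.monomer_cross is None:
        lo, hi = max(t5, t3), min(int(row5.cons_end), int(row3.cons_end))
        if spec.window_start is not None:
            w = spec.window_start
            ok = any(rs == w and rl == spec.mh_length
                     for rs, rl in _shared_runs(cs5, cs3, lo, hi, t5, t3))
            if not ok:
                raise PlantingError("requested mh window is not an identical maximal tract in both copies")
        else:
            runs = [(rs, rl) for rs, rl in _shared_runs(cs5, cs3, lo, hi, t5, t3)
                    if rl == spec.mh_length]
            if not runs:
                raise PlantingError(
                    f"no shared identical tract of exactly {spec.mh_length} bp between "
                    f"{row5.copy_id} and {row3.copy_id}")
            w = runs[int(rng.integers(len(runs)))][0]
        c = int(rng.integers(w, w + spec.mh_length + 1))
        c5 = c3 = c
        cjp = w
    elif spec.mechanism == "HR":
        c5, c3, cjp = _cross_offsets(spec, row5, row3, cs5, cs3, t5, t3, rng)
    else:  # NHE
        if spec.c5 is None or spec.c3 is None:
            raise PlantingError("NHE planting requires explicit c5/c3 consensus offsets "
                                "(use simulate_study or set them on the PlantSpec)")
        c5, c3 = spec.c5, spec.c3
        cjp = None

    bp5 = _genomic_pos(row5, c5)
    bp3 = _genomic_pos(row3, c3)
    if bp3 <= bp5:
        raise PlantingError("degenerate geometry: 3' breakpoint not beyond 5' breakpoint")

    hap_copies = spec.copy_number - 1 if spec.sv_type in ("DUP", "mCNV") else 2
    alt = apply_sv(ref, bp5, bp3, sv_type="DUP" if spec.sv_type == "mCNV" else spec.sv_type,
                   junction_insertion=spec.junction_insertion, copy_number=hap_copies)
    call = compute_microhomology(ref, bp5, bp3,
                                 sv_type="DUP" if spec.sv_type == "mCNV" else spec.sv_type,
                                 junction_insertion=spec.junction_insertion)
    if call.mh_length != spec.mh_length:
        raise PlantingError(
            f"realized microhomology {call.mh_length} != requested {spec.mh_length} "
            f"({row5.copy_id}/{row3.copy_id} at {c5}/{c3})")

    truth = TruthRecord(
        chrom=reference.chrom, start=bp5, end=bp3, sv_type=spec.sv_type,
        mechanism=spec.mechanism, mh_sequence=call.mh_sequence,
        junction_insertion=spec.junction_insertion,
        te5_id=row5.copy_id, te3_id=row3.copy_id,
        consensus_junction_position=cjp if spec.mechanism == "HR" else None,
        te_family=spec.te_family, te_orientation=spec.te_orientation,
        copy_number=spec.copy_number, monomer_cross=spec.monomer_cross,
    )
    return alt, truth


def _resolve_pair(ann: pd.DataFrame, spec: PlantSpec, rng):
    fam = ann[ann.family == spec.te_family]
    if spec.te5_id is not None and spec.te3_id is not None:
        r5 = fam[fam.copy_id == spec.te5_id]
        r3 = fam[fam.copy_id == spec.te3_id]
        if len(r5) != 1 or len(r3) != 1:
            raise PlantingError("requested TE pair not present in the annotation")
        return r5.iloc[0], r3.iloc[0]
    fam = fam.sort_values("start").reset_index(drop=True)
    pairs = []
    for i in range(len(fam) - 1):
        a, b = fam.iloc[i], fam.iloc[i + 1]
        same = a.strand == b.strand
        if (spec.te_orientation == "direct") != same:
            continue
        gap = b.start - a.start
        if 50 <= gap <= 50_000:
            pairs.append((a, b))
    if not pairs:
        raise PlantingError(f"no eligible {spec.te_family} pair with "
                            f"{spec.te_orientation} orientation")
    return pairs[int(rng.integers(len(pairs)))]


def _cross_offsets(spec, row5, row3, cs5, cs3, t5, t3, rng):
    """Breakpoint offsets for a monomer-crossing Alu HR event."""
    from .consensus import TEConsensus  # noqa: F401

    if spec.window_start is None or spec.c5 is None or spec.c3 is None:
        raise PlantingError("monomer-cross planting requires explicit offsets "
                            "(produced by simulate_study)")
    return spec.c5, spec.c3, spec.window_start


# ---------------------------------------------------------------------------
# multi-caller callset simulation

DEFAULT_CALLERS = (
    {"name": "Manta", "technology": "SRS", "jitter_sd": 0.0},
    {"name": "DELLY", "technology": "SRS", "jitter_sd": 3.0},
    {"name": "LUMPY", "technology": "SRS", "jitter_sd": 5.0},
    {"name": "pbsv", "technology": "LRS", "jitter_sd": 2.0},
    {"name": "Sniffles", "technology": "LRS", "jitter_sd": 5.0},
    {"name": "SVIM", "technology": "LRS", "jitter_sd": 8.0},
)

DEFAULT_SUPPORT = {"sr_mean": 12.0, "pr_mean": 20.0, "rs_mean": 15.0, "rd_sd": 0.05,
                   "miss_rate": 0.0}

CALLSET_COLUMNS = ["chrom", "start", "end", "sv_type", "caller", "technology",
                   "sample", "PR", "SR", "RS", "RD"]


def simulate_callsets(truth, genome_length: int, callers=DEFAULT_CALLERS,
                      jitter_sd: float | None = None, fp_rate: float = 0.0,
                      support_model: dict | None = None, seed=0,
                      chrom: str = "chr1") -> dict[str, pd.DataFrame]:
    """Per-caller SV tables for a list of :class:`TruthRecord`.

    Breakpoints are perturbed by rounded Gaussian jitter (per-caller sd, or
    the global ``jitter_sd`` override), support counts are Poisson draws
    around the support-model means, and the depth ratio follows the SV type
    (DEL ~0.5, DUP ~cn/2, INV ~1.0, Gaussian noise).  False positives are
    random intervals not overlapping any true event, at ``fp_rate`` events
    per Mbp per caller.  ``support_model`` may carry an ``overrides`` dict
    mapping truth index -> column values to force specific support counts.
    """
    model = dict(DEFAULT_SUPPORT)
    model.update(support_model or {})
    overrides = model.pop("overrides", {})
    out = {}
    truth = list(truth)
    truth_iv = [(t.start, t.end) for t in truth]
    for ci, caller in enumerate(callers):
        rng = child_rng(seed, 23, ci)
        sd = caller["jitter_sd"] if jitter_sd is None else jitter_sd
        tech = caller["technology"]
        rows = []
        for ti, t in enumerate(truth):
            if rng.random() < model["miss_rate"]:
                continue
            start = t.start + int(np.rint(rng.normal(0, sd))) if sd > 0 else t.start
            end = t.end + int(np.rint(rng.normal(0, sd))) if sd > 0 else t.end
            if end <= start:
                end = start + max(1, t.end - t.start)
            sv_type = "DUP" if t.sv_type == "mCNV" else t.sv_type
            if sv_type == "DEL":
                rd = 0.5
            elif sv_type == "DUP":
                rd = t.copy_number / 2.0
            else:
                rd = 1.0
            rd = max(0.0, rd + rng.normal(0, model["rd_sd"]))
            row = {"chrom": t.chrom, "start": start, "end": end, "sv_type": sv_type,
                   "caller": caller["name"], "technology": tech, "sample": t.sample,
                   "PR": int(rng.poisson(model["pr_mean"])) if tech == "SRS" else pd.NA,
                   "SR": int(rng.poisson(model["sr_mean"])) if tech == "SRS" else pd.NA,
                   "RS": int(rng.poisson(model["rs_mean"])) if tech == "LRS" else pd.NA,
                   "RD": rd}
            row.update(overrides.get(ti, {}))
            rows.append(row)
        n_fp = rng.poisson(fp_rate * genome_length / 1e6)
        for _ in range(int(n_fp)):
            for _try in range(100):
                length = int(np.exp(rng.uniform(np.log(60), np.log(20_000))))
                start = int(rng.integers(0, max(1, genome_length - length)))
                end = start + length
                if all(e <= start or end <= s for s, e in truth_iv):
                    break
            else:
                continue
            sv_type = ["DEL", "DUP", "INV"][int(rng.integers(3))]
            rd = {"DEL": 0.5, "DUP": 1.5, "INV": 1.0}[sv_type] + rng.normal(0, model["rd_sd"])
            rows.append({"chrom": chrom, "start": start, "end": end, "sv_type": sv_type,
                         "caller": caller["name"], "technology": tech,
                         "sample": truth[0].sample if truth else "S1",
                         "PR": int(rng.poisson(model["pr_mean"])) if tech == "SRS" else pd.NA,
                         "SR": int(rng.poisson(model["sr_mean"])) if tech == "SRS" else pd.NA,
                         "RS": int(rng.poisson(model["rs_mean"])) if tech == "LRS" else pd.NA,
                         "RD": max(0.0, rd)})
        df = pd.DataFrame(rows, columns=CALLSET_COLUMNS)
        out[caller["name"]] = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return out


def simulate_depth_profile(genome_length: int, truth, mean_depth: float = 30.0,
                           noise_sd: float = 0.5, bin_size: int = 100, seed=0):
    """Binned read-depth profile consistent with the planted copy numbers.

    Returns (bin_size, numpy array of per-bin depth).  Deletions halve the
    depth over the deleted segment; duplications and mCNVs scale it by
    cn/2.
    """
    rng = child_rng(seed, 31)
    n_bins = (genome_length + bin_size - 1) // bin_size
    depth = mean_depth + rng.normal(0, noise_sd, size=n_bins)
    for t in truth:
        lo, hi = t.start // bin_size, max(t.start // bin_size + 1, -(-t.end // bin_size))
        if t.sv_type == "DEL":
            scale = 0.5
        elif t.sv_type in ("DUP", "mCNV"):
            scale = t.copy_number / 2.0
        else:
            continue
        depth[lo:hi] *= scale
    return bin_size, np.clip(depth, 0, None)


# ---------------------------------------------------------------------------
# whole-study simulation


@dataclass
class StudySimulation:
    """A complete synthetic study: genome, truth, and per-event alt windows."""

    reference: SyntheticReference
    truth: list
    alt_windows: dict                      # truth index -> (win_start, win_end, alt_window_seq)
    consensus_set: dict
    seed: int

    @property
    def truth_frame(self) -> pd.DataFrame:
        return truth_to_frame(self.truth)

    def callsets(self, fp_rate: float = 0.0, jitter_sd: float | None = None,
                 support_model: dict | None = None, callers=DEFAULT_CALLERS):
        return simulate_callsets(self.truth, len(self.reference.sequence), callers=callers,
                                 jitter_sd=jitter_sd, fp_rate=fp_rate,
                                 support_model=support_model, seed=self.seed,
                                 chrom=self.reference.chrom)

    def depth_profile(self, mean_depth: float = 30.0, noise_sd: float = 0.5,
                      bin_size: int = 100):
        return simulate_depth_profile(len(self.reference.sequence), self.truth,
                                      mean_depth=mean_depth, noise_sd=noise_sd,
                                      bin_size=bin_size, seed=self.seed)


def _a_rich(seq: str, frac: float = 0.85) -> bool:
    if not seq:
        return False
    return seq.count("A") / len(seq) >= frac or seq.count("T") / len(seq) >= frac


def _usable_windows(cons: TEConsensus, t: int, m: int):
    """Consensus offsets w where [w-1, w+m+1) sits in TE body (no poly-A/linker)."""
    L = len(cons.sequence)
    hi = cons.polya_span[0] if cons.polya_span else L
    spans = []
    if cons.monomer_bounds:
        for s, e in cons.monomer_bounds:
            spans.append((max(s, t) + 2, min(e, hi) - m - 2))
    else:
        spans.append((t + 2, hi - m - 2))
    out = []
    for lo, hi2 in spans:
        for w in range(lo, hi2):
            if not _a_rich(cons.sequence[w:w + m]):
                out.append(w)
    return out


def _monomer_shared_runs(cons: TEConsensus):
    """Identity runs between the two Alu monomers, in monomer-relative offsets."""
    (s1, e1), (s2, e2) = cons.monomer_bounds[0], cons.monomer_bounds[1]
    n = min(e1 - s1, e2 - s2)
    a = cons.sequence[s1:s1 + n]
    b = cons.sequence[s2:s2 + n]
    runs, i = [], 0
    while i < n:
        if a[i] == b[i]:
            j = i
            while j < n and a[j] == b[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def _mismatch_base(rng, *avoid) -> str:
    choices = [b for b in BASES if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


# composition of the synthetic cohort, mirroring the observed study-scale
# proportions: Alu-dominated, mostly deletions, HR-dominated for Alu and
# NHE-dominated for LINE-1, inversions between opposite-orientation TEs
STUDY_DEFAULTS = {
    "alu_fraction": 0.80,
    "sv_type_probs": {
        "Alu": {"DEL": 0.89, "DUP": 0.06, "INV": 0.03, "mCNV": 0.02},
        "LINE-1": {"DEL": 0.88, "DUP": 0.04, "INV": 0.08, "mCNV": 0.0},
    },
    "hr_prob": {"Alu": 0.89, "LINE-1": 0.375},
    "hr_prob_inv": 0.73,
    "minus_pair_prob": 0.30,
    "nhe_mh_probs": [0.30, 0.30, 0.20, 0.12, 0.08],
    "nhe_insertion_prob": 0.35,
    "monomer_cross_counts": (1, 9),       # (single-monomer, three-monomer) chimeras
    "alu_size_median": 1163.0,
    "alu_size_sigma": 0.7,
    "line1_size_median": 4469.0,
    "line1_size_sigma": 0.5,
    "divergence_range": (0.01, 0.15),
    "line1_truncation_prob": 0.6,
    "line1_max_truncation": 4000,
}


def simulate_study(seed: int = 0, genome_length: int = 5_000_000, n_temr: int = 120,
                   n_background_svs: int = 30, consensus_set=None,
                   params: dict | None = None) -> StudySimulation:
    """Generate a study-scale synthetic genome with planted TEMRs.

    Defaults emulate the study conditions the downstream stages are scored
    against: a 5 Mbp single-chromosome genome carrying 120 TEMRs (80% Alu /
    20% LINE-1; mostly deletions; HR-dominated Alu, NHE-leaning LINE-1; all
    inversions between opposite-orientation TEs), monomer-crossing Alu
    chimeras at a 1:9 single:three-monomer ratio, copy divergence uniform on
    [0.01, 0.15], plus background non-TEMR deletions.
    """
    p = dict(STUDY_DEFAULTS)
    p.update(params or {})
    cons_set = consensus_set or default_consensus_set()
    alu, l1 = cons_set["Alu"], cons_set["LINE-1"]
    rng = child_rng(seed, 7)

    plans = _plan_cohort(rng, n_temr, p, cons_set)

    # --- lay out loci -------------------------------------------------------
    placements: list[TEPlacement] = []
    free_pads: list[list[int]] = []        # [start, end) intervals with plain background
    cursor = 0
    base_pads = rng.integers(1200, 2600, size=len(plans) + 1)
    est = sum(pl["locus_len"] for pl in plans) + int(base_pads.sum())
    leftover = genome_length - est - 2000
    if leftover < 0:
        raise PlantingError("genome_length too small for the requested cohort")
    extra = leftover // (len(plans) + 1)

    bg_id = 0
    for i, pl in enumerate(plans):
        pad = int(base_pads[i]) + extra
        # occasional uninvolved background TE inside the pad
        if pad > 1100 and rng.random() < 0.5:
            fam = alu if rng.random() < 0.8 else l1
            trunc = 0 if fam is alu else int(rng.integers(3000, 5500))
            te_len = len(fam.sequence) - trunc
            if te_len + 400 < pad:
                placements.append(TEPlacement(
                    position=cursor + 150, consensus=fam,
                    divergence=float(rng.uniform(0.05, 0.25)),
                    strand="+" if rng.random() < 0.5 else "-",
                    truncate_5p=trunc, copy_id=f"bgTE_{bg_id}"))
                bg_id += 1
                free_pads.append([cursor + 150 + te_len + 100, cursor + pad - 50])
            else:
                free_pads.append([cursor + 50, cursor + pad - 50])
        else:
            free_pads.append([cursor + 50, cursor + pad - 50])
        cursor += pad
        g5s = cursor
        placements.append(replace(pl["placement5"], position=g5s))
        cursor += pl["len5"]
        cursor += pl["gap"]
        g3s = cursor
        placements.append(replace(pl["placement3"], position=g3s))
        cursor += pl["len3"]
        pl["g5s"], pl["g3s"] = g5s, g3s
    free_pads.append([cursor + 50, genome_length - 50])

    reference = build_reference(genome_length, placements, seed=child_rng(seed, 8))

    # --- plant the TEMRs ----------------------------------------------------
    truth: list[TruthRecord] = []
    alt_windows: dict[int, tuple[int, int, str]] = {}
    for i, pl in enumerate(plans):
        spec = pl["spec"]
        alt, t = plant_temr(reference, spec, seed=child_rng(seed, 9, i))
        idx = len(truth)
        truth.append(t)
        ws = max(0, t.start - 500)
        we = min(len(reference.sequence), t.end + 500)
        delta = len(alt) - len(reference.sequence)
        alt_windows[idx] = (ws, we, alt[ws:we + delta])

    # --- background (non-TEMR) deletions ------------------------------------
    rng_bg = child_rng(seed, 10)
    pads = [iv for iv in free_pads if iv[1] - iv[0] > 800]
    for b in range(n_background_svs):
        iv = pads[int(rng_bg.integers(len(pads)))]
        span = iv[1] - iv[0]
        size = int(rng_bg.integers(200, min(2000, span - 100)))
        start = iv[0] + int(rng_bg.integers(0, span - size - 50))
        end = start + size
        call = compute_microhomology(reference.sequence, start, end, "DEL")
        truth.append(TruthRecord(
            chrom=reference.chrom, start=start, end=end, sv_type="DEL",
            mechanism="", mh_sequence=call.mh_sequence, junction_insertion="",
            te5_id=None, te3_id=None, consensus_junction_position=None,
            te_family=None, te_orientation=None, is_temr=False))

    return StudySimulation(reference=reference, truth=truth, alt_windows=alt_windows,
                           consensus_set=cons_set, seed=seed)


def _plan_cohort(rng, n_temr, p, cons_set):
    """Draw per-event parameters and the TE copy pair constructions."""
    alu, l1 = cons_set["Alu"], cons_set["LINE-1"]
    plans = []
    n_alu = int(round(p["alu_fraction"] * n_temr))
    fams = ["Alu"] * n_alu + ["LINE-1"] * (n_temr - n_alu)

    # deterministic sv-type allocation per family, remainder to DEL
    sv_alloc = []
    for fam in ("Alu", "LINE-1"):
        n_f = fams.count(fam)
        probs = p["sv_type_probs"][fam]
        counts = {sv: int(round(pr * n_f)) for sv, pr in probs.items() if sv != "DEL"}
        counts["DEL"] = n_f - sum(counts.values())
        for sv, c in counts.items():
            sv_alloc += [(fam, sv)] * c
    rng.shuffle(sv_alloc)

    # monomer-cross quota: Alu HR deletions in direct orientation
    n_single, n_triple = p["monomer_cross_counts"]
    cross_queue = ["single"] * n_single + ["triple"] * n_triple

    for k, (fam, sv_type) in enumerate(sv_alloc):
        cons = alu if fam == "Alu" else l1
        L = len(cons.sequence)
        orientation = "inverted" if sv_type == "INV" else "direct"
        if sv_type == "INV":
            mech = "HR" if rng.random() < p["hr_prob_inv"] else "NHE"
        else:
            mech = "HR" if rng.random() < p["hr_prob"][fam] else "NHE"
        if mech == "HR":
            m = int(np.clip(np.rint(rng.lognormal(np.log(17), 0.4)), 5, 40))
            ins = ""
        else:
            m = int(rng.choice(5, p=p["nhe_mh_probs"]))
            ins = ""
            if rng.random() < p["nhe_insertion_prob"]:
                ins_len = int(np.clip(rng.geometric(0.35), 1, 23))
                ins = random_dna(rng, ins_len, gc=0.45)
        cross = None
        if fam == "Alu" and mech == "HR" and sv_type == "DEL" and cross_queue:
            cross = cross_queue.pop(0)

        if orientation == "inverted":
            s5, s3 = ("+", "-")
        elif rng.random() < p["minus_pair_prob"]:
            s5, s3 = ("-", "-")
        else:
            s5, s3 = ("+", "+")
        if cross is not None:
            s5 = s3 = "+"       # monomer-cross bookkeeping assumes plus-strand pairs

        d5 = float(rng.uniform(*p["divergence_range"]))
        d3 = float(rng.uniform(*p["divergence_range"]))
        t5 = t3 = 0
        if fam == "LINE-1":
            if rng.random() < p["line1_truncation_prob"]:
                t5 = int(rng.integers(500, p["line1_max_truncation"]))
            if rng.random() < p["line1_truncation_prob"]:
                t3 = int(rng.integers(500, p["line1_max_truncation"]))

        prot5, prot3, forced5, forced3 = [], [], {}, {}
        if mech == "HR" and cross is None:
            wins = [w for w in _usable_windows(cons, max(t5, t3), m) if w >= max(t5, t3) + 2]
            if not wins:
                t5 = t3 = 0
                wins = _usable_windows(cons, 0, m)
            w = int(wins[int(rng.integers(len(wins)))])
            c5 = c3 = int(rng.integers(w, w + m + 1))
            prot5 = [(w - 1, w + m + 1)]
            prot3 = [(w, w + m)]
            forced3[w - 1] = _mismatch_base(rng, cons.sequence[w - 1])
            forced3[w + m] = _mismatch_base(rng, cons.sequence[w + m])
            window_start = w
        elif mech == "HR":
            runs_all = _monomer_shared_runs(cons)
            max_rl = max((rl for _, rl in runs_all), default=0)
            if max_rl < 7:
                raise PlantingError("monomers too diverged for a crossing mh window")
            m = min(m, max_rl - 2)  # cap at the longest inter-monomer identity run
            runs = [r for r in runs_all if r[1] >= m + 2]
            rs, rl = runs[int(rng.integers(len(runs)))]
            q = max(1, rs + int(rng.integers(0, rl - m + 1)))
            mA, mB = cons.monomer_bounds[0][0], cons.monomer_bounds[1][0]
            j = q + int(rng.integers(0, m + 1))
            if cross == "single":     # chimera ~ one monomer: 5' part from left monomer
                c5, c3 = mA + j, mB + j
                wa, wb = mA + q, mB + q
            else:                     # chimera ~ three monomers
                c5, c3 = mB + j, mA + j
                wa, wb = mB + q, mA + q
            prot5 = [(wa - 1, wa + m + 1)]
            prot3 = [(wb, wb + m)]
            forced3[wb - 1] = _mismatch_base(rng, cons.sequence[wa - 1])
            forced3[wb + m] = _mismatch_base(rng, cons.sequence[wa + m])
            window_start = wb
        else:  # NHE: breakpoints at distinct consensus offsets; no chimera overlap
            lo = max(t5, t3) + 10
            hi = (cons.polya_span[0] if cons.polya_span else L) - 10
            span = hi - lo - m - 8
            if span < 40:
                t5 = t3 = 0
                lo, span = 10, hi - 10 - m - 8
            a = lo + int(rng.integers(0, span - 20))
            b = a + m + 8 + int(rng.integers(4, max(5, min(span - (a - lo) - m - 8, 120))))
            c_left, c_right = a, min(b, hi - 1)
            # identical tract of exactly m at the junction, mismatched at both edges;
            # c_left sits in the element contributing the chimera's consensus-5' part
            prot_left = [(c_left - 1, c_left + m + 1)]
            forced = {}
            for d in range(m):
                forced[c_right + d] = cons.sequence[c_left + d]
            forced[c_right - 1] = _mismatch_base(rng, cons.sequence[c_left - 1])
            if m == 0:
                forced[c_right] = _mismatch_base(rng, cons.sequence[c_left])
            else:
                forced[c_right + m] = _mismatch_base(rng, cons.sequence[c_left + m])
            prot_right = [(max(0, c_right - 1), c_right + m + 1)]
            # which genomic element hosts c_left (the chimera's 5' side) depends on
            # SV geometry and strand: for DEL it is the 5' element on plus pairs but
            # the 3' element on minus pairs; DUP/mCNV swap; INV keeps the 5' element
            if sv_type == "INV":
                five_hosts_left = True
            elif sv_type == "DEL":
                five_hosts_left = (s5 == "+")
            else:  # DUP / mCNV
                five_hosts_left = (s5 == "-")
            if five_hosts_left:
                c5, c3 = c_left, c_right
                prot5, prot3 = prot_left, prot_right
                forced5, forced3 = {}, forced
            else:
                c5, c3 = c_right, c_left
                prot5, prot3 = prot_right, prot_left
                forced5, forced3 = forced, {}
            window_start = None

        len5 = L - t5
        len3 = L - t3
        cn = 2
        if sv_type == "DUP":
            cn = 3
        elif sv_type == "mCNV":
            cn = int(rng.choice([4, 5, 6]))

        # genomic offsets of the breakpoints within each copy
        off5 = (c5 - t5) if s5 == "+" else (L - c5)
        off3 = (c3 - t3) if s3 == "+" else (L - c3)
        size_med = p["alu_size_median"] if fam == "Alu" else p["line1_size_median"]
        size_sig = p["alu_size_sigma"] if fam == "Alu" else p["line1_size_sigma"]
        target = int(np.clip(rng.lognormal(np.log(size_med), size_sig), 300, 45_000))
        gap = target - len5 - off3 + off5
        if gap < 80:
            gap = 80 + int(rng.integers(0, 40))

        pid = f"ev{k}"
        plans.append({
            "spec": PlantSpec(
                sv_type=sv_type, mechanism=mech, te_family=fam,
                te_orientation=orientation, mh_length=m, junction_insertion=ins,
                divergence_5p=d5, divergence_3p=d3, copy_number=cn, seed=k,
                te5_id=f"{pid}_a", te3_id=f"{pid}_b", window_start=window_start,
                c5=c5, c3=c3, monomer_cross=cross),
            "placement5": TEPlacement(0, cons, d5, s5, t5, tuple(prot5),
                                      dict(forced5) or None, copy_id=f"{pid}_a"),
            "placement3": TEPlacement(0, cons, d3, s3, t3, tuple(prot3), dict(forced3),
                                      copy_id=f"{pid}_b"),
            "len5": len5, "len3": len3, "gap": gap,
            "locus_len": len5 + gap + len3,
        })
    return plans
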