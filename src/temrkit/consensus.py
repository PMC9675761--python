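"""TE consensus sequences and their structural metadata.

A :class:`TEConsensus` carries the consensus DNA of a transposable-element
family together with the structural landmarks the mechanism classifier
needs: monomer boundaries (for the dimeric Alu element), the 3' adenosine
rich tract, and optional RNA-pol-III box annotations (A-Box, B-Box, A'-Box)
used when mapping breakpoint microhomologies onto the consensus.

Because real AluY / L1.3 consensus sequences are external data, the module
also provides *synthetic* consensus builders that emulate the structure that
matters for mechanism inference: an Alu-like dimer of two homologous ~132 bp
monomers separated by an A-rich linker and ending in a poly-A tract, and a
6 kbp L1-like element with a poly-A tail.  Users analysing real genomes load
their own consensus FASTA instead (``read_consensus_fasta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, random_dna

__all__ = [
    "TEConsensus",
    "synthetic_alu_consensus",
    "synthetic_line1_consensus",
    "default_consensus_set",
    "read_consensus_fasta",
    "write_consensus_fasta",
]


@dataclass(frozen=True)
class TEConsensus:
    """A TE family consensus with structural annotations.

    Intervals are 0-based half-open offsets on ``sequence``.
    """

    name: str
    sequence: str
    family: str
    monomer_bounds: tuple[tuple[int, int], ...] = ()
    polya_span: tuple[int, int] | None = None
    boxes: dict = field(default_factory=dict)

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq or set(seq) - set(BASES):
            raise ValueError(f"consensus {self.name!r}: sequence must be non-empty over ACGT")
        object.__setattr__(self, "sequence", seq)
        prev_end = 0
        for s, e in self.monomer_bounds:
            if not (0 <= s < e <= len(seq)) or s < prev_end:
                raise ValueError(f"consensus {self.name!r}: monomer bounds must be ordered, disjoint, in range")
            prev_end = e
        if self.polya_span is not None:
            s, e = self.polya_span
            if not (0 <= s < e <= len(seq)):
                raise ValueError(f"consensus {self.name!r}: polyA span out of range")

    def __len__(self) -> int:
        return len(self.sequence)

    def monomer_of(self, offset: int) -> int | None:
        """Index of the monomer containing ``offset``, or None."""
        for i, (s, e) in enumerate(self.monomer_bounds):
            if s <= offset < e:
                return i
        return None


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            alts = [b for b in BASES if b != out[i]]
            out[i] = alts[int(rng.integers(3))]
    return "".join(out)


def synthetic_alu_consensus(seed: int = 101, monomer_len: int = 132,
                            monomer_divergence: float = 0.10) -> TEConsensus:
    """Synthetic Alu-like consensus (~300 bp).

    Structure mirrors the dimeric Alu element: a left monomer, an A-rich
    linker, a right monomer that is a diverged copy of the left (real Alu
    arms derive from a common FLAM/FRAM ancestor), and a poly-A tail.  The
    sequence itself is random (GC-rich, as Alu bodies are) and labelled
    synthetic; it is NOT the AluY consensus.
    """
    rng = np.random.default_rng(seed)
    left = random_dna(rng, monomer_len, gc=0.58)
    linker = "A" * 5 + "TACA" + "A" * 1          # A5TACA6-style A-rich linker, 10 bp
    right = _mutate(rng, left, monomer_divergence)
    tail = "A" * 26
    seq = left + linker + right + tail
    m2 = monomer_len + len(linker)
    boxes = {
        "A-Box": (14, 35),
        "B-Box": (70, 92),
        "A'-Box": (m2 + 14, m2 + 35),
    }
    return TEConsensus(
        name="AluSyn",
        sequence=seq,
        family="Alu",
        monomer_bounds=((0, monomer_len), (m2, m2 + monomer_len)),
        polya_span=(m2 + monomer_len, len(seq)),
        boxes=boxes,
    )


def synthetic_line1_consensus(seed: int = 103, length: int = 6000) -> TEConsensus:
    """Synthetic LINE-1-like consensus (6 kbp, AT-rich body, poly-A tail).

    Labelled synthetic; it is NOT the L1.3 sequence.
    """
    rng = np.random.default_rng(seed)
    tail = 30
    body = random_dna(rng, length - tail, gc=0.42)
    return TEConsensus(
        name="L1Syn",
        sequence=body + "A" * tail,
        family="LINE-1",
        monomer_bounds=(),
        polya_span=(length - tail, length),
    )


def default_consensus_set(alu_seed: int = 101, line1_seed: int = 103) -> dict[str, TEConsensus]:
    """Family -> consensus mapping used throughout the synthetic testbed."""
    alu = synthetic_alu_consensus(seed=alu_seed)
    l1 = synthetic_line1_consensus(seed=line1_seed)
    return {alu.family: alu, l1.family: l1}


# -- FASTA IO with structural metadata in the header ------------------------
#
# Header grammar (whitespace-separated key=value tokens after the name):
#   >AluSyn family=Alu monomers=0-132,142-274 polyA=274-300 boxes=A-Box:14-35;B-Box:70-92


def _fmt_iv(iv: tuple[int, int]) -> str:
    return f"{iv[0]}-{iv[1]}"


def _parse_iv(txt: str) -> tuple[int, int]:
    a, b = txt.split("-")
    return int(a), int(b)


def write_consensus_fasta(path, consensi) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for c in consensi:
        parts = [f"family={c.family}"]
        if c.monomer_bounds:
            parts.append("monomers=" + ",".join(_fmt_iv(iv) for iv in c.monomer_bounds))
        if c.polya_span:
            parts.append("polyA=" + _fmt_iv(c.polya_span))
        if c.boxes:
            parts.append("boxes=" + ";".join(f"{k}:{_fmt_iv(v)}" for k, v in c.boxes.items()))
        records.append(SeqRecord(Seq(c.sequence), id=c.name, description=" ".join(parts)))
    seqio_write(records, str(path), "fasta")


def read_consensus_fasta(path) -> dict[str, TEConsensus]:
    """Load a consensus set keyed by family from an annotated FASTA."""
    from Bio import SeqIO

    out: dict[str, TEConsensus] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()[1:]
        meta = dict(t.split("=", 1) for t in tokens if "=" in t)
        family = meta.get("family", rec.id)
        monomers = tuple(_parse_iv(t) for t in meta["monomers"].split(",")) if "monomers" in meta else ()
        polya = _parse_iv(meta["polyA"]) if "polyA" in meta else None
        boxes = {}
        if "boxes" in meta:
            for item in meta["boxes"].split(";"):
                k, v = item.split(":")
                boxes[k] = _parse_iv(v)
        out[family] = TEConsensus(rec.id, str(rec.seq), family, monomers, polya, boxes)
    return out
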