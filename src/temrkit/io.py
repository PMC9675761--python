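"""File IO: FASTA, BED-like TSV tables, and minimal symbolic-SV VCF.

All tables are plain TSV with headers so they stay diffable; coordinates
are written 0-based half-open except in VCF (1-based POS, INFO END).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synth import ANNOTATION_COLUMNS, CALLSET_COLUMNS


def write_fasta(path, records: dict[str, str]) -> None:
    """Write name -> sequence mappings as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_annotation(path, annotation: pd.DataFrame) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def write_callset(path, calls: pd.DataFrame) -> None:
    cols = [c for c in CALLSET_COLUMNS if c in calls.columns]
    extra = [c for c in calls.columns if c not in cols]
    calls[cols + extra].to_csv(path, sep="\t", index=False)


def write_sv_vcf(path, calls: pd.DataFrame, contigs: dict[str, int],
                 sample: str = "S1") -> None:
    """Minimal VCF 4.2 with symbolic ALTs (<DEL>/<DUP>/<INV>) via pysam."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of the variant")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in calls.itertuples(index=False):
            sv_type = "DUP" if row.sv_type == "mCNV" else row.sv_type
            rec = vf.new_record(
                contig=row.chrom, start=int(row.start), stop=int(row.end),
                alleles=("N", f"<{sv_type}>"))
            rec.info["SVTYPE"] = sv_type
            rec.info["SVLEN"] = int(row.end - row.start) * (-1 if sv_type == "DEL" else 1)
            vf.write(rec)


def read_sv_vcf(path, caller: str | None = None, technology: str = "SRS",
                sample: str = "S1", pass_only: bool = True) -> pd.DataFrame:
    """Read a symbolic-SV VCF into the internal callset table.

    Mines chrom/start/end/svType plus PR/SR/RS support and the Duphold-style
    depth fold-change (RD/DHFFC) when present; FILTER must be PASS (or
    missing) unless ``pass_only`` is off.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        has_samples = len(vf.header.samples) > 0
        for rec in vf:
            filters = set(rec.filter.keys())
            if pass_only and filters and filters != {"PASS"}:
                continue
            sv_type = rec.info.get("SVTYPE")
            if sv_type not in ("DEL", "DUP", "INV"):
                continue
            end = rec.stop
            pr = sr = rs = rd = None
            if has_samples:
                fmt = rec.samples[0]
                def _pair(v):
                    if v is None:
                        return None
                    if isinstance(v, (tuple, list)):
                        return v[-1]
                    return v
                pr = _pair(fmt.get("PR")) if "PR" in fmt else None
                sr = _pair(fmt.get("SR")) if "SR" in fmt else None
                rs = fmt.get("RS") if "RS" in fmt else None
                for key in ("RD", "DHFFC"):
                    if key in fmt:
                        rd = fmt.get(key)
            for key in ("RD", "DHFFC", "RE"):
                if rd is None and key in rec.info:
                    rd = rec.info.get(key)
            rows.append({"chrom": rec.contig, "start": rec.start, "end": end,
                         "sv_type": sv_type, "caller": caller or "unknown",
                         "technology": technology, "sample": sample,
                         "PR": pr, "SR": sr, "RS": rs, "RD": rd})
    return pd.DataFrame(rows, columns=CALLSET_COLUMNS)


def write_json(path, obj) -> None:
    import json

    import numpy as np

    def default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
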