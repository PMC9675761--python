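"""End-to-end orchestration of the TEMR stages with a file-based interface.

Stages communicate through plain files in an output directory so each can
be rerun independently: ``simulate`` writes the synthetic genome, truth and
per-caller callsets; ``merge`` filters and ensembles them; ``classify``
intersects breakpoints with the TE annotation; ``junction`` reconstructs
microhomologies; ``mechanism`` infers HR/NHE against the consensus set;
``stats`` runs the enrichment statistics.  A manifest with content hashes
and the seed makes reruns verifiable: identical configs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .classify import TEAnnotationIndex, classify_callset, summarize_callset
from .consensus import read_consensus_fasta, write_consensus_fasta
from .ensemble import FilterConfig, filter_calls, merge_by_rank
from .junction import compute_microhomology, infer_junction_insertion
from .mechanism import classify_cohort, extract_flanks, infer_mechanism, percent_similarity
from .stats import (binom_two_tailed, gc_content, sample_control_windows, te_density,
                    welch_t)
from .synth import simulate_study

logger = logging.getLogger("temrkit")

STAGES = ("simulate", "merge", "classify", "junction", "mechanism", "stats")

_DEPS = {
    "merge": ["simulate"],
    "classify": ["merge"],
    "junction": ["classify"],
    "mechanism": ["junction"],
    "stats": ["mechanism"],
}

_OUTPUTS = {
    "simulate": ["reference.fa", "consensus.fa", "te_annotation.tsv", "truth.tsv",
                 "truth.vcf", "alt_windows.tsv"],
    "merge": ["merged.tsv", "filter_log.json"],
    "classify": ["classified.tsv", "classify_summary.json"],
    "junction": ["junctions.tsv"],
    "mechanism": ["mechanism.tsv", "mechanism_summary.json"],
    "stats": ["stats.json"],
}


@dataclass
class PipelineConfig:
    """Run configuration; thresholds default to the published funnel values."""

    out_dir: str = "temrkit_out"
    seed: int = 0
    genome_length: int = 5_000_000
    n_temr: int = 120
    n_background_svs: int = 30
    fp_rate: float = 0.0
    jitter_sd: float | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    overlap_tolerance: int = 0
    align_cap: int = 1500
    control_windows: int = 200
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        fc = FilterConfig(**raw.pop("filter", {}))
        return cls(filter=fc, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


class StageDependencyError(RuntimeError):
    pass


def _outputs_present(out: Path, stage: str) -> bool:
    return all((out / f).exists() for f in _OUTPUTS[stage])


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Run the requested stages in order; returns the manifest dict.

    Raises :class:`StageDependencyError` naming the gap when a stage's
    prerequisite outputs are neither scheduled nor already on disk.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in stages]
    if not ordered:
        raise ValueError(f"no valid stages in {stages!r}")
    for s in ordered:
        for dep in _DEPS.get(s, []):
            if dep not in ordered and not _outputs_present(out, dep):
                raise StageDependencyError(f"stage '{s}' requires outputs of '{dep}'")

    for s in ordered:
        logger.info("stage %s", s)
        globals()[f"_stage_{s}"](config, out)

    manifest = {"seed": config.seed, "config": config.to_dict(),
                "stages": ordered, "files": {}}
    for s in ordered:
        for f in _OUTPUTS[s]:
            fp = out / f
            if fp.exists():
                manifest["files"][f] = hashlib.sha256(fp.read_bytes()).hexdigest()
    callset_dir = out / "callsets"
    if callset_dir.exists():
        for fp in sorted(callset_dir.glob("*.tsv")):
            manifest["files"][f"callsets/{fp.name}"] = hashlib.sha256(fp.read_bytes()).hexdigest()
    tio.write_json(out / "manifest.json", manifest)
    return manifest


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sim = simulate_study(seed=cfg.seed, genome_length=cfg.genome_length,
                         n_temr=cfg.n_temr, n_background_svs=cfg.n_background_svs)
    ref = sim.reference
    tio.write_fasta(out / "reference.fa", {ref.chrom: ref.sequence})
    write_consensus_fasta(out / "consensus.fa", sim.consensus_set.values())
    tio.write_annotation(out / "te_annotation.tsv", ref.annotation)
    tdf = sim.truth_frame
    tio.write_table(out / "truth.tsv", tdf)
    tio.write_sv_vcf(out / "truth.vcf", tdf, {ref.chrom: len(ref.sequence)})
    win = pd.DataFrame(
        [{"truth_index": i, "win_start": ws, "win_end": we, "alt_seq": seq}
         for i, (ws, we, seq) in sim.alt_windows.items()])
    tio.write_table(out / "alt_windows.tsv", win)
    (out / "callsets").mkdir(exist_ok=True)
    for caller, df in sim.callsets(fp_rate=cfg.fp_rate, jitter_sd=cfg.jitter_sd).items():
        tio.write_callset(out / "callsets" / f"{caller}.tsv", df)


def _stage_merge(cfg: PipelineConfig, out: Path) -> None:
    frames = [tio.read_table(fp) for fp in sorted((out / "callsets").glob("*.tsv"))]
    calls = pd.concat(frames, ignore_index=True)
    retained, rejected = filter_calls(calls, cfg=cfg.filter)
    merged = merge_by_rank(retained, cfg.filter)
    tio.write_table(out / "merged.tsv", merged)
    counts = {"input": int(len(calls)), "retained": int(len(retained)),
              "rejected": int(len(rejected)),
              "rejected_by_reason": rejected.reason.value_counts().to_dict() if len(rejected) else {},
              "merged": int(len(merged))}
    tio.write_json(out / "filter_log.json", counts)
    logger.info("filter funnel: %s", counts)


def _stage_classify(cfg: PipelineConfig, out: Path) -> None:
    merged = tio.read_table(out / "merged.tsv")
    ann = tio.read_table(out / "te_annotation.tsv")
    classified = classify_callset(merged, ann)
    tio.write_table(out / "classified.tsv", classified)
    tio.write_json(out / "classify_summary.json", summarize_callset(classified))


def _stage_junction(cfg: PipelineConfig, out: Path) -> None:
    classified = tio.read_table(out / "classified.tsv")
    ref = tio.read_fasta(out / "reference.fa")
    windows = tio.read_table(out / "alt_windows.tsv")
    truth = tio.read_table(out / "truth.tsv")
    win_by_iv = {}
    for w in windows.itertuples(index=False):
        t = truth.iloc[int(w.truth_index)]
        win_by_iv[(t.chrom, int(t.start), int(t.end))] = w
    rows = []
    for sv in classified.itertuples(index=False):
        refseq = ref[sv.chrom]
        call = compute_microhomology(refseq, int(sv.start), int(sv.end),
                                     "DUP" if sv.sv_type == "mCNV" else sv.sv_type)
        ins = ""
        w = win_by_iv.get((sv.chrom, int(sv.start), int(sv.end)))
        if w is not None and sv.sv_type == "DEL":
            local5 = int(sv.start) - int(w.win_start)
            local3 = int(sv.end) - int(w.win_start)
            refwin = refseq[int(w.win_start):int(w.win_end)]
            alt_seq = "" if pd.isna(w.alt_seq) else str(w.alt_seq)
            if alt_seq:
                ins = infer_junction_insertion(refwin, alt_seq, local5, local3)
        rows.append({"chrom": sv.chrom, "start": sv.start, "end": sv.end,
                     "sv_type": sv.sv_type,
                     "mh_length": call.mh_length, "mh_sequence": call.mh_sequence,
                     "left_extension": call.left_extension,
                     "right_extension": call.right_extension,
                     "junction_insertion": ins,
                     "ambiguity_start": call.breakpoint_ambiguity_range[0],
                     "ambiguity_end": call.breakpoint_ambiguity_range[1]})
    tio.write_table(out / "junctions.tsv", pd.DataFrame(rows))


def _stage_mechanism(cfg: PipelineConfig, out: Path) -> None:
    classified = tio.read_table(out / "classified.tsv")
    junctions = tio.read_table(out / "junctions.tsv")
    ann = tio.read_table(out / "te_annotation.tsv")
    ref = tio.read_fasta(out / "reference.fa")
    consensi = read_consensus_fasta(out / "consensus.fa")
    index = TEAnnotationIndex(ann)
    jx = junctions.set_index(["chrom", "start", "end"])
    rows = []
    for sv in classified.itertuples(index=False):
        row = {"chrom": sv.chrom, "start": sv.start, "end": sv.end,
               "sv_type": sv.sv_type, "is_temr": sv.is_temr,
               "te_family": sv.te_family, "orientation_class": sv.orientation_class,
               "mechanism": None, "overlap_bp": None,
               "consensus_junction_position": None, "monomer_cross": None,
               "review_reason": None, "mh_length": None, "similarity_percent": None}
        if sv.is_temr and sv.te_family in consensi:
            refseq = ref[sv.chrom]
            te5 = index.query(sv.chrom, int(sv.start))
            te3 = index.query(sv.chrom, int(sv.end))
            j = jx.loc[(sv.chrom, sv.start, sv.end)]
            if isinstance(j, pd.DataFrame):
                j = j.iloc[0]
            mh_seq = "" if pd.isna(j.mh_sequence) else str(j.mh_sequence)
            flanks = extract_flanks(refseq, sv.sv_type, int(sv.start), int(sv.end), te5, te3)
            call = infer_mechanism(flanks, mh_seq, consensi[sv.te_family],
                                   overlap_tolerance=cfg.overlap_tolerance,
                                   align_cap=cfg.align_cap)
            cs5 = refseq[te5.te_start:te5.te_end]
            cs3 = refseq[te3.te_start:te3.te_end]
            from ._seq import revcomp
            if te5.strand == "-":
                cs5 = revcomp(cs5)
            if te3.strand == "-":
                cs3 = revcomp(cs3)
            row.update({
                "mechanism": call.label, "overlap_bp": call.overlap_bp,
                "consensus_junction_position": call.consensus_junction_position,
                "monomer_cross": call.monomer_cross, "review_reason": call.review_reason,
                "mh_length": int(j.mh_length),
                "similarity_percent": round(percent_similarity(cs5, cs3), 2),
            })
        rows.append(row)
    mdf = pd.DataFrame(rows)
    tio.write_table(out / "mechanism.tsv", mdf)
    cohort = classify_cohort(mdf[mdf.is_temr].rename(columns={})) if mdf.is_temr.any() else {}
    tio.write_json(out / "mechanism_summary.json", cohort)


def _stage_stats(cfg: PipelineConfig, out: Path) -> None:
    mech = tio.read_table(out / "mechanism.tsv")
    junctions = tio.read_table(out / "junctions.tsv")
    ann = tio.read_table(out / "te_annotation.tsv")
    ref = tio.read_fasta(out / "reference.fa")
    chrom = next(iter(ref))
    genome_sizes = {chrom: len(ref[chrom])}
    temrs = mech[mech.is_temr.astype(bool)]
    result = {}

    # microhomology summaries (tract lengths, GC of 5+ bp tracts)
    jx = junctions.set_index(["chrom", "start", "end"])
    mh_all, gc_vals = [], []
    for sv in temrs.itertuples(index=False):
        j = jx.loc[(sv.chrom, sv.start, sv.end)]
        if isinstance(j, pd.DataFrame):
            j = j.iloc[0]
        mh_all.append(int(j.mh_length))
        if int(j.mh_length) >= 5 and isinstance(j.mh_sequence, str):
            gc_vals.append(gc_content(j.mh_sequence))
    result["mh_median"] = float(np.median(mh_all)) if mh_all else None
    hr_mask = (temrs.mechanism == "HR").to_numpy()
    nhe_mask = (temrs.mechanism == "NHE").to_numpy()
    mh_arr = np.array(mh_all)
    result["mh_median_hr"] = float(np.median(mh_arr[hr_mask])) if hr_mask.any() else None
    result["mh_median_nhe"] = float(np.median(mh_arr[nhe_mask])) if nhe_mask.any() else None
    result["mh_gc_median"] = float(np.median(gc_vals)) if gc_vals else None
    result["similarity_median_hr"] = (float(temrs.similarity_percent[hr_mask].median())
                                      if hr_mask.any() else None)
    result["similarity_median_nhe"] = (float(temrs.similarity_percent[nhe_mask].median())
                                       if nhe_mask.any() else None)

    # TE density of Alu TEMRs vs random control windows
    alu = temrs[temrs.te_family == "Alu"]
    if len(alu) >= 2:
        dens = [te_density((sv.chrom, sv.start, sv.end), ann, "Alu",
                           genome_sizes=genome_sizes)
                for sv in alu.itertuples(index=False)]
        try:
            controls = sample_control_windows(cfg.control_windows, genome_sizes, ann,
                                              "Alu", seed=cfg.seed)
            result["alu_density"] = {
                "temr_mean": float(np.mean(dens)), "control_mean": float(np.mean(controls)),
                "welch": welch_t(dens, controls)}
        except RuntimeError as exc:
            result["alu_density"] = {"error": str(exc)}

    # monomer-crossing chimera imbalance (two-tailed exact binomial)
    single = int((temrs.monomer_cross == "left-to-right").sum())
    triple = int((temrs.monomer_cross == "right-to-left").sum())
    if single + triple:
        result["monomer_binomial"] = {
            "single": single, "three": triple,
            "p": binom_two_tailed(min(single, triple), single + triple)}
    tio.write_json(out / "stats.json", result)


def summarize(out_dir) -> str:
    """Render a plain-text report from existing stage outputs (no recompute)."""
    out = Path(out_dir)
    lines = ["temrkit run summary", "==================="]
    f = out / "filter_log.json"
    if f.exists():
        c = json.loads(f.read_text())
        lines.append(f"calls in/retained/merged: {c.get('input')}/{c.get('retained')}/{c.get('merged')}")
    f = out / "classify_summary.json"
    if f.exists():
        c = json.loads(f.read_text())
        lines.append(f"SVs: {c['n_sv']}  TEMRs: {c['n_temr']} ({c['temr_percent']}%)")
        lines.append(f"TEMRs by family: {c['by_family']}")
        lines.append(f"TEMRs by type: {c['by_sv_type']}  orientation: {c['by_orientation']}")
        if c.get("median_temr_size") is not None:
            lines.append(f"median TEMR size: {c['median_temr_size']:.0f} bp")
    f = out / "mechanism_summary.json"
    if f.exists():
        c = json.loads(f.read_text())
        if c:
            lines.append(f"mechanism: HR {c['n_hr']} / NHE {c['n_nhe']} "
                         f"(categorized {c['percent_categorized']}%, "
                         f"HR fraction {c['hr_fraction_percent']}%)")
            lines.append(f"monomer chimeras (single/three): "
                         f"{c['monomer_chimeras']['single']}/{c['monomer_chimeras']['three']}")
    f = out / "stats.json"
    if f.exists():
        c = json.loads(f.read_text())
        if c.get("mh_median") is not None:
            lines.append(f"median microhomology: {c['mh_median']:.0f} bp "
                         f"(HR {c.get('mh_median_hr')}, NHE {c.get('mh_median_nhe')})")
        if c.get("alu_density") and "welch" in c["alu_density"]:
            ad = c["alu_density"]
            lines.append(f"Alu density TEMR vs control: {ad['temr_mean']:.1f}% vs "
                         f"{ad['control_mean']:.1f}% (p={ad['welch']['p']:.2g})")
        if "monomer_binomial" in c:
            mb = c["monomer_binomial"]
            lines.append(f"monomer chimera imbalance p = {mb['p']:.3f}")
    if len(lines) == 2:
        lines.append("(no stage outputs found)")
    return "\n".join(lines)
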