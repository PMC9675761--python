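"""Infer the repair mechanism (HR vs NHE) behind planted TEMRs.

For each event the junction flanks are read in consensus orientation and
aligned to the family consensus; the event is homologous recombination (HR)
when the flanks' consensus spans overlap by exactly the junction
microhomology (the chimeric element reconstructs a full TE), and
non-homologous repair (NHE) when they fail to overlap.  Alu chimeras
recombined between homologous positions of different monomers are caught by
a monomer-coordinate retry.
"""

from temrkit import (TEAnnotationIndex, classify_cohort, compute_microhomology,
                     extract_flanks, infer_mechanism)
from temrkit.synth import simulate_study

sim = simulate_study(seed=7, genome_length=1_500_000, n_temr=30, n_background_svs=0)
index = TEAnnotationIndex(sim.reference.annotation)
ref = sim.reference.sequence

rows = []
correct = 0
for t in sim.truth:
    te5 = index.query(t.chrom, t.start)
    te3 = index.query(t.chrom, t.end)
    mh = compute_microhomology(ref, t.start, t.end,
                               "DUP" if t.sv_type == "mCNV" else t.sv_type)
    flanks = extract_flanks(ref, t.sv_type, t.start, t.end, te5, te3)
    call = infer_mechanism(flanks, mh.mh_sequence, sim.consensus_set[t.te_family])
    rows.append((t.te_family, call))
    correct += call.label == t.mechanism

summary = classify_cohort(rows)
print(f"recovered mechanism for {correct}/{len(sim.truth)} planted events")
print(f"HR: {summary['n_hr']}  NHE: {summary['n_nhe']}  "
      f"manual review: {summary['n_manual_review']}")
print(f"systematically categorized: {summary['percent_categorized']}%")
print(f"monomer-crossing chimeras (single/three-monomer): "
      f"{summary['monomer_chimeras']['single']}/{summary['monomer_chimeras']['three']}")

# All planted labels should be recovered; the single:three monomer-chimera
# tally mirrors the generator's 1:9 default, the imbalance that an exact
# binomial test scores at p = 0.021.
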