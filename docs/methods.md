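# Methods

This note records the models, conventions and design choices behind temrkit,
in the order the pipeline applies them. Coordinates are 0-based half-open
throughout the library; VCF output converts at the boundary.

## TEMR model

A transposable element-mediated rearrangement (TEMR) is a structural variant
(deletion, duplication, inversion or multi-copy CNV) whose two breakpoints
fall inside *different* TE copies of the *same* family. Two homologous
elements provide the substrate for ectopic repair; the product carries a
single chimeric element at the junction. "Family" means the
RepeatMasker-style family level (Alu, LINE-1, ERVL-MaLR, ...); an SV with
zero or one breakpoint in a TE, with both breakpoints in one and the same
copy, or spanning two different families is non-TEMR. Orientation class is
`direct` when the two copies share a strand and `inverted` otherwise;
inversions require opposite-orientation substrates by construction of their
junction geometry.

## Ensemble filtering and merging

Filter thresholds (all configurable on `FilterConfig`): SV size within
[50 bp, 50 kbp]; neither breakpoint within 500 bp of an assembly gap or
centromere; less than 50% of the span covered by simple repeats; read
support SR ≥ 5 or PR ≥ 10 (short reads) / RS ≥ 5 (long reads); depth ratio
RD < 0.7 for deletions and RD > 1.3 for duplications. The depth filter is
not applied to inversions (copy-neutral). Rejected calls carry a reason code
with precedence `bad_type > size > exclusion > simple_repeat > support >
depth`; a call violating several rules is logged under the first.

Merging clusters same-type calls by single-linkage at reciprocal overlap
RO ≥ 0.8 and keeps the coordinates of the highest-ranked caller
(SRS: Manta > DELLY > LUMPY; LRS: pbsv > Sniffles > SVIM), ties broken by
smaller start then smaller end — output coordinates always belong to exactly
one input caller, never an average. The high-confidence rule — a record
needs ≥ 2 supporting callers within a technology, or cross-technology RO
support — is the package's explicit operationalization of an ensemble
false-positive screen; both thresholds are configurable. When both
technologies retain an event, the short-read record's coordinates are kept:
the top-ranked short-read caller carries the most precise junctions, and
junction analyses downstream depend on base-exact breakpoints. Re-merging a
merged callset is a no-op (supporter lists are unioned, not recounted).

Cross-sample merging clusters at the same RO threshold and retains the
coordinates of the lexicographically first carrier sample. Duplication
curation validates a DUP call against assembly insertions: an insertion
within the span ± 500 bp whose length matches the duplication length at
min/max ≥ 0.9.

## Junction microhomology

For breakpoints (bp5, bp3), the microhomology is the maximal junction
ambiguity: the right extension is the longest shared prefix of
`ref[bp5..)` and `ref[bp3..)`, the left extension the longest shared suffix
of `ref[..bp5)` and `ref[..bp3)`; both are capped so the total cannot exceed
the SV length. Every breakpoint pair inside the ambiguity range (length
mh + 1) reconstructs the same alternate allele — a property the test suite
asserts by string equality. Only perfect identity counts toward mh;
junction insertions never contribute; near-perfect ("homeologous") tracts
are reported separately by a ≥ 90%-identity window scan. For inversions the
distal flank is compared in reverse complement; writing the two junctions
out shows their tracts are mirror images (the left extension of one is the
right extension of the other), so both junctions carry the same mh length
and the call stores both values.

Secondary junction complexities (the extra deletions and insertions that
accompany some inversions) are detected by globally aligning the observed
alternate against the alternate expected from a clean rearrangement using
affine gap scoring (match +5, mismatch −4, open 10, extend 0.5) and
reporting gaps ≥ 5 bp within 500 bp of a junction. Affine gaps matter here:
a unit-cost edit-distance alignment fragments a 38 bp gap into pieces
separated by chance matches and misreports sizes.

## Mechanism inference

Flanks are extracted in consensus orientation. The chimeric element takes
its consensus-5' part ("head") from one copy and its 3' part ("tail") from
the other; which copy contributes the head depends on SV geometry *and*
strand — for a deletion between plus-strand copies the genomically 5' element
is the head, between minus-strand copies the 3' element is; duplications
swap; inversions keep the 5' element. Both flanks are extended through the
microhomology so each carries the full tract; for a homologous-recombination
event the flanks' consensus spans then overlap by exactly the microhomology
length.

Alignment to the family consensus uses Smith–Waterman with EDNAFULL-style
scoring: match +5, mismatch −4, gap open 10, gap extend 0.5, where a gap of
length L costs 10 + 0.5(L−1). Identity is counted over alignment columns
including gaps. `percent_similarity` aligns the pair in a canonical order so
the value is symmetric even when co-optimal alignments with different gap
placements exist. Flanks longer than 1500 bp (truncated or full-length
LINE-1s) are aligned through their junction-proximal 1500 bp: only the
junction-side endpoint of the consensus span enters the overlap test, and
the cap bounds the O(nm) dynamic program; the cap is configurable
(`align_cap`).

Decision rule, in order:

1. a microhomology of ≥ 5 bp composed of ≥ 90% A (or ≥ 90% T) →
   `MANUAL_REVIEW` (reason `polyA`). The length floor exists because 1–4 bp
   A/T tracts — the bulk of end-joining junctions — would otherwise be
   mass-flagged, while the poly-A ambiguity this flag guards against arises
   from breakpoints in actual adenosine-rich tails.
2. overlap = e1 − s2 (e1 = consensus end of the 5' flank, s2 = consensus
   start of the 3' flank, both corrected for any unaligned junction-side
   query bases). **HR** when overlap ≥ 1 and overlap == mh (tolerance 0 by
   default; `overlap_tolerance` is exposed because SNVs adjacent to real
   junctions can shift alignment ends by a base).
3. Alu monomer retry when step 2 fails and mh ≥ 1: project e1 and s2 into
   the monomers containing them; if they land in *different* monomers and
   the monomer-relative overlap equals mh, the event is HR with a
   `monomer_cross` direction — left-to-right crossings yield single-monomer
   (~150 bp) chimeras, right-to-left crossings three-monomer (~450 bp)
   chimeras. The projection uses the full-consensus alignment endpoints
   rather than a per-monomer re-alignment: with ~90%-similar monomers, a
   free local alignment of a flank against one monomer can latch onto the
   homologous block of the *other* monomer and lose the junction endpoint.
4. a LINE-1 flank whose consensus alignment covers < 50% of it →
   `MANUAL_REVIEW` (reason `truncated`).
5. **NHE** when the flanks fail to overlap (overlap ≤ 0) — this covers both
   blunt junctions and the 1–4 bp chance microhomologies typical of
   end-joining.
6. anything else (overlap > 0 but ≠ mh) → `MANUAL_REVIEW` (reason
   `discordant`).

Every HR call satisfies overlap == mh by construction of the rule; the test
suite asserts it on every call. Cohort summaries report both
published-style ratios whose denominators differ (the share of HR events
that are Alu-driven, and the share of Alu events that are HR-driven), the
fraction systematically categorized, and the single- vs three-monomer
chimera tally that feeds the exact binomial test.

## Statistics

Thin wrappers over scipy with explicit conventions: Welch's t with
Welch–Satterthwaite df (identical constant samples return t = 0, p = 1 with
a degeneracy flag); exact two-tailed binomial via the small
point-probability method (the convention that prints 0.021 for 1 of 10 at
p₀ = 0.5); Fisher's exact test by hypergeometric enumeration; Spearman with
average ranks for ties. No multiple-testing correction is applied by
default. TE density is the percent of family TE sequence in the 50 kbp
window centred on the SV midpoint, clipped at chromosome ends with a
renormalized denominator; control windows are rejection-sampled uniformly
(≥ 2 family TEs required, iteration cap 1000 × n) and compared as a pooled
sample in the Welch test. Copy number from read depth is
CN = round(2 × depth ratio), flagged `low_unique` when < 7% of the locus is
outside TE annotation. Genic categories (exonic > intronic > proximal
within 5 kbp > intergenic) partition any event set.

## Synthetic-data generator

The generator is first-class, tested code: it defines the conditions every
stage is validated under.

**Consensus sequences.** The built-in consensus objects are *synthetic*:
an Alu-like 300 bp dimer (two 132 bp monomers — the right a 10%-diverged
copy of the left, mirroring the shared FLAM/FRAM ancestry of real Alu arms —
an A-rich linker, a poly-A tail, and A-Box/B-Box/A'-Box annotations) and a
6 kbp L1-like element with a poly-A tail. They reproduce the structural
features mechanism inference depends on (monomer homology, poly-A tracts,
element lengths) but are not the real AluY/L1.3 sequences; analyses of real
genomes load those from a consensus FASTA with the same metadata header.

**TE copies** derive from the consensus by i.i.d. substitutions
(substitution-only by default, which keeps microhomology tracts analytically
controllable), optional 5' truncation for LINE-1s, and strand. Realized
divergence is recorded from the mutation log, not the requested rate.

**Planting.** HR events force an identical, substitution-free window of
exactly the requested mh length at the same consensus offset in both copies,
with both window boundaries forced to mismatch so the realized microhomology
equals the request; the junction is placed uniformly inside the window.
Monomer-crossing events pick the window inside an identity run shared by
the two consensus monomers. NHE events place breakpoints at consensus
offsets ≥ mh + 8 apart (so the flanks cannot overlap along the consensus),
copy a 0–4 bp tract between the copies for the junction microhomology, and
optionally insert 1–23 bp at the junction. Which genomic copy hosts the
chimera's consensus-5' side follows the same geometry/strand rule the
classifier uses. Planting never edits the reference: windows are forced at
genome-construction time, and `plant_temr` raises when a requested window
does not exist as a maximal identical tract.

**Study-scale defaults** (a 5 Mbp single chromosome, 120 TEMRs, 30
background non-TE deletions) mirror the observed composition of human TEMR
callsets: 80% Alu / 20% LINE-1; ~90% deletions with small numbers of
duplications, inversions and mCNVs; HR probability 0.89 for Alu, 0.375 for
LINE-1, 0.73 for inversions; HR microhomologies lognormal with median 17 bp
(clipped to [5, 40]); NHE microhomologies 0–4 bp with median 1; junction
insertions in 35% of NHE events (1–23 bp, median 2); copy divergence uniform
on [0.01, 0.15]; Alu TEMR sizes lognormal with median ~1.2 kbp and LINE-1
~4.5 kbp; 30% of direct pairs on the minus strand; ten monomer-crossing
chimeras at a 1:9 single:three-monomer ratio; 60% of LINE-1 copies
5'-truncated.

**Callsets.** Six callers (three short-read, three long-read) report every
true event with rounded-Gaussian breakpoint jitter (defaults: Manta 0 bp —
consistent with its observed base-exact junctions when it reports homology —
DELLY 3, LUMPY 5, pbsv 2, Sniffles 5, SVIM 8), Poisson support counts
(SR ~ 12, PR ~ 20, RS ~ 15) and type-consistent depth ratios
(DEL 0.5, DUP cn/2, INV 1.0, noise sd 0.05). False positives are random
intervals that avoid truth; per-caller noise rarely reaches 80% reciprocal
overlap between two callers, which is what the ensemble screen exploits.
The per-caller jitter magnitudes are free parameters of the simulation (the
ranking they justify is published, the magnitudes are not).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level errors and alignment artifacts (no
FASTQ/BAM simulation), SNV/indel background variation near junctions,
diploid phasing, nested/overlapping repeat structure, segmental
duplications, and reference bias. On real callsets the mechanism classifier
will see discordant overlaps from junction-adjacent SNVs (hence the exposed
`overlap_tolerance`) and manual-review rates closer to the ~10% reported for
human data than the ~0% observed on clean synthetic cohorts.

## Numerical and degenerate-input choices

- Microhomology extensions are capped at the SV length; zero-length SVs and
  inverted coordinates raise.
- Single-linkage RO clustering with deterministic tie-breaks makes merged
  output order-independent; annotation row order never affects
  classification (nested annotations resolve to the smallest containing
  element, with an ambiguity flag).
- The statistical calibration benchmark uses n = 17 draws per replicate for
  the binomial test: the test is discrete, so its attained size depends on
  n, and at n = 17 the attained two-sided size (2 · P(X ≤ 4) = 0.0490) sits
  close to the nominal 5%, making a type-I check informative; at most other
  n the attained size is far below nominal by construction, not by error.
- All randomness flows from numpy Generators derived from a single seed;
  identical seeds give byte-identical FASTA/TSV/VCF outputs (asserted via
  manifest hashes).
- Problem sizes used by the shipped benchmarks: the end-to-end validation
  runs a 5 Mbp genome with 120 planted TEMRs; the per-class mechanism
  benchmark plants 240 events (≥ 100 per mechanism class) on 8 Mbp; type-I
  calibrations use 10,000 null replicates. These sizes give stable
  percentages while keeping the full suite quick to run.

## Known limitations

- Breakend (BND) translocations, genotyping and multi-allelic merging are
  out of scope; mCNVs are represented as DUP records with read-depth copy
  number estimated separately.
- The classifier analyses the 5' junction chimera of an inversion; the 3'
  junction carries the mirror-image tract and is not separately classified.
- `percent_similarity` on full-length LINE-1 pairs is O(nm) and dominates
  runtime for LINE-1-rich cohorts.
- Exact-point breakpoint intersection is used against the TE annotation
  (no padding); callers with multi-base breakpoint uncertainty should be
  merged through the rank-based ensemble first, which is what restores
  base-exact coordinates when a precise caller is present.
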