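# Methods

This note documents the models, conventions and numerical choices behind
`puctools`, and what its synthetic benchmarks do and do not show about
real data.

## Gene discovery and operon pairing

Candidate LH genes are found by two entry paths that produce the same
record type. When GFF3 annotations are supplied, each annotated CDS is
translated (NCBI table 11) and scored directly; unannotated regions are
scanned for ORFs on both strands with start codons ATG/GTG/TTG, ending at
the first in-frame stop. The peptide-length window is 40–75 aa — wider
than the canonical α (60–65 aa) and β (~50 aa) lengths so that divergent
strains are not missed; the role (α vs β) comes from scoring, not length.

Scoring is global pairwise alignment (BLOSUM62, affine gaps: open 10,
extend 1 in score units, free terminal gaps) against a labelled reference
set of α/β peptides. Two identity statistics are used deliberately:

- **role calling** uses matches over *all* alignment columns, so a short
  fragment that matches a tenth of a reference scores ~0.1, not 1.0;
- **classification identities** (LH2 subtyping, numbering sanity check)
  use matches over aligned columns excluding terminal gaps, appropriate
  for comparing full-length peptides.

The role-calling threshold is 0.60: β peptides are >90% identical within
the genus, and 0.60 still admits divergent clades while excluding random
ORFs (a shuffled α scores ≈0.1–0.2). Annotated CDS that fail peptide-level
scoring are rescored at the nucleotide level against the reference coding
sequences — this is how a frameshifted pseudogene, whose conceptual
translation is garbled, is still recognized as a *puc* gene. Nested ORFs
sharing a stop codon are collapsed to the best-scoring start.

Pairing follows the *pucBA* convention: each β is matched to the nearest
downstream α on the same strand (downstream in transcription orientation)
with an intergenic gap ≤300 bp; pairing is a matching, unpaired α genes
become lone-α operons (one real strain carries such a gene) and unpaired
β genes are flagged.

## Signature classification

Signature positions 26/44/45 are defined in the reference LH2A α
coordinate frame; the frame is transferred to each query by global
alignment, so insertions in the query are absorbed and deletions produce
an explicit gap marker. If alignment identity falls below 0.3 the
numbering is considered unreliable and the gene is reported unclassified
rather than guessed. The decision rules, in precedence order:

1. Y44 ∧ W45 → LH2
2. Y44 ∧ M45 → LH2′
3. M26 ∧ F44 ∧ M45 → LH4
4. F44 ∧ (M45 ∨ F45) ∧ ¬M26 → LH3
5. otherwise unclassified

LH4 precedes LH3 because the published LH3 pattern (F44 with M45 or F45)
overlaps the LH4 pattern; the M26 mark is what separates them, and this
precedence is the only reading that makes the four rows disjoint. The
classifier is a total deterministic function of the residue triple,
verified exhaustively over all 20³ triples against an independently coded
rule table. Exact residue matching is required; conservative
substitutions yield "unclassified" and are reported, never forced.

LH2 subtypes (A/B/E) are assigned by maximal whole-peptide identity to
the reference strain's three LH2 α peptides; ties break lexicographically
(A < B < E) with an explicit tie flag, since no published rule exists.

**Pseudogenes** are called when (a) the net indel implied by a global
nucleotide alignment to the reference CDS is not divisible by three
(frameshift — e.g. the classic 2-bp insertion), or (b) conceptual
translation hits an internal stop before 90% of the reference length.
A pseudogene still receives an LH type where its signature is readable
(its conceptual peptide is projected through the reference frame so a
small indel does not scramble downstream residues), but it is excluded
from intact inventory counts and annotated "Pseudo", matching how strain
inventories report such genes. β genes inherit their operon's α category
(LH2A→pucBa, LH2B→pucBb, LH3→pucBc, LH4→pucBd, LH2E→pucBe); β genes in
LH2′ or unclassified operons are reported uncategorized.

## Phylogenetics

Coding sequences are aligned codon-wise: 4-mer distances feed a UPGMA
guide tree (scipy linkage), then profiles are merged progressively with
Needleman–Wunsch over codon columns (per-nucleotide match +1 / mismatch
−1 inside a codon, linear gap penalty −2 per codon column), so gaps only
ever appear in whole-codon units. Trailing partial codons are trimmed
with a warning.

Distances are in substitutions per site, with **pairwise deletion**:
columns containing a gap or ambiguity code in either member of a pair are
dropped for that pair only. Three models:

- **JC69**: d = −(3/4)·ln(1 − (4/3)p).
- **TN93**: the closed form with empirical per-pair base frequencies.
- **MCL** (maximum composite likelihood, the default): the TN93
  purine/pyrimidine transition-transversion ratios (k₁, k₂) are estimated
  once by maximizing the summed pairwise multinomial log-likelihood over
  all pairs (Nelder–Mead over log k, with an inner bounded 1-D search for
  each pair's distance), with pooled empirical base frequencies; each
  pair's distance is then re-estimated under the shared parameters. This
  implements the cited method's core idea — pooled parameter estimation,
  per-pair distances; bit-level replication of MEGA5 internals is out of
  scope. On equal-rate, equal-frequency data MCL agrees with JC69 to
  <0.01 substitutions/site. The TN93 expected difference fractions are
  verified against a matrix-exponential oracle to 1e-12.

Pairs at or beyond model saturation are flagged, reported, and refuse
neighbor joining with an error naming the pairs (bootstrap replicates
substitute the replicate's largest finite distance so a replicate still
contributes a topology).

Neighbor joining is the standard Q-matrix/Studier–Keppler algorithm,
deterministic given the matrix (ties break on the first row-major
minimum). Negative branch-length estimates are clamped to zero with the
deficit moved to the adjacent (sister) branch, preserving path lengths.
NJ recovers topology and branch lengths exactly on additive matrices
(tested against exhaustive topology enumeration + least squares at n=4
and against random additive trees up to n=8, and cross-checked against an
independent NJ implementation).

Bootstrap resamples alignment columns with replacement — codon triplets
by default for codon alignments, per-site optionally, since the original
analysis does not state which — rebuilds the tree per replicate, and
reports per-edge support as the percentage of replicates containing the
same leaf bipartition. A seed is mandatory; supports are bit-reproducible
for a fixed seed. The default is 1,000 replicates (the study used 10,000;
configurable). Reports display supports ≥50% per the usual convention;
machine output always carries all values.

## Expression

rpkm = count / ((length/1000) · (library/10⁶)), with library = uniquely
mapped reads per sample and length = annotated CDS length (no
effective-length correction — this matches the plain rpkm definition).
Replicate samples are averaged on the rpkm scale and the replicate count
recorded. The HL/LL comparison is deliberately descriptive, matching how
these transcript levels are reported: log₂((rpkm_b + c)/(rpkm_a + c))
with pseudocount c = 1 rpkm, plus each gene's genome-wide expression rank
per condition. No differential-test model is added. Per-category
aggregation emits both per-gene values and category sums; categories with
no gene in a strain are reported absent, not zero.

## Spectra

Whole-cell absorption peaks are local maxima of a moving-average-smoothed
trace (centered window, default 5 points) above a prominence threshold,
with each maximum relocated to the vertex of a parabola fitted over ±4
grid points — broad bands (σ≈8 nm) have nearly flat tops, and the
refinement stabilizes their positions against noise. The diagnostic band
catalog is LH2 {800, 860}, LH3 {800, 820}, LH4 {800}, LH2′ {800, 840},
LH1 {875} (whole-cell values; the isolated LH2 complex's red band at
850 nm is recorded alongside). Matching tolerance is ±8 nm, covering the
isolated-vs-whole-cell shift.

Inference is consistency evidence, never a unique deconvolution: each
complex reports matched/total diagnostic bands, and a fully supported
complex is flagged ambiguous when its band set is a strict subset of
another fully supported complex's (an 800-only match for LH4 cannot be
told apart from LH2's own 800-nm band when LH2 is present). Inference is
monotone — adding a peak never removes support. Note the physical limit:
at σ=8 the LH3 800/820 doublet is barely bimodal (saddle depth ≈0.13 of
peak height), so under noise the 800-nm band genuinely masks the 820-nm
one; the package reports the partial evidence rather than inventing a
second peak.

## Synthetic data

The generator emulates the study's data shapes so every stage can be
tested against known truth with no downloads:

- **Reference stand-ins** (`make_reference_set`): α peptides of 62 aa
  with each class's signature planted at positions 26/44/45; LH2 subtypes
  share the LH2 signature but differ at ≥15% of other positions (so
  subtype assignment is unambiguous); β peptides of 50 aa, mutually >90%
  identical. Coding sequences are back-translated with seeded codon
  choice. These are constructed stand-ins, not database sequences; real
  reference FASTAs drop in via the refs path.
- **Genomes**: operons (β, gap of 5–60 bp, α; random strand) embedded in
  uniform-composition intergenic DNA with geometric lengths (mean
  500 bp). Pseudogene specs plant a 2-bp insertion at codon 20 of the α.
  Substitutions are applied per site at a configurable rate;
  `protect_signatures` spares the signature codons and gene boundaries so
  planted truth stays readable at low rates. At rate 0 the pipeline
  reproduces the truth table exactly; category recovery is 100% at rates
  ≤0.02 and degrades monotonically toward 0.2 (tested at fixed seeds).
  Canned configurations reproduce the two signature strain patterns:
  five operons with a pseudogene LH3 (the reference-strain pattern) and
  three LH2-only operons.
- **Counts**: negative-binomial draws (variance μ + αμ², dispersion
  α = 0.1) at the mean implied by each gene's target rpkm, length and
  library size (5×10⁶), 2 replicates × 2 conditions. Default targets
  follow the reported magnitudes: background genes 50–250 rpkm, LH genes
  10³–3.5×10⁵ with the LH3/LH4 operons strongly low-light-induced. The
  two classes without printed α values in the reference strain use
  class-consistent defaults (LH3 α mirrors the LH4 α induction; LH2′
  mirrors LH2B).
- **Spectra**: sums of unit Gaussians (σ = 8 nm) at the catalog bands on
  a 1-nm 700–950 nm grid plus white noise (default sd 0.01).

All generators are deterministic per seed (independent numpy Generator
streams per data type). What passing these benchmarks does **not** show:
real genomes have non-uniform composition, mobile elements and annotation
errors; real counts have library-specific biases and unequal library
sizes; real whole-cell spectra have scattering baselines the pipeline
does not correct. The synthetic results validate the algorithms'
contracts, not field performance on arbitrary genomes.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances — single synthetic genomes of ~4–5 kb carrying 3–5 operons,
200 background genes, trees of 4–10 leaves, bootstrap at 25–400
replicates — chosen so the full validation cycle completes in seconds
while still exercising every code path; all sizes are configurable
upward.

## Known limitations

- The MCL distance shares the cited method's estimator structure but is
  not a bit-level reimplementation of MEGA5.
- ORF scanning cannot find frameshifted pseudogenes as single ORFs; the
  annotated path (or nucleotide-level rescoring of annotated CDS) is the
  supported route to pseudogene discovery.
- Spectral inference is qualitative by design; band stoichiometry and
  baseline correction are out of scope.
- The inventory's lone-α genes are reported separately, not forced into a
  category.
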