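# Methods

## The screening model

`psifootprint` operationalizes a self-resistance argument: a strain producing
a protein-synthesis inhibitor (PSI) must protect its own translation
machinery, and the protection mechanisms — a resistant second copy of the
target gene, a resistance gene carried inside the biosynthetic gene cluster
(BGC), or a horizontally acquired variant — are detectable in the genome
sequence alone.

For each genome the pipeline runs four stages:

1. **Assignment.** Annotated CDS features are mapped onto a catalog of ~100
   protein-synthesis core-gene families. The default mapping is by gene symbol
   and product string (case-insensitive, with a packaged alias table); a
   `best_hit` mode aligns translated CDS against per-family reference proteins
   when those are supplied, and an `external-table` mode ingests a precomputed
   gene→family map. A gene maps to at most one family; unmatched genes are
   ignored, so assignment is a partial function.
2. **Criteria.** Per family: duplication (copy number > expected, default
   expected = 1), BGC co-localization (any gene of the family overlapping any
   region under the configured overlap rule), and the composition-based HGT
   proxy described below.
3. **Footprint.** Hit genes = families with ≥ 1 criterion true (counted per
   family, not per gene copy, matching how published hit tables are printed).
   The seven RI families count as *present* only when they are themselves hit
   genes: every bacterium encodes rpsL, so bare presence carries no signal —
   this is the only reading under which known non-PSI producers show zero RI
   genes. Candidate ⇔ hit_genes ≥ 20 AND RI ≥ 2. The published description
   uses both ">20" and "≥20"; this package uses ≥ 20, the form consistent
   with a prioritized strain that has exactly 20 hit genes.
4. **Dereplication** (optional). Gene-cluster similarity against known-PSI
   reference clusters and m/z matching of observed peaks against a compound
   table.

## The HGT composition proxy

Phylogenetic incongruence proper (gene-tree/species-tree reconciliation)
requires reference phylogenies and is out of scope; the detectable signature
used instead is compositional: horizontally transferred genes deviate from the
host genome in GC content and codon usage. Two per-gene features are computed
against the genome-wide background (all CDS; at least 50 required):

- **Synonymous GC deviation.** Observed GC of the CDS minus the GC *expected
  for that gene's own amino-acid sequence* under the genome-wide
  per-amino-acid codon usage, per position. Conditioning on the protein
  removes amino-acid composition — which varies between genes for reasons
  unrelated to transfer — and leaves only codon *choice*. Flagged two-sided
  (donor genomes can be GC-richer or GC-poorer).
- **Codon-usage (RSCU) deviation.** Mean squared difference between the
  gene's relative synonymous codon usage and the genome profile, over
  degenerate codons observed in the gene. Its null is right-skewed, so it is
  standardized on the log scale and flagged one-sided (only excess deviation
  is evidence).

Both features are converted to robust z-scores (median/MAD with the 1.4826
normal-consistency factor) so that genuine outliers — the thing being looked
for — do not inflate the background scale. A family is flagged when any of its
genes exceeds `z_threshold` (default 2.0) on any enabled feature. Genes
shorter than 100 codons are scored but marked low-confidence. On synthetic
null genomes the per-family false-positive rate of the combined flag at
z = 2.0 is ≈ 7 % (two correlated features, each ~3–5 %), within the ≤ 10 %
calibration bound asserted by the test suite.

Users with upstream tool output can bypass the proxy entirely: the
`external-table` pathway (`from-arts`) takes per-family criterion calls as
printed by resistance-gene screening tools, and criteria tables exported by
this package round-trip losslessly (they carry copy number, deviation score
and region labels as extension columns).

## The core-gene catalog

The reference set ships as a replaceable TSV of 100 families: the accessions
printed in the published hit tables plus the seven RI families under their
standard TIGRFAM identifiers, completed with a curated complement of
ribosomal-protein, translation-factor, aminoacyl-tRNA-synthetase and
rRNA/tRNA-modification families. Complement entries whose public TIGRFAM
accession could not be confirmed carry package-local `PSF`-prefixed
identifiers — deliberately distinguishable from real accessions rather than
risking wrong ones. Because results depend on catalog membership (a resistance
gene absent from the catalog is invisible to the screen), the catalog is a
data file the user can swap out wholesale.

## Cluster similarity and mass matching

Cluster similarity is the fraction of reference-cluster genes with at least
one matching query gene, in percent: 100 % when all are found, decreasing as
fewer are found. A match requires a local alignment (Smith–Waterman, BLOSUM62,
gap open 11 / extend 1 — BLASTP defaults via scikit-bio) with identity
strictly > 30 %, coverage of the shorter sequence strictly > 25 %, and raw
score ≥ 60. The score floor replaces a database e-value cutoff, which is not
reproducible outside a fixed search context; 60 was calibrated so seeded
random 200-residue pairs fail at ≥ 99 % rate (their observed score maximum is
~50, and they already fail the coverage test). Precomputed search tables (with
e-values) can be ingested instead. The default dereplication cutoff is 80 %
similarity — the published screen excluded strains with near-complete matches
to known clusters without printing a numeric threshold.

Masses use the NIST isotope snapshot shipped with pyteomics: average mass =
abundance-weighted isotope mean, monoisotopic = most abundant isotope. Adduct
m/z uses the proton mass (1.007276 Da), not the hydrogen atom mass; the
difference is below reporting precision but stated for exactness. The default
peak-matching tolerance of 0.3 Da reflects low-resolution ion-trap data, where
printed values sit up to ~0.1 Da from theory; sub-0.1 Da tolerances would
reject assignments the validation data itself makes. ivTT reporter readouts
classify as strong (≤ 20 %), specific (≤ 40 %) or none, with boundaries
inclusive.

## Synthetic genomes

The generator builds single-contig genomes from an explicit codon model:
synonymous codons weighted by `exp(β · GC(codon))` with β solved by bisection
for the requested genome GC (default 0.60, actinomycete-like). Background
genes are random proteins (uniform amino acids, default 300 codons, default
150 genes); core genes use deterministic per-family seed proteins (stable
across genomes, so symbol- and alignment-based assignment agree); duplicated
families get a second, lightly mutated copy; BGC members are laid out inside
emitted region coordinates with background filler genes; HGT-planted genes
are encoded from a β shifted so their expected GC moves by `bias_strength`
analytic null standard deviations (default 6, comfortably above the z = 2
detection threshold; the analytic sd comes from the codon model's per-codon
GC variance). All randomness derives from one integer seed and outputs are
byte-identical across runs.

What the generator does **not** emulate: real gene-length and amino-acid
composition distributions, operon structure, genome-scale GC gradients,
pseudogenes, assembly artifacts, or annotation noise (missing/wrong symbols
and products). Passing recovery tests therefore demonstrates that the
pipeline's logic is correct under its own model assumptions — not that
symbol-based assignment or the composition proxy achieve any particular
sensitivity on real annotations, where catalog coverage and annotation quality
dominate.

Validation tables from the published screen (known PSI producers, known
non-PSI producers, the strain-collection showcase, and the prioritized-strain
list) ship verbatim as TSV fixtures; the test suite reapplies the classifier
to them and reproduces the printed candidate counts (3 of 5; 15 of 15; 0 with
any RI gene) and every printed RI count.

## Numerical and design choices

- Coordinates are 1-based inclusive internally (GenBank convention); BED is
  converted on ingest/egress. Genes are keyed by locus tag, else by a
  deterministic `contig:start-end:strand` key.
- Overlap rule defaults to *any-overlap* because resistance copies are
  observed at cluster borders; *fully-contained* is available.
- Ranking sorts by hit genes, then RI count, then strain id — fully
  deterministic under ties.
- `merge_criteria` takes the union of family accessions over the three
  criterion maps, with absent entries false; it is idempotent and independent
  of input dict ordering.
- Degenerate inputs: empty region files yield an empty list with a warning;
  genes on contigs unknown to the region file are treated as non-overlapping
  with a warning; genomes with < 50 CDS raise a background error for the
  composition proxy rather than returning unstable z-scores.

## Limitations

The screen inherits the published method's blind spots: producers protected by
mechanisms that leave no core-gene footprint (e.g. a dedicated rRNA
methyltransferase carried in the BGC but absent from the core catalog) are
missed, as are PSIs whose resistance genes fall outside the ~100-family
reference set. The composition proxy is a stand-in for phylogenetic evidence
and will miss transfers between compositionally similar genomes. Hit-gene
absolute counts from real genomes depend on the (unpublished) reference
core-gene list of the original tooling and are not expected to match this
package's catalog gene-for-gene; the external-table pathway exists precisely
so published per-family calls can be consumed directly.
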