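# psifootprint

Genome-based prioritization of bacterial **protein-synthesis-inhibitor (PSI)
producers** from self-resistance gene footprints ("Ψ-footprinting"), with
dereplication of candidates by gene-cluster similarity and molecular-mass
matching.

Antibiotic producers must survive their own product. For ribosome-targeting
antibiotics this self-protection leaves a recognizable footprint on the
producer's genome: translation core genes that are duplicated, co-located with
a biosynthetic gene cluster (BGC), or compositionally alien to the genome
(the signature of horizontal acquisition). `psifootprint` screens annotated
bacterial genomes — typically actinomycetes — for this footprint and is aimed
at natural-product discovery groups who want to rank strain collections before
committing to cultivation and chemistry.

## The screen

Against a reference catalog of ~100 protein-synthesis core-gene families
(ribosomal proteins, translation factors, aminoacyl-tRNA synthetases, rRNA/tRNA
modification enzymes), each family found in a genome is tested for three
criteria:

1. **duplication** — copy number *n* > expected copies (default 1);
2. **BGC co-localization** — ≥ 1 gene of the family overlaps a predicted BGC
   region (any overlap counts by default, since resistance copies often sit at
   cluster borders);
3. **composition deviation (HGT proxy)** — the gene's synonymous GC usage or
   its relative synonymous codon usage (RSCU) deviates from the genome
   background by more than *z* = 2 robust standard scores.

A family fulfilling ≥ 1 criterion is a **hit gene**. Seven ribosomal-protein
families — *rpsE, rpsL, rplC, rplD, rplK, rplQ, rplV* (S5, S12, L3, L4, L11,
L17, L22), each a classic site of PSI-resistance mutations — are **resistance
indicator (RI) genes**. The classification rule is

```
candidate PSI producer  ⇔  hit_genes ≥ 20  AND  RI genes among hits ≥ 2
```

Candidates are then dereplicated: a query cluster scoring ≥ 80 % similarity
against a known-PSI reference BGC (similarity = % of reference genes with a
matching query gene; match = local alignment with identity > 30 %, coverage of
the shorter sequence > 25 %, and a score floor), or an HPLC-MS peak matching a
known compound's [M+H]⁺/[M−H]⁻ m/z within 0.3 Da, marks an already-known
producer.

## Worked example

Generate a synthetic annotated genome with a known planted footprint, then
screen it:

```sh
$ psifootprint synth --seed 7 --out demo
wrote demo: 13 core genes, 1 regions, expected hits=10

$ psifootprint screen --genome demo/genome.gbk --regions demo/regions.gff \
      --strain-id demo --out demo/report --export-criteria
demo    hit_genes=10    ri=2    candidate=False

$ cat demo/report/footprint_report.tsv
strain_id  hit_genes  rpsE  rpsL  rplC  rplD  rplK  rplQ  rplV  ri_count  candidate
demo       10         -     +     -     +     -     -     -     2         false
```

The generator planted 3 duplicated, 4 BGC-embedded and 3 composition-biased
core families (10 in total); the screen recovers exactly those 10 hit genes.
Two of them are RI families (*rpsL*, *rplD*), so `ri_count` is 2 — but with
only 10 hit genes the strain stays below the 20-hit threshold and is not a
candidate. Reporter-assay readouts classify the same way as in the validation
experiments:

```sh
$ psifootprint ivtt-classify 13 30 85
13   strong
30   specific
85   none
```

Other subcommands: `from-arts` (footprint a strain from a precomputed
per-family criteria table), `rank`, `derep-bgc`, `derep-mass`, `fixtures`
(export the packaged validation tables). The same functionality is available
as a library (`psifootprint.screen_genome`, `psifootprint.cluster_similarity`,
`psifootprint.match_peaks`, …).

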