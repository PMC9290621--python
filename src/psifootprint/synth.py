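"""Synthetic annotated genomes with a known manifest of planted signals.

The generator emulates what the screen sees in a real actinomycete genome:
a background of protein-coding genes drawn from a genome-wide codon model at a
target GC content, a complement of protein-synthesis core genes, and planted
self-resistance signals — duplicated core families, core genes placed inside
emitted BGC regions, and compositionally alien (HGT-like) core genes drawn
from a GC-shifted codon model.

The codon model weights synonymous codons by ``exp(beta * GC(codon))`` with
``beta`` solved for the requested genome GC.  HGT bias is expressed in units
of the analytic null standard deviation of a gene's GC fraction, so "above
the detection threshold by construction" is a checkable statement: a planted
gene at ``bias_strength`` sigma has expected GC z-score ~ bias_strength.

Everything is driven by a single integer seed; outputs are byte-identical
across runs for the same spec.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import codons
from .catalog import CoreFamilyCatalog, load_default_catalog
from .genome_io import RI_SYMBOLS, BgcRegion, GeneRecord, GenomeAnnotation

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
REGION_CAPACITY = 10  # max planted core members per emitted region


@dataclass
class SyntheticSpec:
    seed: int = 0
    n_background_genes: int = 150
    core_families_present: list[str] = field(default_factory=list)
    planted_duplications: list[str] = field(default_factory=list)
    planted_bgc_members: list[tuple[str, int]] = field(default_factory=list)
    planted_hgt: list[tuple[str, float]] = field(default_factory=list)
    n_bgc_regions: int = 2
    genome_gc: float = 0.60
    gene_length: int = 300  # codons per protein
    strain_id: str = "synthetic"

    def __post_init__(self) -> None:
        present = set(self.core_families_present)
        planted = (
            set(self.planted_duplications)
            | {a for a, _ in self.planted_bgc_members}
            | {a for a, _ in self.planted_hgt}
        )
        stray = planted - present
        if stray:
            raise ValueError(f"planted families not in core_families_present: {sorted(stray)}")
        if any(b <= 0 for _, b in self.planted_hgt):
            raise ValueError("bias_strength must be > 0")
        if not (0 < self.genome_gc < 1):
            raise ValueError("genome_gc must be in (0, 1)")
        for acc, ridx in self.planted_bgc_members:
            if not (0 <= ridx < self.n_bgc_regions):
                raise ValueError(f"{acc}: region index {ridx} out of range")
        per_region: dict[int, int] = {}
        for _, ridx in self.planted_bgc_members:
            per_region[ridx] = per_region.get(ridx, 0) + 1
        if any(n > REGION_CAPACITY for n in per_region.values()):
            raise ValueError(
                f"more BGC members than region capacity ({REGION_CAPACITY} per region)"
            )

    @property
    def planted_union(self) -> set[str]:
        return (
            set(self.planted_duplications)
            | {a for a, _ in self.planted_bgc_members}
            | {a for a, _ in self.planted_hgt}
        )


@dataclass
class SyntheticManifest:
    spec: SyntheticSpec
    gene_truth: list[dict]
    expected_hit_accessions: list[str]
    expected_hit_count: int
    expected_ri_profile: dict[str, bool]

    def to_dict(self) -> dict:
        d = asdict(self.spec)
        d["planted_bgc_members"] = [list(t) for t in d["planted_bgc_members"]]
        d["planted_hgt"] = [list(t) for t in d["planted_hgt"]]
        return {
            "spec": d,
            "gene_truth": self.gene_truth,
            "expected_hit_accessions": self.expected_hit_accessions,
            "expected_hit_count": self.expected_hit_count,
            "expected_ri_profile": self.expected_ri_profile,
        }


# ---------------------------------------------------------------------------
# sequence sampling
# ---------------------------------------------------------------------------

def family_seed_protein(accession: str, length: int = 300) -> str:
    """Deterministic per-family seed protein (stable across genomes and seeds)."""
    rng = np.random.default_rng(zlib.crc32(accession.encode()) % (2**31))
    aa = rng.choice(list(AMINO_ACIDS), size=length - 1)
    return "M" + "".join(aa)


def _mutate(protein: str, rng: np.random.Generator, rate: float = 0.05) -> str:
    out = list(protein)
    for i in range(1, len(out)):
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(out)


def _encode(protein: str, beta: float, rng: np.random.Generator) -> str:
    probs = codons.codon_probs(beta)
    syn = codons.synonym_map()
    parts = []
    for aa in protein:
        cs = syn[aa]
        parts.append(cs[rng.choice(len(cs), p=probs[aa])])
    stops = ("TAA", "TAG", "TGA")
    w = np.array([np.exp(beta * codons.gc_count(s)) for s in stops])
    parts.append(stops[rng.choice(3, p=w / w.sum())])
    return "".join(parts)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))


def _spacer(rng: np.random.Generator, gc: float, n: int) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(
    spec: SyntheticSpec,
    catalog: CoreFamilyCatalog | None = None,
    out_dir: str | Path | None = None,
) -> tuple[GenomeAnnotation, list[BgcRegion], SyntheticManifest]:
    """Build the genome, its BGC regions and the ground-truth manifest.

    When ``out_dir`` is given, also writes genome.gbk, genome.gff3, genome.fna,
    regions.gff and manifest.json there.
    """
    catalog = catalog or load_default_catalog()
    unknown = set(spec.core_families_present) - {f.accession for f in catalog.families}
    if unknown:
        raise ValueError(f"spec names families absent from catalog: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)

    beta_bg = codons.solve_beta(spec.genome_gc)
    sd_null = codons.null_gene_gc_sd(beta_bg, spec.gene_length)
    hgt_bias = dict(spec.planted_hgt)
    hgt_beta: dict[str, float] = {}
    for acc, bias in hgt_bias.items():
        direction = -1.0 if spec.genome_gc >= 0.5 else 1.0
        target = spec.genome_gc + direction * bias * sd_null
        hgt_beta[acc] = codons.solve_beta(target)

    dup_set = set(spec.planted_duplications)
    region_of: dict[str, int] = dict(spec.planted_bgc_members)

    # plan: (gene_id, accession|None, protein, beta, region_idx|None)
    plan: list[tuple[str, Optional[str], str, float, Optional[int]]] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"SYN_{counter:05d}"

    for acc in spec.core_families_present:
        seedprot = family_seed_protein(acc, spec.gene_length)
        n_copies = 2 if acc in dup_set else 1
        beta = hgt_beta.get(acc, beta_bg)
        for copy in range(n_copies):
            prot = seedprot if copy == 0 else _mutate(seedprot, rng)
            # only the first copy sits inside its assigned region
            ridx = region_of.get(acc) if copy == 0 else None
            plan.append((next_id(), acc, prot, beta, ridx))
    for _ in range(spec.n_background_genes):
        plan.append((next_id(), None, _random_protein(rng, spec.gene_length), beta_bg, None))

    # layout: region blocks first (members + background fillers), then the rest
    in_region: dict[int, list] = {i: [] for i in range(spec.n_bgc_regions)}
    loose = []
    for entry in plan:
        if entry[4] is not None:
            in_region[entry[4]].append(entry)
        else:
            loose.append(entry)
    loose_arr = list(loose)
    rng.shuffle(loose_arr)
    n_fillers = 3
    for i in range(spec.n_bgc_regions):
        take = []
        for e in list(loose_arr):
            if e[1] is None and len(take) < n_fillers:
                take.append(e)
                loose_arr.remove(e)
        in_region[i].extend(take)

    seq_parts: list[str] = [_spacer(rng, spec.genome_gc, 100)]
    pos = 100  # 0-based cursor
    genes: list[GeneRecord] = []
    regions: list[BgcRegion] = []
    truth: list[dict] = []

    def emit(entry, in_region_flag: bool) -> GeneRecord:
        nonlocal pos
        gene_id, acc, prot, beta, _ = entry
        cds = _encode(prot, beta, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        dna = cds if strand == "+" else _revcomp(cds)
        start = pos + 1  # 1-based
        seq_parts.append(dna)
        pos += len(dna)
        end = pos
        fam = catalog.get(acc) if acc else None
        g = GeneRecord(
            gene_id=gene_id,
            contig_id="contig_1",
            start=start,
            end=end,
            strand=strand,
            product=fam.description if fam else "hypothetical protein",
            symbol=fam.symbol if fam else None,
            cds_sequence=cds,
        )
        genes.append(g)
        if acc:
            truth.append(
                {
                    "gene_id": gene_id,
                    "accession": acc,
                    "duplicated": acc in dup_set,
                    "in_bgc": in_region_flag,
                    "hgt": acc in hgt_bias,
                }
            )
        spacer_len = int(rng.integers(20, 200))
        seq_parts.append(_spacer(rng, spec.genome_gc, spacer_len))
        pos += spacer_len
        return g

    for i in range(spec.n_bgc_regions):
        members = in_region[i]
        if not members:
            continue
        first = None
        last = None
        for e in members:
            g = emit(e, in_region_flag=e[1] is not None)
            first = first or g
            last = g
        regions.append(
            BgcRegion(
                region_id=f"region_{i + 1}",
                contig_id="contig_1",
                start=max(1, first.start - 10),
                end=last.end + 10,
                cluster_type="synthetic",
            )
        )
    for e in loose_arr:
        emit(e, in_region_flag=False)

    genome = GenomeAnnotation(
        strain_id=spec.strain_id,
        contigs={"contig_1": "".join(seq_parts)},
        genes=genes,
    )

    expected = sorted(spec.planted_union)
    ri_profile = {
        s: any(
            (catalog.get(a) is not None and catalog.get(a).symbol == s) for a in expected
        )
        for s in RI_SYMBOLS
    }
    manifest = SyntheticManifest(
        spec=spec,
        gene_truth=truth,
        expected_hit_accessions=expected,
        expected_hit_count=len(expected),
        expected_ri_profile=ri_profile,
    )

    if out_dir is not None:
        _write_outputs(genome, regions, manifest, Path(out_dir))
    return genome, regions, manifest


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _write_outputs(genome, regions, manifest, out_dir: Path) -> None:
    from .genome_io import write_genbank, write_gff3

    out_dir.mkdir(parents=True, exist_ok=True)
    write_genbank(genome, out_dir / "genome.gbk")
    write_gff3(genome, out_dir / "genome.gff3", out_dir / "genome.fna")
    with open(out_dir / "regions.gff", "w") as fh:
        fh.write("##gff-version 3\n")
        for r in regions:
            fh.write(
                f"{r.contig_id}\tpsifootprint\tregion\t{r.start}\t{r.end}\t.\t+\t.\t"
                f"ID={r.region_id};product={r.cluster_type}\n"
            )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# convenience spec builders
# ---------------------------------------------------------------------------

def recovery_spec(
    seed: int,
    n_dup: int = 3,
    n_bgc: int = 4,
    n_hgt: int = 3,
    bias_strength: float = 6.0,
    catalog: CoreFamilyCatalog | None = None,
    **kwargs,
) -> SyntheticSpec:
    """Spec planting disjoint duplication/BGC/HGT families.

    The core complement is exactly the planted union, so the manifest's
    expected hit count is the number of planted families.
    """
    catalog = catalog or load_default_catalog()
    accs = [f.accession for f in catalog.families]
    need = n_dup + n_bgc + n_hgt
    chosen = accs[:need]
    dup = chosen[:n_dup]
    bgc = chosen[n_dup : n_dup + n_bgc]
    hgt = chosen[n_dup + n_bgc :]
    n_regions = kwargs.pop("n_bgc_regions", max(1, (n_bgc + REGION_CAPACITY - 1) // REGION_CAPACITY))
    return SyntheticSpec(
        seed=seed,
        core_families_present=chosen,
        planted_duplications=dup,
        planted_bgc_members=[(a, i % n_regions) for i, a in enumerate(bgc)],
        planted_hgt=[(a, bias_strength) for a in hgt],
        n_bgc_regions=n_regions,
        **kwargs,
    )


def null_spec(seed: int, n_core: int = 20, catalog: CoreFamilyCatalog | None = None, **kwargs) -> SyntheticSpec:
    """Spec with core families present but nothing planted (null genome)."""
    catalog = catalog or load_default_catalog()
    accs = [f.accession for f in catalog.families][:n_core]
    return SyntheticSpec(seed=seed, core_families_present=accs, **kwargs)


def berninamycin_footprint_spec(seed: int, **kwargs) -> SyntheticSpec:
    """Spec reproducing the packaged berninamycin-producer hit table:
    nine duplicated, thirteen BGC-located and six compositionally deviant core
    families whose union is fifteen."""
    import pandas as pd

    df = load_fixture_table("berninamycin_producer_hits")
    dup = list(df.loc[df["duplication"] == "+", "accession"])
    phylo = list(df.loc[df["phylogeny"] == "+", "accession"])
    bgc = list(df.loc[df["bgc"] != "-", "accession"])
    present = list(df["accession"])
    bias = kwargs.pop("bias_strength", 6.0)
    return SyntheticSpec(
        seed=seed,
        core_families_present=present,
        planted_duplications=dup,
        planted_bgc_members=[(a, 0) for a in bgc[:REGION_CAPACITY]]
        + [(a, 1) for a in bgc[REGION_CAPACITY:]],
        planted_hgt=[(a, bias) for a in phylo],
        n_bgc_regions=2,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# packaged validation-table fixtures
# ---------------------------------------------------------------------------

FIXTURE_TABLES = ("berninamycin_producer_hits", "psi_producers", "non_psi_producers", "collection_showcase", "prioritized_strains")


def load_fixture_table(name: str):
    """Load one of the packaged validation tables as a DataFrame."""
    import pandas as pd

    if name not in FIXTURE_TABLES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_TABLES}")
    with resources.as_file(resources.files("psifootprint.data") / "tables" / f"{name}.tsv") as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def generate_fixture_tables(out_dir: str | Path) -> list[Path]:
    """Write copies of the packaged validation-table fixtures to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in FIXTURE_TABLES:
        df = load_fixture_table(name)
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
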