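"""The three self-resistance criteria evaluated per core-gene family.

A core-gene family in a genome is suspicious when it is (i) duplicated beyond
its expected copy number, (ii) co-located with a biosynthetic gene cluster, or
(iii) compositionally alien to its genome — the detectable signature of a
horizontally transferred gene, here measured as GC-content and codon-usage
(RSCU) deviation of the gene from the genome-wide background.  Tree-based
phylogenetic reconciliation is deliberately out of scope; an external criteria
table can inject upstream phylogeny calls instead (see
:func:`flags_from_arts_rows`).

Robust z-scores (median/MAD) are used for both composition features so that the
very outliers the statistic is meant to find do not inflate the background
scale.  The codon-usage deviation is z-scored on the log scale because its null
distribution is right-skewed, and flagged one-sided (only excess deviation is
evidence); GC deviation is flagged two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import codons
from .catalog import CoreFamilyCatalog, FamilyAssignment
from .genome_io import ArtsRow, BgcRegion, GenomeAnnotation

MIN_BACKGROUND_CDS = 50
LOW_CONFIDENCE_CODONS = 100


@dataclass
class HgtParams:
    """Tunables of the composition-based HGT proxy."""

    z_threshold: float = 2.0
    features: tuple[str, ...] = ("gc_content", "codon_usage")

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        unknown = set(self.features) - {"gc_content", "codon_usage"}
        if unknown:
            raise ValueError(f"unknown HGT features: {sorted(unknown)}")


@dataclass
class CriterionFlags:
    """Per-family criterion booleans, in the layout of a resistance hit table."""

    accession: str
    duplication: bool = False
    in_bgc: bool = False
    bgc_labels: list[str] = field(default_factory=list)
    phylogeny: bool = False
    copy_number: int = 0
    deviation_score: Optional[float] = None

    @property
    def is_hit(self) -> bool:
        return self.duplication or self.in_bgc or self.phylogeny

    def to_dict(self) -> dict:
        return {
            "accession": self.accession,
            "duplication": self.duplication,
            "in_bgc": self.in_bgc,
            "bgc_labels": list(self.bgc_labels),
            "phylogeny": self.phylogeny,
            "copy_number": self.copy_number,
            "deviation_score": self.deviation_score,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CriterionFlags":
        return cls(**d)


# ---------------------------------------------------------------------------
# criterion (i): duplication
# ---------------------------------------------------------------------------

def detect_duplication(
    assignments: Sequence[FamilyAssignment], catalog: CoreFamilyCatalog
) -> dict[str, tuple[int, bool]]:
    """Copy number per family and whether it exceeds the expected copy number."""
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.accession] = counts.get(a.accession, 0) + 1
    out = {}
    for acc, n in counts.items():
        fam = catalog.get(acc)
        expected = fam.expected_copies if fam else 1
        out[acc] = (n, n > expected)
    return out


# ---------------------------------------------------------------------------
# criterion (ii): BGC co-localization
# ---------------------------------------------------------------------------

def _overlaps(gene_start: int, gene_end: int, region: BgcRegion, rule: str) -> bool:
    if rule == "any-overlap":
        return gene_start <= region.end and gene_end >= region.start
    if rule == "fully-contained":
        return gene_start >= region.start and gene_end <= region.end
    raise ValueError(f"unknown overlap_rule {rule!r}; use any-overlap or fully-contained")


def detect_bgc_colocalization(
    genome: GenomeAnnotation,
    assignments: Sequence[FamilyAssignment],
    regions: Sequence[BgcRegion],
    overlap_rule: str = "any-overlap",
) -> dict[str, tuple[bool, list[str]]]:
    """Per family: does any assigned gene overlap any BGC region, and which."""
    genes = {g.gene_id: g for g in genome.genes}
    by_contig: dict[str, list[BgcRegion]] = {}
    for r in regions:
        by_contig.setdefault(r.contig_id, []).append(r)
    unknown = {r.contig_id for r in regions} - set(genome.contigs)
    if unknown:
        warnings.warn(f"BGC regions on contigs absent from genome: {sorted(unknown)}")

    out: dict[str, tuple[bool, list[str]]] = {}
    for a in assignments:
        g = genes.get(a.gene_id)
        flag, labels = out.get(a.accession, (False, []))
        if g is not None:
            for r in by_contig.get(g.contig_id, []):
                if _overlaps(g.start, g.end, r, overlap_rule) and r.region_id not in labels:
                    labels.append(r.region_id)
        out[a.accession] = (bool(labels), labels)
    return {acc: (flag, sorted(labels)) for acc, (flag, labels) in out.items()}


# ---------------------------------------------------------------------------
# criterion (iii): HGT composition proxy
# ---------------------------------------------------------------------------

def _robust_z(values: np.ndarray) -> np.ndarray:
    """(x - median) / (1.4826 * MAD); zeros if the scale degenerates."""
    med = np.nanmedian(values)
    mad = np.nanmedian(np.abs(values - med))
    scale = 1.4826 * mad
    if not np.isfinite(scale) or scale == 0:
        return np.zeros_like(values)
    return (values - med) / scale


def hgt_gene_stats(genome: GenomeAnnotation) -> pd.DataFrame:
    """Per-gene composition statistics against the genome-wide background.

    The GC statistic is the *synonymous* GC deviation: observed GC minus the
    GC expected for the gene's own amino-acid sequence under the genome-wide
    per-amino-acid codon usage.  Conditioning on the protein removes
    amino-acid composition as a confounder, so only codon *choice* — the
    actual horizontal-transfer signature — contributes.

    Columns: gene_id, n_codons, gc, gc_dev, gc_z, codon_dev, codon_z,
    low_confidence.  Requires >= 50 CDS with sequence for a stable background.
    """
    genes = [g for g in genome.genes if g.cds_sequence]
    if len(genes) < MIN_BACKGROUND_CDS:
        raise ValueError(
            f"genome background needs >= {MIN_BACKGROUND_CDS} CDS with sequence; "
            f"got {len(genes)}"
        )
    counts = [codons.codon_counts(g.cds_sequence) for g in genes]
    pooled: dict[str, int] = {}
    for c in counts:
        for codon, n in c.items():
            pooled[codon] = pooled.get(codon, 0) + n
    genome_rscu = codons.rscu(pooled)

    # genome-wide expected GC count per codon, conditional on the amino acid
    syn = codons.synonym_map()
    e_gc_given_aa: dict[str, float] = {}
    for aa, cs in syn.items():
        total = sum(pooled.get(c, 0) for c in cs)
        if total:
            e_gc_given_aa[aa] = sum(pooled.get(c, 0) * codons.gc_count(c) for c in cs) / total
        else:
            e_gc_given_aa[aa] = float(np.mean([codons.gc_count(c) for c in cs]))
    cmap = codons.codon_map()

    gc = np.array([codons.gc_fraction(g.cds_sequence) for g in genes])
    gc_dev = np.empty(len(genes))
    for i, c in enumerate(counts):
        n_cod = sum(c.values())
        observed = sum(codons.gc_count(codon) * k for codon, k in c.items())
        expected = sum(e_gc_given_aa[cmap[codon]] * k for codon, k in c.items())
        gc_dev[i] = (observed - expected) / (3 * n_cod) if n_cod else np.nan

    dev = np.empty(len(genes))
    for i, c in enumerate(counts):
        gene_rscu = codons.rscu(c)
        common = [k for k in gene_rscu if k in genome_rscu]
        if not common:
            dev[i] = np.nan
            continue
        diffs = np.array([gene_rscu[k] - genome_rscu[k] for k in common])
        dev[i] = float(np.mean(diffs**2))

    gc_z = _robust_z(gc_dev)
    with np.errstate(divide="ignore"):
        codon_z = _robust_z(np.log(np.where(dev > 0, dev, np.nan)))
    codon_z = np.nan_to_num(codon_z, nan=0.0)

    n_codons = np.array([sum(c.values()) for c in counts])
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "n_codons": n_codons,
            "gc": gc,
            "gc_dev": gc_dev,
            "gc_z": gc_z,
            "codon_dev": dev,
            "codon_z": codon_z,
            "low_confidence": n_codons < LOW_CONFIDENCE_CODONS,
        }
    )


def detect_hgt_signal(
    genome: GenomeAnnotation,
    assignments: Sequence[FamilyAssignment],
    params: HgtParams | None = None,
) -> dict[str, tuple[bool, Optional[float]]]:
    """Per family: is any assigned gene compositionally deviant, and how much.

    The reported deviation score is the family's largest exceedance statistic:
    max over genes of max(|gc_z| if enabled, codon_z if enabled).
    """
    params = params or HgtParams()
    stats = hgt_gene_stats(genome).set_index("gene_id")

    out: dict[str, tuple[bool, Optional[float]]] = {}
    for a in assignments:
        if a.gene_id not in stats.index:
            out.setdefault(a.accession, (False, None))
            continue
        row = stats.loc[a.gene_id]
        parts = []
        if "gc_content" in params.features:
            parts.append(abs(float(row["gc_z"])))
        if "codon_usage" in params.features:
            parts.append(float(row["codon_z"]))
        score = max(parts) if parts else 0.0
        prev_flag, prev_score = out.get(a.accession, (False, None))
        best = score if prev_score is None else max(prev_score, score)
        out[a.accession] = (prev_flag or score > params.z_threshold, best)
    return out


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

def merge_criteria(
    dup: Mapping[str, tuple[int, bool]],
    bgc: Mapping[str, tuple[bool, list[str]]],
    hgt: Mapping[str, tuple[bool, Optional[float]]],
) -> list[CriterionFlags]:
    """One CriterionFlags per family seen by any criterion; missing = false."""
    accs = sorted(set(dup) | set(bgc) | set(hgt))
    out = []
    for acc in accs:
        copy_number, duplication = dup.get(acc, (0, False))
        in_bgc, labels = bgc.get(acc, (False, []))
        phylogeny, score = hgt.get(acc, (False, None))
        out.append(
            CriterionFlags(
                accession=acc,
                duplication=duplication,
                in_bgc=in_bgc,
                bgc_labels=list(labels),
                phylogeny=phylogeny,
                copy_number=copy_number,
                deviation_score=score,
            )
        )
    return out


def evaluate_criteria(
    genome: GenomeAnnotation,
    assignments: Sequence[FamilyAssignment],
    catalog: CoreFamilyCatalog,
    regions: Sequence[BgcRegion] = (),
    hgt_params: HgtParams | None = None,
    overlap_rule: str = "any-overlap",
) -> list[CriterionFlags]:
    """Run all three criteria and merge (the per-genome criteria stage)."""
    dup = detect_duplication(assignments, catalog)
    bgc = detect_bgc_colocalization(genome, assignments, regions, overlap_rule)
    hgt = detect_hgt_signal(genome, assignments, hgt_params)
    return merge_criteria(dup, bgc, hgt)


# ---------------------------------------------------------------------------
# external-table pathway
# ---------------------------------------------------------------------------

def flags_from_arts_rows(rows: Iterable[ArtsRow]) -> list[CriterionFlags]:
    """Build criterion flags from an external (e.g. ARTS-style) hit table.

    Copy number defaults to 2 for duplicated families and 1 otherwise when the
    table does not carry an explicit copy_number column.
    """
    out = []
    for r in rows:
        cn = r.copy_number if r.copy_number is not None else (2 if r.duplication else 1)
        labels = [s for s in (r.bgc_label or "").split(",") if s]
        out.append(
            CriterionFlags(
                accession=r.family_accession,
                duplication=r.duplication,
                in_bgc=r.in_bgc,
                bgc_labels=labels,
                phylogeny=r.phylogeny,
                copy_number=cn,
                deviation_score=r.deviation_score,
            )
        )
    return sorted(out, key=lambda f: f.accession)


def write_criteria_table(flags: Sequence[CriterionFlags], path) -> None:
    """Export flags as a criteria TSV (lossless superset of an ARTS-style table)."""
    with open(path, "w") as fh:
        fh.write("accession\tduplication\tphylogeny\tbgc\tbgc_labels\tcopy_number\tdeviation_score\n")
        for f in sorted(flags, key=lambda f: f.accession):
            fh.write(
                "\t".join(
                    [
                        f.accession,
                        "+" if f.duplication else "-",
                        "+" if f.phylogeny else "-",
                        "+" if f.in_bgc else "-",
                        ",".join(f.bgc_labels),
                        str(f.copy_number),
                        "" if f.deviation_score is None else repr(f.deviation_score),
                    ]
                )
                + "\n"
            )
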