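"""Readers and writers for every external format the screen touches.

All internal coordinates are 1-based inclusive (GenBank convention); BED input
is converted from 0-based half-open on ingest and back on egress.  Genes are
identified by locus tag when present, otherwise by a deterministic
``contig:start-end:strand`` key so joins across files are reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_STRANDS = {"+", "-"}

#: symbols of the seven resistance-indicator ribosomal-protein genes, in the
#: column order used by the published validation tables.
RI_SYMBOLS = ("rpsE", "rpsL", "rplC", "rplD", "rplK", "rplQ", "rplV")


class GenomeFormatError(ValueError):
    """Raised when an input file does not parse under the named standard."""


@dataclass
class GeneRecord:
    """A single CDS with 1-based inclusive coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    symbol: Optional[str] = None
    cds_sequence: Optional[str] = None
    sequence_missing: bool = False

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """A strain's contigs plus its ordered gene list."""

    strain_id: str
    contigs: dict[str, str] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            self._check_gene(g)

    def _check_gene(self, g: GeneRecord) -> None:
        if g.contig_id not in self.contigs:
            raise ValueError(f"gene {g.gene_id}: unknown contig {g.contig_id}")
        if g.end > len(self.contigs[g.contig_id]):
            raise ValueError(
                f"gene {g.gene_id}: end {g.end} beyond contig "
                f"{g.contig_id} length {len(self.contigs[g.contig_id])}"
            )


@dataclass
class BgcRegion:
    """A predicted biosynthetic gene cluster region on a contig."""

    region_id: str
    contig_id: str
    start: int
    end: int
    cluster_type: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region {self.region_id}: end {self.end} < start {self.start}")


@dataclass
class ArtsRow:
    """One core-gene family row of an external self-resistance hit table."""

    family_accession: str
    duplication: bool = False
    phylogeny: bool = False
    in_bgc: bool = False
    bgc_label: Optional[str] = None
    copy_number: Optional[int] = None
    deviation_score: Optional[float] = None


def _gene_key(contig_id: str, start: int, end: int, strand: str) -> str:
    return f"{contig_id}:{start}-{end}:{strand}"


# ---------------------------------------------------------------------------
# genome reading
# ---------------------------------------------------------------------------

def read_genome(
    path: str | Path,
    format: str = "genbank",
    fasta: str | Path | None = None,
    strain_id: str | None = None,
) -> GenomeAnnotation:
    """Read an annotated genome into the internal model.

    Parameters
    ----------
    path:
        GenBank flat file, or GFF3 file when ``format="gff3"``.
    format:
        ``"genbank"`` or ``"gff3"`` (the latter requires ``fasta``).
    fasta:
        Companion FASTA with contig sequences for GFF3 input.
    strain_id:
        Override for the strain identifier; defaults to the file stem.
    """
    path = Path(path)
    if strain_id is None:
        strain_id = path.stem
    if format == "genbank":
        return _read_genbank(path, strain_id)
    if format in ("gff3", "gff3+fasta", "gff"):
        if fasta is None:
            raise GenomeFormatError("gff3 input requires a companion FASTA (fasta=...)")
        return _read_gff3(path, Path(fasta), strain_id)
    raise GenomeFormatError(f"unknown genome format {format!r}; supported: genbank, gff3")


def _read_genbank(path: Path, strain_id: str) -> GenomeAnnotation:
    contigs: dict[str, str] = {}
    genes: list[GeneRecord] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise GenomeFormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"{path}: no GenBank records found")
    for rec in records:
        contigs[rec.id] = str(rec.seq)
        has_seq = len(rec.seq) > 0 and set(str(rec.seq[:50])) != {"N"}
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            start = int(feat.location.start) + 1  # 0-based -> 1-based
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            quals = feat.qualifiers
            gene_id = quals.get("locus_tag", [None])[0] or _gene_key(rec.id, start, end, strand)
            cds = None
            missing = False
            if has_seq:
                cds = str(feat.extract(rec.seq))
            else:
                missing = True
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=quals.get("product", [""])[0],
                    symbol=quals.get("gene", [None])[0],
                    cds_sequence=cds,
                    sequence_missing=missing,
                )
            )
    return GenomeAnnotation(strain_id=strain_id, contigs=contigs, genes=genes)


def _read_gff3(path: Path, fasta: Path, strain_id: str) -> GenomeAnnotation:
    import gffutils

    contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    if not contigs:
        raise GenomeFormatError(f"{fasta}: no FASTA records found")
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise GenomeFormatError(f"{path}: not parseable as GFF3: {exc}") from exc

    genes: list[GeneRecord] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        attrs = feat.attributes
        gene_id = (
            attrs.get("locus_tag", [None])[0]
            or attrs.get("ID", [None])[0]
            or _gene_key(feat.seqid, feat.start, feat.end, feat.strand)
        )
        cds = None
        missing = False
        if feat.seqid in contigs:
            seq = Seq(contigs[feat.seqid][feat.start - 1 : feat.end])
            cds = str(seq.reverse_complement()) if feat.strand == "-" else str(seq)
        else:
            missing = True
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand="-" if feat.strand == "-" else "+",
                product=attrs.get("product", [""])[0],
                symbol=attrs.get("gene", [None])[0],
                cds_sequence=cds,
                sequence_missing=missing,
            )
        )
    # genes on contigs absent from the FASTA are flagged, not dropped, so the
    # annotation constructor must tolerate them: give such contigs an empty entry
    contig_ids = {g.contig_id for g in genes}
    for cid in contig_ids - contigs.keys():
        warnings.warn(f"GFF3 contig {cid} missing from FASTA; sequences flagged missing")
        contigs[cid] = "N" * max(g.end for g in genes if g.contig_id == cid)
    return GenomeAnnotation(strain_id=strain_id, contigs=contigs, genes=genes)


# ---------------------------------------------------------------------------
# genome writing (GenBank / GFF3+FASTA round-trip support)
# ---------------------------------------------------------------------------

def write_genbank(genome: GenomeAnnotation, path: str | Path) -> None:
    records = []
    by_contig: dict[str, list[GeneRecord]] = {cid: [] for cid in genome.contigs}
    for g in genome.genes:
        by_contig[g.contig_id].append(g)
    for cid, seq in genome.contigs.items():
        rec = SeqRecord(Seq(seq), id=cid, name=cid[:16], description=genome.strain_id)
        rec.annotations["molecule_type"] = "DNA"
        for g in by_contig[cid]:
            loc = FeatureLocation(g.start - 1, g.end, strand=-1 if g.strand == "-" else 1)
            quals = {"locus_tag": [g.gene_id], "product": [g.product]}
            if g.symbol:
                quals["gene"] = [g.symbol]
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def write_gff3(genome: GenomeAnnotation, gff_path: str | Path, fasta_path: str | Path) -> None:
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs.items():
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for g in genome.genes:
            attrs = [f"ID={g.gene_id}", f"locus_tag={g.gene_id}"]
            if g.symbol:
                attrs.append(f"gene={g.symbol}")
            if g.product:
                attrs.append(f"product={g.product}")
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "psifootprint",
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    with open(fasta_path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# BGC regions
# ---------------------------------------------------------------------------

def read_bgc_regions(path: str | Path, format: str = "gff3") -> list[BgcRegion]:
    """Read BGC regions from GFF3, BED or an antiSMASH-style JSON file.

    Regions are returned sorted by (contig_id, start); overlapping regions are
    preserved as-is.
    """
    path = Path(path)
    if format in ("gff3", "gff"):
        regions = _regions_from_gff(path)
    elif format == "bed":
        regions = _regions_from_bed(path)
    elif format in ("antismash-json", "json"):
        regions = _regions_from_json(path)
    else:
        raise GenomeFormatError(
            f"unknown region format {format!r}; supported: gff3, bed, antismash-json"
        )
    if not regions:
        logger.warning("%s: no BGC regions found", path)
    return sorted(regions, key=lambda r: (r.contig_id, r.start))


def _regions_from_gff(path: Path) -> list[BgcRegion]:
    regions = []
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise GenomeFormatError(f"{path}:{lineno}: malformed GFF line")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            ) if len(parts) > 8 else {}
            n += 1
            regions.append(
                BgcRegion(
                    region_id=attrs.get("ID", f"region_{n}"),
                    contig_id=parts[0],
                    start=int(parts[3]),
                    end=int(parts[4]),
                    cluster_type=attrs.get("product", attrs.get("cluster_type", parts[2])),
                )
            )
    return regions


def _regions_from_bed(path: Path) -> list[BgcRegion]:
    regions = []
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise GenomeFormatError(f"{path}:{lineno}: BED line needs >=3 fields")
            n += 1
            regions.append(
                BgcRegion(
                    region_id=parts[3] if len(parts) > 3 else f"region_{n}",
                    contig_id=parts[0],
                    start=int(parts[1]) + 1,  # 0-based half-open -> 1-based inclusive
                    end=int(parts[2]),
                    cluster_type=parts[4] if len(parts) > 4 else "",
                )
            )
    return regions


def _regions_from_json(path: Path) -> list[BgcRegion]:
    with open(path) as fh:
        doc = json.load(fh)
    regions = []
    # antiSMASH result JSON: records -> areas/regions with start/end
    records = doc.get("records", [doc]) if isinstance(doc, dict) else doc
    n = 0
    for rec in records:
        cid = rec.get("id") or rec.get("contig_id") or "contig_1"
        for area in rec.get("areas", rec.get("regions", [])):
            n += 1
            start = area.get("start", area.get("from"))
            end = area.get("end", area.get("to"))
            products = area.get("products", area.get("product", ""))
            if isinstance(products, list):
                products = ",".join(products)
            regions.append(
                BgcRegion(
                    region_id=area.get("region_id", f"{cid}_r{n}"),
                    contig_id=cid,
                    start=int(start) + 1 if area.get("zero_based", True) and "from" not in area else int(start),
                    end=int(end),
                    cluster_type=products,
                )
            )
    return regions


def write_bed(regions: Sequence[BgcRegion], path: str | Path) -> None:
    """Export regions as BED (back to 0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.contig_id}\t{r.start - 1}\t{r.end}\t{r.region_id}")
            fh.write(f"\t{r.cluster_type}\n" if r.cluster_type else "\n")


# ---------------------------------------------------------------------------
# external self-resistance hit tables (ARTS compat)
# ---------------------------------------------------------------------------

_TRUE_MARKS = {"+", "true", "yes", "1", "y"}
_FALSE_MARKS = {"-", "–", "false", "no", "0", "n", ""}


def _parse_mark(value: str) -> tuple[bool, Optional[str]]:
    """Map a criterion mark to (flag, label). Any region label means true."""
    v = str(value).strip()
    if v.lower() in _TRUE_MARKS:
        return True, None
    if v.lower() in _FALSE_MARKS:
        return False, None
    return True, v  # e.g. a region label such as "6_3"


def read_arts_table(path: str | Path) -> list[ArtsRow]:
    """Read a TSV of per-family self-resistance criteria.

    Expects header columns for the family accession and the three criteria
    (duplication, phylogeny, BGC).  Optional extension columns ``copy_number``,
    ``deviation_score`` and ``bgc_labels`` are honored when present, which lets
    tables exported by this package round-trip losslessly.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = {c.lower().strip(): c for c in df.columns}

    def find(*names: str) -> Optional[str]:
        for n in names:
            if n in cols:
                return cols[n]
        return None

    acc_col = find("accession", "accession id", "family_accession", "family")
    dup_col = find("duplication", "dup", "duplicated")
    phy_col = find("phylogeny", "phylogenetic", "hgt")
    bgc_col = find("bgc", "in_bgc", "bgc localization", "location")
    for name, col in [("accession", acc_col), ("duplication", dup_col),
                      ("phylogeny", phy_col), ("bgc", bgc_col)]:
        if col is None:
            raise GenomeFormatError(f"{path}: missing required column {name!r}")

    cn_col = find("copy_number")
    dev_col = find("deviation_score")
    lbl_col = find("bgc_labels")

    rows = []
    for _, r in df.iterrows():
        acc = r[acc_col].strip()
        if not acc:
            raise GenomeFormatError(f"{path}: row with empty accession")
        dup, _ = _parse_mark(r[dup_col])
        phy, _ = _parse_mark(r[phy_col])
        bgc, label = _parse_mark(r[bgc_col])
        if lbl_col and r[lbl_col].strip():
            label = r[lbl_col].strip()
        rows.append(
            ArtsRow(
                family_accession=acc,
                duplication=dup,
                phylogeny=phy,
                in_bgc=bgc,
                bgc_label=label,
                copy_number=int(r[cn_col]) if cn_col and r[cn_col].strip() else None,
                deviation_score=float(r[dev_col]) if dev_col and r[dev_col].strip() else None,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(results: Iterable, path: str | Path, format: str = "tsv") -> None:
    """Write FootprintResults as a TSV (validation-table layout) or lossless JSON."""
    results = list(results)
    if format == "tsv":
        lines = ["\t".join(["strain_id", "hit_genes", *RI_SYMBOLS, "ri_count", "candidate"])]
        for r in results:
            marks = ["+" if r.ri_present.get(s, False) else "-" for s in RI_SYMBOLS]
            lines.append(
                "\t".join(
                    [r.strain_id, str(r.hit_genes), *marks, str(r.ri_count),
                     "true" if r.candidate else "false"]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")
    elif format == "json":
        Path(path).write_text(json.dumps([r.to_dict() for r in results], indent=1, sort_keys=True) + "\n")
    else:
        raise GenomeFormatError(f"unknown report format {format!r}; supported: tsv, json")


def read_report_json(path: str | Path) -> list:
    from .footprint import FootprintResult

    with open(path) as fh:
        return [FootprintResult.from_dict(d) for d in json.load(fh)]
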