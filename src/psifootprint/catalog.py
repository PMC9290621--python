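"""The protein-synthesis core-gene family catalog and gene-to-family mapping.

The screen rests on a reference set of ~100 gene families involved in
translation: ribosomal proteins, translation factors, aminoacyl-tRNA
synthetases, and rRNA/tRNA modification enzymes.  Seven ribosomal-protein
families (rpsE, rpsL, rplC, rplD, rplK, rplQ, rplV) are flagged as resistance
indicators (RI): point mutations in these proteins are classic routes to
resistance against ribosome-targeting antibiotics, so a self-resistance signal
on them is especially informative.

The default catalog ships as a TSV data file and is user-replaceable; families
whose public TIGRFAM accession could not be confirmed carry package-local
``PSF``-prefixed accessions.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .genome_io import RI_SYMBOLS, GeneRecord, GenomeAnnotation


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class CoreFamily:
    accession: str
    symbol: str
    description: str = ""
    is_ri: bool = False
    expected_copies: int = 1


@dataclass
class CoreFamilyCatalog:
    families: list[CoreFamily]
    name: str = "custom"
    version: str = "0"
    #: optional reference protein sequences per accession (enables best_hit mode)
    reference_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        accs = [f.accession for f in self.families]
        if len(set(accs)) != len(accs):
            raise CatalogError("duplicate accessions in catalog")
        self._by_accession = {f.accession: f for f in self.families}

    def __len__(self) -> int:
        return len(self.families)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def get(self, accession: str) -> Optional[CoreFamily]:
        return self._by_accession.get(accession)

    @property
    def ri_families(self) -> list[CoreFamily]:
        return [f for f in self.families if f.is_ri]

    @property
    def ri_symbols(self) -> list[str]:
        return [f.symbol for f in self.ri_families]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for f in sorted(self.families, key=lambda f: f.accession):
            h.update(
                f"{f.accession}\t{f.symbol}\t{f.description}\t{f.is_ri}\t{f.expected_copies}\n".encode()
            )
        return h.hexdigest()


@dataclass(frozen=True)
class FamilyAssignment:
    gene_id: str
    accession: str
    method: str  # symbol | profile | best_hit | external
    score: Optional[float] = None


def _data_path(name: str):
    return resources.files("psifootprint.data") / name


def read_catalog(path, name: str = "custom", version: str = "0") -> CoreFamilyCatalog:
    """Read a catalog TSV (accession, symbol, description, is_ri, expected_copies)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"accession", "symbol", "description", "is_ri"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"catalog missing columns: {sorted(missing)}")
    fams = [
        CoreFamily(
            accession=r["accession"],
            symbol=r["symbol"],
            description=r["description"],
            is_ri=str(r["is_ri"]).strip().lower() in ("true", "1", "+", "yes"),
            expected_copies=int(r.get("expected_copies", "1") or 1),
        )
        for _, r in df.iterrows()
    ]
    return CoreFamilyCatalog(families=fams, name=name, version=version)


def load_default_catalog() -> CoreFamilyCatalog:
    """Load the packaged 100-family translation core-gene catalog."""
    with resources.as_file(_data_path("core_catalog.tsv")) as p:
        cat = read_catalog(p, name="psifootprint-default", version="1")
    ri = {f.symbol for f in cat.ri_families}
    assert ri == set(RI_SYMBOLS), "packaged catalog RI subset corrupted"
    return cat


def load_alias_table() -> dict[str, dict[str, str]]:
    """Packaged alias table: {'symbol': {alias->accession}, 'product': {...}}."""
    import pandas as pd

    with resources.as_file(_data_path("aliases.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    out: dict[str, dict[str, str]] = {"symbol": {}, "product": {}}
    for _, r in df.iterrows():
        out[r["kind"]][_norm(r["alias"])] = r["accession"]
    return out


def _norm(s: str) -> str:
    return re.sub(r"\s+", " ", s.strip().lower())


def _symbol_keys(symbol: str) -> list[str]:
    """Lookup keys for a catalog symbol; 'tufA/B' also answers to tufA and tufB."""
    keys = [_norm(symbol)]
    m = re.fullmatch(r"([A-Za-z]+)([A-Z])/([A-Z])", symbol)
    if m:
        keys += [_norm(m.group(1) + m.group(2)), _norm(m.group(1) + m.group(3))]
    return keys


def assign_families(
    genome: GenomeAnnotation,
    catalog: CoreFamilyCatalog,
    mode: str = "symbol",
    external_table=None,
) -> list[FamilyAssignment]:
    """Map annotated genes onto catalog families.

    Modes
    -----
    symbol
        Case-insensitive match of the gene symbol, then of the product string,
        against catalog symbols/descriptions and the packaged alias table.
    best_hit
        Align each gene's translated CDS against catalog reference protein
        sequences and take the best-scoring family above a floor.  Requires
        ``catalog.reference_sequences``.
    external-table
        Take a precomputed ``gene_id -> accession`` mapping (dict or TSV path).

    A gene maps to at most one family; genes with no match are silently left
    unassigned.
    """
    if mode == "symbol":
        return _assign_by_symbol(genome, catalog)
    if mode == "best_hit":
        if not catalog.reference_sequences:
            raise CatalogError(
                "best_hit mode requires catalog reference protein sequences "
                "(catalog.reference_sequences is empty)"
            )
        return _assign_by_best_hit(genome, catalog)
    if mode in ("external-table", "external"):
        if external_table is None:
            raise CatalogError("external-table mode requires external_table")
        return _assign_external(genome, catalog, external_table)
    raise CatalogError(f"unknown assignment mode {mode!r}")


def _assign_by_symbol(genome: GenomeAnnotation, catalog: CoreFamilyCatalog) -> list[FamilyAssignment]:
    aliases = load_alias_table()
    sym_map: dict[str, str] = dict(aliases["symbol"])
    prod_map: dict[str, str] = dict(aliases["product"])
    for f in catalog.families:
        for k in _symbol_keys(f.symbol):
            sym_map.setdefault(k, f.accession)
        if f.description:
            prod_map.setdefault(_norm(f.description), f.accession)

    out = []
    for g in genome.genes:
        acc = None
        if g.symbol:
            acc = sym_map.get(_norm(g.symbol))
        if acc is None and g.product:
            acc = prod_map.get(_norm(g.product))
        if acc is not None and acc in catalog:
            out.append(FamilyAssignment(gene_id=g.gene_id, accession=acc, method="symbol"))
    return out


def _translate(g: GeneRecord) -> Optional[str]:
    if not g.cds_sequence or len(g.cds_sequence) < 6:
        return None
    from Bio.Seq import Seq

    n = len(g.cds_sequence) - len(g.cds_sequence) % 3
    prot = str(Seq(g.cds_sequence[:n]).translate(table=11)).rstrip("*")
    return prot.replace("*", "X") or None


def _assign_by_best_hit(
    genome: GenomeAnnotation, catalog: CoreFamilyCatalog, min_score: float = 60.0
) -> list[FamilyAssignment]:
    from skbio.alignment import pair_align_prot

    out = []
    refs = catalog.reference_sequences
    for g in genome.genes:
        prot = _translate(g)
        if prot is None:
            continue
        best_acc, best_score = None, min_score
        for acc, ref in refs.items():
            score = float(pair_align_prot(prot, ref, mode="local").score)
            if score > best_score:
                best_acc, best_score = acc, score
        if best_acc is not None:
            out.append(
                FamilyAssignment(gene_id=g.gene_id, accession=best_acc,
                                 method="best_hit", score=best_score)
            )
    return out


def _assign_external(genome, catalog, external_table) -> list[FamilyAssignment]:
    if isinstance(external_table, (str, Path)):
        import pandas as pd

        df = pd.read_csv(external_table, sep="\t", dtype=str)
        mapping = dict(zip(df["gene_id"], df["accession"]))
    else:
        mapping = dict(external_table)
    known = {g.gene_id for g in genome.genes}
    return [
        FamilyAssignment(gene_id=gid, accession=acc, method="external")
        for gid, acc in mapping.items()
        if gid in known and acc in catalog
    ]
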