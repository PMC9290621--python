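"""Dereplication by gene-cluster similarity.

The similarity of a query region to a reference biosynthetic gene cluster is
the percentage of reference genes for which the query contains a matching
gene.  Two protein sequences match when a local (Smith-Waterman, BLOSUM62,
BLASTP-default gap costs) alignment has identity above ``min_identity``,
covers more than ``min_coverage`` percent of the shorter sequence, and clears
a raw-score significance floor.  The score floor replaces a database e-value
cutoff, which is search-context-dependent: ``min_score=60`` was calibrated so
that seeded random 200-residue pairs fail at >=99% rate.  If all reference
genes are found the similarity is 100%; it decreases as fewer are found.

Strains whose best similarity against any known-PSI reference cluster reaches
the dereplication cutoff are sorted out as producers of an already known
compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from skbio.alignment import pair_align_prot

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBJXZUO*")


@dataclass
class SimilarityParams:
    min_identity: float = 30.0  # percent, strict >
    min_coverage: float = 25.0  # percent of the shorter sequence, strict >
    min_score: float = 60.0  # raw SW score floor (e-value surrogate)
    max_evalue: float = 1e-5  # applied when ingesting precomputed search tables

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100 and 0 < self.min_coverage <= 100):
            raise ValueError("identity/coverage thresholds must be in (0, 100]")
        if self.min_score < 0 or self.max_evalue <= 0:
            raise ValueError("min_score must be >= 0 and max_evalue > 0")


@dataclass
class ReferenceCluster:
    cluster_id: str
    compound: str
    genes: list[tuple[str, str]]  # (gene_id, protein sequence)
    is_psi: bool = True

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"reference cluster {self.cluster_id} has no genes")
        for gid, seq in self.genes:
            _check_protein(seq, gid)


@dataclass
class BgcSimilarityResult:
    cluster_id: str
    similarity: float  # percent of reference genes matched
    matched_genes: list[tuple[str, str, float, float]] = field(default_factory=list)
    compound: str = ""


def _check_protein(seq: str, label: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{label}: empty protein sequence")
    bad = set(seq.upper()) - _AA_ALPHABET
    if bad:
        raise ValueError(f"{label}: non-amino-acid characters {sorted(bad)}")


def gene_match(
    query_protein: str,
    reference_protein: str,
    params: SimilarityParams | None = None,
) -> tuple[bool, float, float]:
    """Local alignment of two proteins; returns (matched, identity%, coverage%)."""
    params = params or SimilarityParams()
    _check_protein(query_protein, "query")
    _check_protein(reference_protein, "reference")
    q, r = query_protein.upper(), reference_protein.upper()
    res = pair_align_prot(q, r, mode="local")
    if not res.paths:
        return False, 0.0, 0.0
    path = res.paths[0]
    coords = path.to_coordinates()  # (2, nseg+1) cumulative positions
    matches = 0
    columns = 0
    for i in range(coords.shape[1] - 1):
        dq = int(coords[0, i + 1] - coords[0, i])
        dr = int(coords[1, i + 1] - coords[1, i])
        columns += max(dq, dr)
        if dq and dr:  # aligned segment
            qs = q[coords[0, i] : coords[0, i + 1]]
            rs = r[coords[1, i] : coords[1, i + 1]]
            matches += sum(a == b for a, b in zip(qs, rs))
    identity = 100.0 * matches / columns if columns else 0.0
    shorter = min(len(q), len(r))
    aligned_on_shorter = int(
        (path.ranges[0, 1] - path.ranges[0, 0])
        if len(q) <= len(r)
        else (path.ranges[1, 1] - path.ranges[1, 0])
    )
    coverage = 100.0 * aligned_on_shorter / shorter
    matched = (
        identity > params.min_identity
        and coverage > params.min_coverage
        and float(res.score) >= params.min_score
    )
    return matched, identity, coverage


def cluster_similarity(
    query_genes: Sequence[str],
    reference: ReferenceCluster,
    params: SimilarityParams | None = None,
) -> BgcSimilarityResult:
    """Percent of reference genes with at least one matching query gene."""
    params = params or SimilarityParams()
    matched: list[tuple[str, str, float, float]] = []
    n_matched = 0
    for ref_id, ref_seq in reference.genes:
        best = None
        for qi, q in enumerate(query_genes):
            ok, ident, cov = gene_match(q, ref_seq, params)
            if ok and (best is None or ident > best[2]):
                best = (ref_id, f"query_{qi}", ident, cov)
        if best is not None:
            n_matched += 1
            matched.append(best)
    similarity = 100.0 * n_matched / len(reference.genes)
    return BgcSimilarityResult(
        cluster_id=reference.cluster_id,
        similarity=similarity,
        matched_genes=matched,
        compound=reference.compound,
    )


def cluster_similarity_from_table(
    table, reference: ReferenceCluster, params: SimilarityParams | None = None
) -> BgcSimilarityResult:
    """Similarity from a precomputed alignment TSV instead of desk alignment.

    Expected columns: ref_gene, query_gene, identity, coverage, and optionally
    evalue (filtered at ``params.max_evalue``).
    """
    import pandas as pd

    params = params or SimilarityParams()
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep="\t")
    if "evalue" in df.columns:
        df = df[df["evalue"] < params.max_evalue]
    df = df[(df["identity"] > params.min_identity) & (df["coverage"] > params.min_coverage)]
    matched = []
    ref_ids = [gid for gid, _ in reference.genes]
    for rid in ref_ids:
        sub = df[df["ref_gene"] == rid]
        if len(sub):
            best = sub.sort_values("identity", ascending=False).iloc[0]
            matched.append((rid, str(best["query_gene"]), float(best["identity"]),
                            float(best["coverage"])))
    return BgcSimilarityResult(
        cluster_id=reference.cluster_id,
        similarity=100.0 * len(matched) / len(ref_ids),
        matched_genes=matched,
        compound=reference.compound,
    )


def dereplicate(
    results: Iterable,
    similarities: Mapping[str, Sequence[BgcSimilarityResult]],
    cutoff: float = 80.0,
) -> dict[str, list]:
    """Partition strains into novel candidates vs known-PSI matches.

    A strain is moved to ``known-psi-match`` iff any of its cluster
    similarities reaches ``cutoff`` percent.
    """
    if not (0 < cutoff <= 100):
        raise ValueError("cutoff must be in (0, 100]")
    novel, known = [], []
    for r in results:
        sims = similarities.get(r.strain_id, [])
        if any(s.similarity >= cutoff for s in sims):
            known.append(r)
        else:
            novel.append(r)
    return {"novel-candidate": novel, "known-psi-match": known}


# ---------------------------------------------------------------------------
# reference cluster I/O
# ---------------------------------------------------------------------------

def load_reference_clusters(directory: str | Path | None = None) -> list[ReferenceCluster]:
    """Load reference clusters from a directory of FASTAs plus a manifest TSV.

    Manifest columns: cluster_id, compound, is_psi, file.  Defaults to the
    packaged synthetic toy set (constructed sequences for tests and examples,
    not real biosynthetic genes).
    """
    import pandas as pd
    from Bio import SeqIO

    if directory is None:
        ctx = resources.as_file(resources.files("psifootprint.data") / "ref_clusters_synthetic")
        with ctx as p:
            return load_reference_clusters(p)
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t", dtype=str)
    clusters = []
    for _, row in manifest.iterrows():
        genes = [
            (rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(directory / row["file"]), "fasta")
        ]
        clusters.append(
            ReferenceCluster(
                cluster_id=row["cluster_id"],
                compound=row["compound"],
                genes=genes,
                is_psi=str(row.get("is_psi", "true")).lower() in ("true", "1", "+", "yes"),
            )
        )
    return clusters
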