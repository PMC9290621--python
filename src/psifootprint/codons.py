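"""Codon bookkeeping shared by the HGT statistic and the genome generator.

Uses the bacterial translation table (NCBI table 11).  Relative synonymous
codon usage (RSCU) for codon c of amino acid a with k synonyms:
``RSCU(c) = k * n(c) / sum_synonyms n``; 1.0 means no preference.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"


@lru_cache(maxsize=1)
def codon_map() -> dict[str, str]:
    """codon -> amino acid (stop codons excluded), table 11."""
    table = CodonTable.unambiguous_dna_by_id[11]
    return dict(table.forward_table)


@lru_cache(maxsize=1)
def synonym_map() -> dict[str, tuple[str, ...]]:
    """amino acid -> tuple of synonymous codons."""
    syn: dict[str, list[str]] = {}
    for codon, aa in codon_map().items():
        syn.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in syn.items()}


@lru_cache(maxsize=1)
def degenerate_codons() -> tuple[str, ...]:
    """Codons of amino acids with >=2 synonyms (the RSCU-informative set)."""
    out = []
    for aa, cs in synonym_map().items():
        if len(cs) > 1:
            out.extend(cs)
    return tuple(sorted(out))


def gc_count(codon: str) -> int:
    return sum(1 for b in codon if b in "GC")


def codon_counts(cds: str) -> dict[str, int]:
    """Count coding codons of a CDS (start to last full codon; stops ignored)."""
    cmap = codon_map()
    counts: dict[str, int] = {}
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3].upper()
        if codon in cmap:
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def rscu(counts: dict[str, int]) -> dict[str, float]:
    """RSCU per codon, restricted to degenerate amino acids present in counts."""
    out: dict[str, float] = {}
    for aa, codons in synonym_map().items():
        if len(codons) < 2:
            continue
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        k = len(codons)
        for c in codons:
            out[c] = k * counts.get(c, 0) / total
    return out


def gc_fraction(cds: str) -> float:
    s = cds.upper()
    n = sum(1 for b in s if b in BASES)
    if n == 0:
        return float("nan")
    return sum(1 for b in s if b in "GC") / n


# ---------------------------------------------------------------------------
# parametric codon model: synonymous codon weights w(c) ∝ exp(beta * gc(c))
# ---------------------------------------------------------------------------

def codon_probs(beta: float) -> dict[str, np.ndarray]:
    """Per-amino-acid synonymous codon probabilities at GC preference ``beta``."""
    probs = {}
    for aa, codons in synonym_map().items():
        w = np.array([np.exp(beta * gc_count(c)) for c in codons])
        probs[aa] = w / w.sum()
    return probs


def expected_gc(beta: float, aa_probs: dict[str, float] | None = None) -> float:
    """Expected per-position GC of a random CDS under the model.

    ``aa_probs`` defaults to the uniform distribution over the 20 amino acids.
    """
    syn = synonym_map()
    if aa_probs is None:
        aa_probs = {aa: 1.0 / len(syn) for aa in syn}
    probs = codon_probs(beta)
    e = 0.0
    for aa, p_aa in aa_probs.items():
        codons = syn[aa]
        e += p_aa * float(np.dot(probs[aa], [gc_count(c) for c in codons]))
    return e / 3.0


def gc_codon_variance(beta: float, aa_probs: dict[str, float] | None = None) -> float:
    """Variance of the per-codon GC count under the model (aa and codon random)."""
    syn = synonym_map()
    if aa_probs is None:
        aa_probs = {aa: 1.0 / len(syn) for aa in syn}
    probs = codon_probs(beta)
    e1 = e2 = 0.0
    for aa, p_aa in aa_probs.items():
        gcs = np.array([gc_count(c) for c in syn[aa]])
        e1 += p_aa * float(np.dot(probs[aa], gcs))
        e2 += p_aa * float(np.dot(probs[aa], gcs**2))
    return e2 - e1**2


def solve_beta(target_gc: float, tol: float = 1e-9) -> float:
    """Invert ``expected_gc`` by bisection.  Valid for target_gc in ~(0.2, 0.9)."""
    lo, hi = -12.0, 12.0
    if not (expected_gc(lo) < target_gc < expected_gc(hi)):
        raise ValueError(f"target GC {target_gc} outside achievable range")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if expected_gc(mid) < target_gc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def null_gene_gc_sd(beta: float, n_codons: int) -> float:
    """Analytic sd of a gene's GC fraction under iid codon sampling."""
    return float(np.sqrt(gc_codon_variance(beta) / n_codons) / 3.0)
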