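"""The Ψ-footprint: hit-gene counting, RI detection, strain classification.

A *hit gene* is a core-gene family fulfilling at least one of the three
self-resistance criteria.  A strain is a candidate protein-synthesis-inhibitor
(PSI) producer when it carries at least ``min_hit_genes`` hit genes (default
20) and at least ``min_ri_genes`` of the seven resistance-indicator families
are themselves hit genes (default 2).  RI "presence" is criterion-conditional:
every bacterium encodes rpsL, but only an rpsL with a resistance footprint
counts.

Also houses the reporter-assay classifier: relative GFP fluorescence of a
coupled in-vitro transcription/translation (ivTT) assay is read as specific
inhibition at <=40% and strong inhibition at <=20% of the uninhibited control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .catalog import CoreFamilyCatalog
from .criteria import CriterionFlags
from .genome_io import RI_SYMBOLS


@dataclass
class ClassifierConfig:
    min_hit_genes: int = 20
    min_ri_genes: int = 2

    def __post_init__(self) -> None:
        if self.min_hit_genes < 0 or self.min_ri_genes < 0:
            raise ValueError("classifier thresholds must be >= 0")


@dataclass
class IvttThresholds:
    specific_max: float = 40.0
    strong_max: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.strong_max <= self.specific_max <= 100):
            raise ValueError("need 0 < strong_max <= specific_max <= 100")


@dataclass
class FootprintResult:
    strain_id: str
    hit_genes: int
    ri_present: dict[str, bool]
    ri_count: int
    candidate: bool
    flags: list[CriterionFlags] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "hit_genes": self.hit_genes,
            "ri_present": dict(self.ri_present),
            "ri_count": self.ri_count,
            "candidate": self.candidate,
            "flags": [f.to_dict() for f in self.flags],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FootprintResult":
        d = dict(d)
        d["flags"] = [CriterionFlags.from_dict(f) for f in d.get("flags", [])]
        return cls(**d)


def count_hit_genes(flags: Sequence[CriterionFlags]) -> int:
    """Number of families fulfilling at least one criterion."""
    accs = [f.accession for f in flags]
    if len(set(accs)) != len(accs):
        raise ValueError("duplicate accessions in criterion flags (upstream bug)")
    return sum(1 for f in flags if f.is_hit)


def detect_ri(
    flags: Sequence[CriterionFlags], catalog: CoreFamilyCatalog
) -> tuple[dict[str, bool], int]:
    """RI symbol -> present (its family is a hit gene), plus the count."""
    hit_accessions = {f.accession for f in flags if f.is_hit}
    ri_present = {}
    for fam in catalog.ri_families:
        ri_present[fam.symbol] = fam.accession in hit_accessions
    # stable column order of the validation tables
    ri_present = {s: ri_present.get(s, False) for s in RI_SYMBOLS}
    return ri_present, sum(ri_present.values())


def classify_strain(
    hit_genes: int, ri_count: int, config: ClassifierConfig | None = None
) -> bool:
    """Candidate PSI producer iff hit_genes >= 20 and ri_count >= 2 (defaults)."""
    config = config or ClassifierConfig()
    if hit_genes < 0 or ri_count < 0:
        raise ValueError("hit_genes and ri_count must be non-negative")
    return hit_genes >= config.min_hit_genes and ri_count >= config.min_ri_genes


def compute_footprint(
    strain_id: str,
    flags: Sequence[CriterionFlags],
    catalog: CoreFamilyCatalog,
    config: ClassifierConfig | None = None,
) -> FootprintResult:
    """Assemble the per-strain result from merged criterion flags."""
    flags = sorted(flags, key=lambda f: f.accession)
    hits = count_hit_genes(flags)
    ri_present, ri_count = detect_ri(flags, catalog)
    return FootprintResult(
        strain_id=strain_id,
        hit_genes=hits,
        ri_present=ri_present,
        ri_count=ri_count,
        candidate=classify_strain(hits, ri_count, config),
        flags=list(flags),
    )


def rank_strains(results: Iterable[FootprintResult]) -> list[FootprintResult]:
    """Descending by hit genes, then RI count; ties broken by strain id."""
    return sorted(results, key=lambda r: (-r.hit_genes, -r.ri_count, r.strain_id))


def classify_ivtt(
    relative_fluorescence: float, thresholds: IvttThresholds | None = None
) -> str:
    """Classify a relative GFP fluorescence (%) as none / specific / strong."""
    thresholds = thresholds or IvttThresholds()
    if relative_fluorescence < 0:
        raise ValueError("relative fluorescence must be >= 0")
    if relative_fluorescence <= thresholds.strong_max:
        return "strong"
    if relative_fluorescence <= thresholds.specific_max:
        return "specific"
    return "none"
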