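"""Mass-based dereplication of candidate compounds.

Parses Hill-notation molecular formulas, computes average (standard atomic
weight) and monoisotopic masses, derives singly-charged adduct m/z values
([M+H]+ and [M-H]-, using the proton mass 1.007276 Da rather than the hydrogen
atom mass), and matches observed HPLC-MS peaks against a compound reference
table.  The default matching tolerance of 0.3 Da suits low-resolution ion-trap
data, where printed peak values can sit ~0.1 Da off theory.

Element masses come from the NIST isotope table shipped with pyteomics (a
fixed snapshot, so results are reproducible across installations).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from pyteomics import mass as _ptmass

PROTON_MASS = 1.007276  # Da
ADDUCTS = ("[M+H]+", "[M-H]-")
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    pass


@dataclass(frozen=True)
class MolecularFormula:
    element_counts: tuple[tuple[str, int], ...]  # frozen mapping, Hill-sortable

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "MolecularFormula":
        for el, n in counts.items():
            if n < 1:
                raise FormulaError(f"element {el}: count must be >= 1, got {n}")
        return cls(tuple(sorted(counts.items(), key=_hill_key)))

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.element_counts)

    def __str__(self) -> str:
        return format_formula(self)


def _hill_key(item: tuple[str, int]):
    # Hill order: C first, H second, then alphabetical
    el = item[0]
    return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))


def _known_elements() -> set[str]:
    return {k for k in _ptmass.nist_mass if k.isalpha()}


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula like ``C20H29N3O7`` (implicit count = 1)."""
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    known = _known_elements()
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in known:
            raise FormulaError(f"unknown element {el!r} at position {pos} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return MolecularFormula.from_counts(counts)


def format_formula(f: MolecularFormula) -> str:
    out = []
    for el, n in f.element_counts:
        out.append(el if n == 1 else f"{el}{n}")
    return "".join(out)


@dataclass(frozen=True)
class CompoundEntry:
    name: str
    formula: MolecularFormula
    is_psi: bool = True
    notes: str = ""


@dataclass(frozen=True)
class PeakObservation:
    mz: float
    ion_mode: str  # positive | negative
    retention_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be > 0")
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError("ion_mode must be positive or negative")


@dataclass(frozen=True)
class AdductMatch:
    compound: CompoundEntry
    adduct: str
    theoretical_mz: float
    observed_mz: float
    delta: float
    within_tolerance: bool


# ---------------------------------------------------------------------------
# masses
# ---------------------------------------------------------------------------

def average_mass(f: MolecularFormula) -> float:
    """Sum of count x standard atomic weight (isotope-abundance average), Da."""
    total = 0.0
    for el, n in f.element_counts:
        isotopes = _ptmass.nist_mass[el]
        avg = sum(m * abundance for _, (m, abundance) in isotopes.items() if _ != 0)
        if avg == 0:
            raise FormulaError(f"element {el} has no standard atomic weight")
        total += n * avg
    return total


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of count x most-abundant-isotope mass, Da."""
    total = 0.0
    for el, n in f.element_counts:
        isotopes = _ptmass.nist_mass[el]
        candidates = [(ab, m) for iso, (m, ab) in isotopes.items() if iso != 0]
        if not candidates:
            raise FormulaError(f"element {el} has no isotope masses")
        total += n * max(candidates)[1]
    return total


def adduct_mz(f: MolecularFormula, adduct: str) -> float:
    """m/z of a singly charged protonated/deprotonated adduct."""
    mono = monoisotopic_mass(f)
    if adduct == "[M+H]+":
        return mono + PROTON_MASS
    if adduct == "[M-H]-":
        return mono - PROTON_MASS
    raise ValueError(f"unsupported adduct {adduct!r}; supported: {', '.join(ADDUCTS)}")


def _mode_adduct(ion_mode: str) -> str:
    return "[M+H]+" if ion_mode == "positive" else "[M-H]-"


def match_peaks(
    peaks: Sequence[PeakObservation],
    table: Sequence[CompoundEntry],
    tolerance: float = 0.3,
) -> list[AdductMatch]:
    """Match observed peaks against a compound table.

    Every (peak, compound) pair is evaluated with the mode-consistent adduct;
    matches within ``tolerance`` (Da) are returned sorted by delta ascending,
    ties broken by compound name.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    matches = []
    for peak in peaks:
        adduct = _mode_adduct(peak.ion_mode)
        for compound in table:
            theo = adduct_mz(compound.formula, adduct)
            delta = abs(peak.mz - theo)
            if delta <= tolerance:
                matches.append(
                    AdductMatch(
                        compound=compound,
                        adduct=adduct,
                        theoretical_mz=theo,
                        observed_mz=peak.mz,
                        delta=delta,
                        within_tolerance=True,
                    )
                )
    return sorted(matches, key=lambda m: (m.delta, m.compound.name))


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_compound_table(path) -> list[CompoundEntry]:
    """Compound TSV with columns name, formula, is_psi[, notes]."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = []
    seen = set()
    for _, r in df.iterrows():
        if r["name"] in seen:
            raise ValueError(f"duplicate compound name {r['name']!r}")
        seen.add(r["name"])
        entries.append(
            CompoundEntry(
                name=r["name"],
                formula=parse_formula(r["formula"]),
                is_psi=str(r.get("is_psi", "true")).lower() in ("true", "1", "+", "yes"),
                notes=r.get("notes", ""),
            )
        )
    return entries


def read_peak_list(path) -> list[PeakObservation]:
    """Peak TSV with columns mz, mode[, rt]."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    peaks = []
    for _, r in df.iterrows():
        rt = float(r["rt"]) if "rt" in df.columns and not pd.isna(r["rt"]) else None
        peaks.append(PeakObservation(mz=float(r["mz"]), ion_mode=str(r["mode"]), retention_time=rt))
    return peaks


def write_match_report(matches: Sequence[AdductMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("compound\tadduct\ttheoretical_mz\tobserved_mz\tdelta\tis_psi\n")
        for m in matches:
            fh.write(
                f"{m.compound.name}\t{m.adduct}\t{m.theoretical_mz:.4f}\t"
                f"{m.observed_mz:.4f}\t{m.delta:.4f}\t{str(m.compound.is_psi).lower()}\n"
            )
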