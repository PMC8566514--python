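"""Exact-mass arithmetic and halogen isotopologue simulation.

The unit of all mass bookkeeping is the :class:`ElementalFormula`, an
element-count map over the study's element set {C, H, N, O, S, Cl, Br}.
Positive-mode electrospray produces protonated molecules, so ion m/z is
computed as the neutral monoisotopic mass plus a proton (hydrogen atom
minus one electron).  Isotopologue clusters are obtained by exact
convolution of the per-element isotope distributions; the A+2 / A+4
companions produced by Cl and Br are the diagnostic signature the
screening workflow keys on.

Isotope masses and abundances ship as a version-stamped JSON table
(``data/isotopes.json``) so that results do not drift with third-party
library updates.
"""

from __future__ import annotations

import itertools
import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "ELEMENTS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "IonSpec",
    "IsotopePattern",
    "parse_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "cation_mz",
    "ppm_error",
    "rdbe",
    "nitrogen_rule_ok",
    "isotopologue_pattern",
    "round_half_away",
]


def _load_isotopes() -> Tuple[dict, float]:
    with resources.files("halomet.data").joinpath("isotopes.json").open() as fh:
        table = json.load(fh)
    elements = {
        el: tuple((float(m), float(a)) for m, a in rows)
        for el, rows in table["elements"].items()
    }
    return elements, float(table["electron_mass"])


#: per element: tuple of (isotope mass, abundance), most abundant first is
#: not guaranteed by the file; resolved below.
ISOTOPES, ELECTRON_MASS = _load_isotopes()
ELEMENTS: Tuple[str, ...] = tuple(ISOTOPES)

#: monoisotopic (= most abundant isotope) mass per element
MONO_MASS: Dict[str, float] = {
    el: max(rows, key=lambda r: r[1])[0] for el, rows in ISOTOPES.items()
}
#: integer nominal mass of the most abundant isotope
NOMINAL_MASS: Dict[str, int] = {el: round(m) for el, m in MONO_MASS.items()}

PROTON_MASS: float = MONO_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def round_half_away(value: float, ndigits: int) -> float:
    """Round with ties going away from zero (the convention of printed
    mass tables, where e.g. 2.4576 ppm appears as 2.5)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element -> count map; supports addition for adduct and
    conjugate arithmetic."""

    counts: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        total = 0
        for el, n in self.counts:
            if el not in ISOTOPES:
                raise ValueError(f"unsupported element: {el!r}")
            if el in seen:
                raise ValueError(f"duplicate element: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el!r}")
            seen.add(el)
            total += n
        if total == 0:
            raise ValueError("formula must contain at least one atom")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        items = tuple(sorted((el, int(n)) for el, n in counts.items() if n))
        return cls(items)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula.from_counts(merged)

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    def hill(self) -> str:
        """Hill notation: C first, then H, then the rest alphabetically;
        without carbon, everything alphabetical."""
        d = self.as_dict()
        parts: List[str] = []
        if "C" in d:
            order = ["C"] + (["H"] if "H" in d else [])
            order += sorted(el for el in d if el not in ("C", "H"))
        else:
            order = sorted(d)
        for el in order:
            n = d[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``C19H14BrClN6O2``.

    Raises ``ValueError`` on unknown elements or malformed multipliers;
    round-trips through :meth:`ElementalFormula.hill`.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(text):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise ValueError(f"malformed formula {text!r} at offset {pos}")
        el, digits = match.groups()
        if el not in ISOTOPES:
            raise ValueError(f"unknown element {el!r} in {text!r}")
        if digits == "0":
            raise ValueError(f"zero multiplier for {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at offset {pos}")
    return ElementalFormula.from_counts(counts)


@dataclass(frozen=True)
class IonSpec:
    """A singly charged adduct ion of a neutral molecule.

    Only [M+H]+ is exercised by this workflow (positive H-ESI); the enum is
    kept open for future adducts.
    """

    neutral: ElementalFormula
    adduct: str = "M+H"
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError("only charge +1 is supported")
        if self.adduct != "M+H":
            raise ValueError(f"unsupported adduct {self.adduct!r}")

    @property
    def ion_formula(self) -> ElementalFormula:
        return self.neutral + ElementalFormula.from_counts({"H": 1})


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Sum of most-abundant-isotope masses, in Da."""
    return sum(MONO_MASS[el] * n for el, n in f.counts)


def nominal_mass(f: ElementalFormula) -> int:
    return sum(NOMINAL_MASS[el] * n for el, n in f.counts)


def cation_mz(ion: IonSpec | ElementalFormula) -> float:
    """m/z of the protonated molecule: neutral mass + m(H) - m(e).

    The electron mass must be subtracted to land on the accurate values
    that high-resolution instruments report (473.0123 for the parent
    insecticide, not 473.0128).
    """
    if isinstance(ion, ElementalFormula):
        ion = IonSpec(ion)
    return monoisotopic_mass(ion.neutral) + PROTON_MASS


def ppm_error(observed_mz: float, reference_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if reference_mz <= 0:
        raise ValueError("reference m/z must be positive")
    return (observed_mz - reference_mz) / reference_mz * 1e6


def rdbe(f: ElementalFormula) -> float:
    """Ring-plus-double-bond equivalents: C + 1 + (N - H - Cl - Br)/2.

    Halogens count as hydrogen-like monovalent substituents; oxygen and
    sulfur are valence-two and do not contribute.  Half-integral values
    flag odd-electron species and are used to reject formulas.
    """
    d = f.as_dict()
    return (
        d.get("C", 0)
        + 1
        + (d.get("N", 0) - d.get("H", 0) - d.get("Cl", 0) - d.get("Br", 0)) / 2
    )


def nitrogen_rule_ok(f: ElementalFormula) -> bool:
    """Nitrogen rule for a *neutral* molecule: the parity of the integer
    nominal mass must match the parity of the nitrogen count (odd nominal
    mass <=> odd number of N atoms)."""
    return nominal_mass(f) % 2 == f["N"] % 2


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided isotopologue clusters of an ion.

    ``clusters`` are (m/z, relative abundance in % of base peak), sorted by
    m/z; the base peak is normalized to 100.
    """

    clusters: Tuple[Tuple[float, float], ...]
    aggregation_bin: float = 0.01

    def __post_init__(self) -> None:
        mzs = [c[0] for c in self.clusters]
        if mzs != sorted(mzs):
            raise ValueError("clusters must be sorted by m/z")

    @property
    def base_mz(self) -> float:
        return max(self.clusters, key=lambda c: c[1])[0]

    def mz_values(self) -> Tuple[float, ...]:
        return tuple(c[0] for c in self.clusters)

    def abundances(self) -> Tuple[float, ...]:
        return tuple(c[1] for c in self.clusters)

    def rescaled(self, factor: float) -> "IsotopePattern":
        return IsotopePattern(
            tuple((mz, ab * factor) for mz, ab in self.clusters),
            self.aggregation_bin,
        )

    def shifted_ppm(self, ppm: float) -> "IsotopePattern":
        scale = 1.0 + ppm * 1e-6
        return IsotopePattern(
            tuple((mz * scale, ab) for mz, ab in self.clusters),
            self.aggregation_bin,
        )


def _element_compositions(el: str, n: int, floor: float) -> List[Tuple[float, float]]:
    """Mass/probability of all isotope compositions of ``n`` atoms of one
    element (multinomial expansion), pruned below ``floor`` probability."""
    isotopes = ISOTOPES[el]
    k = len(isotopes)
    out: List[Tuple[float, float]] = []
    for split in itertools.combinations_with_replacement(range(k), n):
        # split is a sorted assignment of isotopes to atoms
        counts = [0] * k
        for idx in split:
            counts[idx] += 1
        coef = math.factorial(n)
        prob = 1.0
        mass = 0.0
        for idx, c in enumerate(counts):
            coef //= math.factorial(c)
            prob *= isotopes[idx][1] ** c
            mass += isotopes[idx][0] * c
        prob *= coef
        if prob >= floor:
            out.append((mass, prob))
    return out


def _species_distribution(f: ElementalFormula, floor: float) -> List[Tuple[float, float]]:
    """Exact isotopologue species (mass, probability) of a formula by
    convolving per-element composition distributions."""
    species: List[Tuple[float, float]] = [(0.0, 1.0)]
    for el, n in f.counts:
        part = _element_compositions(el, n, floor)
        species = [
            (m1 + m2, p1 * p2)
            for m1, p1 in species
            for m2, p2 in part
            if p1 * p2 >= floor
        ]
    return species


def _bin_species(
    species: Sequence[Tuple[float, float]], bin_width: float
) -> List[Tuple[float, float]]:
    """Merge species into clusters: a new cluster starts when the gap to
    the previous species exceeds ``bin_width``; cluster m/z is the
    abundance-weighted centroid."""
    ordered = sorted(species)
    clusters: List[Tuple[float, float]] = []
    cur_mass = 0.0
    cur_prob = 0.0
    prev = None
    for mass, prob in ordered:
        if prev is not None and mass - prev > bin_width:
            clusters.append((cur_mass / cur_prob, cur_prob))
            cur_mass, cur_prob = 0.0, 0.0
        cur_mass += mass * prob
        cur_prob += prob
        prev = mass
    if cur_prob > 0:
        clusters.append((cur_mass / cur_prob, cur_prob))
    return clusters


def isotopologue_pattern(
    ion: IonSpec | ElementalFormula,
    prune: float = 0.01,
    bin_width: float = 0.01,
) -> IsotopePattern:
    """Simulate the centroided isotopologue pattern of a singly protonated
    ion.

    Parameters
    ----------
    ion:
        The ion (a bare formula is treated as the neutral of an [M+H]+
        ion).
    prune:
        Relative-abundance floor in % of the base peak; clusters below it
        are dropped.  Pass 0 to keep the exhaustive distribution (useful
        for conservation checks).
    bin_width:
        Aggregation bin in Da.  The default 0.01 Da merges the near-isobaric
        37Cl and 81Br species of each nominal A+2n cluster into a single
        abundance-weighted centroid, matching unit-resolved A/A+1/A+2/A+4
        reporting.
    """
    if isinstance(ion, ElementalFormula):
        ion = IonSpec(ion)
    floor = 0.0 if prune <= 0 else 1e-12
    species = _species_distribution(ion.ion_formula, floor)
    clusters = _bin_species(species, bin_width)
    base = max(p for _, p in clusters)
    out = []
    for mass, prob in clusters:
        rel = prob / base * 100.0
        if prune <= 0 or rel > prune:
            out.append((mass - ELECTRON_MASS, rel))
    return IsotopePattern(tuple(sorted(out)), bin_width)


def total_species_probability(f: ElementalFormula) -> float:
    """Sum of the un-normalized isotopologue probabilities of a formula
    (should equal 1 exactly: the product of per-element distribution
    totals).  Exposed for conservation checks."""
    return sum(p for _, p in _species_distribution(f, 0.0))
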