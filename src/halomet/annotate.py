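"""MS2 fragment matching, identification confidence, phase classification.

Structure support is encoded as transparent, data-driven rules rather
than in-silico bond breaking: a suspect is supported by *characteristic
ions* (diagnostic fragment m/z values compiled per compound) and by
*neutral losses* (precursor minus an exact neutral mass, e.g. the
162.0528 Da anhydroglucose loss that betrays a glycoside).  Confidence
levels follow the Schymanski scale (1, 2a, 2b, 3, 4, 5); the phase of a
transformation product (phase-I functionalization, phase-II conjugation,
or bridge-cleavage breakdown) is read off a curated pathway graph.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import chem
from .chem import ElementalFormula
from .screen import Feature, SuspectEntry

__all__ = [
    "FragmentRule",
    "FragmentMatch",
    "MetaboliteHit",
    "CONFIDENCE_LEVELS",
    "PHASES",
    "load_neutral_losses",
    "match_fragments",
    "assign_confidence",
    "classify_phase",
    "load_pathway_edges",
]

CONFIDENCE_LEVELS = ("1", "2a", "2b", "3", "4", "5")
PHASES = ("parent", "phase_I", "phase_II", "breakdown", "unclassified")

#: pathway edge kinds; conjugations terminate phase-II products, bridge
#: cleavage marks breakdown products, everything else is functionalization.
CONJUGATION_KINDS = frozenset({"glycosylation", "amino_acid_conjugation"})
BREAKDOWN_KINDS = frozenset({"bridge_cleavage"})
FUNCTIONALIZATION_KINDS = frozenset(
    {
        "ring_closure",
        "demethylation",
        "dealkylation",
        "hydroxylation",
        "oxidation",
        "dechlorination",
        "debromination",
    }
)


@dataclass(frozen=True)
class FragmentRule:
    """Either a characteristic product ion (m/z) or a neutral loss (Da)."""

    kind: str  # "characteristic_ion" | "neutral_loss"
    mz_or_mass: float
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ("characteristic_ion", "neutral_loss"):
            raise ValueError(f"unknown fragment rule kind {self.kind!r}")
        if self.mz_or_mass <= 0:
            raise ValueError("fragment rule mass must be positive")
        if not self.label:
            raise ValueError("fragment rule needs a label")


@dataclass(frozen=True)
class FragmentMatch:
    rule: FragmentRule
    observed_mz: float
    expected_mz: float

    @property
    def error_da(self) -> float:
        return self.observed_mz - self.expected_mz


@dataclass
class MetaboliteHit:
    """A suspect assignment carrying its evidence."""

    suspect: SuspectEntry
    feature: Feature
    ppm: float
    matched_fragments: List[FragmentMatch]
    confidence: Optional[str] = None
    phase: Optional[str] = None

    def __post_init__(self) -> None:
        if self.confidence is not None and self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"unknown confidence level {self.confidence!r}")
        if self.phase is not None and self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


def load_neutral_losses() -> List[FragmentRule]:
    """Packaged neutral-loss rules; masses computed from their formulas so
    the rule table stays consistent with the isotope constants."""
    rules: List[FragmentRule] = []
    with resources.files("halomet.data").joinpath("neutral_losses.csv").open() as fh:
        for row in csv.DictReader(fh):
            f = chem.parse_formula(row["formula"])
            rules.append(
                FragmentRule(
                    kind="neutral_loss",
                    mz_or_mass=chem.monoisotopic_mass(f),
                    label=f"{row['label']} -{chem.monoisotopic_mass(f):.4f}",
                )
            )
    return rules


def match_fragments(
    spectrum: Sequence[Tuple[float, float]],
    precursor_mz: float,
    rules: Sequence[FragmentRule],
    mz_tol_ppm: float = 10.0,
    precursor_tol_ppm: float = 25.0,
    candidate_mz: Optional[float] = None,
) -> Tuple[List[FragmentMatch], List[Tuple[float, float]]]:
    """Match an MS2 spectrum against fragment rules.

    ``spectrum`` is a centroided (m/z, intensity) peak list.  A peak
    matches a characteristic-ion rule directly, or a neutral-loss rule
    when it sits at precursor minus the loss mass, within ``mz_tol_ppm``.
    Returns (matches, unmatched peaks).  An empty spectrum yields no
    matches (not an error).  When ``candidate_mz`` is given, the
    precursor must agree with it within ``precursor_tol_ppm`` (the
    inclusion-list tolerance).
    """
    if candidate_mz is not None and abs(
        chem.ppm_error(precursor_mz, candidate_mz)
    ) > precursor_tol_ppm:
        raise ValueError(
            f"precursor {precursor_mz} outside {precursor_tol_ppm} ppm of "
            f"candidate {candidate_mz}"
        )
    matches: List[FragmentMatch] = []
    matched_peaks = set()
    for rule in rules:
        expected = (
            rule.mz_or_mass
            if rule.kind == "characteristic_ion"
            else precursor_mz - rule.mz_or_mass
        )
        if expected <= 0:
            continue
        tol = mz_tol_ppm * 1e-6 * expected
        best = None
        for i, (mz, _inten) in enumerate(spectrum):
            if abs(mz - expected) <= tol and (
                best is None or abs(mz - expected) < abs(spectrum[best][0] - expected)
            ):
                best = i
        if best is not None:
            matched_peaks.add(best)
            matches.append(
                FragmentMatch(rule=rule, observed_mz=spectrum[best][0], expected_mz=expected)
            )
    unmatched = [p for i, p in enumerate(spectrum) if i not in matched_peaks]
    return matches, unmatched


def assign_confidence(
    has_matched_fragments: bool,
    has_reference_standard: bool = False,
    previously_reported: bool = False,
) -> str:
    """Schymanski-style confidence level.

    * 1  — reference standard available and MS2 + RT confirmed;
    * 2b — diagnostic fragments observed and the compound was previously
            reported (registration documents / literature);
    * 3  — diagnostic fragments observed, but alternative structures
            (e.g. conjugation positions) remain possible;
    * 5  — exact mass of interest only (no adequate MS2 fragments).

    Levels 2a and 4 exist in the scale but are not produced by this rule
    set (no spectral-library matching, no structure-less formula claims).
    """
    if has_matched_fragments and has_reference_standard:
        return "1"
    if has_matched_fragments and previously_reported:
        return "2b"
    if has_matched_fragments:
        return "3"
    return "5"


def load_pathway_edges() -> List[Tuple[str, str, str]]:
    """Packaged transformation-pathway graph as (parent, child, kind)."""
    edges: List[Tuple[str, str, str]] = []
    known = CONJUGATION_KINDS | BREAKDOWN_KINDS | FUNCTIONALIZATION_KINDS
    with resources.files("halomet.data").joinpath("pathway_edges.csv").open() as fh:
        for row in csv.DictReader(fh):
            kind = row["kind"]
            if kind not in known:
                raise ValueError(f"unknown pathway edge kind {kind!r}")
            edges.append((row["parent"], row["child"], kind))
    return edges


def classify_phase(
    compound: str,
    edges: Sequence[Tuple[str, str, str]],
    root: str = "Cyantraniliprole",
) -> str:
    """Classify a compound by walking the pathway graph back to the root.

    Rules, applied to the path from root to compound:

    * the root itself is ``parent``;
    * a conjugation on the terminal edge makes a ``phase_II`` product
      (the conjugate is the stored, detoxified end point);
    * any bridge-cleavage edge on the path makes a ``breakdown`` product;
    * otherwise the compound is a ``phase_I`` functionalization product;
    * compounds not reachable from the root are ``unclassified``.
    """
    if compound == root:
        return "parent"
    by_child: Dict[str, Tuple[str, str]] = {}
    for parent, child, kind in edges:
        if child in by_child:
            raise ValueError(f"compound {child!r} has multiple precursors")
        by_child[child] = (parent, kind)
    if compound not in by_child:
        return "unclassified"
    path_kinds: List[str] = []
    node = compound
    seen = set()
    while node != root:
        if node in seen:
            raise ValueError("cycle in pathway graph")
        seen.add(node)
        if node not in by_child:
            return "unclassified"
        node, kind = by_child[node]
        path_kinds.append(kind)
    terminal = path_kinds[0]  # edge that produced the compound
    if terminal in CONJUGATION_KINDS:
        return "phase_II"
    if any(k in BREAKDOWN_KINDS for k in path_kinds):
        return "breakdown"
    return "phase_I"
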