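"""Candidate-formula enumeration and isotope-pattern scoring.

Given an observed [M+H]+ m/z, every elemental formula inside the element
bounds whose protonated mass falls within the ppm tolerance is generated,
then filtered by the nitrogen rule, an RDBE plausibility window and
(optionally) the requirement that at least one Cl or Br atom is retained
from the halogenated parent.  The search is an exact residual-mass
recursive descent over elements in decreasing mass order — no stochastic
shortcuts, so results are reproducible and complete within bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import chem
from .chem import ElementalFormula, IsotopePattern

__all__ = [
    "ElementBounds",
    "CandidateFormula",
    "enumerate_formulas",
    "score_isotope_fit",
    "candidates_to_frame",
]

#: default per-element (min, max) counts; wide enough to cover every
#: plausible transformation product of a mid-size halogenated pesticide.
DEFAULT_BOUNDS: Dict[str, Tuple[int, int]] = {
    "C": (0, 40),
    "H": (0, 60),
    "N": (0, 10),
    "O": (0, 12),
    "S": (0, 2),
    "Cl": (0, 2),
    "Br": (0, 2),
}


@dataclass(frozen=True)
class ElementBounds:
    bounds: Tuple[Tuple[str, Tuple[int, int]], ...] = tuple(
        sorted(DEFAULT_BOUNDS.items())
    )

    def __post_init__(self) -> None:
        for el, (lo, hi) in self.bounds:
            if el not in chem.ISOTOPES:
                raise ValueError(f"unsupported element {el!r}")
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid bounds for {el!r}: ({lo}, {hi})")

    @classmethod
    def from_dict(cls, d: Mapping[str, Tuple[int, int]]) -> "ElementBounds":
        return cls(tuple(sorted((el, (int(lo), int(hi))) for el, (lo, hi) in d.items())))

    def as_dict(self) -> Dict[str, Tuple[int, int]]:
        return dict(self.bounds)


@dataclass(frozen=True)
class CandidateFormula:
    formula: ElementalFormula
    calcd_mz: float
    ppm: float
    rdbe: float
    isotope_score: float
    rank: int


def _candidate_sort_key(c: CandidateFormula) -> tuple:
    heteroatoms = sum(n for el, n in c.formula.counts if el not in ("C", "H"))
    return (abs(c.ppm), -c.isotope_score, heteroatoms, c.formula.hill())


def enumerate_formulas(
    mz: float,
    tol_ppm: float = 5.0,
    bounds: Optional[ElementBounds] = None,
    require_halogen: bool = True,
    observed_pattern: Optional[IsotopePattern] = None,
    rdbe_range: Tuple[float, float] = (0.0, 40.0),
) -> List[CandidateFormula]:
    """Enumerate all neutral formulas whose [M+H]+ m/z lies within
    ``tol_ppm`` of ``mz``.

    Candidates must pass the nitrogen rule (applied to the neutral
    molecule), have an integral RDBE inside ``rdbe_range`` (even-electron
    neutral molecules), and — when ``require_halogen`` — contain at least
    one Cl or Br.  When an observed isotope pattern is supplied, each
    candidate's simulated pattern is scored against it and the score
    participates in ranking.  An empty list is a valid outcome.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if bounds is None:
        bounds = ElementBounds()
    bdict = bounds.as_dict()
    target = mz - chem.PROTON_MASS  # neutral monoisotopic mass
    window = mz * tol_ppm * 1e-6
    lo_mass, hi_mass = target - window, target + window
    if hi_mass <= 0:
        return []

    # elements ordered by decreasing mass, H last (solved near-directly)
    order = sorted(
        (el for el in bdict if el != "H"),
        key=lambda el: -chem.MONO_MASS[el],
    )
    h_lo, h_hi = bdict.get("H", (0, 0))
    h_mass = chem.MONO_MASS["H"]

    found: List[Dict[str, int]] = []
    counts: Dict[str, int] = {}

    def descend(idx: int) -> None:
        if idx == len(order):
            # hydrogen count solved from the residual mass
            heavy = sum(chem.MONO_MASS[el] * n for el, n in counts.items())
            n_min = max(h_lo, int((lo_mass - heavy) / h_mass) - 1)
            n_max = min(h_hi, int((hi_mass - heavy) / h_mass) + 1)
            for n in range(max(n_min, 0), n_max + 1):
                total = heavy + n * h_mass
                if lo_mass <= total <= hi_mass:
                    cand = dict(counts)
                    if n:
                        cand["H"] = n
                    if sum(cand.values()) > 0:
                        found.append(cand)
            return
        el = order[idx]
        el_mass = chem.MONO_MASS[el]
        lo_n, hi_n = bdict[el]
        heavy = sum(chem.MONO_MASS[e] * n for e, n in counts.items())
        # prune: even with zero of everything lighter we must not overshoot
        hi_n = min(hi_n, int((hi_mass - heavy) / el_mass))
        for n in range(lo_n, hi_n + 1):
            counts[el] = n
            # prune: remaining elements plus H at max cannot reach lo_mass?
            remaining_max = sum(
                bdict[e][1] * chem.MONO_MASS[e] for e in order[idx + 1 :]
            ) + h_hi * h_mass
            if heavy + n * el_mass + remaining_max >= lo_mass:
                descend(idx + 1)
            del counts[el]

    descend(0)

    cands: List[CandidateFormula] = []
    for d in found:
        try:
            f = ElementalFormula.from_counts(d)
        except ValueError:
            continue
        if require_halogen and f["Cl"] + f["Br"] < 1:
            continue
        if not chem.nitrogen_rule_ok(f):
            continue
        r = chem.rdbe(f)
        if r != int(r) or not (rdbe_range[0] <= r <= rdbe_range[1]):
            continue
        calcd = chem.cation_mz(f)
        score = 0.0
        if observed_pattern is not None:
            score = score_isotope_fit(observed_pattern, chem.isotopologue_pattern(f))
        cands.append(
            CandidateFormula(
                formula=f,
                calcd_mz=calcd,
                ppm=chem.ppm_error(mz, calcd),
                rdbe=r,
                isotope_score=score,
                rank=0,
            )
        )
    cands.sort(key=_candidate_sort_key)
    return [replace(c, rank=i + 1) for i, c in enumerate(cands)]


def score_isotope_fit(
    observed: IsotopePattern,
    theoretical: IsotopePattern,
    mz_tol: float = 0.01,
    ab_tol: float = 0.25,
) -> float:
    """Score in [0, 1] for how well an observed isotopologue pattern
    matches a simulated one.

    Both patterns are renormalized to base 100, so the score is invariant
    under rescaling.  Theoretical clusters at >= 25% of base ("major" —
    for halogenated ions these are the A/A+2/A+4 envelope) are mandatory:
    a missing major cluster collapses the score quadratically, dropping a
    one-Cl/one-Br candidate below 0.5 when its A+2 companion is absent.
    Minor clusters (5–25%) missing from the observed pattern cost at most
    half their abundance share, so a spectrum reporting only the
    A/A+2/A+4 reference ions still scores above 0.9.  Matched clusters
    contribute an abundance-agreement term that decays linearly with the
    relative abundance deviation on a scale set by ``ab_tol``.
    """
    if not observed.clusters or not theoretical.clusters:
        raise ValueError("patterns must be non-empty")
    obs_base = max(ab for _, ab in observed.clusters)
    the_base = max(ab for _, ab in theoretical.clusters)
    obs = [(mz, ab / obs_base * 100.0) for mz, ab in observed.clusters]
    theo = [(mz, ab / the_base * 100.0) for mz, ab in theoretical.clusters]

    considered = [(mz, ab) for mz, ab in theo if ab >= 5.0]
    if not considered:
        considered = [max(theo, key=lambda c: c[1])]
    major = [(mz, ab) for mz, ab in considered if ab >= 25.0]
    minor = [(mz, ab) for mz, ab in considered if ab < 25.0]

    def nearest(mz: float) -> Optional[float]:
        best = None
        best_d = mz_tol
        for omz, oab in obs:
            d = abs(omz - mz)
            if d <= best_d:
                best, best_d = oab, d
        return best

    def agreement(theo_ab: float, obs_ab: float) -> float:
        dev = abs(obs_ab - theo_ab) / theo_ab
        return max(0.0, 1.0 - dev / (4.0 * ab_tol))

    w_major = sum(ab for _, ab in major)
    matched_major_w = 0.0
    score_major = 0.0
    for mz, ab in major:
        oab = nearest(mz)
        if oab is not None:
            matched_major_w += ab
            score_major += ab * agreement(ab, oab)
    if w_major == 0:
        base_score = 1.0
        cov_major = 1.0
    else:
        base_score = score_major / w_major
        cov_major = matched_major_w / w_major

    w_all = sum(ab for _, ab in considered)
    missing_minor_w = sum(ab for mz, ab in minor if nearest(mz) is None)
    minor_penalty = 1.0 - 0.5 * (missing_minor_w / w_all if w_all else 0.0)

    return base_score * cov_major * minor_penalty


def candidates_to_frame(candidates: Sequence[CandidateFormula]):
    """Candidate set as a table with columns (rank, formula, calcd_mz,
    ppm, rdbe, isotope_score), the interchange format for exports."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rank": [c.rank for c in candidates],
            "formula": [c.formula.hill() for c in candidates],
            "calcd_mz": [c.calcd_mz for c in candidates],
            "ppm": [c.ppm for c in candidates],
            "rdbe": [c.rdbe for c in candidates],
            "isotope_score": [c.isotope_score for c in candidates],
        }
    )
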