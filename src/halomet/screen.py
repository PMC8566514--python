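"""Feature-level suspect-screening workflow.

The screening cascade mirrors a pesticide transformation-product study:

1. features present in non-treated (control) samples are eliminated,
2. an intensity / signal-to-noise cutoff removes weak signals,
3. a Cl/Br isotope filter keeps only halogen-bearing candidates,
4. survivors are matched against a compiled suspect list by accurate
   m/z (and retention time where known), and
5. a targeted mass inclusion list is produced for data-dependent MS2.

Every stage returns a subset of its input and appends to an audit log
instead of silently discarding features, so each elimination can be
reviewed.
"""

from __future__ import annotations

import bisect
import math
import statistics
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import chem
from .chem import ElementalFormula, IsotopePattern

__all__ = [
    "TISSUES",
    "GROUPS",
    "ALLOWED_DAT",
    "SampleMeta",
    "Feature",
    "SuspectEntry",
    "AuditLog",
    "subtract_control",
    "apply_thresholds",
    "halogen_filter",
    "match_suspects",
    "build_inclusion_list",
    "detect_features",
]

GROUPS = ("control", "treated")
TISSUES = ("xylem_sap", "young_leaves", "mature_leaves", "flowers", "fruits")
#: sampling grid: 7- to 14-day intervals across the crop cycle
ALLOWED_DAT = (7, 14, 21, 28, 35, 42, 49, 56, 63, 70, 77, 84)

#: A+2 isotope spacing in Da: 37Cl-35Cl is 1.99705, 81Br-79Br is 1.99795;
#: their blend sits near 1.997.
HALOGEN_SPACING = 1.997

#: expected A+2/A abundance ratio contributed per halogen atom
_CL_RATIO = 0.2424 / 0.7576
_BR_RATIO = 0.4931 / 0.5069


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str
    tissue: str
    dat: int
    replicate: int
    concentration_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.dat not in ALLOWED_DAT:
            raise ValueError(f"DAT {self.dat} outside the sampling design")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.concentration_factor <= 0:
            raise ValueError("concentration factor must be positive")


@dataclass(frozen=True)
class Feature:
    """One aligned MS1 chromatographic feature."""

    mz: float
    rt: float
    area: float
    snr: float
    isotope_cluster: Optional[IsotopePattern] = None
    sample: Optional[SampleMeta] = None
    label: Optional[str] = None  # simulator ground-truth tag, if any

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.rt < 0 or self.area < 0 or self.snr < 0:
            raise ValueError("rt, area and snr must be non-negative")


@dataclass(frozen=True)
class SuspectEntry:
    """A literature/registration-document transformation product to
    search for."""

    name: str
    formula: ElementalFormula
    expected_mz: float
    expected_rt: Optional[float] = None
    source: str = "literature"

    def __post_init__(self) -> None:
        if self.source not in ("registration_document", "literature", "new_TP"):
            raise ValueError(f"unknown suspect source {self.source!r}")
        theo = chem.cation_mz(self.formula)
        if abs(chem.ppm_error(self.expected_mz, theo)) > 5.0:
            raise ValueError(
                f"suspect {self.name}: expected m/z {self.expected_mz} is "
                f"inconsistent with formula {self.formula.hill()} ({theo:.4f})"
            )


class AuditLog:
    """Collects (stage, reason, feature) records for eliminated features."""

    def __init__(self) -> None:
        self.records: List[Tuple[str, str, Feature]] = []

    def note(self, stage: str, reason: str, feature: Feature) -> None:
        self.records.append((stage, reason, feature))

    def by_stage(self, stage: str) -> List[Feature]:
        return [f for s, _, f in self.records if s == stage]


def _mz_match(mz_a: float, mz_b: float, tol_ppm: float) -> bool:
    return abs(mz_a - mz_b) <= tol_ppm * 1e-6 * max(mz_a, mz_b)


def subtract_control(
    treated: Sequence[Feature],
    control: Sequence[Feature],
    mz_tol_ppm: float = 5.0,
    rt_tol: float = 0.1,
    audit: Optional[AuditLog] = None,
) -> List[Feature]:
    """Eliminate treated-sample features that are present in any control
    sample within both tolerances ("any control replicate" semantics).

    Eliminated features are flagged in the audit log, never silently
    dropped.  Output order follows the (sorted) input so the result is
    invariant under permutations of either feature list.
    """
    control_sorted = sorted(control, key=lambda f: f.mz)
    ctrl_mz = [f.mz for f in control_sorted]
    out: List[Feature] = []
    for feat in sorted(treated, key=lambda f: (f.mz, f.rt, f.area)):
        matched = False
        # scan the m/z-sorted control list around the candidate
        lo = bisect.bisect_left(ctrl_mz, feat.mz * (1 - mz_tol_ppm * 1e-6) - 1e-9)
        for cf in control_sorted[lo:]:
            if cf.mz > feat.mz * (1 + mz_tol_ppm * 1e-6) + 1e-9:
                break
            if _mz_match(feat.mz, cf.mz, mz_tol_ppm) and abs(feat.rt - cf.rt) <= rt_tol:
                matched = True
                break
        if matched:
            if audit is not None:
                audit.note("control_subtraction", "matched control feature", feat)
        else:
            out.append(feat)
    return out


def apply_thresholds(
    features: Sequence[Feature],
    min_area: float = 1e4,
    min_snr: float = 10.0,
    audit: Optional[AuditLog] = None,
) -> List[Feature]:
    """Keep features with area >= ``min_area`` and S/N strictly greater
    than ``min_snr`` (the cutoff is an intensity floor of ~1e4 with
    S/N > 10)."""
    if min_area <= 0 or min_snr <= 0:
        raise ValueError("thresholds must be positive")
    out: List[Feature] = []
    for f in sorted(features, key=lambda f: (f.mz, f.rt, f.area)):
        if f.area >= min_area and f.snr > min_snr:
            out.append(f)
        elif audit is not None:
            audit.note("thresholds", f"area={f.area:.3g} snr={f.snr:.3g}", f)
    return out


def _halogen_consistent(ratio: float, ratio_tol: float) -> bool:
    """Is an A+2/A abundance ratio consistent with >= 1 Cl and/or Br?"""
    for n_cl in range(0, 3):
        for n_br in range(0, 3):
            if n_cl + n_br == 0:
                continue
            expected = n_cl * _CL_RATIO + n_br * _BR_RATIO
            if abs(ratio - expected) <= ratio_tol * expected:
                return True
    return False


def halogen_filter(
    features: Sequence[Feature],
    mz_tol: float = 0.005,
    ratio_tol: float = 0.25,
    audit: Optional[AuditLog] = None,
) -> List[Feature]:
    """Cl/Br isotope filter.

    A feature passes when its isotope cluster contains an A+2 companion at
    +1.997 +/- ``mz_tol`` Da from the lightest cluster with an abundance
    ratio consistent (within ``ratio_tol``, relative) with at least one
    chlorine and/or bromine.  The default 0.005 Da spacing tolerance
    accepts both the 37Cl (+1.99705) and 81Br (+1.99795) companions while
    rejecting the +2.00671 double-13C companion of halogen-free organics.
    Features without clusters are dropped with an audit note.
    """
    out: List[Feature] = []
    for f in sorted(features, key=lambda f: (f.mz, f.rt, f.area)):
        cluster = f.isotope_cluster
        if cluster is None or not cluster.clusters:
            if audit is not None:
                audit.note("halogen_filter", "no isotope cluster", f)
            continue
        # the monoisotopic (A) peak is the lightest cluster
        a_mz, a_ab = cluster.clusters[0]
        companion = None
        for mz, ab in cluster.clusters[1:]:
            if abs(mz - (a_mz + HALOGEN_SPACING)) <= mz_tol:
                companion = (mz, ab)
                break
        if companion is None:
            if audit is not None:
                audit.note("halogen_filter", "no A+2 companion", f)
            continue
        ratio = companion[1] / a_ab if a_ab > 0 else math.inf
        if _halogen_consistent(ratio, ratio_tol):
            out.append(f)
        elif audit is not None:
            audit.note("halogen_filter", f"A+2/A={ratio:.3f} inconsistent", f)
    return out


def match_suspects(
    features: Sequence[Feature],
    suspects: Sequence[SuspectEntry],
    mz_tol_ppm: float = 5.0,
    rt_tol: float = 0.1,
) -> List[Tuple[Feature, SuspectEntry]]:
    """Match features to suspects by accurate m/z, and by retention time
    (+/- ``rt_tol`` min) whenever the suspect has a known RT.

    One feature may match several isobaric suspects only when their RTs
    disambiguate; suspects without an expected RT match on m/z alone.
    """
    pairs: List[Tuple[Feature, SuspectEntry]] = []
    for f in sorted(features, key=lambda f: (f.mz, f.rt, f.area)):
        for s in suspects:
            if not _mz_match(f.mz, s.expected_mz, mz_tol_ppm):
                continue
            if s.expected_rt is not None and abs(f.rt - s.expected_rt) > rt_tol:
                continue
            pairs.append((f, s))
    return pairs


def build_inclusion_list(
    candidate_mzs: Iterable[float], mass_tol_ppm: float = 25.0
) -> List[Tuple[float, float]]:
    """Deduplicated targeted-MS2 inclusion list.

    Candidate m/z values closer than ``mass_tol_ppm`` are merged (mean of
    the merged group); entries are (m/z, tol_ppm) sorted ascending.
    """
    mzs = sorted(m for m in candidate_mzs)
    if any(m <= 0 for m in mzs):
        raise ValueError("candidate m/z values must be positive")
    entries: List[Tuple[float, float]] = []
    group: List[float] = []
    for m in mzs:
        if group and not _mz_match(group[-1], m, mass_tol_ppm):
            entries.append((sum(group) / len(group), mass_tol_ppm))
            group = []
        group.append(m)
    if group:
        entries.append((sum(group) / len(group), mass_tol_ppm))
    return entries


def detect_features(
    frames: Sequence[Tuple[float, Sequence[Tuple[float, float]]]],
    mz_tol_ppm: float = 5.0,
    snr_window: float = 0.5,
) -> List[Feature]:
    """Minimal deterministic feature detection from centroided MS1 frames.

    ``frames`` is a sequence of (rt, peaks) with peaks as (m/z, intensity).
    Peaks are grouped across adjacent frames when within ``mz_tol_ppm``;
    the apex intensity of a group is the feature area and its frame's RT
    the feature RT.  S/N is the apex intensity divided by the median
    intensity of non-member peaks within +/- ``snr_window`` Da of the apex
    (1.0 noise floor when the window is empty).
    """
    all_peaks: List[Tuple[float, float, float]] = []  # (mz, rt, intensity)
    for rt, peaks in frames:
        for mz, inten in peaks:
            all_peaks.append((mz, rt, inten))
    all_peaks.sort()
    groups: List[List[Tuple[float, float, float]]] = []
    for p in all_peaks:
        if groups and _mz_match(groups[-1][-1][0], p[0], mz_tol_ppm):
            groups[-1].append(p)
        else:
            groups.append([p])
    features: List[Feature] = []
    for g in groups:
        apex = max(g, key=lambda p: p[2])
        member = set(id(p) for p in g)
        noise = [
            p[2]
            for p in all_peaks
            if id(p) not in member and abs(p[0] - apex[0]) <= snr_window
        ]
        floor = statistics.median(noise) if noise else 1.0
        features.append(
            Feature(mz=apex[0], rt=apex[1], area=apex[2], snr=apex[2] / max(floor, 1e-12))
        )
    return features
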