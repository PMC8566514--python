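"""Readers/writers and the packaged reference catalog.

The catalog (``data/suspect_catalog.csv``) transcribes the mass-spectral
reference table for cyantraniliprole and its 21 transformation products
in tomato: Hill formulas, retention times, calculated and observed
[M+H]+ m/z, printed ppm errors, diagnostic fragment ions, tissue
occurrence flags and identification-confidence levels, plus curated
phase annotations and provenance flags (previously reported vs newly
identified TP, reference standard available).  It is validated on every
load: element counts, mass consistency, nitrogen rule, phase partition.

Peak lists travel as MGF (MS2 spectra, via pyteomics) and as plain CSV
frames (MS1), both with lossless numeric round-trips at the reported
precision.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from pyteomics import mgf as _mgf

from . import chem
from .chem import ElementalFormula
from .screen import Feature, IsotopePattern, SampleMeta, SuspectEntry

__all__ = [
    "FixtureError",
    "CatalogRecord",
    "load_catalog",
    "suspects_from_catalog",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_mgf",
    "write_mgf",
    "features_to_frame",
    "frame_to_features",
]


class FixtureError(ValueError):
    """Raised when the packaged catalog fails validation."""


@dataclass(frozen=True)
class CatalogRecord:
    name: str
    formula: ElementalFormula
    rt_min: float
    calcd_mz: float
    obsd_mz: float
    error_ppm: float
    fragment_ions: Tuple[float, ...]
    leaves: bool
    flowers: bool
    fruits: bool
    level: str
    phase: str
    previously_reported: bool
    has_standard: bool

    @property
    def is_parent(self) -> bool:
        return self.phase == "parent"


def _parse_bool(text: str) -> bool:
    return text.strip() in ("True", "true", "1", "+")


def _validate(records: Sequence[CatalogRecord]) -> None:
    if len(records) != 22:
        raise FixtureError(f"expected 22 catalog records, found {len(records)}")
    parents = [r for r in records if r.is_parent]
    if len(parents) != 1:
        raise FixtureError("catalog must contain exactly one parent compound")
    phases = {"phase_I": 0, "phase_II": 0, "breakdown": 0}
    for r in records:
        computed = chem.cation_mz(r.formula)
        # one unit in the fourth decimal tolerated: printed tables round
        # (and occasionally truncate) the full-precision value
        if abs(chem.round_half_away(computed, 4) - r.calcd_mz) > 1.00001e-4:
            raise FixtureError(
                f"{r.name}: printed calcd m/z {r.calcd_mz} inconsistent with "
                f"formula {r.formula.hill()} ({computed:.5f})"
            )
        if not chem.nitrogen_rule_ok(r.formula):
            raise FixtureError(f"{r.name}: formula violates the nitrogen rule")
        if r.level not in ("1", "2a", "2b", "3", "4", "5"):
            raise FixtureError(f"{r.name}: unknown confidence level {r.level!r}")
        if not r.is_parent:
            if r.phase not in phases:
                raise FixtureError(f"{r.name}: unknown phase {r.phase!r}")
            phases[r.phase] += 1
        if r.level == "5" and r.fragment_ions:
            raise FixtureError(f"{r.name}: level 5 entries cannot carry fragments")
    if (phases["phase_I"], phases["phase_II"], phases["breakdown"]) != (11, 6, 4):
        raise FixtureError(
            f"phase partition must be 11/6/4 (phase-I/phase-II/breakdown), "
            f"got {phases}"
        )


def load_catalog(path: Optional[Path] = None) -> List[CatalogRecord]:
    """Load and validate the packaged compound catalog (or a user copy)."""
    if path is None:
        text = resources.files("halomet.data").joinpath("suspect_catalog.csv").read_text()
    else:
        text = Path(path).read_text()
    records: List[CatalogRecord] = []
    for row in csv.DictReader(_io.StringIO(text)):
        frags = tuple(float(x) for x in row["fragment_ions"].split()) if row[
            "fragment_ions"
        ].strip() else ()
        records.append(
            CatalogRecord(
                name=row["name"],
                formula=chem.parse_formula(row["formula"]),
                rt_min=float(row["rt_min"]),
                calcd_mz=float(row["calcd_mz"]),
                obsd_mz=float(row["obsd_mz"]),
                error_ppm=float(row["error_ppm"]),
                fragment_ions=frags,
                leaves=_parse_bool(row["leaves"]),
                flowers=_parse_bool(row["flowers"]),
                fruits=_parse_bool(row["fruits"]),
                level=row["level"],
                phase=row["phase"],
                previously_reported=_parse_bool(row["previously_reported"]),
                has_standard=_parse_bool(row["has_standard"]),
            )
        )
    _validate(records)
    return records


def suspects_from_catalog(
    records: Optional[Sequence[CatalogRecord]] = None,
) -> List[SuspectEntry]:
    """Suspect-list view of the catalog (expected m/z = calculated m/z)."""
    if records is None:
        records = load_catalog()
    out = []
    for r in records:
        source = "registration_document" if r.previously_reported else "new_TP"
        if r.is_parent:
            source = "registration_document"
        out.append(
            SuspectEntry(
                name=r.name,
                formula=r.formula,
                expected_mz=r.calcd_mz,
                expected_rt=r.rt_min,
                source=source,
            )
        )
    return out


# ---------------------------------------------------------------------------
# peak lists


def read_peaklist_csv(path: Path) -> List[Tuple[float, List[Tuple[float, float]]]]:
    """Read MS1 frames from CSV with columns (frame, rt, mz, intensity).

    Malformed lines raise with their 1-based line number.
    """
    path = Path(path)
    frames: Dict[Tuple[int, float], List[Tuple[float, float]]] = {}
    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["frame", "rt", "mz", "intensity"]:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                frame, rt, mz, inten = int(row[0]), float(row[1]), float(row[2]), float(
                    row[3]
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {row!r}") from exc
            frames.setdefault((frame, rt), []).append((mz, inten))
    return [(rt, peaks) for (_, rt), peaks in sorted(frames.items())]


def write_peaklist_csv(
    path: Path, frames: Sequence[Tuple[float, Sequence[Tuple[float, float]]]]
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "rt", "mz", "intensity"])
        for i, (rt, peaks) in enumerate(frames):
            for mz, inten in peaks:
                writer.writerow([i, f"{rt:.6f}", f"{mz:.6f}", f"{inten:.6f}"])


def read_mgf(path: Path) -> List[dict]:
    """Read MS2 spectra from MGF; one dict per BEGIN/END IONS block with
    keys precursor_mz, rt, title, peaks."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            spectra.append(
                {
                    "title": params.get("title", ""),
                    "precursor_mz": float(params["pepmass"][0]),
                    "rt": float(params.get("rtinseconds", 0.0)) / 60.0,
                    "peaks": list(
                        zip(spec["m/z array"].tolist(), spec["intensity array"].tolist())
                    ),
                }
            )
    return spectra


def write_mgf(path: Path, spectra: Sequence[dict]) -> None:
    entries = []
    for spec in spectra:
        mzs = [p[0] for p in spec["peaks"]]
        intens = [p[1] for p in spec["peaks"]]
        entries.append(
            {
                "m/z array": mzs,
                "intensity array": intens,
                "params": {
                    "title": spec.get("title", ""),
                    "pepmass": spec["precursor_mz"],
                    "rtinseconds": spec.get("rt", 0.0) * 60.0,
                    "charge": "1+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# feature tables


def _cluster_to_text(pattern: Optional[IsotopePattern]) -> str:
    if pattern is None:
        return ""
    return ";".join(f"{mz:.6f}:{ab:.4f}" for mz, ab in pattern.clusters)


def _cluster_from_text(text: str) -> Optional[IsotopePattern]:
    if not text:
        return None
    clusters = []
    for part in text.split(";"):
        mz, ab = part.split(":")
        clusters.append((float(mz), float(ab)))
    return IsotopePattern(tuple(clusters))


def features_to_frame(features: Sequence[Feature]) -> pd.DataFrame:
    rows = []
    for f in features:
        s = f.sample
        rows.append(
            {
                "sample_id": s.sample_id if s else "",
                "group": s.group if s else "",
                "tissue": s.tissue if s else "",
                "dat": s.dat if s else -1,
                "replicate": s.replicate if s else -1,
                "concentration_factor": s.concentration_factor if s else 1.0,
                "mz": f.mz,
                "rt": f.rt,
                "area": f.area,
                "snr": f.snr,
                "isotope_cluster": _cluster_to_text(f.isotope_cluster),
                "label": f.label or "",
            }
        )
    return pd.DataFrame(rows)


def frame_to_features(frame: pd.DataFrame) -> List[Feature]:
    features = []
    for row in frame.itertuples(index=False):
        sample = None
        if row.sample_id:
            sample = SampleMeta(
                sample_id=row.sample_id,
                group=row.group,
                tissue=row.tissue,
                dat=int(row.dat),
                replicate=int(row.replicate),
                concentration_factor=float(row.concentration_factor),
            )
        features.append(
            Feature(
                mz=float(row.mz),
                rt=float(row.rt),
                area=float(row.area),
                snr=float(row.snr),
                isotope_cluster=_cluster_from_text(row.isotope_cluster),
                sample=sample,
                label=row.label or None,
            )
        )
    return features
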