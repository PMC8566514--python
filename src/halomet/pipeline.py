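"""End-to-end orchestration of the screening workflow.

Glues the stage functions together the way an analyst would run them on
a study: per (tissue, DAT) cell, pool the treated and control features,
subtract controls, apply intensity/SNR thresholds and the Cl/Br isotope
filter, then match survivors against the suspect list.  A companion
evaluator scores a simulated study against its ground truth (detection
rate, matrix false positives, quantification error, M/P recovery).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import quant, report, screen
from .screen import AuditLog, Feature, SuspectEntry
from .simulate import GroundTruth, Sample, StudyConfig

__all__ = ["ScreenResult", "screen_study", "evaluate_study"]


@dataclass
class ScreenResult:
    hits: List[Tuple[Feature, SuspectEntry]]
    audit: AuditLog

    def hits_frame(self) -> pd.DataFrame:
        rows = []
        for feat, sus in self.hits:
            s = feat.sample
            rows.append(
                {
                    "compound": sus.name,
                    "sample_id": s.sample_id if s else "",
                    "tissue": s.tissue if s else "",
                    "dat": s.dat if s else -1,
                    "replicate": s.replicate if s else -1,
                    "mz": feat.mz,
                    "rt": feat.rt,
                    "area": feat.area,
                    "snr": feat.snr,
                    "label": feat.label or "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "compound",
                "sample_id",
                "tissue",
                "dat",
                "replicate",
                "mz",
                "rt",
                "area",
                "snr",
                "label",
            ],
        )


def screen_study(
    samples: Sequence[Sample],
    suspects: Sequence[SuspectEntry],
    mz_tol_ppm: float = 5.0,
    rt_tol: float = 0.1,
    min_area: float = 1e4,
    min_snr: float = 10.0,
) -> ScreenResult:
    """Run the full screening cascade over a two-group study."""
    audit = AuditLog()
    cells: Dict[Tuple[str, int], Dict[str, List[Feature]]] = {}
    for s in samples:
        cell = cells.setdefault((s.meta.tissue, s.meta.dat), {"control": [], "treated": []})
        cell[s.meta.group].extend(s.features)
    hits: List[Tuple[Feature, SuspectEntry]] = []
    for key in sorted(cells):
        cell = cells[key]
        surviving = screen.subtract_control(
            cell["treated"], cell["control"], mz_tol_ppm=mz_tol_ppm, rt_tol=rt_tol, audit=audit
        )
        surviving = screen.apply_thresholds(
            surviving, min_area=min_area, min_snr=min_snr, audit=audit
        )
        surviving = screen.halogen_filter(surviving, audit=audit)
        hits.extend(screen.match_suspects(surviving, suspects, mz_tol_ppm=mz_tol_ppm, rt_tol=rt_tol))
    return ScreenResult(hits=hits, audit=audit)


def evaluate_study(
    samples: Sequence[Sample],
    truth: GroundTruth,
    config: StudyConfig,
    suspects: Sequence[SuspectEntry],
    mp_threshold: float = 0.01,
) -> Dict[str, float]:
    """Score the pipeline against the simulator's ground truth.

    Returns:

    * ``detection_rate``: fraction of (tissue, DAT, metabolite) cells with
      planted M/P >= ``mp_threshold`` recovered by the screen in at least
      one replicate;
    * ``matrix_false_positives``: suspect hits caused by planted matrix
      or noise features (should be 0);
    * ``parent_rel_rmse``: relative RMSE of recovery-corrected parent
      concentrations vs truth over all treated samples;
    * ``mp_within_3sd_rate``: fraction of detectable M/P cells whose
      measured mean ratio lies within 3 standard errors (propagated from
      the configured area noise) of the planted fraction.
    """
    result = screen_study(samples, suspects)
    hits_df = result.hits_frame()

    sample_by_id = {s.meta.sample_id: s for s in samples}

    # --- detection of planted metabolites ------------------------------
    planted_cells: Dict[Tuple[str, int, str], List[float]] = {}
    for (sid, name), frac in truth.planted_fractions.items():
        meta = sample_by_id[sid].meta
        planted_cells.setdefault((meta.tissue, meta.dat, name), []).append(frac)
    detectable = {
        cell for cell, fracs in planted_cells.items() if np.mean(fracs) >= mp_threshold
    }
    detected = set()
    if not hits_df.empty:
        genuine = hits_df[hits_df["compound"] == hits_df["label"]]
        for row in genuine.itertuples(index=False):
            detected.add((row.tissue, int(row.dat), row.compound))
    n_det = sum(1 for cell in detectable if cell in detected)
    detection_rate = n_det / len(detectable) if detectable else 1.0

    # --- matrix / noise false positives --------------------------------
    fp = 0
    if not hits_df.empty:
        fp = int(
            hits_df["label"].str.startswith("matrix").sum()
            + (hits_df["label"] == "noise").sum()
        )

    # --- parent quantification -----------------------------------------
    rel_sq = []
    for sid, true_conc in truth.true_parent_conc.items():
        s = sample_by_id[sid]
        corrected = quant.correct_concentration(s.parent_conc_raw, s.recovery_pct)
        rel_sq.append(((corrected - true_conc) / true_conc) ** 2)
    parent_rel_rmse = math.sqrt(float(np.mean(rel_sq))) if rel_sq else 0.0

    # --- M/P fraction recovery -----------------------------------------
    mp_ok = 0
    mp_total = 0
    if not hits_df.empty:
        genuine = hits_df[hits_df["compound"] == hits_df["label"]]
        # measured mean ratio per (tissue, dat, metabolite) from hit areas
        parent_areas = {
            (r.tissue, int(r.dat), int(r.replicate)): r.area
            for r in genuine[genuine["compound"] == truth.parent_name].itertuples(
                index=False
            )
        }
        ratio_rsd = math.sqrt(2.0) * config.area_rsd  # metabolite and parent noise
        for (tissue, dat, name), fracs in sorted(planted_cells.items()):
            if np.mean(fracs) < mp_threshold:
                continue
            rows = genuine[
                (genuine["compound"] == name)
                & (genuine["tissue"] == tissue)
                & (genuine["dat"] == dat)
            ]
            ratios = []
            for r in rows.itertuples(index=False):
                pa = parent_areas.get((tissue, dat, int(r.replicate)))
                if pa:
                    ratios.append(r.area / pa)
            if not ratios:
                continue
            mp_total += 1
            measured = float(np.mean(ratios))
            expected = float(np.mean(fracs))
            se = expected * ratio_rsd / math.sqrt(len(ratios))
            if abs(measured - expected) <= 3.0 * se:
                mp_ok += 1
    mp_within = mp_ok / mp_total if mp_total else 1.0

    return {
        "detection_rate": detection_rate,
        "matrix_false_positives": float(fp),
        "parent_rel_rmse": parent_rel_rmse,
        "mp_within_3sd_rate": mp_within,
        "n_detectable_cells": float(len(detectable)),
        "n_hits": float(len(result.hits)),
    }
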