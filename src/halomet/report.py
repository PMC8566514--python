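"""Study summaries: metabolite-to-parent kinetics, tissue occurrence,
replicate time-series statistics.

The central quantity is the M/P ratio: each metabolite's peak area
normalized to the parent compound's area in the same (tissue, sampling
interval, replicate) cell and expressed as a percentage.  Raw peak areas
are used by default — relative abundance, not recovery-corrected
concentration — with a switch for corrected values.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "validate_study_table",
    "mp_ratios",
    "occurrence_matrix",
    "summarize_timeseries",
]

STUDY_KEY = ["compound", "tissue", "dat", "replicate"]


def validate_study_table(table: pd.DataFrame, value_col: str = "area") -> pd.DataFrame:
    """Check the tidy long-table contract: unique (compound, tissue, dat,
    replicate) keys and non-negative values."""
    missing = [c for c in STUDY_KEY + [value_col] if c not in table.columns]
    if missing:
        raise ValueError(f"study table missing columns: {missing}")
    if table.duplicated(STUDY_KEY).any():
        raise ValueError("duplicate (compound, tissue, dat, replicate) keys")
    if (table[value_col] < 0).any():
        raise ValueError(f"negative values in {value_col!r}")
    return table


def mp_ratios(
    table: pd.DataFrame,
    parent: str = "Cyantraniliprole",
    value_col: str = "area",
    mode: str = "mean_of_ratios",
) -> pd.DataFrame:
    """Metabolite-to-parent ratio kinetics.

    Per replicate, metabolite value / parent value * 100 within the same
    (tissue, dat) cell; then mean +/- sample sd over replicates
    (``mean_of_ratios``).  ``ratio_of_means`` divides the replicate means
    instead.  Cells whose parent value is 0 are flagged undefined rather
    than reported as ratios.

    Returns columns (compound, tissue, dat, mp_ratio_pct, sd, n, flag).
    """
    validate_study_table(table, value_col)
    if mode not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown mode {mode!r}")
    parent_rows = table[table["compound"] == parent]
    if parent_rows.empty:
        raise ValueError(f"parent {parent!r} absent from study table")
    merged = table.merge(
        parent_rows[["tissue", "dat", "replicate", value_col]],
        on=["tissue", "dat", "replicate"],
        suffixes=("", "_parent"),
        how="left",
    )
    if merged[f"{value_col}_parent"].isna().any():
        raise ValueError("parent missing in some (tissue, dat, replicate) cells")
    rows = []
    for (compound, tissue, dat), grp in merged.groupby(
        ["compound", "tissue", "dat"], sort=True
    ):
        pv = grp[f"{value_col}_parent"].to_numpy(dtype=float)
        mv = grp[value_col].to_numpy(dtype=float)
        n = len(grp)
        if np.any(pv == 0):
            rows.append((compound, tissue, dat, np.nan, np.nan, n, "parent_zero"))
            continue
        if mode == "mean_of_ratios":
            ratios = mv / pv * 100.0
            mean = float(np.mean(ratios))
            sd = float(np.std(ratios, ddof=1)) if n > 1 else np.nan
        else:
            mean = float(np.mean(mv) / np.mean(pv) * 100.0)
            ratios = mv / pv * 100.0
            sd = float(np.std(ratios, ddof=1)) if n > 1 else np.nan
        rows.append((compound, tissue, dat, mean, sd, n, ""))
    return pd.DataFrame(
        rows, columns=["compound", "tissue", "dat", "mp_ratio_pct", "sd", "n", "flag"]
    )


def occurrence_matrix(
    hits: Iterable[Tuple[str, str]],
    compounds: Optional[Sequence[str]] = None,
    tissues: Sequence[str] = ("leaves", "flowers", "fruits"),
) -> pd.DataFrame:
    """Per-compound tissue presence matrix with '+' / '-' flags.

    ``hits`` is an iterable of (compound, tissue) detections; a compound
    is '+' in a tissue iff it has at least one confident hit there.  The
    optional ``compounds`` list fixes row order (and yields all '-' rows
    for undetected compounds).
    """
    seen = set()
    order: List[str] = list(compounds) if compounds is not None else []
    for compound, tissue in hits:
        if tissue not in tissues:
            raise ValueError(f"unknown tissue {tissue!r}")
        if compounds is None and compound not in order:
            order.append(compound)
        seen.add((compound, tissue))
    data = {
        t: ["+" if (c, t) in seen else "-" for c in order] for t in tissues
    }
    return pd.DataFrame(data, index=pd.Index(order, name="compound"))


def summarize_timeseries(
    table: pd.DataFrame,
    value_col: str = "area",
    keys: Sequence[str] = ("compound", "tissue", "dat"),
) -> pd.DataFrame:
    """Mean +/- sample sd per (compound, tissue, dat) cell.

    Single-replicate cells report their mean with an undefined (NaN) sd
    and a ``single_replicate`` flag; the result is invariant under
    replicate permutations.
    """
    validate_study_table(table, value_col)
    rows = []
    for key_vals, grp in table.groupby(list(keys), sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        n = len(vals)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
        flag = "" if n > 1 else "single_replicate"
        rows.append((*key_vals, mean, sd, n, flag))
    return pd.DataFrame(rows, columns=[*keys, "mean", "sd", "n", "flag"])
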