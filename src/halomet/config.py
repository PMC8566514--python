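"""Run configuration: every tolerance and threshold of the workflow in
one schema-validated block, serializable to YAML.

Defaults are the workflow's operating points: 5 ppm mass accuracy for
screening and suspect matching, a 25 ppm targeted-MS2 inclusion
tolerance, RT windows of 0.1 min, an intensity cutoff of 1e4 counts with
S/N > 10, and 10 ppm for MS2 fragment matching.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, Tuple

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    ppm_tol: float = 5.0
    inclusion_ppm: float = 25.0
    rt_tol_min: float = 0.1
    min_area: float = 1e4
    min_snr: float = 10.0
    fragment_ppm: float = 10.0
    halogen_mz_tol: float = 0.005
    halogen_ratio_tol: float = 0.25
    lod_alpha: float = 0.01
    seed: int = 0
    log_level: str = "INFO"
    element_bounds: Tuple[Tuple[str, Tuple[int, int]], ...] = (
        ("Br", (0, 2)),
        ("C", (0, 40)),
        ("Cl", (0, 2)),
        ("H", (0, 60)),
        ("N", (0, 10)),
        ("O", (0, 12)),
        ("S", (0, 2)),
    )

    def __post_init__(self) -> None:
        for name in (
            "ppm_tol",
            "inclusion_ppm",
            "rt_tol_min",
            "min_area",
            "min_snr",
            "fragment_ppm",
            "halogen_mz_tol",
            "halogen_ratio_tol",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.lod_alpha < 0.5:
            raise ValueError("lod_alpha must be in (0, 0.5)")

    def to_yaml(self, path: Path) -> None:
        data = asdict(self)
        data["element_bounds"] = {
            el: list(b) for el, b in self.element_bounds
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "element_bounds" in data:
            data["element_bounds"] = tuple(
                sorted((el, tuple(b)) for el, b in data["element_bounds"].items())
            )
        return cls(**data)
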