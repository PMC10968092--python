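"""Tissue codes and electrical conductivities.

The phantom uses an 8-tissue segmentation (air plus seven body tissues).
Conductivities are low-frequency (~1 Hz) literature-style values in S/m;
skin is fixed at 0.1 S/m. At ECG frequencies the quasi-static approximation
holds and a single static table suffices — no dispersion model is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AIR = 0
SKIN = 1
FAT = 2
MUSCLE = 3
BONE = 4
LUNG = 5
MYOCARDIUM = 6
BLOOD = 7

TISSUE_NAMES = {
    AIR: "air",
    SKIN: "skin",
    FAT: "fat",
    MUSCLE: "muscle",
    BONE: "bone",
    LUNG: "lung",
    MYOCARDIUM: "myocardium",
    BLOOD: "blood",
}

#: Low-frequency conductivities in S/m.
DEFAULT_SIGMA = {
    AIR: 0.0,
    SKIN: 0.1,
    FAT: 0.04,
    MUSCLE: 0.2,
    BONE: 0.02,
    LUNG: 0.1,
    MYOCARDIUM: 0.1,
    BLOOD: 0.7,
}

HEART_LABELS = (MYOCARDIUM, BLOOD)


@dataclass
class TissueTable:
    """Mapping tissue code -> (name, conductivity in S/m)."""

    names: dict[int, str] = field(default_factory=lambda: dict(TISSUE_NAMES))
    sigma: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))

    def __post_init__(self) -> None:
        for code, s in self.sigma.items():
            if code == AIR:
                if s != 0.0:
                    raise ValueError("air conductivity must be 0")
            elif s <= 0.0:
                raise ValueError(
                    f"body tissue {self.names.get(code, code)} must have sigma > 0"
                )

    def sigma_array(self, n_codes: int | None = None) -> np.ndarray:
        """Dense lookup table: sigma_array()[labels] vectorizes the mapping."""
        n = max(max(self.sigma) + 1, n_codes or 0)
        out = np.zeros(n, dtype=float)
        for code, s in self.sigma.items():
            out[code] = s
        return out

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "code": list(self.sigma),
                "name": [self.names[c] for c in self.sigma],
                "sigma_S_per_m": [self.sigma[c] for c in self.sigma],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TissueTable":
        df = pd.read_csv(path)
        names = dict(zip(df["code"].astype(int), df["name"].astype(str)))
        sigma = dict(zip(df["code"].astype(int), df["sigma_S_per_m"].astype(float)))
        return cls(names=names, sigma=sigma)


def default_tissue_table() -> TissueTable:
    return TissueTable()
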