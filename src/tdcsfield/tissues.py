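"""Tissue conductivity table for quasi-static volume-conductor models.

Conductivities are scalar and isotropic (S/m).  The default table is the
standard low-frequency set used in individualized tDCS dosimetry, including
the two electrode compartments: a saline-saturated sponge and a conductive
rubber pad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Default scalar conductivities, S/m.
DEFAULT_CONDUCTIVITIES: dict[str, float] = {
    "grey_matter": 0.2,
    "white_matter": 0.14,
    "blood": 0.7,
    "compact_bone": 0.008,
    "spongy_bone": 0.027,
    "csf": 1.8,
    "dura": 0.16,
    "muscle": 0.16,
    "skin": 0.08,
    "fat": 0.08,
    "eye": 1.5,
    "sponge": 1.6,
    "rubber": 0.1,
}


@dataclass(frozen=True)
class TissueTable:
    """Mapping from tissue name to scalar conductivity (S/m).

    All conductivities must be strictly positive; the exterior (air) is not a
    tissue -- it is excluded from the conductive domain entirely.
    """

    conductivities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES)
    )

    def __post_init__(self) -> None:
        for name, sigma in self.conductivities.items():
            if not sigma > 0:
                raise ValueError(f"conductivity of {name!r} must be > 0, got {sigma}")

    def __getitem__(self, tissue: str) -> float:
        return self.conductivities[tissue]

    def __contains__(self, tissue: str) -> bool:
        return tissue in self.conductivities

    def to_config(self) -> dict[str, float]:
        return dict(self.conductivities)

    @classmethod
    def from_config(cls, mapping: dict[str, float]) -> "TissueTable":
        return cls(conductivities={str(k): float(v) for k, v in mapping.items()})
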