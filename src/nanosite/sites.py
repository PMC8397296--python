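"""Site/complex kinds and identities shared by the detectors and the
synthetic generator, plus the default geometric thresholds.

A *bimetallic site* is two chelated Zn ions transiently within 0.50 nm.
*Binding complexes* are substrate phosphoryl oxygens (O4/O5) coordinating one
(monometallic) or two (bimetallic) Zn ions within 0.25 nm.  *Precatalytic
complexes* additionally require the hydroxyl oxygen O3 to coordinate a Zn:

- type 1 (monometallic): one single Zn holds O3, O4 and O5, no other Zn
  contacts any of them;
- type 2 (bimetallic): O4 and O5 bridge two different Zn, one of which also
  holds O3;
- type 3 (pseudo-bimetallic): one Zn holds O4 and/or O5 while a second Zn
  interacts only with O3.

Solvation is a Zn-bound water (d4 < 0.20 nm, strict); the nucleophile is
considered activation-ready when that water's oxygen lies within 0.25 nm of
O3 (d5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class SiteKind(Enum):
    ZN_PAIR = "ZN_PAIR"
    MONO_BINDING = "MONO_BINDING"
    BI_BINDING = "BI_BINDING"
    PRECAT_1 = "PRECAT_1"
    PRECAT_2 = "PRECAT_2"
    PRECAT_3 = "PRECAT_3"
    NONE = "NONE"


#: default geometric thresholds (nm)
ZN_ZN_CUTOFF = 0.50     # bimetallic site: Zn...Zn proximity
O_ZN_CUTOFF = 0.25      # substrate O...Zn coordination (d1, d2, d3)
ZN_WATER_CUTOFF = 0.20  # Zn-bound water, d4 (strict <)
WATER_O3_CUTOFF = 0.25  # nucleophile activation, d5


@dataclass(frozen=True)
class SiteIdentity:
    """Identity of a site/complex: kind + participating Zn (+ substrate)."""

    kind: SiteKind
    zn_ids: frozenset[int]
    substrate_id: int | None = None

    def __post_init__(self) -> None:
        if self.kind is SiteKind.ZN_PAIR:
            if len(self.zn_ids) != 2 or self.substrate_id is not None:
                raise ValueError("ZN_PAIR needs exactly 2 Zn and no substrate")
        elif self.kind is not SiteKind.NONE:
            if self.substrate_id is None:
                raise ValueError(f"{self.kind.value} needs a substrate id")
            if not 1 <= len(self.zn_ids) <= 2:
                raise ValueError(f"{self.kind.value} needs 1 or 2 Zn ids")


@dataclass(frozen=True)
class PrecatalyticGeometry:
    """The d1..d5 distances (nm) of one classified frame.

    d1: O4-Zn1; d2: O5-Zn2 (type 2) or O5-Zn1; d3: O3-Zn; d4: Zn-water O;
    d5: water O-O3.  Missing measurements are ``None``.
    """

    d1: float | None = None
    d2: float | None = None
    d3: float | None = None
    d4: float | None = None
    d5: float | None = None


@dataclass(frozen=True)
class Thresholds:
    o_zn: float = O_ZN_CUTOFF
    zn_water: float = ZN_WATER_CUTOFF
    water_o3: float = WATER_O3_CUTOFF
    zn_zn: float = ZN_ZN_CUTOFF
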