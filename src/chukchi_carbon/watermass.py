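"""T/S water-mass classification for the Chukchi shelf.

Surface waters are assigned to one of the canonical Chukchi Sea water masses
from temperature and salinity alone: newly-ventilated and remnant winter
water (NVWW, RWW), Alaskan Coastal Water (ACW), Bering Summer Water (BSW),
early- and late-season meltwater (ESMW, LSMW) and River Water (RW).
Atlantic Water (AW) is defined by T > -1.0 degC and S > 33.6 but never
surfaces on the shelf, so the AW label is only reachable when the caller
supplies ``below_shelf=True``.

All box boundaries are strict inequalities as conventionally defined; a
(T, S) pair lying exactly on a boundary that no neighboring box includes is
labelled OTHER and excluded from group statistics.  The warm-fresh corner
(T > 8, S < 30) satisfies both RW and LSMW; RW takes precedence since river
water is treated as the warm extreme of the coastal-current group.

The numeric thresholds live in a plain data structure
(:data:`DEFAULT_BOXES`) and can be overridden from a YAML config so the
classification can be amended without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = ["WaterMass", "RegionLabel", "classify", "assign_region_group",
           "DEFAULT_BOXES", "LAT_SPLIT", "LAT_MIN", "LAT_MAX"]


class WaterMass(str, Enum):
    NVWW = "NVWW"
    RWW = "RWW"
    ACW = "ACW"
    BSW = "BSW"
    ESMW = "ESMW"
    LSMW = "LSMW"
    RW = "RW"
    AW = "AW"
    OTHER = "OTHER"


#: T/S boxes as (label, t_min, t_max, s_min, s_max) with None = unbounded;
#: all comparisons strict.  A water mass may own several boxes (BSW).
#: Listed in precedence order: the first matching box wins.
DEFAULT_BOXES: list[tuple[str, float | None, float | None, float | None, float | None]] = [
    ("NVWW", None, -1.6, 31.5, None),
    ("RWW", -1.6, 0.0, 31.5, None),
    ("RW", 8.0, None, None, 30.0),       # precedes LSMW in the shared corner
    ("ACW", 3.0, None, 30.0, 32.0),
    ("BSW", 0.0, 3.0, 30.0, 33.6),
    ("BSW", 3.0, None, 32.0, 33.6),
    ("ESMW", None, 0.0, None, 31.5),
    ("LSMW", 0.0, None, None, 30.0),
]

#: Region split: south of this latitude is the southern Chukchi Sea.
LAT_SPLIT = 69.5
#: Study domain bounds (degN).
LAT_MIN, LAT_MAX = 66.0, 74.0


@dataclass(frozen=True)
class RegionLabel:
    """Region and flux-group membership of one record."""

    region: str  # "southern" | "northern" | "out_of_domain"
    group: str   # "ACW" | "nonACW" | "winter" | "excluded"


def _in_box(t: float, s: float,
            box: tuple[str, float | None, float | None, float | None, float | None]) -> bool:
    _, t_lo, t_hi, s_lo, s_hi = box
    return ((t_lo is None or t > t_lo) and (t_hi is None or t < t_hi)
            and (s_lo is None or s > s_lo) and (s_hi is None or s < s_hi))


def classify(t: float, s: float, below_shelf: bool = False,
             boxes: list | None = None) -> WaterMass:
    """Classify a (T, S) pair into a water mass.

    Parameters
    ----------
    t, s : float
        Temperature (degC) and practical salinity.  NaN raises.
    below_shelf : bool
        Whether the sample comes from below shelf depth; only then can the
        Atlantic Water label be returned.
    boxes : list, optional
        Override for :data:`DEFAULT_BOXES` (e.g. loaded from config).
    """
    if not (math.isfinite(t) and math.isfinite(s)):
        raise ValueError(f"non-finite T/S: T={t}, S={s}")
    if below_shelf and t > -1.0 and s > 33.6:
        return WaterMass.AW
    for box in (DEFAULT_BOXES if boxes is None else boxes):
        if _in_box(t, s, box):
            return WaterMass(box[0])
    return WaterMass.OTHER


_GROUP_OF = {
    WaterMass.ACW: "ACW",
    WaterMass.RW: "ACW",
    WaterMass.BSW: "nonACW",
    WaterMass.ESMW: "nonACW",
    WaterMass.LSMW: "nonACW",
    WaterMass.NVWW: "winter",
    WaterMass.RWW: "winter",
}


def assign_region_group(lat: float, label: WaterMass) -> RegionLabel:
    """Region (by latitude split) and flux group for a labelled record.

    The ACW group bundles ACW with River Water; the non-ACW group bundles
    BSW with both meltwaters; winter waters form their own group; anything
    else (OTHER, AW, out-of-domain latitude) is excluded.
    """
    if not math.isfinite(lat) or not (LAT_MIN <= lat <= LAT_MAX):
        return RegionLabel(region="out_of_domain", group="excluded")
    region = "southern" if lat < LAT_SPLIT else "northern"
    return RegionLabel(region=region, group=_GROUP_OF.get(label, "excluded"))
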