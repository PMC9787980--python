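"""Salinity normalization of tracers with non-zero meltwater endmembers.

Ice melt dilutes every dissolved tracer; to isolate biological change, each
concentration is projected along its conservative mixing line back to the
under-ice spring reference salinity S0:

    nC = (C - C_{S=0}) / S * S0 + C_{S=0}

The S = 0 intercepts follow from a meltwater endmember of S = 5 with
DIC = 400 and TA = 460 umol kg-1 crossing the winter-water line:
DIC_{S=0} = 60 and TA_{S=0} = 106 umol kg-1.  Meltwater carries negligible
nitrate and phosphate, so nutrient intercepts are zero (normalization then
reduces to scaling by S0/S).

At S = S0 the normalization is the identity; it is linear in concentration
at fixed salinity.  DIC and TA are normalized in umol kg-1, nutrients in
uM; density-based unit conversions happen downstream in the NCP module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as cst

__all__ = ["EndmemberSet", "normalize_tracer", "normalize_bottles"]


@dataclass(frozen=True)
class EndmemberSet:
    """Reference salinity and S = 0 mixing-line intercepts."""

    s0: float = cst.S_REFERENCE
    dic_s0: float = cst.DIC_S0_INTERCEPT   # umol kg-1
    ta_s0: float = cst.TA_S0_INTERCEPT     # umol kg-1
    meltwater: dict = field(default_factory=lambda: dict(cst.MELTWATER_ENDMEMBER))

    def __post_init__(self) -> None:
        if self.dic_s0 < 0 or self.ta_s0 < 0:
            raise ValueError("intercepts must be non-negative")
        if self.s0 <= self.meltwater["S"]:
            raise ValueError("reference salinity must exceed the meltwater salinity")

    def intercept(self, tracer: str) -> float:
        tracer = tracer.upper()
        if tracer == "DIC":
            return self.dic_s0
        if tracer == "TA":
            return self.ta_s0
        if tracer in {"NO3", "PO4"}:
            return 0.0
        raise KeyError(f"unknown tracer {tracer!r}")


def normalize_tracer(conc, salinity, em: EndmemberSet | None = None,
                     tracer: str = "DIC"):
    """Normalize a concentration (scalar or array) to the reference salinity."""
    if em is None:
        em = EndmemberSet()
    conc = np.asarray(conc, dtype=float)
    salinity = np.asarray(salinity, dtype=float)
    if np.any(salinity <= 0):
        raise ValueError("salinity must be positive")
    c0 = em.intercept(tracer)
    out = (conc - c0) / salinity * em.s0 + c0
    return float(out) if out.ndim == 0 else out


def normalize_bottles(bottles: pd.DataFrame,
                      em: EndmemberSet | None = None) -> pd.DataFrame:
    """Append nDIC, nTA, nNO3, nPO4 columns to a bottle table."""
    if em is None:
        em = EndmemberSet()
    out = bottles.copy()
    for col, tracer in (("dic", "DIC"), ("ta", "TA"), ("no3", "NO3"), ("po4", "PO4")):
        if col in out.columns:
            out[f"n_{col}"] = normalize_tracer(out[col], out["s"], em, tracer)
    return out
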