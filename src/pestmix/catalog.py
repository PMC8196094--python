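"""Built-in pesticide catalog for a Salinas-Valley-type agricultural cohort.

The catalog lists the neurotoxic pesticides tracked by the pipeline together
with their chemical class, organophosphate ester subtype, countywide use
(kg in the reference years 2000 and 2005, bracketing the prenatal and
postnatal exposure windows), and the observed distribution of wind-adjusted
use within 1 km of the home on the log2(kg + 1) scale (quartiles and
maximum per exposure window, plus the prenatal-postnatal rank correlation).
These marginal targets drive the synthetic-data generator.

Eleven pesticides are analyzed for the prenatal window; naled is added for
the postnatal window (12 total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "PesticideInfo",
    "MarginalTarget",
    "default_catalog",
    "prenatal_pesticides",
    "postnatal_pesticides",
    "marginal_targets",
    "prepost_spearman",
]

VALID_CLASSES = (
    "organophosphate",
    "carbamate",
    "pyrethroid",
    "neonicotinoid",
    "fungicide",
    "herbicide",
)


@dataclass(frozen=True)
class PesticideInfo:
    """Catalog entry for one active ingredient.

    ``bmd10`` is the benchmark dose producing a 10% response in toxicological
    assays, used as an optional potency covariate in the chemistry-informed
    exchangeability matrix.  The shipped values are synthetic placeholders on
    a realistic mg/kg/day scale (the regulatory potency table is not
    redistributable); they only exercise the potency column's plumbing.
    """

    name: str
    chem_class: str
    neurotoxic: bool = True
    op_subtype: Optional[str] = None  # diethyl | dimethyl, OPs only
    bmd10: Optional[float] = None
    county_kg_2000: float = 0.0
    county_kg_2005: float = 0.0

    def __post_init__(self) -> None:
        if self.chem_class not in VALID_CLASSES:
            raise ValueError(f"unknown chemical class {self.chem_class!r}")
        is_op = self.chem_class == "organophosphate"
        if is_op and self.op_subtype not in ("diethyl", "dimethyl"):
            raise ValueError(f"{self.name}: organophosphates need op_subtype")
        if not is_op and self.op_subtype is not None:
            raise ValueError(f"{self.name}: op_subtype only valid for organophosphates")


@dataclass(frozen=True)
class MarginalTarget:
    """Quantile targets for one pesticide/window on the log2(kg+1) scale."""

    p25: float
    p50: float
    p75: float
    maximum: float
    zero_inflation: float = field(default=0.0)

    def __post_init__(self) -> None:
        q = (self.p25, self.p50, self.p75, self.maximum)
        if any(b < a for a, b in zip(q, q[1:])):
            raise ValueError("quantile targets must be nondecreasing")


def _auto_zero_inflation(p25: float, p50: float, default: float = 0.02) -> float:
    """Point mass at zero implied by which quartiles sit exactly at 0."""
    if p50 == 0.0:
        return 0.50
    if p25 == 0.0:
        return 0.25
    return default


_CATALOG = [
    # name, class, subtype, bmd10*, kg2000, kg2005
    PesticideInfo("acephate", "organophosphate", True, "dimethyl", 0.74, 40_077, 22_340),
    PesticideInfo("chlorpyrifos", "organophosphate", True, "diethyl", 0.36, 30_691, 30_459),
    PesticideInfo("diazinon", "organophosphate", True, "diethyl", 0.64, 50_999, 73_707),
    PesticideInfo("malathion", "organophosphate", True, "dimethyl", 24.0, 30_490, 29_513),
    PesticideInfo("oxydemeton_methyl", "organophosphate", True, "dimethyl", 0.22, 31_084, 33_330),
    PesticideInfo("naled", "organophosphate", True, "dimethyl", 0.54, 13_090, 7_839),
    PesticideInfo("dimethoate", "organophosphate", True, "dimethyl", 0.30, 20_259, 18_948),
    PesticideInfo("methomyl", "carbamate", True, None, None, 35_371, 28_843),
    PesticideInfo("permethrin", "pyrethroid", True, None, None, 11_869, 10_467),
    PesticideInfo("imidacloprid", "neonicotinoid", True, None, None, 8_729, 5_753),
    PesticideInfo("mn_fungicides", "fungicide", True, None, None, 161_154, 169_887),
    PesticideInfo("glyphosate", "herbicide", True, None, None, 44_236, 55_886),
]

# log2(kg+1) quartiles and max of wind-adjusted use within 1 km of the home.
_PRENATAL_Q = {
    "acephate": (0.22, 1.12, 2.07, 6.29),
    "chlorpyrifos": (0.19, 0.92, 2.03, 6.76),
    "diazinon": (1.07, 1.95, 3.02, 7.01),
    "malathion": (0.00, 0.31, 1.47, 6.68),
    "oxydemeton_methyl": (0.20, 1.00, 1.97, 5.77),
    "naled": (0.00, 0.00, 0.54, 3.93),
    "dimethoate": (0.10, 0.53, 1.50, 5.01),
    "methomyl": (0.22, 0.82, 1.86, 4.91),
    "permethrin": (0.10, 0.47, 1.16, 4.12),
    "imidacloprid": (0.15, 0.41, 0.89, 3.32),
    "mn_fungicides": (1.62, 3.13, 4.32, 5.30),
    "glyphosate": (0.00, 0.07, 1.23, 4.51),
}

_POSTNATAL_Q = {
    "acephate": (1.69, 3.09, 4.35, 6.98),
    "chlorpyrifos": (1.11, 2.67, 4.22, 7.59),
    "diazinon": (2.53, 3.79, 5.43, 8.47),
    "malathion": (0.92, 2.14, 3.89, 7.86),
    "oxydemeton_methyl": (1.55, 2.94, 4.19, 8.32),
    "naled": (0.00, 0.98, 2.48, 6.37),
    "dimethoate": (0.89, 2.08, 3.56, 6.73),
    "methomyl": (1.50, 2.71, 3.77, 7.33),
    "permethrin": (0.59, 1.49, 2.85, 5.70),
    "imidacloprid": (0.71, 1.42, 2.33, 4.74),
    "mn_fungicides": (3.85, 5.43, 6.76, 10.02),
    "glyphosate": (0.91, 2.01, 3.23, 6.75),
}

# Spearman correlation of a pesticide's use between the two exposure windows.
_PREPOST_RHO = {
    "acephate": 0.60,
    "chlorpyrifos": 0.63,
    "diazinon": 0.55,
    "malathion": 0.31,
    "oxydemeton_methyl": 0.64,
    "naled": 0.50,
    "dimethoate": 0.71,
    "methomyl": 0.51,
    "permethrin": 0.61,
    "imidacloprid": 0.55,
    "mn_fungicides": 0.60,
    "glyphosate": 0.53,
}


def default_catalog() -> list[PesticideInfo]:
    """Return the built-in catalog (12 pesticides, 7 organophosphates)."""
    return list(_CATALOG)


def prenatal_pesticides() -> list[str]:
    """The 11 pesticides analyzed for the pregnancy window (naled excluded)."""
    return [p.name for p in _CATALOG if p.name != "naled"]


def postnatal_pesticides() -> list[str]:
    """The 12 pesticides analyzed for the ages-0-5 window."""
    return [p.name for p in _CATALOG]


def marginal_targets(window: str) -> dict[str, MarginalTarget]:
    """Quantile targets for every catalog pesticide in one window.

    Zero inflation is inferred from quartiles that sit exactly at 0 (a
    quartile of 0.00 on the log2(kg+1) scale means at least that share of
    participants had no proximal use).
    """
    table = {"prenatal": _PRENATAL_Q, "postnatal": _POSTNATAL_Q}[window]
    out = {}
    for name, (p25, p50, p75, mx) in table.items():
        out[name] = MarginalTarget(p25, p50, p75, mx, _auto_zero_inflation(p25, p50))
    return out


def prepost_spearman() -> dict[str, float]:
    """Prenatal-postnatal rank correlation per pesticide."""
    return dict(_PREPOST_RHO)
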