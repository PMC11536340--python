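"""Enantioselectivity arithmetic: ee, kinetic-resolution E values, ddG.

For a kinetic resolution with conversion c and product enantiomeric excess
ee_P, the enantioselectivity factor is computed in the Chen product-ee form

    E = ln[1 - c (1 + ee_P)] / ln[1 - c (1 - ee_P)]

which is >= 1, equals 1 exactly for a racemic product, and diverges as
c (1 + ee_P) -> 1. The Boltzmann bridge between an activation free-energy
difference ddG (kcal/mol) between the two attack channels and the resulting
ee is ee = (r - 1)/(r + 1) with r = exp(ddG / RT), R = 1.9872e-3 kcal/mol/K.

External tables carry percent columns; all internal computation is on
fractions. The ee sign carries the enantiomer direction; E is the magnitude
of the preference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeRecord",
    "EValueResult",
    "SingularDomainError",
    "AchiralSubstrateError",
    "enantiomeric_excess",
    "e_value",
    "regio_ratio",
    "ee_from_ddg",
    "ddg_from_ee",
    "ddg_ee_convert",
    "pct_to_frac",
    "frac_to_pct",
    "add_e_values",
    "load_characterization_data",
    "GAS_CONSTANT_KCAL",
]

#: Gas constant in kcal/mol/K (same value as the Boltzmann constant used for
#: the free-energy surfaces, keeping the two conversions consistent).
GAS_CONSTANT_KCAL = 1.9872e-3


class SingularDomainError(ValueError):
    """(c, ee) lies outside the kinetic-resolution mass-balance domain."""


class AchiralSubstrateError(ValueError):
    """E is requested for an achiral (meso) substrate, where it is undefined."""


@dataclass(frozen=True)
class OutcomeRecord:
    """One characterized reaction outcome.

    ``eeP`` is a signed fraction; positive means the designated reference
    enantiomer. ``achiral`` marks meso substrates (e.g. cyclohexene oxide)
    whose product chirality is set by regioselectivity, not kinetic
    resolution, so no E value exists.
    """

    variant: str
    substrate: str
    nucleophile: str
    conversion: float
    eeP: float
    regio_fractions: Optional[tuple[float, float]] = None
    replicate_sd: Optional[float] = None
    achiral: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion <= 1.0:
            raise ValueError(f"conversion {self.conversion} outside [0, 1]")
        if not -1.0 <= self.eeP <= 1.0:
            raise ValueError(f"eeP {self.eeP} outside [-1, 1]")
        if self.regio_fractions is not None:
            a, b = self.regio_fractions
            if a < 0 or b < 0 or a > 1 or b > 1:
                raise ValueError("regio fractions must each be in [0, 1]")


@dataclass(frozen=True)
class EValueResult:
    """Selectivity factor E with its inputs and a near-singularity flag."""

    E: float
    conversion: float
    eeP: float
    near_singular: bool = False


def pct_to_frac(x):
    """Percent -> fraction (exact: divide by 100)."""
    return np.asarray(x, dtype=float) / 100.0


def frac_to_pct(x):
    """Fraction -> percent (exact: multiply by 100)."""
    return np.asarray(x, dtype=float) * 100.0


def enantiomeric_excess(major: float, minor: float) -> float:
    """ee = (major - minor) / (major + minor) for non-negative amounts."""
    if major < 0 or minor < 0:
        raise ValueError("amounts must be >= 0")
    total = major + minor
    if total == 0:
        raise ValueError("ee undefined: both amounts are zero")
    return (major - minor) / total


def e_value(c: float, eeP: float) -> EValueResult:
    """Kinetic-resolution selectivity factor from conversion and product ee.

    The magnitude of ee is used (direction is carried by the ee sign); the
    result is flagged ``near_singular`` when c (1 + |ee|) exceeds 0.95, and
    the computation refuses entirely at >= 1 (mass balance violated).
    """
    if not 0.0 < c < 1.0:
        raise ValueError(f"conversion must be in (0, 1), got {c}")
    ee = abs(eeP)
    if ee > 1.0:
        raise ValueError(f"|eeP| must be <= 1, got {ee}")
    arg_plus = 1.0 - c * (1.0 + ee)
    arg_minus = 1.0 - c * (1.0 - ee)
    if arg_plus <= 0.0:
        raise SingularDomainError(
            f"c(1+|ee|) = {c * (1 + ee):.4f} >= 1: outside the "
            "kinetic-resolution domain"
        )
    if ee == 0.0:
        return EValueResult(E=1.0, conversion=c, eeP=eeP)
    E = math.log(arg_plus) / math.log(arg_minus)
    return EValueResult(
        E=E, conversion=c, eeP=eeP, near_singular=c * (1 + ee) > 0.95
    )


def regio_ratio(frac_a: float, frac_b: float) -> tuple[float, float]:
    """Normalize two regioisomer fractions to a ratio summing to 1."""
    if frac_a < 0 or frac_b < 0:
        raise ValueError("fractions must be >= 0")
    total = frac_a + frac_b
    if total == 0:
        raise ValueError("ratio undefined: both fractions are zero")
    return (frac_a / total, frac_b / total)


def ee_from_ddg(ddg: float, temperature: float = 300.0) -> float:
    """ee implied by an activation free-energy difference (kcal/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    ratio = math.exp(ddg / (GAS_CONSTANT_KCAL * temperature))
    return (ratio - 1.0) / (ratio + 1.0)


def ddg_from_ee(ee: float, temperature: float = 300.0) -> float:
    """Activation free-energy difference (kcal/mol) implied by an ee."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if abs(ee) >= 1.0:
        raise ValueError("|ee| = 1 implies an infinite ddG")
    return GAS_CONSTANT_KCAL * temperature * math.log((1.0 + ee) / (1.0 - ee))


def ddg_ee_convert(direction: str, value: float, temperature: float = 300.0) -> float:
    """Dispatch between ``ee_from_ddg`` and ``ddg_from_ee``."""
    if direction == "ee_from_ddg":
        return ee_from_ddg(value, temperature)
    if direction == "ddg_from_ee":
        return ddg_from_ee(value, temperature)
    raise ValueError(f"unknown direction {direction!r}")


def add_e_values(
    df: pd.DataFrame,
    conversion_col: str = "conversion_pct",
    ee_col: str = "eeP_pct",
    out_col: str = "E",
    achiral_substrates: frozenset[str] = frozenset(),
    substrate_col: str = "substrate",
) -> pd.DataFrame:
    """Append an E column to a percent-valued outcome table.

    Rows whose substrate is listed in ``achiral_substrates`` get NaN (their
    product chirality is determined by regioselectivity, not kinetic
    resolution); all other rows are computed from the percent columns.
    """
    out = df.copy()
    evals = []
    for _, row in out.iterrows():
        if (
            achiral_substrates
            and substrate_col in out
            and str(row[substrate_col]) in achiral_substrates
        ):
            evals.append(float("nan"))
            continue
        c = float(row[conversion_col]) / 100.0
        ee = float(row[ee_col]) / 100.0
        evals.append(e_value(c, ee).E)
    out[out_col] = evals
    return out


def e_value_for_outcome(record: OutcomeRecord) -> EValueResult:
    """E for a characterized outcome; refuses achiral substrates."""
    if record.achiral:
        raise AchiralSubstrateError(
            f"{record.substrate}: the substrate is achiral, so product "
            "chirality is determined by the regioselectivity of the attack "
            "and a kinetic-resolution E value is undefined"
        )
    return e_value(record.conversion, record.eeP)


# ---------------------------------------------------------------------------
# Bundled characterization data
# ---------------------------------------------------------------------------

# Measured conversion / product-ee pairs (percent, with replicate spreads)
# for purified halohydrin-dehalogenase loop variants: azidolysis of
# trans-2,3-heptene oxide (regioisomers 6a and 6b) and of styrene oxide.
# reported_E is the tabulated selectivity factor for cross-checking.
_CHARACTERIZATION_ROWS = [
    # variant, substrate, regioisomer, conversion_pct, eeP_pct, reported_E, reported_E_sd
    ("WT",   "trans-2,3-heptene oxide", "6a", 48.0,  12.0, 1.4, 0.0),
    ("WT",   "trans-2,3-heptene oxide", "6b", 51.0,  12.0, 1.4, 0.0),
    ("T44K", "trans-2,3-heptene oxide", "6a", 36.0,   4.7, 1.1, 0.1),
    ("T44K", "trans-2,3-heptene oxide", "6b", 40.0,  38.0, 2.8, 0.1),
    ("M45L", "trans-2,3-heptene oxide", "6a", 33.0,   5.6, 1.1, 0.0),
    ("M45L", "trans-2,3-heptene oxide", "6b", 45.0,  36.0, 2.8, 0.0),
    ("M45K", "trans-2,3-heptene oxide", "6a", 25.0,  29.0, 2.0, 0.0),
    ("M45K", "trans-2,3-heptene oxide", "6b", 30.0,  61.0, 5.3, 0.1),
    ("V46R", "trans-2,3-heptene oxide", "6a", 32.0,  10.0, 1.3, 0.1),
    ("V46R", "trans-2,3-heptene oxide", "6b", 36.0,  46.0, 3.5, 0.2),
    ("WT",   "styrene oxide",           "-",  46.0,  84.0, 24.0, 1.9),
    ("T44F", "styrene oxide",           "-",  53.0,  84.0, 44.0, 1.6),
    ("T44Y", "styrene oxide",           "-",  53.0,  85.0, 42.0, 0.4),
    ("T44W", "styrene oxide",           "-",  52.0,  82.0, 32.0, 0.4),
    ("M45F", "styrene oxide",           "-",  52.0,  85.0, 39.0, 0.2),
]


def load_characterization_data() -> pd.DataFrame:
    """Characterization table of the purified loop variants (percent units).

    Columns: variant, substrate, regioisomer, conversion_pct, eeP_pct,
    reported_E, reported_E_sd. The heptene-oxide rows are per-regioisomer
    kinetic resolutions; the styrene-oxide rows are the classic single-product
    resolution.
    """
    return pd.DataFrame(
        _CHARACTERIZATION_ROWS,
        columns=[
            "variant",
            "substrate",
            "regioisomer",
            "conversion_pct",
            "eeP_pct",
            "reported_E",
            "reported_E_sd",
        ],
    )
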