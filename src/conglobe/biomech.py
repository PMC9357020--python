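"""Biomechanical and measurement statistics for beetle exoskeletons.

* defensive strength from uniaxial whole-body compression curves: the force at
  10% normalised deformation, or at the breaking point — the first sample
  where the force instantly (between consecutive samples) drops by more than
  5% from the running maximum — whichever event comes first;
* cuticle thickness ratio: outer (elytra + pronotum) over inner (abdominal
  ventrites + metasternum) surface thickness;
* width/length ratio convention used in species descriptions (exact decimal
  division, one decimal, ties to even — reproduces every printed
  ratio/measurement pair);
* Oliver–Pharr indentation modulus from unloading stiffness and contact area;
* two-tailed two-sample t-tests (Welch by default).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InfeasibleRecordError, InsufficientDataError

BREAK_DROP_FRACTION = 0.05  # ">5% from the maximum force"
STRENGTH_DEFORMATION = 0.10  # 10% of original height

# Berkovich indenter geometry factor and diamond indenter elastic constants
BETA_BERKOVICH = 1.034
DIAMOND_MODULUS_GPA = 1141.0
DIAMOND_POISSON = 0.07
CUTICLE_POISSON = 0.3


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------


@dataclass
class ForceCurve:
    """A uniaxial compression record (displacement in um, force in N)."""

    displacement: np.ndarray
    force: np.ndarray
    original_height: float  # um
    projected_area: float | None = None  # mm^2

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, float)
        self.force = np.asarray(self.force, float)
        if self.displacement.shape != self.force.shape or self.displacement.ndim != 1:
            raise DegenerateInputError("displacement and force must be equal-length vectors")
        if np.any(np.diff(self.displacement) <= 0):
            raise DegenerateInputError("displacement must be strictly increasing")
        if not np.all(np.isfinite(self.force)) or np.any(self.force < 0):
            raise DegenerateInputError("forces must be finite and non-negative")
        if self.original_height <= 0:
            raise DegenerateInputError("original height must be positive")

    def strain(self) -> np.ndarray:
        """Normalised deformation: displacement / original height."""
        return self.displacement / self.original_height


@dataclass
class DefensiveStrength:
    force: float  # N, or N/mm^2 when normalised by projected area
    event: str  # "ten_percent" | "breaking_point"
    strain_at_event: float
    area_normalized: bool = False


def find_breaking_point(curve: ForceCurve) -> int | None:
    """Index of the first sample whose force undercuts 95% of the running
    maximum (an instantaneous >5% drop); None if the curve never breaks."""
    running_max = np.maximum.accumulate(curve.force)
    for i in range(1, len(curve.force)):
        if curve.force[i] < (1.0 - BREAK_DROP_FRACTION) * running_max[i - 1]:
            return i
    return None


def defensive_strength(curve: ForceCurve) -> DefensiveStrength:
    """Force representing defensive strength: at 10% deformation (linear
    interpolation between bracketing samples) or at the breaking point,
    whichever occurs at smaller deformation.  Divided by the projected area
    when the record carries one."""
    eps = curve.strain()
    break_idx = find_breaking_point(curve)
    ten_pct_available = eps[-1] >= STRENGTH_DEFORMATION

    if break_idx is not None:
        pre_drop = int(np.argmax(curve.force[:break_idx]))
        break_eps = eps[pre_drop]
    if break_idx is not None and (not ten_pct_available or break_eps <= STRENGTH_DEFORMATION):
        force = float(np.max(curve.force[:break_idx]))
        event, at = "breaking_point", float(break_eps)
    elif ten_pct_available:
        force = float(np.interp(STRENGTH_DEFORMATION, eps, curve.force))
        event, at = "ten_percent", STRENGTH_DEFORMATION
    else:
        raise InsufficientDataError(
            "curve ends before 10% deformation and contains no breaking event"
        )
    if curve.projected_area is not None:
        return DefensiveStrength(force / curve.projected_area, event, at, True)
    return DefensiveStrength(force, event, at, False)


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

REGIONS = ("pronotum", "elytra", "metasternum", "ventrites")
OUTER_REGIONS = ("elytra", "pronotum")
INNER_REGIONS = ("ventrites", "metasternum")


@dataclass
class ThicknessProfile:
    region: str
    measurements: np.ndarray  # um

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        self.measurements = np.atleast_1d(np.asarray(self.measurements, float))
        if len(self.measurements) < 1 or np.any(self.measurements <= 0):
            raise DegenerateInputError("thickness values must be positive")

    def mean(self) -> float:
        return float(self.measurements.mean())


def thickness_ratio(profiles: list[ThicknessProfile]) -> float:
    """Outer/inner surface thickness: (mean elytra + mean pronotum) /
    (mean ventrites + mean metasternum)."""
    by_region = {p.region: p for p in profiles}
    missing = [r for r in REGIONS if r not in by_region]
    if missing:
        raise InsufficientDataError(f"missing thickness regions: {missing}")
    outer = sum(by_region[r].mean() for r in OUTER_REGIONS)
    inner = sum(by_region[r].mean() for r in INNER_REGIONS)
    return outer / inner


# ---------------------------------------------------------------------------
# W/L ratio convention
# ---------------------------------------------------------------------------


def wl_ratio(width: float, length: float, decimals: int = 1) -> float:
    """Width/length ratio rounded to ``decimals`` places, ties to even.

    The ratio is computed in exact decimal arithmetic and rounded half-to-even
    (banker's rounding).  Every printed ratio/measurement pair in the species
    descriptions is reproduced under this convention (e.g. 1.8 mm / 1.6 mm =
    1.125 printed as 1.1, 3.9 mm / 2.1 mm = 1.857... printed as 1.9); none of
    the printed ratios is an exact tie, so the tie rule itself is
    unconstrained by the data and follows the standard convention.
    """
    if width <= 0 or length <= 0:
        raise DegenerateInputError("width and length must be positive")
    # measurements are decimal numerals; convert via str so e.g. 1.8/1.6 is
    # exactly 1.125 rather than a ratio of binary approximations
    ratio = Decimal(str(width)) / Decimal(str(length))
    q = Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(q, rounding=ROUND_HALF_EVEN))


# ---------------------------------------------------------------------------
# Oliver-Pharr indentation modulus
# ---------------------------------------------------------------------------


@dataclass
class IndentationRecord:
    """Nanoindentation unloading stiffness and contact area."""

    stiffness: float  # S, mN/um
    contact_area: float  # A_c, um^2
    sample_poisson: float = CUTICLE_POISSON
    indenter_modulus_gpa: float = DIAMOND_MODULUS_GPA
    indenter_poisson: float = DIAMOND_POISSON
    beta: float = BETA_BERKOVICH

    def __post_init__(self) -> None:
        if self.stiffness <= 0 or self.contact_area <= 0:
            raise DegenerateInputError("stiffness and contact area must be positive")
        if not (0 <= self.sample_poisson < 0.5):
            raise DegenerateInputError("Poisson ratio must lie in [0, 0.5)")


def reduced_modulus_gpa(record: IndentationRecord) -> float:
    """E_r = (sqrt(pi) / (2 beta)) * S / sqrt(A_c); mN/um^2 == GPa."""
    return (
        math.sqrt(math.pi)
        / (2.0 * record.beta)
        * record.stiffness
        / math.sqrt(record.contact_area)
    )


def oliver_pharr_modulus(record: IndentationRecord) -> float:
    """Sample elastic modulus (MPa) from the Oliver-Pharr relations.

    1/E_r = (1 - nu_s^2)/E_s + (1 - nu_i^2)/E_i with diamond indenter
    defaults (E_i = 1141 GPa, nu_i = 0.07).
    """
    e_r = reduced_modulus_gpa(record)
    indenter_term = (1.0 - record.indenter_poisson**2) / record.indenter_modulus_gpa
    sample_term = 1.0 / e_r - indenter_term
    if sample_term <= 0:
        raise InfeasibleRecordError(
            "reduced modulus does not exceed the indenter compliance contribution"
        )
    e_s_gpa = (1.0 - record.sample_poisson**2) / sample_term
    return e_s_gpa * 1000.0  # MPa


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def two_tailed_t(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample two-sided t-test (Welch by default); returns (t, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each sample needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        raise DegenerateInputError("zero variance in both samples with equal means")
    result = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(result.statistic), float(result.pvalue)
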