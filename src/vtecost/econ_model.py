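"""Break-even economics of postoperative VTE chemoprophylaxis.

The model asks: by how much must a prophylactic drug reduce the symptomatic
venous-thromboembolism (VTE) rate after surgery for the money spent on the
drug across all patients to equal the money saved by the events it prevents?

For an annual volume of ``S`` surgeries, a per-course drug cost ``C_d``
(course price plus any monitoring add-on, e.g. INR testing for warfarin),
a per-event treatment cost ``C_t`` and an initial symptomatic VTE rate
``VR_i``, the break-even *final* rate is

    VR_f = (C_t * VR_i * S - C_d * S) / (C_t * S) = VR_i - C_d / C_t

``S`` cancels, so the result is volume-independent; :func:`break_even_rate`
still evaluates the literal form and checks the cancellation numerically.
The absolute risk reduction the drug must deliver is
``ARR = VR_i - VR_f = C_d / C_t`` and the number needed to treat is
``NNT = 1 / ARR`` — how many patients receive the course per single event
that must be prevented for the drug to pay for itself.  A regimen is
cost-effective when the required ARR does not exceed the initial rate,
i.e. when ``VR_f >= 0``; negative final rates are reported as-is and signal
infeasibility at that price point.

Conventions
-----------
* Rates are decimal fractions everywhere in this module (0.0046, never
  0.46); percent values belong to formatting layers only.
* Currency is carried as exact :class:`decimal.Decimal` dollars on the
  domain types and converted to float at the arithmetic boundary.
* NNT is rounded half away from zero to the nearest integer (50000/138.77 =
  360.31 prints as 360, not the ceiling 361).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal, InvalidOperation

from scipy.stats import norm

__all__ = [
    "DrugCourse",
    "CostScenario",
    "BreakEvenResult",
    "absolute_risk_reduction",
    "break_even_rate",
    "number_needed_to_treat",
    "is_cost_effective",
    "threshold_treatment_cost",
    "threshold_drug_cost",
    "sample_size_two_proportions",
    "round_half_away",
]

#: tolerance on a rate (fraction) below which a value counts as zero; keeps
#: the break-even boundary C_t = C_t* classified cost-effective despite the
#: float round trip of C_d / (C_d / VR_i).
RATE_TOL = 1e-12


def _money(value, name: str) -> Decimal:
    """Coerce to an exact Decimal dollar amount (str/int/Decimal preferred)."""
    try:
        dec = value if isinstance(value, Decimal) else Decimal(repr(float(value)) if isinstance(value, float) else str(value))
    except InvalidOperation as exc:
        raise ValueError(f"{name} is not a valid dollar amount: {value!r}") from exc
    if not dec.is_finite():
        raise ValueError(f"{name} must be finite, got {value!r}")
    return dec


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    This is the rounding the model uses for every displayed quantity; it
    differs from Python's built-in banker's rounding on exact halves.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DrugCourse:
    """One chemoprophylactic regimen: a full course price plus optional
    monitoring add-on (both USD).

    ``monitoring_cost`` is additive wherever the drug cost enters the model;
    the warfarin-with-INR scenario is ``$2.10 + $6.19 = $8.29`` per course.
    """

    name: str
    course_cost: Decimal
    monitoring_cost: Decimal = Decimal("0")
    dose_label: str = ""
    route: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "course_cost", _money(self.course_cost, "course_cost"))
        object.__setattr__(self, "monitoring_cost", _money(self.monitoring_cost, "monitoring_cost"))
        if self.course_cost < 0:
            raise ValueError(f"course_cost must be non-negative, got {self.course_cost}")
        if self.monitoring_cost < 0:
            raise ValueError(f"monitoring_cost must be >= 0, got {self.monitoring_cost}")

    @property
    def effective_cost(self) -> Decimal:
        """Total per-course cost entering the model: course + monitoring."""
        return self.course_cost + self.monitoring_cost

    @property
    def label(self) -> str:
        """Display label, e.g. ``"Aspirin 81"``."""
        return f"{self.name} {self.dose_label}".strip()

    def with_monitoring(self, cost, suffix: str = " + INR") -> "DrugCourse":
        """Variant of this regimen with a monitoring add-on folded in."""
        return replace(
            self,
            monitoring_cost=_money(cost, "monitoring_cost"),
            dose_label=(self.dose_label + suffix).strip(),
        )


@dataclass(frozen=True)
class CostScenario:
    """Economic context: per-event treatment cost ``C_t``, annual surgical
    volume ``S`` (cancels out of the model, kept for the literal equation)
    and the initial symptomatic VTE rate ``VR_i`` as a fraction."""

    treatment_cost: Decimal
    initial_rate: float
    annual_surgeries: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment_cost", _money(self.treatment_cost, "treatment_cost"))
        if self.treatment_cost <= 0:
            raise ValueError(f"treatment_cost must be positive, got {self.treatment_cost}")
        if not isinstance(self.annual_surgeries, int) or self.annual_surgeries < 1:
            raise ValueError(f"annual_surgeries must be an integer >= 1, got {self.annual_surgeries!r}")
        if not 0.0 <= self.initial_rate <= 1.0:
            raise ValueError(f"initial_rate must be a fraction in [0, 1], got {self.initial_rate!r}")


@dataclass(frozen=True)
class BreakEvenResult:
    """Outcome of the break-even computation for one (drug, scenario) pair.

    ``final_rate`` may be negative: the drug would have to prevent more
    events than occur, i.e. it cannot pay for itself at this price point.
    """

    final_rate: float
    arr: float
    nnt_exact: float
    nnt: int
    cost_effective: bool


def absolute_risk_reduction(drug: DrugCourse, scenario: CostScenario) -> float:
    """Required absolute risk reduction ``ARR = C_d / C_t`` as a fraction.

    Independent of the surgical volume and of the initial rate: it is purely
    the price ratio between one prophylactic course and one treated event.
    """
    c_t = float(scenario.treatment_cost)
    if c_t <= 0:
        raise ValueError("treatment cost must be positive")
    return float(drug.effective_cost) / c_t


def number_needed_to_treat(arr: float) -> tuple[float, int]:
    """``NNT = 1 / ARR``: courses bought per event that must be prevented.

    Returns ``(nnt_exact, nnt)`` where ``nnt`` is rounded half away from
    zero to the nearest integer.
    """
    if not arr > 0:
        raise ValueError(f"ARR must be positive, got {arr!r}")
    if arr > 1:
        raise ValueError(f"ARR cannot exceed 1, got {arr!r}")
    nnt_exact = 1.0 / arr
    return nnt_exact, int(round_half_away(nnt_exact, 0))


def break_even_rate(drug: DrugCourse, scenario: CostScenario) -> BreakEvenResult:
    """Solve the break-even equation for one drug in one cost scenario.

    Evaluates the literal volume-carrying form
    ``(C_t*VR_i*S - C_d*S) / (C_t*S)`` and the reduced form
    ``VR_i - C_d/C_t``, checks that the surgical volume cancels to within
    1e-12, and returns the populated :class:`BreakEvenResult`.
    """
    c_d = float(drug.effective_cost)
    c_t = float(scenario.treatment_cost)
    vr_i = scenario.initial_rate
    s = float(scenario.annual_surgeries)

    literal = (c_t * vr_i * s - c_d * s) / (c_t * s)
    reduced = vr_i - c_d / c_t
    if abs(literal - reduced) > 1e-12:
        raise ArithmeticError(
            f"surgical volume failed to cancel: literal={literal!r} reduced={reduced!r}"
        )

    arr = absolute_risk_reduction(drug, scenario)
    if arr > 0:
        nnt_exact, nnt = number_needed_to_treat(arr)
    else:
        # free course: nothing to pay back, no finite NNT
        nnt_exact, nnt = math.inf, 0
    return BreakEvenResult(
        final_rate=reduced,
        arr=arr,
        nnt_exact=nnt_exact,
        nnt=nnt,
        cost_effective=reduced >= -RATE_TOL,
    )


def is_cost_effective(drug: DrugCourse, scenario: CostScenario) -> bool:
    """True iff the required ARR does not exceed the initial rate
    (equivalently, the break-even final rate is non-negative).

    The exact boundary ``C_d / C_t == VR_i`` counts as cost-effective.
    """
    return break_even_rate(drug, scenario).cost_effective


def threshold_treatment_cost(drug: DrugCourse, initial_rate: float) -> float:
    """Smallest per-event treatment cost ``C_t* = C_d / VR_i`` at which the
    drug is cost-effective.

    ``is_cost_effective`` is False for any ``C_t < C_t*`` and True for
    ``C_t >= C_t*``.  No finite threshold exists at a zero initial rate.
    """
    if not 0.0 < initial_rate <= 1.0:
        raise ValueError(f"initial_rate must be in (0, 1], got {initial_rate!r}")
    return float(drug.effective_cost) / initial_rate


def threshold_drug_cost(scenario: CostScenario) -> float:
    """Largest total course cost ``C_d* = C_t * VR_i`` that is still
    cost-effective in this scenario (the drug's break-even purchase price)."""
    return float(scenario.treatment_cost) * scenario.initial_rate


def sample_size_two_proportions(
    p1: float, p2: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Total sample size to detect ``p1`` vs ``p2`` between two equal arms.

    Pooled-variance normal approximation, two-sided ``alpha``, no continuity
    correction:

        n/arm = (z_{1-a/2} * sqrt(2*pbar*(1-pbar))
                 + z_{1-b} * sqrt(p1*(1-p1) + p2*(1-p2)))^2 / (p1-p2)^2

    with ``pbar = (p1+p2)/2``; the per-arm size is rounded up and the total
    over both arms returned.  Risk differences at the NNTs this model
    produces (tens of thousands) make these sizes astronomically large —
    the model's point is that the equivalent trial is infeasible.
    """
    if not (0.0 < p2 < p1 < 1.0):
        raise ValueError(f"need 0 < p2 < p1 < 1, got p1={p1!r}, p2={p2!r}")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_b = norm.ppf(power)
    pbar = (p1 + p2) / 2.0
    num = (z_a * math.sqrt(2.0 * pbar * (1.0 - pbar))
           + z_b * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))) ** 2
    n_per_arm = math.ceil(num / (p1 - p2) ** 2)
    return 2 * n_per_arm
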