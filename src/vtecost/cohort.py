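"""Synthetic surgical cohort generation and VTE incidence estimation.

The empirical input to the break-even model is a single incidence
proportion: the symptomatic VTE rate within 4 weeks of total ankle
arthroplasty among patients who received no chemoprophylaxis, estimated
from a federated EHR registry as 16 events among 1577 eligible patients
(1.01%).  That registry is access-restricted, so this module emulates the
*structure* of the extract rather than querying it: each synthetic patient
carries a prophylaxis flag (drawn Bernoulli at the cohort's prophylaxis
fraction) and a VTE-within-window outcome drawn at an arm-specific true
rate.  The treated-arm rate is a free parameter — no prophylaxis-efficacy
claim is encoded.

Inclusion follows the registry analysis: the incidence denominator is the
patients who did NOT receive prophylaxis; treated patients are excluded.
Interval estimation uses the Wilson score interval by default (well-behaved
at small event counts), with the exact Clopper-Pearson interval available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "REGISTRY_QUERY_METADATA",
    "CohortRecord",
    "CohortSummary",
    "generate_cohort",
    "estimate_incidence",
    "summarize_cohort",
    "cohort_to_csv",
]

#: Documentation-only labels describing the registry query this generator
#: emulates: VTE diagnosis codes (pulmonary embolism; acute embolism and
#: thrombosis of deep veins of upper/lower extremity) and the ankle
#: arthroplasty procedure code, with the 4-week outcome window.
REGISTRY_QUERY_METADATA = {
    "icd10_outcome_codes": ("I26", "I82.62", "I82.64"),
    "cpt_procedure_codes": ("1014588",),
    "window_days": 28,
}


class CohortRecord(NamedTuple):
    """One synthetic registry row: did the patient receive prophylaxis, and
    did a symptomatic VTE occur within the outcome window."""

    patient_id: str
    received_prophylaxis: bool
    vte_within_window: bool
    window_days: int = 28


@dataclass(frozen=True)
class CohortSummary:
    """Event/denominator summary under the no-prophylaxis inclusion rule."""

    n_total: int
    n_no_prophylaxis: int
    n_events: int
    rate: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    ci_method: str = "wilson"


def _check_fraction(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


def generate_cohort(
    n_total: int,
    prophylaxis_fraction: float,
    true_rate_untreated: float,
    true_rate_treated: float = 0.0,
    seed: int = 0,
    window_days: int = 28,
) -> list[CohortRecord]:
    """Draw a synthetic cohort of ``n_total`` independent patients.

    Each patient receives prophylaxis with probability
    ``prophylaxis_fraction``; the VTE outcome is Bernoulli at the
    arm-specific true rate.  Identical seeds give bitwise-identical
    cohorts.
    """
    if n_total < 1:
        raise ValueError(f"n_total must be >= 1, got {n_total!r}")
    if window_days < 1:
        raise ValueError(f"window_days must be positive, got {window_days!r}")
    _check_fraction(prophylaxis_fraction, "prophylaxis_fraction")
    _check_fraction(true_rate_untreated, "true_rate_untreated")
    _check_fraction(true_rate_treated, "true_rate_treated")

    rng = np.random.default_rng(seed)
    treated = rng.random(n_total) < prophylaxis_fraction
    rates = np.where(treated, true_rate_treated, true_rate_untreated)
    vte = rng.random(n_total) < rates
    width = max(6, len(str(n_total - 1)))
    return [
        CohortRecord(f"P{i:0{width}d}", bool(treated[i]), bool(vte[i]), window_days)
        for i in range(n_total)
    ]


def estimate_incidence(
    n_events: int,
    n_denominator: int,
    ci_level: float = 0.95,
    method: str = "wilson",
) -> tuple[float, float, float]:
    """Incidence proportion with a binomial confidence interval.

    Returns ``(rate, ci_low, ci_high)`` where ``rate`` is the exact
    quotient ``n_events / n_denominator``.  ``method`` is ``"wilson"``
    (score interval, default) or ``"clopper-pearson"`` (exact).
    """
    if n_denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= n_events <= n_denominator:
        raise ValueError(f"need 0 <= events <= denominator, got {n_events}/{n_denominator}")
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level!r}")
    methods = {"wilson": "wilson", "clopper-pearson": "beta"}
    if method not in methods:
        raise ValueError(f"unknown interval method {method!r} (expected one of {sorted(methods)})")
    low, high = proportion_confint(
        n_events, n_denominator, alpha=1.0 - ci_level, method=methods[method]
    )
    # the bounds are analytically exact at the degenerate counts; scrub float noise
    low = 0.0 if n_events == 0 else float(low)
    high = 1.0 if n_events == n_denominator else float(high)
    return n_events / n_denominator, low, high


def summarize_cohort(
    records: Iterable[CohortRecord],
    ci_level: float = 0.95,
    method: str = "wilson",
) -> CohortSummary:
    """Apply the no-prophylaxis inclusion rule and estimate the incidence.

    The denominator is the records with ``received_prophylaxis = False``;
    events are VTEs within that subset.  A cohort in which every patient
    received prophylaxis has an empty denominator and raises.
    """
    records = list(records)
    if not records:
        raise ValueError("cohort is empty")
    seen = {r.patient_id for r in records}
    if len(seen) != len(records):
        raise ValueError("patient identifiers are not unique within the cohort")
    n_total = len(records)
    untreated = [r for r in records if not r.received_prophylaxis]
    if not untreated:
        raise ValueError("no patients without prophylaxis: incidence denominator is empty")
    n_events = sum(r.vte_within_window for r in untreated)
    rate, low, high = estimate_incidence(n_events, len(untreated), ci_level, method)
    return CohortSummary(
        n_total=n_total,
        n_no_prophylaxis=len(untreated),
        n_events=n_events,
        rate=rate,
        ci_low=low,
        ci_high=high,
        ci_level=ci_level,
        ci_method=method,
    )


def cohort_to_csv(records: Iterable[CohortRecord]) -> str:
    """Serialize records to the cohort CSV schema
    ``patient_id,received_prophylaxis,vte_within_window,window_days``."""
    lines = ["patient_id,received_prophylaxis,vte_within_window,window_days"]
    for r in records:
        lines.append(
            f"{r.patient_id},{str(r.received_prophylaxis).lower()},"
            f"{str(r.vte_within_window).lower()},{r.window_days}"
        )
    return "\n".join(lines) + "\n"
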