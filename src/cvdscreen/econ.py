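"""Health-economics layer: events prevented, QALYs, adverse events, costs.

Earlier detection of high-risk individuals means earlier statin therapy.
The conversion from person-years of earlier statin treatment (equal to the
reduction in unrecognised high-risk person-years versus the reference
protocol) uses trial-derived per-person-year constants:

* 0.01 major cardiovascular events prevented per person-year,
* 0.00906 QALYs gained per person-year,
* GBP 47.33 saved per person-year (treatment vs placebo, downstream costs),
* statin adverse-event incidences per person-year: diabetes 0.0015,
  haemorrhagic stroke 0.00015, myopathy 0.00010.

Screening itself costs GBP 5.11 per invitation plus GBP 13.28 per screen
(GBP 18.39 per health check).  The statin constants are treated as already
discounted (3.5%/year as in their source); screening costs are not
discounted, to avoid overstating the benefit of deferring screens.  The
:func:`discount` operation exists for sensitivity analyses.

All stored values are full precision; rounding happens only at the
reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EconParameters",
    "EconResult",
    "events_prevented",
    "qalys_gained",
    "adverse_events",
    "statin_savings",
    "health_check_costs",
    "total_costs",
    "event_share_low_int",
    "discount",
    "population_scale",
    "protocol_economics",
]


@dataclass(frozen=True)
class EconParameters:
    invitation_cost: float = 5.11  # GBP per invitation
    screen_cost: float = 13.28  # GBP per screening
    statin_event_reduction: float = 0.01  # events per person-year
    statin_qaly_gain: float = 0.00906  # QALYs per person-year
    statin_cost_saving: float = 47.33  # GBP per person-year
    adverse_incidence: Mapping[str, float] = field(
        default_factory=lambda: {
            "diabetes": 0.0015,
            "haemorrhagic_stroke": 0.00015,
            "myopathy": 0.00010,
        }
    )
    discount_rate: float = 0.035  # per year
    discount_screening: bool = False

    def __post_init__(self):
        for name in (
            "invitation_cost", "screen_cost", "statin_event_reduction",
            "statin_qaly_gain", "statin_cost_saving",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.adverse_incidence.values()):
            raise ValueError("adverse incidences must be >= 0")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount_rate must be in [0, 1)")

    @property
    def health_check_cost(self) -> float:
        """GBP per health check: invitation + screening."""
        return self.invitation_cost + self.screen_cost

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["adverse_incidence"] = dict(self.adverse_incidence)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "EconParameters":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass
class EconResult:
    """Economic outcomes of one protocol (absolute or delta vs reference)."""

    statin_person_years: float
    events_prevented: float
    qalys_gained: float
    adverse_events: dict[str, float]
    health_check_costs: float
    statin_savings: float

    @property
    def total_costs(self) -> float:
        # sign convention: savings positive, subtracted from check costs
        return self.health_check_costs - self.statin_savings


def _require_nonneg(x: float, name: str) -> float:
    x = float(x)
    if x < 0:
        raise ValueError(f"{name} must be >= 0, got {x}")
    return x


def events_prevented(delta_statin_py: float, params: EconParameters | None = None) -> float:
    """Major cardiovascular events prevented by earlier statin treatment."""
    params = params or EconParameters()
    return _require_nonneg(delta_statin_py, "delta_statin_py") * params.statin_event_reduction


def qalys_gained(delta_statin_py: float, params: EconParameters | None = None) -> float:
    """QALYs gained by earlier statin treatment."""
    params = params or EconParameters()
    return _require_nonneg(delta_statin_py, "delta_statin_py") * params.statin_qaly_gain


def adverse_events(
    delta_statin_py: float, params: EconParameters | None = None
) -> dict[str, float]:
    """Statin adverse events (diabetes, haemorrhagic stroke, myopathy) caused."""
    params = params or EconParameters()
    py = _require_nonneg(delta_statin_py, "delta_statin_py")
    return {k: py * v for k, v in params.adverse_incidence.items()}


def statin_savings(delta_statin_py: float, params: EconParameters | None = None) -> float:
    """GBP saved downstream by earlier statin treatment."""
    params = params or EconParameters()
    return _require_nonneg(delta_statin_py, "delta_statin_py") * params.statin_cost_saving


def health_check_costs(
    screens_by_year: Sequence[float] | float, params: EconParameters | None = None
) -> float:
    """Total cost of performed health checks (invitation + screen each).

    ``screens_by_year`` may be a scalar count or a per-year sequence;
    screening costs are undiscounted unless ``params.discount_screening``.
    """
    params = params or EconParameters()
    counts = np.atleast_1d(np.asarray(screens_by_year, dtype=float))
    if (counts < 0).any():
        raise ValueError("screen counts must be >= 0")
    if params.discount_screening:
        return discount(counts * params.health_check_cost, params.discount_rate)
    return float(counts.sum() * params.health_check_cost)


def total_costs(health_check: float, savings: float) -> float:
    """Total costs = health-check costs minus statin savings (savings positive)."""
    return float(health_check) - float(savings)


def event_share_low_int(
    baseline_low_int_events: float, prevented: float, total_events: float
) -> float:
    """Percent of all events still originating in low/intermediate categories.

    Events prevented by earlier detection are events that would have struck
    people not yet detected; preventing them lowers the share of events
    arising below the treatment threshold.
    """
    if not 0 <= prevented <= baseline_low_int_events <= total_events:
        raise ValueError(
            "need 0 <= prevented <= baseline_low_int_events <= total_events"
        )
    return 100.0 * (baseline_low_int_events - prevented) / total_events


def discount(stream: Sequence[float], rate: float) -> float:
    """Present value of a yearly stream: sum_t value_t / (1+rate)^t."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    v = np.asarray(stream, dtype=float)
    t = np.arange(len(v), dtype=float)
    return float((v / (1.0 + rate) ** t).sum())


def protocol_economics(
    delta_statin_py: float,
    screens: float,
    params: EconParameters | None = None,
) -> EconResult:
    """Full economic valuation of one protocol's screening and detection gains."""
    params = params or EconParameters()
    py = _require_nonneg(delta_statin_py, "delta_statin_py")
    return EconResult(
        statin_person_years=py,
        events_prevented=events_prevented(py, params),
        qalys_gained=qalys_gained(py, params),
        adverse_events=adverse_events(py, params),
        health_check_costs=health_check_costs(screens, params),
        statin_savings=statin_savings(py, params),
    )


def population_scale(
    per_category: pd.DataFrame,
    cohort_counts: pd.Series,
    target_population: float,
    category_distribution: pd.Series,
) -> pd.DataFrame:
    """Re-weight per-category cohort totals to a target population.

    ``per_category`` holds extensive cohort totals (rows = risk category,
    columns = quantities); ``cohort_counts`` the cohort's per-category head
    counts; ``category_distribution`` the target population's risk-category
    fractions (externally supplied, e.g. from a national primary-care risk
    distribution).  Each quantity is converted to a per-person rate within
    category and multiplied by the target category head count.  Returns the
    scaled table with a ``TOTAL`` row appended; values are per-year
    averages over the evaluation horizon when the inputs are.
    """
    dist = pd.Series(category_distribution, dtype=float)
    if abs(dist.sum() - 1.0) > 1e-8:
        raise ValueError("category_distribution must sum to 1")
    if set(dist.index) != set(per_category.index) or set(dist.index) != set(
        pd.Series(cohort_counts).index
    ):
        raise ValueError("category labels mismatch between inputs")
    counts = pd.Series(cohort_counts, dtype=float).reindex(per_category.index)
    if (counts <= 0).any():
        raise ValueError("cohort_counts must be positive for every category")
    target_counts = dist.reindex(per_category.index) * float(target_population)
    scaled = per_category.div(counts, axis=0).mul(target_counts, axis=0)
    out = pd.concat([scaled, scaled.sum().to_frame("TOTAL").T])
    return out
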