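"""Red List criteria engine: evaluate B1, B2 and D2; assign a category.

Only the geographic-range criteria are implemented. For vent-endemic
species the population-based criteria are inapplicable: there are no
population estimates or trends (A, C, D/D1) and no defensible quantitative
extinction model while commercial mining regulations are still being
negotiated (E). Criterion B subcondition (c), extreme fluctuations, is never
used — it is not relevant for these species — so a threatened tier under B
always requires both condition (a) (few locations) and condition (b(iii))
(continuing decline in habitat extent/quality, here from mining).

Criterion D2 assigns VU when the range is very restricted (AOO < 20 km² or
≤ 5 locations) AND a plausible future threat could rapidly drive the species
to CR or extinction — operationalised as: the worst-case category, with every
location under a mining license, would be CR. When the worst case is only EN,
the near-miss is expressed as NT downstream.

One rule sits above the criteria: where active commercial mining is under
way across the entire known range, the species is assessed CR (possibly
extinct) regardless of the tier the criteria reach — total habitat
destruction is the anticipated impact of mining a vent field.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dc_field
from typing import Any

from .errors import ConfigurationError
from .geo import RangeMetrics
from .threats import ThreatSummary

__all__ = [
    "Category",
    "Tier",
    "ThresholdTable",
    "CriterionResult",
    "Assessment",
    "evaluate_criterion_b",
    "evaluate_criterion_d2",
    "assign_category",
    "assess_from_metrics",
]


class Category(enum.Enum):
    """IUCN Red List categories, ordered by extinction risk."""

    DD = -1  # data deficient: unordered relative to the rest
    LC = 0
    NT = 1
    VU = 2
    EN = 3
    CR = 4

    @property
    def rank(self) -> int:
        return self.value

    @property
    def threatened(self) -> bool:
        return self in (Category.VU, Category.EN, Category.CR)


class Tier(enum.Enum):
    """Tier at which a single criterion fires."""

    NONE = 0
    VU = 2
    EN = 3
    CR = 4

    @property
    def category(self) -> Category:
        return {Tier.NONE: Category.LC, Tier.VU: Category.VU,
                Tier.EN: Category.EN, Tier.CR: Category.CR}[self]


@dataclass(frozen=True)
class ThresholdTable:
    """Quantitative bounds of criteria B and D2 (IUCN v3.1 standard values).

    A tier fires when the metric is strictly below its bound (EOO/AOO) or
    at most the bound (location counts). All bounds are km² or counts.
    """

    b1_eoo_cr: float = 100.0
    b1_eoo_en: float = 5_000.0
    b1_eoo_vu: float = 20_000.0
    b2_aoo_cr: float = 10.0
    b2_aoo_en: float = 500.0
    b2_aoo_vu: float = 2_000.0
    loc_cr: int = 1
    loc_en: int = 5
    loc_vu: int = 10
    d2_aoo: float = 20.0
    d2_locations: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.b1_eoo_cr < self.b1_eoo_en < self.b1_eoo_vu):
            raise ConfigurationError("B1 EOO bounds must be strictly increasing CR<EN<VU")
        if not (0 < self.b2_aoo_cr < self.b2_aoo_en < self.b2_aoo_vu):
            raise ConfigurationError("B2 AOO bounds must be strictly increasing CR<EN<VU")
        if not (0 < self.loc_cr < self.loc_en < self.loc_vu):
            raise ConfigurationError("location bounds must be strictly increasing CR<EN<VU")
        if self.d2_aoo <= 0 or self.d2_locations <= 0:
            raise ConfigurationError("D2 bounds must be positive")

    def b_bounds(self, criterion: str) -> dict[Tier, float]:
        if criterion == "B1":
            return {Tier.CR: self.b1_eoo_cr, Tier.EN: self.b1_eoo_en, Tier.VU: self.b1_eoo_vu}
        if criterion == "B2":
            return {Tier.CR: self.b2_aoo_cr, Tier.EN: self.b2_aoo_en, Tier.VU: self.b2_aoo_vu}
        raise ConfigurationError(f"unknown criterion {criterion!r}")

    def loc_bounds(self) -> dict[Tier, int]:
        return {Tier.CR: self.loc_cr, Tier.EN: self.loc_en, Tier.VU: self.loc_vu}


@dataclass(frozen=True)
class CriterionResult:
    """Outcome of one criterion: the tier reached and the conditions met."""

    criterion: str  # "B1" | "B2" | "D2"
    tier: Tier
    satisfied_conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tier is not Tier.NONE and not self.satisfied_conditions:
            raise ConfigurationError(
                f"{self.criterion} fired at {self.tier.name} with no conditions recorded"
            )

    @property
    def condition_letters(self) -> tuple[str, ...]:
        """Condition codes without explanatory text, e.g. ('a', 'b(iii)')."""
        return tuple(c.split(":", 1)[0].strip() for c in self.satisfied_conditions)


def evaluate_criterion_b(
    metrics: RangeMetrics, threat: ThreatSummary, thresholds: ThresholdTable | None = None
) -> tuple[CriterionResult, CriterionResult]:
    """Evaluate B1 (EOO) and B2 (AOO) and return both results.

    At each tier from CR down, the criterion fires iff the range metric is
    below the tier bound AND the location count is within the tier's
    condition (a) bound AND there is a continuing decline (condition
    b(iii)). With condition (c) unavailable, (a) and (b) are both required.
    """
    thresholds = thresholds or ThresholdTable()
    loc_bounds = thresholds.loc_bounds()
    results = []
    for criterion, value in (("B1", metrics.eoo_km2), ("B2", metrics.aoo_km2)):
        bounds = thresholds.b_bounds(criterion)
        tier = Tier.NONE
        for t in (Tier.CR, Tier.EN, Tier.VU):
            if (
                value < bounds[t]
                and metrics.n_locations <= loc_bounds[t]
                and threat.continuing_decline
            ):
                tier = t
                break
        conditions: tuple[str, ...] = ()
        if tier is not Tier.NONE:
            decline_kind = "observed" if threat.all_range_destroyed else "projected"
            conditions = (
                f"a: n_locations={metrics.n_locations} ≤ {loc_bounds[tier]}",
                f"b(iii): {decline_kind} continuing decline in habitat extent/quality",
            )
        results.append(CriterionResult(criterion, tier, conditions))
    return results[0], results[1]


def evaluate_criterion_d2(
    metrics: RangeMetrics,
    threat: ThreatSummary,
    thresholds: ThresholdTable | None = None,
    worst_case: Category = Category.LC,
) -> CriterionResult:
    """Evaluate D2 (very restricted range with a plausible rapid threat).

    ``worst_case`` is the category the species would receive were every
    location placed under a mining license (see
    :func:`ventassess.scenarios.worst_case_category`). D2 fires at VU iff
    the range is very restricted, a plausible threat exists, and that worst
    case is CR; a worst case of EN is a near-miss handled by the NT rule in
    :func:`assign_category`.
    """
    thresholds = thresholds or ThresholdTable()
    restricted_parts = []
    if metrics.aoo_km2 < thresholds.d2_aoo:
        restricted_parts.append(f"AOO={metrics.aoo_km2:g} km² < {thresholds.d2_aoo:g}")
    if metrics.n_locations <= thresholds.d2_locations:
        restricted_parts.append(
            f"n_locations={metrics.n_locations} ≤ {thresholds.d2_locations}"
        )
    if restricted_parts and threat.plausible_future_threat and worst_case is Category.CR:
        conditions = tuple(restricted_parts) + (
            "plausible future threat could rapidly lead to CR or EX",
        )
        return CriterionResult("D2", Tier.VU, conditions)
    return CriterionResult("D2", Tier.NONE)


def _merge_criteria_string(fired: list[CriterionResult]) -> str:
    """Assemble the canonical IUCN criteria string, e.g. 'B1ab(iii)+2ab(iii); D2'."""
    b_parts = [r for r in fired if r.criterion in ("B1", "B2")]
    parts: list[str] = []
    if b_parts:
        b_parts.sort(key=lambda r: r.criterion)
        sub = []
        for r in b_parts:
            letters = "".join(r.condition_letters)
            sub.append(f"{r.criterion[1]}{letters}")
        parts.append("B" + "+".join(sub))
    if any(r.criterion == "D2" for r in fired):
        parts.append("D2")
    return "; ".join(parts)


@dataclass(frozen=True)
class Assessment:
    """A completed Red List assessment for one species."""

    category: Category
    possibly_extinct: bool
    criteria_string: str
    rationale: tuple[str, ...]
    metrics: RangeMetrics | None
    threat: ThreatSummary | None
    criteria: tuple[CriterionResult, ...] = ()
    worst_case: Category | None = None
    species_id: str | None = None

    def __post_init__(self) -> None:
        if self.possibly_extinct and self.category is not Category.CR:
            raise ConfigurationError("possibly_extinct tag is only valid with CR")
        if self.category.threatened and not (self.criteria_string or self.possibly_extinct):
            raise ConfigurationError(
                "threatened category requires a criteria string (or the possibly-extinct tag)"
            )
        if not self.category.threatened and self.criteria_string:
            raise ConfigurationError("non-threatened category must have empty criteria string")

    @property
    def category_label(self) -> str:
        return self.category.name + (" (possibly extinct)" if self.possibly_extinct else "")

    def to_dict(self) -> dict[str, Any]:
        """JSON-serialisable report (machine-readable trace)."""
        d: dict[str, Any] = {
            "species_id": self.species_id,
            "category": self.category.name,
            "possibly_extinct": self.possibly_extinct,
            "category_label": self.category_label,
            "criteria_string": self.criteria_string,
            "rationale": list(self.rationale),
            "worst_case_category": self.worst_case.name if self.worst_case else None,
        }
        if self.metrics is not None:
            d["metrics"] = {
                "n_fields": self.metrics.n_fields,
                "n_locations": self.metrics.n_locations,
                "aoo_km2": self.metrics.aoo_km2,
                "eoo_km2": self.metrics.eoo_km2,
            }
        if self.threat is not None:
            d["threat"] = {
                "continuing_decline": self.threat.continuing_decline,
                "plausible_future_threat": self.threat.plausible_future_threat,
                "n_threatened_locations": self.threat.n_threatened_locations,
                "n_protected_locations": self.threat.n_protected_locations,
                "all_range_destroyed": self.threat.all_range_destroyed,
            }
        d["criteria"] = [
            {
                "criterion": c.criterion,
                "tier": c.tier.name,
                "satisfied_conditions": list(c.satisfied_conditions),
            }
            for c in self.criteria
        ]
        return d

    def to_text(self) -> str:
        """Plain-text rationale block mirroring published assessment style."""
        lines = [f"Category: {self.category_label}"]
        if self.criteria_string:
            lines.append(f"Criteria: {self.criteria_string}")
        if self.metrics is not None:
            m = self.metrics
            lines.append(
                f"Range: {m.n_fields} field(s), {m.n_locations} location(s), "
                f"AOO {m.aoo_km2:g} km², EOO {m.eoo_km2:g} km²"
            )
        lines.append("Rationale:")
        lines.extend(f"  - {r}" for r in self.rationale)
        return "\n".join(lines)


def assign_category(
    b1: CriterionResult,
    b2: CriterionResult,
    d2: CriterionResult,
    threat: ThreatSummary,
    worst_case: Category = Category.LC,
    *,
    metrics: RangeMetrics | None = None,
    species_id: str | None = None,
) -> Assessment:
    """Combine criterion results into a final category with rationale.

    The category is the highest tier reached by any criterion. If no
    criterion fires: LC when every location is effectively protected, NT
    otherwise (mixed protection, an unprotected range below no bound, or a
    plausible threat whose worst case is EN). Active mining across the
    entire range forces CR (possibly extinct).
    """
    results = (b1, b2, d2)
    top = max((r.tier for r in results), key=lambda t: t.value)
    rationale: list[str] = []
    possibly_extinct = False

    if top is not Tier.NONE:
        category = top.category
        for r in results:
            if r.tier is top:
                rationale.append(
                    f"criterion {r.criterion} met at {top.name}: "
                    + "; ".join(r.satisfied_conditions)
                )
    elif not threat.plausible_future_threat:
        category = Category.LC
        rationale.append(
            "all locations effectively protected from mining: no continuing "
            "decline and no plausible future threat"
        )
    else:
        category = Category.NT
        if threat.mixed:
            rationale.append(
                f"near threatened: range under mixed regimes "
                f"({threat.n_protected_locations} protected, "
                f"{threat.n_threatened_locations} unprotected location(s))"
            )
        elif worst_case is Category.EN:
            rationale.append(
                "near threatened: plausible future threat could rapidly lead "
                "to an EN (not CR) assessment, so D2 does not apply"
            )
        else:
            rationale.append(
                "near threatened: species not protected across its entire "
                "range, but no range criterion met at a threatened tier"
            )

    if threat.all_range_destroyed:
        if category is not Category.CR:
            rationale.append(
                f"active commercial mining across the entire range elevates the "
                f"category from {category.name} to CR"
            )
        category = Category.CR
        possibly_extinct = True
        rationale.append(
            "possibly extinct: active commercial mining is destroying all known "
            "habitat; confirmation of extinction is required"
        )

    fired = [r for r in results if r.tier is top and top is not Tier.NONE]
    criteria_string = _merge_criteria_string(fired) if category.threatened else ""
    return Assessment(
        category=category,
        possibly_extinct=possibly_extinct,
        criteria_string=criteria_string,
        rationale=tuple(rationale),
        metrics=metrics,
        threat=threat,
        criteria=results,
        worst_case=worst_case,
        species_id=species_id,
    )


def assess_from_metrics(
    metrics: RangeMetrics,
    threat: ThreatSummary,
    thresholds: ThresholdTable | None = None,
    worst_case: Category = Category.LC,
    *,
    species_id: str | None = None,
) -> Assessment:
    """Run the full criteria engine on pre-computed metrics and threat flags.

    Useful when a published EOO or AOO should be used verbatim instead of
    being recomputed from (possibly approximate) coordinates.
    """
    thresholds = thresholds or ThresholdTable()
    b1, b2 = evaluate_criterion_b(metrics, threat, thresholds)
    d2 = evaluate_criterion_d2(metrics, threat, thresholds, worst_case)
    return assign_category(
        b1, b2, d2, threat, worst_case, metrics=metrics, species_id=species_id
    )
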