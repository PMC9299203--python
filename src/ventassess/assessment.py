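"""End-to-end assessment pipeline: occurrences + regimes → Assessment.

Glues the range metrics, the threat mapping and the criteria engine
together, including the worst-case (all-locations-licensed) category that
criterion D2 needs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .engine import (
    Assessment,
    Category,
    ThresholdTable,
    Tier,
    assess_from_metrics,
    evaluate_criterion_b,
)
from .geo import GeoConfig, VentField, cluster_locations, compute_range_metrics
from .threats import RegulatoryRegime, derive_threat_summary

__all__ = ["assess_species", "worst_case_category"]


def worst_case_category(
    fields: Sequence[VentField],
    regimes: Mapping[str, RegulatoryRegime],
    config: GeoConfig | None = None,
    thresholds: ThresholdTable | None = None,
) -> Category:
    """Category under the scenario "every location under a mining license".

    With an exploration license everywhere there is a continuing decline at
    every location, so criterion B is evaluated with decline present; the
    result is the highest B tier, or NT when no tier fires (the threat is
    plausible everywhere by construction). This is the "if the threat is
    realised" endpoint that decides whether D2 applies (worst case CR) or
    the species is merely NT (worst case EN).

    The ``regimes`` mapping is only used to check area coverage; the
    override replaces every regime.
    """
    config = config or GeoConfig()
    thresholds = thresholds or ThresholdTable()
    metrics = compute_range_metrics(fields, config)
    locations = cluster_locations(fields, config)
    overridden = {loc.management_area_id: RegulatoryRegime.EXPLORATION_LICENSE
                  for loc in locations}
    threat = derive_threat_summary(locations, overridden)
    b1, b2 = evaluate_criterion_b(metrics, threat, thresholds)
    top = max((b1.tier, b2.tier), key=lambda t: t.value)
    if top is not Tier.NONE:
        return top.category
    return Category.NT


def assess_species(
    fields: Sequence[VentField],
    regimes: Mapping[str, RegulatoryRegime],
    config: GeoConfig | None = None,
    thresholds: ThresholdTable | None = None,
    *,
    species_id: str | None = None,
) -> Assessment:
    """Assess one species from its occurrence records and the regime table.

    An empty record set yields a Data Deficient (DD) assessment rather than
    an error: with no mappable occurrences neither range criterion can be
    evaluated.
    """
    config = config or GeoConfig()
    thresholds = thresholds or ThresholdTable()
    if not fields:
        return Assessment(
            category=Category.DD,
            possibly_extinct=False,
            criteria_string="",
            rationale=("no occurrence records: range criteria cannot be evaluated",),
            metrics=None,
            threat=None,
            species_id=species_id,
        )
    locations = cluster_locations(fields, config)
    metrics = compute_range_metrics(fields, config)
    threat = derive_threat_summary(locations, regimes)
    worst = worst_case_category(fields, regimes, config, thresholds)
    return assess_from_metrics(
        metrics, threat, thresholds, worst, species_id=species_id
    )
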