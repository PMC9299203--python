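"""Regulatory-change scenarios and the location-threat matrix.

A *scenario* overrides the regime of one or more management areas
(protection enacted, a license granted, mining commencing) and the
assessment is recomputed, yielding a before/after transition record. The
engine reports downlisting eligibility (a species may only move to a lower
category after no higher-category criterion has been met for five years)
but never suppresses the freshly computed category — the five-year rule is
metadata for the assessor.

The *location-threat matrix* is the decision grid mapping (number of
locations × regulatory regime) to an expected category. Every cell is
computed by running the full engine on a canonical synthetic species for
that cell — the matrix is a view of engine behaviour, never an independent
lookup table. Cells confirmed by published assessments are tagged
``text-confirmed`` and are verified at build time; the rest are
``engine-derived``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

from .assessment import assess_species, worst_case_category
from .engine import Assessment, Category, ThresholdTable
from .errors import ConfigurationError
from .geo import GeoConfig, VentField
from .threats import RegulatoryRegime

__all__ = [
    "Scenario",
    "TransitionRecord",
    "MatrixCell",
    "apply_scenario",
    "worst_case_category",
    "build_matrix",
    "LOCATION_BANDS",
    "REGIME_ROWS",
]


@dataclass(frozen=True)
class Scenario:
    """A hypothetical regulatory change: per-area regime overrides."""

    name: str
    regime_overrides: Mapping[str, RegulatoryRegime]
    description: str = ""


@dataclass(frozen=True)
class TransitionRecord:
    """Before/after categories for one scenario application."""

    scenario_name: str
    category_before: Category
    category_after: Category
    possibly_extinct_before: bool
    possibly_extinct_after: bool
    changed: bool
    is_downlisting: bool
    #: a downlisting may only be published once no higher-category criterion
    #: has been met for five years; the engine flags, the assessor decides
    downlisting_requires_five_year_rule: bool
    rule_citations: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario_name,
            "category_before": self.category_before.name,
            "category_after": self.category_after.name,
            "possibly_extinct_before": self.possibly_extinct_before,
            "possibly_extinct_after": self.possibly_extinct_after,
            "changed": self.changed,
            "is_downlisting": self.is_downlisting,
            "downlisting_requires_five_year_rule": self.downlisting_requires_five_year_rule,
            "rule_citations": list(self.rule_citations),
        }


def apply_scenario(
    fields: Sequence[VentField],
    regimes: Mapping[str, RegulatoryRegime],
    scenario: Scenario,
    config: GeoConfig | None = None,
    thresholds: ThresholdTable | None = None,
    *,
    species_id: str | None = None,
) -> tuple[Assessment, Assessment, TransitionRecord]:
    """Recompute an assessment under a scenario's regime overrides.

    Returns ``(before, after, transition)``. Override keys must reference
    management areas present in the regime table.
    """
    unknown = set(scenario.regime_overrides) - set(regimes)
    if unknown:
        raise ConfigurationError(
            f"scenario {scenario.name!r} overrides unknown management area(s): "
            + ", ".join(sorted(unknown))
        )
    before = assess_species(
        fields, regimes, config, thresholds, species_id=species_id
    )
    overridden = dict(regimes)
    overridden.update(scenario.regime_overrides)
    after = assess_species(
        fields, overridden, config, thresholds, species_id=species_id
    )
    # possibly-extinct CR outranks plain CR when deciding transition direction
    rank = lambda a: (a.category.rank, int(a.possibly_extinct))
    down = rank(after) < rank(before)
    return (
        before,
        after,
        TransitionRecord(
            scenario_name=scenario.name,
            category_before=before.category,
            category_after=after.category,
            possibly_extinct_before=before.possibly_extinct,
            possibly_extinct_after=after.possibly_extinct,
            changed=rank(after) != rank(before),
            is_downlisting=down,
            downlisting_requires_five_year_rule=down,
            rule_citations=after.rationale,
        ),
    )


# ---------------------------------------------------------------------------
# Location-threat matrix
# ---------------------------------------------------------------------------

#: location-count bands (interior representatives of the IUCN tiers)
LOCATION_BANDS: tuple[tuple[str, int], ...] = (
    ("1", 1),
    ("2-5", 3),
    ("6-10", 8),
    (">10", 12),
)

#: regime rows in increasing severity (MIXED = half protected, half licensed)
REGIME_ROWS: tuple[str, ...] = (
    "PROTECTED_EFFECTIVE",
    "UNPROTECTED_NO_LICENSE",
    "MIXED",
    "EXPLORATION_LICENSE",
    "ACTIVE_MINING",
)


@dataclass(frozen=True)
class MatrixCell:
    n_locations_band: str
    regime_row: str
    category: Category
    possibly_extinct: bool
    provenance: str  # "text-confirmed" | "engine-derived"

    @property
    def label(self) -> str:
        return self.category.name + (" (possibly extinct)" if self.possibly_extinct else "")


def _canonical_species(
    n_locations: int, config: GeoConfig
) -> tuple[list[VentField], list[str]]:
    """One single-field location per management area, spaced well beyond the
    clustering threshold along a ridge at 15°S. Returns (fields, area ids)."""
    lat = -15.0
    gap_km = max(200.0, 2.5 * config.threshold_km)
    dlon = math.degrees(gap_km / (config.earth_radius_km * math.cos(math.radians(lat))))
    fields, areas = [], []
    for i in range(n_locations):
        area = f"A{i + 1:02d}"
        areas.append(area)
        fields.append(
            VentField(
                site_id=f"S{i + 1:02d}",
                name=f"synthetic vent field {i + 1}",
                lat=lat,
                lon=i * dlon,
                management_area_id=area,
            )
        )
    return fields, areas


def _row_regimes(row: str, areas: list[str]) -> dict[str, RegulatoryRegime]:
    if row == "MIXED":
        # threatened half rounded up
        n_lic = math.ceil(len(areas) / 2)
        return {
            a: (RegulatoryRegime.EXPLORATION_LICENSE if i < n_lic
                else RegulatoryRegime.PROTECTED_EFFECTIVE)
            for i, a in enumerate(areas)
        }
    regime = RegulatoryRegime[row]
    return {a: regime for a in areas}


#: cells whose outcome is confirmed by published assessment text
_TEXT_CONFIRMED: dict[tuple[str, str], tuple[Category, bool]] = {
    ("1", "EXPLORATION_LICENSE"): (Category.CR, False),
    **{(band, "PROTECTED_EFFECTIVE"): (Category.LC, False) for band, _ in LOCATION_BANDS},
    **{(band, "ACTIVE_MINING"): (Category.CR, True) for band, _ in LOCATION_BANDS},
}


def build_matrix(
    config: GeoConfig | None = None, thresholds: ThresholdTable | None = None
) -> list[MatrixCell]:
    """Build the full location-threat matrix by running the engine per cell.

    Raises ``ConfigurationError`` if a text-confirmed cell disagrees with
    the engine — that would indicate an engine defect, not a data problem.
    """
    config = config or GeoConfig()
    thresholds = thresholds or ThresholdTable()
    cells: list[MatrixCell] = []
    for band, n_loc in LOCATION_BANDS:
        fields, areas = _canonical_species(n_loc, config)
        for row in REGIME_ROWS:
            regimes = _row_regimes(row, areas)
            a = assess_species(fields, regimes, config, thresholds)
            expected = _TEXT_CONFIRMED.get((band, row))
            provenance = "engine-derived"
            if expected is not None:
                provenance = "text-confirmed"
                if (a.category, a.possibly_extinct) != expected:
                    raise ConfigurationError(
                        f"matrix cell ({band}, {row}) computed "
                        f"{a.category_label} but published text requires "
                        f"{expected[0].name}{' (possibly extinct)' if expected[1] else ''}"
                    )
            cells.append(
                MatrixCell(
                    n_locations_band=band,
                    regime_row=row,
                    category=a.category,
                    possibly_extinct=a.possibly_extinct,
                    provenance=provenance,
                )
            )
    return cells
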