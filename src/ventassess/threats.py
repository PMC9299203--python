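"""Mapping from mining-regulation regimes to IUCN threat concepts.

The single dominant threat to vent-endemic species is seabed mining, so the
IUCN notions of *continuing decline* and *plausible future threat* reduce to
the regulatory status of each location's management area:

* a signed exploration contract (or active extraction) implies a projected
  continuing decline in habitat quality — exploratory activity may already
  have had an effect;
* any regime short of effective protection leaves mining plausible;
* effective protection (an MPA with a specific mining prohibition, treaty
  protection, or an *enacted* moratorium) removes both. A merely proposed
  moratorium does not count.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ConfigurationError, NoOccurrenceRecordsError
from .geo import Location

__all__ = [
    "RegulatoryRegime",
    "ThreatSummary",
    "regime_of_location",
    "derive_threat_summary",
]


class RegulatoryRegime(enum.Enum):
    """Regulatory regime of a management area, ordered by severity.

    PROTECTED_EFFECTIVE   MPA with a mining ban, treaty protection, or an
                          enacted moratorium. A generic MPA without a
                          specific seabed-mining prohibition does NOT
                          qualify and must be encoded as
                          UNPROTECTED_NO_LICENSE.
    UNPROTECTED_NO_LICENSE  jurisdiction without a moratorium; no mining
                          license granted.
    EXPLORATION_LICENSE   exploratory mining contract signed (also used for
                          an exploitation license where extraction has not
                          yet begun).
    ACTIVE_MINING         commercial extraction under way.
    """

    PROTECTED_EFFECTIVE = 0
    UNPROTECTED_NO_LICENSE = 1
    EXPLORATION_LICENSE = 2
    ACTIVE_MINING = 3

    @property
    def severity(self) -> int:
        return self.value

    @classmethod
    def from_token(cls, token: str) -> "RegulatoryRegime":
        try:
            return cls[token.strip().upper()]
        except KeyError:
            valid = ", ".join(m.name for m in cls)
            raise ConfigurationError(
                f"unknown regime token {token!r}; expected one of: {valid}"
            ) from None


#: regimes under which mining is plausible at all
_THREATENED = frozenset(
    {
        RegulatoryRegime.UNPROTECTED_NO_LICENSE,
        RegulatoryRegime.EXPLORATION_LICENSE,
        RegulatoryRegime.ACTIVE_MINING,
    }
)
#: regimes that imply an (at least projected) continuing decline
_DECLINING = frozenset({RegulatoryRegime.EXPLORATION_LICENSE, RegulatoryRegime.ACTIVE_MINING})


@dataclass(frozen=True)
class ThreatSummary:
    """Threat flags derived from the regimes of a species' locations."""

    continuing_decline: bool
    plausible_future_threat: bool
    n_threatened_locations: int
    n_protected_locations: int
    all_range_destroyed: bool

    def __post_init__(self) -> None:
        if self.continuing_decline and not self.plausible_future_threat:
            raise ConfigurationError(
                "continuing decline without a plausible threat is inconsistent"
            )
        if self.all_range_destroyed and not self.continuing_decline:
            raise ConfigurationError(
                "all_range_destroyed implies continuing decline"
            )

    @property
    def n_locations(self) -> int:
        return self.n_threatened_locations + self.n_protected_locations

    @property
    def mixed(self) -> bool:
        """Some locations protected, some not."""
        return self.n_threatened_locations > 0 and self.n_protected_locations > 0


def regime_of_location(
    location: Location, regimes: Mapping[str, RegulatoryRegime]
) -> RegulatoryRegime:
    """Regime of a location (locations share one management area by construction)."""
    try:
        return regimes[location.management_area_id]
    except KeyError:
        raise ConfigurationError(
            f"management area {location.management_area_id!r} "
            f"(location {location.location_id}) has no regime entry"
        ) from None


def derive_threat_summary(
    locations: Sequence[Location], regimes: Mapping[str, RegulatoryRegime]
) -> ThreatSummary:
    """Derive decline/threat flags from the regime at each location.

    ``continuing_decline`` is true iff any location lies under an
    exploration contract or active mining; ``plausible_future_threat`` iff
    any location lacks effective protection; ``all_range_destroyed`` iff
    every location is under active commercial extraction.
    """
    if not locations:
        raise NoOccurrenceRecordsError("no locations to summarise")
    loc_regimes = [regime_of_location(loc, regimes) for loc in locations]
    n_threatened = sum(r in _THREATENED for r in loc_regimes)
    return ThreatSummary(
        continuing_decline=any(r in _DECLINING for r in loc_regimes),
        plausible_future_threat=n_threatened > 0,
        n_threatened_locations=n_threatened,
        n_protected_locations=len(loc_regimes) - n_threatened,
        all_range_destroyed=all(r is RegulatoryRegime.ACTIVE_MINING for r in loc_regimes),
    )
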