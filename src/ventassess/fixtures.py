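"""Curated case-study bundles for four published vent-mollusc assessments.

Coordinates are approximate positions of the cited vent fields, encoded
from the localities named in the published assessments (the assessments
print categories, not coordinate tables); each bundle therefore carries the
published category as ground truth, while recomputed EOO values are treated
as indicative only. Where a published range metric exists (the 171.23 km²
EOO / 12 km² AOO of the *Bathymodiolus manusensis* worked example) it is
stored alongside so callers can feed the printed value to the engine
verbatim via :func:`ventassess.engine.assess_from_metrics`.

The four species:

* *Gigantopelta chessoia* — two East Scotia Ridge vent fields (E2, E9)
  protected by the SGSSI MPA mining prohibition and the Antarctic Treaty;
  published LC.
* *Dracogyra subfusca* — single vent field (Longqi, Southwest Indian
  Ridge) inside an ISA/COMRA exploration contract area; published CR.
* *Alviniconcha boucheti* — four vent fields across the EEZs of Papua New
  Guinea (Manus Basin, incl. the Solwara 1 license), Fiji (North Fiji
  Basin) and Tonga (Lau Basin); published EN.
* *Bathymodiolus manusensis* — three Manus Basin vent fields within 80 km
  of each other in one licensed management area: one location, AOO
  12 km², published EOO 171.23 km²; published EN.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import Category
from .geo import VentField
from .threats import RegulatoryRegime

__all__ = ["CaseStudy", "CASE_STUDIES", "case_study"]


@dataclass(frozen=True)
class CaseStudy:
    species_id: str
    species_name: str
    fields: tuple[VentField, ...]
    regimes: dict[str, RegulatoryRegime]
    expected_category: Category
    expected_possibly_extinct: bool = False
    published_eoo_km2: float | None = None
    published_aoo_km2: float | None = None
    notes: str = ""


_SGSSI = "MPA_SGSSI"
_COMRA_SWIR = "ISA_COMRA_SWIR"
_EEZ_PNG = "EEZ_PNG"
_EEZ_FJI = "EEZ_FJI"
_EEZ_TON = "EEZ_TON"


CASE_STUDIES: dict[str, CaseStudy] = {
    "G_chessoia": CaseStudy(
        species_id="G_chessoia",
        species_name="Gigantopelta chessoia",
        fields=(
            VentField("ESR_E2", "East Scotia Ridge E2", -56.089, -30.317, _SGSSI),
            VentField("ESR_E9", "East Scotia Ridge E9", -60.028, -29.983, _SGSSI),
        ),
        regimes={_SGSSI: RegulatoryRegime.PROTECTED_EFFECTIVE},
        expected_category=Category.LC,
        notes=(
            "Two vent fields ~440 km apart (two locations) within the SGSSI "
            "MPA, which prohibits all mineral exploitation; the Antarctic "
            "Treaty's Madrid Protocol applies regionally. Coordinates "
            "approximate the published E2/E9 positions."
        ),
    ),
    "D_subfusca": CaseStudy(
        species_id="D_subfusca",
        species_name="Dracogyra subfusca",
        fields=(
            VentField("SWIR_LONGQI", "Longqi", -37.783, 49.650, _COMRA_SWIR,
                      footprint_km2=0.015),
        ),
        regimes={_COMRA_SWIR: RegulatoryRegime.EXPLORATION_LICENSE},
        expected_category=Category.CR,
        notes=(
            "Single 100 × 150 m vent field inside the ISA–COMRA polymetallic "
            "sulfide exploration contract area on the Southwest Indian Ridge."
        ),
    ),
    "A_boucheti": CaseStudy(
        species_id="A_boucheti",
        species_name="Alviniconcha boucheti",
        fields=(
            VentField("MANUS_PACMANUS", "PACMANUS", -3.722, 151.670, _EEZ_PNG),
            VentField("MANUS_SUSU", "SuSu Knolls", -3.798, 152.100, _EEZ_PNG),
            VentField("NFB_WHITELADY", "White Lady", -16.990, 173.920, _EEZ_FJI),
            VentField("LAU_ABE", "ABE", -20.760, -176.190, _EEZ_TON),
        ),
        regimes={
            _EEZ_PNG: RegulatoryRegime.EXPLORATION_LICENSE,  # Solwara 1 project
            _EEZ_FJI: RegulatoryRegime.UNPROTECTED_NO_LICENSE,
            _EEZ_TON: RegulatoryRegime.UNPROTECTED_NO_LICENSE,
        },
        expected_category=Category.EN,
        notes=(
            "Four vent fields in three EEZs (three locations: the two Manus "
            "Basin fields are < 80 km apart); the Solwara 1 mining license in "
            "PNG waters drives the projected continuing decline."
        ),
    ),
    "B_manusensis": CaseStudy(
        species_id="B_manusensis",
        species_name="Bathymodiolus manusensis",
        fields=(
            VentField("MANUS_PACMANUS", "PACMANUS", -3.722, 151.670, _EEZ_PNG),
            VentField("MANUS_DESMOS", "DESMOS", -3.690, 151.870, _EEZ_PNG),
            VentField("MANUS_SUSU", "SuSu Knolls", -3.798, 152.100, _EEZ_PNG),
        ),
        regimes={_EEZ_PNG: RegulatoryRegime.EXPLORATION_LICENSE},
        expected_category=Category.EN,
        published_eoo_km2=171.23,
        published_aoo_km2=12.0,
        notes=(
            "Three Manus Basin vent fields within 80 km of each other in one "
            "licensed management area: a single location whose published EOO "
            "(171.23 km²) and AOO (12 km²) exceed the CR thresholds of 100 "
            "and 10 km², hence EN rather than CR."
        ),
    ),
}


def case_study(species_id: str) -> CaseStudy:
    try:
        return CASE_STUDIES[species_id]
    except KeyError:
        raise KeyError(
            f"unknown case study {species_id!r}; available: {sorted(CASE_STUDIES)}"
        ) from None
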