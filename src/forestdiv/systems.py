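"""Forest management system taxonomy.

Seven archetypal systems, split by production focus: four that primarily
produce wood (reduced-impact logging, selective cutting, clear cutting with
natural regrowth, forest plantations) and three that primarily produce food
(agroforests, silvopasture, perennial tree crop plantations).  Managed
communities are always compared against reference sites — forest with no
clearly visible human activity for decades — which carry the sentinel code
``REFERENCE`` and are not a management system.
"""

from __future__ import annotations

from dataclasses import dataclass

REFERENCE = "REFERENCE"

#: Valid taxonomic groups for abundance records.
TAXON_GROUPS = frozenset(
    {"insects", "birds", "mammals", "amphibians", "reptiles", "plants"}
)

#: Amphibians and reptiles are pooled for inference due to small samples.
HERPETOFAUNA = frozenset({"amphibians", "reptiles"})

ANIMAL_GROUPS = frozenset(
    {"insects", "birds", "mammals", "amphibians", "reptiles"}
)

#: IUCN Red List categories recognised in the threat-status column.
THREAT_CATEGORIES = frozenset({"LC", "NT", "VU", "EN", "CR", "EX"})

#: Categories counted as "threatened" (vulnerable to critically endangered).
THREATENED = frozenset({"VU", "EN", "CR"})

CONTINENTS = frozenset(
    {
        "Africa",
        "Asia",
        "Europe",
        "North America",
        "Oceania",
        "South America",
    }
)


@dataclass(frozen=True)
class ManagementSystem:
    """One of the seven forest management archetypes.

    Attributes
    ----------
    code:
        Two-letter system code used throughout tables and model output.
    production_focus:
        ``"wood"`` or ``"food"`` — systems are only ever contrasted within
        a focus set, never across.
    regeneration:
        How tree cover re-establishes after intervention.
    active_management:
        Whether continuous human intervention follows harvest/planting.
    label:
        Human-readable name.
    """

    code: str
    production_focus: str
    regeneration: str
    active_management: bool
    label: str


SYSTEMS: dict[str, ManagementSystem] = {
    s.code: s
    for s in (
        ManagementSystem("RI", "wood", "natural", False, "reduced-impact logging"),
        ManagementSystem("SC", "wood", "natural", False, "selective cutting"),
        ManagementSystem("CC", "wood", "natural", False, "clear cutting and regrowth"),
        ManagementSystem("PL", "wood", "planted", True, "forest plantation"),
        ManagementSystem("AG", "food", "mixed", True, "agroforest"),
        ManagementSystem("SP", "food", "mixed", True, "silvopasture"),
        ManagementSystem("PC", "food", "planted", True, "perennial tree crop plantation"),
    )
}

WOOD_SYSTEMS = ("RI", "SC", "CC", "PL")
FOOD_SYSTEMS = ("AG", "SP", "PC")
ALL_SYSTEMS = WOOD_SYSTEMS + FOOD_SYSTEMS


def systems_in_set(focus: str) -> tuple[str, ...]:
    """Return the system codes for a production-focus set (``wood``/``food``)."""
    if focus == "wood":
        return WOOD_SYSTEMS
    if focus == "food":
        return FOOD_SYSTEMS
    raise ValueError(f"unknown production focus: {focus!r}")
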