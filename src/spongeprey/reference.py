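"""Published study inputs: pooled prey counts and the 29-family universe.

The Shark Bay sponge-foraging field survey reported its pooled prey
abundance (both sampling modes, transects plus verification dives) as a
per-species table with swimbladder status.  Those printed counts are
reproduced here as input data: 134 prey extracted during sponging over
13.3 hours of diver effort, 85 encountered during non-sponging.

The resampling null universe combines the families extracted during
sponging with families from a long-term historical prey database to give
29 candidate families.  The historical portion of that list was published
only as supplementary material; the family names used here for it are a
SYNTHETIC stand-in — plausible Shark Bay prey families chosen so that the
universe has 29 members of which 9 lack swimbladders, which is consistent
with the study's reported resampling p-value.  Swimbladder counts, not the
stand-in names, drive every computation; the universe is always read from
an annotation table, never assumed.
"""

from __future__ import annotations

from .prey_data import (
    FamilyAnnotation,
    FamilyUniverse,
    PreyObservation,
)

__all__ = [
    "TABLE_ROWS",
    "SYNTHETIC_HISTORICAL_FAMILIES",
    "SPONGING_EFFORT_HOURS",
    "published_universe",
    "published_pooled_counts",
    "published_species_counts",
    "published_observations",
]

#: Diver sponging effort over which the 134 prey were extracted, in hours.
SPONGING_EFFORT_HOURS = 13.3

#: Pooled per-species counts: (common name, family, species or None,
#: sponging count, non-sponging count, has_swimbladder, verification_only).
#: ``verification_only`` marks families encountered only on verification
#: dives (all three during non-sponging).
TABLE_ROWS: tuple[tuple[str, str, str | None, int, int, bool, bool], ...] = (
    ("barred sandperch", "Pinguipedidae", "Parapercis nebulosa", 87, 15, False, False),
    ("sand lizardfish", "Synodontidae", "Synodus dermatogenys", 9, 0, False, False),
    ("cuttlefishes", "Sepiidae", None, 5, 0, False, False),
    ("stingrays", "Dasyatidae", None, 1, 1, False, False),
    ("lefteye flounders", "Bothidae", None, 1, 0, False, False),
    ("painted maskray", "Dasyatidae", "Neotrygon leylandi", 1, 0, False, False),
    ("tasselsnout flathead", "Platycephalidae", "Thysanophrys cirronasa", 1, 0, False, False),
    ("purple tuskfish", "Labridae", "Choerodon cephalotes", 23, 23, True, False),
    ("freckled goatfish", "Mullidae", "Upeneus tragula", 4, 0, True, False),
    ("wrasses", "Labridae", None, 2, 0, True, False),
    ("striped whiptail", "Nemipteridae", "Pentapodus vitta", 0, 29, True, False),
    ("margined coralfish", "Chaetodontidae", "Chelmon marginalis", 0, 6, True, True),
    ("blackspot tuskfish", "Labridae", "Choerodon schoenleinii", 0, 5, True, False),
    ("bluntheaded wrasse", "Labridae", "Thalassoma amblycephalum", 0, 2, True, False),
    ("humpback batfish", "Ephippidae", "Platax batavianus", 0, 2, True, True),
    ("yellowtail clownfish", "Pomacentridae", "Amphiprion clarkii", 0, 1, True, True),
    ("puffers", "Tetraodontidae", None, 0, 1, True, False),
)

#: SYNTHETIC stand-in for the historical portion of the candidate-family
#: universe (16 families; 3 without swimbladders bring the universe to 29
#: families with 9 swimbladderless).  Names are plausible regional prey
#: families; only the swimbladder tallies matter.
SYNTHETIC_HISTORICAL_FAMILIES: tuple[tuple[str, bool], ...] = (
    ("Gobiidae", False),
    ("Soleidae", False),
    ("Callionymidae", False),
    ("Sparidae", True),
    ("Sillaginidae", True),
    ("Terapontidae", True),
    ("Gerreidae", True),
    ("Clupeidae", True),
    ("Atherinidae", True),
    ("Belonidae", True),
    ("Hemiramphidae", True),
    ("Carangidae", True),
    ("Scombridae", True),
    ("Lethrinidae", True),
    ("Serranidae", True),
    ("Scorpaenidae", True),
)


def published_universe() -> FamilyUniverse:
    """The 29-family resampling universe (9 families lack swimbladders)."""
    universe = FamilyUniverse()
    for _, family, _, _, _, has_sb, _ in TABLE_ROWS:
        universe.add(FamilyAnnotation(family, has_sb, evidence="survey"))
    for family, has_sb in SYNTHETIC_HISTORICAL_FAMILIES:
        universe.add(FamilyAnnotation(family, has_sb, evidence="historical (synthetic stand-in)"))
    return universe


def published_pooled_counts() -> dict[tuple[str, str], int]:
    """Family-level pooled counts per (family, mode), all dives."""
    pooled: dict[tuple[str, str], int] = {}
    for _, family, _, spong, non, _, _ in TABLE_ROWS:
        pooled[(family, "sponging")] = pooled.get((family, "sponging"), 0) + spong
        pooled[(family, "non_sponging")] = pooled.get((family, "non_sponging"), 0) + non
    return pooled


def published_species_counts() -> dict[tuple[str, str], int]:
    """Per-row pooled counts keyed by (species-or-common-name, mode)."""
    counts: dict[tuple[str, str], int] = {}
    for common, _, species, spong, non, _, _ in TABLE_ROWS:
        name = species or common
        counts[(name, "sponging")] = spong
        counts[(name, "non_sponging")] = non
    return counts


def published_observations() -> list[PreyObservation]:
    """Expand the pooled counts into one observation per prey encounter.

    The pooled table does not record which dive each encounter came from,
    so the expansion assigns dives deterministically: families reported only
    from verification dives go to verification sites; purple tuskfish
    sponging encounters split 6 transect / 17 verification (74% from
    verification, as reported); everything else is spread round-robin over
    the seven transects, replicate 1.  Any pooling over all dives therefore
    reproduces the published counts exactly.
    """
    transect_ids = [f"T{i}" for i in range(1, 8)]
    obs: list[PreyObservation] = []

    def add(family, species, mode, count, site_kind, start=0):
        for j in range(count):
            if site_kind == "transect":
                tid = transect_ids[(start + j) % len(transect_ids)]
                dive = f"{tid}-{mode}-r1"
            else:
                tid = None
                dive = f"V{(start + j) % 6 + 1}-{mode}"
            length = 12.6 if species == "Parapercis nebulosa" else 10.0
            obs.append(
                PreyObservation(
                    dive_id=dive,
                    site_kind=site_kind,
                    transect_id=tid,
                    replicate=1,
                    mode=mode,
                    family=family,
                    species=species,
                    length_cm=length,
                    identified=True,
                )
            )

    for idx, (common, family, species, spong, non, _, verif_only) in enumerate(TABLE_ROWS):
        if common == "purple tuskfish":
            add(family, species, "sponging", 6, "transect", start=idx)
            add(family, species, "sponging", 17, "verification", start=idx)
            add(family, species, "non_sponging", non, "transect", start=idx)
            continue
        kind = "verification" if verif_only else "transect"
        add(family, species, "sponging", spong, kind, start=idx)
        add(family, species, "non_sponging", non, kind, start=idx)
    return obs
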