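"""Five-trait functional profiles and functional-entity (FE) registry.

Each ZOTU receives five qualitative traits — activity, schooling,
position in the water column, diet, body shape — from a species-keyed
trait table.  Genus- and family-rank ZOTUs are imputed with the most
prevalent value per trait among the species of their taxon; ZOTUs
assigned above family are excluded from functional analyses.  Remaining
gaps are filled from a supplementary table (a local stand-in for
database lookups).  Every complete trait vector maps to a functional
entity: a unique combination of trait values, the categorical unit of
functional diversity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mesofish.io import TRAIT_NAMES, ValidationError

log = logging.getLogger("mesofish")

#: Closed trait vocabularies (category spellings follow field usage for
#: reef-fish functional databases).
TRAIT_VOCABULARY: dict[str, tuple[str, ...]] = {
    "activity": ("diurnal", "nocturnal", "both"),
    "schooling": ("solitary", "pairing", "[3; 20]", "[20; 50]", ">50"),
    "position": ("benthic", "pelagic", "bentho-pelagic", "bathypelagic"),
    "diet": ("piscivorous", "planktivorous", "invertivorous mobile inv.",
             "herbivorous-detritivorous", "macroalgal herbivorous"),
    "body_shape": ("eel-like", "elongated", "fusiform/normal",
                   "short and/or deep"),
}


@dataclass
class TraitProfile:
    zotu_id: str
    values: dict[str, str]
    provenance: str               # species | imputed-genus | imputed-family |
    flags: set[str] = field(default_factory=set)   # supplemented | ambiguous

    @property
    def complete(self) -> bool:
        return all(not pd.isna(self.values.get(t)) for t in TRAIT_NAMES)

    def vector(self) -> tuple[str, ...]:
        return tuple(self.values[t] for t in TRAIT_NAMES)


@dataclass
class FunctionalEntity:
    fe_id: str
    traits: tuple[str, ...]
    members: list[str]


def _validate_values(values: Mapping[str, str], source: str) -> None:
    for trait in TRAIT_NAMES:
        v = values.get(trait)
        if v is not None and not pd.isna(v) and \
                v not in TRAIT_VOCABULARY[trait]:
            raise ValidationError(
                f"out-of-vocabulary {trait} value {v!r} in {source}")


def _mode_with_tiebreak(series: pd.Series) -> tuple[str | None, bool]:
    """Most prevalent non-missing value.

    Ties resolve to the value held by the lexicographically smallest
    species (index) among the tied values; returns (value, ambiguous).
    """
    clean = series.dropna()
    if clean.empty:
        return None, False
    counts = clean.value_counts()
    top = counts.max()
    tied = sorted(counts.index[counts == top])
    if len(tied) == 1:
        return tied[0], False
    first_holder = {v: min(clean.index[clean == v]) for v in tied}
    winner = min(tied, key=lambda v: (first_holder[v], v))
    return winner, True


def assign_traits(assignments: Mapping[str, "object"],
                  trait_table: pd.DataFrame,
                  taxonomy: pd.DataFrame | None = None,
                  supplement: pd.DataFrame | None = None
                  ) -> dict[str, TraitProfile]:
    """Per-ZOTU trait vectors with rank-aware imputation and provenance.

    ``assignments`` maps zotu id to an Assignment (needs ``rank`` and
    ``lineage_name``).  ``trait_table`` is keyed by species; ``taxonomy``
    (species -> genus/family), derived from the trait table's index when
    the species names encode it, widens the pool used for genus/family
    consensus.  ``supplement`` (same layout as the trait table, keyed by
    species, genus or family name) fills remaining gaps.  ZOTUs assigned
    above family, or still incomplete, are excluded with a log line.
    """
    if supplement is not None:
        for taxon, row in supplement.iterrows():
            _validate_values(row.to_dict(), f"supplement row {taxon!r}")

    # species -> genus/family lookup for consensus pools
    def taxon_pool(rank: str, name: str) -> pd.DataFrame:
        if taxonomy is not None and rank in taxonomy.columns:
            members = taxonomy.index[taxonomy[rank] == name]
            return trait_table.loc[trait_table.index.intersection(members)]
        return trait_table.iloc[0:0]

    profiles: dict[str, TraitProfile] = {}
    for zid, a in assignments.items():
        rank = a.rank
        if rank not in ("species", "genus", "family"):
            log.info("ZOTU %s assigned at %s; excluded from functional "
                     "analyses", zid, rank)
            continue
        values: dict[str, str | float] = {t: np.nan for t in TRAIT_NAMES}
        flags: set[str] = set()
        if rank == "species":
            provenance = "species"
            sp = a.lineage_name("species")
            if sp in trait_table.index:
                values.update(trait_table.loc[sp].to_dict())
        else:
            provenance = f"imputed-{rank}"
            pool = taxon_pool(rank, a.lineage_name(rank))
            for trait in TRAIT_NAMES:
                if len(pool):
                    v, ambiguous = _mode_with_tiebreak(pool[trait])
                    if v is not None:
                        values[trait] = v
                    if ambiguous:
                        flags.add("ambiguous")
        if supplement is not None:
            for level in ("species", "genus", "family"):
                key = a.lineage_name(level)
                if key is not None and key in supplement.index:
                    for trait in TRAIT_NAMES:
                        if pd.isna(values[trait]) and \
                                not pd.isna(supplement.loc[key, trait]):
                            values[trait] = supplement.loc[key, trait]
                            flags.add("supplemented")
        profile = TraitProfile(zid, values, provenance, flags)
        if not profile.complete:
            log.info("ZOTU %s has incomplete traits after imputation; "
                     "excluded", zid)
            continue
        _validate_values(profile.values, f"profile for {zid}")
        profiles[zid] = profile
    return profiles


def build_fe_registry(profiles: Mapping[str, TraitProfile],
                      traits: Sequence[str] = TRAIT_NAMES
                      ) -> list[FunctionalEntity]:
    """Enumerate unique trait combinations in first-appearance order.

    ``traits`` may be a subset (the trait-removal sensitivity analysis
    rebuilds the registry on four traits, which can only merge FEs).
    """
    registry: dict[tuple, FunctionalEntity] = {}
    for zid, profile in profiles.items():
        key = tuple(profile.values[t] for t in traits)
        if key not in registry:
            registry[key] = FunctionalEntity(f"FE_{len(registry) + 1}", key,
                                             [])
        registry[key].members.append(zid)
    return list(registry.values())


def fe_map(registry: Sequence[FunctionalEntity]) -> dict[str, str]:
    """zotu id -> FE id mapping from a registry."""
    return {zid: fe.fe_id for fe in registry for zid in fe.members}


def registry_frame(registry: Sequence[FunctionalEntity]) -> pd.DataFrame:
    rows = []
    for fe in registry:
        row = {"fe_id": fe.fe_id}
        row.update({t: v for t, v in zip(TRAIT_NAMES, fe.traits)})
        row["member_count"] = len(fe.members)
        row["members"] = ",".join(fe.members)
        rows.append(row)
    return pd.DataFrame(rows)
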