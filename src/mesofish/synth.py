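"""Seeded generator for two-island eDNA metabarcoding study data.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* a reference library whose pairwise divergences follow a *barcoding
  ladder* — conspecific amplicons differ by ~``intra_species_max``
  substitutions per site while congeneric, confamilial and interfamily
  pairs are separated by guaranteed minima, so a barcoding gap exists by
  construction;
* two island communities of 10 + 8 samples sharing a core of families,
  with island-exclusive families providing turnover and planted indicator
  families honouring configurable specificity (A*) and sensitivity (B*)
  in expectation;
* species trait tables with row-level missingness, forcing rank-aware
  imputation downstream;
* station environment tables with an adjustable island effect on habitat.

Inter-tier minima are enforced deterministically by mutating
sibling-disjoint site sets; the intra-species tier is a substitution
*rate* (per-variant-branch count ~ Binomial(L, intra_species_max/2)), so
conspecific variants differ by ~1 bp on a MiFish-length amplicon, exactly
the regime in which a 0.6 %-scale clustering threshold is recovered.

Every operation draws from its own RNG stream seeded by
``(config.seed, operation name)``: adding an operation never perturbs
another's output.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from math import ceil, log
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mesofish.io import RANKS, SequenceRecord, ZotuTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """The synthetic configuration is internally inconsistent."""


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class IndicatorSpec:
    """A family planted to indicate one island.

    ``specificity`` (A*) is the group-equalized share of mean cumulative
    occurrence on the target island; ``sensitivity`` (B*) the per-sample
    occurrence probability there.
    """

    target: str
    island: str
    specificity: float
    sensitivity: float


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_families: int = 10
    genera_per_family: int = 2
    species_per_genus: int = 2
    variants_per_species: int = 2
    amplicon_length: int = 170
    # divergence ladder, substitutions per site
    intra_species_max: float = 0.004
    congeneric_min: float = 0.02
    confamilial_min: float = 0.06
    interfamily_min: float = 0.10
    # community design
    island_names: tuple[str, str] = ("island_a", "island_b")
    n_samples_per_island: tuple[int, int] = (10, 8)
    core_family_fraction: float = 0.6
    island_exclusive_family_count: int | None = None
    indicators: tuple[IndicatorSpec, ...] | None = None
    occupancy_baseline: float = 0.5
    species_given_family: float = 0.6
    # reads
    read_depth_meanlog: float = log(50_000.0)
    read_depth_sdlog: float = 0.3
    dirichlet_alpha: float = 1.0
    # traits / environment
    trait_missingness: float = 0.2
    env_island_effect: float = 1.0

    def __post_init__(self):
        ladder = (self.intra_species_max, self.congeneric_min,
                  self.confamilial_min, self.interfamily_min)
        if not all(b > a for a, b in zip(ladder, ladder[1:])):
            raise ConfigError(f"divergence ladder must increase: {ladder}")
        if self.intra_species_max < 0:
            raise ConfigError("intra_species_max must be >= 0")
        for name in ("n_families", "genera_per_family", "species_per_genus",
                     "variants_per_species", "amplicon_length"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("occupancy_baseline", "species_given_family",
                     "core_family_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not 0 <= self.trait_missingness < 1:
            raise ConfigError("trait_missingness must lie in [0, 1)")
        if any(n < 1 for n in self.n_samples_per_island):
            raise ConfigError("need at least one sample per island")
        L = self.amplicon_length
        for lo, hi, what in (
            (self.intra_species_max, self.congeneric_min, "intra/congeneric"),
            (self.congeneric_min, self.confamilial_min, "congeneric/confamilial"),
            (self.confamilial_min, self.interfamily_min, "confamilial/interfamily"),
        ):
            if (hi - lo) * L < 1:
                raise ConfigError(
                    f"ladder infeasible for amplicon_length={L}: expected "
                    f"substitutions between {what} tiers below 1"
                )
        if sum(self._site_budget()) > L:
            raise ConfigError(
                f"amplicon_length={L} too short for the requested taxonomy "
                f"(needs {sum(self._site_budget())} reserved sites)"
            )

    # per-branch substitution counts guaranteeing the inter-tier minima
    @property
    def m_family(self) -> int:
        return ceil(self.amplicon_length * self.interfamily_min / 2)

    @property
    def m_genus(self) -> int:
        return ceil(self.amplicon_length * self.confamilial_min / 2)

    @property
    def m_species(self) -> int:
        return ceil(self.amplicon_length * self.congeneric_min / 2)

    def _site_budget(self) -> tuple[int, int, int, int]:
        return (
            self.n_families * self.m_family,
            self.genera_per_family * self.m_genus,
            self.species_per_genus * self.m_species,
            self.variants_per_species,  # at least one free site per variant
        )

    def exclusive_per_island(self) -> int:
        if self.island_exclusive_family_count is not None:
            return self.island_exclusive_family_count
        return int(round(self.n_families * (1 - self.core_family_fraction) / 2))


@dataclass
class SynthTruth:
    """Ground truth the generator commits to; the oracle for every test."""

    seed: int
    config: SynthConfig
    species: list[str]
    species_to_cluster: dict[str, int]
    variant_to_species: dict[str, str]
    sequences: dict[str, str]                     # variant id -> sequence
    taxonomy: pd.DataFrame                        # per variant id, rank columns
    family_occupancy: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_indicators: list[IndicatorSpec] = field(default_factory=list)
    zotu_to_variant: dict[str, str] = field(default_factory=dict)
    zotu_to_species: dict[str, str] = field(default_factory=dict)
    trait_table_full: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Reference library
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator
            ) -> np.ndarray:
    out = seq.copy()
    if len(sites):
        shift = rng.integers(1, 4, size=len(sites))
        out[sites] = (out[sites] + shift) % 4
    return out


def _decode(seq: np.ndarray) -> str:
    return bytes(_BASES[seq]).decode()


def generate_reference_library(config: SynthConfig
                               ) -> tuple[list[SequenceRecord], pd.DataFrame,
                                          SynthTruth]:
    """Simulate a taxonomy-shaped reference library with a barcoding gap.

    Returns the sequence records (one per species variant), a rank-labelled
    taxonomy table indexed by sequence id, and the ground truth.
    """
    rng = _rng(config.seed, "reference")
    L = config.amplicon_length
    root = rng.integers(0, 4, size=L)

    site_order = rng.permutation(L)
    nf, mg, ms = (config.n_families * config.m_family,
                  config.genera_per_family * config.m_genus,
                  config.species_per_genus * config.m_species)
    fam_pool = site_order[:nf]
    gen_pool = site_order[nf:nf + mg]
    spe_pool = site_order[nf + mg:nf + mg + ms]
    var_pool = site_order[nf + mg + ms:]
    max_var_sites = len(var_pool) // config.variants_per_species

    records: list[SequenceRecord] = []
    tax_rows: list[dict] = []
    species_names: list[str] = []
    variant_to_species: dict[str, str] = {}
    sequences: dict[str, str] = {}

    n_orders = max(1, config.n_families // 3)
    for fi in range(config.n_families):
        fam = f"Fam{fi + 1:02d}"
        order = f"Order{fi % n_orders + 1}"
        fam_sites = fam_pool[fi * config.m_family:(fi + 1) * config.m_family]
        fam_seq = _mutate(root, fam_sites, rng)
        for gi in range(config.genera_per_family):
            genus = f"{fam}-G{gi + 1}"
            gen_sites = gen_pool[gi * config.m_genus:(gi + 1) * config.m_genus]
            gen_seq = _mutate(fam_seq, gen_sites, rng)
            for si in range(config.species_per_genus):
                species = f"{genus}-sp{si + 1}"
                species_names.append(species)
                spe_sites = spe_pool[si * config.m_species:
                                     (si + 1) * config.m_species]
                spe_seq = _mutate(gen_seq, spe_sites, rng)
                # sibling variant branches draw disjoint sites from the
                # variant pool; counts are Binomial(L, intra_max / 2),
                # capped at m_species - 1 so conspecific divergence can
                # never reach the congeneric floor (no ladder overlap)
                cap = min(max_var_sites, max(config.m_species - 1, 0))
                counts = np.minimum(
                    rng.binomial(L, config.intra_species_max / 2,
                                 size=config.variants_per_species),
                    cap,
                )
                chosen = rng.choice(var_pool, size=int(counts.sum()),
                                    replace=False)
                offset = 0
                for vi in range(config.variants_per_species):
                    v_sites = chosen[offset:offset + counts[vi]]
                    offset += counts[vi]
                    var_seq = _mutate(spe_seq, v_sites, rng)
                    vid = f"{species}-v{vi + 1}"
                    records.append(SequenceRecord(vid, _decode(var_seq)))
                    sequences[vid] = _decode(var_seq)
                    variant_to_species[vid] = species
                    tax_rows.append({
                        "id": vid, "class": "Actinopteri", "order": order,
                        "family": fam, "genus": genus, "species": species,
                    })

    taxonomy = pd.DataFrame(tax_rows).set_index("id")
    truth = SynthTruth(
        seed=config.seed,
        config=config,
        species=species_names,
        species_to_cluster={s: i for i, s in enumerate(species_names)},
        variant_to_species=variant_to_species,
        sequences=sequences,
        taxonomy=taxonomy,
    )
    return records, taxonomy, truth


# ---------------------------------------------------------------------------
# Two-island communities
# ---------------------------------------------------------------------------

def _family_roles(config: SynthConfig, truth: SynthTruth):
    families = sorted({s.rsplit("-", 2)[0] for s in truth.species})
    k = config.exclusive_per_island()
    if 2 * k > len(families):
        raise ConfigError("more island-exclusive families than families")
    core = families[: len(families) - 2 * k]
    excl_a = families[len(families) - 2 * k: len(families) - k]
    excl_b = families[len(families) - k:]
    indicators = config.indicators
    if indicators is None:
        # default study conditions: one planted indicator per island at the
        # reference effect size A* = 0.8, B* = 0.7
        indicators = []
        if len(core) >= 2:
            indicators = [
                IndicatorSpec(core[0], config.island_names[0], 0.8, 0.7),
                IndicatorSpec(core[1], config.island_names[1], 0.8, 0.7),
            ]
        indicators = tuple(indicators)
    for spec in indicators:
        if spec.target not in families:
            raise ConfigError(f"indicator references unknown family "
                              f"{spec.target!r}")
        if spec.island not in config.island_names:
            raise ConfigError(f"indicator references unknown island "
                              f"{spec.island!r}")
        if not 0 < spec.specificity <= 1 or not 0 <= spec.sensitivity <= 1:
            raise ConfigError("indicator A* must lie in (0, 1], B* in [0, 1]")
        off = spec.sensitivity * (1 - spec.specificity) / spec.specificity
        if off > 1:
            raise ConfigError(
                f"indicator ({spec.target}) implies off-island occupancy "
                f"{off:.2f} > 1"
            )
    return families, core, excl_a, excl_b, indicators


def _occupancy(config: SynthConfig, truth: SynthTruth
               ) -> tuple[dict[tuple[str, str], float], list[IndicatorSpec]]:
    families, core, excl_a, excl_b, indicators = _family_roles(config, truth)
    isl_a, isl_b = config.island_names
    occ: dict[tuple[str, str], float] = {}
    for fam in families:
        for isl in config.island_names:
            occ[(fam, isl)] = config.occupancy_baseline
    for fam in excl_a:
        occ[(fam, isl_b)] = 0.0
    for fam in excl_b:
        occ[(fam, isl_a)] = 0.0
    for spec in indicators:
        other = isl_b if spec.island == isl_a else isl_a
        occ[(spec.target, spec.island)] = spec.sensitivity
        occ[(spec.target, other)] = (
            spec.sensitivity * (1 - spec.specificity) / spec.specificity
        )
    return occ, list(indicators)


def generate_community(config: SynthConfig, truth: SynthTruth
                       ) -> tuple[dict[str, ZotuTable], dict[str, str]]:
    """Draw per-island ZOTU-by-sample read-count tables.

    Family presence per sample follows island-specific occupancy (planted
    indicators included); given family presence, species are drawn with at
    least one present; all variants of a present species are detected.
    Reads for present ZOTUs follow a Dirichlet-multinomial over the
    sample's log-normal depth.  ZOTUs shared between islands carry one id
    per island, as in real two-island ZOTU tables.
    """
    rng = _rng(config.seed, "community")
    occ, indicators = _occupancy(config, truth)
    truth.family_occupancy = occ
    truth.planted_indicators = indicators
    truth.zotu_to_variant = {}
    truth.zotu_to_species = {}

    species_by_family: dict[str, list[str]] = {}
    for sp in truth.species:
        species_by_family.setdefault(sp.rsplit("-", 2)[0], []).append(sp)
    variants_by_species: dict[str, list[str]] = {}
    for vid, sp in truth.variant_to_species.items():
        variants_by_species.setdefault(sp, []).append(vid)

    tables: dict[str, ZotuTable] = {}
    sample_to_island: dict[str, str] = {}
    for k, (isl, n_samples) in enumerate(
            zip(config.island_names, config.n_samples_per_island)):
        prefix = chr(ord("A") + k)
        sample_ids = [f"{prefix}{i + 1:02d}" for i in range(n_samples)]
        for s in sample_ids:
            sample_to_island[s] = isl
        all_variants = [v for sp in truth.species
                        for v in variants_by_species[sp]]
        presence = pd.DataFrame(False, index=all_variants, columns=sample_ids)
        for s in sample_ids:
            for fam, fam_species in species_by_family.items():
                if rng.random() >= occ[(fam, isl)]:
                    continue
                sp_present = rng.random(len(fam_species)) < \
                    config.species_given_family
                if not sp_present.any():
                    sp_present[rng.integers(len(fam_species))] = True
                for sp, here in zip(fam_species, sp_present):
                    if here:
                        presence.loc[variants_by_species[sp], s] = True
        counts = pd.DataFrame(0, index=all_variants, columns=sample_ids,
                              dtype=np.int64)
        for s in sample_ids:
            present = presence.index[presence[s]].tolist()
            if not present:
                continue
            depth = int(max(
                len(present),
                round(rng.lognormal(config.read_depth_meanlog,
                                    config.read_depth_sdlog)),
            ))
            p = rng.dirichlet(np.full(len(present), config.dirichlet_alpha))
            reads = rng.multinomial(depth - len(present), p) + 1
            counts.loc[present, s] = reads
        detected = counts.sum(axis=1) > 0
        island_counts = counts.loc[detected]
        zotu_ids = [f"{prefix}Z{i + 1:04d}"
                    for i in range(island_counts.shape[0])]
        for zid, vid in zip(zotu_ids, island_counts.index):
            truth.zotu_to_variant[zid] = vid
            truth.zotu_to_species[zid] = truth.variant_to_species[vid]
        island_counts = island_counts.set_axis(zotu_ids, axis=0)
        tables[isl] = ZotuTable(island_counts, mode="counts")
    return tables, sample_to_island


def community_sequences(truth: SynthTruth, table: ZotuTable
                        ) -> list[SequenceRecord]:
    """FASTA records for one island's ZOTUs (per-island ids)."""
    return [SequenceRecord(z, truth.sequences[truth.zotu_to_variant[z]])
            for z in table.zotu_ids]


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def generate_traits(truth: SynthTruth, missingness: float | None = None
                    ) -> pd.DataFrame:
    """Species-level trait table with row-level missingness.

    Trait values are phylogenetically structured (family base vector,
    perturbed per genus and per species) so that genus/family consensus
    imputation downstream is usually correct.  A fraction ``missingness``
    of species rows is fully masked; the unmasked table is kept on
    ``truth.trait_table_full``.
    """
    from mesofish.traits import TRAIT_VOCABULARY

    config = truth.config
    if missingness is None:
        missingness = config.trait_missingness
    if not 0 <= missingness < 1:
        raise ConfigError("missingness must lie in [0, 1)")
    rng = _rng(truth.seed, "traits")

    def draw(vocab):
        return vocab[rng.integers(len(vocab))]

    rows = {}
    fam_base: dict[str, dict] = {}
    gen_base: dict[str, dict] = {}
    for sp in truth.species:
        genus = sp.rsplit("-", 1)[0]
        fam = sp.rsplit("-", 2)[0]
        if fam not in fam_base:
            fam_base[fam] = {t: draw(v) for t, v in TRAIT_VOCABULARY.items()}
        if genus not in gen_base:
            gen_base[genus] = {
                t: (draw(v) if rng.random() < 0.2 else fam_base[fam][t])
                for t, v in TRAIT_VOCABULARY.items()
            }
        rows[sp] = {
            t: (draw(v) if rng.random() < 0.1 else gen_base[genus][t])
            for t, v in TRAIT_VOCABULARY.items()
        }
    full = pd.DataFrame.from_dict(rows, orient="index")
    full.index.name = "taxon"
    truth.trait_table_full = full

    # row-level masking that never masks the last unmasked species of a
    # genus (keeps genus-consensus imputation well-posed downstream)
    masked = full.copy()
    n_mask = int(np.floor(missingness * len(masked)))
    genus_of = {sp: sp.rsplit("-", 1)[0] for sp in full.index}
    unmasked_per_genus: dict[str, int] = {}
    for sp, g in genus_of.items():
        unmasked_per_genus[g] = unmasked_per_genus.get(g, 0) + 1
    chosen: list[str] = []
    for i in rng.permutation(len(full)):
        if len(chosen) == n_mask:
            break
        sp = full.index[i]
        g = genus_of[sp]
        if unmasked_per_genus[g] <= 1 and truth.config.species_per_genus >= 2:
            continue
        unmasked_per_genus[g] -= 1
        chosen.append(sp)
    masked.loc[chosen] = np.nan
    return masked


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

_ENV_LEVELS = {
    "slope": ("low", "medium", "high"),
    "rugosity": ("low", "medium", "high"),
    "dominant": ("coral", "meso_community", "mud", "sand"),
}
# island-skew probabilities at full effect; rows sum to 1
_ENV_SKEW = {
    "slope": ((0.1, 0.3, 0.6), (0.6, 0.3, 0.1)),
    "rugosity": ((0.1, 0.3, 0.6), (0.6, 0.3, 0.1)),
    "dominant": ((0.55, 0.25, 0.1, 0.1), (0.1, 0.2, 0.5, 0.2)),
}
_DEPTH_WINDOWS = ((68.0, 89.0), (80.0, 107.0))  # full-effect island windows
_DEPTH_RANGE = (68.0, 107.0)


def generate_environment(config: SynthConfig) -> pd.DataFrame:
    """Station table: depth, distance to coast and habitat categoricals.

    With ``env_island_effect=1`` the first island skews to steep, rugose,
    coral-dominated stations and the second to flat muddy ones; at 0 the
    two islands are drawn from a common distribution (the null used for
    permutation-test calibration).
    """
    rng = _rng(config.seed, "environment")
    e = float(np.clip(config.env_island_effect, 0.0, 1.0))
    rows = []
    for k, (isl, n_samples) in enumerate(
            zip(config.island_names, config.n_samples_per_island)):
        prefix = chr(ord("A") + k)
        lo, hi = _DEPTH_WINDOWS[k]
        lo = _DEPTH_RANGE[0] + e * (lo - _DEPTH_RANGE[0])
        hi = _DEPTH_RANGE[1] + e * (hi - _DEPTH_RANGE[1])
        for i in range(n_samples):
            row = {
                "station_id": f"{prefix}{i + 1:02d}",
                "island": isl,
                "depth": float(np.clip(rng.uniform(lo, hi), *_DEPTH_RANGE)),
                "distance_to_coast": float(
                    rng.lognormal(log(1500.0) + 0.4 * e * (1 - k), 0.4)
                ),
            }
            for var, levels in _ENV_LEVELS.items():
                skew = np.asarray(_ENV_SKEW[var][k])
                uniform = np.full(len(levels), 1 / len(levels))
                p = e * skew + (1 - e) * uniform
                row[var] = levels[rng.choice(len(levels), p=p / p.sum())]
            rows.append(row)
    return pd.DataFrame(rows).set_index("station_id")


# ---------------------------------------------------------------------------
# Reference hits and truth serialization (plumbing)
# ---------------------------------------------------------------------------

def generate_hits(truth: SynthTruth, table: ZotuTable, n_best: int = 10,
                  reference_ids: Sequence[str] | None = None):
    """Reference-hit records for one island's ZOTUs against the library.

    Identity is 100 x (1 - Hamming/length) against each reference variant;
    coverage is 100 and the e-value a fixed strong 1e-50 (the generator
    emulates curated full-length matches, not a search engine).
    """
    from mesofish.io import HitRecord

    ref_ids = list(reference_ids) if reference_ids is not None \
        else list(truth.variant_to_species)
    ref_seqs = np.array([np.frombuffer(truth.sequences[r].encode(), np.uint8)
                         for r in ref_ids])
    hits: dict[str, list[HitRecord]] = {}
    for zid in table.zotu_ids:
        q = np.frombuffer(truth.sequences[truth.zotu_to_variant[zid]].encode(),
                          np.uint8)
        dists = (ref_seqs != q).sum(axis=1)
        order = np.argsort(dists, kind="stable")[:n_best]
        recs = []
        for j in order:
            rid = ref_ids[j]
            lineage = {r: truth.taxonomy.loc[rid, r] for r in RANKS}
            recs.append(HitRecord(
                query_id=zid, subject_id=rid,
                identity=100.0 * (1 - dists[j] / len(q)),
                query_coverage=100.0, evalue=1e-50, lineage=lineage,
            ))
        hits[zid] = recs
    return hits


def write_truth(truth: SynthTruth, path) -> None:
    """Persist the ZOTU-level ground truth as TSV for test harnesses."""
    rows = []
    for zid, vid in truth.zotu_to_variant.items():
        sp = truth.variant_to_species[vid]
        rows.append({
            "zotu_id": zid,
            "variant_id": vid,
            "species": sp,
            "cluster": truth.species_to_cluster[sp],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
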