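"""End-to-end orchestration of the two-island community analysis.

``run_all`` executes the stages in dependency order from a single config:
abundance filtering, tiered + phylogenetic taxonomic assignment, taxon
exclusion, barcoding-gap threshold optimization and complete-linkage
clustering, trait/FE construction, Hill-number curves per island,
beta-diversity statistics (NMDS, PERMANOVA, dispersion), indicator
analysis, the environment ordination, and the sensitivity suite
(family exclusion and trait removal).  Every output lands in the run
directory with a manifest of parameters, seeds and content hashes;
re-running the same config is bit-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from mesofish import (clustering, filtering, hill, indicators, io, stats,
                      taxonomy, traits)

log = logging.getLogger("mesofish")


@dataclass
class RunConfig:
    seed: int = 0
    islands: dict[str, dict[str, str]] = field(default_factory=dict)
    hits: str | None = None
    reference_fasta: str | None = None
    reference_taxonomy: str | None = None
    trait_table: str | None = None
    supplement_table: str | None = None
    environment: str | None = None
    occurrence_list: str | None = None
    blocklist: dict[str, list[str]] = field(default_factory=dict)
    filter_rate: float = 0.00025
    gates: dict[str, float] = field(
        default_factory=lambda: dict(taxonomy.DEFAULT_GATES))
    tiers: dict[str, float] = field(
        default_factory=lambda: dict(taxonomy.DEFAULT_TIERS))
    phylo_families: list[str] = field(default_factory=list)
    bootstrap_replicates: int = 100
    threshold_grid: dict[str, float] | None = None
    cluster_threshold: float | None = None
    diversity_orders: list[int] = field(default_factory=lambda: [0, 1, 2])
    beta_indices: list[str] = field(
        default_factory=lambda: ["jaccard", "bray_curtis"])
    n_perm: int = 999
    nmds_restarts: int = 20
    sensitivity_exclude_families: list[str] = field(default_factory=list)
    sensitivity_drop_traits: list[str] = field(
        default_factory=lambda: list(io.TRAIT_NAMES))

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise io.ValidationError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if not self.islands:
            raise io.ValidationError("config names no island inputs")
        paths = [self.hits, self.reference_fasta, self.reference_taxonomy,
                 self.trait_table, self.supplement_table, self.environment,
                 self.occurrence_list]
        for isl, spec in self.islands.items():
            for key in ("zotu_table", "zotu_fasta"):
                if key not in spec:
                    raise io.ValidationError(f"island {isl!r} lacks {key}")
                paths.append(spec[key])
        for p in paths:
            if p is not None and not Path(p).exists():
                raise io.ValidationError(f"input file missing: {p}")

    def grid(self) -> np.ndarray | None:
        if self.threshold_grid is None:
            return None
        g = self.threshold_grid
        return np.round(np.arange(g["start"], g["stop"] + g["step"] / 2,
                                  g["step"]), 10)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _assignment_frame(assigns: Mapping[str, taxonomy.Assignment]
                      ) -> pd.DataFrame:
    rows = []
    for zid, a in assigns.items():
        row = {"zotu_id": zid, "taxon": a.taxon or "", "rank": a.rank,
               "method": a.method, "flags": ",".join(sorted(a.flags))}
        for r in io.RANKS:
            row[r] = a.lineage.get(r, "")
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "inputs": {}, "outputs": {}, "stages": [], "results": {},
    }

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append(name)

    def record(path: Path):
        manifest["outputs"][path.name] = _sha256(path)

    # ---------------- load + filter ----------------
    stage("load")
    tables: dict[str, io.ZotuTable] = {}
    seqs: dict[str, list[io.SequenceRecord]] = {}
    grouping: dict[str, str] = {}
    for isl, spec in config.islands.items():
        manifest["inputs"][spec["zotu_table"]] = _sha256(Path(spec["zotu_table"]))
        manifest["inputs"][spec["zotu_fasta"]] = _sha256(Path(spec["zotu_fasta"]))
        tables[isl] = io.read_zotu_table(spec["zotu_table"], mode="counts")
        seqs[isl] = io.read_fasta(spec["zotu_fasta"])
        for s in tables[isl].sample_ids:
            grouping[s] = isl

    stage("abundance_filter")
    for isl in list(tables):
        tables[isl], report = filtering.abundance_filter(
            tables[isl], rate=config.filter_rate)
        path = outdir / f"filter_report_{isl}.tsv"
        _write(report.to_frame(), path)
        record(path)

    # ---------------- assignment ----------------
    stage("taxonomic_assignment")
    hits = io.read_hit_table(config.hits) if config.hits else {}
    occurrence = None
    if config.occurrence_list:
        occurrence = [ln.strip() for ln in
                      Path(config.occurrence_list).read_text().splitlines()
                      if ln.strip()]
    ref_seqs = {r.id: r for r in io.read_fasta(config.reference_fasta)} \
        if config.reference_fasta else {}
    automatic: dict[str, taxonomy.Assignment] = {}
    for isl in tables:
        for zid in tables[isl].zotu_ids:
            if zid in hits:
                a = taxonomy.tiered_assign(hits[zid], config.gates,
                                           config.tiers)
            else:
                a = taxonomy.Assignment(zid, None, "unassigned")
            if occurrence is not None:
                a = taxonomy.region_validate(a, occurrence)
            automatic[zid] = a

    final: dict[str, taxonomy.Assignment] = dict(automatic)
    if config.phylo_families:
        zotu_seq = {r.id: r for isl in seqs for r in seqs[isl]}
        by_family: dict[str, list[str]] = {}
        for zid, a in automatic.items():
            fam = a.lineage_name("family")
            if fam in config.phylo_families and zid in zotu_seq:
                by_family.setdefault(fam, []).append(zid)
        for fi, (fam, zids) in enumerate(sorted(by_family.items())):
            gated = {zid: taxonomy.gate_hits(hits.get(zid, []), config.gates)
                     for zid in zids}
            ref_ids, lineages = [], {}
            for zid in zids:
                ranked = sorted(gated[zid],
                                key=lambda h: (h.evalue, -h.identity))[:10]
                for h in ranked:
                    if h.subject_id in ref_seqs and h.subject_id not in lineages:
                        ref_ids.append(h.subject_id)
                        lineages[h.subject_id] = dict(h.lineage)
            leaves = [zotu_seq[z] for z in zids] + \
                     [ref_seqs[r] for r in ref_ids]
            if len(leaves) < 3 or not ref_ids:
                continue
            aligned = taxonomy.center_star_align(leaves)
            tree = taxonomy.bootstrap_support(
                aligned, replicates=config.bootstrap_replicates,
                seed=config.seed + 1000 + fi)
            tree_path = outdir / f"tree_{fam}.nwk"
            tree_path.write_text(io.write_newick(tree) + "\n")
            record(tree_path)
            for zid in zids:
                phylo = taxonomy.mrca_assign(tree, zid, lineages)
                final[zid] = taxonomy.combine_assignments(automatic[zid],
                                                          phylo)

    stage("exclude_taxa")
    if config.blocklist:
        for isl in list(tables):
            tables[isl], report = filtering.exclude_taxa(
                tables[isl], final, config.blocklist)
            if report.excluded:
                path = outdir / f"excluded_{isl}.tsv"
                _write(report.to_frame(), path)
                record(path)
    assign_path = outdir / "assignments.tsv"
    live = {z for isl in tables for z in tables[isl].zotu_ids}
    final = {z: a for z, a in final.items() if z in live}
    _write(_assignment_frame(final), assign_path)
    record(assign_path)

    # ---------------- clustering ----------------
    stage("clustering")
    threshold = config.cluster_threshold
    if threshold is None:
        ref_records = list(ref_seqs.values())
        ref_tax = io.read_taxonomy_table(config.reference_taxonomy)
        species_of = {rid: ref_tax.loc[rid, "species"]
                      for rid in ref_tax.index if rid in ref_seqs}
        opt = clustering.optimize_threshold(ref_records, species_of,
                                            grid=config.grid())
        threshold = opt.optimum
        path = outdir / "threshold_optimization.tsv"
        _write(opt.to_frame(), path)
        record(path)
        manifest["results"]["optimal_threshold"] = threshold
    pooled = [r for isl in sorted(tables) for r in seqs[isl]
              if r.id in set(tables[isl].zotu_ids)]
    dm = taxonomy.pairwise_distance_matrix(pooled, proportional=True)
    partition = clustering.complete_linkage_cluster(dm, threshold)
    path = outdir / "clusters.tsv"
    _write(partition.to_frame(), path)
    record(path)
    manifest["results"]["n_clusters"] = partition.n_clusters

    combined = pd.concat(
        [tables[isl].data for isl in sorted(tables)]).fillna(0).astype(int)
    combined_table = io.ZotuTable(combined, mode="counts")

    # ---------------- traits / FEs ----------------
    stage("functional_entities")
    fe_by_zotu: dict[str, str] = {}
    profiles: dict[str, traits.TraitProfile] = {}
    if config.trait_table:
        trait_tab = io.read_trait_table(config.trait_table)
        supplement = io.read_trait_table(config.supplement_table) \
            if config.supplement_table else None
        sp_tax = None
        if config.reference_taxonomy:
            ref_tax = io.read_taxonomy_table(config.reference_taxonomy)
            sp_tax = (ref_tax[["species", "genus", "family"]]
                      .drop_duplicates("species").set_index("species"))
        profiles = traits.assign_traits(final, trait_tab, taxonomy=sp_tax,
                                        supplement=supplement)
        registry = traits.build_fe_registry(profiles)
        fe_by_zotu = traits.fe_map(registry)
        path = outdir / "fe_registry.tsv"
        _write(traits.registry_frame(registry), path)
        record(path)
        manifest["results"]["n_functional_entities"] = len(registry)

    # ---------------- Hill numbers ----------------
    stage("hill_diversity")
    cluster_units = stats.aggregate(combined_table, partition.assignments)
    curves = []
    for isl in sorted(tables):
        sub = cluster_units.loc[tables[isl].sample_ids]
        inc = hill.to_incidence(sub)
        for q in config.diversity_orders:
            curve = hill.rarefy_extrapolate(inc, q)
            df = curve.to_frame()
            df.insert(0, "island", isl)
            df["asymptote"] = curve.asymptote
            curves.append(df)
            manifest["results"][f"asymptote_q{q}_{isl}"] = curve.asymptote
    path = outdir / "hill_curves.tsv"
    _write(pd.concat(curves, ignore_index=True), path)
    record(path)

    # ---------------- beta diversity ----------------
    stage("beta_diversity")
    family_map = {z: a.lineage_name("family") for z, a in final.items()
                  if a.lineage_name("family")}
    views: dict[str, pd.DataFrame] = {}
    views["family"] = stats.aggregate(combined_table, family_map,
                                      drop_unmapped=True)
    if fe_by_zotu:
        views["fe"] = stats.aggregate(combined_table, fe_by_zotu,
                                      drop_unmapped=True)
    beta_rows = []
    for view_name, counts in views.items():
        for index in config.beta_indices:
            matrix = (counts > 0).astype(int) if index == "jaccard" else counts
            dmat = stats.dissimilarity(matrix, index)
            perm = stats.permanova(dmat, grouping, n_perm=config.n_perm,
                                   seed=config.seed + 17)
            disp = stats.dispersion_test(dmat, grouping, n_perm=config.n_perm,
                                         seed=config.seed + 23)
            ord_res = stats.nmds(dmat, k=2, n_restarts=config.nmds_restarts,
                                 seed=config.seed + 31)
            coords_path = outdir / f"nmds_{view_name}_{index}.tsv"
            _write(ord_res.coords, coords_path, index=True)
            record(coords_path)
            beta_rows.append({
                "view": view_name, "index": index,
                "dispersion_F": disp.F, "dispersion_p": disp.p,
                "R2": perm.R2, "F": perm.F, "p": perm.p,
                "stress": ord_res.stress,
            })
            manifest["results"][f"permanova_{view_name}_{index}_F"] = perm.F
            manifest["results"][f"permanova_{view_name}_{index}_R2"] = perm.R2
    beta_path = outdir / "beta_tests.tsv"
    _write(pd.DataFrame(beta_rows), beta_path)
    record(beta_path)

    # ---------------- indicators ----------------
    stage("indicator_analysis")
    for view_name, counts in views.items():
        res = indicators.multilevel_pattern(counts, grouping,
                                            n_perm=config.n_perm,
                                            seed=config.seed + 41)
        path = outdir / f"indicators_{view_name}.tsv"
        _write(indicators.results_frame(res), path)
        record(path)
        manifest["results"][f"n_significant_{view_name}"] = \
            sum(r.significant for r in res)

    # ---------------- environment ----------------
    stage("environment")
    if config.environment:
        env = io.read_environment_table(config.environment)
        env_vars = env.drop(columns=["island"])
        retained, vifs = stats.vif_screen(env_vars)
        env_dm = stats.dissimilarity(env_vars[retained], "gower")
        env_groups = env["island"].to_dict()
        perm = stats.permanova(env_dm, env_groups, n_perm=config.n_perm,
                               seed=config.seed + 53)
        disp = stats.dispersion_test(env_dm, env_groups,
                                     n_perm=config.n_perm,
                                     seed=config.seed + 59)
        ord_res = stats.nmds(env_dm, k=2, n_restarts=config.nmds_restarts,
                             seed=config.seed + 61)
        fits = stats.envfit(ord_res, env_vars[retained],
                            n_perm=config.n_perm, seed=config.seed + 67)
        env_path = outdir / "environment_tests.tsv"
        _write(pd.DataFrame([{
            "retained_variables": ",".join(retained),
            "permanova_F": perm.F, "permanova_R2": perm.R2,
            "permanova_p": perm.p, "dispersion_F": disp.F,
            "dispersion_p": disp.p, "stress": ord_res.stress,
        }]), env_path)
        record(env_path)
        fit_path = outdir / "environment_envfit.tsv"
        _write(pd.DataFrame([{
            "variable": f.name, "kind": f.kind, "r2": f.r2, "p": f.p,
        } for f in fits]), fit_path)
        record(fit_path)
        manifest["results"]["environment_permanova_F"] = perm.F

    # ---------------- sensitivity ----------------
    stage("sensitivity")
    sens = sensitivity_suite(config, combined_table, final, profiles,
                             grouping, views)
    if len(sens):
        path = outdir / "sensitivity.tsv"
        _write(sens, path)
        record(path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2,
                                        default=float) + "\n")
    return manifest


def sensitivity_suite(config: RunConfig, combined_table: io.ZotuTable,
                      final: Mapping[str, taxonomy.Assignment],
                      profiles: Mapping[str, traits.TraitProfile],
                      grouping: Mapping[str, str],
                      views: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """PERMANOVA grid across family-exclusion and trait-removal variants."""
    rows = []

    def add(variant: str, view: str, counts: pd.DataFrame) -> None:
        if counts.shape[1] == 0:
            return
        keep = counts.sum(axis=1) > 0
        if not keep.all():
            log.warning("%s/%s: %d empty sample(s) dropped", variant, view,
                        int((~keep).sum()))
            counts = counts.loc[keep]
        labels = {s: grouping[s] for s in counts.index}
        if len(set(labels.values())) < 2:
            return
        for index in config.beta_indices:
            matrix = (counts > 0).astype(int) if index == "jaccard" \
                else counts
            dmat = stats.dissimilarity(matrix, index)
            perm = stats.permanova(dmat, labels, n_perm=config.n_perm,
                                   seed=config.seed + 71)
            rows.append({"variant": variant, "view": view, "index": index,
                         "R2": perm.R2, "F": perm.F, "p": perm.p})

    for view, counts in views.items():
        add("base", view, counts)
    family_map = {z: a.lineage_name("family") for z, a in final.items()
                  if a.lineage_name("family")}
    for fam in config.sensitivity_exclude_families:
        keep = {z for z, f in family_map.items() if f != fam}
        fmap = {z: f for z, f in family_map.items() if z in keep}
        sub = io.ZotuTable(
            combined_table.data.loc[
                [z for z in combined_table.zotu_ids if z in keep]].copy(),
            mode="counts")
        add(f"exclude:{fam}", "family",
            stats.aggregate(sub, fmap, drop_unmapped=True))
        if profiles:
            sub_profiles = {z: p for z, p in profiles.items() if z in keep}
            registry = traits.build_fe_registry(sub_profiles)
            add(f"exclude:{fam}", "fe",
                stats.aggregate(sub, traits.fe_map(registry),
                                drop_unmapped=True))
    if profiles:
        for trait in config.sensitivity_drop_traits:
            rest = [t for t in io.TRAIT_NAMES if t != trait]
            registry = traits.build_fe_registry(profiles, traits=rest)
            add(f"drop_trait:{trait}", "fe",
                stats.aggregate(combined_table, traits.fe_map(registry),
                                drop_unmapped=True))
    return pd.DataFrame(rows)
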