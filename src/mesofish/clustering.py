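"""Barcoding-gap threshold optimization and complete-linkage clustering.

ZOTUs carrying heterogeneous assignment depths are made commensurable by
clustering them at a proportional-distance threshold chosen on a
species-labelled reference library: for every candidate threshold each
sequence is queried against all others (leave-one-out) and scored as a
true/false positive/negative depending on whether its neighbourhood
contains only conspecifics; the optimum minimizes total cumulative error
(false positives + false negatives), ties resolving to the smallest
threshold.  Complete linkage then guarantees every cluster's diameter
stays within the threshold.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from mesofish.io import SequenceRecord, ValidationError
from mesofish.taxonomy import pairwise_distance_matrix

DEFAULT_GRID = np.round(np.arange(0.001, 0.0501, 0.001), 10)

RANK_CATEGORIES = ("Intra-species", "Species", "Genus", "Family", "Order",
                   "Class")


@dataclass
class ThresholdOptResult:
    grid: np.ndarray
    counts: pd.DataFrame          # per threshold: TP, FP, FN, TN
    optimum: float

    @property
    def cumulative_error(self) -> pd.Series:
        return self.counts["false_positive"] + self.counts["false_negative"]

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "threshold", self.grid)
        out["cumulative_error"] = self.cumulative_error.to_numpy()
        return out


@dataclass
class ClusterPartition:
    threshold: float
    assignments: dict[str, int]   # zotu id -> cluster id

    @property
    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.assignments.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def check_cut_property(self, dm: DistanceMatrix) -> bool:
        """Max pairwise distance within every cluster <= threshold."""
        idx = {z: i for i, z in enumerate(dm.ids)}
        members: dict[int, list[int]] = {}
        for z, c in self.assignments.items():
            members.setdefault(c, []).append(idx[z])
        for rows in members.values():
            sub = dm.data[np.ix_(rows, rows)]
            if sub.size and sub.max() > self.threshold + 1e-12:
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"zotu_id": list(self.assignments),
             "cluster": list(self.assignments.values())}
        )


def optimize_threshold(records: Sequence[SequenceRecord],
                       species_of: Mapping[str, str],
                       grid: Iterable[float] | None = None,
                       dm: DistanceMatrix | None = None) -> ThresholdOptResult:
    """Scan thresholds for minimum cumulative identification error.

    For query q at threshold t, with N(q, t) the other sequences within
    proportional distance <= t: a query with conspecifics in the library
    scores true positive when N is non-empty and purely conspecific,
    false positive when N contains a heterospecific, false negative when
    N is empty; a singleton species scores true negative on empty N and
    false positive otherwise.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(sorted(grid), float)
    if grid.size == 0:
        raise ValidationError("threshold grid is empty")
    missing = [r.id for r in records if r.id not in species_of]
    if missing:
        raise ValidationError(f"unlabelled sequence(s): {missing[:5]}")
    if dm is None:
        dm = pairwise_distance_matrix(records, proportional=True)
    D = dm.data
    species = np.array([species_of[i] for i in dm.ids])
    consp = (species[:, None] == species[None, :])
    np.fill_diagonal(consp, False)
    has_conspecific = consp.any(axis=1)
    off_diag = ~np.eye(len(species), dtype=bool)

    rows = []
    for t in grid:
        W = (D <= t + 1e-12) & off_diag
        nonempty = W.any(axis=1)
        has_het = (W & ~consp).any(axis=1)
        tp = (has_conspecific & nonempty & ~has_het).sum()
        fp = ((has_conspecific & has_het) |
              (~has_conspecific & nonempty)).sum()
        fn = (has_conspecific & ~nonempty).sum()
        tn = (~has_conspecific & ~nonempty).sum()
        rows.append((int(tp), int(fp), int(fn), int(tn)))
    counts = pd.DataFrame(
        rows, columns=["true_positive", "false_positive",
                       "false_negative", "true_negative"])
    errors = counts["false_positive"] + counts["false_negative"]
    optimum = float(grid[int(np.argmin(errors.to_numpy()))])  # first = smallest
    return ThresholdOptResult(grid=grid, counts=counts, optimum=optimum)


def complete_linkage_cluster(dm: DistanceMatrix,
                             threshold: float) -> ClusterPartition:
    """Cut the complete-linkage dendrogram so cluster diameters stay
    within ``threshold``; cluster ids follow first appearance order."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    ids = list(dm.ids)
    if len(ids) == 1:
        return ClusterPartition(threshold, {ids[0]: 1})
    Z = linkage(squareform(dm.data, checks=False), method="complete")
    raw = fcluster(Z, t=threshold, criterion="distance")
    relabel: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for zid, c in zip(ids, raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        assignments[zid] = relabel[c]
    return ClusterPartition(threshold, assignments)


def rank_distance_summary(records: Sequence[SequenceRecord],
                          lineages: Mapping[str, Mapping[str, str]],
                          dm: DistanceMatrix | None = None
                          ) -> dict[str, np.ndarray]:
    """Pool pairwise proportional distances by lowest shared rank.

    Categories follow the barcoding-gap convention: Intra-species (same
    species), Species (same genus, different species), Genus (same
    family), Family (same order), Order (same class), Class (different
    classes).  Every unordered pair lands in exactly one category.
    """
    for r in records:
        lin = lineages.get(r.id)
        if lin is None or "species" not in lin:
            raise ValidationError(f"sequence {r.id!r} lacks a species label")
    if dm is None:
        dm = pairwise_distance_matrix(records, proportional=True)
    ids = list(dm.ids)
    buckets: dict[str, list[float]] = {c: [] for c in RANK_CATEGORIES}
    for i in range(len(ids)):
        li = lineages[ids[i]]
        for j in range(i + 1, len(ids)):
            lj = lineages[ids[j]]
            if li["species"] == lj["species"]:
                cat = "Intra-species"
            elif li.get("genus") == lj.get("genus") and li.get("genus"):
                cat = "Species"
            elif li.get("family") == lj.get("family") and li.get("family"):
                cat = "Genus"
            elif li.get("order") == lj.get("order") and li.get("order"):
                cat = "Family"
            elif li.get("class") == lj.get("class") and li.get("class"):
                cat = "Order"
            else:
                cat = "Class"
            buckets[cat].append(dm.data[i, j])
    return {c: np.asarray(v) for c, v in buckets.items()}


def distinct_sequence_count(*collections: Sequence[SequenceRecord]) -> int:
    """Number of distinct sequence strings across collections (ZOTUs shared
    between islands carry one id per island but count once here)."""
    return len({r.sequence for coll in collections for r in coll})
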