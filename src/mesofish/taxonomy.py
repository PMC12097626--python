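"""Tiered similarity assignment and phylogenetic refinement of ZOTUs.

The automatic route applies e-value/coverage gates to the reference hits
of each query and then a tiered rule: >= 99 % identity with a single
consistent species gives a species call, >= 97 % with a single genus a
genus call, and >= 95 % the lowest common ancestor of all qualifying
hits, capped at family (95 % identity on a short 12S fragment does not
support genus- or species-level claims).  Species calls absent from a
regional occurrence list are demoted to genus and flagged.

The phylogenetic route builds neighbour-joining trees (number-of-
differences distances, complete deletion of gap/N columns), bootstraps
them by column resampling, and assigns each ZOTU from the smallest
midpoint-rooted clade containing it and at least one reference sequence.
Automatic and phylogenetic calls are then combined, the phylogenetic one
winning on conflict.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from mesofish.io import RANKS, HitRecord, SequenceRecord, ValidationError

log = logging.getLogger("mesofish")

ASSIGN_RANKS = ("species", "genus", "family", "order", "class", "unassigned")

DEFAULT_GATES = {"evalue_max": 1e-20, "coverage_min": 90.0}
DEFAULT_TIERS = {"species": 99.0, "genus": 97.0, "higher": 95.0}


@dataclass
class Assignment:
    zotu_id: str
    taxon: str | None
    rank: str
    method: str = "automatic"          # automatic | phylogenetic | combined
    lineage: dict[str, str] = field(default_factory=dict)
    support: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.rank not in ASSIGN_RANKS:
            raise ValidationError(f"unknown assignment rank {self.rank!r}")

    def lineage_name(self, rank: str) -> str | None:
        return self.lineage.get(rank)

    @property
    def is_assigned(self) -> bool:
        return self.rank != "unassigned"

    def rank_depth(self) -> int:
        """Depth on the class..species axis; -1 when unassigned."""
        if self.rank == "unassigned":
            return -1
        return RANKS.index(self.rank)


def _lineage_prefix(lineage: Mapping[str, str], rank: str) -> dict[str, str]:
    return {r: lineage[r] for r in RANKS[: RANKS.index(rank) + 1]
            if r in lineage}


def lca_lineage(lineages: Sequence[Mapping[str, str]]
                ) -> tuple[str | None, dict[str, str]]:
    """Lowest rank (and its lineage prefix) shared by all lineages.

    Absent ranks do not veto (reference annotation depth varies); a rank
    disagrees as soon as two lineages name it differently, and no rank
    below a disagreement can be the answer.
    """
    consensus: dict[str, str] = {}
    lowest = None
    for rank in RANKS:  # top-down
        names = {lin[rank] for lin in lineages if rank in lin}
        if len(names) != 1:
            break
        consensus[rank] = names.pop()
        lowest = rank
    return lowest, consensus


# ---------------------------------------------------------------------------
# Automatic (similarity-tier) assignment
# ---------------------------------------------------------------------------

def gate_hits(hits: Iterable[HitRecord],
              gates: Mapping[str, float] = DEFAULT_GATES) -> list[HitRecord]:
    """Keep hits passing the e-value and query-coverage gates."""
    kept = []
    for h in hits:
        if h.evalue > gates["evalue_max"] or \
                h.query_coverage < gates["coverage_min"]:
            continue
        if not h.lineage:
            log.warning("hit %s->%s has no lineage at any rank; skipped",
                        h.query_id, h.subject_id)
            continue
        kept.append(h)
    return kept


def tiered_assign(hits: Sequence[HitRecord],
                  gates: Mapping[str, float] = DEFAULT_GATES,
                  tiers: Mapping[str, float] = DEFAULT_TIERS) -> Assignment:
    """Assign one query from its reference hits by the tiered rule.

    Tier sets are cumulative: a 99.5 % hit also participates in the lower
    tiers.  The >= 95 % tier takes the strict LCA of all its hits, capped
    at family.
    """
    if not hits:
        raise ValidationError("tiered_assign needs at least one hit")
    query = hits[0].query_id
    gated = gate_hits(hits, gates)
    if not gated:
        return Assignment(query, None, "unassigned")

    def tier(minimum: float) -> list[HitRecord]:
        return [h for h in gated if h.identity >= minimum]

    # (i) species tier
    sp_hits = tier(tiers["species"])
    if sp_hits:
        rank, consensus = lca_lineage([h.lineage for h in sp_hits])
        if rank == "species":
            return Assignment(query, consensus["species"], "species",
                              lineage=consensus,
                              support=[h.subject_id for h in sp_hits])
    # (ii) genus tier
    ge_hits = tier(tiers["genus"])
    if ge_hits:
        rank, consensus = lca_lineage([h.lineage for h in ge_hits])
        if rank in ("species", "genus") and "genus" in consensus:
            return Assignment(query, consensus["genus"], "genus",
                              lineage=_lineage_prefix(consensus, "genus"),
                              support=[h.subject_id for h in ge_hits])
    # (iii) higher tier: strict LCA, capped at family
    hi_hits = tier(tiers["higher"])
    if hi_hits:
        rank, consensus = lca_lineage([h.lineage for h in hi_hits])
        if rank is not None:
            if RANKS.index(rank) > RANKS.index("family"):
                rank = "family" if "family" in consensus else rank
            if rank in consensus:
                return Assignment(query, consensus[rank], rank,
                                  lineage=_lineage_prefix(consensus, rank),
                                  support=[h.subject_id for h in hi_hits])
    return Assignment(query, None, "unassigned")


def region_validate(assignment: Assignment,
                    occurrence_list: Iterable[str]) -> Assignment:
    """Demote species calls absent from the regional occurrence list.

    The demoted call keeps the genus, gains the ``region_unvalidated``
    flag; other ranks pass through untouched.
    """
    if assignment.rank != "species":
        return assignment
    if assignment.taxon in set(occurrence_list):
        return assignment
    lineage = {r: n for r, n in assignment.lineage.items() if r != "species"}
    demoted = Assignment(
        assignment.zotu_id, lineage.get("genus"), "genus",
        method=assignment.method, lineage=lineage,
        support=list(assignment.support),
        flags=set(assignment.flags) | {"region_unvalidated"},
    )
    log.info("species %s not in regional list; %s demoted to genus",
             assignment.taxon, assignment.zotu_id)
    return demoted


# ---------------------------------------------------------------------------
# Distances and neighbour joining
# ---------------------------------------------------------------------------

def _seq_matrix(records: Sequence[SequenceRecord]) -> np.ndarray:
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValidationError("sequences must be aligned (uniform length)")
    return np.array([np.frombuffer(r.sequence.encode(), np.uint8)
                     for r in records])


def complete_deletion(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Character matrix with every column holding a gap or N removed."""
    mat = _seq_matrix(records)
    bad = np.isin(mat, np.frombuffer(b"-N", np.uint8)).any(axis=0)
    kept = mat[:, ~bad]
    if kept.shape[1] == 0:
        raise ValidationError("complete deletion removed every column; "
                              "no comparable sites")
    return kept


def pairwise_distance_matrix(records: Sequence[SequenceRecord],
                             proportional: bool = False) -> DistanceMatrix:
    """Number-of-differences distances under complete deletion.

    ``proportional=True`` divides by the number of compared sites, the
    length-independent convention the clustering threshold uses; the raw
    count is the tree-building convention.
    """
    if len(records) < 2:
        raise ValidationError("need at least two sequences")
    kept = complete_deletion(records)
    diffs = (kept[:, None, :] != kept[None, :, :]).sum(axis=2)
    d = diffs.astype(float)
    if proportional:
        d /= kept.shape[1]
    return DistanceMatrix(d, ids=[r.id for r in records])


def nj_build(dm: DistanceMatrix | np.ndarray,
             ids: Sequence[str] | None = None) -> TreeNode:
    """Neighbour joining (Saitou-Nei) with deterministic tie-breaking.

    Q-ties resolve to the lowest-index pair in current node order;
    negative branch lengths are clamped to 0 and logged.  Returns an
    unrooted tree as a trifurcating root for n >= 3.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm, dtype=float), ids=ids)
    n = dm.shape[0]
    if n < 3:
        raise ValidationError("neighbour joining needs n >= 3")
    D = dm.data.copy()
    nodes = [TreeNode(name=i) for i in dm.ids]

    def clamp(x: float) -> float:
        if x < 0:
            log.info("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best, best_q = None, np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        parent = TreeNode(children=[child_i, child_j])
        new_row = (D[i, :] + D[j, :] - D[i, j]) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], new_row[keep]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point join
    (a, b, c), d = nodes, D
    a.length = clamp((d[0, 1] + d[0, 2] - d[1, 2]) / 2)
    b.length = clamp((d[0, 1] + d[1, 2] - d[0, 2]) / 2)
    c.length = clamp((d[0, 2] + d[1, 2] - d[0, 1]) / 2)
    return TreeNode(children=[a, b, c])


# ---------------------------------------------------------------------------
# Bootstrap and MRCA assignment
# ---------------------------------------------------------------------------

def _splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized to the side not
    containing the lexicographically first leaf."""
    leaves = sorted(t.name for t in tree.tips())
    anchor, full = leaves[0], set(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            out.add(frozenset(side))
    return out


def _nj_from_matrix(mat: np.ndarray, ids: Sequence[str]) -> TreeNode:
    diffs = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
    return nj_build(DistanceMatrix(diffs, ids=ids))


def bootstrap_support(records: Sequence[SequenceRecord],
                      replicates: int = 1000, seed: int = 0) -> TreeNode:
    """NJ tree with bootstrap support (% of column-resampled replicates
    containing each internal bipartition) on its internal nodes."""
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [r.id for r in records]
    kept = complete_deletion(records)
    tree = _nj_from_matrix(kept, ids)
    counts: dict[frozenset, int] = {}
    m = kept.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, m, size=m)
        for split in _splits(_nj_from_matrix(kept[:, cols], ids)):
            counts[split] = counts.get(split, 0) + 1
    anchor = sorted(ids)[0]
    full = set(ids)
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            node.support = 100.0 * counts.get(frozenset(side), 0) / replicates
    return tree


def _support_map(tree: TreeNode) -> dict[frozenset, float]:
    out = {}
    leaves = sorted(t.name for t in tree.tips())
    anchor, full = leaves[0], set(leaves)
    for node in tree.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is None:
            continue
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = full - side
        out[frozenset(side)] = support
    return out


def mrca_assign(tree: TreeNode, zotu_leaf: str,
                reference_lineages: Mapping[str, Mapping[str, str]],
                support_threshold: float = 70.0) -> Assignment:
    """Assign a ZOTU from the smallest midpoint-rooted clade containing it
    and at least one reference leaf.

    The call is the LCA of the reference leaves in that clade; if the
    clade's subtending edge has bootstrap support below
    ``support_threshold`` the ``low_bootstrap`` flag is set.
    """
    tip_names = {t.name for t in tree.tips()}
    if zotu_leaf not in tip_names:
        raise ValidationError(f"leaf {zotu_leaf!r} not in tree")
    refs_in_tree = tip_names & set(reference_lineages)
    if not refs_in_tree:
        raise ValidationError("tree contains no reference leaf")
    supports = _support_map(tree)
    try:
        rooted = tree.root_at_midpoint()
    except Exception:  # zero-length or degenerate trees keep their rooting
        rooted = tree.copy()
    node = rooted.find(zotu_leaf)
    clade_refs: set[str] = set()
    clade = None
    while node.parent is not None:
        node = node.parent
        clade_refs = {t.name for t in node.tips()} & set(reference_lineages)
        if clade_refs:
            clade = node
            break
    if not clade_refs:  # root reached (possible if refs sit across the root)
        clade = rooted
        clade_refs = refs_in_tree
    rank, consensus = lca_lineage(
        [dict(reference_lineages[r]) for r in sorted(clade_refs)])
    flags = set()
    leaves = sorted(tip_names)
    anchor, full = leaves[0], set(leaves)
    side = {t.name for t in clade.tips()}
    if anchor in side:
        side = full - side
    support = supports.get(frozenset(side))
    if support is not None and support < support_threshold:
        flags.add("low_bootstrap")
    if rank is None:
        return Assignment(zotu_leaf, None, "unassigned",
                          method="phylogenetic", flags=flags,
                          support=sorted(clade_refs))
    return Assignment(zotu_leaf, consensus[rank], rank,
                      method="phylogenetic",
                      lineage=_lineage_prefix(consensus, rank),
                      support=sorted(clade_refs), flags=flags)


def combine_assignments(automatic: Assignment | None,
                        phylogenetic: Assignment | None) -> Assignment:
    """Final call combining both routes, the phylogenetic one winning on
    conflict; on agreement the more precise rank is kept."""
    if automatic is None and phylogenetic is None:
        raise ValidationError("at least one assignment must be present")
    if phylogenetic is None:
        return automatic
    if automatic is None:
        return phylogenetic
    if not automatic.is_assigned:
        result = phylogenetic
    elif not phylogenetic.is_assigned:
        result = automatic
    else:
        # compare at the shallower of the two ranks
        cmp_rank = RANKS[min(automatic.rank_depth(),
                             phylogenetic.rank_depth())]
        if automatic.lineage_name(cmp_rank) == \
                phylogenetic.lineage_name(cmp_rank):
            result = (automatic if automatic.rank_depth() >=
                      phylogenetic.rank_depth() else phylogenetic)
        else:
            result = phylogenetic
    return Assignment(
        automatic.zotu_id, result.taxon, result.rank, method="combined",
        lineage=dict(result.lineage),
        support=sorted(set(automatic.support) | set(phylogenetic.support)),
        flags=set(automatic.flags) | set(phylogenetic.flags),
    )


# ---------------------------------------------------------------------------
# Fallback aligner (center-star) for unaligned inputs
# ---------------------------------------------------------------------------

def center_star_align(records: Sequence[SequenceRecord]
                      ) -> list[SequenceRecord]:
    """Center-star multiple alignment: global pairwise alignment of every
    sequence to the medoid.  Adequate for near-identical, near-equal-length
    amplicons; inputs of uniform length pass through unchanged."""
    if len({len(r) for r in records}) == 1:
        return [SequenceRecord(r.id, r.sequence, aligned=True)
                for r in records]
    from Bio import Align

    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-0.5)
    n = len(records)
    score = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(records[i].sequence, records[j].sequence)
            score[i, j] = score[j, i] = s
    center = int(np.argmax(score.sum(axis=1)))
    c_seq = records[center].sequence
    pair = []
    for i, rec in enumerate(records):
        if i == center:
            pair.append((c_seq, c_seq))
            continue
        aln = aligner.align(c_seq, rec.sequence)[0]
        pair.append((str(aln[0]), str(aln[1])))
    # insertion profile relative to center coordinates
    ins = np.zeros(len(c_seq) + 1, dtype=int)
    for gc, _ in pair:
        pos, run = 0, 0
        for ch in gc:
            if ch == "-":
                run += 1
            else:
                ins[pos] = max(ins[pos], run)
                pos, run = pos + 1, 0
        ins[len(c_seq)] = max(ins[len(c_seq)], run)
    out = []
    for (gc, gs), rec in zip(pair, records):
        chunks, pos, run = [], 0, []
        slots: list[list[str]] = [[] for _ in range(len(c_seq) + 1)]
        cols: list[str] = [""] * len(c_seq)
        for cch, sch in zip(gc, gs):
            if cch == "-":
                slots[pos].append(sch)
            else:
                cols[pos] = sch
                pos += 1
        parts = []
        for p in range(len(c_seq)):
            parts.append("".join(slots[p]).ljust(ins[p], "-"))
            parts.append(cols[p])
        parts.append("".join(slots[len(c_seq)]).ljust(ins[len(c_seq)], "-"))
        out.append(SequenceRecord(rec.id, "".join(parts), aligned=True))
    return out
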