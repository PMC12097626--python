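"""Readers and writers for the external formats the pipeline touches.

Everything tabular is UTF-8, tab-separated, ``.``-decimal, first row a
header; sequences travel as plain FASTA and trees as Newick.  Readers
validate strictly and reject rather than repair: duplicate identifiers,
negative read counts, percentages outside [0, 100], out-of-vocabulary
trait values and ragged alignments are all hard errors.
"""
from __future__ import annotations

import io as _io
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from skbio import TreeNode

log = logging.getLogger("mesofish")

#: Taxonomic ranks used throughout, ordered from highest to lowest.
RANKS = ("class", "order", "family", "genus", "species")

_DNA_CHARS = set("ACGTN")
_DNA_CHARS_ALIGNED = _DNA_CHARS | {"-"}


class ValidationError(ValueError):
    """Input violated a structural invariant (duplicate id, bad value...)."""


class ParseError(ValueError):
    """Input could not be parsed at all."""


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A single DNA sequence (ZOTU amplicon or reference barcode)."""

    id: str
    sequence: str
    aligned: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        allowed = _DNA_CHARS_ALIGNED if self.aligned else _DNA_CHARS
        bad = set(seq) - allowed
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _check_collection(records: Sequence[SequenceRecord], aligned: bool) -> None:
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    if aligned and records:
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise ValidationError(
                f"aligned collection has non-uniform lengths {sorted(lengths)}"
            )


def read_fasta(path, aligned: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    ``aligned=True`` permits gap characters and enforces uniform length.
    Duplicate ids are rejected.
    """
    path = Path(path)
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython parse failure
        raise ParseError(f"cannot parse FASTA {path}: {exc}") from exc
    if not raw and path.stat().st_size > 0:
        raise ParseError(f"{path} is not FASTA (no records parsed)")
    records = [SequenceRecord(r.id, str(r.seq), aligned=aligned) for r in raw]
    _check_collection(records, aligned)
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    records = list(records)
    _check_collection(records, aligned=any(r.aligned for r in records))
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# ZOTU-by-sample table
# ---------------------------------------------------------------------------

@dataclass
class ZotuTable:
    """ZOTU x sample matrix of read counts or per-sample read proportions.

    ``data`` is indexed by ZOTU id with one column per sample.  ``mode`` is
    either ``"counts"`` (non-negative integers; required by the abundance
    filter) or ``"proportions"`` (each sample column sums to at most 1).
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self):
        if self.mode not in ("counts", "proportions"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ZOTU ids {dups}")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if any(str(c).strip() == "" for c in df.columns):
            raise ValidationError("empty sample column header")
        if any(str(i).strip() == "" for i in df.index):
            raise ValidationError("empty ZOTU id")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric cell in ZOTU table")
        if np.isnan(values).any():
            raise ValidationError("missing value in ZOTU table")
        if (values < 0).any():
            raise ValidationError("negative value in ZOTU table")
        if self.mode == "counts":
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts mode requires integer reads")
            self.data = df.astype(np.int64)
        else:
            sums = values.sum(axis=0)
            if (sums > 1 + 1e-9).any():
                bad = df.columns[sums > 1 + 1e-9].tolist()
                raise ValidationError(
                    f"proportions in sample(s) {bad} sum to more than 1"
                )

    @property
    def zotu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def depths(self) -> pd.Series:
        """Per-sample read depth (column sums)."""
        return self.data.sum(axis=0)

    def detected(self) -> pd.DataFrame:
        """Boolean ZOTU x sample detection matrix (value > 0)."""
        return self.data > 0

    def drop_empty(self) -> "ZotuTable":
        """Drop ZOTUs absent from every sample."""
        keep = self.data.sum(axis=1) > 0
        return ZotuTable(self.data.loc[keep].copy(), self.mode)


def read_zotu_table(path, mode: str = "counts") -> ZotuTable:
    """Read a wide ZOTU-by-sample TSV (first column = ZOTU ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot parse ZOTU table {path}: {exc}") from exc
    if any(str(c).startswith("Unnamed:") for c in df.columns):
        raise ValidationError(f"empty sample column header in {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValidationError(f"non-numeric cell in sample column {col!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ZotuTable(df, mode=mode)


def write_zotu_table(table: ZotuTable, path) -> None:
    out = table.data.copy()
    out.index.name = "zotu_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Reference hits (BLAST tabular dialect)
# ---------------------------------------------------------------------------

@dataclass
class HitRecord:
    """One candidate reference match for a query ZOTU."""

    query_id: str
    subject_id: str
    identity: float        # percent, [0, 100]
    query_coverage: float  # percent, [0, 100]
    evalue: float
    lineage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.identity <= 100:
            raise ValidationError(
                f"identity {self.identity} outside [0, 100] "
                f"(query {self.query_id!r})"
            )
        if not 0 <= self.query_coverage <= 100:
            raise ValidationError(
                f"query coverage {self.query_coverage} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValidationError("e-value must be non-negative")
        unknown = set(self.lineage) - set(RANKS)
        if unknown:
            raise ValidationError(f"unknown lineage ranks {sorted(unknown)}")
        # Present ranks must form a top-down prefix: a named genus implies a
        # named family, order and class.
        present = [r in self.lineage for r in RANKS]
        if True in present:
            deepest = max(i for i, p in enumerate(present) if p)
            if not all(present[: deepest + 1]):
                raise ValidationError(
                    f"lineage for {self.subject_id!r} has a gap above its "
                    f"lowest named rank"
                )

    def rank_name(self, rank: str) -> str | None:
        return self.lineage.get(rank)


_HIT_COLUMNS = ["query_id", "subject_id", "identity", "query_coverage",
                "evalue", *RANKS]


def read_hit_table(path) -> "OrderedDict[str, list[HitRecord]]":
    """Read a tab-separated hit table, grouped by query in file order.

    Columns: query_id, subject_id, identity, query_coverage, evalue, then
    one column per rank (class..species); empty cells mean the rank is
    unnamed in the reference annotation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_HIT_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ParseError(f"hit table {path} lacks columns {sorted(missing)}")
    col = {name: i for i, name in enumerate(df.columns)}
    grouped: OrderedDict[str, list[HitRecord]] = OrderedDict()
    for row in df.itertuples(index=False, name=None):
        lineage = {
            r: row[col[r]].strip()
            for r in RANKS
            if r in col and row[col[r]].strip()
        }
        rec = HitRecord(
            query_id=row[col["query_id"]],
            subject_id=row[col["subject_id"]],
            identity=float(row[col["identity"]]),
            query_coverage=float(row[col["query_coverage"]]),
            evalue=float(row[col["evalue"]]),
            lineage=lineage,
        )
        grouped.setdefault(rec.query_id, []).append(rec)
    return grouped


def write_hit_table(hits: Mapping[str, Sequence[HitRecord]], path) -> None:
    rows = []
    for recs in hits.values():
        for h in recs:
            row = {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "identity": h.identity,
                "query_coverage": h.query_coverage,
                "evalue": h.evalue,
            }
            for r in RANKS:
                row[r] = h.lineage.get(r, "")
            rows.append(row)
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy, trait and environment tables
# ---------------------------------------------------------------------------

def read_taxonomy_table(path) -> pd.DataFrame:
    """Rank-labelled lineage table: one row per reference sequence/species.

    Requires an ``id`` column plus rank columns; empty cells = unnamed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ParseError(f"taxonomy table {path} lacks an 'id' column")
    if df["id"].duplicated().any():
        raise ValidationError("duplicate ids in taxonomy table")
    return df.set_index("id")


TRAIT_NAMES = ("activity", "schooling", "position", "diet", "body_shape")


def read_trait_table(path, vocabulary: Mapping[str, Sequence[str]] | None = None
                     ) -> pd.DataFrame:
    """Trait table keyed by taxon name; empty cells are missing values.

    ``vocabulary`` maps trait name -> allowed values; out-of-vocabulary
    values are rejected (pass the registry from :mod:`mesofish.traits`,
    which is also the default).
    """
    if vocabulary is None:
        from mesofish.traits import TRAIT_VOCABULARY
        vocabulary = TRAIT_VOCABULARY
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "taxon" not in df.columns:
        raise ParseError(f"trait table {path} lacks a 'taxon' column")
    missing = set(TRAIT_NAMES) - set(df.columns)
    if missing:
        raise ParseError(f"trait table lacks columns {sorted(missing)}")
    if df["taxon"].duplicated().any():
        raise ValidationError("duplicate taxa in trait table")
    df = df.set_index("taxon")
    for trait in TRAIT_NAMES:
        values = df[trait].str.strip()
        bad = set(values[values != ""]) - set(vocabulary[trait])
        if bad:
            raise ValidationError(
                f"out-of-vocabulary {trait} value(s) {sorted(bad)}"
            )
        df[trait] = values.where(values != "", other=np.nan)
    return df[list(TRAIT_NAMES)]


ENV_QUANTITATIVE = ("depth", "distance_to_coast")
ENV_CATEGORICAL = ("slope", "rugosity", "dominant")


def read_environment_table(path) -> pd.DataFrame:
    """Station environment table: island label + habitat descriptors."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"station_id", "island", *ENV_QUANTITATIVE, *ENV_CATEGORICAL}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"environment table lacks columns {sorted(missing)}")
    if df["station_id"].duplicated().any():
        raise ValidationError("duplicate station ids")
    if (df["island"].str.strip() == "").any():
        raise ValidationError("station without island label")
    df = df.set_index("station_id")
    for col in ENV_QUANTITATIVE:
        df[col] = pd.to_numeric(df[col], errors="raise")
        if not np.isfinite(df[col].to_numpy()).all():
            raise ValidationError(f"non-finite value in {col}")
    return df


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick, clamping negative branch lengths to 0.

    Internal-node ``support`` attributes (bootstrap percentages) are written
    as internal node labels, the convention the tree viewers expect.
    """
    tree = tree.copy()
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            log.warning(
                "negative branch length %.4g clamped to 0", node.length
            )
            node.length = 0.0
        support = getattr(node, "support", None)
        if support is not None and not node.is_tip():
            node.name = f"{support:g}"
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(source) -> TreeNode:
    """Parse Newick text (or a path) into a scikit-bio ``TreeNode``."""
    try:
        is_path = Path(str(source)).exists()
    except OSError:
        is_path = False
    if isinstance(source, (str, Path)) and is_path:
        return TreeNode.read(str(source), format="newick")
    return TreeNode.read(_io.StringIO(str(source)), format="newick")
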