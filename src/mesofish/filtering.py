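"""Per-sample low-abundance filtering and taxon blocklist exclusion.

The abundance filter zeroes any detection below ``rate`` x the sample's
read depth (default 0.025 %), one pass, with depth taken as the column
sum of the unfiltered table.  The comparison keeps a detection exactly on
the threshold.  Taxon exclusion removes ZOTUs whose assignment matches a
blocklist entry at the entry's rank (e.g. implausible freshwater genera
detected in marine samples).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from mesofish.io import RANKS, ValidationError, ZotuTable

log = logging.getLogger("mesofish")


@dataclass
class FilterReport:
    depths: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    zeroed: list[tuple[str, str]] = field(default_factory=list)
    dropped_zotus: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"kind": "zeroed", "zotu": z, "detail": s}
                for z, s in self.zeroed]
        rows += [{"kind": "dropped", "zotu": z, "detail": ""}
                 for z in self.dropped_zotus]
        rows += [{"kind": "excluded", "zotu": z, "detail": why}
                 for z, why in self.excluded]
        return pd.DataFrame(rows, columns=["kind", "zotu", "detail"])


def abundance_filter(table: ZotuTable, rate: float = 0.00025
                     ) -> tuple[ZotuTable, FilterReport]:
    """Zero detections below ``rate`` x per-sample depth; drop empty rows.

    Depth is the column sum *before* filtering and is not recomputed
    (single pass), so the filter is idempotent.
    """
    if table.mode != "counts":
        raise ValidationError(
            "abundance_filter requires a counts-mode table; convert "
            "proportions to counts first"
        )
    if not 0 <= rate < 1:
        raise ValidationError("rate must lie in [0, 1)")
    report = FilterReport()
    data = table.data.copy()
    depths = data.sum(axis=0)
    for s in data.columns:
        depth = int(depths[s])
        threshold = rate * depth
        report.depths[s] = depth
        report.thresholds[s] = threshold
        col = data[s]
        kill = (col > 0) & (col < threshold)
        for z in data.index[kill]:
            report.zeroed.append((z, s))
        data.loc[kill, s] = 0
    empty = data.sum(axis=1) == 0
    report.dropped_zotus = list(data.index[empty])
    filtered = ZotuTable(data.loc[~empty].copy(), mode="counts")
    if report.zeroed:
        log.info("abundance filter zeroed %d detections, dropped %d ZOTUs",
                 len(report.zeroed), len(report.dropped_zotus))
    return filtered, report


def exclude_taxa(table: ZotuTable, assignments: Mapping[str, "object"],
                 blocklist: Mapping[str, list[str] | str]
                 ) -> tuple[ZotuTable, FilterReport]:
    """Remove ZOTUs whose assignment matches a blocklist entry at its rank.

    ``blocklist`` maps rank -> taxon name(s), e.g.
    ``{"genus": ["Hypophthalmichthys"]}``.  ``assignments`` maps zotu id to
    an object exposing ``lineage_name(rank)`` (see
    :class:`mesofish.taxonomy.Assignment`) or to a plain rank->name dict.
    """
    report = FilterReport()
    for rank in blocklist:
        if rank not in RANKS:
            raise ValidationError(f"blocklist rank {rank!r} not one of {RANKS}")
    norm = {rank: [names] if isinstance(names, str) else list(names)
            for rank, names in blocklist.items()}
    doomed = []
    for zid in table.zotu_ids:
        a = assignments.get(zid)
        if a is None:
            continue
        for rank, names in norm.items():
            name = (a.get(rank) if isinstance(a, Mapping)
                    else a.lineage_name(rank))
            if name is not None and name in names:
                doomed.append(zid)
                report.excluded.append((zid, f"{rank}={name}"))
                break
    matched = {why.split("=", 1)[1] for _, why in report.excluded}
    for rank, names in norm.items():
        for name in names:
            if name not in matched:
                log.info("blocklist entry %s=%s matched nothing", rank, name)
    kept = table.data.drop(index=doomed)
    return ZotuTable(kept.copy(), table.mode), report
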