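"""Rarefaction and taxonomic-rank aggregation.

Rarefaction subsamples each sample's reads without replacement down to a
common depth (1,344 by default, the depth used for the normalised tables this
package consumes), which removes library-size differences before ordination.
Aggregation sums OTU counts sharing a lineage prefix down to a chosen rank;
taxa unclassified at that rank are pooled and, by default, excluded — the
analyses at phylum through genus are restricted to classified taxa.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    LEVELS,
    RANKS,
    UNCLASSIFIED,
    OtuTable,
    RankTable,
    TaxonomyMap,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Default rarefaction depth (reads per sample after normalisation).
DEFAULT_DEPTH = 1344


def rarefy(table: OtuTable, depth: int = DEFAULT_DEPTH, seed: int = 0) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained sample's row is a multivariate-hypergeometric draw of
    ``depth`` reads from its observed reads, so per-taxon expectations are
    ``depth * count / total``. Samples with fewer than ``depth`` total reads
    are dropped with a logged warning. Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise ValidationError(
            f"all {len(totals)} samples have fewer than {depth} reads"
        )
    dropped = totals.index[~keep].tolist()
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    rng = np.random.default_rng(seed)
    counts = table.counts.loc[keep]
    out = np.empty(counts.shape, dtype=np.int64)
    for i, row in enumerate(counts.to_numpy()):
        if row.sum() == depth:
            out[i] = row  # exhaustive draw: all reads retained
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    rarefied = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    attrs = None
    if table.sample_attrs is not None:
        attrs = table.sample_attrs.loc[counts.index]
    return OtuTable(rarefied, attrs)


def aggregate(
    table: OtuTable,
    tax: TaxonomyMap,
    level: str,
    drop_unclassified: bool | None = None,
) -> RankTable:
    """Sum OTU counts sharing a full lineage prefix down to ``level``.

    Aggregation keys are the entire lineage from kingdom down to ``level``
    (joined with ``;``), never the bare rank name, so identically named
    orders under different classes stay separate. OTUs unclassified at
    ``level`` are pooled into a single ``unclassified`` column, removed when
    ``drop_unclassified`` is true (the default for phylum..genus; at
    ``level='otu'`` nothing is aggregated or dropped).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    if level == "otu":
        return RankTable(
            table.counts.copy(), "otu",
            unclassified_excluded=False,
            sample_attrs=table.sample_attrs,
        )
    if drop_unclassified is None:
        drop_unclassified = True

    keys = []
    for taxon in table.taxon_ids:
        prefix = tax.prefix_key(taxon, level)
        keys.append(
            UNCLASSIFIED if prefix[-1] == UNCLASSIFIED else ";".join(prefix)
        )
    grouped = table.counts.T.groupby(pd.Index(keys, name=None), sort=False).sum().T
    if UNCLASSIFIED in grouped.columns:
        mass = int(grouped[UNCLASSIFIED].sum())
        if drop_unclassified:
            logger.info(
                "aggregate(%s): dropping unclassified pool (%d reads, "
                "%.1f%% of total)",
                level, mass, 100.0 * mass / max(table.counts.to_numpy().sum(), 1),
            )
            grouped = grouped.drop(columns=[UNCLASSIFIED])
    return RankTable(
        grouped, level,
        unclassified_excluded=drop_unclassified,
        sample_attrs=table.sample_attrs,
    )


def to_relative(table: OtuTable | RankTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; each row sums to 1. Errors on all-zero rows."""
    counts = table if isinstance(table, pd.DataFrame) else table.counts
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        raise ValidationError(
            f"all-zero samples: {counts.index[zero].tolist()}"
        )
    return counts.div(totals, axis=0)


def display_name(lineage_key: str) -> str:
    """Rank-level display name for a full-lineage aggregation key."""
    return lineage_key.rsplit(";", 1)[-1]
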