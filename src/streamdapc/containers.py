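"""In-memory containers for OTU tables, taxonomy maps and site metadata.

Counts live in pandas DataFrames (samples as rows, taxa as columns) so that
label alignment, slicing and TSV round-trips use standard pandas machinery;
the dataclasses below add the validation the analysis relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Taxonomic ranks from coarsest to finest, as used throughout the package.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Aggregation levels accepted by the pipeline: the six lineage ranks plus
#: the raw OTU level.
LEVELS = ("phylum", "class", "order", "family", "genus", "otu")

UNCLASSIFIED = "unclassified"

SEASONS = ("spring", "summer")
MEDIA = ("water", "sediment")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(labels, kind: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {kind} ids: {dups}")


@dataclass
class OtuTable:
    """Rectangular table of non-negative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Samples x taxa, integer dtype, non-negative. The index holds sample
        ids, the columns taxon ids; both must be unique.
    sample_attrs : pandas.DataFrame, optional
        Per-sample provenance labels. Recognised columns are ``season``
        (spring/summer) and ``medium`` (water/sediment); extra columns are
        carried through untouched.
    """

    counts: pd.DataFrame
    sample_attrs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame")
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "taxon")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            bad = self.counts.index[(values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative counts in samples: {bad}")
        if self.sample_attrs is not None:
            missing = self.counts.index.difference(self.sample_attrs.index)
            if len(missing):
                raise ValidationError(
                    f"sample_attrs missing samples: {missing.tolist()}"
                )
            self.sample_attrs = self.sample_attrs.loc[self.counts.index]
            for col, allowed in (("season", SEASONS), ("medium", MEDIA)):
                if col in self.sample_attrs.columns:
                    bad = set(self.sample_attrs[col].dropna()) - set(allowed)
                    if bad:
                        raise ValidationError(
                            f"unknown {col} values: {sorted(bad)}"
                        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids) -> "OtuTable":
        attrs = None
        if self.sample_attrs is not None:
            attrs = self.sample_attrs.loc[sample_ids]
        return OtuTable(self.counts.loc[sample_ids].copy(), attrs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        if not self.counts.equals(other.counts):
            return False
        if (self.sample_attrs is None) != (other.sample_attrs is None):
            return False
        if self.sample_attrs is not None:
            return self.sample_attrs.equals(other.sample_attrs)
        return True


@dataclass
class RankTable:
    """Counts aggregated to a named taxonomic level.

    ``taxon_ids`` are full-lineage keys (rank names joined by ``;``) so that
    identically named orders under different classes are never merged. At
    ``level='otu'`` the table equals its source.
    """

    counts: pd.DataFrame
    level: str
    unclassified_excluded: bool = False
    sample_attrs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(
                f"level must be one of {LEVELS}, got {self.level!r}"
            )
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "taxon")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class TaxonomyMap:
    """Map from taxon id to a six-rank lineage (kingdom .. genus).

    Each rank entry is a name or the sentinel ``"unclassified"``; once a rank
    is unclassified every finer rank must be unclassified too (enforced).
    Taxa absent from the map are treated as fully unclassified.
    """

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, lineage in self.lineages.items():
            self.lineages[taxon] = self._validate_lineage(taxon, lineage)

    @staticmethod
    def _validate_lineage(taxon: str, lineage) -> tuple[str, ...]:
        lineage = tuple(lineage)
        if len(lineage) > len(RANKS):
            raise ValidationError(
                f"{taxon}: lineage has {len(lineage)} ranks, max {len(RANKS)}"
            )
        lineage = lineage + (UNCLASSIFIED,) * (len(RANKS) - len(lineage))
        seen_unclassified = False
        for rank, name in zip(RANKS, lineage):
            if name == UNCLASSIFIED:
                seen_unclassified = True
            elif seen_unclassified:
                raise ValidationError(
                    f"{taxon}: rank {rank!r} named {name!r} below an "
                    "unclassified rank"
                )
        return lineage

    def lineage(self, taxon: str) -> tuple[str, ...]:
        """Lineage for ``taxon``; fully unclassified if unmapped."""
        return self.lineages.get(taxon, (UNCLASSIFIED,) * len(RANKS))

    def name_at(self, taxon: str, rank: str) -> str:
        return self.lineage(taxon)[RANKS.index(rank)]

    def prefix_key(self, taxon: str, rank: str) -> tuple[str, ...]:
        """Lineage truncated at ``rank`` — the aggregation key."""
        return self.lineage(taxon)[: RANKS.index(rank) + 1]

    def __len__(self) -> int:
        return len(self.lineages)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.lineages


@dataclass
class SiteMetadata:
    """Per-sample condition scores and covariates.

    The frame is indexed by sample id and must contain a ``bibi`` column with
    values in [1, 5]. ``season`` and ``medium`` are validated when present;
    any further columns are treated as environmental covariates and carried
    through.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "bibi" not in self.frame.columns:
            raise ValidationError("metadata must contain a 'bibi' column")
        _check_unique(self.frame.index, "sample")
        bibi = pd.to_numeric(self.frame["bibi"], errors="coerce")
        if bibi.isna().any():
            bad = self.frame.index[bibi.isna()].tolist()
            raise ValidationError(f"non-numeric bibi for samples: {bad}")
        out = (bibi < 1.0) | (bibi > 5.0)
        if out.any():
            bad = self.frame.index[out].tolist()
            raise ValidationError(
                f"bibi outside [1, 5] for samples: {bad}"
            )
        self.frame = self.frame.copy()
        self.frame["bibi"] = bibi
        for col, allowed in (("season", SEASONS), ("medium", MEDIA)):
            if col in self.frame.columns:
                bad = set(self.frame[col].dropna()) - set(allowed)
                if bad:
                    raise ValidationError(f"unknown {col} values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def bibi(self) -> pd.Series:
        return self.frame["bibi"]

    def env_columns(self) -> list[str]:
        reserved = {"bibi", "season", "medium"}
        return [c for c in self.frame.columns if c not in reserved]

    def require(self, sample_ids) -> None:
        missing = pd.Index(sample_ids).difference(self.frame.index)
        if len(missing):
            raise ValidationError(
                f"metadata missing samples: {missing.tolist()}"
            )
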