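"""Readers and writers for the package's tabular dialects.

Three inputs are consumed: an OTU count table (plain TSV with a leading
sample-id column, or a mothur ``.shared``-style file), a two-column taxonomy
TSV with GreenGenes-style rank prefixes (``k__``, ``p__``, ...), and a site
metadata TSV keyed by sample id. Assessment reports are written as JSON plus
a plain-text digest. All text I/O is UTF-8 with ``.`` as the decimal mark.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MEDIA,
    RANKS,
    SEASONS,
    UNCLASSIFIED,
    OtuTable,
    SiteMetadata,
    TaxonomyMap,
    ValidationError,
)

logger = logging.getLogger(__name__)

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")

_CONFIDENCE = re.compile(r"\(\d+(?:\.\d+)?\)$")


class ParseError(ValueError):
    """Raised when a file cannot be parsed; names the offending line."""


# ---------------------------------------------------------------------------
# OTU tables


def read_otu_table(path, dialect: str = "plain-tsv") -> OtuTable:
    """Read an OTU count table.

    ``dialect='plain-tsv'`` expects a header of taxon ids, a leading
    sample-id column and one row per sample. ``dialect='shared-tsv'`` reads
    the mothur shared layout (``label``, ``Group``, ``numOtus`` prefix
    columns) into the same container.
    """
    path = Path(path)
    if dialect not in ("plain-tsv", "shared-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file (line 1)")
    header = lines[0].split("\t")
    if dialect == "shared-tsv":
        if len(header) < 4 or header[0] != "label" or header[1] != "Group":
            raise ParseError(
                f"{path}: line 1: shared header must start with "
                "'label', 'Group', 'numOtus'"
            )
        taxa = header[3:]
        first_data_col = 3
        id_col = 1
    else:
        taxa = header[1:]
        first_data_col = 1
        id_col = 0
    if not taxa:
        raise ParseError(f"{path}: line 1: no taxon columns in header")
    dup = pd.Index(taxa)
    if dup.has_duplicates:
        dups = sorted(dup[dup.duplicated()].unique().tolist())
        raise ParseError(f"{path}: line 1: duplicate taxon ids {dups}")

    sample_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}: line {lineno}: expected {len(header)} fields, "
                f"got {len(fields)}"
            )
        sample_ids.append(fields[id_col])
        row = []
        for taxon, raw in zip(taxa, fields[first_data_col:]):
            try:
                value = int(raw)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer count {raw!r} "
                    f"for taxon {taxon!r}"
                ) from exc
            if value < 0:
                raise ParseError(
                    f"{path}: line {lineno}: negative count for {taxon!r}"
                )
            row.append(value)
        rows.append(row)
    idx = pd.Index(sample_ids)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ParseError(f"{path}: duplicate sample ids {dups}")
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(rows), len(taxa)),
        index=sample_ids,
        columns=taxa,
    )
    return OtuTable(counts)


def write_otu_table(table: OtuTable, path, dialect: str = "plain-tsv") -> None:
    """Write an OTU table; inverse of :func:`read_otu_table`."""
    path = Path(path)
    counts = table.counts
    with path.open("w", encoding="utf-8") as fh:
        if dialect == "shared-tsv":
            fh.write(
                "\t".join(["label", "Group", "numOtus", *counts.columns])
                + "\n"
            )
            n_otus = str(counts.shape[1])
            for sid, row in zip(counts.index, counts.to_numpy()):
                fh.write(
                    "\t".join(["0.03", str(sid), n_otus, *map(str, row)])
                    + "\n"
                )
        elif dialect == "plain-tsv":
            fh.write("\t".join(["sample_id", *counts.columns]) + "\n")
            for sid, row in zip(counts.index, counts.to_numpy()):
                fh.write("\t".join([str(sid), *map(str, row)]) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Taxonomy


def parse_lineage_string(text: str, where: str = "") -> tuple[str, ...]:
    """Parse a ``k__...;p__...`` lineage into six rank names.

    Empty prefix payloads and missing trailing ranks map to "unclassified";
    mothur-style bootstrap confidences like ``(100)`` are stripped. Prefixes
    must appear in kingdom..genus order.
    """
    parts = [p.strip() for p in text.strip().rstrip(";").split(";") if p.strip()]
    if len(parts) > len(RANK_PREFIXES):
        raise ParseError(f"{where}: more than {len(RANK_PREFIXES)} ranks")
    names: list[str] = []
    for i, part in enumerate(parts):
        prefix = RANK_PREFIXES[i]
        matched = None
        for known in RANK_PREFIXES:
            if part.startswith(known):
                matched = known
                break
        if matched is None:
            raise ParseError(
                f"{where}: rank entry {part!r} lacks a known prefix"
            )
        if matched != prefix:
            raise ParseError(
                f"{where}: rank prefix {matched!r} out of order "
                f"(expected {prefix!r})"
            )
        payload = _CONFIDENCE.sub("", part[len(prefix):]).strip()
        names.append(payload if payload else UNCLASSIFIED)
    names += [UNCLASSIFIED] * (len(RANK_PREFIXES) - len(names))
    # Suffix rule: below the first unclassified rank everything must be too.
    seen = False
    for rank, name in zip(RANKS, names):
        if name == UNCLASSIFIED:
            seen = True
        elif seen:
            raise ParseError(
                f"{where}: rank {rank!r} named below an unclassified rank"
            )
    return tuple(names)


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column TSV of taxon id and semicolon-joined lineage."""
    path = Path(path)
    lineages: dict[str, tuple[str, ...]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line.lower().startswith(("otu\t", "taxon")):
                continue  # optional header
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected taxon id and lineage"
                )
            taxon = fields[0]
            if taxon in lineages:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate taxon id {taxon!r}"
                )
            lineages[taxon] = parse_lineage_string(
                fields[-1], where=f"{path}: line {lineno}"
            )
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for taxon, lineage in tax.lineages.items():
            parts = [
                prefix + ("" if name == UNCLASSIFIED else name)
                for prefix, name in zip(RANK_PREFIXES, lineage)
            ]
            fh.write(f"{taxon}\t{';'.join(parts)};\n")


# ---------------------------------------------------------------------------
# Metadata


def read_metadata(path) -> SiteMetadata:
    """Read site metadata TSV keyed by sample id.

    Requires a ``bibi`` column in [1, 5]; ``season``/``medium`` are
    validated when present. Unrecognised columns are carried through as
    environmental covariates with a logged note.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    known = {"bibi", "season", "medium"}
    # Environmental variable names as abbreviated in the source survey.
    env_known = {
        "pH", "ANC", "DOC", "TN", "NO3", "NH3", "TP", "OPhos", "Cl",
        "SO4", "Cond", "Carbon", "Forest", "Urban", "Agriculture",
        "ISC", "Human", "Area", "Embed", "Epi",
    }
    unknown = [c for c in frame.columns if c not in known | env_known]
    if unknown:
        logger.warning(
            "%s: unrecognised metadata columns carried through: %s",
            path, unknown,
        )
    try:
        return SiteMetadata(frame)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_metadata(meta: SiteMetadata, path) -> None:
    meta.frame.to_csv(Path(path), sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Reports


def write_report(report, path) -> None:
    """Write an assessment report as JSON plus a sibling ``.txt`` digest.

    ``report`` is any object with ``to_dict()`` and ``text_digest()``
    (see :class:`streamdapc.assessment.AssessmentReport`).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
    digest = path.with_suffix(".txt")
    with digest.open("w", encoding="utf-8") as fh:
        fh.write(report.text_digest())


def read_report(path) -> dict:
    """Read back the JSON form of a written report."""
    with Path(path).open("r", encoding="utf-8") as fh:
        return json.load(fh)
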