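"""End-to-end orchestration: filter, rarefy, aggregate, evaluate, select.

One assessment per requested combination of taxonomic level, season and
medium — the combinations are analysed separately, never pooled, since the
community structure of a summer sediment sample has little in common with a
spring water-column one. A failing combination is logged and skipped; the
others proceed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sdio
from .assessment import (
    AssessmentConfig,
    AssessmentReport,
    resample_evaluate,
    restricted_reassessment,
)
from .containers import LEVELS, OtuTable, SiteMetadata, TaxonomyMap
from .preprocess import aggregate, rarefy

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full multi-combination run.

    ``table``, ``taxonomy`` and ``metadata`` may be filesystem paths or
    already loaded objects. ``seasons``/``media`` of ``None`` mean "no
    filter" (a single unfiltered combination per level).
    """

    table: object
    taxonomy: object
    metadata: object
    levels: tuple[str, ...] = ("order",)
    seasons: tuple[str, ...] | None = None
    media: tuple[str, ...] | None = None
    assessment: AssessmentConfig = field(default_factory=AssessmentConfig)
    restricted: bool = True
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        bad = [lv for lv in self.levels if lv not in LEVELS]
        if bad:
            raise ValueError(f"unknown levels: {bad}; valid: {LEVELS}")


def _load(cfg: RunConfig) -> tuple[OtuTable, TaxonomyMap, SiteMetadata, dict]:
    digests = {}
    table, taxonomy, metadata = cfg.table, cfg.taxonomy, cfg.metadata
    if not isinstance(table, OtuTable):
        digests["table"] = _file_digest(table)
        table = sdio.read_otu_table(table)
    if not isinstance(taxonomy, TaxonomyMap):
        digests["taxonomy"] = _file_digest(taxonomy)
        taxonomy = sdio.read_taxonomy(taxonomy)
    if not isinstance(metadata, SiteMetadata):
        digests["metadata"] = _file_digest(metadata)
        metadata = sdio.read_metadata(metadata)
    return table, taxonomy, metadata, digests


def _file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _filter_samples(
    table: OtuTable, meta: SiteMetadata, season: str | None, medium: str | None
) -> OtuTable:
    keep = pd.Series(True, index=table.counts.index)
    frame = meta.frame.reindex(table.counts.index)
    if season is not None:
        keep &= frame["season"] == season
    if medium is not None:
        keep &= frame["medium"] == medium
    return table.select_samples(table.counts.index[keep])


def run_full_assessment(
    cfg: RunConfig,
) -> tuple[dict[tuple, AssessmentReport], pd.DataFrame]:
    """Run the whole protocol per (level, season, medium) combination.

    Per combination: filter samples, rarefy to the configured depth,
    aggregate to the level, evaluate by resampling, then (when
    ``cfg.restricted``) re-evaluate restricted to the indicator taxa.
    Returns the report per combination plus a summary table of mean
    training, validation and fuzzy-validation accuracies. Raises if every
    requested combination fails or yields no samples.
    """
    table, taxonomy, metadata, digests = _load(cfg)
    acfg = cfg.assessment
    seasons = cfg.seasons if cfg.seasons is not None else (None,)
    media = cfg.media if cfg.media is not None else (None,)

    reports: dict[tuple, AssessmentReport] = {}
    rows = []
    for season in seasons:
        for medium in media:
            subset = _filter_samples(table, metadata, season, medium)
            if subset.shape[0] == 0:
                logger.warning(
                    "combination season=%s medium=%s: no samples, skipped",
                    season, medium,
                )
                continue
            try:
                rarefied = rarefy(
                    subset, depth=acfg.rarefaction_depth, seed=acfg.seed
                )
            except Exception:
                logger.exception(
                    "rarefaction failed for season=%s medium=%s", season, medium
                )
                continue
            for level in cfg.levels:
                key = (level, season or "all", medium or "all")
                try:
                    rank_table = aggregate(rarefied, taxonomy, level)
                    if cfg.restricted:
                        report = restricted_reassessment(
                            rank_table, metadata, acfg
                        )
                    else:
                        report = resample_evaluate(rank_table, metadata, acfg)
                except Exception:
                    logger.exception("combination %s failed, skipped", key)
                    continue
                report.provenance.update(
                    {
                        "level": level,
                        "season": season,
                        "medium": medium,
                        "seed": acfg.seed,
                        "config_digest": _config_digest(cfg),
                        **{f"file_{k}": v for k, v in digests.items()},
                    }
                )
                reports[key] = report
                rows.append(
                    {
                        "level": level,
                        "season": season or "all",
                        "medium": medium or "all",
                        "train_overall": report.summary["train_overall"]["mean"],
                        "val_overall": report.summary["val_overall"]["mean"],
                        "val_fuzzy": report.summary["val_fuzzy"]["mean"],
                    }
                )
    if not reports:
        raise RuntimeError("no requested combination produced a report")
    summary = pd.DataFrame(rows)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (level, season, medium), report in reports.items():
            sdio.write_report(
                report, out / f"report_{level}_{season}_{medium}.json"
            )
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return reports, summary


def _config_digest(cfg: RunConfig) -> str:
    doc = {
        "levels": list(cfg.levels),
        "seasons": list(cfg.seasons) if cfg.seasons else None,
        "media": list(cfg.media) if cfg.media else None,
        "assessment": cfg.assessment.to_dict(),
        "restricted": cfg.restricted,
    }
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode()
    ).hexdigest()[:16]
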