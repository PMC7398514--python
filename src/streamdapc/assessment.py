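"""Classification assessment against discretised stream-condition scores.

The continuous benthic index of biotic integrity (BIBI, 1 = very poor to
5 = very good) is cut into eight 0.5-unit categories and a DAPC is trained
to predict the category from community composition. Because the cut points
are arbitrary, accuracy is reported two ways: *overall* (exact category
match) and *fuzzy* (a prediction into the observed or an adjacent category,
|delta| <= 1, counts as correct). Cohen's kappa, with a permutation test,
corrects both for the non-uniform category distribution. Model performance
is estimated by repeated 80/20 train/validation resampling; indicator taxa
are the variables whose discriminant-axis contributions reach a threshold
(0.03 on one of the first three axes by default), and the whole evaluation
can be re-run restricted to that subset.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import OtuTable, RankTable, SiteMetadata
from .dapc import DAPC

logger = logging.getLogger(__name__)

N_CATEGORIES = 8
CATEGORY_WIDTH = 0.5
#: Cut points 1.0, 1.5, ..., 5.0 bounding the eight categories.
CATEGORY_BOUNDARIES = tuple(1.0 + CATEGORY_WIDTH * i for i in range(N_CATEGORIES + 1))


def discretize_bibi(score) -> int | np.ndarray:
    """Map BIBI scores in [1, 5] to category indices 1..8.

    Categories are half-open on the left, ``(a, a + 0.5]``, with the lower
    endpoint 1.0 folded into category 1 — so 3.9 falls in category 6
    (3.51-4.0) and 4.1 in category 7, and 5.0 in category 8.
    """
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 1.0) or np.any(arr > 5.0):
        raise ValueError(f"BIBI score outside [1, 5]: {score!r}")
    # guard against representation noise right at a cut point
    cat = np.ceil((arr - 1.0) / CATEGORY_WIDTH - 1e-9).astype(int)
    cat = np.clip(cat, 1, N_CATEGORIES)
    return cat if arr.ndim else int(cat)


def fuzzy_match(predicted: int, observed: int, window: int = 1) -> bool:
    """True when ``|predicted - observed| <= window`` (both in 1..8)."""
    for v in (predicted, observed):
        if not 1 <= v <= N_CATEGORIES:
            raise ValueError(f"category index out of range: {v}")
    return abs(predicted - observed) <= window


def confusion_table(observed, predicted) -> np.ndarray:
    """8x8 observed x predicted count table from category indices."""
    observed = np.asarray(observed, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    table = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=int)
    np.add.at(table, (observed - 1, predicted - 1), 1)
    return table


def _agreement_mask(fuzzy: bool, window: int = 1) -> np.ndarray:
    i = np.arange(N_CATEGORIES)
    delta = np.abs(i[:, None] - i[None, :])
    return delta <= (window if fuzzy else 0)


def accuracy(confusion, fuzzy: bool = False, window: int = 1) -> float:
    """Overall (trace/total) or fuzzy (|i - j| <= window mass) accuracy."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("empty confusion table")
    return float(confusion[_agreement_mask(fuzzy, window)].sum() / total)


def cohens_kappa(confusion, fuzzy: bool = False, window: int = 1) -> float:
    """Chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e).

    Plain form uses exact agreement; the fuzzy form restricts both the
    observed and the expected agreement to the |i - j| <= window set
    (binary-weighted kappa). When p_e = 1 kappa is defined as 0.
    """
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("empty confusion table")
    mask = _agreement_mask(fuzzy, window)
    p_o = confusion[mask].sum() / total
    row = confusion.sum(axis=1) / total
    col = confusion.sum(axis=0) / total
    p_e = float((row[:, None] * col[None, :])[mask].sum())
    if p_e >= 1.0 - 1e-15:
        logger.info("cohens_kappa: expected agreement is 1; kappa set to 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_permutation_pvalue(
    observed,
    predicted,
    fuzzy: bool = False,
    n_permutations: int = 1000,
    seed: int = 0,
    window: int = 1,
    randomize_ties: bool = False,
) -> float:
    """One-sided permutation p-value for kappa exceeding chance.

    Predicted labels are permuted against observed ones ``n_permutations``
    times; by default p = (1 + #{kappa_perm >= kappa_obs}) / (1 + B), the
    conservative estimator. Because the margins are fixed under
    permutation, kappa is a monotone function of the integer agreement
    count and ties are frequent; ``randomize_ties=True`` breaks them with
    a uniform draw, which makes the p-value exactly uniform under the
    null (at the cost of a randomised decision on tied statistics).
    """
    observed = np.asarray(observed, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    rng = np.random.default_rng(seed)
    k_obs = cohens_kappa(confusion_table(observed, predicted), fuzzy, window)
    above = 0
    tied = 0
    for _ in range(n_permutations):
        perm = rng.permutation(predicted)
        k_perm = cohens_kappa(confusion_table(observed, perm), fuzzy, window)
        if k_perm > k_obs + 1e-12:
            above += 1
        elif k_perm >= k_obs - 1e-12:
            tied += 1
    if randomize_ties:
        return (above + rng.uniform() * (1 + tied)) / (1 + n_permutations)
    return (1 + above + tied) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# Configuration and report containers


@dataclass
class AssessmentConfig:
    """Knobs of the resampling evaluation.

    Defaults follow the study protocol: 1,000 iterations of an 80/20
    train/validation split, PCA retention at 95% cumulative variance,
    indicator selection at contribution >= 0.03 on one of the first three
    discriminant axes, a +/-1-category fuzzy window and a rarefaction depth
    of 1,344 reads.
    """

    train_fraction: float = 0.8
    n_replicates: int = 1000
    variance_fraction: float = 0.95
    scale: bool = False
    loading_threshold: float = 0.03
    n_loading_axes: int = 3
    fuzzy_window: int = 1
    rarefaction_depth: int = 1344
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        for name in (
            "n_replicates", "variance_fraction", "loading_threshold",
            "n_loading_axes", "fuzzy_window", "rarefaction_depth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class AssessmentReport:
    """Per-replicate and summary results of a resampling evaluation."""

    config: dict
    n_samples: int
    n_variables: int
    category_counts: dict[int, int]
    replicates: pd.DataFrame  # columns: train_overall, train_fuzzy, val_overall, val_fuzzy
    summary: dict[str, dict[str, float]]  # metric -> {mean, ci_low, ci_high}
    confusion: np.ndarray  # pooled validation observed x predicted
    kappa: dict[str, float]  # overall/fuzzy kappa + permutation p-values
    selected_taxa: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        doc = {
            "config": self.config,
            "n_samples": self.n_samples,
            "n_variables": self.n_variables,
            "category_counts": {str(k): int(v) for k, v in self.category_counts.items()},
            "replicates": {
                c: self.replicates[c].tolist() for c in self.replicates.columns
            },
            "summary": self.summary,
            "confusion": np.asarray(self.confusion).tolist(),
            "kappa": self.kappa,
            "provenance": self.provenance,
        }
        if self.selected_taxa is not None:
            doc["selected_taxa"] = {
                "taxon": self.selected_taxa.index.tolist(),
                **{
                    c: self.selected_taxa[c].tolist()
                    for c in self.selected_taxa.columns
                },
            }
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "AssessmentReport":
        selected = None
        if "selected_taxa" in doc:
            sel = dict(doc["selected_taxa"])
            taxa = sel.pop("taxon")
            selected = pd.DataFrame(sel, index=taxa)
        return cls(
            config=doc["config"],
            n_samples=doc["n_samples"],
            n_variables=doc["n_variables"],
            category_counts={int(k): v for k, v in doc["category_counts"].items()},
            replicates=pd.DataFrame(doc["replicates"]),
            summary=doc["summary"],
            confusion=np.asarray(doc["confusion"]),
            kappa=doc["kappa"],
            selected_taxa=selected,
            provenance=doc.get("provenance", {}),
        )

    def text_digest(self) -> str:
        lines = [
            "Stream-condition classification report",
            f"samples: {self.n_samples}   variables: {self.n_variables}",
            f"replicates: {len(self.replicates)}",
            "",
            f"{'metric':<16}{'mean':>8}{'2.5%':>8}{'97.5%':>8}",
        ]
        for metric, stats in self.summary.items():
            lines.append(
                f"{metric:<16}{stats['mean']:>8.3f}"
                f"{stats['ci_low']:>8.3f}{stats['ci_high']:>8.3f}"
            )
        lines.append("")
        for key, value in self.kappa.items():
            lines.append(f"kappa[{key}] = {value:.4f}")
        if self.selected_taxa is not None:
            lines.append("")
            lines.append(f"selected taxa ({len(self.selected_taxa)}):")
            for taxon, row in self.selected_taxa.iterrows():
                lines.append(f"  {taxon}  max_contribution={row['max_contribution']:.4f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Resampling evaluation


def _extract_matrix(X) -> pd.DataFrame:
    if isinstance(X, (OtuTable, RankTable)):
        return X.counts.astype(float)
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    raise TypeError(f"expected OtuTable, RankTable or DataFrame, got {type(X)}")


def _categories_for(X: pd.DataFrame, meta: SiteMetadata) -> np.ndarray:
    meta.require(X.index)
    return discretize_bibi(meta.bibi.loc[X.index].to_numpy())


def _split_metrics(model: DAPC, X: np.ndarray, cats: np.ndarray, window: int):
    pred = model.predict(X).astype(int)
    conf = confusion_table(cats, pred)
    return (
        accuracy(conf, fuzzy=False),
        accuracy(conf, fuzzy=True, window=window),
        pred,
    )


def resample_evaluate(
    X, meta: SiteMetadata, cfg: AssessmentConfig | None = None
) -> AssessmentReport:
    """Repeated 80/20 train/validation evaluation of the DAPC classifier.

    Each replicate draws ``ceil(train_fraction * n)`` samples without
    replacement (unstratified), refits the DAPC on the training split and
    scores both splits for overall and fuzzy accuracy. A replicate whose
    training split holds fewer than two categories is redrawn (at most 100
    attempts, logged). Validation samples whose observed category was
    absent from training count as errors for overall accuracy and are
    scored normally under the fuzzy window. Summaries are means with 2.5/
    97.5 percentile intervals over replicates; kappa (plain and fuzzy, with
    permutation p-values) is computed on the pooled validation confusion.
    Fully reproducible from ``cfg.seed``.
    """
    cfg = cfg or AssessmentConfig()
    frame = _extract_matrix(X)
    n = frame.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    cats = _categories_for(frame, meta)
    if len(np.unique(cats)) < 2:
        raise ValueError("need at least 2 observed categories")
    values = frame.to_numpy()
    n_train = int(np.ceil(cfg.train_fraction * n))
    if n_train >= n:
        n_train = n - 1

    root = np.random.SeedSequence(cfg.seed)
    rep_seeds = root.spawn(cfg.n_replicates + 1)
    rows = []
    pooled_obs: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    redraws = 0
    for r in range(cfg.n_replicates):
        rng = np.random.default_rng(rep_seeds[r])
        for attempt in range(100):
            train_idx = rng.choice(n, size=n_train, replace=False)
            if len(np.unique(cats[train_idx])) >= 2:
                break
            redraws += 1
        else:
            raise RuntimeError(
                "could not draw a training split with 2+ categories in "
                "100 attempts"
            )
        val_mask = np.ones(n, dtype=bool)
        val_mask[train_idx] = False
        model = DAPC(
            variance_fraction=cfg.variance_fraction, scale=cfg.scale
        ).fit(values[train_idx], cats[train_idx])
        tr_o, tr_f, _ = _split_metrics(
            model, values[train_idx], cats[train_idx], cfg.fuzzy_window
        )
        va_o, va_f, va_pred = _split_metrics(
            model, values[val_mask], cats[val_mask], cfg.fuzzy_window
        )
        pooled_obs.append(cats[val_mask])
        pooled_pred.append(va_pred)
        rows.append((tr_o, tr_f, va_o, va_f))
    if redraws:
        logger.info("resample_evaluate: %d degenerate splits redrawn", redraws)

    replicates = pd.DataFrame(
        rows, columns=["train_overall", "train_fuzzy", "val_overall", "val_fuzzy"]
    )
    summary = {
        col: {
            "mean": float(replicates[col].mean()),
            "ci_low": float(np.percentile(replicates[col], 2.5)),
            "ci_high": float(np.percentile(replicates[col], 97.5)),
        }
        for col in replicates.columns
    }
    obs_all = np.concatenate(pooled_obs)
    pred_all = np.concatenate(pooled_pred)
    pooled = confusion_table(obs_all, pred_all)
    perm_seed = int(np.random.default_rng(rep_seeds[-1]).integers(2**31 - 1))
    kappa = {
        "overall": cohens_kappa(pooled, fuzzy=False),
        "fuzzy": cohens_kappa(pooled, fuzzy=True, window=cfg.fuzzy_window),
        "overall_pvalue": kappa_permutation_pvalue(
            obs_all, pred_all, fuzzy=False,
            n_permutations=cfg.n_permutations, seed=perm_seed,
        ),
        "fuzzy_pvalue": kappa_permutation_pvalue(
            obs_all, pred_all, fuzzy=True, window=cfg.fuzzy_window,
            n_permutations=cfg.n_permutations, seed=perm_seed + 1,
        ),
    }
    uniq, counts = np.unique(cats, return_counts=True)
    return AssessmentReport(
        config=cfg.to_dict(),
        n_samples=n,
        n_variables=frame.shape[1],
        category_counts=dict(zip(uniq.tolist(), counts.tolist())),
        replicates=replicates,
        summary=summary,
        confusion=pooled,
        kappa=kappa,
        provenance={
            "input_digest": _digest_frame(frame),
            "metadata_digest": _digest_frame(meta.frame),
        },
    )


# ---------------------------------------------------------------------------
# Indicator-taxon selection


def select_important_taxa(
    model: DAPC, threshold: float = 0.03, n_axes: int = 3
) -> pd.DataFrame:
    """Taxa whose contribution reaches ``threshold`` on an early axis.

    A taxon is retained when its squared, axis-normalised contribution is
    >= ``threshold`` on at least one of the first ``min(n_axes, available)``
    discriminant axes; the result is ordered by maximum contribution,
    descending, with per-axis columns alongside.
    """
    contrib = model.variable_contributions()
    if not isinstance(contrib, pd.DataFrame):
        contrib = pd.DataFrame(
            contrib,
            index=[f"var{i}" for i in range(contrib.shape[0])],
            columns=[f"LD{a + 1}" for a in range(contrib.shape[1])],
        )
    use = contrib.iloc[:, : min(n_axes, contrib.shape[1])]
    max_contrib = use.max(axis=1)
    selected = contrib.loc[max_contrib >= threshold].copy()
    selected["max_contribution"] = max_contrib[max_contrib >= threshold]
    return selected.sort_values("max_contribution", ascending=False)


def restricted_reassessment(
    X, meta: SiteMetadata, cfg: AssessmentConfig | None = None
) -> AssessmentReport:
    """Two-stage evaluation restricted to indicator taxa.

    Stage 1 fits a DAPC on the full data and selects indicator taxa by
    contribution threshold; stage 2 subsets the table to those taxa and
    re-runs :func:`resample_evaluate` on the subset. The report carries the
    stage-1 selection alongside the stage-2 resampling results.
    """
    cfg = cfg or AssessmentConfig()
    frame = _extract_matrix(X)
    cats = _categories_for(frame, meta)
    stage1 = DAPC(variance_fraction=cfg.variance_fraction, scale=cfg.scale)
    stage1.fit(frame, cats)
    selected = select_important_taxa(
        stage1, threshold=cfg.loading_threshold, n_axes=cfg.n_loading_axes
    )
    if len(selected) < 2:
        raise ValueError(
            f"only {len(selected)} taxa reach contribution "
            f"{cfg.loading_threshold}; lower the threshold"
        )
    restricted = frame.loc[:, selected.index]
    report = resample_evaluate(restricted, meta, cfg)
    report.selected_taxa = selected
    report.provenance["stage1_n_variables"] = frame.shape[1]
    report.provenance["restricted_to"] = selected.index.tolist()
    return report


def _digest_frame(frame: pd.DataFrame) -> str:
    return hashlib.sha256(frame.to_csv().encode()).hexdigest()[:16]
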