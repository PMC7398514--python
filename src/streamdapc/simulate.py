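"""Synthetic microbial community generator for headwater-stream assessment.

Emulates the statistical structure of a normalised 16S survey of small
streams: one table per sampling combination with a fixed per-sample read
depth, a few hundred to a couple thousand OTUs organised into orders with a
long-tailed abundance distribution (a few dominant orders, many rare ones),
a heavy unclassified fraction at fine taxonomic ranks, and a minority of
*signal* taxa whose log-abundance responds to the site's latent condition
score (BIBI). Site condition scores are drawn from the survey's observed
rating-class proportions (very poor : poor : fair : good = 5 : 18 : 23 :
37), uniformly within each class. Composition noise is
Dirichlet-multinomial with a single total-concentration parameter.

Everything is reproducible from a single seed, and the generator returns a
truth record naming the planted signal taxa so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import OtuTable, SiteMetadata, TaxonomyMap

#: Aquatic bacterial/archaeal order names seeding the synthetic name pool.
_REAL_ORDERS = [
    "Rhizobiales", "Pirellulales", "Nitrososphaerales", "Cenarchaeales",
    "Burkholderiales", "Actinomycetales", "Sphingomonadales",
    "Rhodospirillales", "Xanthomonadales", "Myxococcales",
    "Sphingobacteriales", "Solirubrobacterales", "Acidimicrobiales",
    "Syntrophobacterales", "Desulfuromonadales", "Anaerolineales",
    "Nitrospirales", "Planctomycetales", "Verrucomicrobiales", "Opitutales",
]

_PHYLA = [
    "Proteobacteria", "Actinobacteria", "Bacteroidetes", "Planctomycetes",
    "Acidobacteria", "Verrucomicrobia", "Chloroflexi", "Nitrospirae",
    "Crenarchaeota", "Firmicutes",
]

_GREEK = ["Alpha", "Beta", "Gamma", "Delta"]

_STEMS = [
    "Aqui", "Fluvi", "Limno", "Rivu", "Fonti", "Palu", "Sedi", "Torrenti",
    "Benthi", "Hydro", "Pota", "Lacu", "Rheo", "Crena", "Stagni", "Ripari",
]
_SUFFIXES = [
    "cocc", "bacter", "spir", "mon", "myc", "vibri", "thrich", "plancto",
    "chlor", "ferr", "nitr", "sulf",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic community.

    Defaults match the emulated survey: 82 sites at 1,344 reads each, about
    100 orders of roughly 5 OTUs, rating-class mixture 5:18:23:37.
    ``effect_size`` is the log-abundance change of a signal taxon per BIBI
    unit (linear response) or its saturating amplitude (logistic-threshold
    response). ``dispersion`` is the total Dirichlet concentration
    (``inf`` disables compositional noise). With ``signal_placement=
    'clustered'`` the signal OTUs occupy dedicated orders so the signal
    survives order-level aggregation; ``'scattered'`` spreads them across
    ordinary orders, diluting the aggregated signal.
    """

    n_sites: int = 82
    depth: int = 1344
    n_orders: int = 100
    otus_per_order: int = 5
    n_signal_taxa: int = 15
    effect_size: float = 1.0
    response_shape: str = "linear"  # or "logistic-threshold"
    dispersion: float = 500.0
    unclassified_fraction: float = 0.25
    bibi_class_counts: tuple[float, ...] = (5, 18, 23, 37)
    signal_placement: str = "clustered"  # or "scattered"
    season: str = "summer"
    medium: str = "sediment"
    env_gradients: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "depth", "n_orders", "otus_per_order"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_signal_taxa < 0 or self.effect_size < 0:
            raise ValueError("n_signal_taxa and effect_size must be >= 0")
        if self.response_shape not in ("linear", "logistic-threshold"):
            raise ValueError(f"unknown response_shape {self.response_shape!r}")
        if self.signal_placement not in ("clustered", "scattered"):
            raise ValueError(
                f"unknown signal_placement {self.signal_placement!r}"
            )
        if not 0.0 <= self.unclassified_fraction < 1.0:
            raise ValueError("unclassified_fraction must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (inf allowed)")
        if any(c < 0 for c in self.bibi_class_counts) or sum(
            self.bibi_class_counts
        ) <= 0:
            raise ValueError("bibi_class_counts must be non-negative, sum > 0")

    def to_dict(self) -> dict:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        doc["bibi_class_counts"] = list(self.bibi_class_counts)
        return doc


def _order_names(n: int, rng: np.random.Generator) -> list[str]:
    pool = list(_REAL_ORDERS)
    for stem in _STEMS:
        for suf in _SUFFIXES:
            pool.append(f"{stem}{suf}ales")
    if n > len(pool):
        pool += [f"Synthetorder{i:03d}ales" for i in range(n - len(pool))]
    head = pool[: len(_REAL_ORDERS)]
    tail = pool[len(_REAL_ORDERS):]
    rng.shuffle(tail)
    return (head + tail)[:n]


def _draw_bibi(n: int, counts, rng: np.random.Generator) -> np.ndarray:
    probs = np.asarray(counts, dtype=float)
    probs = probs / probs.sum()
    cls = rng.choice(len(probs), size=n, p=probs)
    # rating classes: very poor [1,2), poor [2,3), fair [3,4), good [4,5]
    return np.round(1.0 + cls + rng.uniform(0, 1, size=n), 2).clip(1.0, 5.0)


def _signal_shift(bibi: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    centered = bibi - 3.0
    if cfg.response_shape == "linear":
        return cfg.effect_size * centered
    return cfg.effect_size * np.tanh(centered / 0.5)


def simulate_dataset(
    cfg: SyntheticConfig | None = None,
) -> tuple[OtuTable, TaxonomyMap, SiteMetadata, dict]:
    """Generate one (table, taxonomy, metadata, truth) quadruple.

    Per site: a BIBI score from the rating-class mixture; per-OTU baseline
    log-abundances (order-level Normal(0, 1.5) plus OTU-level Normal(0, 1)
    offsets, giving a few dominant and many rare taxa); signal taxa shifted
    by ``effect_size x (BIBI - 3)`` (or its saturating analogue) with
    alternating direction; composition = softmax of the log-abundances,
    perturbed by a Dirichlet draw at the stated concentration; counts a
    multinomial draw of ``depth`` reads. A stated fraction of non-signal
    OTUs receives lineages truncated at a fine rank. The truth record
    lists signal taxa (with response direction), per-site BIBI and the
    generator parameters.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    # ---- taxonomy scaffold -------------------------------------------
    order_names = _order_names(cfg.n_orders, rng)
    order_sizes = 1 + rng.poisson(max(cfg.otus_per_order - 1, 0), cfg.n_orders)
    otu_order: list[int] = []
    for o, size in enumerate(order_sizes):
        otu_order.extend([o] * size)

    signal_idx: list[int]
    if cfg.n_signal_taxa == 0:
        signal_idx = []
    elif cfg.signal_placement == "clustered":
        # dedicated orders of up to 5 signal OTUs each
        n_extra = int(np.ceil(cfg.n_signal_taxa / 5))
        extra_names = [f"Indicomicrobiales{i + 1:02d}" for i in range(n_extra)]
        start = len(otu_order)
        for j in range(cfg.n_signal_taxa):
            otu_order.append(cfg.n_orders + j // 5)
        order_names = order_names + extra_names
        signal_idx = list(range(start, start + cfg.n_signal_taxa))
    else:
        signal_idx = sorted(
            rng.choice(len(otu_order), size=cfg.n_signal_taxa, replace=False).tolist()
        )

    n_otus = len(otu_order)
    otu_ids = [f"Otu{i + 1:05d}" for i in range(n_otus)]
    n_orders_total = len(order_names)
    order_phylum = rng.integers(0, len(_PHYLA), size=n_orders_total)
    order_class = rng.integers(0, len(_GREEK), size=n_orders_total)

    lineages: dict[str, tuple[str, ...]] = {}
    genus_counter: dict[int, int] = {}
    truncate_otus = set()
    non_signal = [i for i in range(n_otus) if i not in set(signal_idx)]
    n_trunc = int(round(cfg.unclassified_fraction * len(non_signal)))
    if n_trunc:
        truncate_otus = set(
            rng.choice(non_signal, size=n_trunc, replace=False).tolist()
        )
    # truncation rank weights: mostly genus/family, rarely coarser
    trunc_ranks = np.array([1, 2, 3, 4, 5])  # phylum..genus index in lineage
    trunc_weights = np.array([0.03, 0.07, 0.15, 0.25, 0.50])
    for i, oid in enumerate(otu_ids):
        o = otu_order[i]
        name = order_names[o]
        stem = name[:-4] if name.endswith("ales") else name
        phylum = _PHYLA[order_phylum[o]]
        clazz = f"{_GREEK[order_class[o]]}{phylum.lower()}"
        genus_counter[o] = genus_counter.get(o, 0) + 1
        lineage = [
            "Bacteria", phylum, clazz, name,
            f"{stem}aceae", f"{stem}bacter{genus_counter[o]:02d}",
        ]
        if i in truncate_otus:
            cut = int(rng.choice(trunc_ranks, p=trunc_weights))
            lineage[cut:] = ["unclassified"] * (6 - cut)
        lineages[oid] = tuple(lineage)
    tax = TaxonomyMap(lineages)

    # ---- abundances ---------------------------------------------------
    order_base = rng.normal(0.0, 1.5, size=n_orders_total)
    baseline = order_base[np.asarray(otu_order)] + rng.normal(0.0, 1.0, n_otus)
    # signal taxa moderately abundant: indicators sit among the commoner taxa
    baseline[signal_idx] = rng.normal(1.0, 0.5, size=len(signal_idx))
    # Response direction alternates between signal orders (clustered) or
    # between taxa (scattered): co-occurring indicators within one order
    # share ecology and respond the same way, so their aggregate keeps the
    # signal instead of cancelling it.
    if cfg.signal_placement == "clustered":
        groups = np.arange(len(signal_idx)) // 5
    else:
        groups = np.arange(len(signal_idx))
    signs = np.where(groups % 2 == 0, 1.0, -1.0)

    bibi = _draw_bibi(cfg.n_sites, cfg.bibi_class_counts, rng)
    shift = _signal_shift(bibi, cfg)

    site_ids = [f"S{i + 1:03d}" for i in range(cfg.n_sites)]
    counts = np.zeros((cfg.n_sites, n_otus), dtype=np.int64)
    for s in range(cfg.n_sites):
        la = baseline.copy()
        if signal_idx:
            la[signal_idx] += signs * shift[s]
        la -= la.max()
        p = np.exp(la)
        p /= p.sum()
        if np.isfinite(cfg.dispersion):
            alpha = np.maximum(cfg.dispersion * p, 1e-6)
            p = rng.dirichlet(alpha)
        counts[s] = rng.multinomial(cfg.depth, p)

    attrs = pd.DataFrame(
        {"season": cfg.season, "medium": cfg.medium}, index=site_ids
    )
    table = OtuTable(
        pd.DataFrame(counts, index=site_ids, columns=otu_ids), attrs
    )

    # ---- metadata -----------------------------------------------------
    meta_frame = pd.DataFrame(
        {"bibi": bibi, "season": cfg.season, "medium": cfg.medium},
        index=site_ids,
    )
    if cfg.env_gradients:
        z = bibi - 3.0
        meta_frame["pH"] = np.round(6.8 + 0.35 * z + rng.normal(0, 0.4, cfg.n_sites), 2)
        meta_frame["DOC"] = np.round(
            np.exp(1.0 - 0.3 * z + rng.normal(0, 0.4, cfg.n_sites)), 3
        )
        meta_frame["NO3"] = np.round(
            np.exp(-0.5 - 0.4 * z + rng.normal(0, 0.5, cfg.n_sites)), 4
        )
        meta_frame["Embed"] = np.round(
            np.clip(50 - 12 * z + rng.normal(0, 15, cfg.n_sites), 0, 100), 1
        )
    meta = SiteMetadata(meta_frame)

    truth = {
        "signal_taxa": [otu_ids[i] for i in signal_idx],
        "signal_signs": {
            otu_ids[i]: float(s) for i, s in zip(signal_idx, signs)
        },
        "signal_orders": sorted(
            {order_names[otu_order[i]] for i in signal_idx}
        ),
        "bibi": dict(zip(site_ids, bibi.tolist())),
        "config": cfg.to_dict(),
    }
    return table, tax, meta, truth


def simulate_replicate_pair(
    cfg: SyntheticConfig | None = None, within_site_sd: float = 0.3
) -> tuple[SiteMetadata, SiteMetadata]:
    """Two condition scores per site, as from field-replicate sampling.

    The first score is drawn from the rating-class mixture; the second adds
    Gaussian within-site noise with the given standard deviation, truncated
    to [1, 5]. Discretising both and scoring their agreement reproduces the
    replicate-consistency computation pattern (overall vs fuzzy agreement).
    """
    cfg = cfg or SyntheticConfig()
    if within_site_sd < 0:
        raise ValueError("within_site_sd must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    bibi1 = _draw_bibi(cfg.n_sites, cfg.bibi_class_counts, rng)
    bibi2 = np.clip(bibi1 + rng.normal(0, within_site_sd, cfg.n_sites), 1.0, 5.0)
    site_ids = [f"S{i + 1:03d}" for i in range(cfg.n_sites)]
    make = lambda b: SiteMetadata(  # noqa: E731
        pd.DataFrame(
            {"bibi": b, "season": cfg.season, "medium": cfg.medium},
            index=site_ids,
        )
    )
    return make(bibi1), make(np.round(bibi2, 2))
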