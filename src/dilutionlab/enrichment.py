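"""Gene-set enrichment: preranked GSEA and single-sample projections.

The environmental stress response (ESR) — coordinated induction of
stress genes and repression of growth genes — is scored here two ways:

- **Preranked GSEA**: genes are ranked by a metric (log2 pooled ratio
  between two sample pools, or signal-to-noise), and for each gene set
  a weighted Kolmogorov-Smirnov-style running sum is computed; the
  enrichment score (ES) is its maximum signed deviation.  Significance
  uses *gene-set permutation*: random sets of the same size drawn from
  the ranked universe provide the null, giving normalized scores (NES)
  and false discovery rates by positive/negative pooling.

- **ssGSEA**: a per-sample projection that integrates the difference
  between the weighted ECDF of set members and the ECDF of
  non-members down the sample's own expression ranking, optionally
  row-centered across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rnaseq import NormalizedMatrix

__all__ = [
    "RankedList",
    "GeneSetCollection",
    "EnrichmentResult",
    "rank_metric",
    "enrichment_score",
    "gsea_preranked",
    "ssgsea_score",
]


@dataclass(frozen=True)
class RankedList:
    """Genes with metric values, ordered descending (ties by gene id)."""

    genes: np.ndarray
    metrics: np.ndarray

    def __post_init__(self) -> None:
        genes = np.asarray(self.genes, dtype=object)
        metrics = np.asarray(self.metrics, dtype=float)
        if genes.size != metrics.size:
            raise ValueError("genes and metrics must have equal length")
        if len(set(genes)) != genes.size:
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(metrics)):
            raise ValueError("metric values must be finite")
        # stable descending sort with gene-id tiebreak for determinism
        order = np.lexsort((genes, -metrics))
        object.__setattr__(self, "genes", genes[order])
        object.__setattr__(self, "metrics", metrics[order])

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        return cls(genes=s.index.to_numpy(object), metrics=s.to_numpy(float))

    def __len__(self) -> int:
        return self.genes.size


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. parsed from a GMT file)."""

    sets: dict[str, frozenset]

    @classmethod
    def from_dict(cls, d: dict) -> "GeneSetCollection":
        return cls(sets={k: frozenset(v) for k, v in d.items()})

    def restricted_to(self, universe, min_size: int = 2) -> "GeneSetCollection":
        """Intersect every set with a gene universe; drop small sets."""
        uni = frozenset(universe)
        out = {}
        for name, s in self.sets.items():
            inter = s & uni
            if len(inter) >= min_size:
                out[name] = frozenset(inter)
        if not out:
            raise ValueError("no gene set retains >= min_size genes in universe")
        return GeneSetCollection(sets=out)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set ES/NES/p/FDR table plus permutation metadata."""

    table: pd.DataFrame  # index: set name; columns: size, ES, NES, p, FDR
    n_perm: int
    seed: int


def rank_metric(
    nm: NormalizedMatrix,
    poolA: list[str],
    poolB: list[str],
    method: str = "log2_ratio",
    pseudocount: float = 1.0,
) -> RankedList:
    """Rank genes by a two-pool differential metric.

    ``log2_ratio``: log2((meanA + pc)/(meanB + pc)) of expression
    values.  ``signal_to_noise``: (muA - muB)/(sdA + sdB) with each
    pool's sd floored at 0.2*|mean| (the standard convention that
    keeps low-variance genes from dominating).
    """
    cols = set(nm.values.columns)
    if not poolA or not poolB:
        raise ValueError("both pools must be non-empty")
    if set(poolA) & set(poolB):
        raise ValueError("pools must be disjoint")
    missing = (set(poolA) | set(poolB)) - cols
    if missing:
        raise ValueError(f"unknown samples: {sorted(missing)}")
    a = nm.values[list(poolA)]
    b = nm.values[list(poolB)]
    if method == "log2_ratio":
        metric = np.log2(
            (a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount)
        )
    elif method == "signal_to_noise":
        if len(poolA) < 2 or len(poolB) < 2:
            raise ValueError("signal_to_noise needs >= 2 samples per pool")
        mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
        sd_a = np.maximum(a.std(axis=1, ddof=1), 0.2 * mu_a.abs())
        sd_b = np.maximum(b.std(axis=1, ddof=1), 0.2 * mu_b.abs())
        denom = sd_a + sd_b
        if (denom == 0).any():
            raise ValueError(
                "sigmaA + sigmaB is zero after flooring for some genes"
            )
        metric = (mu_a - mu_b) / denom
    else:
        raise ValueError(f"unknown method {method!r}")
    return RankedList.from_series(metric)


def enrichment_score(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> float:
    """Weighted running-sum enrichment score of one gene set.

    Walking down the ranked list, set members ("hits") increment the
    running sum by |metric|**weight normalized so hit increments sum
    to 1; non-members decrement by 1/(N - n_set).  The ES is the
    maximum signed deviation of the running sum from zero; |ES| <= 1.
    """
    hit = np.isin(ranked.genes, list(gene_set))
    n_hit = int(hit.sum())
    n = len(ranked)
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n_hit >= n:
        raise ValueError("gene set must be smaller than the universe")
    w = np.abs(ranked.metrics) ** weight
    wsum = w[hit].sum()
    if wsum == 0:  # all hit metrics exactly zero: fall back to equal weights
        steps = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        steps = np.where(hit, w / wsum, -1.0 / (n - n_hit))
    run = np.cumsum(steps)
    return float(run[np.argmax(np.abs(run))])


def _perm_es(
    ranked: RankedList, size: int, n_perm: int, weight: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES null distribution from random gene sets of a given size."""
    n = len(ranked)
    w = np.abs(ranked.metrics) ** weight
    miss = -1.0 / (n - size)
    out = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=size, replace=False)
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        wsum = w[hit].sum()
        if wsum == 0:
            steps = np.where(hit, 1.0 / size, miss)
        else:
            steps = np.where(hit, w / wsum, miss)
        run = np.cumsum(steps)
        out[i] = run[np.argmax(np.abs(run))]
    return out


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 2,
) -> EnrichmentResult:
    """Preranked GSEA with gene-set permutation statistics.

    For each set (after intersection with the ranked universe) the ES
    is computed; the null is built from ``n_perm`` random same-size
    gene sets.  NES = ES / mean(|ES_perm| of the same sign); nominal p
    is the same-sign tail fraction; FDR q pools normalized permutation
    scores across sets, comparing the fraction of null NES at least as
    extreme with the fraction of observed NES at least as extreme
    (positive and negative scores handled separately), clipped to
    [0, 1].
    """
    rng = np.random.default_rng(seed)
    restricted = sets.restricted_to(ranked.genes, min_size=min_size)
    names, sizes, es_obs = [], [], []
    perm_by_size: dict[int, np.ndarray] = {}
    for name, gs in sorted(restricted.sets.items()):
        names.append(name)
        sizes.append(len(gs))
        es_obs.append(enrichment_score(ranked, gs, weight))
    for size in sorted(set(sizes)):
        perm_by_size[size] = _perm_es(ranked, size, n_perm, weight, rng)
    es_obs = np.array(es_obs)

    nes_obs = np.empty_like(es_obs)
    p_nom = np.empty_like(es_obs)
    nes_perm_all: list[np.ndarray] = []
    for i, size in enumerate(sizes):
        perm = perm_by_size[size]
        pos_mean = np.abs(perm[perm > 0]).mean() if (perm > 0).any() else np.nan
        neg_mean = np.abs(perm[perm < 0]).mean() if (perm < 0).any() else np.nan
        # normalized null, pooled across sets for the FDR step
        nes_perm = np.where(
            perm >= 0, perm / pos_mean, perm / neg_mean
        )
        nes_perm_all.append(nes_perm[np.isfinite(nes_perm)])
        if es_obs[i] >= 0:
            nes_obs[i] = es_obs[i] / pos_mean
            same = perm[perm >= 0]
            p_nom[i] = (
                (same >= es_obs[i]).sum() / same.size if same.size else np.nan
            )
        else:
            nes_obs[i] = es_obs[i] / neg_mean
            same = perm[perm < 0]
            p_nom[i] = (
                (same <= es_obs[i]).sum() / same.size if same.size else np.nan
            )

    pooled = np.concatenate(nes_perm_all) if nes_perm_all else np.array([])
    fdr = np.empty_like(es_obs)
    for i in range(es_obs.size):
        nes = nes_obs[i]
        if not np.isfinite(nes):
            fdr[i] = np.nan
            continue
        if nes >= 0:
            null_tail = (pooled >= nes).sum() / max((pooled >= 0).sum(), 1)
            obs_tail = (nes_obs >= nes).sum() / max((nes_obs >= 0).sum(), 1)
        else:
            null_tail = (pooled <= nes).sum() / max((pooled < 0).sum(), 1)
            obs_tail = (nes_obs <= nes).sum() / max((nes_obs < 0).sum(), 1)
        fdr[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else np.nan

    table = pd.DataFrame(
        {
            "size": sizes,
            "ES": es_obs,
            "NES": nes_obs,
            "p": p_nom,
            "FDR": fdr,
        },
        index=pd.Index(names, name="set"),
    )
    return EnrichmentResult(table=table, n_perm=n_perm, seed=seed)


def ssgsea_score(
    nm: NormalizedMatrix,
    gene_set,
    weight: float = 0.25,
    row_center: bool = True,
) -> pd.Series:
    """Single-sample projection score of one gene set per sample.

    Within each sample, genes are rank-normalized by expression (top
    gene -> 1, bottom -> 1/N, ties broken by gene id) and the score is
    the integrated difference between the weighted ECDF of set members
    (rank**weight weighting, default exponent 0.25) and the uniform
    ECDF of non-members, summed over all list positions.  With
    ``row_center`` the across-sample mean is subtracted, making scores
    relative deviations along the time course.
    """
    genes = nm.values.index.to_numpy(object)
    in_set = np.isin(genes, list(gene_set))
    n = genes.size
    n_hit = int(in_set.sum())
    if n_hit < 2:
        raise ValueError("gene set must share at least 2 genes with the matrix")
    if n_hit >= n:
        raise ValueError("gene set must be smaller than the gene universe")
    if row_center and nm.values.shape[1] < 2:
        raise ValueError("row centering needs at least 2 samples")
    scores = {}
    for sample in nm.values.columns:
        expr = nm.values[sample].to_numpy(float)
        order = np.lexsort((genes, -expr))  # descending, gene-id tiebreak
        hit = in_set[order]
        rank_norm = (n - np.arange(n)) / n  # 1 down to 1/N
        w = rank_norm**weight
        num = np.cumsum(np.where(hit, w, 0.0))
        denom = num[-1]
        ecdf_hit = num / denom
        ecdf_miss = np.cumsum(~hit) / (n - n_hit)
        scores[sample] = float(np.sum(ecdf_hit - ecdf_miss))
    out = pd.Series(scores, name="ssgsea")
    if row_center:
        out = out - out.mean()
    return out
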