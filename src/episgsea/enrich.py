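"""Pre-ranked gene-set enrichment analysis.

The enrichment score (ES) of a gene set against a ranked gene list is the
signed maximal deviation from zero of a weighted Kolmogorov-Smirnov-like
running sum: walking the list from top to bottom, set members ("hits") add
|score|^p / N_R (N_R the sum of |score|^p over hits) and non-members
("misses") subtract 1 / (N - N_H).  Significance is assessed by gene-set
permutation: null ES values come from random same-size gene draws from the
ranked universe; NES normalises ES by the mean same-sign null magnitude,
and FDR q-values follow the pooled same-sign NES ratio.  Leading-edge genes
are the set members at or before the running-sum peak (after, for negative
ES) — the genes that drive the enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import GeneSetCollection
from .genemap import RankedGeneList

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Enrichment of one gene set against one ranked list."""

    name: str
    size: int
    es: float
    nes: float
    p: float
    q: float
    peak: int                       # 1-based rank of the running-sum extremum
    leading_edge: list[str]
    running_sum: np.ndarray | None = None


def filter_gene_sets(
    collection: GeneSetCollection,
    ranked_list: RankedGeneList,
    min_size: int = 20,
    max_size: int = 200,
) -> GeneSetCollection:
    """Restrict sets to the ranked universe and apply inclusive size bounds."""
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    universe = set(ranked_list.genes)
    sets, descriptions = {}, {}
    for name, members in collection:
        kept = members & universe
        if min_size <= len(kept) <= max_size:
            sets[name] = kept
            descriptions[name] = collection.descriptions.get(name, "")
    return GeneSetCollection(sets, descriptions)


def _hit_weights(scores: np.ndarray, p: float):
    """|score|^p weights; falls back to p=0 (unit weights) when all hit
    weights would be zero."""
    return np.abs(scores) ** p


def enrichment_score(ranked_list: RankedGeneList, gene_set, p: float = 1.0):
    """Running-sum enrichment score of ``gene_set`` in ``ranked_list``.

    Returns ``(ES, peak, running_sum)`` with ``peak`` the 1-based rank at
    which the running sum attains its maximal absolute deviation from zero.
    """
    genes = ranked_list.genes
    n = len(genes)
    members = set(gene_set)
    extra = members - set(genes)
    if extra:
        raise ValueError(f"gene set contains genes outside the universe: {sorted(extra)[:3]}")
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set is empty (after restriction to universe)")
    if n_hit == n:
        raise ValueError("gene set equals the whole universe; ES undefined")
    w = _hit_weights(ranked_list.scores, p)
    nr = w[hit].sum()
    if nr == 0:
        logger.warning("all hit weights are zero; falling back to unweighted (p=0) ES")
        w = np.ones(n)
        nr = float(n_hit)
    steps = np.where(hit, w / nr, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    peak0 = int(np.argmax(np.abs(running)))
    return float(running[peak0]), peak0 + 1, running


def _es_from_hit_ranks(hit_ranks: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """Vectorised ES for many hit-rank vectors at once.

    ``hit_ranks``: (B, m) sorted 0-based ranks of the m set members in each
    of B draws; ``w``: per-rank hit weights |score|^p.  Exploits that the
    running sum is extremal immediately after a hit (local max) or just
    before one (local min).
    """
    B, m = hit_ranks.shape
    hw = w[hit_ranks]
    nr = hw.sum(axis=1, keepdims=True)
    unit = nr <= 0
    if unit.any():
        # degenerate all-zero-weight draws: unweighted increments
        hw = np.where(unit, 1.0, hw)
        nr = np.where(unit, float(m), nr)
    cum = np.cumsum(hw, axis=1) / nr
    miss_dec = (hit_ranks - np.arange(m)) / (n - m)
    after = cum - miss_dec
    before = np.concatenate([np.zeros((B, 1)), cum[:, :-1]], axis=1) - miss_dec
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(B), idx]


def leading_edge(result: EnrichmentResult, ranked_list: RankedGeneList, gene_set=None):
    """Set members driving the enrichment: ranks <= peak for positive ES,
    ranks >= peak for negative ES, in rank order."""
    members = set(gene_set) if gene_set is not None else set(result.leading_edge)
    if result.es == 0:
        logger.warning("ES is zero for %s; empty leading edge", result.name)
        return []
    genes = ranked_list.genes
    if result.es > 0:
        return [g for g in genes[: result.peak] if g in members]
    return [g for g in genes[result.peak - 1 :] if g in members]


def preranked_gsea(
    ranked_list: RankedGeneList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    p: float = 1.0,
    keep_profiles: bool = False,
) -> list[EnrichmentResult]:
    """Pre-ranked GSEA with a gene-set permutation null.

    For every set the observed ES is compared with ``n_perm`` ES values of
    random same-size gene draws (without replacement) from the universe.
    NES = ES / mean(same-sign null |ES|); the nominal p-value is the
    fraction of same-sign null ES at least as extreme, floored at
    1/(n_perm+1); FDR q is the pooled same-sign NES ratio, clipped to
    [0, 1] and made monotone non-increasing in |NES|.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    genes = ranked_list.genes
    n = len(genes)
    w = _hit_weights(ranked_list.scores, p)
    rank_of = {g: i for i, g in enumerate(genes)}

    results: list[EnrichmentResult] = []
    null_nes_pos: list[np.ndarray] = []
    null_nes_neg: list[np.ndarray] = []
    for name, members in collection:
        kept = members & set(genes)
        m = len(kept)
        if m == 0 or m == n:
            raise ValueError(f"gene set {name!r} has size {m}; must be 0 < size < {n}")
        es, peak, running = enrichment_score(ranked_list, kept, p=p)
        u = rng.random((n_perm, n))
        hit_ranks = np.sort(np.argpartition(u, m, axis=1)[:, :m], axis=1)
        null_es = _es_from_hit_ranks(hit_ranks, w, n)

        pos = null_es[null_es > 0]
        neg = null_es[null_es < 0]
        if len(pos):
            null_nes_pos.append(pos / pos.mean())
        if len(neg):
            null_nes_neg.append(neg / np.abs(neg).mean())
        same = pos if es > 0 else neg if es < 0 else np.array([])
        if es == 0 or len(same) == 0:
            nes = np.nan
            pval = np.nan
            logger.warning("set %s: no same-sign null ES; NES undefined", name)
        else:
            nes = es / np.abs(same).mean()
            pval = max(
                float((np.abs(same) >= abs(es)).mean()), 1.0 / (n_perm + 1)
            )
        le = []
        if es > 0:
            le = [g for g in genes[:peak] if g in kept]
        elif es < 0:
            le = [g for g in genes[peak - 1 :] if g in kept]
        results.append(
            EnrichmentResult(
                name, m, es, float(nes), pval, np.nan, peak, le,
                running if keep_profiles else None,
            )
        )

    _assign_fdr(results, null_nes_pos, null_nes_neg)
    return results


def _assign_fdr(results, null_nes_pos, null_nes_neg) -> None:
    pooled_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.array([])
    pooled_neg = (
        np.abs(np.concatenate(null_nes_neg)) if null_nes_neg else np.array([])
    )
    obs_pos = np.array([r.nes for r in results if r.nes > 0])
    obs_neg = np.array([abs(r.nes) for r in results if r.nes < 0])
    for r in results:
        if not np.isfinite(r.nes) or r.nes == 0:
            r.q = np.nan
            continue
        pooled = pooled_pos if r.nes > 0 else pooled_neg
        obs = obs_pos if r.nes > 0 else obs_neg
        mag = abs(r.nes)
        num = float((pooled >= mag).mean()) if len(pooled) else np.nan
        den = float((obs >= mag).mean())
        r.q = float(np.clip(num / den, 0.0, 1.0)) if den > 0 else np.nan
    # monotone non-increasing in |NES| within each sign: step-up adjustment,
    # each set takes the minimum raw q over itself and all weaker sets
    for sign in (1, -1):
        group = [r for r in results if np.isfinite(r.nes) and np.sign(r.nes) == sign]
        group.sort(key=lambda r: -abs(r.nes))
        best = np.inf
        for r in reversed(group):  # ascending |NES|
            best = min(best, r.q)
            r.q = best


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.name for r in results],
            "size": [r.size for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "peak": [r.peak for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )


def frame_to_results(frame: pd.DataFrame) -> list[EnrichmentResult]:
    out = []
    for _, row in frame.iterrows():
        le = [g for g in str(row["leading_edge"]).split(",") if g and g != "nan"]
        out.append(
            EnrichmentResult(
                str(row["set"]), int(row["size"]), float(row["ES"]),
                float(row["NES"]), float(row["p"]), float(row["q"]),
                int(row["peak"]), le,
            )
        )
    return out


@dataclass
class LeadingEdgeSummary:
    """Cross-analysis occurrence of leading-edge genes in top gene sets."""

    occurrence: pd.DataFrame      # genes x "analysis::set" binary matrix
    le_fraction: pd.Series        # per column: |leading edge| / set size
    gene_counts: pd.Series        # per gene: number of leading edges it is on
    replicated_genes: list[str]   # on >= 1 leading edge in *every* analysis


def leading_edge_analysis(
    results_by_analysis: dict[str, list[EnrichmentResult]], top_n: int = 10
) -> LeadingEdgeSummary:
    """Summarise leading-edge gene occurrence over the top gene sets.

    Per analysis the ``top_n`` sets by |NES| (ties: smaller q, then set
    name) are retained; the binary occurrence matrix marks genes on each
    set's leading edge, and ``replicated_genes`` lists genes present on a
    leading edge in every supplied analysis.
    """
    columns: dict[str, list[str]] = {}
    sizes: dict[str, int] = {}
    per_analysis_genes: dict[str, set] = {}
    for analysis, results in results_by_analysis.items():
        usable = [r for r in results if np.isfinite(r.nes)]
        if len(usable) < top_n:
            logger.warning(
                "analysis %s has %d usable sets (< top_n=%d); using all",
                analysis, len(usable), top_n,
            )
        usable.sort(key=lambda r: (-abs(r.nes), r.q if np.isfinite(r.q) else 1.0, r.name))
        genes_here: set = set()
        for r in usable[:top_n]:
            col = f"{analysis}::{r.name}"
            columns[col] = list(r.leading_edge)
            sizes[col] = r.size
            genes_here |= set(r.leading_edge)
        per_analysis_genes[analysis] = genes_here

    all_genes = sorted(set().union(*columns.values())) if columns else []
    occ = pd.DataFrame(0, index=all_genes, columns=list(columns), dtype=int)
    for col, le in columns.items():
        occ.loc[le, col] = 1
    frac = pd.Series(
        {col: len(le) / sizes[col] for col, le in columns.items()}, dtype=float
    )
    counts = occ.sum(axis=1)
    replicated = sorted(
        set.intersection(*per_analysis_genes.values()) if per_analysis_genes else set()
    )
    return LeadingEdgeSummary(occ, frac, counts, replicated)
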