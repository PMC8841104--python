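"""SNP-to-gene assignment with windowed intervals, max-score aggregation
into a ranked gene list, and rank-agreement evaluation between methods."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import GeneTable
from .snpscore import FeatureScores

logger = logging.getLogger(__name__)


@dataclass
class SnpGeneMap:
    """Result of windowed SNP-to-gene assignment."""

    gene_to_snps: dict[str, set]
    unmapped: list[str]

    @property
    def n_mapped_genes(self) -> int:
        return len(self.gene_to_snps)


def map_snps_to_genes(
    positions: pd.DataFrame, gene_table: GeneTable, window_bp: int = 10_000
) -> SnpGeneMap:
    """Assign SNPs to genes using windows up- and downstream of each gene.

    A SNP at 1-based position ``bp`` (0-based ``bp0 = bp - 1``) is assigned
    to a gene with 0-based half-open interval [start, end) on the same
    chromosome iff ``start - window_bp <= bp0 < end + window_bp``.  One SNP
    may map to several overlapping genes; SNPs mapping nowhere are returned
    in ``unmapped``.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    if not {"chrom", "bp"} <= set(positions.columns):
        raise ValueError("positions needs columns 'chrom' and 'bp'")

    genes = gene_table.to_frame()
    genes["win_start"] = np.maximum(genes["start"] - window_bp, 0)
    genes["win_end"] = genes["end"] + window_bp
    by_chrom = {c: g for c, g in genes.groupby("chrom", sort=False)}

    gene_to_snps: dict[str, set] = {}
    unmapped: list[str] = []
    for snp_id, row in positions.iterrows():
        chrom = str(row["chrom"])
        if not chrom or chrom.lower() in ("nan", "none"):
            logger.warning("SNP %s: malformed chromosome name %r", snp_id, row["chrom"])
            unmapped.append(str(snp_id))
            continue
        bp0 = int(row["bp"]) - 1
        sub = by_chrom.get(chrom)
        if sub is None:
            unmapped.append(str(snp_id))
            continue
        hit = sub[(sub["win_start"] <= bp0) & (bp0 < sub["win_end"])]
        if hit.empty:
            unmapped.append(str(snp_id))
            continue
        for sym in hit["symbol"]:
            gene_to_snps.setdefault(sym, set()).add(str(snp_id))
    return SnpGeneMap(gene_to_snps, unmapped)


@dataclass
class RankedGeneList:
    """Genes with summary scores, sorted descending (ties by symbol)."""

    genes: list[str]
    scores: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("genes must be unique")
        if self.scores.shape != (len(self.genes),):
            raise ValueError("scores length must match genes")
        order = sorted(
            range(len(self.genes)), key=lambda i: (-self.scores[i], self.genes[i])
        )
        self.genes = [self.genes[i] for i in order]
        self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.genes)

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.genes, name=self.method or "score")

    @classmethod
    def from_series(cls, series: pd.Series, method: str = "") -> "RankedGeneList":
        return cls([str(g) for g in series.index], series.to_numpy(float), method)

    def rank_of(self) -> pd.Series:
        """1-based rank per gene (1 = highest score)."""
        return pd.Series(np.arange(1, len(self) + 1), index=self.genes)


_AGGREGATORS = {"max": np.max, "mean": np.mean, "sum": np.sum}


def gene_scores(
    mapping: SnpGeneMap, feature_scores: FeatureScores, agg: str = "max"
) -> RankedGeneList:
    """Aggregate per-SNP scores into per-gene summary scores.

    The default summary is the maximum score over a gene's assigned SNPs.
    Every mapped SNP must be present in the score table; genes whose SNPs
    are all absent raise instead of being silently dropped.
    """
    if not mapping.gene_to_snps:
        raise ValueError("empty SNP-to-gene mapping")
    fn = _AGGREGATORS[agg]
    lookup = pd.Series(feature_scores.scores, index=feature_scores.snp_ids)
    genes, summary = [], []
    for gene, snps in mapping.gene_to_snps.items():
        missing = [s for s in snps if s not in lookup.index]
        if missing:
            raise KeyError(
                f"gene {gene!r}: SNP(s) {sorted(missing)[:3]} absent from scores"
            )
        genes.append(gene)
        summary.append(float(fn(lookup[sorted(snps)].to_numpy())))
    return RankedGeneList(genes, np.array(summary), feature_scores.method)


def rank_correlation(list_a: RankedGeneList, list_b: RankedGeneList):
    """Spearman rank correlation of two gene rankings on their shared genes.

    Returns (rho, two-sided p); requires at least 3 genes in common.
    Ties receive average ranks.
    """
    a = list_a.to_series()
    b = list_b.to_series()
    common = sorted(set(a.index) & set(b.index))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} genes in common; need >= 3")
    rho, p = stats.spearmanr(a[common].to_numpy(), b[common].to_numpy())
    return float(rho), float(p)
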