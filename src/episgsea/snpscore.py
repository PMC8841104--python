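"""Per-SNP importance scoring: univariate chi-square association and the
Relief-based MultiSURF / MultiSURF* algorithms, with k-fold
cross-validation averaging.

Relief-based algorithms score features by contrasting each target instance
with its *near* neighbors (and, for MultiSURF*, its *far* neighbors), where
near/far are defined per target by adaptive thresholds on the pairwise
distance distribution (mean +/- std/2).  Features whose values differ
between a target and a neighbor are rewarded when the phenotypes differ
(miss) and penalised when they agree (hit); the far-neighbor contributions
of MultiSURF* use the opposite signs.  This detects epistatic interactions
without an exhaustive pair search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .genodata import MISSING, GenotypeDataset


@dataclass
class FeatureScores:
    """Per-SNP importance scores from one ranking method."""

    snp_ids: list[str]
    scores: np.ndarray
    method: str
    n_samples_used: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.snp_ids),):
            raise ValueError("scores length must match snp_ids")
        if self.method.startswith("multisurf") and np.abs(self.scores).max(initial=0) > 1 + 1e-12:
            raise ValueError("Relief scores must lie in [-1, 1]")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.snp_ids, name=self.method)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rsID": self.snp_ids, "score": self.scores, "method": self.method}
        )


def write_scores(scores: FeatureScores, path) -> None:
    scores.to_frame().to_csv(path, sep="\t", index=False)


def read_scores(path) -> FeatureScores:
    frame = pd.read_csv(path, sep="\t", dtype={"rsID": str})
    method = str(frame["method"].iloc[0]) if len(frame) else "unknown"
    return FeatureScores(
        frame["rsID"].tolist(), frame["score"].to_numpy(float), method, 0
    )


# ---------------------------------------------------------------------------
# univariate chi-square
# ---------------------------------------------------------------------------


def chi2_scores(dataset: GenotypeDataset, mode: str = "genotypic") -> FeatureScores:
    """Pearson chi-square case/control association statistic per SNP.

    ``genotypic`` compares the 2x3 genotype-count table (df = observed
    genotype classes - 1); ``allelic`` collapses to a 2x2 allele-count
    table (1 df).  Missing genotypes are dropped per SNP; monomorphic SNPs
    score 0.  The statistic is used purely as a ranking score.
    """
    if mode not in ("genotypic", "allelic"):
        raise ValueError(f"unknown chi2 mode {mode!r}")
    y = dataset.phenotype
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("chi2 requires at least one case and one control")
    G = dataset.genotypes
    # per-class genotype counts via one-hot sums, shape (2, 3, n_snps)
    counts = np.stack(
        [
            np.stack([(G[y == cls] == g).sum(axis=0) for g in (0, 1, 2)])
            for cls in (0, 1)
        ]
    ).astype(float)
    if mode == "allelic":
        # allele counts: ref = 2*n0 + n1, alt = n1 + 2*n2
        ref = 2 * counts[:, 0, :] + counts[:, 1, :]
        alt = counts[:, 1, :] + 2 * counts[:, 2, :]
        counts = np.stack([ref, alt], axis=1)  # (2 classes, 2 alleles, n_snps)

    n = counts.sum(axis=(0, 1))
    row = counts.sum(axis=1)  # class margins (2, n_snps)
    col = counts.sum(axis=0)  # genotype/allele margins (k, n_snps)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row[:, None, :] * col[None, :, :] / n
        cell = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = cell.sum(axis=(0, 1))
    # monomorphic -> single non-empty column -> statistic 0 by construction,
    # but guard against numerical noise / empty SNPs
    n_classes = (col > 0).sum(axis=0)
    chi2[n_classes < 2] = 0.0
    chi2[n == 0] = 0.0
    return FeatureScores(
        list(dataset.snp_ids), chi2, f"chi2_{mode}", dataset.n_samples
    )


# ---------------------------------------------------------------------------
# Relief substrate
# ---------------------------------------------------------------------------


def pairwise_distances(dataset: GenotypeDataset) -> np.ndarray:
    """Normalised mismatch distance between all sample pairs.

    distance(i, j) = #(SNPs with differing non-missing genotypes) /
    #(jointly non-missing SNPs); NaN when no SNP is jointly non-missing.
    """
    G = dataset.genotypes
    valid = (G != MISSING).astype(np.float64)
    matches = np.zeros((dataset.n_samples, dataset.n_samples))
    for g in (0, 1, 2):
        m = (G == g).astype(np.float64)
        matches += m @ m.T
    joint = valid @ valid.T
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = (joint - matches) / joint
    dist[joint == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    return dist


def _neighbor_masks(D: np.ndarray):
    """Per-target near/far boolean masks from adaptive thresholds.

    near_j iff d_ij < mu_i - sigma_i/2, far_j iff d_ij > mu_i + sigma_i/2,
    with mu/sigma over the target's defined (non-NaN, non-self) distances.
    """
    n = D.shape[0]
    near = np.zeros((n, n), dtype=bool)
    far = np.zeros((n, n), dtype=bool)
    for i in range(n):
        d = D[i].copy()
        d[i] = np.nan
        finite = ~np.isnan(d)
        if finite.sum() == 0:
            continue
        mu = d[finite].mean()
        sd = d[finite].std()
        near[i] = finite & (d < mu - sd / 2)
        far[i] = finite & (d > mu + sd / 2)
    return near, far


def _diff_rows(G: np.ndarray, i: int, rows: np.ndarray, continuous: bool) -> np.ndarray:
    """Feature-wise diff between target i and a block of rows; missing
    values contribute 0 (no-evidence rule)."""
    block = G[rows]
    ok = (block != MISSING) & (G[i] != MISSING)
    if continuous:
        return np.where(ok, np.abs(block - G[i]) / 2.0, 0.0)
    return (ok & (block != G[i])).astype(float)


def _relief_scores(
    dataset: GenotypeDataset, star: bool, continuous: bool
) -> FeatureScores:
    if dataset.n_samples < 3:
        raise ValueError("Relief scoring needs at least 3 samples")
    y = dataset.phenotype
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("Relief scoring needs at least 2 samples per class")
    G = dataset.genotypes.astype(np.int16)
    n, p = G.shape
    D = pairwise_distances(dataset)
    near, far = _neighbor_masks(D)
    total = np.zeros(p)
    for i in range(n):
        same = y == y[i]
        for mask, sign in ((near[i], 1.0), (far[i], -1.0)):
            if sign < 0 and not star:
                continue
            hits = np.flatnonzero(mask & same)
            misses = np.flatnonzero(mask & ~same)
            delta = np.zeros(p)
            if len(misses):
                delta += _diff_rows(G, i, misses, continuous).mean(axis=0)
            if len(hits):
                delta -= _diff_rows(G, i, hits, continuous).mean(axis=0)
            total += sign * delta
    denom = 2 * n if star else n
    return FeatureScores(
        list(dataset.snp_ids),
        total / denom,
        "multisurf_star" if star else "multisurf",
        n,
    )


def multisurf_scores(
    dataset: GenotypeDataset, continuous: bool = False
) -> FeatureScores:
    """MultiSURF feature importance: near-neighbor hit/miss scoring with
    per-target adaptive thresholds; scores normalised to [-1, 1]."""
    return _relief_scores(dataset, star=False, continuous=continuous)


def multisurf_star_scores(
    dataset: GenotypeDataset, continuous: bool = False
) -> FeatureScores:
    """MultiSURF* feature importance: near-neighbor scoring as MultiSURF
    plus sign-inverted far-neighbor scoring, normalised to [-1, 1].

    The inverted far terms discard univariate signal and retain interaction
    signal, making this variant an interaction-only detector.
    """
    return _relief_scores(dataset, star=True, continuous=continuous)


# ---------------------------------------------------------------------------
# cross-validation averaging
# ---------------------------------------------------------------------------

METHODS = {
    "chi2_genotypic": lambda ds: chi2_scores(ds, "genotypic"),
    "chi2_allelic": lambda ds: chi2_scores(ds, "allelic"),
    "multisurf": multisurf_scores,
    "multisurf_star": multisurf_star_scores,
}


def cv_average_scores(
    dataset: GenotypeDataset,
    method,
    k: int = 10,
    seed: int = 0,
    score_holdout: bool = False,
    folds: list[np.ndarray] | None = None,
) -> FeatureScores:
    """Average per-SNP scores over a stratified k-fold partition.

    By default each fold's *training* portion (k-1 folds) is scored and the
    k score vectors are averaged; ``score_holdout=True`` scores the held-out
    fold instead.  ``folds`` may supply an explicit partition (list of test
    index arrays) in place of the seeded stratified split.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    fn = METHODS[method] if isinstance(method, str) else method
    name = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    if folds is None:
        counts = np.bincount(dataset.phenotype, minlength=2)
        if counts.min() < k:
            raise ValueError(
                f"cannot stratify {k} folds with class counts {counts.tolist()}"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [test for _, test in splitter.split(dataset.genotypes, dataset.phenotype)]
    all_idx = np.arange(dataset.n_samples)
    acc = None
    n_used = 0
    for test in folds:
        part_idx = np.asarray(test) if score_holdout else np.setdiff1d(all_idx, test)
        part = dataset.take_samples(part_idx)
        fs = fn(part)
        acc = fs.scores if acc is None else acc + fs.scores
        n_used = max(n_used, fs.n_samples_used)
    mean = acc / len(folds)
    return FeatureScores(list(dataset.snp_ids), mean, name, n_used)
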