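"""Shared fixtures: random dataset builders and an exhaustive Relief oracle."""

from __future__ import annotations

import numpy as np
import pytest

from episgsea.genodata import MISSING, GenotypeDataset


def make_dataset(seed, n=20, p=5, missing_frac=0.0, balanced=True):
    """Random genotype dataset with uniform {0,1,2} genotypes."""
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    if missing_frac:
        geno[rng.random((n, p)) < missing_frac] = MISSING
    if balanced:
        pheno = np.r_[np.ones(n // 2), np.zeros(n - n // 2)].astype(np.int8)
    else:
        pheno = rng.integers(0, 2, size=n).astype(np.int8)
        if pheno.sum() < 2 or pheno.sum() > n - 2:
            pheno[: 2] = 1
            pheno[-2:] = 0
    return GenotypeDataset(
        [f"s{i}" for i in range(n)], [f"rs{j}" for j in range(p)], geno, pheno
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


def relief_oracle(dataset, star=False):
    """Exhaustive O(n^2 p) MultiSURF / MultiSURF* reference.

    Enumerates every instance pair, computes normalised mismatch distances
    with pairwise-complete missing handling, applies the per-target
    mean +/- std/2 thresholds, and accumulates the hit/miss (and, starred,
    inverted far) updates feature by feature.
    """
    G = dataset.genotypes.astype(int)
    y = dataset.phenotype
    n, p = G.shape

    def dist(i, j):
        num = den = 0
        for a in range(p):
            if G[i, a] != MISSING and G[j, a] != MISSING:
                den += 1
                num += G[i, a] != G[j, a]
        return num / den if den else None

    D = [[dist(i, j) for j in range(n)] for i in range(n)]
    total = np.zeros(p)
    for i in range(n):
        defined = [D[i][j] for j in range(n) if j != i and D[i][j] is not None]
        if not defined:
            continue
        mu, sd = np.mean(defined), np.std(defined)
        near = [j for j in range(n) if j != i and D[i][j] is not None and D[i][j] < mu - sd / 2]
        far = [j for j in range(n) if j != i and D[i][j] is not None and D[i][j] > mu + sd / 2]
        groups = [(near, 1.0)] + ([(far, -1.0)] if star else [])
        for a in range(p):
            def diff(j):
                if G[i, a] == MISSING or G[j, a] == MISSING:
                    return 0.0
                return float(G[i, a] != G[j, a])

            for group, sign in groups:
                hits = [j for j in group if y[j] == y[i]]
                misses = [j for j in group if y[j] != y[i]]
                delta = 0.0
                if misses:
                    delta += np.mean([diff(j) for j in misses])
                if hits:
                    delta -= np.mean([diff(j) for j in hits])
                total[a] += sign * delta
    return total / ((2 if star else 1) * n)
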