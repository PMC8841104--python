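"""Simulation of genome-wide SNP data containing pure two-locus epistasis.

A pure (strict) epistatic pair is described by a 3x3 penetrance table
``f[i, j] = P(case | g_A = i, g_B = j)`` whose single-locus marginal
penetrances are constant under Hardy-Weinberg genotype frequencies, so
neither locus shows a main effect.  Models are generated at a requested
minor allele frequency, prevalence K and heritability

    h2 = sum_ij p_i q_j (f_ij - K)^2 / (K (1 - K)),

where p and q are the HWE genotype frequencies at the two loci.  Several
pairs can be combined additively (mean penetrance across pairs, so each of
M pairs contributes 1/M of the deviation from K) and padded with no-effect
SNPs to emulate a genome-wide array.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .genodata import GenotypeDataset, GeneTable
import pandas as pd

#: gene symbols used to label the eight functional loci of the default
#: four-pair architecture (members of GO "negative regulation of mRNA
#: splicing")
DEFAULT_FUNCTIONAL_GENES: tuple[str, ...] = (
    "PTBP1", "U2AF2", "SRSF9", "SFSWAP", "PCBP4", "NPM1", "C1QBP", "SAP18",
)

_TOL = 1e-9


def hwe_genotype_freqs(maf: float) -> np.ndarray:
    """HWE genotype frequencies [(1-q)^2, 2q(1-q), q^2] for allele freq q."""
    if not (0 < maf <= 0.5):
        raise ValueError("minor allele frequency must be in (0, 0.5]")
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


def prevalence(table, maf_a: float, maf_b: float) -> float:
    """Population prevalence K = sum_ij p_i q_j f_ij under HWE."""
    table = np.asarray(table, dtype=float)
    if table.shape != (3, 3):
        raise ValueError("penetrance table must be 3x3")
    if (table < 0).any() or (table > 1).any():
        raise ValueError("penetrance values must lie in [0, 1]")
    p = hwe_genotype_freqs(maf_a)
    q = hwe_genotype_freqs(maf_b)
    return float(p @ table @ q)


def heritability(table, maf_a: float, maf_b: float) -> float:
    """Broad-sense heritability of a two-locus penetrance model.

    h2 = sum_ij p_i q_j (f_ij - K)^2 / (K (1 - K)); raises if K is 0 or 1.
    """
    table = np.asarray(table, dtype=float)
    K = prevalence(table, maf_a, maf_b)
    if K <= 0 or K >= 1:
        raise ValueError(f"heritability undefined at prevalence K={K}")
    p = hwe_genotype_freqs(maf_a)
    q = hwe_genotype_freqs(maf_b)
    w = np.outer(p, q)
    return float((w * (table - K) ** 2).sum() / (K * (1 - K)))


@dataclass
class PenetranceModel:
    """A pure two-locus epistatic penetrance model.

    Invariants (checked on construction): the stored prevalence and
    heritability match the table; both single-locus marginal penetrances are
    constant and equal to K (purity), so neither locus has a main effect.
    """

    maf_a: float
    maf_b: float
    table: np.ndarray
    K: float
    h2: float

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        k = prevalence(self.table, self.maf_a, self.maf_b)
        if abs(k - self.K) > _TOL:
            raise ValueError(f"stored K={self.K} != table prevalence {k}")
        h = heritability(self.table, self.maf_a, self.maf_b)
        if abs(h - self.h2) > _TOL:
            raise ValueError(f"stored h2={self.h2} != table heritability {h}")
        p = hwe_genotype_freqs(self.maf_a)
        q = hwe_genotype_freqs(self.maf_b)
        row_marg = self.table @ q          # P(case | g_A = i)
        col_marg = p @ self.table          # P(case | g_B = j)
        resid = max(np.abs(row_marg - self.K).max(), np.abs(col_marg - self.K).max())
        if resid > _TOL:
            raise ValueError(f"model is not pure: marginal residual {resid:.3g}")

    def purity_residual(self) -> float:
        """Largest deviation of any single-locus marginal penetrance from K."""
        p = hwe_genotype_freqs(self.maf_a)
        q = hwe_genotype_freqs(self.maf_b)
        return float(
            max(
                np.abs(self.table @ q - self.K).max(),
                np.abs(p @ self.table - self.K).max(),
            )
        )


def gen_penetrance_model(
    maf: float,
    h2_target: float,
    K: float = 0.35,
    seed: int | None = None,
    max_tries: int = 10_000,
) -> PenetranceModel:
    """Generate a random pure two-locus model with exact heritability.

    The purity conditions (all row and column marginal penetrances equal K)
    form a linear system on the deviations d_ij = f_ij - K whose null space
    has dimension 4.  A random direction in that null space is drawn, scaled
    by the unique positive factor that sets the heritability to
    ``h2_target`` exactly, and rejected if any resulting penetrance leaves
    [0, 1].

    Raises
    ------
    RuntimeError
        If no table with all penetrances in [0, 1] is found within
        ``max_tries`` draws (infeasible K / h2 combination).
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    if not (0 < h2_target < 1):
        raise ValueError("h2_target must be in (0, 1)")
    if not (0 < K < 1):
        raise ValueError("K must be in (0, 1)")
    p = hwe_genotype_freqs(maf)
    q = hwe_genotype_freqs(maf)
    # purity constraints on the flattened deviation vector d (row-major)
    constraints = []
    for i in range(3):
        row = np.zeros(9)
        row[3 * i : 3 * i + 3] = q
        constraints.append(row)
    for j in range(3):
        col = np.zeros(9)
        col[j::3] = p
        constraints.append(col)
    basis = null_space(np.array(constraints))  # 9 x 4
    w = np.outer(p, q).ravel()
    target_var = h2_target * K * (1 - K)

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        d = basis @ rng.standard_normal(basis.shape[1])
        var = float(w @ d ** 2)
        if var < 1e-12:
            continue
        d *= np.sqrt(target_var / var)
        f = K + d
        if (f >= 0).all() and (f <= 1).all():
            table = f.reshape(3, 3)
            return PenetranceModel(
                maf, maf, table,
                K=prevalence(table, maf, maf),
                h2=heritability(table, maf, maf),
            )
    raise RuntimeError(
        f"no feasible pure model found for maf={maf}, h2={h2_target}, K={K} "
        f"in {max_tries} tries; try a smaller h2 or K nearer 0.5"
    )


@dataclass
class SimArchitecture:
    """Layout of a simulated dataset: epistatic pairs plus no-effect SNPs.

    ``functional_labels`` carries one gene symbol per functional locus in
    pair order (locus A then B of pair 1, then pair 2, ...); noise SNPs get
    symbols from ``noise_labels``.  All pair models must share the same
    prevalence K for the additive (mean-penetrance) combination to be exact.
    """

    pairs: list[PenetranceModel]
    n_noise: int = 1000
    noise_maf_range: tuple[float, float] = (0.05, 0.5)
    functional_labels: list[str] | None = None
    noise_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("architecture needs at least one epistatic pair")
        ks = [m.K for m in self.pairs]
        if max(ks) - min(ks) > _TOL:
            raise ValueError("all pair models must share the same prevalence K")
        lo, hi = self.noise_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("noise_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.functional_labels is not None:
            self._check_labels(self.functional_labels, 2 * len(self.pairs), "functional")
        if self.noise_labels is not None:
            self._check_labels(self.noise_labels, self.n_noise, "noise")

    @staticmethod
    def _check_labels(labels, expected, kind) -> None:
        if len(labels) != expected:
            raise ValueError(f"{kind} labels: got {len(labels)}, need {expected}")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate {kind} label")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_snps(self) -> int:
        return 2 * self.n_pairs + self.n_noise

    @property
    def K(self) -> float:
        return self.pairs[0].K


def assign_labels(
    arch: SimArchitecture,
    functional_genes: list[str] | None = None,
    noise_id_pool: list[str] | None = None,
) -> SimArchitecture:
    """Return a copy of ``arch`` with gene labels attached to every SNP.

    ``functional_genes`` must supply one symbol per functional locus
    (2 per pair); the default is the eight mRNA-splicing genes used by the
    reference four-pair architecture.  Noise SNPs consume distinct IDs from
    ``noise_id_pool`` (default: generated NOISExxxxx symbols).
    """
    if functional_genes is None:
        if 2 * arch.n_pairs != len(DEFAULT_FUNCTIONAL_GENES):
            raise ValueError(
                "default functional labels fit 4 pairs; supply functional_genes"
            )
        functional_genes = list(DEFAULT_FUNCTIONAL_GENES)
    SimArchitecture._check_labels(functional_genes, 2 * arch.n_pairs, "functional")
    if noise_id_pool is None:
        noise_id_pool = [f"NOISE{i:05d}" for i in range(arch.n_noise)]
    if len(noise_id_pool) < arch.n_noise:
        raise ValueError(
            f"noise ID pool ({len(noise_id_pool)}) smaller than n_noise ({arch.n_noise})"
        )
    noise = list(noise_id_pool[: arch.n_noise])
    SimArchitecture._check_labels(noise, arch.n_noise, "noise")
    if set(noise) & set(functional_genes):
        raise ValueError("noise labels overlap functional labels")
    return dataclasses.replace(
        arch, functional_labels=list(functional_genes), noise_labels=noise
    )


def default_architecture(
    n_pairs: int = 4,
    maf: float = 0.2,
    h2: float = 0.4,
    K: float = 0.35,
    n_noise: int = 1000,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | None = None,
) -> SimArchitecture:
    """The reference simulation design: four pure epistatic pairs at MAF 0.2
    and heritability 0.4, combined additively, plus 1000 no-effect SNPs."""
    rng = np.random.default_rng(seed)
    pairs = [
        gen_penetrance_model(maf, h2, K, seed=int(rng.integers(2 ** 31)))
        for _ in range(n_pairs)
    ]
    arch = SimArchitecture(pairs, n_noise=n_noise, noise_maf_range=noise_maf_range)
    if 2 * n_pairs == len(DEFAULT_FUNCTIONAL_GENES):
        arch = assign_labels(arch)
    else:
        arch = assign_labels(
            arch, functional_genes=[f"FUNC{i:02d}" for i in range(2 * n_pairs)]
        )
    return arch


def _draw_hwe(rng, freqs: np.ndarray, size) -> np.ndarray:
    """Draw genotypes {0,1,2} from per-SNP HWE class probabilities.

    ``freqs`` is (n_snps, 3); returns int8 array of shape (n_ind, n_snps).
    """
    n_ind, n_snp = size
    u = rng.random((n_ind, n_snp))
    c0 = freqs[:, 0][None, :]
    c1 = (freqs[:, 0] + freqs[:, 1])[None, :]
    return ((u >= c0).astype(np.int8) + (u >= c1).astype(np.int8))


def penetrance_of(
    arch: SimArchitecture,
    functional_geno: np.ndarray,
    governing_pair: np.ndarray | None = None,
) -> np.ndarray:
    """Instance penetrance under the architecture's combination rule.

    With ``governing_pair`` given (one pair index per individual), each
    individual's penetrance is its governing model's f_k(g at pair k) — the
    fraction-based combination in which each of M equally weighted pairs
    governs disease status for 1/M of the population.  Without it, the mean
    penetrance across pairs is returned.  Both rules keep every single-locus
    marginal penetrance equal to K (no main effects); the fraction rule
    preserves each pair's full heritability within its governed fraction,
    the mean rule scales every pair's penetrance deviations by 1/M.

    ``functional_geno`` is (n_ind, 2 * n_pairs) in pair order.
    """
    n = functional_geno.shape[0]
    if governing_pair is not None:
        pen = np.empty(n)
        for k, model in enumerate(arch.pairs):
            sel = governing_pair == k
            pen[sel] = model.table[
                functional_geno[sel, 2 * k], functional_geno[sel, 2 * k + 1]
            ]
        return pen
    pen = np.zeros(n)
    for k, model in enumerate(arch.pairs):
        ga = functional_geno[:, 2 * k]
        gb = functional_geno[:, 2 * k + 1]
        pen += model.table[ga, gb]
    return pen / arch.n_pairs


def simulate_dataset(
    arch: SimArchitecture,
    n_cases: int,
    n_controls: int,
    seed: int | None = None,
    combine: str = "fraction",
    noise_template: GenotypeDataset | None = None,
    max_batches: int = 10_000,
) -> GenotypeDataset:
    """Simulate a balanced case/control genotype dataset.

    Functional genotypes are drawn under HWE at each model's MAF; case
    status is Bernoulli with the combined penetrance (see
    :func:`penetrance_of`): ``combine="fraction"`` lets each pair govern
    status for an equal fraction of individuals, ``combine="mean"`` uses
    the mean penetrance across pairs; individuals
    are rejection-sampled until the case and control quotas are filled.
    No-effect SNPs are independent HWE draws with per-SNP MAFs sampled once
    from ``arch.noise_maf_range`` — or, when ``noise_template`` is given,
    resampled values of (cyclically reused) template columns, emulating
    noise built by permuting real array genotypes.

    SNP columns: functional loci in pair order first, then noise SNPs.
    Synthetic positions place SNP k at chromosome "1", bp ``1 + 100000*k``.
    """
    if combine not in ("fraction", "mean"):
        raise ValueError(f"unknown combination rule {combine!r}")
    if arch.functional_labels is None or arch.noise_labels is None:
        arch = assign_labels(arch)
    rng = np.random.default_rng(seed)
    n_func = 2 * arch.n_pairs
    func_mafs = np.array([m for pair in arch.pairs for m in (pair.maf_a, pair.maf_b)])
    func_freqs = np.stack([hwe_genotype_freqs(m) for m in func_mafs])

    cases, controls = [], []
    need_cases, need_controls = n_cases, n_controls
    batch = max(1024, 2 * (n_cases + n_controls))
    for _ in range(max_batches):
        if need_cases <= 0 and need_controls <= 0:
            break
        g = _draw_hwe(rng, func_freqs, (batch, n_func))
        governing = (
            rng.integers(arch.n_pairs, size=batch) if combine == "fraction" else None
        )
        pen = penetrance_of(arch, g, governing)
        is_case = rng.random(batch) < pen
        if need_cases > 0:
            cases.append(g[is_case][:need_cases])
            need_cases -= len(cases[-1])
        if need_controls > 0:
            controls.append(g[~is_case][:need_controls])
            need_controls -= len(controls[-1])
    else:
        raise RuntimeError(
            "rejection sampling did not fill case/control quotas; "
            "prevalence K may be too extreme"
        )
    func_geno = np.vstack([*cases, *controls])
    n_total = n_cases + n_controls

    if arch.n_noise == 0:
        noise_geno = np.empty((n_total, 0), dtype=np.int8)
    elif noise_template is None:
        noise_mafs = rng.uniform(*arch.noise_maf_range, size=arch.n_noise)
        noise_freqs = np.stack([hwe_genotype_freqs(m) for m in noise_mafs])
        noise_geno = _draw_hwe(rng, noise_freqs, (n_total, arch.n_noise))
    else:
        cols = np.arange(arch.n_noise) % noise_template.n_snps
        rows = rng.integers(noise_template.n_samples, size=(n_total, arch.n_noise))
        noise_geno = noise_template.genotypes[rows, cols]

    geno = np.hstack([func_geno, noise_geno]).astype(np.int8)
    snp_ids = [f"rs{k + 1}" for k in range(arch.n_snps)]
    sample_ids = [f"case{i + 1:05d}" for i in range(n_cases)] + [
        f"ctrl{i + 1:05d}" for i in range(n_controls)
    ]
    phenotype = np.r_[np.ones(n_cases), np.zeros(n_controls)].astype(np.int8)
    positions = pd.DataFrame(
        {"chrom": "1", "bp": 1 + 100_000 * np.arange(arch.n_snps, dtype=np.int64)},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeDataset(sample_ids, snp_ids, geno, phenotype, positions)


def architecture_gene_table(arch: SimArchitecture) -> GeneTable:
    """One synthetic gene per simulated SNP, centred on its position.

    Gene symbols are the architecture's labels; intervals are 1 kb wide and,
    with the 100 kb SNP spacing of :func:`simulate_dataset`, far enough
    apart that each SNP maps to exactly one gene under a +/-10 kb window.
    """
    if arch.functional_labels is None or arch.noise_labels is None:
        arch = assign_labels(arch)
    symbols = list(arch.functional_labels) + list(arch.noise_labels)
    bp0 = 100_000 * np.arange(arch.n_snps, dtype=np.int64)  # 0-based SNP position
    start = np.maximum(bp0 - 500, 0)
    end = bp0 + 500
    return GeneTable(symbols, np.full(arch.n_snps, "1", dtype=object), start, end)


def snp_gene_labels(arch: SimArchitecture) -> dict[str, str]:
    """rsID -> gene symbol for a dataset simulated from ``arch``."""
    if arch.functional_labels is None or arch.noise_labels is None:
        arch = assign_labels(arch)
    labels = list(arch.functional_labels) + list(arch.noise_labels)
    return {f"rs{k + 1}": lab for k, lab in enumerate(labels)}
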