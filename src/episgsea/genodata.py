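"""Data model and I/O for genotype matrices, trios, gene tables, gene sets,
and ranked lists, plus LD pruning, pseudo-control generation, and control
balancing.

Genotypes use additive 0/1/2 coding (count of minor alleles); missing
genotypes are stored as ``MISSING`` (-1).  SNP base-pair positions are
1-based; gene intervals follow the BED convention (0-based, half-open).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype in int8 matrices
MISSING: int = -1

#: default token for a missing genotype in text tables
MISSING_TOKEN: str = "NA"


class ParseError(ValueError):
    """Raised when a text input does not conform to its expected format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _as_genotype_matrix(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError("genotypes must be a 2-D matrix (samples x SNPs)")
    out = arr.astype(np.int8, copy=True)
    bad = ~np.isin(out, (MISSING, 0, 1, 2))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"genotype entry at sample row {i}, SNP column {j} is "
            f"{arr[i, j]!r}; expected 0, 1, 2 or missing"
        )
    return out


@dataclass
class GenotypeDataset:
    """Samples x SNPs matrix of 0/1/2 genotypes with a binary phenotype.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per matrix row.
    snp_ids
        Unique SNP (rsID) identifiers, one per matrix column.
    genotypes
        int8 matrix with entries in {0, 1, 2} or ``MISSING``.
    phenotype
        Per-sample binary status: 0 = control, 1 = case.
    positions
        Optional frame indexed by snp_id with columns ``chrom`` (str) and
        ``bp`` (1-based position, positive int).
    """

    sample_ids: list[str]
    snp_ids: list[str]
    genotypes: np.ndarray
    phenotype: np.ndarray
    positions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        self.genotypes = _as_genotype_matrix(self.genotypes)
        if self.genotypes.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        self.phenotype = np.asarray(self.phenotype).astype(np.int8, copy=True)
        if self.phenotype.shape != (len(self.sample_ids),):
            raise ValueError("phenotype must have one entry per sample")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype entries must be 0 (control) or 1 (case)")
        if self.positions is not None:
            pos = self.positions
            if not {"chrom", "bp"} <= set(pos.columns):
                raise ValueError("positions needs columns 'chrom' and 'bp'")
            if list(pos.index) != self.snp_ids:
                try:
                    pos = pos.loc[self.snp_ids]
                except KeyError as exc:
                    raise ValueError("positions index must cover all snp_ids") from exc
            if (pos["bp"] < 1).any():
                raise ValueError("bp positions are 1-based and must be >= 1")
            self.positions = pd.DataFrame(
                {"chrom": pos["chrom"].astype(str), "bp": pos["bp"].astype(np.int64)},
                index=pd.Index(self.snp_ids, name="snp_id"),
            )

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == 1

    def take_samples(self, index) -> "GenotypeDataset":
        """Row subset / reorder by integer index."""
        index = np.asarray(index, dtype=int)
        return GenotypeDataset(
            [self.sample_ids[i] for i in index],
            list(self.snp_ids),
            self.genotypes[index],
            self.phenotype[index],
            self.positions,
        )

    def take_snps(self, index) -> "GenotypeDataset":
        """Column subset / reorder by integer index."""
        index = np.asarray(index, dtype=int)
        ids = [self.snp_ids[j] for j in index]
        pos = self.positions.iloc[index] if self.positions is not None else None
        return GenotypeDataset(
            list(self.sample_ids), ids, self.genotypes[:, index], self.phenotype, pos
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        pos_eq = (self.positions is None) == (other.positions is None) and (
            self.positions is None or self.positions.equals(other.positions)
        )
        return (
            self.sample_ids == other.sample_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
            and pos_eq
        )


@dataclass
class TrioDataset:
    """Father / mother / child genotypes for case-parent trios.

    All three members share one SNP panel; matrices are n_trios x n_snps
    int8 with ``MISSING`` allowed anywhere.
    """

    trio_ids: list[str]
    snp_ids: list[str]
    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray

    def __post_init__(self) -> None:
        self.trio_ids = [str(t) for t in self.trio_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        if len(set(self.trio_ids)) != len(self.trio_ids):
            raise ValueError("trio_ids must be unique")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        shape = (len(self.trio_ids), len(self.snp_ids))
        for name in ("father", "mother", "child"):
            mat = _as_genotype_matrix(getattr(self, name))
            if mat.shape != shape:
                raise ValueError(f"{name} matrix shape {mat.shape} != {shape}")
            setattr(self, name, mat)

    @property
    def n_trios(self) -> int:
        return len(self.trio_ids)


@dataclass
class GeneTable:
    """Gene coordinates: symbol, chromosome and a 0-based half-open interval."""

    symbols: list[str]
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        self.symbols = [str(s) for s in self.symbols]
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("gene symbols must be unique")
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        n = len(self.symbols)
        if not (len(self.chrom) == len(self.start) == len(self.end) == n):
            raise ValueError("gene table columns must have equal length")
        if (self.start >= self.end).any():
            bad = int(np.argmax(self.start >= self.end))
            raise ValueError(
                f"gene {self.symbols[bad]}: start must be < end "
                f"({self.start[bad]} >= {self.end[bad]})"
            )

    def __len__(self) -> int:
        return len(self.symbols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [str(c) for c in self.chrom],
                "start": self.start,
                "end": self.end,
                "symbol": self.symbols,
            }
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO terms) with free-text descriptions."""

    sets: dict[str, set] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# genotype table I/O
# ---------------------------------------------------------------------------

# dialect: tab-delimited, header "sample_id", rsIDs..., "phenotype";
# missing genotypes written as MISSING_TOKEN.


def read_genotype_table(
    path, sep: str = "\t", missing_token: str = MISSING_TOKEN
) -> GenotypeDataset:
    """Read a delimited 0/1/2 genotype table.

    Expected layout: header row ``sample_id <rsID...> phenotype``, then one
    row per sample.
    """
    raw = pd.read_csv(
        path, sep=sep, header=None, dtype=str, skip_blank_lines=True,
        keep_default_na=False,
    )
    header = [str(x) for x in raw.iloc[0]]
    if header[0] != "sample_id" or header[-1] != "phenotype":
        raise ParseError(
            "genotype table header must start with 'sample_id' and end with 'phenotype'"
        )
    snp_ids = header[1:-1]
    dupes = pd.Index(snp_ids)[pd.Index(snp_ids).duplicated()]
    if len(dupes):
        raise ParseError(f"duplicate rsID in header: {dupes[0]!r}")

    body = raw.iloc[1:]
    sample_ids = body.iloc[:, 0].astype(str).tolist()
    pheno_str = body.iloc[:, -1].astype(str)
    if not pheno_str.isin(["0", "1"]).all():
        bad = sample_ids[int(np.argmax(~pheno_str.isin(["0", "1"]).to_numpy()))]
        raise ParseError(f"sample {bad!r}: phenotype must be 0 or 1")

    geno_str = body.iloc[:, 1:-1].to_numpy(dtype=object) if snp_ids else np.empty(
        (len(sample_ids), 0), dtype=object
    )
    geno = np.full(geno_str.shape, MISSING, dtype=np.int8)
    valid_map = {"0": 0, "1": 1, "2": 2}
    for token, value in valid_map.items():
        geno[geno_str == token] = value
    ok = np.isin(geno_str, list(valid_map)) | (geno_str == missing_token)
    if not ok.all():
        i, j = map(int, np.argwhere(~ok)[0])
        raise ParseError(
            f"sample {sample_ids[i]!r}, SNP {snp_ids[j]!r}: genotype token "
            f"{geno_str[i, j]!r} is not 0/1/2 or {missing_token!r}"
        )
    return GenotypeDataset(
        sample_ids, snp_ids, geno, pheno_str.astype(np.int8).to_numpy()
    )


def write_genotype_table(
    dataset: GenotypeDataset, path, sep: str = "\t", missing_token: str = MISSING_TOKEN
) -> None:
    """Write ``dataset`` in the layout that :func:`read_genotype_table` reads."""
    geno = dataset.genotypes.astype(object)
    geno[dataset.genotypes == MISSING] = missing_token
    frame = pd.DataFrame(geno, columns=dataset.snp_ids)
    frame.insert(0, "sample_id", dataset.sample_ids)
    frame["phenotype"] = dataset.phenotype
    frame.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# trio table I/O (one row per trio member: trio_id, member, rsIDs...)
# ---------------------------------------------------------------------------

_MEMBERS = ("father", "mother", "child")


def read_trio_table(path, sep: str = "\t", missing_token: str = MISSING_TOKEN) -> TrioDataset:
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if list(frame.columns[:2]) != ["trio_id", "member"]:
        raise ParseError("trio table must start with columns 'trio_id', 'member'")
    snp_ids = list(frame.columns[2:])
    trio_ids = list(dict.fromkeys(frame["trio_id"]))
    mats = {}
    for member in _MEMBERS:
        sub = frame[frame["member"] == member].set_index("trio_id")
        if set(sub.index) != set(trio_ids) or len(sub) != len(trio_ids):
            raise ParseError(f"every trio needs exactly one {member!r} row")
        vals = sub.loc[trio_ids, snp_ids].to_numpy(dtype=object)
        geno = np.full(vals.shape, MISSING, dtype=np.int8)
        for token, value in {"0": 0, "1": 1, "2": 2}.items():
            geno[vals == token] = value
        bad = ~(np.isin(vals, ["0", "1", "2"]) | (vals == missing_token))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ParseError(
                f"trio {trio_ids[i]!r} {member}, SNP {snp_ids[j]!r}: bad token {vals[i, j]!r}"
            )
        mats[member] = geno
    return TrioDataset(trio_ids, snp_ids, mats["father"], mats["mother"], mats["child"])


def write_trio_table(
    trios: TrioDataset, path, sep: str = "\t", missing_token: str = MISSING_TOKEN
) -> None:
    rows = []
    for member in _MEMBERS:
        mat = getattr(trios, member).astype(object)
        mat[getattr(trios, member) == MISSING] = missing_token
        part = pd.DataFrame(mat, columns=trios.snp_ids)
        part.insert(0, "member", member)
        part.insert(0, "trio_id", trios.trio_ids)
        rows.append(part)
    out = pd.concat(rows).sort_values(["trio_id", "member"], kind="stable")
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# GMT / RNK / gene table I/O
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members... per line)."""
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_rnk(path) -> pd.Series:
    """Read a two-column RNK file into a gene -> score Series (any order)."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], dtype={0: str})
    if frame["gene"].duplicated().any():
        dup = frame["gene"][frame["gene"].duplicated()].iloc[0]
        raise ParseError(f"duplicate gene symbol in RNK file: {dup!r}")
    try:
        scores = frame["score"].astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric score in RNK file: {exc}") from exc
    return pd.Series(scores.to_numpy(), index=frame["gene"].tolist(), name="score")


def write_rnk(ranked: pd.Series, path) -> None:
    """Write gene scores as RNK, sorted descending by score (ties by gene)."""
    if ranked.index.duplicated().any():
        raise ValueError("ranked list has duplicate gene symbols")
    frame = pd.DataFrame({"gene": ranked.index, "score": ranked.to_numpy()})
    frame = frame.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_positions(path, sep: str = "\t") -> pd.DataFrame:
    """Read a SNP position table (snp_id, chrom, bp; header row) into the
    frame layout used by :class:`GenotypeDataset.positions`."""
    frame = pd.read_csv(path, sep=sep, dtype={"snp_id": str, "chrom": str})
    if not {"snp_id", "chrom", "bp"} <= set(frame.columns):
        raise ParseError("positions table needs columns snp_id, chrom, bp")
    return frame.set_index("snp_id")[["chrom", "bp"]]


def write_positions(positions: pd.DataFrame, path, sep: str = "\t") -> None:
    positions.rename_axis("snp_id").reset_index().to_csv(path, sep=sep, index=False)


def read_gene_table(path, sep: str = "\t") -> GeneTable:
    """Read a BED-like gene table: chrom, start, end, symbol (no header)."""
    frame = pd.read_csv(
        path, sep=sep, header=None, names=["chrom", "start", "end", "symbol"],
        dtype={"chrom": str, "symbol": str},
    )
    return GeneTable(
        frame["symbol"].tolist(),
        frame["chrom"].to_numpy(dtype=object),
        frame["start"].to_numpy(dtype=np.int64),
        frame["end"].to_numpy(dtype=np.int64),
    )


def write_gene_table(table: GeneTable, path, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep, header=False, index=False)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _window_r2(geno: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation with pairwise-complete missing
    handling; pairs with <3 complete observations (or zero variance) get 0."""
    frame = pd.DataFrame(np.where(geno == MISSING, np.nan, geno).astype(float))
    r = frame.corr(min_periods=3).to_numpy()
    r2 = np.square(np.nan_to_num(r, nan=0.0))
    return r2


def ld_prune(
    dataset: GenotypeDataset, r2_max: float = 0.2, window: int = 50, step: int = 5
) -> GenotypeDataset:
    """Greedy sliding-window LD pruning of SNPs.

    Within each window of ``window`` SNPs, one SNP of every pair with squared
    genotype correlation above ``r2_max`` is removed (the earlier SNP of the
    pair is kept); the window then slides by ``step`` SNPs.  Windows never
    span chromosomes.  Survivors keep their original order.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    if window < 2:
        raise ValueError("window must be >= 2 SNPs")
    if step < 1:
        raise ValueError("step must be >= 1")

    if dataset.positions is not None:
        pos = dataset.positions
        order = np.lexsort((pos["bp"].to_numpy(), pos["chrom"].to_numpy()))
        chroms = pos["chrom"].to_numpy()[order]
        groups = [order[chroms == c] for c in pd.unique(chroms)]
    else:
        groups = [np.arange(dataset.n_snps)]

    alive = np.ones(dataset.n_snps, dtype=bool)
    for group in groups:
        start = 0
        while True:
            idx = group[start : start + window]
            live = idx[alive[idx]]
            if len(live) >= 2:
                r2 = _window_r2(dataset.genotypes[:, live])
                for a in range(len(live)):
                    if not alive[live[a]]:
                        continue
                    for b in range(a + 1, len(live)):
                        if alive[live[b]] and r2[a, b] > r2_max:
                            alive[live[b]] = False
            if start + window >= len(group):
                break
            start += step
    survivors = np.flatnonzero(alive)
    return dataset.take_snps(survivors)


# ---------------------------------------------------------------------------
# pseudo-controls and control balancing
# ---------------------------------------------------------------------------


def make_pseudo_controls(trios: TrioDataset) -> GenotypeDataset:
    """Build a case/pseudo-control dataset from case-parent trios.

    Each trio contributes the affected child as a case and an artificial
    control whose genotype counts the parental alleles *not* transmitted to
    the child: ``father + mother - child``.  A (trio, SNP) cell where that
    quantity falls outside {0, 1, 2} is Mendelian-inconsistent; the
    pseudo-control genotype is set missing and a warning is logged.  Cells
    with any missing member are missing in the pseudo-control.  Trios with
    all members missing at every SNP are dropped.
    """
    keep = ~(
        (trios.father == MISSING).all(axis=1)
        & (trios.mother == MISSING).all(axis=1)
        & (trios.child == MISSING).all(axis=1)
    )
    if not keep.all():
        logger.warning("dropping %d all-missing trio(s)", int((~keep).sum()))
    father = trios.father[keep].astype(np.int16)
    mother = trios.mother[keep].astype(np.int16)
    child = trios.child[keep].astype(np.int16)
    trio_ids = [t for t, k in zip(trios.trio_ids, keep) if k]

    any_missing = (father == MISSING) | (mother == MISSING) | (child == MISSING)
    pseudo = father + mother - child
    mendel_bad = ~any_missing & ~np.isin(pseudo, (0, 1, 2))
    if mendel_bad.any():
        logger.warning(
            "%d Mendelian-inconsistent (trio, SNP) cell(s); pseudo-control "
            "genotype set missing",
            int(mendel_bad.sum()),
        )
    pseudo[any_missing | mendel_bad] = MISSING

    n = len(trio_ids)
    geno = np.empty((2 * n, len(trios.snp_ids)), dtype=np.int8)
    geno[0::2] = child.astype(np.int8)
    geno[1::2] = pseudo.astype(np.int8)
    sample_ids = []
    for t in trio_ids:
        sample_ids.extend([f"{t}_case", f"{t}_pseudo"])
    phenotype = np.tile([1, 0], n).astype(np.int8)
    return GenotypeDataset(sample_ids, list(trios.snp_ids), geno, phenotype)


def balance_controls(dataset: GenotypeDataset, seed: int) -> GenotypeDataset:
    """Downsample controls (uniformly, without replacement) to the case count.

    All case rows are kept bit-exactly; selected samples keep their original
    row order, so an already balanced dataset is returned unchanged.
    """
    cases = np.flatnonzero(dataset.phenotype == 1)
    controls = np.flatnonzero(dataset.phenotype == 0)
    if len(controls) < len(cases):
        raise ValueError(
            f"cannot balance: {len(controls)} controls < {len(cases)} cases"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(controls, size=len(cases), replace=False)
    keep = np.sort(np.concatenate([cases, chosen]))
    return dataset.take_samples(keep)
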