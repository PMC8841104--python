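"""Configuration-driven orchestration of the three analysis strategies
(chi-square / MultiSURF / MultiSURF*) from genotypes to enriched gene sets.

A run executes, in order: (trio mode) pseudo-control generation, control
balancing, LD pruning, per-method SNP scoring with cross-validation
averaging, SNP-to-gene mapping and RNK export, size-filtered pre-ranked
GSEA per method, the between-method gene-rank correlation table, and a
cross-method leading-edge summary.  Every stage writes its artifact in a
plain-text module format so stages are independently inspectable, and a
manifest records seeds, versions and record counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, enrich, episim, genemap, genodata, snpscore

logger = logging.getLogger(__name__)

_SEED_MOD = 2 ** 31

# fixed per-stage seed offsets from the master seed, so any stage can be
# re-run in isolation with a known seed
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "balance": 1,
    "cv": 2,
    "gsea": 10,       # + method index
    "synthetic_sets": 20,
}


def stage_seed(master: int, stage: str, offset: int = 0) -> int:
    return (int(master) + STAGE_SEED_OFFSETS[stage] + offset) % _SEED_MOD


@dataclass
class RunConfig:
    """Everything needed for a reproducible end-to-end run."""

    mode: str = "simulate"                      # simulate | case_control | trio
    output_dir: str = "episgsea_run"
    seed: int = 0
    # simulate mode
    simulate: dict = field(default_factory=lambda: {
        "n_pairs": 4, "maf": 0.2, "h2": 0.4, "K": 0.35,
        "n_noise": 1000, "noise_maf": [0.05, 0.5],
        "n_cases": 405, "n_controls": 405, "combine": "fraction",
    })
    # case_control / trio modes
    geno_path: str | None = None
    trio_path: str | None = None
    balance: bool = True
    ld_prune: dict = field(default_factory=lambda: {
        "enabled": True, "r2": 0.2, "window": 50, "step": 5,
    })
    scoring: dict = field(default_factory=lambda: {
        "methods": ["chi2_genotypic", "multisurf", "multisurf_star"], "cv_k": 10,
    })
    mapping: dict = field(default_factory=lambda: {
        "gene_table": None, "window": 10000,
    })
    gsea: dict = field(default_factory=lambda: {
        "gmt": None, "min_size": 20, "max_size": 200, "n_perm": 1000,
        "synthetic_sets": 150, "top_n": 10,
    })

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "case_control", "trio"):
            raise ValueError(f"unknown mode {self.mode!r}")
        # merge user dicts over defaults so partial configs work
        for name in ("simulate", "ld_prune", "scoring", "mapping", "gsea"):
            merged = dict(getattr(RunConfig, "__dataclass_fields__")[name].default_factory())
            merged.update(getattr(self, name) or {})
            setattr(self, name, merged)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def synthetic_gene_sets(
    universe: list[str],
    functional_genes: list[str] | None = None,
    n_random: int = 150,
    size_range: tuple[int, int] = (20, 200),
    seed: int | None = None,
) -> genodata.GeneSetCollection:
    """A GMT-style collection for simulation studies: optionally one
    "functional" set holding the epistatic genes, plus random sets drawn
    uniformly (sizes uniform over ``size_range``) from the universe."""
    rng = np.random.default_rng(seed)
    sets: dict[str, set] = {}
    desc: dict[str, str] = {}
    if functional_genes:
        sets["functional_epistasis"] = set(functional_genes)
        desc["functional_epistasis"] = "genes carrying the simulated epistatic pairs"
    lo, hi = size_range
    hi = min(hi, len(universe) - 1)
    for i in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        name = f"RANDOM_{i + 1:04d}"
        sets[name] = {universe[j] for j in members}
        desc[name] = "random gene set"
    return genodata.GeneSetCollection(sets, desc)


@dataclass
class RunBundle:
    """Paths and in-memory products of one pipeline run."""

    output_dir: Path
    config: RunConfig
    ranked: dict[str, genemap.RankedGeneList]
    results: dict[str, list[enrich.EnrichmentResult]]
    correlations: pd.DataFrame
    leading: enrich.LeadingEdgeSummary
    manifest: dict


def _load_inputs(config: RunConfig, counts: dict):
    """Stage 0-2: obtain a balanced case/control dataset plus gene resources."""
    seed = config.seed
    arch = None
    if config.mode == "simulate":
        sim = config.simulate
        arch = episim.default_architecture(
            n_pairs=sim["n_pairs"], maf=sim["maf"], h2=sim["h2"], K=sim["K"],
            n_noise=sim["n_noise"], noise_maf_range=tuple(sim["noise_maf"]),
            seed=stage_seed(seed, "simulate"),
        )
        dataset = episim.simulate_dataset(
            arch, sim["n_cases"], sim["n_controls"],
            seed=stage_seed(seed, "simulate"), combine=sim["combine"],
        )
    elif config.mode == "case_control":
        if not config.geno_path:
            raise ValueError("case_control mode requires geno_path")
        dataset = genodata.read_genotype_table(config.geno_path)
    else:  # trio
        if not config.trio_path:
            raise ValueError("trio mode requires trio_path")
        trios = genodata.read_trio_table(config.trio_path)
        counts["trios"] = trios.n_trios
        dataset = genodata.make_pseudo_controls(trios)
    counts["samples_in"] = dataset.n_samples
    counts["snps_in"] = dataset.n_snps

    if config.balance and (dataset.phenotype == 0).sum() > (dataset.phenotype == 1).sum():
        dataset = genodata.balance_controls(dataset, seed=stage_seed(seed, "balance"))
    counts["samples_balanced"] = dataset.n_samples

    if config.ld_prune["enabled"]:
        dataset = genodata.ld_prune(
            dataset, r2_max=config.ld_prune["r2"],
            window=config.ld_prune["window"], step=config.ld_prune["step"],
        )
    counts["snps_pruned"] = dataset.n_snps

    if config.mapping["gene_table"]:
        gene_table = genodata.read_gene_table(config.mapping["gene_table"])
    elif arch is not None:
        gene_table = episim.architecture_gene_table(arch)
    else:
        raise ValueError("mapping.gene_table is required outside simulate mode")

    if config.gsea["gmt"]:
        collection = genodata.read_gmt(config.gsea["gmt"])
    elif arch is not None:
        collection = synthetic_gene_sets(
            [str(s) for s in gene_table.symbols],
            functional_genes=list(arch.functional_labels),
            n_random=config.gsea["synthetic_sets"],
            size_range=(config.gsea["min_size"], config.gsea["max_size"]),
            seed=stage_seed(seed, "synthetic_sets"),
        )
    else:
        raise ValueError("gsea.gmt is required outside simulate mode")
    return dataset, gene_table, collection, arch


def run(config: RunConfig) -> RunBundle:
    """Execute the full pipeline; see module docstring for the stage list."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("episgsea")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    counts: dict = {}
    stage = "inputs"
    try:
        logger.info("stage inputs: mode=%s seed=%d", config.mode, config.seed)
        dataset, gene_table, collection, arch = _load_inputs(config, counts)
        genodata.write_genotype_table(dataset, out / "genotypes.tsv")
        genodata.write_gene_table(gene_table, out / "genes.bed")
        genodata.write_gmt(collection, out / "gene_sets.gmt")

        stage = "scoring"
        mapping = genemap.map_snps_to_genes(
            dataset.positions, gene_table, window_bp=config.mapping["window"]
        )
        counts["genes_mapped"] = mapping.n_mapped_genes
        counts["snps_unmapped"] = len(mapping.unmapped)

        ranked: dict[str, genemap.RankedGeneList] = {}
        results: dict[str, list[enrich.EnrichmentResult]] = {}
        cv_k = config.scoring["cv_k"]
        for mi, method in enumerate(config.scoring["methods"]):
            stage = f"scoring[{method}]"
            logger.info("stage %s (cv_k=%s)", stage, cv_k)
            if cv_k and cv_k >= 2:
                fs = snpscore.cv_average_scores(
                    dataset, method, k=cv_k, seed=stage_seed(config.seed, "cv")
                )
            else:
                fs = snpscore.METHODS[method](dataset)
            snpscore.write_scores(fs, out / f"scores_{method}.tsv")

            stage = f"mapping[{method}]"
            glist = genemap.gene_scores(mapping, fs, agg="max")
            genodata.write_rnk(glist.to_series(), out / f"genes_{method}.rnk")
            ranked[method] = glist

            stage = f"gsea[{method}]"
            filtered = enrich.filter_gene_sets(
                collection, glist,
                min_size=config.gsea["min_size"], max_size=config.gsea["max_size"],
            )
            counts[f"gene_sets_{method}"] = len(filtered)
            res = enrich.preranked_gsea(
                glist, filtered, n_perm=config.gsea["n_perm"],
                seed=stage_seed(config.seed, "gsea", mi),
            )
            enrich.results_to_frame(res).to_csv(
                out / f"gsea_{method}.tsv", sep="\t", index=False
            )
            results[method] = res

        stage = "correlation"
        methods = list(ranked)
        rows = []
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                rho, pval = genemap.rank_correlation(ranked[methods[i]], ranked[methods[j]])
                rows.append({"method_a": methods[i], "method_b": methods[j],
                             "rho": rho, "p": pval})
        correlations = pd.DataFrame(rows, columns=["method_a", "method_b", "rho", "p"])
        correlations.to_csv(out / "rank_correlations.tsv", sep="\t", index=False)

        stage = "leading_edge"
        leading = enrich.leading_edge_analysis(results, top_n=config.gsea["top_n"])
        leading.occurrence.to_csv(out / "leading_edge_matrix.tsv", sep="\t")
        leading.le_fraction.rename("le_fraction").to_csv(
            out / "leading_edge_fraction.tsv", sep="\t"
        )

        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "seed": config.seed,
            "stage_seeds": {
                "simulate": stage_seed(config.seed, "simulate"),
                "balance": stage_seed(config.seed, "balance"),
                "cv": stage_seed(config.seed, "cv"),
                "gsea": [stage_seed(config.seed, "gsea", i)
                         for i in range(len(config.scoring["methods"]))],
            },
            "counts": counts,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        logger.info("run complete: %s", counts)
        return RunBundle(out, config, ranked, results, correlations, leading, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def report(bundle: RunBundle, top_n: int = 15) -> dict:
    """Per-method summary: significant-set counts, top sets, leading-edge
    fractions, and the rank-correlation table."""
    if not bundle.results:
        raise ValueError("bundle has no GSEA results")
    summary: dict = {"methods": {}, "correlations": bundle.correlations.to_dict("records")}
    for method, results in bundle.results.items():
        frame = enrich.results_to_frame(results)
        frame = frame.sort_values(
            ["q", "p", "set"], na_position="last", kind="stable"
        ).head(top_n)
        summary["methods"][method] = {
            "n_sets": len(results),
            "n_q_below_0.05": int(sum(1 for r in results if np.isfinite(r.q) and r.q < 0.05)),
            "top_sets": frame[["set", "size", "ES", "NES", "p", "q"]].to_dict("records"),
        }
    frac = bundle.leading.le_fraction
    summary["mean_leading_edge_fraction"] = float(frac.mean()) if len(frac) else 0.0
    summary["replicated_leading_edge_genes"] = bundle.leading.replicated_genes
    return summary
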