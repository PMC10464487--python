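"""End-to-end orchestration of the dual-dataset analysis.

The standard workflow in clonal population genetics runs every
analysis twice: on the *per-individual* dataset (all sampled ramets)
and on the *per-genotype* dataset (one representative per clonal group
per population), since clones bias within-population statistics.  The
pipeline wires the modules together behind one config: clone
detection, clonality statistics, per-population summaries, pairwise
FST with permutations, admixture clustering with Delta-K, DAPC/MSN and
isolation by distance, and writes a consolidated TSV/JSON report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import clonality, clustering, differentiation, ibd, multivariate, popstats
from .genotype_io import GenotypeMatrix, read_csv_genotypes, read_genepop, read_distance_matrix
from .synthetic import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_fixture", "FIXTURE_PROFILES"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run; round-trips to/from JSON."""

    input_path: str | None = None
    distance_path: str | None = None
    output_dir: str = "clonepop_out"
    dataset_modes: tuple[str, ...] = ("per_individual", "per_genotype")
    mll_threshold: int = 4
    mlg_min_loci: int = 4
    n_rand: int = 199
    fst_permutations: int = 199
    run_clustering: bool = True
    k_min: int = 1
    k_max: int = 4
    replicates: int = 2
    burnin: int = 500
    iters: int = 2500
    locprior: bool = False
    run_ibd: bool = True
    ibd_permutations: int = 999
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        obj = json.loads(Path(path).read_text())
        obj["dataset_modes"] = tuple(obj.get("dataset_modes", ()))
        return cls(**obj)


FIXTURE_PROFILES = {
    "clonal": SimConfig(
        n_demes=2, deme_sizes=30, n_loci=6, alleles_per_locus=8,
        target_F=0.1, clonality_c=0.5, seed=11,
    ),
    "panmictic": SimConfig(
        n_demes=3, deme_sizes=25, n_loci=6, alleles_per_locus=8,
        target_F=0.0, seed=12,
    ),
    "three_demes": SimConfig(
        n_demes=3, deme_sizes=30, n_loci=8, alleles_per_locus=6,
        target_F=0.2, seed=13,
    ),
    "stepping_stone": SimConfig(
        n_demes=8, deme_sizes=15, n_loci=6, alleles_per_locus=8,
        target_F=0.25, spatial_mode="stepping_stone", seed=14,
    ),
}


def make_fixture(profile: str):
    """Deterministic miniature dataset (<= 120 individuals) for tests/docs."""
    if profile not in FIXTURE_PROFILES:
        raise KeyError(
            f"unknown profile {profile!r}; choose from {sorted(FIXTURE_PROFILES)}"
        )
    return simulate_dataset(FIXTURE_PROFILES[profile])


def _load_matrix(config: RunConfig) -> GenotypeMatrix:
    path = Path(config.input_path)
    if path.suffix.lower() == ".csv":
        return read_csv_genotypes(path)
    return read_genepop(path)


def _clonal_table(matrix: GenotypeMatrix, partition) -> pd.DataFrame:
    rows = []
    for pop in matrix.population_names():
        s = clonality.clonal_statistics(matrix, partition, pop)
        rows.append(
            {
                "population": pop, "N": s.N, "N_MLG": s.N_MLG, "R": s.R,
                "Go": s.Go, "Ge": s.Ge, "G": s.G, "E_D": s.E_D,
                "simpson_1mD": s.simpson_1mD, "shannon_H": s.shannon_H,
                "mode": s.mode_label,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict it also writes."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = f"[{time.time() - t0:8.2f}s] {msg}"
        logger.info(msg)
        log_lines.append(stamp)

    matrix = _load_matrix(config)
    log(f"loaded {matrix.n_individuals} individuals x {matrix.n_loci} loci")

    partition = clonality.assign_mlg(matrix, min_loci=config.mlg_min_loci)
    mll = clonality.collapse_mll(partition, matrix, config.mll_threshold)
    log(f"MLGs: {partition.n_groups}; MLLs at threshold "
        f"{config.mll_threshold}: {mll.n_groups}")

    datasets: dict[str, GenotypeMatrix] = {}
    for mode in config.dataset_modes:
        if mode == "per_individual":
            datasets[mode] = matrix
        elif mode == "per_genotype":
            datasets[mode] = differentiation.to_per_genotype(matrix, partition)
        else:
            raise ValueError(f"unknown dataset mode {mode!r}")

    report: dict = {"config": asdict(config), "stages": {}}
    for mode, data in datasets.items():
        stage: dict = {}
        t_mode = time.time()
        # clonality table is always computed on the per-individual data;
        # for the truncated data it degenerates to all-singletons.
        part_mode = clonality.assign_mlg(data, min_loci=config.mlg_min_loci)
        tab = _clonal_table(data, part_mode)
        tab.to_csv(out / f"clonal_stats_{mode}.tsv", sep="\t", index=False)
        stage["clonal_stats"] = tab.to_dict(orient="records")
        if len(tab) >= 3 and tab["E_D"].nunique() > 1:
            reg = clonality.diversity_evenness_regression(
                [clonality.clonal_statistics(data, part_mode, p)
                 for p in data.population_names()]
            )
            stage["diversity_evenness_regression"] = asdict(reg)

        het = {p: popstats.heterozygosity(data, p) for p in data.population_names()}
        rich = popstats.allelic_richness_and_private(data)
        fis_res = {
            p: asdict(popstats.fis(data, p, n_boot=200, seed=config.seed))
            for p in data.population_names()
        }
        stage["popstats"] = {
            p: {**het[p], **rich[p], **fis_res[p]} for p in data.population_names()
        }

        fst = differentiation.pairwise_fst_matrix(
            data, n_perm=config.fst_permutations, seed=config.seed, dataset_mode=mode
        )
        fst.to_frame().to_csv(out / f"fst_{mode}.tsv", sep="\t")
        stage["fst"] = {
            "labels": fst.labels,
            "theta": np.round(fst.theta, 6).tolist(),
            "p_perm": None if fst.p_perm is None else np.round(fst.p_perm, 6).tolist(),
        }
        log(f"{mode}: clonality + popstats + FST done")

        if config.run_clustering:
            runs = []
            for K in range(config.k_min, config.k_max + 1):
                for rep in range(config.replicates):
                    runs.append(
                        clustering.run_admixture(
                            data, K,
                            burnin=config.burnin, iters=config.iters,
                            locprior=config.locprior,
                            seed=config.seed * 10007 + K * 101 + rep,
                        )
                    )
            try:
                dk = clustering.evanno_delta_k(runs)
                stage["delta_k"] = {
                    "K": dk.K, "mean_lnPD": dk.mean_lnPD, "sd_lnPD": dk.sd_lnPD,
                    "delta_K": {str(k): v for k, v in dk.delta_K.items()},
                    "optimal_K": dk.optimal_K,
                }
            except ValueError as exc:
                stage["delta_k"] = {"error": str(exc)}
            best_k = stage["delta_k"].get("optimal_K") or config.k_min
            best = [r for r in runs if r.K == best_k]
            aligned = clustering.align_replicates(best)
            q_mean = np.mean([r.Q for r in aligned], axis=0)
            pd.DataFrame(
                q_mean, index=data.individuals,
                columns=[f"cluster{j + 1}" for j in range(best_k)],
            ).to_csv(out / f"q_matrix_{mode}.tsv", sep="\t")
            stage["cluster_assignments"] = clustering.assign_clusters(q_mean).tolist()
            log(f"{mode}: clustering done (optimal K = {best_k})")

        table = multivariate.build_count_table(data)
        try:
            dap = multivariate.dapc(table)
            stage["dapc_reassignment"] = dap.reassignment_proportion
        except ValueError as exc:
            stage["dapc_reassignment"] = None
            log(f"{mode}: DAPC skipped ({exc})")
        nei = multivariate.nei_distance_matrix(data)
        msn = multivariate.minimum_spanning_network(nei)
        stage["msn_edges"] = [(a, b, round(w, 6)) for a, b, w in msn]

        if config.run_ibd and config.distance_path:
            dist = read_distance_matrix(config.distance_path)
            res = ibd.ibd_analysis(
                fst, dist, n_perm=config.ibd_permutations, seed=config.seed
            )
            stage["ibd"] = {
                "slope": res.slope, "intercept": res.intercept,
                "r_squared": res.r_squared, "ols_p": res.ols_p,
                "mantel_r": res.mantel_r, "mantel_p": res.mantel_p,
            }
        stage["elapsed_s"] = round(time.time() - t_mode, 3)
        report["stages"][mode] = stage

    report["total_elapsed_s"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
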