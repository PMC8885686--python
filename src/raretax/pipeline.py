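"""End-to-end orchestration: simulate or load, filter, partition,
diversity, ordination, assembly inference, networks, and environment
association, all under one config with hierarchical seeding.

Re-running an identical config reproduces every output byte-for-byte:
each stage derives its random stream from the top-level seed and a fixed
stage name, outputs carry no timestamps, and the manifest records every
threshold alongside the seeds.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assembly, beta, diversity, env, io, network, partition
from .errors import StageError
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger(__name__)

FRACTIONS = ("whole", "abundant", "rare")


@dataclass
class PipelineConfig:
    """Inputs, thresholds, and problem sizes for one pipeline run."""

    outdir: str = "raretax_out"
    # either provide paths ...
    otu_table: str | None = None
    tree: str | None = None
    metadata: str | None = None
    # ... or simulate
    simulation: SimulationConfig | None = None
    # thresholds (paper defaults)
    abundant_thresh: float = 0.001
    rare_thresh: float = 0.0001
    rho_min: float = 0.6
    p_max: float = 0.01
    bnti_cutoff: float = 2.0
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    min_prevalence: float = 1 / 3
    # problem sizes
    rarefy_depth: int | None = None
    n_null: int = 999
    n_random: int = 100
    n_perm: int = 999
    nmds_starts: int = 50
    weighted_bnti: bool = True
    bnti_within_group_only: bool = True
    seed: int = 0


def default_config(outdir: str = "raretax_out",
                   seed: int = 0) -> PipelineConfig:
    """The default synthetic study: two groups of 15 samples under
    variable environmental filtering, so deterministic assembly and
    environment association are visible end to end."""
    return PipelineConfig(
        outdir=outdir, seed=seed,
        simulation=SimulationConfig(assembly_mode="variable_filtering",
                                    seed=seed))


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return np.random.SeedSequence(
        int.from_bytes(digest[:4], "big") % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return a manifest dict (also written to
    ``manifest.json``). Any stage failure raises :class:`StageError`
    naming the stage; outputs of earlier stages are preserved."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "raretax",
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "abundant_mean_rel_abund": cfg.abundant_thresh,
            "rare_mean_rel_abund": cfg.rare_thresh,
            "spearman_rho_min": cfg.rho_min,
            "edge_p_adj_max": cfg.p_max,
            "abs_bnti_deterministic": cfg.bnti_cutoff,
            "zi_module_hub": cfg.zi_threshold,
            "pi_connector": cfg.pi_threshold,
        },
        "sizes": {"n_null": cfg.n_null, "n_random": cfg.n_random,
                  "n_perm": cfg.n_perm, "nmds_starts": cfg.nmds_starts},
        "stages": [],
        "inputs": {},
    }

    def stage(name):
        def wrap(fn):
            import time

            log.info("stage %s", name)
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.1fs", name,
                     time.perf_counter() - t0)
            manifest["stages"].append(name)
            return result
        return wrap

    # ---- inputs -----------------------------------------------------
    def load_inputs():
        if cfg.simulation is not None:
            data = simulate_dataset(cfg.simulation)
            io.write_otu_table(data.table, out / "otu_table.tsv")
            io.write_tree(data.tree, out / "tree.nwk")
            io.write_metadata(data.metadata, out / "metadata.tsv")
            manifest["inputs"]["simulation"] = asdict(cfg.simulation)
            return data.table, data.tree, data.metadata
        if cfg.otu_table is None or cfg.metadata is None:
            raise ValueError(
                "provide either a simulation config or otu_table + "
                "metadata paths")
        table = io.read_otu_table(cfg.otu_table)
        meta = io.read_metadata(cfg.metadata)
        tree = io.read_tree(cfg.tree) if cfg.tree else None
        for key, p in (("otu_table", cfg.otu_table), ("tree", cfg.tree),
                       ("metadata", cfg.metadata)):
            if p:
                manifest["inputs"][key] = {"path": str(p),
                                           "sha256": _sha256(Path(p))}
        return table, tree, meta

    table, tree, metadata = stage("load_inputs")(load_inputs)
    metadata = metadata.aligned_to(table)

    # ---- filtering / rarefaction ------------------------------------
    def do_filter():
        filtered = diversity.filter_low_count_otus(table)
        if cfg.rarefy_depth is not None:
            rng = _stage_seed(cfg.seed, "rarefy")
            filtered = diversity.rarefy(filtered, cfg.rarefy_depth,
                                        seed=rng)
        return filtered

    table = stage("filter_and_rarefy")(do_filter)

    # ---- partition --------------------------------------------------
    def do_partition():
        classes = partition.classify_taxa(
            table, abundant_thresh=cfg.abundant_thresh,
            rare_thresh=cfg.rare_thresh)
        io.write_classes(classes, out / "classes.tsv")
        _write(partition.partition_summary(table, classes),
               out / "partition_summary.tsv")
        return classes

    classes = stage("partition")(do_partition)

    # ---- alpha diversity --------------------------------------------
    def do_alpha():
        alpha = diversity.alpha_diversity_by_fraction(table, classes)
        alpha = alpha.merge(
            metadata.frame[["group"]], left_on="sample_id",
            right_index=True)
        _write(alpha, out / "alpha.tsv", index=False)
        # group contrasts per fraction/index with one shared FDR family
        tests = []
        glabels = sorted(metadata.group.unique())
        if len(glabels) == 2:
            for fraction in FRACTIONS:
                sub = alpha[alpha["fraction"] == fraction]
                for metric in ("observed_richness", "chao1", "shannon",
                               "simpson", "pielou"):
                    by = {g: sub.loc[sub["group"] == g, metric].to_numpy()
                          for g in glabels}
                    res = beta.wilcoxon_fdr(by, [tuple(glabels)])
                    res.insert(0, "fraction", fraction)
                    res.insert(1, "metric", metric)
                    tests.append(res)
        if tests:
            all_tests = pd.concat(tests, ignore_index=True)
            all_tests["q"] = beta.bh_adjust(all_tests["p"].to_numpy())
            _write(all_tests, out / "alpha_tests.tsv", index=False)
        return alpha

    stage("alpha_diversity")(do_alpha)

    # ---- beta diversity / ordination --------------------------------
    def do_beta():
        ss = _stage_seed(cfg.seed, "nmds")
        stress_rows = []
        for fraction, child in zip(FRACTIONS, ss.spawn(len(FRACTIONS))):
            sub = table if fraction == "whole" else table.select_otus(
                classes.otus(fraction))
            keep = sub.sample_sums() > 0
            sub = sub.select_samples(
                [s for s, k in zip(sub.sample_ids, keep) if k])
            bc = beta.bray_curtis(sub)
            _write(bc.to_data_frame(), out / f"bray_curtis_{fraction}.tsv")
            res = beta.nmds(bc, k=2, n_starts=cfg.nmds_starts, seed=child)
            _write(res.coordinates, out / f"nmds_{fraction}.tsv")
            stress_rows.append({"fraction": fraction, "stress": res.stress})
        _write(pd.DataFrame(stress_rows), out / "nmds_stress.tsv",
               index=False)

    stage("beta_ordination")(do_beta)

    # ---- assembly ---------------------------------------------------
    def do_assembly():
        if tree is None:
            raise ValueError("a phylogenetic tree is required for the "
                             "assembly stage")
        coph = assembly.cophenetic_distances(tree)
        pairs = (assembly.within_group_pairs(table, metadata.group)
                 if cfg.bnti_within_group_only else None)
        bnti = assembly.beta_nti_by_fraction(
            table, coph, classes, weighted=cfg.weighted_bnti,
            n_null=cfg.n_null, seed=_stage_seed(cfg.seed, "bnti"),
            sample_pairs=pairs)
        _write(bnti, out / "bnti.tsv", index=False)
        summaries = []
        for fraction in FRACTIONS:
            sub = bnti[bnti["fraction"] == fraction]
            summ = assembly.summarize_assembly(sub, metadata.group)
            summ.insert(0, "fraction", fraction)
            summaries.append(summ.reset_index())
        _write(pd.concat(summaries, ignore_index=True),
               out / "assembly_summary.tsv", index=False)
        nti = assembly.mntd_nti(table, coph, weighted=cfg.weighted_bnti,
                                n_null=cfg.n_null,
                                seed=_stage_seed(cfg.seed, "nti"))
        _write(nti, out / "nti.tsv")

    stage("assembly")(do_assembly)

    # ---- networks ---------------------------------------------------
    def do_networks():
        rows = []
        random_rows = []
        for fraction in FRACTIONS:
            seed_f = int(_stage_seed(cfg.seed, f"network:{fraction}")
                         .generate_state(1)[0])
            try:
                net = network.build_fraction_network(
                    table, classes, fraction=fraction,
                    min_prevalence=cfg.min_prevalence,
                    rho_min=cfg.rho_min, p_max=cfg.p_max)
            except Exception as exc:
                log.warning("skipping %s network: %s", fraction, exc)
                continue
            io.write_network(net, out / f"network_{fraction}.tsv",
                             format="edge_tsv")
            if net.number_of_edges() == 0:
                continue
            topo = network.topology_metrics(net, seed=seed_f)
            io.write_network(net, out / f"network_{fraction}.graphml",
                             format="graphml")
            roles = network.zipi_roles(net,
                                       zi_threshold=cfg.zi_threshold,
                                       pi_threshold=cfg.pi_threshold)
            _write(roles, out / f"node_roles_{fraction}.tsv")
            rows.append({"fraction": fraction, **topo.to_dict()})
            try:
                rand = network.random_network_ensemble(
                    net, n_random=cfg.n_random, seed=seed_f)
                rand.insert(0, "fraction", fraction)
                random_rows.append(rand.reset_index())
            except Exception as exc:
                log.warning("no random baseline for %s: %s", fraction, exc)
        if rows:
            _write(pd.DataFrame(rows), out / "network_topology.tsv",
                   index=False)
        if random_rows:
            _write(pd.concat(random_rows, ignore_index=True),
                   out / "network_random_baseline.tsv", index=False)

    stage("networks")(do_networks)

    # ---- environment association ------------------------------------
    def do_env():
        screen = env.mantel_screen(
            table, classes, metadata, n_perm=cfg.n_perm,
            seed=_stage_seed(cfg.seed, "mantel"))
        _write(screen, out / "mantel.tsv", index=False)
        rda_rows = []
        for fraction in FRACTIONS:
            sub = table if fraction == "whole" else table.select_otus(
                classes.otus(fraction))
            keep = sub.sample_sums() > 0
            sub = sub.select_samples(
                [s for s, k in zip(sub.sample_ids, keep) if k])
            cov = metadata.covariates.loc[list(sub.sample_ids)]
            res = beta.rda_forward(
                sub, cov, n_perm=min(cfg.n_perm, 499),
                seed=_stage_seed(cfg.seed, f"rda:{fraction}"))
            rda_rows.append({
                "fraction": fraction,
                "selected": ",".join(res.selected),
                "constrained_fraction": res.constrained_fraction,
                "axis1_fraction": res.axis_variance_fractions[0]
                if len(res.axis_variance_fractions) > 0 else np.nan,
                "axis2_fraction": res.axis_variance_fractions[1]
                if len(res.axis_variance_fractions) > 1 else np.nan,
            })
            if len(res.site_scores.columns):
                _write(res.site_scores, out / f"rda_sites_{fraction}.tsv")
        _write(pd.DataFrame(rda_rows), out / "rda_summary.tsv", index=False)

    stage("env_association")(do_env)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
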