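"""End-to-end orchestration: simulate/load → rarefy → diversity → assembly → network.

A run is fully described by one :class:`PipelineConfig`; every enabled stage
derives its RNG from the master seed through a named stream, so identical
config + seed reproduce identical outputs (checked via the manifest's
per-file checksums).  Cross-validation of counts/tree/metadata happens
before any stage runs — no partial output on inconsistent inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, diversity, network, simulate
from .io import (
    CountTable,
    PhyloTree,
    SampleMetadata,
    read_count_table,
    read_sample_metadata,
    read_tree_newick,
    write_distance_matrix,
    write_network_edgelist,
    write_network_graphml,
    write_table_tsv,
)

log = logging.getLogger("hydrobiome")

_STAGE_STREAMS = ("rarefy", "diversity", "assembly", "network")


@dataclass
class PipelineConfig:
    # input files (ignored when simulation is set)
    counts: str | None = None
    tree: str | None = None
    metadata: str | None = None
    simulation: simulate.SimulationConfig | None = None
    # stage toggles
    run_diversity: bool = True
    run_assembly: bool = True
    run_network: bool = True
    # parameters
    rarefaction_depth: int | None = None
    n_perm: int = 999
    n_null: int = 999
    top_n: int = 500
    rho_threshold: float = 0.6
    alpha: float = 0.05
    adjust: str = "bh"
    robustness_fractions: list[float] = field(
        default_factory=lambda: list(np.linspace(0, 0.8, 9))
    )
    n_rep: int = 50
    seed: int = 0
    out: str = "hydrobiome_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("simulation", None)
        cfg = cls(**doc)
        if sim is not None:
            cfg.simulation = simulate.SimulationConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def cross_validate(
    counts: CountTable, tree: PhyloTree | None, metadata: SampleMetadata
) -> list[str]:
    """Collect every inconsistency between the three inputs."""
    problems = []
    meta_samples = set(metadata.sample_ids)
    missing_meta = [s for s in counts.sample_ids if s not in meta_samples]
    if missing_meta:
        problems.append(f"samples missing from metadata: {missing_meta}")
    if tree is not None:
        tips = set(tree.tip_names)
        missing_tips = [t for t in counts.taxon_ids if t not in tips]
        if missing_tips:
            problems.append(
                f"{len(missing_tips)} taxa not in tree (e.g. {missing_tips[:5]})"
            )
    return problems


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest."""
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: int(ss.generate_state(1)[0] % (2**31 - 1))
        for name, ss in zip(
            _STAGE_STREAMS, np.random.SeedSequence(config.seed).spawn(len(_STAGE_STREAMS))
        )
    }
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": [],
        "warnings": [],
        "outputs": {},
    }

    # --- inputs -----------------------------------------------------------
    if config.simulation is not None:
        dataset = simulate.simulate_dataset(config.simulation)
        paths = dataset.write(outdir / "simulated")
        counts, tree, metadata = dataset.counts, dataset.tree, dataset.metadata
        for k, p in paths.items():
            manifest["outputs"][f"simulated/{k}"] = _sha256(p)
        manifest["stages"].append(
            {"stage": "simulate", "params": {"seed": config.simulation.seed}}
        )
    else:
        if not (config.counts and config.metadata):
            raise ValueError("either simulation or counts+metadata inputs required")
        counts, _ = read_count_table(config.counts)
        metadata = read_sample_metadata(config.metadata)
        tree = read_tree_newick(config.tree) if config.tree else None

    problems = cross_validate(counts, tree, metadata)
    if problems:
        raise ValueError("input cross-validation failed:\n" + "\n".join(problems))

    groups = {s: str(metadata.frame.loc[s, "group"]) for s in counts.sample_ids}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if config.rarefaction_depth:
            counts = diversity.rarefy(
                counts, config.rarefaction_depth, seed=seeds["rarefy"]
            )
            manifest["stages"].append(
                {"stage": "rarefy", "params": {"depth": config.rarefaction_depth}}
            )

        if config.run_diversity:
            log.info("diversity stage")
            summ = diversity.diversity_summary(counts, tree, metadata)
            write_table_tsv(summ, outdir / "alpha_diversity.tsv")
            bc = diversity.bray_curtis(counts)
            write_distance_matrix(bc, outdir / "bray_curtis.tsv")
            perma = diversity.permanova(
                bc, groups, n_perm=config.n_perm, seed=seeds["diversity"]
            )
            ov = diversity.community_overlap(counts, groups)
            with open(outdir / "overlap.json", "w") as fh:
                json.dump(ov, fh, indent=1, sort_keys=True)
            pd.DataFrame(
                [
                    {
                        "pseudo_F": perma.pseudo_f,
                        "R2": perma.r2,
                        "p": perma.p,
                        "n_perm": perma.n_perm,
                    }
                ]
            ).to_csv(outdir / "permanova.tsv", sep="\t", index=False)
            manifest["stages"].append(
                {"stage": "diversity", "params": {"n_perm": config.n_perm}}
            )
            for f in ("alpha_diversity.tsv", "bray_curtis.tsv", "permanova.tsv", "overlap.json"):
                manifest["outputs"][f] = _sha256(outdir / f)

        if config.run_assembly:
            log.info("assembly stage")
            ncm = assembly.fit_ncm(counts)
            write_table_tsv(ncm.taxa, outdir / "ncm_fit.tsv")
            bnti = assembly.compute_bnti(
                counts, tree, n_null=config.n_null, seed=seeds["assembly"]
            )
            rc = assembly.compute_rcbray(
                counts, n_null=config.n_null, seed=seeds["assembly"] + 1
            )
            part = assembly.partition_processes(bnti, rc, groups)
            pd.DataFrame(bnti.values, index=bnti.ids, columns=bnti.ids).to_csv(
                outdir / "bnti.tsv", sep="\t", float_format="%.6g"
            )
            pd.DataFrame(rc.values, index=rc.ids, columns=rc.ids).to_csv(
                outdir / "rcbray.tsv", sep="\t", float_format="%.6g"
            )
            write_table_tsv(part.fractions, outdir / "partition.tsv")
            manifest["stages"].append(
                {
                    "stage": "assembly",
                    "params": {"n_null": config.n_null},
                    "ncm": {"m": ncm.m, "N": ncm.N, "R2": ncm.r2},
                }
            )
            for f in ("ncm_fit.tsv", "bnti.tsv", "rcbray.tsv", "partition.tsv"):
                manifest["outputs"][f] = _sha256(outdir / f)

        if config.run_network:
            log.info("network stage")
            net = network.build_network(
                counts,
                top_n=config.top_n,
                rho_threshold=config.rho_threshold,
                alpha=config.alpha,
                adjust=config.adjust,
                seed=seeds["network"],
            )
            if net.number_of_nodes() == 0:
                manifest["warnings"].append("network stage produced an empty graph")
            else:
                report = network.topology_report(net, seed=seeds["network"])
                roles = network.zi_pi_roles(net, report.modules)
                rob_r = network.robustness_curve(
                    net,
                    "random",
                    fractions=config.robustness_fractions,
                    n_rep=config.n_rep,
                    seed=seeds["network"],
                )
                rob_t = network.robustness_curve(
                    net,
                    "targeted",
                    fractions=config.robustness_fractions,
                    n_rep=config.n_rep,
                    seed=seeds["network"],
                    roles=roles,
                )
                curves = pd.DataFrame(
                    {
                        "fraction": rob_r.fractions,
                        "robustness_random": rob_r.mean,
                        "robustness_random_sd": rob_r.sd,
                        "robustness_targeted": rob_t.mean,
                        "robustness_targeted_sd": rob_t.sd,
                    }
                ).set_index("fraction")
                write_network_graphml(net, outdir / "network.graphml")
                write_network_edgelist(net, outdir / "network_edges.tsv")
                write_table_tsv(report.to_series().to_frame("value"), outdir / "topology_report.tsv")
                write_table_tsv(roles, outdir / "node_roles.tsv")
                write_table_tsv(curves, outdir / "stability_curves.tsv")
                manifest["stages"].append(
                    {
                        "stage": "network",
                        "params": {
                            "top_n": config.top_n,
                            "rho_threshold": config.rho_threshold,
                            "alpha": config.alpha,
                            "adjust": config.adjust,
                        },
                    }
                )
                for f in (
                    "network.graphml",
                    "network_edges.tsv",
                    "topology_report.tsv",
                    "node_roles.tsv",
                    "stability_curves.tsv",
                ):
                    manifest["outputs"][f] = _sha256(outdir / f)

        manifest["warnings"].extend(str(w.message) for w in caught)

    cfg_dict = dataclasses.asdict(config)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
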