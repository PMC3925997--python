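"""Pipeline orchestration: simulate → infer → properties → motifs → compare.

A :class:`PipelineConfig` (loadable from YAML or JSON) drives the stages;
every output file is recorded in a manifest with its SHA-256 checksum, the
stage parameters and the seeds used, so a rerun with the same configuration
is byte-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compare import (
    classify_genes,
    compare_neighbourhoods,
    link_conservation,
    sequence_vs_regulation,
)
from .inference import build_network, clr_transform, mi_matrix
from .io import (
    read_expression,
    read_go_map,
    read_ortholog_groups,
    read_tf_list,
    write_edge_list,
)
from .motifs import enumerate_motif_classes, motif_zscores
from .properties import compute_centralities, fit_degree_distribution, subnetwork_statistics
from .simulate import ScenarioSpec, write_study

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("crossnet.pipeline")


@dataclass
class PipelineConfig:
    """Declarative description of a full analysis run.

    Either ``simulation`` holds a ScenarioSpec (the study is generated) or
    ``species_inputs`` maps species → dict with ``expression``, ``tfs`` and
    optionally ``go`` paths, plus ``orthologs`` / ``bitscores`` paths.
    """

    out_dir: str = "crossnet_out"
    simulation: ScenarioSpec | None = None
    species_inputs: dict[str, dict[str, str]] = field(default_factory=dict)
    orthologs_path: str | None = None
    bitscores_path: str | None = None
    thresholds: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    compare_threshold: float = 2.0
    motif_threshold: float = 2.0
    motif_sizes: tuple[int, ...] = (3,)
    n_rand: int = 100
    fdr: float = 0.05
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "infer", "properties", "motifs", "compare")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            for key in ("species_names", "module_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = ScenarioSpec(**sim)
        for key in ("thresholds", "motif_sizes", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.simulation is None and not self.species_inputs:
            raise ValueError("config needs either a simulation spec or species inputs")
        if self.simulation is not None:
            self.simulation.validate()
        for sp, paths in self.species_inputs.items():
            for kind, p in paths.items():
                if not Path(p).exists():
                    raise ValueError(f"missing {kind} file for {sp}: {p}")
        for p in (self.orthologs_path, self.bitscores_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"missing file: {p}")
        if self.simulation is None and self.orthologs_path is None and "compare" in self.stages:
            raise ValueError("compare stage needs an orthologs file")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return (and write) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": {},
        "files": {},
        "warnings": [],
    }

    def record(stage: str, name: str, path: Path) -> None:
        manifest["files"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
            "stage": stage,
        }

    # ----- simulate -------------------------------------------------------
    species: list[str] = []
    inputs: dict[str, dict[str, Path]] = {}
    orthologs_path = config.orthologs_path
    bitscores_path = config.bitscores_path
    if config.simulation is not None and "simulate" in config.stages:
        t0 = time.time()
        sim_dir = out / "simulated"
        paths = write_study(config.simulation, sim_dir)
        species = list(config.simulation.species_names)
        for sp in species:
            inputs[sp] = {
                "expression": paths[f"{sp}_expression"],
                "tfs": paths[f"{sp}_tfs"],
                "go": paths[f"{sp}_go"],
            }
        orthologs_path = paths["groups"]
        bitscores_path = paths["bitscores"]
        for name, p in paths.items():
            record("simulate", name, p)
        manifest["stages"]["simulate"] = {"seconds": round(time.time() - t0, 2)}
        logger.info("simulate: wrote %d files in %s", len(paths), sim_dir)
    else:
        species = sorted(config.species_inputs)
        inputs = {
            sp: {k: Path(v) for k, v in kv.items()}
            for sp, kv in config.species_inputs.items()
        }

    # ----- infer ----------------------------------------------------------
    networks: dict[str, dict[float, object]] = {}
    annotations: dict[str, dict] = {}
    if "infer" in config.stages:
        t0 = time.time()
        for sp in species:
            expr = read_expression(inputs[sp]["expression"], species=sp)
            tfs = read_tf_list(inputs[sp]["tfs"])
            go = read_go_map(inputs[sp]["go"]) if "go" in inputs[sp] else {}
            annotations[sp] = {"tfs": tfs, "go": go}
            clr = clr_transform(mi_matrix(expr))
            networks[sp] = {}
            for thr in config.thresholds:
                net = build_network(clr, thr, tfs)
                networks[sp][thr] = net
                p = out / f"{sp}_edges_t{thr:g}.tsv"
                write_edge_list(net.edge_list(), p)
                record("infer", f"{sp}_edges_t{thr:g}", p)
        manifest["stages"]["infer"] = {
            "seconds": round(time.time() - t0, 2),
            "thresholds": list(config.thresholds),
        }
        logger.info("infer: %d species x %d thresholds", len(species), len(config.thresholds))

    # ----- properties -----------------------------------------------------
    if "properties" in config.stages and networks:
        t0 = time.time()
        fit_rows = []
        for sp in species:
            for thr, net in networks[sp].items():
                cent = compute_centralities(net, "coexpression")
                p = out / f"{sp}_centralities_t{thr:g}.tsv"
                cent.to_csv(p, sep="\t")
                record("properties", f"{sp}_centralities_t{thr:g}", p)
                n_connected = len(net.connected_genes())
                if n_connected >= 50:
                    fit = fit_degree_distribution(net)
                    fit_rows.append(
                        {
                            "species": sp,
                            "threshold": thr,
                            "n_connected": n_connected,
                            "classification": fit.classification,
                            "alpha": fit.alpha,
                            "x_min": fit.x_min,
                            "lambda": fit.lam,
                            "delta_loglik": fit.delta_loglik,
                        }
                    )
                go = annotations[sp]["go"]
                if go:
                    stats = subnetwork_statistics(net, go)
                    p = out / f"{sp}_subnetworks_t{thr:g}.tsv"
                    stats.to_csv(p, sep="\t")
                    record("properties", f"{sp}_subnetworks_t{thr:g}", p)
        import pandas as pd

        p = out / "degree_fits.tsv"
        pd.DataFrame(fit_rows).to_csv(p, sep="\t", index=False)
        record("properties", "degree_fits", p)
        manifest["stages"]["properties"] = {"seconds": round(time.time() - t0, 2)}

    # ----- motifs ---------------------------------------------------------
    if "motifs" in config.stages and networks:
        t0 = time.time()
        for size in config.motif_sizes:
            catalog = enumerate_motif_classes(size)
            for sp in species:
                net = networks[sp].get(config.motif_threshold)
                go = annotations[sp]["go"]
                if net is None or not go:
                    continue
                stats = motif_zscores(
                    net, go, catalog, n_rand=config.n_rand, seed=config.seed
                )
                p = out / f"{sp}_motifs{size}_t{config.motif_threshold:g}.tsv"
                stats.to_csv(p, sep="\t")
                record("motifs", f"{sp}_motifs{size}", p)
        manifest["stages"]["motifs"] = {"seconds": round(time.time() - t0, 2)}

    # ----- compare --------------------------------------------------------
    if "compare" in config.stages and networks and orthologs_path is not None:
        t0 = time.time()
        import pandas as pd

        omap = read_ortholog_groups(orthologs_path, bitscores_path)
        summary = {}
        thr = config.compare_threshold
        for sp1 in species:
            for sp2 in species:
                if sp1 == sp2:
                    continue
                net1, net2 = networks[sp1][thr], networks[sp2][thr]
                tests = compare_neighbourhoods(net1, net2, omap, sp1, sp2)
                if not tests:
                    manifest["warnings"].append(
                        f"no eligible neighbourhood tests for {sp1}->{sp2}"
                    )
                    continue
                report = classify_genes(tests, sp1, sp2, fdr=config.fdr)
                rows = [
                    {
                        "gene": t.gene,
                        "ortholog": t.ortholog,
                        "N": t.N,
                        "n": t.n,
                        "k": t.k,
                        "x": t.x,
                        "p_conserved": t.p_conserved,
                        "q_conserved": t.q_conserved,
                        "p_diverged": t.p_diverged,
                        "q_diverged": t.q_diverged,
                    }
                    for t in report.tests
                ]
                p = out / f"tests_{sp1}_vs_{sp2}.tsv"
                pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
                record("compare", f"tests_{sp1}_vs_{sp2}", p)
                p = out / f"categories_{sp1}_vs_{sp2}.tsv"
                pd.Series(report.category, name="category").rename_axis("gene").to_csv(
                    p, sep="\t"
                )
                record("compare", f"categories_{sp1}_vs_{sp2}", p)
                frac, _ = link_conservation(net1, net2, omap, sp1, sp2)
                svr = sequence_vs_regulation(report, omap)
                svr.pop("rank_table", None)
                summary[f"{sp1}->{sp2}"] = {
                    "link_conservation": frac,
                    "category_fractions": report.fractions(),
                    "sequence_vs_regulation": svr,
                }
        p = out / "comparison_summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        record("compare", "comparison_summary", p)
        manifest["stages"]["compare"] = {"seconds": round(time.time() - t0, 2)}

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline finished: %s", manifest_path)
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    if config.simulation is not None:
        echo["simulation"] = dataclasses.asdict(config.simulation)
    return echo
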