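"""End-to-end orchestration of the ceRNA-network analysis.

Stage order mirrors the analysis: simulate (optional) -> normalize -> de ->
evaluate -> enrich -> network -> topology -> qpcr (optional).  A single
YAML config holds per-stage parameter blocks and stage toggles; one global
seed fans out deterministically to per-stage seeds.  Every intermediate
artifact is written to the output directory and the run report records the
counts at each stage (genes in, DE mRNAs/lncRNAs, edges after each filter,
node/edge counts by type, pivotal nodes by type) together with all
parameters, so a run is reproducible from its own report.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cenet, de, enrich, expr, mleval, qpcr, synthio, topo

log = logging.getLogger("cernapivot")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

STAGES = ["simulate", "normalize", "de", "evaluate", "enrich",
          "network", "topology", "qpcr"]
_DEPENDS = {
    "normalize": "simulate", "de": "normalize", "evaluate": "de",
    "enrich": "de", "network": "de", "topology": "network", "qpcr": "simulate",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_log(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


@dataclass
class PipelineConfig:
    """Single-config description of a pipeline run."""

    outdir: str = "cerna_out"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        self.stages = {s: self.stages.get(s, True) for s in STAGES}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        params = {s: dict(raw.get(s, {})) for s in STAGES}
        return cls(
            outdir=raw.get("outdir", "cerna_out"),
            seed=int(raw.get("seed", 0)),
            stages=dict(raw.get("stages", {})),
            inputs=dict(raw.get("inputs", {})),
            params=params,
        )

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "stages": self.stages,
            "inputs": self.inputs,
            **{s: self.params.get(s, {}) for s in STAGES},
        }

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0]
                   % 2**31)


def _check_deps(config: PipelineConfig) -> None:
    for stage, dep in _DEPENDS.items():
        if config.stages.get(stage) and not config.stages.get(dep):
            if dep == "simulate" and config.inputs:
                continue  # file inputs replace the simulate stage
            raise PipelineError(stage, f"requires the {dep!r} stage (disabled)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; return (and write) the run report.

    Any stage error aborts with the stage name and cause; artifacts written
    before the failure are retained in the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_deps(config)
    report: dict[str, Any] = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
    }

    matrix = truth = interactions = gene_sets = None
    de_table = fpkm = network = cent = wells = None

    # -- simulate ---------------------------------------------------------
    if config.stages["simulate"]:
        stage = "simulate"
        try:
            sim_params = dict(config.params.get("simulate", {}))
            sim_params.setdefault("seed", config.stage_seed("simulate"))
            sim_config = synthio.SimulationConfig(**sim_params)
            matrix, truth = synthio.simulate_expression(sim_config)
            interactions = synthio.simulate_interaction_table(sim_config, truth)
            gene_sets = synthio.simulate_gene_sets(sim_config, truth)
            if config.stages["qpcr"]:
                wells = synthio.simulate_qpcr(truth, sim_config)
                synthio.write_qpcr_table(wells, outdir / "qpcr_wells.tsv")
            expr.write_expression(matrix, outdir / "counts.tsv")
            synthio.write_interaction_table(interactions,
                                            outdir / "interactions.tsv")
            enrich.write_gmt(gene_sets, outdir / "gene_sets.gmt")
            truth.to_json(outdir / "truth.json")
            report["stages"][stage] = {
                "genes": int(matrix.values.shape[0]),
                "samples": int(matrix.values.shape[1]),
                "planted_de": len(truth.de_gene_ids),
                "hub_lncrna": truth.hub_lncrna_id,
                "interaction_rows": int(len(interactions)),
                "gene_sets": len(gene_sets),
            }
            _stage_log(stage, f"{matrix.values.shape[0]} genes x "
                              f"{matrix.values.shape[1]} samples -> {outdir}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
    else:
        stage = "inputs"
        try:
            if "counts" in config.inputs:
                matrix = expr.read_expression(config.inputs["counts"])
            if "interactions" in config.inputs:
                interactions = synthio.read_interaction_table(
                    config.inputs["interactions"])
            if "gene_sets" in config.inputs:
                gene_sets = enrich.read_gmt(config.inputs["gene_sets"]).terms
            if "qpcr_wells" in config.inputs:
                wells = qpcr.read_wells(config.inputs["qpcr_wells"])
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # -- normalize --------------------------------------------------------
    if config.stages["normalize"]:
        stage = "normalize"
        try:
            if matrix is None:
                raise ValueError("no count matrix (simulate disabled, no input)")
            p = config.params.get("normalize", {})
            fpkm = expr.compute_fpkm(matrix)
            if p.get("filter_min_fpkm") is not None:
                fpkm = expr.filter_expressed(
                    fpkm, min_fpkm=float(p["filter_min_fpkm"]),
                    min_samples=int(p.get("filter_min_samples", 2)),
                )
            expr.write_expression(fpkm, outdir / "fpkm.tsv")
            report["stages"][stage] = {"genes": int(fpkm.values.shape[0])}
            _stage_log(stage, f"{fpkm.values.shape[0]} genes after normalization")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # -- de ---------------------------------------------------------------
    if config.stages["de"]:
        stage = "de"
        try:
            p = config.params.get("de", {})
            de_table = de.test_differential(fpkm)
            de_table = de.classify_de(
                de_table, alpha=float(p.get("alpha", 0.05)),
                lfc_min=float(p.get("lfc_min", 1.0)),
                use_adjusted=bool(p.get("use_adjusted", False)),
            )
            de.write_de_table(de_table, outdir / "de_results.tsv")
            sig = de_table[de_table["status"] != "ns"]
            report["stages"][stage] = {
                "de_mrna": int((sig["biotype"] == "mRNA").sum()),
                "de_lncrna": int((sig["biotype"] == "lncRNA").sum()),
                "up": int((sig["status"] == "up").sum()),
                "down": int((sig["status"] == "down").sum()),
            }
            _stage_log(stage, f"{len(sig)} DE genes "
                              f"({report['stages'][stage]['de_mrna']} mRNA, "
                              f"{report['stages'][stage]['de_lncrna']} lncRNA)")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # -- evaluate ---------------------------------------------------------
    if config.stages["evaluate"]:
        stage = "evaluate"
        try:
            p = config.params.get("evaluate", {})
            de_mrna = de_table.loc[
                (de_table["status"] != "ns") & (de_table["biotype"] == "mRNA"),
                "gene_id",
            ].tolist()
            sep = mleval.evaluate_separation(
                fpkm, de_mrna,
                posterior_threshold=float(p.get("posterior_threshold", 0.8)),
                seed=config.stage_seed("evaluate"),
            )
            sep.pca_coords.to_csv(outdir / "pca_coords.tsv", sep="\t")
            with open(outdir / "separation.json", "w") as fh:
                json.dump(sep.to_dict(), fh, indent=1, sort_keys=True)
            report["stages"][stage] = sep.to_dict()
            _stage_log(stage, f"concordance={sep.concordance:.3f}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # -- enrich -----------------------------------------------------------
    if config.stages["enrich"]:
        stage = "enrich"
        try:
            if gene_sets is None:
                raise ValueError("no gene-set collection available")
            p = config.params.get("enrich", {})
            collection = (
                gene_sets if isinstance(gene_sets, enrich.GeneSetCollection)
                else enrich.GeneSetCollection(terms=dict(gene_sets))
            )
            universe = de_table.loc[de_table["biotype"] == "mRNA", "gene_id"]
            de_mrna_status = de_table[
                (de_table["status"] != "ns") & (de_table["biotype"] == "mRNA")
            ]
            enr = enrich.enrich_collection(de_mrna_status, collection,
                                           universe=universe)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                       float_format="%.8g")
            n_sig = int((enr["p_value" if p.get("raw_p") else "adj_p"] < 0.05).sum()
                        ) if len(enr) else 0
            report["stages"][stage] = {
                "terms_tested": int(len(enr)),
                "significant": n_sig,
                "top_term": enr["term_id"].iloc[0] if len(enr) else None,
            }
            _stage_log(stage, f"{len(enr)} terms tested, {n_sig} significant")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # -- network ----------------------------------------------------------
    if config.stages["network"]:
        stage = "network"
        try:
            if interactions is None:
                raise ValueError("no interaction table available")
            p = config.params.get("network", {})
            sig = de_table[de_table["status"] != "ns"]
            lnc_ids = sig.loc[sig["biotype"] == "lncRNA", "gene_id"].tolist()
            mrna_ids = sig.loc[sig["biotype"] == "mRNA", "gene_id"].tolist()
            edges = cenet.correlation_edges(fpkm, lnc_ids, mrna_ids)
            filtered = cenet.filter_correlation(
                edges, alpha=float(p.get("alpha", 0.05)),
                r_min=float(p.get("r_min", 0.6)),
                sign_mode=p.get("sign_mode", "positive"),
            )
            supported = cenet.cross_reference(
                filtered, interactions, min_shared=int(p.get("min_shared", 1)))
            network = cenet.build_cerna(supported)
            cenet.write_edges_table(supported, outdir / "network_edges.tsv")
            cenet.write_sif(network, outdir / "network.sif")
            cenet.write_network(network, outdir / "network_edgelist.tsv",
                                outdir / "network_nodes.tsv")
            ntypes = pd.Series(
                [d.get("type") for _, d in network.nodes(data=True)]
            ).value_counts().to_dict()
            ekinds = pd.Series(
                [d.get("kind") for _, _, d in network.edges(data=True)]
            ).value_counts().to_dict()
            report["stages"][stage] = {
                "candidate_pairs": int(len(edges)),
                "after_correlation_filter": int(len(filtered)),
                "after_mirna_support": int(len(supported)),
                "nodes_by_type": {k: int(v) for k, v in ntypes.items()},
                "edges_by_kind": {k: int(v) for k, v in ekinds.items()},
            }
            _stage_log(stage, f"{len(supported)} supported edges, "
                              f"{network.number_of_nodes()} nodes")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # -- topology ---------------------------------------------------------
    if config.stages["topology"]:
        stage = "topology"
        try:
            if network is None:
                raise ValueError("no network available")
            p = config.params.get("topology", {})
            cent = topo.centralities(network,
                                     normalized=bool(p.get("normalized", False)))
            pivotal = topo.pivotal_nodes(cent, k=int(p.get("k", 100)))
            topo.write_centralities(cent, outdir / "centralities.tsv")
            pivotal.to_json(outdir / "pivotal.json")
            by_type = {t: len(v) for t, v in pivotal.members_by_type.items()}
            report["stages"][stage] = {
                "k": pivotal.k,
                "pivotal_nodes": len(pivotal.intersection),
                "pivotal_by_type": by_type,
                "venn_regions": pivotal.venn_regions,
            }
            _stage_log(stage, f"{len(pivotal.intersection)} pivotal nodes "
                              f"at k={pivotal.k}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # -- qpcr -------------------------------------------------------------
    if config.stages["qpcr"]:
        stage = "qpcr"
        try:
            if wells is None:
                raise ValueError("no qPCR well table available")
            p = config.params.get("qpcr", {})
            rel = qpcr.relative_expression(
                wells, reference_gene=p.get("reference_gene", "REF"),
                calibrator_group=p.get("calibrator_group", "control"),
            )
            qpcr.write_relative_expression(rel, outdir / "qpcr_relative.tsv")
            comparisons = {
                t: qpcr.compare_groups(rel, t)
                for t in sorted(rel["target"].unique())
            }
            report["stages"][stage] = {
                "targets": len(comparisons),
                "comparisons": comparisons,
            }
            _stage_log(stage, f"{len(comparisons)} targets quantified")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
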