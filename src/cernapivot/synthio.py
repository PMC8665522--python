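"""Synthetic data generator with planted ground truth.

The generator emulates the statistical structure of a small paired
case-control bulk RNA-seq study — by default six tumor / six matched
normal-skin samples — together with the annotation resources the ceRNA
(competing endogenous RNA) analysis consumes:

* a negative-binomial count matrix over mRNAs and lncRNAs with log-normal
  baseline means, a planted fraction of differentially expressed (DE)
  genes, and one planted hub lncRNA whose expression drives a correlated
  module of mRNAs through a shared per-sample latent factor;
* a miRNA->target interaction table in which the hub lncRNA and each
  module mRNA share a configurable number of miRNAs (the ceRNA "sponge"
  signature), plus random background targeting;
* a gene-set collection in which one term is drawn mostly from the planted
  DE mRNAs (the enriched term) and the rest are background draws;
* a triplicate qPCR well table whose tumor-vs-control delta-Ct shift
  encodes the planted log2 fold changes.

Every output is a pure function of (config, seed): the same configuration
always produces bitwise-identical data.  Ground truth (which genes are DE
and in which direction, the hub, the module, the enriched term) is returned
alongside so downstream stages can be scored for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expr import ExpressionMatrix


class SimulationError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the emulated design: 6 tumor/normal pairs, a bulk
    RNA-seq-shaped count distribution (log-normal baseline means, NB noise
    with var = mu + phi*mu^2), 10% planted DE at |log2FC| = 3, and a hub
    lncRNA co-expressed (target rho 0.8) with an 8-mRNA module sharing
    3 miRNAs per member.
    """

    n_pairs: int = 6
    n_mrna: int = 400
    n_lncrna: int = 80
    n_mirna: int = 150
    nb_mean_log_mu: float = 4.0   # natural-log scale of baseline NB means
    nb_mean_log_sd: float = 1.5
    nb_dispersion: float = 0.2    # phi in var = mu + phi*mu^2; 0 -> Poisson
    de_fraction: float = 0.1
    de_log2fc: float = 3.0
    module_size: int = 8
    module_rho: float = 0.8
    shared_mirna_count: int = 3
    background_targets_per_mirna: int = 4
    geneset_count: int = 50
    geneset_size: int = 20
    pair_sd: float = 0.0          # per-pair baseline offset (log scale); 0 = off
    qpcr_noise_sd: float = 0.2    # replicate Ct noise (cycles)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "n_mrna", "n_lncrna", "n_mirna",
                     "geneset_count", "geneset_size"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise SimulationError("de_fraction must lie in [0, 1]")
        if self.module_size > 0 and not 0.0 < self.module_rho < 1.0:
            raise SimulationError("module_rho must lie in (0, 1)")
        if self.nb_dispersion < 0:
            raise SimulationError("nb_dispersion must be >= 0")
        if self.module_size > self.n_mrna:
            raise SimulationError("module_size exceeds n_mrna")
        if self.shared_mirna_count > self.n_mirna:
            raise SimulationError("shared_mirna_count exceeds n_mirna")
        if self.geneset_size > self.n_mrna:
            raise SimulationError("geneset_size exceeds n_mrna")
        n_genes = self.n_mrna + self.n_lncrna
        if self.de_fraction > 0 and self.de_fraction * n_genes < 1:
            raise SimulationError("de_fraction too small to plant a single gene")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset."""

    de_gene_ids: dict[str, str]        # gene_id -> direction ("up"/"down")
    true_log2fc: dict[str, float]      # gene_id -> planted log2FC (0 if not DE)
    hub_lncrna_id: str | None
    module_mrna_ids: list[str]
    enriched_term_id: str | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    mrna = [f"MRNA{i:05d}" for i in range(1, config.n_mrna + 1)]
    lnc = [f"LNC{i:05d}" for i in range(1, config.n_lncrna + 1)]
    mir = [f"MIR{i:05d}" for i in range(1, config.n_mirna + 1)]
    return mrna, lnc, mir


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Simulate the count matrix and its ground truth.

    Non-DE genes share one NB mean across groups; planted DE genes have
    tumor means scaled by 2^(+-de_log2fc).  The hub lncRNA and its module
    mRNAs additionally share a per-sample latent log-scale factor whose
    loading is set from ``module_rho`` so that their pairwise sample
    correlation approaches the target as the noise model allows (the
    control is monotone in rho, not exact).
    """
    rng = np.random.default_rng(config.seed)
    mrna_ids, lnc_ids, _ = _gene_ids(config)
    gene_ids = mrna_ids + lnc_ids
    n_genes = len(gene_ids)
    n = config.n_pairs
    sample_ids = [f"T{i+1:02d}" for i in range(n)] + [f"N{i+1:02d}" for i in range(n)]
    conditions = ["tumor"] * n + ["control"] * n
    pair_ids = [f"P{i+1:02d}" for i in range(n)] * 2

    log_mu = rng.normal(config.nb_mean_log_mu, config.nb_mean_log_sd, n_genes)
    lengths = rng.integers(200, 10001, n_genes)

    # hub + module: planted DE (shared direction) and co-expression
    hub_id: str | None = None
    module_ids: list[str] = []
    if config.module_size > 0:
        hub_idx = config.n_mrna + int(rng.integers(config.n_lncrna))
        module_idx = rng.choice(config.n_mrna, size=config.module_size, replace=False)
        hub_id = gene_ids[hub_idx]
        module_ids = [gene_ids[i] for i in module_idx]
        planted_idx = np.concatenate([[hub_idx], module_idx])
        # the planted block sits in the upper expression range: a hub whose
        # counts are at the NB noise floor could never show r >= 0.6 at a
        # dozen samples, and ground truth is only useful when detectable
        log_mu[planted_idx] = rng.normal(
            config.nb_mean_log_mu + config.nb_mean_log_sd,
            0.5 * config.nb_mean_log_sd,
            len(planted_idx),
        )
    else:
        planted_idx = np.array([], dtype=int)

    # planted DE genes: fraction of all genes, random sign; when any DE is
    # planted the hub/module block is always part of it, with one shared
    # downregulated direction (the co-suppressed ceRNA axis); de_fraction=0
    # is a true null with no group differences anywhere
    true_lfc = np.zeros(n_genes)
    n_de = int(round(config.de_fraction * n_genes))
    de_idx = np.array([], dtype=int)
    if n_de > 0:
        pool = np.setdiff1d(np.arange(n_genes), planted_idx)
        n_extra = max(n_de - len(planted_idx), 0)
        extra = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
        de_idx = np.concatenate([planted_idx, extra]).astype(int)
        signs = rng.choice([-1.0, 1.0], size=len(de_idx))
        signs[: len(planted_idx)] = -1.0
        true_lfc[de_idx] = signs * config.de_log2fc

    # per-sample mean matrix on the natural-log scale
    log_mean = np.repeat(log_mu[:, None], 2 * n, axis=1)
    is_tumor = np.array([c == "tumor" for c in conditions])
    log_mean[:, is_tumor] += true_lfc[:, None] * np.log(2.0)

    if config.pair_sd > 0:
        pair_off = rng.normal(0.0, config.pair_sd, (n_genes, n))
        log_mean += np.hstack([pair_off, pair_off])

    # shared latent factor for the hub + module block; loading tau chosen so
    # that tau^2 / (tau^2 + v_noise) ~ module_rho, with v_noise an NB
    # log-scale noise proxy phi + exp(-mean log mu).  The factor is centered
    # within each group so that planted co-expression never perturbs the
    # planted group difference: correlation and DE stay orthogonal controls.
    if config.module_size > 0:
        v_noise = config.nb_dispersion + np.exp(
            -(config.nb_mean_log_mu + config.nb_mean_log_sd)
        )
        tau = np.sqrt(config.module_rho / (1.0 - config.module_rho) * v_noise)
        z = rng.normal(0.0, 1.0, 2 * n)
        z[is_tumor] -= z[is_tumor].mean()
        z[~is_tumor] -= z[~is_tumor].mean()
        log_mean[planted_idx] += tau * z[None, :] - 0.5 * tau**2

    mean = np.exp(log_mean)
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        lengths=pd.Series(lengths, index=gene_ids),
        biotypes=pd.Series(
            ["mRNA"] * config.n_mrna + ["lncRNA"] * config.n_lncrna, index=gene_ids
        ),
        samples=pd.DataFrame(
            {"condition": conditions, "pair_id": pair_ids}, index=sample_ids
        ),
        unit="counts",
    )
    truth = PlantedTruth(
        de_gene_ids={
            gene_ids[i]: ("up" if true_lfc[i] > 0 else "down") for i in de_idx
        },
        true_log2fc={gene_ids[i]: float(true_lfc[i]) for i in de_idx},
        hub_lncrna_id=hub_id,
        module_mrna_ids=module_ids,
    )
    return matrix, truth


def simulate_interaction_table(
    config: SimulationConfig, truth: PlantedTruth
) -> pd.DataFrame:
    """Simulate a miRNA->target interaction table (ENCORI-style export).

    Every module mRNA shares at least ``shared_mirna_count`` targeting
    miRNAs with the hub lncRNA; background pairs are drawn uniformly at
    random.  Rows are unique (mirna_id, target_id) pairs with a
    target_biotype column.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mrna_ids, lnc_ids, mir_ids = _gene_ids(config)
    biotype = {g: "mRNA" for g in mrna_ids}
    biotype.update({g: "lncRNA" for g in lnc_ids})
    pairs: set[tuple[str, str]] = set()

    if truth.hub_lncrna_id is not None and config.shared_mirna_count > 0:
        for m in truth.module_mrna_ids:
            shared = rng.choice(
                config.n_mirna, size=config.shared_mirna_count, replace=False
            )
            for j in shared:
                pairs.add((mir_ids[j], truth.hub_lncrna_id))
                pairs.add((mir_ids[j], m))

    targets = mrna_ids + lnc_ids
    for mir in mir_ids:
        picks = rng.choice(
            len(targets),
            size=min(config.background_targets_per_mirna, len(targets)),
            replace=False,
        )
        for j in picks:
            pairs.add((mir, targets[j]))

    rows = sorted(pairs)
    return pd.DataFrame(
        {
            "mirna_id": [m for m, _ in rows],
            "target_id": [t for _, t in rows],
            "target_biotype": [biotype[t] for _, t in rows],
        }
    )


def simulate_gene_sets(
    config: SimulationConfig, truth: PlantedTruth
) -> dict[str, list[str]]:
    """Simulate a gene-set collection with one planted enriched term.

    The enriched term draws >= 80% of its members from planted DE mRNAs
    (all of them when the DE truth is empty, the term is a background draw
    like the rest).  Returns term_id -> member list; updates
    ``truth.enriched_term_id`` in place.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mrna_ids, _, _ = _gene_ids(config)
    de_mrna = [g for g in truth.de_gene_ids if g.startswith("MRNA")]
    collection: dict[str, list[str]] = {}
    for i in range(1, config.geneset_count + 1):
        picks = rng.choice(config.n_mrna, size=config.geneset_size, replace=False)
        collection[f"TERM{i:04d}"] = sorted(mrna_ids[j] for j in picks)
    if de_mrna:
        size = config.geneset_size
        n_de = min(int(np.ceil(0.8 * size)), len(de_mrna))
        members = list(rng.choice(de_mrna, size=n_de, replace=False))
        rest = sorted(set(mrna_ids) - set(members))
        if size - n_de > 0:
            members += [rest[j] for j in rng.choice(len(rest), size=size - n_de,
                                                    replace=False)]
        term_id = f"TERM{config.geneset_count:04d}"
        collection[term_id] = sorted(members)
        truth.enriched_term_id = term_id
    else:
        truth.enriched_term_id = None
    return collection


def simulate_qpcr(
    truth: PlantedTruth,
    config: SimulationConfig,
    targets: Sequence[str] | None = None,
    n_per_group: int | None = None,
    n_replicates: int = 3,
    noise_sd: float | None = None,
    reference_gene: str = "REF",
) -> pd.DataFrame:
    """Simulate a qPCR well table (sample, group, target, replicate, Ct).

    Each sample gets ``n_replicates`` wells per target plus the reference
    gene.  The tumor-vs-control delta-Ct shift for a target equals minus
    its planted log2FC; replicate noise is Gaussian with sd ``noise_sd``
    cycles (default taken from the config).
    """
    if n_replicates <= 0:
        raise SimulationError("n_replicates must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    if targets is None:
        targets = ([truth.hub_lncrna_id] if truth.hub_lncrna_id else []) + list(
            truth.module_mrna_ids[:2]
        )
    if not targets:
        raise SimulationError("no qPCR targets available")
    n_per_group = config.n_pairs if n_per_group is None else n_per_group
    sd = config.qpcr_noise_sd if noise_sd is None else noise_sd

    ref_ct = 20.0
    base_dct = {t: float(rng.uniform(2.0, 8.0)) for t in targets}
    rows = []
    for group, prefix in (("tumor", "QT"), ("control", "QC")):
        for i in range(1, n_per_group + 1):
            sample = f"{prefix}{i:02d}"
            for rep in range(1, n_replicates + 1):
                rows.append((sample, group, reference_gene, rep,
                             ref_ct + rng.normal(0.0, sd) if sd > 0 else ref_ct))
            for t in targets:
                dct = base_dct[t]
                if group == "tumor":
                    dct -= truth.true_log2fc.get(t, 0.0)
                ct = ref_ct + dct + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                for rep in range(1, n_replicates + 1):
                    noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                    rows.append((sample, group, t, rep, ct + noise))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "target", "replicate", "ct"]
    )


# -- writers ---------------------------------------------------------------

def write_interaction_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_interaction_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"mirna_id", "target_id", "target_biotype"}
    if not required <= set(table.columns):
        raise SimulationError(f"interaction table lacks columns {required}")
    return table


def write_qpcr_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
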