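"""Synthetic tissue cohorts with planted miRNA-target interaction types.

Emulates the structure of real tumor/normal multi-assay cohorts at desk
scale: log-normal FPKM-like marginals for miRNA and gene assays, a
normalized (possibly negative) protein array available only when requested,
and a validated-interaction catalog containing both planted regulatory
pairs and null decoys so sensitivity and specificity are both measurable.

For a planted pair with target correlation strength rho:

* degradation: gene log-abundance = -b * miRNA log-abundance + noise and
  protein = +c * gene + noise (transcript and protein both track the decay);
* inhibition: gene = +b * miRNA + noise and protein = -c * gene + noise
  (transcript persists, protein output drops);
* null: all profiles independent.

b and c are set so the population correlation magnitude of each leg equals
``strength``.  miRNA/gene values are exponentiated to the FPKM scale
(2**log-abundance), so the analysis pipeline's log2(v+1) transform
approximately recovers the planted linear structure; protein stays on the
normalized linear scale.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import InteractionCall
from .io_model import (
    Assay,
    CatalogRecord,
    Condition,
    ExpressionMatrix,
    InteractionCatalog,
    write_expression_matrix,
    write_interaction_catalog,
)
from .pipeline import CharacterizedInteraction

log = logging.getLogger(__name__)

PLANTED_TYPES = ("degradation", "inhibition", "null")


class SimulationConfigError(ValueError):
    """The simulation configuration is infeasible or inconsistent."""


@dataclass(frozen=True)
class PlantedPair:
    mirna_idx: int
    gene_idx: int
    type: str  # degradation | inhibition | null
    strength: float = 0.6

    def __post_init__(self) -> None:
        if self.type not in PLANTED_TYPES:
            raise SimulationConfigError(f"unknown planted type {self.type!r}")
        if not 0.0 < self.strength <= 1.0:
            raise SimulationConfigError("strength must be in (0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a mid-sized tumor cohort: 150 matched samples, FPKM
    log2-marginals centered at 3 with spread 1.5, planted effects of
    correlation magnitude 0.6, and protein rows for 80% of unplanted genes
    (planted genes always get one so both legs of their signature exist).
    """

    n_samples: int = 150
    n_mirna: int = 30
    n_gene: int = 120
    planted: list[PlantedPair] = field(default_factory=list)
    noise_sd: float = 1.5
    fpkm_log_mean: float = 3.0
    fpkm_log_sd: float = 1.5
    protein_coverage: float = 0.8
    seed: int = 0
    tissue: str = "SYNTH"
    condition: Condition = Condition.TUMOR

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        if self.n_samples < 2 or self.n_mirna < 1 or self.n_gene < 1:
            raise SimulationConfigError("cohort dimensions must be positive")
        if self.noise_sd <= 0 or self.fpkm_log_sd <= 0:
            raise SimulationConfigError("noise_sd and fpkm_log_sd must be positive")
        if not 0.0 <= self.protein_coverage <= 1.0:
            raise SimulationConfigError("protein_coverage must be in [0, 1]")
        seen_pairs: set[tuple[int, int]] = set()
        seen_genes: set[int] = set()
        for p in self.planted:
            if not (0 <= p.mirna_idx < self.n_mirna and 0 <= p.gene_idx < self.n_gene):
                raise SimulationConfigError(
                    f"planted indices ({p.mirna_idx}, {p.gene_idx}) out of range"
                )
            if (p.mirna_idx, p.gene_idx) in seen_pairs:
                raise SimulationConfigError(
                    f"duplicate planted pair ({p.mirna_idx}, {p.gene_idx})"
                )
            if p.gene_idx in seen_genes:
                raise SimulationConfigError(
                    f"gene {p.gene_idx} appears in more than one planted record; "
                    "each gene profile is generated from a single parent miRNA"
                )
            seen_pairs.add((p.mirna_idx, p.gene_idx))
            seen_genes.add(p.gene_idx)

    @classmethod
    def default(
        cls,
        n_degradation: int = 10,
        n_inhibition: int = 10,
        n_null: int = 30,
        strength: float = 0.6,
        **kwargs,
    ) -> "SimulationConfig":
        """Standard desk-scale cohort: planted degradation + inhibition pairs
        and null decoys assigned round-robin over distinct genes."""
        cfg = cls(**kwargs)
        total = n_degradation + n_inhibition + n_null
        if total > cfg.n_gene:
            raise SimulationConfigError(
                f"{total} planted records need at least {total} genes "
                f"(n_gene={cfg.n_gene})"
            )
        types = (
            ["degradation"] * n_degradation
            + ["inhibition"] * n_inhibition
            + ["null"] * n_null
        )
        cfg.planted = [
            PlantedPair(
                mirna_idx=i % cfg.n_mirna, gene_idx=i, type=t, strength=strength
            )
            for i, t in enumerate(types)
        ]
        cfg.__post_init__()
        return cfg


@dataclass
class SyntheticCohort:
    matrices: dict[Assay, ExpressionMatrix]
    catalog: InteractionCatalog
    truth: dict[tuple[str, str], str]  # (mirna_id, gene_symbol) -> planted type
    config: SimulationConfig


def _mirna_name(i: int) -> str:
    return f"hsa-miR-syn-{i + 1:04d}"


def _gene_name(i: int) -> str:
    return f"SYNG{i + 1:04d}"


def _sample_name(i: int) -> str:
    return f"TCGA-SY-{i + 1:04d}-01A"


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one cohort; bit-identical under the same config + seed."""
    rng = np.random.default_rng(config.seed)
    n, mu, sd = config.n_samples, config.fpkm_log_mean, config.fpkm_log_sd

    mirna_log = rng.normal(mu, sd, size=(config.n_mirna, n))
    planted_by_gene = {p.gene_idx: p for p in config.planted if p.type != "null"}

    gene_log = np.empty((config.n_gene, n))
    gene_sd = np.full(config.n_gene, sd)  # population sd per gene profile
    for g in range(config.n_gene):
        plant = planted_by_gene.get(g)
        if plant is None:
            gene_log[g] = rng.normal(mu, sd, size=n)
            continue
        rho = plant.strength
        direction = -1.0 if plant.type == "degradation" else 1.0
        # slope making |cor(gene, mirna)| == rho with N(0, noise_sd^2) noise
        b = direction * rho * config.noise_sd / (sd * np.sqrt(1.0 - rho**2)) \
            if rho < 1.0 else None
        if b is None:
            raise SimulationConfigError("strength 1.0 with nonzero noise is infeasible")
        noise = rng.normal(0.0, config.noise_sd, size=n)
        gene_log[g] = mu + b * (mirna_log[plant.mirna_idx] - mu) + noise
        gene_sd[g] = config.noise_sd / np.sqrt(1.0 - rho**2)

    # Protein rows: every planted (non-null) gene, plus a seeded coverage
    # fraction of the remaining genes.  Coverage 0 drops the assay entirely.
    if config.protein_coverage == 0.0:
        covered: list[int] = []
    else:
        covered = sorted(planted_by_gene)
        rest = [g for g in range(config.n_gene) if g not in planted_by_gene]
        n_extra = int(round(config.protein_coverage * len(rest)))
        if n_extra and rest:
            extra = rng.choice(len(rest), size=n_extra, replace=False)
            covered = sorted(set(covered) | {rest[i] for i in extra})

    protein = None
    if covered:
        protein = np.empty((len(covered), n))
        for row, g in enumerate(covered):
            z_g = (gene_log[g] - mu) / gene_sd[g]
            plant = planted_by_gene.get(g)
            if plant is None:
                protein[row] = rng.normal(0.0, 1.0, size=n)
                continue
            rho = plant.strength
            sign_p = 1.0 if plant.type == "degradation" else -1.0
            protein[row] = sign_p * rho * z_g + np.sqrt(1.0 - rho**2) * rng.normal(
                0.0, 1.0, size=n
            )

    samples = [_sample_name(i) for i in range(n)]
    matrices = {
        Assay.MIRNA: ExpressionMatrix(
            Assay.MIRNA,
            pd.DataFrame(
                np.exp2(mirna_log),
                index=[_mirna_name(i) for i in range(config.n_mirna)],
                columns=samples,
            ),
        ),
        Assay.GENE: ExpressionMatrix(
            Assay.GENE,
            pd.DataFrame(
                np.exp2(gene_log),
                index=[_gene_name(i) for i in range(config.n_gene)],
                columns=samples,
            ),
        ),
    }
    if protein is not None:
        matrices[Assay.PROTEIN] = ExpressionMatrix(
            Assay.PROTEIN,
            pd.DataFrame(
                protein, index=[_gene_name(g) for g in covered], columns=samples
            ),
        )

    records = []
    truth = {}
    for k, p in enumerate(config.planted):
        key = (_mirna_name(p.mirna_idx), _gene_name(p.gene_idx))
        records.append(
            CatalogRecord(
                mirna_id=key[0],
                gene_symbol=key[1],
                support_type="Functional MTI",
                source_id=f"SYN{k + 1:06d}",
            )
        )
        truth[key] = p.type
    return SyntheticCohort(
        matrices=matrices,
        catalog=InteractionCatalog(records),
        truth=truth,
        config=config,
    )


def write_cohort_bundle(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Materialize matrices + catalog + truth + config as plain-text files
    directly consumable by the CLI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for assay, mat in cohort.matrices.items():
        p = out_dir / f"{assay.value}.tsv"
        write_expression_matrix(mat, p)
        paths[assay.value] = p
    paths["catalog"] = out_dir / "catalog.csv"
    write_interaction_catalog(cohort.catalog, paths["catalog"])
    paths["truth"] = out_dir / "truth.json"
    with paths["truth"].open("w", encoding="utf-8") as fh:
        json.dump(
            [
                {"mirna_id": m, "gene_symbol": g, "type": t}
                for (m, g), t in sorted(cohort.truth.items())
            ],
            fh,
            indent=1,
        )
        fh.write("\n")
    paths["config"] = out_dir / "simulation_config.json"
    cfg = asdict(cohort.config)
    cfg["condition"] = cohort.config.condition.value
    with paths["config"].open("w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=1)
        fh.write("\n")
    return paths


def read_truth(path: str | Path) -> dict[tuple[str, str], str]:
    with Path(path).open("r", encoding="utf-8") as fh:
        entries = json.load(fh)
    return {(e["mirna_id"], e["gene_symbol"]): e["type"] for e in entries}


#: Calls counted as a correct (non-)detection for a null decoy pair.
_NULL_OK = {
    InteractionCall.NO_EVIDENCE,
    InteractionCall.NO_INTERACTION,
    InteractionCall.NO_INTERACTION_STAR,
}
_TYPED = {InteractionCall.DEGRADATION, InteractionCall.INHIBITION}


def evaluate_recovery(
    results: Sequence[CharacterizedInteraction],
    truth: dict[tuple[str, str], str],
) -> dict:
    """Score characterized results against the planted truth.

    Returns a confusion matrix (truth type x observed call), per-type recall
    for the planted types, and the false-typing rate on null decoys (the
    fraction receiving a degradation/inhibition call).
    """
    if not results:
        raise ValueError("no results to evaluate")
    missing = [r.pair_key for r in results if r.pair_key not in truth]
    if missing:
        raise ValueError(f"results contain pairs absent from truth: {missing[:5]}")

    confusion: dict[str, dict[str, int]] = {
        t: {c.value: 0 for c in InteractionCall} for t in PLANTED_TYPES
    }
    for r in results:
        confusion[truth[r.pair_key]][r.call.value] += 1

    recall = {}
    for t, expected in (("degradation", InteractionCall.DEGRADATION),
                        ("inhibition", InteractionCall.INHIBITION)):
        total = sum(confusion[t].values())
        recall[t] = confusion[t][expected.value] / total if total else float("nan")

    n_null = sum(confusion["null"].values())
    n_false = sum(confusion["null"][c.value] for c in _TYPED)
    return {
        "confusion": confusion,
        "recall": recall,
        "null_false_typing_rate": (n_false / n_null) if n_null else float("nan"),
        "n_null": n_null,
    }
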