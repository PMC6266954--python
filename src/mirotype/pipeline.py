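"""Per-cohort characterization of a validated-interaction catalog, plus
comparison views across tissues and conditions."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationConfig, InteractionCall, apply_multiple_testing, classify_interaction
from .globaltest import (
    DEFAULT_TRANSFORMS,
    GlobalTestConfig,
    PairAssociation,
    Sign,
    pair_association,
)
from .io_model import (
    Assay,
    CohortView,
    Condition,
    DEFAULT_NA_TOKEN,
    FormatError,
    InteractionCatalog,
    TABLE_COLUMNS,
)

log = logging.getLogger(__name__)


@dataclass
class CharacterizedInteraction:
    """One catalog pair's typed result in one tissue + condition."""

    mirna_id: str
    gene_symbol: str
    tissue: str
    condition: Condition
    n_used: int
    mg: PairAssociation
    gp: Optional[PairAssociation]
    call: InteractionCall

    @property
    def pair_key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_symbol)


@dataclass(frozen=True)
class SkippedPair:
    mirna_id: str
    gene_symbol: str
    reason: str


@dataclass
class ComparisonRow:
    mirna_id: str
    gene_symbol: str
    cells: dict[str, Optional[CharacterizedInteraction]]


def _pair_seed(base_seed: int, index: int, leg: int) -> int:
    """Deterministic, order-stable sub-seed for one pair's permutation null."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(index, leg))
    return int(ss.generate_state(1)[0] % (2**31))


def characterize_cohort(
    cohort: CohortView,
    catalog: InteractionCatalog,
    gt_config: GlobalTestConfig = GlobalTestConfig(),
    cls_config: ClassificationConfig = ClassificationConfig(),
) -> tuple[list[CharacterizedInteraction], list[SkippedPair]]:
    """Test and type every catalog pair present in the cohort's matrices.

    For each pair the gene is the response to the miRNA (miRNA-gene leg);
    when the cohort carries protein data and the gene has a protein row,
    the protein is the response to the gene (gene-protein leg).  Pairs whose
    features are absent from the matrices go to the skipped list with a
    reason; results come back sorted by miRNA-gene p-value.
    """
    if len(catalog) == 0:
        raise FormatError("interaction catalog is empty")
    mirna_mat = cohort.matrices.get(Assay.MIRNA)
    gene_mat = cohort.matrices.get(Assay.GENE)
    if mirna_mat is None or gene_mat is None:
        raise FormatError("cohort must carry both miRNA and gene assays")
    protein_mat = cohort.matrices.get(Assay.PROTEIN)

    records = sorted(catalog.records, key=lambda r: (r.mirna_id, r.gene_symbol))
    skipped: list[SkippedPair] = []
    staged = []  # (record, mg, gp)
    for i, rec in enumerate(records):
        if rec.mirna_id not in mirna_mat.data.index:
            skipped.append(SkippedPair(rec.mirna_id, rec.gene_symbol, "mirna_not_in_matrix"))
            continue
        if rec.gene_symbol not in gene_mat.data.index:
            skipped.append(SkippedPair(rec.mirna_id, rec.gene_symbol, "gene_not_in_matrix"))
            continue
        mg = pair_association(
            gene_mat.data.loc[rec.gene_symbol],
            mirna_mat.data.loc[rec.mirna_id],
            response_id=rec.gene_symbol,
            covariate_id=rec.mirna_id,
            response_transform=DEFAULT_TRANSFORMS[Assay.GENE],
            covariate_transform=DEFAULT_TRANSFORMS[Assay.MIRNA],
            config=gt_config,
            seed=_pair_seed(gt_config.seed, i, 0),
        )
        gp = None
        if protein_mat is not None and rec.gene_symbol in protein_mat.data.index:
            gp = pair_association(
                protein_mat.data.loc[rec.gene_symbol],
                gene_mat.data.loc[rec.gene_symbol],
                response_id=rec.gene_symbol,
                covariate_id=rec.gene_symbol,
                response_transform=DEFAULT_TRANSFORMS[Assay.PROTEIN],
                covariate_transform=DEFAULT_TRANSFORMS[Assay.GENE],
                config=gt_config,
                seed=_pair_seed(gt_config.seed, i, 1),
            )
        staged.append((rec, mg, gp))

    if not staged:
        raise FormatError(
            "no catalog pair is testable in this cohort: feature namespaces "
            "of the catalog and the expression matrices do not overlap"
        )

    # Multiple-testing correction per family (miRNA-gene, gene-protein).
    mgs = apply_multiple_testing([mg for _, mg, _ in staged], cls_config.mt_correction)
    gp_idx = [j for j, (_, _, gp) in enumerate(staged) if gp is not None]
    gps_adj = apply_multiple_testing(
        [staged[j][2] for j in gp_idx], cls_config.mt_correction
    )
    gps: list[Optional[PairAssociation]] = [None] * len(staged)
    for j, gp in zip(gp_idx, gps_adj):
        gps[j] = gp

    results = []
    for (rec, _, _), mg, gp in zip(staged, mgs, gps):
        call = classify_interaction(mg, gp, cls_config)
        results.append(
            CharacterizedInteraction(
                mirna_id=rec.mirna_id,
                gene_symbol=rec.gene_symbol,
                tissue=cohort.tissue,
                condition=cohort.condition,
                n_used=mg.n_used,
                mg=mg,
                gp=gp,
                call=call,
            )
        )
    if skipped:
        log.info("characterize_cohort: skipped %d catalog pair(s)", len(skipped))
    return _sorted_rows(results), skipped


def _sort_key(row: CharacterizedInteraction):
    p = row.mg.p_value if row.mg.p_value is not None else math.inf
    return (p, row.mirna_id, row.gene_symbol)


def _sorted_rows(rows: Sequence[CharacterizedInteraction]) -> list[CharacterizedInteraction]:
    return sorted(rows, key=_sort_key)


def compare_runs(
    runs: Sequence[tuple[str, Sequence[CharacterizedInteraction]]]
) -> list[ComparisonRow]:
    """Outer-join runs on (mirna_id, gene_symbol) for side-by-side views.

    Supports tumor-vs-tumor and normal-vs-tumor comparisons across tissues;
    a pair absent from a run yields an absent (None) cell.
    """
    if len(runs) < 2:
        raise ValueError("comparison needs at least two runs")
    labels = [label for label, _ in runs]
    if len(set(labels)) != len(labels):
        raise ValueError("run labels must be unique")
    keys: set[tuple[str, str]] = set()
    indexed: dict[str, dict[tuple[str, str], CharacterizedInteraction]] = {}
    for label, rows in runs:
        by_key = {r.pair_key: r for r in rows}
        indexed[label] = by_key
        keys |= set(by_key)
    return [
        ComparisonRow(
            mirna_id=mirna,
            gene_symbol=gene,
            cells={label: indexed[label].get((mirna, gene)) for label in labels},
        )
        for mirna, gene in sorted(keys)
    ]


def filter_view(
    rows: Sequence[CharacterizedInteraction],
    *,
    mirna_ids: Optional[Iterable[str]] = None,
    gene_symbols: Optional[Iterable[str]] = None,
    calls: Optional[Iterable[InteractionCall | str]] = None,
    max_p: Optional[float] = None,
    protein_only: bool = False,
) -> list[CharacterizedInteraction]:
    """Conjunctive row filters, stably sorted by miRNA-gene p-value."""
    out = list(rows)
    if mirna_ids is not None:
        wanted = set(mirna_ids)
        out = [r for r in out if r.mirna_id in wanted]
    if gene_symbols is not None:
        wanted = set(gene_symbols)
        out = [r for r in out if r.gene_symbol in wanted]
    if calls is not None:
        wanted_calls = {InteractionCall(c) for c in calls}
        out = [r for r in out if r.call in wanted_calls]
    if max_p is not None:
        out = [r for r in out if r.mg.p_value is not None and r.mg.p_value <= max_p]
    if protein_only:
        out = [r for r in out if r.gp is not None]
    return _sorted_rows(out)


def summarize_run(rows: Sequence[CharacterizedInteraction]) -> dict:
    """Per-call counts and the fraction of pairs receiving a typed call
    (degradation or inhibition)."""
    counts = {call.value: 0 for call in InteractionCall}
    for r in rows:
        counts[r.call.value] += 1
    total = len(rows)
    typed = counts[InteractionCall.DEGRADATION.value] + counts[InteractionCall.INHIBITION.value]
    return {
        "counts": counts,
        "n_rows": total,
        "fraction_typed": (typed / total) if total else 0.0,
    }


# ---------------------------------------------------------------------------
# (De)serialization of characterization tables and comparison views
# ---------------------------------------------------------------------------

def read_characterization_table(
    path: str | Path, na_token: str = DEFAULT_NA_TOKEN
) -> list[CharacterizedInteraction]:
    """Read a table written by ``io_model.write_characterization_table``."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    def parse_assoc(prow, pcol, scol, response_id, covariate_id, n):
        p, s = prow[pcol], prow[scol]
        if p == na_token and s == na_token:
            return None
        untestable = p == na_token
        return PairAssociation(
            response_id=response_id,
            covariate_id=covariate_id,
            p_value=None if untestable else float(p),
            sign=Sign(s) if s != na_token else Sign.ZERO,
            n_used=n,
            untestable=untestable,
        )

    rows = []
    for _, r in df.iterrows():
        n = int(r["n"])
        mg = parse_assoc(r, "p_mirna_gene", "sign_mirna_gene", r["gene_symbol"], r["mirna_id"], n)
        if mg is None:
            mg = PairAssociation(
                response_id=r["gene_symbol"], covariate_id=r["mirna_id"],
                p_value=None, sign=Sign.ZERO, n_used=n, untestable=True,
            )
        gp = parse_assoc(r, "p_gene_protein", "sign_gene_protein", r["gene_symbol"], r["gene_symbol"], n)
        rows.append(
            CharacterizedInteraction(
                mirna_id=r["mirna_id"],
                gene_symbol=r["gene_symbol"],
                tissue=r["tissue"],
                condition=Condition(r["condition"]),
                n_used=n,
                mg=mg,
                gp=gp,
                call=InteractionCall(r["interaction_type"]),
            )
        )
    return rows


def write_comparison_table(
    rows: Sequence[ComparisonRow],
    labels: Sequence[str],
    path: str | Path,
    na_token: str = DEFAULT_NA_TOKEN,
) -> None:
    """Wide TSV with one per-run column block per label."""
    from .io_model import format_pvalue

    records = []
    for row in rows:
        rec = {"mirna_id": row.mirna_id, "gene_symbol": row.gene_symbol}
        for label in labels:
            cell = row.cells.get(label)
            prefix = f"{label}."
            if cell is None:
                rec[prefix + "p_mirna_gene"] = na_token
                rec[prefix + "sign_mirna_gene"] = na_token
                rec[prefix + "p_gene_protein"] = na_token
                rec[prefix + "sign_gene_protein"] = na_token
                rec[prefix + "interaction_type"] = na_token
            else:
                mg, gp = cell.mg, cell.gp
                rec[prefix + "p_mirna_gene"] = format_pvalue(mg.p_value) or na_token
                rec[prefix + "sign_mirna_gene"] = mg.sign.value if not mg.untestable else na_token
                rec[prefix + "p_gene_protein"] = (
                    format_pvalue(gp.p_value) or na_token if gp is not None else na_token
                )
                rec[prefix + "sign_gene_protein"] = (
                    gp.sign.value if gp is not None and not gp.untestable else na_token
                )
                rec[prefix + "interaction_type"] = cell.call.value
        records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
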