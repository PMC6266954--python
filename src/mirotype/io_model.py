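"""Domain types and file I/O for matched multi-assay expression cohorts.

An analysis run joins up to three assays measured on (a subset of) the same
tissue samples: miRNA and gene abundance as FPKM-like non-negative values,
and protein abundance as already-normalized (possibly negative) antibody
array intensities.  Samples are linked across assays either by identical
identifiers, by a TCGA-barcode-style prefix, or by an explicit mapping file.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Token written for (and recognized as) a missing value in all text formats.
DEFAULT_NA_TOKEN = "NA"

#: TCGA barcode prefix through the sample-type field, e.g. "TCGA-A7-A0CE-01".
DEFAULT_PREFIX_LENGTH = 15

DEFAULT_MIN_SAMPLES = 8


class FormatError(ValueError):
    """A file or in-memory table violates the expected format."""


class CohortTooSmallError(ValueError):
    """Cross-assay matching left fewer samples than ``min_samples``."""


class Assay(str, Enum):
    MIRNA = "mirna"
    GENE = "gene"
    PROTEIN = "protein"


class Condition(str, Enum):
    NORMAL = "normal"
    TUMOR = "tumor"


@dataclass
class ExpressionMatrix:
    """One assay's features x samples abundance table.

    miRNA/gene values are FPKM-like and must be non-negative; protein values
    are normalized intensities and may be negative.  Missing cells are NaN
    and are handled downstream by per-pair complete-case filtering.
    """

    assay: Assay
    data: pd.DataFrame  # features x samples, float64

    def __post_init__(self) -> None:
        self.assay = Assay(self.assay)
        if not isinstance(self.data, pd.DataFrame):
            raise FormatError("expression values must be a pandas DataFrame")
        self.data = self.data.astype(float)
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise FormatError(f"{self.assay.value}: duplicate feature ids {dups}")
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise FormatError(f"{self.assay.value}: duplicate sample ids {dups}")
        if self.assay in (Assay.MIRNA, Assay.GENE):
            _check_non_negative(self.data, self.assay)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise FormatError(
                f"{self.assay.value}: sample ids not present: {missing[:5]}"
            )
        return ExpressionMatrix(self.assay, self.data.loc[:, list(samples)].copy())


def _check_non_negative(data: pd.DataFrame, assay: Assay) -> None:
    vals = data.to_numpy()
    bad = np.asarray((vals < 0) & ~np.isnan(vals)).nonzero()
    if bad[0].size:
        r, c = bad[0][0], bad[1][0]
        raise FormatError(
            f"{assay.value}: negative value {vals[r, c]} at feature "
            f"{data.index[r]!r}, sample {data.columns[c]!r} (FPKM must be >= 0)"
        )


def read_expression_matrix(
    path: str | Path, assay: Assay | str, na_token: str = DEFAULT_NA_TOKEN
) -> ExpressionMatrix:
    """Read a TSV expression table (row 1 headers, column 1 feature ids).

    All-NA feature rows are dropped (and logged); remaining NA cells are kept
    as missing.  Duplicate ids, unparsable cells and negative FPKM values
    raise :class:`FormatError`.
    """
    assay = Assay(assay)
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected a feature-id column plus sample columns")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample ids {dup}")

    raw = pd.read_csv(
        path, sep="\t", dtype=str, index_col=0, keep_default_na=False, encoding="utf-8"
    )
    raw.columns = sample_ids
    raw.index.name = None  # the feature-id header label is format metadata
    cells = raw.where(raw != na_token)
    numeric = cells.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & cells.notna()
    if bad.to_numpy().any():
        r, c = np.asarray(bad.to_numpy()).nonzero()
        i, j = r[0], c[0]
        raise FormatError(
            f"{path}: non-numeric cell {cells.iat[i, j]!r} at feature "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    all_na = numeric.isna().all(axis=1)
    if all_na.any():
        dropped = list(numeric.index[all_na])
        log.warning(
            "%s: dropped %d all-NA feature rows (%s%s)",
            path,
            len(dropped),
            ", ".join(dropped[:3]),
            "..." if len(dropped) > 3 else "",
        )
        numeric = numeric.loc[~all_na]
    return ExpressionMatrix(assay, numeric)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, na_token: str = DEFAULT_NA_TOKEN
) -> None:
    """Write a TSV expression table that round-trips to full float precision."""
    df = matrix.data.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep=na_token)


# ---------------------------------------------------------------------------
# Validated-interaction catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogRecord:
    mirna_id: str
    gene_symbol: str
    support_type: str = ""
    source_id: str = ""


@dataclass
class InteractionCatalog:
    """De-duplicated validated miRNA -> target-gene pairs with provenance."""

    records: list[CatalogRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped = []
        for rec in self.records:
            if not rec.mirna_id or not rec.gene_symbol:
                raise FormatError("catalog record with empty miRNA id or gene symbol")
            key = (rec.mirna_id, rec.gene_symbol)
            if key in seen:
                continue
            seen.add(key)
            deduped.append(rec)
        n_dup = len(self.records) - len(deduped)
        if n_dup:
            log.info("interaction catalog: dropped %d duplicate pair(s)", n_dup)
        self.records = deduped

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> list[tuple[str, str]]:
        return [(r.mirna_id, r.gene_symbol) for r in self.records]


# Recognized (normalized) header names for each catalog field.  Covers both
# plain exports and miRTarBase-style column names ("miRTarBase ID", "miRNA",
# "Target Gene", "Support Type").
_CATALOG_HEADERS = {
    "mirna_id": {"mirna", "mirna id", "mirnaid"},
    "gene_symbol": {"target gene", "gene symbol", "gene", "target", "genesymbol"},
    "support_type": {"support type", "supporttype"},
    "source_id": {"mirtarbase id", "source id", "source", "id"},
}


def _normalize_header(name: str) -> str:
    return " ".join(name.strip().lower().replace("_", " ").split())


def read_interaction_catalog(path: str | Path) -> InteractionCatalog:
    """Read a validated-interaction CSV, mapping headers case-insensitively.

    The miRNA and target-gene columns are mandatory; support-type and
    source-id columns are optional and default to "".
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except pd.errors.EmptyDataError:
        log.warning("%s: empty catalog file", path)
        return InteractionCatalog([])
    colmap: dict[str, str] = {}
    for col in df.columns:
        norm = _normalize_header(col)
        for fld, names in _CATALOG_HEADERS.items():
            if norm in names and fld not in colmap:
                colmap[fld] = col
    for mandatory in ("mirna_id", "gene_symbol"):
        if mandatory not in colmap:
            raise FormatError(
                f"{path}: no column recognized for {mandatory} "
                f"(headers: {list(df.columns)})"
            )
    records = [
        CatalogRecord(
            mirna_id=row[colmap["mirna_id"]].strip(),
            gene_symbol=row[colmap["gene_symbol"]].strip(),
            support_type=row[colmap["support_type"]].strip()
            if "support_type" in colmap
            else "",
            source_id=row[colmap["source_id"]].strip() if "source_id" in colmap else "",
        )
        for _, row in df.iterrows()
    ]
    if not records:
        log.warning("%s: catalog has a header but no records", path)
    return InteractionCatalog(records)


def write_interaction_catalog(catalog: InteractionCatalog, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "miRTarBase ID": r.source_id,
                "miRNA": r.mirna_id,
                "Target Gene": r.gene_symbol,
                "Support Type": r.support_type,
            }
            for r in catalog.records
        ],
        columns=["miRTarBase ID", "miRNA", "Target Gene", "Support Type"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sample maps and cross-assay matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMapEntry:
    cohort_sample: str
    mirna_sample: str | None = None
    gene_sample: str | None = None
    protein_sample: str | None = None

    def assay_sample(self, assay: Assay) -> str | None:
        return {
            Assay.MIRNA: self.mirna_sample,
            Assay.GENE: self.gene_sample,
            Assay.PROTEIN: self.protein_sample,
        }[assay]


@dataclass
class SampleMap:
    entries: list[SampleMapEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.cohort_sample for e in self.entries]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"sample map: duplicate cohort samples {dup}")


def read_sample_map(path: str | Path, na_token: str = DEFAULT_NA_TOKEN) -> SampleMap:
    """Read a TSV with columns cohort_sample, mirna_sample, gene_sample, protein_sample."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "cohort_sample" not in df.columns:
        raise FormatError(f"{path}: sample map needs a 'cohort_sample' column")

    def cell(row, col):
        v = row.get(col, na_token)
        return None if v in (na_token, "") else v

    return SampleMap(
        [
            SampleMapEntry(
                cohort_sample=row["cohort_sample"],
                mirna_sample=cell(row, "mirna_sample"),
                gene_sample=cell(row, "gene_sample"),
                protein_sample=cell(row, "protein_sample"),
            )
            for _, row in df.iterrows()
        ]
    )


@dataclass
class CohortView:
    """Sample-aligned slices of 2-3 assays for one tissue + condition."""

    tissue: str
    condition: Condition
    matrices: dict[Assay, ExpressionMatrix]
    n: int
    has_protein: bool

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        orders = [m.sample_ids for m in self.matrices.values()]
        if any(o != orders[0] for o in orders[1:]):
            raise FormatError("cohort matrices are not identically sample-ordered")
        if orders and len(orders[0]) != self.n:
            raise FormatError("cohort n does not match matrix sample count")
        if self.condition is Condition.NORMAL and self.has_protein:
            log.info(
                "normal-condition cohort carries an explicitly supplied protein assay"
            )

    def profile(self, assay: Assay, feature_id: str) -> pd.Series | None:
        mat = self.matrices.get(assay)
        if mat is None or feature_id not in mat.data.index:
            return None
        return mat.data.loc[feature_id]


def _group_columns_by_prefix(
    matrix: ExpressionMatrix, prefix_length: int
) -> ExpressionMatrix:
    """Collapse aliquot columns sharing a barcode prefix by arithmetic mean.

    Columns are sorted before grouping so aggregation is bitwise independent
    of input column order.
    """
    df = matrix.data[sorted(matrix.data.columns)]
    keys = [str(c)[:prefix_length] for c in df.columns]
    grouped = df.T.groupby(pd.Index(keys, name="group")).mean().T
    return ExpressionMatrix(matrix.assay, grouped)


def match_samples(
    matrices: Mapping[Assay, ExpressionMatrix],
    strategy: str = "exact",
    sample_map: SampleMap | None = None,
    *,
    prefix_length: int = DEFAULT_PREFIX_LENGTH,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    tissue: str = "",
    condition: Condition | str = Condition.TUMOR,
) -> CohortView:
    """Align 2-3 assay matrices on a shared sample set.

    strategy "exact" intersects identical sample ids; "prefix" groups ids by
    a barcode prefix (aliquots within an assay averaged) and intersects the
    groups; "mapfile" follows an explicit :class:`SampleMap`.
    """
    matrices = {Assay(a): m for a, m in matrices.items()}
    if len(matrices) < 2:
        raise FormatError("sample matching needs at least two assays")
    order = [a for a in (Assay.MIRNA, Assay.GENE, Assay.PROTEIN) if a in matrices]

    if strategy == "exact":
        working = {a: matrices[a] for a in order}
        common = [
            s
            for s in working[order[0]].sample_ids
            if all(s in working[a].data.columns for a in order[1:])
        ]
    elif strategy == "prefix":
        working = {a: _group_columns_by_prefix(matrices[a], prefix_length) for a in order}
        common = [
            s
            for s in working[order[0]].sample_ids
            if all(s in working[a].data.columns for a in order[1:])
        ]
    elif strategy == "mapfile":
        if sample_map is None:
            raise FormatError("strategy 'mapfile' requires a sample map")
        usable: list[SampleMapEntry] = []
        for entry in sample_map.entries:
            ids = {a: entry.assay_sample(a) for a in order}
            if any(v is None for v in ids.values()):
                continue
            for a, v in ids.items():
                if v not in matrices[a].data.columns:
                    raise FormatError(
                        f"sample map: {a.value} sample {v!r} (cohort sample "
                        f"{entry.cohort_sample!r}) not found in the {a.value} matrix"
                    )
            usable.append(entry)
        working = {}
        for a in order:
            cols = [entry.assay_sample(a) for entry in usable]
            df = matrices[a].data.loc[:, cols].copy()
            df.columns = [entry.cohort_sample for entry in usable]
            working[a] = ExpressionMatrix(a, df)
        common = [entry.cohort_sample for entry in usable]
    else:
        raise FormatError(f"unknown matching strategy {strategy!r}")

    if len(common) < min_samples:
        limiting = min(order, key=lambda a: working[a].n_samples)
        raise CohortTooSmallError(
            f"matched cohort has {len(common)} samples (< min_samples="
            f"{min_samples}); limiting assay: {limiting.value}"
        )
    aligned = {a: working[a].subset_samples(common) for a in order}
    return CohortView(
        tissue=tissue,
        condition=Condition(condition),
        matrices=aligned,
        n=len(common),
        has_protein=Assay.PROTEIN in aligned,
    )


# ---------------------------------------------------------------------------
# Characterization-table writer
# ---------------------------------------------------------------------------

#: Output column order for characterization tables.
TABLE_COLUMNS = [
    "mirna_id",
    "gene_symbol",
    "tissue",
    "condition",
    "n",
    "p_mirna_gene",
    "sign_mirna_gene",
    "p_gene_protein",
    "sign_gene_protein",
    "interaction_type",
]


def format_pvalue(p: float | None) -> str | None:
    """Scientific notation with 3 significant digits, e.g. 1.60e-03."""
    if p is None:
        return None
    return f"{p:.2e}"


def _row_to_record(row, na_token: str) -> dict[str, str]:
    mg = row.mg
    gp = row.gp

    def na(v):
        return na_token if v is None else v

    return {
        "mirna_id": row.mirna_id,
        "gene_symbol": row.gene_symbol,
        "tissue": row.tissue,
        "condition": str(getattr(row.condition, "value", row.condition)),
        "n": str(row.n_used),
        "p_mirna_gene": na(format_pvalue(mg.p_value) if mg is not None else None),
        "sign_mirna_gene": na(mg.sign.value if mg is not None else None),
        "p_gene_protein": na(format_pvalue(gp.p_value) if gp is not None else None),
        "sign_gene_protein": na(gp.sign.value if gp is not None else None),
        "interaction_type": str(getattr(row.call, "value", row.call)),
    }


def write_characterization_table(
    rows: Iterable,
    path: str | Path,
    fmt: str = "tsv",
    na_token: str = DEFAULT_NA_TOKEN,
) -> None:
    """Serialize characterized interactions to TSV/CSV/JSON.

    Column order is fixed (:data:`TABLE_COLUMNS`); p-values are printed in
    scientific notation with 3 significant digits; absent protein-leg fields
    are written as the NA token.
    """
    records = [_row_to_record(r, na_token) for r in rows]
    df = pd.DataFrame(records, columns=TABLE_COLUMNS)
    path = Path(path)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        with path.open("w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
    else:
        raise FormatError(f"unknown output format {fmt!r}")
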