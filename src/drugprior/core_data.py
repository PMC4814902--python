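"""Domain types, tabular I/O, dataset alignment and the synthetic generator.

All tables are tab-delimited UTF-8 text. Feature matrices and the response
table have the cell-line identifier in the first column and gene / drug
identifiers in the header row; identifier matching is case-sensitive exact
string match (HUGO symbols for genes). Missing IC50 values are stored as
absent (NaN), never as zero or a censored maximum dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_TYPES = ("mutation", "variation", "expression", "cnv")
BINARY_TYPES = frozenset({"mutation", "variation"})

#: IC50 threshold (μM) separating sensitive (≤) from resistant (>) cell lines.
DEFAULT_SENSITIVITY_THRESHOLD = 0.5


class DataError(ValueError):
    """Base error for malformed or inconsistent input data."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending cell."""


class ValidationError(DataError):
    """Parsed data violates a domain invariant."""


class AlignmentWarning(UserWarning):
    """A (feature type, drug) pair has no usable cell lines."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DrugResponseTable:
    """IC50 (μM) per (cell line, drug) with tissue and drug-class annotations.

    ``ic50`` is a cell-line × drug DataFrame; absent measurements are NaN.
    Every cell line carries a tissue label (``"unknown"`` when unannotated).
    """

    ic50: pd.DataFrame
    tissue: dict[str, str] = field(default_factory=dict)
    drug_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ic50.index.duplicated().any():
            dupes = self.ic50.index[self.ic50.index.duplicated()].tolist()
            raise ValidationError(f"duplicate cell-line identifiers: {dupes}")
        if self.ic50.columns.duplicated().any():
            dupes = self.ic50.columns[self.ic50.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate drug identifiers: {dupes}")
        vals = self.ic50.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            bad = np.argwhere(np.isfinite(vals) & (vals <= 0))[0]
            raise ValidationError(
                "non-positive IC50 at cell line "
                f"{self.ic50.index[bad[0]]!r}, drug {self.ic50.columns[bad[1]]!r}"
            )
        for cell in self.ic50.index:
            self.tissue.setdefault(cell, "unknown")

    @property
    def drugs(self) -> list[str]:
        return list(self.ic50.columns)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.ic50.index)

    def assayed_cells(self, drug: str) -> pd.Series:
        """IC50 series for one drug restricted to assayed cell lines."""
        if drug not in self.ic50.columns:
            raise KeyError(f"drug {drug!r} not in response table")
        col = self.ic50[drug].dropna()
        if col.empty:
            raise DataError(f"drug {drug!r} has no assayed cell lines")
        return col


@dataclass
class FeatureMatrix:
    """Cell-line × gene matrix of one genomic feature type.

    Mutation and variation matrices are binary indicators (1 = gene carries
    ≥1 qualifying variant in that cell line). Expression values are log2 RMA
    intensities; CNV values are log2 copy-number ratios (negative = loss).
    """

    feature_type: str
    values: pd.DataFrame
    scale_note: str = ""

    def __post_init__(self) -> None:
        known = set(FEATURE_TYPES) | {"hybrid"}
        if self.feature_type not in known:
            raise ValidationError(f"unknown feature type {self.feature_type!r}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate cell-line identifiers: {dupes}")
        if self.feature_type in BINARY_TYPES:
            arr = self.values.to_numpy(dtype=float)
            ok = np.isin(arr, (0.0, 1.0)) | np.isnan(arr)
            if not ok.all():
                i, j = np.argwhere(~ok)[0]
                raise ValidationError(
                    f"{self.feature_type} matrix must be binary; value "
                    f"{arr[i, j]!r} at cell line {self.values.index[i]!r}, "
                    f"gene {self.values.columns[j]!r}"
                )
        if not self.scale_note:
            self.scale_note = {
                "expression": "log2 RMA",
                "cnv": "log2 copy ratio",
            }.get(self.feature_type, "binary indicator")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def is_binary(self) -> bool:
        return self.feature_type in BINARY_TYPES


@dataclass
class AlignedDataset:
    """A response table plus feature matrices aligned by cell-line intersection.

    ``common_cells[(feature_type, drug)]`` lists, lexicographically, the cell
    lines carrying both that feature type and an IC50 for that drug. Pairs
    with an empty intersection are flagged in ``unusable_pairs`` (a warning is
    emitted at construction); no value is ever imputed.
    """

    response: DrugResponseTable
    matrices: dict[str, FeatureMatrix]
    common_cells: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    unusable_pairs: list[tuple[str, str]] = field(default_factory=list)
    #: synthetic datasets record planted effects: drug -> [(type, gene, beta)]
    causal_genes: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)

    def cells_for(self, feature_type: str, drug: str) -> list[str]:
        key = (feature_type, drug)
        if key not in self.common_cells:
            raise KeyError(f"no alignment for {key}")
        return self.common_cells[key]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic pharmacogenomic panel generator.

    Defaults emulate a CCLE-shaped panel at test scale: a few hundred cell
    lines, Bernoulli(0.1) gene mutations (variations a superset), N(7, 2²)
    log2 expression, N(0, 0.5²) log2 copy ratios, and per-drug IC50 produced
    as 10^(linear effect of ``n_causal`` planted genes + Gaussian noise),
    centred so both resistant (>0.5 μM) and sensitive (≤0.5 μM) lines exist.
    """

    n_cells: int = 200
    n_genes: Mapping[str, int] = field(
        default_factory=lambda: {
            "mutation": 200, "variation": 200, "expression": 300, "cnv": 250,
        }
    )
    n_drugs: int = 6
    n_causal: int = 5
    effect_size: float = 1.0
    noise_sd: float = 0.3
    mutation_rate: float = 0.1
    tissue_count: int = 5
    cell_overlap: float = 0.9
    causal_feature_types: tuple[str, ...] = ("expression",)
    log_ic50_spread: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_cells, self.n_drugs, self.n_causal, self.tissue_count]
        if any(c <= 0 for c in counts) or any(v <= 0 for v in self.n_genes.values()):
            raise ValidationError("all counts must be positive")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValidationError("mutation_rate must lie in [0, 1]")
        if not 0.0 < self.cell_overlap <= 1.0:
            raise ValidationError("cell_overlap must lie in (0, 1]")
        for ftype in self.causal_feature_types:
            if ftype not in FEATURE_TYPES:
                raise ValidationError(f"unknown causal feature type {ftype!r}")
            if self.n_causal > self.n_genes.get(ftype, 0):
                raise ValidationError(
                    f"n_causal={self.n_causal} exceeds n_genes for {ftype!r}"
                )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_numeric_table(path: str | Path, what: str) -> pd.DataFrame:
    """Read a tab-delimited matrix, reporting the first non-numeric cell."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].tolist()
        raise ValidationError(f"duplicate cell-line identifiers in {what}: {dupes}")
    out = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = raw.index[bad.argmax()]
            raise ParseError(
                f"non-numeric value {raw.loc[row, col]!r} in {what} at "
                f"row {row!r}, column {col!r}"
            )
        out[col] = converted
    frame = pd.DataFrame(out, index=raw.index)
    frame.index.name = None  # header label is file formatting, not identity
    return frame


def _read_two_column(path: str | Path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    key_col, val_col = table.columns[:2]
    return dict(zip(table[key_col], table[val_col]))


def load_response_table(
    path: str | Path,
    tissue_path: str | Path | None = None,
    class_path: str | Path | None = None,
) -> DrugResponseTable:
    """Load an IC50 (μM) table plus optional tissue and drug-class annotations.

    The IC50 file is cell-line × drug; blanks denote unassayed pairs. Tissue
    and class files are two-column (identifier, label) tables.
    """
    ic50 = _read_numeric_table(path, "IC50 table")
    tissue = _read_two_column(tissue_path) if tissue_path else {}
    drug_class = _read_two_column(class_path) if class_path else {}
    return DrugResponseTable(ic50=ic50, tissue=tissue, drug_class=drug_class)


def write_response_table(
    table: DrugResponseTable,
    path: str | Path,
    tissue_path: str | Path | None = None,
    class_path: str | Path | None = None,
) -> None:
    table.ic50.to_csv(path, sep="\t", index_label="cell_line")
    if tissue_path:
        pd.Series(table.tissue, name="tissue").rename_axis("cell_line").to_csv(
            tissue_path, sep="\t"
        )
    if class_path:
        pd.Series(table.drug_class, name="class").rename_axis("drug").to_csv(
            class_path, sep="\t"
        )


def load_feature_matrix(path: str | Path, feature_type: str) -> FeatureMatrix:
    """Load one cell-line × gene matrix; binary types are validated as {0,1}."""
    if feature_type not in FEATURE_TYPES:
        raise ValidationError(f"feature_type must be one of {FEATURE_TYPES}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({g for g in header if header.count(g) > 1})
        raise ValidationError(f"duplicate gene columns in {path}: {dupes}")
    values = _read_numeric_table(path, f"{feature_type} matrix")
    return FeatureMatrix(feature_type=feature_type, values=values)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="cell_line")


def load_bias_reference() -> pd.DataFrame:
    """Bundled reference table of per-drug most-biased mutated genes.

    Counts and fractions of mutant cell lines among resistant and sensitive
    groups for the 24-drug CCLE panel (columns: drug, gene, total, mut_res,
    n_res, f_res, mut_sen, n_sen, f_sen, diff).
    """
    with resources.files("drugprior.data").joinpath(
        "mutation_bias_reference.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_drug_annotations() -> pd.DataFrame:
    """Bundled annotation of the 24-drug panel: target, class, clinical status."""
    with resources.files("drugprior.data").joinpath(
        "drug_annotations.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_datasets(
    response: DrugResponseTable, matrices: Sequence[FeatureMatrix]
) -> AlignedDataset:
    """Intersect cell-line sets per (feature type, drug); never impute.

    The CCLE-style cohorts differ per data type (sequencing, expression, CNV
    and drug screening each cover a different subset of lines), so each
    (feature type, drug) pair gets its own lexicographically ordered
    intersection. Empty pairs are flagged unusable with a warning.
    """
    if not matrices:
        raise DataError("at least one feature matrix required")
    mats = {m.feature_type: m for m in matrices}
    if len(mats) != len(matrices):
        raise DataError("one matrix per feature type")
    common: dict[tuple[str, str], list[str]] = {}
    unusable: list[tuple[str, str]] = []
    for ftype, mat in mats.items():
        mat_cells = set(mat.cell_lines)
        for drug in response.drugs:
            assayed = set(response.ic50[drug].dropna().index)
            cells = sorted(mat_cells & assayed)
            common[(ftype, drug)] = cells
            if not cells:
                unusable.append((ftype, drug))
                warnings.warn(
                    f"no shared cell lines for feature {ftype!r}, drug {drug!r}",
                    AlignmentWarning,
                    stacklevel=2,
                )
    return AlignedDataset(
        response=response, matrices=mats, common_cells=common,
        unusable_pairs=unusable,
    )


# ---------------------------------------------------------------------------
# Synthetic panel generator
# ---------------------------------------------------------------------------

def generate_synthetic_dataset(config: SyntheticConfig) -> AlignedDataset:
    """Generate a CCLE-shaped panel with planted gene → IC50 effects.

    For each drug, ``n_causal`` genes are drawn (split across
    ``causal_feature_types``) and log10 IC50 is a linear combination of their
    standardized values plus N(0, noise_sd²) noise, then affinely rescaled to
    mean log10(0.5) and standard deviation ``log_ic50_spread`` so the panel
    contains both resistant and sensitive lines. Planted identities and
    coefficients are recorded in ``causal_genes`` for recovery tests. The same
    seed reproduces the dataset bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    cells = [f"CL{i:04d}" for i in range(config.n_cells)]
    tissues = [f"tissue{t}" for t in range(config.tissue_count)]
    tissue_map = {c: tissues[i % config.tissue_count] for i, c in enumerate(cells)}

    full: dict[str, pd.DataFrame] = {}
    for ftype in FEATURE_TYPES:
        n_genes = config.n_genes.get(ftype, 0)
        if n_genes == 0:
            continue
        genes = [f"{ftype[:3].upper()}{j:04d}" for j in range(n_genes)]
        if ftype == "mutation":
            arr = (rng.random((config.n_cells, n_genes)) < config.mutation_rate)
            arr = arr.astype(float)
        elif ftype == "variation":
            # variations are a superset of mutations plus benign polymorphisms
            base = full.get("mutation")
            extra = (rng.random((config.n_cells, n_genes)) < config.mutation_rate)
            if base is not None and base.shape == extra.shape:
                arr = np.maximum(base.to_numpy(), extra.astype(float))
            else:
                arr = extra.astype(float)
        elif ftype == "expression":
            arr = rng.normal(7.0, 2.0, size=(config.n_cells, n_genes))
        else:  # cnv
            arr = rng.normal(0.0, 0.5, size=(config.n_cells, n_genes))
        full[ftype] = pd.DataFrame(arr, index=cells, columns=genes)

    drugs = [f"drug{d:02d}" for d in range(config.n_drugs)]
    class_labels = ("MEK inhibitor", "cytotoxic", "HSP90 inhibitor")
    drug_class = {d: class_labels[i % len(class_labels)] for i, d in enumerate(drugs)}

    log_half = np.log10(DEFAULT_SENSITIVITY_THRESHOLD)
    ic50 = {}
    causal: dict[str, list[tuple[str, str, float]]] = {}
    per_type = _split_counts(config.n_causal, len(config.causal_feature_types))
    for drug in drugs:
        z = rng.normal(0.0, config.noise_sd, size=config.n_cells)
        planted: list[tuple[str, str, float]] = []
        for ftype, k in zip(config.causal_feature_types, per_type):
            frame = full[ftype]
            usable = [g for g in frame.columns if frame[g].std() > 0]
            picks = rng.choice(len(usable), size=k, replace=False)
            for idx in picks:
                gene = usable[int(idx)]
                beta = float(rng.choice((-1.0, 1.0)) * config.effect_size)
                col = frame[gene].to_numpy()
                z = z + beta * (col - col.mean()) / col.std()
                planted.append((ftype, gene, beta))
        spread = z.std()
        if spread > 0:
            z = (z - z.mean()) / spread * config.log_ic50_spread
        log_ic50 = z + log_half
        ic50[drug] = 10.0 ** log_ic50
        causal[drug] = planted

    response = DrugResponseTable(
        ic50=pd.DataFrame(ic50, index=cells),
        tissue=tissue_map,
        drug_class=drug_class,
    )

    matrices = []
    for ftype, frame in full.items():
        keep_n = max(2, int(round(config.cell_overlap * config.n_cells)))
        keep_idx = np.sort(rng.choice(config.n_cells, size=keep_n, replace=False))
        matrices.append(
            FeatureMatrix(feature_type=ftype, values=frame.iloc[keep_idx])
        )

    aligned = align_datasets(response, matrices)
    aligned.causal_genes = causal
    return aligned


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]
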