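"""Resistance/sensitivity statistics for drug × gene pairs.

Cell lines are dichotomized at an IC50 threshold (default 0.5 μM, sensitive
at or below). For binary features (mutation/variation) the central quantity
is the bias statistic

    diff = f_res − f_sen,

where f_res is the fraction of resistant cell lines carrying the altered
gene and f_sen the corresponding fraction among sensitive lines; a large
positive diff marks a gene whose alteration is enriched in resistant lines.
For continuous features (expression/CNV) the module reports resistant vs
sensitive group means, their difference, and the Pearson correlation with
IC50. The signature statistic flips the conditioning: mean IC50 in mutant vs
wild-type lines, with a two-sample significance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    DEFAULT_SENSITIVITY_THRESHOLD,
    DataError,
    DrugResponseTable,
    FeatureMatrix,
)


class StatsWarning(UserWarning):
    pass


@dataclass
class ResponseLabels:
    """Partition of a drug's assayed cell lines at an IC50 threshold."""

    drug: str
    resistant: list[str]
    sensitive: list[str]
    threshold: float = DEFAULT_SENSITIVITY_THRESHOLD

    def __post_init__(self) -> None:
        overlap = set(self.resistant) & set(self.sensitive)
        if overlap:
            raise DataError(f"cells in both groups: {sorted(overlap)}")

    @property
    def n_assayed(self) -> int:
        return len(self.resistant) + len(self.sensitive)


@dataclass
class BiasResult:
    """Mutation-bias quantities for one (drug, gene) pair.

    Fractions are kept at full precision; ``rounded()`` reproduces the
    3-decimal display convention in which the difference is taken between the
    already-rounded fractions.
    """

    drug: str
    gene: str
    mut_res: int
    n_res: int
    mut_sen: int
    n_sen: int

    def __post_init__(self) -> None:
        if self.mut_res > self.n_res or self.mut_sen > self.n_sen:
            raise DataError("mutant count exceeds group size")

    @property
    def f_res(self) -> float:
        return self.mut_res / self.n_res if self.n_res else float("nan")

    @property
    def f_sen(self) -> float:
        return self.mut_sen / self.n_sen if self.n_sen else float("nan")

    @property
    def diff(self) -> float:
        return self.f_res - self.f_sen

    @property
    def total(self) -> int:
        return self.n_res + self.n_sen

    def rounded(self, ndigits: int = 3) -> tuple[float, float, float]:
        """(f_res, f_sen, diff) for display; diff from the rounded fractions."""
        fr = round(self.f_res, ndigits)
        fs = round(self.f_sen, ndigits)
        return fr, fs, round(fr - fs, ndigits)


@dataclass
class ContinuousDiffResult:
    """Group means, their difference, and the feature–IC50 correlation."""

    drug: str
    gene: str
    mean_res: float
    mean_sen: float
    r_ic50: float  # NaN when undefined (zero variance)

    @property
    def diff(self) -> float:
        return self.mean_res - self.mean_sen


@dataclass
class SignatureRecord:
    """Mean IC50 in mutant vs wild-type cell lines with a two-sample p-value."""

    drug: str
    gene: str
    n_mut: int
    n_wild: int
    mean_ic50_mut: float
    mean_ic50_wild: float
    p_value: float  # NaN when the test is undefined

    @property
    def diff_ic50(self) -> float:
        return self.mean_ic50_mut - self.mean_ic50_wild

    @property
    def testable(self) -> bool:
        return np.isfinite(self.p_value)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def classify_cells(
    response: DrugResponseTable,
    drug: str,
    threshold: float = DEFAULT_SENSITIVITY_THRESHOLD,
) -> ResponseLabels:
    """Partition assayed cell lines: sensitive iff IC50 ≤ threshold (μM).

    Cells without an IC50 for the drug are excluded, not labelled.
    """
    col = response.assayed_cells(drug)
    sensitive = sorted(col.index[col <= threshold])
    resistant = sorted(col.index[col > threshold])
    return ResponseLabels(
        drug=drug, resistant=resistant, sensitive=sensitive, threshold=threshold
    )


def binary_bias(
    labels: ResponseLabels, matrix: FeatureMatrix, gene: str
) -> BiasResult:
    """Bias statistic for one gene, over cells present in both inputs."""
    if not matrix.is_binary:
        raise DataError("binary_bias requires a mutation or variation matrix")
    if gene not in matrix.values.columns:
        raise KeyError(f"gene {gene!r} not in {matrix.feature_type} matrix")
    col = matrix.values[gene].dropna()
    res = [c for c in labels.resistant if c in col.index]
    sen = [c for c in labels.sensitive if c in col.index]
    if not res or not sen:
        empty = "resistant" if not res else "sensitive"
        raise DataError(
            f"empty {empty} group for drug {labels.drug!r}, gene {gene!r}"
        )
    return BiasResult(
        drug=labels.drug,
        gene=gene,
        mut_res=int(col.loc[res].sum()),
        n_res=len(res),
        mut_sen=int(col.loc[sen].sum()),
        n_sen=len(sen),
    )


def bias_table(labels: ResponseLabels, matrix: FeatureMatrix) -> list[BiasResult]:
    """Per-gene bias results sorted by diff descending, ties by gene symbol."""
    results = []
    for gene in matrix.genes:
        try:
            results.append(binary_bias(labels, matrix, gene))
        except DataError as exc:
            warnings.warn(f"skipping gene {gene!r}: {exc}", StatsWarning,
                          stacklevel=2)
    results.sort(key=lambda r: (-r.diff, r.gene))
    return results


def continuous_stats(
    labels: ResponseLabels,
    matrix: FeatureMatrix,
    ic50: pd.Series,
    gene: str,
) -> ContinuousDiffResult:
    """Resistant/sensitive mean difference and Pearson r with IC50.

    The correlation is computed over cell lines having both the feature and
    an IC50; zero variance in either vector yields NaN (undefined), never 0.
    """
    if gene not in matrix.values.columns:
        raise KeyError(f"gene {gene!r} not in {matrix.feature_type} matrix")
    col = matrix.values[gene].dropna()
    res = [c for c in labels.resistant if c in col.index]
    sen = [c for c in labels.sensitive if c in col.index]
    shared = col.index.intersection(ic50.dropna().index)
    if len(shared) < 2:
        raise DataError(f"fewer than 2 cells shared for gene {gene!r}")
    x = col.loc[shared].to_numpy(dtype=float)
    y = ic50.loc[shared].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return ContinuousDiffResult(
        drug=labels.drug,
        gene=gene,
        mean_res=float(col.loc[res].mean()) if res else float("nan"),
        mean_sen=float(col.loc[sen].mean()) if sen else float("nan"),
        r_ic50=r,
    )


def mutant_vs_wild_test(
    response: DrugResponseTable,
    matrix: FeatureMatrix,
    gene: str,
    drug: str,
    test: str = "mannwhitney",
) -> SignatureRecord:
    """Two-sided test of IC50 between mutant and wild-type cell lines.

    ``test`` is ``"mannwhitney"`` (rank test on IC50; robust to the
    heavy-tailed μM scale) or ``"welch"`` (Welch's t on log10 IC50). Means
    are reported on the μM scale. A group of size < 2, or zero spread across
    both groups, leaves the p-value NaN.
    """
    if not matrix.is_binary:
        raise DataError("mutant_vs_wild_test requires a binary matrix")
    if test not in ("mannwhitney", "welch"):
        raise ValueError(f"unknown test {test!r}")
    col = matrix.values[gene].dropna()
    ic50 = response.assayed_cells(drug)
    shared = col.index.intersection(ic50.index)
    mut = ic50.loc[shared[col.loc[shared] == 1]].to_numpy(dtype=float)
    wild = ic50.loc[shared[col.loc[shared] == 0]].to_numpy(dtype=float)
    if mut.size == 0 or wild.size == 0:
        raise DataError(
            f"empty {'mutant' if mut.size == 0 else 'wild'} group for "
            f"gene {gene!r}, drug {drug!r}"
        )
    p = float("nan")
    if mut.size >= 2 and wild.size >= 2:
        pooled = np.concatenate([mut, wild])
        if np.ptp(pooled) > 0:
            if test == "mannwhitney":
                p = float(stats.mannwhitneyu(
                    mut, wild, alternative="two-sided"
                ).pvalue)
            else:
                res = stats.ttest_ind(
                    np.log10(mut), np.log10(wild), equal_var=False
                )
                p = float(res.pvalue)
            if not np.isfinite(p):
                p = float("nan")
    return SignatureRecord(
        drug=drug,
        gene=gene,
        n_mut=int(mut.size),
        n_wild=int(wild.size),
        mean_ic50_mut=float(mut.mean()),
        mean_ic50_wild=float(wild.mean()),
        p_value=p,
    )


def tissue_summary(
    response: DrugResponseTable,
    threshold: float = DEFAULT_SENSITIVITY_THRESHOLD,
) -> pd.DataFrame:
    """Percent of sensitive cell lines per (tissue, drug).

    Entries are 100 × sensitive/assayed within the tissue; (tissue, drug)
    combinations with no assayed lines are NaN, and tissues with no assayed
    lines for any drug are omitted.
    """
    tissues = sorted(set(response.tissue.get(c, "unknown")
                         for c in response.cell_lines))
    out = pd.DataFrame(index=tissues, columns=response.drugs, dtype=float)
    for drug in response.drugs:
        col = response.assayed_cells(drug)
        for tissue in tissues:
            cells = [c for c in col.index
                     if response.tissue.get(c, "unknown") == tissue]
            if cells:
                sens = int((col.loc[cells] <= threshold).sum())
                out.loc[tissue, drug] = 100.0 * sens / len(cells)
    return out.dropna(how="all")


def drug_group_bias(
    response: DrugResponseTable,
    matrix: FeatureMatrix,
    drugs: list[str],
    gene: str,
    threshold: float = DEFAULT_SENSITIVITY_THRESHOLD,
) -> BiasResult:
    """Bias statistic pooled over a biologically related drug class.

    (cell line, drug) pairs across the class's drugs are pooled into one
    resistant set and one sensitive set, then the bias statistic is applied
    to the pooled pairs; a cell line therefore contributes once per drug.
    """
    if not drugs:
        raise DataError("empty drug class")
    if gene not in matrix.values.columns:
        raise KeyError(f"gene {gene!r} not in {matrix.feature_type} matrix")
    col = matrix.values[gene].dropna()
    mut_res = n_res = mut_sen = n_sen = 0
    for drug in drugs:
        labels = classify_cells(response, drug, threshold)
        for cell in labels.resistant:
            if cell in col.index:
                n_res += 1
                mut_res += int(col.loc[cell])
        for cell in labels.sensitive:
            if cell in col.index:
                n_sen += 1
                mut_sen += int(col.loc[cell])
    if n_res == 0 or n_sen == 0:
        empty = "resistant" if n_res == 0 else "sensitive"
        raise DataError(f"empty pooled {empty} group for class {drugs}")
    return BiasResult(
        drug="+".join(drugs), gene=gene,
        mut_res=mut_res, n_res=n_res, mut_sen=mut_sen, n_sen=n_sen,
    )


def bias_table_frame(results: list[BiasResult], ndigits: int = 3) -> pd.DataFrame:
    """Tabulate bias results in the standard column layout (display-rounded)."""
    rows = []
    for r in results:
        fr, fs, d = r.rounded(ndigits)
        rows.append({
            "drug": r.drug, "gene": r.gene, "total": r.total,
            "mut_res": r.mut_res, "n_res": r.n_res, "f_res": fr,
            "mut_sen": r.mut_sen, "n_sen": r.n_sen, "f_sen": fs,
            "diff": d,
        })
    return pd.DataFrame(rows)
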