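"""Filter-gated drug-gene association statistics on pooled IC50 values.

Two nonparametric tests relate a drug's per-cell-line log2 IC50s to genomics:

* **mutation**: Wilcoxon rank-sum comparing IC50 between mutant and wild-type
  cell lines, run only when both groups hold at least 10 lines;
* **expression**: Spearman correlation of TPM against IC50, run only with at
  least 10 overlapping cell lines of which at least 5 express the gene at
  TPM >= 1 (guards against correlating noise-floor expression).

Pairs failing a gate are returned as skipped records with the reason, never
as silently missing rows.  Scans over many genes append Benjamini-Hochberg
q-values per test type as a convenience; raw p-values are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import MutationTable

__all__ = [
    "IC50Table",
    "BiomarkerResult",
    "wilcoxon_rank_sum",
    "spearman",
    "mutation_association",
    "expression_association",
    "run_biomarker_scan",
    "MIN_GROUP_SIZE",
    "MIN_EXPRESSION_CELLS",
    "MIN_EXPRESSED_CELLS",
    "TPM_EXPRESSED_THRESHOLD",
]

MIN_GROUP_SIZE = 10  # mutant and wild-type groups each need >= 10 cell lines
MIN_EXPRESSION_CELLS = 10  # expression test needs >= 10 overlapping cell lines
MIN_EXPRESSED_CELLS = 5  # ... of which >= 5 at TPM >= 1
TPM_EXPRESSED_THRESHOLD = 1.0

_EXACT_MAX_N = 14  # exact rank-sum null up to this combined size (no ties)

IC50_COLUMNS = ["drug_id", "cell_line_id", "cancer_type", "ic50_log2"]


@dataclass
class IC50Table:
    """Per (drug, cell line) pooled-curve IC50s with a cancer-type label."""

    records: pd.DataFrame  # columns: drug_id, cell_line_id, cancer_type, ic50_log2

    def __post_init__(self) -> None:
        missing = set(IC50_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"IC50 table missing columns: {sorted(missing)}")
        if self.records.duplicated(["drug_id", "cell_line_id"]).any():
            raise ValueError("IC50 table must be unique per (drug, cell line)")
        if not np.isfinite(self.records["ic50_log2"].to_numpy(dtype=float)).all():
            raise ValueError("IC50 values must be finite")

    def for_drug(self, drug_id: str, cancer_type: str | None = None) -> pd.DataFrame:
        rows = self.records[self.records["drug_id"] == drug_id]
        if rows.empty:
            raise KeyError(f"drug {drug_id!r} absent from IC50 table")
        if cancer_type is not None:
            rows = rows[rows["cancer_type"] == cancer_type]
        return rows

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(sorted(self.records["drug_id"].unique()))


@dataclass(frozen=True)
class BiomarkerResult:
    """One drug-gene association record (or the reason it was skipped)."""

    drug_id: str
    gene: str
    test_type: str  # "mutation" | "expression"
    n_wt: int | None = None
    n_mut: int | None = None
    n_cells: int | None = None
    statistic: float | None = None
    p_value: float | None = None
    effect_size: float | None = None  # median IC50 diff (mut−WT) or Spearman rho
    rank_biserial: float | None = None  # mutation tests only
    skipped_reason: str | None = None

    @property
    def tested(self) -> bool:
        return self.skipped_reason is None


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the midrank sum of ``group_a`` in the combined
    sample.  The p-value is exact (full enumeration of the rank-sum null)
    when the combined size is at most 14 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)  # midranks for ties
    w = float(ranks[: a.size].sum())
    if np.unique(combined).size == 1:
        return w, 1.0  # every observation tied: the null is exactly symmetric
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (no_ties and combined.size <= _EXACT_MAX_N) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return w, float(res.pvalue)


def spearman(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with its t-approximation p-value.

    Returns (nan, nan) when either variable has zero rank variance — the
    correlation is undefined, and callers surface this as a skipped record.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs two equal-length sequences of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _rank_biserial(w_a: float, n_a: int, n_b: int) -> float:
    """Rank-biserial effect: 2·U/(n_a·n_b) − 1, in [−1, 1]; positive means
    group_a tends to have larger values."""
    u_a = w_a - n_a * (n_a + 1) / 2.0
    return float(2.0 * u_a / (n_a * n_b) - 1.0)


def mutation_association(
    ic50: IC50Table,
    muts: MutationTable,
    drug_id: str,
    gene: str,
    cancer_type: str | None = None,
) -> BiomarkerResult:
    """Mutant-vs-wild-type IC50 comparison for one drug-gene pair.

    Cell lines with an IC50 for the drug (optionally restricted to one cancer
    type first) are split by the gene's mutant flag; with >= 10 lines on each
    side a two-sided rank-sum test runs and the effect size is the median
    IC50 difference (mutant − wild-type, log2 µM; negative = mutants more
    sensitive), alongside the rank-biserial correlation.
    """
    rows = ic50.for_drug(drug_id, cancer_type)
    is_mut = rows["cell_line_id"].map(lambda c: muts.is_mutant(gene, c)).to_numpy(bool)
    values = rows["ic50_log2"].to_numpy(dtype=float)
    mut_vals = values[is_mut]
    wt_vals = values[~is_mut]
    n_mut, n_wt = int(mut_vals.size), int(wt_vals.size)
    base = dict(drug_id=drug_id, gene=gene, test_type="mutation", n_wt=n_wt, n_mut=n_mut)
    if n_mut < MIN_GROUP_SIZE:
        return BiomarkerResult(**base, skipped_reason="insufficient mutants")
    if n_wt < MIN_GROUP_SIZE:
        return BiomarkerResult(**base, skipped_reason="insufficient wild-type")
    w, p = wilcoxon_rank_sum(mut_vals, wt_vals)
    return BiomarkerResult(
        **base,
        statistic=w,
        p_value=p,
        effect_size=float(np.median(mut_vals) - np.median(wt_vals)),
        rank_biserial=_rank_biserial(w, n_mut, n_wt),
    )


def expression_association(
    ic50: IC50Table,
    expr: pd.DataFrame,
    drug_id: str,
    gene: str,
    cancer_type: str | None = None,
) -> BiomarkerResult:
    """Spearman correlation of a gene's TPM with a drug's IC50s.

    Runs on the cell lines that have both an IC50 (after any cancer-type
    restriction) and an expression value, provided there are at least 10 of
    them and at least 5 express the gene at TPM >= 1.
    """
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    rows = ic50.for_drug(drug_id, cancer_type)
    cells = [c for c in rows["cell_line_id"] if c in expr.columns]
    n_cells = len(cells)
    base = dict(drug_id=drug_id, gene=gene, test_type="expression", n_cells=n_cells)
    if n_cells < MIN_EXPRESSION_CELLS:
        return BiomarkerResult(**base, skipped_reason="insufficient cell lines")
    tpm = expr.loc[gene, cells].to_numpy(dtype=float)
    if int((tpm >= TPM_EXPRESSED_THRESHOLD).sum()) < MIN_EXPRESSED_CELLS:
        return BiomarkerResult(**base, skipped_reason="background expression")
    ic = rows.set_index("cell_line_id").loc[cells, "ic50_log2"].to_numpy(dtype=float)
    rho, p = spearman(tpm, ic)
    if math.isnan(rho):
        return BiomarkerResult(**base, skipped_reason="undefined correlation")
    return BiomarkerResult(**base, statistic=rho, p_value=p, effect_size=rho)


def run_biomarker_scan(
    ic50: IC50Table,
    muts: MutationTable | None = None,
    expr: pd.DataFrame | None = None,
    drugs: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    cancer_type: str | None = None,
) -> pd.DataFrame:
    """Both association tests over the drug x gene cross product.

    Gates apply after the cancer-type restriction.  BH-adjusted q-values are
    appended per test type over the tests that actually ran; skipped pairs
    keep NaN q.  Per-pair failures (missing drug/gene) are recorded as
    skipped rows, never raised.
    """
    drug_list = list(drugs) if drugs is not None else list(ic50.drugs)
    if genes is not None:
        gene_list = list(genes)
    else:
        gene_list = sorted(
            set(muts.genes if muts is not None else ())
            | set(expr.index if expr is not None else ())
        )
    results: list[BiomarkerResult] = []
    for drug_id in drug_list:
        for gene in gene_list:
            if muts is not None:
                try:
                    results.append(
                        mutation_association(ic50, muts, drug_id, gene, cancer_type)
                    )
                except KeyError as exc:
                    results.append(
                        BiomarkerResult(
                            drug_id=drug_id, gene=gene, test_type="mutation",
                            skipped_reason=str(exc),
                        )
                    )
            if expr is not None:
                try:
                    results.append(
                        expression_association(ic50, expr, drug_id, gene, cancer_type)
                    )
                except KeyError as exc:
                    results.append(
                        BiomarkerResult(
                            drug_id=drug_id, gene=gene, test_type="expression",
                            skipped_reason=str(exc),
                        )
                    )
    columns = list(BiomarkerResult.__dataclass_fields__)
    table = pd.DataFrame([r.__dict__ for r in results], columns=columns)
    table["q_value"] = np.nan
    for test_type in ("mutation", "expression"):
        mask = (table["test_type"] == test_type) & table["p_value"].notna()
        if mask.any():
            table.loc[mask, "q_value"] = stats.false_discovery_control(
                table.loc[mask, "p_value"].to_numpy(dtype=float), method="bh"
            )
    return table
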