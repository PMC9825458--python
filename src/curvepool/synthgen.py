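"""Seeded generators for multi-dataset dose-response screens with known truth.

Two generators cover the package's study conditions:

* :func:`simulate_experiment` inverts the curve-fitting model: responses are
  the base-2 logistic plus Student-t noise, clipped to [0, 1], measured on
  dataset-specific dose grids.  Per-dataset shifts of the curve center
  reproduce the cross-dataset discordance regime; the default grids give one
  9-point screen over [−4, 4] log2 µM and one 7-point screen over [−2, 6],
  so pooling broadens the observed dose window.

* :func:`simulate_cohort` builds a cell-line cohort with planted drug-gene
  associations: Bernoulli mutant flags that shift IC50 additively, log-normal
  TPM expression whose standardized log level enters IC50 linearly, plus
  Gaussian noise.  :func:`simulate_cohort_experiments` turns the cohort's
  true IC50s into per-cell-line dose-response data so the whole
  simulate → fit → biomarker pipeline can run end to end.

Everything is reproducible from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .biomarker import IC50Table
from .core_data import CurveInput, DoseResponsePoint, MutationTable, assemble_curve_input

__all__ = [
    "SimScenario",
    "CohortScenario",
    "simulate_experiment",
    "simulate_cohort",
    "simulate_cohort_experiments",
    "DEFAULT_DOSE_GRIDS",
]

_LN2 = float(np.log(2.0))

#: default per-dataset log2 µM dose grids: a 9-point screen over [−4, 4] and a
#: 7-point screen over [−2, 6] — overlapping but offset windows, as seen when
#: pooling large public screens.
DEFAULT_DOSE_GRIDS: tuple[tuple[float, ...], ...] = (
    tuple(np.linspace(-4.0, 4.0, 9)),
    tuple(np.linspace(-2.0, 6.0, 7)),
)


@dataclass(frozen=True)
class SimScenario:
    """Ground truth and noise regime for one simulated drug-cell-line pair."""

    true_a: float = -1.0
    true_k: float = 1.5
    doses_per_dataset: tuple[tuple[float, ...], ...] = DEFAULT_DOSE_GRIDS
    replicates: int = 1
    noise_sigma: float = 0.05
    noise_nu: float = 250.0
    dataset_shift: tuple[float, ...] | None = None  # additive offset on true_a
    seed: int = 0
    drug_id: str = "DRUG1"
    cell_line_id: str = "CELL1"

    def __post_init__(self) -> None:
        if not self.noise_sigma > 0:
            raise ValueError("noise_sigma must be positive")
        if not self.doses_per_dataset or any(len(g) == 0 for g in self.doses_per_dataset):
            raise ValueError("every dataset needs a non-empty dose grid")
        if self.dataset_shift is not None and len(self.dataset_shift) != len(
            self.doses_per_dataset
        ):
            raise ValueError("dataset_shift must match the number of datasets")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_experiment(scn: SimScenario) -> CurveInput:
    """Draw one pooled experiment: y = clip(f(x; a + shift_d, k) + σ·t_ν, 0, 1)."""
    rng = np.random.default_rng(np.random.SeedSequence(scn.seed))
    shifts = scn.dataset_shift or (0.0,) * len(scn.doses_per_dataset)
    points: list[DoseResponsePoint] = []
    for d, (grid, shift) in enumerate(zip(scn.doses_per_dataset, shifts)):
        dataset_id = f"DS{chr(ord('A') + d)}"
        center = scn.true_a + shift
        for x in grid:
            mean = float(expit(_LN2 * scn.true_k * (x - center)))
            for _ in range(scn.replicates):
                y = mean + scn.noise_sigma * rng.standard_t(scn.noise_nu)
                points.append(
                    DoseResponsePoint(
                        dataset_id=dataset_id,
                        drug_id=scn.drug_id,
                        cell_line_id=scn.cell_line_id,
                        conc_um=float(2.0**x),
                        response=float(np.clip(y, 0.0, 1.0)),
                    )
                )
    return assemble_curve_input(points, scn.drug_id, scn.cell_line_id)


@dataclass(frozen=True)
class CohortScenario:
    """Cell-line cohort with planted mutation and expression effects on IC50.

    ``mutation_effects`` maps gene -> additive log2 IC50 shift in mutants;
    ``expression_effects`` maps gene -> coefficient on the standardized
    log-TPM level.  ``n_null_genes`` extra genes carry no effect and supply
    the null background for calibration studies.
    """

    n_cell_lines: int = 40
    mutation_effects: Mapping[str, float] = field(default_factory=dict)
    expression_effects: Mapping[str, float] = field(default_factory=dict)
    n_null_genes: int = 10
    mutation_prevalence: float = 0.5
    baseline_ic50: float = 0.0
    ic50_noise_sd: float = 0.5
    expression_log_mean: float = 2.0
    expression_log_sd: float = 1.0
    cancer_types: tuple[str, ...] = ("pan",)
    drug_id: str = "DRUG1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_lines < 1:
            raise ValueError("need at least one cell line")
        if not 0.0 < self.mutation_prevalence < 1.0:
            raise ValueError("mutation_prevalence must lie in (0, 1)")

    @property
    def genes(self) -> tuple[str, ...]:
        planted = sorted(set(self.mutation_effects) | set(self.expression_effects))
        nulls = [f"NULL{i + 1}" for i in range(self.n_null_genes)]
        return tuple(planted + nulls)


def simulate_cohort(
    scn: CohortScenario,
) -> tuple[IC50Table, MutationTable, pd.DataFrame]:
    """Draw (IC50 table, mutant flags, TPM matrix) with the planted structure.

    IC50 per cell line is baseline + Σ mutation shifts·flag + Σ expression
    coefficients·standardized log TPM + Gaussian noise.  Expression is
    log-normal TPM; mutant flags are independent Bernoulli draws per gene.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scn.seed))
    cells = [f"CL{i + 1:03d}" for i in range(scn.n_cell_lines)]
    genes = scn.genes

    flags = pd.DataFrame(
        rng.random((len(genes), scn.n_cell_lines)) < scn.mutation_prevalence,
        index=genes,
        columns=cells,
    )
    log_tpm = rng.normal(
        scn.expression_log_mean, scn.expression_log_sd, (len(genes), scn.n_cell_lines)
    )
    expr = pd.DataFrame(np.exp(log_tpm), index=genes, columns=cells)
    expr.index.name = "gene"

    ic50 = np.full(scn.n_cell_lines, scn.baseline_ic50, dtype=float)
    for gene, shift in scn.mutation_effects.items():
        ic50 += shift * flags.loc[gene].to_numpy(dtype=float)
    for gene, coef in scn.expression_effects.items():
        level = log_tpm[genes.index(gene)]
        sd = level.std()
        if sd > 0:
            ic50 += coef * (level - level.mean()) / sd
    ic50 += rng.normal(0.0, scn.ic50_noise_sd, scn.n_cell_lines)

    records = pd.DataFrame(
        {
            "drug_id": scn.drug_id,
            "cell_line_id": cells,
            "cancer_type": [
                scn.cancer_types[i % len(scn.cancer_types)]
                for i in range(scn.n_cell_lines)
            ],
            "ic50_log2": ic50,
        }
    )
    calls = (
        flags.stack()[lambda s: s]
        .reset_index()
        .rename(columns={"level_0": "gene", "level_1": "cell_line"})[["gene", "cell_line"]]
        .sort_values(["gene", "cell_line"])
        .reset_index(drop=True)
    )
    return IC50Table(records=records), MutationTable(calls=calls), expr


def simulate_cohort_experiments(
    ic50: IC50Table,
    template: SimScenario | None = None,
    seed: int = 0,
) -> list[CurveInput]:
    """One dose-response experiment per cohort cell line, centered at its
    true IC50, so fitting recovers the cohort's IC50 table."""
    tmpl = template or SimScenario()
    seeds = np.random.SeedSequence(seed).spawn(len(ic50.records))
    experiments = []
    for child, row in zip(seeds, ic50.records.itertuples(index=False)):
        scn = replace(
            tmpl,
            true_a=float(row.ic50_log2),
            seed=int(child.generate_state(1)[0] % (2**31)),
            drug_id=row.drug_id,
            cell_line_id=row.cell_line_id,
        )
        experiments.append(simulate_experiment(scn))
    return experiments
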