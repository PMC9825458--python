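"""CSV/JSON readers and writers tying the pipeline together.

Formats (all UTF-8 CSV with header):

* ``dose_response.csv`` — ``dataset,cell_line,drug,conc_um,response`` for
  pre-normalized data, or ``dataset,cell_line,drug,conc_um,signal,neg_mean,
  pos_mean`` for raw signals (normalized on read against the control means).
* ``mutations.csv`` — ``gene,cell_line,consequence,allele_frequency``.
* ``expression.csv`` — genes as rows (first column ``gene``), cell lines as
  columns, TPM values.
* scores CSV — one row per drug-cell-line pair with the five scores, their
  HDI bounds, fit diagnostics and flags.
* chains CSV — one row per retained draw: chain, iteration and every sampled
  parameter.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import PARAM_NAMES, PosteriorChains, PosteriorSummary
from .core_data import (
    CurveInput,
    DoseResponsePoint,
    SynonymTable,
    assemble_curve_input,
    normalize_response,
    validate_expression_matrix,
)
from .scores import SensitivityScores

logger = logging.getLogger(__name__)

__all__ = [
    "read_dose_response",
    "write_dose_response",
    "read_expression",
    "read_mutation_calls",
    "write_scores",
    "read_scores",
    "write_chains",
    "read_chains",
    "summary_to_dict",
    "write_fit_json",
]

_NORMALIZED_COLS = ["dataset", "cell_line", "drug", "conc_um", "response"]
_RAW_COLS = ["dataset", "cell_line", "drug", "conc_um", "signal", "neg_mean", "pos_mean"]


def read_dose_response(
    path,
    cell_line_synonyms: SynonymTable | None = None,
    drug_synonyms: SynonymTable | None = None,
) -> list[CurveInput]:
    """Load a dose-response CSV into per-pair curve inputs.

    Accepts either the pre-normalized or the raw-signal column layout.  Rows
    with non-positive concentrations or unparseable fields are logged and
    skipped; a file whose rows are all bad is an error.  Optional synonym
    tables canonicalize cell-line and drug names before pairing.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if set(_NORMALIZED_COLS) <= set(cols):
        raw = False
    elif set(_RAW_COLS) <= set(cols):
        raw = True
    else:
        raise ValueError(
            f"{path}: expected columns {_NORMALIZED_COLS} or {_RAW_COLS}, got {cols}"
        )

    points: dict[tuple[str, str], list[DoseResponsePoint]] = {}
    n_bad = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            cell = str(row.cell_line)
            drug = str(row.drug)
            if cell_line_synonyms is not None:
                cell, known = cell_line_synonyms.canonicalize(cell)
                if not known:
                    logger.warning("line %d: unknown cell line %r", i, row.cell_line)
            if drug_synonyms is not None:
                drug, known = drug_synonyms.canonicalize(drug)
                if not known:
                    logger.warning("line %d: unknown drug %r", i, row.drug)
            conc = float(row.conc_um)
            if not conc > 0:
                raise ValueError(f"non-positive concentration {conc}")
            if raw:
                response = normalize_response(
                    float(row.signal), float(row.neg_mean), float(row.pos_mean)
                )
            else:
                response = float(row.response)
            point = DoseResponsePoint(
                dataset_id=str(row.dataset),
                drug_id=drug,
                cell_line_id=cell,
                conc_um=conc,
                response=response,
            )
        except (ValueError, TypeError) as exc:
            logger.warning("%s line %d skipped: %s", path, i, exc)
            n_bad += 1
            continue
        points.setdefault((drug, cell), []).append(point)

    if not points:
        raise ValueError(f"{path}: no valid dose-response rows (skipped {n_bad})")
    return [
        assemble_curve_input(pts, drug, cell)
        for (drug, cell), pts in sorted(points.items())
    ]


def write_dose_response(experiments: Iterable[CurveInput], path) -> None:
    """Write pooled experiments back to the pre-normalized CSV layout."""
    rows = [
        {
            "dataset": p.dataset_id,
            "cell_line": p.cell_line_id,
            "drug": p.drug_id,
            "conc_um": p.conc_um,
            "response": p.response,
        }
        for exp in experiments
        for p in exp.points
    ]
    # %.17g round-trips float64 exactly, keeping read(write(x)) == x
    pd.DataFrame(rows, columns=_NORMALIZED_COLS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_expression(path) -> pd.DataFrame:
    """Genes x cell-lines TPM matrix (first column holds gene names)."""
    expr = pd.read_csv(path, index_col=0)
    expr.index.name = "gene"
    return validate_expression_matrix(expr)


def read_mutation_calls(path) -> pd.DataFrame:
    """Raw mutation-call table, ready for :func:`curvepool.filter_mutations`."""
    df = pd.read_csv(path)
    required = {"gene", "cell_line", "consequence", "allele_frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: mutation CSV missing columns {sorted(missing)}")
    return df


_SCORE_COLUMNS = [
    "drug",
    "cell_line",
    "n_points",
    "ic50_log2",
    "ic50_um",
    "ic50_lo",
    "ic50_hi",
    "ic90_log2",
    "ic90_um",
    "ic90_lo",
    "ic90_hi",
    "auc",
    "auc_lo",
    "auc_hi",
    "ec50_log2",
    "ec50_um",
    "ec50_lo",
    "ec50_hi",
    "einf",
    "einf_lo",
    "einf_hi",
    "x_min",
    "x_max",
    "mode_k",
    "mae",
    "rhat_a",
    "rhat_k",
    "flags",
]


def _flags_string(summary: PosteriorSummary, scores: SensitivityScores) -> str:
    flags = []
    if summary.low_information:
        flags.append("low_information")
    if summary.poor_convergence:
        flags.append("poor_convergence")
    if scores.ic90_extrapolated:
        flags.append("ic90_extrapolated")
    if scores.ec50_extrapolated:
        flags.append("ec50_extrapolated")
    return "|".join(flags)


def write_scores(
    results: Sequence[tuple[CurveInput, PosteriorSummary, SensitivityScores]], path
) -> None:
    """Scores table: one row per fitted pair."""
    rows = []
    for data, summary, sc in results:
        rows.append(
            {
                "drug": data.drug_id,
                "cell_line": data.cell_line_id,
                "n_points": data.n_points,
                "ic50_log2": sc.ic50_log2,
                "ic50_um": sc.ic50_um,
                "ic50_lo": sc.hdi95_ic50[0],
                "ic50_hi": sc.hdi95_ic50[1],
                "ic90_log2": sc.ic90_log2,
                "ic90_um": sc.ic90_um,
                "ic90_lo": sc.hdi95_ic90[0],
                "ic90_hi": sc.hdi95_ic90[1],
                "auc": sc.auc,
                "auc_lo": sc.hdi95_auc[0],
                "auc_hi": sc.hdi95_auc[1],
                "ec50_log2": sc.ec50_log2,
                "ec50_um": sc.ec50_um,
                "ec50_lo": sc.hdi95_ec50[0],
                "ec50_hi": sc.hdi95_ec50[1],
                "einf": sc.einf,
                "einf_lo": sc.hdi95_einf[0],
                "einf_hi": sc.hdi95_einf[1],
                "x_min": sc.x_min,
                "x_max": sc.x_max,
                "mode_k": summary.mode_k,
                "mae": summary.mae,
                "rhat_a": summary.rhat_a,
                "rhat_k": summary.rhat_k,
                "flags": _flags_string(summary, sc),
            }
        )
    pd.DataFrame(rows, columns=_SCORE_COLUMNS).to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"drug", "cell_line", "ic50_log2"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: scores CSV missing columns {sorted(missing)}")
    return df


def write_chains(chains: PosteriorChains, path) -> None:
    """Columnar chain export: one row per retained draw."""
    n_chains, n_kept = chains.samples["a"].shape
    data = {
        "chain": np.repeat(np.arange(n_chains), n_kept),
        "iteration": np.tile(np.arange(n_kept) + chains.config.n_burn_in, n_chains),
    }
    for name in PARAM_NAMES:
        data[name] = chains.samples[name].reshape(-1)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_chains(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(PARAM_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: chains CSV missing columns {sorted(missing)}")
    return df


def summary_to_dict(
    data: CurveInput, summary: PosteriorSummary, scores: SensitivityScores
) -> dict:
    """JSON-ready record of one fit (parameters, HDIs, diagnostics, config echo)."""
    return {
        "drug": data.drug_id,
        "cell_line": data.cell_line_id,
        "n_points": data.n_points,
        "datasets": list(data.datasets),
        "mode_a": summary.mode_a,
        "mode_k": summary.mode_k,
        "hdi95_a": list(summary.hdi95_a),
        "hdi95_k": list(summary.hdi95_k),
        "rhat_a": summary.rhat_a,
        "rhat_k": summary.rhat_k,
        "mae": summary.mae,
        "flags": _flags_string(summary, scores),
        "scores": {
            "ic50_log2": scores.ic50_log2,
            "ic50_um": scores.ic50_um,
            "ic90_log2": scores.ic90_log2,
            "auc": scores.auc,
            "ec50_log2": scores.ec50_log2,
            "einf": scores.einf,
        },
        "x_range": [scores.x_min, scores.x_max],
    }


def write_fit_json(records: Sequence[dict], path, config_echo: Mapping | None = None) -> None:
    payload = {"fits": list(records)}
    if config_echo:
        payload["config"] = dict(config_echo)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
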