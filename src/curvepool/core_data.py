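"""Data model for pooled dose-response experiments.

Raw viability signals from different screening datasets are normalized to a
common inhibition scale (0 = negative-control level, 1 = positive-control
level), concentrations are put on a log2(µM) axis, cell-line and drug names
are harmonized through offline synonym tables, and mutation calls are reduced
to a per-(gene, cell line) mutant flag using the standard consequence /
allele-frequency filter.  The unit handed to the Bayesian engine is a
:class:`CurveInput`: every available dose-response point for one drug on one
cell line, pooled across datasets.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponsePoint",
    "CurveInput",
    "SynonymTable",
    "MutationTable",
    "DegenerateControlsError",
    "normalize_response",
    "to_log_concentration",
    "filter_mutations",
    "assemble_curve_input",
    "validate_expression_matrix",
    "CODING_NONSILENT_CONSEQUENCES",
    "MIN_ALLELE_FREQUENCY",
]

#: consequence classes counted as non-silent coding events; everything else
#: (synonymous/silent, UTR, intronic, intergenic, ...) is dropped.
CODING_NONSILENT_CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "inframe_insertion",
        "inframe_deletion",
        "start_lost",
        "stop_lost",
        "splice_site",
        "essential_splice",
    }
)

#: allele-frequency gate, boundary inclusive.
MIN_ALLELE_FREQUENCY = 0.2


class DegenerateControlsError(ValueError):
    """Positive- and negative-control means coincide; normalization undefined."""


def normalize_response(
    signal: float, neg_control_mean: float, pos_control_mean: float
) -> float:
    """Standardize a raw well signal to the [0, 1] inhibition scale.

    0 means the signal sits at the negative-control (untreated growth) level,
    1 means it sits at the positive-control (complete inhibition) level.
    Values outside the control range are clipped.  The map is affine in the
    signal, so any common positive rescaling of (signal, controls) leaves the
    result unchanged.
    """
    if neg_control_mean == pos_control_mean:
        raise DegenerateControlsError(
            "negative and positive control means are equal "
            f"({neg_control_mean!r}); response scale is undefined"
        )
    raw = (neg_control_mean - signal) / (neg_control_mean - pos_control_mean)
    return float(min(1.0, max(0.0, raw)))


def to_log_concentration(conc_um: float) -> float:
    """log2 of a concentration in µM (the model's dose axis)."""
    if not conc_um > 0:
        raise ValueError(f"concentration must be positive, got {conc_um!r}")
    return math.log2(conc_um)


_FOLD_RE = re.compile(r"[^0-9A-Za-z]+")


def _fold(name: str) -> str:
    """Case/punctuation folding used for alias lookup: 'MCF-7' -> 'MCF7'."""
    return _FOLD_RE.sub("", name).upper()


@dataclass(frozen=True)
class DoseResponsePoint:
    """One normalized measurement: a dose (µM) and its inhibition response."""

    dataset_id: str
    drug_id: str
    cell_line_id: str
    conc_um: float
    response: float

    def __post_init__(self) -> None:
        if not self.conc_um > 0:
            raise ValueError(f"conc_um must be positive, got {self.conc_um!r}")
        if not 0.0 <= self.response <= 1.0:
            raise ValueError(f"response must lie in [0, 1], got {self.response!r}")

    @property
    def x(self) -> float:
        """log2 concentration; always exactly log2(conc_um)."""
        return math.log2(self.conc_um)


@dataclass(frozen=True)
class CurveInput:
    """All points for one drug-cell-line pair, pooled across datasets.

    Points are kept as individual wells (replicates are not averaged; the
    likelihood handles them) and sorted by log2 concentration.
    """

    drug_id: str
    cell_line_id: str
    points: tuple[DoseResponsePoint, ...]
    low_information: bool = False

    @property
    def x(self) -> np.ndarray:
        return np.array([p.x for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p.response for p in self.points])

    @property
    def x_min(self) -> float:
        return self.points[0].x

    @property
    def x_max(self) -> float:
        return self.points[-1].x

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def datasets(self) -> tuple[str, ...]:
        return tuple(sorted({p.dataset_id for p in self.points}))


def assemble_curve_input(
    points: Iterable[DoseResponsePoint], drug_id: str, cell_line_id: str
) -> CurveInput:
    """Pool every point for the (drug, cell line) pair into a fit-ready input.

    All points must already carry the canonical pair ids; a mixed batch is a
    programming error, not data to be silently filtered.  A pair with a single
    point (or a single distinct dose) is flagged low-information rather than
    rejected.
    """
    pts = list(points)
    if not pts:
        raise ValueError(f"no dose-response points for ({drug_id}, {cell_line_id})")
    for p in pts:
        if p.drug_id != drug_id or p.cell_line_id != cell_line_id:
            raise ValueError(
                f"point ({p.drug_id}, {p.cell_line_id}) does not belong to "
                f"pair ({drug_id}, {cell_line_id})"
            )
    pts.sort(key=lambda p: (p.x, p.dataset_id, p.response))
    low_info = len(pts) < 2 or pts[0].x == pts[-1].x
    return CurveInput(
        drug_id=drug_id,
        cell_line_id=cell_line_id,
        points=tuple(pts),
        low_information=low_info,
    )


@dataclass
class SynonymTable:
    """Offline alias -> canonical-id lookup for cell lines or drugs.

    Lookup is case- and punctuation-insensitive; unknown names come back
    fold-normalized with ``known=False`` so callers can log them.  Every
    canonical id resolves to itself, which makes canonicalization idempotent.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SynonymTable":
        table = cls()
        for alias, canonical in pairs:
            table.add(alias, canonical)
        return table

    @classmethod
    def from_csv(cls, path) -> "SynonymTable":
        """Load a two-column alias,canonical CSV (header required)."""
        df = pd.read_csv(path)
        cols = [c.strip().lower() for c in df.columns]
        if cols[:2] != ["alias", "canonical"]:
            raise ValueError(
                f"synonym table {path} must have columns alias,canonical; got {list(df.columns)}"
            )
        return cls.from_pairs(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))

    def add(self, alias: str, canonical: str) -> None:
        self.mapping[_fold(alias)] = canonical
        # canonical ids always resolve to themselves
        self.mapping.setdefault(_fold(canonical), canonical)

    def canonicalize(self, name: str) -> tuple[str, bool]:
        """Resolve ``name``; returns (canonical_id, known)."""
        folded = _fold(name)
        if folded in self.mapping:
            return self.mapping[folded], True
        return folded, False


def canonicalize(name: str, table: SynonymTable) -> tuple[str, bool]:
    """Functional form of :meth:`SynonymTable.canonicalize`."""
    return table.canonicalize(name)


@dataclass
class MutationTable:
    """Filtered mutant flags: one record per (gene, cell line) that passed.

    Presence of a (gene, cell line) pair means the cell line carries at least
    one non-silent coding mutation in the gene with allele frequency >= 0.2;
    absence means wild-type with respect to this table.
    """

    calls: pd.DataFrame  # columns: gene, cell_line

    def __post_init__(self) -> None:
        expected = ["gene", "cell_line"]
        if list(self.calls.columns) != expected:
            raise ValueError(f"MutationTable columns must be {expected}")
        if self.calls.duplicated().any():
            raise ValueError("MutationTable must hold unique (gene, cell_line) pairs")
        self._flag_set = set(map(tuple, self.calls.itertuples(index=False)))

    def is_mutant(self, gene: str, cell_line_id: str) -> bool:
        return (gene, cell_line_id) in self._flag_set

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.calls["gene"].unique()))

    def __len__(self) -> int:
        return len(self.calls)


def filter_mutations(raw_calls: pd.DataFrame) -> MutationTable:
    """Reduce raw mutation calls to per-(gene, cell line) mutant flags.

    Keeps non-silent coding calls with allele frequency >= 0.2 (inclusive);
    records with a missing allele frequency are skipped with a warning.
    Multiple passing calls for the same (gene, cell line) collapse to a single
    flag, so re-filtering an already-filtered table is a no-op.
    """
    required = {"gene", "cell_line", "consequence", "allele_frequency"}
    missing = required - set(raw_calls.columns)
    if missing:
        raise ValueError(f"mutation calls missing columns: {sorted(missing)}")
    df = raw_calls.copy()
    n_missing_af = df["allele_frequency"].isna().sum()
    if n_missing_af:
        logger.warning("skipping %d mutation calls with missing allele frequency", n_missing_af)
        df = df.dropna(subset=["allele_frequency"])
    consequence = df["consequence"].astype(str).str.strip().str.lower()
    keep = consequence.isin(CODING_NONSILENT_CONSEQUENCES) & (
        df["allele_frequency"] >= MIN_ALLELE_FREQUENCY
    )
    kept = (
        df.loc[keep, ["gene", "cell_line"]]
        .drop_duplicates()
        .sort_values(["gene", "cell_line"])
        .reset_index(drop=True)
    )
    return MutationTable(calls=kept)


def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x cell-lines TPM matrix: non-negative, unique labels."""
    if expr.index.duplicated().any() or expr.columns.duplicated().any():
        raise ValueError("expression matrix labels must be unique")
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values")
    if (values < 0).any():
        raise ValueError("TPM values must be non-negative")
    return expr
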