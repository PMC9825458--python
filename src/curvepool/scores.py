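"""Sensitivity scores derived from a fitted logistic dose-response curve.

Five summaries are reported per drug-cell-line pair:

* **IC50** — the curve center ``a``: the log2 µM dose inhibiting 50% of cells.
* **IC90** — dose giving 90% inhibition, ``a + log2(9)/k``.
* **AUC**  — mean fitted response over the observed dose window (area under
  the inhibition curve normalized by window width, so it lies in (0, 1) and
  higher means more sensitive).
* **Einf** — fitted response at the highest observed dose.  The logistic's
  asymptote is always 1, so the maximal response a drug actually achieved is
  only meaningful within the tested range.
* **EC50** — dose inducing half of Einf, ``a − log2(2/Einf − 1)/k``.

Each score is evaluated for every posterior draw, giving a 95% HDI per score;
the reported point value is the score at the posterior-mode parameters.
IC90/EC50 landing outside the observed window are reported with an
extrapolation flag rather than suppressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .bayes import LogisticParams, PosteriorChains, hdi, kde_mode, logistic_response

__all__ = [
    "SensitivityScores",
    "ic50",
    "ic90",
    "auc",
    "auc_closed_form",
    "einf",
    "ec50",
    "score_posterior",
]

_LOG2_9 = math.log2(9.0)


def ic50(params: LogisticParams) -> float:
    """log2 µM dose at 50% inhibition — the curve center itself."""
    return params.a


def ic90(params: LogisticParams) -> float:
    """log2 µM dose at 90% inhibition: solves f(x) = 0.9 ⇒ a + log2(9)/k."""
    return params.a + _LOG2_9 / params.k


def einf(params: LogisticParams, x_max: float) -> float:
    """Fitted response at the highest observed dose, kept strictly inside
    (0, 1) (the asymptotes are never attained at finite dose, and downstream
    EC50 needs the open interval even when floats would round to 0 or 1)."""
    value = float(logistic_response(x_max, params))
    return min(max(value, 5e-324), float(np.nextafter(1.0, 0.0)))


def ec50(params: LogisticParams, einf_value: float) -> float:
    """log2 µM dose at half the maximal observed response.

    Solves f(x) = einf_value / 2 ⇒ a − log2(2/einf_value − 1)/k.
    """
    if not 0.0 < einf_value < 1.0:
        raise ValueError(f"einf_value must lie strictly in (0, 1), got {einf_value!r}")
    return params.a - math.log2(2.0 / einf_value - 1.0) / params.k


def _softplus2(t):
    """log2(1 + 2^t), overflow-safe: max(t, 0) + log2(1 + 2^(−|t|))."""
    t = np.asarray(t, dtype=float)
    return np.maximum(t, 0.0) + np.log1p(np.exp2(-np.abs(t))) / math.log(2.0)


def auc_closed_form(a, k, x_min: float, x_max: float):
    """Window-normalized AUC from the logistic antiderivative.

    ∫ f dx = log2(1 + 2^{k(x−a)}) / k, so the normalized area is
    [sp(k(x_max−a)) − sp(k(x_min−a))] / (k (x_max−x_min)) with
    sp(t) = log2(1+2^t).  Accepts scalar or array (a, k) for per-draw scoring.
    """
    a = np.asarray(a, dtype=float)
    k = np.asarray(k, dtype=float)
    upper = _softplus2(k * (x_max - a))
    lower = _softplus2(k * (x_min - a))
    return (upper - lower) / (k * (x_max - x_min))


def auc(params: LogisticParams, x_min: float, x_max: float, n_grid: int = 2001) -> float:
    """Window-normalized area under the fitted response curve.

    Computed by composite trapezoid on an ``n_grid``-point dose grid
    (n_grid ≥ 1001 keeps it within 1e−6 of the closed form).  Higher AUC
    means more inhibition over the tested window, i.e. more sensitive.
    """
    if not x_min < x_max:
        raise ValueError(f"need x_min < x_max, got [{x_min}, {x_max}]")
    if n_grid < 1001:
        raise ValueError("n_grid must be at least 1001")
    grid = np.linspace(x_min, x_max, n_grid)
    values = logistic_response(grid, params)
    return float(np.trapezoid(values, grid) / (x_max - x_min))


def _pow2(log2_value: float) -> float:
    """Back-transform log2 µM to µM, saturating instead of overflowing —
    unidentified near-flat curves can put extrapolated doses at huge log2
    values."""
    if log2_value > 1023.0:
        return math.inf
    if log2_value < -1074.0:
        return 0.0
    return 2.0 ** log2_value


@dataclass(frozen=True)
class SensitivityScores:
    """The five scores with 95% HDIs, on log2 µM and back-transformed µM scales."""

    ic50_log2: float
    ic90_log2: float
    auc: float
    ec50_log2: float
    einf: float
    hdi95_ic50: tuple[float, float]
    hdi95_ic90: tuple[float, float]
    hdi95_auc: tuple[float, float]
    hdi95_ec50: tuple[float, float]
    hdi95_einf: tuple[float, float]
    x_min: float
    x_max: float
    ic90_extrapolated: bool
    ec50_extrapolated: bool

    @property
    def ic50_um(self) -> float:
        return _pow2(self.ic50_log2)

    @property
    def ic90_um(self) -> float:
        return _pow2(self.ic90_log2)

    @property
    def ec50_um(self) -> float:
        return _pow2(self.ec50_log2)


def score_posterior(
    chains: PosteriorChains, x_min: float, x_max: float
) -> SensitivityScores:
    """Propagate the posterior through every score.

    Point values are the scores at the pooled-KDE posterior mode; HDIs come
    from evaluating each score on every retained draw (closed-form AUC is
    used per draw — it agrees with the trapezoid rule to well below the HDI
    resolution).
    """
    if not x_min < x_max:
        raise ValueError(f"need x_min < x_max, got [{x_min}, {x_max}]")
    a_draws = chains.pooled("a")
    k_draws = np.maximum(chains.pooled("k"), 1e-300)

    ic50_draws = a_draws
    ic90_draws = a_draws + _LOG2_9 / k_draws
    auc_draws = auc_closed_form(a_draws, k_draws, x_min, x_max)
    einf_draws = expit(math.log(2.0) * k_draws * (x_max - a_draws))
    einf_draws = np.clip(einf_draws, 1e-300, 1.0 - 1e-16)
    ec50_draws = a_draws - np.log2(2.0 / einf_draws - 1.0) / k_draws

    mode_a = kde_mode(a_draws)
    mode_k = max(kde_mode(k_draws), 1e-12)
    mode_params = LogisticParams(a=mode_a, k=mode_k)
    einf_mode = einf(mode_params, x_max)
    ic90_mode = ic90(mode_params)
    ec50_mode = ec50(mode_params, einf_mode)

    return SensitivityScores(
        ic50_log2=ic50(mode_params),
        ic90_log2=ic90_mode,
        auc=auc(mode_params, x_min, x_max),
        ec50_log2=ec50_mode,
        einf=einf_mode,
        hdi95_ic50=hdi(ic50_draws),
        hdi95_ic90=hdi(ic90_draws),
        hdi95_auc=hdi(auc_draws),
        hdi95_ec50=hdi(ec50_draws),
        hdi95_einf=hdi(einf_draws),
        x_min=x_min,
        x_max=x_max,
        ic90_extrapolated=not (x_min <= ic90_mode <= x_max),
        ec50_extrapolated=not (x_min <= ec50_mode <= x_max),
    )
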