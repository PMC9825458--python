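"""Bayesian fitting of the pooled logistic dose-response curve.

One curve is fitted per drug-cell-line pair to *all* points pooled across
datasets.  The response is a base-2 logistic in log2 concentration,

    f(x) = 1 / (1 + 2^(-k (x - a))),

where ``a`` is the curve center (equal to the log2 IC50) and ``k > 0`` the
slope.  Observed responses get a Student-t likelihood with scale ``sigma``
and degrees of freedom ``nu`` — heavy tails keep single discordant wells from
dragging the whole curve.  The hierarchy is:

    y_i ~ t_nu(f(x_i), scale sigma)
    a   ~ Normal(a_mu, sd a_sigma)      a_mu ~ Normal(0, sd 1)
                                        a_sigma ~ Uniform(0.01, 5)
    k   ~ Gamma(shape k_r, rate k_lam)  k_r  ~ Normal(1, sd 10), k_r > 0
                                        k_lam ~ Normal(2, sd 10), k_lam > 0
    sigma ~ Uniform(0.01, 0.1)
    nu  ~ Normal(250, sd sqrt(1000)), nu > 0

Normal hyperpriors are written in the precision parameterization (variance =
1/precision) and truncated to the parameter's support where the support is
positive.  Sampling is adaptive Metropolis-within-Gibbs: componentwise
Gaussian random-walk proposals whose scales adapt during burn-in only, so the
retained draws come from a fixed Markov kernel.  Posterior point estimates
are KDE modes of the pooled post-burn-in draws; intervals are 95% highest-
density intervals; convergence is guarded by split R-hat on ``a`` and ``k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, gammaln
from scipy.stats import gaussian_kde

from .core_data import CurveInput

__all__ = [
    "LogisticParams",
    "PriorConfig",
    "MCMCConfig",
    "PosteriorChains",
    "PosteriorSummary",
    "PARAM_NAMES",
    "logistic_response",
    "log_posterior",
    "run_mcmc",
    "summarize",
    "fit_curve",
    "hdi",
    "kde_mode",
    "split_rhat",
    "mean_absolute_error",
]

_LN2 = math.log(2.0)
_LOG_2PI = math.log(2.0 * math.pi)

#: sampled quantities, in update order.
PARAM_NAMES = ("a", "k", "sigma", "nu", "a_mu", "a_sigma", "k_r", "k_lam")


@dataclass(frozen=True)
class LogisticParams:
    """Center (log2 µM, equals log2 IC50) and slope of the logistic curve."""

    a: float
    k: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"slope k must be positive, got {self.k!r}")


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the hierarchical priors (precision parameterization)."""

    a_mu_mean: float = 0.0
    a_mu_precision: float = 1.0
    a_sigma_low: float = 0.01
    a_sigma_high: float = 5.0
    sigma_low: float = 0.01
    sigma_high: float = 0.1
    nu_mean: float = 250.0
    nu_precision: float = 0.001
    k_lambda_mean: float = 2.0
    k_lambda_precision: float = 0.01
    k_r_mean: float = 1.0
    k_r_precision: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.a_sigma_low < self.a_sigma_high):
            raise ValueError("a_sigma bounds must satisfy 0 < low < high")
        if not (0 < self.sigma_low < self.sigma_high):
            raise ValueError("sigma bounds must satisfy 0 < low < high")
        for name in ("a_mu_precision", "nu_precision", "k_lambda_precision", "k_r_precision"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 3
    n_iterations: int = 5000
    n_burn_in: int = 500
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.n_burn_in < self.n_iterations:
            raise ValueError("burn-in must be shorter than the chain")


@dataclass
class PosteriorChains:
    """Post-burn-in draws, per chain, for every sampled quantity."""

    samples: dict[str, np.ndarray]  # each (n_chains, n_kept)
    acceptance: dict[str, float]
    config: MCMCConfig
    priors: PriorConfig
    frozen: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.samples["a"].shape[0]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated, for pooled summaries."""
        return self.samples[name].reshape(-1)


@dataclass(frozen=True)
class PosteriorSummary:
    """Point estimates, intervals and diagnostics for one fitted pair."""

    mode_a: float
    mode_k: float
    hdi95_a: tuple[float, float]
    hdi95_k: tuple[float, float]
    rhat_a: float
    rhat_k: float
    mae: float
    n_points: int
    low_information: bool
    poor_convergence: bool

    @property
    def params(self) -> LogisticParams:
        return LogisticParams(a=self.mode_a, k=self.mode_k)


def logistic_response(x, params: LogisticParams):
    """Fitted inhibition fraction at log2 concentration ``x``.

    Strictly increasing in x, 0.5 at the center, asymptotes 0 and 1.
    Computed through the logistic sigmoid for overflow safety; accepts
    scalars or arrays.
    """
    return expit(_LN2 * params.k * (np.asarray(x, dtype=float) - params.a))


def mean_absolute_error(data: CurveInput, params: LogisticParams) -> float:
    """Mean |fitted − observed| over the pair's points (reported at the mode)."""
    return float(np.mean(np.abs(logistic_response(data.x, params) - data.y)))


# --------------------------------------------------------------------------
# log-posterior terms.  Uniform priors keep their normalization constants so
# the total matches an externally coded density sum; truncated normals are
# unnormalized (the truncation constant is fixed, so MCMC is unaffected).

def _loglik(x: np.ndarray, y: np.ndarray, a: float, k: float, sigma: float, nu: float) -> float:
    f = expit(_LN2 * k * (x - a))
    z = (y - f) / sigma
    n = x.size
    const = gammaln(0.5 * (nu + 1.0)) - gammaln(0.5 * nu) - 0.5 * math.log(nu * math.pi)
    return float(
        n * (const - math.log(sigma)) - 0.5 * (nu + 1.0) * np.log1p(z * z / nu).sum()
    )


def _lp_a(a: float, a_mu: float, a_sigma: float) -> float:
    zz = (a - a_mu) / a_sigma
    return -0.5 * zz * zz - math.log(a_sigma) - 0.5 * _LOG_2PI


def _lp_k(k: float, k_r: float, k_lam: float) -> float:
    if k <= 0:
        return -math.inf
    return k_r * math.log(k_lam) - gammaln(k_r) + (k_r - 1.0) * math.log(k) - k_lam * k


def _lp_normal(value: float, mean: float, precision: float, positive: bool) -> float:
    if positive and value <= 0:
        return -math.inf
    zz = (value - mean) * math.sqrt(precision)
    return -0.5 * zz * zz + 0.5 * math.log(precision) - 0.5 * _LOG_2PI


def _lp_uniform(value: float, low: float, high: float) -> float:
    if low <= value <= high:
        return -math.log(high - low)
    return -math.inf


def log_posterior(
    state: Mapping[str, float], data: CurveInput, priors: PriorConfig | None = None
) -> float:
    """Log of the unnormalized joint posterior at a full parameter state.

    ``state`` maps each of :data:`PARAM_NAMES` to a value.  States outside the
    support (k <= 0, sigma or a_sigma outside their uniform bounds, negative
    nu/k_r/k_lam) return −inf rather than raising, so samplers can simply
    reject them.
    """
    pr = priors or PriorConfig()
    a, k = state["a"], state["k"]
    sigma, nu = state["sigma"], state["nu"]
    a_mu, a_sigma = state["a_mu"], state["a_sigma"]
    k_r, k_lam = state["k_r"], state["k_lam"]

    lp = _lp_uniform(sigma, pr.sigma_low, pr.sigma_high)
    lp += _lp_uniform(a_sigma, pr.a_sigma_low, pr.a_sigma_high)
    lp += _lp_normal(nu, pr.nu_mean, pr.nu_precision, positive=True)
    lp += _lp_normal(k_r, pr.k_r_mean, pr.k_r_precision, positive=True)
    lp += _lp_normal(k_lam, pr.k_lambda_mean, pr.k_lambda_precision, positive=True)
    lp += _lp_normal(a_mu, pr.a_mu_mean, pr.a_mu_precision, positive=False)
    if not math.isfinite(lp):
        return -math.inf
    lp += _lp_a(a, a_mu, a_sigma)
    lp_k = _lp_k(k, k_r, k_lam)
    if not math.isfinite(lp_k):
        return -math.inf
    lp += lp_k
    lp += _loglik(data.x, data.y, a, k, sigma, nu)
    return float(lp)


# --------------------------------------------------------------------------
# sampler

_INITIAL_SCALES = {
    "a": 0.3,
    "k": 0.3,
    "sigma": 0.02,
    "nu": 25.0,
    "a_mu": 0.3,
    "a_sigma": 0.5,
    "k_r": 2.0,
    "k_lam": 2.0,
}
_ADAPT_WINDOW = 50
_TARGET_ACCEPT = 0.44  # optimal for one-dimensional random-walk updates


def _initial_state(data: CurveInput, priors: PriorConfig) -> dict[str, float]:
    """Deterministic in-support start: a at the dose whose response is nearest
    0.5 (median dose if responses are degenerate), k = 1, remaining parameters
    at prior means / mid-bounds."""
    y = data.y
    if y.size:
        a0 = float(data.x[int(np.argmin(np.abs(y - 0.5)))])
    else:  # pragma: no cover - assemble_curve_input forbids empty inputs
        a0 = 0.0
    if not np.isfinite(a0):
        a0 = float(np.median(data.x))
    return {
        "a": a0,
        "k": 1.0,
        "sigma": 0.05,
        "nu": priors.nu_mean,
        "a_mu": priors.a_mu_mean,
        "a_sigma": 0.5 * (priors.a_sigma_low + priors.a_sigma_high),
        "k_r": priors.k_r_mean,
        "k_lam": priors.k_lambda_mean,
    }


def _run_chain(
    data: CurveInput,
    priors: PriorConfig,
    config: MCMCConfig,
    seed: np.random.SeedSequence,
    frozen: Mapping[str, float],
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    rng = np.random.default_rng(seed)
    x, y = data.x, data.y
    pr = priors

    state = _initial_state(data, pr)
    state.update(frozen)
    sampled = [p for p in PARAM_NAMES if p not in frozen]
    scales = {p: _INITIAL_SCALES[p] for p in sampled}

    # cached log-posterior components
    ll = _loglik(x, y, state["a"], state["k"], state["sigma"], state["nu"])
    lpa = _lp_a(state["a"], state["a_mu"], state["a_sigma"])
    lpk = _lp_k(state["k"], state["k_r"], state["k_lam"])

    n_keep = config.n_iterations - config.n_burn_in
    out = {p: np.empty(n_keep) for p in PARAM_NAMES}
    acc_total = {p: 0 for p in sampled}
    acc_window = {p: 0 for p in sampled}

    log = math.log
    for it in range(config.n_iterations):
        for p in sampled:
            cur = state[p]
            prop = cur + scales[p] * rng.standard_normal()
            u = rng.random()
            if p == "a":
                new_ll = _loglik(x, y, prop, state["k"], state["sigma"], state["nu"])
                new_lpa = _lp_a(prop, state["a_mu"], state["a_sigma"])
                delta = new_ll + new_lpa - ll - lpa
                if delta >= 0 or log(u) < delta:
                    state[p], ll, lpa = prop, new_ll, new_lpa
                    acc_total[p] += 1
                    acc_window[p] += 1
            elif p == "k":
                new_lpk = _lp_k(prop, state["k_r"], state["k_lam"])
                if math.isfinite(new_lpk):
                    new_ll = _loglik(x, y, state["a"], prop, state["sigma"], state["nu"])
                    delta = new_ll + new_lpk - ll - lpk
                    if delta >= 0 or log(u) < delta:
                        state[p], ll, lpk = prop, new_ll, new_lpk
                        acc_total[p] += 1
                        acc_window[p] += 1
            elif p == "sigma":
                if pr.sigma_low <= prop <= pr.sigma_high:
                    new_ll = _loglik(x, y, state["a"], state["k"], prop, state["nu"])
                    delta = new_ll - ll
                    if delta >= 0 or log(u) < delta:
                        state[p], ll = prop, new_ll
                        acc_total[p] += 1
                        acc_window[p] += 1
            elif p == "nu":
                new_lp = _lp_normal(prop, pr.nu_mean, pr.nu_precision, positive=True)
                if math.isfinite(new_lp):
                    old_lp = _lp_normal(cur, pr.nu_mean, pr.nu_precision, positive=True)
                    new_ll = _loglik(x, y, state["a"], state["k"], state["sigma"], prop)
                    delta = new_ll + new_lp - ll - old_lp
                    if delta >= 0 or log(u) < delta:
                        state[p], ll = prop, new_ll
                        acc_total[p] += 1
                        acc_window[p] += 1
            elif p == "a_mu":
                new_lpa = _lp_a(state["a"], prop, state["a_sigma"])
                delta = (
                    new_lpa
                    + _lp_normal(prop, pr.a_mu_mean, pr.a_mu_precision, positive=False)
                    - lpa
                    - _lp_normal(cur, pr.a_mu_mean, pr.a_mu_precision, positive=False)
                )
                if delta >= 0 or log(u) < delta:
                    state[p], lpa = prop, new_lpa
                    acc_total[p] += 1
                    acc_window[p] += 1
            elif p == "a_sigma":
                if pr.a_sigma_low <= prop <= pr.a_sigma_high:
                    new_lpa = _lp_a(state["a"], state["a_mu"], prop)
                    delta = new_lpa - lpa
                    if delta >= 0 or log(u) < delta:
                        state[p], lpa = prop, new_lpa
                        acc_total[p] += 1
                        acc_window[p] += 1
            elif p == "k_r":
                new_lp = _lp_normal(prop, pr.k_r_mean, pr.k_r_precision, positive=True)
                if math.isfinite(new_lp):
                    new_lpk = _lp_k(state["k"], prop, state["k_lam"])
                    delta = (
                        new_lpk
                        + new_lp
                        - lpk
                        - _lp_normal(cur, pr.k_r_mean, pr.k_r_precision, positive=True)
                    )
                    if delta >= 0 or log(u) < delta:
                        state[p], lpk = prop, new_lpk
                        acc_total[p] += 1
                        acc_window[p] += 1
            else:  # k_lam
                new_lp = _lp_normal(prop, pr.k_lambda_mean, pr.k_lambda_precision, positive=True)
                if math.isfinite(new_lp):
                    new_lpk = _lp_k(state["k"], state["k_r"], prop)
                    delta = (
                        new_lpk
                        + new_lp
                        - lpk
                        - _lp_normal(cur, pr.k_lambda_mean, pr.k_lambda_precision, positive=True)
                    )
                    if delta >= 0 or log(u) < delta:
                        state[p], lpk = prop, new_lpk
                        acc_total[p] += 1
                        acc_window[p] += 1

        # adapt proposal scales during burn-in only; the post-burn-in kernel
        # is fixed, so retained draws are valid MCMC output
        if it < config.n_burn_in and (it + 1) % _ADAPT_WINDOW == 0:
            for p in sampled:
                rate = acc_window[p] / _ADAPT_WINDOW
                scales[p] = float(
                    np.clip(scales[p] * math.exp(rate - _TARGET_ACCEPT), 1e-4, 100.0)
                )
                acc_window[p] = 0

        if it >= config.n_burn_in:
            j = it - config.n_burn_in
            for p in PARAM_NAMES:
                out[p][j] = state[p]

    rates = {p: acc_total[p] / config.n_iterations for p in sampled}
    return out, rates


def run_mcmc(
    data: CurveInput,
    priors: PriorConfig | None = None,
    config: MCMCConfig | None = None,
    frozen: Mapping[str, float] | None = None,
) -> PosteriorChains:
    """Sample the posterior with independent adaptive MwG chains.

    ``frozen`` pins named parameters at fixed values (they are echoed in the
    output arrays but never updated) — used for reduced-model oracles and for
    conditioning studies.  Per-chain seeds are spawned deterministically from
    ``config.master_seed``, so identical inputs reproduce identical chains.
    """
    if data.n_points < 1:
        raise ValueError("cannot fit a curve to zero points")
    pr = priors or PriorConfig()
    cfg = config or MCMCConfig()
    frz = dict(frozen or {})
    for name in frz:
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {name!r}")

    seeds = np.random.SeedSequence(cfg.master_seed).spawn(cfg.n_chains)
    per_chain = [_run_chain(data, pr, cfg, s, frz) for s in seeds]

    samples = {
        p: np.stack([chain[0][p] for chain in per_chain]) for p in PARAM_NAMES
    }
    sampled = [p for p in PARAM_NAMES if p not in frz]
    acceptance = {
        p: float(np.mean([chain[1][p] for chain in per_chain])) for p in sampled
    }
    return PosteriorChains(
        samples=samples, acceptance=acceptance, config=cfg, priors=pr, frozen=frz
    )


# --------------------------------------------------------------------------
# posterior summaries

def hdi(samples: Sequence[float] | np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` of the sorted samples.

    Among tied-width windows the leftmost is returned.
    """
    arr = np.sort(np.asarray(samples, dtype=float).ravel())
    n = arr.size
    if n < 2:
        raise ValueError("hdi needs at least 2 samples")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    m = int(math.ceil(mass * n))
    m = min(m, n)
    widths = arr[m - 1 :] - arr[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first (leftmost) minimum
    return float(arr[i]), float(arr[i + m - 1])


def kde_mode(samples: Sequence[float] | np.ndarray) -> float:
    """Mode of an MCMC sample: argmax of a Silverman-bandwidth Gaussian KDE
    evaluated on a 512-point grid spanning the sample range."""
    arr = np.asarray(samples, dtype=float).ravel()
    if arr.size < 10:
        raise ValueError("kde_mode needs at least 10 samples")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        return lo
    kde = gaussian_kde(arr, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)
    return float(grid[int(np.argmax(kde(grid)))])


def split_rhat(chains: np.ndarray) -> float:
    """Classic split R-hat: each chain is halved, and the between-/within-
    half variance ratio is folded into the usual potential-scale-reduction
    statistic.  Values near 1 indicate the chains agree."""
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("split_rhat needs a 2-D array with at least 2 chains")
    if arr.shape[1] < 4:
        raise ValueError("split_rhat needs at least 4 draws per chain")
    half = arr.shape[1] // 2
    splits = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    chain_means = splits.mean(axis=1)
    chain_vars = splits.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0.0:
        return math.inf if b > 0 else 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w))


#: split R-hat above this on a or k raises the poor-convergence flag.
RHAT_THRESHOLD = 1.05


def summarize(chains: PosteriorChains, data: CurveInput) -> PosteriorSummary:
    """Pooled-KDE modes, 95% HDIs, split R-hat, and fit MAE at the mode."""
    mode_a = kde_mode(chains.pooled("a"))
    mode_k = kde_mode(chains.pooled("k"))
    mode_k = max(mode_k, 1e-12)  # KDE grid can brush zero for diffuse slopes
    params = LogisticParams(a=mode_a, k=mode_k)
    rhat_a = split_rhat(chains.samples["a"]) if chains.n_chains > 1 else math.nan
    rhat_k = split_rhat(chains.samples["k"]) if chains.n_chains > 1 else math.nan
    poor = bool(
        (math.isfinite(rhat_a) and rhat_a > RHAT_THRESHOLD)
        or (math.isfinite(rhat_k) and rhat_k > RHAT_THRESHOLD)
    )
    return PosteriorSummary(
        mode_a=mode_a,
        mode_k=mode_k,
        hdi95_a=hdi(chains.pooled("a")),
        hdi95_k=hdi(chains.pooled("k")),
        rhat_a=rhat_a,
        rhat_k=rhat_k,
        mae=mean_absolute_error(data, params),
        n_points=data.n_points,
        low_information=data.low_information,
        poor_convergence=poor,
    )


def fit_curve(
    data: CurveInput,
    priors: PriorConfig | None = None,
    config: MCMCConfig | None = None,
) -> tuple[PosteriorChains, PosteriorSummary]:
    """Convenience wrapper: sample, then summarize."""
    chains = run_mcmc(data, priors=priors, config=config)
    return chains, summarize(chains, data)
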