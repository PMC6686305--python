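"""Bayesian logistic meta-regression of null-model outcomes.

Null-model outcomes (aggregation / segregation / random) are related to
dataset characteristics one predictor at a time, because the outcome
categories are unbalanced and the characteristics are intercorrelated:

* dichotomous codings -> binomial logit GLM,
* trichotomous codings -> baseline-category multinomial logit GLM,
* guild-level records -> binomial GLMM with a per-dataset random intercept.

Several guild/outcome combinations are completely separated, so maximum
likelihood diverges; weakly informative Cauchy(0, 25) priors on the fixed
effects (and a half-Cauchy(25) prior on the random-intercept SD) keep the
posteriors proper.  Sampling is adaptive random-walk Metropolis; model
support is compared by the deviance information criterion, with
``delta_dic = DIC_null - DIC_model`` so positive values favour the
predictor, and an effect is called significant when the 95% highest
posterior density interval of a slope excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .outcomes import OutcomeRecord, records_to_frame

__all__ = [
    "ChainConfig",
    "DESK_CHAIN",
    "PAPER_CHAIN",
    "LONG_CHAIN",
    "GlmSpec",
    "GlmFit",
    "fit_binomial",
    "fit_multinomial",
    "fit_glmm",
    "dic",
    "delta_dic",
    "chain_diagnostics",
    "hpd_interval",
]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC chain settings: total iterations, burn-in, thinning interval."""

    iterations: int
    burn_in: int
    thinning: int

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.retained < 1000:
            raise ValueError(
                f"chain retains {self.retained} samples; at least 1,000 required"
            )

    @property
    def retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


#: Desk-scale default: ~2,000 retained samples in seconds.
DESK_CHAIN = ChainConfig(iterations=200_000, burn_in=10_000, thinning=95)
#: The published protocol: 10M iterations, 10,000 burn-in, thin 5,000
#: -> 1,998 retained samples.
PAPER_CHAIN = ChainConfig(iterations=10_000_000, burn_in=10_000, thinning=5_000)
#: Fallback for poorly mixing chains (100M iterations).
LONG_CHAIN = ChainConfig(iterations=100_000_000, burn_in=10_000, thinning=50_000)


@dataclass
class GlmSpec:
    """One meta-regression model: a single predictor against an outcome coding.

    ``predictor`` is a dataset-characteristics column (``None`` fits the
    intercept-only null model).  For binomial responses ``success`` is the
    category coded 1; ``contrast`` optionally restricts the data to two
    categories (otherwise success-vs-rest).  For multinomial responses the
    ``baseline`` category anchors the logits.
    """

    predictor: str | None
    response: str = "binomial"  # binomial | multinomial
    success: str = "aggregation"
    contrast: str | None = None
    baseline: str = "random"
    random_intercept: bool = False
    prior_scale: float = 25.0
    chain: ChainConfig = field(default_factory=lambda: DESK_CHAIN)

    def __post_init__(self) -> None:
        if self.response not in ("binomial", "multinomial"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")


@dataclass
class GlmFit:
    """Posterior samples and summaries of one fitted model."""

    spec: GlmSpec
    param_names: list[str]
    samples: np.ndarray  # (retained, n_params)
    hpd: np.ndarray  # (n_params, 2)
    posterior_mean: np.ndarray
    mean_deviance: float
    p_d: float
    dic: float
    significant: bool
    acceptance_rate: float
    lag1_autocorr: np.ndarray
    x_mean: float = 0.0
    x_sd: float = 1.0
    categories: tuple[str, ...] = ()
    _loglik: Callable[[np.ndarray], float] | None = None

    def slope_names(self) -> list[str]:
        return [p for p in self.param_names if p.startswith("beta_")]

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.param_names):
            raw = name.startswith("beta_") and self.x_sd != 1.0
            rows.append(
                {
                    "parameter": name,
                    "mean": self.posterior_mean[i],
                    "hpd_low": self.hpd[i, 0],
                    "hpd_high": self.hpd[i, 1],
                    "mean_raw_scale": self.posterior_mean[i] / self.x_sd
                    if raw
                    else self.posterior_mean[i],
                    "lag1_autocorr": self.lag1_autocorr[i],
                }
            )
        return pd.DataFrame(rows)


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` posterior mass (sorted window)."""
    x = np.sort(np.asarray(samples))
    n = len(x)
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def _lag1(samples: np.ndarray) -> np.ndarray:
    out = np.zeros(samples.shape[1])
    for j in range(samples.shape[1]):
        x = samples[:, j]
        if x.std() == 0:
            out[j] = 0.0
        else:
            out[j] = float(np.corrcoef(x[:-1], x[1:])[0, 1])
    return out


def _log_cauchy_sum(x: np.ndarray, scale: float) -> float:
    x = np.atleast_1d(x)
    return float((-np.log(np.pi * scale) - np.log1p((x / scale) ** 2)).sum())


def _adaptive_metropolis(
    logpost: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    blocks: Sequence[np.ndarray],
    chain: ChainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Blockwise random-walk Metropolis with burn-in scale adaptation.

    Proposal scales per block are tuned toward ~30% acceptance during
    burn-in (Robbins--Monro on the log scale) and frozen afterwards.
    """
    theta = theta0.copy()
    lp = logpost(theta)
    if not np.isfinite(lp):
        raise ValueError("non-finite log posterior at the initial value")
    scales = [0.5] * len(blocks)
    acc = np.zeros(len(blocks))
    tries = np.zeros(len(blocks))
    acc_win = np.zeros(len(blocks))
    try_win = np.zeros(len(blocks))
    retained = np.empty((chain.retained, len(theta)))
    kept = 0
    for it in range(chain.iterations):
        b = it % len(blocks)
        idx = blocks[b]
        prop = theta.copy()
        prop[idx] += rng.normal(0.0, scales[b], size=len(idx))
        lp_prop = logpost(prop)
        try_win[b] += 1
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            acc_win[b] += 1
            if it >= chain.burn_in:
                acc[b] += 1
        if it >= chain.burn_in:
            tries[b] += 1
        if it < chain.burn_in and try_win[b] >= 50:
            rate = acc_win[b] / try_win[b]
            scales[b] = float(np.clip(scales[b] * np.exp(rate - 0.3), 1e-4, 50.0))
            acc_win[b] = try_win[b] = 0
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thinning == 0:
            if kept < chain.retained:
                retained[kept] = theta
                kept += 1
    rate = float(acc.sum() / max(tries.sum(), 1))
    if not 0.1 <= rate <= 0.6:
        warnings.warn(
            f"Metropolis acceptance rate {rate:.2f} outside [0.1, 0.6] after "
            "adaptation; consider a longer chain",
            stacklevel=3,
        )
    return retained[:kept], rate


def _prepare(
    records: Iterable[OutcomeRecord] | pd.DataFrame, spec: GlmSpec
) -> tuple[pd.DataFrame, np.ndarray, float, float]:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to fit")
    if spec.predictor is None:
        return df, np.zeros(len(df)), 0.0, 1.0
    x = df[spec.predictor].to_numpy(dtype=float)
    mu, sd = float(x.mean()), float(x.std())
    if sd == 0:
        raise ValueError(f"predictor {spec.predictor!r} is constant")
    return df, (x - mu) / sd, mu, sd


def _finalize(
    spec: GlmSpec,
    names: list[str],
    samples: np.ndarray,
    rate: float,
    loglik: Callable[[np.ndarray], float],
    x_mean: float,
    x_sd: float,
    categories: tuple[str, ...] = (),
) -> GlmFit:
    mean = samples.mean(axis=0)
    deviances = np.array([-2.0 * loglik(s) for s in samples])
    mean_dev = float(deviances.mean())
    p_d = mean_dev - (-2.0 * loglik(mean))
    hpd = np.array([hpd_interval(samples[:, j]) for j in range(samples.shape[1])])
    slopes = [j for j, n in enumerate(names) if n.startswith("beta_")]
    significant = any(hpd[j, 0] > 0 or hpd[j, 1] < 0 for j in slopes)
    return GlmFit(
        spec=spec,
        param_names=names,
        samples=samples,
        hpd=hpd,
        posterior_mean=mean,
        mean_deviance=mean_dev,
        p_d=float(p_d),
        dic=float(mean_dev + p_d),
        significant=bool(significant),
        acceptance_rate=rate,
        lag1_autocorr=_lag1(samples),
        x_mean=x_mean,
        x_sd=x_sd,
        categories=categories,
        _loglik=loglik,
    )


# ---------------------------------------------------------------------------
# binomial GLM
# ---------------------------------------------------------------------------

def _binomial_data(df: pd.DataFrame, spec: GlmSpec) -> tuple[np.ndarray, pd.DataFrame]:
    if spec.contrast is not None:
        mask = df["outcome"].isin([spec.success, spec.contrast])
        df = df[mask]
        if df.empty:
            raise ValueError("no records in the requested outcome contrast")
    return (df["outcome"] == spec.success).to_numpy(dtype=float), df


def fit_binomial(
    records: Iterable[OutcomeRecord] | pd.DataFrame,
    spec: GlmSpec,
    rng: np.random.Generator,
) -> GlmFit:
    """Binomial logit GLM of a dichotomous outcome coding on one predictor.

    The predictor is z-standardized internally; ``summary()`` reports the
    slope on both the standardized and the raw scale.  Fixed effects carry
    independent Cauchy(0, prior_scale) priors.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    y, df = _binomial_data(df, spec)
    df, x, mu, sd = _prepare(df, spec)
    has_slope = spec.predictor is not None
    X = np.column_stack([np.ones(len(df)), x]) if has_slope else np.ones((len(df), 1))
    names = ["intercept"] + ([f"beta_{spec.predictor}"] if has_slope else [])
    scale = spec.prior_scale

    def loglik(theta: np.ndarray) -> float:
        eta = X @ theta
        return float((y * eta - np.logaddexp(0.0, eta)).sum())

    def logpost(theta: np.ndarray) -> float:
        return loglik(theta) + _log_cauchy_sum(theta, scale)

    samples, rate = _adaptive_metropolis(
        logpost, np.zeros(X.shape[1]), [np.arange(X.shape[1])], spec.chain, rng
    )
    fit = _finalize(spec, names, samples, rate, loglik, mu, sd)
    return fit


def predict_proba_binomial(fit: GlmFit, x: np.ndarray) -> np.ndarray:
    """Posterior-mean fitted success probabilities at standardized ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    X = np.column_stack([np.ones(len(x)), x])[:, : fit.samples.shape[1]]
    eta = X @ fit.samples.T
    return (1.0 / (1.0 + np.exp(-eta))).mean(axis=1)


# ---------------------------------------------------------------------------
# multinomial GLM
# ---------------------------------------------------------------------------

def fit_multinomial(
    records: Iterable[OutcomeRecord] | pd.DataFrame,
    spec: GlmSpec,
    rng: np.random.Generator,
) -> GlmFit:
    """Baseline-category multinomial logit GLM over the three outcomes.

    One linear predictor per non-baseline category; the baseline (default
    ``random``) has logit fixed at zero.  Fitted category probabilities sum
    to one by construction.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df, x, mu, sd = _prepare(df, spec)
    cats = sorted(set(df["outcome"]) - {spec.baseline})
    if not cats:
        raise ValueError("only the baseline category is present")
    has_slope = spec.predictor is not None
    k_per = 2 if has_slope else 1
    X = np.column_stack([np.ones(len(df)), x]) if has_slope else np.ones((len(df), 1))
    Y = np.column_stack([(df["outcome"] == c).to_numpy(float) for c in cats])
    names: list[str] = []
    for c in cats:
        names.append(f"intercept_{c}")
        if has_slope:
            names.append(f"beta_{spec.predictor}_{c}")
    scale = spec.prior_scale

    def loglik(theta: np.ndarray) -> float:
        beta = theta.reshape(len(cats), k_per)
        eta = X @ beta.T  # (n, n_cats)
        full = np.column_stack([np.zeros(len(X)), eta])
        return float((eta * Y).sum() - logsumexp(full, axis=1).sum())

    def logpost(theta: np.ndarray) -> float:
        return loglik(theta) + _log_cauchy_sum(theta, scale)

    n_par = len(cats) * k_per
    samples, rate = _adaptive_metropolis(
        logpost, np.zeros(n_par), [np.arange(n_par)], spec.chain, rng
    )
    return _finalize(
        spec, names, samples, rate, loglik, mu, sd,
        categories=(spec.baseline, *cats),
    )


def predict_proba_multinomial(fit: GlmFit, x: np.ndarray) -> np.ndarray:
    """Posterior-mean category probabilities at standardized ``x``.

    Columns follow ``fit.categories`` (baseline first); rows sum to 1.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n_cats = len(fit.categories) - 1
    k_per = fit.samples.shape[1] // n_cats
    X = np.column_stack([np.ones(len(x)), x])[:, :k_per]
    probs = np.zeros((len(x), n_cats + 1))
    for s in fit.samples:
        beta = s.reshape(n_cats, k_per)
        eta = np.column_stack([np.zeros(len(x)), X @ beta.T])
        e = np.exp(eta - eta.max(axis=1, keepdims=True))
        probs += e / e.sum(axis=1, keepdims=True)
    return probs / len(fit.samples)


# ---------------------------------------------------------------------------
# binomial GLMM (per-dataset random intercept)
# ---------------------------------------------------------------------------

def fit_glmm(
    records: Iterable[OutcomeRecord] | pd.DataFrame,
    spec: GlmSpec,
    rng: np.random.Generator,
) -> GlmFit:
    """Binomial GLMM with a per-dataset random intercept.

    Random intercepts ``u_g ~ N(0, sigma^2)`` with a half-Cauchy(prior_scale)
    prior on ``sigma``; fixed effects as in :func:`fit_binomial`.  With the
    variance forced to zero the fixed-effect model reduces to the GLM.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    y, df = _binomial_data(df, spec)
    df, x, mu, sd = _prepare(df, spec)
    groups, gidx = np.unique(df["dataset_id"].to_numpy(), return_inverse=True)
    G = len(groups)
    has_slope = spec.predictor is not None
    X = np.column_stack([np.ones(len(df)), x]) if has_slope else np.ones((len(df), 1))
    kf = X.shape[1]
    names = (
        ["intercept"]
        + ([f"beta_{spec.predictor}"] if has_slope else [])
        + [f"u_{g}" for g in groups]
        + ["log_sigma"]
    )
    scale = spec.prior_scale

    def loglik(theta: np.ndarray) -> float:
        beta = theta[:kf]
        u = theta[kf : kf + G]
        eta = X @ beta + u[gidx]
        return float((y * eta - np.logaddexp(0.0, eta)).sum())

    def logpost(theta: np.ndarray) -> float:
        beta = theta[:kf]
        u = theta[kf : kf + G]
        log_sigma = theta[-1]
        if not -12.0 < log_sigma < 12.0:  # keep exp() in a safe range
            return -np.inf
        sigma = np.exp(log_sigma)
        lp = loglik(theta)
        lp += _log_cauchy_sum(beta, scale)
        lp += float(
            -0.5 * (u**2).sum() * np.exp(-2.0 * log_sigma)
            - G * (log_sigma + 0.5 * np.log(2 * np.pi))
        )
        # half-Cauchy(scale) on sigma, with the log-scale Jacobian
        lp += float(
            np.log(2.0 / (np.pi * scale)) - np.log1p((sigma / scale) ** 2) + log_sigma
        )
        return lp

    theta0 = np.zeros(kf + G + 1)
    blocks = [np.arange(kf), np.arange(kf, kf + G), np.array([kf + G])]
    samples, rate = _adaptive_metropolis(logpost, theta0, blocks, spec.chain, rng)
    return _finalize(spec, names, samples, rate, loglik, mu, sd)


# ---------------------------------------------------------------------------
# model comparison & diagnostics
# ---------------------------------------------------------------------------

def dic(fit: GlmFit) -> float:
    """Deviance information criterion: mean deviance + p_D."""
    return fit.dic


def delta_dic(fit: GlmFit, null_fit: GlmFit) -> float:
    """DIC improvement of ``fit`` over its intercept-only null model.

    Positive values mean the predictor model is supported (lower DIC than
    the null); zero for a model compared with itself.
    """
    return float(null_fit.dic - fit.dic)


@dataclass
class DiagnosticsReport:
    lag1_autocorr: dict[str, float]
    flagged: list[str]
    advice: str | None

    @property
    def ok(self) -> bool:
        return not self.flagged


def chain_diagnostics(fit: GlmFit, threshold: float = 0.05) -> DiagnosticsReport:
    """Lag-1 autocorrelation of the retained samples, per parameter.

    Parameters with |autocorrelation| at or above ``threshold`` are flagged,
    with the advice to lengthen the chain (e.g. the 100M-iteration preset).
    """
    ac = {n: float(a) for n, a in zip(fit.param_names, fit.lag1_autocorr)}
    flagged = [n for n, a in ac.items() if abs(a) >= threshold]
    advice = (
        "retained-sample autocorrelation >= 0.05; lengthen the chain "
        "(e.g. LONG_CHAIN, 100M iterations) or increase thinning"
        if flagged
        else None
    )
    return DiagnosticsReport(lag1_autocorr=ac, flagged=flagged, advice=advice)
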