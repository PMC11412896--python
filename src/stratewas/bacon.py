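"""Bias and inflation correction of EWAS test statistics.

A set of z-statistics (effect/SE) is modelled as a three-component Gaussian
mixture: a dominant null component N(mu0, sigma0^2) flanked by two
alternative components capturing true associations.  The null component's
mean is the *bias* and its SD the *inflation* of the statistics; corrected
statistics are ``(z - bias)/inflation``, equivalently
``effect - bias*se`` with ``se`` scaled by the inflation.

The mixture is fit by multi-start expectation-maximization with the
constraints mu1 < mu0 < mu2 (alternative components on either side of the
null) and pi0 >= 0.5 (the null dominates), checked at each candidate
solution; the best-likelihood admissible solution wins.  The estimands
(null mean and SD) match the posterior summaries of the Bayesian sampler
formulation of the same mixture; EM is used here for determinism.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = ["BaconParams", "Bacon", "BaconResults", "estimate_bacon", "apply_bacon"]

_SD_FLOOR = 1e-3
_PI_FLOOR = 1e-8
_SEP = 3.0  # minimum |alt mean - null mean| in null SDs


@dataclass
class BaconParams:
    """Fitted mixture parameters.

    ``bias`` and ``inflation`` are the null component's mean and SD;
    ``mix_props``/``alt_means``/``alt_sds`` describe the full mixture with
    the null first.
    """

    bias: float
    inflation: float
    mix_props: tuple[float, float, float]
    alt_means: tuple[float, float]
    alt_sds: tuple[float, float]
    n_stats: int
    converged: bool
    loglik: float = np.nan

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "inflation": self.inflation,
            "mix_props": list(self.mix_props),
            "alt_means": list(self.alt_means),
            "alt_sds": list(self.alt_sds),
            "n_stats": self.n_stats,
            "converged": self.converged,
            "loglik": self.loglik,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaconParams":
        return cls(
            bias=d["bias"],
            inflation=d["inflation"],
            mix_props=tuple(d["mix_props"]),
            alt_means=tuple(d["alt_means"]),
            alt_sds=tuple(d["alt_sds"]),
            n_stats=int(d["n_stats"]),
            converged=bool(d["converged"]),
            loglik=float(d.get("loglik", np.nan)),
        )


_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _em(z: np.ndarray, mu: np.ndarray, sd: np.ndarray, pi: np.ndarray,
        tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    """Plain EM for a 3-component univariate Gaussian mixture.

    Convergence is declared when the mean (per-observation) log-likelihood
    changes by less than ``tol`` between iterations.
    """
    n = z.size
    zc = z[:, None]
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step (hand-rolled normal logpdf: this loop dominates runtime)
        d = (zc - mu[None, :]) / sd[None, :]
        logpdf = -0.5 * d * d - np.log(sd)[None, :] - _LOG_SQRT_2PI + np.log(pi)[None, :]
        m = logpdf.max(axis=1, keepdims=True)
        w = np.exp(logpdf - m)
        tot = w.sum(axis=1, keepdims=True)
        ll = float((np.log(tot).ravel() + m.ravel()).sum())
        w /= tot
        # M step
        nk = w.sum(axis=0)
        pi = np.maximum(nk / n, _PI_FLOOR)
        pi /= pi.sum()
        mu = (w * zc).sum(axis=0) / np.maximum(nk, _PI_FLOOR * n)
        var = (w * (zc - mu[None, :]) ** 2).sum(axis=0) / np.maximum(nk, _PI_FLOOR * n)
        sd = np.sqrt(np.maximum(var, _SD_FLOOR**2))
        # separation constraint: alternative means stay at least _SEP null
        # SDs away from the null mean, mirroring the informative priors of
        # the sampler formulation; without it the flanking components bite
        # into the null's tails on signal-free batches and deflate sigma0
        mu[1] = min(mu[1], mu[0] - _SEP * sd[0])
        mu[2] = max(mu[2], mu[0] + _SEP * sd[0])
        if abs(ll - ll_old) / n < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return mu, sd, pi, ll_old, converged


class Bacon:
    """Three-component mixture model of a vector of z-statistics."""

    def __init__(self, z: np.ndarray, n_starts: int = 10, tol: float = 1e-8,
                 max_iter: int = 500, seed: int = 0):
        z = np.asarray(z, float).ravel()
        if not np.all(np.isfinite(z)):
            raise InputError("z statistics must be finite")
        if z.size < 1000:
            raise InsufficientDataError(
                f"need >= 1000 statistics to estimate bias/inflation, got {z.size}"
            )
        if z.size < 10_000:
            logger.warning("only %d statistics; bias/inflation estimates may be unstable", z.size)
        self.z = z
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def fit(self) -> "BaconResults":
        z = self.z
        rng = np.random.default_rng(self.seed)
        med = float(np.median(z))
        mad = float(1.4826 * np.median(np.abs(z - med))) or float(np.std(z)) or 1.0

        # short-run multi-start: every start gets a few dozen iterations,
        # only the best is refined to full convergence
        starts = []
        for _ in range(self.n_starts):
            mu0 = med + rng.normal(0.0, 0.05 * mad)
            s0 = mad * rng.uniform(0.85, 1.15)
            off = rng.uniform(3.0, 5.0)
            mu = np.array([mu0, mu0 - off * s0, mu0 + off * s0])
            sd = np.array([s0, s0 * rng.uniform(1.0, 2.0), s0 * rng.uniform(1.0, 2.0)])
            pi = np.array([0.9, 0.05, 0.05])
            mu, sd, pi, ll, _ = _em(z, mu, sd, pi, self.tol, min(40, self.max_iter))
            starts.append((ll, mu, sd, pi))
        starts.sort(key=lambda s: s[0], reverse=True)

        best = None  # (admissible, loglik, params)
        for ll0, mu, sd, pi in starts[:2]:
            mu, sd, pi, ll, conv = _em(z, mu, sd, pi, self.tol, self.max_iter)

            null = int(np.argmax(pi))
            ties = np.where(np.isclose(pi, pi[null], rtol=1e-9))[0]
            if len(ties) > 1:  # tie on mixing proportion: smallest |mean| wins
                null = int(ties[np.argmin(np.abs(mu[ties]))])
            alt = [k for k in range(3) if k != null]
            alt.sort(key=lambda k: mu[k])
            admissible = (
                pi[null] >= 0.5
                and mu[alt[0]] <= mu[null] <= mu[alt[1]]
            )
            params = BaconParams(
                bias=float(mu[null]),
                inflation=float(sd[null]),
                mix_props=(float(pi[null]), float(pi[alt[0]]), float(pi[alt[1]])),
                alt_means=(float(mu[alt[0]]), float(mu[alt[1]])),
                alt_sds=(float(sd[alt[0]]), float(sd[alt[1]])),
                n_stats=z.size,
                converged=conv,
                loglik=ll,
            )
            key = (admissible, ll)
            if best is None or key > best[0]:
                best = (key, params)

        params = best[1]
        if not best[0][0]:
            logger.warning("no admissible mixture solution found; returning best fit unconverged")
            params.converged = False
        return BaconResults(params, self)


class BaconResults:
    """Fitted mixture with correction methods."""

    def __init__(self, params: BaconParams, model: "Bacon | None" = None):
        self.params = params
        self.model = model

    @property
    def bias(self) -> float:
        return self.params.bias

    @property
    def inflation(self) -> float:
        return self.params.inflation

    def correct(self, table: pd.DataFrame, override: bool = False) -> pd.DataFrame:
        return apply_bacon(table, self.params, override=override)

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                "Test-statistic bias/inflation estimate",
                "=" * 43,
                f"n statistics: {p.n_stats}   converged: {p.converged}",
                f"bias (null mean):      {p.bias:+.4f}",
                f"inflation (null SD):   {p.inflation:.4f}",
                f"mixing proportions:    null {p.mix_props[0]:.3f}, "
                f"low {p.mix_props[1]:.3f}, high {p.mix_props[2]:.3f}",
                f"alternative means:     {p.alt_means[0]:+.3f}, {p.alt_means[1]:+.3f}",
            ]
        )


def estimate_bacon(z: np.ndarray, **kwargs) -> BaconParams:
    """Fit the mixture and return the bias/inflation parameters."""
    return Bacon(z, **kwargs).fit().params


def apply_bacon(table: pd.DataFrame, params: BaconParams, override: bool = False) -> pd.DataFrame:
    """Correct a summary-statistics table for bias and inflation.

    Adds ``effect_bc``/``se_bc``/``p_bc`` columns:
    ``effect_bc = effect - bias*se``, ``se_bc = inflation*se``, and the
    p-value recomputed two-sided from the corrected z against the standard
    normal.
    """
    if params.inflation <= 0:
        raise InputError("inflation must be > 0")
    if not params.converged and not override:
        raise InputError("mixture fit did not converge; pass override=True to apply anyway")
    out = table.copy()
    se = out["se"].to_numpy(float)
    eff = out["effect"].to_numpy(float)
    out["effect_bc"] = eff - params.bias * se
    out["se_bc"] = params.inflation * se
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, eff / se, np.nan)
    z_bc = (z - params.bias) / params.inflation
    out["p_bc"] = np.clip(2 * stats.norm.sf(np.abs(z_bc)), np.finfo(float).tiny, 1.0)
    return out
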