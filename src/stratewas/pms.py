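"""Polymethylation scores (PMS).

A PMS is the methylation analogue of a polygenic risk score: a weighted sum
of a target sample's (standardized) methylation values at probes passing a
training p-value threshold, weighted by the training effect sizes.  To
avoid optimizing the threshold on the target data, scores are computed at a
fixed ladder of thresholds and summarized by the first principal component
across thresholds.

Before scoring, co-methylated regions are collapsed: maximal runs of
adjacent probes whose every consecutive pair correlates with R^2 above the
cutoff (on covariate-residualized betas) are pruned to the single probe
with the most significant training p-value.

Evaluation is by logistic regression of case/control status on the PMS,
reporting Nagelkerke's pseudo-R^2, AIC/BIC, and a Vuong-style non-nested
comparison between competing scores.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import ComethConfig, PmsConfig
from .containers import BetaMatrix
from .exceptions import (
    DegenerateInputError,
    InputError,
    InsufficientDataError,
    SeparationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "build_cometh_regions",
    "prune_regions",
    "compute_pms_matrix",
    "pms_pc1",
    "evaluate_pms",
    "compare_models",
    "residualize_betas",
    "PolymethylationScore",
    "PMSResults",
    "PmsEval",
]


def residualize_betas(betas: BetaMatrix, design: pd.DataFrame) -> BetaMatrix:
    """Residualize each probe's betas on a covariate design (with intercept).

    Residuals are shifted back by the probe mean so values stay in [0, 1]
    up to clipping; used to estimate co-methylation net of covariates.
    """
    X = design.to_numpy(float)
    Y = betas.values.to_numpy(float).T  # samples x probes
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    vals = (resid + Y.mean(axis=0, keepdims=True)).T
    vals = np.clip(vals, 0.0, 1.0)
    return BetaMatrix(
        pd.DataFrame(vals, index=betas.values.index, columns=betas.values.columns),
        betas.annot,
    )


def build_cometh_regions(residual_betas: BetaMatrix, config: ComethConfig | None = None) -> list[np.ndarray]:
    """Co-methylated regions: runs of adjacent probes with pairwise R^2 above
    the cutoff.

    Probes are taken in genomic order; two consecutive probes are connected
    when they are at most ``max_gap_bp`` apart on the same chromosome and
    the squared Pearson correlation of their methylation across samples is
    strictly greater than ``r2_threshold``.  Maximal connected runs of two
    or more probes are returned as index arrays into the sorted matrix.
    """
    config = config or ComethConfig()
    if residual_betas.n_samples < 2:
        raise InsufficientDataError("need >= 2 samples to estimate co-methylation")
    bm = residual_betas.sorted_by_position()
    vals = bm.values.to_numpy(float)
    chrom = bm.annot["chrom"].to_numpy()
    pos = bm.annot["pos"].to_numpy(int)

    # adjacent-pair correlations, vectorized
    a = vals[:-1]
    b = vals[1:]
    am = a - a.mean(axis=1, keepdims=True)
    bm_ = b - b.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", am, bm_)
    den = np.sqrt(np.einsum("ij,ij->i", am, am) * np.einsum("ij,ij->i", bm_, bm_))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(den > 0, (num / den) ** 2, 0.0)
    connected = (
        (chrom[:-1] == chrom[1:])
        & (pos[1:] - pos[:-1] <= config.max_gap_bp)
        & (r2 > config.r2_threshold)
    )
    regions: list[np.ndarray] = []
    start = None
    for i, conn in enumerate(connected):
        if conn and start is None:
            start = i
        elif not conn and start is not None:
            regions.append(np.arange(start, i + 1))
            start = None
    if start is not None:
        regions.append(np.arange(start, len(connected) + 1))
    # report regions as probe-id arrays so callers need not track sort order
    probe_ids = bm.probe_ids.to_numpy()
    return [probe_ids[idx] for idx in regions]


def prune_regions(regions: list[np.ndarray], training_sumstats: pd.DataFrame,
                  all_probes=None, p_col: str | None = None) -> pd.Index:
    """Collapse each co-methylation region to its most significant probe.

    Probes missing from the training summary statistics are treated as
    p = 1 (logged).  Ties break to the probe with the smallest genomic
    coordinate, i.e. the first in region order.  Probes outside every
    region are all kept.  Returns the kept probe ids.
    """
    p_col = p_col or ("p_re" if "p_re" in training_sumstats.columns else "p")
    pmap = training_sumstats.set_index("probe")[p_col]
    if all_probes is None:
        all_probes = pd.Index(pmap.index)
    all_probes = pd.Index(all_probes)
    drop: set = set()
    n_missing = 0
    for region in regions:
        region = list(region)
        pvals = np.array([float(pmap.get(pr, 1.0)) for pr in region])
        n_missing += int(sum(pr not in pmap.index for pr in region))
        keep_i = int(np.argmin(pvals))  # argmin takes the first minimum: smallest coordinate
        drop.update(pr for i, pr in enumerate(region) if i != keep_i)
    if n_missing:
        logger.info("prune_regions: %d region probes missing from training stats (p=1)", n_missing)
    return all_probes[~all_probes.isin(drop)]


def compute_pms_matrix(target_betas: BetaMatrix, training_sumstats: pd.DataFrame,
                       kept_probes, config: PmsConfig | None = None,
                       p_col: str | None = None, effect_col: str | None = None) -> pd.DataFrame:
    """Per-sample scores at every p-value threshold.

    ``S_t(sample) = sum_{j: p_j <= t} effect_j * m_j(sample)`` over kept
    probes present in both target and training, with per-probe
    standardization of the methylation when configured; each threshold
    column is finally z-scored across samples.
    """
    config = config or PmsConfig()
    p_col = p_col or ("p_re" if "p_re" in training_sumstats.columns else "p")
    effect_col = effect_col or ("effect_re" if "effect_re" in training_sumstats.columns else "effect")
    train = training_sumstats.set_index("probe")
    probes = pd.Index(kept_probes).intersection(target_betas.probe_ids)
    n_missing = len(pd.Index(kept_probes).difference(train.index))
    probes = probes.intersection(train.index)
    if n_missing:
        logger.info("compute_pms_matrix: dropping %d kept probes missing from training", n_missing)
    if not len(probes):
        raise DegenerateInputError("no kept probes present in both target and training data")

    M = target_betas.values.loc[probes].to_numpy(float)  # probes x samples
    if config.standardize_probes:
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        M = (M - mu) / sd
    eff = train.loc[probes, effect_col].to_numpy(float)
    pv = train.loc[probes, p_col].to_numpy(float)

    cols = {}
    for t in config.thresholds:
        mask = pv <= t
        if not mask.any():
            logger.info("threshold %g: no probes pass; score column is all-zero", t)
            cols[f"S_{t:g}"] = np.zeros(M.shape[1])
            continue
        s = eff[mask] @ M[mask]
        cols[f"S_{t:g}"] = s
    out = pd.DataFrame(cols, index=target_betas.sample_ids)
    if not any((pv <= t).any() for t in config.thresholds):
        raise DegenerateInputError("no probes pass any threshold; empty score")
    # z-score each threshold column across samples
    sd = out.std(axis=0, ddof=0)
    out = (out - out.mean(axis=0)) / sd.replace(0.0, 1.0)
    return out


def pms_pc1(score_matrix: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of the threshold-score matrix.

    Columns are standardized; the PC1 sign is oriented so its correlation
    with the column mean is positive.  Returns (per-sample PMS,
    variance fraction explained by PC1).
    """
    X = score_matrix.to_numpy(float)
    sd = X.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise DegenerateInputError("need >= 2 threshold columns with nonzero variance")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    pc1 = U[:, 0] * S[0]
    var_frac = float(S[0] ** 2 / (S**2).sum())
    mean_col = Xs.mean(axis=1)
    if np.corrcoef(pc1, mean_col)[0, 1] < 0:
        pc1 = -pc1
    return pd.Series(pc1, index=score_matrix.index, name="PMS"), var_frac


@dataclass
class PmsEval:
    """Logistic evaluation of a per-sample score against case status."""

    pms: pd.Series
    pc1_var_frac: float
    beta_logit: float
    p_assoc: float
    nagelkerke_r2: float
    aic: float
    bic: float
    n: int
    loglik_obs: np.ndarray  # per-observation log-likelihood contributions
    llf: float
    llnull: float

    def summary(self) -> str:
        return "\n".join(
            [
                "PMS logistic evaluation",
                "=" * 43,
                f"n: {self.n}   PC1 variance fraction: {self.pc1_var_frac:.3f}",
                f"log-odds per SD of PMS: {self.beta_logit:+.4f}   p: {self.p_assoc:.3e}",
                f"Nagelkerke R^2: {self.nagelkerke_r2:.4f}",
                f"AIC: {self.aic:.2f}   BIC: {self.bic:.2f}",
            ]
        )


def _fit_logit(y: np.ndarray, X: np.ndarray):
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    phat = res.predict()
    if np.all((phat > 0.999) == (y > 0.5)) and np.all((phat < 0.001) == (y < 0.5)):
        raise SeparationError("perfect separation: logistic MLE does not exist")
    return res


def evaluate_pms(pms: pd.Series, status, covariates: pd.DataFrame | None = None,
                 pc1_var_frac: float = np.nan) -> PmsEval:
    """Logistic regression of status on the PMS (plus optional covariates).

    Nagelkerke R^2 = [1 - exp((2/n)(l0 - l1))] / [1 - exp((2/n) l0)], where
    l0/l1 are the null and fitted log-likelihoods.
    """
    status_arr = pd.Series(status).reset_index(drop=True)
    if status_arr.dtype.kind in "OUS":
        y = (status_arr == "case").to_numpy(float)
    else:
        y = status_arr.to_numpy(float)
    pms_z = (pms - pms.mean()) / (pms.std(ddof=0) or 1.0)
    n = len(y)
    if n <= 10:
        raise InsufficientDataError("need n > 10 samples for evaluation")
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("both classes must be present")
    X = [np.ones(n), pms_z.to_numpy(float)]
    if covariates is not None:
        for c in covariates.columns:
            X.append(covariates[c].to_numpy(float))
    X = np.column_stack(X)
    k = X.shape[1]  # every supplied parameter counts towards the penalty
    # fit on a linearly independent column subset: redundant covariates
    # (e.g. a constant alongside the intercept) leave the likelihood
    # untouched but would make the Hessian singular
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    keep = diag > max(X.shape) * np.finfo(float).eps * diag.max()
    res = _fit_logit(y, X[:, keep])
    llf = float(res.llf)
    llnull = float(sm.Logit(y, np.ones((n, 1))).fit(disp=0).llf)
    r2 = (1 - np.exp((2 / n) * (llnull - llf))) / (1 - np.exp((2 / n) * llnull))
    phat = np.clip(res.predict(), 1e-12, 1 - 1e-12)
    ll_obs = y * np.log(phat) + (1 - y) * np.log(1 - phat)
    return PmsEval(
        pms=pms,
        pc1_var_frac=pc1_var_frac,
        beta_logit=float(res.params[1]),
        p_assoc=float(res.pvalues[1]),
        nagelkerke_r2=float(r2),
        aic=float(2 * k - 2 * llf),
        bic=float(k * np.log(n) - 2 * llf),
        n=n,
        loglik_obs=ll_obs,
        llf=llf,
        llnull=llnull,
    )


def compare_models(eval_a: PmsEval, eval_b: PmsEval) -> tuple[float, float]:
    """Vuong-style non-nested comparison of two fitted evaluations.

    z = sqrt(n) * mean(d_i) / sd(d_i) on per-observation log-likelihood
    differences d_i; positive z favours model a.  Identical models return
    (0, 1).
    """
    if eval_a.n != eval_b.n or len(eval_a.loglik_obs) != len(eval_b.loglik_obs):
        raise InputError("models must be fit on identical samples")
    d = eval_a.loglik_obs - eval_b.loglik_obs
    sd = float(d.std(ddof=1))
    if sd < 1e-12:
        return 0.0, 1.0
    z = float(np.sqrt(len(d)) * d.mean() / sd)
    return z, float(2 * stats.norm.sf(abs(z)))


class PolymethylationScore:
    """End-to-end PMS construction on a target cohort.

    Parameters
    ----------
    target_betas
        Target-cohort methylation (ideally covariate-residualized for the
        co-methylation step; raw betas are accepted).
    training_sumstats
        Meta-analysis table from the training cohorts (probe, effect, p).
    cometh_config, pms_config
        Region construction and threshold-ladder settings.
    stat
        Which pooled statistics of a meta-analysis table to train on:
        ``"fixed"`` (default; effect_fe/p_fe) or ``"random"``
        (effect_re/p_re).  The fixed-effect columns are the default because
        between-stratum heterogeneity is *expected* whenever effects are
        sex-differential, and the random-effects tau^2 penalty would then
        deweight exactly the probes a stratified training set is meant to
        contribute.  Plain single-EWAS tables (effect/p columns) work with
        either setting.
    """

    def __init__(self, target_betas: BetaMatrix, training_sumstats: pd.DataFrame,
                 cometh_config: ComethConfig | None = None,
                 pms_config: PmsConfig | None = None,
                 stat: str = "fixed"):
        if stat not in ("fixed", "random"):
            raise InputError("stat must be 'fixed' or 'random'")
        self.target_betas = target_betas
        self.training_sumstats = training_sumstats
        self.cometh_config = cometh_config or ComethConfig()
        self.pms_config = pms_config or PmsConfig()
        suffix = "fe" if stat == "fixed" else "re"
        cols = training_sumstats.columns
        self.p_col = f"p_{suffix}" if f"p_{suffix}" in cols else "p"
        self.effect_col = f"effect_{suffix}" if f"effect_{suffix}" in cols else "effect"

    def fit(self) -> "PMSResults":
        regions = build_cometh_regions(self.target_betas, self.cometh_config)
        kept = prune_regions(regions, self.training_sumstats,
                             all_probes=self.target_betas.probe_ids,
                             p_col=self.p_col)
        scores = compute_pms_matrix(self.target_betas, self.training_sumstats,
                                    kept, self.pms_config,
                                    p_col=self.p_col, effect_col=self.effect_col)
        pms, var_frac = pms_pc1(scores)
        return PMSResults(self, regions, kept, scores, pms, var_frac)


class PMSResults:
    """Scores, the PC1 summary, and an evaluation hook."""

    def __init__(self, model, regions, kept_probes, scores, pms, pc1_var_frac):
        self.model = model
        self.regions = regions
        self.kept_probes = kept_probes
        self.scores = scores
        self.pms = pms
        self.pc1_var_frac = pc1_var_frac

    def evaluate(self, status, covariates: pd.DataFrame | None = None) -> PmsEval:
        return evaluate_pms(self.pms, status, covariates, pc1_var_frac=self.pc1_var_frac)

    def summary(self) -> str:
        return "\n".join(
            [
                "Polymethylation score",
                "=" * 43,
                f"co-methylation regions: {len(self.regions)}   kept probes: {len(self.kept_probes)}",
                f"threshold columns: {list(self.scores.columns)}",
                f"PC1 variance fraction: {self.pc1_var_frac:.3f}",
            ]
        )
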