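"""Probe-wise EWAS linear models.

The workhorse is a vectorized OLS over all probes at once: the design matrix
is shared across probes within a cohort/stratum, so coefficients, residual
variances and t-statistics come from a single normal-equations solve.
Effects and SEs are reported on the x100 scale (percentage points of
methylation difference).

Optionally, residual variances can be shrunk towards a common prior by an
empirical-Bayes moderation (method-of-moments fit of a scaled
inverse-chi-square prior, i.e. the classic moderated-t construction); the
default is plain OLS.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import CELL_TYPES, BetaMatrix, validate_sample_sheet
from .exceptions import DegenerateInputError, InsufficientDataError, RankDeficientError

logger = logging.getLogger(__name__)

__all__ = [
    "EWAS",
    "EWASResults",
    "fit_probe_lm",
    "run_ewas",
    "run_interaction_ewas",
    "compute_lambda",
    "squeeze_variances",
]

SUMSTAT_COLUMNS = ["probe", "chrom", "pos", "effect", "se", "t", "df", "p", "n", "cohort", "stratum"]


# ---------------------------------------------------------------------------
# core OLS machinery
# ---------------------------------------------------------------------------

def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise RankDeficientError naming the collinear columns."""
    if X.shape[0] <= X.shape[1]:
        raise InsufficientDataError(
            f"need more samples ({X.shape[0]}) than design columns ({X.shape[1]})"
        )
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [names[i] for i in np.where(diag <= tol)[0]]
    if bad:
        raise RankDeficientError(bad)


def _ols_many(Y: np.ndarray, X: np.ndarray, coef_idx: int, names: list[str]):
    """OLS of each column of Y on the shared design X.

    Returns (effect, se, t, df) arrays for the coefficient ``coef_idx``.
    """
    _check_rank(X, names)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ (X.T @ Y)
    resid = Y - X @ B
    df = n - p
    s2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(s2, 0) * xtx_inv[coef_idx, coef_idx])
    eff = B[coef_idx]
    return eff, se, s2, df


def fit_probe_lm(y: np.ndarray, design: np.ndarray, status_col: int, names: list[str] | None = None):
    """OLS of one probe's methylation on a design; report the status term.

    Returns a dict with ``effect``/``se`` on the x100 scale, the
    t-statistic, residual degrees of freedom and the two-sided p-value from
    the t reference.
    """
    y = np.asarray(y, float).reshape(-1, 1)
    X = np.asarray(design, float)
    names = names or [f"x{i}" for i in range(X.shape[1])]
    eff, se, _, df = _ols_many(y, X, status_col, names)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = float(eff[0] / se[0]) if se[0] > 0 else np.nan
    p = float(2 * stats.t.sf(abs(t), df))
    return {
        "effect": float(eff[0]) * 100.0,
        "se": float(se[0]) * 100.0,
        "t": t,
        "df": int(df),
        "p": p,
    }


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Shrink residual variances towards a common prior.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed
    variances by matching moments of log(s2), then returns the posterior
    variances ``(d0*s0^2 + df*s2)/(d0 + df)`` together with (d0, s0^2).
    ``d0`` may be ``inf`` (complete shrinkage) when the observed spread is
    no wider than chi-square sampling noise.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        d0, s02 = np.inf, float(np.exp(e.mean()))
        post = np.full_like(s2, s02)
    else:
        d0 = 2 * _trigamma_inverse(evar)
        s02 = float(np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2)))
        post = (d0 * s02 + df * s2) / (d0 + df)
    return post, float(d0), s02


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    sheet: pd.DataFrame,
    covariates: list[str],
    include_sex: bool,
    interaction: bool = False,
) -> pd.DataFrame:
    """Assemble the per-sample design matrix as a DataFrame.

    Column order: intercept, status, [sex], [status:sex], then covariates.
    The pseudo-covariate name ``cell_props`` expands to five of the six cell
    proportions (granulocytes dropped as reference, since they sum to one);
    non-numeric covariates are dummy-coded with the first level dropped.
    """
    cols: dict[str, np.ndarray] = {"const": np.ones(len(sheet))}
    cols["status"] = (sheet["status"] == "case").to_numpy(float)
    if include_sex or interaction:
        cols["sex"] = (sheet["sex"] == "male").to_numpy(float)
    if interaction:
        cols["status:sex"] = cols["status"] * cols["sex"]
    for cov in covariates:
        if cov == "cell_props":
            for ct in CELL_TYPES:
                if ct != "Gran":
                    cols[ct] = sheet[ct].to_numpy(float)
        elif pd.api.types.is_numeric_dtype(sheet[cov]):
            cols[cov] = sheet[cov].to_numpy(float)
        else:
            dummies = pd.get_dummies(sheet[cov], prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols[name] = dummies[name].to_numpy(float)
    return pd.DataFrame(cols, index=sheet.index)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class EWAS:
    """Probe-wise association of methylation with case/control status.

    Parameters
    ----------
    betas
        BetaMatrix; sex-chromosome probes are dropped before fitting.
    sheet
        Sample sheet with ``sample_id``, ``status``, ``sex`` and covariates.
    stratum
        ``"all"`` (sex included as covariate), ``"male"`` or ``"female"``
        (sex excluded, samples restricted).
    covariates
        Sheet columns to adjust for; ``"cell_props"`` expands to the cell
        proportions.
    moderate
        If True, shrink residual variances by empirical Bayes before
        computing t/p.
    interaction
        If True, fit status + sex + status:sex and report the interaction
        term instead of the status main effect.
    """

    def __init__(
        self,
        betas: BetaMatrix,
        sheet: pd.DataFrame,
        stratum: str = "all",
        covariates: list[str] | None = None,
        moderate: bool = False,
        interaction: bool = False,
        cohort: str | None = None,
    ):
        if stratum not in ("all", "male", "female"):
            raise DegenerateInputError(f"unknown stratum {stratum!r}")
        if interaction and stratum != "all":
            raise DegenerateInputError("interaction model requires both sexes (stratum='all')")
        validate_sample_sheet(sheet)
        sheet = sheet.set_index("sample_id").loc[betas.sample_ids]
        sheet.index.name = "sample_id"
        sheet = sheet.reset_index()
        if stratum != "all":
            keep = sheet["sex"] == stratum
            sheet = sheet.loc[keep.to_numpy()].reset_index(drop=True)
            betas = betas.subset_samples(sheet["sample_id"])

        self.covariates = list(covariates or [])
        # listwise deletion on missing covariate values
        design = build_design(sheet, self.covariates, include_sex=(stratum == "all" and not interaction), interaction=interaction)
        complete = ~design.isna().any(axis=1)
        if not complete.all():
            logger.info("dropping %d samples with missing covariates", (~complete).sum())
            sheet = sheet.loc[complete.to_numpy()].reset_index(drop=True)
            betas = betas.subset_samples(sheet["sample_id"])
            design = design.loc[complete.to_numpy()].reset_index(drop=True)

        if interaction:
            for col, lab in (("sex", "sexes"), ("status", "statuses")):
                if sheet[col].nunique() < 2:
                    raise InsufficientDataError(f"interaction model requires both {lab}")
        counts = sheet.groupby(["status"]).size()
        if len(counts) < 2 or counts.min() < 3:
            raise InsufficientDataError(
                f"stratum {stratum!r} needs >=3 samples per status group, got {counts.to_dict()}"
            )

        self.betas = betas.autosomal()
        self.sheet = sheet
        self.design = design
        self.stratum = stratum
        self.moderate = moderate
        self.interaction = interaction
        self.cohort = cohort or (sheet["cohort"].iloc[0] if "cohort" in sheet else "NA")
        self.term = "status:sex" if interaction else "status"

    @property
    def exog_names(self) -> list[str]:
        return list(self.design.columns)

    def fit(self) -> "EWASResults":
        X = self.design.to_numpy(float)
        Y = self.betas.values.to_numpy(float).T  # samples x probes
        eff, se, s2, df = _ols_many(Y, X, self.exog_names.index(self.term), self.exog_names)
        df_total = float(df)
        if self.moderate:
            xtx_inv = np.linalg.inv(X.T @ X)
            c = xtx_inv[self.exog_names.index(self.term), self.exog_names.index(self.term)]
            s2_post, d0, _ = squeeze_variances(s2, df)
            se = np.sqrt(s2_post * c)
            df_total = df + d0 if np.isfinite(d0) else 1e6
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, eff / se, np.nan)
        p = 2 * stats.t.sf(np.abs(t), df_total)
        table = pd.DataFrame(
            {
                "probe": self.betas.probe_ids,
                "chrom": self.betas.annot["chrom"].to_numpy(),
                "pos": self.betas.annot["pos"].to_numpy(),
                "effect": eff * 100.0,
                "se": se * 100.0,
                "t": t,
                "df": df_total,
                "p": np.clip(p, np.finfo(float).tiny, 1.0),
                "n": X.shape[0],
                "cohort": self.cohort,
                "stratum": "interaction" if self.interaction else self.stratum,
            }
        ).reset_index(drop=True)
        return EWASResults(self, table)


class EWASResults:
    """Result table plus diagnostics for one probe-wise EWAS fit."""

    def __init__(self, model: EWAS, table: pd.DataFrame):
        self.model = model
        self.table = table

    def genomic_lambda(self) -> float:
        return compute_lambda(self.table["p"].to_numpy())

    def summary(self) -> str:
        t = self.table
        lines = [
            "Probe-wise EWAS results",
            "=" * 47,
            f"cohort: {self.model.cohort}   stratum: {t['stratum'].iloc[0]}",
            f"probes: {len(t)}   samples: {t['n'].iloc[0]}",
            f"covariates: {', '.join(self.model.covariates) or '(none)'}",
            f"moderated t: {self.model.moderate}",
            f"genomic inflation lambda: {self.genomic_lambda():.3f}",
            f"min p: {t['p'].min():.3e}  (probe {t.loc[t['p'].idxmin(), 'probe']})",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional entry points
# ---------------------------------------------------------------------------

def run_ewas(
    betas: BetaMatrix,
    sheet: pd.DataFrame,
    stratum: str = "all",
    covariates: list[str] | None = None,
    moderate: bool = False,
    cohort: str | None = None,
) -> pd.DataFrame:
    """Fit the probe-wise EWAS and return the summary-statistics table."""
    return EWAS(betas, sheet, stratum, covariates, moderate, cohort=cohort).fit().table


def run_interaction_ewas(
    betas: BetaMatrix,
    sheet: pd.DataFrame,
    covariates: list[str] | None = None,
    moderate: bool = False,
    cohort: str | None = None,
) -> pd.DataFrame:
    """Probe-wise status x sex interaction EWAS; effect = interaction term."""
    return EWAS(
        betas, sheet, "all", covariates, moderate, interaction=True, cohort=cohort
    ).fit().table


def compute_lambda(p: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square over its null
    median (chi-square with 1 df, approximately 0.4549)."""
    p = np.asarray(p, float)
    if p.size == 0:
        raise DegenerateInputError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DegenerateInputError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
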