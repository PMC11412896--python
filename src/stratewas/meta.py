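"""Inverse-variance meta-analysis across cohorts and sex strata.

Fixed-effect pooling weights each cohort estimate by its inverse squared
standard error; the random-effects model adds the DerSimonian-Laird moment
estimate of between-study variance tau^2 to every weight.  Four modes mirror
the study designs being compared:

* ``sex_adjusted``  - one whole-cohort table per cohort,
* ``male_only`` / ``female_only`` - one per-sex table per cohort,
* ``sex_stratified`` - both sex strata of every cohort enter as separate
  studies (8 tables for 4 cohorts), with the larger study count absorbed by
  the per-probe degrees of freedom ``k``.

Probes are pooled when present in at least ``min_cohorts`` input tables;
two-sided p-values use the normal reference.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import MetaConfig
from .exceptions import ConfigurationError, InputError

__all__ = [
    "meta_fixed",
    "meta_random",
    "MetaAnalysis",
    "MetaResults",
    "run_meta",
    "meta_interaction",
]

META_COLUMNS = [
    "probe", "chrom", "pos", "k",
    "effect_fe", "se_fe", "p_fe",
    "effect_re", "se_re", "p_re",
    "q_stat", "tau2", "i2",
]


def _validate_estimates(effects, ses):
    effects = np.asarray(effects, float)
    ses = np.asarray(ses, float)
    if effects.size < 2:
        raise InputError("meta-analysis needs at least two estimates")
    if np.any(~np.isfinite(effects)) or np.any(~np.isfinite(ses)):
        raise InputError("estimates must be finite")
    if np.any(ses <= 0):
        raise InputError("all standard errors must be > 0")
    return effects, ses


def meta_fixed(estimates) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance pooling of (effect, se) pairs.

    Returns (pooled effect, pooled SE, two-sided p).
    """
    effects, ses = _validate_estimates(*zip(*estimates))
    w = 1.0 / ses**2
    pooled = float(np.sum(w * effects) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2 * stats.norm.sf(abs(pooled / se)))
    return pooled, se, p


def meta_random(estimates) -> tuple[float, float, float, float, float, float]:
    """DerSimonian-Laird random-effects pooling.

    Returns (pooled effect, SE, p, Cochran's Q, tau^2, I^2).
    """
    effects, ses = _validate_estimates(*zip(*estimates))
    k = effects.size
    w = 1.0 / ses**2
    e_fe = np.sum(w * effects) / np.sum(w)
    q = float(np.sum(w * (effects - e_fe) ** 2))
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    pooled = float(np.sum(w_star * effects) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    p = float(2 * stats.norm.sf(abs(pooled / se)))
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return pooled, se, p, q, tau2, i2


# required number of input tables per mode (paper design: 4 cohorts)
_MIN_TABLES = {"sex_adjusted": 2, "male_only": 2, "female_only": 2, "sex_stratified": 4}


class MetaAnalysis:
    """Per-probe meta-analysis of bacon-corrected summary statistics.

    ``tables`` is a list of per-cohort(-stratum) summary-statistics frames;
    corrected columns (``effect_bc``/``se_bc``) are used when present,
    otherwise the raw ``effect``/``se``.
    """

    def __init__(self, tables, config: MetaConfig | None = None, **kwargs):
        self.config = config or MetaConfig(**kwargs)
        tables = list(tables)
        need = _MIN_TABLES[self.config.mode]
        if len(tables) < need:
            raise ConfigurationError(
                f"mode {self.config.mode!r} requires >= {need} input tables, got {len(tables)}"
            )
        if self.config.mode == "sex_stratified" and len(tables) % 2:
            raise ConfigurationError(
                "sex_stratified mode expects an even number of per-sex tables"
            )
        self.tables = tables

    def fit(self) -> "MetaResults":
        frames = []
        for i, t in enumerate(self.tables):
            eff_col = "effect_bc" if "effect_bc" in t.columns else "effect"
            se_col = "se_bc" if "se_bc" in t.columns else "se"
            f = pd.DataFrame(
                {
                    "probe": t["probe"].to_numpy(),
                    "effect": t[eff_col].to_numpy(float),
                    "se": t[se_col].to_numpy(float),
                }
            )
            for c in ("chrom", "pos"):
                if c in t.columns:
                    f[c] = t[c].to_numpy()
            frames.append(f)
        df = pd.concat(frames, ignore_index=True)
        if (df["se"] <= 0).any():
            raise InputError("all standard errors must be > 0")

        g = df.groupby("probe", sort=True)
        k = g.size()
        keep = k[k >= self.config.min_cohorts].index
        df = df[df["probe"].isin(keep)]
        if df.empty:
            table = pd.DataFrame(columns=META_COLUMNS)
            return MetaResults(self, table)

        w = 1.0 / df["se"].to_numpy(float) ** 2
        df = df.assign(w=w, we=w * df["effect"].to_numpy(float), w2=w**2)
        g = df.groupby("probe", sort=True)
        sums = g[["w", "we", "w2"]].sum()
        kk = g.size()
        e_fe = sums["we"] / sums["w"]
        se_fe = 1.0 / np.sqrt(sums["w"])

        dev = (df["effect"].to_numpy(float) - df["probe"].map(e_fe).to_numpy(float)) ** 2
        q = pd.Series(df["w"].to_numpy(float) * dev, index=df.index).groupby(df["probe"]).sum()
        q = q.reindex(e_fe.index)
        c = sums["w"] - sums["w2"] / sums["w"]
        tau2 = ((q - (kk - 1)) / c).clip(lower=0.0).where(c > 0, 0.0)

        wstar = 1.0 / (df["se"].to_numpy(float) ** 2 + df["probe"].map(tau2).to_numpy(float))
        df2 = df.assign(ws=wstar, wse=wstar * df["effect"].to_numpy(float))
        sums2 = df2.groupby("probe", sort=True)[["ws", "wse"]].sum()
        e_re = sums2["wse"] / sums2["ws"]
        se_re = 1.0 / np.sqrt(sums2["ws"])

        with np.errstate(divide="ignore", invalid="ignore"):
            i2 = ((q - (kk - 1)) / q).clip(lower=0.0).where(q > 0, 0.0)

        table = pd.DataFrame(
            {
                "probe": e_fe.index,
                "k": kk.to_numpy(int),
                "effect_fe": e_fe.to_numpy(float),
                "se_fe": se_fe.to_numpy(float),
                "p_fe": 2 * stats.norm.sf(np.abs(e_fe / se_fe)),
                "effect_re": e_re.to_numpy(float),
                "se_re": se_re.to_numpy(float),
                "p_re": 2 * stats.norm.sf(np.abs(e_re / se_re)),
                "q_stat": q.to_numpy(float),
                "tau2": tau2.to_numpy(float),
                "i2": i2.to_numpy(float),
            }
        ).reset_index(drop=True)
        # carry genomic coordinates (first occurrence per probe) when present
        if "chrom" in df.columns:
            coords = df.dropna(subset=["chrom"]).drop_duplicates("probe").set_index("probe")
            table.insert(1, "chrom", table["probe"].map(coords["chrom"]))
            table.insert(2, "pos", table["probe"].map(coords["pos"]))
        for thr in self.config.thresholds:
            table[f"sig_p{thr:g}"] = table["p_re"] < thr
        return MetaResults(self, table)


class MetaResults:
    """Per-probe pooled estimates with heterogeneity diagnostics."""

    def __init__(self, model: MetaAnalysis, table: pd.DataFrame):
        self.model = model
        self.table = table

    def significant(self, threshold: float | None = None, which: str = "p_re") -> pd.DataFrame:
        thr = threshold if threshold is not None else self.model.config.thresholds[0]
        return self.table[self.table[which] < thr]

    def summary(self) -> str:
        cfg = self.model.config
        t = self.table
        lines = [
            "Inverse-variance meta-analysis",
            "=" * 43,
            f"mode: {cfg.mode}   input tables: {len(self.model.tables)}",
            f"probes pooled (k >= {cfg.min_cohorts}): {len(t)}",
        ]
        for thr in cfg.thresholds:
            lines.append(f"random-effects p < {thr:g}: {int((t['p_re'] < thr).sum())} probes")
        if len(t):
            lines.append(f"median tau^2: {t['tau2'].median():.4g}   median I^2: {t['i2'].median():.3f}")
        return "\n".join(lines)


def run_meta(tables, config: MetaConfig | None = None, **kwargs) -> pd.DataFrame:
    """Pool per-cohort(-stratum) summary statistics; return the meta table."""
    return MetaAnalysis(tables, config, **kwargs).fit().table


def meta_interaction(tables, config: MetaConfig | None = None, **kwargs) -> pd.DataFrame:
    """Meta-analyze sex x status interaction summary statistics.

    Same contracts as :func:`run_meta`; the input tables carry interaction
    effects/SEs instead of status main effects.
    """
    if config is None and "mode" not in kwargs:
        kwargs["mode"] = "sex_adjusted"  # interaction tables are whole-cohort
    return MetaAnalysis(tables, config, **kwargs).fit().table
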