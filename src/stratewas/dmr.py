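"""Region-level discovery by autocorrelation-corrected p-value combination.

The comb-p-style chain: (1) estimate the autocorrelation of per-probe
z-scores as a function of genomic distance, in fixed-width bins up to the
maximum gap; (2) smooth each probe's p-value by a Stouffer-Liptak-Kechris
combination over its neighbourhood, using the ACF for the pairwise
covariances; (3) collect maximal runs of smoothed p below the seed
threshold with inter-probe gaps no larger than the maximum distance;
(4) score each run by a Stouffer-Liptak combination of the *raw* p-values
and apply a Sidak correction whose effective test count is the total base
span tested divided by the region width.

Everything here is deterministic: no randomness enters at any step.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import DmrConfig
from .exceptions import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "DmrRecord",
    "estimate_acf",
    "slk_smooth",
    "find_regions",
    "score_region",
    "call_dmrs",
    "CombP",
    "DmrResults",
]


@dataclass
class DmrRecord:
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    n_probes: int
    p_region: float
    p_sidak: float
    probe_ids: list = field(default_factory=list)


def signed_z(p: np.ndarray, effect: np.ndarray | None = None) -> np.ndarray:
    """Two-sided-consistent signed z-scores.

    ``z = Phi^-1(1 - p/2) * sign(effect)``; probes without an effect sign
    use the one-sided transform ``Phi^-1(1 - p)``.
    """
    p = np.clip(np.asarray(p, float), 1e-300, 1.0)
    if effect is None:
        return stats.norm.isf(p)
    sign = np.sign(np.asarray(effect, float))
    sign[sign == 0] = 1.0
    return stats.norm.isf(p / 2) * sign


def _check_sorted(chrom: np.ndarray, pos: np.ndarray) -> None:
    for c in pd.unique(chrom):
        pp = pos[chrom == c]
        if np.any(np.diff(pp) < 0):
            raise DegenerateInputError("probes must be sorted by (chrom, pos)")


def estimate_acf(z: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                 config: DmrConfig | None = None) -> pd.DataFrame:
    """Distance-binned autocorrelation of z-scores.

    Returns a frame with ``bin_lo``/``bin_hi`` (bp, half-open (lo, hi]),
    ``corr`` and ``n_pairs``.  Correlations are clipped to [0, 1) and made
    non-increasing in distance by pair-count-weighted isotonic pooling.
    """
    config = config or DmrConfig()
    z = np.asarray(z, float)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, int)
    _check_sorted(chrom, pos)

    nbins = int(np.ceil(config.max_gap_bp / config.acf_bin_bp))
    # accumulate per-bin sufficient statistics over pairs (i, i+k), walking
    # the lag offset k outward until every pair exceeds the maximum gap
    sa = np.zeros(nbins); sb = np.zeros(nbins); sab = np.zeros(nbins)
    saa = np.zeros(nbins); sbb = np.zeros(nbins)
    npairs = np.zeros(nbins, dtype=int)
    for c in pd.unique(chrom):
        idx = np.where(chrom == c)[0]
        pp = pos[idx]
        zz = z[idx]
        for k in range(1, len(idx)):
            d = pp[k:] - pp[:-k]
            keep = d <= config.max_gap_bp
            if not keep.any():
                break
            b = np.minimum((np.maximum(d[keep], 1) - 1) // config.acf_bin_bp, nbins - 1)
            a_, b_ = zz[:-k][keep], zz[k:][keep]
            sa += np.bincount(b, a_, minlength=nbins)
            sb += np.bincount(b, b_, minlength=nbins)
            sab += np.bincount(b, a_ * b_, minlength=nbins)
            saa += np.bincount(b, a_ * a_, minlength=nbins)
            sbb += np.bincount(b, b_ * b_, minlength=nbins)
            npairs += np.bincount(b, minlength=nbins)
    corr = np.zeros(nbins)
    with np.errstate(divide="ignore", invalid="ignore"):
        nn = npairs.astype(float)
        cov = sab - sa * sb / np.where(nn > 0, nn, 1)
        va = saa - sa**2 / np.where(nn > 0, nn, 1)
        vb = sbb - sb**2 / np.where(nn > 0, nn, 1)
        ok = (npairs >= 2) & (va > 0) & (vb > 0)
        corr[ok] = cov[ok] / np.sqrt(va[ok] * vb[ok])
    if not npairs.any():
        logger.warning("no probe pairs within %d bp in any bin; using flat-zero ACF", config.max_gap_bp)
    corr = np.clip(corr, 0.0, 1.0 - 1e-12)
    corr = _isotonic_nonincreasing(corr, npairs)
    lo = np.arange(nbins) * config.acf_bin_bp
    hi = np.minimum(lo + config.acf_bin_bp, config.max_gap_bp)
    return pd.DataFrame({"bin_lo": lo, "bin_hi": hi, "corr": corr, "n_pairs": npairs})


def _isotonic_nonincreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators fit, non-increasing in index."""
    # fit non-decreasing on the reversed sequence
    yv = y[::-1].astype(float)
    wv = w[::-1].astype(float)
    vals, wts, cnts = [], [], []
    for yi, wi in zip(yv, wv):
        vals.append(yi); wts.append(wi); cnts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            wtot = wts[-2] + wts[-1]
            if wtot > 0:
                v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / wtot
            else:  # zero-weight (empty) bins carry no information
                v = 0.5 * (vals[-2] + vals[-1])
            wts[-2] = wtot; cnts[-2] += cnts[-1]
            vals[-2] = v
            vals.pop(); wts.pop(); cnts.pop()
    out = np.repeat(vals, cnts)
    return out[::-1]


def _acf_lookup(acf: pd.DataFrame, dist: int) -> float:
    """Covariance (correlation of standard-normal z) at a pairwise distance."""
    hi = acf["bin_hi"].to_numpy()
    if dist <= 0:
        return float(acf["corr"].iloc[0]) if len(acf) else 0.0
    idx = np.searchsorted(hi, dist, side="left")
    if idx >= len(acf):
        return 0.0
    return float(acf["corr"].iloc[idx])


def _combine(z: np.ndarray, pos: np.ndarray, acf: pd.DataFrame) -> float:
    """Stouffer-Liptak combined z for one window of signed z-scores."""
    m = len(z)
    cov = 0.0
    for a in range(m):
        for b in range(a + 1, m):
            cov += _acf_lookup(acf, int(abs(pos[b] - pos[a])))
    denom = m + 2.0 * cov
    return float(z.sum() / np.sqrt(denom))


def slk_smooth(p: np.ndarray, chrom: np.ndarray, pos: np.ndarray, acf: pd.DataFrame,
               config: DmrConfig | None = None,
               effect: np.ndarray | None = None) -> np.ndarray:
    """Smooth per-probe p-values over their genomic neighbourhood.

    Each probe's smoothed p is the two-sided p of the Stouffer-Liptak
    combined z over all probes within ``max_gap_bp`` on the same chromosome
    (including itself).  A probe with no neighbours keeps its input p.
    """
    config = config or DmrConfig()
    p = np.asarray(p, float)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, int)
    _check_sorted(chrom, pos)
    z = signed_z(p, effect)
    # ACF value per distance bin, for vectorized lookup
    nbins = len(acf)
    acf_hi = acf["bin_hi"].to_numpy()
    acf_corr = acf["corr"].to_numpy()

    def sigma_of(dist: np.ndarray) -> np.ndarray:
        bi = np.searchsorted(acf_hi, dist, side="left")
        out = np.zeros(dist.shape)
        ok = bi < nbins
        out[ok] = acf_corr[bi[ok]]
        return out

    out = np.empty_like(p)
    for c in pd.unique(chrom):
        idx = np.where(chrom == c)[0]
        pp = pos[idx]
        zz = z[idx]
        m = len(idx)
        left = np.searchsorted(pp, pp - config.max_gap_bp, side="left")
        right = np.searchsorted(pp, pp + config.max_gap_bp, side="right")
        czz = np.concatenate([[0.0], np.cumsum(zz)])
        num = czz[right] - czz[left]  # window z sums
        count = (right - left).astype(float)
        # pair-covariance sums per window: each pair (i, i+k) within the gap
        # contributes sigma(d) to every probe whose window spans the pair;
        # those probes form a contiguous index range, handled by a
        # difference array
        covsum = np.zeros(m + 1)
        for k in range(1, m):
            d = pp[k:] - pp[:-k]
            keep = d <= config.max_gap_bp
            if not keep.any():
                break
            sig = sigma_of(d[keep])
            nz = sig > 0
            if not nz.any():
                continue
            i_lo = np.where(keep)[0][nz]       # pair is (i_lo, i_lo + k)
            lo = np.searchsorted(pp, pp[i_lo + k] - config.max_gap_bp, side="left")
            hi = np.searchsorted(pp, pp[i_lo] + config.max_gap_bp, side="right")
            s = sig[nz]
            np.add.at(covsum, lo, s)
            np.add.at(covsum, hi, -s)
        pair_cov = np.cumsum(covsum[:-1])
        denom = count + 2.0 * pair_cov
        zc = num / np.sqrt(denom)
        pv = 2 * stats.norm.sf(np.abs(zc))
        single = count == 1
        pv[single] = p[idx][single]
        out[idx] = pv
    return np.clip(out, np.finfo(float).tiny, 1.0)


def find_regions(smoothed_p: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                 config: DmrConfig | None = None) -> list[np.ndarray]:
    """Maximal runs of probes with smoothed p below the seed threshold.

    Consecutive probes must be at most ``max_gap_bp`` apart and on the same
    chromosome; runs shorter than ``min_probes`` are discarded.  Returns
    index arrays into the input ordering.
    """
    config = config or DmrConfig()
    smoothed_p = np.asarray(smoothed_p, float)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, int)
    _check_sorted(chrom, pos)
    regions: list[np.ndarray] = []
    current: list[int] = []
    for i in range(len(smoothed_p)):
        seed = smoothed_p[i] < config.seed_p
        if seed and current:
            same = chrom[i] == chrom[current[-1]]
            close = pos[i] - pos[current[-1]] <= config.max_gap_bp
            if same and close:
                current.append(i)
                continue
        if current and len(current) >= config.min_probes:
            regions.append(np.asarray(current))
        current = [i] if seed else []
    if current and len(current) >= config.min_probes:
        regions.append(np.asarray(current))
    return regions


def score_region(region_idx: np.ndarray, p: np.ndarray, pos: np.ndarray,
                 acf: pd.DataFrame, total_tested_bases: int,
                 effect: np.ndarray | None = None) -> tuple[float, float]:
    """Region p by Stouffer-Liptak over raw p-values, plus Sidak correction.

    The Sidak-effective test count is ``total_tested_bases / region_bases``
    (floored at 1), i.e. how many non-overlapping windows of the region's
    width fit in the tested span.
    """
    region_idx = np.asarray(region_idx, int)
    pos_r = np.asarray(pos, int)[region_idx]
    region_bases = int(pos_r.max() - pos_r.min() + 1)
    if region_bases <= 0:
        raise DegenerateInputError("degenerate region with zero base span")
    z = signed_z(np.asarray(p, float)[region_idx],
                 None if effect is None else np.asarray(effect, float)[region_idx])
    zc = _combine(z, pos_r, acf)
    p_region = float(2 * stats.norm.sf(abs(zc)))
    return p_region, sidak_correct(p_region, total_tested_bases, region_bases)


def sidak_correct(p_region: float, total_tested_bases: int, region_bases: int) -> float:
    """Sidak family-wise correction 1 - (1 - p)^(span ratio)."""
    if region_bases <= 0:
        raise DegenerateInputError("region_bases must be > 0")
    ratio = max(total_tested_bases / region_bases, 1.0)
    if p_region <= 0:
        return 0.0
    return float(-np.expm1(ratio * np.log1p(-min(p_region, 1.0 - 1e-16))))


class CombP:
    """Region caller over a per-probe meta-analysis table.

    ``meta`` must contain ``probe``, ``chrom``, ``pos`` and a p-value column
    (``p_re`` by default, falling back to ``p``); the signed effect column
    (``effect_re``/``effect``) orients the z-scores so only directionally
    consistent neighbourhoods combine strongly.
    """

    def __init__(self, meta: pd.DataFrame, config: DmrConfig | None = None, **kwargs):
        self.config = config or DmrConfig(**kwargs)
        p_col = "p_re" if "p_re" in meta.columns else "p"
        e_col = "effect_re" if "effect_re" in meta.columns else ("effect" if "effect" in meta.columns else None)
        df = meta.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.meta = df
        self.p = df[p_col].to_numpy(float)
        self.effect = df[e_col].to_numpy(float) if e_col else None
        self.chrom = df["chrom"].to_numpy()
        self.pos = df["pos"].to_numpy(int)

    def fit(self) -> "DmrResults":
        cfg = self.config
        acf = estimate_acf(signed_z(self.p, self.effect), self.chrom, self.pos, cfg)
        smoothed = slk_smooth(self.p, self.chrom, self.pos, acf, cfg, effect=self.effect)
        regions = find_regions(smoothed, self.chrom, self.pos, cfg)
        total = 0
        for c in pd.unique(self.chrom):
            pp = self.pos[self.chrom == c]
            total += int(pp.max() - pp.min() + 1)
        records = []
        for idx in regions:
            p_region, p_sidak = score_region(idx, self.p, self.pos, acf, total, self.effect)
            if p_sidak < cfg.sidak_alpha and len(idx) >= cfg.min_probes:
                records.append(
                    DmrRecord(
                        chrom=str(self.chrom[idx[0]]),
                        start_bp=int(self.pos[idx].min()),
                        end_bp=int(self.pos[idx].max()),
                        n_probes=len(idx),
                        p_region=p_region,
                        p_sidak=p_sidak,
                        probe_ids=list(self.meta["probe"].iloc[idx]),
                    )
                )
        records.sort(key=lambda r: (r.chrom, r.start_bp))
        return DmrResults(self, records, acf=acf, smoothed_p=smoothed)


class DmrResults:
    """Called regions plus the intermediate ACF/smoothing artifacts."""

    def __init__(self, model: CombP, records: list[DmrRecord], acf=None, smoothed_p=None):
        self.model = model
        self.records = records
        self.acf = acf
        self.smoothed_p = smoothed_p

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start_bp": r.start_bp,
                    "end_bp": r.end_bp,
                    "n_probes": r.n_probes,
                    "p_region": r.p_region,
                    "p_sidak": r.p_sidak,
                    "probe_ids": ";".join(map(str, r.probe_ids)),
                }
                for r in self.records
            ],
            columns=["chrom", "start_bp", "end_bp", "n_probes", "p_region", "p_sidak", "probe_ids"],
        )

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Differentially methylated regions",
            "=" * 43,
            f"seed p: {cfg.seed_p:g}   max gap: {cfg.max_gap_bp} bp   min probes: {cfg.min_probes}",
            f"regions at Sidak p < {cfg.sidak_alpha:g}: {len(self.records)}",
        ]
        for r in self.records[:10]:
            lines.append(
                f"  {r.chrom}:{r.start_bp}-{r.end_bp}  {r.n_probes} probes  "
                f"p={r.p_region:.3e}  sidak={r.p_sidak:.3e}"
            )
        return "\n".join(lines)


def call_dmrs(meta: pd.DataFrame, config: DmrConfig | None = None, **kwargs) -> pd.DataFrame:
    """Full region-calling chain on a meta table; returns the DMR table."""
    return CombP(meta, config, **kwargs).fit().table
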