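"""Synthetic data generation.

Two generators:

* :func:`simulate_phenotype_study` reproduces the sex-differential power
  simulation: standard-normal "methylation" measurements, a sparse causal
  set shared between the sexes with sex-specific effect-size distributions,
  and a Gaussian phenotype whose non-methylation noise is calibrated to
  explain a stated fraction of total variance.

* :func:`simulate_cohort` emits a realistic case/control methylation cohort
  (logit-normal beta values with block-correlated probes, confounded
  covariates, a full sample sheet) for end-to-end pipeline tests.

All randomness flows from the explicit ``seed`` in the config through one
:class:`numpy.random.Generator`; nothing touches global RNG state.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortConfig, SimScenario
from .containers import CELL_TYPES, BetaMatrix
from .exceptions import ConfigurationError

__all__ = [
    "SimulatedStudy",
    "simulate_phenotype_study",
    "simulate_cohort",
    "inject_dmr",
]


@dataclass
class SimulatedStudy:
    """Output of the phenotype simulation.

    ``methylation`` is individuals x CpGs; ``true_effects_male`` /
    ``true_effects_female`` hold the per-sex causal effect sizes (zero off
    the causal set); ``sex`` is 1 for male, 0 for female.
    """

    methylation: np.ndarray
    phenotype: np.ndarray
    sex: np.ndarray
    true_effects_male: np.ndarray
    true_effects_female: np.ndarray
    causal_index: np.ndarray
    noise_var_frac: float  # realized Var(noise)/Var(phenotype)

    @property
    def n_individuals(self) -> int:
        return self.methylation.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.methylation.shape[1]


def _effect_sd(mean: float, override: float | None) -> float:
    # default: half the mean, keeping nearly all draws same-signed
    return abs(mean) / 2 if override is None else override


def simulate_phenotype_study(scenario: SimScenario) -> SimulatedStudy:
    """Simulate one replicate of the sex-differential phenotype study.

    The phenotype of individual *i* is ``sum_j beta_j(sex_i) m_ij + eps_i``
    where the causal set is identical in both sexes, per-sex effect sizes
    are drawn from normal distributions with the scenario means (SD = half
    the mean unless overridden), and ``eps`` is calibrated per replicate so
    that noise explains ``nonmeth_var_frac`` of total phenotypic variance in
    expectation.
    """
    if not isinstance(scenario, SimScenario):
        raise ConfigurationError("scenario must be a SimScenario")
    rng = np.random.default_rng(scenario.seed)
    n, p = scenario.n_individuals, scenario.n_cpgs

    n_male = int(round(scenario.frac_male * n))
    sex = np.zeros(n, dtype=int)
    sex[:n_male] = 1
    rng.shuffle(sex)

    meth = rng.standard_normal((n, p))

    causal = np.sort(rng.choice(p, size=scenario.n_causal, replace=False))
    eff_m = np.zeros(p)
    eff_f = np.zeros(p)
    eff_m[causal] = rng.normal(
        scenario.mean_effect_male,
        _effect_sd(scenario.mean_effect_male, scenario.effect_sd),
        size=len(causal),
    )
    eff_f[causal] = rng.normal(
        scenario.mean_effect_female,
        _effect_sd(scenario.mean_effect_female, scenario.effect_sd),
        size=len(causal),
    )

    genetic = np.where(sex == 1, meth @ eff_m, meth @ eff_f)
    # noise is calibrated within each sex so that non-methylation factors
    # explain the stated fraction of that sex's phenotypic variance (and
    # hence the same fraction of the total); a single pooled calibration
    # would leave the larger-effect sex with proportionally noisier
    # phenotypes than its own signal warrants
    f = scenario.nonmeth_var_frac
    eps = np.empty(n)
    for s in (0, 1):
        mask = sex == s
        if not mask.any():
            continue
        var_g = float(np.var(genetic[mask]))
        noise_sd = np.sqrt(f / (1 - f) * var_g) if var_g > 0 else 1.0
        eps[mask] = rng.normal(0.0, noise_sd, size=int(mask.sum()))
    pheno = genetic + eps

    tot = float(np.var(pheno))
    return SimulatedStudy(
        methylation=meth,
        phenotype=pheno,
        sex=sex,
        true_effects_male=eff_m,
        true_effects_female=eff_f,
        causal_index=causal,
        noise_var_frac=float(np.var(eps) / tot) if tot > 0 else 1.0,
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

_logit = lambda x: np.log(x / (1 - x))  # noqa: E731
_expit = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731


def _assign_counts(n: int, frac: float) -> int:
    """Deterministic male count: round(frac * n)."""
    return int(round(frac * n))


def _sample_sheet(config: CohortConfig, rng: np.random.Generator, cohort: str) -> pd.DataFrame:
    n = config.n_cases + config.n_controls
    status = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    sex = np.empty(n, dtype=object)
    m_cases = _assign_counts(config.n_cases, config.frac_male_cases)
    m_ctrls = _assign_counts(config.n_controls, config.frac_male_controls)
    sex[: config.n_cases] = ["male"] * m_cases + ["female"] * (config.n_cases - m_cases)
    sex[config.n_cases :] = ["male"] * m_ctrls + ["female"] * (config.n_controls - m_ctrls)

    is_case = status == "case"
    # age and smoking-score distributions follow the pooled cohort profile:
    # cases older and heavier smokers than controls
    age = np.where(is_case, rng.normal(41.6, 14.2, n), rng.normal(36.7, 12.4, n))
    age = np.clip(age, 18, 90)
    smoking = np.where(is_case, rng.normal(4.0, 7.8, n), rng.normal(-1.4, 5.5, n))

    # blood cell-type mixture centered on typical whole-blood composition
    base = np.array([0.078, 0.53, 0.062, 0.183, 0.083, 0.057])
    props = rng.dirichlet(base * 200, size=n)
    batch = rng.integers(0, 2, size=n)

    sheet = pd.DataFrame(
        {
            "sample_id": [f"{cohort}_s{i:05d}" for i in range(n)],
            "cohort": cohort,
            "status": status,
            "sex": sex,
            "age": age,
            "smoking_score": smoking,
            **{ct: props[:, i] for i, ct in enumerate(CELL_TYPES)},
            "batch": np.char.add("b", batch.astype(str)),
        }
    )
    return sheet


def simulate_cohort(
    config: CohortConfig,
    cohort: str = "SYN",
    causal_index: np.ndarray | None = None,
    effects_male: np.ndarray | None = None,
    effects_female: np.ndarray | None = None,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Generate one case/control methylation cohort.

    Beta values are built on the logit scale: per-probe baseline + a
    block-correlated Gaussian noise field (blocks of ``block_size``
    consecutive probes with correlation ``block_rho``) + case-only
    status x sex effects at the causal probes + covariate shifts, then
    mapped through the inverse logit so every value lies in (0, 1).

    Causal effects are stated on the x100 beta scale; they are converted to
    logit shifts via the local derivative of the logistic curve so that the
    induced case-control beta difference matches the nominal effect.

    ``causal_index``/``effects_male``/``effects_female`` may be supplied to
    share one causal architecture across several cohorts (multi-cohort
    meta-analysis and train/target transfer fixtures); when omitted they
    are drawn from the config.
    """
    if config.n_probes < config.block_size:
        raise ConfigurationError("n_probes must be >= block_size")
    rng = np.random.default_rng(config.seed)
    sheet = _sample_sheet(config, rng, cohort)
    n = len(sheet)
    p = config.n_probes

    baseline = rng.uniform(-1.5, 1.5, size=p)  # logit-scale probe means

    # block-correlated noise: shared factor per block per sample
    n_blocks = int(np.ceil(p / config.block_size))
    block_of = np.repeat(np.arange(n_blocks), config.block_size)[:p]
    shared = rng.standard_normal((n_blocks, n))[block_of]  # p x n
    indiv = rng.standard_normal((p, n))
    rho = config.block_rho
    noise = config.noise_sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * indiv)

    logits = baseline[:, None] + noise

    # covariate shifts (confounding): standardized covariate value scales a
    # uniform logit shift across all probes
    for cov, coef in config.covariate_effects.items():
        val = pd.to_numeric(sheet[cov], errors="coerce").to_numpy(float)
        z = (val - np.nanmean(val)) / (np.nanstd(val) or 1.0)
        logits += coef * z[None, :]

    # status x sex causal effects
    if causal_index is not None:
        causal = np.sort(np.asarray(causal_index, int))
        if len(causal) and (causal[0] < 0 or causal[-1] >= p):
            raise ConfigurationError("causal_index out of range")
    elif config.n_causal:
        causal = np.sort(rng.choice(p, size=config.n_causal, replace=False))
    else:
        causal = np.array([], dtype=int)
    if len(causal):
        if effects_male is not None:
            eff_m = np.asarray(effects_male, float)
        else:
            eff_m = rng.normal(
                config.effect_mean_male, _effect_sd(config.effect_mean_male, config.effect_sd), len(causal)
            )
        if effects_female is not None:
            eff_f = np.asarray(effects_female, float)
        else:
            eff_f = rng.normal(
                config.effect_mean_female, _effect_sd(config.effect_mean_female, config.effect_sd), len(causal)
            )
        if len(eff_m) != len(causal) or len(eff_f) != len(causal):
            raise ConfigurationError("effect vectors must match causal_index length")
        is_case = (sheet["status"] == "case").to_numpy()
        is_male = (sheet["sex"] == "male").to_numpy()
        pbase = _expit(baseline[causal])
        slope = pbase * (1 - pbase)  # d beta / d logit at the baseline
        shift_m = (eff_m / 100.0) / slope
        shift_f = (eff_f / 100.0) / slope
        logits[np.ix_(causal, np.where(is_case & is_male)[0])] += shift_m[:, None]
        logits[np.ix_(causal, np.where(is_case & ~is_male)[0])] += shift_f[:, None]

    betas = _expit(logits)
    pos = 1 + np.arange(p) * config.probe_spacing_bp
    annot = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "gene": [f"GENE{b}" for b in block_of],
        },
        index=pd.Index([f"cg{j:08d}" for j in range(p)], name="probe"),
    )
    values = pd.DataFrame(betas, index=annot.index, columns=sheet["sample_id"].to_numpy())
    bm = BetaMatrix(values, annot)
    bm.causal_index = causal  # ground truth for tests; not part of the schema
    return bm, sheet


def inject_dmr(
    betas: BetaMatrix,
    sheet: pd.DataFrame,
    region: tuple[int, int],
    delta: float,
) -> BetaMatrix:
    """Shift cases' logit-scale betas by ``delta`` over a probe index range.

    ``region`` is an inclusive (start, stop) pair of probe *positions in the
    matrix ordering*.  Controls and all probes outside the range are
    untouched; with ``delta == 0`` the output equals the input exactly.
    """
    start, stop = region
    if not (0 <= start <= stop < betas.n_probes):
        raise IndexError(f"region {region} out of bounds for {betas.n_probes} probes")
    if delta == 0:
        return BetaMatrix(betas.values.copy(), betas.annot.copy())
    vals = betas.values.to_numpy().copy()
    is_case = (sheet.set_index("sample_id").loc[betas.sample_ids, "status"] == "case").to_numpy()
    block = vals[start : stop + 1][:, is_case]
    eps = 1e-12
    shifted = _expit(_logit(np.clip(block, eps, 1 - eps)) + delta)
    vals[start : stop + 1, is_case] = shifted
    out = pd.DataFrame(vals, index=betas.values.index, columns=betas.values.columns)
    return BetaMatrix(out, betas.annot.copy())
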