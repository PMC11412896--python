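"""Configuration dataclasses for the synthetic generators and analysis stages.

All configs validate on construction and raise
:class:`~stratewas.exceptions.ConfigurationError` on invalid field values, so
a pipeline fails at setup rather than midway through a long run.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigurationError


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class CohortConfig:
    """Layout of one synthetic case/control methylation cohort.

    Effects are expressed on the x100 beta scale (percentage points of
    methylation difference between cases and controls); ``effect_sd`` is the
    probe-to-probe SD of the drawn effects on the same scale.  Probes are
    laid out in blocks of ``block_size`` consecutive probes sharing a latent
    factor, giving within-block logit-scale correlation ``block_rho``.
    """

    n_cases: int = 200
    n_controls: int = 200
    frac_male_cases: float = 0.65
    frac_male_controls: float = 0.58
    n_probes: int = 2000
    n_causal: int = 0
    effect_mean_male: float = 1.0
    effect_mean_female: float = 1.0
    effect_sd: float | None = None  # default: half the per-sex mean
    block_size: int = 5
    block_rho: float = 0.4
    probe_spacing_bp: int = 300
    covariate_effects: dict = field(default_factory=dict)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_probes", "block_size", "probe_spacing_bp"):
            _require(int(getattr(self, name)) > 0, f"{name} must be > 0")
        _require(0 <= self.n_causal <= self.n_probes, "need 0 <= n_causal <= n_probes")
        for name in ("frac_male_cases", "frac_male_controls"):
            _require(0 <= getattr(self, name) <= 1, f"{name} must lie in [0, 1]")
        _require(0 <= self.block_rho < 1, "block_rho must lie in [0, 1)")
        _require(self.noise_sd > 0, "noise_sd must be > 0")
        _require(self.n_probes >= self.block_size, "n_probes must be >= block_size")
        if self.effect_sd is not None:
            _require(self.effect_sd >= 0, "effect_sd must be >= 0")


@dataclass
class SimScenario:
    """One scenario of the sex-differential power simulation.

    400 individuals (half male), 10,000 normally distributed "methylation"
    measurements, 100 causal CpGs whose per-sex effect sizes are normal with
    the stated means; non-methylation noise is calibrated to explain
    ``nonmeth_var_frac`` of total phenotypic variance.
    """

    n_individuals: int = 400
    frac_male: float = 0.5
    n_cpgs: int = 10_000
    n_causal: int = 100
    mean_effect_male: float = 0.1
    mean_effect_female: float = 0.1
    effect_sd: float | None = None  # default: half the per-sex mean
    nonmeth_var_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_individuals > 0, "n_individuals must be > 0")
        _require(self.n_cpgs > 0, "n_cpgs must be > 0")
        _require(0 <= self.n_causal <= self.n_cpgs, "need 0 <= n_causal <= n_cpgs")
        _require(0 <= self.frac_male <= 1, "frac_male must lie in [0, 1]")
        _require(0 < self.nonmeth_var_frac < 1, "nonmeth_var_frac must lie in (0, 1)")
        if self.effect_sd is not None:
            _require(self.effect_sd >= 0, "effect_sd must be >= 0")


#: The four canonical scenarios: male mean effect fixed at 0.1, female mean
#: effect escalating across scenarios.
SCENARIO_FEMALE_MEANS = {"A": 0.1, "B": 0.2, "C": 0.4, "D": 0.8}


def scenario(label: str, seed: int = 0, **overrides) -> SimScenario:
    """Build a canonical scenario (A-D) by label."""
    try:
        fem = SCENARIO_FEMALE_MEANS[label.upper()]
    except KeyError:
        raise ConfigurationError(f"unknown scenario {label!r}; expected one of A-D") from None
    return SimScenario(mean_effect_female=fem, seed=seed, **overrides)


@dataclass
class MetaConfig:
    """Meta-analysis mode and inclusion rules."""

    mode: str = "sex_adjusted"
    min_cohorts: int = 2
    thresholds: tuple = (2.4e-7, 3.6e-8)

    MODES = ("sex_adjusted", "male_only", "female_only", "sex_stratified")

    def __post_init__(self) -> None:
        _require(self.mode in self.MODES, f"mode must be one of {self.MODES}")
        _require(self.min_cohorts >= 2, "min_cohorts must be >= 2")
        thr = tuple(float(t) for t in self.thresholds)
        _require(all(0 < t < 1 for t in thr), "thresholds must lie in (0, 1)")
        self.thresholds = thr


@dataclass
class DmrConfig:
    """comb-p style region-calling parameters."""

    seed_p: float = 0.001
    max_gap_bp: int = 750
    min_probes: int = 4
    sidak_alpha: float = 0.05
    acf_bin_bp: int = 50

    def __post_init__(self) -> None:
        _require(0 < self.seed_p < 1, "seed_p must lie in (0, 1)")
        _require(self.max_gap_bp > 0, "max_gap_bp must be > 0")
        _require(self.min_probes >= 2, "min_probes must be >= 2")
        _require(0 < self.sidak_alpha < 1, "sidak_alpha must lie in (0, 1)")
        _require(0 < self.acf_bin_bp <= self.max_gap_bp, "need 0 < acf_bin_bp <= max_gap_bp")


@dataclass
class ComethConfig:
    """Co-methylated region construction (adjacent-probe R^2 rule)."""

    r2_threshold: float = 0.3
    max_gap_bp: int = 1000

    def __post_init__(self) -> None:
        _require(0 < self.r2_threshold < 1, "r2_threshold must lie in (0, 1)")
        _require(self.max_gap_bp > 0, "max_gap_bp must be > 0")


@dataclass
class PmsConfig:
    """Polymethylation-score thresholds and standardization."""

    thresholds: tuple = (0.5, 5e-2, 5e-3, 5e-4, 5e-5, 5e-6)
    standardize_probes: bool = True

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.thresholds)
        _require(all(0 < t <= 1 for t in thr), "thresholds must lie in (0, 1]")
        _require(all(a > b for a, b in zip(thr, thr[1:])), "thresholds must be strictly decreasing")
        self.thresholds = thr
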