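"""Monte-Carlo power analysis for the group x manipulation interaction.

Each replicate draws standardized trial-level outcomes with a subject
random intercept carrying the configured share (ICC) of unit total
variance, applies the effect to a single group-vs-reference x
after-vs-before contrast, fits the random-intercept LMM and tests the
omnibus interaction with a Wald chi-square test.  Power is the
rejection fraction with a Wilson binomial interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import trial_model

POWER_FORMULA = "group * manipulation"
INTERACTION_TERM = "group:manipulation"


@dataclass
class PowerConfig:
    effect_beta: float = 0.2
    n_subjects: int = 150
    group_sizes: tuple[int, int, int] = (52, 55, 43)
    trials_per_subject: int = 412
    icc: float = 0.3
    alpha: float = 0.05
    reps: int = 200
    seed: int = 0
    effect_group: str = "ASD"  # group carrying the interaction contrast

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_subjects:
            raise ValueError("group_sizes must sum to n_subjects")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must be in [0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PowerResult:
    power: float
    ci95: tuple[float, float]
    reps_used: int
    n_reject: int
    warnings: list[str] = field(default_factory=list)


def _simulate_replicate(
    config: PowerConfig, template: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n_sub = config.n_subjects
    n_tr = config.trials_per_subject
    u = np.repeat(rng.normal(0.0, np.sqrt(config.icc), n_sub), n_tr)
    eps = rng.normal(0.0, np.sqrt(1.0 - config.icc), n_sub * n_tr)
    df = template.copy()
    df["y"] = u + eps + config.effect_beta * template["effect_cell"]
    return df


def _design_template(config: PowerConfig) -> pd.DataFrame:
    groups = np.repeat(
        ["ASD", "CON", "MHC"], np.asarray(config.group_sizes) * config.trials_per_subject
    )
    subject = np.repeat(
        [f"S{i:03d}" for i in range(config.n_subjects)], config.trials_per_subject
    )
    half = config.trials_per_subject // 2
    manipulation = np.tile(
        np.repeat(["before", "after"], [config.trials_per_subject - half, half]),
        config.n_subjects,
    )
    df = pd.DataFrame(
        {"subject_id": subject, "group": groups, "manipulation": manipulation}
    )
    df["effect_cell"] = (
        (df["group"] == config.effect_group) & (df["manipulation"] == "after")
    ).astype(float)
    return df


def simulate_power(config: PowerConfig) -> PowerResult:
    """Run the Monte-Carlo power simulation; deterministic under the seed."""
    warnings_list: list[str] = []
    if config.reps < 200:
        warnings_list.append(
            f"reps={config.reps} gives a wide binomial interval; consider >= 200"
        )
    template = _design_template(config)
    streams = np.random.SeedSequence(config.seed).spawn(config.reps)
    n_reject = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        df = _simulate_replicate(config, template, rng)
        result = trial_model.fit_lmm(df, "y", POWER_FORMULA)
        _stat, _df, p = trial_model.term_test(result, INTERACTION_TERM)
        if p < config.alpha:
            n_reject += 1
    power = n_reject / config.reps
    lo, hi = proportion_confint(n_reject, config.reps, alpha=0.05, method="wilson")
    return PowerResult(
        power=float(power),
        ci95=(float(lo), float(hi)),
        reps_used=config.reps,
        n_reject=n_reject,
        warnings=warnings_list,
    )
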