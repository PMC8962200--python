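"""Canned cohort-level simulation studies.

These drive the full generator -> preprocessing -> ERSP -> inference chain
at the study's conditions (14 subjects, 60 trials, alpha increments
0 / +1.5 / +3.0 dB with 1 dB between-subject spread) and are shared by the
test suite and the acceptance script.  Replicate studies restrict the
analysis to one motor channel (C3) plus one unrelated control channel and
to the alpha-band frequency grid, which leaves the per-replicate estimates
unchanged while keeping 100-replicate power studies tractable on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import FatigueSpectralModel
from .simulate import SimConfig, simulate_cohort

#: Frequency grid covering the alpha band (8 <= f < 13 Hz at 1 Hz).
ALPHA_GRID = np.arange(8.0, 13.0)


@dataclass
class CohortOutcome:
    """Per-replicate summaries of the alpha-band fatigue contrast at C3."""

    sev_minus_min_db: float
    anova_p: float
    bonferroni_min_sev_p: float
    control_anova_p: float
    control_monotone: bool


@dataclass
class ReplicateStudy:
    """Aggregated outcomes over independent cohort replicates."""

    outcomes: list[CohortOutcome] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.outcomes)

    @property
    def mean_contrast_db(self) -> float:
        return float(np.mean([o.sev_minus_min_db for o in self.outcomes]))

    def rejection_rate(self, alpha: float = 0.05) -> float:
        """Fraction of replicates with omnibus ANOVA p below alpha at C3."""
        return float(np.mean([o.anova_p < alpha for o in self.outcomes]))

    def min_sev_power(self, alpha: float = 0.05) -> float:
        """Fraction with a significant Bonferroni Min-Sev comparison."""
        return float(np.mean([
            o.anova_p < alpha and o.bonferroni_min_sev_p < alpha
            for o in self.outcomes
        ]))

    def control_false_positive_rate(self, alpha: float = 0.05) -> float:
        """Fraction where the unrelated channel shows a significant
        monotone (Min < Mod < Sev) effect."""
        return float(np.mean([
            o.control_anova_p < alpha and o.control_monotone
            for o in self.outcomes
        ]))


def run_alpha_cohort(seed: int, effect: bool = True,
                     channel: str = "C3",
                     control: str = "PO7") -> CohortOutcome:
    """Simulate one cohort and measure the alpha fatigue contrast at C3.

    With ``effect=False`` every injected increment is zero (null cohort).
    The analysis is the standard steady-window pipeline restricted to the
    analysis channel, the control channel, and the alpha grid.
    """
    config = SimConfig(seed=seed)
    if not effect:
        config = config.null()
    recordings = simulate_cohort(config)
    results = FatigueSpectralModel(
        recordings, window="steady", channels=[channel, control],
        freqs=ALPHA_GRID,
    ).fit()
    anova = results.anova(channel, "alpha")
    control_anova = results.anova(control, "alpha")
    control_means = results.condition_means(control, "alpha")
    monotone = (control_means["MinFatg"] < control_means["ModFatg"]
                < control_means["SevFatg"])
    return CohortOutcome(
        sev_minus_min_db=results.contrast(channel, "alpha"),
        anova_p=anova.p,
        bonferroni_min_sev_p=anova.posthoc.get(
            ("MinFatg", "SevFatg"), 1.0
        ),
        control_anova_p=control_anova.p,
        control_monotone=bool(monotone),
    )


def run_replicates(n_replicates: int, seed: int = 0,
                   effect: bool = True) -> ReplicateStudy:
    """Run independent cohort replicates on non-overlapping seed blocks.

    Replicate r uses cohort seed ``seed + 1000 * r`` so no two replicates
    share a subject-level random stream.
    """
    study = ReplicateStudy()
    for r in range(n_replicates):
        study.outcomes.append(
            run_alpha_cohort(seed + 1000 * r, effect=effect)
        )
    return study
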