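"""Configuration objects shared by the simulator and the pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class EffectSizes:
    """Planted effect sizes for the synthetic cohort.

    Multipliers act on dominant animals relative to the pen baseline;
    ``submissive_midday_shift`` is an additive shift (on the 0-1 scale) of
    the probability that a submissive animal's feeder visit starts inside
    the 10:00-13:59 window. ``planted_log2fc`` maps genus name to the
    log2 fold-change of its mean relative abundance in *dominant* over
    *submissive* samples (negative values plant submissive-enriched
    genera).
    """

    dominant_intake_multiplier: float = 3387.0 / 2870.0
    dominant_visit_multiplier: float = 1.23
    submissive_midday_shift: float = 0.041
    hierarchy_weight_effect_kg: float = 6.0
    planted_log2fc: dict[str, float] = field(
        default_factory=lambda: {
            "g01": 3.5,
            "g02": 3.5,
            "g03": 3.5,
            "g04": -3.5,
            "g05": -3.5,
        }
    )

    def validate(self) -> None:
        if self.dominant_intake_multiplier <= 0:
            raise ConfigurationError("dominant_intake_multiplier must be > 0")
        if self.dominant_visit_multiplier <= 0:
            raise ConfigurationError("dominant_visit_multiplier must be > 0")

    @classmethod
    def null(cls) -> "EffectSizes":
        """All effects switched off (no class differences)."""
        return cls(
            dominant_intake_multiplier=1.0,
            dominant_visit_multiplier=1.0,
            submissive_midday_shift=0.0,
            hierarchy_weight_effect_kg=0.0,
            planted_log2fc={},
        )


@dataclass
class CohortConfig:
    """Study-design parameters for one synthetic cohort.

    The default layout mirrors the reference design: 8 pens of 8 animals
    (4 castrated males + 4 females each), half the pens under a stress
    treatment with two mixing events, and three study phases delimited by
    the mixing days.
    """

    n_pens: int = 8
    animals_per_pen: int = 8
    mix_days: tuple[int, int] = (61, 83)
    slaughter_days: tuple[int, int] = (141, 148)
    weigh_days: tuple[int, ...] = (0, 21, 77, 103, 134)
    seed: int = 0
    effects: EffectSizes = field(default_factory=EffectSizes)

    # feeder-event generation knobs (per animal-day)
    base_visit_mean: float = 10.0
    intake_day0_g: float = 800.0
    intake_slope_g_per_day: float = 18.5
    intake_noise_sd: float = 0.08  # lognormal sigma on the daily total
    session_log_mean: float = 6.5  # log-seconds, median ~665 s
    session_log_sd: float = 0.5
    midday_base_share: float = 0.20

    # growth-curve knobs
    weight_day0_kg: float = 18.7
    growth_slope_kg_per_day: float = 0.82
    weight_animal_sd: float = 1.7
    weight_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pens % 2 != 0:
            raise ConfigurationError("n_pens must be even (half control, half stress)")
        if self.n_pens < 2:
            raise ConfigurationError("n_pens must be >= 2")
        if self.animals_per_pen % 2 != 0:
            raise ConfigurationError("animals_per_pen must be even")
        if list(self.mix_days) != sorted(set(self.mix_days)):
            raise ConfigurationError("mix_days must be strictly increasing")
        self.effects.validate()

    @property
    def phase_boundaries(self) -> tuple[int, int]:
        """(first_mix_day, second_mix_day): phase 1 is [0, m1), phase 2
        [m1, m2), phase 3 [m2, end]."""
        return tuple(self.mix_days)  # type: ignore[return-value]

    @property
    def end_day(self) -> int:
        return max(self.slaughter_days)

    def phase_of_day(self, day: int) -> int:
        m1, m2 = self.phase_boundaries
        if day < m1:
            return 1
        if day < m2:
            return 2
        return 3

    def phase_days(self, phase: int) -> range:
        m1, m2 = self.phase_boundaries
        if phase == 1:
            return range(0, m1)
        if phase == 2:
            return range(m1, m2)
        if phase == 3:
            return range(m2, self.end_day)
        raise ValueError(f"unknown phase {phase!r}")


@dataclass
class MicrobiomeConfig:
    """Parameters of the abundance generator and biomarker chain."""

    n_genera: int = 40
    depth_range: tuple[int, int] = (32_000, 60_000)
    rarefaction_depth: int = 31_731
    factor_strength: float = 0.4  # scales the planted class-factor loading
    background_strength: float = 0.9  # class-independent module factors
    within_noise_sd: float = 0.15
    base_log_sd: float = 1.0
    sparcc_iterations: int = 50
    sparcc_exclusion_threshold: float = 0.1
    sparcc_resamples: int = 3
    score_ensemble: int = 16  # network/score replicates averaged for stability
    pseudocount: float = 0.5
    edge_threshold: float = 0.7
    module_cut_height: float = 0.8
    score_threshold: float = 0.25
    fdr_threshold: float = 0.05
    cv_folds: int = 5


@dataclass
class RunConfig:
    """Everything needed for one reproducible end-to-end pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    microbiome: MicrobiomeConfig = field(default_factory=MicrobiomeConfig)
    seed: int = 0
    outdir: str = "herdrank_run"
    run_feeding: bool = True
    run_weights: bool = True
    run_microbiome: bool = True
    feeding_days_per_phase: int | None = None  # None = all study days

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cohort_raw = dict(raw.pop("cohort", {}))
        effects_raw = cohort_raw.pop("effects", None)
        if effects_raw is not None:
            cohort_raw["effects"] = EffectSizes(**effects_raw)
        micro_raw = raw.pop("microbiome", {})
        cfg = cls(
            cohort=CohortConfig(**_tuplify(cohort_raw, CohortConfig)),
            microbiome=MicrobiomeConfig(**_tuplify(micro_raw, MicrobiomeConfig)),
            **raw,
        )
        cfg.cohort.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _tuplify(raw: dict, klass) -> dict:
    """YAML has no tuples; coerce list-valued fields declared as tuples."""
    out = dict(raw)
    for f in dataclasses.fields(klass):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out
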