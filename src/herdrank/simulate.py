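"""Synthetic cohort generators.

Every generator is a pure function of its configuration and seed, and
produces plain :class:`pandas.DataFrame` tables mirroring the CSV/TSV
interchange formats used by the rest of the package:

* animals   -- ``animal_id, sex, pen_id, treatment, latent_ability``
* bouts     -- ``pen_id, phase, day, animal_a, animal_b, outcome, winner, confirmed``
* events    -- ``animal_id, start_time, duration_s, intake_g``
* weights   -- ``animal_id, day, weight_kg``
* abundance -- genera (rows) x samples (columns), integer counts

The bout-outcome model is Bradley-Terry: among decisive bouts the
probability that animal *i* beats *j* is ``sigmoid(ability_i - ability_j)``.
The "smallest" animal exempt from relocation at a mixing event is proxied
by the lowest latent ability of its sex in the pen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, softmax

from herdrank.config import CohortConfig, ConfigurationError, MicrobiomeConfig
from herdrank.dominance import round_robin_schedule

BASE_DATE = pd.Timestamp("2022-06-01")

MIDDAY_START_H = 10.0
MIDDAY_END_H = 14.0


@dataclass
class Cohort:
    """A generated roster plus its mixing plan."""

    animals: pd.DataFrame
    mixing_plan: pd.DataFrame  # columns: day, animal_id, from_pen, to_pen
    config: CohortConfig

    def pens_on_day(self, day: int) -> pd.Series:
        """animal_id -> pen_id mapping valid on study ``day`` (mixing-aware)."""
        pens = self.animals.set_index("animal_id")["pen_id"].copy()
        moved = self.mixing_plan[self.mixing_plan["day"] <= day]
        for _, row in moved.iterrows():
            pens.loc[row["animal_id"]] = row["to_pen"]
        return pens

    def pens_in_phase(self, phase: int) -> pd.Series:
        """Pen membership during a phase (constant within a phase)."""
        day = self.config.phase_days(phase)[0]
        return self.pens_on_day(day)

    def roster_in_phase(self, phase: int) -> pd.DataFrame:
        roster = self.animals.copy()
        roster["pen_id"] = self.pens_in_phase(phase).loc[roster["animal_id"]].values
        return roster


def generate_cohort(config: CohortConfig) -> Cohort:
    """Build the roster, assign treatments, and plan the mixing events.

    Half the pens are control, half stress.  At the first mixing day the
    three highest-latent-ability females of every stress pen are rotated
    one-per-pen among the other stress pens (the lowest-ability female
    stays); the second mixing does the same with males.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC0]))
    per_sex = cfg.animals_per_pen // 2
    rows = []
    for p in range(cfg.n_pens):
        pen_id = f"P{p + 1}"
        treatment = "control" if p < cfg.n_pens // 2 else "stress"
        for sex, tag in (("female", "F"), ("castrated_male", "M")):
            for k in range(per_sex):
                rows.append(
                    {
                        "animal_id": f"{pen_id}{tag}{k + 1}",
                        "sex": sex,
                        "pen_id": pen_id,
                        "treatment": treatment,
                        "latent_ability": rng.normal(0.0, 1.0),
                    }
                )
    animals = pd.DataFrame(rows)

    stress_pens = [f"P{p + 1}" for p in range(cfg.n_pens // 2, cfg.n_pens)]
    plan_rows = []
    for mix_day, sex in zip(cfg.mix_days, ("female", "castrated_male")):
        movers_per_pen = {}
        for pen in stress_pens:
            grp = animals[(animals["pen_id"] == pen) & (animals["sex"] == sex)]
            grp = grp.sort_values("latent_ability")
            movers_per_pen[pen] = list(grp["animal_id"].iloc[1:])  # smallest stays
        n_stress = len(stress_pens)
        for i, pen in enumerate(stress_pens):
            movers = movers_per_pen[pen]
            for k, animal in enumerate(movers):
                dest = stress_pens[(i + k + 1) % n_stress]
                plan_rows.append(
                    {
                        "day": mix_day,
                        "animal_id": animal,
                        "from_pen": pen,
                        "to_pen": dest,
                    }
                )
    mixing_plan = pd.DataFrame(
        plan_rows, columns=["day", "animal_id", "from_pen", "to_pen"]
    )
    return Cohort(animals=animals, mixing_plan=mixing_plan, config=cfg)


def true_hierarchy(cohort: Cohort, phase: int) -> pd.DataFrame:
    """Ground-truth classes from latent ability (top-2/middle/bottom-2 per pen)."""
    roster = cohort.roster_in_phase(phase)
    out = []
    for pen, grp in roster.groupby("pen_id"):
        grp = grp.sort_values("latent_ability", ascending=False)
        n = len(grp)
        classes = ["dominant"] * 2 + ["intermediate"] * (n - 4) + ["submissive"] * 2
        for animal, cls in zip(grp["animal_id"], classes):
            out.append(
                {"animal_id": animal, "pen_id": pen, "phase": phase, "class": cls}
            )
    return pd.DataFrame(out)


def generate_bouts(
    cohort: Cohort,
    phase: int,
    p_draw: float = 0.10,
    p_inconclusive: float = 0.05,
    p_confirm: float = 0.70,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a full round-robin tournament in every pen for one phase."""
    if not (0 <= p_draw <= 1 and 0 <= p_inconclusive <= 1 and 0 <= p_confirm <= 1):
        raise ConfigurationError("bout probabilities must lie in [0, 1]")
    if p_draw + p_inconclusive > 1:
        raise ConfigurationError("p_draw + p_inconclusive must not exceed 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0, phase]))
    ability = cohort.animals.set_index("animal_id")["latent_ability"]
    base_day = cohort.config.phase_days(phase)[0]
    roster = cohort.roster_in_phase(phase)
    rows = []
    for pen, grp in roster.groupby("pen_id"):
        ids = sorted(grp["animal_id"])
        schedule = round_robin_schedule(ids)
        for day_idx, pairs in schedule:
            for a, b in pairs:
                u = rng.uniform()
                if u < p_draw:
                    outcome, winner, confirmed = "draw", None, False
                elif u < p_draw + p_inconclusive:
                    outcome, winner, confirmed = "inconclusive", None, False
                else:
                    outcome = "decisive"
                    p_a = expit(ability.loc[a] - ability.loc[b])
                    winner = a if rng.uniform() < p_a else b
                    confirmed = bool(rng.uniform() < p_confirm)
                rows.append(
                    {
                        "pen_id": pen,
                        "phase": phase,
                        "day": base_day + day_idx,
                        "animal_a": a,
                        "animal_b": b,
                        "outcome": outcome,
                        "winner": winner,
                        "confirmed": confirmed,
                    }
                )
    return pd.DataFrame(rows)


def generate_feeding_events(
    cohort: Cohort,
    hierarchy: pd.DataFrame,
    day_range: range,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate feeder sessions for every animal over ``day_range``.

    Daily visit counts are Poisson (dominant animals get the visit
    multiplier), session durations log-normal, daily intake grows
    linearly with age toward the configured phase-3 level (dominant
    animals get the intake multiplier, ramped in over the study), and
    submissive animals' visit start times are shifted toward the
    10:00-13:59 window by the configured share.
    """
    if len(day_range) == 0:
        raise ConfigurationError("day_range must contain at least one day")
    cfg = cohort.config
    eff = cfg.effects
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFE]))
    cls_lookup = hierarchy.set_index(["animal_id", "phase"])["class"]

    rows = []
    animal_ids = list(cohort.animals["animal_id"])
    for day in day_range:
        phase = cfg.phase_of_day(day)
        ramp = phase / 3.0  # hierarchy effects grow over the study
        for animal in animal_ids:
            cls = cls_lookup.get((animal, phase), "intermediate")
            visit_mu = cfg.base_visit_mean
            if cls == "dominant":
                visit_mu *= 1.0 + (eff.dominant_visit_multiplier - 1.0) * ramp
            n_visits = rng.poisson(visit_mu)
            if n_visits == 0:
                continue
            target = cfg.intake_day0_g + cfg.intake_slope_g_per_day * day
            if cls == "dominant":
                target *= 1.0 + (eff.dominant_intake_multiplier - 1.0) * ramp
            daily_intake = target * rng.lognormal(0.0, cfg.intake_noise_sd)
            shares = rng.dirichlet(np.full(n_visits, 5.0))
            intakes = daily_intake * shares
            durations = rng.lognormal(cfg.session_log_mean, cfg.session_log_sd, n_visits)
            midday_w = cfg.midday_base_share
            if cls == "submissive":
                midday_w += eff.submissive_midday_shift * ramp
            in_midday = rng.uniform(size=n_visits) < midday_w
            hours = np.where(
                in_midday,
                rng.uniform(MIDDAY_START_H, MIDDAY_END_H, n_visits),
                _off_midday_hours(rng, n_visits),
            )
            for h, d, g in zip(hours, durations, intakes):
                rows.append(
                    {
                        "animal_id": animal,
                        "start_time": BASE_DATE
                        + pd.Timedelta(days=day)
                        + pd.Timedelta(hours=float(h)),
                        "duration_s": float(d),
                        "intake_g": float(g),
                    }
                )
    return pd.DataFrame(rows, columns=["animal_id", "start_time", "duration_s", "intake_g"])


def _off_midday_hours(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform start hours over the 20 h of the day outside [10, 14)."""
    u = rng.uniform(0.0, 20.0, n)
    return np.where(u < MIDDAY_START_H, u, u + 4.0)


def generate_weights(
    cohort: Cohort,
    hierarchy: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Weight records at the scheduled weigh days plus each animal's
    slaughter day (half the cohort at each configured slaughter day).

    Growth is linear from ~18.7 kg toward ~140 kg; the hierarchy effect
    ramps linearly with age so the final dominant-submissive gap equals
    ``hierarchy_weight_effect_kg``.
    """
    cfg = cohort.config
    eff = cfg.effects
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAE]))
    cls_lookup = hierarchy.set_index(["animal_id", "phase"])["class"]
    animal_ids = list(cohort.animals["animal_id"])
    animal_re = {a: rng.normal(0.0, cfg.weight_animal_sd) for a in animal_ids}
    half = len(animal_ids) // 2
    slaughter = {
        a: cfg.slaughter_days[0] if i < half else cfg.slaughter_days[1]
        for i, a in enumerate(animal_ids)
    }
    end = cfg.end_day
    rows = []
    for animal in animal_ids:
        days = sorted(set(cfg.weigh_days) | {slaughter[animal]})
        for day in days:
            phase = cfg.phase_of_day(day)
            cls = cls_lookup.get((animal, phase), "intermediate")
            base = cfg.weight_day0_kg + cfg.growth_slope_kg_per_day * day
            offset = 0.0
            if cls == "dominant":
                offset = +0.5 * eff.hierarchy_weight_effect_kg * (day / end)
            elif cls == "submissive":
                offset = -0.5 * eff.hierarchy_weight_effect_kg * (day / end)
            w = base + offset + animal_re[animal] + rng.normal(0.0, cfg.weight_noise_sd)
            rows.append({"animal_id": animal, "day": day, "weight_kg": max(w, 1.0)})
    return pd.DataFrame(rows)


def generate_abundances(
    sample_classes: pd.Series,
    n_genera: int = 40,
    planted: dict[str, float] | None = None,
    depth_range: tuple[int, int] = (32_000, 60_000),
    seed: int = 0,
    config: MicrobiomeConfig | None = None,
) -> pd.DataFrame:
    """Genus-level count matrix (genera x samples) with planted effects.

    ``sample_classes`` maps sample id -> {"dominant", "submissive"};
    ``planted`` maps genus name -> log2 fold-change of dominant over
    submissive mean relative abundance.  Counts are multinomial draws at
    a per-sample depth uniform over ``depth_range``, from logistic-normal
    proportions.

    Planted structure has two components.  (1) Abundance: a class mean
    shift of +- half the log fold-change.  (2) Rewiring: the non-planted
    genera are organized into background modules with independent latent
    factors (stable cliques in every network), while the planted genera
    of each class share a latent factor that is active only in the
    samples of their enriched class.  The planted group therefore forms
    a floating clique in its enriched-class network; in the pooled
    sample set the clique persists (the between-class mean shift adds
    covariance), but in the opposite class's network the planted genera
    are mutually independent.  A planted node is thus rewired in exactly
    one condition network relative to the combined one, which is the
    asymmetry the transition score detects.  Every factor contribution
    is mean-one on the
    natural scale so fold-changes stay on target, and planted genera
    draw moderately high baseline abundances so their counts are
    informative at typical sequencing depths.
    """
    cfg = config or MicrobiomeConfig(n_genera=n_genera, depth_range=depth_range)
    planted = dict(planted or {})
    genera = [f"g{i + 1:02d}" for i in range(n_genera)]
    unknown = set(planted) - set(genera)
    if unknown:
        raise ConfigurationError(f"planted genera not in matrix: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAB]))

    is_planted = np.array([g in planted for g in genera])
    base_mu = rng.normal(0.0, cfg.base_log_sd, n_genera)
    # mid-abundance planted genera: informative counts at typical depths
    # without letting their class factor swing the whole composition
    base_mu[is_planted] = rng.uniform(-0.5, 0.5, int(is_planted.sum()))
    lfc = np.array([planted.get(g, 0.0) for g in genera])
    half_shift = 0.5 * lfc * np.log(2.0)  # +- half the log fold-change per class
    # balance the realized total planted mass across classes, so the class
    # shift of the planted panel does not leak into every other genus's
    # relative abundance through the compositional closure
    up, dn = lfc > 0, lfc < 0
    if up.any() and dn.any():
        base_mu[dn] += np.log(np.exp(base_mu[up]).sum() / np.exp(base_mu[dn]).sum())

    # class-independent background modules over the non-planted genera;
    # small modules keep the estimator's sparsity assumption tenable
    n_modules = max(len(nonplanted_idx := np.flatnonzero(~is_planted)) // 3, 1)
    module_of = np.full(n_genera, -1)
    module_of[nonplanted_idx] = np.arange(len(nonplanted_idx)) % n_modules
    bg = cfg.background_strength

    dom_planted = is_planted & (lfc > 0)
    sub_planted = is_planted & (lfc < 0)
    # class-factor loadings scale with the planted shift so the factor
    # dominates the within-class variance of every planted genus
    lam = cfg.factor_strength * np.sqrt(2.0) * np.abs(half_shift)

    # factors drawn for all samples at once and centred within each
    # class: a chance association between a module factor and the class
    # labels would otherwise make whole null modules spuriously
    # differential in a finite cohort
    sample_ids = list(sample_classes.index)
    cls_vec = sample_classes.to_numpy()
    n_samples = len(sample_ids)
    f_bg = rng.normal(0.0, 1.0, (n_modules, n_samples))
    f_cls = rng.normal(0.0, 1.0, n_samples)
    for cls in np.unique(cls_vec):
        sel = cls_vec == cls
        f_bg[:, sel] -= f_bg[:, sel].mean(axis=1, keepdims=True)
        f_cls[sel] -= f_cls[sel].mean()

    in_module = module_of >= 0
    cols = {}
    for j, (sample_id, cls) in enumerate(zip(sample_ids, cls_vec)):
        sign = 1.0 if cls == "dominant" else -1.0
        eta = base_mu + sign * half_shift
        eta = eta + np.where(
            in_module, bg * f_bg[np.clip(module_of, 0, None), j] - 0.5 * bg**2, 0.0
        )
        on_class = dom_planted if cls == "dominant" else sub_planted
        eta = eta + np.where(on_class, lam * f_cls[j] - 0.5 * lam**2, 0.0)
        eta = eta + rng.normal(0.0, cfg.within_noise_sd, n_genera)
        theta = softmax(eta)
        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        cols[sample_id] = rng.multinomial(depth, theta)
    return pd.DataFrame(cols, index=pd.Index(genera, name="genus"))
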