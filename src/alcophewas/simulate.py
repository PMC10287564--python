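"""Synthetic biobank cohort generator.

Generates person-level cohorts with the statistical structure that the
downstream analyses assume: two biallelic loci in per-area Hardy-Weinberg
equilibrium with a north-south allele-frequency gradient, genotype- and
sex-dependent drinking behaviour, a log-normal reported baseline intake
with usual (long-term) intake regressing toward the genotype mean so the
regression-dilution ratio hits its configured target, and recurrent
ICD-10-coded hospitalization events whose hazards are log-linear in usual
intake, with independent competing mortality and area-level
baseline-hazard variation.

The generator writes/reads plain TSV cohorts (``participants.tsv`` +
``events.tsv``); see :func:`write_cohort`. Within string columns the token
``"."`` means "not applicable" (e.g. mealtime habit for non-drinkers) and
empty numeric cells are missing values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigurationError
from .config import SimulationConfig

__all__ = [
    "Cohort",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_intake_measurements",
    "write_cohort",
    "read_cohort",
]

GENOTYPES = np.array(["GG", "AG", "AA"])
STATUSES = ("non", "ex", "occasional", "current")
BEVERAGES = ("beer", "grape_wine", "rice_wine", "weak_spirits", "strong_spirits")
_BEVERAGE_PROBS = (0.15, 0.05, 0.10, 0.15, 0.55)  # spirits-dominant
_FREQ_LABELS = ("weekly_1_2", "weekly_3_5", "weekly_6_7")
_FREQ_DAYS = {"weekly_1_2": 1.5, "weekly_3_5": 4.0, "weekly_6_7": 6.5}
_VV = {"beer": 0.04, "grape_wine": 0.12, "rice_wine": 0.15,
       "weak_spirits": 0.38, "strong_spirits": 0.53}
_ETHANOL_DENSITY = 0.79


@dataclass
class Cohort:
    """A simulated cohort: one row per participant, one row per event."""

    participants: pd.DataFrame
    events: pd.DataFrame
    config: SimulationConfig | None = None

    @property
    def n(self) -> int:
        return len(self.participants)


# ---------------------------------------------------------------------------
# genotype layer
# ---------------------------------------------------------------------------

def _hwe_probs(freq: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (GG, AG, AA) per area."""
    q = 1.0 - freq
    return np.stack([q * q, 2 * q * freq, freq * freq], axis=-1)


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator,
                       area: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw two-locus genotype dosages and genomic-PC surrogates.

    Genotypes are drawn per area as binomial(2, p_area) A-allele dosages,
    which is exactly Hardy-Weinberg within area. PC surrogates carry
    area-level structure (deterministic loadings) plus unit Gaussian noise.

    Returns
    -------
    (dosage_locus1, dosage_locus2, pcs) where dosages are 0/1/2 A-allele
    counts and pcs has shape (n, config.n_pcs).
    """
    f1 = config.locus1_frequencies()
    f2 = config.locus2_frequencies()
    if np.any(f1 < 0) or np.any(f1 > 1) or np.any(f2 < 0) or np.any(f2 > 1):
        raise ConfigurationError("allele frequency outside [0, 1]")
    d1 = rng.binomial(2, f1[area])
    d2 = rng.binomial(2, f2[area])
    j = np.arange(1, config.n_pcs + 1)[None, :]
    loadings = np.cos(2 * np.pi * j * (area[:, None] + 0.5) / config.n_areas)
    pcs = loadings + rng.normal(0.0, 1.0, size=(len(area), config.n_pcs))
    return d1, d2, pcs


def _genotype_distribution(config: SimulationConfig) -> np.ndarray:
    """Population distribution over the 9 genotype combos, averaged over areas.

    Shape (3, 3): P(locus1 dosage, locus2 dosage) with uniform area weights.
    """
    p1 = _hwe_probs(config.locus1_frequencies())  # (areas, 3)
    p2 = _hwe_probs(config.locus2_frequencies())
    return np.einsum("ai,aj->ij", p1, p2) / config.n_areas


def _ever_regular_base(config: SimulationConfig, sex: str) -> tuple[float, np.ndarray, np.ndarray]:
    """Calibrated base P(ever-regular) plus per-dosage factor arrays."""
    if sex == "M":
        probs = config.male_status_probs
        fac1 = np.asarray(config.locus1_drinking_factors, dtype=float)
        fac2 = np.asarray(config.locus2_drinking_factors, dtype=float)
    else:
        probs = config.female_status_probs
        fac1 = np.asarray(config.female_locus1_drinking_factors or (1.0, 1.0, 1.0), float)
        fac2 = np.asarray(config.female_locus2_drinking_factors or (1.0, 1.0, 1.0), float)
    p_ever = probs[1] + probs[3]
    if p_ever == 0:
        return 0.0, fac1, fac2
    dist = _genotype_distribution(config)
    mean_factor = float(np.einsum("ij,i,j->", dist, fac1, fac2))
    return p_ever / mean_factor, fac1, fac2


def _mean_intake_by_genotype(config: SimulationConfig, sex: str) -> np.ndarray:
    """Mean usual intake (g/week) among current drinkers per genotype combo.

    Genotype factors scale the mean multiplicatively; a normalizing constant
    (computed over the drinker-weighted genotype distribution) keeps the
    configured marginal mean exact in expectation.
    """
    overall = config.male_mean_intake if sex == "M" else config.female_mean_intake
    if sex == "M":
        h1 = np.asarray(config.locus1_intake_factors, float)
        h2 = np.asarray(config.locus2_intake_factors, float)
    else:
        # Intake level in women is genotype-independent by default.
        h1 = np.ones(3)
        h2 = np.ones(3)
    base, fac1, fac2 = _ever_regular_base(config, sex)
    dist = _genotype_distribution(config)
    drinker_w = dist * np.outer(fac1, fac2)
    total = drinker_w.sum()
    if total == 0:
        return np.full((3, 3), overall)
    h = np.outer(h1, h2)
    mean_h = float((drinker_w * h).sum() / total)
    return overall * h / mean_h


def _usual_from_baseline(baseline, genotype_mean, rdr, rng):
    """Usual (long-term) intake given a baseline report.

    The questionnaire report ``B`` is log-normal around the genotype mean
    ``m``; usual intake regresses toward the mean,
    ``U = m + rdr x (B - m) + delta`` with independent within-person
    variation ``delta ~ N(0, (0.5 (1 - rdr) m)^2)``. This makes
    ``E[U | B]`` exactly linear in ``B`` with slope ``rdr``, so the grouped
    McMahon-Peto estimator, the attenuation of a linear Cox term in ``B``
    and the configured target all agree. A target of 1 means no
    within-person variation (``U = B``).
    """
    delta_sd = 0.5 * (1.0 - rdr) * genotype_mean
    u = genotype_mean + rdr * (baseline - genotype_mean) \
        + rng.normal(size=len(baseline)) * delta_sd
    return np.maximum(u, 1.0)


def simulate_intake_measurements(n: int, config: SimulationConfig,
                                 seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw (baseline, resurvey) intake pairs from the measurement model.

    Uses the male current-drinker genotype mixture of the configured
    generator; handy for studying the regression-dilution estimator at a
    chosen number of resurveyed participants without a full cohort.
    """
    rng = np.random.default_rng(seed)
    base, fac1, fac2 = _ever_regular_base(config, "M")
    dist = _genotype_distribution(config)
    w = (dist * np.outer(fac1, fac2)).ravel()
    w = w / w.sum()
    means = _mean_intake_by_genotype(config, "M").ravel()
    m = means[rng.choice(len(w), size=n, p=w)]
    s = config.intake_log_sd
    baseline = np.minimum(np.exp(rng.normal(np.log(m) - s * s / 2.0, s)),
                          config.max_reported_intake)
    usual = _usual_from_baseline(baseline, m, config.rdr_target, rng)
    eps_sd = 0.5 * (1.0 - config.rdr_target) * m
    resurvey = np.maximum(usual + rng.normal(size=n) * eps_sd, 0.1)
    return baseline, resurvey


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig | None = None, *,
                    seed: int | None = None) -> Cohort:
    """Generate a complete synthetic cohort.

    Parameters
    ----------
    config : SimulationConfig, optional
        Defaults to ``SimulationConfig()``.
    seed : int, optional
        Overrides ``config.seed``.

    Returns
    -------
    Cohort
        ``participants`` (one row per person, including the generator-truth
        column ``true_usual_intake``) and ``events`` (id, icd10, age).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants

    # demographics ---------------------------------------------------------
    male = rng.random(n) < config.prop_male
    sex = np.where(male, "M", "F")
    area = rng.integers(0, config.n_areas, size=n)
    age = np.clip(rng.normal(52.0, 10.7, n), 30.0, 79.0)

    d1, d2, pcs = simulate_genotypes(config, rng, area)

    # drinker status -------------------------------------------------------
    status = np.empty(n, dtype=object)
    p_ever = np.empty(n)
    for s, mask in (("M", male), ("F", ~male)):
        base, fac1, fac2 = _ever_regular_base(config, s)
        p_ever[mask] = np.clip(base * fac1[d1[mask]] * fac2[d2[mask]], 0.0, 1.0)
    u = rng.random(n)
    probs_m = config.male_status_probs
    probs_f = config.female_status_probs
    for s, mask, probs in (("M", male, probs_m), ("F", ~male, probs_f)):
        pe = probs[1] + probs[3]
        cur_share = probs[3] / pe if pe > 0 else 0.0
        non_share = probs[0] / (probs[0] + probs[2]) if probs[0] + probs[2] > 0 else 0.0
        p_cur = p_ever[mask] * cur_share
        p_ex = p_ever[mask] * (1.0 - cur_share)
        p_non = (1.0 - p_ever[mask]) * non_share
        um = u[mask]
        st = np.full(mask.sum(), "occasional", dtype=object)
        st[um < p_cur] = "current"
        st[(um >= p_cur) & (um < p_cur + p_ex)] = "ex"
        st[(um >= p_cur + p_ex) & (um < p_cur + p_ex + p_non)] = "non"
        status[mask] = st
    current = status == "current"
    ex = status == "ex"

    # baseline-reported intake (log-normal within genotype), usual intake
    # regressing toward the genotype mean, and resurvey measurements ------
    s_log = config.intake_log_sd
    genotype_mean = np.zeros(n)
    for s, mask in (("M", male & current), ("F", ~male & current)):
        means = _mean_intake_by_genotype(config, s)
        genotype_mean[mask] = means[d1[mask], d2[mask]]
    baseline_intake = np.zeros(n)
    baseline_intake[current] = np.minimum(np.exp(
        np.log(genotype_mean[current]) - s_log ** 2 / 2.0
        + s_log * rng.normal(size=int(current.sum()))),
        config.max_reported_intake)
    usual = np.zeros(n)
    usual[status == "occasional"] = config.occasional_intake
    usual[current] = _usual_from_baseline(
        baseline_intake[current], genotype_mean[current], config.rdr_target,
        rng)

    eps_sd = 0.5 * (1.0 - config.rdr_target) * genotype_mean
    def _resurvey_measure():
        out = usual.copy()
        out[current] = np.maximum(
            usual[current] + rng.normal(size=n)[current] * eps_sd[current], 0.1)
        return out

    resurveyed = rng.random(n) < config.resurvey_fraction
    res1 = np.where(resurveyed, _resurvey_measure(), np.nan)
    res2 = np.where(resurveyed, _resurvey_measure(), np.nan)

    # questionnaire fields -------------------------------------------------
    freq = np.full(n, ".", dtype=object)
    past_weekly = np.zeros(n, dtype=bool)
    freq[current] = rng.choice(_FREQ_LABELS, size=int(current.sum()),
                               p=config.freq_category_probs)
    past_weekly[current] = True
    freq[ex] = rng.choice(["never", "occasional", "monthly"], size=int(ex.sum()),
                          p=(0.5, 0.3, 0.2))
    past_weekly[ex] = True
    occ = status == "occasional"
    freq[occ] = rng.choice(["occasional", "certain_seasons", "monthly"],
                           size=int(occ.sum()), p=(0.7, 0.15, 0.15))
    freq[status == "non"] = "never"

    f_days = np.array([_FREQ_DAYS.get(f, np.nan) for f in freq])
    beverage = rng.choice(BEVERAGES, size=n, p=_BEVERAGE_PROBS)
    volumes = {b: np.zeros(n) for b in BEVERAGES}
    for b in BEVERAGES:
        m = current & (beverage == b)
        # typical-drinking-day volume chosen so the questionnaire formula
        # reproduces the baseline intake measurement exactly
        volumes[b][m] = baseline_intake[m] / (f_days[m] * _VV[b] * _ETHANOL_DENSITY)
    per_occasion = np.where(current, baseline_intake / np.where(current, f_days, 1.0), np.nan)

    mealtime = np.full(n, ".", dtype=object)
    mealtime[current] = rng.choice(["with_meals", "between_after", "no_pattern"],
                                   size=int(current.sum()), p=(0.6, 0.3, 0.1))
    duration = np.clip(rng.uniform(5.0, 35.0, n), 1.0, age - 16.0)
    age_started = np.where(current | ex, np.round(age - duration, 1), np.nan)
    years_stopped = np.where(ex, np.round(rng.uniform(1.0, 15.0, n), 1), np.nan)

    # covariates -----------------------------------------------------------
    education = rng.choice(4, size=n, p=(0.25, 0.30, 0.35, 0.10))
    smoking = np.zeros(n, dtype=int)
    ever_reg = current | ex
    m_ev = male & ever_reg
    m_nv = male & ~ever_reg
    smoking[m_ev] = rng.choice(6, size=int(m_ev.sum()),
                               p=(0.20, 0.05, 0.08, 0.22, 0.26, 0.19))
    smoking[m_nv] = rng.choice(6, size=int(m_nv.sum()),
                               p=(0.36, 0.07, 0.08, 0.19, 0.19, 0.11))
    smoking[~male] = rng.choice(4, size=int((~male).sum()), p=(0.93, 0.02, 0.02, 0.03))
    income = rng.choice(4, size=n, p=(0.25, 0.30, 0.25, 0.20))
    fruit = (rng.random(n) < 0.72).astype(int)  # 1 = infrequent fresh fruit
    met = rng.gamma(2.0, 11.0, n)
    bmi = rng.normal(23.4, 3.2, n)
    p_poor = np.select([status == "non", ex, occ, current],
                       [0.128, 0.171, 0.077, 0.062])
    poor_health = rng.random(n) < p_poor

    # mortality and censoring ---------------------------------------------
    death_age = age + rng.standard_exponential(n) / config.mortality_rate
    censor_age = age + config.followup_years
    end_age = np.minimum(death_age, censor_age)

    # hospitalization events ----------------------------------------------
    area_mult = config.area_hazard_multipliers()[area]
    sick_mult = np.where(ex, config.sick_quitter_hr, 1.0)
    ids_all, codes_all, ages_all = [], [], []
    for eff in config.endpoint_effects:
        rate = eff.baseline_rate * area_mult * sick_mult * np.exp(
            eff.log_hr_per_280g * usual / 280.0)
        counts = rng.poisson(rate * config.followup_years)
        total = int(counts.sum())
        owners = np.repeat(np.arange(n), counts)
        cand = age[owners] + rng.uniform(0.0, config.followup_years, total)
        keep = cand <= end_age[owners]
        ids_all.append(owners[keep])
        codes_all.append(np.full(int(keep.sum()), eff.icd10_code, dtype=object))
        ages_all.append(cand[keep])

    events = pd.DataFrame({
        "id": np.concatenate(ids_all) if ids_all else np.array([], dtype=int),
        "icd10": np.concatenate(codes_all) if codes_all else np.array([], dtype=object),
        "age": np.concatenate(ages_all) if ids_all else np.array([], dtype=float),
    }).sort_values(["id", "age"], kind="mergesort").reset_index(drop=True)

    participants = pd.DataFrame({
        "id": np.arange(n),
        "sex": sex,
        "area": area,
        "age_baseline": age,
        "education": education,
        "smoking": smoking,
        "income": income,
        "fruit": fruit,
        "met": met,
        "bmi": bmi,
        "poor_health": poor_health,
        "genotype_l1": GENOTYPES[d1],
        "genotype_l2": GENOTYPES[d2],
        "freq_category": freq,
        "past_weekly": past_weekly,
        "vol_beer": volumes["beer"],
        "vol_grape_wine": volumes["grape_wine"],
        "vol_rice_wine": volumes["rice_wine"],
        "vol_weak_spirits": volumes["weak_spirits"],
        "vol_strong_spirits": volumes["strong_spirits"],
        "per_occasion_g": per_occasion,
        "mealtime": mealtime,
        "age_started": age_started,
        "years_since_stopped": years_stopped,
        "resurvey1": res1,
        "resurvey2": res2,
        "resurveyed": resurveyed,
        "true_usual_intake": usual,
        "death_age": death_age,
        "censor_age": censor_age,
        "died": death_age <= censor_age,
    })
    for j in range(config.n_pcs):
        participants[f"pc{j + 1}"] = pcs[:, j]

    return Cohort(participants=participants, events=events, config=config)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> None:
    """Write ``participants.tsv``, ``events.tsv`` and ``config.yaml``.

    Floats are written with 17 significant digits so a read round-trips to
    bit-identical values.
    """
    os.makedirs(directory, exist_ok=True)
    cohort.participants.to_csv(os.path.join(directory, "participants.tsv"),
                               sep="\t", index=False, float_format="%.17g")
    cohort.events.to_csv(os.path.join(directory, "events.tsv"),
                         sep="\t", index=False, float_format="%.17g")
    if cohort.config is not None:
        cohort.config.to_yaml(os.path.join(directory, "config.yaml"))


def read_cohort(directory: str | os.PathLike) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    participants = pd.read_csv(os.path.join(directory, "participants.tsv"), sep="\t")
    events = pd.read_csv(os.path.join(directory, "events.tsv"), sep="\t")
    if events.empty:
        events = events.astype({"id": int, "icd10": object, "age": float})
    cfg_path = os.path.join(directory, "config.yaml")
    config = SimulationConfig.from_yaml(cfg_path) if os.path.exists(cfg_path) else None
    return Cohort(participants=participants, events=events, config=config)
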