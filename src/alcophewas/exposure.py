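"""Derivation of drinking exposures from questionnaire fields.

Implements the standard biobank questionnaire algebra: drinker-status
classification from past-year frequency and past weekly drinking, weekly
grams of ethanol from per-beverage typical-day volumes, sex-specific
consumption categories, drinking-pattern flags, the McMahon-Peto
regression-dilution ratio from resurvey measurements, and group-level usual
intake.

Weekly grams are computed as ``f x sum_b(volume_b x vv_b x rho)`` where
``f`` is the drinking frequency in days/week (median of the reported
interval: 1.5, 4 or 6.5), ``vv_b`` the alcohol content by volume (beer 4%,
grape wine 12%, rice wine 15%, weak spirits 38%, strong spirits 53%) and
``rho`` the density of ethanol (0.79 g/ml by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import EstimationError, ValidationError

__all__ = [
    "FREQUENCY_DAYS",
    "ALCOHOL_BY_VOLUME",
    "ETHANOL_DENSITY",
    "classify_drinker_status",
    "weekly_alcohol_grams",
    "assign_intake_category",
    "flag_drinking_patterns",
    "derive_exposure",
    "estimate_regression_dilution_ratio",
    "usual_intake_by_group",
    "RegressionDilutionResult",
]

#: Days/week for each weekly frequency category (median of the interval).
FREQUENCY_DAYS = {"weekly_1_2": 1.5, "weekly_3_5": 4.0, "weekly_6_7": 6.5}

#: Alcohol content by volume per beverage.
ALCOHOL_BY_VOLUME = {
    "beer": 0.04,
    "grape_wine": 0.12,
    "rice_wine": 0.15,
    "weak_spirits": 0.38,
    "strong_spirits": 0.53,
}

#: Ethanol mass density in g/ml (0.789 rounded; configurable per call).
ETHANOL_DENSITY = 0.79

_WEEKLY = set(FREQUENCY_DAYS)
_LESS_THAN_WEEKLY = {"occasional", "certain_seasons", "monthly"}

# Men: four categories; women: three. Upper boundaries are left-closed
# (140 g/week in a man falls in "140-279").
MALE_CATEGORY_EDGES = (140.0, 280.0, 420.0)
MALE_CATEGORY_LABELS = ("<140", "140-279", "280-419", "420+")
FEMALE_CATEGORY_EDGES = (70.0, 140.0)
FEMALE_CATEGORY_LABELS = ("<70", "70-139", "140+")

#: Heavy-episodic thresholds (strictly greater than), g per occasion.
HEAVY_EPISODIC_THRESHOLD = {"M": 60.0, "F": 40.0}


def classify_drinker_status(freq_category, past_weekly):
    """Classify drinker status from past-year frequency and past history.

    Weekly drinking in the past year -> ``current``; less than weekly (or
    never) in the past year but weekly in the past -> ``ex``; drank in the
    past year but less than weekly, never weekly before -> ``occasional``;
    never in the past year and never weekly -> ``non``. A missing
    past-weekly flag when it is needed yields ``unclassifiable``.

    Accepts scalars or array-likes; returns the same shape.
    """
    freq = np.asarray(freq_category, dtype=object)
    scalar = freq.ndim == 0
    freq = np.atleast_1d(freq)
    pw = np.atleast_1d(np.asarray(past_weekly, dtype=object))
    out = np.full(freq.shape, "unclassifiable", dtype=object)
    is_weekly = np.isin(freq, list(_WEEKLY))
    out[is_weekly] = "current"
    known_pw = np.array([p is not None and p == p for p in pw])  # not None/NaN
    pw_true = np.zeros(freq.shape, dtype=bool)
    pw_true[known_pw] = np.array([bool(p) for p in pw[known_pw]])
    out[~is_weekly & known_pw & pw_true] = "ex"
    less = np.isin(freq, list(_LESS_THAN_WEEKLY))
    out[~is_weekly & known_pw & ~pw_true & less] = "occasional"
    out[~is_weekly & known_pw & ~pw_true & (freq == "never")] = "non"
    return out[0] if scalar else out


def weekly_alcohol_grams(freq_category, volumes, density: float = ETHANOL_DENSITY):
    """Weekly grams of ethanol from frequency and typical-day volumes.

    Parameters
    ----------
    freq_category : str or array-like
        A weekly frequency category (``weekly_1_2``/``weekly_3_5``/
        ``weekly_6_7``).
    volumes : mapping or DataFrame
        Per-beverage typical-drinking-day volumes in ml, keyed/named
        ``beer``, ``grape_wine``, ``rice_wine``, ``weak_spirits``,
        ``strong_spirits``. Missing beverages count as zero.
    density : float
        Ethanol density in g/ml.

    Returns 0 when every volume is 0. Negative volumes are rejected.
    """
    freq = np.atleast_1d(np.asarray(freq_category, dtype=object))
    scalar = np.asarray(freq_category, dtype=object).ndim == 0
    f = np.array([FREQUENCY_DAYS.get(c, np.nan) for c in freq])
    total = np.zeros(freq.shape)
    for bev, vv in ALCOHOL_BY_VOLUME.items():
        if isinstance(volumes, pd.DataFrame):
            v = volumes.get(f"vol_{bev}", volumes.get(bev))
            v = np.zeros(freq.shape) if v is None else np.asarray(v, float)
        else:
            v = np.atleast_1d(np.asarray(volumes.get(bev, 0.0), dtype=float))
            if v.shape != freq.shape:
                v = np.broadcast_to(v, freq.shape)
        if np.any(v < 0):
            raise ValidationError(f"negative volume for beverage {bev!r}")
        total = total + np.nan_to_num(v) * vv
    grams = f * total * density
    return float(grams[0]) if scalar else grams


def assign_intake_category(g_per_week, sex):
    """Sex-specific consumption category for a current drinker.

    Men: <140, 140-279, 280-419, 420+ g/week; women: <70, 70-139, 140+.
    """
    g = np.atleast_1d(np.asarray(g_per_week, dtype=float))
    scalar = np.asarray(g_per_week).ndim == 0
    if np.any(g < 0):
        raise ValidationError("negative weekly intake")
    sx = np.broadcast_to(np.atleast_1d(np.asarray(sex, dtype=object)), g.shape)
    out = np.empty(g.shape, dtype=object)
    male = sx == "M"
    out[male] = np.array(MALE_CATEGORY_LABELS, dtype=object)[
        np.searchsorted(MALE_CATEGORY_EDGES, g[male], side="right")]
    out[~male] = np.array(FEMALE_CATEGORY_LABELS, dtype=object)[
        np.searchsorted(FEMALE_CATEGORY_EDGES, g[~male], side="right")]
    return out[0] if scalar else out


@dataclass
class DrinkingPatterns:
    heavy_episodic: bool
    daily: bool
    outside_meals: bool
    spirit_drinker: bool
    duration_years: float


def flag_drinking_patterns(per_occasion_g, sex, freq_category, mealtime,
                           spirit_volume, age_baseline, age_started):
    """Drinking-pattern flags for a current drinker.

    heavy-episodic is strictly greater than 60 g/occasion in men and 40 in
    women; daily means the 6-7 d/week frequency category; outside-meals
    means usually drinking between/after meals or with no regular pattern;
    spirit drinker means any positive weak/strong spirits volume; duration
    is baseline age minus age started drinking.
    """
    age_b = np.atleast_1d(np.asarray(age_baseline, float))
    age_s = np.atleast_1d(np.asarray(age_started, float))
    if np.any(age_s[~np.isnan(age_s)] > age_b[~np.isnan(age_s)]):
        raise ValidationError("age started drinking exceeds baseline age")
    sx = np.atleast_1d(np.asarray(sex, dtype=object))
    thr = np.where(sx == "M", HEAVY_EPISODIC_THRESHOLD["M"], HEAVY_EPISODIC_THRESHOLD["F"])
    occ = np.atleast_1d(np.asarray(per_occasion_g, float))
    heavy = occ > thr
    daily = np.atleast_1d(np.asarray(freq_category, dtype=object)) == "weekly_6_7"
    outside = np.isin(np.atleast_1d(np.asarray(mealtime, dtype=object)),
                      ["between_after", "no_pattern"])
    spirit = np.atleast_1d(np.asarray(spirit_volume, float)) > 0
    duration = age_b - age_s
    if np.asarray(per_occasion_g).ndim == 0:
        return DrinkingPatterns(bool(heavy[0]), bool(daily[0]), bool(outside[0]),
                                bool(spirit[0]), float(duration[0]))
    return pd.DataFrame({
        "heavy_episodic": heavy, "daily": daily, "outside_meals": outside,
        "spirit_drinker": spirit, "duration_years": duration,
    })


def derive_exposure(participants: pd.DataFrame,
                    density: float = ETHANOL_DENSITY) -> pd.DataFrame:
    """Per-participant exposure table from a participants table.

    Returns a DataFrame indexed like ``participants`` with columns
    ``status``, ``ever_regular``, ``g_per_week``, ``category``,
    ``heavy_episodic``, ``daily``, ``outside_meals``, ``spirit_drinker``
    and ``duration_years``. Weekly grams are zero for anyone who is not a
    current drinker; the category is ``"."`` for them.
    """
    p = participants
    status = classify_drinker_status(p["freq_category"].to_numpy(),
                                     p["past_weekly"].to_numpy())
    current = status == "current"
    grams = np.zeros(len(p))
    if current.any():
        sub = p.loc[current]
        grams[current] = weekly_alcohol_grams(
            sub["freq_category"].to_numpy(),
            sub[[f"vol_{b}" for b in ALCOHOL_BY_VOLUME]], density)
    category = np.full(len(p), ".", dtype=object)
    category[current] = assign_intake_category(grams[current],
                                               p.loc[current, "sex"].to_numpy())
    thr = np.where(p["sex"].to_numpy() == "M",
                   HEAVY_EPISODIC_THRESHOLD["M"], HEAVY_EPISODIC_THRESHOLD["F"])
    per_occ = p["per_occasion_g"].to_numpy(dtype=float)
    spirit_vol = (p["vol_weak_spirits"].to_numpy(float)
                  + p["vol_strong_spirits"].to_numpy(float))
    out = pd.DataFrame({
        "id": p["id"].to_numpy(),
        "status": status,
        "ever_regular": (status == "ex") | current,
        "g_per_week": grams,
        "category": category,
        "heavy_episodic": current & (per_occ > thr),
        "daily": current & (p["freq_category"].to_numpy(dtype=object) == "weekly_6_7"),
        "outside_meals": current & np.isin(p["mealtime"].to_numpy(dtype=object),
                                           ["between_after", "no_pattern"]),
        "spirit_drinker": current & (spirit_vol > 0),
        "duration_years": np.where(
            current | (status == "ex"),
            p["age_baseline"].to_numpy(float) - p["age_started"].to_numpy(float),
            np.nan),
    }, index=p.index)
    return out


@dataclass
class RegressionDilutionResult:
    """McMahon-Peto regression-dilution ratio with a bootstrap CI."""

    ratio: float
    ci_lower: float
    ci_upper: float
    n: int
    n_groups: int

    def __float__(self):
        return self.ratio


def estimate_regression_dilution_ratio(baseline, resurvey, n_groups: int = 5,
                                       n_boot: int = 200,
                                       seed: int = 0) -> RegressionDilutionResult:
    """McMahon-Peto estimate of the regression-dilution ratio.

    Participants (current drinkers at baseline with a resurvey measure) are
    partitioned into ``n_groups`` quantile groups of baseline intake; the
    ratio is the least-squares slope of group-mean resurvey intake on
    group-mean baseline intake. The estimator is invariant to rescaling all
    intakes by a common factor.
    """
    b = np.asarray(baseline, dtype=float)
    r = np.asarray(resurvey, dtype=float)
    keep = ~(np.isnan(b) | np.isnan(r))
    b, r = b[keep], r[keep]
    if len(b) < 2 or len(np.unique(b)) < n_groups:
        raise EstimationError(
            f"need >= {n_groups} distinct baseline values, got {len(np.unique(b))}")

    def slope(bv, rv):
        groups = pd.qcut(bv, n_groups, labels=False, duplicates="drop")
        gb = pd.DataFrame({"b": bv, "r": rv, "g": groups}).groupby("g").mean()
        if len(gb) < 2:
            raise EstimationError("fewer than 2 baseline-intake groups with data")
        x = gb["b"].to_numpy()
        y = gb["r"].to_numpy()
        x = x - x.mean()
        return float(np.sum(x * (y - y.mean())) / np.sum(x * x))

    est = slope(b, r)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(b), len(b))
        try:
            boots.append(slope(b[idx], r[idx]))
        except EstimationError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = np.nan
    return RegressionDilutionResult(est, float(lo), float(hi), len(b), n_groups)


def usual_intake_by_group(categories, resurvey) -> pd.Series:
    """Mean resurvey (usual) intake per baseline consumption category.

    Categories with no resurveyed member are returned as NaN so callers can
    flag and exclude them (e.g. when plotting category hazard ratios against
    usual intake).
    """
    df = pd.DataFrame({"category": np.asarray(categories, dtype=object),
                       "resurvey": np.asarray(resurvey, dtype=float)})
    means = df.groupby("category", sort=False)["resurvey"].mean()
    means.name = "usual_intake"
    return means
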