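"""Genotype-area instrument and Mendelian-randomization estimators.

Two biallelic variants that strongly alter alcohol metabolism give nine
genotype combinations; crossed with the study areas they define
genotype-area cells whose *male* mean alcohol intake (current drinkers at
their reported g/week, occasional drinkers at 5 g/week, non-drinkers at 0,
ex-drinkers excluded) spans a wide range. Cells are collapsed into six
ordinal categories C1-C6 at mean-intake cutoffs of 10, 25, 50, 100 and 150
g/week (left-closed upper intervals). Every genotyped participant —
including ex-drinkers and women — is assigned a category from genotype and
area alone, never from individual drinking reports.

Causal dose-response slopes are estimated within each study area by
meta-regression of floated category log hazard ratios on category mean male
intake, then combined across areas by inverse-variance weighting; this
area stratification removes confounding by population structure. Genotypic
effects in women (whose drinking is negligible in every category) probe
pleiotropy via a chi-squared sex-heterogeneity test on the slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._errors import EstimationError
from .coxfit import (StratifiedCoxModel, FloatedEstimates,
                     fit_categorical_profile, lexis_expand)
from .endpoints import EndpointDefinition, extract_first_events

__all__ = [
    "CATEGORY_CUTOFFS",
    "derive_genetic_instrument",
    "InstrumentResult",
    "GenotypeAreaMR",
    "MRResults",
    "sex_heterogeneity_test",
    "two_stage_least_squares",
    "TSLSResult",
]

#: Cell-mean cutoffs (g/week) between categories C1..C6; left-closed above.
CATEGORY_CUTOFFS = (10.0, 25.0, 50.0, 100.0, 150.0)


@dataclass
class InstrumentResult:
    """Genotype-area instrument: cell table and per-participant assignment."""

    assignments: pd.DataFrame  # id, combo, area, cell_mean, category
    cells: pd.DataFrame        # combo, area, cell_mean, n_men, category, pooled

    def category_means(self, areas=None) -> pd.Series:
        """Mean male intake per category (over men, optionally one area)."""
        a = self.assignments
        a = a[a["male_eligible"]]
        if areas is not None:
            a = a[a["area"].isin(np.atleast_1d(areas))]
        return a.groupby("category")["cell_mean"].mean()


def derive_genetic_instrument(participants: pd.DataFrame, exposure: pd.DataFrame,
                              male_subset=None,
                              cutoffs=CATEGORY_CUTOFFS,
                              occasional_intake: float = 5.0) -> InstrumentResult:
    """Build the genotype-area instrument and assign every participant.

    Cell means are computed from men only (optionally a designated random
    male subset), taking current drinkers at their reported weekly grams,
    occasional drinkers at ``occasional_intake`` and non-drinkers at 0;
    ex-drinkers are excluded from the means because their baseline intake
    does not reflect long-term intake, but they (and all women) are still
    assigned a category from their genotype-area cell. Cells with no
    eligible men borrow the mean of the same genotype combination pooled
    across areas (flagged ``pooled``).
    """
    p = participants.merge(exposure[["id", "status", "g_per_week"]], on="id")
    p["combo"] = p["genotype_l1"] + "/" + p["genotype_l2"]

    men = p[p["sex"] == "M"]
    if male_subset is not None:
        men = men[men["id"].isin(male_subset)]
    eligible = men[men["status"] != "ex"].copy()
    eligible["intake"] = np.select(
        [eligible["status"] == "current", eligible["status"] == "occasional"],
        [eligible["g_per_week"], occasional_intake], default=0.0)

    grp = eligible.groupby(["combo", "area"])["intake"]
    cell = grp.mean().rename("cell_mean").reset_index()
    cell["n_men"] = grp.size().to_numpy()
    cell["pooled"] = False

    combos = sorted(p["combo"].unique())
    areas = sorted(p["area"].unique())
    full = pd.MultiIndex.from_product([combos, areas], names=["combo", "area"])
    cell = cell.set_index(["combo", "area"]).reindex(full).reset_index()
    missing = cell["cell_mean"].isna()
    if missing.any():
        combo_mean = eligible.groupby("combo")["intake"].mean()
        fill = cell.loc[missing, "combo"].map(combo_mean)
        fill = fill.fillna(eligible["intake"].mean())
        cell.loc[missing, "cell_mean"] = fill
        cell.loc[missing, "n_men"] = 0
        cell.loc[missing, "pooled"] = True
        warnings.warn(f"{int(missing.sum())} empty genotype-area cell(s) "
                      "assigned the pooled same-genotype mean")
    cell["n_men"] = cell["n_men"].astype(int)
    cell["category"] = ["C" + str(k + 1) for k in
                        np.searchsorted(np.asarray(cutoffs),
                                        cell["cell_mean"].to_numpy(),
                                        side="right")]

    assign = p[["id", "sex", "area", "combo", "status"]].merge(
        cell[["combo", "area", "cell_mean", "category"]], on=["combo", "area"])
    assign["male_eligible"] = ((assign["sex"] == "M")
                               & (assign["status"] != "ex"))
    assign = assign.drop(columns="status").sort_values("id").reset_index(drop=True)
    return InstrumentResult(assignments=assign, cells=cell)


# ---------------------------------------------------------------------------
# genotypic category fits and IVW slope combination
# ---------------------------------------------------------------------------

def _category_profile(surv, subset, n_pcs, strata_cols, reference):
    pc_cols = [f"pc{j}" for j in range(1, n_pcs + 1)]
    df = surv.merge(subset[["id", "area", "category"] + pc_cols], on="id")
    sl = lexis_expand(df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_categorical_profile(sl, "category", reference,
                                       covariate_cols=pc_cols,
                                       strata_cols=strata_cols)


@dataclass
class MRResults:
    """Combined genotypic dose-response slope and per-area detail."""

    slope: float                 # log HR per g/week genotype-predicted intake
    se: float
    method: str
    endpoint: str
    sex: str
    area_slopes: pd.DataFrame = field(repr=False)
    floated: FloatedEstimates | None = field(default=None, repr=False)
    n_events: int = 0

    @property
    def hr_per_280(self) -> float:
        return float(np.exp(280.0 * self.slope))

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return (float(np.exp(280.0 * (self.slope - z * self.se))),
                float(np.exp(280.0 * (self.slope + z * self.se))))

    @property
    def pvalue(self) -> float:
        return float(2 * stats.norm.sf(abs(self.slope / self.se)))

    def summary(self) -> pd.Series:
        lo, hi = self.conf_int()
        return pd.Series({
            "endpoint": self.endpoint, "sex": self.sex, "method": self.method,
            "slope_per_g_week": self.slope, "se": self.se,
            "HR_per_280g": self.hr_per_280, "ci_lower": lo, "ci_upper": hi,
            "p": self.pvalue, "n_events": self.n_events,
            "n_areas": len(self.area_slopes),
        })


def _weighted_slope(x, y, var):
    """Meta-regression slope (free intercept) with known variances."""
    w = 1.0 / np.asarray(var, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar = np.sum(w * x) / np.sum(w)
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx <= 0:
        raise EstimationError("degenerate category means in meta-regression")
    slope = np.sum(w * (x - xbar) * y) / sxx
    return float(slope), float(np.sqrt(1.0 / sxx))


def _gls_slope(x, y, V):
    """Meta-regression slope using the full conventional covariance.

    The reference level (log HR fixed at 0 with no variance row) is pinned:
    the regression runs on non-reference contrasts with the reference's
    category mean absorbed into the intercept via centering.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones(len(x)), x])
    Vi = np.linalg.inv(V)
    A = np.linalg.inv(X.T @ Vi @ X)
    coef = A @ (X.T @ Vi @ y)
    return float(coef[1]), float(np.sqrt(A[1, 1]))


class GenotypeAreaMR:
    """Mendelian-randomization model for one endpoint.

    Parameters
    ----------
    participants, events : DataFrame
        Cohort tables.
    endpoint : EndpointDefinition
        Outcome endpoint.
    instrument : InstrumentResult
        Output of :func:`derive_genetic_instrument`.
    sex : str
        Sex analyzed (the instrument's category means are male regardless).
    n_pcs : int
        Number of genomic principal components adjusted for.
    restrict_non_drinkers : bool
        Sensitivity for women: keep only non-drinkers, removing any
        residual genotype effect on female intake.
    """

    def __init__(self, participants, events, endpoint: EndpointDefinition,
                 instrument: InstrumentResult, sex: str = "M", n_pcs: int = 11,
                 restrict_non_drinkers: bool = False, exposure=None,
                 weight: str = "floated"):
        subset = participants[participants["sex"] == sex].copy()
        if restrict_non_drinkers:
            if exposure is None:
                raise EstimationError("restrict_non_drinkers needs the exposure table")
            non_ids = set(exposure.loc[exposure["status"] == "non", "id"])
            subset = subset[subset["id"].isin(non_ids)]
        self.participants = subset.merge(
            instrument.assignments[["id", "category", "cell_mean"]], on="id")
        self.events = events
        self.endpoint = endpoint
        self.instrument = instrument
        self.sex = sex
        self.n_pcs = n_pcs
        if weight not in ("floated", "conventional"):
            raise ValueError("weight must be 'floated' or 'conventional'")
        self.weight = weight

    def fit(self, method: str = "area_stratified") -> MRResults:
        """Estimate the genotypic dose-response slope.

        ``area_stratified`` (default): per-area meta-regressions of floated
        category log HRs on area-specific category mean male intake,
        combined by inverse-variance weighting. ``area_adjusted``: one
        pooled fit stratified by age band x area. ``unstratified``: one
        pooled fit stratified by age band only — deliberately exposed to
        population-structure confounding, for comparison.
        """
        surv = extract_first_events(self.events, self.endpoint, self.participants)
        n_events = int(surv["event"].sum())
        if method == "area_stratified":
            rows = []
            for area, sub in self.participants.groupby("area"):
                cats = sorted(sub["category"].unique())
                if len(cats) < 2:
                    continue
                means = self.instrument.category_means(areas=[area])
                ref = means.loc[means.index.isin(cats)].idxmin()
                try:
                    fl, res = _category_profile(surv, sub, self.n_pcs,
                                                ("age_band",), ref)
                    s, se = self._slope_from_profile(fl, means)
                except (EstimationError, np.linalg.LinAlgError):
                    continue
                rows.append({"area": area, "slope": s, "se": se,
                             "n_categories": len(fl.levels),
                             "n_events": int(surv.merge(sub[["id"]], on="id")
                                             ["event"].sum())})
            area_df = pd.DataFrame(rows)
            if area_df.empty:
                raise EstimationError("no area provided an estimable slope")
            w = 1.0 / area_df["se"] ** 2
            slope = float(np.sum(w * area_df["slope"]) / np.sum(w))
            se = float(np.sqrt(1.0 / np.sum(w)))
            return MRResults(slope=slope, se=se, method=method,
                             endpoint=self.endpoint.endpoint_id, sex=self.sex,
                             area_slopes=area_df, n_events=n_events)
        if method in ("area_adjusted", "unstratified"):
            strata = ("age_band", "area") if method == "area_adjusted" \
                else ("age_band",)
            means = self.instrument.category_means()
            cats = sorted(self.participants["category"].unique())
            ref = means.loc[means.index.isin(cats)].idxmin()
            fl, res = _category_profile(surv, self.participants, self.n_pcs,
                                        strata, ref)
            slope, se = self._slope_from_profile(fl, means)
            area_df = pd.DataFrame([{"area": "all", "slope": slope, "se": se,
                                     "n_categories": len(fl.levels),
                                     "n_events": n_events}])
            return MRResults(slope=slope, se=se, method=method,
                             endpoint=self.endpoint.endpoint_id, sex=self.sex,
                             area_slopes=area_df, floated=fl, n_events=n_events)
        raise ValueError(f"unknown method {method!r}")

    def _slope_from_profile(self, fl, means):
        if self.weight == "floated":
            x = means.loc[fl.levels].to_numpy()
            return _weighted_slope(x, fl.log_hr, fl.var_floated)
        # conventional: full-covariance GLS over non-reference contrasts
        x = means.loc[fl.levels[1:]].to_numpy()
        return _gls_slope(x, fl.log_hr[1:], fl.cov)

    def category_hrs(self) -> FloatedEstimates:
        """Floated category log HRs (reference = lowest-mean category),
        from the pooled age-band x area stratified fit."""
        surv = extract_first_events(self.events, self.endpoint, self.participants)
        means = self.instrument.category_means()
        cats = sorted(self.participants["category"].unique())
        ref = means.loc[means.index.isin(cats)].idxmin()
        fl, _ = _category_profile(surv, self.participants, self.n_pcs,
                                  ("age_band", "area"), ref)
        return fl


def sex_heterogeneity_test(slope_men: float, se_men: float,
                           slope_women: float, se_women: float):
    """1-df chi-squared comparison of male and female genotypic slopes.

    Returns ``(chi2, p)``; identical slopes give chi2 = 0, p = 1.
    """
    if not (np.isfinite(se_men) and np.isfinite(se_women)):
        raise EstimationError("both slope standard errors are required")
    chi2 = (slope_men - slope_women) ** 2 / (se_men ** 2 + se_women ** 2)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# two-stage least squares
# ---------------------------------------------------------------------------

@dataclass
class TSLSResult:
    log_hr_per_280: float
    se: float
    first_stage_f: float
    weak_instrument: bool
    n_boot: int

    @property
    def hr_per_280(self) -> float:
        return float(np.exp(self.log_hr_per_280))

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return (float(np.exp(self.log_hr_per_280 - z * self.se)),
                float(np.exp(self.log_hr_per_280 + z * self.se)))


def two_stage_least_squares(participants, events, endpoint, instrument,
                            exposure, sex: str = "M", n_pcs: int = 11,
                            occasional_intake: float = 5.0,
                            n_boot: int = 100, seed: int = 0) -> TSLSResult:
    """Two-stage least-squares MR estimate for one endpoint.

    Stage 1 regresses baseline intake (current drinkers at reported g/week,
    occasional at 5, non-drinkers at 0; ex-drinkers excluded) on the
    genetic category indicators plus area and genomic PCs, and reports the
    joint F statistic of the category terms (instrument relevance; F < 10
    flags a weak instrument). Stage 2 fits the stratified Cox model on the
    genotype-predicted intake for *all* participants of the analyzed sex.
    Standard errors come from a participant-level bootstrap re-running both
    stages.
    """
    pc_cols = [f"pc{j}" for j in range(1, n_pcs + 1)]
    p = participants[participants["sex"] == sex].merge(
        instrument.assignments[["id", "category"]], on="id").merge(
        exposure[["id", "status", "g_per_week"]], on="id")
    p["intake"] = np.select(
        [p["status"] == "current", p["status"] == "occasional"],
        [p["g_per_week"], occasional_intake], default=0.0)
    # first-event data are per-participant; merge once so the bootstrap can
    # resample whole rows
    surv = extract_first_events(events, endpoint,
                                participants[participants["sex"] == sex])
    p = p.merge(surv, on="id")

    def one_pass(pp):
        st1 = pp[pp["status"] != "ex"]
        cat_d = pd.get_dummies(st1["category"], prefix="cat", drop_first=True,
                               dtype=float)
        area_d = pd.get_dummies(st1["area"], prefix="area", drop_first=True,
                                dtype=float)
        X1 = sm.add_constant(pd.concat([cat_d, area_d, st1[pc_cols]], axis=1))
        ols = sm.OLS(st1["intake"].to_numpy(), X1.to_numpy()).fit()
        names = list(X1.columns)
        contrast = np.zeros((cat_d.shape[1], len(names)))
        for i, c in enumerate(cat_d.columns):
            contrast[i, names.index(c)] = 1.0
        fval = float(ols.f_test(contrast).fvalue)
        # predict for everyone (including ex-drinkers) from category/area/PCs
        cat_all = pd.get_dummies(pp["category"], prefix="cat", dtype=float)
        area_all = pd.get_dummies(pp["area"], prefix="area", dtype=float)
        Xall = pd.DataFrame({"const": 1.0, **{c: cat_all.get(c, 0.0) for c in cat_d},
                             **{c: area_all.get(c, 0.0) for c in area_d}},
                            index=pp.index)
        Xall = pd.concat([Xall, pp[pc_cols]], axis=1)
        pred = Xall.to_numpy() @ ols.params
        df = pp[["entry_age", "exit_age", "event", "area"] + pc_cols].assign(
            pred=pred / 280.0)
        sl = lexis_expand(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = StratifiedCoxModel.from_dataframe(
                sl, exposure_cols=["pred"], covariate_cols=pc_cols).fit()
        return float(res.params["pred"]), fval

    est, fval = one_pass(p)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(p), len(p))
        bp = p.iloc[idx].reset_index(drop=True)
        try:
            boots.append(one_pass(bp)[0])
        except (EstimationError, np.linalg.LinAlgError):
            continue
    se = float(np.std(boots, ddof=1)) if len(boots) >= 2 else np.nan
    weak = fval < 10
    if weak:
        warnings.warn(f"weak instrument: first-stage F = {fval:.2f} < 10")
    return TSLSResult(log_hr_per_280=est, se=se, first_stage_f=fval,
                      weak_instrument=weak, n_boot=len(boots))
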