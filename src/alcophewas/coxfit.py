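"""Stratified proportional-hazards estimation on the age scale.

The central model is a Cox proportional-hazards fit with age as the
underlying time scale, delayed entry at baseline (left truncation), Efron
handling of tied event ages, and baseline hazards stratified by 5-year
age-at-risk band x study area. Follow-up is first split at band boundaries
(:func:`lexis_expand`), so each risk interval lies inside one stratum.

On top of the fit sit the epidemiological conveniences used throughout the
analyses: floating absolute risks (a variance attribution giving every
exposure level, including the reference, its own confidence interval),
regression-dilution correction of dose-response estimates, and chi-squared
heterogeneity/trend tests across subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._errors import (ConfigurationError, ConvergenceError, EstimationError,
                      ValidationError)

__all__ = [
    "lexis_expand",
    "StratifiedCoxModel",
    "StratifiedCoxResults",
    "FloatedEstimates",
    "float_absolute_risks",
    "DoseResponseResult",
    "dose_response_corrected",
    "SubgroupTests",
    "subgroup_heterogeneity_trend",
    "fit_categorical_profile",
    "encode_covariates",
]


# ---------------------------------------------------------------------------
# Lexis expansion
# ---------------------------------------------------------------------------

def lexis_expand(df: pd.DataFrame, band_width: float = 5.0,
                 window: tuple[float, float] = (35.0, 85.0),
                 entry_col: str = "entry_age", exit_col: str = "exit_age",
                 event_col: str = "event") -> pd.DataFrame:
    """Split follow-up at age-band boundaries.

    Each input row (entry, exit] is split into one row per crossed band;
    the event indicator is kept only on the slice containing the event age.
    Total person-time is conserved. All other columns are carried through.
    Adds an integer ``age_band`` column (0 = first band of the window).
    """
    lo, hi = window
    if not (35.0 <= lo < hi <= 85.0):
        raise ConfigurationError(f"age window {window} outside [35, 85)")
    entry = np.maximum(df[entry_col].to_numpy(float), lo)
    exit_ = np.minimum(df[exit_col].to_numpy(float), hi)
    keep = exit_ > entry
    df = df.loc[keep]
    entry, exit_ = entry[keep], exit_[keep]
    event = df[event_col].to_numpy().astype(bool)

    k_lo = np.floor((entry - lo) / band_width).astype(int)
    k_hi = np.ceil((exit_ - lo) / band_width).astype(int) - 1
    k_hi = np.maximum(k_hi, k_lo)
    counts = k_hi - k_lo + 1
    reps = np.repeat(np.arange(len(df)), counts)
    offs = np.repeat(np.cumsum(counts) - counts, counts)
    s = np.arange(counts.sum()) - offs          # slice index within person
    band = k_lo[reps] + s
    slice_entry = np.maximum(entry[reps], lo + band * band_width)
    slice_exit = np.minimum(exit_[reps], lo + (band + 1) * band_width)
    last = s == (counts[reps] - 1)

    out = df.iloc[reps].copy()
    out[entry_col] = slice_entry
    out[exit_col] = slice_exit
    out[event_col] = (event[reps] & last).astype(int)
    out["age_band"] = band
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Efron partial likelihood machinery
# ---------------------------------------------------------------------------

class _StratumData:
    """Precomputed per-stratum structures for likelihood evaluation."""

    __slots__ = ("X", "entry", "exit", "n", "exit_order", "entry_order",
                 "exit_sorted", "entry_sorted", "ev_rows", "ev_inv", "ev_d",
                 "uniq_times", "rep_k", "frac", "n_events")

    def __init__(self, entry, exit_, event, X):
        self.X = X
        self.entry = entry
        self.exit = exit_
        self.n = len(entry)
        self.exit_order = np.argsort(exit_, kind="mergesort")
        self.entry_order = np.argsort(entry, kind="mergesort")
        self.exit_sorted = exit_[self.exit_order]
        self.entry_sorted = entry[self.entry_order]
        self.ev_rows = np.flatnonzero(event)
        times = exit_[self.ev_rows]
        order = np.argsort(times, kind="mergesort")
        self.ev_rows = self.ev_rows[order]
        self.uniq_times, self.ev_inv, self.ev_d = np.unique(
            times[order], return_inverse=True, return_counts=True)
        self.n_events = len(self.ev_rows)
        d = self.ev_d
        self.rep_k = np.repeat(np.arange(len(d)), d)
        self.frac = (np.arange(d.sum()) - np.repeat(np.cumsum(d) - d, d)) / d[self.rep_k]

    def _suffix(self, values_sorted_by, arr):
        """Prefix-cumsum array with a leading zero row, for suffix lookups."""
        c = np.concatenate([np.zeros((1,) + arr.shape[1:]), np.cumsum(arr, axis=0)])
        return c

    def loglik_grad_info(self, beta, want_derivs=True):
        X, p = self.X, self.X.shape[1]
        eta = X @ beta
        c = eta.max() if len(eta) else 0.0
        r = np.exp(eta - c)
        rX = r[:, None] * X

        u = self.uniq_times
        # risk sums: rows with exit >= u minus rows with entry >= u
        cx_r = np.concatenate([[0.0], np.cumsum(r[self.exit_order])])
        ce_r = np.concatenate([[0.0], np.cumsum(r[self.entry_order])])
        px = np.searchsorted(self.exit_sorted, u, side="left")
        pe = np.searchsorted(self.entry_sorted, u, side="left")
        tot_r = cx_r[-1]
        S0 = (tot_r - cx_r[px]) - (ce_r[-1] - ce_r[pe])

        ev = self.ev_rows
        inv = self.ev_inv
        s0d = np.bincount(inv, weights=r[ev], minlength=len(u))
        rep, frac = self.rep_k, self.frac
        denom = S0[rep] - frac * s0d[rep]
        ll = float(np.sum(eta[ev]) - np.sum(np.log(denom) + c))
        if not want_derivs:
            return ll, None, None

        cx_rX = np.concatenate([np.zeros((1, p)), np.cumsum(rX[self.exit_order], axis=0)])
        ce_rX = np.concatenate([np.zeros((1, p)), np.cumsum(rX[self.entry_order], axis=0)])
        S1 = (cx_rX[-1] - cx_rX[px]) - (ce_rX[-1] - ce_rX[pe])
        s1d = np.zeros((len(u), p))
        np.add.at(s1d, inv, rX[ev])

        rXX = rX[:, :, None] * X[:, None, :]
        cx_rXX = np.concatenate([np.zeros((1, p, p)),
                                 np.cumsum(rXX[self.exit_order], axis=0)])
        ce_rXX = np.concatenate([np.zeros((1, p, p)),
                                 np.cumsum(rXX[self.entry_order], axis=0)])
        S2 = (cx_rXX[-1] - cx_rXX[px]) - (ce_rXX[-1] - ce_rXX[pe])
        s2d = np.zeros((len(u), p, p))
        np.add.at(s2d, inv, rXX[ev])

        num = S1[rep] - frac[:, None] * s1d[rep]
        S2e = S2[rep] - frac[:, None, None] * s2d[rep]
        ratio = num / denom[:, None]
        grad = X[ev].sum(axis=0) - ratio.sum(axis=0)
        info = (S2e / denom[:, None, None]).sum(axis=0) \
            - np.einsum("mi,mj->ij", ratio, ratio)
        return ll, grad, info


class StratifiedCoxModel:
    """Cox proportional-hazards model with delayed entry and strata.

    Parameters
    ----------
    entry, exit, event : array-like
        Risk intervals (entry, exit] on the age scale and the event
        indicator at exit.
    X : (n, p) array or DataFrame
        Covariates. Constant columns are dropped with a warning.
    strata : array-like, optional
        Stratum labels; each stratum carries its own baseline hazard.
    names : sequence of str, optional
        Covariate names (taken from the DataFrame if given).
    """

    def __init__(self, entry, exit, event, X, strata=None, names=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        entry = np.asarray(entry, dtype=float)
        exit_ = np.asarray(exit, dtype=float)
        event = np.asarray(event).astype(bool)
        if np.any(exit_ <= entry):
            raise ValidationError("every risk interval needs exit > entry")
        if event.sum() < 1:
            raise EstimationError("no events: Cox model cannot be fitted")
        names = list(names) if names is not None else \
            [f"x{i}" for i in range(X.shape[1])]

        keep = X.std(axis=0) > 0
        self.dropped = [n for n, k in zip(names, keep) if not k]
        if self.dropped:
            warnings.warn(f"dropping constant covariate column(s): {self.dropped}")
        X = X[:, keep]
        if X.shape[1] == 0:
            raise EstimationError("no non-constant covariates to fit")
        self.names = [n for n, k in zip(names, keep) if k]
        self.n, self.p = X.shape
        self.n_events = int(event.sum())

        if strata is None:
            strata = np.zeros(self.n, dtype=int)
        codes, _ = pd.factorize(np.asarray(strata))
        self._strata_data = []
        for s in range(codes.max() + 1):
            m = codes == s
            if not event[m].any():
                continue  # event-free strata contribute nothing
            self._strata_data.append(_StratumData(entry[m], exit_[m], event[m], X[m]))
        self.n_strata = len(self._strata_data)
        if self.n_strata == 0:
            raise EstimationError("no stratum contains an event")

    def loglik(self, beta) -> float:
        """Stratified Efron partial log-likelihood at ``beta``."""
        beta = np.asarray(beta, dtype=float)
        return sum(s.loglik_grad_info(beta, want_derivs=False)[0]
                   for s in self._strata_data)

    def _eval(self, beta):
        ll, g, i = 0.0, np.zeros(self.p), np.zeros((self.p, self.p))
        for s in self._strata_data:
            l, gs, js = s.loglik_grad_info(beta)
            ll += l
            g += gs
            i += js
        return ll, g, i

    def fit(self, tol: float = 1e-8, max_iter: int = 50) -> "StratifiedCoxResults":
        """Newton-Raphson maximization with step halving.

        Converges when the max-norm of the score drops below ``tol`` per
        event (the score scales with the number of events, and its
        floating-point noise with problem size), or when the Newton step
        becomes negligible. Raises :class:`ConvergenceError` with
        diagnostics otherwise.
        """
        beta = np.zeros(self.p)
        ll, g, info = self._eval(beta)
        score_tol = tol * max(1.0, self.n_events)
        for it in range(1, max_iter + 1):
            if np.max(np.abs(g)) < score_tol:
                break
            try:
                step = np.linalg.solve(info, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, g, rcond=None)[0]
            if np.max(np.abs(step)) < 1e-10:
                break
            for _ in range(30):
                cand = beta + step
                ll_new, g_new, info_new = self._eval(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-9 * abs(ll):
                    break
                step = step / 2.0
            else:
                raise ConvergenceError(
                    "step halving failed (possible separation)",
                    {"iterations": it, "loglik": ll,
                     "score_norm": float(np.max(np.abs(g)))})
            beta, ll, g, info = cand, ll_new, g_new, info_new
        else:
            raise ConvergenceError(
                f"no convergence in {max_iter} iterations",
                {"loglik": ll, "score_norm": float(np.max(np.abs(g)))})
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        return StratifiedCoxResults(
            params=pd.Series(beta, index=self.names),
            cov=pd.DataFrame(cov, index=self.names, columns=self.names),
            loglik=ll, n=self.n, n_events=self.n_events,
            n_strata=self.n_strata, n_iter=it, model=self)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, exposure_cols,
                       covariate_cols=(), entry_col="entry_age",
                       exit_col="exit_age", event_col="event",
                       strata_cols=("age_band", "area")):
        """Build a model from a (Lexis-expanded) survival DataFrame."""
        cols = list(exposure_cols) + list(covariate_cols)
        strata = None
        if strata_cols:
            strata = pd.factorize(
                pd.MultiIndex.from_frame(df[list(strata_cols)]))[0]
        return cls(df[entry_col].to_numpy(float), df[exit_col].to_numpy(float),
                   df[event_col].to_numpy(), df[cols], strata=strata, names=cols)


@dataclass
class StratifiedCoxResults:
    """Maximum-partial-likelihood estimates with inverse-information covariance."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    n: int
    n_events: int
    n_strata: int
    n_iter: int
    model: StratifiedCoxModel = field(repr=False)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "hr_lower": np.exp(self.params - z * self.bse),
            "hr_upper": np.exp(self.params + z * self.bse),
        })

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "coef": self.params,
            "se": self.bse,
            "HR": self.hazard_ratios(),
        }).join(self.conf_int()).assign(p=self.pvalues)
        return out


# ---------------------------------------------------------------------------
# floating absolute risks
# ---------------------------------------------------------------------------

@dataclass
class FloatedEstimates:
    """Per-level log hazard ratios with floated variances.

    ``levels`` starts with the reference (log HR fixed at 0). Floated
    variances attribute uncertainty to every level so that
    ``var(logHR_i - logHR_j) ~= lambda_i + lambda_j`` for all pairs,
    including pairs involving the reference.
    """

    levels: list[str]
    reference: str
    log_hr: np.ndarray
    var_conventional: np.ndarray
    var_floated: np.ndarray
    cov: np.ndarray
    method: str

    def se_floated(self) -> np.ndarray:
        return np.sqrt(self.var_floated)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.se_floated()
        return pd.DataFrame({
            "level": self.levels,
            "log_hr": self.log_hr,
            "se_floated": se,
            "HR": np.exp(self.log_hr),
            "hr_lower": np.exp(self.log_hr - z * se),
            "hr_upper": np.exp(self.log_hr + z * se),
        })

    def reconstruction_error(self) -> float:
        """Max relative error of floated pairwise-difference variances."""
        m = len(self.levels) - 1
        errs = []
        for i in range(m):
            d = self.var_conventional[i + 1]
            errs.append(abs((self.var_floated[0] + self.var_floated[i + 1] - d) / d))
            for j in range(i + 1, m):
                d = (self.var_conventional[i + 1] + self.var_conventional[j + 1]
                     - 2 * self.cov[i, j])
                if d > 0:
                    errs.append(abs((self.var_floated[i + 1]
                                     + self.var_floated[j + 1] - d) / d))
        return float(max(errs)) if errs else 0.0


def _minimax_floated(V: np.ndarray) -> np.ndarray:
    """Iterative fallback: minimize the max relative error in pairwise
    difference variances over positive floated variances."""
    m = V.shape[0]
    pairs = [(-1, i, V[i, i]) for i in range(m)]
    pairs += [(i, j, V[i, i] + V[j, j] - 2 * V[i, j])
              for i in range(m) for j in range(i + 1, m) if
              V[i, i] + V[j, j] - 2 * V[i, j] > 0]

    def objective(log_lam):
        lam = np.exp(log_lam)
        errs = [abs((lam[i + 1] + lam[j + 1] - d) / d) for i, j, d in pairs]
        return max(errs)

    lam0 = np.full(m + 1, max(np.mean(np.diag(V)) / 2, 1e-10))
    res = optimize.minimize(objective, np.log(lam0), method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
    return np.exp(res.x)


def float_absolute_risks(params, cov, reference: str,
                         level_sizes=None) -> FloatedEstimates:
    """Floating absolute risks by the heterogeneity (covariance) method.

    ``lambda_0`` (reference) is the mean off-diagonal covariance of the
    non-reference log hazard ratios and ``lambda_i = V_ii - lambda_0``.
    With a diagonal covariance this gives ``lambda_0 = 0`` and
    ``lambda_i = V_ii`` exactly. If any resulting variance is non-positive
    an iterative minimax fit over the pairwise-difference variances is used
    instead. With a single non-reference level the method is degenerate and
    the variance is split between the two levels in inverse proportion to
    the level sizes (equally when sizes are unknown).

    Parameters
    ----------
    params : Series
        Non-reference log hazard ratios.
    cov : DataFrame or ndarray
        Their covariance matrix.
    reference : str
        Label of the reference level.
    level_sizes : mapping, optional
        Level -> number of participants (or events); used only in the
        two-level degenerate split.
    """
    params = pd.Series(params)
    V = cov.to_numpy() if isinstance(cov, pd.DataFrame) else np.asarray(cov, float)
    m = len(params)
    levels = [reference] + list(params.index)
    log_hr = np.concatenate([[0.0], params.to_numpy(float)])
    var_conv = np.concatenate([[np.nan], np.diag(V)])

    method = "heterogeneity"
    if m == 1:
        if level_sizes:
            w_ref = 1.0 / level_sizes[reference]
            w_lvl = 1.0 / level_sizes[params.index[0]]
            lam0 = V[0, 0] * w_ref / (w_ref + w_lvl)
        else:
            lam0 = V[0, 0] / 2.0
        lam = np.array([lam0, V[0, 0] - lam0])
        method = "two-level split"
    else:
        off = V[~np.eye(m, dtype=bool)]
        lam0 = float(off.mean())
        lam = np.concatenate([[lam0], np.diag(V) - lam0])
        # lam0 == 0 is the legitimate zero-covariance limit
        if lam[0] < 0 or np.any(lam[1:] <= 0):
            lam = _minimax_floated(V)
            method = "iterative minimax"
    return FloatedEstimates(levels=levels, reference=reference, log_hr=log_hr,
                            var_conventional=var_conv, var_floated=lam,
                            cov=V, method=method)


# ---------------------------------------------------------------------------
# dose-response correction and subgroup tests
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseResult:
    """Hazard ratio per unit of *usual* intake after dilution correction."""

    hr: float
    ci_lower: float
    ci_upper: float
    log_hr: float
    se: float
    rdr: float
    p: float

    def __repr__(self):
        return (f"DoseResponseResult(HR={self.hr:.3f} "
                f"[{self.ci_lower:.3f}, {self.ci_upper:.3f}], rdr={self.rdr})")


def dose_response_corrected(log_hr: float, se: float, rdr: float,
                            alpha: float = 0.05) -> DoseResponseResult:
    """Correct a baseline-intake log HR and s.e. for regression dilution.

    Both the log hazard ratio and its standard error are divided by the
    regression-dilution ratio, converting an association with a single
    baseline measurement into one with usual (long-term) intake.
    """
    if not 0.0 < rdr <= 1.0:
        raise ValidationError(f"regression-dilution ratio {rdr} outside (0, 1]")
    b = log_hr / rdr
    s = se / rdr
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(b) / s) if s > 0 else np.nan
    return DoseResponseResult(hr=float(np.exp(b)), ci_lower=float(np.exp(b - z * s)),
                              ci_upper=float(np.exp(b + z * s)), log_hr=float(b),
                              se=float(s), rdr=float(rdr), p=float(p))


@dataclass
class SubgroupTests:
    chi2_heterogeneity: float
    df_heterogeneity: int
    p_heterogeneity: float
    chi2_trend: float | None = None
    p_trend: float | None = None


def subgroup_heterogeneity_trend(estimates, ses, scores=None) -> SubgroupTests:
    """Chi-squared heterogeneity (and optional trend) across subgroups.

    Heterogeneity: ``sum_g w_g (b_g - b_bar)^2`` with inverse-variance
    weights and the IVW mean, on G-1 degrees of freedom. Trend: 1-df
    chi-squared on the slope of an inverse-variance-weighted regression of
    the estimates on ordered scores.
    """
    b = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if len(b) < 2:
        raise EstimationError("subgroup tests need at least 2 subgroups")
    w = 1.0 / se ** 2
    bbar = np.sum(w * b) / np.sum(w)
    chi2 = float(np.sum(w * (b - bbar) ** 2))
    df = len(b) - 1
    out = SubgroupTests(chi2_heterogeneity=chi2, df_heterogeneity=df,
                        p_heterogeneity=float(stats.chi2.sf(chi2, df)))
    if scores is not None:
        x = np.asarray(scores, dtype=float)
        xbar = np.sum(w * x) / np.sum(w)
        sxx = np.sum(w * (x - xbar) ** 2)
        slope = np.sum(w * (x - xbar) * (b - bbar)) / sxx
        chi2_t = float(slope ** 2 * sxx)
        out.chi2_trend = chi2_t
        out.p_trend = float(stats.chi2.sf(chi2_t, 1))
    return out


# ---------------------------------------------------------------------------
# categorical exposure profiles
# ---------------------------------------------------------------------------

def encode_covariates(df: pd.DataFrame, cols) -> pd.DataFrame:
    """One-hot encode adjustment covariates (drop-first), pass floats through."""
    parts = []
    for c in cols:
        col = df[c]
        if col.dtype.kind in "fc" and col.nunique() > 10:
            parts.append(col.to_frame())
        else:
            parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)


def fit_categorical_profile(df: pd.DataFrame, category_col: str, reference: str,
                            covariate_cols=(), entry_col="entry_age",
                            exit_col="exit_age", event_col="event",
                            strata_cols=("age_band", "area"),
                            tol: float = 1e-8):
    """Fit a stratified Cox model with a categorical exposure and float it.

    Levels are ordered with the reference first, then by appearance. Empty
    levels are dropped with a warning. Returns ``(FloatedEstimates,
    StratifiedCoxResults)``.
    """
    cats = df[category_col].astype(str)
    levels = [reference] + [c for c in cats.unique() if c != reference]
    present = [c for c in levels if (cats == c).any()]
    if len(present) < len(levels):
        warnings.warn(f"empty exposure level(s) dropped: "
                      f"{sorted(set(levels) - set(present))}")
    if reference not in present:
        raise EstimationError(f"reference level {reference!r} absent from data")
    dummies = pd.DataFrame(
        {f"{category_col}[{c}]": (cats == c).astype(float) for c in present[1:]},
        index=df.index)
    X = pd.concat([dummies, encode_covariates(df, covariate_cols)], axis=1)
    strata = pd.factorize(pd.MultiIndex.from_frame(df[list(strata_cols)]))[0] \
        if strata_cols else None
    model = StratifiedCoxModel(df[entry_col].to_numpy(float),
                               df[exit_col].to_numpy(float),
                               df[event_col].to_numpy(), X, strata=strata)
    res = model.fit(tol=tol)
    expo_names = [c for c in dummies.columns if c in res.params.index]
    sizes = cats.value_counts().to_dict()
    sizes = {f"{category_col}[{c}]": n for c, n in sizes.items()} | \
        {reference: int((cats == reference).sum())}
    floated = float_absolute_risks(res.params[expo_names],
                                   res.cov.loc[expo_names, expo_names],
                                   reference=reference, level_sizes=sizes)
    # strip the dummy-name wrapper for presentation
    floated.levels = [reference] + [n[len(category_col) + 1:-1] for n in expo_names]
    return floated, res
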