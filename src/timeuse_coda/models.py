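"""Bayesian multilevel affect models and the life-satisfaction linear model.

The affect model is a Gaussian random-intercept regression at the
participant-day level::

    affect_pd = a + b_B . ilr_B_p + b_W . ilr_W_pd + g . covariates_p
                + u_p + e_pd,      u_p ~ N(0, tau^2),  e_pd ~ N(0, sigma^2)

with the day's exposure split into the participant's mean ilr coordinates
(between-person, ``ilr_B``) and the mean-centred daily deviations
(within-person, ``ilr_W``).  Priors are weakly informative: Normal(0, 10)
on the intercept and every regression coefficient, half-Student-t(3, 0, 5)
on both standard deviations.  Because every full conditional is available
in closed form (the half-t priors enter through their inverse-gamma
mixture representation), the posterior is sampled by a blocked Gibbs
sampler; split-R-hat and effective sample size are computed with ArviZ and
a fit raises when any R-hat exceeds 1.01.

Life satisfaction is cross-sectional (one row per participant, no within
terms, no random intercept) and is fitted by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import coda, preprocess
from .coda import PARTS, IlrBasis
from .preprocess import ILR_B_COLS, ILR_W_COLS

__all__ = [
    "ModelSpec",
    "PosteriorFit",
    "LinearFit",
    "build_design",
    "fit_affect_model",
    "fit_life_satisfaction",
    "fit_all_pivots",
    "summarize_fits",
    "summarize_linear_fits",
]

PRIOR_COEF_SD = 10.0
PRIOR_SD_SCALE = 5.0
PRIOR_SD_DF = 3.0
RHAT_LIMIT = 1.01


@dataclass(frozen=True)
class ModelSpec:
    """Sampling and adjustment settings for one model fit."""

    outcome: str
    pivot: str = "sb"
    adjusted: bool = True
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    check_convergence: bool = True


@dataclass
class PosteriorFit:
    """Posterior draws plus convergence diagnostics for one affect model."""

    spec: ModelSpec
    basis: IlrBasis
    param_names: list[str]
    draws: dict[str, np.ndarray]  # name -> (chains, draws)
    sd_draws: dict[str, np.ndarray]
    summary: pd.DataFrame = field(repr=False)
    diagnostics: pd.DataFrame = field(repr=False)
    n_obs: int = 0
    n_participants: int = 0

    def coef_draws(self, names: list[str]) -> np.ndarray:
        """Flattened posterior draws, shape (chains*draws, len(names))."""
        return np.column_stack([self.draws[n].ravel() for n in names])

    @property
    def between_names(self) -> list[str]:
        return [c for c in ILR_B_COLS if c in self.draws]

    @property
    def within_names(self) -> list[str]:
        return [c for c in ILR_W_COLS if c in self.draws]


@dataclass
class LinearFit:
    """OLS fit of the cross-sectional life-satisfaction model."""

    spec: ModelSpec
    basis: IlrBasis
    params: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    rsquared: float
    n_obs: int
    result: object = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _ethnicity_indicators(series: pd.Series) -> pd.DataFrame:
    """0/1 indicator per ethnicity in a semicolon-separated multi-select."""
    lists = series.fillna("").astype(str).str.split(";")
    lists = lists.apply(lambda xs: [x.strip() for x in xs if x.strip()])
    cats = sorted({c for xs in lists for c in xs})
    out = pd.DataFrame(
        {f"eth_{c}": lists.apply(lambda xs, c=c: int(c in xs)) for c in cats},
        index=series.index,
    )
    if not out.empty:
        # reference category = most frequent (dropped to keep identifiability)
        out = out.drop(columns=out.sum().idxmax())
    return out


def covariate_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Covariate design columns: age band and gender dummies (reference =
    most frequent level), ethnicity indicators, numeric deprivation decile."""
    blocks = []
    for col in ("age_band", "gender"):
        if col in table.columns:
            d = pd.get_dummies(table[col], prefix=col, dtype=float)
            if not d.empty:
                d = d.drop(columns=d.sum().idxmax())
            blocks.append(d)
    if "ethnicity" in table.columns:
        blocks.append(_ethnicity_indicators(table["ethnicity"]).astype(float))
    if "deprivation_decile" in table.columns:
        blocks.append(table[["deprivation_decile"]].astype(float))
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=table.index)


def build_design(
    table: pd.DataFrame, adjusted: bool, within: bool = True
) -> pd.DataFrame:
    """Predictor matrix (no intercept column): ilr terms plus covariates."""
    cols = [table[list(ILR_B_COLS)]]
    if within:
        cols.append(table[list(ILR_W_COLS)])
    if adjusted:
        cols.append(covariate_frame(table))
    X = pd.concat(cols, axis=1).astype(float)
    degenerate = [c for c in X.columns if np.isclose(X[c].std(ddof=0), 0.0)]
    if degenerate:
        raise ValueError(f"degenerate (zero-variance) predictors: {degenerate}")
    return X


# ---------------------------------------------------------------------------
# Gibbs sampler for the Gaussian random-intercept model
# ---------------------------------------------------------------------------

def _gibbs_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    chains: int,
    draws: int,
    warmup: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (beta, sigma, tau) from the random-intercept posterior.

    Returns ``(coef, sds)`` with shapes (chains, draws, p) and
    (chains, draws, 2) where the last axis of ``sds`` is (tau, sigma).
    X must already include the intercept column.
    """
    n, p = X.shape
    J = groups.max() + 1
    nu, A = PRIOR_SD_DF, PRIOR_SD_SCALE

    # joint design W = [X | person indicators]; (beta, u) are sampled in one
    # Gaussian block, so mixing is limited only by the variance updates
    Z = np.zeros((n, J))
    Z[np.arange(n), groups] = 1.0
    W = np.hstack([X, Z])
    WtW = W.T @ W
    Wty = W.T @ y
    prior_diag = np.zeros(p + J)
    prior_diag[:p] = 1.0 / PRIOR_COEF_SD**2

    coef = np.empty((chains, draws, p))
    sds = np.empty((chains, draws, 2))
    seeds = np.random.SeedSequence(seed).spawn(chains)
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        sigma2, tau2 = max(np.var(y), 1e-3), max(np.var(y) / 4, 1e-3)
        a_sig = a_tau = 1.0
        for it in range(warmup + draws):
            # (beta, u) | variances: exact multivariate-normal draw
            pd_ = prior_diag.copy()
            pd_[p:] = 1.0 / tau2
            prec = WtW / sigma2 + np.diag(pd_)
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, Wty / sigma2)
            theta = mean + np.linalg.solve(
                chol.T, rng.standard_normal(p + J)
            )
            beta, u = theta[:p], theta[p:]
            # variances | rest (half-t via inverse-gamma mixture)
            sse = np.sum((y - W @ theta) ** 2)
            sigma2 = 1.0 / rng.gamma((nu + n) / 2.0, 1.0 / (nu / a_sig + sse / 2.0))
            a_sig = 1.0 / rng.gamma(
                (nu + 1) / 2.0, 1.0 / (nu / sigma2 + 1.0 / A**2)
            )
            tau2 = 1.0 / rng.gamma(
                (nu + J) / 2.0, 1.0 / (nu / a_tau + np.sum(u**2) / 2.0)
            )
            a_tau = 1.0 / rng.gamma(
                (nu + 1) / 2.0, 1.0 / (nu / tau2 + 1.0 / A**2)
            )
            if it >= warmup:
                coef[c, it - warmup] = beta
                sds[c, it - warmup] = np.sqrt([tau2, sigma2])
    return coef, sds


def _summaries(draws: dict[str, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    idata = az.from_dict(posterior=draws)
    with np.errstate(invalid="ignore", divide="ignore"):  # constant chains
        diag = pd.DataFrame(
            {
                "rhat": az.rhat(idata).to_pandas(),
                "ess_bulk": az.ess(idata).to_pandas(),
            }
        )
    rows = {}
    for name, d in draws.items():
        flat = d.ravel()
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows[name] = {
            "mean": flat.mean(),
            "sd": flat.std(ddof=1),
            "ci_low": lo,
            "ci_high": hi,
            "significant": (lo > 0) or (hi < 0),
        }
    return pd.DataFrame(rows).T, diag


def fit_affect_model(
    table: pd.DataFrame, spec: ModelSpec, basis: IlrBasis | None = None
) -> PosteriorFit:
    """Fit the multilevel model for one affect outcome.

    Only affect-bearing rows (``has_affect``) enter the likelihood; the
    between/within coordinates are taken as provided in ``table`` (they are
    computed from all valid days, including affect-free ones).  Rows are
    sorted internally, so the fit is invariant to input row order at a
    fixed sampler seed.
    """
    if basis is None:
        basis = coda.default_basis(spec.pivot)
    if spec.outcome not in preprocess.AFFECTS:
        raise ValueError(f"{spec.outcome!r} is not an affect outcome")
    df = table.copy()
    if "has_affect" in df.columns:
        df = df.loc[df["has_affect"]]
    df = df.dropna(subset=[spec.outcome])
    df = df.sort_values(["participant_id", "date"] if "date" in df else ["participant_id"])
    per_person = df.groupby("participant_id").size()
    if (per_person >= 2).sum() < 2:
        raise ValueError(
            "need at least two participants with two affect-bearing days each"
        )

    Xf = build_design(df, adjusted=spec.adjusted, within=True)
    names = ["intercept", *Xf.columns]
    X = np.column_stack([np.ones(len(df)), Xf.to_numpy()])
    y = df[spec.outcome].to_numpy(dtype=float)
    groups = pd.factorize(df["participant_id"], sort=True)[0]

    coef, sds = _gibbs_lmm(
        y, X, groups, spec.chains, spec.draws, spec.warmup, spec.seed
    )
    draws = {name: coef[:, :, k] for k, name in enumerate(names)}
    sd_draws = {"person_sd": sds[:, :, 0], "residual_sd": sds[:, :, 1]}
    summary, diag = _summaries({**draws, **sd_draws})
    if spec.check_convergence and (diag["rhat"] > RHAT_LIMIT).any():
        bad = diag.index[diag["rhat"] > RHAT_LIMIT].tolist()
        raise RuntimeError(f"sampler did not converge (R-hat > {RHAT_LIMIT}): {bad}")
    return PosteriorFit(
        spec=spec,
        basis=basis,
        param_names=names,
        draws=draws,
        sd_draws=sd_draws,
        summary=summary,
        diagnostics=diag,
        n_obs=len(df),
        n_participants=int(df["participant_id"].nunique()),
    )


# ---------------------------------------------------------------------------
# Life satisfaction (cross-sectional OLS)
# ---------------------------------------------------------------------------

def fit_life_satisfaction(
    person_table: pd.DataFrame, spec: ModelSpec, basis: IlrBasis | None = None
) -> LinearFit:
    """OLS of life satisfaction on person-level (between) ilr coordinates."""
    if basis is None:
        basis = coda.default_basis(spec.pivot)
    df = person_table.dropna(subset=["life_satisfaction"]).copy()
    if df["participant_id"].duplicated().any():
        raise ValueError("life-satisfaction table must have one row per participant")
    Xf = build_design(df, adjusted=spec.adjusted, within=False)
    X = sm.add_constant(Xf.to_numpy(), has_constant="add")
    if len(df) <= X.shape[1]:
        raise ValueError(
            f"n = {len(df)} participants cannot identify {X.shape[1]} parameters"
        )
    res = sm.OLS(df["life_satisfaction"].to_numpy(dtype=float), X).fit()
    names = ["intercept", *Xf.columns]
    ci = pd.DataFrame(res.conf_int(), index=names, columns=["ci_low", "ci_high"])
    return LinearFit(
        spec=spec,
        basis=basis,
        params=pd.Series(res.params, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        conf_int=ci,
        rsquared=float(res.rsquared),
        n_obs=len(df),
        result=res,
    )


# ---------------------------------------------------------------------------
# Pivot rotations and summary tables
# ---------------------------------------------------------------------------

def _with_pivot_coords(table: pd.DataFrame, pivot: str) -> tuple[pd.DataFrame, IlrBasis]:
    basis = coda.default_basis(pivot)
    df = preprocess.decompose_between_within(
        preprocess.add_ilr_coordinates(table, basis)
    )
    return df, basis


def fit_all_pivots(
    table: pd.DataFrame,
    outcome: str,
    adjusted: bool = True,
    pivots: tuple[str, ...] = PARTS,
    **spec_kw,
) -> dict[str, PosteriorFit | LinearFit]:
    """Refit one outcome under each pivot-first sign-matrix permutation.

    The four fits are linear reparameterisations of one another; refitting
    makes each behaviour's "relative to the rest" coefficient directly
    readable from its ilr1 row.
    """
    fits: dict[str, PosteriorFit | LinearFit] = {}
    for pivot in pivots:
        df, basis = _with_pivot_coords(table, pivot)
        spec = ModelSpec(outcome=outcome, pivot=pivot, adjusted=adjusted, **spec_kw)
        if outcome == "life_satisfaction":
            fits[pivot] = fit_life_satisfaction(
                preprocess.person_level_table(df), spec, basis
            )
        else:
            fits[pivot] = fit_affect_model(df, spec, basis)
    return fits


def summarize_fits(
    fits: dict[str, dict[str, PosteriorFit]],
    unadjusted: dict[str, dict[str, PosteriorFit]] | None = None,
) -> pd.DataFrame:
    """Coefficient table for the pivot ilr1 rows of the affect models.

    ``fits`` maps outcome -> pivot -> fit (the adjusted models); pass the
    unadjusted fits to get both coefficient columns side by side.  One row
    per outcome x level (between/within) x pivot.
    """
    rows = []
    for outcome, by_pivot in fits.items():
        for pivot, fit in by_pivot.items():
            for level, col in (("between", "ilr_b1"), ("within", "ilr_w1")):
                row = {
                    "outcome": outcome,
                    "level": level,
                    "pivot": pivot,
                    **_coef_cells(fit, col, "adjusted"),
                }
                if unadjusted is not None:
                    row.update(
                        _coef_cells(unadjusted[outcome][pivot], col, "unadjusted")
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def _coef_cells(fit: PosteriorFit, coef: str, label: str) -> dict:
    s = fit.summary.loc[coef]
    return {
        f"{label}_mean": s["mean"],
        f"{label}_ci_low": s["ci_low"],
        f"{label}_ci_high": s["ci_high"],
        f"{label}_significant": bool(s["significant"]),
    }


def summarize_linear_fits(
    fits: dict[str, LinearFit], unadjusted: dict[str, LinearFit] | None = None
) -> pd.DataFrame:
    """Coefficient / p-value / R-squared table for life satisfaction."""
    rows = []
    for pivot, fit in fits.items():
        row = {
            "outcome": "life_satisfaction",
            "pivot": pivot,
            "adjusted_coef": fit.params["ilr_b1"],
            "adjusted_p": fit.pvalues["ilr_b1"],
            "adjusted_r2": fit.rsquared,
        }
        if unadjusted is not None:
            u = unadjusted[pivot]
            row.update(
                unadjusted_coef=u.params["ilr_b1"],
                unadjusted_p=u.pvalues["ilr_b1"],
                unadjusted_r2=u.rsquared,
            )
        rows.append(row)
    return pd.DataFrame(rows)
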