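"""General linear model of process traits with bin-abundance covariates.

Reactor traits (methane yield, VFA species, Ac/Pr ratio, pH) are
modelled by ordinary least squares against fixed effects — inoculum
property (2 levels), period (3 levels), LCFA dose — plus, one at a
time, the abundance of a single genome bin at the recording time as a
linear covariate (one covariate per model to avoid confounding through
shared variance). The engine provides treatment-coded design matrices,
a QR-based OLS fit, Type-III-style F-tests per effect (full vs
effect-dropped model), least-squares means with pairwise Student
t-tests, and a per-bin covariate scan reporting the direction
(increasing/decreasing) and significance of each bin's slope.

Observations are reactor-day records treated as independent; no
repeated-measures covariance structure is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from binflux.abundance import BinAbundanceMatrix

TRAITS = (
    "methane_yield",
    "total_vfa",
    "acetate",
    "propionate",
    "butyrate",
    "ac_pr_ratio",
)
FIXED_EFFECTS = ("inoculum", "period", "lcfa_dose")

_EFFECT_SOURCE = {"inoculum": "experimental_set", "period": "period"}


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; carries the aliased columns."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"design matrix rank deficient; aliased columns: {aliased}")


@dataclass
class GLMSpec:
    """One trait/effects/covariate combination to fit."""

    trait: str
    fixed_effects: tuple[str, ...] = ("inoculum", "period", "lcfa_dose")
    covariate_bin: str | None = None

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"trait must be one of {TRAITS}")
        unknown = [e for e in self.fixed_effects if e not in FIXED_EFFECTS]
        if unknown:
            raise ValueError(f"unknown fixed effect(s) {unknown}")


@dataclass
class GLMFit:
    """OLS fit with the pieces lsmeans and effect tests need."""

    spec: GLMSpec
    labels: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    ss_model: float
    ss_resid: float
    ss_total: float
    sigma2: float
    r_squared: float
    effect_tests: pd.DataFrame  # effect, F, df_num, df_den, p_value
    covariate_slope_sign: str  # increasing / decreasing / none
    factor_levels: dict[str, list[str]] = field(repr=False, default_factory=dict)
    effect_columns: dict[str, list[str]] = field(repr=False, default_factory=dict)
    numeric_means: dict[str, float] = field(repr=False, default_factory=dict)
    xtx_inv: np.ndarray = field(repr=False, default=None)


def build_design_matrix(
    observations: pd.DataFrame, spec: GLMSpec
) -> tuple[np.ndarray, list[str], dict[str, list[str]], dict[str, list[str]]]:
    """Treatment-coded design matrix for one model.

    Categorical effects get dummies against the first sorted level as
    reference; ``lcfa_dose`` enters as a numeric column; an optional
    bin-abundance covariate (column ``abundance``) comes last. Raises
    :class:`RankDeficiencyError` naming the aliased columns when the
    coding is not full rank.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(observations))}
    effect_columns: dict[str, list[str]] = {}
    factor_levels: dict[str, list[str]] = {}
    for effect in spec.fixed_effects:
        if effect in _EFFECT_SOURCE:
            src = _EFFECT_SOURCE[effect]
            values = observations[src].astype(str)
            levels = sorted(values.unique())
            if len(levels) < 1:
                raise ValueError(f"effect {effect!r} has no observed levels")
            factor_levels[effect] = levels
            names = []
            for level in levels[1:]:
                name = f"{effect}[T.{level}]"
                cols[name] = (values == level).to_numpy(dtype=float)
                names.append(name)
            effect_columns[effect] = names
        elif effect == "lcfa_dose":
            cols["lcfa_dose"] = observations["lcfa_dose"].to_numpy(dtype=float)
            effect_columns["lcfa_dose"] = ["lcfa_dose"]
    if spec.covariate_bin is not None:
        cols["abundance"] = observations["abundance"].to_numpy(dtype=float)
        effect_columns["abundance"] = ["abundance"]
    labels = list(cols)
    X = np.column_stack([cols[c] for c in labels])

    # rank check with aliased-column identification via pivoted QR
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = sorted(labels[piv[i]] for i in range(rank, X.shape[1]))
        raise RankDeficiencyError(aliased)
    return X, labels, effect_columns, factor_levels


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Least squares via thin QR; returns beta, RSS, (X'X)^-1."""
    Q, R = np.linalg.qr(X)
    beta = scipy.linalg.solve_triangular(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    r_inv = scipy.linalg.solve_triangular(R, np.eye(R.shape[0]))
    xtx_inv = r_inv @ r_inv.T
    return beta, rss, xtx_inv


def fit_glm(observations: pd.DataFrame, spec: GLMSpec) -> GLMFit:
    """Fit one trait model by ordinary least squares.

    ``observations`` must hold one row per reactor-day record with the
    trait column, ``experimental_set``/``period``/``lcfa_dose`` as
    needed by the fixed effects, and an ``abundance`` column when a
    covariate bin is specified.
    """
    y = observations[spec.trait].to_numpy(dtype=float)
    X, labels, effect_columns, factor_levels = build_design_matrix(observations, spec)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"insufficient observations: n={n} for {p} parameters")
    beta, rss, xtx_inv = _ols(X, y)
    df_resid = n - p
    sigma2 = rss / df_resid
    se = np.sqrt(np.clip(np.diag(xtx_inv), 0, None) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_model = ss_total - rss

    # Type-III-style: F of each effect from full vs effect-dropped model
    rows = []
    for effect, names in effect_columns.items():
        keep = [i for i, lab in enumerate(labels) if lab not in names]
        _, rss_red, _ = _ols(X[:, keep], y)
        q = len(names)
        F = ((rss_red - rss) / q) / sigma2 if sigma2 > 0 else np.inf
        p_eff = float(stats.f.sf(F, q, df_resid))
        rows.append(
            {"effect": effect, "F": float(F), "df_num": q, "df_den": df_resid,
             "p_value": p_eff}
        )
    effect_tests = pd.DataFrame(rows, columns=["effect", "F", "df_num", "df_den", "p_value"])

    if spec.covariate_bin is not None:
        slope = beta[labels.index("abundance")]
        sign = "increasing" if slope > 0 else ("decreasing" if slope < 0 else "none")
    else:
        sign = "none"

    numeric_means = {}
    for name in ("lcfa_dose", "abundance"):
        if name in labels:
            numeric_means[name] = float(X[:, labels.index(name)].mean())

    idx = pd.Index(labels)
    return GLMFit(
        spec=spec,
        labels=labels,
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        df_resid=df_resid,
        ss_model=ss_model,
        ss_resid=rss,
        ss_total=ss_total,
        sigma2=sigma2,
        r_squared=1.0 - rss / ss_total if ss_total > 0 else 1.0,
        effect_tests=effect_tests,
        covariate_slope_sign=sign,
        factor_levels=factor_levels,
        effect_columns=effect_columns,
        numeric_means=numeric_means,
        xtx_inv=xtx_inv,
    )


def _lsmean_vector(fit: GLMFit, effect: str, level: str) -> np.ndarray:
    """Prediction row for one level: other factors at equal weight,
    numeric covariates at their grand mean."""
    c = np.zeros(len(fit.labels))
    c[fit.labels.index("Intercept")] = 1.0
    for other, names in fit.effect_columns.items():
        if other == effect:
            for name in names:
                c[fit.labels.index(name)] = 1.0 if name == f"{effect}[T.{level}]" else 0.0
        elif other in fit.factor_levels:
            weight = 1.0 / len(fit.factor_levels[other])
            for name in names:
                c[fit.labels.index(name)] = weight
        else:  # numeric effect or covariate
            for name in names:
                c[fit.labels.index(name)] = fit.numeric_means[name]
    return c


def lsmeans(fit: GLMFit, effect: str) -> pd.DataFrame:
    """Least-squares means and standard errors for one categorical effect."""
    if effect not in fit.factor_levels:
        raise KeyError(f"effect {effect!r} is not a categorical effect of the model")
    rows = []
    for level in fit.factor_levels[effect]:
        c = _lsmean_vector(fit, effect, level)
        est = float(c @ fit.params.to_numpy())
        se = float(np.sqrt(max(c @ fit.xtx_inv @ c, 0.0) * fit.sigma2))
        rows.append({"effect": effect, "level": level, "lsmean": est, "se": se})
    return pd.DataFrame(rows, columns=["effect", "level", "lsmean", "se"])


def lsmeans_ttest(fit: GLMFit, effect: str) -> pd.DataFrame:
    """Pairwise Student t-tests between an effect's least-squares means."""
    if effect not in fit.factor_levels:
        raise KeyError(f"effect {effect!r} is not a categorical effect of the model")
    rows = []
    for la, lb in combinations(fit.factor_levels[effect], 2):
        c = _lsmean_vector(fit, effect, la) - _lsmean_vector(fit, effect, lb)
        diff = float(c @ fit.params.to_numpy())
        se = float(np.sqrt(max(c @ fit.xtx_inv @ c, 0.0) * fit.sigma2))
        t = diff / se if se > 0 else (0.0 if diff == 0 else np.inf * np.sign(diff))
        p = float(2 * stats.t.sf(abs(t), fit.df_resid))
        rows.append(
            {"effect": effect, "level_a": la, "level_b": lb,
             "difference": diff, "se": se, "t": t, "p_value": p}
        )
    return pd.DataFrame(
        rows, columns=["effect", "level_a", "level_b", "difference", "se", "t", "p_value"]
    )


def compute_trait(process: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Attach the requested trait column to a process table copy.

    ``ac_pr_ratio`` is acetate/propionate; rows with zero propionate are
    dropped and their count recorded in ``df.attrs['dropped_zero_propionate']``.
    """
    df = process.copy()
    if trait == "ac_pr_ratio":
        zero = df["propionate"] <= 0
        df = df[~zero].copy()
        df["ac_pr_ratio"] = df["acetate"] / df["propionate"]
        df.attrs["dropped_zero_propionate"] = int(zero.sum())
    elif trait not in df.columns:
        raise KeyError(f"trait {trait!r} not in process table")
    return df


def prepare_observations(
    design: pd.DataFrame, process: pd.DataFrame, trait: str
) -> pd.DataFrame:
    """Join sample metadata to process records by (reactor_id, day).

    Every sample must find its reactor-day process record; unmatched
    samples are a hard error listing the offending (reactor, day) keys.
    """
    proc = compute_trait(process, trait)
    merged = design.merge(
        proc[["reactor_id", "day", trait]], on=["reactor_id", "day"], how="left"
    )
    missing = merged[trait].isna()
    if missing.any():
        keys = [
            f"({r}, day {d})"
            for r, d in zip(
                merged.loc[missing, "reactor_id"], merged.loc[missing, "day"]
            )
        ]
        raise KeyError(f"no process record for sample(s): {', '.join(keys)}")
    return merged


def covariate_scan(
    observations: pd.DataFrame,
    abund: BinAbundanceMatrix,
    trait: str,
    fixed_effects: tuple[str, ...] = ("inoculum", "period", "lcfa_dose"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit one GLM per bin with that bin's abundance as the covariate.

    Each bin is included separately (never jointly) to avoid
    confounding through shared variance. Reports the slope, its
    direction (``increasing`` = directly correlated, ``decreasing`` =
    inversely), and the slope's p-value; bins whose abundance column is
    aliased with the fixed effects (e.g. constant) are reported with an
    ``error`` note and the scan continues.
    """
    rows = []
    for bin_id in sorted(abund.abundance.index):
        obs = observations.copy()
        obs["abundance"] = (
            abund.abundance.loc[bin_id].reindex(obs["sample_id"]).to_numpy()
        )
        if obs["abundance"].isna().any():
            bad = obs.loc[obs["abundance"].isna(), "sample_id"].iloc[0]
            raise KeyError(f"sample {bad!r} absent from abundance matrix")
        spec = GLMSpec(trait=trait, fixed_effects=fixed_effects, covariate_bin=bin_id)
        try:
            fit = fit_glm(obs, spec)
        except RankDeficiencyError as exc:
            rows.append(
                {"bin_id": bin_id, "slope": np.nan, "sign": "none",
                 "p_value": np.nan, "significant": False,
                 "note": f"rank_deficient:{'|'.join(exc.aliased)}"}
            )
            continue
        slope = float(fit.params["abundance"])
        p = float(fit.pvalues["abundance"])
        rows.append(
            {"bin_id": bin_id, "slope": slope, "sign": fit.covariate_slope_sign,
             "p_value": p, "significant": bool(p <= alpha), "note": ""}
        )
    return pd.DataFrame(
        rows, columns=["bin_id", "slope", "sign", "p_value", "significant", "note"]
    )
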