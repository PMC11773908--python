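"""Linear mixed-effects analyses.

Two bespoke fits:

* a changepoint model of the TSPO+/Iba1+ fraction against lesion age, with
  lesion age in months as a *categorical* fixed effect parameterised by
  successive differences from the cumulative average of the preceding
  months (so each coefficient is "this month minus the mean of all earlier
  months"), a binary steroid-treatment fixed effect, random intercepts for
  animal (and optionally lesion-within-animal), REML estimation and
  Bonferroni correction over the month contrasts;

* a weighted random-intercept model of per-ROI neuronal TSPO fractions with
  fixed effects for disease status and ROI laterality, each observation
  weighted by the number of neurons counted in the ROI
  (``Var(e_ij) = sigma^2 / w_ij``).

The changepoint model is fit with statsmodels MixedLM; the weighted model
profiles the REML criterion over the animal-to-residual variance ratio
directly, since precision weights are not expressible in MixedLM.
Fixed-effect p-values use a normal reference for the changepoint model and
a containment-df t reference for the neuron model (disease status is an
animal-level effect); the reference used is recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LesionRecord",
    "ChangepointFit",
    "NeuronFit",
    "successive_difference_contrasts",
    "fit_changepoint_lmm",
    "fit_neuron_lmm",
    "bonferroni",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """The REML optimisation failed; diagnostics in ``args[1]``."""


@dataclass
class LesionRecord:
    """One lesion's observed TSPO+/Iba1+ fraction with design metadata."""

    animal_id: str
    lesion_id: str
    month: int
    treated: bool
    fraction: float
    n_cells: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")


def successive_difference_contrasts(levels: list[int] | tuple[int, ...]) -> np.ndarray:
    """Contrast matrix of successive differences from the cumulative average.

    Row for the t-th level (t >= 2) carries +1 on level t and -1/(t-1) on
    each earlier level, so applying it to a mean vector gives
    ``x_t - mean(x_1, ..., x_{t-1})``.  Rows sum to zero; the matrix has
    rank ``len(levels) - 1``.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need >= 2 levels")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly increasing")
    k = len(levels)
    C = np.zeros((k - 1, k))
    for t in range(1, k):
        C[t - 1, t] = 1.0
        C[t - 1, :t] = -1.0 / t
    return C


def _coding_matrix(k: int) -> np.ndarray:
    """Invertible k x k map from cell means to (first-level mean, contrasts)."""
    C = np.zeros((k, k))
    C[0, 0] = 1.0
    C[1:, :] = successive_difference_contrasts(list(range(1, k + 1)))
    return C


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(p * m, 1)`` elementwise."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(p * m, 1.0)


@dataclass
class ChangepointFit:
    """Result of the lesion-age changepoint model (percentage-point scale)."""

    levels: list[int]
    baseline_pp: float  # estimated mean at the first level
    estimates_pp: dict[int, float]  # level -> contrast vs cumulative average
    ses_pp: dict[int, float]
    p_raw: dict[int, float]
    p_bonferroni: dict[int, float]
    treatment_pp: float | None
    treatment_se_pp: float | None
    treatment_p: float | None
    var_animal: float
    var_lesion: float | None
    var_residual: float
    m_comparisons: int
    df_method: str
    converged: bool
    n_obs: int
    n_animals: int

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": f"month_{lvl}_vs_cumavg",
                "estimate_pp": self.estimates_pp[lvl],
                "se_pp": self.ses_pp[lvl],
                "p_raw": self.p_raw[lvl],
                "p_bonferroni": self.p_bonferroni[lvl],
            }
            for lvl in self.levels[1:]
        ]
        if self.treatment_pp is not None:
            rows.append(
                {
                    "term": "treated",
                    "estimate_pp": self.treatment_pp,
                    "se_pp": self.treatment_se_pp,
                    "p_raw": self.treatment_p,
                    "p_bonferroni": np.nan,
                }
            )
        return pd.DataFrame(rows)


def _validate_lesion_table(df: pd.DataFrame, levels: list[int]) -> None:
    required = {"animal_id", "month", "treated", "fraction"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"lesion table lacks columns: {sorted(missing)}")
    if len(levels) < 2:
        raise ValueError(
            f"changepoint model requires >= 2 month levels, got {levels}"
        )
    if df["animal_id"].nunique() < 2:
        raise ValueError("changepoint model requires >= 2 animals")
    counts = df["month"].value_counts()
    empty = [lvl for lvl in levels if counts.get(lvl, 0) == 0]
    if empty:
        raise ValueError(f"month level(s) with no observations: {empty}")


def fit_changepoint_lmm(
    records: pd.DataFrame,
    levels: list[int] | None = None,
    include_lesion_re: bool | None = None,
) -> ChangepointFit:
    """Fit the lesion-age changepoint linear mixed model by REML.

    ``fraction ~ month (categorical, successive-difference-from-cumulative-
    average coding) + treated`` with a random intercept per animal.  A
    lesion-within-animal intercept is added only when lesions have
    replicate rows (``include_lesion_re=None`` auto-detects); with one row
    per lesion that component is not identifiable apart from the residual.

    Month-contrast p-values are Bonferroni-adjusted over the
    ``len(levels) - 1`` comparisons.  Estimates are reported in percentage
    points.  Raises :class:`ConvergenceError` (estimates withheld) if the
    optimiser fails.
    """
    import statsmodels.api as sm

    df = records.copy().reset_index(drop=True)
    # canonical row order makes the fit exactly invariant to input ordering
    sort_cols = [c for c in ("animal_id", "lesion_id", "month", "fraction")
                 if c in df.columns]
    df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    levels = sorted(df["month"].unique()) if levels is None else sorted(levels)
    _validate_lesion_table(df, levels)
    k = len(levels)
    level_index = {lvl: i for i, lvl in enumerate(levels)}

    D = np.zeros((len(df), k))
    for row, month in enumerate(df["month"]):
        D[row, level_index[int(month)]] = 1.0
    Cinv = np.linalg.inv(_coding_matrix(k))
    X = D @ Cinv
    names = ["baseline"] + [f"cp_{lvl}" for lvl in levels[1:]]

    treated = df["treated"].astype(bool).to_numpy().astype(float)
    has_treated = len(np.unique(treated)) > 1
    if has_treated:
        X = np.column_stack([X, treated])
        names.append("treated")

    y = df["fraction"].to_numpy(dtype=float)
    groups = df["animal_id"].to_numpy()

    if include_lesion_re is None:
        include_lesion_re = (
            "lesion_id" in df.columns
            and df.groupby(["animal_id", "lesion_id"]).size().max() > 1
        )

    exog = pd.DataFrame(X, columns=names)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance warnings are expected
        if include_lesion_re:
            data = exog.copy()
            data["fraction"] = y
            data["_animal"] = df["animal_id"].astype(str).to_numpy()
            data["_lesion"] = (
                df["animal_id"].astype(str) + ":" + df["lesion_id"].astype(str)
            ).to_numpy()
            model = sm.MixedLM.from_formula(
                "fraction ~ 0 + " + " + ".join(f"Q('{n}')" for n in names),
                data=data,
                groups=data["_animal"],
                vc_formula={"lesion": "0 + C(_lesion)"},
                re_formula="1",
            )
        else:
            model = sm.MixedLM(y, exog, groups=groups)
        result = None
        failures = []
        for method in ("lbfgs", "powell", "cg"):
            try:
                result = model.fit(reml=True, method=[method])
                if result.converged:
                    break
            except Exception as exc:  # singular step, optimiser blow-up
                failures.append(f"{method}: {exc}")
                result = None
        if result is None:
            raise ConvergenceError("mixed-model fit failed", "; ".join(failures))

        if not result.converged:
            raise ConvergenceError(
                "REML optimisation did not converge", result.summary().as_text()
            )
        params = np.asarray(result.fe_params, dtype=float)
        bse = np.asarray(result.bse_fe, dtype=float)
    pvals = 2.0 * stats.norm.sf(np.abs(params / bse))

    est = {lvl: 100.0 * params[1 + i] for i, lvl in enumerate(levels[1:])}
    ses = {lvl: 100.0 * bse[1 + i] for i, lvl in enumerate(levels[1:])}
    p_raw = {lvl: float(pvals[1 + i]) for i, lvl in enumerate(levels[1:])}
    m = k - 1
    adj = bonferroni([p_raw[lvl] for lvl in levels[1:]], m)
    p_bonf = {lvl: float(adj[i]) for i, lvl in enumerate(levels[1:])}

    if has_treated:
        t_idx = names.index("treated")
        treat_est, treat_se, treat_p = (
            100.0 * params[t_idx],
            100.0 * bse[t_idx],
            float(pvals[t_idx]),
        )
    else:
        treat_est = treat_se = treat_p = None

    var_animal = float(np.asarray(result.cov_re)[0, 0]) if result.cov_re is not None else 0.0
    var_lesion = None
    if include_lesion_re and getattr(result, "vcomp", None) is not None and len(result.vcomp):
        var_lesion = float(result.vcomp[0])

    return ChangepointFit(
        levels=levels,
        baseline_pp=100.0 * params[0],
        estimates_pp=est,
        ses_pp=ses,
        p_raw=p_raw,
        p_bonferroni=p_bonf,
        treatment_pp=treat_est,
        treatment_se_pp=treat_se,
        treatment_p=treat_p,
        var_animal=var_animal,
        var_lesion=var_lesion,
        var_residual=float(result.scale),
        m_comparisons=m,
        df_method="normal",
        converged=bool(result.converged),
        n_obs=len(df),
        n_animals=int(df["animal_id"].nunique()),
    )


@dataclass
class NeuronFit:
    """Result of the weighted neuronal TSPO model (percentage points)."""

    eae_effect_pp: float
    eae_se_pp: float
    eae_p: float
    side_effect_pp: float
    side_se_pp: float
    side_p: float
    intercept_pp: float
    var_animal: float
    var_residual: float
    df_method: str
    converged: bool
    n_obs: int
    n_animals: int
    weights: np.ndarray = field(repr=False, default=None)


def _reml_criterion(lam: float, y, X, Z, w) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profiled REML criterion for V* = lam * Z Z' + diag(1/w).

    Returns (criterion, beta_hat, cov_unscaled, sigma2_hat).
    """
    n, p = X.shape
    V = lam * (Z @ Z.T) + np.diag(1.0 / w)
    L = np.linalg.cholesky(V)
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf, np.full(p, np.nan), np.full((p, p), np.nan), np.nan
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    sigma2 = quad / (n - p)
    crit = (n - p) * np.log(quad) + logdet_V + logdet_XtViX
    return crit, beta, np.linalg.inv(XtViX), sigma2


def fit_neuron_lmm(records: pd.DataFrame) -> NeuronFit:
    """Fit the weighted neuronal TSPO mixed model by profiled REML.

    ``fraction ~ EAE + side(right)`` with a random intercept per animal and
    residual variance ``sigma^2 / n_neurons`` per ROI (ROIs with more
    counted neurons are more precise).  Only relative weights matter.
    Rows flagged as neuron-free (``n_neurons == 0`` or ``flagged``) must be
    removed by the caller; zero weights raise.
    """
    df = records.copy()
    required = {"animal_id", "group", "side", "fraction", "n_neurons"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"neuron table lacks columns: {sorted(missing)}")
    if "flagged" in df.columns and df["flagged"].any():
        raise ValueError("table contains flagged (neuron-free) ROIs; drop them first")
    groups_present = set(df["group"].unique())
    if not {"control", "EAE"} <= groups_present:
        raise ValueError(f"need both control and EAE groups, got {groups_present}")
    w = df["n_neurons"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights (n_neurons) must be positive")

    y = df["fraction"].to_numpy(dtype=float)
    eae = (df["group"] == "EAE").to_numpy(dtype=float)
    side_right = (df["side"] == "right").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), eae, side_right])
    animals = pd.factorize(df["animal_id"])[0]
    Z = np.zeros((len(y), animals.max() + 1))
    Z[np.arange(len(y)), animals] = 1.0
    w_mean = float(w.mean())
    w = w / w_mean  # scale-free precision weights; rescaled back on report

    def crit(log_lam: float) -> float:
        return _reml_criterion(np.exp(log_lam), y, X, Z, w)[0]

    # profile the animal:residual variance ratio on a log grid, then polish
    grid = np.linspace(-12.0, 6.0, 37)
    vals = [crit(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        crit, bracket=None, bounds=(g0 - 1.5, g0 + 1.5), method="bounded"
    )
    lam = float(np.exp(res.x))
    c_opt, beta, cov_u, sigma2 = _reml_criterion(lam, y, X, Z, w)
    c_zero, beta0, cov0, sigma2_0 = _reml_criterion(1e-12, y, X, Z, w)
    if c_zero <= c_opt:  # boundary solution: no animal variance
        lam, beta, cov_u, sigma2, c_opt = 0.0, beta0, cov0, sigma2_0, c_zero
    if not np.isfinite(c_opt):
        raise ConvergenceError("weighted REML criterion is degenerate")

    se = np.sqrt(np.diag(sigma2 * cov_u))
    tval = beta / se
    n_animals = int(df["animal_id"].nunique())
    # containment degrees of freedom: the group effect varies between
    # animals (df = n_animals - 2), laterality varies within animals
    df_between = max(n_animals - 2, 1)
    df_within = max(len(y) - n_animals - 1, 1)
    p_eae = 2.0 * stats.t.sf(abs(tval[1]), df_between)
    p_side = 2.0 * stats.t.sf(abs(tval[2]), df_within)
    return NeuronFit(
        eae_effect_pp=100.0 * beta[1],
        eae_se_pp=100.0 * se[1],
        eae_p=float(p_eae),
        side_effect_pp=100.0 * beta[2],
        side_se_pp=100.0 * se[2],
        side_p=float(p_side),
        intercept_pp=100.0 * beta[0],
        var_animal=lam * sigma2,
        # residual variance on the raw-weight scale: Var(e_ij) = var_residual / n_neurons_ij
        var_residual=sigma2 * w_mean,
        df_method="containment-t",
        converged=True,
        n_obs=len(df),
        n_animals=int(df["animal_id"].nunique()),
        weights=w,
    )
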