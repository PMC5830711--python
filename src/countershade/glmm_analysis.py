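"""Generalized linear mixed models for visual-search performance.

Two model families, both with a Normal per-participant random intercept on
the linear predictor:

* binomial with logit link for detection accuracy,
* gamma for reaction times, with a log link by default (so fixed effects
  are multiplicative on the mean RT) or an inverse link as an option; the
  gamma shape is estimated jointly by maximum likelihood.

The marginal likelihood integrates the random intercept out participant by
participant with adaptive Gauss-Hermite quadrature: the integrand is
recentred at its mode and rescaled by its curvature before the Hermite
rule is applied, so even one node (the Laplace approximation) is accurate
for well-populated participants, and a handful of nodes suffices in
general. Inference follows the reporting conventions of mixed-model
analyses of search experiments: likelihood-ratio chi-square tests for
dropping a factor, and all-pairwise Tukey (single-step max-|z|)
comparisons based on the joint normal law of the contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .synthetic_observer import (
    PATTERNS,
    TRIAL_COLUMNS,
    WEATHERS,
    TrialRecord,
    records_to_frame,
)

__all__ = [
    "ModelSpec",
    "GLMMResult",
    "TestResult",
    "PairwiseResult",
    "TrialTable",
    "read_trial_data",
    "fit_glmm",
    "lr_test",
    "tukey_pairwise",
]

# Candidate column names for the tolerant reader, in priority order.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "participant": ("participant", "subject", "participant_id", "subj",
                    "observer", "id"),
    "session": ("session", "sess", "block"),
    "weather": ("weather", "light", "lighting", "sky", "illumination"),
    "pattern": ("pattern", "reflectance", "cs", "target_pattern",
                "coloration", "condition"),
    "n_distractors": ("n_distractors", "distractors", "ndist", "set_size",
                      "n_items", "nb_distractors"),
    "correct": ("correct", "accuracy", "acc", "found", "success"),
    "rt_s": ("rt_s", "rt", "reaction_time", "rts", "latency", "time"),
}

_WEATHER_NORMALIZE = {"cloudy": "cloudy", "overcast": "cloudy",
                      "diffuse": "cloudy", "sunny": "sunny",
                      "clear": "sunny", "direct": "sunny"}
_PATTERN_NORMALIZE = {
    "no_cs": "no_CS", "nocs": "no_CS", "uniform": "no_CS", "none": "no_CS",
    "cloudy_cs": "cloudy_CS", "cs_cloudy": "cloudy_CS", "cloudy": "cloudy_CS",
    "sunny_cs": "sunny_CS", "cs_sunny": "sunny_CS", "sunny": "sunny_CS",
}


class TrialTable(list):
    """List of :class:`TrialRecord` plus opaque extra-column annotations."""

    def __init__(self, records, extras: pd.DataFrame | None = None,
                 rt_in_milliseconds: bool = False):
        super().__init__(records)
        self.extras = extras if extras is not None else pd.DataFrame()
        self.rt_in_milliseconds = rt_in_milliseconds

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self)


def read_trial_data(path, convert_ms: bool = False,
                    aliases: dict | None = None) -> TrialTable:
    """Read a delimited per-trial table, mapping columns case-insensitively
    through an alias table and normalizing factor spellings.

    Reaction times whose median exceeds 100 look like milliseconds; they
    are flagged (``rt_in_milliseconds``) and converted to seconds only when
    ``convert_ms=True``. Unknown extra columns are kept as annotations.
    Raises a schema error naming the candidates found if a mandatory
    column is missing.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    # round_trip parsing keeps float64 values bit-exact across write/read
    table = pd.read_csv(path, sep=sep, float_precision="round_trip")
    lookup = {c.lower().strip(): c for c in table.columns}
    alias_map = dict(COLUMN_ALIASES)
    if aliases:
        alias_map.update(aliases)

    resolved: dict[str, str] = {}
    for canonical, names in alias_map.items():
        for name in names:
            if name.lower() in lookup:
                resolved[canonical] = lookup[name.lower()]
                break
    missing = [c for c in TRIAL_COLUMNS if c not in resolved]
    if missing:
        raise ValueError(
            f"missing mandatory columns {missing}; columns found: "
            f"{list(table.columns)}"
        )

    data = table[[resolved[c] for c in TRIAL_COLUMNS]].copy()
    data.columns = TRIAL_COLUMNS
    extras = table[[c for c in table.columns
                    if c not in resolved.values()]].copy()

    data["weather"] = (
        data["weather"].astype(str).str.lower().map(_WEATHER_NORMALIZE)
    )
    data["pattern"] = (
        data["pattern"].astype(str).str.lower().map(_PATTERN_NORMALIZE)
    )
    if data["weather"].isna().any() or data["pattern"].isna().any():
        raise ValueError("unrecognized weather/pattern level in trial table")

    rt = data["rt_s"].astype(float)
    in_ms = bool(rt.median() > 100.0)
    if in_ms:
        if convert_ms:
            rt = rt / 1000.0
        else:
            warnings.warn(
                "reaction-time column medians above 100: values look like "
                "milliseconds; pass convert_ms=True to convert",
                stacklevel=2,
            )
    records = [
        TrialRecord(
            participant=int(r.participant),
            session=int(r.session),
            weather=r.weather,
            pattern=r.pattern,
            n_distractors=int(r.n_distractors),
            correct=int(r.correct),
            rt_s=float(rt_val),
        )
        for r, rt_val in zip(data.itertuples(index=False), rt)
    ]
    return TrialTable(records, extras, rt_in_milliseconds=in_ms and not convert_ms)


# --------------------------------------------------------------------------
# model specification and design matrices
# --------------------------------------------------------------------------

_FACTOR_LEVELS = {
    "weather": list(WEATHERS),
    "pattern": list(PATTERNS),
    "session": [1, 2],
}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, family, fixed effects, data filter."""

    response: str = "rt"  # "accuracy" | "rt"
    family: str | None = None  # default: binomial-logit / gamma-log
    fixed_effects: tuple = ("weather", "pattern", "session")
    interaction: bool = False  # weather x pattern
    data_filter: str = "all_trials"

    def __post_init__(self) -> None:
        fam = self.family
        if fam is None:
            fam = "binomial-logit" if self.response == "accuracy" else "gamma-log"
            object.__setattr__(self, "family", fam)
        if self.response == "accuracy" and self.family != "binomial-logit":
            raise ValueError("accuracy requires the binomial-logit family")
        if self.response == "rt" and not self.family.startswith("gamma"):
            raise ValueError("rt requires a gamma family")
        if self.data_filter not in (
            "all_trials", "correct_only", "cloudy_only", "sunny_only"
        ):
            raise ValueError(f"unknown data_filter {self.data_filter!r}")
        unknown = set(self.fixed_effects) - set(_FACTOR_LEVELS)
        if unknown:
            raise ValueError(f"unknown fixed effects {sorted(unknown)}")
        if self.interaction and not {
            "weather", "pattern"
        } <= set(self.fixed_effects):
            raise ValueError("interaction requires weather and pattern")

    def without(self, factor: str) -> "ModelSpec":
        """Nested spec with one factor (and its interactions) dropped."""
        return replace(
            self,
            fixed_effects=tuple(f for f in self.fixed_effects if f != factor),
            interaction=self.interaction
            and factor not in ("weather", "pattern"),
        )


def _apply_filter(frame: pd.DataFrame, data_filter: str) -> pd.DataFrame:
    if data_filter == "correct_only":
        return frame[frame["correct"] == 1]
    if data_filter == "cloudy_only":
        return frame[frame["weather"] == "cloudy"]
    if data_filter == "sunny_only":
        return frame[frame["weather"] == "sunny"]
    return frame


def _design_matrix(frame: pd.DataFrame, spec: ModelSpec):
    """Treatment (reference-cell) coding; returns (X, names, factor_cols)."""
    cols = [np.ones(len(frame))]
    names = ["Intercept"]
    factor_cols: dict[str, list[str]] = {}
    dummies: dict[str, np.ndarray] = {}
    for factor in spec.fixed_effects:
        levels = _FACTOR_LEVELS[factor]
        present = frame[factor].unique()
        factor_cols[factor] = []
        for level in levels[1:]:
            if level not in present and len(present) < len(levels):
                continue  # filtered-out level (e.g. weather subset)
            name = f"{factor}[T.{level}]"
            col = (frame[factor] == level).to_numpy(dtype=float)
            dummies[name] = col
            cols.append(col)
            names.append(name)
            factor_cols[factor].append(name)
    if spec.interaction:
        factor_cols["weather:pattern"] = []
        for wn in factor_cols["weather"]:
            for pn in factor_cols["pattern"]:
                name = f"{wn}:{pn}"
                cols.append(dummies[wn] * dummies[pn])
                names.append(name)
                factor_cols["weather:pattern"].append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design matrix rank-deficient after filtering; columns {names}"
        )
    return X, names, factor_cols


# --------------------------------------------------------------------------
# families
# --------------------------------------------------------------------------


class _Binomial:
    n_extra = 0

    @staticmethod
    def loglik(y, eta, extra):
        return y * eta - np.logaddexp(0.0, eta)

    @staticmethod
    def d1(y, eta, extra):
        return y - special.expit(eta)

    @staticmethod
    def d2(y, eta, extra):
        p = special.expit(eta)
        return -p * (1.0 - p)


class _GammaLog:
    """log mu = eta; extra parameter: log shape."""

    n_extra = 1

    @staticmethod
    def loglik(y, eta, extra):
        k = np.exp(extra[0])
        return (
            k * np.log(k)
            - k * eta
            + (k - 1.0) * np.log(y)
            - k * y * np.exp(-eta)
            - special.gammaln(k)
        )

    @staticmethod
    def d1(y, eta, extra):
        k = np.exp(extra[0])
        return k * (y * np.exp(-eta) - 1.0)

    @staticmethod
    def d2(y, eta, extra):
        k = np.exp(extra[0])
        return -k * y * np.exp(-eta)


class _GammaInverse:
    """mu = 1/eta (canonical-style inverse link); requires eta > 0."""

    n_extra = 1

    @staticmethod
    def loglik(y, eta, extra):
        k = np.exp(extra[0])
        eta = np.maximum(eta, 1e-10)
        return (
            k * np.log(k)
            + k * np.log(eta)
            + (k - 1.0) * np.log(y)
            - k * y * eta
            - special.gammaln(k)
        )

    @staticmethod
    def d1(y, eta, extra):
        k = np.exp(extra[0])
        return k / np.maximum(eta, 1e-10) - k * y

    @staticmethod
    def d2(y, eta, extra):
        k = np.exp(extra[0])
        return -k / np.maximum(eta, 1e-10) ** 2


_FAMILIES = {
    "binomial-logit": _Binomial,
    "gamma-log": _GammaLog,
    "gamma-inverse": _GammaInverse,
}


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------


@dataclass
class GLMMResult:
    params: pd.Series  # fixed effects
    se: pd.Series
    cov: pd.DataFrame  # fixed-effect covariance
    sigma_u: float  # random-intercept SD
    gamma_shape: float | None
    loglik: float
    n_params: int  # all estimated parameters incl. sigma (and shape)
    n_obs: int
    n_groups: int
    converged: bool
    gradient_norm: float
    spec: ModelSpec
    factor_columns: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        z = self.params / self.se
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "z": z,
                "p": 2.0 * stats.norm.sf(np.abs(z)),
            }
        )


@dataclass(frozen=True)
class TestResult:
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class PairwiseResult:
    contrast: str
    estimate: float
    se: float
    z: float
    p_unadjusted: float
    p_adjusted: float


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _group_index(participants: np.ndarray):
    codes, uniques = pd.factorize(participants)
    return codes, len(uniques)


def _marginal_loglik(theta, X, y, codes, n_groups, family, nodes, weights,
                     mode_cache):
    """Marginal log-likelihood via adaptive Gauss-Hermite quadrature."""
    p = X.shape[1]
    beta = theta[:p]
    sigma = theta[p]
    extra = theta[p + 1:]
    eta0 = X @ beta
    inv_var = 1.0 / max(sigma, 1e-8) ** 2

    # per-group mode of l(u) - u^2/(2 sigma^2) by Newton, warm-started
    u = mode_cache.get("u")
    if u is None or len(u) != n_groups:
        u = np.zeros(n_groups)
    for _ in range(50):
        eta = eta0 + u[codes]
        g = np.bincount(codes, family.d1(y, eta, extra),
                        minlength=n_groups) - u * inv_var
        h = -np.bincount(codes, family.d2(y, eta, extra),
                         minlength=n_groups) + inv_var
        step = g / h
        step = np.clip(step, -5.0, 5.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mode_cache["u"] = u
    eta = eta0 + u[codes]
    h = -np.bincount(codes, family.d2(y, eta, extra),
                     minlength=n_groups) + inv_var

    scale = np.sqrt(2.0 / h)  # (n_groups,)
    # log integrand at transformed nodes, summed per group
    log_colsums = np.empty((len(nodes), n_groups))
    for k, x_k in enumerate(nodes):
        u_k = u + scale * x_k
        eta_k = eta0 + u_k[codes]
        ll = np.bincount(codes, family.loglik(y, eta_k, extra),
                         minlength=n_groups)
        log_colsums[k] = (
            ll
            - 0.5 * u_k**2 * inv_var
            - 0.5 * np.log(2.0 * np.pi)
            - np.log(max(sigma, 1e-8))
            + x_k**2
            + np.log(weights[k])
        )
    m = log_colsums.max(axis=0)
    group_ll = m + np.log(np.exp(log_colsums - m).sum(axis=0)) + np.log(scale)
    return float(group_ll.sum())


def _glm_start(X, y, spec):
    """Fixed-effect starting values from an ordinary GLM fit."""
    import statsmodels.api as sm

    if spec.family == "binomial-logit":
        fam = sm.families.Binomial()
    elif spec.family == "gamma-log":
        fam = sm.families.Gamma(link=sm.families.links.Log())
    else:
        fam = sm.families.Gamma(link=sm.families.links.InversePower())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=fam).fit()
    shape0 = None
    if spec.family.startswith("gamma"):
        # moment estimate of the shape from the GLM deviance residuals
        mu = res.fittedvalues
        cv2 = np.mean(((y - mu) / mu) ** 2)
        shape0 = 1.0 / max(cv2, 1e-3)
    return np.asarray(res.params, dtype=float), shape0


def fit_glmm(
    records,
    spec: ModelSpec,
    n_quadrature: int = 8,
    fix_sigma: float | None = None,
    compute_cov: bool = True,
) -> GLMMResult:
    """Maximum-likelihood fit of the random-intercept GLMM.

    ``n_quadrature`` adaptive Gauss-Hermite nodes integrate the participant
    intercept (1 node = the Laplace approximation). ``fix_sigma`` pins the
    random-intercept SD (0 reduces the model to an ordinary GLM).
    ``compute_cov=False`` skips the observed-information covariance (for
    simulation studies that only need estimates and log-likelihoods).
    """
    frame = records.to_frame() if isinstance(records, TrialTable) else (
        records if isinstance(records, pd.DataFrame)
        else records_to_frame(records)
    )
    frame = _apply_filter(frame, spec.data_filter)
    if frame["participant"].nunique() < 2 and fix_sigma is None:
        raise ValueError(
            "random-intercept model needs >= 2 participants"
        )
    y = (
        frame["correct"].to_numpy(dtype=float)
        if spec.response == "accuracy"
        else frame["rt_s"].to_numpy(dtype=float)
    )
    X, names, factor_cols = _design_matrix(frame, spec)
    codes, n_groups = _group_index(frame["participant"].to_numpy())
    family = _FAMILIES[spec.family]
    nodes, weights = np.polynomial.hermite.hermgauss(max(n_quadrature, 1))

    beta0, shape0 = _glm_start(X, y, spec)
    p = X.shape[1]
    theta0 = list(beta0)
    sigma0 = 0.3 if fix_sigma is None else max(fix_sigma, 1e-8)
    theta0.append(sigma0)
    if family.n_extra:
        theta0.append(np.log(shape0 if shape0 else 2.0))
    theta0 = np.asarray(theta0, dtype=float)

    mode_cache: dict = {}

    sigma_bounds = (
        (1e-8, None) if fix_sigma is None
        else (max(fix_sigma, 1e-8), max(fix_sigma, 1e-8))
    )
    bounds = [(None, None)] * p + [sigma_bounds] + [
        (None, None)
    ] * family.n_extra

    def negll(theta):
        return -_marginal_loglik(
            theta, X, y, codes, n_groups, family, nodes, weights, mode_cache
        )

    with np.errstate(over="ignore", invalid="ignore"):
        res = optimize.minimize(
            negll,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    # an "abnormal" line-search exit with a vanishing gradient is converged
    converged = bool(res.success) or grad_norm < 1e-3
    if not converged:
        warnings.warn(
            f"GLMM fit did not converge: {res.message} "
            f"(max |gradient| = {grad_norm:.3g})",
            stacklevel=2,
        )

    # covariance of the fixed effects from the observed information
    cov_fixed = np.full((p, p), np.nan)
    if compute_cov:
        free = [True] * p + [fix_sigma is None] + [True] * family.n_extra
        free_idx = np.where(free)[0]
        hess = _numerical_hessian(negll, theta, free_idx)
        cov_all = _safe_inverse(hess)
        pos = {j: i for i, j in enumerate(free_idx)}
        for a in range(p):
            for b in range(p):
                cov_fixed[a, b] = cov_all[pos[a], pos[b]]

    params = pd.Series(theta[:p], index=names)
    se = pd.Series(np.sqrt(np.maximum(np.diag(cov_fixed), 0.0)), index=names)
    return GLMMResult(
        params=params,
        se=se,
        cov=pd.DataFrame(cov_fixed, index=names, columns=names),
        sigma_u=float(theta[p]),
        gamma_shape=(
            float(np.exp(theta[p + 1])) if family.n_extra else None
        ),
        loglik=float(-res.fun),
        n_params=p + 1 + family.n_extra,
        n_obs=len(y),
        n_groups=n_groups,
        converged=converged,
        gradient_norm=grad_norm,
        spec=spec,
        factor_columns=factor_cols,
    )


def _numerical_hessian(f, x, free_idx, rel_step=1e-4):
    n = len(free_idx)
    h = np.array([rel_step * max(1.0, abs(x[j])) for j in free_idx])
    hess = np.empty((n, n))
    f0 = f(x)
    for a in range(n):
        for b in range(a, n):
            xa, xb = free_idx[a], free_idx[b]
            if a == b:
                xp = x.copy(); xp[xa] += h[a]
                xm = x.copy(); xm[xa] -= h[a]
                hess[a, a] = (f(xp) - 2.0 * f0 + f(xm)) / h[a] ** 2
            else:
                xpp = x.copy(); xpp[xa] += h[a]; xpp[xb] += h[b]
                xpm = x.copy(); xpm[xa] += h[a]; xpm[xb] -= h[b]
                xmp = x.copy(); xmp[xa] -= h[a]; xmp[xb] += h[b]
                xmm = x.copy(); xmm[xa] -= h[a]; xmm[xb] -= h[b]
                hess[a, b] = hess[b, a] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (4.0 * h[a] * h[b])
    return hess


def _safe_inverse(hess):
    try:
        return np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(hess)


# --------------------------------------------------------------------------
# tests
# --------------------------------------------------------------------------


def lr_test(full: GLMMResult, reduced: GLMMResult) -> TestResult:
    """Likelihood-ratio chi-square for nested models on the same data."""
    if full.spec.family != reduced.spec.family:
        raise ValueError("models use different families")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models fitted to different data")
    if not set(reduced.params.index) <= set(full.params.index):
        raise ValueError("reduced model is not nested in the full model")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full")
    chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    if df == 0:
        return TestResult(chi2, 0, 1.0)
    return TestResult(chi2, df, float(stats.chi2.sf(chi2, df)))


def _max_abs_z_adjust(z_values: np.ndarray, corr: np.ndarray,
                      n_points: int = 100_000, seed: int = 2024) -> np.ndarray:
    """Single-step adjusted p: P(max_j |Z_j| >= |z|) under Z ~ MVN(0, R),
    by quasi-random (Sobol) integration with a fixed seed."""
    from scipy.stats import qmc

    k = corr.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    root = eigvec @ np.diag(np.sqrt(np.maximum(eigval, 0.0)))
    sob = qmc.Sobol(d=k, scramble=True, seed=seed)
    m = int(np.ceil(np.log2(n_points)))
    uniforms = sob.random_base2(m)
    normals = stats.norm.ppf(
        np.clip(uniforms, 1e-12, 1.0 - 1e-12)
    ) @ root.T
    max_abs = np.max(np.abs(normals), axis=1)
    return np.array(
        [np.mean(max_abs >= abs(z)) for z in z_values]
    )


def tukey_pairwise(
    result: GLMMResult,
    factor: str,
    n_points: int = 100_000,
    seed: int = 2024,
) -> list[PairwiseResult]:
    """All pairwise comparisons between a factor's levels with the
    single-step (Tukey-style) max-|z| familywise adjustment."""
    if factor not in result.factor_columns:
        raise ValueError(
            f"factor {factor!r} not in model "
            f"({sorted(result.factor_columns)})"
        )
    cols = result.factor_columns[factor]
    levels = [c.split("[T.")[1].rstrip("]") for c in cols]
    ref = str(_FACTOR_LEVELS[factor][0])
    all_levels = [ref] + levels
    names = list(result.params.index)
    p = len(names)

    contrasts, labels = [], []
    for i in range(len(all_levels)):
        for j in range(i + 1, len(all_levels)):
            c = np.zeros(p)
            if i > 0:
                c[names.index(cols[i - 1])] -= 1.0
            c[names.index(cols[j - 1])] += 1.0
            contrasts.append(c)
            labels.append(f"{all_levels[j]} - {all_levels[i]}")
    C = np.array(contrasts)
    est = C @ result.params.to_numpy()
    cov = C @ result.cov.to_numpy() @ C.T
    se = np.sqrt(np.diag(cov))
    z = est / se
    corr = cov / np.outer(se, se)
    p_unadj = 2.0 * stats.norm.sf(np.abs(z))
    if len(z) == 1:
        p_adj = p_unadj.copy()  # one contrast: no multiplicity to adjust
    else:
        p_adj = _max_abs_z_adjust(z, corr, n_points=n_points, seed=seed)
        p_adj = np.maximum(p_adj, p_unadj)  # single-step >= unadjusted
    return [
        PairwiseResult(labels[i], float(est[i]), float(se[i]), float(z[i]),
                       float(p_unadj[i]), float(min(p_adj[i], 1.0)))
        for i in range(len(labels))
    ]
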