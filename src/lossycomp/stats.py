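"""Statistical layer: correlations, mixed model, GAM, bootstrap contrast.

The bin-level behavioral table (participant x lure-difficulty bin) is
modelled two ways:

* a random-intercept linear mixed model,
  LDI = b0 + b1 * lossiness (+ b2 * age) + (1 | participant) + e,
  fit with statsmodels' MixedLM; and
* a Gaussian generalized additive model,
  LDI = b0 + s(lossiness, k=4) [+ s(lossiness, k=4) * age],
  with penalized cubic regression splines whose smoothing parameters are
  chosen by restricted maximum likelihood (REML). The by-age term is a
  varying-coefficient smooth: the spline basis in lossiness multiplied by
  (centered) age, so the shape of the lossiness effect changes with age.

Supporting pieces: Spearman rank correlation (average ranks for ties,
large-sample p), Bonferroni and Benjamini-Hochberg multiplicity
correction, and a participant-resampling bootstrap contrast of a
reference region against the mean of the remaining regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.stats import f as f_dist
from scipy.stats import spearmanr
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined on this input."""


class AlignmentError(ValueError):
    """Participant vectors are not aligned across regions."""


class BasisError(ValueError):
    """Too few unique covariate values for the spline basis."""


# --------------------------------------------------------------------------
# correlations and multiplicity


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value comes from the standard large-sample t approximation used
    by scipy. Constant input leaves ranks undefined and raises.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("constant input: rank correlation undefined")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


def adjust_pvalues(pvals, method: str) -> np.ndarray:
    """Bonferroni (min(1, m*p)) or Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, float)
    if p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, len(p) * p)
    if method == "fdr":
        return multipletests(p, method="fdr_bh")[1]
    raise ValidationError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# mixed model


@dataclass
class MixedModelFit:
    """Random-intercept mixed-model fit of bin-level LDI on lossiness."""

    params: pd.DataFrame          # index term; columns estimate, se, p
    random_intercept_var: float
    residual_var: float
    n_obs: int
    converged: bool
    singular: bool
    method: str
    fallback_ols: pd.DataFrame | None = None  # reported separately when singular

    @property
    def beta1(self) -> float:
        return float(self.params.loc["lossiness", "estimate"])


def fit_mixed_ldi(
    bin_table: pd.DataFrame, include_age: bool = False, reml: bool = True
) -> MixedModelFit:
    """Fit LDI ~ lossiness (+ age) with a participant random intercept.

    Singular fits (zero random-intercept or residual variance, or failed
    convergence) are flagged and accompanied by a fixed-effects-only OLS
    fit reported separately; the mixed-model point estimates are still
    returned.
    """
    required = {"participant", "ldi", "lossiness"} | ({"age"} if include_age else set())
    missing = required - set(bin_table.columns)
    if missing:
        raise ValidationError(f"bin table missing columns: {sorted(missing)}")
    if bin_table["participant"].nunique() < 2:
        raise ValidationError("need >= 2 participants")
    terms = ["lossiness"] + (["age"] if include_age else [])
    exog = sm.add_constant(bin_table[terms].astype(float))
    endog = bin_table["ldi"].astype(float)
    groups = bin_table["participant"]

    singular = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = MixedLM(endog, exog, groups=groups)
            fit = model.fit(reml=reml, method="lbfgs")
            converged = bool(fit.converged)
            re_var = float(np.asarray(fit.cov_re).ravel()[0])
            resid_var = float(fit.scale)
            params = pd.DataFrame(
                {"estimate": fit.params[: len(terms) + 1],
                 "se": fit.bse[: len(terms) + 1],
                 "p": fit.pvalues[: len(terms) + 1]}
            )
            params.index = ["const"] + terms
            if re_var <= 1e-12 or resid_var <= 1e-12 or not converged:
                singular = True
        except (np.linalg.LinAlgError, ValueError):
            singular = True
            converged = False
            re_var = 0.0
            resid_var = float("nan")
            params = None

    ols_params = None
    if singular:
        ols = sm.OLS(endog, exog).fit()
        ols_params = pd.DataFrame(
            {"estimate": ols.params, "se": ols.bse, "p": ols.pvalues}
        )
        ols_params.index = ["const"] + terms
        if params is None:
            params = ols_params
            resid_var = float(ols.mse_resid)
    params = params.rename(index={"const": "intercept"})
    return MixedModelFit(
        params=params,
        random_intercept_var=re_var,
        residual_var=resid_var,
        n_obs=len(bin_table),
        converged=converged,
        singular=singular,
        method="REML" if reml else "ML",
        fallback_ols=None if ols_params is None
        else ols_params.rename(index={"const": "intercept"}),
    )


# --------------------------------------------------------------------------
# penalized-spline GAM (REML)


def _spline_basis(x: np.ndarray, knots: np.ndarray, k: int = 3) -> np.ndarray:
    xc = np.clip(x, knots[k], knots[-k - 1])
    return BSpline.design_matrix(xc, knots, k).toarray()


def _centering_transform(B: np.ndarray) -> np.ndarray:
    """Null-space basis of the sum-to-zero constraint over the data."""
    c = B.sum(axis=0, keepdims=True)  # 1 x p
    q, _ = np.linalg.qr(c.T, mode="complete")
    return q[:, 1:]  # p x (p-1)


def _second_difference_penalty(p: int) -> np.ndarray:
    d = np.diff(np.eye(p), 2, axis=0)
    return d.T @ d


@dataclass
class SmoothTerm:
    """One penalized smooth in a GAM fit."""

    name: str
    edf: float
    F: float
    p: float
    lam: float
    basis_dim: int


@dataclass
class GAMFit:
    """Penalized-regression-spline GAM fit (Gaussian, REML)."""

    intercept: float
    terms: dict[str, SmoothTerm]
    fitted: np.ndarray
    residual_var: float
    edf_total: float
    n_obs: int
    k: int
    method: str = "REML"
    _predictor: object = field(default=None, repr=False)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self._predictor(table)


def fit_gam_ldi(table: pd.DataFrame, k: int = 4, by_age: bool | None = None) -> GAMFit:
    """Fit LDI = b0 + s(lossiness, k) [+ s(lossiness, k) by age] + e.

    The smooth is a cubic regression spline with ``k`` basis functions,
    sum-to-zero centered, penalized by a second-difference penalty; the
    by-age term multiplies the same centered basis by mean-centered age.
    Smoothing parameters minimize the Gaussian REML criterion. Each
    smooth's F statistic is a Wald test on its coefficients at the REML
    smoothing level, on edf-based degrees of freedom.
    """
    for col in ("ldi", "lossiness"):
        if col not in table.columns:
            raise ValidationError(f"table missing column {col!r}")
    x = table["lossiness"].to_numpy(float)
    y = table["ldi"].to_numpy(float)
    if len(np.unique(x)) < k:
        raise BasisError(f"need >= {k} unique lossiness values for a k={k} basis")
    if by_age is None:
        by_age = "age" in table.columns and table["age"].nunique() > 1
    if by_age and "age" not in table.columns:
        raise ValidationError("by_age requested but no age column")

    deg = 3
    lo, hi = float(x.min()), float(x.max())
    interior = np.quantile(x, np.linspace(0, 1, k - deg + 1))[1:-1]
    knots = np.concatenate([[lo] * (deg + 1), interior, [hi] * (deg + 1)])
    B = _spline_basis(x, knots, deg)
    # main smooth: sum-to-zero centered (the intercept absorbs its level);
    # by-age smooth: uncentered, so a constant coefficient function -- a
    # linear age effect -- stays in the span
    Z = _centering_transform(B)
    Xs = B @ Z
    S_full = _second_difference_penalty(B.shape[1])
    Sz = Z.T @ S_full @ Z

    n = len(y)
    blocks = [("s(lossiness)", Xs, Sz)]
    age_mean = 0.0
    if by_age:
        age = table["age"].to_numpy(float)
        age_mean = float(age.mean())
        blocks.append(("s(lossiness):age", B * (age - age_mean)[:, None], S_full))

    X = np.column_stack([np.ones(n)] + [b[1] for b in blocks])
    p_dims = [1] + [b[1].shape[1] for b in blocks]
    offsets = np.cumsum([0] + p_dims)
    XtX = X.T @ X
    Xty = X.T @ y

    rank_s = [int(np.linalg.matrix_rank(b[2])) for b in blocks]
    null_dim = 1 + sum(b[1].shape[1] - r for b, r in zip(blocks, rank_s))
    logdet_S_pos = [
        float(np.sum(np.log(np.sort(np.linalg.eigvalsh(b[2]))[-r:])))
        for b, r in zip(blocks, rank_s)
    ]

    LOGLAM_LO, LOGLAM_HI = -15.0, 22.0

    def assemble_S(log_lams):
        S = np.zeros_like(XtX)
        for (start, stop), loglam, (_, _, Sj) in zip(
            zip(offsets[1:-1], offsets[2:]), log_lams, blocks
        ):
            S[start:stop, start:stop] = math.exp(loglam) * Sj
        return S

    def reml_score(log_lams):
        log_lams = np.clip(log_lams, LOGLAM_LO, LOGLAM_HI)
        S = assemble_S(log_lams)
        A = XtX + S
        try:
            chol = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
            beta = np.linalg.solve(A, Xty)
        except np.linalg.LinAlgError:
            return 1e10
        rss_p = float(y @ y - 2 * beta @ Xty + beta @ XtX @ beta + beta @ S @ beta)
        if rss_p <= 0:
            rss_p = 1e-12
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(chol))))
        logdet_Sp = sum(
            r * ll + ld for r, ll, ld in zip(rank_s, log_lams, logdet_S_pos)
        )
        return 0.5 * (n - null_dim) * math.log(rss_p) + 0.5 * logdet_A - 0.5 * logdet_Sp

    n_lam = len(blocks)
    if n_lam == 1:
        res = optimize.minimize_scalar(
            lambda ll: reml_score([ll]), bounds=(-12, 18), method="bounded"
        )
        log_lams = [float(res.x)]
    else:
        best = None
        for start in ([0.0] * n_lam, [5.0] * n_lam, [-5.0] * n_lam):
            r = optimize.minimize(reml_score, start, method="Nelder-Mead",
                                  options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 400})
            if best is None or r.fun < best.fun:
                best = r
        log_lams = [float(v) for v in np.clip(best.x, LOGLAM_LO, LOGLAM_HI)]

    S = assemble_S(log_lams)
    A = XtX + S
    Ainv = np.linalg.inv(A + 1e-10 * np.eye(len(A)))
    beta = Ainv @ Xty
    F_mat = Ainv @ XtX
    edf_total = float(np.trace(F_mat))
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    sigma2 = rss / max(n - edf_total, 1.0)
    Vb = sigma2 * Ainv

    terms: dict[str, SmoothTerm] = {}
    for j, ((name, _, _), loglam) in enumerate(zip(blocks, log_lams)):
        sl = slice(offsets[j + 1], offsets[j + 2])
        edf_j = float(np.trace(F_mat[sl, sl]))
        bj = beta[sl]
        Vj = Vb[sl, sl]
        r = max(1, int(round(min(edf_j, len(bj)))) if edf_j > 0.5 else 1)
        # rank-r pseudo-inverse Wald statistic
        w, U = np.linalg.eigh(Vj)
        order = np.argsort(w)[::-1][:r]
        w_r, U_r = w[order], U[:, order]
        stat = float(np.sum((U_r.T @ bj) ** 2 / np.maximum(w_r, 1e-300)))
        F_stat = stat / r
        df2 = max(n - edf_total, 1.0)
        p_val = float(f_dist.sf(F_stat, r, df2))
        terms[name] = SmoothTerm(
            name=name, edf=edf_j, F=F_stat, p=p_val,
            lam=math.exp(loglam), basis_dim=len(bj),
        )

    def predictor(new_table: pd.DataFrame) -> np.ndarray:
        xn = new_table["lossiness"].to_numpy(float)
        Bn = _spline_basis(xn, knots, deg)
        cols = [np.ones(len(xn)), Bn @ Z]
        if by_age:
            agen = new_table["age"].to_numpy(float)
            cols.append(Bn * (agen - age_mean)[:, None])
        return np.column_stack(cols) @ beta

    return GAMFit(
        intercept=float(beta[0]),
        terms=terms,
        fitted=fitted,
        residual_var=sigma2,
        edf_total=edf_total,
        n_obs=n,
        k=k,
        _predictor=predictor,
    )


# --------------------------------------------------------------------------
# bootstrap region contrast


@dataclass
class BootstrapContrast:
    """Reference region versus the mean of other regions, bootstrapped."""

    observed: float
    boot_mean: float
    ci_low: float
    ci_high: float
    p_value: float
    n_iter: int
    seed: int
    degenerate: bool = False


def bootstrap_contrast(
    values_by_region: dict[str, np.ndarray],
    reference: str,
    n_iter: int = 10_000,
    seed: int = 0,
) -> BootstrapContrast:
    """Bootstrap the contrast mean(reference) - mean(other regions).

    ``values_by_region`` maps each region to a per-participant vector
    (aligned across regions). Participants are resampled with replacement;
    the 95% CI is percentile-based and the p-value is the two-sided
    percentile probability of the null value 0.
    """
    if reference not in values_by_region:
        raise ValidationError(f"reference region {reference!r} absent")
    others = [r for r in values_by_region if r != reference]
    if len(others) < 2:
        raise ValidationError("need >= 2 regions besides the reference")
    lengths = {len(np.asarray(v)) for v in values_by_region.values()}
    if len(lengths) != 1:
        raise AlignmentError("per-participant vectors differ in length across regions")
    n_part = lengths.pop()
    ref = np.asarray(values_by_region[reference], float)
    other = np.column_stack([np.asarray(values_by_region[r], float) for r in others])

    def stat(idx):
        return float(ref[idx].mean() - other[idx].mean())

    observed = stat(np.arange(n_part))
    rng = np.random.default_rng(seed)
    boots = np.array(
        [stat(rng.integers(0, n_part, size=n_part)) for _ in range(n_iter)]
    )
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min(np.mean(boots <= 0.0), np.mean(boots >= 0.0))
    p = min(max(p, 1.0 / n_iter), 1.0)
    degenerate = n_iter < 2
    if degenerate:
        warnings.warn("bootstrap with n_iter < 2: degenerate CI", stacklevel=2)
    return BootstrapContrast(
        observed=observed,
        boot_mean=float(boots.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        n_iter=n_iter,
        seed=seed,
        degenerate=degenerate,
    )
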