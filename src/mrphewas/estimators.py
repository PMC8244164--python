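"""Two-sample Mendelian-randomization estimators.

Wald ratio, correlated-instrument inverse-variance weighting (generalized
least squares through the origin) with multiplicative random effects,
MR-Egger with its directional-pleiotropy intercept test, multivariable MR,
and the linear-probability-to-odds-ratio conversion for binary traits fit
with linear regression.

All p-values and confidence intervals use standard-normal quantiles; the
multiplicative overdispersion phi = max(1, Q/df) inflates standard errors but
is never allowed to shrink them below the fixed-effect value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.linalg import cho_factor, cho_solve

from .sumstats import InstrumentSet, SummaryAssociation, SumstatsError

Z975 = float(special.ndtri(0.975))
#: Omega condition numbers above this are treated as numerically singular.
MAX_CONDITION = 1e8


class EstimatorError(ValueError):
    """Invalid input to an MR estimator."""


@dataclass(frozen=True, slots=True)
class MREstimate:
    """A causal-effect estimate on the exposure's unit scale."""

    beta_hat: float
    se_hat: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    method: str  # wald | ivw_fixed | ivw_mre | egger | mvmr
    dispersion_phi: float | None = None
    heterogeneity_q: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    exposure_label: str | None = None  # mvmr: which exposure column

    @property
    def neglog10_p(self) -> float:
        """-log10 p computed in log space (survives p underflow)."""
        z = self.beta_hat / self.se_hat
        return -(math.log(2.0) + float(special.log_ndtr(-abs(z)))) / math.log(10.0)


@dataclass(frozen=True, slots=True)
class ORResult:
    """Odds-ratio presentation of a linear-probability-scale estimate."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    case_fraction: float


def _two_sided_p(z: float) -> float:
    return 2.0 * float(special.ndtr(-abs(z)))


def _finish(
    beta: float, se: float, method: str, n_snps: int, **extra
) -> MREstimate:
    return MREstimate(
        beta_hat=float(beta),
        se_hat=float(se),
        ci_low=float(beta - Z975 * se),
        ci_high=float(beta + Z975 * se),
        pval=_two_sided_p(beta / se),
        n_snps=n_snps,
        method=method,
        **extra,
    )


def wald_ratio(
    outcome: SummaryAssociation, exposure: SummaryAssociation
) -> MREstimate:
    """Single-instrument causal estimate: SNP-outcome beta divided by
    SNP-exposure beta, with the first-order delta-method standard error
    ``se_out / |beta_exp|`` (exposure uncertainty ignored, the two-sample
    convention for strong instruments)."""
    if exposure.beta == 0:
        raise EstimatorError(
            f"{exposure.variant_id}: exposure beta is 0 — Wald ratio undefined"
        )
    beta = outcome.beta / exposure.beta
    se = outcome.se / abs(exposure.beta)
    return _finish(beta, se, "wald", 1)


def _check_alignment(
    instruments: InstrumentSet, outcomes: list[SummaryAssociation]
) -> None:
    if len(outcomes) != len(instruments):
        raise EstimatorError(
            f"{len(instruments)} instruments but {len(outcomes)} outcome records"
        )
    for m, o in zip(instruments.members, outcomes):
        if m.variant_id != o.variant_id:
            raise EstimatorError(
                f"instrument/outcome order mismatch at {m.variant_id} vs {o.variant_id}"
            )


def _omega(
    se_out: np.ndarray, correlation: np.ndarray | None
) -> tuple[np.ndarray | None, object | None]:
    """Outcome covariance Omega_ij = se_i se_j rho_ij and its Cholesky factor.

    Returns (None, None) for the identity case, signalling the scalar path.
    """
    if correlation is None:
        return None, None
    omega = np.outer(se_out, se_out) * correlation
    cond = np.linalg.cond(omega)
    if cond > MAX_CONDITION:
        r = np.abs(correlation - np.eye(len(se_out)))
        i, j = np.unravel_index(np.argmax(r), r.shape)
        raise EstimatorError(
            f"outcome covariance is near-singular (cond {cond:.3g}); "
            f"most correlated pair: instruments {i} and {j} "
            f"(rho = {correlation[i, j]:.4f}) — prune near-duplicate variants"
        )
    return omega, cho_factor(omega, lower=True)


def ivw(
    instruments: InstrumentSet,
    outcomes: list[SummaryAssociation],
    random_effects: bool = True,
) -> MREstimate:
    """Inverse-variance-weighted estimate over >= 2 harmonized instruments.

    Generalized weighted least squares through the origin of outcome betas on
    exposure betas, with Omega_ij = se_i se_j rho_ij from the instrument
    correlation matrix (identity when absent).  With multiplicative random
    effects and J >= 3 the standard error is inflated by
    sqrt(max(1, Q/(J-1))) where Q is the residual GLS sum of squares.
    """
    _check_alignment(instruments, outcomes)
    j = len(instruments)
    if j < 2:
        raise EstimatorError("IVW needs >= 2 instruments; use wald_ratio for J = 1")
    x = np.array([m.beta for m in instruments.members], dtype=float)
    y = np.array([o.beta for o in outcomes], dtype=float)
    s = np.array([o.se for o in outcomes], dtype=float)

    _, chol = _omega(s, instruments.correlation)
    if chol is None:
        w = 1.0 / s**2
        xwx = float(w @ x**2)
        beta = float(w @ (x * y)) / xwx
        q = float(w @ (y - beta * x) ** 2)
    else:
        oi_x = cho_solve(chol, x)
        xwx = float(x @ oi_x)
        beta = float(y @ oi_x) / xwx
        resid = y - beta * x
        q = float(resid @ cho_solve(chol, resid))

    var_fixed = 1.0 / xwx
    use_mre = random_effects and j >= 3
    phi = max(1.0, q / (j - 1)) if use_mre else 1.0
    se = math.sqrt(phi * var_fixed)
    return _finish(
        beta, se,
        "ivw_mre" if use_mre else "ivw_fixed",
        j,
        dispersion_phi=phi,
        heterogeneity_q=q,
    )


def egger(
    instruments: InstrumentSet, outcomes: list[SummaryAssociation]
) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure betas *with* an
    intercept, after orienting every pair so the exposure beta is positive.

    The intercept estimates the mean directional-pleiotropy effect; its
    two-sided test is the exclusion-restriction diagnostic.  Overdispersion
    phi = max(1, Q/(J-2)).  A correlation matrix, when present, enters through
    the same Omega as IVW (an extension beyond the independent-instrument
    formulation, flagged by the shared Omega).
    """
    _check_alignment(instruments, outcomes)
    j = len(instruments)
    if j < 3:
        raise EstimatorError(
            "MR-Egger needs >= 3 instruments (intercept not identifiable at J-2 df)"
        )
    x = np.array([m.beta for m in instruments.members], dtype=float)
    y = np.array([o.beta for o in outcomes], dtype=float)
    s = np.array([o.se for o in outcomes], dtype=float)

    flip = np.where(x < 0, -1.0, 1.0)
    x, y = x * flip, y * flip

    design = np.column_stack([np.ones(j), x])
    _, chol = _omega(s, instruments.correlation)
    if chol is None:
        wi = design / s[:, None] ** 2
    else:
        wi = cho_solve(chol, design)
    a = design.T @ wi  # 2x2 normal matrix W' Omega^-1 W
    b = y @ wi
    coef = np.linalg.solve(a, b)
    resid = y - design @ coef
    if chol is None:
        q = float(resid**2 @ (1.0 / s**2))
    else:
        q = float(resid @ cho_solve(chol, resid))
    phi = max(1.0, q / (j - 2))
    cov = phi * np.linalg.inv(a)

    intercept, slope = float(coef[0]), float(coef[1])
    int_se = math.sqrt(cov[0, 0])
    return _finish(
        slope, math.sqrt(cov[1, 1]),
        "egger", j,
        dispersion_phi=phi,
        heterogeneity_q=q,
        egger_intercept=intercept,
        egger_intercept_se=int_se,
        egger_intercept_p=_two_sided_p(intercept / int_se),
    )


def mvmr(
    exposure_matrix: np.ndarray,
    exposure_ses: np.ndarray,
    outcomes: list[SummaryAssociation],
    exposure_labels: list[str] | None = None,
) -> list[MREstimate]:
    """Multivariable MR: weighted regression of outcome betas on all exposure
    beta columns jointly, no intercept, weights 1/se_out^2.

    Separates direct effects when instruments act through several exposures
    (e.g. a target's effect on basal metabolic rate adjusted for BMI).
    ``exposure_ses`` must match ``exposure_matrix`` in shape; the estimator
    conditions on the exposure betas, so the SEs do not enter the weights.
    """
    b = np.asarray(exposure_matrix, dtype=float)
    ses = np.asarray(exposure_ses, dtype=float)
    if b.ndim != 2:
        raise EstimatorError("exposure_matrix must be 2-D (J x E)")
    j, e = b.shape
    if ses.shape != b.shape:
        raise EstimatorError("exposure_ses shape must match exposure_matrix")
    if e < 2:
        raise EstimatorError("multivariable MR needs >= 2 exposures; use ivw")
    if j <= e:
        raise EstimatorError(f"need more instruments than exposures (J={j}, E={e})")
    if len(outcomes) != j:
        raise EstimatorError(f"{j} instrument rows but {len(outcomes)} outcomes")
    labels = exposure_labels or [f"exposure_{k}" for k in range(e)]
    # all-zero columns carry no instrument signal: excluded from the fit so
    # the remaining exposures reduce to the lower-dimensional regression
    active = [k for k in range(e) if np.any(b[:, k] != 0.0)]
    if not active:
        raise EstimatorError("all exposure columns are zero")
    ba = b[:, active]
    if np.linalg.matrix_rank(ba) < len(active):
        corr = np.corrcoef(ba, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i0, i1 = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise EstimatorError(
            f"exposure matrix is rank-deficient; columns {labels[active[i0]]!r} "
            f"and {labels[active[i1]]!r} are collinear (r = {corr[i0, i1]:.4f})"
        )
    y = np.array([o.beta for o in outcomes], dtype=float)
    w = 1.0 / np.array([o.se for o in outcomes], dtype=float) ** 2

    a = (ba * w[:, None]).T @ ba
    rhs = (ba * w[:, None]).T @ y
    coef = np.linalg.solve(a, rhs)
    resid = y - ba @ coef
    q = float(w @ resid**2)
    phi = max(1.0, q / (j - len(active)))
    cov = phi * np.linalg.inv(a)
    out: list[MREstimate] = []
    pos = {k: i for i, k in enumerate(active)}
    for k in range(e):
        if k in pos:
            i = pos[k]
            out.append(
                _finish(
                    coef[i], math.sqrt(cov[i, i]),
                    "mvmr", j,
                    dispersion_phi=phi,
                    heterogeneity_q=q,
                    exposure_label=labels[k],
                )
            )
        else:
            out.append(
                MREstimate(
                    beta_hat=0.0, se_hat=math.inf,
                    ci_low=-math.inf, ci_high=math.inf,
                    pval=1.0, n_snps=j, method="mvmr",
                    dispersion_phi=phi, heterogeneity_q=q,
                    exposure_label=labels[k],
                )
            )
    return out


def linear_beta_to_or(estimate: MREstimate, case_fraction: float) -> ORResult:
    """Convert a linear-probability-scale estimate to an odds ratio.

    Uses the prevalence approximation log OR = beta / (k (1-k)) with the
    standard error scaled identically, then exponentiates the point estimate
    and its normal 95% CI.  Presentation only — significance testing stays on
    the linear scale.
    """
    k = case_fraction
    if not (0.0 < k < 1.0):
        raise EstimatorError(f"case fraction must be in (0, 1), got {k}")
    f = k * (1.0 - k)
    log_or = estimate.beta_hat / f
    se = estimate.se_hat / f
    return ORResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        case_fraction=k,
    )


def or_to_linear_beta(result: ORResult) -> tuple[float, float]:
    """Inverse of :func:`linear_beta_to_or` (beta_hat, se_hat)."""
    k = result.case_fraction
    f = k * (1.0 - k)
    log_or = math.log(result.odds_ratio)
    se_log = math.log(result.ci_high / result.odds_ratio) / Z975
    return log_or * f, se_log * f


def estimate_auto(
    instruments: InstrumentSet, outcomes: list[SummaryAssociation]
) -> MREstimate:
    """Dispatch on instrument count: J=1 Wald ratio, J=2 fixed-effect IVW,
    J>=3 IVW with multiplicative random effects.  The correlation matrix is
    used whenever the instrument set carries one."""
    j = len(instruments)
    if j == 0:
        raise EstimatorError("empty instrument set")
    _check_alignment(instruments, outcomes)
    if j == 1:
        return wald_ratio(outcomes[0], instruments.members[0])
    return ivw(instruments, outcomes, random_effects=j >= 3)
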