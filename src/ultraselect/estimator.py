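"""Maximum-likelihood estimation of the rare-variant depletion parameter.

The depletion parameter lambda_s is the fractional reduction in the rate at
which rare variants occur in a target region relative to the neutral
mutation-model expectation. Under the allele-specific Bernoulli model the
indicator Y_i^(j) for rare variant j at site i has success probability
(1 - lambda_s) * P_i^(j), independently across sites and alleles.

The bias-corrected closed-form MLE is

    lambda_hat = 1 - R' / (M * P_bar)

with R' the total number of rare-variant indicators, M the number of
retained sites, and P_bar the mean over sites of the summed per-allele
probabilities. Its variance follows from the Bernoulli variance of R':

    Var(lambda_hat) = (1 - lambda_hat) / (M P_bar)
                      - (1 - lambda_hat)^2 T / (M P_bar)^2,   T = sum P^2.

lambda_s may be negative (rare variants in excess of expectation) and is
reported unclamped. A likelihood-ratio test against lambda_s = 0 uses the
exact likelihood with 2*delta-log-likelihood ~ chi^2(1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import optimize, stats

from .errors import NumericalError, ValidationError
from .io_genomics import SiteTable


@dataclass
class LambdaEstimate:
    """Point estimate of lambda_s with its sufficient statistics."""

    lambda_s: float
    stderr: float
    R_prime: int
    M: int
    P_bar: float
    Q_bar: float
    T: float
    loglik_alt: float = float("nan")
    loglik_null: float = float("nan")
    p_value: float = float("nan")

    def to_json(self, path: str | None = None, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _extract_arrays(table: SiteTable) -> tuple[np.ndarray, np.ndarray]:
    ret = table.retained
    if len(ret) == 0:
        raise ValidationError("no retained sites (M = 0)")
    P = ret["P"].to_numpy(dtype=float)
    if np.isnan(P).any():
        raise ValidationError("P not filled for all retained rows")
    if np.any((P <= 0) | (P >= 1)):
        raise ValidationError("all P must lie strictly in (0, 1)")
    Y = ret["Y"].to_numpy(dtype=float)
    return Y, P


def loglikelihood_arrays(Y: np.ndarray, P: np.ndarray, lambda_s: float) -> float:
    """Exact Bernoulli log-likelihood at ``lambda_s`` for indicator/probability
    arrays over (site, alt) pairs."""
    q = (1.0 - lambda_s) * P
    if np.any(q < 0) or np.any(q >= 1):
        if lambda_s == 1.0:
            # q == 0 everywhere: legal boundary
            q = np.zeros_like(P)
        else:
            raise NumericalError(
                f"lambda_s = {lambda_s} puts a Bernoulli parameter outside [0, 1)"
            )
    with np.errstate(divide="ignore"):
        term1 = np.where(Y == 1, np.log(np.where(q > 0, q, 1.0)), 0.0)
        term1 = np.where((Y == 1) & (q == 0), -np.inf, term1)
        term2 = np.where(Y == 0, np.log1p(-q), 0.0)
    return float(np.sum(term1) + np.sum(term2))


def loglikelihood(table: SiteTable, lambda_s: float) -> float:
    """Exact log-likelihood of the allele-specific model at ``lambda_s``."""
    Y, P = _extract_arrays(table)
    return loglikelihood_arrays(Y, P, lambda_s)


def estimate_lambda_arrays(
    Y: np.ndarray, P: np.ndarray, compute_lrt: bool = True
) -> LambdaEstimate:
    """Closed-form estimator (with LRT) on raw (site, alt) arrays.

    ``Y`` and ``P`` must have length 3 * M (three alleles per site).
    """
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    if len(Y) != len(P) or len(Y) == 0 or len(Y) % 3 != 0:
        raise ValidationError("Y and P must be equal-length, non-empty, length 3M")
    M = len(Y) // 3
    sumP = float(P.sum())
    if sumP <= 0:
        raise NumericalError("M * P_bar = 0: no variants expected under the model")
    R_prime = int(Y.sum())
    P_bar = sumP / M  # mean over sites of the summed per-allele P
    Q_bar = P_bar / 3.0
    T = float(np.sum(P**2))
    lam = 1.0 - R_prime / sumP
    var = (1.0 - lam) / sumP - (1.0 - lam) ** 2 * T / sumP**2
    if var < 0:
        warnings.warn("negative variance estimate clamped to 0", RuntimeWarning)
        var = 0.0
    if lam == 1.0:
        warnings.warn(
            "lambda_s at boundary 1: standard error is not regular there",
            RuntimeWarning,
        )
    est = LambdaEstimate(
        lambda_s=lam,
        stderr=float(np.sqrt(var)),
        R_prime=R_prime,
        M=M,
        P_bar=P_bar,
        Q_bar=Q_bar,
        T=T,
    )
    if compute_lrt:
        _attach_lrt(est, Y, P)
    return est


def _mle_bounds(Y: np.ndarray, P: np.ndarray) -> tuple[float, float]:
    lo = 1.0 - (1.0 - 1e-12) / float(P.max())
    hi = 1.0 - 1e-12 if Y.sum() > 0 else 1.0
    return lo, hi


def maximize_loglikelihood(Y: np.ndarray, P: np.ndarray) -> tuple[float, float]:
    """Numerically maximize the exact likelihood; returns (lambda_hat, loglik).

    One-dimensional bounded optimization seeded at the closed form, so the
    LRT statistic is never negative.
    """
    if Y.sum() == 0:
        return 1.0, 0.0
    lo, hi = _mle_bounds(Y, P)
    closed = 1.0 - float(Y.sum()) / float(P.sum())
    res = optimize.minimize_scalar(
        lambda lam: -loglikelihood_arrays(Y, P, lam),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    best_lam, best_ll = float(res.x), -float(res.fun)
    if lo < closed < hi:
        ll_closed = loglikelihood_arrays(Y, P, closed)
        if ll_closed > best_ll:
            best_lam, best_ll = closed, ll_closed
    return best_lam, best_ll


def _attach_lrt(est: LambdaEstimate, Y: np.ndarray, P: np.ndarray) -> None:
    _, ll_alt = maximize_loglikelihood(Y, P)
    ll_null = loglikelihood_arrays(Y, P, 0.0)
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    est.loglik_alt = ll_alt
    est.loglik_null = ll_null
    est.p_value = float(stats.chi2.sf(stat, df=1))


def estimate_lambda(
    table: SiteTable,
    compute_lrt: bool = True,
    max_sites: int | None = None,
    seed: int | None = None,
) -> LambdaEstimate:
    """Estimate lambda_s from a SiteTable with filled P.

    When ``max_sites`` is given and fewer than the number of retained sites,
    a seeded simple random subsample of sites is used.
    """
    Y, P = _extract_arrays(table)
    M = len(Y) // 3
    if max_sites is not None and max_sites < M:
        rng = np.random.default_rng(seed)
        take = rng.choice(M, size=max_sites, replace=False)
        idx = (take[:, None] * 3 + np.arange(3)).ravel()
        Y, P = Y[idx], P[idx]
    return estimate_lambda_arrays(Y, P, compute_lrt=compute_lrt)


def lrt_pvalue(table: SiteTable) -> float:
    """p-value of the likelihood-ratio test of lambda_s != 0 vs lambda_s = 0."""
    Y, P = _extract_arrays(table)
    est = estimate_lambda_arrays(Y, P, compute_lrt=True)
    return est.p_value


def estimate_lambda_simple(n_rare: int, n_sites: int, mean_P: float) -> float:
    """Site-level estimator 1 - R / (M * P_bar).

    The site-level variant allows at most one rare-variant flag per site;
    it coincides with the allele-specific estimator when no site carries
    more than one rare variant.
    """
    if n_sites <= 0:
        raise ValidationError("n_sites must be positive")
    if mean_P <= 0:
        raise ValidationError("mean_P must be positive")
    if n_rare > n_sites:
        raise ValidationError("n_rare exceeds n_sites (one flag per site)")
    if n_rare < 0:
        raise ValidationError("n_rare must be non-negative")
    return 1.0 - n_rare / (n_sites * mean_P)
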