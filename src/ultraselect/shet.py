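"""Conversion of lambda_s to heterozygous selection coefficients.

Under strong selection against heterozygotes and mutation-selection
balance, the equilibrium frequency of a deleterious allele is mu / s_het,
so the expected number of copies in a sample of 2N chromosomes is
2 N mu / s_het. Equating the expected number of polymorphic sites under
this model with the depletion model's expectation M (1 - lambda_s) P_bar
gives

    s_het ~= (2 N / c) / (1 - lambda_s),      c = P_bar / mu.

When s_het varies across sites the same expression estimates the harmonic
mean H[s] = M / sum(1/s_i), a lower bound on the arithmetic mean. If a
fraction pi0 of target sites is neutral and an external estimate rho of the
selected fraction (1 - pi0) is available, the adjusted estimator

    H[s] ~= (2 N / c) * rho / (rho - lambda_s)

removes part of the resulting downward bias.

The approximation is intended for strong depletion; in a gnomAD-v3-sized
panel (N = 71,702 diploids, P_bar = 0.162) it is reliable only for
lambda_s above roughly 0.45 (s_het >= ~0.02). A warning is emitted below
that range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .errors import ConfigError, NumericalError

#: depletion below which the mutation-selection-balance conversion is
#: unreliable for a gnomAD-v3-sized panel
LAMBDA_RELIABLE_MIN = 0.45


class WeakDepletionWarning(UserWarning):
    """Conversion requested outside the strong-depletion regime."""


@dataclass(frozen=True)
class SelectionParams:
    """Sample size and mutation-rate parameters of the conversion.

    N
        number of diploid individuals in the panel (gnomAD v3: 71,702)
    mu
        per-site, per-generation mutation rate
    P_bar
        mean rate at which rare variants occur per site under neutrality
    """

    N: int = 71_702
    mu: float = 1.2e-8
    P_bar: float = 0.162

    def __post_init__(self):
        if self.N <= 0 or self.mu <= 0 or self.P_bar <= 0:
            raise ConfigError("N, mu and P_bar must all be positive")

    @property
    def c(self) -> float:
        """Copies of rare variation per unit mutation rate, P_bar / mu."""
        return self.P_bar / self.mu


def shet_from_lambda(lambda_s: float, params: SelectionParams = SelectionParams()) -> float:
    """Harmonic-mean s_het implied by a depletion ``lambda_s``.

    Strictly increasing in lambda_s; defined only for lambda_s < 1.
    """
    if lambda_s >= 1:
        raise NumericalError("lambda_s must be < 1 for the s_het conversion")
    if lambda_s < LAMBDA_RELIABLE_MIN:
        warnings.warn(
            f"lambda_s = {lambda_s:.3g} is below {LAMBDA_RELIABLE_MIN}; the "
            "mutation-selection-balance conversion is unreliable in this regime",
            WeakDepletionWarning,
            stacklevel=2,
        )
    return (2.0 * params.N / params.c) / (1.0 - lambda_s)


def shet_adjusted(
    lambda_s: float, rho: float, params: SelectionParams = SelectionParams()
) -> float:
    """s_het conversion adjusted for a neutral fraction pi0 = 1 - rho.

    ``rho`` is the externally estimated fraction of target sites under any
    selection (e.g. on the human-chimpanzee divergence timescale); it must
    exceed ``lambda_s`` for the harmonic mean to be defined.
    """
    if not 0 < rho <= 1:
        raise NumericalError("rho must lie in (0, 1]")
    if rho <= lambda_s:
        raise NumericalError(
            f"rho ({rho}) must exceed lambda_s ({lambda_s}); "
            "harmonic mean undefined otherwise"
        )
    return (2.0 * params.N / params.c) * rho / (rho - lambda_s)


def harmonic_mean_s(s_values: Iterable[float]) -> float:
    """Harmonic mean H[s] = M / sum(1/s_i) of positive selection coefficients."""
    arr = np.asarray(list(s_values), dtype=float)
    if arr.size == 0:
        raise NumericalError("empty collection of selection coefficients")
    if np.any(arr <= 0):
        raise NumericalError("all selection coefficients must be positive")
    return float(stats.hmean(arr))
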