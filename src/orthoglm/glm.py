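"""Ordinary-least-squares fitting with residual-variance summaries.

For model comparison between equally complex designs, the log residual
variance ``ln(RSS/n)`` is the working statistic: AIC and BIC are linear
functions of it when the number of free parameters matches, so ranking by
any of the three is identical. The solver is QR-based with column pivoting
so that near-collinear designs — the package's whole subject — are either
solved stably or rejected with the offending columns named.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .design import DesignMatrix
from .errors import CollinearityError, DegenerateInputError

__all__ = ["GLMFit", "fit_glm", "information_criteria"]

#: relative tolerance on pivoted-QR diagonal for the rank check
RANK_RTOL = 1e-10


@dataclass(frozen=True)
class GLMFit:
    """Result of an OLS fit of one design to one series.

    ``k`` counts all design columns including the intercept.
    ``log_res_var`` is ``ln(rss / n)`` with no degrees-of-freedom
    correction, matching the AIC/BIC forms
    ``aic = n ln(rss/n) + 2k`` and ``bic = n ln(rss/n) + k ln(n)``.
    """

    betas: np.ndarray = field(repr=False)
    column_names: tuple[str, ...]
    residuals: np.ndarray = field(repr=False)
    rss: float
    n: int
    k: int
    r_squared: float

    @property
    def log_res_var(self) -> float:
        if self.rss == 0.0:
            return -np.inf
        return float(np.log(self.rss / self.n))

    @property
    def aic(self) -> float:
        return self.n * self.log_res_var + 2 * self.k

    @property
    def bic(self) -> float:
        return self.n * self.log_res_var + self.k * np.log(self.n)

    def beta(self, name: str) -> float:
        """Parameter estimate for the named design column."""
        try:
            return float(self.betas[self.column_names.index(name)])
        except ValueError:
            raise KeyError(
                f"no column {name!r}; design has {self.column_names}"
            ) from None


def fit_glm(y: np.ndarray, X: DesignMatrix) -> GLMFit:
    """Fit a design to a series by ordinary least squares.

    Parameters
    ----------
    y
        Observed series, length equal to the design's ``n_samples``.
    X
        Design matrix; must have full column rank.

    Raises
    ------
    CollinearityError
        If the design is rank deficient; the message names the columns
        that are (numerically) linear combinations of earlier ones.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be 1-D")
    if y.size != X.n_samples:
        raise ValueError(
            f"series has {y.size} samples but design has {X.n_samples}"
        )
    M = X.matrix()
    names = X.column_names
    n, k = M.shape

    q, r, piv = linalg.qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > RANK_RTOL * diag[0])) if diag[0] > 0 else 0
    if rank < k:
        bad = sorted(names[p] for p in piv[rank:])
        raise CollinearityError(
            f"design is rank deficient (rank {rank} of {k}); collinear "
            f"columns: {bad}"
        )
    beta_piv = linalg.solve_triangular(r, q.T @ y)
    betas = np.empty(k)
    betas[piv] = beta_piv

    residuals = y - M @ betas
    rss = float(residuals @ residuals)
    if X.include_intercept:
        tss = float(np.sum((y - y.mean()) ** 2))
    else:
        tss = float(y @ y)
    r_squared = 1.0 - rss / tss if tss > 0 else 0.0
    return GLMFit(
        betas=betas,
        column_names=names,
        residuals=residuals,
        rss=rss,
        n=n,
        k=k,
        r_squared=r_squared,
    )


def information_criteria(fit: GLMFit) -> tuple[float, float]:
    """Return ``(aic, bic)`` for a fit.

    Raises
    ------
    DegenerateInputError
        If ``rss == 0`` — the criteria are undefined (−inf), which signals
        an overfit design or noise-free input.
    """
    if fit.rss == 0.0:
        raise DegenerateInputError(
            "information criteria are undefined for a zero-residual fit"
        )
    return fit.aic, fit.bic
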