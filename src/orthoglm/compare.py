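"""Three equivalent model-comparison approaches for correlated regressors.

When two candidate parametric regressors (say a reward-outcome indicator
and a reward-prediction-error trace) are highly correlated, part of the
signal variance is explained equally well by either. A comparison of which
candidate better describes a series can nevertheless be run in three
equivalent ways, all based on ordinary GLMs:

1. ``orthogonalized_betas`` — compare the betas of the *orthogonalized*
   regressors from the two full designs; each measures variance uniquely
   explained by its candidate.
2. ``nonorthogonalized_betas`` — compare the betas of the
   *non-orthogonalized* regressors (shared plus unique variance); the
   subtraction implicit in the comparison cancels the shared part.
3. ``residual_variance`` — fit the two reduced single-candidate designs
   and pick the one with lower log residual variance, which for equal
   complexity is the minimum-AIC/BIC choice.

Away from ties the three approaches select the same winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignMatrix, Regressor, build_designs
from .errors import DegenerateInputError
from .glm import GLMFit, fit_glm

__all__ = [
    "ComparisonResult",
    "ComparisonReport",
    "compare_orthogonalized",
    "compare_nonorthogonalized",
    "compare_residuals",
    "run_report",
]

APPROACHES = (
    "orthogonalized_betas",
    "nonorthogonalized_betas",
    "residual_variance",
)

DEFAULT_TIE_TOLERANCE = 1e-6

#: shared variance (r^2) above which the report carries a caveat that
#: attributing the shared part needs prior knowledge
SHARED_VARIANCE_WARNING = 0.5


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one comparison approach for one series.

    ``margin`` is ``statistic_A - statistic_B`` on the approach's scale
    (betas for the first two approaches, negative log residual variance
    for the third), so positive margins favor model A. ``winner`` is
    ``"A"``, ``"B"`` or ``"tie"`` (when ``|margin| < tie_tolerance``).
    """

    region: str
    approach: str
    statistic_A: float
    statistic_B: float
    margin: float
    winner: str
    tie_tolerance: float
    name_A: str = "A"
    name_B: str = "B"

    @property
    def winner_name(self) -> str:
        return {"A": self.name_A, "B": self.name_B}.get(self.winner, "tie")


@dataclass(frozen=True)
class ComparisonReport:
    """All three comparison results for one series, plus diagnostics.

    ``agreement`` is true when all non-tie winners are identical (and
    vacuously true if every approach tied). ``r`` is the Pearson
    correlation between the candidates before orthogonalization; when its
    square exceeds 0.5 the ``warnings`` list notes that interpreting the
    shared variance requires prior knowledge.
    """

    region: str
    results: tuple[ComparisonResult, ...]
    agreement: bool
    r: float
    n: int
    k: int
    warnings: tuple[str, ...] = ()

    def result(self, approach: str) -> ComparisonResult:
        for res in self.results:
            if res.approach == approach:
                return res
        raise KeyError(approach)

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "diagnostics": {"r": self.r, "n": self.n, "k": self.k},
            "agreement": self.agreement,
            "warnings": list(self.warnings),
            "results": [
                {
                    "approach": res.approach,
                    "statistic_A": res.statistic_A,
                    "statistic_B": res.statistic_B,
                    "margin": res.margin,
                    "winner": res.winner,
                    "winner_name": res.winner_name,
                    "tie_tolerance": res.tie_tolerance,
                }
                for res in self.results
            ],
        }


def _decide(margin: float, tie_tolerance: float) -> str:
    if abs(margin) < tie_tolerance:
        return "tie"
    return "A" if margin > 0 else "B"


def _stat(value: float, use_abs: bool) -> float:
    return abs(value) if use_abs else value


def _result(
    region: str,
    approach: str,
    stat_a: float,
    stat_b: float,
    tie_tolerance: float,
    regA: Regressor,
    regB: Regressor,
) -> ComparisonResult:
    margin = stat_a - stat_b
    return ComparisonResult(
        region=region,
        approach=approach,
        statistic_A=stat_a,
        statistic_B=stat_b,
        margin=margin,
        winner=_decide(margin, tie_tolerance),
        tie_tolerance=tie_tolerance,
        name_A=regA.name,
        name_B=regB.name,
    )


def _fit_full(y: np.ndarray, designs: dict[str, DesignMatrix]) -> tuple[GLMFit, GLMFit]:
    return fit_glm(y, designs["full_1"]), fit_glm(y, designs["full_2"])


def compare_orthogonalized(
    y: np.ndarray,
    regA: Regressor,
    regB: Regressor,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
    region: str = "region",
    use_abs: bool = False,
) -> ComparisonResult:
    """Compare betas of the orthogonalized regressors (unique variance).

    Fits both full designs; model A's statistic is the beta of A
    orthogonalized against B (from the second full design) and vice
    versa. The larger beta — more uniquely explained variance — wins.
    """
    designs = build_designs(regA, regB)
    fit1, fit2 = _fit_full(y, designs)
    stat_b = _stat(float(fit1.betas[1]), use_abs)  # B orth. against A
    stat_a = _stat(float(fit2.betas[1]), use_abs)  # A orth. against B
    return _result(
        region, "orthogonalized_betas", stat_a, stat_b, tie_tolerance, regA, regB
    )


def compare_nonorthogonalized(
    y: np.ndarray,
    regA: Regressor,
    regB: Regressor,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
    region: str = "region",
    use_abs: bool = False,
) -> ComparisonResult:
    """Compare betas of the non-orthogonalized regressors.

    Each beta measures shared plus uniquely explained variance; the
    difference cancels the shared part, so the winner again is the model
    with more unique variance. Either beta alone (against baseline) can be
    large for *both* candidates — comparing them is what prevents
    misattribution.
    """
    designs = build_designs(regA, regB)
    fit1, fit2 = _fit_full(y, designs)
    stat_a = _stat(float(fit1.betas[0]), use_abs)  # A, not orthogonalized
    stat_b = _stat(float(fit2.betas[0]), use_abs)  # B, not orthogonalized
    return _result(
        region, "nonorthogonalized_betas", stat_a, stat_b, tie_tolerance, regA, regB
    )


def compare_residuals(
    y: np.ndarray,
    regA: Regressor,
    regB: Regressor,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
    region: str = "region",
    use_abs: bool = False,
) -> ComparisonResult:
    """Compare log residual variance of the two reduced designs.

    The statistic reported per model is the *negative* log residual
    variance so that, as in the other approaches, larger is better; the
    winner is the reduced design leaving less unexplained variance, i.e.
    the minimum-AIC/BIC model at equal complexity.
    """
    if regA.name == regB.name and np.array_equal(regA.samples, regB.samples):
        stat = -fit_glm(y, DesignMatrix([regA])).log_res_var
        return _result(
            region, "residual_variance", stat, stat, tie_tolerance, regA, regB
        )
    fit_a = fit_glm(y, DesignMatrix([regA]))
    fit_b = fit_glm(y, DesignMatrix([regB]))
    if fit_a.rss == 0.0 or fit_b.rss == 0.0:
        raise DegenerateInputError(
            "a reduced design has zero residual sum of squares; log "
            "residual variance is undefined for noise-free input"
        )
    return _result(
        region,
        "residual_variance",
        -fit_a.log_res_var,
        -fit_b.log_res_var,
        tie_tolerance,
        regA,
        regB,
    )


def run_report(
    y: np.ndarray,
    regA: Regressor,
    regB: Regressor,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
    region: str = "region",
    use_abs: bool = False,
) -> ComparisonReport:
    """Run all three comparison approaches and summarize agreement."""
    designs = build_designs(regA, regB)
    fit1, fit2 = _fit_full(y, designs)
    fit_a = fit_glm(y, designs["reduced_A"])
    fit_b = fit_glm(y, designs["reduced_B"])

    results = [
        _result(
            region,
            "orthogonalized_betas",
            _stat(float(fit2.betas[1]), use_abs),
            _stat(float(fit1.betas[1]), use_abs),
            tie_tolerance,
            regA,
            regB,
        ),
        _result(
            region,
            "nonorthogonalized_betas",
            _stat(float(fit1.betas[0]), use_abs),
            _stat(float(fit2.betas[0]), use_abs),
            tie_tolerance,
            regA,
            regB,
        ),
        _result(
            region,
            "residual_variance",
            -fit_a.log_res_var,
            -fit_b.log_res_var,
            tie_tolerance,
            regA,
            regB,
        ),
    ]

    non_tie = {res.winner for res in results if res.winner != "tie"}
    agreement = len(non_tie) <= 1

    r = float(np.corrcoef(regA.samples, regB.samples)[0, 1])
    warnings: list[str] = []
    if r * r > SHARED_VARIANCE_WARNING:
        warnings.append(
            f"candidates share {r * r:.0%} of their variance (r = {r:.2f}); "
            "attributing the shared variance to the winner requires prior "
            "knowledge about the region"
        )
    return ComparisonReport(
        region=region,
        results=tuple(results),
        agreement=agreement,
        r=r,
        n=fit1.n,
        k=fit1.k,
        warnings=tuple(warnings),
    )
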