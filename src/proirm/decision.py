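"""Go/stop decision-confidence analytics.

Given the precision (SD of the estimated arm difference) delivered by an
analysis method and a clinically meaningful target value TV (negative =
benefit), this module quantifies decision operating characteristics under a
mixture prior for the true effect: 80% point mass at zero (ineffective
compound) and 20% normal around the TV with SD 1. A *go* is declared when
the estimated difference is at or below the TV.

Every Monte-Carlo quantity has a closed-form counterpart
(:func:`decision_table_analytic`, normal CDFs plus a standard bivariate
orthant probability) so the stochastic procedure can be validated exactly.

Note on the go-probability sign: the power function is
``P(Go) = Phi((TV - delta) / sigma)`` — more-negative true effects give a
higher go probability when benefit is negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "DecisionInputs",
    "DecisionTable",
    "MethodSummary",
    "sample_size_ratio",
    "ci_width",
    "sd_from_ci",
    "p_go",
    "p_stop",
    "decision_table_mc",
    "decision_table_analytic",
    "ppv",
    "npv",
    "power_curve",
    "power_threshold",
    "roc_and_auc",
]

#: two-sided 95% normal quantile used to convert CI widths to SDs
Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class DecisionInputs:
    """Inputs to the decision-probability computation.

    ``tv``: target value (score units, negative = benefit). ``sigma_delta``:
    SD of the estimated arm difference for the method. The mixture prior for
    the true effect puts weight ``w0`` on a point mass at 0 and ``1 - w0``
    on Normal(tv, prior_sd^2).
    """

    tv: float
    sigma_delta: float
    w0: float = 0.8
    prior_sd: float = 1.0
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_delta <= 0:
            raise ValueError("sigma_delta must be > 0")
        if not 0.0 <= self.w0 <= 1.0:
            raise ValueError("w0 must be in [0, 1]")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class DecisionTable:
    """Joint probabilities of (true state, decision) plus the predictive values."""

    p_correct_go: float
    p_incorrect_go: float
    p_correct_stop: float
    p_incorrect_stop: float

    @property
    def p_go(self) -> float:
        return self.p_correct_go + self.p_incorrect_go

    @property
    def p_stop(self) -> float:
        return self.p_correct_stop + self.p_incorrect_stop

    @property
    def ppv(self) -> float | None:
        return ppv(self)

    @property
    def npv(self) -> float | None:
        return npv(self)

    def to_dict(self) -> dict:
        return {
            "p_correct_go": self.p_correct_go,
            "p_incorrect_go": self.p_incorrect_go,
            "p_correct_stop": self.p_correct_stop,
            "p_incorrect_stop": self.p_incorrect_stop,
            "p_go": self.p_go,
            "p_stop": self.p_stop,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass(frozen=True)
class MethodSummary:
    """Per-arm endpoint mean and SE for one method/scale (ROC inputs)."""

    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("SE must be > 0")


def ci_width(lower: float, upper: float) -> float:
    """Width of a confidence interval given its bounds."""
    if upper <= lower:
        raise ValueError("upper bound must exceed lower bound")
    return upper - lower


def sd_from_ci(lower: float, upper: float) -> float:
    """SD implied by an equal-tailed 95% normal CI."""
    return ci_width(lower, upper) / (2.0 * Z975)


def sample_size_ratio(ci_width_reference: float, ci_width_alternative: float) -> float:
    """Fold-increase in sample size for the reference method to reach the
    alternative method's precision: (width_ref / width_alt)^2."""
    if ci_width_reference <= 0 or ci_width_alternative <= 0:
        raise ValueError("CI widths must be > 0")
    return (ci_width_reference / ci_width_alternative) ** 2


def p_go(delta: float | np.ndarray, sigma_delta: float, tv: float) -> float | np.ndarray:
    """Probability of a go decision at true effect ``delta``:
    Phi((tv - delta) / sigma_delta)."""
    if sigma_delta <= 0:
        raise ValueError("sigma_delta must be > 0")
    out = stats.norm.cdf((tv - np.asarray(delta, dtype=float)) / sigma_delta)
    return float(out) if np.ndim(delta) == 0 else out


def p_stop(delta: float | np.ndarray, sigma_delta: float, tv: float) -> float | np.ndarray:
    return 1.0 - p_go(delta, sigma_delta, tv)


def _bvn_orthant(rho: float) -> float:
    """P(X <= 0, Y <= 0) for standard bivariate normal with correlation rho."""
    return 0.25 + math.asin(rho) / (2.0 * math.pi)


def decision_table_analytic(inputs: DecisionInputs) -> DecisionTable:
    """Exact decision table under the mixture prior.

    For the point-mass component the go probability is ``Phi(tv / sigma)``
    (a true effect of 0 exceeds a negative TV, so any go is incorrect). For
    the normal component write the true effect as ``tv + s*U`` with
    U ~ N(0,1); go means ``tv + s*U + sigma*Z <= tv``; the joint cell
    probabilities are orthant probabilities of (U, s*U + sigma*Z) with
    correlation ``s / sqrt(s^2 + sigma^2)``.
    """
    tv, sigma, w0, s = inputs.tv, inputs.sigma_delta, inputs.w0, inputs.prior_sd
    w1 = 1.0 - w0
    go_point = stats.norm.cdf(tv / sigma)  # estimate <= tv given true effect 0
    rho = s / math.sqrt(s * s + sigma * sigma)
    both_neg = _bvn_orthant(rho)  # P(U <= 0, sU + sigma Z <= 0)
    correct_go = w1 * both_neg
    incorrect_stop = w1 * (0.5 - both_neg)
    incorrect_go = w0 * go_point + w1 * (0.5 - both_neg)
    correct_stop = w0 * (1.0 - go_point) + w1 * both_neg
    return DecisionTable(
        p_correct_go=correct_go,
        p_incorrect_go=incorrect_go,
        p_correct_stop=correct_stop,
        p_incorrect_stop=incorrect_stop,
    )


def decision_table_mc(inputs: DecisionInputs) -> DecisionTable:
    """Monte-Carlo decision table: draw the true effect from the mixture,
    then an estimated effect ~ Normal(true, sigma_delta); go iff the
    estimate is at or below the TV."""
    rng = np.random.default_rng(inputs.seed)
    n = inputs.n_samples
    effective = rng.random(n) >= inputs.w0
    delta_t = np.where(
        effective, rng.normal(inputs.tv, inputs.prior_sd, size=n), 0.0
    )
    estimate = rng.normal(delta_t, inputs.sigma_delta)
    go = estimate <= inputs.tv
    truth = delta_t <= inputs.tv
    return DecisionTable(
        p_correct_go=float(np.mean(truth & go)),
        p_incorrect_go=float(np.mean(~truth & go)),
        p_correct_stop=float(np.mean(~truth & ~go)),
        p_incorrect_stop=float(np.mean(truth & ~go)),
    )


def ppv(table: DecisionTable) -> float | None:
    """P(correct | go); None (with a warning) when P(go) = 0."""
    if table.p_go == 0:
        warnings.warn("P(Go) is zero; PPV undefined", stacklevel=2)
        return None
    return table.p_correct_go / table.p_go


def npv(table: DecisionTable) -> float | None:
    """P(correct | stop); None (with a warning) when P(stop) = 0."""
    if table.p_stop == 0:
        warnings.warn("P(Stop) is zero; NPV undefined", stacklevel=2)
        return None
    return table.p_correct_stop / table.p_stop


def power_curve(
    sigma_delta: float, tv: float, delta_grid: np.ndarray
) -> np.ndarray:
    """P(Go) over a grid of true effects (monotone decreasing in delta)."""
    delta_grid = np.asarray(delta_grid, dtype=float)
    if not (delta_grid.min() <= tv <= delta_grid.max()):
        raise ValueError("delta grid must cover the target value")
    return p_go(delta_grid, sigma_delta, tv)


def power_threshold(sigma_delta: float, tv: float, target_power: float) -> float:
    """True effect at which P(Go) reaches ``target_power``:
    delta = tv - sigma * Phi^{-1}(target_power)."""
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    if sigma_delta <= 0:
        raise ValueError("sigma_delta must be > 0")
    return tv - sigma_delta * float(stats.norm.ppf(target_power))


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    auc_closed_form: float


def roc_and_auc(
    drug: MethodSummary,
    placebo: MethodSummary,
    n_draws: int = 2000,
    seed: int = 0,
    n_bootstrap: int = 2000,
) -> RocResult:
    """ROC curve for discriminating the drug arm from placebo when each
    arm's endpoint is Normal(mean, SE). Empirical AUC from paired draws with
    a bootstrap 95% CI; closed form Phi(|mean difference| / sqrt(SE_d^2 +
    SE_p^2)) reported alongside.

    The positive class is the drug arm; because benefit lowers scores, drug
    draws below a threshold count as true positives.
    """
    rng = np.random.default_rng(seed)
    xd = rng.normal(drug.mean, drug.se, size=n_draws)
    xp = rng.normal(placebo.mean, placebo.se, size=n_draws)
    thresholds = np.concatenate([[-np.inf], np.sort(np.concatenate([xd, xp])), [np.inf]])
    tpr = np.array([(xd <= t).mean() for t in thresholds])
    fpr = np.array([(xp <= t).mean() for t in thresholds])
    auc = _auc_mw(xd, xp)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        bd = xd[rng.integers(0, n_draws, n_draws)]
        bp = xp[rng.integers(0, n_draws, n_draws)]
        boot[b] = _auc_mw(bd, bp)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    closed = float(
        stats.norm.cdf(
            abs(drug.mean - placebo.mean) / math.sqrt(drug.se**2 + placebo.se**2)
        )
    )
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, auc_ci=(float(lo), float(hi)), auc_closed_form=closed)


def _auc_mw(pos_low: np.ndarray, neg: np.ndarray) -> float:
    """AUC via the Mann-Whitney statistic; positives score *lower*."""
    n1, n2 = len(pos_low), len(neg)
    ranks = stats.rankdata(np.concatenate([-pos_low, -neg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))
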