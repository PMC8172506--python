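"""Graded-response item model, latent disease trajectories and the Markov
dependence layer, plus forward simulation of item-level diaries.

The latent disease severity ``psi`` drives every item through a logistic
graded-response model: ``P(y >= k) = expit(a * (psi - b_k))`` with ordered
difficulties ``b_1 < ... < b_K``. Severity follows one of five per-subject
time courses (linear, power, asymptotic, weibull, step); day-to-day
correlation of responses is induced by a first-order Markov layer whose
stationary distribution at any day equals the marginal graded-response
probabilities at that day's ``psi``, with a single equilibration time scale
MET (mean equilibrium time) that may drift linearly over the study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .scales import ARMS, ITEM_MAX_SCORE, MAX_RAW_SUM, DiaryDataset, DiaryRecord, ScoreMap

__all__ = [
    "ItemParameters",
    "OccasionDistribution",
    "TrajectoryParameters",
    "MarkovParameters",
    "SubjectEffects",
    "TRAJECTORY_MODELS",
    "prob_at_or_above",
    "category_probabilities",
    "trajectory_value",
    "transition_matrix",
    "simulate_subject_diary",
    "simulate_trial",
    "draw_subject_effects",
    "expected_item_score",
    "default_score_map",
    "spawn_rng",
]

LN2 = math.log(2.0)

#: Parameters with multiplicative (exponential / lognormal) inter-individual
#: variability; all others use additive normal variability.
LOGNORMAL_PARAMS = frozenset({"t_prog", "t_r"})

TRAJECTORY_MODELS = ("linear", "power", "asymptotic", "weibull", "step")

_MODEL_PARAMS = {
    "linear": ("slope",),
    "power": ("slope", "gamma"),
    "asymptotic": ("rmax", "t_prog"),
    "weibull": ("rmax", "t_prog", "gamma"),
    "step": ("rmax", "t_r"),
}


def spawn_rng(seed: int | np.random.Generator, *keys: int) -> np.random.Generator:
    """Derive an independent generator from a root seed and integer keys.

    A counter-based fan-out: the same (seed, keys) always yields the same
    stream, and distinct key tuples yield independent streams.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=keys))


@dataclass(frozen=True)
class ItemParameters:
    """Discrimination ``a`` and ordered difficulties ``b`` for one item."""

    item_id: int
    a: float
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"item {self.item_id}: discrimination must be > 0")
        b = np.asarray(self.b, dtype=float)
        if np.any(np.diff(b) <= 0):
            raise ValueError(f"item {self.item_id}: difficulties must be strictly increasing")
        expected = ITEM_MAX_SCORE.get(self.item_id)
        if expected is not None and len(b) != expected:
            raise ValueError(
                f"item {self.item_id}: needs {expected} difficulties, got {len(b)}"
            )

    @property
    def max_score(self) -> int:
        return len(self.b)


@dataclass(frozen=True)
class OccasionDistribution:
    """Latent-variable distribution at non-baseline occasions.

    Baseline occasions are anchored at N(0, 1) for identifiability; later
    occasions share an estimated N(mu, omega2).
    """

    mu: float = 0.0
    omega2: float = 1.0

    def __post_init__(self) -> None:
        if self.omega2 <= 0:
            raise ValueError("omega2 must be > 0")


@dataclass(frozen=True)
class TrajectoryParameters:
    """Per-arm fixed effects and IIV variances for the latent time course.

    ``fixed`` maps arm -> {parameter -> value} using the parameter names of
    the chosen model (see ``_MODEL_PARAMS``); ``iiv`` maps parameter ->
    variance (omit or zero to disable that random effect). ``psi0`` has mean
    fixed at 0 with additive variability (default variance 1, the baseline
    anchoring); ``t_prog``/``t_r`` variability is exponential (lognormal).
    """

    model: str
    fixed: Mapping[str, Mapping[str, float]]
    iiv: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in TRAJECTORY_MODELS:
            raise ValueError(f"unknown trajectory model {self.model!r}")
        for arm, params in self.fixed.items():
            for name in _MODEL_PARAMS[self.model]:
                if name not in params:
                    raise ValueError(
                        f"trajectory model {self.model!r} requires parameter "
                        f"{name!r} for arm {arm!r}"
                    )
            if params.get("t_prog", 1.0) <= 0 or params.get("t_r", 1.0) < 0:
                raise ValueError(f"arm {arm!r}: time parameters must be positive")
            if params.get("gamma", 1.0) <= 0:
                raise ValueError(f"arm {arm!r}: gamma must be > 0")
        for name, var in self.iiv.items():
            if var < 0:
                raise ValueError(f"IIV variance for {name!r} must be >= 0")

    def iiv_variance(self, name: str) -> float:
        if name == "psi0":
            return float(self.iiv.get("psi0", 1.0))
        return float(self.iiv.get(name, 0.0))


@dataclass(frozen=True)
class MarkovParameters:
    """Mean equilibrium time MET(t) = met0 + met_slope * t, with optional
    lognormal IIV (variance ``omega_met2``)."""

    met0: float
    met_slope: float = 0.0
    omega_met2: float = 0.0

    def __post_init__(self) -> None:
        if self.met0 <= 0:
            raise ValueError("met0 must be > 0")
        if self.omega_met2 < 0:
            raise ValueError("omega_met2 must be >= 0")

    def met_at(self, t: float | np.ndarray) -> np.ndarray:
        met = self.met0 + self.met_slope * np.asarray(t, dtype=float)
        if np.any(met <= 0):
            raise ValueError("MET(t) must stay > 0 over the requested horizon")
        return met


@dataclass(frozen=True)
class SubjectEffects:
    """Realized subject-level parameter values (fixed effect + random effect
    already combined) plus the subject's MET multiplier ``exp(eta_met)``."""

    psi0: float
    params: Mapping[str, float]
    eta_met: float = 0.0

    def require(self, name: str):
        if name == "psi0":
            return self.psi0
        if name not in self.params:
            raise ValueError(f"subject effects missing required parameter {name!r}")
        return self.params[name]


def prob_at_or_above(item: ItemParameters, psi, k: int):
    """P(response >= k) under the logistic graded-response curve.

    ``k = 0`` returns 1 by convention; valid category indices are
    ``0 <= k <= max_score``.
    """
    if not 0 <= k <= item.max_score:
        raise ValueError(f"category index {k} out of range 0..{item.max_score}")
    psi = np.asarray(psi, dtype=float)
    if k == 0:
        return np.ones_like(psi) if psi.ndim else 1.0
    p = expit(item.a * (psi - item.b[k - 1]))
    return p if psi.ndim else float(p)


def category_probabilities(item: ItemParameters, psi) -> np.ndarray:
    """Probability vector over categories 0..max_score; last axis sums to 1."""
    psi = np.asarray(psi, dtype=float)
    ge = expit(item.a * (psi[..., None] - np.asarray(item.b)))  # (..., K)
    ones = np.ones(psi.shape + (1,))
    zeros = np.zeros(psi.shape + (1,))
    ge_full = np.concatenate([ones, ge, zeros], axis=-1)  # (..., K+2)
    return ge_full[..., :-1] - ge_full[..., 1:]


def expected_item_score(item: ItemParameters, psi) -> np.ndarray:
    """E[y | psi] = sum_k P(y >= k); monotone increasing in psi."""
    psi = np.asarray(psi, dtype=float)
    ge = expit(item.a * (psi[..., None] - np.asarray(item.b)))
    return ge.sum(axis=-1)


def trajectory_value(
    params: TrajectoryParameters,
    effects: SubjectEffects,
    t,
    arm: str | None = None,
) -> np.ndarray:
    """Latent severity psi at day(s) ``t`` for one subject.

    ``effects`` carries the realized subject-level parameters; the arm enters
    only through how effects were drawn, so it is accepted but unused here.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    psi0 = effects.psi0
    m = params.model
    if m == "linear":
        return psi0 + effects.require("slope") * t
    if m == "power":
        return psi0 + effects.require("slope") * t ** effects.require("gamma")
    if m == "asymptotic":
        t_prog = effects.require("t_prog")
        rmax = effects.require("rmax")
        return psi0 + (rmax - psi0) * (1.0 - np.exp(-LN2 / t_prog * t))
    if m == "weibull":
        t_prog = effects.require("t_prog")
        rmax = effects.require("rmax")
        gamma = effects.require("gamma")
        return psi0 + rmax * (1.0 - np.exp(-((LN2 / t_prog * t) ** gamma)))
    # step
    t_r = effects.require("t_r")
    rmax = effects.require("rmax")
    return np.where(t > t_r, psi0 + rmax, psi0)


def transition_matrix(item: ItemParameters, psi: float, dt: float, met: float) -> np.ndarray:
    """One-step transition matrix over item categories.

    Shrinkage of the identity toward the stationary graded-response
    distribution: ``P(dt) = lam * I + (1 - lam) * 1 pi^T`` with
    ``lam = exp(-dt / met)``, so the stationary law is the marginal
    category distribution at ``psi``, MET is the mean of the exponential
    equilibration time (half-time ``met * ln2``), and Chapman-Kolmogorov
    holds exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if met <= 0:
        raise ValueError("MET must be > 0")
    pi = category_probabilities(item, float(psi))
    lam = math.exp(-dt / met)
    n = pi.shape[-1]
    return lam * np.eye(n) + (1.0 - lam) * np.tile(pi, (n, 1))


def draw_subject_effects(
    traj: TrajectoryParameters,
    markov: MarkovParameters | None,
    arm: str,
    rng: np.random.Generator,
) -> SubjectEffects:
    """Draw one subject's realized parameters from the IIV distributions."""
    fixed = traj.fixed[arm]
    psi0 = rng.normal(0.0, math.sqrt(traj.iiv_variance("psi0")))
    params: dict[str, float] = {}
    for name in _MODEL_PARAMS[traj.model]:
        mu = float(fixed[name])
        var = traj.iiv_variance(name)
        if name in LOGNORMAL_PARAMS:
            eta = rng.normal(0.0, math.sqrt(var)) if var > 0 else 0.0
            params[name] = mu * math.exp(eta)
        else:
            params[name] = mu + (rng.normal(0.0, math.sqrt(var)) if var > 0 else 0.0)
    eta_met = 0.0
    if markov is not None and markov.omega_met2 > 0:
        eta_met = rng.normal(0.0, math.sqrt(markov.omega_met2))
    return SubjectEffects(psi0=psi0, params=params, eta_met=eta_met)


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw along the last axis."""
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(probs.shape[:-1] + (1,))
    return (u > cum[..., :-1]).sum(axis=-1)


def simulate_subject_diary(
    items: Sequence[ItemParameters],
    traj: TrajectoryParameters,
    markov: MarkovParameters | None,
    effects: SubjectEffects,
    days: Sequence[int],
    missing_days: set[int] | frozenset[int] = frozenset(),
    rng: np.random.Generator | int = 0,
    subject_id: str = "s1",
    arm: str = "drug",
) -> list[DiaryRecord]:
    """Simulate one subject's diary over ``days``.

    Present days carry all 14 items; days in ``missing_days`` are emitted as
    whole-day missing records. The first present day is drawn from the
    marginal graded-response distribution at psi(t); subsequent present days
    are drawn through the Markov transition kernel with ``dt`` the gap since
    the last present day. With ``markov=None`` days are independent.
    """
    rng = spawn_rng(rng) if isinstance(rng, int) else rng
    days = sorted(int(d) for d in days)
    present = [d for d in days if d not in missing_days]
    records: list[DiaryRecord] = [
        DiaryRecord(subject_id, arm, d, None) for d in days if d in missing_days
    ]
    if not present:
        return sorted(records, key=lambda r: r.day)

    t = np.asarray(present, dtype=float)
    psi = np.atleast_1d(trajectory_value(traj, effects, t, arm))
    n_days, n_items = len(present), len(items)

    pi = np.zeros((n_days, n_items, 5))
    for j, it in enumerate(items):
        pi[:, j, : it.max_score + 1] = category_probabilities(it, psi)
    fresh = _draw_categorical(rng, pi)  # (n_days, n_items)

    if markov is None or n_days == 1:
        draws = fresh
    else:
        met = np.asarray(markov.met_at(t[1:]), dtype=float) * math.exp(effects.eta_met)
        lam = np.exp(-np.diff(t) / met)
        stay = rng.random((n_days - 1, n_items)) < lam[:, None]
        draws = fresh.copy()
        for d in range(1, n_days):
            draws[d] = np.where(stay[d - 1], draws[d - 1], fresh[d])

    for idx, day in enumerate(present):
        responses = {it.item_id: int(draws[idx, j]) for j, it in enumerate(items)}
        records.append(DiaryRecord(subject_id, arm, day, responses))
    return sorted(records, key=lambda r: r.day)


def simulate_trial(
    n_subjects: Mapping[str, int],
    items: Sequence[ItemParameters],
    traj: TrajectoryParameters,
    markov: MarkovParameters | None,
    horizon_days: int,
    seed: int,
    missing_days: Mapping[str, set[int]] | None = None,
    last_day: Mapping[str, int] | None = None,
) -> tuple[DiaryDataset, dict[str, SubjectEffects]]:
    """Simulate a two-arm trial; returns the dataset and per-subject effects.

    ``missing_days`` / ``last_day`` are optional per-subject-id overrides
    (ids are ``"d001".."dNNN"`` and ``"p001".."pNNN"``) used by the synthetic
    data generator to impose missingness and drop-out.
    """
    for arm in n_subjects:
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}")
    records: list[DiaryRecord] = []
    all_effects: dict[str, SubjectEffects] = {}
    missing_days = missing_days or {}
    last_day = last_day or {}
    for arm_idx, arm in enumerate(ARMS):
        n = int(n_subjects.get(arm, 0))
        for i in range(n):
            subject_id = f"{arm[0]}{i + 1:03d}"
            rng = spawn_rng(seed, arm_idx, i)
            effects = draw_subject_effects(traj, markov, arm, rng)
            all_effects[subject_id] = effects
            stop = last_day.get(subject_id, horizon_days)
            days = range(0, stop + 1)
            records.extend(
                simulate_subject_diary(
                    items,
                    traj,
                    markov,
                    effects,
                    days,
                    missing_days=missing_days.get(subject_id, frozenset()),
                    rng=rng,
                    subject_id=subject_id,
                    arm=arm,
                )
            )
    return DiaryDataset(records=records), all_effects


def simulate_scores_window(
    n_subj: int,
    items: Sequence[ItemParameters],
    traj: TrajectoryParameters,
    markov: MarkovParameters | None,
    arm: str,
    window_days: Sequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized simulation of raw item responses over a short day window.

    Returns an array (n_subj, n_days, n_items). Because the Markov layer is
    stationary at each day's marginal distribution, starting the chain from
    the marginal at the first window day is exact — earlier days need not be
    simulated. Used by the trial-simulation stage where only end-of-study
    scores matter.
    """
    window_days = np.asarray(sorted(window_days), dtype=float)
    n_days = len(window_days)
    n_items = len(items)
    if n_subj == 0:
        return np.zeros((0, n_days, n_items), dtype=int)

    fixed = traj.fixed[arm]
    # draw subject-level parameters (vectorized mirror of draw_subject_effects)
    psi0 = rng.normal(0.0, math.sqrt(traj.iiv_variance("psi0")), size=n_subj)
    params: dict[str, np.ndarray] = {}
    for name in _MODEL_PARAMS[traj.model]:
        mu = float(fixed[name])
        var = traj.iiv_variance(name)
        eta = rng.normal(0.0, math.sqrt(var), size=n_subj) if var > 0 else np.zeros(n_subj)
        params[name] = mu * np.exp(eta) if name in LOGNORMAL_PARAMS else mu + eta
    eta_met = (
        rng.normal(0.0, math.sqrt(markov.omega_met2), size=n_subj)
        if markov is not None and markov.omega_met2 > 0
        else np.zeros(n_subj)
    )

    m = traj.model
    t = window_days[None, :]
    if m == "linear":
        psi = psi0[:, None] + params["slope"][:, None] * t
    elif m == "power":
        psi = psi0[:, None] + params["slope"][:, None] * t ** params["gamma"][:, None]
    elif m == "asymptotic":
        decay = 1.0 - np.exp(-LN2 / params["t_prog"][:, None] * t)
        psi = psi0[:, None] + (params["rmax"][:, None] - psi0[:, None]) * decay
    elif m == "weibull":
        decay = 1.0 - np.exp(-((LN2 / params["t_prog"][:, None] * t) ** params["gamma"][:, None]))
        psi = psi0[:, None] + params["rmax"][:, None] * decay
    else:
        psi = psi0[:, None] + np.where(t > params["t_r"][:, None], params["rmax"][:, None], 0.0)

    out = np.zeros((n_subj, n_days, n_items), dtype=np.int64)
    prev = None
    for d in range(n_days):
        # (n_subj, n_items, 5) padded category probabilities at this day
        pi = np.zeros((n_subj, n_items, 5))
        for j, it in enumerate(items):
            pi[:, j, : it.max_score + 1] = category_probabilities(it, psi[:, d])
        fresh = _draw_categorical(rng, pi)
        if prev is None or markov is None:
            out[:, d, :] = fresh
        else:
            dt = window_days[d] - window_days[d - 1]
            met = markov.met_at(window_days[d]) * np.exp(eta_met)
            lam = np.exp(-dt / met)[:, None]
            stay = rng.random((n_subj, n_items)) < lam
            out[:, d, :] = np.where(stay, prev, fresh)
        prev = out[:, d, :]
    return out


def _raw_sum_distribution(items: Sequence[ItemParameters], psi: float) -> np.ndarray:
    """Exact pmf of the 14-item raw sum at a fixed psi, by convolution."""
    pmf = np.array([1.0])
    for it in items:
        pmf = np.convolve(pmf, category_probabilities(it, float(psi)))
    return pmf


def default_score_map(items: Sequence[ItemParameters], n_quad: int = 201) -> ScoreMap:
    """Score-to-measure table from item parameters.

    For each raw 14-item sum, the expected-a-posteriori latent value under a
    standard-normal population is computed exactly (sum pmf by convolution
    over items on a quadrature grid), then linearly rescaled so the minimum
    sum maps to 0 and the maximum to 100. Monotone because the raw sum
    carries a monotone likelihood ratio in psi.
    """
    grid = np.linspace(-6.0, 6.0, n_quad)
    w = np.exp(-0.5 * grid**2)
    w /= w.sum()
    pmf = np.stack([_raw_sum_distribution(items, g) for g in grid])  # (Q, 52)
    marginal = w @ pmf
    eap = (w[:, None] * pmf * grid[:, None]).sum(axis=0) / marginal
    lo, hi = eap[0], eap[-1]
    values = (eap - lo) / (hi - lo) * 100.0
    values = np.maximum.accumulate(values)  # guard tiny numerical wiggles
    return ScoreMap(tuple(float(v) for v in values))
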