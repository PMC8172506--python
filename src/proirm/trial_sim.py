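"""Propagation of parameter uncertainty into the end-of-trial endpoint.

Replicates the simulation scheme used to attach a confidence interval to
the arm difference in mean score: each replicate draws a parameter vector
from the estimation-uncertainty distribution (normal for fixed effects,
scaled inverse-chi-square — the scalar inverse-Wishart — for variances),
simulates a large virtual trial over the evaluation window, and records the
drug-minus-placebo difference in mean score per scale. The SD of those
replicate differences is the sigma_delta consumed by the decision layer.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import irt_core
from .irt_core import (
    ItemParameters,
    MarkovParameters,
    TrajectoryParameters,
    default_score_map,
    spawn_rng,
)
from .scales import ARMS, ERS_ITEMS, MAX_RAW_SUM, SUBSCALE_ITEMS, ScoreMap

__all__ = [
    "UncertaintySpec",
    "EndpointDistribution",
    "df_from_se",
    "sample_parameters",
    "simulate_endpoint_distribution",
    "SCALES",
]

SCALES = ("exact_total", "rs_total", "breathlessness", "cough_sputum", "chest_symptoms")

_DF_CAP = 1e6


def df_from_se(variance: float, se: float) -> float:
    """Inverse-Wishart degrees of freedom matching a variance estimate and
    its SE: df = 2 * (variance / se)^2 + 1."""
    if variance <= 0 or se < 0:
        raise ValueError("variance must be > 0 and se >= 0")
    if se == 0:
        warnings.warn("zero SE: capping degrees of freedom", stacklevel=2)
        return _DF_CAP
    df = 2.0 * (variance / se) ** 2 + 1.0
    if df > _DF_CAP:
        warnings.warn("very small SE: capping degrees of freedom", stacklevel=2)
        return _DF_CAP
    return df


@dataclass(frozen=True)
class UncertaintySpec:
    """Uncertainty distribution around a fitted model.

    ``fixed_names`` address fixed effects with dotted paths:
    ``traj.<arm>.<param>`` (e.g. ``traj.drug.rmax``), ``markov.met0``,
    ``markov.met_slope``. ``variances`` maps IIV paths (``iiv.psi0``,
    ``iiv.rmax``, ``iiv.t_r``, ``markov.omega_met2``) to (estimate, df).
    """

    base_traj: TrajectoryParameters
    base_markov: MarkovParameters | None
    fixed_names: tuple[str, ...]
    fixed_estimates: np.ndarray
    fixed_cov: np.ndarray
    variances: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.fixed_names)
        est = np.asarray(self.fixed_estimates, dtype=float)
        cov = np.asarray(self.fixed_cov, dtype=float)
        if est.shape != (n,) or cov.shape != (n, n):
            raise ValueError("estimates/covariance shape mismatch with fixed_names")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if n:
            eig = np.linalg.eigvalsh(0.5 * (cov + cov.T))
            if eig.min() < -1e-8 * max(eig.max(), 1.0):
                raise ValueError("covariance must be positive semi-definite")
        for name, (v, df) in self.variances.items():
            if v < 0 or df <= 0:
                raise ValueError(f"variance entry {name!r}: need estimate >= 0, df > 0")
        object.__setattr__(self, "fixed_estimates", est)
        object.__setattr__(self, "fixed_cov", 0.5 * (cov + cov.T))

    @classmethod
    def point(
        cls,
        traj: TrajectoryParameters,
        markov: MarkovParameters | None,
    ) -> "UncertaintySpec":
        """Degenerate spec with no parameter uncertainty."""
        return cls(
            base_traj=traj,
            base_markov=markov,
            fixed_names=(),
            fixed_estimates=np.zeros(0),
            fixed_cov=np.zeros((0, 0)),
            variances={},
        )


_POSITIVE_FIXED = {"t_r", "t_prog", "gamma", "met0"}


def _apply(spec: UncertaintySpec, fixed: np.ndarray, variances: Mapping[str, float]):
    """Materialize trajectory/Markov objects from sampled parameter values."""
    traj_fixed = {arm: dict(spec.base_traj.fixed[arm]) for arm in spec.base_traj.fixed}
    iiv = dict(spec.base_traj.iiv)
    markov_kwargs = (
        dataclasses.asdict(spec.base_markov) if spec.base_markov is not None else None
    )
    for name, value in zip(spec.fixed_names, fixed):
        parts = name.split(".")
        if parts[0] == "traj":
            traj_fixed[parts[1]][parts[2]] = float(value)
        elif parts[0] == "markov":
            markov_kwargs[parts[1]] = float(value)
        else:
            raise ValueError(f"unknown fixed-effect path {name!r}")
    for name, value in variances.items():
        parts = name.split(".")
        if parts[0] == "iiv":
            iiv[parts[1]] = float(value)
        elif name == "markov.omega_met2":
            markov_kwargs["omega_met2"] = float(value)
        else:
            raise ValueError(f"unknown variance path {name!r}")
    traj = TrajectoryParameters(model=spec.base_traj.model, fixed=traj_fixed, iiv=iiv)
    markov = MarkovParameters(**markov_kwargs) if markov_kwargs is not None else None
    return traj, markov


def _valid_fixed(spec: UncertaintySpec, draw: np.ndarray) -> bool:
    for name, value in zip(spec.fixed_names, draw):
        leaf = name.split(".")[-1]
        if leaf in _POSITIVE_FIXED and value <= 0:
            return False
    return True


def sample_parameters(
    spec: UncertaintySpec, seed: int | np.random.Generator
) -> tuple[TrajectoryParameters, MarkovParameters | None]:
    """One draw from the uncertainty distribution.

    Fixed effects ~ multivariate normal; each variance ~ scaled
    inverse-chi-square matching (estimate, df). Draws violating domain
    constraints (non-positive times, MET going non-positive) are resampled.
    """
    rng = spawn_rng(seed) if isinstance(seed, int) else seed
    for _ in range(1000):
        if len(spec.fixed_names):
            draw = rng.multivariate_normal(
                spec.fixed_estimates, spec.fixed_cov, method="svd"
            )
        else:
            draw = np.zeros(0)
        if not _valid_fixed(spec, draw):
            continue
        variances = {}
        for name, (est, df) in spec.variances.items():
            if df >= _DF_CAP:
                variances[name] = est
            else:
                # scaled inverse chi-square: est * df / chi2(df)
                variances[name] = est * df / float(rng.chisquare(df))
        try:
            return _apply(spec, draw, variances)
        except ValueError:
            continue
    raise RuntimeError("could not draw valid parameters in 1000 attempts")


@dataclass(frozen=True)
class EndpointDistribution:
    """Replicate arm differences (drug - placebo) in mean score per scale."""

    differences: pd.DataFrame  # columns: replicate, scale, difference
    n_rep: int
    n_subj: int
    evaluation_days: tuple[int, ...]

    def per_scale(self, scale: str) -> np.ndarray:
        sel = self.differences[self.differences["scale"] == scale]
        return sel.sort_values("replicate")["difference"].to_numpy()

    def summary(self) -> pd.DataFrame:
        rows = []
        for scale in self.differences["scale"].unique():
            d = self.per_scale(scale)
            lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5])
            rows.append(
                {
                    "scale": scale,
                    "mean": float(d.mean()),
                    "median": float(med),
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                    "ci_width": float(hi - lo),
                    "sd_delta": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
                }
            )
        return pd.DataFrame(rows)

    def sd_delta(self, scale: str) -> float:
        return float(self.per_scale(scale).std(ddof=1))

    def ci(self, scale: str) -> tuple[float, float]:
        lo, hi = np.percentile(self.per_scale(scale), [2.5, 97.5])
        return float(lo), float(hi)


def _mean_scores(
    raw: np.ndarray, items: Sequence[ItemParameters], score_map: ScoreMap
) -> dict[str, float]:
    """Mean of subject-mean scores for each scale from raw responses
    (n_subj, n_days, n_items ordered by item_id)."""
    item_ids = [it.item_id for it in sorted(items, key=lambda x: x.item_id)]
    idx = {iid: j for j, iid in enumerate(item_ids)}
    out: dict[str, float] = {}
    ers_cols = [idx[i] for i in ERS_ITEMS]
    out["rs_total"] = float(raw[:, :, ers_cols].sum(axis=2).mean())
    raw_sum = raw.sum(axis=2)
    measures = np.asarray([score_map(s) for s in range(MAX_RAW_SUM + 1)])
    out["exact_total"] = float(measures[raw_sum].mean())
    for name, members in SUBSCALE_ITEMS.items():
        cols = [idx[i] for i in members]
        out[name] = float(raw[:, :, cols].sum(axis=2).mean())
    return out


def simulate_endpoint_distribution(
    spec: UncertaintySpec,
    items: Sequence[ItemParameters],
    n_subj: int = 5000,
    n_rep: int = 2000,
    evaluation_days: Sequence[int] = tuple(range(351, 366)),
    scales: Sequence[str] = SCALES,
    score_map: ScoreMap | None = None,
    seed: int = 0,
) -> EndpointDistribution:
    """Distribution of end-of-trial arm differences under parameter
    uncertainty.

    Each replicate draws one parameter vector, simulates ``n_subj`` subjects
    per arm over the evaluation window (the Markov chain is stationary at
    each day's marginal, so earlier days need not be simulated), and records
    the drug-minus-placebo difference in the mean of subject-mean scores.
    """
    if score_map is None:
        score_map = default_score_map(items)
    items = sorted(items, key=lambda it: it.item_id)
    rows = []
    for rep in range(n_rep):
        rng = spawn_rng(seed, 31, rep)
        traj, markov = sample_parameters(spec, rng)
        means: dict[str, dict[str, float]] = {}
        for arm in ARMS:
            raw = irt_core.simulate_scores_window(
                n_subj, items, traj, markov, arm, evaluation_days, rng
            )
            means[arm] = _mean_scores(raw, items, score_map)
        for scale in scales:
            rows.append(
                {
                    "replicate": rep,
                    "scale": scale,
                    "difference": means["drug"][scale] - means["placebo"][scale],
                }
            )
    return EndpointDistribution(
        differences=pd.DataFrame(rows),
        n_rep=n_rep,
        n_subj=n_subj,
        evaluation_days=tuple(int(d) for d in evaluation_days),
    )
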