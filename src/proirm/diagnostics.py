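"""Simulation-based model checks.

Visual predictive checks compare observed statistics (score percentiles,
item-category proportions, day-to-day transition proportions) with 95%
bands obtained by re-simulating the fitted model under exactly the observed
design — same subjects, same present/missing days — many times. A
non-parametric smooth of observed item score against the latent estimate
provides an item-level goodness-of-fit curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import irt_core
from .irt_core import (
    ItemParameters,
    MarkovParameters,
    TrajectoryParameters,
    category_probabilities,
    draw_subject_effects,
    expected_item_score,
    simulate_subject_diary,
    spawn_rng,
)
from .scales import ITEM_MAX_SCORE, DiaryDataset, ScoreMap, score_dataset

__all__ = [
    "VpcResult",
    "vpc_total_score",
    "vpc_items",
    "vpc_transitions",
    "icf_smooth_check",
    "simulate_like",
]


@dataclass(frozen=True)
class VpcResult:
    """Tidy VPC summary: one row per (stratum, bin, statistic)."""

    table: pd.DataFrame  # columns: stratum, bin, t_mid, statistic, observed, band_lo, band_hi
    n_sim: int
    kind: str

    def __post_init__(self) -> None:
        if self.n_sim < 2:
            raise ValueError("VPC bands need at least 2 simulation replicates")
        bad = self.table["band_lo"] > self.table["band_hi"]
        if bad.any():
            raise AssertionError("VPC bands inverted")

    def coverage(self) -> float:
        """Fraction of observed statistics inside their 95% band."""
        t = self.table
        inside = (t["observed"] >= t["band_lo"]) & (t["observed"] <= t["band_hi"])
        return float(inside.mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, path=None):
        """Percentile-vs-time panels per stratum (matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        strata = self.table["stratum"].unique()
        fig, axes = plt.subplots(1, len(strata), figsize=(5 * len(strata), 4), squeeze=False)
        for ax, stratum in zip(axes[0], strata):
            sub = self.table[self.table["stratum"] == stratum]
            for stat in sub["statistic"].unique():
                s = sub[sub["statistic"] == stat].sort_values("t_mid")
                ax.fill_between(s["t_mid"], s["band_lo"], s["band_hi"], alpha=0.3)
                ax.plot(s["t_mid"], s["observed"], lw=1.2, label=str(stat))
            ax.set_title(f"{self.kind} — {stratum}")
            ax.set_xlabel("day")
            ax.legend(fontsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def simulate_like(
    data: DiaryDataset,
    items: Sequence[ItemParameters],
    traj: TrajectoryParameters,
    markov: MarkovParameters | None,
    seed: int | np.random.Generator,
) -> DiaryDataset:
    """Simulate one replicate dataset under the observed design: same
    subjects, arms and present/missing day patterns, fresh random effects."""
    rng = spawn_rng(seed) if isinstance(seed, int) else seed
    records = []
    for sid in data.subjects:
        recs = data.subject_records(sid)
        arm = recs[0].arm
        days = [r.day for r in recs]
        missing = {r.day for r in recs if r.is_missing}
        effects = draw_subject_effects(traj, markov, arm, rng)
        records.extend(
            simulate_subject_diary(
                items, traj, markov, effects, days, missing_days=missing,
                rng=rng, subject_id=sid, arm=arm,
            )
        )
    return DiaryDataset(records=records)


def _day_bins(days: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bin edges over observed days."""
    qs = np.linspace(0, 100, n_bins + 1)
    edges = np.unique(np.percentile(days, qs))
    if len(edges) < 2:
        edges = np.array([days.min() - 0.5, days.max() + 0.5])
    edges[0] -= 0.5
    edges[-1] += 0.5
    return edges


def _percentile_stats(scored: pd.DataFrame, value_col: str, edges: np.ndarray) -> pd.DataFrame:
    scored = scored.copy()
    scored["bin"] = np.digitize(scored["day"], edges[1:-1])
    rows = []
    for (arm, b), grp in scored.groupby(["arm", "bin"]):
        for q, name in ((2.5, "p2.5"), (50.0, "p50"), (97.5, "p97.5")):
            rows.append(
                {
                    "stratum": arm,
                    "bin": int(b),
                    "t_mid": float(grp["day"].median()),
                    "statistic": name,
                    "value": float(np.percentile(grp[value_col], q)),
                }
            )
    return pd.DataFrame(rows)


def _assemble(observed: pd.DataFrame, simulated: list[pd.DataFrame], kind: str, n_sim: int) -> VpcResult:
    keys = ["stratum", "bin", "statistic"]
    sim_all = pd.concat(simulated, ignore_index=True)
    bands = (
        sim_all.groupby(keys)["value"]
        .agg(band_lo=lambda v: np.percentile(v, 2.5), band_hi=lambda v: np.percentile(v, 97.5))
        .reset_index()
    )
    merged = observed.rename(columns={"value": "observed"}).merge(bands, on=keys, how="left")
    return VpcResult(table=merged, n_sim=n_sim, kind=kind)


def vpc_total_score(
    data: DiaryDataset,
    items: Sequence[ItemParameters],
    traj: TrajectoryParameters,
    markov: MarkovParameters | None,
    n_sim: int = 500,
    scale: str = "exact_total",
    score_map: ScoreMap | None = None,
    n_bins: int = 14,
    seed: int = 0,
) -> VpcResult:
    """VPC of the 2.5th/50th/97.5th total-score percentiles over time,
    stratified by arm."""
    if score_map is None:
        score_map = irt_core.default_score_map(items) if scale == "exact_total" else ScoreMap.linear()
    obs_scored = score_dataset(data, score_map)
    if obs_scored.empty:
        raise ValueError("no present days to check")
    edges = _day_bins(obs_scored["day"].to_numpy(), n_bins)
    observed = _percentile_stats(obs_scored, scale, edges)
    sims = []
    for s in range(n_sim):
        rep = simulate_like(data, items, traj, markov, spawn_rng(seed, 11, s))
        sims.append(_percentile_stats(score_dataset(rep, score_map), scale, edges))
    return _assemble(observed, sims, f"vpc_total[{scale}]", n_sim)


def _category_stats(frame: pd.DataFrame, edges: np.ndarray, per_item: bool) -> pd.DataFrame:
    frame = frame.copy()
    frame["bin"] = np.digitize(frame["day"], edges[1:-1])
    rows = []
    group_cols = ["arm", "bin"] + (["item_id"] in [] and [] or (["item_id"] if per_item else []))
    for key, grp in frame.groupby(group_cols):
        arm, b = key[0], key[1]
        stratum = f"{arm}/item{key[2]}" if per_item else arm
        n = len(grp)
        k_max = int(grp["item_id"].map(ITEM_MAX_SCORE).max()) if not per_item else ITEM_MAX_SCORE[int(key[2])]
        for c in range(0, k_max + 1):
            rows.append(
                {
                    "stratum": stratum,
                    "bin": int(b),
                    "t_mid": float(grp["day"].median()),
                    "statistic": f"prop_cat{c}",
                    "value": float((grp["score"] == c).mean()),
                }
            )
    return pd.DataFrame(rows)


def vpc_items(
    data: DiaryDataset,
    items: Sequence[ItemParameters],
    traj: TrajectoryParameters,
    markov: MarkovParameters | None,
    n_sim: int = 500,
    per_item: bool = False,
    n_bins: int = 14,
    seed: int = 0,
) -> VpcResult:
    """VPC of item-category proportions over time (optionally per item)."""
    obs = data.to_frame()
    if obs.empty:
        raise ValueError("no present days to check")
    edges = _day_bins(obs["day"].to_numpy(), n_bins)
    observed = _category_stats(obs, edges, per_item)
    sims = []
    for s in range(n_sim):
        rep = simulate_like(data, items, traj, markov, spawn_rng(seed, 13, s))
        sims.append(_category_stats(rep.to_frame(), edges, per_item))
    return _assemble(observed, sims, "vpc_items" + ("_per_item" if per_item else ""), n_sim)


def _transition_stats(data: DiaryDataset, edges: np.ndarray) -> pd.DataFrame:
    item_ids = sorted(ITEM_MAX_SCORE)
    rows = []
    pairs = []
    for sid in data.subjects:
        recs = [r for r in data.subject_records(sid) if not r.is_missing]
        for prev, cur in zip(recs, recs[1:]):
            if cur.day - prev.day != 1:
                continue  # transitions are evaluated on consecutive days
            for i in item_ids:
                d = cur.responses[i] - prev.responses[i]
                pairs.append((cur.arm, cur.day, np.sign(d)))
    if not pairs:
        raise ValueError("no consecutive-day pairs for a transition check")
    df = pd.DataFrame(pairs, columns=["arm", "day", "direction"])
    df["bin"] = np.digitize(df["day"], edges[1:-1])
    for (arm, b), grp in df.groupby(["arm", "bin"]):
        for d, name in ((-1, "down"), (0, "same"), (1, "up")):
            rows.append(
                {
                    "stratum": arm,
                    "bin": int(b),
                    "t_mid": float(grp["day"].median()),
                    "statistic": f"prop_{name}",
                    "value": float((grp["direction"] == d).mean()),
                }
            )
    return pd.DataFrame(rows)


def vpc_transitions(
    data: DiaryDataset,
    items: Sequence[ItemParameters],
    traj: TrajectoryParameters,
    markov: MarkovParameters | None,
    n_sim: int = 500,
    n_bins: int = 6,
    seed: int = 0,
) -> VpcResult:
    """VPC of day-to-day score-change proportions (down / same / up pooled
    over items) — the check that exercises the Markov layer."""
    obs = data.to_frame()
    if obs.empty:
        raise ValueError("no present days to check")
    edges = _day_bins(obs["day"].to_numpy(), n_bins)
    observed = _transition_stats(data, edges)
    sims = []
    for s in range(n_sim):
        rep = simulate_like(data, items, traj, markov, spawn_rng(seed, 17, s))
        sims.append(_transition_stats(rep, edges))
    return _assemble(observed, sims, "vpc_transitions", n_sim)


def _eap_psi(data: DiaryDataset, items: Sequence[ItemParameters], n_quad: int = 61) -> pd.DataFrame:
    """Posterior-mean latent value per present occasion under a N(0,1) prior."""
    z, w = np.polynomial.hermite_e.hermegauss(n_quad)
    logw = np.log(w)
    item_ids = sorted(ITEM_MAX_SCORE)
    by_id = {it.item_id: it for it in items}
    logP = {i: np.log(np.clip(category_probabilities(by_id[i], z), 1e-300, None)) for i in item_ids}
    rows = []
    for rec in data.records:
        if rec.is_missing:
            continue
        lg = logw.copy()
        for i in item_ids:
            lg = lg + logP[i][:, rec.responses[i]]
        r = np.exp(lg - lg.max())
        r /= r.sum()
        psi_hat = float(np.dot(r, z))
        for i in item_ids:
            rows.append({"psi": psi_hat, "item_id": i, "score": rec.responses[i]})
    return pd.DataFrame(rows)


def _smooth_on_grid(x: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian-kernel smooth with Silverman's bandwidth."""
    sd = x.std(ddof=1)
    bw = 1.06 * (sd if sd > 0 else 1.0) * len(x) ** (-1 / 5)
    k = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bw) ** 2)
    return (k * y[None, :]).sum(axis=1) / np.clip(k.sum(axis=1), 1e-300, None)


def icf_smooth_check(
    items: Sequence[ItemParameters],
    data: DiaryDataset,
    n_grid: int = 60,
    n_sim: int = 10,
    seed: int = 0,
) -> dict[int, pd.DataFrame]:
    """Observed vs simulated non-parametric item-score smooths.

    Both curves plot the kernel-smoothed mean item score against the
    occasion-level posterior-mean latent value; the reference curve comes
    from data re-simulated under the item model (same number of occasions,
    latent values from the standard-normal pseudo-occasion prior), so both
    smooths carry the same posterior-shrinkage geometry. The model-implied
    expected score vs psi is included as a third column for reference.

    Returns, per item, a frame with columns psi, observed_smooth,
    simulated_smooth, expected. Requires at least 20 present occasions.
    """
    n_occ = sum(1 for r in data.records if not r.is_missing)
    if n_occ < 20:
        raise ValueError(f"need >= 20 occasions for a reliable smooth, got {n_occ}")
    eap = _eap_psi(data, items)
    rng = spawn_rng(seed, 19)
    item_ids = sorted(ITEM_MAX_SCORE)
    by_id = {it.item_id: it for it in items}
    # simulated pseudo-occasions under the fitted item curves
    sim_psi = rng.normal(size=n_occ * n_sim)
    sim_scores: dict[int, np.ndarray] = {}
    for i in item_ids:
        p = category_probabilities(by_id[i], sim_psi)
        u = rng.random(len(sim_psi))[:, None]
        sim_scores[i] = (u > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)
    sim_records = []
    from .scales import DiaryRecord

    for n, psi_val in enumerate(sim_psi):
        sim_records.append(
            DiaryRecord(f"sim{n:06d}", "drug", 0, {i: int(sim_scores[i][n]) for i in item_ids})
        )
    sim_eap = _eap_psi(DiaryDataset(records=sim_records), items)

    out: dict[int, pd.DataFrame] = {}
    for item_id, grp in eap.groupby("item_id"):
        x = grp["psi"].to_numpy()
        y = grp["score"].to_numpy(dtype=float)
        grid = np.linspace(np.percentile(x, 5), np.percentile(x, 95), n_grid)
        sgrp = sim_eap[sim_eap["item_id"] == item_id]
        out[int(item_id)] = pd.DataFrame(
            {
                "psi": grid,
                "observed_smooth": _smooth_on_grid(x, y, grid),
                "simulated_smooth": _smooth_on_grid(
                    sgrp["psi"].to_numpy(), sgrp["score"].to_numpy(dtype=float), grid
                ),
                "expected": expected_item_score(by_id[int(item_id)], grid),
            }
        )
    return out
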