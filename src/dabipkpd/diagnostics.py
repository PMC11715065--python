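"""Prediction-corrected visual predictive check (pcVPC).

Observations are corrected by the ratio of the bin's median population
prediction to the record's own population prediction, then 10/50/90th
percentiles per nominal-time bin are compared with the same percentiles
computed from cohorts re-simulated under the fitted model at the observed
design.  Percentiles use linear interpolation (type 7), stated because
percentile conventions differ between tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .dataio import StudyDataset
from .errors import InvalidInputError
from .model import PARAM_INDEX, typical_vector
from .population import PopulationModel

__all__ = ["VPCResult", "prediction_correct", "run_vpc", "plot_vpc"]

PCTS = (10.0, 50.0, 90.0)


@dataclass
class VPCResult:
    """Percentile bands per bin for one observation channel."""

    channel: int
    n_replicates: int
    table: pd.DataFrame
    # columns: bin_time, n_obs, obs_p10/p50/p90, sim_p10/p50/p90 (medians),
    #          and *_lo/*_hi 95% CI bounds for each simulated percentile

    def coverage(self, percentile: int = 50) -> float:
        """Fraction of bins whose observed percentile lies in the sim CI."""
        t = self.table
        lo = t[f"sim_p{percentile}_lo"]
        hi = t[f"sim_p{percentile}_hi"]
        obs = t[f"obs_p{percentile}"]
        return float(((obs >= lo) & (obs <= hi)).mean())


def prediction_correct(y, pred_ij, pred_bin):
    """Prediction-corrected observation: y * pred_bin / pred_ij."""
    y = np.asarray(y, dtype=float)
    pred_ij = np.asarray(pred_ij, dtype=float)
    if np.any(pred_ij <= 0):
        raise InvalidInputError("population prediction must be positive for "
                                "prediction correction")
    return y * np.asarray(pred_bin, dtype=float) / pred_ij


def _population_model_of(fit) -> PopulationModel:
    if isinstance(fit, PopulationModel):
        return fit
    return fit.to_population()


def _assign_bins(times: np.ndarray, min_per_bin: int = 3) -> np.ndarray:
    """Bin by nominal time, merging sparse bins into their left neighbour."""
    uniq = np.unique(times)
    counts = {t: int(np.sum(times == t)) for t in uniq}
    # keep nominal bins; a sparse bin opens a carry that absorbs successors
    # until the merged bin reaches min_per_bin
    mapping: dict[float, float] = {}
    carry = None
    carry_count = 0
    for t in uniq:
        if carry is None:
            mapping[t] = t
            if counts[t] < min_per_bin:
                carry = t
                carry_count = counts[t]
        else:
            mapping[t] = carry
            carry_count += counts[t]
            if carry_count >= min_per_bin:
                carry = None
    merged = [t for t in uniq if mapping[t] != t]
    if merged:
        warnings.warn(f"bins at nominal times {merged} had fewer than "
                      f"{min_per_bin} observations and were merged",
                      RuntimeWarning, stacklevel=3)
    return np.array([mapping[t] for t in times])


def run_vpc(dataset: StudyDataset, fit, n_replicates: int = 1000,
            seed: int = 0, channels=(1, 2)) -> dict[int, VPCResult]:
    """Prediction-corrected VPC per channel; deterministic given ``seed``.

    ``fit`` may be a FitResult or a PopulationModel.  Replicate cohorts are
    simulated at the observed design (same subjects, weights, dose events
    and sampling times), with fresh etas and residuals.
    """
    if n_replicates < 100:
        raise InvalidInputError("n_replicates must be >= 100 for stable bands")
    pop = _population_model_of(fit)
    values = pop.parameter_values()
    eta_names = sorted((k for k, v in pop.omega.items() if v > 0),
                       key=lambda k: PARAM_INDEX[k])
    eta_idx = np.array([PARAM_INDEX[k] for k in eta_names], dtype=np.int64)
    eta_sd = np.sqrt(np.array([pop.omega[k] for k in eta_names]))
    # subjects sorted by id and randomness streamed per (replicate, subject),
    # so the bands are invariant to row order in the dataset
    subjects = sorted(dataset.subject_records(channels=tuple(channels)),
                      key=lambda s: str(s.id))
    results: dict[int, VPCResult] = {}
    for ch_id in channels:
        rows = []
        for s in subjects:
            mask = s.channel == ch_id
            if not np.any(mask):
                continue
            # sort within subject so results do not depend on row order
            order = np.argsort(s.times[mask], kind="stable")
            t = s.times[mask][order]
            y = s.y[mask][order]
            p0 = typical_vector(values, s.weight)
            pred = _kernels.predict_obs(t, np.full(t.size, ch_id, np.int64),
                                        s.events, p0)
            rows.append((s, t, y, pred))
        if not rows:
            continue
        all_times = np.concatenate([t for _, t, _, _ in rows])
        all_y = np.concatenate([y for _, _, y, _ in rows])
        all_pred = np.concatenate([p for _, _, _, p in rows])
        bins = _assign_bins(all_times)
        bin_ids = np.unique(bins)
        pred_bin = np.empty_like(all_pred)
        for b in bin_ids:
            pred_bin[bins == b] = np.median(all_pred[bins == b])
        pc_obs = prediction_correct(all_y, all_pred, pred_bin)
        obs_pct = {b: np.percentile(pc_obs[bins == b], PCTS) for b in bin_ids}
        # simulate replicates
        sp = pop.sigma_prop_conc if ch_id == 1 else pop.sigma_prop_r
        sa = pop.sigma_add_conc if ch_id == 1 else pop.sigma_add_r
        sim_pct = np.empty((n_replicates, bin_ids.size, len(PCTS)))
        for r in range(n_replicates):
            sim_y = np.empty_like(all_y)
            pos = 0
            for si, (s, t, y, pred) in enumerate(rows):
                rng = np.random.default_rng((seed, ch_id, r, si))
                eta = rng.normal(0.0, 1.0, size=eta_idx.size) * eta_sd
                p = typical_vector(values, s.weight)
                for k in range(eta_idx.size):
                    p[eta_idx[k]] *= np.exp(eta[k])
                f = _kernels.predict_obs(t, np.full(t.size, ch_id, np.int64),
                                         s.events, p)
                yy = (f * (1.0 + rng.normal(0.0, 1.0, size=t.size) * sp)
                      + rng.normal(0.0, 1.0, size=t.size) * sa)
                sim_y[pos:pos + t.size] = np.maximum(yy, 0.0)
                pos += t.size
            pc_sim = prediction_correct(sim_y, all_pred, pred_bin)
            for bi, b in enumerate(bin_ids):
                sim_pct[r, bi] = np.percentile(pc_sim[bins == b], PCTS)
        table_rows = []
        for bi, b in enumerate(bin_ids):
            row = {"bin_time": b, "n_obs": int(np.sum(bins == b))}
            for pi, pct in enumerate((10, 50, 90)):
                row[f"obs_p{pct}"] = obs_pct[b][pi]
                row[f"sim_p{pct}"] = float(np.median(sim_pct[:, bi, pi]))
                row[f"sim_p{pct}_lo"] = float(np.percentile(sim_pct[:, bi, pi], 2.5))
                row[f"sim_p{pct}_hi"] = float(np.percentile(sim_pct[:, bi, pi], 97.5))
            table_rows.append(row)
        results[ch_id] = VPCResult(channel=ch_id, n_replicates=n_replicates,
                                   table=pd.DataFrame(table_rows))
    return results


def plot_vpc(result: VPCResult, ax=None):
    """Band plot of one channel's pcVPC (matplotlib axes returned)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    t = result.table["bin_time"]
    for pct, color in ((10, "tab:blue"), (50, "tab:red"), (90, "tab:blue")):
        ax.fill_between(t, result.table[f"sim_p{pct}_lo"],
                        result.table[f"sim_p{pct}_hi"], alpha=0.25,
                        color=color, lw=0)
        ax.plot(t, result.table[f"sim_p{pct}"], color=color, ls="--", lw=1)
        ax.plot(t, result.table[f"obs_p{pct}"], color="0.3", ls="-", lw=1.2)
    label = "concentration (mg/L)" if result.channel == 1 else "R-time (min)"
    ax.set_xlabel("time (min)")
    ax.set_ylabel(f"prediction-corrected {label}")
    ax.set_xscale("log")
    return ax
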