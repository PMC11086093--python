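"""Accuracy statistics and the contact-noise sensitivity experiment.

Agreement between predicted and measured (or ground-truth) channels is
summarized per channel by Pearson's correlation with the four-class
gait-analysis interpretation (weak <= 0.35 < moderate <= 0.67 < strong
<= 0.9 < excellent), the RMSE (optionally body-mass normalized), and the
relative RMSE — RMSE as a percentage of the mean of the two series'
peak-to-peak amplitudes, which makes channels of different magnitude
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DimensionError, ParameterError
from .estimator import FootWrenchSeries, condition_contacts, estimate

__all__ = [
    "AccuracyReport", "classify_rho", "compare", "compare_wrenches",
    "wrench_channels", "sensitivity", "CHANNELS",
]

#: paper-style channel order: forces then moments of one foot
CHANNELS = (
    "anterior_grf", "medial_grf", "vertical_grf",
    "frontal_grm", "transverse_grm", "sagittal_grm",
)


@dataclass
class AccuracyReport:
    """Per-channel agreement statistics."""

    table: pd.DataFrame  # index: channel; columns: rho, rho_class, rmse, rrmse

    def __getitem__(self, channel: str) -> pd.Series:
        return self.table.loc[channel]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def classify_rho(rho: float) -> str:
    """Four-class interpretation of Pearson's correlation coefficient:
    weak (rho <= 0.35), moderate (0.35 < rho <= 0.67), strong
    (0.67 < rho <= 0.9), excellent (rho > 0.9)."""
    if rho <= 0.35:
        return "weak"
    if rho <= 0.67:
        return "moderate"
    if rho <= 0.9:
        return "strong"
    return "excellent"


def _one_channel(pred: np.ndarray, meas: np.ndarray, scale: float):
    if pred.shape != meas.shape:
        raise DimensionError("predicted and measured series differ in length")
    if pred.size < 2:
        raise ParameterError("need at least two samples")
    if np.ptp(pred) == 0 or np.ptp(meas) == 0:
        raise ParameterError("correlation undefined for a constant series")
    rho = float(stats.pearsonr(pred, meas).statistic)
    rmse = float(np.sqrt(np.mean((pred - meas) ** 2)))
    ptp = 0.5 * (np.ptp(pred) + np.ptp(meas))
    rrmse = 100.0 * rmse / ptp
    return rho, classify_rho(rho), rmse / scale, rrmse


def compare(pred, meas, body_mass: float | None = None) -> AccuracyReport:
    """Channel-wise accuracy of ``pred`` against ``meas``.

    Inputs are mappings/DataFrames of equally long 1-D series (a single
    pair of arrays is treated as one channel).  When ``body_mass`` is
    given, RMSEs are normalized to it (N/kg or N m/kg); rho and rRMSE are
    scale-invariant and unaffected.
    """
    if isinstance(pred, np.ndarray) and pred.ndim == 1:
        pred, meas = {"series": pred}, {"series": np.asarray(meas)}
    pred = dict(pred)
    meas = dict(meas)
    if set(pred) != set(meas):
        raise DimensionError("prediction and measurement channels differ")
    scale = body_mass if body_mass else 1.0
    rows = {}
    for ch in pred:
        rho, cls, rmse, rrmse = _one_channel(
            np.asarray(pred[ch], float), np.asarray(meas[ch], float), scale
        )
        rows[ch] = {"rho": rho, "rho_class": cls, "rmse": rmse, "rrmse": rrmse}
    return AccuracyReport(pd.DataFrame(rows).T[["rho", "rho_class", "rmse", "rrmse"]])


def wrench_channels(w: FootWrenchSeries, foot: str = "right") -> dict[str, np.ndarray]:
    """The six per-foot channels in paper order: anterior/medial/vertical
    force, frontal/transverse/sagittal moment."""
    k = w.feet.index(foot)
    return {
        "anterior_grf": w.force[:, k, 0],
        "medial_grf": w.force[:, k, 2],
        "vertical_grf": w.force[:, k, 1],
        "frontal_grm": w.moment[:, k, 0],
        "transverse_grm": w.moment[:, k, 1],
        "sagittal_grm": w.moment[:, k, 2],
    }


def compare_wrenches(pred: FootWrenchSeries, truth: FootWrenchSeries,
                     body_mass: float | None = None,
                     foot: str = "right") -> AccuracyReport:
    return compare(wrench_channels(pred, foot), wrench_channels(truth, foot),
                   body_mass=body_mass)


def sensitivity(trial, amplitudes, seeds, foot: str = "right",
                cutoff: float = 6.0) -> pd.DataFrame:
    """Contact-point measurement-noise sensitivity table.

    For each amplitude (m) and seed, uniform white noise is added to every
    contact-point coordinate, the noisy positions pass through the standard
    measurement low-pass, the estimator reruns, and each channel's RMSE
    (body-mass normalized) and rRMSE against the trial's truth are
    averaged over seeds.  Rows are the six wrench channels; columns are a
    (amplitude, metric) MultiIndex.
    """
    from .syngait import add_noise

    amplitudes = list(amplitudes)
    if any(a < 0 for a in amplitudes):
        raise ParameterError("noise amplitudes must be non-negative")
    truth_ch = wrench_channels(trial.truth_wrenches, foot)
    mass = trial.model.body_mass
    cols = {}
    for amp in amplitudes:
        acc = {ch: {"rmse": [], "rrmse": []} for ch in CHANNELS}
        for seed in seeds:
            noisy = add_noise(trial, amp, seed=seed)
            contacts = condition_contacts(noisy.contacts, cutoff=cutoff)
            est = estimate(trial.kin, contacts, trial.model)
            rep = compare(wrench_channels(est, foot), truth_ch, body_mass=mass)
            for ch in CHANNELS:
                acc[ch]["rmse"].append(rep[ch]["rmse"])
                acc[ch]["rrmse"].append(rep[ch]["rrmse"])
        cols[(amp, "rmse")] = [float(np.mean(acc[ch]["rmse"])) for ch in CHANNELS]
        cols[(amp, "rrmse")] = [float(np.mean(acc[ch]["rrmse"])) for ch in CHANNELS]
    df = pd.DataFrame(cols, index=list(CHANNELS))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["amplitude_m", "metric"])
    return df
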