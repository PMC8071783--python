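"""Group-level aggregation, waveform correlation and significance testing.

Per-condition summaries report mean and sample SD over animals, a one-sample
Kolmogorov-Smirnov normality check on the standardized values, and two-tailed
Student's t-tests against a designated reference condition (paired within
animal by default, since every animal is measured at every stimulus
current).  Waveform agreement between the diffuse channel and a
depth-resolved vessel class is measured as the Pearson correlation of the
full 30-s waveforms on a common time grid.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .response import FlowWaveform

__all__ = [
    "pearson_r", "interp_noise_variance_factor", "noise_sd_for_target_r",
    "Comparison", "GroupSummary", "group_aggregate",
]


def pearson_r(w1: FlowWaveform, w2: FlowWaveform) -> float:
    """Sample Pearson correlation of two waveforms on the same time grid.

    Requires >= 3 samples and nonzero variance in both; waveforms on
    different grids must first be resampled
    (:func:`~flowdissect.response.resample_to_grid`).
    """
    if w1.times.shape != w2.times.shape or not np.allclose(w1.times, w2.times):
        raise ValueError("waveforms are on different time grids; resample first")
    if w1.times.size < 3:
        raise ValueError("need >= 3 samples")
    if np.var(w1.values) == 0 or np.var(w2.values) == 0:
        raise ValueError("correlation undefined for zero-variance waveform")
    return float(sps.pearsonr(w1.values, w2.values).statistic)


def interp_noise_variance_factor(source_times: np.ndarray,
                                 target_times: np.ndarray) -> float:
    """Variance retention of i.i.d. noise under linear resampling.

    Linear interpolation of unit-variance i.i.d. samples onto a target grid
    yields per-point variance (1-w)^2 + w^2 with w the local interpolation
    weight; this returns that factor averaged over the target grid.
    """
    src = np.asarray(source_times, dtype=float)
    tgt = np.asarray(target_times, dtype=float)
    idx = np.clip(np.searchsorted(src, tgt, side="right") - 1, 0, src.size - 2)
    w = (tgt - src[idx]) / (src[idx + 1] - src[idx])
    w = np.clip(w, 0.0, 1.0)
    return float(np.mean((1.0 - w) ** 2 + w ** 2))


def noise_sd_for_target_r(signal_values: np.ndarray, rho: float,
                          variance_factor: float = 1.0) -> float:
    """Noise SD making ``signal + noise`` correlate with ``signal`` at ``rho``.

    For additive independent noise, rho = 1/sqrt(1 + var_noise/var_signal),
    so var_noise = var_signal*(1/rho^2 - 1).  ``variance_factor`` accounts
    for variance lost when the noisy channel is later resampled (see
    :func:`interp_noise_variance_factor`): the returned SD is for the noise
    *before* resampling such that the target correlation holds *after*.
    """
    if not 0 < rho <= 1:
        raise ValueError("rho must be in (0, 1]")
    var_signal = float(np.var(np.asarray(signal_values, dtype=float)))
    if var_signal == 0:
        raise ValueError("signal has zero variance")
    var_noise = var_signal * (1.0 / rho ** 2 - 1.0) / variance_factor
    return float(np.sqrt(var_noise))


@dataclasses.dataclass(frozen=True)
class Comparison:
    reference: str
    t_statistic: float
    p_value: float
    paired: bool
    two_tailed: bool = True
    degenerate: bool = False


@dataclasses.dataclass
class GroupSummary:
    condition: str
    mean: float
    sd: float
    n_animals: int
    normality_p: float
    comparisons: list[Comparison] = dataclasses.field(default_factory=list)
    degenerate: bool = False


def group_aggregate(values_by_condition: dict[str, np.ndarray],
                    reference: Optional[str] = None,
                    paired: bool = True) -> dict[str, GroupSummary]:
    """Summarize per-animal metric values across conditions.

    ``values_by_condition`` maps condition labels to per-animal arrays; with
    ``paired=True`` arrays must align animal-by-animal across conditions.
    Each non-reference condition is compared with the reference by a
    two-tailed t-test.  Conditions with identical values across animals are
    flagged degenerate (SD = 0; tests undefined).
    """
    out: dict[str, GroupSummary] = {}
    ref_vals = None
    if reference is not None:
        if reference not in values_by_condition:
            raise ValueError(f"reference condition {reference!r} missing")
        ref_vals = np.asarray(values_by_condition[reference], dtype=float)

    for cond, vals in values_by_condition.items():
        x = np.asarray(vals, dtype=float)
        if x.size < 2:
            raise ValueError(f"condition {cond!r}: need >= 2 animals")
        sd = float(x.std(ddof=1))
        degenerate = sd == 0.0
        if degenerate:
            normality_p = float("nan")
        else:
            normality_p = float(sps.kstest((x - x.mean()) / sd, "norm").pvalue)
        summary = GroupSummary(condition=cond, mean=float(x.mean()), sd=sd,
                               n_animals=int(x.size), normality_p=normality_p,
                               degenerate=degenerate)
        if ref_vals is not None and cond != reference:
            if paired and x.size != ref_vals.size:
                raise ValueError("paired comparison needs equal group sizes")
            diffs_degenerate = paired and np.allclose(x, ref_vals)
            if degenerate and np.allclose(ref_vals.std(ddof=1), 0) or diffs_degenerate:
                summary.comparisons.append(Comparison(
                    reference=reference, t_statistic=float("nan"),
                    p_value=float("nan"), paired=paired, degenerate=True))
            else:
                test = (sps.ttest_rel(x, ref_vals) if paired
                        else sps.ttest_ind(x, ref_vals))
                summary.comparisons.append(Comparison(
                    reference=reference, t_statistic=float(test.statistic),
                    p_value=float(test.pvalue), paired=paired))
        out[cond] = summary
    return out
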