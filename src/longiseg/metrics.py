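"""Longitudinal volumetry statistics.

Change measures between scans and across a volume trajectory:

* ASPC — absolute symmetrized percent change, ``100 |v2 - v1| / ((v1+v2)/2)``;
  the test–retest reliability measure (smaller is better when no biological
  change is expected).
* SPC — the signed version, revealing systematic under/over-segmentation.
* APC — annualized percent change: an OLS line is fitted to the volume
  trajectory against time re-zeroed at the first scan, and APC is
  ``100 * slope / intercept``; negative values mean yearly shrinkage.
* Cohen's d and the normal-approximation power analysis quantify how well a
  method separates the APC distributions of two patient groups.
* LES_I / LES_D — annualized lesion voxel gain and loss between consecutive
  time points, counting each direction separately.
* Dice — the usual overlap coefficient between two masks.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

__all__ = [
    "VolumeSeries",
    "aspc",
    "spc",
    "apc",
    "cohens_d",
    "required_sample_size",
    "lesion_change_rates",
    "LesionChangeRates",
    "dice",
]


@dataclasses.dataclass
class VolumeSeries:
    """One structure's volume trajectory (ml) at given times (years)."""

    structure: str
    volumes: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.volumes.shape != self.times.shape or self.volumes.ndim != 1:
            raise ValueError("volumes and times must be 1D and equal length")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def aspc(v1: float, v2: float) -> float:
    """Absolute symmetrized percent change between two volumes."""
    if v1 + v2 <= 0:
        raise ValueError("ASPC undefined for v1 + v2 = 0")
    return 100.0 * abs(v2 - v1) / ((v1 + v2) / 2.0)


def spc(v1: float, v2: float) -> float:
    """Signed symmetrized percent change; antisymmetric in its arguments."""
    if v1 + v2 <= 0:
        raise ValueError("SPC undefined for v1 + v2 = 0")
    return 100.0 * (v2 - v1) / ((v1 + v2) / 2.0)


def apc(series: VolumeSeries) -> float:
    """Annualized percent change from an OLS line fit.

    The line is fitted against time measured from the first scan, so the
    intercept is the fitted volume at baseline.
    """
    t = series.times - series.times[0]
    if t.size < 2:
        raise ValueError("APC needs at least two time points")
    slope, intercept = np.polyfit(t, series.volumes, 1)
    if intercept == 0:
        raise ValueError("APC undefined: zero fitted baseline volume")
    return 100.0 * slope / intercept


def cohens_d(group_a, group_b) -> float:
    """Effect size between two groups with the pooled-SD convention
    (nA + nB - 2 denominator)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (
        na + nb - 2
    )
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def required_sample_size(group_a, group_b, power=0.80, alpha=0.05) -> int:
    """Subjects per group to detect the two groups' standardized difference.

    Uses the two-sided normal-approximation formula
    ``n = ceil( 2 (z_{1-alpha/2} + z_{power})^2 / d^2 )`` with d estimated
    from the two-group linear model (equivalently, Cohen's d).
    """
    d = cohens_d(group_a, group_b)
    if d == 0:
        raise ValueError("zero effect size: infinite sample size")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    return int(math.ceil(2.0 * (z_a + z_b) ** 2 / d**2))


@dataclasses.dataclass
class LesionChangeRates:
    les_i_ml: float
    les_d_ml: float
    les_i_voxels: float
    les_d_voxels: float


def lesion_change_rates(masks, times, voxel_size) -> LesionChangeRates:
    """Annualized lesion voxel gain (LES_I) and loss (LES_D).

    For each consecutive pair, voxels labeled lesion at t+1 but not at t
    count as gain and vice versa for loss; each pair's counts are divided by
    its time interval (years) and the pairs averaged.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    times = np.asarray(times, dtype=float)
    if len(masks) < 2:
        raise ValueError("need at least two time points")
    if len(masks) != times.size:
        raise ValueError("one mask per time point required")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(
                f"mask grids disagree: {m.shape} vs {shape}")
    gain = loss = 0.0
    for m_prev, m_next, dt in zip(masks, masks[1:], np.diff(times)):
        gain += int((m_next & ~m_prev).sum()) / dt
        loss += int((m_prev & ~m_next).sum()) / dt
    n_pairs = len(masks) - 1
    gain /= n_pairs
    loss /= n_pairs
    vox_ml = float(np.prod(np.asarray(voxel_size, dtype=float))) / 1000.0
    return LesionChangeRates(les_i_ml=gain * vox_ml, les_d_ml=loss * vox_ml,
                             les_i_voxels=gain, les_d_voxels=loss)


def dice(mask_x, mask_y) -> float:
    """Overlap coefficient 2|X ∩ Y| / (|X| + |Y|)."""
    x = np.asarray(mask_x, dtype=bool)
    y = np.asarray(mask_y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"mask grids disagree: {x.shape} vs {y.shape}")
    total = int(x.sum()) + int(y.sum())
    if total == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * int((x & y).sum()) / total
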