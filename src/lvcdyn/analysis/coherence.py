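"""Per-mode coherence descriptors of the nuclear motion.

Operational definitions (conventions fixed here, not a literature
reproduction; sigma0 = 1/sqrt(2) is the ground-state Wigner width of the
dimensionless coordinates):

* shiftEX_i = |time mean of the ensemble-mean Q_i| / sigma0 - how far the
  average position shifts after excitation;
* cohEX_i = std-over-time of the ensemble-mean trace divided by the
  trajectory mean of each trajectory's own std-over-time, clipped to [0, 1] -
  in-phase motion scores 1, randomly-phased motion tends to 0;
* delta_sigma_i = (time mean of the ensemble std - sigma0) / sigma0 - how
  much the distribution broadens.

A mode is flagged important when at least two descriptors exceed their
thresholds.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ..dynamics.ensemble import Ensemble

__all__ = ["CoherenceDescriptors", "coherence_descriptors", "SIGMA0"]

SIGMA0 = 1.0 / np.sqrt(2.0)

DEFAULT_THRESHOLDS = {"shift": 0.5, "coh": 0.3, "dsigma": 0.25}


@dataclass
class CoherenceDescriptors:
    shift: np.ndarray  # (F,)
    coh: np.ndarray  # (F,) in [0, 1]
    dsigma: np.ndarray  # (F,)
    thresholds: dict
    important: np.ndarray  # (F,) bool


def coherence_descriptors(
    ens_or_q,
    window: Optional[Tuple[float, float]] = None,
    thresholds: Optional[dict] = None,
    times: Optional[np.ndarray] = None,
) -> CoherenceDescriptors:
    """Compute the three descriptors per mode over a time window.

    Accepts an :class:`Ensemble` or a raw (n_traj, T, F) coordinate array
    (then ``times`` must be given).  Requires at least two trajectories.
    """
    if isinstance(ens_or_q, Ensemble):
        q = ens_or_q.Q
        t = ens_or_q.times
    else:
        q = np.asarray(ens_or_q, dtype=float)
        if times is None:
            raise ValueError("times required when passing a raw coordinate array")
        t = np.asarray(times, dtype=float)
    if q.ndim != 3:
        raise ValueError("coordinates must have shape (n_traj, T, F)")
    if q.shape[0] < 2:
        raise ValueError("coherence descriptors require at least 2 trajectories")
    if window is not None:
        lo, hi = window
        if hi > t[-1]:
            warnings.warn("analysis window exceeds the archive; truncating")
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 2:
            raise ValueError("window contains fewer than 2 time frames")
        q = q[:, mask]

    mean_trace = q.mean(axis=0)  # (T, F) ensemble mean
    shift = np.abs(mean_trace.mean(axis=0)) / SIGMA0

    coherent_amp = mean_trace.std(axis=0)  # std over time of the mean trace
    per_traj_amp = q.std(axis=1).mean(axis=0)  # mean over traj of std over time
    # amplitudes at float-noise level mean "no motion", not perfect coherence
    floor = 1e-10 * max(1.0, float(np.abs(q).max()))
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(per_traj_amp > floor, coherent_amp / per_traj_amp, 0.0)
    coh = np.clip(coh, 0.0, 1.0)

    ens_std = q.std(axis=0)  # (T, F) std across trajectories
    dsigma = (ens_std.mean(axis=0) - SIGMA0) / SIGMA0

    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    count = (
        (shift > th["shift"]).astype(int)
        + (coh > th["coh"]).astype(int)
        + (np.abs(dsigma) > th["dsigma"]).astype(int)
    )
    return CoherenceDescriptors(
        shift=shift, coh=coh, dsigma=dsigma, thresholds=th, important=count >= 2
    )
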