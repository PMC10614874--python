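"""Single-trial comparison measures of coordinated spiking.

Three model-light measures commonly used to characterize ensemble synchrony:
windowed average pairwise Pearson correlation of kernel-smoothed spike trains,
spiking regularity (coefficient of variation of inter-spike intervals; ~1 for
Poisson statistics, <1 for regular/globally coordinated spiking), and the
average difference between order-r mark CIFs and the corresponding
independence probabilities under a fitted model.  All three are pure functions
of their inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .markspace import SpikeRaster, order_r_marks
from .model import ModelParams, mark_cifs

logger = logging.getLogger(__name__)


@dataclass
class WindowedMeasure:
    """Per-window measure with symmetric confidence band; NaN marks windows
    where the measure is undefined (flagged, not silently zeroed)."""

    value: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    window: int

    def to_table(self) -> np.ndarray:
        k = np.arange(1, self.value.size + 1)
        return np.column_stack([k, self.value, self.ci_low, self.ci_high])


def avg_pairwise_correlation(raster: SpikeRaster, smoothing_sd: float = 5.0,
                             window: int = 200) -> WindowedMeasure:
    """Mean Pearson correlation over all neuron pairs of smoothed trains.

    Trains are smoothed with a Gaussian kernel (sd in bins), correlations are
    computed over non-overlapping windows and averaged across the C(C-1)/2
    pairs with a 95% normal-approximation confidence interval.  Pairs in
    which either train has zero variance within a window are excluded; if no
    pair remains the window is flagged missing (zero-variance convention).
    """
    C, T = raster.data.shape
    if C < 2:
        raise ValueError("need at least two neurons")
    sm = gaussian_filter1d(raster.data.astype(float), smoothing_sd, axis=1,
                           mode="constant")
    K = T // window
    val = np.full(K, np.nan)
    lo = np.full(K, np.nan)
    hi = np.full(K, np.nan)
    iu = np.triu_indices(C, k=1)
    for k in range(K):
        seg = sm[:, k * window:(k + 1) * window]
        sd = seg.std(axis=1)
        ok = sd > 0
        if ok.sum() < 2:
            logger.warning("window %d: fewer than two varying trains", k + 1)
            continue
        cc = np.corrcoef(seg[ok])
        sub = cc[np.triu_indices(int(ok.sum()), k=1)]
        if sub.size == 0:
            continue
        val[k] = sub.mean()
        sem = sub.std(ddof=1) / np.sqrt(sub.size) if sub.size > 1 else 0.0
        lo[k] = val[k] - 1.96 * sem
        hi[k] = val[k] + 1.96 * sem
    dropped = int(np.isnan(val).sum())
    if dropped:
        logger.warning("%d windows had zero-variance trains (flagged missing)", dropped)
    return WindowedMeasure(val, lo, hi, window)


def spiking_regularity(raster: SpikeRaster, window: int = 200) -> WindowedMeasure:
    """Mean coefficient of variation of inter-spike intervals per window.

    Neurons with fewer than three spikes in a window (fewer than two ISIs)
    are excluded from that window's average; the band is +-2 SEM across the
    included neurons.  A perfectly periodic train gives CV 0; Poisson spiking
    gives CV near 1.
    """
    C, T = raster.data.shape
    K = T // window
    val = np.full(K, np.nan)
    lo = np.full(K, np.nan)
    hi = np.full(K, np.nan)
    for k in range(K):
        cvs = []
        for c in range(C):
            t = np.nonzero(raster.data[c, k * window:(k + 1) * window])[0]
            if t.size < 3:
                continue
            isi = np.diff(t).astype(float)
            m = isi.mean()
            if m > 0:
                cvs.append(isi.std(ddof=0) / m)
        if not cvs:
            continue
        cvs = np.asarray(cvs)
        val[k] = cvs.mean()
        sem = cvs.std(ddof=1) / np.sqrt(cvs.size) if cvs.size > 1 else 0.0
        lo[k] = val[k] - 2 * sem
        hi[k] = val[k] + 2 * sem
    return WindowedMeasure(val, lo, hi, window)


def mark_cif_difference(params: ModelParams, X: np.ndarray, r: int,
                        ) -> WindowedMeasure:
    """Per-bin average of ``lam*(m)dt - independence probability`` over order-r marks.

    The independence probability of mark m is the product
    ``prod_{c in m} lam(c)dt * prod_{c not in m} (1 - lam(c)dt)`` with the
    per-neuron intensities read off the same fitted model; the band is
    +-2 SEM across the order-r marks.  Single-neuron marks give exactly zero
    only when the model itself factorizes.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = params.C
    kr = order_r_marks(C, r)
    present = np.isin(kr, params.marks)
    p_marks, _, _ = mark_cifs(params, X)
    p_marks = np.atleast_2d(p_marks)
    bits_all = ((params.marks[:, None] >> np.arange(C)) & 1).astype(float)
    lam = np.clip(p_marks @ bits_all, 1e-12, 1 - 1e-12)      # T x C
    diffs = np.zeros((X.shape[0], kr.size))
    for i, m in enumerate(kr):
        mbits = ((int(m) >> np.arange(C)) & 1).astype(bool)
        indep = np.prod(np.where(mbits, lam, 1 - lam), axis=1)
        if present[i]:
            row = int(np.nonzero(params.marks == m)[0][0])
            diffs[:, i] = p_marks[:, row] - indep
        else:
            diffs[:, i] = 0.0 - indep  # pruned marks have rate 0 under the model
    val = diffs.mean(axis=1)
    sem = diffs.std(axis=1, ddof=1) / np.sqrt(kr.size) if kr.size > 1 else np.zeros_like(val)
    return WindowedMeasure(val, val - 2 * sem, val + 2 * sem, window=1)
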