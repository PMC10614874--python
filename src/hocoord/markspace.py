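"""Disjoint marked representation of multivariate binned spiking.

An ensemble of ``C`` neurons binned at width ``delta`` yields a binary vector
``n_t`` per bin.  Treating the components of ``n_t`` as the bits of a C-bit
binary number maps every non-zero spiking pattern to one of ``C* = 2**C - 1``
*marks*; neuron ``c`` corresponds to the c-th least-significant bit, so e.g.
with C=3 the pattern "only neuron 3 spikes" is mark 4 and neuron 3's spike
train is the sum of the mark processes 4-7.  Mark index 0 is reserved for the
no-event outcome and is never a mark.

The module provides the encode/decode maps, conversion between the raster and
the marked series, enumeration of the order-r mark sets (all marks with binary
popcount r), and pruning of the mark space to the "reliable" marks that occur
more than ``n_thr`` times in a recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SpikeRaster:
    """Binned binary ensemble spiking: neurons x time bins.

    Parameters
    ----------
    data:
        Binary matrix of shape ``(C, T)``; ``data[c, t]`` is 1 iff neuron
        ``c+1`` spikes in bin ``t``.
    bin_size:
        Bin width in seconds (``delta``).
    """

    data: np.ndarray
    bin_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("raster must be a C x T matrix with C, T >= 1")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.data = self.data.astype(np.uint8)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]


@dataclass
class MarkedSeries:
    """Sparse marked Bernoulli series: at most one mark event per time bin.

    Stored as parallel arrays of event ``times`` (bin indices) and ``marks``
    (indices in ``1..2**C - 1``), which is the natural representation given
    disjointness: each column of the dense ``C* x T`` matrix has at most one
    nonzero entry.
    """

    C: int
    T: int
    times: np.ndarray
    marks: np.ndarray
    bin_size: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.marks = np.asarray(self.marks, dtype=np.int64)
        if self.times.shape != self.marks.shape:
            raise ValueError("times and marks must have equal length")
        if self.times.size:
            if self.times.min() < 0 or self.times.max() >= self.T:
                raise ValueError("event time out of range")
            if self.marks.min() < 1 or self.marks.max() > self.n_marks:
                raise ValueError("mark index out of range")
            if np.unique(self.times).size != self.times.size:
                raise ValueError("disjointness violated: multiple marks in one bin")

    @property
    def n_marks(self) -> int:
        """Size of the full mark space, ``C* = 2**C - 1``."""
        return (1 << self.C) - 1

    @property
    def ground(self) -> np.ndarray:
        """Binary ground process: 1 in bins containing any spiking event."""
        g = np.zeros(self.T, dtype=np.uint8)
        g[self.times] = 1
        return g

    def counts(self) -> np.ndarray:
        """Event count per mark, indexed ``counts[m-1]`` for mark ``m``."""
        return np.bincount(self.marks, minlength=self.n_marks + 1)[1:]

    def mark_rows(self, mark_order: np.ndarray, T: int | None = None) -> np.ndarray:
        """Per-bin outcome row: index into ``mark_order`` or -1 (no modeled event).

        Events whose mark is not in ``mark_order`` (pruned marks) map to -1.
        """
        T = self.T if T is None else T
        lut = -np.ones(self.n_marks + 1, dtype=np.int64)
        lut[np.asarray(mark_order, dtype=np.int64)] = np.arange(len(mark_order))
        rows = -np.ones(T, dtype=np.int64)
        keep = self.times < T
        rows[self.times[keep]] = lut[self.marks[keep]]
        return rows

    def to_dense(self) -> np.ndarray:
        """Dense ``C* x T`` binary matrix (small C only)."""
        out = np.zeros((self.n_marks, self.T), dtype=np.uint8)
        out[self.marks - 1, self.times] = 1
        return out


@dataclass
class MarkSpace:
    """Full and pruned ("reliable") mark sets for a C-neuron assembly."""

    C: int
    n_thr: int
    reliable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.reliable is None:
            self.reliable = self.full
        self.reliable = np.asarray(self.reliable, dtype=np.int64)
        if self.reliable.size and (
            self.reliable.min() < 1 or self.reliable.max() > (1 << self.C) - 1
        ):
            raise ValueError("reliable marks out of range")

    @property
    def full(self) -> np.ndarray:
        return np.arange(1, (1 << self.C), dtype=np.int64)

    @property
    def n_marks(self) -> int:
        return (1 << self.C) - 1

    def order_r(self, r: int) -> np.ndarray:
        """Reliable marks of coordination order ``r`` (popcount r)."""
        kr = order_r_marks(self.C, r)
        return kr[np.isin(kr, self.reliable)]


# ---------------------------------------------------------------------------
# operations


def _check_binary(vec: np.ndarray) -> np.ndarray:
    vec = np.asarray(vec)
    if not np.isin(vec, (0, 1)).all():
        raise ValueError("spike vector entries must be 0 or 1")
    return vec.astype(np.int64)


def encode_mark(spike_vector) -> int:
    """Binary word value of a spike pattern; neuron c is the c-th LSB.

    Returns 0 for the all-zero pattern (no event; not a mark).
    """
    vec = _check_binary(spike_vector)
    return int(vec @ (1 << np.arange(vec.size, dtype=np.int64)))


def decode_mark(m: int, C: int) -> np.ndarray:
    """Inverse of :func:`encode_mark`: binary length-C pattern of mark ``m``."""
    if not 0 <= m <= (1 << C) - 1:
        raise ValueError(f"mark {m} out of range for C={C}")
    return (m >> np.arange(C)) & 1


def to_marked(raster: SpikeRaster) -> MarkedSeries:
    """Map a raster to its disjoint marked series (vectorized encode per bin)."""
    weights = 1 << np.arange(raster.n_neurons, dtype=np.int64)
    codes = weights @ raster.data.astype(np.int64)
    times = np.nonzero(codes)[0]
    return MarkedSeries(
        C=raster.n_neurons,
        T=raster.n_bins,
        times=times,
        marks=codes[times],
        bin_size=raster.bin_size,
    )


def from_marked(marked: MarkedSeries) -> SpikeRaster:
    """Reconstruct the raster (inverse of :func:`to_marked`)."""
    data = np.zeros((marked.C, marked.T), dtype=np.uint8)
    for c in range(marked.C):
        data[c] = recover_neuron(marked, c + 1)
    return SpikeRaster(data, bin_size=marked.bin_size)


def recover_neuron(marked: MarkedSeries, c: int) -> np.ndarray:
    """Spike train of neuron ``c`` (1-based): sum of marks with bit c set."""
    if not 1 <= c <= marked.C:
        raise ValueError(f"neuron index {c} out of range for C={marked.C}")
    out = np.zeros(marked.T, dtype=np.uint8)
    hit = (marked.marks >> (c - 1)) & 1
    out[marked.times[hit == 1]] = 1
    return out


def order_r_marks(C: int, r: int) -> np.ndarray:
    """All marks whose binary popcount equals ``r`` (the order-r set)."""
    if not 1 <= r <= C:
        raise ValueError(f"order r={r} out of range for C={C}")
    marks = np.arange(1, 1 << C, dtype=np.int64)
    pop = np.array([bin(m).count("1") for m in marks])
    return marks[pop == r]


def mark_order(m: int) -> int:
    """Coordination order (popcount) of mark ``m``."""
    return bin(int(m)).count("1")


def reliable_marks(marked: MarkedSeries, n_thr: int) -> MarkSpace:
    """Prune the mark space to marks with event count strictly above ``n_thr``."""
    if n_thr < 0:
        raise ValueError("n_thr must be >= 0")
    counts = marked.counts()
    keep = np.nonzero(counts > n_thr)[0] + 1
    dropped = marked.n_marks - keep.size
    if dropped:
        logger.debug("pruned %d of %d marks (n_thr=%d)", dropped, marked.n_marks, n_thr)
    return MarkSpace(C=marked.C, n_thr=n_thr, reliable=keep)


# ---------------------------------------------------------------------------
# text I/O


def read_raster_txt(path, bin_size: float = 1.0, delimiter=None) -> SpikeRaster:
    """Read a delimited text matrix (rows = neurons, columns = bins)."""
    data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return SpikeRaster(data.astype(np.uint8), bin_size=bin_size)


def write_raster_txt(path, raster: SpikeRaster, delimiter: str = "\t") -> None:
    np.savetxt(path, raster.data, fmt="%d", delimiter=delimiter)


def read_events_tsv(path, bin_size: float, n_neurons: int | None = None,
                    duration: float | None = None) -> SpikeRaster:
    """Bin a spike-time event list (TSV: neuron_id, time_s) into a raster.

    Binning is half-open ``[t, t + delta)``.  Multiple spikes of one neuron in
    one bin are clipped to 1 with a warning (Bernoulli binning assumption).
    """
    tbl = np.loadtxt(path, ndmin=2)
    if tbl.size == 0:
        raise ValueError("empty event list")
    ids = tbl[:, 0].astype(np.int64)
    times = tbl[:, 1].astype(float)
    if ids.min() < 1:
        raise ValueError("neuron_id must be 1-based")
    C = int(ids.max()) if n_neurons is None else int(n_neurons)
    tmax = times.max() if duration is None else duration
    T = max(1, int(np.ceil(tmax / bin_size + 1e-12)))
    bins = np.minimum((times / bin_size).astype(np.int64), T - 1)
    data = np.zeros((C, T), dtype=np.int64)
    np.add.at(data, (ids - 1, bins), 1)
    if (data > 1).any():
        n_clip = int((data > 1).sum())
        logger.warning("clipped %d bins with >1 spike of the same neuron", n_clip)
        data = np.minimum(data, 1)
    return SpikeRaster(data.astype(np.uint8), bin_size=bin_size)


def write_marked_triplets(path, marked: MarkedSeries, delimiter: str = "\t") -> None:
    """Export the marked series as sparse (mark, bin, 1) triplets."""
    trip = np.column_stack([marked.marks, marked.times, np.ones_like(marked.marks)])
    np.savetxt(path, trip, fmt="%d", delimiter=delimiter, header="mark\tbin\tvalue")
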