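"""Phase Lag Index (PLI) functional connectivity.

The PLI between two signals is computed from their instantaneous phase
difference Δϕ(t_k), obtained via the Hilbert analytic signal::

    PLI = | < sign( sin Δϕ(t_k) ) > |        (average over samples k)

PLI lies in [0, 1]. It is 0 for no coupling or for coupling whose phase
difference is centered on 0 (mod π) — which is what instantaneous
("volume-conducted") mixing of a common source produces — and 1 for perfect
phase locking at any lag different from 0 (mod π). sign(0) contributes 0,
so two identical channels give PLI exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .core import BandSpec, EpochedRecording

__all__ = [
    "PhaseSeries",
    "ConnectivityMatrix",
    "instantaneous_phase",
    "pli_pair",
    "pli_matrix",
    "epoch_pli_matrices",
    "mean_total_pli",
    "band_mean_pli",
]


@dataclass
class PhaseSeries:
    """Instantaneous phase of one channel over one epoch, radians in (−π, π]."""

    phases: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phase series contains non-finite values")

    def __len__(self) -> int:
        return len(self.phases)


@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels PLI matrix for one band and epoch."""

    values: np.ndarray
    band: BandSpec | None = None
    epoch_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def mean_upper(self) -> float:
        """Mean PLI over all channel pairs (upper triangle)."""
        iu = np.triu_indices(self.n_channels, k=1)
        return float(self.values[iu].mean())


def instantaneous_phase(x: np.ndarray, fs: float) -> PhaseSeries:
    """Instantaneous phase of a band-limited signal via the analytic signal.

    The input should already be band-pass filtered; the phase of a broadband
    signal is not interpretable. Raises on an (all-zero) degenerate input,
    whose phase is undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("instantaneous_phase expects a single channel vector")
    if not np.any(x):
        raise ValueError("degenerate all-zero signal has no instantaneous phase")
    return PhaseSeries(phases=np.angle(hilbert(x)), fs=fs)


def pli_pair(a: PhaseSeries, b: PhaseSeries) -> float:
    """PLI between two phase series: ``|mean(sign(sin(b − a)))|``."""
    if len(a) != len(b):
        raise ValueError(f"phase series lengths differ: {len(a)} vs {len(b)}")
    return float(np.abs(np.mean(np.sign(np.sin(b.phases - a.phases)))))


def _phase_stack(rec_band: EpochedRecording, edge_trim_s: float = 0.0) -> np.ndarray:
    """Analytic-signal phases for all epochs/channels: (n_epochs, n_ch, n_samp).

    ``edge_trim_s`` discards that many seconds of phase samples at each
    epoch edge, where the Hilbert transform and filter transients distort
    the phase estimate. Default 0 (no trimming).
    """
    phases = np.angle(hilbert(rec_band.epochs, axis=-1))
    trim = int(round(edge_trim_s * rec_band.fs))
    if trim > 0:
        if 2 * trim >= phases.shape[-1]:
            raise ValueError(
                f"edge trim of {edge_trim_s} s leaves no samples in a "
                f"{rec_band.epoch_duration} s epoch"
            )
        phases = phases[..., trim:-trim]
    return phases


def _pli_from_phases(phases: np.ndarray) -> np.ndarray:
    """PLI matrix from per-channel phases (n_channels, n_samples)."""
    n = phases.shape[0]
    out = np.zeros((n, n))
    for i in range(n - 1):
        d = phases[i + 1 :] - phases[i]
        out[i, i + 1 :] = np.abs(np.sign(np.sin(d)).mean(axis=-1))
    return out + out.T


def pli_matrix(
    rec_band: EpochedRecording,
    epoch_index: int,
    band: BandSpec | None = None,
    edge_trim_s: float = 0.0,
) -> ConnectivityMatrix:
    """PLI between all channel pairs for one epoch of a band-filtered recording.

    The result is symmetric with zero diagonal and entries in [0, 1], and is
    equivariant under channel permutation.
    """
    if rec_band.n_channels < 2:
        raise ValueError("connectivity needs at least 2 channels")
    phases = _phase_stack(
        rec_band.with_epochs(rec_band.epochs[epoch_index : epoch_index + 1]),
        edge_trim_s,
    )[0]
    return ConnectivityMatrix(
        values=_pli_from_phases(phases), band=band, epoch_index=epoch_index
    )


def epoch_pli_matrices(
    rec_band: EpochedRecording,
    band: BandSpec | None = None,
    edge_trim_s: float = 0.0,
) -> list[ConnectivityMatrix]:
    """PLI matrices for every epoch of a band-filtered recording.

    PLI is always computed within an epoch and only then averaged across
    epochs — never on concatenated epochs.
    """
    if rec_band.n_channels < 2:
        raise ValueError("connectivity needs at least 2 channels")
    phases = _phase_stack(rec_band, edge_trim_s)
    return [
        ConnectivityMatrix(values=_pli_from_phases(phases[k]), band=band, epoch_index=k)
        for k in range(rec_band.n_epochs)
    ]


def mean_total_pli(mats: list[ConnectivityMatrix] | ConnectivityMatrix) -> float:
    """Mean total PLI: average over all channel pairs, then over epochs."""
    if isinstance(mats, ConnectivityMatrix):
        mats = [mats]
    if not mats:
        raise ValueError("no connectivity matrices given")
    return float(np.mean([m.mean_upper() for m in mats]))


def band_mean_pli(rec_band: EpochedRecording, edge_trim_s: float = 0.0) -> float:
    """Mean total PLI of a band-filtered recording (all epochs).

    Fast path equivalent to ``mean_total_pli(epoch_pli_matrices(rec))``.
    """
    if rec_band.n_channels < 2:
        raise ValueError("connectivity needs at least 2 channels")
    phases = _phase_stack(rec_band, edge_trim_s)
    n = rec_band.n_channels
    total = 0.0
    count = 0
    for i in range(n - 1):
        d = phases[:, i + 1 :, :] - phases[:, i : i + 1, :]
        pli = np.abs(np.sign(np.sin(d)).mean(axis=-1))  # (n_epochs, n-i-1)
        total += pli.sum()
        count += pli.size
    return float(total / count)
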