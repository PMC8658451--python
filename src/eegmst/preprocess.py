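"""Segmentation, average referencing, zero-phase band filtering, FFT power.

Filtering uses a windowed-sinc (Hamming) FIR applied forward and backward
(:func:`scipy.signal.filtfilt`), i.e. zero phase: band-limited components
come out with no group delay, which is what the Hilbert-phase connectivity
step downstream assumes. The filter order is chosen from the transition
width so that signals one octave outside the band are attenuated by well
over 20 dB, capped so the filter still fits inside one epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import BandSpec, EpochedRecording

__all__ = [
    "PowerSummary",
    "segment",
    "average_reference",
    "design_bandpass_fir",
    "bandpass",
    "relative_power",
    "TOTAL_POWER_RANGE",
]

#: Default denominator range for relative power: the union of the four
#: analysis bands, so their relative powers sum to 1.
TOTAL_POWER_RANGE = (0.5, 30.0)


@dataclass
class PowerSummary:
    """Relative spectral power of one band for one recording.

    ``relative_power`` is band power divided by total power, averaged over
    epochs and then channels; ``per_channel`` holds the per-channel
    fractions (epoch-averaged) in recording channel order.
    """

    band: BandSpec
    relative_power: float
    per_channel: np.ndarray
    total_range: tuple[float, float] = TOTAL_POWER_RANGE


def segment(
    continuous: np.ndarray,
    fs: float,
    epoch_s: float = 4.0,
    n_keep: int | None = 30,
    **rec_kwargs,
) -> EpochedRecording:
    """Cut a continuous (channels x samples) record into consecutive epochs.

    Non-overlapping epochs of ``epoch_s`` seconds are taken from the start;
    the first ``n_keep`` are retained (all full epochs if ``None``). This is
    the deterministic counterpart of selecting 30 artifact-free 4-s epochs
    from a longer recording.

    Raises
    ------
    ValueError
        If fewer than ``n_keep`` full epochs fit, stating how many do.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_samples_epoch = int(round(epoch_s * fs))
    n_fit = continuous.shape[1] // n_samples_epoch
    if n_keep is None:
        n_keep = n_fit
    if n_fit < n_keep:
        raise ValueError(
            f"only {n_fit} epochs of {epoch_s} s fit in "
            f"{continuous.shape[1] / fs:.3f} s of data; {n_keep} requested"
        )
    used = continuous[:, : n_keep * n_samples_epoch]
    epochs = used.reshape(continuous.shape[0], n_keep, n_samples_epoch)
    epochs = np.transpose(epochs, (1, 0, 2))
    defaults = dict(subject_id="", group="typical", condition="baseline")
    defaults.update(rec_kwargs)
    channels = defaults.pop(
        "channels", tuple(f"ch{i:02d}" for i in range(continuous.shape[0]))
    )
    return EpochedRecording(fs=fs, channels=channels, epochs=epochs, **defaults)


def average_reference(rec: EpochedRecording) -> EpochedRecording:
    """Re-reference to the average of all channels.

    After referencing, the mean across channels is zero at every sample.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    referenced = rec.epochs - rec.epochs.mean(axis=1, keepdims=True)
    return rec.with_epochs(referenced)


def design_bandpass_fir(band: BandSpec, fs: float, n_samples: int | None = None) -> np.ndarray:
    """Design the Hamming-window FIR band-pass taps for ``band`` at ``fs``.

    The transition width is half the smaller of the band's low edge and its
    width (floored at 0.5 Hz); the Hamming design rule then gives ~53 dB
    stopband per pass, doubled by the forward-backward application. When
    ``n_samples`` is given the tap count is capped so filtfilt's padding
    still fits inside one epoch (relevant only for the delta band at short
    epochs, where the ideal transition would need a longer filter).
    """
    if band.hi >= fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.hi} Hz >= Nyquist {fs / 2} Hz"
        )
    trans = max(0.5 * min(band.lo, band.width), 0.5)
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1  # Hamming rule, odd length
    if n_samples is not None:
        cap = max((n_samples - 2) // 3, 3) | 1
        numtaps = min(numtaps, cap)
    return signal.firwin(
        numtaps, [band.lo, band.hi], pass_zero=False, fs=fs, window="hamming"
    )


def bandpass(rec: EpochedRecording, band: BandSpec) -> EpochedRecording:
    """Zero-phase FIR band-pass of every epoch and channel.

    Returns a copy tagged with the band name so downstream steps can tell
    band-limited from broadband data.
    """
    taps = design_bandpass_fir(band, rec.fs, rec.n_samples)
    padlen = min(3 * (len(taps) - 1), rec.n_samples - 1)
    filtered = signal.filtfilt(taps, [1.0], rec.epochs, axis=-1, padlen=padlen)
    return rec.with_epochs(filtered, band=band.name)


def _epoch_power_spectrum(epochs: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch, per-channel one-sided power spectrum.

    Scaled so that summing over all frequency bins reproduces the
    time-domain mean square (Parseval), making band/total ratios exact
    fractions of total power.
    """
    n = epochs.shape[-1]
    spec = np.fft.rfft(epochs, axis=-1)
    power = np.abs(spec) ** 2 / n**2
    # fold negative frequencies into positive bins (all but DC and Nyquist)
    if n % 2 == 0:
        power[..., 1:-1] *= 2.0
    else:
        power[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def relative_power(
    rec: EpochedRecording,
    band: BandSpec,
    total_lo: float = TOTAL_POWER_RANGE[0],
    total_hi: float = TOTAL_POWER_RANGE[1],
) -> PowerSummary:
    """Relative band power from per-epoch FFTs.

    Per epoch and channel, power is summed over bins with
    ``band.lo <= f < band.hi`` (half-open, so boundary bins are never double
    counted across adjacent bands) and divided by the power summed over
    ``[total_lo, total_hi)``. The fractions are averaged over epochs, then
    over channels. The frequency resolution is ``1 / epoch duration``
    (0.25 Hz for 4-s epochs).

    Warns if called on band-limited input, where "total power" is no longer
    a broadband denominator.
    """
    if rec.band is not None:
        import warnings

        warnings.warn(
            f"relative_power called on {rec.band}-filtered data; expected "
            "broadband input",
            UserWarning,
            stacklevel=2,
        )
    if not (total_lo <= band.lo and band.hi <= total_hi):
        raise ValueError(
            f"band [{band.lo}, {band.hi}) not inside total range "
            f"[{total_lo}, {total_hi})"
        )
    freqs, power = _epoch_power_spectrum(rec.epochs, rec.fs)
    in_band = (freqs >= band.lo) & (freqs < band.hi)
    in_total = (freqs >= total_lo) & (freqs < total_hi)
    band_p = power[..., in_band].sum(axis=-1)
    total_p = power[..., in_total].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total_p > 0, band_p / np.maximum(total_p, 1e-300), 0.0)
    per_channel = frac.mean(axis=0)  # average over epochs
    return PowerSummary(
        band=band,
        relative_power=float(per_channel.mean()),
        per_channel=per_channel,
        total_range=(total_lo, total_hi),
    )
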