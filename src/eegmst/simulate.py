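"""Synthetic multichannel EEG with controllable band-limited phase coupling.

The generator emulates the statistical structure the pipeline assumes, so
every stage — spectra, PLI, MST metrics, group statistics — is testable
without recorded data. Per frequency band b, channel i carries

    x_i(t) = sum_b A_b * [ sqrt(c_b) * Re(S_b(t) e^{i delta_i})
                           + sqrt(1 - c_b) * n_{b,i}(t) ]  + pink noise

where S_b is a shared narrowband analytic signal, delta_i is a constant
channel phase offset drawn away from 0 (mod pi) so nonzero-lag coupling is
visible to the PLI, n_{b,i} is independent narrowband noise in the same
band, and c_b in [0, 1] is the coupling knob: c = 0 gives channels that are
exactly independent in that band, c = 1 perfect nonzero-lag phase locking.
A zero-lag mixing step (1-v) I + (v/N) J emulates volume conduction: it
spreads every channel instantaneously into every other, which inflates
amplitude covariance but, by construction of the PLI, not phase-lag
coupling.

Group x condition effects (e.g. reduced theta coupling for dyslexics during
the task) enter as multiplicative modifiers on c_b. All randomness flows
from a single seed through a documented splitting scheme (one child seed
per subject x condition), so any recording is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import hilbert

from .core import CONDITIONS, DEFAULT_BANDS, BandSpec, EpochedRecording, StudyDesign
from .io import write_ascii_epochs

__all__ = [
    "SimulationParams",
    "EffectSpec",
    "generate_recording",
    "generate_study",
    "generate_learning_curves",
    "write_study",
]


@dataclass(frozen=True)
class SimulationParams:
    """Study-level simulation conditions.

    Defaults mirror the recording geometry of the emulated study: 64 scalp
    channels at 1024 Hz, thirty 4-s epochs per subject and condition.
    Amplitudes are in µV (alpha-dominant resting spectrum); ``coupling``
    maps band name to the phase-coupling knob c in [0, 1]; ``mixing`` is
    the zero-lag (volume conduction) strength v in [0, 1);
    ``noise_amplitude`` scales the pink (1/f) background. The jitter
    standard deviations control between-subject and between-condition
    variability of the coupling knob in simulated studies.
    """

    n_channels: int = 64
    fs: float = 1024.0
    epoch_s: float = 4.0
    n_epochs: int = 30
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    amplitudes: dict = field(
        default_factory=lambda: {"delta": 4.0, "theta": 3.0, "alpha": 6.0, "beta": 2.0}
    )
    coupling: dict = field(
        default_factory=lambda: {"delta": 0.3, "theta": 0.45, "alpha": 0.5, "beta": 0.35}
    )
    phase_offset_margin: float = 0.2
    mixing: float = 0.2
    noise_amplitude: float = 2.0
    subject_coupling_sd: float = 0.04
    condition_coupling_sd: float = 0.02
    amplitude_jitter_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.bands:
            c = self.coupling.get(b.name, 0.0)
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"coupling for {b.name} must be in [0, 1], got {c}")
        if not (0.0 <= self.mixing < 1.0):
            raise ValueError(f"mixing strength must be in [0, 1), got {self.mixing}")
        if not (0.0 < self.phase_offset_margin < 0.5):
            raise ValueError("phase_offset_margin must be in (0, 0.5)")


@dataclass(frozen=True)
class EffectSpec:
    """Multiplicative group x condition x band coupling modifiers.

    ``modifiers`` maps ``(group, condition, band_name)`` to a positive
    factor applied to that band's coupling knob; unlisted cells get 1.
    E.g. ``{("dyslexic", "task", "theta"): 0.8}`` programs a 20% theta
    coupling reduction for the dyslexic group during the task — the
    qualitative pattern the analysis is meant to detect.
    """

    modifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.modifiers.items():
            if v <= 0:
                raise ValueError(f"effect modifier for {key} must be > 0, got {v}")

    def modifier(self, group: str, condition: str, band: str) -> float:
        return float(self.modifiers.get((group, condition, band), 1.0))

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls()


def _narrowband_noise(rng: np.random.Generator, band: BandSpec, fs: float, n: int) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (FFT brick-wall)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band.lo) | (freqs >= band.hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, fs: float, n: int) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise (white noise shaped in the FFT domain)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * scale, n=n)
    return x / np.sqrt(np.mean(x**2))


def generate_recording(
    params: SimulationParams,
    subject_id: str = "sim",
    group: str = "typical",
    condition: str = "baseline",
    coupling_modifiers: dict | None = None,
    rng: np.random.Generator | None = None,
) -> EpochedRecording:
    """Simulate one subject x condition recording.

    ``coupling_modifiers`` (band name -> positive factor) rescale the
    per-band coupling knobs, clipped to [0, 1]. Identical parameters and
    seed give bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_samp = int(round(params.epoch_s * params.fs))
    total = params.n_epochs * n_samp
    n_ch = params.n_channels

    x = np.zeros((n_ch, total))
    for band in params.bands:
        amp = float(params.amplitudes.get(band.name, 0.0))
        c = float(params.coupling.get(band.name, 0.0))
        if coupling_modifiers:
            c = float(np.clip(c * coupling_modifiers.get(band.name, 1.0), 0.0, 1.0))
        if amp == 0.0:
            continue
        shared = hilbert(_narrowband_noise(rng, band, params.fs, total))
        lo, hi = params.phase_offset_margin * np.pi, (1 - params.phase_offset_margin) * np.pi
        delta = rng.uniform(lo, hi, size=n_ch) * rng.choice([-1.0, 1.0], size=n_ch)
        locked = np.cos(delta)[:, None] * shared.real - np.sin(delta)[:, None] * shared.imag
        indep = np.stack(
            [_narrowband_noise(rng, band, params.fs, total) for _ in range(n_ch)]
        )
        x += amp * (np.sqrt(c) * locked + np.sqrt(1.0 - c) * indep)
    if params.noise_amplitude > 0:
        x += params.noise_amplitude * np.stack(
            [_pink_noise(rng, params.fs, total) for _ in range(n_ch)]
        )

    v = params.mixing
    if v > 0:
        x = (1.0 - v) * x + v * x.mean(axis=0, keepdims=True)

    epochs = x.reshape(n_ch, params.n_epochs, n_samp).transpose(1, 0, 2)
    return EpochedRecording(
        subject_id=subject_id,
        group=group,
        condition=condition,
        fs=params.fs,
        channels=tuple(f"ch{i:02d}" for i in range(n_ch)),
        epochs=epochs,
    )


def generate_study(
    n_per_group: dict | tuple = (31, 24),
    base: SimulationParams | None = None,
    effects: EffectSpec | None = None,
    seed: int = 0,
) -> StudyDesign:
    """Simulate a full two-group, two-condition study.

    ``n_per_group`` is ``(n_typical, n_dyslexic)`` or a dict; the default
    mirrors the emulated study's 31 typical readers and 24 dyslexics. Each
    subject gets a multiplicative coupling jitter shared across conditions
    (between-subject variability) plus a smaller independent per-condition
    jitter; amplitudes get log-normal jitter. Programmed effects multiply
    the coupling knob per group x condition x band.

    Randomness splits deterministically: child seed j of ``SeedSequence
    (seed)`` drives subject j's parameters and both its recordings, so any
    subject is reproducible in isolation.
    """
    if base is None:
        base = SimulationParams()
    if effects is None:
        effects = EffectSpec.null()
    if isinstance(n_per_group, tuple):
        n_per_group = {"typical": n_per_group[0], "dyslexic": n_per_group[1]}
    if any(n < 2 for n in n_per_group.values()):
        raise ValueError("need at least 2 subjects per group")

    design = StudyDesign()
    roster = [
        (f"{group[:3]}{i + 1:02d}", group)
        for group in ("typical", "dyslexic")
        for i in range(n_per_group[group])
    ]
    children = np.random.SeedSequence(seed).spawn(len(roster))
    for (sid, group), child in zip(roster, children):
        design.subjects.append((sid, group))
        rng = np.random.default_rng(child)
        subj_coupling_jit = rng.normal(0.0, base.subject_coupling_sd)
        amp_jit = {
            name: float(a * np.exp(rng.normal(0.0, base.amplitude_jitter_sd)))
            for name, a in base.amplitudes.items()
        }
        for condition in CONDITIONS:
            cond_jit = rng.normal(0.0, base.condition_coupling_sd)
            coupling = {
                b.name: float(
                    np.clip(
                        (base.coupling.get(b.name, 0.0) + subj_coupling_jit + cond_jit)
                        * effects.modifier(group, condition, b.name),
                        0.0,
                        1.0,
                    )
                )
                for b in base.bands
            }
            params = replace(base, coupling=coupling, amplitudes=amp_jit)
            design.recordings[(sid, condition)] = generate_recording(
                params, subject_id=sid, group=group, condition=condition, rng=rng
            )
    return design


def generate_learning_curves(
    n_subjects: int,
    bins: int = 4,
    asymptote: float = 0.9,
    rate: float = 0.8,
    noise: float = 0.05,
    seed: int = 0,
    start: float = 0.5,
) -> np.ndarray:
    """Per-subject task accuracy over time-on-task bins.

    Expected accuracy rises from ``start`` (chance) toward ``asymptote``
    as ``asymptote - (asymptote - start) * exp(-rate * (bin - 1))``, with
    additive Gaussian noise per subject x bin. ``rate = 0`` gives flat
    curves; ``noise = 0`` the exact deterministic curve. Returns an
    ``(n_subjects, bins)`` array for the repeated-measures ANOVA.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    rng = np.random.default_rng(seed)
    b = np.arange(1, bins + 1, dtype=float)
    curve = asymptote - (asymptote - start) * np.exp(-rate * (b - 1))
    return curve[None, :] + rng.normal(0.0, noise, size=(n_subjects, bins))


def write_study(design: StudyDesign, outdir: str | Path, fs: float | None = None) -> Path:
    """Write a study as ASCII epoch files plus a ``study.yaml`` config.

    Returns the path of the written config, consumable by
    :func:`eegmst.io.load_study`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sid, group in design.subjects:
        entry: dict = {"id": sid, "group": group}
        for condition in CONDITIONS:
            rec = design.recordings.get((sid, condition))
            if rec is None:
                continue
            fname = f"{sid}_{condition}.txt"
            write_ascii_epochs(rec, outdir / fname)
            entry[condition] = fname
            fs = rec.fs
        entries.append(entry)
    cfg = {"fs": float(fs if fs is not None else 1024.0), "subjects": entries}
    cfg_path = outdir / "study.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return cfg_path
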