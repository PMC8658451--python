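"""Reading and writing epoched EEG as plain-text ASCII, plus study configs.

ASCII dialect (one file per subject x condition):

* a header line ``# channels: <tab-separated labels>``
* for each epoch, a separator line ``# epoch k`` (k counts from 0) followed
  by one row per sample with one tab-separated column per channel (µV).

The dialect is self-describing and round-trips losslessly at the written
precision. EDF/BDF ingestion is available when :mod:`mne` is installed, but
the ASCII path is the contract the rest of the pipeline is tested against.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import CONDITIONS, GROUPS, EpochedRecording, StudyDesign

__all__ = [
    "AsciiFormatError",
    "StudyConfigError",
    "write_ascii_epochs",
    "read_ascii_epochs",
    "load_study",
    "read_edf",
]

#: Decimal digits written per sample; read(write(x)) is exact at this precision.
ASCII_PRECISION = 6


class AsciiFormatError(ValueError):
    """Malformed ASCII epoch file (ragged rows, non-numeric cells, ...)."""


class StudyConfigError(ValueError):
    """Invalid study configuration."""


def write_ascii_epochs(rec: EpochedRecording, path: str | os.PathLike) -> None:
    """Write an :class:`EpochedRecording` in the ASCII epoch dialect."""
    path = Path(path)
    fmt = f"%.{ASCII_PRECISION}f"
    with open(path, "w") as fh:
        fh.write("# channels: " + "\t".join(rec.channels) + "\n")
        for k in range(rec.n_epochs):
            fh.write(f"# epoch {k}\n")
            np.savetxt(fh, rec.epochs[k].T, fmt=fmt, delimiter="\t")


def read_ascii_epochs(
    path: str | os.PathLike,
    fs: float,
    channel_labels: Sequence[str] | None = None,
    subject_id: str = "",
    group: str = "typical",
    condition: str = "baseline",
) -> EpochedRecording:
    """Read an ASCII epoch file into an :class:`EpochedRecording`.

    Parameters
    ----------
    path
        File in the dialect written by :func:`write_ascii_epochs`.
    fs
        Sampling rate in Hz (the ASCII format does not carry it).
    channel_labels
        Overrides the labels in the file header; required if the file has
        no ``# channels:`` header.

    Raises
    ------
    AsciiFormatError
        On ragged rows (with the offending line number), non-numeric cells,
        or inconsistent epoch shapes.
    """
    path = Path(path)
    header_labels: list[str] | None = None
    epochs: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    n_cols: int | None = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("channels:"):
                    header_labels = body.split(":", 1)[1].split("\t")
                    header_labels = [c.strip() for c in header_labels if c.strip()]
                elif body.lower().startswith("epoch"):
                    current = []
                    epochs.append(current)
                continue
            cells = line.split("\t") if "\t" in line else line.split()
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                raise AsciiFormatError(
                    f"{path.name}:{lineno}: non-numeric cell ({exc})"
                ) from None
            if n_cols is None:
                n_cols = len(row)
            elif len(row) != n_cols:
                raise AsciiFormatError(
                    f"{path.name}:{lineno}: ragged row with {len(row)} values, "
                    f"expected {n_cols}"
                )
            if current is None:  # data before any "# epoch" marker: one epoch
                current = []
                epochs.append(current)
            current.append(row)

    if not epochs or all(len(e) == 0 for e in epochs):
        raise AsciiFormatError(f"{path.name}: no data rows")
    lengths = {len(e) for e in epochs}
    if len(lengths) != 1:
        raise AsciiFormatError(
            f"{path.name}: epochs have inconsistent sample counts {sorted(lengths)}"
        )

    data = np.asarray(epochs, dtype=float).transpose(0, 2, 1)  # epoch, ch, sample
    labels = list(channel_labels) if channel_labels is not None else header_labels
    if labels is None:
        labels = [f"ch{i:02d}" for i in range(data.shape[1])]
    if len(labels) != data.shape[1]:
        raise AsciiFormatError(
            f"{path.name}: {data.shape[1]} data columns but {len(labels)} "
            "channel labels"
        )
    return EpochedRecording(
        subject_id=subject_id,
        group=group,
        condition=condition,
        fs=fs,
        channels=tuple(labels),
        epochs=data,
    )


def load_study(config: str | os.PathLike | dict) -> StudyDesign:
    """Build a :class:`StudyDesign` from a YAML/JSON config file or dict.

    Expected layout::

        fs: 1024
        subjects:
          - id: s01
            group: typical
            baseline: s01_baseline.txt
            task: s01_task.txt
          ...

    Relative paths resolve against the config file's directory. A missing
    or unreadable file flags that subject incomplete instead of aborting
    the whole study.
    """
    base = Path(".")
    if not isinstance(config, dict):
        cfg_path = Path(config)
        base = cfg_path.parent
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise StudyConfigError("study config must be a mapping")
    subjects_cfg = config.get("subjects") or []
    if not subjects_cfg:
        raise StudyConfigError("study config lists no subjects")
    fs = float(config.get("fs", 1024.0))

    design = StudyDesign()
    for entry in subjects_cfg:
        sid = str(entry["id"])
        group = str(entry["group"]).lower()
        if group not in GROUPS:
            raise StudyConfigError(
                f"subject {sid!r}: unknown group {group!r}; expected one of {GROUPS}"
            )
        design.subjects.append((sid, group))
        for condition in CONDITIONS:
            if condition not in entry:
                design.incomplete[sid] = f"no {condition} file listed"
                continue
            fpath = base / entry[condition]
            if not fpath.exists():
                design.incomplete[sid] = f"missing file {fpath}"
                continue
            try:
                rec = read_ascii_epochs(
                    fpath, fs=fs, subject_id=sid, group=group, condition=condition
                )
            except AsciiFormatError as exc:
                design.incomplete[sid] = f"unreadable {condition} file: {exc}"
                continue
            design.recordings[(sid, condition)] = rec
    return design


def read_edf(
    path: str | os.PathLike,
    subject_id: str = "",
    group: str = "typical",
    condition: str = "baseline",
) -> EpochedRecording:
    """Read a continuous EDF/BDF file as a single-epoch recording (needs mne).

    The returned recording holds one epoch spanning the whole file; use
    :func:`eegmst.preprocess.segment` to cut it into analysis epochs.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("EDF/BDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EpochedRecording(
        subject_id=subject_id,
        group=group,
        condition=condition,
        fs=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        epochs=data[np.newaxis, :, :],
    )
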