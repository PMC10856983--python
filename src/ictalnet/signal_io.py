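"""Reading and writing single-channel EEG records.

The on-disk input dialect is the University of Bonn one: plain ASCII text,
one sample value per line (microvolts), no header, typically 100 files per
set and 4096-4097 samples per file at 173.61 Hz.  Because the files carry
no metadata, the class label and sampling rate are always supplied by the
caller.

Labelled datasets are persisted in a single portable HDF5 container holding
one array per record plus a metadata table (id, label, fs, group_id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

#: sampling rate of the Bonn recordings, in Hz
BONN_FS = 173.61

LABELS = ("ictal", "interictal", "unlabeled")

#: sentinel used when a record's sampling rate is not specified
FS_UNSPECIFIED = "unspecified"

_CONTAINER_FORMAT = "ictalnet-dataset"
_CONTAINER_VERSION = 1


class BonnFormatError(ValueError):
    """A Bonn ASCII file violated the one-number-per-line format."""


@dataclass
class EEGRecord:
    """One labelled single-channel EEG signal.

    Parameters
    ----------
    record_id : str
        Short identifier, usually derived from the source file name.
    samples : ndarray
        The signal samples in microvolts, in recording order.
    fs : float or "unspecified"
        Sampling rate in Hz, or the sentinel ``"unspecified"`` when the
        scalograms are to be computed in normalized frequency.
    label : {"ictal", "interictal", "unlabeled"}
    group_id : str, optional
        Subject/group identifier for grouped (LOSO) splits.
    """

    record_id: str
    samples: np.ndarray
    fs: float | str = FS_UNSPECIFIED
    label: str = "unlabeled"
    group_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.fs != FS_UNSPECIFIED:
            self.fs = float(self.fs)
            if not math.isfinite(self.fs) or self.fs <= 0:
                raise ValueError("fs must be strictly positive when specified")

    def __len__(self) -> int:
        return int(self.samples.size)


def read_bonn_file(
    path: str | Path,
    label: str = "unlabeled",
    fs: float | str = BONN_FS,
    group_id: str | None = None,
) -> EEGRecord:
    """Read one Bonn ASCII file (one numeric sample per line).

    Blank lines (typically trailing) are tolerated; any other non-numeric
    line raises :class:`BonnFormatError` naming the offending line number.
    """
    path = Path(path)
    samples: list[float] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                samples.append(float(text))
            except ValueError:
                raise BonnFormatError(
                    f"{path}: line {lineno}: not a number: {text!r}"
                ) from None
    if not samples:
        raise BonnFormatError(f"{path}: file contains no samples")
    return EEGRecord(
        record_id=path.stem, samples=np.array(samples), fs=fs, label=label,
        group_id=group_id,
    )


def read_bonn_set(
    directory: str | Path,
    label: str = "unlabeled",
    fs: float | str = BONN_FS,
    pattern: str = "*.[tT][xX][tT]",
) -> list[EEGRecord]:
    """Read every matching text file in `directory`, lexicographic order."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    files = sorted(directory.glob(pattern), key=lambda p: p.name)
    if not files:
        raise FileNotFoundError(f"no files matching {pattern!r} in {directory}")
    return [read_bonn_file(f, label=label, fs=fs) for f in files]


def write_dataset(records: Sequence[EEGRecord], path: str | Path) -> None:
    """Write records to a single HDF5 container (samples + metadata)."""
    if not records:
        raise ValueError("cannot write an empty dataset")
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("record_ids must be unique within a dataset")
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _CONTAINER_FORMAT
        f.attrs["version"] = _CONTAINER_VERSION
        f.attrs["order"] = ids
        grp = f.create_group("records")
        for r in records:
            d = grp.create_dataset(r.record_id, data=r.samples)
            d.attrs["label"] = r.label
            d.attrs["fs"] = -1.0 if r.fs == FS_UNSPECIFIED else float(r.fs)
            d.attrs["group_id"] = "" if r.group_id is None else r.group_id


def read_dataset(path: str | Path) -> list[EEGRecord]:
    """Read a container written by :func:`write_dataset`; order preserved."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != _CONTAINER_FORMAT:
            raise ValueError(f"{path}: not an ictalnet dataset container")
        if int(f.attrs.get("version", -1)) != _CONTAINER_VERSION:
            raise ValueError(
                f"{path}: unsupported container version {f.attrs.get('version')!r}"
            )
        out = []
        for rid in f.attrs["order"]:
            d = f["records"][rid]
            fs_raw = float(d.attrs["fs"])
            gid = str(d.attrs["group_id"]) or None
            out.append(
                EEGRecord(
                    record_id=str(rid),
                    samples=d[()],
                    fs=FS_UNSPECIFIED if fs_raw < 0 else fs_raw,
                    label=str(d.attrs["label"]),
                    group_id=gid,
                )
            )
        return out
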