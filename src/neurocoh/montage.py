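"""EEG data model: montages, recordings, sensorimotor clusters and frequency bands.

The package works on multichannel scalp EEG stored as a real matrix
(channels x samples, microvolts) together with a channel montage based on
the extended international 10-20 layout.  Two on-disk dialects are
supported: EDF (read-only, via :mod:`mne` when installed) and a plain-text
"matrix + header" dialect — a delimited numeric file with channels as rows
plus a JSON sidecar carrying the sampling rate, channel labels and unit.
The text dialect is the native round-trip format and is what the synthetic
cohort generator writes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ChannelMontage",
    "Recording",
    "ClusterPair",
    "BandSet",
    "DEFAULT_64_LABELS",
    "LEFT_SENSORIMOTOR",
    "RIGHT_SENSORIMOTOR",
    "default_montage",
    "default_cluster_pair",
    "default_bands",
    "cluster_indices",
    "load_recording",
    "save_recording",
]

#: 64-channel extended 10-20 cap layout (TMS-compatible 64-electrode caps).
DEFAULT_64_LABELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "M1", "T7", "C3", "Cz",
    "C4", "T8", "M2", "CP5", "CP1", "CP2", "CP6", "P7",
    "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FC3", "FCz", "FC4", "C5", "C1", "C2", "C6", "CP3",
    "CPz", "CP4", "P5", "P1", "P2", "P6", "PO5", "PO3",
    "PO4", "PO6", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8",
)

#: Electrode clusters around C3/C4 overlying left / right sensorimotor cortex.
LEFT_SENSORIMOTOR: frozenset[str] = frozenset(
    {"C1", "C3", "C5", "CP1", "CP3", "CP5", "FC1", "FC3", "FC5"}
)
RIGHT_SENSORIMOTOR: frozenset[str] = frozenset(
    {"C2", "C4", "C6", "CP2", "CP4", "CP6", "FC2", "FC4", "FC6"}
)


def _norm(label: str) -> str:
    """Normalized form used for label comparison: trimmed, case-folded."""
    return label.strip().casefold()


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered set of channel labels.

    Labels are compared case-insensitively and with surrounding whitespace
    ignored ("CPZ" matches "CPz"), because EDF exports are inconsistent in
    their casing.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(l).strip() for l in self.labels))
        normed = [_norm(l) for l in self.labels]
        if len(set(normed)) != len(normed):
            dupes = sorted({l for l in normed if normed.count(l) > 1})
            raise ValueError(f"duplicate channel labels (case-insensitive): {dupes}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return isinstance(label, str) and _norm(label) in self._index_map()

    def _index_map(self) -> dict[str, int]:
        return {_norm(l): i for i, l in enumerate(self.labels)}

    def index(self, label: str) -> int:
        """Index of ``label`` (case-insensitive); raises KeyError if absent."""
        try:
            return self._index_map()[_norm(label)]
        except KeyError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels: Iterable[str]) -> list[int]:
        return [self.index(l) for l in labels]


def default_montage() -> ChannelMontage:
    """The 64-channel extended 10-20 montage."""
    return ChannelMontage(DEFAULT_64_LABELS)


@dataclass
class Recording:
    """One subject/session of multichannel EEG.

    Parameters
    ----------
    data
        Real matrix, shape ``(n_channels, n_samples)``, amplitudes in μV.
    fs
        Sampling rate in Hz.
    montage
        Channel montage; ``montage.n_channels`` must equal ``data.shape[0]``.
    subject_id, timepoint, group
        Optional study metadata (``timepoint`` in {"pre", "post"},
        ``group`` in {"active", "sham"} when used in a cohort context).
    """

    data: np.ndarray
    fs: float
    montage: ChannelMontage
    subject_id: str = ""
    timepoint: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


@dataclass(frozen=True)
class ClusterPair:
    """Homologous left/right electrode clusters (default: sensorimotor)."""

    left: frozenset[str] = LEFT_SENSORIMOTOR
    right: frozenset[str] = RIGHT_SENSORIMOTOR

    def __post_init__(self) -> None:
        object.__setattr__(self, "left", frozenset(self.left))
        object.__setattr__(self, "right", frozenset(self.right))
        overlap = {_norm(l) for l in self.left} & {_norm(r) for r in self.right}
        if overlap:
            raise ValueError(f"left/right clusters overlap: {sorted(overlap)}")


def default_cluster_pair() -> ClusterPair:
    return ClusterPair()


@dataclass(frozen=True)
class BandSet:
    """Named frequency bands, ``name -> (f_lo, f_hi)`` in Hz.

    Band edges are half-open ``[f_lo, f_hi)`` throughout the package, so a
    shared edge (e.g. 4 Hz between delta and theta) is counted once.
    """

    bands: tuple[tuple[str, tuple[float, float]], ...] = (
        ("delta", (1.0, 4.0)),
        ("theta", (4.0, 8.0)),
        ("alpha", (8.0, 13.0)),
        ("beta", (13.0, 30.0)),
    )

    def __post_init__(self) -> None:
        if isinstance(self.bands, Mapping):
            object.__setattr__(
                self, "bands", tuple((k, (float(v[0]), float(v[1]))) for k, v in self.bands.items())
            )
        else:
            object.__setattr__(
                self,
                "bands",
                tuple((str(k), (float(v[0]), float(v[1]))) for k, v in self.bands),
            )
        intervals = []
        for name, (lo, hi) in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name!r}: f_lo must be < f_hi")
            intervals.append((lo, hi, name))
        intervals.sort()
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(intervals, intervals[1:]):
            if lo2 < hi1:
                raise ValueError(f"bands {n1!r} and {n2!r} overlap in their interiors")

    def items(self) -> tuple[tuple[str, tuple[float, float]], ...]:
        return self.bands

    def names(self) -> list[str]:
        return [name for name, _ in self.bands]

    def __getitem__(self, name: str) -> tuple[float, float]:
        for k, v in self.bands:
            if k == name:
                return v
        raise KeyError(name)

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)


def default_bands() -> BandSet:
    """Delta 1-4, theta 4-8, alpha 8-13, beta 13-30 Hz."""
    return BandSet()


def cluster_indices(
    montage: ChannelMontage, pair: ClusterPair | None = None
) -> tuple[list[int], list[int]]:
    """Montage indices of the left and right cluster channels.

    Returned index lists follow montage order, so the selection is invariant
    to how the cluster sets are stored and to label casing.  Raises
    ``KeyError`` naming the first absent channel.
    """
    pair = pair or ClusterPair()
    left_norm = {_norm(l) for l in pair.left}
    right_norm = {_norm(r) for r in pair.right}
    for name in sorted(pair.left | pair.right):
        if name not in montage:
            raise KeyError(f"cluster channel {name!r} not in montage")
    left_idx = [i for i, l in enumerate(montage.labels) if _norm(l) in left_norm]
    right_idx = [i for i, l in enumerate(montage.labels) if _norm(l) in right_norm]
    return left_idx, right_idx


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording in the matrix+header dialect.

    ``<path>`` receives the tab-delimited sample matrix (channels as rows);
    ``<path>.json`` receives ``{fs, labels, unit, subject_id, timepoint,
    group}``.  Returns the matrix path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.10g")
    header = {
        "fs": rec.fs,
        "labels": list(rec.montage.labels),
        "unit": "uV",
        "subject_id": rec.subject_id,
        "timepoint": rec.timepoint,
        "group": rec.group,
    }
    _sidecar_path(path).write_text(json.dumps(header, indent=1))
    return path


def _load_matrix(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar header {sidecar}")
    header = json.loads(sidecar.read_text())
    labels = header.get("labels")
    if not labels:
        raise ValueError(f"{sidecar}: header has no channel labels")
    try:
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric payload ({exc})") from exc
    unit = str(header.get("unit", "uV")).lower()
    scale = {"uv": 1.0, "µv": 1.0, "μv": 1.0, "mv": 1e3, "v": 1e6}.get(unit)
    if scale is None:
        raise ValueError(f"{sidecar}: unknown unit {header.get('unit')!r}")
    return Recording(
        data=data * scale,
        fs=float(header["fs"]),
        montage=ChannelMontage(tuple(labels)),
        subject_id=str(header.get("subject_id", "")),
        timepoint=str(header.get("timepoint", "")),
        group=str(header.get("group", "")),
    )


def _load_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF requires the 'mne' package (install neurocoh[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    labels = tuple(raw.ch_names)
    return Recording(data=data, fs=float(raw.info["sfreq"]), montage=ChannelMontage(labels))


def load_recording(
    path: str | Path,
    fmt: str | None = None,
    require_channels: Iterable[str] | None = None,
) -> Recording:
    """Load a recording from EDF or the matrix+header dialect.

    ``fmt`` is inferred from the extension when omitted (".edf" vs anything
    else).  When ``require_channels`` is given, a hard error lists every
    channel absent from the loaded montage.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if fmt not in {"edf", "matrix"}:
        raise ValueError(f"unknown format {fmt!r}")
    rec = _load_edf(path) if fmt == "edf" else _load_matrix(path)
    if require_channels is not None:
        missing = sorted(c for c in require_channels if c not in rec.montage)
        if missing:
            raise ValueError(f"{path}: required channels absent: {missing}")
    return rec
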