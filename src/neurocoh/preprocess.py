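"""Resting-state EEG preprocessing chain.

The fixed stage order is: resample -> band-pass -> epoch -> (optional) ICA
artifact removal -> amplitude-based epoch rejection -> common-average
re-reference.  Defaults reproduce a standard clinical resting-state
workflow: downsample to 1000 Hz, 0.1-40 Hz zero-phase band-pass,
non-overlapping 2000 ms epochs, rejection of epochs exceeding 100 μV, and
average reference over all scalp electrodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal, stats

from .montage import ChannelMontage, Recording

__all__ = [
    "EpochSet",
    "PreprocessConfig",
    "resample",
    "bandpass",
    "epoch",
    "reject_epochs",
    "average_reference",
    "ica_clean",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Cleaned, epoched EEG ready for spectral estimation.

    ``epochs`` has shape ``(n_epochs, n_channels, samples_per_epoch)`` in μV.
    ``rejected_count`` accumulates across rejection passes.
    """

    epochs: np.ndarray
    fs: float
    epoch_ms: float
    montage: ChannelMontage
    rejected_count: int = 0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x samples)")
        expected = int(round(self.fs * self.epoch_ms / 1000.0))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"samples per epoch {self.epochs.shape[2]} != fs*epoch_ms/1000 = {expected}"
            )
        if self.epochs.shape[1] != self.montage.n_channels:
            raise ValueError("channel dimension does not match montage")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]


def resample(rec: Recording, fs_target: float) -> Recording:
    """Polyphase rational resampling with anti-alias low-pass.

    The up/down ratio is the exact rational ``fs_target/fs`` (e.g. 2048 ->
    1000 Hz uses 125/256), so long recordings do not drift.  Output length is
    ``ceil(n * fs_target / fs)``.
    """
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    if fs_target > rec.fs:
        raise ValueError("fs_target must not exceed the recording rate")
    if fs_target == rec.fs:
        return rec.copy_with(data=rec.data.copy())
    ratio = Fraction(fs_target / rec.fs).limit_denominator(10000)
    out = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return rec.copy_with(data=out, fs=float(fs_target))


from functools import lru_cache


@lru_cache(maxsize=64)
def _bandpass_sos(f_lo: float, f_hi: float, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(f"invalid band ({f_lo}, {f_hi}) for fs={fs}")
    return signal.butter(order, [f_lo / nyq, f_hi / nyq], btype="bandpass", output="sos")


def bandpass(rec: Recording, f_lo: float = 0.1, f_hi: float = 40.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward, order doubled)."""
    sos = _bandpass_sos(f_lo, f_hi, rec.fs, order)
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=out)


def epoch(rec: Recording, epoch_ms: float = 2000.0) -> EpochSet:
    """Segment into consecutive non-overlapping epochs; remainder dropped."""
    if epoch_ms <= 0:
        raise ValueError("epoch_ms must be positive")
    spe = int(round(rec.fs * epoch_ms / 1000.0))
    n_ep = rec.n_samples // spe
    if n_ep < 1:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{epoch_ms} ms epoch ({spe} samples)"
        )
    trimmed = rec.data[:, : n_ep * spe]
    eps = trimmed.reshape(rec.n_channels, n_ep, spe).transpose(1, 0, 2)
    return EpochSet(epochs=eps.copy(), fs=rec.fs, epoch_ms=epoch_ms, montage=rec.montage)


def reject_epochs(es: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Drop epochs whose peak absolute amplitude exceeds ``threshold_uv``.

    The rule is strictly greater-than: an epoch whose maximum equals the
    threshold is kept.  Raises if nothing survives.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    peaks = np.max(np.abs(es.epochs), axis=(1, 2))
    keep = peaks <= threshold_uv
    n_bad = int(np.sum(~keep))
    if not np.any(keep):
        raise ValueError(
            "all epochs exceed the amplitude threshold; inspect the recording "
            "before lowering the threshold"
        )
    if n_bad:
        log.info("rejected %d/%d epochs above %.1f uV", n_bad, es.n_epochs, threshold_uv)
    return replace(es, epochs=es.epochs[keep], rejected_count=es.rejected_count + n_bad)


def average_reference(es: EpochSet) -> EpochSet:
    """Re-reference to the common average of every scalp electrode.

    After the transform the per-sample mean across channels is zero to
    numeric precision.  Idempotent.
    """
    if es.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    mean = es.epochs.mean(axis=1, keepdims=True)
    return replace(es, epochs=es.epochs - mean)


def _component_flags(sources: np.ndarray, fs: float) -> np.ndarray:
    """Automatic artifact flags for ICA sources (components x samples).

    A component is flagged when its sample kurtosis is extreme (transients,
    blinks) or when its spectrum is dominated by broadband high-frequency
    power (muscle): power(20-40 Hz) / power(1-10 Hz) > 2.
    """
    flags = np.zeros(sources.shape[0], dtype=bool)
    kurt = stats.kurtosis(sources, axis=1, fisher=True)
    flags |= np.abs(kurt) > 5.0
    freqs, psd = signal.welch(sources, fs=fs, nperseg=min(sources.shape[1], int(fs)), axis=1)
    lo = (freqs >= 1.0) & (freqs < 10.0)
    hi = (freqs >= 20.0) & (freqs < 40.0)
    if lo.any() and hi.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = psd[:, hi].mean(axis=1) / psd[:, lo].mean(axis=1)
        flags |= np.nan_to_num(ratio) > 2.0
    return flags


def ica_clean(es: EpochSet, enabled: bool = True, seed: int = 0) -> EpochSet:
    """Best-effort ICA artifact removal with automatic component flagging.

    Epochs are concatenated, decomposed with FastICA (seeded, hence
    deterministic), components flagged by :func:`_component_flags` are
    zeroed, and the data are reconstructed.  Skipped with a warning when
    disabled, when the data are too short for a stable decomposition
    (< 20 x n_channels samples), or when the decomposition fails: this
    stage never raises.
    """
    if not enabled:
        return es
    n_ch = es.n_channels
    cont = es.epochs.transpose(1, 0, 2).reshape(n_ch, -1)
    if cont.shape[1] < 20 * n_ch:
        warnings.warn("too few samples for ICA; skipping artifact removal")
        return es
    try:
        from sklearn.decomposition import FastICA

        ica = FastICA(n_components=n_ch, random_state=int(seed), max_iter=500, tol=1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sources = ica.fit_transform(cont.T).T
        flags = _component_flags(sources, es.fs)
        if not flags.any():
            return es
        sources = sources.copy()
        sources[flags] = 0.0
        cleaned = ((ica.mixing_ @ sources).T + ica.mean_).T
        out = cleaned.reshape(n_ch, es.n_epochs, es.samples_per_epoch).transpose(1, 0, 2)
        log.info("ICA removed %d/%d components", int(flags.sum()), n_ch)
        return replace(es, epochs=out)
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"ICA decomposition failed ({exc}); passing data through")
        return es


@dataclass(frozen=True)
class PreprocessConfig:
    """Stage parameters with resting-state defaults."""

    fs_target: float = 1000.0
    band: tuple[float, float] = (0.1, 40.0)
    epoch_ms: float = 2000.0
    reject_uv: float = 100.0
    ica_enabled: bool = False
    ica_seed: int = 0


def preprocess(rec: Recording, config: PreprocessConfig | None = None) -> EpochSet:
    """Run the full chain in the fixed order.

    resample -> bandpass -> epoch -> ica_clean -> reject_epochs ->
    average_reference.
    """
    cfg = config or PreprocessConfig()
    rec = resample(rec, min(cfg.fs_target, rec.fs))
    rec = bandpass(rec, *cfg.band)
    es = epoch(rec, cfg.epoch_ms)
    es = ica_clean(es, enabled=cfg.ica_enabled, seed=cfg.ica_seed)
    es = reject_epochs(es, cfg.reject_uv)
    es = average_reference(es)
    return es
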