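"""Absolute band power per channel and per sensorimotor cluster.

Power spectral densities use Welch's averaged modified periodogram:
windowed, overlapping segments are pooled across every retained epoch and
their periodograms averaged.  Defaults give 1 Hz resolution (1 s Hann
segments, 50% overlap), which places the band edges 1, 4, 8, 13 and 30 Hz
on exact frequency bins.  "Absolute power" for a band is the integral of
the one-sided density over the half-open bin range ``[f_lo, f_hi)``, in
μV².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .montage import BandSet, ClusterPair, cluster_indices
from .preprocess import EpochSet

__all__ = ["PsdResult", "BandPowerTable", "segment_rfft", "welch_psd", "band_power"]


def segment_rfft(
    epochs: np.ndarray,
    fs: float,
    seg_len: int,
    overlap: float = 0.5,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Windowed, detrended segment rFFTs pooled across epochs.

    Parameters
    ----------
    epochs
        ``(n_epochs, n_channels, samples_per_epoch)`` array.
    seg_len
        Segment length in samples (``<= samples_per_epoch``).
    overlap
        Fractional overlap between consecutive segments, in ``[0, 1)``.

    Returns
    -------
    freqs : one-sided frequency grid, Hz.
    X : complex array ``(n_segments_total, n_channels, n_freqs)``.
    scale : density normalization such that the one-sided PSD is
        ``scale * mean_k(|X_k|^2)`` with interior bins doubled.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be 3-D")
    n_ep, n_ch, spe = epochs.shape
    seg_len = int(seg_len)
    if seg_len < 2 or seg_len > spe:
        raise ValueError(f"seg_len must be in [2, {spe}]")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = max(1, int(round(seg_len * (1 - overlap))))
    starts = range(0, spe - seg_len + 1, step)
    n_per_epoch = len(list(starts))
    if n_ep * n_per_epoch < 2:
        raise ValueError("need at least 2 segments in total for Welch averaging")
    win = get_window(window, seg_len)
    segs = []
    for s in range(0, spe - seg_len + 1, step):
        seg = epochs[:, :, s : s + seg_len]
        seg = seg - seg.mean(axis=2, keepdims=True)
        segs.append(seg * win)
    stacked = np.concatenate(segs, axis=0)  # (n_ep * n_per_epoch, n_ch, seg_len)
    X = np.fft.rfft(stacked, axis=2)
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    scale = 1.0 / (fs * np.sum(win**2))
    return freqs, X, scale


def _one_sided(psd_two: np.ndarray, seg_len: int) -> np.ndarray:
    """Double interior bins of a one-sided raw spectrum in place."""
    out = psd_two.copy()
    if seg_len % 2 == 0:
        out[..., 1:-1] *= 2.0
    else:
        out[..., 1:] *= 2.0
    return out


@dataclass
class PsdResult:
    """One-sided Welch PSD, μV²/Hz, channels x frequencies."""

    freqs: np.ndarray
    psd: np.ndarray
    fs: float
    seg_len: int
    overlap: float
    window: str

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandPowerTable:
    """Absolute band power (μV²) per channel and per cluster side.

    ``per_channel`` columns: band, channel, power_uv2.
    ``per_cluster`` columns: band, side, power_uv2 (mean over members).
    """

    per_channel: pd.DataFrame
    per_cluster: pd.DataFrame | None = None


def welch_psd(
    es: EpochSet,
    seg_len: int | None = None,
    overlap: float = 0.5,
    window: str = "hann",
) -> PsdResult:
    """Welch PSD with segments pooled across all epochs.

    Density scaling satisfies Parseval: the integral of the PSD over
    ``[0, fs/2]`` approximates the signal variance.
    """
    seg_len = int(seg_len if seg_len is not None else round(es.fs))
    seg_len = min(seg_len, es.samples_per_epoch)
    freqs, X, scale = segment_rfft(es.epochs, es.fs, seg_len, overlap, window)
    raw = (np.abs(X) ** 2).mean(axis=0) * scale
    psd = _one_sided(raw, seg_len)
    return PsdResult(freqs=freqs, psd=psd, fs=es.fs, seg_len=seg_len,
                     overlap=overlap, window=window)


def band_bins(freqs: np.ndarray, f_lo: float, f_hi: float) -> np.ndarray:
    """Boolean mask of bins in the half-open band ``[f_lo, f_hi)``."""
    return (freqs >= f_lo) & (freqs < f_hi)


def band_power(
    psd: PsdResult,
    bands: BandSet | None = None,
    labels: list[str] | tuple[str, ...] | None = None,
    pair: ClusterPair | None = None,
    montage=None,
) -> BandPowerTable:
    """Integrate the PSD over each band; optionally append cluster means.

    The cluster value for a side is the arithmetic mean of its member
    channels' band powers (exactly, by construction).
    """
    bands = bands or BandSet()
    if labels is None:
        labels = [f"ch{i}" for i in range(psd.psd.shape[0])]
    rows = []
    for name, (lo, hi) in bands.items():
        if hi > psd.fs / 2 + 1e-9 or lo < 0:
            raise ValueError(f"band {name!r} outside [0, fs/2]")
        mask = band_bins(psd.freqs, lo, hi)
        if not mask.any():
            raise ValueError(f"band {name!r} contains no frequency bins")
        power = psd.psd[:, mask].sum(axis=1) * psd.df
        for ch, p in zip(labels, power):
            rows.append({"band": name, "channel": ch, "power_uv2": float(p)})
    per_channel = pd.DataFrame(rows)
    per_cluster = None
    if pair is not None and montage is not None:
        li, ri = cluster_indices(montage, pair)
        crows = []
        for name, _ in bands.items():
            sub = per_channel[per_channel["band"] == name].reset_index(drop=True)
            vals = sub["power_uv2"].to_numpy()
            crows.append({"band": name, "side": "left", "power_uv2": float(vals[li].mean())})
            crows.append({"band": name, "side": "right", "power_uv2": float(vals[ri].mean())})
        per_cluster = pd.DataFrame(crows)
    return BandPowerTable(per_channel=per_channel, per_cluster=per_cluster)
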