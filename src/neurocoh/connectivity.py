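"""Magnitude-squared coherence, Fisher z, and the interhemispheric summary.

Coherence between channels x and y is estimated with Welch's averaged
modified periodogram: segment-averaged auto- and cross-spectra give

    MSC(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f))  in [0, 1].

Band-level values are the mean of the coherence spectrum over the band's
half-open bin range; they are then variance-stabilized with the Fisher
transform z = atanh(sqrt(MSC)), treating sqrt(MSC) as a correlation
magnitude (a config switch selects atanh(MSC) instead for sensitivity
analysis).  The interhemispheric summary for a band is the arithmetic mean
of z over all left x right sensorimotor cluster pairs (9 x 9 = 81 with the
default clusters); within-hemisphere pairs are excluded.

With L averaged segments the MSC of two independent signals is biased
upward by approximately 1/L — a property the test suite exploits as a
calibration check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .montage import BandSet, ClusterPair, cluster_indices
from .preprocess import EpochSet
from .spectral import band_bins, segment_rfft

__all__ = [
    "ConnectivityMatrix",
    "msc_welch",
    "band_coherence",
    "fisher_z",
    "connectivity_matrix",
    "interhemispheric_mean",
]

log = logging.getLogger(__name__)

_CLIP = 1.0 - 1e-12


def fisher_z(msc, mode: str = "sqrt"):
    """Fisher variance-stabilizing transform of squared coherence.

    ``mode="sqrt"`` (default) applies z = atanh(sqrt(MSC)); ``mode="direct"``
    applies z = atanh(MSC).  Both are strictly increasing on [0, 1); values
    at or above 1 - 1e-12 are clipped (and the clipping logged) so identical
    signals do not map to infinity.
    """
    arr = np.asarray(msc, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1 + 1e-9):
        raise ValueError("squared coherence must lie in [0, 1]")
    clipped = np.minimum(arr, _CLIP)
    n_clip = int(np.sum(arr > _CLIP))
    if n_clip:
        log.info("fisher_z clipped %d value(s) at 1-1e-12", n_clip)
    if mode == "sqrt":
        z = np.arctanh(np.sqrt(clipped))
    elif mode == "direct":
        z = np.arctanh(clipped)
    else:
        raise ValueError(f"unknown fisher mode {mode!r}")
    return float(z) if np.isscalar(msc) else z


def _as_epochs(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("series must be 1-D or (n_epochs, n_samples)")
    return x


def msc_welch(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    seg_len: int | None = None,
    overlap: float = 0.5,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence spectrum between two epoch series.

    ``x`` and ``y`` are 1-D signals or ``(n_epochs, n_samples)`` arrays of
    matching shape.  Returns ``(freqs, msc)``.
    """
    x, y = _as_epochs(x), _as_epochs(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have matching shape")
    seg_len = int(seg_len if seg_len is not None else min(round(fs), x.shape[1]))
    stack = np.stack([x, y], axis=1)  # (n_ep, 2, n_samp)
    freqs, X, _ = segment_rfft(stack, fs, seg_len, overlap, window)
    sxx = (np.abs(X[:, 0, :]) ** 2).mean(axis=0)
    syy = (np.abs(X[:, 1, :]) ** 2).mean(axis=0)
    sxy = (X[:, 0, :] * np.conj(X[:, 1, :])).mean(axis=0)
    denom = sxx * syy
    if np.all(denom == 0):
        raise ValueError("zero-variance segment set: coherence undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = np.abs(sxy) ** 2 / denom
    msc = np.nan_to_num(msc, nan=0.0)
    return freqs, np.clip(msc, 0.0, 1.0)


def band_coherence(
    freqs: np.ndarray, cspec: np.ndarray, bands: BandSet | None = None
) -> dict[str, float]:
    """Mean of a coherence spectrum over each band's half-open bin range."""
    bands = bands or BandSet()
    out = {}
    for name, (lo, hi) in bands.items():
        mask = band_bins(np.asarray(freqs), lo, hi)
        if not mask.any():
            raise ValueError(f"band {name!r} contains no frequency bins")
        out[name] = float(np.mean(np.asarray(cspec)[..., mask], axis=-1))
    return out


@dataclass
class ConnectivityMatrix:
    """Symmetric all-pairs coherence for one band.

    ``msc`` is the band-mean squared coherence in [0, 1]; ``z`` its Fisher
    transform.  The diagonal is excluded by convention and stored as zero.
    """

    band: str
    labels: tuple[str, ...]
    msc: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        for m in (self.msc, self.z):
            if m.shape != (n, n):
                raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.msc, self.msc.T, atol=1e-12):
            raise ValueError("msc matrix must be symmetric")


def connectivity_matrix(
    es: EpochSet,
    bands: BandSet | None = None,
    seg_len: int | None = None,
    overlap: float = 0.5,
    window: str = "hann",
    fisher_mode: str = "sqrt",
    z_order: str = "average-then-transform",
) -> dict[str, ConnectivityMatrix]:
    """Per-band Fisher-z coherence between every pair of electrodes.

    All pairwise spectra are computed in one vectorized pass from pooled
    segment FFTs; the result is symmetric by construction and equals
    pairwise :func:`msc_welch` calls.  ``z_order`` selects whether the
    Fisher transform is applied to the band-averaged coherence (default)
    or per frequency bin before band averaging.
    """
    bands = bands or BandSet()
    if es.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if z_order not in {"average-then-transform", "transform-then-average"}:
        raise ValueError(f"unknown z_order {z_order!r}")
    seg_len = int(seg_len if seg_len is not None else min(round(es.fs), es.samples_per_epoch))
    freqs, X, _ = segment_rfft(es.epochs, es.fs, seg_len, overlap, window)
    # S[i, j, f] = mean_k X_k[i, f] conj(X_k[j, f])
    S = np.einsum("kif,kjf->ijf", X, np.conj(X)) / X.shape[0]
    auto = np.real(np.einsum("iif->if", S))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        msc_f = np.abs(S) ** 2 / denom
    msc_f = np.clip(np.nan_to_num(msc_f, nan=0.0), 0.0, 1.0)
    out: dict[str, ConnectivityMatrix] = {}
    labels = tuple(es.montage.labels)
    for name, (lo, hi) in bands.items():
        mask = band_bins(freqs, lo, hi)
        if not mask.any():
            raise ValueError(f"band {name!r} contains no frequency bins")
        if z_order == "average-then-transform":
            msc_b = msc_f[:, :, mask].mean(axis=2)
            z = fisher_z(msc_b, mode=fisher_mode)
        else:
            z = fisher_z(msc_f[:, :, mask], mode=fisher_mode).mean(axis=2)
            msc_b = msc_f[:, :, mask].mean(axis=2)
        msc_b = (msc_b + msc_b.T) / 2.0
        z = (z + z.T) / 2.0
        np.fill_diagonal(msc_b, 0.0)
        np.fill_diagonal(z, 0.0)
        out[name] = ConnectivityMatrix(band=name, labels=labels, msc=msc_b, z=z)
    return out


def interhemispheric_mean(
    cm: ConnectivityMatrix, pair: ClusterPair | None = None
) -> float:
    """Mean Fisher-z coherence over all left x right cluster electrode pairs.

    Within-hemisphere pairs do not contribute; with the default clusters the
    mean runs over exactly 81 entries.
    """
    from .montage import ChannelMontage

    pair = pair or ClusterPair()
    montage = ChannelMontage(cm.labels)
    li, ri = cluster_indices(montage, pair)
    block = cm.z[np.ix_(li, ri)]
    return float(block.mean())
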