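"""Synthetic multichannel EEG with known band-specific interhemispheric
coupling.

Signal model, per frequency band b with coupling strength kappa in [0, 1]:
a shared narrowband source ``s_b`` (band-pass-filtered unit-variance
Gaussian noise) is mixed into every channel of the left and right
sensorimotor clusters as

    x_ch = amp_b * ( sqrt(kappa_b) * s_b + sqrt(1 - kappa_b) * n_ch,b )

where the ``n_ch,b`` are independent narrowband noises produced by the
same filter, hence with exactly matched in-band spectra.  Channels outside
the clusters receive independent narrowband noise of the same amplitude.
All channels additionally receive 1/f (pink) background and white sensor
noise.  Under this matched-spectrum mixing the in-band squared coherence
between any left/right cluster pair is kappa^2 exactly (in expectation,
before any re-referencing and ignoring broadband leakage); with an
additional independent broadband power fraction rho in the band it is
attenuated to (kappa * (1 - rho))^2 — see :func:`expected_msc`.

A cohort generator layers study structure on top: per-subject baseline
couplings drawn once (so pre and post are correlated through the subject),
with an additive coupling shift applied to the active group's post-session
recordings only, and a ground-truth table for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import signal

from .montage import (
    BandSet,
    ChannelMontage,
    ClusterPair,
    Recording,
    cluster_indices,
    default_montage,
)

__all__ = [
    "SimulationConfig",
    "CohortSpec",
    "bandlimited_noise",
    "pink_noise",
    "simulate_recording",
    "simulate_cohort",
    "expected_msc",
]

#: Realistic eyes-closed resting EEG band amplitudes (RMS, μV).
DEFAULT_BAND_AMP_UV: dict[str, float] = {
    "delta": 12.0,
    "theta": 8.0,
    "alpha": 10.0,
    "beta": 5.0,
}


from functools import lru_cache


@lru_cache(maxsize=256)
def _band_sos(w_lo: float, w_hi: float) -> np.ndarray:
    return signal.butter(4, [w_lo, w_hi], btype="bandpass", output="sos")


def bandlimited_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    f_lo: float,
    f_hi: float,
    n_series: int | None = None,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [f_lo, f_hi] (zero phase).

    With ``n_series`` an ``(n_series, n)`` array of independent noises is
    returned (each row unit variance); channels are filtered in one batch.
    """
    nyq = fs / 2.0
    sos = _band_sos(f_lo / nyq, min(f_hi, nyq * 0.99) / nyq)
    shape = (n,) if n_series is None else (n_series, n)
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=x.ndim > 1)
    return np.divide(x, sd, out=x, where=sd > 0)


def pink_noise(rng: np.random.Generator, n: int, n_series: int | None = None) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping."""
    shape = (n,) if n_series is None else (n_series, n)
    white = rng.standard_normal(shape)
    X = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = 1.0
    X /= np.sqrt(f)
    X[..., 0] = 0.0  # no DC offset
    x = np.fft.irfft(X, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=x.ndim > 1)
    return np.divide(x, sd, out=x, where=sd > 0)


@dataclass
class SimulationConfig:
    """Single-recording generator parameters.

    ``kappa`` maps band name -> coupling in [0, 1]; bands absent from the
    map are uncoupled.  ``pink_uv`` and ``white_uv`` are the RMS amplitudes
    of the 1/f background and white sensor noise.  The seed fully
    determines the output.
    """

    montage: ChannelMontage = field(default_factory=default_montage)
    fs: float = 2048.0
    duration_s: float = 360.0
    bands: BandSet = field(default_factory=BandSet)
    kappa: Mapping[str, float] = field(default_factory=dict)
    band_amp_uv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_AMP_UV))
    pink_uv: float = 4.0
    white_uv: float = 2.0
    cluster_pair: ClusterPair = field(default_factory=ClusterPair)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, k in dict(self.kappa).items():
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"coupling for band {name!r} outside [0, 1]: {k}")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")


def simulate_recording(
    cfg: SimulationConfig,
    subject_id: str = "",
    timepoint: str = "",
    group: str = "",
) -> Recording:
    """Generate one multichannel recording under the shared-source model."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    n_ch = cfg.montage.n_channels
    data = np.zeros((n_ch, n))
    li, ri = cluster_indices(cfg.montage, cfg.cluster_pair)
    coupled = set(li) | set(ri)
    for name, (lo, hi) in cfg.bands.items():
        amp = float(cfg.band_amp_uv.get(name, 1.0))
        kappa = float(dict(cfg.kappa).get(name, 0.0))
        batch = bandlimited_noise(rng, n, cfg.fs, lo, hi, n_series=n_ch + 1)
        shared, private = batch[0], batch[1:]
        for ch in range(n_ch):
            if ch in coupled:
                data[ch] += amp * (np.sqrt(kappa) * shared + np.sqrt(1.0 - kappa) * private[ch])
            else:
                data[ch] += amp * private[ch]
    if cfg.pink_uv > 0:
        data += cfg.pink_uv * pink_noise(rng, n, n_series=n_ch)
    if cfg.white_uv > 0:
        data += cfg.white_uv * rng.standard_normal((n_ch, n))
    return Recording(
        data=data, fs=cfg.fs, montage=cfg.montage,
        subject_id=subject_id, timepoint=timepoint, group=group,
    )


def expected_msc(kappa: float, rho: float = 0.0) -> float:
    """Expected in-band squared coherence under the mixing model.

    With matched in-band spectra and no broadband background the squared
    coherence between two coupled channels is ``kappa**2``: the
    cross-spectrum is ``kappa * P``, each auto-spectrum is ``P``.  An
    independent broadband background contributing the fraction ``rho`` of
    each channel's total in-band power scales each auto-spectrum by
    ``1/(1 - rho)``, giving ``(kappa * (1 - rho))**2``.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must be in [0, 1]")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    return (kappa * (1.0 - rho)) ** 2


@dataclass
class CohortSpec:
    """Two-group, pre/post synthetic cohort.

    Per subject and band, a baseline coupling is drawn once from
    ``Normal(kappa_mean[band], kappa_sd)`` (clipped to [0.02, 0.95]); the
    active group's post recordings use baseline + ``delta_kappa[band]``.
    Defaults mirror the study design this package targets: 15 subjects per
    group, 64-channel montage, coupling shifts in the delta and theta
    bands.
    """

    n_per_group: int = 15
    montage: ChannelMontage = field(default_factory=default_montage)
    fs: float = 2048.0
    duration_s: float = 360.0
    bands: BandSet = field(default_factory=BandSet)
    kappa_mean: Mapping[str, float] = field(
        default_factory=lambda: {"delta": 0.45, "theta": 0.45, "alpha": 0.45, "beta": 0.45}
    )
    kappa_sd: float = 0.10
    delta_kappa: Mapping[str, float] = field(
        default_factory=lambda: {"delta": 0.25, "theta": 0.25}
    )
    band_amp_uv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_AMP_UV))
    pink_uv: float = 4.0
    white_uv: float = 2.0
    cluster_pair: ClusterPair = field(default_factory=ClusterPair)
    seed: int = 0

    def truth_table(self) -> pd.DataFrame:
        """Ground-truth couplings (and per-recording seeds), deterministic in seed."""
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0x5EED]))
        rows = []
        band_names = self.bands.names()
        for group in ("active", "sham"):
            for i in range(self.n_per_group):
                subject = f"{group[0].upper()}{i + 1:02d}"
                base = {
                    b: float(np.clip(
                        rng.normal(dict(self.kappa_mean).get(b, 0.0), self.kappa_sd),
                        0.02, 0.95))
                    for b in band_names
                }
                for timepoint in ("pre", "post"):
                    shift = dict(self.delta_kappa) if (group == "active" and timepoint == "post") else {}
                    rec_seed = int(rng.integers(0, 2**31 - 1))
                    for b in band_names:
                        kappa = float(np.clip(base[b] + shift.get(b, 0.0), 0.0, 0.95))
                        rows.append({
                            "subject": subject, "group": group, "timepoint": timepoint,
                            "band": b, "kappa": kappa, "rec_seed": rec_seed,
                        })
        return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, Iterator[Recording]]:
    """Ground-truth table plus a lazy iterator of the cohort's recordings.

    Recordings are yielded subject-major, pre before post, active group
    first; the same spec (same seed) reproduces byte-identical output.
    """
    truth = spec.truth_table()

    def _iter() -> Iterator[Recording]:
        keys = truth.drop_duplicates(["subject", "timepoint"])[
            ["subject", "group", "timepoint", "rec_seed"]]
        for row in keys.itertuples(index=False):
            sub = truth[(truth.subject == row.subject) & (truth.timepoint == row.timepoint)]
            kappa = dict(zip(sub.band, sub.kappa))
            cfg = SimulationConfig(
                montage=spec.montage, fs=spec.fs, duration_s=spec.duration_s,
                bands=spec.bands, kappa=kappa, band_amp_uv=spec.band_amp_uv,
                pink_uv=spec.pink_uv, white_uv=spec.white_uv,
                cluster_pair=spec.cluster_pair, seed=int(row.rec_seed),
            )
            yield simulate_recording(cfg, subject_id=row.subject,
                                     timepoint=row.timepoint, group=row.group)

    return truth, _iter()
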