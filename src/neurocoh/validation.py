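"""Reduced-scale validation protocols: estimator calibration and
whole-pipeline statistical validity.

These routines run the *full* analysis chain (synthetic cohort ->
preprocessing -> coherence -> network metrics -> mixed-model inference) at
deliberately small problem sizes so that repeated-simulation checks finish
quickly:

* coupling recovery — a two-channel recording per coupling value, 180
  two-second epochs, no background noise, so the estimated in-band squared
  coherence can be compared against the closed form kappa^2;
* type-I error / power — cohorts of 15 + 15 subjects on a 12-channel
  montage (coupling between C3 and C4 only, so the coupled channels stay a
  small minority and common-average referencing does not cancel the shared
  source), 250 Hz, 12 s per recording, delta and theta bands only.

Type-I error of the interaction test does not depend on recording length,
so the reduced duration changes nothing about that check; power does, and
the shipped effect size (coupling shift 0.25) is large enough to be seen
at this scale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .connectivity import band_coherence, msc_welch
from .group_stats import OutcomeTable, fit_group_time, posthoc_within_group
from .montage import BandSet, ChannelMontage, ClusterPair
from .pipeline import RunConfig, WelchParams, run_pipeline
from .preprocess import PreprocessConfig, epoch
from .simulate import CohortSpec, SimulationConfig, simulate_recording

__all__ = [
    "validation_montage",
    "validation_pair",
    "reduced_cohort_spec",
    "reduced_run_config",
    "msc_recovery",
    "interaction_pvalues",
    "null_rejection_rate",
    "effect_detection",
]

_VALIDATION_LABELS = ("Fp1", "Fp2", "F3", "F4", "Fz", "C3", "C4", "Cz",
                      "P3", "P4", "O1", "O2")
_VALIDATION_BANDS = BandSet((("delta", (1.0, 4.0)), ("theta", (4.0, 8.0))))


def validation_montage() -> ChannelMontage:
    """12-channel reduced 10-20 montage used by the validity simulations."""
    return ChannelMontage(_VALIDATION_LABELS)


def validation_pair() -> ClusterPair:
    """Single homologous electrode pair (C3 | C4)."""
    return ClusterPair(left=frozenset({"C3"}), right=frozenset({"C4"}))


def reduced_cohort_spec(seed: int, effect: float = 0.0) -> CohortSpec:
    """Reduced cohort: 15/group, 12 channels, 250 Hz, 12 s, delta+theta.

    ``effect`` is the coupling shift added to the active group's post
    recordings in both bands (0 gives a null cohort).
    """
    shift = {"delta": effect, "theta": effect} if effect else {}
    return CohortSpec(
        n_per_group=15,
        montage=validation_montage(),
        fs=250.0,
        duration_s=12.0,
        bands=_VALIDATION_BANDS,
        kappa_mean={"delta": 0.45, "theta": 0.45},
        kappa_sd=0.10,
        delta_kappa=shift,
        band_amp_uv={"delta": 12.0, "theta": 8.0},
        pink_uv=4.0,
        white_uv=2.0,
        cluster_pair=validation_pair(),
        seed=int(seed),
    )


def reduced_run_config(spec: CohortSpec) -> RunConfig:
    return RunConfig(
        simulate=spec,
        preprocess=PreprocessConfig(fs_target=spec.fs, band=(0.5, 40.0),
                                    epoch_ms=2000.0, reject_uv=100.0, ica_enabled=False),
        bands=spec.bands,
        cluster_pair=spec.cluster_pair,
        welch=WelchParams(),
        with_stats=False,  # validation fits only the contrasts it needs
        seed=spec.seed,
    )


def msc_recovery(
    seed: int,
    kappas=(0.2, 0.4, 0.6, 0.8),
    n_epochs: int = 180,
    band: str = "theta",
    fs: float = 250.0,
) -> pd.DataFrame:
    """Estimate in-band coherence of the shared-source generator per kappa.

    Two coupled channels, no 1/f or sensor noise, ``n_epochs`` two-second
    epochs.  Under the matched-spectrum mixing model the in-band squared
    coherence equals kappa^2.  Columns: kappa, msc, expected.
    """
    montage = ChannelMontage(("C3", "C4"))
    pair = validation_pair()
    bands = BandSet(((band, dict(BandSet().items())[band]),))
    rows = []
    rng = np.random.default_rng(seed)
    for kappa in kappas:
        cfg = SimulationConfig(
            montage=montage, fs=fs, duration_s=2.0 * n_epochs, bands=bands,
            kappa={band: float(kappa)}, band_amp_uv={band: 10.0},
            pink_uv=0.0, white_uv=0.0, cluster_pair=pair,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec = simulate_recording(cfg)
        es = epoch(rec, 2000.0)
        freqs, msc = msc_welch(es.epochs[:, 0, :], es.epochs[:, 1, :], fs)
        est = band_coherence(freqs, msc, bands)[band]
        rows.append({"kappa": float(kappa), "msc": est, "expected": float(kappa) ** 2})
    return pd.DataFrame(rows)


def interaction_pvalues(spec: CohortSpec, measure: str = "interhem_z") -> dict[str, dict]:
    """Run the full pipeline on one cohort; per band, the interaction P and
    the Tukey-adjusted within-group pre-vs-post P values."""
    result = run_pipeline(reduced_run_config(spec))
    outcomes = OutcomeTable(result["outcomes"])
    out: dict[str, dict] = {}
    for band in spec.bands.names():
        res = fit_group_time(outcomes, measure, band)
        post = posthoc_within_group(outcomes, measure, band, res)
        post_p = dict(zip(post["group"], post["p_tukey"]))
        out[band] = {
            "interaction_p": res.effects["group:timepoint"].p,
            "active_p": post_p.get("active", np.nan),
            "sham_p": post_p.get("sham", np.nan),
        }
    return out


def null_rejection_rate(
    n_reps: int = 200,
    seed: int = 0,
    band: str = "delta",
    measure: str = "interhem_z",
    alpha: float = 0.05,
) -> float:
    """Fraction of null cohorts whose Group x Timepoint interaction rejects."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        spec = reduced_cohort_spec(int(rng.integers(0, 2**31 - 1)), effect=0.0)
        pvals = interaction_pvalues(spec, measure=measure)
        hits += pvals[band]["interaction_p"] < alpha
    return hits / n_reps


def effect_detection(
    n_reps: int = 25,
    seed: int = 0,
    effect: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Detection behaviour with a real coupling shift in the active group.

    Per band: the fraction of cohorts where the interhemispheric-z
    interaction rejects, where the active within-group change is flagged,
    and where the sham within-group change is (spuriously) flagged.
    """
    rng = np.random.default_rng(seed)
    bands = _VALIDATION_BANDS.names()
    counts = {b: {"interaction": 0, "active": 0, "sham": 0} for b in bands}
    for _ in range(n_reps):
        spec = reduced_cohort_spec(int(rng.integers(0, 2**31 - 1)), effect=effect)
        pvals = interaction_pvalues(spec)
        for b in bands:
            counts[b]["interaction"] += pvals[b]["interaction_p"] < alpha
            counts[b]["active"] += pvals[b]["active_p"] < alpha
            counts[b]["sham"] += pvals[b]["sham_p"] < alpha
    rows = [
        {"band": b,
         "interaction_rate": counts[b]["interaction"] / n_reps,
         "active_posthoc_rate": counts[b]["active"] / n_reps,
         "sham_posthoc_rate": counts[b]["sham"] / n_reps}
        for b in bands
    ]
    return pd.DataFrame(rows)
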