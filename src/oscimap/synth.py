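"""Synthetic resting-state EEG cohorts with known spatio-oscillatory structure.

The generator emulates the statistical structure the downstream analysis
assumes: a 1/f ("pink") background per channel, cohort-specific band-limited
oscillations confined to named electrode sets, 60 Hz line noise, stereotyped
frontal blink transients, occasional bad channels, and a clinical table whose
scores are coupled by construction to the injected per-subject band gains.

Three cohorts are simulated, mirroring the clinical contrast the classifier
is asked to learn:

* ``HC`` — healthy controls, with strong occipitoparietal beta power;
* ``PD_OFF`` — Parkinson's disease off dopaminergic medication, with
  left-premotor/motor gamma (and weaker beta) power;
* ``PD_ON`` — the same patients on medication, with frontoparietal
  delta/theta power.

All randomness is driven by independent child streams of a single seed, so
that e.g. setting the blink rate to zero reproduces the blink-free recording
bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS_64, FRONTAL_BLINK_CHANNELS, ElectrodeLayout, standard_layout

COHORTS = ("HC", "PD_OFF", "PD_ON")

# Electrode sets used by the default cohort signatures (ground truth for the
# localization recovery experiments).
OCCIPITOPARIETAL = (
    "P9", "P7", "P10", "PO9", "PO7", "PO5", "PO3", "PO1", "POz",
    "PO2", "PO4", "PO6", "O1", "Oz", "O2",
)
LEFT_MOTOR = ("FC3", "FC1", "C3", "C1")
FRONTOPARIETAL = (
    "AF7", "AF8", "F7", "F5", "F6", "F8", "FC6", "FT8", "C4", "C6",
    "TP7", "CP5", "CP6", "TP8", "P9", "P7", "P5", "P6", "P8", "PO7", "PO8",
)


@dataclass(frozen=True)
class BandEffect:
    """A named, multiplicative band-power gain over an electrode set.

    ``gain`` scales the oscillatory power added on top of the background:
    an affected electrode's band power becomes ``(1 + gain)`` times the
    background band power.
    """

    name: str
    electrodes: tuple
    band: tuple  # (low Hz, high Hz)
    gain: float

    def __post_init__(self):
        lo, hi = self.band
        if not (1.0 <= lo < hi <= 100.0):
            raise ValueError(f"band must lie within [1, 100] Hz, got {self.band}")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")


@dataclass(frozen=True)
class CohortSignature:
    label: str
    effects: tuple  # tuple[BandEffect, ...]

    def __post_init__(self):
        if self.label not in COHORTS:
            raise ValueError(f"label must be one of {COHORTS}")

    def with_gains(self, gains: dict) -> "CohortSignature":
        """Return a copy with per-effect gains replaced (by effect name)."""
        new = tuple(
            replace(e, gain=float(gains.get(e.name, e.gain))) for e in self.effects
        )
        return CohortSignature(self.label, new)


def default_signatures(gain: float = 2.0) -> dict:
    """The three default cohort signatures at a common headline effect size.

    Secondary effects (PD_OFF motor beta, residual occipitoparietal beta in
    the patient cohorts) are scaled down relative to ``gain`` so that each
    cohort keeps one dominant, class-unique spatio-oscillatory feature.
    """
    return {
        "HC": CohortSignature(
            "HC", (BandEffect("op_beta", OCCIPITOPARIETAL, (13.0, 30.0), gain),)
        ),
        "PD_OFF": CohortSignature(
            "PD_OFF",
            (
                BandEffect("motor_gamma", LEFT_MOTOR, (30.0, 50.0), gain),
                BandEffect("motor_beta", LEFT_MOTOR, (13.0, 30.0), 0.5 * gain),
                BandEffect("op_beta", OCCIPITOPARIETAL, (13.0, 30.0), 0.3 * gain),
            ),
        ),
        "PD_ON": CohortSignature(
            "PD_ON",
            (
                BandEffect("fp_theta", FRONTOPARIETAL, (4.0, 8.0), gain),
                BandEffect("op_beta", OCCIPITOPARIETAL, (13.0, 30.0), 0.3 * gain),
            ),
        ),
    }


#: Electrode/band ground truth per cohort for localization-recovery checks:
#: the dominant class-unique effect (electrode set, list of bands in Hz).
RECOVERY_TRUTH = {
    "HC": (OCCIPITOPARIETAL, [(13.0, 30.0)]),
    "PD_OFF": (LEFT_MOTOR, [(30.0, 50.0), (13.0, 30.0)]),
    "PD_ON": (FRONTOPARIETAL, [(4.0, 8.0)]),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition-level settings of the simulator.

    The recorded cohorts' sampling rate is not public knowledge, so 500 Hz
    is used as a configurable default — comfortably above twice the 100 Hz
    upper edge of the analysis band.
    """

    duration_s: float = 120.0
    rate: float = 500.0
    background_exponent: float = 1.0   # chi in the 1/f^chi background
    background_rms: float = 10.0       # microvolts per channel
    background_highpass: float = 0.5   # Hz; hardware-like low-frequency cutoff
    line_freq: float = 60.0
    line_amplitude: float = 2.0        # microvolts
    blink_rate: float = 0.12           # events per second
    blink_amplitude: float = 150.0     # microvolts at Fp electrodes
    blink_width: float = 0.12          # Gaussian SD of the transient, seconds
    bad_channel_rate: float = 0.0      # per-channel probability of a bad contact
    effect_falloff_radius: float = 0.11  # planar radius (~1 grid cell) of spillover
    effect_falloff_gain: float = 0.5     # relative gain on neighbouring electrodes


@dataclass
class EEGRecording:
    """Continuous multichannel recording in microvolts."""

    data: np.ndarray               # (n_channels, n_samples)
    rate: float
    layout: ElectrodeLayout
    subject_id: str
    cohort: str
    session: str | None = None     # "on"/"off" for patients, None for controls
    bad_channels: tuple = ()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.data.copy(), self.rate, self.layout, self.subject_id,
            self.cohort, self.session, tuple(self.bad_channels),
        )


def _pink_spectrum(rng, n_samples, rate, chi, highpass):
    """Complex rfft coefficients of randomized-phase 1/f^chi noise (one channel)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    amp = np.zeros_like(freqs)
    nz = freqs >= highpass
    amp[nz] = freqs[nz] ** (-chi / 2.0)
    z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    return amp * z, freqs


def _band_variance(coeffs, freqs, band, n_samples):
    lo, hi = band
    m = (freqs >= lo) & (freqs < hi)
    # Parseval: per-sample variance contribution of a set of rfft bins.
    return 2.0 * np.sum(np.abs(coeffs[m]) ** 2) / n_samples**2


def _effect_channel_gains(effect: BandEffect, layout: ElectrodeLayout, config) -> np.ndarray:
    """Per-channel gain vector: full gain on listed electrodes, reduced gain
    on planar neighbours within the falloff radius."""
    idx = layout.indices(effect.electrodes)  # raises KeyError on unknown labels
    gains = np.zeros(len(layout))
    gains[idx] = effect.gain
    pos = layout.positions2d
    member = pos[idx]
    for ch in range(len(layout)):
        if gains[ch] > 0:
            continue
        d = np.min(np.linalg.norm(member - pos[ch], axis=1))
        if d <= config.effect_falloff_radius:
            gains[ch] = effect.gain * config.effect_falloff_gain
    return gains


def generate_recording(
    signature: CohortSignature,
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    layout: ElectrodeLayout | None = None,
    subject_id: str = "sub-01",
    session: str | None = None,
) -> EEGRecording:
    """Simulate one continuous 64-channel resting recording.

    The signal is the sum of a per-channel randomized-phase 1/f^chi
    background (normalized to ``background_rms``), band-limited oscillations
    at the signature's electrode sets whose variance is ``gain`` times the
    realized background band variance, a 60 Hz sinusoid, and Gaussian blink
    transients on the frontal channels. Reproducible given ``seed``.
    """
    if layout is None:
        layout = standard_layout()
    n = int(round(config.duration_s * config.rate))
    n_ch = len(layout)
    ss = np.random.SeedSequence(seed)
    bg_rng, osc_rng, line_rng, blink_rng, bad_rng = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # --- 1/f background -------------------------------------------------
    coeffs = np.empty((n_ch, n // 2 + 1), dtype=complex)
    for ch in range(n_ch):
        coeffs[ch], freqs = _pink_spectrum(
            bg_rng, n, config.rate, config.background_exponent, config.background_highpass
        )
    data = np.fft.irfft(coeffs, n=n, axis=1)
    sd = data.std(axis=1, ddof=0, keepdims=True)
    scale = config.background_rms / np.where(sd > 0, sd, 1.0)
    data *= scale
    coeffs *= scale  # keep coefficients consistent for band-power bookkeeping

    # --- band-limited oscillatory effects --------------------------------
    for effect in signature.effects:
        ch_gains = _effect_channel_gains(effect, layout, config)
        lo, hi = effect.band
        m = (freqs >= lo) & (freqs < hi)
        for ch in np.nonzero(ch_gains > 0)[0]:
            g = ch_gains[ch]
            target_var = g * _band_variance(coeffs[ch], freqs, effect.band, n)
            if target_var <= 0:
                continue
            osc_coeffs = np.zeros(len(freqs), dtype=complex)
            z = osc_rng.standard_normal(m.sum()) + 1j * osc_rng.standard_normal(m.sum())
            osc_coeffs[m] = freqs[m] ** (-config.background_exponent / 2.0) * z
            osc = np.fft.irfft(osc_coeffs, n=n)
            v = osc.var()
            if v > 0:
                data[ch] += osc * np.sqrt(target_var / v)

    # --- line noise -------------------------------------------------------
    if config.line_amplitude > 0:
        t = np.arange(n) / config.rate
        phase = line_rng.uniform(0, 2 * np.pi)
        data += config.line_amplitude * np.sin(2 * np.pi * config.line_freq * t + phase)

    # --- blink transients on frontal channels ----------------------------
    if config.blink_rate > 0:
        t = np.arange(n) / config.rate
        n_events = blink_rng.poisson(config.blink_rate * config.duration_s)
        times = np.sort(blink_rng.uniform(0, config.duration_s, size=n_events))
        frontal = layout.indices(
            [c for c in FRONTAL_BLINK_CHANNELS if c in layout.names]
        )
        weights = np.linspace(1.0, 0.6, num=len(frontal))
        for t0 in times:
            pulse = np.exp(-0.5 * ((t - t0) / config.blink_width) ** 2)
            amp = config.blink_amplitude * blink_rng.uniform(0.8, 1.2)
            for w, ch in zip(weights, frontal):
                data[ch] += w * amp * pulse

    # --- bad channels -----------------------------------------------------
    bad: tuple = ()
    if config.bad_channel_rate > 0:
        mask = bad_rng.random(n_ch) < config.bad_channel_rate
        bad_idx = np.nonzero(mask)[0]
        for ch in bad_idx:
            # dead-contact model: heavily attenuated signal plus sensor noise
            data[ch] = 0.1 * data[ch] + bad_rng.standard_normal(n)
        bad = tuple(layout.names[i] for i in bad_idx)

    if not np.all(np.isfinite(data)):
        raise FloatingPointError("simulated recording contains non-finite samples")
    return EEGRecording(
        data=data, rate=config.rate, layout=layout, subject_id=subject_id,
        cohort=signature.label, session=session, bad_channels=bad,
    )


# ---------------------------------------------------------------------------
# Clinical model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Coupling:
    """Linear coupling of an outcome to one injected effect's standardized
    per-subject gain: outcome_z = rho * gain_z + noise_scale*sqrt(1-rho^2)*eps
    (+ optional age term), then shifted/scaled to clinical units."""

    effect: str          # effect name whose per-subject gain drives the outcome
    session: str | None  # which session's draw ("off"/"on"); None for controls
    rho: float           # target correlation with the injected gain
    loc: float
    scale: float
    age_slope: float = 0.0
    noise_scale: float = 1.0

    def __post_init__(self):
        if not np.isfinite([self.rho, self.loc, self.scale, self.age_slope, self.noise_scale]).all():
            raise ValueError("clinical coefficients must be finite")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")


@dataclass(frozen=True)
class ClinicalModel:
    """Generative model of the per-subject clinical table.

    The couplings mirror the association structure the analysis is meant to
    recover: occipitoparietal beta (off) with the off-medication UPDRS motor
    score, left-motor beta (off) with disease duration, frontoparietal theta
    (on) with the on-off change in UPDRS; LEDD is generated without any
    coupling (a built-in null).
    """

    gain_jitter_rel: float = 0.25   # SD of per-subject gain, relative to class mean
    age_mean: float = 70.0
    age_sd: float = 9.0
    updrs_off: Coupling = Coupling("op_beta", "off", -0.6, 24.0, 8.0)
    duration: Coupling = Coupling("motor_beta", "off", +0.6, 5.4, 4.1)
    dupdrs: Coupling = Coupling("fp_theta", "on", -0.6, -5.0, 4.0)
    ledd: Coupling = Coupling("op_beta", "off", 0.0, 685.0, 452.0)
    education_mean: float = 16.0
    education_sd: float = 3.0
    mmse_mean: float = 28.7
    mmse_sd: float = 1.0


def _draw_outcome(coupling: Coupling, gain_z, age_z, rng):
    eps = rng.standard_normal(np.shape(gain_z))
    z = (
        coupling.rho * gain_z
        + coupling.noise_scale * np.sqrt(max(0.0, 1.0 - coupling.rho**2)) * eps
        + coupling.age_slope * coupling.noise_scale * age_z
    )
    return coupling.loc + coupling.scale * z


def simulate_clinical(
    gains_z: pd.DataFrame,
    model: ClinicalModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical rows for PD subjects from standardized per-subject gains.

    ``gains_z`` must have one row per PD subject and columns named
    ``z_<effect>_<session>`` holding the standardized injected gains.
    """
    n = len(gains_z)
    age = model.age_mean + model.age_sd * rng.standard_normal(n)
    age_z = (age - model.age_mean) / model.age_sd

    def col(c: Coupling):
        return gains_z[f"z_{c.effect}_{c.session}"].to_numpy()

    updrs_off = np.maximum(0.0, _draw_outcome(model.updrs_off, col(model.updrs_off), age_z, rng))
    duration = np.maximum(0.0, _draw_outcome(model.duration, col(model.duration), age_z, rng))
    dupdrs = _draw_outcome(model.dupdrs, col(model.dupdrs), age_z, rng)
    updrs_on = np.maximum(0.0, updrs_off + dupdrs)
    ledd = np.maximum(0.0, _draw_outcome(model.ledd, col(model.ledd), age_z, rng))
    education = model.education_mean + model.education_sd * rng.standard_normal(n)
    mmse = np.clip(model.mmse_mean + model.mmse_sd * rng.standard_normal(n), 26.0, 30.0)
    return pd.DataFrame(
        {
            "subject_id": gains_z["subject_id"].to_numpy(),
            "age": age,
            "updrs_motor_on": updrs_on,
            "updrs_motor_off": updrs_off,
            "disease_duration": duration,
            "ledd": ledd,
            "education": education,
            "mmse": mmse,
        }
    )


def generate_cohorts(
    n_per_class: int,
    signatures: dict | None = None,
    clinical_model: ClinicalModel | None = None,
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    layout: ElectrodeLayout | None = None,
) -> tuple[list, pd.DataFrame]:
    """Simulate a full three-cohort study.

    ``n_per_class`` healthy controls are generated with a single session,
    and ``n_per_class`` patients with both an off- and an on-medication
    session (so the medication contrast is within-subject, as in the primary
    study design). Per-subject effect gains are jittered around the class
    means, and the clinical table is coupled to those jitters by
    construction.

    Returns the list of recordings and the clinical table (one row per
    subject; patient-only fields are NaN for controls). The clinical table
    additionally carries the standardized injected gains in ``z_*`` columns
    as simulation ground truth.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if signatures is None:
        signatures = default_signatures()
    if clinical_model is None:
        clinical_model = ClinicalModel()
    if layout is None:
        layout = standard_layout()

    children = np.random.SeedSequence(seed).spawn(3)
    gain_rng = np.random.default_rng(children[0])
    clin_rng = np.random.default_rng(children[1])
    rec_ss = children[2]
    rec_seeds = rec_ss.generate_state(3 * n_per_class * 8)
    seed_iter = iter(int(s) % (2**31 - 1) for s in rec_seeds)

    recordings: list[EEGRecording] = []

    def subject_signature(base: CohortSignature, zrow: dict, session_key: str | None):
        gains = {}
        for e in base.effects:
            z = gain_rng.standard_normal()
            g = max(0.0, e.gain * (1.0 + clinical_model.gain_jitter_rel * z))
            gains[e.name] = g
            zrow[f"z_{e.name}_{session_key}"] = z
        return base.with_gains(gains)

    # Healthy controls --------------------------------------------------
    hc_rows = []
    for i in range(n_per_class):
        sid = f"sub-hc{i + 1:02d}"
        zrow: dict = {"subject_id": sid}
        sig = subject_signature(signatures["HC"], zrow, None)
        recordings.append(
            generate_recording(sig, config, next(seed_iter), layout, sid, session=None)
        )
        hc_rows.append(zrow)

    # Patients: off and on sessions -------------------------------------
    pd_rows = []
    for i in range(n_per_class):
        sid = f"sub-pd{i + 1:02d}"
        zrow = {"subject_id": sid}
        sig_off = subject_signature(signatures["PD_OFF"], zrow, "off")
        sig_on = subject_signature(signatures["PD_ON"], zrow, "on")
        recordings.append(
            generate_recording(sig_off, config, next(seed_iter), layout, sid, session="off")
        )
        recordings.append(
            generate_recording(sig_on, config, next(seed_iter), layout, sid, session="on")
        )
        pd_rows.append(zrow)

    gains_pd = pd.DataFrame(pd_rows)
    clinical_pd = simulate_clinical(gains_pd, clinical_model, clin_rng)
    clinical_pd.insert(1, "cohort", "PD")

    age_hc = clinical_model.age_mean + clinical_model.age_sd * clin_rng.standard_normal(n_per_class)
    mmse_hc = np.clip(
        clinical_model.mmse_mean + clinical_model.mmse_sd * clin_rng.standard_normal(n_per_class),
        26.0, 30.0,
    )
    edu_hc = clinical_model.education_mean + clinical_model.education_sd * clin_rng.standard_normal(n_per_class)
    clinical_hc = pd.DataFrame(
        {
            "subject_id": [r["subject_id"] for r in hc_rows],
            "cohort": "HC",
            "age": age_hc,
            "updrs_motor_on": np.nan,
            "updrs_motor_off": np.nan,
            "disease_duration": np.nan,
            "ledd": np.nan,
            "education": edu_hc,
            "mmse": mmse_hc,
        }
    )
    clinical = pd.concat(
        [clinical_hc, clinical_pd.merge(gains_pd, on="subject_id")],
        ignore_index=True,
    )
    return recordings, clinical


# ---------------------------------------------------------------------------
# BIDS-like persistence
# ---------------------------------------------------------------------------

def write_cohort(recordings, clinical: pd.DataFrame, outdir) -> Path:
    """Write recordings in a BIDS-like layout plus the clinical TSV.

    One ``.npy`` array container per subject/session with a JSON sidecar
    holding the rate, montage name, cohort label and bad channels.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        sub = outdir / rec.subject_id
        d = sub / (f"ses-{rec.session}" if rec.session else "ses-rest") / "eeg"
        d.mkdir(parents=True, exist_ok=True)
        stem = rec.subject_id + (f"_ses-{rec.session}" if rec.session else "")
        np.save(d / f"{stem}_eeg.npy", rec.data)
        sidecar = {
            "rate": rec.rate,
            "montage": "standard_1005-64",
            "channels": list(rec.layout.names),
            "cohort": rec.cohort,
            "session": rec.session,
            "bad_channels": list(rec.bad_channels),
        }
        (d / f"{stem}_eeg.json").write_text(json.dumps(sidecar, indent=1))
    clinical.to_csv(outdir / "participants.tsv", sep="\t", index=False)
    return outdir


def read_cohort(indir) -> tuple[list, pd.DataFrame]:
    """Read back a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    layout = standard_layout()
    recordings = []
    for sidecar in sorted(indir.glob("sub-*/ses-*/eeg/*_eeg.json")):
        meta = json.loads(sidecar.read_text())
        data = np.load(sidecar.with_name(sidecar.name.replace(".json", ".npy")))
        if list(layout.names) != meta["channels"]:
            raise ValueError(f"channel list mismatch in {sidecar}")
        recordings.append(
            EEGRecording(
                data=data, rate=meta["rate"], layout=layout,
                subject_id=sidecar.name.split("_")[0], cohort=meta["cohort"],
                session=meta["session"], bad_channels=tuple(meta["bad_channels"]),
            )
        )
    clinical = pd.read_csv(indir / "participants.tsv", sep="\t")
    return recordings, clinical
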