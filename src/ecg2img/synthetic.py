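"""Synthetic labelled ECG cohorts for end-to-end pipeline runs.

Each patient is a 10 s, 500 Hz, multi-lead record built from a
sum-of-Gaussians beat template: every wave w in {P, Q, R, S, T}
contributes a_w * exp(-(t - mu_w)^2 / (2 sigma_w^2)) relative to the
beat fiducial (the R peak), scaled per lead. Beats are laid down with
RR intervals 60/HR plus truncated Gaussian jitter, and white measurement
noise is added. Leads I, II, V3 and V5 are emitted, leaving aVR to the
derivation path.

Non-survivors differ from survivors by three morphological effects that
mirror what gradient attribution highlights on real CCU ECGs: an
ST-segment offset (a plateau between the S and T wave centers, injected
into lead V3 by default), a tripled RR jitter (rhythm irregularity) and
a 1.3x taller R wave. Neutralizing all three (``neutralized()``) makes
the two classes distributionally identical — the null cohort used for
sanity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .signal_io import (
    NON_SURVIVOR,
    SURVIVOR,
    WaveformRecord,
    write_csv_waveform,
)

#: (amplitude mV, center offset s from the R fiducial, width s)
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.15, -0.20, 0.025),
    "Q": (-0.10, -0.035, 0.010),
    "R": (1.00, 0.0, 0.012),
    "S": (-0.25, 0.035, 0.010),
    "T": (0.35, 0.22, 0.045),
}

DEFAULT_LEAD_SCALE: dict[str, float] = {"I": 0.7, "II": 1.0,
                                        "V3": 1.2, "V5": 1.1}


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters; defaults define the standard study cohort."""

    sampling_rate_hz: float = 500.0
    duration_s: float = 10.0
    heart_rate_bpm: tuple[float, float] = (55.0, 100.0)
    wave_components: dict[str, tuple[float, float, float]] = \
        field(default_factory=lambda: dict(DEFAULT_WAVES))
    lead_scale: dict[str, float] = \
        field(default_factory=lambda: dict(DEFAULT_LEAD_SCALE))
    rr_jitter_sd: float = 0.010
    noise_sd_mv: float = 0.02
    # class effects, applied to non-survivor records only
    st_offset_mv: float = 0.2
    st_lead: str = "V3"
    rr_jitter_multiplier: float = 3.0
    r_amp_multiplier: float = 1.3

    def __post_init__(self) -> None:
        for w, (_a, _mu, sigma) in self.wave_components.items():
            if sigma <= 0:
                raise ParameterError(f"wave {w!r} has non-positive width")
        n = self.duration_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ParameterError(
                "duration_s * sampling_rate_hz must be a positive integer")
        lo, hi = self.heart_rate_bpm
        if not 0 < lo <= hi:
            raise ParameterError("invalid heart-rate range")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    def neutralized(self) -> "SynthParams":
        """Copy with all class effects switched off (null cohort)."""
        return replace(self, st_offset_mv=0.0, rr_jitter_multiplier=1.0,
                       r_amp_multiplier=1.0)


def gen_beat_template(params: SynthParams, lead: str) -> np.ndarray:
    """One beat of the noiseless template on the lead's sample grid.

    The grid spans [-0.3 s, +0.5 s) around the R fiducial.
    """
    scale = params.lead_scale.get(lead, 1.0)
    dt = 1.0 / params.sampling_rate_hz
    t = np.arange(-0.3, 0.5, dt)
    beat = np.zeros_like(t)
    for a, mu, sigma in params.wave_components.values():
        beat += a * scale * np.exp(-((t - mu) ** 2) / (2.0 * sigma ** 2))
    return beat


def _beat_fiducials(rng: np.random.Generator, params: SynthParams,
                    jitter_sd: float) -> np.ndarray:
    lo, _hi = params.heart_rate_bpm
    if params.duration_s * lo / 60.0 < 2:
        raise ParameterError(
            "parameters imply fewer than 2 beats in the record")
    hr = rng.uniform(*params.heart_rate_bpm)
    base_rr = 60.0 / hr
    times = [rng.uniform(0.0, base_rr) - base_rr]
    while times[-1] < params.duration_s + 0.5:
        rr = base_rr + rng.normal(0.0, jitter_sd)
        rr = max(rr, 0.25 * base_rr)  # truncate positive
        times.append(times[-1] + rr)
    return np.asarray(times)


def gen_patient(label: int, seed: int,
                params: SynthParams | None = None,
                patient_id: str | None = None,
                return_fiducials: bool = False):
    """Generate one labelled patient record (deterministic per seed)."""
    params = params or SynthParams()
    if label not in (SURVIVOR, NON_SURVIVOR):
        raise ParameterError(f"label must be 0 or 1, got {label!r}")
    rng = np.random.default_rng(seed)
    is_case = label == NON_SURVIVOR
    jitter_sd = params.rr_jitter_sd * (params.rr_jitter_multiplier
                                       if is_case else 1.0)
    fiducials = _beat_fiducials(rng, params, jitter_sd)
    t = np.arange(params.n_samples) / params.sampling_rate_hz

    mu_s = params.wave_components["S"][1]
    mu_t = params.wave_components["T"][1]
    leads: dict[str, np.ndarray] = {}
    for lead in ("I", "II", "V3", "V5"):
        scale = params.lead_scale.get(lead, 1.0)
        signal = np.zeros_like(t)
        for a, mu, sigma in (
                (a * (params.r_amp_multiplier if is_case and w == "R" else 1.0),
                 mu, sigma)
                for w, (a, mu, sigma) in params.wave_components.items()):
            centers = fiducials + mu
            keep = (centers > -0.5) & (centers < params.duration_s + 0.5)
            for c in centers[keep]:
                signal += a * scale * np.exp(-((t - c) ** 2) / (2 * sigma ** 2))
        if is_case and lead == params.st_lead and params.st_offset_mv != 0.0:
            for fk in fiducials:
                signal[(t >= fk + mu_s) & (t <= fk + mu_t)] += params.st_offset_mv
        signal += rng.normal(0.0, params.noise_sd_mv, size=t.shape)
        leads[lead] = signal
    record = WaveformRecord(
        patient_id=patient_id or f"syn{seed:010d}",
        leads=leads, sampling_rate_hz=params.sampling_rate_hz, label=label)
    if return_fiducials:
        return record, fiducials
    return record


def gen_cohort(n_per_class: int, seed: int,
               params: SynthParams | None = None,
               outdir: str | Path | None = None) -> list[WaveformRecord]:
    """Generate a balanced labelled cohort (survivors first).

    Patient seeds are derived from the master seed, so a fixed master
    seed reproduces the cohort exactly. With ``outdir`` set, one CSV per
    patient, a ``labels.csv`` and a ``params.json`` provenance record
    are written.
    """
    params = params or SynthParams()
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=2 * n_per_class)
    records = []
    i = 0
    for label, tag in ((SURVIVOR, "s"), (NON_SURVIVOR, "n")):
        for k in range(n_per_class):
            pid = f"syn_{tag}{k:04d}"
            records.append(gen_patient(label, int(child_seeds[i]),
                                       params, patient_id=pid))
            i += 1
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        label_names = {SURVIVOR: "survivor", NON_SURVIVOR: "non_survivor"}
        with (outdir / "labels.csv").open("w", encoding="utf-8") as fh:
            fh.write("patient_id,label\n")
            for rec in records:
                write_csv_waveform(rec, outdir / f"{rec.patient_id}.csv")
                fh.write(f"{rec.patient_id},{label_names[rec.label]}\n")
        prov = {"n_per_class": n_per_class, "seed": seed,
                "params": {k: v for k, v in params.__dict__.items()}}
        (outdir / "params.json").write_text(json.dumps(prov, indent=2))
    return records
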