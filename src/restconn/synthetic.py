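"""Synthetic ROI-level EEG with known phase-coupling ground truth.

Each region's trace is a sum of band-limited noise components (one per
band, unit variance, produced by zero-phase Butterworth filtering of
white noise) plus independent broadband sensor noise. Phase coupling is
planted per band and per directed pair: a fraction ``coupling_strength``
of the target's band power is replaced by a copy of the source's band
component delayed by ``phase_lag`` radians at the band's center
frequency (a fractional-sample delay, so the planted phase difference is
controllable and auditable). Zero-lag "coupling" — the volume-conduction
case the phase lag index must suppress — is available both as
``phase_lag = 0`` and as an explicit instantaneous mixing matrix.

A full randomized crossover study (subjects x {Ctrl, SM} sessions x
{pre, post} phases) is generated with per-cell seeds derived from the
study seed, so any single recording is regenerable in isolation. Effect
couplings are applied only in the (SM, post) cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import BandSpec, DEFAULT_BANDS, DMN_LABELS, Recording

__all__ = [
    "CouplingSpec",
    "StudySpec",
    "StudyDataset",
    "generate_coupled_sources",
    "apply_instantaneous_mixing",
    "generate_crossover_study",
    "default_effect_couplings",
    "SESSIONS",
    "PHASES",
]

SESSIONS: tuple[str, str] = ("Ctrl", "SM")
PHASES: tuple[str, str] = ("pre", "post")


@dataclass(frozen=True)
class CouplingSpec:
    """A planted directed phase coupling between two regions in one band.

    ``coupling_strength`` is the fraction of the target's band power
    that is a lagged copy of the source's band component; ``phase_lag``
    is the planted phase difference (radians) at the band center.
    """

    source: str
    target: str
    band: str
    phase_lag: float
    coupling_strength: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"coupling source and target must differ, got {self.source!r} twice")
        if not -np.pi < self.phase_lag <= np.pi:
            raise ValueError(f"phase_lag must lie in (-pi, pi], got {self.phase_lag}")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError(
                f"coupling_strength must lie in [0, 1], got {self.coupling_strength}"
            )


@dataclass
class StudySpec:
    """Parameters of a synthetic crossover connectivity study.

    Defaults emulate the study design being modelled: 24 subjects, the
    14 default-mode-network regions, 60-s resting recordings, the three
    bands alpha/beta/gamma, and a ±20% multiplicative between-subject
    jitter on planted coupling strengths (constant across a subject's
    four recordings, so edge-level t-tests see realistic between-subject
    variance of the effect, not extra within-pair noise).
    """

    n_subjects: int = 24
    roi_labels: tuple[str, ...] = DMN_LABELS
    fs: float = 256.0
    duration: float = 60.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    noise_sd: float = 0.5
    baseline_couplings: tuple[CouplingSpec, ...] = ()
    effect_couplings: tuple[CouplingSpec, ...] = ()
    mixing: np.ndarray | None = None
    coupling_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.roi_labels = tuple(self.roi_labels)
        if self.n_subjects < 2:
            raise ValueError(f"need n_subjects >= 2, got {self.n_subjects}")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"duration * fs must be an integer sample count, got {n}")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            k = len(self.roi_labels)
            if self.mixing.shape != (k, k):
                raise ValueError(
                    f"mixing matrix shape {self.mixing.shape} != ({k}, {k})"
                )
        band_names = {b.name for b in self.bands}
        for c in (*self.baseline_couplings, *self.effect_couplings):
            for lb in (c.source, c.target):
                if lb not in self.roi_labels:
                    raise ValueError(f"coupling references unknown ROI label {lb!r}")
            if c.band not in band_names:
                raise ValueError(f"coupling references unknown band {c.band!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def default_effect_couplings(
    strength: float = 0.35, phase_lag: float = np.pi / 2
) -> tuple[CouplingSpec, ...]:
    """Alpha-band couplings on the four parahippocampal↔posterior-cingulate
    edges — the planted analogue of the connectivity increase the
    pipeline is meant to detect."""
    pairs = [
        ("L ParaH", "L PCC"),
        ("L ParaH", "R PCC"),
        ("R ParaH", "L PCC"),
        ("R ParaH", "R PCC"),
    ]
    return tuple(
        CouplingSpec(source=a, target=b, band="alpha", phase_lag=phase_lag, coupling_strength=strength)
        for a, b in pairs
    )


# ---------------------------------------------------------------------------
# signal synthesis

def _band_noise(rng: np.random.Generator, n: int, fs: float, band: BandSpec, order: int = 4) -> np.ndarray:
    """Unit-variance band-limited noise: zero-phase Butterworth-filtered
    white noise."""
    sos = sps.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _fractional_delay(x: np.ndarray, delay_samples: float) -> np.ndarray:
    """Delay a signal by a (possibly fractional) number of samples via a
    frequency-domain phase ramp (circular; fine for noise signals much
    longer than the delay)."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n)
    spectrum = np.fft.rfft(x) * np.exp(-2j * np.pi * freqs * delay_samples)
    return np.fft.irfft(spectrum, n=n)


def generate_coupled_sources(
    spec: StudySpec,
    subject_seed: int,
    couplings: tuple[CouplingSpec, ...] | None = None,
    strengths: np.ndarray | None = None,
    return_components: bool = False,
):
    """Generate one ROI x samples recording with planted couplings.

    Each ROI receives one unit-variance band-limited noise component per
    band; components are summed across bands and independent Gaussian
    noise of SD ``spec.noise_sd`` is added. For every coupling the
    target's band component becomes

        sqrt(1 - c) * own + sqrt(c) * delay(source, tau)

    with ``tau = phase_lag / (2*pi*f_center)`` — both terms unit
    variance and independent, so band power is preserved and ``c`` is
    exactly the planted power fraction. ``phase_lag = 0`` is allowed
    (zero-lag coupling, the case PLI must suppress). Deterministic given
    ``(spec.seed, subject_seed)``.

    Parameters
    ----------
    couplings
        Defaults to ``spec.baseline_couplings``.
    strengths
        Optional per-coupling strength overrides (e.g. jittered values).
    return_components
        Also return the post-coupling band components
        ``{band: {roi: trace}}`` for auditing the planted phases.
    """
    if couplings is None:
        couplings = spec.baseline_couplings
    for c in couplings:
        for lb in (c.source, c.target):
            if lb not in spec.roi_labels:
                raise ValueError(f"coupling references unknown ROI label {lb!r}")
    if strengths is None:
        strengths = np.array([c.coupling_strength for c in couplings])
    strengths = np.clip(np.asarray(strengths, dtype=float), 0.0, 1.0)

    rng = np.random.default_rng([spec.seed, int(subject_seed)])
    n = spec.n_samples
    bands = {b.name: b for b in spec.bands}
    comps: dict[str, dict[str, np.ndarray]] = {
        b.name: {roi: _band_noise(rng, n, spec.fs, b) for roi in spec.roi_labels}
        for b in spec.bands
    }
    for c, strength in zip(couplings, strengths):
        band = bands[c.band]
        tau = c.phase_lag / (2 * np.pi * band.center) * spec.fs  # samples
        delayed = _fractional_delay(comps[c.band][c.source], tau)
        own = comps[c.band][c.target]
        comps[c.band][c.target] = np.sqrt(1 - strength) * own + np.sqrt(strength) * delayed

    data = np.zeros((len(spec.roi_labels), n))
    for b in spec.bands:
        for r, roi in enumerate(spec.roi_labels):
            data[r] += comps[b.name][roi]
    data += spec.noise_sd * rng.standard_normal(data.shape)
    rec = Recording(spec.roi_labels, spec.fs, data)
    if spec.mixing is not None:
        rec = apply_instantaneous_mixing(rec, spec.mixing)
    if return_components:
        return rec, comps
    return rec


def apply_instantaneous_mixing(rec: Recording, mixing: np.ndarray) -> Recording:
    """Mix channels with zero temporal lag (volume-conduction surrogate).

    The output sample vector at every instant is ``mixing @ input``;
    channel labels are preserved. Because the mixing is instantaneous it
    creates only zero-lag dependence — the kind coherence picks up and
    the phase lag index is designed to discard.
    """
    mixing = np.asarray(mixing, dtype=float)
    k = rec.n_channels
    if mixing.shape != (k, k):
        raise ValueError(
            f"mixing matrix shape {mixing.shape} does not match channel count {k}"
        )
    return rec.copy_with(mixing @ rec.data)


# ---------------------------------------------------------------------------
# crossover study

def _subject_seed(subject: int, session: str, phase: str) -> int:
    """Stable per-cell seed component: regenerate any recording from
    (spec.seed, this)."""
    return 4 * subject + 2 * SESSIONS.index(session) + PHASES.index(phase)


@dataclass
class StudyDataset:
    """A generated crossover study: recordings indexed by
    (subject, session, phase) plus the manifest."""

    spec: StudySpec
    recordings: dict[tuple[int, str, str], Recording]
    manifest: pd.DataFrame

    def save(self, outdir: str | Path) -> Path:
        """Write each recording as .npy + JSON sidecar and the manifest CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for (subj, session, phase), rec in self.recordings.items():
            stem = f"sub-{subj:02d}_ses-{session}_phase-{phase}"
            np.save(outdir / f"{stem}.npy", rec.data)
            sidecar = {
                "labels": list(rec.labels),
                "fs": rec.fs,
                "study_seed": self.spec.seed,
                "subject_seed": _subject_seed(subj, session, phase),
            }
            (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
            rows.append(
                {"subject": subj, "session": session, "phase": phase, "file": f"{stem}.npy"}
            )
        manifest = pd.DataFrame(rows).sort_values(["subject", "session", "phase"])
        manifest.to_csv(outdir / "manifest.csv", index=False)
        return outdir / "manifest.csv"


def generate_crossover_study(
    spec: StudySpec, sessions: tuple[str, ...] = SESSIONS
) -> StudyDataset:
    """Generate the full subject x session x phase dataset.

    Ctrl pre, Ctrl post and SM pre receive ``baseline_couplings`` only;
    SM post receives baseline plus ``effect_couplings``. Coupling
    strengths are jittered per subject by a multiplicative factor
    uniform in ``[1 - j, 1 + j]`` (j = ``spec.coupling_jitter``), drawn
    once per subject so the jitter is constant across that subject's
    recordings. ``sessions`` restricts generation to a subset of
    sessions; per-cell seeding makes the generated recordings identical
    to the corresponding cells of the full study.
    """
    for s in sessions:
        if s not in SESSIONS:
            raise ValueError(f"unknown session {s!r}; expected one of {SESSIONS}")
    all_couplings = (*spec.baseline_couplings, *spec.effect_couplings)
    n_base = len(spec.baseline_couplings)
    recordings: dict[tuple[int, str, str], Recording] = {}
    rows = []
    for subj in range(spec.n_subjects):
        jrng = np.random.default_rng([spec.seed, 987_654_321, subj])
        jitter = jrng.uniform(
            1 - spec.coupling_jitter, 1 + spec.coupling_jitter, size=len(all_couplings)
        )
        strengths = np.clip(
            np.array([c.coupling_strength for c in all_couplings]) * jitter, 0.0, 1.0
        )
        for session in sessions:
            for phase in PHASES:
                if session == "SM" and phase == "post":
                    coup, stren = all_couplings, strengths
                else:
                    coup, stren = spec.baseline_couplings, strengths[:n_base]
                rec = generate_coupled_sources(
                    spec, _subject_seed(subj, session, phase), couplings=coup, strengths=stren
                )
                recordings[(subj, session, phase)] = rec
                rows.append({"subject": subj, "session": session, "phase": phase})
    manifest = pd.DataFrame(rows)
    return StudyDataset(spec=spec, recordings=recordings, manifest=manifest)
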