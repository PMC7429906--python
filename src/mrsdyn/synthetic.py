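"""Synthetic MEGA-PRESS cohort generation with known ground truth.

The generator emulates the statistical structure the dynamic analyses are
designed to detect, without simulating editing physics: OFF transients carry
complex Lorentzian tCr (3.0 ppm) and tNAA (2.0 ppm) singlets (plus an
optional broad residual component at 4.7 ppm and a linear baseline), and ON
transients additionally carry the edited difference signature -- a positive
GABA+ Gaussian at 3.0 ppm, a positive double-Gaussian Glx multiplet at
3.71/3.79 ppm, and a negative co-edited tNAA Lorentzian at 2.0 ppm.

Time structure per subject and metabolite: a deterministic linear drift
(fractional endpoint-to-endpoint change ``drift_total``), plus a
cohort-shared latent fluctuation defined per high-resolution bin.  The GABA+
latent is a stationary AR(1) process; the Glx latent is a delayed,
anti-coupled copy of it plus independent innovation::

    glx[t] = -kappa * gaba[t - delay] + e[t]

which is the lagged relationship the cross-correlation analysis recovers.
Per-transient instrument effects: frequency jitter, optional linear scanner
frequency drift, and zero-order phase jitter, all invertible by the
creatine-reference correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import dawsn

from .core import (
    PEAK_PPM,
    AcquisitionProfile,
    Cohort,
    ConfigurationError,
    GroundTruth,
    Transient,
)
from .fitting import GAUSS_FWHM_FACTOR

__all__ = [
    "LINEWIDTHS_HZ",
    "LatentTimecourses",
    "simulate_latent_timecourses",
    "synthesize_transient",
    "simulate_cohort",
    "generate_tissue_fractions",
]

#: true line widths injected into the spectra, in Hz.  Lorentzian widths are
#: half-widths gamma (FWHM = 2 gamma, so tCr fits at ~8.5 Hz, tNAA ~8.4 Hz);
#: Gaussian widths are sigmas chosen so the fitted FWHM (2 sigma sqrt(2 ln 2))
#: lands near 25 Hz for GABA+ and 14 Hz per Glx sub-peak.
LINEWIDTHS_HZ = {
    "tcr": 4.25,
    "tnaa": 4.2,
    "naa_edit": 4.2,
    "gaba": 25.0 / GAUSS_FWHM_FACTOR,
    "glx": 14.0 / GAUSS_FWHM_FACTOR,
    "water": 25.0,
}

#: area of the broad residual water component, tCr units (unsuppressed data)
RESIDUAL_WATER_AREA = 0.8

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)


@dataclass
class LatentTimecourses:
    """Cohort-shared fractional fluctuation per high-resolution bin."""

    gaba: np.ndarray
    glx: np.ndarray
    drift: dict  # metabolite -> per-bin deterministic drift component

    @property
    def n_bins(self) -> int:
        return len(self.gaba)


def simulate_latent_timecourses(truth: GroundTruth, n_bins: int, seed: int) -> LatentTimecourses:
    """Draw the shared GABA+/Glx latent series and the per-bin drift ramps.

    The GABA+ latent ``g`` is a stationary AR(1) with SD ``latent_sd`` and
    coefficient ``latent_ar``.  The Glx latent at bin t is
    ``-coupling_kappa * g[t - coupling_delay_bins]`` plus an independent
    Gaussian innovation of SD ``glx_innovation_sd``; the AR(1) is extended
    ``coupling_delay_bins`` bins into the past so the coupling is defined at
    every output bin.
    """
    d = int(truth.coupling_delay_bins)
    if n_bins <= d:
        raise ConfigurationError(
            f"n_bins ({n_bins}) must exceed coupling_delay_bins ({d})"
        )
    rng = np.random.default_rng(seed)
    total = n_bins + d
    g_ext = np.zeros(total)
    if truth.latent_sd > 0:
        rho = truth.latent_ar
        innov_sd = truth.latent_sd * np.sqrt(1.0 - rho * rho)
        eps = rng.standard_normal(total)
        g_ext[0] = truth.latent_sd * eps[0]
        for k in range(1, total):
            g_ext[k] = rho * g_ext[k - 1] + innov_sd * eps[k]
    else:
        rng.standard_normal(total)  # keep the stream layout stable
    e = rng.standard_normal(n_bins) * truth.glx_innovation_sd
    gaba = g_ext[d:]
    # gaba[t - d] in cohort time is g_ext[t], t = 0..n_bins-1
    glx = -truth.coupling_kappa * g_ext[:n_bins] + e
    frac = np.arange(n_bins) / max(n_bins - 1, 1)
    drift = {met: dt * frac for met, dt in truth.drift_total.items()}
    return LatentTimecourses(gaba=gaba, glx=glx, drift=drift)


# ------------------------------------------------------------- spectra

def _lorentz_complex(x, f0, gamma):
    """Unit-amplitude complex Lorentzian: absorption + i dispersion."""
    u = (x - f0) / gamma
    den = 1.0 / (1.0 + u * u)
    return den + 1j * (u * den)


def _gauss_complex(x, f0, sigma):
    """Unit-amplitude complex Gaussian; the dispersive channel is the
    Hilbert transform of the absorption shape (a Dawson function)."""
    u = (x - f0) / sigma
    return np.exp(-0.5 * u * u) + 1j * (_TWO_OVER_SQRT_PI * dawsn(u / np.sqrt(2.0)))


def _build_spectra(
    profile: AcquisitionProfile,
    amplitudes: dict,
    is_on: np.ndarray,
    freq_offset_ppm: np.ndarray,
    phase_rad: np.ndarray,
    baseline: tuple,
    edit_efficiency: float,
    width_scale: float,
    noise_sd: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Vectorised builder for a block of transients.

    ``amplitudes`` maps metabolite -> peak areas, scalar or per-transient
    array of length T.  Returns complex spectra of shape (T, n_points).
    """
    x = profile.ppm_axis().astype(np.float32)
    T = len(is_on)
    is_on = np.asarray(is_on, dtype=bool)
    off = np.asarray(freq_offset_ppm, dtype=np.float32).reshape(T, 1)
    hzppm = profile.hz_per_ppm

    def area_rows(name, rows=None):
        a = np.asarray(amplitudes.get(name, 0.0), dtype=np.float32)
        a = np.broadcast_to(a, (T,))
        if np.any(a < 0):
            raise ValueError(f"peak areas must be >= 0 (got negative {name})")
        if rows is not None:
            a = a[rows]
        return a.reshape(-1, 1)

    def widths(name):
        return np.float32(LINEWIDTHS_HZ[name] * width_scale / hzppm)

    spec = np.zeros((T, profile.n_points), dtype=np.complex64)
    xr = x[None, :]

    # OFF content, present in every transient
    g = widths("tcr")
    spec += (area_rows("tcr") / (np.pi * g)) * _lorentz_complex(xr, PEAK_PPM["tcr"] + off, g)
    g = widths("tnaa")
    spec += (area_rows("tnaa") / (np.pi * g)) * _lorentz_complex(xr, PEAK_PPM["tnaa"] + off, g)
    if profile.residual_water:
        g = widths("water")
        spec += (RESIDUAL_WATER_AREA / (np.pi * g)) * _lorentz_complex(
            xr, PEAK_PPM["water"] + off, g
        )

    # edited difference signature, evaluated on ON transients only
    rows = np.nonzero(is_on)[0]
    if rows.size and edit_efficiency != 0.0:
        off_on = off[rows]
        sig = np.zeros((rows.size, profile.n_points), dtype=np.complex64)
        s = widths("gaba")
        sig += (area_rows("gaba", rows) / (s * _SQRT_2PI)) * _gauss_complex(
            xr, PEAK_PPM["gaba"] + off_on, s
        )
        s = widths("glx")
        half = area_rows("glx", rows) / 2.0
        for c in PEAK_PPM["glx"]:
            sig += (half / (s * _SQRT_2PI)) * _gauss_complex(xr, c + off_on, s)
        g = widths("naa_edit")
        sig -= (area_rows("naa_edit", rows) / (np.pi * g)) * _lorentz_complex(
            xr, PEAK_PPM["naa_edit"] + off_on, g
        )
        spec[rows] += np.float32(edit_efficiency) * sig

    b0, b1 = baseline
    spec += np.float32(b0) + np.float32(b1) * (xr - np.float32(3.0))
    ph = np.asarray(phase_rad, dtype=np.float32).reshape(T, 1)
    spec *= np.cos(ph) + 1j * np.sin(ph)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        noise = rng.standard_normal((T, profile.n_points, 2), dtype=np.float32)
        spec += np.float32(noise_sd) * noise.view(np.complex64)[..., 0]
    return spec


def synthesize_transient(
    profile: AcquisitionProfile,
    amplitudes: dict,
    condition: str,
    freq_offset_ppm: float = 0.0,
    phase_deg: float = 0.0,
    baseline: tuple = (0.0, 0.0),
    edit_efficiency: float = 1.0,
    width_scale: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "S00",
    index: int = 0,
) -> Transient:
    """Synthesise one transient.

    ``amplitudes`` maps metabolite name (tcr, tnaa, gaba, glx, naa_edit) to
    its peak area in tCr units at this acquisition time.  The edited
    signature (GABA+, Glx, negative tNAA) is injected only when
    ``condition == "ON"``.
    """
    if condition not in ("ON", "OFF"):
        raise ValueError(f"condition must be ON or OFF, got {condition!r}")
    is_on = np.array([condition == "ON"])
    spec = _build_spectra(
        profile,
        amplitudes,
        is_on,
        np.array([freq_offset_ppm]),
        np.array([np.deg2rad(phase_deg)]),
        baseline,
        edit_efficiency,
        width_scale,
        noise_sd,
        rng,
    )
    return Transient(
        subject_id=subject_id,
        index=index,
        condition=condition,
        spectrum=spec[0].astype(np.complex128),
        ppm=profile.ppm_axis(),
    )


def generate_tissue_fractions(
    n_subjects: int,
    seed: int,
    mean: tuple = (0.45, 0.35, 0.20),
    concentration: float = 120.0,
) -> pd.DataFrame:
    """Per-subject GM/WM/CSF voxel fractions from a Dirichlet draw.

    The Dirichlet parameters are ``mean * concentration``, so the sample
    means match ``mean`` and fractions sum to one by construction.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = np.asarray(mean, dtype=float) * concentration
    frac = rng.dirichlet(alpha, size=n_subjects)
    return pd.DataFrame(frac, columns=["gm", "wm", "csf"])


def simulate_cohort(
    profile: AcquisitionProfile,
    truth: GroundTruth,
    n_subjects: int,
    seed: int,
    broad_linewidth_subjects: int = 0,
) -> Cohort:
    """Simulate a full cohort; deterministic for a fixed seed.

    Per subject, baseline areas are drawn from the configured normals, the
    per-transient amplitude of each metabolite follows
    ``base * (1 + drift_total * t/(T-1) + latent[bin(t)])``, and transients
    alternate OFF, ON, ... .  ``broad_linewidth_subjects`` makes the first k
    subjects' lines 1.6x wider (a linewidth outlier, used to exercise the
    FWHM-based participant exclusion).

    The realised ground truth (including the latent series) is attached to
    the returned cohort.
    """
    if n_subjects < 2:
        raise ConfigurationError("n_subjects must be >= 2")
    truth.validate()
    N = profile.n_transients
    tpb = int(truth.transients_per_bin)
    n_bins = -(-N // tpb)  # ceil: partial final bin shares the last latent value

    rng = np.random.default_rng(seed)
    latent_seed = int(rng.integers(2**31 - 1))
    tissue_seed = int(rng.integers(2**31 - 1))
    subject_seeds = rng.integers(2**31 - 1, size=n_subjects)

    latents = simulate_latent_timecourses(truth, n_bins, latent_seed)
    tissue = generate_tissue_fractions(
        n_subjects, tissue_seed, truth.tissue_mean, truth.tissue_concentration
    )

    is_on = np.arange(N) % 2 == 1  # OFF first
    t_frac = np.arange(N) / (N - 1)
    bin_of = np.minimum(np.arange(N) // tpb, n_bins - 1)
    latent_of = {
        "gaba": latents.gaba[bin_of],
        "glx": latents.glx[bin_of],
    }

    spectra = np.empty((n_subjects, N, profile.n_points), dtype=np.complex64)
    for s in range(n_subjects):
        srng = np.random.default_rng(int(subject_seeds[s]))
        base = {
            met: max(
                srng.normal(truth.baseline_mean[met], truth.baseline_sd.get(met, 0.0)),
                0.05 * truth.baseline_mean[met],
            )
            for met in truth.baseline_mean
        }
        width_scale = max(srng.normal(1.0, 0.05), 0.7)
        if s < broad_linewidth_subjects:
            width_scale *= 1.6
        b0 = srng.normal(0.0, 0.03)
        b1 = srng.normal(0.0, 0.01)
        amps = {}
        for met in ("tcr", "tnaa", "gaba", "glx", "naa_edit"):
            ramp = 1.0 + truth.drift_total.get(met, 0.0) * t_frac
            ramp = ramp + latent_of.get(met, 0.0)
            amps[met] = np.maximum(base[met] * ramp, 0.0)
        freq_off = (
            srng.normal(0.0, truth.freq_jitter_ppm, size=N)
            + truth.scanner_drift_ppm * t_frac
        )
        phase = np.deg2rad(srng.normal(0.0, truth.phase_jitter_deg, size=N))
        spectra[s] = _build_spectra(
            profile,
            amps,
            is_on,
            freq_off,
            phase,
            (b0, b1),
            truth.edit_efficiency,
            width_scale,
            truth.noise_sd,
            srng,
        )

    subject_ids = [f"{profile.name}{s:03d}" for s in range(n_subjects)]
    return Cohort(
        profile=profile,
        spectra=spectra,
        is_on=is_on,
        subject_ids=subject_ids,
        tissue_fractions=tissue,
        truth=truth,
        latents={
            "gaba": latents.gaba,
            "glx": latents.glx,
            "transients_per_bin": tpb,
            "drift": latents.drift,
        },
    )
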