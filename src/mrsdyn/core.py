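"""Core domain types shared across the package.

The package works with MEGA-PRESS edited MRS data: sequences of single-shot
acquisitions ("transients") that alternate between an editing pulse applied
ON resonance (1.9 ppm) and OFF resonance (7.5 ppm).  The ON-OFF difference
spectrum isolates the coupled GABA+ (3.0 ppm) and Glx (~3.75 ppm) signals
plus a negative co-edited NAA lobe at 2.0 ppm; the OFF spectrum carries the
tCr (3.0 ppm) and tNAA (2.0 ppm) reference singlets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

#: chemical-shift reference of the carrier (residual water position, ppm)
WATER_PPM = 4.7

#: canonical peak centers (ppm)
PEAK_PPM = {
    "tcr": 3.0,
    "tnaa": 2.0,
    "gaba": 3.0,
    "glx": (3.71, 3.79),
    "naa_edit": 2.0,
    "water": WATER_PPM,
}

METABOLITES = ("gaba", "glx", "tnaa", "tcr")


class ConfigurationError(ValueError):
    """Raised when a profile, ground truth or pipeline config is invalid."""


@dataclass(frozen=True)
class AcquisitionProfile:
    """Acquisition geometry of a MEGA-PRESS time series.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"vc"`` (visual cortex) or ``"pcc"``
        (posterior cingulate cortex).
    n_transients : int
        Number of transients acquired (must be even; ON/OFF alternate).
    tr_s : float
        Repetition time between transients, seconds.
    n_points : int
        Spectral points per transient.
    sweep_hz : float
        Spectral width in Hz.
    larmor_mhz : float
        Proton frequency in MHz; numerically equal to Hz per ppm.
    residual_water : bool
        Include a broad residual component at 4.7 ppm (data acquired
        without water suppression).
    """

    name: str
    n_transients: int
    tr_s: float
    n_points: int
    sweep_hz: float = 2000.0
    larmor_mhz: float = 127.7
    residual_water: bool = False

    def __post_init__(self) -> None:
        if self.n_transients <= 0 or self.n_transients % 2 != 0:
            raise ConfigurationError(
                f"n_transients must be a positive even count, got {self.n_transients}"
            )
        if self.n_points < 512:
            raise ConfigurationError(f"n_points must be >= 512, got {self.n_points}")
        if self.tr_s <= 0:
            raise ConfigurationError(f"tr_s must be > 0, got {self.tr_s}")
        if self.sweep_hz <= 0:
            raise ConfigurationError(f"sweep_hz must be > 0, got {self.sweep_hz}")

    @property
    def hz_per_ppm(self) -> float:
        return self.larmor_mhz

    @property
    def duration_s(self) -> float:
        return self.n_transients * self.tr_s

    def ppm_axis(self) -> np.ndarray:
        """Chemical-shift axis, stored high-to-low ppm (field convention).

        The carrier sits at 4.7 ppm (water); the axis spans
        ``sweep_hz / larmor_mhz`` ppm symmetrically around it.
        """
        half = self.sweep_hz / (2.0 * self.larmor_mhz)
        return np.linspace(WATER_PPM + half, WATER_PPM - half, self.n_points)


#: visual-cortex profile: 256 transients of 2048 points, TR 3 s (13 min)
VC_PROFILE = AcquisitionProfile("vc", n_transients=256, tr_s=3.0, n_points=2048)

#: posterior-cingulate profile: 320 transients, TR 2 s, macromolecule/water
#: unsuppressed acquisitions carry a residual 4.7 ppm component
PCC_PROFILE = AcquisitionProfile(
    "pcc", n_transients=320, tr_s=2.0, n_points=2048, residual_water=True
)

PROFILES = {"vc": VC_PROFILE, "pcc": PCC_PROFILE}


def _vc_baseline_mean() -> dict:
    return {"gaba": 0.12, "glx": 1.00, "tnaa": 1.40, "tcr": 1.00, "naa_edit": 0.40}


def _vc_baseline_sd() -> dict:
    return {"gaba": 0.012, "glx": 0.08, "tnaa": 0.10, "tcr": 0.08, "naa_edit": 0.0}


@dataclass
class GroundTruth:
    """Statistical structure injected into a synthetic cohort.

    ``baseline_mean``/``baseline_sd`` give the across-subject distribution of
    peak areas in tCr units (tCr itself is the absolute scale).  ``drift_total``
    is the fractional endpoint-to-endpoint linear change of each metabolite's
    amplitude over the acquisition.  A cohort-shared latent AR(1) fluctuation
    (per high-resolution bin) modulates GABA+, and Glx receives a delayed
    anti-coupled copy of it: ``glx[t] = -kappa * g[t - delay] + e[t]``.
    """

    baseline_mean: dict = field(default_factory=_vc_baseline_mean)
    baseline_sd: dict = field(default_factory=_vc_baseline_sd)
    drift_total: dict = field(
        default_factory=lambda: {"gaba": -0.100, "glx": 0.054, "tnaa": 0.0, "tcr": 0.0}
    )
    #: stationary SD of the shared GABA+ AR(1) latent, fractional units per bin
    latent_sd: float = 0.02
    #: AR(1) coefficient of the latent, per 12 s bin
    latent_ar: float = 0.5
    #: strength of the delayed GABA+ -> Glx anti-coupling
    coupling_kappa: float = 1.5
    #: delay of the anti-coupling in high-resolution bins (10 bins = 120 s)
    coupling_delay_bins: int = 10
    #: SD of the independent innovation of the Glx latent, fractional units
    glx_innovation_sd: float = 0.006
    #: complex noise SD per spectral point per transient (tCr area units)
    noise_sd: float = 0.05
    #: per-transient frequency jitter SD, ppm
    freq_jitter_ppm: float = 0.0088
    #: total linear scanner frequency drift over the acquisition, ppm
    scanner_drift_ppm: float = 0.0
    #: per-transient zero-order phase jitter SD, degrees
    phase_jitter_deg: float = 2.0
    #: scale of the edited difference signature (GABA+, Glx, -tNAA)
    edit_efficiency: float = 1.0
    #: across-subject mean of (GM, WM, CSF) voxel fractions
    tissue_mean: tuple = (0.45, 0.35, 0.20)
    #: Dirichlet concentration of the tissue-fraction draw
    tissue_concentration: float = 120.0
    #: bins per latent step; the latent is piecewise constant over this many
    #: transients (4 transients x TR 3 s = 12 s for the VC profile)
    transients_per_bin: int = 4

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("latent_sd", "glx_innovation_sd", "noise_sd",
                     "freq_jitter_ppm", "phase_jitter_deg"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for met, d in self.drift_total.items():
            if not abs(d) < 1.0:
                raise ConfigurationError(
                    f"|drift_total[{met!r}]| must be < 1, got {d}"
                )
        if self.coupling_delay_bins < 0:
            raise ConfigurationError("coupling_delay_bins must be >= 0")
        if not 0 <= self.latent_ar < 1:
            raise ConfigurationError("latent_ar must be in [0, 1)")
        if abs(sum(self.tissue_mean) - 1.0) > 1e-9 or any(
            f < 0 or f >= 1 for f in self.tissue_mean
        ):
            raise ConfigurationError("tissue_mean must lie in [0,1) and sum to 1")

    @classmethod
    def vc_defaults(cls) -> "GroundTruth":
        """Visual-cortex conditions: opposing GABA+/Glx drift plus the
        delayed anti-coupling (120 s at 12 s bins)."""
        return cls()

    @classmethod
    def pcc_defaults(cls) -> "GroundTruth":
        """Posterior-cingulate conditions: stable concentrations (no drift,
        no shared fluctuation, no coupling), slightly lower frequency jitter."""
        return cls(
            drift_total={"gaba": 0.0, "glx": 0.0, "tnaa": 0.0, "tcr": 0.0},
            latent_sd=0.0,
            coupling_kappa=0.0,
            glx_innovation_sd=0.0,
            freq_jitter_ppm=0.0065,
            tissue_mean=(0.55, 0.33, 0.12),
            transients_per_bin=6,
        )

    @classmethod
    def null(cls, base: Optional["GroundTruth"] = None) -> "GroundTruth":
        """A no-signal variant: no drift, no shared latent, no coupling.

        Transient-level noise, jitter and subject variability are retained,
        so the null cohort is a pure negative control for the dynamic
        analyses.
        """
        gt = base if base is not None else cls.vc_defaults()
        d = asdict(gt)
        d["drift_total"] = {k: 0.0 for k in d["drift_total"]}
        d["latent_sd"] = 0.0
        d["coupling_kappa"] = 0.0
        d["glx_innovation_sd"] = 0.0
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissue_mean"] = list(self.tissue_mean)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["tissue_mean"] = tuple(d["tissue_mean"])
        return cls(**d)


@dataclass
class Transient:
    """A single acquired spectrum with its acquisition metadata."""

    subject_id: str
    index: int
    condition: str  # "ON" or "OFF"
    spectrum: np.ndarray  # complex, frequency domain
    ppm: np.ndarray  # decreasing ppm axis, same length

    def __post_init__(self) -> None:
        if len(self.spectrum) != len(self.ppm):
            raise ValueError("spectrum and ppm axis lengths differ")
        if self.condition not in ("ON", "OFF"):
            raise ValueError(f"condition must be ON or OFF, got {self.condition!r}")


@dataclass
class Cohort:
    """A cohort of per-subject MEGA-PRESS transient series.

    ``spectra`` is complex with shape (n_subjects, n_transients, n_points);
    ``is_on`` marks the editing condition per transient (shared alternation,
    OFF first).  ``tissue_fractions`` holds per-subject GM/WM/CSF columns.
    ``truth``/``latents`` are populated for synthetic cohorts only.
    """

    profile: AcquisitionProfile
    spectra: np.ndarray
    is_on: np.ndarray
    subject_ids: list
    tissue_fractions: pd.DataFrame
    truth: Optional[GroundTruth] = None
    latents: Optional[dict] = None

    def __post_init__(self) -> None:
        s = np.asarray(self.spectra)
        if s.ndim != 3 or s.shape[1] != self.profile.n_transients \
                or s.shape[2] != self.profile.n_points:
            raise ValueError(
                f"spectra shape {s.shape} does not match profile "
                f"({self.profile.n_transients} transients x {self.profile.n_points} points)"
            )
        self._ppm = self.profile.ppm_axis()

    @property
    def n_subjects(self) -> int:
        return self.spectra.shape[0]

    @property
    def ppm(self) -> np.ndarray:
        return self._ppm

    def transient(self, subject: int, index: int) -> Transient:
        return Transient(
            subject_id=str(self.subject_ids[subject]),
            index=index,
            condition="ON" if self.is_on[index] else "OFF",
            spectrum=self.spectra[subject, index],
            ppm=self.ppm,
        )
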