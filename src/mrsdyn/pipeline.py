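"""End-to-end orchestration: configuration, stage execution and the
CSV/manifest artifact bundle.

``run_pipeline`` executes simulate (optional) -> preprocess -> static
quantification and participant exclusion -> sliding-window analysis with
cluster permutation tests and controls -> high-resolution binning with the
lagged GABA+/Glx cross-correlation -> low/high cross-validation, and writes
every result table with a declared column schema plus a YAML run manifest
(config, seeds, versions, per-stage retention counts).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import PROFILES, Cohort, ConfigurationError, GroundTruth
from .dynamics_high import highres_analysis, peak_significant_negative_lag, validate_low_high
from .dynamics_low import lowres_analysis, interindividual_correlations
from .io import read_cohort, write_cohort, write_csv
from .preprocess import preprocess_cohort
from .quantify import partial_correlation_table, static_estimates
from .synthetic import simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "analyze_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run.

    Defaults follow the analysis conventions for the two acquisition
    profiles: sliding window width 128 (VC) / 192 (PCC) transients at step
    2, 4- / 6-transient (12 s) high-resolution bins, >= 25 overlapping bins
    per cross-correlation lag, 5000 permutations at alpha 0.05, and 3 SD
    outlier thresholds for transients and participants.
    """

    profile: str = "vc"
    n_subjects: int = 57
    seed: int = 1
    simulate: bool = True
    null_truth: bool = False
    cohort_path: str | None = None
    save_cohort: bool = False
    out_dir: str = "results"
    width: int | None = None  # profile default: 128 (vc) / 192 (pcc)
    step: int = 2
    bin_size: int | None = None  # profile default: 4 (vc) / 6 (pcc)
    min_overlap: int = 25
    n_perm: int = 5000
    alpha: float = 0.05
    outlier_k: float = 3.0
    fwhm_k: float = 3.0
    reference: str = "tcr"
    normalization: str = "change_from_first"
    scheme: str = "sign_flip"

    def validate(self) -> None:
        if self.profile not in PROFILES:
            raise ConfigurationError(f"unknown profile {self.profile!r}")
        prof = PROFILES[self.profile]
        width = self.width
        if width is not None and width > prof.n_transients:
            raise ConfigurationError(
                f"window width {width} exceeds {prof.n_transients} transients"
            )
        if not self.simulate and not self.cohort_path:
            raise ConfigurationError("either simulate=True or cohort_path required")
        if self.n_perm < 100:
            raise ConfigurationError("n_perm must be >= 100")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class PipelineResult:
    """In-memory handle on everything a pipeline run produced."""

    config: PipelineConfig
    cohort: Cohort
    pre: object
    static: pd.DataFrame
    included: np.ndarray
    low: object
    high: object
    validation: dict
    interindividual: pd.DataFrame
    counts: dict = field(default_factory=dict)


def _get_cohort(config: PipelineConfig) -> Cohort:
    if config.cohort_path and not config.simulate:
        return read_cohort(config.cohort_path)
    profile = PROFILES[config.profile]
    truth = (
        GroundTruth.vc_defaults() if config.profile == "vc" else GroundTruth.pcc_defaults()
    )
    if config.null_truth:
        truth = GroundTruth.null(truth)
    return simulate_cohort(profile, truth, config.n_subjects, config.seed)


def analyze_cohort(cohort: Cohort, config: PipelineConfig) -> PipelineResult:
    """Run every analysis stage on an in-memory cohort."""
    config.validate()
    pre = preprocess_cohort(cohort, k=config.outlier_k)
    static = static_estimates(pre, reference=config.reference, fwhm_k=config.fwhm_k)
    included = static["included"].to_numpy(dtype=bool)

    low = lowres_analysis(
        pre,
        width=config.width,
        step=config.step,
        reference=config.reference,
        n_perm=config.n_perm,
        alpha=config.alpha,
        seed=config.seed,
        scheme=config.scheme,
        mode=config.normalization,
        subject_mask=included,
    )
    high = highres_analysis(
        pre,
        bin_size=config.bin_size,
        reference=config.reference,
        min_overlap=config.min_overlap,
        n_perm=config.n_perm,
        alpha=config.alpha,
        seed=config.seed + 1,
        subject_mask=included,
    )

    validation = {}
    width_bins = low.plan.width // high.bin_size
    if width_bins * high.bin_size == low.plan.width:
        for met in ("gaba", "glx"):
            validation[met] = validate_low_high(
                low.tests[met].group_mean,
                low.plan.starts,
                high.traces[met],
                width_bins,
            )

    conc_change = {
        met: low.traces[met][:, -1] - low.traces[met][:, 0]
        for met in ("gaba", "glx")
    }
    fe_change = {
        met: low.control_traces[f"fit_error_{met}"][:, -1]
        - low.control_traces[f"fit_error_{met}"][:, 0]
        for met in ("gaba", "glx")
    }
    inter = interindividual_correlations(
        conc_change, fe_change, pre.freq_drift_ppm[included]
    )

    counts = {
        "n_subjects": int(cohort.n_subjects),
        "n_subjects_included": int(included.sum()),
        "n_transients": int(cohort.profile.n_transients),
        "n_transients_retained_mean": float(pre.retained.sum(axis=1).mean()),
        "n_windows": int(low.plan.n_windows),
        "n_bins": int(high.traces["gaba"].n_bins),
        "n_lags_per_direction": int(high.xcorr.lags_per_direction),
    }
    return PipelineResult(
        config=config,
        cohort=cohort,
        pre=pre,
        static=static,
        included=included,
        low=low,
        high=high,
        validation=validation,
        interindividual=inter,
        counts=counts,
    )


def _cluster_id_column(n: int, clusters: list) -> np.ndarray:
    ids = np.full(n, -1)
    for i, c in enumerate(clusters):
        ids[c["start"]:c["end"]] = i
    return ids


def _lowres_table(region: str, low) -> pd.DataFrame:
    rows = []
    for met, test in low.tests.items():
        ids = _cluster_id_column(low.plan.n_windows, test.clusters)
        rows.append(
            pd.DataFrame(
                {
                    "region": region,
                    "metabolite": met,
                    "time_s": low.plan.times_s,
                    "group_mean_pct": test.group_mean,
                    "sem": test.group_sem,
                    "t": test.t_map,
                    "significant": test.significant_mask,
                    "cluster_id": ids,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _controls_table(region: str, low) -> pd.DataFrame:
    rows = []
    for name, test in low.control_tests.items():
        ids = _cluster_id_column(low.plan.n_windows, test.clusters)
        rows.append(
            pd.DataFrame(
                {
                    "region": region,
                    "control": name,
                    "time_s": low.plan.times_s,
                    "group_mean": test.group_mean,
                    "sem": test.group_sem,
                    "t": test.t_map,
                    "significant": test.significant_mask,
                    "cluster_id": ids,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _highres_table(high) -> pd.DataFrame:
    rows = []
    for met in ("gaba", "glx", "tnaa"):
        tr = high.traces[met]
        rows.append(
            pd.DataFrame(
                {
                    "metabolite": met,
                    "time_s": tr.times_s,
                    "value": tr.values,
                    "value_pct": high.normalized[met],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _xcorr_table(high) -> pd.DataFrame:
    cc = high.xcorr
    from .dynamics_high import _t_from_r

    ids = _cluster_id_column(len(cc.r), cc.clusters)
    return pd.DataFrame(
        {
            "direction": np.where(
                cc.lag_bins < 0, "gaba_predicts_glx",
                np.where(cc.lag_bins > 0, "glx_predicts_gaba", "zero_lag"),
            ),
            "lag_s": cc.lags_s,
            "r": cc.r,
            "n": cc.n,
            "ci_lo": cc.ci_lo,
            "ci_hi": cc.ci_hi,
            "t": _t_from_r(cc.r, cc.n),
            "significant": cc.significant_mask,
            "cluster_id": ids,
        }
    )


def _quality_table(result: PipelineResult) -> pd.DataFrame:
    """Across-subject quality summary (FWHM, frequency drift, fit error)."""
    df = result.static[result.included]
    rows = []
    for met in ("gaba", "glx", "tnaa", "tcr"):
        rows.append(
            {
                "metric": f"fwhm_{met}_hz",
                "mean": df[f"fwhm_{met}_hz"].mean(),
                "sd": df[f"fwhm_{met}_hz"].std(),
            }
        )
        rows.append(
            {
                "metric": f"fit_error_{met}_pct",
                "mean": df[f"fit_error_{met}_pct"].mean(),
                "sd": df[f"fit_error_{met}_pct"].std(),
            }
        )
    drift = result.pre.freq_drift_ppm[result.included]
    rows.append(
        {"metric": "frequency_drift_ppm", "mean": float(np.nanmean(drift)),
         "sd": float(np.nanstd(drift, ddof=1))}
    )
    return pd.DataFrame(rows)


def _partial_corr_tables(result: PipelineResult) -> pd.DataFrame:
    """Partial correlations between static concentrations and between
    concentration changes, controlling the reference-peak area."""
    ref = result.config.reference
    df = result.static[result.included].reset_index(drop=True)
    static_vals = pd.DataFrame(
        {met: df[f"{met}_{ref}_corr"] for met in ("gaba", "glx", "tnaa")}
    )
    control = df[f"{ref}_area"].to_numpy()
    tab_static = partial_correlation_table(static_vals, control)
    tab_static.insert(0, "kind", "static")

    low = result.low
    change_vals = pd.DataFrame(
        {met: low.traces[met][:, -1] - low.traces[met][:, 0]
         for met in ("gaba", "glx", "tnaa")}
    )
    tab_change = partial_correlation_table(change_vals, control)
    tab_change.insert(0, "kind", "change")
    return pd.concat([tab_static, tab_change], ignore_index=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the artifact bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _get_cohort(config)
    if config.simulate and config.save_cohort:
        write_cohort(cohort, out / "cohort.h5")
    result = analyze_cohort(cohort, config)
    region = config.profile

    write_csv(result.static, out / "static_estimates.csv",
              "per-subject static ratios (raw + CSF-corrected) and quality metrics")
    write_csv(_quality_table(result), out / "quality_summary.csv",
              "across-subject spectral quality summary")
    write_csv(_partial_corr_tables(result), out / "partial_correlations.csv",
              "pairwise partial correlations controlling the reference area")
    write_csv(_lowres_table(region, result.low), out / "lowres_traces.csv",
              "sliding-window group change traces with cluster significance")
    write_csv(_controls_table(region, result.low), out / "lowres_controls.csv",
              "fit-error and edited-tNAA control traces")
    write_csv(result.interindividual, out / "interindividual_correlations.csv",
              "subject-level change vs fit-error change and frequency drift")
    write_csv(_highres_table(result.high), out / "highres_traces.csv",
              "across-subject binned concentration traces")
    write_csv(_xcorr_table(result.high), out / "crosscorr.csv",
              "lagged GABA+/Glx correlations with cluster significance")
    if result.validation:
        val = pd.DataFrame(
            [
                {"metabolite": met, "r": v["r"], "p": v["p"], "n": v["n"]}
                for met, v in result.validation.items()
            ]
        )
        write_csv(val, out / "validation_low_high.csv",
                  "correlation between low-res trace and smoothed high-res trace")

    peak_lag = peak_significant_negative_lag(result.high.xcorr)
    manifest = {
        "package": {"name": "mrsdyn", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": asdict(config),
        "counts": result.counts,
        "summary": {
            "max_change_pct": {
                met: result.low.max_group_change(met) for met in ("gaba", "glx", "tnaa")
            },
            "peak_significant_negative_lag_s": peak_lag,
            "validation_r": {m: v["r"] for m, v in result.validation.items()},
        },
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    logger.info("pipeline complete: %s", out)
    return result
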