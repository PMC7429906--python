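"""Low-resolution dynamic analysis: sliding-window traces per subject and
group inference with cluster-based permutation correction.

Each subject's transients are quantified over a sliding window (default
width 128 transients, step 2, i.e. 65 windows over a 256-transient series)
and expressed as percent change from the first window.  At every window a
one-sample two-sided t test against zero is computed across subjects;
contiguous same-sign windows whose |t| exceeds the point-wise critical value
form clusters scored by the sum of their t values.  Cluster masses are
compared against a permutation null distribution of maximal cluster masses
(positive and negative tails kept separate); clusters below the 95th null
percentile are disregarded.

The default permutation scheme flips the sign of each subject's whole trace
(valid exchangeability for a change-from-zero test, and it preserves the
strong autocorrelation that overlapping windows induce).  Shuffling each
subject's window labels is available as an alternative scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import PreprocessedCohort, _window_slice
from .quantify import quantify_batch

__all__ = [
    "WindowPlan",
    "sliding_windows",
    "window_quantification",
    "subject_change_trace",
    "change_traces",
    "ClusterTestResult",
    "cluster_permutation_test",
    "control_traces",
    "interindividual_correlations",
    "lowres_analysis",
    "LowResResult",
]

logger = logging.getLogger(__name__)

#: ppm range retained for windowed quantification (covers all fit windows)
QUANT_RANGE_PPM = (1.7, 4.2)


@dataclass(frozen=True)
class WindowPlan:
    """Half-open sliding-window index intervals over a transient series."""

    width: int
    step: int
    starts: np.ndarray
    tr_s: float

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def ranges(self) -> list:
        return [(int(s), int(s + self.width)) for s in self.starts]

    @property
    def times_s(self) -> np.ndarray:
        """Window-centre acquisition times in seconds."""
        return (self.starts + (self.width - 1) / 2.0) * self.tr_s


def sliding_windows(n_transients: int, width: int, step: int = 2, tr_s: float = 1.0) -> WindowPlan:
    """Plan ``floor((N - width)/step) + 1`` windows of ``width`` transients."""
    if not 0 < width <= n_transients:
        raise ValueError(
            f"window width must satisfy 0 < width <= {n_transients}, got {width}"
        )
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    n = (n_transients - width) // step + 1
    starts = np.arange(n) * step
    return WindowPlan(width=width, step=step, starts=starts, tr_s=tr_s)


def _windowed_condition_means(
    spectra: np.ndarray,
    is_on: np.ndarray,
    retained: np.ndarray,
    plan: WindowPlan,
) -> tuple:
    """Mean ON/OFF spectra per sliding window for one subject.

    Uses prefix sums over the transient axis, so the cost is independent of
    the window overlap.  Returns (mean_on, mean_off, valid) with shapes
    (W, P), (W, P), (W,); windows missing a condition are flagged invalid.
    """
    T = spectra.shape[0]
    keep_on = (retained & is_on).astype(spectra.real.dtype)
    keep_off = (retained & ~is_on).astype(spectra.real.dtype)
    cs_on = np.zeros((T + 1,) + spectra.shape[1:], dtype=spectra.dtype)
    cs_off = np.zeros_like(cs_on)
    np.cumsum(spectra * keep_on[:, None], axis=0, out=cs_on[1:])
    np.cumsum(spectra * keep_off[:, None], axis=0, out=cs_off[1:])
    cn_on = np.concatenate([[0], np.cumsum(keep_on)])
    cn_off = np.concatenate([[0], np.cumsum(keep_off)])

    a = plan.starts
    b = plan.starts + plan.width
    n_on = cn_on[b] - cn_on[a]
    n_off = cn_off[b] - cn_off[a]
    valid = (n_on > 0) & (n_off > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_on = (cs_on[b] - cs_on[a]) / np.where(n_on > 0, n_on, np.nan)[:, None]
        mean_off = (cs_off[b] - cs_off[a]) / np.where(n_off > 0, n_off, np.nan)[:, None]
    return mean_on, mean_off, valid


def window_quantification(
    pre: PreprocessedCohort,
    plan: WindowPlan,
    reference: str = "tcr",
) -> dict:
    """Quantify every (subject, window) selection of a preprocessed cohort.

    Returns a dict of (S, W) arrays: ``ratio_<met>`` for gaba/glx/tnaa
    against the reference, ``fit_error_<met>`` for all four peaks,
    ``naa_edit_area`` (magnitude of the edited negative tNAA lobe) and
    ``ok``; unquantifiable windows are NaN.
    """
    S = pre.corrected.shape[0]
    W = plan.n_windows
    ppm = pre.ppm
    sl = _window_slice(ppm, QUANT_RANGE_PPM)
    x = ppm[sl]

    off_all = np.empty((S, W, sl.stop - sl.start), dtype=np.complex128)
    dif_all = np.empty_like(off_all)
    valid = np.empty((S, W), dtype=bool)
    for s in range(S):
        mean_on, mean_off, v = _windowed_condition_means(
            pre.corrected[s, :, sl], pre.is_on, pre.retained[s], plan
        )
        off_all[s] = mean_off
        dif_all[s] = mean_on - mean_off
        valid[s] = v
        if not v.all():
            logger.warning(
                "subject %s: %d windows without both conditions",
                pre.cohort.subject_ids[s], int((~v).sum()),
            )

    flat_off = np.nan_to_num(off_all.reshape(S * W, -1))
    flat_dif = np.nan_to_num(dif_all.reshape(S * W, -1))
    res = quantify_batch(flat_off, flat_dif, x, pre.cohort.profile.hz_per_ppm)

    out = {}
    ok = valid.copy()
    for met in ("gaba", "glx", "tnaa", "tcr"):
        ok &= res[met]["ok"].reshape(S, W)
    out["ok"] = ok
    ref_area = res[reference]["area"].reshape(S, W)
    for met in ("gaba", "glx", "tnaa"):
        ratio = res[met]["area"].reshape(S, W) / ref_area
        out[f"ratio_{met}"] = np.where(ok, ratio, np.nan)
    for met in ("gaba", "glx", "tnaa", "tcr"):
        fe = res[met]["fit_error_pct"].reshape(S, W)
        out[f"fit_error_{met}"] = np.where(ok, fe, np.nan)
    out["naa_edit_area"] = np.where(
        ok & res["naa_edit"]["ok"].reshape(S, W),
        res["naa_edit"]["area"].reshape(S, W),
        np.nan,
    )
    return out


def change_traces(values: np.ndarray, mode: str = "change_from_first") -> np.ndarray:
    """Per-subject traces normalised to percent change.

    ``change_from_first``: 100 (v - v0) / v0 (first window == 0);
    ``percent_of_mean``: 100 (v - mean) / mean (subject-mean == 0);
    ``difference_from_first``: v - v0 in the variable's own units (used for
    fit-error traces, which are already percentages).
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if mode == "change_from_first":
        v0 = v[:, [0]]
        return 100.0 * (v - v0) / v0
    if mode == "percent_of_mean":
        m = np.nanmean(v, axis=1, keepdims=True)
        return 100.0 * (v - m) / m
    if mode == "difference_from_first":
        return v - v[:, [0]]
    raise ValueError(f"unknown normalisation mode {mode!r}")


def subject_change_trace(
    pre: PreprocessedCohort,
    subject: int,
    plan: WindowPlan,
    metabolite: str = "gaba",
    reference: str = "tcr",
    mode: str = "change_from_first",
) -> pd.DataFrame:
    """Sliding-window percent-change trace for one subject."""
    sub = PreprocessedCohort(
        cohort=pre.cohort,
        corrected=pre.corrected[[subject]],
        freq_ppm=pre.freq_ppm[[subject]],
        phase_deg=pre.phase_deg[[subject]],
        area=pre.area[[subject]],
        fwhm_hz=pre.fwhm_hz[[subject]],
        fit_ok=pre.fit_ok[[subject]],
        retained=pre.retained[[subject]],
        freq_drift_ppm=pre.freq_drift_ppm[[subject]],
    )
    wq = window_quantification(sub, plan, reference)
    trace = change_traces(wq[f"ratio_{metabolite}"], mode)[0]
    return pd.DataFrame(
        {"time_s": plan.times_s, "change_pct": trace}
    )


# ------------------------------------------------------- cluster inference

def _max_run_masses(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Max sum of ``vals`` over contiguous True runs, per row.

    ``vals`` and ``mask`` are (P, W); values outside the mask are ignored.
    Rows without any run return 0.
    """
    P, W = vals.shape
    padded = np.zeros((P, W + 1), dtype=bool)
    padded[:, :W] = mask
    vpad = np.zeros((P, W + 1))
    vpad[:, :W] = np.where(mask, vals, 0.0)
    flat_mask = padded.ravel()
    flat_vals = vpad.ravel()
    d = np.diff(flat_mask.astype(np.int8), prepend=np.int8(0))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    cs = np.concatenate([[0.0], np.cumsum(flat_vals)])
    masses = cs[ends] - cs[starts]
    out = np.zeros(P)
    np.maximum.at(out, starts // (W + 1), masses)
    return out


def _clusters_from_tmap(t_map: np.ndarray, crit: np.ndarray) -> list:
    """Maximal same-sign threshold-exceeding runs with their summed t."""
    clusters = []
    for sign, exceed in ((1, t_map > crit), (-1, t_map < -crit)):
        idx = np.nonzero(exceed)[0]
        if idx.size == 0:
            continue
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        for seg in np.split(idx, breaks + 1):
            clusters.append(
                {
                    "start": int(seg[0]),
                    "end": int(seg[-1] + 1),
                    "sign": sign,
                    "mass": float(t_map[seg].sum()),
                }
            )
    return sorted(clusters, key=lambda c: c["start"])


def _t_one_sample(x: np.ndarray, mask: np.ndarray) -> tuple:
    """Column-wise one-sample t statistics over masked data.

    Returns (t, n); columns with zero variance (e.g. the all-zero first
    window of change traces) get t = 0.
    """
    n = mask.sum(axis=0)
    xs = np.where(mask, x, 0.0)
    s1 = xs.sum(axis=0)
    s2 = (xs * xs).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n
        var = (s2 - n * mean * mean) / (n - 1)
        var = np.maximum(var, 0.0)
        t = mean / np.sqrt(var / n)
    t = np.where((var <= 1e-300) | (n < 2), 0.0, t)
    return t, n


@dataclass
class ClusterTestResult:
    """Cluster-corrected one-sample test of a set of subject traces."""

    t_map: np.ndarray
    crit: np.ndarray
    clusters: list
    null_pos_q: float
    null_neg_q: float
    significant_mask: np.ndarray
    n_perm: int
    scheme: str
    group_mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    group_sem: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def any_significant(self) -> bool:
        return bool(self.significant_mask.any())


def cluster_permutation_test(
    traces: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str = "sign_flip",
) -> ClusterTestResult:
    """Cluster-based permutation test of subject traces against zero.

    Parameters
    ----------
    traces : (n_subjects, n_windows) array
        Per-subject change traces; NaN marks missing windows (excluded
        pairwise).
    scheme : {"sign_flip", "shuffle_windows"}
        Exchangeability unit of the permutation null: whole-trace sign
        flips (default) or independent shuffles of each subject's window
        labels.
    """
    x = np.atleast_2d(np.asarray(traces, dtype=float))
    S, W = x.shape
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mask = np.isfinite(x)
    n = mask.sum(axis=0)
    if (n == 0).any():
        w = int(np.nonzero(n == 0)[0][0])
        raise ValueError(f"window {w} has no non-missing values")
    if (n < 3).any():
        raise ValueError("every window needs >= 3 subjects with values")

    t_map, _ = _t_one_sample(x, mask)
    crit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    clusters = _clusters_from_tmap(t_map, crit)

    rng = np.random.default_rng(seed)
    xs = np.where(mask, x, 0.0)
    if scheme == "sign_flip":
        flips = rng.integers(0, 2, size=(n_perm, S)) * 2.0 - 1.0
        s1 = flips @ xs  # (n_perm, W)
        s2 = (xs * xs).sum(axis=0)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s1 / n
            var = np.maximum((s2 - n * mean * mean) / (n - 1), 0.0)
            t_null = mean / np.sqrt(var / n)
        t_null = np.where(var <= 1e-300, 0.0, t_null)
        crit_null = crit[None, :]
    elif scheme == "shuffle_windows":
        t_null = np.empty((n_perm, W))
        n_null = np.empty((n_perm, W))
        for p in range(n_perm):
            idx = np.argsort(rng.random((S, W)), axis=1)
            xp = np.take_along_axis(x, idx, axis=1)
            mp = np.isfinite(xp)
            t_null[p], n_null[p] = _t_one_sample(np.where(mp, xp, 0.0), mp)
        bad = n_null < 2
        t_null[bad] = 0.0
        crit_null = stats.t.ppf(1.0 - alpha / 2.0, np.maximum(n_null - 1, 1))
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    max_pos = _max_run_masses(t_null, t_null > crit_null)
    max_neg = _max_run_masses(-t_null, t_null < -crit_null)
    # positive and negative tails are tested separately, so each uses the
    # 1 - alpha/2 null quantile to keep the two-sided family-wise rate alpha
    q = 100.0 * (1.0 - alpha / 2.0)
    pos_q = float(np.percentile(max_pos, q))
    neg_q = float(np.percentile(max_neg, q))

    sig_mask = np.zeros(W, dtype=bool)
    for c in clusters:
        null = max_pos if c["sign"] > 0 else max_neg
        m = abs(c["mass"])
        c["p"] = float((1 + np.sum(null >= m)) / (n_perm + 1))
        c["significant"] = bool(m > (pos_q if c["sign"] > 0 else neg_q))
        if c["significant"]:
            sig_mask[c["start"]:c["end"]] = True

    mean = np.nanmean(x, axis=0)
    sem = np.nanstd(x, axis=0, ddof=1) / np.sqrt(n)
    return ClusterTestResult(
        t_map=t_map,
        crit=crit,
        clusters=clusters,
        null_pos_q=pos_q,
        null_neg_q=neg_q,
        significant_mask=sig_mask,
        n_perm=n_perm,
        scheme=scheme,
        group_mean=mean,
        group_sem=sem,
    )


# ----------------------------------------------------------- orchestration

@dataclass
class LowResResult:
    """Sliding-window analysis bundle for one cohort."""

    plan: WindowPlan
    reference: str
    traces: dict  # metabolite -> (S, W) percent-change traces
    tests: dict  # metabolite -> ClusterTestResult
    window_quant: dict
    control_tests: dict = field(default_factory=dict)
    control_traces: dict = field(default_factory=dict)

    def max_group_change(self, metabolite: str) -> float:
        """Extremum (largest |value|) of the group-mean change trace, %."""
        m = self.tests[metabolite].group_mean
        return float(m[np.nanargmax(np.abs(m))])


def control_traces(
    wq: dict,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str = "sign_flip",
) -> tuple:
    """Fit-error traces and the edited negative-tNAA amplitude trace, with
    their cluster tests.

    Fit-error traces are differences from the first window (already in
    percent units); the negative-tNAA edit amplitude uses percent change,
    like the concentration traces.
    """
    traces = {}
    tests = {}
    for i, met in enumerate(("gaba", "glx", "tnaa", "tcr")):
        tr = change_traces(wq[f"fit_error_{met}"], "difference_from_first")
        traces[f"fit_error_{met}"] = tr
        tests[f"fit_error_{met}"] = cluster_permutation_test(
            tr, n_perm=n_perm, alpha=alpha, seed=seed + i, scheme=scheme
        )
    tr = change_traces(wq["naa_edit_area"], "change_from_first")
    traces["naa_edit"] = tr
    tests["naa_edit"] = cluster_permutation_test(
        tr, n_perm=n_perm, alpha=alpha, seed=seed + 4, scheme=scheme
    )
    return traces, tests


def lowres_analysis(
    pre: PreprocessedCohort,
    width: int | None = None,
    step: int = 2,
    reference: str = "tcr",
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str = "sign_flip",
    mode: str = "change_from_first",
    subject_mask: np.ndarray | None = None,
    with_controls: bool = True,
) -> LowResResult:
    """Full sliding-window group analysis of a preprocessed cohort.

    ``width`` defaults to 128 transients for 256-transient acquisitions and
    192 for 320 (matching the ~6.4 min window duration across profiles).
    """
    profile = pre.cohort.profile
    if width is None:
        width = {256: 128, 320: 192}.get(profile.n_transients, profile.n_transients // 2)
    plan = sliding_windows(profile.n_transients, width, step, profile.tr_s)

    sub = pre
    if subject_mask is not None:
        subject_mask = np.asarray(subject_mask, dtype=bool)
        sub = PreprocessedCohort(
            cohort=pre.cohort,
            corrected=pre.corrected[subject_mask],
            freq_ppm=pre.freq_ppm[subject_mask],
            phase_deg=pre.phase_deg[subject_mask],
            area=pre.area[subject_mask],
            fwhm_hz=pre.fwhm_hz[subject_mask],
            fit_ok=pre.fit_ok[subject_mask],
            retained=pre.retained[subject_mask],
            freq_drift_ppm=pre.freq_drift_ppm[subject_mask],
        )

    wq = window_quantification(sub, plan, reference)
    traces = {}
    tests = {}
    for i, met in enumerate(("gaba", "glx", "tnaa")):
        tr = change_traces(wq[f"ratio_{met}"], mode)
        traces[met] = tr
        tests[met] = cluster_permutation_test(
            tr, n_perm=n_perm, alpha=alpha, seed=seed + 10 * i, scheme=scheme
        )
    ctr_traces, ctr_tests = ({}, {})
    if with_controls:
        ctr_traces, ctr_tests = control_traces(
            wq, n_perm=n_perm, alpha=alpha, seed=seed + 100, scheme=scheme
        )
    return LowResResult(
        plan=plan,
        reference=reference,
        traces=traces,
        tests=tests,
        window_quant=wq,
        control_tests=ctr_tests,
        control_traces=ctr_traces,
    )


def interindividual_correlations(
    concentration_change: dict,
    fit_error_change: dict,
    freq_drift_ppm: np.ndarray,
) -> pd.DataFrame:
    """Across-subject Pearson correlations of concentration change against
    fit-error change and frequency drift.

    ``concentration_change`` and ``fit_error_change`` map metabolite name to
    per-subject scalars (last-minus-first window change).
    """
    drift = np.asarray(freq_drift_ppm, dtype=float)
    rows = []
    for met, dc in concentration_change.items():
        dc = np.asarray(dc, dtype=float)
        if len(dc) < 4:
            raise ValueError("interindividual correlations need >= 4 subjects")
        for name, other in (
            ("fit_error_change", np.asarray(fit_error_change[met], dtype=float)),
            ("frequency_drift", drift),
        ):
            keep = np.isfinite(dc) & np.isfinite(other)
            a, b = dc[keep], other[keep]
            if len(a) < 4:
                raise ValueError("interindividual correlations need >= 4 subjects")
            if a.std() == 0 or b.std() == 0:
                raise ValueError("zero variance in correlation input")
            r, p = stats.pearsonr(a, b)
            rows.append({"metabolite": met, "against": name, "r": r, "p": p, "n": len(a)})
    return pd.DataFrame(rows)
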