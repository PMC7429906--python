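"""Simple trace and cross-correlation figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .dynamics_high import CrossCorrResult, smooth_trace  # noqa: E402

__all__ = ["plot_lowres_traces", "plot_crosscorr", "plot_highres_traces"]

_COLORS = {"gaba": "#c0392b", "glx": "#2980b9", "tnaa": "#7f8c8d"}


def plot_lowres_traces(low, path) -> Path:
    """Group-mean sliding-window change traces with significant periods."""
    fig, ax = plt.subplots(figsize=(7, 4))
    t = low.plan.times_s
    for met, test in low.tests.items():
        c = _COLORS.get(met, None)
        ax.plot(t, test.group_mean, label=f"{met}:{low.reference}", color=c)
        ax.fill_between(
            t,
            test.group_mean - test.group_sem,
            test.group_mean + test.group_sem,
            alpha=0.2,
            color=c,
        )
        if test.significant_mask.any():
            y = test.group_mean.min() - 0.5
            ax.plot(t[test.significant_mask],
                    [y] * int(test.significant_mask.sum()),
                    ".", ms=3, color=c)
    ax.axhline(0.0, ls="--", c="k", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("change from first window (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_highres_traces(high, path, smooth_window: int = 8) -> Path:
    """Binned across-subject traces, raw plus smoothed overlay."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for met in ("gaba", "glx"):
        tr = high.traces[met]
        c = _COLORS.get(met)
        ax.plot(tr.times_s, high.normalized[met], color=c, alpha=0.3)
        ax.plot(tr.times_s, smooth_trace(high.normalized[met], smooth_window),
                color=c, label=met)
    ax.axhline(0.0, ls="--", c="k", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("change (% of mean)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_crosscorr(cc: CrossCorrResult, path) -> Path:
    """Per-lag correlations with Fisher-z CIs; significant lags highlighted."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.vlines(cc.lags_s, cc.ci_lo, cc.ci_hi, color="0.7", lw=1)
    ax.plot(cc.lags_s, cc.r, "o", ms=3, color="0.3", label="r")
    if cc.significant_mask.any():
        ax.plot(cc.lags_s[cc.significant_mask], cc.r[cc.significant_mask],
                "o", ms=5, color="#27ae60", label="significant")
    ax.axhline(0.0, ls="--", c="k", lw=0.8)
    ax.axvline(0.0, ls=":", c="k", lw=0.8)
    ax.set_xlabel("lag (s)  [negative: GABA+ predicts Glx]")
    ax.set_ylabel("Pearson r")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
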