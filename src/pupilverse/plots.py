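"""Matplotlib renderings of the multiverse outputs.

All functions accept tidy result tables (so plots can be re-rendered from
CSV alone) and return a matplotlib Figure.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_FORK_FIELDS = [
    "extreme_filter",
    "aoi_filter",
    "gap_handling",
    "baseline_ms",
    "participant_rule",
]

_COLORS = {"positive": "#2166ac", "negative": "#b2182b", "none": "#999999"}


def plot_spec_curve(estimates: pd.DataFrame):
    """Specification curve: sorted estimates with CIs plus the fork matrix."""
    est = estimates[~estimates["absent"].fillna(False)].reset_index(drop=True)
    est = est.sort_values("estimate").reset_index(drop=True)
    n = len(est)
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(12, 9), sharex=True,
        gridspec_kw={"height_ratios": [2, 3]},
    )
    x = np.arange(n)
    colors = [_COLORS.get(d, "#999999") for d in est["direction"]]
    ax1.vlines(x, est["ci_low"], est["ci_high"], color=colors, alpha=0.6, lw=1)
    ax1.scatter(x, est["estimate"], c=colors, s=12, zorder=3)
    ax1.axhline(0.0, color="k", lw=0.8, ls="--")
    ax1.set_ylabel("Visual - Audiovisual effect (mm)")
    ax1.set_title("Specification curve of the familiarization-block effect")

    rows = []
    labels = []
    for field in _FORK_FIELDS + ["model_kind"]:
        for level in sorted(est[field].astype(str).unique()):
            rows.append((est[field].astype(str) == level).to_numpy())
            labels.append(f"{field}: {level}")
    mat = np.array(rows)
    for i, row in enumerate(mat):
        xs = x[row]
        ax2.scatter(xs, np.full(len(xs), i), marker="|", s=40, color="#333333")
    ax2.set_yticks(np.arange(len(labels)))
    ax2.set_yticklabels(labels, fontsize=7)
    ax2.set_xlabel("specification (sorted by estimate)")
    ax2.invert_yaxis()
    fig.tight_layout()
    return fig


def plot_model_comparison(comparisons: pd.DataFrame):
    """Delta-BIC and R^2 of both models across the lattice."""
    comp = comparisons[comparisons["status"] == "ok"].reset_index(drop=True)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(12, 7), sharex=True)
    x = np.arange(len(comp))
    loser_delta = comp["delta_bic"].to_numpy(dtype=float)
    time_wins = comp["winner"] == "time_model"
    delta_time = np.where(time_wins, 0.0, loser_delta)
    delta_no_time = np.where(time_wins, loser_delta, 0.0)
    ax1.plot(x, delta_time, "o-", ms=4, label="time model", color="#2166ac")
    ax1.plot(x, delta_no_time, "s-", ms=4, label="no-time model", color="#b2182b")
    ax1.set_ylabel("delta BIC (0 = best)")
    ax1.legend()
    ax2.plot(x, comp["r2_time"], "o-", ms=4, label="time model", color="#2166ac")
    ax2.plot(x, comp["r2_no_time"], "s-", ms=4, label="no-time model", color="#b2182b")
    ax2.set_ylabel("adjusted R^2")
    ax2.set_xlabel("dataset")
    ax2.set_xticks(x)
    ax2.set_xticklabels(comp["fork"], rotation=90, fontsize=6)
    ax2.legend()
    fig.tight_layout()
    return fig


def plot_difference_smooth(smooth: pd.DataFrame, token: str | None = None):
    """Condition-difference curve over time with CI band and significant windows.

    ``smooth`` needs columns t, diff, ci_low, ci_high (one fork; filter by
    ``token`` if a combined table is passed).
    """
    if token is not None and "fork" in smooth.columns:
        smooth = smooth[smooth["fork"] == token]
    fig, ax = plt.subplots(figsize=(8, 5))
    t = smooth["t"].to_numpy(dtype=float)
    ax.plot(t, smooth["diff"], color="#2166ac")
    ax.fill_between(t, smooth["ci_low"], smooth["ci_high"], alpha=0.25, color="#2166ac")
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    sig = (smooth["ci_low"].to_numpy() > 0) | (smooth["ci_high"].to_numpy() < 0)
    if sig.any():
        ax.scatter(t[sig], np.zeros(sig.sum()), marker="|", color="#b2182b", s=60)
    ax.set_xlabel("trial time (ms)")
    ax.set_ylabel("Visual - Audiovisual difference (mm)")
    title = "Estimated condition difference over time"
    if token:
        title += f" ({token})"
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_diagnostics(diag: dict):
    """Missingness / blink diagnostic panels."""
    fig, axes = plt.subplots(2, 2, figsize=(12, 8))
    ep = diag["eye_patterns"]
    axes[0, 0].bar(ep["pattern"], ep["n_samples"], color="#555555")
    axes[0, 0].set_title("Eye missingness patterns")
    axes[0, 0].tick_params(axis="x", rotation=20)

    miss = diag["missingness"]
    colors = np.where(miss["flagged"], "#b2182b", "#555555")
    axes[0, 1].bar(miss["participant_id"].astype(str), miss["percent_missing"], color=colors)
    axes[0, 1].axhline(30.0, color="#b2182b", ls="--", lw=1)
    axes[0, 1].set_title("Percent missing by participant (30% cut-off)")

    bc = diag["blink_counts"]
    for (ef, af), grp in bc.groupby(["extreme_filter", "aoi_filter"]):
        axes[1, 0].plot(
            grp["participant_id"], grp["n_blinks"], "o-", ms=3, label=f"{ef}/{af}"
        )
    axes[1, 0].legend(fontsize=7)
    axes[1, 0].set_title("Blink counts per participant by filter variant")
    axes[1, 0].set_xlabel("participant")

    tl = diag["trackloss_by_trial"]
    pivot = tl.pivot_table(
        index="participant_id", columns=["block", "trial"], values="missing_fraction"
    )
    im = axes[1, 1].imshow(pivot.to_numpy(), aspect="auto", cmap="Reds", vmin=0, vmax=1)
    axes[1, 1].set_title("Missing fraction by participant and trial")
    axes[1, 1].set_xlabel("block x trial")
    axes[1, 1].set_ylabel("participant")
    fig.colorbar(im, ax=axes[1, 1], shrink=0.8)
    fig.tight_layout()
    return fig
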