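"""Figures and markdown summary for a pipeline run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from adhertraj import gbtm

GROUP_COLORS = ["#1b7837", "#f5a623", "#c0392b", "#2980b9", "#8e44ad", "#16a085", "#7f8c8d"]


def plot_trajectories(model, panel, path) -> None:
    """Modeled mean PDC per group over time with 95% CI bands."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    t_grid = np.linspace(0, model.time_denom, 50)
    for j in range(model.J):
        pred = gbtm.predicted_trajectory(model, j, t_grid, panel=panel)
        c = GROUP_COLORS[j % len(GROUP_COLORS)]
        ax.plot(t_grid / 2, pred["mean_pdc"], "--", color=c,
                label=f"group {j + 1} ({model.pi[j]:.0%})")
        if "ci_low" in pred:
            ax.fill_between(t_grid / 2, pred["ci_low"], pred["ci_high"], color=c, alpha=0.2)
    ax.set_xlabel("years since AET initiation")
    ax.set_ylabel("proportion of days covered")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spaghetti(panel, assignments, group, path, max_lines: int = 100, seed: int = 0) -> None:
    """Observed per-patient PDC series for one assigned group."""
    merged = panel.merge(assignments[["patient_id", "assigned_group"]], on="patient_id")
    sub = merged[merged["assigned_group"] == group]
    ids = sub["patient_id"].unique()
    if len(ids) > max_lines:
        ids = np.random.default_rng(seed).choice(ids, max_lines, replace=False)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for pid in ids:
        s = sub[sub["patient_id"] == pid].sort_values("t")
        ax.plot(s["t"] / 2, s["pdc"], color="grey", alpha=0.25, lw=0.8)
    mean = sub.groupby("t")["pdc"].mean()
    ax.plot(mean.index / 2, mean.values, color=GROUP_COLORS[(group - 1) % len(GROUP_COLORS)], lw=2)
    ax.set_xlabel("years since AET initiation")
    ax.set_ylabel("PDC")
    ax.set_ylim(0, 1)
    ax.set_title(f"assigned group {group}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_forest(or_table: pd.DataFrame, path) -> None:
    """Forest plot of ORs (log scale) per exposure level and outcome group."""
    rows = or_table[or_table["OR"] != 1.0].reset_index(drop=True)
    if rows.empty:
        return
    fig, ax = plt.subplots(figsize=(7, max(3, 0.28 * len(rows))))
    y = np.arange(len(rows))[::-1]
    for g, sub in rows.groupby("outcome_group"):
        c = GROUP_COLORS[(int(g) - 1) % len(GROUP_COLORS)]
        yy = y[sub.index]
        ax.errorbar(
            sub["OR"], yy,
            xerr=[sub["OR"] - sub["ci_low"], sub["ci_high"] - sub["OR"]],
            fmt="o", color=c, ms=4, lw=1, capsize=2, label=f"group {g} vs reference",
        )
    ax.axvline(1.0, color="k", lw=0.8)
    ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(rows["exposure"] + "=" + rows["level"], fontsize=7)
    ax.set_xlabel("odds ratio (95% CI)")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(report, model, panel, assignments, out_dir) -> list[str]:
    """Write trajectory, spaghetti and forest figures plus summary.md."""
    out = Path(out_dir)
    paths = []
    p = out / "trajectory_plot.png"
    plot_trajectories(model, panel, p)
    paths.append(str(p))
    for j in range(1, model.J + 1):
        p = out / f"spaghetti_{j}.png"
        plot_spaghetti(panel, assignments, j, p)
        paths.append(str(p))
    p = out / "forest.png"
    plot_forest(report.or_tables, p)
    paths.append(str(p))

    lines = [
        "# Adherence trajectory run summary",
        "",
        f"- package version: {report.version}, seed: {report.seed}",
        "",
        "## Eligibility cascade",
        "",
        f"starting count: {report.exclusions['starting_count']}",
        "",
    ]
    for step in report.exclusions["steps"]:
        lines.append(f"- {step['step']}: removed {step['removed']}, remaining {step['remaining']}")
    lines += [
        "",
        "## Selected trajectory model",
        "",
        f"- groups: {report.model['J']}, polynomial orders: {report.model['orders']}",
        f"- mixing proportions: {[round(p, 3) for p in report.model['pi']]}",
        f"- BIC: {report.model['bic']:.1f}, sigma: {report.model['sigma']:.3f}",
        "",
        "## Assigned group shares",
        "",
    ]
    n = len(assignments)
    for key, share in report.group_shares.items():
        lines.append(f"- {key}: {share * 100:.1f}% ({int(round(share * n))}/{n})")
    lines += ["", "## Diagnostics", ""]
    for j, (a, o) in enumerate(zip(report.diagnostics["appa"], report.diagnostics["occ"])):
        lines.append(f"- group {j + 1}: APPA {a:.3f}, OCC {o:.1f}")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    paths.append(str(out / "summary.md"))
    return paths
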