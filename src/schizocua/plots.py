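"""Plot rendering from the CSV artifacts (data series only, no styling ambitions)."""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["render_plots"]


def _save(fig, path: Path) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _empty(df: pd.DataFrame, name: str) -> bool:
    if df.empty:
        warnings.warn(f"{name}: empty input, plot skipped", stacklevel=3)
        return True
    return False


def plot_tornado(tornado_csv: Path, out: Path) -> Path | None:
    df = pd.read_csv(tornado_csv)
    if _empty(df, "tornado"):
        return None
    df = df.sort_values("width", ascending=True)  # widest ends up on top
    fig, ax = plt.subplots(figsize=(8, 0.35 * len(df) + 1.5))
    base = df[["icer_low", "icer_high"]].mean(axis=1)
    ax.barh(df["parameter_id"], df["icer_high"] - df["icer_low"],
            left=df["icer_low"], color="tab:red", alpha=0.6)
    ax.scatter(base, df["parameter_id"], color="k", s=6, zorder=3)
    ax.set_xlabel("ICER (USD/QALY)")
    ax.set_title("One-way sensitivity")
    return _save(fig, out)


def plot_ceac(ceac_csv: Path, out: Path) -> Path | None:
    df = pd.read_csv(ceac_csv)
    if _empty(df, "ceac"):
        return None
    fig, ax = plt.subplots(figsize=(7, 5))
    for comparison, grp in df.groupby("comparison"):
        ax.plot(grp["wtp"], grp["probability_cost_effective"], label=comparison)
        ax.plot(grp["wtp"], 1.0 - grp["probability_cost_effective"],
                linestyle="--", label=f"{comparison} (comparator)")
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return _save(fig, out)


def plot_scatter(psa_csv: Path, out: Path, wtp: float) -> Path | None:
    df = pd.read_csv(psa_csv)
    if _empty(df, "psa"):
        return None
    delta_cost_cols = [c for c in df.columns if c.startswith("delta_cost_")]
    fig, axes = plt.subplots(1, max(1, len(delta_cost_cols)),
                             figsize=(5 * max(1, len(delta_cost_cols)), 5),
                             squeeze=False)
    for ax, col in zip(axes[0], delta_cost_cols):
        comparison = col[len("delta_cost_"):]
        dq = df[f"delta_qaly_{comparison}"]
        ax.scatter(dq, df[col], s=6, alpha=0.5)
        lim = max(abs(dq).max(), 1e-9)
        ax.plot([-lim, lim], [-wtp * lim, wtp * lim], color="k", lw=1,
                label=f"WTP {wtp:,.0f}/QALY")
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel("Incremental QALYs")
        ax.set_ylabel("Incremental cost (USD)")
        ax.set_title(comparison)
        ax.legend(fontsize=8)
    return _save(fig, out)


def plot_scenario(scenario_csv: Path, out: Path) -> Path | None:
    df = pd.read_csv(scenario_csv)
    if _empty(df, "scenario"):
        return None
    axis_name = df["axis_name"].iloc[0]
    fig, ax = plt.subplots(figsize=(7, 5))
    for comparison, grp in df.groupby("comparison"):
        grp = grp.sort_values("axis_value")
        ax.plot(grp["axis_value"], grp["icer"], marker="o", label=comparison)
    ax.set_xlabel(axis_name)
    ax.set_ylabel("ICER (USD/QALY)")
    ax.legend(fontsize=8)
    return _save(fig, out)


def render_plots(output_directory: str | Path, wtp: float = 12_756.55) -> list[Path]:
    """Render every known CSV artifact found in a run directory.

    Plot failures never corrupt CSVs; missing artifacts are skipped.
    """
    outdir = Path(output_directory)
    produced: list[Path] = []

    def maybe(fn, src: str, dst: str, *args):
        path = outdir / src
        if path.exists():
            result = fn(path, outdir / dst, *args)
            if result is not None:
                produced.append(result)

    maybe(plot_tornado, "tornado.csv", "tornado.png")
    maybe(plot_ceac, "ceac.csv", "ceac.png")
    maybe(plot_scatter, "psa_samples.csv", "psa_scatter.png", wtp)
    for csv in sorted(outdir.glob("scenario_*.csv")):
        result = plot_scenario(csv, csv.with_suffix(".png"))
        if result is not None:
            produced.append(result)
    maybe(plot_scenario, "icer_by_cycle.csv", "icer_by_cycle.png")
    return produced
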