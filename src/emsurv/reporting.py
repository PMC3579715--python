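"""Human-readable summaries and plots of scenario results."""

from __future__ import annotations

import pathlib
from typing import Any

import pandas as pd


def _fmt(value: float, rounding: str) -> str:
    return f"{value:.0f}" if rounding == "integer" else f"{value:.1f}"


def summarise(results: dict[str, Any], rounding: str = "decimal") -> str:
    """Baseline table plus pairwise survivor differences, as plain text."""
    lines = ["Expected annual survivors by resource set",
             "-" * 58]
    lines.append(f"{'resource set':<22}{'beta/yr':>10}{'S %':>8}{'beta/I %':>10}")
    for sc in results["scenarios"]:
        lines.append(f"{sc['label']:<22}{_fmt(sc['beta'], rounding):>10}"
                     f"{sc['survival_pct']:>8.1f}{sc['beta_over_incidence_pct']:>10.1f}")
    for pair, delta in (results.get("delta_beta") or {}).items():
        better, worse = pair.split("-", 1)
        lines.append("")
        lines.append(f"{_fmt(delta, rounding)} additional survivors/yr "
                     f"from '{better}' vs '{worse}'")
    return "\n".join(lines)


def summarise_marginal(table: pd.DataFrame, rounding: str = "decimal") -> str:
    """Shift grid table: survivors per year per static-interval shift."""
    lines = ["", "Marginal effects of static-interval shifts (minutes)",
             "-" * 58,
             f"{'shift':>6}  {'resource set':<22}{'beta/yr':>10}{'delta':>8}"]
    for row in table.itertuples():
        lines.append(f"{row.shift_minutes:>+6d}  {row.resource_set:<22}"
                     f"{_fmt(row.beta, rounding):>10}"
                     f"{row.delta_beta:>+8.1f}")
    return "\n".join(lines)


def plot_reach_curves(reach_files: dict[str, pathlib.Path],
                      out_path: pathlib.Path) -> pathlib.Path:
    """Population newly reached per minute, one line per resource set."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, path in reach_files.items():
        df = pd.read_csv(path)
        ax.plot(df["minute_bin"], df["population_reached"], marker=".", label=label)
    ax.set_xlabel("minute bin (total time to defibrillation)")
    ax.set_ylabel("population newly reached")
    ax.legend()
    fig.tight_layout()
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_marginal_effects(table: pd.DataFrame, out_path: pathlib.Path) -> pathlib.Path:
    """Survivors per year against static-interval shift, per resource set."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, grp in table.groupby("resource_set"):
        grp = grp.sort_values("shift_minutes")
        ax.plot(grp["shift_minutes"], grp["beta"], marker="o", label=label)
    ax.set_xlabel("shift of time to defibrillation (minutes)")
    ax.set_ylabel("expected survivors / year")
    ax.legend()
    fig.tight_layout()
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
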