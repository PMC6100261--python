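"""Convenience plots: calculated responses as lines, in-silico data as points."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .timeseries import TimeSeries


def plot_species(
    ideal_by_label: dict[str, TimeSeries],
    noisy_by_label: dict[str, TimeSeries] | None,
    species: str,
    out_path: str | Path,
) -> Path:
    """One figure per species: a line per experiment, scatter for its noisy data."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, series in ideal_by_label.items():
        (line,) = ax.plot(series.times, series.column(species), label=label)
        if noisy_by_label and label in noisy_by_label:
            noisy = noisy_by_label[label]
            ax.plot(
                noisy.times,
                noisy.column(species),
                linestyle="none",
                marker="o",
                markersize=2.5,
                color=line.get_color(),
            )
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"{species} (mol/L)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
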