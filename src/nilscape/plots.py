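"""Simple Lorenz and Marey figure writers (PNG/SVG)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .heterogeneity import GiniResult  # noqa: E402
from .panel_io import CrossoverTable  # noqa: E402


def lorenz_plot(results: dict[str, GiniResult], path) -> None:
    """Lorenz curves (cumulative physical vs genetic fraction) per label."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    for label, res in results.items():
        ax.plot(res.lorenz_points[:, 0], res.lorenz_points[:, 1],
                label=f"{label} (Gini {res.gini:.3f})")
    ax.set_xlabel("cumulative physical fraction")
    ax.set_ylabel("cumulative genetic fraction")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def marey_plot(table: CrossoverTable, path) -> None:
    """Cumulative genetic fraction against physical position, per cross."""
    fig, ax = plt.subplots(figsize=(6, 4))
    df = table.unmasked().sort_values("start")
    for cross in ("faxnil", "lonnil"):
        c = df[f"count_{cross}"].to_numpy()
        if c.sum() == 0:
            continue
        ax.step(df["end"], c.cumsum() / c.sum(), where="post", label=cross)
    ax.set_xlabel("physical position (bp)")
    ax.set_ylabel("cumulative crossover fraction")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
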