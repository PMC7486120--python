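"""Optional plotting helpers (require matplotlib)."""

from __future__ import annotations


def plot_sweep(table, path):
    """Line chart of effective species versus bolus size, one line per
    supply composition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for f1, sub in table.groupby("composition"):
        sub = sub.sort_values("c0_over_K")
        ax.plot(sub["c0_over_K"], sub["m_e"], marker="o", ms=3, label=f"{f1:g}")
    ax.set_xscale("log")
    ax.set_xlabel(r"$c_0 / K$")
    ax.set_ylabel(r"effective species $m_e$")
    ax.legend(title="nutrient-1 fraction", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
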