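"""Headless-safe plots for calculated-vs-experimental affinity comparisons."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def scatter_calc_vs_exp(pairs, path, annotate: str | None = None) -> None:
    """Scatter of calculated (y) vs experimental (x) ΔG with ±1 kcal/mol bands.

    The solid diagonal marks perfect agreement; dashed lines are offset by
    ±1 kcal/mol. ``annotate`` text (e.g. MUE and R) is placed in the corner.
    """
    arr = np.asarray(list(pairs), dtype=float)
    calc, exp = arr[:, 0], arr[:, 1]
    lo = min(calc.min(), exp.min()) - 0.5
    hi = max(calc.max(), exp.max()) + 0.5
    fig, ax = plt.subplots(figsize=(5, 5))
    line = np.array([lo, hi])
    ax.plot(line, line, "k-", lw=1)
    ax.plot(line, line + 1, "k--", lw=0.8)
    ax.plot(line, line - 1, "k--", lw=0.8)
    ax.scatter(exp, calc, s=28, zorder=3)
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel(r"$\Delta G$ experimental (kcal/mol)")
    ax.set_ylabel(r"$\Delta G$ calculated (kcal/mol)")
    if annotate:
        ax.text(0.03, 0.97, annotate, transform=ax.transAxes, va="top", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
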