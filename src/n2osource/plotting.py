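"""The d15N-SP vs d18O map figure: endmember boxes, reduction line,
mixing lines, and emitted samples with error bars."""

from __future__ import annotations

import math
from typing import Iterable, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .endmembers import EndmemberSet, ReductionLine  # noqa: E402
from .mixing import EmittedDelta  # noqa: E402


def plot_sp_o_map(
    endmembers: EndmemberSet,
    eps: ReductionLine,
    samples: Iterable[EmittedDelta] = (),
    r_min: float = 0.05,
    ax: Optional[plt.Axes] = None,
) -> plt.Figure:
    """Draw the dual-isotope map; returns the figure (Agg backend)."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 5))
    else:
        fig = ax.figure
    for proc, marker in (("bD", "s"), ("fD", "D"), ("nD", "v"), ("Ni", "^")):
        e = endmembers[proc]
        ax.errorbar(e.d18o, e.sp, marker=marker, color="k", ms=7, ls="none")
        ax.add_patch(
            plt.Rectangle(
                (e.d18o - e.d18o_sd, e.sp - e.sp_sd),
                2 * e.d18o_sd, 2 * e.sp_sd,
                fill=False, edgecolor="grey", lw=0.8,
            )
        )
        ax.annotate(proc, (e.d18o + 0.5, e.sp + 0.5), fontsize=9)
    # reduction line from bD for r in [r_min, 1]
    bd = endmembers["bD"]
    lnr = [math.log(r_min) * i / 50 for i in range(51)]
    ax.plot(
        [bd.d18o + eps.eps_o * t for t in lnr],
        [bd.sp + eps.eps_sp * t for t in lnr],
        "k-", lw=1.2, label=f"reduction line (r {r_min}-1)",
    )
    for minor, style in (("fD", ":"), ("Ni", "--")):
        m = endmembers[minor]
        ax.plot([bd.d18o, m.d18o], [bd.sp, m.sp], "k" + style, lw=0.9,
                label=f"bD-{minor} mixing")
    for s in samples:
        ax.errorbar(
            s.d18o, s.sp, xerr=s.sigma_d18o, yerr=s.sigma_sp,
            marker="o", ms=4, color="tab:blue", ls="none", alpha=0.8,
        )
    water = endmembers.d18o_h2o
    suffix = f" (water-adjusted, d18O_H2O = {water}‰)" if endmembers.water_adjusted else ""
    ax.set_xlabel("δ¹⁸O of N₂O (‰ vs VSMOW)")
    ax.set_ylabel("δ¹⁵N site preference of N₂O (‰)")
    ax.set_title("N₂O source map" + suffix, fontsize=10)
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    return fig
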