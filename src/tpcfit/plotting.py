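"""Optional matplotlib figures (requires the ``plot`` extra)."""

from __future__ import annotations

import numpy as np


def plot_inflation_vs_th_tref(sweep_table, ax=None):
    """Hex-style scatter of log-fold inflation against T_h - T_ref."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    acc = sweep_table[sweep_table["accepted"] == True]  # noqa: E712
    x = acc["T_h_C"] - acc["T_ref_C"]
    y = acc["log_fold_increase"].replace([-np.inf], np.nan)
    ax.scatter(x, y, s=8, alpha=0.4)
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel(r"$T_h - T_{ref}$ ($^\circ$C)")
    ax.set_ylabel(r"$\log_2(B_0/B(T_{ref}) - 1)$")
    return ax


def plot_mca_violins(b0_cold, b0_warm, btref_cold, btref_warm, ax=None):
    """Violin plots of normalised rates per adaptation group and estimator."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    data = [b0_cold, b0_warm, btref_cold, btref_warm]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks([1, 2, 3, 4],
                  ["$B_0$ cold", "$B_0$ warm",
                   "$B(T_{ref})$ cold", "$B(T_{ref})$ warm"])
    ax.set_ylabel("normalised rate at $T_{ref}$")
    return ax
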