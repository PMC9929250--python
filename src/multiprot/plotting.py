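"""Small plotting helpers for consensus clustering and survival curves."""

from __future__ import annotations

import numpy as np

from .subtyping import ConsensusResult


def plot_consensus_cdf(result: ConsensusResult, ax=None):
    """Consensus CDF per k (the curves whose delta-area guides k selection)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for k, (grid, cdf) in sorted(result.cdf.items()):
        ax.plot(grid, cdf, label=f"k={k}")
    ax.set_xlabel("consensus index")
    ax.set_ylabel("CDF")
    ax.legend()
    return ax


def plot_consensus_matrix(result: ConsensusResult, k: int, ax=None):
    """Heatmap of the consensus matrix at k, ordered by the final labels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = result.labels[k]
    order = np.argsort(labels.to_numpy(), kind="mergesort")
    C = result.consensus[k][np.ix_(order, order)]
    im = ax.imshow(C, cmap="Blues", vmin=0, vmax=1)
    ax.figure.colorbar(im, ax=ax, label="consensus")
    ax.set_title(f"consensus matrix, k={k}")
    return ax


def plot_km(fit, ax=None):
    """Step plot of Kaplan-Meier curves per group from a SurvivalFit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g, curve in fit.curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=str(g))
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
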