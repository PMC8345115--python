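"""Optional figure rendering (violin+box bin distributions, ring box plots)."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def violin_box_plot(distributions: Mapping[str, np.ndarray],
                    path: str | Path, title: str = "") -> None:
    """Violin + box plot of occupied-bin count multisets, log count axis."""
    names = list(distributions)
    data = [np.asarray(distributions[n], dtype=float) for n in names]
    fig, ax = plt.subplots(figsize=(1.6 * len(names) + 2, 4))
    ax.violinplot([np.log10(d) for d in data], showextrema=False)
    ax.boxplot([np.log10(d) for d in data], widths=0.15,
               medianprops={"color": "black"})
    ax.set_xticks(range(1, len(names) + 1), names, rotation=20, ha="right")
    ax.set_ylabel("log10 localisations per bin")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ring_box_plot(profiles: Sequence[np.ndarray], path: str | Path,
                  title: str = "") -> None:
    """Per-ring density box plot, ring 1 (centre) to ring n (periphery)."""
    arr = np.asarray(profiles, dtype=float)  # (n_nuclei, n_rings)
    n_rings = arr.shape[1]
    fig, ax = plt.subplots(figsize=(1 + n_rings, 4))
    ax.boxplot([arr[:, k] for k in range(n_rings)],
               medianprops={"color": "black"})
    ax.set_xticks(range(1, n_rings + 1),
                  [f"Nucleus ring area {k}" for k in range(1, n_rings + 1)],
                  rotation=30, ha="right")
    ax.set_ylabel("localisations per um^2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
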