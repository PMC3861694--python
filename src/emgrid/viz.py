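"""Optional rendering of amplitude maps.

Heat map of the RMS distribution on the grid with the automatically
selected relevant channels marked as black dots and the barycenter as a
white cross — the standard way these maps are displayed. Purely an
export convenience; nothing in the analysis depends on it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .grid import GridLayout
from .mapping import LocalizationResult


def render_map(result: LocalizationResult, path: str | Path, title: str | None = None):
    """Write a PNG heat map of a localization result."""
    layout: GridLayout = result.amplitude_map.layout
    g = result.amplitude_map.to_grid()
    spec = layout.spec
    extent = (
        (1 - spec.reference_col - 0.5) * spec.pitch_mm,
        (spec.n_cols - spec.reference_col + 0.5) * spec.pitch_mm,
        (spec.n_rows - 0.5) * spec.pitch_mm,
        -0.5 * spec.pitch_mm,
    )
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    im = ax.imshow(g, extent=extent, cmap="viridis", interpolation="nearest")
    idx = [layout.index(ch) for ch in result.relevant_channels]
    if idx:
        pos = layout.positions[np.asarray(idx)]
        ax.plot(pos[:, 0], pos[:, 1], "k.", ms=8)
    ax.plot(*result.barycenter_mm, "w+", ms=14, mew=2)
    ax.set_xlabel("medio-lateral x (mm)")
    ax.set_ylabel("proximal-distal y (mm)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="RMS (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
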