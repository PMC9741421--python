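"""PNG previews of coefficient images (matplotlib, Agg backend)."""

from __future__ import annotations

import numpy as np


def save_coefficient_png(
    image, path: str, title: str = "", diameter_mm: float | None = None
) -> None:
    """Render the two coefficient channels side by side to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    extent = None
    if diameter_mm is not None:
        r = diameter_mm / 2.0
        extent = (-r, r, -r, r)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, grid, name in (
        (axes[0], image.mu_a_grid, "mu_a"),
        (axes[1], image.mu_s_grid, "mu_s'"),
    ):
        shown = np.where(image.mask, grid, np.nan)
        im = ax.imshow(shown, origin="lower", extent=extent, cmap="viridis")
        ax.set_title(f"{title} {name}".strip())
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
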