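"""Snapshot rendering: orientation-coloured ellipses with direction arrows."""

from __future__ import annotations

import numpy as np


def plot_snapshot(population, junctions=None, ax=None, color_by="orientation",
                  arrows=True):
    """Draw a population frame.

    ``color_by`` is ``"orientation"`` (nematic hue, period π),
    ``"aspect_ratio"`` or ``"degree"`` (junction count; needs ``junctions``).
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib import cm
    from matplotlib.patches import Ellipse as MplEllipse

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    L = population.box
    if color_by == "degree":
        from .observables import junction_graph
        deg = dict(junction_graph(population, junctions or []).degree())
        vals = np.array([deg.get(i, 0) for i in range(population.n)], float)
        colors = cm.viridis(vals / max(vals.max(), 1.0))
    elif color_by == "aspect_ratio":
        r = population.r
        colors = cm.viridis((r - r.min()) / max(np.ptp(r), 1e-9))
    else:
        colors = cm.hsv((population.alpha % np.pi) / np.pi)

    for i in range(population.n):
        for sx in (-L, 0.0, L):
            for sy in (-L, 0.0, L):
                cx, cy = population.X[i, 0] + sx, population.X[i, 1] + sy
                if not (-2 <= cx <= L + 2 and -2 <= cy <= L + 2):
                    continue
                ax.add_patch(MplEllipse(
                    (cx, cy), 2 * population.a[i], 2 * population.b[i],
                    angle=np.degrees(population.alpha[i]),
                    facecolor=colors[i], edgecolor="k", lw=0.3, alpha=0.85))
                if arrows:
                    e = np.array([np.cos(population.alpha[i]),
                                  np.sin(population.alpha[i])])
                    ax.annotate("", xy=(cx + e[0], cy + e[1]), xytext=(cx, cy),
                                arrowprops=dict(arrowstyle="->", lw=0.6))
    if junctions:
        from .junction_dynamics import cell_endpoints
        cells = population.cells()
        for jn in junctions:
            p = cell_endpoints(cells[jn.i])[0 if jn.end_i == "front" else 1]
            ax.plot([p[0], p[0] + jn.separation[0]],
                    [p[1], p[1] + jn.separation[1]], color="grey", lw=1.5)
    ax.set_xlim(0, L)
    ax.set_ylim(0, L)
    ax.set_aspect("equal")
    return ax
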