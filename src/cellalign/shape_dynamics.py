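"""Aspect-ratio dynamics at fixed cell area.

Cells deform only through their aspect ratio r = a/b, with the area held at
π (so a = √r, b = 1/√r).  Overlap drives r down or up through the boundary
angles of the contact points; a restoring term relaxes r towards the
preferred aspect ratio r̄:

    dr/dt = (4r²/(r²+1)) Σ_j Σ_k [sin(2θ_{2k-1}) - sin(2θ_{2k})]
            + 16γ (1 + r̄ r³)/(1 + r²) (1 - r/r̄)

The overlap term is the (mobility-scaled) negative r-derivative of the
overlap area at fixed area; the restoring term derives from the symmetric
shape energy (g/2)[(r - r̄)² + (1/r - 1/r̄)²] and vanishes at r = r̄.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def axes_from_r(r: float) -> tuple[float, float]:
    """Semi-axes (a, b) = (√r, 1/√r) of a unit-area (π) ellipse."""
    if r <= 0:
        raise ValueError(f"aspect ratio must be positive, got {r}")
    sr = np.sqrt(r)
    return sr, 1.0 / sr


def restoring_rate(r: float, gamma: float, rbar: float) -> float:
    """Relaxation of the aspect ratio towards r̄ (zero at r = r̄)."""
    return 16.0 * gamma * (1.0 + rbar * r ** 3) / (1.0 + r * r) * (1.0 - r / rbar)


def shape_rate(thetas: Sequence[float], r: float, gamma: float,
               rbar: float) -> float:
    """dr/dt from ordered, paired contact angles plus shape restoration.

    ``thetas`` concatenates the θ parameters of the cell's contact points in
    pair order (θ_1, θ_2, θ_3, θ_4, ...); an empty sequence gives the pure
    restoring rate.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size % 2:
        raise ValueError("contact angles must come in ordered pairs")
    s = 0.0
    for k in range(0, thetas.size, 2):
        s += np.sin(2.0 * thetas[k]) - np.sin(2.0 * thetas[k + 1])
    return 4.0 * r * r / (r * r + 1.0) * s + restoring_rate(r, gamma, rbar)
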