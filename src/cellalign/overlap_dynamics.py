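"""Base-model right-hand sides: overlap avoidance + self-propulsion.

In non-dimensional units (cell area π, overlap-avoidance strength scaled to
one) the centre and orientation of cell i obey

    dX_i/dt = -Σ_j Σ_k (Y_{2k-1} - Y_{2k})^⊥ + ν e(α_i)
    dα_i/dt = (2r / (r² + 1)) Σ_j Σ_k (|X_i - Y_{2k}|² - |X_i - Y_{2k-1}|²)

where the Y are the ordered, paired boundary crossings with each overlapping
neighbour j and ⊥ is the left-turn map.  Both terms are the gradient flow of
the pairwise overlap area: the translation term equals -∇_X(overlap area) and
the rotation term equals -(4r / (π(r²+1)))·∂(overlap area)/∂α, which the test
suite verifies against finite differences of the polygon-clipped area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import OverlapContact, perp, unit_vector


@dataclass
class CellDerivative:
    """Time derivative of one cell's state (non-dimensional units)."""

    dX: np.ndarray
    dalpha: float
    dr: float = 0.0


def overlap_translation_term(contacts: Sequence[OverlapContact]) -> np.ndarray:
    """-Σ_j Σ_k (Y_{2k-1} - Y_{2k})^⊥ over cell i's (non-degenerate) contacts.

    Each chord's left-turned normal pushes the cell away from the overlap;
    the magnitude of one pair's contribution equals the chord length.
    """
    out = np.zeros(2)
    for ct in contacts:
        if ct.degenerate_flag == "containment":
            continue
        for k in range(ct.K):
            out -= perp(ct.points[2 * k] - ct.points[2 * k + 1])
    return out


def overlap_rotation_term(contacts: Sequence[OverlapContact],
                          centre: np.ndarray, r: float) -> float:
    """(2r/(r²+1))·Σ (|X-Y_{2k}|² - |X-Y_{2k-1}|²).

    Positive values turn the cell anticlockwise, in the direction from the
    shorter to the longer centre-to-crossing segment.
    """
    s = 0.0
    for ct in contacts:
        if ct.degenerate_flag == "containment":
            continue
        for k in range(ct.K):
            d1 = ct.points[2 * k] - centre
            d2 = ct.points[2 * k + 1] - centre
            s += d2 @ d2 - d1 @ d1
    return 2.0 * r / (r * r + 1.0) * s


def containment_fallback(contact: OverlapContact, centre_i: np.ndarray,
                         centre_j: np.ndarray, b_containing: float,
                         box_L: float) -> np.ndarray:
    """Velocity applied to a contained cell: the crossing-point forces
    vanish under strict containment even though overlap is maximal, so the
    contained cell is pushed along the centre-difference unit vector with
    speed equal to the containing cell's semi-minor axis."""
    from .geometry import min_image
    d = min_image(centre_i - centre_j, box_L)
    nrm = np.linalg.norm(d)
    if nrm < 1e-12:
        return np.array([b_containing, 0.0])
    return b_containing * d / nrm


def base_rhs(population, params, contacts=None) -> list[CellDerivative]:
    """Assemble the base-model derivatives for every cell.

    ``contacts`` maps cell index -> list of OverlapContact (from that cell's
    perspective); recomputed from the population when omitted.  The
    containment fallback is applied here, not inside the term operations, so
    the pure formulas stay testable against the energy oracle.
    """
    if contacts is None:
        contacts = population.contact_lists(params.box)
    derivs = []
    for i, cell in enumerate(population.cells()):
        cts = contacts.get(i, [])
        regular = [c for c in cts if c.degenerate_flag != "containment"]
        dX = overlap_translation_term(regular) + params.nu * unit_vector(cell.alpha)
        for c in cts:
            if c.degenerate_flag == "containment":
                other = population.cells()[c.cell_j]
                # contained iff own area is smaller
                if cell.a * cell.b < other.a * other.b:
                    dX += containment_fallback(
                        c, cell.X, other.X, other.b, params.box)
        dalpha = overlap_rotation_term(regular, cell.X, cell.r)
        derivs.append(CellDerivative(dX=dX, dalpha=dalpha, dr=0.0))
    return derivs
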