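"""Cell-cell junctions and supracellular actin torques.

Junctions are deterministic zero-rest-length Hookean springs between cell
endpoints X^± = X ± a·e(α): they exist exactly while the minimum-image
distance between two endpoints is below the junction range λ, and break when
stretched beyond it.  Front-to-back (fb) pairs join endpoints of opposite
polarity; front-to-front / back-to-back (ff/bb) pairs join like endpoints.

A junction additionally carries a supracellular actin cable, modelled as an
inextensible rod spanning both cells (discretised with three points) whose
bending energy m/(4a)·|e(α_i) ∓ e(α_j)|² yields a pure orientation torque:
fb junctions drive polar alignment, ff/bb junctions drive head-to-head
(anti-polar, hence still nematic) alignment.  Cell aspect ratio is held
constant while junctions are active.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import min_image, perp, unit_vector

FRONT = "front"
BACK = "back"


@dataclass(frozen=True)
class Junction:
    """An active endpoint-to-endpoint spring between two cells.

    ``separation`` points from cell i's endpoint to cell j's endpoint
    (minimum image); ``type`` is ``"fb"`` iff exactly one endpoint is a
    front.
    """

    i: int
    end_i: str
    j: int
    end_j: str
    type: str
    separation: np.ndarray

    @property
    def is_fb(self) -> bool:
        return self.type == "fb"


def cell_endpoints(cell) -> tuple[np.ndarray, np.ndarray]:
    """Front and back connection points X ± a·e(α)."""
    e = unit_vector(cell.alpha)
    return cell.X + cell.a * e, cell.X - cell.a * e


def find_junctions(population, lam: float, box_L: float) -> list[Junction]:
    """The stateless active junction set of a population.

    A junction exists for every endpoint pair (any front/back combination,
    self-pairs excluded) whose minimum-image distance is strictly below λ.
    Several junctions may share an endpoint (clumps).  Each junction is
    reported once, from the lower cell index's perspective.
    """
    if lam <= 0:
        return []
    cells = population.cells()
    ends = [cell_endpoints(c) for c in cells]
    out: list[Junction] = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            for ei, pi in zip((FRONT, BACK), ends[i]):
                for ej, pj in zip((FRONT, BACK), ends[j]):
                    sep = min_image(pj - pi, box_L)
                    if sep @ sep < lam * lam:
                        jtype = "fb" if ei != ej else "ffbb"
                        out.append(Junction(i, ei, j, ej, jtype, sep))
    return out


def junctions_of(junctions: Sequence[Junction], i: int) -> list[Junction]:
    """Junction list re-expressed from cell i's perspective."""
    mine = []
    for jn in junctions:
        if jn.i == i:
            mine.append(jn)
        elif jn.j == i:
            mine.append(Junction(i, jn.end_j, jn.i, jn.end_i, jn.type,
                                 -jn.separation))
    return mine


def junction_translation_term(junctions: Sequence[Junction],
                              kappa: float) -> np.ndarray:
    """κ·Σ separation vectors: the zero-rest-length Hookean pull towards the
    partner endpoints."""
    out = np.zeros(2)
    for jn in junctions:
        out += kappa * jn.separation
    return out


def junction_rotation_term(junctions: Sequence[Junction], r: float,
                           alpha_i: float, kappa: float) -> float:
    """(4κ r^{3/2}/(r²+1))·Σ separation·(s·e⊥(α_i)), s = +1 at the cell's
    front, -1 at its back."""
    ep = perp(unit_vector(alpha_i))
    s = 0.0
    for jn in junctions:
        sign = 1.0 if jn.end_i == FRONT else -1.0
        s += jn.separation @ (sign * ep)
    return 4.0 * kappa * r ** 1.5 / (r * r + 1.0) * s


def actin_rotation_term(junctions: Sequence[Junction], r: float,
                        alpha_i: float, alphas: np.ndarray,
                        mu: float) -> float:
    """(μ r/(r²+1))·(-Σ_fb sin(α_i - α_j) + Σ_ffbb sin(α_i - α_j)).

    The actin torque acts only through currently active junctions; it is the
    gradient flow of the discretised cable bending energy under the same
    rotational mobility as the overlap torque.
    """
    s = 0.0
    for jn in junctions:
        term = np.sin(alpha_i - alphas[jn.j])
        s += -term if jn.is_fb else term
    return mu * r / (r * r + 1.0) * s


def bending_energy(alpha_i: float, alpha_j: float, a: float, m: float,
                   type: str = "fb") -> float:
    """Bending energy m/(4a)·|e(α_i) ∓ e(α_j)|² of a 3-point discretised
    supracellular actin cable (minus for fb, plus for ff/bb)."""
    ei = unit_vector(alpha_i)
    ej = unit_vector(alpha_j)
    d = ei - ej if type == "fb" else ei + ej
    return m / (4.0 * a) * float(d @ d)
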