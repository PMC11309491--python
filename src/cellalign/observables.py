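"""Population-level measurements.

* **alignment** — the global 2D nematic order parameter
  S = |⟨e^{2iα}⟩| = √(⟨cos 2α⟩² + ⟨sin 2α⟩²), blind to polarity
  (α and α+π are equivalent); 1 for perfect nematic order, ≈ N^{-1/2} for an
  isotropic population.
* **packing fraction** — area of the periodic union of all cells divided by
  L², measured on a raster; less mutual overlap means a larger union and a
  higher packing fraction.
* **contact statistics** — distinct interaction partners per cell and the
  durations of pairwise contacts over a sampled time window.
* **alignment length scale** — the exponential correlation length of the
  nematic pair correlation C(d) = ⟨cos 2(α_i − α_j)⟩ over pair distance.
* **junction graph** — cells as nodes, junctioned pairs as (simple) edges;
  the degree distribution and its correlation with alignment across an
  ensemble diagnose chain formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .geometry import rotation_matrix


@dataclass
class ObservablesReport:
    """Summary of one population / trajectory."""

    alignment: float
    packing_fraction: float | None = None
    mean_partners: float | None = None
    mean_duration: float | None = None
    length_scale: float | None = None
    degree_fractions: dict[int, float] = field(default_factory=dict)
    mean_r: float | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        if "degree_fractions" in d:
            d["degree_fractions"] = {str(k): v
                                     for k, v in d["degree_fractions"].items()}
        return d


def alignment(population_or_alpha) -> float:
    """Nematic order parameter S = √(⟨cos 2α⟩² + ⟨sin 2α⟩²) ∈ [0, 1]."""
    alpha = getattr(population_or_alpha, "alpha", population_or_alpha)
    alpha = np.asarray(alpha, dtype=float)
    return float(np.abs(np.mean(np.exp(2j * alpha))))


def alignment_series(trajectory) -> np.ndarray:
    return np.array([alignment(f.alpha) for f in trajectory.frames])


def equilibrated_alignment(trajectory, fraction: float = 0.1) -> float:
    """Mean alignment over the final ``fraction`` of recorded frames (the
    operational reading of "measured at the dynamic equilibrium")."""
    s = alignment_series(trajectory)
    k = max(1, int(round(len(s) * fraction)))
    return float(np.mean(s[-k:]))


def packing_fraction(population, box_L: float | None = None,
                     resolution: int = 1024) -> float:
    """Union area of all cells (periodic) / L² on a raster of
    resolution² sample points.  Bounded by N·π/L², with equality (to raster
    tolerance) iff no two cells overlap."""
    L = population.box if box_L is None else box_L
    px = L / resolution
    covered = np.zeros((resolution, resolution), dtype=bool)
    a, b = population.a, population.b
    for i in range(population.n):
        R = rotation_matrix(population.alpha[i])
        half = a[i]  # bounding half-width
        x0, y0 = population.X[i]
        ix0 = int(np.floor((x0 - half) / px))
        ix1 = int(np.ceil((x0 + half) / px))
        iy0 = int(np.floor((y0 - half) / px))
        iy1 = int(np.ceil((y0 + half) / px))
        xs = (np.arange(ix0, ix1 + 1) + 0.5) * px - x0
        ys = (np.arange(iy0, iy1 + 1) + 0.5) * px - y0
        XX, YY = np.meshgrid(xs, ys, indexing="ij")
        u = (XX * R[0, 0] + YY * R[1, 0]) / a[i]
        v = (XX * R[0, 1] + YY * R[1, 1]) / b[i]
        inside = u * u + v * v < 1.0
        gx = np.arange(ix0, ix1 + 1) % resolution
        gy = np.arange(iy0, iy1 + 1) % resolution
        covered[np.ix_(gx, gy)] |= inside
    return float(covered.sum()) / resolution ** 2


def contact_stats(trajectory, window_start: float = 0.0,
                  window_length: float = 10.0,
                  sample_interval: float = 0.1):
    """Interaction partners per cell and pairwise contact durations.

    The window is sampled at ``sample_interval`` (default: 100 samples over a
    t=10 window).  A pair is "in contact" at a sample if a non-degenerate
    overlap contact exists; each maximal run of consecutive in-contact
    samples counts as one interaction of duration run-length × interval.

    Returns ``(partners, durations)``: partners[i] = number of distinct cells
    overlapping cell i at any sampled time; durations = list of all
    interaction durations.
    """
    times = trajectory.times
    t_end = window_start + window_length
    if window_start < times[0] - 1e-9 or t_end > times[-1] + 1e-9:
        raise ValueError(
            f"window [{window_start}, {t_end}] outside trajectory "
            f"[{times[0]}, {times[-1]}]")
    sample_times = np.arange(window_start, t_end + 1e-9, sample_interval)
    idx = [int(np.argmin(np.abs(times - t))) for t in sample_times]
    n = len(trajectory.frames[0].alpha)
    partner_sets: list[set[int]] = [set() for _ in range(n)]
    runs: dict[tuple[int, int], int] = {}
    durations: list[float] = []
    for k in idx:
        pop = trajectory.population_at(k)
        contacts = pop.contact_lists()
        now = set()
        for i, lst in contacts.items():
            for ct in lst:
                if ct.degenerate_flag == "containment":
                    continue
                pair = (min(i, ct.cell_j), max(i, ct.cell_j))
                now.add(pair)
        for i, j in now:
            partner_sets[i].add(j)
            partner_sets[j].add(i)
            runs[(i, j)] = runs.get((i, j), 0) + 1
        ended = [p for p in runs if p not in now]
        for p in ended:
            durations.append(runs.pop(p) * sample_interval)
    durations.extend(c * sample_interval for c in runs.values())
    partners = np.array([len(s) for s in partner_sets])
    return partners, np.array(durations)


def nematic_pair_correlation(population, box_L: float | None = None,
                             bin_width: float = 0.5):
    """Binned C(d) = ⟨cos 2(α_i - α_j)⟩ over minimum-image pair distances
    d ≤ L/2.  Returns (bin centres, C, pair counts)."""
    L = population.box if box_L is None else box_L
    X, alpha = population.X, population.alpha
    n = population.n
    ii, jj = np.triu_indices(n, k=1)
    d = X[jj] - X[ii]
    d -= L * np.round(d / L)
    dist = np.hypot(d[:, 0], d[:, 1])
    c2 = np.cos(2.0 * (alpha[ii] - alpha[jj]))
    nbins = int(np.ceil(0.5 * L / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    which = np.digitize(dist, edges) - 1
    ok = (which >= 0) & (which < nbins)
    counts = np.bincount(which[ok], minlength=nbins)
    sums = np.bincount(which[ok], weights=c2[ok], minlength=nbins)
    with np.errstate(invalid="ignore"):
        C = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = edges[:-1] + 0.5 * bin_width
    return centres, C, counts


def alignment_length_scale(population, box_L: float | None = None,
                           bin_width: float = 0.5) -> float:
    """Exponential correlation length ℓ of the nematic pair correlation.

    Fits C(d) = exp(-d/ℓ) to the binned correlation (d ≤ L/2) and returns ℓ
    capped at L; degenerate fits (uniformly high or structureless
    correlation) return the cap.
    """
    L = population.box if box_L is None else box_L
    if population.n < 10:
        raise ValueError("need at least 10 cells")
    centres, C, counts = nematic_pair_correlation(population, L, bin_width)
    ok = counts > 0
    d, c = centres[ok], C[ok]
    if np.all(c > 0.9):
        return float(L)
    try:
        (ell,), _ = optimize.curve_fit(
            lambda x, ell: np.exp(-x / ell), d, c,
            p0=[2.0], bounds=(1e-3, 10.0 * L), maxfev=2000)
    except RuntimeError:
        import warnings
        warnings.warn("length-scale fit did not converge; returning cap")
        return float(L)
    return float(min(ell, L))


def junction_graph(population, junctions) -> nx.Graph:
    """Simple undirected junction graph: nodes are cells, an edge joins every
    pair connected by at least one junction (parallel junctions collapse)."""
    g = nx.Graph()
    g.add_nodes_from(range(population.n))
    for jn in junctions:
        g.add_edge(jn.i, jn.j)
    return g


def degree_fractions(graph: nx.Graph) -> dict[int, float]:
    """Fraction of cells at each degree (sums to 1)."""
    n = graph.number_of_nodes()
    out: dict[int, float] = {}
    for _, deg in graph.degree():
        out[deg] = out.get(deg, 0.0) + 1.0 / n
    return out


def degree_alignment_correlation(ensemble, degrees=(0, 1, 2)):
    """Correlation between per-run degree-d cell percentages and alignment.

    ``ensemble`` is a sequence of ``(degree_fractions, alignment)`` pairs,
    one per simulation run.  For each requested degree returns a dict with
    the Pearson R, its (two-sided) p-value and the least-squares slope and
    intercept of alignment against % of degree-d cells; entries are None
    when the degree percentage has zero variance.
    """
    if len(ensemble) < 10:
        raise ValueError("need at least 10 ensemble members")
    align = np.array([a for _, a in ensemble])
    out = {}
    for d in degrees:
        pct = np.array([100.0 * fr.get(d, 0.0) for fr, _ in ensemble])
        if np.ptp(pct) < 1e-12 or np.ptp(align) < 1e-12:
            out[d] = dict(R=None, p=None, slope=None, intercept=None)
            continue
        R, p = stats.pearsonr(pct, align)
        slope, intercept = np.polyfit(pct, align, 1)
        out[d] = dict(R=float(R), p=float(p), slope=float(slope),
                      intercept=float(intercept))
    return out


def report(trajectory, fraction: float = 0.1,
           with_packing: bool = True) -> ObservablesReport:
    """Standard end-of-run summary from the final frames of a trajectory."""
    pop = trajectory.final
    rep = ObservablesReport(
        alignment=equilibrated_alignment(trajectory, fraction),
        mean_r=float(np.mean(pop.r)))
    if with_packing:
        rep.packing_fraction = packing_fraction(pop)
    if trajectory.params.junctions_on:
        g = junction_graph(pop, trajectory.junctions_at(-1))
        rep.degree_fractions = degree_fractions(g)
    if trajectory.params.n_cells >= 10:
        rep.length_scale = alignment_length_scale(pop)
    return rep
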