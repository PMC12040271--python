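"""Free-energy landscapes and grid-based cluster analysis over (V1, V2).

The probability density ρ(V1, V2) is estimated by a 2-D histogram of the
first two principal-component projections.  The free-energy surface is

    ΔG(V1, V2) = −k_B T [ln ρ(V1, V2) − ln ρ_max],

so ΔG = 0 exactly in the most populated cell and only density *ratios*
matter (any positive rescaling of ρ leaves ΔG unchanged).  ΔG is reported
in units of k_B T by default; an absolute conversion to kcal/mol is
available for a given temperature.

Clusters are the basins of the density grid: local maxima (8-neighborhood,
equal-density plateaus merged) above a density threshold seed clusters, and
every other populated cell is attached by steepest-ascent hill climbing.
Cluster 1 is by construction the cluster whose peak is the global density
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FreeEnergySurface",
    "ClusterMap",
    "density",
    "free_energy",
    "find_clusters",
    "assign_frames",
    "KB_KCAL",
]

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL = 0.0019872


@dataclass
class FreeEnergySurface:
    """Density and ΔG grids over the first two principal components."""

    x_edges: np.ndarray  # (B+1,) bin edges for V1
    y_edges: np.ndarray  # (B+1,) bin edges for V2
    density: np.ndarray  # (B, B) ρ >= 0
    counts: np.ndarray  # (B, B) raw frame counts
    delta_g: np.ma.MaskedArray | None = None  # (B, B), k_B T units, masked where ρ=0

    @property
    def rho_max(self) -> float:
        return float(self.density.max())


@dataclass
class ClusterMap:
    """Cluster labels on the density grid and (optionally) per frame."""

    cell_labels: np.ndarray  # (B, B) int, 0 = unassigned/empty
    ranking: list[tuple[int, float]]  # (label, peak density), descending
    frame_labels: np.ndarray | None = None  # (T,)

    @property
    def n_clusters(self) -> int:
        return len(self.ranking)


def density(v1: np.ndarray, v2: np.ndarray, bins: int = 64, padding: float = 0.01) -> FreeEnergySurface:
    """Histogram density estimate of (V1, V2) on a ``bins``×``bins`` grid.

    The grid spans the data's bounding box padded by ``padding`` of the span
    per side, so boundary points fall strictly inside the outer bins.
    Density is counts / (T · cell area), a proper probability density.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("v1 and v2 must be equal-length 1-D arrays")
    if v1.size == 0:
        raise ValueError("cannot histogram an empty projection")
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")

    def padded(v: np.ndarray) -> tuple[float, float]:
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        pad = padding * span if span > 0 else max(abs(lo), 1.0) * 1e-6 + 1e-12
        return lo - pad, hi + pad

    counts, x_edges, y_edges = np.histogram2d(
        v1, v2, bins=bins, range=[padded(v1), padded(v2)]
    )
    cell_area = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
    rho = counts / (v1.size * cell_area)
    return FreeEnergySurface(x_edges=x_edges, y_edges=y_edges, density=rho, counts=counts)


def free_energy(
    surface: FreeEnergySurface,
    temperature: float | None = None,
) -> FreeEnergySurface:
    """Fill ``delta_g`` from the density: ΔG = −[ln ρ − ln ρ_max].

    With ``temperature`` (K) the surface is converted to kcal/mol via
    ΔG·k_B·T; otherwise values are in k_B T units.  Cells with ρ = 0 are
    masked (ΔG is undefined there).
    """
    rho = surface.density
    if rho.max() <= 0:
        raise ValueError("density is identically zero; free energy undefined")
    mask = rho == 0
    with np.errstate(divide="ignore"):
        dg = -(np.log(rho, where=~mask, out=np.zeros_like(rho)) - np.log(rho.max()))
    if temperature is not None:
        dg = dg * KB_KCAL * temperature
    dg = dg + 0.0  # normalize IEEE -0.0 at the density maximum to +0.0
    surface.delta_g = np.ma.MaskedArray(dg, mask=mask)
    return surface


_NEIGHBOR_FOOTPRINT = np.ones((3, 3), dtype=bool)


def find_clusters(
    surface: FreeEnergySurface,
    min_density_fraction: float = 0.05,
    smooth_sigma: float = 2.0,
    prominence_fraction: float = 0.2,
) -> ClusterMap:
    """Basin decomposition of the density grid.

    A raw 2-D histogram carries a Poisson-noise local maximum every few
    cells, so the topography used for seed detection and hill climbing is
    the density smoothed with a Gaussian of ``smooth_sigma`` grid cells
    (0 operates on the raw histogram).  Seeds are 8-neighborhood local
    maxima of that field with at least ``min_density_fraction`` of its
    maximum (adjacent equal-density maxima merge into one plateau seed).
    Every other populated cell climbs to its steepest-ascent terminus;
    basins whose terminal maximum is below the seed threshold are absorbed
    into the adjacent dominant basin.

    Watershed over-segmentation is then pruned by topographic persistence:
    a basin whose peak rises less than ``prominence_fraction`` of the
    global (smoothed) maximum above its highest connecting saddle is merged
    into the neighbor across that saddle, repeatedly, so shoulders of one
    mode collapse into it while genuinely separated modes survive.
    Clusters are finally relabeled 1, 2, ... by descending *raw* peak
    density, so cluster 1 contains the cell with the global density
    maximum.
    """
    rho_raw = surface.density
    if rho_raw.max() <= 0:
        raise ValueError("density is identically zero")
    rho = ndimage.gaussian_filter(rho_raw, smooth_sigma) if smooth_sigma > 0 else rho_raw
    nmax = ndimage.maximum_filter(rho, footprint=_NEIGHBOR_FOOTPRINT, mode="constant")
    is_max = (rho == nmax) & (rho > 0)
    seed_mask = is_max & (rho >= min_density_fraction * rho.max())
    seed_labels, n_seeds = ndimage.label(seed_mask, structure=_NEIGHBOR_FOOTPRINT)
    # sub-threshold maxima: provisional labels, merged away afterwards
    weak_labels, n_weak = ndimage.label(
        is_max & ~seed_mask, structure=_NEIGHBOR_FOOTPRINT
    )
    labels = seed_labels.copy()
    labels[weak_labels > 0] = weak_labels[weak_labels > 0] + n_seeds

    B1, B2 = rho.shape
    assignment = np.zeros_like(labels)
    nonzero = list(zip(*np.nonzero(rho > 0)))

    def steepest_neighbor(i: int, j: int) -> tuple[int, int]:
        best, bi, bj = rho[i, j], i, j
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if 0 <= ni < B1 and 0 <= nj < B2 and rho[ni, nj] > best:
                    best, bi, bj = rho[ni, nj], ni, nj
        return bi, bj

    cache: dict[tuple[int, int], int] = {}

    def terminus(i: int, j: int) -> int:
        path = []
        while True:
            if (i, j) in cache:
                lab = cache[(i, j)]
                break
            if labels[i, j] > 0:
                lab = int(labels[i, j])
                break
            path.append((i, j))
            i, j = steepest_neighbor(i, j)
        for cell in path:
            cache[cell] = lab
        return lab

    for i, j in nonzero:
        assignment[i, j] = terminus(i, j)

    # absorb sub-threshold basins into the strongest adjacent seeded basin
    for weak in range(n_seeds + 1, n_seeds + n_weak + 1):
        region = assignment == weak
        if not region.any():
            continue
        ring = ndimage.binary_dilation(region, structure=_NEIGHBOR_FOOTPRINT) & ~region
        candidates = assignment[ring & (assignment > 0) & (assignment <= n_seeds)]
        if candidates.size:
            # seeded basin sharing the longest boundary with this region
            target = np.bincount(candidates).argmax()
        else:
            peak = np.unravel_index(rho.argmax(), rho.shape)
            target = assignment[peak]
        assignment[region] = target

    # persistence pruning: merge low-prominence basins across their saddle
    threshold = prominence_fraction * rho.max()
    while True:
        live = sorted(set(assignment[assignment > 0].tolist()))
        if len(live) <= 1:
            break
        peaks_s = {
            lab: float(ndimage.maximum(rho, labels=assignment, index=lab))
            for lab in live
        }
        saddles = _basin_saddles(rho, assignment)
        best_merge = None  # (prominence, victim, target)
        for lab in live:
            higher = [
                (s, other)
                for (a, b), s in saddles.items()
                for other in ((b,) if a == lab else (a,) if b == lab else ())
                if peaks_s[other] > peaks_s[lab]
            ]
            if not higher:
                continue  # the global-maximum basin never merges
            s_max, target = max(higher)
            prom = peaks_s[lab] - s_max
            if prom < threshold and (best_merge is None or prom < best_merge[0]):
                best_merge = (prom, lab, target)
        if best_merge is None:
            break
        _, victim, target = best_merge
        assignment[assignment == victim] = target

    # rank surviving basins by raw peak density, relabel 1..n
    live = sorted(set(assignment[assignment > 0].tolist()))
    peaks = np.array(
        [float(ndimage.maximum(rho_raw, labels=assignment, index=lab)) for lab in live]
    )
    order = np.argsort(peaks)[::-1]
    relabel = np.zeros(assignment.max() + 1, dtype=int)
    ranking: list[tuple[int, float]] = []
    for rank, k in enumerate(order, start=1):
        relabel[live[k]] = rank
        ranking.append((rank, float(peaks[k])))
    cell_labels = relabel[assignment]
    return ClusterMap(cell_labels=cell_labels, ranking=ranking)


def _basin_saddles(rho: np.ndarray, labels: np.ndarray) -> dict[tuple[int, int], float]:
    """Highest connecting density between each pair of adjacent basins.

    The saddle of basins (a, b) is max over adjacent cell pairs (one in
    each basin) of min(ρ₁, ρ₂).
    """
    saddles: dict[tuple[int, int], float] = {}
    for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
        l1 = labels[max(0, -di): labels.shape[0] - max(0, di) or None,
                    max(0, -dj): labels.shape[1] - max(0, dj) or None]
        l2 = labels[max(0, di): labels.shape[0] - max(0, -di) or None,
                    max(0, dj): labels.shape[1] - max(0, -dj) or None]
        r1 = rho[max(0, -di): rho.shape[0] - max(0, di) or None,
                 max(0, -dj): rho.shape[1] - max(0, dj) or None]
        r2 = rho[max(0, di): rho.shape[0] - max(0, -di) or None,
                 max(0, dj): rho.shape[1] - max(0, -dj) or None]
        mask = (l1 != l2) & (l1 > 0) & (l2 > 0)
        if not mask.any():
            continue
        lo = np.minimum(l1[mask], l2[mask])
        hi = np.maximum(l1[mask], l2[mask])
        val = np.minimum(r1[mask], r2[mask])
        for a, b, v in zip(lo.tolist(), hi.tolist(), val.tolist()):
            key = (a, b)
            if v > saddles.get(key, -1.0):
                saddles[key] = v
    return saddles


def assign_frames(
    cluster_map: ClusterMap,
    surface: FreeEnergySurface,
    v1: np.ndarray,
    v2: np.ndarray,
) -> np.ndarray:
    """Label each frame by the cluster of its grid cell.

    Points must lie inside the grid bounds (always true for the data the
    surface was built from; guards reuse on foreign data).
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    xe, ye = surface.x_edges, surface.y_edges
    if (
        v1.min() < xe[0] or v1.max() > xe[-1]
        or v2.min() < ye[0] or v2.max() > ye[-1]
    ):
        raise ValueError("projection values fall outside the landscape grid")
    i = np.clip(np.searchsorted(xe, v1, side="right") - 1, 0, len(xe) - 2)
    j = np.clip(np.searchsorted(ye, v2, side="right") - 1, 0, len(ye) - 2)
    labels = cluster_map.cell_labels[i, j]
    cluster_map.frame_labels = labels
    return labels


def plot_surface(surface: FreeEnergySurface, path: str, title: str = "Free energy landscape") -> None:
    """Export the ΔG surface as a heat map (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if surface.delta_g is None:
        raise ValueError("call free_energy first")
    fig, ax = plt.subplots(figsize=(5, 4))
    pcm = ax.pcolormesh(surface.x_edges, surface.y_edges, surface.delta_g.T, cmap="viridis")
    fig.colorbar(pcm, ax=ax, label=r"$\Delta G$ ($k_B T$)")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
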