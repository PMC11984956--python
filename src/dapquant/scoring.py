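"""Categorical assay scoring: ciliation, preciliary-vesicle positivity and
CP110 removal.

A cell is ciliated when it bears a centrosome-associated, ARL13B-positive
filament longer than 1 um (strictly greater). Vesicle positivity assigns a
marker to a centriole when a marker punctum lies within a colocalization
radius (default 500 nm — sub-diffraction proximity at 63x). CP110 removal
counts CP110 dots per cell: two when CP110 colocalizes with both FOP dots,
one when it colocalizes only with the CEP164-negative (daughter) FOP dot,
zero otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from skimage import morphology

logger = logging.getLogger(__name__)

__all__ = [
    "measure_cilium_length",
    "score_ciliation",
    "score_vesicle_positivity",
    "CellCentrioles",
    "score_cp110",
    "CILIATION_LENGTH_UM",
    "DEFAULT_COLOC_RADIUS_NM",
]

#: Minimum cilium length; comparison is strict (> 1 um).
CILIATION_LENGTH_UM = 1.0
#: Default punctum-to-centriole colocalization radius.
DEFAULT_COLOC_RADIUS_NM = 500.0

_SQRT2 = float(np.sqrt(2.0))


def _skeleton_geodesic_px(skel: np.ndarray) -> float:
    """Longest geodesic path length (px) through a skeleton, 8-connected.

    Edges between 4-neighbors cost 1, diagonal neighbors sqrt(2); the
    skeleton of a filament is (close to) a path, so the longest shortest
    path between its pixels is its geodesic length.
    """
    pts = np.argwhere(skel)
    n = len(pts)
    if n <= 1:
        return 0.0
    index = {tuple(p): i for i, p in enumerate(pts)}
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    cost = _SQRT2 if dr and dc else 1.0
                    adj[i].append((j, cost))
                    adj[j].append((i, cost))

    def far(start: int) -> tuple[int, float]:
        # Dijkstra; skeleton graphs are tiny so a heap-free scan suffices
        import heapq

        dist = np.full(n, np.inf)
        dist[start] = 0.0
        heap = [(0.0, start)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist[u]:
                continue
            for v, w in adj[u]:
                nd = d + w
                if nd < dist[v]:
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        dist[np.isinf(dist)] = -1.0
        best = int(np.argmax(dist))
        return best, float(dist[best])

    # double sweep: farthest point from an arbitrary start, then farthest
    # from that — exact for trees, excellent for near-path skeletons
    a, _ = far(0)
    _, length = far(a)
    return length


def measure_cilium_length(component_mask: np.ndarray, pixel_size_nm: float) -> float:
    """Geodesic skeleton length of a filamentous component, in micrometres."""
    component_mask = np.asarray(component_mask, dtype=bool)
    if not component_mask.any():
        raise ValueError("empty component")
    skel = morphology.skeletonize(component_mask)
    if not skel.any():  # single-pixel or degenerate component
        skel = component_mask
    length_px = _skeleton_geodesic_px(skel)
    return length_px * pixel_size_nm / 1000.0


def score_ciliation(records: pd.DataFrame, n_cells: int) -> float:
    """Fraction of cells bearing a primary cilium.

    ``records`` holds one row per cilium candidate with boolean columns
    ``arl13b_positive`` and ``centrosome_associated`` and a ``length_um``
    column. A candidate counts when ARL13B-positive, centrosome-associated
    and strictly longer than 1 um; at most one cilium per cell is assumed.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if len(records) == 0:
        return 0.0
    ok = (
        records["arl13b_positive"].astype(bool)
        & records["centrosome_associated"].astype(bool)
        & (records["length_um"] > CILIATION_LENGTH_UM)
    )
    return float(ok.sum()) / n_cells


def score_vesicle_positivity(
    distances: pd.DataFrame,
    radius_nm: float = DEFAULT_COLOC_RADIUS_NM,
    marker_columns: tuple[str, str] = ("dist_marker1_nm", "dist_marker2_nm"),
) -> dict:
    """Per-marker and double-positive centriole percentages.

    ``distances`` has one row per centriole; each marker column holds the
    distance from the nearest punctum of that marker to the centriole
    (NaN when the marker shows no punctum). A centriole is positive for a
    marker when that distance is <= ``radius_nm``.
    Returns percentages on the 0–100 scale plus the centriole count.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    n = len(distances)
    out = {"n_centrioles": n}
    positives = []
    for col in marker_columns:
        d = distances[col].to_numpy(dtype=float)
        pos = np.isfinite(d) & (d <= radius_nm)
        positives.append(pos)
        out[f"pct_{col}"] = 100.0 * pos.mean() if n else 0.0
    both = np.logical_and.reduce(positives) if positives else np.zeros(0, bool)
    out["pct_double"] = 100.0 * both.mean() if n else 0.0
    return out


@dataclass
class CellCentrioles:
    """Dot positions (nm, 2D or 3D) for one cell in the CP110 assay."""

    fop: list = dc_field(default_factory=list)  # up to two centriole anchors
    cep164: list = dc_field(default_factory=list)  # at most one mother marker
    cp110: list = dc_field(default_factory=list)


def _near(p, q, radius) -> bool:
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float))) <= radius


def score_cp110(
    cells: list[CellCentrioles],
    radius_nm: float = DEFAULT_COLOC_RADIUS_NM,
) -> pd.DataFrame:
    """CP110 dots per cell in {0, 1, 2}.

    2 — CP110 colocalizes with both FOP dots; 1 — CP110 colocalizes only
    with the CEP164-negative FOP dot (daughter centriole); 0 — otherwise.
    Cells with more than two FOP dots are skipped with a logged reason;
    skipped cells appear with ``dots = -1`` and a reason string.
    """
    rows = []
    for i, cell in enumerate(cells):
        if len(cell.fop) > 2:
            logger.warning("cell %d skipped: %d FOP dots (>2)", i, len(cell.fop))
            rows.append({"cell": i, "dots": -1, "reason": "more than two FOP dots"})
            continue
        if len(cell.cep164) > 1:
            logger.warning("cell %d skipped: %d CEP164 dots (>1)", i, len(cell.cep164))
            rows.append({"cell": i, "dots": -1, "reason": "more than one CEP164 dot"})
            continue
        hits = [
            any(_near(f, c, radius_nm) for c in cell.cp110) for f in cell.fop
        ]
        mother = [
            any(_near(f, m, radius_nm) for m in cell.cep164) for f in cell.fop
        ]
        if len(cell.fop) == 2 and all(hits):
            dots = 2
        elif any(h and not m for h, m in zip(hits, mother)) and not any(
            h and m for h, m in zip(hits, mother)
        ):
            dots = 1
        else:
            dots = 0
        rows.append({"cell": i, "dots": dots, "reason": ""})
    return pd.DataFrame(rows)
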