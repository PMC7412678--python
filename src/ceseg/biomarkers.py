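"""Clinical morphometry of the segmented endothelial mosaic.

Three biomarkers summarise endothelial health:

* ECD (endothelial cell density, cells/mm^2): the mean cell area
  S_bar = sum(S_i)/n in px^2 converted through the pixel pitch,
  density = 10^6 / (S_bar * pitch^2).  Each cell's area is
  S_i = B_i + E_i/2: its body pixel count plus half of the edge pixels
  adjacent to it, since every 1-px border is shared by two cells.
* CV (polymegethism, %): population coefficient of variation of cell
  areas, 100 * sqrt(sum((S_i - S_bar)^2)/n) / S_bar.
* HEX (pleomorphism, %): percentage of six-sided cells, where the side
  count is the number of neighbouring cells in the region-adjacency
  graph.  Two cells are neighbours iff they share a boundary run of at
  least 2 edge pixels, so corner-touching cells do not count as sides.

Cells in contact with the image borders, and cells outside the
region-of-interest mask (the gold-standard coverage), are excluded from
all three estimators identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .postprocess import CellSegmentation

__all__ = [
    "CellRecord",
    "Biomarkers",
    "DEFAULT_PIXEL_PITCH",
    "cell_areas",
    "ecd",
    "cv",
    "hexagonality",
    "compute_biomarkers",
]

#: lateral pixel size of the specular microscope, um per pixel
DEFAULT_PIXEL_PITCH = 1.038

_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class CellRecord:
    """Per-cell pixel accounting and adjacency."""

    label: int
    body: int            # B_i, body pixel count
    edge: int            # E_i, edge pixels whose 8-neighbourhood touches the cell
    neighbors: int       # number of adjacent cells (shared boundary >= 2 px)
    touches_border: bool
    in_roi: bool

    @property
    def area(self) -> float:
        """S_i = B_i + E_i / 2, in pixels."""
        return self.body + self.edge / 2.0

    @property
    def included(self) -> bool:
        return self.in_roi and not self.touches_border


@dataclass
class Biomarkers:
    ecd: float        # cells/mm^2
    cv: float         # %
    hex: float        # %
    n: int            # cells used
    n_hex: int        # six-sided cells among those used
    mean_area: float  # S_bar, px^2


def _as_labels(seg: CellSegmentation | np.ndarray) -> np.ndarray:
    labels = seg.labels if isinstance(seg, CellSegmentation) else np.asarray(seg)
    if labels.ndim != 2:
        raise ValueError("segmentation must be a 2-D label grid")
    if labels.min() < 0:
        raise ValueError("labels must be >= 0 (0 = edge skeleton)")
    return labels


def _edge_adjacency(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(edge pixel flat index, adjacent cell label) pairs, deduplicated.

    Returns flat edge-pixel indices, the adjacent label for each pair, and
    the boolean border-ring membership of each edge pixel.
    """
    h, w = labels.shape
    edge_idx = np.flatnonzero(labels.ravel() == 0)
    ey, ex = np.unravel_index(edge_idx, labels.shape)
    pairs = []
    for dy, dx in _SHIFTS:
        ny, nx = ey + dy, ex + dx
        ok = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        lab = labels[ny[ok], nx[ok]]
        pos = lab > 0
        pairs.append(np.stack([edge_idx[ok][pos], lab[pos]], axis=1))
    if pairs:
        all_pairs = np.unique(np.concatenate(pairs, axis=0), axis=0)
    else:
        all_pairs = np.empty((0, 2), dtype=int)
    border = (ey == 0) | (ey == h - 1) | (ex == 0) | (ex == w - 1)
    border_flat = np.zeros(h * w, dtype=bool)
    border_flat[edge_idx] = border
    return all_pairs[:, 0], all_pairs[:, 1], border_flat


def _neighbor_counts(labels: np.ndarray, n_labels: int, *, min_run: int = 2) -> np.ndarray:
    """Neighbour count per label from the edge-skeleton adjacency graph."""
    pix, lab, _ = _edge_adjacency(labels)
    counts = np.zeros(n_labels + 1, dtype=int)
    if len(pix) == 0:
        return counts
    # group the labels adjacent to each edge pixel, then enumerate pairs
    order = np.argsort(pix, kind="stable")
    pix, lab = pix[order], lab[order]
    starts = np.flatnonzero(np.r_[True, pix[1:] != pix[:-1]])
    ends = np.r_[starts[1:], len(pix)]
    pair_list = []
    for s, e in zip(starts, ends):
        ls = lab[s:e]
        if len(ls) > 1:
            a, b = np.meshgrid(ls, ls, indexing="ij")
            m = a < b
            pair_list.append(np.stack([a[m], b[m]], axis=1))
    if not pair_list:
        return counts
    pairs = np.concatenate(pair_list, axis=0)
    uniq, support = np.unique(pairs, axis=0, return_counts=True)
    good = uniq[support >= min_run]
    for a, b in good:
        counts[a] += 1
        counts[b] += 1
    return counts


def cell_areas(
    seg: CellSegmentation | np.ndarray,
    roi: np.ndarray | None = None,
    *,
    min_adjacency_run: int = 2,
) -> list[CellRecord]:
    """Per-cell body/edge pixel accounting with exclusion flags.

    ``roi`` is the boolean coverage mask of the gold standard; a cell is
    inside the ROI iff all of its body pixels are covered.  With
    ``roi=None`` the whole frame counts as covered.
    ``min_adjacency_run`` is the shared-boundary length (in edge pixels)
    below which two cells do not count as neighbours; 2 px at the native
    resolution excludes corner-touching cells, and it should be scaled
    with any resampling of the segmentation.
    """
    labels = _as_labels(seg)
    h, w = labels.shape
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != labels.shape:
            raise ValueError("ROI mask shape must match the segmentation")
        if not roi.any():
            raise ValueError("empty ROI: no cell can be evaluated")
    n_labels = int(labels.max())
    if n_labels < 1:
        raise ValueError("segmentation contains no cells")

    body = np.bincount(labels.ravel(), minlength=n_labels + 1)

    pix, lab, border_flat = _edge_adjacency(labels)
    edge_count = np.bincount(lab, minlength=n_labels + 1) if len(lab) else np.zeros(n_labels + 1, int)

    # border contact: body pixel on the frame border, or adjacent edge pixel on it
    flat = labels.ravel()
    border_ring = np.zeros((h, w), dtype=bool)
    border_ring[0, :] = border_ring[-1, :] = True
    border_ring[:, 0] = border_ring[:, -1] = True
    touches = np.zeros(n_labels + 1, dtype=bool)
    body_on_border = flat[border_ring.ravel()]
    touches[np.unique(body_on_border[body_on_border > 0])] = True
    if len(pix):
        edge_on_border = lab[border_flat[pix]]
        touches[np.unique(edge_on_border)] = True

    in_roi = np.ones(n_labels + 1, dtype=bool)
    if roi is not None:
        outside = np.bincount(flat[~roi.ravel()], minlength=n_labels + 1)
        in_roi = outside == 0

    neighbors = _neighbor_counts(labels, n_labels, min_run=min_adjacency_run)

    records = [
        CellRecord(
            label=i,
            body=int(body[i]),
            edge=int(edge_count[i]),
            neighbors=int(neighbors[i]),
            touches_border=bool(touches[i]),
            in_roi=bool(in_roi[i]),
        )
        for i in range(1, n_labels + 1)
        if body[i] > 0
    ]
    if not any(r.included for r in records):
        raise ValueError("no interior cell survives border/ROI exclusion")
    return records


def _included_areas(records: list[CellRecord]) -> np.ndarray:
    areas = np.array([r.area for r in records if r.included], dtype=float)
    if len(areas) == 0:
        raise ValueError("no included cells")
    return areas


def ecd(records: list[CellRecord], pixel_pitch: float = DEFAULT_PIXEL_PITCH) -> float:
    """Endothelial cell density in cells/mm^2 from the mean cell area."""
    if pixel_pitch <= 0:
        raise ValueError("pixel pitch must be positive")
    mean_area = _included_areas(records).mean()  # px^2
    return 1e6 / (mean_area * pixel_pitch**2)


def cv(records: list[CellRecord]) -> float:
    """Polymegethism: population coefficient of variation of cell areas, %."""
    areas = _included_areas(records)
    if len(areas) < 2:
        raise ValueError("CV requires at least 2 included cells")
    mean = areas.mean()
    sd = np.sqrt(np.mean((areas - mean) ** 2))
    return 100.0 * sd / mean


def hexagonality(records: list[CellRecord]) -> float:
    """Pleomorphism: percentage of included cells with exactly 6 neighbours."""
    included = [r for r in records if r.included]
    if not included:
        raise ValueError("no included cells")
    n_hex = sum(1 for r in included if r.neighbors == 6)
    return 100.0 * n_hex / len(included)


def compute_biomarkers(
    seg: CellSegmentation | np.ndarray,
    roi: np.ndarray | None = None,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    *,
    min_adjacency_run: int = 2,
) -> Biomarkers:
    """ECD, CV and HEX on the same included-cell set."""
    records = cell_areas(seg, roi, min_adjacency_run=min_adjacency_run)
    areas = _included_areas(records)
    included = [r for r in records if r.included]
    return Biomarkers(
        ecd=ecd(records, pixel_pitch),
        cv=cv(records),
        hex=hexagonality(records),
        n=len(included),
        n_hex=sum(1 for r in included if r.neighbors == 6),
        mean_area=float(areas.mean()),
    )
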