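"""Segmentation quality metrics and the alpha robustness sweep.

Pixel level: accuracy and AUC over all pixels (ground truth binarised at
p > 0.5); precision/sensitivity/specificity restricted to the pixels whose
probabilistic label is exactly 0 or 1 — the crest of the traced edge and
the inner cell body — marked with an asterisk (PRE*, SEN*, SPE*).

Cell level: each gold-standard cell C_i is matched with the proposed
superpixel S_j of largest overlap; DICE_i = 2 TP / (2 TP + FP + FN) and the
image DICE is their mean.  A cell is correctly segmented iff
TP_i > 0.80 * max(|C_i|, |S_j|); a failing cell is undersegmented when its
superpixel is the larger of the two (one superpixel covers several cells)
and oversegmented otherwise (the cell is split across superpixels).

Boundary distance: the modified Hausdorff distance between the two 1-px
edge skeletons, MHD(U, V) = max(hd(U, V), hd(V, U)) with hd the mean
directed nearest-neighbour Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score

from . import postprocess
from .postprocess import CellSegmentation, SmoothingParams

__all__ = [
    "PixelMetrics",
    "CellMatchReport",
    "pixel_metrics",
    "mhd",
    "cell_dice",
    "cell_match",
    "alpha_sweep",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID = np.round(np.linspace(0.60, 1.40, 17), 2)


@dataclass
class PixelMetrics:
    accuracy: float          # %, over all pixels
    auc: float               # NaN when undefined (single-class ground truth)
    auc_defined: bool
    precision_star: float    # on {p=0, p=1} pixels only, edge = positive
    sensitivity_star: float
    specificity_star: float


@dataclass
class CellMatchReport:
    n_cells: int             # evaluated gold-standard cells
    correct_pct: float
    oversegmented_pct: float
    undersegmented_pct: float
    per_cell_dice: list[float] = field(repr=False)
    image_dice: float = float("nan")
    mhd: float = float("nan")


def pixel_metrics(pred: np.ndarray, label: np.ndarray) -> PixelMetrics:
    """Pixel-level network metrics against a probabilistic label."""
    pred = np.asarray(pred, dtype=float)
    label = np.asarray(label, dtype=float)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {label.shape}")
    y = (label > 0.5).ravel()
    score = pred.ravel()
    accuracy = 100.0 * np.mean((score > 0.5) == y)
    auc_defined = bool(y.any() and not y.all())
    auc = float(roc_auc_score(y, score)) if auc_defined else float("nan")

    starred = (label == 0.0) | (label == 1.0)
    pos = label == 1.0
    pred_edge = pred > 0.5
    tp = np.sum(starred & pos & pred_edge)
    fn = np.sum(starred & pos & ~pred_edge)
    fp = np.sum(starred & ~pos & pred_edge)
    tn = np.sum(starred & ~pos & ~pred_edge)
    pre = tp / (tp + fp) if (tp + fp) else float("nan")
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spe = tn / (tn + fp) if (tn + fp) else float("nan")
    return PixelMetrics(
        accuracy=float(accuracy),
        auc=auc,
        auc_defined=auc_defined,
        precision_star=float(pre),
        sensitivity_star=float(sen),
        specificity_star=float(spe),
    )


def mhd(u: np.ndarray, v: np.ndarray) -> float:
    """Modified Hausdorff distance between two point sets (n, 2)."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if len(u) == 0 or len(v) == 0:
        raise ValueError("MHD is undefined for empty point sets")
    d_uv = cKDTree(v).query(u)[0].mean()
    d_vu = cKDTree(u).query(v)[0].mean()
    return float(max(d_uv, d_vu))


def _labels_of(seg: CellSegmentation | np.ndarray) -> np.ndarray:
    return seg.labels if isinstance(seg, CellSegmentation) else np.asarray(seg)


def _overlap_matrix(truth: np.ndarray, pred: np.ndarray) -> dict[int, dict[int, int]]:
    """truth label -> {pred label -> overlap pixel count}, truth > 0 only."""
    mask = truth > 0
    t = truth[mask].astype(np.int64)
    p = pred[mask].astype(np.int64)
    key = t * (pred.max() + 1) + p
    uniq, counts = np.unique(key, return_counts=True)
    out: dict[int, dict[int, int]] = {}
    base = pred.max() + 1
    for k, c in zip(uniq, counts):
        ti, pi = divmod(int(k), int(base))
        out.setdefault(ti, {})[pi] = int(c)
    return out


def _evaluated_cells(truth: np.ndarray, roi: np.ndarray | None) -> np.ndarray:
    """Gold-standard cell ids kept for evaluation (interior, inside ROI)."""
    h, w = truth.shape
    keep = np.ones(int(truth.max()) + 1, dtype=bool)
    keep[0] = False
    border = np.concatenate([truth[0, :], truth[-1, :], truth[:, 0], truth[:, -1]])
    keep[np.unique(border[border > 0])] = False
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        outside = np.bincount(truth[~roi].ravel(), minlength=len(keep))
        keep &= outside == 0
    return np.flatnonzero(keep)


def _best_matches(
    truth: np.ndarray, pred: np.ndarray, cells: np.ndarray
) -> tuple[dict[int, int], dict[int, int], np.ndarray, np.ndarray]:
    """Best-overlap superpixel and TP per evaluated truth cell."""
    overlaps = _overlap_matrix(truth, pred)
    truth_sizes = np.bincount(truth.ravel())
    pred_sizes = np.bincount(pred.ravel())
    best: dict[int, int] = {}
    tp: dict[int, int] = {}
    for ci in cells:
        row = overlaps.get(int(ci), {})
        candidates = {pj: n for pj, n in row.items() if pj > 0}
        if not candidates:
            best[int(ci)], tp[int(ci)] = 0, 0
            continue
        pj = max(candidates, key=lambda j: (candidates[j], -j))
        best[int(ci)] = int(pj)
        tp[int(ci)] = candidates[pj]
    return best, tp, truth_sizes, pred_sizes


def cell_dice(
    truth: CellSegmentation | np.ndarray,
    pred: CellSegmentation | np.ndarray,
    roi: np.ndarray | None = None,
) -> tuple[dict[int, float], float]:
    """Per-cell and image-level DICE of the best-overlap matching."""
    t, p = _labels_of(truth), _labels_of(pred)
    if t.shape != p.shape:
        raise ValueError("segmentations must share the same frame")
    cells = _evaluated_cells(t, roi)
    if len(cells) == 0:
        raise ValueError("no evaluable gold-standard cells")
    best, tp, t_sizes, p_sizes = _best_matches(t, p, cells)
    per_cell: dict[int, float] = {}
    for ci in cells:
        ci = int(ci)
        tpi = tp[ci]
        if tpi == 0:
            per_cell[ci] = 0.0
            continue
        fn = t_sizes[ci] - tpi
        fp = p_sizes[best[ci]] - tpi
        per_cell[ci] = 2.0 * tpi / (2.0 * tpi + fp + fn)
    image = float(np.mean(list(per_cell.values())))
    return per_cell, image


def cell_match(
    truth: CellSegmentation | np.ndarray,
    pred: CellSegmentation | np.ndarray,
    roi: np.ndarray | None = None,
    *,
    with_distances: bool = True,
) -> CellMatchReport:
    """Classify evaluated cells as correct / oversegmented / undersegmented."""
    t, p = _labels_of(truth), _labels_of(pred)
    if t.shape != p.shape:
        raise ValueError("segmentations must share the same frame")
    cells = _evaluated_cells(t, roi)
    if len(cells) == 0:
        raise ValueError("no evaluable gold-standard cells")
    best, tp, t_sizes, p_sizes = _best_matches(t, p, cells)

    status: dict[int, str] = {}
    for ci in cells:
        ci = int(ci)
        sj = best[ci]
        tpi = tp[ci]
        if sj > 0 and tpi > 0.80 * max(t_sizes[ci], p_sizes[sj]):
            status[ci] = "correct"
        elif sj > 0 and p_sizes[sj] > t_sizes[ci]:
            status[ci] = "under"
        else:
            status[ci] = "over"
    # a superpixel that is best match for several truth cells covers more
    # than one cell: its failing matches are undersegmentations
    matches_per_sj: dict[int, list[int]] = {}
    for ci in cells:
        matches_per_sj.setdefault(best[int(ci)], []).append(int(ci))
    for sj, cis in matches_per_sj.items():
        if sj > 0 and len(cis) >= 2:
            for ci in cis:
                if status[ci] != "correct":
                    status[ci] = "under"

    n = len(cells)
    n_corr = sum(1 for s in status.values() if s == "correct")
    n_over = sum(1 for s in status.values() if s == "over")
    n_under = sum(1 for s in status.values() if s == "under")

    per_cell, image = cell_dice(t, p, roi)
    report = CellMatchReport(
        n_cells=n,
        correct_pct=100.0 * n_corr / n,
        oversegmented_pct=100.0 * n_over / n,
        undersegmented_pct=100.0 * n_under / n,
        per_cell_dice=[per_cell[int(ci)] for ci in cells],
        image_dice=image,
    )
    if with_distances:
        roi_mask = np.ones_like(t, dtype=bool) if roi is None else np.asarray(roi, bool)
        u = np.argwhere((t == 0) & roi_mask)
        v = np.argwhere((p == 0) & roi_mask)
        if len(u) and len(v):
            report.mhd = mhd(u, v)
    return report


def alpha_sweep(
    prob_maps: list[np.ndarray],
    truths: list[CellSegmentation | np.ndarray],
    rois: list[np.ndarray] | None = None,
    alphas: np.ndarray = DEFAULT_ALPHA_GRID,
    *,
    k_sigma: float = postprocess.DEFAULT_K_SIGMA,
) -> pd.DataFrame:
    """Robustness of the postprocessing to scaling of f*.

    For each alpha in the grid, every map is segmented with
    sigma = k_sigma / (alpha f*) and the mean percentage of wrongly
    detected cells (over- plus under-segmented) is reported.  The
    characteristic frequency is estimated once per map; only the
    smoothing scale varies with alpha.
    """
    if len(prob_maps) != len(truths):
        raise ValueError("need one truth per probability map")
    if rois is None:
        rois = [None] * len(prob_maps)
    base_params: list[SmoothingParams] = []
    for m in prob_maps:
        spectrum = postprocess.radial_magnitude(m)
        base_params.append(postprocess.estimate_characteristic_frequency(spectrum, k_sigma=k_sigma))
    rows = []
    for alpha in np.asarray(alphas, dtype=float):
        wrong, over, under = [], [], []
        for m, t, roi, bp in zip(prob_maps, truths, rois, base_params):
            seg = postprocess.segment(m, alpha, k_sigma=k_sigma, params=bp)
            rep = cell_match(t, seg, roi, with_distances=False)
            over.append(rep.oversegmented_pct)
            under.append(rep.undersegmented_pct)
            wrong.append(rep.oversegmented_pct + rep.undersegmented_pct)
        rows.append(
            {
                "alpha": float(alpha),
                "wrong_pct": float(np.mean(wrong)),
                "oversegmented_pct": float(np.mean(over)),
                "undersegmented_pct": float(np.mean(under)),
            }
        )
    return pd.DataFrame(rows)
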