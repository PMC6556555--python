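"""Three-scale evaluation of harmonised feature maps.

Predicted scalar maps (FA, MD, R0, R2) are compared with the maps derived
from the actually acquired target data via three voxel-wise errors:

* ME  = predicted - acquired              (signed accuracy)
* MNE = (predicted - acquired)/acquired   (relative accuracy)
* MSE = (predicted - acquired)^2          (accuracy + precision)

aggregated at three scales: globally (mean over a brain mask), regionally
(per-ROI mean within subject, then median across subjects) and locally
(mean over sliding 3x3x3 neighbourhoods, pooled across subjects and
summarised by median and 95th percentile).

Voxels at the edge of the brain are excluded by eroding the mask; voxels
with a near-zero acquired value are excluded from MNE; regions that score
systematically poorly (at or above the tissue-class-specific 90th
percentile of the regional median MSE for >= 3 algorithms in >= 1 feature)
can be flagged and excluded from the local analysis.  All exclusions are
counted so mask accounting sums to the full mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ErrorMaps",
    "erode_mask",
    "error_maps",
    "global_error",
    "regional_error",
    "local_error",
    "flag_poor_regions",
    "summarise",
]

MNE_EPS = 1e-6
ERROR_KINDS = ("me", "mne", "mse")


@dataclass
class ErrorMaps:
    """Per-voxel error fields for one scalar feature of one subject."""

    me: np.ndarray
    mne: np.ndarray
    mse: np.ndarray
    mask: np.ndarray  # voxels where me/mse are valid
    mne_mask: np.ndarray  # additionally excludes near-zero denominators
    n_excluded_nonfinite: int = 0
    n_excluded_denominator: int = 0

    def kind(self, kind: str) -> tuple[np.ndarray, np.ndarray]:
        if kind not in ERROR_KINDS:
            raise ValueError(f"unknown error kind {kind!r}")
        m = self.mne_mask if kind == "mne" else self.mask
        return getattr(self, kind), m


def erode_mask(mask: np.ndarray, width: int = 1) -> np.ndarray:
    """Drop ``width`` voxels at the mask boundary (edge-of-brain exclusion)."""
    mask = np.asarray(mask).astype(bool)
    if width == 0:
        return mask
    return ndimage.binary_erosion(mask, iterations=width, border_value=0)


def error_maps(pred: np.ndarray, acq: np.ndarray, mask: np.ndarray) -> ErrorMaps:
    """Element-wise ME/MNE/MSE fields inside ``mask``."""
    pred = np.asarray(pred, dtype=float)
    acq = np.asarray(acq, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if pred.shape != acq.shape or pred.shape != mask.shape:
        raise ValueError(
            f"grid mismatch: pred {pred.shape}, acq {acq.shape}, mask {mask.shape}"
        )
    finite = np.isfinite(pred) & np.isfinite(acq)
    valid = mask & finite
    e = np.where(valid, pred - acq, 0.0)
    denom_ok = np.abs(acq) >= MNE_EPS
    mne_mask = valid & denom_ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mne = np.where(mne_mask, e / np.where(denom_ok, acq, 1.0), 0.0)
    return ErrorMaps(
        me=e,
        mne=mne,
        mse=e**2,
        mask=valid,
        mne_mask=mne_mask,
        n_excluded_nonfinite=int(np.count_nonzero(mask & ~finite)),
        n_excluded_denominator=int(np.count_nonzero(valid & ~denom_ok)),
    )


def global_error(maps: ErrorMaps) -> dict[str, float]:
    """Mean of each error field over its valid mask."""
    out = {}
    for kind in ERROR_KINDS:
        e, m = maps.kind(kind)
        if not np.any(m):
            raise ValueError("empty mask after exclusions")
        out[kind] = float(e[m].mean())
    return out


def regional_error(
    subject_maps: list[ErrorMaps],
    subject_labels: list[np.ndarray],
    kind: str = "mse",
) -> pd.DataFrame:
    """Per-ROI mean within subject, then median across subjects.

    Returns a DataFrame indexed by ROI label with columns ``median`` and
    ``n_subjects`` (labels absent or empty in a subject are excluded from
    that subject's contribution).  Label 0 is background and ignored.
    """
    if len(subject_maps) == 0:
        raise ValueError("need at least one subject")
    if len(subject_maps) != len(subject_labels):
        raise ValueError("one label map per subject required")
    per_subject: list[dict[int, float]] = []
    all_labels: set[int] = set()
    for maps, labels in zip(subject_maps, subject_labels):
        labels = np.asarray(labels)
        e, m = maps.kind(kind)
        vals = {}
        for lab in np.unique(labels[labels > 0]):
            sel = (labels == lab) & m
            if np.any(sel):
                vals[int(lab)] = float(e[sel].mean())
        per_subject.append(vals)
        all_labels.update(vals)
    rows = []
    for lab in sorted(all_labels):
        vv = [s[lab] for s in per_subject if lab in s]
        rows.append({"label": lab, "median": float(np.median(vv)), "n_subjects": len(vv)})
    return pd.DataFrame(rows).set_index("label")


def local_error(maps: ErrorMaps, kind: str = "mse", window: int = 3) -> np.ndarray:
    """Pooled distribution of means over fully-in-mask ``window``^3 blocks."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    e, m = maps.kind(kind)
    if window == 1:
        return e[m]
    k = np.ones((window,) * 3)
    counts = ndimage.convolve(m.astype(float), k, mode="constant")
    sums = ndimage.convolve(np.where(m, e, 0.0), k, mode="constant")
    full = counts > window**3 - 0.5
    if not np.any(full):
        raise ValueError("no fully-in-mask neighbourhood")
    return sums[full] / counts[full]


def flag_poor_regions(
    regional_tables: dict[str, pd.DataFrame],
    tissue_class: dict[int, str],
    percentile: float = 90.0,
    min_algorithms: int = 3,
) -> set[int]:
    """Systematically poor ROIs across algorithms.

    ``regional_tables`` maps algorithm name -> DataFrame whose columns are
    feature names and whose index is the ROI label (regional median MSE per
    feature).  An ROI is flagged iff its value is at or above the
    ``percentile``-th percentile within its tissue class (WM or GM) for at
    least ``min_algorithms`` algorithms in at least one feature.
    """
    if len(regional_tables) < min_algorithms:
        raise ValueError(f"need >= {min_algorithms} algorithms")
    algos = list(regional_tables)
    features = list(regional_tables[algos[0]].columns)
    labels = list(regional_tables[algos[0]].index)
    missing = [lab for lab in labels if lab not in tissue_class]
    if missing:
        raise ValueError(f"labels without tissue class: {missing}")

    flagged: set[int] = set()
    for feat in features:
        # count, per ROI, how many algorithms put it at/above the class threshold
        counts = {lab: 0 for lab in labels}
        for algo in algos:
            col = regional_tables[algo][feat]
            for cls in set(tissue_class.values()):
                cls_labels = [lab for lab in labels if tissue_class[lab] == cls]
                vals = col.loc[cls_labels].to_numpy(dtype=float)
                thr = np.percentile(vals, percentile)
                for lab, v in zip(cls_labels, vals):
                    # strict inequality of the threshold against the rest:
                    # ties at the threshold count as "at the percentile"
                    if v >= thr and v > vals.min():
                        counts[lab] += 1
        for lab, c in counts.items():
            if c >= min_algorithms:
                flagged.add(lab)
    return flagged


def summarise(distribution: np.ndarray) -> tuple[float, float]:
    """Median and 95th percentile (linear-interpolation quantiles)."""
    d = np.asarray(distribution, dtype=float)
    if d.size == 0:
        raise ValueError("empty distribution")
    return float(np.median(d)), float(np.percentile(d, 95))
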