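"""Tumor detection and quantitative evaluation.

Detection thresholds a reconstructed real-permittivity volume at a
fraction (85% by default) of its maximum; multi-frequency detection ANDs
the per-frequency masks.  Separability of tumor from non-tumor voxels is
quantified by the voxel-pooled ROC curve and its AUC, the DMTD curve
(Euclidean distance from each ROC operating point to the ideal corner
FPR=0, TPR=1, as a function of the detection threshold), and the
reconstruction error of the enhanced images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .unet import loss_mse, loss_rms

__all__ = [
    "BinaryMask",
    "RocCurve",
    "DmtdCurve",
    "threshold_detect",
    "intersect_masks",
    "intersection_score",
    "roc_analysis",
    "dmtd",
    "reconstruction_error",
    "compare_methods",
    "DetectionReport",
]


@dataclass
class BinaryMask:
    """Boolean detection volume aligned with its source grid."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.values.sum())


def threshold_detect(volume: np.ndarray, frac: float = 0.85,
                     region: np.ndarray | None = None) -> BinaryMask:
    """Voxels at or above ``frac`` of the volume maximum inside ``region``.

    The 85% default follows the practice of thresholding relative to the
    maximum reconstructed value, since reconstructions undershoot the
    true tumor permittivity.
    """
    if not 0 < frac <= 1:
        raise ValueError("threshold fraction must be in (0, 1]")
    vol = np.asarray(volume, dtype=float)
    if region is None:
        region = np.ones(vol.shape, dtype=bool)
    vmax = vol[region].max() if region.any() else 0.0
    if vmax <= 0:
        warnings.warn("volume has no positive values; detection mask is empty",
                      RuntimeWarning)
        return BinaryMask(np.zeros(vol.shape, dtype=bool))
    return BinaryMask((vol >= frac * vmax) & region)


def intersect_masks(masks) -> BinaryMask:
    """Voxel-wise AND of detection masks on one grid."""
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    out = masks[0].values.copy()
    for m in masks[1:]:
        if m.values.shape != out.shape:
            raise ValueError("masks live on different grids")
        out &= m.values
    return BinaryMask(out)


def intersection_score(volumes, region: np.ndarray | None = None) -> np.ndarray:
    """Continuous score whose level sets are multi-frequency intersections.

    Each volume is normalized by its own maximum (inside ``region``); the
    score is the minimum across frequencies, so ``score >= t`` is exactly
    the AND of the per-frequency masks thresholded at fraction ``t``.
    """
    vols = [np.asarray(v, dtype=float) for v in volumes]
    if region is None:
        region = np.ones(vols[0].shape, dtype=bool)
    normed = []
    for v in vols:
        vmax = v[region].max()
        normed.append(v / vmax if vmax > 0 else np.zeros_like(v))
    return np.min(normed, axis=0)


@dataclass
class RocCurve:
    """ROC operating points ordered from the highest threshold down."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def __post_init__(self):
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve must be monotone non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0
                and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must include (0,0) and (1,1)")


def roc_analysis(scores, truth, region=None) -> RocCurve:
    """Voxel-pooled ROC of tumor vs non-tumor scores.

    ``scores``/``truth`` may be single volumes or sequences of volumes
    (pooled); ``truth`` is boolean tumor ground truth.  ``region``
    restricts pooling (e.g. the breast interior, excluding air).  AUC is
    the trapezoidal area under the curve.
    """
    s, y = _pool(scores, truth, region)
    if y.all() or not y.any():
        raise ValueError("need both tumor and non-tumor voxels for a ROC")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    if fpr[0] != 0 or tpr[0] != 0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
        thr = np.concatenate([[np.inf], thr])
    if fpr[-1] != 1 or tpr[-1] != 1:
        fpr = np.concatenate([fpr, [1.0]])
        tpr = np.concatenate([tpr, [1.0]])
        thr = np.concatenate([thr, [-np.inf]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def _pool(scores, truth, region):
    def listify(v):
        if isinstance(v, (list, tuple)):
            return [np.asarray(x) for x in v]
        return [np.asarray(v)]

    svols, yvols = listify(scores), listify(truth)
    if region is None:
        rvols = [np.ones(s.shape, dtype=bool) for s in svols]
    elif isinstance(region, (list, tuple)):
        rvols = [np.asarray(r, dtype=bool) for r in region]
    else:
        rvols = [np.asarray(region, dtype=bool)] * len(svols)
    if len(svols) != len(yvols):
        raise ValueError("scores and truth counts differ")
    s, y = [], []
    for sv, yv, rv in zip(svols, yvols, rvols):
        if sv.shape != yv.shape:
            raise ValueError("score and truth volumes are not aligned")
        s.append(sv[rv].ravel())
        y.append(yv[rv].astype(bool).ravel())
    return np.concatenate(s), np.concatenate(y)


@dataclass
class DmtdCurve:
    """Distance-to-MaxTD: distance from ROC points to the (0, 1) corner.

    The x axis is the detection threshold normalized to [0, 1] across the
    finite thresholds of the ROC; the dip minimum, its location and its
    width (where distance <= min + 0.05) summarize detection quality,
    tumor/background separation and robustness of the threshold choice.
    """

    thresholds: np.ndarray   # normalized to [0, 1]
    distances: np.ndarray
    min_distance: float
    argmin_threshold: float
    dip_width: float

    def __post_init__(self):
        if np.any(self.distances < -1e-12) or \
                np.any(self.distances > np.sqrt(2) + 1e-12):
            raise ValueError("DMTD distances must lie in [0, sqrt(2)]")


def dmtd(roc: RocCurve, dip_slack: float = 0.05) -> DmtdCurve:
    """DMTD curve of a ROC: d(t) = sqrt(FPR(t)^2 + (1 - TPR(t))^2)."""
    dist = np.sqrt(roc.fpr ** 2 + (1 - roc.tpr) ** 2)
    thr = roc.thresholds.astype(float)
    finite = np.isfinite(thr)
    if finite.any():
        lo, hi = thr[finite].min(), thr[finite].max()
        span = hi - lo if hi > lo else 1.0
        tnorm = np.clip((thr - lo) / span, 0.0, 1.0)
    else:
        tnorm = np.linspace(1, 0, len(thr))
    i = int(np.argmin(dist))
    dmin = float(dist[i])
    in_dip = dist <= dmin + dip_slack
    width = float(tnorm[in_dip].max() - tnorm[in_dip].min()) if in_dip.any() else 0.0
    return DmtdCurve(thresholds=tnorm, distances=dist, min_distance=dmin,
                     argmin_threshold=float(tnorm[i]), dip_width=width)


def reconstruction_error(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Mean-squared reconstruction error and its square root.

    The headline number is the pixel-wise mean of squared differences;
    the square-root variant is reported alongside it.
    """
    return {"mse": loss_mse(pred, truth), "rms": loss_rms(pred, truth)}


@dataclass
class DetectionReport:
    """Per-method ROC/AUC/DMTD/error table for one test set."""

    methods: dict = field(default_factory=dict)

    def add(self, name: str, roc: RocCurve, dm: DmtdCurve,
            error: dict | None = None):
        self.methods[name] = {"roc": roc, "dmtd": dm, "error": error}

    def table(self) -> list:
        rows = []
        for name, m in self.methods.items():
            rows.append({
                "method": name,
                "auc": m["roc"].auc,
                "min_dmtd": m["dmtd"].min_distance,
                "dip_width": m["dmtd"].dip_width,
                "mse": None if m["error"] is None else m["error"]["mse"],
                "rms": None if m["error"] is None else m["error"]["rms"],
            })
        return rows

    def to_json_dict(self) -> dict:
        out = {}
        for name, m in self.methods.items():
            out[name] = {
                "auc": m["roc"].auc,
                "roc": {"fpr": m["roc"].fpr.tolist(),
                        "tpr": m["roc"].tpr.tolist()},
                "dmtd": {"min_distance": m["dmtd"].min_distance,
                         "argmin_threshold": m["dmtd"].argmin_threshold,
                         "dip_width": m["dmtd"].dip_width},
                "error": m["error"],
            }
        return out


def plot_report(report: "DetectionReport", path, methods=None):
    """ROC and DMTD panels for selected methods (SVG/PNG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = methods or list(report.methods)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for name in names:
        m = report.methods[name]
        ax1.plot(m["roc"].fpr, m["roc"].tpr,
                 label=f"{name} (AUC {m['roc'].auc:.3f})")
        ax2.plot(m["dmtd"].thresholds, m["dmtd"].distances, label=name)
    ax1.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax1.set_xlabel("false positive rate")
    ax1.set_ylabel("true positive rate")
    ax1.legend(fontsize=7)
    ax2.set_xlabel("normalized threshold")
    ax2.set_ylabel("distance to (FPR 0, TPR 1)")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def compare_methods(csi_stacks, cnn_volumes, truth_labels, tumor_label: int,
                    region_masks, frequencies,
                    threshold_frac: float = 0.85) -> DetectionReport:
    """Tabulate detection and error for CSI, intersection and CNN scores.

    Parameters are parallel lists over test phantoms: complex CSI stacks
    (F, spatial...), CNN real-permittivity outputs, integer truth label
    volumes, and breast-interior region masks.  Scores are the real part
    of the CSI permittivity (per frequency and best-of), the normalized
    multi-frequency intersection score, and the CNN output.
    """
    truths = [np.asarray(t) == tumor_label for t in truth_labels]
    report = DetectionReport()

    n_freq = len(frequencies)
    best = None
    for fi in range(n_freq):
        scores = [np.asarray(st)[fi].real for st in csi_stacks]
        roc = roc_analysis(scores, truths, region_masks)
        name = f"csi_{frequencies[fi] / 1e9:.2f}GHz"
        err = _pooled_error(scores, truth_labels, tumor_label)
        report.add(name, roc, dmtd(roc), err)
        if best is None or roc.auc > best[1].auc:
            best = (name, roc)
    report.methods["csi_best_single"] = dict(report.methods[best[0]])

    inter = [intersection_score([np.asarray(st)[fi].real
                                 for fi in range(n_freq)], rm)
             for st, rm in zip(csi_stacks, region_masks)]
    roc_i = roc_analysis(inter, truths, region_masks)
    report.add("csi_intersection", roc_i, dmtd(roc_i), None)

    if cnn_volumes is not None:
        cnn = [np.asarray(v) for v in cnn_volumes]
        roc_c = roc_analysis(cnn, truths, region_masks)
        err = _pooled_error(cnn, truth_labels, tumor_label)
        report.add("cnn", roc_c, dmtd(roc_c), err)
    return report


def _pooled_error(pred_volumes, truth_labels, tumor_label) -> dict:
    """Eq.-style error of predictions against the tissue-table truth."""
    from .phantoms import TissueTable

    table = np.zeros(4, dtype=complex)
    for k, v in TissueTable().lookup().items():
        table[k] = v
    pred = np.concatenate([np.asarray(p).ravel() for p in pred_volumes])
    truth = np.concatenate([table[np.asarray(t)].real.ravel()
                            for t in truth_labels])
    return reconstruction_error(pred, truth)
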