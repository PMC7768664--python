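"""Restoration-quality metrics and biometric error rates.

Skeleton recovery compares a restored skeleton against ground truth inside
the damaged area with a pixel tolerance (distance-transform based). The
improvement ratio r = (S_restore - S_frac) / (S_ideal - S_frac) normalizes a
matcher-score gain by the headroom between the fractured and the ideal
score. EER / FMR1000 / ROC / CMC are computed from externally supplied
genuine and impostor score lists; no matcher is bundled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi


@dataclass
class ScoreTriple:
    s_frac: float
    s_restore: float
    s_ideal: float


@dataclass
class ScoreSet:
    genuine: np.ndarray
    impostor: np.ndarray

    def __post_init__(self):
        self.genuine = np.asarray(self.genuine, dtype=float)
        self.impostor = np.asarray(self.impostor, dtype=float)
        if self.genuine.size == 0 or self.impostor.size == 0:
            raise ValueError("both genuine and impostor scores are required")


def improvement_ratio(t: ScoreTriple) -> float:
    """Normalized match-score gain; 1 = full recovery, 0 = no improvement."""
    denom = t.s_ideal - t.s_frac
    if abs(denom) < 1e-12:
        raise ValueError("improvement ratio undefined: s_ideal equals s_frac")
    return (t.s_restore - t.s_frac) / denom


def skeleton_recovery(restored: np.ndarray, truth: np.ndarray,
                      mask: np.ndarray | None = None, tol: float = 2.0):
    """(recall, precision) of restored vs true skeleton pixels within ``mask``.

    recall: fraction of true pixels (in the mask) within ``tol`` of a restored
    pixel; precision: fraction of restored pixels (in the mask) within ``tol``
    of a true pixel. Precision is NaN when nothing was restored in the mask.
    """
    restored = np.asarray(restored).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if restored.shape != truth.shape:
        raise ValueError("shape mismatch")
    mask = np.ones_like(truth) if mask is None else np.asarray(mask).astype(bool)
    truth_in = truth & mask
    rest_in = restored & mask
    if not truth_in.any():
        raise ValueError("no true skeleton pixels inside the mask: recall undefined")
    if restored.any():
        d_to_rest = ndi.distance_transform_edt(~restored)
        recall = float((d_to_rest[truth_in] <= tol).mean())
    else:
        recall = 0.0
    if rest_in.any():
        d_to_truth = ndi.distance_transform_edt(~truth)
        precision = float((d_to_truth[rest_in] <= tol).mean())
    else:
        precision = float("nan")
    return recall, precision


def _rates(scores: ScoreSet):
    thresholds = np.unique(np.concatenate([scores.genuine, scores.impostor]))
    if len(thresholds) < 2:
        raise ValueError("degenerate score lists: a single distinct value")
    fmr = np.array([(scores.impostor >= t).mean() for t in thresholds])
    fnmr = np.array([(scores.genuine < t).mean() for t in thresholds])
    return thresholds, fmr, fnmr


def eer_fmr(scores: ScoreSet, ranked: list | None = None):
    """EER, FNMR @ FMR<=0.1% (FMR1000), the ROC, and optionally the CMC.

    EER is linearly interpolated where FMR - FNMR changes sign as the
    threshold sweeps the observed scores. ``ranked`` is an optional list of
    true-match ranks (1-based) from identification trials; when given, the
    CMC curve (fraction identified within rank k) is computed from it.
    """
    thresholds, fmr, fnmr = _rates(scores)
    diff = fmr - fnmr
    idx = np.where(np.diff(np.sign(diff)) != 0)[0]
    if len(idx) == 0:
        # curves never cross inside the range: EER at the closest point
        k = int(np.argmin(np.abs(diff)))
        eer = float((fmr[k] + fnmr[k]) / 2)
    else:
        k = int(idx[0])
        d0, d1 = diff[k], diff[k + 1]
        w = 0.0 if d1 == d0 else d0 / (d0 - d1)
        eer = float((1 - w) * (fmr[k] + fnmr[k]) / 2 + w * (fmr[k + 1] + fnmr[k + 1]) / 2)
    ok = fmr <= 0.001
    fmr1000 = float(fnmr[ok][0]) if ok.any() else 1.0
    roc = np.stack([fmr, 1.0 - fnmr], axis=1)
    cmc = None
    if ranked is not None:
        ranked = np.asarray(ranked, dtype=int)
        kmax = int(ranked.max())
        cmc = np.array([(ranked <= k).mean() for k in range(1, kmax + 1)])
    return eer, fmr1000, roc, cmc


def read_scores_csv(path) -> ScoreSet:
    """Read ``pair_id, kind{genuine|impostor}, score`` CSV score exports."""
    genuine, impostor = [], []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() == "pair_id":
                continue
            kind = row[1].strip().lower()
            score = float(row[2])
            (genuine if kind == "genuine" else impostor).append(score)
    return ScoreSet(genuine=np.array(genuine), impostor=np.array(impostor))
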