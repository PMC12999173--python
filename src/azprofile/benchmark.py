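"""Detection benchmarking: one-to-one matching against ground truth,
precision / recall / F-score, and parameter sweeps.

Detected maxima are matched to ground-truth centres greedily by distance
(candidate pairs within the tolerance sorted ascending, both endpoints must
be unmatched), which mirrors scoring detections against a manual
annotation.  F = 2PR / (P + R), the harmonic mean of precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .segment import find_maxima_3d

#: default match tolerance, um (about four lateral voxels and under one
#: axial voxel at typical confocal sampling)
DEFAULT_MATCH_TOLERANCE_UM = 0.3


@dataclass
class MatchResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    match_tolerance: float
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0


@dataclass
class SweepResult:
    thresholds: np.ndarray
    tolerances: np.ndarray
    f_matrix: np.ndarray          # [i_threshold, j_tolerance]
    best_params: tuple[float, float]
    best_f: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.f_matrix,
                            index=pd.Index(self.thresholds, name="threshold"),
                            columns=pd.Index(self.tolerances, name="noise_tolerance"))


def match_detections(detected_centers, truth_centers,
                     tolerance_um: float = DEFAULT_MATCH_TOLERANCE_UM) -> MatchResult:
    """Greedy one-to-one matching of detections to truth within a tolerance.

    Candidate pairs with distance <= tolerance are sorted by distance
    ascending (ties broken by detected id, then truth id) and accepted when
    both endpoints are still unmatched.  Unmatched detections are false
    positives; unmatched truths, false negatives.
    """
    if tolerance_um <= 0:
        raise ValueError("tolerance_um must be > 0")
    det = np.asarray(detected_centers, dtype=float).reshape(-1, 3)
    tru = np.asarray(truth_centers, dtype=float).reshape(-1, 3)
    if len(det) == 0 or len(tru) == 0:
        return MatchResult(0, len(det), len(tru), tolerance_um)

    pairs = []
    tree = cKDTree(tru)
    for di, neighbours in enumerate(tree.query_ball_point(det, tolerance_um)):
        for ti in neighbours:
            d = float(np.linalg.norm(det[di] - tru[ti]))
            pairs.append((d, di, ti))
    pairs.sort()

    matched_d = np.zeros(len(det), dtype=bool)
    matched_t = np.zeros(len(tru), dtype=bool)
    accepted = []
    for d, di, ti in pairs:
        if not matched_d[di] and not matched_t[ti]:
            matched_d[di] = matched_t[ti] = True
            accepted.append((di, ti, d))
    tp = len(accepted)
    return MatchResult(tp, len(det) - tp, len(tru) - tp, tolerance_um, accepted)


def precision_recall_f(match: MatchResult) -> tuple[float, float, float]:
    """(precision, recall, F) with F = 2PR/(P+R) and F = 0 when P = R = 0."""
    return match.precision, match.recall, match.f_score


def parameter_sweep(image, truth_centers_um, threshold_list, tolerance_list,
                    match_tolerance: float = DEFAULT_MATCH_TOLERANCE_UM,
                    spacing=None) -> SweepResult:
    """F-score over a (threshold x noise tolerance) grid of maxima-detection
    settings, scored on seeds against ground-truth centres."""
    thresholds = np.asarray(list(threshold_list), dtype=float)
    tolerances = np.asarray(list(tolerance_list), dtype=float)
    if len(thresholds) == 0 or len(tolerances) == 0:
        raise ValueError("parameter grids must be non-empty")
    if spacing is None:
        spacing = image.spacing
    dz, dy, dx = spacing
    tru = np.asarray(truth_centers_um, dtype=float).reshape(-1, 3)

    f = np.zeros((len(thresholds), len(tolerances)))
    for i, thr in enumerate(thresholds):
        for j, nt in enumerate(tolerances):
            seeds = find_maxima_3d(image, thr, nt)
            det = seeds[:, ::-1] * np.array([dx, dy, dz]) if len(seeds) \
                else np.empty((0, 3))
            f[i, j] = match_detections(det, tru, match_tolerance).f_score
    best = np.unravel_index(int(np.argmax(f)), f.shape)
    return SweepResult(thresholds, tolerances, f,
                       (float(thresholds[best[0]]), float(tolerances[best[1]])),
                       float(f[best]))
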