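"""Scoring of detected fetal R peaks against ground truth.

Detections are matched one-to-one to true fetal peaks by greedy
nearest-neighbour pairing within a tolerance window.  Residual maternal R
peaks act as the negative (distractor) class: a maternal beat with no
detection nearby counts as a true negative, so specificity measures how well
the detector rejects the maternal residue.  All counts are restricted to the
post-burn-in segment, matching the FHR convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DetectionMetrics", "match_peaks"]


@dataclass(frozen=True)
class DetectionMetrics:
    """TP/FP/FN/TN counts and the derived percentage metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    matched_pairs: tuple[tuple[int, int], ...]

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity_pct(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy_pct(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return 100.0 * (self.tp + self.tn) / total if total else float("nan")


def _greedy_match(detected: np.ndarray, truth: np.ndarray, tol: int) -> list[tuple[int, int]]:
    """One-to-one nearest-neighbour pairs (truth_idx, det_idx) within +-tol."""
    pairs = [
        (abs(int(t) - int(d)), ti, di)
        for ti, t in enumerate(truth)
        for di, d in enumerate(detected)
        if abs(int(t) - int(d)) <= tol
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    out = []
    for _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        out.append((int(truth[ti]), int(detected[di])))
    return out


def match_peaks(
    detected: np.ndarray,
    truth_foetal: np.ndarray,
    truth_maternal: np.ndarray,
    tolerance: int,
    burn_in: int = 0,
    n_samples: int | None = None,
) -> DetectionMetrics:
    """Score detections against fetal truth, with maternal beats as distractors.

    TP: detections matched to a fetal truth within ``tolerance`` samples;
    FN: unmatched fetal truths; FP: unmatched detections; TN: maternal
    truths with no detection within tolerance.  Indices below ``burn_in``
    are ignored; detections outside ``[0, n_samples)`` are rejected.
    """
    if tolerance <= 0:
        raise ValueError("match tolerance must be > 0 samples")
    detected = np.sort(np.asarray(detected, dtype=np.int64))
    foetal = np.sort(np.asarray(truth_foetal, dtype=np.int64))
    maternal = np.sort(np.asarray(truth_maternal, dtype=np.int64))
    if n_samples is not None:
        detected = detected[(detected >= 0) & (detected < n_samples)]
    detected = detected[detected >= burn_in]
    foetal = foetal[foetal >= burn_in]
    maternal = maternal[maternal >= burn_in]

    matched = _greedy_match(detected, foetal, int(tolerance))
    tp = len(matched)
    fn = int(foetal.size) - tp
    fp = int(detected.size) - tp
    tn = int(
        sum(
            1
            for mp in maternal
            if not np.any(np.abs(detected - mp) <= tolerance)
        )
    )
    return DetectionMetrics(tp=tp, fp=fp, fn=fn, tn=tn, matched_pairs=tuple(matched))
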