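"""Reconstruction-accuracy metrics and benchmark scoring.

Reconstruction metrics compare an observed spectrum v with its
reconstruction r = S a. Benchmark scoring compares an estimated activity
vector with a known ground truth at the level of signature presence/absence.
"""

from __future__ import annotations

import numpy as np

from .types import ActivityVector

__all__ = ["reconstruction_metrics", "confusion_counts", "prf1"]

_KL_FLOOR = 1e-12


def reconstruction_metrics(v: np.ndarray, r: np.ndarray) -> dict[str, float]:
    """Cosine similarity, KL divergence, Pearson correlation and L1/L2
    relative errors between an observed spectrum and its reconstruction.

    KL is computed between the two spectra normalized to probability
    distributions, with cells floored at 1e-12 before the logarithm so that
    empty channels do not produce infinities. Pearson is computed on the raw
    count vectors.
    """
    v = np.asarray(v, dtype=float)
    r = np.asarray(r, dtype=float)
    if v.shape != r.shape:
        raise ValueError("shape mismatch")
    if np.any(v < 0) or np.any(r < 0):
        raise ValueError("negative spectra")
    v1 = float(np.abs(v).sum())
    if v1 <= 0:
        raise ValueError("all-zero observed spectrum")
    r1 = float(np.abs(r).sum())

    nv = float(np.linalg.norm(v))
    nr = float(np.linalg.norm(r))
    cosine = float(v @ r / (nv * nr)) if nr > 0 else 0.0

    p = np.maximum(v / v1, _KL_FLOOR)
    q = np.maximum(r / r1, _KL_FLOOR) if r1 > 0 else np.full_like(p, _KL_FLOOR)
    kl = float(np.sum(p * np.log(p / q)))

    if nr > 0 and np.std(v) > 0 and np.std(r) > 0:
        pearson = float(np.corrcoef(v, r)[0, 1])
    else:
        pearson = 0.0

    diff = v - r
    return {
        "cosine": cosine,
        "kl": kl,
        "pearson": pearson,
        "l1_rel": float(np.abs(diff).sum()) / v1,
        "l2_rel": float(np.linalg.norm(diff)) / nv,
    }


def confusion_counts(
    truth: ActivityVector,
    estimate: ActivityVector,
    universe: tuple[str, ...],
) -> tuple[int, int, int]:
    """Signature-level (TP, FP, FN) between ground-truth and estimated
    activities over a shared signature universe.

    A signature is TP when the estimate attributes at least one mutation to
    it and its true activity is positive; FP when estimated but truly
    absent; FN when truly active but unassigned. Magnitudes beyond
    presence/absence do not matter.
    """
    t = truth.as_full(universe)
    e = estimate.as_full(universe)
    tp = int(np.sum((e >= 1) & (t > 0)))
    fp = int(np.sum((e >= 1) & (t == 0)))
    fn = int(np.sum((e == 0) & (t > 0)))
    return tp, fp, fn


def prf1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, sensitivity and F1 from signature-level confusion counts.

    Degenerate denominators: a sample with no assignments at all (TP+FP = 0)
    gets precision 1.0 — it made no false claims — and a sample with no
    truly active signatures (TP+FN = 0) gets sensitivity 1.0; F1 is 0 when
    precision + sensitivity is 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("negative confusion counts")
    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if (precision + sensitivity) > 0
        else 0.0
    )
    return precision, sensitivity, f1
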