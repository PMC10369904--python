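"""Sparse signature assignment by alternating backward removal and forward
addition around nonnegative least squares.

Starting from the full reference set, signatures are greedily removed one at
a time as long as the cheapest removal raises the relative error eps by at
most ``removal_threshold`` (default 0.01); then previously excluded
signatures are greedily added back as long as the best addition lowers eps
by at least ``addition_threshold`` (default 0.05). The remove/add passes
alternate until a full pass changes nothing. The final NNLS activities on
the selected set are rounded to nonnegative integers.

The asymmetric thresholds are what make the result sparse: dropping a
signature is cheap, re-admitting one is expensive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import reconstruction_metrics
from .nnls import calc_nnls
from .types import (
    ActivityVector,
    AssignmentResult,
    Catalog,
    SignatureSet,
    validate_compatibility,
)

__all__ = [
    "StepwiseConfig",
    "remove_signatures",
    "add_signatures",
    "assign_sample",
    "assign_cohort",
]

#: two candidate moves with eps within this of each other count as tied;
#: ties go to the earliest column in the reference set's order.
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class StepwiseConfig:
    """Tuning knobs of the stepwise selection.

    removal_threshold : max allowed increase in relative error per removal.
    addition_threshold : min required decrease in relative error per addition.
    max_outer_iterations : hard cap on remove/add passes (the procedure
        normally converges in a handful; the cap guards against cycling).
    """

    removal_threshold: float = 0.01
    addition_threshold: float = 0.05
    max_outer_iterations: int = 100

    def __post_init__(self) -> None:
        if self.removal_threshold < 0 or self.addition_threshold < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.max_outer_iterations < 1:
            raise ValueError("max_outer_iterations must be positive")


def _argmin_tied(eps: list[float]) -> int:
    """Index of the smallest eps; ties within _TIE_TOL go to the lowest
    index (candidate lists are always in reference-column order)."""
    best = 0
    for i in range(1, len(eps)):
        if eps[i] < eps[best] - _TIE_TOL:
            best = i
    return best


def remove_signatures(
    v: np.ndarray,
    S_all: np.ndarray,
    current: list[int],
    eps_min: float,
    cfg: StepwiseConfig,
    trajectory: list[float] | None = None,
) -> tuple[float, list[int]]:
    """Backward pass: repeatedly drop the signature whose removal raises the
    relative error least, while that increase is <= removal_threshold.

    ``current`` holds column indices into ``S_all`` (ascending). Never
    empties the set. Returns the updated (eps_min, current).
    """
    current = list(current)
    while len(current) > 1:
        # Columns with zero coefficient in the current solution can be
        # dropped without changing the minimizer, so eps_after == eps_min
        # exactly for them and the solve is skipped.
        _, a_cur = calc_nnls(v, S_all[:, current])
        eps_cand: list[float] = []
        for pos in range(len(current)):
            if a_cur[pos] == 0.0:
                eps_cand.append(eps_min)
            else:
                rest = current[:pos] + current[pos + 1 :]
                eps_j, _ = calc_nnls(v, S_all[:, rest])
                eps_cand.append(eps_j)
        best = _argmin_tied(eps_cand)
        if eps_cand[best] - eps_min <= cfg.removal_threshold:
            eps_min = eps_cand[best]
            del current[best]
            if trajectory is not None:
                trajectory.append(eps_min)
        else:
            break
    return eps_min, current


def add_signatures(
    v: np.ndarray,
    S_all: np.ndarray,
    current: list[int],
    eps_min: float,
    cfg: StepwiseConfig,
    trajectory: list[float] | None = None,
) -> tuple[float, list[int]]:
    """Forward pass: repeatedly add back the excluded signature whose
    inclusion lowers the relative error most, while that decrease is
    >= addition_threshold."""
    current = list(current)
    n = S_all.shape[1]
    while True:
        candidates = [p for p in range(n) if p not in current]
        if not candidates:
            break
        eps_cand = [calc_nnls(v, S_all[:, sorted(current + [p])])[0] for p in candidates]
        best = _argmin_tied(eps_cand)
        if eps_min - eps_cand[best] >= cfg.addition_threshold:
            eps_min = eps_cand[best]
            current = sorted(current + [candidates[best]])
            if trajectory is not None:
                trajectory.append(eps_min)
        else:
            break
    return eps_min, current


def assign_sample(
    v: np.ndarray,
    sigs: SignatureSet,
    cfg: StepwiseConfig | None = None,
    sample_id: str = "sample",
) -> AssignmentResult:
    """Assign signatures to one sample spectrum.

    Raises on an all-zero spectrum (the caller should skip such samples;
    ``assign_cohort`` does this automatically).
    """
    cfg = cfg or StepwiseConfig()
    v = np.asarray(v, dtype=float)
    if v.sum() <= 0:
        raise ValueError(
            f"sample {sample_id!r} has no mutations; skip zero-count samples"
        )
    S = sigs.probs
    trajectory: list[float] = []

    # Full-set fit fixes the error floor; its activities are discarded.
    eps_min, _ = calc_nnls(v, S)
    trajectory.append(eps_min)
    current = list(range(sigs.n_signatures))

    converged = False
    for _ in range(cfg.max_outer_iterations):
        before = list(current)
        eps_min, current = remove_signatures(v, S, current, eps_min, cfg, trajectory)
        eps_min, current = add_signatures(v, S, current, eps_min, cfg, trajectory)
        if current == before:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"sample {sample_id!r}: stepwise selection did not converge within "
            f"{cfg.max_outer_iterations} passes; returning current state",
            stacklevel=2,
        )

    _, a_real = calc_nnls(v, S[:, current])
    a_int = np.floor(a_real + 0.5).astype(np.int64)  # half away from zero; a_real >= 0
    keep = a_int > 0
    sel_idx = [c for c, k in zip(current, keep) if k]
    ids = tuple(sigs.signature_ids[c] for c in sel_idx)
    activities = ActivityVector(ids, a_int[keep])
    reconstruction = S[:, sel_idx] @ a_int[keep] if sel_idx else np.zeros_like(v)
    resid = v - reconstruction
    rel_err = float(resid @ resid) / float(v @ v)
    return AssignmentResult(
        sample_id=sample_id,
        activities=activities,
        observed=v,
        reconstruction=reconstruction,
        relative_error=rel_err,
        metrics=reconstruction_metrics(v, reconstruction),
        converged=converged,
        trajectory=tuple(trajectory),
    )


def assign_cohort(
    catalog: Catalog,
    sigs: SignatureSet,
    cfg: StepwiseConfig | None = None,
) -> list[AssignmentResult]:
    """Assign signatures to every sample of a catalog independently.

    Zero-count samples yield an all-zero result flagged ``skipped``.
    """
    validate_compatibility(catalog, sigs)
    results = []
    for j, sid in enumerate(catalog.sample_ids):
        v = catalog.counts[:, j]
        if v.sum() <= 0:
            results.append(
                AssignmentResult(
                    sample_id=sid,
                    activities=ActivityVector((), np.zeros(0, dtype=np.int64)),
                    observed=v,
                    reconstruction=np.zeros_like(v),
                    relative_error=0.0,
                    metrics={},
                    skipped=True,
                )
            )
        else:
            results.append(assign_sample(v, sigs, cfg, sample_id=sid))
    return results
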