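"""Independent oracles used by the tests.

These deliberately do not share code paths with the package:

* ``brute_nnls`` solves nonnegative least squares by exhaustive enumeration
  of active sets (unconstrained least squares on every support, keeping the
  feasible minimum) — the global constrained minimizer's support is among
  them, so this is exact for small column counts.
* ``literal_stepwise`` is a line-by-line transcription of the alternating
  removal/addition pseudocode, scanning every candidate with a fresh solve
  and no shortcuts, recording eps_min after the initial full-set fit and
  after every accepted move.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import nnls as _scipy_nnls


def brute_nnls(v: np.ndarray, S: np.ndarray) -> tuple[float, np.ndarray]:
    """Exact NNLS by enumeration over all supports (2^q subsets)."""
    v = np.asarray(v, float)
    S = np.asarray(S, float)
    q = S.shape[1]
    best_a = np.zeros(q)
    best_r2 = float(v @ v)
    for r in range(1, q + 1):
        for support in itertools.combinations(range(q), r):
            sub = S[:, support]
            coef, *_ = np.linalg.lstsq(sub, v, rcond=None)
            if np.any(coef < -1e-12):
                continue
            coef = np.maximum(coef, 0.0)
            resid = v - sub @ coef
            r2 = float(resid @ resid)
            if r2 < best_r2 - 1e-15:
                best_r2 = r2
                best_a = np.zeros(q)
                best_a[list(support)] = coef
    return best_r2 / float(v @ v), best_a


def _eps(v: np.ndarray, S: np.ndarray) -> float:
    _, rnorm = _scipy_nnls(S, v)
    return rnorm * rnorm / float(v @ v)


def literal_stepwise(
    v: np.ndarray,
    S_all: np.ndarray,
    removal_threshold: float = 0.01,
    addition_threshold: float = 0.05,
    max_outer: int = 100,
):
    """Literal transcription of the alternating stepwise selection.

    Returns (selected column indices, trajectory of eps_min values: after
    the initial full-set fit and after every accepted removal/addition).
    """
    v = np.asarray(v, float)
    S_all = np.asarray(S_all, float)
    n = S_all.shape[1]
    eps_min = _eps(v, S_all)
    trajectory = [eps_min]
    current = list(range(n))

    for _ in range(max_outer):
        before = list(current)

        # backward removal
        while len(current) > 1:
            eps_cand = []
            for pos in range(len(current)):
                rest = current[:pos] + current[pos + 1 :]
                eps_cand.append(_eps(v, S_all[:, rest]))
            best = 0
            for i in range(1, len(eps_cand)):
                if eps_cand[i] < eps_cand[best] - 1e-12:
                    best = i
            if eps_cand[best] - eps_min <= removal_threshold:
                eps_min = eps_cand[best]
                del current[best]
                trajectory.append(eps_min)
            else:
                break

        # forward addition
        while True:
            candidates = [p for p in range(n) if p not in current]
            if not candidates:
                break
            eps_cand = [
                _eps(v, S_all[:, sorted(current + [p])]) for p in candidates
            ]
            best = 0
            for i in range(1, len(eps_cand)):
                if eps_cand[i] < eps_cand[best] - 1e-12:
                    best = i
            if eps_min - eps_cand[best] >= addition_threshold:
                eps_min = eps_cand[best]
                current = sorted(current + [candidates[best]])
                trajectory.append(eps_min)
            else:
                break

        if current == before:
            break
    return current, trajectory


def random_instance(rng: np.random.Generator, xi: int = 96, n: int = 6):
    """A random refitting instance: sparse random signatures, a spectrum
    generated from a random subset of them plus Poisson-ish jitter."""
    raw = rng.dirichlet(np.full(xi, 0.1), size=n).T  # xi x n, columns sum to 1
    k = int(rng.integers(1, min(4, n) + 1))
    active = rng.choice(n, size=k, replace=False)
    acts = rng.integers(50, 2000, size=k)
    v = np.zeros(xi)
    for t, a in zip(active, acts):
        v += rng.multinomial(a, raw[:, t])
    v = v + rng.integers(0, 3, size=xi)  # mild background so v is never exact
    return v.astype(float), raw
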