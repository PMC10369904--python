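"""Core domain types for mutational-signature assignment.

The model is the superposition v ~ S a: a sample's mutation spectrum v
(counts over a fixed alphabet of mutation channels) is approximated as a
nonnegative combination of known signatures S (columns are probability mass
functions over the channels) with activities a (mutations attributed to each
signature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelAlphabet",
    "Catalog",
    "SignatureSet",
    "ActivityVector",
    "AssignmentResult",
    "MutationRecord",
    "validate_compatibility",
]


@dataclass(frozen=True)
class ChannelAlphabet:
    """An ordered, fixed alphabet of mutation-type channels.

    Channel order is part of the alphabet's identity: two alphabets with the
    same labels in different order are incompatible.
    """

    labels: tuple[str, ...]
    schema_name: str = "custom"

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("alphabet needs at least 2 channels")
        if any(not lab for lab in labels):
            raise ValueError("empty channel label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate channel labels: {dupes}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def _as_2d(values, n_rows: int, n_cols: int, what: str) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape != (n_rows, n_cols):
        raise ValueError(f"{what} has shape {arr.shape}, expected {(n_rows, n_cols)}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite values")
    return arr


@dataclass(frozen=True)
class Catalog:
    """Mutation-count spectra for one or more samples.

    ``counts`` is channels x samples. Counts are stored as floats so that
    noise-perturbed benchmark catalogs fit the same container; loaders for
    observed data reject negatives and non-finite cells.
    """

    alphabet: ChannelAlphabet
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        arr = _as_2d(self.counts, len(self.alphabet), len(self.sample_ids), "counts")
        if np.any(arr < 0):
            raise ValueError("negative counts")
        arr.flags.writeable = False
        object.__setattr__(self, "counts", arr)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def totals(self) -> np.ndarray:
        """Total mutation count per sample."""
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class SignatureSet:
    """A channels x signatures matrix whose columns are probability mass
    functions over the channel alphabet."""

    alphabet: ChannelAlphabet
    signature_ids: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "signature_ids", tuple(self.signature_ids))
        if len(set(self.signature_ids)) != len(self.signature_ids):
            raise ValueError("duplicate signature ids")
        arr = _as_2d(self.probs, len(self.alphabet), len(self.signature_ids), "probs")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("signature probabilities must lie in [0, 1]")
        sums = arr.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
        if bad.size:
            raise ValueError(
                f"signature column(s) {[self.signature_ids[i] for i in bad]} "
                f"do not sum to 1 (use from_raw to renormalize)"
            )
        arr.flags.writeable = False
        object.__setattr__(self, "probs", arr)

    @classmethod
    def from_raw(
        cls,
        alphabet: ChannelAlphabet,
        signature_ids,
        values,
        warn: bool = True,
    ) -> "SignatureSet":
        """Build a SignatureSet from raw columns, renormalizing each column
        to sum exactly 1. A zero (or negative-sum) column is an error.

        Reference signature files typically carry rounding error; the model
        requires true probability mass functions, so columns are divided by
        their sums, with a warning when the discrepancy exceeds 1e-6.
        """
        arr = _as_2d(values, len(alphabet), len(tuple(signature_ids)), "probs")
        if np.any(arr < 0):
            raise ValueError("negative signature probabilities")
        sums = arr.sum(axis=0)
        if np.any(sums <= 0):
            bad = [tuple(signature_ids)[i] for i in np.flatnonzero(sums <= 0)]
            raise ValueError(f"zero signature column(s): {bad}")
        off = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
        if off.size and warn:
            warnings.warn(
                f"renormalized {off.size} signature column(s) whose sums "
                f"deviated from 1 by more than 1e-6",
                stacklevel=2,
            )
        return cls(alphabet, tuple(signature_ids), arr / sums)

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)

    def column(self, signature_id: str) -> np.ndarray:
        return self.probs[:, self.signature_ids.index(signature_id)]

    def subset(self, ids) -> "SignatureSet":
        idx = [self.signature_ids.index(i) for i in ids]
        return SignatureSet(self.alphabet, tuple(ids), self.probs[:, idx])


@dataclass(frozen=True)
class ActivityVector:
    """Nonnegative integer mutation counts attributed to signatures in one
    sample. Only signatures present in ``signature_ids`` carry activity;
    anything absent is implicitly zero."""

    signature_ids: tuple[str, ...]
    activities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "signature_ids", tuple(self.signature_ids))
        arr = np.asarray(self.activities)
        if arr.shape != (len(self.signature_ids),):
            raise ValueError("activities must align with signature_ids")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("activities must be integers")
            arr = np.round(arr).astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("negative activities")
        arr.flags.writeable = False
        object.__setattr__(self, "activities", arr)

    def total(self) -> int:
        return int(self.activities.sum())

    def as_dict(self) -> dict[str, int]:
        return {s: int(a) for s, a in zip(self.signature_ids, self.activities)}

    def as_full(self, universe: tuple[str, ...]) -> np.ndarray:
        """Dense activity vector over a full signature universe."""
        out = np.zeros(len(universe), dtype=np.int64)
        lookup = dict(zip(self.signature_ids, self.activities))
        for i, s in enumerate(universe):
            if s in lookup:
                out[i] = lookup[s]
        missing = set(self.signature_ids) - set(universe)
        if missing:
            raise KeyError(f"activities for signatures outside universe: {sorted(missing)}")
        return out


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of fitting one sample: selected signatures with integer
    activities, the reconstructed spectrum S a, the relative reconstruction
    error eps = ||v - S a||^2 / ||v||^2, and accuracy metrics."""

    sample_id: str
    activities: ActivityVector
    observed: np.ndarray
    reconstruction: np.ndarray
    relative_error: float
    metrics: dict[str, float] = field(default_factory=dict)
    skipped: bool = False
    converged: bool = True
    # eps_min after the initial full-set fit and after every accepted
    # removal/addition, in order; kept for auditability of the greedy path.
    trajectory: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        rec = np.asarray(self.reconstruction, dtype=float)
        if obs.shape != rec.shape:
            raise ValueError("observed/reconstruction shape mismatch")
        if np.any(rec < -1e-12):
            raise ValueError("negative reconstruction")
        for a in (obs, rec):
            a.flags.writeable = False
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "reconstruction", rec)
        if not self.skipped:
            denom = float(obs @ obs)
            if denom <= 0:
                raise ValueError("zero observed spectrum in a non-skipped result")
            resid = obs - rec
            eps = float(resid @ resid) / denom
            if abs(eps - self.relative_error) > 1e-9:
                raise ValueError(
                    f"stored relative_error {self.relative_error} does not match "
                    f"recomputed value {eps}"
                )


@dataclass
class MutationRecord:
    """A single somatic single-base substitution with its mutation channel
    and (after annotation) per-signature posterior probabilities."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    channel: str | None = None
    probabilities: dict[str, float] = field(default_factory=dict)
    flagged: bool = False


def validate_compatibility(catalog: Catalog, sigs: SignatureSet) -> None:
    """Raise unless catalog and signatures share an identical channel
    alphabet (same labels in the same order)."""
    a, b = catalog.alphabet.labels, sigs.alphabet.labels
    n = max(len(a), len(b))
    for k in range(n):
        la = a[k] if k < len(a) else "<missing>"
        lb = b[k] if k < len(b) else "<missing>"
        if la != lb:
            raise ValueError(
                f"channel alphabet mismatch at position {k}: "
                f"catalog has {la!r}, signatures have {lb!r}"
            )
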