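"""Posterior assignment of signatures to individual mutations.

Given fitted activities a over selected signatures S, the probability that
a mutation of channel k was caused by signature t is

    p_kt = s_kt * a_t / (S a)_k

i.e. the share of the reconstructed count of channel k contributed by
signature t. Channels with zero reconstructed count carry no information
and get an all-zero row.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .types import AssignmentResult, MutationRecord, SignatureSet

__all__ = ["ChannelProbabilities", "channel_probabilities", "annotate_mutations"]


class ChannelProbabilities(NamedTuple):
    """Per-channel posterior over signatures plus the mask of channels whose
    reconstruction is zero (rows left all-zero)."""

    probs: np.ndarray  # channels x signatures
    zero_channels: np.ndarray  # bool mask, True where (S a)_k == 0


def channel_probabilities(S_sel: np.ndarray, a: np.ndarray) -> ChannelProbabilities:
    """Posterior probability matrix p_kt = s_kt a_t / (S a)_k.

    Rows with positive reconstruction sum to 1; rows with zero reconstructed
    count are all zeros and flagged in ``zero_channels``.
    """
    S_sel = np.asarray(S_sel, dtype=float)
    a = np.asarray(a, dtype=float)
    if S_sel.ndim == 1:
        S_sel = S_sel[:, None]
    if S_sel.ndim != 2 or a.shape != (S_sel.shape[1],):
        raise ValueError(f"dimension mismatch: S {S_sel.shape}, a {a.shape}")
    if np.any(a < 0):
        raise ValueError("negative activities")
    recon = S_sel @ a
    contrib = S_sel * a  # s_kt * a_t
    zero = recon == 0
    probs = np.zeros_like(contrib)
    nz = ~zero
    probs[nz] = contrib[nz] / recon[nz, None]
    return ChannelProbabilities(probs, zero)


def annotate_mutations(
    records: list[MutationRecord],
    result: AssignmentResult,
    sigs: SignatureSet,
) -> list[MutationRecord]:
    """Attach per-signature probabilities to each mutation record of a
    sample, from the channel-probability row for the record's channel.

    Only signatures with positive fitted activity appear in the maps. A
    record whose channel has zero reconstructed count gets an empty map and
    is flagged. Records are modified in place and returned.
    """
    sel_ids = result.activities.signature_ids
    if sel_ids:
        S_sel = np.column_stack([sigs.column(s) for s in sel_ids])
        table = channel_probabilities(S_sel, result.activities.activities)
    else:
        xi = len(sigs.alphabet)
        table = ChannelProbabilities(np.zeros((xi, 0)), np.ones(xi, dtype=bool))
    labels = sigs.alphabet.labels
    index = {lab: k for k, lab in enumerate(labels)}
    for rec in records:
        if rec.channel not in index:
            raise ValueError(f"channel {rec.channel!r} not in alphabet")
        k = index[rec.channel]
        if table.zero_channels[k]:
            rec.probabilities = {}
            rec.flagged = True
        else:
            rec.probabilities = {
                s: float(table.probs[k, t]) for t, s in enumerate(sel_ids)
            }
            rec.flagged = False
    return records
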