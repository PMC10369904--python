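"""Tabular outputs: activity tables, reconstruction-error tables and
probability tables, written as tab-delimited text with a provenance header."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .probabilities import channel_probabilities
from .types import AssignmentResult, MutationRecord, SignatureSet

__all__ = [
    "activity_table",
    "error_table",
    "decomposed_probability_table",
    "mutation_probability_table",
    "write_table",
]

_METRIC_COLS = ["cosine", "kl", "pearson", "l1_rel", "l2_rel"]


def activity_table(
    results: list[AssignmentResult], sigs: SignatureSet
) -> pd.DataFrame:
    """Samples x signatures integer activity table over the full reference
    (zeros for unselected signatures)."""
    universe = sigs.signature_ids
    rows = [r.activities.as_full(universe) for r in results]
    df = pd.DataFrame(
        np.asarray(rows, dtype=np.int64) if rows else np.zeros((0, len(universe)), int),
        columns=list(universe),
    )
    df.insert(0, "Samples", [r.sample_id for r in results])
    return df


def error_table(results: list[AssignmentResult]) -> pd.DataFrame:
    """Per-sample relative error and reconstruction metrics."""
    rows = []
    for r in results:
        row = {"Samples": r.sample_id, "relative_error": r.relative_error}
        for m in _METRIC_COLS:
            row[m] = r.metrics.get(m, float("nan"))
        row["skipped"] = r.skipped
        rows.append(row)
    return pd.DataFrame(rows, columns=["Samples", "relative_error", *_METRIC_COLS, "skipped"])


def decomposed_probability_table(
    results: list[AssignmentResult], sigs: SignatureSet
) -> pd.DataFrame:
    """Per-sample, per-channel posterior probabilities over the selected
    signatures (long format: one row per sample x channel)."""
    frames = []
    for r in results:
        sel = r.activities.signature_ids
        if not sel:
            continue
        S_sel = np.column_stack([sigs.column(s) for s in sel])
        probs = channel_probabilities(S_sel, r.activities.activities).probs
        df = pd.DataFrame(probs, columns=list(sel))
        df.insert(0, "MutationType", list(sigs.alphabet.labels))
        df.insert(0, "Samples", r.sample_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["Samples", "MutationType"])
    return pd.concat(frames, ignore_index=True).fillna(0.0)


def mutation_probability_table(records: list[MutationRecord]) -> pd.DataFrame:
    """One row per annotated mutation with per-signature probabilities."""
    sig_cols: list[str] = []
    for rec in records:
        for s in rec.probabilities:
            if s not in sig_cols:
                sig_cols.append(s)
    rows = []
    for rec in records:
        row = {
            "Samples": rec.sample_id,
            "Chrom": rec.chrom,
            "Pos": rec.pos,
            "Ref": rec.ref,
            "Alt": rec.alt,
            "MutationType": rec.channel,
        }
        for s in sig_cols:
            row[s] = rec.probabilities.get(s, 0.0)
        rows.append(row)
    cols = ["Samples", "Chrom", "Pos", "Ref", "Alt", "MutationType", *sig_cols]
    return pd.DataFrame(rows, columns=cols)


def write_table(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a TSV with '# key=value' header comment lines recording the
    package version and run parameters."""
    with open(path, "w") as fh:
        fh.write(f"# sigassign={__version__}\n")
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
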