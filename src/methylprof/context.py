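"""Cytosine context classification: CG / CHG / CHH and trinucleotide subcontexts.

The context of a cytosine is read from the next one or two bases 5'->3' on the
cytosine's own strand (H = A, C, or T): C followed by G is CG; C,H,G is CHG;
C,H,H is CHH. A site whose required downstream bases run off the sequence end
or contain N is UNCLASSIFIED and excluded from all downstream profiles.

On the minus strand a cytosine sits under a reference G; its reference
coordinate is the position of that G on the plus axis, matching the coordinate
convention of both per-read caller dialects.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .io import GenomeSequence

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
UNCLASSIFIED = "UNCLASSIFIED"

CHG_SUBCONTEXTS = ("CAG", "CCG", "CTG")
CHH_SUBCONTEXTS = ("CAA", "CAC", "CAT", "CCA", "CCC", "CCT", "CTA", "CTC", "CTT")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_H = set("ACT")


def _classify_from_downstream(b1: str | None, b2: str | None) -> tuple[str, str]:
    """Classify from the two bases 3' of the C on its own strand.

    ``None`` means the base falls off the sequence end.
    """
    if b1 is None:
        return UNCLASSIFIED, "C"
    if b1 == "G":
        return "CG", "CG"
    if b1 not in _H:  # N or other
        return UNCLASSIFIED, "C" + b1
    if b2 is None:
        return UNCLASSIFIED, "C" + b1
    if b2 == "G":
        return "CHG", "C" + b1 + "G"
    if b2 in _H:
        return "CHH", "C" + b1 + b2
    return UNCLASSIFIED, "C" + b1 + b2


def classify_cytosine(residues: str, position: int, strand: str) -> tuple[str, str]:
    """Classify one cytosine at ``position`` on ``strand``.

    ``position`` is always on the plus reference axis; a minus-strand cytosine
    is located where the reference shows G. Raises ``ValueError`` if the base
    at (position, strand) is not a cytosine.
    """
    n = len(residues)
    if not 0 <= position < n:
        raise ValueError(f"position {position} outside sequence of length {n}")
    if strand == "+":
        if residues[position] != "C":
            raise ValueError(
                f"base at +{position} is {residues[position]!r}, not C"
            )
        b1 = residues[position + 1] if position + 1 < n else None
        b2 = residues[position + 2] if position + 2 < n else None
    elif strand == "-":
        if residues[position] != "G":
            raise ValueError(
                f"reference base at {position} is {residues[position]!r}, not G "
                "(required for a minus-strand C)"
            )
        b1 = _COMPLEMENT[residues[position - 1]] if position - 1 >= 0 else None
        b2 = _COMPLEMENT[residues[position - 2]] if position - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    return _classify_from_downstream(b1, b2)


# Byte codes used by the vectorized classifier.
_A, _C, _G, _T, _N = (ord(c) for c in "ACGTN")
_PAD = 0  # sentinel for off-sequence positions
_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _x, _y in ((_A, _T), (_C, _G), (_G, _C), (_T, _A), (_N, _N)):
    _COMP_TABLE[_x] = _y


def _classify_arrays(b1: np.ndarray, b2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized form of :func:`_classify_from_downstream` on byte codes.

    Returns (context codes, subcontext bytes (n, 3) with pad-trimmed tails),
    context codes: 0=CG, 1=CHG, 2=CHH, 3=UNCLASSIFIED.
    """
    is_h1 = (b1 == _A) | (b1 == _C) | (b1 == _T)
    is_h2 = (b2 == _A) | (b2 == _C) | (b2 == _T)
    ctx = np.full(b1.shape, 3, dtype=np.int8)
    ctx[b1 == _G] = 0
    ctx[is_h1 & (b2 == _G)] = 1
    ctx[is_h1 & is_h2] = 2
    sub = np.zeros((len(b1), 3), dtype=np.uint8)
    sub[:, 0] = _C
    # CG subcontext is the dinucleotide regardless of b2
    cg = ctx == 0
    sub[cg, 1] = _G
    rest = ~cg
    sub[rest, 1] = np.where(b1[rest] == _PAD, _PAD, b1[rest])
    keep2 = rest & (b1 != _PAD)
    sub[keep2, 2] = np.where(b2[keep2] == _PAD, _PAD, b2[keep2])
    return ctx, sub


def _index_one_sequence(sequence_id: str, residues: str) -> pd.DataFrame:
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    n = len(arr)

    frames = []
    # plus strand: every reference C
    pos_f = np.flatnonzero(arr == _C)
    b1 = np.full(len(pos_f), _PAD, dtype=np.uint8)
    b2 = np.full(len(pos_f), _PAD, dtype=np.uint8)
    ok1 = pos_f + 1 < n
    b1[ok1] = arr[pos_f[ok1] + 1]
    ok2 = pos_f + 2 < n
    b2[ok2] = arr[pos_f[ok2] + 2]
    ctx_f, sub_f = _classify_arrays(b1, b2)
    frames.append((pos_f, "+", ctx_f, sub_f))

    # minus strand: every reference G, downstream = complemented upstream bases
    pos_r = np.flatnonzero(arr == _G)
    b1 = np.full(len(pos_r), _PAD, dtype=np.uint8)
    b2 = np.full(len(pos_r), _PAD, dtype=np.uint8)
    ok1 = pos_r - 1 >= 0
    b1[ok1] = _COMP_TABLE[arr[pos_r[ok1] - 1]]
    ok2 = pos_r - 2 >= 0
    b2[ok2] = _COMP_TABLE[arr[pos_r[ok2] - 2]]
    ctx_r, sub_r = _classify_arrays(b1, b2)
    frames.append((pos_r, "-", ctx_r, sub_r))

    ctx_labels = np.array(list(CONTEXTS) + [UNCLASSIFIED])
    parts = []
    for pos, strand, ctx, sub in frames:
        subs = (
            pd.Series(sub.view(dtype="S3").ravel())
            .str.decode("ascii")
            .str.rstrip("\x00")
        )
        parts.append(
            pd.DataFrame(
                {
                    "sequence_id": sequence_id,
                    "pos": pos.astype(np.int64),
                    "strand": strand,
                    "context": ctx_labels[ctx],
                    "subcontext": subs.values,
                }
            )
        )
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="stable", ignore_index=True)


def build_context_index(
    genome: Mapping[str, GenomeSequence] | Mapping[str, str]
) -> pd.DataFrame:
    """Build the per-cytosine context index for both strands of a genome.

    Returns one row per cytosine per strand with columns
    (sequence_id, pos, strand, context, subcontext). Context counts are
    reported to the log.
    """
    parts = []
    for sid, seq in genome.items():
        residues = seq.residues if isinstance(seq, GenomeSequence) else seq
        parts.append(_index_one_sequence(sid, residues))
    if parts:
        index = pd.concat(parts, ignore_index=True)
    else:
        index = pd.DataFrame(
            columns=["sequence_id", "pos", "strand", "context", "subcontext"]
        )
    for col, cats in (
        ("sequence_id", sorted(genome.keys())),
        ("strand", ["+", "-"]),
        ("context", list(CONTEXTS) + [UNCLASSIFIED]),
        ("subcontext", None),
    ):
        index[col] = pd.Categorical(index[col], categories=cats) if cats else index[
            col
        ].astype("category")
    counts = index["context"].value_counts()
    logger.info(
        "context index: %d sites (%s)",
        len(index),
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return index


def subcontext_table(index: pd.DataFrame) -> pd.DataFrame:
    """Count classified sites per (sequence_id, context, subcontext).

    UNCLASSIFIED sites are excluded; per-sequence subcontext counts sum to the
    per-sequence context totals by construction.
    """
    classified = index[index["context"].isin(CONTEXTS)]
    if len(classified) == 0:
        return pd.DataFrame(
            columns=["sequence_id", "context", "subcontext", "n_sites"]
        )
    tbl = (
        classified.groupby(
            ["sequence_id", "context", "subcontext"], observed=True
        )
        .size()
        .rename("n_sites")
        .reset_index()
    )
    return tbl.sort_values(
        ["sequence_id", "context", "subcontext"], ignore_index=True
    )
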