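"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's vectorized code paths: context
classification works by reverse-complementing the whole sequence and applying
the forward definition; interval aggregations loop per base or per interval.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def forward_context(seq: str, i: int) -> str:
    """Context of the C at position i of ``seq`` read left to right."""
    b1 = seq[i + 1] if i + 1 < len(seq) else None
    b2 = seq[i + 2] if i + 2 < len(seq) else None
    if b1 is None:
        return "UNCLASSIFIED"
    if b1 == "G":
        return "CG"
    if b1 in "ACT":
        if b2 is None:
            return "UNCLASSIFIED"
        if b2 == "G":
            return "CHG"
        if b2 in "ACT":
            return "CHH"
    return "UNCLASSIFIED"


def forward_subcontext(seq: str, i: int) -> str:
    ctx = forward_context(seq, i)
    if ctx == "CG":
        return "CG"
    if ctx in ("CHG", "CHH"):
        return seq[i : i + 3]
    return seq[i : min(i + 3, len(seq))].rstrip()


def classify_both_strands(seq: str) -> list[tuple[int, str, str, str]]:
    """(pos, strand, context, subcontext) for every cytosine on both strands,
    classifying the minus strand on the reverse complement with forward logic."""
    rc = revcomp(seq)
    n = len(seq)
    sites = []
    for i, b in enumerate(seq):
        if b == "C":
            sites.append((i, "+", forward_context(seq, i), forward_subcontext(seq, i)))
    for j, b in enumerate(rc):
        if b == "C":
            sites.append(
                (n - 1 - j, "-", forward_context(rc, j), forward_subcontext(rc, j))
            )
    return sorted(sites)


def window_means_bruteforce(positions, values, windows) -> list[float]:
    """Per-window mean by explicit membership test (site in [start, end))."""
    out = []
    for _, w in windows.iterrows():
        hit = [v for p, v in zip(positions, values) if w.start <= p < w.end]
        out.append(float(np.mean(hit)) if hit else float("nan"))
    return out


def masked_bp_bruteforce(intervals, length: int) -> int:
    """Per-base boolean-mask coverage of a set of (start, end) intervals."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(s, 0) : min(e, length)] = True
    return int(mask.sum())
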