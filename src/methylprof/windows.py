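"""Windowed genome-wide summaries.

Fixed windows (1 Mb) and sliding windows (100 Kb with 50 Kb steps) tile each
chromosome starting at 0, with the trailing window truncated at the
chromosome end so every base is covered. Per-window unweighted means of site
frequencies, gene counts, and their Pearson correlation reproduce the
standard windowed views of a methylome.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, GenomeSequence

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = ["sequence_id", "start", "end"]


def _sequence_lengths(genome) -> dict[str, int]:
    out = {}
    for sid, seq in genome.items():
        out[sid] = seq.length if isinstance(seq, GenomeSequence) else len(seq)
    return out


def make_windows(
    genome: Mapping[str, GenomeSequence] | Mapping[str, str] | Mapping[str, int],
    size: int,
    step: int | None = None,
) -> pd.DataFrame:
    """Tile every sequence with windows of ``size`` bp every ``step`` bp.

    ``genome`` maps sequence IDs to sequences or lengths. Windows start at 0;
    the final window is truncated at the chromosome end. ``size`` must be
    >= ``step`` so that every base is covered.
    """
    step = size if step is None else step
    if step <= 0 or size < step:
        raise ValueError(f"require size >= step > 0, got size={size}, step={step}")
    lengths = (
        dict(genome)
        if all(isinstance(v, int) for v in genome.values())
        else _sequence_lengths(genome)
    )
    rows = []
    for sid, length in lengths.items():
        n = max(1, math.ceil(length / step))  # every start < length
        for k in range(n):
            start = k * step
            rows.append((sid, start, min(start + size, length)))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def _window_hits(pos: np.ndarray, size: int, step: int, n_windows: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of every window covering each position (overlap-aware).

    Returns (row_selector, window_index) arrays: position ``pos[row]`` falls
    in window ``window_index``.
    """
    max_span = math.ceil(size / step)
    rows, widx = [], []
    base = pos // step
    for j in range(max_span):
        k = base - j
        ok = (k >= 0) & (k < n_windows) & (k * step + size > pos)
        rows.append(np.flatnonzero(ok))
        widx.append(k[ok])
    return np.concatenate(rows), np.concatenate(widx)


def window_mean_frequency(
    frequencies: pd.DataFrame,
    windows: pd.DataFrame,
    group_by: str = "context",
    labels: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Unweighted mean site frequency per window per (sub)context group.

    A site contributes to every window overlapping it. Output has one row per
    (window, group) over the full grid; windows with no sites for a group get
    a missing mean and ``n_sites`` 0. ``labels`` fixes the group universe
    (defaults to the labels observed in ``frequencies``).
    """
    if group_by not in ("context", "subcontext"):
        raise ValueError("group_by must be 'context' or 'subcontext'")
    if labels is None:
        labels = sorted(frequencies[group_by].astype(str).unique())
    labels = list(labels)

    grids = []
    for sid, wchrom in windows.groupby("sequence_id", observed=True, sort=False):
        wchrom = wchrom.sort_values("start", kind="stable").reset_index(drop=True)
        starts = wchrom["start"].to_numpy()
        size = int((wchrom["end"] - wchrom["start"]).max())
        step = int(starts[1] - starts[0]) if len(starts) > 1 else size
        n_win = len(wchrom)
        n_lab = len(labels)
        sums = np.zeros((n_win, n_lab))
        counts = np.zeros((n_win, n_lab), dtype=np.int64)
        fchrom = frequencies[frequencies["sequence_id"].astype(str) == str(sid)]
        if len(fchrom):
            lab_codes = pd.Categorical(
                fchrom[group_by].astype(str), categories=labels
            ).codes
            keep = lab_codes >= 0
            pos = fchrom["pos"].to_numpy()[keep]
            freq = fchrom["frequency"].to_numpy(float)[keep]
            lab = lab_codes[keep]
            rows, widx = _window_hits(pos, size, step, n_win)
            flat = widx * n_lab + lab[rows]
            sums += np.bincount(flat, weights=freq[rows], minlength=n_win * n_lab).reshape(
                n_win, n_lab
            )
            counts += np.bincount(flat, minlength=n_win * n_lab).reshape(n_win, n_lab)
        grid = wchrom.loc[wchrom.index.repeat(n_lab)].reset_index(drop=True)
        grid[group_by] = labels * n_win
        grid["n_sites"] = counts.ravel()
        with np.errstate(invalid="ignore"):
            grid["mean_frequency"] = np.where(
                counts.ravel() > 0, sums.ravel() / np.maximum(counts.ravel(), 1), np.nan
            )
        grids.append(grid)
    return pd.concat(grids, ignore_index=True) if grids else pd.DataFrame(
        columns=WINDOW_COLUMNS + [group_by, "n_sites", "mean_frequency"]
    )


def count_genes_per_window(
    genes: Iterable[GeneModel], windows: pd.DataFrame
) -> pd.DataFrame:
    """Count genes per window; a gene counts in every window its span overlaps
    by at least 1 bp."""
    out = windows.copy()
    out["gene_count"] = 0
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.sequence_id, []).append(g)
    counts = np.zeros(len(out), dtype=np.int64)
    starts = out["start"].to_numpy()
    ends = out["end"].to_numpy()
    chroms = out["sequence_id"].astype(str).to_numpy()
    for sid, chrom_genes in by_chrom.items():
        sel = np.flatnonzero(chroms == sid)
        if len(sel) == 0:
            continue
        ws, we = starts[sel], ends[sel]
        for g in chrom_genes:
            counts[sel] += (g.start < we) & (g.end > ws)
    out["gene_count"] = counts
    return out


def gene_methylation_correlation(window_stats: pd.DataFrame) -> dict[str, dict]:
    """Pearson R between per-window gene counts and mean methylation, per context.

    ``window_stats`` must carry ``gene_count``, ``mean_frequency`` and a
    ``context`` column. Windows with missing means are excluded; a context
    with fewer than 3 usable windows or zero variance in either variable
    yields a missing value (never 0) with a warning.
    """
    results: dict[str, dict] = {}
    for ctx, part in window_stats.groupby("context", observed=True):
        part = part.dropna(subset=["mean_frequency"])
        n = len(part)
        x = part["gene_count"].to_numpy(float)
        y = part["mean_frequency"].to_numpy(float)
        if n < 3 or np.std(x) == 0 or np.std(y) == 0:
            logger.warning(
                "context %s: correlation undefined (n=%d, var_x=%g, var_y=%g)",
                ctx,
                n,
                np.var(x) if n else 0.0,
                np.var(y) if n else 0.0,
            )
            results[str(ctx)] = {"r": None, "n": n}
            continue
        r, _ = stats.pearsonr(x, y)
        results[str(ctx)] = {"r": float(r), "n": n}
    return results


def chh_subcontext_tracks(
    frequencies: pd.DataFrame, windows: pd.DataFrame
) -> pd.DataFrame:
    """Per-window mean CHH methylation for each of the 9 CHH subcontexts.

    All 9 tracks are emitted even when empty, each with one row per window.
    """
    from .context import CHH_SUBCONTEXTS

    chh = frequencies[frequencies["context"] == "CHH"]
    return window_mean_frequency(
        chh, windows, group_by="subcontext", labels=CHH_SUBCONTEXTS
    )
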