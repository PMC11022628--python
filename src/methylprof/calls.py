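"""Standardization of per-read caller output into per-site frequencies.

Two caller dialects are supported:

* an HMM-style log-likelihood-ratio TSV (CG context), where one record may
  cover a group of adjacent CG motifs (``num_motifs`` > 1) that all share the
  record's call, and
* a per-read probability TSV (all contexts) with explicit methylated /
  unmethylated probabilities per read and site.

Both are reduced to binary per-read calls (ambiguous calls are kept but
excluded from counting) and aggregated into per-site, per-strand methylation
frequencies annotated with sequence context.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FormatError

logger = logging.getLogger(__name__)

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
AMBIGUOUS = "ambiguous"

CALL_COLUMNS = ["sequence_id", "pos", "strand", "read_id", "source", "raw_score", "call"]

LLR_FILE_COLUMNS = [
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "log_lik_methylated",
    "log_lik_unmethylated",
    "num_calling_strands",
    "num_motifs",
    "sequence",
]

PROB_FILE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "pos_in_strand",
    "read_name",
    "read_strand",
    "prob_unmethylated",
    "prob_methylated",
    "called_label",
    "kmer",
]


def _threshold_llr(llr: np.ndarray, threshold: float) -> np.ndarray:
    call = np.full(len(llr), AMBIGUOUS, dtype=object)
    call[llr >= threshold] = METHYLATED
    call[llr <= -threshold] = UNMETHYLATED
    return call


def parse_llr_records(path: str | Path, llr_threshold: float = 2.0) -> pd.DataFrame:
    """Parse the log-likelihood-ratio dialect into per-read, per-motif calls.

    A record with ``num_motifs`` > 1 is split into one call per CG motif; the
    genomic position of the k-th motif is ``start`` plus the offset of the
    k-th "CG" in the record's sequence field relative to the first "CG". The
    group's call (LLR >= +threshold methylated, <= -threshold unmethylated,
    otherwise ambiguous) is replicated to every motif.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "chromosome": "category",
            "strand": "category",
            "start": np.int64,
            "num_motifs": np.int32,
            "log_lik_ratio": np.float64,
            "read_name": str,
            "sequence": str,
        },
    )
    missing = [c for c in LLR_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    single = df["num_motifs"].to_numpy() == 1
    frames = []
    if single.any():
        part = df.loc[single]
        frames.append(
            pd.DataFrame(
                {
                    "sequence_id": part["chromosome"].astype(str),
                    "pos": part["start"].to_numpy(),
                    "strand": part["strand"].astype(str),
                    "read_id": part["read_name"].to_numpy(),
                    "raw_score": part["log_lik_ratio"].to_numpy(),
                }
            )
        )
    multi_idx = np.flatnonzero(~single)
    if len(multi_idx):
        chroms, poss, strands, reads, scores = [], [], [], [], []
        chrom_arr = df["chromosome"].astype(str).to_numpy()
        strand_arr = df["strand"].astype(str).to_numpy()
        start_arr = df["start"].to_numpy()
        nmot_arr = df["num_motifs"].to_numpy()
        read_arr = df["read_name"].to_numpy()
        llr_arr = df["log_lik_ratio"].to_numpy()
        seq_arr = df["sequence"].to_numpy()
        for i in multi_idx:
            seq, nmot = seq_arr[i], int(nmot_arr[i])
            offsets = []
            off = seq.find("CG")
            while off != -1 and len(offsets) < nmot:
                offsets.append(off)
                off = seq.find("CG", off + 1)
            if len(offsets) < nmot:
                raise FormatError(
                    f"{path}: line {i + 2}: sequence field contains "
                    f"{len(offsets)} CG motifs, num_motifs={nmot}"
                )
            for off in offsets:
                chroms.append(chrom_arr[i])
                poss.append(start_arr[i] + off - offsets[0])
                strands.append(strand_arr[i])
                reads.append(read_arr[i])
                scores.append(llr_arr[i])
        frames.append(
            pd.DataFrame(
                {
                    "sequence_id": chroms,
                    "pos": np.asarray(poss, dtype=np.int64),
                    "strand": strands,
                    "read_id": reads,
                    "raw_score": scores,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sequence_id", "pos", "strand", "read_id", "raw_score"]
    )
    out["source"] = "llr_caller"
    out["call"] = _threshold_llr(out["raw_score"].to_numpy(float), llr_threshold)
    return out[CALL_COLUMNS]


def _prob_chunk_to_calls(df: pd.DataFrame, path) -> pd.DataFrame:
    pm = df["prob_methylated"].to_numpy()
    pu = df["prob_unmethylated"].to_numpy()
    if ((pm < 0) | (pm > 1) | (pu < 0) | (pu > 1)).any():
        raise FormatError(f"{path}: probabilities outside [0, 1]")
    bad = np.abs(pm + pu - 1.0) > 1e-6
    if bad.any():
        raise FormatError(
            f"{path}: {int(bad.sum())} rows with probabilities not summing to 1"
        )
    call = np.full(len(df), AMBIGUOUS, dtype=object)
    call[pm > pu] = METHYLATED
    call[pm < pu] = UNMETHYLATED
    return pd.DataFrame(
        {
            "sequence_id": df["chrom"].astype(str),
            "pos": df["pos"],
            "strand": df["strand"].astype(str),
            "read_id": df["read_name"],
            "source": "prob_caller",
            "raw_score": pm,
            "call": call,
        }
    )


_PROB_USECOLS = ["chrom", "pos", "strand", "read_name", "prob_unmethylated", "prob_methylated"]
_PROB_DTYPES = {
    "chrom": "category",
    "pos": np.int64,
    "strand": "category",
    "read_name": str,
    "prob_unmethylated": np.float64,
    "prob_methylated": np.float64,
}


def parse_prob_records(
    path: str | Path,
    sites: pd.DataFrame | None = None,
    chunksize: int = 4_000_000,
) -> pd.DataFrame:
    """Parse the per-read probability dialect into per-read calls.

    A read is methylated iff prob_methylated > prob_unmethylated; equal
    probabilities are ambiguous. Probabilities outside [0, 1] or not summing
    to 1 within 1e-6 are format errors. ``sites`` optionally restricts the
    result to calls at the given (sequence_id, pos, strand) keys; the file is
    read in chunks so genome-scale inputs stay within memory.
    """
    header = pd.read_csv(path, sep="\t", nrows=0)
    missing = [c for c in PROB_FILE_COLUMNS if c not in header.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if sites is not None:
        sites = sites[["sequence_id", "pos", "strand"]].drop_duplicates()
        sites = sites.astype({"sequence_id": str, "strand": str})
    frames = []
    for chunk in pd.read_csv(
        path, sep="\t", usecols=_PROB_USECOLS, dtype=_PROB_DTYPES, chunksize=chunksize
    ):
        calls = _prob_chunk_to_calls(chunk, path)
        if sites is not None:
            calls = calls.merge(sites, on=["sequence_id", "pos", "strand"])
        frames.append(calls)
    if not frames:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def aggregate_site_frequency(
    calls: pd.DataFrame,
    context_index: pd.DataFrame,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Aggregate per-read calls into per-site, per-strand frequencies.

    Ambiguous calls are dropped before counting. Sites with fewer than
    ``min_coverage`` unambiguous reads are suppressed. Each emitted row is
    annotated with context/subcontext from the index; calls at positions not
    present in the index (caller/reference mismatches) and calls at
    UNCLASSIFIED cytosines are dropped with a counted warning.
    """
    grouped = _count_calls_by_site(calls)
    if len(grouped) == 0:
        return pd.DataFrame(
            columns=[
                "sequence_id",
                "pos",
                "strand",
                "context",
                "subcontext",
                "n_total",
                "n_methylated",
                "frequency",
            ]
        )
    return _finalize_site_counts(grouped, context_index, min_coverage)


def _count_calls_by_site(calls: pd.DataFrame) -> pd.DataFrame:
    mask = (calls["call"] != AMBIGUOUS).to_numpy()
    key = calls.loc[mask, ["sequence_id", "pos", "strand"]].copy()
    key["methylated"] = (calls.loc[mask, "call"] == METHYLATED).to_numpy(np.int32)
    return (
        key.groupby(["sequence_id", "pos", "strand"], observed=True, sort=False)
        .agg(n_total=("methylated", "size"), n_methylated=("methylated", "sum"))
        .reset_index()
    )


def _finalize_site_counts(
    grouped: pd.DataFrame, context_index: pd.DataFrame, min_coverage: int
) -> pd.DataFrame:
    idx = context_index[["sequence_id", "pos", "strand", "context", "subcontext"]].copy()
    idx["sequence_id"] = idx["sequence_id"].astype(str)
    idx["strand"] = idx["strand"].astype(str)
    merged = grouped.merge(idx, on=["sequence_id", "pos", "strand"], how="left")
    mismatch = merged["context"].isna()
    if mismatch.any():
        logger.warning(
            "%d sites (%d reads) at positions absent from the context index "
            "dropped (caller/reference mismatch)",
            int(mismatch.sum()),
            int(merged.loc[mismatch, "n_total"].sum()),
        )
        merged = merged[~mismatch]
    unclassified = merged["context"] == "UNCLASSIFIED"
    if unclassified.any():
        logger.warning(
            "%d sites with unclassifiable context dropped", int(unclassified.sum())
        )
        merged = merged[~unclassified]
    merged = merged[merged["n_total"] >= min_coverage].copy()
    merged["frequency"] = merged["n_methylated"] / merged["n_total"]
    merged = merged.sort_values(
        ["sequence_id", "pos", "strand"], kind="stable", ignore_index=True
    )
    return merged[
        [
            "sequence_id",
            "pos",
            "strand",
            "context",
            "subcontext",
            "n_total",
            "n_methylated",
            "frequency",
        ]
    ]


def aggregate_prob_file(
    path: str | Path,
    context_index: pd.DataFrame,
    min_coverage: int = 5,
    chunksize: int = 4_000_000,
) -> pd.DataFrame:
    """Streamed equivalent of ``parse_prob_records`` + ``aggregate_site_frequency``.

    Reads the probability dialect in chunks and keeps only per-site counts in
    memory, which is what genome-scale per-read files require.
    """
    header = pd.read_csv(path, sep="\t", nrows=0)
    missing = [c for c in PROB_FILE_COLUMNS if c not in header.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    partials = []
    for chunk in pd.read_csv(
        path, sep="\t", usecols=_PROB_USECOLS, dtype=_PROB_DTYPES, chunksize=chunksize
    ):
        partials.append(_count_calls_by_site(_prob_chunk_to_calls(chunk, path)))
    if not partials:
        return aggregate_site_frequency(
            pd.DataFrame(columns=CALL_COLUMNS), context_index, min_coverage
        )
    grouped = (
        pd.concat(partials, ignore_index=True)
        .groupby(["sequence_id", "pos", "strand"], observed=True, sort=False)
        .sum()
        .reset_index()
    )
    return _finalize_site_counts(grouped, context_index, min_coverage)


def split_by_context(frequencies: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a frequency table into per-context tables (CG, CHG, CHH)."""
    return {
        ctx: frequencies[frequencies["context"] == ctx].reset_index(drop=True)
        for ctx in ("CG", "CHG", "CHH")
    }


def combine_strands(frequencies: pd.DataFrame, min_coverage: int = 1) -> pd.DataFrame:
    """Merge symmetric CG and CHG partner sites by summing read counts.

    CG and CHG are strand-symmetric motifs: the minus-strand partner of a
    plus-strand site sits 1 bp (CG) or 2 bp (CHG) downstream on the reference
    axis. Merged rows are reported at the plus-strand coordinate with strand
    ".". CHH is asymmetric and passes through unchanged. This is a derived
    view; per-strand reporting stays the primary output.
    """
    frames = []
    for ctx, offset in (("CG", 1), ("CHG", 2)):
        part = frequencies[frequencies["context"] == ctx].copy()
        if not len(part):
            continue
        strand = part["strand"].astype(str)
        anchor = part["pos"].to_numpy() - np.where(strand == "-", offset, 0)
        part["pos"] = anchor
        # "+" sorts before "-", so merged rows keep the plus-strand subcontext
        part = part.sort_values(["sequence_id", "pos", "strand"], kind="stable")
        merged = (
            part.groupby(["sequence_id", "pos"], observed=True, sort=False)
            .agg(
                context=("context", "first"),
                subcontext=("subcontext", "first"),
                n_total=("n_total", "sum"),
                n_methylated=("n_methylated", "sum"),
            )
            .reset_index()
        )
        merged.insert(2, "strand", ".")
        frames.append(merged)
    chh = frequencies[~frequencies["context"].isin(["CG", "CHG"])]
    if len(chh):
        frames.append(chh[["sequence_id", "pos", "strand", "context",
                           "subcontext", "n_total", "n_methylated"]].copy())
    if not frames:
        return frequencies.iloc[:0].copy()
    out = pd.concat(frames, ignore_index=True)
    out = out[out["n_total"] >= min_coverage].copy()
    out["frequency"] = out["n_methylated"] / out["n_total"]
    return out.sort_values(["sequence_id", "pos"], kind="stable", ignore_index=True)


def global_levels(frequencies: pd.DataFrame, by: str = "context") -> pd.DataFrame:
    """Unweighted mean of per-site frequencies per context (or subcontext).

    ``by`` is "context" or "subcontext" (the latter also keeps the context
    column). Contexts with no sites are absent from the result rather than
    reported as zero.
    """
    keys = ["context"] if by == "context" else ["context", "subcontext"]
    if len(frequencies) == 0:
        return pd.DataFrame(columns=keys + ["mean_frequency", "n_sites"])
    out = (
        frequencies.groupby(keys, observed=True)
        .agg(mean_frequency=("frequency", "mean"), n_sites=("frequency", "size"))
        .reset_index()
    )
    return out.sort_values(keys, ignore_index=True)
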