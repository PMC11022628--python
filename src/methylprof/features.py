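"""Feature-anchored methylation profiles.

Metagene curves (fixed-width flanks, length-scaled body), genic-region
breakdowns (1 Kb upstream of the TSS, CDS, first intron, other introns, 1 Kb
downstream of the TES), gene-set comparisons, TE meta-profiles, repeat
coverage summaries, and repeat divergence landscapes.

Element orientation follows the transcript/element strand: bin 0 is always
the 5'-most flank bin. Elements are weighted equally (per-element bin means
are averaged across elements) so long genes or elements do not dominate the
curves; a site-weighted mode is available. Sites overlapping several
genes/regions are counted for each — multi-assignment, never loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .context import CONTEXTS
from .io import GeneModel, GenomeSequence

logger = logging.getLogger(__name__)

REGIONS = ("upstream_1kb", "CDS", "first_intron", "other_introns", "downstream_1kb")


# ---------------------------------------------------------------------------
# shared scaled-profile engine
# ---------------------------------------------------------------------------


class _SiteLookup:
    """Per-chromosome sorted views of a frequency table for fast range queries."""

    def __init__(self, frequencies: pd.DataFrame, contexts: Sequence[str]):
        self.contexts = list(contexts)
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        ctx_codes = pd.Categorical(
            frequencies["context"].astype(str), categories=self.contexts
        ).codes
        keep = ctx_codes >= 0
        df = frequencies.loc[keep]
        codes = ctx_codes[keep]
        for sid, part in df.assign(_ctx=codes).groupby(
            df["sequence_id"].astype(str), sort=False
        ):
            order = np.argsort(part["pos"].to_numpy(), kind="stable")
            self.by_chrom[str(sid)] = (
                part["pos"].to_numpy()[order],
                part["frequency"].to_numpy(float)[order],
                part["_ctx"].to_numpy()[order],
            )

    def query(self, sid: str, lo: int, hi: int):
        """Sites with lo <= pos < hi on chromosome ``sid``."""
        if sid not in self.by_chrom:
            return None
        pos, freq, ctx = self.by_chrom[sid]
        i, j = np.searchsorted(pos, (lo, hi))
        return pos[i:j], freq[i:j], ctx[i:j]


def _segment_bins(
    pos: np.ndarray,
    anchor_lo: int,
    span: int,
    n_bins: int,
    reverse: bool,
) -> np.ndarray:
    """Bin index within one segment for positions in [anchor_lo, anchor_lo+span)."""
    if reverse:
        x = (anchor_lo + span - 1 - pos) / span
    else:
        x = (pos - anchor_lo) / span
    return np.clip((x * n_bins).astype(int), 0, n_bins - 1)


@dataclass
class MetaProfile:
    """A scaled meta-profile: per (context, bin) mean frequency and counts."""

    table: pd.DataFrame  # columns: context, bin, segment, mean_frequency, n_elements, n_sites
    n_elements: int
    flank_bins: int
    body_bins: int
    flank_bp: int


def _profile_elements(
    lookup: _SiteLookup,
    elements: Iterable[tuple[str, int, int, str]],
    flank_bp: int,
    flank_bins: int,
    body_bins: int,
    site_weighted: bool = False,
) -> MetaProfile:
    contexts = lookup.contexts
    n_ctx = len(contexts)
    total = 2 * flank_bins + body_bins
    elem_sum = np.zeros((n_ctx, total))
    elem_cnt = np.zeros((n_ctx, total), dtype=np.int64)
    site_sum = np.zeros((n_ctx, total))
    site_cnt = np.zeros((n_ctx, total), dtype=np.int64)
    n_elements = 0

    for sid, start, end, strand in elements:
        res = lookup.query(sid, start - flank_bp, end + flank_bp)
        n_elements += 1
        if res is None:
            continue
        pos, freq, ctx = res
        glen = end - start
        minus = strand == "-"
        segments = [
            # (lo, hi, anchor_lo, span, n_bins, bin_offset, reverse)
            (start - flank_bp, start, start - flank_bp, flank_bp, flank_bins,
             flank_bins + body_bins if minus else 0, minus),
            (start, end, start, glen, body_bins, flank_bins, minus),
            (end, end + flank_bp, end, flank_bp, flank_bins,
             0 if minus else flank_bins + body_bins, minus),
        ]
        bins = np.full(len(pos), -1, dtype=np.int64)
        for lo, hi, a_lo, span, nb, off, rev in segments:
            sel = (pos >= lo) & (pos < hi)
            if not sel.any() or span <= 0:
                continue
            b = _segment_bins(pos[sel], a_lo, span, nb, rev)
            bins[sel] = b + off
        ok = bins >= 0
        if not ok.any():
            continue
        flat = ctx[ok].astype(np.int64) * total + bins[ok]
        s = np.bincount(flat, weights=freq[ok], minlength=n_ctx * total).reshape(
            n_ctx, total
        )
        c = np.bincount(flat, minlength=n_ctx * total).reshape(n_ctx, total)
        site_sum += s
        site_cnt += c
        nonzero = c > 0
        with np.errstate(invalid="ignore"):
            elem_sum[nonzero] += s[nonzero] / c[nonzero]
        elem_cnt += nonzero

    if site_weighted:
        num, den = site_sum, site_cnt
    else:
        num, den = elem_sum, elem_cnt
    with np.errstate(invalid="ignore"):
        mean = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    seg_labels = (
        ["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins
    )
    rows = []
    for ci, ctx_name in enumerate(contexts):
        for b in range(total):
            rows.append(
                (
                    ctx_name,
                    b,
                    seg_labels[b],
                    mean[ci, b],
                    int(elem_cnt[ci, b]),
                    int(site_cnt[ci, b]),
                )
            )
    table = pd.DataFrame(
        rows,
        columns=["context", "bin", "segment", "mean_frequency", "n_elements", "n_sites"],
    )
    return MetaProfile(
        table=table,
        n_elements=n_elements,
        flank_bins=flank_bins,
        body_bins=body_bins,
        flank_bp=flank_bp,
    )


# ---------------------------------------------------------------------------
# gene-anchored profiles
# ---------------------------------------------------------------------------


def metagene_profile(
    frequencies: pd.DataFrame,
    genes: Iterable[GeneModel],
    flank_bp: int = 5000,
    flank_bins: int = 50,
    body_bins: int = 60,
    contexts: Sequence[str] = CONTEXTS,
    site_weighted: bool = False,
) -> MetaProfile:
    """Average methylation curve over genes aligned at TSS/TES.

    Sites in the ``flank_bp`` upstream of the TSS map to fixed-width upstream
    bins, gene-body sites to fractional-position bins, and the downstream
    flank likewise; minus-strand genes are mirrored so bin 0 is always
    5'-most. The curve is the unweighted mean over genes of per-gene bin
    means (``site_weighted`` pools sites instead). Flanks running off the
    chromosome are truncated by construction (no sites exist there).
    """
    lookup = _SiteLookup(frequencies, contexts)
    elements = [(g.sequence_id, g.start, g.end, g.strand) for g in genes]
    return _profile_elements(
        lookup, elements, flank_bp, flank_bins, body_bins, site_weighted
    )


@dataclass
class RegionBreakdown:
    """Genic-region histogram and means per (region, context)."""

    histogram: pd.DataFrame  # region, context, freq_bin, bin_left, n_sites
    means: pd.DataFrame  # region, context, mean_frequency, n_sites
    n_genes: int
    n_genes_skipped: int  # genes without CDS


def _gene_regions(g: GeneModel, flank_bp: int) -> list[tuple[str, int, int]]:
    if g.strand == "+":
        upstream = (g.start - flank_bp, g.start)
        downstream = (g.end, g.end + flank_bp)
    else:
        upstream = (g.end, g.end + flank_bp)
        downstream = (g.start - flank_bp, g.start)
    regions = [("upstream_1kb", *upstream), ("downstream_1kb", *downstream)]
    regions += [("CDS", s, e) for s, e in g.cds]
    fi = g.first_intron
    if fi is not None:
        regions.append(("first_intron", *fi))
    regions += [("other_introns", s, e) for s, e in g.other_introns]
    return regions


def region_breakdown(
    frequencies: pd.DataFrame,
    genes: Iterable[GeneModel],
    flank_bp: int = 1000,
    n_freq_bins: int = 10,
    contexts: Sequence[str] = CONTEXTS,
) -> RegionBreakdown:
    """Site counts per genic region, context and frequency decile, plus means.

    Every site is assigned to every region of every overlapping gene. Genes
    without a CDS are skipped and counted. Frequency bins partition [0, 1]
    into ``n_freq_bins`` left-closed bins, the last one closed on the right.
    """
    lookup = _SiteLookup(frequencies, contexts)
    n_ctx = len(contexts)
    n_reg = len(REGIONS)
    counts = np.zeros((n_reg, n_ctx, n_freq_bins), dtype=np.int64)
    sums = np.zeros((n_reg, n_ctx))
    totals = np.zeros((n_reg, n_ctx), dtype=np.int64)
    reg_idx = {r: i for i, r in enumerate(REGIONS)}
    n_genes = 0
    n_skipped = 0
    for g in genes:
        if not g.has_cds:
            n_skipped += 1
            continue
        n_genes += 1
        for region, lo, hi in _gene_regions(g, flank_bp):
            if hi <= lo:
                continue
            res = lookup.query(g.sequence_id, lo, hi)
            if res is None:
                continue
            pos, freq, ctx = res
            if len(pos) == 0:
                continue
            ri = reg_idx[region]
            fbin = np.minimum((freq * n_freq_bins).astype(int), n_freq_bins - 1)
            flat = ctx * n_freq_bins + fbin
            counts[ri] += np.bincount(flat, minlength=n_ctx * n_freq_bins).reshape(
                n_ctx, n_freq_bins
            )
            sums[ri] += np.bincount(ctx, weights=freq, minlength=n_ctx)
            totals[ri] += np.bincount(ctx, minlength=n_ctx)
    if n_skipped:
        logger.info("region breakdown: %d genes without CDS skipped", n_skipped)

    hist_rows = []
    mean_rows = []
    for ri, region in enumerate(REGIONS):
        for ci, ctx_name in enumerate(contexts):
            for b in range(n_freq_bins):
                hist_rows.append(
                    (region, ctx_name, b, b / n_freq_bins, int(counts[ri, ci, b]))
                )
            t = int(totals[ri, ci])
            mean_rows.append(
                (region, ctx_name, sums[ri, ci] / t if t else np.nan, t)
            )
    return RegionBreakdown(
        histogram=pd.DataFrame(
            hist_rows, columns=["region", "context", "freq_bin", "bin_left", "n_sites"]
        ),
        means=pd.DataFrame(
            mean_rows, columns=["region", "context", "mean_frequency", "n_sites"]
        ),
        n_genes=n_genes,
        n_genes_skipped=n_skipped,
    )


def gene_set_profiles(
    frequencies: pd.DataFrame,
    genes: Sequence[GeneModel],
    gene_sets: Mapping[str, Iterable[str]],
    metagene_kwargs: dict | None = None,
    region_kwargs: dict | None = None,
) -> dict:
    """Metagene and region profiles restricted to named gene sets.

    Returns ``{"baseline": {...}, <set>: {...}, "unresolved": {...}}`` where
    each profile entry carries ``metagene``, ``regions`` and ``n_genes``.
    Unresolved IDs are reported per set; a set resolving to no genes is
    skipped with a warning.
    """
    metagene_kwargs = metagene_kwargs or {}
    region_kwargs = region_kwargs or {}
    by_id = {g.gene_id: g for g in genes}

    def _profiles(subset: Sequence[GeneModel]) -> dict:
        return {
            "metagene": metagene_profile(frequencies, subset, **metagene_kwargs),
            "regions": region_breakdown(frequencies, subset, **region_kwargs),
            "n_genes": len(subset),
        }

    out: dict = {"baseline": _profiles(list(genes)), "unresolved": {}}
    for name, ids in gene_sets.items():
        ids = list(ids)
        resolved = [by_id[i] for i in ids if i in by_id]
        unresolved = [i for i in ids if i not in by_id]
        out["unresolved"][name] = unresolved
        if unresolved:
            logger.warning("gene set %s: %d unresolved IDs", name, len(unresolved))
        if not resolved:
            logger.warning("gene set %s resolved to no genes; skipped", name)
            continue
        out[name] = _profiles(resolved)
    return out


# ---------------------------------------------------------------------------
# repeat-anchored profiles
# ---------------------------------------------------------------------------


def te_metaprofile(
    frequencies: pd.DataFrame,
    repeats: pd.DataFrame,
    group_by: str = "superfamily",
    flank_bp: int = 2000,
    body_bins: int = 40,
    flank_bins: int = 20,
    contexts: Sequence[str] = CONTEXTS,
    min_elements: int = 10,
    site_weighted: bool = False,
) -> dict[str, MetaProfile]:
    """Scaled meta-profile per repeat group (class, superfamily, or family).

    Element bodies are scaled to ``body_bins``; flanks are fixed-width.
    Groups with fewer than ``min_elements`` elements are still profiled but
    flagged low-confidence (``profile.table.attrs['low_confidence']``).
    """
    if group_by not in ("repeat_class", "superfamily", "repeat_name"):
        raise ValueError(f"cannot group repeats by {group_by!r}")
    lookup = _SiteLookup(frequencies, contexts)
    profiles: dict[str, MetaProfile] = {}
    for name, part in repeats.groupby(group_by, observed=True, sort=True):
        elements = list(
            zip(
                part["sequence_id"].astype(str),
                part["start"].astype(int),
                part["end"].astype(int),
                part["strand"].astype(str),
            )
        )
        prof = _profile_elements(
            lookup, elements, flank_bp, flank_bins, body_bins, site_weighted
        )
        prof.table.attrs["low_confidence"] = prof.n_elements < min_elements
        if prof.n_elements < min_elements:
            logger.info(
                "repeat group %s has %d elements (< %d): flagged low-confidence",
                name,
                prof.n_elements,
                min_elements,
            )
        profiles[str(name)] = prof
    return profiles


def _merged_bp(intervals: pd.DataFrame) -> int:
    """Total bp covered by a set of (sequence_id, start, end) intervals after
    merging overlaps within each sequence."""
    total = 0
    for _, part in intervals.groupby("sequence_id", observed=True, sort=False):
        arr = part[["start", "end"]].to_numpy()
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        cur_s, cur_e = None, None
        for s, e in arr:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
    return int(total)


def repeat_coverage_summary(
    repeats: pd.DataFrame,
    genome: Mapping[str, GenomeSequence] | Mapping[str, str],
) -> pd.DataFrame:
    """Percent of the genome masked per repeat class, superfamily and family.

    Overlapping intervals are merged within each group before summing, so
    nested elements are not double-counted. Percentages are exact floats
    (format to >= 4 decimals when printing).
    """
    genome_bp = sum(
        s.length if isinstance(s, GenomeSequence) else len(s) for s in genome.values()
    )
    rows = []
    levels = [
        ("class", "repeat_class"),
        ("superfamily", "superfamily"),
        ("family", "repeat_name"),
    ]
    rows.append(
        ("all", "all", len(repeats), _merged_bp(repeats), 100.0 * _merged_bp(repeats) / genome_bp)
    )
    for level, col in levels:
        for name, part in repeats.groupby(col, observed=True, sort=True):
            bp = _merged_bp(part)
            rows.append((level, str(name), len(part), bp, 100.0 * bp / genome_bp))
    return pd.DataFrame(
        rows, columns=["level", "group", "n_elements", "bp", "percent"]
    )


def divergence_landscape(
    repeats: pd.DataFrame, bin_width_pct: float = 1.0
) -> pd.DataFrame:
    """Repeat abundance (bp) binned by percent divergence from consensus.

    Bins are left-closed right-open multiples of ``bin_width_pct`` spanning
    [0, 50); elements more divergent than 50% land in an overflow bin at 50
    with a warning. Per-family and per-class roll-ups are both emitted; bin
    totals sum exactly to the total annotated bp of each group.
    """
    df = repeats.copy()
    df["bp"] = df["end"] - df["start"]
    div = df["divergence_pct"].to_numpy(float)
    over = div >= 50.0
    if over.any():
        logger.warning("%d elements with divergence >= 50%% in overflow bin", int(over.sum()))
    bin_left = np.floor(div / bin_width_pct) * bin_width_pct
    bin_left[over] = 50.0
    df["bin_left"] = bin_left
    parts = []
    for level, col in (("family", "repeat_name"), ("class", "repeat_class")):
        agg = (
            df.groupby([col, "bin_left"], observed=True)["bp"]
            .sum()
            .rename("bp")
            .reset_index()
            .rename(columns={col: "group"})
        )
        agg.insert(0, "level", level)
        parts.append(agg)
    return pd.concat(parts, ignore_index=True)
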