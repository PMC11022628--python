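"""Reference I/O: genomes, gene models, repeat annotations, and tabular exports.

All coordinates are converted to a single internal convention at the file
boundary: 0-based, half-open ``[start, end)``. GFF3 and RepeatMasker ``.out``
files are 1-based inclusive on disk; bedMethyl/bedGraph are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_RESIDUES = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomeSequence:
    """One reference sequence, uppercase residues over {A,C,G,T,N}.

    Softmasked (lowercase) bases are folded to uppercase on load; masking
    state is carried by the repeat annotation, not the sequence itself.
    """

    sequence_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A gene with one representative transcript (longest CDS).

    ``exons``/``cds`` are sorted, non-overlapping 0-based half-open intervals.
    Introns are the gaps between consecutive exons. ``first_intron`` is the
    5'-most intron in transcript orientation: the lowest-coordinate gap for a
    ``+`` gene, the highest-coordinate gap for a ``-`` gene.
    """

    gene_id: str
    sequence_id: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def has_cds(self) -> bool:
        return len(self.cds) > 0

    @property
    def introns(self) -> list[tuple[int, int]]:
        gaps = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                gaps.append((e0, s1))
        return gaps

    @property
    def first_intron(self) -> tuple[int, int] | None:
        gaps = self.introns
        if not gaps:
            return None
        return gaps[0] if self.strand == "+" else gaps[-1]

    @property
    def other_introns(self) -> list[tuple[int, int]]:
        fi = self.first_intron
        return [iv for iv in self.introns if iv != fi]


#: Column order of the parsed RepeatMasker table.
REPEAT_COLUMNS = [
    "sequence_id",
    "start",
    "end",
    "strand",
    "repeat_name",
    "repeat_class",
    "superfamily",
    "divergence_pct",
]


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Load a FASTA genome, folding softmask to uppercase.

    Residues outside {A,C,G,T,N} (IUPAC ambiguity codes) are mapped to N with
    a logged count. Duplicate record IDs and empty records are rejected.
    """
    path = Path(path)
    genome: dict[str, GenomeSequence] = {}
    n_folded = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"duplicate sequence ID {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        if not set(seq) <= _VALID_RESIDUES:
            arr = np.frombuffer(seq.encode(), dtype="S1")
            bad = ~np.isin(arr, [b"A", b"C", b"G", b"T", b"N"])
            n_folded += int(bad.sum())
            arr = arr.copy()
            arr[bad] = b"N"
            seq = arr.tobytes().decode()
        genome[rec.id] = GenomeSequence(rec.id, seq)
    if not genome:
        raise FormatError(f"no FASTA records found in {path}")
    if n_folded:
        logger.warning("%d ambiguous residues folded to N", n_folded)
    return genome


def write_fasta(genome: Mapping[str, GenomeSequence] | Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = []
    for sid, seq in genome.items():
        residues = seq.residues if isinstance(seq, GenomeSequence) else seq
        records.append(SeqRecord(Seq(residues), id=sid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _cds_span_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def read_gff3(path: str | Path, genome: Mapping[str, GenomeSequence]) -> list[GeneModel]:
    """Parse a GFF3 gene annotation into :class:`GeneModel` objects.

    For multi-transcript genes the representative transcript is the one with
    the longest total CDS (ties broken by file order). Genes without any CDS
    are retained (``has_cds`` False) so they still count for gene density, but
    are ineligible for genic-region breakdowns.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    known_ids = {f.id for f in db.all_features()}
    for f in db.all_features():
        for parent_id in f.attributes.get("Parent", []):
            if parent_id not in known_ids:
                raise FormatError(
                    f"feature {f.id!r} references missing parent {parent_id!r}"
                )
        if f.seqid not in genome:
            raise FormatError(f"feature {f.id!r} on unknown sequence {f.seqid!r}")
        if f.start < 1 or f.end > genome[f.seqid].length:
            raise FormatError(
                f"feature {f.id!r} [{f.start},{f.end}] exceeds bounds of "
                f"{f.seqid!r} (length {genome[f.seqid].length})"
            )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = list(db.children(gene, featuretype="mRNA", order_by="start"))
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        if transcripts:
            rep = max(
                transcripts,
                key=lambda t: _cds_span_length(
                    (c.start - 1, c.end) for c in db.children(t, featuretype="CDS")
                ),
            )
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(rep, featuretype="exon")
            )
            cds = sorted(
                (f.start - 1, f.end) for f in db.children(rep, featuretype="CDS")
            )
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                sequence_id=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
                cds=cds,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS rows, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.sequence_id}\tmethylprof\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(
                f"{base}gene\t{g.start + 1}\t{g.end}{tail}\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{base}mRNA\t{g.start + 1}\t{g.end}{tail}\tID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{base}exon\t{s + 1}\t{e}{tail}\tID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{base}CDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def read_repeatmasker_out(path: str | Path) -> pd.DataFrame:
    """Parse a RepeatMasker ``.out`` file into a repeat-feature table.

    Expects the standard dialect: 3 header lines, then whitespace-delimited
    columns (score, %div, %del, %ins, query, begin, end, (left), strand,
    repeat name, class/family, ...). Strand ``C`` maps to ``-``; the
    class/family token splits at the first ``/`` into class and superfamily
    (superfamily "Unknown" when absent); 1-based inclusive coordinates become
    0-based half-open.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, 1):
        if lineno <= 3 or not line.strip():
            continue
        parts = line.split()
        if len(parts) < 11:
            raise FormatError(
                f"{path}:{lineno}: expected >=11 columns, found {len(parts)}"
            )
        try:
            div = float(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric %div {parts[1]!r}") from exc
        if not 0.0 <= div <= 100.0:
            raise FormatError(f"{path}:{lineno}: %div {div} outside [0, 100]")
        query = parts[4]
        begin, end = int(parts[5]), int(parts[6])
        strand = parts[8]
        if strand == "C":
            strand = "-"
        if strand not in "+-":
            raise FormatError(f"{path}:{lineno}: bad strand {parts[8]!r}")
        name = parts[9]
        token = parts[10]
        if "/" in token:
            cls, superfam = token.split("/", 1)
        else:
            cls, superfam = token, "Unknown"
        rows.append((query, begin - 1, end, strand, name, cls, superfam, div))
    df = pd.DataFrame(rows, columns=REPEAT_COLUMNS)
    return df.astype({"start": "int64", "end": "int64", "divergence_pct": "float64"})


def write_repeatmasker_out(repeats: pd.DataFrame, path: str | Path) -> None:
    """Write a repeat table back out in the ``.out`` dialect (round-trippable)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query     position in query    matching"
            "  repeat              position in repeat\n"
            "score   div. del. ins.  sequence  begin  end   (left)  repeat"
            "  class/family          begin  end    (left)  ID\n\n"
        )
        for i, r in enumerate(repeats.itertuples(index=False), 1):
            strand = "C" if r.strand == "-" else "+"
            token = (
                r.repeat_class
                if r.superfamily == "Unknown"
                else f"{r.repeat_class}/{r.superfamily}"
            )
            fh.write(
                f"  100 {r.divergence_pct:6.2f}  0.0  0.0  {r.sequence_id}  "
                f"{r.start + 1}  {r.end}  (0)  {strand}  {r.repeat_name}  "
                f"{token}  1  {r.end - r.start}  (0)  {i}\n"
            )


def write_bedmethyl(site_frequencies: pd.DataFrame, path: str | Path) -> None:
    """Write per-site frequencies as bedMethyl (9+2 columns).

    score = min(int(1000*freq), 1000); the last two columns are read coverage
    and percent methylation rounded to 2 decimals. Rows sorted by
    (chrom, start).
    """
    df = site_frequencies
    if len(df) == 0:
        Path(path).write_text("")
        return
    if df["frequency"].isna().any():
        raise FormatError("NaN frequency rows cannot be written to bedMethyl")
    df = df.sort_values(["sequence_id", "pos"], kind="stable")
    out = pd.DataFrame(
        {
            "chrom": df["sequence_id"].astype(str),
            "start": df["pos"],
            "end": df["pos"] + 1,
            "name": df["context"].astype(str),
            "score": np.minimum((1000 * df["frequency"]).astype(int), 1000),
            "strand": df["strand"].astype(str),
            "thickStart": df["pos"],
            "thickEnd": df["pos"] + 1,
            "color": "0,0,0",
            "coverage": df["n_total"],
            "percent": (100 * df["frequency"]).round(2),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(window_stats: pd.DataFrame, path: str | Path, value_column: str = "mean_frequency") -> None:
    """Write windowed means as bedGraph (chrom, start, end, value); NaN rows dropped."""
    df = window_stats.dropna(subset=[value_column])
    if len(df) == 0:
        Path(path).write_text("")
        return
    df = df.sort_values(["sequence_id", "start"], kind="stable")
    out = df[["sequence_id", "start", "end", value_column]].copy()
    out[value_column] = out[value_column].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", header=False, index=False)
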