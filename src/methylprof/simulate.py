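"""Synthetic methylome generator with planted ground truth.

Generates everything the pipeline consumes — a multi-chromosome genome with a
gene-density gradient, TE insertions from named family consensi with realized
divergence, a GFF3 annotation, a RepeatMasker-style ``.out`` file, and
per-read caller files in both dialects — plus truth tables, so every stage of
the analysis can be verified offline at desk scale.

The planted statistical structure mirrors what is observed in broadleaf tree
methylomes: global means near 53% (CG), 40% (CHG) and 10% (CHH); a CHH
subcontext preference CTA > CAA > rest; a CHH spike immediately upstream of
the TSS (stronger for a designated "DE" gene set); first-intron depletion;
negative coupling between local gene density and methylation; and per-family
TE body/flank levels. Caller noise covers LLR score spread, class-conditional
miscalls of the probability caller, and per-caller read dropout; an
"over-calling" configuration emulates the single-tool false-positive excess
that a two-caller consensus is designed to remove.

Coverage is Poisson per site; adjacent CG sites within 10 bp form chains that
share one LLR record per read (``num_motifs`` > 1) and, reflecting the
near-perfect within-read correlation of CpGs a few bp apart, a single planted
probability and per-read state.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .context import build_context_index
from .io import (
    GeneModel,
    GenomeSequence,
    write_fasta,
    write_gff3,
    write_repeatmasker_out,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}
#: maximum gap (bp) between CG sites sharing one LLR record
CG_GROUP_GAP = 10


# ---------------------------------------------------------------------------
# model parameterization
# ---------------------------------------------------------------------------


@dataclass
class CallerNoise:
    """Noise model for the two emulated callers.

    LLR scores are Normal(+mu, sigma) for methylated reads and
    Normal(-mu, sigma) for unmethylated reads, both shifted by ``llr_bias``
    (a positive bias makes unmethylated reads mostly ambiguous rather than
    negative, producing the over-calling behaviour of LLR callers in
    hypomethylated regions). The probability caller miscalls methylated reads
    at rate ``prob_fn`` and unmethylated reads at rate ``prob_fp``, drawing
    its probabilities to match the emitted label. Each caller independently
    drops a fraction of reads (``*_dropout``), which controls the designed
    overlap available for read pairing.
    """

    llr_mu: float = 2.5
    llr_sigma: float = 1.0
    llr_bias: float = 0.0
    prob_fp: float = 0.02
    prob_fn: float = 0.05
    llr_dropout: float = 0.05
    prob_dropout: float = 0.05

    @classmethod
    def noiseless(cls) -> "CallerNoise":
        """Effectively infinite LLR separation, no miscalls, no dropout."""
        return cls(
            llr_mu=50.0, llr_sigma=0.01, llr_bias=0.0,
            prob_fp=0.0, prob_fn=0.0, llr_dropout=0.0, prob_dropout=0.0,
        )

    @classmethod
    def overcalling(cls) -> "CallerNoise":
        """Both callers overpredict methylation (single-tool false positives)."""
        return cls(llr_bias=1.0, prob_fp=0.15, prob_fn=0.01)


@dataclass
class TEFamilySpec:
    """One repeat family in the synthetic TE library."""

    name: str
    classification: str  # class/superfamily token, e.g. "LTR/Copia"
    consensus_length: int
    target_divergence_pct: float
    weight: float


def default_te_library() -> list[TEFamilySpec]:
    return [
        TEFamilySpec("Copia-7_fam", "LTR/Copia", 1500, 12.0, 0.22),
        TEFamilySpec("rnd-1_family-42", "LTR/Copia", 800, 0.5, 0.18),  # recent burst
        TEFamilySpec("Gypsy-3_fam", "LTR/Gypsy", 2000, 8.0, 0.20),
        TEFamilySpec("MuDR-2_fam", "DNA/MULE-MuDR", 600, 15.0, 0.15),
        TEFamilySpec("hAT-5_fam", "DNA/hAT", 500, 18.0, 0.12),
        TEFamilySpec("L1-9_fam", "LINE/L1", 1200, 20.0, 0.13),
    ]


@dataclass
class MethylomeModel:
    """Planted methylation structure plus caller noise.

    All planted frequencies live in [0, 1]; base means are per-context global
    targets that the generator calibrates to exactly (the structural effects
    below redistribute methylation without moving the global mean).
    """

    base_mean: dict = field(
        default_factory=lambda: {"CG": 0.53, "CHG": 0.40, "CHH": 0.10}
    )
    chh_subcontext_multipliers: dict = field(
        default_factory=lambda: {"CTA": 1.6, "CAA": 1.3}
    )
    gene_body_multipliers: dict = field(
        default_factory=lambda: {"CG": 0.9, "CHG": 0.7, "CHH": 0.5}
    )
    first_intron_multiplier: float = 0.5
    tss_spike_height: float = 2.5  # CHH multiplier in the spike window
    tss_spike_bp: int = 1000
    de_spike_extra: float = 1.6  # additional CHH spike multiplier for the DE set
    gene_density_coupling: float = 0.8  # >0: dense regions are less methylated
    te_body_multipliers: dict = field(
        default_factory=lambda: {
            "Copia": {"CHH": 1.5},
            "MULE-MuDR": {"CHH": 2.5},
            "hAT": {"CHH": 2.0},
        }
    )
    te_absolute_levels: dict = field(
        default_factory=lambda: {
            "Gypsy": {"body": {"CG": 0.8}, "flank": {"CG": 0.4}}
        }
    )
    te_flank_bp: int = 2000
    beta_concentration: float = 8.0
    coverage_lambda: float = 30.0
    noise: CallerNoise = field(default_factory=CallerNoise)

    def validated(self) -> "MethylomeModel":
        for ctx, p in self.base_mean.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"base mean for {ctx} outside [0, 1]: {p}")
        if self.coverage_lambda <= 0:
            raise ValueError("coverage lambda must be > 0")
        if self.noise.llr_mu <= 0 or self.noise.llr_sigma <= 0:
            raise ValueError("LLR mu and sigma must be > 0")
        return self


@dataclass
class ScenarioConfig:
    """Genome-scale parameters of a synthetic study."""

    n_chrom: int = 2
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.35
    genes_per_mb: float = 100.0
    te_per_mb: float = 150.0
    gene_density_profile: str = "arm_biased"
    cds_fraction: float = 0.95
    de_fraction: float = 0.08
    model: MethylomeModel = field(default_factory=MethylomeModel)


def default_scenario() -> ScenarioConfig:
    """The standard desk-scale study: 2 chromosomes x 1 Mb, ~200 genes,
    ~300 TE copies, coverage lambda 30."""
    return ScenarioConfig()


def structure_scenario() -> ScenarioConfig:
    """A larger genome (5 x 2 Mb) for structure-recovery checks that need
    many populated 1 Mb windows (gene-density correlation) and many genes."""
    return ScenarioConfig(n_chrom=5, chrom_length=2_000_000)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenome:
    """A generated genome plus its annotations and planted truth helpers."""

    genome: dict[str, GenomeSequence]
    genes: list[GeneModel]
    repeats: pd.DataFrame
    gene_sets: dict[str, list[str]]
    density: dict[str, np.ndarray]  # per-kb gene-density profile in [0, 1]
    density_resolution: int
    te_truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "rmout": outdir / "repeats.out",
            "te_truth": outdir / "te_truth.tsv",
        }
        write_fasta(self.genome, paths["fasta"])
        write_gff3(self.genes, paths["gff3"])
        write_repeatmasker_out(self.repeats, paths["rmout"])
        self.te_truth.to_csv(paths["te_truth"], sep="\t", index=False)
        for name, ids in self.gene_sets.items():
            p = outdir / f"gene_set_{name}.txt"
            p.write_text("".join(f"{i}\n" for i in ids))
            paths[f"gene_set_{name}"] = p
        return paths


def _density_profile(kind: str, n_cells: int) -> np.ndarray:
    u = (np.arange(n_cells) + 0.5) / n_cells
    if kind == "uniform":
        return np.full(n_cells, 0.5)
    if kind == "arm_biased":
        return 0.05 + 0.95 * (2.0 * np.abs(u - 0.5)) ** 2
    raise ValueError(f"unknown gene density profile {kind!r}")


def _sample_gene_structure(rng: np.random.Generator) -> tuple[list[int], list[int]]:
    n_exons = int(rng.integers(1, 7))
    exon_lens = rng.integers(120, 400, size=n_exons).tolist()
    intron_lens = rng.integers(80, 400, size=max(n_exons - 1, 0)).tolist()
    return exon_lens, intron_lens


def _free_slot(occupied: list[tuple[int, int]], start: int, end: int) -> bool:
    i = bisect_left(occupied, (start, end))
    if i > 0 and occupied[i - 1][1] > start:
        return False
    if i < len(occupied) and occupied[i][0] < end:
        return False
    return True


def generate_genome(
    seed: int,
    config: ScenarioConfig | None = None,
    **overrides,
) -> SyntheticGenome:
    """Generate a genome with gene-density gradients and TE insertions.

    Deterministic under ``seed``. Genes are placed proportionally to the
    density profile (arm-enriched by default), TEs proportionally to its
    complement (pericentromere-enriched). Each TE copy is the family
    consensus mutated at a per-base substitution rate equal to the family's
    target divergence; the realized divergence is recorded in the ``.out``.
    """
    config = replace(config or ScenarioConfig(), **overrides) if (config or overrides) else ScenarioConfig()
    rng = np.random.default_rng(seed)
    res = 1000  # density grid resolution, bp
    gc = config.gc_fraction
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    te_library = default_te_library()
    consensi = {
        fam.name: _BASES[rng.choice(4, size=fam.consensus_length, p=base_probs)]
        for fam in te_library
    }
    fam_weights = np.array([f.weight for f in te_library])
    fam_weights = fam_weights / fam_weights.sum()

    genome: dict[str, GenomeSequence] = {}
    genes: list[GeneModel] = []
    repeat_rows = []
    te_rows = []
    density: dict[str, np.ndarray] = {}

    requested_bp = (
        config.te_per_mb
        * (config.chrom_length / 1e6)
        * sum(f.weight * f.consensus_length for f in te_library)
    )
    if requested_bp > 0.8 * config.chrom_length:
        raise ValueError("requested TE bp exceeds what the genome can hold")

    for ci in range(config.n_chrom):
        sid = f"chr{ci + 1}"
        length = config.chrom_length
        arr = _BASES[rng.choice(4, size=length, p=base_probs)].copy()
        # chromosomes differ in overall gene density (gene-rich vs gene-poor),
        # which is what windowed density-methylation correlations measure
        density_scale = rng.uniform(0.5, 1.5)
        d = _density_profile(config.gene_density_profile, length // res) * density_scale
        density[sid] = d
        cell_p = d / d.sum()

        occupied: list[tuple[int, int]] = []
        n_genes = round(config.genes_per_mb * length / 1e6 * density_scale)
        margin = 6000
        for gi in range(n_genes):
            for _attempt in range(60):
                cell = int(rng.choice(len(d), p=cell_p))
                start = int(cell * res + rng.integers(0, res))
                exon_lens, intron_lens = _sample_gene_structure(rng)
                span = sum(exon_lens) + sum(intron_lens)
                end = start + span
                if start < margin or end > length - margin:
                    continue
                if _free_slot(occupied, start - 1200, end + 1200):
                    break
            else:
                continue
            insort(occupied, (start - 1200, end + 1200))
            exons = []
            cursor = start
            for k, el in enumerate(exon_lens):
                exons.append((cursor, cursor + el))
                cursor += el
                if k < len(intron_lens):
                    cursor += intron_lens[k]
            strand = "+" if rng.random() < 0.5 else "-"
            has_cds = rng.random() < config.cds_fraction
            genes.append(
                GeneModel(
                    gene_id=f"{sid}_g{gi:04d}",
                    sequence_id=sid,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds=list(exons) if has_cds else [],
                )
            )

        te_weight = d.max() - d + 0.05 * d.max()
        te_cell_p = te_weight / te_weight.sum()
        n_te = round(config.te_per_mb * length / 1e6)
        for _ti in range(n_te):
            fam = te_library[int(rng.choice(len(te_library), p=fam_weights))]
            cons = consensi[fam.name]
            n_mut = int(rng.binomial(len(cons), fam.target_divergence_pct / 100.0))
            copy = cons.copy()
            if n_mut:
                sites = rng.choice(len(cons), size=n_mut, replace=False)
                shifts = rng.integers(1, 4, size=n_mut)
                copy[sites] = _BASES[
                    (np.searchsorted(_BASES, cons[sites]) + shifts) % 4
                ]
            realized_div = 100.0 * n_mut / len(cons)
            placed = False
            for _attempt in range(60):
                cell = int(rng.choice(len(d), p=te_cell_p))
                start = int(cell * res + rng.integers(0, res))
                end = start + len(copy)
                if start < 2500 or end > length - 2500:
                    continue
                if _free_slot(occupied, start, end):
                    placed = True
                    break
            if not placed:
                continue
            insort(occupied, (start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                comp = np.array([_COMP.get(b, b) for b in copy[::-1]], dtype=np.uint8)
                arr[start:end] = comp
            else:
                arr[start:end] = copy
            cls, superfam = fam.classification.split("/", 1)
            repeat_rows.append(
                (sid, start, end, strand, fam.name, cls, superfam, round(realized_div, 2))
            )
            te_rows.append(
                (sid, start, end, fam.name, fam.classification,
                 fam.target_divergence_pct, realized_div)
            )

        genome[sid] = GenomeSequence(sid, arr.tobytes().decode("ascii"))

    genes_with_cds = [g.gene_id for g in genes if g.has_cds]
    n_de = max(2, round(config.de_fraction * len(genes_with_cds)))
    de_ids = sorted(
        rng.choice(genes_with_cds, size=min(n_de, len(genes_with_cds)), replace=False)
    )
    repeats = pd.DataFrame(
        repeat_rows,
        columns=[
            "sequence_id", "start", "end", "strand",
            "repeat_name", "repeat_class", "superfamily", "divergence_pct",
        ],
    )
    te_truth = pd.DataFrame(
        te_rows,
        columns=[
            "sequence_id", "start", "end", "repeat_name", "classification",
            "target_divergence_pct", "realized_divergence_pct",
        ],
    )
    logger.info(
        "generated %d chromosomes, %d genes, %d TE copies",
        config.n_chrom, len(genes), len(repeats),
    )
    return SyntheticGenome(
        genome=genome,
        genes=genes,
        repeats=repeats,
        gene_sets={"DE": list(de_ids)},
        density=density,
        density_resolution=res,
        te_truth=te_truth,
    )


# ---------------------------------------------------------------------------
# methylation planting
# ---------------------------------------------------------------------------


def _rows_in_range(pos_sorted: np.ndarray, lo: int, hi: int) -> slice:
    i, j = np.searchsorted(pos_sorted, (lo, hi))
    return slice(i, j)


def plant_methylation(
    synth: SyntheticGenome,
    model: MethylomeModel | None = None,
    seed: int = 0,
    context_index: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Plant a per-site methylation probability for every classified cytosine.

    The structural probability is base(context) x subcontext multiplier x
    gene-region effects x density coupling x TE multipliers, then each
    context is calibrated so its genome-wide mean equals the base mean
    exactly (absolute TE overrides are accounted for in the calibration), and
    finally a mean-preserving beta dispersion is drawn per site. Deterministic
    under ``seed``. Returns the context index with planted ``p`` and
    ``p_structural`` columns (UNCLASSIFIED sites are excluded).
    """
    model = (model or MethylomeModel()).validated()
    rng = np.random.default_rng(seed)
    index = (
        context_index
        if context_index is not None
        else build_context_index(synth.genome)
    )
    truth = index[index["context"] != "UNCLASSIFIED"].copy()
    truth = truth.sort_values(["sequence_id", "pos", "strand"], kind="stable", ignore_index=True)

    ctx = truth["context"].astype(str).to_numpy()
    sub = truth["subcontext"].astype(str).to_numpy()
    base = np.select(
        [ctx == "CG", ctx == "CHG", ctx == "CHH"],
        [model.base_mean["CG"], model.base_mean["CHG"], model.base_mean["CHH"]],
    )
    mult = np.ones(len(truth))
    for subctx, m in model.chh_subcontext_multipliers.items():
        mult[sub == subctx] *= m

    chrom_arr = truth["sequence_id"].astype(str).to_numpy()
    pos_arr = truth["pos"].to_numpy()
    is_chh = ctx == "CHH"
    de_ids = set(synth.gene_sets.get("DE", []))
    override_mask = np.zeros(len(truth), dtype=bool)
    override_p = np.zeros(len(truth))
    all_density = np.concatenate(list(synth.density.values()))
    dmax = all_density.max()
    dbar = (all_density / dmax).mean()

    for sid in synth.genome:
        sel = np.flatnonzero(chrom_arr == sid)
        if len(sel) == 0:
            continue
        pos = pos_arr[sel]  # sorted within chromosome

        # gene-density coupling, normalized against the genome-wide profile so
        # that gene-poor chromosomes really are more methylated than gene-rich
        d = synth.density[sid] / dmax
        cells = np.minimum(pos // synth.density_resolution, len(d) - 1)
        mult[sel] *= np.maximum(
            1.0 - model.gene_density_coupling * (d[cells] - dbar), 0.05
        )

        # gene-region effects
        for g in synth.genes:
            if g.sequence_id != sid:
                continue
            body = _rows_in_range(pos, g.start, g.end)
            rows = sel[body]
            for c, m in model.gene_body_multipliers.items():
                mult[rows[ctx[rows] == c]] *= m
            fi = g.first_intron
            if fi is not None:
                rows_fi = sel[_rows_in_range(pos, fi[0], fi[1])]
                mult[rows_fi] *= model.first_intron_multiplier
            if g.strand == "+":
                spike = (g.start - model.tss_spike_bp, g.start)
            else:
                spike = (g.end, g.end + model.tss_spike_bp)
            rows_sp = sel[_rows_in_range(pos, spike[0], spike[1])]
            rows_sp = rows_sp[is_chh[rows_sp]]
            h = model.tss_spike_height
            if g.gene_id in de_ids:
                h *= model.de_spike_extra
            mult[rows_sp] *= h

        # TE effects
        chrom_repeats = synth.repeats[synth.repeats["sequence_id"] == sid]
        for r in chrom_repeats.itertuples(index=False):
            effects = model.te_body_multipliers.get(
                r.superfamily, model.te_body_multipliers.get(r.repeat_name)
            )
            if effects:
                rows = sel[_rows_in_range(pos, r.start, r.end)]
                for c, m in effects.items():
                    mult[rows[ctx[rows] == c]] *= m
            levels = model.te_absolute_levels.get(
                r.superfamily, model.te_absolute_levels.get(r.repeat_name)
            )
            if levels:
                flank = levels.get("flank", {})
                for c, p_abs in flank.items():
                    for lo, hi in (
                        (r.start - model.te_flank_bp, r.start),
                        (r.end, r.end + model.te_flank_bp),
                    ):
                        rows = sel[_rows_in_range(pos, lo, hi)]
                        rows = rows[ctx[rows] == c]
                        override_mask[rows] = True
                        override_p[rows] = p_abs
        # body overrides win over any flank override from a neighbour
        for r in chrom_repeats.itertuples(index=False):
            levels = model.te_absolute_levels.get(
                r.superfamily, model.te_absolute_levels.get(r.repeat_name)
            )
            if levels:
                for c, p_abs in levels.get("body", {}).items():
                    rows = sel[_rows_in_range(pos, r.start, r.end)]
                    rows = rows[ctx[rows] == c]
                    override_mask[rows] = True
                    override_p[rows] = p_abs

    p = np.clip(base * mult, 1e-3, 0.999)
    n_clamped = int(((base * mult) > 0.999).sum())
    if n_clamped:
        logger.info("%d planted probabilities clamped into [0.001, 0.999]", n_clamped)

    # calibrate each context's genome-wide mean to the base mean exactly,
    # holding absolute TE overrides fixed
    for c, target in model.base_mean.items():
        in_ctx = ctx == c
        bg = in_ctx & ~override_mask
        ov = in_ctx & override_mask
        if not bg.any():
            continue
        f_ov = ov.sum() / in_ctx.sum()
        ov_mean = override_p[ov].mean() if ov.any() else 0.0
        bg_target = (target - f_ov * ov_mean) / (1.0 - f_ov)
        bg_target = min(max(bg_target, 1e-3), 0.999)
        for _ in range(3):
            scale = bg_target / p[bg].mean()
            p[bg] = np.clip(p[bg] * scale, 1e-3, 0.999)
    p[override_mask] = override_p[override_mask]

    truth["p_structural"] = p
    k = model.beta_concentration
    truth["p"] = rng.beta(np.maximum(k * p, 1e-6), np.maximum(k * (1.0 - p), 1e-6))
    return truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedReads:
    """Paths and bookkeeping for one simulated sequencing run."""

    llr_path: Path
    prob_path: Path
    truth: pd.DataFrame  # site-level truth (with chain-shared p where grouped)
    read_truth: pd.DataFrame | None
    n_reads: int
    n_llr_records: int
    n_prob_records: int
    n_expected_pairs: int


def _chain_units(truth: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Assign unit ids: CG sites within CG_GROUP_GAP bp on the same
    chromosome and strand share a unit; every other site is its own unit.

    ``truth`` must be sorted by (sequence_id, strand, pos). Returns
    (unit_id per row, is_cg per row).
    """
    chrom = truth["sequence_id"].astype(str).to_numpy()
    strand = truth["strand"].astype(str).to_numpy()
    pos = truth["pos"].to_numpy()
    is_cg = truth["context"].astype(str).to_numpy() == "CG"
    same = np.zeros(len(truth), dtype=bool)
    if len(truth) > 1:
        same[1:] = (
            is_cg[1:]
            & is_cg[:-1]
            & (chrom[1:] == chrom[:-1])
            & (strand[1:] == strand[:-1])
            & (pos[1:] - pos[:-1] <= CG_GROUP_GAP)
        )
    unit_id = np.cumsum(~same) - 1
    return unit_id, is_cg


def _llr_sequence_field(
    residues: str, member_pos: np.ndarray, strand: str, flank: int = 5
) -> str:
    """The sequence field of one LLR record: forward-reference substring
    containing exactly the group's CG motifs at matching relative offsets."""
    if strand == "+":
        lo = max(int(member_pos[0]) - flank, 0)
        hi = min(int(member_pos[-1]) + 2 + flank, len(residues))
    else:  # member positions are G coordinates; motifs start one base left
        lo = max(int(member_pos[0]) - 1 - flank, 0)
        hi = min(int(member_pos[-1]) + 1 + flank, len(residues))
    return residues[lo:hi]


def _site_kmers(residues: str, pos: np.ndarray, k: int = 9) -> np.ndarray:
    """Reference k-mer centred on each position (edges padded with N)."""
    half = k // 2
    padded = ("N" * half) + residues + ("N" * half)
    arr = np.frombuffer(padded.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    return win[pos].copy().view(f"S{k}").ravel().astype(str)


def _write_tsv(
    path: Path,
    frames: dict,
    float_format: str = "%.4f",
    chunk: int = 2_000_000,
    n: int | None = None,
) -> int:
    """Write columns as a TSV in bounded-memory chunks; returns rows written.

    A column may be an array or a callable ``f(lo, hi)`` producing the slice,
    which avoids materializing genome-scale columns all at once.
    """
    if n is None:
        n = len(next(v for v in frames.values() if not callable(v)))
    with open(path, "w") as fh:
        fh.write("\t".join(frames.keys()) + "\n")
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            df = pd.DataFrame(
                {k: (v(lo, hi) if callable(v) else v[lo:hi]) for k, v in frames.items()}
            )
            df.to_csv(fh, sep="\t", header=False, index=False, float_format=float_format)
    return n


def simulate_reads(
    synth: SyntheticGenome,
    truth: pd.DataFrame,
    model: MethylomeModel | None = None,
    seed: int = 0,
    outdir: str | Path = ".",
    contexts: tuple[str, ...] | None = None,
    keep_read_truth: bool = True,
    read_truth_contexts: tuple[str, ...] | None = None,
) -> SimulatedReads:
    """Emit per-read caller files in both dialects plus per-read truth.

    Per unit (CG chain or single site), N ~ Poisson(lambda) reads are drawn;
    each read's methylation state is Bernoulli(planted p). The probability
    dialect covers all contexts; the LLR dialect covers CG only, with one
    record per read per chain (``num_motifs`` = chain size) and a sequence
    field whose CG offsets reproduce the member coordinates. Read ids are
    shared across dialects so reads can be paired. Deterministic under
    ``seed``.
    """
    model = (model or MethylomeModel()).validated()
    noise = model.noise
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    truth = truth if contexts is None else truth[truth["context"].isin(contexts)]
    # CG rows are sorted into contiguous per-(chromosome, strand) blocks so
    # that chain members occupy consecutive rows
    truth = (
        truth.assign(_cg=(truth["context"].astype(str) == "CG"))
        .sort_values(
            ["sequence_id", "strand", "_cg", "pos"],
            ascending=[True, True, False, True],
            kind="stable",
            ignore_index=True,
        )
        .drop(columns="_cg")
    )
    unit_id, is_cg = _chain_units(truth)
    n_units = int(unit_id[-1]) + 1 if len(truth) else 0
    p_site = truth["p"].to_numpy()
    unit_size = np.bincount(unit_id, minlength=n_units)
    unit_start_row = np.concatenate([[0], np.cumsum(unit_size)[:-1]])
    unit_p = np.bincount(unit_id, weights=p_site, minlength=n_units) / np.maximum(unit_size, 1)
    # chained CG sites share one per-read state; record the shared p back
    p_shared = unit_p[unit_id]
    truth = truth.assign(p=p_shared)
    unit_is_cg = is_cg[unit_start_row]

    n_per_unit = rng.poisson(model.coverage_lambda, size=n_units)
    n_reads = int(n_per_unit.sum())
    read_unit = np.repeat(np.arange(n_units, dtype=np.int32), n_per_unit)
    read_label = rng.random(n_reads) < unit_p[read_unit]
    read_ids = np.arange(n_reads, dtype=np.int64)

    chrom_by_unit = truth["sequence_id"].astype(str).to_numpy()[unit_start_row]
    strand_by_unit = truth["strand"].astype(str).to_numpy()[unit_start_row]
    pos_arr = truth["pos"].to_numpy()
    unit_first_pos = pos_arr[unit_start_row]
    unit_last_pos = pos_arr[unit_start_row + unit_size - 1]

    # ---- LLR dialect: one record per read per CG unit ----
    cg_read = unit_is_cg[read_unit]
    keep_llr_read = np.zeros(n_reads, dtype=bool)
    keep_llr_read[cg_read] = rng.random(int(cg_read.sum())) >= noise.llr_dropout
    llr_sel = np.flatnonzero(keep_llr_read)
    mu = np.where(read_label[llr_sel], noise.llr_mu, -noise.llr_mu) + noise.llr_bias
    llr_vals = rng.normal(mu, noise.llr_sigma)

    seq_fields = np.empty(n_units, dtype=object)
    for u in np.flatnonzero(unit_is_cg):
        sid = chrom_by_unit[u]
        members = pos_arr[unit_start_row[u] : unit_start_row[u] + unit_size[u]]
        seq_fields[u] = _llr_sequence_field(
            synth.genome[sid].residues, members, strand_by_unit[u]
        )

    llr_units = read_unit[llr_sel]
    llr_path = outdir / "llr_calls.tsv"
    n_llr = _write_tsv(
        llr_path,
        {
            "chromosome": chrom_by_unit[llr_units],
            "strand": strand_by_unit[llr_units],
            "start": unit_first_pos[llr_units],
            "end": unit_last_pos[llr_units],
            "read_name": read_ids[llr_sel],
            "log_lik_ratio": llr_vals,
            "log_lik_methylated": llr_vals / 2.0,
            "log_lik_unmethylated": -llr_vals / 2.0,
            "num_calling_strands": np.ones(len(llr_sel), dtype=np.int64),
            "num_motifs": unit_size[llr_units],
            "sequence": seq_fields[llr_units],
        },
    )

    # ---- probability dialect: one row per read per member site ----
    m_per_read = unit_size[read_unit].astype(np.int32)
    total_rows = int(m_per_read.sum())
    row_read = np.repeat(np.arange(n_reads, dtype=np.int32), m_per_read)
    offsets = np.arange(total_rows, dtype=np.int32) - np.repeat(
        np.concatenate([[0], np.cumsum(m_per_read, dtype=np.int64)[:-1]]).astype(np.int32),
        m_per_read,
    )
    row_site = unit_start_row.astype(np.int32)[read_unit[row_read]] + offsets
    del offsets, m_per_read
    row_label = read_label[row_read]

    keep_prob = rng.random(total_rows) >= noise.prob_dropout
    flip = np.where(
        row_label,
        rng.random(total_rows) < noise.prob_fn,
        rng.random(total_rows) < noise.prob_fp,
    )
    emitted = row_label ^ flip
    del flip
    if noise.prob_fp == 0 and noise.prob_fn == 0:
        conf = np.full(total_rows, 0.95, dtype=np.float32)
    else:
        conf = rng.uniform(0.55, 0.99, size=total_rows).astype(np.float32)
    prob_m = np.round(np.where(emitted, conf, np.float32(1.0) - conf), 4)
    del conf

    kmers_by_row = np.empty(len(truth), dtype=object)
    chrom_rows = truth["sequence_id"].astype(str).to_numpy()
    for sid in synth.genome:
        rows = np.flatnonzero(chrom_rows == sid)
        if len(rows):
            kmers_by_row[rows] = _site_kmers(synth.genome[sid].residues, pos_arr[rows])

    n_expected_pairs = int((keep_llr_read[row_read] & keep_prob).sum())
    prob_sel = np.flatnonzero(keep_prob)
    del keep_prob
    site_of = row_site[prob_sel]
    read_of = row_read[prob_sel]
    strand_rows = truth["strand"].astype(str).to_numpy()
    chrom_lengths = {sid: seq.length for sid, seq in synth.genome.items()}
    len_by_row = pd.Series(chrom_rows).map(chrom_lengths).to_numpy(np.int64)
    pos_in_strand = np.where(strand_rows == "+", pos_arr, len_by_row - 1 - pos_arr)

    prob_path = outdir / "prob_calls.tsv"
    n_prob = _write_tsv(
        prob_path,
        {
            "chrom": lambda lo, hi: chrom_rows[site_of[lo:hi]],
            "pos": lambda lo, hi: pos_arr[site_of[lo:hi]],
            "strand": lambda lo, hi: strand_rows[site_of[lo:hi]],
            "pos_in_strand": lambda lo, hi: pos_in_strand[site_of[lo:hi]],
            "read_name": lambda lo, hi: read_ids[read_of[lo:hi]],
            "read_strand": lambda lo, hi: np.full(hi - lo, "t"),
            "prob_unmethylated": lambda lo, hi: np.round(
                1.0 - prob_m[prob_sel[lo:hi]].astype(np.float64), 4
            ),
            "prob_methylated": lambda lo, hi: prob_m[prob_sel[lo:hi]].astype(np.float64),
            "called_label": lambda lo, hi: emitted[prob_sel[lo:hi]].astype(np.int64),
            "kmer": lambda lo, hi: kmers_by_row[site_of[lo:hi]],
        },
        n=len(prob_sel),
    )
    del prob_sel, site_of, read_of, prob_m, emitted

    read_truth = None
    if keep_read_truth:
        if read_truth_contexts is not None:
            in_ctx = (
                truth["context"].astype(str).isin(read_truth_contexts).to_numpy()
            )
            rt_sel = np.flatnonzero(in_ctx[row_site])
        else:
            rt_sel = np.arange(total_rows)
        read_truth = pd.DataFrame(
            {
                "sequence_id": chrom_rows[row_site[rt_sel]],
                "pos": pos_arr[row_site[rt_sel]],
                "strand": strand_rows[row_site[rt_sel]],
                "read_id": read_ids[row_read[rt_sel]].astype(str),
                "true_label": row_label[rt_sel].astype(np.int8),
            }
        )
    logger.info(
        "simulated %d reads -> %d LLR records, %d probability records",
        n_reads, n_llr, n_prob,
    )
    return SimulatedReads(
        llr_path=llr_path,
        prob_path=prob_path,
        truth=truth,
        read_truth=read_truth,
        n_reads=n_reads,
        n_llr_records=n_llr,
        n_prob_records=n_prob,
        n_expected_pairs=n_expected_pairs,
    )


def simulate_site_frequencies(
    truth: pd.DataFrame,
    coverage_lambda: float = 30.0,
    seed: int = 0,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Site-level shortcut: Poisson coverage and binomial methylated counts
    without materializing per-read files.

    Produces the same SiteFrequency schema the standardization step emits;
    intended for profile-scale studies where the per-read files would run to
    tens of millions of rows.
    """
    if coverage_lambda <= 0:
        raise ValueError("coverage lambda must be > 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(coverage_lambda, size=len(truth))
    k = rng.binomial(n, truth["p"].to_numpy())
    out = truth[["sequence_id", "pos", "strand", "context", "subcontext"]].copy()
    out["n_total"] = n
    out["n_methylated"] = k
    keep = n >= min_coverage
    out = out[keep].reset_index(drop=True)
    out["frequency"] = out["n_methylated"] / out["n_total"]
    return out
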