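"""Pipeline orchestration: simulate/ingest -> context -> standardize ->
consensus -> windows -> features, from a single validated configuration.

Stages communicate only through their declared files, run in dependency
order, and are idempotent: a stage is skipped when its outputs already exist
and are newer than its inputs (unless ``force``). A manifest records every
artifact with a checksum, so the provenance of each output is reconstructible.
Execution is single-process and deterministic under the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import calls as _calls
from . import consensus as _consensus
from . import context as _context
from . import features as _features
from . import io as _io
from . import simulate as _simulate
from . import windows as _windows

logger = logging.getLogger(__name__)

STAGES = ["simulate", "ingest", "context", "standardize", "consensus", "windows", "features"]


class SimulateSection(BaseModel):
    enabled: bool = True
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.35
    genes_per_mb: float = 100.0
    te_per_mb: float = 150.0
    gene_density_profile: str = "arm_biased"
    noise: Literal["default", "noiseless", "overcalling"] = "default"
    coverage_lambda: float = 30.0
    contexts: list[str] | None = None  # restrict read simulation, e.g. ["CG"]


class InputsSection(BaseModel):
    fasta: str
    gff3: str
    rmout: str
    llr: str
    prob: str
    read_truth: str | None = None
    gene_sets: dict[str, str] = Field(default_factory=dict)


class ParamsSection(BaseModel):
    min_coverage: int = 5
    llr_threshold: float = 2.0
    window_size: int = 1_000_000
    window_step: int | None = None
    small_window_size: int = 100_000
    small_window_step: int = 50_000
    gene_flank_bp: int = 5000
    gene_flank_bins: int = 50
    gene_body_bins: int = 60
    region_flank_bp: int = 1000
    te_flank_bp: int = 2000
    te_flank_bins: int = 20
    te_body_bins: int = 40
    te_group_by: str = "superfamily"
    consensus_mode: Literal["model", "rule"] = "model"
    consensus_n_trees: int = 3
    consensus_max_depth: int = 10
    consensus_training_pairs: int = 50_000
    fallback: Literal["single", "drop"] = "single"


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    seed: int = 0
    output_dir: str = "methylprof_out"
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    inputs: InputsSection | None = None
    params: ParamsSection = Field(default_factory=ParamsSection)
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def validate_run(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not self.simulate.enabled and self.inputs is None:
            raise ValueError("either simulate.enabled or explicit inputs are required")


def _derived_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _up_to_date(outputs: list[Path], inputs: list[Path]) -> bool:
    if not outputs or not all(p.exists() for p in outputs):
        return False
    newest_in = max((p.stat().st_mtime for p in inputs if p.exists()), default=0.0)
    return min(p.stat().st_mtime for p in outputs) >= newest_in


def _write_freq(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _read_freq(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "strand": str})


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the output manifest.

    On a stage failure the run aborts with the failing stage named and a
    partial manifest marked incomplete is left in the output directory.
    """
    trace: dict = {"stage": None, "manifest": None}
    try:
        return _execute(config, trace)
    except Exception as exc:
        stage = trace["stage"]
        manifest = trace["manifest"] or {"stages": {}, "files": {}}
        manifest["incomplete"] = True
        manifest["failed_stage"] = stage
        try:
            out = Path(config.output_dir)
            if out.exists():
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        except OSError:  # the partial manifest is best-effort
            pass
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _execute(config: RunConfig, trace: dict) -> dict:
    config.validate_run()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_text = yaml.safe_dump(config.model_dump())
    config_path = out / "config.yaml"
    # rewrite only on change so an unchanged re-run can skip every stage
    if not config_path.exists() or config_path.read_text() != config_text:
        config_path.write_text(config_text)
    params = config.params

    manifest: dict = {"stages": {}, "files": {}}
    trace["manifest"] = manifest
    state: dict = {}

    def record(stage: str, paths: list[Path], elapsed: float, skipped: bool) -> None:
        manifest["stages"][stage] = {
            "elapsed_s": round(elapsed, 3),
            "skipped": skipped,
            "outputs": [str(p.relative_to(out)) for p in paths],
        }
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = {
                "sha256": _sha256(p),
                "bytes": p.stat().st_size,
            }

    # ---- resolve input paths ----
    sim_dir = out / "sim"
    if config.simulate.enabled:
        inputs = InputsSection(
            fasta=str(sim_dir / "genome.fa"),
            gff3=str(sim_dir / "genes.gff3"),
            rmout=str(sim_dir / "repeats.out"),
            llr=str(sim_dir / "llr_calls.tsv"),
            prob=str(sim_dir / "prob_calls.tsv"),
            read_truth=str(sim_dir / "read_truth.tsv"),
            gene_sets={"DE": str(sim_dir / "gene_set_DE.txt")},
        )
    else:
        inputs = config.inputs

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    # ---- simulate ----
    if stage_enabled("simulate") and config.simulate.enabled:
        trace["stage"] = "simulate"
        sim = config.simulate
        outputs = [Path(inputs.fasta), Path(inputs.gff3), Path(inputs.rmout),
                   Path(inputs.llr), Path(inputs.prob), Path(inputs.read_truth),
                   sim_dir / "site_truth.tsv"]
        t0 = time.perf_counter()
        if config.force or not _up_to_date(outputs, [out / "config.yaml"]):
            noise = {
                "default": _simulate.CallerNoise(),
                "noiseless": _simulate.CallerNoise.noiseless(),
                "overcalling": _simulate.CallerNoise.overcalling(),
            }[sim.noise]
            model = _simulate.MethylomeModel(
                coverage_lambda=sim.coverage_lambda, noise=noise
            )
            synth = _simulate.generate_genome(
                _derived_seed(config.seed, 1),
                n_chrom=sim.n_chrom,
                chrom_length=sim.chrom_length,
                gc_fraction=sim.gc_fraction,
                genes_per_mb=sim.genes_per_mb,
                te_per_mb=sim.te_per_mb,
                gene_density_profile=sim.gene_density_profile,
                model=model,
            )
            synth.write(sim_dir)
            truth = _simulate.plant_methylation(
                synth, model, seed=_derived_seed(config.seed, 2)
            )
            reads = _simulate.simulate_reads(
                synth,
                truth,
                model,
                seed=_derived_seed(config.seed, 3),
                outdir=sim_dir,
                contexts=tuple(sim.contexts) if sim.contexts else None,
                read_truth_contexts=("CG",),  # labels are only needed for the
                # CG consensus; full per-read truth at genome scale is huge
            )
            reads.truth.to_csv(
                sim_dir / "site_truth.tsv", sep="\t", index=False, float_format="%.6g"
            )
            reads.read_truth.to_csv(sim_dir / "read_truth.tsv", sep="\t", index=False)
            skipped = False
        else:
            skipped = True
        record("simulate", outputs, time.perf_counter() - t0, skipped)

    # ---- ingest ----
    genome = genes = repeats = None
    if stage_enabled("ingest"):
        trace["stage"] = "ingest"
        t0 = time.perf_counter()
        genome = _io.read_fasta(inputs.fasta)
        genes = _io.read_gff3(inputs.gff3, genome)
        repeats = _io.read_repeatmasker_out(inputs.rmout)
        record("ingest", [], time.perf_counter() - t0, False)
        state.update(genome=genome, genes=genes, repeats=repeats)

    # ---- context ----
    ctx_dir = out / "context"
    sites_path = ctx_dir / "sites.tsv"
    if stage_enabled("context"):
        trace["stage"] = "context"
        ctx_dir.mkdir(exist_ok=True)
        outputs = [sites_path, ctx_dir / "subcontext_counts.tsv"]
        t0 = time.perf_counter()
        if config.force or not _up_to_date(outputs, [Path(inputs.fasta)]):
            index = _context.build_context_index(genome)
            index.to_csv(sites_path, sep="\t", index=False)
            _context.subcontext_table(index).to_csv(
                ctx_dir / "subcontext_counts.tsv", sep="\t", index=False
            )
            state["index"] = index
            skipped = False
        else:
            skipped = True
        record("context", outputs, time.perf_counter() - t0, skipped)

    def get_index() -> pd.DataFrame:
        if "index" not in state:
            state["index"] = pd.read_csv(
                sites_path, sep="\t", dtype={"sequence_id": str, "strand": str}
            )
        return state["index"]

    # ---- standardize ----
    freq_dir = out / "freq"
    tool_tables = {
        "llr": freq_dir / "llr_frequencies.tsv",
        "prob": freq_dir / "prob_frequencies.tsv",
    }
    if stage_enabled("standardize"):
        trace["stage"] = "standardize"
        freq_dir.mkdir(exist_ok=True)
        outputs = list(tool_tables.values()) + [
            freq_dir / "global_levels.tsv",
            freq_dir / "prob.bedmethyl.bed",
        ]
        t0 = time.perf_counter()
        if config.force or not _up_to_date(
            outputs, [Path(inputs.llr), Path(inputs.prob), sites_path]
        ):
            index = get_index()
            llr_calls = _calls.parse_llr_records(inputs.llr, params.llr_threshold)
            llr_freq = _calls.aggregate_site_frequency(
                llr_calls, index, params.min_coverage
            )
            del llr_calls
            _write_freq(llr_freq, tool_tables["llr"])
            prob_freq = _calls.aggregate_prob_file(
                inputs.prob, index, params.min_coverage
            )
            _write_freq(prob_freq, tool_tables["prob"])
            levels = []
            for tool, freq in (("llr", llr_freq), ("prob", prob_freq)):
                lv = _calls.global_levels(freq)
                lv.insert(0, "tool", tool)
                levels.append(lv)
            pd.concat(levels, ignore_index=True).to_csv(
                freq_dir / "global_levels.tsv", sep="\t", index=False, float_format="%.6g"
            )
            _io.write_bedmethyl(prob_freq, freq_dir / "prob.bedmethyl.bed")
            state["prob_freq"] = prob_freq
            skipped = False
        else:
            skipped = True
        record("standardize", outputs, time.perf_counter() - t0, skipped)

    def get_prob_freq() -> pd.DataFrame:
        if "prob_freq" not in state:
            state["prob_freq"] = _read_freq(tool_tables["prob"])
        return state["prob_freq"]

    # ---- consensus (CG only) ----
    cons_dir = out / "consensus"
    cons_path = cons_dir / "consensus_CG_frequencies.tsv"
    if stage_enabled("consensus"):
        trace["stage"] = "consensus"
        cons_dir.mkdir(exist_ok=True)
        outputs = [cons_path]
        t0 = time.perf_counter()
        if config.force or not _up_to_date(
            outputs, [Path(inputs.llr), Path(inputs.prob), sites_path]
        ):
            index = get_index()
            llr_calls = _calls.parse_llr_records(inputs.llr, params.llr_threshold)
            cg_sites = index[index["context"] == "CG"]
            prob_cg = _calls.parse_prob_records(inputs.prob, sites=cg_sites)
            pairs, fallback = _consensus.pair_reads(llr_calls, prob_cg)
            del llr_calls, prob_cg
            model = None
            if params.consensus_mode == "model" and inputs.read_truth:
                labels = pd.read_csv(
                    inputs.read_truth,
                    sep="\t",
                    dtype={"sequence_id": str, "strand": str, "read_id": str},
                )
                labeled = pairs.merge(
                    labels, on=["sequence_id", "pos", "strand", "read_id"], how="inner"
                ).rename(columns={"true_label": "label"})
                rng_n = min(len(labeled), params.consensus_training_pairs)
                training = labeled.sample(
                    n=rng_n, random_state=_derived_seed(config.seed, 4)
                )
                model = _consensus.train_consensus(
                    training,
                    n_trees=params.consensus_n_trees,
                    max_depth=params.consensus_max_depth,
                    seed=_derived_seed(config.seed, 5),
                )
                model.save(cons_dir / "consensus_model.pkl")
            cons_calls = _consensus.consensus_calls(pairs, model)
            cons_freq = _consensus.consensus_site_frequency(
                cons_calls, fallback, index, params.min_coverage, params.fallback
            )
            _write_freq(cons_freq, cons_path)
            state["cons_freq"] = cons_freq
            skipped = False
        else:
            skipped = True
        record("consensus", outputs, time.perf_counter() - t0, skipped)

    def get_downstream_freq() -> pd.DataFrame:
        """Consensus for CG, probability caller for CHG/CHH (the combination
        carried into all profile stages)."""
        if "downstream_freq" not in state:
            cons = state.get("cons_freq")
            if cons is None:
                cons = _read_freq(cons_path) if cons_path.exists() else None
            prob = get_prob_freq()
            if cons is not None and len(cons):
                frames = [cons[cons["context"] == "CG"],
                          prob[prob["context"] != "CG"]]
                state["downstream_freq"] = pd.concat(frames, ignore_index=True)
            else:
                state["downstream_freq"] = prob
        return state["downstream_freq"]

    # ---- windows ----
    win_dir = out / "windows"
    if stage_enabled("windows"):
        trace["stage"] = "windows"
        win_dir.mkdir(exist_ok=True)
        outputs = [
            win_dir / "context_windows.tsv",
            win_dir / "gene_counts.tsv",
            win_dir / "correlation.json",
            win_dir / "chh_subcontext_windows.tsv",
        ]
        t0 = time.perf_counter()
        if config.force or not _up_to_date(outputs, [cons_path, tool_tables["prob"]]):
            freq = get_downstream_freq()
            big = _windows.make_windows(genome, params.window_size, params.window_step)
            small = _windows.make_windows(
                genome, params.small_window_size, params.small_window_step
            )
            stats = _windows.window_mean_frequency(
                freq, big, "context", labels=list(_context.CONTEXTS)
            )
            gene_counts = _windows.count_genes_per_window(genes, big)
            stats = stats.merge(gene_counts, on=["sequence_id", "start", "end"])
            stats.to_csv(
                win_dir / "context_windows.tsv", sep="\t", index=False, float_format="%.6g"
            )
            gene_counts.to_csv(win_dir / "gene_counts.tsv", sep="\t", index=False)
            corr = _windows.gene_methylation_correlation(stats)
            (win_dir / "correlation.json").write_text(json.dumps(corr, indent=2))
            chh = _windows.chh_subcontext_tracks(freq, small)
            chh.to_csv(
                win_dir / "chh_subcontext_windows.tsv",
                sep="\t", index=False, float_format="%.6g",
            )
            for ctx_name, part in stats.groupby("context", observed=True):
                _io.write_bedgraph(part, win_dir / f"{ctx_name}.bedgraph")
            skipped = False
        else:
            skipped = True
        record("windows", outputs, time.perf_counter() - t0, skipped)

    # ---- features ----
    feat_dir = out / "features"
    if stage_enabled("features"):
        trace["stage"] = "features"
        feat_dir.mkdir(exist_ok=True)
        outputs = [
            feat_dir / "metagene.tsv",
            feat_dir / "regions_histogram.tsv",
            feat_dir / "regions_means.tsv",
            feat_dir / "te_profiles.tsv",
            feat_dir / "repeat_coverage.tsv",
            feat_dir / "divergence_landscape.tsv",
        ]
        t0 = time.perf_counter()
        if config.force or not _up_to_date(outputs, [cons_path, tool_tables["prob"]]):
            freq = get_downstream_freq()
            meta = _features.metagene_profile(
                freq, genes,
                flank_bp=params.gene_flank_bp,
                flank_bins=params.gene_flank_bins,
                body_bins=params.gene_body_bins,
            )
            tables = [meta.table.assign(gene_set="all")]
            gene_sets = {}
            for name, path in (inputs.gene_sets or {}).items():
                ids = [
                    line.strip()
                    for line in Path(path).read_text().splitlines()
                    if line.strip()
                ]
                gene_sets[name] = ids
            if gene_sets:
                profiles = _features.gene_set_profiles(
                    freq, genes, gene_sets,
                    metagene_kwargs=dict(
                        flank_bp=params.gene_flank_bp,
                        flank_bins=params.gene_flank_bins,
                        body_bins=params.gene_body_bins,
                    ),
                    region_kwargs=dict(flank_bp=params.region_flank_bp),
                )
                for name in gene_sets:
                    if name in profiles:
                        tables.append(profiles[name]["metagene"].table.assign(gene_set=name))
            pd.concat(tables, ignore_index=True).to_csv(
                feat_dir / "metagene.tsv", sep="\t", index=False, float_format="%.6g"
            )
            regions = _features.region_breakdown(
                freq, genes, flank_bp=params.region_flank_bp
            )
            regions.histogram.to_csv(
                feat_dir / "regions_histogram.tsv", sep="\t", index=False
            )
            regions.means.to_csv(
                feat_dir / "regions_means.tsv", sep="\t", index=False, float_format="%.6g"
            )
            te_profiles = _features.te_metaprofile(
                freq, repeats,
                group_by=params.te_group_by,
                flank_bp=params.te_flank_bp,
                flank_bins=params.te_flank_bins,
                body_bins=params.te_body_bins,
            )
            pd.concat(
                [p.table.assign(group=name) for name, p in te_profiles.items()],
                ignore_index=True,
            ).to_csv(feat_dir / "te_profiles.tsv", sep="\t", index=False, float_format="%.6g")
            _features.repeat_coverage_summary(repeats, genome).to_csv(
                feat_dir / "repeat_coverage.tsv", sep="\t", index=False, float_format="%.6f"
            )
            _features.divergence_landscape(repeats).to_csv(
                feat_dir / "divergence_landscape.tsv", sep="\t", index=False, float_format="%.6g"
            )
            skipped = False
        else:
            skipped = True
        record("features", outputs, time.perf_counter() - t0, skipped)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished; manifest at %s", manifest_path)
    return manifest
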