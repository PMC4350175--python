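"""End-to-end orchestration: config parsing, staged execution, manifest.

One structured config (YAML or JSON) drives the whole pipeline:
simulate -> sequence -> (optional FASTQ fixture preprocessing) -> call ->
trajectories -> sweeps.  Every stage writes standard text formats (TSV,
VCF, FASTQ) into the output directory, and a JSON manifest -- config
snapshot, root seed, per-stage derived seeds, file checksums, timings --
is written last.  Re-running with the same config and seed reproduces the
tabular outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess, seqsim, sweepscan, trajdyn, varcall
from .popsim import GeneModel, SimConfig, TruthTable, run_simulation
from .preprocess import TrimPolicy
from .seqsim import QualityProfile, SeqConfig
from .varcall import CallPolicy

logger = logging.getLogger("chemosweep.pipeline")

STAGES = ("simulate", "sequence", "fixtures", "call", "traj", "sweeps")


class ConfigError(ValueError):
    """Raised with the full list of config violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  " + "\n  ".join(errors))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class SweepParams:
    eps: float = 0.05
    min_peak: float = 0.05
    hard_hi: float = 0.90
    soft_min: float = 0.10
    origin_max: float = 0.01


@dataclass
class FixtureParams:
    """Optional FASTQ fixture stage (exercises preprocessing end to end)."""

    enabled: bool = False
    n_fragments: int = 200
    dup_fraction: float = 0.1


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    seq: SeqConfig = field(default_factory=SeqConfig)
    trim: TrimPolicy = field(default_factory=TrimPolicy)
    call: CallPolicy = field(default_factory=CallPolicy)
    sweep: SweepParams = field(default_factory=SweepParams)
    fixtures: FixtureParams = field(default_factory=FixtureParams)
    seed: int = 0

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["genes"] = [dataclasses.asdict(g) for g in self.sim.genes]
        d["sim"]["class_fractions"] = dict(self.sim.class_fractions)
        return d


def validate_config(raw) -> PipelineConfig:
    """Build a PipelineConfig from YAML/JSON text, a path, or a dict.

    Every constraint is checked and all violations are reported at once in
    a single ConfigError.
    """
    if isinstance(raw, Path) or (
        isinstance(raw, str) and raw.strip() and "\n" not in raw and Path(raw).is_file()
    ):
        raw = Path(str(raw)).read_text()
    if isinstance(raw, str):
        try:
            raw = yaml.safe_load(raw) or {}
        except yaml.YAMLError as exc:
            raise ConfigError([f"unparseable config: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])

    errors: list[str] = []
    unknown = set(raw) - {"sim", "seq", "trim", "call", "sweep", "fixtures", "seed"}
    for key in sorted(unknown):
        errors.append(f"{key}: unknown section")

    def build(section: str, factory, transform=None):
        sub = dict(raw.get(section, {}) or {})
        if transform:
            sub = transform(sub, errors)
        try:
            known = {f.name for f in dataclasses.fields(factory)}
            bad = set(sub) - known
            for k in sorted(bad):
                errors.append(f"{section}.{k}: unknown field")
            return factory(**{k: v for k, v in sub.items() if k in known})
        except (TypeError, ValueError) as exc:
            errors.append(f"{section}: {exc}")
            return factory()

    def sim_transform(sub: dict, errs: list[str]) -> dict:
        if "genes" in sub and sub["genes"] is not None:
            try:
                sub["genes"] = tuple(GeneModel(**g) for g in sub["genes"])
            except (TypeError, ValueError) as exc:
                errs.append(f"sim.genes: {exc}")
                del sub["genes"]
        for key in ("sample_days", "epistasis_genes"):
            if key in sub and sub[key] is not None:
                sub[key] = tuple(sub[key])
        return sub

    sim = build("sim", SimConfig, sim_transform)
    seq = build("seq", SeqConfig)
    trim = build("trim", TrimPolicy)
    call = build("call", CallPolicy)
    sweep = build("sweep", SweepParams)
    fixtures = build("fixtures", FixtureParams)
    errors.extend(f"sim.{e}" for e in sim.validate())
    errors.extend(f"seq.{e}" for e in seq.validate())
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"seed: must be a non-negative integer, got {seed!r}")
        seed = 0
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(sim=sim, seq=seq, trim=trim, call=call,
                          sweep=sweep, fixtures=fixtures, seed=seed)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_seeds(root_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the root seed."""
    children = np.random.SeedSequence(root_seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for stage, child in zip(STAGES, children)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_simulate(cfg: PipelineConfig, outdir: Path, seed: int) -> TruthTable:
    sim_cfg = dataclasses.replace(cfg.sim, seed=seed)
    truth = run_simulation(sim_cfg)
    truth.to_tsv(outdir / "truth.tsv", outdir / "linkage.tsv")
    return truth


def run_sequence(cfg: PipelineConfig, outdir: Path, truth: TruthTable, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    counts = seqsim.sequence_truth(truth, cfg.seq, rng)
    seqsim.write_site_counts(counts, outdir / "site_counts.tsv")
    return counts


def run_fixtures(cfg: PipelineConfig, outdir: Path, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    batch = seqsim.make_read_pairs(
        cfg.fixtures.n_fragments, cfg.fixtures.dup_fraction, cfg.seq,
        QualityProfile(), rng,
    )
    seqsim.write_fastq(batch, outdir / "reads_1.fastq", outdir / "reads_2.fastq")
    return preprocess.process_fastq(
        outdir / "reads_1.fastq", outdir / "reads_2.fastq",
        outdir / "clean_1.fastq", outdir / "clean_2.fastq", cfg.trim,
    )


def run_call(cfg: PipelineConfig, outdir: Path, counts: pd.DataFrame,
             truth_meta: pd.DataFrame) -> pd.DataFrame:
    calls = varcall.call_table(counts, cfg.call)
    varcall.write_calls_tsv(calls, outdir / "calls.tsv")
    varcall.write_vcf(
        calls, truth_meta, outdir / "calls.vcf",
        contig="sim", contig_length=cfg.sim.genome_length,
    )
    return calls


def run_traj(cfg: PipelineConfig, outdir: Path, calls: pd.DataFrame,
             truth: TruthTable) -> trajdyn.TrajectoryTable:
    table = trajdyn.build_table(calls, truth.mutations, truth.sample_days)
    table.to_tsv(outdir / "trajectories.tsv")
    trajdyn.occurrence_spectrum(table).to_csv(outdir / "occurrence_spectrum.tsv", sep="\t")
    trajdyn.load_series(table).to_csv(outdir / "load.tsv", sep="\t")
    trajdyn.gene_summary(table).to_csv(outdir / "gene_summary.tsv", sep="\t", index=False)
    return table


def run_sweeps(cfg: PipelineConfig, outdir: Path, table: trajdyn.TrajectoryTable) -> dict:
    cohorts = sweepscan.detect_cohorts(table, eps=cfg.sweep.eps, min_peak=cfg.sweep.min_peak)
    sweepscan.cohorts_to_frame(cohorts).to_csv(outdir / "cohorts.tsv", sep="\t", index=False)
    calls = sweepscan.classify_sweeps(
        table, hard_hi=cfg.sweep.hard_hi, soft_min=cfg.sweep.soft_min,
        origin_max=cfg.sweep.origin_max,
    )
    sweepscan.sweeps_to_frame(calls).to_csv(outdir / "sweep_calls.tsv", sep="\t", index=False)
    hitch = sweepscan.detect_hitchhikers(cohorts, table.meta["role"])
    pd.DataFrame(
        [dataclasses.asdict(h) for h in hitch],
        columns=["mutation_id", "cohort_index", "driver_genes"],
    ).to_csv(outdir / "hitchhikers.tsv", sep="\t", index=False)
    return {"n_cohorts": len(cohorts), "n_hitchhikers": len(hitch),
            "verdicts": {c.gene: c.verdict for c in calls}}


def run_pipeline(cfg: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed = cfg.seed if seed is None else seed
    seeds = stage_seeds(root_seed)
    manifest: dict = {
        "config": cfg.snapshot(),
        "root_seed": root_seed,
        "stage_seeds": seeds,
        "timings_s": {},
        "summaries": {},
        "completed_stages": [],
    }

    def timed(stage: str, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:
            manifest["failed_stage"] = stage
            _write_manifest(manifest, outdir)
            raise PipelineError(stage, exc) from exc
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        manifest["completed_stages"].append(stage)
        logger.info("[%s] done in %.2fs", stage, manifest["timings_s"][stage])
        return result

    truth = timed("simulate", run_simulate, cfg, outdir, seeds["simulate"])
    counts = timed("sequence", run_sequence, cfg, outdir, truth, seeds["sequence"])
    if cfg.fixtures.enabled:
        manifest["summaries"]["preprocess"] = timed(
            "fixtures", run_fixtures, cfg, outdir, seeds["fixtures"]
        )
    calls = timed("call", run_call, cfg, outdir, counts, truth.mutations)
    table = timed("traj", run_traj, cfg, outdir, calls, truth)
    manifest["summaries"]["sweeps"] = timed("sweeps", run_sweeps, cfg, outdir, table)
    manifest["summaries"]["n_truth_mutations"] = int(len(truth.freqs))
    manifest["summaries"]["n_detected_mutations"] = int((table.freqs > 0).any(axis=1).sum())

    manifest["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.suffix in (".tsv", ".vcf", ".fastq")
    }
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
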