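"""End-to-end pipeline: simulate -> popgen -> scan -> date.

Each stage is independently runnable; ``run_pipeline`` executes the
selected stages in order on a shared scenario and seed, writes every
stage product to the output directory, and emits a JSON + Markdown
report with provenance (config hash, seed, package version).  Identical
config and seed reproduce every numeric output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment import AlignmentScoring, global_align
from .fixtures import five_system_counts, load_table1, table1_population_specs
from .genotypes import assignment_accuracy, fst_pair, summarize_frequencies
from .hky import HkyModel, hky_distance
from .io import (
    write_event_log,
    write_fasta,
    write_genotype_table,
    write_track_csv,
    write_variants_csv,
    write_vcf,
    write_wig,
)
from .mcmc import CalibrationPrior, ChainConfig, point_clock_estimate, run_mcmc
from .simulate import SimScenario, simulate_allele_divergence, simulate_genotype_table
from .variants import call_variants, percent_divergence, window_similarity

logger = logging.getLogger("nerkasweep")

STAGES = ("simulate", "popgen", "scan", "date")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    out_dir: str = "nerkasweep_out"
    scenario: SimScenario = field(default_factory=SimScenario)
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    window: int = 500
    fst_estimator: str = "nei_gst"
    calibration: CalibrationPrior = field(default_factory=CalibrationPrior)
    chain: ChainConfig = field(default_factory=ChainConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage name(s): {sorted(unknown)}")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        for key, typ in (
            ("scenario", SimScenario),
            ("scoring", AlignmentScoring),
            ("calibration", CalibrationPrior),
            ("chain", ChainConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                block = dict(kwargs[key])
                if key == "scenario" and "base_freqs" in block:
                    block["base_freqs"] = tuple(block["base_freqs"])
                if key == "chain" and "rate_bounds" in block:
                    block["rate_bounds"] = tuple(block["rate_bounds"])
                kwargs[key] = typ(**block)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def content_hash(self) -> str:
        """Hash of the analytic configuration (paths and logging excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        canon = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_simulate(cfg: PipelineConfig, out: Path, report: dict) -> dict:
    seqs, log = simulate_allele_divergence(cfg.scenario, seed=cfg.seed)
    write_fasta(seqs, out / "haplotypes.fasta")
    write_event_log(log, out / "true_events.tsv")
    table = simulate_genotype_table(table1_population_specs(), seed=cfg.seed)
    write_genotype_table(table, out / "genotypes.csv")
    report["simulate"] = {
        "seq_length": cfg.scenario.seq_length,
        "n_true_substitutions": int((log["event"] == "substitution").sum()),
        "n_true_deletions": int((log["event"] == "deletion").sum()),
        "n_individuals": int(len(table)),
    }
    return {"seqs": seqs, "log": log, "table": table}


def _stage_popgen(cfg: PipelineConfig, out: Path, report: dict, state: dict) -> None:
    table = state.get("table")
    if table is None:
        table = simulate_genotype_table(table1_population_specs(), seed=cfg.seed)
    fixture = load_table1()
    shore_n, stream_n = five_system_counts(fixture)
    freqs = {f.population: f for f in summarize_frequencies(table)}
    from .fixtures import FIVE_SYSTEM_SHORE, FIVE_SYSTEM_STREAM

    systems = list(FIVE_SYSTEM_SHORE) + list(FIVE_SYSTEM_STREAM)
    acc = assignment_accuracy(table, systems)
    fst = fst_pair(freqs["Okanagan Lake"], freqs["Mission Creek"], cfg.fst_estimator)
    freq_rows = [
        {"population": f.population, "n": f.n, "p_G": f.p_g, "n_GG": f.n_gg,
         "n_GT": f.n_gt, "n_TT": f.n_tt}
        for f in freqs.values()
    ]
    import pandas as pd

    pd.DataFrame(freq_rows).to_csv(out / "allele_frequencies.csv", index=False)
    acc.per_population.to_csv(out / "assignment_by_population.csv", index=False)
    report["popgen"] = {
        "five_system_shore_n": shore_n,
        "five_system_stream_n": stream_n,
        "assignment_accuracy_pct": acc.accuracy_pct,
        "gg_in_stream": acc.gg_in_stream,
        "gt_in_shore": acc.gt_in_shore,
        "tt_in_shore": acc.tt_in_shore,
        "fst_okanagan_pair": {"estimator": fst.estimator, "value": fst.value},
    }
    state["freqs"] = freqs


def _stage_scan(cfg: PipelineConfig, out: Path, report: dict, state: dict) -> None:
    seqs = state.get("seqs")
    if seqs is None:
        seqs, log = simulate_allele_divergence(cfg.scenario, seed=cfg.seed)
        state["seqs"] = seqs
    aln = global_align(seqs["shore"], seqs["stream"], cfg.scoring)
    variants = call_variants(aln)
    divergence = percent_divergence(aln)
    track = window_similarity(aln, cfg.window)
    write_vcf(variants, "shore_allele", seqs["shore"], out / "variants.vcf")
    write_variants_csv(variants, out / "variants.csv")
    write_wig(track, "alignment", out / "similarity.wig")
    write_track_csv(track, out / "similarity.csv")
    report["scan"] = {
        "alignment_columns": aln.n_columns,
        "alignment_score": aln.score,
        "percent_divergence": divergence,
        "n_snps": variants.n_snps,
        "n_indel_events": variants.n_indels,
        "n_fixed_total": variants.n_snps + variants.n_indels,
        "max_indel_length": max((i.length for i in variants.indels), default=0),
        "min_window_similarity": float(track.values.min()),
    }
    state["aln"] = aln


def _stage_date(cfg: PipelineConfig, out: Path, report: dict, state: dict) -> None:
    seqs = state.get("seqs")
    if seqs is None:
        seqs, _ = simulate_allele_divergence(cfg.scenario, seed=cfg.seed)
        state["seqs"] = seqs
    model = cfg.scenario.model
    # gap-free 3-way frame: the generator's deletions are lineage-specific, so
    # the dating alignment is built from ungapped columns via the event-free route
    a, b, o = _common_frame(seqs)
    posterior = run_mcmc(a, b, o, model=model, calibration=cfg.calibration,
                         config=cfg.chain, seed=cfg.seed)
    d_pair = hky_distance(a, b, model)
    d_out = 0.5 * (hky_distance(a, o, model) + hky_distance(b, o, model))
    point = point_clock_estimate(d_pair, d_out, cfg.calibration.mean)
    samples_path = out / "posterior_samples.csv"
    import pandas as pd

    pd.DataFrame(posterior.samples).to_csv(samples_path, index=False)
    summary = posterior.summary()
    summary["point_clock_estimate"] = point
    (out / "dating_summary.json").write_text(json.dumps(summary, indent=2))
    report["date"] = {
        "tmrca_mean": posterior.mean["t_split"],
        "tmrca_median": posterior.median["t_split"],
        "tmrca_hpd95": list(posterior.hpd95["t_split"]),
        "calibration_mean": posterior.mean["t_cal"],
        "point_clock_estimate": point,
        "acceptance_rate": posterior.acceptance_rate,
    }


def _common_frame(seqs: dict[str, str]) -> tuple[str, str, str]:
    """Project the three sequences onto shared ungapped columns.

    Aligns stream and outgroup to the shore allele and keeps columns where
    all three carry a base.  With the generator's deletion-only indels this
    recovers homologous columns well; substitution-only dating then uses
    those columns.
    """
    aln_ab = global_align(seqs["shore"], seqs["stream"])
    aln_ao = global_align(seqs["shore"], seqs["outgroup"])

    def ref_map(aln):
        m = {}
        pos = 0
        for ca, cb in zip(aln.a_gapped, aln.b_gapped):
            if ca != "-":
                pos += 1
                if cb != "-":
                    m[pos] = cb
        return m

    map_b = ref_map(aln_ab)
    map_o = ref_map(aln_ao)
    a_out, b_out, o_out = [], [], []
    for pos in range(1, len(seqs["shore"]) + 1):
        if pos in map_b and pos in map_o:
            a_out.append(seqs["shore"][pos - 1])
            b_out.append(map_b[pos])
            o_out.append(map_o[pos])
    return "".join(a_out), "".join(b_out), "".join(o_out)


_STAGE_FUNCS = {
    "popgen": _stage_popgen,
    "scan": _stage_scan,
    "date": _stage_date,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the selected stages; returns the report dict (also written
    as report.json and report.md under config.out_dir)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package": "nerkasweep",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.content_hash(),
            "stages": list(config.stages),
        }
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            if stage == "simulate":
                state.update(_stage_simulate(config, out, report))
            else:
                _STAGE_FUNCS[stage](config, out, report, state)
        except Exception as exc:  # partial outputs are retained on disk
            _write_report(report, out)
            raise StageError(stage, exc) from exc
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    lines = ["# nerkasweep pipeline report", ""]
    for section, content in report.items():
        lines.append(f"## {section}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(content, indent=2, default=float))
        lines.append("```")
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))
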