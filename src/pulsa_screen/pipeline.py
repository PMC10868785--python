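"""Config-driven orchestration of the synthetic screen.

Stages mirror the bench workflow: ``simulate`` (library → planted effects →
cell population → pulses → sort gates → sorted-pool tallies, optionally
sequenced into FASTQ), ``count`` (reads or tallies → sgRNA count matrix),
``score`` (count matrix → gene results), and ``run`` (all of the above plus
an evaluation of called hits against the planted truth).

All randomness derives from the single top-level seed: each stage draws from
``default_rng([seed, crc32(stage_name)])``, so stages can be re-run
independently and reproducibly. Identical config + seed gives byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from pulsa_screen.counting import (
    AmpliconDesign,
    CountMatrix,
    count_spacers,
    read_counts_tsv,
    synthesize_reads,
    write_counts_tsv,
    write_fastq,
)
from pulsa_screen.pulsa import (
    OpticalModel,
    acquire_population,
    apply_gates,
    calibrate_pulsa_gates,
    gate_expression,
    normal_diameters,
)
from pulsa_screen.screen_model import (
    GuideLibrary,
    ScreenTruth,
    assign_effects,
    beta_efficacies,
    constant,
    generate_library,
    simulate_population,
    uniform_magnitudes,
)
from pulsa_screen.scoring import ScoringConfig, score_screen


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator derived from the run seed and the stage name."""
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode()) & 0x7FFFFFFF])


def _strict(cls, data: Mapping[str, Any] | None, where: str):
    data = dict(data or {})
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown keys in config section {where!r}: {unknown}")
    return cls(**data)


@dataclass(frozen=True)
class ScreenSection:
    """Library, planted effects, and population of the simulated screen."""

    n_genes: int = 2000
    guides_per_gene: int = 4
    n_ntc: int = 1000
    spacer_length: int = 20
    n_up: int = 0
    n_down: int = 0
    effect_low: float = 2.0
    effect_high: float = 4.0
    down_effect_low: float | None = None
    down_effect_high: float | None = None
    efficacy_a: float = 8.0
    efficacy_b: float = 2.0
    efficacy_constant: float | None = None
    base_logit: float = -2.2
    cells_per_guide: int = 1000
    guide_abundance_spread: float = 0.3
    expression_spread: float = 0.5
    mean_fluorescence: float = 1000.0

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.guides_per_gene + self.n_ntc

    @property
    def n_cells(self) -> int:
        return self.cells_per_guide * self.n_guides


@dataclass(frozen=True)
class OpticsSection:
    beam_sigma: float = 2.0
    cell_sigma_factor: float = 0.25
    punctum_sigma: float = 0.5
    cell_diameter_mean: float = 15.0
    cell_diameter_sd: float = 1.5
    scan_speed: float = 1.0
    trigger_threshold: float = 2.0
    noise_sd: float = 0.5

    def model(self) -> OpticalModel:
        return OpticalModel(
            beam_sigma=self.beam_sigma,
            cell_sigma_factor=self.cell_sigma_factor,
            punctum_sigma=self.punctum_sigma,
            cell_diameter_sampler=normal_diameters(self.cell_diameter_mean, self.cell_diameter_sd),
            scan_speed=self.scan_speed,
            trigger_threshold=self.trigger_threshold,
            noise_sd=self.noise_sd,
        )


@dataclass(frozen=True)
class GatesSection:
    q_lo: float = 0.1
    q_hi: float = 0.9
    target_fraction: float = 0.05


@dataclass(frozen=True)
class SequencingSection:
    reads_per_guide: int = 100
    error_rate: float = 0.001
    mode: str = "tally"  # "tally": multinomial counts straight from sorted tallies; "reads": full FASTQ round trip
    read_length: int | None = None
    n_replicates: int = 2
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tally", "reads"):
            raise ValueError("sequencing mode must be 'tally' or 'reads'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full synthetic screen run."""

    screen: ScreenSection = field(default_factory=ScreenSection)
    optics: OpticsSection = field(default_factory=OpticsSection)
    gates: GatesSection = field(default_factory=GatesSection)
    sequencing: SequencingSection = field(default_factory=SequencingSection)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    outdir: str = "pulsa_run"
    seed: int = 0

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        known = {"screen", "optics", "gates", "sequencing", "scoring", "outdir", "seed"}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown top-level config keys: {unknown}")
        return cls(
            screen=_strict(ScreenSection, data.get("screen"), "screen"),
            optics=_strict(OpticsSection, data.get("optics"), "optics"),
            gates=_strict(GatesSection, data.get("gates"), "gates"),
            sequencing=_strict(SequencingSection, data.get("sequencing"), "sequencing"),
            scoring=_strict(ScoringConfig, data.get("scoring"), "scoring"),
            outdir=str(data.get("outdir", "pulsa_run")),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = self.to_dict()
        payload.pop("outdir", None)
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sample_names(n_replicates: int) -> list[str]:
    names = []
    for r in range(1, n_replicates + 1):
        names += [f"agg_r{r}", f"dif_r{r}"]
    return names


def _sorted_pool_tallies(config: RunConfig):
    """Simulate through sorting; returns (library, truth, per-sample tallies, gate info)."""
    sc = config.screen
    library = generate_library(
        sc.n_genes, sc.guides_per_gene, sc.n_ntc, sc.spacer_length,
        seed=int(stage_rng(config.seed, "library").integers(2**31)),
    )
    efficacy = (
        constant(sc.efficacy_constant) if sc.efficacy_constant is not None else beta_efficacies(sc.efficacy_a, sc.efficacy_b)
    )
    down_sampler = None
    if sc.down_effect_low is not None:
        down_sampler = uniform_magnitudes(
            sc.down_effect_low, sc.down_effect_high or sc.down_effect_low
        )
    truth = assign_effects(
        library,
        sc.n_up,
        sc.n_down,
        magnitude_sampler=uniform_magnitudes(sc.effect_low, sc.effect_high),
        efficacy_sampler=efficacy,
        base_logit=sc.base_logit,
        seed=int(stage_rng(config.seed, "effects").integers(2**31)),
        down_magnitude_sampler=down_sampler,
    )
    population = simulate_population(
        truth,
        sc.n_cells,
        guide_abundance_spread=sc.guide_abundance_spread,
        expression_spread=sc.expression_spread,
        mean_fluorescence=sc.mean_fluorescence,
        seed=int(stage_rng(config.seed, "population").integers(2**31)),
    )
    pulses = acquire_population(
        population, config.optics.model(), seed=int(stage_rng(config.seed, "pulses").integers(2**31))
    )
    gated = gate_expression(pulses, config.gates.q_lo, config.gates.q_hi)
    gates = calibrate_pulsa_gates(
        gated, config.gates.target_fraction, config.gates.q_lo, config.gates.q_hi
    )
    agg_pool, dif_pool = apply_gates(gated, gates)

    # split each sorted pool into technical replicates, as the bench protocol
    # divided each collected pool before gDNA extraction
    rng = stage_rng(config.seed, "replicate_split")
    n_rep = config.sequencing.n_replicates
    tallies: dict[str, pd.Series] = {}
    for pool_name, pool in (("agg", agg_pool), ("dif", dif_pool)):
        assignment = rng.integers(0, n_rep, size=len(pool))
        idx = pool["guide_idx"].to_numpy()
        for r in range(n_rep):
            t = np.bincount(idx[assignment == r], minlength=len(library))
            tallies[f"{pool_name}_r{r + 1}"] = pd.Series(
                t, index=pd.Index(library.guide_ids, name="guide_id")
            )
    info = {
        "n_cells": int(sc.n_cells),
        "n_gated": int(len(gated)),
        "n_aggregate_pool": int(len(agg_pool)),
        "n_diffuse_pool": int(len(dif_pool)),
        "aggregate_gate_purity": float(pool_purity(agg_pool)),
        "true_aggregated_fraction": float(population["aggregated"].mean()),
    }
    return library, truth, tallies, info


def pool_purity(pool: pd.DataFrame) -> float:
    """Fraction of truly aggregated cells in a sorted pool (NaN if empty)."""
    return float(pool["truth_aggregated"].mean()) if len(pool) else float("nan")


def run_simulate(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Simulate the screen through sorting and write all stage artifacts.

    Writes ``library.csv``, ``truth.tsv``, ``manifest.json`` and, per sorted
    sample, either FASTQ reads (sequencing mode ``reads``) or sorted-cell
    tallies (``tallies.tsv``, mode ``tally``).
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    library, truth, tallies, info = _sorted_pool_tallies(config)
    library.to_csv(out / "library.csv")
    truth.to_tsv(out / "truth.tsv")

    seq = config.sequencing
    sample_files: dict[str, str] = {}
    tally_df = pd.DataFrame(tallies)
    tally_df.to_csv(out / "tallies.tsv", sep="\t")
    if seq.mode == "reads":
        design = AmpliconDesign()
        depth = seq.reads_per_guide * len(library)
        for name in _sample_names(seq.n_replicates):
            reads = synthesize_reads(
                tallies[name],
                library,
                design,
                depth=depth,
                error_rate=seq.error_rate,
                seed=int(stage_rng(config.seed, f"sequencing:{name}").integers(2**31)),
                read_length=seq.read_length,
            )
            path = out / f"{name}.fastq"
            write_fastq(reads, path)
            sample_files[name] = str(path)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_info": info,
        "samples": _sample_names(seq.n_replicates),
        "sequencing_mode": seq.mode,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"outdir": str(out), "library": library, "truth": truth, "tallies": tallies,
            "sample_files": sample_files, "info": info}


def run_count(
    config: RunConfig,
    outdir: str | Path | None = None,
    library: GuideLibrary | None = None,
    fastq_files: Mapping[str, str | Path] | None = None,
    tallies: Mapping[str, pd.Series] | None = None,
) -> CountMatrix:
    """Build the sgRNA count matrix from FASTQ files or sorted-cell tallies.

    In ``tally`` mode sequencing is modeled as a multinomial draw of
    ``reads_per_guide x n_guides`` error-free reads per sample directly from
    the tallies; in ``reads`` mode FASTQ files go through spacer extraction
    and matching. Writes ``counts.tsv`` and ``counts_qc.json``.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if library is None:
        library = GuideLibrary.from_csv(out / "library.csv")
    seq = config.sequencing
    design = AmpliconDesign()
    columns: dict[str, pd.Series] = {}
    qc: dict[str, dict[str, int]] = {}
    if seq.mode == "reads":
        if fastq_files is None:
            fastq_files = {name: out / f"{name}.fastq" for name in _sample_names(seq.n_replicates)}
        for name, path in fastq_files.items():
            col, sample_qc = count_spacers(path, library, design, max_mismatch=seq.max_mismatch)
            columns[name] = col
            qc[name] = sample_qc
    else:
        if tallies is None:
            tdf = pd.read_csv(out / "tallies.tsv", sep="\t", index_col="guide_id")
            tallies = {c: tdf[c] for c in tdf.columns}
        depth = seq.reads_per_guide * len(library)
        for name in _sample_names(seq.n_replicates):
            t = tallies[name].to_numpy(dtype=float)
            if t.sum() <= 0:
                raise ValueError(f"sample {name} has an empty sorted pool; cannot sequence")
            rng = stage_rng(config.seed, f"sequencing:{name}")
            draw = rng.multinomial(depth, t / t.sum())
            columns[name] = pd.Series(draw, index=tallies[name].index)
            qc[name] = {
                "n_reads": depth, "n_assigned": depth,
                "n_flank_fail": 0, "n_no_match": 0, "n_ambiguous": 0,
            }
    matrix = CountMatrix(pd.DataFrame(columns), qc=qc)
    write_counts_tsv(matrix, out / "counts.tsv")
    (out / "counts_qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True) + "\n")
    return matrix


def run_score(
    config: RunConfig,
    counts: CountMatrix | str | Path | None = None,
    library: GuideLibrary | str | Path | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Score a count matrix and write the report tables.

    Writes ``gene_results.tsv`` (stable order: p, then |phenotype|
    descending, then gene), ``guide_stats.tsv``, ``ntc_pseudogenes.tsv`` and
    ``volcano.tsv`` (gene, phenotype, -log10 p).
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if counts is None:
        counts = out / "counts.tsv"
    if isinstance(counts, (str, Path)):
        counts = read_counts_tsv(counts)
    if library is None:
        library = out / "library.csv"
    if isinstance(library, (str, Path)):
        library = GuideLibrary.from_csv(library)

    names = _sample_names(config.sequencing.n_replicates)
    pairs = [(names[i], names[i + 1]) for i in range(0, len(names), 2)]
    pairs = [p for p in pairs if p[0] in counts.counts.columns]
    gene_results, guide_stats, ntc_results = score_screen(
        counts, library, config.scoring, sample_pairs=pairs or None
    )
    fmt = "%.10g"
    gene_results.to_csv(out / "gene_results.tsv", sep="\t", index=False, float_format=fmt)
    guide_stats.to_csv(out / "guide_stats.tsv", sep="\t", index=False, float_format=fmt)
    if ntc_results is not None:
        ntc_results.to_csv(out / "ntc_pseudogenes.tsv", sep="\t", index=False, float_format=fmt)
    volcano = gene_results[["gene", "phenotype"]].copy()
    volcano["neg_log10_p"] = -np.log10(gene_results["p_value"])
    volcano.to_csv(out / "volcano.tsv", sep="\t", index=False, float_format=fmt)
    return {"gene_results": gene_results, "guide_stats": guide_stats, "ntc_results": ntc_results}


def evaluate_against_truth(
    gene_results: pd.DataFrame, truth: ScreenTruth, ntc_results: pd.DataFrame | None = None
) -> dict:
    """Compare called hits with the planted truth.

    Reports per-planted-gene rank (1-based position in the stable report
    order), recovery sensitivity, false-positive rate among null genes, NTC
    pseudo-gene hits, and the AUROC of the report ranking against truth.
    """
    planted = {g: e for g, e in truth.gene_effect.items() if e != 0.0}
    res = gene_results.reset_index(drop=True)
    rank = {g: i + 1 for i, g in enumerate(res["gene"])}
    per_gene = []
    for g, eff in sorted(planted.items()):
        row = res.loc[res["gene"] == g]
        if len(row) == 0:
            continue
        row = row.iloc[0]
        per_gene.append(
            {
                "gene": g,
                "effect_logit": eff,
                "rank": rank[g],
                "p_value": float(row["p_value"]),
                "phenotype": float(row["phenotype"]),
                "is_hit": bool(row["is_hit"]),
                "direction_correct": bool(np.sign(row["phenotype"]) == np.sign(eff)),
            }
        )
    n_planted = len(per_gene)
    recovered = sum(1 for r in per_gene if r["is_hit"] and r["direction_correct"])
    null_genes = res.loc[~res["gene"].isin(planted)]
    is_planted = res["gene"].isin(planted).to_numpy()
    auroc = _ranking_auroc(is_planted)
    return {
        "n_planted": n_planted,
        "n_recovered": recovered,
        "sensitivity": recovered / n_planted if n_planted else float("nan"),
        "null_hits": int(null_genes["is_hit"].sum()),
        "null_fraction_significant": float(
            (null_genes["p_value"] < 0.005).mean() if len(null_genes) else float("nan")
        ),
        "specificity": float(1.0 - null_genes["is_hit"].mean()) if len(null_genes) else float("nan"),
        "auroc": auroc,
        "ntc_pseudo_hits": int(ntc_results["is_hit"].sum()) if ntc_results is not None else None,
        "planted": per_gene,
    }


def _ranking_auroc(is_positive_in_rank_order: np.ndarray) -> float:
    """AUROC of a binary truth vector already sorted best-first."""
    y = np.asarray(is_positive_in_rank_order, dtype=bool)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    # count of (positive, negative) pairs ranked correctly
    neg_seen = np.cumsum(~y)
    correct = (n_neg - neg_seen[y]).sum()
    return float(correct / (n_pos * n_neg))


def run_end_to_end(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """simulate → count → score → evaluate; writes ``evaluation.json``."""
    out = Path(outdir or config.outdir)
    sim = run_simulate(config, out)
    counts = run_count(config, out, library=sim["library"],
                       tallies=sim["tallies"] if config.sequencing.mode == "tally" else None)
    scored = run_score(config, counts=counts, library=sim["library"], outdir=out)
    evaluation = evaluate_against_truth(
        scored["gene_results"], sim["truth"], scored["ntc_results"]
    )
    evaluation["stage_info"] = sim["info"]
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2, sort_keys=True) + "\n")
    return {**sim, **scored, "evaluation": evaluation, "counts": counts}
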