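"""End-to-end orchestration: config -> collapse -> diversity -> neutrality
-> AMOVA -> TFBS scan -> enrichment -> report files.

A run takes either input paths (aligned FASTA + population map TSV, plus an
optional motif library TSV) or a simulation config; a single root seed
deterministically derives per-stage seeds, so reruns are byte-identical and
stages can be reproduced standalone.  Failure of the motif stage is
isolated: population-genetic tables are still produced and the error is
recorded in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (
    AlignmentSet,
    HaplotypeTable,
    PopulationMap,
    call_polymorphic_sites,
    classify_rare_sites,
    collapse_haplotypes,
    consensus_sequence,
    diff_from_consensus,
    read_alignment,
    read_population_map,
)
from .amova import AmovaResult, DistanceSpec, amova, amova_permutation_test
from .diversity import diversity_summary
from .errors import InvalidArgument
from .motifs import (
    MotifLibrary,
    classify_conservation,
    aggregate_categories,
    hits_to_frame,
    load_motif_library,
    permutation_enrichment,
    scan_motifs,
)
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger("promopop")


@dataclass(frozen=True)
class RunConfig:
    alignment: str | None = None
    population_map: str | None = None
    motif_library: str | None = None
    simulation: SimulationConfig | None = None
    gap_mode: str = "complete"
    distance_mode: str = "identity"
    strands: str = "forward"
    shuffle_mode: str = "mono"
    neutrality_reps: int = 1000
    amova_reps: int = 999
    enrichment_reps: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_paths = self.alignment is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise InvalidArgument(
                "exactly one of input paths or a simulation config is required"
            )
        if has_paths and self.population_map is None:
            raise InvalidArgument("alignment input requires a population map")
        for reps in (self.neutrality_reps, self.amova_reps, self.enrichment_reps):
            if reps < 100:
                raise InvalidArgument("all reps must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunReport:
    haplotype_table: HaplotypeTable | None = None
    diversity: pd.DataFrame | None = None
    amova_result: AmovaResult | None = None
    amova_pvalues: dict | None = None
    consensus: str | None = None
    consensus_diffs: dict | None = None
    polymorphic_sites: pd.DataFrame | None = None
    motif_hits: pd.DataFrame | None = None
    conservation: pd.DataFrame | None = None
    category_counts: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    motif_error: str | None = None
    provenance: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all analysis stages in order; see module docstring."""
    report = RunReport()
    report.provenance = {
        "package": "promopop",
        "version": __version__,
        "seed": config.seed,
        "gap_mode": config.gap_mode,
        "distance_mode": config.distance_mode,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }

    # --- inputs -----------------------------------------------------------
    if config.simulation is not None:
        logger.info("stage=simulate seed=%d", config.simulation.seed)
        aln, pmap, _ = simulate_study(config.simulation)
    else:
        logger.info("stage=read alignment=%s", config.alignment)
        aln = read_alignment(config.alignment)
        pmap = read_population_map(config.population_map)

    # --- haplotypes -------------------------------------------------------
    logger.info("stage=collapse n=%d", aln.n)
    table = collapse_haplotypes(aln, pmap)
    report.haplotype_table = table

    has_sequences = table.sequences is not None
    if has_sequences:
        report.consensus = consensus_sequence(aln)
        report.consensus_diffs = diff_from_consensus(table, report.consensus)
        poly = classify_rare_sites(call_polymorphic_sites(aln))
        report.polymorphic_sites = poly.to_frame()

    # --- diversity and neutrality ----------------------------------------
    logger.info("stage=diversity gap_mode=%s", config.gap_mode)
    rows = []
    scopes = [*table.populations, None]
    for scope in scopes:
        sub = table if scope is None else table.subset(scope)
        if sub.n < 4:
            continue
        stats = diversity_summary(
            table,
            scope,
            config.gap_mode,
            pvalue_reps=config.neutrality_reps,
            seed=config.stage_seed(f"neutrality:{scope}"),
        )
        rows.append(dataclasses.asdict(stats))
    report.diversity = pd.DataFrame(rows)

    # --- AMOVA ------------------------------------------------------------
    logger.info("stage=amova distance=%s", config.distance_mode)
    spec = DistanceSpec(mode=config.distance_mode)
    report.amova_result = amova(table, pmap, spec)
    report.amova_pvalues = amova_permutation_test(
        table, pmap, spec, reps=config.amova_reps, seed=config.stage_seed("amova")
    )

    # --- motifs (isolated) -------------------------------------------------
    if config.motif_library is not None:
        try:
            logger.info("stage=motifs library=%s", config.motif_library)
            lib = load_motif_library(config.motif_library)
            hits = scan_motifs(table, lib, config.strands)
            report.motif_hits = hits_to_frame(hits)
            summary = classify_conservation(hits, table.h)
            report.conservation = pd.DataFrame(
                [
                    {
                        "motif": l.motif_id,
                        "aln_start": l.aln_start + 1,
                        "aln_end": l.aln_end,
                        "n_haplotypes": len(l.present_in),
                        "class": "conserved" if l.conserved else "non-conserved",
                    }
                    for l in summary.loci
                ]
            )
            report.category_counts = aggregate_categories(hits, lib)
            ref = consensus_sequence(aln)
            enr_rows = []
            for i, motif in enumerate(lib):
                res = permutation_enrichment(
                    ref,
                    motif.motif_id,
                    lib,
                    reps=config.enrichment_reps,
                    shuffle_mode=config.shuffle_mode,
                    seed=config.stage_seed(f"enrich:{motif.motif_id}"),
                )
                enr_rows.append(dataclasses.asdict(res))
            report.enrichment = pd.DataFrame(enr_rows)
        except Exception as exc:  # stage isolation: popgen outputs survive
            logger.error("motif stage failed: %s", exc)
            report.motif_error = f"{type(exc).__name__}: {exc}"
    else:
        logger.info("stage=motifs skipped (no library configured)")

    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def write_report(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Write every table as TSV plus a single summary JSON.

    Files are written atomically (tmp file + rename) with stable names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write_tsv(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        tmp = path.with_suffix(".tsv.tmp")
        df.to_csv(tmp, sep="\t", index=False)
        tmp.rename(path)
        written[name] = path

    if report.haplotype_table is not None:
        table = report.haplotype_table
        df = table.counts.reset_index().rename(columns={"index": "haplotype"})
        if table.sequences is not None:
            df.insert(1, "sequence", [table.sequences[h] for h in table.haplotype_ids])
        _write_tsv("haplotypes", df)
    if report.diversity is not None:
        div = report.diversity.copy()
        for col in ("Hd", "pi", "k", "tajima_d", "fu_li_f_star"):
            if col in div:
                div[col] = div[col].astype(float).round(3)
        _write_tsv("diversity", div)
    if report.amova_result is not None:
        _write_tsv("amova", report.amova_result.to_frame())
    if report.polymorphic_sites is not None:
        _write_tsv("polymorphic_sites", report.polymorphic_sites)
    if report.motif_hits is not None:
        _write_tsv("motif_hits", report.motif_hits)
    if report.conservation is not None:
        _write_tsv("conservation", report.conservation)
    if report.category_counts is not None:
        _write_tsv(
            "category_counts",
            report.category_counts.reset_index().rename(columns={"index": "scope"}),
        )
    if report.enrichment is not None:
        _write_tsv("enrichment", report.enrichment)

    summary = {
        "provenance": report.provenance,
        "haplotypes": (
            {
                "h": report.haplotype_table.h,
                "n": report.haplotype_table.n,
            }
            if report.haplotype_table is not None
            else {}
        ),
        "diversity": (
            report.diversity.to_dict(orient="records")
            if report.diversity is not None
            else []
        ),
        "amova": (
            {
                "ss": [
                    report.amova_result.ss_among_groups,
                    report.amova_result.ss_among_pops_within,
                    report.amova_result.ss_within,
                    report.amova_result.ss_total,
                ],
                "df": list(report.amova_result.df),
                "components": [
                    report.amova_result.Va,
                    report.amova_result.Vb,
                    report.amova_result.Vc,
                ],
                "percentages": list(report.amova_result.pct),
                "phi": {
                    "CT": report.amova_result.phi_CT,
                    "SC": report.amova_result.phi_SC,
                    "ST": report.amova_result.phi_ST,
                },
                "p_values": report.amova_pvalues,
            }
            if report.amova_result is not None
            else {}
        ),
        "consensus_diffs": report.consensus_diffs or {},
        "motif_error": report.motif_error,
        "enrichment": (
            report.enrichment.to_dict(orient="records")
            if report.enrichment is not None
            else []
        ),
    }
    path = out / "summary.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    tmp.rename(path)
    written["summary"] = path
    return written
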