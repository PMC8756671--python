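"""End-to-end orchestration: classify → TE → relative TE → group summaries.

A run is driven by a single TOML config, validated before any computation,
and writes a machine-readable JSON report (versions, seed, parameter echo,
gene-exclusion log) next to the tidy TSV outputs.  Reruns with the same
config and seed produce byte-identical report payloads.
"""

from __future__ import annotations

import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import (
    AbundanceTable,
    aggregate_replicates,
    group_summary,
    high_glucose_treatments,
    load_treatment_metadata,
    relative_abundance,
    relative_te,
    tolerant_ratio,
    transcription_efficiency,
    DEFAULT_TREATMENTS,
)
from .crossmap import matches_to_frame, reciprocal_match
from .network import build_network, edge_list, network_stats, stats_to_frame, write_graphml
from .tolerance import (
    AlignmentParams,
    ReferenceProfile,
    classify_fasta,
    default_reference,
    read_fasta_records,
)

logger = logging.getLogger("bglccr")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    fasta: Path
    dna_table: Path
    rna_table: Path
    out_dir: Path
    ck_label: str = "CK"
    metadata: Path | None = None
    reference: Path | None = None
    positions: tuple[tuple[int, str], ...] = ((168, "W"), (173, "L"))
    min_identity: float = 0.30
    min_columns: int = 150
    te_direction: str = "rna_over_dna"
    normalize: bool = True           # per-sample normalisation over called genes
    dna_units: str = "read_abundance"
    rna_units: str = "read_abundance"
    crossmap_rna_fasta: Path | None = None
    crossmap_min_identity: float = 95.0
    network_table: Path | None = None
    network_r_min: float = 0.8
    network_alpha: float = 0.05
    network_n_perm: int = 1000
    seed: int = 0
    raw_config: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        inputs = raw.get("inputs", {})
        params = raw.get("params", {})
        base = Path(path).parent

        def _p(section: dict, key: str, required: bool = False) -> Path | None:
            if key not in section:
                if required:
                    raise PipelineError("config", f"missing required input {key!r}")
                return None
            p = Path(section[key])
            return p if p.is_absolute() else base / p

        positions = params.get("positions", "168:W,173:L")
        if isinstance(positions, str):
            positions = tuple(
                (int(tok.split(":")[0]), tok.split(":")[1])
                for tok in positions.split(",")
            )
        return cls(
            fasta=_p(inputs, "fasta", required=True),
            dna_table=_p(inputs, "dna_table", required=True),
            rna_table=_p(inputs, "rna_table", required=True),
            metadata=_p(inputs, "metadata"),
            reference=_p(inputs, "reference"),
            crossmap_rna_fasta=_p(inputs, "crossmap_rna_fasta"),
            network_table=_p(inputs, "network_table"),
            out_dir=_p(raw.get("output", {}), "dir", required=True),
            ck_label=params.get("ck_label", "CK"),
            positions=tuple(positions),
            min_identity=params.get("min_identity", 0.30),
            min_columns=params.get("min_columns", 150),
            te_direction=params.get("te_direction", "rna_over_dna"),
            normalize=params.get("normalize", True),
            dna_units=params.get("dna_units", "read_abundance"),
            rna_units=params.get("rna_units", "read_abundance"),
            crossmap_min_identity=params.get("crossmap_min_identity", 95.0),
            network_r_min=params.get("network_r_min", 0.8),
            network_alpha=params.get("network_alpha", 0.05),
            network_n_perm=params.get("network_n_perm", 1000),
            seed=params.get("seed", 0),
            raw_config=raw,
        )

    def validate(self) -> None:
        for name in ("fasta", "dna_table", "rna_table"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError("config", f"input {name} not found: {p}")
        for name in ("metadata", "reference", "crossmap_rna_fasta", "network_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"input {name} not found: {p}")
        dna = pd.read_csv(self.dna_table, sep="\t", index_col=0)
        treatments = (
            dna["treatment"].unique().tolist() if "treatment" in dna else dna.index.tolist()
        )
        if self.ck_label not in treatments:
            raise PipelineError(
                "config", f"control treatment {self.ck_label!r} absent from DNA table"
            )


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    report: dict = {
        "tool": "bglccr",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "ck_label": config.ck_label,
            "positions": [list(p) for p in config.positions],
            "min_identity": config.min_identity,
            "min_columns": config.min_columns,
            "te_direction": config.te_direction,
            "normalize": config.normalize,
        },
        "config_echo": config.raw_config,
        "exclusions": {},
    }

    # --- classification ---------------------------------------------------
    stage = "classify"
    try:
        if config.reference is not None:
            ref_records = read_fasta_records(config.reference, moltype="aa")
            profile = ReferenceProfile(
                ref_id=ref_records[0].gene_id,
                ref_protein=ref_records[0].sequence,
                discriminating_positions=config.positions,
            )
        else:
            profile = default_reference()
            if config.positions != ((168, "W"), (173, "L")):
                profile = ReferenceProfile(
                    profile.ref_id, profile.ref_protein, config.positions
                )
        params = AlignmentParams(
            min_identity=config.min_identity, min_columns=config.min_columns
        )
        calls = classify_fasta(config.fasta, profile, params)
        calls.to_csv(out / "tolerance_calls.tsv", sep="\t", index=False)
        counts = calls["call"].value_counts().to_dict()
        logger.info("classified %d genes: %s", len(calls), counts)
        report["classification"] = {"n_genes": len(calls), "counts": counts}
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        raise PipelineError(stage, str(exc)) from exc

    # --- abundance / TE ---------------------------------------------------
    stage = "te"
    try:
        dna = AbundanceTable.read_tsv(config.dna_table, level="DNA", units=config.dna_units)
        rna = AbundanceTable.read_tsv(config.rna_table, level="RNA", units=config.rna_units)
        if dna.replicate_of is not None:
            dna, _ = aggregate_replicates(dna)
        if rna.replicate_of is not None:
            rna, _ = aggregate_replicates(rna)
        called = calls.loc[calls["call"] != "indeterminate", "gene_id"]
        universe = [g for g in called if g in dna.data.columns and g in rna.data.columns]
        report["exclusions"]["indeterminate_genes"] = sorted(
            set(calls["gene_id"]) - set(called)
        )
        if config.normalize:
            dna_n = relative_abundance(dna, universe)
            rna_n = relative_abundance(rna, universe)
        else:
            dna_n = AbundanceTable(dna.data[universe], level="DNA", units=dna.units)
            rna_n = AbundanceTable(rna.data[universe], level="RNA", units=rna.units)
        te = transcription_efficiency(dna_n, rna_n, direction=config.te_direction)
        te.te.to_csv(out / "te.tsv", sep="\t")
        rel = relative_te(te, config.ck_label)
        rel.rel_te.to_csv(out / "relative_te.tsv", sep="\t")
        report["exclusions"]["undefined_ck_te"] = rel.excluded_genes
        if rel.excluded_genes:
            logger.info("excluded %d genes with undefined control TE", len(rel.excluded_genes))
        summary = group_summary(rel.rel_te, calls)
        summary.to_csv(out / "group_summary.tsv", sep="\t", index=False)
        report["group_summary"] = summary.to_dict(orient="records")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- glucose-tolerant gene ratios ------------------------------------
    stage = "ratios"
    try:
        designs = (
            load_treatment_metadata(config.metadata)
            if config.metadata is not None
            else list(DEFAULT_TREATMENTS)
        )
        ratios: dict[str, dict] = {
            "unweighted": {"all": tolerant_ratio(calls)},
            "rna_weighted": {},
        }
        for treatment in rna_n.data.index:
            weights = rna_n.data.loc[treatment].to_dict()
            ratios["rna_weighted"][treatment] = tolerant_ratio(calls, weights)
        report["tolerant_ratios"] = ratios
        report["high_glucose_treatments"] = high_glucose_treatments(designs)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- optional crossmap ------------------------------------------------
    if config.crossmap_rna_fasta is not None:
        stage = "crossmap"
        try:
            dna_seqs = {r.gene_id: r.sequence for r in read_fasta_records(config.fasta)}
            rna_seqs = {
                r.gene_id: r.sequence
                for r in read_fasta_records(config.crossmap_rna_fasta)
            }
            matches = reciprocal_match(
                dna_seqs, rna_seqs, threshold=config.crossmap_min_identity
            )
            matches_to_frame(matches).to_csv(out / "crossmap.tsv", sep="\t", index=False)
            report["crossmap"] = {"n_pairs": len(matches)}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # --- optional network -------------------------------------------------
    if config.network_table is not None:
        stage = "network"
        try:
            taxa = pd.read_csv(config.network_table, sep="\t", index_col=0)
            graph = build_network(
                taxa,
                r_min=config.network_r_min,
                alpha=config.network_alpha,
                n_perm=config.network_n_perm,
                seed=config.seed,
            )
            edge_list(graph).to_csv(out / "network_edges.tsv", sep="\t", index=False)
            stats = network_stats(graph)
            stats_to_frame(stats).to_csv(out / "network_stats.tsv", sep="\t", index=False)
            write_graphml(graph, str(out / "network.graphml"))
            report["network"] = stats.__dict__
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("run complete: %s", out / "report.json")
    return report
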