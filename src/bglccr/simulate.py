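"""Synthetic data generator with planted ground truth.

Emulates the study design end to end so every analysis step can be tested
without sequencing data: GH1 β-glucosidase gene sequences derived from the
bundled reference that carry or lack the Trp168/Leu173 glucose-tolerance
motif; per-treatment DNA and RNA abundance tables in which glucose-tolerant
genes are transcriptionally up-regulated (TE × f_up) and non-tolerant genes
down-regulated (TE × f_down) under the 200 mmol/L glucose treatments
relative to the additive-free control CK; triplicate qPCR copy numbers with
multiplicative lognormal noise; and block-structured taxon abundance
profiles for co-occurrence network tests.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; the same seed and configuration reproduce
files byte-identically.  Noise factors are mean-one lognormal
(``exp(N(-s²/2, s²))`` with ``s² = ln(1+CV²)``) so expected abundances are
preserved; ratios of such factors still exceed 1 in expectation (Jensen),
which matters when interpreting mean relative-TE under noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .abundance import DEFAULT_TREATMENTS, AbundanceTable, TreatmentDesign
from .tolerance import GeneRecord, ReferenceProfile, default_reference

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 100 genes, half glucose-tolerant, TE doubled
    for tolerant genes and halved for non-tolerant genes under high glucose,
    20% multiplicative noise, triplicate qPCR."""

    n_genes: int = 100
    fraction_gt: float = 0.5
    treatments: tuple[TreatmentDesign, ...] = DEFAULT_TREATMENTS
    f_up: float = 2.0
    f_down: float = 0.5
    base_te_mu: float = 0.0      # lognormal log-mean of per-gene baseline TE
    base_te_sigma: float = 0.5   # lognormal log-sd of per-gene baseline TE
    dna_sigma: float = 1.0       # lognormal log-sd of per-gene DNA abundance
    noise_cv: float = 0.2
    depth: float = 1_000_000.0   # reads per metagenome/metatranscriptome sample
    qpcr_scale: float = 10_000.0  # copies per reaction at unit abundance
    n_replicates: int = 3
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_gt <= 1.0:
            raise SimulationError("fraction_gt must be in [0, 1]")
        if not (self.f_up >= 1.0 >= self.f_down > 0.0):
            raise SimulationError("need f_up >= 1 >= f_down > 0")
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        if self.mutation_rate >= 0.5:
            raise SimulationError(
                "mutation_rate >= 0.5 would destroy homology to the reference"
            )

    @property
    def high_glucose(self) -> list[str]:
        return [t.name for t in self.treatments if t.is_high_glucose]

    @property
    def treatment_names(self) -> list[str]:
        return [t.name for t in self.treatments]


@dataclass
class SyntheticTruth:
    """Planted labels and effects, serialised alongside generated data."""

    labels: dict[str, str]  # gene_id -> glucose_tolerant | non_tolerant
    effects: pd.DataFrame | None = None  # treatments × genes TE multipliers
    base_te: dict[str, float] = field(default_factory=dict)
    block_membership: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "effects": None
            if self.effects is None
            else {t: self.effects.loc[t].to_dict() for t in self.effects.index},
            "base_te": self.base_te,
            "block_membership": self.block_membership,
            "seed": self.seed,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        effects = payload["effects"]
        if effects is not None:
            effects = pd.DataFrame(effects).T
        return cls(
            labels=payload["labels"],
            effects=effects,
            base_te=payload["base_te"],
            block_membership=payload["block_membership"],
            seed=payload["seed"],
            params=payload["params"],
        )


def _config_record(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["treatments"] = [t.name for t in config.treatments]
    return d


def _codon_choices() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    choices: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        choices.setdefault(aa, []).append(codon)
    return choices


_CODONS = _codon_choices()
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gen_sequences(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    profile: ReferenceProfile | None = None,
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Generate nucleotide gene records from the reference protein.

    Every gene is the reference with random substitutions at
    non-discriminating positions at ``mutation_rate``; glucose-tolerant
    genes keep the required residues at the discriminating positions,
    non-tolerant genes have one or both ablated to a different residue.
    Genes are reverse-translated with uniform synonymous codon choice and
    placed on a random strand.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    profile = profile or default_reference()
    ref = list(profile.ref_protein)
    disc = dict(profile.discriminating_positions)
    disc_idx = {pos - 1 for pos in disc}
    n_gt = int(round(config.n_genes * config.fraction_gt))
    records: list[GeneRecord] = []
    labels: dict[str, str] = {}
    aa_list = list(STANDARD_AA)
    for i in range(config.n_genes):
        gene_id = f"gene_{i + 1:04d}"
        is_gt = i < n_gt
        protein = ref.copy()
        for j in range(len(protein)):
            if j in disc_idx:
                continue
            if rng.random() < config.mutation_rate:
                current = protein[j]
                alternatives = [a for a in aa_list if a != current]
                protein[j] = alternatives[rng.integers(len(alternatives))]
        if not is_gt:
            # ablate one or both discriminating residues
            positions = sorted(disc)
            mode = rng.integers(3)  # 0: first, 1: second, 2: both
            to_ablate = {
                0: [positions[0]],
                1: [positions[1]],
                2: positions,
            }[int(mode)]
            for pos in to_ablate:
                required = disc[pos]
                alternatives = [a for a in aa_list if a != required]
                protein[pos - 1] = alternatives[rng.integers(len(alternatives))]
        nt = "".join(
            _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
        )
        if rng.random() < 0.5:
            nt = _reverse_complement(nt)
        records.append(
            GeneRecord(gene_id=gene_id, sequence=nt, moltype="nt", source="synthetic")
        )
        labels[gene_id] = "glucose_tolerant" if is_gt else "non_tolerant"
    truth = SyntheticTruth(labels=labels, seed=config.seed, params=_config_record(config))
    return records, truth


def write_fasta(records: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for k in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[k : k + 80] + "\n")


def _noise_factors(
    rng: np.random.Generator, cv: float, shape: tuple[int, ...]
) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(shape)
    s2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-s2 / 2, np.sqrt(s2), size=shape))


def _planted_effects(config: SimulationConfig, truth: SyntheticTruth) -> pd.DataFrame:
    genes = list(truth.labels)
    effects = pd.DataFrame(1.0, index=config.treatment_names, columns=genes)
    high = config.high_glucose
    for gene, label in truth.labels.items():
        mult = config.f_up if label == "glucose_tolerant" else config.f_down
        effects.loc[high, gene] = mult
    return effects


def _base_levels(
    config: SimulationConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    genes = list(truth.labels)
    dna_base = np.exp(rng.normal(0.0, config.dna_sigma, size=len(genes)))
    base_te = np.exp(
        rng.normal(config.base_te_mu, config.base_te_sigma, size=len(genes))
    )
    truth.base_te = dict(zip(genes, base_te.tolist()))
    return dna_base, base_te


def gen_abundance(
    config: SimulationConfig,
    truth: SyntheticTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[AbundanceTable, AbundanceTable, SyntheticTruth]:
    """Metagenome/metatranscriptome-style read-count tables per treatment.

    DNA abundance of a gene is lognormal and treatment-independent; expected
    RNA = DNA × baseTE × effect(g, t).  Observed values get mean-one
    lognormal noise, are scaled to the sequencing depth within each sample
    and rounded to integer counts.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if truth is None:
        n_gt = int(round(config.n_genes * config.fraction_gt))
        labels = {
            f"gene_{i + 1:04d}": "glucose_tolerant" if i < n_gt else "non_tolerant"
            for i in range(config.n_genes)
        }
        truth = SyntheticTruth(labels=labels, seed=config.seed, params=_config_record(config))
    genes = list(truth.labels)
    effects = _planted_effects(config, truth)
    truth.effects = effects
    dna_base, base_te = _base_levels(config, truth, rng)
    n_t, n_g = len(config.treatment_names), len(genes)
    dna_expect = np.tile(dna_base, (n_t, 1))
    rna_expect = dna_expect * base_te[None, :] * effects.to_numpy()
    dna_obs = dna_expect * _noise_factors(rng, config.noise_cv, (n_t, n_g))
    rna_obs = rna_expect * _noise_factors(rng, config.noise_cv, (n_t, n_g))
    dna_counts = np.rint(
        dna_obs / dna_obs.sum(axis=1, keepdims=True) * config.depth
    )
    rna_counts = np.rint(
        rna_obs / rna_obs.sum(axis=1, keepdims=True) * config.depth
    )
    index = pd.Index(config.treatment_names, name="treatment")
    dna_table = AbundanceTable(
        pd.DataFrame(dna_counts, index=index, columns=genes), level="DNA"
    )
    rna_table = AbundanceTable(
        pd.DataFrame(rna_counts, index=index, columns=genes), level="RNA"
    )
    return dna_table, rna_table, truth


def gen_qpcr(
    config: SimulationConfig,
    truth: SyntheticTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[AbundanceTable, AbundanceTable, SyntheticTruth]:
    """Triplicate qPCR copy-number tables (DNA and cDNA) per treatment.

    Copy numbers are proportional to the planted abundances with mean-one
    lognormal replicate noise; with zero noise the replicates are identical.
    Unlike read tables these are absolute copy numbers — no per-sample
    rescaling — so the noiseless relative TE recovers the planted effect
    exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if truth is None:
        n_gt = int(round(config.n_genes * config.fraction_gt))
        labels = {
            f"gene_{i + 1:04d}": "glucose_tolerant" if i < n_gt else "non_tolerant"
            for i in range(config.n_genes)
        }
        truth = SyntheticTruth(labels=labels, seed=config.seed, params=_config_record(config))
    genes = list(truth.labels)
    effects = _planted_effects(config, truth)
    truth.effects = effects
    dna_base, base_te = _base_levels(config, truth, rng)
    n_t, n_g, n_r = len(config.treatment_names), len(genes), config.n_replicates
    dna_expect = config.qpcr_scale * np.tile(dna_base, (n_t, 1))
    rna_expect = dna_expect * base_te[None, :] * effects.to_numpy()
    dna_obs = dna_expect[:, None, :] * _noise_factors(rng, config.noise_cv, (n_t, n_r, n_g))
    rna_obs = rna_expect[:, None, :] * _noise_factors(rng, config.noise_cv, (n_t, n_r, n_g))
    samples = [
        f"{t}__rep{k + 1}" for t in config.treatment_names for k in range(n_r)
    ]
    replicate_of = {s: s.split("__rep")[0] for s in samples}
    dna_table = AbundanceTable(
        pd.DataFrame(dna_obs.reshape(n_t * n_r, n_g), index=samples, columns=genes),
        level="DNA",
        units="copies_per_reaction",
        replicate_of=replicate_of,
    )
    rna_table = AbundanceTable(
        pd.DataFrame(rna_obs.reshape(n_t * n_r, n_g), index=samples, columns=genes),
        level="RNA",
        units="copies_per_reaction",
        replicate_of=replicate_of,
    )
    return dna_table, rna_table, truth


def gen_crossmap_sets(
    n_dna: int = 50,
    n_planted_high: int = 5,
    n_planted_low: int = 5,
    high_rates: Sequence[float] = (0.01, 0.02, 0.03, 0.04, 0.02),
    low_rate: float = 0.15,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], list[tuple[str, str, float]]]:
    """DNA/RNA gene sets with planted cross-mapping structure.

    The RNA set holds ``n_planted_high`` near-identical copies of DNA genes
    (substitution rates ``high_rates`` → ≥95% identity) and
    ``n_planted_low`` diverged copies (``low_rate`` → ~85% identity).
    Substitutions hit an exact count of distinct positions, so the planted
    identity of each copy is known exactly: 100 × (L − k)/L for k changes
    over length L.  Returns (dna_set, rna_set, expected_pairs) where
    expected_pairs lists (dna_id, rna_id, planted_identity) for the
    above-threshold copies only.
    """
    config = SimulationConfig(n_genes=n_dna, seed=seed)
    records, _ = gen_sequences(config)
    dna_set = {r.gene_id: r.sequence for r in records}
    rng = np.random.default_rng(seed + 1)
    rna_set: dict[str, str] = {}
    expected: list[tuple[str, str, float]] = []
    bases = "ACGT"

    def mutate(seq: str, rate: float) -> tuple[str, float]:
        L = len(seq)
        k = int(round(rate * L))
        positions = rng.choice(L, size=k, replace=False)
        s = list(seq)
        for p in positions:
            s[p] = rng.choice([b for b in bases if b != s[p]])
        return "".join(s), 100.0 * (L - k) / L

    source_ids = sorted(dna_set)[: n_planted_high + n_planted_low]
    for i, d_id in enumerate(source_ids[:n_planted_high]):
        rate = high_rates[i % len(high_rates)]
        seq, pid = mutate(dna_set[d_id], rate)
        r_id = f"rna_{i + 1:03d}"
        rna_set[r_id] = seq
        expected.append((d_id, r_id, pid))
    for i, d_id in enumerate(source_ids[n_planted_high:]):
        seq, _ = mutate(dna_set[d_id], low_rate)
        rna_set[f"rna_low_{i + 1:03d}"] = seq
    return dna_set, rna_set, expected


def gen_block_abundance(
    n_blocks: int = 2,
    taxa_per_block: int = 5,
    n_samples: int = 20,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Taxon abundance profiles with planted correlation blocks.

    One latent factor per sample drives all taxa; blocks alternate sign, so
    taxa are positively correlated within a block and negatively across
    blocks.  Returns (taxa × samples table, block membership).
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, 1.0, size=n_samples)
    rows = {}
    membership = {}
    for b in range(n_blocks):
        sign = 1.0 if b % 2 == 0 else -1.0
        for k in range(taxa_per_block):
            taxon = f"taxon_b{b + 1}_{k + 1}"
            rows[taxon] = 10.0 + sign * z + rng.normal(0.0, noise_sd, size=n_samples)
            membership[taxon] = b
    samples = [f"sample_{i + 1:02d}" for i in range(n_samples)]
    return pd.DataFrame(rows, index=samples).T, membership
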