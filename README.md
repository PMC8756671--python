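# bglccr

Differential expression of glucose-tolerant vs non-glucose-tolerant GH1
β-glucosidase genes under carbon catabolite repression (CCR).

When glucose accumulates, microbial communities repress cellulose
degradation; β-glucosidase, the rate-limiting enzyme that converts
cellobiose to glucose, is where the community's counter-strategy shows.
Within the GH1 family, glucose-tolerant β-glucosidases carry a conserved
Trp/Leu residue pair (Trp168/Leu173 in reference numbering). This package
implements the complete analysis for asking whether communities
up-regulate the tolerant group and down-regulate the non-tolerant group
under high glucose:

- **Tolerance classification** — six-frame translation, end-gap-free
  global alignment to a reference GH1 protein (BLOSUM62, affine gaps), and
  an exact residue read-out at the two discriminating positions. Calls are
  `glucose_tolerant`, `non_tolerant`, or `indeterminate` (quality gates:
  identity ≥ 30% over ≥ 150 aligned residues).
- **Transcription efficiency (TE)** — per-gene RNA/DNA abundance ratio
  (transcripts per gene copy), from metagenome/metatranscriptome relative
  abundances or qPCR copy numbers, and the relative-TE statistic against
  the additive-free control:

  `relative TE = (TE_treatment − TE_CK) / TE_CK`

  with group means over tolerant/non-tolerant genes, glucose-tolerant gene
  ratios (unweighted and expression-weighted) and relative enzyme
  activity.
- **Cross-mapping** — reciprocal-best-hit matching of metagenome and
  metatranscriptome gene sets at ≥ 95% nucleotide identity.
- **Co-occurrence networks** — signed taxon networks (|r| ≥ 0.8 plus a
  seeded permutation test) with topology statistics.
- **Synthetic data** — a generator that plants known tolerance labels, TE
  effect multipliers and correlation blocks, so the whole pipeline is
  testable end to end with exported ground truth.

The bundled reference protein is a constructed stand-in (labelled
synthetic) carrying W168/L173; swap in any curated glucose-tolerant GH1
sequence via `ReferenceProfile`.

## Worked example

```python
from bglccr import SimulationConfig, classify_records, gen_sequences, tolerant_ratio

config = SimulationConfig(n_genes=40, mutation_rate=0.05, seed=1)
records, truth = gen_sequences(config)      # 20 tolerant, 20 ablated
calls = classify_records(records)
print(calls["call"].value_counts().to_dict())
print(f"glucose-tolerant gene ratio: {tolerant_ratio(calls):.4f}")
```

prints

```
{'glucose_tolerant': 20, 'non_tolerant': 20}
glucose-tolerant gene ratio: 0.5000
```

— every planted label is recovered, and the ratio is the tolerant fraction
among called genes. Recovering a planted expression effect
(`examples/transcription_efficiency.py`, f_up = 2, f_down = 0.5, 20%
noise):

```
treatment            group  n_genes      mean       sd  mean_diff
       CK glucose_tolerant       15  0.000000 0.000000   0.000000
      C_H glucose_tolerant       15  0.051617 0.252776   0.008202
      C_H     non_tolerant       15  0.043415 0.223674   0.008202
  G_H_C_H glucose_tolerant       15  1.115876 0.605360   1.564520
  G_H_C_H     non_tolerant       15 -0.448644 0.148175   1.564520
```

Under 200 mmol/L glucose (`G_H_C_H`) the tolerant group's mean relative TE
sits near +1 (TE doubled) and the non-tolerant group near −0.5 (TE
halved); in the cellobiose-only treatment (`C_H`) both groups sit near 0,
and the control row is 0 by construction. Each script in `examples/`
exercises one capability (classification, TE, cross-mapping, networks,
full pipeline) and prints what the numbers mean.

A thin CLI mirrors the library:

```sh
bglccr simulate --n-genes 100 --seed 1 --out-dir sim/
bglccr classify --fasta sim/genes.fasta --out calls.tsv
bglccr te --dna sim/dna_abundance.tsv --rna sim/rna_abundance.tsv \
          --calls calls.tsv --ck CK --out-dir te_out/
bglccr crossmap --dna a.fasta --rna b.fasta --min-identity 95 --out pairs.tsv
bglccr network --table taxa.tsv --r-min 0.8 --n-perm 1000 --seed 7 --out-dir net/
bglccr run --config run.toml
```

## Layout

```
src/bglccr/        tolerance, abundance, crossmap, network, simulate,
                   calibration, pipeline, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and end-to-end tests)
docs/methods.md    model, assumptions, numerical choices, limitations
```
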