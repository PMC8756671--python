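"""Run the whole pipeline — classify → TE → relative TE → group summaries —
from a TOML config on a simulated dataset, as `bglccr run` would.
"""

import json
import tempfile
from pathlib import Path

from bglccr import RunConfig, SimulationConfig, gen_abundance, gen_sequences, run_pipeline
from bglccr.abundance import write_treatment_metadata
from bglccr.simulate import write_fasta

workdir = Path(tempfile.mkdtemp(prefix="bglccr_demo_"))
config = SimulationConfig(n_genes=30, noise_cv=0.1, seed=5)
records, truth = gen_sequences(config)
write_fasta(records, workdir / "genes.fasta")
dna, rna, truth = gen_abundance(config, truth)
dna.write_tsv(workdir / "dna.tsv")
rna.write_tsv(workdir / "rna.tsv")
write_treatment_metadata(config.treatments, workdir / "treatments.tsv")

(workdir / "run.toml").write_text(f"""
[inputs]
fasta = "genes.fasta"
dna_table = "dna.tsv"
rna_table = "rna.tsv"
metadata = "treatments.tsv"

[params]
ck_label = "CK"
seed = 5

[output]
dir = "out"
""")

report = run_pipeline(RunConfig.from_toml(workdir / "run.toml"))
print("outputs in", workdir / "out")
print("classification:", report["classification"]["counts"])
for row in report["group_summary"]:
    if row["treatment"] in ("G_H_C_H", "C_H"):
        print(f"{row['treatment']:>9} {row['group']:<17} "
              f"n={row['n_genes']:<3} mean rel TE={row['mean']:+.3f}")
print("expressed tolerant fraction per treatment:",
      json.dumps({t: round(v, 3) for t, v in report["tolerant_ratios"]["rna_weighted"].items()}))
# Under high glucose the tolerant group's mean relative TE exceeds the
# non-tolerant group's, and the expressed tolerant fraction rises above the
# unweighted gene-level fraction — the signature of differential regulation.
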