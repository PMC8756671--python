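"""Relative abundance, transcription efficiency (TE) and relative-TE statistics.

Transcription efficiency of a gene is the ratio of its transcript-level
(RNA/cDNA) abundance to its gene-level (DNA) abundance — transcripts per
gene copy.  For metagenome/metatranscriptome read abundances, per-gene
values are first normalised to the sum over the set of genes with a
characterised (classifiable) sequence; for qPCR copy numbers the ratio is
taken on copy numbers directly.  The treatment effect on a gene is the
relative TE against the no-additive control CK::

    relative TE = (TE_treatment - TE_ck) / TE_ck

so a gene transcribed identically in treatment and control scores 0, a
doubling scores +1 and a halving scores -0.5.  Group averages of relative
TE over glucose-tolerant and non-tolerant genes summarise the
transcriptional response of each functional group to carbon catabolite
repression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HIGH_GLUCOSE_MMOL = 200.0


class AbundanceError(ValueError):
    pass


@dataclass
class AbundanceTable:
    """Samples/treatments × genes matrix of non-negative abundances.

    ``replicate_of`` maps sample ids to their treatment for replicated
    (qPCR-style) tables; when absent each row is taken as one treatment.
    """

    data: pd.DataFrame
    level: str  # "DNA" | "RNA"
    units: str = "read_abundance"  # or "copies_per_reaction"
    replicate_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.level not in ("DNA", "RNA"):
            raise AbundanceError("level must be 'DNA' or 'RNA'")
        if (self.data.values < 0).any():
            raise AbundanceError(f"{self.level} table contains negative entries")
        if self.replicate_of is not None:
            missing = set(self.data.index) - set(self.replicate_of)
            if missing:
                raise AbundanceError(f"samples without treatment assignment: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        level: str,
        units: str = "read_abundance",
        replicate_col: str = "treatment",
    ) -> "AbundanceTable":
        """Read a TSV whose first column holds sample/treatment ids; an
        optional ``treatment`` column marks replicate membership."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        replicate_of = None
        if replicate_col in df.columns:
            replicate_of = df[replicate_col].to_dict()
            df = df.drop(columns=[replicate_col])
        return cls(df.astype(float), level=level, units=units, replicate_of=replicate_of)

    def write_tsv(self, path: str | Path) -> None:
        df = self.data.copy()
        if self.replicate_of is not None:
            df.insert(0, "treatment", [self.replicate_of[s] for s in df.index])
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class TreatmentDesign:
    """One incubation treatment: additive concentrations and compost phase."""

    name: str
    glucose_mmol: float
    cellobiose_mmol: float
    gluconolactone_mmol: float
    phase: str = "T2"

    @property
    def is_high_glucose(self) -> bool:
        return self.glucose_mmol >= HIGH_GLUCOSE_MMOL

    @property
    def is_control(self) -> bool:
        return (
            self.glucose_mmol == 0
            and self.cellobiose_mmol == 0
            and self.gluconolactone_mmol == 0
        )


#: the seven incubation treatments: CK is additive-free; G_H treatments carry
#: 200 mmol/L glucose; C_L/C_H low/high cellobiose; _D adds gluconolactone.
DEFAULT_TREATMENTS: tuple[TreatmentDesign, ...] = (
    TreatmentDesign("G_H_C_L", 200.0, 0.8, 0.0),
    TreatmentDesign("G_H_C_H", 200.0, 8.0, 0.0),
    TreatmentDesign("G_H_C_H_D", 200.0, 8.0, 2.0),
    TreatmentDesign("C_L", 0.0, 0.8, 0.0),
    TreatmentDesign("C_H", 0.0, 8.0, 0.0),
    TreatmentDesign("C_H_D", 0.0, 8.0, 2.0),
    TreatmentDesign("CK", 0.0, 0.0, 0.0),
)


def high_glucose_treatments(
    designs: Sequence[TreatmentDesign] = DEFAULT_TREATMENTS,
) -> list[str]:
    return [d.name for d in designs if d.is_high_glucose]


def load_treatment_metadata(path: str | Path) -> list[TreatmentDesign]:
    """TSV columns: treatment, glucose_mmol, cellobiose_mmol,
    gluconolactone_mmol, phase."""
    df = pd.read_csv(path, sep="\t")
    return [
        TreatmentDesign(
            name=str(r["treatment"]),
            glucose_mmol=float(r["glucose_mmol"]),
            cellobiose_mmol=float(r["cellobiose_mmol"]),
            gluconolactone_mmol=float(r["gluconolactone_mmol"]),
            phase=str(r.get("phase", "T2")),
        )
        for _, r in df.iterrows()
    ]


def write_treatment_metadata(designs: Sequence[TreatmentDesign], path: str | Path) -> None:
    pd.DataFrame(
        {
            "treatment": [d.name for d in designs],
            "glucose_mmol": [d.glucose_mmol for d in designs],
            "cellobiose_mmol": [d.cellobiose_mmol for d in designs],
            "gluconolactone_mmol": [d.gluconolactone_mmol for d in designs],
            "phase": [d.phase for d in designs],
        }
    ).to_csv(path, sep="\t", index=False)


def relative_abundance(raw: AbundanceTable, gene_universe: Iterable[str]) -> AbundanceTable:
    """Normalise each sample to the sum over the characterised gene universe.

    Rows then sum to 1 over the universe; genes outside it are dropped.
    """
    universe = [g for g in raw.data.columns if g in set(gene_universe)]
    missing = set(gene_universe) - set(raw.data.columns)
    if missing:
        raise AbundanceError(f"gene universe not in table: {sorted(missing)}")
    sub = raw.data[universe]
    sums = sub.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise AbundanceError(
            f"all-zero abundance over gene universe in sample(s): {list(zero.index)}"
        )
    return AbundanceTable(
        sub.div(sums, axis=0), level=raw.level, units=raw.units, replicate_of=raw.replicate_of
    )


def aggregate_replicates(table: AbundanceTable) -> tuple[AbundanceTable, pd.DataFrame]:
    """Arithmetic mean per treatment; returns the collapsed table and a
    per-(treatment, gene) CV table (NaN where the mean is 0)."""
    if table.replicate_of is None:
        raise AbundanceError("table has no replicate mapping")
    groups = pd.Series(table.replicate_of).reindex(table.data.index)
    mean = table.data.groupby(groups).mean()
    sd = table.data.groupby(groups).std(ddof=1).fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = (sd / mean).where(mean > 0)
    collapsed = AbundanceTable(mean, level=table.level, units=table.units)
    return collapsed, cv


@dataclass
class TETable:
    """Per-(treatment, gene) transcription efficiency; NaN where undefined."""

    te: pd.DataFrame  # treatments × genes
    direction: str = "rna_over_dna"  # or "dna_over_rna"
    level_basis: str = ""


@dataclass
class RelativeTETable:
    rel_te: pd.DataFrame  # treatments × genes, CK row identically 0
    ck_label: str
    excluded_genes: list[str] = field(default_factory=list)


def transcription_efficiency(
    dna: AbundanceTable,
    rna: AbundanceTable,
    direction: str = "rna_over_dna",
) -> TETable:
    """TE(g, t) = RNA(g, t) / DNA(g, t) on matched tables.

    Undefined (NaN) where the denominator is 0; 0/0 is also undefined.  The
    ``dna_over_rna`` direction is available for the inverse convention.
    """
    if direction not in ("rna_over_dna", "dna_over_rna"):
        raise AbundanceError(f"unknown TE direction {direction!r}")
    if set(dna.data.columns) != set(rna.data.columns):
        diff = set(dna.data.columns) ^ set(rna.data.columns)
        raise AbundanceError(f"DNA/RNA gene sets differ: {sorted(diff)}")
    if set(dna.data.index) != set(rna.data.index):
        diff = set(dna.data.index) ^ set(rna.data.index)
        raise AbundanceError(f"DNA/RNA treatments differ: {sorted(diff)}")
    d = dna.data
    r = rna.data.reindex(index=d.index, columns=d.columns)
    if direction == "rna_over_dna":
        num, den = r, d
    else:
        num, den = d, r
    te = num.div(den).where(den > 0)
    return TETable(
        te,
        direction=direction,
        level_basis=f"DNA:{dna.units}, RNA:{rna.units}",
    )


def relative_te(te: TETable, ck_label: str) -> RelativeTETable:
    """(TE_treatment - TE_ck) / TE_ck per gene; CK row is identically 0.

    Genes whose control TE is 0 or undefined cannot be scored and are
    excluded (listed in ``excluded_genes``).
    """
    if ck_label not in te.te.index:
        raise AbundanceError(f"control treatment {ck_label!r} not in TE table")
    ck = te.te.loc[ck_label]
    usable = ck.notna() & (ck > 0)
    excluded = [g for g in te.te.columns if not usable[g]]
    kept = te.te.loc[:, usable]
    rel = kept.sub(ck[usable]).div(ck[usable])
    rel.loc[ck_label] = 0.0
    return RelativeTETable(rel_te=rel, ck_label=ck_label, excluded_genes=excluded)


def group_summary(
    values: pd.DataFrame,
    calls: pd.DataFrame,
) -> pd.DataFrame:
    """Per-treatment group means of a (treatments × genes) value table.

    ``calls`` is a classification table with ``gene_id`` and ``call``
    columns; indeterminate genes are excluded.  Each gene carries one vote
    (unweighted mean).  Output columns: treatment, group, n_genes, mean, sd,
    plus a ``mean_diff`` (glucose_tolerant − non_tolerant) column repeated
    per treatment.
    """
    call_of = calls.set_index("gene_id")["call"]
    bad = [g for g in values.columns if call_of.get(g) == "indeterminate"]
    if bad:
        values = values.drop(columns=bad)
    rows = []
    for treatment in values.index:
        means = {}
        for group in ("glucose_tolerant", "non_tolerant"):
            genes = [g for g in values.columns if call_of.get(g) == group]
            vals = values.loc[treatment, genes].dropna()
            mean = float(vals.mean()) if len(vals) else float("nan")
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
            means[group] = mean
            rows.append(
                {
                    "treatment": treatment,
                    "group": group,
                    "n_genes": int(len(vals)),
                    "mean": mean,
                    "sd": sd,
                }
            )
        diff = means["glucose_tolerant"] - means["non_tolerant"]
        rows[-1]["mean_diff"] = diff
        rows[-2]["mean_diff"] = diff
    return pd.DataFrame(rows, columns=["treatment", "group", "n_genes", "mean", "sd", "mean_diff"])


def tolerant_ratio(calls: pd.DataFrame, weights: Mapping[str, float] | None = None) -> float:
    """Fraction of glucose-tolerant genes among called (non-indeterminate)
    genes; abundance-weighted when ``weights`` is given (e.g. RNA relative
    abundances, yielding the expressed GT fraction)."""
    called = calls[calls["call"].isin(["glucose_tolerant", "non_tolerant"])]
    if weights is None:
        if not len(called):
            raise AbundanceError("no called genes")
        return float((called["call"] == "glucose_tolerant").mean())
    w = pd.Series(weights).reindex(called["gene_id"]).fillna(0.0)
    if (w < 0).any():
        raise AbundanceError("negative weights")
    total = float(w.sum())
    if total <= 0:
        raise AbundanceError("weights sum to zero over called genes")
    gt_mask = (called["call"] == "glucose_tolerant").to_numpy()
    return float(w.to_numpy()[gt_mask].sum() / total)


def relative_activity(activity_with_glucose: float, activity_without: float) -> float:
    """Percent residual β-glucosidase activity under added glucose."""
    if activity_without <= 0:
        raise AbundanceError("baseline activity must be positive")
    return 100.0 * activity_with_glucose / activity_without


def activity_gradient(
    activities: Mapping[float, float], baseline: float
) -> tuple[dict[float, float], bool]:
    """Relative activities across a glucose gradient (e.g. 50/100/200 mM).

    Returns the percentage per concentration and a flag that is True when
    the profile is non-monotone (tolerance profiles are expected to decline
    with glucose; a rise is flagged, not rejected).
    """
    rel = {
        conc: relative_activity(act, baseline)
        for conc, act in sorted(activities.items())
    }
    vals = list(rel.values())
    non_monotone = any(b > a for a, b in zip(vals, vals[1:]))
    return rel, non_monotone
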