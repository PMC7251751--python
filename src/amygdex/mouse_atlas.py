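"""Developmental mouse atlas filtering.

Operates on a long-form annotation table (gene, structure, age, level)
where level is an opaque scalar on a log scale bounded to [-1.5, 3.5].
A gene passes when at least one record hits a qualifying structure at a
qualifying age with level at or above the threshold (inclusive ">=",
unlike the strict human threshold).  Human-mouse symbol matching is
case-insensitive; no ortholog mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genesets import GeneSet, ValidationError, normalize_symbol

LEVEL_MIN = -1.5
LEVEL_MAX = 3.5

DEFAULT_STRUCTURES = frozenset({"RSP", "Tel", "PedHy"})
DEFAULT_AGES = frozenset({"E11.5", "E13.5", "E15.5", "E18.5", "P4"})
DEFAULT_MIN_LEVEL = 2.0

ATLAS_COLUMNS = ("gene", "structure", "age", "level")


@dataclass
class AtlasTable:
    """Long-form atlas records: one row per (gene, structure, age)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ATLAS_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"atlas table missing columns: {missing}")
        levels = self.records["level"].astype(float)
        bad = ~levels.between(LEVEL_MIN, LEVEL_MAX)
        if bad.any():
            row = self.records[bad].iloc[0]
            raise ValidationError(
                f"atlas level {row['level']} outside [{LEVEL_MIN}, {LEVEL_MAX}] "
                f"for gene={row['gene']} structure={row['structure']} age={row['age']}"
            )
        self.records = self.records.assign(
            gene=self.records["gene"].map(normalize_symbol), level=levels
        )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.records["gene"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AtlasTable":
        return cls(records=pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AtlasCriteria:
    """Structure / level / age gates for the atlas filter."""

    structures: frozenset[str] = DEFAULT_STRUCTURES
    min_level: float = DEFAULT_MIN_LEVEL
    ages: frozenset[str] = DEFAULT_AGES

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValidationError("structures must be non-empty")
        if not self.ages:
            raise ValidationError("ages must be non-empty")
        object.__setattr__(self, "structures", frozenset(self.structures))
        object.__setattr__(self, "ages", frozenset(self.ages))


def filter_atlas(
    table: AtlasTable, genes: GeneSet, crit: AtlasCriteria = AtlasCriteria()
) -> tuple[GeneSet, GeneSet, GeneSet]:
    """Partition query genes into (pass, fail, no_data).

    pass: >= 1 record with structure in ``crit.structures``, level >=
    ``crit.min_level`` (inclusive) and age in ``crit.ages``.
    no_data: absent from the table entirely.  fail: present, never
    qualifying.  The three sets partition the query set.
    """
    rec = table.records
    qualifying = rec[
        rec["structure"].isin(crit.structures)
        & rec["age"].isin(crit.ages)
        & (rec["level"] >= crit.min_level)
    ]
    qualifying_genes = frozenset(qualifying["gene"])
    with_data = table.genes

    passed = genes.symbols & qualifying_genes
    no_data = genes.symbols - with_data
    failed = genes.symbols - passed - no_data
    return (
        GeneSet(name=f"{genes.name}|atlas_pass", symbols=passed),
        GeneSet(name=f"{genes.name}|atlas_fail", symbols=failed),
        GeneSet(name=f"{genes.name}|atlas_no_data", symbols=no_data),
    )


def coverage_report(table: AtlasTable, genes: GeneSet) -> tuple[int, int]:
    """Counts of query genes (with_data, without_data) in the table."""
    with_data = len(genes.symbols & table.genes)
    return with_data, len(genes) - with_data


def write_atlas_report(
    table: AtlasTable,
    passed: GeneSet,
    failed: GeneSet,
    no_data: GeneSet,
    crit: AtlasCriteria,
    path: str | Path,
) -> None:
    """TSV report: status per gene plus its qualifying records, if any."""
    rec = table.records
    qualifying = rec[
        rec["structure"].isin(crit.structures)
        & rec["age"].isin(crit.ages)
        & (rec["level"] >= crit.min_level)
    ]
    by_gene = {
        g: ";".join(f"{r.structure}@{r.age}={r.level:g}" for r in sub.itertuples())
        for g, sub in qualifying.groupby("gene")
    }
    rows = ["gene\tstatus\tqualifying_records"]
    for status, gs in (("pass", passed), ("fail", failed), ("no_data", no_data)):
        rows.extend(f"{g}\t{status}\t{by_gene.get(g, '')}" for g in sorted(gs.symbols))
    Path(path).write_text("\n".join(rows) + "\n")
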