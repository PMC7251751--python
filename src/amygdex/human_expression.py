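"""Developmental human brain expression: hemisphere averaging, per-period
medians, expression filtering, and variance summaries.

The expression matrix holds log2 intensities (genes x samples) with
per-sample metadata: region code, developmental period (integer 1-15),
hemisphere (L / R / NA) and donor.  The filter retains genes whose
amygdala expression in a developmental window rises above a log2
threshold; the threshold comparison is strict (">"), so a value exactly
at the threshold fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genesets import GeneSet, ValidationError, normalize_symbol

logger = logging.getLogger(__name__)

META_COLUMNS = ("region", "period", "hemisphere", "donor")

#: Developmental window defaults: early fetal (period 2) through
#: neonatal / early infancy (period 8).
DEFAULT_PERIOD_LO = 2
DEFAULT_PERIOD_HI = 8
DEFAULT_THRESHOLD = 6.0
DEFAULT_REGION = "AMY"


@dataclass
class DevExpressionMatrix:
    """Genes x samples log2 intensity matrix plus per-sample metadata.

    ``values``: DataFrame indexed by gene symbol, columns = sample ids.
    ``sample_meta``: DataFrame indexed by sample id with columns
    region, period, hemisphere, donor.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValidationError(f"sample_meta missing columns: {missing}")
        if list(self.values.columns) != list(self.sample_meta.index):
            # allow reordering, but every sample must have metadata
            unmatched = set(self.values.columns) - set(self.sample_meta.index)
            if unmatched:
                raise ValidationError(
                    f"samples without metadata: {sorted(unmatched)[:5]} ..."
                )
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression values must be finite")
        self.values.index = [normalize_symbol(g) for g in self.values.index]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def from_tsv(cls, expr_path: str | Path, meta_path: str | Path) -> "DevExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"period": int})
        return cls(values=values, sample_meta=meta)

    def to_tsv(self, expr_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(expr_path, sep="\t")
        self.sample_meta.to_csv(meta_path, sep="\t")


@dataclass
class PeriodProfile:
    """Per-gene median log2 intensity per developmental period.

    ``medians``: genes x periods DataFrame (columns are period ints).
    ``samples``: genes x hemisphere-averaged samples for the same region,
    kept so per-sample ("any_sample") filtering stays available.
    ``sample_periods``: period of each column of ``samples``.
    """

    medians: pd.DataFrame
    samples: pd.DataFrame
    sample_periods: pd.Series

    @property
    def periods(self) -> list[int]:
        return list(self.medians.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.medians.to_csv(path, sep="\t")


@dataclass(frozen=True)
class HumanFilterCriteria:
    """Window + threshold rule for calling a gene amygdala-expressed."""

    region: str = DEFAULT_REGION
    period_lo: int = DEFAULT_PERIOD_LO
    period_hi: int = DEFAULT_PERIOD_HI
    threshold: float = DEFAULT_THRESHOLD
    mode: str = "period_median"  # or "any_sample"

    def __post_init__(self) -> None:
        if self.period_lo > self.period_hi:
            raise ValidationError("period_lo must be <= period_hi")
        if not np.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")
        if self.mode not in ("period_median", "any_sample"):
            raise ValidationError(f"unknown mode {self.mode!r}")


def average_hemispheres(m: DevExpressionMatrix) -> DevExpressionMatrix:
    """Collapse hemisphere pairs to one value per (donor, region, period).

    Pairs are averaged arithmetically; samples with a single hemisphere
    pass through unchanged.  More than two samples for one
    (donor, region, period) is a validation error.
    """
    meta = m.sample_meta
    keys = list(zip(meta["donor"], meta["region"], meta["period"]))
    groups: dict[tuple, list[str]] = {}
    for sample, key in zip(meta.index, keys):
        groups.setdefault(key, []).append(sample)

    new_cols: dict[str, np.ndarray] = {}
    rows = []
    for (donor, region, period), samples in groups.items():
        if len(samples) > 2:
            raise ValidationError(
                f"more than 2 hemisphere entries for donor={donor} "
                f"region={region} period={period}: {samples}"
            )
        new_id = f"{donor}|{region}|P{period}"
        new_cols[new_id] = m.values[samples].mean(axis=1).to_numpy()
        rows.append((new_id, region, int(period), "NA", donor))

    values = pd.DataFrame(new_cols, index=m.values.index)
    sample_meta = pd.DataFrame(
        rows, columns=["sample", *META_COLUMNS]
    ).set_index("sample")
    return DevExpressionMatrix(values=values, sample_meta=sample_meta)


def summarize_by_period(m: DevExpressionMatrix, region: str = DEFAULT_REGION) -> PeriodProfile:
    """Per-gene, per-period median of hemisphere-averaged samples in ``region``.

    Medians over an even number of samples use the midpoint convention
    (numpy default).
    """
    if region not in set(m.sample_meta["region"]):
        raise ValidationError(f"region {region!r} absent from sample metadata")
    averaged = average_hemispheres(m)
    mask = averaged.sample_meta["region"] == region
    samples = averaged.values.loc[:, mask.to_numpy()]
    periods = averaged.sample_meta.loc[mask, "period"].astype(int)

    medians = {
        int(p): samples.loc[:, (periods == p).to_numpy()].median(axis=1)
        for p in sorted(periods.unique())
    }
    return PeriodProfile(
        medians=pd.DataFrame(medians),
        samples=samples,
        sample_periods=periods,
    )


def filter_expressed(profile: PeriodProfile, crit: HumanFilterCriteria) -> GeneSet:
    """Genes whose expression exceeds ``crit.threshold`` in the window.

    ``period_median`` mode: a gene passes iff its per-period median is
    strictly above the threshold in at least one period within
    [period_lo, period_hi].  ``any_sample`` mode: a gene passes iff any
    single hemisphere-averaged sample in the window exceeds it.
    """
    if profile.medians.empty:
        raise ValidationError("empty period profile")
    window = [p for p in profile.periods if crit.period_lo <= p <= crit.period_hi]
    if not window:
        raise ValidationError(
            f"no periods in [{crit.period_lo}, {crit.period_hi}] present in the profile"
        )
    if crit.mode == "period_median":
        passing = (profile.medians[window] > crit.threshold).any(axis=1)
    else:
        in_window = profile.sample_periods.between(crit.period_lo, crit.period_hi)
        sub = profile.samples.loc[:, in_window.to_numpy()]
        passing = (sub > crit.threshold).any(axis=1)
    symbols = frozenset(profile.medians.index[passing.to_numpy()])
    return GeneSet(name=f"expressed|{crit.region}", symbols=symbols)


def classify_genes(
    genes: GeneSet, profile: PeriodProfile, crit: HumanFilterCriteria
) -> tuple[GeneSet, GeneSet, GeneSet]:
    """Partition a query gene set into (passing, failing, no-data).

    Genes absent from the expression matrix land in the no-data bucket
    and are never counted as failures.
    """
    available = frozenset(profile.medians.index)
    no_data = genes.symbols - available
    queried = genes.symbols & available
    expressed = filter_expressed(profile, crit).symbols
    passed = queried & expressed
    failed = queried - expressed
    return (
        GeneSet(name=f"{genes.name}|pass", symbols=passed),
        GeneSet(name=f"{genes.name}|fail", symbols=failed),
        GeneSet(name=f"{genes.name}|no_data", symbols=no_data),
    )


def window_mean(profile: PeriodProfile, crit: HumanFilterCriteria) -> pd.Series:
    """Mean of per-period medians across the developmental window.

    Reported for reference only; it is not part of the pass criterion.
    """
    window = [p for p in profile.periods if crit.period_lo <= p <= crit.period_hi]
    if not window:
        raise ValidationError("no periods in window")
    return profile.medians[window].mean(axis=1)


def variance_summary(m: DevExpressionMatrix, subset: GeneSet | None = None) -> float:
    """Mean of per-gene sample variances (ddof=1) over a gene subset.

    ``subset=None`` uses the expressed background: all genes whose mean
    expression is > 0.  Subset genes missing from the matrix are skipped
    with a logged warning.
    """
    values = m.values
    if subset is None:
        expressed = values.mean(axis=1) > 0
        values = values.loc[expressed]
    else:
        present = [g for g in subset.symbols if g in values.index]
        missing = len(subset) - len(present)
        if missing:
            logger.warning(
                "variance_summary: %d of %d subset genes absent from matrix",
                missing,
                len(subset),
            )
        values = values.loc[present]
    if values.empty:
        raise ValidationError("no genes left to summarize")
    per_gene_var = values.var(axis=1, ddof=1)
    return float(per_gene_var.mean())


def write_filter_report(
    passed: GeneSet, failed: GeneSet, no_data: GeneSet, path: str | Path
) -> None:
    """TSV report with one row per query gene and its filter status."""
    rows = ["gene\tstatus"]
    for status, gs in (("pass", passed), ("fail", failed), ("no_data", no_data)):
        rows.extend(f"{g}\t{status}" for g in sorted(gs.symbols))
    Path(path).write_text("\n".join(rows) + "\n")
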