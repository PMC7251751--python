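"""Synthetic fixtures with the statistical structure the pipeline assumes.

Four generators: scored gene lists with a controlled overlap, a
developmental expression matrix with a designated passing gene set, a
long-form atlas table likewise, and a single-nucleus dataset drawn from
the same two-part (detection + positive level) process the DE stage
models, with donor random intercepts and optional planted effects.

Every generator is a pure function of its :class:`SimConfig` (and
explicit arguments): the same seed gives byte-identical output.  The
distributional shapes are an artifact choice for testing — they are not
a claim about any source dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit, logit

from .genesets import GeneSet, ScoredGeneList, ValidationError
from .human_expression import DevExpressionMatrix
from .mouse_atlas import (
    DEFAULT_AGES,
    DEFAULT_MIN_LEVEL,
    DEFAULT_STRUCTURES,
    LEVEL_MAX,
    LEVEL_MIN,
    AtlasTable,
)
from .sc_de import DEFAULT_SCALE_FACTOR, SnucDataset

#: (gene, cluster, log2 effect on the continuous part, logit effect on detection)
PlantedEffect = tuple[str, int, float, float]


@dataclass(frozen=True)
class SimConfig:
    """Knobs for all generators; seed fixed => byte-identical outputs."""

    seed: int = 0
    n_genes: int = 100
    n_samples_per_period: int = 6
    periods: tuple[int, ...] = tuple(range(1, 16))
    n_donors_per_group: int = 5
    n_cells_per_donor: int = 400
    n_clusters: int = 3
    planted_de: tuple[PlantedEffect, ...] = ()
    donor_sd: float = 0.02
    dropout_base: float = 0.25

    # artifact-level knobs (documented defaults, not sourced from data)
    both_hemisphere_fraction: float = 0.8
    expr_threshold: float = 6.0
    pass_window: tuple[int, int] = (2, 8)
    base_mean: float = 2.0
    resid_sd: float = 1.0
    planted_markers: tuple[PlantedEffect, ...] = ()

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples_per_period", "n_donors_per_group",
                     "n_cells_per_donor", "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.dropout_base <= 1.0:
            raise ValidationError("dropout_base must be in [0, 1]")
        if not 0.0 <= self.both_hemisphere_fraction <= 1.0:
            raise ValidationError("both_hemisphere_fraction must be in [0, 1]")
        if self.donor_sd < 0:
            raise ValidationError("donor_sd must be non-negative")
        if any(not 1 <= p <= 15 for p in self.periods):
            raise ValidationError("periods must lie in 1..15")


def gene_names(n: int, prefix: str = "G") -> list[str]:
    """Deterministic, seed-independent gene namespace: G000001, G000002, ..."""
    return [f"{prefix}{i + 1:06d}" for i in range(n)]


# ---------------------------------------------------------------------------
# scored gene lists
# ---------------------------------------------------------------------------


def gen_scored_genelists(
    config: SimConfig,
    size_a: int = 280,
    size_b: int = 102,
    overlap: int = 59,
    categories: tuple[str, ...] = ("S", "1", "2", "3"),
) -> tuple[ScoredGeneList, ScoredGeneList]:
    """Two scored lists with exactly the requested sizes and intersection."""
    if overlap > min(size_a, size_b):
        raise ValidationError(
            f"overlap ({overlap}) exceeds the smaller list ({min(size_a, size_b)})"
        )
    if min(size_a, size_b, overlap) < 0:
        raise ValidationError("sizes and overlap must be non-negative")
    total = size_a + size_b - overlap
    symbols = gene_names(total)
    shared = symbols[:overlap]
    only_a = symbols[overlap : size_a]
    only_b = symbols[size_a :]
    rng = np.random.default_rng(config.seed)

    def scored(name: str, members: list[str]) -> ScoredGeneList:
        cats = rng.choice(list(categories), size=len(members))
        return ScoredGeneList(name=name, entries=dict(zip(members, cats)))

    return scored("list_a", shared + only_a), scored("list_b", shared + only_b)


# ---------------------------------------------------------------------------
# developmental expression matrix
# ---------------------------------------------------------------------------


def gen_dev_expression(
    config: SimConfig,
    pass_genes: GeneSet | frozenset[str],
    genes: list[str] | None = None,
    region: str = "AMY",
) -> DevExpressionMatrix:
    """Expression matrix where exactly ``pass_genes`` clear the filter.

    Passing genes get one designated period inside ``config.pass_window``
    where every sample sits well above the threshold (so the per-period
    median does too); all other gene x sample values stay strictly below
    it.  A configurable fraction of (donor, period) samples carries both
    hemispheres; the rest alternate L/R deterministically.
    """
    if genes is None:
        genes = gene_names(config.n_genes)
    passing = set(pass_genes.symbols if isinstance(pass_genes, GeneSet) else pass_genes)
    unknown = passing - set(genes)
    if unknown:
        raise ValidationError(f"pass_genes outside the gene namespace: {sorted(unknown)[:5]}")
    window = [
        p for p in config.periods
        if config.pass_window[0] <= p <= config.pass_window[1]
    ]
    if passing and not window:
        raise ValidationError("no periods inside the pass window")

    rng = np.random.default_rng(config.seed + 1)
    thr = config.expr_threshold

    columns: list[str] = []
    meta_rows = []
    for period in config.periods:
        for j in range(config.n_samples_per_period):
            donor = f"D{period}_{j}"
            both = j < config.both_hemisphere_fraction * config.n_samples_per_period
            hemis = ("L", "R") if both else (("L",) if j % 2 == 0 else ("R",))
            for h in hemis:
                columns.append(f"{donor}_{h}")
                meta_rows.append((f"{donor}_{h}", region, period, h, donor))

    n_samples = len(columns)
    # baseline: everything clearly below threshold
    values = rng.uniform(thr - 2.5, thr - 0.6, size=(len(genes), n_samples))
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "region", "period", "hemisphere", "donor"]
    ).set_index("sample")
    period_of_col = meta["period"].to_numpy()

    pass_idx = [i for i, g in enumerate(genes) if g in passing]
    if pass_idx:
        chosen = rng.choice(window, size=len(pass_idx))
        for i, gene_period in zip(pass_idx, chosen):
            cols = period_of_col == gene_period
            values[i, cols] = rng.uniform(thr + 0.5, thr + 2.5, size=int(cols.sum()))

    return DevExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=columns),
        sample_meta=meta,
    )


# ---------------------------------------------------------------------------
# atlas table
# ---------------------------------------------------------------------------


def gen_atlas_table(
    config: SimConfig,
    pass_genes: GeneSet | frozenset[str],
    genes: list[str] | None = None,
    structures: frozenset[str] = DEFAULT_STRUCTURES,
    ages: frozenset[str] = DEFAULT_AGES,
    min_level: float = DEFAULT_MIN_LEVEL,
) -> AtlasTable:
    """Atlas records where exactly ``pass_genes`` meet the default criteria.

    Passing genes get one qualifying record (level drawn in
    [min_level, 3.5]) plus low-level noise records; failing genes get
    only sub-threshold levels at qualifying coordinates and, for half of
    them, a high level at a non-qualifying age.
    """
    if genes is None:
        genes = gene_names(config.n_genes)
    passing = set(pass_genes.symbols if isinstance(pass_genes, GeneSet) else pass_genes)
    unknown = passing - set(genes)
    if unknown:
        raise ValidationError(f"pass_genes outside the gene namespace: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(config.seed + 2)
    structures_list = sorted(structures)
    ages_list = sorted(ages)
    rows = []
    for i, gene in enumerate(genes):
        structure = structures_list[int(rng.integers(len(structures_list)))]
        age = ages_list[int(rng.integers(len(ages_list)))]
        if gene in passing:
            level = float(rng.uniform(min_level, LEVEL_MAX))
            rows.append((gene, structure, age, level))
            # plus a sub-threshold record elsewhere
            rows.append((gene, structure, ages_list[0], float(rng.uniform(LEVEL_MIN, 0.0))))
        else:
            rows.append((gene, structure, age, float(rng.uniform(LEVEL_MIN, min_level - 0.1))))
            if i % 2 == 0:
                # strong expression, but at an age outside the criteria
                rows.append((gene, structure, "P14", float(rng.uniform(min_level, LEVEL_MAX))))
    return AtlasTable(records=pd.DataFrame(rows, columns=["gene", "structure", "age", "level"]))


# ---------------------------------------------------------------------------
# single-nucleus dataset
# ---------------------------------------------------------------------------


def gen_snuc_dataset(config: SimConfig, counts: bool = False) -> SnucDataset:
    """Single-nucleus dataset from a two-part generative process.

    Detection is Bernoulli with a logit linear in diagnosis plus a donor
    random intercept; the positive level is Gaussian on the normalized
    log2 scale with mean linear in diagnosis (and carrying the
    age/sex/RIN/PMI covariates in the metadata) plus an independent
    donor random intercept.  Genes without planted effects have zero
    diagnosis effect in both parts.  ``counts=True`` back-transforms the
    simulated values through a Poisson draw to genuine UMI counts for
    end-to-end MTX testing.
    """
    if config.n_donors_per_group < 2:
        raise ValidationError("need at least 2 donors per group")
    genes = gene_names(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for effect_list, label in ((config.planted_de, "planted_de"),
                               (config.planted_markers, "planted_markers")):
        for gene, cluster, _, _ in effect_list:
            if gene not in gene_index:
                raise ValidationError(f"{label}: unknown gene {gene!r}")
            if not 1 <= cluster <= config.n_clusters:
                raise ValidationError(f"{label}: cluster {cluster} out of range")

    rng = np.random.default_rng(config.seed + 3)
    n_donors = 2 * config.n_donors_per_group
    donors = [f"A{i + 1}" for i in range(config.n_donors_per_group)] + [
        f"C{i + 1}" for i in range(config.n_donors_per_group)
    ]
    diagnosis = ["ASD"] * config.n_donors_per_group + ["control"] * config.n_donors_per_group
    ages = rng.uniform(4.0, 20.0, size=n_donors)
    sexes = np.where(np.arange(n_donors) % 2 == 0, "M", "F")
    rins = rng.uniform(6.5, 8.5, size=n_donors)
    pmis = rng.uniform(10.0, 30.0, size=n_donors)

    n_cells = n_donors * config.n_cells_per_donor
    donor_of_cell = np.repeat(np.arange(n_donors), config.n_cells_per_donor)
    cluster_of_cell = rng.integers(1, config.n_clusters + 1, size=n_cells)
    is_asd = np.repeat(np.array([d == "ASD" for d in diagnosis]), config.n_cells_per_donor)

    meta = pd.DataFrame(
        {
            "donor": np.array(donors)[donor_of_cell],
            "diagnosis": np.array(diagnosis)[donor_of_cell],
            "cluster": cluster_of_cell,
            "age": ages[donor_of_cell],
            "sex": sexes[donor_of_cell],
            "RIN": rins[donor_of_cell],
            "PMI": pmis[donor_of_cell],
        },
        index=[f"cell{i:06d}" for i in range(n_cells)],
    )

    det_base = logit(1.0 - config.dropout_base) if config.dropout_base > 0 else 12.0

    de_by_gene: dict[int, list[PlantedEffect]] = {}
    for gene, cluster, cont_eff, det_eff in config.planted_de:
        de_by_gene.setdefault(gene_index[gene], []).append((gene, cluster, cont_eff, det_eff))
    mk_by_gene: dict[int, list[PlantedEffect]] = {}
    for gene, cluster, cont_eff, det_eff in config.planted_markers:
        mk_by_gene.setdefault(gene_index[gene], []).append((gene, cluster, cont_eff, det_eff))

    values = np.zeros((config.n_genes, n_cells))
    for gi in range(config.n_genes):
        b_det = rng.normal(0.0, config.donor_sd, size=n_donors)
        b_cont = rng.normal(0.0, config.donor_sd, size=n_donors)
        eta = det_base + b_det[donor_of_cell]
        mu = config.base_mean + b_cont[donor_of_cell]
        if gi in de_by_gene:
            for _, cluster, cont_eff, det_eff in de_by_gene[gi]:
                affected = is_asd & (cluster_of_cell == cluster)
                eta = np.where(affected, eta + det_eff, eta)
                mu = np.where(affected, mu + cont_eff, mu)
        if gi in mk_by_gene:
            for _, cluster, cont_eff, det_eff in mk_by_gene[gi]:
                in_cluster = cluster_of_cell == cluster
                eta = np.where(in_cluster, eta + det_eff, eta)
                mu = np.where(in_cluster, mu + cont_eff, mu)
        detected = rng.random(n_cells) < expit(eta)
        level = rng.normal(mu, config.resid_sd)
        values[gi] = np.where(detected, np.maximum(level, 0.01), 0.0)

    if not counts:
        return SnucDataset(
            genes=genes, cell_meta=meta, normalized=sp.csr_matrix(values)
        )

    # count-level generator: invert the log2(1 + c * scale/total) transform
    totals = rng.lognormal(mean=np.log(5000.0), sigma=0.25, size=n_cells)
    rates = (2.0**values - 1.0) * totals[None, :] / DEFAULT_SCALE_FACTOR
    count_mat = rng.poisson(rates).astype(float)
    count_mat[values == 0.0] = 0.0
    return SnucDataset(genes=genes, cell_meta=meta, counts=sp.csr_matrix(count_mat))


# ---------------------------------------------------------------------------
# fixture writers
# ---------------------------------------------------------------------------


def write_genelists(lists: tuple[ScoredGeneList, ScoredGeneList], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for gl in lists:
        gl.to_tsv(out / f"{gl.name}.tsv")


def write_dev_expression(m: DevExpressionMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m.to_tsv(out / "expression.tsv", out / "sample_meta.tsv")


def write_atlas(table: AtlasTable, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_tsv(out / "atlas.tsv")


def write_snuc(dataset: SnucDataset, out_dir: str | Path) -> None:
    dataset.to_mtx_dir(out_dir)
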