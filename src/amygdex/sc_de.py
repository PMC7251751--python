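"""Single-nucleus differential expression via a two-part hurdle model.

The workflow: normalize UMI counts to ``log2(1 + count * scale / total)``,
then per cluster and per gene fit a hurdle model — a logistic component
for detection and a Gaussian component for the positive expression
level, each with the diagnosis/covariate fixed effects and a donor
random intercept — and test the diagnosis term with a likelihood-ratio
test over the components actually fitted.  Calls combine a BH FDR gate
with a fold-change gate evaluated under both the full and a simplified
(diagnosis-only) model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.special import expit
from scipy.stats import chi2

from . import mixed
from .genesets import GeneSet, ValidationError, normalize_symbol, overlap_test

logger = logging.getLogger(__name__)

CELL_META_COLUMNS = ("donor", "diagnosis", "cluster", "age", "sex", "RIN", "PMI")
DEFAULT_SCALE_FACTOR = 10_000
DEFAULT_FDR_CUT = 0.05
DEFAULT_FC_CUT = 0.10
DEFAULT_MIN_DETECT = 0.01


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class SnucDataset:
    """Genes x cells UMI counts (or pre-normalized values) plus cell metadata.

    Either ``counts`` (sparse, non-negative integers) or ``normalized``
    (values already on the log2(1 + scaled) scale) must be present.
    """

    genes: list[str]
    cell_meta: pd.DataFrame
    counts: sp.spmatrix | None = None
    normalized: sp.spmatrix | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CELL_META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValidationError(f"cell_meta missing columns: {missing}")
        if self.counts is None and self.normalized is None:
            raise ValidationError("need counts or normalized values")
        mat = self.counts if self.counts is not None else self.normalized
        if mat.shape != (len(self.genes), len(self.cell_meta)):
            raise ValidationError(
                f"matrix shape {mat.shape} != (n_genes={len(self.genes)}, "
                f"n_cells={len(self.cell_meta)})"
            )
        if self.counts is not None:
            data = self.counts.data if sp.issparse(self.counts) else self.counts
            arr = np.asarray(data)
            if arr.size and (np.any(arr < 0) or np.any(arr != np.round(arr))):
                raise ValidationError("counts must be non-negative integers")
        self.genes = [normalize_symbol(g) for g in self.genes]

    @property
    def n_cells(self) -> int:
        return len(self.cell_meta)

    @classmethod
    def from_mtx_dir(cls, directory: str | Path) -> "SnucDataset":
        """Read a 10x-style triplet: matrix.mtx, genes.tsv, cell_meta.tsv."""
        directory = Path(directory)
        counts = sp.csr_matrix(mmread(directory / "matrix.mtx"))
        genes = [
            line.split("\t")[0].strip()
            for line in (directory / "genes.tsv").read_text().splitlines()
            if line.strip()
        ]
        meta = pd.read_csv(directory / "cell_meta.tsv", sep="\t", index_col=0)
        return cls(genes=genes, cell_meta=meta, counts=counts)

    def to_mtx_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.counts is not None:
            mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(self.counts))
        else:
            mmwrite(str(directory / "normalized.mtx"), sp.coo_matrix(self.normalized))
        (directory / "genes.tsv").write_text("\n".join(self.genes) + "\n")
        self.cell_meta.to_csv(directory / "cell_meta.tsv", sep="\t")


@dataclass
class NormalizedMatrix:
    """Genes x cells values on the log2(1 + scaled count) scale."""

    values: sp.csr_matrix
    genes: list[str]
    cell_meta: pd.DataFrame
    scale_factor: int = DEFAULT_SCALE_FACTOR

    def gene_vector(self, gene_index: int) -> np.ndarray:
        return np.asarray(self.values.getrow(gene_index).todense()).ravel()


def normalize(d: SnucDataset, scale_factor: int = DEFAULT_SCALE_FACTOR) -> NormalizedMatrix:
    """Depth-normalize and log-transform: log2(1 + count * scale / total).

    Zeros stay exactly zero (sparsity preserved).  Cells with zero total
    count are dropped with a logged warning.
    """
    if d.counts is None:
        return NormalizedMatrix(
            values=sp.csr_matrix(d.normalized),
            genes=d.genes,
            cell_meta=d.cell_meta,
            scale_factor=scale_factor,
        )
    counts = sp.csc_matrix(d.counts, dtype=float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    keep = totals > 0
    meta = d.cell_meta
    if not keep.all():
        dropped = int((~keep).sum())
        logger.warning("normalize: dropping %d cells with zero total counts", dropped)
        counts = counts[:, keep]
        totals = totals[keep]
        meta = meta.loc[keep]
    norm = counts.multiply(scale_factor / totals[None, :]).tocsr()
    norm.data = np.log2(1.0 + norm.data)
    return NormalizedMatrix(
        values=norm, genes=d.genes, cell_meta=meta, scale_factor=scale_factor
    )


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HurdleModelSpec:
    """Fixed effects, random grouping and fitting options for the hurdle model."""

    fixed: tuple[str, ...] = ("diagnosis", "age", "sex", "RIN", "PMI")
    group: str = "donor"
    test_term: str = "diagnosis"
    simplified: bool = False  # diagnosis-only fixed effects
    mixed: bool = True  # donor random intercepts in both components
    min_detect: float = DEFAULT_MIN_DETECT
    n_quad: int = 9

    def __post_init__(self) -> None:
        if self.test_term not in self.fixed:
            raise ValidationError("test_term must be among the fixed effects")


@dataclass
class Design:
    """Design matrices and donor codes shared by all genes in a cluster."""

    X_full: np.ndarray
    X_reduced: np.ndarray
    names: list[str]
    test_col: int
    groups: np.ndarray  # donor codes per cell
    n_groups: int

    # discrete-part collapse is y-independent: precompute the row mapping
    def __post_init__(self) -> None:
        stacked = np.column_stack([self.groups.astype(float), self.X_full])
        uniq, inv = np.unique(stacked, axis=0, return_inverse=True)
        self._row_of_cell = inv
        self._Xr_full = uniq[:, 1:]
        self._gr = uniq[:, 0].astype(int)
        self._n = np.bincount(inv).astype(float)
        keep = [i for i in range(self.X_full.shape[1]) if i != self.test_col]
        self._Xr_reduced = self._Xr_full[:, keep]

    def binomial_rows(self, detected: np.ndarray):
        k = np.bincount(self._row_of_cell, weights=detected.astype(float))
        return self._Xr_full, self._Xr_reduced, self._gr, k, self._n


def build_design(meta: pd.DataFrame, spec: HurdleModelSpec) -> Design:
    """Build full/reduced design matrices from per-cell metadata.

    Diagnosis is coded 0 = control (reference), 1 = ASD; sex as a binary
    factor; continuous covariates (age, RIN, PMI, ...) are centered and
    scaled.  Zero-variance covariates are dropped with a warning.
    """
    fixed = ("diagnosis",) if spec.simplified else spec.fixed
    cols: list[np.ndarray] = [np.ones(len(meta))]
    names = ["intercept"]
    for term in fixed:
        if term == "diagnosis":
            vals = meta["diagnosis"].astype(str).str.upper()
            col = (vals == "ASD").astype(float).to_numpy()
        elif term == "sex":
            levels = sorted(meta["sex"].astype(str).unique())
            col = (meta["sex"].astype(str) == levels[-1]).astype(float).to_numpy()
        else:
            raw = meta[term].astype(float).to_numpy()
            sd = raw.std()
            if sd == 0:
                logger.warning("dropping zero-variance covariate %r", term)
                continue
            col = (raw - raw.mean()) / sd
        if term != "diagnosis" and np.all(col == col[0]):
            logger.warning("dropping constant covariate %r", term)
            continue
        cols.append(col)
        names.append(term)
    X_full = np.column_stack(cols)
    if spec.test_term not in names:
        raise ValidationError(f"test term {spec.test_term!r} missing from design")
    test_col = names.index(spec.test_term)
    keep = [i for i in range(X_full.shape[1]) if i != test_col]
    donors, groups = np.unique(meta[spec.group].astype(str), return_inverse=True)
    return Design(
        X_full=X_full,
        X_reduced=X_full[:, keep],
        names=names,
        test_col=test_col,
        groups=groups,
        n_groups=len(donors),
    )


# ---------------------------------------------------------------------------
# hurdle fitting
# ---------------------------------------------------------------------------


@dataclass
class HurdleFit:
    """Fitted two-part model for one gene (one side of full vs reduced)."""

    discrete: mixed.MixedFit | None
    continuous: mixed.MixedFit | None
    names: list[str]
    test_col: int | None  # None for a reduced fit
    fit_status: str  # mixed | fixed_fallback | failed
    n_cells: int
    n_pos: int
    pos_mean: float

    @property
    def loglik(self) -> float:
        total = 0.0
        for part in (self.discrete, self.continuous):
            if part is not None:
                total += part.loglik
        return total

    @property
    def n_components(self) -> int:
        return sum(part is not None for part in (self.discrete, self.continuous))


def _failed_fit(n_cells: int = 0, n_pos: int = 0) -> HurdleFit:
    return HurdleFit(
        discrete=None,
        continuous=None,
        names=[],
        test_col=None,
        fit_status="failed",
        n_cells=n_cells,
        n_pos=n_pos,
        pos_mean=float("nan"),
    )


def _fit_parts(
    y: np.ndarray,
    detected: np.ndarray,
    design: Design,
    reduced: bool,
    use_mixed: bool,
    n_quad: int,
    fit_discrete: bool,
    fit_continuous: bool,
) -> tuple[mixed.MixedFit | None, mixed.MixedFit | None]:
    disc = cont = None
    if fit_discrete:
        Xr_full, Xr_red, gr, k, n = design.binomial_rows(detected)
        Xr = Xr_red if reduced else Xr_full
        if use_mixed:
            disc = mixed.fit_logistic_mixed(Xr, gr, k, n, n_quad=n_quad)
        else:
            disc = mixed.fit_logistic_fixed(Xr, k, n)
    if fit_continuous:
        pos = detected
        Xc = (design.X_reduced if reduced else design.X_full)[pos]
        yc = y[pos]
        if use_mixed:
            cont = mixed.fit_lmm(Xc, yc, design.groups[pos])
        else:
            cont = mixed.fit_ols(Xc, yc)
    return disc, cont


def fit_hurdle(
    y: np.ndarray,
    meta: pd.DataFrame,
    spec: HurdleModelSpec = HurdleModelSpec(),
    design: Design | None = None,
    need_reduced: bool = True,
) -> tuple[HurdleFit, HurdleFit]:
    """Fit the full and reduced (minus the test term) hurdle models.

    ``y`` is the normalized expression vector for one gene across the
    cells of one cluster; zeros mean not detected.  Degenerate parts are
    dropped: the discrete part when every cell is detected, the
    continuous part when there are too few or constant positive values.
    Genes with insufficient detection or fewer than two donors per
    diagnosis group come back with ``fit_status='failed'``.
    """
    y = np.asarray(y, float)
    detected = y > 0
    n_cells = len(y)
    n_pos = int(detected.sum())

    diag = meta["diagnosis"].astype(str).str.upper()
    donors_per_group = meta.groupby(diag)[spec.group].nunique()
    if len(donors_per_group) < 2 or (donors_per_group < 2).any():
        return _failed_fit(n_cells, n_pos), _failed_fit(n_cells, n_pos)
    if n_pos < max(1, spec.min_detect * n_cells):
        return _failed_fit(n_cells, n_pos), _failed_fit(n_cells, n_pos)

    if design is None:
        design = build_design(meta, spec)

    p_dim = design.X_full.shape[1]
    fit_discrete = n_pos < n_cells  # all-detected -> uninformative
    pos_values = y[detected]
    fit_continuous = n_pos >= p_dim + 3 and float(np.var(pos_values)) > 1e-12
    if not fit_discrete and not fit_continuous:
        return _failed_fit(n_cells, n_pos), _failed_fit(n_cells, n_pos)

    pos_mean = float(pos_values.mean()) if n_pos else float("nan")

    def _both(use_mixed: bool) -> tuple[HurdleFit, HurdleFit]:
        status = "mixed" if use_mixed else "fixed_fallback"
        fits = []
        for reduced in ((False, True) if need_reduced else (False,)):
            disc, cont = _fit_parts(
                y, detected, design, reduced, use_mixed, spec.n_quad,
                fit_discrete, fit_continuous,
            )
            fits.append(
                HurdleFit(
                    discrete=disc,
                    continuous=cont,
                    names=design.names,
                    test_col=None if reduced else design.test_col,
                    fit_status=status,
                    n_cells=n_cells,
                    n_pos=n_pos,
                    pos_mean=pos_mean,
                )
            )
        return (fits[0], fits[1]) if need_reduced else (fits[0], fits[0])

    if spec.mixed:
        full, reduced = _both(use_mixed=True)
        parts = [p for f in (full, reduced) for p in (f.discrete, f.continuous) if p]
        if all(p.converged for p in parts):
            return full, reduced
        logger.warning("mixed fit did not converge; falling back to fixed effects")
    return _both(use_mixed=False)


def lrt_diagnosis(full: HurdleFit, reduced: HurdleFit) -> tuple[float, int, float]:
    """Likelihood-ratio test for the diagnosis term.

    Sums the statistic over the hurdle components actually fitted; df is
    the number of diagnosis parameters removed (one per component).
    Comparing fits of different status (mixed vs fixed) is an error.
    """
    if full.fit_status == "failed" or reduced.fit_status == "failed":
        raise ValidationError("cannot run LRT on a failed fit")
    if full.fit_status != reduced.fit_status:
        raise ValidationError(
            f"mismatched fit statuses: {full.fit_status} vs {reduced.fit_status}"
        )
    if full.n_components != reduced.n_components:
        raise ValidationError("full and reduced fits have different components")
    df = full.n_components
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


# ---------------------------------------------------------------------------
# fold change and DE calls
# ---------------------------------------------------------------------------


def predicted_group_means(fit: HurdleFit) -> tuple[float, float]:
    """Model-predicted mean normalized expression (control, ASD).

    Detection probability times conditional mean, with continuous
    covariates at their (centered) means, factors at reference levels
    and the random intercept at zero.
    """
    if fit.test_col is None:
        raise ValidationError("predictions require a full (test-term) fit")
    means = []
    for group_value in (0.0, 1.0):
        x = np.zeros(len(fit.names))
        x[0] = 1.0  # intercept
        x[fit.test_col] = group_value
        if fit.discrete is not None:
            p_det = float(expit(x @ fit.discrete.beta))
        else:
            p_det = 1.0
        if fit.continuous is not None:
            level = float(x @ fit.continuous.beta)
        else:
            level = fit.pos_mean
        means.append(p_det * level)
    return means[0], means[1]


@dataclass(frozen=True)
class FoldChange:
    """Diagnosis effect on predicted expression, full and simplified models."""

    log2_fc: float  # full model
    pct_change: float
    log2_fc_simplified: float
    pct_change_simplified: float

    def passes_gate(self, fc_cut: float = DEFAULT_FC_CUT) -> bool:
        """Both the full and the simplified estimates must clear the cut."""
        return (
            abs(self.pct_change) >= fc_cut
            and abs(self.pct_change_simplified) >= fc_cut
        )


def fold_change(full: HurdleFit, simplified: HurdleFit) -> FoldChange:
    """log2 fold change and linear-scale percent change, both models.

    Values are on the log2 normalized scale, so the difference of the
    predicted means is itself a log2 fold change; the percent change is
    ``2**log2_fc - 1``.
    """
    out = []
    for fit in (full, simplified):
        mu_ctrl, mu_asd = predicted_group_means(fit)
        lfc = mu_asd - mu_ctrl
        if not np.isfinite(lfc):
            raise ValidationError("non-finite fold-change prediction")
        out.append((lfc, float(2.0**lfc - 1.0)))
    return FoldChange(
        log2_fc=out[0][0],
        pct_change=out[0][1],
        log2_fc_simplified=out[1][0],
        pct_change_simplified=out[1][1],
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up).  NaNs stay NaN."""
    p = np.asarray(p_values, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(q, 1.0)
    out[ok] = adj
    return out


@dataclass
class DEResult:
    """One differential-expression test: a (gene, cluster) pair."""

    gene: str
    cluster: int | str
    log2_fc: float
    pct_change: float
    lrt_stat: float
    df: int
    p_value: float
    fdr: float
    is_de: bool
    fit_status: str
    pct_change_simplified: float = float("nan")


def call_de(
    results: list[DEResult],
    fdr_cut: float = DEFAULT_FDR_CUT,
    fc_cut: float = DEFAULT_FC_CUT,
) -> list[DEResult]:
    """Apply BH FDR within the cluster and the FDR x fold-change gate.

    ``is_de`` requires FDR below the cut AND at least ``fc_cut`` percent
    change under both the full and simplified models.
    """
    p = np.array([r.p_value for r in results], float)
    fdr = bh_fdr(p)
    called = []
    for r, q in zip(results, fdr):
        gate = (
            np.isfinite(q)
            and q < fdr_cut
            and abs(r.pct_change) >= fc_cut
            and abs(r.pct_change_simplified) >= fc_cut
        )
        called.append(replace(r, fdr=float(q), is_de=bool(gate)))
    return called


def de_analysis(
    dataset: SnucDataset,
    clusters: list | None = None,
    spec: HurdleModelSpec = HurdleModelSpec(),
    fdr_cut: float = DEFAULT_FDR_CUT,
    fc_cut: float = DEFAULT_FC_CUT,
    scale_factor: int = DEFAULT_SCALE_FACTOR,
    fdr_scope: str = "cluster",
    genes: list[str] | None = None,
) -> list[DEResult]:
    """Full DE workflow: normalize, fit per cluster x gene, test, call.

    ``fdr_scope`` is "cluster" (default: BH within each cluster) or
    "global" (one BH correction across all tests).
    """
    if fdr_scope not in ("cluster", "global"):
        raise ValidationError(f"unknown fdr_scope {fdr_scope!r}")
    norm = normalize(dataset, scale_factor)
    meta = norm.cell_meta
    if clusters is None:
        clusters = sorted(meta["cluster"].unique())
    gene_idx = range(len(norm.genes))
    if genes is not None:
        wanted = {normalize_symbol(g) for g in genes}
        gene_idx = [i for i, g in enumerate(norm.genes) if g in wanted]

    simplified_spec = replace(spec, simplified=True)
    all_results: list[DEResult] = []
    for cluster in clusters:
        cells = (meta["cluster"] == cluster).to_numpy()
        meta_c = meta.loc[cells]
        sub = sp.csc_matrix(norm.values)[:, cells].tocsr()
        try:
            design = build_design(meta_c, spec)
            design_s = build_design(meta_c, simplified_spec)
        except ValidationError as err:
            logger.warning("cluster %s: cannot build design (%s)", cluster, err)
            continue
        cluster_results: list[DEResult] = []
        for i in gene_idx:
            y = np.asarray(sub.getrow(i).todense()).ravel()
            n_pos = int((y > 0).sum())
            if n_pos < max(1, spec.min_detect * len(y)):
                continue  # below the detection floor: not tested
            full, reduced = fit_hurdle(y, meta_c, spec, design=design)
            if full.fit_status == "failed":
                cluster_results.append(
                    DEResult(
                        gene=norm.genes[i], cluster=cluster,
                        log2_fc=float("nan"), pct_change=float("nan"),
                        lrt_stat=float("nan"), df=0, p_value=float("nan"),
                        fdr=float("nan"), is_de=False, fit_status="failed",
                    )
                )
                continue
            simp_full, _ = fit_hurdle(
                y, meta_c, simplified_spec, design=design_s, need_reduced=False
            )
            try:
                stat, df, p = lrt_diagnosis(full, reduced)
                fc = fold_change(full, simp_full)
            except ValidationError:
                cluster_results.append(
                    DEResult(
                        gene=norm.genes[i], cluster=cluster,
                        log2_fc=float("nan"), pct_change=float("nan"),
                        lrt_stat=float("nan"), df=0, p_value=float("nan"),
                        fdr=float("nan"), is_de=False, fit_status="failed",
                    )
                )
                continue
            cluster_results.append(
                DEResult(
                    gene=norm.genes[i], cluster=cluster,
                    log2_fc=fc.log2_fc, pct_change=fc.pct_change,
                    lrt_stat=stat, df=df, p_value=p,
                    fdr=float("nan"), is_de=False, fit_status=full.fit_status,
                    pct_change_simplified=fc.pct_change_simplified,
                )
            )
        if fdr_scope == "cluster":
            cluster_results = call_de(cluster_results, fdr_cut, fc_cut)
        all_results.extend(cluster_results)
    if fdr_scope == "global":
        all_results = call_de(all_results, fdr_cut, fc_cut)
    return all_results


def de_event_counts(results: list[DEResult]) -> tuple[int, int]:
    """(number of DE events, number of distinct DE genes)."""
    events = [(r.gene, r.cluster) for r in results if r.is_de]
    return len(events), len({g for g, _ in events})


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------


@dataclass
class MarkerResult:
    """One-vs-rest enrichment of a gene in a cluster."""

    gene: str
    cluster: int | str
    log2_enrichment: float
    lrt_stat: float
    df: int
    p_value: float
    fdr: float
    is_marker: bool


def _binom_ll(k: float, n: float) -> float:
    """Binomial log-likelihood kernel at the MLE p = k/n (0 log 0 = 0)."""
    if n == 0:
        return 0.0
    ll = 0.0
    if k > 0:
        ll += k * np.log(k / n)
    if n - k > 0:
        ll += (n - k) * np.log(1.0 - k / n)
    return float(ll)


def _gauss_ll(sse: float, n: float) -> float:
    """Gaussian ML log-likelihood given the residual sum of squares."""
    sigma2 = max(sse / n, 1e-12)
    return float(-0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0))


def markers(
    dataset: SnucDataset,
    cluster: int | str,
    min_detect: float = DEFAULT_MIN_DETECT,
    fdr_cut: float = DEFAULT_FDR_CUT,
    scale_factor: int = DEFAULT_SCALE_FACTOR,
    norm: NormalizedMatrix | None = None,
) -> list[MarkerResult]:
    """Hurdle test of the cluster indicator vs all other cells.

    No covariates and no random effect, so both components have
    closed-form MLEs.  Enrichment is the difference of predicted means
    (detection rate x positive-level mean) on the log2 scale; markers
    are positive enrichments with FDR below the cut.
    """
    if norm is None:
        norm = normalize(dataset, scale_factor)
    in_cluster = (norm.cell_meta["cluster"] == cluster).to_numpy()
    if in_cluster.sum() == 0 or in_cluster.sum() == len(in_cluster):
        raise ValidationError(f"cluster {cluster!r} empty or covering all cells")

    out: list[MarkerResult] = []
    for i, gene in enumerate(norm.genes):
        y = norm.gene_vector(i)
        det = y > 0
        if det.mean() < min_detect:
            continue
        stat = 0.0
        df = 0
        k1, n1 = float(det[in_cluster].sum()), float(in_cluster.sum())
        k0, n0 = float(det[~in_cluster].sum()), float((~in_cluster).sum())
        if 0 < k1 + k0 < n1 + n0:  # discrete part informative
            ll_full = _binom_ll(k1, n1) + _binom_ll(k0, n0)
            ll_red = _binom_ll(k1 + k0, n1 + n0)
            stat += 2.0 * (ll_full - ll_red)
            df += 1
        pos1 = y[in_cluster & det]
        pos0 = y[~in_cluster & det]
        m1 = float(pos1.mean()) if pos1.size else 0.0
        m0 = float(pos0.mean()) if pos0.size else 0.0
        if pos1.size >= 2 and pos0.size >= 2:
            pos_all = np.concatenate([pos1, pos0])
            sse_full = float(((pos1 - m1) ** 2).sum() + ((pos0 - m0) ** 2).sum())
            sse_red = float(((pos_all - pos_all.mean()) ** 2).sum())
            stat += 2.0 * (_gauss_ll(sse_full, pos_all.size) - _gauss_ll(sse_red, pos_all.size))
            df += 1
        if df == 0:
            continue
        p = float(chi2.sf(max(stat, 0.0), df))
        enrich = (k1 / n1) * m1 - (k0 / n0) * m0
        out.append(
            MarkerResult(
                gene=gene, cluster=cluster, log2_enrichment=enrich,
                lrt_stat=max(stat, 0.0), df=df, p_value=p,
                fdr=float("nan"), is_marker=False,
            )
        )
    fdr = bh_fdr(np.array([r.p_value for r in out]))
    for r, q in zip(out, fdr):
        r.fdr = float(q)
        r.is_marker = bool(np.isfinite(q) and q < fdr_cut and r.log2_enrichment > 0)
    return out


# ---------------------------------------------------------------------------
# cell-type-resolved gene-set overlap
# ---------------------------------------------------------------------------


def celltype_overlap(
    de_results: list[DEResult],
    sets: list[GeneSet],
    universe: int = 20_000,
) -> pd.DataFrame:
    """Overlap of per-cluster DE genes with candidate gene sets.

    One row per (cluster, gene set): intersecting symbols and a
    hypergeometric enrichment p-value against the stated universe.
    """
    rows = []
    clusters = sorted({r.cluster for r in de_results}, key=str)
    for cluster in clusters:
        de_genes = frozenset(r.gene for r in de_results if r.cluster == cluster and r.is_de)
        de_set = GeneSet(name=f"de_cluster_{cluster}", symbols=de_genes)
        for gs in sets:
            inter = de_genes & gs.symbols
            if de_genes or gs.symbols:
                res = overlap_test(de_set, gs, universe=universe)
                p = res.p_value
            else:
                p = 1.0
            rows.append(
                {
                    "cluster": cluster,
                    "gene_set": gs.name,
                    "n_de": len(de_genes),
                    "n_set": len(gs),
                    "overlap": len(inter),
                    "symbols": ",".join(sorted(inter)),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_de_table(results: list[DEResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": r.gene, "cluster": r.cluster, "log2_fc": r.log2_fc,
                "pct_change": r.pct_change, "lrt_stat": r.lrt_stat, "df": r.df,
                "p_value": r.p_value, "fdr": r.fdr, "is_de": r.is_de,
                "fit_status": r.fit_status,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def write_marker_table(results: list[MarkerResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": r.gene, "cluster": r.cluster,
                "log2_enrichment": r.log2_enrichment, "lrt_stat": r.lrt_stat,
                "df": r.df, "p_value": r.p_value, "fdr": r.fdr,
                "is_marker": r.is_marker,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
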