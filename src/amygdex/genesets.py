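"""Scored gene lists, evidence-category filtering, set integration, and
overlap enrichment.

Gene symbols are normalized to uppercase with surrounding whitespace
stripped; no alias resolution is attempted.  The overlap test is a
one-sided hypergeometric enrichment test, ``P(X >= k)``, with the tail
sum accumulated in log space so that extremely small p-values (down to
~1e-300) remain finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

#: Allowed evidence-score categories, SFARI-style: S (syndromic) plus 1-6.
CATEGORIES = frozenset({"S", "1", "2", "3", "4", "5", "6"})

#: Default categories retained by the high-confidence filter.
HIGH_CONFIDENCE = frozenset({"S", "1", "2", "3"})

#: Default gene universe for enrichment tests (~protein-coding genome).
DEFAULT_UNIVERSE = 20_000


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol."""
    return symbol.strip().upper()


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ScoredGeneList:
    """A named list of gene symbols with evidence-score categories."""

    name: str
    entries: dict[str, str]

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        for symbol, category in self.entries.items():
            category = str(category).strip().upper()
            if category not in CATEGORIES:
                raise ValidationError(
                    f"unknown category {category!r} for symbol {symbol!r}; "
                    f"allowed: {sorted(CATEGORIES)}"
                )
            normalized[normalize_symbol(symbol)] = category
        self.entries = normalized

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "ScoredGeneList":
        """Read a 2-column TSV of (symbol, category); '#' lines are comments."""
        path = Path(path)
        entries: dict[str, str] = {}
        for line_no, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{line_no}: expected 2 tab-separated columns, got {len(parts)}"
                )
            entries[parts[0]] = parts[1]
        return cls(name=name or path.stem, entries=entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{s}\t{c}" for s, c in sorted(self.entries.items())]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class GeneSet:
    """A named set of normalized gene symbols."""

    name: str
    symbols: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "symbols", frozenset(normalize_symbol(s) for s in self.symbols)
        )

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbols

    @classmethod
    def from_iterable(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        return cls(name=name, symbols=frozenset(symbols))

    @classmethod
    def from_text(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        """Read a 1-column text file of symbols; '#' lines are comments."""
        path = Path(path)
        symbols = [
            line.strip()
            for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(name=name or path.stem, symbols=frozenset(symbols))

    def to_text(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(sorted(self.symbols)) + "\n")


@dataclass(frozen=True)
class OverlapResult:
    """Result of a hypergeometric overlap-enrichment test."""

    size_a: int
    size_b: int
    overlap: int
    universe: int
    p_value: float
    expected_overlap: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.size_a, self.size_b):
            raise ValidationError("overlap exceeds the smaller set")
        if max(self.size_a, self.size_b) > self.universe:
            raise ValidationError("set larger than universe")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


def filter_by_category(gene_list: ScoredGeneList, keep: Iterable[str]) -> GeneSet:
    """Return the symbols whose category is in ``keep``.

    Parameters
    ----------
    gene_list
        Scored input list.
    keep
        Non-empty subset of :data:`CATEGORIES`.
    """
    keep_set = {str(c).strip().upper() for c in keep}
    if not keep_set:
        raise ValidationError("keep must be non-empty")
    unknown = keep_set - CATEGORIES
    if unknown:
        raise ValidationError(f"unknown categories in keep: {sorted(unknown)}")
    symbols = frozenset(s for s, c in gene_list.entries.items() if c in keep_set)
    return GeneSet(name=f"{gene_list.name}|{'+'.join(sorted(keep_set))}", symbols=symbols)


def integrate(a: GeneSet, b: GeneSet) -> tuple[GeneSet, GeneSet]:
    """Union and intersection of two gene sets."""
    union = GeneSet(name=f"{a.name}|{b.name}|union", symbols=a.symbols | b.symbols)
    inter = GeneSet(name=f"{a.name}|{b.name}|intersection", symbols=a.symbols & b.symbols)
    return union, inter


def hypergeom_sf_log(k: int, universe: int, size_a: int, size_b: int) -> float:
    """log of the upper tail P(X >= k) for X ~ Hypergeom(universe, size_a, size_b).

    Accumulated with logsumexp over the pmf so the result is finite even
    when the tail probability underflows a naive sum.
    """
    if k <= 0:
        return 0.0
    k_max = min(size_a, size_b)
    if k > k_max:
        return -np.inf
    support = np.arange(k, k_max + 1)
    logpmf = hypergeom.logpmf(support, universe, size_a, size_b)
    return float(logsumexp(logpmf))


def overlap_test(a: GeneSet, b: GeneSet, universe: int = DEFAULT_UNIVERSE) -> OverlapResult:
    """One-sided enrichment test for the overlap of two gene sets.

    ``p_value = P(X >= k)`` where ``k = |a & b|`` and X follows the
    hypergeometric distribution for drawing ``|b|`` genes out of
    ``universe`` of which ``|a|`` are marked.
    """
    union_size = len(a.symbols | b.symbols)
    if universe < union_size:
        raise ValidationError(
            f"universe ({universe}) smaller than the union of the sets ({union_size})"
        )
    k = len(a.symbols & b.symbols)
    log_p = hypergeom_sf_log(k, universe, len(a), len(b))
    p = float(min(1.0, np.exp(log_p)))
    return OverlapResult(
        size_a=len(a),
        size_b=len(b),
        overlap=k,
        universe=universe,
        p_value=p,
        expected_overlap=len(a) * len(b) / universe,
    )


def write_overlap_report(results: Mapping[str, OverlapResult], path: str | Path) -> None:
    """Write overlap results as a TSV report, one row per comparison."""
    header = "comparison\tsize_a\tsize_b\toverlap\texpected_overlap\tuniverse\tp_value"
    rows = [
        f"{label}\t{r.size_a}\t{r.size_b}\t{r.overlap}\t{r.expected_overlap:.4f}"
        f"\t{r.universe}\t{r.p_value:.6g}"
        for label, r in results.items()
    ]
    Path(path).write_text("\n".join([header, *rows]) + "\n")
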