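"""Gene-set overlap statistics.

Over-representation of one gene set in another is quantified against an
explicit universe: the observed overlap ``k`` is compared with the overlap
expected under independence, ``|A||B|/N``, and its significance is the
upper tail of the hypergeometric distribution, ``P(X >= k)``.  The tail is
evaluated in log space via log-gamma so that probabilities far below the
double-precision underflow threshold remain usable through ``log10_p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeometric_tail",
    "overlap_enrichment",
    "venn3_counts",
    "read_gene_set",
    "write_gene_set",
    "write_enrichment_table",
]

_LN10 = math.log(10.0)


def normalize_symbol(symbol: str) -> str:
    """Case-normalize a gene symbol (uppercased, surrounding space stripped).

    Symbol joins across datasets with inconsistent casing (``Ncor1`` vs
    ``NCOR1``) require a single canonical form.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named set of case-normalized gene symbols with an optional universe tag."""

    name: str
    members: frozenset[str]
    universe_ref: str | None = None

    @classmethod
    def from_symbols(
        cls, name: str, symbols: Iterable[str], universe_ref: str | None = None
    ) -> "GeneSet":
        return cls(name, frozenset(normalize_symbol(s) for s in symbols), universe_ref)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.members

    def intersection(self, other: "GeneSet") -> frozenset[str]:
        return self.members & other.members


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of two gene sets against a universe.

    ``fold`` is ``k / expected`` with ``expected = n_a * n_b / N``; it is
    ``None`` when either set is empty (the ratio is undefined, not zero).
    ``p`` is the upper-tail hypergeometric probability ``P(X >= k)``;
    ``log10_p`` is its log10, finite even when ``p`` underflows.
    """

    k: int
    n_a: int
    n_b: int
    N: int
    expected: float
    fold: float | None
    p: float
    log10_p: float
    name_a: str = ""
    name_b: str = ""


def hypergeometric_tail(k: int, N: int, K: int, n: int) -> tuple[float, float]:
    """Upper-tail probability ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    ``N`` is the universe size, ``K`` the number of marked items, ``n`` the
    draw size, ``k`` the observed number of marked items in the draw.  The
    tail includes ``k`` itself (the standard over-representation convention).

    Returns ``(p, log10_p)``.  The sum runs in log space over log-gamma
    binomial terms, so ``log10_p`` stays finite (p down to 1e-300 and
    beyond); ``p`` itself may underflow to the smallest positive double.
    The function is exactly symmetric under swapping ``K`` and ``n``.
    """
    for label, v in (("k", k), ("N", N), ("K", K), ("n", n)):
        if v != int(v) or v < 0:
            raise ValueError(f"{label} must be a non-negative integer, got {v!r}")
    k, N, K, n = int(k), int(N), int(K), int(n)
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0, 0.0
    # bitwise symmetry in (K, n): evaluate with the smaller as the draw
    if n > K:
        K, n = n, K
    i = np.arange(k, n + 1, dtype=np.float64)
    log_pmf = (
        _log_comb(K, i)
        + _log_comb(N - K, n - i)
        - _log_comb(N, n)
    )
    log_p = float(logsumexp(log_pmf))
    log_p = min(log_p, 0.0)  # clamp tiny positive rounding at p ~ 1
    p = math.exp(log_p)
    if p == 0.0:  # below ~1e-323: keep p strictly positive
        p = 5e-324
    return p, log_p / _LN10


def _log_comb(n: float | np.ndarray, k: float | np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    # out-of-range k (k < 0 or k > n) has zero ways
    return np.where((k < 0) | (k > n), -np.inf, out)


def overlap_enrichment(a: GeneSet, b: GeneSet, universe: GeneSet) -> EnrichmentResult:
    """Fold enrichment and hypergeometric p-value of the overlap of two sets.

    Both sets must be contained in the universe; violations raise with the
    offending symbols listed.  Empty ``a`` or ``b`` yields ``k=0``, ``p=1``
    and an undefined (``None``) fold.
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    for s in (a, b):
        stray = s.members - universe.members
        if stray:
            shown = ", ".join(sorted(stray)[:10])
            raise ValueError(
                f"gene set {s.name!r} has {len(stray)} symbols outside the "
                f"universe {universe.name!r}: {shown}"
            )
    N = len(universe)
    n_a, n_b = len(a), len(b)
    k = len(a.intersection(b))
    if n_a == 0 or n_b == 0:
        return EnrichmentResult(0, n_a, n_b, N, 0.0, None, 1.0, 0.0, a.name, b.name)
    expected = n_a * n_b / N
    fold = k * N / (n_a * n_b)  # one rounding from the exact rational
    p, log10_p = hypergeometric_tail(k, N, n_a, n_b)
    return EnrichmentResult(k, n_a, n_b, N, expected, fold, p, log10_p, a.name, b.name)


def venn3_counts(
    a: GeneSet | Iterable[str], b: GeneSet | Iterable[str], c: GeneSet | Iterable[str]
) -> tuple[int, int, int, int, int, int, int]:
    """Counts of the seven regions of a 3-set Venn decomposition.

    Order: (A only, B only, A∩B only, C only, A∩C only, B∩C only, A∩B∩C) —
    the conventional (100, 010, 110, 001, 101, 011, 111) region order.
    The regions partition the union of the three sets.
    """
    sa = a.members if isinstance(a, GeneSet) else frozenset(a)
    sb = b.members if isinstance(b, GeneSet) else frozenset(b)
    sc = c.members if isinstance(c, GeneSet) else frozenset(c)
    return (
        len(sa - sb - sc),
        len(sb - sa - sc),
        len((sa & sb) - sc),
        len(sc - sa - sb),
        len((sa & sc) - sb),
        len((sb & sc) - sa),
        len(sa & sb & sc),
    )


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set from one-symbol-per-line text or 2-column TSV (set, gene)."""
    path = Path(path)
    symbols: list[str] = []
    set_name = name
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            symbols.append(parts[0])
        else:
            if set_name is None:
                set_name = parts[0]
            symbols.append(parts[1])
    return GeneSet.from_symbols(set_name or path.stem, symbols)


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{g}\n" for g in sorted(gs.members)), encoding="utf-8", newline="\n"
    )


def write_enrichment_table(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    """Write overlap results as TSV: comparison, fold_enrichment, p_value, k, n_a, n_b, N."""
    lines = ["comparison\tfold_enrichment\tp_value\tlog10_p\tk\tn_a\tn_b\tN"]
    for r in results:
        fold = "NA" if r.fold is None else f"{r.fold:.6g}"
        lines.append(
            f"{r.name_a} vs {r.name_b}\t{fold}\t{r.p:.6g}\t{r.log10_p:.6g}"
            f"\t{r.k}\t{r.n_a}\t{r.n_b}\t{r.N}"
        )
    Path(path).write_text("".join(s + "\n" for s in lines), encoding="utf-8", newline="\n")
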