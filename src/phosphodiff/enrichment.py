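"""Candidate-gene-set enrichment and cross-group count comparisons.

Enrichment of a candidate-gene set (e.g. a curated disease-gene database)
among the proteins carrying biased phosphopeptides is assessed at the
protein/gene level with the same pooled two-proportion z statistic used for
differential detection: the tested proportion k/n is compared against the
set's universe-wide proportion K/N (default universe 20,000 genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detection import one_sided_p, two_proportion_z

DEFAULT_UNIVERSE = 20_000


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    universe: int = DEFAULT_UNIVERSE

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be non-empty")
        if self.universe < len(self.genes):
            raise ValueError("universe smaller than gene set")

    @classmethod
    def from_symbols(cls, name: str, symbols, universe: int = DEFAULT_UNIVERSE):
        return cls(name, frozenset(s.upper() for s in symbols), universe)


@dataclass
class EnrichmentResult:
    k: int
    n: int
    K: int
    N: int
    z: float
    p_one_sided: float

    @property
    def proportion_tested(self) -> float:
        return self.k / self.n

    @property
    def proportion_universe(self) -> float:
        return self.K / self.N


def proportion_enrichment(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """Pooled two-proportion z comparing k/n hits against the K/N universe
    rate, with one-sided upper-tail p.  Delegates to the same
    :func:`~phosphodiff.detection.two_proportion_z` used for detection calls.
    """
    z = two_proportion_z(k, n, K, N)
    return EnrichmentResult(k=k, n=n, K=K, N=N, z=z, p_one_sided=one_sided_p(z))


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric alternative, P(X >= k) drawing n from an
    N-gene urn with K annotated.  Not the default method; provided for
    sensitivity analyses."""
    if not (0 <= k <= n and k <= K <= N and n <= N):
        raise ValueError("require 0 <= k <= n <= N and k <= K <= N")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def annotate_hits(result_keys, gene_map, gene_set: GeneSet) -> tuple[int, list[str]]:
    """Count candidate-set members among the genes behind a set of peptide keys.

    ``gene_map`` maps each key to its gene symbol or an iterable of symbols
    (shared sequences may map to several homologous genes).  Matching is
    case-insensitive and each gene counts once regardless of peptide
    multiplicity.
    """
    unique: set[str] = set()
    for key in result_keys:
        genes = gene_map[str(key)]
        if isinstance(genes, str):
            genes = [genes]
        unique.update(g.upper() for g in genes)
    hits = sorted(unique & gene_set.genes)
    return len(hits), hits


def bias_direction_counts(
    detection_results, quant_results, contrast
) -> dict:
    """Count peptide keys biased toward each side of a contrast.

    A-biased = exclusively detected in group A plus significantly higher in
    A by quantification, de-duplicated on peptide key; the two counts over
    the combined total are compared with the pooled two-proportion z.
    """
    a_keys: set[str] = set()
    b_keys: set[str] = set()
    for r in detection_results:
        (a_keys if r.direction == contrast.level_a else b_keys).add(str(r.key))
    for r in quant_results:
        if not r.significant:
            continue
        (a_keys if r.direction == contrast.level_a else b_keys).add(str(r.key))
    count_a, count_b = len(a_keys), len(b_keys)
    total = count_a + count_b
    out = {"count_a": count_a, "count_b": count_b, "total": total}
    if total and count_a != count_b:
        z = two_proportion_z(count_a, total, count_b, total)
        out["z"] = z
        out["p_one_sided"] = one_sided_p(abs(z))
    elif total:
        out["z"] = 0.0
        out["p_one_sided"] = 0.5
    else:
        out["z"] = float("nan")
        out["p_one_sided"] = float("nan")
    return out


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    X^2 = sum (O - E)^2 / E with expectations from the margins,
    df = (r-1)(c-1), p from the upper chi-square tail.  Raises on zero
    margins (expectation undefined).
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (observed < 0).any():
        raise ValueError("counts must be non-negative")
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(row, col) / observed.sum()
    x2 = float(((observed - expected) ** 2 / expected).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    p = float(stats.chi2.sf(x2, df))
    return x2, df, p
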