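"""Hypergeometric over-representation tests.

Used in two places: (a) is the SNP set linked to the target genes enriched
for strongly divergent SNPs (between-population allele-frequency difference
above a threshold, strict ``>``), and (b) are the top-decile genes
concentrated on particular chromosomes.

``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)`` is the one-sided
over-representation p-value and includes the observed ``k``; the survival
function is evaluated by scipy in a numerically stable way.  No
multiple-testing correction is applied by default (a Benjamini-Hochberg
helper is provided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genediff import GeneDiffRecord


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric test: draw n from N containing K successes, see k."""

    label: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    enrichment_ratio: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    ``N`` population size, ``K`` successes in the population, ``n`` sample
    size, ``k`` observed successes.  ``k = 0`` gives exactly 1.
    """
    _check_bounds(k, N, K, n)
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_lower_tail(k: int, N: int, K: int, n: int) -> float:
    """``P(X <= k)`` — the under-representation ("conserved") tail."""
    _check_bounds(k, N, K, n)
    return float(stats.hypergeom.cdf(k, N, K, n))


def _check_bounds(k: int, N: int, K: int, n: int) -> None:
    if N < 0 or not 0 <= K <= N or not 0 <= n <= N:
        raise ValueError(f"invalid hypergeometric arguments N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")


def _result(label: str, N: int, K: int, n: int, k: int, tail: str) -> EnrichmentResult:
    if tail == "upper":
        p = hypergeom_upper_tail(k, N, K, n)
    elif tail == "lower":
        p = hypergeom_lower_tail(k, N, K, n)
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    ratio = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return EnrichmentResult(
        label=label, N=N, K=K, n=n, k=k, p_value=p, enrichment_ratio=ratio
    )


def divergent_snp_enrichment(
    differences: pd.DataFrame,
    subset: set[str],
    threshold: float = 0.3,
    label: str = "subset",
    tail: str = "upper",
) -> EnrichmentResult:
    """Over-representation of divergent SNPs (``abs_delta > threshold``)
    within a SNP subset, against all SNPs with defined differences.

    ``differences`` is the table from
    :func:`epidiff.frequencies.frequency_differences`; ``subset`` is a set
    of variant ids contained in it.
    """
    if not subset:
        raise ValueError("subset is empty")
    ids = set(differences["variant_id"])
    stray = subset - ids
    if stray:
        raise ValueError(
            f"{len(stray)} subset variants absent from the difference table"
        )
    divergent = differences["abs_delta"].to_numpy() > threshold
    in_subset = differences["variant_id"].isin(subset).to_numpy()
    return _result(
        label,
        N=len(differences),
        K=int(divergent.sum()),
        n=int(in_subset.sum()),
        k=int((divergent & in_subset).sum()),
        tail=tail,
    )


def chromosome_enrichment(
    ranked: list[GeneDiffRecord],
    which: str = "top",
    tail: str = "upper",
) -> list[EnrichmentResult]:
    """Per-chromosome concentration of top- (or bottom-) decile genes.

    For each chromosome c: N = all ranked genes, K = genes on c,
    n = decile size, k = decile genes on c, tested one-sided.
    """
    if which not in ("top", "bottom"):
        raise ValueError("which must be 'top' or 'bottom'")
    flag = "top_decile" if which == "top" else "bottom_decile"
    in_decile = [r for r in ranked if getattr(r, flag)]
    N, n = len(ranked), len(in_decile)
    chroms = sorted({r.chromosome for r in ranked})
    out = []
    for c in chroms:
        K = sum(r.chromosome == c for r in ranked)
        k = sum(r.chromosome == c for r in in_decile)
        out.append(_result(f"{which}:{c}", N=N, K=K, n=n, k=k, tail=tail))
    return out


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH-adjusted p-values (optional; raw p-values are the default report)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adjusted[order[i]] = running
    return adjusted.tolist()


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    frame = pd.DataFrame([r.__dict__ for r in results])
    frame["significant"] = frame["p_value"] < 0.05
    return frame
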