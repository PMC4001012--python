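"""Per-population genotypic and allelic frequencies.

For each variant and population: ``p0`` is the homozygous-allele-A
fraction, ``p1`` heterozygous, ``p2`` homozygous-allele-B, and
``pA = p0 + p1/2`` the allele-A frequency — all computed over non-missing
calls only.  Frequencies are proportions in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class PopulationFrequencies:
    """Tidy per-variant, per-population frequency table.

    ``table`` columns: variant_id, population, p0, p1, p2, pA, n_called.
    Variants with no calls in a population carry NaN frequencies and are
    excluded from difference and density computations downstream.
    """

    populations: tuple[str, ...]
    table: pd.DataFrame

    def for_population(self, population: str) -> pd.DataFrame:
        if population not in self.populations:
            raise ValueError(f"unknown population {population!r}")
        sub = self.table[self.table["population"] == population]
        return sub.set_index("variant_id")

    def defined_in_all(self) -> pd.Index:
        """Variant ids with defined frequencies in every population."""
        ok = self.table.dropna(subset=["pA"])
        counts = ok.groupby("variant_id", sort=False)["population"].nunique()
        return counts.index[counts == len(self.populations)]


def compute_frequencies(dataset: GenotypeDataset) -> PopulationFrequencies:
    """Genotypic and allelic frequencies for each population.

    Missing calls are excluded from the denominators; a variant with zero
    calls in a population is flagged undefined (NaN) and logged.
    """
    pops = dataset.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    blocks = []
    vids = dataset.variant_ids
    for pop in pops:
        sub = dataset.calls[dataset.sample_rows(pop)]
        n_called = (sub != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p0 = (sub == 2).sum(axis=0) / n_called
            p1 = (sub == 1).sum(axis=0) / n_called
            p2 = (sub == 0).sum(axis=0) / n_called
        undefined = n_called == 0
        if undefined.any():
            logger.warning(
                "population %s: %d variants with all calls missing (undefined)",
                pop, int(undefined.sum()),
            )
        for arr in (p0, p1, p2):
            arr[undefined] = np.nan
        blocks.append(
            pd.DataFrame(
                {
                    "variant_id": vids,
                    "population": pop,
                    "p0": p0,
                    "p1": p1,
                    "p2": p2,
                    "pA": p0 + p1 / 2.0,
                    "n_called": n_called,
                }
            )
        )
    return PopulationFrequencies(
        populations=pops, table=pd.concat(blocks, ignore_index=True)
    )


def frequency_differences(
    freqs: PopulationFrequencies,
    pop1: str | None = None,
    pop2: str | None = None,
) -> pd.DataFrame:
    """Allele-A frequency differences ``delta = pA(pop1) - pA(pop2)``.

    One row per variant with defined frequencies in both populations;
    columns variant_id, delta, abs_delta.
    """
    if pop1 is None or pop2 is None:
        if len(freqs.populations) != 2:
            raise ValueError("specify pop1/pop2 when more than two populations")
        pop1, pop2 = freqs.populations
    a = freqs.for_population(pop1)["pA"]
    b = freqs.for_population(pop2)["pA"]
    delta = (a - b).dropna()
    n_dropped = len(a) - len(delta)
    if n_dropped:
        logger.info("%d variants dropped from differences (undefined)", n_dropped)
    return pd.DataFrame(
        {
            "variant_id": delta.index,
            "delta": delta.to_numpy(),
            "abs_delta": np.abs(delta.to_numpy()),
        }
    )


def frequency_density(
    freqs: PopulationFrequencies,
    variant_subset: set[str],
    bins: int = 20,
) -> pd.DataFrame:
    """Binned allele-frequency densities, full panel vs. a SNP subset.

    Histograms of ``pA`` over [0, 1], normalised to unit area, computed per
    population for all defined variants ("all") and for the subset
    ("subset").  Columns: population, snp_set, bin_left, bin_right, density.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if not variant_subset:
        raise ValueError("variant subset is empty")
    edges = np.linspace(0.0, 1.0, bins + 1)
    out = []
    for pop in freqs.populations:
        pa = freqs.for_population(pop)["pA"].dropna()
        sets = {"all": pa, "subset": pa[pa.index.isin(variant_subset)]}
        if sets["subset"].empty:
            raise ValueError("no defined frequencies among the subset variants")
        for name, values in sets.items():
            dens, _ = np.histogram(values, bins=edges, density=True)
            out.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "snp_set": name,
                        "bin_left": edges[:-1],
                        "bin_right": edges[1:],
                        "density": dens,
                    }
                )
            )
    return pd.concat(out, ignore_index=True)
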