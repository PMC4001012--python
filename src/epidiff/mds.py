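"""Population structure from SNP subsets: IBS distances, classical MDS and
the random-subset null comparison of the leading component.

The pairwise distance is allele-sharing (identity-by-state): for samples i
and j with dosages ``d_i, d_j`` at a shared non-missing SNP the similarity
is ``(2 - |d_i - d_j|) / 2`` (1 for identical genotypes, 0 for opposite
homozygotes); the distance is one minus the mean similarity over the
pairwise-complete SNP set.

Classical (Torgerson) MDS double-centres the squared-distance matrix,

    B = -1/2 * J D^2 J,      J = I - 11'/n,

takes the top-k eigenpairs of B and scales eigenvectors by the square root
of their (non-negative, clamped) eigenvalues.  Component 1 is the leading
axis; because an MDS axis has arbitrary sign, subsets are compared through
the *squared* Pearson correlation of their component-1 coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        if v.min(initial=0.0) < -1e-12 or v.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        self.values = v


@dataclass
class MdsResult:
    """Sample coordinates on the top-k MDS axes, eigenvalues descending."""

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    def component(self, i: int = 0) -> np.ndarray:
        return self.coordinates[:, i]


def ibs_distance(
    dataset: GenotypeDataset,
    variant_subset: set[str] | list[str] | None = None,
    block: int = 128,
) -> DistanceMatrix:
    """Identity-by-state distance matrix over a variant subset.

    Missing genotypes are handled pairwise-complete: each sample pair is
    averaged over the SNPs where both are called.  A pair sharing no called
    SNP is an error naming the pair.
    """
    if variant_subset is None:
        cols = np.arange(dataset.n_variants)
    else:
        cols = np.array(
            sorted(dataset.variant_index(v) for v in variant_subset), dtype=np.intp
        )
        if cols.size == 0:
            raise ValueError("variant subset is empty")
    X = dataset.calls[:, cols].astype(np.float64)
    X[X == MISSING] = np.nan
    n = dataset.n_samples
    sim_sum = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for lo in range(0, cols.size, block):
        chunk = X[:, lo:lo + block]               # n x b
        valid = ~np.isnan(chunk)
        filled = np.where(valid, chunk, 0.0)
        # |d_i - d_j| accumulated pairwise over the block
        diff = np.abs(filled[:, None, :] - filled[None, :, :])
        both = valid[:, None, :] & valid[None, :, :]
        sim_sum += ((2.0 - diff) / 2.0 * both).sum(axis=2)
        cnt += both.sum(axis=2)
    if (cnt == 0).any():
        i, j = np.argwhere(cnt == 0)[0]
        raise ValueError(
            f"samples {dataset.sample_ids[i]!r} and {dataset.sample_ids[j]!r} "
            "share no called variant in the subset"
        )
    dist = 1.0 - sim_sum / cnt
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(sample_ids=list(dataset.sample_ids), values=dist)


def classical_mds(distances: DistanceMatrix, k: int = 2) -> MdsResult:
    """Torgerson MDS of a distance matrix.

    Negative eigenvalues (non-Euclidean distances) are clamped to zero with
    a warning; coordinates are eigenvectors scaled by sqrt(eigenvalue).
    """
    n = len(distances.sample_ids)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_samples ({n}), got {k}")
    d2 = distances.values ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1][:k]
    lam = eigvals[order]
    if (lam < -1e-9 * max(abs(eigvals).max(), 1.0)).any():
        warnings.warn(
            "negative MDS eigenvalues clamped to zero (non-Euclidean distances)",
            RuntimeWarning,
            stacklevel=2,
        )
    lam = np.clip(lam, 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lam)
    return MdsResult(
        sample_ids=list(distances.sample_ids),
        coordinates=coords,
        eigenvalues=lam,
    )


def component1_r2(result_a: MdsResult, result_b: MdsResult) -> float:
    """Squared Pearson correlation of two embeddings' first components.

    Squaring makes the arbitrary sign of an MDS axis irrelevant.  Sample
    orderings must match; a constant component is an error.
    """
    if result_a.sample_ids != result_b.sample_ids:
        raise ValueError("sample orderings differ between the two MDS results")
    x, y = result_a.component(0), result_b.component(0)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("component 1 is constant; correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def random_subset_comparison(
    dataset: GenotypeDataset,
    reference_subset: set[str] | list[str],
    subset_size: int = 113,
    runs: int = 10,
    seed: int | None = None,
    run_seeds: list[int] | None = None,
    k: int = 2,
) -> dict:
    """Compare the reference subset's MDS against random-subset MDS runs.

    For each run, ``subset_size`` variants are drawn uniformly without
    replacement from the *entire* variant panel (the reference subset is
    not excluded), IBS + classical MDS are recomputed, and the squared
    Pearson correlation of component 1 against the reference embedding is
    recorded.

    Returns a dict with ``reference`` (MdsResult), ``per_run_r2``,
    ``mean_r2``, ``min_r2`` and ``r2_of_mean_component`` (r² against the
    sign-aligned average of the runs' first components — the two readings
    of "average over runs").
    """
    if subset_size > dataset.n_variants:
        raise ValueError(
            f"subset_size {subset_size} exceeds variant count {dataset.n_variants}"
        )
    if run_seeds is not None and len(run_seeds) != runs:
        raise ValueError("run_seeds must have one seed per run")
    reference = classical_mds(ibs_distance(dataset, reference_subset), k=k)
    all_ids = np.array(dataset.variant_ids)
    per_run_r2: list[float] = []
    aligned_components = []
    for run in range(runs):
        if run_seeds is not None:
            rng = np.random.default_rng(run_seeds[run])
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence(seed).spawn(runs)[run]
            )
        drawn = rng.choice(all_ids, size=subset_size, replace=False)
        result = classical_mds(ibs_distance(dataset, set(drawn)), k=k)
        per_run_r2.append(component1_r2(reference, result))
        comp = result.component(0)
        sign = np.sign(np.dot(comp, reference.component(0))) or 1.0
        aligned_components.append(sign * comp)
    mean_component = np.mean(aligned_components, axis=0)
    r = np.corrcoef(reference.component(0), mean_component)[0, 1]
    return {
        "reference": reference,
        "per_run_r2": per_run_r2,
        "mean_r2": float(np.mean(per_run_r2)),
        "min_r2": float(min(per_run_r2)),
        "r2_of_mean_component": float(r * r),
    }
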