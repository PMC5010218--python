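"""Allelic-correlation kinship (genomic relationship) and related quantities.

The kinship coefficient between individuals i and j is the average over
markers of the product of their standardized allele counts,

    k_ij = (1/m) * sum_k  X~_ik * X~_jk,

the usual marker-based genomic relationship.  Because the columns of the
standardized matrix have unit population variance, the diagonal of K
averages to 1 and the trace equals the sample size.  Kinship is tied to the
Euclidean distance between standardized marker profiles by the identity

    ||X~_i - X~_j||^2 = m * (k_ii + k_jj - 2 k_ij),

which is why Euclidean clustering (k-means) of standardized genotypes
separates minimally related groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .genotype_io import StandardizedMatrix


@dataclass
class KinshipMatrix:
    values: np.ndarray
    sample_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError("kinship matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("kinship matrix is not symmetric")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def kinship_matrix(x: StandardizedMatrix) -> KinshipMatrix:
    """K = X~ X~^T / m from a standardized genotype matrix."""
    if x.n_samples < 2 or x.n_markers < 1:
        raise ValidationError("need >=2 samples and >=1 marker")
    k = x.values @ x.values.T / x.n_markers
    k = (k + k.T) / 2.0  # enforce exact symmetry against rounding
    return KinshipMatrix(values=k, sample_ids=list(x.sample_ids))


def mean_cross_kinship(k: KinshipMatrix, idx_a, idx_b) -> float:
    """Mean kinship k-bar over all pairs (i in A, j in B); A, B disjoint."""
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValidationError("index sets must be non-empty")
    if np.intersect1d(idx_a, idx_b).size:
        raise ValidationError("index sets overlap")
    return float(k.values[np.ix_(idx_a, idx_b)].mean())


def squared_distance(x: StandardizedMatrix, i: int, j: int) -> float:
    """Squared Euclidean distance between standardized marker profiles.

    Equals ``m * (k_ii + k_jj - 2 k_ij)`` with k from :func:`kinship_matrix`.
    """
    d = x.values[i] - x.values[j]
    return float(d @ d)


def write_kinship_csv(k: KinshipMatrix, path) -> None:
    """Square CSV with sample ids as header row and first column."""
    pd.DataFrame(k.values, index=k.sample_ids, columns=k.sample_ids).to_csv(
        Path(path), index_label="id"
    )
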