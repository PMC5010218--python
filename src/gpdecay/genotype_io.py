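"""Genotype/phenotype I/O, quality control, imputation, pruning and standardization.

Genotypes are biallelic SNP allele counts coded 0/1/2 (1 = heterozygote),
stored as a float matrix with ``nan`` marking missing calls.  Two text
dialects are supported: a PLINK ``.raw``-style whitespace table and a plain
CSV with the sample id in the first column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import MonomorphicMarkerError, ParseError, ValidationError

_LEGAL = frozenset((0.0, 1.0, 2.0))


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele-count matrix with optional metadata.

    Parameters
    ----------
    sample_ids : sequence of unique sample identifiers (length n).
    marker_ids : sequence of unique marker identifiers (length m).
    counts : (n, m) float array with values in {0, 1, 2} or nan for missing.
    chrom : optional per-marker chromosome label.
    pos : optional per-marker genetic-map position.
    pop_labels : optional per-sample population/family label.
    """

    sample_ids: list
    marker_ids: list
    counts: np.ndarray
    chrom: Optional[np.ndarray] = None
    pos: Optional[np.ndarray] = None
    pop_labels: Optional[list] = None

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.marker_ids = list(self.marker_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n, m = self.counts.shape
        if n != len(self.sample_ids) or m != len(self.marker_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicated sample ids")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("duplicated marker ids")
        observed = self.counts[~np.isnan(self.counts)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
            raise ValidationError(f"allele count {bad!r} outside {{0,1,2}}")
        if self.pop_labels is not None and len(self.pop_labels) != n:
            raise ValidationError("pop_labels length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.counts).any())

    def take_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the marker index array ``keep``."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            marker_ids=[self.marker_ids[j] for j in keep],
            counts=self.counts[:, keep].copy(),
            chrom=None if self.chrom is None else np.asarray(self.chrom)[keep],
            pos=None if self.pos is None else np.asarray(self.pos)[keep],
            pop_labels=self.pop_labels,
        )

    def take_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in keep],
            marker_ids=self.marker_ids,
            counts=self.counts[keep].copy(),
            chrom=self.chrom,
            pos=self.pos,
            pop_labels=None
            if self.pop_labels is None
            else [self.pop_labels[i] for i in keep],
        )


@dataclass
class StandardizedMatrix:
    """Column-standardized allele counts with the centering/scaling recorded.

    ``values`` has per-marker mean 0 and population (denominator-n) variance 1
    when computed on the same sample the standardization was fitted on.  The
    stored ``center``/``scale`` allow projecting new samples into the same
    coordinate system via :meth:`apply`.
    """

    values: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    sample_ids: list
    marker_ids: list

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def apply(self, counts: np.ndarray) -> np.ndarray:
        """Standardize new allele-count rows with the stored center/scale."""
        counts = np.asarray(counts, dtype=float)
        if counts.shape[-1] != len(self.center):
            raise ValidationError("marker count mismatch in apply()")
        return (counts - self.center) / self.scale


@dataclass
class Phenotype:
    """A quantitative trait vector keyed by sample id."""

    sample_ids: list
    y: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or len(self.y) != len(self.sample_ids):
            raise ValidationError("phenotype vector length must match sample ids")
        if not np.isfinite(self.y).all():
            raise ValidationError("phenotype values must be finite")


_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes(path, format: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from ``path``.

    ``format='plink_raw'`` expects a whitespace table with the header
    ``FID IID PAT MAT SEX PHENOTYPE`` followed by one column per marker and
    ``NA`` for missing calls; the IID column becomes the sample id.
    ``format='csv'`` expects the sample id in the first column and one marker
    per remaining column, with empty cells for missing calls.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format == "plink_raw":
        try:
            df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"{path}: {exc}") from exc
        missing_meta = [c for c in _RAW_META if c not in df.columns]
        if missing_meta:
            raise ParseError(f"{path}: missing PLINK raw columns {missing_meta}")
        sample_ids = df["IID"].astype(str).tolist()
        marker_ids = [c for c in df.columns if c not in _RAW_META]
        counts = df[marker_ids].to_numpy(dtype=float)
    elif format == "csv":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        sample_ids = df.index.astype(str).tolist()
        marker_ids = [str(c) for c in df.columns]
        counts = df.to_numpy(dtype=float)
    else:
        raise ValidationError(f"unknown genotype format {format!r}")

    observed = counts[~np.isnan(counts)]
    bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
    if bad.size:
        # locate the first offending cell for the error message
        idx = np.argwhere(~np.isnan(counts) & ~np.isin(counts, (0.0, 1.0, 2.0)))[0]
        raise ParseError(
            f"{path}: line {idx[0] + 2}: allele count {counts[tuple(idx)]!r} "
            "is not 0, 1 or 2"
        )
    return GenotypeMatrix(sample_ids=sample_ids, marker_ids=marker_ids, counts=counts)


def write_genotypes(g: GenotypeMatrix, path, format: str = "csv") -> None:
    """Write ``g`` in the named dialect (inverse of :func:`read_genotypes`)."""
    path = Path(path)

    def _cell(v):
        return "" if np.isnan(v) else str(int(v))

    if format == "csv":
        with open(path, "w") as fh:
            fh.write("id," + ",".join(g.marker_ids) + "\n")
            for sid, row in zip(g.sample_ids, g.counts):
                fh.write(sid + "," + ",".join(_cell(v) for v in row) + "\n")
    elif format == "plink_raw":
        with open(path, "w") as fh:
            fh.write(" ".join(_RAW_META + list(g.marker_ids)) + "\n")
            for sid, row in zip(g.sample_ids, g.counts):
                cells = [sid, sid, "0", "0", "0", "-9"]
                cells += ["NA" if np.isnan(v) else str(int(v)) for v in row]
                fh.write(" ".join(cells) + "\n")
    else:
        raise ValidationError(f"unknown genotype format {format!r}")


def read_phenotypes(path) -> Phenotype:
    """Read a two-column (id, value) delimited phenotype file."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, header=None, names=["id", "y"], comment="#")
    # tolerate a header line
    try:
        y = df["y"].astype(float)
    except (TypeError, ValueError):
        df = df.iloc[1:]
        y = df["y"].astype(float)
    return Phenotype(sample_ids=df["id"].astype(str).tolist(), y=y.to_numpy())


def match_phenotype(g: GenotypeMatrix, pheno: Phenotype) -> Phenotype:
    """Reorder ``pheno`` to the sample order of ``g``; error on unmatched ids."""
    lookup = {sid: i for i, sid in enumerate(pheno.sample_ids)}
    missing = [sid for sid in g.sample_ids if sid not in lookup]
    if missing:
        raise ValidationError(f"samples without phenotype: {missing[:5]}")
    order = [lookup[sid] for sid in g.sample_ids]
    return Phenotype(sample_ids=list(g.sample_ids), y=pheno.y[order])


def apply_qc(
    g: GenotypeMatrix, maf_min: float = 0.01, missing_max: float = 0.20
) -> GenotypeMatrix:
    """Drop markers with MAF < ``maf_min`` or missingness > ``missing_max``.

    Allele frequency is computed on non-missing entries only.  The sample set
    is unchanged.
    """
    if not (0 < maf_min <= 0.5):
        raise ValidationError("maf_min must be in (0, 0.5]")
    if not (0 < missing_max < 1):
        raise ValidationError("missing_max must be in (0, 1)")
    miss = np.isnan(g.counts)
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        raise ValidationError("marker with no observed genotypes")
    with np.errstate(invalid="ignore"):
        p = np.nansum(g.counts, axis=0) / (2.0 * n_obs)
    maf = np.minimum(p, 1.0 - p)
    miss_frac = miss.mean(axis=0)
    keep = np.flatnonzero((maf >= maf_min) & (miss_frac <= missing_max))
    if keep.size == 0:
        raise ValidationError("quality control removed every marker")
    return g.take_markers(keep)


def impute_missing(
    g: GenotypeMatrix, k_neighbours: int = 10, seed: int = 0
) -> GenotypeMatrix:
    """k-nearest-neighbour imputation of missing allele counts.

    For each sample with missing calls, neighbours are ranked by Euclidean
    distance computed over the markers non-missing in both samples (ties
    broken by sample order).  Each missing cell is filled with the
    inverse-distance weighted mean of the ``k_neighbours`` nearest samples
    observed at that marker, rounded to the nearest legal count.  Non-missing
    entries are never altered.  ``seed`` is accepted for interface symmetry;
    the procedure is deterministic.
    """
    if not g.has_missing():
        return g
    counts = g.counts.copy()
    miss = np.isnan(counts)
    if miss.all(axis=1).any():
        bad = int(np.flatnonzero(miss.all(axis=1))[0])
        raise ValidationError(
            f"sample {g.sample_ids[bad]!r} is missing at every marker"
        )
    n = g.n_samples
    filled = counts.copy()
    for i in range(n):
        mk = np.flatnonzero(miss[i])
        if mk.size == 0:
            continue
        # distances from sample i to all others over shared observed markers
        diff = counts[i] - counts
        shared = ~np.isnan(diff)
        sq = np.where(shared, diff, 0.0) ** 2
        n_shared = shared.sum(axis=1)
        dist = np.sqrt(sq.sum(axis=1))
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        order = np.lexsort((np.arange(n), dist))
        for j in mk:
            donors = [s for s in order if not miss[s, j] and np.isfinite(dist[s])]
            if not donors:
                raise ValidationError(
                    f"marker {g.marker_ids[j]!r}: no usable donor samples"
                )
            donors = donors[:k_neighbours]
            d = dist[donors]
            w = 1.0 / (d + 1e-12)
            value = float(np.dot(w, counts[donors, j]) / w.sum())
            filled[i, j] = np.clip(np.rint(value), 0, 2)
    out = GenotypeMatrix(
        sample_ids=g.sample_ids,
        marker_ids=g.marker_ids,
        counts=filled,
        chrom=g.chrom,
        pos=g.pos,
        pop_labels=g.pop_labels,
    )
    return out


def prune_correlated(g: GenotypeMatrix, r_max: float = 0.95) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning at |Pearson r| > ``r_max``.

    Scanning markers in file order, a marker is dropped if its absolute
    correlation with any already-retained marker exceeds ``r_max``.
    Zero-variance markers are dropped with a warning (their correlation is
    undefined).
    """
    if g.has_missing():
        raise ValidationError("prune_correlated requires imputed (complete) data")
    x = g.counts
    n = x.shape[0]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    retained: list[int] = []
    z_cols: list[np.ndarray] = []
    for j in range(g.n_markers):
        if sd[j] == 0:
            warnings.warn(
                f"dropping zero-variance marker {g.marker_ids[j]!r}", stacklevel=2
            )
            continue
        zj = (x[:, j] - mu[j]) / sd[j]
        if z_cols:
            r = np.abs(np.column_stack(z_cols).T @ zj) / n
            if (r > r_max).any():
                continue
        retained.append(j)
        z_cols.append(zj)
    return g.take_markers(np.array(retained, dtype=int))


def standardize(g: GenotypeMatrix) -> StandardizedMatrix:
    """Center and scale each marker to mean 0 and population variance 1.

    The scale is the denominator-n standard deviation computed on the full
    sample, so later subsamples share one coordinate system.  Monomorphic
    markers are an error: run :func:`apply_qc` first.
    """
    if g.has_missing():
        raise ValidationError("standardize requires imputed (complete) data")
    center = g.counts.mean(axis=0)
    scale = g.counts.std(axis=0)  # ddof=0
    if (scale == 0).any():
        j = int(np.flatnonzero(scale == 0)[0])
        raise MonomorphicMarkerError(
            f"marker {g.marker_ids[j]!r} is monomorphic; apply_qc before standardize"
        )
    values = (g.counts - center) / scale
    return StandardizedMatrix(
        values=values,
        center=center,
        scale=scale,
        sample_ids=list(g.sample_ids),
        marker_ids=list(g.marker_ids),
    )
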