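"""Dissimilarity matrices, partitions, and their block decomposition.

The central data structure is a square matrix of pairwise dissimilarities
``delta[a, b]`` between ``N`` objects.  No metric axiom is assumed: the
matrix may be asymmetric, may carry a nonzero diagonal, and individual
entries may be missing.  A :class:`Partition` assigns every object to one
of ``g >= 2`` groups, which splits the matrix into ``g`` diagonal
("within") blocks and ``g**2 - g`` off-diagonal ("between") blocks.
:func:`block_summary` computes the per-block means and counts that all
downstream statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InputError",
    "DissimilarityMatrix",
    "Partition",
    "BlockSummary",
    "validate_inputs",
    "block_summary",
]


class InputError(ValueError):
    """An input violates one of the documented contracts."""


def _as_ids(ids: Sequence | None, n: int, what: str) -> tuple[str, ...]:
    if ids is None:
        return tuple(f"o{i + 1}" for i in range(n))
    out = tuple(str(i) for i in ids)
    if len(out) != n:
        raise InputError(f"{what}: got {len(out)} ids for {n} objects")
    if len(set(out)) != len(out):
        raise InputError(f"{what}: duplicate id")
    return out


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square matrix of pairwise dissimilarities with optional missing entries.

    Missing entries are encoded as NaN in ``values``.  Asymmetry, nonzero
    diagonal and zero off-diagonal entries are all legal: the matrix is
    used exactly as given, with no symmetrization or repair.

    Parameters
    ----------
    values:
        ``(N, N)`` array of real dissimilarities; NaN marks a missing entry.
    ids:
        Object identifiers, one per row/column.  Defaults to ``o1..oN``.
    mask:
        Optional boolean array, True where the entry is observed.  Entries
        with ``mask == False`` are forced to NaN.
    """

    values: np.ndarray
    ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __init__(self, values, ids=None, mask=None):
        vals = np.array(values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise InputError(f"matrix must be square, got shape {vals.shape}")
        if vals.shape[0] < 2:
            raise InputError("matrix must contain at least 2 objects")
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != vals.shape:
                raise InputError("mask shape does not match values")
            vals[~mask] = np.nan
        if np.isinf(vals).any():
            raise InputError("non-finite observed entry")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "ids", _as_ids(ids, vals.shape[0], "matrix"))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the entry is observed."""
        return ~np.isnan(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    def reordered(self, order: np.ndarray) -> "DissimilarityMatrix":
        """Return a copy with rows/columns permuted by ``order``."""
        return DissimilarityMatrix(
            self.values[np.ix_(order, order)],
            ids=[self.ids[i] for i in order],
        )


@dataclass(frozen=True)
class Partition:
    """Assignment of each object to one of ``g >= 2`` groups.

    Group codes ``0..g-1`` are assigned in order of first appearance of
    each label, so the numbering (and hence every seeded computation
    downstream) is fully determined by the label input order.
    """

    ids: tuple[str, ...]
    labels: tuple = ()
    codes: np.ndarray = field(default=None)  # type: ignore[assignment]
    group_names: tuple = ()
    sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __init__(self, labels, ids=None):
        labels = tuple(labels)
        if not labels:
            raise InputError("empty partition")
        oids = _as_ids(ids, len(labels), "partition")
        names: list = []
        index: dict = {}
        codes = np.empty(len(labels), dtype=np.intp)
        for i, lab in enumerate(labels):
            if lab not in index:
                index[lab] = len(names)
                names.append(lab)
            codes[i] = index[lab]
        g = len(names)
        if g < 2:
            raise InputError("g < 2: at least two groups required")
        sizes = np.bincount(codes, minlength=g)
        object.__setattr__(self, "ids", oids)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "group_names", tuple(names))
        object.__setattr__(self, "sizes", sizes)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def g(self) -> int:
        return len(self.group_names)

    def reordered(self, order: np.ndarray) -> "Partition":
        return Partition(
            [self.labels[i] for i in order], ids=[self.ids[i] for i in order]
        )


@dataclass(frozen=True)
class BlockSummary:
    """Observed-entry means and counts for every block of the partitioned matrix.

    ``between_means``/``between_counts`` are ``(g, g)`` arrays indexed by
    ordered group pairs; their diagonals hold the within quantities for
    convenience (``within_means``/``within_counts`` expose them directly).
    All means are taken over observed entries only.
    """

    within_means: np.ndarray
    between_means: np.ndarray
    within_counts: np.ndarray
    between_counts: np.ndarray
    n_diag: int
    n_off: int
    overall_within_mean: float
    include_diagonal: bool


def validate_inputs(
    matrix: DissimilarityMatrix, partition: Partition
) -> tuple[DissimilarityMatrix, Partition]:
    """Check id agreement and reorder both inputs into canonical order.

    Canonical order is group-major: objects of group 0 first, then group 1,
    and so on, each group keeping the relative order of the partition input.
    Group numbering itself comes from the partition, so shuffling the matrix
    rows never changes any downstream result.
    """
    mset = set(matrix.ids)
    pset = set(partition.ids)
    missing = [i for i in matrix.ids if i not in pset]
    if missing:
        raise InputError(f"unlabeled object: {missing[0]!r}")
    unknown = [i for i in partition.ids if i not in mset]
    if unknown:
        raise InputError(f"label for unknown object: {unknown[0]!r}")
    # group-major, partition input order within each group (stable sort)
    order_p = np.argsort(partition.codes, kind="stable")
    partition = partition.reordered(order_p)
    pos = {oid: k for k, oid in enumerate(matrix.ids)}
    order_m = np.array([pos[oid] for oid in partition.ids], dtype=np.intp)
    matrix = matrix.reordered(order_m)
    return matrix, partition


def block_summary(
    matrix: DissimilarityMatrix,
    partition: Partition,
    include_diagonal: bool = True,
) -> BlockSummary:
    """Compute per-block means/counts and the overall within mean.

    With ``include_diagonal=True`` (default) the self-dissimilarities
    ``delta[a, a]`` belong to the within blocks, so with complete data
    ``n_diag == sum(nj**2)``.  With ``include_diagonal=False`` they are
    dropped and ``n_diag == sum(nj * (nj - 1))``.

    Raises :class:`InputError` if any block has no observed entry.
    """
    if matrix.ids != partition.ids:
        matrix, partition = validate_inputs(matrix, partition)
    g = partition.g
    codes = partition.codes
    obs = matrix.mask
    vals = np.where(obs, matrix.values, 0.0)

    onehot = np.zeros((matrix.n, g))
    onehot[np.arange(matrix.n), codes] = 1.0
    sums = onehot.T @ vals @ onehot
    counts = np.rint(onehot.T @ obs.astype(float) @ onehot).astype(np.int64)

    if not include_diagonal:
        d = np.einsum("ii->i", vals).copy()
        d_obs = np.einsum("ii->i", obs).astype(float)
        sums[np.arange(g), np.arange(g)] -= np.bincount(
            codes, weights=d * d_obs, minlength=g
        )
        counts[np.arange(g), np.arange(g)] -= np.rint(
            np.bincount(codes, weights=d_obs, minlength=g)
        ).astype(np.int64)

    if (counts == 0).any():
        j, k = np.argwhere(counts == 0)[0]
        kind = "within" if j == k else "between"
        raise InputError(
            f"empty block: {kind} block ({partition.group_names[j]!r}, "
            f"{partition.group_names[k]!r}) has no observed entry"
        )

    means = sums / counts
    diag = np.arange(g)
    n_diag = int(counts[diag, diag].sum())
    n_off = int(counts.sum() - n_diag)
    overall = float(sums[diag, diag].sum() / n_diag)
    between_means = means.copy()
    between_means[diag, diag] = np.nan
    return BlockSummary(
        within_means=means[diag, diag].copy(),
        between_means=between_means,
        within_counts=counts[diag, diag].copy(),
        between_counts=counts,
        n_diag=n_diag,
        n_off=n_off,
        overall_within_mean=overall,
        include_diagonal=include_diagonal,
    )
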