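"""Build nonmetric dissimilarity matrices from raw feature data.

Three constructors cover the typical sources of nonmetric dissimilarity:
inverted alignment similarity scores (semimetric), correlation distance
between directional sensitivity profiles (quasimetric), and pairwise
Kullback-Leibler divergence between count profiles (asymmetric, zero
diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.special import rel_entr

from .core import DissimilarityMatrix, InputError

__all__ = [
    "FeatureTable",
    "invert_bit_scores",
    "correlation_dissimilarity",
    "kl_divergence_matrix",
]

_KINDS = ("similarity-scores", "sensitivity", "counts")


@dataclass(frozen=True)
class FeatureTable:
    """Objects-by-features real matrix with a kind tag.

    ``kind`` is one of ``"similarity-scores"``, ``"sensitivity"`` or
    ``"counts"``; count tables must be nonnegative.
    """

    values: pd.DataFrame
    kind: str = "sensitivity"

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InputError(f"kind must be one of {_KINDS}")
        if not isinstance(self.values, pd.DataFrame):
            object.__setattr__(
                self, "values", pd.DataFrame(np.asarray(self.values, float))
            )
        if self.kind == "counts" and (self.values.to_numpy() < 0).any():
            raise InputError("counts must be nonnegative")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.values.index)


def _square_frame(scores) -> pd.DataFrame:
    if isinstance(scores, DissimilarityMatrix):
        return pd.DataFrame(scores.values, index=scores.ids, columns=scores.ids)
    if isinstance(scores, FeatureTable):
        scores = scores.values
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame(np.asarray(scores, dtype=float))
    if scores.shape[0] != scores.shape[1]:
        raise InputError(f"similarity matrix must be square, got {scores.shape}")
    return scores.astype(float)


def invert_bit_scores(scores, mode: str = "reciprocal") -> DissimilarityMatrix:
    """Turn a square similarity-score matrix into dissimilarities.

    ``mode="reciprocal"`` (default) maps each score ``s`` to ``1/s`` and
    requires every observed score to be positive; ``mode="max-minus"``
    maps ``s`` to ``max(scores) - s``.  Asymmetry and missing entries of
    the input are preserved.
    """
    frame = _square_frame(scores)
    vals = frame.to_numpy(dtype=float, copy=True)
    obs = ~np.isnan(vals)
    if mode == "reciprocal":
        if (vals[obs] <= 0).any():
            raise InputError("reciprocal mode requires strictly positive scores")
        out = np.where(obs, 1.0 / np.where(obs, vals, 1.0), np.nan)
    elif mode == "max-minus":
        out = np.where(obs, np.nanmax(vals) - vals, np.nan)
    else:
        raise InputError("mode must be 'reciprocal' or 'max-minus'")
    return DissimilarityMatrix(out, ids=[str(i) for i in frame.index])


def _pair_correlation(x, y, method):
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise InputError("need >= 3 paired observations per object pair")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        raise InputError("undefined correlation: zero-variance profile")
    if method == "pearson":
        return float(np.corrcoef(xs, ys)[0, 1])
    if method == "spearman":
        return float(_st.spearmanr(xs, ys).statistic)
    raise InputError("method must be 'pearson' or 'spearman'")


def correlation_dissimilarity(
    profiles: FeatureTable | pd.DataFrame,
    profiles_ref: FeatureTable | pd.DataFrame | None = None,
    method: str = "pearson",
) -> DissimilarityMatrix:
    """``1 - correlation`` dissimilarity between object profiles.

    ``delta[a, b] = 1 - cor(profiles[a], profiles_ref[b])`` computed over
    the shared feature columns with pairwise-complete observations.  When
    two tables are given they play directional roles (object ``a`` from
    the first table, reference object ``b`` from the second), so the
    resulting matrix is in general asymmetric; with a single table the
    result is symmetric.  Values lie in ``[0, 2]``.
    """
    a = profiles.values if isinstance(profiles, FeatureTable) else profiles
    if profiles_ref is None:
        b = a
    else:
        b = (
            profiles_ref.values
            if isinstance(profiles_ref, FeatureTable)
            else profiles_ref
        )
    a = pd.DataFrame(a).astype(float)
    b = pd.DataFrame(b).astype(float)
    if list(a.index) != list(b.index):
        raise InputError("both profile tables must index the same objects")
    cols = [c for c in a.columns if c in set(b.columns)]
    if len(cols) < 3:
        raise InputError("need >= 3 shared feature columns")
    av = a[cols].to_numpy()
    bv = b[cols].to_numpy()
    n = av.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = 1.0 - _pair_correlation(av[i], bv[j], method)
    return DissimilarityMatrix(out, ids=[str(i) for i in a.index])


def kl_divergence_matrix(
    counts: FeatureTable | pd.DataFrame,
    pseudocount: float = 1e-8,
    variant: str = "kl",
) -> DissimilarityMatrix:
    """Pairwise Kullback-Leibler divergence between count profiles.

    Each object's feature vector is shifted by ``pseudocount`` and
    normalized into a probability vector ``p``.  Variant ``"kl"``
    (default) gives ``delta[a, b] = sum_k p_a[k] * log(p_a[k] / p_b[k])``
    in nats: asymmetric, nonnegative, zero diagonal.  Variant ``"js"``
    gives the symmetrized, smoothed Jensen-Shannon divergence, bounded by
    ``log(2)``.
    """
    frame = counts.values if isinstance(counts, FeatureTable) else counts
    frame = pd.DataFrame(frame).astype(float)
    vals = frame.to_numpy()
    if (vals < 0).any():
        raise InputError("counts must be nonnegative")
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    vals = vals + pseudocount
    row_sums = vals.sum(axis=1)
    if (row_sums <= 0).any():
        raise InputError("all-zero count row with zero pseudocount")
    p = vals / row_sums[:, None]
    if variant == "kl":
        if (p == 0).any():
            raise InputError(
                "zero probability cell: use a positive pseudocount"
            )
        # KL(a||b) = sum p_a log p_a - sum p_a log p_b
        self_ent = (p * np.log(p)).sum(axis=1)
        cross = p @ np.log(p).T
        out = self_ent[:, None] - cross
        np.fill_diagonal(out, 0.0)
    elif variant == "js":
        n = p.shape[0]
        out = np.empty((n, n))
        for i in range(n):
            m = 0.5 * (p[i][None, :] + p)
            out[i] = 0.5 * (
                rel_entr(p[i][None, :], m).sum(axis=1)
                + rel_entr(p, m).sum(axis=1)
            )
        np.fill_diagonal(out, 0.0)
    else:
        raise InputError("variant must be 'kl' or 'js'")
    return DissimilarityMatrix(out, ids=[str(i) for i in frame.index])
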