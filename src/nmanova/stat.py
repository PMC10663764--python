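"""The nonmetric-ANOVA test statistic and its replicate-sampling procedure.

Given a partitioned dissimilarity matrix the test compares, for every
ordered group pair ``(j, k)``, the mean of the between block against a
*proportionally sampled* reference mean drawn from within blocks of the
remaining groups.  Squared standardized differences accumulate into
``SNMB`` (between); the dispersion of the within-block means around the
overall within mean gives ``SNMW``.  Under the null of equal block means

    F = (SNMB / g) / SNMW   ~   F(g**2 - g, g - 1),

and the upper tail of that F law yields the p value.  Because the
reference means are random, the procedure is replicated ``R`` times and
the headline p value is the arithmetic mean of the per-replicate p
values.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .core import (
    BlockSummary,
    DissimilarityMatrix,
    InputError,
    Partition,
    block_summary,
    validate_inputs,
)

__all__ = [
    "SamplingOptions",
    "NmaResult",
    "proportional_sample_means",
    "snm_statistics",
    "f_and_p",
    "nm_anova",
]

log = logging.getLogger(__name__)

_FALLBACKS = ("all-within", "error")
_POLICIES = ("without-capped", "without-then-with")


@dataclass(frozen=True)
class SamplingOptions:
    """Knobs of the proportional-sampling procedure.

    ``fallback_pool`` controls what happens when the exclusion restriction
    empties the donor pool (always the case for g = 2): ``"all-within"``
    falls back to sampling from every within entry, ``"error"`` raises.
    ``replacement_policy`` handles a requested sample size larger than the
    pool: ``"without-capped"`` (default) caps it at the pool size,
    ``"without-then-with"`` switches to sampling with replacement.
    """

    n_samplings: int = 10_000
    seed: int | None = None
    fallback_pool: str = "all-within"
    replacement_policy: str = "without-capped"

    def __post_init__(self):
        if self.n_samplings < 1:
            raise InputError("n_samplings must be >= 1")
        if self.fallback_pool not in _FALLBACKS:
            raise InputError(f"fallback_pool must be one of {_FALLBACKS}")
        if self.replacement_policy not in _POLICIES:
            raise InputError(f"replacement_policy must be one of {_POLICIES}")


@dataclass
class NmaResult:
    """Per-replicate statistics and their summaries."""

    f_values: np.ndarray
    p_values: np.ndarray
    mean_p: float
    sd_p: float
    mean_f: float
    p_of_mean_f: float
    df1: int
    df2: int
    snm_within: float
    g: int
    sizes: tuple[int, ...]
    n_samplings: int
    degenerate: bool = False
    fallback_used: bool = False
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "mean_p": self.mean_p,
            "sd_p": self.sd_p,
            "mean_f": self.mean_f,
            "p_of_mean_f": self.p_of_mean_f,
            "df1": self.df1,
            "df2": self.df2,
            "snm_within": self.snm_within,
            "g": self.g,
            "sizes": list(self.sizes),
            "n_samplings": self.n_samplings,
            "degenerate": self.degenerate,
            "fallback_used": self.fallback_used,
            "seed": self.seed,
            "f_values": self.f_values.tolist(),
            "p_values": self.p_values.tolist(),
        }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "NmaResult":
        return cls(
            f_values=np.asarray(d["f_values"], dtype=float),
            p_values=np.asarray(d["p_values"], dtype=float),
            mean_p=d["mean_p"],
            sd_p=d["sd_p"],
            mean_f=d["mean_f"],
            p_of_mean_f=d["p_of_mean_f"],
            df1=d["df1"],
            df2=d["df2"],
            snm_within=d["snm_within"],
            g=d["g"],
            sizes=tuple(d["sizes"]),
            n_samplings=d["n_samplings"],
            degenerate=d["degenerate"],
            fallback_used=d["fallback_used"],
            seed=d.get("seed"),
        )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _ordered_pairs(g: int) -> list[tuple[int, int]]:
    return [(j, k) for j in range(g) for k in range(g) if j != k]


def _within_entries(
    matrix: DissimilarityMatrix, partition: Partition, include_diagonal: bool
) -> list[np.ndarray]:
    """Observed within-block entries per group, canonical row-major order."""
    out = []
    for j in range(partition.g):
        idx = np.flatnonzero(partition.codes == j)
        block = matrix.values[np.ix_(idx, idx)]
        if not include_diagonal:
            block = block.copy()
            np.fill_diagonal(block, np.nan)
        flat = block.ravel()
        out.append(flat[~np.isnan(flat)])
    return out


class _ProportionalSampler:
    """Precomputed pools and sample sizes for repeated proportional draws.

    For ordered pair ``(j, k)`` the pool holds every observed within entry
    of the groups other than j and k (ascending group order); the target
    sample size is ``round(nj * nk * n_diag / n_off)`` rounded half away
    from zero and floored at one.  One shared RNG stream is consumed pair
    by pair in ascending ``(j, k)`` order, so a seed fully determines the
    whole replicate sequence.  A pair whose (possibly capped) sample size
    equals its pool size is *forced*: its mean is constant and no
    randomness is consumed for it.
    """

    def __init__(
        self,
        matrix: DissimilarityMatrix,
        partition: Partition,
        summary: BlockSummary,
        options: SamplingOptions,
    ):
        self.pairs = _ordered_pairs(partition.g)
        within = _within_entries(matrix, partition, summary.include_diagonal)
        sizes = partition.sizes
        self.fallback_used = False
        self.pools: list[np.ndarray] = []
        self.sample_sizes: list[int] = []
        self.with_replacement: list[bool] = []
        for j, k in self.pairs:
            others = [within[m] for m in range(partition.g) if m not in (j, k)]
            pool = (
                np.concatenate(others) if others else np.empty(0, dtype=float)
            )
            if pool.size == 0:
                if options.fallback_pool == "error":
                    raise InputError("empty exclusion pool (g=2)")
                pool = np.concatenate(within)
                if not self.fallback_used:
                    log.warning(
                        "empty exclusion pool for pair (%d, %d); falling back "
                        "to all within entries (numerator/denominator "
                        "independence weakened)",
                        j + 1,
                        k + 1,
                    )
                self.fallback_used = True
            s = _round_half_away(
                sizes[j] * sizes[k] * summary.n_diag / summary.n_off
            )
            s = max(s, 1)
            replace = False
            if s > pool.size:
                if options.replacement_policy == "without-then-with":
                    replace = True
                else:
                    s = pool.size
            self.pools.append(pool)
            self.sample_sizes.append(s)
            self.with_replacement.append(replace)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One replicate: the proportional reference mean per ordered pair."""
        out = np.empty(len(self.pairs))
        for i, pool in enumerate(self.pools):
            s = self.sample_sizes[i]
            if self.with_replacement[i]:
                out[i] = pool[rng.integers(0, pool.size, size=s)].mean()
            elif s == pool.size:
                out[i] = pool.mean()
            else:
                out[i] = pool[rng.permutation(pool.size)[:s]].mean()
        return out


def proportional_sample_means(
    matrix: DissimilarityMatrix,
    partition: Partition,
    summary: BlockSummary,
    rng: np.random.Generator,
    options: SamplingOptions | None = None,
) -> dict[tuple[int, int], float]:
    """One proportional-sampling replicate.

    Returns the reference mean for every ordered group pair ``(j, k)``
    (0-based), the mean of a without-replacement sample of within entries
    drawn from the groups other than j and k.
    """
    options = options or SamplingOptions()
    sampler = _ProportionalSampler(matrix, partition, summary, options)
    means = sampler.draw(rng)
    return dict(zip(sampler.pairs, means))


def snm_statistics(
    summary: BlockSummary,
    prop_means: dict[tuple[int, int], float],
    partition: Partition,
) -> tuple[float, float]:
    """Sums of squared normalized means: ``(snm_within, snm_between)``.

    snm_within  = sum_j ( w_j * (mean_jj - overall_within_mean) )**2,
                  w_j = sqrt(observed within count of group j)
                  (equals nj with complete data and diagonal included);
    snm_between = sum_{j != k} (mean_jk - prop_mean_jk)**2
                  / (1/(nj*nk) + n_off/(nj*nk*n_diag)).
    """
    w = np.sqrt(summary.within_counts)
    snm_w = float(
        np.sum((w * (summary.within_means - summary.overall_within_mean)) ** 2)
    )
    sizes = partition.sizes
    snm_b = 0.0
    for (j, k), pm in prop_means.items():
        if j == k:
            raise InputError("prop_means keys must be ordered pairs j != k")
        njk = sizes[j] * sizes[k]
        var_factor = 1.0 / njk + summary.n_off / (njk * summary.n_diag)
        snm_b += (summary.between_means[j, k] - pm) ** 2 / var_factor
    return snm_w, float(snm_b)


def f_and_p(
    snm_between: float, snm_within: float, g: int
) -> tuple[float, int, int, float]:
    """F statistic and upper-tail p value.

    ``F = (snm_between / g) / snm_within`` referred to the F distribution
    with ``df1 = g**2 - g`` and ``df2 = g - 1``.  A zero denominator with a
    positive numerator gives ``(inf, ..., 0.0)``; both zero is degenerate
    and raises.
    """
    if g < 2:
        raise InputError("g < 2")
    if snm_between < 0 or snm_within < 0:
        raise InputError("negative sum of squares")
    df1, df2 = g * g - g, g - 1
    if snm_within == 0.0:
        if snm_between == 0.0:
            raise InputError("degenerate constant input")
        return math.inf, df1, df2, 0.0
    f = (snm_between / g) / snm_within
    p = float(_st.f.sf(f, df1, df2))
    return f, df1, df2, p


def nm_anova(
    matrix: DissimilarityMatrix,
    partition: Partition,
    options: SamplingOptions | None = None,
    include_diagonal: bool = True,
) -> NmaResult:
    """Run the full replicated test on a partitioned dissimilarity matrix.

    The block summary (and hence ``snm_within``) is computed once; each of
    the ``options.n_samplings`` replicates draws fresh proportional
    reference means and yields one (F, p) pair.  The headline p value is
    the mean of the per-replicate p values; the p value of the mean F is
    also reported.  Fully reproducible given ``options.seed``.
    """
    options = options or SamplingOptions()
    matrix, partition = validate_inputs(matrix, partition)
    summary = block_summary(matrix, partition, include_diagonal)
    sampler = _ProportionalSampler(matrix, partition, summary, options)
    rng = np.random.default_rng(options.seed)

    g = partition.g
    sizes = partition.sizes
    df1, df2 = g * g - g, g - 1
    log.info(
        "nmA: N=%d g=%d sizes=%s n_diag=%d n_off=%d missing=%.3f "
        "sample sizes=%s",
        matrix.n,
        g,
        sizes.tolist(),
        summary.n_diag,
        summary.n_off,
        matrix.missing_fraction,
        dict(zip(sampler.pairs, sampler.sample_sizes)),
    )

    w = np.sqrt(summary.within_counts)
    snm_w = float(
        np.sum((w * (summary.within_means - summary.overall_within_mean)) ** 2)
    )
    bm = np.array([summary.between_means[j, k] for j, k in sampler.pairs])
    njk = np.array([sizes[j] * sizes[k] for j, k in sampler.pairs], dtype=float)
    var_factor = 1.0 / njk + summary.n_off / (njk * summary.n_diag)

    R = options.n_samplings
    f_values = np.empty(R)
    snm_bs = np.empty(R)
    for r in range(R):
        pm = sampler.draw(rng)
        snm_bs[r] = float(np.sum((bm - pm) ** 2 / var_factor))

    degenerate = False
    if snm_w == 0.0:
        if np.all(snm_bs == 0.0):
            raise InputError("degenerate constant input")
        degenerate = True
        log.warning("snm_within is zero: F set to +inf, p to 0")
        f_values[:] = np.inf
        p_values = np.zeros(R)
    else:
        f_values = (snm_bs / g) / snm_w
        p_values = _st.f.sf(f_values, df1, df2)

    mean_f = float(f_values.mean())
    if math.isinf(mean_f):
        p_of_mean_f = 0.0
    else:
        p_of_mean_f = float(_st.f.sf(mean_f, df1, df2))
    return NmaResult(
        f_values=f_values,
        p_values=p_values,
        mean_p=float(p_values.mean()),
        sd_p=float(p_values.std(ddof=1)) if R > 1 else 0.0,
        mean_f=mean_f,
        p_of_mean_f=p_of_mean_f,
        df1=df1,
        df2=df2,
        snm_within=snm_w,
        g=g,
        sizes=tuple(int(s) for s in sizes),
        n_samplings=R,
        degenerate=degenerate,
        fallback_used=sampler.fallback_used,
        seed=options.seed,
    )
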