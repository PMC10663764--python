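"""Named sampling distributions for synthetic dissimilarity matrices.

A small extensible registry maps family names to validated samplers.  The
stock registry covers the common continuous/discrete families plus a few
deliberately exotic ones (von Mises, Zipf, Borel, Poisson-Dirichlet) so
that simulated dissimilarities can exercise heavy tails, circular support
and discreteness.  Register additional families with
:func:`register_family`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import InputError

__all__ = [
    "DistributionSpec",
    "register_family",
    "registered_families",
    "sample_distribution",
    "random_spec",
]


@dataclass(frozen=True)
class DistributionSpec:
    """A distribution family name plus its parameter vector."""

    family: str
    params: tuple[float, ...]

    def __init__(self, family: str, *params: float):
        if len(params) == 1 and isinstance(params[0], (tuple, list)):
            params = tuple(params[0])
        object.__setattr__(self, "family", str(family).lower())
        object.__setattr__(self, "params", tuple(float(p) for p in params))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return sample_distribution(self, n, rng)

    def __str__(self) -> str:
        return f"{self.family}({', '.join(repr(p) for p in self.params)})"


@dataclass(frozen=True)
class _Family:
    name: str
    n_params: int
    validate: Callable[[tuple], None]
    sampler: Callable[[tuple, int, np.random.Generator], np.ndarray]


_REGISTRY: dict[str, _Family] = {}


def register_family(name, n_params, validate, sampler) -> None:
    """Add (or replace) a family in the registry."""
    _REGISTRY[name.lower()] = _Family(name.lower(), n_params, validate, sampler)


def registered_families() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def sample_distribution(
    spec: DistributionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` iid values from ``spec``; reproducible given ``rng`` state."""
    fam = _REGISTRY.get(spec.family)
    if fam is None:
        raise InputError(
            f"unknown distribution family {spec.family!r}; "
            f"known: {registered_families()}"
        )
    if len(spec.params) != fam.n_params:
        raise InputError(
            f"{spec.family} expects {fam.n_params} parameters, "
            f"got {len(spec.params)}"
        )
    fam.validate(spec.params)
    return np.asarray(fam.sampler(spec.params, int(n), rng), dtype=float)


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise InputError(msg)


def _borel_tanner(params, n, rng):
    # Total progeny of a Poisson(a) branching process started from k
    # ancestors; finite a.s. for a < 1.
    k, a = params
    total = np.full(n, int(k), dtype=np.int64)
    current = total.copy()
    while current.any():
        offspring = rng.poisson(a * current)
        total += offspring
        current = offspring
    return total


def _poisson_dirichlet_first(params, n, rng):
    # First size-biased weight of the two-parameter Poisson-Dirichlet
    # (GEM) stick-breaking representation: Beta(1 - alpha, theta + alpha).
    alpha, theta = params
    return rng.beta(1.0 - alpha, theta + alpha, size=n)


def _install_stock_families() -> None:
    register_family(
        "normal",
        2,
        lambda p: _check(p[1] > 0, "normal: sd must be > 0"),
        lambda p, n, rng: rng.normal(p[0], p[1], size=n),
    )
    register_family(
        "uniform",
        2,
        lambda p: _check(p[0] < p[1], "uniform: requires a < b"),
        lambda p, n, rng: rng.uniform(p[0], p[1], size=n),
    )
    register_family(
        "cauchy",
        2,
        lambda p: _check(p[1] > 0, "cauchy: scale must be > 0"),
        lambda p, n, rng: p[0] + p[1] * rng.standard_cauchy(size=n),
    )
    register_family(
        "binomial",
        2,
        lambda p: _check(
            p[0] >= 1 and float(p[0]).is_integer() and 0 < p[1] <= 1,
            "binomial: requires integer n >= 1 and p in (0, 1]",
        ),
        lambda p, n, rng: rng.binomial(int(p[0]), p[1], size=n),
    )
    register_family(
        "poisson",
        1,
        lambda p: _check(p[0] > 0, "poisson: rate must be > 0"),
        lambda p, n, rng: rng.poisson(p[0], size=n),
    )
    register_family(
        "exponential",
        1,
        lambda p: _check(p[0] > 0, "exponential: scale must be > 0"),
        lambda p, n, rng: rng.exponential(p[0], size=n),
    )
    register_family(
        "gamma",
        2,
        lambda p: _check(
            p[0] > 0 and p[1] > 0, "gamma: shape and scale must be > 0"
        ),
        lambda p, n, rng: rng.gamma(p[0], p[1], size=n),
    )
    register_family(
        "beta",
        2,
        lambda p: _check(p[0] > 0 and p[1] > 0, "beta: a, b must be > 0"),
        lambda p, n, rng: rng.beta(p[0], p[1], size=n),
    )
    register_family(
        "vonmises",
        2,
        lambda p: _check(p[1] > 0, "vonmises: kappa must be > 0"),
        lambda p, n, rng: rng.vonmises(p[0], p[1], size=n),
    )
    register_family(
        "zipf",
        1,
        lambda p: _check(p[0] > 1, "zipf: exponent must be > 1"),
        lambda p, n, rng: rng.zipf(p[0], size=n),
    )
    register_family(
        "borel",
        2,
        lambda p: _check(
            p[0] >= 1 and float(p[0]).is_integer() and 0 < p[1] < 1,
            "borel: requires integer ancestors >= 1 and rate in (0, 1)",
        ),
        _borel_tanner,
    )
    register_family(
        "poisson-dirichlet",
        2,
        lambda p: _check(
            0 <= p[0] < 1 and p[1] > -p[0],
            "poisson-dirichlet: requires 0 <= alpha < 1 and theta > -alpha",
        ),
        _poisson_dirichlet_first,
    )


_install_stock_families()

# Families whose parameters get drawn from the 1..400 integer range in the
# randomized grid experiment, with the documented normalization exceptions
# (probability-like parameters divided by 400, ordering of uniform bounds,
# lower bounds for constrained parameters).
_GRID_MAX = 400


def random_spec(family: str, rng: np.random.Generator) -> DistributionSpec:
    """Random parameters for ``family``, integers in ``1..400``.

    The second parameter of binomial and borel is divided by 400 to land
    in (0, 1); uniform bounds are drawn until a < b; the zipf exponent is
    drawn from 2..400; poisson-dirichlet draws alpha in (0, 1) the same
    normalized way.
    """
    fam = family.lower()
    if fam not in _REGISTRY:
        raise InputError(f"unknown distribution family {family!r}")
    ints = lambda: int(rng.integers(1, _GRID_MAX + 1))  # noqa: E731
    if fam == "uniform":
        a, b = ints(), ints()
        while a == b:
            b = ints()
        return DistributionSpec(fam, min(a, b), max(a, b))
    if fam == "binomial":
        return DistributionSpec(fam, ints(), min(ints(), _GRID_MAX - 1) / _GRID_MAX)
    if fam == "borel":
        return DistributionSpec(fam, ints(), min(ints(), _GRID_MAX - 1) / _GRID_MAX)
    if fam == "zipf":
        return DistributionSpec(fam, int(rng.integers(2, _GRID_MAX + 1)))
    if fam == "poisson-dirichlet":
        return DistributionSpec(fam, min(ints(), _GRID_MAX - 1) / _GRID_MAX, ints())
    n_params = _REGISTRY[fam].n_params
    return DistributionSpec(fam, *(ints() for _ in range(n_params)))
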