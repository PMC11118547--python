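"""The two-parameter family of gauges for all-order interaction models.

Each member of the family is specified by a penalization strength
``lambda`` in [0, inf] and a factorized position-specific probability
distribution ``p``.  The derived quantity ``eta = lambda / (1 + lambda)``
runs over [0, 1] and is the natural coordinate: the projection matrix onto
the gauge space is a Kronecker product over positions of small
``(alpha+1) x (alpha+1)`` blocks whose entries are linear in ``eta``, so
every gauge-fixed parameter is a polynomial in ``eta`` of degree at most L.

Named special cases:

========================  ==========  =====================================
gauge                     lambda      p
========================  ==========  =====================================
trivial                   0           any (irrelevant)
euclidean                 alpha       uniform
equitable                 1           any
hierarchical              inf         any
zero_sum                  inf         uniform
wild_type                 inf         indicator of a wild-type sequence
generalized_wild_type     inf         zeros allowed for excluded characters
========================  ==========  =====================================

For 0 < lambda < inf and strictly positive ``p`` the gauge also arises from
constrained minimization of a diagonal quadratic penalty on parameters,
``Lambda[s', s'] = p(s') * lambda**order(s')``, over the gauge orbit.  At
the limit points (lambda in {0, inf} or zero probabilities) the projection
formula remains finite and is used directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce
from typing import Mapping, Sequence

import numpy as np

from .features import (
    Alphabet,
    ModelSpec,
    ParameterVector,
    WILDCARD,
)

NAMED_GAUGES = (
    "trivial",
    "euclidean",
    "equitable",
    "zero_sum",
    "hierarchical",
    "wild_type",
    "generalized_wild_type",
)

#: Above this feature count the projector is applied lazily (per-position
#: tensor contractions) instead of materializing the M x M matrix.
LAZY_KRON_THRESHOLD = 10_000


@dataclass(frozen=True)
class PositionDistribution:
    """A factorized distribution over sequences: p(s) = prod_l p[l, s_l].

    ``probs`` has shape (L, alpha); every row sums to one.  Zero entries are
    permitted (generalized wild-type gauges) — the projection route stays
    well-defined, while the penalization route refuses them.
    """

    alphabet: Alphabet
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2 or p.shape[1] != self.alphabet.size:
            raise ValueError(
                f"probs must have shape (L, {self.alphabet.size}), got {p.shape}"
            )
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        sums = p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"position {bad + 1}: probabilities sum to {sums[bad]!r}, not 1"
            )

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def uniform(cls, alphabet: Alphabet, length: int) -> "PositionDistribution":
        a = alphabet.size
        return cls(alphabet, np.full((length, a), 1.0 / a))

    @classmethod
    def from_sequence(cls, alphabet: Alphabet, sequence: str) -> "PositionDistribution":
        """Indicator distribution concentrated on one (wild-type) sequence."""
        p = np.zeros((len(sequence), alphabet.size))
        for l, c in enumerate(sequence):
            p[l, alphabet.index(c)] = 1.0
        return cls(alphabet, p)

    @classmethod
    def from_allowed(
        cls, alphabet: Alphabet, length: int, allowed: Mapping[int, Sequence[str]]
    ) -> "PositionDistribution":
        """Uniform over an allowed character set per position, zero outside.

        ``allowed`` maps 1-based positions to character collections;
        positions not listed allow the full alphabet.
        """
        p = np.zeros((length, alphabet.size))
        for l in range(1, length + 1):
            chars = allowed.get(l, alphabet.characters)
            chars = list(chars)
            if not chars:
                raise ValueError(f"position {l}: allowed character set is empty")
            for c in chars:
                p[l - 1, alphabet.index(c)] = 1.0 / len(chars)
        return cls(alphabet, p)

    def feature_probability(self, spec: ModelSpec) -> np.ndarray:
        """p(s') for every active feature: the product over non-wildcard
        positions of p[l, s'_l], with wildcard positions contributing 1."""
        codes = spec.codes
        out = np.ones(spec.n_features)
        for l in range(spec.length):
            col = codes[:, l]
            nonstar = col > 0
            out[nonstar] *= self.probs[l, col[nonstar] - 1]
        return out

    def mix_with_uniform(self, eps: float) -> "PositionDistribution":
        """(1 - eps) * p + eps / alpha at every position — the smoothing
        family whose eps -> 0 limit defines generalized wild-type gauges."""
        a = self.alphabet.size
        return PositionDistribution(
            self.alphabet, (1.0 - eps) * self.probs + eps / a
        )


@dataclass(frozen=True)
class GaugeParams:
    """A member (lambda, p) of the parametric gauge family.

    ``lam`` may be ``math.inf`` (hierarchical limit); all computations go
    through ``eta = lam / (1 + lam)``, which is finite everywhere on the
    family including the limit points.
    """

    lam: float
    dist: PositionDistribution

    def __post_init__(self) -> None:
        if not (self.lam >= 0):
            raise ValueError("lambda must be non-negative (inf allowed)")

    @property
    def eta(self) -> float:
        if math.isinf(self.lam):
            return 1.0
        return self.lam / (1.0 + self.lam)

    @classmethod
    def from_eta(cls, eta: float, dist: PositionDistribution) -> "GaugeParams":
        if not 0.0 <= eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        lam = math.inf if eta == 1.0 else eta / (1.0 - eta)
        return cls(lam, dist)


def single_position_block(alphabet: Alphabet, eta: float, p_l: np.ndarray) -> np.ndarray:
    """The (alpha+1) x (alpha+1) single-position projector block.

    Rows/columns are indexed by the augmented symbols (wildcard first).
    Row ``*`` is ``(eta, p_1 eta, ..., p_alpha eta)``; row ``c`` is
    ``(1 - eta, delta_{cc'} - p_{c'} eta)``.  The Kronecker product of these
    blocks over positions is the full projection matrix.
    """
    a = alphabet.size
    p = np.asarray(p_l, dtype=float)
    if p.shape != (a,):
        raise ValueError(f"p_l must have length {a}")
    B = np.empty((a + 1, a + 1))
    B[0, 0] = eta
    B[0, 1:] = eta * p
    B[1:, 0] = 1.0 - eta
    B[1:, 1:] = np.eye(a) - eta * p[None, :]
    return B


class ProjectionMatrix:
    """Projector onto the gauge space of a parametric-family member.

    Holds the per-position blocks; materializes the explicit M x M matrix
    only for small models, otherwise applies the Kronecker factorization as
    a sequence of tensor contractions.
    """

    def __init__(self, spec: ModelSpec, params: GaugeParams, lazy: bool | None = None):
        if not spec.is_all_order:
            raise ValueError(
                "parametric projection matrices are defined on the all-order "
                "feature space; for lower-order (hierarchical) models use "
                "seqgauge.hierarchical.project_hierarchical"
            )
        if params.dist.length != spec.length:
            raise ValueError("distribution length does not match spec length")
        self.spec = spec
        self.params = params
        self.blocks = [
            single_position_block(spec.alphabet, params.eta, params.dist.probs[l])
            for l in range(spec.length)
        ]
        if lazy is None:
            lazy = spec.n_features > LAZY_KRON_THRESHOLD
        self.lazy = lazy
        self._matrix: np.ndarray | None = None

    def matrix(self) -> np.ndarray:
        """Explicit M x M projector (Kronecker product of position blocks)."""
        if self._matrix is None:
            self._matrix = reduce(np.kron, self.blocks)
        return self._matrix

    def apply(self, theta: ParameterVector | np.ndarray) -> np.ndarray:
        vals = theta.values if isinstance(theta, ParameterVector) else np.asarray(theta, float)
        if self.lazy:
            a1 = self.spec.alphabet.size + 1
            L = self.spec.length
            t = vals.reshape((a1,) * L)
            for l, B in enumerate(self.blocks):
                t = np.moveaxis(np.tensordot(B, t, axes=([1], [l])), 0, l)
            return t.reshape(-1)
        return self.matrix() @ vals

    def project(self, theta: ParameterVector) -> ParameterVector:
        return ParameterVector(self.spec, self.apply(theta))


def projection_matrix(spec: ModelSpec, params: GaugeParams, lazy: bool | None = None) -> ProjectionMatrix:
    """Projector onto the gauge space for (lambda, p); all-order specs only."""
    return ProjectionMatrix(spec, params, lazy=lazy)


def projection_matrix_elements(spec: ModelSpec, params: GaugeParams) -> np.ndarray:
    """Direct elementwise evaluation of the projector entries.

    ``P[s', t']`` is a product over positions of per-position factors that
    depend on whether ``s'`` and ``t'`` carry the wildcard there.  This
    duplicates :class:`ProjectionMatrix` by construction and serves as an
    independent cross-check of the Kronecker route.
    """
    if not spec.is_all_order:
        raise ValueError("elementwise projector requires the all-order spec")
    eta = params.eta
    p = params.dist.probs
    codes = spec.codes  # (M, L), 0 = wildcard
    M = spec.n_features
    P = np.ones((M, M))
    for l in range(spec.length):
        row = codes[:, l][:, None]  # s'
        col = codes[:, l][None, :]  # t'
        factor = np.empty((M, M))
        both_char = (row > 0) & (col > 0)
        pc = np.where(col > 0, p[l, np.clip(col, 1, None) - 1], 0.0)
        factor = np.where(both_char, (row == col).astype(float) - pc * eta, factor)
        factor = np.where((row == 0) & (col > 0), pc * eta, factor)
        factor = np.where((row > 0) & (col == 0), 1.0 - eta, factor)
        factor = np.where((row == 0) & (col == 0), eta, factor)
        P *= factor
    return P


@dataclass(frozen=True)
class PenalizationMatrix:
    """Diagonal penalizer whose constrained minimizer realizes the gauge.

    Entries are ``p(s') * lambda**order(s')`` with wildcard positions
    contributing factor 1 to ``p(s')``.  Positive-definite exactly when
    0 < lambda < inf and all character probabilities are positive.
    """

    spec: ModelSpec
    diagonal: np.ndarray

    def matrix(self) -> np.ndarray:
        return np.diag(self.diagonal)


def penalization_matrix(spec: ModelSpec, params: GaugeParams) -> PenalizationMatrix:
    if params.lam == 0 or math.isinf(params.lam):
        raise ValueError(
            "limit gauge (lambda = 0 or inf) has no positive-definite "
            "penalizer; use the projection route"
        )
    if np.any(params.dist.probs <= 0):
        raise ValueError(
            "zero character probabilities give a singular penalizer; "
            "use the projection route (limit gauge)"
        )
    pfeat = params.dist.feature_probability(spec)
    diag = pfeat * params.lam ** spec.orders.astype(float)
    return PenalizationMatrix(spec, diag)


def named_gauge(
    name: str,
    spec: ModelSpec,
    dist: PositionDistribution | None = None,
    wt_sequence: str | None = None,
) -> GaugeParams:
    """GaugeParams for a named member of the parametric family.

    ``wild_type`` requires ``wt_sequence``; ``hierarchical``,
    ``equitable`` and ``generalized_wild_type`` accept a distribution
    (hierarchical/equitable default to uniform).
    """
    alphabet, L = spec.alphabet, spec.length
    uniform = PositionDistribution.uniform(alphabet, L)
    if name == "trivial":
        return GaugeParams(0.0, dist or uniform)
    if name == "euclidean":
        return GaugeParams(float(alphabet.size), uniform)
    if name == "equitable":
        return GaugeParams(1.0, dist or uniform)
    if name == "zero_sum":
        return GaugeParams(math.inf, uniform)
    if name == "hierarchical":
        return GaugeParams(math.inf, dist or uniform)
    if name == "wild_type":
        if wt_sequence is None:
            raise ValueError("wild_type gauge requires a wild-type sequence")
        spec.validate_sequence(wt_sequence)
        return GaugeParams(math.inf, PositionDistribution.from_sequence(alphabet, wt_sequence))
    if name == "generalized_wild_type":
        if dist is None:
            raise ValueError("generalized_wild_type gauge requires a distribution")
        return GaugeParams(math.inf, dist)
    raise ValueError(f"unknown gauge {name!r}; choose one of {NAMED_GAUGES}")


def wildtype_limit_check(
    spec: ModelSpec,
    p: PositionDistribution,
    eps_list: Sequence[float],
    theta: ParameterVector | None = None,
    seed: int = 20240512,
) -> "pd.DataFrame":
    """Distances between the smoothed-distribution hierarchical projections
    and the direct eta = 1 projection at ``p``, for each smoothing ``eps``.

    Confirms empirically that gauges with zero character probabilities are
    limits of gauges with positive probabilities.
    """
    import pandas as pd

    if theta is None:
        rng = np.random.default_rng(seed)
        theta = ParameterVector(spec, rng.standard_normal(spec.n_features))
    target = ProjectionMatrix(spec, GaugeParams(math.inf, p)).apply(theta)
    rows = []
    for eps in eps_list:
        smoothed = p.mix_with_uniform(eps)
        proj = ProjectionMatrix(spec, GaugeParams(math.inf, smoothed)).apply(theta)
        rows.append({"eps": eps, "distance": float(np.linalg.norm(proj - target))})
    return pd.DataFrame(rows)


def eta_sweep(
    spec: ModelSpec,
    p: PositionDistribution,
    theta_init: ParameterVector,
    eta_grid: Sequence[float] | None = None,
) -> "pd.DataFrame":
    """Gauge-fixed parameter values as functions of eta (long-format table).

    Each feature's trajectory is a polynomial in eta of degree at most L,
    interpolating between the trivial gauge at eta = 0 and the hierarchical
    gauge at eta = 1.
    """
    import pandas as pd

    if eta_grid is None:
        eta_grid = np.linspace(0.0, 1.0, 21)
    rows = []
    for eta in eta_grid:
        fixed = ProjectionMatrix(spec, GaugeParams.from_eta(float(eta), p)).apply(theta_init)
        for lab, val in zip(spec.features, fixed):
            rows.append({"feature": lab, "eta": float(eta), "value": float(val)})
    return pd.DataFrame(rows)
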