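"""Hierarchical-gauge machinery that scales to lower-order models.

The hierarchical gauge (the lambda -> inf member of the parametric family)
has an ANOVA interpretation: the constant term is the p-mean activity, each
additive term is the average effect of fixing one position to one
character, each pairwise term is the excess average effect of fixing two,
and so on.  That interpretation yields closed-form projection formulas
built entirely from conditional means of the landscape under the factorized
distribution p — no enumeration of sequence space is ever required, so the
same code handles additive, pairwise, nearest-neighbor and other
hierarchical models at protein-alphabet scale.

A model is *hierarchical* when its inactive features are closed upward:
zeroing a feature zeroes every higher-order feature that refines it.
Hierarchical-gauge projection preserves that zero pattern, which is what
lets a pairwise model stay a pairwise model after gauge fixing.

The same gauge underlies two landscape-analysis tools:

* variance decomposition — in the hierarchical gauge the landscape splits
  into p-orthogonal components, one per star/non-star pattern, so the
  p-variance of the landscape is the sum of per-order variances;
* truncation — discarding all terms above a chosen order yields the
  p-weighted least-squares approximation of the landscape among models of
  that order, giving local (e.g. additive) approximations tailored to a
  region of sequence space when p is supported on that region.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import (
    Alphabet,
    ModelSpec,
    ParameterVector,
    WILDCARD,
    feature_order,
)
from .parametric import PositionDistribution

logger = logging.getLogger(__name__)

MARGINALIZATION_ATOL = 1e-10


def _fixed_weights(
    model: ParameterVector,
    p: PositionDistribution,
    fixed: Mapping[int, int],
) -> np.ndarray:
    """Expectation of each feature indicator when sequences are drawn from p
    and the ``fixed`` positions (1-based -> character code 1..alpha) are then
    overridden with the given characters."""
    spec = model.spec
    codes = spec.codes
    w = np.ones(spec.n_features)
    for l in range(spec.length):
        col = codes[:, l]
        nonstar = col > 0
        if (l + 1) in fixed:
            w[nonstar] *= (col[nonstar] == fixed[l + 1]).astype(float)
        else:
            w[nonstar] *= p.probs[l, col[nonstar] - 1]
    return w


def _normalize_fixed(
    spec: ModelSpec, fixed: Iterable[tuple[int, str]] | Mapping[int, str]
) -> dict[int, int]:
    items = fixed.items() if isinstance(fixed, Mapping) else fixed
    out: dict[int, int] = {}
    for pos, char in items:
        if not 1 <= pos <= spec.length:
            raise ValueError(f"position {pos} out of range 1..{spec.length}")
        if pos in out:
            raise ValueError(f"position {pos} fixed more than once")
        out[pos] = spec.alphabet.index(char) + 1
    return out


def conditional_mean(
    model: ParameterVector,
    p: PositionDistribution,
    fixed: Iterable[tuple[int, str]] | Mapping[int, str] = (),
) -> float:
    """Mean activity over sequences drawn from p with some positions fixed.

    Fixing overrides p at the fixed positions, so the result is well-defined
    even when p assigns the fixed character probability zero.  Computed in
    closed form from the factorization of p — no sequence enumeration.
    """
    fx = _normalize_fixed(model.spec, fixed)
    return float(_fixed_weights(model, p, fx) @ model.values)


def marginalization_residual(model: ParameterVector, p: PositionDistribution) -> float:
    """Maximum violation of the hierarchical-gauge marginalization property.

    For every active feature group and every one of its non-wildcard
    positions, the p-weighted sum of parameters over characters at that
    position (inactive siblings counting as zero) must vanish.
    """
    sums: dict[tuple[str, int], float] = {}
    for lab, val in zip(model.spec.features, model.values):
        for i, c in enumerate(lab):
            if c == WILDCARD:
                continue
            key = (lab[:i] + WILDCARD + lab[i + 1 :], i)
            w = p.probs[i, model.spec.alphabet.index(c)]
            sums[key] = sums.get(key, 0.0) + w * val
    if not sums:
        return 0.0
    return max(abs(v) for v in sums.values())


def is_in_hierarchical_gauge(
    model: ParameterVector, p: PositionDistribution, atol: float = MARGINALIZATION_ATOL
) -> bool:
    scale = max(1.0, float(np.max(np.abs(model.values), initial=0.0)))
    return marginalization_residual(model, p) <= atol * scale


def project_hierarchical(
    model: ParameterVector, p: PositionDistribution
) -> ParameterVector:
    """Project a hierarchical model onto the hierarchical gauge defined by p.

    Each gauge-fixed parameter is built by inclusion-exclusion over
    conditional means: for the feature fixing character set F,

        theta'_F = sum over subsets F' of F of (-1)^{|F| - |F'|} E[f | F'],

    which makes the constant the p-mean, additive terms average mutational
    effects, pairwise terms epistatic excesses, and so on.  Predictions are
    unchanged on every sequence and the model's zero pattern is preserved.
    """
    spec = model.spec
    if not spec.is_hierarchical:
        raise ValueError(
            "model is not hierarchical: an inactive feature has an active "
            "refinement, so the zero pattern is not closed and the "
            "hierarchical gauge does not preserve the model's form"
        )
    if p.length != spec.length:
        raise ValueError("distribution length does not match spec length")

    cache: dict[frozenset[tuple[int, int]], float] = {}

    def cmean(fx: frozenset[tuple[int, int]]) -> float:
        if fx not in cache:
            cache[fx] = float(_fixed_weights(model, p, dict(fx)) @ model.values)
        return cache[fx]

    out = np.empty(spec.n_features)
    codes = spec.codes
    for m in range(spec.n_features):
        fixed = tuple(
            (l + 1, int(codes[m, l])) for l in range(spec.length) if codes[m, l] > 0
        )
        k = len(fixed)
        total = 0.0
        for r in range(k + 1):
            for sub in itertools.combinations(fixed, r):
                total += (-1.0) ** (k - r) * cmean(frozenset(sub))
        out[m] = total
    return ParameterVector(spec, out)


@dataclass
class LandscapeComponent:
    """One pattern-component of a landscape: the sum of all terms whose
    features share a star/non-star mask.  In the hierarchical gauge the
    components are mutually p-orthogonal."""

    model: ParameterVector
    pattern: tuple[int, ...]  # non-wildcard positions, 1-based

    @property
    def order(self) -> int:
        return len(self.pattern)

    def member_mask(self) -> np.ndarray:
        codes = self.model.spec.codes
        nonstar = codes > 0
        want = np.zeros(self.model.spec.length, dtype=bool)
        for pos in self.pattern:
            want[pos - 1] = True
        return np.all(nonstar == want[None, :], axis=1)

    def evaluate(self, sequences: Sequence[str]) -> np.ndarray:
        from .features import embed_sequences

        mask = self.member_mask()
        vals = np.where(mask, self.model.values, 0.0)
        return embed_sequences(self.model.spec, list(sequences)) @ vals


def landscape_components(model: ParameterVector) -> list[LandscapeComponent]:
    """All pattern components with at least one active feature."""
    patterns = sorted(
        {
            tuple(l + 1 for l in range(model.spec.length) if code[l] > 0)
            for code in model.spec.codes
        }
    )
    return [LandscapeComponent(model, pat) for pat in patterns]


@dataclass
class VarianceTable:
    """Per-order p-variances of a landscape in the hierarchical gauge."""

    orders: np.ndarray
    variances: np.ndarray
    p_has_zeros: bool = False

    @property
    def total(self) -> float:
        return float(self.variances.sum())

    def fractions(self) -> np.ndarray:
        t = self.total
        return self.variances / t if t > 0 else np.zeros_like(self.variances)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "order": self.orders,
                "variance": self.variances,
                "fraction": self.fractions(),
            }
        )


def variance_decomposition(
    model: ParameterVector,
    p: PositionDistribution,
    auto_project: bool = False,
    atol: float = MARGINALIZATION_ATOL,
) -> VarianceTable:
    """ANOVA-style decomposition of the landscape p-variance by interaction
    order: var_k = sum over order-k features of p(s') theta_{s'}^2.

    Requires the model to already satisfy the hierarchical-gauge
    marginalization property for p (pass ``auto_project=True`` to project
    first; a notice is logged).  The constant component carries no variance
    by convention.  When p has zero entries the variance refers to the
    supported region of sequence space only.
    """
    if not is_in_hierarchical_gauge(model, p, atol=atol):
        if not auto_project:
            raise ValueError(
                "model is not in the hierarchical gauge for this distribution "
                "(marginalization residual too large); project first or pass "
                "auto_project=True"
            )
        logger.info("auto-projecting model onto the hierarchical gauge for p")
        model = project_hierarchical(model, p)
    pfeat = p.feature_probability(model.spec)
    orders = model.spec.orders
    ks = np.arange(0, model.spec.length + 1)
    var = np.zeros(len(ks))
    for k in ks[1:]:
        sel = orders == k
        var[k] = float(np.sum(pfeat[sel] * model.values[sel] ** 2))
    has_zeros = bool(np.any(p.probs == 0))
    if has_zeros:
        logger.info("p has zero entries; variances refer to the supported subspace")
    return VarianceTable(ks, var, p_has_zeros=has_zeros)


def truncate_to_order(model: ParameterVector, max_order: int) -> ParameterVector:
    """Drop all terms above ``max_order`` from a hierarchical-gauge model.

    Because hierarchical-gauge components are p-orthogonal, the truncated
    model is the p-weighted least-squares approximation of the original
    landscape among models of the retained order — e.g. the best additive
    approximation on the region where p lives when ``max_order=1``.
    """
    spec = model.spec
    if not 0 <= max_order <= spec.length:
        raise ValueError(f"max_order must be in [0, {spec.length}]")
    new_spec = spec.restrict_to_order(max_order)
    keep = spec.orders <= max_order
    return ParameterVector(new_spec, model.values[keep])


def maximum_gauge_additive(model: ParameterVector) -> ParameterVector:
    """Express an additive model in the maximum gauge.

    The constant becomes the activity of the highest-activity sequence and
    every additive parameter the (non-positive) cost of deviating from the
    per-position optimum; at least one parameter per position is zero.  The
    maximum-gauge space is nonlinear, and for non-additive models it is not
    a gauge in the linear sense, so only additive specs are accepted.
    """
    spec = model.spec
    if spec.max_order > 1:
        raise ValueError(
            "maximum gauge is implemented for additive models only; the "
            "constraint set is nonlinear and ill-defined for interaction models"
        )
    n_additive = spec.length * spec.alphabet.size
    if spec.n_features != 1 + n_additive:
        raise ValueError("additive spec must contain every (position, character) feature")
    values = model.values.copy()
    codes = spec.codes
    const_idx = int(np.where(spec.orders == 0)[0][0])
    for l in range(spec.length):
        sel = np.where((spec.orders == 1) & (codes[:, l] > 0))[0]
        m = float(values[sel].max())
        values[sel] -= m
        values[const_idx] += m
    return ParameterVector(spec, values)


def region_distribution(
    alphabet: Alphabet,
    length: int,
    allowed: Mapping[int, Sequence[str]],
) -> PositionDistribution:
    """Factorized distribution uniform over a region of sequence space.

    ``allowed`` maps 1-based positions to allowed characters; unlisted
    positions allow everything.  The result is uniform over allowed
    characters at each position and zero outside — the distributions used
    to define region-specific hierarchical gauges.
    """
    return PositionDistribution.from_allowed(alphabet, length, allowed)
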