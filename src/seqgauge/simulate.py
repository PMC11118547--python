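"""Synthetic landscapes and a least-squares fitter.

Three generator presets cover the study designs this package is exercised
on:

* ``random_all_order`` — i.i.d. Gaussian activities on every sequence
  (a random landscape on, e.g., binary sequences of length 3), handed back
  as a trivial-gauge all-order parameter vector plus the full activity
  table;
* ``region_structured_pairwise`` — a pairwise-interaction landscape with a
  random additive/pairwise background plus planted positive effects for a
  few designated character combinations, creating disjoint high-activity
  regions of sequence space with distinct local structure;
* ``additive`` — a random additive landscape.

Activities are ``X theta`` plus optional i.i.d. Gaussian noise.  The
fitter is ordinary (optionally ridge-penalized) least squares; with an
identity ridge the unique minimizer lies in the Euclidean gauge, and the
unpenalized minimum-norm solution has the same property.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import (
    Alphabet,
    ModelSpec,
    ParameterVector,
    EnumerationCapError,
    MAX_DENSE_ROWS,
    WILDCARD,
    embed_sequences,
    enumerate_sequences,
)

PRESETS = ("random_all_order", "region_structured_pairwise", "additive")

#: Default region layout for a 4-letter, length-4 landscape: three disjoint
#: high-activity regions distinguished by the characters at positions 3 and 4,
#: mirroring landscapes whose epistatic hotspots sit at a couple of positions.
DEFAULT_REGIONS: tuple[dict[int, str], ...] = (
    {3: "G"},
    {3: "AC", 4: "G"},
    {3: "T", 4: "A"},
)


@dataclass
class SimConfig:
    """Configuration of a synthetic landscape.

    ``effect_scales`` maps interaction order to the standard deviation of
    the random coefficients of that order (order 0 = constant offset scale).
    ``regions`` lists per-region maps from 1-based position to the string of
    characters defining the region.  The seed is mandatory: every draw goes
    through one generator derived from it.
    """

    alphabet: str = "ACGT"
    length: int = 4
    preset: str = "region_structured_pairwise"
    effect_scales: Mapping[int, float] = field(default_factory=lambda: {0: 1.0, 1: 0.5, 2: 0.5})
    region_effect: float = 6.0
    region_pairwise_scale: float = 1.0
    noise_sd: float = 0.0
    regions: Sequence[Mapping[int, str]] = DEFAULT_REGIONS
    seed: int = 20240512

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        if any(s < 0 for s in self.effect_scales.values()) or self.noise_sd < 0:
            raise ValueError("scales and noise must be non-negative")


def _spec_for(config: SimConfig) -> ModelSpec:
    alphabet = Alphabet.from_string(config.alphabet)
    if config.preset == "random_all_order":
        return ModelSpec.all_order(alphabet, config.length)
    if config.preset == "additive":
        return ModelSpec.additive(alphabet, config.length)
    return ModelSpec.pairwise(alphabet, config.length)


def simulate_landscape(config: SimConfig) -> tuple[ParameterVector, pd.DataFrame]:
    """Draw a landscape and tabulate activities on all alpha^L sequences.

    Returns the true parameter vector and a DataFrame with columns
    ``sequence`` and ``activity`` (activities include noise if configured).
    """
    spec = _spec_for(config)
    if spec.n_sequences > MAX_DENSE_ROWS:
        raise EnumerationCapError(
            f"{spec.n_sequences} sequences exceed the enumeration cap"
        )
    rng = np.random.default_rng(config.seed)
    alphabet = spec.alphabet

    if config.preset == "random_all_order":
        # i.i.d. activities, expressed as a trivial-gauge parameter vector:
        # full-order features carry the activities, everything else is zero.
        scale = config.effect_scales.get(spec.length, 1.0)
        values = np.zeros(spec.n_features)
        full = spec.orders == spec.length
        values[full] = rng.standard_normal(int(full.sum())) * scale
        theta = ParameterVector(spec, values)
    else:
        values = np.zeros(spec.n_features)
        for k in range(0, spec.max_order + 1):
            sel = spec.orders == k
            scale = config.effect_scales.get(k, 0.0)
            values[sel] = rng.standard_normal(int(sel.sum())) * scale
        theta = ParameterVector(spec, values)
        if config.preset == "region_structured_pairwise":
            _plant_regions(theta, config, rng)

    sequences = list(enumerate_sequences(spec))
    activities = embed_sequences(spec, sequences) @ theta.values
    if config.noise_sd > 0:
        activities = activities + rng.normal(0.0, config.noise_sd, size=len(sequences))
    table = pd.DataFrame({"sequence": sequences, "activity": activities})
    return theta, table


def _pair_label(L: int, pos_a: int, char_a: str, pos_b: int, char_b: str) -> str:
    (lo, clo), (hi, chi) = sorted([(pos_a, char_a), (pos_b, char_b)])
    return (
        WILDCARD * (lo - 1)
        + clo
        + WILDCARD * (hi - lo - 1)
        + chi
        + WILDCARD * (L - hi)
    )


def _plant_regions(theta: ParameterVector, config: SimConfig, rng: np.random.Generator) -> None:
    """Add large positive effects on each region's defining character
    conjunctions and region-specific pairwise structure, in place.

    The region bonus is planted on the conjunction of the region's defining
    characters — the additive feature for a one-position region, split
    across the pairwise features of the defining combination otherwise — so
    every region member gains exactly ``region_effect`` and no sequence
    outside the region gains any of it.  Random pairwise terms coupling the
    defining characters to the free positions then give each region its own
    local additive structure."""
    import itertools

    spec = theta.spec
    idx = spec.feature_index
    L = spec.length
    for region in config.regions:
        positions = sorted(region)
        k = len(positions)
        for combo in itertools.product(*[region[pos] for pos in positions]):
            if k == 1:
                pos, c = positions[0], combo[0]
                lab = WILDCARD * (pos - 1) + c + WILDCARD * (L - pos)
                theta.values[idx[lab]] += config.region_effect
            else:
                n_pairs = k * (k - 1) // 2
                for i, j in itertools.combinations(range(k), 2):
                    lab = _pair_label(L, positions[i], combo[i], positions[j], combo[j])
                    theta.values[idx[lab]] += config.region_effect / n_pairs
        free = [l for l in range(1, L + 1) if l not in region]
        anchors = [(pos, c) for pos, chars in region.items() for c in chars]
        for pos, c in anchors:
            for l in free:
                for c2 in spec.alphabet.characters:
                    lab = _pair_label(L, pos, c, l, c2)
                    theta.values[idx[lab]] += rng.normal(0.0, config.region_pairwise_scale)


def fit_least_squares(
    table: pd.DataFrame, spec: ModelSpec, ridge: float = 0.0
) -> ParameterVector:
    """Least-squares fit of a one-hot model to a sequence-activity table.

    With ``ridge > 0`` the (unique) minimizer of
    ``||y - X theta||^2 + ridge ||theta||^2`` is returned, which lies in
    the Euclidean gauge up to O(ridge).  With ``ridge = 0`` the minimum-norm
    least-squares solution is returned, which lies in the Euclidean gauge
    exactly.
    """
    if len(table) == 0:
        raise ValueError("empty sequence-activity table")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    sequences = table["sequence"].tolist()
    y = table["activity"].to_numpy(dtype=float)
    X = embed_sequences(spec, sequences)
    if ridge == 0.0:
        theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        # augmented form [X; sqrt(ridge) I] keeps the solve well-conditioned
        # even for tiny ridge weights
        M = spec.n_features
        A = np.vstack([X, np.sqrt(ridge) * np.eye(M)])
        b = np.concatenate([y, np.zeros(M)])
        theta, *_ = np.linalg.lstsq(A, b, rcond=None)
    return ParameterVector(spec, theta)
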