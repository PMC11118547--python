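"""Alphabets, augmented-sequence features, one-hot embeddings, and gauge freedoms.

A one-hot model assigns one parameter to each *augmented sequence*: a
length-``L`` string over the alphabet plus the wildcard ``*``.  An augmented
sequence acts as a match pattern — its feature is 1 on every sequence that
agrees with it at all non-wildcard positions.  The constant feature is
``"*" * L``, additive features have one non-wildcard position, pairwise
features two, and so on up to order ``L``.

Because lower-order features are sums of higher-order ones (summing a
feature over all characters at one of its positions yields the feature of
order one less), the columns of the design matrix are linearly dependent and
the model has gauge freedoms: directions in parameter space along which all
predictions are unchanged.  :func:`gauge_freedom_basis` computes an
orthonormal basis for that null space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.linalg

WILDCARD = "*"

#: Guard rails for dense enumeration (rows = sequences, cols = features).
MAX_DENSE_ROWS = 1_000_000
MAX_DENSE_COLS = 100_000

#: Relative singular-value cutoff used for null-space / rank computations.
NULLSPACE_RCOND = 1e-10


class EnumerationCapError(ValueError):
    """Raised when a dense enumeration would exceed the configured cap."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered alphabet of single-character symbols.

    The wildcard ``"*"`` is reserved and may never appear among the
    characters; it is used to build augmented sequences.
    """

    characters: tuple[str, ...]

    def __post_init__(self) -> None:
        chars = tuple(self.characters)
        object.__setattr__(self, "characters", chars)
        if len(chars) < 2:
            raise ValueError("alphabet needs at least 2 characters")
        if len(set(chars)) != len(chars):
            raise ValueError("alphabet characters must be unique")
        for c in chars:
            if len(c) != 1:
                raise ValueError(f"alphabet symbols must be single characters, got {c!r}")
        if WILDCARD in chars:
            raise ValueError('"*" is reserved as the wildcard and cannot be a character')

    @classmethod
    def from_string(cls, s: str) -> "Alphabet":
        return cls(tuple(s))

    @property
    def size(self) -> int:
        return len(self.characters)

    @property
    def augmented(self) -> tuple[str, ...]:
        """Symbols of the augmented alphabet, wildcard first."""
        return (WILDCARD,) + self.characters

    def index(self, c: str) -> int:
        try:
            return self.characters.index(c)
        except ValueError:
            raise ValueError(f"character {c!r} not in alphabet {''.join(self.characters)!r}")

    def __contains__(self, c: str) -> bool:
        return c in self.characters

    def __str__(self) -> str:
        return "".join(self.characters)


def feature_order(label: str) -> int:
    """Interaction order of an augmented sequence = number of non-wildcard positions."""
    return sum(1 for c in label if c != WILDCARD)


def _label_rank(label: str, alphabet: Alphabet) -> int:
    """Mixed-radix rank of a label in tensor-product order (wildcard first,
    position 1 most significant)."""
    aug = alphabet.augmented
    r = 0
    for c in label:
        r = r * len(aug) + aug.index(c)
    return r


@dataclass(frozen=True)
class ModelSpec:
    """A one-hot model: alphabet, sequence length, and the set of active features.

    ``features`` is the ordered tuple of active augmented-sequence labels in
    canonical tensor-product order: per position the symbol order is
    ``("*", c1, ..., c_alpha)`` and position 1 is the most significant digit.
    This ordering makes the parametric projection matrix an exact Kronecker
    product of per-position blocks.
    """

    alphabet: Alphabet
    length: int
    features: tuple[str, ...]
    preset: str = "custom"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        aug = set(self.alphabet.augmented)
        seen = set()
        for lab in self.features:
            if len(lab) != self.length:
                raise ValueError(f"feature label {lab!r} does not have length {self.length}")
            for pos, c in enumerate(lab, start=1):
                if c not in aug:
                    raise ValueError(
                        f"feature label {lab!r}: position {pos}: character {c!r} "
                        f"not in augmented alphabet"
                    )
            if lab in seen:
                raise ValueError(f"duplicate feature label {lab!r}")
            seen.add(lab)
        ranks = [_label_rank(lab, self.alphabet) for lab in self.features]
        if any(a >= b for a, b in zip(ranks, ranks[1:])):
            order = tuple(lab for _, lab in sorted(zip(ranks, self.features)))
            object.__setattr__(self, "features", order)

    # ---- constructors ----------------------------------------------------

    @classmethod
    def constant(cls, alphabet: Alphabet, length: int) -> "ModelSpec":
        return cls(alphabet, length, (WILDCARD * length,), preset="constant")

    @classmethod
    def additive(cls, alphabet: Alphabet, length: int) -> "ModelSpec":
        return cls.up_to_order(alphabet, length, 1, preset="additive")

    @classmethod
    def pairwise(cls, alphabet: Alphabet, length: int) -> "ModelSpec":
        return cls.up_to_order(alphabet, length, 2, preset="pairwise")

    @classmethod
    def all_order(cls, alphabet: Alphabet, length: int) -> "ModelSpec":
        labels = tuple(
            "".join(t) for t in itertools.product(alphabet.augmented, repeat=length)
        )
        return cls(alphabet, length, labels, preset="all_order")

    @classmethod
    def up_to_order(
        cls, alphabet: Alphabet, length: int, max_order: int, preset: str | None = None
    ) -> "ModelSpec":
        if not 0 <= max_order <= length:
            raise ValueError(f"max_order must be in [0, {length}]")
        labels = tuple(
            "".join(t)
            for t in itertools.product(alphabet.augmented, repeat=length)
            if feature_order("".join(t)) <= max_order
        )
        return cls(alphabet, length, labels, preset=preset or "custom")

    @classmethod
    def nearest_neighbor(cls, alphabet: Alphabet, length: int) -> "ModelSpec":
        """Constant + additive + pairwise features at adjacent positions only."""
        labels = []
        for t in itertools.product(alphabet.augmented, repeat=length):
            lab = "".join(t)
            nonstar = [i for i, c in enumerate(lab) if c != WILDCARD]
            if len(nonstar) <= 1:
                labels.append(lab)
            elif len(nonstar) == 2 and nonstar[1] - nonstar[0] == 1:
                labels.append(lab)
        return cls(alphabet, length, tuple(labels), preset="nearest_neighbor")

    @classmethod
    def from_features(
        cls, alphabet: Alphabet, length: int, labels: Iterable[str]
    ) -> "ModelSpec":
        return cls(alphabet, length, tuple(labels), preset="custom")

    # ---- derived quantities ----------------------------------------------

    @property
    def n_features(self) -> int:
        """M, the number of active features (model parameters)."""
        return len(self.features)

    @property
    def n_sequences(self) -> int:
        """N = alpha^L, the number of sequences."""
        return self.alphabet.size**self.length

    @cached_property
    def orders(self) -> np.ndarray:
        """Interaction order of each active feature."""
        return np.array([feature_order(lab) for lab in self.features], dtype=int)

    @property
    def max_order(self) -> int:
        return int(self.orders.max())

    @cached_property
    def codes(self) -> np.ndarray:
        """(M, L) integer codes: 0 for wildcard, 1..alpha for characters."""
        aug = {c: i for i, c in enumerate(self.alphabet.augmented)}
        return np.array([[aug[c] for c in lab] for lab in self.features], dtype=np.int64)

    @cached_property
    def feature_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.features)}

    @property
    def is_all_order(self) -> bool:
        return self.n_features == (self.alphabet.size + 1) ** self.length

    @cached_property
    def is_hierarchical(self) -> bool:
        """Zero-pattern closure: if a feature is inactive, so is every
        refinement obtained by replacing one of its wildcards with a
        character.  Equivalently, replacing any non-wildcard character of an
        active feature with a wildcard must yield another active feature."""
        active = set(self.features)
        for lab in self.features:
            for i, c in enumerate(lab):
                if c != WILDCARD:
                    parent = lab[:i] + WILDCARD + lab[i + 1 :]
                    if parent not in active:
                        return False
        return True

    def restrict_to_order(self, max_order: int, preset: str | None = None) -> "ModelSpec":
        """Spec with features above ``max_order`` removed."""
        if not 0 <= max_order <= self.length:
            raise ValueError(f"max_order must be in [0, {self.length}]")
        keep = tuple(
            lab for lab in self.features if feature_order(lab) <= max_order
        )
        return ModelSpec(self.alphabet, self.length, keep, preset=preset or "custom")

    def validate_sequence(self, s: str) -> None:
        if len(s) != self.length:
            raise ValueError(f"sequence {s!r} does not have length {self.length}")
        for pos, c in enumerate(s, start=1):
            if c not in self.alphabet:
                raise ValueError(
                    f"sequence {s!r}: position {pos}: character {c!r} not in "
                    f"alphabet {str(self.alphabet)!r}"
                )


@dataclass
class ParameterVector:
    """Real parameter values keyed by the active features of a spec."""

    spec: ModelSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.spec.n_features,):
            raise ValueError(
                f"expected {self.spec.n_features} values, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("parameter values must be finite")
        self.values = v

    @classmethod
    def from_dict(cls, spec: ModelSpec, mapping: Mapping[str, float]) -> "ParameterVector":
        extra = set(mapping) - set(spec.features)
        if extra:
            raise ValueError(f"labels not active in spec: {sorted(extra)[:5]}")
        vals = np.array([mapping.get(lab, 0.0) for lab in spec.features], dtype=float)
        return cls(spec, vals)

    @classmethod
    def zeros(cls, spec: ModelSpec) -> "ParameterVector":
        return cls(spec, np.zeros(spec.n_features))

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.spec.features, self.values.tolist()))

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.spec.feature_index[label]])

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.spec, self.values.copy())

    @property
    def constant(self) -> float:
        return self[WILDCARD * self.spec.length]


# ---------------------------------------------------------------------------
# Enumeration, embedding, design matrices


def enumerate_features(spec: ModelSpec) -> list[str]:
    """Active augmented-sequence labels in canonical tensor-product order."""
    return list(spec.features)


def enumerate_sequences(spec: ModelSpec) -> Iterator[str]:
    """All alpha^L sequences, lexicographic in declared alphabet order."""
    for t in itertools.product(spec.alphabet.characters, repeat=spec.length):
        yield "".join(t)


def sequence_codes(spec: ModelSpec, sequences: Sequence[str]) -> np.ndarray:
    """(n, L) integer codes 1..alpha for a batch of sequences."""
    idx = {c: i + 1 for i, c in enumerate(spec.alphabet.characters)}
    out = np.empty((len(sequences), spec.length), dtype=np.int64)
    for r, s in enumerate(sequences):
        spec.validate_sequence(s)
        out[r] = [idx[c] for c in s]
    return out


def embed_sequence(spec: ModelSpec, s: str) -> np.ndarray:
    """Binary feature vector of a sequence: component ``s'`` is 1 iff the
    sequence matches ``s'`` at every non-wildcard position."""
    return embed_sequences(spec, [s])[0]


def embed_sequences(spec: ModelSpec, sequences: Sequence[str]) -> np.ndarray:
    """(n, M) binary design rows for a batch of sequences."""
    sc = sequence_codes(spec, sequences)  # (n, L)
    fc = spec.codes  # (M, L)
    # match at position l: feature is wildcard or equal character
    out = np.ones((len(sequences), spec.n_features), dtype=float)
    for l in range(spec.length):
        col = fc[:, l]  # (M,)
        match = (col[None, :] == 0) | (col[None, :] == sc[:, l][:, None])
        out *= match
    return out


def build_design_matrix(
    spec: ModelSpec,
    max_rows: int = MAX_DENSE_ROWS,
    max_cols: int = MAX_DENSE_COLS,
) -> np.ndarray:
    """Dense N x M design matrix, rows in lexicographic sequence order.

    Refuses to enumerate when N or M exceed the caps; closed-form routes
    (see :mod:`seqgauge.hierarchical`) should be used instead at that scale.
    """
    N, M = spec.n_sequences, spec.n_features
    if N > max_rows:
        raise EnumerationCapError(
            f"design matrix would have N={N} rows, exceeding the cap of {max_rows}"
        )
    if M > max_cols:
        raise EnumerationCapError(
            f"design matrix would have M={M} columns, exceeding the cap of {max_cols}"
        )
    seqs = list(enumerate_sequences(spec))
    chunks = []
    for start in range(0, N, 8192):
        chunks.append(embed_sequences(spec, seqs[start : start + 8192]))
    return np.vstack(chunks)


def predict(spec: ModelSpec, theta: ParameterVector | np.ndarray, sequences: Sequence[str]) -> np.ndarray:
    """Model predictions f(s) = x(s) . theta for a batch of sequences."""
    vals = theta.values if isinstance(theta, ParameterVector) else np.asarray(theta, float)
    out = np.empty(len(sequences))
    for start in range(0, len(sequences), 8192):
        batch = sequences[start : start + 8192]
        out[start : start + len(batch)] = embed_sequences(spec, list(batch)) @ vals
    return out


def predict_all(spec: ModelSpec, theta: ParameterVector | np.ndarray) -> np.ndarray:
    """Predictions on all alpha^L sequences, in lexicographic order."""
    return predict(spec, theta, list(enumerate_sequences(spec)))


def feature_gram(spec: ModelSpec) -> np.ndarray:
    """The M x M Gram matrix X^T X in closed form.

    For one-hot features the (s', t') entry counts sequences matching both
    patterns: alpha^(L - u) when the patterns agree on their shared
    non-wildcard positions (u = size of the union of non-wildcard position
    sets), zero when they conflict.  Avoids enumerating sequence space.
    """
    codes = spec.codes
    M = spec.n_features
    compatible = np.ones((M, M), dtype=bool)
    union = np.zeros((M, M), dtype=np.int64)
    for l in range(spec.length):
        col = codes[:, l]
        row_c, col_c = col[:, None], col[None, :]
        both = (row_c > 0) & (col_c > 0)
        compatible &= ~(both & (row_c != col_c))
        union += ((row_c > 0) | (col_c > 0)).astype(np.int64)
    a = float(spec.alphabet.size)
    return np.where(compatible, a ** (spec.length - union).astype(float), 0.0)


def gauge_freedom_basis(spec: ModelSpec) -> np.ndarray:
    """Orthonormal basis (M x d) of the space of gauge freedoms G = null(X).

    Additive models have d = L; pairwise models have
    d = L + C(L,2)(2*alpha - 1); the all-order model has
    d = (alpha+1)^L - alpha^L.  Small models use an SVD of the dense design
    matrix; larger ones use the closed-form Gram matrix, whose null space is
    the same.
    """
    if spec.n_features > MAX_DENSE_COLS:
        raise EnumerationCapError(
            f"M={spec.n_features} columns exceed the cap of {MAX_DENSE_COLS}"
        )
    if spec.n_sequences <= 8192:
        X = build_design_matrix(spec)
        return scipy.linalg.null_space(X, rcond=NULLSPACE_RCOND)
    # Gram eigenvalues of a null direction are exactly 0 analytically but
    # come out at ~eps * w_max numerically, so the cutoff must be relative
    # to the eigenvalue scale (the true nonzero spectrum sits many orders
    # above it for these binary designs).
    w, V = scipy.linalg.eigh(feature_gram(spec))
    return V[:, w <= NULLSPACE_RCOND * w.max()]
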