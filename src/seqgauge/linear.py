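"""Projection onto arbitrary linear gauge spaces.

A linear gauge is a subspace Theta of parameter space that meets every
gauge orbit exactly once; fixing the gauge means projecting a parameter
vector along the space of gauge freedoms G onto Theta.  Two specifications
are supported:

* an explicit basis for Theta, giving an oblique projector along G;
* a positive-definite penalizer Lambda, whose gauge space is the set of
  minimum-Lambda-norm representatives of each orbit, with projector
  ``P = Lambda^{-1/2} (X Lambda^{-1/2})^+ X``.

Inference with an L2 parameter regularizer Lambda lands in the Lambda
gauge: as the penalty weight shrinks, the ridge solution approaches the
gauge space determined by Lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .features import (
    ModelSpec,
    ParameterVector,
    build_design_matrix,
    gauge_freedom_basis,
    predict_all,
)

PINV_RCOND = 1e-10
MAX_PENALIZER_CONDITION = 1e12
MIN_PRINCIPAL_ANGLE = 1e-8


@dataclass
class LinearGaugeSpec:
    """A linear gauge, given either by a basis of Theta or a penalizer."""

    basis: np.ndarray | None = None
    penalizer: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.basis is None) == (self.penalizer is None):
            raise ValueError("specify exactly one of basis or penalizer")
        if self.basis is not None:
            B = np.asarray(self.basis, dtype=float)
            if B.ndim != 2:
                raise ValueError("basis must be a 2-D array (M x dim)")
            if np.linalg.matrix_rank(B, tol=None) < B.shape[1]:
                raise ValueError("basis vectors must be linearly independent")
            self.basis = B
        if self.penalizer is not None:
            L = np.asarray(self.penalizer, dtype=float)
            if L.ndim != 2 or L.shape[0] != L.shape[1]:
                raise ValueError("penalizer must be a square matrix")
            self.penalizer = L

    @classmethod
    def from_basis(cls, basis: np.ndarray) -> "LinearGaugeSpec":
        return cls(basis=basis)

    @classmethod
    def from_penalizer(cls, penalizer: np.ndarray) -> "LinearGaugeSpec":
        return cls(penalizer=penalizer)


def _penalizer_inv_sqrt(Lam: np.ndarray) -> np.ndarray:
    """Lambda^{-1/2} by symmetric eigendecomposition; refuses ill-conditioned
    or non-positive-definite penalizers."""
    Lam = 0.5 * (Lam + Lam.T)
    w, V = scipy.linalg.eigh(Lam)
    if w[0] <= 0:
        raise ValueError("penalizer must be positive-definite")
    if w[-1] / w[0] > MAX_PENALIZER_CONDITION:
        raise ValueError(
            f"penalizer condition number {w[-1] / w[0]:.3g} exceeds "
            f"{MAX_PENALIZER_CONDITION:.0e}; result would not be trustworthy"
        )
    return (V / np.sqrt(w)) @ V.T


def linear_projector(spec: ModelSpec, gauge: LinearGaugeSpec) -> np.ndarray:
    """The M x M projector onto the gauge space along the gauge freedoms."""
    X = build_design_matrix(spec)
    if gauge.penalizer is not None:
        S = _penalizer_inv_sqrt(gauge.penalizer)
        return S @ np.linalg.pinv(X @ S, rcond=PINV_RCOND) @ X
    B = gauge.basis
    G = gauge_freedom_basis(spec)
    rank_x = B.shape[0] - G.shape[1]
    if B.shape[1] != rank_x:
        raise ValueError(
            f"gauge space has dimension {B.shape[1]} but must equal "
            f"rank(X) = {rank_x} to intersect each orbit exactly once"
        )
    if G.shape[1] > 0:
        # smallest principal angle between span(B) and G, measured through
        # the smallest singular value of the stacked orthonormal bases
        # (sigma_min ~ angle / sqrt(2) for small angles); this resolves far
        # below the sqrt(eps) floor of arccos-based routines
        Bq = scipy.linalg.orth(B)
        sigma_min = scipy.linalg.svdvals(np.hstack([Bq, G]))[-1]
        angle = math.sqrt(2.0) * sigma_min
        if angle < MIN_PRINCIPAL_ANGLE:
            raise ValueError(
                "gauge space is not transversal to the gauge freedoms: "
                f"smallest principal angle ~{angle:.3g} rad"
            )
    # oblique projector: theta = B a + G b, keep the B part
    A = np.hstack([B, G])
    coeff = np.linalg.solve(A, np.eye(A.shape[0])) if A.shape[0] == A.shape[1] else np.linalg.pinv(A)
    return B @ coeff[: B.shape[1], :]


def project_linear(
    spec: ModelSpec, gauge: LinearGaugeSpec, theta: ParameterVector
) -> ParameterVector:
    """Gauge-fix ``theta``: the unique vector in the gauge space producing
    the same predictions on every sequence."""
    P = linear_projector(spec, gauge)
    return ParameterVector(spec, P @ theta.values)


def same_orbit(
    spec: ModelSpec,
    theta_a: ParameterVector,
    theta_b: ParameterVector,
    tol: float = 1e-9,
) -> tuple[bool, float]:
    """Whether two parameter vectors make identical predictions.

    Returns the verdict and the maximum absolute prediction discrepancy
    over all sequences.
    """
    diff = predict_all(spec, theta_a.values - theta_b.values)
    disc = float(np.max(np.abs(diff))) if diff.size else 0.0
    scale = max(
        1.0,
        float(np.max(np.abs(theta_a.values), initial=0.0)),
        float(np.max(np.abs(theta_b.values), initial=0.0)),
    )
    return disc <= tol * scale, disc
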