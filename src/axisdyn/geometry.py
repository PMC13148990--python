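"""Orthogonal decomposition of late encoding axes into old and new tuning.

The late-window face axis ν2 is decomposed into a component parallel to the
early-window axis ν1 and a residual ν⊥ orthogonal to it; ν⊥ is the newly
emergent tuning direction.  The module also computes the principal orthogonal
direction of the stimulus features after removal of the ν⊥ component (used as
a visualization ordinate) and samples feature-space points along ν⊥ at fixed
multiples of the projection s.d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_space import fix_signs

__all__ = [
    "AxisDecomposition",
    "decompose",
    "principal_orthogonal_direction",
    "sample_along_direction",
]


@dataclass
class AxisDecomposition:
    v1: np.ndarray  # early axis
    v2: np.ndarray  # late axis
    v_par: np.ndarray  # component of v2 along v1
    v_perp: np.ndarray  # residual (new tuning direction)
    principal_orth: np.ndarray | None = None

    @property
    def new_tuning_fraction(self) -> float:
        """Fraction of |v2|² carried by the orthogonal component."""
        n2 = float(np.linalg.norm(self.v2) ** 2)
        if n2 == 0:
            return float("nan")
        return float(np.linalg.norm(self.v_perp) ** 2 / n2)


def decompose(v1: np.ndarray, v2: np.ndarray) -> AxisDecomposition:
    """Split ``v2 = v_par + v_perp`` relative to ``v1``.

    ``v1`` is normalized to unit length first, so
    ``v_par = <v̂1, v2> v̂1`` is the orthogonal projection of ``v2`` onto the
    ``v1`` direction regardless of the norm of ``v1``.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    if n1 == 0:
        raise ValueError("v1 has zero norm")
    v1_hat = v1 / n1
    v_par = (v1_hat @ v2) * v1_hat
    return AxisDecomposition(v1=v1, v2=v2, v_par=v_par, v_perp=v2 - v_par)


def principal_orthogonal_direction(F: np.ndarray, v_perp: np.ndarray) -> np.ndarray:
    """First PC of the stimulus features after removing their ν⊥ component.

    Each feature row ``u`` is replaced by ``u - <u, v̂⊥> v̂⊥``; the first
    principal direction of the residuals (sign-fixed) is returned as a unit
    vector orthogonal to ``v_perp``.
    """
    F = np.asarray(F, dtype=float)
    v_perp = np.asarray(v_perp, dtype=float)
    n = np.linalg.norm(v_perp)
    if n == 0:
        raise ValueError("v_perp has zero norm")
    v_hat = v_perp / n
    resid = F - np.outer(F @ v_hat, v_hat)
    resid = resid - resid.mean(axis=0)
    _, s, Vt = np.linalg.svd(resid, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise ValueError("feature residuals have rank 0")
    return fix_signs(Vt[:1])[0]


def sample_along_direction(
    v_perp: np.ndarray,
    F: np.ndarray,
    multipliers: np.ndarray = (-4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0),
) -> np.ndarray:
    """Feature-space points at fixed multiples of the ν⊥ projection s.d.

    ``σ`` is the standard deviation of the stimulus projections onto the unit
    direction ``v̂⊥``; returns ``m·σ·v̂⊥`` for each multiplier (rows).
    """
    v_perp = np.asarray(v_perp, dtype=float)
    n = np.linalg.norm(v_perp)
    if n == 0:
        raise ValueError("v_perp has zero norm")
    v_hat = v_perp / n
    sigma = float((np.asarray(F, dtype=float) @ v_hat).std())
    if sigma == 0:
        raise ValueError("stimulus projections along v_perp have zero s.d.")
    return np.outer(np.asarray(multipliers, dtype=float) * sigma, v_hat)
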