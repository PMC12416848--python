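"""Linear stability analysis: community (Jacobian) matrix and eigenspectrum.

The community matrix is the Jacobian ``J_ij = df_i/dx_j`` of the dynamics'
right-hand side ``f`` evaluated at an equilibrium. The equilibrium is
locally stable when every eigenvalue of ``J`` has negative real part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import InteractionMatrices, ModelParams, SpeciesTraits
from .dynamics import _percap_jacobian, growth_rhs

__all__ = [
    "jacobian_at",
    "finite_difference_jacobian",
    "eigenspectrum",
    "EigenSpectrum",
    "is_linearly_stable",
]


def jacobian_at(
    x_star: np.ndarray,
    net: InteractionMatrices,
    traits: SpeciesTraits,
    params: ModelParams,
) -> np.ndarray:
    """Analytic Jacobian of the dynamics at ``x_star``.

    ``J = diag(g) + diag(x) dg/dx`` with the per-capita rates ``g`` and
    their closed-form derivatives, including the saturating (Type II)
    terms. The constant interaction cost ``delta * n+`` enters only through
    ``g`` on the diagonal.
    """
    x_star = np.asarray(x_star, dtype=float)
    if x_star.shape != (net.S,):
        raise ValueError(f"abundance vector has shape {x_star.shape}, expected ({net.S},)")
    g, dg = _percap_jacobian(x_star, net, traits, params)
    J = x_star[:, None] * dg
    J[np.diag_indices_from(J)] += g
    return J


def finite_difference_jacobian(
    x_star: np.ndarray,
    net: InteractionMatrices,
    traits: SpeciesTraits,
    params: ModelParams,
) -> np.ndarray:
    """Central-finite-difference Jacobian (cross-check for :func:`jacobian_at`).

    The step in coordinate ``i`` scales with the abundance,
    ``max(1e-7, 1e-4 * x_i)``, so that species near the extinction
    threshold are differentiated at a resolvable scale.
    """
    x_star = np.asarray(x_star, dtype=float)
    S = len(x_star)
    J = np.empty((S, S))
    for j in range(S):
        h = max(1e-7, 1e-4 * x_star[j])
        xp, xm = x_star.copy(), x_star.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        J[:, j] = (growth_rhs(xp, net, traits, params) - growth_rhs(xm, net, traits, params)) / (
            xp[j] - xm[j]
        )
    return J


@dataclass
class EigenSpectrum:
    """Eigenvalues of a community matrix, with multiplicity."""

    values: np.ndarray
    community_size: int

    @property
    def max_real(self) -> float:
        return float(np.max(self.values.real))


def eigenspectrum(J: np.ndarray) -> EigenSpectrum:
    """All eigenvalues of the (real) community matrix ``J``.

    Complex eigenvalues come in conjugate pairs; their real parts govern
    stability, their imaginary parts the oscillatory character of the
    return to equilibrium.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("community matrix must be square")
    if not np.all(np.isfinite(J)):
        raise ValueError("community matrix contains non-finite entries")
    return EigenSpectrum(np.linalg.eigvals(J), J.shape[0])


def is_linearly_stable(spec: EigenSpectrum, tol: float = 1e-8) -> bool:
    """True when every eigenvalue's real part is below ``tol``.

    The small positive tolerance absorbs numerically-zero modes of
    marginally stable directions.
    """
    if len(spec.values) == 0:
        raise ValueError("empty spectrum")
    return spec.max_real < tol
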