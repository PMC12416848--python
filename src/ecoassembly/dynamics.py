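"""Generalized Lotka-Volterra dynamics with Type II functional responses.

The per-capita growth rate of species ``i`` is

    g_i = r_i - delta * n+_i - s_i x_i
          - sum_j c_ij x_j
          - sum_j pminus_ij x_j / (1 + h_p sum_k pplus_jk x_k)
          + sum_j pplus_ij x_j / (1 + h_p sum_k pplus_ik x_k)
          + sum_j m_ij x_j    / (1 + h_m sum_k m_ik x_k)

and ``dx_i/dt = x_i g_i``. ``n+_i`` counts the beneficial positive
interactions of ``i`` (its mutualistic partners plus the resources it
consumes); each one costs ``delta`` off the intrinsic growth rate.
Consumer and mutualist gains saturate with the focal species' own total
intake; the loss of a resource saturates with its *consumer's* total
intake, hence the differing denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .community import Community, InteractionMatrices, ModelParams, SpeciesTraits, remove_species

__all__ = [
    "positive_interaction_count",
    "positive_interaction_counts",
    "per_capita_growth",
    "growth_rhs",
    "integrate_to_equilibrium",
    "EquilibrationResult",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """ODE integrator failure; carries the abundance state at failure."""

    def __init__(self, message: str, x: np.ndarray):
        super().__init__(message)
        self.x = x


def positive_interaction_counts(net: InteractionMatrices) -> np.ndarray:
    """Number of beneficial positive interactions per species.

    Counts, for each species, its mutualistic partners plus the resources it
    consumes. Being consumed is not beneficial and does not count.
    """
    return (net.m > 0).sum(axis=1) + (net.pplus > 0).sum(axis=1)


def positive_interaction_count(i: int, net: InteractionMatrices) -> int:
    """Beneficial positive interactions of species ``i`` (costed at ``delta`` each)."""
    if not 0 <= i < net.S:
        raise IndexError(f"species index {i} out of range for S={net.S}")
    return int((net.m[i] > 0).sum() + (net.pplus[i] > 0).sum())


def _percap(
    x: np.ndarray,
    net: InteractionMatrices,
    traits: SpeciesTraits,
    params: ModelParams,
    npos: np.ndarray,
) -> np.ndarray:
    """Per-capita growth rates; no input validation (integrator hot path)."""
    gain_p_tot = net.pplus @ x
    denom_p = 1.0 + params.h_p * gain_p_tot
    gain_m_tot = net.m @ x
    denom_m = 1.0 + params.h_m * gain_m_tot
    return (
        traits.r
        - params.delta * npos
        - traits.s * x
        - net.c @ x
        - net.pminus @ (x / denom_p)
        + gain_p_tot / denom_p
        + gain_m_tot / denom_m
    )


def per_capita_growth(
    x: np.ndarray,
    net: InteractionMatrices,
    traits: SpeciesTraits,
    params: ModelParams,
) -> np.ndarray:
    """Per-capita growth rate ``g`` of every species (``dx/dt = x * g``)."""
    x = np.asarray(x, dtype=float)
    _check_inputs(x, net)
    return _percap(x, net, traits, params, positive_interaction_counts(net))


def _check_inputs(x: np.ndarray, net: InteractionMatrices) -> None:
    if x.shape != (net.S,):
        raise ValueError(f"abundance vector has shape {x.shape}, expected ({net.S},)")
    if np.any(x < 0):
        raise ValueError("negative abundance")
    for name, a in (("c", net.c), ("pplus", net.pplus), ("pminus", net.pminus), ("m", net.m)):
        if not np.all(np.isfinite(a)):
            raise ValueError(f"non-finite entries in matrix {name}")


def growth_rhs(
    x: np.ndarray,
    net: InteractionMatrices,
    traits: SpeciesTraits,
    params: ModelParams,
) -> np.ndarray:
    """Right-hand side ``dx/dt`` of the community dynamics.

    Extinction is absorbing: species at abundance zero have derivative
    exactly zero.
    """
    x = np.asarray(x, dtype=float)
    _check_inputs(x, net)
    return x * _percap(x, net, traits, params, positive_interaction_counts(net))


def _percap_jacobian(
    x: np.ndarray,
    net: InteractionMatrices,
    traits: SpeciesTraits,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(g, dg/dx)`` — per-capita rates and their Jacobian.

    Closed-form derivatives of the Type II terms:
      d/dx_j [A_i / (1 + h A_i)] = w_ij / (1 + h A_i)^2     (own-intake saturation)
      d/dx_j [sum_l pminus_il x_l / D_l]
          = pminus_ij / D_j - h_p sum_l pminus_il x_l pplus_lj / D_l^2
    where ``A_i`` is the focal species' weighted intake and ``D_l`` the
    consumer ``l``'s saturation denominator.
    """
    npos = positive_interaction_counts(net)
    gain_p_tot = net.pplus @ x
    denom_p = 1.0 + params.h_p * gain_p_tot
    gain_m_tot = net.m @ x
    denom_m = 1.0 + params.h_m * gain_m_tot
    g = (
        traits.r
        - params.delta * npos
        - traits.s * x
        - net.c @ x
        - net.pminus @ (x / denom_p)
        + gain_p_tot / denom_p
        + gain_m_tot / denom_m
    )
    dg = (
        -np.diag(traits.s)
        - net.c
        + net.pplus / denom_p[:, None] ** 2
        + net.m / denom_m[:, None] ** 2
        - net.pminus / denom_p[None, :]
        + params.h_p * (net.pminus * (x / denom_p**2)[None, :]) @ net.pplus
    )
    return g, dg


@dataclass
class EquilibrationResult:
    """Outcome of :func:`integrate_to_equilibrium`."""

    community: Community
    converged: bool
    extinct_ids: list[int]
    t_elapsed: float


def integrate_to_equilibrium(
    com: Community,
    params: ModelParams,
    max_windows: int | None = None,
    require_convergence: bool = True,
) -> EquilibrationResult:
    """Integrate the community forward until (approximate) equilibrium.

    The ODE is integrated in windows of ``params.t_check`` time units. After
    each window any species whose abundance fell below ``params.x_ext`` is
    removed (matrices and trait vectors shrink consistently) and integration
    continues. The community is considered equilibrated when the maximum
    relative abundance change across one window is below
    ``params.eq_rel_tol`` and no extinction occurred in that window.

    Parameters
    ----------
    max_windows : int, optional
        Stop after this many windows regardless of convergence (used by the
        fixed-interval assembly variant).
    require_convergence : bool
        When False, hitting ``max_windows`` is a normal return, not a
        non-convergence.

    Returns
    -------
    EquilibrationResult
        New community (input is not mutated), convergence flag, ids of
        species that went extinct, and elapsed model time. Hitting
        ``params.t_max`` without convergence returns ``converged=False``;
        the caller decides whether to proceed from the capped state.
    """
    com = com.copy()
    extinct: list[int] = []
    t = 0.0
    windows = 0
    converged = False
    batch = 4  # windows per solver call; grown adaptively, checks unchanged
    while True:
        if com.S == 0:
            converged = True
            break
        remaining = int(round((params.t_max - t) / params.t_check))
        if max_windows is not None:
            remaining = min(remaining, max_windows - windows)
        if remaining <= 0:
            if max_windows is not None and windows >= max_windows:
                converged = converged or not require_convergence
            break
        n_win = min(batch, remaining)
        npos = positive_interaction_counts(com.net)
        sol = solve_ivp(
            lambda _t, y: y * _percap(np.maximum(y, 0.0), com.net, com.traits, params, npos),
            (0.0, n_win * params.t_check),
            com.x,
            method="LSODA",
            jac=lambda _t, y: _rhs_jacobian(np.maximum(y, 0.0), com.net, com.traits, params),
            t_eval=params.t_check * np.arange(1, n_win + 1),
            rtol=1e-8,
            atol=1e-12,
        )
        if not sol.success:
            raise IntegrationError(f"ODE solver failed: {sol.message}", sol.y[:, -1])
        # walk the window boundaries; stop at the first extinction or
        # convergence so later (already-computed) windows are discarded
        event_hit = False
        prev = com.x
        for w in range(n_win):
            xw = np.maximum(sol.y[:, w], 0.0)
            t += params.t_check
            windows += 1
            dead = xw < params.x_ext
            if np.any(dead):
                extinct.extend(sid for sid, d in zip(com.species_ids, dead) if d)
                com.x = xw
                com = remove_species(com, [sid for sid, d in zip(com.species_ids, dead) if d])
                event_hit = True
                batch = 4
                break
            rel = np.abs(xw - prev) / np.maximum(prev, params.x_ext)
            com.x = xw
            if np.max(rel) < params.eq_rel_tol:
                converged = True
                event_hit = True
                break
            prev = xw
            if max_windows is not None and windows >= max_windows:
                converged = converged or not require_convergence
                event_hit = True
                break
        if converged or (max_windows is not None and windows >= max_windows):
            break
        if not event_hit:
            batch = min(batch * 2, 64)
        if t >= params.t_max:
            break
    return EquilibrationResult(com, converged, extinct, t)


def _rhs_jacobian(
    x: np.ndarray,
    net: InteractionMatrices,
    traits: SpeciesTraits,
    params: ModelParams,
) -> np.ndarray:
    g, dg = _percap_jacobian(x, net, traits, params)
    J = x[:, None] * dg
    J[np.diag_indices_from(J)] += g
    return J
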