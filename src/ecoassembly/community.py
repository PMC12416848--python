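"""Community containers: interaction matrices, species traits, model parameters.

A community couples three kinds of pairwise interactions — competition
(``-/-``), consumer-resource (``+/-``) and mutualism (``+/+``) — with
per-species intrinsic growth and intraspecific competition. Interaction
weights are stored in four dense non-negative matrices; each unordered
species pair carries at most one interaction type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "InteractionMatrices",
    "SpeciesTraits",
    "ModelParams",
    "Community",
    "InvariantError",
    "build_community",
    "remove_species",
]


class InvariantError(ValueError):
    """Raised when a community violates a structural invariant."""


@dataclass
class InteractionMatrices:
    """Signed, typed, weighted interaction structure of an ``S``-species community.

    Attributes
    ----------
    c : ndarray, shape (S, S)
        Competition strength of species ``j`` on species ``i`` (entry ``[i, j]``).
    pplus : ndarray, shape (S, S)
        Benefit to consumer ``i`` from resource ``j``.
    pminus : ndarray, shape (S, S)
        Loss to resource ``i`` from consumer ``j``.
    m : ndarray, shape (S, S)
        Mutualistic benefit to ``i`` from ``j``.

    All entries are non-negative, diagonals are zero (intraspecific effects
    live in :class:`SpeciesTraits`), and each unordered pair carries at most
    one interaction type.
    """

    c: np.ndarray
    pplus: np.ndarray
    pminus: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.pplus = np.asarray(self.pplus, dtype=float)
        self.pminus = np.asarray(self.pminus, dtype=float)
        self.m = np.asarray(self.m, dtype=float)

    @property
    def S(self) -> int:
        return self.c.shape[0]

    def copy(self) -> "InteractionMatrices":
        return InteractionMatrices(
            self.c.copy(), self.pplus.copy(), self.pminus.copy(), self.m.copy()
        )

    @classmethod
    def zeros(cls, S: int) -> "InteractionMatrices":
        return cls(*(np.zeros((S, S)) for _ in range(4)))

    def validate(self) -> None:
        """Check every structural invariant; raise :class:`InvariantError` on breach."""
        mats = {"c": self.c, "pplus": self.pplus, "pminus": self.pminus, "m": self.m}
        S = self.S
        for name, a in mats.items():
            if a.shape != (S, S):
                raise InvariantError(f"matrix {name} has shape {a.shape}, expected {(S, S)}")
            if not np.all(np.isfinite(a)):
                raise InvariantError(f"matrix {name} contains non-finite entries")
            if np.any(a < 0):
                raise InvariantError(f"matrix {name} contains negative entries")
            if np.any(np.diag(a) != 0):
                raise InvariantError(f"matrix {name} has a nonzero diagonal entry")
        # consumer-resource pairing: i consumes j  <=>  j loses to i
        if not np.array_equal(self.pplus > 0, (self.pminus > 0).T):
            mismatch = (self.pplus > 0) != (self.pminus > 0).T
            i, j = np.argwhere(mismatch)[0]
            raise InvariantError(
                f"consumer-resource pairing broken for pair ({i}, {j}): "
                f"pplus[{i},{j}]={self.pplus[i, j]}, pminus[{j},{i}]={self.pminus[j, i]}"
            )
        if np.any(self.pplus > self.pminus.T):
            i, j = np.argwhere(self.pplus > self.pminus.T)[0]
            raise InvariantError(
                f"consumer bound violated for pair ({i}, {j}): conversion efficiency "
                f"pplus[{i},{j}]={self.pplus[i, j]} > pminus[{j},{i}]={self.pminus[j, i]}"
            )
        for name in ("m", "c"):
            a = mats[name]
            if not np.array_equal(a > 0, (a > 0).T):
                i, j = np.argwhere((a > 0) != (a > 0).T)[0]
                raise InvariantError(f"support of {name} is not symmetric at pair ({i}, {j})")
        # exclusivity: at most one interaction type per unordered pair
        comp = self.c > 0
        mut = self.m > 0
        cons = (self.pplus > 0) | (self.pminus > 0)
        cons = cons | cons.T
        overlap = (comp & mut) | (comp & cons) | (mut & cons)
        if np.any(overlap):
            i, j = np.argwhere(overlap)[0]
            raise InvariantError(f"pair ({i}, {j}) carries more than one interaction type")

    def degree(self) -> np.ndarray:
        """Number of interacting partners of each species (any type)."""
        linked = (self.c > 0) | (self.m > 0) | (self.pplus > 0) | (self.pminus > 0)
        return (linked | linked.T).sum(axis=1)


@dataclass
class SpeciesTraits:
    """Per-species intrinsic growth rate ``r`` (1/time) and intraspecific
    competition strength ``s`` (1/(abundance*time))."""

    r: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))

    def copy(self) -> "SpeciesTraits":
        return SpeciesTraits(self.r.copy(), self.s.copy())

    def validate(self) -> None:
        if self.r.shape != self.s.shape:
            raise InvariantError("r and s have different lengths")
        if not np.all(np.isfinite(self.r)):
            raise InvariantError("non-finite intrinsic growth rate")
        if not np.all(self.s > 0):
            raise InvariantError("intraspecific competition strength must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Global dynamical parameters.

    Parameters
    ----------
    delta : float
        Growth-rate cost per beneficial positive interaction (1/time). Each
        mutualistic partner and each resource a species consumes contributes
        one unit of cost.
    h_m, h_p : float
        Type II saturation (handling) times for mutualistic and
        consumer-resource intake.
    x_ext : float
        Extinction threshold: a species whose abundance falls below it is
        removed; new species are introduced at exactly this abundance.
    eq_rel_tol : float
        Equilibrium criterion — maximum relative abundance change across one
        check window (0.01% by default).
    t_check : float
        Integration window (time units) between equilibrium/extinction checks.
    t_max : float
        Cap on total integration time per equilibration.
    """

    delta: float = 0.01
    h_m: float = 0.1
    h_p: float = 0.1
    x_ext: float = 1e-6
    eq_rel_tol: float = 1e-4
    t_check: float = 10.0
    t_max: float = 1e5

    def __post_init__(self) -> None:
        if self.delta < 0 or self.h_m < 0 or self.h_p < 0:
            raise ValueError("delta, h_m, h_p must be non-negative")
        if not 0 < self.x_ext < 1:
            raise ValueError("x_ext must lie in (0, 1)")
        if self.eq_rel_tol <= 0 or self.t_check <= 0 or self.t_max < self.t_check:
            raise ValueError("invalid equilibration controls")


@dataclass
class Community:
    """Full state of a community at one point of the assembly process.

    Bundles abundances, stable lineage identifiers, the speciation genealogy,
    the interaction matrices and the trait vectors. Index ``i`` of every
    array refers to the same species.
    """

    net: InteractionMatrices
    traits: SpeciesTraits
    x: np.ndarray
    species_ids: list[int]
    parent_of: dict[int, Optional[int]] = field(default_factory=dict)
    event_index: int = 0

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.species_ids = list(self.species_ids)

    @property
    def S(self) -> int:
        return len(self.species_ids)

    def copy(self) -> "Community":
        return Community(
            self.net.copy(),
            self.traits.copy(),
            self.x.copy(),
            list(self.species_ids),
            dict(self.parent_of),
            self.event_index,
        )

    def index_of(self, species_id: int) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise KeyError(f"unknown species id {species_id}") from None

    def validate(self) -> None:
        self.net.validate()
        self.traits.validate()
        if len(self.x) != self.S or self.net.S != self.S or len(self.traits.r) != self.S:
            raise InvariantError("inconsistent community dimensions")
        if len(set(self.species_ids)) != self.S:
            raise InvariantError("duplicate species ids")
        if np.any(self.x < 0):
            raise InvariantError("negative abundance")


def remove_species(com: Community, ids: Iterable[int]) -> Community:
    """Return a copy of ``com`` with the given species removed.

    All four interaction matrices lose the corresponding rows and columns;
    abundance and trait vectors shrink consistently. Used both for
    extinctions and for purging species decoupled from the network.
    """
    ids = list(ids)
    for sid in ids:
        if sid not in com.species_ids:
            raise KeyError(f"unknown species id {sid}")
    keep = np.array([sid not in ids for sid in com.species_ids], dtype=bool)
    net = InteractionMatrices(
        com.net.c[np.ix_(keep, keep)],
        com.net.pplus[np.ix_(keep, keep)],
        com.net.pminus[np.ix_(keep, keep)],
        com.net.m[np.ix_(keep, keep)],
    )
    traits = SpeciesTraits(com.traits.r[keep], com.traits.s[keep])
    survivors = [sid for sid in com.species_ids if sid not in ids]
    return Community(
        net, traits, com.x[keep], survivors, dict(com.parent_of), com.event_index
    )


_TYPE_ALIASES = {
    "competition": "competition",
    "comp": "competition",
    "mutualism": "mutualism",
    "mut": "mutualism",
    "consumer_resource": "consumer_resource",
    "cons": "consumer_resource",
}


def build_community(
    species: Sequence[dict],
    links: Sequence[dict] = (),
    validate: bool = True,
) -> Community:
    """Construct a community from an explicit description (test fixtures, IO).

    Parameters
    ----------
    species : sequence of dict
        Each with keys ``id``, ``r``, ``s``, ``x`` (and optionally ``parent``).
    links : sequence of dict
        Each with keys ``source``, ``target``, ``type`` and weights
        ``w_st`` / ``w_ts``. For ``consumer_resource`` the source is the
        consumer: ``w_st`` is the consumer's gain (``pplus``), ``w_ts`` the
        resource's loss (``pminus``).

    Raises
    ------
    InvariantError
        If the description breaches a structural invariant (with the
        violated invariant named in the message).
    """
    ids = [sp["id"] for sp in species]
    idx = {sid: k for k, sid in enumerate(ids)}
    S = len(ids)
    net = InteractionMatrices.zeros(S)
    traits = SpeciesTraits(
        np.array([sp["r"] for sp in species], dtype=float),
        np.array([sp["s"] for sp in species], dtype=float),
    )
    x = np.array([sp["x"] for sp in species], dtype=float)
    parent_of = {sp["id"]: sp.get("parent") for sp in species}
    for lk in links:
        i, j = idx[lk["source"]], idx[lk["target"]]
        kind = _TYPE_ALIASES[lk["type"]]
        w_st, w_ts = float(lk["w_st"]), float(lk.get("w_ts", lk["w_st"]))
        if kind == "competition":
            net.c[i, j] = w_st
            net.c[j, i] = w_ts
        elif kind == "mutualism":
            net.m[i, j] = w_st
            net.m[j, i] = w_ts
        else:  # source consumes target
            net.pplus[i, j] = w_st
            net.pminus[j, i] = w_ts
    com = Community(net, traits, x, ids, parent_of)
    if validate:
        com.validate()
    return com
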