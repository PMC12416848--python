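"""Assembly of communities by speciation (interaction inheritance) and invasion.

An *assembly event* is one successful species addition. The resident
community sits at equilibrium; a candidate species is proposed — an
offspring inheriting its parent's interactions with up to ``delta_mut``
link differences and small weight noise, or an invader with randomly drawn
links — and is accepted iff its instantaneous per-capita growth rate at
the extinction-threshold abundance is positive. Accepted species enter at
exactly that abundance and the community is re-equilibrated, with possible
extinctions. Rejected candidates are redrawn until one establishes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .community import (
    Community,
    InteractionMatrices,
    ModelParams,
    SpeciesTraits,
    remove_species,
)
from .dynamics import (
    _percap,
    integrate_to_equilibrium,
    positive_interaction_counts,
)
from .metrics import type_proportions, undirected_pair_graph, connectance

__all__ = [
    "AssemblyConfig",
    "CandidateSpecies",
    "Link",
    "AssemblyError",
    "SkipEvent",
    "draw_interaction_strength",
    "enforce_consumer_bound",
    "draw_traits",
    "propose_offspring",
    "propose_invader",
    "can_establish",
    "assembly_event",
    "run_assembly",
    "initial_community",
]

log = logging.getLogger(__name__)

LinkType = Literal["competition", "mutualism", "consumer", "resource"]

# weight noise on inherited links: sd as a fraction of the parental weight
INHERITANCE_NOISE_CV = 0.05


class AssemblyError(RuntimeError):
    """No candidate established within the proposal budget."""

    def __init__(self, event_index: int, n_proposals: int):
        super().__init__(
            f"no candidate established at assembly event {event_index} "
            f"after {n_proposals} proposals"
        )
        self.event_index = event_index


class SkipEvent(Exception):
    """Raised when a proposal is structurally infeasible (e.g. a lone,
    linkless parent that cannot differ by any link)."""


@dataclass(frozen=True)
class AssemblyConfig:
    """Full specification of one assembly scenario.

    Defaults are the main-run settings: half-normal interaction strengths
    with scale ``sigma=0.2``, cost ``delta=0.01`` per positive interaction,
    mutation budget ``delta_mut=5``, invader connectance drawn from
    ``[0.05, 0.5]``, 5 linkless founders with abundances uniform on
    ``[0, 0.02]``, extinction threshold ``1e-6``, and disconnected-species
    purging from event 20 onward.
    """

    scenario: Literal["evolution", "invasion", "mixed"] = "evolution"
    p_invasion: float = 0.0
    delta_mut: int = 5
    rho1: float = 0.05
    rho2: float = 0.5
    sigma: float = 0.2
    mu_r: float = 0.1
    s_lognorm_mu: float = 0.1
    s_lognorm_sd: float = 0.5
    mutualism_mode: Literal["free", "none", "high", "switch_on", "switch_off"] = "free"
    mutualism_switch_at: Optional[int] = None
    high_m_lo: float = 0.8
    high_m_hi: float = 1.0
    n_events: int = 1000
    n_init: int = 5
    init_abund_hi: float = 0.02
    parent_weighting: Literal["uniform", "abundance"] = "uniform"
    event_timing: Literal["at_equilibrium", "fixed_interval"] = "at_equilibrium"
    fixed_interval_windows: int = 10
    disconnect_removal_after: int = 20
    seed: Optional[int] = None
    max_proposals: int = 10_000
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_invasion <= 1.0:
            raise ValueError("p_invasion must lie in [0, 1]")
        if self.delta_mut < 1:
            raise ValueError("delta_mut must be a positive integer")
        if not 0 < self.rho1 <= self.rho2 <= 1:
            raise ValueError("need 0 < rho1 <= rho2 <= 1")
        if self.n_events < 0 or self.max_proposals < 1:
            raise ValueError("invalid event/proposal counts")
        if self.mutualism_mode in ("switch_on", "switch_off") and self.mutualism_switch_at is None:
            raise ValueError("switch modes require mutualism_switch_at")

    def mut_mode_at(self, event_index: int) -> str:
        """Effective mutualism mode for the event with 1-based index ``event_index``.

        ``switch_on``: no mutualistic links are offered until the switch
        event, free afterwards; ``switch_off`` is the reverse. The change
        applies to events *after* the switch index.
        """
        if self.mutualism_mode == "switch_on":
            return "none" if event_index <= self.mutualism_switch_at else "free"
        if self.mutualism_mode == "switch_off":
            return "free" if event_index <= self.mutualism_switch_at else "none"
        return self.mutualism_mode


@dataclass
class Link:
    """A typed candidate link to a resident species.

    ``type`` is one of competition / mutualism / consumer (candidate gains
    from the partner) / resource (candidate is consumed by the partner).
    ``w_out`` is the weight on the candidate's row (its own gain or loss),
    ``w_in`` the weight on the partner's row.
    """

    partner_id: int
    type: LinkType
    w_out: float
    w_in: float


@dataclass
class CandidateSpecies:
    """A proposed species: fresh traits, a set of typed links, and its origin."""

    r: float
    s: float
    links: list[Link]
    origin: Literal["speciation", "invasion"]
    parent_id: Optional[int] = None


def draw_interaction_strength(sigma: float, rng: np.random.Generator) -> float:
    """Half-normal interaction strength ``|N(0, sigma^2)|``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return abs(rng.normal(0.0, sigma))


def enforce_consumer_bound(pplus_ij: float, pminus_ji: float) -> float:
    """Cap the consumer's gain at the resource's loss (conversion efficiency <= 1)."""
    return min(pplus_ij, pminus_ji)


def draw_traits(
    mu_r: float,
    s_mu: float,
    s_sd: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw intrinsic growth and intraspecific competition for a new species.

    ``r ~ N(mu_r, (0.1 mu_r)^2)``; ``s`` is the inverse of a lognormal draw
    whose underlying normal has mean ``s_mu`` and sd ``s_sd``. Traits are
    never inherited.
    """
    if mu_r <= 0:
        raise ValueError("mu_r must be positive")
    r = rng.normal(mu_r, 0.1 * mu_r)
    s = 1.0 / rng.lognormal(s_mu, s_sd)
    return float(r), float(s)


def _parent_links(com: Community, parent_idx: int) -> list[Link]:
    """Extract the parent's links as candidate links (weights copied verbatim)."""
    links: list[Link] = []
    for j in range(com.S):
        if j == parent_idx:
            continue
        pid = com.species_ids[j]
        if com.net.c[parent_idx, j] > 0:
            links.append(Link(pid, "competition", com.net.c[parent_idx, j], com.net.c[j, parent_idx]))
        elif com.net.m[parent_idx, j] > 0:
            links.append(Link(pid, "mutualism", com.net.m[parent_idx, j], com.net.m[j, parent_idx]))
        elif com.net.pplus[parent_idx, j] > 0:
            links.append(Link(pid, "consumer", com.net.pplus[parent_idx, j], com.net.pminus[j, parent_idx]))
        elif com.net.pminus[parent_idx, j] > 0:
            links.append(Link(pid, "resource", com.net.pminus[parent_idx, j], com.net.pplus[j, parent_idx]))
    return links


def _allowed_types(mutualism_allowed: bool) -> list[LinkType]:
    types: list[LinkType] = ["competition", "consumer", "resource"]
    if mutualism_allowed:
        types.insert(1, "mutualism")
    return types


def _new_link(partner_id: int, kind: LinkType, sigma: float, rng: np.random.Generator) -> Link:
    w_out = draw_interaction_strength(sigma, rng)
    w_in = draw_interaction_strength(sigma, rng)
    if kind == "consumer":
        w_out = enforce_consumer_bound(w_out, w_in)
    elif kind == "resource":
        w_in = enforce_consumer_bound(w_in, w_out)
    return Link(partner_id, kind, w_out, w_in)


def propose_offspring(
    com: Community,
    parent_id: int,
    delta_mut: int,
    sigma: float,
    mutualism_allowed: bool,
    rng: np.random.Generator,
    mu_r: float = 0.1,
    s_mu: float = 0.1,
    s_sd: float = 0.5,
) -> CandidateSpecies:
    """Speciation: an offspring inheriting the parent's links with variation.

    The number of link differences ``d`` is uniform on ``{1..delta_mut}``;
    a split ``(n_remove, n_create)`` with ``n_remove + n_create = d`` is
    chosen uniformly among feasible splits. Removed links are chosen
    uniformly without replacement; created links go to uniformly chosen
    unoccupied partners with a uniformly chosen allowed type. Every
    inherited weight ``w`` is perturbed to ``w + N(0, (0.05 w)^2)``,
    clamped at zero, with the consumer bound re-enforced. Traits are drawn
    fresh.

    Raises
    ------
    SkipEvent
        If no link difference is realizable (lone parent with no links).
    """
    pi = com.index_of(parent_id)
    inherited = _parent_links(com, pi)
    occupied = {lk.partner_id for lk in inherited}
    # the parent itself is a legal new partner for its offspring
    free_partners = [sid for sid in com.species_ids if sid not in occupied]
    L, U = len(inherited), len(free_partners)
    if L + U == 0:
        raise SkipEvent("offspring cannot differ from a lone, linkless parent")
    d = int(rng.integers(1, delta_mut + 1))
    d = min(d, L + U)  # cannot differ by more links than exist or can be placed
    lo, hi = max(0, d - U), min(d, L)
    n_remove = int(rng.integers(lo, hi + 1))
    n_create = d - n_remove

    keep_idx = rng.choice(L, size=L - n_remove, replace=False) if n_remove else np.arange(L)
    kept = [inherited[k] for k in sorted(keep_idx)]
    # inherited weights mutate by a small multiplicative-scale noise
    links: list[Link] = []
    for lk in kept:
        w_out = max(0.0, lk.w_out + rng.normal(0.0, INHERITANCE_NOISE_CV * lk.w_out))
        w_in = max(0.0, lk.w_in + rng.normal(0.0, INHERITANCE_NOISE_CV * lk.w_in))
        if lk.type == "consumer":
            w_out = enforce_consumer_bound(w_out, w_in)
        elif lk.type == "resource":
            w_in = enforce_consumer_bound(w_in, w_out)
        links.append(Link(lk.partner_id, lk.type, w_out, w_in))
    if n_create:
        targets = rng.choice(U, size=n_create, replace=False)
        types = _allowed_types(mutualism_allowed)
        for t in targets:
            kind = types[rng.integers(len(types))]
            links.append(_new_link(free_partners[t], kind, sigma, rng))
    r, s = draw_traits(mu_r, s_mu, s_sd, rng)
    return CandidateSpecies(r, s, links, "speciation", parent_id)


def _type_menu(mode: str, rng: np.random.Generator, high_lo: float, high_hi: float) -> np.ndarray:
    """Interaction-type proportions (competition, consumer-resource, mutualism)."""
    if mode == "none":
        q_c = rng.uniform()
        return np.array([q_c, 1.0 - q_c, 0.0])
    if mode == "high":
        q_m = rng.uniform(high_lo, high_hi)
        rest = (1.0 - q_m) / 2.0
        return np.array([rest, rest, q_m])
    return rng.dirichlet(np.ones(3))  # uniform on the 2-simplex


def propose_invader(
    com: Community,
    rho1: float,
    rho2: float,
    mutualism_mode: str,
    sigma: float,
    rng: np.random.Generator,
    mu_r: float = 0.1,
    s_mu: float = 0.1,
    s_sd: float = 0.5,
    high_lo: float = 0.8,
    high_hi: float = 1.0,
) -> CandidateSpecies:
    """Invasion: a species with randomly drawn links.

    A connectance ``rho ~ U(rho1, rho2)`` is drawn for the invader and each
    resident becomes a partner independently with probability ``rho``. The
    invader's interaction-type proportions are drawn according to
    ``mutualism_mode`` (free: uniform on the simplex; none: zero mutualism;
    high: mutualism share uniform on ``[high_lo, high_hi]``, the rest split
    equally); each link's type is then a draw from those proportions, with
    the consumer/resource role uniform. Weights are half-normal with the
    consumer bound enforced. Zero-link invaders are legal.
    """
    rho = rng.uniform(rho1, rho2)
    partners = [sid for sid in com.species_ids if rng.uniform() < rho]
    q = _type_menu(mutualism_mode, rng, high_lo, high_hi)
    links: list[Link] = []
    for pid in partners:
        kind_ix = rng.choice(3, p=q)
        if kind_ix == 0:
            kind: LinkType = "competition"
        elif kind_ix == 2:
            kind = "mutualism"
        else:
            kind = "consumer" if rng.uniform() < 0.5 else "resource"
        links.append(_new_link(pid, kind, sigma, rng))
    r, s = draw_traits(mu_r, s_mu, s_sd, rng)
    return CandidateSpecies(r, s, links, "invasion")


def _augment(com: Community, cand: CandidateSpecies, new_id: int) -> Community:
    """Community with the candidate appended (at index S) at zero abundance."""
    S = com.S
    net = InteractionMatrices.zeros(S + 1)
    for mat, src in (
        (net.c, com.net.c),
        (net.pplus, com.net.pplus),
        (net.pminus, com.net.pminus),
        (net.m, com.net.m),
    ):
        mat[:S, :S] = src
    for lk in cand.links:
        j = com.index_of(lk.partner_id)
        if lk.type == "competition":
            net.c[S, j], net.c[j, S] = lk.w_out, lk.w_in
        elif lk.type == "mutualism":
            net.m[S, j], net.m[j, S] = lk.w_out, lk.w_in
        elif lk.type == "consumer":
            net.pplus[S, j], net.pminus[j, S] = lk.w_out, lk.w_in
        else:  # candidate is the resource
            net.pminus[S, j], net.pplus[j, S] = lk.w_out, lk.w_in
    traits = SpeciesTraits(np.append(com.traits.r, cand.r), np.append(com.traits.s, cand.s))
    parent_of = dict(com.parent_of)
    parent_of[new_id] = cand.parent_id
    return Community(
        net,
        traits,
        np.append(com.x, 0.0),
        com.species_ids + [new_id],
        parent_of,
        com.event_index,
    )


def can_establish(
    cand: CandidateSpecies,
    com: Community,
    params: ModelParams,
) -> tuple[bool, float]:
    """Establishment test: positive per-capita growth at the threshold abundance.

    The resident community (assumed at equilibrium) is temporarily
    augmented with the candidate at abundance ``x_ext``; the candidate
    establishes iff its instantaneous per-capita growth rate — including
    its interaction costs and self-limitation at ``x_ext`` — is strictly
    positive. Returns the flag and the rate.
    """
    aug = _augment(com, cand, new_id=-1)
    aug.x[-1] = params.x_ext
    g = _percap(aug.x, aug.net, aug.traits, params, positive_interaction_counts(aug.net))
    rate = float(g[-1])
    return rate > 0.0, rate


@dataclass
class EventRecord:
    """Per-assembly-event summary row."""

    event: int
    origin: str
    parent_id: Optional[int]
    n_rejected: int
    n_extinct: int
    S: int
    C: float
    SC: float
    prop_comp: float
    prop_cons: float
    prop_mut: float
    mean_abundance: float
    converged: bool
    accepted_growth_rate: float
    n_link_diff: float  # speciation: |offspring links XOR parent links|; invasion: NaN


def _choose_origin(config: AssemblyConfig, rng: np.random.Generator) -> str:
    """One origin draw per assembly event (shared by all retries of the event)."""
    if config.scenario == "evolution":
        return "speciation"
    if config.scenario == "invasion":
        return "invasion"
    return "invasion" if rng.uniform() < config.p_invasion else "speciation"


def _choose_parent(com: Community, config: AssemblyConfig, rng: np.random.Generator) -> int:
    if config.parent_weighting == "abundance":
        w = com.x / com.x.sum()
        return com.species_ids[rng.choice(com.S, p=w)]
    return com.species_ids[rng.integers(com.S)]


def assembly_event(
    com: Community,
    config: AssemblyConfig,
    rng: np.random.Generator,
    next_id: int,
) -> tuple[Community, EventRecord]:
    """Run one assembly event to completion.

    Candidates are proposed (origin fixed by one scenario draw) until one
    establishes or ``config.max_proposals`` is exhausted. The accepted
    species enters at ``x_ext``, the community is integrated to the next
    equilibrium, and — once ``event_index`` has reached
    ``disconnect_removal_after`` — species left without any interaction are
    purged. ``event_index`` increments only on acceptance.
    """
    event_no = com.event_index + 1
    mut_mode = config.mut_mode_at(event_no)
    origin = _choose_origin(config, rng)
    n_rejected = 0
    cand: Optional[CandidateSpecies] = None
    rate = math.nan
    for _ in range(config.max_proposals):
        try:
            if origin == "speciation":
                parent = _choose_parent(com, config, rng)
                proposal = propose_offspring(
                    com,
                    parent,
                    config.delta_mut,
                    config.sigma,
                    mutualism_allowed=(mut_mode != "none"),
                    rng=rng,
                    mu_r=config.mu_r,
                    s_mu=config.s_lognorm_mu,
                    s_sd=config.s_lognorm_sd,
                )
            else:
                proposal = propose_invader(
                    com,
                    config.rho1,
                    config.rho2,
                    mut_mode,
                    config.sigma,
                    rng,
                    mu_r=config.mu_r,
                    s_mu=config.s_lognorm_mu,
                    s_sd=config.s_lognorm_sd,
                    high_lo=config.high_m_lo,
                    high_hi=config.high_m_hi,
                )
        except SkipEvent:
            n_rejected += 1
            continue
        ok, rate = can_establish(proposal, com, config.params)
        if ok:
            cand = proposal
            break
        n_rejected += 1
    if cand is None:
        raise AssemblyError(event_no, config.max_proposals)

    if cand.origin == "speciation":
        parent_partners = {lk.partner_id for lk in _parent_links(com, com.index_of(cand.parent_id))}
        n_link_diff = float(len({lk.partner_id for lk in cand.links} ^ parent_partners))
    else:
        n_link_diff = math.nan
    com = _augment(com, cand, next_id)
    com.x[-1] = config.params.x_ext
    if config.event_timing == "fixed_interval":
        res = integrate_to_equilibrium(
            com,
            config.params,
            max_windows=config.fixed_interval_windows,
            require_convergence=False,
        )
    else:
        res = integrate_to_equilibrium(com, config.params)
        if not res.converged:
            log.warning("event %d: equilibration hit t_max; proceeding from capped state", event_no)
    com = res.community
    com.event_index = event_no
    if com.event_index >= config.disconnect_removal_after and com.S:
        lonely = [sid for sid, deg in zip(com.species_ids, com.net.degree()) if deg == 0]
        if lonely:
            com = remove_species(com, lonely)
    G = undirected_pair_graph(com.net)
    C = connectance(G)
    pc, pp, pm = type_proportions(com.net)
    rec = EventRecord(
        event=event_no,
        origin=origin,
        parent_id=cand.parent_id,
        n_rejected=n_rejected,
        n_extinct=len(res.extinct_ids),
        S=com.S,
        C=C,
        SC=com.S * C,
        prop_comp=pc,
        prop_cons=pp,
        prop_mut=pm,
        mean_abundance=float(com.x.sum() / com.S) if com.S else 0.0,
        converged=res.converged,
        accepted_growth_rate=rate,
        n_link_diff=n_link_diff,
    )
    log.debug(
        "event %d: %s, rejected=%d, extinct=%d, S=%d, C=%.3f",
        event_no, origin, n_rejected, rec.n_extinct, rec.S, rec.C,
    )
    return com, rec


def initial_community(config: AssemblyConfig, rng: np.random.Generator) -> Community:
    """Founder community: ``n_init`` non-interacting species with uniform abundances."""
    n = config.n_init
    r = np.empty(n)
    s = np.empty(n)
    for i in range(n):
        r[i], s[i] = draw_traits(config.mu_r, config.s_lognorm_mu, config.s_lognorm_sd, rng)
    x = rng.uniform(0.0, config.init_abund_hi, size=n)
    return Community(
        InteractionMatrices.zeros(n),
        SpeciesTraits(r, s),
        x,
        list(range(n)),
        {i: None for i in range(n)},
    )


def run_assembly(config: AssemblyConfig) -> tuple[Community, pd.DataFrame]:
    """Run a full assembly scenario from founders to ``config.n_events`` events.

    Fully reproducible from ``config.seed``: one generator drives every
    draw. Returns the final community and the per-event trajectory table.
    """
    rng = np.random.default_rng(config.seed)
    com = initial_community(config, rng)
    res = integrate_to_equilibrium(com, config.params)
    com = res.community
    next_id = config.n_init
    records: list[EventRecord] = []
    for _ in range(config.n_events):
        com, rec = assembly_event(com, config, rng, next_id)
        next_id += 1
        records.append(rec)
    traj = pd.DataFrame([vars(r) for r in records])
    return com, traj
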