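"""Scenario presets, replicated runs, and trajectory aggregation.

The preset families mirror the study designs the simulator is built for:
pure evolutionary assembly (``Evo``), pure invasion (``Inv``), their
no-mutualism controls, invasion with enforced high mutualism, mid-run
switching of mutualism availability, mixed evolution/invasion schedules,
abundance-weighted parent choice, and fixed-interval ("fast") assembly
that does not wait for ecological equilibrium.

Full-scale runs are 15 replicates of 1000 assembly events with metrics
aggregated every 50 events (mean and standard error across replicates).
Reduced-scale runs (fewer replicates/events) use the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .assembly import AssemblyConfig, run_assembly
from .community import Community, build_community

__all__ = [
    "ScenarioPreset",
    "PRESETS",
    "ScenarioResult",
    "replicate_seeds",
    "run_scenario",
    "aggregate_trajectories",
    "final_state_scatter",
    "make_fixture_community",
]

#: metrics aggregated across replicates at every stride
AGGREGATED_METRICS = [
    "S", "C", "SC", "prop_comp", "prop_cons", "prop_mut", "mean_abundance",
]


@dataclass(frozen=True)
class ScenarioPreset:
    """A named scenario family with its default configuration."""

    name: str
    config: AssemblyConfig
    n_replicates: int = 15
    record_every: int = 50


def _preset(name: str, n_events: int = 1000, **kw) -> ScenarioPreset:
    switch = kw.pop("switch_halfway", False)
    if switch:
        kw["mutualism_switch_at"] = n_events // 2
    return ScenarioPreset(name, AssemblyConfig(n_events=n_events, **kw))


PRESETS: dict[str, ScenarioPreset] = {
    p.name: p
    for p in [
        _preset("Evo", scenario="evolution"),
        _preset("Inv", scenario="invasion"),
        _preset("Evo-No-M", scenario="evolution", mutualism_mode="none"),
        _preset("Inv-No-M", scenario="invasion", mutualism_mode="none"),
        _preset("Inv-High-M", scenario="invasion", mutualism_mode="high"),
        _preset("Inv-switch-on", scenario="invasion", mutualism_mode="switch_on",
                switch_halfway=True),
        _preset("Inv-switch-off", scenario="invasion", mutualism_mode="switch_off",
                switch_halfway=True),
        _preset("Mixed-0.2", scenario="mixed", p_invasion=0.2),
        _preset("Mixed-0.5", scenario="mixed", p_invasion=0.5),
        _preset("Mixed-0.8", scenario="mixed", p_invasion=0.8),
        _preset("Evo-abundance-weighted", scenario="evolution", parent_weighting="abundance"),
        _preset("fast-assembly", scenario="evolution", event_timing="fixed_interval"),
    ]
}


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Per-replicate child seeds derived from one master seed.

    Fixed rule: the first ``n`` words of ``SeedSequence(master_seed)``'s
    generated state, folded into the 31-bit range.
    """
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(w % (2**31)) for w in state]


@dataclass
class ScenarioResult:
    """Replicated-run output: raw trajectories, aggregate, final communities."""

    preset: ScenarioPreset
    seeds: list[int]
    trajectories: list[pd.DataFrame]
    finals: list[Community]
    aggregate: pd.DataFrame
    failures: list[tuple[int, str]] = field(default_factory=list)


def aggregate_trajectories(
    trajectories: Sequence[pd.DataFrame],
    record_every: int = 50,
) -> pd.DataFrame:
    """Across-replicate mean and standard error at every ``record_every`` events.

    The standard error is the across-replicate standard deviation divided
    by the square root of the number of replicates.
    """
    n_events = min(len(t) for t in trajectories)
    strides = list(range(record_every, n_events + 1, record_every))
    n = len(trajectories)
    rows = []
    for ev in strides:
        row: dict = {"event": ev}
        for metric in AGGREGATED_METRICS:
            vals = np.array([t.loc[t["event"] == ev, metric].iloc[0] for t in trajectories])
            row[f"{metric}_mean"] = vals.mean()
            row[f"{metric}_se"] = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def run_scenario(
    preset: ScenarioPreset | str,
    n_replicates: Optional[int] = None,
    n_events: Optional[int] = None,
    master_seed: int = 0,
    progress: Optional[Callable[[int, int], None]] = None,
) -> ScenarioResult:
    """Run a scenario across replicates and aggregate its trajectories.

    ``n_replicates`` / ``n_events`` override the preset (reduced-scale
    runs). A replicate that errors is recorded in ``failures`` and skipped
    in the aggregation, with a warning.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    n_rep = n_replicates if n_replicates is not None else preset.n_replicates
    config = preset.config
    if n_events is not None:
        kw = {"n_events": n_events}
        if config.mutualism_switch_at is not None:
            kw["mutualism_switch_at"] = n_events // 2
        config = replace(config, **kw)
    seeds = replicate_seeds(master_seed, n_rep)
    trajectories: list[pd.DataFrame] = []
    finals: list[Community] = []
    failures: list[tuple[int, str]] = []
    for k, seed in enumerate(seeds):
        try:
            com, traj = run_assembly(replace(config, seed=seed))
        except Exception as exc:  # noqa: BLE001 — replicate failures are data
            import logging

            logging.getLogger(__name__).warning("replicate seed %d failed: %s", seed, exc)
            failures.append((seed, str(exc)))
            continue
        traj = traj.copy()
        traj.insert(0, "replicate", k)
        traj.insert(0, "scenario", preset.name)
        trajectories.append(traj)
        finals.append(com)
        if progress is not None:
            progress(k + 1, n_rep)
    stride = min(preset.record_every, config.n_events)
    agg = aggregate_trajectories(trajectories, record_every=stride) if trajectories else pd.DataFrame()
    return ScenarioResult(preset, seeds, trajectories, finals, agg, failures)


def final_state_scatter(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """One row per replicate: scenario, replicate, final richness and connectance.

    Supports the outcome-diversity comparison across assembly modes (does
    growing rich cost connectance, or not?).
    """
    rows = []
    for res in results:
        for k, traj in enumerate(res.trajectories):
            last = traj.iloc[-1]
            rows.append(
                {
                    "scenario": res.preset.name,
                    "replicate": k,
                    "S": int(last["S"]),
                    "C": float(last["C"]),
                }
            )
    return pd.DataFrame(rows)


def make_fixture_community(spec: dict) -> Community:
    """Build a small hand-written community for tests and examples.

    ``spec`` has keys ``species`` (list of dicts with id/r/s/x) and
    ``links`` (list of dicts with source/target/type/w_st/w_ts). Invariant
    breaches raise a descriptive error naming the violated invariant.
    """
    return build_community(spec["species"], spec.get("links", ()))
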