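"""Engine/gear orchestration: the recurring exploration loop.

The loop mirrors the standard minimal setup: a *compound gear* optimizes,
sorts and deduplicates new structures into compounds; a *kinetics gear*
decides which compounds are accessible for further trials (all of them, or
only those reachable below a barrier cutoff); a *step-trial gear* enumerates
trial reactive coordinates for accessible compounds and schedules scan jobs;
a *scheduler* runs pending jobs in priority order (geometry optimizations
before Hessian evaluations before scans, by default); and a *reaction gear*
aggregates validated elementary steps into reactions.  The loop repeats
until no gear produces new work or a budget is hit.

Jobs execute in-process and sequentially; the contract is only that any
scheduled job may run and its results land in the database, so the loop is
deterministic for a fixed configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Any, Optional, Sequence

from .calculator import Calculator, CalculationFailure, CapabilityError
from .data_model import (
    Database,
    Structure,
    ValidationError,
    add_calculation,
    add_elementary_step,
    add_structure,
    aggregate_into_compound,
    aggregate_into_reaction,
    finish_calculation,
)
from .elements import DEFAULT_RADII, CovalentRadiiTable
from .molgraph import canonical_key, perceive_graph, split_components
from .nt_scan import NTSettings, run_nt_scan
from .reactive_complex import (
    ClashError,
    ExplorationOptions,
    Filter,
    TrialCoordinate,
    build_reactive_complex,
    enumerate_trial_coordinates,
    reactive_sites,
)
from .step_refinement import (
    IRCSettings,
    NoTransitionStateGuess,
    TSOptimizationError,
    compute_energy_profile,
    endpoint_structure,
    extract_ts_guess,
    irc,
    optimize_minimum,
    optimize_ts,
    spline_path,
    validate_step,
)

logger = logging.getLogger("rxnet.exploration")

DEFAULT_PRIORITIES = {
    "geometry_optimization": 0,
    "hessian": 2,
    "elementary_step_trial": 3,
}


@dataclass
class GearConfig:
    """Configuration of the exploration gears and budgets."""

    kinetics_mode: str = "enable_all"  # or "barrier_cutoff"
    barrier_cutoff: Optional[float] = None  # energy; forward complexed barrier
    priorities: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PRIORITIES))
    max_trials: int = 10_000
    max_loop_iterations: int = 25
    explore_products: bool = False  # False: one-step mode (inputs only react)
    probe_unimolecular: bool = True
    probe_bimolecular: bool = True
    graph_threshold: float = 0.5
    ts_method: str = "bofill"

    def __post_init__(self) -> None:
        if self.kinetics_mode not in {"enable_all", "barrier_cutoff"}:
            raise ValidationError(f"unknown kinetics mode: {self.kinetics_mode!r}")
        if self.kinetics_mode == "barrier_cutoff":
            if self.barrier_cutoff is None or self.barrier_cutoff <= 0:
                raise ValidationError("barrier_cutoff mode needs a positive cutoff")


@dataclass
class ExplorationSummary:
    n_trials: int = 0
    n_validated_steps: int = 0
    n_reactions: int = 0
    n_compounds: int = 0
    stop_reason: str = "quiescent"
    verdict_counts: dict[str, int] = field(default_factory=dict)


def schedule(jobs: Sequence[dict[str, Any]], priorities: dict[str, int]) -> list[dict]:
    """Stable sort of pending jobs by job-type rank, then insertion order."""
    for job in jobs:
        if job["job_type"] not in priorities:
            raise ValidationError(f"no priority rank for job type {job['job_type']!r}")
    return sorted(jobs, key=lambda job: priorities[job["job_type"]])


def kinetics_gate(
    compound_id: str,
    db: Database,
    gear_config: GearConfig,
    input_compound_ids: Optional[set[str]] = None,
) -> bool:
    """Is a compound accessible for further elementary-step trials?

    ``enable_all`` accepts everything.  ``barrier_cutoff`` accepts user-input
    compounds and anything reachable from them through steps whose forward
    complexed barrier lies at or below the cutoff (forward reachability
    only; reverse accessibility is not modeled).
    """
    if gear_config.kinetics_mode == "enable_all":
        return True
    inputs = set(input_compound_ids or ())
    reachable = set(inputs)
    changed = True
    while changed:
        changed = False
        for _, reaction in db.all("reactions").items():
            for step_id in reaction["step_ids"]:
                step = db.get("elementary_steps", step_id)
                barrier = step.get("barriers", {}).get("barrier_complexed")
                if barrier is None or barrier > gear_config.barrier_cutoff:
                    continue
                lhs = set(reaction["reactant_compound_ids"])
                rhs = set(reaction["product_compound_ids"])
                if lhs <= reachable and not rhs <= reachable:
                    reachable |= rhs
                    changed = True
    return compound_id in reachable


# ---------------------------------------------------------------------------
# gears


def _compound_gear(
    db: Database, calculator: Calculator, gear_config: GearConfig
) -> dict[str, str]:
    """Optimize, sort and deduplicate unsorted structures into compounds.

    Returns a map of newly sorted structure id → compound id.
    """
    sorted_now: dict[str, str] = {}
    assigned = {
        sid
        for compound in db.all("compounds").values()
        for sid in compound["structure_ids"]
    }
    for sid in list(db.all("structures")):
        doc = db.get("structures", sid)
        if sid in assigned or doc["label"] not in {"user_guess", "unoptimized", "minimum"}:
            continue
        structure = db.get_structure(sid)
        calc_id = add_calculation(db, "geometry_optimization", input_structure_ids=[sid])
        try:
            if doc["label"] != "minimum":
                structure = optimize_minimum(structure, calculator)
            result = calculator.compute(structure, {"energy", "bond_orders"})
            graph = perceive_graph(structure, result.bond_orders, gear_config.graph_threshold)
            structure.graph_key = str(canonical_key(graph))
        except (CalculationFailure, CapabilityError):
            finish_calculation(db, calc_id, [], failed=True)
            db.update("structures", sid, label="unoptimized", graph_key=None)
            continue
        db.update(
            "structures",
            sid,
            positions=structure.positions.tolist(),
            label="minimum",
            graph_key=structure.graph_key,
        )
        compound_id = aggregate_into_compound(sid, db)
        finish_calculation(db, calc_id, [compound_id])
        sorted_now[sid] = compound_id
    return sorted_now


def _representative_structure(db: Database, compound_id: str) -> Structure:
    compound = db.get("compounds", compound_id)
    return db.get_structure(compound["structure_ids"][0])


def _coordinate_signature(coordinate: TrialCoordinate) -> tuple:
    return (
        tuple(sorted(coordinate.form_pairs)),
        tuple(sorted(coordinate.break_pairs)),
        coordinate.mode,
        coordinate.molecularity,
    )


def _step_trial_gear(
    db: Database,
    calculator: Calculator,
    options: ExplorationOptions,
    gear_config: GearConfig,
    accessible: list[str],
    tried: set[tuple],
    coordinate_filter: Optional[Filter],
) -> list[dict[str, Any]]:
    """Enumerate untried trial coordinates for accessible compounds."""
    jobs: list[dict[str, Any]] = []

    def graph_of(compound_id: str):
        structure = _representative_structure(db, compound_id)
        result = calculator.compute(structure, {"energy", "bond_orders"})
        return structure, perceive_graph(
            structure, result.bond_orders, gear_config.graph_threshold
        )

    if gear_config.probe_unimolecular:
        for compound_id in accessible:
            structure, graph = graph_of(compound_id)
            for coordinate in enumerate_trial_coordinates([graph], options):
                if coordinate_filter is not None and not coordinate_filter.accept(
                    coordinate, [structure]
                ):
                    continue
                key = (compound_id, _coordinate_signature(coordinate))
                if key in tried:
                    continue
                tried.add(key)
                jobs.append(
                    {
                        "job_type": "elementary_step_trial",
                        "compounds": (compound_id,),
                        "coordinate": coordinate,
                    }
                )
    if gear_config.probe_bimolecular:
        for cid_a, cid_b in combinations_with_replacement(accessible, 2):
            if cid_a == cid_b and not options.allow_self_reactions:
                continue
            s_a, g_a = graph_of(cid_a)
            s_b, g_b = graph_of(cid_b)
            for coordinate in enumerate_trial_coordinates([g_a, g_b], options):
                if coordinate_filter is not None and not coordinate_filter.accept(
                    coordinate, [s_a, s_b]
                ):
                    continue
                key = ((cid_a, cid_b), _coordinate_signature(coordinate))
                if key in tried:
                    continue
                tried.add(key)
                jobs.append(
                    {
                        "job_type": "elementary_step_trial",
                        "compounds": (cid_a, cid_b),
                        "coordinate": coordinate,
                    }
                )
    return jobs


def _run_trial(
    db: Database,
    calculator: Calculator,
    job: dict[str, Any],
    options: ExplorationOptions,
    gear_config: GearConfig,
    nt_settings: NTSettings,
    irc_settings: IRCSettings,
    radii: CovalentRadiiTable,
) -> Optional[str]:
    """Execute one elementary-step trial; returns the step id on success."""
    coordinate: TrialCoordinate = job["coordinate"]
    compound_ids = job["compounds"]
    calc_id = add_calculation(
        db,
        "elementary_step_trial",
        settings={"coordinate": repr(_coordinate_signature(coordinate))},
    )
    s1 = _representative_structure(db, compound_ids[0])
    s2 = (
        _representative_structure(db, compound_ids[1])
        if len(compound_ids) == 2
        else None
    )
    try:
        if s2 is not None:
            result = calculator.compute(s1, {"energy", "bond_orders"})
            graph1 = perceive_graph(s1, result.bond_orders, gear_config.graph_threshold)
            sites1 = reactive_sites(s1, graph1)
            a, b_global = sorted(coordinate.form_pairs)[0]
            b = b_global - s1.n_atoms
            d1 = _site_direction(sites1, a)
            result2 = calculator.compute(s2, {"energy", "bond_orders"})
            graph2 = perceive_graph(s2, result2.bond_orders, gear_config.graph_threshold)
            d2 = _site_direction(reactive_sites(s2, graph2), b)
            complexes = build_reactive_complex(
                s1, s2, coordinate, options, radii, d1, d2
            )
        else:
            complexes = build_reactive_complex(s1, None, coordinate, options, radii)
    except (ClashError, ValidationError) as error:
        logger.info("trial %s: complex rejected (%s)", _coordinate_signature(coordinate), error)
        finish_calculation(db, calc_id, [], failed=True)
        return None
    for complex_structure in complexes:
        trajectory = run_nt_scan(
            complex_structure, coordinate, calculator, nt_settings, radii
        )
        if trajectory.stop_reason == "calc_failure" and trajectory.n_frames <= 5:
            continue
        try:
            guess, _ = extract_ts_guess(trajectory)
            ts_result = optimize_ts(guess, calculator, method=gear_config.ts_method)
            forward, backward = irc(
                ts_result.structure,
                calculator,
                irc_settings,
                imaginary_mode=ts_result.imaginary_mode,
            )
        except (NoTransitionStateGuess, TSOptimizationError, CalculationFailure, ValidationError) as error:
            logger.info(
                "trial %s: %s: %s",
                _coordinate_signature(coordinate),
                trajectory.stop_reason,
                error,
            )
            continue
        endpoints = (endpoint_structure(forward), endpoint_structure(backward))
        verdict = validate_step(
            complex_structure, endpoints, calculator, gear_config.graph_threshold
        )
        logger.info(
            "trial %s: stop=%s verdict=%s",
            _coordinate_signature(coordinate),
            trajectory.stop_reason,
            verdict.status,
        )
        job["verdict"] = verdict.status
        if verdict.status != "new_step":
            continue
        reactant_end = endpoints[0] if verdict.matched_end == "forward" else endpoints[1]
        product_end = endpoints[1] if verdict.matched_end == "forward" else endpoints[0]
        try:
            reactant_ids = _store_side(db, calculator, reactant_end, gear_config, radii)
            product_ids = _store_side(db, calculator, product_end, gear_config, radii)
            profile = compute_energy_profile(
                [db.get_structure(sid) for sid in reactant_ids],
                [db.get_structure(sid) for sid in product_ids],
                (reactant_end, product_end),
                ts_result.structure,
                calculator,
            )
            ts_id = add_structure(ts_result.structure, db)
            step_id = add_elementary_step(
                db,
                reactant_ids,
                product_ids,
                ts_id,
                barriers=profile.to_doc(),
                path_spline=spline_path(trajectory).to_doc(),
            )
        except (CalculationFailure, ValidationError) as error:
            logger.info("trial %s: storage failed (%s)", _coordinate_signature(coordinate), error)
            continue
        finish_calculation(db, calc_id, [step_id])
        return step_id
    finish_calculation(db, calc_id, [])
    return None


def _site_direction(sites, atom_index: int):
    import numpy as np

    for site in sites:
        if site.atom_index == atom_index:
            return np.asarray(site.attack_directions[0])
    return np.array([1.0, 0.0, 0.0])


def _store_side(
    db: Database,
    calculator: Calculator,
    endpoint: Structure,
    gear_config: GearConfig,
    radii: CovalentRadiiTable,
) -> list[str]:
    """Split an IRC endpoint into molecules, optimize each, store and sort."""
    result = calculator.compute(endpoint, {"energy", "bond_orders", "partial_charges"})
    graph = perceive_graph(endpoint, result.bond_orders, gear_config.graph_threshold)
    fragments = split_components(
        endpoint, graph, result.partial_charges, endpoint.charge, radii=radii
    )
    ids = []
    for fragment in fragments:
        optimized = optimize_minimum(fragment, calculator)
        frag_result = calculator.compute(optimized, {"energy", "bond_orders"})
        frag_graph = perceive_graph(
            optimized, frag_result.bond_orders, gear_config.graph_threshold
        )
        optimized.graph_key = str(canonical_key(frag_graph))
        sid = add_structure(optimized, db)
        aggregate_into_compound(sid, db)
        ids.append(sid)
    return ids


def _reaction_gear(db: Database) -> int:
    """Aggregate unassigned validated steps into reactions."""
    assigned = {
        step_id
        for reaction in db.all("reactions").values()
        for step_id in reaction["step_ids"]
    }
    new = 0
    for step_id in list(db.all("elementary_steps")):
        if step_id in assigned:
            continue
        aggregate_into_reaction(step_id, db)
        new += 1
    return new


# ---------------------------------------------------------------------------
# the engine loop


def run_exploration(
    db: Database,
    calculator: Calculator,
    options: Optional[ExplorationOptions] = None,
    gear_config: Optional[GearConfig] = None,
    nt_settings: Optional[NTSettings] = None,
    irc_settings: Optional[IRCSettings] = None,
    coordinate_filter: Optional[Filter] = None,
    radii: CovalentRadiiTable = DEFAULT_RADII,
) -> ExplorationSummary:
    """Run the exploration loop until quiescence or budget exhaustion.

    The database must contain at least one user structure.  Per-job failures
    are recorded in calculation records, never raised.
    """
    options = options or ExplorationOptions()
    gear_config = gear_config or GearConfig()
    nt_settings = nt_settings or NTSettings()
    irc_settings = irc_settings or IRCSettings()
    if not db.all("structures"):
        raise ValidationError("the database holds no input structures")
    user_ids = {
        sid
        for sid, doc in db.all("structures").items()
        if doc["label"] in {"user_guess", "minimum", "unoptimized"}
    }
    summary = ExplorationSummary()
    tried: set[tuple] = set()
    input_compounds: set[str] = set()
    for _ in range(gear_config.max_loop_iterations):
        sorted_now = _compound_gear(db, calculator, gear_config)
        for sid, compound_id in sorted_now.items():
            if sid in user_ids:
                input_compounds.add(compound_id)
        accessible = [
            cid
            for cid in sorted(db.all("compounds"))
            if kinetics_gate(cid, db, gear_config, input_compounds)
        ]
        if not gear_config.explore_products:
            accessible = [cid for cid in accessible if cid in input_compounds]
        jobs = _step_trial_gear(
            db, calculator, options, gear_config, accessible, tried, coordinate_filter
        )
        if not jobs:
            break
        budget_hit = False
        for job in schedule(jobs, gear_config.priorities):
            if summary.n_trials >= gear_config.max_trials:
                budget_hit = True
                break
            summary.n_trials += 1
            step_id = _run_trial(
                db, calculator, job, options, gear_config, nt_settings, irc_settings, radii
            )
            verdict = job.get("verdict", "no_step")
            summary.verdict_counts[verdict] = summary.verdict_counts.get(verdict, 0) + 1
            if step_id is not None:
                summary.n_validated_steps += 1
        _reaction_gear(db)
        if budget_hit:
            summary.stop_reason = "budget"
            break
    summary.n_reactions = len(db.all("reactions"))
    summary.n_compounds = len(db.all("compounds"))
    return summary


# ---------------------------------------------------------------------------
# reporting


def check_reference_reactions(
    db: Database,
    calculator: Calculator,
    reference_product_sets: Sequence[Sequence[Structure]],
    gear_config: Optional[GearConfig] = None,
) -> list[bool]:
    """Evaluation protocol: a reference reaction counts as found iff a
    stored reaction connects the input compounds to compounds matching all
    of the reference products (by graph key, after optimization)."""
    gear_config = gear_config or GearConfig()
    threshold = gear_config.graph_threshold
    found: list[bool] = []
    for product_set in reference_product_sets:
        keys = []
        try:
            for product in product_set:
                optimized = optimize_minimum(product, calculator)
                result = calculator.compute(optimized, {"energy", "bond_orders"})
                graph = perceive_graph(optimized, result.bond_orders, threshold)
                keys.append(str(canonical_key(graph)))
        except (CalculationFailure, CapabilityError):
            found.append(False)  # reference optimization failed
            continue
        key_multiset = sorted(keys)
        hit = False
        for reaction in db.all("reactions").values():
            for side in ("reactant_compound_ids", "product_compound_ids"):
                side_keys = sorted(
                    db.get("compounds", cid)["graph_key"] for cid in reaction[side]
                )
                if side_keys == key_multiset:
                    hit = True
        found.append(hit)
    return found


def network_statistics(db: Database) -> dict[str, int]:
    return {
        "structures": len(db.all("structures")),
        "compounds": len(db.all("compounds")),
        "elementary_steps": len(db.all("elementary_steps")),
        "reactions": len(db.all("reactions")),
        "calculations": len(db.all("calculations")),
    }
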