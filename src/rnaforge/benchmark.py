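"""Sensitivity panel: how tightly do designs track their stated goals?

The panel generates achievable design problems and measures, across many
independent runs, the worst-case relative deviation of the achieved
neutrality and free energy from their desired values, plus the shape
distance of every returned design.  "Achievable" is made concrete by
construction: a target is admitted only if an adaptive walk from a random
compatible start reaches base-pair distance 0 under the chosen backend,
and the desired dG/neutrality are set to the values realised by that
reference sequence — so a sequence meeting every goal exactly is known to
exist before the designer is asked to find one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backends import get_backend
from .design import (
    AnnealConfig,
    DesignGoals,
    ObjectiveWeights,
    adaptive_walk,
    design,
    init_sequence,
)
from .fixtures import TOPOLOGIES, gen_structure
from .robustness import neutrality
from .structures import bp_distance


@dataclass
class PanelOutcome:
    worst_neutrality_pct: float
    worst_dG_pct: float
    shape_distances: list = field(default_factory=list)
    n_runs: int = 0
    per_target: list = field(default_factory=list)

    @property
    def worst_pct(self) -> float:
        return max(self.worst_neutrality_pct, self.worst_dG_pct)

    @property
    def all_shapes_exact(self) -> bool:
        return all(d == 0 for d in self.shape_distances)


def make_achievable_goals(
    length: int,
    topology: str,
    rng: np.random.Generator,
    backend,
    max_attempts: int = 50,
) -> tuple[DesignGoals, str]:
    """Generate a target and goals realised by a concrete reference sequence.

    Returns ``(goals, reference_sequence)``; the reference folds exactly to
    the target, and its dG and neutrality become the desired values.
    """
    for _ in range(max_attempts):
        pt = gen_structure(length, topology, rng=rng)
        probe_goals = DesignGoals(pt, desired_dG=0.0, desired_neutrality=0.5)
        for _ in range(5):
            start = init_sequence(probe_goals, rng)
            ref = adaptive_walk(start, probe_goals, backend).sequence
            fr = backend.fold(ref)
            if bp_distance(fr.structure, pt) == 0:
                eta = neutrality(ref, backend).value
                return (
                    DesignGoals(pt, desired_dG=fr.dG, desired_neutrality=eta),
                    ref,
                )
    raise RuntimeError(
        f"no achievable {topology} target of length {length} found in "
        f"{max_attempts} attempts"
    )


def sensitivity_panel(
    seed: int,
    n_targets: int = 10,
    runs_per_target: int = 5,
    length_range: tuple[int, int] = (30, 60),
    backend_name: str = "toy",
    weights: ObjectiveWeights | None = None,
    steps: int = 300,
) -> PanelOutcome:
    """Run the full sensitivity sweep and collect worst-case deviations."""
    rng = np.random.default_rng(seed)
    weights = weights or ObjectiveWeights()
    worst_eta, worst_dg = 0.0, 0.0
    shape_dists: list[float] = []
    per_target = []
    n_runs = 0
    for t in range(n_targets):
        backend = get_backend(backend_name)  # fresh cache per target
        topology = TOPOLOGIES[t % len(TOPOLOGIES)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        goals, _ref = make_achievable_goals(length, topology, rng, backend)
        cfg = AnnealConfig(steps=steps, seed=int(rng.integers(0, 2**31 - 1)))
        results = design(goals, runs_per_target, weights, cfg, backend)
        for r in results:
            eta_dev = abs(r.neutrality.value - goals.desired_neutrality) / abs(
                goals.desired_neutrality
            )
            dg_dev = abs(r.predicted.dG - goals.desired_dG) / abs(
                goals.desired_dG
            )
            worst_eta = max(worst_eta, 100.0 * eta_dev)
            worst_dg = max(worst_dg, 100.0 * dg_dev)
            shape_dists.append(r.shape_distance)
            n_runs += 1
        per_target.append(
            {
                "length": length,
                "topology": topology,
                "desired_dG": goals.desired_dG,
                "desired_neutrality": goals.desired_neutrality,
                "results": results,
            }
        )
    return PanelOutcome(
        worst_neutrality_pct=worst_eta,
        worst_dG_pct=worst_dg,
        shape_distances=shape_dists,
        n_runs=n_runs,
        per_target=per_target,
    )
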