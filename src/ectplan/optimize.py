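"""Electrode-pair voltage optimization with fixed electrode geometry.

The treatment goal is lexicographic: first reach full tumor coverage at
the treatment's target field (success means >= 99.9% of tumor volume),
then minimize the healthy-liver volume exposed above the liver
irreversible-electroporation threshold (400 V/cm).  Only the two voltage
parameters are free — the voltage between neighboring (outer) electrode
pairs and the diagonal voltage — electrode positions never move.

The default search is a deterministic coarse-to-fine scan of a voltage
grid (100 V resolution over [100, 3000] V: the resolution and range at
which published optimal voltages for these configurations are reported).
A seeded genetic-algorithm backend mirroring the stochastic optimizers
used in treatment-planning literature is available via ``method="ga"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .metrics import CURRENT_LIMIT, SUCCESS_THRESHOLD, coverage
from .scenes import LabelScene
from .solver import SolverSettings, make_pulse_plan, solve_sequence

__all__ = ["OptimizationResult", "optimize_voltages"]


@dataclass
class OptimizationResult:
    """Best voltages found, their scores, and the full evaluation log."""

    U_outer: float
    U_diag: float
    coverage_pct: float
    liver_ire_volume_mm3: float
    success: bool
    evaluations: list[dict] = dfield(default_factory=list)


def _score_key(entry: dict, enforce_current_limit: bool, current_limit: float):
    """Lexicographic minimization key.

    Feasible candidates (coverage at/above the success threshold, and
    within the current limit when enforced) rank by liver exposure, then
    higher coverage, then lower total voltage.  Infeasible ones rank by
    coverage first.  The key makes the winner Pareto-undominated on
    (coverage, -liver volume) among everything evaluated.
    """
    over_limit = enforce_current_limit and entry["max_current_A"] > current_limit
    feasible = entry["coverage_pct"] >= SUCCESS_THRESHOLD and not over_limit
    total = entry["U_outer"] + entry["U_diag"]
    if feasible:
        return (
            0,
            entry["liver_ire_volume_mm3"],
            -entry["coverage_pct"],
            total,
            entry["U_outer"],
        )
    return (
        1 if not over_limit else 2,
        -entry["coverage_pct"],
        entry["liver_ire_volume_mm3"],
        total,
        entry["U_outer"],
    )


def optimize_voltages(
    scene: LabelScene,
    n_electrodes: int,
    treatment: str,
    *,
    bounds: tuple[float, float] = (100.0, 3000.0),
    step: float = 100.0,
    coarse_factor: int = 4,
    method: str = "grid",
    seed: int | None = None,
    enforce_current_limit: bool = False,
    current_limit: float = CURRENT_LIMIT,
    tissues=None,
    settings: SolverSettings | None = None,
) -> OptimizationResult:
    """Find (U_outer, U_diag) achieving tumor coverage at least liver cost.

    Parameters
    ----------
    scene
        Scene with rasterized electrodes matching ``n_electrodes``.
    n_electrodes
        Layout size (4, 5 or 7); fixes the pulse plan topology.
    treatment
        ``"ECT"`` or ``"IRE"`` (sets the coverage target field).
    bounds, step
        Voltage grid ``[lo, hi]`` and resolution in volts.
    coarse_factor
        The first scan uses ``coarse_factor * step``; the grid is then
        refined around the incumbent.  Grids of at most 25 candidates are
        searched exhaustively, so small grids equal brute force.
    method
        ``"grid"`` (deterministic, default) or ``"ga"`` (seeded genetic
        algorithm on the same voltage grid).
    enforce_current_limit
        When True, candidates driving any pair above ``current_limit``
        amps are treated as infeasible; otherwise currents are only
        reported.

    Returns
    -------
    OptimizationResult
        Best voltages with achieved coverage/exposure (recomputable by
        solving the returned voltages) and the evaluation log.  If no
        candidate reaches the success threshold the best-effort candidate
        is returned with ``success=False``.
    """
    lo, hi = bounds
    if not (0 < lo <= hi):
        raise ValueError("invalid voltage bounds")
    cache: dict[tuple[float, float], dict] = {}

    def evaluate(U_outer: float, U_diag: float, stage: str) -> dict:
        key = (U_outer, U_diag)
        if key in cache:
            return cache[key]
        plan = make_pulse_plan(n_electrodes, U_outer, U_diag)
        env = solve_sequence(scene, plan, tissues=tissues, settings=settings)
        rep = coverage(env, scene, treatment)
        entry = dict(
            U_outer=U_outer,
            U_diag=U_diag,
            coverage_pct=rep.tumor_coverage_pct,
            liver_ire_volume_mm3=rep.liver_ire_volume_mm3,
            max_current_A=max(env.currents),
            stage=stage,
        )
        cache[key] = entry
        return entry

    def best_of(entries) -> dict:
        return min(entries, key=lambda e: _score_key(e, enforce_current_limit, current_limit))

    def axis(lo_, hi_, step_):
        vals = np.arange(lo_, hi_ + step_ / 2, step_)
        return [float(v) for v in vals if lo_ - 1e-9 <= v <= hi + 1e-9]

    if method == "grid":
        fine = axis(lo, hi, step)
        if len(fine) ** 2 <= 25 or coarse_factor <= 1:
            entries = [evaluate(a, b, "exhaustive") for a in fine for b in fine]
        else:
            coarse = axis(lo, hi, step * coarse_factor)
            entries = [evaluate(a, b, "coarse") for a in coarse for b in coarse]
            inc = best_of(entries)
            span = step * coarse_factor
            ref_o = axis(max(lo, inc["U_outer"] - span), min(hi, inc["U_outer"] + span), step)
            ref_d = axis(max(lo, inc["U_diag"] - span), min(hi, inc["U_diag"] + span), step)
            entries += [evaluate(a, b, "refine") for a in ref_o for b in ref_d]
    elif method == "ga":
        entries = _ga_search(evaluate, lo, hi, step, seed)
    else:
        raise ValueError(f"unknown optimization method {method!r}")

    log = list(cache.values())
    best = best_of(log)
    return OptimizationResult(
        U_outer=best["U_outer"],
        U_diag=best["U_diag"],
        coverage_pct=best["coverage_pct"],
        liver_ire_volume_mm3=best["liver_ire_volume_mm3"],
        success=best["coverage_pct"] >= SUCCESS_THRESHOLD,
        evaluations=log,
    )


def _ga_search(evaluate, lo, hi, step, seed, *, pop_size=16, generations=12):
    """Small elitist genetic algorithm on the snapped voltage grid."""
    rng = np.random.default_rng(0 if seed is None else seed)

    def snap(v):
        return float(np.clip(np.round(v / step) * step, lo, hi))

    pop = [(snap(rng.uniform(lo, hi)), snap(rng.uniform(lo, hi))) for _ in range(pop_size)]
    entries = [evaluate(a, b, "ga") for a, b in pop]
    for _ in range(generations):
        ranked = sorted(entries, key=lambda e: _score_key(e, False, CURRENT_LIMIT))
        parents = ranked[: max(4, pop_size // 3)]
        children = []
        while len(children) < pop_size:
            p, q = rng.choice(len(parents), size=2, replace=False)
            w = rng.uniform()
            a = snap(w * parents[p]["U_outer"] + (1 - w) * parents[q]["U_outer"])
            b = snap(w * parents[p]["U_diag"] + (1 - w) * parents[q]["U_diag"])
            if rng.uniform() < 0.3:
                a = snap(a + rng.integers(-2, 3) * step)
            if rng.uniform() < 0.3:
                b = snap(b + rng.integers(-2, 3) * step)
            children.append((a, b))
        entries = [evaluate(a, b, "ga") for a, b in children] + parents
    return entries
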