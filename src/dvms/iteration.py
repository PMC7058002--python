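"""Self-consistent tile-centroid iteration (the "dynamic" part of DVMS).

A wavefunction tile R is the Voronoi cell of its centroid x̄ among the
like-spin permutation images of x̄, while x̄ is the |Psi|^2-weighted
centroid of R -- the two definitions must be solved together.  Each cycle
runs a block of Metropolis steps, folds every walker into the current
reference cell, and replaces x̄ by the folded walker mean (Metropolis
walkers are |Psi|^2-distributed, so the plain mean estimates the integral
centroid over R).  Iteration stops when x̄ moves less than a tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fold import VoronoiSite, even_fold
from .sampler import StepPolicy, WalkerEnsemble, run_walk
from .wavefunction import CIExpansion


@dataclass
class DVMSState:
    """Bookkeeping of one self-consistency run."""

    site: VoronoiSite
    cycle: int = 0
    block_length: int = 2000
    tolerance: float = 0.05  # bohr, max-norm of site displacement
    stable_cycles: int = 3
    max_cycles: int = 40
    burn_in_fraction: float = 0.25
    collect_stride: int = 0  # 0: once per sweep (N steps) for electron moves
    history: list = field(default_factory=list)  # (cycle, site, psi_at_site)
    converged: bool = False
    odd_fold_count: int = 0


def update_site(folded_positions: np.ndarray, partition,
                label: str = "") -> VoronoiSite:
    """Centroid estimate: unweighted mean of folded walker positions."""
    arr = np.asarray(folded_positions, float)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("need at least one folded position (W, N, 3)")
    return VoronoiSite(arr.mean(axis=0), partition, label)


def _fold_block(positions: np.ndarray, site: VoronoiSite):
    """Fold every walker onto the even images of ``site``.

    Returns (folded array, odd count), where the count tallies folds whose
    unconstrained nearest image was odd (repaired to even, since walkers
    cannot occupy the opposite-signed odd images).
    """
    folded = np.empty_like(positions)
    odd = 0
    for w in range(positions.shape[0]):
        f, was_odd = even_fold(positions[w], site)
        folded[w] = f.folded
        if was_odd:
            odd += 1
    return folded, odd


def run_dvms(ci: CIExpansion, initial_point, policy: StepPolicy,
             n_walkers: int, rng: np.random.Generator,
             state: DVMSState | None = None,
             verbose: bool = False) -> DVMSState:
    """Iterate sampling blocks and centroid updates until the site is
    stationary.

    Convergence: the max-norm site displacement stays below
    ``state.tolerance`` for ``state.stable_cycles`` consecutive cycles.
    Non-convergence at ``max_cycles`` is reported on the returned state,
    not raised.
    """
    part = ci.partition
    if state is None:
        state = DVMSState(site=VoronoiSite(
            np.asarray(initial_point, float).reshape(part.n_electrons, 3),
            part, "x̄"))
    ens = WalkerEnsemble.from_point(ci.value_batch, initial_point,
                                    n_walkers, part)
    stable = 0
    burn = int(state.burn_in_fraction * state.block_length)
    stride = state.collect_stride or (
        part.n_electrons if policy.move == "electron" else 1)
    for _ in range(state.max_cycles):
        collected = []

        def hook(step, e, acc, _c=collected, _b=burn, _s=state, _k=stride):
            off = (step - 1) % _s.block_length
            if off >= _b and off % _k == 0:
                _c.append(e.positions.copy())

        run_walk(ens, ci, policy, state.block_length, rng, hook=hook)
        block = np.concatenate(collected, axis=0)
        folded, odd = _fold_block(block, state.site)
        state.odd_fold_count += odd
        cycle_site = update_site(folded, part, state.site.label)
        state.cycle += 1
        # average the last few cycle estimates to suppress Monte-Carlo
        # noise in the convergence decision and the reported site
        recent = [s.point for _, s, _ in state.history[-2:]] + \
            [cycle_site.point]
        new_site = VoronoiSite(np.mean(recent, axis=0), part,
                               state.site.label)
        delta = np.max(np.abs(new_site.point - state.site.point))
        psi_site = ci.value(new_site.point)
        state.history.append((state.cycle, cycle_site, psi_site))
        if verbose:
            print(f"  cycle {state.cycle:3d}  |dx̄|_max = {delta:.4f} bohr"
                  f"  Psi(x̄) = {psi_site:.3e}")
        state.site = new_site
        # keep walkers in the updated reference cell
        refold, _ = _fold_block(ens.positions, state.site)
        ens.positions = refold
        # even folds preserve the wavefunction value exactly; refresh the
        # cache anyway to stop numerical drift in long runs
        ens.psi_values = ci.value_batch(ens.positions)
        stable = stable + 1 if delta < state.tolerance else 0
        if stable >= state.stable_cycles:
            state.converged = True
            break
    return state


@dataclass
class StageResult:
    n_configs: int
    completeness: float
    psi_eclipsed: float
    psi_staggered: float
    site_eclipsed: VoronoiSite
    site_staggered: VoronoiSite


def staged_truncation_run(ci_full: CIExpansion, schedule,
                          eclipsed_start: VoronoiSite,
                          staggered_start: VoronoiSite,
                          policy: StepPolicy, n_walkers: int,
                          block_length: int, rng: np.random.Generator,
                          burn_in_fraction: float = 0.25,
                          collect_stride: int = 0,
                          verbose: bool = False) -> list[StageResult]:
    """Grow the CI expansion through ``schedule`` (strictly increasing term
    counts), relaxing an eclipsed-lineage and a staggered-lineage site one
    sampling block per stage, each restarted from the previous stage's site.

    Records Psi at both lineage sites per stage, the raw material for
    locating the truncation at which the staggered site overtakes the
    eclipsed one.

    ``block_length = 0`` skips the relaxation entirely and evaluates each
    stage at the fixed start sites (useful when the sites are already
    converged or known analytically).
    """
    from .wavefunction import completeness as _completeness

    schedule = list(schedule)
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly increasing")
    part = ci_full.partition
    results = []
    lineage = {"eclipsed": eclipsed_start, "staggered": staggered_start}
    burn = int(burn_in_fraction * block_length)
    stride = collect_stride or (
        part.n_electrons if policy.move == "electron" else 1)
    for n in schedule:
        ci_n = ci_full.truncate(n)
        new_sites = {}
        for name, site in lineage.items():
            if ci_n.value(site.point) == 0.0:
                raise RuntimeError(
                    f"stage {n}: Psi = 0 at the previous {name} site")
            if block_length == 0:
                new_sites[name] = site
                continue
            ens = WalkerEnsemble.from_point(ci_n.value_batch, site.point,
                                            n_walkers, part)
            collected = []

            def hook(step, e, acc, _c=collected, _b=burn, _k=stride):
                if step - 1 >= _b and (step - 1) % _k == 0:
                    _c.append(e.positions.copy())

            run_walk(ens, ci_n, policy, block_length, rng, hook=hook)
            block = np.concatenate(collected, axis=0)
            folded, _ = _fold_block(block, site)
            new_sites[name] = update_site(folded, part, site.label)
        lineage = new_sites
        res = StageResult(
            n_configs=len(ci_n),
            completeness=_completeness(ci_full, ci_n),
            psi_eclipsed=ci_n.value(lineage["eclipsed"].point),
            psi_staggered=ci_n.value(lineage["staggered"].point),
            site_eclipsed=lineage["eclipsed"],
            site_staggered=lineage["staggered"],
        )
        if verbose:
            print(f"  stage n={res.n_configs:3d}  completeness = "
                  f"{res.completeness:.4f}  Psi_ecl = {res.psi_eclipsed:.4e}"
                  f"  Psi_stag = {res.psi_staggered:.4e}")
        results.append(res)
    return results


def crossing_stage(results: list[StageResult]) -> StageResult | None:
    """First stage at which |Psi| at the staggered site exceeds the
    eclipsed one, or None if it never does."""
    for r in results:
        if abs(r.psi_staggered) > abs(r.psi_eclipsed):
            return r
    return None
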