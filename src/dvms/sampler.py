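"""Metropolis random walk over |Psi|^2 with node-crossing rejection.

All walkers move jointly: one proposal displaces every coordinate of a
walker by an independent Gaussian step. A proposal is accepted with
probability min(1, Psi_new^2 / Psi_old^2), and always rejected when the
sign of Psi changes -- walkers never cross nodes, so each walker stays in
the sign-tile it started in.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .wavefunction import SpinPartition, as_config_array


@dataclass
class StepPolicy:
    """Gaussian step parameters.

    ``step_variance`` is the variance (bohr^2) of the Gaussian displacement
    of each perturbed coordinate. ``move`` selects the proposal granularity:

    * ``"electron"`` (default): one trial move displaces the three
      coordinates of a single electron, electrons visited cyclically. For
      many-electron molecules this is the only granularity with a usable
      acceptance rate -- a joint move of all 3N coordinates at this step
      size is essentially always rejected once N is large.
    * ``"joint"``: every coordinate of the walker is displaced at once
      (appropriate for few-electron systems).

    The stationary distribution |Psi|^2 (restricted to the start tile by
    node rejection) is the same for either choice; only the step-number
    time scale differs.
    """

    step_variance: float = 0.2
    move: str = "electron"

    def __post_init__(self):
        if self.step_variance <= 0:
            raise ValueError("step_variance must be positive")
        if self.move not in ("electron", "joint"):
            raise ValueError("move must be 'electron' or 'joint'")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.step_variance))


@dataclass
class WalkerEnsemble:
    """W walkers with cached wavefunction values.

    ``positions`` has shape (W, N, 3); ``psi_values`` the signed Psi at
    each position (cache kept coherent by the walk loop).
    """

    positions: np.ndarray
    psi_values: np.ndarray
    step_index: int = 0

    @property
    def n_walkers(self) -> int:
        return self.positions.shape[0]

    @property
    def tile_signs(self) -> np.ndarray:
        return np.sign(self.psi_values)

    @classmethod
    def from_point(cls, psi: Callable[[np.ndarray], np.ndarray], x0,
                   n_walkers: int, partition: SpinPartition):
        """All walkers at a common start point (typically near a local
        maximum of |Psi|). Refuses a start on a node."""
        x0 = as_config_array(x0, partition)
        positions = np.repeat(x0[None], n_walkers, axis=0)
        v = float(psi(x0[None])[0])
        if v == 0.0:
            raise ValueError(
                "|Psi| = 0 at the start point; pick a point off the node "
                "surface (e.g. a local maximum of |Psi|)")
        return cls(positions=positions,
                   psi_values=np.full(n_walkers, v))


@dataclass
class WalkTrace:
    """Per-step records from a walk."""

    n_steps: int = 0
    acceptance: list = field(default_factory=list)  # fraction per step
    records: list = field(default_factory=list)  # hook outputs

    @property
    def mean_acceptance(self) -> float:
        return float(np.mean(self.acceptance)) if self.acceptance else 0.0


def propose(positions: np.ndarray, policy: StepPolicy,
            rng: np.random.Generator) -> np.ndarray:
    """Symmetric Gaussian proposal for every walker coordinate."""
    return positions + rng.normal(scale=policy.sigma, size=positions.shape)


def accept_step(psi_old: np.ndarray, psi_new: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Vectorized Metropolis acceptance with node rejection.

    Accept with probability min(1, (psi_new/psi_old)^2) unless the sign
    changes, which is always rejected.
    """
    psi_old = np.atleast_1d(np.asarray(psi_old, float))
    psi_new = np.atleast_1d(np.asarray(psi_new, float))
    if np.any(psi_old == 0.0):
        raise ValueError("walker sits on a node (psi_old == 0)")
    u = rng.random(psi_old.shape)
    ratio = (psi_new / psi_old) ** 2
    same_sign = np.sign(psi_new) == np.sign(psi_old)
    return same_sign & (u < ratio)


def run_walk(ensemble: WalkerEnsemble,
             psi,
             policy: StepPolicy,
             n_steps: int,
             rng: np.random.Generator,
             hook: Callable | None = None,
             stuck_window: int = 200) -> WalkTrace:
    """Advance all walkers ``n_steps`` Metropolis steps (in place).

    ``psi`` is either a callable mapping a batch (W, N, 3) -> (W,) of
    signed wavefunction values, or a `CIExpansion`, in which case
    single-electron moves re-use cached orbital-value matrices and only
    re-evaluate the moved electron's orbitals.

    ``hook(step, ensemble, accepted_mask)`` is invoked after each step; its
    return value (if not None) is appended to the trace records. The walk
    is fully reproducible given the generator state.
    """
    ci = psi if hasattr(psi, "value_from_cache") else None
    psi_fn = ci.value_batch if ci is not None else psi
    trace = WalkTrace()
    zero_accept_run = 0
    n_elec = ensemble.positions.shape[1]
    per_electron = policy.move == "electron" and n_elec > 1
    mo = ci.mo_cache(ensemble.positions) if (ci is not None and
                                             per_electron) else None

    def warn_if_stuck(frac):
        nonlocal zero_accept_run
        zero_accept_run = zero_accept_run + 1 if frac == 0.0 else 0
        if zero_accept_run == stuck_window:
            import warnings
            warnings.warn(
                f"no walker moved for {stuck_window} consecutive steps; "
                "step variance may be too large for this wavefunction")

    for _ in range(n_steps):
        if per_electron:
            e = ensemble.step_index % n_elec
            disp = rng.normal(scale=policy.sigma,
                              size=(ensemble.n_walkers, 3))
            new_pts = ensemble.positions[:, e, :] + disp
            if mo is not None:
                old_rows = mo[:, e, :].copy()
                mo[:, e, :] = ci.orbitals.evaluate(new_pts)
                psi_new = ci.value_from_cache(mo)
            else:
                prop = ensemble.positions.copy()
                prop[:, e, :] = new_pts
                psi_new = psi_fn(prop)
            acc = accept_step(ensemble.psi_values, psi_new, rng)
            ensemble.positions[acc, e, :] = new_pts[acc]
            ensemble.psi_values[acc] = psi_new[acc]
            if mo is not None:
                mo[~acc, e, :] = old_rows[~acc]
        else:
            prop = propose(ensemble.positions, policy, rng)
            psi_new = psi_fn(prop)
            acc = accept_step(ensemble.psi_values, psi_new, rng)
            ensemble.positions[acc] = prop[acc]
            ensemble.psi_values[acc] = psi_new[acc]
        ensemble.step_index += 1
        trace.n_steps += 1
        frac = float(acc.mean())
        trace.acceptance.append(frac)
        warn_if_stuck(frac)
        if hook is not None:
            rec = hook(ensemble.step_index, ensemble, acc)
            if rec is not None:
                trace.records.append(rec)
    return trace


def find_local_maximum(psi: Callable[[np.ndarray], np.ndarray], x0,
                       partition: SpinPartition,
                       step: float = 0.1, grad_eps: float = 1e-4,
                       tol: float = 1e-6, max_iter: int = 2000) -> np.ndarray:
    """Gradient ascent on log|Psi| from a guess configuration.

    Numerical central-difference gradient, adaptive step halving; stops when
    the position update falls below ``tol`` (bohr). Used to construct the
    common start point of a walker swarm.
    """
    x = as_config_array(x0, partition).copy()
    n = x.size
    v = abs(float(psi(x[None])[0]))
    if v == 0.0:
        raise ValueError("|Psi| = 0 at the initial guess")
    for _ in range(max_iter):
        flat = x.reshape(-1)
        pts = np.repeat(flat[None], 2 * n, axis=0)
        for i in range(n):
            pts[2 * i, i] += grad_eps
            pts[2 * i + 1, i] -= grad_eps
        vals = psi(pts.reshape(2 * n, *x.shape))
        sign = np.sign(float(psi(x[None])[0]))
        vals = vals * sign  # work with |Psi| in the current tile
        with np.errstate(divide="ignore"):
            grad = (np.log(np.abs(vals[0::2])) -
                    np.log(np.abs(vals[1::2]))) / (2 * grad_eps)
        grad[~np.isfinite(grad)] = 0.0
        gn = np.linalg.norm(grad)
        if gn == 0.0:
            break
        while step > tol / 10:
            xn = x + (step * grad / gn).reshape(x.shape)
            vn = float(psi(xn[None])[0]) * sign
            if vn > v:
                x, v = xn, vn
                break
            step *= 0.5
        else:
            break
        if step * 1.0 < tol:
            break
        step *= 1.2  # mild re-expansion after a successful move
        step = min(step, 0.5)
    return x
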