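"""Kekulé reference sites, on-the-fly walker classification, equilibrium
occupancies and two-state exchange kinetics.

For benzene, the converged tile centroid shows each spin set forming one of
the two Kekulé structures (alternating one- and two-electron C-C bonds per
spin). Rotating the C-C bonding electrons of either or both spin sets by
60 degrees about the ring axis generates four reference sites: two
"eclipsed" (both spins on the same Kekulé structure) and two "staggered"
(spins on alternate structures, three electrons per C-C bond).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .fold import SpinFactoredSites, VoronoiSite
from .sampler import StepPolicy, WalkerEnsemble, run_walk
from .wavefunction import Geometry, SpinPartition

ECLIPSED_A, STAGGERED_A, STAGGERED_B, ECLIPSED_B = 0, 1, 2, 3
SITE_LABELS = ("eclipsed-A", "staggered-A", "staggered-B", "eclipsed-B")
# class of each site index: True = staggered
IS_STAGGERED = (False, True, True, False)


def _rotation_z(angle_deg: float) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def identify_cc_bonding_electrons(block: np.ndarray, geometry: Geometry,
                                  min_gap: float = 1e-6) -> np.ndarray:
    """Indices of the C-C bonding electrons in one spin block of a site.

    Each electron is assigned to its nearest anchor among carbon nuclei,
    C-H bond midpoints and C-C bond midpoints; the C-C set is returned.
    For a Kekulé arrangement of benzene this yields 9 electrons per spin
    (one per single bond, two per double bond).
    """
    sym = np.array(geometry.symbols)
    carbons = geometry.coords[sym == "C"]
    hydros = geometry.coords[sym == "H"]
    nC = len(carbons)
    # ring order by angle about the z axis
    order = np.argsort(np.arctan2(carbons[:, 1], carbons[:, 0]))
    ring = carbons[order]
    cc_mid = 0.5 * (ring + np.roll(ring, -1, axis=0))
    # C-H midpoints: each hydrogen with its nearest carbon
    ch_mid = []
    for h in hydros:
        c = carbons[np.argmin(np.linalg.norm(carbons - h, axis=1))]
        ch_mid.append(0.5 * (c + h))
    anchors = np.concatenate([carbons, np.array(ch_mid), cc_mid])
    kinds = np.array(["core"] * nC + ["ch"] * len(ch_mid) + ["cc"] * nC)
    d = np.linalg.norm(block[:, None, :] - anchors[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    # ambiguity check: nearest and second-nearest anchor of different kind
    dsort = np.sort(d, axis=1)
    if np.any(dsort[:, 1] - dsort[:, 0] < min_gap):
        raise ValueError("ambiguous electron-anchor assignment")
    return np.where(kinds[nearest] == "cc")[0]


def build_reference_sites(base: VoronoiSite, geometry: Geometry,
                          angle: float = 60.0) -> SpinFactoredSites:
    """The four Kekulé reference sites from a converged (eclipsed) base
    site: rotate the C-C bonding electrons of the alpha set, the beta set,
    or both, by ``angle`` degrees about the ring (z) axis."""
    R = _rotation_z(angle)

    def rotated(block):
        idx = identify_cc_bonding_electrons(block, geometry)
        out = block.copy()
        out[idx] = block[idx] @ R.T
        return out

    alpha_variants = [base.alpha, rotated(base.alpha)]
    beta_variants = [base.beta, rotated(base.beta)]
    # site order: (a0,b0)=eclipsed-A, (a0,b1)=staggered-A,
    #             (a1,b0)=staggered-B, (a1,b1)=eclipsed-B
    labels = [SITE_LABELS[ECLIPSED_A], SITE_LABELS[STAGGERED_A],
              SITE_LABELS[STAGGERED_B], SITE_LABELS[ECLIPSED_B]]
    return SpinFactoredSites(alpha_variants, beta_variants, base.partition,
                             labels=labels)


@dataclass
class OccupancyTrace:
    """Per-step counts of walkers in each reference cell."""

    site_counts: np.ndarray  # (n_steps, n_sites) integers
    n_walkers: int
    metadata: dict

    def __post_init__(self):
        counts = np.asarray(self.site_counts, dtype=int)
        if np.any(counts.sum(axis=1) != self.n_walkers):
            raise ValueError("per-step counts must sum to the walker count")
        self.site_counts = counts

    @property
    def n_steps(self) -> int:
        return self.site_counts.shape[0]

    @property
    def eclipsed(self) -> np.ndarray:
        stag = np.array(IS_STAGGERED)
        return self.site_counts[:, ~stag].sum(axis=1)

    @property
    def staggered(self) -> np.ndarray:
        stag = np.array(IS_STAGGERED)
        return self.site_counts[:, stag].sum(axis=1)


def classify_trace(ci, sites: SpinFactoredSites, start: VoronoiSite,
                   n_walkers: int, n_steps: int, policy: StepPolicy,
                   rng: np.random.Generator,
                   metadata: dict | None = None) -> OccupancyTrace:
    """Metropolis walk from a common start with per-step nearest-site
    classification of every walker."""
    part = ci.partition
    ens = WalkerEnsemble.from_point(ci.value_batch, start.point,
                                    n_walkers, part)
    n_sites = len(sites.alpha_variants) * len(sites.beta_variants)
    counts = np.zeros((n_steps, n_sites), dtype=int)
    # walkers keep the sign of the start point; each reference site is
    # reachable only through images whose relabelling parity matches
    # sign(walker) * sign(Psi(site))
    s0 = np.sign(float(ci.value(start.point)))
    parities = []
    for s in sites.sites:
        v = float(ci.value(s.point))
        if v == 0.0:
            raise ValueError(f"Psi vanishes at reference site {s.label}")
        parities.append(int(s0 * np.sign(v)))

    def hook(step, e, acc):
        idx, _ = sites.classify(e.positions, parities=parities)
        counts[step - 1] = np.bincount(idx, minlength=n_sites)

    run_walk(ens, ci, policy, n_steps, rng, hook=hook)
    meta = {"n_walkers": n_walkers, "n_steps": n_steps,
            "n_configs": len(ci), **(metadata or {})}
    return OccupancyTrace(site_counts=counts, n_walkers=n_walkers,
                          metadata=meta)


@dataclass
class EquilibriumEstimate:
    """Decorrelation-corrected class means over a post-equilibration
    window. The naive standard deviation of per-step counts is deflated by
    sqrt(n_step / decorrelation_steps) independent samples."""

    mean_eclipsed: float
    mean_staggered: float
    se_eclipsed: float
    se_staggered: float
    window: tuple[int, int]
    decorrelation_steps: float

    @property
    def two_sigma(self) -> tuple[float, float]:
        return 2 * self.se_eclipsed, 2 * self.se_staggered


def equilibrium_occupancy(trace: OccupancyTrace, window_start: int,
                          window_stop: int | None = None,
                          decorrelation_steps: float = 200.0
                          ) -> EquilibriumEstimate:
    """Class means and standard errors over steps
    [window_start, window_stop) (0-based)."""
    stop = window_stop if window_stop is not None else trace.n_steps
    n = stop - window_start
    if n < decorrelation_steps:
        raise ValueError("window shorter than one decorrelation length")
    n_indep = n / decorrelation_steps
    out = {}
    for name, series in (("eclipsed", trace.eclipsed),
                         ("staggered", trace.staggered)):
        w = series[window_start:stop].astype(float)
        out[name] = (w.mean(), w.std(ddof=1) / np.sqrt(n_indep))
    return EquilibriumEstimate(
        mean_eclipsed=out["eclipsed"][0], mean_staggered=out["staggered"][0],
        se_eclipsed=out["eclipsed"][1], se_staggered=out["staggered"][1],
        window=(window_start, stop), decorrelation_steps=decorrelation_steps)


@dataclass
class KineticFit:
    """Symmetric two-state exchange fit to the equilibration transient.

    N_staggered(k) = N_eq + (N_0 - N_eq) exp(-k_relax k); for a near-50/50
    equilibrium the per-direction crossing rate is k_x = k_relax / 2 and
    walker cell assignments decorrelate after about 1 / k_x steps.
    """

    relaxation_rate: float  # k_relax, per step
    crossing_rate: float  # k_x, per step
    n_equilibrium: float
    n_start: float
    residual_rms: float
    identifiable: bool

    @property
    def decorrelation_steps(self) -> float:
        return 1.0 / self.crossing_rate


def fit_kinetics(trace: OccupancyTrace, fit_window: int | None = None
                 ) -> KineticFit:
    """Least-squares exponential relaxation fit to the staggered-count
    trace; requires a start away from equilibrium (e.g. all walkers
    eclipsed at step 0)."""
    y = trace.staggered.astype(float)
    if fit_window is not None:
        y = y[:fit_window]
    k = np.arange(1, y.size + 1, dtype=float)
    n_eq0 = y[y.size // 2:].mean()
    n00 = y[0]
    if abs(n00 - n_eq0) < 2.0 * y.std(ddof=1) / np.sqrt(y.size / 200.0):
        return KineticFit(relaxation_rate=np.nan, crossing_rate=np.nan,
                          n_equilibrium=n_eq0, n_start=n00,
                          residual_rms=np.nan, identifiable=False)

    def model(kk, n_eq, n0, rate):
        return n_eq + (n0 - n_eq) * np.exp(-rate * kk)

    p0 = (n_eq0, n00, 0.01)
    popt, _ = optimize.curve_fit(model, k, y, p0=p0, maxfev=20000)
    n_eq, n0, rate = popt
    resid = y - model(k, *popt)
    if rate <= 0:
        return KineticFit(relaxation_rate=rate, crossing_rate=np.nan,
                          n_equilibrium=n_eq, n_start=n0,
                          residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                          identifiable=False)
    return KineticFit(relaxation_rate=float(rate),
                      crossing_rate=float(rate) / 2.0,
                      n_equilibrium=float(n_eq), n_start=float(n0),
                      residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                      identifiable=True)


@dataclass
class BlockComparison:
    block_a: tuple[int, int]
    block_b: tuple[int, int]
    z_score: float
    p_value: float
    passed: bool  # no significant difference at alpha


def block_stationarity(trace: OccupancyTrace, blocks,
                       alpha: float = 0.05,
                       decorrelation_steps: float = 200.0
                       ) -> list[BlockComparison]:
    """Pairwise two-sample z-tests on staggered-count block means, with
    decorrelation-corrected standard errors. Blocks are (start, stop)
    0-based step ranges and must not overlap."""
    blocks = [tuple(b) for b in blocks]
    if len(blocks) < 2:
        raise ValueError("need at least two blocks")
    for (a0, a1) in blocks:
        if a1 - a0 < decorrelation_steps:
            raise ValueError("block shorter than one decorrelation length")
    for i, (a0, a1) in enumerate(blocks):
        for (b0, b1) in blocks[i + 1:]:
            if max(a0, b0) < min(a1, b1):
                raise ValueError("blocks overlap")
    y = trace.staggered.astype(float)
    stats_per_block = []
    for (b0, b1) in blocks:
        w = y[b0:b1]
        n_indep = (b1 - b0) / decorrelation_steps
        stats_per_block.append((w.mean(), w.std(ddof=1) / np.sqrt(n_indep)))
    out = []
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            (ma, sa), (mb, sb) = stats_per_block[i], stats_per_block[j]
            denom = np.sqrt(sa ** 2 + sb ** 2)
            if denom == 0.0:
                z = 0.0 if ma == mb else np.inf
            else:
                z = (ma - mb) / denom
            p = 2.0 * stats.norm.sf(abs(z))
            out.append(BlockComparison(blocks[i], blocks[j], float(z),
                                       float(p), bool(p >= alpha)))
    return out
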