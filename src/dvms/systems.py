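"""Built-in systems: the benzene fixtures, analytic toy wavefunctions, and
the adapter contract to an external quantum-chemistry engine.

The committed benzene fixtures hold RHF/6-31G(d) molecular orbitals at an
ideal D6h geometry together with two determinant CI vectors computed from
those orbitals: the all-pi (6,6) CAS-CI and the valence (30,18) CAS-CI
(all valence electrons, occupancy allowed in the lowest three unoccupied
orbitals). Checksums in the fixture manifest guard against silent edits.

Toy systems are few-electron wavefunctions with closed-form orbitals whose
nodes, tiles and centroids are known or recomputable by quadrature; they
exercise every stage of the pipeline without any quantum-chemistry input.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np

from .fold import VoronoiSite
from .io import civec_to_expansion, read_civec, read_molden
from .wavefunction import (AnalyticOrbitalSet, BOHR_PER_ANGSTROM, CIExpansion,
                           Geometry, GaussianOrbitalSet, SpinDeterminant,
                           SpinPartition)


class EngineUnavailableError(RuntimeError):
    """Raised when fixture regeneration is requested without a quantum
    chemistry backend installed."""


# ------------------------------------------------------------ geometry

def build_benzene(r_cc: float = 1.397, r_ch: float = 1.087) -> Geometry:
    """Ideal D6h benzene in the xy-plane, C6 axis along z.

    ``r_cc`` and ``r_ch`` are bond lengths in angstrom (defaults near
    B3LYP/6-31G(d)-quality values); for a regular hexagon the ring radius
    equals the C-C bond length.
    """
    if not 1.2 < r_cc < 1.6:
        raise ValueError("r_cc out of the plausible 1.2-1.6 angstrom range")
    if not 0.9 < r_ch < 1.3:
        raise ValueError("r_ch out of the plausible 0.9-1.3 angstrom range")
    coords = []
    for radius in (r_cc, r_cc + r_ch):
        for i in range(6):
            th = math.pi / 3 * i
            coords.append([radius * math.cos(th), radius * math.sin(th), 0.0])
    coords = np.array(coords) * BOHR_PER_ANGSTROM
    return Geometry(tuple(["C"] * 6 + ["H"] * 6), coords)


# ------------------------------------------------------------ fixtures

_FIXDIR = resources.files("dvms") / "data"


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def fixture_manifest() -> dict:
    with (_FIXDIR / "manifest.json").open() as f:
        return json.load(f)


def verify_fixtures() -> None:
    """Check committed fixture checksums; raises on mismatch."""
    man = fixture_manifest()
    for name, meta in man["files"].items():
        got = _sha256(_FIXDIR / name)
        if got != meta["sha256"]:
            raise RuntimeError(f"fixture {name} checksum mismatch")


def load_benzene_orbitals():
    """(Geometry, GaussianOrbitalSet) from the committed Molden fixture."""
    path = _FIXDIR / "benzene_rhf_631gd.molden"
    geometry, basis, coeff, energies, occ, labels = read_molden(str(path))
    return geometry, GaussianOrbitalSet(geometry, basis, coeff,
                                        energies=energies, labels=labels)


def load_benzene_ci(kind: str = "cas66") -> tuple[Geometry, CIExpansion]:
    """Benzene wavefunctions from committed fixtures.

    kind: 'rhf' (single determinant), 'cas66' (all-pi (6,6) CAS-CI) or
    'cas3018' (valence (30,18) CAS-CI, leading terms).
    """
    names = {"rhf": "benzene_rhf.civec",
             "cas66": "benzene_cas66_pi.civec",
             "cas3018": "benzene_cas3018_valence.civec"}
    if kind not in names:
        raise ValueError(f"unknown benzene wavefunction {kind!r}; "
                         f"choose from {sorted(names)}")
    geometry, orbitals = load_benzene_orbitals()
    civec = read_civec(str(_FIXDIR / names[kind]))
    ci = civec_to_expansion(civec, orbitals)
    if ci.partition.n_alpha != 21 or ci.partition.n_beta != 21:
        raise RuntimeError("benzene fixture must have 21 electrons per spin")
    return geometry, ci


def lewis_guess(geometry: Geometry, double_bonds=(0, 2, 4),
                pi_offset: float = 0.5, staggered: bool = False) -> np.ndarray:
    """Chemically-motivated start configuration for benzene (42, 3).

    Per spin: one electron at each carbon nucleus (1s core), one at each
    C-H bond midpoint, one at each single C-C bond midpoint and two per
    double bond displaced +-``pi_offset`` bohr out of plane. ``double_bonds``
    selects which ring bonds (0..5, between ring neighbours i and i+1) are
    double for the alpha set; the beta set uses the same structure
    (eclipsed) or the complementary one (staggered).
    """
    sym = np.array(geometry.symbols)
    carbons = geometry.coords[sym == "C"]
    hydros = geometry.coords[sym == "H"]
    order = np.argsort(np.arctan2(carbons[:, 1], carbons[:, 0]))
    ring = carbons[order]
    cc_mid = 0.5 * (ring + np.roll(ring, -1, axis=0))
    ch_mid = []
    for h in hydros:
        c = carbons[np.argmin(np.linalg.norm(carbons - h, axis=1))]
        ch_mid.append(0.5 * (c + h))

    def spin_block(dbl):
        pts = [c for c in carbons] + list(ch_mid)
        for b in range(6):
            if b in dbl:
                up = cc_mid[b] + [0.0, 0.0, pi_offset]
                dn = cc_mid[b] - [0.0, 0.0, pi_offset]
                pts.extend([up, dn])
            else:
                pts.append(cc_mid[b])
        return np.array(pts)

    alt = tuple(b for b in range(6) if b not in double_bonds)
    alpha = spin_block(tuple(double_bonds))
    beta = spin_block(alt if staggered else tuple(double_bonds))
    return np.concatenate([alpha, beta])


# ------------------------------------------------------------ toys

@dataclass
class ToySystem:
    """Analytic few-electron wavefunction with known tile structure."""

    name: str
    ci: CIExpansion
    partition: SpinPartition
    sites: list  # representative VoronoiSite per distinct cell
    notes: str = ""
    cell_probability: Callable | None = None  # analytic, if derivable
    extras: dict = field(default_factory=dict)


def _gaussian(center, alpha=0.5):
    center = np.asarray(center, float)

    def f(pts):
        d = pts - center
        return np.exp(-alpha * np.einsum("md,md->m", d, d))

    return f


def make_toy(name: str, **params) -> ToySystem:
    """Toy registry.

    two_electron_triplet
        Two same-spin electrons in Gaussians displaced along x; the node is
        exactly x1 = x2 and the two tiles are permutation images with
        analytic-by-quadrature centroids.
    two_plus_two
        Separable 2-alpha + 2-beta version; four cells, each with
        probability 1/4 by symmetry.
    double_well_ci
        One electron per spin, two wells, a 2-configuration expansion
        c1 |L R| + c2 |R L|: the minimal analogue of competing resonance
        structures. Cell probabilities tend to c_i^2/(c1^2+c2^2) as the
        wells separate.
    """
    if name == "two_electron_triplet":
        a = params.get("separation", 1.0)
        alpha = params.get("alpha", 0.5)
        orbs = AnalyticOrbitalSet([_gaussian([-a, 0, 0], alpha),
                                   _gaussian([+a, 0, 0], alpha)])
        part = SpinPartition(2, 0)
        ci = CIExpansion([(SpinDeterminant((0, 1), ()), 1.0)], orbs, part)
        site = VoronoiSite(np.array([[-a, 0, 0], [a, 0, 0]], float), part,
                           "left-right")
        return ToySystem(name=name, ci=ci, partition=part, sites=[site],
                         notes="node at x1 = x2; tiles swap under "
                               "transposition",
                         extras={"separation": a, "alpha": alpha})
    if name == "two_plus_two":
        a = params.get("separation", 1.0)
        alpha = params.get("alpha", 0.5)
        orbs = AnalyticOrbitalSet([_gaussian([-a, 0, 0], alpha),
                                   _gaussian([+a, 0, 0], alpha)])
        part = SpinPartition(2, 2)
        ci = CIExpansion([(SpinDeterminant((0, 1), (0, 1)), 1.0)], orbs, part)
        base = np.array([[-a, 0, 0], [a, 0, 0]] * 2, float)
        site = VoronoiSite(base, part, "LR|LR")
        return ToySystem(name=name, ci=ci, partition=part, sites=[site],
                         notes="multiplicatively separable spins; 4 cells "
                               "of probability 1/4",
                         cell_probability=lambda i: 0.25,
                         extras={"separation": a, "alpha": alpha})
    if name == "double_well_ci":
        a = params.get("separation", 2.0)
        alpha = params.get("alpha", 1.0)
        c1 = params.get("c1", 1.0)
        c2 = params.get("c2", 1.0)
        orbs = AnalyticOrbitalSet([_gaussian([-a, 0, 0], alpha),
                                   _gaussian([+a, 0, 0], alpha)])
        part = SpinPartition(1, 1)
        nrm = math.sqrt(c1 * c1 + c2 * c2)
        ci = CIExpansion([(SpinDeterminant((0,), (1,)), c1 / nrm),
                          (SpinDeterminant((1,), (0,)), c2 / nrm)],
                         orbs, part)
        s1 = VoronoiSite(np.array([[-a, 0, 0], [a, 0, 0]], float), part, "LR")
        s2 = VoronoiSite(np.array([[a, 0, 0], [-a, 0, 0]], float), part, "RL")
        w1, w2 = (c1 / nrm) ** 2, (c2 / nrm) ** 2
        return ToySystem(
            name=name, ci=ci, partition=part, sites=[s1, s2],
            notes="two-cell competition controlled by c1:c2",
            cell_probability=lambda i: (w1, w2)[i],
            extras={"separation": a, "alpha": alpha, "c1": c1, "c2": c2})
    raise ValueError(
        f"unknown toy {name!r}; registry: two_electron_triplet, "
        "two_plus_two, double_well_ci")


# ------------------------------------------------------------ backend

@dataclass(frozen=True)
class BackendRequest:
    """Description of a wavefunction to obtain from an external engine."""

    geometry: Geometry
    basis_name: str = "6-31G(d)"
    n_active_electrons: int | None = None
    n_active_orbitals: int | None = None
    orbital_selection: str = "lowest-virtuals"  # or "pi-space"


def request_wavefunction(request: BackendRequest):
    """Regenerate MO/CI fixture data through an external quantum-chemistry
    engine (pyscf), when one is installed.

    The committed fixtures cover all tests and analyses; this adapter
    exists so the fixture data can be re-derived from first principles.
    """
    try:
        import pyscf  # noqa: F401
    except ImportError as exc:
        raise EngineUnavailableError(
            "no quantum-chemistry backend installed (pip install pyscf); "
            "committed fixtures in dvms/data cover all built-in analyses"
        ) from exc
    raise NotImplementedError(
        "backend regeneration is a maintenance path; see docs/methods.md")
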