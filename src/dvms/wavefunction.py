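"""Evaluation of many-electron wavefunctions written as CI expansions.

A wavefunction is a sum of Slater determinants over a common set of spatial
orbitals,

    Psi(x) = sum_i c_i  det[A_i(x_alpha)] * det[B_i(x_beta)],

where ``x`` is a configuration point -- the positions of all N electrons,
alpha block first -- and A_i / B_i are the matrices of occupied-orbital
values at the alpha / beta electron positions of configuration ``i``.
Orbitals may be molecular orbitals expanded in a contracted Cartesian
Gaussian basis, or closed-form model orbitals.

Everything is evaluated in atomic units (bohr).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903

_ELEMENTS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}

# Cartesian component exponents (lx,ly,lz) per angular momentum, in the
# order used throughout (s; px,py,pz; xx,yy,zz,xy,xz,yz).
CARTESIAN_COMPONENTS = {
    0: ((0, 0, 0),),
    1: ((1, 0, 0), (0, 1, 0), (0, 0, 1)),
    2: ((2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)),
}


class ConfigurationError(ValueError):
    """Inconsistent geometry / basis / orbital / CI input."""


def _double_factorial(n: int) -> int:
    r = 1
    while n > 1:
        r *= n
        n -= 2
    return r


def primitive_norm(alpha: float, lx: int, ly: int, lz: int) -> float:
    """Normalization constant of a Cartesian Gaussian primitive
    x^lx y^ly z^lz exp(-alpha r^2)."""
    L = lx + ly + lz
    return ((2.0 * alpha / math.pi) ** 0.75 * (4.0 * alpha) ** (L / 2.0)
            / math.sqrt(_double_factorial(2 * lx - 1)
                        * _double_factorial(2 * ly - 1)
                        * _double_factorial(2 * lz - 1)))


@dataclass(frozen=True)
class Geometry:
    """Molecular geometry; coordinates in bohr."""

    symbols: tuple[str, ...]
    coords: np.ndarray  # (natom, 3), bohr

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if len(self.symbols) == 0:
            raise ConfigurationError("geometry needs at least one atom")
        if coords.shape != (len(self.symbols), 3):
            raise ConfigurationError("coords shape must be (natom, 3)")
        if not np.all(np.isfinite(coords)):
            raise ConfigurationError("non-finite coordinates")
        for s in self.symbols:
            if s not in _ELEMENTS:
                raise ConfigurationError(f"unknown element symbol {s!r}")

    @property
    def natom(self) -> int:
        return len(self.symbols)

    @property
    def charges(self) -> np.ndarray:
        return np.array([_ELEMENTS[s] for s in self.symbols], dtype=float)


@dataclass(frozen=True)
class Shell:
    """One contracted Cartesian Gaussian shell."""

    center: int  # atom index
    l: int  # angular momentum (0=s, 1=p, 2=d)
    exponents: tuple[float, ...]
    coefficients: tuple[float, ...]
    cartesian: bool = True

    def __post_init__(self):
        if len(self.exponents) != len(self.coefficients):
            raise ConfigurationError("exponent/coefficient length mismatch")
        if any(e <= 0 for e in self.exponents):
            raise ConfigurationError("exponents must be positive")
        if self.l not in CARTESIAN_COMPONENTS:
            raise ConfigurationError(f"unsupported angular momentum {self.l}")
        if not self.cartesian and self.l >= 2:
            raise ConfigurationError("only Cartesian shells are supported")

    @property
    def n_components(self) -> int:
        return len(CARTESIAN_COMPONENTS[self.l])


@dataclass(frozen=True)
class AOBasis:
    """Contracted Cartesian Gaussian basis over a geometry.

    Convention: contraction coefficients multiply *normalized* primitives,
    and each contracted component is afterwards renormalized to unit
    self-overlap (the usual quantum-chemistry convention for published
    basis sets).
    """

    shells: tuple[Shell, ...]

    @property
    def n_ao(self) -> int:
        return sum(s.n_components for s in self.shells)

    def ao_labels(self) -> list[tuple[int, int, tuple[int, int, int]]]:
        """(atom, shell index, (lx,ly,lz)) per AO."""
        out = []
        for i, sh in enumerate(self.shells):
            for lmn in CARTESIAN_COMPONENTS[sh.l]:
                out.append((sh.center, i, lmn))
        return out


def _contracted_self_overlap(exps, coefs, lmn):
    lx, ly, lz = lmn
    s = 0.0
    for a, ca in zip(exps, coefs):
        for b, cb in zip(exps, coefs):
            p = a + b
            val = (math.pi / p) ** 1.5
            for l in (lx, ly, lz):
                val *= _double_factorial(2 * l - 1) / (2.0 * p) ** l
            s += ca * cb * val
    return s


class _CompiledBasis:
    """Primitive data grouped per atomic center for vectorized AO
    evaluation: one exp() call per center, radial sums as a dense
    (primitive -> AO) matrix product, angular factors applied per AO."""

    def __init__(self, geometry: Geometry, basis: AOBasis):
        # unique centers actually carrying shells
        center_ids = sorted({sh.center for sh in basis.shells})
        self.centers = geometry.coords[center_ids]
        cmap = {c: i for i, c in enumerate(center_ids)}
        # per center: unique exponents; per AO: sparse rows over those
        exps_per_center: list[dict] = [dict() for _ in center_ids]
        ao_center, ao_lmn, ao_rows = [], [], []
        for sh in basis.shells:
            ic = cmap[sh.center]
            table = exps_per_center[ic]
            for lmn in CARTESIAN_COMPONENTS[sh.l]:
                cn = [c * primitive_norm(a, *lmn)
                      for a, c in zip(sh.exponents, sh.coefficients)]
                norm = math.sqrt(
                    _contracted_self_overlap(sh.exponents, cn, lmn))
                row = []
                for a, c in zip(sh.exponents, cn):
                    k = table.setdefault(a, len(table))
                    row.append((k, c / norm))
                ao_center.append(ic)
                ao_lmn.append(lmn)
                ao_rows.append(row)
        self.nao = len(ao_center)
        self.ao_center = np.array(ao_center)
        self.ao_lmn = np.array(ao_lmn)
        self.center_exps = [np.array(sorted(t, key=t.get))
                            for t in exps_per_center]
        # radial coefficient matrix per center: (n_exp_c, n_ao_c)
        self.center_ao = []
        for ic in range(len(center_ids)):
            aos = np.where(self.ao_center == ic)[0]
            coef = np.zeros((len(self.center_exps[ic]), len(aos)))
            for j, mu in enumerate(aos):
                for k, c in ao_rows[mu]:
                    coef[k, j] = c
            self.center_ao.append((aos, coef))

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """AO values at ``points`` (M, 3) -> (M, nao)."""
        pts = np.asarray(points, dtype=float)
        M = pts.shape[0]
        out = np.empty((M, self.nao))
        for ic, (aos, coef) in enumerate(self.center_ao):
            d = pts - self.centers[ic]
            r2 = np.einsum("md,md->m", d, d)
            E = np.exp(-np.outer(r2, self.center_exps[ic]))
            rad = E @ coef  # (M, n_ao_c)
            lmn = self.ao_lmn[aos]
            for j, mu in enumerate(aos):
                lx, ly, lz = lmn[j]
                col = rad[:, j]
                if lx == 1:
                    col = col * d[:, 0]
                elif lx == 2:
                    col = col * d[:, 0] * d[:, 0]
                if ly == 1:
                    col = col * d[:, 1]
                elif ly == 2:
                    col = col * d[:, 1] * d[:, 1]
                if lz == 1:
                    col = col * d[:, 2]
                elif lz == 2:
                    col = col * d[:, 2] * d[:, 2]
                out[:, mu] = col
        return out


class GaussianOrbitalSet:
    """Molecular orbitals expanded in a contracted Gaussian AO basis."""

    def __init__(self, geometry: Geometry, basis: AOBasis,
                 coefficients: np.ndarray,
                 energies: np.ndarray | None = None,
                 labels: Sequence[str] | None = None):
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.shape[0] != basis.n_ao:
            raise ConfigurationError(
                f"MO coefficient rows ({coefficients.shape[0]}) do not match "
                f"AO count ({basis.n_ao})")
        if not np.all(np.isfinite(coefficients)):
            raise ConfigurationError("non-finite MO coefficients")
        self.geometry = geometry
        self.basis = basis
        self.coefficients = coefficients
        self.energies = (np.asarray(energies, float)
                         if energies is not None else None)
        self.labels = list(labels) if labels is not None else None
        self._compiled = _CompiledBasis(geometry, basis)

    @property
    def n_orbitals(self) -> int:
        return self.coefficients.shape[1]

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Orbital values at ``points`` (M, 3) -> (M, n_orbitals)."""
        return self._compiled.evaluate(points) @ self.coefficients


class AnalyticOrbitalSet:
    """Closed-form model orbitals, each a vectorized callable (M,3)->(M,)."""

    def __init__(self, functions: Sequence[Callable[[np.ndarray], np.ndarray]]):
        self.functions = list(functions)

    @property
    def n_orbitals(self) -> int:
        return len(self.functions)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return np.stack([f(pts) for f in self.functions], axis=-1)


@dataclass(frozen=True)
class SpinPartition:
    """Numbers of alpha and beta electrons."""

    n_alpha: int
    n_beta: int

    def __post_init__(self):
        if self.n_alpha < 0 or self.n_beta < 0:
            raise ConfigurationError("negative electron count")

    @property
    def n_electrons(self) -> int:
        return self.n_alpha + self.n_beta


@dataclass(frozen=True)
class SpinDeterminant:
    """Occupied spatial-orbital indices per spin."""

    alpha_occ: tuple[int, ...]
    beta_occ: tuple[int, ...]

    def __post_init__(self):
        for occ in (self.alpha_occ, self.beta_occ):
            if len(set(occ)) != len(occ):
                raise ConfigurationError("duplicate orbital in determinant")
            if tuple(sorted(occ)) != tuple(occ):
                raise ConfigurationError("occupations must be sorted")


def slater_value(mo_matrix: np.ndarray) -> float:
    """Value of a Slater determinant from the square matrix with entry
    (i, j) = orbital j evaluated at electron i."""
    m = np.asarray(mo_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("orbital-value matrix must be square")
    if m.shape[0] == 0:
        return 1.0
    return float(np.linalg.det(m))


def as_config_array(x, partition: SpinPartition) -> np.ndarray:
    """Coerce a flat 3N vector or (N,3) array to (N,3); validate length."""
    arr = np.asarray(x, dtype=float)
    n = partition.n_electrons
    if arr.ndim == 1:
        if arr.size != 3 * n:
            raise ValueError(f"expected 3N = {3*n} coordinates, got {arr.size}")
        arr = arr.reshape(n, 3)
    elif arr.shape != (n, 3):
        raise ValueError(f"expected shape ({n}, 3), got {arr.shape}")
    return arr


class CIExpansion:
    """CI expansion: ordered (determinant, coefficient) terms over an
    orbital set, with alpha/beta electron counts fixed by ``partition``.

    Terms are stored sorted by decreasing |c_i| (ties broken by the
    determinant's occupation strings, for deterministic truncation).
    """

    def __init__(self, terms, orbitals, partition: SpinPartition,
                 sort: bool = True):
        terms = [(d, float(c)) for d, c in terms]
        seen = set()
        for d, _ in terms:
            if len(d.alpha_occ) != partition.n_alpha or \
                    len(d.beta_occ) != partition.n_beta:
                raise ConfigurationError(
                    "determinant occupation does not match spin partition")
            if max(d.alpha_occ + d.beta_occ, default=-1) >= orbitals.n_orbitals:
                raise ConfigurationError("orbital index out of range")
            key = (d.alpha_occ, d.beta_occ)
            if key in seen:
                raise ConfigurationError("duplicate determinant in expansion")
            seen.add(key)
        if sort:
            terms.sort(key=lambda t: (-abs(t[1]), t[0].alpha_occ, t[0].beta_occ))
        self.terms = terms
        self.orbitals = orbitals
        self.partition = partition
        self._tables = None

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.terms])

    def norm_squared(self) -> float:
        return float(np.sum(self.coefficients ** 2))

    # -- evaluation ------------------------------------------------------

    def _build_tables(self):
        """Distinct alpha/beta strings and per-term index maps."""
        astrings, bstrings = {}, {}
        ia, ib = [], []
        for d, _ in self.terms:
            ia.append(astrings.setdefault(d.alpha_occ, len(astrings)))
            ib.append(bstrings.setdefault(d.beta_occ, len(bstrings)))
        self._tables = (
            [np.array(s, dtype=int) for s in astrings],
            [np.array(s, dtype=int) for s in bstrings],
            np.array(ia, dtype=int), np.array(ib, dtype=int),
        )

    def mo_cache(self, X: np.ndarray) -> np.ndarray:
        """Orbital-value matrices for a batch (W, N, 3) -> (W, N, norb).

        Row e of a walker's matrix depends only on electron e's position,
        so single-electron moves can update one row via
        ``orbitals.evaluate`` and re-use the rest.
        """
        X = np.asarray(X, dtype=float)
        n = self.partition.n_electrons
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (n, 3):
            raise ValueError(f"expected (..., {n}, 3) configuration batch")
        W = X.shape[0]
        return self.orbitals.evaluate(X.reshape(W * n, 3)).reshape(W, n, -1)

    def value_from_cache(self, mo: np.ndarray) -> np.ndarray:
        """Psi from cached orbital-value matrices (W, N, norb) -> (W,)."""
        na, nb = self.partition.n_alpha, self.partition.n_beta
        W = mo.shape[0]
        if self._tables is None:
            self._build_tables()
        astr, bstr, ia, ib = self._tables
        mo_a, mo_b = mo[:, :na, :], mo[:, na:, :]
        if na:
            det_a = np.stack(
                [np.linalg.det(mo_a[:, :, occ]) for occ in astr], axis=1)
        else:
            det_a = np.ones((W, max(len(astr), 1)))
        if nb:
            det_b = np.stack(
                [np.linalg.det(mo_b[:, :, occ]) for occ in bstr], axis=1)
        else:
            det_b = np.ones((W, max(len(bstr), 1)))
        c = self.coefficients
        return (det_a[:, ia] * det_b[:, ib]) @ c

    def value_batch(self, X: np.ndarray) -> np.ndarray:
        """Psi at a batch of configuration points, shape (W, N, 3) -> (W,)."""
        return self.value_from_cache(self.mo_cache(X))

    def value(self, x) -> float:
        """Psi at one configuration point (flat 3N or (N,3))."""
        arr = as_config_array(x, self.partition)
        return float(self.value_batch(arr[None])[0])

    # -- truncation ------------------------------------------------------

    def degenerate_groups(self, tol: float = 1e-6) -> list[tuple[int, int]]:
        """(start, stop) index ranges of |c_i|-degenerate groups, in order.

        Consecutive terms whose |c_i| differ by less than ``tol`` belong to
        the same group and are only ever truncated as a set.
        """
        c = np.abs(self.coefficients)
        groups = []
        start = 0
        for i in range(1, len(c) + 1):
            if i == len(c) or abs(c[i] - c[i - 1]) > tol:
                groups.append((start, i))
                start = i
        return groups

    def truncate(self, n_configs: int, tol: float = 1e-6) -> "CIExpansion":
        """Leading ``n_configs`` terms by |c_i|; a group of terms degenerate
        in |c_i| is kept or dropped as a whole, so the result may hold more
        than ``n_configs`` terms. Coefficients are not renormalized."""
        if n_configs < 1:
            raise ValueError("n_configs must be >= 1")
        if n_configs >= len(self.terms):
            return self
        stop = n_configs
        for lo, hi in self.degenerate_groups(tol):
            if lo < n_configs <= hi:
                stop = hi
                break
        return CIExpansion(self.terms[:stop], self.orbitals, self.partition,
                           sort=False)

    def scaled(self, factor: float) -> "CIExpansion":
        if factor == 0:
            raise ValueError("zero scale factor")
        return CIExpansion([(d, c * factor) for d, c in self.terms],
                           self.orbitals, self.partition, sort=False)


def completeness(full: CIExpansion, truncated: CIExpansion) -> float:
    """Cumulative squared-coefficient weight of ``truncated`` relative to the
    normalized ``full`` expansion (fraction in [0, 1])."""
    keys = {(d.alpha_occ, d.beta_occ): c for d, c in full.terms}
    acc = 0.0
    for d, c in truncated.terms:
        key = (d.alpha_occ, d.beta_occ)
        if key not in keys:
            raise ValueError("truncated term absent from full expansion")
        acc += keys[key] ** 2
    return acc / full.norm_squared()


def eval_orbitals(orbitals, point) -> np.ndarray:
    """Values of every orbital at a single 3-vector point."""
    pt = np.asarray(point, dtype=float).reshape(1, 3)
    return orbitals.evaluate(pt)[0]


def psi_value(ci: CIExpansion, x) -> float:
    """Signed wavefunction value at a configuration point."""
    return ci.value(x)
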