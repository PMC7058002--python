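"""File formats: Molden (geometry/basis/MOs), XYZ, and the CI-vector text
format.

Conventions
-----------
* Molden files are written/read with Cartesian d functions ([6D]); MO
  coefficients refer to AOs whose contracted components are individually
  normalized to unit self-overlap (see `dvms.wavefunction.AOBasis`).
* XYZ files are in angstrom; everything in memory is bohr.
* CI-vector files list one determinant per line as alpha and beta
  occupation strings over the active orbitals plus a coefficient; the
  coefficient sign convention is "orbitals in ascending index order" within
  each spin block. A header records the core (always doubly occupied)
  orbitals and the active orbital indices, as positions in the
  accompanying MO set.
"""
from __future__ import annotations

import numpy as np

from .wavefunction import (AOBasis, BOHR_PER_ANGSTROM, CIExpansion,
                           ConfigurationError, Geometry, Shell,
                           SpinDeterminant, SpinPartition)

_L_LETTER = {0: "s", 1: "p", 2: "d"}
_LETTER_L = {v: k for k, v in _L_LETTER.items()}


# ---------------------------------------------------------------- XYZ

def write_xyz(path, symbols, coords_bohr, comment=""):
    coords = np.asarray(coords_bohr, float) / BOHR_PER_ANGSTROM
    with open(path, "w") as f:
        f.write(f"{len(symbols)}\n{comment}\n")
        for s, (x, y, z) in zip(symbols, coords):
            f.write(f"{s:<4s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def read_xyz(path):
    """Returns (symbols, coords in bohr)."""
    with open(path) as f:
        n = int(f.readline())
        f.readline()
        symbols, coords = [], []
        for _ in range(n):
            parts = f.readline().split()
            symbols.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
    return symbols, np.asarray(coords) * BOHR_PER_ANGSTROM


# ---------------------------------------------------------------- Molden

def write_molden(path, geometry: Geometry, basis: AOBasis,
                 coefficients: np.ndarray, energies, occupations,
                 labels=None, title="dvms"):
    """Minimal Molden writer (restricted orbitals, Cartesian d)."""
    coefficients = np.asarray(coefficients, float)
    with open(path, "w") as f:
        f.write("[Molden Format]\n[Title]\n" + title + "\n")
        f.write("[Atoms] AU\n")
        for i, (sym, xyz) in enumerate(zip(geometry.symbols,
                                           geometry.coords)):
            q = int(geometry.charges[i])
            f.write(f"{sym:<3s} {i+1:4d} {q:3d} "
                    f"{xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}\n")
        f.write("[GTO]\n")
        by_atom = {}
        for sh in basis.shells:
            by_atom.setdefault(sh.center, []).append(sh)
        for ia in range(geometry.natom):
            f.write(f"{ia+1} 0\n")
            for sh in by_atom.get(ia, []):
                f.write(f" {_L_LETTER[sh.l]} {len(sh.exponents)} 1.00\n")
                for a, c in zip(sh.exponents, sh.coefficients):
                    f.write(f"  {a:18.10E} {c:18.10E}\n")
            f.write("\n")
        f.write("[6D]\n[MO]\n")
        nmo = coefficients.shape[1]
        for m in range(nmo):
            lab = labels[m] if labels is not None else f"mo{m}"
            f.write(f" Sym= {lab}\n Ene= {energies[m]:.8f}\n"
                    f" Spin= Alpha\n Occup= {occupations[m]:.2f}\n")
            for mu in range(coefficients.shape[0]):
                f.write(f" {mu+1:3d} {coefficients[mu, m]: .8E}\n")


def read_molden(path):
    """Parse a Molden file (restricted, Cartesian d only).

    Returns (Geometry, AOBasis, coefficients (nao, nmo), energies,
    occupations, labels).
    """
    with open(path) as f:
        lines = f.read().splitlines()
    sections = {}
    current = None
    for ln in lines:
        stripped = ln.strip()
        if stripped.startswith("["):
            current = stripped.split("]")[0][1:].lower()
            sections.setdefault(current, [])
            rest = stripped.split("]", 1)[1].strip()
            if rest:
                sections[current].append(rest)
        elif current is not None:
            sections[current].append(ln)
    if "5d" in sections or "7f" in sections:
        raise ConfigurationError("only Cartesian ([6D]) shells are supported")
    # atoms
    atom_lines = [ln for ln in sections.get("atoms", []) if ln.split()]
    unit = "au"
    hdr = sections.get("atoms", [])
    if hdr and hdr[0].strip().lower().startswith(("angs", "au")):
        unit = hdr[0].strip().lower()
        atom_lines = atom_lines[1:] if atom_lines[0] == hdr[0] else atom_lines
    symbols, coords = [], []
    for ln in atom_lines:
        parts = ln.split()
        if len(parts) < 6:
            continue
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[3:6]])
    coords = np.asarray(coords)
    if unit.startswith("angs"):
        coords = coords * BOHR_PER_ANGSTROM
    geometry = Geometry(tuple(symbols), coords)
    # GTO
    shells = []
    it = iter([ln for ln in sections.get("gto", [])])
    atom_idx = None
    for ln in it:
        parts = ln.split()
        if not parts:
            atom_idx = None
            continue
        if atom_idx is None:
            atom_idx = int(parts[0]) - 1
            continue
        letter = parts[0].lower()
        if letter in _LETTER_L:
            nprim = int(parts[1])
            exps, coefs = [], []
            for _ in range(nprim):
                p = next(it).replace("D", "E").replace("d", "e").split()
                exps.append(float(p[0]))
                coefs.append(float(p[1]))
            shells.append(Shell(atom_idx, _LETTER_L[letter],
                                tuple(exps), tuple(coefs)))
        else:
            raise ConfigurationError(f"unsupported shell type {letter!r}")
    basis = AOBasis(tuple(shells))
    # MOs
    energies, occupations, labels, cols = [], [], [], []
    cur = None
    for ln in sections.get("mo", []):
        s = ln.strip()
        low = s.lower()
        if low.startswith("sym="):
            if cur is not None:
                cols.append(cur)
            labels.append(s.split("=", 1)[1].strip())
            cur = np.zeros(basis.n_ao)
        elif low.startswith("ene="):
            energies.append(float(s.split("=", 1)[1]))
        elif low.startswith("occup="):
            occupations.append(float(s.split("=", 1)[1]))
        elif low.startswith("spin="):
            continue
        elif s:
            parts = s.split()
            cur[int(parts[0]) - 1] = float(parts[1])
    if cur is not None:
        cols.append(cur)
    coefficients = np.column_stack(cols) if cols else np.zeros((basis.n_ao, 0))
    return (geometry, basis, coefficients, np.asarray(energies),
            np.asarray(occupations), labels)


# ---------------------------------------------------------------- CI vector

def write_civec(path, terms, core, active, n_alpha, n_beta,
                n_determinants_full, total_norm_squared=1.0, comment=""):
    """Write a CI-vector file.

    ``terms``: iterable of (alpha_string, beta_string, coefficient) with
    occupation strings over ``active`` (e.g. "110100"); ``core`` and
    ``active`` are orbital indices into the accompanying MO set.
    """
    terms = list(terms)
    stored = sum(c * c for _, _, c in terms)
    with open(path, "w") as f:
        f.write(f"# dvms CI vector. {comment}\n")
        f.write(f"norb {len(active)}\n")
        f.write(f"n_alpha {n_alpha}\nn_beta {n_beta}\n")
        f.write("core " + " ".join(map(str, core)) + "\n")
        f.write("active " + " ".join(map(str, active)) + "\n")
        f.write(f"n_terms {len(terms)}\n")
        f.write(f"n_determinants_full {n_determinants_full}\n")
        f.write(f"total_norm_squared {total_norm_squared:.12f}\n")
        f.write(f"stored_norm_squared {stored:.12f}\n")
        f.write("terms\n")
        for a, b, c in terms:
            f.write(f"{a} {b} {c: .12e}\n")


def read_civec(path):
    """Read a CI-vector file; returns a dict with header fields and a
    ``terms`` list of (alpha_string, beta_string, coefficient)."""
    head = {}
    terms = []
    with open(path) as f:
        in_terms = False
        for ln in f:
            s = ln.strip()
            if not s or s.startswith("#"):
                continue
            if s == "terms":
                in_terms = True
                continue
            if in_terms:
                a, b, c = s.split()
                terms.append((a, b, float(c)))
            else:
                key, _, val = s.partition(" ")
                head[key] = val
    out = {
        "norb": int(head["norb"]),
        "n_alpha": int(head["n_alpha"]),
        "n_beta": int(head["n_beta"]),
        "core": tuple(int(v) for v in head["core"].split()) if head["core"].strip() else (),
        "active": tuple(int(v) for v in head["active"].split()),
        "n_terms": int(head["n_terms"]),
        "n_determinants_full": int(head["n_determinants_full"]),
        "total_norm_squared": float(head["total_norm_squared"]),
        "stored_norm_squared": float(head["stored_norm_squared"]),
        "terms": terms,
    }
    if len(terms) != out["n_terms"]:
        raise ConfigurationError("term count does not match header")
    return out


def civec_to_expansion(civec: dict, orbitals) -> CIExpansion:
    """Build a CIExpansion from a parsed CI-vector file and an orbital set.

    Core orbitals are merged into every determinant; occupations are sorted
    ascending (matching the stored coefficient sign convention).
    """
    core = civec["core"]
    active = civec["active"]
    n_core = len(core)
    part = SpinPartition(civec["n_alpha"], civec["n_beta"])
    terms = []
    for a, b, c in civec["terms"]:
        aocc = tuple(sorted(core + tuple(active[i]
                                         for i, ch in enumerate(a)
                                         if ch == "1")))
        bocc = tuple(sorted(core + tuple(active[i]
                                         for i, ch in enumerate(b)
                                         if ch == "1")))
        if len(aocc) != part.n_alpha or len(bocc) != part.n_beta:
            raise ConfigurationError("occupation string/electron count "
                                     "mismatch")
        terms.append((SpinDeterminant(aocc, bocc), c))
    return CIExpansion(terms, orbitals, part)


# ---------------------------------------------------------------- sites

def write_site(path, site, comment=""):
    """Serialize a Voronoi site (restart point) as labelled text."""
    with open(path, "w") as f:
        f.write(f"# dvms Voronoi site. {comment}\n")
        f.write(f"label {site.label}\n")
        f.write(f"n_alpha {site.partition.n_alpha}\n")
        f.write(f"n_beta {site.partition.n_beta}\n")
        for spin, block in (("a", site.alpha), ("b", site.beta)):
            for (x, y, z) in block:
                f.write(f"{spin} {x: .12e} {y: .12e} {z: .12e}\n")


def read_site(path):
    from .fold import VoronoiSite
    label = ""
    na = nb = 0
    rows_a, rows_b = [], []
    with open(path) as f:
        for ln in f:
            s = ln.strip()
            if not s or s.startswith("#"):
                continue
            key, _, val = s.partition(" ")
            if key == "label":
                label = val
            elif key == "n_alpha":
                na = int(val)
            elif key == "n_beta":
                nb = int(val)
            elif key == "a":
                rows_a.append([float(v) for v in val.split()])
            elif key == "b":
                rows_b.append([float(v) for v in val.split()])
    if len(rows_a) != na or len(rows_b) != nb:
        raise ConfigurationError("site row count mismatch")
    pt = np.array(rows_a + rows_b, dtype=float)
    return VoronoiSite(pt, SpinPartition(na, nb), label)
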