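"""Real-space projections of a wavefunction tile.

A tile lives in 3N dimensions; to look at it we scan one electron over a
3-D grid while holding all other electrons at the Voronoi site, producing
a scalar field per electron (the signed wavefunction value). Fields are
exported in Gaussian cube format (bohr); site geometries as XYZ files with
pseudo-atom markers for the electron positions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fold import VoronoiSite
from .wavefunction import BOHR_PER_ANGSTROM, CIExpansion, Geometry

# pseudo-element tags for exported electron positions
ALPHA_TAG = "X"   # dummy-atom convention, alpha spin
BETA_TAG = "Xx"
_TAG_Z = {ALPHA_TAG: 0, BETA_TAG: 0}


@dataclass
class CrossSectionField:
    """Signed wavefunction values of one electron over a uniform grid."""

    origin: np.ndarray  # (3,), bohr
    axes: np.ndarray  # (3, 3): axes[i] = step vector along grid dim i
    values: np.ndarray  # (nx, ny, nz)
    electron_index: int

    @property
    def shape(self):
        return self.values.shape


def default_grid(center, side: float = 4.0, npts: int = 40):
    """Cubic grid spec centered on a point: (origin, axes, shape)."""
    center = np.asarray(center, float)
    step = side / (npts - 1)
    origin = center - side / 2.0
    axes = np.eye(3) * step
    return origin, axes, (npts, npts, npts)


def cross_section(ci: CIExpansion, site: VoronoiSite, electron_index: int,
                  origin=None, axes=None, shape=None) -> CrossSectionField:
    """Map the wavefunction in the dimensions of one electron, holding the
    others at the site."""
    n = ci.partition.n_electrons
    if not 0 <= electron_index < n:
        raise ValueError("electron index out of range")
    if origin is None:
        origin, axes, shape = default_grid(site.point[electron_index])
    origin = np.asarray(origin, float)
    axes = np.asarray(axes, float)
    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    pts = (origin[None, :]
           + ii.reshape(-1, 1) * axes[0]
           + jj.reshape(-1, 1) * axes[1]
           + kk.reshape(-1, 1) * axes[2])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    p = site.point[electron_index]
    if np.any(p < lo) or np.any(p > hi):
        import warnings
        warnings.warn("grid does not contain the electron's site position")
    X = np.repeat(site.point[None, :, :], pts.shape[0], axis=0)
    X[:, electron_index, :] = pts
    vals = np.empty(pts.shape[0])
    # evaluate in chunks to bound memory
    chunk = 8192
    for s in range(0, pts.shape[0], chunk):
        vals[s:s + chunk] = ci.value_batch(X[s:s + chunk])
    return CrossSectionField(origin=origin, axes=axes,
                             values=vals.reshape(nx, ny, nz),
                             electron_index=electron_index)


def write_cube(path, field: CrossSectionField, geometry: Geometry,
               comment="dvms cross-section"):
    """Gaussian cube file (bohr, z-fastest value ordering)."""
    v = field.values
    with open(path, "w") as f:
        f.write(comment + "\n")
        f.write(f"electron {field.electron_index}\n")
        ox, oy, oz = field.origin
        f.write(f"{geometry.natom:5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}\n")
        for i in range(3):
            ax = field.axes[i]
            f.write(f"{v.shape[i]:5d} {ax[0]:12.6f} {ax[1]:12.6f} "
                    f"{ax[2]:12.6f}\n")
        for q, xyz in zip(geometry.charges, geometry.coords):
            f.write(f"{int(q):5d} {q:12.6f} {xyz[0]:12.6f} {xyz[1]:12.6f} "
                    f"{xyz[2]:12.6f}\n")
        flat = v.reshape(v.shape[0] * v.shape[1], v.shape[2])
        for row in flat:
            for s in range(0, row.size, 6):
                f.write("".join(f"{x:13.5E}" for x in row[s:s + 6]) + "\n")


def read_cube(path):
    """Read a cube file written by `write_cube`; returns
    (CrossSectionField, symbols Z list, coords)."""
    with open(path) as f:
        f.readline()
        hdr2 = f.readline()
        parts = f.readline().split()
        natom = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]])
        shape = []
        axes = []
        for _ in range(3):
            parts = f.readline().split()
            shape.append(int(parts[0]))
            axes.append([float(x) for x in parts[1:4]])
        zs, coords = [], []
        for _ in range(natom):
            parts = f.readline().split()
            zs.append(int(parts[0]))
            coords.append([float(x) for x in parts[2:5]])
        data = np.array(f.read().split(), dtype=float)
    ei = int(hdr2.split()[-1]) if hdr2.split() else 0
    field = CrossSectionField(origin=origin, axes=np.array(axes),
                              values=data.reshape(shape),
                              electron_index=ei)
    return field, zs, np.array(coords)


def export_site_xyz(path, site: VoronoiSite, geometry: Geometry,
                    comment="dvms Voronoi site"):
    """XYZ file with the atoms plus pseudo-atoms at the alpha (tag 'X') and
    beta (tag 'Xx') electron positions; coordinates in angstrom."""
    syms = list(geometry.symbols)
    coords = [xyz for xyz in geometry.coords]
    for r in site.alpha:
        syms.append(ALPHA_TAG)
        coords.append(r)
    for r in site.beta:
        syms.append(BETA_TAG)
        coords.append(r)
    coords = np.array(coords) / BOHR_PER_ANGSTROM
    with open(path, "w") as f:
        f.write(f"{len(syms)}\n{comment}\n")
        for s, (x, y, z) in zip(syms, coords):
            f.write(f"{s:<4s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def read_site_xyz(path):
    """Inverse of `export_site_xyz`; returns (symbols, coords bohr,
    alpha positions, beta positions)."""
    with open(path) as f:
        n = int(f.readline())
        f.readline()
        syms, coords = [], []
        for _ in range(n):
            parts = f.readline().split()
            syms.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
    coords = np.asarray(coords) * BOHR_PER_ANGSTROM
    alpha = coords[[i for i, s in enumerate(syms) if s == ALPHA_TAG]]
    beta = coords[[i for i, s in enumerate(syms) if s == BETA_TAG]]
    atoms = [(s, c) for s, c in zip(syms, coords)
             if s not in (ALPHA_TAG, BETA_TAG)]
    return ([s for s, _ in atoms], np.array([c for _, c in atoms]),
            alpha, beta)
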