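"""Shared fixtures: toy systems and (session-cached) benzene wavefunctions."""
import itertools

import numpy as np
import pytest

from dvms import (load_benzene_ci, make_toy)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def triplet_toy():
    return make_toy("two_electron_triplet")


@pytest.fixture(scope="session")
def two_plus_two_toy():
    return make_toy("two_plus_two")


@pytest.fixture(scope="session")
def double_well_toy():
    return make_toy("double_well_ci")


@pytest.fixture(scope="session")
def benzene_rhf():
    return load_benzene_ci("rhf")


@pytest.fixture(scope="session")
def benzene_cas66():
    return load_benzene_ci("cas66")


@pytest.fixture(scope="session")
def benzene_cas3018():
    return load_benzene_ci("cas3018")


def brute_force_psi(ci, x):
    """Independent oracle: explicit antisymmetrized sum over all same-spin
    permutations with signs (viable for <= 3-4 electrons per spin)."""
    part = ci.partition
    x = np.asarray(x, float).reshape(part.n_electrons, 3)
    ra, rb = x[: part.n_alpha], x[part.n_alpha:]
    total = 0.0
    for det, c in ci.terms:
        da = _perm_det(ci.orbitals, det.alpha_occ, ra)
        db = _perm_det(ci.orbitals, det.beta_occ, rb)
        total += c * da * db
    return total


def _perm_det(orbitals, occ, r):
    n = len(occ)
    if n == 0:
        return 1.0
    vals = orbitals.evaluate(r)  # (n, norb)
    total = 0.0
    for perm in itertools.permutations(range(n)):
        sign = _perm_sign(perm)
        prod = 1.0
        for k in range(n):
            prod *= vals[perm[k], occ[k]]
        total += sign * prod
    return total


def _perm_sign(perm):
    perm = list(perm)
    sign = 1
    for i in range(len(perm)):
        for j in range(i + 1, len(perm)):
            if perm[i] > perm[j]:
                sign = -sign
    return sign
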