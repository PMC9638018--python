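"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from immetab.isotopes import NATURAL_ABUNDANCE


def brute_force_isotope_distribution(
    formula: dict[str, int],
    table: dict[str, dict[int, float]] | None = None,
) -> np.ndarray:
    """Exhaustive enumeration over every atom's isotope state.

    Independent of the convolution implementation: expands the full product
    space of per-atom (shift, probability) choices and accumulates the total
    probability of each summed mass shift.  Only feasible for small formulas
    (<= ~8 atoms), which is exactly its role as an oracle.
    """
    if table is None:
        table = NATURAL_ABUNDANCE
    atoms: list[list[tuple[int, float]]] = []
    for element, count in formula.items():
        for _ in range(int(count)):
            atoms.append(sorted(table[element].items()))
    if not atoms:
        return np.array([1.0])
    max_total = sum(max(s for s, _ in a) for a in atoms)
    out = np.zeros(max_total + 1)
    for combo in itertools.product(*atoms):
        shift = sum(s for s, _ in combo)
        prob = 1.0
        for _, p in combo:
            prob *= p
        out[shift] += prob
    return out


def brute_force_correction_matrix(
    formula: dict[str, int],
    n_tracer_positions: int,
    K: int,
    table: dict[str, dict[int, float]] | None = None,
) -> np.ndarray:
    """Correction matrix built from the enumeration oracle, column by column."""
    M = np.zeros((K + 1, n_tracer_positions + 1))
    for j in range(n_tracer_positions + 1):
        residual = dict(formula)
        residual["C"] = residual.get("C", 0) - j
        p = brute_force_isotope_distribution(residual, table)
        n_rows = min(len(p), K + 1 - j)
        if n_rows > 0:
            M[j : j + n_rows, j] = p[:n_rows]
    return M


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
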