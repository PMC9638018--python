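"""Natural-abundance correction of GC-MS mass isotopomer distributions.

Stable-isotope tracing experiments (e.g. cells fed fully ``13C``-labeled
succinate or glucose) are read out as isotopologue ion counts at mass shifts
m+0 ... m+K for a derivatized metabolite fragment.  The measured pattern is the
tracer-derived labeling convolved with the natural isotope pattern of *every*
atom in the fragment (including the TBDMS derivatization groups, whose silicon
contributes heavily).  This module builds the forward convolution matrix from
the fragment's elemental formula, inverts it by non-negative least squares, and
derives the usual summary quantities: the corrected mass isotopomer
distribution (MID), fractional enrichment, internal-standard-normalized
abundances, and labeled-species abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "NATURAL_ABUNDANCE",
    "FRAGMENT_FORMULAS",
    "IsotopologueSpectrum",
    "MID",
    "parse_formula",
    "natural_isotope_distribution",
    "build_correction_matrix",
    "correct_mid",
    "fractional_enrichment",
    "normalize_to_internal_standard",
    "labeled_abundance",
    "metabolite_ratio",
]

#: Natural fractional isotope abundances indexed by integer mass shift
#: relative to the lightest isotope (unit-mass resolution).  Standard IUPAC
#: representative values; users may supply their own table.
NATURAL_ABUNDANCE: dict[str, dict[int, float]] = {
    "H": {0: 0.999885, 1: 0.000115},
    "C": {0: 0.9893, 1: 0.0107},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "S": {0: 0.9499, 1: 0.0075, 2: 0.0425, 4: 0.0001},
    "Si": {0: 0.92223, 1: 0.04685, 2: 0.03092},
    "P": {0: 1.0},
    "F": {0: 1.0},
}

#: Default elemental formulas of the quantified TBDMS-derivatized fragments
#: ([M-57]+ ions, i.e. loss of the tert-butyl group).  The measured fragment is
#: instrument- and method-dependent, so every entry can be overridden.
#: Values are (formula, n carbon backbone positions that can carry tracer).
FRAGMENT_FORMULAS: dict[str, tuple[dict[str, int], int]] = {
    "succinate": ({"C": 12, "H": 25, "O": 4, "Si": 2}, 4),
    "fumarate": ({"C": 12, "H": 23, "O": 4, "Si": 2}, 4),
    "malate": ({"C": 18, "H": 39, "O": 5, "Si": 3}, 4),
    "citrate": ({"C": 26, "H": 55, "O": 7, "Si": 4}, 6),
    "aspartate": ({"C": 18, "H": 40, "N": 1, "O": 4, "Si": 3}, 4),
    "glutamate": ({"C": 19, "H": 42, "N": 1, "O": 4, "Si": 3}, 5),
    "alanine": ({"C": 11, "H": 26, "N": 1, "O": 2, "Si": 2}, 3),
    "lactate": ({"C": 11, "H": 25, "O": 3, "Si": 2}, 3),
}


def parse_formula(text: str) -> dict[str, int]:
    """Parse ``"C12H25O4Si2"`` into an element -> count map."""
    import re

    out: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
        if m.start() != pos or not m.group(0):
            break
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text) or not out:
        raise ValueError(f"cannot parse elemental formula {text!r}")
    return out


def _validate_abundance_table(table: dict[str, dict[int, float]]) -> None:
    for element, dist in table.items():
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"natural abundances for {element} sum to {total}, not 1"
            )
        if any(shift < 0 or shift != int(shift) for shift in dist):
            raise ValueError(f"mass shifts for {element} must be non-negative integers")


def _element_shift_distribution(
    element: str, n_atoms: int, table: dict[str, dict[int, float]]
) -> np.ndarray:
    """Mass-shift distribution of the sum over ``n_atoms`` iid atoms."""
    if element not in table:
        raise KeyError(f"unknown element symbol {element!r} in abundance table")
    dist = table[element]
    max_shift = max(dist)
    single = np.zeros(max_shift + 1)
    for shift, p in dist.items():
        single[int(shift)] = p
    out = np.array([1.0])
    for _ in range(n_atoms):
        out = np.convolve(out, single)
    return out


def natural_isotope_distribution(
    formula: dict[str, int],
    table: dict[str, dict[int, float]] | None = None,
    max_shift: int | None = None,
) -> np.ndarray:
    """Probability of each total mass shift from natural isotopes.

    Convolves per-element multinomial shift distributions over all atoms in
    ``formula``.  With ``max_shift`` the result is truncated (not
    renormalized); untruncated, it sums to 1.

    Parameters
    ----------
    formula
        Element symbol -> atom count.  An empty formula yields ``[1.0]``.
    table
        Natural-abundance table; defaults to :data:`NATURAL_ABUNDANCE`.
    max_shift
        Truncate the returned vector to length ``max_shift + 1``.
    """
    if table is None:
        table = NATURAL_ABUNDANCE
    _validate_abundance_table(table)
    if any(n < 0 or n != int(n) for n in formula.values()):
        raise ValueError("atom counts must be non-negative integers")
    out = np.array([1.0])
    for element, n_atoms in formula.items():
        if n_atoms:
            out = np.convolve(out, _element_shift_distribution(element, int(n_atoms), table))
    if max_shift is not None:
        if max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        padded = np.zeros(max_shift + 1)
        k = min(len(out), max_shift + 1)
        padded[:k] = out[:k]
        out = padded
    return out


def build_correction_matrix(
    formula: dict[str, int],
    n_tracer_positions: int,
    table: dict[str, dict[int, float]] | None = None,
    K: int | None = None,
    carbon_only: bool = False,
) -> np.ndarray:
    """Forward natural-abundance convolution matrix.

    Column ``j`` is the predicted measured mass-shift pattern when exactly
    ``j`` tracer-position carbons are heavy: the natural isotope distribution
    of the residual formula (all atoms minus the ``j`` fixed-heavy carbons)
    shifted up by ``j``.  Rows run over measured shifts 0..K.

    ``carbon_only=True`` restricts the correction to the carbon atoms of the
    fragment, mimicking legacy carbon-only correction schemes.
    """
    if n_tracer_positions < 0:
        raise ValueError("n_tracer_positions must be >= 0")
    n_carbons = int(formula.get("C", 0))
    if n_carbons < n_tracer_positions:
        raise ValueError(
            f"n_tracer_positions ({n_tracer_positions}) exceeds carbon count ({n_carbons})"
        )
    if K is None:
        K = n_tracer_positions
    if K < n_tracer_positions:
        raise ValueError("K must be >= n_tracer_positions")
    if carbon_only:
        base = {"C": n_carbons}
    else:
        base = dict(formula)
    M = np.zeros((K + 1, n_tracer_positions + 1))
    for j in range(n_tracer_positions + 1):
        residual = dict(base)
        residual["C"] = residual["C"] - j
        p = natural_isotope_distribution(residual, table)
        n_rows = min(len(p), K + 1 - j)
        if n_rows > 0:
            M[j : j + n_rows, j] = p[:n_rows]
    return M


@dataclass
class IsotopologueSpectrum:
    """Raw integrated ion counts for one metabolite fragment in one sample."""

    sample_id: str
    metabolite_id: str
    ion_counts: np.ndarray  # indexed by mass shift 0..K
    internal_standard_count: float = 1.0

    def __post_init__(self) -> None:
        self.ion_counts = np.asarray(self.ion_counts, dtype=float)
        if np.any(self.ion_counts < 0):
            raise ValueError("ion counts must be non-negative")
        if self.internal_standard_count <= 0:
            raise ValueError("internal standard count must be positive")


@dataclass
class MID:
    """Corrected fractional isotopologue abundances M0..Mn (sum to 1)."""

    sample_id: str
    metabolite_id: str
    fractions: np.ndarray
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < -1e-12):
            raise ValueError("MID fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("MID fractions must sum to 1")


def correct_mid(spectrum: IsotopologueSpectrum, matrix: np.ndarray) -> MID:
    """Deconvolve natural abundance from a measured isotopologue spectrum.

    Solves ``matrix @ x ~= counts`` by non-negative least squares and
    renormalizes ``x`` to sum to 1.  Negative isotopologue fractions are
    unphysical, which is why plain inversion is not used by default.
    """
    counts = spectrum.ion_counts
    matrix = np.asarray(matrix, dtype=float)
    if counts.shape[0] != matrix.shape[0]:
        raise ValueError(
            f"spectrum length {counts.shape[0]} does not match matrix rows {matrix.shape[0]}"
        )
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum: no signal to correct")
    if np.linalg.matrix_rank(matrix) < matrix.shape[1]:
        raise ValueError("rank-deficient correction matrix")
    x, rnorm = nnls(matrix, counts / total)
    s = x.sum()
    if s <= 0:
        raise ValueError("non-negative least squares returned an all-zero solution")
    return MID(spectrum.sample_id, spectrum.metabolite_id, x / s, residual=float(rnorm))


def fractional_enrichment(mid: MID | np.ndarray) -> float:
    """Average labeled fraction of tracer positions: sum(i * M_i) / n."""
    fractions = mid.fractions if isinstance(mid, MID) else np.asarray(mid, dtype=float)
    n = len(fractions) - 1
    if n == 0:
        return 0.0
    return float(np.dot(np.arange(len(fractions)), fractions) / n)


def normalize_to_internal_standard(ion_count: float, internal_standard_count: float) -> float:
    """Relative abundance: ion count / internal-standard ion count."""
    if internal_standard_count <= 0:
        raise ValueError("internal standard count must be positive")
    return ion_count / internal_standard_count


def labeled_abundance(mid: MID | np.ndarray, relative_abundance: float) -> np.ndarray:
    """Per-isotopologue relative abundances of the labeled species (M1..Mn).

    Returns ``M_i * relative_abundance`` for ``i >= 1``; the unlabeled M0
    species is excluded.
    """
    fractions = mid.fractions if isinstance(mid, MID) else np.asarray(mid, dtype=float)
    return fractions[1:] * relative_abundance


def total_labeled_abundance(mid: MID | np.ndarray, relative_abundance: float) -> float:
    """Summed abundance of all labeled isotopologues (alternative readout)."""
    return float(labeled_abundance(mid, relative_abundance).sum())


def metabolite_ratio(a: float, b: float) -> float:
    """Ratio of two relative abundances (e.g. succinate/malate)."""
    if b <= 0:
        raise ValueError("denominator abundance must be positive")
    return a / b
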