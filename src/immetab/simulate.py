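"""Ground-truth-labelled synthetic data for every pipeline stage.

Each generator draws from an explicit noise model with a seeded
``numpy.random.Generator``, returns both the synthetic observations and a
machine-readable truth record, and is byte-reproducible for a fixed scenario
and seed.  The default scenarios mirror the study designs the pipeline is
meant for: a fully 13C-labeled C4 succinate tracer, mitochondrial/glycolytic
stress-test traces with 3 measurement cycles per phase, and a two-group tumor
cohort of 18 vs 27 samples with a subset of IFN-gamma-response signature
genes shifted down in the mutant group.

Noise models (platform conventions; replicate-level variances are rarely
published): multiplicative log-normal noise on ion counts, additive Gaussian
noise on flux rates and ODs, and negative-binomial counts for RNA-seq.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotopes import FRAGMENT_FORMULAS, build_correction_matrix
from .elisa import four_pl

__all__ = [
    "TracerScenario",
    "FluxScenario",
    "CountScenario",
    "ElisaScenario",
    "gen_isotopologue_spectra",
    "gen_flux_trace",
    "gen_count_matrix",
    "gen_elisa_plate",
]


def _check_prob_vector(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{name} entries must be non-negative")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ValueError(f"{name} must sum to 1 (got {p.sum()!r})")
    return p


@dataclass
class TracerScenario:
    """Isotope-tracing simulation settings for one metabolite fragment.

    The default emulates cells grown on fully 13C-labeled succinate: most of
    the intracellular succinate pool is the m+4 isotopologue.
    """

    metabolite_id: str = "succinate"
    fragment_formula: dict[str, int] = field(
        default_factory=lambda: dict(FRAGMENT_FORMULAS["succinate"][0])
    )
    n_tracer_positions: int = 4
    true_mid: np.ndarray = field(
        default_factory=lambda: np.array([0.15, 0.03, 0.04, 0.08, 0.70])
    )
    ion_count_scale: float = 1e6
    noise_cv: float = 0.01
    internal_standard_count: float = 5e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracer_positions < 1:
            raise ValueError("n_tracer_positions must be >= 1")
        self.true_mid = _check_prob_vector(self.true_mid, "true_mid")
        if len(self.true_mid) != self.n_tracer_positions + 1:
            raise ValueError("true_mid must have length n_tracer_positions + 1")
        if self.ion_count_scale <= 0:
            raise ValueError("ion_count_scale must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def gen_isotopologue_spectra(
    scenario: TracerScenario, n_samples: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate isotopologue spectra plus the truth record.

    Each spectrum is ``ion_count_scale * (M @ true_mid)`` where ``M`` is the
    fragment's natural-abundance correction matrix, degraded by multiplicative
    log-normal noise with coefficient of variation ``noise_cv`` and truncated
    at zero.  Returns a long-format spectra table (sample, metabolite,
    mass_shift, ion_count, internal_standard_count) and a truth table holding
    the true MID and scale.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(scenario.seed)
    M = build_correction_matrix(
        scenario.fragment_formula, scenario.n_tracer_positions
    )
    expected = scenario.ion_count_scale * (M @ scenario.true_mid)
    if scenario.noise_cv > 0:
        sigma2 = np.log1p(scenario.noise_cv**2)
        mu = -sigma2 / 2.0
        noise = rng.lognormal(mu, np.sqrt(sigma2), size=(n_samples, len(expected)))
    else:
        noise = np.ones((n_samples, len(expected)))
    counts = np.clip(expected[None, :] * noise, 0.0, None)
    rows = []
    for i in range(n_samples):
        for k in range(len(expected)):
            rows.append(
                {
                    "sample": f"s{i:03d}",
                    "metabolite": scenario.metabolite_id,
                    "mass_shift": k,
                    "ion_count": counts[i, k],
                    "internal_standard_count": scenario.internal_standard_count,
                }
            )
    spectra = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "metabolite": scenario.metabolite_id,
            "mass_shift": np.arange(len(scenario.true_mid)),
            "true_mid": scenario.true_mid,
            "ion_count_scale": scenario.ion_count_scale,
            "noise_cv": scenario.noise_cv,
        }
    )
    return spectra, truth


#: Default stress-test phase means: (OCR pmol/min, ECAR mpH/min) per phase,
#: in injection order.  Combined protocol with a glucose injection so that
#: both ATP-coupled OCR and basal glycolysis are defined.
DEFAULT_PHASE_MEANS: dict[str, tuple[float, float]] = {
    "basal": (100.0, 15.0),
    "glucose": (105.0, 60.0),
    "oligomycin": (40.0, 80.0),
    "bam15": (160.0, 70.0),
    "rotenone_antimycin": (15.0, 40.0),
}

#: Injection that starts each non-basal phase.
PHASE_INJECTIONS = {
    "glucose": "glucose",
    "oligomycin": "oligomycin",
    "bam15": "bam15",
    "rotenone_antimycin": "rotenone_antimycin",
}


@dataclass
class FluxScenario:
    """Extracellular-flux trace simulation settings for one well."""

    phase_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_MEANS)
    )
    cycles_per_phase: int = 3
    noise_sd: float = 0.0
    well: str = "A1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles_per_phase < 1:
            raise ValueError("cycles_per_phase must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for phase, (ocr, ecar) in self.phase_means.items():
            if ocr < 0 or ecar < 0:
                raise ValueError(f"phase {phase!r} means must be non-negative")


def gen_flux_trace(scenario: FluxScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one well's flux trace plus the truth record.

    Emits ``cycles_per_phase`` measurement cycles per phase with additive
    Gaussian noise, annotating the injection that starts each post-basal
    phase on its first cycle.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = []
    cycle = 1
    for phase, (ocr_mean, ecar_mean) in scenario.phase_means.items():
        for i in range(scenario.cycles_per_phase):
            rows.append(
                {
                    "well": scenario.well,
                    "cycle_index": cycle,
                    "phase": phase,
                    "injection": PHASE_INJECTIONS.get(phase, "") if i == 0 else "",
                    "ocr": ocr_mean + rng.normal(0.0, scenario.noise_sd)
                    if scenario.noise_sd
                    else ocr_mean,
                    "ecar": ecar_mean + rng.normal(0.0, scenario.noise_sd)
                    if scenario.noise_sd
                    else ecar_mean,
                }
            )
            cycle += 1
    trace = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            {"phase": phase, "true_ocr": ocr, "true_ecar": ecar, "noise_sd": scenario.noise_sd}
            for phase, (ocr, ecar) in scenario.phase_means.items()
        ]
    )
    return trace, truth


@dataclass
class CountScenario:
    """Two-group RNA-seq count-matrix simulation settings.

    Defaults emulate the tumor cohort the signature score is applied to:
    18 SDH-mutant vs 27 other samples, negative-binomial counts, and the
    signature genes shifted down 2-fold (log2_effect = -1) in group 1.
    """

    n_genes: int = 2000
    group_sizes: tuple[int, int] = (18, 27)
    n_signature_genes: int = 45
    log2_effect: float = -1.0
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.1
    group_labels: tuple[str, str] = ("SDHB_D", "other")
    seed: int = 0

    def __post_init__(self) -> None:
        for n in self.group_sizes:
            if not isinstance(n, (int, np.integer)) or n <= 0:
                raise ValueError("group sizes must be positive integers")
        if self.n_signature_genes > self.n_genes:
            raise ValueError("more signature genes than genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def signature_gene_ids(self) -> list[str]:
        return [f"IFNG_RESP_{i:03d}" for i in range(self.n_signature_genes)]


def gen_count_matrix(
    scenario: CountScenario,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate an HTSeq-style count matrix plus group labels and truth.

    Counts are negative binomial with gene-wise means drawn log-normally;
    signature genes in group 1 have their mean multiplied by
    ``2**log2_effect``.  Returns (counts gene x sample, group labels,
    truth table of per-gene baseline means and effects).
    """
    rng = np.random.default_rng(scenario.seed)
    n1, n2 = scenario.group_sizes
    sig_ids = scenario.signature_gene_ids
    gene_ids = sig_ids + [f"GENE_{i:05d}" for i in range(scenario.n_genes - len(sig_ids))]
    sample_ids = [f"T{i:03d}" for i in range(n1 + n2)]
    groups = pd.Series(
        [scenario.group_labels[0]] * n1 + [scenario.group_labels[1]] * n2,
        index=pd.Index(sample_ids, name="sample"),
        name="group",
    )
    base_mean = 2.0 ** rng.normal(
        scenario.baseline_log2_mean, scenario.baseline_log2_sd, size=scenario.n_genes
    )
    effect = np.ones(scenario.n_genes)
    effect[: len(sig_ids)] = 2.0**scenario.log2_effect
    mu = np.tile(base_mean[:, None], (1, n1 + n2))
    mu[:, :n1] *= effect[:, None]
    # NB parameterized by mean mu and dispersion alpha: var = mu + alpha mu^2
    r = 1.0 / scenario.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    matrix = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    matrix.index.name = "gene_id"
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline_mean": base_mean,
            "log2_effect_group1": np.where(effect != 1.0, scenario.log2_effect, 0.0),
            "is_signature": [g in set(sig_ids) for g in gene_ids],
        }
    )
    return matrix, groups, truth


@dataclass
class ElisaScenario:
    """Synthetic ELISA plate: 4PL standards plus unknown wells."""

    a: float = 0.05  # OD at zero concentration
    b: float = 1.2  # Hill slope (positive: OD rises from a toward d)
    c: float = 250.0  # inflection concentration, pg/mL
    d: float = 3.2  # saturating OD
    standard_concs: np.ndarray = field(
        default_factory=lambda: 2000.0 / 2.0 ** np.arange(8)
    )
    true_concentrations: np.ndarray = field(
        default_factory=lambda: np.array([50.0, 120.0, 300.0, 700.0])
    )
    input_cell_counts: np.ndarray | None = None
    viability_fractions: np.ndarray | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("inflection concentration c must be positive")
        if self.b == 0:
            raise ValueError("slope b must be nonzero")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.standard_concs = np.asarray(self.standard_concs, dtype=float)
        self.true_concentrations = np.asarray(self.true_concentrations, dtype=float)
        n = len(self.true_concentrations)
        if self.input_cell_counts is None:
            self.input_cell_counts = np.full(n, 200_000.0)
        if self.viability_fractions is None:
            self.viability_fractions = np.ones(n)


def gen_elisa_plate(scenario: ElisaScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a plate of standards and unknowns plus the truth record.

    OD = 4PL(concentration) + Gaussian(noise_sd).  Standards carry their
    nominal concentration; unknown wells carry cell counts and viability so
    the full interpolate-and-correct path can be exercised.
    """
    rng = np.random.default_rng(scenario.seed)

    def od(conc: np.ndarray) -> np.ndarray:
        clean = four_pl(conc, scenario.a, scenario.b, scenario.c, scenario.d)
        if scenario.noise_sd:
            return clean + rng.normal(0.0, scenario.noise_sd, size=np.shape(clean))
        return np.asarray(clean)

    rows = []
    for i, conc in enumerate(scenario.standard_concs):
        rows.append(
            {
                "well": f"STD{i + 1}",
                "role": "standard",
                "known_concentration": conc,
                "od": float(od(np.array([conc]))[0]),
                "input_cell_count": np.nan,
                "viability_fraction": np.nan,
            }
        )
    for i, conc in enumerate(scenario.true_concentrations):
        rows.append(
            {
                "well": f"U{i + 1}",
                "role": "unknown",
                "known_concentration": np.nan,
                "od": float(od(np.array([conc]))[0]),
                "input_cell_count": float(scenario.input_cell_counts[i]),
                "viability_fraction": float(scenario.viability_fractions[i]),
            }
        )
    plate = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "well": [f"U{i + 1}" for i in range(len(scenario.true_concentrations))],
            "true_concentration": scenario.true_concentrations,
            "a": scenario.a,
            "b": scenario.b,
            "c": scenario.c,
            "d": scenario.d,
        }
    )
    return plate, truth
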