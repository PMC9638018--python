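"""Bioenergetic metrics from extracellular-flux (Seahorse-type) traces.

A trace is an ordered series of measurement cycles per well, each with an
oxygen consumption rate (OCR, pmol O2/min) and extracellular acidification
rate (ECAR, mpH/min), punctuated by injections of metabolic perturbants
(glucose, the ATP-synthase inhibitor oligomycin, an uncoupler such as Bam-15,
and rotenone/antimycin A).  The derived metrics follow the standard
mitochondrial/glycolytic stress-test arithmetic:

* ATP-coupled OCR = mean of the 3 cycles before oligomycin minus the mean of
  the 3 cycles after it (the respiration abolished by blocking ATP synthase).
* Basal glycolysis = mean of the 3 cycles after glucose minus the mean of the
  3 cycles before it.
* ATP production rates re-derive the published rate equations with every
  constant exposed (vendor software keeps them internal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FluxTrace",
    "AtpRateConstants",
    "atp_coupled_ocr",
    "basal_glycolysis",
    "ocr_ecar_ratio",
    "atp_rates",
    "summarize_wells",
]


@dataclass
class FluxTrace:
    """Ordered OCR/ECAR measurement cycles for one well.

    ``cycles`` columns: cycle_index, phase, ocr, ecar.  ``injections`` maps a
    compound name to the cycle index *before* which it was injected (i.e. the
    first cycle of the post-injection phase).
    """

    well: str
    cycles: pd.DataFrame
    injections: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"cycle_index", "phase", "ocr", "ecar"}
        missing = required - set(self.cycles.columns)
        if missing:
            raise ValueError(f"flux trace missing columns: {sorted(missing)}")
        idx = self.cycles["cycle_index"].to_numpy()
        if len(idx) and not np.all(np.diff(idx) > 0):
            raise ValueError("measurement cycles must be strictly ordered")

    def _window(self, injection: str, window: int) -> tuple[np.ndarray, np.ndarray]:
        if injection not in self.injections:
            raise ValueError(
                f"no {injection!r} injection annotated on well {self.well!r}"
            )
        at = self.injections[injection]
        idx = self.cycles["cycle_index"].to_numpy()
        pre = self.cycles.loc[idx < at]
        post = self.cycles.loc[idx >= at]
        if len(pre) < window or len(post) < window:
            raise ValueError(
                f"need >= {window} cycles on each side of the {injection} injection"
            )
        return pre.tail(window).to_records(), post.head(window).to_records()

    def pre_post_means(
        self, injection: str, channel: str, window: int = 3
    ) -> tuple[float, float]:
        """Mean of the ``window`` cycles immediately before / after an injection."""
        pre, post = self._window(injection, window)
        return float(np.mean(pre[channel])), float(np.mean(post[channel]))

    def phase_mean(self, phase: str, channel: str) -> float:
        sel = self.cycles.loc[self.cycles["phase"] == phase, channel]
        if sel.empty:
            raise ValueError(f"phase {phase!r} absent from well {self.well!r}")
        return float(sel.mean())


@dataclass
class AtpRateConstants:
    """Constants of the ATP production-rate equations.

    po_ratio
        ATP synthesized per O atom reduced (default 2.75, the standard value
        for oxidative phosphorylation fueled by mixed substrates).
    oxygen_atoms_per_o2
        2 O atoms per O2 consumed.
    ecar_to_per
        Converts ECAR (mpH/min) to a proton efflux rate (pmol H+/min); equals
        the buffer factor x chamber volume x instrument Kvol. Default 1.0 (a
        configured buffer factor is required for absolute glycolytic rates).
    mito_acidification_factor
        pmol H+ per pmol mitochondrial O consumption attributable to CO2-derived
        acidification (default 0.61).
    atp_per_lactate_h
        ATP per glycolytic proton exported (1 for glucose -> lactate).
    """

    po_ratio: float = 2.75
    oxygen_atoms_per_o2: float = 2.0
    ecar_to_per: float = 1.0
    mito_acidification_factor: float = 0.61
    atp_per_lactate_h: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "po_ratio",
            "oxygen_atoms_per_o2",
            "ecar_to_per",
            "atp_per_lactate_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mito_acidification_factor < 0:
            raise ValueError("mito_acidification_factor must be non-negative")


def atp_coupled_ocr(trace: FluxTrace, window: int = 3) -> float:
    """Oligomycin-sensitive respiration.

    Mean of the ``window`` OCR cycles before the oligomycin injection minus the
    mean of the ``window`` cycles after it.
    """
    pre, post = trace.pre_post_means("oligomycin", "ocr", window)
    return pre - post


def basal_glycolysis(trace: FluxTrace, window: int = 3) -> float:
    """Glucose-stimulated acidification.

    Mean of the ``window`` ECAR cycles after the glucose injection minus the
    mean of the ``window`` cycles before it.  Traces run without a glucose
    injection (perturbation-only protocol) raise rather than guess.
    """
    pre, post = trace.pre_post_means("glucose", "ecar", window)
    return post - pre


def ocr_ecar_ratio(coupled_ocr: float, glycolysis: float) -> float:
    """ATP-coupled OCR / basal glycolysis (oxidative vs glycolytic balance)."""
    if glycolysis <= 0:
        raise ValueError("basal glycolysis must be positive to form the ratio")
    return coupled_ocr / glycolysis


def atp_rates(
    trace: FluxTrace,
    constants: AtpRateConstants | None = None,
    window: int = 3,
) -> dict[str, float]:
    """Mitochondrial, glycolytic and total ATP synthesis rates (pmol ATP/min).

    mito_atp = ATP-coupled OCR x O atoms per O2 x P/O ratio.
    glyco_atp = (basal ECAR x ecar_to_per
                 - mito_acidification_factor x (basal OCR - post-rot/AA OCR))
                x atp_per_lactate_h.
    total_atp = mito_atp + glyco_atp.
    """
    if constants is None:
        constants = AtpRateConstants()
    coupled = atp_coupled_ocr(trace, window)
    ocr_basal, _ = trace.pre_post_means("oligomycin", "ocr", window)
    ecar_basal, _ = trace.pre_post_means("oligomycin", "ecar", window)
    _, ocr_rot_aa = trace.pre_post_means("rotenone_antimycin", "ocr", window)
    mito_atp = coupled * constants.oxygen_atoms_per_o2 * constants.po_ratio
    glyco_per = ecar_basal * constants.ecar_to_per - constants.mito_acidification_factor * (
        ocr_basal - ocr_rot_aa
    )
    glyco_atp = glyco_per * constants.atp_per_lactate_h
    return {
        "mito_atp": mito_atp,
        "glyco_atp": glyco_atp,
        "total_atp": mito_atp + glyco_atp,
    }


def traces_from_table(table: pd.DataFrame) -> list[FluxTrace]:
    """Split a long-format flux table (well, cycle_index, phase, injection,
    ocr, ecar) into per-well :class:`FluxTrace` objects.

    The ``injection`` column names the compound injected immediately before
    that cycle (empty/NaN otherwise).
    """
    traces = []
    for well, sub in table.groupby("well", sort=True):
        sub = sub.sort_values("cycle_index").reset_index(drop=True)
        injections: dict[str, int] = {}
        if "injection" in sub.columns:
            for _, row in sub.iterrows():
                inj = row["injection"]
                if isinstance(inj, str) and inj:
                    injections[inj] = int(row["cycle_index"])
        traces.append(
            FluxTrace(
                well=str(well),
                cycles=sub[["cycle_index", "phase", "ocr", "ecar"]],
                injections=injections,
            )
        )
    return traces


def summarize_wells(
    traces: list[FluxTrace],
    constants: AtpRateConstants | None = None,
    window: int = 3,
) -> pd.DataFrame:
    """Per-well metric table; aggregation across replicate wells is left to
    the caller as an explicit step."""
    rows = []
    for trace in traces:
        row: dict[str, object] = {"well": trace.well}
        row["atp_coupled_ocr"] = atp_coupled_ocr(trace, window)
        try:
            row["basal_glycolysis"] = basal_glycolysis(trace, window)
            row["ocr_ecar_ratio"] = ocr_ecar_ratio(
                row["atp_coupled_ocr"], row["basal_glycolysis"]
            )
        except ValueError:
            row["basal_glycolysis"] = np.nan
            row["ocr_ecar_ratio"] = np.nan
        try:
            row.update(atp_rates(trace, constants, window))
        except ValueError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)
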