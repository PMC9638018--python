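"""Readers and writers for the pipeline's plain-text table schemas.

All tables are TSV (CSV for ELISA plates, matching plate-reader exports) with
fixed column sets so that every stage's inputs and outputs are diffable and
versionable.  Floats are written with a stable general format so that runs
with identical inputs and seeds are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .isotopes import IsotopologueSpectrum

FLOAT_FORMAT = "%.10g"

SPECTRA_COLUMNS = ["sample", "metabolite", "mass_shift", "ion_count", "internal_standard_count"]
FLUX_COLUMNS = ["well", "cycle_index", "phase", "injection", "ocr", "ecar"]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_csv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=",", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_spectra_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SPECTRA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spectra table {path} missing columns: {sorted(missing)}")
    return df


def spectra_from_table(table: pd.DataFrame) -> list[IsotopologueSpectrum]:
    """Group a long-format spectra table into per-(sample, metabolite) objects."""
    out = []
    for (sample, metabolite), sub in table.groupby(["sample", "metabolite"], sort=True):
        sub = sub.sort_values("mass_shift")
        shifts = sub["mass_shift"].to_numpy()
        if not np.array_equal(shifts, np.arange(len(shifts))):
            raise ValueError(
                f"mass shifts for {sample}/{metabolite} must be contiguous from 0"
            )
        out.append(
            IsotopologueSpectrum(
                sample_id=str(sample),
                metabolite_id=str(metabolite),
                ion_counts=sub["ion_count"].to_numpy(dtype=float),
                internal_standard_count=float(sub["internal_standard_count"].iloc[0]),
            )
        )
    return out


def read_flux_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""], comment="#")
    missing = set(FLUX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"flux table {path} missing columns: {sorted(missing)}")
    df["injection"] = df["injection"].fillna("").astype(str)
    return df


def read_counts_tsv(path) -> pd.DataFrame:
    """HTSeq-style layout: gene-id column followed by one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if (df.dtypes == object).any():
        raise ValueError(f"count matrix {path} contains non-numeric columns")
    return df


def read_groups_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(f"group table {path} needs 'sample' and 'group' columns")
    return df.set_index("sample")["group"]


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"well", "role", "od"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table {path} missing columns: {sorted(missing)}")
    return df


def read_formula_tsv(path) -> dict[str, tuple[dict[str, int], int]]:
    """metabolite -> (fragment formula, n tracer positions) override table.

    Columns: metabolite, formula (e.g. C12H25O4Si2), n_tracer_positions.
    """
    from .isotopes import parse_formula

    df = pd.read_csv(path, sep="\t")
    required = {"metabolite", "formula", "n_tracer_positions"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"formula table {path} missing columns: {sorted(missing)}")
    return {
        str(r["metabolite"]): (parse_formula(str(r["formula"])), int(r["n_tracer_positions"]))
        for _, r in df.iterrows()
    }


def read_abundance_tsv(path) -> dict[str, dict[int, float]]:
    """element, mass_shift, abundance rows -> natural-abundance table."""
    df = pd.read_csv(path, sep="\t")
    required = {"element", "mass_shift", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"abundance table {path} missing columns: {sorted(missing)}")
    table: dict[str, dict[int, float]] = {}
    for _, r in df.iterrows():
        table.setdefault(str(r["element"]), {})[int(r["mass_shift"])] = float(r["abundance"])
    return table
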