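"""Dataset tables, readers/writers and quality-control filters.

Datasets are long-format CSV: one row per (complex, a_HF) with the complex
identified by metal, oxidation state and equatorial/axial ligand names from
the ligand library. Property columns (splitting, minimum metal-ligand bond
lengths) and QC columns (spin-contamination deviation, geometry status) are
optional; missing values stay explicit as empty cells / NaN.

QC mirrors the data-set construction rules: structures are excluded when
the <s^2> expectation deviates by more than 1 from the exact value for the
targeted multiplicity, when a ligand dissociated in either spin state, or
when no stable minimum was found.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .analysis import fit_sensitivity
from .complexes import ComplexSpec, validate_complex
from .ligands import LigandLibrary, load_ligand_library

__all__ = [
    "DatasetTable",
    "DatasetError",
    "read_dataset",
    "apply_qc_filters",
    "QCReport",
    "extract_target",
]

#: Columns identifying one (complex, a_HF) observation.
KEY_COLUMNS = ["metal", "oxidation", "eq_ligand", "ax_ligand", "a_hf"]
PROPERTY_COLUMNS = ["delta_e_hl", "min_r_ls", "min_r_hs"]
QC_COLUMNS = ["s2_deviation", "geometry_status"]

#: Maximum tolerated <s^2> deviation from the exact value.
S2_DEVIATION_LIMIT = 1.0


class DatasetError(ValueError):
    """Malformed or invalid dataset content."""


@dataclass
class DatasetTable:
    """Validated long-format property table plus the ligand library resolving it."""

    df: pd.DataFrame
    library: LigandLibrary = field(default_factory=load_ligand_library)

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLUMNS if c not in self.df.columns]
        if missing:
            raise DatasetError(f"dataset lacks required columns: {missing}")
        problems: list[str] = []
        for line, row in enumerate(self.df.itertuples(index=False), start=2):
            try:
                spec = self._row_spec(row._asdict())
            except (KeyError, ValueError) as exc:
                problems.append(f"line {line}: {exc}")
                continue
            report = validate_complex(spec)
            if not report.ok:
                problems.extend(f"line {line}: {m}" for m in report.messages)
        if problems:
            raise DatasetError("invalid dataset rows:\n" + "\n".join(problems[:20]))
        dup = self.df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            lines = (self.df.index[dup] + 2).tolist()
            raise DatasetError(f"duplicate (complex, a_HF) keys at lines {lines}")
        self.df = self.df.reset_index(drop=True)

    def _row_spec(self, row: dict) -> ComplexSpec:
        return ComplexSpec(
            metal=str(row["metal"]),
            oxidation=int(row["oxidation"]),
            eq_ligand=self.library[str(row["eq_ligand"])],
            ax_ligand=self.library[str(row["ax_ligand"])],
            a_hf=float(row["a_hf"]),
        )

    def specs(self) -> list[ComplexSpec]:
        """One ComplexSpec per row (carrying that row's a_HF)."""
        return [self._row_spec(dict(r)) for _, r in self.df.iterrows()]

    def __len__(self) -> int:
        return len(self.df)

    def write(self, path: str) -> None:
        self.df.to_csv(path, index=False)


def read_dataset(path: str, library: LigandLibrary | None = None) -> DatasetTable:
    """Read and validate a long-format dataset CSV.

    Bad rows (unknown ligands or metals, malformed numbers, duplicate keys)
    are reported with their line numbers.
    """
    library = library or load_ligand_library()
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, ValueError) as exc:
        raise DatasetError(f"could not parse {path}: {exc}") from exc
    for col in ("oxidation",):
        if col in df.columns and not np.issubdtype(df[col].dtype, np.integer):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()] + 2
            if len(bad):
                raise DatasetError(f"non-numeric {col!r} at lines {bad.tolist()}")
            df[col] = df[col].astype(int)
    return DatasetTable(df=df, library=library)


@dataclass
class QCReport:
    total_rows: int
    excluded: dict[str, int]
    kept_rows: int

    @property
    def total_excluded(self) -> int:
        return sum(self.excluded.values())


def apply_qc_filters(table: DatasetTable) -> tuple[DatasetTable, QCReport]:
    """Drop spin-contaminated, dissociated and unconverged rows.

    Rows with an <s^2> deviation above 1 are excluded as spin-contaminated;
    geometry status values ``"dissociated"`` and ``"unconverged"`` mark the
    other two categories. Missing QC columns pass with a warning. Categories
    are counted in order (spin contamination first), so each excluded row is
    attributed to exactly one category.
    """
    df = table.df
    excluded = {"spin_contamination": 0, "dissociated": 0, "unconverged": 0}
    drop = np.zeros(len(df), dtype=bool)
    if "s2_deviation" in df.columns:
        bad = df["s2_deviation"].to_numpy(dtype=float) > S2_DEVIATION_LIMIT
        bad &= ~np.isnan(df["s2_deviation"].to_numpy(dtype=float))
        excluded["spin_contamination"] = int(bad.sum())
        drop |= bad
    else:
        warnings.warn("no s2_deviation column; spin-contamination filter skipped")
    if "geometry_status" in df.columns:
        status = df["geometry_status"].astype(str)
        for cat in ("dissociated", "unconverged"):
            bad = (status == cat).to_numpy() & ~drop
            excluded[cat] = int(bad.sum())
            drop |= bad
    else:
        warnings.warn("no geometry_status column; geometry filters skipped")
    kept = DatasetTable(df=df.loc[~drop].reset_index(drop=True), library=table.library)
    return kept, QCReport(total_rows=len(df), excluded=excluded, kept_rows=len(kept))


def extract_target(table: DatasetTable, target: str):
    """Pull (specs, y) pairs for one prediction target from a dataset.

    ``"splitting"`` uses every row with a finite splitting (a_HF is an
    input descriptor). ``"sensitivity"`` groups rows by complex and fits
    the least-squares slope over that complex's exchange fractions, one
    target per complex. ``"bond"`` uses rows where both minimum bond
    lengths are present, returning an (n, 2) target array (LS, HS).
    """
    df = table.df
    if target == "splitting":
        mask = df["delta_e_hl"].notna() if "delta_e_hl" in df.columns else pd.Series(False, index=df.index)
        sub = df.loc[mask]
        specs = [table._row_spec(dict(r)) for _, r in sub.iterrows()]
        return specs, sub["delta_e_hl"].to_numpy(dtype=float)
    if target == "sensitivity":
        if "delta_e_hl" not in df.columns:
            raise DatasetError("sensitivity target requires a delta_e_hl column")
        specs: list[ComplexSpec] = []
        slopes: list[float] = []
        group_cols = ["metal", "oxidation", "eq_ligand", "ax_ligand"]
        for key, grp in df.dropna(subset=["delta_e_hl"]).groupby(group_cols, sort=False):
            if grp["a_hf"].nunique() < 2:
                continue
            fit = fit_sensitivity(grp["a_hf"].to_numpy(), grp["delta_e_hl"].to_numpy())
            row = dict(zip(group_cols, key))
            row["a_hf"] = 0.0  # placeholder; a_HF is excluded from this model's inputs
            specs.append(table._row_spec(row))
            slopes.append(fit.slope)
        return specs, np.asarray(slopes)
    if target == "bond":
        for col in ("min_r_ls", "min_r_hs"):
            if col not in df.columns:
                raise DatasetError(f"bond target requires a {col} column")
        mask = df["min_r_ls"].notna() & df["min_r_hs"].notna()
        sub = df.loc[mask]
        specs = [table._row_spec(dict(r)) for _, r in sub.iterrows()]
        return specs, sub[["min_r_ls", "min_r_hs"]].to_numpy(dtype=float)
    raise ValueError("target must be 'splitting', 'sensitivity' or 'bond'")
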