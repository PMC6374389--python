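"""Core domain types and file I/O for targeted metabolomics panels.

The central objects are :class:`PanelManifest` (metabolite identities, assay
classes and LOD/LLOQ/ULOQ bounds), :class:`SampleTable` (samples × metabolites
concentrations in µM with per-cell status flags), :class:`StudyDesign`
(treatment × procedure group assignment) and :class:`CovariateTable`.

Concentrations are stored in µM throughout; missing measurements are explicit
(NaN + ``missing`` flag), never imputed zeros.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# constants

CLASSES = (
    "acylcarnitine",
    "amino_acid",
    "biogenic_amine",
    "glycerophospholipid",
    "sphingolipid",
)

TREATMENTS = ("SHAM", "ROT")
PROCEDURES = ("CT", "SR", "REB")

#: the six treatment-procedure group labels, control first
GROUPS = tuple(f"{t}-{p}" for t in TREATMENTS for p in PROCEDURES)
CONTROL_GROUP = "SHAM-CT"

ROLES = ("study", "qc1", "qc2", "qc3", "blank")

# per-cell status flags
VALID = "valid"
BELOW_LOD = "below_lod"
BELOW_LLOQ = "below_lloq"
ABOVE_ULOQ = "above_uloq"
MISSING = "missing"
FLAGS = (VALID, BELOW_LOD, BELOW_LLOQ, ABOVE_ULOQ, MISSING)

_CELL_TOKENS = {"<LOD": BELOW_LOD, "<LLOQ": BELOW_LLOQ, ">ULOQ": ABOVE_ULOQ, "NA": MISSING}
_TOKEN_OF_FLAG = {v: k for k, v in _CELL_TOKENS.items()}


class PanelError(ValueError):
    """Raised on invalid panel / table input."""


# ---------------------------------------------------------------------------
# PanelManifest


@dataclass
class PanelManifest:
    """Metabolite identities, compound classes and quantification bounds.

    ``table`` is indexed by metabolite_id with columns ``class``, ``lod``,
    ``lloq``, ``uloq`` (all bounds in µM). Entry order is preserved.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"class", "lod", "lloq", "uloq"}
        if not required.issubset(t.columns):
            raise PanelError(f"manifest missing columns: {sorted(required - set(t.columns))}")
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise PanelError(f"duplicate metabolite ids: {dups}")
        bad = set(t["class"]) - set(CLASSES)
        if bad:
            rows = t.index[t["class"].isin(bad)].tolist()
            raise PanelError(f"unknown compound class {sorted(bad)} in rows {rows}")
        for mid, row in t.iterrows():
            if not (0 <= row["lod"] <= row["lloq"] < row["uloq"]):
                raise PanelError(
                    f"{mid}: bounds must satisfy 0 <= lod <= lloq < uloq "
                    f"(got {row['lod']}, {row['lloq']}, {row['uloq']})"
                )

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def class_of(self, metabolite_id: str) -> str:
        return str(self.table.at[metabolite_id, "class"])

    def counts_by_class(self, subset: list[str] | None = None) -> dict[str, int]:
        t = self.table if subset is None else self.table.loc[subset]
        counts = t["class"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CLASSES}

    def write_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "metabolite_id", out.index)
        out.to_csv(path, index=False)


def load_panel_manifest(path: str | Path) -> PanelManifest:
    """Read a panel manifest CSV (metabolite_id,class,lod,lloq,uloq)."""
    df = pd.read_csv(path, dtype={"metabolite_id": str, "class": str})
    expected = ["metabolite_id", "class", "lod", "lloq", "uloq"]
    if list(df.columns) != expected:
        raise PanelError(f"manifest header must be {expected}, got {list(df.columns)}")
    if df.empty:
        warnings.warn("empty panel manifest", stacklevel=2)
    df = df.set_index("metabolite_id")
    return PanelManifest(df)


# ---------------------------------------------------------------------------
# packaged p180-style manifest (constructed stand-in)

_AA = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile", "Leu",
    "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]

_BA = [
    "Ac-Orn", "ADMA", "alpha-AAA", "Carnosine", "Creatinine", "DOPA", "Histamine",
    "Kynurenine", "Met-SO", "Nitro-Tyr", "OH-Pro", "PEA", "Putrescine",
    "Sarcosine", "SDMA", "Serotonin", "Spermidine", "Spermine", "Taurine",
]

_AC = [
    "C0", "C2", "C3", "C3:1", "C3-OH", "C4", "C4:1", "C5", "C5:1", "C5:1-DC",
    "C5-DC", "C5-OH", "C5-M-DC", "C6", "C6:1", "C7-DC", "C8", "C9", "C10",
    "C10:1", "C10:2", "C12", "C12:1", "C12-DC", "C14", "C14:1", "C14:1-OH",
    "C14:2", "C14:2-OH", "C16", "C16:1", "C16:1-OH", "C16:2", "C16:2-OH",
    "C16-OH", "C18", "C18:1", "C18:1-OH", "C18:2", "C3-DC",
]

_LYSO = [
    "lysoPC a C14:0", "lysoPC a C16:0", "lysoPC a C16:1", "lysoPC a C17:0",
    "lysoPC a C18:0", "lysoPC a C18:1", "lysoPC a C18:2", "lysoPC a C20:3",
    "lysoPC a C20:4", "lysoPC a C24:0", "lysoPC a C26:0", "lysoPC a C26:1",
    "lysoPC a C28:0", "lysoPC a C28:1",
]

_PC_AA = [
    "PC aa C24:0", "PC aa C26:0", "PC aa C28:1", "PC aa C30:0", "PC aa C30:2",
    "PC aa C32:0", "PC aa C32:1", "PC aa C32:2", "PC aa C32:3", "PC aa C34:1",
    "PC aa C34:2", "PC aa C34:3", "PC aa C34:4", "PC aa C36:0", "PC aa C36:1",
    "PC aa C36:2", "PC aa C36:3", "PC aa C36:4", "PC aa C36:5", "PC aa C36:6",
    "PC aa C38:0", "PC aa C38:3", "PC aa C38:4", "PC aa C38:5", "PC aa C38:6",
    "PC aa C40:1", "PC aa C40:2", "PC aa C40:3", "PC aa C40:4", "PC aa C40:5",
    "PC aa C40:6", "PC aa C42:0", "PC aa C42:1", "PC aa C42:2", "PC aa C42:4",
    "PC aa C42:5", "PC aa C42:6", "PC aa C44:4",
]

_PC_AE = [
    "PC ae C30:0", "PC ae C30:1", "PC ae C30:2", "PC ae C32:1", "PC ae C32:2",
    "PC ae C34:0", "PC ae C34:1", "PC ae C34:2", "PC ae C34:3", "PC ae C36:0",
    "PC ae C36:1", "PC ae C36:2", "PC ae C36:3", "PC ae C36:4", "PC ae C36:5",
    "PC ae C38:0", "PC ae C38:1", "PC ae C38:2", "PC ae C38:3", "PC ae C38:4",
    "PC ae C38:5", "PC ae C38:6", "PC ae C40:1", "PC ae C40:2", "PC ae C40:3",
    "PC ae C40:4", "PC ae C40:5", "PC ae C40:6", "PC ae C42:1", "PC ae C42:2",
    "PC ae C42:3", "PC ae C42:4", "PC ae C42:5", "PC ae C44:3", "PC ae C44:4",
    "PC ae C44:5", "PC ae C44:6",
]

_SM = [
    "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1", "SM C20:2", "SM C24:0",
    "SM C24:1", "SM C26:0", "SM C26:1", "SM (OH) C14:1", "SM (OH) C16:1",
    "SM (OH) C22:1", "SM (OH) C22:2", "SM (OH) C24:1",
]

_CLASS_LISTS = {
    "acylcarnitine": _AC,
    "amino_acid": _AA,
    "biogenic_amine": _BA,
    "glycerophospholipid": _LYSO + _PC_AA + _PC_AE,
    "sphingolipid": _SM,
}

# typical rat plasma concentrations (µM) for named analytes; the remaining
# panel members get reproducible class-typical values from _hashed_baseline
_NAMED_BASELINES = {
    "Ile": 95.0, "Leu": 155.0, "Val": 190.0, "Phe": 62.0, "Met": 48.0,
    "Trp": 78.0, "Orn": 55.0, "Arg": 110.0, "Lys": 320.0, "Pro": 170.0,
    "Ser": 200.0, "Ala": 380.0, "Gly": 250.0, "Gln": 550.0, "Glu": 140.0,
    "Creatinine": 45.0, "Kynurenine": 2.1, "Putrescine": 0.15, "SDMA": 0.5,
    "alpha-AAA": 1.2, "OH-Pro": 25.0, "Spermidine": 0.3, "Taurine": 210.0,
    "C0": 32.0, "C2": 9.0, "C3": 0.45, "C14:1": 0.08, "C5:1-DC": 0.03,
}

_CLASS_BASE_RANGE = {
    "acylcarnitine": (0.02, 2.0),
    "amino_acid": (20.0, 600.0),
    "biogenic_amine": (0.05, 50.0),
    "glycerophospholipid": (0.5, 200.0),
    "sphingolipid": (3.0, 150.0),
}


def _hashed_baseline(metabolite_id: str, cls: str) -> float:
    """Deterministic class-typical baseline (µM), log-uniform in the class range."""
    lo, hi = _CLASS_BASE_RANGE[cls]
    h = hashlib.md5(metabolite_id.encode()).digest()
    u = int.from_bytes(h[:8], "big") / 2**64
    return float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))


def default_baselines(manifest: PanelManifest) -> pd.Series:
    """Baseline (SHAM-CT mean) concentration in µM for each panel metabolite."""
    vals = {}
    for mid in manifest.ids:
        cls = manifest.class_of(mid)
        vals[mid] = _NAMED_BASELINES.get(mid, _hashed_baseline(mid, cls))
    return pd.Series(vals, name="baseline_uM")


def build_default_manifest() -> PanelManifest:
    """Construct the packaged 183-metabolite p180-style manifest.

    A constructed stand-in for the vendor panel: 40 acylcarnitines, 21 amino
    acids, 19 biogenic amines, 89 glycerophospholipids and 14 sphingolipids.
    Quantification bounds are tied to each metabolite's plasma baseline:
    LOD = baseline/50, LLOQ = baseline/20, ULOQ = 20×baseline.
    """
    rows = []
    for cls in CLASSES:
        for mid in _CLASS_LISTS[cls]:
            base = _NAMED_BASELINES.get(mid, _hashed_baseline(mid, cls))
            rows.append(
                {
                    "metabolite_id": mid,
                    "class": cls,
                    "lod": round(base / 50.0, 6),
                    "lloq": round(base / 20.0, 6),
                    "uloq": round(base * 20.0, 6),
                }
            )
    df = pd.DataFrame(rows).set_index("metabolite_id")
    return PanelManifest(df)


def default_manifest() -> PanelManifest:
    """Load the packaged 183-metabolite manifest."""
    with resources.as_file(resources.files("sleepmet.data") / "panel_p180.csv") as p:
        return load_panel_manifest(p)


# ---------------------------------------------------------------------------
# StudyDesign


@dataclass
class StudyDesign:
    """Sample → treatment {SHAM,ROT} × procedure {CT,SR,REB} mapping."""

    table: pd.DataFrame  # index sample_id; columns treatment, procedure, group

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise PanelError("duplicate sample ids in study design")
        if not set(t["treatment"]).issubset(TREATMENTS):
            raise PanelError(f"unknown treatment in {set(t['treatment'])}")
        if not set(t["procedure"]).issubset(PROCEDURES):
            raise PanelError(f"unknown procedure in {set(t['procedure'])}")
        expected = t["treatment"] + "-" + t["procedure"]
        if "group" not in t.columns:
            self.table = t.assign(group=expected)
        elif not (t["group"] == expected).all():
            raise PanelError("group label must equal treatment-procedure")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_of(self, sample_id: str) -> str:
        return str(self.table.at[sample_id, "group"])

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def write_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, index=False)


def read_study_design(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path, dtype=str).set_index("sample_id")
    return StudyDesign(df)


# ---------------------------------------------------------------------------
# CovariateTable


@dataclass
class CovariateTable:
    """Behavioural covariates per sample (e.g. total_activity, sleep_condition)."""

    table: pd.DataFrame  # index sample_id

    @property
    def names(self) -> list[str]:
        return list(self.table.columns)

    def write_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, index=False)


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path).set_index("sample_id")
    return CovariateTable(df)


# ---------------------------------------------------------------------------
# SampleTable


@dataclass
class SampleTable:
    """Samples × metabolites concentration matrix with per-cell status flags.

    ``concentrations`` holds µM values (NaN where no number is available);
    ``status`` holds one flag per cell; ``roles`` assigns each sample a role in
    {study, qc1, qc2, qc3, blank}.
    """

    concentrations: pd.DataFrame
    status: pd.DataFrame
    roles: pd.Series

    def __post_init__(self) -> None:
        c, s = self.concentrations, self.status
        if not (c.index.equals(s.index) and c.columns.equals(s.columns)):
            raise PanelError("concentrations and status must share index/columns")
        if not c.index.equals(self.roles.index):
            raise PanelError("roles index must match sample index")
        bad_roles = set(self.roles) - set(ROLES)
        if bad_roles:
            raise PanelError(f"unknown roles: {sorted(bad_roles)}")
        bad_flags = set(np.unique(s.values.astype(str))) - set(FLAGS)
        if bad_flags:
            raise PanelError(f"unknown flags: {sorted(bad_flags)}")
        # normalize axis names so I/O round trips compare clean
        for frame in (self.concentrations, self.status):
            frame.index.name = "sample_id"
            frame.columns.name = None
        self.roles.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.concentrations.columns)

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.roles.index[self.roles == role])

    def study_samples(self) -> list[str]:
        return self.samples_with_role("study")

    def subset_metabolites(self, ids: list[str]) -> "SampleTable":
        return SampleTable(self.concentrations[ids].copy(), self.status[ids].copy(), self.roles.copy())

    def subset_samples(self, ids: list[str]) -> "SampleTable":
        return SampleTable(
            self.concentrations.loc[ids].copy(), self.status.loc[ids].copy(), self.roles.loc[ids].copy()
        )

    def study_concentrations(self) -> pd.DataFrame:
        """Concentrations of study samples, non-valid cells masked to NaN."""
        ids = self.study_samples()
        conc = self.concentrations.loc[ids]
        ok = self.status.loc[ids] == VALID
        return conc.where(ok)

    def write_csv(self, path: str | Path) -> None:
        """Write the wide-format CSV; value-less flags become their token."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("sample_id,role," + ",".join(self.metabolite_ids) + "\n")
            for sid in self.sample_ids:
                cells = []
                for mid in self.metabolite_ids:
                    v = self.concentrations.at[sid, mid]
                    flag = self.status.at[sid, mid]
                    if isinstance(v, float) and math.isnan(v):
                        cells.append(_TOKEN_OF_FLAG.get(flag, "NA"))
                    else:
                        cells.append(repr(float(v)))
                fh.write(f"{sid},{self.roles.at[sid]}," + ",".join(cells) + "\n")


def _flag_numeric(x: float, lod: float, lloq: float, uloq: float) -> str:
    if x < lod:
        return BELOW_LOD
    if x < lloq:
        return BELOW_LLOQ
    if x > uloq:
        return ABOVE_ULOQ
    return VALID


def flag_concentrations(conc: pd.DataFrame, manifest: PanelManifest) -> pd.DataFrame:
    """Derive status flags for a numeric concentration frame from manifest bounds."""
    status = pd.DataFrame(MISSING, index=conc.index, columns=conc.columns, dtype=object)
    for mid in conc.columns:
        row = manifest.table.loc[mid]
        x = conc[mid].to_numpy(dtype=float)
        f = np.where(
            np.isnan(x),
            MISSING,
            np.where(
                x < row["lod"],
                BELOW_LOD,
                np.where(x < row["lloq"], BELOW_LLOQ, np.where(x > row["uloq"], ABOVE_ULOQ, VALID)),
            ),
        )
        status[mid] = f
    return status


def read_sample_table(path: str | Path, manifest: PanelManifest) -> SampleTable:
    """Read a wide sample-table CSV and derive per-cell status flags.

    Cell syntax: a number, "<LOD", "<LLOQ", ">ULOQ" or "NA". Numeric cells are
    additionally re-flagged against the manifest bounds so the QC rules do not
    depend on upstream export conventions.
    """
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["sample_id", "role"]:
        raise PanelError("sample table must start with columns sample_id,role")
    mets = list(df.columns[2:])
    unknown = set(mets) - set(manifest.ids)
    if unknown:
        raise PanelError(f"unknown metabolite columns: {sorted(unknown)}")
    df = df.set_index("sample_id")
    roles = df["role"].astype(str)
    bad_roles = set(roles) - set(ROLES)
    if bad_roles:
        raise PanelError(f"unknown roles: {sorted(bad_roles)}")

    conc = pd.DataFrame(np.nan, index=df.index, columns=mets, dtype=float)
    status = pd.DataFrame(MISSING, index=df.index, columns=mets, dtype=object)
    for mid in mets:
        row = manifest.table.loc[mid]
        for sid, cell in df[mid].items():
            cell = "NA" if cell is None or (isinstance(cell, float) and math.isnan(cell)) else str(cell).strip()
            if cell in _CELL_TOKENS:
                status.at[sid, mid] = _CELL_TOKENS[cell]
            else:
                try:
                    x = float(cell)
                except ValueError as exc:
                    raise PanelError(f"non-parsable cell {cell!r} at ({sid}, {mid})") from exc
                conc.at[sid, mid] = x
                status.at[sid, mid] = _flag_numeric(x, row["lod"], row["lloq"], row["uloq"])
    return SampleTable(conc, status, roles)


# ---------------------------------------------------------------------------
# sample size for a finite population


def required_sample_size(population_n: float, sigma: float, z: float, e: float) -> int:
    """Sample size for a finite population: n = N σ² z² / ((N−1) e² + σ² z²).

    Returns the ceiling of the raw value. With e = 0 the formula collapses to
    n = N (sample everyone).
    """
    if population_n <= 0 or sigma <= 0 or z <= 0 or e < 0:
        raise ValueError("population_n, sigma, z must be > 0 and e >= 0")
    num = population_n * sigma**2 * z**2
    den = (population_n - 1) * e**2 + sigma**2 * z**2
    if den == 0:
        raise ZeroDivisionError("zero denominator in sample-size formula")
    return math.ceil(num / den - 1e-12)
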