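"""Molecule ingest, activity filtering, and molecular descriptor matrices.

The descriptor engine turns SMILES/SDF inputs into a compounds-by-descriptors
numeric matrix. In the default ``2D+3D`` configuration it emits well over
1000 descriptor columns per molecule: the full RDKit 2D descriptor list,
2D autocorrelations, and — on a deterministically embedded, force-field
minimized conformer — 3D autocorrelations, RDF, MoRSE, WHIM, GETAWAY and
shape descriptors. Descriptors that cannot be evaluated for a molecule are
recorded as missing rather than silently set to zero.

3D descriptors are computed on a single ligand-only conformer (seeded ETKDG
embedding + MMFF minimization). This is a deliberate, documented choice:
no receptor docking is performed, so absolute descriptor values differ from
pipelines that compute them on bound poses, while all downstream template
and scoring logic is unaffected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors, Descriptors3D, rdMolDescriptors

logger = logging.getLogger(__name__)

# RDKit is chatty about sanitization failures; we report them ourselves.
RDLogger.DisableLog("rdApp.error")

#: conversion factors into nanomolar
_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "M": 1e9}

DEFAULT_CUTOFF_NM = 100.0
DEFAULT_CONFORMER_SEED = 20230719


@dataclass(frozen=True)
class MoleculeRecord:
    """A named molecule with a canonical SMILES structure."""

    id: str
    structure: str  # canonical SMILES
    source_format: str = "smiles"  # "smiles" | "sdf"


@dataclass(frozen=True)
class ActivityRecord:
    """A single activity measurement (IC50-like) for a compound."""

    compound_id: str
    value: float
    unit: str = "nM"

    def value_nM(self) -> float:
        return to_nM(self.value, self.unit, compound_id=self.compound_id)


class ParseFailure(NamedTuple):
    """An input entry that could not be parsed, with its position."""

    index: int
    text: str
    reason: str


class LoadedMolecules(NamedTuple):
    records: list[MoleculeRecord]
    failures: list[ParseFailure]


def to_nM(value: float, unit: str, compound_id: str | None = None) -> float:
    """Convert an activity value to nanomolar. Unknown units are fatal."""
    try:
        factor = _UNIT_TO_NM[unit]
    except KeyError:
        where = f" (compound {compound_id!r})" if compound_id else ""
        raise ValueError(
            f"unknown activity unit {unit!r}{where}; expected one of "
            f"{sorted(_UNIT_TO_NM)}"
        ) from None
    return float(value) * factor


def load_molecules(
    path: str | Path,
    format: str | None = None,
    id_property: str | None = None,
) -> LoadedMolecules:
    """Load molecules from a SMILES (.smi) or SDF (V2000) file.

    SMILES files hold one record per line: ``SMILES[ whitespace id]``; a
    missing id becomes ``mol<line>``. SDF ids come from the title line or,
    if `id_property` is given, from that property tag.

    Returns the parsed records together with the entries that failed to
    parse (1-based line/record index plus reason); zero parseable
    molecules is fatal.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"molecule file not found: {path}")
    if format is None:
        format = "sdf" if path.suffix.lower() in {".sdf", ".sd", ".mol"} else "smiles"
    if format not in {"smiles", "sdf"}:
        raise ValueError(f"unsupported molecule format {format!r}")

    records: list[MoleculeRecord] = []
    failures: list[ParseFailure] = []
    seen: set[str] = set()

    def _add(idx: int, mol: Chem.Mol | None, raw: str, mol_id: str) -> None:
        if mol is None:
            failures.append(ParseFailure(idx, raw, "unparseable structure"))
            return
        if mol_id in seen:
            failures.append(ParseFailure(idx, raw, f"duplicate id {mol_id!r}"))
            return
        seen.add(mol_id)
        records.append(
            MoleculeRecord(id=mol_id, structure=Chem.MolToSmiles(mol), source_format=format)
        )

    if format == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            _add(lineno, Chem.MolFromSmiles(smiles), line, mol_id)
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for recno, mol in enumerate(supplier, start=1):
            if mol is None:
                _add(recno, None, f"record {recno}", "")
                continue
            if id_property is not None:
                mol_id = mol.GetProp(id_property) if mol.HasProp(id_property) else ""
            else:
                mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            _add(recno, mol, f"record {recno}", mol_id or f"mol{recno}")

    for f in failures:
        logger.warning("skipped entry %d in %s: %s", f.index, path.name, f.reason)
    if not records:
        raise ValueError(f"no parseable molecules in {path}")
    return LoadedMolecules(records, failures)


def load_activities(path: str | Path) -> list[ActivityRecord]:
    """Read an activity CSV with columns compound_id, value, unit."""
    df = pd.read_csv(path, dtype={"compound_id": str, "unit": str})
    required = {"compound_id", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity CSV {path} lacks columns: {sorted(missing)}")
    records = [
        ActivityRecord(str(r.compound_id), float(r.value), str(r.unit))
        for r in df.itertuples(index=False)
    ]
    for rec in records:
        if rec.value <= 0:
            raise ValueError(f"non-positive activity for {rec.compound_id!r}: {rec.value}")
        rec.value_nM()  # fail fast on unknown units
    return records


def filter_actives(
    records: Sequence[ActivityRecord], cutoff_nM: float = DEFAULT_CUTOFF_NM
) -> list[ActivityRecord]:
    """Keep records with activity strictly below `cutoff_nM`, in input order.

    The strict inequality mirrors the usual "IC50 < cutoff" convention for
    defining a high-affinity training set.
    """
    if cutoff_nM <= 0:
        raise ValueError(f"cutoff_nM must be positive, got {cutoff_nM}")
    return [r for r in records if r.value_nM() < cutoff_nM]


@dataclass
class DescriptorMatrix:
    """Compounds-by-descriptors values with NaN marking missing cells.

    `values` is a float DataFrame indexed by compound id with one column
    per descriptor; every non-NaN cell is finite (infinities are coerced
    to missing at construction).
    """

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate compound ids: {dupes}")
        vals = self.values.astype(float)
        vals.index.name = "compound_id"
        self.values = vals.where(np.isfinite(vals))

    @property
    def compound_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def row(self, compound_id: str) -> pd.Series:
        return self.values.loc[compound_id]

    def subset(self, compound_ids: Iterable[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(self.values.loc[list(compound_ids)].copy())

    def drop_sparse_descriptors(self, max_missing_frac: float = 0.5) -> "DescriptorMatrix":
        """Drop descriptors missing for more than `max_missing_frac` of rows.

        A (mean, SD) couple estimated from a minority of molecules is
        unstable, so such descriptors are removed globally before template
        building.
        """
        frac = self.values.isna().mean(axis=0)
        keep = frac[frac <= max_missing_frac].index
        dropped = self.n_descriptors - len(keep)
        if dropped:
            logger.info("dropped %d descriptors missing in >%.0f%% of molecules",
                        dropped, 100 * max_missing_frac)
        return DescriptorMatrix(self.values[keep].copy())

    def to_csv(self, path: str | Path) -> None:
        # str() float formatting is shortest-repr, hence lossless on re-read
        self.values.to_csv(path, index_label="compound_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        return cls(pd.read_csv(path, index_col="compound_id"))


def _descriptor_block_2d(mol: Chem.Mol) -> dict[str, float]:
    out = dict(Descriptors.CalcMolDescriptors(mol))
    for i, v in enumerate(rdMolDescriptors.CalcAUTOCORR2D(mol), start=1):
        out[f"AUTOCORR2D_{i}"] = v
    return out


def _embed_conformer(mol: Chem.Mol, seed: int) -> Chem.Mol | None:
    """Embed and MMFF-minimize one conformer; None if embedding fails."""
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(molh, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(molh, params) != 0:
            return None
    try:
        AllChem.MMFFOptimizeMolecule(molh)
    except Exception:  # fall back to the unminimized conformer
        pass
    return molh


_3D_VECTOR_CALCS = (
    ("AUTOCORR3D", rdMolDescriptors.CalcAUTOCORR3D),
    ("RDF", rdMolDescriptors.CalcRDF),
    ("MORSE", rdMolDescriptors.CalcMORSE),
    ("WHIM", rdMolDescriptors.CalcWHIM),
    ("GETAWAY", rdMolDescriptors.CalcGETAWAY),
)

#: vector lengths, fixed by the descriptor definitions; used to emit
#: missing values with the right column names when a calculator fails
_3D_VECTOR_LENGTHS = {"AUTOCORR3D": 80, "RDF": 210, "MORSE": 224, "WHIM": 114, "GETAWAY": 273}

_3D_SHAPE_CALCS = (
    ("Asphericity", Descriptors3D.Asphericity),
    ("Eccentricity", Descriptors3D.Eccentricity),
    ("InertialShapeFactor", Descriptors3D.InertialShapeFactor),
    ("NPR1", Descriptors3D.NPR1),
    ("NPR2", Descriptors3D.NPR2),
    ("PBF", Descriptors3D.PBF),
    ("PMI1", Descriptors3D.PMI1),
    ("PMI2", Descriptors3D.PMI2),
    ("PMI3", Descriptors3D.PMI3),
    ("RadiusOfGyration", Descriptors3D.RadiusOfGyration),
    ("SpherocityIndex", Descriptors3D.SpherocityIndex),
)


def _descriptor_block_3d(mol: Chem.Mol, seed: int) -> dict[str, float]:
    out: dict[str, float] = {}
    molh = _embed_conformer(mol, seed)
    for prefix, calc in _3D_VECTOR_CALCS:
        n = _3D_VECTOR_LENGTHS[prefix]
        try:
            vec = calc(molh) if molh is not None else [np.nan] * n
        except Exception:
            vec = [np.nan] * n
        for i, v in enumerate(vec, start=1):
            out[f"{prefix}_{i}"] = v
    for name, calc in _3D_SHAPE_CALCS:
        try:
            out[name] = calc(molh) if molh is not None else np.nan
        except Exception:
            out[name] = np.nan
    return out


def compute_descriptors(
    molecules: Sequence[MoleculeRecord],
    level: str = "2D+3D",
    conformer_seed: int = DEFAULT_CONFORMER_SEED,
) -> DescriptorMatrix:
    """Compute the descriptor matrix for a set of molecules.

    Parameters
    ----------
    molecules
        Non-empty list of records; ids must be unique.
    level
        ``"2D+3D"`` (default, >1000 columns) or ``"2D"`` (fast, ~400).
    conformer_seed
        Seed for the 3D embedding; identical structures with an identical
        seed yield byte-identical rows.
    """
    if not molecules:
        raise ValueError("compute_descriptors requires at least one molecule")
    if level not in {"2D", "2D+3D"}:
        raise ValueError(f"level must be '2D' or '2D+3D', got {level!r}")

    rows: list[dict[str, float]] = []
    ids: list[str] = []
    for rec in molecules:
        mol = Chem.MolFromSmiles(rec.structure)
        if mol is None:
            raise ValueError(f"invalid structure for {rec.id!r}: {rec.structure!r}")
        row = _descriptor_block_2d(mol)
        if level == "2D+3D":
            row.update(_descriptor_block_3d(mol, conformer_seed))
        rows.append(row)
        ids.append(rec.id)

    df = pd.DataFrame(rows, index=pd.Index(ids, name="compound_id"), dtype=float)
    return DescriptorMatrix(df)
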