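"""Bioactivity dataset curation.

Loads compound/activity tables (CSV, TSV or SDF), standardizes structures
(salt stripping, tautomer canonicalization), converts IC50 values to pIC50,
assigns the four-level activity class, balances classes by random
oversampling, and splits train/test.

Conventions
-----------
* pIC50 = -log10(IC50 in mol/L).
* Activity classes: potent (pIC50 >= 8), active (8 > pIC50 >= 7),
  intermediate (7 > pIC50 >= 6), inactive (pIC50 < 6). Boundaries belong to
  the upper class.
* The internal canonical concentration unit is mol/L; when no unit is
  declared, nM (the ChEMBL norm) is assumed and a warning is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize
from sklearn.model_selection import train_test_split

from .errors import ConfigurationError, EmptyDatasetError, StructureError

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

DEFAULT_SEED = 42

#: Multiplicative factors converting a concentration in the given unit to mol/L.
UNIT_FACTORS: Mapping[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


@dataclass(frozen=True)
class ActivityClassScheme:
    """Ordered pIC50 cut points and the class labels they delimit.

    ``thresholds`` must be strictly decreasing; a pIC50 greater than or equal
    to ``thresholds[i]`` (and below all earlier cuts) receives ``labels[i]``;
    values below the last cut receive the final label.
    """

    thresholds: tuple[float, ...] = (8.0, 7.0, 6.0)
    labels: tuple[str, ...] = ("potent", "active", "intermediate", "inactive")
    binary_positive: tuple[str, ...] = ("potent", "active")

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds, reverse=True) or len(
            set(self.thresholds)
        ) != len(self.thresholds):
            raise ConfigurationError("thresholds must be strictly decreasing")
        if len(self.labels) != len(self.thresholds) + 1:
            raise ConfigurationError("need one more label than cut points")
        if not set(self.binary_positive) <= set(self.labels):
            raise ConfigurationError("binary_positive must be a subset of labels")


DEFAULT_SCHEME = ActivityClassScheme()


@dataclass
class CompoundRecord:
    """One curated molecule with structure, potency and class labels."""

    compound_id: str
    smiles: str
    pic50: float
    activity_class: str
    category: str = "unknown"
    ic50: float | None = None  # mol/L, when the source reported IC50

    def __post_init__(self) -> None:
        if self.ic50 is not None:
            expected = -math.log10(self.ic50)
            if abs(expected - self.pic50) > 1e-9:
                raise ConfigurationError(
                    f"{self.compound_id}: pic50={self.pic50} inconsistent with "
                    f"ic50={self.ic50} mol/L (expected {expected})"
                )


def compute_pic50(value: float, unit: str = "M") -> float:
    """Convert an IC50 (``value`` in ``unit``) to pIC50 = -log10(mol/L)."""
    if unit not in UNIT_FACTORS:
        raise ConfigurationError(f"unknown concentration unit {unit!r}")
    if not (value > 0):
        raise ValueError(f"IC50 must be positive, got {value}")
    return -math.log10(value * UNIT_FACTORS[unit])


def assign_activity_class(pic50: float, scheme: ActivityClassScheme = DEFAULT_SCHEME) -> str:
    """Map a pIC50 to its activity class; boundaries belong to the upper class."""
    if not math.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50}")
    for cut, label in zip(scheme.thresholds, scheme.labels):
        if pic50 >= cut:
            return label
    return scheme.labels[-1]


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()
_TAUTOMER: rdMolStandardize.TautomerEnumerator | None = None


def _tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    global _TAUTOMER
    if _TAUTOMER is None:
        _TAUTOMER = rdMolStandardize.TautomerEnumerator()
    return _TAUTOMER


def strip_salts_and_canonicalize(smiles: str, standardize_tautomer: bool = True) -> str:
    """Return the canonical SMILES of the largest fragment.

    Counter-ions and co-crystallized fragments are dropped (largest-fragment
    rule) and, by default, the structure is mapped to its canonical tautomer.
    The operation is idempotent.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = _FRAGMENT_CHOOSER.choose(mol)
    if standardize_tautomer:
        mol = _tautomer_enumerator().Canonicalize(mol)
    return Chem.MolToSmiles(mol)


_DEFAULT_COLUMNS = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "pic50": "pic50",
    "ic50": "ic50",
    "ic50_unit": "ic50_unit",
    "category": "category",
}


def _record_from_fields(
    compound_id: str,
    smiles: str,
    pic50: float | None,
    ic50: float | None,
    unit: str | None,
    category: str,
    scheme: ActivityClassScheme,
    default_unit: str,
    standardize_tautomer: bool,
) -> CompoundRecord:
    canon = strip_salts_and_canonicalize(smiles, standardize_tautomer=standardize_tautomer)
    ic50_molar: float | None = None
    if pic50 is None:
        if ic50 is None:
            raise ConfigurationError(f"{compound_id}: neither pIC50 nor IC50 present")
        if unit is None:
            unit = default_unit
        pic50 = compute_pic50(ic50, unit)
        ic50_molar = ic50 * UNIT_FACTORS[unit]
    return CompoundRecord(
        compound_id=str(compound_id),
        smiles=canon,
        pic50=float(pic50),
        activity_class=assign_activity_class(float(pic50), scheme),
        category=category,
        ic50=ic50_molar,
    )


def load_dataset(
    path: str,
    format: str = "csv",
    column_map: Mapping[str, str] | None = None,
    ic50_unit: str | None = None,
    scheme: ActivityClassScheme = DEFAULT_SCHEME,
    standardize_tautomer: bool = True,
) -> list[CompoundRecord]:
    """Load and curate a compound activity table.

    Rows with unparseable SMILES, duplicate compound ids, duplicate
    structures, or missing potency are rejected with a logged reason.
    ``column_map`` renames the expected logical columns (compound_id, smiles,
    pic50, ic50, ic50_unit, category) to the file's actual headers.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="\t" if format == "tsv" else ",")
        if cols["smiles"] not in df.columns:
            raise ConfigurationError(f"missing required column {cols['smiles']!r}")
        if cols["pic50"] not in df.columns and cols["ic50"] not in df.columns:
            raise ConfigurationError(
                f"need at least one of {cols['pic50']!r} or {cols['ic50']!r}"
            )
        rows = []
        for i, row in df.iterrows():
            cid = row.get(cols["compound_id"], f"row{i}")
            pic50 = row.get(cols["pic50"])
            ic50 = row.get(cols["ic50"])
            unit = row.get(cols["ic50_unit"])
            rows.append(
                (
                    str(cid),
                    row[cols["smiles"]],
                    None if pd.isna(pic50) else float(pic50),
                    None if pd.isna(ic50) else float(ic50),
                    None if unit is None or pd.isna(unit) else str(unit),
                    str(row.get(cols["category"], "unknown") or "unknown"),
                )
            )
    elif format == "sdf":
        rows = []
        supplier = Chem.SDMolSupplier(path)
        for i, mol in enumerate(supplier):
            if mol is None:
                log.warning("rejected SDF entry %d: unparseable structure", i)
                continue
            props = mol.GetPropsAsDict()
            cid = props.get("compound_id", mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}")
            rows.append(
                (
                    str(cid) or f"mol{i}",
                    Chem.MolToSmiles(mol),
                    float(props["pic50"]) if "pic50" in props else None,
                    float(props["ic50"]) if "ic50" in props else None,
                    str(props["ic50_unit"]) if "ic50_unit" in props else None,
                    str(props.get("category", "unknown")),
                )
            )
    else:
        raise ConfigurationError(f"unsupported format {format!r}")

    default_unit = ic50_unit
    if default_unit is None:
        default_unit = "nM"
        if any(r[3] is not None and r[4] is None for r in rows):
            log.warning(
                "no IC50 unit declared; assuming nM (the ChEMBL convention) — "
                "pass ic50_unit or an ic50_unit column to silence this"
            )

    records: list[CompoundRecord] = []
    seen_ids: set[str] = set()
    seen_smiles: set[str] = set()
    for cid, smi, pic50, ic50, unit, category in rows:
        try:
            rec = _record_from_fields(
                cid, smi, pic50, ic50, unit, category, scheme, default_unit,
                standardize_tautomer,
            )
        except (StructureError, ConfigurationError, ValueError) as exc:
            log.warning("rejected %s: %s", cid, exc)
            continue
        if rec.compound_id in seen_ids:
            log.warning("rejected %s: duplicate compound_id", cid)
            continue
        if rec.smiles in seen_smiles:
            log.warning("rejected %s: duplicate structure (keeping first occurrence)", cid)
            continue
        seen_ids.add(rec.compound_id)
        seen_smiles.add(rec.smiles)
        records.append(rec)

    if not records:
        raise EmptyDatasetError(f"no valid rows in {path}")
    return records


def balance_by_oversampling(
    records: Sequence[CompoundRecord], seed: int = DEFAULT_SEED
) -> list[CompoundRecord]:
    """Equalize class sizes by duplicating randomly chosen minority records.

    Every original record is retained; each minority class is padded with
    uniform-with-replacement copies of its own members until all class counts
    equal the majority count. Duplicate copies receive a ``__dupN`` id suffix
    so compound ids stay unique. Deterministic for a fixed seed.
    """
    if not records:
        raise EmptyDatasetError("cannot balance an empty dataset")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.activity_class, []).append(rec)
    target = max(len(v) for v in by_class.values())
    out = list(records)
    for label in sorted(by_class):
        members = by_class[label]
        deficit = target - len(members)
        if deficit == 0:
            continue
        picks = rng.integers(0, len(members), size=deficit)
        for k, idx in enumerate(picks):
            src = members[idx]
            out.append(replace(src, compound_id=f"{src.compound_id}__dup{k + 1}"))
    return out


def split_train_test(
    records: Sequence[CompoundRecord],
    test_fraction: float,
    seed: int = DEFAULT_SEED,
    stratify: bool = True,
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Random train/test split; |test| = ceil(test_fraction * N).

    Stratifies on activity_class by default. Deterministic for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise ConfigurationError(f"test_fraction must be in (0,1), got {test_fraction}")
    if len(records) < 2:
        raise EmptyDatasetError("need at least 2 records to split")
    labels = [r.activity_class for r in records] if stratify else None
    train, test = train_test_split(
        list(records),
        test_size=test_fraction,
        random_state=seed,
        shuffle=True,
        stratify=labels,
    )
    return list(train), list(test)


def to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Curated records as a DataFrame (the curated-CSV schema)."""
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "smiles": r.smiles,
                "pic50": r.pic50,
                "activity_class": r.activity_class,
                "category": r.category,
            }
            for r in records
        ]
    )


def from_frame(df: pd.DataFrame, scheme: ActivityClassScheme = DEFAULT_SCHEME) -> list[CompoundRecord]:
    """Rebuild records from a curated-CSV DataFrame (no re-standardization)."""
    return [
        CompoundRecord(
            compound_id=str(row.compound_id),
            smiles=row.smiles,
            pic50=float(row.pic50),
            activity_class=assign_activity_class(float(row.pic50), scheme),
            category=getattr(row, "category", "unknown"),
        )
        for row in df.itertuples(index=False)
    ]
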