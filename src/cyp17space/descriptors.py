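"""Drug-likeness descriptors and molecular fingerprints.

Six descriptors drive the chemical-space analysis: molecular weight (MW,
g/mol), the Crippen octanol-water partition estimate (LogP), hydrogen-bond
acceptor and donor counts (nHA, nHD), rotatable-bond count (nRot) and the
topological polar surface area (TPSA, A^2).

Fingerprints: MACCS keys (167 bits, toolkit convention with unused bit 0)
and ECFP4 (Morgan radius 2, folded to 2048 bits by default) are computed
natively. PubChem (881) and Klekota-Roth (4860) style keys are supported
through a pluggable SMARTS key set or by loading a precomputed table
(e.g. PaDEL output) as an external fingerprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdMolDescriptors
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator

from .errors import CapabilityError, ConfigurationError, StructureError

log = logging.getLogger(__name__)

DESCRIPTOR_NAMES = ("MW", "LogP", "nHA", "nHD", "nRot", "TPSA")


@dataclass(frozen=True)
class DescriptorVector:
    MW: float
    LogP: float
    nHA: int
    nHD: int
    nRot: int
    TPSA: float

    def as_array(self) -> np.ndarray:
        return np.array([self.MW, self.LogP, self.nHA, self.nHD, self.nRot, self.TPSA], dtype=float)


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-width bit or count vector for one molecule."""

    scheme: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.int32))
        if np.any(self.bits < 0):
            raise ConfigurationError("fingerprint values must be non-negative")

    @property
    def length(self) -> int:
        return int(self.bits.size)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    return mol


def compute_druglikeness(smiles: str) -> DescriptorVector:
    """Compute the six drug-likeness descriptors for one molecule."""
    mol = _mol(smiles)
    return DescriptorVector(
        MW=Descriptors.MolWt(mol),
        LogP=Crippen.MolLogP(mol),
        nHA=Lipinski.NumHAcceptors(mol),
        nHD=Lipinski.NumHDonors(mol),
        nRot=Lipinski.NumRotatableBonds(mol),
        TPSA=rdMolDescriptors.CalcTPSA(mol),
    )


def descriptor_table(records: Sequence) -> pd.DataFrame:
    """Descriptor DataFrame (index = compound_id) for curated records."""
    data = {r.compound_id: compute_druglikeness(r.smiles).as_array() for r in records}
    return pd.DataFrame.from_dict(data, orient="index", columns=list(DESCRIPTOR_NAMES))


@dataclass(frozen=True)
class SubstructureKeySet:
    """A named list of SMARTS patterns defining a substructure-key fingerprint.

    ``counts=False`` emits presence/absence bits (PubChem-style);
    ``counts=True`` emits match counts (Klekota-Roth count style).
    """

    name: str
    smarts: tuple[str, ...]
    counts: bool = False

    def __post_init__(self) -> None:
        patterns = []
        for s in self.smarts:
            patt = Chem.MolFromSmarts(s)
            if patt is None:
                raise ConfigurationError(f"invalid SMARTS in key set {self.name!r}: {s!r}")
            patterns.append(patt)
        object.__setattr__(self, "_patterns", tuple(patterns))

    def apply(self, mol: Chem.Mol) -> np.ndarray:
        out = np.zeros(len(self.smarts), dtype=np.int32)
        for i, patt in enumerate(self._patterns):
            if self.counts:
                out[i] = len(mol.GetSubstructMatches(patt))
            else:
                out[i] = 1 if mol.HasSubstructMatch(patt) else 0
        return out


_KEY_TABLES: dict[str, SubstructureKeySet] = {}


def register_key_table(scheme: str, keys: SubstructureKeySet) -> None:
    """Back a substructure-key scheme (e.g. pubchem, klekota_roth) with SMARTS."""
    _KEY_TABLES[scheme] = keys


def compute_fingerprint(smiles: str, scheme: str = "ecfp4", n_bits: int = 2048) -> Fingerprint:
    """Compute a fingerprint for one molecule.

    Native schemes: ``maccs`` (167 keys) and ``ecfp4`` (Morgan radius 2,
    ``n_bits`` wide). Other schemes must be registered via
    :func:`register_key_table` or loaded from a table with
    :func:`load_fingerprint_table`.
    """
    mol = _mol(smiles)
    if scheme == "maccs":
        return Fingerprint("maccs", np.array(MACCSkeys.GenMACCSKeys(mol), dtype=np.int32))
    if scheme == "ecfp4":
        gen = GetMorganGenerator(radius=2, fpSize=n_bits)
        return Fingerprint("ecfp4", np.array(gen.GetFingerprint(mol), dtype=np.int32))
    if scheme in _KEY_TABLES:
        return Fingerprint(scheme, _KEY_TABLES[scheme].apply(mol))
    raise CapabilityError(
        f"fingerprint scheme {scheme!r} has no key table loaded; register SMARTS "
        "keys with register_key_table() or supply a precomputed table via "
        "load_fingerprint_table()"
    )


def fingerprint_table(records: Sequence, scheme: str = "ecfp4", n_bits: int = 2048) -> dict[str, Fingerprint]:
    return {r.compound_id: compute_fingerprint(r.smiles, scheme, n_bits) for r in records}


def load_fingerprint_table(path: str, id_column: str | None = None) -> dict[str, Fingerprint]:
    """Load a precomputed fingerprint CSV (one row per compound).

    The first column (or ``id_column``) holds compound ids; all remaining
    columns must be numeric and homogeneous in width. The scheme is recorded
    as ``external``.
    """
    df = pd.read_csv(path)
    if df.empty:
        log.warning("empty fingerprint table %s", path)
        return {}
    idc = id_column or df.columns[0]
    if idc not in df.columns:
        raise ConfigurationError(f"id column {idc!r} not in {path}")
    value_cols = [c for c in df.columns if c != idc]
    values = df[value_cols]
    if not all(np.issubdtype(dt, np.number) for dt in values.dtypes):
        raise ConfigurationError(f"non-numeric fingerprint cells in {path}")
    if values.isna().any().any():
        raise ConfigurationError(f"ragged/missing fingerprint cells in {path}")
    return {
        str(cid): Fingerprint("external", row)
        for cid, row in zip(df[idc], values.to_numpy())
    }


def align_fingerprints(
    fps: Mapping[str, Fingerprint], compound_ids: Sequence[str]
) -> np.ndarray:
    """Stack fingerprints into an (n, width) matrix in the given id order.

    Ids absent from the map are reported; presence of orphan fingerprints
    (ids not in ``compound_ids``) is logged as a warning.
    """
    missing = [cid for cid in compound_ids if cid not in fps]
    if missing:
        raise ConfigurationError(f"missing fingerprints for ids: {missing[:5]}...")
    orphans = set(fps) - set(compound_ids)
    if orphans:
        log.warning("%d orphan fingerprint ids not in dataset (e.g. %s)",
                    len(orphans), sorted(orphans)[:3])
    return np.vstack([fps[cid].bits for cid in compound_ids])
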