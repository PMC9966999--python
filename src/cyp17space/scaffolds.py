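"""Bemis-Murcko scaffold analysis.

A molecule is dissected into ring systems, linkers and side chains; the
Murcko framework (scaffold) is the union of ring systems and linkers after
side-chain removal. The cyclic skeleton further genericizes the framework:
every atom becomes carbon and every bond a single bond, so molecules
differing only in heteroatoms or bond orders share one skeleton.

On top of the decomposition this module provides frequency-ranked scaffold
tables with enrichment factors, scaffold-diversity reports, representative
scaffold selection, skeleton-based grouping for scaffold-stratified
modeling, and a simplified R-group decomposition of a scaffold's members.

Enrichment factor (EF): (active fraction within a scaffold) / (active
fraction of the whole dataset). EF = 0 means no active members; EF = 1
matches the dataset average; EF = 1/p (p the dataset active proportion)
means every member is active. By default the dataset proportion is rounded
to two decimals before dividing, mirroring how the statistic is usually
quoted (351/683 -> 0.51 -> an all-active scaffold scores 1/0.51 = 1.961);
the exact-fraction variant is also computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.Chem import rdRGroupDecomposition

from .curation import CompoundRecord
from .errors import ConfigurationError, EmptyDatasetError, StructureError

log = logging.getLogger(__name__)

#: Sentinel scaffold for acyclic molecules (no ring system).
NO_SCAFFOLD = ""


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    return mol


def murcko_scaffold(smiles: str) -> str:
    """Canonical Murcko framework SMILES; '' for acyclic molecules."""
    scaffold = MurckoScaffold.GetScaffoldForMol(_mol(smiles))
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return NO_SCAFFOLD
    return Chem.MolToSmiles(scaffold)


def cyclic_skeleton(smiles: str) -> str:
    """All-carbon, all-single-bond genericization of the Murcko framework."""
    scaffold = MurckoScaffold.GetScaffoldForMol(_mol(smiles))
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return NO_SCAFFOLD
    generic = MurckoScaffold.MakeScaffoldGeneric(scaffold)
    return Chem.MolToSmiles(generic)


@dataclass
class ScaffoldRecord:
    scaffold_smiles: str
    skeleton_smiles: str
    member_ids: list[str]
    n_active: int
    ef: float  # rounded-proportion variant (reporting default)
    ef_exact: float

    @property
    def frequency(self) -> int:
        return len(self.member_ids)


def enrichment_factor(
    n_active: int,
    frequency: int,
    dataset_active: int,
    dataset_total: int,
    rounded_proportion: bool = True,
) -> float:
    """EF of one scaffold against the dataset's active proportion."""
    if frequency < 1 or not 0 <= n_active <= frequency:
        raise ConfigurationError("need 0 <= n_active <= frequency, frequency >= 1")
    p = dataset_active / dataset_total
    if rounded_proportion:
        p = round(p, 2)
    if p <= 0:
        return float("nan")
    return (n_active / frequency) / p


def scaffold_table(
    records: Sequence[CompoundRecord],
    activity_threshold: float = 7.0,
    rounded_proportion: bool = True,
) -> list[ScaffoldRecord]:
    """One ScaffoldRecord per distinct Murcko scaffold, frequency-ranked.

    Active means pic50 >= ``activity_threshold``. Frequency ties break by
    scaffold SMILES lexicographic order. Acyclic molecules fall into the
    empty-scaffold pseudo-group (a warning is emitted if the whole input is
    acyclic). EF is computed against the whole input's active proportion.
    """
    if not records:
        raise EmptyDatasetError("scaffold_table needs at least one record")
    groups: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        groups.setdefault(murcko_scaffold(rec.smiles), []).append(rec)
    if set(groups) == {NO_SCAFFOLD}:
        log.warning("all compounds are acyclic: only the no-scaffold group exists")
    n_total = len(records)
    n_active_total = sum(r.pic50 >= activity_threshold for r in records)
    out = []
    for scaf, members in groups.items():
        n_active = sum(r.pic50 >= activity_threshold for r in members)
        skeleton = cyclic_skeleton(scaf) if scaf != NO_SCAFFOLD else NO_SCAFFOLD
        out.append(
            ScaffoldRecord(
                scaffold_smiles=scaf,
                skeleton_smiles=skeleton,
                member_ids=[r.compound_id for r in members],
                n_active=n_active,
                ef=enrichment_factor(n_active, len(members), n_active_total, n_total,
                                     rounded_proportion=rounded_proportion),
                ef_exact=enrichment_factor(n_active, len(members), n_active_total,
                                           n_total, rounded_proportion=False),
            )
        )
    out.sort(key=lambda s: (-s.frequency, s.scaffold_smiles))
    return out


@dataclass(frozen=True)
class DiversityReport:
    """Scaffold-diversity counts and ratios.

    N: compounds; Ns: distinct Murcko scaffolds; Nss: singleton scaffolds
    (frequency 1); Ncsk: distinct cyclic skeletons. Acyclic molecules count
    in N but contribute no scaffold. Ratios are exact; use ``rounded()`` for
    3-decimal report values.
    """

    N: int
    Ns: int
    Nss: int
    Ncsk: int

    def __post_init__(self) -> None:
        if not (0 <= self.Nss <= self.Ns <= self.N and self.Ncsk <= self.Ns):
            raise ConfigurationError("inconsistent diversity counts")

    @property
    def ns_ratio(self) -> float:
        return self.Ns / self.N

    @property
    def nss_ratio(self) -> float:
        return self.Nss / self.N

    @property
    def ncsk_ratio(self) -> float:
        return self.Ncsk / self.N

    @property
    def ncsk_ns_ratio(self) -> float:
        return self.Ncsk / self.Ns if self.Ns else float("nan")

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {
            "Ns/N": round(self.ns_ratio, ndigits),
            "Nss/N": round(self.nss_ratio, ndigits),
            "Ncsk/N": round(self.ncsk_ratio, ndigits),
            "Ncsk/Ns": round(self.ncsk_ns_ratio, ndigits),
        }


def diversity_report(
    records: Sequence[CompoundRecord],
    subset_filter: Callable[[CompoundRecord], bool] | None = None,
) -> DiversityReport:
    """Diversity counts for the (optionally filtered) dataset."""
    subset = [r for r in records if subset_filter is None or subset_filter(r)]
    if not subset:
        raise EmptyDatasetError("empty subset after filtering")
    scaffolds: dict[str, int] = {}
    skeletons: set[str] = set()
    for rec in subset:
        scaf = murcko_scaffold(rec.smiles)
        if scaf == NO_SCAFFOLD:
            continue
        scaffolds[scaf] = scaffolds.get(scaf, 0) + 1
        skeletons.add(cyclic_skeleton(scaf))
    return DiversityReport(
        N=len(subset),
        Ns=len(scaffolds),
        Nss=sum(1 for c in scaffolds.values() if c == 1),
        Ncsk=len(skeletons),
    )


def select_representative(
    scaffolds: Sequence[ScaffoldRecord],
    min_frequency: int = 10,
    min_ef: float = 1.0,
) -> list[ScaffoldRecord]:
    """Scaffolds with frequency >= min_frequency OR ef >= min_ef.

    Ranked by (ef descending, frequency descending); the empty-scaffold
    pseudo-group is never representative.
    """
    picked = [
        s
        for s in scaffolds
        if s.scaffold_smiles != NO_SCAFFOLD
        and (s.frequency >= min_frequency or s.ef >= min_ef)
    ]
    picked.sort(key=lambda s: (-s.ef, -s.frequency, s.scaffold_smiles))
    return picked


def group_by_skeleton(
    scaffolds: Sequence[ScaffoldRecord],
    manual_groups: Sequence[Iterable[str]] | None = None,
) -> list[list[ScaffoldRecord]]:
    """Group scaffolds sharing a cyclic skeleton.

    ``manual_groups`` (lists of scaffold SMILES) explicitly merges the
    skeleton groups containing those scaffolds, mirroring hand-curated
    modeling groups. Unknown scaffold SMILES raise a configuration error.
    """
    by_skel: dict[str, list[ScaffoldRecord]] = {}
    for s in scaffolds:
        by_skel.setdefault(s.skeleton_smiles, []).append(s)
    groups = {skel: list(members) for skel, members in by_skel.items()}
    if manual_groups:
        known = {s.scaffold_smiles: s.skeleton_smiles for s in scaffolds}
        for merge in manual_groups:
            skels = []
            for smi in merge:
                if smi not in known:
                    raise ConfigurationError(f"manual group references unknown scaffold {smi!r}")
                skels.append(known[smi])
            skels = [s for s in dict.fromkeys(skels) if s in groups]
            if len(skels) < 2:
                continue
            merged = []
            for skel in skels:
                merged.extend(groups.pop(skel))
            groups[skels[0]] = merged
    return [groups[k] for k in sorted(groups)]


def rgroup_decompose(
    member_smiles: Mapping[str, str] | Sequence[str],
    core_smiles: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Decompose scaffold members into core + numbered substituents.

    ``member_smiles`` maps compound id -> SMILES (a plain sequence gets
    positional ids). Returns (table, unmatched_ids); the table has one row
    per matched member with columns Core, R1, R2, ... as SMILES fragments.
    """
    core = Chem.MolFromSmiles(core_smiles)
    if core is None:
        core = Chem.MolFromSmarts(core_smiles)
    if core is None:
        raise StructureError(f"core is not a valid substructure query: {core_smiles!r}")
    if isinstance(member_smiles, Mapping):
        ids = list(member_smiles)
        mols = [_mol(member_smiles[i]) for i in ids]
    else:
        ids = [str(i) for i in range(len(member_smiles))]
        mols = [_mol(s) for s in member_smiles]
    params = rdRGroupDecomposition.RGroupDecompositionParameters()
    params.removeAllHydrogenRGroups = False
    decomp, unmatched_idx = rdRGroupDecomposition.RGroupDecompose(
        [core], mols, asSmiles=True, options=params
    )
    unmatched = [ids[i] for i in unmatched_idx]
    matched_ids = [i for i in ids if i not in set(unmatched)]
    table = pd.DataFrame(decomp, index=matched_ids)
    return table, unmatched


def scaffold_frame(scaffolds: Sequence[ScaffoldRecord], ndigits: int = 3) -> pd.DataFrame:
    """Scaffold table as a DataFrame (CSV report shape)."""
    return pd.DataFrame(
        [
            {
                "scaffold_smiles": s.scaffold_smiles,
                "skeleton_smiles": s.skeleton_smiles,
                "frequency": s.frequency,
                "n_active": s.n_active,
                "ef": round(s.ef, ndigits),
                "ef_exact": round(s.ef_exact, ndigits),
                "member_ids": ";".join(s.member_ids),
            }
            for s in scaffolds
        ]
    )
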