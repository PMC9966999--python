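"""Synthetic SMILES datasets with known scaffold structure and activity.

The generator enumerates molecules from hand-written scaffold templates
(SMILES with ``{R1}``, ``{R2}`` placeholders on ring atoms) decorated with
substituents drawn from a small R-group library. Activity follows an
additive model: the true pIC50 of a molecule is its scaffold's baseline plus
the sum of its substituents' effects, with optional Gaussian observation
noise. Because every substituent is acyclic, the Murcko scaffold of each
product equals its template's framework, so scaffold recovery has an exact
ground truth.

Activity cliffs are planted explicitly: a pair sharing a scaffold and all
but one substituent, where the swapped substituent is a strong
activity-killing group (a nitro), giving a true pIC50 gap >= 3.

The default template set mimics the shape of a curated inhibitor dataset:
a frequency-ranked scaffold tail down to singletons, a steroid-like
(tetracyclic) subset that is potent-heavy, several all-active scaffolds,
one all-inactive scaffold, and four unbalanced activity classes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .curation import CompoundRecord, assign_activity_class
from .errors import ConfigurationError

#: Substituent SMILES fragment -> additive pIC50 effect.
DEFAULT_RGROUP_EFFECTS: dict[str, float] = {
    "[H]": 0.0,
    "C": 0.2,
    "CC": 0.1,
    "CCC": -0.2,
    "O": 0.5,
    "OC": 0.3,
    "OCC": -0.1,
    "N": 0.4,
    "F": -0.3,
    "Cl": -0.5,
    "Br": -0.7,
    "C(F)(F)F": -0.9,
    "C#N": 0.6,
    "C(=O)N": 0.8,
    "S(N)(=O)=O": 1.0,
}

#: The planted-cliff substituent: swapping it in wipes out activity.
CLIFF_SUBSTITUENT = "[N+](=O)[O-]"
CLIFF_EFFECT = -3.5

#: Scaffold templates: (SMILES with placeholders, baseline pIC50, steroid-like).
#: Ordered by intended frequency rank; the tetracyclic steroid-like entries
#: carry high baselines (potent-heavy), one low-baseline scaffold is
#: all-inactive, and the single-position baselines >= 8.2 are all-active.
DEFAULT_TEMPLATES: list[tuple[str, float, bool]] = [
    ("c1cc({R1})ccc1Cc1ccc({R2})cc1", 6.9, False),           # diphenylmethane
    ("c1cc({R1})ccc1-c1ccc({R2})nc1", 7.6, False),           # phenylpyridine
    ("c1cc({R1})ccc1Oc1ccc({R2})cc1", 7.4, False),           # diphenyl ether
    ("c1cc({R1})ccc1-c1ccc2ccc({R2})cc2c1", 6.5, False),     # phenylnaphthalene
    ("c1cc({R1})ccc1N1CCN(c2ccc({R2})cc2)CC1", 7.0, False),  # phenylpiperazine
    ("c1cc({R1})ccc1S(=O)(=O)Nc1ccc({R2})cc1", 6.2, False),  # sulfonanilide
    ("c1cc({R1})ccc1-c1cncn1C", 8.3, False),                 # imidazolylbenzene (all-active)
    ("c1cc({R1})ccc1-c1ccno1", 6.6, False),                  # isoxazolylbenzene
    ("CC12CCC3c4ccc({R1})cc4CCC3C1CCC2O", 8.4, True),        # steroid-like, aromatic A ring
    ("CC12CCC3C(CCC4CC(=O)CCC43C)C1CCC2{R1}", 8.2, True),    # steroid-like, 3-keto
    ("CC12CCC3C(CCC4CCCCC43C)C1CCC2{R1}", 8.5, True),        # steroid-like, saturated
    ("c1cc({R1})ccc1-c1ccccc1", 6.4, False),                 # biphenyl
    ("c1cc({R1})ccc1CNc1ncccn1", 7.1, False),                # pyrimidinylmethylamine
    ("c1cc({R1})ccc1C1CCNCC1", 4.8, False),                  # phenylpiperidine (all-inactive)
    ("c1cc({R1})ccc1-c1cccs1", 6.8, False),                  # phenylthiophene
    ("c1cc({R1})ccc1-c1ccc2[nH]ccc2c1", 7.2, False),         # phenylindole
    ("c1cc({R1})ccc1-n1ccnc1", 8.6, False),                  # N-arylimidazole (all-active)
    ("c1cc({R1})ccc1C1CC2CCC1C2", 6.1, False),               # norbornylbenzene
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic dataset generator."""

    n_scaffolds: int = 18
    templates: Sequence[tuple[str, float, bool]] = field(
        default_factory=lambda: list(DEFAULT_TEMPLATES)
    )
    rgroup_library: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RGROUP_EFFECTS)
    )
    n_per_scaffold: Sequence[int] | int = field(
        default_factory=lambda: [60, 45, 35, 30, 25, 20, 14, 12, 10, 8, 6, 5, 4, 3, 2, 1, 1, 1]
    )
    noise_sd: float = 0.3  # pIC50 units of Gaussian observation noise
    n_cliff_pairs: int = 5
    steroid_fraction: float | None = None  # None: use template flags
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1 or self.n_scaffolds > len(self.templates):
            raise ConfigurationError(
                f"n_scaffolds must be in 1..{len(self.templates)}"
            )
        if self.noise_sd < 0 or self.n_cliff_pairs < 0:
            raise ConfigurationError("noise_sd and n_cliff_pairs must be >= 0")
        for smi, _, _ in self.templates[: self.n_scaffolds]:
            probe = smi.replace("{R1}", "C").replace("{R2}", "C")
            if Chem.MolFromSmiles(probe) is None:
                raise ConfigurationError(f"invalid scaffold template {smi!r}")


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    scaffold_index: dict[str, int]  # compound id -> scaffold index
    true_pic50: dict[str, float]  # compound id -> noise-free pIC50
    expected_ef: dict[int, float]  # scaffold index -> EF at pIC50 >= 7.0
    cliff_pairs: list[tuple[str, str, float]]  # (id_a, id_b, |delta true pIC50|)
    scaffold_smiles: dict[int, str] = field(default_factory=dict)


def _ecfp4_tanimoto(smiles_a: str, smiles_b: str) -> float:
    from .descriptors import compute_fingerprint
    from .landscape import tanimoto

    return tanimoto(
        compute_fingerprint(smiles_a, "ecfp4").bits,
        compute_fingerprint(smiles_b, "ecfp4").bits,
    )


def _positions(template: str) -> list[str]:
    return [p for p in ("{R1}", "{R2}") if p in template]


def _build(template: str, subs: Sequence[str]) -> str | None:
    smi = template
    for placeholder, sub in zip(_positions(template), subs):
        smi = smi.replace(placeholder, sub)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def generate_dataset(config: SyntheticConfig) -> tuple[list[CompoundRecord], GroundTruth]:
    """Generate a synthetic compound set plus its ground truth.

    Deterministic for a fixed seed. All product SMILES are valid and
    pairwise distinct (symmetric substitutions that collapse to one
    canonical structure are deduplicated; additivity makes their true pIC50
    unambiguous).
    """
    rng = np.random.default_rng(config.seed)
    subs = sorted(config.rgroup_library)
    effects = config.rgroup_library
    sizes = (
        [config.n_per_scaffold] * config.n_scaffolds
        if isinstance(config.n_per_scaffold, int)
        else list(config.n_per_scaffold)[: config.n_scaffolds]
    )
    if len(sizes) < config.n_scaffolds:
        raise ConfigurationError("n_per_scaffold shorter than n_scaffolds")

    records: list[CompoundRecord] = []
    truth = GroundTruth({}, {}, {}, [])
    seen: set[str] = set()
    counter = itertools.count(1)

    def add_compound(scaf_idx: int, canon: str, true: float, category: str, prefix: str = "SYN") -> str:
        cid = f"{prefix}-{next(counter):04d}"
        observed = true + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles=canon,
                pic50=float(observed),
                activity_class=assign_activity_class(float(observed)),
                category=category,
            )
        )
        truth.scaffold_index[cid] = scaf_idx
        truth.true_pic50[cid] = float(true)
        seen.add(canon)
        return cid

    for scaf_idx in range(config.n_scaffolds):
        template, base, steroidal = config.templates[scaf_idx]
        if config.steroid_fraction is not None:
            steroidal = scaf_idx >= config.n_scaffolds * (1 - config.steroid_fraction)
        category = "steroidal" if steroidal else "nonsteroidal"
        n_pos = len(_positions(template))
        truth.scaffold_smiles[scaf_idx] = _build(template, ["[H]"] * n_pos)
        wanted = sizes[scaf_idx]
        made = 0
        attempts = 0
        max_attempts = 200 * max(wanted, 1)
        while made < wanted and attempts < max_attempts:
            attempts += 1
            chosen = [subs[k] for k in rng.integers(0, len(subs), size=n_pos)]
            canon = _build(template, chosen)
            if canon is None or canon in seen:
                continue
            true = base + sum(effects[s] for s in chosen)
            add_compound(scaf_idx, canon, true, category)
            made += 1
        if made < wanted:
            # deterministic fallback: enumerate remaining combinations
            for chosen in itertools.product(subs, repeat=n_pos):
                if made >= wanted:
                    break
                canon = _build(template, list(chosen))
                if canon is None or canon in seen:
                    continue
                true = base + sum(effects[s] for s in chosen)
                add_compound(scaf_idx, canon, true, category)
                made += 1
        if made < wanted:
            raise ConfigurationError(
                f"scaffold {scaf_idx}: template supports only {made} distinct molecules, "
                f"{wanted} requested"
            )

    # plant activity cliffs on two-position scaffolds with mid/high baselines
    cliff_scaffolds = [
        i
        for i in range(config.n_scaffolds)
        if len(_positions(config.templates[i][0])) >= 2
    ]
    if config.n_cliff_pairs > 0 and not cliff_scaffolds:
        raise ConfigurationError("cliff planting needs a template with two positions")
    benign = [s for s in subs if effects[s] >= -0.4]
    planted = 0
    attempts = 0
    while planted < config.n_cliff_pairs and attempts < 500 * max(config.n_cliff_pairs, 1):
        attempts += 1
        scaf_idx = cliff_scaffolds[attempts % len(cliff_scaffolds)]
        template, base, steroidal = config.templates[scaf_idx]
        category = "steroidal" if steroidal else "nonsteroidal"
        n_pos = len(_positions(template))
        base_subs = [benign[k] for k in rng.integers(0, len(benign), size=n_pos)]
        var_subs = list(base_subs)
        var_subs[0] = CLIFF_SUBSTITUENT
        canon_a = _build(template, base_subs)
        canon_b = _build(template, var_subs)
        if canon_a is None or canon_b is None or canon_a in seen or canon_b in seen or canon_a == canon_b:
            continue
        if _ecfp4_tanimoto(canon_a, canon_b) <= 0.5:
            # pair would violate the planted-cliff similarity contract
            continue
        true_a = base + sum(effects[s] for s in base_subs)
        true_b = base + CLIFF_EFFECT + sum(effects[s] for s in base_subs[1:])
        id_a = add_compound(scaf_idx, canon_a, true_a, category, prefix="CLF")
        id_b = add_compound(scaf_idx, canon_b, true_b, category, prefix="CLF")
        truth.cliff_pairs.append((id_a, id_b, abs(true_a - true_b)))
        planted += 1
    if planted < config.n_cliff_pairs:
        raise ConfigurationError("could not plant the requested number of cliff pairs")

    # ground-truth EF at the potent/active threshold, from true pIC50
    ids_by_scaffold: dict[int, list[str]] = {}
    for cid, idx in truth.scaffold_index.items():
        ids_by_scaffold.setdefault(idx, []).append(cid)
    n_total = len(records)
    n_active = sum(truth.true_pic50[r.compound_id] >= 7.0 for r in records)
    p = round(n_active / n_total, 2)
    for idx, ids in ids_by_scaffold.items():
        frac = sum(truth.true_pic50[i] >= 7.0 for i in ids) / len(ids)
        truth.expected_ef[idx] = frac / p if p > 0 else math.nan
    return records, truth


def make_paper_shaped_fixture(seed: int = 42) -> tuple[list[CompoundRecord], GroundTruth]:
    """A ~300-compound noise-free fixture shaped like a curated inhibitor set.

    18 scaffolds with a frequency tail down to singletons, unbalanced
    activity classes, a potent-heavy steroid-like subset, at least three
    all-active scaffolds (EF = 1/p) and one all-inactive scaffold (EF = 0).
    Noise-free so that ground-truth quantities are recovered exactly.
    """
    config = SyntheticConfig(noise_sd=0.0, n_cliff_pairs=5, seed=seed)
    return generate_dataset(config)
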