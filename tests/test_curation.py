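"""Dataset curation: pIC50 transform, class binning, balancing, splitting."""

import collections
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyp17space.curation import (
    ActivityClassScheme,
    CompoundRecord,
    assign_activity_class,
    balance_by_oversampling,
    compute_pic50,
    load_dataset,
    split_train_test,
    strip_salts_and_canonicalize,
)
from cyp17space.errors import ConfigurationError, EmptyDatasetError, StructureError
from cyp17space.synthetic import SyntheticConfig, generate_dataset


def _rec(cid, pic50, smiles="c1ccccc1"):
    return CompoundRecord(cid, smiles, pic50, assign_activity_class(pic50))


@pytest.mark.parametrize(
    "value,unit,expected",
    [
        (1.0, "uM", 6.0),
        (10.0, "nM", 8.0),
        (100.0, "nM", 7.0),
        (50.0, "nM", 7.30103),  # -log10(5e-8)
        (1.0, "M", 0.0),
        (1.0, "pM", 12.0),
    ],
)
def test_compute_pic50(value, unit, expected):
    assert compute_pic50(value, unit) == pytest.approx(expected, abs=1e-5)


def test_compute_pic50_rejects_nonpositive_and_bad_units():
    with pytest.raises(ValueError):
        compute_pic50(0.0, "nM")
    with pytest.raises(ValueError):
        compute_pic50(-5.0, "nM")
    with pytest.raises(ConfigurationError):
        compute_pic50(1.0, "fM")


@given(st.floats(min_value=0.0, max_value=12.0, allow_nan=False))
@settings(max_examples=50, deadline=None)
def test_pic50_round_trip(x):
    """compute_pic50(10^-x, M) = x: the transform inverts exactly."""
    assert compute_pic50(10 ** (-x), "M") == pytest.approx(x, abs=1e-9)


@pytest.mark.parametrize(
    "pic50,label",
    [
        (9.5, "potent"),
        (8.0, "potent"),  # boundary belongs to the upper class
        (7.99, "active"),
        (7.0, "active"),
        (6.5, "intermediate"),
        (6.0, "intermediate"),
        (5.99, "inactive"),
        (-1.0, "inactive"),
    ],
)
def test_activity_class_boundaries(pic50, label):
    assert assign_activity_class(pic50) == label


def test_scheme_validation():
    with pytest.raises(ConfigurationError):
        ActivityClassScheme(thresholds=(6.0, 7.0, 8.0))
    with pytest.raises(ConfigurationError):
        ActivityClassScheme(labels=("a", "b"))


def test_strip_salts_examples():
    assert strip_salts_and_canonicalize("CCO.Cl") == strip_salts_and_canonicalize("CCO")
    assert strip_salts_and_canonicalize("c1ccccc1") == "c1ccccc1"
    # counter-ion removal keeps the organic acetate fragment
    assert "Na" not in strip_salts_and_canonicalize("[Na+].CC(=O)[O-]")
    with pytest.raises(StructureError):
        strip_salts_and_canonicalize("not_a_smiles")


def test_strip_salts_idempotent_on_synthetic_smiles():
    records, _ = generate_dataset(SyntheticConfig(seed=7, noise_sd=0.0))
    smiles = [r.smiles for r in records[:100]]
    for smi in smiles:
        once = strip_salts_and_canonicalize(smi)
        assert strip_salts_and_canonicalize(once) == once


def test_balance_equalizes_class_counts():
    records = (
        [_rec(f"a{i}", 8.5) for i in range(4)]
        + [_rec(f"b{i}", 7.5) for i in range(2)]
        + [_rec(f"c{i}", 6.5) for i in range(1)]
    )
    out = balance_by_oversampling(records, seed=1)
    counts = collections.Counter(r.activity_class for r in out)
    assert counts == {"potent": 4, "active": 4, "intermediate": 4}
    assert len(out) == 12
    # originals all retained
    orig_ids = {r.compound_id for r in records}
    assert orig_ids <= {r.compound_id for r in out}
    # duplicates are copies of existing records
    by_id = {r.compound_id: r for r in records}
    for r in out:
        if r.compound_id not in orig_ids:
            src = by_id[r.compound_id.split("__dup")[0]]
            assert (r.smiles, r.pic50) == (src.smiles, src.pic50)


def test_balance_majority_112_gives_448():
    """Four classes with majority 112 balance to 4 x 112 = 448 records."""
    records = (
        [_rec(f"p{i}", 8.5) for i in range(112)]
        + [_rec(f"a{i}", 7.5) for i in range(43)]
        + [_rec(f"i{i}", 6.5) for i in range(30)]
        + [_rec(f"n{i}", 5.0) for i in range(20)]
    )
    out = balance_by_oversampling(records, seed=42)
    assert len(out) == 448
    counts = collections.Counter(r.activity_class for r in out)
    assert set(counts.values()) == {112}


def test_balance_noop_and_determinism_and_empty():
    records = [_rec("a", 8.5), _rec("b", 7.5)]
    assert balance_by_oversampling(records, seed=0) == records
    big = [_rec(f"x{i}", 8.5) for i in range(5)] + [_rec("y", 5.0)]
    r1 = balance_by_oversampling(big, seed=3)
    r2 = balance_by_oversampling(big, seed=3)
    assert [r.compound_id for r in r1] == [r.compound_id for r in r2]
    with pytest.raises(EmptyDatasetError):
        balance_by_oversampling([], seed=0)


def test_split_sizes_match_ceiling_rule():
    records = [_rec(f"p{i}", 8.5) for i in range(112)] + \
              [_rec(f"a{i}", 7.5) for i in range(112)] + \
              [_rec(f"i{i}", 6.5) for i in range(112)] + \
              [_rec(f"n{i}", 5.0) for i in range(112)]
    train, test = split_train_test(records, 0.2, seed=42)
    assert (len(train), len(test)) == (358, 90)
    small = [_rec(f"x{i}", 8.5) for i in range(5)] + [_rec(f"y{i}", 5.0) for i in range(5)]
    tr, te = split_train_test(small, 0.5, seed=0)
    assert (len(tr), len(te)) == (5, 5)


def test_split_partition_properties():
    records = [_rec(f"x{i}", 8.5 - 0.03 * i) for i in range(60)]
    train, test = split_train_test(records, 0.25, seed=9)
    ids_train = {r.compound_id for r in train}
    ids_test = {r.compound_id for r in test}
    assert ids_train.isdisjoint(ids_test)
    assert ids_train | ids_test == {r.compound_id for r in records}
    train2, test2 = split_train_test(records, 0.25, seed=9)
    assert [r.compound_id for r in test] == [r.compound_id for r in test2]
    with pytest.raises(ConfigurationError):
        split_train_test(records, 1.5, seed=0)


def test_load_dataset_csv_rejects_bad_rows(tmp_path, caplog):
    p = tmp_path / "in.csv"
    p.write_text(
        "compound_id,smiles,ic50,ic50_unit\n"
        "c1,c1ccccc1,100,nM\n"
        "c2,CCO,1,uM\n"
        "c3,not_a_smiles,5,nM\n"
    )
    records = load_dataset(str(p), format="csv")
    assert [r.compound_id for r in records] == ["c1", "c2"]
    assert records[0].pic50 == pytest.approx(7.0)
    assert records[1].pic50 == pytest.approx(6.0)
    assert records[0].activity_class == "active"


def test_load_dataset_duplicates_and_errors(tmp_path):
    p = tmp_path / "dups.csv"
    p.write_text(
        "compound_id,smiles,pic50\n"
        "c1,c1ccccc1,8.0\n"
        "c1,CCO,7.0\n"           # duplicate id -> rejected
        "c2,c1ccccc1.Cl,6.0\n"   # duplicate structure after salt strip -> rejected
    )
    records = load_dataset(str(p))
    assert [r.compound_id for r in records] == ["c1"]
    bad = tmp_path / "nocol.csv"
    bad.write_text("compound_id,foo\nc1,1\n")
    with pytest.raises(ConfigurationError):
        load_dataset(str(bad))
    empty = tmp_path / "empty.csv"
    empty.write_text("compound_id,smiles,pic50\nc1,xxx,8.0\n")
    with pytest.raises(EmptyDatasetError):
        load_dataset(str(empty))


def test_load_dataset_sdf(tmp_path):
    from rdkit import Chem

    out = tmp_path / "mols.sdf"
    writer = Chem.SDWriter(str(out))
    for name, smi, pic in [("m1", "c1ccccc1", 8.2), ("m2", "CCO", 5.5)]:
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("_Name", name)
        mol.SetProp("pic50", str(pic))
        writer.write(mol)
    writer.close()
    records = load_dataset(str(out), format="sdf")
    assert len(records) == 2
    assert records[0].pic50 == pytest.approx(8.2)
    assert records[1].activity_class == "inactive"
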