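import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admetnet.endpoints import EndpointSpec
from admetnet.preprocess import (AssayRecord, aggregate_replicates,
                                 apply_qualifier, build_assay_matrix,
                                 invert_model_scale, to_model_scale)

SOL = EndpointSpec("SOL", "log10_molar")
LOG = EndpointSpec("LOG", "log10")
RAW = EndpointSpec("RAW", "none")


@pytest.mark.parametrize("value,qualifier,expected", [
    (10.0, "lt", 5.0),
    (10.0, "gt", 20.0),
    (7.3, "eq", 7.3),
])
def test_qualifier_rule(value, qualifier, expected):
    assert apply_qualifier(value, qualifier) == pytest.approx(expected)


def test_qualifier_rejects_bad_input():
    with pytest.raises(ValueError):
        apply_qualifier(float("nan"), "eq")
    with pytest.raises(ValueError):
        apply_qualifier(1.0, "le")


def _rec(value, qualifier="eq", endpoint="RAW", smiles="CCO", cid="C1", date=None):
    return AssayRecord(cid, smiles, endpoint, value, qualifier, date)


def test_replicate_averaging():
    assert aggregate_replicates([_rec(5.0)]) == 5.0
    assert aggregate_replicates([_rec(1.0), _rec(3.0)]) == 2.0
    # qualifier applied per record before the mean: (10/2 + 6) / 2
    assert aggregate_replicates([_rec(10.0, "lt"), _rec(6.0)]) == pytest.approx(5.5)
    with pytest.raises(ValueError):
        aggregate_replicates([])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.floats(0.1, 1e4), st.sampled_from(["eq", "lt", "gt"])),
                min_size=1, max_size=8))
def test_aggregation_matches_per_record_oracle(items):
    """Adjust-then-average equals the brute-force per-record computation."""
    records = [_rec(v, q) for v, q in items]
    oracle = sum({"eq": v, "lt": v / 2, "gt": 2 * v}[q] for v, q in items) / len(items)
    assert aggregate_replicates(records) == pytest.approx(oracle, rel=1e-12)


@pytest.mark.parametrize("value,spec,mw,expected", [
    (180.0, SOL, 180.0, -3.0),   # 180 mg/L at MW 180 g/mol is 1 mmol/L
    (100.0, LOG, None, 2.0),
    (120.0, RAW, None, 120.0),   # melting point passes through
])
def test_to_model_scale(value, spec, mw, expected):
    assert to_model_scale(value, spec, mw) == pytest.approx(expected)


def test_log_transform_rejects_nonpositive():
    with pytest.raises(ValueError):
        to_model_scale(0.0, LOG)
    with pytest.raises(ValueError):
        to_model_scale(-5.0, SOL, 100.0)


def test_invert_examples():
    assert invert_model_scale(-3.0, SOL, None, 180.0) == pytest.approx(180.0)
    assert invert_model_scale(0.0, RAW, (42.0, 3.0)) == pytest.approx(42.0)


@settings(derandomize=True, max_examples=100)
@given(st.floats(1e-6, 1e6), st.floats(10.0, 900.0))
def test_transform_round_trip(value, mw):
    for spec in (SOL, LOG, RAW):
        model = to_model_scale(value, spec, mw)
        assert invert_model_scale(model, spec, None, mw) == pytest.approx(value, rel=1e-9)


SPECS = [EndpointSpec("A", "none"), EndpointSpec("B", "log10")]


def test_matrix_bookkeeping():
    records = [
        _rec(1.0, endpoint="A", smiles="CCO", cid="c1"),
        _rec(2.0, endpoint="B", smiles="CCO", cid="c1"),
        _rec(3.0, endpoint="A", smiles="CCN", cid="c2"),
        _rec(4.0, endpoint="A", smiles="CCC", cid="c3"),
    ]
    matrix, molecules = build_assay_matrix(records, SPECS)
    assert matrix.values.shape == (3, 2)
    assert matrix.mask.sum() == 4
    assert [m.canonical_smiles for m in molecules] == matrix.smiles
    assert list(matrix.task_sizes()) == [3, 1]


def test_replicates_collapse_to_mean_cell():
    records = [_rec(2.0, endpoint="A"), _rec(4.0, endpoint="A")]
    matrix, _ = build_assay_matrix(records, SPECS)
    assert matrix.values[0, 0] == pytest.approx(3.0)
    assert matrix.mask.sum() == 1


def test_structure_level_deduplication():
    # same structure registered under two vendor ids and SMILES spellings
    records = [_rec(1.0, endpoint="A", smiles="OCC", cid="v1"),
               _rec(3.0, endpoint="A", smiles="C(O)C", cid="v2")]
    matrix, _ = build_assay_matrix(records, SPECS)
    assert matrix.n_compounds == 1
    assert matrix.values[0, 0] == pytest.approx(2.0)


def test_unparseable_structures_dropped():
    records = [_rec(1.0, endpoint="A"), _rec(2.0, endpoint="A", smiles="not_a_smiles")]
    matrix, _ = build_assay_matrix(records, SPECS)
    assert matrix.n_compounds == 1


def test_standardization_invariants(tiny_matrix):
    matrix, _ = tiny_matrix
    std = matrix.standardized()
    for t in range(std.n_tasks):
        col = std.values[std.mask[:, t], t]
        assert abs(col.mean()) < 1e-6
        assert abs(col.std() - 1.0) < 1e-6
    back = std.destandardized()
    masked = matrix.mask
    assert np.allclose(back.values[masked], matrix.values[masked], atol=1e-9)


def test_scalers_fit_on_training_rows_only(tiny_matrix):
    matrix, _ = tiny_matrix
    train_rows = np.zeros(matrix.n_compounds, bool)
    train_rows[: matrix.n_compounds // 2] = True
    std = matrix.standardized(train_mask=np.broadcast_to(
        train_rows[:, None], matrix.mask.shape))
    fit = matrix.mask & train_rows[:, None]
    for t in range(std.n_tasks):
        col = matrix.values[fit[:, t], t]
        assert std.scalers[t, 0] == pytest.approx(col.mean())
        assert std.scalers[t, 1] == pytest.approx(col.std())
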