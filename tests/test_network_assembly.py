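"""Network assembly: RHS correctness, gating, molar bookkeeping, validation,
and serialization round-trips.

The bookkeeping oracle recomputes every flux with the scalar rate laws by
looping over the process list — fully independent of the vectorized
compilation used by ``assemble_rhs``.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ketoflux as kf
from ketoflux.core import (
    MOLE_EQUIVALENTS,
    Compartment,
    FluxProcess,
    ModelInstance,
    ModelValidationError,
    ProcessKind,
    SpeciesState,
    Substance,
    assemble_jacobian,
    assemble_rhs,
    competitive_rate,
    first_order_rate,
    mole_equivalents,
    saturable_rate,
    zero_order_with_feedback,
)


def two_state_chain(k=1.0, indicator=1):
    states = [
        SpeciesState(1, Compartment.BLOOD, Substance.BHB, 10.0),
        SpeciesState(2, Compartment.TISSUES, Substance.BHB, 0.0),
    ]
    proc = FluxProcess(
        name="a_to_b",
        kind=ProcessKind.FIRST_ORDER,
        source=1,
        products={2: 1.0},
        rate_constant=k,
    )
    return ModelInstance(states=states, processes=[proc])


def reference_rhs(model: ModelInstance, A: np.ndarray) -> np.ndarray:
    """Independent slow oracle: scalar flux laws over the process list."""
    idx = model.state_index()
    dA = np.zeros_like(A)
    for p in model.processes:
        if p.indicator == 0:
            continue
        if p.kind is ProcessKind.FIRST_ORDER:
            rate = first_order_rate(p.rate_constant, max(A[idx[p.source]], 0.0))
        elif p.kind is ProcessKind.SATURABLE:
            rate = saturable_rate(p.vmax, p.km, max(A[idx[p.source]], 0.0))
        elif p.kind is ProcessKind.SATURABLE_COMPETITIVE:
            rate = competitive_rate(
                p.vmax,
                p.km,
                max(A[idx[p.source]], 0.0),
                p.km_j,
                max(A[idx[p.competitor]], 0.0),
            )
        else:
            inhib = [max(A[idx[s]], 0.0) for s in (p.feedback.inhibitor_states if p.feedback else [])]
            rate = zero_order_with_feedback(p.base_rate, p.feedback, inhib)
        flux = p.fraction * rate
        if p.source is not None:
            dA[idx[p.source]] -= flux
        for sid, coeff in p.products.items():
            dA[idx[sid]] += coeff * flux
    return dA


def test_two_state_chain_rhs():
    model = two_state_chain()
    rhs = assemble_rhs(model)
    dA = rhs(0.0, np.array([10.0, 0.0]))
    np.testing.assert_allclose(dA, [-10.0, 10.0])


def test_gate_equivalence_to_zero_rate():
    """Indicator 0 on a process equals the same process with zero rate."""
    gated = two_state_chain(k=1.0)
    gated.processes[0].indicator = 0
    zeroed = two_state_chain(k=0.0)
    A = np.array([7.0, 3.0])
    np.testing.assert_array_equal(assemble_rhs(gated)(0.0, A), assemble_rhs(zeroed)(0.0, A))


def test_full_model_rhs_matches_scalar_oracle(model):
    rng = np.random.default_rng(42)
    rhs = assemble_rhs(model)
    for _ in range(20):
        A = rng.uniform(0.0, 50.0, size=model.n_states)
        np.testing.assert_allclose(rhs(0.0, A), reference_rhs(model, A), rtol=1e-12, atol=1e-12)


def test_jacobian_matches_finite_differences(model):
    rng = np.random.default_rng(7)
    rhs = assemble_rhs(model)
    jac = assemble_jacobian(model)
    A = rng.uniform(0.5, 30.0, size=model.n_states)
    J = jac(0.0, A)
    eps = 1e-6
    for j in range(model.n_states):
        dA = np.zeros(model.n_states)
        dA[j] = eps
        col = (rhs(0.0, A + dA) - rhs(0.0, A - dA)) / (2 * eps)
        np.testing.assert_allclose(J[:, j], col, rtol=1e-5, atol=1e-7)


def test_equivalent_bookkeeping_identity(model):
    """Weighted sum of dA/dt equals the instantaneous endogenous production.

    Every non-production column of the stoichiometry is equivalence-neutral,
    so d/dt Σ(equiv·A) must equal the zero-order input rate alone.
    """
    rng = np.random.default_rng(3)
    rhs = assemble_rhs(model)
    eq = mole_equivalents(model)
    idx = model.state_index()
    for _ in range(10):
        A = rng.uniform(0.0, 40.0, size=model.n_states)
        production = 0.0
        for p in model.processes:
            if p.kind is ProcessKind.ZERO_ORDER and p.indicator == 1:
                inhib = [A[idx[s]] for s in (p.feedback.inhibitor_states if p.feedback else [])]
                rate = zero_order_with_feedback(p.base_rate, p.feedback, inhib)
                production += p.fraction * rate * sum(
                    coeff * eq[idx[s]] for s, coeff in p.products.items()
                )
        assert np.dot(eq, rhs(0.0, A)) == pytest.approx(production, rel=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=2, max_size=2))
def test_chain_rhs_conserves_mass(amounts):
    model = two_state_chain()
    dA = assemble_rhs(model)(0.0, np.array(amounts))
    assert dA.sum() == pytest.approx(0.0, abs=1e-12)


class TestValidation:
    def test_dangling_product(self):
        model = two_state_chain()
        model.processes[0].products = {99: 1.0}
        with pytest.raises(ModelValidationError, match="dangling product state 99"):
            model.validate()

    def test_dangling_source(self):
        model = two_state_chain()
        model.processes[0].source = 42
        with pytest.raises(ModelValidationError, match="dangling source state 42"):
            model.validate()

    def test_partition_fractions_must_sum_to_one(self):
        model = two_state_chain()
        states = model.states + [SpeciesState(3, Compartment.LIVER, Substance.BHB)]
        procs = [
            FluxProcess(
                name=f"split_{i}",
                kind=ProcessKind.FIRST_ORDER,
                source=1,
                products={t: 1.0},
                rate_constant=1.0,
                fraction=f,
                partition="fate",
            )
            for i, (t, f) in enumerate([(2, 0.5), (3, 0.3)])
        ]
        bad = ModelInstance(states=states, processes=procs)
        with pytest.raises(ModelValidationError, match="fractions sum to 0.8"):
            bad.validate()

    def test_sink_cannot_have_outgoing_process(self):
        states = [
            SpeciesState(1, Compartment.FAECES_SINK, Substance.OTHER, 1.0),
            SpeciesState(2, Compartment.BLOOD, Substance.BHB),
        ]
        proc = FluxProcess(
            name="leak",
            kind=ProcessKind.FIRST_ORDER,
            source=1,
            products={2: 1.0},
            rate_constant=1.0,
        )
        with pytest.raises(ModelValidationError, match="sink"):
            ModelInstance(states=states, processes=[proc]).validate()

    def test_assemble_rejects_invalid_model(self):
        model = two_state_chain()
        model.processes[0].products = {99: 1.0}
        with pytest.raises(ModelValidationError):
            assemble_rhs(model)


class TestSerialization:
    def test_json_round_trip_value_identical(self, model, tmp_path):
        p1 = tmp_path / "model.json"
        p2 = tmp_path / "model2.json"
        kf.save_model(model, p1)
        kf.save_model(kf.load_model(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_yaml_round_trip_value_identical(self, model, tmp_path):
        p1 = tmp_path / "model.yaml"
        p2 = tmp_path / "model2.yaml"
        kf.save_model(model, p1)
        kf.save_model(kf.load_model(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_loaded_model_same_rhs(self, model, tmp_path):
        path = tmp_path / "model.json"
        kf.save_model(model, path)
        loaded = kf.load_model(path)
        A = np.linspace(0.0, 10.0, model.n_states)
        np.testing.assert_array_equal(
            assemble_rhs(model)(0.0, A), assemble_rhs(loaded)(0.0, A)
        )


def test_clone_with_indicators_leaves_original_untouched(model):
    clone = model.clone_with_indicators({6, 7})
    assert all(p.indicator == 1 for p in model.processes)
    gated = [p.name for p in clone.processes if p.indicator == 0]
    assert gated and all("upper_distal" in n for n in gated)
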