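"""Builder tests: model structure, transporter anatomy, fixture handling."""

import numpy as np
import pytest

import ketoflux as kf
from ketoflux.builder import (
    ACTIVE_SEGMENTS,
    SEGMENTS,
    BuildError,
    ParameterFixture,
    build_model,
    competitive_links,
    first_order_limit,
)
from ketoflux.core import Compartment, ProcessKind, Substance


def test_five_components(model):
    assert model.components == ["gut", "portal", "liver", "systemic_circulation", "tissues"]


def test_ten_knockout_tags_over_gut_processes(model):
    tags = model.knockout_tag_map()
    assert sorted(tags) == list(range(1, 11))
    for processes in tags.values():
        assert processes  # every tag owns at least one process


def test_gut_segments_and_enterocytes(model):
    lumen_states = [s for s in model.states if s.compartment.value.endswith("_lumen")]
    assert len(lumen_states) == 12  # 4 segments x {ester, butanediol, BHB}
    entero = [s for s in model.states if s.compartment.value.endswith("_enterocyte")]
    assert len(entero) == 3 and all(s.substance is Substance.BHB for s in entero)


def test_transit_chain_ends_in_faeces(model):
    faeces = model.find_state(Compartment.FAECES_SINK, Substance.OTHER)
    last = [p for p in model.processes if p.name.startswith("transit.lower_distal")]
    assert len(last) == 3
    assert all(list(p.products) == [faeces.id] for p in last)


def test_capacity_increases_down_the_gut(fixture):
    for carrier in ("apical_mct1", "apical_smct1", "basolateral_mct4"):
        vmaxes = [fixture.get(f"gut.{seg}.{carrier}.vmax") for seg in ACTIVE_SEGMENTS]
        assert vmaxes == sorted(vmaxes)


def test_smct1_is_high_affinity(fixture):
    for seg in ACTIVE_SEGMENTS:
        assert fixture.get(f"gut.{seg}.apical_smct1.km") < fixture.get(f"gut.{seg}.apical_mct1.km")


def test_builder_rejects_capacity_inversion(fixture):
    bad = fixture.with_overrides({"gut.lower_distal.apical_mct1.vmax": 0.01})
    with pytest.raises(BuildError, match="non-decreasing"):
        build_model(bad)


def test_missing_parameter_named_in_error(fixture):
    entries = fixture.to_dict()
    del entries["portal.to_liver_k"]
    with pytest.raises(BuildError, match="portal.to_liver_k"):
        build_model(ParameterFixture(entries))


def test_unknown_provenance_rejected():
    with pytest.raises(BuildError, match="provenance"):
        ParameterFixture({"x": {"value": 1.0, "provenance": "guessed"}})


class TestCompetitiveLinks:
    def test_liver_blood_and_tissue_pairs(self, model):
        links = competitive_links(model)
        assert len(links) == 8  # 2 substances x 2 interfaces x 2 directions
        for rec in links:
            sub = rec["substrate"].split(":")[1]
            comp = rec["competitor"].split(":")[1]
            assert {sub, comp} == {"BHB", "AcAc"}

    def test_gut_bhb_transport_has_no_competitor(self, model):
        for p in model.processes:
            if p.name.startswith(("apical.", "basolateral.")):
                assert p.kind is ProcessKind.SATURABLE
                assert p.competitor is None

    def test_pinned_competitor_reduces_to_saturable(self, model, baseline):
        """With AcAc absent the competitive BHB fluxes equal the plain
        Michaelis-Menten value, state by state."""
        from ketoflux.core import competitive_rate, saturable_rate

        idx = model.state_index()
        A = baseline.copy()
        for s in model.states:
            if s.substance is Substance.ACAC:
                A[idx[s.id]] = 0.0
        for p in model.processes:
            if p.kind is ProcessKind.SATURABLE_COMPETITIVE:
                a = A[idx[p.source]]
                assert competitive_rate(p.vmax, p.km, a, p.km_j, 0.0) == pytest.approx(
                    saturable_rate(p.vmax, p.km, a)
                )


@pytest.mark.parametrize("seg", ACTIVE_SEGMENTS)
def test_zero_basolateral_vmax_traps_bhb_in_enterocyte(fixture, seg):
    """Shutting the basolateral exit traps BHB intracellularly: the active
    pathway delivers zero cumulative mass to the portal circulation while the
    enterocyte pool accumulates."""
    from ketoflux.core import _CompiledNetwork

    # zero the exit for this segment and every segment upstream of it so the
    # build-time capacity-monotonicity invariant still holds
    upto = ACTIVE_SEGMENTS[: ACTIVE_SEGMENTS.index(seg) + 1]
    trapped = build_model(
        fixture.with_overrides({f"gut.{s}.basolateral_mct4.vmax": 0.0 for s in upto})
    )
    grid = kf.default_grid(3.0, 0.05)
    res = kf.simulate(trapped, kf.DoseEvent(192.0), grid, baseline=kf.equilibrate(trapped))
    net = _CompiledNetwork(trapped)
    names = [p.name for p in trapped.processes if p.indicator == 1]
    fluxes = np.array([net.fluxes(A) for A in res.amounts])
    j = names.index(f"basolateral.{seg}.mct4")
    assert np.trapezoid(fluxes[:, j], res.time) == 0.0  # nothing reaches portal
    entero = next(
        i for i, s in enumerate(trapped.states) if s.compartment.value == f"{seg}_enterocyte"
    )
    apical = [k for k, n in enumerate(names) if n.startswith(f"apical.{seg}.")]
    uptake = sum(np.trapezoid(fluxes[:, k], res.time) for k in apical)
    assert uptake > 0.0
    # trapezoid quadrature of the flux on the output grid vs the ODE integral
    assert res.amounts[-1, entero] == pytest.approx(
        res.amounts[0, entero] + uptake, rel=1e-3
    )


def test_first_order_limit_has_no_saturable_terms(model):
    lin = first_order_limit(model)
    kinds = {p.kind for p in lin.processes}
    assert ProcessKind.SATURABLE not in kinds
    assert ProcessKind.SATURABLE_COMPETITIVE not in kinds
    assert all(p.feedback is None for p in lin.processes)
    # limit slope preserved: k = vmax / km
    orig = {p.name: p for p in model.processes}
    for p in lin.processes:
        if orig[p.name].kind is ProcessKind.SATURABLE:
            assert p.rate_constant == pytest.approx(orig[p.name].vmax / orig[p.name].km)
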