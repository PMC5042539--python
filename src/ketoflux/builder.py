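"""Builder for the whole-body ketone monoester absorption/catabolism model.

The model tracks the oral ketone monoester ((R)-3-hydroxybutyl
(R)-3-hydroxybutyrate) and its products — butane-1,3-diol, d-β-hydroxybutyrate
(BHB), acetoacetate (AcAc), acetone and acetyl-CoA — through five components:

1. **Gut**: four lumen segments (upper/lower proximal, upper/lower distal)
   chained by first-order transit ending in a faeces sink.  The ester is
   hydrolysed to butanediol + BHB along the whole gut; all three species are
   absorbed passively into the portal circulation from every segment; in the
   three segments distal to the upper proximal one, BHB is additionally taken
   up across the apical enterocyte membrane by MCT1 (low affinity, high
   capacity) and SMCT1 (high affinity, low capacity) acting in parallel, and
   exported basolaterally by MCT4.  Transporter capacity (Vmax) increases
   down the gut, mirroring the distal-increasing expression of these proteins.
2. **Portal vein**: transfers absorbed species to the liver.
3. **Liver**: ester hydrolysis, butanediol→BHB, BHB↔AcAc interconversion,
   irreversible AcAc→acetone decarboxylation, and zero-order endogenous AcAc
   production under saturable negative feedback from circulating factors.
   BHB and AcAc exchange with blood through shared MCT1 carriers and hence
   compete for transport; other species move passively.
4. **Systemic circulation (blood)**: ester and butanediol conversion to BHB,
   AcAc→acetone, renal/pulmonary excretion, and the lumped "other" state
   (glucose, insulin, ...) that feeds back on endogenous ketogenesis.
5. **Tissues**: saturable MCT1/MCT2 uptake of BHB and AcAc (again mutually
   competitive), conversion to acetyl-CoA and terminal consumption in the
   Krebs cycle.

Every gut absorption process carries a knockout tag (variants 1–10) so that
indicator gating can remove passive diffusion or apical/basolateral active
transport per segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .core import (
    MOLE_EQUIVALENTS,
    Compartment,
    FeedbackLaw,
    FluxProcess,
    ModelInstance,
    ProcessKind,
    SpeciesState,
    Substance,
)

__all__ = [
    "ParameterFixture",
    "SegmentSpec",
    "load_fixture",
    "default_fixture",
    "build_model",
    "competitive_links",
    "first_order_limit",
    "BuildError",
    "SEGMENTS",
    "ACTIVE_SEGMENTS",
]


class BuildError(ValueError):
    """Raised when the parameter fixture is incomplete or inconsistent."""


#: gut segments in anatomical order (nominally stomach, proximal small
#: intestine, distal small intestine, colon)
SEGMENTS = ("upper_proximal", "lower_proximal", "upper_distal", "lower_distal")
#: segments with carrier-mediated BHB transport (all but the stomach-like one)
ACTIVE_SEGMENTS = ("lower_proximal", "upper_distal", "lower_distal")

_LUMEN = {
    "upper_proximal": Compartment.UPPER_PROXIMAL_LUMEN,
    "lower_proximal": Compartment.LOWER_PROXIMAL_LUMEN,
    "upper_distal": Compartment.UPPER_DISTAL_LUMEN,
    "lower_distal": Compartment.LOWER_DISTAL_LUMEN,
}
_ENTEROCYTE = {
    "lower_proximal": Compartment.LOWER_PROXIMAL_ENTEROCYTE,
    "upper_distal": Compartment.UPPER_DISTAL_ENTEROCYTE,
    "lower_distal": Compartment.LOWER_DISTAL_ENTEROCYTE,
}

#: knockout variant tags: passive diffusion per segment and
#: apical/basolateral active transport per active segment.
PASSIVE_TAG = {"upper_proximal": 1, "lower_proximal": 2, "upper_distal": 5, "lower_distal": 8}
APICAL_TAG = {"lower_proximal": 3, "upper_distal": 6, "lower_distal": 9}
BASOLATERAL_TAG = {"lower_proximal": 4, "upper_distal": 7, "lower_distal": 10}

_GUT_SUBSTANCES = (Substance.ESTER, Substance.BUTANEDIOL, Substance.BHB)


class ParameterFixture:
    """Provenance-tagged parameter table (name -> value, unit, provenance).

    Provenance is one of ``literature``, ``scaled``, ``estimated`` or
    ``fixture-default``.
    """

    PROVENANCES = frozenset({"literature", "scaled", "estimated", "fixture-default"})

    def __init__(self, entries: Mapping[str, Mapping]):
        self.entries: dict[str, dict] = {}
        for name, rec in entries.items():
            rec = dict(rec)
            if "value" not in rec:
                raise BuildError(f"fixture entry {name!r} lacks a value")
            rec.setdefault("unit", "")
            rec.setdefault("provenance", "fixture-default")
            if rec["provenance"] not in self.PROVENANCES:
                raise BuildError(
                    f"fixture entry {name!r}: unknown provenance {rec['provenance']!r}"
                )
            rec["value"] = float(rec["value"])
            self.entries[name] = rec

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> float:
        try:
            return self.entries[name]["value"]
        except KeyError:
            raise BuildError(f"missing fixture parameter {name!r}") from None

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.entries]
        if missing:
            raise BuildError("missing fixture parameters: " + ", ".join(missing))

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterFixture":
        """New fixture with the given values replaced (provenance 'estimated')."""
        entries = {k: dict(v) for k, v in self.entries.items()}
        for name, value in overrides.items():
            if name not in entries:
                raise BuildError(f"cannot override unknown parameter {name!r}")
            entries[name] = {**entries[name], "value": float(value), "provenance": "estimated"}
        return ParameterFixture(entries)

    def to_dict(self) -> dict:
        return {k: dict(v) for k, v in self.entries.items()}


@dataclass(frozen=True)
class SegmentSpec:
    """Resolved kinetic description of one gut segment."""

    name: str
    transit_k: float
    hydrolysis_k: float
    passive_k: dict  # substance value -> 1/h
    has_active_transport: bool
    apical_mct1: tuple[float, float] | None = None  # (vmax mmol/h, km mmol)
    apical_smct1: tuple[float, float] | None = None
    basolateral_mct4: tuple[float, float] | None = None


def load_fixture(path: str | Path) -> ParameterFixture:
    """Load a parameter fixture from JSON or YAML.

    The same schema serves the shipped default fixture and externally supplied
    parameter tables (e.g. a supplementary-table-shaped file for exact
    reproduction runs).
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return ParameterFixture(data)


def default_fixture() -> ParameterFixture:
    """The shipped, documented, plausible default parameterization."""
    ref = resources.files("ketoflux").joinpath("data/fixture_default.json")
    return ParameterFixture(json.loads(ref.read_text()))


def _segment_specs(fx: ParameterFixture) -> list[SegmentSpec]:
    specs = []
    for seg in SEGMENTS:
        active = seg in ACTIVE_SEGMENTS
        spec = SegmentSpec(
            name=seg,
            transit_k=fx.get(f"gut.{seg}.transit_k"),
            hydrolysis_k=fx.get(f"gut.{seg}.hydrolysis_k"),
            passive_k={
                sub.value: fx.get(f"gut.{seg}.passive_k.{sub.value}") for sub in _GUT_SUBSTANCES
            },
            has_active_transport=active,
            apical_mct1=(
                (fx.get(f"gut.{seg}.apical_mct1.vmax"), fx.get(f"gut.{seg}.apical_mct1.km"))
                if active
                else None
            ),
            apical_smct1=(
                (fx.get(f"gut.{seg}.apical_smct1.vmax"), fx.get(f"gut.{seg}.apical_smct1.km"))
                if active
                else None
            ),
            basolateral_mct4=(
                (
                    fx.get(f"gut.{seg}.basolateral_mct4.vmax"),
                    fx.get(f"gut.{seg}.basolateral_mct4.km"),
                )
                if active
                else None
            ),
        )
        specs.append(spec)
    return specs


def _check_segment_invariants(specs: list[SegmentSpec]) -> None:
    """Capacity rises down the gut; SMCT1 is the high-affinity carrier."""
    active = [s for s in specs if s.has_active_transport]
    for attr in ("apical_mct1", "apical_smct1", "basolateral_mct4"):
        vmaxes = [getattr(s, attr)[0] for s in active]
        if any(b < a for a, b in zip(vmaxes, vmaxes[1:])):
            raise BuildError(
                f"{attr} vmax must be non-decreasing down the gut, got {vmaxes}"
            )
    for s in active:
        if not s.apical_smct1[1] < s.apical_mct1[1]:
            raise BuildError(
                f"segment {s.name}: SMCT1 km ({s.apical_smct1[1]}) must be below "
                f"MCT1 km ({s.apical_mct1[1]})"
            )


def build_model(fixture: ParameterFixture | None = None) -> ModelInstance:
    """Assemble and validate the full five-component model from a fixture.

    Raises :class:`BuildError` naming any missing parameters.
    """
    fx = fixture if fixture is not None else default_fixture()
    specs = _segment_specs(fx)
    _check_segment_invariants(specs)

    states: list[SpeciesState] = []
    sid: dict[tuple[Compartment, Substance], int] = {}

    def add_state(compartment: Compartment, substance: Substance, initial: float = 0.0) -> int:
        i = len(states) + 1
        states.append(SpeciesState(i, compartment, substance, initial))
        sid[(compartment, substance)] = i
        return i

    for seg in SEGMENTS:
        for sub in _GUT_SUBSTANCES:
            add_state(_LUMEN[seg], sub)
    for seg in ACTIVE_SEGMENTS:
        add_state(_ENTEROCYTE[seg], Substance.BHB)
    for sub in _GUT_SUBSTANCES:
        add_state(Compartment.PORTAL, sub)
    for sub in (Substance.ESTER, Substance.BUTANEDIOL, Substance.BHB, Substance.ACAC, Substance.ACETONE):
        add_state(Compartment.LIVER, sub)
    for sub in (Substance.ESTER, Substance.BUTANEDIOL, Substance.BHB, Substance.ACAC, Substance.ACETONE):
        add_state(Compartment.BLOOD, sub)
    for sub in (
        Substance.ESTER,
        Substance.BUTANEDIOL,
        Substance.BHB,
        Substance.ACAC,
        Substance.ACETONE,
        Substance.ACETYL_COA,
    ):
        add_state(Compartment.TISSUES, sub)
    faeces = add_state(Compartment.FAECES_SINK, Substance.OTHER)
    excretion = add_state(Compartment.EXCRETION_SINK, Substance.OTHER)
    other = add_state(Compartment.BLOOD, Substance.OTHER)  # lumped feedback factors
    consumption = add_state(Compartment.CONSUMPTION_SINK, Substance.ACETYL_COA)

    procs: list[FluxProcess] = []

    def fo(name, src, dst, k, **kw):
        procs.append(
            FluxProcess(
                name=name,
                kind=ProcessKind.FIRST_ORDER,
                source=src,
                products={dst: 1.0},
                rate_constant=k,
                **kw,
            )
        )

    # -- gut: transit chain, luminal hydrolysis, passive absorption ---------
    for i, seg in enumerate(SEGMENTS):
        spec = specs[i]
        lumen = _LUMEN[seg]
        for sub in _GUT_SUBSTANCES:
            src = sid[(lumen, sub)]
            if i + 1 < len(SEGMENTS):
                dst, coeff = sid[(_LUMEN[SEGMENTS[i + 1]], sub)], 1.0
            else:
                # sinks account in BHB equivalents, so the ester counts double
                dst, coeff = faeces, MOLE_EQUIVALENTS[sub]
            procs.append(
                FluxProcess(
                    name=f"transit.{seg}.{sub.value}",
                    kind=ProcessKind.FIRST_ORDER,
                    source=src,
                    products={dst: coeff},
                    rate_constant=spec.transit_k,
                )
            )
        procs.append(
            FluxProcess(
                name=f"hydrolysis.{seg}",
                kind=ProcessKind.FIRST_ORDER,
                source=sid[(lumen, Substance.ESTER)],
                products={
                    sid[(lumen, Substance.BUTANEDIOL)]: 1.0,
                    sid[(lumen, Substance.BHB)]: 1.0,
                },
                rate_constant=spec.hydrolysis_k,
            )
        )
        for sub in _GUT_SUBSTANCES:
            fo(
                f"passive.{seg}.{sub.value}",
                sid[(lumen, sub)],
                sid[(Compartment.PORTAL, sub)],
                spec.passive_k[sub.value],
                knockout_tags=frozenset({PASSIVE_TAG[seg]}),
            )

    # -- gut: carrier-mediated BHB uptake through the enterocyte ------------
    for seg in ACTIVE_SEGMENTS:
        spec = specs[SEGMENTS.index(seg)]
        lumen_bhb = sid[(_LUMEN[seg], Substance.BHB)]
        entero = sid[(_ENTEROCYTE[seg], Substance.BHB)]
        for carrier, (vmax, km) in (
            ("mct1", spec.apical_mct1),
            ("smct1", spec.apical_smct1),
        ):
            procs.append(
                FluxProcess(
                    name=f"apical.{seg}.{carrier}",
                    kind=ProcessKind.SATURABLE,
                    source=lumen_bhb,
                    products={entero: 1.0},
                    vmax=vmax,
                    km=km,
                    knockout_tags=frozenset({APICAL_TAG[seg]}),
                )
            )
        vmax, km = spec.basolateral_mct4
        procs.append(
            FluxProcess(
                name=f"basolateral.{seg}.mct4",
                kind=ProcessKind.SATURABLE,
                source=entero,
                products={sid[(Compartment.PORTAL, Substance.BHB)]: 1.0},
                vmax=vmax,
                km=km,
                knockout_tags=frozenset({BASOLATERAL_TAG[seg]}),
            )
        )

    # -- portal -> liver -----------------------------------------------------
    k_portal = fx.get("portal.to_liver_k")
    for sub in _GUT_SUBSTANCES:
        fo(
            f"portal_to_liver.{sub.value}",
            sid[(Compartment.PORTAL, sub)],
            sid[(Compartment.LIVER, sub)],
            k_portal,
        )

    # -- liver metabolism ----------------------------------------------------
    L = lambda sub: sid[(Compartment.LIVER, sub)]
    B = lambda sub: sid[(Compartment.BLOOD, sub)]
    T = lambda sub: sid[(Compartment.TISSUES, sub)]
    procs.append(
        FluxProcess(
            name="liver.hydrolysis",
            kind=ProcessKind.FIRST_ORDER,
            source=L(Substance.ESTER),
            products={L(Substance.BUTANEDIOL): 1.0, L(Substance.BHB): 1.0},
            rate_constant=fx.get("liver.hydrolysis_k"),
        )
    )
    fo("liver.butanediol_to_bhb", L(Substance.BUTANEDIOL), L(Substance.BHB), fx.get("liver.butanediol_to_bhb_k"))
    fo("liver.bhb_to_acac", L(Substance.BHB), L(Substance.ACAC), fx.get("liver.bhb_to_acac_k"))
    fo("liver.acac_to_bhb", L(Substance.ACAC), L(Substance.BHB), fx.get("liver.acac_to_bhb_k"))
    fo("liver.acac_to_acetone", L(Substance.ACAC), L(Substance.ACETONE), fx.get("liver.acac_to_acetone_k"))
    feedback = FeedbackLaw(
        inhibitor_states=(B(Substance.BHB), B(Substance.ACAC), other),
        imax=fx.get("feedback.imax"),
        ic50=fx.get("feedback.ic50"),
        weights=(
            fx.get("feedback.weight.BHB"),
            fx.get("feedback.weight.AcAc"),
            fx.get("feedback.weight.other"),
        ),
    )
    procs.append(
        FluxProcess(
            name="liver.endogenous_acac_production",
            kind=ProcessKind.ZERO_ORDER,
            products={L(Substance.ACAC): 1.0},
            base_rate=fx.get("liver.endogenous_acac_rate"),
            feedback=feedback,
        )
    )

    # -- liver <-> blood transport (MCT1, BHB/AcAc mutually competitive) ----
    for sub, comp in ((Substance.BHB, Substance.ACAC), (Substance.ACAC, Substance.BHB)):
        procs.append(
            FluxProcess(
                name=f"mct1.liver_to_blood.{sub.value}",
                kind=ProcessKind.SATURABLE_COMPETITIVE,
                source=L(sub),
                products={B(sub): 1.0},
                vmax=fx.get(f"transport.liver_to_blood.{sub.value}.vmax"),
                km=fx.get(f"transport.liver_to_blood.{sub.value}.km"),
                competitor=L(comp),
                km_j=fx.get(f"transport.liver_to_blood.{comp.value}.km"),
            )
        )
        procs.append(
            FluxProcess(
                name=f"mct1.blood_to_liver.{sub.value}",
                kind=ProcessKind.SATURABLE_COMPETITIVE,
                source=B(sub),
                products={L(sub): 1.0},
                vmax=fx.get(f"transport.blood_to_liver.{sub.value}.vmax"),
                km=fx.get(f"transport.blood_to_liver.{sub.value}.km"),
                competitor=B(comp),
                km_j=fx.get(f"transport.blood_to_liver.{comp.value}.km"),
            )
        )
    for sub in (Substance.ESTER, Substance.BUTANEDIOL, Substance.ACETONE):
        k = fx.get(f"transport.liver_blood_passive.{sub.value}.k")
        fo(f"passive.liver_to_blood.{sub.value}", L(sub), B(sub), k)
        fo(f"passive.blood_to_liver.{sub.value}", B(sub), L(sub), k)

    # -- blood metabolism, "other" pool, excretion ---------------------------
    procs.append(
        FluxProcess(
            name="blood.hydrolysis",
            kind=ProcessKind.FIRST_ORDER,
            source=B(Substance.ESTER),
            products={B(Substance.BUTANEDIOL): 1.0, B(Substance.BHB): 1.0},
            rate_constant=fx.get("blood.hydrolysis_k"),
        )
    )
    fo("blood.butanediol_to_bhb", B(Substance.BUTANEDIOL), B(Substance.BHB), fx.get("blood.butanediol_to_bhb_k"))
    fo("blood.acac_to_acetone", B(Substance.ACAC), B(Substance.ACETONE), fx.get("blood.acac_to_acetone_k"))
    procs.append(
        FluxProcess(
            name="blood.other_production",
            kind=ProcessKind.ZERO_ORDER,
            products={other: 1.0},
            base_rate=fx.get("blood.other_production_rate"),
        )
    )
    fo("blood.other_elimination", other, excretion, fx.get("blood.other_elimination_k"))
    fo("excretion.renal.BHB", B(Substance.BHB), excretion, fx.get("excretion.renal_bhb_k"))
    fo("excretion.renal.AcAc", B(Substance.ACAC), excretion, fx.get("excretion.renal_acac_k"))
    fo("excretion.exhaled.acetone", B(Substance.ACETONE), excretion, fx.get("excretion.acetone_exhalation_k"))

    # -- blood <-> tissues (lumped MCT1/MCT2, mutually competitive) ----------
    for sub, comp in ((Substance.BHB, Substance.ACAC), (Substance.ACAC, Substance.BHB)):
        procs.append(
            FluxProcess(
                name=f"mct.blood_to_tissues.{sub.value}",
                kind=ProcessKind.SATURABLE_COMPETITIVE,
                source=B(sub),
                products={T(sub): 1.0},
                vmax=fx.get(f"transport.blood_to_tissues.{sub.value}.vmax"),
                km=fx.get(f"transport.blood_to_tissues.{sub.value}.km"),
                competitor=B(comp),
                km_j=fx.get(f"transport.blood_to_tissues.{comp.value}.km"),
            )
        )
        procs.append(
            FluxProcess(
                name=f"mct.tissues_to_blood.{sub.value}",
                kind=ProcessKind.SATURABLE_COMPETITIVE,
                source=T(sub),
                products={B(sub): 1.0},
                vmax=fx.get(f"transport.tissues_to_blood.{sub.value}.vmax"),
                km=fx.get(f"transport.tissues_to_blood.{sub.value}.km"),
                competitor=T(comp),
                km_j=fx.get(f"transport.tissues_to_blood.{comp.value}.km"),
            )
        )
    for sub in (Substance.ESTER, Substance.BUTANEDIOL, Substance.ACETONE):
        k = fx.get(f"transport.blood_tissues_passive.{sub.value}.k")
        fo(f"passive.blood_to_tissues.{sub.value}", B(sub), T(sub), k)
        fo(f"passive.tissues_to_blood.{sub.value}", T(sub), B(sub), k)

    # -- tissue consumption --------------------------------------------------
    fo("tissues.bhb_to_acetylcoa", T(Substance.BHB), T(Substance.ACETYL_COA), fx.get("tissues.bhb_to_acetylcoa_k"))
    fo("tissues.acac_to_acetylcoa", T(Substance.ACAC), T(Substance.ACETYL_COA), fx.get("tissues.acac_to_acetylcoa_k"))
    fo("tissues.krebs_consumption", T(Substance.ACETYL_COA), consumption, fx.get("tissues.acetylcoa_consumption_k"))

    model = ModelInstance(
        states=states,
        processes=procs,
        parameters=fx.to_dict(),
        metadata={
            "components": ["gut", "portal", "liver", "systemic_circulation", "tissues"],
            "knockout_tags": sorted(set(PASSIVE_TAG.values()) | set(APICAL_TAG.values()) | set(BASOLATERAL_TAG.values())),
            "segments": list(SEGMENTS),
            "active_segments": list(ACTIVE_SEGMENTS),
            "blood_volume_L": fx.get("physiology.blood_volume_L"),
            "body_weight_kg": fx.get("physiology.body_weight_kg"),
            "ester_molar_mass_g_per_mol": fx.get("physiology.ester_molar_mass_g_per_mol"),
        },
    )
    model.validate()
    return model


def competitive_links(model: ModelInstance) -> list[dict]:
    """List the BHB/AcAc shared-carrier transport pairs in the model.

    Each record names the process, its substrate and the competing state.
    """
    idx = {s.id: s for s in model.states}
    out = []
    for p in model.processes:
        if p.kind is ProcessKind.SATURABLE_COMPETITIVE:
            out.append(
                {
                    "process": p.name,
                    "substrate": idx[p.source].label,
                    "competitor": idx[p.competitor].label,
                }
            )
    return out


def first_order_limit(model: ModelInstance) -> ModelInstance:
    """Clone with every saturable process replaced by its vmax/km first-order
    limit and feedback removed; the result is a linear system (zero-order
    inputs become constant), useful as a dose-superposition reference."""
    clone = model.clone()
    for p in clone.processes:
        if p.kind in (ProcessKind.SATURABLE, ProcessKind.SATURABLE_COMPETITIVE):
            p.kind = ProcessKind.FIRST_ORDER
            p.rate_constant = p.vmax / p.km
            p.vmax = None
            p.km = None
            p.competitor = None
            p.km_j = None
        elif p.kind is ProcessKind.ZERO_ORDER and p.feedback is not None:
            p.feedback = None
    clone.validate()
    return clone
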