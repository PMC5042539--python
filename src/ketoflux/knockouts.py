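"""In silico knockout catalogue and application.

Ten knockout variants cover the gut absorption machinery: one passive-diffusion
knockout per segment (removing passive transfer of ester, butanediol and BHB
into the portal circulation from that segment) and apical/basolateral
active-transport knockouts for each of the three carrier-expressing segments
(removing MCT1+SMCT1 uptake or MCT4 export of BHB).  Fifteen combination sets
explore single processes, regions, and process classes across the whole gut.

Knockouts are applied by indicator gating: every gut absorption process is
tagged at build time with the variant ids that own it, and applying a set
clones the model with indicator=0 on every tagged process.  Gating a process
off is trajectory-identical to deleting it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import ModelInstance

__all__ = ["KnockoutVariant", "KnockoutSet", "catalogue", "combination_sets", "apply_knockout"]


@dataclass(frozen=True)
class KnockoutVariant:
    """One knockout: a process class in one gut segment."""

    id: int
    process_kind: str  # passive | active_apical | active_basolateral
    region: str  # segment name
    substrates: frozenset[str]


@dataclass(frozen=True)
class KnockoutSet:
    """A combination of knockout variants explored together."""

    set_id: int
    variant_ids: frozenset[int]
    label: str


_PASSIVE_SUBSTRATES = frozenset({"ester", "butanediol", "BHB"})
_ACTIVE_SUBSTRATES = frozenset({"BHB"})

_CATALOGUE: tuple[KnockoutVariant, ...] = (
    KnockoutVariant(1, "passive", "upper_proximal", _PASSIVE_SUBSTRATES),
    KnockoutVariant(2, "passive", "lower_proximal", _PASSIVE_SUBSTRATES),
    KnockoutVariant(3, "active_apical", "lower_proximal", _ACTIVE_SUBSTRATES),
    KnockoutVariant(4, "active_basolateral", "lower_proximal", _ACTIVE_SUBSTRATES),
    KnockoutVariant(5, "passive", "upper_distal", _PASSIVE_SUBSTRATES),
    KnockoutVariant(6, "active_apical", "upper_distal", _ACTIVE_SUBSTRATES),
    KnockoutVariant(7, "active_basolateral", "upper_distal", _ACTIVE_SUBSTRATES),
    KnockoutVariant(8, "passive", "lower_distal", _PASSIVE_SUBSTRATES),
    KnockoutVariant(9, "active_apical", "lower_distal", _ACTIVE_SUBSTRATES),
    KnockoutVariant(10, "active_basolateral", "lower_distal", _ACTIVE_SUBSTRATES),
)

_SETS: tuple[tuple[int, tuple[int, ...], str], ...] = (
    (1, (1,), "Passive diffusion, upper proximal gut"),
    (2, (2,), "Passive diffusion, lower proximal gut"),
    (3, (5,), "Passive diffusion, upper distal gut"),
    (4, (8,), "Passive diffusion, lower distal gut"),
    (5, (3, 4), "Active absorption, lower proximal gut"),
    (6, (6, 7), "Active absorption, upper distal gut"),
    (7, (9, 10), "Active absorption, lower distal gut"),
    (8, (1,), "Passive diffusion, upper proximal gut"),
    (9, (2, 3, 4), "Passive diffusion & active absorption, lower proximal gut"),
    (10, (5, 6, 7), "Passive diffusion & active absorption, upper distal gut"),
    (11, (8, 9, 10), "Passive diffusion & active absorption, lower distal gut"),
    (12, (1, 2, 5, 8), "Passive diffusion, whole gut"),
    (13, (3, 4, 6, 7, 9, 10), "Active absorption, whole gut"),
    (14, (1, 2, 3, 4), "Passive diffusion & active absorption, proximal gut"),
    (15, (5, 6, 7, 8, 9, 10), "Passive diffusion & active absorption, distal gut"),
)


def catalogue() -> list[KnockoutVariant]:
    """The ten knockout variants across the length of the gut."""
    return list(_CATALOGUE)


def combination_sets() -> list[KnockoutSet]:
    """The fifteen explored combinations of knockout variants."""
    return [KnockoutSet(sid, frozenset(vids), label) for sid, vids, label in _SETS]


def get_set(set_id: int) -> KnockoutSet:
    for s in combination_sets():
        if s.set_id == set_id:
            return s
    raise KeyError(f"unknown knockout set {set_id}")


def apply_knockout(
    model: ModelInstance, knockout: KnockoutSet | frozenset[int] | set[int] | list[int]
) -> ModelInstance:
    """Return a clone with indicator=0 on every process owned by the set.

    The original model is untouched.  Applying an empty set returns a
    trajectory-identical clone; application is idempotent and commutes over
    disjoint sets.  Unknown variant ids raise ``KeyError``.
    """
    if isinstance(knockout, KnockoutSet):
        variant_ids = knockout.variant_ids
    else:
        variant_ids = frozenset(knockout)
    known = {v.id for v in _CATALOGUE}
    unknown = variant_ids - known
    if unknown:
        raise KeyError(f"unknown knockout variant(s): {sorted(unknown)}")
    return model.clone_with_indicators(variant_ids)
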