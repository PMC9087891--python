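"""Enumeration of unidentifiable towers of BDI models.

A BDI event between sister branches makes the posterior invariant under
the involution

    phi_X -> 1 - phi_X,  phi_Y -> 1 - phi_Y,  theta_X <-> theta_Y,

so every point Theta has a mirror point Theta' with identical
likelihood.  With m sister BDI events and n nonsister BDI events a model
has 2^n unidentifiable model variants (mirrored topologies), each with
2^m within-model towers.  Two BDI events stacked between the same two
species (a double-BDI) jointly admit four transforms forming a Klein
four-group; these replace the two independent sister involutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import BDIEvent, MSciModel, detect_bdi_events

__all__ = [
    "TowerMapping",
    "ModelVariant",
    "TowerSet",
    "identity_mapping",
    "single_bdi_mapping",
    "double_bdi_mappings",
    "compose",
    "apply_mapping",
    "enumerate_towers",
    "find_stacked_pairs",
]
# find_stacked_pairs: two BDI events are "stacked" iff the parental
# branches of the lower pair are exactly the two child branches of the
# upper pair (the double-BDI geometry).


@dataclass(frozen=True)
class TowerMapping:
    """A parameter transform between unidentifiable towers.

    ``moves`` sends each affected target parameter to
    ``(source parameter, complement?)``: the new value of the target is
    the source's old value, or one minus it when the complement flag is
    set.  Complements apply only to phi entries; plain renames swap
    theta (or phi) values within one event.  Parameters absent from
    ``moves`` are copied unchanged.  Every mapping produced here is an
    involution.
    """

    moves: tuple[tuple[str, str, bool], ...] = ()  # (target, source, complement)
    topology_flips: tuple[str, ...] = ()  # nonsister event ids whose subtrees swap
    events: tuple[str, ...] = ()
    code: int = 0  # binary tower code (youngest event = least-significant bit)

    @property
    def is_identity(self) -> bool:
        return not self.moves and not self.topology_flips

    def moves_dict(self) -> dict[str, tuple[str, bool]]:
        return {t: (s, c) for t, s, c in self.moves}

    def describe(self) -> list[tuple[str, str]]:
        """Human-readable (parameter, transform) rows."""
        out = []
        for t, s, c in self.moves:
            if c and s == t:
                out.append((t, f"1 - {s}"))
            elif c:
                out.append((t, f"1 - {s}"))
            elif s != t:
                out.append((t, s))
        return out


def identity_mapping(events: Iterable[str] = (), code: int = 0) -> TowerMapping:
    return TowerMapping(moves=(), events=tuple(events), code=code)


def single_bdi_mapping(event: BDIEvent) -> TowerMapping:
    """The within-event involution: complement both phis, swap the two
    parental thetas; everything else identity."""
    px, py = event.phi_params
    tx, ty = event.theta_params
    return TowerMapping(
        moves=((px, px, True), (py, py, True), (tx, ty, False), (ty, tx, False)),
        events=(_event_id(event),),
        code=1,
    )


def double_bdi_mappings(lower: BDIEvent, upper: BDIEvent) -> list[TowerMapping]:
    """The four transforms z=0..3 of a stacked double-BDI event.

    With (phi_X, phi_Y, theta_X, theta_Y) the lower-event parameters and
    (phi_Z, phi_W, theta_Z, theta_W) the upper-event parameters:

    * z=0: identity;
    * z=1: complement phi_Z, phi_W and swap theta_Z, theta_W;
    * z=2: complement phi_X, phi_Y, swap theta_X, theta_Y, swap
      phi_Z, phi_W, swap theta_Z, theta_W;
    * z=3: complement phi_X, phi_Y, swap theta_X, theta_Y, and set
      phi_Z' = 1 - phi_W, phi_W' = 1 - phi_Z.

    The set is closed under composition and each element is its own
    inverse (a Klein four-group; composition is XOR on z).
    """
    if lower.time >= upper.time or set(lower.params) & set(upper.params):
        raise ValueError("events are not a stacked double-BDI between the same two species")
    px, py = lower.phi_params
    tx, ty = lower.theta_params
    pz, pw = upper.phi_params
    tz, tw = upper.theta_params
    evs = (_event_id(lower), _event_id(upper))
    z0 = TowerMapping(moves=(), events=evs, code=0)
    z1 = TowerMapping(
        moves=((pz, pz, True), (pw, pw, True), (tz, tw, False), (tw, tz, False)),
        events=evs,
        code=1,
    )
    z2 = TowerMapping(
        moves=(
            (px, px, True), (py, py, True), (tx, ty, False), (ty, tx, False),
            (pz, pw, False), (pw, pz, False), (tz, tw, False), (tw, tz, False),
        ),
        events=evs,
        code=2,
    )
    z3 = TowerMapping(
        moves=(
            (px, px, True), (py, py, True), (tx, ty, False), (ty, tx, False),
            (pz, pw, True), (pw, pz, True),
        ),
        events=evs,
        code=3,
    )
    return [z0, z1, z2, z3]


def compose(first: TowerMapping, second: TowerMapping, code: int | None = None) -> TowerMapping:
    """The mapping equivalent to applying ``first`` then ``second``."""
    m1 = first.moves_dict()
    m2 = second.moves_dict()
    combined: dict[str, tuple[str, bool]] = {}
    for target in set(m1) | set(m2):
        src2, c2 = m2.get(target, (target, False))
        src1, c1 = m1.get(src2, (src2, False))
        combined[target] = (src1, c1 ^ c2)
    moves = tuple(
        (t, s, c) for t, (s, c) in sorted(combined.items()) if not (s == t and not c)
    )
    flips = tuple(sorted(set(first.topology_flips) ^ set(second.topology_flips)))
    return TowerMapping(
        moves=moves,
        topology_flips=flips,
        events=tuple(dict.fromkeys(first.events + second.events)),
        code=first.code | second.code if code is None else code,
    )


def apply_mapping(row: Mapping[str, float], mapping: TowerMapping) -> dict[str, float]:
    """Transform a named parameter vector; parameters outside the
    mapping are copied unchanged."""
    missing = [t for t, s, _ in mapping.moves if s not in row or t not in row]
    if missing:
        raise KeyError(f"row is missing mapped parameter(s): {sorted(set(missing))}")
    out = dict(row)
    for target, source, comp in mapping.moves:
        v = row[source]
        out[target] = 1.0 - v if comp else v
    return out


# ---------------------------------------------------------------------------
# enumeration


@dataclass
class ModelVariant:
    """One of the 2^n mirrored-topology variants of an MSci model."""

    topology_tag: tuple[str, ...]  # flipped nonsister event ids; () = input model
    cross_mapping: TowerMapping  # maps variant-0 parameters onto this variant
    tower_mappings: list[TowerMapping] = field(default_factory=list)


@dataclass
class TowerSet:
    variants: list[ModelVariant]
    m: int  # sister BDI events (stacked pairs count as two)
    n: int  # nonsister BDI events

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def towers_per_variant(self) -> int:
        return len(self.variants[0].tower_mappings) if self.variants else 1

    @property
    def total(self) -> int:
        return sum(len(v.tower_mappings) for v in self.variants)


def _event_id(event: BDIEvent) -> str:
    return "-".join(event.nodes)


def find_stacked_pairs(model: MSciModel, events: list[BDIEvent]) -> list[tuple[BDIEvent, BDIEvent]]:
    pairs = []
    for lo in events:
        for up in events:
            if lo is up:
                continue
            lx, ly = lo.nodes
            parents = {model.nodes[lx].parent, model.nodes[ly].parent}
            if parents == set(up.nodes) and lo.time < up.time:
                pairs.append((lo, up))
    return pairs


def enumerate_towers(model: MSciModel) -> TowerSet:
    """Enumerate all 2^n model variants x 2^m within-model towers.

    Sister events contribute the within-model involutions (stacked
    double-BDI pairs contribute their four joint transforms instead of
    two independent ones); nonsister events contribute mirrored-topology
    model variants whose mappings carry a topology edit alongside the
    parameter renames.  Towers within a variant are ordered by binary
    code over events, youngest event = least-significant bit.
    """
    events = detect_bdi_events(model)
    stacked = find_stacked_pairs(model, events)
    in_stack = {id(e) for pair in stacked for e in pair}

    sister = [e for e in events if e.sister and id(e) not in in_stack]
    nonsister = [e for e in events if not e.sister and id(e) not in in_stack]
    m = len(sister) + 2 * len(stacked)
    n = len(nonsister)

    # within-model groups, youngest first (events come pre-sorted by time)
    groups: list[tuple[float, list[TowerMapping]]] = []
    for e in sister:
        groups.append((e.time, [identity_mapping((_event_id(e),)), single_bdi_mapping(e)]))
    for lo, up in stacked:
        groups.append((lo.time, double_bdi_mappings(lo, up)))
    groups.sort(key=lambda g: g[0])

    within: list[TowerMapping] = [identity_mapping()]
    shift = 0
    for _, maps in groups:
        bits = max(1, (len(maps) - 1).bit_length())
        within = [
            compose(w, g, code=w.code | (g.code << shift)) for g in maps for w in within
        ]
        shift += bits
    within.sort(key=lambda t: t.code)

    variants: list[ModelVariant] = []
    for mask in range(2 ** n):
        flipped = [e for i, e in enumerate(nonsister) if mask >> i & 1]
        cross = identity_mapping()
        for e in flipped:
            em = single_bdi_mapping(e)
            em = TowerMapping(
                moves=em.moves, topology_flips=(_event_id(e),), events=em.events, code=0
            )
            cross = compose(cross, em)
        variants.append(
            ModelVariant(
                topology_tag=tuple(_event_id(e) for e in flipped),
                cross_mapping=cross,
                tower_mappings=list(within),
            )
        )
    return TowerSet(variants=variants, m=m, n=n)
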