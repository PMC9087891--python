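"""MSci model representation: species trees with episodic introgression.

An MSci model is a rooted species tree augmented with pairs of
introgression nodes.  A *bidirectional introgression* (BDI) event places
two hybridization nodes, one on each of two contemporaneous branches, at
a shared time; lineages traced backwards through either node may cross
to the partner branch.  A *unidirectional* (UDI) event places a hybrid
node on the recipient branch and a plain pass-through node on the donor
branch.

Parameterization and conventions
--------------------------------
* Times (``tau``) and population sizes (``theta``) are measured in
  expected substitutions per site; the pairwise coalescent rate in a
  population of size theta is 2/theta.  Leaves sit at time 0.
* Every branch of the MSci graph carries a theta, named by its daughter
  node ("branch A" is the branch from node A up to its parent); the
  root stem carries ``theta_R``.
* ``phi`` at a hybrid node is the probability that a lineage entering
  the node takes the HORIZONTAL (cross-species) parent path; 1 - phi is
  the probability of the vertical path.  This matches the bpp
  convention in which, e.g., sequences from A passing node X continue
  into the population above X with probability 1 - phi_X.

Model-spec text format (line oriented, ``#`` comments)::

    tree (((A,B)S,C)R;)
    bdi X=A@0.00125 Y=B@0.00125
    udi H=C@0.002 D=S@0.002
    tau R=0.005 S=0.0025
    theta A=0.01 B=0.01 X=0.01 Y=0.01 S=0.01 C=0.01 R=0.01 ...
    phi X=0.1 Y=0.2

``bdi``/``udi`` lines name the new nodes and the branches (by daughter
node) on which they are inserted, with the shared event time after
``@``.  For ``udi`` the first node is the hybrid (recipient-branch)
node, the second the donor-branch pass-through node.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "MSciModel",
    "Node",
    "IntrogressionEvent",
    "BDIEvent",
    "ModelSyntaxError",
    "parse_model",
    "write_model",
    "count_parameters",
    "detect_bdi_events",
    "classify_bdi",
    "validate",
]

LEAF = "leaf"
SPECIATION = "speciation"
HYBRID = "hybrid"
CONNECTOR = "connector"  # donor-branch node of a UDI event (no phi)


class ModelSyntaxError(ValueError):
    """Raised when a model-spec text cannot be parsed into a valid graph."""


@dataclass
class Node:
    name: str
    kind: str
    parent: str | None = None
    children: list[str] = field(default_factory=list)
    partner: str | None = None  # other node of the introgression pair
    event: str | None = None  # event id this node belongs to


@dataclass
class IntrogressionEvent:
    """A pair of introgression nodes inserted at a shared time.

    For a BDI event both nodes are hybrid; for a UDI event only the
    first is (the recipient-branch node).
    """

    id: str
    nodes: tuple[str, str]
    time: float
    bidirectional: bool


@dataclass
class BDIEvent:
    """A detected bidirectional-introgression node pair.

    ``theta_params`` name the sizes of the two parental populations
    directly above the pair (branches named by the hybrid nodes
    themselves); ``sister`` is determined purely by topology on the
    condensed graph (see :func:`classify_bdi`).
    """

    nodes: tuple[str, str]
    time: float
    phi_params: tuple[str, str]
    theta_params: tuple[str, str]
    sister: bool

    @property
    def params(self) -> tuple[str, str, str, str]:
        return self.phi_params + self.theta_params


@dataclass
class MSciModel:
    nodes: dict[str, Node]
    root: str
    tau: dict[str, float]  # per internal node (hybrid pair members share)
    theta: dict[str, float]  # per branch, keyed by daughter node
    phi: dict[str, float]  # per hybrid node
    events: list[IntrogressionEvent] = field(default_factory=list)
    newick: str = ""  # backbone tree as given, without inserted nodes

    # -- convenience -------------------------------------------------
    def node_time(self, name: str) -> float:
        if self.nodes[name].kind == LEAF:
            return 0.0
        return self.tau[name]

    def leaves(self) -> list[str]:
        return [n for n, nd in self.nodes.items() if nd.kind == LEAF]

    def parameter_names(self) -> list[str]:
        """All free parameters, in a deterministic order.

        One tau per speciation node plus one per event (named after the
        event's first node); one theta per branch; one phi per hybrid
        node.
        """
        names: list[str] = []
        for n, nd in sorted(self.nodes.items()):
            if nd.kind == SPECIATION:
                names.append(f"tau_{n}")
        for ev in self.events:
            names.append(f"tau_{ev.nodes[0]}")
        names += [f"theta_{n}" for n in sorted(self.nodes)]
        names += [f"phi_{n}" for n in sorted(self.phi)]
        return names

    def parameter_vector(self) -> dict[str, float]:
        vec: dict[str, float] = {}
        for name in self.parameter_names():
            kind, _, node = name.partition("_")
            vec[name] = {"tau": self.tau, "theta": self.theta, "phi": self.phi}[kind][node]
        return vec


# ---------------------------------------------------------------------------
# parsing


def _parse_backbone(newick: str) -> tuple[dict[str, Node], str]:
    """Parse the labeled Newick backbone into a node table."""
    text = newick.strip().replace(";", "")
    if not text:
        raise ModelSyntaxError("empty tree line")
    try:
        tree = dendropy.Tree.get(
            data=text + ";",
            schema="newick",
            suppress_internal_node_taxa=False,
            suppress_leaf_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ModelSyntaxError(f"cannot parse tree: {exc}") from exc

    nodes: dict[str, Node] = {}

    # `tree ((A,B)R;)` style input leaves an anonymous single-child root
    # wrapper; collapse it so R is the true root
    seed = tree.seed_node
    while (seed.taxon is None and not seed.label
           and len(seed.child_nodes()) == 1):
        seed = seed.child_nodes()[0]
        seed.parent_node = None
        tree.seed_node = seed

    def label(nd: dendropy.Node) -> str:
        lab = nd.taxon.label if nd.taxon is not None else nd.label
        if not lab:
            raise ModelSyntaxError("every node in the tree line must be labeled")
        return str(lab).strip()

    for nd in tree.preorder_node_iter():
        name = label(nd)
        if name in nodes:
            raise ModelSyntaxError(f"duplicate node name {name!r} in tree")
        kind = LEAF if nd.is_leaf() else SPECIATION
        parent = label(nd.parent_node) if nd.parent_node is not None else None
        nodes[name] = Node(name=name, kind=kind, parent=parent)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nodes[label(nd.parent_node)].children.append(label(nd))
    root = label(tree.seed_node)
    return nodes, root


def _parse_assignments(rest: str, line_no: int) -> list[tuple[str, str]]:
    pairs = []
    for tok in rest.split():
        if "=" not in tok:
            raise ModelSyntaxError(f"line {line_no}: expected name=value, got {tok!r}")
        k, _, v = tok.partition("=")
        pairs.append((k.strip(), v.strip()))
    return pairs


def _insert_event(
    nodes: dict[str, Node],
    event_times: dict[str, float],
    new_name: str,
    base: str,
    time: float,
    kind: str,
    line_no: int,
) -> None:
    """Insert a new event node on the branch above ``base`` at ``time``.

    If earlier events already placed nodes on this branch, climb past
    those with a smaller time so that stacked events nest correctly.
    """
    if new_name in nodes:
        raise ModelSyntaxError(f"line {line_no}: node name {new_name!r} already in use")
    if base not in nodes:
        raise ModelSyntaxError(f"line {line_no}: unknown branch/species name {base!r}")
    cur = base
    while True:
        par = nodes[cur].parent
        if par is None:
            break
        if nodes[par].kind in (HYBRID, CONNECTOR) and event_times[par] < time:
            cur = par
        else:
            break
    par = nodes[cur].parent
    if par is None:
        raise ModelSyntaxError(
            f"line {line_no}: cannot insert {new_name!r} above the root node {cur!r}"
        )
    nodes[new_name] = Node(name=new_name, kind=kind, parent=par, children=[cur])
    nodes[par].children = [new_name if c == cur else c for c in nodes[par].children]
    nodes[cur].parent = new_name
    event_times[new_name] = time


def parse_model(text: str) -> MSciModel:
    """Parse a model-spec string into a structurally valid :class:`MSciModel`.

    Raises :class:`ModelSyntaxError` on malformed input and
    :class:`ValueError` on out-of-range parameter values (phi outside
    [0, 1], nonpositive tau/theta).  Semantic invariants (time ordering,
    equal pair times) are checked by :func:`validate`.
    """
    nodes: dict[str, Node] | None = None
    root = ""
    newick = ""
    events: list[IntrogressionEvent] = []
    event_times: dict[str, float] = {}
    tau: dict[str, float] = {}
    theta: dict[str, float] = {}
    phi: dict[str, float] = {}

    for line_no, raw in enumerate(io.StringIO(text), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        keyword, _, rest = line.partition(" ")
        keyword = keyword.lower()
        if keyword == "tree":
            if nodes is not None:
                raise ModelSyntaxError(f"line {line_no}: duplicate tree line")
            nodes, root = _parse_backbone(rest)
            newick = rest.strip().strip(";").replace(";", "")
        elif keyword in ("bdi", "udi"):
            if nodes is None:
                raise ModelSyntaxError(f"line {line_no}: {keyword} before tree line")
            pairs = _parse_assignments(rest, line_no)
            if len(pairs) != 2:
                raise ModelSyntaxError(
                    f"line {line_no}: {keyword} takes exactly two NAME=branch@time terms"
                )
            names, times = [], []
            for i, (name, val) in enumerate(pairs):
                if "@" not in val:
                    raise ModelSyntaxError(f"line {line_no}: expected branch@time, got {val!r}")
                base, _, tstr = val.partition("@")
                t = _number(tstr, line_no)
                node_kind = HYBRID if (keyword == "bdi" or i == 0) else CONNECTOR
                _insert_event(nodes, event_times, name, base, t, node_kind, line_no)
                names.append(name)
                times.append(t)
            ev = IntrogressionEvent(
                id=f"{names[0]}-{names[1]}",
                nodes=(names[0], names[1]),
                time=times[0],
                bidirectional=(keyword == "bdi"),
            )
            nodes[names[0]].partner = names[1]
            nodes[names[1]].partner = names[0]
            nodes[names[0]].event = ev.id
            nodes[names[1]].event = ev.id
            events.append(ev)
            tau[names[0]] = times[0]
            tau[names[1]] = times[1]
        elif keyword in ("tau", "theta", "phi"):
            target = {"tau": tau, "theta": theta, "phi": phi}[keyword]
            for name, val in _parse_assignments(rest, line_no):
                if nodes is None or name not in nodes:
                    raise ModelSyntaxError(f"line {line_no}: unknown node name {name!r}")
                x = _number(val, line_no)
                if keyword == "phi" and not 0.0 <= x <= 1.0:
                    raise ValueError(f"line {line_no}: phi_{name}={x} outside [0, 1]")
                if keyword in ("tau", "theta") and x <= 0.0:
                    raise ValueError(f"line {line_no}: {keyword}_{name}={x} must be > 0")
                target[name] = x
        else:
            raise ModelSyntaxError(f"line {line_no}: unknown keyword {keyword!r}")

    if nodes is None:
        raise ModelSyntaxError("model spec has no tree line")
    for ev in events:
        if ev.bidirectional:
            for n in ev.nodes:
                phi.setdefault(n, None)  # placeholder to catch missing assignment
        else:
            phi.setdefault(ev.nodes[0], None)
    missing_phi = [n for n, v in phi.items() if v is None]
    if missing_phi:
        raise ModelSyntaxError(f"missing phi for hybrid node(s): {', '.join(sorted(missing_phi))}")
    extra_phi = [n for n in phi if nodes[n].kind != HYBRID]
    if extra_phi:
        raise ModelSyntaxError(f"phi assigned to non-hybrid node(s): {', '.join(sorted(extra_phi))}")

    return MSciModel(
        nodes=nodes, root=root, tau=tau, theta=theta, phi=phi, events=events, newick=newick
    )


def _number(s: str, line_no: int) -> float:
    try:
        x = float(s)
    except ValueError:
        raise ModelSyntaxError(f"line {line_no}: not a number: {s!r}") from None
    if not math.isfinite(x):
        raise ModelSyntaxError(f"line {line_no}: non-finite value {s!r}")
    return x


def write_model(model: MSciModel) -> str:
    """Serialize a model back to the spec text format (parse round-trips)."""
    lines = [f"tree {model.newick};"]
    for ev in model.events:
        kw = "bdi" if ev.bidirectional else "udi"
        parts = []
        for n in ev.nodes:
            base = model.nodes[n].children[0]
            parts.append(f"{n}={base}@{model.tau[n]!r}")
        lines.append(f"{kw} " + " ".join(parts))
    spec_taus = [
        f"{n}={model.tau[n]!r}"
        for n in sorted(model.tau)
        if model.nodes[n].kind == SPECIATION
    ]
    if spec_taus:
        lines.append("tau " + " ".join(spec_taus))
    if model.theta:
        lines.append("theta " + " ".join(f"{n}={model.theta[n]!r}" for n in sorted(model.theta)))
    if model.phi:
        lines.append("phi " + " ".join(f"{n}={model.phi[n]!r}" for n in sorted(model.phi)))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# interrogation


@dataclass
class ParameterTally:
    n_tau: int
    n_theta: int
    n_phi: int

    @property
    def total(self) -> int:
        return self.n_tau + self.n_theta + self.n_phi


def count_parameters(model: MSciModel) -> ParameterTally:
    """Tally free parameters: one theta per branch (root stem included),
    one tau per distinct internal node time (each event pair shares one),
    one phi per hybrid node."""
    n_theta = len(model.nodes)
    n_spec = sum(1 for nd in model.nodes.values() if nd.kind == SPECIATION)
    n_tau = n_spec + len(model.events)
    n_phi = sum(1 for nd in model.nodes.values() if nd.kind == HYBRID)
    return ParameterTally(n_tau=n_tau, n_theta=n_theta, n_phi=n_phi)


def _condensed_parent_map(model: MSciModel) -> dict[str, str]:
    """Map each node to its representative after merging every BDI pair
    into a single condensed node (iterated to a fixed point; merging is
    pairwise so one simultaneous pass is the fixed point)."""
    rep = {n: n for n in model.nodes}
    for ev in model.events:
        if ev.bidirectional:
            a, b = sorted(ev.nodes)
            rep[b] = a
    # path-compress (pairs only, but keep general)
    def find(n: str) -> str:
        while rep[n] != n:
            rep[n] = rep[rep[n]]
            n = rep[n]
        return n

    return {n: find(n) for n in model.nodes}


def detect_bdi_events(model: MSciModel) -> list[BDIEvent]:
    """One event per hybrid pair whose horizontal links point at each
    other (bidirectional).  UDI nodes are not reported here; see
    :func:`udi_nodes`.  Events are returned youngest first, ties broken
    by node label."""
    out = []
    for ev in sorted(model.events, key=lambda e: (e.time, e.nodes)):
        if not ev.bidirectional:
            continue
        x, y = ev.nodes
        out.append(
            BDIEvent(
                nodes=(x, y),
                time=ev.time,
                phi_params=(f"phi_{x}", f"phi_{y}"),
                theta_params=(f"theta_{x}", f"theta_{y}"),
                sister=_is_sister(model, (x, y)),
            )
        )
    return out


def udi_nodes(model: MSciModel) -> list[str]:
    """Hybrid nodes belonging to unidirectional events (reported only)."""
    return [ev.nodes[0] for ev in model.events if not ev.bidirectional]


def _is_sister(model: MSciModel, pair: tuple[str, str]) -> bool:
    rep = _condensed_parent_map(model)
    x, y = pair
    px, py = model.nodes[x].parent, model.nodes[y].parent
    if px is None or py is None:
        return False
    return rep[px] == rep[py]


def classify_bdi(model: MSciModel, event: BDIEvent) -> str:
    """Classify a BDI event as ``"sister"`` or ``"nonsister"``.

    Computed on the condensed graph in which every BDI node pair is
    merged into one node: the event is sister iff the (condensed)
    parents of its two nodes coincide.  Sister events create
    within-model unidentifiability; nonsister events create cross-model
    unidentifiability.
    """
    return "sister" if _is_sister(model, event.nodes) else "nonsister"


def validate(model: MSciModel) -> list[str]:
    """Check every model invariant; returns ALL violations (empty = ok)."""
    violations: list[str] = []

    for n, nd in model.nodes.items():
        if nd.kind != LEAF and n not in model.tau:
            violations.append(f"internal node {n} has no tau")
        if n not in model.theta:
            violations.append(f"branch {n} has no theta")

    for n, t in model.tau.items():
        if t <= 0:
            violations.append(f"tau_{n}={t} must be > 0")
    for n, t in model.theta.items():
        if t <= 0:
            violations.append(f"theta_{n}={t} must be > 0")
    for n, p in model.phi.items():
        if not 0.0 <= p <= 1.0:
            violations.append(f"phi_{n}={p} outside [0, 1]")

    # time increases strictly rootward along every vertical edge
    for n, nd in model.nodes.items():
        if nd.parent is None:
            continue
        try:
            tn, tp = model.node_time(n), model.node_time(nd.parent)
        except KeyError:
            continue
        if tn >= tp:
            violations.append(
                f"node {n} (t={tn}) not strictly younger than its parent {nd.parent} (t={tp})"
            )

    for ev in model.events:
        ta, tb = model.tau.get(ev.nodes[0]), model.tau.get(ev.nodes[1])
        if ta is not None and tb is not None and ta != tb:
            violations.append(
                f"introgression pair {ev.id} has unequal times ({ta} != {tb})"
            )

    return violations
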