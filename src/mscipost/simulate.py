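"""Synthetic data for exercising the relabeling machinery.

Two generators:

* :func:`simulate_label_switching_samples` emulates an MCMC sample
  whose chain wanders between unidentifiable towers: within the
  reference tower the phi columns follow specified beta laws and the
  theta columns gamma laws; other towers are realized by pushing
  reference draws through the corresponding tower mapping; the tower
  occupied at each step follows a Markov switching process with a given
  stay probability and stationary weights.  True tower labels are
  returned alongside the table.

* :func:`simulate_gene_trees` draws genealogies under an MSci model by
  the backwards-in-time coalescent: exponential waiting times at rate
  k(k-1)/theta within each population, binomial path choice with
  probability phi at each hybridization node, population merges at
  speciation times.

:func:`pairwise_coal_density` is the closed-form density of the
coalescent time between one A and one B sequence under the two-species
single-BDI model; it is the analytic oracle for the mirror-invariance
property f(G | Theta) = f(G | Theta').
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import HYBRID, LEAF, MSciModel, detect_bdi_events
from .towers import TowerMapping, apply_mapping

__all__ = [
    "TowerSpec",
    "GeneTree",
    "simulate_label_switching_samples",
    "simulate_gene_trees",
    "pairwise_coal_density",
    "single_bdi_tower_spec",
    "double_bdi_tower_spec",
]


# ---------------------------------------------------------------------------
# label-switching sample emulation


@dataclass
class TowerSpec:
    """Reference-tower marginals and switching dynamics.

    ``phi_params`` maps each phi column to beta (p, q); ``theta_params``
    maps each theta column to gamma (shape, rate).  ``weights`` are the
    stationary tower weights; the per-step transition matrix is
    stay * I + (1 - stay) * outer(1, weights), which leaves ``weights``
    stationary for any stay probability.
    """

    phi_params: dict[str, tuple[float, float]]
    theta_params: dict[str, tuple[float, float]]
    weights: tuple[float, ...] = (0.5, 0.5)
    stay_prob: float = 0.999
    n: int = 10_000
    seed: int | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if not np.isclose(w.sum(), 1.0) or np.any(w < 0):
            raise ValueError("tower weights must be nonnegative and sum to 1")
        if not 0.0 <= self.stay_prob <= 1.0:
            raise ValueError("stay probability must be in [0, 1]")
        for name, (a, b) in {**self.phi_params, **self.theta_params}.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"nonpositive shape for column {name!r}")


def single_bdi_tower_spec(n: int = 10_000, seed: int | None = None,
                          stay_prob: float = 0.999) -> TowerSpec:
    """Two symmetric mirror towers for one sister BDI event.

    The reference tower has phi_X mean 0.7 and phi_Y mean 0.2 at
    moderate concentration, and theta marginals around 0.01 and 0.002 —
    the regime of the poorly-separated single-BDI study conditions.
    """
    return TowerSpec(
        phi_params={"phi_X": (7.0, 3.0), "phi_Y": (2.0, 8.0)},
        theta_params={"theta_X": (8.0, 800.0), "theta_Y": (8.0, 4000.0)},
        weights=(0.5, 0.5),
        stay_prob=stay_prob,
        n=n,
        seed=seed,
    )


def double_bdi_tower_spec(n: int = 10_000, seed: int | None = None,
                          stay_prob: float = 0.99) -> TowerSpec:
    """Four towers for a stacked double-BDI event.

    Reference means (phi_X, phi_Y, phi_Z, phi_W) = (0.1, 0.2, 0.2, 0.3)
    and theta means 0.005 / 0.02 alternating, the double-BDI simulation
    conditions; concentrations are tight enough that the four towers
    are well separated.
    """
    return TowerSpec(
        phi_params={
            "phi_X": (10.0, 90.0),
            "phi_Y": (20.0, 80.0),
            "phi_Z": (20.0, 80.0),
            "phi_W": (30.0, 70.0),
        },
        theta_params={
            "theta_X": (100.0, 20000.0),
            "theta_Y": (100.0, 5000.0),
            "theta_Z": (100.0, 20000.0),
            "theta_W": (100.0, 5000.0),
        },
        weights=(0.25, 0.25, 0.25, 0.25),
        stay_prob=stay_prob,
        n=n,
        seed=seed,
    )


def simulate_label_switching_samples(
    spec: TowerSpec, mappings: list[TowerMapping]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Emulated posterior sample with tower structure and true labels.

    Tower 0 is the reference; draws assigned to tower z are reference
    draws pushed through ``mappings[z]``, so within-tower marginals
    follow the specified (mapped) beta/gamma laws exactly.
    """
    if len(mappings) != len(spec.weights):
        raise ValueError("need one mapping per tower (identity first)")
    if not mappings[0].is_identity:
        raise ValueError("mappings[0] must be the identity (reference tower)")
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    # Markov switching chain with the given stationary weights
    w = np.asarray(spec.weights, dtype=float)
    z = np.empty(n, dtype=int)
    z[0] = rng.choice(len(w), p=w)
    jump = rng.random(n) >= spec.stay_prob
    fresh = rng.choice(len(w), p=w, size=n)
    for t in range(1, n):
        z[t] = fresh[t] if jump[t] else z[t - 1]

    ref = {}
    for col, (p, q) in spec.phi_params.items():
        ref[col] = rng.beta(p, q, size=n)
    for col, (a, b) in spec.theta_params.items():
        ref[col] = rng.gamma(a, 1.0 / b, size=n)
    table = pd.DataFrame(ref)

    out = table.copy()
    for code in np.unique(z):
        if mappings[code].is_identity:
            continue
        rows = z == code
        sub = {c: table.loc[rows, c].to_numpy() for c in table.columns}
        mapped = apply_mapping(sub, mappings[code])
        for c in table.columns:
            out.loc[rows, c] = mapped[c]
    return out, z


# ---------------------------------------------------------------------------
# gene-tree simulation


@dataclass
class _Lineage:
    label: str
    time: float
    children: list["_Lineage"] = field(default_factory=list)
    choices: list[tuple[str, str]] = field(default_factory=list)

    def tips(self) -> list[str]:
        if not self.children:
            return [self.label]
        return [t for c in self.children for t in c.tips()]

    def newick(self, parent_time: float | None = None) -> str:
        if self.children:
            inner = ",".join(c.newick(self.time) for c in self.children)
            core = f"({inner})"
        else:
            core = self.label
        if parent_time is None:
            return core
        return f"{core}:{parent_time - self.time:.10g}"


@dataclass
class GeneTree:
    """A simulated genealogy: rooted, binary, ultrametric in time.

    ``coalescent_times`` are the n - 1 node times (expected
    substitutions per site), sorted ascending; ``path_choices`` records,
    for every lineage that passed a hybridization node, the node name,
    the tips the lineage subtended and the path taken ("horizontal" or
    "vertical").
    """

    root: _Lineage
    coalescent_times: list[float]
    path_choices: list[tuple[str, tuple[str, ...], str]]

    @property
    def tmrca(self) -> float:
        return self.root.time

    def newick(self) -> str:
        return self.root.newick() + ";"


def _coalesce_epoch(
    lineages: list[_Lineage], theta: float, t0: float, t1: float, rng
) -> float:
    """Run the coalescent in one population from t0 to t1 (inf allowed);
    returns the time reached."""
    t = t0
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / theta
        t_next = t + rng.exponential(1.0 / rate)
        if t_next >= t1:
            return t1
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        parent = _Lineage(label="", time=t_next, children=[a, b])
        lineages[:] = [ln for m, ln in enumerate(lineages) if m not in (i, j)]
        lineages.append(parent)
        t = t_next
    return t1


def simulate_gene_trees(
    model: MSciModel,
    nseq: dict[str, int],
    nloci: int,
    seed: int | None = None,
) -> list[GeneTree]:
    """Simulate genealogies under the MSci model.

    ``nseq`` gives the number of sampled sequences per species (leaf
    name -> count; at least one species with >= 1).  Each locus uses an
    independent generator derived from (seed, locus index), so changing
    ``nloci`` does not perturb earlier loci.
    """
    leaves = model.leaves()
    counts = {s: int(nseq.get(s, 0)) for s in leaves}
    unknown = set(nseq) - set(leaves)
    if unknown:
        raise ValueError(f"unknown species in nseq: {sorted(unknown)}")
    total = sum(counts.values())
    if total < 2:
        raise ValueError("need at least two sampled sequences in total")

    # internal nodes in time order; partners processed together
    internal = [(model.node_time(n), n) for n, nd in model.nodes.items() if nd.kind != LEAF]
    internal.sort()

    out = []
    for locus in range(nloci):
        rng = np.random.default_rng((seed, locus) if seed is not None else None)
        pops: dict[str, list[_Lineage]] = {
            s: [_Lineage(label=f"{s}_{i + 1}", time=0.0) for i in range(counts[s])]
            for s in leaves
        }
        clock: dict[str, float] = {s: 0.0 for s in leaves}
        times: list[float] = []
        choices: list[tuple[str, tuple[str, ...], str]] = []

        done = set()
        for t_node, name in internal:
            nd = model.nodes[name]
            if name in done:
                continue
            # bring every child population of this node (and its partner,
            # processed jointly for introgression pairs) up to t_node
            group = [name]
            if nd.partner is not None and nd.partner not in done:
                group.append(nd.partner)
            moved: dict[str, list[_Lineage]] = {g: [] for g in group}
            for g in group:
                for child in model.nodes[g].children:
                    if child in pops:
                        _coalesce_epoch(pops[child], model.theta[child],
                                        clock[child], t_node, rng)
                        moved[g].extend(pops.pop(child))
            for g in group:
                gnode = model.nodes[g]
                pops.setdefault(g, [])
                clock[g] = t_node
                if gnode.partner is not None:
                    pops.setdefault(gnode.partner, [])
                    clock[gnode.partner] = t_node
                phi = model.phi.get(g, 0.0) if gnode.kind == HYBRID else 0.0
                for ln in moved[g]:
                    if gnode.kind == HYBRID and rng.random() < phi:
                        pops[gnode.partner].append(ln)
                        choices.append((g, tuple(ln.tips()), "horizontal"))
                    else:
                        pops[g].append(ln)
                        if gnode.kind == HYBRID:
                            choices.append((g, tuple(ln.tips()), "vertical"))
                done.add(g)

        # root population: coalesce to completion
        root_lin = pops[model.root]
        _coalesce_epoch(root_lin, model.theta[model.root], clock[model.root],
                        np.inf, rng)
        root = root_lin[0]

        def collect(node: _Lineage):
            if node.children:
                times.append(node.time)
                for c in node.children:
                    collect(c)

        collect(root)
        out.append(GeneTree(root=root, coalescent_times=sorted(times),
                            path_choices=choices))
    return out


# ---------------------------------------------------------------------------
# analytic pairwise-density oracle (two-species single-BDI model)


def pairwise_coal_density(model: MSciModel, t) -> np.ndarray:
    """Density of the coalescent time between one A and one B sequence
    under the two-species single-BDI model.

    Piecewise: zero before the introgression time tau_X (the sequences
    share no population); between tau_X and tau_R a two-component
    mixture — both lineages in the left parental population (weight
    (1 - phi_X) * phi_Y, rate 2/theta_X) or both in the right (weight
    phi_X * (1 - phi_Y), rate 2/theta_Y); past tau_R the surviving mass
    coalesces in the root population at rate 2/theta_R.

    Integrates to one; invariant under the single-BDI tower mapping.
    """
    events = detect_bdi_events(model)
    leaves = model.leaves()
    if len(leaves) != 2 or len(events) != 1 or len(model.events) != 1:
        raise ValueError("pairwise density requires the two-species single-BDI model")
    ev = events[0]
    x, y = ev.nodes

    def leaf_below(h: str) -> str:
        n = h
        while model.nodes[n].kind != LEAF:
            n = model.nodes[n].children[0]
        return n

    a, b = leaf_below(x), leaf_below(y)
    if {a, b} != set(leaves):
        raise ValueError("hybrid nodes must sit on the two leaf branches")
    phi_x, phi_y = model.phi[x], model.phi[y]
    th_x, th_y, th_r = model.theta[x], model.theta[y], model.theta[model.root]
    tau_x, tau_r = ev.time, model.tau[model.root]

    w_left = (1.0 - phi_x) * phi_y
    w_right = phi_x * (1.0 - phi_y)

    t = np.asarray(t, dtype=float)
    f = np.zeros_like(t)
    mid = (t >= tau_x) & (t < tau_r)
    dt = t[mid] - tau_x
    f[mid] = (w_left * (2.0 / th_x) * np.exp(-2.0 * dt / th_x)
              + w_right * (2.0 / th_y) * np.exp(-2.0 * dt / th_y))
    span = tau_r - tau_x
    surv = (w_left * np.exp(-2.0 * span / th_x)
            + w_right * np.exp(-2.0 * span / th_y)
            + (1.0 - w_left - w_right))
    late = t >= tau_r
    f[late] = surv * (2.0 / th_r) * np.exp(-2.0 * (t[late] - tau_r) / th_r)
    return f
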