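"""Contractile actomyosin network simulation on a hexagonal furrow lattice.

The model represents cortical myosin as point nodes threaded on bundles of
parallel actin fibers running along each edge of a hexagonal template.
Interfaces (bonds) between neighbouring nodes carry a constant active
tension ``T`` — motor-generated tension is strain-independent to first
order — except below a contact distance ``d_min`` where the force is zero,
which prevents node collapse.  Dynamics are overdamped explicit Euler:
``x <- x + mu * F`` with one stochastic turnover sweep per step.

Turnover and network integrity
------------------------------
Every alive node dies with probability ``k_off`` per step; recruitment
draws ``B ~ Binomial(N_max - N_alive, k_on)`` new nodes per step.  The
interplay of three rules reproduces the two regimes observed for the
presets (k_on, k_off) = (0.05, 0.001) and (0.003, 0.001):

* **Crosslink inheritance.**  When a node unbinds, the fiber segments it
  held can stay connected if another myosin engages before the strained
  ends slip apart.  Each inherited link between former partners at
  distance d succeeds with probability ``1 - (1 - k_on)^m`` where
  ``m = (r_c - d) / (mu T)`` is the number of steps a mesh-held end needs
  to slip beyond the interaction radius — a pure race between
  re-engagement (rate k_on) and slippage, with no extra parameters.
  Links to the structural junction anchors are always inherited.
* **Severed-pair repair.**  Failed links are tracked as exposed fiber ends
  while they remain within ``r_c``; recruited nodes preferentially bind
  such gaps (weight proportional to the exposed length beyond the
  ``binding_length``), reconnecting the break.  Once the ends retract past
  ``r_c`` the break is permanent: fully ruptured regions present no
  interfaces to bind to and can never be repopulated.
* **Stretch rupture.**  Any interface stretched beyond ``r_c`` snaps.

With k_on >> k_off breaks are reconnected promptly and the network remains
an interconnected honeycomb whose edge bands narrow perpendicular to each
edge (wild-type-like).  With k_on / k_off ~ 3 reconnection loses the race,
edges rupture under continued contraction and the nodes reel into discrete
foci centred at the lattice vertices (*dunk*-mutant-like).

Distances are in micrometres; time is in simulation steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .lattice import HexLattice, build_hex_lattice

__all__ = [
    "SimParams", "NetworkState", "Trajectory", "SimConfigError",
    "EmptyStateError", "seed_nodes", "compute_forces", "step", "run_sim",
    "simulate", "ablate", "rebuild_interfaces", "network_metrics",
    "total_interface_length", "interface_energy", "effective_edge_geometry",
    "save_trajectory", "load_trajectory",
]


class SimConfigError(ValueError):
    """Invalid or inconsistent simulation parameters."""


class EmptyStateError(ValueError):
    """Operation undefined on a state with no alive nodes."""


# home_edge sentinels
HOME_VERTEX = -1
HOME_RECRUITED = -2


@dataclass
class SimParams:
    """Parameters of the contractile-network model.

    ``k_on`` is the per-step recruitment probability per vacant capacity
    slot, ``k_off`` the per-step dissociation probability per node; both
    dimensionless in [0, 1].  ``tension`` (arbitrary force units) and
    ``mobility`` (um per unit force per step) enter only through their
    product, the per-step displacement of a singly pulled node; explicit
    Euler integration requires ``tension * mobility <= 0.2 *
    contact_distance`` (enforced).  ``binding_length`` is the stretch of
    exposed fiber beyond which an interface or severed gap attracts
    recruitment; ``basal_binding_weight`` is the small residual binding
    weight of fully occupied interfaces.
    """

    k_on: float = 0.05
    k_off: float = 0.001
    tension: float = 1.0
    mobility: float = 0.005
    interaction_radius: float = 1.6   # r_c, um
    contact_distance: float = 0.2     # d_min, um
    n_steps: int = 8000
    seed: int = 0
    fibers_per_edge: int = 3          # parallel fibers per edge band
    nodes_per_fiber: int = 11         # nodes per fiber along the edge
    initial_band_width: float = 2.0   # w0, um
    boundary_mode: str = "pinned"     # pinned | free
    binding_length: float = 0.75      # um
    basal_binding_weight: float = 1e-4
    vertex_turnover: bool = False     # junction anchors exempt by default

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errs = []
        if not (0.0 <= self.k_on <= 1.0):
            errs.append(f"k_on must be in [0, 1], got {self.k_on}")
        if not (0.0 <= self.k_off <= 1.0):
            errs.append(f"k_off must be in [0, 1], got {self.k_off}")
        for name in ("mobility", "interaction_radius",
                     "initial_band_width", "binding_length"):
            if not getattr(self, name) > 0:
                errs.append(f"{name} must be > 0, got {getattr(self, name)}")
        if self.tension < 0:
            errs.append(f"tension must be >= 0, got {self.tension}")
        if self.contact_distance < 0:
            errs.append("contact_distance must be >= 0")
        if self.contact_distance >= self.interaction_radius:
            errs.append("contact_distance must be smaller than "
                        "interaction_radius")
        if self.n_steps < 0:
            errs.append(f"n_steps must be >= 0, got {self.n_steps}")
        if self.fibers_per_edge < 1 or self.nodes_per_fiber < 1:
            errs.append("fibers_per_edge and nodes_per_fiber must be >= 1")
        if self.basal_binding_weight <= 0:
            errs.append("basal_binding_weight must be > 0")
        if self.boundary_mode not in ("pinned", "free"):
            errs.append(f"boundary_mode must be 'pinned' or 'free', got "
                        f"{self.boundary_mode!r}")
        if self.tension * self.mobility > 0.2 * self.contact_distance + 1e-12:
            errs.append(
                "tension * mobility must be <= 0.2 * contact_distance for "
                f"stable integration (got {self.tension * self.mobility:g} > "
                f"{0.2 * self.contact_distance:g})")
        if errs:
            raise SimConfigError("; ".join(errs))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NetworkState:
    """Positions and interfaces of the myosin nodes at one step.

    Arrays are sized to the fixed capacity ``N_max`` (the seeded count);
    dead slots are reused by recruitment.  ``bonds`` is the persistent
    interface set (sorted id pairs); ``severed`` the latent reconnection
    sites left by failed crosslink inheritance.
    """

    t: int
    pos: np.ndarray          # (N_max, 2) um
    alive: np.ndarray        # (N_max,) bool
    pinned: np.ndarray       # (N_max,) bool — zero mobility
    immortal: np.ndarray     # (N_max,) bool — turnover-exempt anchors
    home_edge: np.ndarray    # (N_max,) int
    bonds: set               # {(i, j)} with i < j
    severed: dict            # {(i, j): expiry step} exposed severed pairs
    capacity: int
    lattice: HexLattice = None

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def interfaces(self) -> np.ndarray:
        """Sorted (M, 2) array of interface id pairs."""
        if not self.bonds:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self.bonds), dtype=int)

    def copy(self) -> "NetworkState":
        return NetworkState(
            t=self.t, pos=self.pos.copy(), alive=self.alive.copy(),
            pinned=self.pinned.copy(), immortal=self.immortal.copy(),
            home_edge=self.home_edge.copy(), bonds=set(self.bonds),
            severed=dict(self.severed), capacity=self.capacity,
            lattice=self.lattice)

    def alive_positions(self) -> np.ndarray:
        return self.pos[self.alive]

    def occupancy(self) -> float:
        """Occupied fraction of turnover-eligible capacity."""
        elig = ~self.immortal
        return float((self.alive & elig).sum() / max(elig.sum(), 1))

    @classmethod
    def from_positions(cls, pos, interaction_radius, pinned=None,
                       lattice=None) -> "NetworkState":
        """Ad-hoc state with interfaces = all pairs within the radius
        (mainly for tests and small worked examples)."""
        from scipy.spatial import cKDTree
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        n = len(pos)
        bonds = set()
        if n > 1:
            tree = cKDTree(pos)
            for i, j in tree.query_pairs(
                    r=interaction_radius * (1 + 1e-12)):
                bonds.add((min(i, j), max(i, j)))
        if pinned is None:
            pinned = np.zeros(n, dtype=bool)
        return cls(t=0, pos=pos, alive=np.ones(n, bool),
                   pinned=np.asarray(pinned, bool),
                   immortal=np.zeros(n, bool),
                   home_edge=np.full(n, HOME_RECRUITED, dtype=int),
                   bonds=bonds, severed={}, capacity=n, lattice=lattice)


def seed_nodes(lattice: HexLattice, params: SimParams,
               rng: np.random.Generator) -> NetworkState:
    """Seed the initial broad meshwork of myosin nodes and fiber bonds.

    Each edge carries ``fibers_per_edge`` parallel fibers of
    ``nodes_per_fiber`` equispaced nodes spanning a band of width ``w0``
    centred on the edge, plus one anchor node at every lattice vertex.
    Bonds: consecutive nodes along each fiber, fiber ends to the vertex
    anchors, and rungs between adjacent fibers at matching positions.
    Capacity ``N_max`` is fixed at the seeded count.
    """
    L = lattice.edge_length
    n_f, n_per = params.fibers_per_edge, params.nodes_per_fiber
    w0 = params.initial_band_width

    offs = (np.zeros(1) if n_f == 1
            else np.linspace(-w0 / 2, w0 / 2, n_f))
    fracs = (np.arange(n_per) + 1.0) / (n_per + 1.0)

    ends = lattice.edge_endpoints()
    u = lattice.edge_unit_vectors()
    perp = np.column_stack([-u[:, 1], u[:, 0]])

    pos_list = [lattice.vertices]
    home_list = [np.full(lattice.n_vertices, HOME_VERTEX, dtype=int)]
    bonds = set()
    nid = lattice.n_vertices
    for e in range(lattice.n_edges):
        va, vb = lattice.edges[e]
        base = ends[e, 0]
        rows = []
        for off in offs:
            ids = list(range(nid, nid + n_per))
            nid += n_per
            pos_list.append(base + fracs[:, None] * (L * u[e])[None, :]
                            + off * perp[e])
            home_list.append(np.full(n_per, e, dtype=int))
            rows.append(ids)
            for k in range(n_per - 1):
                bonds.add((ids[k], ids[k + 1]))
            bonds.add((min(va, ids[0]), max(va, ids[0])))
            bonds.add((min(ids[-1], vb), max(ids[-1], vb)))
        for r in range(n_f - 1):
            for k in range(n_per):
                a, b = rows[r][k], rows[r + 1][k]
                bonds.add((min(a, b), max(a, b)))

    pos = np.concatenate(pos_list, axis=0)
    home = np.concatenate(home_list)
    n = len(pos)
    if not bonds:
        raise SimConfigError("seeding produced no interfaces")
    # interfaces longer than the interaction radius cannot exist
    drop = [(i, j) for (i, j) in bonds
            if np.linalg.norm(pos[i] - pos[j]) > params.interaction_radius]
    if drop:
        raise SimConfigError(
            "interaction_radius is smaller than the seeded node spacing; "
            "the initial fiber network would be disconnected")

    pinned = np.zeros(n, dtype=bool)
    if params.boundary_mode == "pinned":
        pinned[:lattice.n_vertices] = lattice.boundary_vertex_mask()
    immortal = np.zeros(n, dtype=bool)
    if not params.vertex_turnover:
        immortal[:lattice.n_vertices] = True

    return NetworkState(t=0, pos=pos, alive=np.ones(n, bool), pinned=pinned,
                        immortal=immortal, home_edge=home, bonds=bonds,
                        severed={}, capacity=n, lattice=lattice)


def compute_forces(state: NetworkState, params: SimParams) -> np.ndarray:
    """Constant-tension force on every node.

    F_i = T * sum over interface partners j of unit(x_j - x_i); pairs at
    distance <= d_min contribute nothing and pinned nodes receive zero.
    """
    F = np.zeros_like(state.pos)
    ifc = state.interfaces
    if len(ifc) == 0:
        return F
    i, j = ifc[:, 0], ifc[:, 1]
    d = state.pos[j] - state.pos[i]
    dist = np.linalg.norm(d, axis=1)
    act = dist > params.contact_distance
    unit = np.zeros_like(d)
    unit[act] = d[act] / dist[act, None]
    np.add.at(F, i, params.tension * unit)
    np.add.at(F, j, -params.tension * unit)
    F[state.pinned] = 0.0
    return F


def _adjacency(bonds: set, n: int) -> dict:
    adj = {}
    for a, b in bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def step(state: NetworkState, params: SimParams,
         rng: np.random.Generator) -> NetworkState:
    """Advance the network one step (mutates and returns ``state``).

    Sub-steps: (1) overdamped Euler position update; (2) death sweep at
    k_off with crosslink inheritance gated by the k_on-vs-slippage race,
    failures recorded as severed pairs; (3) recruitment of
    B ~ Binomial(vacancies, k_on) nodes at midpoints (plus Gaussian jitter
    of sigma = d_min) of interfaces or severed pairs chosen by exposed
    binding length; (4) stretch rupture of interfaces beyond r_c;
    (5) t += 1.
    """
    rc = params.interaction_radius
    muT = params.mobility * params.tension
    pos, alive = state.pos, state.alive
    bonds, severed = state.bonds, state.severed

    F = compute_forces(state, params)
    pos[alive] += params.mobility * F[alive]

    def unbond(a, b):
        bonds.discard((min(a, b), max(a, b)))

    def bond(a, b):
        bonds.add((min(a, b), max(a, b)))

    # --- deaths with gated crosslink inheritance
    if params.k_off > 0:
        u = rng.random(state.capacity)
        eligible = alive & ~state.pinned & ~state.immortal
        deaths = np.flatnonzero(eligible & (u < params.k_off))
        if len(deaths):
            adj = _adjacency(bonds, state.capacity)
            for dd in deaths:
                part = sorted(adj.get(dd, ()))
                for p in part:
                    unbond(dd, p)
                    adj[p].discard(dd)
                adj.pop(dd, None)
                alive[dd] = False
                if len(part) < 2:
                    continue
                # spanning-tree inheritance over the partner set, seeded
                # with their existing mutual connectivity
                comp = {p: p for p in part}

                def find(x):
                    while comp[x] != x:
                        comp[x] = comp[comp[x]]
                        x = comp[x]
                    return x

                for x in part:
                    for y in adj.get(x, ()):
                        if y in comp and find(x) != find(y):
                            comp[find(x)] = find(y)
                cand = sorted((np.linalg.norm(pos[p] - pos[q]), p, q)
                              for i_, p in enumerate(part)
                              for q in part[i_ + 1:])
                for dpq, p, q in cand:
                    if dpq > rc:
                        break
                    if find(p) == find(q):
                        continue
                    # links to junction anchors are structural (the fiber
                    # terminates at the vertex) and are always inherited
                    anchored = state.immortal[p] or state.immortal[q]
                    m = (rc - dpq) / muT if muT > 0 else np.inf
                    if anchored or \
                            rng.random() < 1.0 - (1.0 - params.k_on) ** m:
                        bond(p, q)
                        adj.setdefault(p, set()).add(q)
                        adj.setdefault(q, set()).add(p)
                        comp[find(p)] = find(q)
                    else:
                        # exposed ends persist for the slippage window,
                        # after which they fray and cannot be rejoined
                        expiry = (state.t + int(np.ceil(m))
                                  if np.isfinite(m)
                                  else np.iinfo(np.int64).max)
                        severed[(min(p, q), max(p, q))] = expiry

    # --- prune severed pairs that died, reconnected, slipped apart or
    # exceeded their slippage window
    if severed:
        gone = [pq for pq, expiry in severed.items()
                if not (alive[pq[0]] and alive[pq[1]]) or pq in bonds
                or state.t >= expiry
                or np.linalg.norm(pos[pq[0]] - pos[pq[1]]) > rc]
        for pq in gone:
            severed.pop(pq, None)

    # --- recruitment
    n_vacant = state.capacity - state.n_alive
    if n_vacant > 0 and params.k_on > 0 and (bonds or severed):
        b_new = int(rng.binomial(n_vacant, params.k_on))
        l0 = params.binding_length
        basal = params.basal_binding_weight
        for _ in range(b_new):
            blist = sorted(bonds)
            slist = sorted(severed)
            if not blist and not slist:
                break
            wb = np.empty(0)
            ws = np.empty(0)
            if blist:
                ba = np.array(blist)
                dl = np.linalg.norm(pos[ba[:, 1]] - pos[ba[:, 0]], axis=1)
                wb = np.maximum(dl - l0, 0.0) + basal
            if slist:
                sa = np.array(slist)
                ds = np.linalg.norm(pos[sa[:, 1]] - pos[sa[:, 0]], axis=1)
                ws = np.maximum(ds - l0, 0.0) + basal
            wall = np.concatenate([wb, ws])
            c = int(rng.choice(len(wall), p=wall / wall.sum()))
            if c < len(blist):
                a, b = blist[c]
                on_bond = True
            else:
                a, b = slist[c - len(blist)]
                on_bond = False
            if not (alive[a] and alive[b]):
                continue
            slots = np.flatnonzero(~alive)
            if not len(slots):
                break
            slot = int(slots[0])
            pos[slot] = (0.5 * (pos[a] + pos[b])
                         + rng.normal(0.0, params.contact_distance, 2))
            alive[slot] = True
            state.pinned[slot] = False
            state.immortal[slot] = False
            state.home_edge[slot] = HOME_RECRUITED
            if on_bond:
                unbond(a, b)
            else:
                severed.pop((min(a, b), max(a, b)), None)
            bond(a, slot)
            bond(slot, b)

    # --- stretch rupture
    if bonds:
        ba = np.array(sorted(bonds))
        dl = np.linalg.norm(pos[ba[:, 1]] - pos[ba[:, 0]], axis=1)
        for a, b in ba[dl > rc]:
            unbond(int(a), int(b))

    state.t += 1
    return state


@dataclass
class Trajectory:
    """Recorded snapshots plus per-snapshot metrics of one run."""

    params: SimParams
    lattice: HexLattice
    steps: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)
    metrics: pd.DataFrame = None

    def node_positions(self) -> list:
        """Alive-node coordinate arrays, one per snapshot."""
        return [s.alive_positions() for s in self.snapshots]


def simulate(state: NetworkState, params: SimParams, n_steps: int,
             rng: np.random.Generator, snapshot_stride: int = 200,
             vertex_radius: float = 1.2) -> Trajectory:
    """Run ``n_steps`` steps from ``state``, recording at a stride.

    The initial state and the final step are always recorded.
    """
    traj = Trajectory(params=params, lattice=state.lattice)
    rows = []

    def record(s: NetworkState) -> None:
        traj.steps.append(s.t)
        traj.snapshots.append(s.copy())
        m = {"step": s.t, "n_alive": s.n_alive, "occupancy": s.occupancy()}
        if s.lattice is not None and s.n_alive > 0:
            m.update(network_metrics(s, vertex_radius=vertex_radius))
        rows.append(m)

    record(state)
    for k in range(n_steps):
        step(state, params, rng)
        if state.t % snapshot_stride == 0 or k == n_steps - 1:
            record(state)
    traj.metrics = pd.DataFrame(rows)
    return traj


def run_sim(params: SimParams, lattice: HexLattice = None, rows: int = 3,
            cols: int = 3, edge_length: float = 6.0,
            snapshot_stride: int = 200, rng: np.random.Generator = None,
            vertex_radius: float = 1.2) -> Trajectory:
    """Seed a network and run the full simulation; deterministic given
    ``params.seed``."""
    if lattice is None:
        lattice = build_hex_lattice(rows, cols, edge_length)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = seed_nodes(lattice, params, rng)
    return simulate(state, params, params.n_steps, rng,
                    snapshot_stride=snapshot_stride,
                    vertex_radius=vertex_radius)


def ablate(state: NetworkState, edge_id: int, radius: float) -> NetworkState:
    """Point incision: remove all alive nodes strictly within ``radius``
    of the midpoint of a template edge (their interfaces with them).

    Returns a modified copy; the surviving severed chain ends retract
    under the residual tension, which is the recoil read out by PIV.
    """
    lat = state.lattice
    if lat is None or not (0 <= edge_id < lat.n_edges):
        raise LookupError(f"unknown edge id {edge_id}")
    center = lat.edge_midpoints()[edge_id]
    out = state.copy()
    d = np.linalg.norm(out.pos - center, axis=1)
    killed = set(np.flatnonzero(out.alive & (d < radius)).tolist())
    out.alive[list(killed)] = False
    out.bonds = {(a, b) for (a, b) in out.bonds
                 if a not in killed and b not in killed}
    out.severed = {pq: exp for pq, exp in out.severed.items()
                   if pq[0] not in killed and pq[1] not in killed}
    return out


def rebuild_interfaces(state: NetworkState, params: SimParams
                       ) -> NetworkState:
    """Drop interfaces that reference dead nodes or exceed the radius."""
    pos = state.pos
    rc = params.interaction_radius
    state.bonds = {(a, b) for (a, b) in state.bonds
                   if state.alive[a] and state.alive[b]
                   and np.linalg.norm(pos[a] - pos[b]) <= rc}
    return state


def total_interface_length(state: NetworkState) -> float:
    ifc = state.interfaces
    if len(ifc) == 0:
        return 0.0
    d = state.pos[ifc[:, 1]] - state.pos[ifc[:, 0]]
    return float(np.linalg.norm(d, axis=1).sum())


def interface_energy(state: NetworkState, r_c: float) -> float:
    """Sum over interfaces of (d_ij - r_c); non-increasing with turnover
    disabled (each term is negative and ruptures only remove terms at
    d = r_c where the contribution vanishes)."""
    ifc = state.interfaces
    if len(ifc) == 0:
        return 0.0
    d = state.pos[ifc[:, 1]] - state.pos[ifc[:, 0]]
    return float((np.linalg.norm(d, axis=1) - r_c).sum())


def _assign_nodes_to_edges(state: NetworkState):
    """Nearest-segment assignment of alive nodes to template edges.

    Returns (edge_index, t_along, perp_offset) per alive node.
    """
    lat = state.lattice
    p = state.alive_positions()
    a = lat.vertices[lat.edges[:, 0]]
    b = lat.vertices[lat.edges[:, 1]]
    ab = b - a
    L2 = (ab ** 2).sum(axis=1)
    t = ((p[:, None, :] - a[None, :, :]) * ab[None, :, :]).sum(-1) / L2[None, :]
    tc = np.clip(t, 0.0, 1.0)
    closest = a[None, :, :] + tc[:, :, None] * ab[None, :, :]
    dist = np.linalg.norm(p[:, None, :] - closest, axis=-1)
    e = dist.argmin(axis=1)
    idx = np.arange(len(p))
    tt = t[idx, e]
    u = ab[e] / np.sqrt(L2[e])[:, None]
    rel = p - a[e]
    perp = rel[:, 0] * (-u[:, 1]) + rel[:, 1] * u[:, 0]
    return e, tt, perp


def network_metrics(state: NetworkState, vertex_radius: float = 1.2) -> dict:
    """Geometric summary of a state against its lattice template.

    * ``density_ratio`` — (nodes in vertex discs / disc area) over
      (remaining nodes / edge-strip area), strips of width
      2 * vertex_radius; +inf sentinel when the strips are empty.
    * ``line_ratio`` — nodes per unit outline arc length, vertex class
      over edge class (commensurate with the intensity quantification).
    * ``mean_band_width`` — mean over edges of the standard deviation of
      perpendicular node offsets.
    * ``frac_intact_edges`` — fraction of edges with >= 1 assigned node
      projecting into the middle third of the edge.
    * ``n_components`` — connected components of the interface graph.
    """
    if state.n_alive == 0:
        raise EmptyStateError("no alive nodes")
    lat = state.lattice
    if lat is None:
        raise ValueError("state has no lattice template")
    R = vertex_radius
    L = lat.edge_length
    p = state.alive_positions()

    dv = np.linalg.norm(p[:, None, :] - lat.vertices[None, :, :], axis=-1)
    in_vertex = (dv < R).any(axis=1)
    nv, ne = int(in_vertex.sum()), int((~in_vertex).sum())

    v_area = lat.n_vertices * np.pi * R ** 2
    e_area = lat.n_edges * max(L - 2 * R, 0.0) * 2 * R
    if ne == 0 or e_area == 0:
        density_ratio = np.inf
        line_ratio = np.inf
    else:
        density_ratio = (nv / v_area) / (ne / e_area)
        v_arc = float(lat.vertex_degrees().sum()) * R
        e_arc = lat.n_edges * max(L - 2 * R, 0.0)
        line_ratio = (nv / v_arc) / (ne / e_arc)

    e, tt, perp = _assign_nodes_to_edges(state)
    widths = np.full(lat.n_edges, np.nan)
    intact = np.zeros(lat.n_edges, dtype=bool)
    for k in range(lat.n_edges):
        sel = e == k
        if sel.sum() >= 2:
            widths[k] = perp[sel].std()
        intact[k] = bool((sel & (tt >= 1 / 3) & (tt <= 2 / 3)).any())

    ids = np.flatnonzero(state.alive)
    remap = np.full(state.capacity, -1)
    remap[ids] = np.arange(len(ids))
    ifc = state.interfaces
    if len(ifc) > 0:
        ok = state.alive[ifc[:, 0]] & state.alive[ifc[:, 1]]
        ifc = ifc[ok]
    if len(ifc) > 0:
        i = remap[ifc[:, 0]]
        j = remap[ifc[:, 1]]
        g = coo_matrix((np.ones(len(i)), (i, j)),
                       shape=(len(ids), len(ids)))
        ncomp = connected_components(g, directed=False)[0]
    else:
        ncomp = len(ids)

    return {
        "density_ratio": float(density_ratio),
        "line_ratio": float(line_ratio),
        "mean_band_width": float(np.nanmean(widths)),
        "frac_intact_edges": float(intact.mean()),
        "n_components": int(ncomp),
    }


def effective_edge_geometry(state: NetworkState, vertex_radius: float = 1.5):
    """Per-edge realized endpoints and lengths from node positions.

    Each template vertex is replaced by the centroid of alive nodes within
    ``vertex_radius`` (template position when the disc is empty).  In the
    rupture regime intact edges contract while ruptured edges are
    stretched by their neighbours, so realized lengths diverge.
    Returns (endpoints (E, 2, 2) um, lengths (E,) um).
    """
    lat = state.lattice
    p = state.alive_positions()
    eff = lat.vertices.copy()
    for v in range(lat.n_vertices):
        d = np.linalg.norm(p - lat.vertices[v], axis=1)
        sel = d < vertex_radius
        if sel.any():
            eff[v] = p[sel].mean(axis=0)
    endpoints = eff[lat.edges]
    lengths = np.linalg.norm(endpoints[:, 1] - endpoints[:, 0], axis=1)
    return endpoints, lengths


# ---------------------------------------------------------------------------
# Trajectory persistence: one JSON per snapshot plus a CSV metrics table.

def save_trajectory(traj: Trajectory, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "params.json").write_text(
        json.dumps(traj.params.to_dict(), indent=1))
    lat = traj.lattice
    (outdir / "lattice.json").write_text(json.dumps({
        "vertices": lat.vertices.tolist(),
        "edges": lat.edges.tolist(),
        "cells": [np.asarray(c).tolist() for c in lat.cells],
        "edge_length": lat.edge_length,
    }))
    for s in traj.snapshots:
        rec = {
            "step": s.t,
            "nodes": [
                {"id": int(i), "x": float(s.pos[i, 0]),
                 "y": float(s.pos[i, 1]), "alive": bool(s.alive[i]),
                 "pinned": bool(s.pinned[i]),
                 "immortal": bool(s.immortal[i]),
                 "home_edge": int(s.home_edge[i])}
                for i in range(s.capacity)
            ],
            "interfaces": s.interfaces.tolist(),
            "severed": sorted([pq[0], pq[1], int(exp)]
                              for pq, exp in s.severed.items()),
        }
        (outdir / f"snapshot_{s.t:06d}.json").write_text(json.dumps(rec))
    if traj.metrics is not None:
        traj.metrics.to_csv(outdir / "metrics.csv", index=False)


def load_trajectory(indir) -> Trajectory:
    indir = Path(indir)
    params = SimParams(**json.loads((indir / "params.json").read_text()))
    lj = json.loads((indir / "lattice.json").read_text())
    lat = HexLattice(vertices=np.asarray(lj["vertices"], float),
                     edges=np.asarray(lj["edges"], int),
                     cells=[np.asarray(c, int) for c in lj["cells"]],
                     edge_length=lj["edge_length"])
    traj = Trajectory(params=params, lattice=lat)
    for f in sorted(indir.glob("snapshot_*.json")):
        rec = json.loads(f.read_text())
        nodes = rec["nodes"]
        n = len(nodes)
        s = NetworkState(
            t=rec["step"],
            pos=np.array([[d["x"], d["y"]] for d in nodes]),
            alive=np.array([d["alive"] for d in nodes], bool),
            pinned=np.array([d["pinned"] for d in nodes], bool),
            immortal=np.array([d["immortal"] for d in nodes], bool),
            home_edge=np.array([d["home_edge"] for d in nodes], int),
            bonds={(min(a, b), max(a, b)) for a, b in rec["interfaces"]},
            severed={(min(a, b), max(a, b)): exp
                     for a, b, exp in rec["severed"]},
            capacity=n, lattice=lat)
        traj.steps.append(s.t)
        traj.snapshots.append(s)
    mpath = indir / "metrics.csv"
    if mpath.exists():
        traj.metrics = pd.read_csv(mpath)
    return traj
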