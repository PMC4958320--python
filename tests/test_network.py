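import numpy as np
import pytest

from furrownet import (
    SimParams, NetworkState, SimConfigError, EmptyStateError,
    build_hex_lattice, seed_nodes, compute_forces, step, run_sim, simulate,
    ablate, rebuild_interfaces, network_metrics, total_interface_length,
    interface_energy,
)


def small_params(**kw):
    defaults = dict(n_steps=0, seed=0)
    defaults.update(kw)
    return SimParams(**defaults)


# ---------------------------------------------------------------- params

def test_param_validation_rejects_bad_values():
    with pytest.raises(SimConfigError):
        SimParams(k_on=1.5)
    with pytest.raises(SimConfigError):
        SimParams(k_off=-0.1)
    with pytest.raises(SimConfigError):
        SimParams(contact_distance=2.0, interaction_radius=1.6)
    with pytest.raises(SimConfigError):
        # integration stability bound: mu*T <= 0.2*d_min
        SimParams(mobility=0.2, tension=1.0, contact_distance=0.2)


# ---------------------------------------------------------------- seeding

def test_seed_counts_single_hexagon(hex1):
    p = small_params(fibers_per_edge=3, nodes_per_fiber=5)
    s = seed_nodes(hex1, p, np.random.default_rng(0))
    assert s.n_alive == 6 * 15 + 6
    assert s.capacity == s.n_alive


def test_seed_band_offsets_match_equispaced_rows(hex1):
    """Perpendicular offsets of a fresh edge band have the std of n_f
    equispaced rows across w0."""
    p = small_params(fibers_per_edge=3, initial_band_width=2.0)
    s = seed_nodes(hex1, p, np.random.default_rng(0))
    band = s.home_edge == 0
    a, b = hex1.vertices[hex1.edges[0]]
    u = (b - a) / np.linalg.norm(b - a)
    perp = np.array([-u[1], u[0]])
    offsets = (s.pos[band] - a) @ perp
    expected = np.linspace(-1.0, 1.0, 3).std()
    assert np.isclose(offsets.std(), expected, atol=1e-9)


def test_seed_zero_band_width_is_collinear(hex1):
    p = small_params(initial_band_width=1e-12)
    s = seed_nodes(hex1, p, np.random.default_rng(0))
    band = s.home_edge == 0
    a, b = hex1.vertices[hex1.edges[0]]
    u = (b - a) / np.linalg.norm(b - a)
    perp = np.array([-u[1], u[0]])
    assert np.abs((s.pos[band] - a) @ perp).max() < 1e-9


def test_seed_interaction_radius_too_small_raises(hex1):
    with pytest.raises(SimConfigError):
        p = small_params(interaction_radius=0.3, contact_distance=0.05)
        seed_nodes(hex1, p, np.random.default_rng(0))


# ---------------------------------------------------------------- forces

def test_two_nodes_equal_opposite_tension():
    p = small_params()
    d = 2 * p.contact_distance
    s = NetworkState.from_positions([[0, 0], [d, 0]], p.interaction_radius)
    F = compute_forces(s, p)
    assert np.allclose(F[0], [p.tension, 0.0])
    assert np.allclose(F[1], [-p.tension, 0.0])


def test_symmetric_partners_cancel():
    p = small_params()
    s = NetworkState.from_positions([[0, 0], [1, 0], [-1, 0]],
                                    p.interaction_radius)
    F = compute_forces(s, p)
    assert np.allclose(F[0], 0.0)


def test_contact_cutoff_zeroes_force():
    p = small_params()
    s = NetworkState.from_positions([[0, 0], [0.5 * p.contact_distance, 0]],
                                    p.interaction_radius)
    assert np.allclose(compute_forces(s, p), 0.0)


def test_pinned_nodes_feel_no_force():
    p = small_params()
    s = NetworkState.from_positions([[0, 0], [1, 0]], p.interaction_radius,
                                    pinned=[True, False])
    F = compute_forces(s, p)
    assert np.allclose(F[0], 0.0)
    assert not np.allclose(F[1], 0.0)


# ---------------------------------------------------------------- stepping

def test_null_dynamics_only_advances_time(hex1):
    p = small_params(k_on=0.0, k_off=0.0, tension=1e-12)
    rng = np.random.default_rng(0)
    s = seed_nodes(hex1, p, rng)
    before = s.copy()
    step(s, p, rng)
    assert s.t == before.t + 1
    assert np.allclose(s.pos, before.pos, atol=1e-9)
    assert np.array_equal(s.alive, before.alive)
    assert s.bonds == before.bonds


def test_full_dissociation_kills_everything(hex1):
    # all nodes participate in turnover here, including vertex anchors
    p = small_params(k_on=0.0, k_off=1.0, boundary_mode="free",
                     vertex_turnover=True)
    rng = np.random.default_rng(0)
    s = seed_nodes(hex1, p, rng)
    step(s, p, rng)
    assert s.n_alive == 0
    assert len(s.bonds) == 0


def test_conservation_without_turnover(hex1):
    p = small_params(k_on=0.0, k_off=0.0)
    rng = np.random.default_rng(0)
    s = seed_nodes(hex1, p, rng)
    n0 = s.n_alive
    for _ in range(200):
        step(s, p, rng)
    assert s.n_alive == n0


@pytest.mark.parametrize("k_on,k_off", [(0.05, 0.001), (0.003, 0.001),
                                        (0.02, 0.02)])
def test_stationary_occupancy_matches_two_state_chain(hex1, k_on, k_off):
    """Long-run occupied fraction of turnover-eligible slots equals the
    two-state Markov stationary value k_on/(k_on+k_off) within 0.01
    (mean over 3 seeds of a 20,000-step average after burn-in)."""
    expected = k_on / (k_on + k_off)
    means = []
    for seed in (0, 1, 2):
        p = small_params(k_on=k_on, k_off=k_off, seed=seed)
        rng = np.random.default_rng(seed)
        s = seed_nodes(hex1, p, rng)
        occ = []
        for t in range(20000):
            step(s, p, rng)
            if t >= 4000:
                occ.append(s.occupancy())
        means.append(np.mean(occ))
    assert abs(np.mean(means) - expected) < 0.01


def test_interfaces_respect_radius_invariant(hex1):
    p = small_params(k_on=0.05, k_off=0.01)
    rng = np.random.default_rng(3)
    s = seed_nodes(hex1, p, rng)
    for _ in range(300):
        step(s, p, rng)
    ifc = s.interfaces
    assert s.alive[ifc].all()
    d = np.linalg.norm(s.pos[ifc[:, 1]] - s.pos[ifc[:, 0]], axis=1)
    assert (d <= p.interaction_radius + 1e-9).all()


def test_determinism_bitwise(hex22):
    p = SimParams(k_on=0.05, k_off=0.001, n_steps=300, seed=7)
    t1 = run_sim(p, lattice=hex22, snapshot_stride=100)
    t2 = run_sim(p, lattice=hex22, snapshot_stride=100)
    for a, b in zip(t1.snapshots, t2.snapshots):
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.alive, b.alive)
        assert a.bonds == b.bonds
    assert t1.metrics.equals(t2.metrics)


def test_mirror_symmetry_no_parallel_flow(hex1):
    """With turnover disabled on the symmetric hexagon, each edge's node
    population acquires no net displacement parallel to its edge."""
    p = small_params(k_on=0.0, k_off=0.0)
    rng = np.random.default_rng(0)
    s = seed_nodes(hex1, p, rng)
    start = s.pos.copy()
    for _ in range(100):
        step(s, p, rng)
    disp = s.pos - start
    u = hex1.edge_unit_vectors()
    for e in range(hex1.n_edges):
        band = s.home_edge == e
        assert abs((disp[band] @ u[e]).mean()) < 1e-6


def test_interface_length_and_energy_monotone_without_turnover(hex22):
    """The constant-tension dynamics minimize total interface length when
    turnover is off; both the length and the (d - r_c) energy are
    non-increasing over 100-step windows."""
    p = small_params(k_on=0.0, k_off=0.0)
    rng = np.random.default_rng(0)
    s = seed_nodes(hex22, p, rng)
    lengths = [total_interface_length(s)]
    energies = [interface_energy(s, p.interaction_radius)]
    for _ in range(6):
        for _ in range(100):
            step(s, p, rng)
        lengths.append(total_interface_length(s))
        energies.append(interface_energy(s, p.interaction_radius))
    tol = 1e-6 * abs(lengths[0])
    assert all(b <= a + tol for a, b in zip(lengths, lengths[1:]))
    assert all(b <= a + tol for a, b in zip(energies, energies[1:]))


def test_zero_steps_returns_seeded_state_only(hex1):
    p = SimParams(n_steps=0, seed=0)
    traj = run_sim(p, lattice=hex1)
    assert len(traj.snapshots) == 1
    assert traj.snapshots[0].t == 0


# ---------------------------------------------------------------- ablation

def test_ablate_zero_radius_removes_nothing(hex1):
    p = small_params()
    s = seed_nodes(hex1, p, np.random.default_rng(0))
    out = ablate(s, 0, 0.0)
    assert out.n_alive == s.n_alive


def test_ablate_huge_radius_removes_everything(hex1):
    p = small_params()
    s = seed_nodes(hex1, p, np.random.default_rng(0))
    out = ablate(s, 0, 100.0)
    assert out.n_alive == 0
    assert len(out.bonds) == 0


def test_ablate_unknown_edge_raises(hex1):
    p = small_params()
    s = seed_nodes(hex1, p, np.random.default_rng(0))
    with pytest.raises(LookupError):
        ablate(s, 999, 1.0)


def test_ablation_recoil_points_away_from_cut():
    """After cutting a tensioned network, nearby nodes move away from the
    incision site on average over the next steps."""
    lat = build_hex_lattice(2, 2, 6.0)
    p = SimParams(k_on=0.05, k_off=0.001, n_steps=2000, seed=2)
    rng = np.random.default_rng(p.seed)
    s = seed_nodes(lat, p, rng)
    for _ in range(2000):
        step(s, p, rng)
    # innermost edge
    mids = lat.edge_midpoints()
    center = lat.vertices.mean(axis=0)
    edge_id = int(np.linalg.norm(mids - center, axis=1).argmin())
    cut = mids[edge_id]
    radius = 1.0
    s = ablate(s, edge_id, radius)
    rebuild_interfaces(s, p)
    near = s.alive & (np.linalg.norm(s.pos - cut, axis=1) < 2 * radius)
    start = s.pos.copy()
    for _ in range(10):
        step(s, p, rng)
    disp = s.pos[near] - start[near]
    outward = start[near] - cut
    outward /= np.linalg.norm(outward, axis=1, keepdims=True)
    assert (disp * outward).sum(axis=1).mean() > 0


# ---------------------------------------------------------------- metrics

def test_metrics_uniform_nodes_give_unit_ratio(hex1):
    """Nodes spread uniformly over discs and strips give density_ratio 1
    within sampling error."""
    rng = np.random.default_rng(0)
    R, L = 1.2, 6.0
    pts = []
    # uniform in vertex discs
    for v in hex1.vertices:
        n = 400
        r = R * np.sqrt(rng.random(n))
        th = rng.random(n) * 2 * np.pi
        pts.append(v + np.column_stack([r * np.cos(th), r * np.sin(th)]))
    # uniform in edge strips
    ends = hex1.edge_endpoints()
    u = hex1.edge_unit_vectors()
    for e in range(hex1.n_edges):
        n = int(400 * (L - 2 * R) * 2 * R / (np.pi * R ** 2))
        s_ = R + rng.random(n) * (L - 2 * R)
        off = (rng.random(n) - 0.5) * 2 * R
        perp = np.array([-u[e][1], u[e][0]])
        pts.append(ends[e, 0] + s_[:, None] * u[e] + off[:, None] * perp)
    state = NetworkState.from_positions(np.concatenate(pts), 1.6,
                                        lattice=hex1)
    m = network_metrics(state, vertex_radius=R)
    assert abs(m["density_ratio"] - 1.0) < 0.15


def test_metrics_all_nodes_at_vertices_gives_inf(hex1):
    state = NetworkState.from_positions(hex1.vertices, 1.6, lattice=hex1)
    m = network_metrics(state, vertex_radius=1.2)
    assert np.isinf(m["density_ratio"])


def test_metrics_empty_state_raises(hex1):
    p = small_params()
    s = seed_nodes(hex1, p, np.random.default_rng(0))
    s.alive[:] = False
    with pytest.raises(EmptyStateError):
        network_metrics(s)


# ------------------------------------------------------- regime behaviour

def test_wt_network_stays_interconnected_and_intact(wt_traj):
    """High-k_on regime: every edge keeps middle-third occupancy at every
    recorded snapshot and the interface graph stays one component."""
    m = wt_traj.metrics
    assert (m["frac_intact_edges"] == 1.0).all()
    assert m["n_components"].iloc[-1] == 1


def test_dunk_network_ruptures(dunk_traj):
    """Low-k_on regime: at t=8000 at least half of the edges have lost all
    middle-third nodes."""
    m = dunk_traj.metrics
    assert m["frac_intact_edges"].iloc[-1] <= 0.5


def test_wt_band_width_narrows(wt_traj):
    """Smoothed band width is non-increasing through the first half of the
    run (the flow phase narrows the myosin band)."""
    bw = wt_traj.metrics["mean_band_width"].to_numpy()
    half = bw[:len(bw) // 2 + 1]
    sm = np.convolve(half, np.ones(3) / 3, mode="valid")
    assert np.all(np.diff(sm) <= 0.05)
    assert sm[-1] < sm[0] / 2
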