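"""Particle transit: integration, PDFs, KL distances, lobules, saddles."""

import numpy as np
import pytest

from chorioflow.geometry import Junction, JunctionMap
from chorioflow.oracle import (SourceSinkLayout, layout_from_junctions,
                               solve_plane_potential)
from chorioflow.tracer import (PlanarVelocityField, TransitPDF,
                               dye_lobule_map,
                               find_stagnation_and_separatrices, kl_distance,
                               kl_divergence, pdf_pearson,
                               shared_transit_pdfs, trace_particles,
                               transit_pdf)


def _radial_pair_field(n=128, spacing=5.0, strength=2e-11):
    """Analytic source/sink pair rasterized on a grid (free-space kernel)."""
    jm = JunctionMap((Junction(0, "arteriole", (0.25 * n * spacing,
                                                0.5 * n * spacing), 15.0),
                      Junction(1, "venule", (0.75 * n * spacing,
                                              0.5 * n * spacing), 15.0)))
    layout = SourceSinkLayout(
        positions_um=np.array([j.center_um for j in jm.junctions]),
        strengths_m3s=np.array([strength, -strength]),
        domain_um=(n * spacing, n * spacing), gap_um=10.0,
        core_radius_um=np.array([15.0, 15.0]))
    field = solve_plane_potential(layout, (n, n), kernel="free")
    field.periodic = False
    return field, jm


# ----------------------------------------------------------- integration ---

def test_uniform_duct_transit_times():
    """Constant speed U across a duct gives travel time = L / U."""
    n = 64
    spacing = 5.0
    U = 1e-3  # m/s
    field = PlanarVelocityField(np.full((n, n), U), np.zeros((n, n)),
                                spacing, periodic=True)
    # wide venule so every release angle is captured downstream
    jm = JunctionMap((Junction(0, "arteriole", (40.0, 160.0), 15.0),
                      Junction(1, "venule", (280.0, 160.0), 30.0)))
    rec = trace_particles(field, jm, n_particles=120, seed=0)
    exited = [r for r in rec if r.status == "exited"]
    assert len(exited) == 120
    # fastest path: on-axis from rim + 1 cell to the venule rim
    L_min = (280.0 - 30.0 - (40.0 + 20.0)) * 1e-6
    times = np.array([r.travel_time_s for r in exited])
    assert times.min() == pytest.approx(L_min / U, rel=0.02)
    # off-axis release only lengthens the straight path slightly
    assert np.median(times) == pytest.approx(L_min / U, rel=0.08)
    assert times.max() < 1.25 * L_min / U


def test_trace_deterministic_under_seed():
    field, jm = _radial_pair_field()
    r1 = trace_particles(field, jm, n_particles=200, seed=42)
    r2 = trace_particles(field, jm, n_particles=200, seed=42)
    assert [x.travel_time_s for x in r1] == [x.travel_time_s for x in r2]
    assert [x.status for x in r1] == [x.status for x in r2]


def test_record_conservation():
    field, jm = _radial_pair_field()
    rec = trace_particles(field, jm, n_particles=300, seed=1)
    counts = {"exited": 0, "stagnant": 0, "max_steps": 0}
    for r in rec:
        counts[r.status] += 1
    assert sum(counts.values()) == 300


def test_no_throughflow_raises():
    n = 32
    field = PlanarVelocityField(np.zeros((n, n)), np.zeros((n, n)), 5.0)
    jm = JunctionMap((Junction(0, "arteriole", (40.0, 80.0), 12.0),
                      Junction(1, "venule", (120.0, 80.0), 12.0)))
    with pytest.raises(ValueError, match="no through-flow"):
        trace_particles(field, jm, n_particles=50, seed=0)


def test_halving_step_changes_times_below_half_percent():
    field, jm = _radial_pair_field()
    r1 = trace_particles(field, jm, n_particles=150, seed=3, step_frac=0.2)
    r2 = trace_particles(field, jm, n_particles=150, seed=3, step_frac=0.1)
    t1 = np.array([r.travel_time_s for r in r1 if r.status == "exited"])
    t2 = np.array([r.travel_time_s for r in r2 if r.status == "exited"])
    m = min(len(t1), len(t2))
    assert np.abs(t1[:m] - t2[:m]).max() / t1[:m].max() < 0.005


# ------------------------------------------------------------------ PDFs ---

def test_transit_pdf_normalizes():
    field, jm = _radial_pair_field()
    rec = trace_particles(field, jm, n_particles=400, seed=5)
    pdf = transit_pdf(rec)
    assert (pdf.density >= 0).all()
    widths = np.diff(pdf.bin_edges)
    assert (pdf.density * widths).sum() == pytest.approx(1.0, abs=1e-9)


def test_transit_pdf_single_value_single_bin():
    from chorioflow.tracer import TransitRecord
    rec = [TransitRecord(i, 0, 1, 0.5, 100.0, "exited") for i in range(150)]
    pdf = transit_pdf(rec, bin_edges=np.array([0.0, 0.25, 0.5, 0.75, 1.0]))
    occupied = pdf.density > 0
    assert occupied.sum() == 1
    assert pdf.density[occupied][0] == pytest.approx(1 / 0.25)


def test_transit_pdf_requires_exits():
    from chorioflow.tracer import TransitRecord
    rec = [TransitRecord(0, 0, -1, 1.0, 10.0, "stagnant")]
    with pytest.raises(ValueError, match="no exited"):
        transit_pdf(rec)


def test_exponential_histogram_matches_generator():
    """10^4 exponential draws stay within 3 sigma sampling bands."""
    from chorioflow.tracer import TransitRecord
    rng = np.random.default_rng(7)
    scale = 0.2
    times = rng.exponential(scale, size=10_000)
    rec = [TransitRecord(i, 0, 1, float(t), 1.0, "exited")
           for i, t in enumerate(times)]
    edges = np.linspace(0, 1.0, 21)
    pdf = transit_pdf(rec, bin_edges=edges)
    width = edges[1] - edges[0]
    p_bin = (np.exp(-edges[:-1] / scale) - np.exp(-edges[1:] / scale))
    expect = p_bin / width / p_bin.sum() * (times < 1.0).mean()
    n_in = pdf.density * width * len(times)
    n_exp = p_bin * len(times)
    sigma = np.sqrt(n_exp * (1 - p_bin))
    assert np.all(np.abs(n_in - n_exp) <= 3 * sigma + 1)


# -------------------------------------------------------------------- KL ---

def test_kl_identity_and_closed_form():
    assert kl_divergence([0.5, 0.5], [0.5, 0.5]) == 0.0
    val = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
    assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
        val, rel=1e-12)


def test_kl_nonnegative_over_random_pairs():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        k = rng.integers(2, 12)
        p = rng.uniform(0.01, 1.0, k)
        q = rng.uniform(0.01, 1.0, k)
        assert kl_divergence(p, q) >= 0.0


def test_kl_distance_modes_and_shared_bins():
    edges = np.linspace(0.0, 1.0, 6)
    d = np.array([2.0, 1.0, 1.0, 0.5, 0.5])
    d = d / (d * np.diff(edges)).sum()
    p = TransitPDF(edges, d, 500)
    q = TransitPDF(edges, d[::-1].copy(), 500)
    assert kl_distance(p, p) == 0.0
    sym = kl_distance(p, q, mode="symmetrized")
    d_pq = kl_distance(p, q, mode="directed")
    d_qp = kl_distance(q, p, mode="directed")
    assert sym == pytest.approx(0.5 * (d_pq + d_qp))
    bad = TransitPDF(np.linspace(0, 2, 6), d / 2, 500)
    with pytest.raises(ValueError, match="share bin edges"):
        kl_distance(p, bad)


def test_pdf_pearson_identical_is_one():
    edges = np.linspace(0.0, 1.0, 8)
    d = np.abs(np.sin(np.arange(7) + 1.0))
    d = d / (d * np.diff(edges)).sum()
    p = TransitPDF(edges, d, 300)
    assert pdf_pearson(p, p) == pytest.approx(1.0)


def test_doubling_particles_keeps_mean_within_3se():
    field, jm = _radial_pair_field()
    r1 = trace_particles(field, jm, n_particles=500, seed=9)
    r2 = trace_particles(field, jm, n_particles=1000, seed=10)
    t1 = np.array([r.travel_time_s for r in r1 if r.status == "exited"])
    t2 = np.array([r.travel_time_s for r in r2 if r.status == "exited"])
    se = np.sqrt(t1.var() / len(t1) + t2.var() / len(t2))
    assert abs(t1.mean() - t2.mean()) < 3 * se


# ---------------------------------------------------------------- lobules ---

def test_single_arteriole_lobule_purity_is_one():
    field, jm = _radial_pair_field()
    lm = dye_lobule_map(field, jm, n_particles_per_arteriole=200, seed=2)
    reached = lm.dominant >= 0
    assert reached.any()
    assert np.allclose(lm.purity[reached], 1.0)
    assert np.isnan(lm.purity[~reached]).all()


def test_two_source_lobule_boundary_on_mirror_line():
    """Symmetric two-arteriole layout splits lobules at the midline."""
    n = 96
    spacing = 5.0
    L = n * spacing
    jm = JunctionMap((
        Junction(0, "arteriole", (0.25 * L, 0.3 * L), 15.0),
        Junction(1, "arteriole", (0.75 * L, 0.3 * L), 15.0),
        Junction(2, "venule", (0.25 * L, 0.8 * L), 15.0),
        Junction(3, "venule", (0.75 * L, 0.8 * L), 15.0)))
    layout = layout_from_junctions(jmap=jm, domain_um=(L, L), gap_um=10.0,
                                   kernel="free")
    field = solve_plane_potential(layout, (n, n), kernel="free")
    field.periodic = False
    lm = dye_lobule_map(field, jm, n_particles_per_arteriole=400, seed=4)
    mid = n // 2
    # sample well inside each lobule, away from the unperfused far field
    band = lm.dominant[:, int(0.3 * n):int(0.7 * n)]
    left = band[:mid - 2]
    right = band[mid + 2:]
    assert (left[left >= 0] == 0).mean() > 0.97
    assert (right[right >= 0] == 1).mean() > 0.97


def test_lobule_partition_tiles_perfused_area():
    field, jm = _radial_pair_field()
    lm = dye_lobule_map(field, jm, n_particles_per_arteriole=300, seed=6)
    reached = lm.counts.sum(axis=0) > 0
    assert ((lm.dominant >= 0) == reached).all()


# ---------------------------------------------------- stagnation/saddles ---

def test_single_pair_has_no_interior_saddle():
    field, jm = _radial_pair_field()
    saddles, _ = find_stagnation_and_separatrices(field, jm)
    assert saddles == []


def _two_sources_one_sink(n=128, spacing=5.0):
    L = n * spacing
    d = 0.15 * L
    cx, cy = 0.35 * L, 0.5 * L
    q = 2e-11
    jm = JunctionMap((
        Junction(0, "arteriole", (cx - d, cy), 12.0),
        Junction(1, "arteriole", (cx + d, cy), 12.0),
        Junction(2, "venule", (0.85 * L, cy), 12.0)))
    layout = SourceSinkLayout(
        positions_um=np.array([j.center_um for j in jm.junctions]),
        strengths_m3s=np.array([q, q, -2 * q]),
        domain_um=(L, L), gap_um=10.0,
        core_radius_um=np.array([12.0, 12.0, 12.0]))
    field = solve_plane_potential(layout, (n, n), kernel="free")
    field.periodic = False
    return field, jm, layout


def test_two_sources_saddle_at_analytic_zero():
    """Saddle sits at the root of the superposed kernel field on the axis.

    With equal sources at x1, x2 and a sink at x3 (all on one line), the
    on-axis velocity is q/(2 pi h) [1/(x-x1) + 1/(x-x2) - 2/(x-x3)]; the
    detected saddle must match the bracketed root between the sources.
    """
    from scipy.optimize import brentq
    field, jm, layout = _two_sources_one_sink()
    saddles, lines = find_stagnation_and_separatrices(field, jm)
    assert len(saddles) >= 1
    x1, x2, x3 = (layout.positions_um[k][0] for k in range(3))
    y0 = layout.positions_um[0][1]

    def u_axis(x):
        return 1.0 / (x - x1) + 1.0 / (x - x2) - 2.0 / (x - x3)

    x_root = brentq(u_axis, x1 + 15.0, x2 - 15.0)
    best = min(saddles, key=lambda s: abs(s.position_um[0] - x_root)
               + abs(s.position_um[1] - y0))
    assert best.position_um[0] == pytest.approx(x_root, abs=field.spacing_um)
    assert best.position_um[1] == pytest.approx(y0, abs=field.spacing_um)
    # saddle speed far below the domain maximum
    smax = np.hypot(field.ux, field.uy).max()
    assert best.speed < 1e-6 * smax
    assert len(lines) >= 4


def test_separatrix_on_mirror_line():
    """Two mirrored sources + two mirrored sinks: separatrix = midline."""
    n = 96
    spacing = 5.0
    L = n * spacing
    jm = JunctionMap((
        Junction(0, "arteriole", (0.3 * L, 0.35 * L), 12.0),
        Junction(1, "arteriole", (0.7 * L, 0.35 * L), 12.0),
        Junction(2, "venule", (0.3 * L, 0.75 * L), 12.0),
        Junction(3, "venule", (0.7 * L, 0.75 * L), 12.0)))
    q = 2e-11
    layout = SourceSinkLayout(
        positions_um=np.array([j.center_um for j in jm.junctions]),
        strengths_m3s=np.array([q, q, -q, -q]),
        domain_um=(L, L), gap_um=10.0,
        core_radius_um=np.full(4, 12.0))
    field = solve_plane_potential(layout, (n, n), kernel="free")
    field.periodic = False
    saddles, lines = find_stagnation_and_separatrices(field, jm)
    assert len(saddles) >= 1
    sx = [s.position_um[0] for s in saddles]
    assert min(abs(x - 0.5 * L) for x in sx) < spacing
    # the separatrix polylines through the central saddle hug the midline
    central = [ln for ln in lines
               if abs(ln[0][0] - 0.5 * L) < spacing and len(ln) > 5]
    assert central
    vertical = [ln for ln in central
                if np.abs(ln[:, 0] - 0.5 * L).max() < spacing]
    assert vertical
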