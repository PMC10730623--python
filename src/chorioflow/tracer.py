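"""Particle transport through converged planar velocity fields.

Corpuscles are released at arteriole junction rims (weighted by local
influx), advected along pathlines of the bilinearly-interpolated in-plane
velocity with adaptive RK4, and terminated when they cross a venule rim.
The resulting arteriole-to-venule transit times form the transit-time PDF;
Kullback-Leibler distances compare PDFs between anatomies, and per-source
dye bookkeeping yields functional lobule maps.  Saddle-type stagnation
points of the mid-plane flow and the separatrices emanating from them
delineate the lobule boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import JunctionMap

__all__ = [
    "PlanarVelocityField",
    "TransitRecord",
    "TransitPDF",
    "LobuleMap",
    "SaddlePoint",
    "planar_field_from_macro",
    "trace_particles",
    "transit_pdf",
    "shared_transit_pdfs",
    "pdf_pearson",
    "kl_divergence",
    "kl_distance",
    "dye_lobule_map",
    "find_stagnation_and_separatrices",
]

RECOMMENDED_MIN_OBS = 2700


@dataclass
class PlanarVelocityField:
    """In-plane velocity sampled on a cell-centred 2-D grid (m/s)."""

    ux: np.ndarray
    uy: np.ndarray
    spacing_um: float
    periodic: bool = True

    def __post_init__(self) -> None:
        self.ux = np.ascontiguousarray(self.ux, dtype=np.float64)
        self.uy = np.ascontiguousarray(self.uy, dtype=np.float64)
        if self.ux.shape != self.uy.shape or self.ux.ndim != 2:
            raise ValueError("ux and uy must be matching 2-D arrays")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ux.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.shape[0] * self.spacing_um,
                self.shape[1] * self.spacing_um)

    def interp(self, pts_um: np.ndarray) -> np.ndarray:
        """Bilinear velocity at (K, 2) positions in um; returns (K, 2) m/s."""
        nx, ny = self.shape
        fx = pts_um[:, 0] / self.spacing_um - 0.5
        fy = pts_um[:, 1] / self.spacing_um - 0.5
        if self.periodic:
            i0 = np.floor(fx).astype(np.int64)
            j0 = np.floor(fy).astype(np.int64)
            tx = fx - i0
            ty = fy - j0
            i0 %= nx
            j0 %= ny
            i1 = (i0 + 1) % nx
            j1 = (j0 + 1) % ny
        else:
            fx = np.clip(fx, 0, nx - 1.0)
            fy = np.clip(fy, 0, ny - 1.0)
            i0 = np.clip(np.floor(fx).astype(np.int64), 0, nx - 2)
            j0 = np.clip(np.floor(fy).astype(np.int64), 0, ny - 2)
            tx = fx - i0
            ty = fy - j0
            i1 = i0 + 1
            j1 = j0 + 1
        out = np.empty((pts_um.shape[0], 2))
        for c, comp in enumerate((self.ux, self.uy)):
            out[:, c] = ((1 - tx) * (1 - ty) * comp[i0, j0]
                         + tx * (1 - ty) * comp[i1, j0]
                         + (1 - tx) * ty * comp[i0, j1]
                         + tx * ty * comp[i1, j1])
        return out


def planar_field_from_macro(macro, grid, mode: str = "depth_averaged"
                            ) -> PlanarVelocityField:
    """Extract the capillary-plane velocity from a 3-D solution.

    ``mode='midplane'`` slices the capillary mid-plane; the default
    depth-averages the in-plane components over the capillary layers,
    weighted by the fluid volume fraction of each cell.
    """
    u = macro.velocity
    if mode == "midplane":
        z = macro.layer_index
        return PlanarVelocityField(u[0, :, :, z].copy(), u[1, :, :, z].copy(),
                                   spacing_um=macro.units.dx * 1e6)
    zsl = grid.capillary_layers()
    w = (1.0 - grid.P[:, :, zsl])
    wsum = np.maximum(w.sum(axis=2), 1e-12)
    ux = (u[0, :, :, zsl] * w).sum(axis=2) / wsum
    uy = (u[1, :, :, zsl] * w).sum(axis=2) / wsum
    return PlanarVelocityField(ux, uy, spacing_um=macro.units.dx * 1e6)


@dataclass(frozen=True)
class TransitRecord:
    """One traced corpuscle."""

    particle_id: int
    arteriole_id: int
    venule_id: int          # -1 unless exited
    travel_time_s: float
    path_length_um: float
    status: str             # exited | stagnant | max_steps


@dataclass
class TransitPDF:
    """Normalized transit-time histogram (density integrates to one)."""

    bin_edges: np.ndarray   # seconds, length n_bins + 1
    density: np.ndarray     # 1/s
    n_obs: int

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        if (self.density < 0).any():
            raise ValueError("density must be non-negative")
        if abs((self.density * widths).sum() - 1.0) > 1e-9:
            raise ValueError("density must integrate to one")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def masses(self) -> np.ndarray:
        return self.density * np.diff(self.bin_edges)

    @property
    def mean_time(self) -> float:
        return float((self.masses * self.bin_centers).sum())


@dataclass
class LobuleMap:
    """Per-cell dominant feeding arteriole and purity of supply."""

    dominant: np.ndarray    # (nx, ny) arteriole id, -1 where unperfused
    purity: np.ndarray      # (nx, ny) in [0, 1], nan where unperfused
    arteriole_ids: np.ndarray
    counts: np.ndarray      # (n_art, nx, ny) traced-mass tallies


@dataclass(frozen=True)
class SaddlePoint:
    position_um: tuple[float, float]
    speed: float
    eigenvalues: tuple[float, float]


# ---------------------------------------------------------------------------
# release and integration
# ---------------------------------------------------------------------------

def _junction_label_grid(field: PlanarVelocityField, jmap: JunctionMap,
                         kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Integer grid labelling junction discs of one kind (-1 elsewhere)."""
    nx, ny = field.shape
    xs = (np.arange(nx) + 0.5) * field.spacing_um
    ys = (np.arange(ny) + 0.5) * field.spacing_um
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    label = np.full((nx, ny), -1, dtype=np.int64)
    ids = []
    for j in jmap.junctions:
        if j.kind != kind:
            continue
        m = (X - j.center_um[0])**2 + (Y - j.center_um[1])**2 <= j.radius_um**2
        label[m] = j.id
        ids.append(j.id)
    return label, np.array(ids, dtype=np.int64)


def _release_points(field: PlanarVelocityField, jmap: JunctionMap,
                    n_particles: int, rng: np.random.Generator,
                    release_offset_cells: float = 1.0,
                    n_angles: int = 128):
    """Flux-weighted release positions on arteriole rims.

    Particles are apportioned to arterioles in proportion to the positive
    radial flux on each release circle, and within a circle the release
    angle is drawn from the positive-flux distribution (with jitter).
    """
    arts = jmap.arterioles
    offsets = release_offset_cells * field.spacing_um
    ang = 2 * np.pi * (np.arange(n_angles) + 0.5) / n_angles
    per_art = []
    for j in arts:
        r = j.radius_um + offsets
        pts = np.stack([j.center_um[0] + r * np.cos(ang),
                        j.center_um[1] + r * np.sin(ang)], axis=1)
        u = field.interp(pts)
        u_r = u[:, 0] * np.cos(ang) + u[:, 1] * np.sin(ang)
        w = np.maximum(u_r, 0.0)
        per_art.append((j, r, w))
    totals = np.array([w.sum() for _, _, w in per_art])
    if totals.sum() <= 0:
        raise ValueError("no through-flow: zero inlet flux at all arterioles")
    counts = np.floor(n_particles * totals / totals.sum()).astype(int)
    # distribute the remainder to the largest fluxes
    for k in np.argsort(-totals)[: n_particles - counts.sum()]:
        counts[k] += 1
    positions = []
    sources = []
    for (j, r, w), m in zip(per_art, counts):
        if m == 0 or w.sum() == 0:
            continue
        p = w / w.sum()
        idx = rng.choice(n_angles, size=m, p=p)
        theta = ang[idx] + rng.uniform(-np.pi / n_angles, np.pi / n_angles,
                                       size=m)
        positions.append(np.stack([j.center_um[0] + r * np.cos(theta),
                                   j.center_um[1] + r * np.sin(theta)],
                                  axis=1))
        sources.append(np.full(m, j.id, dtype=np.int64))
    return np.concatenate(positions), np.concatenate(sources)


def _integrate(field: PlanarVelocityField, jmap: JunctionMap,
               pos: np.ndarray, src: np.ndarray,
               step_frac: float = 0.2,
               max_time_factor: float = 50.0,
               stagnation_speed_frac: float = 1e-6,
               stagnation_patience: int = 100,
               max_steps: int = 500_000,
               deposit: np.ndarray | None = None,
               art_index: dict[int, int] | None = None):
    """Adaptive-step RK4 pathline integration of all particles at once.

    Returns arrays (status_code, venule_id, time_s, path_um).  Status
    codes: 0 exited, 1 stagnant, 2 max_steps.
    """
    K = pos.shape[0]
    h_um = field.spacing_um
    ven_label, _ = _junction_label_grid(field, jmap, "venule")
    nx, ny = field.shape
    Lx, Ly = field.extent_um

    u0 = field.interp(pos)
    speed0 = np.sqrt((u0**2).sum(axis=1))
    u_ref = max(speed0.mean(), 1e-30)
    t_adv = max(Lx, Ly) * 1e-6 / u_ref       # domain advective time, s
    t_max = max_time_factor * t_adv
    stag_speed = stagnation_speed_frac * u_ref

    pos = pos.copy()
    time_s = np.zeros(K)
    path_um = np.zeros(K)
    stag_count = np.zeros(K, dtype=np.int64)
    status = np.full(K, -1, dtype=np.int64)
    venule = np.full(K, -1, dtype=np.int64)
    active = np.arange(K)

    for it in range(max_steps):
        if active.size == 0:
            break
        p = pos[active]
        u1 = field.interp(p)
        sp = np.sqrt((u1**2).sum(axis=1))
        # stagnation bookkeeping
        slow = sp < stag_speed
        stag_count[active] = np.where(slow, stag_count[active] + 1, 0)
        dt = step_frac * h_um * 1e-6 / np.maximum(sp, stag_speed / 10)
        dt = np.minimum(dt, t_adv)           # cap pathological steps
        # RK4 in um with u in m/s
        f = 1e6
        k1 = u1 * f
        k2 = field.interp(p + 0.5 * dt[:, None] * k1) * f
        k3 = field.interp(p + 0.5 * dt[:, None] * k2) * f
        k4 = field.interp(p + dt[:, None] * k3) * f
        dp = dt[:, None] / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        p = p + dp
        p[:, 0] %= Lx
        p[:, 1] %= Ly
        pos[active] = p
        time_s[active] += dt
        path_um[active] += np.sqrt((dp**2).sum(axis=1))
        if deposit is not None:
            ci = (p[:, 0] / h_um).astype(np.int64) % nx
            cj = (p[:, 1] / h_um).astype(np.int64) % ny
            si = np.array([art_index[s] for s in src[active]])
            np.add.at(deposit, (si, ci, cj), 1.0)
        # termination checks
        ci = (p[:, 0] / h_um).astype(np.int64) % nx
        cj = (p[:, 1] / h_um).astype(np.int64) % ny
        vlab = ven_label[ci, cj]
        exited = vlab >= 0
        stagnant = (stag_count[active] >= stagnation_patience) | \
                   (time_s[active] > t_max)
        done = exited | stagnant
        if done.any():
            gi = active[done]
            status[gi] = np.where(exited[done], 0, 1)
            venule[gi] = np.where(exited[done], vlab[done], -1)
            active = active[~done]
    status[status < 0] = 2
    return status, venule, time_s, path_um


def trace_particles(field: PlanarVelocityField, jmap: JunctionMap,
                    n_particles: int = 3000, seed: int = 0,
                    step_frac: float = 0.2,
                    max_time_factor: float = 50.0,
                    max_steps: int = 500_000) -> list[TransitRecord]:
    """Trace corpuscles from arteriole rims to venule rims.

    Stagnant or over-long paths are flagged (and excluded from PDFs by
    :func:`transit_pdf`); the record list always conserves
    ``exited + stagnant + max_steps = n_particles``.
    """
    rng = np.random.default_rng(seed)
    pos, src = _release_points(field, jmap, n_particles, rng)
    status, venule, time_s, path_um = _integrate(
        field, jmap, pos, src, step_frac=step_frac,
        max_time_factor=max_time_factor, max_steps=max_steps)
    names = {0: "exited", 1: "stagnant", 2: "max_steps"}
    return [TransitRecord(i, int(src[i]), int(venule[i]), float(time_s[i]),
                          float(path_um[i]), names[int(status[i])])
            for i in range(len(src))]


# ---------------------------------------------------------------------------
# transit-time PDFs and their comparison
# ---------------------------------------------------------------------------

def _exit_times(records) -> np.ndarray:
    return np.array([r.travel_time_s for r in records
                     if r.status == "exited"])


def transit_pdf(records, n_bins: int = 40,
                bin_edges: np.ndarray | None = None) -> TransitPDF:
    """Normalized histogram of exited transit times."""
    times = _exit_times(records)
    if times.size == 0:
        raise ValueError("no exited records")
    if times.size < 100:
        warnings.warn("fewer than 100 exited records; PDF is unreliable",
                      stacklevel=2)
    elif times.size < RECOMMENDED_MIN_OBS:
        warnings.warn(f"fewer than {RECOMMENDED_MIN_OBS} exited records",
                      stacklevel=2)
    if bin_edges is None:
        density, bin_edges = np.histogram(times, bins=n_bins, density=True)
    else:
        density, bin_edges = np.histogram(times, bins=bin_edges, density=True)
    return TransitPDF(bin_edges=np.asarray(bin_edges), density=density,
                      n_obs=int(times.size))


def shared_transit_pdfs(records_a, records_b, n_bins: int = 40,
                        upper_quantile: float = 0.99
                        ) -> tuple[TransitPDF, TransitPDF]:
    """Two PDFs on shared bin edges spanning both record sets.

    The common support runs from zero to the given quantile of the pooled
    exit times, so a handful of extreme stragglers cannot dominate the
    binning.
    """
    ta, tb = _exit_times(records_a), _exit_times(records_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("no exited records")
    hi = np.quantile(np.concatenate([ta, tb]), upper_quantile)
    edges = np.linspace(0.0, hi, n_bins + 1)
    pa = transit_pdf(records_a, bin_edges=edges)
    pb = transit_pdf(records_b, bin_edges=edges)
    return pa, pb


def pdf_pearson(p: TransitPDF, q: TransitPDF) -> float:
    """Pearson correlation of two PDFs binned on identical edges."""
    if not np.array_equal(p.bin_edges, q.bin_edges):
        raise ValueError("PDFs must share bin edges")
    return float(stats.pearsonr(p.density, q.density)[0])


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Directed KL(p || q) in nats for probability mass vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("mass vectors must have equal length")
    p = p / p.sum()
    q = q / q.sum()
    m = p > 0
    if (q[m] <= 0).any():
        raise ValueError("q must be positive wherever p is")
    return float((p[m] * np.log(p[m] / q[m])).sum())


def kl_distance(p: TransitPDF, q: TransitPDF,
                mode: str = "symmetrized") -> float:
    """Kullback-Leibler distance between two transit-time PDFs.

    Both PDFs must share bin edges (see :func:`shared_transit_pdfs`).
    Empty shared bins receive a pseudocount of one observation before
    normalization.  ``mode='directed'`` returns KL(p || q);
    ``'symmetrized'`` returns the average of the two directions.
    """
    if not np.array_equal(p.bin_edges, q.bin_edges):
        raise ValueError("PDFs must share bin edges; empty overlap")
    if mode not in ("directed", "symmetrized"):
        raise ValueError("mode must be 'directed' or 'symmetrized'")
    cp = np.maximum(np.rint(p.masses * p.n_obs), 0.0)
    cq = np.maximum(np.rint(q.masses * q.n_obs), 0.0)
    cp[cp == 0] = 1.0
    cq[cq == 0] = 1.0
    d_pq = kl_divergence(cp, cq)
    if mode == "directed":
        return d_pq
    return 0.5 * (d_pq + kl_divergence(cq, cp))


# ---------------------------------------------------------------------------
# lobules
# ---------------------------------------------------------------------------

def dye_lobule_map(field: PlanarVelocityField, jmap: JunctionMap,
                   n_particles_per_arteriole: int = 400,
                   seed: int = 0, **integrate_kwargs) -> LobuleMap:
    """Synthetic-dye lobule map: dominant feeding arteriole per cell.

    Each arteriole releases its own tracer bundle; every cell a pathline
    visits tallies one unit of that arteriole's dye.  The dominant source
    and the purity (dominant fraction of total dye) define the functional
    lobules; cells never visited are flagged unperfused (id -1).
    """
    arts = jmap.arterioles
    art_ids = np.array([j.id for j in arts], dtype=np.int64)
    art_index = {j.id: k for k, j in enumerate(arts)}
    nx, ny = field.shape
    deposit = np.zeros((len(arts), nx, ny))
    rng = np.random.default_rng(seed)
    ang = None
    pos_all = []
    src_all = []
    for j in arts:
        m = n_particles_per_arteriole
        theta = rng.uniform(0, 2 * np.pi, m)
        r = j.radius_um + field.spacing_um
        pos_all.append(np.stack([j.center_um[0] + r * np.cos(theta),
                                 j.center_um[1] + r * np.sin(theta)], axis=1))
        src_all.append(np.full(m, j.id, dtype=np.int64))
    pos = np.concatenate(pos_all)
    src = np.concatenate(src_all)
    _integrate(field, jmap, pos, src, deposit=deposit, art_index=art_index,
               **integrate_kwargs)
    total = deposit.sum(axis=0)
    kmax = deposit.argmax(axis=0)
    dominant = np.where(total > 0, art_ids[kmax], -1)
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(total > 0, deposit.max(axis=0) / total, np.nan)
    return LobuleMap(dominant=dominant, purity=purity, arteriole_ids=art_ids,
                     counts=deposit)


# ---------------------------------------------------------------------------
# stagnation points and separatrices
# ---------------------------------------------------------------------------

def _jacobian(field: PlanarVelocityField, pt: np.ndarray,
              h_um: float) -> np.ndarray:
    J = np.empty((2, 2))
    for a in range(2):
        dp = np.zeros(2)
        dp[a] = h_um
        up = field.interp((pt + dp)[None])[0]
        um = field.interp((pt - dp)[None])[0]
        J[:, a] = (up - um) / (2 * h_um * 1e-6)
    return J


def find_stagnation_and_separatrices(field: PlanarVelocityField,
                                     jmap: JunctionMap | None = None,
                                     candidate_frac: float = 0.05,
                                     newton_iters: int = 50,
                                     max_arc_cells: int = 4000):
    """Locate saddle-type stagnation points and trace their separatrices.

    Grid-local speed minima below ``candidate_frac`` of the domain maximum
    seed a Newton iteration on the interpolated velocity; converged zeros
    with a saddle Jacobian (real eigenvalues of opposite sign) are kept.
    From each saddle the four separatrix branches are traced along the
    eigenvector directions (unstable forward, stable backward).
    """
    from scipy.ndimage import minimum_filter

    speed = np.hypot(field.ux, field.uy)
    smax = speed.max()
    if smax == 0:
        return [], []
    h = field.spacing_um
    local_min = (speed == minimum_filter(speed, size=3, mode="wrap"))
    cand = np.argwhere(local_min & (speed < candidate_frac * smax))
    Lx, Ly = field.extent_um
    saddles: list[SaddlePoint] = []
    for ci, cj in cand:
        pt = np.array([(ci + 0.5) * h, (cj + 0.5) * h])
        ok = False
        for _ in range(newton_iters):
            u = field.interp(pt[None])[0]
            if np.hypot(*u) < 1e-9 * smax:
                ok = True
                break
            J = _jacobian(field, pt, 0.2 * h)
            try:
                step = np.linalg.solve(J, -u)
            except np.linalg.LinAlgError:
                break
            step_um = step * 1e6
            norm = np.hypot(*step_um)
            if norm > 2 * h:
                step_um *= 2 * h / norm
            pt = pt + step_um
            pt[0] %= Lx
            pt[1] %= Ly
        if not ok:
            continue
        if jmap is not None and any(
                np.hypot(pt[0] - j.center_um[0], pt[1] - j.center_um[1])
                < j.radius_um + h for j in jmap.junctions):
            continue
        J = _jacobian(field, pt, 0.2 * h)
        lam, vec = np.linalg.eig(J)
        if np.iscomplexobj(lam) and np.abs(lam.imag).max() > \
                1e-6 * np.abs(lam).max():
            continue
        lam = lam.real
        if not (lam.min() < 0 < lam.max()):
            continue
        if any(np.hypot(pt[0] - s.position_um[0], pt[1] - s.position_um[1])
               < h for s in saddles):
            continue
        saddles.append(SaddlePoint((float(pt[0]), float(pt[1])),
                                   float(np.hypot(*field.interp(pt[None])[0])),
                                   (float(lam[0]), float(lam[1]))))

    # trace separatrices from each saddle
    polylines: list[np.ndarray] = []
    for s in saddles:
        pt0 = np.array(s.position_um)
        J = _jacobian(field, pt0, 0.2 * h)
        lam, vec = np.linalg.eig(J)
        lam = lam.real
        vec = vec.real
        for k in range(2):
            direction = 1.0 if lam[k] > 0 else -1.0  # unstable fwd, stable bwd
            for sgn in (1.0, -1.0):
                pts = [pt0.copy()]
                p = pt0 + sgn * vec[:, k] / np.linalg.norm(vec[:, k]) * 0.5 * h
                for _ in range(max_arc_cells):
                    u = field.interp(p[None])[0] * direction
                    nrm = np.hypot(*u)
                    if nrm < 1e-12 * smax:
                        break
                    p = p + u / nrm * 0.5 * h
                    if not (0 <= p[0] < Lx and 0 <= p[1] < Ly):
                        break
                    if jmap is not None and any(
                            np.hypot(p[0] - j.center_um[0],
                                     p[1] - j.center_um[1]) <= j.radius_um
                            for j in jmap.junctions):
                        pts.append(p.copy())
                        break
                    pts.append(p.copy())
                polylines.append(np.array(pts))
    return saddles, polylines
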