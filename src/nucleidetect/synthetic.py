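"""Synthetic embryo-like 4D scenes with exact ground truth.

Frames emulate confocal recordings of early mouse embryos: a handful to a
few dozen bright quasi-spherical nuclei (soft-edged spheres with
low-amplitude internal texture) on a dark background, fluorescence
attenuation along z, anisotropic voxels and additive Gaussian noise at a
controllable SNR.  Cell divisions replace one nucleus by two children of
radius parent / 2^(1/3) (volume conserving) that drift apart over a few
frames.

All randomness is driven by the scene seed, so identical specs render
identical sequences; the ground-truth centroid table of every frame is
exact by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_io import Volume

DEFAULT_FRAME_SHAPE = (103, 103, 51)
DEFAULT_VOXEL_SIZE = (0.8, 0.8, 2.0)


@dataclass
class NucleusTrack:
    """Trajectory of one nucleus: alive from frame ``start`` for
    ``len(centers)`` frames.  Centers are native-grid voxel coordinates;
    radii and the derived diameters are in isotropic (x-voxel) units."""

    id: int
    start: int
    centers: np.ndarray   # (n_alive, 3) voxel coordinates (x, y, z native)
    radii: np.ndarray     # (n_alive,) isotropic voxel units
    peak: float

    def alive(self, t: int) -> bool:
        return self.start <= t < self.start + len(self.centers)

    def at(self, t: int) -> tuple[np.ndarray, float]:
        i = t - self.start
        return self.centers[i], float(self.radii[i])


@dataclass
class SceneSpec:
    """Full description of a synthetic 4D scene."""

    frame_shape: tuple[int, int, int] = DEFAULT_FRAME_SHAPE
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    n_frames: int = 1
    nuclei: list[NucleusTrack] = field(default_factory=list)
    background: float = 20.0
    texture_amp: float = 0.05       # smooth modulation, fraction of peak
    speckle_density: float = 0.01   # impulsive bright-spot probability per voxel
    speckle_amp: float = 0.8        # bright-spot amplitude, fraction of peak
    z_attenuation: float = 0.005    # per native z-slice decay coefficient
    snr_db: float | None = 15.0     # additive-noise level; None = noise-free
    noise_sigma: float | None = None  # explicit sigma overrides snr_db
    edge_width: float = 2.0         # smoothstep edge width, isotropic voxels
    seed: int = 0

    def nuclei_at(self, t: int) -> list[NucleusTrack]:
        return [n for n in self.nuclei if n.alive(t)]


def _smoothstep(x: np.ndarray) -> np.ndarray:
    s = np.clip(x, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def render_clean_frame(spec: SceneSpec, t: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Noise-free render of frame t plus its exact ground-truth table."""
    if t >= spec.n_frames:
        raise ValueError(f"frame {t} out of range (n_frames={spec.n_frames})")
    nx, ny, nz = spec.frame_shape
    dx, dy, dz = spec.voxel_size
    rz = dz / dx  # native z step in isotropic units
    data = np.full(spec.frame_shape, float(spec.background))
    rng = np.random.default_rng((spec.seed, 1, t))
    rows = []
    live = spec.nuclei_at(t)
    for a in live:
        ca, ra = a.at(t)
        for b in live:
            if b.id <= a.id or not b.alive(t):
                continue
            cb, rb = b.at(t)
            dist = np.sqrt(
                (ca[0] - cb[0]) ** 2 + (ca[1] - cb[1]) ** 2 + ((ca[2] - cb[2]) * rz) ** 2
            )
            if dist < max(ra, rb):
                warnings.warn(
                    f"frame {t}: nuclei {a.id} and {b.id} overlap beyond half "
                    f"their size (separation {dist:.1f})", stacklevel=2,
                )
    for n in live:
        center, radius = n.at(t)
        cx, cy, cz = center
        # bounding box in native grid; radius is isotropic, z extent shrinks by rz
        ext = radius + spec.edge_width + 1
        x0, x1 = max(0, int(cx - ext)), min(nx, int(np.ceil(cx + ext)) + 1)
        y0, y1 = max(0, int(cy - ext)), min(ny, int(np.ceil(cy + ext)) + 1)
        z0, z1 = max(0, int(cz - ext / rz)), min(nz, int(np.ceil(cz + ext / rz)) + 1)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        gx, gy, gz = np.meshgrid(
            np.arange(x0, x1) - cx, np.arange(y0, y1) - cy,
            (np.arange(z0, z1) - cz) * rz, indexing="ij",
        )
        d = np.sqrt(gx**2 + gy**2 + gz**2)
        prof = _smoothstep((radius - d) / spec.edge_width + 0.5)
        zatt = np.exp(-spec.z_attenuation * (cz + gz / rz))
        blob = n.peak * prof * zatt
        if spec.texture_amp > 0:
            # impulsive bright spots (chromatin speckles, removable by the
            # median prefilter) plus a weak smooth modulation
            inside = prof > 0.5
            speckle = (rng.random(blob.shape) < spec.speckle_density) & inside
            blob = blob + speckle * (spec.speckle_amp * n.peak)
            tex = rng.normal(0.0, 1.0, blob.shape)
            for ax in range(3):
                tex = (np.roll(tex, 1, ax) + tex + np.roll(tex, -1, ax)) / 3.0
            blob = blob * (1.0 + spec.texture_amp * tex * inside)
        region = data[x0:x1, y0:y1, z0:z1]
        data[x0:x1, y0:y1, z0:z1] = np.maximum(region, spec.background + blob)
        rows.append(
            dict(x=cx, y=cy, z=cz, t=t, id=n.id, diameter=2.0 * radius)
        )
    gt = pd.DataFrame(rows, columns=["x", "y", "z", "t", "id", "diameter"])
    return data, gt


def noise_sigma_for(spec: SceneSpec, clean: np.ndarray) -> float:
    """Noise spread realizing the spec's SNR on a given clean frame."""
    if spec.noise_sigma is not None:
        return float(spec.noise_sigma)
    if spec.snr_db is None:
        return 0.0
    power = float(np.mean(clean.astype(np.float64) ** 2))
    return float(np.sqrt(power / 10.0 ** (spec.snr_db / 10.0)))


def render_frame(spec: SceneSpec, t: int) -> tuple[Volume, pd.DataFrame]:
    """Render frame t (with noise per the spec) and its ground truth."""
    clean, gt = render_clean_frame(spec, t)
    sigma = noise_sigma_for(spec, clean)
    if sigma > 0:
        rng = np.random.default_rng((spec.seed, 2, t))
        noisy = clean + rng.normal(0.0, sigma, clean.shape)
        data = np.clip(noisy, 0.0, None)
    else:
        data = clean
    return Volume(data, spec.voxel_size, t), gt


def render_sequence(spec: SceneSpec) -> list[tuple[Volume, pd.DataFrame]]:
    """Render every frame of the scene."""
    return [render_frame(spec, t) for t in range(spec.n_frames)]


def place_nuclei(
    rng: np.random.Generator,
    frame_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    radii: np.ndarray,
    margin: float = 4.0,
    gap: float = 2.0,
    max_tries: int = 20000,
    packing: str = "box",
    ball_frac: float = 1.0,
) -> np.ndarray:
    """Random non-overlapping centers (native grid) by rejection sampling.

    Spheres keep at least ``gap`` isotropic voxels of clearance between
    surfaces and ``margin`` voxels from every border.  ``packing="ball"``
    confines the centers to the inscribed ellipsoid of the frame, the way
    cells pack inside the roughly spherical embryo volume; ``"box"``
    scatters them over the whole frame.
    """
    nx, ny, nz = frame_shape
    dx, _dy, dz = voxel_size
    rz = dz / dx
    mid = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])
    # place large spheres first: dense configurations pack far more easily
    order = np.argsort(radii)[::-1]
    radii_sorted = np.asarray(radii)[order]
    centers: list[np.ndarray] = []
    for i, r in enumerate(radii_sorted):
        m = r + margin
        lo = np.array([m, m, m / rz])
        hi = np.array([nx - 1 - m, ny - 1 - m, nz - 1 - m / rz])
        if np.any(hi <= lo):
            raise ValueError("frame too small for requested radii/margin")
        for _ in range(max_tries):
            c = rng.uniform(lo, hi)
            if packing == "ball":
                semi = (np.array([nx, ny, nz]) / 2.0 - [m, m, m / rz]) * ball_frac
                u = (c - mid) / semi
                if np.dot(u, u) > 1.0:
                    continue
            ok = True
            for j, other in enumerate(centers):
                d = np.sqrt(
                    (c[0] - other[0]) ** 2 + (c[1] - other[1]) ** 2
                    + ((c[2] - other[2]) * rz) ** 2
                )
                if d < r + radii_sorted[j] + gap:
                    ok = False
                    break
            if ok:
                centers.append(c)
                break
        else:
            raise RuntimeError(f"could not place nucleus {i} after {max_tries} tries")
    out = np.empty((len(radii), 3))
    out[order] = np.array(centers)
    return out


def condense_centers(
    centers: np.ndarray,
    radii: np.ndarray,
    frame_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    gap: float = 0.5,
    n_iter: int = 40,
    step: float = 1.5,
) -> np.ndarray:
    """Pull nuclei into a tight cluster around the frame center.

    Emulates the compacted geometry of a late-cleavage embryo, where most
    neighboring nuclei are near contact: every center drifts toward the
    frame middle each iteration, with pairwise overlaps resolved so that
    surfaces keep ``gap`` isotropic voxels of clearance.
    """
    nx, ny, nz = frame_shape
    rz = voxel_size[2] / voxel_size[0]
    mid = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) * rz / 2.0])
    pos = centers.copy().astype(np.float64)
    pos[:, 2] *= rz
    n = len(pos)
    for _ in range(n_iter):
        for i in range(n):
            v = mid - pos[i]
            d = np.linalg.norm(v)
            if d > 1e-9:
                pos[i] += min(step, d) * v / d
        for _ in range(20):
            moved = False
            for i in range(n):
                for j in range(i + 1, n):
                    v = pos[i] - pos[j]
                    d = np.linalg.norm(v)
                    need = radii[i] + radii[j] + gap
                    if d < need:
                        u = v / d if d > 1e-9 else np.array([1.0, 0.0, 0.0])
                        push = 0.5 * (need - d) + 0.05
                        pos[i] += push * u
                        pos[j] -= push * u
                        moved = True
            if not moved:
                break
    out = pos.copy()
    out[:, 2] /= rz
    for i in range(n):
        m = radii[i] + 3.0
        out[i, 0] = np.clip(out[i, 0], m, nx - 1 - m)
        out[i, 1] = np.clip(out[i, 1], m, ny - 1 - m)
        out[i, 2] = np.clip(out[i, 2], m / rz, nz - 1 - m / rz)
    return out


def blastocyst_scene(
    n_nuclei: int = 32,
    radius_range: tuple[float, float] = (5.0, 8.0),
    seed: int = 0,
    frame_shape: tuple[int, int, int] = DEFAULT_FRAME_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    snr_db: float | None = None,
    **kwargs,
) -> SceneSpec:
    """Single-frame scene emulating an early-blastocyst-stage embryo:
    many small nuclei condensed into a tight cluster with most neighbors
    near contact (fused candidate regions)."""
    spec = constant_scene(
        n_nuclei=n_nuclei, n_frames=1, radius_range=radius_range, seed=seed,
        frame_shape=frame_shape, voxel_size=voxel_size, snr_db=snr_db,
        packing="ball", **kwargs,
    )
    radii = np.array([n.radii[0] for n in spec.nuclei])
    centers = np.array([n.centers[0] for n in spec.nuclei])
    packed = condense_centers(centers, radii, frame_shape, voxel_size)
    for n, c in zip(spec.nuclei, packed):
        n.centers[0] = c
    return spec


def constant_scene(
    n_nuclei: int = 8,
    n_frames: int = 1,
    radius_range: tuple[float, float] = (6.0, 12.0),
    drift: float = 0.0,
    seed: int = 0,
    frame_shape: tuple[int, int, int] = DEFAULT_FRAME_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    snr_db: float | None = 15.0,
    peak_range: tuple[float, float] = (140.0, 200.0),
    packing: str = "box",
    gap: float = 2.0,
    ball_frac: float = 1.0,
    **kwargs,
) -> SceneSpec:
    """Scene with a fixed population, optional per-frame random drift
    (``drift`` isotropic voxels per frame along a random direction)."""
    rng = np.random.default_rng((seed, 0))
    radii = rng.uniform(*radius_range, size=n_nuclei)
    centers0 = place_nuclei(rng, frame_shape, voxel_size, radii, gap=gap,
                            packing=packing, ball_frac=ball_frac)
    rz = voxel_size[2] / voxel_size[0]
    nuclei = []
    for i in range(n_nuclei):
        centers = np.empty((n_frames, 3))
        centers[0] = centers0[i]
        for t in range(1, n_frames):
            step = rng.normal(0.0, 1.0, 3)
            step = drift * step / max(np.linalg.norm(step), 1e-9)
            step[2] /= rz
            centers[t] = centers[t - 1] + step
        nuclei.append(
            NucleusTrack(
                id=i + 1, start=0, centers=centers,
                radii=np.full(n_frames, radii[i]),
                peak=float(rng.uniform(*peak_range)),
            )
        )
    return SceneSpec(
        frame_shape=frame_shape, voxel_size=voxel_size, n_frames=n_frames,
        nuclei=nuclei, snr_db=snr_db, seed=seed, **kwargs,
    )


def make_division_sequence(
    base: SceneSpec,
    division_times: list[tuple[int, int]],
    separation_frames: int = 3,
    seed: int | None = None,
) -> SceneSpec:
    """Scene in which nuclei divide at the given ``(frame, parent_id)``
    events.

    At each division the parent track ends and two children of radius
    parent / 2^(1/3) appear, initially touching (surface separation ~2
    voxels) and drifting apart along a random direction over
    ``separation_frames`` frames.  Total nuclear volume is conserved.
    """
    rng = np.random.default_rng((base.seed if seed is None else seed, 3))
    nuclei = {n.id: n for n in base.nuclei}
    parents: dict[int, int] = {}
    next_id = max(nuclei) + 1 if nuclei else 1
    n_frames = base.n_frames
    rz = base.voxel_size[2] / base.voxel_size[0]
    nx, ny, nz = base.frame_shape

    for t_div, parent_id in sorted(division_times):
        parent = nuclei[parent_id]
        if not parent.alive(t_div - 1):
            raise ValueError(f"parent {parent_id} not alive at frame {t_div - 1}")
        i_end = t_div - parent.start
        c_par, r_par = parent.at(t_div - 1)
        r_child = r_par / 2.0 ** (1.0 / 3.0)
        # truncate parent track at the division
        nuclei[parent_id] = NucleusTrack(
            id=parent.id, start=parent.start,
            centers=parent.centers[:i_end].copy(),
            radii=parent.radii[:i_end].copy(),
            peak=parent.peak,
        )
        direction = rng.normal(0.0, 1.0, 3)
        direction /= max(np.linalg.norm(direction), 1e-9)
        n_alive = n_frames - t_div
        # daughters reform after chromosome segregation roughly one child
        # diameter apart, then drift to about two diameters center-to-center
        half_sep0 = r_child + 2.0
        half_sep1 = 2.0 * r_child + 2.0
        for sgn, cid in ((+1.0, next_id), (-1.0, next_id + 1)):
            centers = np.empty((n_alive, 3))
            for i in range(n_alive):
                f = min(1.0, i / max(separation_frames, 1))
                half = half_sep0 + f * (half_sep1 - half_sep0)
                offset = sgn * half * direction
                offset = offset.copy()
                offset[2] /= rz
                centers[i] = c_par + offset
            m = r_child + 3.0
            centers[:, 0] = np.clip(centers[:, 0], m, nx - 1 - m)
            centers[:, 1] = np.clip(centers[:, 1], m, ny - 1 - m)
            centers[:, 2] = np.clip(centers[:, 2], m / rz, nz - 1 - m / rz)
            nuclei[cid] = NucleusTrack(
                id=cid, start=t_div, centers=centers,
                radii=np.full(n_alive, r_child), peak=parent.peak,
            )
            parents[cid] = parent_id
        next_id += 2

    out = SceneSpec(**{**base.__dict__, "nuclei": list(nuclei.values())})
    _relax_collisions(out, rng, parents=parents)
    return out


def _relax_collisions(spec: SceneSpec, rng: np.random.Generator, gap: float = 2.0,
                      max_iter: int = 60, parents: dict[int, int] | None = None) -> None:
    """Push apart nuclei that interpenetrate, frame by frame.

    Nuclei are solid bodies: any pair closer than the sum of their radii
    plus ``gap`` (isotropic voxels) is displaced symmetrically along the
    line joining the centers.  Displacements accumulate per track and are
    inherited by later frames (and by daughters at birth), so trajectories
    stay smooth.
    """
    nx, ny, nz = spec.frame_shape
    rz = spec.voxel_size[2] / spec.voxel_size[0]
    parents = parents or {}
    delta: dict[int, np.ndarray] = {}

    for t in range(spec.n_frames):
        live = spec.nuclei_at(t)
        for n in live:
            if n.id not in delta:
                # daughters start from their parent's accumulated shift
                delta[n.id] = delta.get(parents.get(n.id, -1), np.zeros(3)).copy()
        # positions in isotropic units
        pos = {}
        rad = {}
        for n in live:
            c, r = n.at(t)
            p = c + delta[n.id]
            pos[n.id] = np.array([p[0], p[1], p[2] * rz])
            rad[n.id] = r
        for _ in range(max_iter):
            moved = False
            for i, a in enumerate(live):
                for b in live[i + 1:]:
                    v = pos[a.id] - pos[b.id]
                    d = np.linalg.norm(v)
                    need = rad[a.id] + rad[b.id] + gap
                    if d >= need:
                        continue
                    u = v / d if d > 1e-9 else rng.normal(0.0, 1.0, 3)
                    u = u / max(np.linalg.norm(u), 1e-9)
                    push = 0.5 * (need - d) + 0.1
                    pos[a.id] = pos[a.id] + push * u
                    pos[b.id] = pos[b.id] - push * u
                    moved = True
            if not moved:
                break
        for n in live:
            r = rad[n.id]
            p = pos[n.id]
            m = r + 3.0
            new_c = np.array([
                np.clip(p[0], m, nx - 1 - m),
                np.clip(p[1], m, ny - 1 - m),
                np.clip(p[2] / rz, m / rz, nz - 1 - m / rz),
            ])
            i_t = t - n.start
            delta[n.id] = new_c - n.centers[i_t]
            n.centers[i_t] = new_c


def embryo_sequence(
    n_frames: int = 20,
    n_initial: int = 8,
    n_final: int = 32,
    seed: int = 0,
    initial_radius_range: tuple[float, float] = (10.0, 13.0),
    frame_shape: tuple[int, int, int] = DEFAULT_FRAME_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    snr_db: float | None = 15.0,
    **kwargs,
) -> SceneSpec:
    """Embryo-like sequence stepping the population from ``n_initial`` to
    ``n_final`` by staggered divisions.

    With the default radii (10-13 isotropic voxels, i.e. diameters 20-26),
    one round of division yields diameters ~16-21 and a second ~12.6-16.4,
    so diameters stay within the 10-26 voxel range throughout.
    """
    if n_final % n_initial != 0 or n_final // n_initial not in (1, 2, 4, 8):
        raise ValueError("n_final must be n_initial * 2^k")
    base = constant_scene(
        n_nuclei=n_initial, n_frames=n_frames, radius_range=initial_radius_range,
        drift=0.3, seed=seed, frame_shape=frame_shape, voxel_size=voxel_size,
        snr_db=snr_db, **kwargs,
    )
    rng = np.random.default_rng((seed, 4))
    n_rounds = int(np.log2(n_final // n_initial))
    events: list[tuple[int, int]] = []
    spec = base
    next_id = n_initial + 1
    ids = list(range(1, n_initial + 1))
    # stagger each round's divisions over a window of frames
    window = max(1, (n_frames - 4) // max(n_rounds, 1))
    for round_i in range(n_rounds):
        t0 = 3 + round_i * window
        times = np.sort(rng.integers(t0, t0 + max(window - 3, 1), size=len(ids)))
        new_ids = []
        for t_div, pid in zip(times, ids):
            events.append((int(t_div), pid))
            new_ids += [next_id, next_id + 1]
            next_id += 2
        ids = new_ids
    return make_division_sequence(base, events, seed=seed)
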