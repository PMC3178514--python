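"""Concentric three-sphere head model: source disc, montage and analytic lead field.

The source space is a single axial slice of grid cells ("voxels", each
carrying one current dipole) inside the innermost sphere of a three-shell
(brain / skull / scalp) spherical conductor.  Scalp potentials are computed
from the Legendre-series solution of the quasi-static forward problem for a
dipole inside the innermost shell.

Units: head geometry is expressed in normalized units with scalp radius 1;
``MM_PER_UNIT`` converts millimetres of the acquisition geometry (slice
height, field of view) to normalized units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MM_PER_UNIT = 100.0  # scalp radius 1 <-> 100 mm

#: default shell radii (brain, skull, scalp) in scalp-radius units
DEFAULT_RADII = (0.87, 0.89, 1.0)
#: default conductivities brain : skull : scalp (classic 1 : 1/80 : 1)
DEFAULT_CONDUCTIVITIES = (1.0, 1.0 / 80.0, 1.0)

#: per-source dipole counts for the four simulated sources S1..S4
SOURCE_SIZES = (90, 30, 32, 100)
#: seed positions (x, y) of the four source patches on the slice: S1
#: "auditory" top, S2/S3 "cognition" right/left, S4 "default mode" lower
#: centre; spaced so the three EEG-visible scalp topographies stay weakly
#: correlated (spatial ICA cannot separate strongly overlapping patterns)
SOURCE_SEEDS = ((0.2, 0.6), (0.6, -0.3), (-0.6, -0.3), (-0.15, -0.6))
#: fixed centres of the two "white matter" holes
HOLE_CENTERS = ((-0.30, -0.12), (0.30, -0.12))


class GeometryError(ValueError):
    """Requested source geometry does not fit inside the head model."""


class ConfigurationError(ValueError):
    """Inconsistent disc / template configuration."""


@dataclass
class SourceDisc:
    """Planar dipole grid inside the brain sphere.

    dipole_positions : (d, 3) array, normalized head units.
    grid_index       : (d, 2) integer (row, col) of each dipole on the grid.
    hole_mask        : (grid, grid) bool, True where a cell was removed by a hole.
    per_source_masks : list of 4 index arrays into the dipole list.
    """

    dipole_positions: np.ndarray
    grid_index: np.ndarray
    hole_mask: np.ndarray
    per_source_masks: list[np.ndarray]
    slice_z: float
    fov_mm: float
    grid_size: int
    hole_radii: tuple[float, float] = (0.0, 0.0)

    @property
    def n_dipoles(self) -> int:
        return self.dipole_positions.shape[0]

    def source_profiles(self) -> np.ndarray:
        """(n_sources, d) indicator maps of the source patches."""
        profiles = np.zeros((len(self.per_source_masks), self.n_dipoles))
        for i, mask in enumerate(self.per_source_masks):
            profiles[i, mask] = 1.0
        return profiles


@dataclass
class Montage:
    """Electrode positions on the unit (scalp) sphere, upper hemisphere."""

    electrode_positions: np.ndarray  # (e, 3), unit norm
    labels: list[str] = field(default_factory=list)

    @property
    def n_electrodes(self) -> int:
        return self.electrode_positions.shape[0]


@dataclass
class LeadField:
    """Gain matrix (electrodes x dipoles) under a recording reference."""

    gain: np.ndarray
    reference: str = "average"


def build_source_disc(
    grid_size: int = 70,
    fov_mm: float = 200.0,
    slice_z_mm: float = 18.0,
    sphere_radii: tuple[float, float, float] = DEFAULT_RADII,
    hole_spec: list[tuple[float, float, float]] | None = None,
    target_count: int | None = 2452,
    disc_radius: float | None = None,
) -> SourceDisc:
    """Build the slice source space: grid cells inside the brain-sphere
    cross-section, minus two circular "white matter" holes.

    With ``hole_spec=None`` the hole radii are calibrated deterministically so
    that exactly ``target_count`` cells survive (the default reproduces the
    2452-dipole disc).  An explicit ``hole_spec`` is a list of
    ``(cx, cy, radius)`` tuples applied literally.
    """
    if grid_size < 2:
        raise ConfigurationError("grid_size must be >= 2")
    r_brain = float(sphere_radii[0])
    if not (sphere_radii[0] < sphere_radii[1] < sphere_radii[2]):
        raise GeometryError("sphere radii must be strictly increasing")
    z = slice_z_mm / MM_PER_UNIT
    if abs(z) >= r_brain:
        raise GeometryError(
            f"slice at z={z:.3f} lies outside the brain sphere (radius {r_brain})"
        )
    rho_max = np.sqrt(r_brain**2 - z**2)  # cross-section radius
    if disc_radius is not None and disc_radius > rho_max:
        raise GeometryError(
            f"requested disc radius {disc_radius:.3f} exceeds the brain-sphere "
            f"cross-section radius {rho_max:.3f} at z={z:.3f}"
        )
    rho = disc_radius if disc_radius is not None else rho_max

    half = fov_mm / MM_PER_UNIT / 2.0
    step = 2.0 * half / grid_size
    centers = (np.arange(grid_size) + 0.5) * step - half
    gx, gy = np.meshgrid(centers, centers, indexing="ij")
    in_circle = gx**2 + gy**2 < rho**2 - 1e-12

    hole_mask = np.zeros_like(in_circle)
    hole_radii = [0.0, 0.0]
    if hole_spec is not None:
        for cx, cy, hr in hole_spec:
            hole_mask |= in_circle & ((gx - cx) ** 2 + (gy - cy) ** 2 < hr**2)
        hole_radii = [hr for (_, _, hr) in hole_spec][:2] + [0.0, 0.0]
    elif target_count is not None:
        n_remove = int(in_circle.sum()) - target_count
        if n_remove < 0:
            raise ConfigurationError(
                f"target_count {target_count} exceeds available cells {in_circle.sum()}"
            )
        # split removals between the two fixed hole centres ~3:2, then take
        # the nearest surviving cells to each centre; the implied radius is
        # the midpoint between the last removed and first kept distance.
        splits = [int(round(n_remove * 0.6)), 0]
        splits[1] = n_remove - splits[0]
        alive = in_circle.copy()
        for (cx, cy), n_h, j in zip(HOLE_CENTERS, splits, range(2)):
            if n_h <= 0:
                continue
            d2 = (gx - cx) ** 2 + (gy - cy) ** 2
            d2 = np.where(alive, d2, np.inf)
            order = np.argsort(d2, axis=None)
            cut = order[:n_h]
            rows, cols = np.unravel_index(cut, d2.shape)
            hole_mask[rows, cols] = True
            alive[rows, cols] = False
            d_last = np.sqrt(d2.flat[order[n_h - 1]])
            d_next = np.sqrt(d2.flat[order[n_h]]) if n_h < order.size else d_last
            hole_radii[j] = 0.5 * (d_last + d_next)

    keep = in_circle & ~hole_mask
    rows, cols = np.nonzero(keep)
    pos = np.column_stack([gx[rows, cols], gy[rows, cols], np.full(rows.size, z)])
    grid_index = np.column_stack([rows, cols])

    # assign the four source patches: nearest surviving cells to each seed,
    # greedily in source order (patches are pairwise disjoint by construction)
    taken = np.zeros(pos.shape[0], dtype=bool)
    masks: list[np.ndarray] = []
    for (sx, sy), size in zip(SOURCE_SEEDS, SOURCE_SIZES):
        d2 = (pos[:, 0] - sx) ** 2 + (pos[:, 1] - sy) ** 2
        d2 = np.where(taken, np.inf, d2)
        idx = np.argsort(d2)[:size]
        if np.isinf(d2[idx]).any():
            raise ConfigurationError(
                "per-source template incompatible with hole placement: "
                f"not enough free cells near seed ({sx}, {sy})"
            )
        taken[idx] = True
        masks.append(np.sort(idx))

    return SourceDisc(
        dipole_positions=pos,
        grid_index=grid_index,
        hole_mask=hole_mask,
        per_source_masks=masks,
        slice_z=z,
        fov_mm=fov_mm,
        grid_size=grid_size,
        hole_radii=(hole_radii[0], hole_radii[1]),
    )


def build_montage(
    n_electrodes: int = 62,
    scheme: str = "spiral",
    position_file: str | None = None,
) -> Montage:
    """Place electrodes on the upper unit hemisphere.

    ``scheme="spiral"`` lays out a quasi-uniform golden-angle spiral;
    ``scheme="file"`` reads a whitespace-delimited ``label x y z`` file and
    projects any off-sphere point onto the sphere (with a logged warning).
    """
    if scheme == "file":
        if position_file is None:
            raise ValueError("scheme='file' requires position_file")
        return read_electrode_positions(position_file)
    if n_electrodes < 1:
        raise ValueError("n_electrodes must be >= 1")
    if n_electrodes == 1:
        pos = np.array([[0.0, 0.0, 1.0]])
    else:
        i = np.arange(n_electrodes)
        zc = 1.0 - (i + 0.5) / n_electrodes  # z in (0, 1): upper hemisphere
        phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
        s = np.sqrt(1.0 - zc**2)
        pos = np.column_stack([s * np.cos(phi), s * np.sin(phi), zc])
    labels = [f"E{j + 1}" for j in range(n_electrodes)]
    return Montage(electrode_positions=pos, labels=labels)


def read_electrode_positions(path: str) -> Montage:
    """Read a whitespace-delimited ``label x y z`` electrode file."""
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 'label x y z'")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if not rows:
        raise ValueError(f"{path}: no electrodes found")
    pos = np.asarray(rows)
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"{path}: electrode at origin cannot be projected")
    off = np.abs(norms - 1.0) > 1e-6
    if off.any():
        logger.warning(
            "%d electrode(s) off the unit sphere; projecting onto it", int(off.sum())
        )
    pos = pos / norms[:, None]
    return Montage(electrode_positions=pos, labels=labels)


def _transfer_coefficients(
    n_max: int,
    radii: tuple[float, float, float],
    conductivities: tuple[float, float, float],
) -> np.ndarray:
    """Per-degree transfer factors t_n of the three-shell conductor.

    For each harmonic degree n the primary dipole field contributes a term
    ``u * r**-(n+1)`` inside the brain shell; t_n is the scalp-surface value
    of the full (primary + secondary) degree-n field per unit u, obtained by
    solving the 5x5 boundary-condition system (continuity of potential and
    radial current at both interfaces, zero current through the scalp).
    """
    r1, r2, r3 = radii
    s1, s2, s3 = conductivities
    t = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        # unknowns [A, B, C, D, E]
        M = np.zeros((5, 5))
        b = np.zeros(5)
        rn = lambda r: r**n
        rm = lambda r: r ** (-n - 1)
        drn = lambda r: n * r ** (n - 1)
        drm = lambda r: -(n + 1) * r ** (-n - 2)
        # V1 = r^-(n+1) + A r^n ; V2 = B r^n + C r^-(n+1) ; V3 = D r^n + E r^-(n+1)
        M[0] = [rn(r1), -rn(r1), -rm(r1), 0, 0]
        b[0] = -rm(r1)
        M[1] = [s1 * drn(r1), -s2 * drn(r1), -s2 * drm(r1), 0, 0]
        b[1] = -s1 * drm(r1)
        M[2] = [0, rn(r2), rm(r2), -rn(r2), -rm(r2)]
        M[3] = [0, s2 * drn(r2), s2 * drm(r2), -s3 * drn(r2), -s3 * drm(r2)]
        M[4] = [0, 0, 0, drn(r3), drm(r3)]
        sol = np.linalg.solve(M, b)
        t[n] = sol[3] * rn(r3) + sol[4] * rm(r3)
    return t


def compute_leadfield(
    montage: Montage,
    disc: SourceDisc,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES,
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0),
    truncation: int = 60,
    tol: float = 1e-8,
    max_truncation: int = 1024,
    reference: str = "average",
) -> LeadField:
    """Analytic lead field of unit dipoles (fixed orientation) in the
    three-sphere model.

    The Legendre series is summed adaptively: starting from ``truncation``
    terms the order is doubled until the scalp potentials change by less than
    ``tol`` (relative), up to ``max_truncation``.
    """
    if np.any(np.asarray(conductivities) <= 0):
        raise ValueError("conductivities must be positive")
    pos = disc.dipole_positions
    b = np.linalg.norm(pos, axis=1)
    if np.any(b >= radii[0]):
        raise GeometryError("all dipoles must lie strictly inside the brain sphere")
    q = np.asarray(orientation, dtype=float)
    q = q / np.linalg.norm(q)

    E = montage.electrode_positions  # (e,3) unit
    safe_b = np.where(b > 0, b, 1.0)
    rhat0 = pos / safe_b[:, None]  # (d,3); arbitrary for b=0 (term vanishes)
    x = E @ rhat0.T  # cos(gamma), (e,d)
    q_r0 = rhat0 @ q  # (d,)
    q_re = E @ q  # (e,)

    t = _transfer_coefficients(max_truncation, radii, conductivities)

    e_n, d_n = x.shape
    V = np.zeros((e_n, d_n))
    P_prev = np.ones_like(x)  # P_0
    P = x.copy()  # P_1
    dP_prev = np.zeros_like(x)  # P_0'
    dP = np.ones_like(x)  # P_1'
    b_pow = np.ones_like(b)  # b^(n-1)
    checkpoint = truncation
    V_prev_cp = None
    n = 1
    while n <= max_truncation:
        term = t[n] * b_pow * ((n * P - x * dP) * q_r0 + dP * q_re[:, None])
        V += term
        if n == checkpoint:
            if V_prev_cp is not None:
                scale = np.max(np.abs(V))
                if scale == 0 or np.max(np.abs(V - V_prev_cp)) < tol * scale:
                    break
            V_prev_cp = V.copy()
            checkpoint *= 2
        # advance recurrences to degree n+1
        P_next = ((2 * n + 1) * x * P - n * P_prev) / (n + 1)
        dP_next = dP_prev + (2 * n + 1) * P
        P_prev, P = P, P_next
        dP_prev, dP = dP, dP_next
        b_pow = b_pow * b
        n += 1
    else:
        logger.warning(
            "lead-field series not converged at order %d (dipoles close to the "
            "brain-sphere boundary); result kept at the highest order",
            max_truncation,
        )

    V /= 4.0 * np.pi * conductivities[0]
    if reference == "average":
        V = V - V.mean(axis=0, keepdims=True)
    return LeadField(gain=V, reference=reference)


def save_leadfield(lf: LeadField, path: str) -> None:
    """Write the gain matrix as delimited text with a JSON sidecar."""
    np.savetxt(path, lf.gain)
    with open(path + ".json", "w") as fh:
        json.dump({"reference": lf.reference, "shape": list(lf.gain.shape)}, fh)


def load_leadfield(path: str) -> LeadField:
    gain = np.loadtxt(path)
    ref = "average"
    try:
        with open(path + ".json") as fh:
            ref = json.load(fh).get("reference", "average")
    except FileNotFoundError:
        pass
    return LeadField(gain=np.atleast_2d(gain), reference=ref)
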