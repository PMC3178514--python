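"""Spatial ICA with multi-run consensus clustering and component screening.

Spatial ICA imposes statistical independence across spatial locations
(channels for EEG, voxels for fMRI): the data matrix (locations x times) is
decomposed as ``data ~ maps.T @ time_courses`` where the rows of ``maps``
are independent spatial patterns and the mixing columns are time courses.

The fixed-point (FastICA-style) iteration is implemented here rather than
delegated because deflation must stop early the first time a unit fails to
converge: on the low-rank network data this is what terminates extraction
after the few genuine components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


class DecompositionError(RuntimeError):
    """No independent component could be extracted."""


@dataclass
class ComponentSet:
    """Row-aligned spatial maps (n_comp x n_loc) and time courses (n_comp x n_time).

    Spatial maps are unit-norm with the largest-magnitude entry positive.
    """

    spatial_maps: np.ndarray
    time_courses: np.ndarray
    modality: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]


def _canonicalize(maps: np.ndarray) -> np.ndarray:
    """Unit-norm rows, largest-|entry| positive."""
    maps = np.atleast_2d(maps).astype(float)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms = np.where(norms > 0, norms, 1.0)
    maps = maps / norms
    for row in maps:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    return maps


def _fit_time_courses(maps: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Least-squares mixing time courses of the maps against the data."""
    G = maps @ maps.T
    return np.linalg.solve(G, maps @ data)


def whiten(data: np.ndarray, n_max: int | str | None = None, rank_tol: float = 1e-10):
    """PCA-whitening of the spatial-sample arrangement.

    ``data`` is (n_loc, n_time); each time point is centered across
    locations.  Returns ``Z`` (r x n_loc): the whitened coordinates of the
    n_loc spatial samples in r principal directions.

    ``n_max="auto"`` keeps only eigenvalues standing clear of the noise
    bulk (above twice the median of the lower half of the positive
    spectrum) -- the dominant-subspace rule for data whose signal occupies
    a few high-variance directions.
    """
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    n_loc = data.shape[0]
    Xc = data - data.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > rank_tol * s[0])) if s.size else 0
    if rank == 0:
        raise DecompositionError("rank-zero data")
    if n_max == "auto":
        ev = s[:rank] ** 2
        lower = ev[rank // 2 :]
        thresh = 2.0 * np.median(lower) if lower.size else 0.0
        r = max(2, int(np.sum(ev > thresh)))
        r = min(r, rank)
    else:
        r = rank if n_max is None else min(int(n_max), rank)
        if n_max is not None and r < int(n_max):
            logger.warning("rank-deficient data: reducing n_max from %d to %d", int(n_max), r)
    Z = np.sqrt(n_loc) * U[:, :r].T  # (r, n_loc), unit-variance rows
    return Z


CONTRASTS = {
    # g, g' pairs of the fixed-point contrast
    "skew": (lambda u: u**2, lambda u: 2.0 * u),
    "logcosh": (np.tanh, lambda u: 1.0 - np.tanh(u) ** 2),
    "cube": (lambda u: u**3, lambda u: 3.0 * u**2),
}


def _fastica_units(
    Z: np.ndarray, n_units: int, mode: str, rng: np.random.Generator,
    tol: float, max_iter: int, fun: str = "skew", n_attempts: int = 1,
) -> np.ndarray:
    """Fixed-point iteration in whitened space.

    Returns the unmixing matrix W (n_found x r).  In deflation mode units
    are extracted one at a time and extraction stops at the first unit that
    fails to converge; in symmetric mode exactly ``n_units`` are iterated
    jointly with symmetric decorrelation.

    The default contrast is skewness (g = u^2): spatial maps of focal
    networks are one-signed patches, strongly skewed across locations but
    only weakly kurtotic, and the classic even contrasts (logcosh, cube)
    are nearly blind to them.
    """
    r, n = Z.shape
    n_units = min(n_units, r)
    try:
        g_fun, gp_fun = CONTRASTS[fun]
    except KeyError:
        raise ValueError(f"unknown contrast {fun!r}") from None

    def g(u):
        return g_fun(u), gp_fun(u)

    if mode == "symmetric":
        W = rng.standard_normal((n_units, r))
        W = _sym_decorrelate(W)
        for _ in range(max_iter):
            U = W @ Z
            gu, gp = g(U)
            W_new = (gu @ Z.T) / n - gp.mean(axis=1)[:, None] * W
            W_new = _sym_decorrelate(W_new)
            lim = np.max(
                np.minimum(
                    np.linalg.norm(W_new - W, axis=1), np.linalg.norm(W_new + W, axis=1)
                )
            )
            W = W_new
            if lim < tol:
                break
        return W

    if mode != "deflation":
        raise ValueError(f"unknown ICA mode {mode!r}")

    def _one_unit(w: np.ndarray, W_rows: list[np.ndarray], damped: bool):
        for _ in range(max_iter):
            u = w @ Z
            gu, gp = g(u)
            w_new = (Z @ gu) / n - gp.mean() * w
            for wj in W_rows:  # Gram-Schmidt against found units
                w_new = w_new - (w_new @ wj) * wj
            nrm = np.linalg.norm(w_new)
            if nrm < 1e-12:
                return None
            w_new /= nrm
            if damped:  # half-step update; breaks period-2 cycles
                if w_new @ w < 0:
                    w_new = -w_new
                w_new = w_new + w
                w_new /= np.linalg.norm(w_new)
            # sign-insensitive displacement, as in classic FastICA
            if min(np.linalg.norm(w_new - w), np.linalg.norm(w_new + w)) < tol:
                return w_new
            w = w_new
        return None

    W_rows: list[np.ndarray] = []
    for _ in range(n_units):
        found = None
        # optional restarts (the last one damped) before giving up: the
        # plain iteration can fall into a stable two-cycle between extrema
        for attempt in range(max(1, n_attempts)):
            w0 = rng.standard_normal(r)
            w0 /= np.linalg.norm(w0)
            found = _one_unit(w0, W_rows, damped=attempt == n_attempts - 1 and n_attempts > 1)
            if found is not None:
                break
        if found is None:
            break  # deflation terminates once a unit fails to converge
        W_rows.append(found)
    if not W_rows:
        raise DecompositionError("no ICA unit converged")
    return np.array(W_rows)


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    s, E = np.linalg.eigh(W @ W.T)
    s = np.maximum(s, 1e-12)
    return E @ np.diag(1.0 / np.sqrt(s)) @ E.T @ W


def spatial_ica(
    data: np.ndarray,
    n_max: int | str | None = None,
    mode: str = "deflation",
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 1000,
    modality: str = "",
    fun: str = "skew",
    n_attempts: int = 1,
    _whitened: np.ndarray | None = None,
) -> ComponentSet:
    """Spatial ICA of a (locations x times) matrix.

    ``n_max`` bounds the whitened problem; it defaults to the smaller data
    dimension (channels for EEG in its trials-concatenated arrangement,
    time points for fMRI) and accepts ``"auto"`` for dominant-subspace
    retention.  Deflation mode stops early once a unit fails to converge;
    symmetric mode extracts exactly the whitened dimension.
    """
    data = np.asarray(data, dtype=float)
    if n_max is None:
        n_max = min(data.shape)
    Z = _whitened if _whitened is not None else whiten(data, n_max=n_max)
    rng = np.random.default_rng(seed)
    n_units = Z.shape[0] if not isinstance(n_max, int) else min(n_max, Z.shape[0])
    W = _fastica_units(Z, n_units, mode, rng, tol, max_iter, fun=fun, n_attempts=n_attempts)
    maps = _canonicalize(W @ Z)
    tcs = _fit_time_courses(maps, data)
    return ComponentSet(
        spatial_maps=maps,
        time_courses=tcs,
        modality=modality,
        provenance={"seed": seed, "mode": mode, "n_units": maps.shape[0]},
    )


def consensus_components(
    runs: list[ComponentSet],
    similarity_threshold: float = 0.8,
    min_occurrence: float = 0.5,
    data: np.ndarray | None = None,
) -> ComponentSet:
    """Cluster spatial maps across ICA runs and return cluster centroids.

    Maps are clustered by average-linkage agglomeration on the sign-invariant
    correlation distance ``1 - |corr|``; clusters present in at least
    ``min_occurrence`` of the runs survive.  Centroid maps are sign-aligned
    means (re-normalized); time courses are refit by least squares against
    ``data`` when provided, else averaged over members.
    """
    if len(runs) < 2:
        raise ValueError("consensus requires at least 2 runs")
    maps = np.vstack([r.spatial_maps for r in runs])
    tcs = np.vstack([r.time_courses for r in runs])
    run_of = np.concatenate([np.full(r.n_components, i) for i, r in enumerate(runs)])
    n_runs = len(runs)
    if maps.shape[0] == 0:
        return ComponentSet(maps, tcs, modality=runs[0].modality)

    mc = maps - maps.mean(axis=1, keepdims=True)
    sd = np.linalg.norm(mc, axis=1)
    sd = np.where(sd > 0, sd, 1.0)
    C = np.abs((mc / sd[:, None]) @ (mc / sd[:, None]).T)
    D = np.clip(1.0 - C, 0.0, None)
    np.fill_diagonal(D, 0.0)
    if maps.shape[0] > 1:
        labels = fcluster(
            linkage(squareform(D, checks=False), method="average"),
            t=1.0 - similarity_threshold,
            criterion="distance",
        )
    else:
        labels = np.array([1])

    cent_maps, cent_tcs, sizes = [], [], []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        occ = len(np.unique(run_of[members])) / n_runs
        if occ < min_occurrence:
            continue
        ref = maps[members[0]]
        signs = np.sign(maps[members] @ ref)
        signs[signs == 0] = 1.0
        mean_map = (signs[:, None] * maps[members]).mean(axis=0)
        cent_maps.append(mean_map)
        cent_tcs.append((signs[:, None] * tcs[members]).mean(axis=0))
        sizes.append(len(members))
    if not cent_maps:
        logger.warning("no consensus cluster met min_occurrence=%.2f", min_occurrence)
        empty = np.empty((0, maps.shape[1]))
        return ComponentSet(empty, np.empty((0, tcs.shape[1])), modality=runs[0].modality)

    order = np.argsort(-np.asarray(sizes), kind="stable")
    cmaps = _canonicalize(np.array(cent_maps)[order])
    if data is not None:
        ctcs = _fit_time_courses(cmaps, np.asarray(data, dtype=float))
    else:
        ctcs = np.array(cent_tcs)[order]
    return ComponentSet(
        spatial_maps=cmaps,
        time_courses=ctcs,
        modality=runs[0].modality,
        provenance={"cluster_sizes": [int(sizes[i]) for i in order], "n_runs": n_runs},
    )


def consensus_ica(
    data: np.ndarray,
    n_runs: int = 20,
    n_max: int | str | None = None,
    mode: str = "deflation",
    seed: int = 0,
    similarity_threshold: float = 0.8,
    min_occurrence: float = 0.5,
    modality: str = "",
    tol: float = 1e-4,
    max_iter: int = 1000,
    fun: str = "skew",
    n_attempts: int = 1,
) -> ComponentSet:
    """Run spatial ICA ``n_runs`` times with random initialisation (sharing
    one whitening) and return the consensus components."""
    data = np.asarray(data, dtype=float)
    if n_max is None:
        n_max = min(data.shape)
    Z = whiten(data, n_max=n_max)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(n_runs)
    runs = []
    for ss in seeds:
        try:
            runs.append(
                spatial_ica(
                    data, n_max=n_max, mode=mode, seed=ss, tol=tol,
                    max_iter=max_iter, modality=modality, fun=fun,
                    n_attempts=n_attempts, _whitened=Z,
                )
            )
        except DecompositionError:
            continue
    if len(runs) < 2:
        raise DecompositionError("fewer than 2 ICA runs produced components")
    return consensus_components(
        runs, similarity_threshold=similarity_threshold,
        min_occurrence=min_occurrence, data=data,
    )


def screen_components(components: ComponentSet, exclude: list[int]) -> ComponentSet:
    """Drop the listed component indices (user judgement of artifacts)."""
    n = components.n_components
    for i in exclude:
        if not (0 <= i < n):
            raise IndexError(f"component index {i} out of range (n={n})")
    keep = [i for i in range(n) if i not in set(exclude)]
    prov = dict(components.provenance)
    prov["excluded"] = sorted(set(exclude))
    return ComponentSet(
        spatial_maps=components.spatial_maps[keep],
        time_courses=components.time_courses[keep],
        modality=components.modality,
        provenance=prov,
    )


def activation_zmap(spatial_map: np.ndarray, z_threshold: float = 3.0) -> np.ndarray:
    """z-score a spatial map; entries with |z| below threshold are zeroed.

    The |z| > 3 convention marks "activated" voxels for reporting.
    """
    z = (spatial_map - spatial_map.mean()) / spatial_map.std()
    return np.where(np.abs(z) >= z_threshold, z, 0.0)
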