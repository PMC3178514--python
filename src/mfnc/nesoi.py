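"""Network-based source imaging (NESOI): empirical-Bayes EEG inversion with
fMRI spatial-pattern priors.

Each EEG topography Y (one channel vector per network) is modelled as
``Y = X Phi + e`` with ``e ~ N(0, g0 I)`` and source activity
``Phi ~ N(0, sum_i g_i Q_i)``.  The covariance components Q_i are built
from z-scored fMRI spatial maps (diagonal on their supra-threshold
support), complemented by a library of multiple sparse priors (MSP):
rank-one smoothed patches tiling the dipoles no fMRI map claims.  The
nonnegative hyperparameters g are estimated by restricted maximum
likelihood (ReML, Fisher scoring on log-hyperparameters with a monotone
free-energy line search); automatic relevance determination prunes the
patches so each topography is explained sparsely.  Per EEG network the
patch contributions are aggregated into a single MSP figure, and the
trace-weighted relative contributions decide which fMRI network (if any)
supports it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .decompose import ComponentSet
from .headmodel import LeadField, SourceDisc

logger = logging.getLogger(__name__)

MSP_LABEL = "MSP"


@dataclass
class PriorComponent:
    """One source-covariance component.

    ``kind="diag"``: Q = diag(diag_values); ``kind="factor"``: Q = F F^T
    (rank = number of factor columns; MSP patches are rank one).
    ``coverage`` is the dipole support set.
    """

    label: str
    kind: str
    coverage: np.ndarray
    diag_values: np.ndarray | None = None
    factor: np.ndarray | None = None

    def sensor_cov(self, X: np.ndarray) -> np.ndarray:
        """X Q X^T (channels x channels)."""
        if self.kind == "diag":
            return (X * self.diag_values) @ X.T
        XF = X @ self.factor
        return XF @ XF.T

    def q_xt(self, X: np.ndarray) -> np.ndarray:
        """Q X^T (dipoles x channels)."""
        if self.kind == "diag":
            return self.diag_values[:, None] * X.T
        return self.factor @ (X @ self.factor).T

    def trace(self) -> float:
        if self.kind == "diag":
            return float(self.diag_values.sum())
        return float(np.sum(self.factor**2))


@dataclass
class ReMLResult:
    """Hyperparameters, free-energy trace and posterior mean of one inversion."""

    gamma: np.ndarray  # per prior component (original Q scale)
    gamma_sensor: float
    free_energy_trace: np.ndarray
    posterior_mean: np.ndarray
    converged: bool
    prior_labels: list[str] = field(default_factory=list)
    sensor_traces: np.ndarray | None = None  # tr(X Q_i X^T) per prior

    def normalized_contributions(self) -> np.ndarray:
        """rho_i = g_i tr(X Q_i X^T) / sum_j g_j tr(X Q_j X^T), per component."""
        w = self.gamma * self.sensor_traces
        s = w.sum()
        return w / s if s > 0 else np.full_like(w, 1.0 / len(w))

    def contributions_by_label(self) -> tuple[list[str], np.ndarray]:
        """Contributions with all MSP patches aggregated into one column."""
        rho = self.normalized_contributions()
        labels: list[str] = []
        vals: list[float] = []
        for lab, r in zip(self.prior_labels, rho):
            if lab in labels:
                vals[labels.index(lab)] += r
            else:
                labels.append(lab)
                vals.append(float(r))
        return labels, np.array(vals)


@dataclass
class MatchTable:
    """Per-EEG-network matching decisions and the three network categories."""

    contributions: np.ndarray  # (n_eeg, n_priors) with MSP aggregated
    prior_labels: list[str]
    match: list[str]  # per EEG component: fMRI label or MSP_LABEL
    common: list[tuple[int, int]]  # (eeg index, fmri index)
    eeg_specific: list[int]
    fmri_specific: list[int]


def build_prior_components(
    fmri_maps: ComponentSet,
    disc: SourceDisc,
    z_threshold: float = 3.0,
    smooth_sigma_cells: float = 3.5,
    patch_stride_cells: float = 4.0,
    msp_mode: str = "patches",
    fmri_prior_form: str = "pattern",
) -> list[PriorComponent]:
    """Covariance priors from fMRI spatial maps plus MSP patches.

    Per fMRI map: z-score across voxels, zero sub-threshold entries.  The
    default prior form is the coherent-pattern covariance ``Q = m m^T``
    (m the thresholded z-map): an ICA network is one spatial pattern with
    one time course, and the rank-one form also puts the network priors on
    the same complexity footing as the MSP patches.
    ``fmri_prior_form="diag"`` uses ``Q = diag(z^2)`` instead.

    Dipoles covered by no fMRI prior are tiled by rank-one
    Gaussian-smoothed patch priors (grid of centres with spacing
    ``patch_stride_cells``), all labelled "MSP".  ``msp_mode="aggregate"``
    sums the patches into a single component instead.
    """
    d = disc.n_dipoles
    if fmri_maps.spatial_maps.shape[1] != d:
        raise ValueError("fMRI voxel grid and dipole grid must be in registration")
    priors: list[PriorComponent] = []
    covered = np.zeros(d, dtype=bool)
    for idx, m in enumerate(fmri_maps.spatial_maps):
        sd = m.std()
        if sd == 0:
            logger.warning("fMRI map %d is constant; dropped", idx)
            continue
        z = (m - m.mean()) / sd
        z = np.where(np.abs(z) >= z_threshold, z, 0.0)
        support = np.nonzero(z)[0]
        if support.size == 0:
            logger.warning("fMRI map %d empty after |z| >= %g; dropped", idx, z_threshold)
            continue
        covered[support] = True
        if fmri_prior_form == "pattern":
            priors.append(
                PriorComponent(
                    label=f"fMRI-{idx}", kind="factor", coverage=support,
                    factor=z[:, None],
                )
            )
        else:
            priors.append(
                PriorComponent(
                    label=f"fMRI-{idx}", kind="diag", coverage=support,
                    diag_values=z**2,
                )
            )
    rest = np.nonzero(~covered)[0]
    if rest.size == 0:
        logger.warning("fMRI priors cover every dipole; MSP omitted")
    else:
        pos = disc.dipole_positions[:, :2]
        cell = disc.fov_mm / 100.0 / disc.grid_size
        sigma = smooth_sigma_cells * cell
        tree = cKDTree(pos)
        # patch centres: greedy grid cover of the complement with the given
        # stride (deterministic: ascending dipole order)
        stride = patch_stride_cells * cell
        centres: list[int] = []
        taken = np.zeros(d, dtype=bool)
        for j in rest:
            if taken[j]:
                continue
            centres.append(j)
            for nb in tree.query_ball_point(pos[j], r=stride):
                taken[nb] = True
        cols = []
        for j in centres:
            nbrs = tree.query_ball_point(pos[j], r=3.0 * sigma)
            g = np.zeros(d)
            g[nbrs] = np.exp(-np.sum((pos[nbrs] - pos[j]) ** 2, axis=1) / (2 * sigma**2))
            cols.append(g)
        if msp_mode == "aggregate":
            priors.append(
                PriorComponent(
                    label=MSP_LABEL, kind="factor", coverage=rest,
                    factor=np.column_stack(cols),
                )
            )
        else:
            for g in cols:
                priors.append(
                    PriorComponent(
                        label=MSP_LABEL, kind="factor",
                        coverage=np.nonzero(g)[0], factor=g[:, None],
                    )
                )
    if not priors:
        raise ValueError("no usable prior component")
    return priors


def _free_energy(chol: np.ndarray, CiY: np.ndarray, Y: np.ndarray) -> float:
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return -0.5 * (logdet + float(Y @ CiY))


def reml_invert(
    Y: np.ndarray,
    leadfield: LeadField,
    priors: list[PriorComponent],
    tol: float = 1e-6,
    max_iter: int = 256,
) -> ReMLResult:
    """ReML hyperparameter estimation and posterior source mean.

    Fisher scoring on log-hyperparameters (so g >= 0 automatically) with
    step backtracking: the free energy is non-decreasing along the trace.
    Rank-one patch priors are handled in closed form, so a few hundred
    sparse priors cost little.
    """
    X = leadfield.gain
    Y = np.asarray(Y, dtype=float).ravel()
    if Y.shape[0] != X.shape[0]:
        raise ValueError("topography dimension does not match leadfield rows")
    if not priors:
        raise ValueError("at least one prior component is required")
    n_c = X.shape[0]
    traces_raw = np.array([p.trace() for p in priors])
    scale = float(Y @ Y) / n_c
    sensor_traces = np.array([float(np.trace(p.sensor_cov(X))) for p in priors])
    if np.any(sensor_traces <= 0):
        raise ValueError("prior with non-positive sensor-space trace")
    if scale == 0:
        return ReMLResult(
            gamma=np.zeros(len(priors)), gamma_sensor=0.0,
            free_energy_trace=np.zeros(1), posterior_mean=np.zeros(X.shape[1]),
            converged=True, prior_labels=[p.label for p in priors],
            sensor_traces=sensor_traces,
        )
    Ys = Y / np.sqrt(scale)

    # unit-sensor-trace components: dense for the (few) fMRI priors, sensor
    # vectors for the rank-one patches
    dense_idx = [i for i, p in enumerate(priors) if p.kind == "diag" or p.factor.shape[1] > 1]
    r1_idx = [i for i in range(len(priors)) if i not in dense_idx]
    dense_P = [priors[i].sensor_cov(X) / sensor_traces[i] for i in dense_idx]
    U = (
        np.column_stack([(X @ priors[i].factor[:, 0]) / np.sqrt(sensor_traces[i]) for i in r1_idx])
        if r1_idx
        else np.zeros((n_c, 0))
    )
    n_d, n_r = len(dense_idx), len(r1_idx)
    n_h = 1 + n_d + n_r  # sensor noise + components

    # data-aligned initialisation: start each component proportional to how
    # much of the (whitened) topography energy it explains; a uniform start
    # often lands the many-component ARD problem in a poor local optimum
    align = np.empty(n_h)
    align[0] = 1.0
    for a, P in enumerate(dense_P):
        align[1 + a] = max(float(Ys @ (P @ Ys)), 1e-6)
    if n_r:
        align[1 + n_d :] = np.maximum((Ys @ U) ** 2, 1e-6)
    lam = np.log(align / align.sum())
    lam_floor = -32.0
    lam = np.maximum(lam, lam_floor)

    def build_C(lam):
        C = np.exp(lam[0]) * np.eye(n_c)
        for a, P in enumerate(dense_P):
            C += np.exp(lam[1 + a]) * P
        if n_r:
            C += (U * np.exp(lam[1 + n_d :])) @ U.T
        return C

    def chol_F(C):
        L = np.linalg.cholesky(C)
        CiY = np.linalg.solve(C, Ys)
        return L, CiY, _free_energy(L, CiY, Ys)

    C = build_C(lam)
    L, CiY, F = chol_F(C)
    F_trace = [F]
    converged = False
    for _ in range(max_iter):
        Ci = np.linalg.inv(C)
        gam = np.exp(lam)
        # gradient dF/dlam_i = -0.5 g_i [tr(Ci P_i) - Y' Ci P_i Ci Y]
        g = np.empty(n_h)
        CiU = Ci @ U if n_r else np.zeros((n_c, 0))
        uCiY = U.T @ CiY if n_r else np.zeros(0)
        g[0] = -0.5 * gam[0] * (np.trace(Ci) - float(CiY @ CiY))
        CiP = [Ci @ P for P in dense_P]
        for a, P in enumerate(dense_P):
            g[1 + a] = -0.5 * gam[1 + a] * (
                float(np.trace(CiP[a])) - float(CiY @ (P @ CiY))
            )
        if n_r:
            g[1 + n_d :] = -0.5 * gam[1 + n_d :] * (
                np.einsum("ij,ij->j", U, CiU) - uCiY**2
            )
        # Fisher information on lam: H_ab = 0.5 g_a g_b tr(Ci P_a Ci P_b)
        H = np.empty((n_h, n_h))
        mats = [Ci] + CiP  # Ci P for P = I and dense components
        for a in range(1 + n_d):
            for b in range(a, 1 + n_d):
                H[a, b] = H[b, a] = 0.5 * gam[a] * gam[b] * float(
                    np.sum(mats[a] * mats[b].T)
                )
        if n_r:
            for a in range(1 + n_d):
                # tr(Ci P_a Ci u u^T) = u^T Ci P_a Ci u
                Pa_CiU = CiU if a == 0 else dense_P[a - 1] @ CiU
                blk = Ci @ Pa_CiU
                H[a, 1 + n_d :] = H[1 + n_d :, a] = (
                    0.5 * gam[a] * gam[1 + n_d :] * np.einsum("ij,ij->j", U, blk)
                )
            M = U.T @ CiU
            H[1 + n_d :, 1 + n_d :] = 0.5 * np.outer(gam[1 + n_d :], gam[1 + n_d :]) * M * M
        # Levenberg-Marquardt damped Fisher step: with many mutually
        # correlated patch priors the information matrix is near-singular,
        # and an undamped step stalls far from the optimum
        diagH = np.clip(np.diag(H), 1e-10, None)
        improved = False
        lm = 1e-6
        for _bt in range(12):
            try:
                step = np.linalg.solve(H + lm * np.diag(diagH) + 1e-12 * np.eye(n_h), g)
            except np.linalg.LinAlgError:
                lm *= 10.0
                continue
            step = np.clip(step, -8.0, 8.0)
            lam_new = np.maximum(lam + step, lam_floor)
            C_new = build_C(lam_new)
            try:
                L_new, CiY_new, F_new = chol_F(C_new)
            except np.linalg.LinAlgError:
                lm *= 10.0
                continue
            if np.isfinite(F_new) and F_new >= F - 1e-12:
                improved = True
                break
            lm *= 10.0
        if not improved:
            converged = True
            break
        dF = F_new - F
        lam, C, L, CiY, F = lam_new, C_new, L_new, CiY_new, F_new
        F_trace.append(F)
        if not np.isfinite(F):
            raise FloatingPointError(
                f"non-finite free energy at iteration {len(F_trace)}"
            )
        if dF < tol * max(abs(F), 1.0):
            converged = True
            break
    gam = np.exp(lam)
    # undo internal normalisations (data scale, unit sensor trace)
    gamma = np.empty(len(priors))
    for a, i in enumerate(dense_idx):
        gamma[i] = gam[1 + a] * scale / sensor_traces[i]
    for a, i in enumerate(r1_idx):
        gamma[i] = gam[1 + n_d + a] * scale / sensor_traces[i]
    gamma_sensor = gam[0] * scale
    C_full = C * scale
    CiY_full = np.linalg.solve(C_full, Y)
    XtCiY = X.T @ CiY_full
    phi = np.zeros(X.shape[1])
    for g_i, p in zip(gamma, priors):
        if g_i > 0:
            if p.kind == "diag":
                phi += g_i * p.diag_values * XtCiY
            else:
                phi += g_i * (p.factor @ (p.factor.T @ XtCiY))
    return ReMLResult(
        gamma=gamma,
        gamma_sensor=float(gamma_sensor),
        free_energy_trace=np.array(F_trace),
        posterior_mean=phi,
        converged=converged,
        prior_labels=[p.label for p in priors],
        sensor_traces=sensor_traces,
    )


def match_networks(results: list[ReMLResult], priors: list[PriorComponent]) -> MatchTable:
    """Assign each EEG network to the label with the largest aggregated
    trace-weighted contribution; an MSP win (or exact tie) marks it
    EEG-specific.  fMRI components matched by no EEG network are
    fMRI-specific."""
    if not results:
        raise ValueError("no inversion results to match")
    labels0, _ = results[0].contributions_by_label()
    contrib = np.vstack([r.contributions_by_label()[1] for r in results])
    match: list[str] = []
    matched_fmri: set[int] = set()
    for r in results:
        # per-component argmax: each MSP patch competes individually, so a
        # network prior must only beat the best single generic patch (the
        # aggregated MSP column is for reporting)
        rho = r.normalized_contributions()
        is_msp = np.array([lab == MSP_LABEL for lab in r.prior_labels])
        best_msp = float(rho[is_msp].max()) if is_msp.any() else 0.0
        best_fmri_val = float(rho[~is_msp].max()) if (~is_msp).any() else -1.0
        # exact ties break conservatively toward MSP
        if best_msp >= best_fmri_val - 1e-12:
            match.append(MSP_LABEL)
        else:
            match.append(r.prior_labels[int(np.argmax(np.where(is_msp, -1.0, rho)))])
    common, eeg_specific = [], []
    for e, lab in enumerate(match):
        if lab == MSP_LABEL:
            eeg_specific.append(e)
        else:
            f = int(lab.split("-")[1])
            common.append((e, f))
            matched_fmri.add(f)
    fmri_all = {int(l.split("-")[1]) for l in labels0 if l != MSP_LABEL}
    fmri_specific = sorted(fmri_all - matched_fmri)
    return MatchTable(
        contributions=contrib,
        prior_labels=labels0,
        match=match,
        common=common,
        eeg_specific=eeg_specific,
        fmri_specific=fmri_specific,
    )


def source_map(result: ReMLResult, quantile: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Top-``quantile`` fraction of dipoles by posterior magnitude.

    Returns ``(values, support)`` where ``support`` holds the retained
    dipole indices (ceil(quantile * d), ties resolved by index order).
    """
    phi = result.posterior_mean
    d = phi.shape[0]
    n_keep = min(d, max(1, int(np.ceil(quantile * d))))
    order = np.lexsort((np.arange(d), -np.abs(phi)))
    support = np.sort(order[:n_keep])
    values = np.zeros(d)
    values[support] = phi[support]
    return values, support
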