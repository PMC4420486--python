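"""Nonlinear electrostatic field solver on the labeled voxel grid.

Solves div( sigma(|grad phi|) grad phi ) = 0 for each electrode-pair
drive of a pulse sequence and accumulates the per-voxel field envelope
(the maximum field magnitude each voxel experiences).

Discretization
--------------
Cell-centered finite volumes on the structured voxel grid with a 7-point
stencil; face conductivities are harmonic means of the adjacent voxel
conductivities, which reproduces the exact series-resistance behavior
across tissue interfaces.  The driven electrode pair is a Dirichlet
condition at +V/2 and -V/2 on the two active-tip voxel sets; all other
electrodes are floating perfect conductors, modeled by collapsing each
passive tip's voxels into a single equipotential unknown (this conserves
their net current exactly and keeps the system well conditioned).
Insulated shafts are zero-conductivity voxels excluded from the system;
the outer boundary is no-flux.

Electroporation makes the problem nonlinear: each voxel's conductivity
follows sigma(E) of its tissue, evaluated at the *largest* field the
voxel has seen so far in the pulse train (membrane permeabilization does
not reseal between pulses), so the conductivity state grows monotonically
over the sequence.  Each drive is solved self-consistently by damped
Picard iteration.

Linear systems are symmetric positive definite; small ones are solved by
sparse LU, large ones by conjugate gradients preconditioned with an
in-package smoothed-aggregation multigrid V-cycle (the solve path is
fully deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .scenes import (
    ELECTRODE_ACTIVE_BASE,
    ConfigError,
    LabelScene,
)
from .tissues import ConductivityModel, TissueProperties, builtin_tissue_table

__all__ = [
    "Drive",
    "PulsePlan",
    "FieldEnvelope",
    "SolverError",
    "SolverSettings",
    "make_pulse_plan",
    "solve_drive",
    "solve_sequence",
]

_SIGMA_METAL = 1.0e6  # S/m, effectively a perfect conductor in harmonic means


class SolverError(RuntimeError):
    """Iteration failed to converge; carries the residual history."""

    def __init__(self, message: str, history: list[float] | None = None):
        super().__init__(message)
        self.history = history or []


@dataclass(frozen=True)
class Drive:
    """One electrode-pair pulse: ``voltage`` volts between anode and cathode."""

    anode: int
    cathode: int
    voltage: float

    def __post_init__(self) -> None:
        if self.anode == self.cathode:
            raise ValueError("anode and cathode must differ")
        if self.voltage < 0:
            raise ValueError("drive voltage must be non-negative")


@dataclass(frozen=True)
class PulsePlan:
    """Ordered electrode-pair drives for one treatment."""

    drives: tuple[Drive, ...]

    def __iter__(self):
        return iter(self.drives)

    def __len__(self):
        return len(self.drives)


@dataclass
class SolverSettings:
    """Numerical knobs for the nonlinear solve.

    Picard iteration is damped with ``relaxation`` and stops when the
    largest relative conductivity change drops below ``tolerance``.
    Linear systems below ``direct_threshold`` unknowns use a sparse LU
    factorization; mid-size ones Jacobi-preconditioned conjugate
    gradients; only systems above ``multigrid_threshold`` pay for the
    multigrid setup.  All solves use relative tolerance ``cg_rtol``.
    """

    relaxation: float = 0.5
    tolerance: float = 1.0e-3
    max_iterations: int = 50
    cg_rtol: float = 3.0e-7
    cg_maxiter: int = 4000
    direct_threshold: int = 1_000
    multigrid_threshold: int = 50_000


def make_pulse_plan(n_electrodes: int, U_outer: float, U_diag: float) -> PulsePlan:
    """Pulse plan for a standard layout from the two optimized voltages.

    Neighboring electrodes around the ring are driven at ``U_outer``;
    "diagonal" drives at ``U_diag`` connect the center electrode to every
    ring electrode, or — for the centerless 4-electrode box — the two
    non-neighbor pairs.  Ring (outer) drives come first, then diagonals.
    """
    if U_outer < 0 or U_diag < 0:
        raise ValueError("voltages must be non-negative")
    if n_electrodes == 4:
        ring = [(0, 1), (1, 2), (2, 3), (3, 0)]
        diag = [(0, 2), (1, 3)]
    elif n_electrodes == 5:
        ring = [(0, 1), (1, 2), (2, 3), (3, 0)]
        diag = [(4, k) for k in range(4)]
    elif n_electrodes == 7:
        ring = [(k, (k + 1) % 6) for k in range(6)]
        diag = [(6, k) for k in range(6)]
    else:
        raise ConfigError(f"no pulse plan for {n_electrodes} electrodes")
    drives = [Drive(a, c, U_outer) for a, c in ring]
    drives += [Drive(a, c, U_diag) for a, c in diag]
    return PulsePlan(tuple(drives))


@dataclass
class FieldEnvelope:
    """Field envelope and conductivity state after a pulse sequence.

    ``E_max`` is the per-voxel maximum field magnitude over all drives in
    V/cm; ``sigma`` the final per-voxel conductivity in S/m; ``currents``
    the per-drive total current in A.
    """

    E_max: np.ndarray
    sigma: np.ndarray
    currents: list[float] = field(default_factory=list)
    drive_info: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# scene context: per-voxel tissue parameters and electrode voxel sets


class _SceneContext:
    def __init__(
        self,
        scene: LabelScene,
        tissues: dict[str, TissueProperties] | None = None,
        model: ConductivityModel | None = None,
    ):
        self.scene = scene
        self.model = model or ConductivityModel()
        tissues = tissues or builtin_tissue_table()

        labels = scene.labels
        shape = labels.shape
        self.E0 = np.zeros(shape)
        self.E1 = np.ones(shape)
        self.s0 = np.zeros(shape)
        self.s1 = np.zeros(shape)
        self.tissue_mask = np.zeros(shape, dtype=bool)
        for code, role in scene.role_map.items():
            if role in tissues:
                m = labels == code
                t = tissues[role]
                self.E0[m], self.E1[m] = t.E0, t.E1
                self.s0[m], self.s1[m] = t.sigma0, t.sigma1
                self.tissue_mask |= m

        self.metal_masks: dict[int, np.ndarray] = {}
        for code, role in scene.role_map.items():
            if role == "electrode_active":
                idx = code - ELECTRODE_ACTIVE_BASE
                m = labels == code
                if m.any():
                    self.metal_masks[idx] = m
        if not self.metal_masks:
            raise ValueError("scene has no rasterized electrodes")
        self.metal_any = np.zeros(shape, dtype=bool)
        for m in self.metal_masks.values():
            self.metal_any |= m
        self.participates = self.tissue_mask | self.metal_any
        self._build_faces()

    def _electrode_surface_distance(self, k: int, x, y, z, h: float):
        """Distance from points to the surface of electrode k's active tip.

        Used for the embedded-boundary subcell correction: the staircase
        voxelization of a thin cylindrical electrode is corrected by
        evaluating the true tissue gap between a neighboring voxel center
        and the analytic capped-cylinder surface, clamped to
        [0.2 h, 1.0 h] so conductances stay bounded.
        """
        e = self.scene.electrodes[k]
        rho = np.hypot(x - e.x, y - e.y)
        dr = rho - e.diameter / 2.0
        dz = np.maximum(np.maximum(e.tip_bottom_z - z, z - e.tip_top_z), 0.0)
        d = np.where(dz > 0, np.hypot(np.maximum(dr, 0.0), dz), dr)
        return np.clip(d, 0.2 * h, 1.0 * h)

    def _build_faces(self) -> None:
        """Face topology shared by every drive on this scene.

        ``vox_a/vox_b`` are flat voxel indices of each interior face
        (both sides conducting), ``geo`` the A/h metric factor, ``gcorr``
        a per-face multiplier on the harmonic conductance and ``escale``
        per-axis grids scaling face potential differences into tissue
        fields (1 in the bulk; at electrode surfaces the entire drop
        happens in the tissue gap d, giving h/d).
        """
        scene = self.scene
        shape = scene.labels.shape
        spacing = scene.spacing
        part = self.participates
        metal = self.metal_any
        has_specs = bool(scene.electrodes)
        # electrode ownership per metal voxel (-1 where no spec available)
        owner = np.full(shape, -1, dtype=np.int32)
        if has_specs:
            for k in self.metal_masks:
                if k < len(scene.electrodes):
                    owner[self.metal_masks[k]] = k

        flat_idx = np.arange(int(np.prod(shape)), dtype=np.int64).reshape(shape)
        xs = scene.axis_coords(0)[:, None, None]
        ys = scene.axis_coords(1)[None, :, None]
        zs = scene.axis_coords(2)[None, None, :]
        X = np.broadcast_to(xs, shape)
        Y = np.broadcast_to(ys, shape)
        Z = np.broadcast_to(zs, shape)

        vox_a, vox_b, geo, gcorr = [], [], [], []
        self.escale = []
        for axis in range(3):
            h = spacing[axis]
            area = np.prod([spacing[a] for a in range(3) if a != axis])
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = slice(None, -1)
            sl_b[axis] = slice(1, None)
            ta, tb = tuple(sl_a), tuple(sl_b)

            scale = np.ones([s - 1 if a == axis else s for a, s in enumerate(shape)])
            m_a, m_b = metal[ta], metal[tb]
            mixed = m_a ^ m_b
            scale[mixed] = 2.0  # default: drop over the tissue half-cell
            scale[m_a & m_b] = 0.0
            corr = np.ones_like(scale)
            if has_specs:
                own_face = np.where(m_a, owner[ta], owner[tb])
                tx = np.where(m_a, X[tb], X[ta])
                ty = np.where(m_a, Y[tb], Y[ta])
                tz = np.where(m_a, Z[tb], Z[ta])
                for k in self.metal_masks:
                    if k >= len(scene.electrodes):
                        continue
                    sel = mixed & (own_face == k)
                    if not sel.any():
                        continue
                    d = self._electrode_surface_distance(
                        k, tx[sel], ty[sel], tz[sel], h
                    )
                    scale[sel] = h / d
                    corr[sel] = (h / 2.0) / d
            self.escale.append(scale)

            keep = (part[ta] & part[tb]).ravel()
            vox_a.append(flat_idx[ta].ravel()[keep])
            vox_b.append(flat_idx[tb].ravel()[keep])
            geo.append(np.full(vox_a[-1].size, area / h * 1.0e-3))
            gcorr.append(corr.ravel()[keep])
        self.vox_a = np.concatenate(vox_a)
        self.vox_b = np.concatenate(vox_b)
        self.geo = np.concatenate(geo)
        self.gcorr = np.concatenate(gcorr)
        self.metal_flat = np.flatnonzero(metal.ravel())

    def conductances(self, sig: np.ndarray) -> np.ndarray:
        """Harmonic-mean face conductances (S), subcell-corrected at metal."""
        sf = sig.ravel().copy()
        sf[self.metal_flat] = _SIGMA_METAL
        sa = sf[self.vox_a]
        sb = sf[self.vox_b]
        return self.geo * self.gcorr * 2.0 * sa * sb / (sa + sb)

    def sigma_of(self, E: np.ndarray) -> np.ndarray:
        """Tissue conductivity at field magnitude E (V/cm), per voxel."""
        t = np.zeros_like(E)
        span = self.E1 - self.E0
        np.divide(E - self.E0, span, out=t, where=span > 0)
        ramp = self.model.ramp(t)
        sig = self.s0 + (self.s1 - self.s0) * ramp
        sig[~self.tissue_mask] = 0.0
        return sig


# ---------------------------------------------------------------------------
# smoothed-aggregation multigrid preconditioner


class _MultigridPreconditioner:
    """Geometric smoothed-aggregation V-cycle for the FV Laplacian.

    Voxel unknowns aggregate into 2x2x2 blocks of their grid coordinates;
    floating-electrode unknowns stay singleton aggregates.  Tentative
    prolongators are smoothed with one damped-Jacobi step and coarse
    operators formed by Galerkin products.  Symmetric V(1,1) cycles with
    damped Jacobi smoothing keep the operator SPD for use inside CG.
    """

    omega = 2.0 / 3.0
    coarsest = 1500

    def __init__(self, A: sparse.csr_matrix, coords: np.ndarray):
        self.levels: list[dict] = []
        keys = coords.astype(np.int64)
        while A.shape[0] > self.coarsest and len(self.levels) < 12:
            d = A.diagonal()
            inv_d = np.where(d > 0, 1.0 / np.maximum(d, 1e-300), 0.0)
            keys2 = keys.copy()
            vox = keys2[:, 0] >= 0
            keys2[vox] //= 2
            flat = (
                keys2[:, 0] * (keys2[:, 1].max() + 2) + keys2[:, 1]
            ) * (keys2[:, 2].max() + 2) + keys2[:, 2]
            flat[~vox] = -np.arange(1, (~vox).sum() + 1) - flat.max() * 0 - 10**15
            _, agg = np.unique(flat, return_inverse=True)
            nc = int(agg.max()) + 1
            counts = np.bincount(agg, minlength=nc).astype(float)
            P = sparse.csr_matrix(
                (1.0 / np.sqrt(counts[agg]), (np.arange(A.shape[0]), agg)),
                shape=(A.shape[0], nc),
            )
            AP = A @ P
            P = P - sparse.diags(self.omega * inv_d) @ AP
            Ac = (P.T @ (A @ P)).tocsr()
            self.levels.append(dict(A=A, inv_d=inv_d, P=P.tocsr()))
            # coarse coords: representative per aggregate
            rep = np.zeros(nc, dtype=np.int64)
            rep[agg] = np.arange(A.shape[0])
            keys = keys2[rep]
            keys[np.bincount(agg, weights=vox.astype(float), minlength=nc) == 0] = -1
            A = Ac
        self.coarse_solve = spla.splu(A.tocsc()).solve
        self.n_levels = len(self.levels)

    def _cycle(self, lvl: int, b: np.ndarray) -> np.ndarray:
        if lvl == self.n_levels:
            return self.coarse_solve(b)
        L = self.levels[lvl]
        A, inv_d, P = L["A"], L["inv_d"], L["P"]
        x = self.omega * inv_d * b
        r = b - A @ x
        x = x + P @ self._cycle(lvl + 1, P.T @ r)
        x = x + self.omega * inv_d * (b - A @ x)
        return x

    def __call__(self, b: np.ndarray) -> np.ndarray:
        return self._cycle(0, b)


# ---------------------------------------------------------------------------
# per-drive linear system with precomputed sparsity pattern


class _DriveSystem:
    """Precomputed face topology of one drive's linear system.

    Between Picard iterations only the conductivities change; the unknown
    numbering, face index arrays and Dirichlet pattern stay fixed, so
    assembly reduces to recomputing face conductances and re-binning them.
    """

    def __init__(self, ctx: _SceneContext, anode: int, cathode: int, voltage: float):
        scene = ctx.scene
        shape = scene.labels.shape
        spacing = scene.spacing
        self.ctx = ctx

        uid = np.full(shape, -1, dtype=np.int64)
        tissue = ctx.tissue_mask
        n = int(tissue.sum())
        uid[tissue] = np.arange(n)
        coords_list = [np.argwhere(tissue)]
        for k, m in ctx.metal_masks.items():
            if k in (anode, cathode):
                uid[m] = -2
            else:
                uid[m] = n
                coords_list.append(np.array([[-1, -1, -1]]))
                n += 1
        self.uid = uid
        self.n = n
        self.coords = np.vstack(coords_list)

        phi_fixed = np.zeros(shape)
        phi_fixed[ctx.metal_masks[anode]] = +voltage / 2.0
        phi_fixed[ctx.metal_masks[cathode]] = -voltage / 2.0
        self.phi_fixed = phi_fixed
        self.anode_mask = ctx.metal_masks[anode]
        self.cathode_mask = ctx.metal_masks[cathode]
        self.vox_a = ctx.vox_a
        self.vox_b = ctx.vox_b

        ua = uid.ravel()[self.vox_a]
        ub = uid.ravel()[self.vox_b]
        interior = (ua >= 0) & (ub >= 0) & (ua != ub)
        dir_a = (ua == -2) & (ub >= 0)
        dir_b = (ub == -2) & (ua >= 0)
        self.sel_int = np.flatnonzero(interior)
        self.ia = ua[interior]
        self.ib = ub[interior]
        self.sel_dir = np.concatenate([np.flatnonzero(dir_a), np.flatnonzero(dir_b)])
        self.iu_dir = np.concatenate([ub[dir_a], ua[dir_b]])
        pf = phi_fixed.ravel()
        self.val_dir = np.concatenate(
            [pf[self.vox_a[dir_a]], pf[self.vox_b[dir_b]]]
        )

        # Precompute the CSR pattern: entry order -> canonical sorted
        # positions, so each Picard iteration only refills the data array.
        ar = np.arange(self.n)
        rows = np.concatenate([self.ia, self.ib, ar])
        cols = np.concatenate([self.ib, self.ia, ar])
        order = np.lexsort((cols, rows))
        r_s, c_s = rows[order], cols[order]
        newseg = np.empty(order.size, dtype=bool)
        newseg[0] = True
        newseg[1:] = (r_s[1:] != r_s[:-1]) | (c_s[1:] != c_s[:-1])
        self._order = order
        self._seg_starts = np.flatnonzero(newseg)
        self._indices = c_s[newseg].astype(np.int32)
        row_unique = r_s[newseg]
        counts = np.bincount(row_unique, minlength=self.n)
        self._indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int32)

    def assemble(self, sig: np.ndarray):
        g = self.ctx.conductances(sig)
        g_int = g[self.sel_int]
        g_dir = g[self.sel_dir]
        diag = (
            np.bincount(self.ia, g_int, self.n)
            + np.bincount(self.ib, g_int, self.n)
            + np.bincount(self.iu_dir, g_dir, self.n)
        )
        rhs = np.bincount(self.iu_dir, g_dir * self.val_dir, self.n)
        vals = np.concatenate([-g_int, -g_int, diag])[self._order]
        data = np.add.reduceat(vals, self._seg_starts)
        A = sparse.csr_matrix(
            (data, self._indices, self._indptr), shape=(self.n, self.n), copy=False
        )
        return A, rhs

    def scatter(self, x: np.ndarray) -> np.ndarray:
        """Full potential grid (V); NaN in excluded voxels."""
        shape = self.ctx.scene.labels.shape
        phi = np.full(shape, np.nan)
        sel = self.uid >= 0
        phi[sel] = x[self.uid[sel]]
        phi[self.uid == -2] = self.phi_fixed[self.uid == -2]
        return phi

    def electrode_current(self, sig: np.ndarray, phi_safe: np.ndarray, mask) -> float:
        """Net current (A) leaving the voxel set through its faces."""
        g = self.ctx.conductances(sig)
        mf = mask.ravel()
        pf = phi_safe.ravel()
        in_a = mf[self.vox_a]
        in_b = mf[self.vox_b]
        cross = in_a != in_b
        sgn = np.where(in_a[cross], 1.0, -1.0)
        return float(
            np.sum(sgn * g[cross] * (pf[self.vox_a[cross]] - pf[self.vox_b[cross]]))
        )


def _linear_solve(A, b, x0, settings: SolverSettings, mg=None):
    n = A.shape[0]
    if not np.any(b):
        return np.zeros(n)
    if n <= settings.direct_threshold:
        return spla.splu(A.tocsc()).solve(b)
    if mg is not None:
        M = spla.LinearOperator((n, n), matvec=mg)
    else:
        d = A.diagonal()
        inv_d = np.where(d > 0, 1.0 / np.maximum(d, 1e-300), 0.0)
        M = spla.LinearOperator((n, n), matvec=lambda v: inv_d * v)
    x, info = spla.cg(
        A, b, x0=x0, M=M, rtol=settings.cg_rtol, atol=0.0, maxiter=settings.cg_maxiter
    )
    if info > 0:
        raise SolverError(f"CG failed to converge within {settings.cg_maxiter} iterations")
    return x


def _field_magnitude(ctx: _SceneContext, phi_safe: np.ndarray) -> np.ndarray:
    """|grad phi| at voxel centers in V/cm from valid face differences.

    Face potential differences are scaled by the per-face ``escale``
    factors (one-sided across electrode surfaces, where the entire drop
    happens in the tissue gap) and averaged onto voxel centers per axis.
    """
    spacing = ctx.scene.spacing
    shape = phi_safe.shape
    part = ctx.participates
    metal = ctx.metal_any
    E2 = np.zeros(shape)
    for axis in range(3):
        h = spacing[axis]
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        ta, tb = tuple(sl_a), tuple(sl_b)
        valid = part[ta] & part[tb]
        dphi = np.abs(phi_safe[tb] - phi_safe[ta]) / h * ctx.escale[axis]
        dphi[~valid] = 0.0

        num = np.zeros(shape)
        cnt = np.zeros(shape)
        v = valid.astype(float)
        num[ta] += dphi
        cnt[ta] += v
        num[tb] += dphi
        cnt[tb] += v
        comp = np.divide(num, cnt, out=np.zeros(shape), where=cnt > 0)
        E2 += comp**2
    E = np.sqrt(E2) * 10.0  # V/mm -> V/cm
    E[metal] = 0.0
    E[~part] = 0.0
    return E


def solve_drive(
    scene: LabelScene,
    drive: Drive,
    *,
    E_state: np.ndarray | None = None,
    tissues: dict[str, TissueProperties] | None = None,
    model: ConductivityModel | None = None,
    settings: SolverSettings | None = None,
    _ctx: "_SceneContext | None" = None,
) -> tuple[np.ndarray, np.ndarray, float, dict]:
    """Solve one electrode-pair drive self-consistently in sigma(E).

    Parameters
    ----------
    scene
        Rasterized scene (must contain the drive's electrodes).
    drive
        Anode/cathode indices and voltage; potentials are set to +V/2 and
        -V/2 (only the difference matters under no-flux outer boundaries).
    E_state
        Per-voxel maximum field (V/cm) already experienced earlier in the
        pulse train; conductivities never fall below sigma(E_state).

    Returns
    -------
    (phi, E, current, info)
        Potential grid (V, NaN in excluded voxels), field magnitude grid
        (V/cm), delivered current (A), and an info dict with the Picard
        history and the current-conservation residual.
    """
    settings = settings or SolverSettings()
    ctx = _ctx or _SceneContext(scene, tissues, model)
    if drive.anode not in ctx.metal_masks or drive.cathode not in ctx.metal_masks:
        raise ValueError(f"drive electrodes {drive.anode}/{drive.cathode} not in scene")

    shape = scene.labels.shape
    E_hist = np.zeros(shape) if E_state is None else E_state
    sys_ = _DriveSystem(ctx, drive.anode, drive.cathode, drive.voltage)

    sig_floor = ctx.sigma_of(E_hist)
    sig = sig_floor.copy()
    x = None
    mg = None
    history: list[float] = []
    for _ in range(settings.max_iterations):
        A, b = sys_.assemble(sig)
        if mg is None and A.shape[0] > settings.multigrid_threshold and np.any(b):
            mg = _MultigridPreconditioner(A, sys_.coords)
        x = _linear_solve(A, b, x, settings, mg)
        phi = sys_.scatter(x)
        phi_safe = np.where(np.isnan(phi), 0.0, phi)
        E = _field_magnitude(ctx, phi_safe)
        target = np.maximum(ctx.sigma_of(np.maximum(E_hist, E)), sig_floor)
        new = sig + settings.relaxation * (target - sig)
        denom = np.where(sig > 0, sig, 1.0)
        change = float(np.max(np.abs(new - sig) / denom))
        history.append(change)
        sig = new
        if change < settings.tolerance:
            break
    else:
        raise SolverError(
            f"Picard iteration did not converge (last change {history[-1]:.3e})",
            history,
        )

    I_an = sys_.electrode_current(sig, phi_safe, ctx.metal_masks[drive.anode])
    I_ca = sys_.electrode_current(sig, phi_safe, ctx.metal_masks[drive.cathode])
    current = 0.5 * (abs(I_an) + abs(I_ca))
    cons = abs(I_an + I_ca) / max(current, 1e-30)
    info = dict(picard_history=history, conservation_residual=cons, sigma=sig)
    return phi, E, current, info


def solve_sequence(
    scene: LabelScene,
    plan: PulsePlan,
    *,
    tissues: dict[str, TissueProperties] | None = None,
    model: ConductivityModel | None = None,
    settings: SolverSettings | None = None,
    carry_conductivity: bool = True,
) -> FieldEnvelope:
    """Solve all drives of a pulse plan and accumulate the field envelope.

    Drives run in plan order.  With ``carry_conductivity`` (default) each
    voxel's conductivity is evaluated at the maximum field it has
    experienced in any earlier drive — electroporation does not reseal
    within a pulse train — so the conductivity state grows monotonically.
    Setting it False resets the tissue state before every drive.
    """
    ctx = _SceneContext(scene, tissues, model)
    shape = scene.labels.shape
    E_hist = np.zeros(shape)
    env = FieldEnvelope(E_max=np.zeros(shape), sigma=ctx.sigma_of(E_hist))
    for drive in plan:
        state = E_hist if carry_conductivity else np.zeros(shape)
        _, E, current, info = solve_drive(
            scene,
            drive,
            E_state=state,
            settings=settings,
            _ctx=ctx,
        )
        E_hist = np.maximum(E_hist, E)
        env.currents.append(current)
        env.drive_info.append(
            dict(
                anode=drive.anode,
                cathode=drive.cathode,
                voltage=drive.voltage,
                current=current,
                conservation_residual=info["conservation_residual"],
                picard_iterations=len(info["picard_history"]),
            )
        )
    env.E_max = E_hist
    env.sigma = ctx.sigma_of(E_hist)
    return env
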