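"""Quasi-static volume-conductor model of hippocampal stimulation.

The intracranial potential obeys the quasi-static approximation
``div(sigma grad V) = 0`` with current injected at electrode contacts and an
insulating (zero normal current) outer boundary. The model compares a
wide-field (WF) montage — current driven between anterior and posterior
depth electrodes spanning each hippocampus — against sequential
narrow-field (SNF) stimulation, where eight small bipolar dipoles placed
along both hippocampi are driven one at a time so each solution is a
separate quasi-static field (temporal combination happens only at the
membrane, see `snfsim.neuron`).

Geometry is a parametric stand-in for a segmented rat brain: an ellipsoidal
brain (24 x 16 x 12 mm) containing two curved-slab hippocampi that follow
the stereotaxic electrode coordinates (bregma origin; AP anterior+, ML
right+, DV down-). Conductivities (S/m): brain 0.0626, hippocampus 0.0988,
electrode insulation 6.62e-7, air 0. Contacts are single source voxels;
the 1.45e6 S/m stainless-steel value is kept for reference but metal is
treated as the current source rather than a conductor voxel.

The solver is conjugate-gradient on the 7-point finite-difference stencil
with harmonic-mean face conductances. Potentials are reported in mV and
field magnitudes in mV/mm for an injected current in microamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

# --- conductivities, S/m -----------------------------------------------------
SIGMA_BRAIN = 0.0626
SIGMA_HIPPOCAMPUS = 0.0988
SIGMA_INSULATION = 6.62e-7
SIGMA_STEEL = 1.45e6          # reference only; contacts are source voxels
SIGMA_AIR = 0.0
SIGMA_HOMOGENEOUS = 0.7       # homogeneous tissue used in robustness runs

# --- field thresholds, mV/mm -------------------------------------------------
THRESH_NETWORK_MOD = 10.0     # affects network rhythms
THRESH_SUPPRESSION = 50.0     # suppresses seizures (pulsed stimulation)
THRESH_TARGET = 100.0         # required inside the target tissue

SNF_ORDER = ("L1", "L2", "L3", "L4", "R4", "R3", "R2", "R1")

#: Vertical spacing between contact tips on one shaft, mm.
TIP_SPACING = 0.4


@dataclass
class GeometryConfig:
    """Parametric brain + hippocampus geometry in stereotaxic mm."""

    resolution: float = 0.25
    brain_semiaxes: tuple[float, float, float] = (12.0, 8.0, 6.0)  # AP, ML, DV
    brain_center: tuple[float, float, float] = (-3.0, 0.0, -5.0)
    # hippocampal curved slab: ML and DV centerlines are linear in AP depth
    hpc_ap_range: tuple[float, float] = (-5.8, -1.4)
    hpc_ml_at_front: float = 1.2      # |ML| of centerline at hpc AP front
    hpc_ml_slope: float = 1.22        # d|ML|/d(-AP)
    hpc_dv_at_front: float = -3.2
    hpc_dv_slope: float = -0.35       # dDV/d(-AP)
    hpc_half_ml: float = 1.5
    hpc_half_dv: float = 1.5
    homogeneous: bool = False         # single 0.7 S/m tissue (robustness runs)

    def __post_init__(self) -> None:
        if not 0.1 <= self.resolution <= 0.5:
            raise ValueError("resolution must lie in [0.1, 0.5] mm")

    def hpc_centerline(self, ap: np.ndarray, side: str):
        """(ML, DV) centerline of one hippocampus at AP positions."""
        depth = -(ap - self.hpc_ap_range[1])  # 0 at front, grows posterior
        ml = self.hpc_ml_at_front + self.hpc_ml_slope * depth
        dv = self.hpc_dv_at_front + self.hpc_dv_slope * depth
        return (ml if side == "R" else -ml), dv


@dataclass
class ConductivityGrid:
    """Voxel conductivity volume with region masks, axes (AP, ML, DV)."""

    sigma: np.ndarray                  # S/m
    resolution: float                  # mm
    origin: tuple[float, float, float]  # stereotaxic mm of voxel (0,0,0)
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.sigma.shape

    def index_of(self, point: Sequence[float]) -> tuple[int, int, int]:
        idx = tuple(
            int(round((p - o) / self.resolution))
            for p, o in zip(point, self.origin)
        )
        if any(i < 0 or i >= s for i, s in zip(idx, self.shape)):
            raise ValueError(f"point {tuple(point)} outside grid")
        return idx

    def coords(self):
        """1-D coordinate arrays (AP, ML, DV) of voxel centers, mm."""
        return tuple(
            self.origin[d] + self.resolution * np.arange(self.shape[d])
            for d in range(3)
        )


@dataclass
class Contact:
    position: tuple[float, float, float]  # stereotaxic mm (tip)
    role: str                             # 'anode' | 'cathode'
    group: str                            # 'WF-L', 'WF-R', 'L1'..'R4', sweep ids


@dataclass
class ElectrodeMontage:
    """Contacts wired into named sub-configurations.

    ``configurations`` maps a label (e.g. ``L1`` or ``WF``) to the contacts
    active when that sub-configuration is driven; anode and cathode counts
    are balanced per configuration.
    """

    contacts: list[Contact]

    def configuration(self, label: str) -> list[Contact]:
        if label == "WF":
            cs = [c for c in self.contacts if c.group.startswith("WF")]
        else:
            cs = [c for c in self.contacts if c.group == label]
        if not cs:
            raise ValueError(f"unknown configuration {label!r}")
        n_a = sum(c.role == "anode" for c in cs)
        n_c = sum(c.role == "cathode" for c in cs)
        if n_a == 0 or n_a != n_c:
            raise ValueError(f"unbalanced configuration {label!r}")
        return cs

    @property
    def labels(self) -> list[str]:
        return sorted({c.group for c in self.contacts})


@dataclass
class FieldMap:
    """Solved potential (mV) and field (mV/mm) for one configuration."""

    potential: np.ndarray       # mV
    e_field: np.ndarray         # (3, ...) mV/mm vector components
    e_mag: np.ndarray           # mV/mm
    grid: ConductivityGrid
    config_label: str
    current_uA: float
    residual: float

    def scaled(self, current_uA: float) -> "FieldMap":
        """Linearity: rescale the solution to a different injected current."""
        k = current_uA / self.current_uA
        return FieldMap(self.potential * k, self.e_field * k, self.e_mag * k,
                        self.grid, self.config_label, current_uA,
                        self.residual)


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

def build_grid(config: GeometryConfig | None = None) -> ConductivityGrid:
    """Voxelize the parametric brain/hippocampus geometry.

    Masks: ``air`` (outside the brain ellipsoid), ``brain`` (tissue
    excluding hippocampus), ``hippocampus``, ``hippocampus_L/R``. Masks are
    disjoint and cover the domain; conductivities follow the constants at
    the top of this module unless ``config.homogeneous`` selects the single
    0.7 S/m tissue used by the heterogeneity-robustness experiment.
    """
    config = config or GeometryConfig()
    res = config.resolution
    a = np.asarray(config.brain_semiaxes)
    c = np.asarray(config.brain_center)
    lo = c - a - 2 * res
    hi = c + a + 2 * res
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / res)) + 1 for d in range(3))
    ap, ml, dv = (lo[d] + res * np.arange(shape[d]) for d in range(3))
    AP, ML, DV = np.meshgrid(ap, ml, dv, indexing="ij")

    inside = (((AP - c[0]) / a[0]) ** 2 + ((ML - c[1]) / a[1]) ** 2
              + ((DV - c[2]) / a[2]) ** 2) <= 1.0

    hpc = np.zeros(shape, dtype=bool)
    hpc_side = {}
    ap0, ap1 = config.hpc_ap_range
    in_ap = (AP >= ap0) & (AP <= ap1)
    for side in ("L", "R"):
        ml_c, dv_c = config.hpc_centerline(AP, side)
        m = (in_ap
             & (np.abs(ML - ml_c) <= config.hpc_half_ml)
             & (np.abs(DV - dv_c) <= config.hpc_half_dv)
             & inside)
        hpc_side[side] = m
        hpc |= m
    if not hpc.any() or not (hpc <= inside).all():
        raise ValueError("hippocampus mask empty or outside brain")

    sigma = np.full(shape, SIGMA_AIR)
    if config.homogeneous:
        sigma[inside] = SIGMA_HOMOGENEOUS
    else:
        sigma[inside] = SIGMA_BRAIN
        sigma[hpc] = SIGMA_HIPPOCAMPUS
    masks = {
        "air": ~inside,
        "brain": inside & ~hpc,
        "hippocampus": hpc,
        "hippocampus_L": hpc_side["L"],
        "hippocampus_R": hpc_side["R"],
        "electrode_insulation": np.zeros(shape, dtype=bool),
        "electrode_metal": np.zeros(shape, dtype=bool),
    }
    return ConductivityGrid(sigma, res, tuple(lo), masks)


def add_electrode_tracks(grid: ConductivityGrid,
                         montage: ElectrodeMontage) -> None:
    """Mark insulated shafts (sigma 6.62e-7) above each contact tip.

    Shafts run dorsally (increasing DV) from just above the top contact to
    the brain surface, one voxel wide (0.2 mm wire at default resolution).
    """
    dz = grid.resolution
    tops: dict[tuple[int, int], float] = {}
    for c in montage.contacts:
        i, j, k = grid.index_of(c.position)
        grid.masks["electrode_metal"][i, j, k] = True
        tops[(i, j)] = max(tops.get((i, j), -np.inf), c.position[2])
    for (i, j), z_top in tops.items():
        k0 = grid.index_of((grid.origin[0] + i * dz, grid.origin[1] + j * dz,
                            z_top))[2]
        col = grid.sigma[i, j, k0 + 2:]
        tissue = col > 0
        grid.sigma[i, j, k0 + 2:][tissue] = SIGMA_INSULATION
        grid.masks["electrode_insulation"][i, j, k0 + 2:][tissue] = True
        for name in ("brain", "hippocampus", "hippocampus_L", "hippocampus_R"):
            grid.masks[name][i, j, k0 + 2:][tissue] = False


# ---------------------------------------------------------------------------
# montages
# ---------------------------------------------------------------------------

#: Stereotaxic (AP, ML|, DV) of the SNF sites, medial-anterior to
#: lateral-posterior; ML is mirrored per hemisphere.
SNF_SITES = {
    1: (-2.2, 1.2, -3.6),
    2: (-3.0, 2.3, -3.6),
    3: (-3.7, 3.4, -3.6),
    4: (-4.5, 4.5, -4.0),
}

#: WF electrode shaft positions (anterior, posterior) per hemisphere.
WF_SITES = {"anterior": (-2.2, 2.2, -3.6), "posterior": (-4.5, 4.5, -4.0)}


def _mirror(pos: tuple[float, float, float], side: str):
    ap, ml, dv = pos
    return (ap, ml if side == "R" else -ml, dv)


def snf_montage() -> ElectrodeMontage:
    """Eight narrow bipolar dipoles (L1..L4, R1..R4) along both hippocampi.

    Each site is a vertical bipolar pair: cathode at the tip, anode one tip
    spacing (0.4 mm) dorsal, so each sub-configuration is a small local
    dipole inside the hippocampus.
    """
    contacts = []
    for side in ("L", "R"):
        for idx, pos in SNF_SITES.items():
            ap, ml, dv = _mirror(pos, side)
            label = f"{side}{idx}"
            contacts.append(Contact((ap, ml, dv), "cathode", label))
            contacts.append(Contact((ap, ml, dv + TIP_SPACING), "anode", label))
    return ElectrodeMontage(contacts)


def wf_montage() -> ElectrodeMontage:
    """Wide-field montage: anterior shafts anode, posterior shafts cathode.

    Both tips of each bipolar shaft are driven with the same polarity so
    the current flows broadly along the hippocampal axis (sub-configurations
    ``WF-L``, ``WF-R``, or ``WF`` for the bilateral assembly).
    """
    contacts = []
    for side in ("L", "R"):
        for which, role in (("anterior", "anode"), ("posterior", "cathode")):
            ap, ml, dv = _mirror(WF_SITES[which], side)
            for dz in (0.0, TIP_SPACING):
                contacts.append(Contact((ap, ml, dv + dz), role, f"WF-{side}"))
    return ElectrodeMontage(contacts)


def sweep_montage(n_pairs: int,
                  config: GeometryConfig | None = None,
                  side: str = "R") -> ElectrodeMontage:
    """`n_pairs` vertical bipolar dipoles evenly spaced along one hippocampus."""
    config = config or GeometryConfig()
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    ap0, ap1 = -4.5, -2.2
    aps = (np.linspace(ap0, ap1, n_pairs + 2)[1:-1] if n_pairs > 1
           else np.array([(ap0 + ap1) / 2]))
    contacts = []
    for i, ap in enumerate(aps, start=1):
        ml, dv_c = config.hpc_centerline(np.asarray(ap), side)
        label = f"{side}{i}"
        dv = float(dv_c) - 0.2
        contacts.append(Contact((float(ap), float(ml), dv), "cathode", label))
        contacts.append(Contact((float(ap), float(ml), dv + TIP_SPACING),
                                "anode", label))
    return ElectrodeMontage(contacts)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _assemble_system(grid: ConductivityGrid):
    """Sparse 7-point Laplacian over conducting voxels (harmonic-mean faces).

    Air voxels (sigma 0) are excluded, which realizes the insulating outer
    boundary exactly. Returns (matrix, flat index map).
    """
    sigma = grid.sigma
    active = sigma > 0
    n = int(active.sum())
    idx = -np.ones(sigma.shape, dtype=np.int64)
    idx[active] = np.arange(n)
    h = grid.resolution * 1e-3  # m; face conductance g = sigma * h (cube)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        s_lo, s_hi = sigma[tuple(sl_lo)], sigma[tuple(sl_hi)]
        both = (s_lo > 0) & (s_hi > 0)
        g = np.zeros_like(s_lo)
        g[both] = 2.0 * s_lo[both] * s_hi[both] / (s_lo[both] + s_hi[both]) * h
        i_lo = idx[tuple(sl_lo)][both]
        i_hi = idx[tuple(sl_hi)][both]
        gv = g[both]
        rows.extend([i_lo, i_hi])
        cols.extend([i_hi, i_lo])
        vals.extend([-gv, -gv])
        np.add.at(diag, i_lo, gv)
        np.add.at(diag, i_hi, gv)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A, idx


class SolverError(RuntimeError):
    def __init__(self, residual: float):
        super().__init__(f"CG did not converge; final residual {residual:.2e}")
        self.residual = residual


def solve_quasistatic(
    grid: ConductivityGrid,
    montage: ElectrodeMontage,
    active_config: str,
    current_uA: float = 1000.0,
    tol: float = 1e-8,
    maxiter: int = 50_000,
    x0: np.ndarray | None = None,
    _system=None,
) -> FieldMap:
    """Solve div(sigma grad V) = 0 for one active configuration.

    The injected current is partitioned uniformly over anode contact voxels
    and withdrawn at cathode voxels; the outer boundary is insulating. The
    returned potential is in mV, field magnitude in mV/mm; both are linear
    in the injected current.
    """
    if current_uA <= 0:
        raise ValueError("current must be positive")
    contacts = montage.configuration(active_config)
    A, idx = _system if _system is not None else _assemble_system(grid)
    n = A.shape[0]
    b = np.zeros(n)
    I = current_uA * 1e-6  # A
    anodes = [c for c in contacts if c.role == "anode"]
    cathodes = [c for c in contacts if c.role == "cathode"]
    cathode_voxels = {grid.index_of(c.position) for c in cathodes}
    for c in cathodes:
        b[idx[grid.index_of(c.position)]] -= I / len(cathodes)
    for c in anodes:
        i, j, k = grid.index_of(c.position)
        # at coarse resolution a dipole's contacts can round into one voxel;
        # keep source and sink distinct by nudging the anode one voxel dorsal
        while (i, j, k) in cathode_voxels:
            k += 1
        b[idx[i, j, k]] += I / len(anodes)
    if abs(b.sum()) > 1e-3 * np.abs(b).sum():
        raise ValueError("source and sink currents do not balance")

    M = sparse.diags(1.0 / A.diagonal())
    v, info = cg(A, b, x0=x0, rtol=tol, maxiter=maxiter, M=M)
    residual = float(np.linalg.norm(A @ v - b) / np.linalg.norm(b))
    if info != 0:
        raise SolverError(residual)
    v -= v.mean()  # gauge: zero-mean potential

    V = np.zeros(grid.shape)
    V[idx >= 0] = v * 1e3  # -> mV
    E = _field_from_potential(V, idx >= 0, grid.resolution)  # mV/mm
    e_mag = np.sqrt((E ** 2).sum(axis=0))
    return FieldMap(V, E, e_mag, grid, active_config, current_uA, residual)


def _field_from_potential(V: np.ndarray, active: np.ndarray,
                          res_mm: float) -> np.ndarray:
    """E = -grad V with differences restricted to conducting voxels.

    Central differences where both axis neighbors conduct, one-sided at
    domain boundaries (never differencing into air, where V is undefined),
    zero outside the conducting domain.
    """
    E = np.zeros((3,) + V.shape)
    Vp = np.pad(V, 1)
    ap = np.pad(active, 1)
    core = (slice(1, -1),) * 3
    for ax in range(3):
        up_sl = list(core)
        dn_sl = list(core)
        up_sl[ax] = slice(2, None)
        dn_sl[ax] = slice(None, -2)
        v_up, v_dn = Vp[tuple(up_sl)], Vp[tuple(dn_sl)]
        a_up, a_dn = ap[tuple(up_sl)], ap[tuple(dn_sl)]
        grad = np.zeros_like(V)
        both = a_up & a_dn
        grad[both] = (v_up[both] - v_dn[both]) / (2 * res_mm)
        fwd = a_up & ~a_dn
        grad[fwd] = (v_up[fwd] - V[fwd]) / res_mm
        bwd = a_dn & ~a_up
        grad[bwd] = (V[bwd] - v_dn[bwd]) / res_mm
        grad[~active] = 0.0
        E[ax] = -grad
    return E


def sequential_field_set(
    grid: ConductivityGrid,
    montage: ElectrodeMontage,
    order: Sequence[str] = SNF_ORDER,
    current_uA: float = 650.0,
    **solver_kwargs,
) -> list[FieldMap]:
    """One quasi-static solution per SNF sub-configuration, in firing order.

    Fields of different time steps never superpose electrically; any
    temporal combination happens at the neural membrane.
    """
    if sorted(order) != sorted(set(order)):
        raise ValueError("order must not repeat sub-configurations")
    system = _assemble_system(grid)
    return [
        solve_quasistatic(grid, montage, label, current_uA,
                          _system=system, **solver_kwargs)
        for label in order
    ]


# ---------------------------------------------------------------------------
# coverage / spread metrics
# ---------------------------------------------------------------------------

def coverage_and_spread(
    fieldmaps: Sequence[FieldMap],
    target_mask: np.ndarray,
    off_target_mask: np.ndarray,
    thresholds=(THRESH_NETWORK_MOD, THRESH_SUPPRESSION, THRESH_TARGET),
) -> dict:
    """Target coverage and off-target exceedance fractions.

    Target coverage is the fraction of target voxels where the *union* over
    the sequence of |E| >= the 100 mV/mm target threshold. Off-target spread
    at 10 and 50 mV/mm is the maximum over sub-configurations of the
    fraction of off-target voxels exceeded (each sub-field exists at a
    different time, so spreads do not union).
    """
    if not target_mask.any() or not off_target_mask.any():
        raise ValueError("empty mask")
    t10, t50, t100 = thresholds
    union = np.zeros(target_mask.shape, dtype=bool)
    off10 = off50 = 0.0
    for fm in fieldmaps:
        union |= fm.e_mag >= t100
        off10 = max(off10, (fm.e_mag[off_target_mask] >= t10).mean())
        off50 = max(off50, (fm.e_mag[off_target_mask] >= t50).mean())
    return {
        "target_coverage_fraction": float(union[target_mask].mean()),
        "off_target_fraction@10": float(off10),
        "off_target_fraction@50": float(off50),
    }


def match_current_for_coverage(
    fieldmaps: Sequence[FieldMap],
    target_mask: np.ndarray,
    coverage: float = 0.9,
    current_cap_uA: float = 2e6,
    rel_tol: float = 1e-3,
) -> float:
    """Smallest common current (uA) reaching union target coverage.

    Exploits solver linearity: the maps are rescaled rather than re-solved.
    Bisection between 0 and the cap; raises if the cap cannot reach the
    requested coverage.
    """
    def cov(current: float) -> float:
        union = np.zeros(target_mask.shape, dtype=bool)
        for fm in fieldmaps:
            union |= fm.e_mag * (current / fm.current_uA) >= THRESH_TARGET
        return float(union[target_mask].mean())

    if cov(current_cap_uA) < coverage:
        raise ValueError(
            f"coverage {coverage} unreachable at current cap {current_cap_uA}"
        )
    lo, hi = 0.0, current_cap_uA
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if cov(mid) >= coverage:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def perturb_conductivity(grid: ConductivityGrid, max_rel: float = 0.10,
                         seed: int = 0) -> ConductivityGrid:
    """Multiply each tissue voxel's sigma by U(1 - max_rel, 1 + max_rel).

    Electrode-insulation and air voxels are untouched. ``max_rel = 0`` is
    the identity.
    """
    if not 0 <= max_rel < 1:
        raise ValueError("max_rel must be in [0, 1)")
    out = ConductivityGrid(grid.sigma.copy(), grid.resolution, grid.origin,
                           {k: v.copy() for k, v in grid.masks.items()})
    if max_rel == 0:
        return out
    rng = np.random.default_rng(seed)
    tissue = (grid.sigma > 0) & ~grid.masks["electrode_insulation"]
    factors = rng.uniform(1 - max_rel, 1 + max_rel, int(tissue.sum()))
    out.sigma[tissue] = grid.sigma[tissue] * factors
    return out


def heterogeneity_experiment(
    geometry: GeometryConfig | None = None,
    n_seeds: int = 10,
    max_rel: float = 0.10,
    current_uA: float = 650.0,
    seed: int = 0,
    tol: float = 1e-8,
) -> dict:
    """Robustness of the induced field to +-10% conductivity heterogeneity.

    Solves the full SNF sequence (fixed current per dipole) on the
    homogeneous 0.7 S/m brain, then re-solves with each tissue voxel's
    conductivity independently perturbed, for `n_seeds` seeds. The field a
    voxel experiences during sequential stimulation is the per-voxel
    maximum of |E| over the eight sub-fields; the report is the maximum
    over seeds and hippocampal voxels of the relative deviation of that
    induced field, excluding voxels where the homogeneous value is below
    1% of the target-region median (relative error near field nulls is
    meaningless — with the sequential maximum no target voxel is near a
    null).
    """
    if n_seeds < 1:
        raise ValueError("need at least one seed")
    geometry = geometry or GeometryConfig(homogeneous=True)
    if not geometry.homogeneous:
        geometry = GeometryConfig(
            **{**geometry.__dict__, "homogeneous": True})
    montage = snf_montage()
    grid = build_grid(geometry)
    add_electrode_tracks(grid, montage)
    hom_maps = sequential_field_set(grid, montage, SNF_ORDER,
                                    current_uA=current_uA, tol=tol)
    hom_max = np.max([m.e_mag for m in hom_maps], axis=0)

    hpc = grid.masks["hippocampus"]
    med = np.median(hom_max[hpc])
    valid = hpc & (hom_max >= 0.01 * med)

    rng = np.random.default_rng(seed)
    deviations = []
    for _ in range(n_seeds):
        pg = perturb_conductivity(grid, max_rel, int(rng.integers(2**31)))
        system = _assemble_system(pg)
        het_maps = [
            solve_quasistatic(pg, montage, label, current_uA, tol=tol,
                              x0=hm.potential[pg.sigma > 0] * 1e-3,
                              _system=system)
            for label, hm in zip(SNF_ORDER, hom_maps)
        ]
        het_max = np.max([m.e_mag for m in het_maps], axis=0)
        dev = np.abs(het_max[valid] - hom_max[valid]) / hom_max[valid]
        deviations.append(float(dev.max()))
    return {
        "max_deviation": max(deviations),
        "per_seed": deviations,
        "n_valid_voxels": int(valid.sum()),
    }


def _all_pairs_configuration(montage: ElectrodeMontage) -> ElectrodeMontage:
    """Relabel every contact into one simultaneous configuration 'ALL'."""
    return ElectrodeMontage(
        [Contact(c.position, c.role, "ALL") for c in montage.contacts]
    )


def electrode_count_sweep(
    geometry: GeometryConfig | None = None,
    pair_counts: Sequence[int] = (1, 2, 3, 4, 5, 6),
    coverage: float = 0.9,
    side: str = "R",
    tol: float = 1e-8,
) -> dict:
    """Required current and off-target spread vs number of SNF pairs.

    For each pair count, dipoles are placed evenly along one hippocampal
    axis, the common amplitude is bisected until the union 100 mV/mm target
    coverage reaches `coverage`, and the off-target exceedance fraction at
    10 mV/mm (per-sub-configuration maximum) is evaluated at that current.
    """
    geometry = geometry or GeometryConfig()
    results = {"pair_counts": list(pair_counts), "required_current_uA": [],
               "off_target_fraction": []}
    for n in pair_counts:
        montage = sweep_montage(n, geometry, side)
        grid = build_grid(geometry)
        add_electrode_tracks(grid, montage)
        order = [f"{side}{i}" for i in range(1, n + 1)]
        maps = sequential_field_set(grid, montage, order, current_uA=100.0,
                                    tol=tol)
        target = grid.masks[f"hippocampus_{side}"]
        off = grid.masks["brain"] | grid.masks[
            "hippocampus_L" if side == "R" else "hippocampus_R"]
        current = match_current_for_coverage(maps, target, coverage)
        scaled = [m.scaled(current) for m in maps]
        metrics = coverage_and_spread(scaled, target, off)
        results["required_current_uA"].append(current)
        results["off_target_fraction"].append(
            metrics["off_target_fraction@10"])
    return results
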