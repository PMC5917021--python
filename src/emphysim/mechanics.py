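"""2D plane-stress linear elasticity on the structured alveolar grid.

The alveolar grid maps one-to-one onto a structured mesh of bilinear
quadrilateral elements.  Each element's Young's modulus is a linear mixture
of its normalized elastin and collagen content; a dead cell keeps its place
in the mesh but is assigned a negligible modulus (1 Pa) so the topology
never changes.  Breathing is modeled as a displacement-controlled uniform
boundary strain.  Rupture is evaluated per element by comparing the maximum
principal strain at the centroid against a composition-weighted tensile
limit: pure elastin stretches to 100% strain, pure low-crosslink collagen
fibrils fail near 10%.

The stiffness assembly exploits the structured geometry: every element is
the same square, so the global matrix is a modulus-weighted scatter of a
single unit-modulus element stiffness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "DELTA_EL", "DELTA_CL", "E_EL", "E_CL", "E_DEAD",
    "STRAIN_LIMIT_EL", "STRAIN_LIMIT_CL",
    "QuadMesh", "MaterialField", "BreathingLoad", "StrainField",
    "mixture_modulus", "build_mesh", "solve_elasticity",
    "max_tensile_strain_limit", "rupture",
]

DELTA_EL = 0.7       # elastin mixture weight
DELTA_CL = 0.3       # collagen mixture weight
E_EL = 100.0         # elastin phase modulus, Pa (0.1 kPa)
E_CL = 20_000.0      # collagen phase modulus, Pa (20 kPa)
E_DEAD = 1.0         # modulus of a dead cell, Pa
STRAIN_LIMIT_EL = 1.0    # elastin tensile strain limit (100 %)
STRAIN_LIMIT_CL = 0.1    # collagen tensile strain limit (10 %)


class SolverError(RuntimeError):
    """Raised when the linear elastic system cannot be solved."""


def mixture_modulus(cel, ccl, alive=True):
    """Per-cell Young's modulus (Pa) from normalized matrix content.

    Accepts scalars or arrays.  Alive tissue mixes the elastin and collagen
    phase moduli linearly; a dead cell is fixed at ``E_DEAD`` = 1 Pa.
    """
    cel = np.asarray(cel, dtype=float)
    ccl = np.asarray(ccl, dtype=float)
    if np.any(cel < 0) or np.any(cel > 1) or np.any(ccl < 0) or np.any(ccl > 1):
        raise ValueError("elastin/collagen fractions must lie in [0, 1]")
    e = DELTA_EL * cel * E_EL + DELTA_CL * ccl * E_CL
    # a fully depleted but still-alive cell is floored at the dead-cell modulus
    out = np.where(np.asarray(alive, dtype=bool), np.maximum(e, E_DEAD), E_DEAD)
    return float(out) if out.ndim == 0 else out


def max_tensile_strain_limit(cel, ccl):
    """Composition-weighted maximum tensile strain before rupture.

    Normalized linear blend of the elastin (1.0) and collagen (0.1)
    endpoints.  A cell with no matrix left gets the conservative collagen
    limit, with a warning.
    """
    cel = np.asarray(cel, dtype=float)
    ccl = np.asarray(ccl, dtype=float)
    total = cel + ccl
    if np.any(total <= 0):
        warnings.warn("cell with no elastin or collagen: using collagen limit",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        lim = np.where(total > 0,
                       (cel * STRAIN_LIMIT_EL + ccl * STRAIN_LIMIT_CL)
                       / np.where(total > 0, total, 1.0),
                       STRAIN_LIMIT_CL)
    return float(lim) if lim.ndim == 0 else lim


@dataclass
class QuadMesh:
    """Structured mesh of square bilinear quads, one element per grid cell.

    Node ``(r, c)`` sits at ``(x, y) = (c * h, r * h)``; element node order
    is counter-clockwise.  Element ``r * cols + c`` maps to grid cell
    ``(r, c)``.
    """

    rows: int
    cols: int
    cell_size: float = 1.0
    nodes: np.ndarray = field(init=False)      # (n_nodes, 2) coordinates, mm
    elements: np.ndarray = field(init=False)   # (n_elems, 4) node indices

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("mesh dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        h = self.cell_size
        rr, cc = np.meshgrid(np.arange(self.rows + 1), np.arange(self.cols + 1),
                             indexing="ij")
        self.nodes = np.column_stack([cc.ravel() * h, rr.ravel() * h]).astype(float)
        n = lambda r, c: r * (self.cols + 1) + c
        elems = []
        for r in range(self.rows):
            for c in range(self.cols):
                elems.append([n(r, c), n(r, c + 1), n(r + 1, c + 1), n(r + 1, c)])
        self.elements = np.array(elems, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_of_cell(self, r: int, c: int) -> int:
        return r * self.cols + c

    def boundary_nodes(self) -> np.ndarray:
        """Indices of all nodes on the rectangle boundary."""
        rr = self.nodes[:, 1] / self.cell_size
        cc = self.nodes[:, 0] / self.cell_size
        on = (np.isclose(rr, 0) | np.isclose(rr, self.rows)
              | np.isclose(cc, 0) | np.isclose(cc, self.cols))
        return np.flatnonzero(on)


def build_mesh(rows: int, cols: int, cell_size: float = 1.0) -> QuadMesh:
    """Structured quad mesh topologically equivalent to a rows x cols grid."""
    return QuadMesh(rows, cols, cell_size)


@dataclass
class MaterialField:
    """Per-element Young's modulus (Pa) and a global Poisson ratio."""

    E: np.ndarray
    nu: float = 0.3

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float).ravel()
        if np.any(self.E < E_DEAD):
            raise ValueError(f"element modulus below E_DEAD = {E_DEAD} Pa")
        if not 0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")

    @classmethod
    def from_grid(cls, cel, ccl, alive, nu: float = 0.3) -> "MaterialField":
        return cls(mixture_modulus(cel, ccl, alive).ravel(), nu)


@dataclass
class BreathingLoad:
    """Displacement-controlled boundary strain emulating tidal breathing.

    ``eps_app`` is the uniform strain imposed on the boundary (default 5%,
    the order of magnitude of tidal breathing); ``mode`` selects biaxial or
    uniaxial stretching.
    """

    eps_app: float = 0.05
    mode: str = "biaxial"

    def __post_init__(self) -> None:
        if self.eps_app < 0:
            raise ValueError("eps_app must be >= 0")
        if self.mode not in ("biaxial", "uniaxial-x", "uniaxial-y"):
            raise ValueError(f"unknown load mode {self.mode!r}")

    def applied_strain(self) -> tuple[float, float]:
        if self.mode == "biaxial":
            return self.eps_app, self.eps_app
        if self.mode == "uniaxial-x":
            return self.eps_app, 0.0
        return 0.0, self.eps_app


@dataclass
class StrainField:
    """Element-centroid small strains and the derived max principal strain."""

    exx: np.ndarray
    eyy: np.ndarray
    exy: np.ndarray  # tensor shear strain (not engineering)

    @property
    def max_principal(self) -> np.ndarray:
        mean = 0.5 * (self.exx + self.eyy)
        radius = np.sqrt((0.5 * (self.exx - self.eyy)) ** 2 + self.exy ** 2)
        return mean + radius


# -- element matrices (reference square, 2x2 Gauss) --------------------------

_XI = np.array([-1.0, 1.0, 1.0, -1.0])
_ETA = np.array([-1.0, -1.0, 1.0, 1.0])


def _unit_stiffness(nu: float, h: float) -> np.ndarray:
    """8x8 element stiffness of a square Q4 element with E = 1 (plane stress)."""
    D = (1.0 / (1.0 - nu ** 2)) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]])
    g = 1.0 / np.sqrt(3.0)
    K = np.zeros((8, 8))
    det_j = h * h / 4.0
    for xi in (-g, g):
        for eta in (-g, g):
            B = _b_matrix(xi, eta, h)
            K += B.T @ D @ B * det_j
    return K


def _b_matrix(xi: float, eta: float, h: float) -> np.ndarray:
    dN_dxi = 0.25 * _XI * (1.0 + eta * _ETA)
    dN_deta = 0.25 * _ETA * (1.0 + xi * _XI)
    dN_dx = dN_dxi * 2.0 / h
    dN_dy = dN_deta * 2.0 / h
    B = np.zeros((3, 8))
    B[0, 0::2] = dN_dx
    B[1, 1::2] = dN_dy
    B[2, 0::2] = dN_dy
    B[2, 1::2] = dN_dx
    return B


def solve_elasticity(
    mesh: QuadMesh,
    mat: MaterialField,
    load: BreathingLoad | None = None,
    boundary_displacement=None,
) -> tuple[np.ndarray, StrainField]:
    """Static plane-stress solve under a prescribed boundary displacement.

    By default the boundary displacement realizes the uniform strain field
    of ``load`` (relative to the mesh center); passing a callable
    ``boundary_displacement(x, y) -> (ux, uy)`` overrides it (used e.g. for
    patch tests).  Returns nodal displacements (n_nodes, 2) and the
    element-centroid strain field.  The reduced stiffness matrix is
    symmetric positive definite; the solution's relative residual is
    checked against 1e-8.
    """
    if mat.E.size != mesh.n_elements:
        raise ValueError("material field size does not match mesh")
    if load is None and boundary_displacement is None:
        raise ValueError("either load or boundary_displacement is required")

    n_dof = 2 * mesh.n_nodes
    K0 = _unit_stiffness(mat.nu, mesh.cell_size)

    # scatter E_e * K0 into COO triplets
    edofs = np.empty((mesh.n_elements, 8), dtype=int)
    edofs[:, 0::2] = 2 * mesh.elements
    edofs[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(edofs, 8, axis=1).ravel()
    cols = np.tile(edofs, (1, 8)).ravel()
    data = (mat.E[:, None] * K0.ravel()[None, :]).ravel()
    K = sp.coo_matrix((data, (rows, cols)), shape=(n_dof, n_dof)).tocsr()

    # prescribed boundary displacements
    bnodes = mesh.boundary_nodes()
    xy = mesh.nodes[bnodes]
    if boundary_displacement is not None:
        ub = np.array([boundary_displacement(x, y) for x, y in xy], dtype=float)
    else:
        ex, ey = load.applied_strain()
        center = mesh.nodes.mean(axis=0)
        ub = np.column_stack([ex * (xy[:, 0] - center[0]),
                              ey * (xy[:, 1] - center[1])])

    fixed = np.concatenate([2 * bnodes, 2 * bnodes + 1])
    u = np.zeros(n_dof)
    u[2 * bnodes] = ub[:, 0]
    u[2 * bnodes + 1] = ub[:, 1]
    free = np.setdiff1d(np.arange(n_dof), fixed)

    if free.size:
        K_ff = K[np.ix_(free, free)]
        rhs = -K[np.ix_(free, fixed)] @ u[fixed]
        try:
            u_f = spla.spsolve(K_ff.tocsc(), rhs)
        except Exception as exc:  # pragma: no cover - singular systems
            raise SolverError(f"elastic solve failed: {exc}") from exc
        if not np.all(np.isfinite(u_f)):
            raise SolverError("elastic solve produced non-finite displacements")
        u[free] = u_f
        res = np.linalg.norm(K_ff @ u_f - rhs)
        scale = max(np.linalg.norm(rhs), 1e-30)
        if res > 1e-8 * max(scale, 1.0):
            raise SolverError(f"linear-system residual too large: {res:g}")

    # centroid strains
    B_c = _b_matrix(0.0, 0.0, mesh.cell_size)
    ue = u[edofs]                               # (n_elems, 8)
    strains = ue @ B_c.T                        # (n_elems, 3): exx, eyy, gamma
    return u.reshape(-1, 2), StrainField(
        exx=strains[:, 0], eyy=strains[:, 1], exy=0.5 * strains[:, 2])


def rupture(
    strains: StrainField,
    cel: np.ndarray,
    ccl: np.ndarray,
    alive: np.ndarray,
) -> list[tuple[int, int]]:
    """Grid cells whose element strain exceeds their tensile limit.

    ``cel``, ``ccl`` and ``alive`` are the (rows, cols) grid arrays; the
    element order is the row-major grid order.  Only currently alive cells
    can rupture.
    """
    shape = np.asarray(alive).shape
    limits = max_tensile_strain_limit(np.asarray(cel).ravel(),
                                      np.asarray(ccl).ravel())
    over = (strains.max_principal > limits) & np.asarray(alive).ravel()
    return [tuple(divmod(int(i), shape[1])) for i in np.flatnonzero(over)]
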