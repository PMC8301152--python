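"""Five-parameter Mooney–Rivlin hyperelasticity under plane stress.

The tissue model is the polynomial (5-parameter) Mooney–Rivlin strain-energy
density

    W = C10 (I1b - 3) + C01 (I2b - 3) + C20 (I1b - 3)^2 + C02 (I2b - 3)^2
        + C11 (I1b - 3)(I2b - 3) + (1/d1) (J - 1)^2 ,

where ``I1b``, ``I2b`` are by default the *isochoric* invariants of the right
Cauchy–Green tensor (``I1b = J^{-2/3} I1``, ``I2b = J^{-4/3} I2``) and ``J``
is the volume ratio.  The isochoric split is what the commercial hyperelastic
plane elements implement and is required for a stress-free reference
configuration; a literal total-invariant variant is available with
``isochoric=False`` for sensitivity studies (it carries a spurious reference
pre-stress ``S(I) = (2 C10 + 4 C01) I`` and is never the default).

Plane stress is enforced pointwise: for a given in-plane Cauchy–Green tensor
``C`` the through-thickness stretch ``lam3`` solves ``S33(C, lam3^2) = 0`` by
a guarded Newton iteration, and the condensed in-plane tangent includes the
``d lam3 / d C`` contribution so that the outer Newton loop keeps its
quadratic rate.

Stress and tangent expressions are derived symbolically (sympy) from W and
compiled once at import into vectorised numpy kernels; they are therefore
exact derivatives of the implemented energy, which the finite-difference
oracles in the test-suite verify independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "MooneyRivlin5",
    "DeformationState",
    "MATERIALS",
    "material_table",
    "InvertedStateError",
    "PlaneStressError",
    "invariants_of",
    "strain_energy",
    "pk2_stress",
    "material_tangent",
    "plane_stress_stretch",
    "plane_stress_state",
    "stress_and_condensed_tangent",
    "cauchy_stress",
]

# Voigt component order used throughout: [11, 22, 33, 12].
_VOIGT = ((0, 0), (1, 1), (2, 2), (0, 1))

# Guard bracket for the through-thickness stretch root search.
LAM3_MIN, LAM3_MAX = 0.05, 20.0


class InvertedStateError(ValueError):
    """Deformation state with non-positive volume ratio."""


class PlaneStressError(RuntimeError):
    """No through-thickness stretch satisfies S33 = 0 inside the guard bracket."""


@dataclass(frozen=True)
class MooneyRivlin5:
    """Material constants of the 5-parameter Mooney–Rivlin model.

    ``c10 .. c11`` are stress-like deviatoric coefficients [Pa]; ``d1`` is the
    inverse-stress volumetric coefficient [Pa^-1] (volumetric stiffness
    2/d1).  ``name`` is carried for provenance in reports.
    """

    c10: float
    c01: float
    c20: float
    c02: float
    c11: float
    d1: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.d1 <= 0:
            raise ValueError(f"d1 must be positive, got {self.d1}")
        if self.mu0 <= 0:
            raise ValueError(
                f"initial shear modulus 2*(c10+c01) must be positive, got {self.mu0}"
            )

    @property
    def mu0(self) -> float:
        """Initial (small-strain) shear modulus, 2 (C10 + C01) [Pa]."""
        return 2.0 * (self.c10 + self.c01)

    @property
    def bulk0(self) -> float:
        """Initial bulk modulus of the volumetric penalty, 2 / d1 [Pa]."""
        return 2.0 / self.d1

    def constants(self) -> tuple[float, ...]:
        return (self.c10, self.c01, self.c20, self.c02, self.c11, self.d1)


#: Material presets for the three tissue classes of the sphincter model.
#: Dense connective tissue forms the stiff epithelial ring around the lumen,
#: spongy tissue (lamina propria) the compliant bulk, and fibrotic tissue the
#: pathologically stiffened spongy material (deviatoric coefficients scaled
#: ten-fold, volumetric coefficient unchanged).
MATERIALS: dict[str, MooneyRivlin5] = {
    "dense_connective": MooneyRivlin5(
        c10=3030.83, c01=2142.94, c20=59059.00, c02=82911.00, c11=-1.431e5,
        d1=8.00e-7, name="dense_connective",
    ),
    "spongy": MooneyRivlin5(
        c10=89.12, c01=82.60, c20=2064.50, c02=2953.61, c11=-4737.35,
        d1=8.00e-7, name="spongy",
    ),
    "fibrotic": MooneyRivlin5(
        c10=891.18, c01=825.97, c20=20645.00, c02=29536.10, c11=-47373.50,
        d1=8.00e-7, name="fibrotic",
    ),
}


def material_table() -> dict[str, MooneyRivlin5]:
    """Return a copy of the preset material table."""
    return dict(MATERIALS)


# ---------------------------------------------------------------------------
# Symbolic derivation of stress and tangent kernels
# ---------------------------------------------------------------------------
#
# The state is parametrised by the four independent components of the
# block-diagonal right Cauchy–Green tensor
#
#     C = [[c11, c12, 0], [c12, c22, 0], [0, 0, c33]],   c33 = lam3^2.
#
# With W written as a function of (c11, c22, c33, c12) — c12 entering both
# off-diagonal slots — the second Piola–Kirchhoff components are
#
#     S_11 = 2 dW/dc11,  S_22 = 2 dW/dc22,  S_33 = 2 dW/dc33,  S_12 = dW/dc12,
#
# and M_ij = dS_i/dc_j is the (non-symmetric, single-c12-count) Jacobian from
# which both the full Voigt tangent and the plane-stress condensation are
# assembled.


@lru_cache(maxsize=None)
def _kernels(isochoric: bool):
    import sympy as sp

    c11, c22, c33, c12 = sp.symbols("c11 c22 c33 c12", positive=False)
    a10, a01, a20, a02, a11, d1 = sp.symbols("a10 a01 a20 a02 a11 d1")

    I1 = c11 + c22 + c33
    detC = c33 * (c11 * c22 - c12**2)
    # I2 = (I1^2 - tr(C^2)) / 2 for the block-diagonal C
    trC2 = c11**2 + c22**2 + c33**2 + 2 * c12**2
    I2 = (I1**2 - trC2) / 2
    J = sp.sqrt(detC)

    if isochoric:
        i1 = J ** sp.Rational(-2, 3) * I1
        i2 = J ** sp.Rational(-4, 3) * I2
    else:
        i1, i2 = I1, I2

    W = (
        a10 * (i1 - 3)
        + a01 * (i2 - 3)
        + a20 * (i1 - 3) ** 2
        + a02 * (i2 - 3) ** 2
        + a11 * (i1 - 3) * (i2 - 3)
        + (J - 1) ** 2 / d1
    )

    comps = (c11, c22, c33, c12)
    factors = (2, 2, 2, 1)
    S = [sp.together(f * sp.diff(W, c)) for f, c in zip(factors, comps)]
    M = [[sp.diff(S[i], comps[j]) for j in range(4)] for i in range(4)]

    args = (c11, c22, c33, c12, a10, a01, a20, a02, a11, d1)
    flat = [W] + S + [M[i][j] for i in range(4) for j in range(4)]
    fn_all = sp.lambdify(args, flat, modules="numpy", cse=True)
    # mini-kernel for the plane-stress scalar Newton: S33 and dS33/dc33
    fn_ps = sp.lambdify(args, [S[2], M[2][2]], modules="numpy", cse=True)
    return fn_all, fn_ps


def _eval_kernel(mat: MooneyRivlin5, c11, c22, c33, c12, isochoric: bool):
    fn_all, _ = _kernels(isochoric)
    out = fn_all(c11, c22, c33, c12, *mat.constants())
    shape = np.broadcast(c11, c22, c33, c12).shape
    out = [np.broadcast_to(np.asarray(v, dtype=float), shape) for v in out]
    W = out[0]
    S = np.stack(out[1:5], axis=-1)
    M = np.stack(out[5:], axis=-1).reshape(shape + (4, 4))
    return W, S, M


# ---------------------------------------------------------------------------
# Deformation state and invariants
# ---------------------------------------------------------------------------


@dataclass
class DeformationState:
    """In-plane deformation gradient plus through-thickness stretch.

    ``F`` has shape (..., 2, 2); ``lam3`` broadcasts against the leading
    dimensions.  The invariants refer to the full three-dimensional state
    ``diag-block(F, lam3)``.
    """

    F: np.ndarray
    lam3: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.lam3 = np.asarray(self.lam3, dtype=float)
        J2d = np.linalg.det(self.F)
        if np.any(J2d * self.lam3 <= 0):
            raise InvertedStateError("non-positive volume ratio det(F) * lam3")

    @property
    def C2d(self) -> np.ndarray:
        return np.einsum("...ki,...kj->...ij", self.F, self.F)

    @property
    def invariants(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return invariants_of(self.F, self.lam3)


def _c_components(C2d: np.ndarray, lam3) -> tuple[np.ndarray, ...]:
    C2d = np.asarray(C2d, dtype=float)
    lam3 = np.asarray(lam3, dtype=float)
    return C2d[..., 0, 0], C2d[..., 1, 1], lam3**2, C2d[..., 0, 1]


def invariants_of(F, lam3=1.0):
    """Invariants (I1, I2, J) of the 3D right Cauchy–Green tensor.

    ``F`` is the in-plane 2x2 deformation gradient (batched in the leading
    axes), ``lam3`` the out-of-plane stretch.  Raises
    :class:`InvertedStateError` if ``det(F) * lam3 <= 0``.
    """
    F = np.asarray(F, dtype=float)
    lam3 = np.asarray(lam3, dtype=float)
    J2d = np.linalg.det(F)
    if np.any(J2d * lam3 <= 0):
        raise InvertedStateError("non-positive volume ratio det(F) * lam3")
    C = np.einsum("...ki,...kj->...ij", F, F)
    t = lam3**2
    I1 = C[..., 0, 0] + C[..., 1, 1] + t
    trC2 = (
        C[..., 0, 0] ** 2 + C[..., 1, 1] ** 2 + t**2 + 2 * C[..., 0, 1] ** 2
    )
    I2 = (I1**2 - trC2) / 2
    J = J2d * lam3
    return I1, I2, J


def strain_energy(mat: MooneyRivlin5, state: DeformationState, *, isochoric: bool = True):
    """Strain-energy density W [Pa] at the given state."""
    W, _, _ = _eval_kernel(mat, *_c_components(state.C2d, state.lam3), isochoric)
    return W if W.ndim else float(W)


def pk2_stress(mat: MooneyRivlin5, state: DeformationState, *, isochoric: bool = True):
    """Second Piola–Kirchhoff stress: in-plane 2x2 block and S33 component."""
    _, S, _ = _eval_kernel(mat, *_c_components(state.C2d, state.lam3), isochoric)
    S2d = np.empty(S.shape[:-1] + (2, 2))
    S2d[..., 0, 0] = S[..., 0]
    S2d[..., 1, 1] = S[..., 1]
    S2d[..., 0, 1] = S2d[..., 1, 0] = S[..., 3]
    return S2d, S[..., 2]


def material_tangent(mat: MooneyRivlin5, state: DeformationState, *, isochoric: bool = True):
    """Voigt tangent CC = 4 d2W/dCdC over components [11, 22, 33, 12].

    Convention: ``dS_AB = 1/2 * CC[AB, CD] * dC_CD`` with the tensor ``dC``
    (both off-diagonal slots varying).  The returned 4x4 matrix is symmetric
    (major symmetry).
    """
    _, _, M = _eval_kernel(mat, *_c_components(state.C2d, state.lam3), isochoric)
    colf = np.array([2.0, 2.0, 2.0, 1.0])
    return M * colf


# ---------------------------------------------------------------------------
# Plane-stress condensation
# ---------------------------------------------------------------------------


def plane_stress_stretch(
    mat: MooneyRivlin5,
    C2d: np.ndarray,
    *,
    isochoric: bool = True,
    lam3_init: np.ndarray | None = None,
    rtol: float = 1e-10,
    max_iter: int = 140,
):
    """Through-thickness stretch lam3 solving S33 = 0 for in-plane C.

    Guarded scalar Newton on ``c33 = lam3^2``, vectorised over quadrature
    points, with bisection fallback inside the bracket
    ``lam3 in (0.05, 20)``.  Convergence: |S33| <= rtol-driven tolerance
    relative to the initial shear modulus; the returned states satisfy
    |S33| <= 1e-8 * mu0.
    """
    C2d = np.asarray(C2d, dtype=float)
    c11, c22, c12 = C2d[..., 0, 0], C2d[..., 1, 1], C2d[..., 0, 1]
    det2 = c11 * c22 - c12**2
    if np.any(det2 <= 0):
        raise InvertedStateError("in-plane C is not positive definite")

    _, fn_ps = _kernels(isochoric)
    consts = mat.constants()
    shape = det2.shape
    tol = rtol * mat.mu0

    lo = np.full(shape, LAM3_MIN**2)
    hi = np.full(shape, LAM3_MAX**2)

    def s33(c33):
        v, dv = fn_ps(c11, c22, c33, c12, *consts)
        return (
            np.broadcast_to(np.asarray(v, float), shape),
            np.broadcast_to(np.asarray(dv, float), shape),
        )

    # bracket check: S33 decreases in compression, increases in tension, so a
    # root requires S33(lo) < 0 < S33(hi)
    s_lo, _ = s33(lo)
    s_hi, _ = s33(hi)
    if np.any(s_lo > 0) or np.any(s_hi < 0):
        raise PlaneStressError(
            "no through-thickness root in (0.05, 20) for some quadrature point"
        )

    if lam3_init is not None:
        c33 = np.broadcast_to(np.asarray(lam3_init, float) ** 2, shape).copy()
        c33 = np.clip(c33, lo * 1.01, hi * 0.99)
    else:
        # incompressible initial guess lam3 = 1/sqrt(det C2d)
        c33 = 1.0 / det2

    eps = np.finfo(float).eps
    for it in range(max_iter):
        s, ds = s33(c33)
        # maintain bisection bracket
        neg = s < 0
        lo = np.where(neg, np.maximum(lo, c33), lo)
        hi = np.where(~neg, np.minimum(hi, c33), hi)
        # converged when the residual is below tolerance or the root is
        # bracketed to near machine relative width (at large stretches the
        # kernel's floating-point noise floor exceeds the nominal stress
        # tolerance, so the bracket width is the honest convergence measure
        # there; a loose root would inject noise into the outer Newton
        # residual above its own tolerance)
        done = ((hi - lo) <= 1e-13 * np.maximum(c33, 1e-6)) | (np.abs(s) <= tol)
        if done.all():
            break
        step = np.where(np.abs(ds) > 0, -s / np.where(ds == 0, 1.0, ds), 0.0)
        c33_new = c33 + step
        bad = (c33_new <= lo) | (c33_new >= hi) | (step == 0)
        # interleave pure bisection so the bracket keeps halving even when
        # Newton hovers inside the evaluation-noise ball around the root
        if it % 2 == 1:
            bad = bad | ~done & (np.abs(step) < 0.25 * (hi - lo))
        c33 = np.where(bad, 0.5 * (lo + hi), c33_new)
    else:
        raise PlaneStressError(
            f"plane-stress iteration stalled, max |S33|/mu0 = "
            f"{float(np.max(np.abs(s))) / mat.mu0:.3e}"
        )
    return np.sqrt(c33)


def plane_stress_state(mat: MooneyRivlin5, F, *, isochoric: bool = True, lam3_init=None):
    """DeformationState with lam3 solved from the plane-stress condition."""
    F = np.asarray(F, dtype=float)
    C2d = np.einsum("...ki,...kj->...ij", F, F)
    lam3 = plane_stress_stretch(mat, C2d, isochoric=isochoric, lam3_init=lam3_init)
    return DeformationState(F=F, lam3=lam3)


def stress_and_condensed_tangent(
    mat: MooneyRivlin5, C2d: np.ndarray, lam3: np.ndarray, *, isochoric: bool = True
):
    """In-plane PK2 stress and statically condensed material tangent.

    ``lam3`` must already satisfy the plane-stress condition.  Returns
    ``(W, S2d, CC)`` with ``S2d`` of shape (..., 2, 2) and ``CC`` the
    condensed fourth-order in-plane tangent of shape (..., 2, 2, 2, 2) in the
    convention ``dS_ij = 1/2 * CC[ijkl] * dC_kl``; the condensation term
    ``- M_p3 M_3p / M_33`` carries the d(lam3)/dC dependence.
    """
    W, S, M = _eval_kernel(mat, *_c_components(C2d, lam3), isochoric)
    # condense out the 33 slot (index 2): rows/cols [0, 1, 3]
    p = [0, 1, 3]
    Mpp = M[..., p, :][..., :, p]
    Mp3 = M[..., p, 2]
    M3p = M[..., 2, :][..., p]
    M33 = M[..., 2, 2]
    Mc = Mpp - Mp3[..., :, None] * M3p[..., None, :] / M33[..., None, None]

    S2d = np.empty(S.shape[:-1] + (2, 2))
    S2d[..., 0, 0] = S[..., 0]
    S2d[..., 1, 1] = S[..., 1]
    S2d[..., 0, 1] = S2d[..., 1, 0] = S[..., 3]

    # expand condensed Voigt rows [11, 22, 12] to full minor-symmetric tensor:
    # CC_{AB,CD} = Mc[v(AB), v(CD)] * (2 if C == D else 1)
    shape = Mc.shape[:-2]
    CC = np.empty(shape + (2, 2, 2, 2))
    vmap = {(0, 0): 0, (1, 1): 1, (0, 1): 2, (1, 0): 2}
    for (A, B), r in vmap.items():
        for (C_, D), c in vmap.items():
            CC[..., A, B, C_, D] = Mc[..., r, c] * (2.0 if C_ == D else 1.0)
    return W, S2d, CC


def cauchy_stress(state: DeformationState, S2d: np.ndarray) -> np.ndarray:
    """Push the in-plane PK2 stress forward to Cauchy stress.

    sigma = (1/J) F S F^T with the full volume ratio J = det(F) * lam3
    (plane stress: sigma33 = 0 by construction).
    """
    J = np.linalg.det(state.F) * state.lam3
    sig = np.einsum("...ik,...kl,...jl->...ij", state.F, S2d, state.F)
    return sig / J[..., None, None]
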