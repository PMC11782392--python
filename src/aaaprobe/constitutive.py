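"""Constitutive laws for the aneurysm wall and the surrounding abdominal tissue.

Three materials are modeled:

* the aneurysm wall as a Holzapfel--Gasser--Ogden (HGO) anisotropic
  hyperelastic membrane: an isotropic neo-Hookean matrix (``C10``) reinforced
  by two symmetric collagen-fiber families at ``±θ`` from the circumferential
  direction, with Gasser-type dispersion ``κ`` and an exponential stiffening
  exponent ``k2`` — the classic J-shaped arterial response;
* the same wall linearized as an orthotropic elastic membrane (circumferential
  and longitudinal moduli ``E_θ``, ``E_z``, Poisson ratio ``ν``);
* the surrounding soft tissue as a nearly incompressible neo-Hookean solid in
  plane strain.

The wall laws are reduced to scalar membrane form: through-thickness Cauchy
stress is zero, the axial stretch is held at 1 (the cross-sectional plane is a
symmetry plane), and the wall is incompressible, so the through-thickness
stretch is ``1/λ_circ``.  This yields closed-form circumferential stress and
tangent, which the nonlinear solver consumes through
:meth:`WallMaterial.tension`.

Units: stresses and moduli in kPa, lengths in mm throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MaterialDefinitionError, StretchRangeError

__all__ = [
    "HGOWallParams",
    "LinearWallParams",
    "TissueParams",
    "MembraneState",
    "hgo_membrane_response",
    "linear_membrane_response",
    "neo_hookean_stress",
    "neo_hookean_pk1",
    "HGOWall",
    "LinearWall",
]

# Guard against overflow of the exponential fiber term: exp(k2*E^2) beyond
# this argument means stretches far outside the physiological range.
_EXP_ARG_MAX = 60.0


@dataclass(frozen=True)
class HGOWallParams:
    """HGO wall parameters (defaults: elderly healthy aorta).

    ``k1`` is stored in kPa; literature tables often quote it in MPa
    (use ``HGOWallParams.from_k1_mpa`` for those).
    """

    C10: float = 100.9          # kPa, isotropic matrix stiffness
    k1: float = 4070.0          # kPa, fiber stiffness
    k2: float = 165.55          # -, exponential stiffening
    kappa: float = 0.16         # -, fiber dispersion in [0, 1/3]
    theta_deg: float = 48.4     # deg, fiber angle from circumferential

    def __post_init__(self):
        if not self.C10 > 0:
            raise MaterialDefinitionError(f"C10 must be > 0, got {self.C10}")
        if self.k1 < 0:
            raise MaterialDefinitionError(f"k1 must be >= 0, got {self.k1}")
        if not self.k2 > 0:
            raise MaterialDefinitionError(f"k2 must be > 0, got {self.k2}")
        if not 0.0 <= self.kappa <= 1.0 / 3.0:
            raise MaterialDefinitionError(
                f"kappa must lie in [0, 1/3], got {self.kappa}")
        if not 0.0 <= self.theta_deg <= 90.0:
            raise MaterialDefinitionError(
                f"theta_deg must lie in [0, 90], got {self.theta_deg}")

    @classmethod
    def from_k1_mpa(cls, C10: float, k1_mpa: float, k2: float,
                    kappa: float, theta_deg: float) -> "HGOWallParams":
        return cls(C10=C10, k1=k1_mpa * 1000.0, k2=k2,
                   kappa=kappa, theta_deg=theta_deg)


@dataclass(frozen=True)
class LinearWallParams:
    """Orthotropic linearized wall parameters (kPa).

    The single Poisson ratio ``nu`` is interpreted as ``ν_θz``; the reciprocal
    ratio follows from the symmetry relation ``ν_θz/E_θ = ν_zθ/E_z``.
    """

    E_theta: float = 1110.0     # kPa, circumferential modulus
    E_z: float = 3580.0         # kPa, longitudinal modulus
    G: float = 4000.0           # kPa, shear modulus (unused in-plane)
    nu: float = 0.44            # -, Poisson ratio nu_theta_z

    def __post_init__(self):
        for name in ("E_theta", "E_z", "G"):
            if not getattr(self, name) > 0:
                raise MaterialDefinitionError(f"{name} must be > 0")
        if not 0.0 <= self.nu < 0.5:
            raise MaterialDefinitionError(
                f"nu must lie in [0, 0.5), got {self.nu}")
        if 1.0 - self.nu * self.nu_z_theta <= 0.0:
            raise MaterialDefinitionError(
                "non-positive-definite orthotropic reduction: "
                f"1 - nu_theta_z*nu_z_theta = {1.0 - self.nu * self.nu_z_theta:.4g}")

    @property
    def nu_z_theta(self) -> float:
        """Reciprocal Poisson ratio from orthotropic symmetry."""
        return self.nu * self.E_z / self.E_theta

    @property
    def hoop_modulus(self) -> float:
        """Effective circumferential modulus under ε_z = 0 and zero
        through-thickness stress: ``E_θ / (1 − ν_θz ν_zθ)``."""
        return self.E_theta / (1.0 - self.nu * self.nu_z_theta)


@dataclass(frozen=True)
class TissueParams:
    """Nearly incompressible neo-Hookean surrounding tissue.

    ``bulk_penalty`` is the volumetric penalty modulus K in
    ``W = (μ/2)(Ī1 − 3) + (K/2)(J − 1)²``.  The default keeps |J−1| below
    1e-3 under the firmest probe load without ill-conditioning the tangent.
    """

    mu: float = 5.0                     # kPa, shear modulus
    bulk_penalty: float | None = None   # kPa; default max(1000*mu, 6e4)

    def __post_init__(self):
        if not self.mu > 0:
            raise MaterialDefinitionError(f"mu must be > 0, got {self.mu}")
        if self.bulk_penalty is None:
            object.__setattr__(self, "bulk_penalty",
                               max(1000.0 * self.mu, 6.0e4))
        if self.bulk_penalty < 100.0 * self.mu:
            raise MaterialDefinitionError(
                "bulk_penalty must be >= 100*mu for near-incompressibility")


@dataclass
class MembraneState:
    """State of one wall membrane element."""

    lambda_circ: float
    lambda_z: float = 1.0
    sigma_circ: float = 0.0      # kPa
    thickness_current: float = 0.0  # mm

    @classmethod
    def from_stretch(cls, lambda_circ: float, t_ref: float,
                     sigma_circ: float = 0.0,
                     lambda_z: float = 1.0) -> "MembraneState":
        if lambda_circ <= 0:
            raise StretchRangeError("lambda_circ must be > 0", lambda_circ)
        # incompressible wall: thickness stretch = 1/(lambda_circ*lambda_z)
        return cls(lambda_circ=lambda_circ, lambda_z=lambda_z,
                   sigma_circ=sigma_circ,
                   thickness_current=t_ref / (lambda_circ * lambda_z))


def hgo_membrane_response(lambda_circ, lambda_z: float = 1.0,
                          p: HGOWallParams | None = None):
    """Circumferential Cauchy stress and tangent of the HGO membrane.

    The energy is the Gasser dispersion form

        Ψ = C10 (I1 − 3) + (k1 / 2 k2) Σ_{i=4,6} [exp(k2 E_i²) − 1],
        E_i = κ (I1 − 3) + (1 − 3κ)(I4i − 1),

    with incompressibility eliminating the through-thickness stretch
    (λ_t = 1/(λ_circ λ_z)) and zero through-thickness stress.  Fibers only
    contribute in tension (E_i > 0).  Both symmetric families at ±θ share the
    same pseudo-invariant, hence the single doubled term.

    Parameters
    ----------
    lambda_circ : float or ndarray
        Circumferential stretch ratio(s), > 0.
    lambda_z : float
        Axial stretch (1 in the cross-sectional reduction).
    p : HGOWallParams

    Returns
    -------
    (sigma_circ, dsigma_dlambda) : kPa, each shaped like ``lambda_circ``.
    """
    if p is None:
        p = HGOWallParams()
    lam = np.asarray(lambda_circ, dtype=float)
    if np.any(lam <= 0) or lambda_z <= 0:
        raise StretchRangeError("stretch out of admissible range",
                                float(np.min(lam)))
    lz2 = lambda_z * lambda_z
    lam2 = lam * lam
    lt2 = 1.0 / (lam2 * lz2)            # squared thickness stretch
    I1 = lam2 + lz2 + lt2
    dI1 = 2.0 * lam - 2.0 / (lam2 * lam * lz2)
    d2I1 = 2.0 + 6.0 / (lam2 * lam2 * lz2)

    theta = np.deg2rad(p.theta_deg)
    c2, s2 = np.cos(theta) ** 2, np.sin(theta) ** 2
    I4 = lam2 * c2 + lz2 * s2
    dI4 = 2.0 * lam * c2
    d2I4 = 2.0 * c2

    kap, onem3k = p.kappa, 1.0 - 3.0 * p.kappa
    E = kap * (I1 - 3.0) + onem3k * (I4 - 1.0)
    dE = kap * dI1 + onem3k * dI4
    d2E = kap * d2I1 + onem3k * d2I4

    arg = p.k2 * E * E
    if np.any(arg > _EXP_ARG_MAX):
        bad = lam if lam.ndim == 0 else lam[np.argmax(arg)]
        raise StretchRangeError(
            f"stretch out of admissible range (exp overflow at lambda={float(bad):.4g})",
            float(bad))
    active = E > 0.0                    # tension-only fiber switch
    expf = np.where(active, np.exp(np.where(active, arg, 0.0)), 0.0)

    dpsi = p.C10 * dI1 + 2.0 * p.k1 * np.where(active, E, 0.0) * expf * dE
    d2psi = p.C10 * d2I1 + 2.0 * p.k1 * expf * np.where(
        active,
        (1.0 + 2.0 * p.k2 * E * E) * dE * dE + E * d2E,
        0.0,
    )
    sigma = lam * dpsi
    dsigma = dpsi + lam * d2psi
    if lam.ndim == 0:
        return float(sigma), float(dsigma)
    return sigma, dsigma


def linear_membrane_response(eps_circ, p: LinearWallParams | None = None):
    """Hoop stress of the linearized orthotropic wall membrane.

    Under ε_z = 0 and zero through-thickness stress the law reduces to
    ``σ_circ = C_eff · ε_circ`` with constant ``C_eff = E_θ/(1 − ν_θz ν_zθ)``.

    Returns ``(sigma_circ, modulus)`` in kPa.
    """
    if p is None:
        p = LinearWallParams()
    eps = np.asarray(eps_circ, dtype=float)
    if np.any(np.abs(eps) >= 0.5):
        raise StretchRangeError("strain magnitude >= 0.5 outside linear range",
                                float(1.0 + np.max(np.abs(eps))))
    c_eff = p.hoop_modulus
    sigma = c_eff * eps
    if eps.ndim == 0:
        return float(sigma), c_eff
    return sigma, np.full_like(eps, c_eff)


# ---------------------------------------------------------------------------
# Wall material adapters used by the solver: membrane tension per unit axial
# depth N(λ) = σ(λ) · t(λ) and its derivative.  A thin arterial wall wrinkles
# rather than supports circumferential compression, so by default the
# membranes are tension-field ("slack") elements: for λ < 1 the carried
# tension is scaled down smoothly to a small residual fraction, which also
# removes the destabilizing negative geometric stiffness of a compressed
# ring.  Set ``compression="elastic"`` to keep the full elastic response.
# ---------------------------------------------------------------------------

_SLACK_RESIDUAL = 0.05       # residual compressive-load fraction when slack
_SLACK_BAND = 0.02           # smooth blend over λ in [1 - band, 1]


def _slack_scale(lam):
    """Smooth Hermite blend 1 → residual across λ ∈ [1-band, 1]; returns
    (g, dg/dλ)."""
    lam = np.asarray(lam, dtype=float)
    s = np.clip((lam - (1.0 - _SLACK_BAND)) / _SLACK_BAND, 0.0, 1.0)
    h = s * s * (3.0 - 2.0 * s)
    dh = np.where((s > 0.0) & (s < 1.0), 6.0 * s * (1.0 - s) / _SLACK_BAND,
                  0.0)
    g = _SLACK_RESIDUAL + (1.0 - _SLACK_RESIDUAL) * h
    dg = (1.0 - _SLACK_RESIDUAL) * dh
    return g, dg


def _apply_compression_model(lam, n, dn, mode):
    if mode == "elastic":
        return n, dn
    g, dg = _slack_scale(lam)
    return g * n, g * dn + dg * n


@dataclass(frozen=True)
class HGOWall:
    """HGO wall as seen by the solver: tension from reference thickness.

    Incompressible membrane, λ_z = 1, so current thickness is t_ref/λ.
    """

    params: HGOWallParams = field(default_factory=HGOWallParams)
    thickness: float = 2.0      # mm, reference wall thickness
    compression: str = "slack"  # "slack" (tension-field) or "elastic"
    name = "hgo"

    def stress(self, lam):
        """Carried circumferential Cauchy stress and tangent (kPa)."""
        sig, dsig = hgo_membrane_response(lam, 1.0, self.params)
        return _apply_compression_model(lam, sig, dsig, self.compression)

    def tension(self, lam):
        """N(λ) = σ(λ) t_ref/λ and dN/dλ, per unit axial depth (kPa·mm)."""
        sig, dsig = hgo_membrane_response(lam, 1.0, self.params)
        t = self.thickness
        n = sig * t / lam
        dn = t * (dsig / lam - sig / (lam * lam))
        return _apply_compression_model(lam, n, dn, self.compression)


@dataclass(frozen=True)
class LinearWall:
    """Linearized wall: constant hoop modulus, small-strain thickness."""

    params: LinearWallParams = field(default_factory=LinearWallParams)
    thickness: float = 2.0
    compression: str = "slack"
    name = "linear"

    def stress(self, lam):
        lam = np.asarray(lam, dtype=float)
        sig, mod = linear_membrane_response(lam - 1.0, self.params)
        mod = np.broadcast_to(mod, np.shape(sig)) if np.ndim(sig) else mod
        return _apply_compression_model(lam, sig, mod, self.compression)

    def tension(self, lam):
        lam = np.asarray(lam, dtype=float)
        sig, mod = linear_membrane_response(lam - 1.0, self.params)
        n = sig * self.thickness
        dn = np.broadcast_to(mod * self.thickness, np.shape(n)) \
            if np.ndim(n) else mod * self.thickness
        return _apply_compression_model(lam, n, dn, self.compression)


# ---------------------------------------------------------------------------
# Plane-strain nearly incompressible neo-Hookean tissue
# ---------------------------------------------------------------------------

def _as_batch(F):
    F = np.asarray(F, dtype=float)
    single = F.ndim == 2
    return (F[None] if single else F), single


def neo_hookean_energy(F, p: TissueParams):
    """Strain energy density W = (μ/2)(Ī1 − 3) + (K/2)(J − 1)², plane strain.

    ``Ī1 = J^{-2/3} I1`` with the 3D first invariant ``I1 = tr(C) + 1``
    (unit out-of-plane stretch).  Accepts a single 2×2 ``F`` or a batch
    (n, 2, 2).
    """
    Fb, single = _as_batch(F)
    J = Fb[:, 0, 0] * Fb[:, 1, 1] - Fb[:, 0, 1] * Fb[:, 1, 0]
    I1 = np.einsum("nij,nij->n", Fb, Fb) + 1.0
    W = 0.5 * p.mu * (J ** (-2.0 / 3.0) * I1 - 3.0) \
        + 0.5 * p.bulk_penalty * (J - 1.0) ** 2
    return float(W[0]) if single else W


def neo_hookean_pk1(F, p: TissueParams, tangent: bool = True):
    """First Piola–Kirchhoff stress P = ∂W/∂F and tangent A = ∂P/∂F.

    Vectorized over a batch of deformation gradients (n, 2, 2); also accepts
    a single 2×2 array.  Raises :class:`ElementInversionError` if any
    det(F) ≤ 0.
    """
    from .errors import ElementInversionError

    Fb, single = _as_batch(F)
    n = Fb.shape[0]
    J = Fb[:, 0, 0] * Fb[:, 1, 1] - Fb[:, 0, 1] * Fb[:, 1, 0]
    if np.any(J <= 0.0):
        raise ElementInversionError(
            "element inversion: det(F) <= 0",
            element=int(np.argmax(J <= 0.0)))
    I1 = np.einsum("nij,nij->n", Fb, Fb) + 1.0

    # inverse transpose of a 2x2
    Fit = np.empty_like(Fb)
    Fit[:, 0, 0] = Fb[:, 1, 1]
    Fit[:, 0, 1] = -Fb[:, 1, 0]
    Fit[:, 1, 0] = -Fb[:, 0, 1]
    Fit[:, 1, 1] = Fb[:, 0, 0]
    Fit /= J[:, None, None]

    mu, K = p.mu, p.bulk_penalty
    Jm23 = J ** (-2.0 / 3.0)
    P = (mu * Jm23[:, None, None] * (Fb - (I1 / 3.0)[:, None, None] * Fit)
         + (K * (J - 1.0) * J)[:, None, None] * Fit)
    if not tangent:
        return (P[0] if single else P)

    # A_{iJkL} = dP_{iJ}/dF_{kL}
    I2 = np.eye(2)
    # dFit_{iJ}/dF_{kL} = -Finv_{Jk} Finv_{Li} = -Fit_{kJ} Fit_{iL}
    dFit = -np.einsum("nkJ,niL->niJkL", Fit, Fit)
    A = np.zeros((n, 2, 2, 2, 2))
    # isochoric part
    A += mu * np.einsum(
        "n,nkL,niJ->niJkL", -2.0 / 3.0 * Jm23, Fit,
        Fb - (I1 / 3.0)[:, None, None] * Fit)
    A += mu * Jm23[:, None, None, None, None] * (
        np.einsum("ik,JL->iJkL", I2, I2)[None]
        - (2.0 / 3.0) * np.einsum("nkL,niJ->niJkL", Fb, Fit)
        - (I1 / 3.0)[:, None, None, None, None] * dFit)
    # volumetric part
    A += K * np.einsum("n,nkL,niJ->niJkL", (2.0 * J - 1.0) * J, Fit, Fit)
    A += K * ((J - 1.0) * J)[:, None, None, None, None] * dFit
    if single:
        return P[0], A[0]
    return P, A


def neo_hookean_stress(F, p: TissueParams, tangent: bool = True):
    """Cauchy stress σ = P Fᵀ / J of the plane-strain neo-Hookean tissue.

    Returns ``(sigma, A)`` where ``A = ∂P/∂F`` is the first-elasticity
    (nominal) tangent, or just ``sigma`` with ``tangent=False``.
    """
    Fb, single = _as_batch(F)
    out = neo_hookean_pk1(Fb, p, tangent=tangent)
    P = out[0] if tangent else out
    J = Fb[:, 0, 0] * Fb[:, 1, 1] - Fb[:, 0, 1] * Fb[:, 1, 0]
    sigma = np.einsum("niJ,njJ->nij", P, Fb) / J[:, None, None]
    if single:
        return (sigma[0], out[1][0]) if tangent else sigma[0]
    return (sigma, out[1]) if tangent else sigma
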