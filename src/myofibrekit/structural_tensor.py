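"""Generalized structural tensor of a dispersed fibre family.

With the mean fibre along e3, the sheet along e1 and the sheet-normal along
e2, a unit fibre direction is

    M(Theta, Phi) = (sin Theta cos Phi, sin Theta sin Phi, cos Theta),

and the dispersed density is the product of two pi-periodic von Mises
factors: in-plane rho(Theta; b_in) centred at Theta = 0 and out-of-plane
rho(Phi - pi/2; b_out).  The structural tensor is the density-weighted
spherical average

    H = (1/N) int_0^pi int_0^{2 pi} rho_in rho_op sin(Theta) M (x) M dPhi dTheta,

with N normalizing the weighted integral of 1.  H is symmetric, positive
semi-definite with unit trace; its diagonal entries in the (sheet,
sheet-normal, fibre) axes are the active-tension proportions
(n_s, n_n, n_f).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

from .dispersion import sample_pi_vonmises, vonmises_pdf

__all__ = [
    "SphericalDensity",
    "StructuralTensor",
    "compute_structural_tensor",
    "mc_structural_tensor",
    "active_proportions",
]


@dataclass
class SphericalDensity:
    """Product von Mises density on the sphere with its normalization."""

    b_in: float
    b_out: float
    N: float

    def __call__(self, theta, phi):
        return (
            vonmises_pdf(theta, self.b_in)
            * vonmises_pdf(np.asarray(phi) - np.pi / 2.0, self.b_out)
            / self.N
        )


@dataclass
class StructuralTensor:
    """Symmetric unit-trace tensor H in the (s0, n0, f0) axes."""

    H: np.ndarray
    n_theta: int = 0
    n_phi: int = 0

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float).reshape(3, 3)

    @property
    def n_s(self) -> float:
        return float(self.H[0, 0])

    @property
    def n_n(self) -> float:
        return float(self.H[1, 1])

    @property
    def n_f(self) -> float:
        return float(self.H[2, 2])


def _quad_tensor(b_in: float, b_out: float, n_theta: int, n_phi: int):
    xt, wt = leggauss(n_theta)
    xp, wp = leggauss(n_phi)
    theta = 0.5 * np.pi * (xt + 1.0)
    wtheta = 0.5 * np.pi * wt
    phi = np.pi * (xp + 1.0)
    wphi = np.pi * wp
    T, P = np.meshgrid(theta, phi, indexing="ij")
    W = np.outer(wtheta, wphi)
    dens = (
        vonmises_pdf(T, b_in)
        * vonmises_pdf(P - np.pi / 2.0, b_out)
        * np.sin(T)
    )
    N = float((dens * W).sum())
    M = np.stack(
        [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1
    )
    H = np.einsum("tp,tp,tpi,tpj->ij", dens, W, M, M) / N
    return H, N


def compute_structural_tensor(
    b_in: float,
    b_out: float,
    n_theta: int = 96,
    n_phi: int = 192,
    tol: float = 1e-6,
    max_doublings: int = 6,
) -> StructuralTensor:
    """Structural tensor by tensor-product Gauss-Legendre quadrature.

    The rule is doubled until no component changes by more than ``tol``
    (raises if that never happens within ``max_doublings``).  The
    normalization N is computed with the same rule as H, so the unit trace
    is exact by construction up to round-off.
    """
    if b_in < 0 or b_out < 0:
        raise ValueError("concentrations must be >= 0")
    H, _ = _quad_tensor(b_in, b_out, n_theta, n_phi)
    for _ in range(max_doublings):
        n_theta2, n_phi2 = 2 * n_theta, 2 * n_phi
        H2, _ = _quad_tensor(b_in, b_out, n_theta2, n_phi2)
        if np.abs(H2 - H).max() <= tol:
            return StructuralTensor(H=H2, n_theta=n_theta2, n_phi=n_phi2)
        H, n_theta, n_phi = H2, n_theta2, n_phi2
    raise RuntimeError(
        f"structural-tensor quadrature did not converge to {tol} "
        f"within {max_doublings} doublings (b_in={b_in}, b_out={b_out})"
    )


def mc_structural_tensor(
    b_in: float,
    b_out: float,
    n_samples: int = 10_000_000,
    seed: int = 0,
    chunk: int = 1_000_000,
) -> tuple[StructuralTensor, np.ndarray]:
    """Monte-Carlo estimate of H with per-component standard errors.

    Independent sampling oracle for the quadrature: Theta is drawn from the
    density proportional to rho_in(Theta) sin(Theta) on [0, pi] and Phi from
    rho_op(Phi - pi/2) on [0, 2 pi], both by inverse-CDF table lookup; the
    estimate is the sample mean of M (x) M.  Returns (tensor, SE) where SE
    is the (3, 3) standard error of each component.
    """
    rng = np.random.default_rng(seed)
    # inverse-CDF table for Theta ~ rho_in(Theta) sin(Theta), Theta in [0, pi]
    tgrid = np.linspace(0.0, np.pi, 8193)
    tpdf = vonmises_pdf(tgrid, b_in) * np.sin(tgrid)
    tcdf = np.concatenate([[0.0], np.cumsum(0.5 * (tpdf[1:] + tpdf[:-1]) * np.diff(tgrid))])
    tcdf /= tcdf[-1]
    s1 = np.zeros((3, 3))
    s2 = np.zeros((3, 3))
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        theta = np.interp(rng.uniform(size=m), tcdf, tgrid)
        # Phi: pi/2 plus an axial von Mises deviation, antipodal branch at random
        phi = np.pi / 2.0 + sample_pi_vonmises(b_out, m, rng)
        phi = phi + np.pi * rng.integers(0, 2, size=m)
        M = np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        outer = np.einsum("ki,kj->kij", M, M)
        s1 += outer.sum(axis=0)
        s2 += (outer**2).sum(axis=0)
        done += m
    mean = s1 / n_samples
    var = s2 / n_samples - mean**2
    se = np.sqrt(np.maximum(var, 0.0) / n_samples)
    return StructuralTensor(H=mean), se


def active_proportions(H: StructuralTensor) -> tuple[float, float, float]:
    """(n_f, n_s, n_n) = (H33, H11, H22); they sum to trace(H) = 1."""
    return H.n_f, H.n_s, H.n_n
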