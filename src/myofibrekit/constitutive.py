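"""Myocardial constitutive laws at a material point.

Passive response: a reduced Holzapfel-Ogden strain-energy function with an
isotropic exponential matrix term, fibre and sheet-normal ``I4`` terms
(tension-only, via ``max(I4, 1)``), two coupling-invariant shear terms and
a volumetric penalty,

    Psi_dev = a/(2b) exp[b (I1b - 3)]
            + sum_{i=f,n}   a_i/(2 b_i) {exp[b_i (max(I4i_b, 1) - 1)^2] - 1}
            + sum_{ij=fs,fn} a_ij/(2 b_ij) [exp(b_ij I8ij_b^2) - 1]
    Psi_vol = (1/D) ((J^2 - 1)/2 - ln J),

where the bar marks isochoric invariants of ``C_bar = F_bar^T F_bar`` with
``F_bar = J^(-1/3) F`` and ``D = 2/K`` (K the bulk modulus).  The Cauchy
stress follows the standard decoupled form with deviatoric projections of
the pushed-forward structure tensors.

Active response: a time-varying elastance gives the fibre tension

    Ta(t, l) = (Tmax/2) Ca0^2/(Ca0^2 + ECa50(l)^2) (1 - cos omega(t, l)),

with length-dependent calcium sensitivity
``ECa50(l) = Ca0max / sqrt(exp(B (l - l0)) - 1)`` and phase
``omega = pi t/t0`` during activation, ``pi (t - t0 + tr)/tr`` with
``tr = m l + b_t`` during relaxation, and 0 otherwise; ``l`` is the
sarcomere length ``lr sqrt(I4f)``.  The dispersed active Cauchy stress
distributes Ta over the deformed fibre / sheet / sheet-normal dyads with
proportions (n_f, n_s, n_n).

All stress routines broadcast over leading batch dimensions of ``F``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PassiveParams",
    "ActiveParams",
    "DeformationState",
    "passive_cauchy_stress",
    "strain_energy",
    "active_tension",
    "active_cauchy_stress",
]

KPA_PER_MMHG = 0.1333224  # 1 mmHg in kPa
MMHG_PER_KPA = 7.5006168


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class PassiveParams:
    """Reduced Holzapfel-Ogden constants (kPa / unitless) and D = 2/K (kPa^-1).

    ``a_scale`` multiplies all stress-like constants (a, a_f, a_n, a_fs,
    a_fn); it exposes the global passive scaling used when matching *in
    vivo* compliance from *ex vivo* fits, default 1 (table values as given).
    """

    a: float
    b: float
    a_f: float
    b_f: float
    a_n: float
    b_n: float
    a_fs: float
    b_fs: float
    a_fn: float
    b_fn: float
    D: float = 2.0e-3  # kPa^-1, i.e. bulk modulus K = 1000 kPa
    a_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "a_f", "b_f", "a_n", "b_n",
                     "a_fs", "b_fs", "a_fn", "b_fn", "D", "a_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"passive parameter {name} must be > 0")

    def scaled(self) -> "PassiveParams":
        if self.a_scale == 1.0:
            return self
        return replace(
            self,
            a=self.a * self.a_scale, a_f=self.a_f * self.a_scale,
            a_n=self.a_n * self.a_scale, a_fs=self.a_fs * self.a_scale,
            a_fn=self.a_fn * self.a_scale, a_scale=1.0,
        )

    @classmethod
    def lv(cls, **overrides) -> "PassiveParams":
        """Left-ventricular myocardium fit (neonatal porcine)."""
        p = dict(a=0.0381, b=8.143, a_f=3.533, b_f=51.339, a_n=1.373, b_n=4.495,
                 a_fs=0.929, b_fs=4.067, a_fn=1.771, b_fn=8.225)
        p.update(overrides)
        return cls(**p)

    @classmethod
    def rv(cls, **overrides) -> "PassiveParams":
        """Right-ventricular myocardium fit (neonatal porcine)."""
        p = dict(a=0.485, b=7.513, a_f=2.777, b_f=1.685, a_n=0.704, b_n=9.407,
                 a_fs=0.121, b_fs=15.314, a_fn=1.351, b_fn=17.235)
        p.update(overrides)
        return cls(**p)


@dataclass
class ActiveParams:
    """Time-varying elastance constants.

    Units: kPa (Tmax), uM (calcium), um (lengths), ms (times),
    ms/um and ms (relaxation-duration slope/intercept).  ``proportions``
    are (n_f, n_s, n_n); they must be non-negative and, when
    ``normalized_proportions`` is set (the dispersed-tensor mode), sum to 1.
    """

    T_max: float = 180.0
    Ca0: float = 4.35
    Ca0max: float = 4.35
    B: float = 4.75
    l0_len: float = 1.58
    lr: float = 1.85
    t0: float = 150.0
    m: float = 1048.9
    b_t: float = -1629.0
    proportions: tuple = (1.0, 0.0, 0.0)
    normalized_proportions: bool = False

    def __post_init__(self) -> None:
        if self.T_max < 0:
            raise ValueError("T_max must be >= 0")
        if min(self.proportions) < 0:
            raise ValueError("active proportions must be >= 0")
        if self.normalized_proportions and abs(sum(self.proportions) - 1.0) > 1e-8:
            raise ValueError("normalized proportions must sum to 1")
        if self.t0 <= 0 or self.lr <= 0 or self.Ca0 <= 0 or self.Ca0max <= 0:
            raise ValueError("t0, lr, Ca0, Ca0max must be > 0")

    @classmethod
    def lv(cls, **overrides) -> "ActiveParams":
        return cls(**{"T_max": 180.0, **overrides})

    @classmethod
    def rv(cls, **overrides) -> "ActiveParams":
        return cls(**{"T_max": 135.0, **overrides})


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

def _dot(a, b):
    return np.einsum("...i,...i->...", a, b)


@dataclass
class DeformationState:
    """Deformation gradient with its isochoric invariants and deformed triad."""

    F: np.ndarray
    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray
    J: np.ndarray = field(init=False)
    Fbar: np.ndarray = field(init=False)
    bbar: np.ndarray = field(init=False)
    I1: np.ndarray = field(init=False)
    I4f: np.ndarray = field(init=False)
    I4n: np.ndarray = field(init=False)
    I8fs: np.ndarray = field(init=False)
    I8fn: np.ndarray = field(init=False)
    fbar: np.ndarray = field(init=False)
    sbar: np.ndarray = field(init=False)
    nbar: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        self.F = F
        self.J = np.linalg.det(F)
        if np.any(self.J <= 0):
            raise ValueError("det F must be positive")
        self.Fbar = F * self.J[..., None, None] ** (-1.0 / 3.0)
        self.bbar = np.einsum("...ik,...jk->...ij", self.Fbar, self.Fbar)
        Cbar = np.einsum("...ki,...kj->...ij", self.Fbar, self.Fbar)
        self.I1 = np.einsum("...ii->...", Cbar)
        f0 = np.asarray(self.f0, dtype=float)
        s0 = np.asarray(self.s0, dtype=float)
        n0 = np.asarray(self.n0, dtype=float)
        self.fbar = np.einsum("...ij,...j->...i", self.Fbar, f0)
        self.sbar = np.einsum("...ij,...j->...i", self.Fbar, s0)
        self.nbar = np.einsum("...ij,...j->...i", self.Fbar, n0)
        self.I4f = _dot(self.fbar, self.fbar)
        self.I4n = _dot(self.nbar, self.nbar)
        self.I8fs = _dot(self.fbar, self.sbar)
        self.I8fn = _dot(self.fbar, self.nbar)


def _dev(t: np.ndarray) -> np.ndarray:
    tr = np.einsum("...ii->...", t)
    return t - tr[..., None, None] * np.eye(3) / 3.0


def _outer_sym(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 0.5 * (
        np.einsum("...i,...j->...ij", a, b) + np.einsum("...i,...j->...ij", b, a)
    )


# --------------------------------------------------------------------------
# passive law
# --------------------------------------------------------------------------

def strain_energy(state: DeformationState, params: PassiveParams) -> np.ndarray:
    """Total strain energy Psi_dev + Psi_vol (kPa)."""
    p = params.scaled()
    I4f = np.maximum(state.I4f, 1.0)
    I4n = np.maximum(state.I4n, 1.0)
    psi = p.a / (2.0 * p.b) * np.exp(p.b * (state.I1 - 3.0))
    psi = psi + p.a_f / (2.0 * p.b_f) * (np.exp(p.b_f * (I4f - 1.0) ** 2) - 1.0)
    psi = psi + p.a_n / (2.0 * p.b_n) * (np.exp(p.b_n * (I4n - 1.0) ** 2) - 1.0)
    psi = psi + p.a_fs / (2.0 * p.b_fs) * (np.exp(p.b_fs * state.I8fs**2) - 1.0)
    psi = psi + p.a_fn / (2.0 * p.b_fn) * (np.exp(p.b_fn * state.I8fn**2) - 1.0)
    J = state.J
    return psi + (1.0 / p.D) * ((J**2 - 1.0) / 2.0 - np.log(J))


def passive_cauchy_stress(state: DeformationState, params: PassiveParams) -> np.ndarray:
    """Passive Cauchy stress (kPa), symmetric, broadcast over batches.

    The fibre and sheet-normal terms switch off in compression (I4 < 1);
    the volumetric pressure is p_vol = (1/D)(J - 1/J).
    """
    p = params.scaled()
    I4f = np.maximum(state.I4f, 1.0)
    I4n = np.maximum(state.I4n, 1.0)
    psi1 = p.a / 2.0 * np.exp(p.b * (state.I1 - 3.0))
    psi4f = p.a_f * (I4f - 1.0) * np.exp(p.b_f * (I4f - 1.0) ** 2)
    psi4n = p.a_n * (I4n - 1.0) * np.exp(p.b_n * (I4n - 1.0) ** 2)
    psi8fs = p.a_fs * state.I8fs * np.exp(p.b_fs * state.I8fs**2)
    psi8fn = p.a_fn * state.I8fn * np.exp(p.b_fn * state.I8fn**2)
    pvol = (1.0 / p.D) * (state.J - 1.0 / state.J)

    s = psi1[..., None, None] * _dev(state.bbar)
    s = s + psi4f[..., None, None] * _dev(
        np.einsum("...i,...j->...ij", state.fbar, state.fbar)
    )
    s = s + psi4n[..., None, None] * _dev(
        np.einsum("...i,...j->...ij", state.nbar, state.nbar)
    )
    s = s + psi8fs[..., None, None] * _dev(_outer_sym(state.fbar, state.sbar))
    s = s + psi8fn[..., None, None] * _dev(_outer_sym(state.fbar, state.nbar))
    return pvol[..., None, None] * np.eye(3) + 2.0 / state.J[..., None, None] * s


# --------------------------------------------------------------------------
# active law
# --------------------------------------------------------------------------

def active_tension(t, l, params: ActiveParams):
    """Elastance active tension Ta(t, l) in kPa; broadcasts over t and l.

    ``t`` in ms from activation onset, ``l`` the sarcomere length in um.
    Zero before onset, after relaxation completes, and at or below the
    zero-tension length ``l0_len``.
    """
    t = np.asarray(t, dtype=float)
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValueError("sarcomere length must be positive")
    t, l = np.broadcast_arrays(t, l)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    l = np.atleast_1d(l)
    above = l > params.l0_len
    denom = np.sqrt(np.maximum(np.exp(params.B * (l - params.l0_len)) - 1.0, 1e-300))
    eca50 = params.Ca0max / denom
    ca_frac = params.Ca0**2 / (params.Ca0**2 + eca50**2)
    tr = np.maximum(params.m * l + params.b_t, 0.0)
    omega = np.zeros_like(t)
    act = (t >= 0) & (t < params.t0)
    omega[act] = np.pi * t[act] / params.t0
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = (t >= params.t0) & (t < params.t0 + tr) & (tr > 0)
        omega[rel] = np.pi * (t[rel] - params.t0 + tr[rel]) / tr[rel]
    ta = 0.5 * params.T_max * ca_frac * (1.0 - np.cos(omega))
    ta = np.where(above, ta, 0.0)
    return float(ta[0]) if scalar else ta


def sarcomere_length(I4f, params: ActiveParams):
    """l = lr * sqrt(I4f): slack length scaled by the fibre stretch."""
    return params.lr * np.sqrt(np.asarray(I4f, dtype=float))


def active_cauchy_stress(T_a, state: DeformationState, proportions) -> np.ndarray:
    """Dispersed active Cauchy stress (kPa).

    sigma_a = Ta (n_f fhat (x) fhat + n_s shat (x) shat + n_n nhat (x) nhat)
    with the deformed, normalized directions.  When the proportions sum to
    one, trace(sigma_a) = Ta exactly.
    """
    n_f, n_s, n_n = proportions
    if min(n_f, n_s, n_n) < 0:
        raise ValueError("active proportions must be >= 0")
    T_a = np.asarray(T_a, dtype=float)
    out = np.zeros(state.F.shape)
    for w, v in ((n_f, state.fbar), (n_s, state.sbar), (n_n, state.nbar)):
        nrm2 = _dot(v, v)
        if np.any(nrm2 <= 0):
            raise ValueError("zero-length deformed direction")
        out = out + w * np.einsum("...i,...j->...ij", v, v) / nrm2[..., None, None]
    return T_a[..., None, None] * out
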