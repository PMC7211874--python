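"""Desk-scale cardiac-cycle simulation.

A lumped circulatory network (two-element-Windkessel-equivalent: viscous
flow resistances between fluid cavities, compliant aorta / pulmonary
artery, atria held at constant end-diastolic pressure, one-way valves)
is coupled to reduced-order ventricles: thick-walled incompressible
spheres whose wall stress comes from the full passive + dispersed-active
constitutive law, evaluated at transmural quadrature points with the local
fibre triad (fibre tangential at its rule-based rotation angle, sheet
radial).

On a sphere the tangential stretch is equibiaxial, so the in-plane fibre
rotation angle is mechanically inert; the model deliberately isolates what
the dispersion proportions (n_f, n_s, n_n) and the circulation do to pump
function, and makes no claim about twist or regional mechanics.  Cavity
pressure follows from the spherical equilibrium integral

    P = int_{r_i}^{r_o} 2 (sigma_tangential - sigma_radial) / r dr

with incompressible kinematics r^3 - r_i^3 = R^3 - R_i^3, so pressure is
an explicit function of cavity volume and time and the volume ODEs of the
closed loop can be integrated explicitly.

Internal units: pressures mmHg and volumes ml at every interface; the
viscous coefficients of the fluid-exchange formulation are kept in the
mm-tonne-s-MPa system and converted through a single calibrated linear
factor (equivalently, a blood density and effective exchange area).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

from .constitutive import (
    MMHG_PER_KPA,
    ActiveParams,
    DeformationState,
    PassiveParams,
    active_cauchy_stress,
    active_tension,
    passive_cauchy_stress,
    sarcomere_length,
)

__all__ = [
    "CirculationParams",
    "SphericalVentricle",
    "CycleResult",
    "connection_flow",
    "windkessel_equivalents",
    "equilibrium_pressure",
    "run_cycle",
    "default_lv",
    "default_rv",
]


# --------------------------------------------------------------------------
# circulation parameters
# --------------------------------------------------------------------------

#: Viscous resistance coefficients of the fluid exchanges, MPa mm^2 s / tonne.
DEFAULT_CV = {
    "AV": 20.0, "MV": 50.0, "PV": 55.0, "TV": 16.0, "Sys": 3600.0, "Pul": 300.0,
}

#: Which connections carry a one-way valve (forward direction only).
VALVED = frozenset({"AV", "MV", "PV", "TV"})


@dataclass
class CirculationParams:
    """Lumped circulation: exchange coefficients, compliances, atrial sources.

    ``cv`` holds the viscous coefficients C_V (MPa mm^2 s / tonne) per
    connection; ``calibration`` is one printed (connection, R) pair pinning
    the linear C_V -> R conversion.  ``c_ao`` / ``c_pa`` are the aortic and
    pulmonary-artery compliances (ml/mmHg, from the grounded-spring
    stiffnesses); the atria are ideal pressure sources at the end-diastolic
    pressures ``p_la`` / ``p_ra`` (their compliance is whatever keeps those
    pressures constant).  ``c_h`` is the hydrodynamic coefficient, zero here.
    """

    cv: dict = field(default_factory=lambda: dict(DEFAULT_CV))
    calibration: tuple = ("AV", 0.150)            # (connection, mmHg s / ml)
    c_ao: float = 0.061                           # ml / mmHg
    c_pa: float = 0.065
    p_la: float = 8.0                             # mmHg, constant
    p_ra: float = 4.0
    p_ao0: float = 67.5                           # initial (diastolic) pressures
    p_pa0: float = 10.0
    rho_blood: float = 1.055e-9                   # tonne / mm^3
    c_h: float = 0.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.cv.values()):
            raise ValueError("viscous coefficients must be > 0")
        if self.c_h != 0.0:
            raise ValueError("hydrodynamic coefficient C_H must be 0 in this model")
        if self.rho_blood <= 0:
            raise ValueError("blood density must be > 0")

    # -- unit conversion ----------------------------------------------------

    @property
    def conversion_factor(self) -> float:
        """(mmHg s/ml) per (MPa mm^2 s/tonne), from the calibration pair."""
        name, r_cal = self.calibration
        cv_cal = self.cv[name]
        if cv_cal == 0:
            raise ValueError("calibration C_V must be non-zero")
        return r_cal / cv_cal

    @property
    def effective_area(self) -> float:
        """Exchange area A (mm^2) that realizes the calibrated conversion.

        R [mmHg s/ml] = C_V * rho_blood / A * (7.5006e6 mmHg mm^3 / MPa ml),
        so A = 7.5006e6 * rho_blood / factor.
        """
        return 7.5006168e6 * self.rho_blood / self.conversion_factor

    def resistances(self) -> dict:
        """Windkessel-equivalent resistances R (mmHg s/ml) per connection."""
        f = self.conversion_factor
        return {k: v * f for k, v in self.cv.items()}


def windkessel_equivalents(
    params: CirculationParams, calibration_pair: tuple | None = None
) -> dict:
    """R (mmHg s/ml) for every connection from one printed calibration pair.

    The single linear factor R_cal / C_V,cal is applied to all C_V values;
    the factor is also reported as the physical blood-density/area
    conversion it corresponds to.
    """
    p = params if calibration_pair is None else replace(params, calibration=calibration_pair)
    return {
        "R": p.resistances(),
        "factor_mmHg_s_per_ml_per_CV": p.conversion_factor,
        "effective_area_mm2": p.effective_area,
        "rho_blood_tonne_per_mm3": p.rho_blood,
    }


def connection_flow(
    dp_mmHg: float,
    c_v: float,
    area_mm2: float,
    valve: bool = False,
) -> float:
    """Mass flow rate (tonne/s) through one fluid exchange.

    dp * A = C_V * mdot with C_H = 0; valved connections clip reverse flow
    to zero (diode behaviour).
    """
    if c_v <= 0 or area_mm2 <= 0:
        raise ValueError("C_V and area must be > 0")
    dp_mpa = dp_mmHg / (MMHG_PER_KPA * 1000.0)
    if valve and dp_mpa <= 0.0:
        return 0.0
    return dp_mpa * area_mm2 / c_v


# --------------------------------------------------------------------------
# reduced-order ventricle
# --------------------------------------------------------------------------

@dataclass
class SphericalVentricle:
    """Thick-walled incompressible spherical ventricle.

    ``r_inner`` / ``r_outer`` are the stress-free reference radii (mm);
    the wall volume is constant over the cycle by the incompressible
    kinematics.  The fibre rotation angle varies linearly endo->epi between
    ``theta_endo`` / ``theta_epi`` (degrees) in the tangent plane, the sheet
    is radial, and the active tension is distributed with
    ``active.proportions`` = (n_f, n_s, n_n).
    """

    r_inner: float
    r_outer: float
    passive: PassiveParams
    active: ActiveParams
    theta_endo: float = 40.0
    theta_epi: float = -30.0
    n_quad: int = 5

    def __post_init__(self) -> None:
        if not (self.r_outer > self.r_inner > 0):
            raise ValueError("require r_outer > r_inner > 0")
        if self.n_quad < 2:
            raise ValueError("need at least 2 transmural quadrature points")
        x, w = leggauss(self.n_quad)
        self._Rq = 0.5 * (self.r_outer - self.r_inner) * (x + 1.0) + self.r_inner
        self._wq = 0.5 * (self.r_outer - self.r_inner) * w
        ebar = (self._Rq - self.r_inner) / (self.r_outer - self.r_inner)
        theta = np.radians(self.theta_endo + ebar * (self.theta_epi - self.theta_endo))
        # local basis: e1 radial (sheet), e2/e3 tangential; fibre in-plane
        z = np.zeros_like(theta)
        self._f0 = np.column_stack([z, np.sin(theta), np.cos(theta)])
        self._s0 = np.column_stack([np.ones_like(theta), z, z])
        self._n0 = np.cross(self._f0, self._s0)

    @property
    def reference_cavity_volume_ml(self) -> float:
        return 4.0 / 3.0 * np.pi * self.r_inner**3 / 1000.0

    @property
    def wall_volume_ml(self) -> float:
        return 4.0 / 3.0 * np.pi * (self.r_outer**3 - self.r_inner**3) / 1000.0

    # -- mechanics ----------------------------------------------------------

    def pressure(self, volume_ml: float, t_ms: float) -> float:
        return equilibrium_pressure(self, volume_ml, t_ms)

    def end_diastolic_volume(self, edp_mmHg: float) -> float:
        """Cavity volume (ml) at which the passive pressure equals ``edp``."""
        v0 = self.reference_cavity_volume_ml
        lo, hi = v0 * (1.0 + 1e-9), v0 * 8.0
        f = lambda v: equilibrium_pressure(self, v, t_ms=-1.0) - edp_mmHg
        if f(hi) < 0:
            raise ValueError("end-diastolic pressure unreachable below 8 x V_ref")
        return float(brentq(f, lo, hi, xtol=1e-10))


def equilibrium_pressure(
    ventricle: SphericalVentricle, cavity_volume_ml: float, t_ms: float
) -> float:
    """Cavity pressure (mmHg) of the thick-walled sphere at time ``t_ms``.

    Integrates 2 (sigma_tangential - sigma_radial)/r over the deformed wall
    at the ventricle's transmural quadrature points, with incompressible
    spherical kinematics mapping reference radius R to
    r = (R^3 + r_i^3 - R_i^3)^(1/3).  ``t_ms < 0`` means "passive only".
    """
    v_mm3 = cavity_volume_ml * 1000.0
    if v_mm3 <= 0.0:
        raise ValueError("cavity volume must be positive")
    ri3 = 3.0 * v_mm3 / (4.0 * np.pi)
    R = ventricle._Rq
    r3 = R**3 + ri3 - ventricle.r_inner**3
    if np.any(r3 <= 0.0):
        raise ValueError("cavity volume implies non-positive wall radius")
    r = np.cbrt(r3)
    lam = r / R
    F = np.zeros((ventricle.n_quad, 3, 3))
    F[:, 0, 0] = lam**-2
    F[:, 1, 1] = lam
    F[:, 2, 2] = lam
    state = DeformationState(F=F, f0=ventricle._f0, s0=ventricle._s0, n0=ventricle._n0)
    sigma = passive_cauchy_stress(state, ventricle.passive)
    if t_ms >= 0.0 and ventricle.active.T_max > 0.0:
        l = sarcomere_length(state.I4f, ventricle.active)
        ta = active_tension(t_ms, l, ventricle.active)
        n_f, n_s, n_n = ventricle.active.proportions
        sigma = sigma + active_cauchy_stress(ta, state, (n_f, n_s, n_n))
    dtang = 0.5 * (sigma[:, 1, 1] + sigma[:, 2, 2]) - sigma[:, 0, 0]
    # dr = (R/r)^2 dR under the incompressible map
    p_kpa = float(np.sum(ventricle._wq * 2.0 * dtang / r * (R / r) ** 2))
    return p_kpa * MMHG_PER_KPA


# --------------------------------------------------------------------------
# defaults: neonatal-scale ventricles
# --------------------------------------------------------------------------

def default_lv(**overrides) -> SphericalVentricle:
    """Neonatal-scale LV: reference radii chosen so that passive inflation
    to the 8 mmHg end-diastolic pressure gives a cavity volume near 2.85 ml."""
    kw = dict(
        r_inner=8.05,
        r_outer=11.55,
        passive=PassiveParams.lv(),
        active=ActiveParams.lv(t0=120.0),
        theta_endo=40.0,
        theta_epi=-30.0,
    )
    kw.update(overrides)
    return SphericalVentricle(**kw)


def default_rv(**overrides) -> SphericalVentricle:
    """Neonatal-scale RV: thinner wall, 4 mmHg end-diastolic pressure,
    cavity volume near 1.95 ml at end diastole."""
    kw = dict(
        r_inner=6.9,
        r_outer=8.9,
        passive=PassiveParams.rv(),
        active=ActiveParams.rv(t0=120.0),
        theta_endo=40.0,
        theta_epi=-30.0,
    )
    kw.update(overrides)
    return SphericalVentricle(**kw)


# --------------------------------------------------------------------------
# cycle integration
# --------------------------------------------------------------------------

@dataclass
class CycleResult:
    """Time series of the closed loop plus pressure-volume summaries."""

    time_ms: np.ndarray
    p_lv: np.ndarray
    v_lv: np.ndarray
    p_rv: np.ndarray
    v_rv: np.ndarray
    p_ao: np.ndarray
    p_pa: np.ndarray
    total_volume_ml: np.ndarray
    t_cycle_ms: float

    def _last_cycle(self) -> np.ndarray:
        t_end = self.time_ms[-1]
        return self.time_ms > t_end - self.t_cycle_ms + 1e-9

    def metrics(self, side: str = "lv") -> dict:
        m = self._last_cycle()
        v = {"lv": self.v_lv, "rv": self.v_rv}[side][m]
        p = {"lv": self.p_lv, "rv": self.p_rv}[side][m]
        edv, esv = float(v.max()), float(v.min())
        sv = edv - esv
        ef = sv / edv if edv > 0 else 0.0
        area = 0.5 * abs(float(np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p)))
        gap = abs(float(v[0] - v[-1]))  # volume gap between loop start and end
        tot = self.total_volume_ml
        cons = float(np.abs(tot - tot[0]).max() / tot[0])
        return {
            "EDV_ml": edv,
            "ESV_ml": esv,
            "SV_ml": sv,
            "EF": ef,
            "pv_area_ml_mmHg": area,
            "loop_gap_over_SV": gap / sv if sv > 0 else float("nan"),
            "volume_conservation_rel": cons,
        }

    def ef(self, side: str = "lv") -> float:
        return self.metrics(side)["EF"]


def run_cycle(
    lv: SphericalVentricle | None = None,
    rv: SphericalVentricle | None = None,
    circulation: CirculationParams | None = None,
    n_cycles: int = 3,
    t_cycle_ms: float = 1000.0,
    edp_lv: float = 8.0,
    edp_rv: float = 4.0,
    dt_ms: float = 0.1,
    record_every: int = 10,
) -> CycleResult:
    """Integrate the closed loop for ``n_cycles`` cardiac cycles.

    The run starts at end diastole (ventricular volumes located where the
    passive pressure equals the end-diastolic pressures, the protocol's
    linear pre-inflation being history-independent for an elastic wall) and
    t = 0 is activation onset.  Explicit fixed-step integration of the
    cavity-volume / arterial-pressure ODEs; each shared flow enters one
    cavity and leaves another, so the closed-loop blood volume is conserved
    to round-off by construction -- reported, not assumed.
    """
    lv = lv if lv is not None else default_lv()
    rv = rv if rv is not None else default_rv()
    circ = circulation if circulation is not None else CirculationParams()
    R = circ.resistances()
    r_mv, r_av, r_sys = R["MV"], R["AV"], R["Sys"]
    r_tv, r_pv, r_pul = R["TV"], R["PV"], R["Pul"]

    v_lv = lv.end_diastolic_volume(edp_lv)
    v_rv = rv.end_diastolic_volume(edp_rv)
    p_ao, p_pa = circ.p_ao0, circ.p_pa0
    # bookkeeping volumes for conservation (absolute offsets are arbitrary)
    v_ao = v_pa = v_la = v_ra = 10.0

    n_steps = int(round(n_cycles * t_cycle_ms / dt_ms))
    rec_t, rec = [], []
    for step in range(n_steps + 1):
        t = step * dt_ms
        tc = t % t_cycle_ms
        p_lv = lv.pressure(v_lv, tc)
        p_rv = rv.pressure(v_rv, tc)
        if step % record_every == 0 or step == n_steps:
            rec_t.append(t)
            rec.append(
                (p_lv, v_lv, p_rv, v_rv, p_ao, p_pa,
                 v_lv + v_rv + v_ao + v_pa + v_la + v_ra)
            )
        if step == n_steps:
            break
        q_mv = max(circ.p_la - p_lv, 0.0) / r_mv
        q_av = max(p_lv - p_ao, 0.0) / r_av
        q_sys = (p_ao - circ.p_ra) / r_sys
        q_tv = max(circ.p_ra - p_rv, 0.0) / r_tv
        q_pv = max(p_rv - p_pa, 0.0) / r_pv
        q_pul = (p_pa - circ.p_la) / r_pul
        dt_s = dt_ms / 1000.0
        v_lv += (q_mv - q_av) * dt_s
        v_rv += (q_tv - q_pv) * dt_s
        v_ao += (q_av - q_sys) * dt_s
        v_pa += (q_pv - q_pul) * dt_s
        v_la += (q_pul - q_mv) * dt_s
        v_ra += (q_sys - q_tv) * dt_s
        p_ao += (q_av - q_sys) / circ.c_ao * dt_s
        p_pa += (q_pv - q_pul) / circ.c_pa * dt_s

    arr = np.asarray(rec)
    return CycleResult(
        time_ms=np.asarray(rec_t),
        p_lv=arr[:, 0], v_lv=arr[:, 1],
        p_rv=arr[:, 2], v_rv=arr[:, 3],
        p_ao=arr[:, 4], p_pa=arr[:, 5],
        total_volume_ml=arr[:, 6],
        t_cycle_ms=t_cycle_ms,
    )
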