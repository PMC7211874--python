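"""Rule-based myofibre generation.

A rule-based method (RBM) assigns the fibre rotation (helix) angle as a
linear function of the transmural coordinate ``ebar``,

    theta(ebar) = theta_endo + ebar * (theta_epi - theta_endo),

and places the fibre in the local circumferential-longitudinal plane:
``f0 = cos(theta) c0 + sin(theta) l0`` (positive rotation from +c0 towards
+l0, right-handed about the transmural direction r0).  Two flavours are
provided: a single endo/epi angle pair for the whole ventricle (uniform
mode) and a per-AHA17-segment table (aha17 mode, no smoothing across
segment boundaries).  The sheet direction is transmural (``s0 = r0``) with
an optional rigid sheet rotation about the fibre; the sheet-normal
completes the right-handed triad, ``n0 = f0 x s0``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .geometry_frames import (
    RV_SEGMENT,
    LocalFrameField,
    SegmentLabelField,
    TetMesh,
    TransmuralField,
)

__all__ = [
    "RotationAngleTable",
    "FibreField",
    "rbm_fibre_angle",
    "generate_rbm_field",
]


@dataclass
class FibreField:
    """Per-element orthonormal fibre / sheet / sheet-normal unit triads."""

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.n0 = np.asarray(self.n0, dtype=float)

    @classmethod
    def from_fibre_and_sheet(cls, f0: np.ndarray, sheet_hint: np.ndarray) -> "FibreField":
        """Complete a triad from unit fibres and a (possibly oblique) sheet hint.

        The sheet is orthogonalized against the fibre and the sheet-normal is
        ``f0 x s0``.
        """
        f0 = np.asarray(f0, dtype=float)
        f0 = f0 / np.linalg.norm(f0, axis=-1, keepdims=True)
        s = np.asarray(sheet_hint, dtype=float)
        s = s - np.einsum("...k,...k->...", s, f0)[..., None] * f0
        nrm = np.linalg.norm(s, axis=-1, keepdims=True)
        if np.any(nrm < 1e-12):
            raise ValueError("sheet hint parallel to fibre; cannot complete triad")
        s = s / nrm
        return cls(f0=f0, s0=s, n0=np.cross(f0, s))

    def max_orthonormality_error(self) -> float:
        errs = [
            np.abs(np.einsum("ij,ij->i", a, b)).max()
            for a, b in ((self.f0, self.s0), (self.f0, self.n0), (self.s0, self.n0))
        ]
        errs += [
            np.abs(np.linalg.norm(v, axis=1) - 1.0).max()
            for v in (self.f0, self.s0, self.n0)
        ]
        return float(max(errs))


# --------------------------------------------------------------------------
# rotation-angle tables
# --------------------------------------------------------------------------

@dataclass
class RotationAngleTable:
    """Endo/epi fibre rotation angles (degrees) per AHA17 segment plus RV.

    ``segments`` maps segment id (1..17, and ``RV_SEGMENT`` for the right
    ventricle) to an ``(theta_endo, theta_epi)`` pair; ``uniform`` is the
    whole-LV pair used in uniform mode.
    """

    segments: dict = field(default_factory=dict)
    uniform: tuple = (40.0, -30.0)

    def __post_init__(self) -> None:
        for seg, (e, p) in self.segments.items():
            for ang in (e, p):
                if not (-90.0 < ang <= 90.0):
                    raise ValueError(
                        f"segment {seg}: angle {ang} outside (-90, 90] degrees"
                    )
        for ang in self.uniform:
            if not (-90.0 < ang <= 90.0):
                raise ValueError(f"uniform angle {ang} outside (-90, 90] degrees")

    def angles_for(self, segment: int) -> tuple:
        try:
            return self.segments[int(segment)]
        except KeyError:
            name = "RV" if segment == RV_SEGMENT else str(segment)
            raise KeyError(f"rotation-angle table has no entry for segment {name}")

    @classmethod
    def default(cls) -> "RotationAngleTable":
        """Packaged per-segment averages (with the whole-LV 40/-30 pair)."""
        with resources.files("myofibrekit.data").joinpath(
            "rotation_angles.csv"
        ).open("r") as fh:
            return cls.from_csv(fh)

    @classmethod
    def from_csv(cls, path_or_buf, uniform: tuple = (40.0, -30.0)) -> "RotationAngleTable":
        """Read ``segment, theta_endo_deg, theta_epi_deg`` rows (segment 'RV' allowed)."""
        df = pd.read_csv(path_or_buf, comment="#")
        required = {"segment", "theta_endo_deg", "theta_epi_deg"}
        if not required.issubset(df.columns):
            raise ValueError(f"angle CSV needs columns {sorted(required)}")
        segs = {}
        for _, row in df.iterrows():
            raw = str(row["segment"]).strip()
            seg = RV_SEGMENT if raw.upper() == "RV" else int(raw)
            segs[seg] = (float(row["theta_endo_deg"]), float(row["theta_epi_deg"]))
        return cls(segments=segs, uniform=uniform)

    def to_csv(self, path) -> None:
        rows = []
        for seg in sorted(self.segments, key=lambda s: (s == RV_SEGMENT, s)):
            e, p = self.segments[seg]
            rows.append(
                {
                    "segment": "RV" if seg == RV_SEGMENT else seg,
                    "theta_endo_deg": e,
                    "theta_epi_deg": p,
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def rbm_fibre_angle(ebar_elem, theta_endo, theta_epi):
    """Linear endo->epi interpolation of the fibre rotation angle (degrees)."""
    e = np.asarray(ebar_elem, dtype=float)
    if np.any((e < -1e-12) | (e > 1.0 + 1e-12)):
        raise ValueError("ebar outside [0, 1]")
    return theta_endo + e * (theta_epi - theta_endo)


def rbm_angles_for_elements(
    ebar_elem: np.ndarray,
    table: RotationAngleTable,
    mode: str = "uniform",
    segments: SegmentLabelField | None = None,
) -> np.ndarray:
    """Per-element fibre rotation angles (degrees) for either RBM mode."""
    ebar_elem = np.asarray(ebar_elem, dtype=float)
    if mode == "uniform":
        e, p = table.uniform
        return rbm_fibre_angle(ebar_elem, e, p)
    if mode == "aha17":
        if segments is None:
            raise ValueError("aha17 mode requires a SegmentLabelField")
        seg = segments.segment
        if seg.shape[0] != ebar_elem.shape[0]:
            raise ValueError("segment labels and ebar have different element counts")
        out = np.empty_like(ebar_elem)
        for s in np.unique(seg):
            e, p = table.angles_for(int(s))
            m = seg == s
            out[m] = rbm_fibre_angle(ebar_elem[m], e, p)
        return out
    raise ValueError(f"unknown RBM mode {mode!r}")


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return (
        v * c
        + np.cross(axis, v) * s
        + axis * np.einsum("...k,...k->...", axis, v)[..., None] * (1.0 - c)
    )


def generate_rbm_field(
    mesh: TetMesh,
    frames: LocalFrameField,
    ebar: TransmuralField,
    table: RotationAngleTable,
    mode: str = "uniform",
    sheet_rotation: float = 0.0,
    segments: SegmentLabelField | None = None,
) -> FibreField:
    """Rule-based fibre field on a mesh with local frames.

    ``sheet_rotation`` (degrees) rigidly rotates the sheet away from the
    transmural direction about the fibre axis; the default 0 keeps the sheet
    radial.  In ``aha17`` mode every element takes its own segment's angle
    pair with no smoothing across segment boundaries.
    """
    ebar_elem = ebar.element_means(mesh)
    theta = np.radians(rbm_angles_for_elements(ebar_elem, table, mode, segments))
    f0 = np.cos(theta)[:, None] * frames.c0 + np.sin(theta)[:, None] * frames.l0
    s0 = frames.r0.copy()
    if sheet_rotation != 0.0:
        s0 = _rodrigues(s0, f0, np.radians(sheet_rotation))
    n0 = np.cross(f0, s0)
    return FibreField(f0=f0, s0=s0, n0=n0)
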