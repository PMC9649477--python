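"""Asymmetry indices (AI) for recovery-cycle and hemispheric MRI metrics.

AI = |Side1 − Side2| / (Side1 + Side2) ∈ [0, 1]: 0 means perfect symmetry,
1 maximal asymmetry. For the blink-reflex recovery cycle the two sides are
the recovery ratios obtained by stimulating the clinically more affected
side (MAS) and less affected side (LAS) at the same ISI. For MRI the two
sides are hemispheric cortical metrics of the hemispheres *contralateral*
to the clinical MAS and LAS (motor signs lateralise contralaterally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .blink_reflex import R2RecoveryCurve
from .errors import DataError, DomainError, ProtocolError, UndefinedAsymmetryError

#: ISIs (ms) for which the AI of the recovery cycle is reported.
AI_ISIS = (100, 150, 200)

#: ISI used as the primary classification feature.
PRIMARY_ISI = 100


def asymmetry_index(side1: float, side2: float) -> float:
    """Absolute asymmetry index of two non-negative side values.

    Symmetric in its arguments and invariant to common rescaling.
    Raises ``DomainError`` for negative inputs and
    ``UndefinedAsymmetryError`` when both sides are zero.
    """
    if side1 < 0 or side2 < 0:
        raise DomainError(f"sides must be non-negative, got ({side1}, {side2})")
    total = side1 + side2
    if total == 0:
        raise UndefinedAsymmetryError("both sides are zero: asymmetry undefined")
    return abs(side1 - side2) / total


def r2brrc_ai(curve_mas: R2RecoveryCurve, curve_las: R2RecoveryCurve, isi_ms: int) -> float:
    """AI of the R2 recovery cycle at one ISI.

    The two sides of the index are the recovery ratios for MAS-stimulation
    and LAS-stimulation at `isi_ms`.
    """
    if curve_mas.stim_side != "MAS" or curve_las.stim_side != "LAS":
        raise DataError(
            "expected (MAS curve, LAS curve), got "
            f"({curve_mas.stim_side}, {curve_las.stim_side})"
        )
    missing = [i for c in (curve_mas, curve_las) for i in [isi_ms] if i not in c.ratios]
    if missing:
        raise ProtocolError(set(missing), f"ISI {isi_ms} ms absent from a recovery curve")
    return asymmetry_index(curve_mas.ratios[isi_ms], curve_las.ratios[isi_ms])


def contralateral(side: str) -> str:
    """Hemisphere contralateral to a body side (an involution)."""
    try:
        return {"left": "right", "right": "left"}[side]
    except KeyError:
        raise DomainError(f"side must be 'left' or 'right', got {side!r}") from None


@dataclass
class HemisphereMetrics:
    """Per-hemisphere cortical metrics (derived upstream, e.g. FreeSurfer).

    Volumes in mm³, thickness in mm. If ``total_gm_volume_mm3`` is given it
    must agree with left+right within ``total_rel_tol``.
    """

    left_volume_mm3: float
    right_volume_mm3: float
    left_thickness_mm: float | None = None
    right_thickness_mm: float | None = None
    total_gm_volume_mm3: float | None = None
    total_rel_tol: float = 0.05

    def __post_init__(self):
        if not (self.left_volume_mm3 > 0 and self.right_volume_mm3 > 0):
            raise DataError("hemisphere volumes must be > 0")
        if self.total_gm_volume_mm3 is not None:
            s = self.left_volume_mm3 + self.right_volume_mm3
            if abs(s - self.total_gm_volume_mm3) > self.total_rel_tol * self.total_gm_volume_mm3:
                raise DataError(
                    f"left+right = {s:.0f} mm³ inconsistent with total "
                    f"{self.total_gm_volume_mm3:.0f} mm³"
                )

    def value(self, hemisphere: str, metric: str = "volume") -> float:
        if metric == "volume":
            v = {"left": self.left_volume_mm3, "right": self.right_volume_mm3}[hemisphere]
        elif metric == "thickness":
            v = {"left": self.left_thickness_mm, "right": self.right_thickness_mm}[hemisphere]
            if v is None:
                raise DataError(f"{hemisphere} thickness not available")
        else:
            raise DomainError(f"metric must be 'volume' or 'thickness', got {metric!r}")
        return v


def mri_ai(metrics: HemisphereMetrics, mas_side: str, metric: str = "volume") -> float:
    """AI of hemispheric MRI metrics, MAS/LAS-referenced.

    Side1 is the metric of the hemisphere contralateral to the clinical MAS
    (right MAS → left hemisphere), Side2 contralateral to the LAS. The
    absolute value makes the result independent of which side is called
    MAS; the mapping matters only for signed (non-default) uses upstream.
    """
    h1 = contralateral(mas_side)
    h2 = "left" if h1 == "right" else "right"
    return asymmetry_index(metrics.value(h1, metric), metrics.value(h2, metric))


@dataclass
class AsymmetryProfile:
    """Per-patient asymmetry indices: AI of the recovery cycle per ISI and AI of MRI."""

    ai_r2brrc: dict
    ai_mri: float
    mas_side: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = {k: v for k, v in self.ai_r2brrc.items() if not (0 <= v <= 1)}
        if bad or not (0 <= self.ai_mri <= 1):
            raise DataError(f"AI values must lie in [0,1]; offending: {bad or self.ai_mri}")


def profiles_from_curves(curves_by_patient, mri_by_patient, mas_sides, isis=AI_ISIS, metric="volume"):
    """Build ``AsymmetryProfile`` objects from extracted curves and MRI metrics.

    `curves_by_patient` maps patient_id -> {"MAS": curve, "LAS": curve}.
    """
    out = {}
    for pid, curves in curves_by_patient.items():
        mas = mas_sides[pid]
        ai_r2 = {isi: r2brrc_ai(curves["MAS"], curves["LAS"], isi) for isi in isis}
        out[pid] = AsymmetryProfile(ai_r2, mri_ai(mri_by_patient[pid], mas, metric), mas)
    return out


def ai_table(patients, profiles) -> pd.DataFrame:
    """Per-patient AI table: patient_id, group, mas_side, ai_r2brrc_<isi>…, ai_mri."""
    rows = []
    for p in patients:
        prof = profiles[p.patient_id]
        row = {"patient_id": p.patient_id, "group": p.group, "mas_side": p.mas_side}
        for isi in sorted(prof.ai_r2brrc):
            row[f"ai_r2brrc_{isi}"] = prof.ai_r2brrc[isi]
        row["ai_mri"] = prof.ai_mri
        rows.append(row)
    return pd.DataFrame(rows)
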