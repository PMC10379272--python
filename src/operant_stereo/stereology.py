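"""Design-based stereology: Cavalieri volume, physical disector counts,
point-sampled-intercept particle volumes, and coefficient-of-error auditing.

Estimators operate on per-animal, per-section counting sheets — the raw
point counts (P), sampled disector frames (F), disector counts (Q-) and
point-sampled intercept lengths collected on printed section montages —
together with the grid/frame geometry of the sampling design:

    Vref = sum(P) * a(p) * t * s            (Cavalieri reference volume)
    TSV  = sum(F) * ASF * t                 (total disector volume)
    Nv   = sum(Q-) / TSV                    (numerical density)
    N    = (Vref / TSV) * sum(Q-) = Vref*Nv (absolute number)
    vV   = (pi/3) * lbar^3                  (volume-weighted mean volume)

Precision is audited per estimate with coefficients of error (CE): the
Gundersen-Jensen systematic-sampling approximation for the Cavalieri
volume, 1/sqrt(sum Q-) for the density, quadrature for N, and
CV/sqrt(n) for intercept-derived particle volumes.  Group reliability uses
the classic rule that the mean within-animal sampling variance (CE^2)
should be less than half the observed between-animal variance (CV^2).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GridGeometry",
    "SectionRecord",
    "CountingSheet",
    "StereoEstimate",
    "PrecisionAudit",
    "AuditCell",
    "cavalieri_volume",
    "total_sampled_volume",
    "numerical_density",
    "absolute_number",
    "volume_weighted_mean_volume",
    "ce_cavalieri",
    "ce_numerical_density",
    "ce_absolute_number",
    "ce_volume_estimate",
    "group_mean_ce",
    "precision_audit",
    "estimate_sheet",
    "REGIONS",
    "COUNTING_MODES",
]

REGIONS = ("VTA", "CLi", "SNCd", "SNCv", "RRF", "VTA_plus_CLi", "midbrain_total")
COUNTING_MODES = ("unidirectional", "bidirectional_paper_literal", "bidirectional_corrected")

#: Smoothness-class constant of the Gundersen-Jensen variance approximation
#: for systematic point counts on smooth (once-differentiable) boundaries.
GUNDERSEN_SMOOTHNESS_DENOM = 240.0


@dataclass(frozen=True)
class GridGeometry:
    """Sampling geometry as recorded on the printed montages.

    Lengths are in mm *on the montage*; division by ``magnification``
    converts to real tissue scale.  ``a(p)`` is the real area associated
    with one grid point and ``ASF`` the real area of one disector frame.
    """

    point_spacing_mm: float
    frame_side_mm: float
    magnification: float = 220.0
    section_thickness_t_mm: float = 0.005
    section_interval_s: int = 20
    frame_sampling_interval: int = 2

    def __post_init__(self) -> None:
        for name in ("point_spacing_mm", "frame_side_mm", "magnification",
                     "section_thickness_t_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.section_interval_s < 1 or self.frame_sampling_interval < 1:
            raise ValueError("sampling intervals must be >= 1")

    @property
    def a_p_mm2(self) -> float:
        """Real area per grid point: (spacing / magnification)^2."""
        return (self.point_spacing_mm / self.magnification) ** 2

    @property
    def asf_mm2(self) -> float:
        """Real area of one sampling frame: (side / magnification)^2."""
        return (self.frame_side_mm / self.magnification) ** 2


@dataclass(frozen=True)
class SectionRecord:
    section_index: int
    points_P: int = 0
    frames_F: int = 0
    disector_Q: int = 0

    def __post_init__(self) -> None:
        if min(self.points_P, self.frames_F, self.disector_Q) < 0:
            raise ValueError("section counts must be >= 0")


@dataclass
class CountingSheet:
    """Per-animal, per-region stereological raw counts plus geometry."""

    animal_id: str
    group: str
    region: str
    geometry: GridGeometry
    sections: list[SectionRecord] = field(default_factory=list)
    stain: str = "TH"
    intercept_lengths_um: list[float] | None = None
    counting_mode: str = "unidirectional"

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.counting_mode not in COUNTING_MODES:
            raise ValueError(f"unknown counting_mode {self.counting_mode!r}")
        idx = [s.section_index for s in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("section_index must be strictly increasing")
        if self.intercept_lengths_um is not None and any(
            l <= 0 for l in self.intercept_lengths_um
        ):
            raise ValueError("intercept lengths must be > 0")

    @property
    def sum_P(self) -> int:
        return sum(s.points_P for s in self.sections)

    @property
    def sum_F(self) -> int:
        return sum(s.frames_F for s in self.sections)

    @property
    def sum_Q(self) -> int:
        return sum(s.disector_Q for s in self.sections)


@dataclass
class StereoEstimate:
    animal_id: str
    region: str
    stain: str
    Vref_mm3: float
    TSV_mm3: float
    Nv_per_mm3: float
    N_absolute: float
    ce_vref: float
    ce_nv: float
    ce_n: float
    Vv_um3: float | None = None
    ce_vv: float | None = None
    group: str = ""

    def __post_init__(self) -> None:
        if self.Vref_mm3 > 0 and self.Nv_per_mm3 > 0:
            if not math.isclose(self.N_absolute, self.Vref_mm3 * self.Nv_per_mm3,
                                rel_tol=1e-9):
                raise ValueError("identity N = Vref * Nv violated")


# ---------------------------------------------------------------------------
# first-order estimators

def cavalieri_volume(sheet: CountingSheet) -> float:
    """Cavalieri reference volume: Vref = sum(P) * a(p) * t * s  [mm^3]."""
    if not sheet.sections:
        raise ValueError("no sections on counting sheet")
    g = sheet.geometry
    if sheet.sum_P == 0:
        warnings.warn(f"{sheet.animal_id}/{sheet.region}: no points counted; Vref = 0")
    return sheet.sum_P * g.a_p_mm2 * g.section_thickness_t_mm * g.section_interval_s


def total_sampled_volume(sheet: CountingSheet) -> float:
    """Total disector volume: TSV = sum(F) * ASF * t  [mm^3].

    In ``bidirectional_corrected`` mode the disector pairs were counted in
    both directions, so the effective sampled thickness per pair is 2t and
    TSV is doubled; ``bidirectional_paper_literal`` keeps the single-
    thickness formula against bidirectional counts (and is therefore a
    documented ~2x overestimator of density).
    """
    if sheet.sum_F == 0:
        raise ValueError("no frames counted (TSV undefined)")
    g = sheet.geometry
    tsv = sheet.sum_F * g.asf_mm2 * g.section_thickness_t_mm
    if sheet.counting_mode == "bidirectional_corrected":
        tsv *= 2.0
    return tsv


def numerical_density(sheet: CountingSheet) -> float:
    """Numerical density Nv = sum(Q-) / TSV  [per mm^3]."""
    return sheet.sum_Q / total_sampled_volume(sheet)


def absolute_number(sheet: CountingSheet) -> float:
    """Absolute number N = (Vref / TSV) * sum(Q-) = Vref * Nv."""
    return cavalieri_volume(sheet) * numerical_density(sheet)


def volume_weighted_mean_volume(
    lengths_um: Sequence[float],
    estimator: str = "cube_of_mean",
) -> float:
    """Volume-weighted mean particle volume from point-sampled intercepts.

    ``cube_of_mean`` (default) cubes the per-animal mean intercept length,
    vV = (pi/3) * lbar^3 — the convention used with manual rulers, where
    each neuron contributes its mean intercept once.  ``mean_of_cubes``
    averages l^3 per intercept, (pi/3) * mean(l^3), the form for which the
    point-sampled-intercept identity E[(pi/3) l^3] = vV holds exactly.
    """
    lengths = np.asarray(lengths_um, dtype=float)
    if lengths.size == 0:
        raise ValueError("no intercept lengths")
    if estimator == "cube_of_mean":
        return float(np.pi / 3.0 * lengths.mean() ** 3)
    if estimator == "mean_of_cubes":
        return float(np.pi / 3.0 * np.mean(lengths ** 3))
    raise ValueError(f"unknown estimator {estimator!r}")


# ---------------------------------------------------------------------------
# coefficients of error

def ce_cavalieri(sheet: CountingSheet,
                 smoothness_denom: float = GUNDERSEN_SMOOTHNESS_DENOM) -> float:
    """Gundersen-Jensen CE of the Cavalieri volume from per-section point counts.

    With section counts P_i, A = sum P_i^2, B = sum P_i P_{i+1},
    C = sum P_i P_{i+2}:  CE = sqrt((3A - 4B + C) / 240) / sum(P).
    Truncated lag sums (B, C) are used for very short series.
    """
    P = np.array([s.points_P for s in sheet.sections], dtype=float)
    total = P.sum()
    if total == 0:
        raise ValueError("sum(P) = 0: CE undefined")
    A = float(np.sum(P * P))
    B = float(np.sum(P[:-1] * P[1:])) if P.size > 1 else 0.0
    C = float(np.sum(P[:-2] * P[2:])) if P.size > 2 else 0.0
    var = (3.0 * A - 4.0 * B + C) / smoothness_denom
    return math.sqrt(max(var, 0.0)) / total


def ce_numerical_density(sheet: CountingSheet) -> float:
    """Poisson-counting CE of the density: 1 / sqrt(sum Q-)."""
    q = sheet.sum_Q
    if q <= 0:
        raise ValueError("sum(Q-) = 0: CE undefined")
    return 1.0 / math.sqrt(q)


def ce_absolute_number(ce_vref: float, ce_nv: float) -> float:
    """CE of N = Vref * Nv by quadrature of its (independent) factors."""
    if ce_vref < 0 or ce_nv < 0:
        raise ValueError("CEs must be >= 0")
    return math.hypot(ce_vref, ce_nv)


def ce_volume_estimate(per_neuron_volumes_um3: Sequence[float]) -> float:
    """CE of the mean particle volume: within-animal CV / sqrt(n neurons)."""
    v = np.asarray(per_neuron_volumes_um3, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 per-neuron volume estimates")
    cv = v.std(ddof=1) / v.mean()
    return float(cv / math.sqrt(v.size))


def group_mean_ce(ces: Iterable[float]) -> float:
    """Group mean CE = sqrt(mean of squared per-animal CEs)."""
    arr = np.asarray(list(ces), dtype=float)
    if arr.size == 0:
        raise ValueError("empty CE list")
    return float(np.sqrt(np.mean(arr ** 2)))


# ---------------------------------------------------------------------------
# precision audit

@dataclass
class AuditCell:
    group: str
    region: str
    quantity: str
    mean_ce: float
    cv: float
    ratio: float
    verdict: str  # "ok" | "flagged_low_CV"
    note: str = ""


@dataclass
class PrecisionAudit:
    cells: list[AuditCell]

    def flagged(self) -> list[AuditCell]:
        return [c for c in self.cells if c.verdict != "ok"]


def _audit_one(group: str, region: str, quantity: str,
               values: Sequence[float], ces: Sequence[float]) -> AuditCell:
    if len(values) < 2:
        raise ValueError(f"{group}/{region}/{quantity}: need >= 2 animals for CV")
    values = np.asarray(values, dtype=float)
    mean_ce = group_mean_ce(ces)
    cv = float(values.std(ddof=1) / values.mean())
    if cv == 0.0:
        return AuditCell(group, region, quantity, mean_ce, cv, math.inf,
                         "flagged_low_CV", "zero biological variance")
    ratio = mean_ce ** 2 / cv ** 2
    if ratio < 0.5:
        return AuditCell(group, region, quantity, mean_ce, cv, ratio, "ok")
    return AuditCell(group, region, quantity, mean_ce, cv, ratio,
                     "flagged_low_CV", f"low biological variance (CV = {cv:.3f})")


def precision_audit(estimates: Sequence[StereoEstimate]) -> PrecisionAudit:
    """CE^2-versus-CV^2 reliability audit per (group, region, quantity).

    A cell is reliable ("ok") when the mean within-animal sampling variance
    (mean CE^2) is less than half the observed between-animal variance
    (CV^2); otherwise it is flagged, carrying the (low) CV — a flagged cell
    is acceptable when biological variance is genuinely small.
    """
    by_key: dict[tuple[str, str], list[StereoEstimate]] = {}
    for e in estimates:
        by_key.setdefault((e.group, e.region), []).append(e)
    cells: list[AuditCell] = []
    for (grp, region), ests in sorted(by_key.items()):
        quantities = [
            ("Vref", [e.Vref_mm3 for e in ests], [e.ce_vref for e in ests]),
            ("Nv", [e.Nv_per_mm3 for e in ests], [e.ce_nv for e in ests]),
            ("N", [e.N_absolute for e in ests], [e.ce_n for e in ests]),
        ]
        if all(e.Vv_um3 is not None and e.ce_vv is not None for e in ests):
            quantities.append(
                ("Vv", [e.Vv_um3 for e in ests], [e.ce_vv for e in ests])
            )
        for qname, vals, ces in quantities:
            cells.append(_audit_one(grp, region, qname, vals, ces))
    return PrecisionAudit(cells)


# ---------------------------------------------------------------------------
# per-sheet driver

def estimate_sheet(sheet: CountingSheet,
                   vv_estimator: str = "cube_of_mean") -> StereoEstimate:
    """All estimates plus CEs for one counting sheet."""
    vref = cavalieri_volume(sheet)
    nv = numerical_density(sheet)
    tsv = total_sampled_volume(sheet)
    est = StereoEstimate(
        animal_id=sheet.animal_id,
        region=sheet.region,
        stain=sheet.stain,
        Vref_mm3=vref,
        TSV_mm3=tsv,
        Nv_per_mm3=nv,
        N_absolute=vref * nv,
        ce_vref=ce_cavalieri(sheet),
        ce_nv=ce_numerical_density(sheet),
        ce_n=ce_absolute_number(ce_cavalieri(sheet), ce_numerical_density(sheet)),
        group=sheet.group,
    )
    if sheet.intercept_lengths_um:
        est.Vv_um3 = volume_weighted_mean_volume(
            sheet.intercept_lengths_um, estimator=vv_estimator
        )
        if len(sheet.intercept_lengths_um) >= 2:
            per_neuron = [np.pi / 3.0 * l ** 3 for l in sheet.intercept_lengths_um]
            est.ce_vv = ce_volume_estimate(per_neuron)
    return est
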