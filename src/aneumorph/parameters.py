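"""One-call computation of all 40 parameters for a single dome."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .curvature_metrics import curvature_field, curvature_metrics
from .mesh_core import (
    AneurysmDome,
    cap_neck,
    convex_hull_metrics,
    minimal_bounding_sphere,
)
from .neck_geometry import fit_neck_plane, neck_metrics
from .shape_indices import shape_indices
from .size_metrics import (
    assemble_size_metrics,
    height_metrics,
    max_dimension,
    plane_parallel_diameter,
)

__all__ = ["PARAMETER_NAMES", "ParameterRecord", "compute_parameters"]

#: the 40 parameter abbreviations, in canonical (#1-#40) order
PARAMETER_NAMES = [
    "H", "L_max", "H_max", "D_max", "H_b",
    "A", "A_CH", "A_MBS", "A_closed", "V", "V_CH", "V_MBS",
    "D_neck_min", "D_neck_max", "P_neck", "D_neck_equiv",
    "A_neck", "A_neck_elliptical",
    "SR", "AR", "eAR", "BF", "BL", "NSI", "IPR", "AVSV", "AASA",
    "UI", "CR", "EI",
    "MAA", "absMAA", "MSD", "HMC", "MLN",
    "GAA", "absGAA", "GSD", "HGC", "GLN",
]


@dataclass
class ParameterRecord:
    """All 40 named parameter values for one aneurysm x group mesh."""

    aneurysm_id: str
    group_id: str
    values: dict
    flags: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        data = {"aneurysm": self.aneurysm_id, "group": self.group_id}
        data.update({k: self.values.get(k) for k in PARAMETER_NAMES})
        return pd.Series(data)

    def __getitem__(self, name: str):
        return self.values[name]


def compute_parameters(
    dome: AneurysmDome,
    n_slices: int = 100,
    check_invariants: bool = True,
) -> ParameterRecord:
    """Compute parameters #1-#40 for one dome.

    SR is left missing (None) when the dome carries no parent-vessel
    diameter.
    """
    plane = fit_neck_plane(dome)
    neck = neck_metrics(dome, plane)
    closed = cap_neck(dome)
    _, hull_area, hull_volume = convex_hull_metrics(dome.surface)
    _, mbs_radius, _, _ = minimal_bounding_sphere(dome.surface)
    H, H_max = height_metrics(dome, plane)
    L_max = max_dimension(dome)
    D_max, H_b = plane_parallel_diameter(dome, plane, n_slices=n_slices)
    size = assemble_size_metrics(
        dome, closed, hull_area, hull_volume, mbs_radius,
        H, H_max, L_max, D_max, H_b, check=check_invariants,
    )
    shape = shape_indices(size, neck, dome.parent_vessel_diameter)
    cfield = curvature_field(dome)
    curv = curvature_metrics(cfield, size.A, mbs_radius)

    values = {
        "H": size.H, "L_max": size.L_max, "H_max": size.H_max,
        "D_max": size.D_max, "H_b": size.H_b,
        "A": size.A, "A_CH": size.A_CH, "A_MBS": size.A_MBS,
        "A_closed": size.A_closed, "V": size.V, "V_CH": size.V_CH,
        "V_MBS": size.V_MBS,
        "D_neck_min": neck.D_neck_min, "D_neck_max": neck.D_neck_max,
        "P_neck": neck.P_neck, "D_neck_equiv": neck.D_neck_equiv,
        "A_neck": neck.A_neck, "A_neck_elliptical": neck.A_neck_elliptical,
        "SR": shape.SR, "AR": shape.AR, "eAR": shape.eAR, "BF": shape.BF,
        "BL": shape.BL, "NSI": shape.NSI, "IPR": shape.IPR,
        "AVSV": shape.AVSV, "AASA": shape.AASA, "UI": shape.UI,
        "CR": shape.CR, "EI": shape.EI,
        "MAA": curv.MAA, "absMAA": curv.absMAA, "MSD": curv.MSD,
        "HMC": curv.HMC, "MLN": curv.MLN,
        "GAA": curv.GAA, "absGAA": curv.absGAA, "GSD": curv.GSD,
        "HGC": curv.HGC, "GLN": curv.GLN,
    }
    flags = {
        "SR_missing": shape.SR is None,
        "neck_polygon_convexified": neck.projected_polygon_convexified,
        "curvature_barycentric_fallback": cfield.barycentric_fallback,
    }
    return ParameterRecord(
        aneurysm_id=dome.aneurysm_id,
        group_id=dome.group_id,
        values=values,
        flags=flags,
    )
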