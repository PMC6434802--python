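"""The twelve non-dimensional shape parameters (#19-#30).

Area-to-volume indices (NSI, IPR, AASA) use the *closed* surface area
``A_closed``: their normalizations are defined for a closed body, and
``(18 pi)^(1/3)`` is the classic hemisphere-referenced constant (a
closed hemisphere gets NSI = 1/3 exactly):

    IPR = A_closed / V^(2/3)
    NSI = 1 - (18 pi)^(1/3) / IPR
    EI  = 1 - (18 pi)^(1/3) * V_CH^(2/3) / A_CH

so NSI and IPR are exact monotone transforms of each other, and
UI = 1 - CR by definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .neck_geometry import NeckMetrics
from .size_metrics import SizeMetrics

__all__ = ["ShapeIndices", "shape_indices", "SPHERE_NORMALIZATION"]

#: (18 pi)^(1/3): NSI/EI normalization; = 2/3 of a hemisphere's A/V^(2/3)
SPHERE_NORMALIZATION = (18.0 * np.pi) ** (1.0 / 3.0)


@dataclass
class ShapeIndices:
    SR: Optional[float]  # size ratio, None when no parent-vessel diameter
    AR: float            # aspect ratio H / D_neck_max
    eAR: float           # equivalent aspect ratio H / D_neck_equiv
    BF: float            # bottleneck factor D_max / D_neck_max
    BL: float            # bulge location H_b / H
    NSI: float           # nonsphericity index
    IPR: float           # isoperimetric ratio
    AVSV: float          # V / V_MBS
    AASA: float          # A_closed / A_MBS
    UI: float            # undulation index 1 - CR
    CR: float            # convexity ratio V / V_CH
    EI: float            # ellipticity index (on the convex hull)


def shape_indices(
    size: SizeMetrics,
    neck: NeckMetrics,
    parent_vessel_diameter: Optional[float] = None,
) -> ShapeIndices:
    """Assemble #19-#30 from the size and neck records of one dome."""
    for name, den in [
        ("AR/BF (D_neck_max)", neck.D_neck_max),
        ("eAR (D_neck_equiv)", neck.D_neck_equiv),
        ("BL (H)", size.H),
        ("NSI/IPR (V)", size.V),
        ("AVSV (V_MBS)", size.V_MBS),
        ("AASA (A_MBS)", size.A_MBS),
        ("CR/UI (V_CH)", size.V_CH),
        ("EI (A_CH)", size.A_CH),
    ]:
        if den <= 0:
            raise ValueError(f"zero or negative denominator for {name}")
    sr = None
    if parent_vessel_diameter is not None:
        if parent_vessel_diameter <= 0:
            raise ValueError("parent vessel diameter must be positive")
        sr = size.H_max / parent_vessel_diameter
    ipr = size.A_closed / size.V ** (2.0 / 3.0)
    cr = size.V / size.V_CH
    return ShapeIndices(
        SR=sr,
        AR=size.H / neck.D_neck_max,
        eAR=size.H / neck.D_neck_equiv,
        BF=size.D_max / neck.D_neck_max,
        BL=size.H_b / size.H,
        NSI=1.0 - SPHERE_NORMALIZATION / ipr,
        IPR=ipr,
        AVSV=size.V / size.V_MBS,
        AASA=size.A_closed / size.A_MBS,
        UI=1.0 - cr,
        CR=cr,
        EI=1.0 - SPHERE_NORMALIZATION * size.V_CH ** (2.0 / 3.0) / size.A_CH,
    )
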