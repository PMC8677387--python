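"""The five MICCAI 2007 liver-segmentation metrics and their aggregation.

For a segmentation mask A and a gold-standard mask B on the same grid:

- ``VOE  = 100 · (1 − |A∩B| / |A∪B|)``                 (%, volumetric overlap error)
- ``RVD  = 100 · (|A| − |B|) / |B|``                    (%, signed relative volume difference)
- ``ASSD``   — mean of all surface-to-nearest-surface distances, both directions (mm)
- ``RMSSSD`` — root mean square of the same distances (mm)
- ``MSSD``   — maximum of the same distances (mm; symmetric Hausdorff)

Surfaces are the 6-neighbour surface voxel sets; distances are Euclidean
between voxel centres in physical mm.  Per-dataset results are aggregated
as arithmetic mean ± sample (n−1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial import cKDTree

from .registration import extract_surface_points
from .volume_io import Mask

__all__ = ["MetricsReport", "compute_metrics", "aggregate", "format_table"]

_METRIC_UNITS = {"voe": "%", "rvd": "%", "assd": "mm", "rmsssd": "mm", "mssd": "mm"}


@dataclass
class MetricsReport:
    voe: float
    rvd: float
    assd: float
    rmsssd: float
    mssd: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __post_init__(self) -> None:
        if not (0.0 <= self.voe <= 100.0):
            raise ValueError(f"VOE must be in [0, 100], got {self.voe}")
        if min(self.assd, self.rmsssd, self.mssd) < 0:
            raise ValueError("surface distances must be non-negative")


def compute_metrics(A: Mask, B: Mask, signed_rvd: bool = True) -> MetricsReport:
    """Five-metric comparison of segmentation A against gold standard B.

    Both masks must share grid shape and spacing and be non-empty (the
    volume ratio and surface distances are undefined otherwise).  With
    ``signed_rvd=False`` the absolute relative volume difference is
    reported instead of the signed one.
    """
    if A.shape != B.shape or not np.allclose(A.spacing, B.spacing):
        raise ValueError("masks must share grid shape and spacing")
    a = A.data.astype(bool)
    b = B.data.astype(bool)
    nb = int(b.sum())
    if nb == 0:
        raise ValueError("gold-standard mask is empty; RVD undefined")
    na = int(a.sum())
    if na == 0:
        raise ValueError("segmentation mask is empty; surface distances undefined")

    inter = int((a & b).sum())
    union = int((a | b).sum())
    voe = 100.0 * (1.0 - inter / union)
    rvd = 100.0 * (na - nb) / nb
    if not signed_rvd:
        rvd = abs(rvd)

    spacing = np.asarray(A.spacing)
    sa = extract_surface_points(A).points * spacing
    sb = extract_surface_points(B).points * spacing
    d_ab, _ = cKDTree(sb).query(sa)
    d_ba, _ = cKDTree(sa).query(sb)
    n = len(sa) + len(sb)
    assd = (d_ab.sum() + d_ba.sum()) / n
    rmsssd = float(np.sqrt((np.square(d_ab).sum() + np.square(d_ba).sum()) / n))
    mssd = float(max(d_ab.max(), d_ba.max()))
    return MetricsReport(voe=voe, rvd=rvd, assd=float(assd), rmsssd=rmsssd, mssd=float(mssd))


def aggregate(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Per-metric mean and sample (n−1) standard deviation.

    Returns ``{metric: (mean, std)}``; requires at least two reports.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to aggregate")
    out: dict[str, tuple[float, float]] = {}
    for name in _METRIC_UNITS:
        values = np.array([getattr(r, name) for r in reports])
        out[name] = (float(values.mean()), float(values.std(ddof=1)))
    return out


def format_table(reports: list[MetricsReport], decimals: int = 2) -> str:
    """Per-case rows plus an Average row in mean ± std form."""
    header = ["Case", "VOE (%)", "RVD (%)", "ASSD (mm)", "RMSSSD (mm)", "MSSD (mm)"]
    lines = ["\t".join(header)]
    for i, r in enumerate(reports, start=1):
        lines.append(
            "\t".join([str(i)] + [f"{getattr(r, n):.{decimals}f}" for n in _METRIC_UNITS])
        )
    if len(reports) >= 2:
        agg = aggregate(reports)
        cells = [f"{m:.1f} ± {s:.1f}" for m, s in agg.values()]
        lines.append("\t".join(["Average"] + cells))
    return "\n".join(lines)
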