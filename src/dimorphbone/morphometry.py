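"""3D pore labelling, per-pore descriptors, and lacuna/canal classification.

Pores are 26-connected components of the porosity mask. Each pore carries its
volume, equivalent spherical diameter (6V/pi)^(1/3), centroid, elongation
(sqrt of the largest/smallest principal second-moment ratio of the voxel
cloud) and maximum extent (range of voxel projections onto the principal
axis). Vascular canals are separated from osteocyte lacunae by a per-specimen
volume threshold set just below the smallest pore that satisfies a canal
shape-and-size criterion (high elongation, long extent); anything below a
noise floor is left unclassified ("noise").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BinaryMask

__all__ = [
    "PoreCatalog",
    "MorphometrySummary",
    "label_pores",
    "select_separation_threshold",
    "classify_pores",
    "summarize",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: columns of a pore catalog table, one row per pore
CATALOG_COLUMNS = [
    "pore_id", "n_voxels", "volume_um3", "diameter_um",
    "centroid_z_um", "centroid_y_um", "centroid_x_um",
    "elongation", "extent_um", "pore_class",
]


@dataclass
class PoreCatalog:
    """Labelled pores of one specimen plus the normalising cortical volume."""

    table: pd.DataFrame
    voxel_size_um: float
    cortical_solid_volume_um3: float = float("nan")
    separation_threshold_um3: float = float("nan")
    noise_floor_um3: float = float("nan")

    def __len__(self) -> int:
        return len(self.table)

    def volumes(self, pore_class: str | None = None) -> np.ndarray:
        t = self.table
        if pore_class is not None:
            t = t[t.pore_class == pore_class]
        return t.volume_um3.to_numpy()


@dataclass
class MorphometrySummary:
    """Scalar porosity indices (Lc.* = lacunae, Ca.* = canals).

    Densities are per mm^3 of cortical solid volume; volumes in µm³,
    diameters in µm; the three class fractions are percentages of total pore
    volume and sum to 100.
    """

    n_lacunae: int
    n_canals: int
    n_noise: int
    lc_dn_per_mm3: float
    lc_v_um3: float
    lc_dm_um: float
    ca_dn_per_mm3: float
    ca_v_um3: float
    ca_dm_um: float
    lacuna_pct: float
    canal_pct: float
    noise_pct: float
    ct_po_pct: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _pore_descriptors(coords: np.ndarray, vs: float) -> tuple[float, float]:
    """Elongation and principal extent (µm) of a voxel coordinate cloud.

    Each voxel contributes the second moment of a unit cube (1/12 on the
    diagonal), which regularises single-voxel and planar pores.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords) + np.eye(3) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    elong = float(np.sqrt(evals[-1] / evals[0]))
    proj = centered @ evecs[:, -1]
    extent = float(proj.max() - proj.min() + 1.0) * vs
    return elong, extent


def label_pores(porosity: BinaryMask,
                cortex_solid: BinaryMask | None = None) -> PoreCatalog:
    """Label 26-connected pores and compute per-pore descriptors.

    An empty mask yields an empty catalog, not an error.
    """
    vs = porosity.voxel_size_um
    vox_um3 = vs ** 3
    labels, n = ndimage.label(porosity.voxels, structure=_CONN26)
    rows = []
    if n:
        objects = ndimage.find_objects(labels)
        for i, sl in enumerate(objects, start=1):
            local = labels[sl] == i
            coords = np.argwhere(local).astype(float)
            coords += [s.start for s in sl]
            n_vox = len(coords)
            vol = n_vox * vox_um3
            elong, extent = _pore_descriptors(coords, vs)
            cz, cy, cx = coords.mean(axis=0) * vs
            rows.append({
                "pore_id": i,
                "n_voxels": n_vox,
                "volume_um3": vol,
                "diameter_um": (6.0 * vol / np.pi) ** (1.0 / 3.0),
                "centroid_z_um": cz, "centroid_y_um": cy, "centroid_x_um": cx,
                "elongation": elong,
                "extent_um": extent,
                "pore_class": None,
            })
    table = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    csv_um3 = cortex_solid.volume_um3() if cortex_solid is not None else float("nan")
    return PoreCatalog(table=table, voxel_size_um=vs,
                       cortical_solid_volume_um3=csv_um3)


def select_separation_threshold(catalog: PoreCatalog,
                                elongation_min: float = 3.0,
                                extent_min_um: float = 30.0,
                                eps: float = 0.01) -> float:
    """Per-specimen lacuna/canal volume threshold.

    Canal candidates are pores that look like canals (elongation >=
    ``elongation_min`` and principal extent >= ``extent_min_um``); the
    threshold is set a fraction ``eps`` below the smallest candidate volume.
    With no candidates the threshold is +inf (no pore is a canal).
    """
    t = catalog.table
    cand = t[(t.elongation >= elongation_min) & (t.extent_um >= extent_min_um)]
    if cand.empty:
        return float("inf")
    return float((1.0 - eps) * cand.volume_um3.min())


def classify_pores(catalog: PoreCatalog, threshold_um3: float,
                   noise_floor_um3: float | None = None) -> PoreCatalog:
    """Assign each pore to noise / lacuna / canal by volume.

    volume < noise floor -> noise; floor <= volume < threshold -> lacuna;
    volume >= threshold -> canal (the threshold is inclusive on the canal
    side). The default noise floor is 8 voxels.
    """
    if noise_floor_um3 is None:
        noise_floor_um3 = 8 * catalog.voxel_size_um ** 3
    if not threshold_um3 > noise_floor_um3:
        raise ValueError(
            f"separation threshold ({threshold_um3}) must exceed the "
            f"noise floor ({noise_floor_um3})")
    v = catalog.table.volume_um3.to_numpy()
    cls = np.where(v < noise_floor_um3, "noise",
                   np.where(v < threshold_um3, "lacuna", "canal"))
    table = catalog.table.copy()
    table["pore_class"] = cls if len(table) else table.pore_class
    return replace(catalog, table=table,
                   separation_threshold_um3=threshold_um3,
                   noise_floor_um3=noise_floor_um3)


def _mean_or_nan(x: np.ndarray) -> float:
    return float(np.mean(x)) if len(x) else float("nan")


def summarize(catalog: PoreCatalog) -> MorphometrySummary:
    """Porosity indices over a classified catalog.

    Densities use the cortical solid volume as denominator (1 mm³ = 1e9 µm³).
    Means over an empty class are reported as NaN (missing), not zero.
    """
    csv = catalog.cortical_solid_volume_um3
    if not csv > 0:
        raise ValueError("cortical solid volume must be > 0 to summarise")
    t = catalog.table
    lac, can = t[t.pore_class == "lacuna"], t[t.pore_class == "canal"]
    noi = t[t.pore_class == "noise"]
    total = float(t.volume_um3.sum())
    per_mm3 = 1e9 / csv

    def pct(sub: pd.DataFrame) -> float:
        return 100.0 * float(sub.volume_um3.sum()) / total if total else float("nan")

    return MorphometrySummary(
        n_lacunae=len(lac), n_canals=len(can), n_noise=len(noi),
        lc_dn_per_mm3=len(lac) * per_mm3,
        lc_v_um3=_mean_or_nan(lac.volume_um3.to_numpy()),
        lc_dm_um=_mean_or_nan(lac.diameter_um.to_numpy()),
        ca_dn_per_mm3=len(can) * per_mm3,
        ca_v_um3=_mean_or_nan(can.volume_um3.to_numpy()),
        ca_dm_um=_mean_or_nan(can.diameter_um.to_numpy()),
        lacuna_pct=pct(lac), canal_pct=pct(can), noise_pct=pct(noi),
        ct_po_pct=100.0 * total / csv,
    )
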