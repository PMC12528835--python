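"""Abstract ROI atlas: labeled voxel sets grouped into large-scale networks.

The default registry mirrors a 216-parcel whole-brain parcellation —
200 cortical parcels assigned to seven functional networks plus 16
subcortical parcels treated as an eighth network.  Geometry is abstract:
an ROI is a named set of voxel indices into a flat feature space, which
is all that pattern decoding requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ROI", "ROIAtlas", "NETWORKS", "CORTICAL_NETWORK_SIZES",
           "make_default_atlas", "make_atlas"]

NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal-attention",
    "salience/ventral-attention",
    "limbic",
    "control",
    "default",
    "subcortical",
)

#: Parcel counts per cortical network (sum 200); subcortical adds 16.
CORTICAL_NETWORK_SIZES = {
    "visual": 31,
    "somatomotor": 37,
    "dorsal-attention": 23,
    "salience/ventral-attention": 22,
    "limbic": 12,
    "control": 30,
    "default": 45,
}
N_SUBCORTICAL = 16


@dataclass(frozen=True)
class ROI:
    roi_id: int
    name: str
    network: str
    voxel_ids: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)


@dataclass
class ROIAtlas:
    """Disjoint ROIs over a flat voxel index space."""

    rois: dict[int, ROI]

    def __post_init__(self):
        seen: set[int] = set()
        for roi in self.rois.values():
            vox = set(int(v) for v in roi.voxel_ids)
            if seen & vox:
                raise ValueError(f"ROI {roi.roi_id} overlaps another ROI")
            seen |= vox
            if roi.network not in NETWORKS:
                raise ValueError(f"unknown network {roi.network!r}")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois.values())

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.rois)

    @property
    def networks(self) -> list[str]:
        return sorted({r.network for r in self.rois.values()},
                      key=NETWORKS.index)

    @property
    def n_voxels(self) -> int:
        return sum(r.n_voxels for r in self.rois.values())

    def network_of(self, roi_id: int) -> str:
        return self.rois[roi_id].network

    def rois_in_network(self, network: str) -> list[int]:
        return [i for i in self.roi_ids if self.rois[i].network == network]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"roi_id": r.roi_id, "name": r.name, "network": r.network,
                 "n_voxels": r.n_voxels} for r in self]
        return pd.DataFrame(rows).sort_values("roi_id").reset_index(drop=True)


def make_atlas(n_per_network: dict[str, int],
               voxels_per_roi: tuple[int, int] = (20, 60),
               seed: int = 0) -> ROIAtlas:
    """Build a synthetic atlas with the given parcel counts per network.

    Voxel counts per ROI are drawn uniformly from ``voxels_per_roi``
    (inclusive), and voxel ids tile a flat index space contiguously.
    """
    rng = np.random.default_rng(seed)
    rois: dict[int, ROI] = {}
    roi_id, next_vox = 0, 0
    for network, count in n_per_network.items():
        if network not in NETWORKS:
            raise ValueError(f"unknown network {network!r}")
        for k in range(count):
            n_vox = int(rng.integers(voxels_per_roi[0], voxels_per_roi[1] + 1))
            vox = np.arange(next_vox, next_vox + n_vox)
            short = network.split("/")[0]
            rois[roi_id] = ROI(roi_id, f"{short}_{k + 1}", network, vox)
            roi_id += 1
            next_vox += n_vox
    return ROIAtlas(rois)


def make_default_atlas(seed: int = 0,
                       voxels_per_roi: tuple[int, int] = (20, 60)) -> ROIAtlas:
    """The default 216-parcel atlas: 200 cortical ROIs over seven networks
    plus 16 subcortical ROIs as the eighth network."""
    sizes = dict(CORTICAL_NETWORK_SIZES)
    sizes["subcortical"] = N_SUBCORTICAL
    return make_atlas(sizes, voxels_per_roi=voxels_per_roi, seed=seed)
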