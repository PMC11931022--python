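"""Combined gray-matter / white-matter parcellation bookkeeping.

The analysis operates on a single 164-region scheme built from three label
sources: 100 cortical parcels, 14 subcortical structures and 50 white-matter
tracts.  Regions carry a tissue class; the WM family (50 regions) and GM
family (cortical + subcortical, 114 regions) define the two connectivity
strength statistics (WW-FCS and GW-FCS).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import RegionTimeSeries

__all__ = [
    "Region",
    "ParcellationScheme",
    "default_scheme",
    "generic_scheme",
    "combine_atlases",
    "extract_mean_timeseries",
]

TISSUE_CLASSES = ("cortical", "subcortical", "wm")


@dataclass(frozen=True)
class Region:
    id: int
    name: str
    hemisphere: str  # lh, rh or mid
    tissue_class: str


@dataclass
class ParcellationScheme:
    """Ordered region list with tissue classes and family masks."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        ids = [r.id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids are not unique")
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("region ids must be contiguous starting at 1")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names are not unique")
        for r in self.regions:
            if r.tissue_class not in TISSUE_CLASSES:
                raise ValueError(f"unknown tissue class {r.tissue_class!r}")
        self._index = {r.name: i for i, r in enumerate(self.regions)}

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def ids(self) -> np.ndarray:
        return np.array([r.id for r in self.regions])

    @property
    def tissue_classes(self) -> np.ndarray:
        return np.array([r.tissue_class for r in self.regions])

    @property
    def wm_indices(self) -> np.ndarray:
        """0-based positions of the white-matter family."""
        return np.flatnonzero(self.tissue_classes == "wm")

    @property
    def gm_indices(self) -> np.ndarray:
        """0-based positions of the gray-matter family (cortical + subcortical)."""
        return np.flatnonzero(self.tissue_classes != "wm")

    @property
    def n_wm(self) -> int:
        return self.wm_indices.size

    @property
    def n_gm(self) -> int:
        return self.gm_indices.size

    def index_of(self, name: str) -> int:
        if name not in self._index:
            raise KeyError(f"unknown region {name!r}")
        return self._index[name]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "id": [r.id for r in self.regions],
                "name": self.names,
                "hemisphere": [r.hemisphere for r in self.regions],
                "tissue_class": [r.tissue_class for r in self.regions],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParcellationScheme":
        df = pd.read_csv(path, sep="\t")
        return cls.from_table(df)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "ParcellationScheme":
        required = {"id", "name", "hemisphere", "tissue_class"}
        if not required.issubset(df.columns):
            raise ValueError(f"scheme table needs columns {sorted(required)}")
        return cls(
            tuple(
                Region(int(row.id), str(row.name), str(row.hemisphere), str(row.tissue_class))
                for row in df.itertuples(index=False)
            )
        )


# Cortical parcel layout: 50 parcels per hemisphere grouped into the seven
# canonical resting-state networks, with sub-component labels.
_CORTICAL_LAYOUT = (
    ("Vis", 8),
    ("SomMot", 8),
    ("DorsAttn_Post", 4),
    ("DorsAttn_FEF", 2),
    ("SalVentAttn_ParOper", 3),
    ("SalVentAttn_FrOper", 3),
    ("Limbic_OFC", 2),
    ("Limbic_TempPole", 2),
    ("Cont_Par", 3),
    ("Cont_PFCl", 3),
    ("Cont_pCun", 1),
    ("Cont_Cing", 1),
    ("Default_Temp", 3),
    ("Default_Par", 2),
    ("Default_PFC", 2),
    ("Default_PFCv", 2),
    ("Default_pCun", 1),
)

_SUBCORTICAL = (
    "Thalamus_Proper",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens_area",
)

_WM_MIDLINE = (
    "Middle_cerebellar_peduncle",
    "Pontine_crossing_tract",
    "Genu_of_corpus_callosum",
    "Body_of_corpus_callosum",
    "Splenium_of_corpus_callosum",
    "Fornix",
)

_WM_BILATERAL = (
    "Corticospinal_tract",
    "Medial_lemniscus",
    "Inferior_cerebellar_peduncle",
    "Superior_cerebellar_peduncle",
    "Cerebral_peduncle",
    "Anterior_limb_of_internal_capsule",
    "Posterior_limb_of_internal_capsule",
    "Retrolenticular_part_of_internal_capsule",
    "Anterior_corona_radiata",
    "Superior_corona_radiata",
    "Posterior_corona_radiata",
    "Posterior_thalamic_radiation",
    "Sagittal_stratum",
    "External_capsule",
    "Cingulum_cingulate_gyrus",
    "Cingulum_hippocampus",
    "Fornix_cres_stria_terminalis",
    "Superior_longitudinal_fasciculus",
    "Superior_fronto_occipital_fasciculus",
    "Inferior_fronto_occipital_fasciculus",
    "Uncinate_fasciculus",
    "Tapetum",
)


def default_scheme() -> ParcellationScheme:
    """The 164-region scheme: 100 cortical + 14 subcortical + 50 WM tracts."""
    regions: list[Region] = []
    rid = 1
    for hemi in ("lh", "rh"):
        for network, count in _CORTICAL_LAYOUT:
            for k in range(1, count + 1):
                regions.append(Region(rid, f"{hemi}_{network}_{k}", hemi, "cortical"))
                rid += 1
    for hemi in ("lh", "rh"):
        for name in _SUBCORTICAL:
            regions.append(Region(rid, f"{hemi}_{name}", hemi, "subcortical"))
            rid += 1
    for name in _WM_MIDLINE:
        regions.append(Region(rid, name, "mid", "wm"))
        rid += 1
    for name in _WM_BILATERAL:
        for hemi in ("lh", "rh"):
            regions.append(Region(rid, f"{hemi}_{name}", hemi, "wm"))
            rid += 1
    return ParcellationScheme(tuple(regions))


def generic_scheme(
    n_cortical: int = 100, n_subcortical: int = 14, n_wm: int = 50
) -> ParcellationScheme:
    """A scheme of arbitrary size with generated names (for small test cases)."""
    if n_cortical == 100 and n_subcortical == 14 and n_wm == 50:
        return default_scheme()
    regions: list[Region] = []
    rid = 1
    for i in range(n_cortical):
        regions.append(Region(rid, f"ctx_{i + 1:03d}", "lh" if i % 2 == 0 else "rh", "cortical"))
        rid += 1
    for i in range(n_subcortical):
        regions.append(Region(rid, f"subctx_{i + 1:03d}", "lh" if i % 2 == 0 else "rh", "subcortical"))
        rid += 1
    for i in range(n_wm):
        regions.append(Region(rid, f"wm_{i + 1:03d}", "mid", "wm"))
        rid += 1
    return ParcellationScheme(tuple(regions))


def combine_atlases(
    atlases: Sequence[tuple[nib.Nifti1Image, pd.DataFrame]],
) -> tuple[nib.Nifti1Image, ParcellationScheme, int]:
    """Merge label volumes into one contiguous id space.

    ``atlases`` is an ordered list of (label image, lookup table) pairs; each
    lookup table has columns ``id, name, hemisphere, tissue_class`` describing
    the labels of that volume.  Labels are re-indexed 1..N preserving atlas
    order and, within an atlas, original-id order.  Voxels claimed by more
    than one atlas are assigned by precedence (earlier atlas wins); the
    conflict count is returned.
    """
    if not atlases:
        raise ValueError("no atlases supplied")
    ref_img, _ = atlases[0]
    ref_shape = ref_img.shape
    ref_affine = ref_img.affine
    combined = np.zeros(ref_shape, dtype=np.int32)
    regions: list[Region] = []
    rid = 0
    n_conflicts = 0
    for img, lookup in atlases:
        if img.shape != ref_shape or not np.allclose(img.affine, ref_affine):
            raise ValueError("atlas volumes do not share grid and orientation")
        data = np.asarray(img.dataobj).astype(np.int64)
        lookup = lookup.sort_values("id")
        if lookup["id"].duplicated().any():
            raise ValueError("duplicate labels within one atlas")
        if len(lookup) == 0:
            raise ValueError("empty atlas lookup table")
        for row in lookup.itertuples(index=False):
            rid += 1
            mask = data == row.id
            if not mask.any():
                raise ValueError(f"label {row.id} ({row.name}) has no voxels")
            taken = mask & (combined != 0)
            n_conflicts += int(taken.sum())
            combined[mask & (combined == 0)] = rid
            regions.append(Region(rid, str(row.name), str(row.hemisphere), str(row.tissue_class)))
    scheme = ParcellationScheme(tuple(regions))
    out = nib.Nifti1Image(combined, ref_affine)
    return out, scheme, n_conflicts


def extract_mean_timeseries(
    bold: nib.Nifti1Image,
    labels: nib.Nifti1Image,
    scheme: ParcellationScheme,
    tr: float | None = None,
) -> tuple[RegionTimeSeries, list[str]]:
    """Unweighted per-region mean of the BOLD signal at each frame.

    Regions without any labelled voxel get NaN series and are returned in the
    ``missing`` list.  ``tr`` defaults to the BOLD header's fourth zoom.
    """
    if bold.shape[:3] != labels.shape[:3]:
        raise ValueError("BOLD and label volumes do not share a grid")
    if tr is None:
        zooms = bold.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    data = np.asarray(bold.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("BOLD volume must be 4D")
    lab = np.asarray(labels.dataobj).astype(np.int64).ravel()
    flat = data.reshape(-1, data.shape[3])
    n = len(scheme)
    counts = np.bincount(lab, minlength=n + 1)[1 : n + 1]
    sums = np.zeros((n + 1, data.shape[3]))
    np.add.at(sums, lab, flat)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums[1:] / counts[:, None]
    missing = [scheme.names[i] for i in np.flatnonzero(counts == 0)]
    if len(missing) == n:
        raise ValueError("no labelled voxels for any region")
    ts = RegionTimeSeries(means, scheme.ids, tr)
    return ts, missing
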