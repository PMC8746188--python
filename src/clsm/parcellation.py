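"""Dual-stream ROI parcellation bookkeeping.

The default configuration models a parcellation with 26 dorsal-stream ROIs
confined to the left hemisphere plus 41 ventral-stream ROIs per hemisphere
(bilateral), 108 ROIs in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = ["ROI", "ParcellationSpec", "make_parcellation"]

HEMISPHERES = ("L", "R")
STREAMS = ("dorsal", "ventral")


@dataclass(frozen=True)
class ROI:
    """A single region of interest."""

    roi_id: int
    name: str
    hemisphere: str
    stream: str
    subregion: Optional[int] = None

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}")
        if self.stream not in STREAMS:
            raise ValueError(f"stream must be one of {STREAMS}, got {self.stream!r}")


@dataclass(frozen=True)
class ParcellationSpec:
    """An ordered collection of ROIs; defines node and edge indexing.

    Invariants: roi_ids are unique, contiguous and equal to list position.
    """

    rois: tuple[ROI, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [r.roi_id for r in self.rois]
        if ids != list(range(len(ids))):
            raise ValueError("roi_ids must be 0-based, unique and contiguous")
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self) -> Iterator[ROI]:
        return iter(self.rois)

    def __getitem__(self, roi_id: int) -> ROI:
        return self.rois[roi_id]

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def index_of(self, name: str) -> int:
        """Map an ROI label to its 0-based id; raises KeyError if unknown."""
        try:
            return self._name_index[name]
        except AttributeError:
            object.__setattr__(
                self, "_name_index", {r.name: r.roi_id for r in self.rois}
            )
            return self._name_index[name]

    def ids_where(
        self,
        hemisphere: Optional[str] = None,
        stream: Optional[str] = None,
    ) -> list[int]:
        """ROI ids matching the given hemisphere and/or stream."""
        out = []
        for r in self.rois:
            if hemisphere is not None and r.hemisphere != hemisphere:
                continue
            if stream is not None and r.stream != stream:
                continue
            out.append(r.roi_id)
        return out

    @property
    def left_ids(self) -> list[int]:
        return self.ids_where(hemisphere="L")

    @property
    def right_ids(self) -> list[int]:
        return self.ids_where(hemisphere="R")


def make_parcellation(
    n_dorsal_left: int = 26, n_ventral_per_hemi: int = 41
) -> ParcellationSpec:
    """Build the dual-stream parcellation.

    Dorsal-stream ROIs are left-hemisphere only; ventral-stream ROIs are
    bilateral with ``n_ventral_per_hemi`` per hemisphere, so the total ROI
    count is ``n_dorsal_left + 2 * n_ventral_per_hemi`` (108 with the
    defaults).
    """
    if n_dorsal_left < 1 or n_ventral_per_hemi < 1:
        raise ValueError(
            "ROI counts must be positive, got "
            f"n_dorsal_left={n_dorsal_left}, n_ventral_per_hemi={n_ventral_per_hemi}"
        )
    rois: list[ROI] = []

    def add(name: str, hemi: str, stream: str, sub: int) -> None:
        rois.append(ROI(len(rois), name, hemi, stream, sub))

    for k in range(n_dorsal_left):
        add(f"L_dorsal_({k + 1})", "L", "dorsal", k + 1)
    for k in range(n_ventral_per_hemi):
        add(f"L_ventral_({k + 1})", "L", "ventral", k + 1)
    for k in range(n_ventral_per_hemi):
        add(f"R_ventral_({k + 1})", "R", "ventral", k + 1)
    return ParcellationSpec(tuple(rois))
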