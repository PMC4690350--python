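"""In-memory containers shared across the pipeline stages.

A :class:`FieldImage` holds the channels of one microscope field (a DNA
stain plus two protein channels), a :class:`CompartmentMasks` the labeled
nucleus / nucleolus / cytoplasm regions derived from it.  Labels are
positive integers shared across the mask layers; 0 is background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: canonical channel roles, in storage order
DNA = "dna_stain"
CHANNEL_A = "channel_A"
CHANNEL_B = "channel_B"
PROTEIN_CHANNELS = (CHANNEL_A, CHANNEL_B)

#: compartments a cell is decomposed into
NUCLEUS = "nucleus"
NUCLEOLUS = "nucleolus"
CYTOPLASM = "cytoplasm"
COMPARTMENTS = (NUCLEUS, CYTOPLASM, NUCLEOLUS)

#: µm² covered by one pixel on the original acquisition setup
DEFAULT_PIXEL_AREA = 0.14


@dataclass
class FieldImage:
    """One imaged field: co-registered 2D channels plus acquisition metadata.

    Parameters
    ----------
    channels
        Mapping from channel role (``dna_stain``, ``channel_A``,
        ``channel_B``; optionally ``nuclear_marker``) to a 2D float or
        integer array.  All channels must share one shape and be
        non-negative.
    pixel_area
        Area of one pixel in µm².
    condition, replicate, field_id
        Experimental labels carried through to every output table.
    """

    channels: dict[str, np.ndarray]
    pixel_area: float = DEFAULT_PIXEL_AREA
    condition: str = ""
    replicate: str = ""
    field_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        (self.shape,) = shapes
        if len(self.shape) != 2:
            raise ValueError("channels must be 2D arrays")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        for name, arr in self.channels.items():
            if np.asarray(arr).min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


@dataclass
class CompartmentMasks:
    """Per-cell labeled compartment masks for one field.

    All four label images share cell IDs: the pixels of nucleus label *i*
    lie inside cell label *i*, nucleolus pixels of ID *i* lie inside
    nucleus *i*, and nucleus and cytoplasm of a given cell are disjoint.
    ``border_excluded`` lists IDs that were dropped because their nucleus
    touched the image border.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    nucleolus_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    border_excluded: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        shapes = {
            self.cell_labels.shape,
            self.nucleus_labels.shape,
            self.nucleolus_labels.shape,
            self.cytoplasm_labels.shape,
        }
        if len(shapes) != 1:
            raise ValueError("mask layers must share one shape")
        (self.shape,) = shapes

    @property
    def cell_ids(self) -> list[int]:
        ids = np.unique(self.nucleus_labels)
        return [int(i) for i in ids if i > 0]

    def validate(self) -> None:
        """Assert the containment/disjointness invariants; raise on violation."""
        for cid in self.cell_ids:
            nuc = self.nucleus_labels == cid
            cyt = self.cytoplasm_labels == cid
            cell = self.cell_labels == cid
            nlo = self.nucleolus_labels == cid
            if np.any(nlo & ~nuc):
                raise AssertionError(f"nucleolus {cid} escapes its nucleus")
            if np.any(nuc & cyt):
                raise AssertionError(f"nucleus/cytoplasm overlap for cell {cid}")
            if np.any((nuc | cyt) & ~cell):
                raise AssertionError(f"nucleus∪cytoplasm escapes cell {cid}")

    def compartment_mask(self, cell_id: int, compartment: str,
                         nucleus_excludes_nucleoli: bool = False) -> np.ndarray:
        """Boolean pixel mask of one compartment of one cell."""
        if compartment == NUCLEUS:
            m = self.nucleus_labels == cell_id
            if nucleus_excludes_nucleoli:
                m = m & ~(self.nucleolus_labels == cell_id)
            return m
        if compartment == CYTOPLASM:
            return self.cytoplasm_labels == cell_id
        if compartment == NUCLEOLUS:
            return self.nucleolus_labels == cell_id
        raise KeyError(compartment)


def relabel_consistently(reference: np.ndarray, others: Iterable[np.ndarray],
                         keep: Iterable[int]) -> None:
    """Zero out, in-place, labels not in ``keep`` across all mask layers."""
    keep = set(int(k) for k in keep)
    for arr in (reference, *others):
        drop = ~np.isin(arr, list(keep) + [0])
        arr[drop] = 0
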