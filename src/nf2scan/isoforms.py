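"""Protein isoform architectures and residue coordinate mapping.

NF2 (merlin) is expressed in several splice isoforms. The canonical
isoform 1 is 595 residues long; isoform 7 skips exons 2-3 (residues
39-121 of isoform 1, most of the F1 FERM subdomain and the start of F2)
and carries an alternatively spliced C-terminus that begins at isoform-1
residue 580 and is five residues shorter, giving a 507-residue protein.

This module represents such interval-deletion isoform relationships and
maps residue indices between the reference (isoform-1) numbering and the
alternate isoform numbering.  Variant labels in this package always use
isoform-1 numbering (the convention of the NF2 literature), while the
mutagenic library itself is built on the isoform-7 ORF, so the
conversion is explicit throughout.

Coordinates are 1-based and intervals are closed/inclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Tuple

import yaml

__all__ = [
    "MapStatus",
    "IsoformSpec",
    "RegionAnnotation",
    "IsoformMap",
    "nf2_isoform_specs",
    "nf2_map",
    "NF2_REGIONS",
]


class MapStatus(enum.Enum):
    """Outcome of mapping one residue index between isoforms."""

    IDENTICAL = "identical"
    DIVERGENT_SEQUENCE = "divergent_sequence"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class IsoformSpec:
    """Architecture of one isoform relative to a reference isoform.

    Parameters
    ----------
    name : str
        Isoform identifier (e.g. ``"NF2-iso7"``).
    reference_length : int
        Length of the reference isoform in residues.
    deletion : tuple of (int, int), optional
        Closed interval of reference residues absent from this isoform,
        strictly inside ``[1, reference_length]``. ``None`` for no deletion.
    cterm_divergence_start : int, optional
        Reference residue index at which the alternate C-terminus begins.
        Positions from here on are positionally mapped but their residue
        identity differs. ``None`` if the C-terminus is shared.
    cterm_delta : int
        Signed length difference of the alternate C-terminus in residues
        (negative = shorter than the reference tail).
    """

    name: str
    reference_length: int
    deletion: Optional[Tuple[int, int]] = None
    cterm_divergence_start: Optional[int] = None
    cterm_delta: int = 0

    def __post_init__(self) -> None:
        if self.deletion is not None:
            d1, d2 = self.deletion
            if not (1 < d1 <= d2 < self.reference_length):
                raise ValueError(
                    f"deletion {self.deletion} must lie strictly inside "
                    f"[1, {self.reference_length}]"
                )
        if self.cterm_divergence_start is not None:
            if not (1 <= self.cterm_divergence_start <= self.reference_length):
                raise ValueError("cterm_divergence_start outside the reference")

    @property
    def deletion_length(self) -> int:
        if self.deletion is None:
            return 0
        return self.deletion[1] - self.deletion[0] + 1

    @property
    def length(self) -> int:
        """Isoform length implied by the architecture."""
        return self.reference_length - self.deletion_length + self.cterm_delta


@dataclass(frozen=True)
class RegionAnnotation:
    """A named region (domain / helix / cluster) in one isoform's coordinates."""

    name: str
    isoform: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad interval for region {self.name}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


class IsoformMap:
    """Residue-index mapping between a reference isoform and an alternate one.

    Built from an :class:`IsoformSpec`; the forward direction maps
    reference (isoform-1) positions to alternate-isoform positions.
    """

    def __init__(self, spec: IsoformSpec):
        self.spec = spec
        ref_len = spec.reference_length
        if spec.deletion is not None:
            self._del_start, self._del_end = spec.deletion
        else:
            # empty deletion sentinel past the end: nothing is deleted
            self._del_start, self._del_end = ref_len + 1, ref_len
        self._offset = self.spec.deletion_length
        if spec.cterm_divergence_start is not None:
            self._div_start = spec.cterm_divergence_start
            # last reference position that still has a positional partner
            # in the (possibly shorter/longer) alternate tail
            alt_tail_len = ref_len - self._div_start + 1 + spec.cterm_delta
            self._div_end = self._div_start + alt_tail_len - 1
        else:
            self._div_start = self._div_end = None

    # -- reference -> alternate ------------------------------------------------

    def ref_to_alt(self, pos: int) -> Tuple[Optional[int], MapStatus]:
        """Map a reference residue index into alternate-isoform numbering."""
        if not 1 <= pos <= self.spec.reference_length:
            raise ValueError(
                f"position {pos} outside reference [1, {self.spec.reference_length}]"
            )
        if self._del_start <= pos <= self._del_end:
            return None, MapStatus.UNMAPPED
        mapped = pos - self._offset if pos > self._del_end else pos
        if self._div_start is not None and pos >= self._div_start:
            if pos > self._div_end:
                return None, MapStatus.UNMAPPED
            return mapped, MapStatus.DIVERGENT_SEQUENCE
        return mapped, MapStatus.IDENTICAL

    # -- alternate -> reference ------------------------------------------------

    def alt_to_ref(self, pos: int) -> Tuple[Optional[int], MapStatus]:
        """Exact inverse of :meth:`ref_to_alt` on the mappable range."""
        if not 1 <= pos <= self.spec.length:
            raise ValueError(
                f"position {pos} outside isoform [1, {self.spec.length}]"
            )
        ref = pos if pos < self._del_start else pos + self._offset
        if self._div_start is not None and ref >= self._div_start:
            return ref, MapStatus.DIVERGENT_SEQUENCE
        return ref, MapStatus.IDENTICAL


# -- NF2 built-ins -------------------------------------------------------------


def _load_builtin() -> dict:
    text = resources.files("nf2scan.data").joinpath("isoforms_nf2.yaml").read_text()
    return yaml.safe_load(text)


def nf2_isoform_specs() -> dict[str, IsoformSpec]:
    """The shipped NF2 isoform specs (isoform 1 reference, isoform 7 alternate)."""
    raw = _load_builtin()
    specs = {}
    for name, d in raw["isoforms"].items():
        deletion = tuple(d["deletion"]) if d.get("deletion") else None
        specs[name] = IsoformSpec(
            name=name,
            reference_length=raw["reference_length"],
            deletion=deletion,
            cterm_divergence_start=d.get("cterm_divergence_start"),
            cterm_delta=d.get("cterm_delta", 0),
        )
    return specs


def nf2_map() -> IsoformMap:
    """Isoform-1 <-> isoform-7 residue map for NF2.

    ``ref_to_alt`` maps isoform-1 positions to isoform-7; positions 39-121
    (deleted in isoform 7) and 591-595 (isoform-1-only tail) are unmapped,
    and 580-590 map positionally onto the divergent exon-16 tail.
    """
    return IsoformMap(nf2_isoform_specs()["NF2-iso7"])


#: Mutational-cluster and domain annotations in isoform-7 coordinates.
#: The alpha-2H cluster sits around residue 310 and alpha-3H proximal to
#: residues 350-400 of isoform 7; F1/F2/F3 are the FERM subdomains
#: (isoform-7 coordinates, i.e. F1 is mostly absent from this isoform).
NF2_REGIONS: tuple[RegionAnnotation, ...] = (
    RegionAnnotation("F1", "NF2-iso7", 1, 38),
    RegionAnnotation("F2", "NF2-iso7", 39, 130),
    RegionAnnotation("F3", "NF2-iso7", 131, 230),
    RegionAnnotation("a1F3", "NF2-iso7", 218, 240),
    RegionAnnotation("a2H", "NF2-iso7", 295, 325),
    RegionAnnotation("a3H", "NF2-iso7", 350, 400),
)
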