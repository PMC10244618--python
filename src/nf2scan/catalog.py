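"""Programmed single-codon substitution catalogs (AKEL scans).

The mutagenic library replaces every codon of the target ORF with each of
four fixed replacement codons -- alanine (GCT), lysine (AAA), glutamic
acid (GAA) and leucine (TTG) -- one substitution per molecule.  The
catalog of (codon position, wild-type codon -> mutant codon) entries is
the contract between library design, the screen simulator and the
mutant-calling / scoring stages.

Entries whose replacement codon equals the wild-type codon are suppressed
(they are unobservable in sequencing); entries that change the codon but
not the encoded residue are kept and flagged ``protein_synonymous`` --
they are sequencable and serve as internal negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .isoforms import IsoformMap, MapStatus

__all__ = ["AKEL_CODONS", "MutantCatalogEntry", "design_catalog",
           "catalog_to_tsv", "catalog_from_tsv", "translate_codon",
           "variant_label"]

#: The four programmed replacement codons of the AKEL scan.
AKEL_CODONS: tuple[str, ...] = ("GCT", "AAA", "GAA", "TTG")

_TABLE = standard_dna_table.forward_table


def translate_codon(codon: str) -> str:
    """Translate one DNA codon under the standard code ('*' for stop)."""
    return _TABLE.get(codon, "*")


@dataclass(frozen=True)
class MutantCatalogEntry:
    codon_index: int            # 1-based codon position in the ORF
    wt_codon: str
    mut_codon: str
    wt_aa: str
    mut_aa: str
    protein_synonymous: bool


def _validate_cds(cds: str) -> str:
    cds = cds.upper()
    if set(cds) - set("ACGT"):
        raise ValueError("CDS contains non-ACGT characters")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    aa = str(Seq(cds).translate())
    if "*" in aa[:-1]:
        raise ValueError(f"internal stop codon at codon {aa.index('*') + 1}")
    return cds


def design_catalog(
    cds: str,
    codon_set: Sequence[str] = AKEL_CODONS,
    iso_map: Optional[IsoformMap] = None,
) -> pd.DataFrame:
    """Enumerate the programmed substitution catalog for an ORF.

    Parameters
    ----------
    cds : str
        Coding sequence (length divisible by 3, no internal stop).
    codon_set : sequence of str
        Replacement codons; one entry is emitted per position per codon
        whose DNA differs from the wild-type codon.
    iso_map : IsoformMap, optional
        If given, each entry additionally carries ``iso1_position`` (the
        reference-isoform residue index of the codon, or <NA> when the
        position has no reference partner) and a ``label`` such as
        ``"Q147A"`` in reference numbering.

    Returns
    -------
    pandas.DataFrame
        Columns: codon_index, wt_codon, mut_codon, wt_aa, mut_aa,
        protein_synonymous [, iso1_position, label].
    """
    cds = _validate_cds(cds)
    for c in codon_set:
        if len(c) != 3 or set(c) - set("ACGT"):
            raise ValueError(f"bad replacement codon {c!r}")
    rows = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        wt = cds[3 * i: 3 * i + 3]
        wt_aa = translate_codon(wt)
        for mut in codon_set:
            if mut == wt:
                continue
            mut_aa = translate_codon(mut)
            rows.append((i + 1, wt, mut, wt_aa, mut_aa, wt_aa == mut_aa))
    df = pd.DataFrame(
        rows,
        columns=["codon_index", "wt_codon", "mut_codon", "wt_aa", "mut_aa",
                 "protein_synonymous"],
    )
    if iso_map is not None:
        iso1_pos, labels = [], []
        for idx, wt_aa, mut_aa in zip(df["codon_index"], df["wt_aa"], df["mut_aa"]):
            ref, status = iso_map.alt_to_ref(int(idx))
            if status is MapStatus.UNMAPPED or ref is None:
                iso1_pos.append(pd.NA)
                labels.append(f"{wt_aa}{idx}{mut_aa}(iso7)")
            else:
                iso1_pos.append(ref)
                labels.append(f"{wt_aa}{ref}{mut_aa}")
        df["iso1_position"] = pd.array(iso1_pos, dtype="Int64")
        df["label"] = labels
    return df


def variant_label(entry: MutantCatalogEntry, iso_map: IsoformMap) -> str:
    """Reference-numbering variant label (e.g. S518D) for a catalog entry."""
    ref, status = iso_map.alt_to_ref(entry.codon_index)
    if ref is None:
        return f"{entry.wt_aa}{entry.codon_index}{entry.mut_aa}(iso7)"
    return f"{entry.wt_aa}{ref}{entry.mut_aa}"


def catalog_to_tsv(df: pd.DataFrame, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def catalog_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
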