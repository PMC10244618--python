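"""Codon-level mutant calling from paired-end reads of a single known ORF.

The pipeline stage between raw FASTQ and enrichment scoring:

1. read pairs are collapsed to unique (seq1, seq2) pairs with their
   multiplicities -- the counting unit downstream is the unique pair
   weighted by multiplicity;
2. each mate is placed on the reference by a seed-and-verify aligner
   (k-mer anchoring plus mismatch verification; bounded-gap fallback via
   edlib when the ungapped placement fails).  Insertions and deletions
   are locally removed: inserted bases are dropped and deleted reference
   positions are masked, and the read is flagged ``indel_corrected``;
3. mismatches are grouped per codon (1-3 nt changes within one codon are
   one codon call).  A codon is callable in a pair only when all three
   of its bases are covered by the sequenced mates; positions where the
   two mates disagree are voided for that pair;
4. read-level co-occurrence of calls on the same pair is recorded, which
   feeds two confidence filters: exclusion of reads dominated by a
   co-occurring secondary mutation (> 0.8 of the primary signal by
   default) and removal of indel-corrected low-support calls (< 0.7 of
   the strongest signal at the locus by default).

The exact operand of the 0.8 / 0.7 "maximal signal" cutoffs used in
existing screens of this kind is not standardized; both rules are implemented behind named, configurable
thresholds (see :func:`filter_secondary` and
:func:`filter_low_confidence` for the interpretation used here).
"""

from __future__ import annotations

import copy
from collections import defaultdict
from dataclasses import dataclass, field

from typing import Iterable, Iterator, Optional

import edlib
import numpy as np
import pandas as pd
import pysam

__all__ = [
    "UniquePair", "AlignedRead", "SampleCounts", "ReferenceAligner",
    "read_fastq_pairs", "read_sam_pairs", "dedup_pairs",
    "call_codon_mutations", "call_sample",
    "filter_secondary", "filter_low_confidence",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# input plumbing
# ---------------------------------------------------------------------------

def read_fastq_pairs(r1_path, r2_path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, seq1, seq2) from a FASTQ pair (plain or gzip)."""
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            n1 = e1.name.removesuffix("/1")
            n2 = e2.name.removesuffix("/2")
            if n1 != n2:
                raise ValueError(f"mate-name mismatch: {e1.name} vs {e2.name}")
            yield n1, e1.sequence.upper(), e2.sequence.upper()
    # pysam stops at the shorter file; verify both exhausted
    _check_same_length(r1_path, r2_path)


def _check_same_length(r1_path, r2_path) -> None:
    n1 = sum(1 for _ in pysam.FastxFile(str(r1_path)))
    n2 = sum(1 for _ in pysam.FastxFile(str(r2_path)))
    if n1 != n2:
        raise ValueError(f"mate-count mismatch: {n1} vs {n2}")


def read_sam_pairs(sam_path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, seq1, seq2) pairs from a SAM file (by query name)."""
    first: dict[str, str] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary or rec.query_sequence is None:
                continue
            seq = rec.query_sequence.upper()
            if rec.is_reverse:
                seq = _revcomp(seq)
            if rec.query_name in first:
                if rec.is_read1:
                    yield rec.query_name, seq, first.pop(rec.query_name)
                else:
                    yield rec.query_name, first.pop(rec.query_name), seq
            else:
                first[rec.query_name] = seq


@dataclass
class UniquePair:
    seq1: str
    seq2: str
    multiplicity: int
    first_name: str


def dedup_pairs(pairs: Iterable[tuple[str, str, str]]) -> list[UniquePair]:
    """Collapse identical (seq1, seq2) pairs, keeping multiplicities."""
    seen: dict[tuple[str, str], UniquePair] = {}
    for name, s1, s2 in pairs:
        key = (s1, s2)
        up = seen.get(key)
        if up is None:
            seen[key] = UniquePair(s1, s2, 1, name)
        else:
            up.multiplicity += 1
    return list(seen.values())


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedRead:
    """A mate placed on the reference, indels locally removed.

    ``obs`` holds the observed base (uint8 ASCII) for each reference
    position in ``[offset, offset + span)``; ``mask`` is False at
    reference positions without a usable observation (deletions).
    """

    offset: int
    obs: np.ndarray
    mask: np.ndarray
    indel_removed: bool
    identity: float

    @property
    def span(self) -> int:
        return len(self.obs)


class ReferenceAligner:
    """Seed-and-verify placement of short reads on one known ORF.

    Exact k-mer seeds anchor candidate offsets; the best ungapped
    placement is kept when its identity passes ``min_identity``.
    Otherwise a bounded-gap infix alignment (edlib) is attempted and
    indels are locally removed.  Reads failing both are reported as
    unalignable, never fatal.
    """

    def __init__(self, reference: str, k: int = 25, min_identity: float = 0.8,
                 fallback_k: int = 12):
        self.reference = reference.upper()
        self.k = k
        self.fallback_k = fallback_k
        self.min_identity = min_identity
        self.ref_arr = np.frombuffer(self.reference.encode(), dtype=np.uint8)
        self.index = self._build_index(k)
        self._fallback_index: Optional[dict[str, list[int]]] = None

    def _build_index(self, k: int) -> dict[str, list[int]]:
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(self.reference) - k + 1):
            index[self.reference[i:i + k]].append(i)
        return index

    def _seed_positions(self, L: int, k: int, stride: int) -> list[int]:
        if L < k:
            return []
        pos = list(range(0, L - k + 1, stride))
        if pos[-1] != L - k:
            pos.append(L - k)
        return pos

    def _candidates(self, seq: str) -> list[int]:
        """Candidate offsets from exact k-mer seeds; the first anchored seed
        usually suffices, a denser small-k pass rescues short reads whose
        long seeds all straddle a mutation."""
        offs: list[int] = []
        L = len(seq)
        for sp in self._seed_positions(L, self.k, self.k):
            for ref_pos in self.index.get(seq[sp:sp + self.k], ()):
                off = ref_pos - sp
                if 0 <= off <= len(self.reference) - L and off not in offs:
                    offs.append(off)
            if offs:
                return offs
        k2 = self.fallback_k
        if L >= k2:
            if self._fallback_index is None:
                self._fallback_index = self._build_index(k2)
            for sp in self._seed_positions(L, k2, max(k2 // 2, 1)):
                for ref_pos in self._fallback_index.get(seq[sp:sp + k2], ()):
                    off = ref_pos - sp
                    if 0 <= off <= len(self.reference) - L and off not in offs:
                        offs.append(off)
                if len(offs) >= 8:
                    break
        return offs

    def _ungapped(self, seq: str) -> Optional[AlignedRead]:
        best: Optional[AlignedRead] = None
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for off in self._candidates(seq):
            nmis = int(np.count_nonzero(arr != self.ref_arr[off:off + len(arr)]))
            ident = 1.0 - nmis / len(arr)
            if best is None or ident > best.identity:
                best = AlignedRead(off, arr, np.ones(len(arr), bool), False, ident)
        if best is not None and best.identity >= self.min_identity:
            return best
        return None

    def _gapped(self, seq: str) -> Optional[AlignedRead]:
        max_ed = int(len(seq) * (1.0 - self.min_identity)) + 3
        res = edlib.align(seq, self.reference, mode="HW", task="path", k=max_ed)
        if res["editDistance"] < 0 or not res["locations"]:
            return None
        start, end = res["locations"][0]
        end += 1
        span = end - start
        obs = np.zeros(span, dtype=np.uint8)
        mask = np.zeros(span, bool)
        qi, ri = 0, 0
        indel = False
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "=XM":
                obs[ri:ri + n] = np.frombuffer(seq[qi:qi + n].encode(), np.uint8)
                mask[ri:ri + n] = True
                qi += n
                ri += n
            elif ch == "I":      # extra bases in the read: drop them
                qi += n
                indel = True
            elif ch == "D":      # reference positions with no observation
                ri += n
                indel = True
        identity = 1.0 - res["editDistance"] / len(seq)
        if identity < self.min_identity:
            return None
        return AlignedRead(start, obs, mask, indel, identity)

    def align(self, seq: str, try_revcomp: bool = True) -> Optional[AlignedRead]:
        """Best placement of ``seq`` (or its reverse complement)."""
        if len(seq) < 3:
            return None
        hits = []
        for s in ((seq, _revcomp(seq)) if try_revcomp else (seq,)):
            a = self._ungapped(s)
            if a is not None:
                hits.append(a)
        if hits:
            return max(hits, key=lambda a: a.identity)
        for s in ((seq, _revcomp(seq)) if try_revcomp else (seq,)):
            a = self._gapped(s)
            if a is not None:
                hits.append(a)
        if hits:
            return max(hits, key=lambda a: a.identity)
        return None


# ---------------------------------------------------------------------------
# per-sample counts
# ---------------------------------------------------------------------------

Call = tuple[int, str]  # (1-based codon index, observed codon)


@dataclass
class SampleCounts:
    """Per-sample codon-level mutation counts with co-occurrence records."""

    sample_id: str
    n_codons: int
    counts: dict[Call, int] = field(default_factory=dict)
    coverage: np.ndarray = None  # per-codon pair coverage, weighted
    cooc: dict[Call, dict[Call, int]] = field(default_factory=dict)
    ambiguous: dict[Call, int] = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    filter_log: list = field(default_factory=list)

    def __post_init__(self):
        if self.coverage is None:
            self.coverage = np.zeros(self.n_codons, dtype=np.int64)

    def count(self, call: Call) -> int:
        return self.counts.get(call, 0)

    def total_mutant_reads(self) -> int:
        return int(sum(self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [(pos, codon, n, int(self.coverage[pos - 1]))
                for (pos, codon), n in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["codon_index", "codon", "count",
                                           "coverage"])

    def to_tsv(self, path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# sample={self.sample_id} n_codons={self.n_codons}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, sample_id: Optional[str] = None) -> "SampleCounts":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
        df = pd.read_csv(path, sep="\t", comment="#")
        n_codons = int(meta.get("n_codons", df["codon_index"].max()))
        sc = cls(sample_id or meta.get("sample", str(path)), n_codons)
        for _, r in df.iterrows():
            sc.counts[(int(r.codon_index), r.codon)] = int(r["count"])
            sc.coverage[int(r.codon_index) - 1] = int(r.coverage)
        return sc


def _merge_codon_calls(
    mates: list[AlignedRead], ref_arr: np.ndarray, n_codons: int
) -> tuple[list[Call], np.ndarray]:
    """Merge aligned mates into per-pair codon calls + callable-codon flags.

    A position covered by both mates with disagreeing bases is voided;
    a codon is callable only when all three bases are covered.
    """
    lo = min(a.offset for a in mates)
    hi = max(a.offset + a.span for a in mates)
    obs = np.zeros(hi - lo, dtype=np.uint8)
    cov = np.zeros(hi - lo, dtype=bool)
    for a in mates:
        sl = slice(a.offset - lo, a.offset - lo + a.span)
        both = cov[sl] & a.mask
        disagree = both & (obs[sl] != a.obs)
        new = a.mask & ~cov[sl]
        obs_sl = obs[sl]
        obs_sl[new] = a.obs[new]
        obs[sl] = obs_sl
        cov[sl] |= a.mask
        if disagree.any():
            cov_sl = cov[sl]
            cov_sl[disagree] = False
            cov[sl] = cov_sl
    first_codon = -(-lo // 3)          # ceil
    last_codon = hi // 3               # exclusive
    callable_flags = np.zeros(n_codons, dtype=bool)
    calls: list[Call] = []
    if first_codon >= last_codon:
        return calls, callable_flags
    span_codons = np.arange(first_codon, last_codon)
    base0 = span_codons * 3 - lo
    ok = cov[base0] & cov[base0 + 1] & cov[base0 + 2]
    callable_flags[span_codons[ok]] = True
    mism = cov & (obs != ref_arr[lo:hi])
    if mism.any():
        for c in np.unique((np.nonzero(mism)[0] + lo) // 3):
            c = int(c)
            if first_codon <= c < last_codon and callable_flags[c]:
                b0 = c * 3 - lo
                codon = bytes(obs[b0:b0 + 3]).decode()
                calls.append((c + 1, codon))
    return calls, callable_flags


def call_codon_mutations(
    unique_pairs: Iterable[UniquePair],
    aligner: ReferenceAligner,
    sample_id: str = "sample",
) -> SampleCounts:
    """Align unique pairs and accumulate codon-level mutation counts."""
    ref_arr = aligner.ref_arr
    n_codons = len(aligner.reference) // 3
    sc = SampleCounts(sample_id, n_codons)
    pairs_total = pairs_unique = unaligned = indel_pairs = 0
    for up in unique_pairs:
        pairs_unique += 1
        pairs_total += up.multiplicity
        a1 = aligner.align(up.seq1)
        a2 = aligner.align(up.seq2)
        mates = [a for a in (a1, a2) if a is not None]
        if not mates:
            unaligned += up.multiplicity
            continue
        calls, callable_flags = _merge_codon_calls(mates, ref_arr, n_codons)
        sc.coverage[callable_flags] += up.multiplicity
        indel = any(a.indel_removed for a in mates)
        if indel:
            indel_pairs += up.multiplicity
        for call in calls:
            sc.counts[call] = sc.counts.get(call, 0) + up.multiplicity
            if indel:
                sc.ambiguous[call] = sc.ambiguous.get(call, 0) + up.multiplicity
        if len(calls) > 1:
            for call in calls:
                d = sc.cooc.setdefault(call, {})
                for other in calls:
                    if other != call:
                        d[other] = d.get(other, 0) + up.multiplicity
    sc.stats.update(pairs_total=pairs_total, pairs_unique=pairs_unique,
                    pairs_unaligned=unaligned, pairs_indel_corrected=indel_pairs)
    return sc


def call_sample(
    r1_path=None,
    r2_path=None,
    sam_path=None,
    reference: str = "",
    sample_id: str = "sample",
    min_identity: float = 0.8,
    k: int = 25,
) -> SampleCounts:
    """FASTQ pair (or SAM) -> deduplicated, aligned, codon-level counts."""
    if sam_path is not None:
        pairs = read_sam_pairs(sam_path)
    else:
        pairs = read_fastq_pairs(r1_path, r2_path)
    unique = dedup_pairs(pairs)
    aligner = ReferenceAligner(reference, k=k, min_identity=min_identity)
    return call_codon_mutations(unique, aligner, sample_id=sample_id)


# ---------------------------------------------------------------------------
# confidence filters
# ---------------------------------------------------------------------------

def filter_secondary(sc: SampleCounts, threshold: float = 0.8) -> SampleCounts:
    """Exclude reads dominated by a co-occurring secondary mutation.

    For a primary call ``m``, if some other call ``s`` co-occurs with
    ``m`` on more than ``threshold`` x count(m) of its supporting pairs,
    those joint pairs are removed from ``m``'s count.  Lowering the
    threshold makes the filter stricter (removes more).
    """
    out = copy.deepcopy(sc)
    for call, joint in sc.cooc.items():
        base = sc.count(call)
        if base <= 0:
            continue
        removed = sum(n for n in joint.values() if n > threshold * base)
        if removed:
            out.counts[call] = max(0, out.counts.get(call, 0) - removed)
            out.filter_log.append(
                ("secondary", call, removed,
                 f"co-occurring secondary > {threshold} x {base}"))
            if out.counts[call] == 0:
                del out.counts[call]
    return out


def filter_low_confidence(sc: SampleCounts, threshold: float = 0.7) -> SampleCounts:
    """Drop indel-corrected calls far below the strongest signal at the locus.

    A call supported (at least in part) by indel-corrected, ambiguously
    placed reads is dropped when its support is below ``threshold`` x the
    maximal call support at that codon position.  Raising the threshold
    makes the filter stricter.  Clean calls are never touched.
    """
    out = copy.deepcopy(sc)
    max_at_pos: dict[int, int] = {}
    for (pos, _codon), n in sc.counts.items():
        max_at_pos[pos] = max(max_at_pos.get(pos, 0), n)
    for call, n in list(sc.counts.items()):
        if sc.ambiguous.get(call, 0) <= 0:
            continue
        if n < threshold * max_at_pos[call[0]]:
            out.counts.pop(call, None)
            out.filter_log.append(
                ("low_confidence", call, n,
                 f"indel-corrected support < {threshold} x max signal "
                 f"{max_at_pos[call[0]]} at position {call[0]}"))
    return out
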