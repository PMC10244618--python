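"""Synthetic reverse-Y2H deep mutational scanning screens.

Simulates the complete sequencing side of an interaction-perturbation
screen: a mutant-library "control" pool (no selection pressure) and a
"selected" pool in which a planted subset of variants is enriched, both
emitted as 150 bp paired-end FASTQ plus a ground-truth table.

The generative model, molecule by molecule:

* each molecule is a full-length ORF copy carrying either no programmed
  mutation (``wt_fraction``) or exactly one catalog substitution, drawn
  with probability proportional to a log-normally distributed library
  abundance;
* in the selected pool the draw probability is additionally multiplied
  by the entry's enrichment factor (``f >= 1``; reverse-Y2H selection
  enriches non-interacting variants, all non-perturbing entries keep
  ``f = 1``);
* with probability ``secondary_rate`` the molecule carries one extra,
  unprogrammed codon change (PCR/synthesis artifact);
* a fragment of normally distributed length is placed uniformly on the
  ORF and sequenced from both ends; a variant is visible in a pair only
  if the sequenced bases cover its codon, which reproduces the smooth
  position-dependent coverage geometry of real libraries;
* per-base substitution errors and rare 1-3 bp indels are applied per
  read; base qualities are constant high quality.

Identical seeds give byte-identical output.  Read names encode the
molecule, its variant and fragment so that calling results can be
checked against the ground truth exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["SimulationConfig", "ScreenFiles", "simulate_screen"]

_COMP = str.maketrans("ACGT", "TGCA")
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SimulationConfig:
    """Conditions for one simulated screen.

    Defaults emulate a desk-scale analogue of an Illumina 150 bp
    paired-end run on a single-ORF mutagenic library: log-normal entry
    abundances (sigma 0.5, typical of on-chip oligo pools), 5% unmutated
    carryover, one spurious extra codon change per ~100 molecules,
    residual post-QC substitution miscalls at 5e-5 per base and rare
    read-level indels.
    """

    seed: int = 0
    n_pairs_control: int = 100_000
    n_pairs_selected: int = 100_000
    read_length: int = 150
    fragment_length_mean: float = 280.0
    fragment_length_sd: float = 30.0
    abundance_sigma: float = 0.5
    enrichment_factor: float = 20.0
    n_perturbing: int = 10
    perturbing_entries: Optional[Sequence[int]] = None   # catalog row indices
    error_rate: float = 5e-5
    secondary_rate: float = 0.01
    indel_rate: float = 1e-3
    wt_fraction: float = 0.05

    def validate(self) -> None:
        for name in ("error_rate", "secondary_rate", "indel_rate", "wt_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1 (reverse-Y2H enriches)")
        if self.fragment_length_mean < 3:
            raise ValueError("fragment shorter than one codon")
        if self.read_length < 3:
            raise ValueError("read_length shorter than one codon")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if d["perturbing_entries"] is not None:
            d["perturbing_entries"] = [int(x) for x in d["perturbing_entries"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class ScreenFiles:
    """Paths of one simulated screen plus its planted truth."""

    control_r1: Path
    control_r2: Path
    selected_r1: Path
    selected_r2: Path
    ground_truth: Path
    config: Path
    perturbing_entries: np.ndarray = field(default_factory=lambda: np.array([], int))


def _apply_patch(frag: str, frag_start: int, pos0: int, codon: str) -> str:
    """Substitute ``codon`` at absolute nt position ``pos0`` into a fragment,
    clipping at the fragment boundaries."""
    rel = pos0 - frag_start
    lo, hi = max(rel, 0), min(rel + 3, len(frag))
    if lo >= hi:
        return frag
    return frag[:lo] + codon[lo - rel: hi - rel] + frag[hi:]


def _simulate_sample(
    rng: np.random.Generator,
    ref: str,
    catalog: pd.DataFrame,
    weights: np.ndarray,
    n_pairs: int,
    cfg: SimulationConfig,
    sample: str,
    r1_path: Path,
    r2_path: Path,
    nonprogrammed: dict[str, list[str]],
):
    """Emit one FASTQ pair; return realized and covered molecule counts."""
    L = len(ref)
    n_entries = len(catalog)
    rl = cfg.read_length
    var_pos0 = (catalog["codon_index"].to_numpy() - 1) * 3
    var_codon = catalog["mut_codon"].to_numpy()

    vidx = rng.choice(n_entries + 1, size=n_pairs, p=weights)  # n_entries == WT
    flen = np.rint(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd,
                              n_pairs)).astype(int)
    flen = np.clip(flen, 3, L)
    start = (rng.random(n_pairs) * (L - flen + 1)).astype(int)
    end = start + flen
    has_secondary = rng.random(n_pairs) < cfg.secondary_rate
    n_err = rng.binomial(np.minimum(flen, rl), cfg.error_rate, size=(2, n_pairs))
    has_indel = rng.random((2, n_pairs)) < cfg.indel_rate

    molecules = np.bincount(vidx, minlength=n_entries + 1)[:n_entries]
    covered = np.zeros(n_entries, dtype=np.int64)

    # covered = variant codon fully inside the sequenced part of the fragment
    is_var = vidx < n_entries
    p0 = np.where(is_var, var_pos0[np.minimum(vidx, n_entries - 1)], -1)
    l1 = np.minimum(flen, rl)
    if True:
        contiguous = flen <= 2 * rl
        in_union = np.where(
            contiguous,
            (p0 >= start) & (p0 + 3 <= end),
            ((p0 >= start) & (p0 + 3 <= start + l1))
            | ((p0 >= end - l1) & (p0 + 3 <= end)),
        )
        np.add.at(covered, vidx[is_var & in_union], 1)

    codon_index = catalog["codon_index"].to_numpy()
    n_codons = L // 3
    out1, out2 = [], []
    for i in range(n_pairs):
        s, e, fl = int(start[i]), int(end[i]), int(flen[i])
        frag = ref[s:e]
        v = int(vidx[i])
        sec_tag = "-"
        if v < n_entries:
            frag = _apply_patch(frag, s, int(var_pos0[v]), var_codon[v])
        if has_secondary[i]:
            cpos = int(rng.integers(0, n_codons))
            wt = ref[3 * cpos: 3 * cpos + 3]
            choices = nonprogrammed[wt]
            sec = choices[int(rng.integers(0, len(choices)))]
            frag = _apply_patch(frag, s, 3 * cpos, sec)
            sec_tag = f"{cpos + 1}.{sec}"
        r1 = frag[:rl]
        r2 = _revcomp(frag[-rl:]) if fl > rl else _revcomp(frag)
        reads = [r1, r2]
        for m in (0, 1):
            k = int(n_err[m, i])
            if k:
                read = list(reads[m])
                for p in rng.integers(0, len(read), size=k):
                    cur = read[p]
                    read[p] = "ACGT"[(("ACGT".index(cur) + int(rng.integers(1, 4))) % 4)]
                reads[m] = "".join(read)
            if has_indel[m, i]:
                read = reads[m]
                ilen = int(rng.integers(1, 4))
                p = int(rng.integers(0, max(len(read) - ilen, 1)))
                if rng.random() < 0.5:
                    ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, ilen))
                    reads[m] = read[:p] + ins + read[p:]
                else:
                    reads[m] = read[:p] + read[p + ilen:]
        name = f"{sample}.m{i}|v{v if v < n_entries else 'WT'}|f{s}:{fl}|x{sec_tag}"
        out1.append(f"@{name}/1\n{reads[0]}\n+\n{'I' * len(reads[0])}")
        out2.append(f"@{name}/2\n{reads[1]}\n+\n{'I' * len(reads[1])}")

    r1_path.write_text("\n".join(out1) + "\n")
    r2_path.write_text("\n".join(out2) + "\n")
    return molecules, covered


def simulate_screen(
    config: SimulationConfig,
    catalog: pd.DataFrame,
    cds: str,
    outdir,
) -> ScreenFiles:
    """Simulate control + selected pools for a catalog on one ORF.

    Writes ``{control,selected}_R{1,2}.fastq``, ``ground_truth.tsv`` and
    ``config.yaml`` into ``outdir`` and returns their paths.
    """
    config.validate()
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    cds = cds.upper()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n_entries = len(catalog)

    programmed = set(catalog["mut_codon"].unique())
    nonprogrammed = {}
    for wt in set(cds[i:i + 3] for i in range(0, len(cds), 3)):
        nonprogrammed[wt] = [c for c in _ALL_CODONS
                             if c != wt and c not in programmed]

    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n_entries)
    if config.perturbing_entries is not None:
        perturbing = np.asarray(sorted(config.perturbing_entries), dtype=int)
    else:
        perturbing = np.sort(rng.choice(n_entries, size=config.n_perturbing,
                                        replace=False))
    f = np.ones(n_entries)
    f[perturbing] = config.enrichment_factor

    # WT behaves like a pseudo-entry with f = 1 occupying wt_fraction of the
    # unselected pool
    if config.wt_fraction < 1.0:
        wt_abund = config.wt_fraction / (1.0 - config.wt_fraction) * abundance.sum()
    else:
        raise ValueError("wt_fraction must be < 1")
    w_ctrl = np.append(abundance, wt_abund)
    w_ctrl = w_ctrl / w_ctrl.sum()
    w_sel = np.append(abundance * f, wt_abund)
    w_sel = w_sel / w_sel.sum()

    paths = ScreenFiles(
        control_r1=outdir / "control_R1.fastq",
        control_r2=outdir / "control_R2.fastq",
        selected_r1=outdir / "selected_R1.fastq",
        selected_r2=outdir / "selected_R2.fastq",
        ground_truth=outdir / "ground_truth.tsv",
        config=outdir / "config.yaml",
        perturbing_entries=perturbing,
    )
    mol_c, cov_c = _simulate_sample(rng, cds, catalog, w_ctrl,
                                    config.n_pairs_control, config, "ctrl",
                                    paths.control_r1, paths.control_r2,
                                    nonprogrammed)
    mol_s, cov_s = _simulate_sample(rng, cds, catalog, w_sel,
                                    config.n_pairs_selected, config, "sel",
                                    paths.selected_r1, paths.selected_r2,
                                    nonprogrammed)

    gt = catalog[["codon_index", "wt_codon", "mut_codon"]].copy()
    gt.insert(0, "entry_id", np.arange(n_entries))
    gt["abundance"] = abundance
    gt["enrichment_factor"] = f
    gt["molecules_control"] = mol_c
    gt["molecules_selected"] = mol_s
    gt["covered_control"] = cov_c
    gt["covered_selected"] = cov_s
    with open(paths.ground_truth, "w") as fh:
        fh.write("# simulated screen ground truth; covered_* = molecules whose "
                 "variant codon lies fully inside the sequenced bases\n")
        gt.to_csv(fh, sep="\t", index=False)
    config.to_yaml(paths.config)
    return paths
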