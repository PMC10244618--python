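"""End-to-end pipeline: simulate (optional) -> call -> filter -> score ->
Z-profile -> hotspots, each stage writing a TSV artifact with a
provenance header (package version, config hash, coordinate system) and
a log line with record counts in and out.

Given one seed and one configuration the outputs are byte-identical
across reruns."""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


import yaml

from . import __version__
from .calling import call_sample, filter_low_confidence, filter_secondary
from .catalog import catalog_to_tsv, design_catalog
from .enrichment import (EnrichmentModel, detect_hotspots, hotspots_to_tsv)
from .isoforms import nf2_map
from .simulate import SimulationConfig, simulate_screen

log = logging.getLogger("nf2scan")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and provenance switches for one pipeline run.

    Every threshold is echoed into the output headers so each artifact
    records the configuration that produced it."""

    outdir: str = "nf2scan_out"
    reference_fasta: Optional[str] = None      # single-record CDS FASTA
    interaction: str = "interaction"
    # inputs: either simulate, or explicit FASTQ pairs
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    control_r1: Optional[str] = None
    control_r2: Optional[str] = None
    selected_r1: Optional[str] = None
    selected_r2: Optional[str] = None
    # calling
    min_identity: float = 0.8
    secondary_threshold: float = 0.8
    lowconf_threshold: float = 0.7
    # scoring
    read_cutoff: int = 50
    confidence_mode: str = "residual"
    position_agg: str = "max"
    # hotspots
    hotspot_window: int = 9
    hotspot_z: float = 1.5
    hotspot_min_run: int = 5
    use_nf2_coordinates: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["sim"]["perturbing_entries"] is not None:
            d["sim"]["perturbing_entries"] = [
                int(x) for x in d["sim"]["perturbing_entries"]]
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)          # location, not an analysis parameter
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()
        ).hexdigest()[:12]


def _read_single_fasta(path) -> str:
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 1:
        raise ValueError(f"{path} must contain exactly one sequence")
    return str(recs[0].seq).upper()


def _default_reference() -> str:
    from importlib import resources
    from io import StringIO

    from Bio import SeqIO

    text = resources.files("nf2scan.data").joinpath(
        "nf2_iso7_synthetic_cds.fasta").read_text()
    return str(next(SeqIO.parse(StringIO(text), "fasta")).seq)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the artifact directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    head = [f"nf2scan {__version__}", f"config_hash={config.config_hash()}",
            "coordinates=isoform-7 codon index, 1-based"]

    cds = (_read_single_fasta(config.reference_fasta)
           if config.reference_fasta else _default_reference())
    iso_map = nf2_map() if config.use_nf2_coordinates else None
    catalog = design_catalog(cds, iso_map=iso_map)
    catalog_to_tsv(catalog, out / "catalog.tsv", head)
    log.info("catalog: %d entries over %d codons", len(catalog), len(cds) // 3)

    if config.simulate:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        files = simulate_screen(sim_cfg, catalog, cds, out / "reads")
        c_r1, c_r2 = files.control_r1, files.control_r2
        s_r1, s_r2 = files.selected_r1, files.selected_r2
    else:
        for p in (config.control_r1, config.control_r2,
                  config.selected_r1, config.selected_r2):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        c_r1, c_r2 = config.control_r1, config.control_r2
        s_r1, s_r2 = config.selected_r1, config.selected_r2

    samples = {}
    for sid, (r1, r2) in (("control", (c_r1, c_r2)),
                          ("selected", (s_r1, s_r2))):
        sc = call_sample(r1, r2, reference=cds, sample_id=sid,
                         min_identity=config.min_identity)
        before = sc.total_mutant_reads()
        sc = filter_secondary(sc, config.secondary_threshold)
        sc = filter_low_confidence(sc, config.lowconf_threshold)
        after = sc.total_mutant_reads()
        log.info("%s: %d pairs (%d unique, %d unaligned); mutant reads "
                 "%d -> %d after filters", sid, sc.stats["pairs_total"],
                 sc.stats["pairs_unique"], sc.stats["pairs_unaligned"],
                 before, after)
        sc.to_tsv(out / f"counts_{sid}.tsv",
                  head + [f"filters: secondary>{config.secondary_threshold} "
                          f"lowconf<{config.lowconf_threshold}"])
        samples[sid] = sc

    model = EnrichmentModel(samples["control"], samples["selected"],
                            catalog=catalog, read_cutoff=config.read_cutoff,
                            confidence_mode=config.confidence_mode,
                            position_agg=config.position_agg)
    res = model.fit()
    with open(out / "codon_fits.tsv", "w") as fh:
        for line in head:
            fh.write(f"# {line}\n")
        res.fit_table().to_csv(fh, sep="\t", index=False)
    with open(out / "enrichment.tsv", "w") as fh:
        for line in head + [f"read_cutoff={config.read_cutoff} "
                            f"confidence_mode={config.confidence_mode}"]:
            fh.write(f"# {line}\n")
        res.records.to_csv(fh, sep="\t", index=False)
    log.info("enrichment: %d records, %d high-confidence",
             len(res.records), int(res.records["high_confidence"].sum()))

    profile = res.zscore_profile(config.interaction)
    profile.to_tsv(out / "profile.tsv", head)
    hotspots = detect_hotspots(profile, window=config.hotspot_window,
                               z_threshold=config.hotspot_z,
                               min_run=config.hotspot_min_run,
                               iso_map=iso_map)
    hotspots_to_tsv(hotspots, out / "hotspots.tsv",
                    head + [f"window={config.hotspot_window} "
                            f"z>={config.hotspot_z} "
                            f"min_run={config.hotspot_min_run}"])
    log.info("profile: %d scored positions; %d hotspot regions",
             int(profile.scores.notna().sum()), len(hotspots))
    (out / "summary.txt").write_text(res.summary() + "\n")
    return out
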