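"""Configuration and the end-to-end demonstration pipeline.

``run_pipeline`` chains the stages on synthetic data with known truth:
simulate a strain panel and pooled samples, derive the metareference and
diagnostic sites, estimate strain composition per sample, call CNVs from
the coverage matrix, call HGT fragments, and compute windowed
population-genetic statistics. Every output is a TSV/BED/FASTA file
stamped with the tool version, a hash of the configuration, and the seed;
no timestamps are written, so a rerun with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .cnv import CoverageMatrix, call_cnvs, contig_copy_number
from .composition import compose_population
from .hgt import call_fragments, fragment_frequency
from .panel import build_metareference, find_diagnostic_sites
from .popgen import sliding_windows
from .simulate import simulate_pooled_sample, simulate_strain_panel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults.

    Defaults mirror the analysis the package implements: 10 kb windows
    with 5 kb steps, MAF 0.05, 100-bp merge gap, 1-kb minimum HGT length,
    0.04 treatment-variance screen, FDR 0.05.
    """

    seed: int = 0
    n_strains: int = 5
    genome_length: int = 50_000
    n_contigs: int = 2
    n_plasmid_contigs: int = 0
    divergence: float = 0.01
    n_samples: int = 4
    mean_coverage: float = 100.0
    mixture: list[float] | None = None
    error_rate: float = 0.001
    min_depth: int = 10
    min_sites: int = 20
    maf: float = 0.05
    window: int = 10_000
    step: int = 5_000
    merge_gap: int = 100
    hgt_min_length: int = 1000
    hgt_variance_threshold: float = 0.04
    fdr: float = 0.05
    cnv_rho: float = 1.0
    sample_blacklist: list[str] = field(default_factory=list)

    _RANGES = {
        "divergence": (0.0, 0.2),
        "error_rate": (0.0, 0.25),
        "maf": (0.0, 0.5),
        "fdr": (0.0, 1.0),
    }

    def __post_init__(self) -> None:
        for key, (lo, hi) in self._RANGES.items():
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ValueError(f"{key}={v} outside [{lo}, {hi}]")
        if self.window < self.step:
            raise ValueError("window must be >= step")
        if self.mixture is not None and len(self.mixture) != self.n_strains:
            raise ValueError("mixture length must equal n_strains")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive per-sample seeds below 2**31 from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run simulate -> panel -> strainfreq -> cnv -> hgt -> popgen.

    Returns a machine-readable run log (stage record counts, output
    paths); also written as ``run_log.json`` in ``outdir``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.config_hash(), "seed": config.seed}
    log: dict = {"config_hash": prov["config_hash"], "seed": config.seed, "stages": {}}

    # --- simulate ---------------------------------------------------------
    panel, truth = simulate_strain_panel(
        n_strains=config.n_strains,
        genome_length=config.genome_length,
        n_contigs=config.n_contigs,
        n_plasmid_contigs=config.n_plasmid_contigs,
        divergence=config.divergence,
        seed=config.seed,
    )
    mixture = config.mixture
    if mixture is None:
        raw = np.array([0.6, 0.25, 0.10, 0.04, 0.01][: config.n_strains])
        mixture = (raw / raw.sum()).tolist()
    truth = truth.with_mixture(mixture)
    truth = dataclasses.replace(truth, error_rate=config.error_rate)
    sample_seeds = _spawn_seeds(config.seed, config.n_samples)
    samples = [
        simulate_pooled_sample(
            panel, truth, config.mean_coverage, sample_id=f"pop{i + 1}", seed=s
        )
        for i, s in enumerate(sample_seeds)
        if f"pop{i + 1}" not in config.sample_blacklist
    ]
    log["stages"]["simulate"] = {"n_samples": len(samples)}

    # --- panel ------------------------------------------------------------
    pio.write_fasta(out / "panel.fasta", list(zip(panel.strain_ids, panel.aligned_sequences)))
    pio.write_fasta(out / "metareference.fasta", [("metareference", build_metareference(panel))])
    sites = find_diagnostic_sites(panel)
    pio.write_tsv(out / "diagnostic_sites.tsv", sites, prov)
    log["stages"]["panel"] = {"n_diagnostic_sites": len(sites)}

    # --- strain composition ----------------------------------------------
    profiles = []
    for s in samples:
        prof = compose_population(
            s.pileup, sites, min_depth=config.min_depth, min_sites=config.min_sites
        )
        profiles.append(prof.to_frame(s.sample_id))
    strainfreq = pd.concat(profiles, ignore_index=True)
    pio.write_tsv(out / "strain_composition.tsv", strainfreq, prov)
    log["stages"]["strainfreq"] = {"n_estimates": len(strainfreq)}

    # --- CNV --------------------------------------------------------------
    roles = dict(zip(panel.contig_table["contig"], panel.contig_table["role"]))
    matrix = CoverageMatrix.from_samples(samples, roles)
    cnv_calls = call_cnvs(matrix, rho=config.cnv_rho, max_gap=config.merge_gap)
    pio.write_bed(
        out / "cnv.bed",
        [(c.contig, c.start, c.end, f"cnv{i + 1}", c.n_positions) for i, c in enumerate(cnv_calls)],
        prov,
    )
    cnv_rows = [
        {"call": f"cnv{i + 1}", "contig": c.contig, "start": c.start, "end": c.end,
         "sample": smp, "copy_number": cn}
        for i, c in enumerate(cnv_calls)
        for smp, cn in c.copy_number.items()
    ]
    pio.write_tsv(out / "cnv_copy_numbers.tsv", pd.DataFrame(cnv_rows), prov)
    contig_cn = contig_copy_number(matrix, seed=config.seed)
    pio.write_tsv(out / "contig_copy_numbers.tsv", contig_cn, prov)
    log["stages"]["cnv"] = {"n_calls": len(cnv_calls)}

    # --- HGT --------------------------------------------------------------
    chrom_contigs = [c for c, r in roles.items() if r == "chromosomal"]
    hgt_rows = []
    bed_rows = []
    for s in samples:
        focal_depths = np.concatenate([s.depth[c] for c in chrom_contigs])
        for donor, tracks in s.nonfocal_depth.items():
            for frag in call_fragments(
                tracks, donor, min_length=config.hgt_min_length, max_gap=config.merge_gap
            ):
                freq = fragment_frequency(frag, tracks[frag.contig], focal_depths)
                hgt_rows.append(
                    {"sample": s.sample_id, "donor": donor, "contig": frag.contig,
                     "start": frag.start, "end": frag.end, "frequency": freq}
                )
                bed_rows.append((frag.contig, frag.start, frag.end, donor))
    pio.write_bed(out / "hgt.bed", sorted(set(bed_rows)), prov)
    pio.write_tsv(out / "hgt_frequencies.tsv", pd.DataFrame(
        hgt_rows, columns=["sample", "donor", "contig", "start", "end", "frequency"]
    ), prov)
    log["stages"]["hgt"] = {"n_fragments": len(hgt_rows)}

    # --- popgen -----------------------------------------------------------
    contig_lengths = {
        row["contig"]: int(row["end"]) - int(row["start"])
        for _, row in panel.contig_table.iterrows()
    }
    window_frames = []
    for s in samples:
        pu = s.pileup
        alt = pu[["A", "C", "G", "T"]].max(axis=1)
        # derived frequency at diagnostic sites: non-majority fraction
        freq = 1.0 - alt / pu["depth"].replace(0, np.nan)
        site_df = pd.DataFrame(
            {"contig": pu["contig"], "position": pu["position"],
             "coverage": pu["depth"], "freq": freq.fillna(0.0)}
        )
        wf = sliding_windows(
            site_df, contig_lengths, window=config.window, step=config.step, maf=config.maf
        )
        wf.insert(0, "sample", s.sample_id)
        window_frames.append(wf)
    windows = pd.concat(window_frames, ignore_index=True)
    pio.write_tsv(out / "popgen_windows.tsv", windows, prov)
    log["stages"]["popgen"] = {"n_windows": len(windows)}

    log["outputs"] = sorted(p.name for p in out.iterdir() if p.name != "run_log.json")
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return log
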