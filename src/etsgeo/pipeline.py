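"""End-to-end orchestration: synth -> annotation -> signal -> motifs ->
{association, multiplicity, geometry}, from one structured config.

Every tunable of the analysis (promoter width, 145-bp peak width, FDR 0.005,
2-kb isolation, 0..6 copy-number range, 100-bp spacing window, resampling
runs, helix pitch 10.4, 40-degree phase window) is a named config key with
the analysis default.  A run writes TSV/BED/FASTA artifacts plus a JSON
manifest recording parameters and seed; a rerun with an identical config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation, association, geometry, motifs, multiplicity, signal, synth
from .io import read_fasta, write_fasta

log = logging.getLogger(__name__)

STAGE_ORDER = ["synth", "annotation", "signal", "motifs", "association", "multiplicity", "geometry"]
STAGE_DEPS = {
    "synth": [],
    "annotation": [],
    "signal": ["annotation"],
    "motifs": ["annotation"],
    "association": ["annotation", "signal"],
    "multiplicity": ["signal", "motifs"],
    "geometry": ["signal", "motifs"],
}


@dataclass
class RunConfig:
    outdir: str
    seed: int
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    synth: Optional[dict] = None  # SynthConfig overrides; None = user inputs
    genes: Optional[str] = None  # paths, used when synth is None
    genome_fasta: Optional[str] = None
    treatment_reads: Optional[dict[str, list[str]]] = None  # factor -> BEDs
    control_reads: Optional[list[str]] = None
    pattern: str = "CCGGAAG"
    promoter_len: int = 1000
    fdr: float = 0.005
    peak_width: int = 145
    kmax: int = 6
    isolation: int = 2000
    resample_runs: int = 2500
    pitch: float = 10.4
    phase_window: float = 40.0
    top_signal_fraction: float = 0.5
    offset_search_max: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for req in ("outdir", "seed"):
            if req not in raw:
                raise ValueError(f"config missing required field: {req}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        requested = set(self.stages)
        for s in self.stages:
            missing = [d for d in STAGE_DEPS[s] if d not in requested]
            if missing:
                raise ValueError(
                    f"stage {s!r} requires stage(s) {missing}; run them first"
                )
        if self.synth is None and "synth" not in requested:
            if "annotation" in requested and not self.genes:
                raise ValueError("config missing `genes` (no synth stage requested)")
            if "signal" in requested and not self.control_reads:
                raise ValueError("config missing `controls` (control_reads)")


def run(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate()
    stages = [s for s in STAGE_ORDER if s in set(config.stages)]
    artifacts: list[str] = []

    def emit(name: str) -> Path:
        artifacts.append(name)
        return out / name

    genes = None
    chrom_lengths = None
    genome = None
    truth = None
    treatments = None
    controls = None

    if "synth" in stages:
        scfg_kwargs = dict(config.synth or {})
        if "factors" in scfg_kwargs:
            scfg_kwargs["factors"] = tuple(
                synth.FactorModel(**f) for f in scfg_kwargs["factors"]
            )
        scfg = synth.SynthConfig(pattern=config.pattern, **scfg_kwargs)
        ss = np.random.SeedSequence(config.seed).spawn(3)
        genes, chrom_lengths = synth.generate_annotation(scfg, ss[0])
        genome, promoters, truth = synth.plant_motifs(scfg, genes, chrom_lengths, ss[1])
        treatments, controls, truth = synth.simulate_chip_reads(
            scfg, promoters, truth, chrom_lengths, ss[2]
        )
        synth.genes_to_tsv(genes, emit("genes.tsv"))
        synth.genome_to_fasta(genome, emit("genome.fa"))
        motifs.hits_to_bed(truth.hits, emit("truth_hits.bed"), motif_len=len(scfg.pattern))
        pd.DataFrame(
            sorted(truth.counts.items()), columns=["gene_id", "count"]
        ).to_csv(emit("truth_counts.tsv"), sep="\t", index=False)
        for fac, reps in treatments.items():
            for i, df in enumerate(reps, 1):
                synth.reads_to_bed(df, emit(f"reads_{fac}_rep{i}.bed"))
        for i, df in enumerate(controls, 1):
            synth.reads_to_bed(df, emit(f"reads_control_rep{i}.bed"))

    if genes is None and (set(stages) - {"synth"}):
        if not config.genes:
            raise ValueError("config missing `genes` input")
        genes = annotation.read_gene_table(config.genes)
        genome = read_fasta(config.genome_fasta) if config.genome_fasta else None
        chrom_lengths = {c: len(s) for c, s in (genome or {}).items()}

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "artifacts": artifacts,
    }

    if "annotation" in stages:
        promoters = annotation.derive_promoters(genes, config.promoter_len)
        pairs = annotation.classify_promoter_pairs(genes, promoters)
        annotation.promoters_to_bed(promoters, emit("promoters.bed"))
        annotation.pairs_to_tsv(pairs, emit("pairs.tsv"))
    else:
        promoters, pairs = None, None

    calls_by_factor: dict[str, list[signal.BindingCall]] = {}
    signals_by_factor: dict[str, list[signal.PromoterSignal]] = {}
    if "signal" in stages:
        if treatments is None:
            treatments = {
                fac: [signal.read_bed_reads(p) for p in paths]
                for fac, paths in (config.treatment_reads or {}).items()
            }
            controls = [signal.read_bed_reads(p) for p in config.control_reads or []]
        if not controls:
            raise ValueError("no control replicates configured (controls)")
        ctrl_tracks = []
        for df in controls:
            ctrl_tracks.append(signal.normalize_coverage(df, chrom_lengths))
        ctrl_signals = signal.collect_signals(
            [signal.promoter_signal(t, promoters) for t in ctrl_tracks], "control"
        )
        for fac, reps in treatments.items():
            rep_signals = []
            track0 = signal.normalize_coverage(reps[0], chrom_lengths)
            offset = signal.estimate_strand_offset(track0, config.offset_search_max)
            for df in reps:
                track = signal.normalize_coverage(
                    signal.shift_reads(df, offset), chrom_lengths
                )
                rep_signals.append(signal.promoter_signal(track, promoters))
            sigs = signal.collect_signals(rep_signals, fac)
            calls = signal.call_bound_promoters(sigs, ctrl_signals, config.fdr)
            signals_by_factor[fac] = sigs
            calls_by_factor[fac] = calls
            signal.calls_to_tsv(calls, emit(f"calls_{fac}.tsv"))
            pd.DataFrame(
                [(s.gene_id, *s.replicate_signals, s.mean_signal) for s in sigs],
                columns=["gene_id"]
                + [f"rep{i+1}" for i in range(len(sigs[0].replicate_signals))]
                + ["mean"],
            ).to_csv(emit(f"signals_{fac}.tsv"), sep="\t", index=False)
            manifest[f"offset_{fac}"] = offset

    hits_by_promoter: dict[str, list[motifs.MotifHit]] = {}
    counts: dict[str, int] = {}
    promoter_seqs: dict[str, str] = {}
    if "motifs" in stages:
        if genome is None:
            raise ValueError("motifs stage needs a genome FASTA")
        for p in promoters:
            promoter_seqs[p.gene_id] = genome[p.chrom][p.start : p.end]
        all_hits: list[motifs.MotifHit] = []
        for gid in sorted(promoter_seqs):
            h = motifs.scan_motifs(promoter_seqs[gid], config.pattern, gid)
            hits_by_promoter[gid] = h
            all_hits.extend(h)
            counts[gid] = len(h)
        motifs.hits_to_bed(all_hits, emit("motif_hits.bed"), motif_len=len(config.pattern))
        pd.DataFrame(sorted(counts.items()), columns=["gene_id", "count"]).to_csv(
            emit("motif_counts.tsv"), sep="\t", index=False
        )
        if calls_by_factor:
            fac0 = sorted(calls_by_factor)[0]
            bound0 = {c.gene_id for c in calls_by_factor[fac0] if c.bound}
            if bound0:
                enr = motifs.enrich_7mers(
                    {g: promoter_seqs[g] for g in bound0}, promoter_seqs
                )
                enr.head(200).to_csv(emit("enrichment_top.tsv"), sep="\t", index=False)

    if "association" in stages:
        rows = []
        for fac, calls in sorted(calls_by_factor.items()):
            bound = {c.gene_id for c in calls if c.bound}
            ov = association.bidirectional_overlap(
                bound, pairs, [g.gene_id for g in genes]
            )
            rows.append(
                (fac, ov.n_regions, ov.n_bidirectional, ov.n_bound_regions,
                 ov.overlap, ov.fraction_of_bound, ov.fraction_of_bidirectional,
                 ov.result.p_value, ov.result.log10_p)
            )
        pd.DataFrame(
            rows,
            columns=["factor", "n_regions", "n_bidirectional", "n_bound",
                     "overlap", "frac_of_bound", "frac_of_bidirectional",
                     "p_value", "log10_p"],
        ).to_csv(emit("bidirectional_association.tsv"), sep="\t", index=False)

    if "multiplicity" in stages:
        for fac, calls in sorted(calls_by_factor.items()):
            bound = {c.gene_id for c in calls if c.bound}
            pcurve = multiplicity.probability_curve(bound, counts, config.kmax)
            multiplicity.curve_to_tsv(pcurve, emit(f"probability_curve_{fac}.tsv"))
            try:
                efit = multiplicity.fit_exponential(pcurve)
                manifest[f"exp_fit_{fac}"] = {"a": efit.a, "b": efit.b, "r": efit.r}
            except ValueError:
                pass
            bound_sigs = [s for s in signals_by_factor[fac] if s.gene_id in bound]
            if bound_sigs:
                scurve = multiplicity.signal_curve(bound_sigs, counts, config.kmax)
                multiplicity.curve_to_tsv(scurve, emit(f"signal_curve_{fac}.tsv"))
                if len(scurve) >= 2:
                    lfit = multiplicity.fit_linear(scurve)
                    manifest[f"signal_fit_{fac}"] = {"a": lfit.a, "b": lfit.b, "r": lfit.r}

    if "geometry" in stages:
        mpairs = geometry.select_two_motif_promoters(
            hits_by_promoter, motif_len=len(config.pattern)
        )
        all_track = geometry.spacing_density(mpairs)
        geometry.density_to_tsv(all_track, emit("spacing_all.tsv"))
        all_phases = [p.phase for p in mpairs]
        for fac, calls in sorted(calls_by_factor.items()):
            bound = {c.gene_id for c in calls if c.bound}
            bound_track = geometry.spacing_density(mpairs, subset=bound)
            n_bound_pairs = sum(1 for p in mpairs if p.promoter_id in bound)
            if n_bound_pairs:
                pv = geometry.resample_pvalues(
                    mpairs, bound_track, n_bound_pairs,
                    runs=config.resample_runs, seed=config.seed,
                )
                geometry.density_to_tsv(pv, emit(f"spacing_{fac}.tsv"))
                bound_phases = [p.phase for p in mpairs if p.promoter_id in bound]
                try:
                    prof = geometry.phase_profile(
                        all_phases, bound_phases, window=config.phase_window
                    )
                    geometry.phase_to_tsv(prof, emit(f"phase_{fac}.tsv"))
                except ValueError:
                    pass

    manifest["artifacts"] = sorted(artifacts)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
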