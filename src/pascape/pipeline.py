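"""End-to-end orchestration: simulate -> call PAS -> annotate -> profiles.

A single :class:`RunConfig` (JSON-serializable, every threshold defaulted to
the pipeline's standard values) drives :func:`run_pipeline`, which executes
the enabled stages in dependency order, writes every output under one
directory and finishes with a manifest listing each file with its SHA-256,
so identical config + seed reruns are verifiably bit-identical.
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

from . import annotation, discovery, iclip, motifs, synthetic
from .io_formats import GeneModel, GenomeSequence, write_annotation, write_bed6

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "call_pas",
    "annotate",
    "motif_profile",
    "tandem_ugua",
    "xlink_profile",
    "xlink_compare",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Every knob of an end-to-end run, with the standard defaults.

    Thresholds: 25-nt cluster distance, 15-nt windows, CE_average > 4,
    PU_average > 5%, TPM_maximum > 0.25, APA significance FDR ≤ 0.1 with
    |ΔPDUI| ≥ 0.05, 100 background resamples, motif window ±300 nt and
    crosslink window −400..+100 nt.
    """

    seed: int = 1
    stages: tuple = ALL_STAGES
    # synthetic genome
    n_genes: int = 8
    strand_mix: float = 0.5
    utr_length_range: tuple = (350, 650)
    n_pas_range: tuple = (1, 4)
    a_stretch_rate: float = 1.0
    # reads
    conditions: dict = field(default_factory=lambda: {"control": 2, "knockdown": 2})
    reads_per_pas: int = 30
    tail_length_range: tuple = (12, 20)
    tail_error_rate: float = 0.0
    cleavage_jitter_sd: float = 1.0
    internal_priming_fraction: float = 0.3
    duplicate_rate: float = 0.1
    # PAS calling thresholds
    cluster_dist: int = 25
    window_nt: int = 15
    min_ce: float = 4.0
    min_pu: float = 5.0
    min_tpm: float = 0.25
    ip_adjacency: int = 5
    # APA significance
    apa_fdr_max: float = 0.1
    apa_min_abs_dpdui: float = 0.05
    # motif analysis
    motif_pattern: str = "UGUA"
    motif_half_window: int = 300
    n_resamples: int = 100
    profile_fdr: float = 0.01
    tandem_mode: str = "enclosing"
    # crosslinks
    xlink_libraries: tuple = ("libA", "libB")
    xlink_background_rate: float = 0.02
    xlink_bump_offset: int = -75
    xlink_bump_sd: float = 8.0
    xlink_bump_height: float = 3.0
    xlink_depth: float = 1.0
    xlink_window: tuple = (-400, 100)
    xlink_compare_fdr: float = 0.01

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "utr_length_range", "n_pas_range", "tail_length_range",
                    "xlink_libraries", "xlink_window"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CallResult:
    """Outcome of PAS calling on a set of libraries."""

    atlas: pd.DataFrame  # quantified windows incl. failed ones
    records: list  # annotated PASRecords for windows passing the filter
    funnel: pd.DataFrame  # per-sample read/event counts through each filter


def call_pas_from_libraries(
    genome: GenomeSequence,
    genes: dict[str, GeneModel],
    libraries: dict[str, "synthetic.MaceLibrary"],
    condition_map: dict[str, str],
    min_ce: float = 4.0,
    min_pu: float = 5.0,
    min_tpm: float = 0.25,
    cluster_dist: int = 25,
    ip_adjacency: int = 5,
    phred_cutoff: int = 16,
    assign_cse_hexamers: bool = True,
) -> CallResult:
    """Full PAS calling: trim, dedup, mask internal priming, cluster, quantify, annotate.

    Per sample, reads are quality-trimmed and UMI+coordinate deduplicated,
    trailing poly(A) detected (A10, 5-nt sliding window) and only poly(A)
    reads kept; cleavage events are taken 1 nt downstream of the trimmed
    3' ends, events adjacent to genomic A-stretches removed, events pooled
    across samples into clusters (≤``cluster_dist`` nt from the running
    median), resized to 15-nt mode-centred windows, assigned to genes and
    quantified with the CE/PU/TPM filter.
    """
    stretches = discovery.find_genomic_a_stretches(genome)
    all_events = []
    funnel_rows = []
    for sample, lib in sorted(libraries.items()):
        coords = lib.coordinates()
        prepared, log = discovery.prepare_reads(
            ((n, s, q) for n, s, q in lib.reads),
            phred_cutoff=phred_cutoff,
            coordinates=coords,
        )
        polya_names = []
        n_not_polya = 0
        for r in prepared:
            tr = discovery.trim_polya(r.seq)
            if tr.is_polya and tr.usable:
                polya_names.append(r.name)
            else:
                n_not_polya += 1
        keep = set(polya_names)
        bed = lib.bed.loc[lib.bed["name"].isin(keep)]
        events = discovery.events_from_bed(bed, sample_id=sample)
        n_events = int(events["count"].sum())
        events, n_removed = discovery.filter_internal_priming(
            events, stretches, adjacency_nt=ip_adjacency
        )
        all_events.append(events)
        funnel_rows.append(
            dict(
                sample_id=sample,
                reads_in=log["n_in"],
                duplicates_removed=log["n_duplicates"],
                no_umi=log["n_no_umi"],
                not_polya=n_not_polya,
                events_before_ip_filter=n_events,
                events_removed_internal_priming=n_removed,
                events_retained=int(events["count"].sum()),
            )
        )
    events = pd.concat(all_events, ignore_index=True)
    clusters = discovery.cluster_cleavage_events(events, max_dist=cluster_dist)
    windows = [discovery.define_pas_window(c) for c in clusters]
    records, n_unassigned = annotation.annotate_windows(windows, genes)
    assigned = [r.window for r in records]
    atlas = discovery.quantify_and_filter(
        assigned, events, condition_map, genes,
        min_ce=min_ce, min_pu=min_pu, min_tpm=min_tpm,
    )
    passed_idx = set(atlas.loc[atlas["passed"], "window_index"]) if not atlas.empty else set()
    kept_records = [r for i, r in enumerate(records) if i in passed_idx]
    annotation.classify_pas_types(kept_records)
    if assign_cse_hexamers and kept_records:
        hexamers = annotation.load_cse_hexamers()
        for rec in kept_records:
            annotation.assign_cse(rec, genome, hexamers)
    funnel = pd.DataFrame(funnel_rows)
    logger.info("PAS calling: %d windows, %d passed, %d unassigned",
                len(windows), len(kept_records), n_unassigned)
    return CallResult(atlas=atlas, records=kept_records, funnel=funnel)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the enabled stages, write outputs and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    outputs: dict[str, Path] = {}
    counts: dict[str, object] = {}

    def need(stage: str, wanted_by: str):
        if stage not in stages:
            raise PipelineError(
                f"stage '{wanted_by}' requires stage '{stage}', which is disabled"
            )

    genome = genes = truth = None
    libraries: dict[str, synthetic.MaceLibrary] = {}
    if "simulate" in stages:
        genome, genes, truth = synthetic.simulate_genome(
            n_genes=config.n_genes,
            strand_mix=config.strand_mix,
            utr_length_range=tuple(config.utr_length_range),
            n_pas_range=tuple(config.n_pas_range),
            a_stretch_rate=config.a_stretch_rate,
            seed=config.seed,
        )
        genome.to_fasta(outdir / "genome.fa")
        write_annotation(genes.values(), outdir / "annotation.gtf")
        outputs["genome"] = outdir / "genome.fa"
        outputs["annotation"] = outdir / "annotation.gtf"
        truth_df = pd.DataFrame(
            [
                dict(gene_id=p.gene_id, position=p.position, weight=p.weight,
                     cse=p.cse, cse_offset=p.cse_offset)
                for p in truth.all_pas()
            ]
        )
        truth_df.to_csv(outdir / "truth_pas.tsv", sep="\t", index=False)
        outputs["truth_pas"] = outdir / "truth_pas.tsv"
        sub_seed = np.random.default_rng(config.seed).integers(1, 2**31 - 1, size=64)
        si = 0
        condition_map = {}
        for cond, n_reps in sorted(config.conditions.items()):
            for rep in range(1, n_reps + 1):
                sample = f"{cond}_{rep}"
                libraries[sample] = synthetic.simulate_mace_reads(
                    genome,
                    truth,
                    reads_per_pas=config.reads_per_pas,
                    tail_length_range=tuple(config.tail_length_range),
                    tail_error_rate=config.tail_error_rate,
                    cleavage_jitter_sd=config.cleavage_jitter_sd,
                    internal_priming_fraction=config.internal_priming_fraction,
                    duplicate_rate=config.duplicate_rate,
                    sample_id=sample,
                    seed=int(sub_seed[si]),
                )
                libraries[sample].write_fastq(outdir / f"reads_{sample}.fastq")
                libraries[sample].write_bed(outdir / f"reads_{sample}.bed")
                outputs[f"reads_{sample}_fastq"] = outdir / f"reads_{sample}.fastq"
                outputs[f"reads_{sample}_bed"] = outdir / f"reads_{sample}.bed"
                condition_map[sample] = cond
                si += 1
        counts["n_samples"] = len(libraries)

    result = None
    if "call_pas" in stages:
        need("simulate", "call_pas")
        result = call_pas_from_libraries(
            genome, genes, libraries, condition_map,
            min_ce=config.min_ce, min_pu=config.min_pu, min_tpm=config.min_tpm,
            cluster_dist=config.cluster_dist, ip_adjacency=config.ip_adjacency,
            assign_cse_hexamers="annotate" in stages,
        )
        result.atlas.to_csv(outdir / "pas_atlas.tsv", sep="\t", index=False)
        result.funnel.to_csv(outdir / "read_funnel.tsv", sep="\t", index=False)
        outputs["pas_atlas"] = outdir / "pas_atlas.tsv"
        outputs["read_funnel"] = outdir / "read_funnel.tsv"
        counts["n_windows"] = int(len(result.atlas))
        counts["n_pas_passed"] = len(result.records)

    records = []
    if "annotate" in stages:
        need("call_pas", "annotate")
        records = result.records
        table = annotation.records_to_table(records)
        table.to_csv(outdir / "pas_annotated.tsv", sep="\t", index=False)
        bed = pd.DataFrame(
            dict(
                contig=table["contig"], start=table["start"], end=table["end"],
                name=table["gene_id"] + "|" + table["pas_type"].astype(str),
                score=1, strand=table["strand"],
            )
        ).sort_values(["contig", "start"], kind="mergesort")
        write_bed6(bed, outdir / "pas_annotated.bed")
        outputs["pas_annotated"] = outdir / "pas_annotated.tsv"
        outputs["pas_annotated_bed"] = outdir / "pas_annotated.bed"
        counts["pas_types"] = table["pas_type"].value_counts().to_dict()

    anchors = []
    if records:
        anchors = [(r.contig, r.strand, r.center) for r in records]

    if "motif_profile" in stages:
        need("annotate", "motif_profile")
        prof = motifs.metaprofile(
            anchors, genome, config.motif_pattern, half_window=config.motif_half_window
        )
        pd.DataFrame(
            dict(offset=prof.offsets, raw=prof.raw, smoothed=prof.smoothed)
        ).to_csv(outdir / "motif_profile.tsv", sep="\t", index=False)
        outputs["motif_profile"] = outdir / "motif_profile.tsv"

    if "tandem_ugua" in stages:
        need("annotate", "tandem_ugua")
        tp = motifs.tandem_ugua(anchors, genome, mode=config.tandem_mode)
        pd.DataFrame(dict(win_size=tp.win_sizes, fraction=tp.fraction)).to_csv(
            outdir / "tandem_ugua.tsv", sep="\t", index=False
        )
        outputs["tandem_ugua"] = outdir / "tandem_ugua.tsv"

    tracks = {}
    if "xlink_profile" in stages or "xlink_compare" in stages:
        need("simulate", "xlink_profile")
        need("annotate", "xlink_profile")
        xseed = int(np.random.default_rng(config.seed + 7).integers(1, 2**31 - 1))
        tracks = synthetic.simulate_crosslinks(
            genes, truth,
            library_ids=tuple(config.xlink_libraries),
            depth=config.xlink_depth,
            background_rate=config.xlink_background_rate,
            bump_offset=config.xlink_bump_offset,
            bump_sd=config.xlink_bump_sd,
            bump_height=config.xlink_bump_height,
            seed=xseed,
        )
        lo, hi = config.xlink_window
        if "xlink_profile" in stages:
            for lib, track in tracks.items():
                prof = iclip.pas_metaprofile(track, anchors, lo=lo, hi=hi)
                pd.DataFrame(
                    dict(offset=prof.offsets, raw=prof.raw, smoothed=prof.smoothed)
                ).to_csv(outdir / f"xlink_profile_{lib}.tsv", sep="\t", index=False)
                outputs[f"xlink_profile_{lib}"] = outdir / f"xlink_profile_{lib}.tsv"
        if "xlink_compare" in stages:
            libs = tuple(config.xlink_libraries)
            cmpres = iclip.compare_profiles(
                tracks[libs[0]], tracks[libs[1]], anchors, lo=lo, hi=hi,
                fdr=config.xlink_compare_fdr,
            )
            pd.DataFrame(
                dict(offset=cmpres.offsets, z=cmpres.z, qval=cmpres.qvals, flag=cmpres.flags)
            ).to_csv(outdir / "xlink_compare.tsv", sep="\t", index=False)
            outputs["xlink_compare"] = outdir / "xlink_compare.tsv"
            counts["xlink_flagged_positions"] = int(cmpres.flags.sum())

    config.to_json(outdir / "config.json")
    outputs["config"] = outdir / "config.json"
    manifest = {
        "stages": sorted(stages),
        "counts": counts,
        "outputs": {
            key: {"path": p.name, "sha256": _sha256(p)} for key, p in sorted(outputs.items())
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
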