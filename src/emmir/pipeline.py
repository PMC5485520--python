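"""End-to-end orchestration of the analysis stages.

Each stage is a function reading its inputs from the run directory and
writing its outputs there, so running stages individually composes to
exactly the ``run_all`` result. A JSON manifest records input hashes and
parameters for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import discovery, genome_map, preprocess, quantify, qpcr, reports, simulate, targets
from .config import PipelineConfig
from .seqtools import read_fasta, write_fasta

log = logging.getLogger("emmir")

STAGES = ("preprocess", "map", "discover", "quantify", "targets", "report")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: PipelineConfig, overwrite: bool = False) -> PipelineConfig:
    """Generate a synthetic dataset on disk and point the config at it."""
    out = _outdir(config) / "sim"
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} already holds a dataset (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    sp = config.simulate
    genome = simulate.generate_genome(sp.genome_length, gc=sp.gc, seed=config.seed)
    genome, truth = simulate.plant_hairpins(
        genome, sp.n_mirnas, seed=config.seed + 1, n_conserved=sp.n_conserved
    )
    truth = simulate.assign_fold_changes(
        truth, sp.n_up, sp.n_down, fold=sp.fold, seed=config.seed + 2
    )
    design = simulate.SimDesign(
        n_replicates=sp.n_replicates,
        library_depth=sp.library_depth,
        nb_dispersion=sp.nb_dispersion,
        adapter3=sp.adapter3,
        adapter5=sp.adapter5,
        contaminant_fraction=sp.contaminant_fraction,
        seed=config.seed + 3,
    )
    counts = simulate.simulate_counts(truth, design)
    ncrna = simulate.make_ncrna_references(seed=config.seed + 4)
    simulate.synthesize_reads(counts, truth, design, ncrna, out_dir=out)
    simulate.write_truth(truth, out)
    write_fasta([("chr1", genome)], out / "genome.fasta")
    n_ref = simulate.write_mature_reference(truth, out / "mature_ref.fasta")
    for cat, refs in ncrna.items():
        write_fasta(refs.items(), out / f"ncrna_{cat}.fasta")
    counts.to_csv(out / "true_counts.tsv", sep="\t")
    log.info("simulated %d miRNAs (%d with a conserved reference) over %d libraries",
             sp.n_mirnas, n_ref, len(design.libraries))
    config.genome = str(out / "genome.fasta")
    config.mature_reference = str(out / "mature_ref.fasta") if n_ref else None
    config.ncrna_references = {cat: str(out / f"ncrna_{cat}.fasta") for cat in ncrna}
    config.fastq = {lib: str(out / f"{lib}.fastq") for lib in design.libraries}
    return config


def run_preprocess(config: PipelineConfig) -> None:
    out = _outdir(config)
    sp = config.simulate
    tags, stats = preprocess.preprocess_fastq(
        config.fastq,
        adapter3=sp.adapter3,
        adapter5=sp.adapter5,
        min_len=config.preprocess.min_len,
        max_len=config.preprocess.max_len,
    )
    for lib, st in stats.items():
        log.info("%s: %d reads in = %d kept + %d removed", lib, st.total_reads,
                 st.high_quality_reads, st.rejected_reads)
        assert st.total_reads == st.high_quality_reads + st.rejected_reads
    preprocess.tags_to_fasta(tags, out / "tags.fasta")
    preprocess.tag_count_table(tags, list(config.fastq)).to_csv(out / "tag_counts.tsv", sep="\t")
    preprocess.stats_table(stats).to_csv(out / "library_stats.tsv", sep="\t")
    dist = preprocess.length_distribution(tags, by="total")
    pd.Series(dist, name="reads").rename_axis("length").to_csv(out / "length_distribution.tsv", sep="\t")


def _load_tags(out: Path) -> list[preprocess.UniqueTag]:
    df = pd.read_csv(out / "tag_counts.tsv", sep="\t", index_col=0)
    libs = [c for c in df.columns if c != "sequence"]
    return [
        preprocess.UniqueTag(
            tag_id=idx,
            sequence=row["sequence"],
            counts={lib: int(row[lib]) for lib in libs if int(row[lib]) > 0},
        )
        for idx, row in df.iterrows()
    ]


def run_map(config: PipelineConfig) -> None:
    out = _outdir(config)
    tags = _load_tags(out)
    genome = read_fasta(config.genome)
    ncrna = {cat: read_fasta(path) for cat, path in config.ncrna_references.items()}
    classes = genome_map.annotate_ncrna(tags, ncrna)
    index = genome_map.KmerIndex(genome, k=config.map.k)
    residual = [t for t in tags if t.tag_id not in classes]
    hits = genome_map.map_tags(
        residual, index, max_mismatches=config.map.max_mismatches, max_hits=config.map.max_hits
    )
    classes.update(genome_map.classify_residual(residual, hits))
    genome_map.hits_to_bed(hits, out / "hits.bed")
    pd.Series(classes, name="category").rename_axis("tag_id").to_csv(out / "tag_classes.tsv", sep="\t")

    stats = pd.read_csv(out / "library_stats.tsv", sep="\t", index_col=0)
    mapped = {lib: 0 for lib in stats.index}
    unique_mapped = {lib: 0 for lib in stats.index}
    tag_lookup = {t.tag_id: t for t in tags}
    for tag_id, th in hits.items():
        if not th.hits:
            continue
        for lib, c in tag_lookup[tag_id].counts.items():
            mapped[lib] += c
            unique_mapped[lib] += 1
    stats["mapped_reads"] = [mapped[lib] for lib in stats.index]
    stats["unique_mapped"] = [unique_mapped[lib] for lib in stats.index]
    stats.to_csv(out / "library_stats.tsv", sep="\t")


def run_discover(config: PipelineConfig) -> None:
    out = _outdir(config)
    dp = config.discovery
    tags = _load_tags(out)
    classes = pd.read_csv(out / "tag_classes.tsv", sep="\t", index_col=0)["category"]
    genome = read_fasta(config.genome)
    tags_by_id = {t.tag_id: t for t in tags}

    conserved: list[discovery.MiRNARecord] = []
    conserved_tag_ids: set[str] = set()
    candidates = [t for t in tags if classes.get(t.tag_id) == "candidate"]
    if config.mature_reference:
        refs = discovery.load_mature_references(read_fasta(config.mature_reference))
        conserved = discovery.call_conserved(
            candidates, refs, max_mismatches=dp.conserved_max_mismatches
        )
        for tag in candidates:
            if discovery.match_conserved(tag, refs, dp.conserved_max_mismatches) is not None:
                conserved_tag_ids.add(tag.tag_id)

    hit_rows = pd.read_csv(
        out / "hits.bed", sep="\t",
        names=["chrom", "start", "end", "tag_id", "mismatches", "strand"],
    )
    cand_ids = {t.tag_id for t in candidates} - conserved_tag_ids
    hits = [
        genome_map.AlignmentHit(r.tag_id, r.chrom, int(r.start), int(r.end), r.strand, int(r.mismatches))
        for r in hit_rows.itertuples()
        if r.tag_id in cand_ids
    ]
    loci = discovery.cluster_loci(hits, max_gap=dp.cluster_max_gap)
    criteria = discovery.HairpinCriteria(
        mature_min_len=dp.mature_min_len,
        mature_max_len=dp.mature_max_len,
        max_unpaired=dp.max_unpaired,
        max_unpaired_run=dp.max_unpaired_run,
        max_bulges=dp.max_bulges,
        bulge_size=dp.bulge_size,
        min_hairpin_len=dp.min_hairpin_len,
    )
    ir_params = dict(
        threshold=dp.ir_threshold,
        match=dp.ir_match,
        mismatch=dp.ir_mismatch,
        gap_penalty=dp.ir_gap_penalty,
        max_repeat=dp.ir_max_repeat,
        min_loop=dp.ir_min_loop,
    )
    novel = discovery.call_novel(
        loci, tags_by_id, genome,
        flank=dp.flank, ir_params=ir_params, pad=dp.extend_pad,
        criteria=criteria, fold_min_loop=dp.fold_min_loop,
    )
    log.info("called %d conserved and %d novel miRNAs from %d loci",
             len(conserved), len(novel), len(loci))

    records = conserved + novel
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.id,
                "kind": rec.kind,
                "family": rec.family or "",
                "mature_seq": rec.mature_seq,
                "star_seq": rec.star_seq or "",
                "precursors": ";".join(
                    f"{c}:{s}-{e}({st})" for c, s, e, st in rec.precursors
                ),
            }
        )
    pd.DataFrame(rows).to_csv(out / "mirna_records.tsv", sep="\t", index=False)
    libs = list(config.fastq)
    counts = pd.DataFrame(
        {lib: [rec.counts.get(lib, 0) for rec in records] for lib in libs},
        index=[rec.id for rec in records],
    )
    counts.index.name = "mirna_id"
    counts.to_csv(out / "mirna_counts.tsv", sep="\t")
    write_fasta(((rec.id, rec.mature_seq) for rec in records), out / "mirna_mature.fasta")
    with open(out / "novel_structures.txt", "w") as fh:
        for rec in novel:
            fh.write(f">{rec.id}\n{rec.mature_seq}\n{rec.structure}\n")
    with open(out / "novel_precursors.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in novel:
            for chrom, s, e, st in rec.precursors:
                fh.write(
                    f"{chrom}\temmir\tmiRNA_primary_transcript\t{s + 1}\t{e}\t.\t{st}\t.\tID={rec.id}\n"
                )


def run_quantify(config: PipelineConfig) -> None:
    out = _outdir(config)
    counts = pd.read_csv(out / "mirna_counts.tsv", sep="\t", index_col=0)
    if counts.empty:
        log.warning("no miRNAs to quantify")
        return
    stats = pd.read_csv(out / "library_stats.tsv", sep="\t", index_col=0)
    conditions = {lib: ("salt" if lib.startswith("S") else "control") for lib in counts.columns}
    totals = stats.loc[counts.columns, "mapped_reads"].astype(float)
    totals[totals <= 0] = counts.sum(axis=0)[totals <= 0]
    de = quantify.call_differential(
        counts, conditions,
        alpha=config.quantify.alpha,
        totals=totals,
        pseudocount=config.quantify.pseudocount,
    )
    de.to_csv(out / "differential_expression.tsv", sep="\t")
    seqs = {
        r["id"]: r["mature_seq"]
        for _, r in pd.read_csv(out / "mirna_records.tsv", sep="\t").iterrows()
    }
    quantify.de_table(de, seqs, out / "de_table.tsv")
    tpms = quantify.tpm_matrix(counts, totals)
    quantify.scaled_matrix(tpms).to_csv(out / "scaled_tpm.tsv", sep="\t")


def run_targets(config: PipelineConfig) -> None:
    out = _outdir(config)
    if not config.transcripts:
        log.info("no transcript set configured; skipping target scan")
        return
    transcripts = read_fasta(config.transcripts)
    mirnas = read_fasta(out / "mirna_mature.fasta")
    hits = targets.scan_all(
        mirnas, transcripts,
        max_mm=config.targets.max_mismatches,
        protected=tuple(config.targets.protected_positions),
    )
    targets.hits_table(hits, out / "target_hits.tsv")
    targets.target_summary(hits, sorted(mirnas)).to_csv(out / "target_summary.tsv", sep="\t")


def run_qpcr(config: PipelineConfig) -> None:
    out = _outdir(config)
    if not config.ct_table:
        log.info("no Ct table configured; skipping qPCR stage")
        return
    ct = pd.read_csv(config.ct_table, sep="\t")
    res = qpcr.relative_expression(
        ct,
        reference_id=config.qpcr.reference_id,
        control_sample=config.qpcr.control_sample,
        equal_var=config.qpcr.equal_var,
    )
    res.to_csv(out / "qpcr_relative_expression.tsv", sep="\t", index=False)


def run_report(config: PipelineConfig) -> None:
    out = _outdir(config)
    stats = pd.read_csv(out / "library_stats.tsv", sep="\t", index_col=0)
    tags = _load_tags(out)
    classes = pd.read_csv(out / "tag_classes.tsv", sep="\t", index_col=0)["category"].to_dict()
    cond_counts = {}
    for cond, prefix in (("salt", "S"), ("control", "Ck")):
        libs = [l for l in stats.index if l.startswith(prefix) and not (prefix == "S" and not l[1:].isdigit())]
        sub = stats.loc[libs]
        uniq = sum(1 for t in tags if any(t.counts.get(l, 0) > 0 for l in libs))
        uniq_mapped = 0
        mapped_ids = {t.tag_id for t in tags if classes.get(t.tag_id) not in (None,)}
        for t in tags:
            if any(t.counts.get(l, 0) > 0 for l in libs) and classes.get(t.tag_id) in (
                "candidate", "high_repeat", "low_expression"
            ):
                uniq_mapped += 1
        cond_counts[cond] = {
            "total": int(sub["total_reads"].sum()),
            "high_quality": int(sub["high_quality_reads"].sum()),
            "matched": int(sub["mapped_reads"].sum()),
            "unique": uniq,
            "unique_matched": uniq_mapped,
        }
    cat_counts = reports.category_counts_from_classes(tags, classes)
    t1, t2 = reports.composition_table(cond_counts, cat_counts)
    t1.to_csv(out / "table1_summary.tsv", sep="\t")
    t2.to_csv(out / "table2_categories.tsv", sep="\t")
    freq, first = reports.nucleotide_bias([t.sequence for t in tags])
    freq.to_csv(out / "nucleotide_bias.tsv", sep="\t")
    first.to_csv(out / "first_base_by_length.tsv", sep="\t")


def write_manifest(config: PipelineConfig) -> Path:
    out = _outdir(config)
    inputs = {}
    for label, path in [
        ("genome", config.genome),
        ("mature_reference", config.mature_reference),
        ("transcripts", config.transcripts),
        ("ct_table", config.ct_table),
        *[(f"fastq:{lib}", p) for lib, p in config.fastq.items()],
        *[(f"ncrna:{cat}", p) for cat, p in config.ncrna_references.items()],
    ]:
        if path and Path(path).exists():
            inputs[label] = _sha256(Path(path))
    outputs = {
        p.name: _sha256(p)
        for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.fasta")) + sorted(out.glob("*.gff3"))
    }
    manifest = {"inputs": inputs, "outputs": outputs, "parameters": asdict(config)}
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def run_all(config: PipelineConfig) -> Path:
    """Run every configured stage in order and write the manifest."""
    stage_funcs = {
        "preprocess": run_preprocess,
        "map": run_map,
        "discover": run_discover,
        "quantify": run_quantify,
        "targets": run_targets,
        "report": run_report,
    }
    for stage in STAGES:
        try:
            stage_funcs[stage](config)
        except Exception:
            marker = _outdir(config) / "FAILED"
            marker.write_text(f"stage failed: {stage}\n")
            log.exception("stage %r failed; partial outputs retained", stage)
            raise
    if config.ct_table:
        run_qpcr(config)
    return write_manifest(config)
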