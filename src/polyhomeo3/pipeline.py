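"""End-to-end orchestration: preprocess -> map -> extend -> count -> report.

A pipeline run is a pure function of (input files, parameters, seed): every
output file is recorded with its SHA-256 checksum in ``manifest.json``, so
two runs with the same config produce byte-identical manifests.  Stage
failures abort with the stage name; partial outputs are left in place for
inspection.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path
from typing import Optional

import pandas as pd

from polyhomeo3 import aligner, assign, depth, expression, preprocess, sim, triads
from polyhomeo3.annotation import extend_three_prime, read_gff3, write_gff3
from polyhomeo3.errors import ConfigurationError, PolyhomeoError

logger = logging.getLogger("polyhomeo3")


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    _validate_config(cfg, base=Path(path).parent)
    return cfg


def _validate_config(cfg: dict, base: Path) -> None:
    paths = cfg.get("paths", {})
    for key in ("reads", "references", "annotation", "outdir"):
        if key not in paths:
            raise ConfigurationError(f"pipeline config lacks paths.{key}")
    for key in ("reads", "references", "annotation"):
        p = base / paths[key]
        if not p.exists():
            raise ConfigurationError(f"paths.{key} does not exist: {p}")
    mode = cfg.get("mode", "hexaploid")
    if mode not in ("hexaploid", "null-subgenome"):
        raise ConfigurationError(f"mode must be 'hexaploid' or 'null-subgenome', got {mode!r}")
    if mode == "null-subgenome" and "null_label" not in cfg:
        raise ConfigurationError("null-subgenome mode requires a null_label entry")


def run_pipeline(config_path) -> dict:
    """Run every stage described by a TOML config; returns the manifest."""
    config_path = Path(config_path)
    cfg = load_config(config_path)
    base = config_path.parent
    paths = cfg["paths"]
    outdir = base / paths["outdir"]
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stats: dict = {}

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        current = stage("preprocess")
        params = preprocess.PreprocessParams(**cfg.get("preprocess", {}))
        clean_fastq = outdir / "preprocessed.fastq"
        report = preprocess.preprocess_fastq(base / paths["reads"], clean_fastq, params)
        report_path = outdir / "preprocess_report.tsv"
        report.to_tsv(report_path)
        outputs["preprocessed_fastq"] = clean_fastq
        outputs["preprocess_report"] = report_path
        stats["reads_in"] = report.reads_in
        stats["reads_preprocessed"] = report.reads_out

        current = stage("map")
        refs = _read_fasta(base / paths["references"])
        map_cfg = cfg.get("map", {})
        index = aligner.build_index(refs, k=map_cfg.get("k", 15))
        reads = preprocess.read_fastq(clean_fastq)
        calls = aligner.map_reads(
            index,
            reads,
            min_margin=map_cfg.get("min_margin", 1),
            seed_step=map_cfg.get("seed_step", 5),
        )
        sam_path = outdir / "alignments.sam"
        aligner.write_sam(calls, reads, refs, sam_path)
        outputs["alignments_sam"] = sam_path

        current = stage("assign")
        chrom_map = assign.chrom_map_from_names(refs)
        labels = [assign.assign_subgenome(c, chrom_map) for c in calls]
        t = assign.tally(labels)
        tally_path = outdir / "subgenome_tally.tsv"
        t.to_frame().to_csv(tally_path, sep="\t", index=False)
        outputs["subgenome_tally"] = tally_path
        stats["unique_assigned"] = t.n_subgenome_assigned
        stats["attributable_pct"] = t.attributable_pct
        if cfg.get("mode", "hexaploid") == "null-subgenome":
            est = assign.estimate_null_error(t, cfg["null_label"])
            err_path = outdir / "null_error_estimate.tsv"
            pd.DataFrame(
                [{"null_label": est.null_label, "error_pct": est.error_pct, **est.breakdown}]
            ).to_csv(err_path, sep="\t", index=False)
            outputs["null_error_estimate"] = err_path
            stats["null_error_pct"] = est.error_pct

        current = stage("extend_annotation")
        genes_base = read_gff3(base / paths["annotation"])
        ext_len = cfg.get("extend", {}).get("length", 1000)
        chrom_lengths = {name: len(seq) for name, seq in refs.items()}
        genes_ext = extend_three_prime(genes_base, ext_len, chrom_lengths)
        ext_gff = outdir / f"annotation_ext{ext_len}.gff3"
        write_gff3(genes_ext, ext_gff)
        outputs["extended_annotation"] = ext_gff

        current = stage("count")
        stranded = cfg.get("count", {}).get("stranded", "sense")
        unique_records = [c.record for c in calls if c.status == "unique"]
        n_multi = sum(1 for c in calls if c.status == "multi")
        counts_base = expression.count_reads(
            unique_records, genes_base, stranded=stranded, n_non_unique=n_multi,
            annotation_tag="original",
        )
        counts_ext = expression.count_reads(
            unique_records, genes_ext, stranded=stranded, n_non_unique=n_multi,
            annotation_tag=f"extended+{ext_len}",
        )
        for tag, table in (("base", counts_base), ("ext", counts_ext)):
            p = outdir / f"counts_{tag}.tsv"
            table.to_tsv(p)
            outputs[f"counts_{tag}"] = p
        cat_path = outdir / "count_categories.tsv"
        pd.concat(
            [counts_base.categories_frame(), counts_ext.categories_frame()]
        ).to_csv(cat_path, sep="\t", index=False)
        outputs["count_categories"] = cat_path
        comparison = expression.compare_annotations(counts_base, counts_ext)
        cmp_path = outdir / "annotation_comparison.tsv"
        pd.DataFrame([{k: v for k, v in comparison.items() if k != "classes"}]).to_csv(
            cmp_path, sep="\t", index=False
        )
        outputs["annotation_comparison"] = cmp_path
        stats["assigned_fraction_ext"] = comparison["assigned_fraction_ext"]

        current = stage("normalize")
        cpm_path = outdir / "cpm_ext.tsv"
        expression.cpm(counts_ext).rename("cpm").rename_axis("gene_id").reset_index().to_csv(
            cpm_path, sep="\t", index=False
        )
        outputs["cpm"] = cpm_path

        triad_list: list[triads.Triad] = []
        if "transcripts" in paths:
            current = stage("triads")
            transcript_sets = {
                label: {
                    name: seq for name, seq in _read_fasta(base / p).items()
                }
                for label, p in paths["transcripts"].items()
            }
            triad_list = triads.triads_from_transcripts(transcript_sets)
            triads_path = outdir / "triads.tsv"
            triads.write_triads(triad_list, triads_path)
            outputs["triads"] = triads_path
            stats["n_triads"] = len(triad_list)
            ternary, n_omitted = expression.ternary_fractions(triad_list, counts_ext.counts)
            ternary_path = outdir / "ternary_fractions.tsv"
            ternary.to_csv(ternary_path, sep="\t", index=False)
            outputs["ternary_fractions"] = ternary_path
            stats["n_triads_all_zero"] = n_omitted

        current = stage("downsample")
        ds_cfg = cfg.get("downsample", {})
        rates = list(ds_cfg.get("rates", list(depth.DEFAULT_RATES)))
        ds_seed = int(ds_cfg.get("seed", cfg.get("seed", 0)))
        _, assigned_gene_per_read = expression.count_reads(
            unique_records, genes_ext, stranded=stranded, return_assignments=True
        )
        summaries = [
            depth.detect(
                _labels_to_counts(assigned_gene_per_read, counts_ext.counts.index),
                triad_list,
                depth=len(assigned_gene_per_read),
                rate=1.0,
                seed=ds_seed,
            )
        ]
        nested = depth.nested_subsets(assigned_gene_per_read, rates, ds_seed)
        for rate in sorted(rates):
            subset = nested[rate]
            summaries.append(
                depth.detect(
                    _labels_to_counts(subset, counts_ext.counts.index),
                    triad_list,
                    depth=len(subset),
                    rate=rate,
                    seed=ds_seed,
                )
            )
        det_path = outdir / "detection.tsv"
        depth.detection_table(summaries).to_csv(det_path, sep="\t", index=False)
        outputs["detection"] = det_path
        fit = depth.fit_saturation(summaries)
        fit_path = outdir / "saturation_fit.json"
        with open(fit_path, "w") as fh:
            json.dump(
                {"intercept": fit.intercept, "slope": fit.slope, "rss": fit.rss},
                fh,
                indent=2,
                sort_keys=True,
            )
        outputs["saturation_fit"] = fit_path
        stats["detected_genes_full"] = summaries[0].n_detected_genes
    except PolyhomeoError as exc:
        raise PolyhomeoError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest = {
        "mode": cfg.get("mode", "hexaploid"),
        "files": {
            name: {
                "path": str(p.relative_to(outdir)),
                "sha256": _sha256(p),
                "bytes": p.stat().st_size,
            }
            for name, p in sorted(outputs.items())
        },
        "stats": stats,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _labels_to_counts(labels, index) -> pd.Series:
    s = pd.Series(labels).value_counts()
    return s.reindex(index, fill_value=0)


def make_demo(
    outdir,
    seed: int = 0,
    mode: str = "hexaploid",
    n_genes: int = 200,
    n_reads: int = 50_000,
    utr_truncate: int = 150,
) -> Path:
    """Emit a ready-to-run simulated dataset plus pipeline config.

    Simulates a three-subgenome polyploid at the default divergence regime,
    writes references, a deliberately 3'-truncated annotation (to exercise
    the extension stage), transcript FASTAs, 3' reads with truth labels, and
    a ``pipeline.toml``; returns the config path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes = sim.simulate_subgenomes(sim.SimConfig(n_genes=n_genes, seed=seed))
    genomes.write_fasta(outdir / "references.fa")
    genomes.write_gff3(outdir / "annotation.gff3", truncate_bp=utr_truncate)
    transcript_paths = genomes.write_transcripts(outdir)
    excluded = frozenset({"D"}) if mode == "null-subgenome" else frozenset()
    reads, truth = sim.simulate_3prime_reads(
        genomes,
        sim.ReadSimConfig(n_reads=n_reads, excluded_subgenomes=excluded, seed=seed + 1),
    )
    sim.write_fastq(reads, outdir / "reads.fastq")
    sim.write_truth(truth, outdir / "truth.tsv")

    lines = [
        f'mode = "{mode}"',
        f"seed = {seed}",
    ]
    if mode == "null-subgenome":
        lines.append('null_label = "D"')
    lines += [
        "",
        "[paths]",
        'reads = "reads.fastq"',
        'references = "references.fa"',
        'annotation = "annotation.gff3"',
        'outdir = "out"',
        "",
        "[paths.transcripts]",
    ]
    for label, p in sorted(transcript_paths.items()):
        lines.append(f'{label} = "{p.name}"')
    lines += [
        "",
        "[extend]",
        "length = 500",
        "",
        "[downsample]",
        "rates = [0.2, 0.4, 0.6, 0.8]",
        f"seed = {seed}",
        "",
    ]
    config_path = outdir / "pipeline.toml"
    config_path.write_text("\n".join(lines))
    return config_path
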