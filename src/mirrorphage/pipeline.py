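"""End-to-end orchestration: simulate/load -> cluster -> conserve -> coevolve.

Every stage writes its tables before the next begins, so a failed run
leaves the completed stages on disk together with a FAILED marker in the
run summary.  Identical configuration and seed give byte-identical output
files.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, DataError
from .records import CATEGORIES, DistanceMatrix, HitRecord, OrfRecord
from . import clustering, coevolution, conservation, io as mio, simulate as sim

logger = logging.getLogger("mirrorphage")


@dataclass
class PipelineConfig:
    """One run of the full analysis.

    ``mode`` is ``"synthetic"`` (generate the inputs) or ``"fasta"`` (read a
    directory of per-contig protein FASTAs plus a reference FASTA and a
    category TSV; pre-computed tabular hits and .mldist matrices optional).
    """

    mode: str = "synthetic"
    out_dir: str = "mirrorphage_out"
    seed: int = 0
    coverage_threshold: float = 0.8
    significance_threshold: float = 1e-3
    min_contig_orfs: int = 2
    min_shared: int = 5
    lenient_coverage: float = 0.25
    focal_category: str = "Capsid"
    # synthetic mode
    simulation: sim.SimulationConfig | None = None
    # fasta mode
    fasta_dir: str | None = None
    reference_fasta: str | None = None
    category_table: str | None = None
    hits_table: str | None = None
    mldist_dir: str | None = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "fasta"):
            raise ConfigError(f"unknown input mode {self.mode!r}")
        if not 0 < self.coverage_threshold <= 1:
            raise ConfigError("coverage_threshold must be in (0,1]")
        if self.significance_threshold <= 0:
            raise ConfigError("significance_threshold must be positive")
        if self.min_contig_orfs < 1 or self.min_shared < 1:
            raise ConfigError("count thresholds must be >= 1")
        if self.mode == "fasta":
            for name in ("fasta_dir", "reference_fasta", "category_table"):
                if getattr(self, name) is None:
                    raise ConfigError(f"fasta mode requires {name}")


@dataclass
class RunReport:
    config: dict
    version: str = __version__
    status: str = "OK"
    counts: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    capsid_test: dict | None = None


def _setup_logging(out_dir: str) -> logging.Handler:
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s [%(levelname)s] %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def _load_inputs(config: PipelineConfig, out_dir: str):
    """Stage 1: produce (reference_orfs, all_orfs, categories)."""
    if config.mode == "synthetic":
        simcfg = config.simulation or sim.SimulationConfig(seed=config.seed)
        dataset = sim.simulate(simcfg)
        paths = sim.write_dataset(dataset, os.path.join(out_dir, "synthetic"))
        logger.info(
            "simulated %d genomes, %d families",
            simcfg.n_genomes,
            simcfg.n_families,
        )
        categories = {
            dataset.reference_orf_for_family(f): cat
            for f, cat in dataset.truth.category.items()
        }
        return dataset.reference_orfs(), dataset.all_orfs(), categories, paths
    reference = mio.read_orf_fasta(config.reference_fasta)
    all_orfs = mio.read_orf_fasta_dir(config.fasta_dir)
    cats = pd.read_csv(config.category_table, sep="\t")
    categories = dict(zip(cats.iloc[:, 0], cats.iloc[:, 1]))
    return reference, all_orfs, categories, {}


def _get_hits(config, reference, all_orfs, threshold):
    if config.mode == "fasta" and config.hits_table:
        raw = mio.read_hits_table(config.hits_table)
        return clustering.filter_imported_hits(
            raw,
            {r.orf_id: len(r.sequence) for r in reference},
            coverage_threshold=threshold,
            significance_threshold=config.significance_threshold,
        )
    return clustering.search_homologs(
        reference,
        all_orfs,
        coverage_threshold=threshold,
        significance_threshold=config.significance_threshold,
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    handler = _setup_logging(out_dir)
    report = RunReport(config={k: str(v) for k, v in asdict(config).items()})
    stage = "inputs"
    try:
        reference, all_orfs, categories, paths = _load_inputs(config, out_dir)
        report.paths.update(paths)
        all_orfs = clustering.deduplicate_contigs(all_orfs)
        n_contigs_in = len({o.contig_id for o in all_orfs})
        report.counts["contigs_in"] = n_contigs_in

        stage = "clustering"
        hits = _get_hits(config, reference, all_orfs, config.coverage_threshold)
        clusters = clustering.build_clusters(
            hits, all_orfs, reference, categories, config.coverage_threshold
        )
        retained, clusters = clustering.filter_contigs(
            clusters, min_orfs=config.min_contig_orfs
        )
        report.counts["contigs_retained"] = len(retained)
        report.counts["contigs_filtered"] = n_contigs_in - len(retained)
        report.counts["clusters"] = len(clusters)
        duplications = clustering.detect_duplications(clusters)
        lenient_hits = _get_hits(config, reference, all_orfs, config.lenient_coverage)
        splits = clustering.detect_split_genes(lenient_hits, all_orfs, reference)
        # a split gene's two pieces also pair up as an apparent duplication in
        # lenient clusters; at the working threshold they rarely both qualify,
        # but drop any duplication event explained by a detected split
        split_pairs = {
            (s.reference_orf_id, s.contig_id) for s in splits
        }
        duplications = [
            d for d in duplications if (d.cluster_id, d.contig_id) not in split_pairs
        ]
        report.counts["duplication_events"] = len(duplications)
        report.counts["split_gene_events"] = len(splits)
        _write_cluster_tables(out_dir, clusters, duplications, splits, report)

        stage = "conservation"
        hits_by_subject = {}
        for h in hits:
            hits_by_subject.setdefault(h.query_id, {})[h.subject_id] = h
        ref_len = {r.orf_id: len(r.sequence) for r in reference}
        alignments = {}
        for c in clusters:
            if not c.members:
                continue
            alignments[c.cluster_id] = clustering.cluster_alignment(
                c,
                reference_length=ref_len[c.reference_orf_ids[0]],
                hits_by_subject=hits_by_subject.get(c.reference_orf_ids[0], {}),
            )
        records = [
            conservation.ConservationRecord(
                c.cluster_id,
                len(c.members),
                conservation.alignment_information(alignments[c.cluster_id]),
                c.category,
            )
            for c in clusters
            if c.cluster_id in alignments
        ]
        correlations = conservation.conservation_size_correlation(
            records, group_by="category"
        ) + conservation.conservation_size_correlation(records, group_by="all")
        _write_conservation_tables(out_dir, records, correlations, report)

        stage = "coevolution"
        dms: dict[str, DistanceMatrix] = {}
        if config.mode == "fasta" and config.mldist_dir:
            import glob

            for p in sorted(glob.glob(os.path.join(config.mldist_dir, "*.mldist"))):
                cid = os.path.splitext(os.path.basename(p))[0]
                dms[cid] = mio.read_distance_matrix(p)
        else:
            for cid, aln in alignments.items():
                if len(aln) >= 2:
                    dms[cid] = coevolution.distances_from_alignment(aln)
        if len(dms) >= 2:
            summary = coevolution.all_pairs_summary(
                dms,
                categories={c.cluster_id: c.category for c in clusters},
                min_shared=config.min_shared,
            )
            report.counts["pairs_reported"] = summary.n_reported
            report.counts["pairs_discarded"] = summary.n_discarded
            report.counts["pairs_undefined"] = summary.n_undefined
            cats_by_cluster = {c.cluster_id: c.category for c in clusters}
            focal_present = any(
                cats_by_cluster.get(cid) == config.focal_category
                and not math.isnan(v)
                for cid, v in summary.per_cluster_mean.items()
            )
            rest_present = any(
                cats_by_cluster.get(cid) != config.focal_category
                and not math.isnan(v)
                for cid, v in summary.per_cluster_mean.items()
            )
            if focal_present and rest_present:
                u, p = coevolution.category_test(
                    summary.per_cluster_mean, cats_by_cluster, config.focal_category
                )
                report.capsid_test = {
                    "focal": config.focal_category,
                    "U": u,
                    "p_one_tailed": p,
                }
            _write_coevolution_tables(out_dir, summary, report)

        stage = "summary"
        _write_summary(out_dir, report)
        logger.info("run complete")
        return report
    except Exception:
        report.status = f"FAILED at stage {stage}"
        try:
            _write_summary(out_dir, report)
        except OSError:
            pass
        logger.exception("pipeline failed at stage %s", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_cluster_tables(out_dir, clusters, duplications, splits, report):
    rows = []
    for c in clusters:
        for m in c.members:
            rows.append(
                (c.cluster_id, "+".join(c.reference_orf_ids), c.category,
                 m.contig_id, m.orf_id)
            )
    df = pd.DataFrame(
        rows, columns=["cluster_id", "reference_orf_ids", "category",
                       "contig_id", "orf_id"]
    )
    p = os.path.join(out_dir, "clusters.tsv")
    df.to_csv(p, sep="\t", index=False)
    report.paths["clusters"] = p

    sizes = pd.DataFrame(
        [(c.cluster_id, c.category, len(c.members)) for c in clusters],
        columns=["cluster_id", "category", "n_members"],
    )
    p = os.path.join(out_dir, "cluster_sizes_by_category.tsv")
    sizes.to_csv(p, sep="\t", index=False)
    report.paths["cluster_sizes"] = p

    p = os.path.join(out_dir, "duplications.tsv")
    pd.DataFrame(
        [(d.cluster_id, d.contig_id, ",".join(d.orf_ids)) for d in duplications],
        columns=["cluster_id", "contig_id", "orf_ids"],
    ).to_csv(p, sep="\t", index=False)
    report.paths["duplication_events"] = p

    p = os.path.join(out_dir, "split_genes.tsv")
    pd.DataFrame(
        [
            (s.reference_orf_id, s.contig_id, s.n_terminal_orf,
             s.c_terminal_orf, s.marker_orf or "")
            for s in splits
        ],
        columns=["reference_orf_id", "contig_id", "n_terminal_orf",
                 "c_terminal_orf", "marker_orf"],
    ).to_csv(p, sep="\t", index=False)
    report.paths["split_gene_events"] = p


def _write_conservation_tables(out_dir, records, correlations, report):
    p = os.path.join(out_dir, "conservation.tsv")
    pd.DataFrame(
        [(r.cluster_id, r.category, r.n_sequences, r.mean_information)
         for r in records],
        columns=["cluster_id", "category", "n_sequences", "mean_information_bits"],
    ).to_csv(p, sep="\t", index=False, float_format="%.6f")
    report.paths["conservation"] = p

    p = os.path.join(out_dir, "conservation_correlation.tsv")
    pd.DataFrame(
        [(c.group, c.r, c.p_value, c.n) for c in correlations],
        columns=["group", "R", "p", "n"],
    ).to_csv(p, sep="\t", index=False, float_format="%.6g")
    report.paths["conservation_correlation"] = p


def _write_coevolution_tables(out_dir, summary, report):
    p = os.path.join(out_dir, "coevolution_pairs.tsv")
    pd.DataFrame(
        [
            (q.cluster_a, q.cluster_b, q.n_shared,
             "" if math.isnan(q.r) else f"{q.r:.6f}",
             "" if math.isnan(q.p_value) else f"{q.p_value:.6g}",
             q.status)
            for q in summary.pairs
        ],
        columns=["cluster_a", "cluster_b", "n_shared", "r", "p", "status"],
    ).to_csv(p, sep="\t", index=False)
    report.paths["coevolution_pairs"] = p

    p = os.path.join(out_dir, "coevolution_matrix.tsv")
    summary.r_matrix.to_csv(p, sep="\t", float_format="%.6f", index_label="cluster_id")
    report.paths["coevolution_matrix"] = p

    p = os.path.join(out_dir, "coevolution_per_cluster_mean.tsv")
    pd.DataFrame(
        sorted(summary.per_cluster_mean.items()),
        columns=["cluster_id", "mean_r"],
    ).to_csv(p, sep="\t", index=False, float_format="%.6f")
    report.paths["coevolution_per_cluster_mean"] = p

    edges = coevolution.HISTOGRAM_EDGES
    p = os.path.join(out_dir, "coevolution_histogram.tsv")
    pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": summary.histogram,
        }
    ).to_csv(p, sep="\t", index=False, float_format="%.2f")
    report.paths["coevolution_histogram"] = p

    p = os.path.join(out_dir, "coevolution_category_means.tsv")
    rows = [(cat, summary.category_means.get(cat, float("nan")))
            for cat in CATEGORIES]
    pd.DataFrame(rows, columns=["category", "mean_of_means"]).to_csv(
        p, sep="\t", index=False, float_format="%.6f"
    )
    report.paths["coevolution_category_means"] = p


def _write_summary(out_dir, report):
    p = os.path.join(out_dir, "run_summary.json")
    with open(p, "w") as fh:
        json.dump(
            {
                "version": report.version,
                "status": report.status,
                "counts": report.counts,
                "capsid_test": report.capsid_test,
                "config": report.config,
                "paths": report.paths,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    report.paths["run_summary"] = p
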