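"""End-to-end orchestration: parse, expand, pair, compare, benchmark, report.

A single YAML config drives the whole analysis. Reports are JSON-first (TSV
mirrors for the tabular parts), deterministic given identical inputs and
config: keys are sorted, no timestamps are embedded, and the run metadata
carries the package version, the seed and a hash of the resolved config so a
report can be traced back to its run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
import time
from dataclasses import asdict, dataclass, field
from importlib import resources

import yaml

from . import __version__
from .compare import (
    match_complexes,
    pair_overlap_matrix,
    protein_overlap,
    proteins_per_complex_distribution,
    size_statistics,
)
from .enrichment import (
    average_allele_similarities,
    contact_similarity_comparison,
    read_similarity_table,
    relative_difference_comparison,
    standard_enrichment,
)
from .io import (
    ComplexDataset,
    expand_paralog_sets,
    expand_subcomplexes,
    map_identifiers,
    read_complex_table,
    read_contacts,
    read_id_mapping,
    read_paralog_sets,
)
from .pairs import background_pairs, cocomplex_pairs, map_pairs, restrict_to_tested
from .standards import (
    classify_complexes_by_slim,
    coannotation_standard,
    coexpression_standard,
    colocalization_standard,
    consensus_genetic_interactions,
    read_annotations,
    read_coexpression_scores,
    read_gi_screens,
    read_localizations,
    read_obo,
    read_ontology_edges,
)

__all__ = ["RunConfig", "load_config", "default_slim_roots", "run_full_analysis"]

logger = logging.getLogger("complexome")


@dataclass
class DatasetConfig:
    name: str
    path: str
    dialect: str = "simple_tsv"
    paralogs: str | None = None
    mapping: str | None = None
    contacts: str | None = None
    drop_unmapped: bool = False


@dataclass
class RunConfig:
    datasets: list[DatasetConfig]
    output_dir: str = "reports"
    seed: int = 0
    jaccard_thresholds: list[float] = field(default_factory=lambda: [1.0, 0.75, 0.5])
    min_size: int = 3
    coexpression_cutoff: float = 1.0
    max_annotation_count: float | None = None
    gi_screens: str | None = None
    coexpression: str | None = None
    localizations: str | None = None
    annotations: str | None = None
    ontology: str | None = None
    relative_difference_values: dict[str, str] = field(default_factory=dict)
    similarity_table: str | None = None
    slim_roots: list[str] | None = None
    slim_annotations: str | None = None
    run_comparison: bool = True
    run_standards: bool = True
    run_contacts: bool = True
    run_slim: bool = True

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("config must list at least one dataset")
        if not self.jaccard_thresholds:
            raise ValueError("jaccard_thresholds must be nonempty")


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    datasets = [DatasetConfig(**d) for d in raw.pop("datasets")]
    return RunConfig(datasets=datasets, **raw)


def default_slim_roots() -> list[str]:
    """The 12 default SLIM roots shipped with the package."""
    text = resources.files("complexome").joinpath("data/slim_roots.yaml").read_text()
    return [entry["id"] for entry in yaml.safe_load(text)["slim_roots"]]


def _config_hash(cfg: RunConfig) -> str:
    payload = asdict(cfg)
    payload.pop("output_dir")  # where the report lands is not part of the run
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _load_dataset(dc: DatasetConfig, warnings_out: list[str]) -> ComplexDataset:
    ds = read_complex_table(dc.path, dialect=dc.dialect, dataset_name=dc.name)
    if dc.contacts:
        by_id = read_contacts(dc.contacts)
        for rec in ds.records:
            if rec.complex_id in by_id:
                rec.contacts = by_id[rec.complex_id]
    ds = expand_subcomplexes(ds)
    if dc.paralogs:
        ds.paralog_sets = read_paralog_sets(dc.paralogs)
        ds = expand_paralog_sets(ds)
    if dc.mapping:
        ds, unmapped = map_identifiers(
            ds, read_id_mapping(dc.mapping), drop_unmapped=dc.drop_unmapped
        )
        if unmapped:
            warnings_out.append(
                f"{dc.name}: {len(unmapped)} unmapped identifiers"
            )
    return ds


def _stage(name: str):
    """Decorator-free stage wrapper: times a stage, re-raises with its name."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the configured pipeline and write the report bundle.

    Stages: load+expand datasets, per-dataset size statistics and
    multifunctionality, pairwise dataset comparison at every Jaccard
    threshold, functional standards with enrichment of co-complex over
    background pairs, relative-difference comparison, direct-vs-indirect
    contact analysis, and SLIM classification. Toggled-off stages are
    skipped. The returned dict is also written to ``report.json``.
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    warnings_out: list[str] = []
    report: dict = {
        "metadata": {
            "package_version": __version__,
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
        },
        "warnings": warnings_out,
    }

    with _stage("load"):
        datasets = [_load_dataset(dc, warnings_out) for dc in cfg.datasets]

    with _stage("size_statistics"):
        stats = {}
        for ds in datasets:
            st = size_statistics(ds)
            hist, frac_one = proteins_per_complex_distribution(ds)
            stats[ds.dataset_name] = {
                **asdict(st),
                "size_histogram": {str(k): v for k, v in st.size_histogram.items()},
                "n_cocomplex_pairs": len(cocomplex_pairs(ds)),
                "proteins_per_complex": {str(k): v for k, v in hist.items()},
                "fraction_in_one_complex": frac_one,
            }
        report["size_statistics"] = stats

    if cfg.run_comparison and len(datasets) >= 2:
        with _stage("comparison"):
            comp: dict = {"protein_overlap": {}, "complex_matching": {}}
            for i, da in enumerate(datasets):
                for db in datasets[i + 1 :]:
                    key = f"{da.dataset_name}|{db.dataset_name}"
                    comp["protein_overlap"][key] = protein_overlap(da, db)
                    per_thr = {}
                    for thr in cfg.jaccard_thresholds:
                        matches, fa, fb = match_complexes(
                            da, db, threshold=thr, min_size=cfg.min_size
                        )
                        per_thr[str(thr)] = {
                            "n_matches": len(matches),
                            "matched_fraction_a": fa,
                            "matched_fraction_b": fb,
                        }
                    comp["complex_matching"][key] = per_thr
            comp["pair_overlap_matrix"] = pair_overlap_matrix(datasets)
            report["comparison"] = comp

    if cfg.run_standards:
        with _stage("standards"):
            standards: dict[str, tuple] = {}
            if cfg.gi_screens:
                gi = consensus_genetic_interactions(read_gi_screens(cfg.gi_screens))
                standards["gi_negative"] = (gi.pairs_with("negative"), gi.tested)
                standards["gi_positive"] = (gi.pairs_with("positive"), gi.tested)
            if cfg.coexpression:
                std, uni = coexpression_standard(
                    read_coexpression_scores(cfg.coexpression),
                    cutoff=cfg.coexpression_cutoff,
                )
                standards["coexpression"] = (std, uni)
            ont = None
            if cfg.ontology:
                ont = (
                    read_obo(cfg.ontology)
                    if cfg.ontology.endswith(".obo")
                    else read_ontology_edges(cfg.ontology)
                )
            enr: dict = {}
            for ds in datasets:
                co = cocomplex_pairs(ds)
                bg = background_pairs(ds)
                per_std = {}
                for name, (std, uni) in standards.items():
                    co_t, cov = restrict_to_tested(co, uni)
                    if not co_t.pairs:
                        warnings_out.append(
                            f"{ds.dataset_name}/{name}: no tested co-complex pairs"
                        )
                        continue
                    res = standard_enrichment(co, bg, std, uni)
                    per_std[name] = {"coverage_cocomplex": cov, **res.as_dict()}
                # protein-level standards classify only this dataset's pairs
                cand = co.pairs | bg.pairs
                if cfg.localizations:
                    locs = read_localizations(cfg.localizations)
                    std, uni = colocalization_standard(locs, candidate_pairs=cand)
                    co_t, cov = restrict_to_tested(co, uni)
                    if co_t.pairs:
                        res = standard_enrichment(co, bg, std, uni)
                        per_std["colocalization"] = {
                            "coverage_cocomplex": cov,
                            **res.as_dict(),
                        }
                if cfg.annotations and ont is not None:
                    ann, _ns = read_annotations(cfg.annotations)
                    std, uni = coannotation_standard(
                        ann,
                        ont,
                        max_annotation_count=cfg.max_annotation_count,
                        candidate_pairs=cand,
                    )
                    co_t, cov = restrict_to_tested(co, uni)
                    if co_t.pairs:
                        res = standard_enrichment(co, bg, std, uni)
                        per_std["coannotation"] = {
                            "coverage_cocomplex": cov,
                            **res.as_dict(),
                        }
                if per_std:
                    enr[ds.dataset_name] = per_std
            if enr:
                report["enrichment"] = enr

            if cfg.relative_difference_values:
                rd: dict = {}
                for measure, path in cfg.relative_difference_values.items():
                    values = _read_value_table(path)
                    per_ds = {}
                    for ds in datasets:
                        per_ds[ds.dataset_name] = relative_difference_comparison(
                            cocomplex_pairs(ds), background_pairs(ds), values
                        )
                    rd[measure] = per_ds
                report["relative_difference"] = rd

    if cfg.run_contacts and cfg.similarity_table:
        with _stage("contacts"):
            sims = read_similarity_table(cfg.similarity_table)
            gene_sims = average_allele_similarities(sims)
            contacts_report = {}
            for ds in datasets:
                if any(rec.contacts for rec in ds.records):
                    res = contact_similarity_comparison(ds, gene_sims)
                    res.pop("distributions")
                    contacts_report[ds.dataset_name] = res
            if contacts_report:
                report["contacts"] = contacts_report

    if cfg.run_slim and cfg.ontology:
        with _stage("slim"):
            ont = (
                read_obo(cfg.ontology)
                if cfg.ontology.endswith(".obo")
                else read_ontology_edges(cfg.ontology)
            )
            roots = set(cfg.slim_roots) if cfg.slim_roots else set(default_slim_roots())
            roots &= ont.terms  # only roots present in the supplied ontology
            if roots:
                ann = None
                if cfg.slim_annotations:
                    ann, _ = read_annotations(cfg.slim_annotations)
                slim = {}
                for ds in datasets:
                    per_root, overall = classify_complexes_by_slim(
                        ds, ont, roots, ann=ann
                    )
                    slim[ds.dataset_name] = {
                        "per_root": per_root,
                        "n_annotated": overall,
                        "n_complexes": len(ds),
                    }
                report["slim"] = slim

    out_path = os.path.join(cfg.output_dir, "report.json")
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_tsv_mirrors(report, cfg.output_dir)
    logger.info("report written to %s", out_path)
    return report


def _read_value_table(path) -> dict[str, float]:
    values: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            values[cols[0].strip()] = float(cols[1])
    return values


def _write_tsv_mirrors(report: dict, outdir: str) -> None:
    """TSV mirrors of the tabular report sections."""
    if "size_statistics" in report:
        rows = ["dataset\tn_complexes\tn_proteins\tmax_size\tmean_size\tmedian_size\tn_cocomplex_pairs"]
        for name, st in sorted(report["size_statistics"].items()):
            rows.append(
                f"{name}\t{st['n_complexes']}\t{st['n_proteins']}\t{st['max_size']}"
                f"\t{st['mean_size']:.2f}\t{st['median_size']:g}\t{st['n_cocomplex_pairs']}"
            )
        with open(os.path.join(outdir, "size_statistics.tsv"), "w") as fh:
            fh.write("\n".join(rows) + "\n")
    if "enrichment" in report:
        rows = ["dataset\tstandard\tfraction_cocomplex\tfraction_background\tfold\tp_value"]
        for ds, per_std in sorted(report["enrichment"].items()):
            for std, r in sorted(per_std.items()):
                rows.append(
                    f"{ds}\t{std}\t{r['fraction_cocomplex']:.4f}"
                    f"\t{r['fraction_background']:.4f}\t{r['fold']:.3f}\t{r['p_value']:.3g}"
                )
        with open(os.path.join(outdir, "enrichment.tsv"), "w") as fh:
            fh.write("\n".join(rows) + "\n")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
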