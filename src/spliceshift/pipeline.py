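"""End-to-end orchestration: detect -> quantify -> test -> enrich.

A run is driven by a flat key/value config (YAML).  Every stage writes a TSV
with a provenance header (package version, config hash, seed), logs its
event/gene counts, and leaves earlier outputs intact if a later stage fails.
Outputs are byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .differential_test import (DEFAULT_BF_THRESHOLD, DEFAULT_MIN_COVERAGE,
                                DEFAULT_MIN_IDENTITY, DEFAULT_MIN_READS,
                                call_differential, calls_to_table,
                                gene_level_calls)
from .enrichment_stats import (build_reference_universe,
                               event_type_distribution_test,
                               splicing_gene_enrichment, term_enrichment)
from .event_detection import event_catalog, events_from_table
from .gene_models import read_gtf
from .psi_quant import EventCounts, assign_reads, psi_posterior
from .synthetic_data import reads_from_table

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; carries the full list of problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class PipelineError(RuntimeError):
    """A pipeline stage failed; earlier stage outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Inputs, thresholds and flags of one pipeline run."""

    gtf: str = ""
    counts: str = ""                # precomputed event-count TSV, or
    reads: str = ""                 # block-level read TSV (one of the two)
    annotations: str = ""           # gene_id <tab> term_id
    term_parents: str = ""          # child <tab> parent
    splicing_genes: str = ""        # one gene id per line
    expression: str = ""            # gene_id <tab> reads
    exclude_genes: str = ""         # one gene id per line
    out_dir: str = "spliceshift_run"
    min_reads: int = DEFAULT_MIN_READS
    bf_threshold: float = DEFAULT_BF_THRESHOLD
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE
    enrichment_alpha: float = 0.01
    go_report_cutoff: float = 0.005
    propagate_terms: bool = True
    yates: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        # out_dir does not influence any result, so it stays out of the hash
        payload = json.dumps(
            {f.name: getattr(self, f.name) for f in dc_fields(self)
             if f.name != "out_dir"},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_RANGES = {
    "min_reads": (0, 10_000),
    "bf_threshold": (0.0, float("inf")),
    "min_identity": (0.0, 100.0),
    "min_coverage": (0.0, 1.0),
    "enrichment_alpha": (0.0, 1.0),
    "go_report_cutoff": (0.0, 1.0),
}


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a flat YAML config; all problems reported together."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a flat key/value mapping"])
    known = {f.name: f.type for f in dc_fields(RunConfig)}
    errors: list[str] = []
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            log.warning("config: unknown key %r ignored", key)
            continue
        kwargs[key] = value
    config = RunConfig()
    for key, value in kwargs.items():
        default = getattr(config, key)
        try:
            coerced = type(default)(value)
        except (TypeError, ValueError):
            errors.append(f"{key}: cannot interpret {value!r} as "
                          f"{type(default).__name__}")
            continue
        if key in _RANGES:
            lo, hi = _RANGES[key]
            if not (lo <= coerced <= hi):
                errors.append(f"{key}: {coerced} outside [{lo}, {hi}]")
                continue
        setattr(config, key, coerced)
    for key in ("gtf", "counts", "reads", "annotations", "term_parents",
                "splicing_genes", "expression", "exclude_genes"):
        value = getattr(config, key)
        if value and not Path(value).exists():
            errors.append(f"{key}: file not found: {value}")
    if not config.gtf:
        errors.append("gtf: required input missing")
    if not config.counts and not config.reads:
        errors.append("one of counts/reads is required")
    if errors:
        raise ConfigError(errors)
    return config


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with path.open("w") as fh:
        fh.write(f"# spliceshift {__version__}\n")
        fh.write(f"# config_hash={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def quantify_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample PSI posterior summaries from an event-count table."""
    rows = []
    for rec in counts.itertuples(index=False):
        post = psi_posterior(EventCounts(rec.event_id, rec.sample_id,
                                         int(rec.inclusion), int(rec.exclusion)))
        rows.append({
            "event_id": rec.event_id, "sample_id": rec.sample_id,
            "psi_mean": post.mean, "ci_low": post.ci_low,
            "ci_high": post.ci_high, "n_specific": post.n_specific,
        })
    return pd.DataFrame(rows, columns=["event_id", "sample_id", "psi_mean",
                                       "ci_low", "ci_high", "n_specific"])


def counts_from_reads(events_df: pd.DataFrame, reads_df: pd.DataFrame,
                      gene_by_event: Mapping[str, str] | None = None
                      ) -> pd.DataFrame:
    """Assign block-level reads to events, per sample.

    Sample ids of the form ``<condition>_r<replicate>`` are split into the
    condition/replicate columns that the differential stage expects.
    """
    events = events_from_table(events_df)
    by_sample = reads_from_table(reads_df)
    rows = []
    for event in events:
        for sample_id in sorted(by_sample):
            sample_reads = [r for r in by_sample[sample_id]]
            counts = assign_reads(event, sample_reads, sample_id=sample_id)
            cond, _, rep = sample_id.rpartition("_r")
            rows.append({
                "event_id": event.event_id,
                "gene_id": (gene_by_event or {}).get(event.event_id,
                                                     event.gene_id),
                "sample_id": sample_id,
                "condition": cond or sample_id,
                "replicate": int(rep) if rep.isdigit() else 1,
                "inclusion": counts.inclusion,
                "exclusion": counts.exclusion,
            })
    return pd.DataFrame(rows, columns=[
        "event_id", "gene_id", "sample_id", "condition", "replicate",
        "inclusion", "exclusion"])


def differential_from_counts(counts: pd.DataFrame,
                             bf_threshold: float = DEFAULT_BF_THRESHOLD,
                             min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Filtered pooled Bayes-factor calls for every event in a count table."""
    conditions = sorted(counts["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(f"expected exactly two conditions, got {conditions}")
    calls = []
    for event_id, group in counts.groupby("event_id", sort=True):
        gene_id = str(group["gene_id"].iloc[0]) if "gene_id" in group else ""
        by_cond = {
            cond: [
                EventCounts(event_id, r.sample_id, int(r.inclusion),
                            int(r.exclusion))
                for r in group[group["condition"] == cond]
                .sort_values("replicate").itertuples(index=False)
            ]
            for cond in conditions
        }
        calls.append(call_differential(by_cond, gene_id=gene_id,
                                       bf_threshold=bf_threshold,
                                       min_reads=min_reads))
    return calls_to_table(calls)


def run_pipeline(config: RunConfig) -> dict:
    """Execute detect -> quantify -> diff -> enrich; return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "stages": {}}

    stage = "detect"
    try:
        genes = read_gtf(config.gtf)
        catalog = event_catalog(genes)
        _write_tsv(catalog, out / "events.tsv", config)
        report["stages"][stage] = {
            "genes": len(genes), "events": len(catalog),
            "type_counts": catalog.attrs["type_counts"],
        }
        log.info("detect: %d genes, %d events", len(genes), len(catalog))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "quantify"
    try:
        if config.counts:
            counts = read_tsv(config.counts)
        else:
            reads_df = read_tsv(config.reads)
            counts = counts_from_reads(catalog, reads_df)
        psi = quantify_from_counts(counts)
        _write_tsv(counts, out / "counts.tsv", config)
        _write_tsv(psi, out / "psi.tsv", config)
        report["stages"][stage] = {
            "events": int(counts["event_id"].nunique()),
            "samples": int(counts["sample_id"].nunique()),
        }
        log.info("quantify: %d events x %d samples",
                 counts["event_id"].nunique(), counts["sample_id"].nunique())
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "diff"
    try:
        calls = differential_from_counts(counts, config.bf_threshold,
                                         config.min_reads)
        _write_tsv(calls, out / "calls.tsv", config)
        n_sig = int(calls["significant"].sum())
        report["stages"][stage] = {
            "events_tested": len(calls), "significant_events": n_sig,
            "significant_genes": len(gene_level_calls(calls)),
        }
        log.info("diff: %d/%d events significant", n_sig, len(calls))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "enrich"
    try:
        enrich_report = {}
        catalog_five = catalog[catalog["etype"] != "complex"]
        diff_events = catalog_five[catalog_five["event_id"].isin(
            set(calls.loc[calls["significant"], "event_id"]))]
        dist = event_type_distribution_test(diff_events, catalog_five)
        _write_tsv(dist, out / "event_type_distribution.tsv", config)
        enrich_report["type_shift_min_p"] = (
            float(dist["p"].min()) if len(dist) else 1.0)

        if config.expression:
            expr = read_tsv(config.expression)
            expression = dict(zip(expr.iloc[:, 0], expr.iloc[:, 1]))
        else:
            expression = {g.gene_id: 1 for g in genes}
        exclude = (_read_list(config.exclude_genes)
                   if config.exclude_genes else set())
        universe = build_reference_universe(genes, expression, exclude)
        diff_genes = gene_level_calls(calls) & universe

        if config.splicing_genes:
            splicing = _read_list(config.splicing_genes)
            frac, stat, p = splicing_gene_enrichment(diff_genes, splicing,
                                                     universe)
            enrich_report["splicing_gene_fraction"] = frac
            enrich_report["splicing_gene_p"] = p
        if config.annotations:
            ann_df = read_tsv(config.annotations)
            annotations: dict[str, set[str]] = {}
            for rec in ann_df.itertuples(index=False):
                annotations.setdefault(str(rec[0]), set()).add(str(rec[1]))
            parents = []
            if config.term_parents:
                par_df = read_tsv(config.term_parents)
                parents = [(str(r[0]), str(r[1]))
                           for r in par_df.itertuples(index=False)]
            terms = term_enrichment(annotations, diff_genes, universe,
                                    propagate=config.propagate_terms,
                                    parent_edges=parents)
            _write_tsv(terms, out / "term_enrichment.tsv", config)
            enrich_report["terms_tested"] = len(terms)
            enrich_report["terms_below_cutoff"] = int(
                (terms["q"] < config.go_report_cutoff).sum()) if len(terms) else 0
        report["stages"][stage] = enrich_report
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    with (out / "run_report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _read_list(path: str | Path) -> set[str]:
    with Path(path).open() as fh:
        return {line.strip() for line in fh
                if line.strip() and not line.startswith("#")}
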