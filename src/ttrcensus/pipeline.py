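"""End-to-end TTR census pipeline: read → TM features → classify →
summarise → statistics → report bundle.

All outputs are plain TSV/JSON and deterministic: rerunning an identical
configuration yields byte-identical files.  Every output embeds the
hashes of the analysis settings, registry and area table plus the seed,
so a result can always be traced to its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

from . import resources
from .classify import TTRRecord, classify_protein, resolve_overlaps
from .genome_stats import (
    adjusted_correlation,
    domain_composition_tally,
    genome_summary,
    raft_stratified_sensory_test,
    taxon_aggregate,
)
from .io_annotation import (
    InputFormatError,
    format_gtdb_taxonomy,
    read_domain_hits,
    read_genome_meta,
    read_proteome_fasta,
    read_tm_segments,
    load_registry,
)
from .tm_features import AreaTable, TMParams, TMProfile, TMRegion, predict_tm_regions, tm_profile

log = logging.getLogger("ttrcensus")

NA = "NA"


class ValidationError(ValueError):
    """Configuration or input validation failure (exit code 1)."""


class StageError(RuntimeError):
    """Failure inside a pipeline stage (exit code 2)."""


@dataclass
class PipelineConfig:
    proteome: str
    hits: str
    genome_meta: str
    outdir: str
    tm_segments: str | None = None
    hits_dialect: str = "tsv"
    registry_path: str | None = None
    area_table_path: str | None = None
    max_i_evalue: float = 1e-5
    max_overlap: int = 15
    min_genomes: int = 10
    tm_params: TMParams = field(default_factory=TMParams)
    distinct_sensory_models: bool = False
    equal_var: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.min_genomes < 1:
            raise ValidationError("min_genomes must be >= 1")
        for name in ("proteome", "hits", "genome_meta"):
            path = getattr(self, name)
            if not path or not os.path.isfile(path):
                raise ValidationError(f"{name} file not found: {path!r}")
        for name in ("tm_segments", "registry_path", "area_table_path"):
            path = getattr(self, name)
            if path is not None and not os.path.isfile(path):
                raise ValidationError(f"{name} file not found: {path!r}")

    def analysis_settings(self) -> dict:
        """The settings that determine analysis results (no paths)."""
        return {
            "max_i_evalue": self.max_i_evalue,
            "max_overlap": self.max_overlap,
            "min_genomes": self.min_genomes,
            "tm_params": asdict(self.tm_params),
            "distinct_sensory_models": self.distinct_sensory_models,
            "equal_var": self.equal_var,
        }


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _sha256_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def provenance(config: PipelineConfig, table: AreaTable) -> dict:
    registry_path = config.registry_path or resources.default_registry_path()
    table_path = config.area_table_path or resources.default_area_table_path()
    return {
        "config_hash": _sha256_obj(config.analysis_settings()),
        "registry_sha256": _sha256_file(registry_path),
        "area_table_sha256": _sha256_file(table_path),
        "calibration_factor": round(table.calibration_factor, 6),
        "seed": config.seed,
    }


# ---------------------------------------------------------------------------
# classification stage


def build_profiles(proteins, tm_map, tm_params: TMParams, table: AreaTable) -> dict:
    """TM profile per protein: supplied segments take precedence; the
    hydropathy predictor is only consulted for proteins absent from the
    supplied map (or when no map was supplied at all)."""
    profiles = {}
    for prot in proteins:
        if tm_map is not None and prot.protein_id in tm_map:
            regions = [TMRegion(s, e) for s, e in tm_map[prot.protein_id]]
        else:
            regions = predict_tm_regions(prot.sequence, tm_params)
        profiles[prot.protein_id] = tm_profile(prot.sequence, regions, tm_params, table)
    return profiles


def classify_cohort(
    proteins, hits, profiles, registry, max_overlap=15, distinct_sensory_models=False
):
    """Resolve per-protein hit overlaps and classify every protein.

    Returns (records, resolved_hits_by_protein).
    """
    by_protein: dict = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    resolved = {
        pid: resolve_overlaps(hs, max_overlap=max_overlap)
        for pid, hs in by_protein.items()
    }
    records = [
        classify_protein(
            prot,
            resolved.get(prot.protein_id, []),
            profiles[prot.protein_id],
            registry,
            distinct_sensory_models=distinct_sensory_models,
        )
        for prot in proteins
    ]
    return records, resolved


# ---------------------------------------------------------------------------
# statistics


def _pct(x, nd=4):
    return None if x is None else round(100.0 * x, nd)


def _pair_dict(pair) -> dict:
    return {
        "undefined": pair.undefined,
        "spearman_rho": pair.spearman_rho,
        "spearman_p": pair.spearman_p,
        "kendall_tau": pair.kendall_tau,
        "kendall_p": pair.kendall_p,
    }


def _superkingdom_block(records, summaries) -> dict:
    ttrs = [r for r in records if r.is_ttr]
    n_ttr = len(ttrs)
    block: dict = {
        "n_genomes": len(summaries),
        "n_ttr_total": n_ttr,
        "n_ttr_bearing_genomes": sum(1 for s in summaries if s.n_ttr > 0),
    }
    if summaries:
        import numpy as np

        ttr_counts = [s.n_ttr for s in summaries]
        bearing = [s.n_ttr for s in summaries if s.n_ttr > 0]
        block["mean_ttr_per_genome"] = round(float(np.mean(ttr_counts)), 4)
        block["sd_ttr_per_genome"] = (
            round(float(np.std(ttr_counts, ddof=1)), 4) if len(ttr_counts) > 1 else None
        )
        block["mean_ttr_per_ttr_bearing_genome"] = (
            round(float(np.mean(bearing)), 4) if bearing else None
        )
        block["pct_ttr_cds_mean"] = _pct(float(np.mean([s.ratio_ttr_cds for s in summaries])))
        ttr_st = [s.ratio_ttr_st for s in summaries if s.ratio_ttr_st is not None]
        block["pct_ttr_st_mean"] = _pct(float(np.mean(ttr_st))) if ttr_st else None
        block["pct_st_cds_mean"] = _pct(float(np.mean([s.ratio_st_cds for s in summaries])))
    if n_ttr:
        import numpy as np

        block["hybrid_pct"] = _pct(sum(1 for r in ttrs if r.is_hybrid) / n_ttr)
        block["pass_class_pct"] = {
            "single_pass": _pct(sum(1 for r in ttrs if r.pass_class == "single_pass") / n_ttr),
            "two_pass": _pct(sum(1 for r in ttrs if r.pass_class == "two_pass") / n_ttr),
            "multi_pass": _pct(sum(1 for r in ttrs if r.pass_class == "multi_pass") / n_ttr),
        }
        block["raft_pct"] = _pct(sum(1 for r in ttrs if r.tm_profile.raft_flag) / n_ttr)
        block["mean_sa_per_aa"] = round(
            float(np.mean([r.tm_profile.sa_per_aa for r in ttrs])), 4
        )
        block["mean_tm_length"] = round(
            float(np.mean([r.tm_profile.mean_length for r in ttrs])), 4
        )
        block["mean_tm_per_ttr"] = round(
            float(np.mean([r.tm_profile.n_regions for r in ttrs])), 4
        )
    try:
        corr = adjusted_correlation(summaries)
        block["adjusted_correlation"] = {
            "n": corr.n,
            "ttr_vs_st_minus_ttr": _pair_dict(corr.ttr_vs_st_minus_ttr),
            "ttr_vs_cds_minus_st": _pair_dict(corr.ttr_vs_cds_minus_st),
            "shapiro_wilk": {
                k: (None if v is None else {"W": round(v[0], 6), "p": v[1]})
                for k, v in corr.shapiro.items()
            },
        }
    except ValueError as exc:
        block["adjusted_correlation"] = {"unavailable": str(exc)}
    return block


def compute_statistics(records, metas, min_genomes=10, equal_var=True) -> dict:
    """The statistics report: cohort and per-superkingdom blocks.

    Computable from classification records plus genome metadata alone,
    so `report` reproduces it exactly from a per-protein table.
    """
    by_genome: dict = {}
    for r in records:
        by_genome.setdefault(r.genome_id, []).append(r)
    summaries = [genome_summary(by_genome.get(m.genome_id, []), m) for m in metas]
    sk_of = {m.genome_id: m.superkingdom for m in metas}

    stats: dict = {"cohort": {}, "bacteria": {}, "archaea": {}}
    cohort = _superkingdom_block(records, summaries)
    try:
        t = raft_stratified_sensory_test(records, equal_var=equal_var)
        cohort["raft_stratified_sensory_test"] = {
            "n_low": t.n_low, "n_high": t.n_high,
            "mean_low": round(t.mean_low, 4), "mean_high": round(t.mean_high, 4),
            "sd_low": round(t.sd_low, 4), "sd_high": round(t.sd_high, 4),
            "t_statistic": round(t.t_statistic, 4), "p_value": t.p_value,
            "equal_var": t.equal_var,
        }
    except ValueError as exc:
        cohort["raft_stratified_sensory_test"] = {"unavailable": str(exc)}
    stats["cohort"] = cohort
    for sk in ("bacteria", "archaea"):
        sk_records = [r for r in records if sk_of.get(r.genome_id) == sk]
        sk_summaries = [s for s in summaries if s.superkingdom == sk]
        stats[sk] = _superkingdom_block(sk_records, sk_summaries)
    return stats, summaries


# ---------------------------------------------------------------------------
# output writers / readers


PER_PROTEIN_COLUMNS = (
    "protein_id", "genome_id", "is_ttr", "is_hybrid", "is_st", "has_dna_binding",
    "pass_class", "n_tm", "mean_tm_length", "sa_per_aa", "raft_flag",
    "n_sensory_domains", "dna_binding_models",
)


def _fmt(v) -> str:
    if v is None:
        return NA
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)


def _header_lines(prov: dict, title: str) -> str:
    provline = " ".join(f"{k}={v}" for k, v in prov.items())
    return f"# ttrcensus {title}\n# {provline}\n"


def write_per_protein_tsv(records, path, prov) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(prov, "per-protein table"))
        fh.write("\t".join(PER_PROTEIN_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: (r.genome_id, r.protein_id)):
            p = r.tm_profile
            fh.write("\t".join([
                r.protein_id, r.genome_id, _fmt(r.is_ttr), _fmt(r.is_hybrid),
                _fmt(r.is_st), _fmt(r.has_dna_binding), r.pass_class,
                str(p.n_regions), _fmt(p.mean_length), _fmt(p.sa_per_aa),
                _fmt(p.raft_flag), str(r.n_sensory_domains),
                ";".join(sorted(r.dna_binding_models)) or NA,
            ]) + "\n")


def read_per_protein_tsv(path) -> list:
    """Rebuild classification records from a per-protein table (for the
    statistics-only `report` path)."""
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("protein_id"):
                continue
            c = line.rstrip("\n").split("\t")
            if len(c) != len(PER_PROTEIN_COLUMNS):
                raise InputFormatError(
                    f"per-protein table: expected {len(PER_PROTEIN_COLUMNS)} columns, "
                    f"got {len(c)}"
                )
            n_tm = int(c[7])
            profile = TMProfile(
                n_regions=n_tm,
                regions=(),
                mean_length=None if c[8] == NA else float(c[8]),
                sa_per_aa=None if c[9] == NA else float(c[9]),
                raft_flag=None if c[10] == NA else bool(int(c[10])),
            )
            records.append(TTRRecord(
                protein_id=c[0], genome_id=c[1],
                is_ttr=bool(int(c[2])), is_hybrid=bool(int(c[3])),
                is_st=bool(int(c[4])), has_dna_binding=bool(int(c[5])),
                pass_class=c[6], n_sensory_domains=int(c[11]),
                dna_binding_models=frozenset() if c[12] == NA else frozenset(c[12].split(";")),
                tm_profile=profile,
            ))
    return records


def write_per_genome_tsv(summaries, path, prov) -> None:
    cols = ("genome_id", "taxonomy", "superkingdom", "cds_total", "n_proteins",
            "n_st", "n_ttr", "n_hybrid", "n_dna_binding_total",
            "ratio_ttr_cds", "ratio_ttr_st", "ratio_st_cds", "mean_tm_per_ttr")
    with open(path, "w") as fh:
        fh.write(_header_lines(prov, "per-genome table"))
        fh.write("\t".join(cols) + "\n")
        for s in sorted(summaries, key=lambda s: s.genome_id):
            fh.write("\t".join([
                s.genome_id, format_gtdb_taxonomy(s.taxonomy), s.superkingdom,
                str(s.cds_total), str(s.n_proteins), str(s.n_st), str(s.n_ttr),
                str(s.n_hybrid), str(s.n_dna_binding_total),
                _fmt(s.ratio_ttr_cds), _fmt(s.ratio_ttr_st), _fmt(s.ratio_st_cds),
                _fmt(s.mean_tm_per_ttr),
            ]) + "\n")


def write_per_taxon_tsv(taxa, path, prov) -> None:
    cols = ("taxon", "superkingdom", "n_genomes", "included",
            "mean_n_ttr", "sd_n_ttr", "mean_ratio_ttr_cds", "sd_ratio_ttr_cds",
            "mean_ratio_ttr_st", "sd_ratio_ttr_st", "mean_ratio_st_cds",
            "sd_ratio_st_cds", "hybrid_fraction", "mean_tm_per_ttr")
    with open(path, "w") as fh:
        fh.write(_header_lines(prov, "per-taxon table"))
        fh.write("\t".join(cols) + "\n")
        for t in taxa:
            fh.write("\t".join([
                t.taxon_key, t.superkingdom, str(t.n_genomes), _fmt(t.included),
                _fmt(t.mean_n_ttr), _fmt(t.sd_n_ttr),
                _fmt(t.mean_ratio_ttr_cds), _fmt(t.sd_ratio_ttr_cds),
                _fmt(t.mean_ratio_ttr_st), _fmt(t.sd_ratio_ttr_st),
                _fmt(t.mean_ratio_st_cds), _fmt(t.sd_ratio_st_cds),
                _fmt(t.hybrid_fraction), _fmt(t.mean_tm_per_ttr),
            ]) + "\n")


def write_domain_tally_tsv(rows, path, prov) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(prov, "domain tally"))
        fh.write("model\tn_ttrs\tfraction\tcumulative_coverage\n")
        for model, n, frac, cum in rows:
            fh.write(f"{model}\t{n}\t{frac:.6g}\t{cum:.6g}\n")


# ---------------------------------------------------------------------------
# run


@dataclass
class PipelineResult:
    records: list
    summaries: list
    taxa: list
    statistics: dict
    tallies: dict
    outputs: dict  # name -> path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle into ``config.outdir``."""
    config.validate()
    registry = (
        load_registry(config.registry_path)
        if config.registry_path
        else resources.default_registry()
    )
    table = (
        AreaTable.from_yaml(config.area_table_path)
        if config.area_table_path
        else resources.default_area_table()
    )
    prov = provenance(config, table)
    log_lines = []

    def stage(msg):
        log.info(msg)
        log_lines.append(msg)

    try:
        proteins = read_proteome_fasta(config.proteome)
        stage(f"read: {len(proteins)} proteins")
        hits = read_domain_hits(config.hits, config.hits_dialect, config.max_i_evalue)
        stage(f"read: {len(hits)} domain hits (i-Evalue <= {config.max_i_evalue:g})")
        tm_map = read_tm_segments(config.tm_segments) if config.tm_segments else None
        stage(
            "read: TM segments for "
            + (f"{len(tm_map)} proteins" if tm_map is not None else "0 proteins (predictor fallback)")
        )
        metas = read_genome_meta(config.genome_meta)
        stage(f"read: {len(metas)} genomes")

        profiles = build_profiles(proteins, tm_map, config.tm_params, table)
        n_with_tm = sum(1 for p in profiles.values() if p.n_regions > 0)
        stage(f"tm_features: {n_with_tm} proteins with >=1 TM region")

        records, resolved = classify_cohort(
            proteins, hits, profiles, registry,
            max_overlap=config.max_overlap,
            distinct_sensory_models=config.distinct_sensory_models,
        )
        n_ttr = sum(1 for r in records if r.is_ttr)
        n_hybrid = sum(1 for r in records if r.is_hybrid)
        stage(f"classify: {n_ttr} TTRs ({n_hybrid} hybrid) among {len(records)} proteins")

        statistics, summaries = compute_statistics(
            records, metas, config.min_genomes, config.equal_var
        )
        statistics = {"provenance": prov, **statistics}
        taxa = taxon_aggregate(summaries, config.min_genomes)
        tallies = domain_composition_tally(records, resolved, registry)
        stage(
            f"summarize: {len(summaries)} genomes, {len(taxa)} taxa "
            f"({sum(1 for t in taxa if t.included)} with >= {config.min_genomes} genomes)"
        )
    except (InputFormatError, FileNotFoundError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise StageError(str(exc)) from exc

    os.makedirs(config.outdir, exist_ok=True)
    outputs = {
        "per_protein": os.path.join(config.outdir, "per_protein.tsv"),
        "per_genome": os.path.join(config.outdir, "per_genome.tsv"),
        "per_taxon": os.path.join(config.outdir, "per_taxon.tsv"),
        "domain_tally_dna_binding": os.path.join(config.outdir, "domain_tally_dna_binding.tsv"),
        "domain_tally_sensory": os.path.join(config.outdir, "domain_tally_sensory.tsv"),
        "statistics": os.path.join(config.outdir, "statistics.json"),
        "log": os.path.join(config.outdir, "run.log"),
    }
    written = []
    try:
        write_per_protein_tsv(records, outputs["per_protein"], prov)
        written.append(outputs["per_protein"])
        write_per_genome_tsv(summaries, outputs["per_genome"], prov)
        written.append(outputs["per_genome"])
        write_per_taxon_tsv(taxa, outputs["per_taxon"], prov)
        written.append(outputs["per_taxon"])
        write_domain_tally_tsv(tallies["dna_binding"], outputs["domain_tally_dna_binding"], prov)
        written.append(outputs["domain_tally_dna_binding"])
        write_domain_tally_tsv(tallies["sensory"], outputs["domain_tally_sensory"], prov)
        written.append(outputs["domain_tally_sensory"])
        with open(outputs["statistics"], "w") as fh:
            json.dump(statistics, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(outputs["statistics"])
        with open(outputs["log"], "w") as fh:
            for line in log_lines:
                fh.write(line + "\n")
        written.append(outputs["log"])
    except Exception as exc:  # partial bundle must not survive
        for path in written:
            try:
                os.remove(path)
            except OSError:
                pass
        raise StageError(f"failed writing outputs: {exc}") from exc

    return PipelineResult(records, summaries, taxa, statistics, tallies, outputs)


def run_report(per_protein_path, genome_meta_path, outdir, config: PipelineConfig | None = None) -> dict:
    """Recompute the statistics JSON from a prior per-protein table.

    With the same analysis settings this reproduces a bundle's
    statistics.json byte-for-byte.
    """
    config = config or PipelineConfig(
        proteome=per_protein_path, hits=per_protein_path,
        genome_meta=genome_meta_path, outdir=outdir,
    )
    records = read_per_protein_tsv(per_protein_path)
    if not any(r.is_ttr for r in records):
        raise ValidationError("no TTRs in input")
    metas = read_genome_meta(genome_meta_path)
    table = (
        AreaTable.from_yaml(config.area_table_path)
        if config.area_table_path
        else resources.default_area_table()
    )
    statistics, _ = compute_statistics(records, metas, config.min_genomes, config.equal_var)
    statistics = {"provenance": provenance(config, table), **statistics}
    os.makedirs(outdir, exist_ok=True)
    out = os.path.join(outdir, "statistics.json")
    with open(out, "w") as fh:
        json.dump(statistics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return statistics
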