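"""Genome-, taxon- and cohort-level statistics of the TTR census.

Per genome: TTR, hybrid-TTR and signal-transduction (ST) counts plus the
three normalisation ratios (TTR/CDS, TTR/ST, ST/CDS).  Per taxon
(``phylum;class``): unweighted means and sample SDs over genomes, with
taxa below a minimum genome count excluded from statistical output but
retained in a census sidebar.  Cohort level: rank correlations between
TTR counts and the rest of the signalling repertoire and proteome —
computed on the count partition (TTR, ST−TTR, CDS−ST) so a count never
correlates with a superset containing itself — plus Shapiro–Wilk
normality checks and the raft-stratified comparison of sensory-domain
counts (classic two-sample t test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import PASS_CLASSES, TTRRecord
from .io_annotation import GenomeMeta


@dataclass(frozen=True)
class GenomeSummary:
    """Counts and ratios for one genome.

    Ratios with a zero denominator are ``None`` (absent), never 0.
    """

    genome_id: str
    taxonomy: tuple
    superkingdom: str
    cds_total: int
    n_proteins: int
    n_st: int
    n_ttr: int
    n_hybrid: int
    n_dna_binding_total: int
    tm_count_histogram: dict
    mean_tm_per_ttr: float | None

    @property
    def taxon_key(self) -> str:
        return f"{self.taxonomy[1]};{self.taxonomy[2]}"

    @property
    def ratio_ttr_cds(self) -> float:
        return self.n_ttr / self.cds_total

    @property
    def ratio_ttr_st(self) -> float | None:
        return None if self.n_st == 0 else self.n_ttr / self.n_st

    @property
    def ratio_st_cds(self) -> float:
        return self.n_st / self.cds_total


def genome_summary(records, meta: GenomeMeta) -> GenomeSummary:
    """Tally one genome's records against its metadata."""
    records = list(records)
    for rec in records:
        if rec.genome_id != meta.genome_id:
            raise ValueError(
                f"record {rec.protein_id!r} belongs to genome {rec.genome_id!r}, "
                f"not {meta.genome_id!r}"
            )
    if meta.cds_total < len(records):
        raise ValueError(
            f"genome {meta.genome_id!r}: cds_total {meta.cds_total} < "
            f"{len(records)} supplied proteins"
        )
    ttrs = [r for r in records if r.is_ttr]
    hist: dict = {}
    for r in ttrs:
        hist[r.tm_profile.n_regions] = hist.get(r.tm_profile.n_regions, 0) + 1
    return GenomeSummary(
        genome_id=meta.genome_id,
        taxonomy=meta.taxonomy,
        superkingdom=meta.superkingdom,
        cds_total=meta.cds_total,
        n_proteins=len(records),
        n_st=sum(1 for r in records if r.is_st),
        n_ttr=len(ttrs),
        n_hybrid=sum(1 for r in ttrs if r.is_hybrid),
        n_dna_binding_total=sum(1 for r in records if r.has_dna_binding),
        tm_count_histogram=hist,
        mean_tm_per_ttr=(
            sum(r.tm_profile.n_regions for r in ttrs) / len(ttrs) if ttrs else None
        ),
    )


@dataclass(frozen=True)
class TaxonSummary:
    """Aggregate over the genomes of one ``phylum;class`` taxon."""

    taxon_key: str
    superkingdom: str
    n_genomes: int
    included: bool  # meets the minimum-genome rule for statistical output
    mean_n_ttr: float
    sd_n_ttr: float | None
    mean_ratio_ttr_cds: float
    sd_ratio_ttr_cds: float | None
    mean_ratio_ttr_st: float | None
    sd_ratio_ttr_st: float | None
    mean_ratio_st_cds: float
    sd_ratio_st_cds: float | None
    hybrid_fraction: float | None  # sum(hybrid)/sum(ttr) over the taxon
    mean_tm_per_ttr: float | None


def _mean_sd(values) -> tuple:
    values = [v for v in values if v is not None]
    if not values:
        return None, None
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else None
    return mean, sd


def taxon_aggregate(summaries, min_genomes: int = 10) -> list:
    """Group genome summaries by ``phylum;class`` and aggregate.

    Genomes with an empty phylum are routed to an ``unclassified`` bucket
    rather than dropped.  Taxa with fewer than ``min_genomes`` genomes
    are flagged ``included=False`` (census sidebar only).
    """
    groups: dict = {}
    for s in summaries:
        key = s.taxon_key if s.taxonomy[1] else "unclassified"
        groups.setdefault(key, []).append(s)
    out = []
    for key in sorted(groups):
        gs = groups[key]
        mean_ttr, sd_ttr = _mean_sd([g.n_ttr for g in gs])
        m_tc, s_tc = _mean_sd([g.ratio_ttr_cds for g in gs])
        m_ts, s_ts = _mean_sd([g.ratio_ttr_st for g in gs])
        m_sc, s_sc = _mean_sd([g.ratio_st_cds for g in gs])
        tot_ttr = sum(g.n_ttr for g in gs)
        tot_hyb = sum(g.n_hybrid for g in gs)
        mtm, _ = _mean_sd([g.mean_tm_per_ttr for g in gs])
        out.append(
            TaxonSummary(
                taxon_key=key,
                superkingdom=gs[0].superkingdom,
                n_genomes=len(gs),
                included=len(gs) >= min_genomes,
                mean_n_ttr=mean_ttr,
                sd_n_ttr=sd_ttr,
                mean_ratio_ttr_cds=m_tc,
                sd_ratio_ttr_cds=s_tc,
                mean_ratio_ttr_st=m_ts,
                sd_ratio_ttr_st=s_ts,
                mean_ratio_st_cds=m_sc,
                sd_ratio_st_cds=s_sc,
                hybrid_fraction=(tot_hyb / tot_ttr) if tot_ttr else None,
                mean_tm_per_ttr=mtm,
            )
        )
    return out


@dataclass(frozen=True)
class PairCorrelation:
    spearman_rho: float | None
    spearman_p: float | None
    kendall_tau: float | None
    kendall_p: float | None
    undefined: bool


@dataclass(frozen=True)
class CorrelationReport:
    """Adjusted rank correlations over a genome cohort.

    Vectors: x = TTR count, y = ST count minus TTR count, z = CDS count
    minus ST count — the three cells of the count partition, so neither
    tested pair shares members.  Spearman uses average ranks for ties;
    Kendall is the tie-corrected tau-b.
    """

    n: int
    ttr_vs_st_minus_ttr: PairCorrelation
    ttr_vs_cds_minus_st: PairCorrelation
    shapiro: dict  # vector name -> (W, p) or None when n out of range


def _pair(x, y) -> PairCorrelation:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return PairCorrelation(None, None, None, None, undefined=True)
    rho, rho_p = stats.spearmanr(x, y)
    tau, tau_p = stats.kendalltau(x, y)  # tau-b by default
    return PairCorrelation(
        float(rho), float(rho_p), float(tau), float(tau_p), undefined=False
    )


def _shapiro(v) -> tuple | None:
    if len(v) < 3 or np.all(v == v[0]):
        return None
    w, p = stats.shapiro(v)
    return float(w), float(p)


def adjusted_correlation(summaries) -> CorrelationReport:
    """Rank correlations of TTR counts against the adjusted ST and
    proteome counts.

    The adjustment subtracts TTR counts from ST counts and ST counts
    from total protein counts before correlating, removing the
    contribution of a count correlating with itself.
    """
    summaries = list(summaries)
    if len(summaries) < 3:
        raise ValueError(f"need >= 3 genomes for correlation, got {len(summaries)}")
    x = np.array([s.n_ttr for s in summaries], dtype=float)
    y = np.array([s.n_st - s.n_ttr for s in summaries], dtype=float)
    z = np.array([s.cds_total - s.n_st for s in summaries], dtype=float)
    return CorrelationReport(
        n=len(summaries),
        ttr_vs_st_minus_ttr=_pair(x, y),
        ttr_vs_cds_minus_st=_pair(x, z),
        shapiro={
            "n_ttr": _shapiro(x),
            "n_st_minus_ttr": _shapiro(y),
            "cds_minus_st": _shapiro(z),
        },
    )


@dataclass(frozen=True)
class StratifiedTestResult:
    n_low: int
    n_high: int
    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    t_statistic: float
    p_value: float
    equal_var: bool


def raft_stratified_sensory_test(
    ttr_records, equal_var: bool = True
) -> StratifiedTestResult:
    """Compare sensory-domain counts between raft-propensity strata.

    Strata are TTRs whose pooled TM surface area is at/below the raft
    threshold (``raft_flag`` true) versus above it.  The default test is
    the classic pooled-variance two-sample t test, two-tailed; Welch's
    form is available via ``equal_var=False``.
    """
    low = [r.n_sensory_domains for r in ttr_records if r.is_ttr and r.tm_profile.raft_flag]
    high = [
        r.n_sensory_domains
        for r in ttr_records
        if r.is_ttr and r.tm_profile.raft_flag is False
    ]
    for name, grp in (("at/below-threshold", low), ("above-threshold", high)):
        if len(grp) < 2:
            raise ValueError(
                f"stratum {name!r} has {len(grp)} TTRs; need >= 2 per stratum"
            )
    low_a, high_a = np.array(low, float), np.array(high, float)
    if np.array_equal(low_a, high_a) and np.std(low_a) == 0:
        t, p = 0.0, 1.0  # degenerate identical-constant strata
    else:
        t, p = stats.ttest_ind(low_a, high_a, equal_var=equal_var)
    return StratifiedTestResult(
        n_low=len(low),
        n_high=len(high),
        mean_low=float(np.mean(low_a)),
        mean_high=float(np.mean(high_a)),
        sd_low=float(np.std(low_a, ddof=1)),
        sd_high=float(np.std(high_a, ddof=1)),
        t_statistic=float(t),
        p_value=float(p),
        equal_var=equal_var,
    )


def domain_composition_tally(ttr_records, hits_by_protein, registry) -> dict:
    """Rank DNA-binding and sensory models by the fraction of TTRs
    carrying them.

    Returns ``{"dna_binding": rows, "sensory": rows}`` where each row is
    ``(model, n_ttrs, fraction, cumulative_coverage)``; the cumulative
    coverage is the fraction of TTRs carrying at least one of the top-k
    models (set union, so a TTR with two top models counts once).
    """
    ttrs = [r for r in ttr_records if r.is_ttr]
    carriers_dna: dict = {}
    carriers_sens: dict = {}
    for r in ttrs:
        for h in hits_by_protein.get(r.protein_id, []):
            if h.model_name in registry.dna_binding or (
                h.model_accession and h.model_accession in registry.dna_binding
            ):
                carriers_dna.setdefault(h.model_name, set()).add(r.protein_id)
            else:
                carriers_sens.setdefault(h.model_name, set()).add(r.protein_id)

    def table(carriers: dict) -> list:
        n = len(ttrs)
        if n == 0:
            return []
        ranked = sorted(carriers.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        rows, covered = [], set()
        for model, pids in ranked:
            covered |= pids
            rows.append((model, len(pids), len(pids) / n, len(covered) / n))
        return rows

    return {"dna_binding": table(carriers_dna), "sensory": table(carriers_sens)}
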