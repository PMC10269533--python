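"""Synthetic cohort generator with known ground truth.

Emits everything the pipeline consumes — proteome FASTA, domain-hit TSV,
TM-segment file, genome metadata — for a cohort of bacterial and
archaeal genomes whose statistical structure mirrors the census
assumptions: per-genome CDS totals (log-normal), a signal-transduction
fraction of the proteome (~9% bacteria / 6% archaea), a TTR fraction of
coding sequences (~0.15% / 0.13%), a hybrid-TTR fraction (~8.2% of
TTRs), a pass-count split of ~56% single-pass / 17% two-pass / 27% with
three or more TM regions (capped at 22), and ~43% of TTRs whose pooled
TM surface area falls at or below the 172 Å²/residue raft threshold.

Every generated protein's intended labels are written to a ground-truth
table so downstream tests are oracle-based.  TM segments are composed
from two-residue hydrophobic mixtures chosen so the pooled surface area
lands on the intended side of the threshold under the shipped area
table, which also keeps the segments detectable by the hydropathy
fallback predictor.  Sequence realism beyond these constraints (codon
usage, operon structure, Pfam score distributions) is explicitly not
attempted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .io_annotation import (
    DomainHit,
    GenomeMeta,
    format_gtdb_taxonomy,
    parse_gtdb_taxonomy,
    write_domain_hits_tsv,
    write_genome_meta,
)
from .tm_features import AreaTable, TMParams

# background (non-TM) residue frequencies, loosely soluble-protein-like
_BG_RESIDUES = list("ADEFGHIKLMNPQRSTVWYC")
_BG_FREQS = np.array(
    [0.08, 0.06, 0.07, 0.03, 0.08, 0.03, 0.04, 0.07, 0.07, 0.02,
     0.05, 0.05, 0.04, 0.05, 0.06, 0.07, 0.06, 0.05, 0.01, 0.03]
)
_BG_FREQS = _BG_FREQS / _BG_FREQS.sum()

# model vocabularies; all names must exist in the shipped registry
_DBD_MODELS = ["HTH_1", "HTH_AraC", "GerE", "Trans_reg_C", "LytTR",
               "HTH_8", "MerR", "PadR", "Fe_dep_repress"]
_DBD_WEIGHTS = np.array([0.28, 0.15, 0.12, 0.12, 0.09, 0.08, 0.06, 0.05, 0.05])
_SENSORY_MODELS = ["PAS", "Cache_1", "GAF", "Y_Y_Y", "CHASE", "sCache_2"]
_SENSORY_WEIGHTS = np.array([0.30, 0.20, 0.16, 0.14, 0.10, 0.10])
_TCS_CORE_MODELS = ["Response_reg", "HATPase_c", "HisKA"]
_TCS_WEIGHTS = np.array([0.4, 0.3, 0.3])
_ST_ONLY_MODELS = ["MCPsignal", "GGDEF", "EAL", "PAS", "Cache_1"]
_ST_ONLY_WEIGHTS = np.array([0.3, 0.25, 0.15, 0.15, 0.15])

# two-residue palette used to compose TM segments: both strongly
# hydrophobic (Kyte-Doolittle 1.8 / 2.8) but with well-separated
# surface-area constants, so any mixture is predictor-detectable while
# the pooled area can be steered to either side of the raft threshold
_TM_LOW, _TM_HIGH = "A", "F"


@dataclass(frozen=True)
class SuperkingdomParams:
    """Per-superkingdom cohort settings."""

    cds_median: float
    cds_sigma: float
    st_fraction: float
    ttr_fraction: float


#: default taxon layout: (phylum, class, superkingdom, weight)
DEFAULT_TAXON_LAYOUT = (
    ("Pseudomonadota", "Gammaproteobacteria", "bacteria", 0.22),
    ("Pseudomonadota", "Alphaproteobacteria", "bacteria", 0.13),
    ("Bacillota", "Bacilli", "bacteria", 0.15),
    ("Bacillota", "Clostridia", "bacteria", 0.10),
    ("Actinomycetota", "Actinomycetes", "bacteria", 0.12),
    ("Actinomycetota", "Coriobacteriia", "bacteria", 0.04),
    ("Bacteroidota", "Bacteroidia", "bacteria", 0.10),
    ("Spirochaetota", "Leptospirae", "bacteria", 0.03),
    ("Acidobacteriota", "Acidobacteriae", "bacteria", 0.03),
    ("Campylobacterota", "Campylobacteria", "bacteria", 0.04),
    ("Halobacteriota", "Methanomicrobia", "archaea", 0.015),
    ("Methanobacteriota", "Methanobacteria", "archaea", 0.010),
    ("Thermoproteota", "Thermoprotei", "archaea", 0.015),
)


@dataclass(frozen=True)
class CohortParams:
    """Study conditions of the synthetic cohort (defaults are the census
    figures the generator emulates)."""

    n_genomes: int = 500
    seed: int = 0
    bacteria: SuperkingdomParams = SuperkingdomParams(3000.0, 0.40, 0.09, 0.0015)
    archaea: SuperkingdomParams = SuperkingdomParams(2000.0, 0.35, 0.06, 0.0013)
    hybrid_fraction: float = 0.082
    tm_class_probs: tuple = (0.56, 0.17, 0.27)  # 1 / 2 / >=3 TM regions
    tm_multi_geom_p: float = 0.5
    tm_count_cap: int = 22
    sa_low_fraction: float = 0.43
    sensory_mean_low_sa: float = 0.7   # mean sensory domains, raft stratum
    sensory_mean_high_sa: float = 1.5  # mean sensory domains, non-raft stratum
    decoys_per_genome: int = 2
    taxon_layout: tuple = DEFAULT_TAXON_LAYOUT

    def validate(self) -> None:
        for sk in (self.bacteria, self.archaea):
            if not (0 <= sk.ttr_fraction <= sk.st_fraction <= 1):
                raise ValueError(
                    "infeasible params: need 0 <= ttr_fraction <= st_fraction <= 1 "
                    f"(got ttr={sk.ttr_fraction}, st={sk.st_fraction})"
                )
        if abs(sum(self.tm_class_probs) - 1.0) > 1e-9:
            raise ValueError("tm_class_probs must sum to 1")
        for frac in (self.hybrid_fraction, self.sa_low_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0,1]")
        if self.tm_count_cap > 22:
            raise ValueError("TM count cap may not exceed 22")


@dataclass(frozen=True)
class GroundTruth:
    protein_id: str
    genome_id: str
    category: str  # ttr | st_only | decoy_dna | decoy_tm
    is_ttr: bool
    is_hybrid: bool
    is_st: bool
    n_tm: int
    sa_stratum: str  # low | high | na
    n_sensory: int


@dataclass(frozen=True)
class CohortFiles:
    """Paths of a generated cohort (all plain text)."""

    proteome_fasta: str
    hits_tsv: str
    tm_tsv: str
    genome_meta_tsv: str
    ground_truth_tsv: str


# ---------------------------------------------------------------------------
# label sampling (exposed separately so distribution-recovery tests can
# draw many TTR label vectors without realising sequences)


def sample_tm_count(params: CohortParams, rng) -> int:
    cls = rng.choice(3, p=np.asarray(params.tm_class_probs))
    if cls == 0:
        return 1
    if cls == 1:
        return 2
    extra = int(rng.geometric(params.tm_multi_geom_p)) - 1
    return min(3 + extra, params.tm_count_cap)


def sample_ttr_labels(n: int, params: CohortParams, rng) -> list:
    """Draw intended labels for ``n`` TTRs: TM count, hybrid flag, raft
    stratum and sensory-domain count."""
    labels = []
    for _ in range(n):
        n_tm = sample_tm_count(params, rng)
        hybrid = bool(rng.random() < params.hybrid_fraction)
        low_sa = bool(rng.random() < params.sa_low_fraction)
        mean = params.sensory_mean_low_sa if low_sa else params.sensory_mean_high_sa
        n_sensory = int(rng.poisson(mean))
        if hybrid and n_sensory == 0:
            n_sensory = 1  # the hybrid-defining core domain is itself sensory
        labels.append(
            {"n_tm": n_tm, "hybrid": hybrid, "low_sa": low_sa, "n_sensory": n_sensory}
        )
    return labels


def compose_tm_residues(
    n_res: int, low_sa: bool, table: AreaTable, rng, raft_threshold: float = 172.0
) -> list:
    """Compose ``n_res`` TM residues from the two-residue palette so the
    pooled surface area lands on the intended side of the threshold."""
    lo, hi = table[_TM_LOW], table[_TM_HIGH]
    if not lo < raft_threshold < hi:
        raise ValueError(
            "area table incompatible with the TM palette: need "
            f"table[{_TM_LOW}] < {raft_threshold} < table[{_TM_HIGH}]"
        )
    if low_sa:
        target = rng.uniform(max(lo + 3.0, raft_threshold - 22.0), raft_threshold - 3.0)
    else:
        target = rng.uniform(raft_threshold + 4.0, min(hi - 3.0, raft_threshold + 33.0))
    a = int(round(n_res * (hi - target) / (hi - lo)))
    a = min(max(a, 0), n_res)

    def pooled(a_low: int) -> float:
        return (a_low * lo + (n_res - a_low) * hi) / n_res

    if low_sa:
        while pooled(a) > raft_threshold and a < n_res:
            a += 1
    else:
        while pooled(a) <= raft_threshold and a > 0:
            a -= 1
    residues = [_TM_LOW] * a + [_TM_HIGH] * (n_res - a)
    rng.shuffle(residues)
    return residues


# ---------------------------------------------------------------------------
# protein realisation


def _background(n: int, rng) -> str:
    return "".join(rng.choice(_BG_RESIDUES, size=n, p=_BG_FREQS))


def _pick(models, weights, rng) -> str:
    return str(rng.choice(models, p=weights / weights.sum()))


def _score(rng) -> tuple:
    return round(float(rng.uniform(25.0, 150.0)), 1), float(10.0 ** rng.uniform(-30, -8))


def _realise_ttr(pid, gid, label, table, rng, raft_threshold):
    """Build sequence, TM intervals and domain hits for one TTR."""
    tm_lengths = [int(rng.integers(17, 26)) for _ in range(label["n_tm"])]
    pool = compose_tm_residues(sum(tm_lengths), label["low_sa"], table, rng, raft_threshold)
    parts, tm_intervals, hits = [], [], []
    pos = 0

    def emit(s: str):
        nonlocal pos
        parts.append(s)
        pos += len(s)

    emit(_background(10, rng))
    offset = 0
    for ln in tm_lengths:
        tm_intervals.append((pos + 1, pos + ln))
        emit("".join(pool[offset : offset + ln]))
        offset += ln
        emit(_background(8, rng))
    # sensory domains, each in its own 70-residue slot
    sensory_models = []
    for i in range(label["n_sensory"]):
        if label["hybrid"] and i == 0:
            sensory_models.append(_pick(_TCS_CORE_MODELS, _TCS_WEIGHTS, rng))
        else:
            sensory_models.append(_pick(_SENSORY_MODELS, _SENSORY_WEIGHTS, rng))
    for model in sensory_models:
        bits, iev = _score(rng)
        hits.append(DomainHit(pid, model, "", pos + 6, pos + 65, bits, iev))
        emit(_background(70, rng))
    bits, iev = _score(rng)
    hits.append(DomainHit(pid, _pick(_DBD_MODELS, _DBD_WEIGHTS, rng), "",
                          pos + 6, pos + 65, bits, iev))
    emit(_background(70, rng))
    return "".join(parts), tm_intervals, hits


def _genome_taxonomy(phylum, klass, superkingdom, idx):
    domain = "Bacteria" if superkingdom == "bacteria" else "Archaea"
    return parse_gtdb_taxonomy(
        f"d__{domain};p__{phylum};c__{klass};o__;f__;g__;s__"
    )


def _assign_taxa(params: CohortParams) -> list:
    """Largest-remainder apportionment of genomes across the taxon layout."""
    weights = np.array([t[3] for t in params.taxon_layout], dtype=float)
    weights = weights / weights.sum()
    quotas = weights * params.n_genomes
    counts = np.floor(quotas).astype(int)
    remainder = params.n_genomes - counts.sum()
    for i in np.argsort(-(quotas - counts))[:remainder]:
        counts[i] += 1
    assignment = []
    for taxon, k in zip(params.taxon_layout, counts):
        assignment.extend([taxon] * int(k))
    return assignment


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(params: CohortParams, outdir, table: AreaTable | None = None) -> CohortFiles:
    """Generate a cohort on disk; byte-identical for identical params.

    The area table defaults to the shipped calibrated table so that the
    generated raft strata agree with the pipeline's scoring.
    """
    params.validate()
    if table is None:
        from .resources import default_area_table

        table = default_area_table()
    raft_threshold = TMParams().raft_threshold
    os.makedirs(outdir, exist_ok=True)
    assignment = _assign_taxa(params)
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_genomes)

    metas, truths = [], []
    fasta_path = os.path.join(outdir, "proteome.fasta")
    hits_path = os.path.join(outdir, "hits.tsv")
    tm_path = os.path.join(outdir, "tm_segments.tsv")
    meta_path = os.path.join(outdir, "genome_meta.tsv")
    truth_path = os.path.join(outdir, "ground_truth.tsv")

    all_hits = []
    with open(fasta_path, "w") as fa, open(tm_path, "w") as tm:
        for gi, (taxon, seed_seq) in enumerate(zip(assignment, seeds)):
            phylum, klass, superkingdom, _w = taxon
            rng = np.random.default_rng(seed_seq)
            sk = params.bacteria if superkingdom == "bacteria" else params.archaea
            cds = max(int(rng.lognormal(np.log(sk.cds_median), sk.cds_sigma)), 500)
            n_ttr = int(rng.binomial(cds, sk.ttr_fraction))
            n_st = max(int(rng.binomial(cds, sk.st_fraction)), n_ttr)
            gid = f"G{gi:05d}"
            metas.append(GenomeMeta(gid, _genome_taxonomy(phylum, klass, superkingdom, gi), cds))

            labels = sample_ttr_labels(n_ttr, params, rng)
            pidx = 0

            def next_pid():
                nonlocal pidx
                pidx += 1
                return f"{gid}_p{pidx:05d}"

            def write_fasta(pid, seq):
                fa.write(f">{pid} genome={gid}\n")
                for k in range(0, len(seq), 60):
                    fa.write(seq[k : k + 60] + "\n")

            for label in labels:
                pid = next_pid()
                seq, tm_ivals, hits = _realise_ttr(pid, gid, label, table, rng, raft_threshold)
                write_fasta(pid, seq)
                for s, e in tm_ivals:
                    tm.write(f"{pid}\tttrcensus-sim\tTMhelix\t{s}\t{e}\n")
                all_hits.extend(hits)
                truths.append(GroundTruth(
                    pid, gid, "ttr", True, label["hybrid"], True, label["n_tm"],
                    "low" if label["low_sa"] else "high", label["n_sensory"]))
            for _ in range(n_st - n_ttr):
                pid = next_pid()
                seq = _background(int(rng.integers(120, 401)), rng)
                write_fasta(pid, seq)
                tm.write(f"{pid}\tttrcensus-sim\toutside\t1\t{len(seq)}\n")
                bits, iev = _score(rng)
                all_hits.append(DomainHit(pid, _pick(_ST_ONLY_MODELS, _ST_ONLY_WEIGHTS, rng),
                                          "", 11, 70, bits, iev))
                truths.append(GroundTruth(pid, gid, "st_only", False, False, True, 0, "na", 1))
            for d in range(params.decoys_per_genome):
                pid = next_pid()
                if d % 2 == 0:  # soluble DNA-binding protein, not ST
                    seq = _background(160, rng)
                    write_fasta(pid, seq)
                    tm.write(f"{pid}\tttrcensus-sim\toutside\t1\t{len(seq)}\n")
                    bits, iev = _score(rng)
                    all_hits.append(DomainHit(pid, _pick(_DBD_MODELS, _DBD_WEIGHTS, rng),
                                              "", 21, 80, bits, iev))
                    truths.append(GroundTruth(pid, gid, "decoy_dna", False, False, False, 0, "na", 0))
                else:  # membrane protein with no recognised domains
                    tm_res = compose_tm_residues(21, bool(rng.random() < 0.5), table, rng, raft_threshold)
                    seq = _background(10, rng) + "".join(tm_res) + _background(30, rng)
                    write_fasta(pid, seq)
                    tm.write(f"{pid}\tttrcensus-sim\tTMhelix\t11\t31\n")
                    truths.append(GroundTruth(pid, gid, "decoy_tm", False, False, False, 1, "na", 0))

    write_domain_hits_tsv(all_hits, hits_path)
    write_genome_meta(metas, meta_path)
    write_ground_truth(truths, truth_path)
    return CohortFiles(fasta_path, hits_path, tm_path, meta_path, truth_path)


def write_ground_truth(truths, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgenome_id\tcategory\tis_ttr\tis_hybrid\tis_st\t"
                 "n_tm\tsa_stratum\tn_sensory\n")
        for t in truths:
            fh.write(f"{t.protein_id}\t{t.genome_id}\t{t.category}\t"
                     f"{int(t.is_ttr)}\t{int(t.is_hybrid)}\t{int(t.is_st)}\t"
                     f"{t.n_tm}\t{t.sa_stratum}\t{t.n_sensory}\n")


def read_ground_truth(path) -> list:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            p = line.rstrip("\n").split("\t")
            out.append(GroundTruth(p[0], p[1], p[2], bool(int(p[3])), bool(int(p[4])),
                                   bool(int(p[5])), int(p[6]), p[7], int(p[8])))
    return out


# ---------------------------------------------------------------------------
# worked toy genome


def generate_worked_genome(outdir) -> CohortFiles:
    """The fixed 10-protein toy genome used in the documentation.

    Hand-tallied summary: cds_total 10, n_st 3 (two TTRs plus one
    chemoreceptor-like ST protein), n_ttr 2 (one plain single-pass, one
    two-pass hybrid), n_hybrid 1 — hence TTR/CDS 0.2, TTR/ST 2/3, ST/CDS
    0.3.
    """
    from .resources import default_area_table

    table = default_area_table()
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(20240101)
    gid = "GTOY001"
    raft_threshold = TMParams().raft_threshold

    fasta_path = os.path.join(outdir, "proteome.fasta")
    hits_path = os.path.join(outdir, "hits.tsv")
    tm_path = os.path.join(outdir, "tm_segments.tsv")
    meta_path = os.path.join(outdir, "genome_meta.tsv")
    truth_path = os.path.join(outdir, "ground_truth.tsv")

    hits, truths = [], []
    with open(fasta_path, "w") as fa, open(tm_path, "w") as tm:
        def write_fasta(pid, seq):
            fa.write(f">{pid} genome={gid}\n")
            for k in range(0, len(seq), 60):
                fa.write(seq[k : k + 60] + "\n")

        # p01: plain single-pass TTR, raft stratum
        pool = compose_tm_residues(21, True, table, rng, raft_threshold)
        seq = _background(12, rng) + "".join(pool) + _background(15, rng) + _background(70, rng)
        write_fasta(f"{gid}_p01", seq)
        tm.write(f"{gid}_p01\tttrcensus-sim\tTMhelix\t13\t33\n")
        hits.append(DomainHit(f"{gid}_p01", "HTH_1", "PF00046", len(seq) - 64, len(seq) - 5, 62.1, 1e-15))
        truths.append(GroundTruth(f"{gid}_p01", gid, "ttr", True, False, True, 1, "low", 0))

        # p02: two-pass hybrid TTR, non-raft stratum, 1 sensory (Response_reg)
        pool = compose_tm_residues(42, False, table, rng, raft_threshold)
        seq = (_background(10, rng) + "".join(pool[:21]) + _background(9, rng)
               + "".join(pool[21:]) + _background(8, rng) + _background(70, rng)
               + _background(70, rng))
        write_fasta(f"{gid}_p02", seq)
        tm.write(f"{gid}_p02\tttrcensus-sim\tTMhelix\t11\t31\n")
        tm.write(f"{gid}_p02\tttrcensus-sim\tTMhelix\t41\t61\n")
        hits.append(DomainHit(f"{gid}_p02", "Response_reg", "PF00072", 75, 134, 88.0, 1e-22))
        hits.append(DomainHit(f"{gid}_p02", "Trans_reg_C", "PF00486", 145, 204, 55.4, 1e-13))
        truths.append(GroundTruth(f"{gid}_p02", gid, "ttr", True, True, True, 2, "high", 1))

        # p03: soluble chemoreceptor-like ST protein
        seq = _background(150, rng)
        write_fasta(f"{gid}_p03", seq)
        tm.write(f"{gid}_p03\tttrcensus-sim\toutside\t1\t150\n")
        hits.append(DomainHit(f"{gid}_p03", "MCPsignal", "PF00015", 11, 70, 71.2, 1e-18))
        truths.append(GroundTruth(f"{gid}_p03", gid, "st_only", False, False, True, 0, "na", 1))

        # p04: soluble DNA-binding protein (transcription factor, not ST)
        seq = _background(160, rng)
        write_fasta(f"{gid}_p04", seq)
        tm.write(f"{gid}_p04\tttrcensus-sim\toutside\t1\t160\n")
        hits.append(DomainHit(f"{gid}_p04", "GerE", "PF00196", 21, 80, 48.9, 1e-11))
        truths.append(GroundTruth(f"{gid}_p04", gid, "decoy_dna", False, False, False, 0, "na", 0))

        # p05: membrane protein with two TM regions and no recognised domains
        pool = compose_tm_residues(42, True, table, rng, raft_threshold)
        seq = (_background(10, rng) + "".join(pool[:21]) + _background(9, rng)
               + "".join(pool[21:]) + _background(20, rng))
        write_fasta(f"{gid}_p05", seq)
        tm.write(f"{gid}_p05\tttrcensus-sim\tTMhelix\t11\t31\n")
        tm.write(f"{gid}_p05\tttrcensus-sim\tTMhelix\t41\t61\n")
        truths.append(GroundTruth(f"{gid}_p05", gid, "decoy_tm", False, False, False, 2, "na", 0))

        # p06..p10: plain soluble proteins, no hits, no TM
        for i in range(6, 11):
            pid = f"{gid}_p{i:02d}"
            seq = _background(int(rng.integers(110, 220)), rng)
            write_fasta(pid, seq)
            tm.write(f"{pid}\tttrcensus-sim\toutside\t1\t{len(seq)}\n")
            truths.append(GroundTruth(pid, gid, "decoy_dna", False, False, False, 0, "na", 0))

    write_domain_hits_tsv(hits, hits_path)
    write_genome_meta(
        [GenomeMeta(gid, parse_gtdb_taxonomy(
            "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;o__Enterobacterales;f__;g__;s__"
        ), 10)],
        meta_path,
    )
    write_ground_truth(truths, truth_path)
    return CohortFiles(fasta_path, hits_path, tm_path, meta_path, truth_path)
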