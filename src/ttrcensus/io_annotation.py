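"""Readers for the four input artifacts of the TTR census pipeline.

A cohort is described by four plain-text files:

* a proteome FASTA (amino acids; one record per protein, the first
  whitespace-delimited header token is the protein id, an optional
  ``genome=<id>`` token links the protein to its genome),
* a domain-hit table, either HMMER3 ``domtblout`` or a simplified
  7-column TSV dialect,
* optionally, TM segments in TMHMM long format (one ``TMhelix`` line per
  predicted helix) — when absent the built-in hydropathy predictor in
  :mod:`ttrcensus.tm_features` is used instead,
* genome metadata (TSV) carrying a GTDB-style taxonomy string and the
  total protein-coding gene count per genome.

All residue coordinates are 1-based inclusive throughout the package,
matching the HMMER and TMHMM conventions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import yaml
from Bio import SeqIO

# 20 canonical residues; X is tolerated as an unknown residue.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(CANONICAL_RESIDUES + "X")

#: GTDB rank prefixes in canonical order.
GTDB_RANKS = ("d", "p", "c", "o", "f", "g", "s")

TSV_HIT_COLUMNS = (
    "protein_id",
    "model_name",
    "model_accession",
    "env_from",
    "env_to",
    "bit_score",
    "i_evalue",
)


class InputFormatError(ValueError):
    """Raised when an input artifact violates its declared format."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its genome linkage."""

    protein_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise InputFormatError("protein_id must be nonempty")
        if not self.sequence:
            raise InputFormatError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise InputFormatError(
                f"protein {self.protein_id!r}: illegal residue letter(s) "
                f"{''.join(sorted(bad))!r} (allowed: 20 canonical + X)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM match on a protein (envelope coordinates)."""

    protein_id: str
    model_name: str
    model_accession: str
    env_from: int
    env_to: int
    bit_score: float
    i_evalue: float

    def __post_init__(self) -> None:
        if self.env_from < 1 or self.env_from > self.env_to:
            raise InputFormatError(
                f"hit {self.model_name!r} on {self.protein_id!r}: bad envelope "
                f"{self.env_from}..{self.env_to} (need 1 <= from <= to)"
            )
        if self.i_evalue < 0:
            raise InputFormatError(
                f"hit {self.model_name!r} on {self.protein_id!r}: negative i-Evalue"
            )


@dataclass(frozen=True)
class GenomeMeta:
    """Per-genome metadata: taxonomy ranks and total CDS count."""

    genome_id: str
    taxonomy: tuple  # 7 rank values (domain..species), '' where unfilled
    cds_total: int

    def __post_init__(self) -> None:
        if len(self.taxonomy) != 7:
            raise InputFormatError(
                f"genome {self.genome_id!r}: taxonomy must have 7 rank slots"
            )
        if not self.taxonomy[0]:
            raise InputFormatError(
                f"genome {self.genome_id!r}: taxonomy missing the d__ (domain) field"
            )
        if self.cds_total <= 0:
            raise InputFormatError(
                f"genome {self.genome_id!r}: cds_total must be positive"
            )

    @property
    def domain(self) -> str:
        return self.taxonomy[0]

    @property
    def phylum(self) -> str:
        return self.taxonomy[1]

    @property
    def klass(self) -> str:
        return self.taxonomy[2]

    @property
    def superkingdom(self) -> str:
        d = self.taxonomy[0].lower()
        if d == "bacteria":
            return "bacteria"
        if d == "archaea":
            return "archaea"
        raise InputFormatError(
            f"genome {self.genome_id!r}: domain {self.taxonomy[0]!r} is neither "
            "Bacteria nor Archaea"
        )

    @property
    def taxon_key(self) -> str:
        """Group label used by the taxon aggregation: ``phylum;class``."""
        return f"{self.phylum};{self.klass}"


@dataclass(frozen=True)
class DomainRegistry:
    """Model-name sets driving the classification rules.

    ``dna_binding`` marks DNA-binding (transcription-factor) domains,
    ``tcs_core`` the two-component core domains whose presence on a TTR
    makes it a hybrid TTR, and ``st_membership`` the models that place a
    protein in the genome's signal-transduction (ST) repertoire.  TTRs
    are ST by definition regardless of ``st_membership``.
    """

    dna_binding: frozenset
    tcs_core: frozenset = frozenset({"Response_reg", "HATPase_c", "HisKA"})
    st_membership: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.dna_binding:
            raise InputFormatError("registry: dna_binding set may not be empty")
        if not self.tcs_core:
            raise InputFormatError("registry: tcs_core set may not be empty")
        if not self.st_membership:
            raise InputFormatError("registry: st_membership set may not be empty")
        overlap = self.dna_binding & self.tcs_core
        if overlap:
            raise InputFormatError(
                "registry: models may not be both dna_binding and tcs_core: "
                + ", ".join(sorted(overlap))
            )


# ---------------------------------------------------------------------------
# readers


def _require_file(path) -> None:
    if not os.path.isfile(path):
        raise FileNotFoundError(f"input file not found: {path}")


def read_proteome_fasta(path, default_genome_id: str = "") -> list:
    """Read an amino-acid FASTA into :class:`ProteinRecord` objects.

    The protein id is the first whitespace-delimited header token; a
    ``genome=<id>`` token elsewhere in the header assigns the genome,
    otherwise ``default_genome_id`` is used.  Sequences are uppercased;
    any letter outside the 20 canonical residues plus X is rejected.
    """
    _require_file(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise InputFormatError(f"duplicate protein_id in FASTA: {pid!r}")
        seen.add(pid)
        genome_id = default_genome_id
        for token in rec.description.split()[1:]:
            if token.startswith("genome="):
                genome_id = token[len("genome=") :]
        records.append(
            ProteinRecord(protein_id=pid, genome_id=genome_id, sequence=str(rec.seq).upper())
        )
    return records


def _parse_domtblout_line(parts, lineno):
    # HMMER3 domtblout: 22 fixed whitespace columns + free-text description.
    if len(parts) < 22:
        raise InputFormatError(
            f"domtblout line {lineno}: expected >=22 columns, got {len(parts)}"
        )
    return DomainHit(
        protein_id=parts[0],
        model_name=parts[3],
        model_accession="" if parts[4] == "-" else parts[4],
        env_from=int(parts[19]),
        env_to=int(parts[20]),
        bit_score=float(parts[13]),
        i_evalue=float(parts[12]),
    )


def _parse_tsv_hit_line(parts, lineno):
    if len(parts) != 7:
        raise InputFormatError(
            f"hit TSV line {lineno}: expected 7 columns, got {len(parts)}"
        )
    return DomainHit(
        protein_id=parts[0],
        model_name=parts[1],
        model_accession=parts[2],
        env_from=int(parts[3]),
        env_to=int(parts[4]),
        bit_score=float(parts[5]),
        i_evalue=float(parts[6]),
    )


def read_domain_hits(path, dialect: str = "tsv", max_i_evalue: float = 1e-5) -> list:
    """Read domain hits, keeping only hits with ``i_evalue <= max_i_evalue``.

    ``dialect`` is ``"domtblout"`` (HMMER3 per-domain table, '#' comment
    lines) or ``"tsv"`` (7 columns: protein_id, model_name,
    model_accession, env_from, env_to, bit_score, i_evalue; an optional
    header row naming those columns is skipped).  Input order is
    preserved.
    """
    if dialect not in ("domtblout", "tsv"):
        raise ValueError(f"unknown hit-table dialect: {dialect!r}")
    _require_file(path)
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if dialect == "tsv" else line.split()
            if dialect == "tsv" and lineno == 1 and parts[0] == "protein_id":
                continue
            try:
                hit = (
                    _parse_domtblout_line(parts, lineno)
                    if dialect == "domtblout"
                    else _parse_tsv_hit_line(parts, lineno)
                )
            except (ValueError, IndexError) as exc:
                if isinstance(exc, InputFormatError):
                    raise
                raise InputFormatError(
                    f"hit table line {lineno}: malformed ({exc})"
                ) from exc
            if hit.i_evalue <= max_i_evalue:
                hits.append(hit)
    return hits


def write_domain_hits_tsv(hits, path) -> None:
    """Write hits in the 7-column TSV dialect (round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.model_name}\t{h.model_accession}\t"
                f"{h.env_from}\t{h.env_to}\t{h.bit_score:g}\t{h.i_evalue:g}\n"
            )


def read_tm_segments(path) -> dict:
    """Read TMHMM long-format TM segments.

    Only lines whose region label is ``TMhelix`` are consumed; ``inside``
    and ``outside`` lines register the protein (so it maps to an empty
    list) but contribute no interval.  Per protein, intervals are
    returned sorted by start and must not overlap.
    """
    _require_file(path)
    segments: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise InputFormatError(
                    f"TM segment line {lineno}: expected 5 columns, got {len(parts)}"
                )
            pid, _prog, label, s, e = parts[0], parts[1], parts[2], parts[3], parts[4]
            segments.setdefault(pid, [])
            if label != "TMhelix":
                continue
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise InputFormatError(
                    f"TM segment line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or start > end:
                raise InputFormatError(
                    f"TM segment line {lineno}: bad interval {start}..{end}"
                )
            segments[pid].append((start, end))
    for pid, ivals in segments.items():
        ivals.sort()
        for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise InputFormatError(
                    f"protein {pid!r}: overlapping TMhelix intervals "
                    f"({s1},{e1}) and starting {s2}"
                )
    return segments


def parse_gtdb_taxonomy(tax_string: str) -> tuple:
    """Parse a GTDB-style ``d__X;p__Y;...`` string into 7 rank values."""
    values = [""] * 7
    for part in tax_string.split(";"):
        part = part.strip()
        if not part:
            continue
        if len(part) < 3 or part[1:3] != "__":
            raise InputFormatError(f"malformed taxonomy field: {part!r}")
        prefix = part[0]
        if prefix not in GTDB_RANKS:
            raise InputFormatError(f"unknown taxonomy rank prefix: {part!r}")
        values[GTDB_RANKS.index(prefix)] = part[3:]
    return tuple(values)


def format_gtdb_taxonomy(ranks) -> str:
    return ";".join(f"{p}__{v}" for p, v in zip(GTDB_RANKS, ranks))


def read_genome_meta(path) -> list:
    """Read the genome metadata TSV (genome_id, taxonomy, cds_total)."""
    _require_file(path)
    metas = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "genome_id":
                continue
            if len(parts) != 3:
                raise InputFormatError(
                    f"genome metadata line {lineno}: expected 3 columns, got {len(parts)}"
                )
            gid, tax, cds = parts
            if gid in seen:
                raise InputFormatError(f"duplicate genome_id: {gid!r}")
            seen.add(gid)
            try:
                cds_total = int(cds)
            except ValueError as exc:
                raise InputFormatError(
                    f"genome metadata line {lineno}: non-integer cds_total {cds!r}"
                ) from exc
            metas.append(
                GenomeMeta(genome_id=gid, taxonomy=parse_gtdb_taxonomy(tax), cds_total=cds_total)
            )
    return metas


def write_genome_meta(metas, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\ttaxonomy\tcds_total\n")
        for m in metas:
            fh.write(f"{m.genome_id}\t{format_gtdb_taxonomy(m.taxonomy)}\t{m.cds_total}\n")


DEFAULT_TCS_CORE = frozenset({"Response_reg", "HATPase_c", "HisKA"})


def load_registry(path) -> DomainRegistry:
    """Load the domain registry from YAML.

    The file declares ``dna_binding``, ``st_membership`` and optionally
    ``tcs_core`` (defaulting to the two-component core trio
    Response_reg / HATPase_c / HisKA).
    """
    _require_file(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return registry_from_dict(cfg)


def registry_from_dict(cfg: dict) -> DomainRegistry:
    dna = frozenset(cfg.get("dna_binding") or [])
    tcs = frozenset(cfg.get("tcs_core") or DEFAULT_TCS_CORE)
    st = frozenset(cfg.get("st_membership") or [])
    return DomainRegistry(dna_binding=dna, tcs_core=tcs, st_membership=st)
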