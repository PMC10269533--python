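"""Classification rules of the TTR census.

A transmembrane transcription regulator (TTR) is a protein that carries
(i) at least one DNA-binding domain and (ii) at least one transmembrane
region.  A hybrid TTR additionally carries one or more two-component
core domains (receiver, HisKA dimerization, or HATPase_c catalytic
domain).  TTRs are categorised by membrane pass count (single-pass,
two-pass, multi-pass) and by their number of sensory domains — all
recognised domains other than DNA-binding ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_annotation import DomainHit, DomainRegistry, ProteinRecord
from .tm_features import TMProfile

PASS_CLASSES = ("none", "single_pass", "two_pass", "multi_pass")


def pass_class(n_regions: int) -> str:
    if n_regions == 0:
        return "none"
    if n_regions == 1:
        return "single_pass"
    if n_regions == 2:
        return "two_pass"
    return "multi_pass"


@dataclass(frozen=True)
class TTRRecord:
    """Classification outcome for one protein."""

    protein_id: str
    genome_id: str
    is_ttr: bool
    is_hybrid: bool
    is_st: bool
    has_dna_binding: bool
    pass_class: str
    n_sensory_domains: int
    dna_binding_models: frozenset
    tm_profile: TMProfile


def resolve_overlaps(hits, max_overlap: int = 15) -> list:
    """Resolve conflicting domain hits on one protein.

    Greedy selection by descending bit score; a candidate is kept iff it
    overlaps every already-kept hit by at most ``max_overlap`` residues.
    Ties in score break deterministically (envelope start, then model
    name).  The result is sorted by envelope start.
    """
    ranked = sorted(
        hits, key=lambda h: (-h.bit_score, h.env_from, h.model_name, h.env_to)
    )
    kept: list = []
    for cand in ranked:
        ok = True
        for k in kept:
            overlap = min(cand.env_to, k.env_to) - max(cand.env_from, k.env_from) + 1
            if overlap > max_overlap:
                ok = False
                break
        if ok:
            kept.append(cand)
    kept.sort(key=lambda h: (h.env_from, h.env_to, h.model_name))
    return kept


def count_sensory_domains(hits, registry: DomainRegistry) -> int:
    """Number of resolved hits whose model is not a DNA-binding model.

    Tandem repeats of one model count once per hit (per-hit counting).
    """
    return sum(
        1
        for h in hits
        if h.model_name not in registry.dna_binding
        and h.model_accession not in registry.dna_binding
    )


def _in_set(hit: DomainHit, names: frozenset) -> bool:
    return hit.model_name in names or (
        bool(hit.model_accession) and hit.model_accession in names
    )


def classify_protein(
    protein: ProteinRecord,
    hits,
    profile: TMProfile,
    registry: DomainRegistry,
    distinct_sensory_models: bool = False,
) -> TTRRecord:
    """Apply the TTR / hybrid / ST classification rules to one protein.

    ``hits`` must already be overlap-resolved.  With
    ``distinct_sensory_models`` the sensory-domain count tallies distinct
    models instead of hits.
    """
    dna_models = frozenset(
        h.model_name for h in hits if _in_set(h, registry.dna_binding)
    )
    has_dna_binding = bool(dna_models)
    is_ttr = has_dna_binding and profile.n_regions >= 1
    is_hybrid = is_ttr and any(_in_set(h, registry.tcs_core) for h in hits)
    is_st = is_ttr or any(_in_set(h, registry.st_membership) for h in hits)
    sensory_hits = [h for h in hits if not _in_set(h, registry.dna_binding)]
    if distinct_sensory_models:
        n_sensory = len({h.model_name for h in sensory_hits})
    else:
        n_sensory = len(sensory_hits)
    return TTRRecord(
        protein_id=protein.protein_id,
        genome_id=protein.genome_id,
        is_ttr=is_ttr,
        is_hybrid=is_hybrid,
        is_st=is_st,
        has_dna_binding=has_dna_binding,
        pass_class=pass_class(profile.n_regions),
        n_sensory_domains=n_sensory,
        dna_binding_models=dna_models,
        tm_profile=profile,
    )
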