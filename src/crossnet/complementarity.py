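"""Pairwise pathway complementarity between annotated genomes.

A donor genome *complements* a beneficiary genome for a KEGG module when it
carries exactly the KOs the beneficiary is missing to complete one of the
module's alternatives.  Modules the beneficiary already completes yield no
complements.  Results can be deduplicated to unique (module, missing-KO-set)
pairs and rendered as colored KEGG pathway-map URLs where the donor's
contribution is drawn in blue-green and the beneficiary's own KOs in red.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .kegg_modules import Alternative, ModuleDefinition, is_complete

__all__ = [
    "GenomeAnnotation",
    "PathwayComplement",
    "find_pathway_complements",
    "minimal_complements",
    "unique_complements",
    "kegg_map_color_url",
    "BENEFICIARY_COLOR",
    "DONOR_COLOR",
]

#: KEGG show_pathway color tokens: beneficiary-owned KOs in red, donor
#: contributions in blue-green (teal), URL-encoded hex.
BENEFICIARY_COLOR = "red"
DONOR_COLOR = "%2300b8b8"

_KEGG_SHOW_PATHWAY = "https://www.kegg.jp/kegg-bin/show_pathway?"


@dataclass(frozen=True)
class GenomeAnnotation:
    """A genome with its KO-term annotation and optional taxonomy labels."""

    genome_id: str
    kos: frozenset[str]
    taxon_label: str = ""
    ncbi_like_id: str = ""


@dataclass(frozen=True)
class PathwayComplement:
    """One way a donor completes a beneficiary's incomplete module alternative."""

    beneficiary_id: str
    donor_id: str
    module_id: str
    module_name: str
    category: str
    missing_kos: frozenset[str]
    completed_alternative: frozenset[str]
    map_url: str


def find_pathway_complements(
    beneficiary: GenomeAnnotation,
    donor: GenomeAnnotation,
    modules: Sequence[tuple[ModuleDefinition, Sequence[Alternative]]],
    max_missing: int | None = None,
    min_covered_fraction: float = 0.0,
) -> list[PathwayComplement]:
    """All donor KO sets completing an incomplete module alternative.

    For each module the beneficiary does not already complete, and for each
    alternative ``A`` of that module, a complement is emitted iff

    * ``missing = A - beneficiary.kos`` is nonempty,
    * ``missing`` is fully contained in the donor's KOs, and
    * ``len(missing) <= max_missing`` (when a bound is given).

    ``min_covered_fraction`` optionally requires the beneficiary to already
    hold at least that fraction of the alternative's KOs (default 0: any
    coverage qualifies, matching the database behaviour).
    """
    out: list[PathwayComplement] = []
    bkos = beneficiary.kos
    dkos = donor.kos
    for definition, alternatives in modules:
        if is_complete(bkos, alternatives):
            continue
        for alt in alternatives:
            missing = alt.ko_set - bkos
            if not missing or not missing <= dkos:
                continue
            if max_missing is not None and len(missing) > max_missing:
                continue
            if min_covered_fraction > 0 and alt.ko_set:
                covered = len(alt.ko_set & bkos) / len(alt.ko_set)
                if covered < min_covered_fraction:
                    continue
            out.append(
                PathwayComplement(
                    beneficiary_id=beneficiary.genome_id,
                    donor_id=donor.genome_id,
                    module_id=definition.module_id,
                    module_name=definition.name,
                    category=definition.category,
                    missing_kos=missing,
                    completed_alternative=alt.ko_set,
                    map_url=kegg_map_color_url(
                        definition.module_id, alt.ko_set & bkos, missing
                    ),
                )
            )
    return out


def minimal_complements(
    complements: Iterable[PathwayComplement],
) -> list[PathwayComplement]:
    """Drop complements whose missing set strictly contains another's.

    Minimality is judged within (beneficiary, donor, module) groups: if two
    records share those keys and one missing set is a strict superset of the
    other, the superset is removed.
    """
    by_group: dict[tuple[str, str, str], list[PathwayComplement]] = {}
    for c in complements:
        by_group.setdefault(
            (c.beneficiary_id, c.donor_id, c.module_id), []
        ).append(c)
    kept: list[PathwayComplement] = []
    for group in by_group.values():
        for c in group:
            if any(
                other.missing_kos < c.missing_kos
                for other in group
                if other is not c
            ):
                continue
            kept.append(c)
    return kept


def unique_complements(
    complements: Iterable[PathwayComplement],
) -> dict[tuple[str, frozenset[str]], int]:
    """Deduplicate on (module_id, missing KO set).

    Returns each unique pair with its multiplicity (how many source records,
    i.e. alternatives/pairs, produced it).
    """
    counts: Counter[tuple[str, frozenset[str]]] = Counter()
    for c in complements:
        counts[(c.module_id, c.missing_kos)] += 1
    return dict(counts)


def kegg_map_color_url(
    map_or_module_id: str,
    beneficiary_kos: Iterable[str],
    donor_kos: Iterable[str],
) -> str:
    """KEGG show_pathway URL coloring each KO by its provenance.

    Donor-contributed KOs carry the blue-green token, beneficiary KOs the red
    token.  KOs are sorted so the URL is deterministic; a KO present in both
    sets is colored as donor-contributed.
    """
    donor = frozenset(donor_kos)
    beneficiary = frozenset(beneficiary_kos) - donor
    parts = [map_or_module_id]
    for ko in sorted(beneficiary | donor):
        color = DONOR_COLOR if ko in donor else BENEFICIARY_COLOR
        parts.append(f"{ko}%09{color}")
    return _KEGG_SHOW_PATHWAY + "/".join(parts)
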