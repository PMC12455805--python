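"""Taxon-name matching: exact lineage dialects and Levenshtein fuzzy fallback.

Network nodes carry taxonomy strings in one of several dialects.  GTDB- and
Silva-style lineages are matched exactly after normalization (rank prefixes
such as ``s__`` stripped, case-insensitive).  Any other naming scheme falls
back to fuzzy matching of the deepest taxon name against a name→id
dictionary, using a normalized Levenshtein similarity on a 0–100 scale with
a high acceptance threshold (90) to avoid false positives.

Genome assignment is gated at the species or strain level: a node resolved
only to genus or above maps to zero genomes.  One node may map to several
representative genomes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib

__all__ = [
    "TaxonMatch",
    "levenshtein_similarity",
    "match_taxon_name",
    "normalize_lineage",
    "lineage_level",
    "map_taxa_to_genomes",
    "DEFAULT_FUZZY_THRESHOLD",
    "SCHEMES",
]

DEFAULT_FUZZY_THRESHOLD = 90
SCHEMES = ("gtdb", "silva", "other")

_RANK_PREFIX_RE = re.compile(r"^[a-z]__")
_RANK_LETTERS = ("d", "p", "c", "o", "f", "g", "s", "t")
_RANK_NAMES = {
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
    "t": "strain",
}


@dataclass(frozen=True)
class TaxonMatch:
    query: str
    matched_name: str
    matched_id: str
    score: float  # similarity in [0, 100]


def levenshtein_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity on a 0–100 scale.

    ``100 * (1 - d / max(|a|, |b|))`` where ``d`` is the plain edit
    distance; identical strings score 100, fully dissimilar ones 0.
    """
    if a == b:
        return 100.0
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(a), len(b)))


def match_taxon_name(
    query: str,
    dictionary: Mapping[str, str],
    threshold: float = DEFAULT_FUZZY_THRESHOLD,
) -> TaxonMatch | None:
    """Best fuzzy dictionary hit for a taxon name, or None below threshold.

    Among equal-score hits the lexicographically smallest name wins (the
    tie is deterministic, not meaningful).  Matching is case-insensitive.
    """
    if not query or not query.strip() or not dictionary:
        return None
    q = query.strip().lower()
    best: TaxonMatch | None = None
    for name in sorted(dictionary):
        score = levenshtein_similarity(q, name.strip().lower())
        if best is None or score > best.score:
            best = TaxonMatch(query, name, dictionary[name], score)
    if best is not None and best.score >= threshold:
        return best
    return None


def normalize_lineage(lineage: str) -> str:
    """Canonical form of a lineage string for exact-dialect matching.

    Rank prefixes (``d__`` … ``s__``) are stripped, fields are trimmed and
    lowercased, and empty trailing fields removed.
    """
    fields = [
        _RANK_PREFIX_RE.sub("", f.strip()).strip().lower()
        for f in lineage.split(";")
    ]
    while fields and not fields[-1]:
        fields.pop()
    return ";".join(fields)


def lineage_level(lineage: str) -> str:
    """Deepest populated rank of a lineage string.

    With rank prefixes the prefix letter decides; without, the field count
    against the standard seven-rank ladder does (7 fields → species, more →
    strain).  A bare binomial such as ``Escherichia coli`` counts as
    species.
    """
    fields = [f.strip() for f in lineage.split(";") if f.strip()]
    if not fields:
        return "unknown"
    prefixed = [f for f in fields if _RANK_PREFIX_RE.match(f)]
    if prefixed:
        deepest = "d"
        for f in prefixed:
            letter = f[0]
            if letter in _RANK_LETTERS and _RANK_LETTERS.index(
                letter
            ) > _RANK_LETTERS.index(deepest):
                if _RANK_PREFIX_RE.sub("", f).strip():
                    deepest = letter
        return _RANK_NAMES[deepest]
    if len(fields) == 1:
        # single free-form field: binomial or lower → species
        return "species" if len(fields[0].split()) >= 2 else "genus"
    if len(fields) >= 8:
        return "strain"
    if len(fields) == 7:
        return "species"
    return _RANK_NAMES[_RANK_LETTERS[len(fields) - 1]]


def species_name(lineage: str) -> str:
    """The deepest taxon name of a lineage (prefix stripped)."""
    fields = [
        _RANK_PREFIX_RE.sub("", f.strip()).strip()
        for f in lineage.split(";")
        if _RANK_PREFIX_RE.sub("", f.strip()).strip()
    ]
    return fields[-1] if fields else ""


def map_taxa_to_genomes(
    node_taxonomies: Mapping[str, str],
    genome_index: Mapping[str, Sequence[str]],
    scheme: str = "gtdb",
    fuzzy_threshold: float = DEFAULT_FUZZY_THRESHOLD,
) -> dict[str, list[str]]:
    """Assign representative genomes to network nodes.

    ``genome_index`` maps a taxonomy string (full lineage for the exact
    dialects, or a species name for fuzzy use) to its genome ids.  Exact
    dialects (``gtdb``, ``silva``) compare normalized lineages; the
    ``other`` scheme fuzzy-matches the deepest taxon name.  Nodes resolved
    above species level map to zero genomes.

    Raises
    ------
    ValueError
        On an unknown scheme label.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown taxonomy scheme {scheme!r}; use one of {SCHEMES}")
    exact_index: dict[str, list[str]] = {}
    name_index: dict[str, str] = {}
    genomes_by_key: dict[str, list[str]] = {}
    for taxonomy, genome_ids in genome_index.items():
        norm = normalize_lineage(taxonomy)
        exact_index.setdefault(norm, []).extend(genome_ids)
        name = species_name(taxonomy).lower()
        if name:
            name_index[name] = name
            genomes_by_key.setdefault(name, []).extend(genome_ids)

    out: dict[str, list[str]] = {}
    for node, taxonomy in node_taxonomies.items():
        if lineage_level(taxonomy) not in ("species", "strain"):
            out[node] = []
            continue
        if scheme in ("gtdb", "silva"):
            out[node] = sorted(set(exact_index.get(normalize_lineage(taxonomy), [])))
        else:
            hit = match_taxon_name(
                species_name(taxonomy), name_index, fuzzy_threshold
            )
            out[node] = (
                sorted(set(genomes_by_key[hit.matched_id])) if hit else []
            )
    return out
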