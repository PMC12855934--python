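"""Consequence-term severity grouping (Ensembl impact categories).

Functional consequence terms (Sequence Ontology, as emitted by VEP) are
grouped into the four standard Ensembl impact categories — HIGH, MODERATE,
LOW, MODIFIER — which the genomic filter uses as its severity axis.  The
term table ships with the package as a versioned TSV fixture so nothing is
fetched at run time.
"""

from __future__ import annotations

import logging
from importlib import resources

logger = logging.getLogger(__name__)

IMPACT_CATEGORIES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

_cached_table: dict[str, str] | None = None


def load_impact_table() -> dict[str, str]:
    """The bundled consequence-term -> impact-category mapping."""
    global _cached_table
    if _cached_table is None:
        table: dict[str, str] = {}
        text = (
            resources.files("cohortstore")
            .joinpath("data/consequence_impact.tsv")
            .read_text()
        )
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            term, impact = line.split("\t")
            if impact not in IMPACT_CATEGORIES:
                raise ValueError(f"bad impact category {impact!r} in table")
            table[term] = impact
        _cached_table = table
    return _cached_table


def severity_group(term: str, table: dict[str, str] | None = None) -> str:
    """Impact category for a consequence term.

    Unknown terms fall back to MODIFIER (with a warning): the most
    conservative choice for severity filtering, since it keeps unknown
    terms out of HIGH-impact cohorts.
    """
    if table is None:
        table = load_impact_table()
    impact = table.get(term)
    if impact is None:
        logger.warning(
            "unknown consequence term %r; grouping as MODIFIER", term
        )
        return "MODIFIER"
    return impact
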