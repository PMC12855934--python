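"""Structure-asserting authorization and consent scoping.

Authorization never inspects data values: a decision depends only on the
user's tier and rules and on the canonical structure of the query.  Open-
tier users may run aggregate COUNT queries only; authorized users carry a
set of consent-group labels and a list of access rules, each of which
constrains what a query may contain — its result type and the concept-path
prefixes it touches.  Consent scoping rewrites a query so the reserved
consent concept is constrained to the user's authorized groups, which makes
every participant-level result consent-bounded by construction.

Every decision can be appended to a JSON-lines audit log with the rule that
produced it.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .phenotype import CONSENT_CONCEPT
from .query import COUNT, Query

logger = logging.getLogger(__name__)

OPEN = "open"
AUTHORIZED = "authorized"


@dataclass
class AccessRule:
    """A predicate over query structure, never over row data."""

    name: str
    allowed_result_types: list[str] | None = None  # None = any
    allowed_concept_prefixes: list[str] | None = None  # None = any
    required_consents: list[str] | None = None  # query must stay inside

    def violation(self, query: Query) -> str | None:
        """A human-readable reason if the query violates this rule."""
        if (
            self.allowed_result_types is not None
            and query.result_type not in self.allowed_result_types
        ):
            return (
                f"rule {self.name!r}: result type {query.result_type} "
                f"not in {self.allowed_result_types}"
            )
        if self.allowed_concept_prefixes is not None:
            for concept in _referenced_concepts(query):
                if concept == CONSENT_CONCEPT:
                    continue
                if not any(
                    concept.startswith(p)
                    for p in self.allowed_concept_prefixes
                ):
                    return (
                        f"rule {self.name!r}: concept {concept!r} outside "
                        f"allowed prefixes {self.allowed_concept_prefixes}"
                    )
        if self.required_consents is not None:
            labels = query.categorical_filters.get(CONSENT_CONCEPT)
            if labels is None or not labels <= set(self.required_consents):
                return (
                    f"rule {self.name!r}: query must constrain consent to a "
                    f"subset of {self.required_consents}"
                )
        return None


def _referenced_concepts(query: Query) -> Iterable[str]:
    yield from query.categorical_filters
    yield from query.numeric_filters
    yield from query.required_concepts
    yield from query.export_fields


@dataclass
class User:
    user_id: str
    tier: str = OPEN
    authorized_consents: set[str] = field(default_factory=set)
    rules: list[AccessRule] = field(default_factory=list)

    def __post_init__(self):
        if self.tier not in (OPEN, AUTHORIZED):
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == OPEN and self.authorized_consents:
            raise ValueError("open-tier users cannot hold consents")


@dataclass(frozen=True)
class Decision:
    allowed: bool
    reason: str | None = None
    rule: str | None = None

    def __bool__(self) -> bool:
        return self.allowed


ALLOW = Decision(True)


def authorize(user: User, query: Query) -> Decision:
    """ALLOW unless the tier or any of the user's rules is violated.

    Deterministic in (user, canonical query); denial is a result, not an
    error.
    """
    if user.tier == OPEN and query.result_type != COUNT:
        decision = Decision(
            False, "open tier: aggregate counts only", rule="tier:open"
        )
    else:
        decision = ALLOW
        for rule in user.rules:
            reason = rule.violation(query)
            if reason is not None:
                decision = Decision(False, reason, rule=rule.name)
                break
    logger.info(
        "authorize user=%s query=%s -> %s (%s)",
        user.user_id,
        query.content_hash()[:12],
        "ALLOW" if decision.allowed else "DENY",
        decision.reason or "ok",
    )
    return decision


def apply_consent_scope(query: Query, user: User) -> Query:
    """Constrain the consent concept to the user's authorized groups.

    Idempotent: an existing consent filter is intersected with the user's
    consents, so applying the scope twice equals applying it once.  An
    authorized user without consents yields an empty consent filter — an
    empty cohort — and is flagged in the log.
    """
    if user.tier != AUTHORIZED:
        raise ValueError("consent scoping applies to authorized users only")
    if not user.authorized_consents:
        logger.warning(
            "user %s is authorized but holds no consent groups; "
            "scoped queries match nothing",
            user.user_id,
        )
    existing = query.categorical_filters.get(CONSENT_CONCEPT)
    scoped = (
        set(user.authorized_consents)
        if existing is None
        else existing & set(user.authorized_consents)
    )
    filters = {k: set(v) for k, v in query.categorical_filters.items()}
    filters[CONSENT_CONCEPT] = scoped
    return Query(
        categorical_filters=filters,
        numeric_filters=dict(query.numeric_filters),
        required_concepts=list(query.required_concepts),
        genomic_filters=list(query.genomic_filters),
        export_fields=list(query.export_fields),
        result_type=query.result_type,
    )


# ---------------------------------------------------------------------------
# users.json + audit log
# ---------------------------------------------------------------------------

def load_users(path) -> dict[str, User]:
    """Read a plaintext users.json: list of users with tiers/consents/rules."""
    data = json.loads(Path(path).read_text())
    users: dict[str, User] = {}
    for u in data["users"]:
        rules = [
            AccessRule(
                name=r["name"],
                allowed_result_types=r.get("allowed_result_types"),
                allowed_concept_prefixes=r.get("allowed_concept_prefixes"),
                required_consents=r.get("required_consents"),
            )
            for r in u.get("rules", [])
        ]
        user = User(
            user_id=u["user_id"],
            tier=u.get("tier", OPEN),
            authorized_consents=set(u.get("authorized_consents", [])),
            rules=rules,
        )
        users[user.user_id] = user
    return users


def log_decision(audit_path, user: User, query: Query, decision: Decision,
                 dataset_id=None) -> None:
    entry = {
        "time": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "user": user.user_id,
        "query_hash": query.content_hash(),
        "dataset_id": str(dataset_id) if dataset_id else None,
        "decision": "ALLOW" if decision.allowed else "DENY",
        "reason": decision.reason,
        "rule": decision.rule,
    }
    path = Path(audit_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")
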