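"""EC-number agreement metrics.

An EC number is a four-field hierarchical enzyme classification; two
enzymes agreeing on the first k fields share progressively finer
function, and full agreement (depth 4) means they catalyze the same
reaction.  Agreement depth between two codes is the length of the common
specified prefix.  For queries with several close structural matches,
``top_range_consistency`` asks how functionally coherent the top of the
score range is: it scores every hit in the upper q-fraction of the
bit-score range against the best hit's EC set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

_WILDCARD_RE = re.compile(r"^(-|n\d*)$")


class EcParseError(ValueError):
    """Text is not a valid dotted EC code."""


@dataclass(frozen=True)
class EcNumber:
    """A 4-field EC code; ``None`` marks a wildcard field.

    The fields form a specified prefix followed by wildcards: once a
    wildcard appears every later field is a wildcard (enforced by
    normalization in :func:`parse_ec`).
    """

    fields: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.fields) != 4:
            raise ValueError("EC number must have exactly 4 fields")
        seen_wildcard = False
        for f in self.fields:
            if f is None:
                seen_wildcard = True
            elif seen_wildcard:
                raise ValueError("specified field after wildcard")
            elif f <= 0:
                raise ValueError("EC fields must be positive integers")

    def __str__(self) -> str:
        return ".".join("-" if f is None else str(f) for f in self.fields)


def parse_ec(text: str) -> EcNumber:
    """Parse a dotted EC code; ``-`` and preliminary ``n``-prefixed fields
    are wildcards.  Fields after the first wildcard are normalized to
    wildcards."""
    parts = [p.strip() for p in text.strip().split(".")]
    if len(parts) != 4:
        raise EcParseError(f"{text!r}: expected 4 dot-separated fields")
    fields: list[Optional[int]] = []
    seen_wildcard = False
    for part in parts:
        if seen_wildcard or _WILDCARD_RE.match(part):
            fields.append(None)
            seen_wildcard = True
            continue
        try:
            value = int(part)
        except ValueError as exc:
            raise EcParseError(f"{text!r}: field {part!r} is not numeric") from exc
        if value <= 0:
            raise EcParseError(f"{text!r}: field {part!r} must be positive")
        fields.append(value)
    return EcNumber(tuple(fields))


def parse_ec_set(text: str, sep: str = ";") -> frozenset[EcNumber]:
    """Parse a separator-joined list of EC codes; empty/'-' text -> empty set."""
    if not text or text.strip() in ("", "-"):
        return frozenset()
    return frozenset(parse_ec(tok) for tok in text.split(sep) if tok.strip())


def prefix_agreement(
    fields_a: Sequence[Optional[int]], fields_b: Sequence[Optional[int]]
) -> int:
    """Common specified prefix length of two raw 4-field tuples.

    Counting stops at the first mismatch or at the first wildcard
    (``None``) in either operand; symmetric by construction.  Works on
    arbitrary field tuples, not only normalized codes.
    """
    depth = 0
    for fa, fb in zip(fields_a, fields_b):
        if fa is None or fb is None or fa != fb:
            break
        depth += 1
    return depth


def agreement_depth(a: EcNumber, b: EcNumber) -> int:
    """Length of the common specified prefix of two EC codes (0..4)."""
    return prefix_agreement(a.fields, b.fields)


def best_pair_depth(
    set_a: Iterable[EcNumber], set_b: Iterable[EcNumber]
) -> Optional[int]:
    """Best agreement depth over all cross pairs of two EC sets.

    A protein may carry several EC numbers; the pair agreement is scored
    by the most favorable pairing.  Returns ``None`` (not evaluable) if
    either set is empty — callers skip such proteins.
    """
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        return None
    return max(agreement_depth(a, b) for a in set_a for b in set_b)


def top_range_consistency(
    hits_with_ec: Sequence[tuple[float, Iterable[EcNumber]]],
    q: float = 0.9,
    mode: str = "range",
) -> Optional[float]:
    """Mean EC agreement depth between the best hit and its near-top peers.

    ``mode="range"`` (default) selects hits with
    ``bit_score >= s_min + q * (s_max - s_min)`` — the upper fraction of
    the *score range*; ``mode="rank"`` instead uses the q-th rank
    percentile of the scores.  The best hit (highest score, first on
    ties) anchors the comparison; each selected non-best hit with EC
    annotation contributes ``best_pair_depth`` against the anchor.
    Returns ``None`` for single-hit queries, an EC-less best hit, or no
    evaluable selected peers.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    hits = [(float(score), frozenset(ecs)) for score, ecs in hits_with_ec]
    if len(hits) < 2:
        return None
    scores = np.array([s for s, _ in hits])
    best_index = int(np.argmax(scores))
    best_ecs = hits[best_index][1]
    if not best_ecs:
        return None
    if mode == "range":
        threshold = scores.min() + q * (scores.max() - scores.min())
    elif mode == "rank":
        threshold = float(np.quantile(scores, q))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    depths = []
    for i, (score, ecs) in enumerate(hits):
        if i == best_index or score < threshold:
            continue
        depth = best_pair_depth(best_ecs, ecs)
        if depth is not None:
            depths.append(depth)
    if not depths:
        return None
    return float(np.mean(depths))
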