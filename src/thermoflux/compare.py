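"""EC-number-based comparison of reaction content across models.

Different reconstructions write the "same" biochemistry with different
metabolite naming, protonation and anomer conventions, so reactions are
compared through their Enzyme Commission numbers instead.  Models that
attach several ECs to one reaction are reconciled against the models
they are compared with: an EC found nowhere else is kept only if none of
that reaction's *other* ECs occurs in any reference model — otherwise
the unique EC is judged an annotation artefact and dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

__all__ = [
    "EcAnnotation",
    "EcComparisonResult",
    "extract_ec_set",
    "compare_models",
    "pathway_frequency",
    "read_ec_annotations_tsv",
    "is_complete_ec",
]

_EC_COMPLETE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
_EC_PARTIAL = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


def is_complete_ec(ec: str) -> bool:
    return bool(_EC_COMPLETE.match(ec))


def is_valid_ec(ec: str) -> bool:
    return bool(_EC_PARTIAL.match(ec))


@dataclass
class EcAnnotation:
    reaction_id: str
    ec_numbers: List[str]


@dataclass
class EcComparisonResult:
    """Venn partition of per-model EC sets."""

    sets: Dict[str, FrozenSet[str]]
    exclusive: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    pairwise: Dict[Tuple[str, str], FrozenSet[str]] = field(default_factory=dict)
    core: FrozenSet[str] = frozenset()

    def counts(self) -> Dict[str, int]:
        out = {f"{m} exclusive": len(s) for m, s in self.exclusive.items()}
        out["shared by all"] = len(self.core)
        return out


def extract_ec_set(
    annotations: Iterable[EcAnnotation],
    reference_sets: Sequence[Set[str]] = (),
    include_partial: bool = False,
) -> FrozenSet[str]:
    """Collapse reaction-level EC annotations into one model-level EC set.

    Single-EC reactions contribute their EC unconditionally.  For a
    multi-EC reaction, an EC absent from every reference set is kept
    only when none of the reaction's other ECs occurs in any reference
    set — multi-EC uniqueness must not manufacture apparent exclusivity.
    Partial ECs (``1.2.-.-``) are excluded from comparison by default;
    malformed strings are always dropped.
    """
    reference_union: Set[str] = set().union(*reference_sets) if reference_sets else set()
    keep: Set[str] = set()
    for ann in annotations:
        ecs = [e.strip() for e in ann.ec_numbers if e.strip()]
        ecs = [
            e for e in ecs
            if (is_complete_ec(e) or (include_partial and is_valid_ec(e)))
        ]
        if not ecs:
            continue
        if len(ecs) == 1:
            keep.add(ecs[0])
            continue
        any_in_reference = any(e in reference_union for e in ecs)
        for e in ecs:
            if e in reference_union or not any_in_reference:
                keep.add(e)
            # else: e is unique but a sibling EC already matches → dropped
    return frozenset(keep)


def compare_models(sets: Mapping[str, Iterable[str]]) -> EcComparisonResult:
    """Full Venn partition (exclusives, pairwise-only, common core).

    The partition cells are disjoint and union to the overall EC
    universe; the result is independent of model ordering.
    """
    if len(sets) < 2:
        raise ValueError("need at least two models to compare")
    fsets = {m: frozenset(s) for m, s in sets.items()}
    names = sorted(fsets)
    result = EcComparisonResult(sets=fsets)
    result.core = frozenset(set.intersection(*(set(fsets[m]) for m in names)))
    for m in names:
        others = set().union(*(fsets[o] for o in names if o != m))
        result.exclusive[m] = frozenset(fsets[m] - others)
    for a, b in [(x, y) for i, x in enumerate(names) for y in names[i + 1:]]:
        rest = set().union(*(fsets[o] for o in names if o not in (a, b))) if len(names) > 2 else set()
        result.pairwise[(a, b)] = frozenset((fsets[a] & fsets[b]) - rest - result.core)
    return result


def pathway_frequency(
    ec_set: Iterable[str],
    ec_to_pathways: Mapping[str, Iterable[str]],
    top: int = 0,
) -> pd.DataFrame:
    """Count ECs per pathway over a set, ranked descending.

    ECs missing from the mapping are tallied under ``"unmapped"``.  With
    ``top > 0`` only the most frequent pathways are returned.
    """
    counts: Dict[str, int] = {}
    for ec in ec_set:
        pathways = list(ec_to_pathways.get(ec, []))
        if not pathways:
            counts["unmapped"] = counts.get("unmapped", 0) + 1
            continue
        for p in pathways:
            counts[p] = counts.get(p, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["pathway", "ec_count"],
    )
    return df.head(top) if top else df


def read_ec_annotations_tsv(path) -> List[EcAnnotation]:
    """Read ``reaction id <tab> semicolon-joined ECs`` rows."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if cells[0].lower() in ("reaction", "reaction_id", "id"):
                continue
            ecs = cells[1].split(";") if len(cells) > 1 else []
            out.append(EcAnnotation(cells[0], [e.strip() for e in ecs if e.strip()]))
    return out
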