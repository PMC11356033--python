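"""Cross-platform identification concordance.

Two lipidomics platforms processing the same spectra rarely agree; this
module quantifies how much they do. Two identifications agree when the
molecular formula is identical, the lipid class is identical and the
aligned retention times lie within a tolerance (default 5 s). Agreement
is reported as common / union after a one-to-one pairing.

Pairing is solved exactly: annotations are blocked by (formula, class)
— only within-block pairs can be eligible — and each block is resolved
by optimal assignment, maximizing the number of matched pairs and,
among maximum matchings, minimizing the total retention-time gap. A
greedy nearest-gap pairing can strand matchable rows (two near-boundary
candidates on either side of a middle row), so the assignment route is
used to keep the count equal to the brute-force optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .annotations import MS1, MS2, AnnotationTable, LipidAnnotation, canonical_class
from .formula import to_hill

__all__ = ["MatchResult", "match_annotations", "subset_by_ms_level"]


@dataclass
class MatchResult:
    """Outcome of matching two annotation tables one-to-one."""

    pairs: list[tuple[str, str]]
    unique_a: list[str]
    unique_b: list[str]
    n_common: int
    n_union: int
    agreement_fraction: float
    per_class_counts: dict[str, tuple[int, int, int]]  # common, unique_a, unique_b

    def summary(self) -> dict:
        return {
            "n_common": self.n_common,
            "n_union": self.n_union,
            "agreement_fraction": self.agreement_fraction,
            "agreement_percent": round(100.0 * self.agreement_fraction, 1),
            "n_unique_a": len(self.unique_a),
            "n_unique_b": len(self.unique_b),
        }


def _match_key(a: LipidAnnotation, synonyms: dict[str, str] | None) -> tuple[str, str]:
    klass = canonical_class(a.lipid_class)
    if synonyms:
        klass = synonyms.get(klass, klass)
    return (to_hill(a.composition), klass)


def _dedup(
    rows: list[LipidAnnotation],
    tol_min: float,
    synonyms: dict[str, str] | None,
) -> list[LipidAnnotation]:
    """Collapse within-table duplicates.

    Rows identical in (formula, class) whose retention times fall within
    the matching tolerance of a group representative collapse onto the
    earliest-eluting one. Platforms report the same species several
    times across adducts/alignment slices; counting those as distinct
    would inflate the union.
    """
    groups: dict[tuple[str, str], list[LipidAnnotation]] = {}
    for a in rows:
        groups.setdefault(_match_key(a, synonyms), []).append(a)
    kept_ids = set()
    for members in groups.values():
        members = sorted(members, key=lambda a: (a.rt_min, a.id))
        rep_rt = None
        for a in members:
            if rep_rt is None or a.rt_min - rep_rt > tol_min:
                kept_ids.add(a.id)
                rep_rt = a.rt_min
    return [a for a in rows if a.id in kept_ids]


def match_annotations(
    a: AnnotationTable,
    b: AnnotationTable,
    rt_tol_sec: float = 5.0,
    class_synonyms: dict[str, str] | None = None,
    dedup: bool = True,
) -> MatchResult:
    """Match two annotation tables under the identity agreement rule.

    A pair is eligible iff formula and (synonym-mapped) class are
    identical and |Δrt| ≤ ``rt_tol_sec``. Eligible pairs are resolved
    one-to-one per (formula, class) block by optimal assignment; the
    agreement fraction is common / union, with within-table duplicates
    collapsed first unless ``dedup=False``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot match empty annotation tables")
    if rt_tol_sec <= 0:
        raise ValueError("rt_tol_sec must be positive")
    tol_min = rt_tol_sec / 60.0

    rows_a = _dedup(a.annotations, tol_min, class_synonyms) if dedup else list(a)
    rows_b = _dedup(b.annotations, tol_min, class_synonyms) if dedup else list(b)

    blocks_a: dict[tuple[str, str], list[LipidAnnotation]] = {}
    blocks_b: dict[tuple[str, str], list[LipidAnnotation]] = {}
    for x in rows_a:
        blocks_a.setdefault(_match_key(x, class_synonyms), []).append(x)
    for y in rows_b:
        blocks_b.setdefault(_match_key(y, class_synonyms), []).append(y)

    pairs: list[tuple[str, str]] = []
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    for key in sorted(set(blocks_a) & set(blocks_b)):
        xs = sorted(blocks_a[key], key=lambda r: (r.rt_min, r.id))
        ys = sorted(blocks_b[key], key=lambda r: (r.rt_min, r.id))
        delta = np.abs(
            np.subtract.outer([r.rt_min for r in xs], [r.rt_min for r in ys])
        )
        eligible = delta <= tol_min + 1e-12
        if not eligible.any():
            continue
        # Big constant beats any sum of eligible gaps, so the assignment
        # first maximizes eligible-pair count, then minimizes total |Δrt|.
        big = tol_min * (delta.size + 1) + 1.0
        cost = np.where(eligible, delta, big)
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            if eligible[i, j]:
                pairs.append((xs[i].id, ys[j].id))
                matched_a.add(xs[i].id)
                matched_b.add(ys[j].id)

    unique_a = [r.id for r in rows_a if r.id not in matched_a]
    unique_b = [r.id for r in rows_b if r.id not in matched_b]
    n_common = len(pairs)
    n_union = len(rows_a) + len(rows_b) - n_common
    agreement = n_common / n_union if n_union > 0 else float("nan")

    per_class: dict[str, list[int]] = {}
    by_id_a = {r.id: r for r in rows_a}
    by_id_b = {r.id: r for r in rows_b}
    for id_a, _ in pairs:
        key = _match_key(by_id_a[id_a], class_synonyms)[1]
        per_class.setdefault(key, [0, 0, 0])[0] += 1
    for rid in unique_a:
        key = _match_key(by_id_a[rid], class_synonyms)[1]
        per_class.setdefault(key, [0, 0, 0])[1] += 1
    for rid in unique_b:
        key = _match_key(by_id_b[rid], class_synonyms)[1]
        per_class.setdefault(key, [0, 0, 0])[2] += 1

    return MatchResult(
        pairs=sorted(pairs),
        unique_a=sorted(unique_a),
        unique_b=sorted(unique_b),
        n_common=n_common,
        n_union=n_union,
        agreement_fraction=agreement,
        per_class_counts={k: tuple(v) for k, v in sorted(per_class.items())},
    )


def subset_by_ms_level(
    a: AnnotationTable, b: AnnotationTable, level: str
) -> tuple[AnnotationTable, AnnotationTable]:
    """Restrict both tables to one MS level (MS1 precursor-only vs
    MS2 fragmentation-backed) for level-specific agreement."""
    if level not in (MS1, MS2):
        raise ValueError(f"level must be MS1 or MS2, got {level!r}")
    return (
        a.replace([x for x in a if x.ms_level == level]),
        b.replace([x for x in b if x.ms_level == level]),
    )
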