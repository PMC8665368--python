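"""Majority-vote reference standard and diagnostic concordance statistics.

The reference diagnosis of each lesion is the modal MOLEM class across its
rater panel; bimodal (or multimodal) ties resolve toward the more severe
class under the configured severity order.  Concordance, overcall and
undercall statistics then compare every individual rating against its
lesion's reference:

* concordant — the rating equals the reference class;
* overcall / undercall — the rating's *mapped ordinal value* is above /
  below the reference's (so a class V call on a class I lesion is a
  single-step overcall, not a four-step one);
* level-discordant — a different class at the same mapped value (II vs V);
  reported separately, never silently merged into concordant.

Melanoma over/underdiagnosis treats classes I-II as the benign set and
III-IV as the melanoma set (class V, nonmelanoma cancer, is excluded from
both reference denominators and never counts in a numerator).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, asdict

from .errors import DataError
from .ratings import RatingTable
from .schema import (
    CLASSES,
    MolemClass,
    OrdinalMapping,
    SeverityOrder,
    severity_max,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePanel",
    "ClassConcordance",
    "ConcordanceReport",
    "Rate",
    "majority_class",
    "build_reference",
    "concordance",
    "melanoma_over_under",
    "assignment_distribution",
    "BENIGN_SET",
    "MELANOMA_SET",
]

#: Benign and melanoma reference sets for the over/underdiagnosis rates.
BENIGN_SET = frozenset({MolemClass.I, MolemClass.II})
MELANOMA_SET = frozenset({MolemClass.III, MolemClass.IV})


def majority_class(
    ratings: list[MolemClass],
    severity: SeverityOrder | None = None,
) -> tuple[MolemClass, bool]:
    """Modal class of one lesion's ratings, ties broken toward severity.

    Returns ``(class, tie_broken)`` where ``tie_broken`` is True iff the mode
    was not unique.
    """
    if not ratings:
        raise DataError("majority of an empty rating set")
    tallies = Counter(ratings)
    top = max(tallies.values())
    modal = {c for c, n in tallies.items() if n == top}
    if len(modal) == 1:
        return next(iter(modal)), False
    return severity_max(modal, severity), True


@dataclass(frozen=True)
class ReferencePanel:
    """Majority reference class per lesion, with tie-break bookkeeping."""

    majority_of: dict[str, MolemClass]
    tie_broken: dict[str, bool]

    @property
    def n_ties(self) -> int:
        return sum(self.tie_broken.values())

    def __getitem__(self, lesion_id: str) -> MolemClass:
        return self.majority_of[str(lesion_id)]


def build_reference(
    table: RatingTable,
    severity: SeverityOrder | None = None,
    leave_one_out: bool = False,
) -> ReferencePanel:
    """Majority reference for every lesion in the table.

    By default the rater under later evaluation is included in the majority
    (a single fixed panel reference).  ``leave_one_out`` is not meaningful
    for a per-lesion reference and is reserved for rater-level comparisons;
    it is accepted here for API symmetry and must be False.
    """
    if leave_one_out:
        raise NotImplementedError(
            "leave-one-out referencing applies per rating; see concordance()"
        )
    majority: dict[str, MolemClass] = {}
    ties: dict[str, bool] = {}
    for lid, group in table.df.groupby("lesion_id", sort=True):
        cls, tb = majority_class(list(group["molem_class"]), severity)
        majority[str(lid)] = cls
        ties[str(lid)] = tb
    n_ties = sum(ties.values())
    if n_ties:
        logger.info("severity tie-break applied on %d lesion(s)", n_ties)
    return ReferencePanel(majority, ties)


@dataclass(frozen=True)
class Rate:
    """An exact count-based rate; ``value`` is None when undefined (0 denominator)."""

    count: int
    denominator: int

    @property
    def value(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.count / self.denominator

    @property
    def pct(self) -> float | None:
        v = self.value
        return None if v is None else 100.0 * v

    def to_dict(self) -> dict:
        return {"count": self.count, "denominator": self.denominator,
                "rate": self.value}


@dataclass(frozen=True)
class ClassConcordance:
    """Rating-level outcome partition for lesions of one reference class."""

    concordant: int
    overcalled: int
    undercalled: int
    level_discordant: int

    @property
    def total(self) -> int:
        return self.concordant + self.overcalled + self.undercalled + self.level_discordant

    @property
    def rate(self) -> Rate:
        return Rate(self.concordant, self.total)


@dataclass(frozen=True)
class ConcordanceReport:
    per_class: dict[MolemClass, ClassConcordance]
    overall: Rate
    melanoma_overdx: Rate
    melanoma_underdx: Rate

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c.value: {
                    "concordant": cc.concordant,
                    "overcalled": cc.overcalled,
                    "undercalled": cc.undercalled,
                    "level_discordant": cc.level_discordant,
                    "total": cc.total,
                    "rate": cc.rate.value,
                }
                for c, cc in self.per_class.items()
            },
            "overall": self.overall.to_dict(),
            "melanoma_overdiagnosis": self.melanoma_overdx.to_dict(),
            "melanoma_underdiagnosis": self.melanoma_underdx.to_dict(),
        }


def concordance(
    table: RatingTable,
    reference: ReferencePanel,
    mapping: OrdinalMapping | None = None,
) -> ConcordanceReport:
    """Partition every rating against its lesion's reference class.

    Over/undercall comparisons use mapped ordinal values v(c), so a class V
    rating on a class II lesion is level-discordant (same value, different
    class), not an over- or undercall.
    """
    mapping = mapping or OrdinalMapping()
    counts: dict[MolemClass, dict[str, int]] = {
        c: {"concordant": 0, "over": 0, "under": 0, "level": 0} for c in CLASSES
    }
    for lid, rating in zip(table.df["lesion_id"], table.df["molem_class"]):
        ref = reference[lid]
        cell = counts[ref]
        if rating == ref:
            cell["concordant"] += 1
        else:
            dv = mapping.value_of[rating] - mapping.value_of[ref]
            if dv > 0:
                cell["over"] += 1
            elif dv < 0:
                cell["under"] += 1
            else:
                cell["level"] += 1
    per_class = {
        c: ClassConcordance(
            concordant=d["concordant"], overcalled=d["over"],
            undercalled=d["under"], level_discordant=d["level"],
        )
        for c, d in counts.items()
    }
    total = sum(cc.total for cc in per_class.values())
    conc = sum(cc.concordant for cc in per_class.values())
    overdx, underdx = melanoma_over_under(table, reference)
    return ConcordanceReport(
        per_class=per_class,
        overall=Rate(conc, total),
        melanoma_overdx=overdx,
        melanoma_underdx=underdx,
    )


def melanoma_over_under(
    table: RatingTable,
    reference: ReferencePanel,
    benign: frozenset[MolemClass] = BENIGN_SET,
    melanoma: frozenset[MolemClass] = MELANOMA_SET,
) -> tuple[Rate, Rate]:
    """Melanoma over- and underdiagnosis rates against the reference.

    Overdiagnosis: melanoma-set (III/IV) ratings on benign-reference (I/II)
    lesions, over all ratings on benign-reference lesions.  Underdiagnosis:
    benign-set ratings on melanoma-reference lesions, over all ratings on
    melanoma-reference lesions.  Class V ratings sit in denominators but
    never in numerators; class-V-reference lesions are in neither.
    """
    over_n = over_d = under_n = under_d = 0
    for lid, rating in zip(table.df["lesion_id"], table.df["molem_class"]):
        ref = reference[lid]
        if ref in benign:
            over_d += 1
            if rating in melanoma:
                over_n += 1
        elif ref in melanoma:
            under_d += 1
            if rating in benign:
                under_n += 1
    return Rate(over_n, over_d), Rate(under_n, under_d)


def assignment_distribution(
    counts_per_class: dict[MolemClass, int] | None = None,
    table: RatingTable | None = None,
    n_total: int | None = None,
) -> dict[MolemClass, Rate]:
    """Share of diagnoses assigned to each class.

    Either pass a table (counts derived from its records) or explicit
    per-class counts.  ``n_total`` overrides the denominator when the
    published total differs from the sum of the per-class counts; by default
    the denominator is the count sum.
    """
    if counts_per_class is None:
        if table is None:
            raise DataError("need counts_per_class or table")
        tallies = Counter(table.df["molem_class"])
        counts_per_class = {c: tallies.get(c, 0) for c in CLASSES}
    denom = n_total if n_total is not None else sum(counts_per_class.values())
    return {c: Rate(counts_per_class.get(c, 0), denom) for c in CLASSES}
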