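"""Analysis of the pathologists' 1-5 diagnostic-confidence scores.

Confidence is recorded per rating on a 5-point scale where 1 is *most*
confident.  Three views are provided: per-reference-class summaries (mean,
SD), inter-rater agreement of the confidence scores themselves (Gwet AC
with quadratic weights on the raw 1..5 scale — the confidence scale is a
distinct ordinal object from the MOLEM mapping), and the association
between per-lesion mean confidence and the fraction of ratings matching the
majority reference (Spearman rank correlation with a permutation null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .agreement import AgreementResult, gwet_ac
from .consensus import ReferencePanel
from .errors import InsufficientDataError
from .ratings import RatingTable, confidence_counts
from .schema import CLASSES, MolemClass, build_weight_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConfidenceSummary",
    "ConfidenceAssociation",
    "confidence_summary",
    "confidence_agreement",
    "confidence_vs_discordance",
]


@dataclass(frozen=True)
class ConfidenceSummary:
    """Mean/SD/n of confidence scores, per reference class and overall."""

    per_class: dict[MolemClass, tuple[float, float, int]]
    overall: tuple[float, float, int]
    n_missing: int

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c.value: {"mean": m, "sd": s, "n": n}
                for c, (m, s, n) in self.per_class.items()
            },
            "overall": {
                "mean": self.overall[0], "sd": self.overall[1], "n": self.overall[2]
            },
            "n_missing": self.n_missing,
        }


def _mean_sd(x: np.ndarray) -> tuple[float, float, int]:
    n = len(x)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n >= 2 else 0.0
    return mean, sd, n


def confidence_summary(
    table: RatingTable, reference: ReferencePanel
) -> ConfidenceSummary:
    """Sample mean and SD (n-1 denominator) of confidence per reference class."""
    df = table.df
    present = df.dropna(subset=["confidence"])
    n_missing = len(df) - len(present)
    if present.empty:
        raise InsufficientDataError("no confidence scores present")
    if n_missing:
        logger.info("%d rating(s) lack a confidence score; excluded", n_missing)
    per_class: dict[MolemClass, tuple[float, float, int]] = {}
    for cls in CLASSES:
        vals = present.loc[
            [reference[lid] == cls for lid in present["lesion_id"]], "confidence"
        ].to_numpy(dtype=float)
        if len(vals):
            per_class[cls] = _mean_sd(vals)
    overall = _mean_sd(present["confidence"].to_numpy(dtype=float))
    return ConfidenceSummary(per_class=per_class, overall=overall, n_missing=n_missing)


def confidence_agreement(
    table: RatingTable,
    ci_level: float = 0.95,
    variance: str = "jackknife",
) -> AgreementResult:
    """Inter-rater agreement of the confidence scores themselves.

    Quadratic weights on the face values 1..5 (the confidence scale carries
    no class remapping).
    """
    counts = confidence_counts(table)
    if not (counts.r_i >= 2).any():
        raise InsufficientDataError("no lesion carries >= 2 confidence scores")
    w = build_weight_matrix("quadratic", values=[1, 2, 3, 4, 5])
    return gwet_ac(counts, w, ci_level=ci_level, variance=variance)


@dataclass(frozen=True)
class ConfidenceAssociation:
    """Spearman association between per-lesion mean confidence and agreement.

    ``rho`` is None when one margin is constant (correlation undefined).
    With 1 = most confident, a *negative* rho between the agreement fraction
    and the confidence score means raters were least confident on the
    lesions they agreed on least.
    """

    rho: float | None
    p_value: float | None
    n_lesions: int
    n_permutations: int

    def to_dict(self) -> dict:
        return {"spearman_rho": self.rho, "p_value": self.p_value,
                "n_lesions": self.n_lesions, "n_permutations": self.n_permutations}


def confidence_vs_discordance(
    table: RatingTable,
    reference: ReferencePanel,
    n_permutations: int = 2000,
    seed: int | None = None,
) -> ConfidenceAssociation:
    """Correlate per-lesion mean confidence score with reference agreement.

    For every lesion with >= 2 ratings and at least one confidence score,
    computes (mean confidence score, fraction of ratings equal to the
    reference class) and returns the Spearman rank correlation with a
    permutation p-value.
    """
    pairs: list[tuple[float, float]] = []
    for lid, group in table.df.groupby("lesion_id", sort=True):
        if len(group) < 2:
            continue
        conf = group["confidence"].dropna()
        if conf.empty:
            continue
        frac = float((group["molem_class"] == reference[str(lid)]).mean())
        pairs.append((float(conf.mean()), frac))
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need >= 3 usable lesions for the association, got {len(pairs)}"
        )
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ConfidenceAssociation(None, None, len(pairs), 0)
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = stats.spearmanr(x, rng.permutation(y)).statistic
    p = float((np.sum(np.abs(null) >= abs(rho) - 1e-12) + 1) / (n_permutations + 1))
    return ConfidenceAssociation(rho, p, len(pairs), n_permutations)
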