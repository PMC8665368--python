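"""Synthetic multi-rater panel generator and deterministic fixture builder.

``simulate_panel`` emulates the statistical structure of a multi-reader
dermatopathology panel study: ~217 lesions whose true-class mix matches the
study's majority-class distribution, a pool of 9 pathologists of whom a
uniform-random 5-9 read each slide, per-rater class assignments drawn from a
truth-conditional confusion matrix, and 1-5 confidence scores whose
distribution depends on whether the assignment matched truth (so confidence
is inversely related to agreement, as observed).  Ground truth is returned
alongside the table for parameter-recovery tests.

``fixture_from_counts`` is the deterministic counterpart: given per-class
rating-outcome counts it constructs an exact table whose majority classes
and tallies reproduce those counts, which is how printed summary tables are
turned into analyzable data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .consensus import ReferencePanel
from .errors import ConstructionError, DataError
from .ratings import RatingTable
from .schema import CLASSES, MolemClass, OrdinalMapping

__all__ = [
    "SimulationConfig",
    "simulate_panel",
    "calibrated_default",
    "fixture_from_counts",
    "results_fixture",
    "RESULTS_COUNTS",
    "HEADLINE_ASSIGNMENT_COUNTS",
    "HEADLINE_TOTAL_DIAGNOSES",
]


def _simplex(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if (a < 0).any() or abs(a.sum() - 1.0) > 1e-9:
        raise DataError(f"{name} must be a probability vector summing to 1")
    return a


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model for a synthetic rater panel.

    Defaults reflect the emulated study: 217 lesions, class mix proportional
    to the majority-class lesion counts 95/16/82/16/8 (I-V), 9 raters with
    5-9 of them reading each lesion (uniform), and confidence drawn from a
    match- or mismatch-conditional distribution over scores 1..5.
    """

    n_lesions: int = 217
    class_probs: tuple[float, ...] = (95 / 217, 16 / 217, 82 / 217, 16 / 217, 8 / 217)
    n_raters_total: int = 9
    panel_size_range: tuple[int, int] = (5, 9)
    #: rows: true class (I..V); columns: assigned class probabilities
    confusion: tuple[tuple[float, ...], ...] = tuple(
        tuple(row) for row in np.eye(5)
    )
    confidence_match: tuple[float, ...] = (0.80, 0.15, 0.05, 0.0, 0.0)
    confidence_mismatch: tuple[float, ...] = (0.25, 0.35, 0.25, 0.10, 0.05)
    seed: int = 0

    def validate(self) -> None:
        _simplex(self.class_probs, "class_probs")
        if len(self.class_probs) != 5:
            raise DataError("class_probs must have 5 entries")
        conf = np.asarray(self.confusion, dtype=float)
        if conf.shape != (5, 5):
            raise DataError("confusion must be 5x5")
        for k in range(5):
            _simplex(conf[k], f"confusion row {CLASSES[k].value}")
        _simplex(self.confidence_match, "confidence_match")
        _simplex(self.confidence_mismatch, "confidence_mismatch")
        lo, hi = self.panel_size_range
        if not (1 <= lo <= hi <= self.n_raters_total):
            raise DataError(
                f"panel sizes {self.panel_size_range} must lie within "
                f"[1, {self.n_raters_total}]"
            )

    def to_dict(self) -> dict:
        return {
            "n_lesions": self.n_lesions,
            "class_probs": list(self.class_probs),
            "n_raters_total": self.n_raters_total,
            "panel_size_range": list(self.panel_size_range),
            "confusion": [list(r) for r in self.confusion],
            "confidence_match": list(self.confidence_match),
            "confidence_mismatch": list(self.confidence_mismatch),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for key in ("class_probs", "confidence_match", "confidence_mismatch"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "panel_size_range" in kwargs:
            kwargs["panel_size_range"] = tuple(kwargs["panel_size_range"])
        if "confusion" in kwargs:
            kwargs["confusion"] = tuple(tuple(r) for r in kwargs["confusion"])
        return cls(**kwargs)


def simulate_panel(
    config: SimulationConfig, seed: int | None = None
) -> tuple[RatingTable, dict[str, MolemClass]]:
    """Draw a synthetic rating table and its ground truth.

    ``seed`` overrides ``config.seed`` when given; identical seeds produce
    identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    conf = np.asarray(config.confusion, dtype=float)
    probs = np.asarray(config.class_probs, dtype=float)
    cmatch = np.asarray(config.confidence_match, dtype=float)
    cmis = np.asarray(config.confidence_mismatch, dtype=float)
    lo, hi = config.panel_size_range

    width = len(str(config.n_lesions))
    records = []
    truth: dict[str, MolemClass] = {}
    for i in range(config.n_lesions):
        lid = f"L{i + 1:0{width}d}"
        t = int(rng.choice(5, p=probs))
        truth[lid] = CLASSES[t]
        m = int(rng.integers(lo, hi + 1))
        raters = rng.choice(config.n_raters_total, size=m, replace=False)
        assigned = rng.choice(5, size=m, p=conf[t])
        for rater, a in zip(np.sort(raters), assigned):
            score = int(rng.choice(5, p=cmatch if a == t else cmis)) + 1
            records.append(
                (lid, f"R{rater + 1}", CLASSES[int(a)], score)
            )
    df = pd.DataFrame(
        records, columns=["lesion_id", "rater_id", "molem_class", "confidence"]
    )
    return RatingTable(df), truth


def calibrated_default() -> SimulationConfig:
    """Simulation config calibrated to the emulated study's concordance profile.

    Confusion rows place miscall mass on classes adjacent in *mapped* ordinal
    value (class V neighbours I and III; class II splits between I and III),
    with diagonals set so that simulated per-majority-class concordance at
    large n tracks the study's 88.6 / 50.8 / 76.2 / 77.2 / 74.5 percent
    profile: class II is by far the hardest call, class I the easiest.
    """
    return SimulationConfig(
        confusion=(
            # assigned:  I      II     III    IV     V
            (0.895, 0.048, 0.010, 0.000, 0.047),  # truth I
            (0.320, 0.340, 0.320, 0.020, 0.000),  # truth II
            (0.040, 0.095, 0.775, 0.075, 0.015),  # truth III
            (0.000, 0.030, 0.190, 0.775, 0.005),  # truth IV
            (0.115, 0.050, 0.100, 0.000, 0.735),  # truth V
        ),
    )


# ---------------------------------------------------------------------------
# Deterministic fixture from printed per-class counts
# ---------------------------------------------------------------------------

#: Canonical per-majority-class rating outcomes of the emulated study:
#: number of lesions, concordant ratings, and the breakdown of discordant
#: ratings by assigned class.  Aggregates reproduce every printed total
#: (600/677, 61/120 with 29 over + 30 under, 430/564, 88/114, 41/55;
#: melanoma calls on benign-majority lesions 44/797; benign calls on
#: melanoma-majority lesions 123/678); the split of the discordant mass
#: among specific classes, where unpublished, is a fixed package choice.
RESULTS_COUNTS: dict[MolemClass, dict] = {
    MolemClass.I: {
        "lesions": 95,
        "concordant": 600,
        "discordant": {MolemClass.II: 40, MolemClass.V: 22,
                       MolemClass.III: 10, MolemClass.IV: 5},
    },
    MolemClass.II: {
        "lesions": 16,
        "concordant": 61,
        "discordant": {MolemClass.I: 30, MolemClass.III: 20, MolemClass.IV: 9},
    },
    MolemClass.III: {
        "lesions": 82,
        "concordant": 430,
        "discordant": {MolemClass.I: 60, MolemClass.II: 43,
                       MolemClass.V: 5, MolemClass.IV: 26},
    },
    MolemClass.IV: {
        "lesions": 16,
        "concordant": 88,
        "discordant": {MolemClass.I: 5, MolemClass.II: 15, MolemClass.III: 6},
    },
    MolemClass.V: {
        "lesions": 8,
        "concordant": 41,
        "discordant": {MolemClass.I: 6, MolemClass.II: 4, MolemClass.III: 4},
    },
}

#: Headline class-assignment counts and the separately printed diagnosis
#: total they were reported against (the study's own arithmetic: the
#: per-class counts sum to 1530 yet the stated total is 1516; both variants
#: are carried, unreconciled).
HEADLINE_ASSIGNMENT_COUNTS: dict[MolemClass, int] = {
    MolemClass.I: 677, MolemClass.II: 120, MolemClass.III: 564,
    MolemClass.IV: 114, MolemClass.V: 55,
}
HEADLINE_TOTAL_DIAGNOSES: int = 1516


def fixture_from_counts(
    per_class: dict[MolemClass, dict],
    with_confidence: bool = False,
) -> tuple[RatingTable, ReferencePanel]:
    """Build a deterministic table reproducing given per-class outcomes.

    ``per_class`` maps each intended majority class to ``{"lesions": L,
    "concordant": C, "discordant": {class: count, ...}}``.  Concordant
    ratings are spread round-robin over the L lesions and each discordant
    class's ratings are spread with a stagger, so that on every lesion the
    intended class is the strict mode; construction fails if any lesion's
    majority would flip.  When ``with_confidence`` is set, concordant ratings
    carry confidence 1 and discordant ratings confidence 3 (a deterministic
    stand-in for the confidence-tracks-agreement pattern).
    """
    records = []
    majority: dict[str, MolemClass] = {}
    ties: dict[str, bool] = {}
    for ref_cls, spec_c in per_class.items():
        L = int(spec_c["lesions"])
        C = int(spec_c["concordant"])
        discordant: dict[MolemClass, int] = spec_c.get("discordant", {})
        if L < 1 or C < 0 or any(n < 0 for n in discordant.values()):
            raise ConstructionError("counts must be non-negative, lesions >= 1")
        if ref_cls in discordant:
            raise ConstructionError(
                f"{ref_cls.value} listed as discordant with itself"
            )
        # per-lesion tallies: concordant round-robin, discordant staggered
        tallies = [dict.fromkeys(CLASSES, 0) for _ in range(L)]
        for j in range(C):
            tallies[j % L][ref_cls] += 1
        for offset, (cls, n) in enumerate(sorted(discordant.items(),
                                                 key=lambda kv: kv[0].value), 1):
            for j in range(n):
                tallies[(j + offset * (L // (len(discordant) + 1) + 1)) % L][cls] += 1
        for j, tal in enumerate(tallies):
            others = max((n for c, n in tal.items() if c != ref_cls), default=0)
            if tal[ref_cls] <= others:
                raise ConstructionError(
                    f"lesion {j} of class {ref_cls.value}: intended majority "
                    f"({tal[ref_cls]} ratings) does not strictly out-count the "
                    f"largest discordant class ({others})"
                )
        for j, tal in enumerate(tallies):
            lid = f"{ref_cls.value}-{j + 1:03d}"
            majority[lid] = ref_cls
            ties[lid] = False
            rater = 0
            for cls in CLASSES:
                for _ in range(tal[cls]):
                    rater += 1
                    conf = (1 if cls == ref_cls else 3) if with_confidence else None
                    records.append((lid, f"R{rater:02d}", cls, conf))
    df = pd.DataFrame(
        records, columns=["lesion_id", "rater_id", "molem_class", "confidence"]
    )
    return RatingTable(df), ReferencePanel(majority, ties)


def results_fixture(with_confidence: bool = False) -> tuple[RatingTable, ReferencePanel]:
    """The canonical printed-results fixture (1530 ratings on 217 lesions)."""
    return fixture_from_counts(RESULTS_COUNTS, with_confidence=with_confidence)
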