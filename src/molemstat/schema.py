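"""MOLEM classification schema: classes, ordinal value mapping, severity order,
agreement-weight matrices and strength bands.

The MOLEM (Management of Lesions to Exclude Melanoma) schema classifies skin
lesions excised to exclude melanoma into five management-oriented classes:

=====  ================================================  ==========  =======================================
Class  Exemplar diagnoses                                Risk        Suggested management
=====  ================================================  ==========  =======================================
I      benign naevus, mild atypia, seborrheic            very low    no further treatment
       keratosis, lichenoid keratosis, cyst
II     moderately atypical naevus, Spitz, deep           low         narrow but complete excision (<5 mm)
       penetrating naevus
III    melanoma in situ, severely atypical naevus        higher      complete excision (>5 mm, <10 mm)
IV     invasive melanoma                                 highest     complete excision, margins >10 mm
V      basal cell carcinoma, squamous cell carcinoma     high        definitive malignant-nonmelanoma
       in situ                                                       management
=====  ================================================  ==========  =======================================

Because the schema mixes melanocytic (I-IV) and nonmelanocytic (V) lesions on
one ordinal axis, agreement statistics use a bespoke value mapping: classes
I-IV take their face values 1-4, while class V is mapped to 2 (it shares its
suggested management tier with class II).  Quadratic agreement weights are
built from these mapped values, so a I-vs-V disagreement is a single step,
not four.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateScaleError, SchemaError

__all__ = [
    "MolemClass",
    "CLASS_INFO",
    "OrdinalMapping",
    "SeverityOrder",
    "WeightMatrix",
    "MolemSchema",
    "mapped_value",
    "build_weight_matrix",
    "band",
    "severity_max",
    "BANDS",
]


class MolemClass(str, enum.Enum):
    """The five MOLEM classes, in reporting order."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Descriptive metadata per class (exemplar diagnoses, risk tier, management).
CLASS_INFO: dict[MolemClass, dict[str, str]] = {
    MolemClass.I: {
        "examples": "benign naevus; naevus with mild atypia; seborrheic "
        "keratosis; lichenoid keratosis; cyst",
        "risk": "very low",
        "management": "generally no further treatment",
    },
    MolemClass.II: {
        "examples": "moderately atypical naevus; Spitz naevus; deep "
        "penetrating naevus",
        "risk": "low",
        "management": "narrow but complete excision (<5 mm margins)",
    },
    MolemClass.III: {
        "examples": "melanoma in situ; severely atypical naevus",
        "risk": "higher",
        "management": "complete excision (>5 mm but <10 mm margins)",
    },
    MolemClass.IV: {
        "examples": "invasive melanoma",
        "risk": "highest",
        "management": "complete excision, margins larger than 10 mm",
    },
    MolemClass.V: {
        "examples": "basal cell carcinoma; in situ squamous cell carcinoma",
        "risk": "high",
        "management": "definitive malignant-nonmelanoma management",
    },
}

#: Fixed category order used by every count matrix and weight matrix.
CLASSES: tuple[MolemClass, ...] = tuple(MolemClass)


def parse_class(label: str) -> MolemClass:
    """Parse a class label, tolerating case and an optional ``class`` prefix."""
    text = str(label).strip()
    if text.lower().startswith("class"):
        text = text[5:].strip()
    text = text.upper()
    try:
        return MolemClass(text)
    except ValueError:
        raise SchemaError(f"unknown MOLEM class label: {label!r}") from None


@dataclass(frozen=True)
class OrdinalMapping:
    """Map from class to the integer score used in agreement weighting.

    The default places class V at value 2, collapsing it onto class II's
    management tier, so the ordinal distance I-to-V is one step.
    """

    value_of: dict[MolemClass, int] = field(
        default_factory=lambda: {
            MolemClass.I: 1,
            MolemClass.II: 2,
            MolemClass.III: 3,
            MolemClass.IV: 4,
            MolemClass.V: 2,
        }
    )

    def __post_init__(self) -> None:
        missing = [c for c in MolemClass if c not in self.value_of]
        if missing:
            raise SchemaError(f"mapping lacks values for {missing}")

    @property
    def v_min(self) -> int:
        return min(self.value_of.values())

    @property
    def v_max(self) -> int:
        return max(self.value_of.values())

    def values(self) -> list[int]:
        """Mapped values in fixed class order (I, II, III, IV, V)."""
        return [self.value_of[c] for c in CLASSES]


@dataclass(frozen=True)
class SeverityOrder:
    """Strict total order on classes used to break bimodal majority ties.

    The default rank is derived from each class's risk-of-progression tier:
    I (very low) < II (low) < V (high) < III (higher) < IV (highest).  The
    position of class V is the one genuinely ambiguous choice (its mapped
    ordinal value equals class II's, but its risk text is "high"); it is
    configurable for that reason.
    """

    rank_of: dict[MolemClass, int] = field(
        default_factory=lambda: {
            MolemClass.I: 1,
            MolemClass.II: 2,
            MolemClass.V: 3,
            MolemClass.III: 4,
            MolemClass.IV: 5,
        }
    )

    def __post_init__(self) -> None:
        ranks = sorted(self.rank_of[c] for c in MolemClass)
        if ranks != [1, 2, 3, 4, 5]:
            raise SchemaError(
                "severity ranks must be a permutation of 1..5 (no ties); "
                f"got {self.rank_of}"
            )


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric agreement-weight matrix over the scale categories.

    ``w[k, l]`` is the partial credit given when one rater picks category k
    and another picks l: 1 on the diagonal, in [0, 1] everywhere.
    """

    w: np.ndarray
    scheme: str  # "unweighted" | "quadratic"

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise SchemaError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise SchemaError("weight matrix must be symmetric")
        if not np.allclose(np.diag(w), 1.0):
            raise SchemaError("weight matrix diagonal must be 1")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise SchemaError("weights must lie in [0, 1]")
        object.__setattr__(self, "w", w)

    @property
    def q(self) -> int:
        return self.w.shape[0]

    @property
    def total(self) -> float:
        """Sum of all entries, T_w — enters the chance-agreement formula."""
        return float(self.w.sum())


def mapped_value(c: MolemClass | str, m: OrdinalMapping | None = None) -> int:
    """Return the ordinal score of class ``c`` under mapping ``m``."""
    m = m or OrdinalMapping()
    if not isinstance(c, MolemClass):
        c = parse_class(c)
    return m.value_of[c]


def build_weight_matrix(scheme: str, values: list[int] | None = None) -> WeightMatrix:
    """Build an agreement-weight matrix.

    Parameters
    ----------
    scheme
        ``"unweighted"`` gives the identity matrix (exact matches only);
        ``"quadratic"`` gives ``w_kl = 1 - (v_k - v_l)^2 / (v_max - v_min)^2``
        from the mapped category values, so the penalty grows with the squared
        ordinal distance.
    values
        Mapped values per category, in category order.  Required for the
        quadratic scheme; defaults to the MOLEM mapping (1, 2, 3, 4, 2).
    """
    if scheme == "unweighted":
        q = 5 if values is None else len(values)
        return WeightMatrix(np.eye(q), "unweighted")
    if scheme != "quadratic":
        raise SchemaError(f"unknown weighting scheme: {scheme!r}")
    if values is None:
        values = OrdinalMapping().values()
    v = np.asarray(values, dtype=float)
    span = v.max() - v.min()
    if span <= 0:
        raise DegenerateScaleError(
            "quadratic weights need at least two distinct mapped values"
        )
    d = v[:, None] - v[None, :]
    w = 1.0 - d**2 / span**2
    return WeightMatrix(w, "quadratic")


#: Agreement-strength bands: (upper bound inclusive, label).  The printed
#: bands leave (0.20, 0.21) uncovered; intervals here are half-open with the
#: upper endpoint included, and negative coefficients band as "poor".
BANDS: tuple[tuple[float, str], ...] = (
    (0.20, "poor"),
    (0.40, "slight"),
    (0.60, "fair"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def band(coefficient: float) -> str:
    """Return the strength label for a chance-corrected agreement coefficient."""
    if not np.isfinite(coefficient) or coefficient > 1 + 1e-12:
        raise SchemaError(f"coefficient must be finite and <= 1, got {coefficient}")
    for upper, label in BANDS:
        if coefficient <= upper + 1e-12:
            return label
    return "almost perfect"  # pragma: no cover - unreachable after guard


def severity_max(
    classes: set[MolemClass] | list[MolemClass],
    severity: SeverityOrder | None = None,
) -> MolemClass:
    """Return the most severe class of a non-empty collection."""
    severity = severity or SeverityOrder()
    items = list(classes)
    if not items:
        raise SchemaError("severity_max of an empty class set")
    return max(items, key=lambda c: severity.rank_of[c])


@dataclass(frozen=True)
class MolemSchema:
    """Bundle of mapping + severity order, serializable for configuration."""

    mapping: OrdinalMapping = field(default_factory=OrdinalMapping)
    severity: SeverityOrder = field(default_factory=SeverityOrder)

    def to_dict(self) -> dict:
        return {
            "classes": [c.value for c in CLASSES],
            "mapping": {c.value: self.mapping.value_of[c] for c in CLASSES},
            "severity_rank": {c.value: self.severity.rank_of[c] for c in CLASSES},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MolemSchema":
        mapping = OrdinalMapping(
            {parse_class(k): int(v) for k, v in d["mapping"].items()}
        )
        severity = SeverityOrder(
            {parse_class(k): int(v) for k, v in d["severity_rank"].items()}
        )
        return cls(mapping=mapping, severity=severity)

    def with_severity(self, rank_of: dict[MolemClass, int]) -> "MolemSchema":
        return replace(self, severity=SeverityOrder(rank_of))
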