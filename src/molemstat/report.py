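"""End-to-end analysis pipeline and report rendering.

``analyze`` composes the full pipeline — read/tally, majority reference,
agreement suite, concordance and confidence analyses — into one
JSON-serializable :class:`AnalysisReport`.  ``render`` emits it as JSON
(lossless), a majority-class-stratified markdown table, or CSV.
Percentages are recomputed from counts at render time, never stored
pre-rounded.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, asdict

from .agreement import (
    agreement_by_reference_class,
    gwet_ac,
    rater_vs_reference_agreement,
)
from .confidence import (
    confidence_agreement,
    confidence_summary,
    confidence_vs_discordance,
)
from .consensus import assignment_distribution, build_reference, concordance
from .errors import DataError, InsufficientDataError
from .ratings import RatingTable, read_ratings, tally
from .schema import CLASSES, MolemClass, MolemSchema, build_weight_matrix

__all__ = ["AnalysisReport", "analyze", "render"]


@dataclass
class AnalysisReport:
    """Complete serializable analysis output (all blocks are plain dicts)."""

    metadata: dict
    assignment: dict
    rating_vs_reference: dict
    interrater: dict
    by_class: dict
    concordance: dict
    confidence_summary: dict | None
    confidence_agreement: dict | None
    confidence_association: dict | None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(**d)


def analyze(
    ratings: RatingTable | str,
    schema: MolemSchema | None = None,
    weights: str = "quadratic",
    ci: str = "jackknife",
    ci_level: float = 0.95,
    seed: int = 0,
) -> AnalysisReport:
    """Run the full reliability pipeline on a ratings table or CSV path.

    Deterministic given the input and configuration: any resampling
    (bootstrap CI, permutation p-values) is driven by ``seed``.
    """
    schema = schema or MolemSchema()
    table = ratings if isinstance(ratings, RatingTable) else read_ratings(ratings)
    counts = tally(table)
    w = build_weight_matrix(weights, schema.mapping.values())
    reference = build_reference(table, schema.severity)

    interrater = gwet_ac(counts, w, ci_level=ci_level, variance=ci, seed=seed)
    vs_ref = rater_vs_reference_agreement(
        table, reference.majority_of, w, ci_level=ci_level, variance=ci
    )
    by_class = agreement_by_reference_class(
        counts, w, reference.majority_of, ci_level=ci_level, variance=ci
    )
    conc = concordance(table, reference, schema.mapping)
    assignment = assignment_distribution(table=table)

    conf_summary = conf_agree = conf_assoc = None
    try:
        conf_summary = confidence_summary(table, reference).to_dict()
        conf_agree = confidence_agreement(table, ci_level=ci_level, variance=ci).to_dict()
        conf_assoc = confidence_vs_discordance(table, reference, seed=seed).to_dict()
    except (InsufficientDataError, DataError):
        pass

    lesions_per_class = {c.value: 0 for c in CLASSES}
    for cls in reference.majority_of.values():
        lesions_per_class[cls.value] += 1
    metadata = {
        "n_lesions": len(table.lesions),
        "n_lesions_per_class": lesions_per_class,
        "n_ratings": table.n_records,
        "n_raters": len(table.raters),
        "n_tie_broken": reference.n_ties,
        "weights_scheme": w.scheme,
        "ci_method": ci,
        "ci_level": ci_level,
        "seed": seed,
        "schema": schema.to_dict(),
    }
    return AnalysisReport(
        metadata=metadata,
        assignment={
            c.value: r.to_dict() for c, r in assignment.items()
        },
        rating_vs_reference=vs_ref.to_dict(),
        interrater=interrater.to_dict(),
        by_class={c.value: res.to_dict() for c, res in by_class.items()},
        concordance=conc.to_dict(),
        confidence_summary=conf_summary,
        confidence_agreement=conf_agree,
        confidence_association=conf_assoc,
    )


def _pct(x: float | None) -> str:
    return "NA" if x is None else f"{100 * x:.1f}"


def _ac_ci(block: dict | None) -> str:
    if block is None:
        return "NA"
    ac = f"{block['coefficient']:.2f}"
    if block.get("ci_low") is None:
        return ac
    return f"{ac} ({block['ci_low']:.2f}-{block['ci_high']:.2f})"


def _conf_cell(summary: dict | None, cls: str) -> str:
    if summary is None:
        return "NA"
    per = summary["per_class"].get(cls)
    if per is None:
        return "NA"
    return f"{per['mean']:.1f} ({per['sd']:.1f})"


def _rows(report: AnalysisReport) -> list[dict]:
    conc = report.concordance
    meta = report.metadata
    rows = [
        {
            "block": "ratings vs majority class",
            "lesions": meta["n_lesions"],
            "ratings": meta["n_ratings"],
            "concordance_pct": _pct(conc["overall"]["rate"]),
            "agreement_pct": _pct(report.rating_vs_reference["percent_agreement"]),
            "ac_ci": _ac_ci(report.rating_vs_reference),
            "confidence_mean_sd": "NA",
        },
        {
            "block": "interrater agreement",
            "lesions": meta["n_lesions"],
            "ratings": meta["n_ratings"],
            "concordance_pct": "NA",
            "agreement_pct": _pct(report.interrater["percent_agreement"]),
            "ac_ci": _ac_ci(report.interrater),
            "confidence_mean_sd": (
                "NA" if report.confidence_summary is None else
                f"{report.confidence_summary['overall']['mean']:.1f} "
                f"({report.confidence_summary['overall']['sd']:.1f})"
            ),
        },
    ]
    for cls in (c.value for c in CLASSES):
        if cls not in report.by_class:
            continue
        pc = conc["per_class"][cls]
        block = report.by_class[cls]
        rows.append({
            "block": f"majority class {cls}",
            "lesions": meta.get("n_lesions_per_class", {}).get(cls, "NA"),
            "ratings": pc["total"],
            "concordance_pct": _pct(pc["rate"]),
            "agreement_pct": _pct(block["percent_agreement"]),
            "ac_ci": _ac_ci(block),
            "confidence_mean_sd": _conf_cell(report.confidence_summary, cls),
        })
    return rows


def render(report: AnalysisReport, format: str = "json") -> str:
    """Render a report as ``json`` (lossless), ``markdown`` or ``csv``."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2)
    rows = _rows(report)
    header = ["block", "lesions", "ratings", "concordance_pct",
              "agreement_pct", "ac_ci", "confidence_mean_sd"]
    if format == "markdown":
        lines = [
            "| Agreement | Lesions | Ratings | Concordance, % | Agreement, % "
            "| Gwet AC (95% CI) | Confidence mean (SD) |",
            "|---|---|---|---|---|---|---|",
        ]
        for r in rows:
            lines.append(
                "| " + " | ".join(str(r[h]) for h in header) + " |"
            )
        return "\n".join(lines) + "\n"
    if format == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=header)
        writer.writeheader()
        writer.writerows(rows)
        return buf.getvalue()
    raise ValueError(f"unknown format: {format!r}")
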