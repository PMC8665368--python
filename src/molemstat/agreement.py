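"""Weighted multi-rater chance-corrected agreement (Gwet AC1/AC2).

The statistic is computed from the per-lesion category tallies r_ik.  With
agreement weights w_kl (identity for AC1, quadratic for AC2) and weighted
counts r*_ik = sum_l w_kl r_il:

    per-item agreement   p_a|i = sum_k r_ik (r*_ik - 1) / (r_i (r_i - 1))
    percent agreement    p_a   = mean of p_a|i over the n' items with r_i >= 2
    prevalence           pi_k  = (1/n) sum_i r_ik / r_i        (over all n items)
    chance agreement     p_e   = T_w / (q (q-1)) * sum_k pi_k (1 - pi_k)
    coefficient          AC    = (p_a - p_e) / (1 - p_e)

where T_w = sum_kl w_kl (= q for identity weights).  Unlike the kappa family,
the chance term is driven by how far the prevalences sit from uniform rather
than by rater-marginal products, which keeps the coefficient stable under the
severe class imbalance typical of diagnostic panels.

Standard errors use a delete-one-lesion jackknife over the n' agreement
items, treating the rater panel as fixed and lesions as the sampled units;
a lesion bootstrap is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .errors import DegenerateScaleError, InsufficientDataError
from .ratings import CountMatrix, RatingTable, tally
from .schema import CLASSES, MolemClass, WeightMatrix, band

__all__ = [
    "AgreementResult",
    "percent_agreement",
    "chance_agreement",
    "gwet_ac",
    "agreement_by_reference_class",
    "rater_vs_reference_agreement",
]


@dataclass(frozen=True)
class AgreementResult:
    """Point estimate, uncertainty and strength band for one agreement analysis."""

    coefficient: float
    percent_agreement: float
    chance_agreement: float
    se: float | None
    ci_low: float | None
    ci_high: float | None
    ci_level: float
    n_items: int          # lesions entering percent agreement (r_i >= 2)
    n_ratings: int
    band: str
    weights_scheme: str
    variance_method: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _per_item_agreement(counts: CountMatrix, w: WeightMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Return (p_a|i for agreement items, boolean mask of agreement items)."""
    r = counts.r.astype(float)
    r_i = counts.r_i.astype(float)
    mask = r_i >= 2
    if not mask.any():
        raise InsufficientDataError("no lesion carries >= 2 ratings")
    rstar = r @ w.w  # w symmetric
    with np.errstate(invalid="ignore", divide="ignore"):
        pa_i = (r * (rstar - 1.0)).sum(axis=1) / (r_i * (r_i - 1.0))
    return pa_i, mask


def percent_agreement(counts: CountMatrix, w: WeightMatrix) -> float:
    """Weighted probability that two random raters of a lesion (partially) agree."""
    pa_i, mask = _per_item_agreement(counts, w)
    return float(pa_i[mask].mean())


def _prevalence(counts: CountMatrix) -> np.ndarray:
    r = counts.r.astype(float)
    return (r / counts.r_i[:, None]).mean(axis=0)


def chance_agreement(counts: CountMatrix, w: WeightMatrix) -> float:
    """Expected weighted agreement under prevalence-driven random rating."""
    q = counts.q
    if q < 2:
        raise DegenerateScaleError("need at least two categories")
    pi = _prevalence(counts)
    return float(w.total / (q * (q - 1)) * (pi * (1.0 - pi)).sum())


def _jackknife(counts: CountMatrix, w: WeightMatrix) -> np.ndarray:
    """Leave-one-lesion-out AC replicates over the agreement items.

    Lesions with a single rating stay in the prevalence term of every
    replicate; only lesions contributing to p_a are deleted.
    """
    pa_i, mask = _per_item_agreement(counts, w)
    n = counts.n_lesions
    q = counts.q
    n_prime = int(mask.sum())
    r = counts.r.astype(float)
    p = r / counts.r_i[:, None]  # per-lesion category proportions
    pi = p.mean(axis=0)
    c = w.total / (q * (q - 1))

    S = pa_i[mask].sum()
    idx = np.flatnonzero(mask)
    if n_prime < 2 or n < 2:
        return np.array([])
    # leave-one-out percent agreement
    pa_loo = (S - pa_i[idx]) / (n_prime - 1)
    # leave-one-out prevalence: pi' = (n*pi - p_i) / (n - 1), vectorized
    pi_loo = (n * pi[None, :] - p[idx]) / (n - 1)
    pe_loo = c * (pi_loo * (1.0 - pi_loo)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ac_loo = (pa_loo - pe_loo) / (1.0 - pe_loo)
    return ac_loo


def gwet_ac(
    counts: CountMatrix,
    w: WeightMatrix,
    ci_level: float = 0.95,
    variance: str = "jackknife",
    n_boot: int = 2000,
    seed: int | None = None,
) -> AgreementResult:
    """Gwet's chance-corrected agreement coefficient with CI.

    Identity weights give AC1, non-trivial weights AC2; the result records
    which scheme was used.  ``variance`` is ``"jackknife"`` (default,
    t-based CI), ``"bootstrap"`` (lesion bootstrap, percentile CI) or
    ``"none"``.  The upper CI bound is clipped at 1; the lower bound is not
    clipped, since chance-corrected coefficients can be negative.
    """
    p_a = percent_agreement(counts, w)
    p_e = chance_agreement(counts, w)
    if p_e >= 1.0 - 1e-12:
        raise DegenerateScaleError(
            "chance agreement is 1: single effective category under weights"
        )
    ac = (p_a - p_e) / (1.0 - p_e)
    _, mask = _per_item_agreement(counts, w)
    n_prime = int(mask.sum())

    se = ci_low = ci_high = None
    method = None
    if variance == "jackknife":
        reps = _jackknife(counts, w)
        if reps.size >= 2:
            se = float(np.sqrt((n_prime - 1) / n_prime * ((reps - reps.mean()) ** 2).sum()))
            tq = stats.t.ppf(0.5 + ci_level / 2, df=n_prime - 1)
            ci_low = ac - tq * se
            ci_high = min(ac + tq * se, 1.0)
            method = "jackknife"
    elif variance == "bootstrap":
        rng = np.random.default_rng(seed)
        n = counts.n_lesions
        reps = np.empty(n_boot)
        for b in range(n_boot):
            rows = rng.integers(0, n, size=n)
            sub = CountMatrix(
                tuple(f"b{j}" for j in range(n)), counts.r[rows], counts.categories
            )
            try:
                pa_b = percent_agreement(sub, w)
                pe_b = chance_agreement(sub, w)
                reps[b] = (pa_b - pe_b) / (1.0 - pe_b)
            except (InsufficientDataError, ZeroDivisionError):
                reps[b] = np.nan
        reps = reps[np.isfinite(reps)]
        if reps.size >= 2:
            se = float(reps.std(ddof=1))
            alpha = 1.0 - ci_level
            ci_low = float(np.quantile(reps, alpha / 2))
            ci_high = min(float(np.quantile(reps, 1 - alpha / 2)), 1.0)
            method = "bootstrap"
    elif variance != "none":
        raise ValueError(f"unknown variance method: {variance!r}")

    return AgreementResult(
        coefficient=float(ac),
        percent_agreement=p_a,
        chance_agreement=p_e,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=ci_level,
        n_items=n_prime,
        n_ratings=counts.n_ratings,
        band=band(min(ac, 1.0)),
        weights_scheme=w.scheme,
        variance_method=method,
    )


def agreement_by_reference_class(
    counts: CountMatrix,
    w: WeightMatrix,
    reference: dict[str, MolemClass],
    ci_level: float = 0.95,
    variance: str = "jackknife",
) -> dict[MolemClass, AgreementResult]:
    """Agreement within each reference-class stratum.

    Lesions are partitioned by their majority (reference) class and the
    coefficient recomputed within each subset, with category prevalences
    re-estimated from the subset alone — each stratum is a self-contained
    analysis.  Strata with < 2 lesions yield a point estimate without a CI.
    """
    out: dict[MolemClass, AgreementResult] = {}
    for cls in CLASSES:
        lids = [lid for lid in counts.lesion_ids if reference[lid] == cls]
        if not lids:
            continue
        sub = counts.subset(lids)
        method = variance if len(lids) >= 2 else "none"
        out[cls] = gwet_ac(sub, w, ci_level=ci_level, variance=method)
    return out


def rater_vs_reference_agreement(
    table: RatingTable,
    reference: dict[str, MolemClass],
    w: WeightMatrix,
    ci_level: float = 0.95,
    variance: str = "jackknife",
) -> AgreementResult:
    """Agreement between individual ratings and the majority reference.

    Every rating record is paired with its lesion's reference class to form a
    two-rating item; the coefficient is then computed over these items, so it
    measures how well a typical single pathologist reproduces the panel
    majority rather than how well pathologists agree among themselves.
    """
    if table.n_records == 0:
        raise InsufficientDataError("empty ratings table")
    cat_index = {c: k for k, c in enumerate(CLASSES)}
    n = table.n_records
    r = np.zeros((n, len(CLASSES)), dtype=int)
    for row, (lid, cls) in enumerate(zip(table.df["lesion_id"], table.df["molem_class"])):
        r[row, cat_index[cls]] += 1
        r[row, cat_index[reference[lid]]] += 1
    cm = CountMatrix(tuple(f"pair{j}" for j in range(n)), r)
    method = variance if n >= 2 else "none"
    return gwet_ac(cm, w, ci_level=ci_level, variance=method)
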