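"""Plate QC, robust SD-distance scoring, hit calling and group comparisons.

The screen's scoring rule: for each of the four LD parameters, a compound's
score is its distance from the reference median in units of the reference
standard deviation,

    z_ck = (x_ck - median_k) / sd_k ,

with the reference set defaulting to all compound wells on the plate (with
~hundreds of mostly-inert compounds the sample median sits at the null
centre). A compound is a hit only if it clears the per-parameter bar in all
four parameters simultaneously: |z| >= 2 for LD area and compactness, z <= -2
for total LD area (the screen looks for reduced LD burden), and |z| >= 4 for
form factor.

Plate quality is summarised by the Z' factor between positive and negative
control wells, Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|; values
above 0.5 conventionally indicate an excellent assay window.

``compare_groups`` implements the normality-gated two-sample test used for
the organelle quantifications: Shapiro-Wilk per group, Student's t when both
groups look normal, two-sided Mann-Whitney U otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PARAMETERS", "DEFAULT_THRESHOLDS", "DEFAULT_DIRECTIONS",
    "ZPrimeResult", "PlateScores", "GroupComparison",
    "zprime", "score_plate", "call_hits", "compare_groups",
    "ssmd_replicate", "adjust_fdr",
]

PARAMETERS = ("ld_area", "ld_total_area", "ld_compactness", "ld_form_factor")

#: SD-distance bars per parameter: 2 for area, total area and compactness,
#: a stricter 4 for form factor.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "ld_area": 2.0, "ld_total_area": 2.0, "ld_compactness": 2.0,
    "ld_form_factor": 4.0,
}

#: Total LD area must decrease (a hit clears LDs); the other three parameters
#: are scored two-sided since either direction reflects a changed LD state.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "ld_area": "two_sided", "ld_total_area": "decrease",
    "ld_compactness": "two_sided", "ld_form_factor": "two_sided",
}


@dataclass
class ZPrimeResult:
    value: float  # NaN when group means coincide
    mean_pos: float
    mean_neg: float
    sd_pos: float
    sd_neg: float
    n_pos: int
    n_neg: int
    flags: list[str] = field(default_factory=list)


def zprime(pos: Sequence[float], neg: Sequence[float]) -> ZPrimeResult:
    """Z' factor between two control groups (sample SDs, ddof=1).

    Symmetric in its arguments; equals 1 exactly in the zero-variance limit
    and is NaN (flagged) when the group means coincide.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 wells per control group")
    mp, mn = float(pos.mean()), float(neg.mean())
    sp = float(pos.std(ddof=1))
    sn = float(neg.std(ddof=1))
    sep = abs(mp - mn)
    flags = []
    if sep == 0:
        value = float("nan")
        flags.append("equal_group_means")
    else:
        value = 1.0 - 3.0 * (sp + sn) / sep
    return ZPrimeResult(value, mp, mn, sp, sn, len(pos), len(neg), flags)


@dataclass
class PlateScores:
    """Per-compound SD-distance scores plus the reference statistics used."""

    scores: pd.DataFrame  # compound_id, well, value_<p> and z_<p> per parameter
    reference: dict[str, dict]  # parameter -> {median, sd, n, source, robust}
    flags: list[str] = field(default_factory=list)


def _reference_sd(values: np.ndarray, robust: bool) -> float:
    if robust:
        med = np.median(values)
        return float(1.4826 * np.median(np.abs(values - med)))
    return float(np.std(values, ddof=1))


def score_plate(
    well_summaries: pd.DataFrame,
    reference_source: str = "all_samples",
    robust_sd: bool = False,
    parameters: Sequence[str] = PARAMETERS,
) -> PlateScores:
    """Score every compound well against the plate's reference distribution.

    ``well_summaries`` needs columns ``well``, ``role``, ``compound_id``, the
    four parameters, and optionally ``qc_flags`` (wells with QC flags are
    excluded from the reference and from scoring). ``reference_source`` is
    ``all_samples`` (median/SD over all compound wells — the default, since a
    mostly-inert library centres on the null) or ``negative_controls``.
    """
    df = well_summaries.copy()
    if "qc_flags" in df.columns:
        flagged = df["qc_flags"].fillna("").astype(str) != ""
    else:
        flagged = pd.Series(False, index=df.index)
    compounds = df[(df["role"] == "compound") & ~flagged]
    if reference_source == "all_samples":
        ref_df = compounds
    elif reference_source == "negative_controls":
        ref_df = df[(df["role"] == "negative_control") & ~flagged]
    else:
        raise ValueError(f"unknown reference_source {reference_source!r}")

    reference: dict[str, dict] = {}
    flags: list[str] = []
    out = compounds[["compound_id", "well"]].reset_index(drop=True).copy()
    for p in parameters:
        vals = ref_df[p].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 3:
            raise ValueError(f"reference set for {p!r} has < 3 defined wells")
        med = float(np.median(vals))
        sd = _reference_sd(vals, robust_sd)
        reference[p] = {"median": med, "sd": sd, "n": int(len(vals)),
                        "source": reference_source, "robust_sd": bool(robust_sd)}
        x = compounds[p].to_numpy(dtype=float)
        out[f"value_{p}"] = x
        if sd == 0:
            out[f"z_{p}"] = np.nan
            flags.append(f"zero_sd:{p}")
        else:
            out[f"z_{p}"] = (x - med) / sd
    return PlateScores(out, reference, flags)


def call_hits(
    scores: PlateScores,
    thresholds: Mapping[str, float] | None = None,
    directions: Mapping[str, str] | None = None,
    parameters: Sequence[str] = PARAMETERS,
) -> pd.DataFrame:
    """Four-parameter hit table.

    Per parameter the pass rule is |z| >= t (``two_sided``), z <= -t
    (``decrease``) or z >= t (``increase``). A compound is a hit iff it passes
    all four parameters. Compounds with any undefined score are excluded
    (``excluded=True``, ``hit=False``), never silently passed. The table also
    records the direction of the total-area change.
    """
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    dr = dict(DEFAULT_DIRECTIONS)
    dr.update(directions or {})
    df = scores.scores
    out = df[["compound_id", "well"]].copy()
    all_pass = np.ones(len(df), dtype=bool)
    excluded = np.zeros(len(df), dtype=bool)
    for p in parameters:
        z = df[f"z_{p}"].to_numpy(dtype=float)
        t = float(th[p])
        if dr[p] == "two_sided":
            ok = np.abs(z) >= t
        elif dr[p] == "decrease":
            ok = z <= -t
        elif dr[p] == "increase":
            ok = z >= t
        else:
            raise ValueError(f"unknown direction {dr[p]!r} for {p}")
        undef = ~np.isfinite(z)
        excluded |= undef
        ok = ok & ~undef
        out[f"pass_{p}"] = ok
        all_pass &= ok
    out["excluded"] = excluded
    out["hit"] = all_pass & ~excluded
    zt = df["z_ld_total_area"].to_numpy(dtype=float)
    out["total_area_direction"] = np.where(
        np.isfinite(zt), np.where(zt < 0, "decrease", "increase"), "")
    return out


@dataclass
class GroupComparison:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    sd_a: float
    sd_b: float
    normality_p_a: float
    normality_p_b: float
    test_used: str  # "t" | "mann-whitney"
    statistic: float
    p_value: float
    flags: list[str] = field(default_factory=list)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha_norm: float = 0.05,
    equal_var: bool = True,
) -> GroupComparison:
    """Normality-gated two-sample comparison.

    Shapiro-Wilk per group; if both p-values are >= ``alpha_norm`` a two-sided
    Student's t-test is used, otherwise a two-sided Mann-Whitney U. Degenerate
    all-tied groups (normality test undefined) fall through to Mann-Whitney
    with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    flags: list[str] = []

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            flags.append("degenerate_group")
            return 0.0  # all-tied: treat as non-normal
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # above n~5000 the Shapiro p is approximate; it only gates the
            # test choice, where that accuracy is ample
            warnings.filterwarnings("ignore", message=".*N > 5000.*")
            return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa >= alpha_norm and pb >= alpha_norm:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        test = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    return GroupComparison(
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        normality_p_a=pa, normality_p_b=pb,
        test_used=test, statistic=float(res.statistic),
        p_value=float(res.pvalue), flags=flags,
    )


def ssmd_replicate(a: Sequence[float], b: Sequence[float]) -> float:
    """Canonical strictly-standardised mean difference for replicated designs:
    (mean_a - mean_b) / sqrt(sd_a^2 + sd_b^2). Provided for plates with
    per-compound replicates; the screen's single-well scoring uses
    :func:`score_plate` instead."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = math.sqrt(a.var(ddof=1) + b.var(ddof=1))
    if denom == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / denom)


def adjust_fdr(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Optional Benjamini-Hochberg layer (off by default in the pipeline —
    the screen's thresholds are plain SD distances)."""
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(np.asarray(p_values, float), alpha=alpha,
                               method="fdr_bh")
    return q
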