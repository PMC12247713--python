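"""Misincorporation-based modification calling.

The core statistic is the per-position misincorporation (MI) frequency: the
fraction of aligned reads whose base call (or deletion) differs from the
reference base.  Modified nucleosides that perturb the Watson-Crick face
(m1A, m2G, m22G, ...) force the reverse transcriptase to misread or skip the
position, so a high MI frequency is evidence of modification.

Background misread rates differ by reference base — G and C run noticeably
hotter than A and U even at unmodified positions — so the null model is
fitted per base: MI frequencies at unannotated positions are summarised by a
beta distribution (method-of-moments), and each observed position is scored
by the upper-tail probability of its MI under that null.  p-values are
Benjamini-Hochberg adjusted within a species, and calls are classified
high/moderate/none with base-specific MI thresholds (>10% for G/C, >5% for
A/U) on top of the significance gate (adjusted p < 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BASES, COUNT_COLUMNS, DELETION

#: MI thresholds for a high-confidence call, by reference base (DNA alphabet).
DEFAULT_MI_THRESHOLDS = {"G": 0.10, "C": 0.10, "A": 0.05, "T": 0.05}

#: Canonical positions excluded from background fitting: the 5' end and the
#: NCCA 3' end are artifact-prone in RT-based protocols.
DEFAULT_EXCLUDE_POSITIONS = ("1", "74", "75", "76")


class CallingError(ValueError):
    """Invalid inputs to the calling statistics."""


@dataclass
class CallingConfig:
    """Tunable settings of the calling stage.

    pvalue_mode
        ``"null-tail"`` (default): p = upper tail of the fitted beta null at
        the observed MI.  ``"posterior-exceedance"``: p = posterior
        probability that the position's latent MI lies below the
        base-specific 75th-percentile threshold, using the null's (alpha,
        beta) as pseudocounts.
    pseudo_source
        ``"background"`` (default) takes pseudocounts from the null fitted on
        unannotated positions; ``"known"`` takes them from the MI moments at
        known modified positions.
    """

    min_coverage: int = 20
    alpha: float = 0.05
    mi_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_MI_THRESHOLDS))
    pvalue_mode: str = "null-tail"
    pseudo_source: str = "background"
    fdr_method: str = "fdr_bh"
    exclude_positions: tuple = DEFAULT_EXCLUDE_POSITIONS
    min_fit_sites: int = 30
    floor_concentration: float = 1000.0


@dataclass
class BetaNull:
    """Per-reference-base null model of background misincorporation."""

    ref_base: str
    alpha: float
    beta: float
    pseudo_mismatch: float
    pseudo_match: float
    threshold_q75: float
    n_fit: int = 0
    fallback: bool = False

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise CallingError(
                f"invalid beta null for {self.ref_base}: alpha={self.alpha}, "
                f"beta={self.beta}")
        if not (0.0 <= self.threshold_q75 <= 1.0):
            raise CallingError(
                f"threshold_q75 out of [0,1]: {self.threshold_q75}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def mi_frequency(counts: Mapping[str, int], ref_base: str) -> float:
    """Misincorporation frequency of one position.

    ``counts`` maps A/C/G/T/- (deletion) to read counts.  Deletions count as
    non-reference calls and contribute to coverage.  Returns NaN (an explicit
    no-coverage marker, never a silent 0) when coverage is zero.
    """
    ref_base = ref_base.upper().replace("U", "T")
    if ref_base not in BASES:
        raise CallingError(f"unknown reference base {ref_base!r}")
    coverage = sum(int(counts.get(k, 0)) for k in (*BASES, DELETION))
    if coverage == 0:
        return math.nan
    return (coverage - int(counts.get(ref_base, 0))) / coverage


def read_identity(counts: Mapping[str, int]) -> dict[str, float]:
    """Composition of base calls at a position (fractions summing to 1)."""
    coverage = sum(int(counts.get(k, 0)) for k in (*BASES, DELETION))
    if coverage == 0:
        return {k: math.nan for k in (*BASES, DELETION)}
    return {k: int(counts.get(k, 0)) / coverage for k in (*BASES, DELETION)}


def _annotated_keys(annotations: pd.DataFrame | None) -> set:
    if annotations is None or len(annotations) == 0:
        return set()
    return set(zip(annotations["species"], annotations["trna"],
                   annotations["position"].astype(str)))


def _with_mi(coverage: pd.DataFrame) -> pd.DataFrame:
    df = coverage.copy()
    counts = df[COUNT_COLUMNS].to_numpy(dtype=float)
    total = counts.sum(axis=1)
    ref_idx = df["ref_base"].map({"A": 0, "C": 1, "G": 2, "T": 3}).to_numpy()
    ref_count = counts[np.arange(len(df)), ref_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = np.where(total > 0, (total - ref_count) / np.maximum(total, 1),
                      np.nan)
        fracs = counts / np.maximum(total[:, None], 1)
    fracs[total == 0] = np.nan
    df["coverage"] = total.astype(int)
    df["mi_frequency"] = mi
    df[["frac_a", "frac_c", "frac_g", "frac_t", "frac_del"]] = fracs
    return df


def _moment_fit(values: np.ndarray, floor_concentration: float,
                label: str) -> tuple[float, float, bool]:
    """Method-of-moments beta fit; falls back to a floor dispersion when the
    sample variance is degenerate (zero, or >= m(1-m))."""
    m = float(np.mean(values))
    v = float(np.var(values, ddof=1)) if len(values) > 1 else 0.0
    m = min(max(m, 1e-6), 1 - 1e-6)
    if v <= 0 or v >= m * (1 - m):
        warnings.warn(
            f"{label}: degenerate MI variance (m={m:.4g}, v={v:.4g}); "
            f"falling back to concentration {floor_concentration}",
            stacklevel=2)
        return m * floor_concentration, (1 - m) * floor_concentration, True
    c = m * (1 - m) / v - 1
    return m * c, (1 - m) * c, False


def fit_background(coverage: pd.DataFrame,
                   known: pd.DataFrame | None = None,
                   config: CallingConfig | None = None) -> dict[str, BetaNull]:
    """Fit one beta null per reference base from unannotated positions.

    MI frequencies are collected at positions not present in ``known``
    (and outside the excluded end positions), a beta distribution is fitted
    by method of moments, pseudocounts are taken from the fit (or, with
    ``pseudo_source="known"``, from the moments at known modified
    positions), and the base-specific detection threshold is set at the 75th
    percentile of the same empirical MI values.
    """
    config = config or CallingConfig()
    df = _with_mi(coverage)
    known_keys = _annotated_keys(known)
    keys = list(zip(df["species"], df["trna"], df["position"].astype(str)))
    is_known = np.array([k in known_keys for k in keys])
    usable = (
        (df["coverage"] >= config.min_coverage)
        & ~df["position"].astype(str).isin(config.exclude_positions)
    )

    nulls: dict[str, BetaNull] = {}
    present = [b for b in BASES if (df["ref_base"] == b).any()]
    for base in present:
        sel = usable & ~is_known & (df["ref_base"] == base)
        mi = df.loc[sel, "mi_frequency"].to_numpy()
        mi = mi[~np.isnan(mi)]
        if len(mi) < config.min_fit_sites:
            raise CallingError(
                f"only {len(mi)} unannotated {base} positions available for "
                f"background fitting (need >= {config.min_fit_sites})")
        a, b, fb = _moment_fit(mi, config.floor_concentration,
                               f"background fit for base {base}")
        pseudo_a, pseudo_b = a, b
        if config.pseudo_source == "known":
            ksel = usable & is_known & (df["ref_base"] == base)
            kmi = df.loc[ksel, "mi_frequency"].to_numpy()
            kmi = kmi[~np.isnan(kmi)]
            if len(kmi) >= 2:
                pseudo_a, pseudo_b, _ = _moment_fit(
                    kmi, config.floor_concentration,
                    f"known-site pseudocounts for base {base}")
        elif config.pseudo_source != "background":
            raise CallingError(
                f"unknown pseudo_source {config.pseudo_source!r}")
        nulls[base] = BetaNull(
            ref_base=base, alpha=a, beta=b,
            pseudo_mismatch=pseudo_a, pseudo_match=pseudo_b,
            threshold_q75=float(np.quantile(mi, 0.75)),
            n_fit=len(mi), fallback=fb,
        )
    return nulls


def position_pvalue(counts: Mapping[str, int], ref_base: str, null: BetaNull,
                    mode: str = "null-tail") -> float:
    """p-value of one position's MI under the base-specific null.

    ``null-tail``: probability of an MI frequency at least as large as the
    observed one under the fitted background beta.  ``posterior-exceedance``:
    probability that the position's latent MI is below the base-specific
    threshold given the observed counts and the null's pseudocounts.  Both
    are monotone: larger MI gives a smaller p.
    """
    mi = mi_frequency(counts, ref_base)
    if math.isnan(mi):
        return math.nan
    if mode == "null-tail":
        return float(stats.beta.sf(mi, null.alpha, null.beta))
    if mode == "posterior-exceedance":
        coverage = sum(int(counts.get(k, 0)) for k in (*BASES, DELETION))
        mismatches = coverage - int(counts.get(
            ref_base.upper().replace("U", "T"), 0))
        matches = coverage - mismatches
        return float(stats.beta.cdf(
            null.threshold_q75,
            mismatches + null.pseudo_mismatch,
            matches + null.pseudo_match))
    raise CallingError(f"unknown p-value mode {mode!r}")


def adjust_pvalues(p_values: Sequence[float],
                   method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg step-up by default).

    Applied within one species across all tested positions; the output is
    element-wise >= the input and bounded by 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise CallingError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def classify_confidence(ref_base: str, mi_frequency: float, p_adjusted: float,
                        thresholds: Mapping[str, float] | None = None,
                        alpha: float = 0.05) -> str:
    """Base-specific confidence class of a tested position.

    high: adjusted p < alpha and MI strictly above the base threshold
    (0.10 for G/C, 0.05 for A/U).  moderate: significant but MI at or below
    the threshold.  none: not significant.  Ties at exactly the threshold
    resolve to moderate.
    """
    thresholds = thresholds or DEFAULT_MI_THRESHOLDS
    base = ref_base.upper().replace("U", "T")
    if base not in thresholds:
        raise CallingError(f"unknown reference base {ref_base!r}")
    if not (p_adjusted < alpha):
        return "none"
    return "high" if mi_frequency > thresholds[base] else "moderate"


def call_modifications(coverage: pd.DataFrame,
                       known: pd.DataFrame | None = None,
                       config: CallingConfig | None = None,
                       nulls: Mapping[str, Mapping[str, BetaNull]] | None = None,
                       ) -> pd.DataFrame:
    """Run the full calling stage on a coverage table.

    Per species: fit the per-base background nulls (on unannotated
    positions), compute MI frequency, identity composition and p-value for
    every covered position, BH-adjust within the species, and classify.
    Positions with coverage below ``min_coverage`` are reported but marked
    ``low-coverage``; zero-coverage positions are marked ``no-coverage``.

    Returns a calls table (one row per coverage row); ``inferred_code`` is
    left empty here and filled by :mod:`trnamod.type_inference`.
    """
    config = config or CallingConfig()
    out = []
    for species, cov_sp in coverage.groupby("species", sort=True):
        sp_nulls = (nulls or {}).get(species) if nulls else None
        if sp_nulls is None:
            known_sp = None
            if known is not None and len(known):
                known_sp = known[known["species"] == species]
            sp_nulls = fit_background(cov_sp, known_sp, config)
        df = _with_mi(cov_sp)
        mi = df["mi_frequency"].to_numpy()
        testable = (df["coverage"] >= config.min_coverage).to_numpy()

        p = np.full(len(df), np.nan)
        for base, null in sp_nulls.items():
            sel = testable & (df["ref_base"] == base).to_numpy()
            if config.pvalue_mode == "null-tail":
                p[sel] = stats.beta.sf(mi[sel], null.alpha, null.beta)
            elif config.pvalue_mode == "posterior-exceedance":
                cov_n = df["coverage"].to_numpy()[sel]
                mism = np.rint(mi[sel] * cov_n)
                p[sel] = stats.beta.cdf(
                    null.threshold_q75,
                    mism + null.pseudo_mismatch,
                    cov_n - mism + null.pseudo_match)
            else:
                raise CallingError(
                    f"unknown p-value mode {config.pvalue_mode!r}")

        p_adj = np.full(len(df), np.nan)
        p_adj[testable] = adjust_pvalues(p[testable], config.fdr_method)

        confidence = []
        for i in range(len(df)):
            if df["coverage"].iloc[i] == 0:
                confidence.append("no-coverage")
            elif not testable[i]:
                confidence.append("low-coverage")
            else:
                confidence.append(classify_confidence(
                    df["ref_base"].iloc[i], mi[i], p_adj[i],
                    config.mi_thresholds, config.alpha))

        res = df[["species", "trna", "position", "ref_base", "coverage",
                  "mi_frequency", "frac_a", "frac_c", "frac_g", "frac_t",
                  "frac_del"]].copy()
        res["p_value"] = p
        res["p_adjusted"] = p_adj
        res["confidence"] = confidence
        res["inferred_code"] = pd.Series([np.nan] * len(res), dtype=object,
                                         index=res.index)
        out.append(res)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["species", "trna", "position", "ref_base", "coverage",
                 "mi_frequency", "frac_a", "frac_c", "frac_g", "frac_t",
                 "frac_del", "p_value", "p_adjusted", "confidence",
                 "inferred_code"])


def confident(calls: pd.DataFrame) -> pd.DataFrame:
    """Subset of calls with high or moderate confidence."""
    return calls[calls["confidence"].isin(["high", "moderate"])]
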