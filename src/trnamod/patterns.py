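"""Coordination and identity-element analyses of called modifications.

Three downstream questions about the modification landscape:

* Do modifications at two canonical positions co-occur within the same tRNA
  or exclude one another (e.g. the acceptor-stem pair 6:67, or the core
  positions 10 and 26)?  Quantified as a 2x2 contingency over eligible
  tRNAs with an odds ratio and a two-sided Fisher exact test.
* How frequent is each modification per position per clade?
* Which stem-pair identities (e.g. the wobble G10oU25 in the D-arm) act as
  determinants — or anti-determinants — of modification at a focal
  position?

A tRNA is eligible for an analysis only when its reference base at the
position(s) under study permits the modification class (a tRNA with C6
simply cannot carry m2G6).  Pair identities are written with ``=`` for
Watson-Crick and ``o`` for non-Watson-Crick (wobble/other) pairs, with U
rendered for T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .numbering import pair_partner

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


class PatternError(ValueError):
    pass


@dataclass
class CooccurrenceResult:
    group: str
    positions: tuple[str, str]
    n_both: int
    n_p_only: int
    n_q_only: int
    n_neither: int
    odds_ratio: float
    p_value: float
    paired_mi: pd.DataFrame   # per-tRNA MI at both positions
    reason: str = ""

    @property
    def n_eligible(self) -> int:
        return self.n_both + self.n_p_only + self.n_q_only + self.n_neither


@dataclass
class IdentityElementResult:
    focal_position: str
    table: pd.DataFrame   # stem_pair/identity/counts/odds_ratio/p_value


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with the Haldane-Anscombe 0.5 correction applied
    when any cell is zero (so the ratio is always finite and nonzero)."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def fisher_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table."""
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative="two-sided")[1])


def _modified_status(calls: pd.DataFrame, position: str,
                     affected_base: str,
                     annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per (species, tRNA): eligibility and modified flag at one position."""
    c = calls[calls["position"].astype(str) == str(position)].copy()
    c = c[c["confidence"].isin(["high", "moderate", "none"])]
    c = c[c["ref_base"] == affected_base]
    c["modified"] = c["confidence"].isin(["high", "moderate"])
    if annotations is not None:
        ann = annotations[annotations["position"].astype(str)
                          == str(position)]
        annotated = set(zip(ann["species"], ann["trna"]))
        keys = list(zip(c["species"], c["trna"]))
        c["modified"] &= np.array([k in annotated for k in keys])
    return c[["species", "trna", "mi_frequency", "modified"]]


def cooccurrence(calls: pd.DataFrame, positions: tuple[str, str],
                 affected_base: str = "G",
                 annotations: pd.DataFrame | None = None,
                 grouping: dict | None = None) -> list[CooccurrenceResult]:
    """Co-occurrence / mutual-exclusivity analysis of two positions.

    Eligible tRNAs carry ``affected_base`` at BOTH positions (with a
    classified call at each).  Per group (species by default, or a coarser
    clade grouping via ``grouping``: species -> group), the 2x2 table of
    modified-at-p x modified-at-q is tabulated, with a Haldane-Anscombe
    corrected odds ratio and a two-sided Fisher exact p-value.  The per-tRNA
    paired MI values are returned for plotting.

    With ``annotations`` (known plus predicted records), "modified" means a
    confident call AT an annotated site; without it, any high/moderate call
    counts.  The former matches how modification sets are interpreted in
    practice and is robust to isolated background false positives.
    """
    p, q = str(positions[0]), str(positions[1])
    at_p = _modified_status(calls, p, affected_base, annotations)
    at_q = _modified_status(calls, q, affected_base, annotations)
    merged = at_p.merge(at_q, on=["species", "trna"],
                        suffixes=("_p", "_q"))
    if grouping:
        merged["group"] = merged["species"].map(grouping)
    else:
        merged["group"] = merged["species"]

    results = []
    for group in sorted(pd.unique(merged["group"].dropna())):
        sub = merged[merged["group"] == group]
        if len(sub) == 0:
            results.append(CooccurrenceResult(
                group=group, positions=(p, q), n_both=0, n_p_only=0,
                n_q_only=0, n_neither=0, odds_ratio=float("nan"),
                p_value=float("nan"), paired_mi=sub,
                reason="no eligible tRNAs"))
            continue
        both = int((sub["modified_p"] & sub["modified_q"]).sum())
        p_only = int((sub["modified_p"] & ~sub["modified_q"]).sum())
        q_only = int((~sub["modified_p"] & sub["modified_q"]).sum())
        neither = int((~sub["modified_p"] & ~sub["modified_q"]).sum())
        results.append(CooccurrenceResult(
            group=group, positions=(p, q),
            n_both=both, n_p_only=p_only, n_q_only=q_only,
            n_neither=neither,
            odds_ratio=odds_ratio_2x2(both, p_only, q_only, neither),
            p_value=fisher_pvalue(both, p_only, q_only, neither),
            paired_mi=sub[["species", "trna", "mi_frequency_p",
                           "mi_frequency_q", "modified_p",
                           "modified_q"]].reset_index(drop=True)))
    if not results:
        results.append(CooccurrenceResult(
            group="all", positions=(p, q), n_both=0, n_p_only=0,
            n_q_only=0, n_neither=0, odds_ratio=float("nan"),
            p_value=float("nan"), paired_mi=merged,
            reason="no eligible tRNAs"))
    return results


def cooccurrence_to_frame(results: list[CooccurrenceResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": r.group, "position_p": r.positions[0],
        "position_q": r.positions[1], "n_both": r.n_both,
        "n_p_only": r.n_p_only, "n_q_only": r.n_q_only,
        "n_neither": r.n_neither, "n_eligible": r.n_eligible,
        "odds_ratio": r.odds_ratio, "p_value": r.p_value,
        "reason": r.reason,
    } for r in results])


def modification_frequency_summary(calls: pd.DataFrame,
                                   grouping: dict | None = None,
                                   ) -> pd.DataFrame:
    """Counts and fractions of modified tRNAs per (group, position, base).

    Eligible = classified call (high/moderate/none) with that reference
    base; modified = high or moderate.  Cells with zero eligible tRNAs get a
    NaN fraction.  Output is deterministically ordered.
    """
    c = calls[calls["confidence"].isin(["high", "moderate", "none"])].copy()
    c["group"] = c["species"].map(grouping) if grouping else c["species"]
    c["position"] = c["position"].astype(str)
    c["modified"] = c["confidence"].isin(["high", "moderate"])
    rows = []
    for (group, position, base), sub in c.groupby(
            ["group", "position", "ref_base"], sort=True):
        n_mod = int(sub["modified"].sum())
        n_elig = len(sub)
        rows.append({
            "group": group, "position": position, "ref_base": base,
            "n_modified": n_mod, "n_eligible": n_elig,
            "fraction": n_mod / n_elig if n_elig else float("nan"),
        })
    out = pd.DataFrame(rows, columns=["group", "position", "ref_base",
                                      "n_modified", "n_eligible", "fraction"])
    return out.sort_values(["group", "position", "ref_base"],
                           kind="mergesort").reset_index(drop=True)


def pair_identity(base_x: str, base_y: str) -> str:
    """Render a stem pair identity, e.g. ``G=C`` (Watson-Crick) or ``GoU``."""
    sym = "=" if (base_x, base_y) in WC_PAIRS else "o"
    show = lambda b: b.replace("T", "U")
    return f"{show(base_x)}{sym}{show(base_y)}"


def identity_element_enrichment(calls: pd.DataFrame, focal_position: str,
                                stem_pairs: list[tuple[str, str]] | None = None,
                                affected_base: str = "G",
                                ) -> IdentityElementResult:
    """Base-pair determinants of modification at a focal position.

    For each stem pair (x, y), every eligible tRNA (one carrying
    ``affected_base`` at the focal position, with a classified call) is
    assigned its pair identity (e.g. ``GoU``, ``G=C``); each identity class
    is tested against the rest for association with modified status at the
    focal position (Haldane-Anscombe odds ratio, two-sided Fisher exact p).
    An odds ratio below 1 marks an anti-determinant: the identity is
    enriched among UNmodified tRNAs.
    """
    focal = str(focal_position)
    if stem_pairs is None:
        partner = pair_partner(focal)
        if partner is None:
            raise PatternError(
                f"focal position {focal} is unpaired; supply stem_pairs")
        stem_pairs = [(focal, partner)]

    c = calls.copy()
    c["position"] = c["position"].astype(str)
    if focal not in set(c["position"]):
        raise PatternError(f"focal position {focal} absent from calls")
    status = _modified_status(c, focal, affected_base)

    base_at = c.set_index(["species", "trna", "position"])["ref_base"]
    rows = []
    for x, y in stem_pairs:
        x, y = str(x), str(y)
        per_trna = []
        for _, rec in status.iterrows():
            try:
                bx = base_at.loc[(rec["species"], rec["trna"], x)]
                by = base_at.loc[(rec["species"], rec["trna"], y)]
            except KeyError:
                continue
            per_trna.append((pair_identity(bx, by), bool(rec["modified"])))
        if not per_trna:
            continue
        df = pd.DataFrame(per_trna, columns=["identity", "modified"])
        for ident in sorted(df["identity"].unique()):
            in_class = df["identity"] == ident
            a = int((in_class & df["modified"]).sum())
            b = int((in_class & ~df["modified"]).sum())
            cc = int((~in_class & df["modified"]).sum())
            d = int((~in_class & ~df["modified"]).sum())
            rows.append({
                "stem_pair": f"{x}:{y}", "identity": ident,
                "n_modified": a, "n_unmodified": b,
                "n_other_modified": cc, "n_other_unmodified": d,
                "odds_ratio": odds_ratio_2x2(a, b, cc, d),
                "p_value": fisher_pvalue(a, b, cc, d),
            })
    table = pd.DataFrame(rows, columns=[
        "stem_pair", "identity", "n_modified", "n_unmodified",
        "n_other_modified", "n_other_unmodified", "odds_ratio", "p_value"])
    return IdentityElementResult(focal_position=focal, table=table)
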