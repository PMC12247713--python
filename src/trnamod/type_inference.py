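"""Assigning a most-likely modification type to confident calls.

Different modifications of the same base at the same canonical position
leave different footprints: N2,N2-dimethylguanosine (m22G) drives much
higher misincorporation than its monomethyl form m2G, and the
ribose-methylated m22Gm additionally leaves a deletion-rich read pattern.
This module summarises those footprints at annotated sites into per-type
profiles (median MI, interquartile range, mean read-identity composition)
and uses them — together with annotations from related species — to label
new calls.  Where the candidate profiles overlap too much to separate, the
call receives the ambiguity code ``xN`` for its reference base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Vocabulary, load_vocabulary

FRAC_COLUMNS = ["frac_a", "frac_c", "frac_g", "frac_t", "frac_del"]

#: IQR floor used when scaling MI distance, so single-valued profiles do not
#: produce infinite scores.
IQR_FLOOR = 0.05


class TypeInferenceError(ValueError):
    pass


@dataclass
class TypeProfile:
    """Empirical MI footprint of one modification code at one position."""

    code: str
    ref_base: str
    position: str
    median_mi: float
    iqr_mi: float
    mean_composition: dict
    deletion_enriched: bool
    n: int
    low_support: bool


def build_type_profiles(calls: pd.DataFrame, annotations: pd.DataFrame,
                        vocab: Vocabulary | None = None,
                        min_support: int = 3,
                        deletion_threshold: float = 0.1,
                        ) -> dict[tuple[str, str], TypeProfile]:
    """One profile per (modification code, canonical position).

    Joins known annotations with the corresponding calls and summarises the
    MI distribution and mean read-identity composition per type.  Profiles
    with fewer than ``min_support`` instances are flagged low-support.
    Deterministic given identical inputs.
    """
    vocab = vocab or load_vocabulary()
    ann = annotations.copy()
    ann["position"] = ann["position"].astype(str)
    c = calls.copy()
    c["position"] = c["position"].astype(str)
    joined = ann.merge(c, on=["species", "trna", "position"], how="inner",
                       suffixes=("_ann", ""))
    joined = joined[~joined["mi_frequency"].isna()]
    if len(joined) == 0:
        raise TypeInferenceError(
            "no annotated sites overlap the calls table; cannot build "
            "type profiles")

    profiles: dict[tuple[str, str], TypeProfile] = {}
    for (code, position), grp in sorted(
            joined.groupby(["code", "position"], sort=True),
            key=lambda kv: kv[0]):
        bases = grp["ref_base"].mode()
        ref_base = bases.iloc[0]
        if code in vocab and vocab.affected_base[code] != ref_base:
            # annotation/base disagreement: trust the vocabulary
            grp = grp[grp["ref_base"] == vocab.affected_base[code]]
            if len(grp) == 0:
                continue
            ref_base = vocab.affected_base[code]
        mi = grp["mi_frequency"].to_numpy()
        comp = {col: float(np.nanmean(grp[col])) for col in FRAC_COLUMNS}
        profiles[(code, position)] = TypeProfile(
            code=code, ref_base=ref_base, position=position,
            median_mi=float(np.median(mi)),
            iqr_mi=float(np.quantile(mi, 0.75) - np.quantile(mi, 0.25)),
            mean_composition=comp,
            deletion_enriched=comp["frac_del"] > deletion_threshold,
            n=len(grp), low_support=len(grp) < min_support,
        )
    return profiles


def _tv_distance(comp_a: dict, comp_b: dict) -> float:
    return 0.5 * sum(abs(comp_a.get(k, 0.0) - comp_b.get(k, 0.0))
                     for k in FRAC_COLUMNS)


def _ambiguity_code(ref_base: str) -> str:
    return "x" + ref_base.replace("T", "U")


def score_against_profile(mi: float, composition: dict,
                          profile: TypeProfile,
                          w_mi: float = 0.5, w_comp: float = 0.5) -> float:
    """Distance of a call to a type profile: IQR-scaled MI offset plus
    total-variation distance between read-identity compositions, weighted
    equally by default."""
    d_mi = abs(mi - profile.median_mi) / max(profile.iqr_mi, IQR_FLOOR)
    d_comp = _tv_distance(composition, profile.mean_composition)
    return w_mi * d_mi + w_comp * d_comp


def assign_type(call, profiles: dict, related_annotations: pd.DataFrame,
                vocab: Vocabulary | None = None,
                separation: float = 0.5,
                deletion_threshold: float = 0.1,
                w_mi: float = 0.5, w_comp: float = 0.5) -> str:
    """Most-likely modification code for one confident call.

    Candidate codes are those annotated at the same canonical position on
    the same reference base in related species.  A single candidate is
    assigned directly.  Multiple candidates are scored against their
    profiles; the best wins only if its margin over the runner-up exceeds
    ``separation``, otherwise the ambiguity code ``xN`` is returned.
    Deletion-enriched profiles are only assignable when the call itself
    shows a deletion fraction above ``deletion_threshold``.
    """
    vocab = vocab or load_vocabulary()
    ref_base = str(call["ref_base"]).upper().replace("U", "T")
    position = str(call["position"])
    mi = float(call["mi_frequency"])
    composition = {col: float(call[col]) for col in FRAC_COLUMNS}

    ra = related_annotations
    if len(ra):
        ra = ra[ra["position"].astype(str) == position]
        candidates = sorted({
            code for code in ra["code"]
            if vocab.affected_base.get(code, ref_base) == ref_base
            and not (code.startswith("x") and len(code) == 2)})
    else:
        candidates = []

    if not candidates:
        return _ambiguity_code(ref_base)
    if len(candidates) == 1:
        return candidates[0]

    scored = []
    for code in candidates:
        profile = profiles.get((code, position)) or profiles.get((code, "any"))
        if profile is None:
            continue
        if profile.deletion_enriched and \
                composition["frac_del"] <= deletion_threshold:
            continue
        scored.append((score_against_profile(mi, composition, profile,
                                             w_mi, w_comp), code))
    if not scored:
        return _ambiguity_code(ref_base)
    scored.sort()
    if len(scored) == 1:
        return scored[0][1]
    best, runner = scored[0], scored[1]
    if runner[0] - best[0] > separation:
        return best[1]
    return _ambiguity_code(ref_base)


def assign_types(calls: pd.DataFrame, profiles: dict,
                 annotations: pd.DataFrame, clade_map: dict,
                 vocab: Vocabulary | None = None,
                 separation: float = 0.5,
                 deletion_threshold: float = 0.1) -> pd.DataFrame:
    """Fill ``inferred_code`` for all high/moderate calls.

    Related species for each call are the other members of its clade per
    ``clade_map`` (species -> clade); their known annotations provide the
    candidate codes.
    """
    vocab = vocab or load_vocabulary()
    out = calls.copy()
    out["inferred_code"] = out["inferred_code"].astype(object)
    ann = annotations.copy()
    ann["position"] = ann["position"].astype(str)
    for idx, call in out.iterrows():
        if call["confidence"] not in ("high", "moderate"):
            continue
        clade = clade_map.get(call["species"])
        related = ann[(ann["species"] != call["species"])
                      & (ann["species"].map(clade_map) == clade)]
        out.at[idx, "inferred_code"] = assign_type(
            call, profiles, related, vocab,
            separation=separation, deletion_threshold=deletion_threshold)
    return out


def profiles_to_frame(profiles: dict) -> pd.DataFrame:
    """Serializable table of type profiles (TSV-friendly)."""
    rows = []
    for (code, position), p in sorted(profiles.items()):
        row = {
            "code": code, "position": position, "ref_base": p.ref_base,
            "median_mi": p.median_mi, "iqr_mi": p.iqr_mi,
            "deletion_enriched": int(p.deletion_enriched),
            "n": p.n, "low_support": int(p.low_support),
        }
        row.update({f"mean_{k}": v for k, v in p.mean_composition.items()})
        rows.append(row)
    return pd.DataFrame(rows)
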