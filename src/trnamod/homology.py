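"""Cross-species transfer of modification annotations and concordance.

Known modification sites from a characterised species are mapped onto
orthologous tRNAs of a related, unannotated species.  Orthology is taken as
identity of (isotype, anticodon) — the naming scheme tRNA biologists use —
with duplicate isodecoders resolved by global sequence identity.  A source
annotation propagates only where the target tRNA conserves the reference
base and shows a confident misincorporation signal of its own.

Concordance between the species is quantified as the Pearson correlation of
(known MI, predicted MI) pairs across transferred sites; residuals are taken
about the identity line (perfect correlation), and sites farther than two
residual standard deviations from it are flagged as outliers — the
interesting cases, where the modification state or stoichiometry diverges
between species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Vocabulary, load_vocabulary


class HomologyError(ValueError):
    pass


@dataclass(frozen=True)
class OrthologPair:
    source_species: str
    source_trna: str
    target_species: str
    target_trna: str
    rule: str = "isotype+anticodon"
    identity: float = float("nan")


@dataclass
class HomologyComparison:
    """Paired known/predicted MI values for one species pair."""

    source_species: str
    target_species: str
    sites: pd.DataFrame          # trna/position/code/known_mi/predicted_mi/...
    pearson_r: float
    residual_sd: float
    insufficient: bool = False

    @property
    def outliers(self) -> pd.DataFrame:
        return self.sites[self.sites["outlier"]]


def parse_trna_id(trna: str) -> tuple[str, str]:
    """(isotype, anticodon) from ids like ``Ala-AGC-1`` or ``iMet-CAU``."""
    parts = trna.split("-")
    if len(parts) < 2:
        raise HomologyError(f"cannot parse tRNA id {trna!r}; expected "
                            "isotype-anticodon[-copy]")
    return parts[0], parts[1].upper().replace("U", "T")


def sequence_identity(a: str, b: str) -> float:
    """Global identity of two canonical-grid sequences.

    Equal-length sequences (the common case on a shared numbering template)
    are compared column-wise; otherwise a global alignment is used.
    """
    if len(a) == len(b):
        if len(a) == 0:
            return 0.0
        return sum(x == y for x, y in zip(a, b)) / len(a)
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    matches = sum(x == y for x, y in zip(str(aln[0]), str(aln[1])))
    return matches / max(len(a), len(b))


def match_orthologs(source_seqs: dict, target_seqs: dict,
                    source_species: str = "source",
                    target_species: str = "target",
                    ) -> tuple[list[OrthologPair], list[str], list[str]]:
    """One-to-one ortholog pairing by (isotype, anticodon).

    Duplicate isodecoders on either side are resolved greedily by highest
    global sequence identity.  Returns (pairs, unmatched source ids,
    unmatched target ids).
    """
    if not source_seqs or not target_seqs:
        import warnings
        warnings.warn("empty tRNA set supplied to match_orthologs",
                      stacklevel=2)
        return [], sorted(source_seqs), sorted(target_seqs)

    def by_key(seqs):
        groups: dict[tuple[str, str], list[str]] = {}
        for trna in sorted(seqs):
            groups.setdefault(parse_trna_id(trna), []).append(trna)
        return groups

    src_groups, tgt_groups = by_key(source_seqs), by_key(target_seqs)
    pairs: list[OrthologPair] = []
    matched_src: set[str] = set()
    matched_tgt: set[str] = set()
    for key in sorted(set(src_groups) & set(tgt_groups)):
        srcs, tgts = src_groups[key], list(tgt_groups[key])
        # greedy best-identity assignment; deterministic through sorting
        scored = sorted(
            ((-sequence_identity(source_seqs[s], target_seqs[t]), s, t)
             for s in srcs for t in tgts))
        used_s: set[str] = set()
        used_t: set[str] = set()
        for neg_ident, s, t in scored:
            if s in used_s or t in used_t:
                continue
            used_s.add(s)
            used_t.add(t)
            pairs.append(OrthologPair(
                source_species=source_species, source_trna=s,
                target_species=target_species, target_trna=t,
                identity=-neg_ident))
        matched_src.update(used_s)
        matched_tgt.update(used_t)
    unmatched_src = sorted(set(source_seqs) - matched_src)
    unmatched_tgt = sorted(set(target_seqs) - matched_tgt)
    return pairs, unmatched_src, unmatched_tgt


def transfer_annotations(pairs: list[OrthologPair],
                         source_annotations: pd.DataFrame,
                         target_calls: pd.DataFrame,
                         vocab: Vocabulary | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Propagate source annotations to ortholog targets.

    A record transfers iff (a) the target reference base at that canonical
    position matches the modification's affected base, and (b) the target's
    own call there is high- or moderate-confidence.  Returns
    (predicted annotation table with provenance columns, table of
    non-propagating sites with the failed criterion).
    """
    vocab = vocab or load_vocabulary()
    call_ix = {}
    if len(target_calls):
        tc = target_calls.copy()
        tc["position"] = tc["position"].astype(str)
        call_ix = {(r["species"], r["trna"], r["position"]): r
                   for _, r in tc.iterrows()}

    predicted, rejected = [], []
    ann = source_annotations.copy()
    ann["position"] = ann["position"].astype(str)
    for pair in pairs:
        src = ann[(ann["species"] == pair.source_species)
                  & (ann["trna"] == pair.source_trna)]
        for _, rec in src.iterrows():
            key = (pair.target_species, pair.target_trna, rec["position"])
            call = call_ix.get(key)
            base = vocab.affected_base.get(rec["code"])
            common = {
                "species": pair.target_species, "trna": pair.target_trna,
                "position": rec["position"], "code": rec["code"],
                "source_species": pair.source_species,
                "source_trna": pair.source_trna,
            }
            if call is None:
                rejected.append({**common, "reason": "no-call"})
            elif base is not None and call["ref_base"] != base:
                rejected.append({**common, "reason": "base-mismatch"})
            elif call["confidence"] not in ("high", "moderate"):
                rejected.append({**common, "reason": "no-signal"})
            else:
                predicted.append({
                    **common, "source": "predicted",
                    "confidence": call["confidence"],
                })
    pred_cols = ["species", "trna", "position", "code", "source",
                 "confidence", "source_species", "source_trna"]
    rej_cols = ["species", "trna", "position", "code", "source_species",
                "source_trna", "reason"]
    return (pd.DataFrame(predicted, columns=pred_cols),
            pd.DataFrame(rejected, columns=rej_cols))


def comparison_from_pairs(sites: pd.DataFrame, source_species: str,
                          target_species: str,
                          min_sites: int = 3) -> HomologyComparison:
    """Concordance statistics from matched (known_mi, predicted_mi) pairs.

    Residuals are predicted - known (about the identity line); outliers have
    |residual| > 2 x sample SD of the residuals.  Fewer than ``min_sites``
    pairs marks the comparison insufficient.
    """
    sites = sites.copy().reset_index(drop=True)
    sites["residual"] = sites["predicted_mi"] - sites["known_mi"]
    n = len(sites)
    if n < min_sites:
        sites["outlier"] = False
        return HomologyComparison(source_species, target_species, sites,
                                  pearson_r=float("nan"),
                                  residual_sd=float("nan"),
                                  insufficient=True)
    known = sites["known_mi"].to_numpy()
    pred = sites["predicted_mi"].to_numpy()
    if np.std(known) == 0 or np.std(pred) == 0:
        r = 1.0 if np.allclose(known, pred) else float("nan")
    else:
        r = float(stats.pearsonr(known, pred)[0])
    res = sites["residual"].to_numpy()
    sd = float(np.std(res, ddof=1))
    # deviation from the mean residual, so a common offset (all residuals
    # equal) never produces outliers
    if sd > 1e-12:
        sites["outlier"] = np.abs(res - res.mean()) > 2 * sd
    else:
        sites["outlier"] = False
    return HomologyComparison(source_species, target_species, sites,
                              pearson_r=r, residual_sd=sd)


def compare_species(source_calls: pd.DataFrame,
                    predicted: pd.DataFrame,
                    target_calls: pd.DataFrame,
                    min_sites: int = 3) -> HomologyComparison:
    """Known-vs-predicted MI concordance for one species pair.

    ``predicted`` is the output of :func:`transfer_annotations` (it carries
    the source tRNA provenance used to look up the known MI).  Read-identity
    compositions of both sides are attached per site so outliers can be
    inspected.
    """
    if len(predicted) == 0:
        return comparison_from_pairs(
            pd.DataFrame(columns=["trna", "position", "code", "known_mi",
                                  "predicted_mi"]),
            source_species="?", target_species="?", min_sites=min_sites)
    source_species = predicted["source_species"].iloc[0]
    target_species = predicted["species"].iloc[0]

    def index_calls(calls):
        c = calls.copy()
        c["position"] = c["position"].astype(str)
        return {(r["trna"], r["position"]): r for _, r in c.iterrows()}

    src_ix = index_calls(source_calls)
    tgt_ix = index_calls(target_calls)
    frac_cols = ["frac_a", "frac_c", "frac_g", "frac_t", "frac_del"]
    rows = []
    for _, rec in predicted.iterrows():
        src = src_ix.get((rec["source_trna"], str(rec["position"])))
        tgt = tgt_ix.get((rec["trna"], str(rec["position"])))
        if src is None or tgt is None:
            continue
        row = {
            "trna": rec["trna"], "position": rec["position"],
            "code": rec["code"],
            "known_mi": float(src["mi_frequency"]),
            "predicted_mi": float(tgt["mi_frequency"]),
        }
        row.update({f"known_{c}": float(src[c]) for c in frac_cols})
        row.update({f"predicted_{c}": float(tgt[c]) for c in frac_cols})
        rows.append(row)
    sites = pd.DataFrame(rows)
    return comparison_from_pairs(sites, source_species, target_species,
                                 min_sites=min_sites)


def comparison_report(comparisons: list[HomologyComparison]) -> pd.DataFrame:
    """Flat per-site report across species pairs (TSV-friendly)."""
    frames = []
    for comp in comparisons:
        df = comp.sites.copy()
        df.insert(0, "source_species", comp.source_species)
        df.insert(1, "target_species", comp.target_species)
        df["pearson_r"] = comp.pearson_r
        df["residual_sd"] = comp.residual_sd
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
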