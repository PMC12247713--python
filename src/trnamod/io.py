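"""Readers and writers for the tables the pipeline consumes and produces.

Everything on disk is tab-delimited UTF-8 text with ``#`` comment lines, so
results diff cleanly and round-trip losslessly.  RNA sequences are stored in
the DNA alphabet internally (T for U, matching upstream aligners) and
rendered with U only in human-facing reports.

Tables
------
coverage    per (species, tRNA, canonical position): counts of A/C/G/T calls
            and deletions observed in aligned reads.
calls       per-position modification calls (see :mod:`trnamod.calling`).
annotations known or predicted modification records with Modomics-style
            short codes validated against a packaged controlled vocabulary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .numbering import NumberingTemplate, position_sort_key

BASES = ("A", "C", "G", "T")
DELETION = "-"

COVERAGE_COLUMNS = [
    "species", "trna", "position", "ref_base",
    "count_a", "count_c", "count_g", "count_t", "count_del",
]
COUNT_COLUMNS = ["count_a", "count_c", "count_g", "count_t", "count_del"]

CALL_COLUMNS = [
    "species", "trna", "position", "ref_base", "coverage",
    "mi_frequency", "frac_a", "frac_c", "frac_g", "frac_t", "frac_del",
    "p_value", "p_adjusted", "confidence", "inferred_code",
]

ANNOTATION_COLUMNS = ["species", "trna", "position", "code", "source"]

# Columns of the tRAX per-position coverage output mapped onto the native
# schema.  Best effort: tRAX variants differ slightly, so the mapping is
# overridable via `column_map`.
TRAX_COLUMN_MAP = {
    "Feature": "trna",
    "Sample": "species",
    "position": "position",
    "actualbase": "ref_base",
    "adenines": "count_a",
    "cytosines": "count_c",
    "guanines": "count_g",
    "thymines": "count_t",
    "deletions": "count_del",
}


class FormatError(ValueError):
    """Malformed or invariant-violating input table."""


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False)


def read_coverage(path: str | Path, dialect: str = "native",
                  column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a per-position base-call count table.

    ``dialect`` is ``"native"`` (long-format TSV with the columns in
    :data:`COVERAGE_COLUMNS`) or ``"trax"`` (the tRAX coverage output, mapped
    through :data:`TRAX_COLUMN_MAP` or a user-supplied ``column_map``).
    """
    df = _read_tsv(path)
    if dialect == "trax":
        cmap = dict(TRAX_COLUMN_MAP)
        if column_map:
            cmap.update(column_map)
        missing = [src for src in cmap if src not in df.columns]
        if missing:
            raise FormatError(
                f"{path}: tRAX dialect missing column(s) {missing}")
        df = df.rename(columns=cmap)[list(cmap.values())]
    elif dialect != "native":
        raise FormatError(f"unknown coverage dialect {dialect!r}")

    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[COVERAGE_COLUMNS].copy()

    for col in COUNT_COLUMNS:
        try:
            df[col] = df[col].astype(int)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer value in {col}: {exc}")
        bad = df.index[df[col] < 0]
        if len(bad):
            # +2: one for the header line, one for 0- vs 1-based
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise FormatError(
                f"{path}: negative count in column {col} at line(s) {lines}")

    df["ref_base"] = df["ref_base"].str.upper().str.replace("U", "T")
    bad = df.index[~df["ref_base"].isin(BASES)]
    if len(bad):
        raise FormatError(
            f"{path}: invalid reference base at line(s) "
            + ", ".join(str(i + 2) for i in bad[:5]))

    dup = df.duplicated(subset=["species", "trna", "position"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["species", "trna", "position"]].drop_duplicates()
        shown = "; ".join("/".join(r) for r in keys.itertuples(index=False))
        raise FormatError(f"{path}: duplicated (species, tRNA, position) "
                          f"key(s): {shown}")
    return df.reset_index(drop=True)


def write_coverage(df: pd.DataFrame, path: str | Path,
                   header_comment: str | None = None) -> None:
    _write_tsv(df[COVERAGE_COLUMNS], path, header_comment)


def _write_tsv(df: pd.DataFrame, path: str | Path,
               header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n",
                  float_format="%.10g")


def sort_calls(calls: pd.DataFrame,
               template: NumberingTemplate | None = None) -> pd.DataFrame:
    key = calls["position"].map(lambda p: position_sort_key(p, template))
    return (calls.assign(_k=key)
            .sort_values(["species", "trna", "_k"], kind="mergesort")
            .drop(columns="_k")
            .reset_index(drop=True))


def write_calls(calls: pd.DataFrame, path: str | Path,
                template: NumberingTemplate | None = None,
                header_comment: str | None = None) -> None:
    """Write a calls table with deterministic column and row order.

    Rows sort by (species, tRNA, canonical position order); two writes of the
    same records are byte-identical.
    """
    df = calls.copy()
    for col in CALL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = sort_calls(df[CALL_COLUMNS], template)
    _write_tsv(df, path, header_comment)


def read_calls(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[CALL_COLUMNS].copy()
    df["coverage"] = df["coverage"].replace("", "0").astype(float).astype(int)
    float_cols = ["mi_frequency", "frac_a", "frac_c", "frac_g", "frac_t",
                  "frac_del", "p_value", "p_adjusted"]
    for col in float_cols:
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
    df["inferred_code"] = df["inferred_code"].mask(
        df["inferred_code"] == "", np.nan)
    return df


@dataclass(frozen=True)
class Vocabulary:
    """Controlled vocabulary of modification short codes."""

    affected_base: dict  # code -> base (DNA alphabet)
    wc_face: dict        # code -> bool
    chemical_name: dict  # code -> str

    def __contains__(self, code: str) -> bool:
        return code in self.affected_base

    @property
    def codes(self) -> list[str]:
        return sorted(self.affected_base)


_VOCAB: Vocabulary | None = None


def load_vocabulary(path: str | Path | None = None) -> Vocabulary:
    global _VOCAB
    if path is None and _VOCAB is not None:
        return _VOCAB
    if path is None:
        ref = resources.files("trnamod.data") / "modification_codes.tsv"
        with resources.as_file(ref) as p:
            vocab = _load_vocab_file(p)
        _VOCAB = vocab
        return vocab
    return _load_vocab_file(path)


def _load_vocab_file(path: str | Path) -> Vocabulary:
    df = _read_tsv(path)
    for col in ("code", "chemical_name", "affected_base", "wc_face"):
        if col not in df.columns:
            raise FormatError(f"{path}: vocabulary missing column {col!r}")
    affected = {}
    for _, row in df.iterrows():
        base = row["affected_base"].upper().replace("U", "T")
        if base not in BASES:
            raise FormatError(
                f"{path}: bad affected_base {row['affected_base']!r} "
                f"for code {row['code']!r}")
        affected[row["code"]] = base
    return Vocabulary(
        affected_base=affected,
        wc_face={r["code"]: bool(int(r["wc_face"])) for _, r in df.iterrows()},
        chemical_name={r["code"]: r["chemical_name"]
                       for _, r in df.iterrows()},
    )


def read_annotations(path: str | Path,
                     vocab: Vocabulary | None = None) -> pd.DataFrame:
    """Read a known/predicted modification annotation table.

    Codes are validated against the controlled vocabulary; unknown codes are
    preserved verbatim with a warning (the vocabulary is permissive, not a
    gate).  ``xN`` ambiguity codes are allowed only for the four nucleosides.
    """
    vocab = vocab or load_vocabulary()
    df = _read_tsv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns
               and c != "source"]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if "source" not in df.columns:
        df["source"] = "known"
    if "confidence" not in df.columns:
        df["confidence"] = "none"
    df = df[ANNOTATION_COLUMNS + ["confidence"]].copy()

    unknown = sorted(set(df["code"]) - set(vocab.codes))
    for code in unknown:
        if code.startswith("x") and len(code) == 2:
            if code[1].upper() not in ("A", "C", "G", "U"):
                raise FormatError(
                    f"{path}: ambiguity code {code!r} not of the form xN "
                    "with N in A/C/G/U")
        warnings.warn(f"{path}: unknown modification code {code!r} kept "
                      "verbatim", stacklevel=2)
    bad_source = set(df["source"]) - {"known", "predicted"}
    if bad_source:
        raise FormatError(f"{path}: invalid source value(s) {sorted(bad_source)}")
    return df.reset_index(drop=True)


def write_annotations(df: pd.DataFrame, path: str | Path,
                      header_comment: str | None = None) -> None:
    cols = [c for c in ANNOTATION_COLUMNS + ["confidence"] if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    out = df[cols + extra].sort_values(
        ["species", "trna", "position", "code"], kind="mergesort")
    _write_tsv(out.reset_index(drop=True), path, header_comment)


def read_fasta(path: str | Path) -> dict[str, str]:
    """tRNA sequences as a dict id -> DNA-alphabet uppercase string."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in seqs.items()]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def coverage_counts(row: Mapping) -> dict[str, int]:
    """Per-base + deletion counts of one coverage row, keyed A/C/G/T/-."""
    return {
        "A": int(row["count_a"]), "C": int(row["count_c"]),
        "G": int(row["count_g"]), "T": int(row["count_t"]),
        DELETION: int(row["count_del"]),
    }
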