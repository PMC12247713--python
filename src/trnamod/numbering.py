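"""Canonical tRNA coordinate system and the cloverleaf base-pair table.

Mature tRNAs are compared across genes and species on a shared coordinate
grid (positions 1-76 in the community convention, with alphabetic insertion
suffixes such as ``17a`` for expanded D-loops).  Every downstream analysis in
this package — modification calling, homology transfer, identity-element
enrichment — indexes residues by these canonical labels rather than by raw
sequence offsets.

The standard 76-column template ships as an editable TSV
(``data/standard_template.tsv``); archaeal tRNAs with unusual D- or variable
loops can be handled with a user-supplied template.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

GAP_CHARS = "-."
_IUPAC = set("ACGTUNRYSWKMBDHV")


class NumberingError(ValueError):
    """Raised when a sequence cannot be reconciled with a numbering template."""


@dataclass(frozen=True)
class CanonicalPosition:
    """One labelled column of the canonical coordinate grid.

    ``order_index`` ranks positions 5'->3'; insertion positions share the
    integer rank of the preceding canonical column and are disambiguated by
    their alphabetic suffix.
    """

    label: str
    order_index: int
    region: str = ""
    is_insertion: bool = False

    def sort_key(self) -> tuple[int, str]:
        suffix = self.label[len(str(self.order_index)):]
        return (self.order_index, suffix)


class NumberingTemplate:
    """Ordered set of canonical positions, one per alignment column."""

    def __init__(self, positions: Iterable[CanonicalPosition]):
        self.positions = list(positions)
        labels = [p.label for p in self.positions]
        if len(set(labels)) != len(labels):
            raise NumberingError("duplicate canonical labels in template")
        orders = [p.order_index for p in self.positions]
        if any(b <= a for a, b in zip(orders, orders[1:])):
            raise NumberingError("order_index must strictly increase 5'->3'")
        self._by_label = {p.label: p for p in self.positions}

    @property
    def n_columns(self) -> int:
        return len(self.positions)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.positions]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def position(self, label: str) -> CanonicalPosition:
        try:
            return self._by_label[label]
        except KeyError:
            raise NumberingError(f"unknown canonical label {label!r}") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NumberingTemplate":
        positions = []
        with open(path) as fh:
            header = None
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    header = fields
                    for col in ("column_index", "canonical_label", "region"):
                        if col not in header:
                            raise NumberingError(
                                f"template {path} missing column {col!r}")
                    continue
                row = dict(zip(header, fields))
                positions.append(CanonicalPosition(
                    label=row["canonical_label"],
                    order_index=int(row["column_index"]),
                    region=row["region"],
                ))
        return cls(positions)

    @classmethod
    def standard(cls) -> "NumberingTemplate":
        """The 76-column template covering positions 1-76."""
        ref = resources.files("trnamod.data") / "standard_template.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def map_alignment_to_canonical(
    aligned_sequence: str,
    template: NumberingTemplate,
    template_gaps: str | None = None,
    name: str | None = None,
) -> dict[int, CanonicalPosition]:
    """Map each residue of a gapped sequence onto a canonical position.

    Parameters
    ----------
    aligned_sequence
        IUPAC nucleotide string, possibly containing gap characters
        (``-`` or ``.``), aligned column-for-column with the template.
    template
        The numbering template whose columns label the alignment.
    template_gaps
        Optional same-length string marking alignment columns NOT covered by
        the template (gap character at insertion columns).  Residues landing
        in such columns receive an alphabetic insertion label derived from
        the preceding canonical position (``17a``, ``17b``, ...).
    name
        tRNA identifier used in error messages.

    Returns
    -------
    dict mapping residue index (0-based position within the ungapped
    sequence) to :class:`CanonicalPosition`.
    """
    who = f" for tRNA {name!r}" if name else ""
    seq = aligned_sequence.upper()
    bad = {c for c in seq if c not in _IUPAC and c not in GAP_CHARS}
    if bad:
        raise NumberingError(f"non-IUPAC characters {sorted(bad)}{who}")

    if template_gaps is None:
        if len(seq) != template.n_columns:
            raise NumberingError(
                f"aligned sequence length {len(seq)} != template columns "
                f"{template.n_columns}{who}")
        columns: list[CanonicalPosition | None] = list(template.positions)
    else:
        if len(template_gaps) != len(seq):
            raise NumberingError(
                f"template_gaps length {len(template_gaps)} != alignment "
                f"length {len(seq)}{who}")
        if sum(c not in GAP_CHARS for c in template_gaps) != template.n_columns:
            raise NumberingError(
                f"template_gaps covers a different number of columns than "
                f"the template{who}")
        it = iter(template.positions)
        columns = [next(it) if c not in GAP_CHARS else None
                   for c in template_gaps]

    mapping: dict[int, CanonicalPosition] = {}
    residue = 0
    last_canonical: CanonicalPosition | None = None
    insert_count = 0
    for col, pos in zip(seq, columns):
        if pos is not None:
            last_canonical = pos
            insert_count = 0
        if col in GAP_CHARS:
            continue
        if pos is None:
            # insertion column: suffix the preceding canonical label
            if last_canonical is None:
                base_label, base_order = "0", 0
            else:
                base_label = last_canonical.label
                base_order = last_canonical.order_index
            suffix = string.ascii_lowercase[insert_count]
            insert_count += 1
            mapping[residue] = CanonicalPosition(
                label=f"{base_label}{suffix}",
                order_index=base_order,
                region=last_canonical.region if last_canonical else "",
                is_insertion=True,
            )
        else:
            mapping[residue] = pos
        residue += 1
    return mapping


# Cloverleaf secondary-structure pairs, by canonical label:
# acceptor stem 1:72 .. 7:66, D-stem 10:25 .. 13:22,
# anticodon stem 27:43 .. 31:39, T-stem 49:65 .. 53:61.
_STEM_PAIRS: list[tuple[str, str]] = (
    [(str(i), str(73 - i)) for i in range(1, 8)]
    + [(str(i), str(35 - i)) for i in range(10, 14)]
    + [(str(i), str(70 - i)) for i in range(27, 32)]
    + [(str(i), str(114 - i)) for i in range(49, 54)]
)


class PairTable:
    """Symmetric lookup of cloverleaf stem partners."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = _STEM_PAIRS):
        self._partner: dict[str, str] = {}
        for a, b in pairs:
            if a in self._partner or b in self._partner:
                raise NumberingError(f"position in more than one pair: {a}:{b}")
            self._partner[a] = b
            self._partner[b] = a

    @property
    def pairs(self) -> list[tuple[str, str]]:
        seen = set()
        out = []
        for a, b in self._partner.items():
            if a not in seen and b not in seen:
                out.append((a, b))
                seen.update((a, b))
        return out

    def partner(self, label: str) -> str | None:
        return self._partner.get(label)


_DEFAULT_PAIR_TABLE = PairTable()
_DEFAULT_TEMPLATE: NumberingTemplate | None = None


def standard_template() -> NumberingTemplate:
    global _DEFAULT_TEMPLATE
    if _DEFAULT_TEMPLATE is None:
        _DEFAULT_TEMPLATE = NumberingTemplate.standard()
    return _DEFAULT_TEMPLATE


def pair_partner(label: str, template: NumberingTemplate | None = None) -> str | None:
    """Stem partner of a canonical position, or None for loop positions.

    Raises :class:`NumberingError` for labels absent from the template.
    """
    tmpl = template if template is not None else standard_template()
    if label not in tmpl:
        raise NumberingError(f"unknown canonical label {label!r}")
    return _DEFAULT_PAIR_TABLE.partner(label)


def position_sort_key(label: str, template: NumberingTemplate | None = None) -> tuple[int, str]:
    """Sort key placing canonical labels in 5'->3' order, insertions after
    their anchor position."""
    tmpl = template if template is not None else standard_template()
    if label in tmpl:
        return tmpl.position(label).sort_key()
    # insertion label: strip trailing letters
    stem = label.rstrip(string.ascii_lowercase)
    if stem in tmpl:
        return (tmpl.position(stem).order_index, label[len(stem):])
    raise NumberingError(f"unknown canonical label {label!r}")
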