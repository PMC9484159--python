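"""Text formats: reaction-equation files (.rxn), matrix TSV, energies TSV.

.rxn format, one reaction per line::

    # comment
    r1: 2 A + B -> C
    r2: A <=> B        # reversible, expanded into two columns r2, r2_rev
    r3: 0 -> A         # import; the empty side is written 0 (or the
                       # empty-set symbol)

Coefficients default to 1; whitespace is flexible.  Matrix TSV files carry
reaction ids in the first row and species ids in the first column.
"""

from __future__ import annotations

import re
import warnings
from fractions import Fraction
from pathlib import Path

from .network import (
    NullReactionWarning,
    Reaction,
    ReactionNetwork,
    StoichiometricMatrix,
    reverse_reaction,
)

__all__ = [
    "parse_rxn",
    "write_rxn",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_energies_tsv",
    "write_energies_tsv",
    "ParseError",
]

EMPTY_TOKENS = {"0", "∅"}
_TERM_RE = re.compile(r"^(?:(\d+)\s+)?(\S+)$")


class ParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


def _parse_side(text: str, lineno: int) -> dict[str, int]:
    text = text.strip()
    if text in EMPTY_TOKENS:
        return {}
    coeffs: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ParseError("empty term (stray '+'?)", lineno)
        m = _TERM_RE.match(term)
        if not m:
            raise ParseError(f"cannot parse term {term!r}", lineno)
        coeff = int(m.group(1)) if m.group(1) else 1
        sp = m.group(2)
        if sp in EMPTY_TOKENS:
            raise ParseError("empty-complex token mixed with species", lineno)
        coeffs[sp] = coeffs.get(sp, 0) + coeff
    return coeffs


def parse_rxn(text: str) -> ReactionNetwork:
    """Parse the reaction text format; reversible arrows expand to pairs.

    Species order is first appearance; reaction order is file order with the
    reverse of each reversible reaction immediately following it.
    """
    species: list[str] = []
    seen: set[str] = set()
    reactions: list[Reaction] = []
    ids: set[str] = set()

    def note_species(side: dict[str, int]):
        for sp in side:
            if sp not in seen:
                seen.add(sp)
                species.append(sp)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" in line:
            rid, body = line.split(":", 1)
            rid = rid.strip()
            if not rid:
                raise ParseError("empty reaction id", lineno)
        else:
            rid, body = f"r{len(reactions) + 1}", line
        if rid in ids:
            raise ParseError(f"duplicate reaction id {rid!r}", lineno)
        if "<=>" in body:
            left, right = body.split("<=>", 1)
            reversible = True
        elif "->" in body:
            left, right = body.split("->", 1)
            reversible = False
        else:
            raise ParseError("missing arrow ('->' or '<=>')", lineno)
        educts = _parse_side(left, lineno)
        products = _parse_side(right, lineno)
        if not educts and not products:
            raise ParseError("reaction with empty support", lineno)
        note_species(educts)
        note_species(products)
        r = Reaction(rid, educts, products, reversible=reversible)
        reactions.append(r)
        ids.add(rid)
        if reversible:
            rbar = reverse_reaction(r)
            if rbar.id in ids:
                raise ParseError(f"duplicate reaction id {rbar.id!r}", lineno)
            reactions.append(rbar)
            ids.add(rbar.id)
    if not reactions:
        raise ParseError("no reactions found")
    return ReactionNetwork(species, reactions)


def write_rxn(net: ReactionNetwork, header: str | None = None) -> str:
    """Canonical text form; expanded reversible pairs collapse back to <=>."""
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    skip: set[str] = set()
    sides = {
        r.id: (frozenset(r.educts.items()), frozenset(r.products.items()))
        for r in net.reactions
    }
    for r in net.reactions:
        if r.id in skip:
            continue
        arrow = "->"
        if r.reversible:
            e, p = sides[r.id]
            for q in net.reactions:
                if q.id != r.id and q.id not in skip and sides[q.id] == (p, e):
                    arrow = "<=>"
                    skip.add(q.id)
                    break
        def fmt(side: dict[str, int]) -> str:
            if not side:
                return "0"
            return " + ".join(
                sp if c == 1 else f"{c} {sp}" for sp, c in side.items()
            )
        lines.append(f"{r.id}: {fmt(r.educts)} {arrow} {fmt(r.products)}")
    return "\n".join(lines) + "\n"


def read_matrix_tsv(
    path: str | Path,
    irreversible_ids: list[str] | None = None,
) -> tuple[StoichiometricMatrix, list[str]]:
    """Read a labelled integer matrix (tab or whitespace delimited).

    Returns the matrix and the list of irreversible column ids (defaulting
    to all columns).  Emits warnings for null (all-zero) columns and for a
    suspicious wide-and-short shape suggesting a transposed file.
    """
    path = Path(path)
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t") if "\t" in line else line.split()
        rows.append((lineno, cells))
    if len(rows) < 2:
        raise ParseError("matrix file needs a header row and at least one species row")
    header = rows[0][1]
    col_labels = header[1:] if header and not _is_int(header[0]) else header
    row_labels = []
    entries = []
    for lineno, cells in rows[1:]:
        if len(cells) != len(col_labels) + 1:
            raise ParseError(
                f"expected {len(col_labels) + 1} cells, got {len(cells)}", lineno
            )
        row_labels.append(cells[0])
        try:
            entries.append([int(c) for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"non-integer cell: {exc}", lineno) from None
    S = StoichiometricMatrix(entries, row_labels, col_labels)
    n_sp, n_rx = S.shape
    if n_sp < n_rx / 4:
        warnings.warn(
            "matrix is much wider than tall; check for a transposed file",
            UserWarning, stacklevel=2,
        )
    for j in range(n_rx):
        if all(row[j] == 0 for row in entries):
            warnings.warn(
                f"null reaction column {col_labels[j]!r}",
                NullReactionWarning, stacklevel=2,
            )
    if irreversible_ids is None:
        irr = list(col_labels)
    else:
        unknown = set(irreversible_ids) - set(col_labels)
        if unknown:
            raise ParseError(f"unknown irreversible ids {sorted(unknown)}")
        irr = list(irreversible_ids)
    return S, irr


def _is_int(cell: str) -> bool:
    try:
        int(cell)
        return True
    except ValueError:
        return False


def write_matrix_tsv(S: StoichiometricMatrix) -> str:
    lines = ["\t".join(["species"] + S.col_labels)]
    for label, row in zip(S.row_labels, S.entries):
        lines.append("\t".join([label] + [str(x) for x in row]))
    return "\n".join(lines) + "\n"


def read_energies_tsv(path: str | Path) -> dict[str, Fraction]:
    """Two-column (id, rational/decimal value) energy file."""
    out: dict[str, Fraction] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cells = line.split("\t") if "\t" in line else line.split()
        if len(cells) != 2:
            raise ParseError("expected two columns (id, value)", lineno)
        try:
            out[cells[0]] = Fraction(cells[1])
        except ValueError:
            raise ParseError(f"cannot parse value {cells[1]!r}", lineno) from None
    return out


def write_energies_tsv(labels: list[str], values: list) -> str:
    return "\n".join(f"{l}\t{v}" for l, v in zip(labels, values)) + "\n"
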