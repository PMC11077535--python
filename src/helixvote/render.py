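"""Rendering the circularly permuted multi-family helix alignment.

Androglobin expresses the globin helices out of canonical order: D-H on the
N-terminal side of the chain, then the IQ calmodulin-binding motif, then
A-C.  The renderer emits one block per helix in canonical A..H order, each
block carrying the template representatives' helix windows, the query's
window read at its winning offset, a lowercase flank of inter-helix
context, and a marker line for key residues (CD1 aromatic 'a', proximal
histidine 'b', distal histidine/glutamine 'c', disulfide cysteines '#').
'/' marks the chain break in the discontiguous query sequence.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from .consensus import ConsensusResult
from .errors import ConfigurationError, ValidationError
from .families import GAP, OUT_OF_RANGE, ProfileFamily, extract_window

#: Androglobin's helix order: D-H first, chain break, IQ motif, then A-C.
ADGB_QUERY_ORDER = ("D", "E", "F", "G", "H", "IQ", "A", "B", "C")


@dataclass(frozen=True)
class Annotation:
    """One key-residue marker: a glyph at a 1-based residue of one family."""

    label: str
    family_id: str
    residue_index: int
    glyph: str

    def __post_init__(self) -> None:
        if len(self.glyph) != 1:
            raise ValidationError(f"annotation glyph must be one character: {self.glyph!r}")


@dataclass
class PermutedLayout:
    """Helix order of the query relative to the canonical A..H order."""

    canonical_order: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")
    query_order: tuple[str, ...] = ADGB_QUERY_ORDER
    chain_break_after: str = "H"
    annotations: dict[str, Annotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        helices = tuple(h for h in self.query_order if h in self.canonical_order)
        n = len(self.canonical_order)
        rotations = [
            self.canonical_order[i:] + self.canonical_order[:i] for i in range(n)
        ]
        if helices not in rotations:
            raise ValidationError(
                f"query helix order {helices} is not a rotation of "
                f"{self.canonical_order}"
            )
        if self.chain_break_after not in self.query_order:
            raise ValidationError(
                f"chain break after unknown helix {self.chain_break_after!r}"
            )


def load_annotations(path: str | Path) -> dict[str, Annotation]:
    """Annotations from YAML: ``label: {family, residue, glyph}``."""
    data = yaml.safe_load(Path(path).read_text())
    out = {}
    for label, spec in (data or {}).items():
        out[label] = Annotation(
            label=label,
            family_id=str(spec["family"]),
            residue_index=int(spec["residue"]),
            glyph=str(spec["glyph"]),
        )
    return out


def _resolve_offsets(
    helices: list[str],
    consensus: dict[str, ConsensusResult],
    manual_offsets: dict[str, int] | None,
) -> dict[str, int]:
    manual_offsets = manual_offsets or {}
    offsets = {}
    for h in helices:
        if h in consensus:
            offsets[h] = consensus[h].winning_offset
        elif h in manual_offsets:
            offsets[h] = manual_offsets[h]
        else:
            raise ConfigurationError(
                f"helix {h} has neither a consensus offset nor a manual offset"
            )
    return offsets


def _block_helices(
    layout: PermutedLayout, templates: list[ProfileFamily], query: ProfileFamily
) -> list[str]:
    return [
        h
        for h in layout.canonical_order
        if h in query.windows and all(h in t.windows for t in templates)
    ]


def assemble_permuted_alignment(
    templates: list[ProfileFamily],
    query: ProfileFamily,
    consensus: dict[str, ConsensusResult],
    layout: PermutedLayout | None = None,
    manual_offsets: dict[str, int] | None = None,
    representatives: dict[str, str] | None = None,
    context: int = 3,
) -> str:
    """Render the permuted alignment as a plain-text block per helix.

    Every helix in canonical order that all families define is rendered;
    voted helices take their consensus winning offset, non-voted helices
    (typically C and D) require an entry in ``manual_offsets``.  Representative
    sequences default to each family's first record, overridable by id via
    ``representatives``.  Inter-helix flanks of ``context`` residues are shown
    in lowercase; '/' ends the query line of the helix after which its chain
    breaks; annotation glyphs appear on a marker line beneath their family.
    """
    layout = layout or PermutedLayout()
    representatives = representatives or {}
    helices = _block_helices(layout, templates, query)
    if not helices:
        raise ConfigurationError("no helix is defined across all families")
    offsets = _resolve_offsets(helices, consensus, manual_offsets)

    name_w = max(len(f.family_id) for f in [*templates, query]) + 2
    lines: list[str] = []
    lines.append(
        "# query helix order: "
        + " ".join(
            h + (" /" if h == layout.chain_break_after else "")
            for h in layout.query_order
        )
    )
    for h in helices:
        lines.append("")
        lines.append(f"Helix {h}  (offset {offsets[h]:+d})")
        for fam, shift in [(t, 0) for t in templates] + [(query, offsets[h])]:
            rep = fam.representative(representatives.get(fam.family_id))
            w = fam.window(h)
            body = extract_window(rep, w, shift).replace(OUT_OF_RANGE, "-")
            left = _flank(rep, w.start + shift - context, context)
            right = _flank(rep, w.end + shift + 1, context)
            row = left.lower() + body + right.lower()
            if fam is query and h == layout.chain_break_after:
                row += "/"
            lines.append(f"{fam.family_id:<{name_w}}{row}")
            marker = _marker_line(
                layout, fam, w, shift, context, len(body)
            )
            if marker.strip():
                lines.append(f"{'':<{name_w}}{marker}")
    return "\n".join(lines) + "\n"


def _flank(rec, start_1based: int, length: int) -> str:
    chars = []
    for pos in range(start_1based, start_1based + length):
        chars.append(rec.residues[pos - 1] if 1 <= pos <= len(rec) else " ")
    return "".join(chars)


def _marker_line(layout, fam, window, shift, context, body_len) -> str:
    cols = [" "] * (context + body_len + context)
    for ann in layout.annotations.values():
        if ann.family_id != fam.family_id:
            continue
        col = context + (ann.residue_index - window.start - shift)
        if context <= col < context + body_len:
            cols[col] = ann.glyph
    return "".join(cols)


def permuted_alignment_fasta(
    templates: list[ProfileFamily],
    query: ProfileFamily,
    consensus: dict[str, ConsensusResult],
    layout: PermutedLayout | None = None,
    manual_offsets: dict[str, int] | None = None,
    representatives: dict[str, str] | None = None,
) -> str:
    """The same block alignment as aligned FASTA (helix windows concatenated).

    Window lengths per helix agree across families, so rows have one common
    width and the result round-trips through any aligned-FASTA reader.
    Out-of-range positions become gaps; the chain-break glyph is a rendering
    device and is omitted here.
    """
    layout = layout or PermutedLayout()
    representatives = representatives or {}
    helices = _block_helices(layout, templates, query)
    if not helices:
        raise ConfigurationError("no helix is defined across all families")
    offsets = _resolve_offsets(helices, consensus, manual_offsets)
    rows = []
    for fam, is_query in [(t, False) for t in templates] + [(query, True)]:
        rep = fam.representative(representatives.get(fam.family_id))
        parts = []
        for h in helices:
            shift = offsets[h] if is_query else 0
            parts.append(
                extract_window(rep, fam.window(h), shift).replace(OUT_OF_RANGE, GAP)
            )
        rows.append((fam.family_id, "".join(parts)))
    buf = _io.StringIO()
    for name, seq in rows:
        buf.write(f">{name}\n{seq}\n")
    return buf.getvalue()


def read_aligned_fasta_names(text: str) -> list[str]:
    """Names in an aligned-FASTA string, via the standard reader."""
    return [r.id for r in SeqIO.parse(_io.StringIO(text), "fasta")]
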