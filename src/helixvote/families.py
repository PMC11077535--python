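"""Sequence families, helix windows, and their file formats.

A *profile family* is a named set of homologous protein sequences (for
example, a few hundred vertebrate alpha-hemoglobins) together with the
residue spans of its globin helices.  Families may be internally aligned
(all records the same length, gaps allowed, windows in alignment-column
coordinates) or plain sequence sets with per-sequence window coordinates.

All user-facing coordinates are 1-based inclusive residue spans, matching
the conventional residue numbering used for helix annotations (e.g. a
helix running Val939-Glu951 is the span 939-951).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, FastaParseError, ValidationError

#: The 20 standard residues plus ambiguity 'X'.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"

#: Sentinel for a window position that falls outside the sequence after a
#: shift.  Out-of-range is a value, not an error: scoring assigns it a fixed
#: penalty so every offset compares windows of identical length.
OUT_OF_RANGE = "!"

#: Canonical globin helix labels in structural order, plus the IQ
#: calmodulin-binding motif that androglobin inserts between H and A.
HELIX_IDS = ("A", "B", "C", "D", "E", "F", "G", "H", "IQ")

#: Helices scored by offset voting.  C and D are short and structurally
#: variable; they are placed by explicit offsets, not voted on.
VOTED_HELICES = ("A", "B", "E", "F", "G", "H")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with a unique identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"record id {self.id!r} is empty or contains whitespace")
        if not self.residues:
            raise ValidationError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


def _validate_residues(rec_id: str, residues: str, allow_gaps: bool) -> None:
    allowed = ALPHABET | ({GAP} if allow_gaps else set())
    for pos, ch in enumerate(residues, start=1):
        if ch not in allowed:
            raise ValidationError(
                f"record {rec_id!r}: illegal character {ch!r} at position {pos}"
            )


@dataclass(frozen=True)
class HelixWindow:
    """A 1-based inclusive residue span naming one helix of one family.

    ``coordinate_space`` is ``"sequence"`` for per-sequence residue numbering
    or ``"alignment-column"`` for columns of the family's internal alignment.
    """

    helix_id: str
    family_id: str
    start: int
    end: int
    coordinate_space: str = "alignment-column"

    def __post_init__(self) -> None:
        if self.helix_id not in HELIX_IDS:
            raise ValidationError(
                f"unknown helix id {self.helix_id!r}; expected one of {HELIX_IDS}"
            )
        if self.coordinate_space not in ("sequence", "alignment-column"):
            raise ValidationError(
                f"coordinate_space must be 'sequence' or 'alignment-column', "
                f"got {self.coordinate_space!r}"
            )
        if self.start > self.end:
            raise ValidationError(
                f"helix {self.helix_id} of {self.family_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValidationError(
                f"helix {self.helix_id} of {self.family_id}: start must be >= 1"
            )
        if len(self) < 4:
            raise ValidationError(
                f"helix {self.helix_id} of {self.family_id}: window length "
                f"{len(self)} < 4"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProfileFamily:
    """A named set of sequences plus helix-window definitions.

    If ``is_aligned``, all residue strings have equal length (the alignment
    width) and windows may use alignment-column coordinates.
    """

    family_id: str
    records: list[SequenceRecord]
    windows: dict[str, HelixWindow] = field(default_factory=dict)
    is_aligned: bool = False

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError(f"family {self.family_id!r} has no records")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"family {self.family_id!r}: duplicate record ids {dupes}"
            )
        if self.is_aligned:
            widths = {len(r) for r in self.records}
            if len(widths) > 1:
                raise ValidationError(
                    f"family {self.family_id!r} is flagged aligned but record "
                    f"lengths differ: {sorted(widths)}"
                )
        for w in self.windows.values():
            if w.family_id != self.family_id:
                raise ConfigurationError(
                    f"window for helix {w.helix_id} belongs to family "
                    f"{w.family_id!r}, not {self.family_id!r}"
                )
            if w.coordinate_space == "alignment-column":
                if not self.is_aligned:
                    raise ConfigurationError(
                        f"family {self.family_id!r}: alignment-column window "
                        f"for helix {w.helix_id} requires an internal alignment"
                    )
                if w.end > self.alignment_width:
                    raise ValidationError(
                        f"family {self.family_id!r}: helix {w.helix_id} window "
                        f"end {w.end} exceeds alignment width {self.alignment_width}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def alignment_width(self) -> int:
        if not self.is_aligned:
            raise ConfigurationError(f"family {self.family_id!r} is not aligned")
        return len(self.records[0])

    def window(self, helix_id: str) -> HelixWindow:
        try:
            return self.windows[helix_id]
        except KeyError:
            raise ConfigurationError(
                f"family {self.family_id!r} defines no window for helix {helix_id!r}"
            ) from None

    def with_windows(self, windows: Mapping[str, HelixWindow]) -> "ProfileFamily":
        return ProfileFamily(
            family_id=self.family_id,
            records=list(self.records),
            windows=dict(windows),
            is_aligned=self.is_aligned,
        )

    def representative(self, record_id: str | None = None) -> SequenceRecord:
        """First record by default; a specific record when ``record_id`` given."""
        if record_id is None:
            return self.records[0]
        for r in self.records:
            if r.id == record_id:
                return r
        raise ConfigurationError(
            f"family {self.family_id!r} has no record {record_id!r}"
        )


def read_fasta(
    path: str | Path,
    family_id: str | None = None,
    allow_gaps: bool = False,
) -> ProfileFamily:
    """Read a FASTA file into a :class:`ProfileFamily` (order preserved).

    Gap characters are rejected unless ``allow_gaps``; with ``allow_gaps``
    the family is marked aligned and all records must share one length.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"{path}: no such file")
    text = path.read_text()
    _precheck_fasta(text, path)
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        residues = str(rec.seq).upper()
        if not residues:
            raise ValidationError(f"{path}: record {rec.id!r} has an empty sequence")
        _validate_residues(rec.id, residues, allow_gaps)
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise ValidationError(f"{path}: FASTA file contains no records")
    return ProfileFamily(
        family_id=family_id if family_id is not None else path.stem,
        records=records,
        is_aligned=allow_gaps,
    )


def _precheck_fasta(text: str, path: Path) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected '>' header, got {line[:30]!r}"
                )
            return
    raise FastaParseError(f"{path}: file is empty")


def write_fasta(family: ProfileFamily, path: str | Path, width: int = 60) -> None:
    """Write a family back to FASTA, preserving record order."""
    seqrecs = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in family.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def load_helix_config(path: str | Path) -> dict[str, dict[str, HelixWindow]]:
    """Load helix windows from a TSV or YAML config file.

    TSV columns: ``family_id  helix_id  start  end  [coordinate_space]``.
    YAML: a mapping ``family_id -> helix_id -> {start, end, coordinate_space}``
    (or ``[start, end]``).  Returns ``{family_id: {helix_id: HelixWindow}}``.
    Missing helices are permitted (C and D are not voted on).
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        return _load_helix_yaml(path)
    return _load_helix_tsv(path)


def _make_window(family_id, helix_id, start, end, space) -> HelixWindow:
    try:
        start, end = int(start), int(end)
    except (TypeError, ValueError):
        raise ValidationError(
            f"helix {helix_id} of {family_id}: start/end must be integers, "
            f"got {start!r}/{end!r}"
        ) from None
    return HelixWindow(
        helix_id=str(helix_id),
        family_id=str(family_id),
        start=start,
        end=end,
        coordinate_space=space,
    )


def _load_helix_yaml(path: Path) -> dict[str, dict[str, HelixWindow]]:
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping of family ids")
    out: dict[str, dict[str, HelixWindow]] = {}
    for fam, helices in data.items():
        out[fam] = {}
        for hid, spec in helices.items():
            if isinstance(spec, (list, tuple)):
                start, end = spec
                space = "alignment-column"
            else:
                start, end = spec["start"], spec["end"]
                space = spec.get("coordinate_space", "alignment-column")
            out[fam][str(hid)] = _make_window(fam, hid, start, end, space)
    return out


def _load_helix_tsv(path: Path) -> dict[str, dict[str, HelixWindow]]:
    out: dict[str, dict[str, HelixWindow]] = {}
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                for col in ("family_id", "helix_id", "start", "end"):
                    if col not in header:
                        raise ValidationError(
                            f"{path}: line {lineno}: missing column {col!r}"
                        )
                continue
            row = dict(zip(header, fields))
            space = row.get("coordinate_space", "alignment-column") or "alignment-column"
            w = _make_window(row["family_id"], row["helix_id"], row["start"], row["end"], space)
            out.setdefault(w.family_id, {})[w.helix_id] = w
    if header is None:
        raise ValidationError(f"{path}: empty helix config")
    return out


def extract_window(
    record: SequenceRecord, window: HelixWindow, shift: int = 0
) -> str:
    """Read a helix window at an integer shift.

    Returns the ``len(window)`` characters at positions
    ``start+shift .. end+shift`` (1-based).  Positions falling before the
    first or after the last residue are returned as the :data:`OUT_OF_RANGE`
    marker; gaps in aligned families are preserved.  Out-of-range is a
    value, not an error, so every shift yields a string of identical length.
    """
    seq = record.residues
    lo = window.start + shift  # 1-based inclusive
    chars = []
    for pos in range(lo, lo + len(window)):
        if 1 <= pos <= len(seq):
            chars.append(seq[pos - 1])
        else:
            chars.append(OUT_OF_RANGE)
    return "".join(chars)


def windows_for(
    families: Iterable[ProfileFamily],
    config: Mapping[str, Mapping[str, HelixWindow]],
) -> list[ProfileFamily]:
    """Attach windows from a loaded helix config to each family by id."""
    out = []
    for fam in families:
        if fam.family_id not in config:
            raise ConfigurationError(
                f"helix config defines no windows for family {fam.family_id!r}"
            )
        out.append(fam.with_windows(dict(config[fam.family_id])))
    return out
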