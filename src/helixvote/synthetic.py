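"""Synthetic profile families with controlled identity and planted truth.

Every other module is testable without any sequence download: families are
generated from a common ancestral seed sequence by independent per-sequence
substitution, so two families derived from one seed are genuine remote
homologues whose true helix alignment is known.  ``target_identity`` is the
desired *mean pairwise identity among generated records* — the quantity the
twilight zone is defined by — and the per-position substitution rate is
calibrated accordingly (see :func:`substitution_rate_for_identity`).
Offsets are planted by physically displacing the helix content inside the
query records, creating ground truth for vote-recovery experiments.

Generation is fully deterministic: one integer seed drives per-record
substreams keyed by record index, so output is byte-identical across runs
and independent of iteration order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .families import AMINO_ACIDS, HelixWindow, ProfileFamily, SequenceRecord, write_fasta
from .voting import OffsetRange

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_N_AA = len(AMINO_ACIDS)


def substitution_rate_for_identity(target_identity: float) -> float:
    """Per-position substitution rate giving a target mean pairwise identity.

    Two records independently substituted at rate *m* (uniformly over the 19
    non-ancestral residues) agree at a position with probability
    ``(1-m)^2 + m^2/19``.  Solving that for *m* makes ``target_identity`` the
    expected all-vs-all pairwise identity rather than the identity to the
    hidden seed.  The minimum reachable pairwise identity under this model is
    5% (at m = 0.95); lower targets are clamped there.
    """
    t = float(target_identity)
    if not (0.0 < t <= 1.0):
        raise ValidationError(f"target_identity must be in (0, 1], got {t}")
    disc = 1.0 - (20.0 / 19.0) * (1.0 - t)
    if disc < 0.0:
        return 0.95
    return (19.0 / 20.0) * (1.0 - math.sqrt(disc))


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic family."""

    seed_sequence: str
    n_sequences: int
    target_identity: float = 0.25
    planted_offsets: dict = field(default_factory=dict)
    column_plants: dict = field(default_factory=dict)  # (column, residue) -> count
    rng_seed: int = 0
    family_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValidationError("n_sequences must be positive")
        if not self.seed_sequence:
            raise ValidationError("seed_sequence is empty")
        for ch in self.seed_sequence:
            if ch not in AMINO_ACIDS:
                raise ValidationError(f"seed_sequence contains non-standard residue {ch!r}")
        if not (0.0 < self.target_identity <= 1.0):
            raise ValidationError("target_identity must be in (0, 1]")
        if self.target_identity * len(self.seed_sequence) < 1.0:
            raise ValidationError("target_identity x length must be >= 1")
        rng = OffsetRange()
        for helix, shift in self.planted_offsets.items():
            if shift not in rng:
                raise ValidationError(
                    f"planted offset {shift} for helix {helix} outside {rng}"
                )
        for (col, res), count in self.column_plants.items():
            if count > self.n_sequences:
                raise ValidationError(
                    f"column plant ({col}, {res!r}): count {count} exceeds "
                    f"n_sequences {self.n_sequences}"
                )
            if not (1 <= col <= len(self.seed_sequence)):
                raise ValidationError(f"planted column {col} outside sequence")
            if res not in AMINO_ACIDS:
                raise ValidationError(f"planted residue {res!r} is not a standard residue")


def _record_rng(rng_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([rng_seed, index])


def _substitute(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(seq.size) < rate
    if mask.any():
        # uniform over the 19 residues other than the original
        draws = rng.integers(0, _N_AA - 1, size=int(mask.sum()))
        orig_idx = np.searchsorted(_AA, out[mask])
        draws = np.where(draws >= orig_idx, draws + 1, draws)
        out[mask] = _AA[draws]
    return out


def generate_family(
    spec: SyntheticSpec,
    windows: dict[str, HelixWindow] | None = None,
) -> ProfileFamily:
    """Generate a family of mutated copies of the seed sequence.

    Each record substitutes a Bernoulli-sampled set of positions at the
    calibrated rate; column plants then override the sampled residues so the
    planted (column, residue) counts are exact.  Records are equal length
    with no gaps, so the family is internally aligned by construction.
    """
    rate = substitution_rate_for_identity(spec.target_identity)
    seed = np.frombuffer(spec.seed_sequence.encode(), dtype=np.uint8)
    rows = [
        _substitute(seed, rate, _record_rng(spec.rng_seed, i))
        for i in range(spec.n_sequences)
    ]
    by_column: dict[int, list[tuple[str, int]]] = {}
    for (col, res), count in sorted(spec.column_plants.items()):
        by_column.setdefault(col, []).append((res, count))
    for col, plants in by_column.items():
        if sum(c for _, c in plants) > spec.n_sequences:
            raise ValidationError(
                f"column {col}: planted counts exceed n_sequences"
            )
        plant_rng = np.random.default_rng([spec.rng_seed, 997, col])
        order = plant_rng.permutation(spec.n_sequences)
        planted = set("".join(r for r, _ in plants))
        others = np.frombuffer(
            "".join(a for a in AMINO_ACIDS if a not in planted).encode(),
            dtype=np.uint8,
        )
        pos = 0
        for res, count in plants:  # disjoint record sets, exact counts
            for i in order[pos : pos + count]:
                rows[i][col - 1] = ord(res)
            pos += count
        for i in order[pos:]:  # leftovers must avoid every planted residue
            if chr(rows[i][col - 1]) in planted:
                rows[i][col - 1] = others[plant_rng.integers(0, others.size)]
    records = [
        SequenceRecord(id=f"{spec.family_id}_{i:04d}", residues=row.tobytes().decode())
        for i, row in enumerate(rows)
    ]
    fam = ProfileFamily(
        family_id=spec.family_id, records=records, is_aligned=True
    )
    if windows:
        fam = fam.with_windows(
            {
                h: HelixWindow(h, spec.family_id, w.start, w.end, w.coordinate_space)
                for h, w in windows.items()
            }
        )
    return fam


def plant_offsets(
    family: ProfileFamily,
    shifts: dict[str, int],
    rng_seed: int = 0,
    offset_range: OffsetRange | None = None,
) -> ProfileFamily:
    """Displace several helices' content simultaneously inside every record.

    For each ``helix_id -> shift`` the residues of the configured window are
    moved ``shift`` positions to the right (negative = left); vacated
    positions are filled with uniform random residues.  Records too short
    for a rightward shift are padded with random residues.  All contents are
    read before any are written, so adjacent helices never clobber each
    other.  Shifted windows must not overlap.
    """
    if offset_range is None:
        offset_range = OffsetRange()
    for helix_id, shift in shifts.items():
        if shift not in offset_range:
            raise ValidationError(f"shift {shift} for helix {helix_id} outside {offset_range}")
        w = family.window(helix_id)
        if w.start + shift < 1:
            raise ValidationError(
                f"shift {shift} pushes helix {helix_id} before the sequence start"
            )
    active = {h: s for h, s in shifts.items() if s != 0}
    if not active:
        return family
    spans = sorted(
        (family.window(h).start + s, family.window(h).end + s)
        for h, s in shifts.items()
    )
    for (_, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValidationError("shifted helix windows overlap")
    max_end = max(family.window(h).end + s for h, s in shifts.items())
    new_records = []
    for i, rec in enumerate(family.records):
        rng = _record_rng(rng_seed, i)
        res = np.frombuffer(rec.residues.encode(), dtype=np.uint8).copy()
        pad = max_end - res.size
        if pad > 0:
            res = np.concatenate([res, _AA[rng.integers(0, _N_AA, size=pad)]])
        windows = [(family.window(h), s) for h, s in active.items()]
        contents = {w.helix_id: res[w.start - 1 : w.end].copy() for w, _ in windows}
        shifted = [(w.start + s, w.end + s) for w, s in windows]
        for w, _ in windows:  # vacated positions -> random fill
            for pos in range(w.start, w.end + 1):
                if not any(lo <= pos <= hi for lo, hi in shifted):
                    res[pos - 1] = _AA[rng.integers(0, _N_AA)]
        for w, s in windows:
            res[w.start + s - 1 : w.end + s] = contents[w.helix_id]
        new_records.append(SequenceRecord(id=rec.id, residues=res.tobytes().decode()))
    widths = {len(r.residues) for r in new_records}
    return ProfileFamily(
        family_id=family.family_id,
        records=new_records,
        windows=dict(family.windows),
        is_aligned=family.is_aligned and len(widths) == 1,
    )


def plant_offset(
    family: ProfileFamily,
    helix_id: str,
    shift: int,
    rng_seed: int = 0,
    offset_range: OffsetRange | None = None,
) -> ProfileFamily:
    """Displace one helix's content by ``shift``; see :func:`plant_offsets`.

    After planting, extracting the query window at ``shift`` recovers the
    original helix content, so vote tallies peak at ``+shift`` under the
    query-moved-right sign convention.
    """
    return plant_offsets(family, {helix_id: shift}, rng_seed, offset_range)


def mean_pairwise_identity(family: ProfileFamily) -> float:
    """All-vs-all mean fraction of identical positions (equal-length records)."""
    mat = np.array(
        [np.frombuffer(r.residues.encode(), dtype=np.uint8) for r in family.records]
    )
    n = mat.shape[0]
    if n < 2:
        return 1.0
    total = 0.0
    for i in range(n - 1):
        total += (mat[i + 1 :] == mat[i]).mean(axis=1).sum()
    return float(total / (n * (n - 1) / 2))


def random_seed_sequence(length: int, rng_seed: int = 0) -> str:
    """A uniform random sequence over the 20 standard residues."""
    rng = np.random.default_rng(rng_seed)
    return _AA[rng.integers(0, _N_AA, size=length)].tobytes().decode()


#: Helix spans used by the synthetic study: six voted helices with
#: realistic lengths (12-15 residues) spaced along a 140-residue chain,
#: leaving room for shifts within the default -25..+25 range.
DEFAULT_HELIX_SPANS = {
    "A": (8, 20),
    "B": (26, 40),
    "E": (48, 61),
    "F": (67, 79),
    "G": (85, 99),
    "H": (105, 116),
}
DEFAULT_CHAIN_LENGTH = 140


def default_windows(family_id: str) -> dict[str, HelixWindow]:
    return {
        h: HelixWindow(h, family_id, start, end)
        for h, (start, end) in DEFAULT_HELIX_SPANS.items()
    }


def write_fixture(spec: SyntheticSpec, family: ProfileFamily, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the family as FASTA plus a JSON sidecar of the planted truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{spec.family_id}.fasta"
    truth = out_dir / f"{spec.family_id}.truth.json"
    write_fasta(family, fasta)
    truth.write_text(
        json.dumps(
            {
                "family_id": spec.family_id,
                "n_sequences": spec.n_sequences,
                "target_identity": spec.target_identity,
                "rng_seed": spec.rng_seed,
                "planted_offsets": dict(spec.planted_offsets),
                "column_plants": {
                    f"{col}:{res}": count
                    for (col, res), count in spec.column_plants.items()
                },
                "realized_mean_pairwise_identity": mean_pairwise_identity(family),
            },
            indent=2,
        )
        + "\n"
    )
    return fasta, truth
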