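"""Presence/absence/pseudogene matrices (gene subtype x species)."""

from __future__ import annotations

from enum import Enum
from typing import Dict, Iterable, List, Optional

from wgdkit.io_formats.tables import ValidationError


class State(str, Enum):
    PRESENT = "present"
    PSEUDOGENE = "pseudogene"
    ABSENT = "absent"
    UNKNOWN = "unknown"

    @property
    def token(self) -> str:
        return _STATE_TO_TOKEN[self]


_TOKEN_TO_STATE = {
    "1": State.PRESENT,
    "P": State.PSEUDOGENE,
    "0": State.ABSENT,
    "?": State.UNKNOWN,
}
_STATE_TO_TOKEN = {v: k for k, v in _TOKEN_TO_STATE.items()}


class PresenceMatrix:
    """Rows = gene subtype labels, columns = species, cells = states."""

    def __init__(self, species: List[str]):
        if not species:
            raise ValidationError("presence matrix needs at least one species column")
        if len(set(species)) != len(species):
            raise ValidationError("duplicate species columns")
        self.species = list(species)
        self._rows: Dict[str, Dict[str, State]] = {}

    @property
    def subtypes(self) -> List[str]:
        return list(self._rows)

    def set_row(self, subtype: str, states: Dict[str, State]) -> None:
        unknown = set(states) - set(self.species)
        if unknown:
            raise ValidationError(
                f"row {subtype!r}: unknown species {sorted(unknown)}"
            )
        row = {sp: states.get(sp, State.ABSENT) for sp in self.species}
        if all(s == State.ABSENT for s in row.values()):
            raise ValidationError(f"row {subtype!r}: every cell absent")
        self._rows[subtype] = row

    def row(self, subtype: str) -> Dict[str, State]:
        try:
            return dict(self._rows[subtype])
        except KeyError:
            raise KeyError(f"no row {subtype!r} in presence matrix") from None

    def __contains__(self, subtype: str) -> bool:
        return subtype in self._rows

    def cell(self, subtype: str, species: str) -> State:
        return self._rows[subtype][species]

    def __len__(self) -> int:
        return len(self._rows)


def read_presence_matrix(path, species_check: Optional[Iterable[str]] = None) -> PresenceMatrix:
    """Read a TSV presence matrix; header = species, cells in {1, P, 0, ?}.

    When ``species_check`` is given, every column species must be a member.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty presence matrix")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ValidationError(f"{path}: header must list at least one species")
    species = header[1:]
    if species_check is not None:
        known = set(species_check)
        bad = [sp for sp in species if sp not in known]
        if bad:
            raise ValidationError(f"{path}: unknown species {bad}")
    matrix = PresenceMatrix(species)
    if len(lines) == 1:
        raise ValidationError(f"{path}: presence matrix has no rows")
    for row_no, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValidationError(
                f"{path}: row {row_no}: expected {len(header)} columns, got {len(fields)}"
            )
        subtype = fields[0]
        states = {}
        for sp, token in zip(species, fields[1:]):
            if token not in _TOKEN_TO_STATE:
                raise ValidationError(
                    f"{path}: row {row_no}: unknown state token {token!r}"
                )
            states[sp] = _TOKEN_TO_STATE[token]
        matrix.set_row(subtype, states)
    return matrix


def write_presence_matrix(matrix: PresenceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("subtype\t" + "\t".join(matrix.species) + "\n")
        for subtype in matrix.subtypes:
            row = matrix.row(subtype)
            fh.write(
                subtype
                + "\t"
                + "\t".join(row[sp].token for sp in matrix.species)
                + "\n"
            )
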