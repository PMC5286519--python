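"""Back-to-consensus β-turn mutation design.

β-turns are four-residue chain reversals (positions i..i+3) classified by
the backbone dihedrals of the two central residues.  Statistical surveys of
β-turns show strong residue preferences at specific (turn type, position)
slots — e.g. A, E, K and P dominate the second position of type II turns.
The designer proposes mutating any non-conforming residue of a type I or II
turn toward the preferred set for its slot.  Turns that share residues
("overlapping" turns) are handled with the shared-residue rule: only the
shared residues are considered, and their target set is the union of the
preferred sets over every slot the residue occupies, minus the wild type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .structure import LoopDefinition

__all__ = [
    "BetaTurn",
    "PositionalPreferenceTable",
    "MutationCandidate",
    "load_turns",
    "load_preference_table",
    "default_preference_table",
    "propose_mutations",
    "candidates_to_table",
    "packaged_turn_table",
]

_DESIGNED_TYPES = ("I", "II")
_KNOWN_TYPES = ("I", "II", "IV", "VIII")

_AA1 = set("ACDEFGHIKLMNPQRSTVWY")
AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class BetaTurn:
    """Four consecutive residues (i..i+3) with a turn-type label."""

    turn_id: int
    chain_id: str
    start_residue: int
    sequence: str  # four 1-letter codes
    turn_type: str

    def __post_init__(self):
        if len(self.sequence) != 4 or not set(self.sequence) <= _AA1:
            raise ValueError(f"turn sequence must be 4 one-letter codes, got {self.sequence!r}")
        if self.turn_type not in _KNOWN_TYPES:
            raise ValueError(f"unknown turn type {self.turn_type!r}")

    @property
    def residue_numbers(self) -> tuple[int, int, int, int]:
        return tuple(self.start_residue + i for i in range(4))

    @property
    def sequence_label(self) -> str:
        return f"{self.start_residue}{self.sequence}{self.start_residue + 3}"

    def position_of(self, residue_number: int) -> int:
        """1-based turn position of a residue number."""
        offset = residue_number - self.start_residue
        if not 0 <= offset <= 3:
            raise ValueError(f"residue {residue_number} not in turn {self.sequence_label}")
        return offset + 1

    def overlaps(self, other: "BetaTurn") -> bool:
        return (self.chain_id == other.chain_id
                and set(self.residue_numbers) & set(other.residue_numbers))


@dataclass
class PositionalPreferenceTable:
    """Map (turn type, position 1..4) -> preferred 1-letter residue set."""

    preferences: dict[tuple[str, int], frozenset[str]]

    def __post_init__(self):
        for (ttype, pos), residues in self.preferences.items():
            if ttype not in _KNOWN_TYPES or pos not in (1, 2, 3, 4):
                raise ValueError(f"bad preference key ({ttype}, {pos})")
            if not residues or not set(residues) <= _AA1:
                raise ValueError(f"bad preference set for ({ttype}, {pos}): {residues}")

    def covers(self, turn_type: str, position: int) -> bool:
        return (turn_type, position) in self.preferences

    def preferred(self, turn_type: str, position: int) -> frozenset[str]:
        return self.preferences[(turn_type, position)]


@dataclass(frozen=True)
class MutationCandidate:
    chain_id: str
    residue_number: int
    wt_residue: str
    proposed_residue: str
    source_turns: tuple[int, ...]
    loop_id: int | None = None

    def __post_init__(self):
        if self.proposed_residue == self.wt_residue:
            raise ValueError("candidate proposes the wild-type residue")

    @property
    def name(self) -> str:
        """Variant name, e.g. ``A282P``."""
        return f"{self.wt_residue}{self.residue_number}{self.proposed_residue}"


def default_preference_table() -> PositionalPreferenceTable:
    """The preference sets shipped with the package (see data/turn_preferences.txt).

    Type II all four positions; type I positions 3 and 4.  Type I positions
    1 and 2 are not covered by the shipped statistics and are skipped with a
    warning unless a user table supplies them.
    """
    with resources.files("loopstab.data").joinpath("turn_preferences.txt").open() as fh:
        return _parse_preference_stream(fh)


def load_preference_table(path: str | Path) -> PositionalPreferenceTable:
    """Read a key-value preference file: lines ``TYPE POSITION: RES,RES,...``."""
    with open(path) as fh:
        return _parse_preference_stream(fh)


def _parse_preference_stream(fh) -> PositionalPreferenceTable:
    prefs: dict[tuple[str, int], frozenset[str]] = {}
    for raw in fh:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, residues = line.partition(":")
        parts = key.split()
        if len(parts) != 2:
            raise ValueError(f"malformed preference line: {raw!r}")
        ttype, pos = parts[0], int(parts[1])
        aa = frozenset(r.strip().upper() for r in residues.split(",") if r.strip())
        prefs[(ttype, pos)] = aa
    return PositionalPreferenceTable(prefs)


def packaged_turn_table() -> Path:
    """Path of the packaged β-turn annotation fixture (the designed turns of
    the transketolase flexible loops, chain A)."""
    return Path(str(resources.files("loopstab.data").joinpath("turns_designed.tsv")))


def load_turns(path: str | Path, chain_id: str = "A") -> list[BetaTurn]:
    """Read a turn annotation table (TSV: start_res, sequence, type).

    Turns sharing at least one residue are overlapping; use
    :func:`overlap_clusters` or :func:`propose_mutations` to apply the
    shared-residue rule.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "type": str})
    if df.empty:
        return []
    required = {"start_res", "sequence", "type"}
    if not required <= set(df.columns):
        raise ValueError(f"turn table needs columns {sorted(required)}")
    turns = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        turns.append(BetaTurn(i, chain_id, int(row.start_res),
                              str(row.sequence).upper(), str(row.type)))
    return turns


def overlap_clusters(turns: Sequence[BetaTurn]) -> list[list[BetaTurn]]:
    """Group turns into clusters connected by shared residues."""
    clusters: list[list[BetaTurn]] = []
    for turn in turns:
        hits = [c for c in clusters if any(turn.overlaps(t) for t in c)]
        if not hits:
            clusters.append([turn])
        else:
            merged = hits[0]
            for other in hits[1:]:
                merged.extend(other)
                clusters.remove(other)
            merged.append(turn)
    return clusters


def propose_mutations(
    turns: Sequence[BetaTurn],
    prefs: PositionalPreferenceTable | None = None,
    restrict_to_loops: Sequence[LoopDefinition] | None = None,
) -> list[MutationCandidate]:
    """Back-to-consensus candidates for a set of annotated β-turns.

    Only type I and II turns are designed against.  Isolated-turn residues
    whose wild type is outside the preferred set for their slot yield one
    candidate per preferred residue; residues shared between overlapping
    turns use the union of the preferred sets over all their slots.  Slots
    without a preference entry are skipped with a warning.  Candidates are
    returned deduplicated and canonically sorted (residue number, then
    proposed residue), independent of the turn input order.
    """
    prefs = prefs or default_preference_table()
    designable = [t for t in turns if t.turn_type in _DESIGNED_TYPES]
    candidates: dict[tuple[str, int, str], MutationCandidate] = {}
    missing_slots: set[tuple[str, int]] = set()

    for cluster in overlap_clusters(list(designable)):
        if len(cluster) == 1:
            targets = {r: [cluster[0]] for r in cluster[0].residue_numbers}
        else:
            # overlapping cluster: only the residues common to every turn of
            # the cluster are designed against
            common = set(cluster[0].residue_numbers)
            for turn in cluster[1:]:
                common &= set(turn.residue_numbers)
            targets = {r: list(cluster) for r in sorted(common)}
        for residue_number, sharing in targets.items():
            wt = None
            preferred: set[str] = set()
            covered = False
            for turn in sharing:
                pos = turn.position_of(residue_number)
                wt = turn.sequence[pos - 1]
                if not prefs.covers(turn.turn_type, pos):
                    missing_slots.add((turn.turn_type, pos))
                    continue
                covered = True
                preferred |= prefs.preferred(turn.turn_type, pos)
            if not covered or wt is None:
                continue
            if len(sharing) == 1 and wt in preferred:
                continue  # conforming residue of an isolated turn
            chain = sharing[0].chain_id
            if restrict_to_loops is not None and not any(
                lp.chain_id == chain and lp.covers(residue_number)
                for lp in restrict_to_loops
            ):
                continue
            loop_id = None
            if restrict_to_loops is not None:
                loop_id = next(
                    lp.loop_id for lp in restrict_to_loops
                    if lp.chain_id == chain and lp.covers(residue_number)
                )
            for aa in preferred - {wt}:
                key = (chain, residue_number, aa)
                turn_ids = tuple(sorted(t.turn_id for t in sharing))
                if key in candidates:
                    merged = tuple(sorted(set(candidates[key].source_turns) | set(turn_ids)))
                    candidates[key] = MutationCandidate(
                        chain, residue_number, wt, aa, merged, loop_id)
                else:
                    candidates[key] = MutationCandidate(
                        chain, residue_number, wt, aa, turn_ids, loop_id)

    if missing_slots:
        warnings.warn(
            "no preference statistics for slots "
            + ", ".join(f"(type {t}, pos {p})" for t, p in sorted(missing_slots))
            + "; those positions were skipped",
            stacklevel=2,
        )
    out = sorted(candidates.values(),
                 key=lambda c: (c.chain_id, c.residue_number, c.proposed_residue))
    return out


def candidates_to_table(candidates: Sequence[MutationCandidate]) -> pd.DataFrame:
    """Candidate list as a tidy table; ``variant`` names are compatible with
    the ΔΔG module (e.g. ``A282P``)."""
    return pd.DataFrame(
        [
            {
                "variant": c.name,
                "chain": c.chain_id,
                "residue": c.residue_number,
                "wt": c.wt_residue,
                "proposed": c.proposed_residue,
                "source_turns": ",".join(str(t) for t in c.source_turns),
                "loop_id": c.loop_id,
            }
            for c in candidates
        ],
        columns=["variant", "chain", "residue", "wt", "proposed", "source_turns", "loop_id"],
    )
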