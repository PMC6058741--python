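"""Protease active-site motif extraction and activity triage.

Two five-residue motifs drive the classification: the active-site loop B1
(canonical ``DTGAD``) and the associated helix C2 (canonical ``GRDLL``).
Motifs are read out of a codon-aware alignment at columns anchored on the
canonical motifs of intact reference rows; rows interrupted by stops or
frameshifts are excluded from frequency tables.

The activity rule set is data, not code: per-position *allowed* residues
(no penalty), *tolerated* residues (counted as a deviation), and everything
else disallowed.  A sequence is predicted inactive when a motif has the
wrong length, carries a disallowed residue, accumulates two deviations in
the active-site loop, or deviates in both motifs at once; it is predicted
active only for the canonical loop (or its A->V variant) paired with the
canonical helix, and potentially active otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .codonalign import CodonAlignment, GAP, FS
from .errors import ConfigurationError, InputError

PREDICTED_ACTIVE = "PREDICTED_ACTIVE"
POTENTIALLY_ACTIVE = "POTENTIALLY_ACTIVE"
PREDICTED_INACTIVE = "PREDICTED_INACTIVE"

B1_CANONICAL = "DTGAD"
C2_CANONICAL = "GRDLL"

VALID_AA = set("ARNDCQEGHILKMFPSTWYV")


@dataclass(frozen=True)
class PositionRule:
    allowed: frozenset[str]
    tolerated: frozenset[str] = frozenset()

    def judge(self, residue: str) -> str:
        if residue in self.allowed:
            return "allowed"
        if residue in self.tolerated:
            return "deviation"
        return "disallowed"


def _pr(allowed: str, tolerated: str = "") -> PositionRule:
    return PositionRule(frozenset(allowed), frozenset(tolerated))


@dataclass
class ActivityRuleSet:
    """Per-position residue tolerances plus the combination rules."""

    b1: tuple[PositionRule, ...]
    c2: tuple[PositionRule, ...]
    active_b1: frozenset[str] = frozenset({"DTGAD", "DTGVD"})
    active_c2: frozenset[str] = frozenset({"GRDLL"})
    max_b1_deviations: int = 1     # more -> inactive
    both_motif_deviation_inactive: bool = True

    def to_dict(self) -> dict:
        return {
            "b1": [{"allowed": sorted(r.allowed), "tolerated": sorted(r.tolerated)}
                   for r in self.b1],
            "c2": [{"allowed": sorted(r.allowed), "tolerated": sorted(r.tolerated)}
                   for r in self.c2],
            "active_b1": sorted(self.active_b1),
            "active_c2": sorted(self.active_c2),
            "max_b1_deviations": self.max_b1_deviations,
            "both_motif_deviation_inactive": self.both_motif_deviation_inactive,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ActivityRuleSet":
        return cls(
            b1=tuple(PositionRule(frozenset(r["allowed"]),
                                  frozenset(r.get("tolerated", [])))
                     for r in data["b1"]),
            c2=tuple(PositionRule(frozenset(r["allowed"]),
                                  frozenset(r.get("tolerated", [])))
                     for r in data["c2"]),
            active_b1=frozenset(data.get("active_b1", {"DTGAD", "DTGVD"})),
            active_c2=frozenset(data.get("active_c2", {"GRDLL"})),
            max_b1_deviations=int(data.get("max_b1_deviations", 1)),
            both_motif_deviation_inactive=bool(
                data.get("both_motif_deviation_inactive", True)),
        )


# Catalytic aspartate strict at loop position 1; the final aspartate may be
# another small polar/charged residue; the dimer-interface threonine admits
# only serine; helix position 1 glycine and position 5 leucine are strict.
DEFAULT_RULES = ActivityRuleSet(
    b1=(
        _pr("D"),
        _pr("T", "S"),
        _pr("G", "RKEDASVNQ"),
        _pr("AV", "SETMIGD"),
        _pr("D", "NE"),
    ),
    c2=(
        _pr("G"),
        _pr("RK", "Q"),
        _pr("D", "EH"),
        _pr("L", "I"),
        _pr("L"),
    ),
)


@dataclass
class MotifCall:
    seq_id: str
    b1: str
    c2: str
    interrupted: str = "none"           # none | stop | frameshift | both
    deletion_38_42: bool = False
    activity: str | None = None
    rules_fired: list[str] = field(default_factory=list)


def locate_anchor_columns(calign: CodonAlignment, motif: str,
                          reference_ids: Sequence[str] | None = None,
                          ) -> list[int]:
    """Columns spanned by ``motif`` in the first reference row containing it.

    The motif must occur in consecutive non-gap columns of a reference row.
    """
    candidates = reference_ids if reference_ids is not None else calign.ids
    for name in candidates:
        row = calign.aa_rows[name]
        residue_cols = [c for c, ch in enumerate(row) if ch not in (GAP, FS)]
        residues = "".join(row[c] for c in residue_cols)
        pos = residues.find(motif)
        if pos >= 0:
            return residue_cols[pos:pos + len(motif)]
    raise ConfigurationError(
        f"anchor motif {motif!r} not found in any reference row")


def extract_motifs(calign: CodonAlignment,
                   b1_columns: Sequence[int] | None = None,
                   c2_columns: Sequence[int] | None = None,
                   reference_ids: Sequence[str] | None = None,
                   ) -> list[MotifCall]:
    """Per-row B1/C2 motif strings; gap columns shorten the motif."""
    if b1_columns is None:
        b1_columns = locate_anchor_columns(calign, B1_CANONICAL, reference_ids)
    if c2_columns is None:
        c2_columns = locate_anchor_columns(calign, C2_CANONICAL, reference_ids)
    calls = []
    for name in calign.ids:
        row = calign.aa_rows[name]
        b1 = "".join(row[c] for c in b1_columns if row[c] not in (GAP, FS))
        c2 = "".join(row[c] for c in c2_columns if row[c] not in (GAP, FS))
        calls.append(MotifCall(seq_id=name, b1=b1, c2=c2))
    return calls


def flag_interruptions(calign: CodonAlignment, seq_id: str,
                       span: tuple[int, int] | None = None) -> str:
    """Interruption status from stop/frameshift annotations within a source span.

    ``span`` is a 0-based half-open interval in source nucleotide coordinates
    (default: the whole sequence).
    """
    ann = calign.annotations[seq_id]

    def in_span(src: int) -> bool:
        return span is None or span[0] <= src < span[1]

    has_stop = any(in_span(src) for _, src in ann.stops)
    has_fs = any(in_span(src) for _, src in ann.frameshifts)
    if has_stop and has_fs:
        return "both"
    if has_stop:
        return "stop"
    if has_fs:
        return "frameshift"
    return "none"


def reference_position_columns(calign: CodonAlignment, reference_id: str,
                               positions: Sequence[int]) -> list[int]:
    """Alignment columns of 1-based residue positions of a reference row."""
    row = calign.aa_rows[reference_id]
    residue_cols = [c for c, ch in enumerate(row) if ch not in (GAP, FS)]
    cols = []
    for pos in positions:
        if not 1 <= pos <= len(residue_cols):
            raise InputError(f"reference position {pos} outside reference row")
        cols.append(residue_cols[pos - 1])
    return cols


def flag_38_42_deletion(calign: CodonAlignment, seq_id: str,
                        reference_id: str,
                        positions: Sequence[int] = (38, 39, 40, 41, 42),
                        ) -> bool:
    """True iff every column mapping to the given reference positions is a gap."""
    cols = reference_position_columns(calign, reference_id, positions)
    row = calign.aa_rows[seq_id]
    return all(row[c] == GAP for c in cols)


def classify_activity(call: MotifCall,
                      rules: ActivityRuleSet = DEFAULT_RULES) -> MotifCall:
    """Assign the three-tier activity verdict; records every fired rule."""
    for motif, label in ((call.b1, "B1"), (call.c2, "C2")):
        bad = set(motif) - VALID_AA
        if bad:
            raise InputError(f"non-amino-acid characters in {label}: {sorted(bad)}")
    trace: list[str] = []
    if call.b1 in rules.active_b1 and call.c2 in rules.active_c2:
        call.activity = PREDICTED_ACTIVE
        call.rules_fired = [f"canonical pair {call.b1}+{call.c2}"]
        return call
    inactive = False
    if len(call.b1) != len(rules.b1):
        trace.append(f"B1 length {len(call.b1)} != {len(rules.b1)}")
        inactive = True
    if len(call.c2) != len(rules.c2):
        trace.append(f"C2 length {len(call.c2)} != {len(rules.c2)}")
        inactive = True
    b1_dev = c2_dev = 0
    if not inactive:
        for label, motif, pos_rules in (("B1", call.b1, rules.b1),
                                        ("C2", call.c2, rules.c2)):
            for i, (residue, rule) in enumerate(zip(motif, pos_rules), 1):
                verdict = rule.judge(residue)
                if verdict == "disallowed":
                    trace.append(f"{label}[{i}]={residue} disallowed")
                    inactive = True
                elif verdict == "deviation":
                    trace.append(f"{label}[{i}]={residue} tolerated deviation")
                    if label == "B1":
                        b1_dev += 1
                    else:
                        c2_dev += 1
        if b1_dev > rules.max_b1_deviations:
            trace.append(f"B1 deviations {b1_dev} > {rules.max_b1_deviations}")
            inactive = True
        if rules.both_motif_deviation_inactive and b1_dev and c2_dev:
            trace.append("deviations in both B1 and C2")
            inactive = True
    call.activity = PREDICTED_INACTIVE if inactive else POTENTIALLY_ACTIVE
    call.rules_fired = trace or ["no deviations from tolerated sets"]
    return call


def tabulate_motifs(calls: Sequence[MotifCall]) -> pd.DataFrame:
    """Frequency table of (B1, C2) pairs; interrupted rows are excluded.

    Sorted by count descending, then lexicographically; counts sum to the
    number of uninterrupted calls.
    """
    kept = [c for c in calls if c.interrupted == "none"]
    if not kept:
        return pd.DataFrame(columns=["count", "b1", "c2", "activity"])
    rows: dict[tuple[str, str, str], int] = {}
    for call in kept:
        key = (call.b1, call.c2, call.activity or "")
        rows[key] = rows.get(key, 0) + 1
    table = pd.DataFrame(
        [(n, b1, c2, act) for (b1, c2, act), n in rows.items()],
        columns=["count", "b1", "c2", "activity"])
    table = table.sort_values(["count", "b1", "c2"],
                              ascending=[False, True, True],
                              kind="mergesort").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# published motif survey (golden fixture)
# ---------------------------------------------------------------------------

def load_motif_survey() -> pd.DataFrame:
    """Curated ERVK B1/C2 motif pairs with literature activity annotations."""
    from importlib.resources import files

    path = files("ervscan.data").joinpath("ervk_motif_survey.tsv")
    with path.open("r", encoding="utf-8") as handle:
        table = pd.read_csv(handle, sep="\t", keep_default_na=False)
    return table


def evaluate_against_survey(rules: ActivityRuleSet = DEFAULT_RULES,
                            ) -> tuple[float, pd.DataFrame]:
    """Classify every surveyed motif pair and compare with its annotation.

    Returns the agreement fraction and an exception report listing each
    mismatching pair with the predicted class and the rules fired.
    """
    survey = load_motif_survey()
    predicted = []
    traces = []
    for _, row in survey.iterrows():
        call = classify_activity(MotifCall(seq_id="survey",
                                           b1=row["b1"], c2=row["c2"]),
                                 rules)
        predicted.append(call.activity)
        traces.append("; ".join(call.rules_fired))
    survey = survey.assign(predicted_class=predicted, rules_fired=traces)
    mismatches = survey[survey["predicted_class"]
                        != survey["published_class"]].copy()
    agreement = 1.0 - len(mismatches) / len(survey)
    return agreement, mismatches
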