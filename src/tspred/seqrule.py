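"""Sequence-based burial prediction.

A residue buried in the hydrophobic core tends to sit in a locally
hydrophobic stretch of sequence whose hydrophobicity is distributed
evenly around the helical wheel. Two windowed quantities capture this:

* mean_H — the arithmetic mean hydrophobicity of a window centred on the
  target residue (Rose mean-fractional-buried-area scale by default);
* mu_H — the hydrophobic moment, the magnitude of the vector sum of the
  window hydrophobicities placed at successive angles delta apart
  (delta = 100 deg for an alpha helix):

      mu_H = | sum_n H(n) * (cos n*delta, sin n*delta) |

A position is called buried when mean_H >= tau_H and mu_H <= tau_mu
(hydrophobic surroundings, no marked amphipathic asymmetry). Of the
hydrophobic residues, only Val, Ile, Leu, Met, Phe and Trp are mutation
targets; Cys is excluded because of possible disulphide bonds or metal
coordination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import BoundaryError, InputError

#: Mean fractional buried surface area per residue in folded proteins
#: (Rose et al. scale); higher = more buried on average.
ROSE_SCALE: dict[str, float] = {
    "A": 0.74, "R": 0.64, "N": 0.63, "D": 0.62, "C": 0.91,
    "Q": 0.62, "E": 0.62, "G": 0.72, "H": 0.78, "I": 0.88,
    "L": 0.85, "K": 0.52, "M": 0.85, "F": 0.88, "P": 0.64,
    "S": 0.66, "T": 0.70, "W": 0.85, "Y": 0.76, "V": 0.86,
}

#: Hydrophobic residues targeted for Ts mutations ('C' deliberately absent).
TARGET_RESIDUES = frozenset("VILMFW")


def _scale_value(scale: dict[str, float], letter: str) -> float:
    if letter in scale:
        return scale[letter]
    # ambiguous letters (B, Z, X...) take the scale mean and are never
    # themselves predicted
    return sum(scale.values()) / len(scale)


@dataclass(frozen=True)
class SequenceRuleParams:
    """Window geometry, thresholds and scale of the sequence rule.

    window
        Odd window size w; the target residue plus (w-1)/2 flanking
        neighbours on each side.
    delta
        Angular period in degrees between successive residues (100 for an
        alpha helix).
    tau_H
        Minimum windowed mean hydrophobicity for a buried call.
    tau_mu
        Maximum hydrophobic-moment magnitude for a buried call.
    terminal_policy
        'truncate' scores terminal residues with a shortened window;
        'skip' leaves positions without a full window unscored.
    """

    window: int = 5
    delta: float = 100.0
    tau_H: float = 0.78
    tau_mu: float = 1.10
    scale: dict[str, float] = field(default_factory=lambda: dict(ROSE_SCALE))
    terminal_policy: str = "truncate"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise InputError("window must be odd and >= 1")
        if not 0 < self.delta < 360:
            raise InputError("delta must be in (0, 360) degrees")
        if self.terminal_policy not in ("skip", "truncate"):
            raise InputError("terminal_policy must be 'skip' or 'truncate'")
        missing = [aa for aa in "ACDEFGHIKLMNPQRSTVWY" if aa not in self.scale]
        if missing:
            raise InputError(f"hydrophobicity scale missing residues: {''.join(missing)}")

    @property
    def half(self) -> int:
        return (self.window - 1) // 2


@dataclass
class PositionScore:
    """Windowed scores at one sequence position (0-based)."""

    position: int
    residue: str
    mean_H: float
    mu_H: float
    in_target_set: bool


def _window_indices(seq: str, i: int, p: SequenceRuleParams) -> range:
    if not 0 <= i < len(seq):
        raise BoundaryError(f"position {i} outside sequence of length {len(seq)}")
    lo, hi = i - p.half, i + p.half
    if lo < 0 or hi >= len(seq):
        if p.terminal_policy == "skip":
            raise BoundaryError(
                f"position {i}: window extends past the terminus (terminal_policy='skip')"
            )
        lo, hi = max(lo, 0), min(hi, len(seq) - 1)
    return range(lo, hi + 1)


def window_hydrophobicity(seq: str, i: int, p: SequenceRuleParams | None = None) -> float:
    """Mean scale value over the window centred at position ``i`` (0-based)."""
    p = p or SequenceRuleParams()
    idx = _window_indices(seq, i, p)
    return sum(_scale_value(p.scale, seq[j]) for j in idx) / len(idx)


def hydrophobic_moment(seq: str, i: int, p: SequenceRuleParams | None = None) -> float:
    """Hydrophobic moment magnitude of the window centred at ``i``.

    Residue j contributes its hydrophobicity at angle (j - i) * delta;
    the moment is the magnitude of the 2-vector sum.
    """
    p = p or SequenceRuleParams()
    idx = _window_indices(seq, i, p)
    x = y = 0.0
    for j in idx:
        h = _scale_value(p.scale, seq[j])
        ang = math.radians((j - i) * p.delta)
        x += h * math.cos(ang)
        y += h * math.sin(ang)
    return math.hypot(x, y)


def sequence_profile(seq: str, p: SequenceRuleParams | None = None) -> list[PositionScore]:
    """Score every position admitted by the terminal policy."""
    p = p or SequenceRuleParams()
    if not seq:
        raise InputError("empty sequence")
    seq = seq.upper()
    out: list[PositionScore] = []
    for i, aa in enumerate(seq):
        try:
            mean_h = window_hydrophobicity(seq, i, p)
            mu = hydrophobic_moment(seq, i, p)
        except BoundaryError:
            continue
        out.append(
            PositionScore(
                position=i,
                residue=aa,
                mean_H=mean_h,
                mu_H=mu,
                in_target_set=aa in TARGET_RESIDUES,
            )
        )
    return out


def predict_buried_sequence(seq: str, p: SequenceRuleParams | None = None):
    """Positions predicted buried by the two-threshold sequence rule.

    Returns :class:`~tspred.tspredict.PredictionRecord` objects, one per
    predicted position (1-based author-style numbering over the input
    sequence). Only Val/Ile/Leu/Met/Phe/Trp can be predicted; Cys and
    ambiguous letters never are.
    """
    from .structio import ONE_TO_THREE
    from .tspredict import PredictionRecord

    p = p or SequenceRuleParams()
    records = set()
    for score in sequence_profile(seq, p):
        if not score.in_target_set:
            continue
        if score.mean_H >= p.tau_H and score.mu_H <= p.tau_mu:
            records.add(
                PredictionRecord(
                    position=score.position + 1,
                    res_name=ONE_TO_THREE[score.residue],
                    methods=frozenset({"sequence"}),
                    mean_H=round(score.mean_H, 6),
                    mu_H=round(score.mu_H, 6),
                )
            )
    return records


def write_profile_tsv(seq: str, p: SequenceRuleParams | None = None) -> str:
    """Per-position profile TSV: position, residue, mean_H, mu_H, predicted."""
    p = p or SequenceRuleParams()
    predicted = {r.position for r in predict_buried_sequence(seq, p)}
    lines = ["position\tresidue\tmean_H\tmu_H\tpredicted"]
    for s in sequence_profile(seq, p):
        pos1 = s.position + 1
        lines.append(
            f"{pos1}\t{s.residue}\t{s.mean_H:.4f}\t{s.mu_H:.4f}\t{int(pos1 in predicted)}"
        )
    return "\n".join(lines) + "\n"
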