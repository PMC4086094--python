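"""Combine predictions, suggest substitutions, gate models, evaluate.

The sequence and structure rules each emit a set of candidate positions;
this module merges them (labelling each position sequence / structure /
both), attaches the five destabilizing substitutions (Ala, Trp, Asn, Asp,
Pro minus the wild type, unranked), gates homology models on externally
computed reliability scores (GA341, normalized DOPE), and scores
prediction sets against experimentally validated Ts positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConsistencyError, InputError

#: Stereochemically diverse substitutions suggested at predicted positions.
SUGGESTED_SUBSTITUTIONS = frozenset({"ALA", "TRP", "ASN", "ASP", "PRO"})

TARGET_TYPES = frozenset({"VAL", "ILE", "LEU", "MET", "PHE", "TRP"})

GA341_CUTOFF = 0.75
DOPE_CUTOFF = -1.0


@dataclass(frozen=True)
class PredictionRecord:
    """A candidate Ts position with method provenance and substitutions.

    ``position`` is the author residue number; ``methods`` is a non-empty
    subset of {'sequence', 'structure'}. Optional per-method metadata
    (mean depth, windowed hydrophobicity, moment) rides along for
    reporting.
    """

    position: int
    res_name: str
    methods: frozenset = frozenset({"sequence"})
    suggested: frozenset = None  # type: ignore[assignment]
    mean_depth: float | None = None
    mean_H: float | None = None
    mu_H: float | None = None
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.methods or not set(self.methods) <= {"sequence", "structure"}:
            raise InputError("methods must be a non-empty subset of {sequence, structure}")
        if self.res_name not in TARGET_TYPES:
            raise InputError(
                f"{self.res_name} at {self.position} is not a Ts mutation target type"
            )
        if self.suggested is None:
            object.__setattr__(self, "suggested", SUGGESTED_SUBSTITUTIONS - {self.res_name})
        if self.res_name in self.suggested:
            raise InputError("suggested substitutions must exclude the wild type")

    @property
    def method_label(self) -> str:
        return "both" if len(self.methods) == 2 else next(iter(self.methods))


def suggest_mutations(record_or_resname: "PredictionRecord | str") -> frozenset:
    """The unranked substitution set for a predicted position.

    Ala (cavity), Trp (over-packing), Asn/Asp (buried polar/charge) and
    Pro (backbone strain) minus the wild-type residue. Only the six
    hydrophobic target types are valid wild types; Cys in particular is
    never a target.
    """
    res_name = (
        record_or_resname.res_name
        if isinstance(record_or_resname, PredictionRecord)
        else record_or_resname.upper()
    )
    if res_name not in TARGET_TYPES:
        raise InputError(f"{res_name} is not a Ts mutation target")
    return SUGGESTED_SUBSTITUTIONS - {res_name}


def combine_predictions(
    seq_set: set[PredictionRecord],
    struct_set: set[PredictionRecord],
) -> set[PredictionRecord]:
    """Union of sequence and structure predictions keyed by author position.

    Positions present in both sets are labelled with both methods and
    their metadata merged. A position claimed with two different
    wild-type residues is a consistency error. Commutative and
    idempotent.
    """
    merged: dict[tuple[int, str], PredictionRecord] = {}
    for rec in list(seq_set) + list(struct_set):
        key = (rec.position, rec.insertion_code)
        prev = merged.get(key)
        if prev is None:
            merged[key] = rec
            continue
        if prev.res_name != rec.res_name:
            raise ConsistencyError(
                f"position {rec.position}: wild type {prev.res_name} vs {rec.res_name}"
            )
        merged[key] = PredictionRecord(
            position=rec.position,
            res_name=rec.res_name,
            methods=prev.methods | rec.methods,
            mean_depth=prev.mean_depth if prev.mean_depth is not None else rec.mean_depth,
            mean_H=prev.mean_H if prev.mean_H is not None else rec.mean_H,
            mu_H=prev.mu_H if prev.mu_H is not None else rec.mu_H,
            insertion_code=rec.insertion_code,
        )
    return set(merged.values())


@dataclass(frozen=True)
class ModelScores:
    """Homology-model reliability scores supplied by an external modeller."""

    ga341: float
    dope: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ga341 <= 1.0:
            raise InputError("GA341 score must lie in [0, 1]")


def assess_model(m: ModelScores) -> bool:
    """Accept a homology model for structure-based prediction?

    Accept iff GA341 >= 0.75 and normalized DOPE <= -1 (both boundaries
    inclusive). On rejection the caller should fall back to sequence-only
    prediction.
    """
    return m.ga341 >= GA341_CUTOFF and m.dope <= DOPE_CUTOFF


def jaccard_index(a: set, b: set) -> float:
    """|a & b| / |a | b|; 0.0 for two empty sets."""
    union = set(a) | set(b)
    if not union:
        return 0.0
    return len(set(a) & set(b)) / len(union)


@dataclass
class EvaluationReport:
    """Prediction-set performance against validated Ts positions.

    coverage counts every prediction; precision is computed only over
    predictions whose experimental status is known (an untested
    prediction is neither a hit nor a false positive).
    """

    n_predictions: int
    n_known_status: int
    n_validated_hits: int
    precision: float | None
    jaccard: float
    precision_defined: bool = True

    @property
    def coverage(self) -> int:
        return self.n_predictions


def evaluate(
    predictions: set,
    validated: set,
    universe: set | None = None,
) -> EvaluationReport:
    """Score a prediction set against experimentally validated positions.

    ``predictions`` and ``validated`` are sets of hashable position keys
    (author numbers, or (position, residue) pairs). ``universe`` is the
    set of positions with known experimental status; when omitted it
    defaults to ``validated``, i.e. every non-validated prediction counts
    as untested rather than wrong.
    """
    predictions = set(predictions)
    validated = set(validated)
    known = set(universe) if universe is not None else validated
    known |= validated

    hits = predictions & validated
    denom = predictions & known
    precision = len(hits) / len(denom) if denom else None
    return EvaluationReport(
        n_predictions=len(predictions),
        n_known_status=len(denom),
        n_validated_hits=len(hits),
        precision=precision,
        jaccard=jaccard_index(predictions, validated),
        precision_defined=bool(denom),
    )


def write_predictions_tsv(records: set[PredictionRecord]) -> str:
    """Predictions as TSV: position, wildtype, method, suggestions, scores."""

    def fmt(x: float | None) -> str:
        return "" if x is None else f"{x:.3f}"

    lines = ["position\twildtype\tmethod\tsuggestions\tmean_depth\tmean_H\tmu_H"]
    for rec in sorted(records, key=lambda r: (r.position, r.insertion_code)):
        lines.append(
            f"{rec.position}{rec.insertion_code}\t{rec.res_name}\t{rec.method_label}\t"
            f"{','.join(sorted(rec.suggested))}\t{fmt(rec.mean_depth)}\t"
            f"{fmt(rec.mean_H)}\t{fmt(rec.mu_H)}"
        )
    return "\n".join(lines) + "\n"
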