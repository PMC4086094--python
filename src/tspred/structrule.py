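"""Structure-based burial prediction: residue-depth thresholds.

A hydrophobic residue deeper than its type-specific threshold depth is
called buried and becomes a Ts mutation target. The thresholds correspond
to the depth at which each residue type reaches ~5% mean side-chain
solvent accessibility, derived once from a non-redundant high-resolution
structure corpus and used here as constants.
"""

from __future__ import annotations

from .depth import ResidueDepthProfile
from .errors import InputError

#: Depth (A) beyond which each target residue type is considered buried.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "VAL": 6.25,
    "ILE": 6.75,
    "LEU": 6.75,
    "MET": 7.00,
    "PHE": 7.00,
    "TRP": 7.00,
}


def validate_thresholds(t: dict[str, float]) -> dict[str, float]:
    if set(t) != set(DEFAULT_THRESHOLDS):
        raise InputError(
            "thresholds must cover exactly VAL, ILE, LEU, MET, PHE, TRP"
        )
    if any(v <= 0 for v in t.values()):
        raise InputError("depth thresholds must be positive")
    return dict(t)


def predict_buried_structure(
    profile: ResidueDepthProfile,
    thresholds: dict[str, float] | None = None,
):
    """Residues strictly deeper than their type threshold.

    Returns :class:`~tspred.tspredict.PredictionRecord` objects keyed by
    author position. Residue types outside the six-type table are never
    predicted. For assemblies where the same author position occurs in
    several chains, the position is predicted if ANY copy exceeds the
    threshold and its reported depth is the maximum over copies.
    """
    from .tspredict import PredictionRecord

    thresholds = validate_thresholds(thresholds or DEFAULT_THRESHOLDS)
    # collapse symmetry copies to author position
    best: dict[tuple[int, str, str], float] = {}
    for key in profile.keys():
        if key.res_name not in thresholds:
            continue
        pos = (key.seq_num, key.insertion_code, key.res_name)
        d = profile.mean_depth[key]
        if pos not in best or d > best[pos]:
            best[pos] = d

    records = set()
    for (seq_num, icode, res_name), d in best.items():
        if d > thresholds[res_name]:
            records.add(
                PredictionRecord(
                    position=seq_num,
                    res_name=res_name,
                    methods=frozenset({"structure"}),
                    mean_depth=round(d, 6),
                    insertion_code=icode,
                )
            )
    return records
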