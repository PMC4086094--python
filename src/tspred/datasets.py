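"""Bundled benchmark data.

Small published datasets shipped with the package: the CcdB case-study
prediction lists with their experimental Ts status, the 15 externally
computed homology-model reliability scores used to exercise the model
gate, and the six-protein validated Ts-position benchmark table.
"""

from __future__ import annotations

import csv
import json
from importlib import resources

from .tspredict import PredictionRecord


def _data_text(name: str) -> str:
    return resources.files("tspred.data").joinpath(name).read_text()


def load_ccdb_benchmark() -> dict:
    """CcdB case-study lists as PredictionRecord sets plus status metadata.

    Returns a dict with 'sequence' and 'structure' prediction sets, the
    set of experimentally 'validated' positions, the 'known_status'
    universe (validated plus confirmed false positives) and the raw
    metadata under 'meta'.
    """
    raw = json.loads(_data_text("ccdb_benchmark.json"))
    seq = {
        PredictionRecord(position=pos, res_name=res, methods=frozenset({"sequence"}))
        for pos, res in raw["sequence_predictions"]
    }
    struct = {
        PredictionRecord(position=pos, res_name=res, methods=frozenset({"structure"}))
        for pos, res in raw["structure_predictions"]
    }
    all_positions = {r.position for r in seq | struct}
    false_pos = set(raw["false_positive_positions"])
    return {
        "sequence": seq,
        "structure": struct,
        "validated": all_positions - false_pos,
        "known_status": all_positions,
        "false_positives": false_pos,
        "meta": raw,
    }


def load_model_scores() -> list[dict]:
    """Externally computed (GA341, DOPE) scores for 15 homology models."""
    rows = []
    reader = csv.DictReader(_data_text("model_scores.tsv").splitlines(), delimiter="\t")
    for row in reader:
        rows.append(
            {
                "template": row["template"],
                "seq_id_pct": float(row["seq_id_pct"]),
                "dope": float(row["dope"]),
                "ga341": float(row["ga341"]),
            }
        )
    return rows


def load_ts_benchmark() -> list[dict]:
    """Validated Ts-position benchmark across six proteins."""
    rows = []
    reader = csv.DictReader(
        _data_text("ts_benchmark_positions.tsv").splitlines(), delimiter="\t"
    )
    for row in reader:
        rows.append(
            {
                "protein": row["protein"],
                "pdb_id": row["pdb_id"],
                "chain_length": int(row["chain_length"]),
                "position": int(row["position"]),
                "res_name": row["res_name"],
                "method": row["method"],
                "validated": bool(int(row["validated"])),
            }
        )
    return rows
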