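"""Character-matrix input and table output.

Character matrices arrive either as a two-column ``taxon,state`` CSV/TSV
(ambiguity sets use ``&``, unknowns ``?``) or as a NEXUS standard-characters
block (one character; ``{ab}`` polymorphism becomes an ``a&b`` set).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd


class FormatError(ValueError):
    pass


def read_character_matrix(path: str | Path) -> dict[str, str]:
    """Read taxon -> state-code mapping from CSV/TSV or NEXUS."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".nex", ".nexus"}:
        return _read_nexus_characters(path)
    sep = "\t" if suffix in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in frame.columns}
    if "taxon" not in cols or "state" not in cols:
        raise FormatError("character table needs 'taxon' and 'state' columns")
    taxa = frame[cols["taxon"]].astype(str)
    if taxa.duplicated().any():
        raise FormatError("duplicate taxon in character table")
    return dict(zip(taxa, frame[cols["state"]].astype(str)))


def _read_nexus_characters(path: Path) -> dict[str, str]:
    try:
        mat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:
        raise FormatError(f"unreadable NEXUS characters: {exc}") from exc
    codes: dict[str, str] = {}
    for taxon in mat:
        seq = mat[taxon]
        if len(seq) != 1:
            raise FormatError("expected a single-character NEXUS matrix")
        cell = seq[0]
        sym = getattr(cell, "symbol", None)
        member = getattr(cell, "member_states", None)
        if sym in {"?", "-"}:
            codes[taxon.label] = "?"
        elif member and len(member) > 1:
            codes[taxon.label] = "&".join(sorted(s.symbol for s in member))
        else:
            codes[taxon.label] = sym if sym is not None else str(cell)
    return codes


def write_character_matrix(codes: Mapping[str, str], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"taxon": list(codes), "state": [codes[t] for t in codes]}
    )
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame.to_csv(path, sep=sep, index=False)


def write_marginals_json(table, path: str | Path) -> None:
    payload = {
        "states": list(table.states),
        "nodes": [
            {"node": nid, "is_tip": bool(tip),
             "probabilities": [round(float(p), 10) for p in row]}
            for nid, tip, row in zip(table.node_ids, table.is_tip, table.probs)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
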