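"""Readers and writers for the flat-file formats the commands exchange.

All writers emit "\n" line endings and "." decimal separators regardless
of locale, so reruns are byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .joint_model import PredictionMatrix
from .ontology import AnnotationSet, OntologyGraph

_NAMESPACE_LONG = {"MF": "molecular_function", "CC": "cellular_component", "BP": "biological_process"}


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Serialize an ontology back to OBO flat-file format."""
    by_child: dict[str, list[tuple[str, str]]] = {}
    for c, p, rel in graph.edges:
        by_child.setdefault(c, []).append((p, rel))
    lines = ["format-version: 1.2", ""]
    for t in graph.terms:
        lines += [
            "[Term]",
            f"id: {t}",
            f"name: {t}",
            f"namespace: {_NAMESPACE_LONG[graph.namespace[t]]}",
            f'def: "{graph.definitions.get(t, t)}" [synthetic]',
        ]
        for p, rel in sorted(by_child.get(t, [])):
            lines.append(f"is_a: {p}" if rel == "is_a" else f"relationship: part_of {p}")
        lines.append("")
    Path(path).write_text("\n".join(lines), newline="\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id; gaps and stop '*' stripped."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper().replace("-", "").replace("*", "")
    return out


def write_annotations(anns: AnnotationSet, path: str | Path) -> None:
    lines = ["#protein_id\tterm_id\tevidence_code"]
    lines += [f"{p}\t{t}\t{c}" for p, t, c in anns.records]
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def read_annotations(path: str | Path, closed: bool = False) -> AnnotationSet:
    records = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed annotation line: {raw!r}")
        protein, term = fields[0], fields[1]
        code = fields[2] if len(fields) > 2 else "EXP"
        records.append((protein, term, code))
    return AnnotationSet(records=records, closed=closed)


def write_feature_table(
    protein_ids: Sequence[str], features: np.ndarray, path: str | Path
) -> None:
    """protein_id + one column per feature dimension, tab-separated."""
    df = pd.DataFrame(features, columns=[f"f{i}" for i in range(features.shape[1])])
    df.insert(0, "protein_id", list(protein_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.8g", lineterminator="\n")


def read_feature_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    ids = df["protein_id"].astype(str).tolist()
    return ids, df.drop(columns="protein_id").to_numpy(dtype=float)


def write_label_embedding(terms: Sequence[str], Z: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(Z, columns=[f"z{i}" for i in range(Z.shape[1])])
    df.insert(0, "term_id", list(terms))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_label_embedding(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    terms = df["term_id"].astype(str).tolist()
    return terms, df.drop(columns="term_id").to_numpy(dtype=float)


def write_predictions(
    preds: PredictionMatrix, path: str | Path, floor: float = 0.01
) -> None:
    """CAFA-style prediction TSV: one (protein, term, score) line per pair.

    Scores are rounded to 3 decimals; rounded scores below ``floor`` are
    omitted.
    """
    lines = ["protein_id\tterm_id\tscore"]
    for i, pid in enumerate(preds.protein_ids):
        row = preds.scores[i]
        for j, t in enumerate(preds.terms):
            s = round(float(row[j]), 3)
            if s >= floor:
                lines.append(f"{pid}\t{t}\t{s:.3f}")
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def read_predictions(
    path: str | Path, protein_ids: Sequence[str], terms: Sequence[str]
) -> np.ndarray:
    """Prediction TSV -> dense score matrix (missing pairs score 0)."""
    p_index = {p: i for i, p in enumerate(protein_ids)}
    t_index = {t: j for j, t in enumerate(terms)}
    scores = np.zeros((len(protein_ids), len(terms)))
    lines = Path(path).read_text().splitlines()
    body = [l for l in lines if l.strip() and not l.startswith(("#", "protein_id"))]
    if not body:
        raise ValueError(f"prediction file {path} contains no score lines")
    for raw in body:
        pid, term, score = raw.split("\t")
        i, j = p_index.get(pid), t_index.get(term)
        if i is not None and j is not None:
            scores[i, j] = float(score)
    return scores


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", newline="\n")
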