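"""File formats and run products.

The single tabular dialect is TSV (tab-separated, header, UTF-8, '.'
decimal).  Sequences travel as FASTA with a TSV annotation file
(columns: id, tmd_start, tmd_stop, label[, sequence]); sequences may
alternatively be inlined in the TSV.  Figures are rendered from the
tables, never the other way around.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence_parts import Label, ProteinEntry

ANNOT_COLUMNS = ("id", "tmd_start", "tmd_stop", "label")


def read_dataset(
    annot_path, fasta_path: Optional[str] = None
) -> List[ProteinEntry]:
    """Merge a TSV annotation file with FASTA sequences into entries.

    Raises on duplicate ids, annotation rows without a sequence, and
    FASTA records that the annotation does not mention are ignored.
    """
    annot = pd.read_csv(annot_path, sep="\t", dtype={"id": str})
    missing = [c for c in ANNOT_COLUMNS if c not in annot.columns]
    if missing:
        raise ValueError(f"annotation file lacks columns: {missing}")
    if annot["id"].duplicated().any():
        dups = annot.loc[annot["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in annotation: {dups[:5]}")
    seqs: Dict[str, str] = {}
    if fasta_path is not None:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate FASTA record: {rec.id}")
            seqs[rec.id] = str(rec.seq).upper()
    entries = []
    for _, row in annot.iterrows():
        pid = str(row["id"])
        if "sequence" in annot.columns and isinstance(row.get("sequence"), str):
            seq = row["sequence"].upper()
        elif pid in seqs:
            seq = seqs[pid]
        else:
            raise ValueError(f"no sequence for annotation id {pid!r}")
        entries.append(
            ProteinEntry(
                id=pid,
                sequence=seq,
                tmd_start=int(row["tmd_start"]),
                tmd_stop=int(row["tmd_stop"]),
                label=Label(str(row["label"])),
            )
        )
    return entries


def write_dataset(
    entries: Sequence[ProteinEntry], fasta_path, annot_path
) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.id, description="") for e in entries
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "id": [e.id for e in entries],
            "tmd_start": [e.tmd_start for e in entries],
            "tmd_stop": [e.tmd_stop for e in entries],
            "label": [e.label.value for e in entries],
        }
    ).to_csv(annot_path, sep="\t", index=False)


def labels_series(entries: Sequence[ProteinEntry]) -> pd.Series:
    return pd.Series(
        {e.id: e.label.value for e in entries}, name="label"
    )


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_outputs(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    config: Optional[Mapping] = None,
    figures: Optional[Mapping[str, object]] = None,
) -> Dict[str, object]:
    """Write TSV tables (and matplotlib figures) plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    products = []
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        products.append(path.name)
    if figures:
        for name, fig in figures.items():
            path = out / f"{name}.png"
            fig.savefig(path, dpi=150, bbox_inches="tight")
            products.append(path.name)
    manifest = {
        "products": sorted(products),
        "config_hash": config_hash(config or {}),
        "config": dict(config or {}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
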